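"""Deterministic named child seeds from a single root seed.

Every source of randomness in a run (cohort draw, fold split, weight
initialization, augmentation noise) derives its own stream from the root seed
and a name path, so stages can be rerun independently yet reproducibly.
"""

from __future__ import annotations

import hashlib


def derive_seed(root: int, *names) -> int:
    """Stable 31-bit child seed for the stream named by ``names``."""
    key = "/".join(str(x) for x in (root, *names))
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
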