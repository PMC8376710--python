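"""84-node brain parcellation: Desikan-Killiany cortex plus subcortical and cerebellar nodes.

The canonical node set used throughout the package is the 68-region
Desikan-Killiany cortical parcellation (34 per hemisphere) extended with eight
bilateral subcortical/cerebellar grey-matter nodes (thalamus, caudate, putamen,
pallidum, hippocampus, amygdala, accumbens area, cerebellar cortex), for a
total of 84 nodes.  Connectome matrices are always indexed in the canonical
order defined here: all left-hemisphere regions first (cortex, then
subcortical, then cerebellar cortex), then the right hemisphere in the same
within-hemisphere order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

N_NODES = 84

_DK_CORTICAL = (
    "banks of superior temporal sulcus",
    "caudal anterior cingulate",
    "caudal middle frontal",
    "cuneus",
    "entorhinal",
    "frontal pole",
    "fusiform",
    "inferior parietal",
    "inferior temporal",
    "insula",
    "isthmus cingulate",
    "lateral occipital",
    "lateral orbitofrontal",
    "lingual",
    "medial orbitofrontal",
    "middle temporal",
    "paracentral",
    "parahippocampal",
    "pars opercularis",
    "pars orbitalis",
    "pars triangularis",
    "pericalcarine",
    "postcentral",
    "posterior cingulate",
    "precentral",
    "precuneus",
    "rostral anterior cingulate",
    "rostral middle frontal",
    "superior frontal",
    "superior parietal",
    "superior temporal",
    "supramarginal",
    "temporal pole",
    "transverse temporal",
)

_SUBCORTICAL = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
    "accumbens area",
    "cerebellar cortex",
)


@dataclass(frozen=True)
class NodeAtlas:
    """Ordered node labels with a hemisphere tag per label.

    Parameters
    ----------
    labels
        Region names in canonical matrix order.  Must be unique.
    hemisphere
        One of ``"left"``, ``"right"``, ``"midline"`` per label.
    """

    labels: tuple[str, ...]
    hemisphere: tuple[str, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.labels) != N_NODES:
            raise ValidationError(
                f"atlas must have exactly {N_NODES} labels, got {len(self.labels)}"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("atlas labels must be unique")
        if len(self.hemisphere) != len(self.labels):
            raise ValidationError("hemisphere tags must match labels one-to-one")
        bad = set(self.hemisphere) - {"left", "right", "midline"}
        if bad:
            raise ValidationError(f"unknown hemisphere tags: {sorted(bad)}")
        object.__setattr__(self, "_index", {lab: i for i, lab in enumerate(self.labels)})

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        """Canonical matrix row/column of ``label``."""
        try:
            return self._index[label]
        except KeyError:
            raise ValidationError(f"unknown atlas label: {label!r}") from None


def default_atlas() -> NodeAtlas:
    """The canonical 84-node atlas (68 DK cortical + 16 subcortical/cerebellar)."""
    labels: list[str] = []
    hemi: list[str] = []
    for side in ("Left", "Right"):
        for name in _DK_CORTICAL + _SUBCORTICAL:
            labels.append(f"{side} {name}")
            hemi.append(side.lower())
    return NodeAtlas(tuple(labels), tuple(hemi))


def read_atlas(path) -> NodeAtlas:
    """Read an atlas file: one ``label<TAB>hemisphere`` line per node."""
    labels: list[str] = []
    hemi: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            try:
                lab, h = line.rsplit("\t", 1)
            except ValueError:
                raise ValidationError(f"malformed atlas line: {line!r}") from None
            labels.append(lab)
            hemi.append(h.strip().lower())
    return NodeAtlas(tuple(labels), tuple(hemi))


def write_atlas(atlas: NodeAtlas, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for lab, h in zip(atlas.labels, atlas.hemisphere):
            fh.write(f"{lab}\t{h}\n")
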