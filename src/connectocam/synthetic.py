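"""Synthetic two-group connectome cohorts with planted edge effects.

Real structural connectomes are symmetric, non-negative, sparse and
heavy-tailed: a minority of region pairs carries most streamlines, and
streamline counts vary over orders of magnitude.  The generator emulates this
with a log-normal edge-strength template shared by the whole cohort, a shared
binary sparsity scaffold, and multiplicative per-subject log-normal noise.
Group differences are planted multiplicatively on a designated set of edges
(default: basal-ganglia <-> cerebellar-cortex connections, the circuit family
implicated in Parkinson's disease), so matrices stay non-negative by
construction and every downstream stage — classification, paired AUC testing,
Grad-CAM attribution — can be exercised against a known ground truth.

The generator makes no attempt to simulate tractography, regional volume or
distance effects; see the methods note for what that implies about the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .atlas import NodeAtlas, default_atlas
from .cohort import RAW_PREFIX, CohortDataset, SubjectRecord
from .core import INDEX_MAP, N_EDGES, ConnectomeMatrix, devectorize, EdgeVector
from .errors import ConfigurationError

#: Basal-ganglia / cerebellar connections used as the default planted circuit:
#: the union of the connection lists the attribution stage is expected to
#: recover (pallidum, putamen, caudate, hippocampus, amygdala and accumbens
#: partners of the cerebellar cortex on either side).
DEFAULT_EFFECT_EDGES: tuple[tuple[str, str], ...] = (
    ("Left cerebellar cortex", "Right pallidum"),
    ("Left putamen", "Right cerebellar cortex"),
    ("Left pallidum", "Right cerebellar cortex"),
    ("Left cerebellar cortex", "Right cerebellar cortex"),
    ("Left cerebellar cortex", "Right putamen"),
    ("Left cerebellar cortex", "Right hippocampus"),
    ("Left cerebellar cortex", "Left pallidum"),
    ("Left caudate", "Right cerebellar cortex"),
    ("Right hippocampus", "Right cerebellar cortex"),
    ("Left pallidum", "Left accumbens area"),
    ("Right pallidum", "Right cerebellar cortex"),
    ("Left cerebellar cortex", "Left amygdala"),
    ("Left cerebellar cortex", "Left caudate"),
)


@dataclass(frozen=True)
class EffectSpec:
    """A multiplicative group effect on a set of connections.

    ``effect_size`` is the ratio between the patient and control group means
    on the affected edges; ``direction="increase"`` multiplies patient edges
    by the factor, ``"decrease"`` divides.
    """

    edges: tuple[tuple[str, str], ...] = DEFAULT_EFFECT_EDGES
    effect_size: float = 2.5
    direction: str = "increase"

    def __post_init__(self) -> None:
        if self.effect_size <= 0:
            raise ConfigurationError("effect_size must be > 0")
        if self.direction not in ("increase", "decrease"):
            raise ConfigurationError("direction must be 'increase' or 'decrease'")

    def edge_indices(self, atlas: NodeAtlas) -> list[tuple[int, int]]:
        out = []
        for a, b in self.edges:
            i, j = atlas.index(a), atlas.index(b)
            if i == j:
                raise ConfigurationError(f"effect edge connects {a!r} to itself")
            out.append((min(i, j), max(i, j)))
        return out


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of a simulated cohort.

    Defaults describe a two-group clinical imaging cohort of 115 subjects
    per group, with edge strengths drawn log-normally (natural-log mean 3.0,
    sd 1.0), 60 % of connections structurally present, and per-subject
    multiplicative noise with log-sd 0.3.
    """

    n_per_group: int = 115
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    subject_noise_sd: float = 0.3
    density: float = 0.6
    seed: int = 0
    effects: tuple[EffectSpec, ...] = (EffectSpec(),)
    param_metrics: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if not (0 < self.density <= 1):
            raise ConfigurationError("density must lie in (0, 1]")
        if self.baseline_log_sd < 0 or self.subject_noise_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")


def generate_cohort(cfg: CohortConfig, atlas: NodeAtlas | None = None) -> CohortDataset:
    """Draw a two-group cohort of NOS connectomes with planted effects.

    A binary scaffold (edge present/absent) and a log-normal template are
    drawn once per cohort; each subject's matrix is the group template times
    exp(subject noise) on present edges.  Edges named in an effect spec are
    always structurally present.  Identical config and seed give a
    bit-identical cohort.
    """
    atlas = atlas or default_atlas()
    rng = np.random.default_rng(cfg.seed)

    edge_of = {(int(i), int(j)): k for k, (i, j) in enumerate(INDEX_MAP)}
    planted: list[int] = []
    log_shift = np.zeros(N_EDGES)
    for eff in cfg.effects:
        delta = np.log(eff.effect_size) * (1 if eff.direction == "increase" else -1)
        for ij in eff.edge_indices(atlas):
            k = edge_of[ij]
            planted.append(k)
            log_shift[k] += delta

    present = rng.random(N_EDGES) < cfg.density
    present[planted] = True  # an effect on an absent edge would be vacuous

    template_log = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, N_EDGES)
    group_template = {
        "control": template_log,
        "patient": template_log + log_shift,
    }

    subjects: list[SubjectRecord] = []
    nos: dict[str, ConnectomeMatrix] = {}
    width = len(str(cfg.n_per_group))
    for group in ("patient", "control"):
        for k in range(cfg.n_per_group):
            sid = f"{group}{k + 1:0{width}d}"
            if group == "patient":
                side = "left" if k % 2 == 0 else "right"
            else:
                side = "none"
            subjects.append(SubjectRecord(sid, group, side))
            log_vals = group_template[group] + rng.normal(0.0, cfg.subject_noise_sd, N_EDGES)
            vals = np.where(present, np.exp(log_vals), 0.0)
            nos[sid] = ConnectomeMatrix(sid, "NOS", devectorize(EdgeVector(vals)))

    matrices: dict[str, dict[str, ConnectomeMatrix]] = {"NOS": nos}
    for name in cfg.param_metrics:
        matrices[RAW_PREFIX + name] = _generate_param_maps(
            name, subjects, present, rng
        )
    return CohortDataset(subjects, matrices, atlas)


def _generate_param_maps(name: str, subjects: list[SubjectRecord],
                         present: np.ndarray, rng: np.random.Generator,
                         ) -> dict[str, ConnectomeMatrix]:
    """Fraction-like tract-averaged parameter maps in (0, 1) on present edges.

    A Beta(5, 5) template per edge plus small per-subject jitter; no group
    effect of its own (weighted matrices inherit the NOS effects).
    """
    template = rng.beta(5.0, 5.0, N_EDGES)
    maps = {}
    for s in subjects:
        vals = np.clip(template + rng.normal(0.0, 0.05, N_EDGES), 0.01, 0.99)
        vals = np.where(present, vals, 0.0)
        maps[s.subject_id] = ConnectomeMatrix(s.subject_id, RAW_PREFIX + name,
                                              devectorize(EdgeVector(vals)))
    return maps


def edge_group_zscores(dataset: CohortDataset, metric: str = "NOS") -> np.ndarray:
    """Per-edge two-sample Welch z/t statistics (patient minus control) on
    log1p edge values.

    A CNN-free sanity oracle: on a cohort with multiplicative planted
    increases, planted edges should rank near the top of these statistics.
    """
    labels = dataset.labels()
    stack = np.array([
        np.log1p(dataset.matrices[metric][s.subject_id].values[np.triu_indices(84, 1)])
        for s in dataset.subjects
    ])
    pat, con = stack[labels == 1], stack[labels == 0]
    t, _ = stats.ttest_ind(pat, con, axis=0, equal_var=False)
    return np.nan_to_num(t)


def planted_edge_indices(cfg: CohortConfig, atlas: NodeAtlas | None = None) -> np.ndarray:
    """Flat edge-vector indices of all edges named in the config's effects."""
    atlas = atlas or default_atlas()
    edge_of = {(int(i), int(j)): k for k, (i, j) in enumerate(INDEX_MAP)}
    idx = sorted({edge_of[ij] for eff in cfg.effects for ij in eff.edge_indices(atlas)})
    return np.array(idx, dtype=int)
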