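"""Edge-level microstructure math and connectome preprocessing.

This module owns three things:

1. The microstructure identities used to derive axon volume fraction (AVF)
   and the g-ratio from myelin volume fraction (MVF) and NODDI compartment
   fractions::

       AVF = (1 - MVF) * (1 - ISOVF) * ICVF
       g   = sqrt(AVF / (MVF + AVF))

2. Parameter weighting of number-of-streamlines (NOS) connectomes: the
   weighted edge is the streamline count multiplied by the tract-averaged
   parameter value on that edge.

3. The exact, invertible transform from an 84x84 symmetric connectome to the
   normalized 60x60 grid consumed by the classifier: extract the 3486
   independent strict-upper-triangle edges ((84*84 - 84)/2), append 114 zeros
   to reach 3600 cells, reshape row-major to 60x60, and divide by the grid
   maximum.  ``reorganize_to_connectome`` is the exact inverse used to map
   Grad-CAM heat back onto the connection space.

Flattening is row-major over the strict upper triangle (i ascending, j
ascending within each row, i < j) and the padding zeros occupy the final 114
cells of the grid; every inverse map shares these conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import N_NODES
from .errors import DegenerateInputError, DomainError, ValidationError

#: All matrix types the pipeline knows about: the raw streamline-count matrix
#: plus 13 parameter weightings (4 DTI, 3 DKI, 3 NODDI, 3 g-ratio-family).
METRICS = (
    "NOS",
    "FA", "MD", "AD", "RD",
    "MK", "AK", "RK",
    "ICVF", "ISOVF", "ODI",
    "AVF", "MVF", "GRATIO",
)

#: The 11 tract-averaged parameter maps measured directly (AVF and GRATIO are
#: derived from MVF/ISOVF/ICVF).
MEASURED_PARAMS = ("FA", "MD", "AD", "RD", "MK", "AK", "RK", "ICVF", "ISOVF", "ODI", "MVF")

N_EDGES = (N_NODES * N_NODES - N_NODES) // 2  # 3486 independent connections
GRID_SIDE = 60
N_PAD = GRID_SIDE * GRID_SIDE - N_EDGES  # 114 zero cells
SYMMETRY_RTOL = 1e-8


def _upper_triangle_index_map() -> np.ndarray:
    """(3486, 2) array of (row, col) pairs, row-major, row < col."""
    iu = np.triu_indices(N_NODES, k=1)
    return np.stack(iu, axis=1)


INDEX_MAP = _upper_triangle_index_map()
INDEX_MAP.setflags(write=False)

#: Grid positions (row-major cell index >= 3486) that hold padding zeros.
PAD_CELLS = tuple((p // GRID_SIDE, p % GRID_SIDE) for p in range(N_EDGES, GRID_SIDE * GRID_SIDE))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MicrostructureEdgeParams:
    """Tract-averaged compartment fractions on one edge, each in [0, 1]."""

    mvf: float
    isovf: float
    icvf: float

    def __post_init__(self) -> None:
        for name in ("mvf", "isovf", "icvf"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class ConnectomeMatrix:
    """One subject's 84x84 symmetric non-negative connectivity for one metric."""

    subject_id: str
    metric: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_NODES, N_NODES):
            raise ValidationError(
                f"connectome must be {N_NODES}x{N_NODES}, got {v.shape}"
            )
        if np.any(v < 0):
            raise ValidationError("connectome entries must be non-negative")
        scale = max(np.abs(v).max(), 1.0)
        if not np.allclose(v, v.T, rtol=SYMMETRY_RTOL, atol=SYMMETRY_RTOL * scale):
            raise ValidationError("connectome must be symmetric")
        # Accept rounding noise from text files: store the symmetrized matrix.
        self.values = 0.5 * (v + v.T)


@dataclass
class EdgeVector:
    """The 3486 independent edges of a symmetric connectome plus their positions."""

    values: np.ndarray
    index_map: np.ndarray = field(default_factory=lambda: INDEX_MAP)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_EDGES,):
            raise ValidationError(f"edge vector must have length {N_EDGES}")


@dataclass
class ModelInput:
    """Normalized 60x60 grid fed to the classifier."""

    grid: np.ndarray
    source_subject: str = ""
    metric: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != (GRID_SIDE, GRID_SIDE):
            raise ValidationError(f"model input must be {GRID_SIDE}x{GRID_SIDE}")


# ---------------------------------------------------------------------------
# Microstructure formulas
# ---------------------------------------------------------------------------

def compute_avf(params: MicrostructureEdgeParams) -> float:
    """Axon volume fraction: AVF = (1 - MVF)(1 - ISOVF) ICVF."""
    return (1.0 - params.mvf) * (1.0 - params.isovf) * params.icvf


def compute_gratio(mvf: float, avf: float) -> float:
    """g-ratio = sqrt(AVF / (MVF + AVF)); undefined when both fractions vanish."""
    if mvf < 0 or avf < 0:
        raise DomainError("mvf and avf must be non-negative")
    total = mvf + avf
    if total == 0:
        raise DomainError("g-ratio undefined: mvf + avf == 0")
    return float(np.sqrt(avf / total))


def derive_avf_matrix(mvf: ConnectomeMatrix, isovf: ConnectomeMatrix,
                      icvf: ConnectomeMatrix) -> ConnectomeMatrix:
    """Elementwise AVF from edge-level MVF/ISOVF/ICVF maps.

    The voxelwise identity is applied to tract-averaged edge values, so the
    result is an edge-level approximation of the tract-averaged AVF.
    """
    for m in (mvf, isovf, icvf):
        if np.any(m.values > 1.0 + 1e-12):
            raise DomainError(f"{m.metric} map has entries above 1; volume fractions required")
    vals = (1.0 - mvf.values) * (1.0 - isovf.values) * icvf.values
    return ConnectomeMatrix(mvf.subject_id, "AVF", vals)


def derive_gratio_matrix(mvf: ConnectomeMatrix, avf: ConnectomeMatrix) -> ConnectomeMatrix:
    """Elementwise g-ratio map; edges with MVF + AVF == 0 are set to 0.

    Structurally absent edges carry no parameter estimate, so the undefined
    0/0 ratio there is mapped to zero by convention.
    """
    total = mvf.values + avf.values
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(total > 0, np.sqrt(np.divide(avf.values, total,
                                                  out=np.zeros_like(total),
                                                  where=total > 0)), 0.0)
    return ConnectomeMatrix(mvf.subject_id, "GRATIO", g)


# ---------------------------------------------------------------------------
# Weighting and the matrix suite
# ---------------------------------------------------------------------------

def weight_connectome(nos: ConnectomeMatrix, param_edges: ConnectomeMatrix) -> ConnectomeMatrix:
    """Parameter-weighted connectome: NOS times the tract-averaged parameter.

    The output inherits the NOS zero pattern (no streamlines, no weighted
    connection) and is labelled with the parameter's metric name.
    """
    if nos.metric != "NOS":
        raise ValidationError(f"first argument must be a NOS matrix, got {nos.metric!r}")
    if nos.values.shape != param_edges.values.shape:
        raise ValidationError("matrix shapes do not match")
    return ConnectomeMatrix(nos.subject_id, param_edges.metric,
                            nos.values * param_edges.values)


def build_matrix_suite(nos: ConnectomeMatrix,
                       params: dict[str, ConnectomeMatrix]) -> dict[str, ConnectomeMatrix]:
    """All 14 per-subject matrices: NOS plus 13 parameter weightings.

    ``params`` maps each of the 11 measured parameter names to its edge-level
    tract-averaged map; AVF and GRATIO maps are derived from MVF/ISOVF/ICVF
    before weighting.
    """
    missing = set(MEASURED_PARAMS) - set(params)
    if missing:
        raise ValidationError(f"missing parameter maps: {sorted(missing)}")
    maps = dict(params)
    maps["AVF"] = derive_avf_matrix(maps["MVF"], maps["ISOVF"], maps["ICVF"])
    maps["GRATIO"] = derive_gratio_matrix(maps["MVF"], maps["AVF"])
    suite = {"NOS": nos}
    for name in METRICS[1:]:
        suite[name] = weight_connectome(nos, maps[name])
    return suite


# ---------------------------------------------------------------------------
# Matrix <-> model-input transform and its inverse
# ---------------------------------------------------------------------------

def vectorize_upper(m: ConnectomeMatrix) -> EdgeVector:
    """Extract the 3486 strict-upper-triangle edges in row-major order.

    Diagonal (self-connection) entries are ignored.
    """
    iu = np.triu_indices(N_NODES, k=1)
    return EdgeVector(m.values[iu])


def devectorize(v: EdgeVector) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`: symmetric 84x84 with zero diagonal."""
    out = np.zeros((N_NODES, N_NODES))
    rows, cols = v.index_map[:, 0], v.index_map[:, 1]
    out[rows, cols] = v.values
    out[cols, rows] = v.values
    return out


def pad_and_reshape(v: EdgeVector, subject_id: str = "", metric: str = "") -> ModelInput:
    """Append 114 zeros (3486 + 114 = 3600) and reshape row-major to 60x60."""
    flat = np.concatenate([v.values, np.zeros(N_PAD)])
    return ModelInput(flat.reshape(GRID_SIDE, GRID_SIDE), subject_id, metric)


def normalize_input(x: ModelInput) -> ModelInput:
    """Divide every cell by the grid maximum so the largest entry becomes 1."""
    mx = x.grid.max()
    if mx <= 0:
        raise DegenerateInputError("cannot normalize an all-zero (or non-positive) grid")
    return ModelInput(x.grid / mx, x.source_subject, x.metric)


def preprocess_matrix(m: ConnectomeMatrix) -> ModelInput:
    """Full preprocessing chain: vectorize, pad, reshape, max-normalize."""
    return normalize_input(pad_and_reshape(vectorize_upper(m), m.subject_id, m.metric))


def reorganize_to_connectome(grid: np.ndarray,
                             index_map: np.ndarray = INDEX_MAP) -> np.ndarray:
    """Map a 60x60 grid back onto the 84x84 connection space.

    Exact inverse of ``pad_and_reshape(vectorize_upper(.))`` up to the lost
    diagonal: the 114 padding cells are discarded, each edge value is mirrored
    to (i, j) and (j, i), and the diagonal is zero.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.shape != (GRID_SIDE, GRID_SIDE):
        raise ValidationError(f"grid must be {GRID_SIDE}x{GRID_SIDE}, got {grid.shape}")
    flat = grid.reshape(-1)[:N_EDGES]
    return devectorize(EdgeVector(flat, index_map))
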