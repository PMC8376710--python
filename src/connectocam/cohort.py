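"""Cohort container shared by the generator, the evaluator, and file I/O."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import NodeAtlas, default_atlas
from .core import ConnectomeMatrix, build_matrix_suite, weight_connectome
from .errors import DataError, ValidationError

GROUPS = ("control", "patient")
DOMINANT_SIDES = ("left", "right", "none", "unknown")

#: Two-element teacher vectors: healthy control [1, 0], patient [0, 1].
TEACHER = {"control": (1.0, 0.0), "patient": (0.0, 1.0)}

#: Prefix marking a raw (unweighted) tract-averaged parameter map in a dataset.
RAW_PREFIX = "RAW_"


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    dominant_side: str = "unknown"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.dominant_side not in DOMINANT_SIDES:
            raise ValidationError(
                f"dominant_side must be one of {DOMINANT_SIDES}, got {self.dominant_side!r}"
            )


@dataclass
class CohortDataset:
    """All subjects of a study plus their matrices, keyed metric -> subject."""

    subjects: list[SubjectRecord]
    matrices: dict[str, dict[str, ConnectomeMatrix]]
    atlas: NodeAtlas = field(default_factory=default_atlas)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValidationError("subject ids must be unique")
        for metric, per_subject in self.matrices.items():
            missing = set(ids) - set(per_subject)
            if missing:
                raise ValidationError(
                    f"metric {metric!r} lacks matrices for subjects {sorted(missing)[:5]}"
                )

    @property
    def metrics(self) -> tuple[str, ...]:
        return tuple(self.matrices)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def labels(self) -> np.ndarray:
        """Binary class labels with patient = 1, control = 0."""
        return np.array([1 if s.group == "patient" else 0 for s in self.subjects])

    def teacher_vectors(self) -> np.ndarray:
        """(n_subjects, 2) teacher matrix in subject order."""
        return np.array([TEACHER[s.group] for s in self.subjects])

    def record(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise DataError(f"unknown subject: {subject_id!r}")

    def matrix(self, metric: str, subject_id: str) -> ConnectomeMatrix:
        try:
            return self.matrices[metric][subject_id]
        except KeyError:
            raise DataError(f"no {metric!r} matrix for subject {subject_id!r}") from None


def weight_cohort(dataset: CohortDataset, metrics: list[str] | None = None) -> CohortDataset:
    """Attach parameter-weighted matrices (NOS x raw parameter map) to a cohort.

    Raw maps are stored under ``RAW_<param>`` keys; the weighted matrix is
    stored under the bare parameter name.  With ``metrics=None`` every raw map
    present is weighted; the full 14-matrix suite is produced when all 11
    measured maps are available.
    """
    if "NOS" not in dataset.matrices:
        raise DataError("cohort has no NOS matrices to weight")
    raw_params = {m[len(RAW_PREFIX):]: dataset.matrices[m]
                  for m in dataset.matrices if m.startswith(RAW_PREFIX)}
    if metrics is None:
        metrics = sorted(raw_params)
    out = dict(dataset.matrices)
    from .core import MEASURED_PARAMS  # local import to keep module load cheap

    if set(MEASURED_PARAMS) <= set(raw_params):
        # Full suite: derive AVF and GRATIO too.
        for sid in dataset.subject_ids:
            suite = build_matrix_suite(
                dataset.matrices["NOS"][sid],
                {p: raw_params[p][sid] for p in MEASURED_PARAMS},
            )
            for name, mat in suite.items():
                out.setdefault(name, {})[sid] = mat
    else:
        for name in metrics:
            if name not in raw_params:
                raise DataError(f"no raw parameter map {RAW_PREFIX}{name} in cohort")
            out[name] = {
                sid: weight_connectome(dataset.matrices["NOS"][sid], raw_params[name][sid])
                for sid in dataset.subject_ids
            }
    return CohortDataset(dataset.subjects, out, dataset.atlas)
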