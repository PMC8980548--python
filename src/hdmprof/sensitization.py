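"""Binarization of sIgE levels and cohort stratification.

A level at or above the sensitization threshold (0.35 kU/L by convention
for specific IgE) is coded 1, anything below is 0. The comparison is
inclusive (>=) with no epsilon slack. Age strata follow the strict
paediatric convention: child means age < 18 years; age exactly 18 is adult.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .panel_io import Cohort

#: Conventional specific-IgE positivity cut-off, kU/L.
DEFAULT_THRESHOLD = 0.35

#: Age (years) below which a patient counts as a child.
CHILD_AGE_LIMIT = 18.0

AGE_GROUPS = ("child", "adult")


@dataclass(frozen=True)
class BinarizationConfig:
    """Sensitization threshold in kU/L; must be positive."""

    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ConfigError(f"threshold must be > 0, got {self.threshold}")


@dataclass
class SensitizationMatrix:
    """Patients x molecules 0/1 matrix aligned to a cohort's row order."""

    values: np.ndarray
    patient_ids: tuple[str, ...]
    panel: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.patient_ids = tuple(self.patient_ids)
        self.panel = tuple(self.panel)
        if self.values.shape != (len(self.patient_ids), len(self.panel)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.patient_ids)} patients x {len(self.panel)} molecules"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix entries must be 0 or 1")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    def column(self, molecule: str) -> np.ndarray:
        return self.values[:, self.panel.index(molecule)]

    def subset(self, mask: np.ndarray) -> "SensitizationMatrix":
        mask = np.asarray(mask, dtype=bool)
        return SensitizationMatrix(
            self.values[mask],
            tuple(pid for pid, keep in zip(self.patient_ids, mask) if keep),
            self.panel,
        )


def binarize(cohort: Cohort, config: BinarizationConfig = BinarizationConfig()) -> SensitizationMatrix:
    """Threshold a cohort's sIgE levels into a sensitization matrix.

    An entry is 1 iff the level equals or exceeds the threshold. Patient and
    molecule order are those of the cohort.
    """
    values = (cohort.levels() >= config.threshold).astype(np.int8)
    return SensitizationMatrix(values, tuple(cohort.frame["patient_id"].astype(str)), cohort.panel)


def classify_age(age: float) -> str:
    """Map an age in years to ``"child"`` (< 18) or ``"adult"`` (>= 18)."""
    if not np.isfinite(age) or age < 0:
        raise ConfigError(f"age must be a finite non-negative number, got {age!r}")
    return "child" if age < CHILD_AGE_LIMIT else "adult"


def age_group_labels(cohort: Cohort) -> np.ndarray:
    """Vectorized :func:`classify_age` over a cohort's rows."""
    ages = cohort.frame["age"].to_numpy(dtype=float)
    if (ages < 0).any() or not np.isfinite(ages).all():
        raise ConfigError("cohort contains negative or non-finite ages")
    return np.where(ages < CHILD_AGE_LIMIT, "child", "adult")


def group_mask(cohort: Cohort, group: str) -> np.ndarray:
    """Boolean row mask for ``"all"``, ``"child"`` or ``"adult"``."""
    if group == "all":
        return np.ones(len(cohort), dtype=bool)
    if group in AGE_GROUPS:
        return age_group_labels(cohort) == group
    raise ConfigError(f"unknown group {group!r}; expected 'all', 'child' or 'adult'")


def sensitized_mask(matrix: SensitizationMatrix) -> np.ndarray:
    """Per-patient 0/1 vector: 1 iff sensitized to at least one molecule."""
    return (matrix.values.any(axis=1)).astype(np.int8)


def stratify(
    cohort: Cohort,
    matrix: SensitizationMatrix,
    by: str,
) -> dict:
    """Partition a cohort (and its aligned matrix) into strata.

    ``by`` is ``"age"`` (keys ``"child"``/``"adult"``), ``"region"`` (keys are
    region labels) or ``"age_region"`` (keys ``(region, age_group)``). Every
    patient falls in exactly one stratum; sub-matrix rows stay aligned with
    sub-cohort rows. Strata are returned in deterministic key order.
    """
    if matrix.n_patients != len(cohort):
        raise ValueError("matrix is not aligned with cohort")
    labels = age_group_labels(cohort)
    regions = cohort.frame["region"].to_numpy(dtype=object)
    if by == "age":
        keys = [g for g in AGE_GROUPS if (labels == g).any()]
        masks = {g: labels == g for g in keys}
    elif by == "region":
        keys = sorted(cohort.region_set)
        masks = {r: regions == r for r in keys}
    elif by == "age_region":
        keys = [
            (r, g)
            for r in sorted(cohort.region_set)
            for g in AGE_GROUPS
            if ((regions == r) & (labels == g)).any()
        ]
        masks = {(r, g): (regions == r) & (labels == g) for (r, g) in keys}
    else:
        raise ConfigError(f"unknown grouping {by!r}; expected 'age', 'region' or 'age_region'")
    return {k: (cohort.subset(masks[k]), matrix.subset(masks[k])) for k in keys}
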