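"""Per-molecule prevalence summaries among HDM-sensitized patients.

The reporting convention: for each molecule, the number of patients
sensitized to it, its share as a percentage of the group's patients
sensitized to at least one panel molecule, and the mean +/- sigma sIgE
among the patients positive for that molecule. Shares use the
sensitized-to-any denominator, not the full tested cohort — cohort-wide
prevalence is exposed separately and explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import UndefinedDenominatorError
from .panel_io import Cohort
from .sensitization import SensitizationMatrix, group_mask, sensitized_mask


@dataclass(frozen=True)
class SummaryRow:
    """One molecule's summary within a group.

    ``share_pct`` is NaN (undefined, not zero) when the group has no
    sensitized patients; ``mean_sige``/``sd_sige`` are NaN when nobody in
    the group is sensitized to the molecule.
    """

    molecule: str
    n_sensitized: int
    share_pct: float
    mean_sige: float
    sd_sige: float
    group: str


def compute_share(count: int, total: int) -> float:
    """Percentage 100*count/total, half-up rounded to 2 decimals.

    The rounding is done in exact decimal arithmetic so printed-precision
    comparisons are reproducible (e.g. 2106/2875 -> 73.25).
    """
    if total <= 0:
        raise UndefinedDenominatorError("share undefined for an empty group")
    if count < 0 or count > total:
        raise ValueError(f"count {count} outside [0, total={total}]")
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def total_sensitized(cohort: Cohort, matrix: SensitizationMatrix, group: str = "all") -> int:
    """Number of patients in the group sensitized to >= 1 panel molecule."""
    mask = group_mask(cohort, group)
    return int((sensitized_mask(matrix).astype(bool) & mask).sum())


def sensitized_ratio(cohort: Cohort, matrix: SensitizationMatrix) -> float:
    """Child:adult ratio of sensitized counts, half-up rounded to 2 decimals."""
    child = total_sensitized(cohort, matrix, "child")
    adult = total_sensitized(cohort, matrix, "adult")
    if adult == 0:
        raise UndefinedDenominatorError("ratio undefined: no sensitized adults")
    return float((Decimal(child) / Decimal(adult)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize(
    cohort: Cohort,
    matrix: SensitizationMatrix,
    group: str = "all",
    sample_sd: bool = False,
) -> list[SummaryRow]:
    """One :class:`SummaryRow` per panel molecule for the requested group.

    ``n_sensitized`` is the molecule's positive count within the group;
    ``share_pct`` divides it by the group's sensitized-to-any count;
    ``mean_sige``/``sd_sige`` are taken over the sIgE levels of the positive
    patients only. Sigma is the population standard deviation by default
    (matching the M+/-sigma reporting convention); set ``sample_sd`` for the
    n-1 estimator. Rows are sorted by ``n_sensitized`` descending, ties by
    canonical panel order.
    """
    if matrix.n_patients != len(cohort):
        raise ValueError("matrix is not aligned with cohort")
    mask = group_mask(cohort, group)
    denominator = total_sensitized(cohort, matrix, group)
    levels = cohort.levels()
    ddof = 1 if sample_sd else 0
    rows = []
    for j, molecule in enumerate(cohort.panel):
        positive = mask & (matrix.values[:, j] == 1)
        n = int(positive.sum())
        share = compute_share(n, denominator) if denominator > 0 else math.nan
        if n > 0:
            vals = levels[positive, j]
            mean = float(vals.mean())
            sd = float(vals.std(ddof=ddof)) if n > ddof else math.nan
        else:
            mean = sd = math.nan
        rows.append(SummaryRow(molecule, n, share, mean, sd, group))
    order = {m: i for i, m in enumerate(cohort.panel)}
    rows.sort(key=lambda r: (-r.n_sensitized, order[r.molecule]))
    return rows


def summarize_tige(cohort: Cohort, matrix: SensitizationMatrix, group: str = "all") -> tuple[float, float, int]:
    """Mean and population sigma of total IgE among the group's sensitized
    patients with a recorded tIgE; returns (mean, sd, n). NaNs are skipped
    because tIgE is optional metadata."""
    mask = group_mask(cohort, group) & sensitized_mask(matrix).astype(bool)
    vals = cohort.frame.loc[mask, "tige"].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return (math.nan, math.nan, 0)
    return (float(vals.mean()), float(vals.std(ddof=0)), int(vals.size))


def cohort_prevalence_pct(cohort: Cohort, matrix: SensitizationMatrix, group: str = "all") -> float:
    """Sensitized-to-any share of the FULL tested group, in percent.

    This is the cohort-wide prevalence (denominator = everyone tested in
    the group), distinct from the within-sensitized shares of
    :func:`summarize`.
    """
    mask = group_mask(cohort, group)
    return compute_share(total_sensitized(cohort, matrix, group), int(mask.sum()))
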