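"""Region-wise priority-molecule classification.

For each region (optionally split by age group) the per-molecule
sensitization shares are computed among the region's patients sensitized
to at least one panel molecule. The 1-2 "priority" molecules are then
chosen by a two-stage rule:

1. **Margin rule.** If the largest share exceeds the second largest by
   more than the margin (default 5 percentage points), the top molecule
   alone is the priority.
2. **t-step.** Otherwise the top two are a provisional pair. For every
   molecule with a positive share, a one-sample Student's t test of the
   full share series against that molecule's own share (upper tail,
   alternative "greater") asks whether the series holds another maximum
   above it. The runner-up is retained iff its p-value is relatively close
   (within ``p_similarity``, default 5%) to the p-value of the absolute
   maximum — i.e. the null that the runner-up can be ignored is just as
   unconfirmed for it as for the maximum.

Small groups are excluded, not silently dropped: groups with no sensitized
patients and groups below ``min_group_n`` carry an explicit exclusion
reason. ``alpha`` (default 0.002) annotates which per-molecule null
hypotheses would count as unconfirmed; it is a reporting annotation, not a
gate, because the pair decision rests on the p-similarity rule. Every
decision carries a full trace (both maxima, whether the margin rule fired,
the complete p-value map, and the rule path taken) so the classification
can be audited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats

from .errors import ConfigError, ConsistencyError
from .panel_io import Cohort
from .sensitization import SensitizationMatrix, group_mask, sensitized_mask

RULE_PATHS = ("margin_single", "margin_equal_pair", "ttest_pair", "ttest_single")
EXCLUSION_REASONS = ("none", "no_sensitized", "below_min_n")


@dataclass(frozen=True)
class PriorityConfig:
    """Decision parameters.

    margin
        Share difference (absolute, proportion units) above which the top
        molecule wins outright. The default 0.05 reads the 5% margin as
        5 percentage points of share, since the compared quantities are
        themselves percentages; set ``margin_relative`` to interpret it as
        a relative difference instead.
    p_similarity
        Maximum relative difference between the runner-up's p-value and the
        absolute maximum's p-value for the runner-up to be retained.
    alpha
        Significance annotation level for the per-molecule null hypotheses.
    min_group_n
        Minimum sensitized-to-any count for a region-group to be classified.
    """

    margin: float = 0.05
    p_similarity: float = 0.05
    alpha: float = 0.002
    min_group_n: int = 3
    margin_relative: bool = False

    def __post_init__(self) -> None:
        for name in ("margin", "p_similarity", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")
        if self.min_group_n < 1:
            raise ConfigError(f"min_group_n must be >= 1, got {self.min_group_n}")


@dataclass(frozen=True)
class ShareSeries:
    """Per-molecule sensitization shares of one region-group.

    ``shares`` maps every panel molecule to count(sensitized to molecule) /
    count(sensitized to >= 1 molecule) within the region-group; molecules
    nobody is sensitized to keep share 0. ``n_sensitized`` is the
    denominator.
    """

    region: str
    group: str
    shares: dict[str, float]
    n_sensitized: int

    def __post_init__(self) -> None:
        for m, s in self.shares.items():
            if not (0.0 <= s <= 1.0):
                raise ConsistencyError(f"share for {m!r} outside [0, 1]: {s}")


class TTestResult(NamedTuple):
    statistic: float
    pvalue: float
    degenerate: bool


@dataclass(frozen=True)
class DecisionTrace:
    """Audit record of one priority decision."""

    first_max: tuple[str, float] | None
    second_max: tuple[str, float] | None
    margin_rule_fired: bool
    p_values: dict[str, float]
    rule_path: str | None
    alpha: float
    unconfirmed_at_alpha: dict[str, bool] = field(default_factory=dict)


@dataclass(frozen=True)
class PriorityDecision:
    region: str
    group: str
    priority: tuple[str, ...]
    excluded_reason: str
    trace: DecisionTrace

    @property
    def excluded(self) -> bool:
        return self.excluded_reason != "none"


def ttest_one_sample_greater(series, popmean: float) -> TTestResult:
    """Upper-tail one-sample Student's t test from the closed form.

    t = (mean - popmean) / (s / sqrt(n)) with the sample standard deviation
    (n-1 denominator); p is the upper-tail probability of Student's t with
    n-1 degrees of freedom. A constant series has no defined t; by
    convention it returns p = 1 when mean <= popmean and p = 0 otherwise,
    flagged degenerate.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("series must be one-dimensional with length >= 2")
    n = x.size
    mean = float(x.mean())
    s = float(x.std(ddof=1))
    if s == 0.0:
        return TTestResult(math.nan, 1.0 if mean <= popmean else 0.0, True)
    t = (mean - popmean) / (s / math.sqrt(n))
    p = float(stats.t.sf(t, df=n - 1))
    return TTestResult(t, p, False)


def region_shares(
    cohort: Cohort,
    matrix: SensitizationMatrix,
    region: str,
    group: str = "all",
) -> ShareSeries:
    """Compute one region-group's per-molecule share series."""
    if matrix.n_patients != len(cohort):
        raise ValueError("matrix is not aligned with cohort")
    in_region = cohort.frame["region"].to_numpy(dtype=object) == region
    mask = in_region & group_mask(cohort, group) & sensitized_mask(matrix).astype(bool)
    n = int(mask.sum())
    if n == 0:
        shares = {m: 0.0 for m in matrix.panel}
    else:
        counts = matrix.values[mask].sum(axis=0)
        shares = {m: float(c) / n for m, c in zip(matrix.panel, counts)}
    return ShareSeries(region, group, shares, n)


def _ranked(series: ShareSeries) -> list[tuple[str, float]]:
    molecules = list(series.shares)
    return sorted(
        ((m, series.shares[m]) for m in molecules),
        key=lambda item: (-item[1], molecules.index(item[0])),
    )


def priority_molecules(series: ShareSeries, config: PriorityConfig = PriorityConfig()) -> PriorityDecision:
    """Apply the margin + t-step decision rule to one share series.

    See the module docstring for the rule. The returned decision always
    carries a fully populated trace; excluded groups get an empty priority
    list and an explicit reason.
    """

    def excluded(reason: str) -> PriorityDecision:
        return PriorityDecision(
            series.region,
            series.group,
            (),
            reason,
            DecisionTrace(None, None, False, {}, None, config.alpha),
        )

    if series.n_sensitized == 0:
        return excluded("no_sensitized")
    if series.n_sensitized < config.min_group_n:
        return excluded("below_min_n")

    ranked = _ranked(series)
    (m1, s1), (m2, s2) = ranked[0], ranked[1]
    if s1 <= 0.0:
        raise ConsistencyError(
            f"region {series.region!r}/{series.group}: {series.n_sensitized} "
            "sensitized patients but all shares are zero"
        )

    gap = (s1 - s2) / s1 if config.margin_relative else s1 - s2
    if gap > config.margin:
        trace = DecisionTrace((m1, s1), (m2, s2), True, {}, "margin_single", config.alpha)
        return PriorityDecision(series.region, series.group, (m1,), "none", trace)

    # t-step: ask, for each positive-share molecule, whether the full series
    # holds another maximum above that molecule's own share.
    values = np.array([series.shares[m] for m in series.shares], dtype=float)
    p_values = {
        m: ttest_one_sample_greater(values, s).pvalue
        for m, s in series.shares.items()
        if s > 0.0
    }
    unconfirmed = {m: p >= config.alpha for m, p in p_values.items()}

    if s2 <= 0.0:
        # No runner-up exists (only possible when the top share <= margin):
        # the provisional pair collapses to the single maximum.
        trace = DecisionTrace((m1, s1), (m2, s2), False, p_values, "ttest_single", config.alpha, unconfirmed)
        return PriorityDecision(series.region, series.group, (m1,), "none", trace)

    p1, p2 = p_values[m1], p_values[m2]
    retained = abs(p2 - p1) / p1 <= config.p_similarity
    if retained:
        rule_path = "margin_equal_pair" if s1 == s2 else "ttest_pair"
        priority: tuple[str, ...] = (m1, m2)
    else:
        rule_path = "ttest_single"
        priority = (m1,)
    trace = DecisionTrace((m1, s1), (m2, s2), False, p_values, rule_path, config.alpha, unconfirmed)
    return PriorityDecision(series.region, series.group, priority, "none", trace)


def classify_all_regions(
    cohort: Cohort,
    matrix: SensitizationMatrix,
    config: PriorityConfig = PriorityConfig(),
    by: str = "all",
) -> list[PriorityDecision]:
    """One priority decision per region (``by="all"``) or per region x age
    group (``by="age"``). Regions are processed in sorted label order;
    exclusions are reported, never dropped. Output is deterministic."""
    if by == "all":
        groups = ("all",)
    elif by == "age":
        groups = ("child", "adult")
    else:
        raise ConfigError(f"unknown grouping {by!r}; expected 'all' or 'age'")
    decisions = []
    for region in sorted(cohort.region_set):
        for group in groups:
            series = region_shares(cohort, matrix, region, group)
            decisions.append(priority_molecules(series, config))
    return decisions
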