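"""Independent reference implementations used only for cross-checking.

These deliberately take different routes from the package:

* the priority-rule oracle is a literal, unoptimized transcription of the
  decision rules, and gets its p-values from
  ``scipy.stats.ttest_1samp(alternative="greater")`` instead of the
  package's hand-computed closed form;
* the Student-t upper-tail oracle integrates the explicit t density by
  adaptive quadrature instead of using any distribution function.
"""

import math

import numpy as np
from scipy import stats
from scipy.integrate import quad


def t_upper_tail_quad(t: float, df: int) -> float:
    """Upper-tail Student-t probability by quadrature of the density."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))

    def pdf(x):
        return c * (1.0 + x * x / df) ** (-(df + 1) / 2)

    if t >= 0:
        val, _ = quad(pdf, t, np.inf)
        return val
    val, _ = quad(pdf, t, 0.0)
    return val + 0.5


def reference_pvalue(series, popmean: float) -> float:
    """p-value via scipy's one-sample t test (upper tail), with the same
    constant-series convention the package documents."""
    arr = np.asarray(series, dtype=float)
    if arr.std(ddof=1) == 0.0:
        return 1.0 if arr.mean() <= popmean else 0.0
    return float(stats.ttest_1samp(arr, popmean, alternative="greater").pvalue)


def brute_force_priority(shares: dict, n_sensitized: int, margin=0.05, p_similarity=0.05, min_group_n=3):
    """Literal transcription of the priority decision rules.

    Returns ``(priority_tuple, rule_path_or_exclusion_reason)``; raises
    ValueError on the inconsistent all-zero-shares case.
    """
    if n_sensitized == 0:
        return ((), "no_sensitized")
    if n_sensitized < min_group_n:
        return ((), "below_min_n")
    names = list(shares)
    ranked = sorted(names, key=lambda m: (-shares[m], names.index(m)))
    m1, m2 = ranked[0], ranked[1]
    if shares[m1] <= 0.0:
        raise ValueError("all shares zero yet patients are sensitized")
    if shares[m1] - shares[m2] > margin:
        return ((m1,), "margin_single")
    values = [shares[m] for m in names]
    p = {m: reference_pvalue(values, shares[m]) for m in names if shares[m] > 0}
    if shares[m2] <= 0.0:
        return ((m1,), "ttest_single")
    if abs(p[m2] - p[m1]) / p[m1] <= p_similarity:
        path = "margin_equal_pair" if shares[m1] == shares[m2] else "ttest_pair"
        return ((m1, m2), path)
    return ((m1,), "ttest_single")
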