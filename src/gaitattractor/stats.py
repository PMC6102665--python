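"""Group-level statistics: normality screening, Mann-Whitney U between
groups, one-way repeated-measures ANOVA within subjects, and Bonferroni
correction.

The U test is implemented here rather than delegated because the analysis
needs a fixed, documented convention: midranks for ties, exact two-sided p
by enumeration of rank configurations for small samples (combined n ≤ 16
in ``auto`` mode, matching the regime where enumeration is cheap while the
study's own group sizes of 24 vs 19 fall to the approximation), and a
tie- and continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

from .exceptions import ComputationError, ConfigurationError

EXACT_LIMIT = 16  # combined sample size up to which auto mode enumerates


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (3 ≤ n ≤ 5000)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or not (3 <= values.size <= 5000):
        raise ComputationError("Shapiro-Wilk requires a 1-D sample with 3 <= n <= 5000")
    if np.ptp(values) == 0:
        raise ComputationError("Shapiro-Wilk W is undefined for a constant sample")
    w, p = sps.shapiro(values)
    return float(w), float(p)


@lru_cache(maxsize=64)
def _exact_null_deviations(n_a: int, n_b: int) -> np.ndarray:
    """Sorted |U − n_a·n_b/2| over all rank configurations, no ties."""
    n = n_a + n_b
    mu = n_a * n_b / 2.0
    offset = n_a * (n_a + 1) / 2.0
    devs = np.empty(comb(n, n_a))
    for i, combo in enumerate(combinations(range(1, n + 1), n_a)):
        devs[i] = abs(sum(combo) - offset - mu)
    devs.sort()
    return devs


def _exact_deviations_with_ties(ranks: np.ndarray, n_a: int) -> np.ndarray:
    """As above but enumerating configurations of the observed midranks."""
    n = ranks.size
    mu = n_a * (n - n_a) / 2.0
    offset = n_a * (n_a + 1) / 2.0
    combos = np.array(list(combinations(range(n), n_a)))
    u = ranks[combos].sum(axis=1) - offset
    return np.sort(np.abs(u - mu))


def mann_whitney_u(group_a, group_b, mode: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U (for group A) and two-sided p-value.

    ``mode``: ``exact`` enumerates all C(n, n_a) rank configurations
    (two-sided p = probability of a U at least as far from its null mean as
    observed); ``normal_approx`` uses the tie-corrected normal
    approximation with continuity correction; ``auto`` picks exact when
    n_a + n_b ≤ 16.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ComputationError("both groups must be non-empty")
    if mode not in ("exact", "normal_approx", "auto"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks for ties
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
    mu = n_a * n_b / 2.0

    exact = mode == "exact" or (mode == "auto" and n <= EXACT_LIMIT)
    if exact:
        has_ties = np.unique(pooled).size < n
        if has_ties:
            devs = _exact_deviations_with_ties(ranks, n_a)
        else:
            devs = _exact_null_deviations(n_a, n_b)
        observed = abs(u_a - mu)
        # count configurations at least as extreme (tolerate float rounding)
        count = devs.size - np.searchsorted(devs, observed - 1e-9, side="left")
        p = count / devs.size
    else:
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
        var = n_a * n_b / 12.0 * (n + 1 - tie_term)
        if var <= 0:
            return u_a, 1.0
        z = (abs(u_a - mu) - 0.5) / np.sqrt(var)
        z = max(z, 0.0)
        p = min(1.0, 2.0 * sps.norm.sf(z))
    return u_a, float(p)


@dataclass
class RMAnovaResult:
    F: float
    p: float
    df_treatment: int
    df_error: int
    n_complete: int
    n_dropped: int
    sphericity_corrected: bool = False  # plain within-subject F; flagged


def rm_anova(matrix) -> RMAnovaResult:
    """One-way repeated-measures ANOVA on a subjects × conditions matrix.

    Rows with any missing value are dropped (listwise deletion; the count
    is reported). F = MS_conditions / MS_error with (k−1, (n−1)(k−1))
    degrees of freedom; sphericity is not corrected and the result is
    flagged accordingly.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] < 2:
        raise ComputationError("need a subjects × (>=2 conditions) matrix")
    complete = ~np.isnan(matrix).any(axis=1)
    dropped = int((~complete).sum())
    data = matrix[complete]
    n, k = data.shape
    if n < 2:
        raise ComputationError("need at least 2 complete cases")

    grand = data.mean()
    ss_treat = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_error = ss_total - ss_treat - ss_subj
    df_t, df_e = k - 1, (n - 1) * (k - 1)
    ms_treat = ss_treat / df_t
    ms_error = ss_error / df_e
    if ms_error <= 0:
        f = 0.0 if ms_treat == 0 else np.inf
    else:
        f = ms_treat / ms_error
    p = float(sps.f.sf(f, df_t, df_e)) if np.isfinite(f) else 0.0
    return RMAnovaResult(F=float(f), p=p, df_treatment=df_t, df_error=df_e,
                         n_complete=n, n_dropped=dropped)


def bonferroni(p_values, k: int | None = None):
    """Bonferroni adjustment: each p multiplied by k and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    if np.any((p < 0) | (p > 1)):
        raise ComputationError("p-values must lie in [0, 1]")
    k = k if k is not None else p.size
    if k < 1:
        raise ConfigurationError("k must be at least 1")
    adjusted = np.minimum(1.0, p * k)
    return float(adjusted[0]) if scalar else adjusted


def paired_posthoc(matrix, labels=None) -> list[dict]:
    """Bonferroni-corrected pairwise paired t-tests between conditions.

    Complements :func:`rm_anova` the way SPSS's post-hoc option does: every
    pair of time points is compared with a paired t-test and the raw
    p-values are multiplied by the number of pairs (capped at 1).
    """
    matrix = np.asarray(matrix, dtype=float)
    complete = ~np.isnan(matrix).any(axis=1)
    data = matrix[complete]
    k = data.shape[1]
    labels = labels if labels is not None else list(range(k))
    pairs = list(combinations(range(k), 2))
    out = []
    for i, j in pairs:
        t, p = sps.ttest_rel(data[:, i], data[:, j])
        out.append({"pair": (labels[i], labels[j]), "t": float(t),
                    "p_raw": float(p),
                    "p_adjusted": bonferroni(float(p), k=len(pairs))})
    return out
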