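"""Task/context specificity of neuronal populations.

Given per-neuron activity summaries (isolation distance or mean deconvolved
rate) across labeled conditions, this module computes task-preference
indices, active/inactive scatter categories, Spearman correlation matrices
within and across conditions and days, within-vs-across group tests, and the
silent-population simulation showing how a large shared-baseline silent
majority drives across-task activity correlations toward +1.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PopulationActivity",
    "UndefinedCorrelationError",
    "task_preference",
    "categorize",
    "spearman",
    "condition_correlation",
    "correlation_matrix",
    "compare_within_across",
    "simulate_silent_population",
    "cross_day_comparison",
    "CATEGORY_LABELS",
]

CATEGORY_LABELS = ("TM-only", "SW-only", "both", "neither")


class UndefinedCorrelationError(ValueError):
    """Raised when a rank correlation is undefined (constant input)."""


@dataclass(frozen=True)
class PopulationActivity:
    """Per-neuron activity summaries across labeled conditions.

    ``activity`` is a DataFrame indexed by stable neuron ids with one column
    per condition label (e.g. "TM", "SW", "passive_ball"; optionally with day
    tags like "TM_day1"). Every neuron must be present in every column —
    a neuron recorded but inactive carries zero, never NaN.
    """

    activity: pd.DataFrame

    def __post_init__(self) -> None:
        if self.activity.isna().any().any():
            raise ValueError("activity must not contain missing values; "
                             "recorded-but-inactive neurons carry 0")
        if (self.activity.to_numpy() < 0).any():
            raise ValueError("activity values must be nonnegative")

    @property
    def conditions(self) -> list[str]:
        return list(self.activity.columns)

    @property
    def neuron_ids(self) -> pd.Index:
        return self.activity.index


def task_preference(a, b):
    """Normalized task-preference index (a - b) / (a + b) in [-1, 1].

    Vectorized; the 0/0 case (inactive in both) returns NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("activities must be nonnegative")
    total = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        pref = np.where(total > 0, (a - b) / np.where(total > 0, total, 1.0), np.nan)
    return pref if pref.ndim else float(pref)


def categorize(a, b, threshold: float):
    """Activity-scatter category per neuron.

    "both" if both activities strictly exceed the threshold, "TM-only" /
    "SW-only" if only the first / second does, else "neither".
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    a = np.atleast_1d(np.asarray(a, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    out = np.full(a.shape, "neither", dtype=object)
    out[(a > threshold) & (b > threshold)] = "both"
    out[(a > threshold) & (b <= threshold)] = "TM-only"
    out[(a <= threshold) & (b > threshold)] = "SW-only"
    return out if out.size > 1 else str(out[0])


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p for Spearman's rho by full enumeration of the n!
    pairings of y-ranks against x-ranks (conditional on observed ties)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt((rxc @ rxc) * (ryc @ ryc))
    if denom == 0:
        raise UndefinedCorrelationError("constant ranks")
    n = len(x)
    target = abs(rho_obs) - 1e-12
    count = 0
    total = 0
    chunk: list = []
    chunk_size = 200_000
    for perm in itertools.permutations(ryc):
        chunk.append(perm)
        if len(chunk) == chunk_size:
            rhos = np.asarray(chunk) @ rxc / denom
            count += int(np.count_nonzero(np.abs(rhos) >= target))
            total += len(chunk)
            chunk = []
    if chunk:
        rhos = np.asarray(chunk) @ rxc / denom
        count += int(np.count_nonzero(np.abs(rhos) >= target))
        total += len(chunk)
    return count / total


def spearman(x, y, exact_max_n: int = 10) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p-value.

    Ties receive average ranks. The p-value uses exact enumeration of
    pairings for n <= ``exact_max_n`` and the t approximation above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("constant input: rho undefined")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if len(x) <= exact_max_n:
        p = _exact_spearman_p(x, y, rho)
    else:
        p = float(res.pvalue)
    return rho, p


def condition_correlation(
    pop: PopulationActivity, cond_i: str, cond_j: str
) -> tuple[float, float]:
    """Spearman correlation of per-neuron activity between two conditions."""
    for c in (cond_i, cond_j):
        if c not in pop.activity.columns:
            raise KeyError(f"condition {c!r} not present")
    if len(pop.activity) < 3:
        raise ValueError("need >= 3 neurons")
    return spearman(pop.activity[cond_i].to_numpy(),
                    pop.activity[cond_j].to_numpy())


def correlation_matrix(pop: PopulationActivity) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All pairwise condition correlations; returns (rho, p) DataFrames.

    rho is symmetric with unit diagonal; diagonal p-values are NaN.
    """
    conds = pop.conditions
    k = len(conds)
    rho = np.eye(k)
    pmat = np.full((k, k), np.nan)
    for i, j in itertools.combinations(range(k), 2):
        r, p = condition_correlation(pop, conds[i], conds[j])
        rho[i, j] = rho[j, i] = r
        pmat[i, j] = pmat[j, i] = p
    return (
        pd.DataFrame(rho, index=conds, columns=conds),
        pd.DataFrame(pmat, index=conds, columns=conds),
    )


def compare_within_across(
    within,
    across,
    mode: str = "t_test_one_tailed",
    groups=None,
) -> tuple[float, float]:
    """Compare within-context vs across-context correlation values.

    ``t_test_one_tailed``: two-sample t test of within > across.
    ``anova``: one-way ANOVA across ``groups`` (a sequence of sequences;
    defaults to (within, across)).
    """
    within = np.asarray(within, dtype=float)
    across = np.asarray(across, dtype=float)
    if mode == "t_test_one_tailed":
        if len(within) < 1 or len(across) < 1:
            raise ValueError("both groups must be non-empty")
        res = stats.ttest_ind(within, across, alternative="greater")
        return float(res.statistic), float(res.pvalue)
    if mode == "anova":
        gs = [np.asarray(g, float) for g in (groups if groups is not None
                                             else (within, across))]
        if any(len(g) < 2 for g in gs):
            raise ValueError("each ANOVA group needs >= 2 values")
        res = stats.f_oneway(*gs)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown mode: {mode!r}")


def simulate_silent_population(
    n: int,
    silent_fraction: float,
    active_fractions: tuple[float, float, float],
    shared_baseline_sd: float,
    independent_noise_sd: float,
    seed: int,
    active_amplitude: float = 1.0,
) -> float:
    """Across-task Pearson r of a population including its silent majority.

    Each neuron draws a once-per-neuron baseline (log-normal, scaled by
    ``shared_baseline_sd``) present in both tasks, plus independent per-task
    Gaussian noise. Active neurons (fractions over TM-only, SW-only, both)
    additionally get ``active_amplitude`` in their preferred task(s). When
    the silent fraction is large and the shared baseline dominates the
    independent noise, the correlation approaches +1 even though the active
    minority is perfectly task-exclusive — inactive-in-both dominates.
    """
    if n < 100:
        raise ValueError("n must be >= 100")
    af = np.asarray(active_fractions, dtype=float)
    if af.shape != (3,) or np.any(af < 0) or silent_fraction < 0:
        raise ValueError("invalid fractions")
    if abs(af.sum() + silent_fraction - 1.0) > 1e-9:
        raise ValueError("active fractions and silent_fraction must sum to 1")
    rng = np.random.default_rng(seed)
    classes = rng.choice(4, size=n, p=[*af, silent_fraction])
    baseline = shared_baseline_sd * rng.lognormal(0.0, 1.0, size=n)
    a = baseline + independent_noise_sd * rng.normal(size=n)
    b = baseline + independent_noise_sd * rng.normal(size=n)
    a = a + active_amplitude * ((classes == 0) | (classes == 2))
    b = b + active_amplitude * ((classes == 1) | (classes == 2))
    return float(np.corrcoef(a, b)[0, 1])


def cross_day_comparison(
    pop_day1: PopulationActivity,
    pop_day2: PopulationActivity,
    pairing: str = "same_task",
) -> dict[tuple[str, str], tuple[float, float]]:
    """Correlate activity across two days, within or across tasks.

    Neurons are resolved to the union of ids across the pair; a neuron not
    detected on one day carries zero activity there (activity-based
    segmentation misses inactive cells). ``same_task`` pairs each shared
    condition with itself; ``cross_task`` pairs the two tasks both ways.
    Returns {(cond_day1, cond_day2): (rho, p)}.
    """
    ids1, ids2 = set(pop_day1.neuron_ids), set(pop_day2.neuron_ids)
    if not ids1 & ids2:
        raise ValueError("no shared neuron ids between days")
    union = pop_day1.neuron_ids.union(pop_day2.neuron_ids)
    a1 = pop_day1.activity.reindex(union, fill_value=0.0)
    a2 = pop_day2.activity.reindex(union, fill_value=0.0)
    shared = [c for c in a1.columns if c in a2.columns]
    if pairing == "same_task":
        pairs = [(c, c) for c in shared]
    elif pairing == "cross_task":
        pairs = [(ci, cj) for ci in shared for cj in shared if ci != cj]
    else:
        raise ValueError(f"unknown pairing: {pairing!r}")
    if not pairs:
        raise ValueError("no condition pairs to compare")
    out = {}
    for ci, cj in pairs:
        out[(ci, cj)] = spearman(a1[ci].to_numpy(), a2[cj].to_numpy())
    return out
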