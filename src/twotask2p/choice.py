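"""Combined-conditions choice probability (ccCP) and trial filtering.

Choice probability is classically the ROC area between the activity
distributions on left- versus right-choice trials, equivalently a normalized
Mann-Whitney U statistic. With many stimulus conditions but few trials per
condition, per-condition ROC areas are noisy and confound stimulus with
choice; the combined-conditions form instead sums the pairwise-comparison
numerators and denominators over all conditions before dividing:

    AUC = sum_c U_c / sum_c (n_R(c) * n_L(c)),   ccCP = 2 * AUC - 1

where U_c counts (R-trial, L-trial) pairs within condition c whose R-trial
activity is larger (ties count 1/2). ccCP lies in [-1, 1]; negative values
mean higher activity on left choices. Significance comes from a permutation
test shuffling choice labels *within* each condition, preserving the
per-condition class counts and thus accounting for imbalanced conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .specificity import spearman

__all__ = [
    "CcCPResult",
    "FilteredTrials",
    "CrossTaskCcCP",
    "UndefinedCcCPError",
    "filter_trials",
    "trial_activity",
    "cccp",
    "cccp_permutation_p",
    "cross_task_cccp",
    "MIN_REACTION_TIME",
]

#: Trials with movement earlier than this (s) after stimulus onset are
#: discarded as unlikely to be stimulus-driven.
MIN_REACTION_TIME = 0.125


class UndefinedCcCPError(ValueError):
    """No condition contains trials of both choices."""


@dataclass(frozen=True)
class FilteredTrials:
    """Outcome of trial filtering. Session invalidity is a typed outcome,
    not an exception: downstream code checks ``session_valid``."""

    trials: pd.DataFrame
    session_valid: bool
    n_left: int
    n_right: int
    reason: str | None = None


@dataclass(frozen=True)
class CcCPResult:
    """Pooled choice-probability statistic."""

    cccp: float
    numerator: float
    denominator: float
    p_perm: float | None = None
    n_trials_used: dict | None = None

    def __post_init__(self) -> None:
        if abs(self.cccp) > 1 + 1e-12:
            raise ValueError("|ccCP| must be <= 1")
        if self.denominator < 1:
            raise ValueError("denominator must be >= 1 when defined")
        if self.p_perm is not None and not 0 < self.p_perm <= 1:
            raise ValueError("p_perm must lie in (0, 1]")


@dataclass(frozen=True)
class CrossTaskCcCP:
    """Cross-task comparison of choice selectivity over both-active neurons."""

    rho: float
    p: float
    n_both_active: int
    session_valid: bool


def filter_trials(
    table: pd.DataFrame, min_per_class: int = 10
) -> FilteredTrials:
    """Apply the standard trial exclusions.

    Drops repeated-stimulus trials and trials with reaction time strictly
    below 125 ms; the session is flagged invalid if fewer than
    ``min_per_class`` trials of either choice remain.
    """
    keep = (~table["repeat_flag"].astype(bool)) & (
        table["reaction_time"] >= MIN_REACTION_TIME
    )
    filtered = table.loc[keep].reset_index(drop=True)
    n_left = int((filtered["choice"] == "L").sum())
    n_right = int((filtered["choice"] == "R").sum())
    valid = n_left >= min_per_class and n_right >= min_per_class
    reason = None if valid else (
        f"fewer than {min_per_class} trials of each choice remain "
        f"(L={n_left}, R={n_right})"
    )
    return FilteredTrials(
        trials=filtered, session_valid=valid,
        n_left=n_left, n_right=n_right, reason=reason,
    )


def trial_activity(
    trace: np.ndarray, table: pd.DataFrame, frame_rate: float = 10.0
) -> np.ndarray:
    """Mean deconvolved activity over each trial's [t_start, t_choice).

    The window runs from stimulus presentation through the motor execution
    of the choice; frames are half-open on the right.
    """
    trace = np.asarray(trace, dtype=float)
    T = len(trace)
    out = np.empty(len(table))
    for i, (t0, t1) in enumerate(zip(table["t_start"], table["t_choice"])):
        f0 = int(np.ceil(t0 * frame_rate - 1e-9))
        f1 = int(np.ceil(t1 * frame_rate - 1e-9))
        if f0 < 0 or f1 > T:
            raise ValueError("trial window outside the trace")
        if f1 <= f0:
            raise ValueError("empty trial window")
        out[i] = trace[f0:f1].mean()
    return out


def _condition_key(table_or_cond) -> np.ndarray:
    return np.asarray(table_or_cond)


def cccp(activity, condition, choice) -> CcCPResult:
    """Combined-conditions choice probability (statistic only).

    ``activity`` is the per-trial scalar; ``condition`` labels the stimulus
    condition of each trial (contrast x side; a zero-contrast condition is a
    single condition); ``choice`` is 'L'/'R' per trial. Conditions lacking
    one of the two choices contribute nothing.
    """
    a = np.asarray(activity, dtype=float)
    cond = _condition_key(condition)
    ch = np.asarray(choice)
    if not (len(a) == len(cond) == len(ch)):
        raise ValueError("activity, condition, choice must be equal length")
    num = 0.0
    den = 0
    n_used: dict = {}
    for c in pd.unique(cond):
        mask = cond == c
        is_r = ch[mask] == "R"
        n_r, n_l = int(is_r.sum()), int((~is_r).sum())
        if n_r == 0 or n_l == 0:
            continue
        ranks = stats.rankdata(a[mask])
        # Mann-Whitney U of R-trials over L-trials, ties as halves
        num += float(ranks[is_r].sum() - n_r * (n_r + 1) / 2.0)
        den += n_r * n_l
        n_used[c] = n_r + n_l
    if den == 0:
        raise UndefinedCcCPError(
            "no condition contains both left- and right-choice trials"
        )
    auc = num / den
    return CcCPResult(
        cccp=2.0 * auc - 1.0, numerator=num, denominator=den,
        n_trials_used=n_used,
    )


def cccp_permutation_p(
    activity, condition, choice, n_perm: int = 1000, seed: int | None = None
) -> CcCPResult:
    """ccCP with its two-sided within-condition permutation p-value.

    Choice labels are shuffled within each condition (preserving the
    per-condition counts of each choice), the statistic recomputed
    ``n_perm`` times, and p = (1 + #{|ccCP_perm| >= |ccCP_obs|}) /
    (1 + n_perm) — never exactly zero.
    """
    obs = cccp(activity, condition, choice)
    a = np.asarray(activity, dtype=float)
    cond = _condition_key(condition)
    ch = np.asarray(choice)
    rng = np.random.default_rng(seed)

    num_perm = np.zeros(n_perm)
    den = 0
    for c in pd.unique(cond):
        mask = cond == c
        is_r = ch[mask] == "R"
        n = int(mask.sum())
        n_r, n_l = int(is_r.sum()), n - int(is_r.sum())
        if n_r == 0 or n_l == 0:
            continue
        ranks = stats.rankdata(a[mask])
        # random subsets of size n_r get the "R" label, all perms at once
        order = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_r]
        num_perm += ranks[order].sum(axis=1) - n_r * (n_r + 1) / 2.0
        den += n_r * n_l
    cccp_perm = 2.0 * num_perm / den - 1.0
    n_extreme = int(np.count_nonzero(np.abs(cccp_perm) >= abs(obs.cccp) - 1e-12))
    p = (1.0 + n_extreme) / (1.0 + n_perm)
    return CcCPResult(
        cccp=obs.cccp, numerator=obs.numerator, denominator=obs.denominator,
        p_perm=float(p), n_trials_used=obs.n_trials_used,
    )


def cross_task_cccp(
    cccp_task1,
    cccp_task2,
    isolation_task1,
    isolation_task2,
    activity_threshold: float = 0.3,
    min_both_active: int = 10,
) -> CrossTaskCcCP:
    """Correlate choice selectivity across tasks over both-active neurons.

    Only neurons whose isolation distance strictly exceeds
    ``activity_threshold`` in *both* tasks enter; if fewer than
    ``min_both_active`` qualify the session is flagged invalid (typed
    outcome, rho/p are NaN).
    """
    c1 = np.asarray(cccp_task1, dtype=float)
    c2 = np.asarray(cccp_task2, dtype=float)
    i1 = np.asarray(isolation_task1, dtype=float)
    i2 = np.asarray(isolation_task2, dtype=float)
    if not (c1.shape == c2.shape == i1.shape == i2.shape):
        raise ValueError("per-neuron arrays must be matched")
    both = (i1 > activity_threshold) & (i2 > activity_threshold)
    n_both = int(both.sum())
    if n_both < min_both_active:
        return CrossTaskCcCP(rho=float("nan"), p=float("nan"),
                             n_both_active=n_both, session_valid=False)
    rho, p = spearman(c1[both], c2[both])
    return CrossTaskCcCP(rho=rho, p=p, n_both_active=n_both, session_valid=True)
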