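"""Event-kernel ridge encoding models of single-neuron activity.

Each neuron's deconvolved activity is modeled as a weighted combination of
task events: temporally windowed indicator kernels around stimulus onset,
choice, and reward (split by side), plus lagged copies of continuous
apparatus signals (wheel velocity split by rotation direction, ball forward
velocity, turning). The weights are fit by ridge regression with the penalty
chosen by k-fold cross-validation over a fixed grid; model quality is the
cross-validated percentage of variance explained.

Default windows (ms): stimulus (-50, 500); choice (-150, 400); reward
(-100, 400); continuous signals (-500, 500) in steps of 250. Window edges
round *outward* to the frame grid (at 10 Hz, -50 ms becomes -1 frame), and
each column carries metadata naming its predictor, side, and lag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .specificity import spearman

__all__ = [
    "EventStreams",
    "KernelWindows",
    "DesignMatrix",
    "EncodingFit",
    "build_design_matrix",
    "ridge_solve",
    "RidgeEncodingCV",
    "fit_ridge_cv",
    "variance_explained",
    "encoding_cross_task",
    "raised_cosine_basis",
    "LAMBDA_GRID",
]

#: Cross-validation penalty grid.
LAMBDA_GRID = (0.01, 0.05, 0.1, 0.5, 1.0)

#: Explained-variance threshold (%) marking a neuron as task-relevant.
TASK_RELEVANT_VE = 8.0


@dataclass(frozen=True)
class KernelWindows:
    """Per-predictor kernel windows, in ms relative to the event."""

    event_windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "stimulus": (-50.0, 500.0),
            "choice": (-150.0, 400.0),
            "reward": (-100.0, 400.0),
        }
    )
    continuous_window: tuple[float, float] = (-500.0, 500.0)
    continuous_step: float = 250.0

    def __post_init__(self) -> None:
        for name, (pre, post) in self.event_windows.items():
            if pre > post:
                raise ValueError(f"window for {name!r} has pre > post")
        if self.continuous_window[0] > self.continuous_window[1]:
            raise ValueError("continuous window has pre > post")
        if self.continuous_step <= 0:
            raise ValueError("continuous step must be positive")


@dataclass(frozen=True)
class EventStreams:
    """Task events and continuous signals feeding the design matrix.

    ``stimulus_onsets`` / ``choice_times`` pair times (s) with sides in
    {"L", "R"} ("none" for zero-contrast stimuli); ``reward_times`` are
    times only. ``continuous`` maps signal names to frame-rate series.
    """

    stimulus_onsets: tuple[np.ndarray, np.ndarray]
    choice_times: tuple[np.ndarray, np.ndarray]
    reward_times: np.ndarray
    continuous: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass(frozen=True)
class DesignMatrix:
    """Time x predictor matrix with per-column metadata.

    Column 0 is an unpenalized intercept; all other columns are z-scored
    (columns with zero variance — e.g., an event type that never occurred —
    are left as zeros). ``columns`` holds one dict per column with keys
    ``predictor``, ``side``, ``lag_frames``, ``kind``.
    """

    X: np.ndarray
    columns: list[dict]
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return self.X.shape[0]

    @property
    def penalized(self) -> np.ndarray:
        """Boolean mask of penalized columns (everything but the intercept)."""
        return np.array([c["kind"] != "intercept" for c in self.columns])


def _frames_outward(pre_ms: float, post_ms: float, frame_rate: float) -> tuple[int, int]:
    frame_ms = 1000.0 / frame_rate
    return math.floor(pre_ms / frame_ms), math.ceil(post_ms / frame_ms)


def _event_frames(times: np.ndarray, frame_rate: float, T: int) -> np.ndarray:
    frames = np.round(np.asarray(times, dtype=float) * frame_rate).astype(int)
    if np.any((frames < 0) | (frames >= T)):
        raise ValueError("event outside the trace's time span")
    return frames


def build_design_matrix(
    events: EventStreams,
    windows: KernelWindows,
    frame_rate: float,
    T: int,
) -> DesignMatrix:
    """Assemble the event-kernel design matrix.

    For each event type and side, one indicator column per frame lag in the
    (outward-rounded) window; overlapping event windows add. For each
    continuous channel, one copy per lag step (5 lags at the defaults:
    -500, -250, 0, +250, +500 ms, rounded outward to the frame grid).
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    cols: list[np.ndarray] = [np.ones(T)]
    meta: list[dict] = [{"predictor": "intercept", "side": None,
                         "lag_frames": 0, "kind": "intercept"}]

    sided = {
        "stimulus": events.stimulus_onsets,
        "choice": events.choice_times,
    }
    for name, (times, sides) in sided.items():
        if name not in windows.event_windows:
            continue
        pre_f, post_f = _frames_outward(*windows.event_windows[name], frame_rate)
        times = np.asarray(times, dtype=float)
        sides = np.asarray(sides)
        for side in ("L", "R", "none"):
            t_side = times[sides == side]
            if len(t_side) == 0:  # a side never observed gets no columns
                continue
            frames = _event_frames(t_side, frame_rate, T)
            for lag in range(pre_f, post_f + 1):
                col = np.zeros(T)
                idx = frames + lag
                ok = (idx >= 0) & (idx < T)
                np.add.at(col, idx[ok], 1.0)
                cols.append(col)
                meta.append({"predictor": name, "side": side,
                             "lag_frames": lag, "kind": "event"})
    if "reward" in windows.event_windows and len(events.reward_times) > 0:
        pre_f, post_f = _frames_outward(*windows.event_windows["reward"], frame_rate)
        frames = _event_frames(events.reward_times, frame_rate, T)
        for lag in range(pre_f, post_f + 1):
            col = np.zeros(T)
            idx = frames + lag
            ok = (idx >= 0) & (idx < T)
            np.add.at(col, idx[ok], 1.0)
            cols.append(col)
            meta.append({"predictor": "reward", "side": None,
                         "lag_frames": lag, "kind": "event"})

    lo, hi = windows.continuous_window
    lags_ms = np.arange(lo, hi + windows.continuous_step / 2, windows.continuous_step)
    frame_ms = 1000.0 / frame_rate
    lag_frames = [
        math.floor(l / frame_ms) if l < 0 else math.ceil(l / frame_ms)
        for l in lags_ms
    ]
    for name, sig in events.continuous.items():
        sig = np.asarray(sig, dtype=float)
        if len(sig) != T:
            raise ValueError(f"continuous signal {name!r} length != T")
        for lag in lag_frames:
            col = np.zeros(T)
            if lag >= 0:
                col[lag:] = sig[: T - lag] if lag > 0 else sig
            else:
                col[:lag] = sig[-lag:]
            cols.append(col)
            meta.append({"predictor": name, "side": None,
                         "lag_frames": int(lag), "kind": "continuous"})

    X = np.column_stack(cols)
    # z-score everything but the intercept; all-constant columns stay zero
    mu = X[:, 1:].mean(axis=0)
    sd = X[:, 1:].std(axis=0)
    nonzero = sd > 0
    X[:, 1:] = np.where(nonzero, (X[:, 1:] - mu) / np.where(nonzero, sd, 1.0), 0.0)
    if X.shape[1] == 1:
        import warnings

        warnings.warn("empty event streams: intercept-only design matrix")
    return DesignMatrix(X=X, columns=meta, frame_rate=frame_rate)


def ridge_solve(X, y, lam: float, penalized=None) -> np.ndarray:
    """Ridge solution minimizing ||y - Xw||^2 + lam * ||w_penalized||^2.

    ``penalized`` is a boolean mask of columns subject to the penalty
    (default: all except column 0, the intercept convention of
    ``DesignMatrix``). Accepts a DesignMatrix or a plain array.
    """
    if isinstance(X, DesignMatrix):
        penalized = X.penalized if penalized is None else penalized
        X = X.X
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    if X.shape[0] != len(y):
        raise ValueError("X rows must match y length")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in X or y")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    p = X.shape[1]
    if penalized is None:
        penalized = np.ones(p, dtype=bool)
        penalized[0] = False
    d = np.where(np.asarray(penalized, dtype=bool), lam, 0.0)
    return np.linalg.solve(X.T @ X + np.diag(d), X.T @ y)


def variance_explained(y, yhat) -> float:
    """Percentage variance explained, 100 * (1 - SSE / SST).

    Can be negative on held-out data; errors on constant ``y``.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        raise ValueError("constant y: variance explained undefined")
    return float(100.0 * (1.0 - np.sum((y - yhat) ** 2) / sst))


def _contiguous_folds(T: int, k: int) -> np.ndarray:
    """Per-frame fold index in 1..k, contiguous time blocks."""
    return np.concatenate(
        [np.full(len(block), i + 1) for i, block in
         enumerate(np.array_split(np.arange(T), k))]
    )


@dataclass(frozen=True)
class EncodingFit:
    """Result of a cross-validated ridge encoding fit."""

    weights: np.ndarray
    lam: float
    fold_assignment: np.ndarray
    cv_variance_explained: float
    model_label: str = "SW"
    columns: list[dict] | None = None

    def __post_init__(self) -> None:
        if self.cv_variance_explained > 100.0:
            raise ValueError("variance explained cannot exceed 100%")


class RidgeEncodingCV(BaseEstimator, RegressorMixin):
    """Ridge encoding model with cross-validated penalty selection.

    The penalty is chosen from ``lambda_grid`` to maximize the mean held-out
    variance explained over ``n_folds`` contiguous time-block folds
    (contiguous, not shuffled, because neural traces are autocorrelated in
    time and random frame folds would leak). Final weights are refit on all
    data at the chosen penalty; the reported ``cv_variance_explained_`` comes
    from held-out predictions concatenated across folds.

    Attributes after ``fit``: ``coef_``, ``lambda_``, ``fold_assignment_``,
    ``cv_variance_explained_``.
    """

    def __init__(
        self,
        lambda_grid: tuple[float, ...] = LAMBDA_GRID,
        n_folds: int = 11,
        penalized=None,
    ):
        self.lambda_grid = lambda_grid
        self.n_folds = n_folds
        self.penalized = penalized

    def fit(self, X, y):
        design_cols = None
        if isinstance(X, DesignMatrix):
            design_cols = X.columns
            pen = X.penalized if self.penalized is None else self.penalized
            X = X.X
        else:
            pen = self.penalized
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        T = X.shape[0]
        k = int(self.n_folds)
        if k < 2:
            raise ValueError("need at least 2 folds")
        if T < k:
            raise ValueError("need at least as many frames as folds")
        if any(l <= 0 for l in self.lambda_grid):
            raise ValueError("lambda grid must be positive")
        folds = _contiguous_folds(T, k)
        mean_ve = []
        preds = {}
        for lam in self.lambda_grid:
            yhat = np.empty(T)
            fold_ves = []
            for f in range(1, k + 1):
                test = folds == f
                w = ridge_solve(X[~test], y[~test], lam, penalized=pen)
                yhat[test] = X[test] @ w
                fold_ves.append(variance_explained(y[test], yhat[test]))
            mean_ve.append(float(np.mean(fold_ves)))
            preds[lam] = yhat.copy()
        best = int(np.argmax(mean_ve))
        lam = float(self.lambda_grid[best])
        self.lambda_ = lam
        self.fold_assignment_ = folds
        self.cv_variance_explained_ = variance_explained(y, preds[lam])
        self.coef_ = ridge_solve(X, y, lam, penalized=pen)
        self._columns = design_cols
        return self

    def predict(self, X):
        if isinstance(X, DesignMatrix):
            X = X.X
        return np.asarray(X, dtype=float) @ self.coef_


def fit_ridge_cv(
    X,
    y,
    lambda_grid: tuple[float, ...] = LAMBDA_GRID,
    k: int = 11,
    seed: int | None = None,
    model_label: str = "SW",
) -> EncodingFit:
    """Functional wrapper over :class:`RidgeEncodingCV`.

    ``seed`` is accepted for interface uniformity; fold assignment is
    deterministic (contiguous blocks), so it is unused.
    """
    est = RidgeEncodingCV(lambda_grid=lambda_grid, n_folds=k).fit(X, y)
    return EncodingFit(
        weights=est.coef_,
        lam=est.lambda_,
        fold_assignment=est.fold_assignment_,
        cv_variance_explained=est.cv_variance_explained_,
        model_label=model_label,
        columns=est._columns,
    )


def encoding_cross_task(
    ve_task1,
    ve_task2,
    ve_threshold: float = TASK_RELEVANT_VE,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Compare per-neuron encoding quality across tasks.

    Returns the Spearman correlation (rho, p) of cross-validated variance
    explained across all matched neurons, plus boolean masks of task-relevant
    neurons (VE strictly > ``ve_threshold``) in each task.
    """
    v1 = np.asarray(ve_task1, dtype=float)
    v2 = np.asarray(ve_task2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("per-neuron VE arrays must be matched")
    rho, p = spearman(v1, v2)
    return rho, p, v1 > ve_threshold, v2 > ve_threshold


def raised_cosine_basis(
    x: np.ndarray, n_basis: int, x_min: float, x_max: float
) -> np.ndarray:
    """Raised-cosine basis functions over a continuous variable.

    A lightweight stand-in for position/heading tuning in the maze: maps a
    signal (e.g., corridor position z or heading angle theta) onto
    ``n_basis`` smooth overlapping bumps tiling [x_min, x_max], entered as
    design columns of a simplified position-heading model.
    """
    if n_basis < 1:
        raise ValueError("n_basis must be >= 1")
    x = np.asarray(x, dtype=float)
    centers = np.linspace(x_min, x_max, n_basis)
    width = (x_max - x_min) / max(n_basis - 1, 1) * 2 if n_basis > 1 else (x_max - x_min) or 1.0
    arg = np.clip((x[:, None] - centers[None, :]) * np.pi / width, -np.pi, np.pi)
    return 0.5 * (1 + np.cos(arg))
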