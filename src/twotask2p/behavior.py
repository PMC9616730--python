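"""Psychometric fitting and movement-modulation statistics.

The psychometric model describes the probability of a rightward choice as a
function of signed stimulus contrast c (negative = left, positive = right):

    P(right | c) = gamma_L + (1 - gamma_L - gamma_R) * F((c - mu) / sigma)

with bias mu, slope sigma, lapse rates gamma_L / gamma_R, and F either the
standard normal CDF (default) or the logistic function. Parameters are
estimated by maximizing the Bernoulli likelihood with multi-start bounded
optimization.

Movement modulation is the Pearson correlation between a neuron's activity
and a movement trace (running speed, face motion, ...), with significance from
a circular-shift permutation test that preserves the autocorrelation of both
series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "PsychometricParams",
    "PsychometricModel",
    "ModulationResult",
    "fit_psychometric",
    "predict_psychometric",
    "psychometric_probability",
    "gaussian_smooth",
    "block_average",
    "movement_modulation",
]

_SLOPE_MIN = 0.1
_SLOPE_MAX = 200.0
_BIAS_MAX = 100.0
_LAPSE_MAX = 0.45


@dataclass(frozen=True)
class PsychometricParams:
    """Fitted (or generating) psychometric parameters.

    bias and slope are in signed-contrast (%) units; lapses in [0, 0.45].
    ``boundary_fit`` flags an estimate pinned at an optimization bound
    (e.g., step-function data driving the slope to its lower bound).
    """

    bias: float
    slope: float
    lapse_left: float
    lapse_right: float
    form: str = "gaussian"
    boundary_fit: bool = False

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not (0 <= self.lapse_left < 0.5 and 0 <= self.lapse_right < 0.5):
            raise ValueError("lapse rates must lie in [0, 0.5)")
        if self.lapse_left + self.lapse_right >= 1:
            raise ValueError("lapse rates must sum to < 1")
        if self.form not in ("gaussian", "logistic"):
            raise ValueError(f"unknown psychometric form: {self.form!r}")


def psychometric_probability(
    contrast: np.ndarray,
    bias: float,
    slope: float,
    lapse_left: float,
    lapse_right: float,
    form: str = "gaussian",
) -> np.ndarray:
    """P(rightward choice) at signed contrast ``contrast``."""
    c = np.asarray(contrast, dtype=float)
    z = (c - bias) / slope
    if form == "gaussian":
        core = stats.norm.cdf(z)
    elif form == "logistic":
        core = 1.0 / (1.0 + np.exp(-z))
    else:
        raise ValueError(f"unknown psychometric form: {form!r}")
    return lapse_left + (1.0 - lapse_left - lapse_right) * core


def predict_psychometric(params: PsychometricParams, contrast) -> np.ndarray:
    """Evaluate a psychometric model at signed contrast(s)."""
    return psychometric_probability(
        contrast,
        params.bias,
        params.slope,
        params.lapse_left,
        params.lapse_right,
        params.form,
    )


class PsychometricModel(BaseEstimator):
    """Maximum-likelihood psychometric curve, as an sklearn-style estimator.

    Parameters
    ----------
    form : {"gaussian", "logistic"}
        Shape of the core sigmoid.
    n_starts : int
        Number of multi-start initializations for the bounded optimizer.

    Attributes (after ``fit``)
    --------------------------
    bias_, slope_, lapse_left_, lapse_right_ : float
    params_ : PsychometricParams
    boundary_fit_ : bool
        True when any parameter landed on an optimization bound.
    nll_ : float
        Negative log-likelihood at the optimum.
    """

    def __init__(self, form: str = "gaussian", n_starts: int = 9):
        self.form = form
        self.n_starts = n_starts

    def fit(self, X, y):
        """Fit to signed contrasts ``X`` (1-D or (n, 1)) and binary rightward
        choices ``y``."""
        c = np.asarray(X, dtype=float).reshape(-1)
        choice = np.asarray(y, dtype=float).reshape(-1)
        if c.shape != choice.shape:
            raise ValueError("X and y must have the same length")
        if len(c) < 20:
            raise ValueError("need at least 20 trials to fit")
        if len(np.unique(c)) < 2:
            raise ValueError("need at least 2 distinct signed contrasts")
        if not np.all(np.isin(choice, (0.0, 1.0))):
            raise ValueError("y must be binary (1 = rightward choice)")

        def nll(theta):
            p = psychometric_probability(c, *theta, form=self.form)
            p = np.clip(p, 1e-9, 1 - 1e-9)
            return -np.sum(choice * np.log(p) + (1 - choice) * np.log(1 - p))

        span = max(np.ptp(c), 1.0)
        bounds = [
            (-_BIAS_MAX, _BIAS_MAX),
            (_SLOPE_MIN, _SLOPE_MAX),
            (0.0, _LAPSE_MAX),
            (0.0, _LAPSE_MAX),
        ]
        rng = np.random.default_rng(0)  # starts only; fit is deterministic in data
        starts = [np.array([np.median(c), span / 4, 0.05, 0.05])]
        for _ in range(self.n_starts - 1):
            starts.append(
                np.array(
                    [
                        rng.uniform(c.min(), c.max()),
                        rng.uniform(_SLOPE_MIN * 2, span),
                        rng.uniform(0, 0.2),
                        rng.uniform(0, 0.2),
                    ]
                )
            )
        best = None
        for x0 in starts:
            res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
        theta = best.x
        at_bound = any(
            np.isclose(v, lo, atol=1e-6) or np.isclose(v, hi, atol=1e-6)
            for v, (lo, hi) in zip(theta, bounds)
        )
        self.bias_, self.slope_, self.lapse_left_, self.lapse_right_ = theta
        self.boundary_fit_ = bool(at_bound)
        self.nll_ = float(best.fun)
        self.params_ = PsychometricParams(
            bias=float(theta[0]),
            slope=float(theta[1]),
            lapse_left=float(theta[2]),
            lapse_right=float(theta[3]),
            form=self.form,
            boundary_fit=self.boundary_fit_,
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise ValueError("model is not fitted")
        return predict_psychometric(self.params_, np.asarray(X, float).reshape(-1))


def fit_psychometric(trials: pd.DataFrame, form: str = "gaussian") -> PsychometricParams:
    """Fit the psychometric model to a trial table.

    Expects columns ``signed_contrast`` and ``choice`` ('L'/'R').
    """
    c = trials["signed_contrast"].to_numpy(dtype=float)
    y = (trials["choice"].to_numpy() == "R").astype(float)
    return PsychometricModel(form=form).fit(c, y).params_


def gaussian_smooth(
    signal: np.ndarray, sigma: float, frame_rate: float
) -> np.ndarray:
    """Convolve a series with a Gaussian of s.d. ``sigma`` seconds.

    The kernel is truncated at +/- 4 s.d. and renormalized; boundaries are
    reflective, so a constant signal passes through unchanged and the mean is
    preserved.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(signal, dtype=float)
    return ndimage.gaussian_filter1d(
        x, sigma=sigma * frame_rate, mode="reflect", truncate=4.0
    )


def block_average(signal: np.ndarray, factor: int) -> np.ndarray:
    """Downsample by averaging non-overlapping blocks of ``factor`` samples
    (trailing partial block dropped). Used to bring movement traces recorded
    at higher rates onto the imaging frame grid."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    x = np.asarray(signal, dtype=float)
    n = (len(x) // factor) * factor
    if n == 0:
        raise ValueError("signal shorter than one block")
    return x[:n].reshape(-1, factor).mean(axis=1)


@dataclass(frozen=True)
class ModulationResult:
    """Movement-modulation statistic with its circular-shift p-value."""

    r: float
    p_perm: float
    n_shifts: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("|r| must be <= 1")
        if not 0 < self.p_perm <= 1:
            raise ValueError("p_perm must lie in (0, 1]")


def _circular_shift_correlations(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between ``a`` and every circular shift of ``b``.

    Entry k is corr(a[t], b[(t + k) mod T]); computed for all T shifts at
    once via FFT cross-correlation (means and variances are shift-invariant).
    """
    t = len(a)
    az = a - a.mean()
    bz = b - b.mean()
    denom = np.sqrt((az @ az) * (bz @ bz))
    if denom == 0:
        raise ValueError("constant series: correlation undefined")
    cross = np.fft.irfft(np.fft.rfft(az) * np.conj(np.fft.rfft(bz)), n=t)
    # irfft gives sum_t az[t] * bz[(t - k) % T]; index -k for the +k shift
    return cross[(-np.arange(t)) % t] / denom


def movement_modulation(
    activity: np.ndarray,
    movement: np.ndarray,
    sigma: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
    frame_rate: float = 10.0,
    smooth: bool = True,
) -> ModulationResult:
    """Correlation of a neuron's activity with a movement trace, with a
    circular-shift permutation test.

    Both series are smoothed with a ``sigma``-second Gaussian (running-speed
    convention) unless ``smooth=False``. Significance: the movement series is
    circularly shifted by ``n_perm`` uniformly random offsets on [1, T-1] and
    p = (1 + #{|r_shift| >= |r|}) / (1 + n_perm).
    """
    a = np.asarray(activity, dtype=float)
    m = np.asarray(movement, dtype=float)
    if a.shape != m.shape or a.ndim != 1:
        raise ValueError("activity and movement must be equal-length 1-D series")
    if len(a) < 3:
        raise ValueError("series too short")
    if smooth:
        a = gaussian_smooth(a, sigma, frame_rate)
        m = gaussian_smooth(m, sigma, frame_rate)
    r_all = _circular_shift_correlations(a, m)
    r_obs = float(r_all[0])
    rng = np.random.default_rng(seed)
    shifts = rng.integers(1, len(a), size=n_perm)
    r_null = np.abs(r_all[shifts])
    p = (1.0 + np.count_nonzero(r_null >= abs(r_obs) - 1e-12)) / (1.0 + n_perm)
    return ModulationResult(r=r_obs, p_perm=float(p), n_shifts=int(n_perm))
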