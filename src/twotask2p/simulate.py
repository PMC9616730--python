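"""Ground-truth synthetic sessions for the two-task imaging pipeline.

Generates everything the downstream analyses consume, with known structure:

* per-neuron deconvolved activity traces at the imaging frame rate across up
  to five conditions (T-maze task ``TM``, steering-wheel task ``SW``, passive
  ball, passive wheel, hybrid), where each neuron belongs to a latent class —
  active only in the ball context, only in the wheel context, in both, or
  silent everywhere;
* trial tables (contrast, side, choice, reward, reaction time, repeat flag)
  whose choices follow a known psychometric curve;
* ROI pixel x time patches with a neuropil surround and a controllable
  cell/neuropil separation, for testing the isolation-distance statistic;
* piecewise-linear azimuth/elevation retinotopy with known field signs;
* running-speed (ball) and wheel-velocity (wheel) movement traces.

Every generator is a pure function of (config, seed). Traces are built as
kernel-convolved event responses for neurons whose class matches the
condition's physical context, plus a per-neuron baseline shared across
conditions (drawn once per neuron, log-normal), plus independent noise,
rectified at zero. The shared baseline is what makes a silent majority
produce strongly positive across-task activity correlations, mimicking the
effect of including anatomically silent neurons in a population comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .activity import RoiPixelPatch
from .behavior import gaussian_smooth, psychometric_probability
from .retinotopy import RetinotopyMaps

__all__ = [
    "SimConfig",
    "Kernel",
    "GroundTruthSession",
    "SyntheticRetinotopy",
    "generate_session",
    "generate_trials",
    "generate_roi_patch",
    "generate_retinotopy",
    "CLASSES",
    "CONDITIONS",
    "TASKS",
    "BALL_CONTEXT",
    "WHEEL_CONTEXT",
]

CLASSES = ("TM-only", "SW-only", "both", "silent")
CONDITIONS = ("TM", "SW", "passive_ball", "passive_wheel", "hybrid")
TASKS = ("TM", "SW", "hybrid")
#: Conditions sharing the ball (spherical treadmill) physical context.
BALL_CONTEXT = frozenset({"TM", "passive_ball"})
#: Conditions sharing the steering-wheel physical context (the hybrid task
#: uses the wheel apparatus with the maze's visual scene).
WHEEL_CONTEXT = frozenset({"SW", "passive_wheel", "hybrid"})


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class Kernel:
    """Event-response kernel: a Gaussian bump of given peak amplitude (a.u.),
    latency to peak (s), and width (s.d., s)."""

    amplitude: float = 1.0
    latency: float = 0.2
    width: float = 0.3

    def sample(self, frame_rate: float) -> np.ndarray:
        """Kernel sampled on the frame grid from 0 to latency + 4 widths."""
        n = max(int(math.ceil((self.latency + 4 * self.width) * frame_rate)), 1)
        t = np.arange(n) / frame_rate
        return self.amplitude * np.exp(
            -0.5 * ((t - self.latency) / self.width) ** 2
        )


def _default_kernels() -> dict[str, Kernel]:
    return {
        "stimulus": Kernel(amplitude=1.0, latency=0.2, width=0.3),
        "choice": Kernel(amplitude=0.8, latency=0.1, width=0.25),
        "reward": Kernel(amplitude=1.2, latency=0.15, width=0.3),
    }


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic sessions.

    ``fractions`` are the latent-class proportions over
    (TM-only, SW-only, both, silent); the defaults reflect an imaged
    population where over half of the active neurons are single-task with a
    minority active in both. ``contrast_set`` and ``frame_rate`` are the task
    contrasts (%) and per-plane imaging rate. The psychometric parameters
    generate choices; the kernel library generates event responses.
    Noise: ``baseline_scale`` scales a per-neuron log-normal baseline shared
    across all conditions; ``noise_scale`` is the s.d. of per-condition
    independent noise; ``ar1`` optionally colors that noise (the trial-to-
    trial correlation structure of real traces is not asserted — this is an
    exposed knob, default white).
    """

    n_neurons: int = 100
    fractions: tuple[float, float, float, float] = (0.40, 0.35, 0.15, 0.10)
    frame_rate: float = 10.0
    session_minutes: float = 10.0
    contrast_set: tuple[float, ...] = (0.0, 6.0, 12.0, 25.0, 50.0)
    psychometric_params: tuple[float, float, float, float] = (0.0, 10.0, 0.05, 0.05)
    kernel_library: dict[str, Kernel] = field(default_factory=_default_kernels)
    baseline_scale: float = 0.05
    noise_scale: float = 0.02
    gain_sigma: float = 0.3
    spontaneous_rate: float = 0.3  # Hz, passive-condition event rate
    ar1: float = 0.0
    neuropil_ratio: float = 5.0
    neuropil_coefficient: float = 0.7
    rt_median: float = 0.8  # s
    rt_sigma: float = 0.4  # log-space s.d.
    repeat_prob: float = 0.5  # P(repeat stimulus after an error)
    zero_contrast_reward_p: float = 0.5
    iti: float = 2.0  # s, inter-trial interval
    seed: int = 0

    def __post_init__(self) -> None:
        fr = np.asarray(self.fractions, dtype=float)
        if fr.shape != (4,):
            raise SimConfigError("fractions must have 4 entries "
                                 "(TM-only, SW-only, both, silent)")
        if np.any(fr < 0):
            raise SimConfigError("fractions must be nonnegative")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise SimConfigError(f"fractions must sum to 1 (got {fr.sum()})")
        if self.frame_rate <= 0:
            raise SimConfigError("frame_rate must be positive")
        cs = np.asarray(self.contrast_set, dtype=float)
        if cs.size == 0 or 0.0 not in cs or not np.any(cs > 0):
            raise SimConfigError(
                "contrast_set must contain 0 and at least one positive value"
            )
        if self.n_neurons < 1:
            raise SimConfigError("n_neurons must be >= 1")
        _, slope, ll, lr = self.psychometric_params
        if slope <= 0 or not (0 <= ll < 0.5 and 0 <= lr < 0.5):
            raise SimConfigError("invalid psychometric parameters")


@dataclass
class GroundTruthSession:
    """A generated session with its latent structure attached."""

    config: SimConfig
    seed: int
    condition_labels: tuple[str, ...]
    classes: np.ndarray  # latent class per neuron
    gains: np.ndarray  # per-neuron response gain
    baselines: np.ndarray  # shared per-neuron baseline (a.u.)
    choice_pref: dict[str, np.ndarray]  # signed preference per task
    traces: dict[str, np.ndarray]  # condition -> (n_neurons, T), >= 0
    trials: dict[str, pd.DataFrame]  # task -> trial table
    events: dict[str, dict]  # condition -> event streams for encoding
    running: dict[str, np.ndarray]  # ball conditions -> cm/s
    wheel: dict[str, np.ndarray]  # wheel conditions -> deg/s

    @property
    def n_neurons(self) -> int:
        return len(self.classes)

    def active_in(self, condition: str) -> np.ndarray:
        """Ground-truth mask of neurons with nonzero response in a
        condition's context."""
        ctx = "ball" if condition in BALL_CONTEXT else "wheel"
        if ctx == "ball":
            return (self.classes == "TM-only") | (self.classes == "both")
        return (self.classes == "SW-only") | (self.classes == "both")


def _class_active(classes: np.ndarray, condition: str) -> np.ndarray:
    if condition in BALL_CONTEXT:
        return (classes == "TM-only") | (classes == "both")
    if condition in WHEEL_CONTEXT:
        return (classes == "SW-only") | (classes == "both")
    raise SimConfigError(f"unknown condition: {condition!r}")


def generate_trials(
    config: SimConfig, task: str, n_trials: int, seed: int
) -> pd.DataFrame:
    """Generate a trial table for one task.

    Contrasts are drawn uniformly from ``config.contrast_set``; the side is
    uniform L/R for nonzero contrast. Choices are Bernoulli draws from the
    configured psychometric function of signed contrast (negative = left).
    Reward is choice == side for nonzero contrast; at zero contrast the
    reward is random with probability ``zero_contrast_reward_p``. Reaction
    times are log-normal; after an error the next trial repeats the stimulus
    with probability ``repeat_prob`` and is flagged.
    """
    if task not in TASKS:
        raise SimConfigError(f"unknown task label: {task!r}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    bias, slope, ll, lr = config.psychometric_params
    contrasts = np.asarray(config.contrast_set, dtype=float)

    rows = []
    t = config.iti
    prev_error = False
    prev_contrast, prev_side = 0.0, "none"
    for i in range(n_trials):
        is_repeat = prev_error and rng.random() < config.repeat_prob
        if is_repeat:
            contrast, side = prev_contrast, prev_side
        else:
            contrast = float(rng.choice(contrasts))
            side = ("R" if rng.random() < 0.5 else "L") if contrast > 0 else "none"
        signed = contrast * (1 if side == "R" else -1 if side == "L" else 0)
        p_right = float(
            psychometric_probability(signed, bias, slope, ll, lr)
        )
        choice = "R" if rng.random() < p_right else "L"
        if contrast > 0:
            rewarded = choice == side
        else:
            rewarded = bool(rng.random() < config.zero_contrast_reward_p)
        rt = float(rng.lognormal(math.log(config.rt_median), config.rt_sigma))
        rows.append(
            dict(
                trial_id=i,
                contrast=contrast,
                side=side,
                signed_contrast=signed,
                choice=choice,
                rewarded=rewarded,
                reaction_time=rt,
                repeat_flag=is_repeat,
                t_start=t,
                t_choice=t + rt,
            )
        )
        t += rt + config.iti
        prev_error, prev_contrast, prev_side = (not rewarded), contrast, side
    return pd.DataFrame(rows)


def _impulse_train(times: np.ndarray, frame_rate: float, T: int) -> np.ndarray:
    train = np.zeros(T)
    frames = np.round(np.asarray(times, float) * frame_rate).astype(int)
    frames = frames[(frames >= 0) & (frames < T)]
    np.add.at(train, frames, 1.0)
    return train


def _color_noise(noise: np.ndarray, ar1: float) -> np.ndarray:
    if ar1 == 0.0:
        return noise
    return sp_signal.lfilter([1.0], [1.0, -ar1], noise, axis=-1)


def generate_session(
    config: SimConfig,
    seed: int,
    conditions: tuple[str, ...] = ("TM", "SW", "passive_ball", "passive_wheel"),
) -> GroundTruthSession:
    """Generate a full multi-condition session with ground truth.

    Deterministic given (config, seed). Task conditions get trial-locked
    event responses (stimulus at trial start, choice at response time with
    amplitude modulated by the neuron's signed choice preference, reward
    shortly after correct choices); passive conditions get spontaneous
    Poisson events at ``config.spontaneous_rate``. Only neurons whose latent
    class matches the condition's physical context respond.
    """
    for cond in conditions:
        if cond not in CONDITIONS:
            raise SimConfigError(f"unknown condition: {cond!r}")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(0,))
    rng_pop, rng_cond = [np.random.default_rng(s) for s in ss.spawn(2)]

    n = config.n_neurons
    classes = rng_pop.choice(CLASSES, size=n, p=np.asarray(config.fractions))
    gains = rng_pop.lognormal(0.0, config.gain_sigma, size=n)
    baselines = config.baseline_scale * rng_pop.lognormal(0.0, 1.0, size=n)
    choice_pref = {
        task: rng_pop.uniform(-1.0, 1.0, size=n) for task in TASKS
    }

    T = int(round(config.session_minutes * 60 * config.frame_rate))
    fr = config.frame_rate
    kernels = {k: v.sample(fr) for k, v in config.kernel_library.items()}
    duration = T / fr

    traces: dict[str, np.ndarray] = {}
    trials: dict[str, pd.DataFrame] = {}
    events: dict[str, dict] = {}
    running: dict[str, np.ndarray] = {}
    wheel: dict[str, np.ndarray] = {}

    cond_rngs = dict(zip(conditions, rng_cond.spawn(len(conditions))))

    for cond in conditions:
        rng = cond_rngs[cond]
        active = _class_active(classes, cond)
        drive = np.zeros((n, T))

        if cond in TASKS:
            # ~6 s/trial on average; generate generously, keep what fits
            n_gen = max(int(duration / (config.rt_median + config.iti)) + 2, 1)
            table = generate_trials(
                config, cond, n_gen, seed=int(rng.integers(2**31))
            )
            table = table[table["t_choice"] < duration - 1.0].reset_index(drop=True)
            trials[cond] = table
            stim_t = table["t_start"].to_numpy()
            stim_side = table["side"].to_numpy()
            choice_t = table["t_choice"].to_numpy()
            choice_dir = table["choice"].to_numpy()
            reward_t = choice_t[table["rewarded"].to_numpy()] + 0.1
            events[cond] = {
                "stimulus": (stim_t, stim_side),
                "choice": (choice_t, choice_dir),
                "reward": reward_t,
            }
            stim_train = _impulse_train(stim_t, fr, T)
            cl_train = _impulse_train(choice_t[choice_dir == "L"], fr, T)
            cr_train = _impulse_train(choice_t[choice_dir == "R"], fr, T)
            rew_train = _impulse_train(reward_t, fr, T)
            conv = {
                "stim": np.convolve(stim_train, kernels["stimulus"])[:T],
                "cl": np.convolve(cl_train, kernels["choice"])[:T],
                "cr": np.convolve(cr_train, kernels["choice"])[:T],
                "rew": np.convolve(rew_train, kernels["reward"])[:T],
            }
            pref = choice_pref[cond]
            drive[active] = (
                np.outer(gains[active], conv["stim"])
                + np.outer(gains[active] * (1 - pref[active]), conv["cl"])
                + np.outer(gains[active] * (1 + pref[active]), conv["cr"])
                + np.outer(gains[active], conv["rew"])
            )
        else:
            # passive: per-neuron spontaneous events, stimulus-kernel shaped
            n_active = int(active.sum())
            p_event = min(config.spontaneous_rate / fr, 1.0)
            spikes = (rng.random((n_active, T)) < p_event).astype(float)
            if n_active > 0:
                resp = sp_signal.fftconvolve(
                    spikes, kernels["stimulus"][None, :], axes=1
                )[:, :T]
                drive[active] = gains[active, None] * resp
            events[cond] = {"stimulus": (np.array([]), np.array([])),
                            "choice": (np.array([]), np.array([])),
                            "reward": np.array([])}

        noise = _color_noise(
            rng.normal(0.0, 1.0, size=(n, T)), config.ar1
        ) * config.noise_scale
        traces[cond] = np.maximum(drive + baselines[:, None] + noise, 0.0)

        if cond in BALL_CONTEXT:
            run = gaussian_smooth(rng.normal(3.0, 4.0, T), 1.0, fr)
            running[cond] = np.maximum(run, 0.0)  # cm/s
            events[cond]["continuous"] = {"forward_velocity": running[cond]}
        else:
            w = gaussian_smooth(rng.normal(0.0, 30.0, T), 0.5, fr)  # deg/s
            if cond in trials:
                # turn pulses around choice times, signed by direction
                tbl = trials[cond]
                pulse = np.zeros(T)
                for tt, ch in zip(tbl["t_choice"], tbl["choice"]):
                    f = int(round(tt * fr))
                    lo, hi = max(f - 3, 0), min(f + 2, T)
                    pulse[lo:hi] += 60.0 if ch == "R" else -60.0
                w = w + pulse
            wheel[cond] = w
            events[cond]["continuous"] = {
                "wheel_ccw": np.maximum(w, 0.0),
                "wheel_cw": np.maximum(-w, 0.0),
            }

    return GroundTruthSession(
        config=config,
        seed=seed,
        condition_labels=tuple(conditions),
        classes=classes,
        gains=gains,
        baselines=baselines,
        choice_pref=choice_pref,
        traces=traces,
        trials=trials,
        events=events,
        running=running,
        wheel=wheel,
    )


def generate_roi_patch(
    config: SimConfig,
    separation: float,
    seed: int,
    n_cell_pixels: int = 30,
    n_frames: int = 1000,
    pixel_noise_sd: float = 0.3,
) -> RoiPixelPatch:
    """ROI pixel patch with a controllable cell/neuropil separation.

    All pixels share a common neuropil time course (unit variance); cell
    pixels additionally carry a rank-one signal — known per-pixel weights
    times a temporal trace of variance ``separation`` — so ``separation`` is
    the ratio of cell-signal variance to neuropil variance. At separation 0
    cell pixels are statistically identical to neuropil pixels.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    n_np_pixels = int(round(config.neuropil_ratio * n_cell_pixels))
    if n_cell_pixels < 2 or n_np_pixels < 2:
        raise ValueError("need at least 2 pixels in each compartment")
    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, 1.0, n_frames)
    cell_signal = math.sqrt(separation) * rng.normal(0.0, 1.0, n_frames)
    weights = rng.uniform(0.5, 1.5, n_cell_pixels)
    cell = (
        base[None, :]
        + np.outer(weights, cell_signal)
        + pixel_noise_sd * rng.normal(0.0, 1.0, (n_cell_pixels, n_frames))
    )
    neuropil = base[None, :] + pixel_noise_sd * rng.normal(
        0.0, 1.0, (n_np_pixels, n_frames)
    )
    return RoiPixelPatch(
        cell_pixels=cell, neuropil_pixels=neuropil, frame_rate=config.frame_rate
    )


@dataclass(frozen=True)
class SyntheticRetinotopy:
    """Generated retinotopy with ground-truth field signs attached
    (0 marks pixels on a fold line where the sign is undefined)."""

    maps: RetinotopyMaps
    true_sign: np.ndarray


def generate_retinotopy(
    shape: tuple[int, int],
    layout: str,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticRetinotopy:
    """Piecewise-linear azimuth/elevation maps with known field signs.

    Layouts: ``"single-non-mirror"`` — azimuth increases along x, elevation
    along y, ground-truth sign +1 everywhere. ``"mirror-pair"`` — the azimuth
    map folds back at the grid midline, giving a +1 region and a -1 region.
    ``noise_sd`` adds i.i.d. zero-mean Gaussian perturbation (deg) to both
    maps.
    """
    h, w = shape
    if h < 3 or w < 3:
        raise ValueError("grid must be at least 3x3")
    y, x = np.mgrid[0:h, 0:w].astype(float)
    scale = 60.0 / max(w - 1, 1)  # deg across the grid
    el = y * (40.0 / max(h - 1, 1))
    if layout == "single-non-mirror":
        az = x * scale
        truth = np.ones(shape, dtype=int)
    elif layout == "mirror-pair":
        az = np.minimum(x, (w - 1) - x) * 2 * scale
        truth = np.sign((w - 1) / 2.0 - x).astype(int)
    else:
        raise ValueError(f"unknown layout: {layout!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        az = az + rng.normal(0.0, noise_sd, shape)
        el = el + rng.normal(0.0, noise_sd, shape)
    return SyntheticRetinotopy(
        maps=RetinotopyMaps(azimuth=az, elevation=el), true_sign=truth
    )
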