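"""End-to-end pipeline over a synthetic session, and its configuration.

``run_pipeline`` executes simulate -> activity -> specificity -> encoding ->
choice selectivity -> behavior (-> retinotopy when enabled) and writes
per-stage outputs plus a JSON session report. All stage parameters default
to the analysis constants used throughout the package (activity threshold
0.3, the encoding windows and penalty grid with 11-fold CV, 1000
permutations, the 125 ms reaction-time cutoff, 10-trial minima).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import choice as choice_mod
from . import encoding as enc
from . import io as io_mod
from . import retinotopy as ret
from . import specificity as spec_mod
from .activity import mean_rate
from .behavior import fit_psychometric, movement_modulation
from .simulate import SimConfig, generate_retinotopy, generate_session

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "validate_report"]

logger = logging.getLogger("twotask2p")


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the culprit."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Parameters for every pipeline stage, with explicit seeds throughout."""

    sim: SimConfig = field(default_factory=lambda: SimConfig(n_neurons=60,
                                                             session_minutes=6.0))
    seed: int = 0
    conditions: tuple[str, ...] = ("TM", "SW", "passive_ball", "passive_wheel")
    activity_threshold: float = 0.3
    rate_threshold: float = 0.1  # active/inactive cut on mean rate (a.u./frame)
    lambda_grid: tuple[float, ...] = enc.LAMBDA_GRID
    n_folds: int = 11
    ve_threshold: float = enc.TASK_RELEVANT_VE
    n_perm: int = 1000
    min_trials_per_class: int = 10
    min_both_active: int = 10
    smooth_sigma: float = 1.0
    run_retinotopy: bool = True
    retinotopy_shape: tuple[int, int] = (40, 40)
    retinotopy_layout: str = "mirror-pair"
    sign_threshold: float = 0.3
    max_encode_neurons: int = 30  # cap per-neuron ridge fits for runtime
    out_dir: str | None = None
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.lambda_grid):
            raise ValueError("lambda grid entries must be positive")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.activity_threshold < 0 or self.rate_threshold < 0:
            raise ValueError("thresholds must be nonnegative")

    def hash(self) -> str:
        blob = json.dumps(io_mod._jsonable(dataclasses.asdict(self)),
                          sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


REPORT_SCHEMA = {
    "config_hash": str,
    "seed": int,
    "n_neurons": int,
    "categories": dict,
    "rho": dict,
    "within_vs_across": dict,
    "encoding": dict,
    "cccp": dict,
    "psychometric": dict,
    "movement": dict,
}


def validate_report(report: dict) -> None:
    """Check a session report against the published structure."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} has wrong type")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - re-typed with stage name
                raise PipelineError(name, str(e)) from e
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on one simulated session; return the session report.

    Deterministic given the config (all randomness flows from
    ``config.seed``); when ``config.out_dir`` is set, per-stage CSV/JSON
    outputs and the report are written there.
    """
    logging.basicConfig(level=config.verbosity)
    logger.info("pipeline start: config %s seed %d", config.hash(), config.seed)
    rng = np.random.default_rng(config.seed)

    session = _stage("simulate")(generate_session)(
        config.sim, seed=config.seed, conditions=config.conditions
    )
    fr = config.sim.frame_rate

    # --- activity: per-neuron mean deconvolved rate per condition
    @_stage("activity")
    def activity_stage():
        act = pd.DataFrame(
            {c: [mean_rate(tr) for tr in session.traces[c]]
             for c in session.condition_labels},
            index=pd.RangeIndex(session.n_neurons, name="neuron"),
        )
        return spec_mod.PopulationActivity(activity=act)

    pop = activity_stage()

    # --- specificity: categories, preferences, correlation matrices
    @_stage("specificity")
    def specificity_stage():
        a = pop.activity["TM"].to_numpy()
        b = pop.activity["SW"].to_numpy()
        cats = spec_mod.categorize(a, b, config.rate_threshold)
        prefs = spec_mod.task_preference(a, b)
        rho, pmat = spec_mod.correlation_matrix(pop)
        within, across = [], []
        for ci in pop.conditions:
            for cj in pop.conditions:
                if ci >= cj:
                    continue
                same = ({ci, cj} <= {"TM", "passive_ball"}
                        or {ci, cj} <= {"SW", "passive_wheel", "hybrid"})
                (within if same else across).append(rho.loc[ci, cj])
        if within and len(across) >= 1:
            tstat, tp = spec_mod.compare_within_across(within, across)
        else:
            tstat, tp = float("nan"), float("nan")
        counts = pd.Series(cats).value_counts().to_dict()
        return cats, prefs, rho, pmat, counts, (tstat, tp), (within, across)

    cats, prefs, rho, pmat, counts, (tstat, tp), _ = specificity_stage()

    # --- encoding: ridge fits per neuron per task
    @_stage("encode")
    def encode_stage():
        ve = {}
        n_fit = min(config.max_encode_neurons, session.n_neurons)
        for task in ("TM", "SW"):
            if task not in session.condition_labels:
                continue
            ev = session.events[task]
            streams = enc.EventStreams(
                stimulus_onsets=ev["stimulus"],
                choice_times=ev["choice"],
                reward_times=ev["reward"],
                continuous=ev.get("continuous", {}),
            )
            T = session.traces[task].shape[1]
            X = enc.build_design_matrix(streams, enc.KernelWindows(), fr, T)
            ve[task] = np.array([
                enc.fit_ridge_cv(X, session.traces[task][i],
                                 lambda_grid=config.lambda_grid,
                                 k=config.n_folds,
                                 model_label=task).cv_variance_explained
                for i in range(n_fit)
            ])
        summary = {t: {"median_ve": float(np.median(v)),
                       "n_task_relevant": int((v > config.ve_threshold).sum()),
                       "n_fit": len(v)} for t, v in ve.items()}
        if len(ve) == 2:
            r, p, _, _ = enc.encoding_cross_task(ve["TM"], ve["SW"],
                                                 config.ve_threshold)
            summary["cross_task"] = {"rho": r, "p": p}
        return ve, summary

    ve, enc_summary = encode_stage()

    # --- choice selectivity: ccCP per neuron per task
    @_stage("cccp")
    def cccp_stage():
        out = {}
        for task in ("TM", "SW"):
            if task not in session.trials:
                continue
            filt = choice_mod.filter_trials(
                session.trials[task], config.min_trials_per_class
            )
            if not filt.session_valid:
                out[task] = {"session_valid": False, "reason": filt.reason}
                continue
            tbl = filt.trials
            cond_key = tbl["signed_contrast"].to_numpy()
            chs = tbl["choice"].to_numpy()
            rows = []
            for i in range(session.n_neurons):
                acts = choice_mod.trial_activity(
                    session.traces[task][i], tbl, frame_rate=fr
                )
                res = choice_mod.cccp_permutation_p(
                    acts, cond_key, chs, n_perm=config.n_perm,
                    seed=int(rng.integers(2**31)),
                )
                rows.append({"neuron": i, "cccp": res.cccp, "p": res.p_perm})
            out[task] = {
                "session_valid": True,
                "table": pd.DataFrame(rows),
                "n_trials": len(tbl),
            }
        return out

    cccp_out = cccp_stage()

    # --- behavior: psychometrics per task + running modulation
    @_stage("behavior")
    def behavior_stage():
        psych = {}
        for task, tbl in session.trials.items():
            if len(tbl) >= 20 and tbl["signed_contrast"].nunique() >= 2:
                p = fit_psychometric(tbl)
                psych[task] = {"bias": p.bias, "slope": p.slope,
                               "lapse_left": p.lapse_left,
                               "lapse_right": p.lapse_right,
                               "boundary_fit": p.boundary_fit}
        movement = {}
        if "passive_ball" in session.running:
            run = session.running["passive_ball"]
            rs = [
                movement_modulation(
                    session.traces["passive_ball"][i], run,
                    sigma=config.smooth_sigma, n_perm=config.n_perm,
                    seed=int(rng.integers(2**31)), frame_rate=fr,
                )
                for i in range(session.n_neurons)
            ]
            movement = {
                "n_significant": int(sum(m.p_perm < 0.05 for m in rs)),
                "median_r": float(np.median([m.r for m in rs])),
                "n_neurons": len(rs),
            }
        return psych, movement

    psych, movement = behavior_stage()

    # --- retinotopy (optional)
    retino = {}
    if config.run_retinotopy:
        @_stage("retinotopy")
        def retinotopy_stage():
            synth = generate_retinotopy(
                config.retinotopy_shape, config.retinotopy_layout,
                noise_sd=0.5, seed=config.seed,
            )
            fs = ret.field_sign(synth.maps)
            seg = ret.segment_sign_regions(fs, config.sign_threshold)
            return {
                "n_regions": int(len(seg.region_signs)),
                "region_signs": {str(k): v for k, v in seg.region_signs.items()},
            }

        retino = retinotopy_stage()

    report = {
        "config_hash": config.hash(),
        "seed": int(config.seed),
        "n_neurons": int(session.n_neurons),
        "categories": {str(k): int(v) for k, v in counts.items()},
        "rho": {c: {d: float(rho.loc[c, d]) for d in rho.columns}
                for c in rho.index},
        "within_vs_across": {"t": float(tstat), "p": float(tp)},
        "encoding": io_mod._jsonable(enc_summary),
        "cccp": {
            t: ({"session_valid": False, "reason": v["reason"]}
                if not v["session_valid"] else
                {"session_valid": True,
                 "n_trials": v["n_trials"],
                 "n_significant": int((v["table"]["p"] < 0.05).sum()),
                 "median_cccp": float(v["table"]["cccp"].median())})
            for t, v in cccp_out.items()
        },
        "psychometric": io_mod._jsonable(psych),
        "movement": io_mod._jsonable(movement),
        "retinotopy": retino,
    }
    validate_report(report)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io_mod.save_session(session, out / "session")
        pd.DataFrame(
            {"neuron": np.arange(session.n_neurons),
             "category": cats, "preference": prefs}
        ).to_csv(out / "specificity.csv", index=False)
        rho.to_csv(out / "rho_matrix.csv")
        for t, v in cccp_out.items():
            if v.get("session_valid"):
                v["table"].to_csv(out / f"cccp_{t}.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    logger.info("pipeline done")
    return report
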