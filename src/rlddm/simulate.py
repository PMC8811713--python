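"""Forward simulation: DDM trials, RLDDM agents, task schedules, recovery.

The generative counterpart of the likelihood.  Single first-passage draws
use Euler-Maruyama integration of the diffusion (default dt = 1e-4 s) with
a 20 s horizon after which the trial is redrawn; the discretization is
guarded by distributional tests against the analytic wfpt density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _wfpt
from .data import TrialTable
from .likelihood import DDMParams
from .model import A_FLOOR, _invlogit

DEFAULT_DT = 1e-4
DEFAULT_HORIZON = 20.0


@dataclass
class TaskSchedule:
    """Reward schedule of a two-option instrumental task.

    ``conditions`` holds (label, p_reward_upper, p_reward_lower, n_trials)
    per condition; ``q_init`` seeds both options' expected values.
    """

    conditions: list
    q_init: float = 0.5

    def __post_init__(self) -> None:
        for label, p_up, p_lo, n in self.conditions:
            if not (0 <= p_up <= 1 and 0 <= p_lo <= 1):
                raise ValueError(f"condition {label!r}: probabilities must be in [0,1]")
            if n < 1:
                raise ValueError(f"condition {label!r}: n_trials must be >= 1")

    @property
    def n_trials_total(self) -> int:
        return sum(c[3] for c in self.conditions)


def pst_schedule(n_trials: int = 60) -> TaskSchedule:
    """The probabilistic selection task learning phase: three condition
    pairs rewarded 80/20 (AB), 70/30 (CD) and 60/40 (EF) percent, with
    binary 0/1 feedback and unbiased initial values of 0.5."""
    return TaskSchedule(conditions=[
        ("AB", 0.8, 0.2, n_trials),
        ("CD", 0.7, 0.3, n_trials),
        ("EF", 0.6, 0.4, n_trials),
    ], q_init=0.5)


@dataclass
class RecoveryDesign:
    """Grid design of the group-parameter recovery study.

    Defaults: all 81 combinations of a in {1.5, 2.0, 2.5}, t in {0.3, 0.4,
    0.5}, alpha in {0.15, 0.3, 0.45} and v in {1.5, 2.25, 3.0}; subject SDs
    a 0.1, t 0.02, alpha 0.1 (probability scale), v 0.25; 40 subjects with
    60 trials in each of the three task conditions.
    """

    a_grid: tuple = (1.5, 2.0, 2.5)
    t_grid: tuple = (0.3, 0.4, 0.5)
    alpha_grid: tuple = (0.15, 0.3, 0.45)
    v_grid: tuple = (1.5, 2.25, 3.0)
    subject_sds: dict = field(default_factory=lambda: {
        "a": 0.1, "t": 0.02, "alpha": 0.1, "v": 0.25})
    n_subjects: int = 40
    n_trials: int = 60
    seed: int = 0

    def cells(self):
        for a in self.a_grid:
            for t in self.t_grid:
                for alpha in self.alpha_grid:
                    for v in self.v_grid:
                        yield {"a": a, "t": t, "alpha": alpha, "v": v}


def _seed_kernels(rng: np.random.Generator) -> None:
    _wfpt.seed_numba(int(rng.integers(2 ** 31)))


def sample_ddm_trial(params: DDMParams, rng: np.random.Generator,
                     dt: float = DEFAULT_DT,
                     horizon: float = DEFAULT_HORIZON):
    """One simulated decision -> (boundary, rt); boundary 1 = upper."""
    _seed_kernels(rng)
    b, rt = _wfpt.em_first_passage(params.a, params.v, params.t, params.z,
                                   params.s_v, params.s_t, params.s_z,
                                   dt, horizon)
    return int(b), float(rt)


def sample_ddm_trials(n: int, params: DDMParams, rng: np.random.Generator,
                      dt: float = DEFAULT_DT, horizon: float = DEFAULT_HORIZON):
    """n independent simulated decisions -> (responses, rts)."""
    _seed_kernels(rng)
    return _wfpt.em_sample_many(n, params.a, params.v, params.t, params.z,
                                params.s_v, params.s_t, params.s_z, dt, horizon)


def _draw_subject_params(group_means: dict, subject_sds: dict,
                         rng: np.random.Generator,
                         alpha_scale: str = "logit-delta",
                         max_retries: int = 100) -> dict:
    out = {}
    for name, mu in group_means.items():
        sd = subject_sds.get(name, 0.0)
        if name in ("alpha", "alpha_neg"):
            p = float(mu)
            if alpha_scale == "probability":
                for _ in range(max_retries):
                    x = rng.normal(p, sd) if sd > 0 else p
                    if 0 < x < 1:
                        break
                else:
                    x = np.clip(p, 1e-3, 1 - 1e-3)
                out[name] = float(x)
            else:
                # normal on the logit scale; the probability-scale SD maps
                # through the delta method: sd_logit = sd / (p (1 - p))
                raw_mu = np.log(p / (1 - p))
                raw_sd = sd / (p * (1 - p)) if sd > 0 else 0.0
                out[name] = float(_invlogit(rng.normal(raw_mu, raw_sd)
                                            if raw_sd > 0 else raw_mu))
        else:
            lo = 0.0 if name in ("a", "t") else -np.inf
            for _ in range(max_retries):
                x = rng.normal(mu, sd) if sd > 0 else mu
                if name == "z":
                    if 0 < x < 1:
                        break
                elif x > lo or (name == "t" and x >= 0):
                    break
            else:
                x = max(mu, lo + 1e-3)
            out[name] = float(x)
    return out


def simulate_rlddm_dataset(group_means: dict, subject_sds: dict,
                           schedule: TaskSchedule, n_subjects: int,
                           seed: int | np.random.Generator = 0,
                           dual: bool = False,
                           alpha_scale: str = "logit-delta",
                           dt: float = DEFAULT_DT,
                           horizon: float = DEFAULT_HORIZON) -> TrialTable:
    """Simulate a full multi-subject RLDDM dataset on a task schedule.

    Subject parameters are drawn from normal distributions around the group
    means (the learning rate on the logit scale, see ``alpha_scale``); each
    trial's drift is the running value difference times the subject's
    scaling parameter, feedback is Bernoulli per the schedule, and values
    update by the delta rule.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    frames = []
    for j in range(n_subjects):
        p = _draw_subject_params(group_means, subject_sds, rng,
                                 alpha_scale=alpha_scale)
        a, v, t = p["a"], p["v"], p["t"]
        z = p.get("z", 0.5)
        ap = p.get("alpha", 0.0)
        an = p.get("alpha_neg", ap) if dual else ap
        s_v = p.get("s_v", 0.0)
        s_t = p.get("s_t", 0.0)
        s_z = p.get("s_z", 0.0)
        _seed_kernels(rng)
        for label, p_up, p_lo, n in schedule.conditions:
            resp, rt, fb = _wfpt.sim_rl_block(
                n, p_up, p_lo, schedule.q_init, a, v, t, z, ap, an,
                s_v, s_t, s_z, dt, horizon)
            frames.append(pd.DataFrame({
                "rt": rt, "response": resp, "split_by": label,
                "subj_idx": j, "feedback": fb, "q_init": schedule.q_init}))
    return TrialTable(pd.concat(frames, ignore_index=True))


def simulate_regression_dataset(baseline: float, coefficient: float,
                                group_means: dict, subject_sds: dict,
                                schedule: TaskSchedule, n_subjects: int,
                                seed: int | np.random.Generator = 0,
                                covariate: str = "neural",
                                alpha_scale: str = "logit-delta",
                                dt: float = DEFAULT_DT,
                                horizon: float = DEFAULT_HORIZON) -> TrialTable:
    """Simulate RLDDM data whose decision threshold varies trial by trial.

    The covariate is drawn Normal(0, 1) per trial and the trial threshold
    is ``baseline + coefficient * covariate`` (floored at a small positive
    bound); everything else follows :func:`simulate_rlddm_dataset`.
    ``group_means`` supplies v, t and alpha (any ``a`` entry is ignored).
    """
    if not np.isfinite(coefficient):
        raise ValueError("coefficient must be finite")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    frames = []
    for j in range(n_subjects):
        p = _draw_subject_params(
            {k: v for k, v in group_means.items() if k != "a"},
            subject_sds, rng, alpha_scale=alpha_scale)
        v, t = p["v"], p["t"]
        z = p.get("z", 0.5)
        ap = p.get("alpha", 0.0)
        _seed_kernels(rng)
        for label, p_up, p_lo, n in schedule.conditions:
            x = rng.normal(0.0, 1.0, size=n)
            a_arr = np.maximum(baseline + coefficient * x, A_FLOOR)
            resp, rt, fb = _wfpt.sim_rl_block_atrial(
                n, p_up, p_lo, schedule.q_init, a_arr, v, t, z, ap, ap,
                0.0, 0.0, 0.0, dt, horizon)
            frames.append(pd.DataFrame({
                "rt": rt, "response": resp, "split_by": label,
                "subj_idx": j, "feedback": fb, "q_init": schedule.q_init,
                covariate: x}))
    return TrialTable(pd.concat(frames, ignore_index=True))


def simulate_from_subject_params(subject_params: list[dict],
                                 schedule: TaskSchedule,
                                 rng: np.random.Generator,
                                 dt: float = DEFAULT_DT,
                                 horizon: float = DEFAULT_HORIZON) -> TrialTable:
    """Simulate one dataset from explicit per-subject parameter dicts.

    Used by posterior predictive checks, where each replicate takes the
    subject-level parameters of one posterior draw.
    """
    frames = []
    for j, p in enumerate(subject_params):
        _seed_kernels(rng)
        for label, p_up, p_lo, n in schedule.conditions:
            resp, rt, fb = _wfpt.sim_rl_block(
                n, p_up, p_lo, schedule.q_init,
                p["a"], p["v"], p["t"], p.get("z", 0.5),
                p.get("alpha", 0.0), p.get("alpha_neg", p.get("alpha", 0.0)),
                p.get("s_v", 0.0), p.get("s_t", 0.0), p.get("s_z", 0.0),
                dt, horizon)
            frames.append(pd.DataFrame({
                "rt": rt, "response": resp, "split_by": label,
                "subj_idx": j, "feedback": fb, "q_init": schedule.q_init}))
    return TrialTable(pd.concat(frames, ignore_index=True))


def run_recovery(design: RecoveryDesign, fit_config=None,
                 schedule: TaskSchedule | None = None,
                 cells=None, alpha_scale: str = "logit-delta",
                 verbose: bool = False) -> pd.DataFrame:
    """Simulate-and-refit over a grid of generating group parameters.

    For every grid cell a dataset is simulated, the default hierarchical
    RLDDM is fit, and the posterior means of the group parameters are
    recorded next to the generating truth.  Individual fit failures are
    recorded (``error`` column) rather than fatal.  Returns a tidy frame
    with one row per (cell, parameter).
    """
    from .diagnostics import invlogit
    from .model import ModelSpec, build_model
    from .sampler import SamplerConfig, sample_posterior

    if fit_config is None:
        fit_config = SamplerConfig()
    if schedule is None:
        schedule = pst_schedule(design.n_trials)
    if cells is None:
        cells = list(design.cells())
    rows = []
    rng = np.random.default_rng(design.seed)
    for ci, cell in enumerate(cells):
        data = simulate_rlddm_dataset(cell, design.subject_sds, schedule,
                                      design.n_subjects,
                                      seed=np.random.default_rng(
                                          [design.seed, ci]),
                                      alpha_scale=alpha_scale)
        err = ""
        try:
            model = build_model(data, ModelSpec())
            cfg = SamplerConfig(n_samples=fit_config.n_samples,
                                n_burn=fit_config.n_burn,
                                n_chains=fit_config.n_chains,
                                seed=int(rng.integers(2 ** 31)))
            store = sample_posterior(model, cfg)
            est = {
                "a": store.mean("a"),
                "t": store.mean("t"),
                "v": store.mean("v"),
                "alpha": float(np.mean(invlogit(store.pooled("alpha")))),
            }
        except Exception as exc:  # recorded, not fatal
            err = f"{type(exc).__name__}: {exc}"
            est = {k: np.nan for k in ("a", "t", "v", "alpha")}
        for param in ("a", "t", "v", "alpha"):
            truth = cell[param]
            rows.append({
                "cell": ci, "parameter": param, "truth": truth,
                "estimate": est[param],
                "abs_error": abs(est[param] - truth),
                "n_subjects": design.n_subjects,
                "n_trials": design.n_trials, "error": err})
        if verbose:
            print(f"cell {ci + 1}/{len(cells)} done")
    return pd.DataFrame(rows)
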