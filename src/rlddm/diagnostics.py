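"""Posterior summaries, convergence diagnostics, DIC, predictive checks.

Summaries follow the familiar print-stats layout (mean, SD, and the
2.5/25/50/75/97.5 posterior percentiles).  Convergence uses the classic
Gelman-Rubin potential scale reduction factor (between- vs within-chain
variance; heuristic bound 1.1).  Model comparison is by DIC.  Posterior
predictive checks simulate full datasets from posterior draws on the task
schedule and summarize choice evolution, signed RT distributions, and
quantile-probability data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import _invlogit
from .sampler import PosteriorStore
from .simulate import TaskSchedule, simulate_from_subject_params

SUMMARY_COLUMNS = ["mean", "std", "2.5q", "25q", "50q", "75q", "97.5q"]


def invlogit(x):
    """Inverse logit e^x / (1 + e^x), overflow-safe for large |x|."""
    return _invlogit(x)


def _transformed_families(name: str) -> bool:
    base = name.split("(")[0].split(".")[0]
    for fam in ("alpha", "alpha_neg", "z"):
        if base == fam or base == f"{fam}_subj":
            return True
    return False


def summarize(store: PosteriorStore) -> pd.DataFrame:
    """Posterior summary table, chains pooled.

    Quantiles use linear interpolation (numpy default) so outputs are
    reproducible.  Inverse-logit-transformed parameters (learning rates and
    starting points, which are sampled on the unconstrained scale) are
    additionally reported on the probability scale as ``<name>_trans``.
    """
    if store.n_draws == 0:
        raise ValueError("empty posterior store")
    rows = {}
    for name in store.params:
        x = store.pooled(name)
        qs = np.quantile(x, [0.025, 0.25, 0.5, 0.75, 0.975])
        rows[name] = [x.mean(), x.std(ddof=1) if x.size > 1 else 0.0, *qs]
        if _transformed_families(name):
            y = _invlogit(x)
            qs = np.quantile(y, [0.025, 0.25, 0.5, 0.75, 0.975])
            rows[f"{name}_trans"] = [y.mean(),
                                     y.std(ddof=1) if y.size > 1 else 0.0, *qs]
    return pd.DataFrame.from_dict(rows, orient="index", columns=SUMMARY_COLUMNS)


def _chain_matrix(stores_or_store, name: str) -> np.ndarray:
    if isinstance(stores_or_store, PosteriorStore):
        return stores_or_store.get(name)
    return np.vstack([s.get(name) for s in stores_or_store])


def gelman_rubin(stores_or_store) -> dict:
    """Potential scale reduction factor per parameter.

    Accepts one multi-chain store or a list of same-model stores (one per
    run).  Classic statistic: with m chains of length n, W the mean
    within-chain variance and B/n the variance of chain means,
    R-hat = sqrt(((n-1)/n W + B/n) / W), floored at 1 (so identical chains
    report exactly 1).  Values below the 1.1 heuristic indicate convergence.
    """
    if isinstance(stores_or_store, PosteriorStore):
        params = stores_or_store.params
        m = stores_or_store.n_chains
    else:
        stores_or_store = list(stores_or_store)
        params = stores_or_store[0].params
        m = sum(s.n_chains for s in stores_or_store)
    if m < 2:
        raise ValueError("gelman_rubin needs at least two chains")
    out = {}
    for name in params:
        chains = _chain_matrix(stores_or_store, name)
        n = chains.shape[1]
        within = chains.var(axis=1, ddof=1).mean()
        between = n * chains.mean(axis=1).var(ddof=1)
        if within == 0:
            out[name] = 1.0
            continue
        var_plus = (n - 1) / n * within + between / n
        out[name] = max(float(np.sqrt(var_plus / within)), 1.0)
    return out


def autocorrelation(draws, max_lag: int) -> np.ndarray:
    """Sample autocorrelation of one chain at lags 0..max_lag."""
    x = np.asarray(draws, dtype=float)
    n = x.size
    if n <= max_lag:
        raise ValueError("chain length must exceed max_lag")
    x = x - x.mean()
    c0 = (x * x).sum() / n
    if c0 == 0:
        return np.concatenate([[1.0], np.zeros(max_lag)])
    acf = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        acf[k] = (x[:n - k] * x[k:]).sum() / n / c0
    return acf


def dic(store: PosteriorStore, model, max_draws: int | None = None) -> dict:
    """Deviance information criterion of a fitted model.

    DIC = mean deviance + p_D, where p_D = mean deviance minus the deviance
    at the posterior mean of the parameters (transformed parameters
    averaged on the unconstrained scale, which is the scale the draws are
    stored on).  ``model`` must expose ``total_loglik(state)`` over the
    store's parameter order.  Returns a dict with dic, mean_deviance, p_d.
    """
    draws = store.draws.reshape(-1, len(store.params))
    if max_draws is not None and draws.shape[0] > max_draws:
        idx = np.linspace(0, draws.shape[0] - 1, max_draws).astype(int)
        draws = draws[idx]
    devs = np.array([-2.0 * model.total_loglik(d) for d in draws])
    mean_dev = float(devs.mean())
    d_at_mean = -2.0 * model.total_loglik(draws.mean(axis=0))
    p_d = mean_dev - float(d_at_mean)
    return {"dic": mean_dev + p_d, "mean_deviance": mean_dev, "p_d": p_d}


def hdi(samples, mass: float = 0.9) -> tuple:
    """Narrowest interval containing the requested probability mass."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    k = max(int(np.ceil(mass * n)), 1)  # samples inside the interval
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1:] - x[:n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


@dataclass
class PPCResult:
    """Posterior predictive summaries.

    ``choice_curves``: per condition and 4-trial bin, the predicted choice
    proportion of the upper (better) option with a 90% HDI band across
    replicates, plus the observed proportion when observed data were given.
    ``rt_pred`` / ``rt_obs``: signed RTs per condition (lower-boundary
    choices negated).  ``qp``: choice proportions and RT quantiles by
    inferred difficulty tercile of |Q_upper - Q_lower|.
    """

    choice_curves: pd.DataFrame
    rt_pred: dict
    rt_obs: dict | None
    qp: pd.DataFrame
    n_replicates: int


QP_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)
BIN_SIZE = 4


def _subject_params_from_draw(store, model, chain: int, draw: int) -> list:
    params = []
    state = store.draws[chain, draw]
    idx = {p: i for i, p in enumerate(store.params)}
    for j, subj in enumerate(model.subjects):
        p = {}
        for (fam, cond, jj), node in model.subj_idx.items():
            if jj != j or cond is not None:
                continue
            val = state[idx[model.node_names[node]]]
            if fam in ("alpha", "alpha_neg", "z"):
                val = _invlogit(val)
            p[fam] = float(val)
        for sname in ("s_v", "s_t", "s_z"):
            if sname in model.coef_idx:
                p[sname] = float(state[idx[sname]])
        params.append(p)
    return params


def _qp_table(tables, alpha_by_subject, edges=None, source="predicted"):
    """Quantile-probability rows from one or more trial tables."""
    qd_all, rt_all, resp_all = [], [], []
    for table in tables:
        for subj, _cond, block in table.iter_blocks():
            from ._wfpt import q_trajectory_kernel
            resp = block["response"].to_numpy(dtype=np.int64)
            fb = block["feedback"].to_numpy(dtype=np.float64)
            a = alpha_by_subject.get(subj, 0.0)
            qu, ql, _ = q_trajectory_kernel(resp, fb,
                                            float(block["q_init"].iloc[0]), a, a)
            qd_all.append(np.abs(qu - ql))
            rt_all.append(block["rt"].to_numpy(dtype=float))
            resp_all.append(resp)
    qd = np.concatenate(qd_all)
    rt = np.concatenate(rt_all)
    resp = np.concatenate(resp_all)
    if edges is None:
        edges = np.quantile(qd, [1 / 3, 2 / 3])
    tercile = np.digitize(qd, edges)  # 0 = high conflict .. 2 = low conflict
    labels = {0: "high", 1: "medium", 2: "low"}  # difficulty
    rows = []
    for tc in (0, 1, 2):
        m = tercile == tc
        if not m.any():
            continue
        prop_upper = resp[m].mean()
        for boundary, sel in (("upper", m & (resp == 1)),
                              ("lower", m & (resp == 0))):
            if not sel.any():
                continue
            for q in QP_QUANTILES:
                rows.append({
                    "difficulty": labels[2 - tc], "boundary": boundary,
                    "choice_prop": prop_upper if boundary == "upper"
                    else 1 - prop_upper,
                    "quantile": q, "rt": float(np.quantile(rt[sel], q)),
                    "source": source})
    return pd.DataFrame(rows), edges


def posterior_predict(store: PosteriorStore, model, schedule: TaskSchedule,
                      n_replicates: int = 100, seed: int = 0,
                      observed=None) -> PPCResult:
    """Simulate replicate datasets from posterior draws and summarize them.

    Each replicate draws one joint parameter vector (a retained MCMC draw),
    takes its subject-level parameters, and simulates the full task
    schedule.  Observed data, when given, are only overlaid on the
    summaries -- they never influence the simulations.
    """
    if getattr(model, "regressions", None):
        raise ValueError("posterior predictive simulation is defined for "
                         "non-regression models")
    rng = np.random.default_rng(seed)
    conds = [c[0] for c in schedule.conditions]
    curves = {c: [] for c in conds}
    rt_pred = {c: [] for c in conds}
    qp_frames = []
    alpha_mean = {}
    idx = {p: i for i, p in enumerate(store.params)}
    for j, subj in enumerate(model.subjects):
        name = f"alpha_subj.{subj}"
        if name in idx:
            alpha_mean[j] = float(_invlogit(store.pooled(name)).mean())
        else:
            alpha_mean[j] = 0.0

    # difficulty tercile edges from posterior-mean trajectories on the
    # observed data when available, else from the first replicates
    edges = None
    if observed is not None:
        obs_alpha = {s: alpha_mean[model.subjects.index(s)]
                     for s in observed.subjects if s in model.subjects}
        qp_obs, edges = _qp_table([observed], obs_alpha, source="observed")
        qp_frames.append(qp_obs)

    sims = []
    for _ in range(n_replicates):
        chain = rng.integers(store.n_chains)
        draw = rng.integers(store.n_draws)
        sp = _subject_params_from_draw(store, model, chain, draw)
        sim = simulate_from_subject_params(sp, schedule, rng)
        sims.append(sim)
        df = sim.df
        for c in conds:
            sub = df[df["split_by"] == c]
            per_subj = sub.groupby("subj_idx")["response"]
            # trial index within block, then 4-trial bins
            resp_mat = np.vstack([g.to_numpy() for _, g in per_subj])
            nbin = resp_mat.shape[1] // BIN_SIZE
            binned = resp_mat[:, :nbin * BIN_SIZE].reshape(
                resp_mat.shape[0], nbin, BIN_SIZE).mean(axis=(0, 2))
            curves[c].append(binned)
            signed = np.where(sub["response"] == 1, sub["rt"], -sub["rt"])
            rt_pred[c].append(np.asarray(signed, dtype=float))

    sim_alpha = {j: alpha_mean[j] for j in range(len(model.subjects))}
    qp_pred, _ = _qp_table(sims[:min(20, len(sims))], sim_alpha,
                           edges=edges, source="predicted")
    qp_frames.append(qp_pred)

    rows = []
    for c in conds:
        mat = np.vstack(curves[c])
        for b in range(mat.shape[1]):
            lo, hi = hdi(mat[:, b], 0.9)
            row = {"condition": c, "bin": b, "pred_mean": mat[:, b].mean(),
                   "hdi_low": lo, "hdi_high": hi, "observed": np.nan}
            rows.append(row)
    curve_df = pd.DataFrame(rows)

    rt_obs = None
    if observed is not None:
        rt_obs = {}
        df = observed.df
        for c in conds:
            sub = df[df["split_by"] == c]
            rt_obs[c] = np.where(sub["response"] == 1, sub["rt"],
                                 -sub["rt"]).astype(float)
            per_subj = sub.groupby("subj_idx")["response"]
            resp_mat = np.vstack([g.to_numpy() for _, g in per_subj])
            nbin = resp_mat.shape[1] // BIN_SIZE
            binned = resp_mat[:, :nbin * BIN_SIZE].reshape(
                resp_mat.shape[0], nbin, BIN_SIZE).mean(axis=(0, 2))
            sel = curve_df["condition"] == c
            curve_df.loc[sel, "observed"] = binned[:sel.sum()]

    return PPCResult(choice_curves=curve_df,
                     rt_pred={c: np.concatenate(v) for c, v in rt_pred.items()},
                     rt_obs=rt_obs,
                     qp=pd.concat(qp_frames, ignore_index=True),
                     n_replicates=n_replicates)


def plot_ppc(result: PPCResult, path=None):
    """Choice-evolution curves with 90% HDI bands and signed-RT densities."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    conds = list(dict.fromkeys(result.choice_curves["condition"]))
    fig, axes = plt.subplots(2, len(conds), figsize=(4 * len(conds), 6),
                             squeeze=False)
    for i, c in enumerate(conds):
        sub = result.choice_curves[result.choice_curves["condition"] == c]
        ax = axes[0][i]
        ax.fill_between(sub["bin"], sub["hdi_low"], sub["hdi_high"],
                        alpha=0.3, color="green", label="predicted 90% HDI")
        ax.plot(sub["bin"], sub["pred_mean"], color="green")
        if sub["observed"].notna().any():
            ax.plot(sub["bin"], sub["observed"], color="tab:blue",
                    label="observed")
        ax.set_ylim(0, 1)
        ax.set_title(f"condition {c}")
        ax.set_xlabel("4-trial bin")
        if i == 0:
            ax.set_ylabel("p(upper choice)")
            ax.legend(fontsize=8)
        ax = axes[1][i]
        grid = np.linspace(-4, 4, 400)
        pred = result.rt_pred[c]
        ax.plot(grid, gaussian_kde(pred)(grid), color="green")
        if result.rt_obs is not None:
            ax.plot(grid, gaussian_kde(result.rt_obs[c])(grid),
                    color="tab:blue")
        ax.set_xlabel("signed RT (s)")
        if i == 0:
            ax.set_ylabel("density")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_qp(result: PPCResult, path=None):
    """Quantile-probability plot: RT quantiles vs choice proportions."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    colors = {"observed": "tab:blue", "predicted": "green"}
    for source, sub in result.qp.groupby("source"):
        for (_d, _b), grp in sub.groupby(["difficulty", "boundary"]):
            ax.plot(grp["choice_prop"], grp["rt"], "o-", ms=3,
                    color=colors.get(source, "gray"), alpha=0.7)
    ax.set_xlabel("choice proportion")
    ax.set_ylabel("RT quantile (s)")
    handles = [plt.Line2D([], [], color=c, marker="o", label=s)
               for s, c in colors.items()]
    ax.legend(handles=handles, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
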