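"""Markov chain Monte Carlo over the hierarchical graph.

Each free node is updated in turn by univariate slice sampling (Neal 2003:
stepping-out then shrinkage), a rejection-free scheme that only needs log
densities.  Group nodes condition on their subject nodes; subject nodes
condition on their group distribution and on that subject's likelihood;
group-level likelihood nodes (between-trial variabilities, regression
coefficients) condition on the full likelihood.  Per-subject likelihoods
are cached so a node update only recomputes what it can change.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from .model import RLDDMModel


class InitializationError(RuntimeError):
    pass


@dataclass
class SamplerConfig:
    """Sampling run configuration.

    Defaults mirror the basic workflow: 1500 draws with the first 500
    discarded as burn-in, one chain.  Convergence checks are run with three
    chains.  ``width`` is the initial slice bracket (on the sampled scale);
    ``max_steps`` bounds the stepping-out expansions per side.
    """

    n_samples: int = 1500
    n_burn: int = 500
    n_chains: int = 1
    seed: int = 0
    width: float = 1.0
    max_steps: int = 10
    interweave_every: int = 2

    def __post_init__(self) -> None:
        if self.n_burn >= self.n_samples:
            raise ValueError("n_burn must be smaller than n_samples")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")


class PosteriorStore:
    """Retained posterior draws indexed by (chain, iteration, parameter)."""

    def __init__(self, params: list[str], draws: np.ndarray, metadata: dict):
        assert draws.ndim == 3 and draws.shape[2] == len(params)
        self.params = list(params)
        self.draws = draws
        self.metadata = metadata
        self._index = {p: i for i, p in enumerate(self.params)}

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (chains, retained draws)."""
        return self.draws[:, :, self._index[name]]

    def pooled(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def mean(self, name: str) -> float:
        return float(self.pooled(name).mean())

    @staticmethod
    def combine(stores: list["PosteriorStore"]) -> "PosteriorStore":
        """Stack same-model single/multi-chain stores along the chain axis."""
        first = stores[0]
        for s in stores[1:]:
            if s.params != first.params:
                raise ValueError("stores come from different models")
            if s.n_draws != first.n_draws:
                raise ValueError("stores have different numbers of retained draws")
        draws = np.concatenate([s.draws for s in stores], axis=0)
        meta = dict(first.metadata)
        meta["combined_chains"] = int(draws.shape[0])
        return PosteriorStore(first.params, draws, meta)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: chain, draw, parameter, value."""
        c, d, p = self.draws.shape
        return pd.DataFrame({
            "chain": np.repeat(np.arange(c), d * p),
            "draw": np.tile(np.repeat(np.arange(d), p), c),
            "parameter": np.tile(self.params, c * d),
            "value": self.draws.reshape(-1),
        })

    def save(self, path) -> None:
        path = str(path)
        self.to_frame().to_csv(path, index=False)
        with open(path + ".meta.yaml", "w") as fh:
            yaml.safe_dump(self.metadata, fh)

    @classmethod
    def load(cls, path) -> "PosteriorStore":
        path = str(path)
        df = pd.read_csv(path)
        params = list(dict.fromkeys(df["parameter"]))
        chains = sorted(df["chain"].unique())
        n_draws = df["draw"].max() + 1
        draws = np.empty((len(chains), n_draws, len(params)))
        pivot = df.pivot_table(index=["chain", "draw"], columns="parameter",
                               values="value", sort=False)
        for ci, ch in enumerate(chains):
            draws[ci] = pivot.loc[ch][params].to_numpy()
        try:
            with open(path + ".meta.yaml") as fh:
                meta = yaml.safe_load(fh)
        except FileNotFoundError:
            meta = {}
        return cls(params, draws, meta)


def _slice_update(f, x0: float, f0: float, rng, width: float, max_steps: int):
    """One slice-sampling update; returns (x1, f1)."""
    logy = f0 + np.log(rng.random())
    u = rng.random()
    left = x0 - width * u
    right = left + width
    j = int(np.floor(max_steps * rng.random()))
    k = max_steps - 1 - j
    fl = f(left)
    while fl > logy and j > 0:
        left -= width
        fl = f(left)
        j -= 1
    fr = f(right)
    while fr > logy and k > 0:
        right += width
        fr = f(right)
        k -= 1
    for _ in range(200):
        x1 = left + rng.random() * (right - left)
        f1 = f(x1)
        if f1 > logy:
            return x1, f1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0, f0  # numerically degenerate slice; keep the current point


def initialize_state(model: RLDDMModel, seed_or_rng, max_retries: int = 50):
    """Draw a finite-density starting state from the prior structure.

    Group nodes come from their priors, subject nodes from their group
    distributions (non-decision times resampled until below the subject's
    minimum rt); the whole draw is retried until the joint log density is
    finite.
    """
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) \
        else np.random.default_rng(seed_or_rng)
    worst = None
    for _ in range(max_retries):
        state = model.draw_initial_state(rng)
        ok = True
        for i in range(model.n_nodes):
            if not np.isfinite(model.node_prior_logpdf(i, state[i], state)):
                worst, ok = model.node_names[i], False
                break
        if not ok:
            continue
        for j in range(model.n_subjects):
            if not np.isfinite(model.loglik_subject(j, state)):
                worst, ok = f"likelihood of subject {model.subjects[j]}", False
                break
        if ok:
            return state
    raise InitializationError(
        f"no finite starting state in {max_retries} tries "
        f"(last non-finite node: {worst})")


def _interweave_group_scales(model, state, subj_ll, rng, config) -> None:
    """Non-centered update of each normal family's group SD.

    Centered univariate updates mix slowly through the hierarchical funnel
    when a subject spread is weakly identified: small sigma pins the subject
    values near the mean, which in turn keeps sigma small.  Holding the
    standardized deviations u_j = (x_j - mu) / sigma fixed (their N(0, 1)
    density does not depend on sigma) and slice sampling sigma against
    prior x likelihood breaks that coupling; subject values are then mapped
    back as mu + sigma' u_j.
    """
    for (fam, cond), mu_i in getattr(model, "gmean_idx", {}).items():
        if model.priors.families[fam].subject != "normal":
            continue  # the rescaling is linear-Gaussian only
        sd_i = model.gsd_idx[(fam, cond)]
        kids = np.array(model._children[mu_i])
        mu = state[mu_i]
        sd = state[sd_i]
        if sd <= 0:
            continue
        u = (state[kids] - mu) / sd
        prior = model._dist[sd_i]
        old_vals = state[kids].copy()

        def f(s):
            if s <= 0:
                return -np.inf
            lp = float(prior.logpdf(s))
            if not np.isfinite(lp):
                return -np.inf
            state[kids] = mu + s * u
            ll = 0.0
            for j in range(model.n_subjects):
                ll += model.loglik_subject(j, state)
                if not np.isfinite(ll):
                    break
            state[kids] = old_vals
            return lp + ll

        f0 = float(prior.logpdf(sd)) + subj_ll.sum()
        s1, _ = _slice_update(f, sd, f0, rng, config.width, config.max_steps)
        if s1 != sd:
            state[sd_i] = s1
            state[kids] = mu + s1 * u
            for j in range(model.n_subjects):
                subj_ll[j] = model.loglik_subject(j, state)


def _model_hash(model: RLDDMModel) -> str:
    h = hashlib.sha256(",".join(model.node_names).encode())
    return h.hexdigest()[:12]


def sample_posterior(model: RLDDMModel, config: SamplerConfig | None = None,
                     verbose: bool = False) -> PosteriorStore:
    """Sample the posterior of all free nodes; deterministic given the seed.

    Chains are run sequentially with independent substreams of the
    configured seed; burn-in draws are discarded.
    """
    if config is None:
        config = SamplerConfig()
    kept = config.n_samples - config.n_burn
    draws = np.empty((config.n_chains, kept, model.n_nodes))

    for chain in range(config.n_chains):
        rng = np.random.default_rng([int(config.seed) % (2 ** 31), chain])
        state = initialize_state(model, rng)
        subj_ll = np.array([model.loglik_subject(j, state)
                            for j in range(model.n_subjects)])
        for it in range(config.n_samples):
            for i in range(model.n_nodes):
                x0 = state[i]
                kind = model._kind[i]
                if kind in (0, 1):  # group mean / group sd
                    def f(x, i=i):
                        lp = model.node_prior_logpdf(i, x, state)
                        if not np.isfinite(lp):
                            return -np.inf
                        return lp + model.children_logpdf(i, x, state)
                    f0 = model.node_prior_logpdf(i, x0, state) \
                        + model.children_logpdf(i, x0, state)
                    x1, _ = _slice_update(f, x0, f0, rng, config.width,
                                          config.max_steps)
                    state[i] = x1
                elif kind == 2:  # subject node
                    j = model._subj[i]

                    def f(x, i=i, j=j):
                        lp = model.node_prior_logpdf(i, x, state)
                        if not np.isfinite(lp):
                            return -np.inf
                        old = state[i]
                        state[i] = x
                        ll = model.loglik_subject(j, state)
                        state[i] = old
                        return lp + ll

                    f0 = model.node_prior_logpdf(i, x0, state) + subj_ll[j]
                    x1, _ = _slice_update(f, x0, f0, rng, config.width,
                                          config.max_steps)
                    if x1 != x0:
                        state[i] = x1
                        subj_ll[j] = model.loglik_subject(j, state)
                else:  # group-level likelihood node
                    def f(x, i=i):
                        lp = model.node_prior_logpdf(i, x, state)
                        if not np.isfinite(lp):
                            return -np.inf
                        old = state[i]
                        state[i] = x
                        ll = 0.0
                        for j in range(model.n_subjects):
                            ll += model.loglik_subject(j, state)
                            if not np.isfinite(ll):
                                break
                        state[i] = old
                        return lp + ll

                    f0 = model.node_prior_logpdf(i, x0, state) + subj_ll.sum()
                    x1, _ = _slice_update(f, x0, f0, rng, config.width,
                                          config.max_steps)
                    if x1 != x0:
                        state[i] = x1
                        subj_ll = np.array([model.loglik_subject(j, state)
                                            for j in range(model.n_subjects)])
            if it % config.interweave_every == config.interweave_every - 1:
                _interweave_group_scales(model, state, subj_ll, rng, config)
            if it >= config.n_burn:
                draws[chain, it - config.n_burn] = state
            if verbose and (it + 1) % 100 == 0:
                print(f"chain {chain}: {it + 1}/{config.n_samples} draws")

    meta = dict(asdict(config))
    meta["model_hash"] = _model_hash(model)
    meta["node_names"] = list(model.node_names)
    return PosteriorStore(list(model.node_names), draws, meta)
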