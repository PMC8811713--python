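import numpy as np
import pandas as pd
import pytest

from rlddm import TrialTable


def make_table(n_subjects=2, n_trials=8, conditions=("AB",), seed=0,
               rt=True, q_init=0.5, covariates=()):
    """Small deterministic trial table for unit tests (not a simulation)."""
    rng = np.random.default_rng(seed)
    frames = []
    for j in range(n_subjects):
        for cond in conditions:
            df = pd.DataFrame({
                "response": rng.integers(0, 2, n_trials),
                "split_by": cond,
                "subj_idx": j,
                "feedback": rng.integers(0, 2, n_trials).astype(float),
                "q_init": q_init,
            })
            if rt:
                df.insert(0, "rt", np.round(0.3 + rng.random(n_trials), 4))
            for c in covariates:
                df[c] = np.round(rng.normal(size=n_trials), 4)
            frames.append(df)
    return TrialTable(pd.concat(frames, ignore_index=True), has_rt=rt)


@pytest.fixture
def tiny_table():
    return make_table()


@pytest.fixture(scope="session")
def pst_dataset():
    """A small simulated PST dataset reused across sampler/diagnostic tests."""
    from rlddm import pst_schedule, simulate_rlddm_dataset
    return simulate_rlddm_dataset(
        {"a": 2.0, "v": 2.25, "t": 0.3, "alpha": 0.3},
        {"a": 0.1, "v": 0.25, "t": 0.02, "alpha": 0.1},
        pst_schedule(20), n_subjects=5, seed=7)


class GaussianShimModel:
    """Normal-likelihood, normal-prior toy model exposing the same node
    interface as the RLDDM graph; its posterior is available in closed
    form, making it an independent oracle for the sampler and for DIC."""

    def __init__(self, data, mu0=0.0, tau0=2.0, sigma=1.0, extra_covariate=None):
        self.data = np.asarray(data, dtype=float)
        self.mu0, self.tau0, self.sigma = mu0, tau0, sigma
        self.cov = None if extra_covariate is None \
            else np.asarray(extra_covariate, dtype=float)
        self.node_names = ["mu"] + ([] if self.cov is None else ["beta"])
        self.n_nodes = len(self.node_names)
        self._kind = [3] * self.n_nodes
        self._subj = [-1] * self.n_nodes
        self.n_subjects = 1
        self.subjects = [0]

    def node_prior_logpdf(self, i, x, state):
        return -0.5 * np.log(2 * np.pi) - np.log(self.tau0) \
            - 0.5 * ((x - self.mu0) / self.tau0) ** 2

    def children_logpdf(self, i, x, state):
        return 0.0

    def loglik_subject(self, j, state):
        pred = state[0]
        if self.cov is not None:
            pred = state[0] + state[1] * self.cov
        r = self.data - pred
        return float(-0.5 * len(self.data) * np.log(2 * np.pi * self.sigma ** 2)
                     - 0.5 * np.sum(r * r) / self.sigma ** 2)

    def total_loglik(self, state):
        return self.loglik_subject(0, state)

    def draw_initial_state(self, rng):
        return rng.normal(self.mu0, self.tau0, size=self.n_nodes)

    def conjugate_posterior(self):
        n = len(self.data)
        prec = 1 / self.tau0 ** 2 + n / self.sigma ** 2
        mean = (self.mu0 / self.tau0 ** 2
                + self.data.sum() / self.sigma ** 2) / prec
        return mean, np.sqrt(1 / prec)


class PriorShimModel:
    """A single free node with an arbitrary prior and flat likelihood."""

    def __init__(self, dist, init=None):
        self.dist = dist
        self.init = init
        self.node_names = ["theta"]
        self.n_nodes = 1
        self._kind = [3]
        self._subj = [-1]
        self.n_subjects = 1
        self.subjects = [0]

    def node_prior_logpdf(self, i, x, state):
        return float(self.dist.logpdf(x))

    def children_logpdf(self, i, x, state):
        return 0.0

    def loglik_subject(self, j, state):
        return 0.0

    def draw_initial_state(self, rng):
        return np.array([self.dist.rvs(rng) if self.init is None else self.init])


@pytest.fixture(scope="session")
def small_fit(pst_dataset):
    """A quick single-chain fit of the small PST dataset."""
    from rlddm import SamplerConfig, build_model, sample_posterior
    model = build_model(pst_dataset)
    store = sample_posterior(model, SamplerConfig(n_samples=300, n_burn=100,
                                                 seed=11))
    return model, store
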