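import numpy as np
import pandas as pd
import pytest

from rlddm import (PosteriorStore, autocorrelation, dic, gelman_rubin, hdi,
                   invlogit, summarize)
from conftest import GaussianShimModel


def _store(arrays: dict, n_chains=1):
    params = list(arrays)
    n = len(next(iter(arrays.values())))
    draws = np.stack([np.asarray(arrays[p], dtype=float)
                      for p in params], axis=-1)
    return PosteriorStore(params, draws.reshape(n_chains, n // n_chains,
                                                len(params)), {})


def test_summarize_constant_and_ordered_draws():
    store = _store({"a": np.full(50, 1.7), "v": np.arange(1, 101)[:50]})
    s = summarize(store)
    row = s.loc["a"]
    assert row["mean"] == 1.7 and row["std"] == 0.0
    assert all(row[q] == 1.7 for q in ("2.5q", "25q", "50q", "75q", "97.5q"))

    store = _store({"v": np.arange(1, 101, dtype=float)})
    row = summarize(store).loc["v"]
    assert row["mean"] == pytest.approx(50.5)
    assert row["50q"] == pytest.approx(50.5)
    # percentiles non-decreasing
    assert list(row[["2.5q", "25q", "50q", "75q", "97.5q"]]) == sorted(
        row[["2.5q", "25q", "50q", "75q", "97.5q"]])


def test_summarize_reports_transformed_learning_rate():
    draws = np.random.default_rng(0).normal(-2.32, 0.3, 400)
    s = summarize(_store({"alpha": draws, "alpha_std": np.abs(draws)}))
    assert "alpha_trans" in s.index
    assert s.loc["alpha_trans", "mean"] == pytest.approx(
        invlogit(draws).mean())
    # SD nodes are not probability-scale parameters
    assert "alpha_std_trans" not in s.index


def test_invlogit_values():
    assert invlogit(0.0) == 0.5
    assert round(float(invlogit(-2.32)), 2) == 0.09
    assert invlogit(800.0) == pytest.approx(1.0)
    assert invlogit(-800.0) == pytest.approx(0.0)


def test_gelman_rubin_identical_chains_exactly_one():
    x = np.random.default_rng(1).normal(size=200)
    store = PosteriorStore(["p"], np.tile(x, (3, 1))[:, :, None], {})
    assert gelman_rubin(store)["p"] == 1.0


def test_gelman_rubin_iid_chains_near_one():
    rng = np.random.default_rng(2)
    draws = rng.normal(size=(4, 10_000, 1))
    store = PosteriorStore(["p"], draws, {})
    r = gelman_rubin(store)["p"]
    assert 1.0 <= r <= 1.01


def test_gelman_rubin_flags_disagreeing_chains():
    rng = np.random.default_rng(3)
    draws = np.stack([rng.normal(0, 1, 1000), rng.normal(5, 1, 1000)])
    store = PosteriorStore(["p"], draws[:, :, None], {})
    assert gelman_rubin(store)["p"] > 1.5


def test_gelman_rubin_affine_invariant():
    rng = np.random.default_rng(4)
    draws = rng.normal(size=(3, 500, 1)) + np.array([0.0, 0.3, -0.2]).reshape(3, 1, 1)
    s1 = PosteriorStore(["p"], draws, {})
    s2 = PosteriorStore(["p"], 2.5 * draws - 7.0, {})
    assert gelman_rubin(s1)["p"] == pytest.approx(gelman_rubin(s2)["p"])


def test_gelman_rubin_list_of_single_chain_stores():
    rng = np.random.default_rng(5)
    stores = [PosteriorStore(["p"], rng.normal(size=(1, 400, 1)), {})
              for _ in range(3)]
    r = gelman_rubin(stores)["p"]
    assert 1.0 <= r < 1.1
    with pytest.raises(ValueError, match="two chains"):
        gelman_rubin(stores[:1])


def test_gelman_rubin_cross_checked_against_arviz():
    """Independent cross-check: the classic statistic agrees with arviz's
    non-rank-normalized (identity) R-hat on the same chains."""
    arviz = pytest.importorskip("arviz")
    rng = np.random.default_rng(6)
    m, n = 4, 2000
    chains = np.empty((m, n))
    for c in range(m):
        x = 0.0
        for i in range(n):
            x = 0.6 * x + rng.normal()
            chains[c, i] = x
    ours = gelman_rubin(PosteriorStore(["p"], chains[:, :, None], {}))["p"]
    theirs = float(arviz.rhat(arviz.convert_to_dataset(chains),
                              method="identity")["x"])
    assert ours == pytest.approx(theirs, abs=1e-9)


def test_autocorrelation_properties():
    rng = np.random.default_rng(7)
    x = rng.normal(size=10_000)
    acf = autocorrelation(x, 5)
    assert acf[0] == 1.0
    assert abs(acf[1]) < 0.05  # iid bound ~ 2/sqrt(n)

    ar = np.empty(20_000)
    ar[0] = 0.0
    eps = rng.normal(size=20_000)
    for i in range(1, len(ar)):
        ar[i] = 0.9 * ar[i - 1] + eps[i]
    acf = autocorrelation(ar, 3)
    assert acf[1] == pytest.approx(0.9, abs=0.03)
    with pytest.raises(ValueError):
        autocorrelation([1.0, 2.0], 5)


def test_dic_degenerate_posterior():
    rng = np.random.default_rng(8)
    model = GaussianShimModel(rng.normal(size=20))
    store = _store({"mu": np.full(100, 0.7)})
    out = dic(store, model)
    assert out["p_d"] == pytest.approx(0.0, abs=1e-10)
    assert out["dic"] == pytest.approx(-2 * model.total_loglik(np.array([0.7])))


def test_dic_conjugate_closed_form():
    """For the normal-mean model, p_D = n * posterior variance / sigma^2 and
    the mean deviance follows from the posterior moments."""
    rng = np.random.default_rng(9)
    data = rng.normal(1.0, 1.0, 30)
    model = GaussianShimModel(data)
    mean, sd = model.conjugate_posterior()
    draws = rng.normal(mean, sd, 4000)  # exact posterior samples
    store = _store({"mu": draws})
    out = dic(store, model)
    n = len(data)
    p_d_expected = n * sd ** 2
    assert out["p_d"] == pytest.approx(p_d_expected, rel=0.15)
    d_at_mean = -2 * model.total_loglik(np.array([draws.mean()]))
    assert out["dic"] == pytest.approx(d_at_mean + 2 * p_d_expected, rel=0.01)


def test_dic_counts_an_inert_extra_parameter():
    """A slope on a pure-noise covariate adds ~1 effective parameter."""
    from rlddm import SamplerConfig, sample_posterior
    rng = np.random.default_rng(10)
    data = rng.normal(0.5, 1.0, 60)
    cov = rng.normal(size=60)
    base = GaussianShimModel(data)
    ext = GaussianShimModel(data, extra_covariate=cov)
    cfg = SamplerConfig(n_samples=4000, n_burn=500, seed=3)
    p_base = dic(sample_posterior(base, cfg), base)["p_d"]
    p_ext = dic(sample_posterior(ext, cfg), ext)["p_d"]
    assert p_ext - p_base == pytest.approx(1.0, abs=0.4)


def test_hdi_narrowest_interval():
    x = np.concatenate([np.zeros(90), np.full(10, 5.0)])
    lo, hi = hdi(x, 0.9)
    assert (lo, hi) == (0.0, 0.0)
    rng = np.random.default_rng(11)
    x = rng.normal(size=5000)
    lo, hi = hdi(x, 0.9)
    frac = np.mean((x >= lo) & (x <= hi))
    assert frac == pytest.approx(0.9, abs=0.01)
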