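import numpy as np
import pytest

from rlddm import (ConfigurationError, FormulaError, LearningParams, ModelSpec,
                   RegressionSpec, build_model, compute_q_trajectory,
                   conflict_series, default_priors, evaluate_trial_parameter,
                   parse_formula)
from conftest import make_table


def test_default_model_node_set_two_subjects():
    table = make_table(n_subjects=2)
    model = build_model(table)
    expected = set()
    for fam in ("a", "v", "t", "alpha"):
        expected |= {fam, f"{fam}_std", f"{fam}_subj.0", f"{fam}_subj.1"}
    assert set(model.node_names) == expected
    assert model.n_nodes == 16


def test_depends_on_creates_one_family_per_condition():
    table = make_table(n_subjects=2, conditions=("AB", "CD", "EF"))
    model = build_model(table, ModelSpec(depends_on={"v": "split_by"}))
    v_nodes = [n for n in model.node_names if n.startswith("v")]
    # 3 conditions x (mean + sd + 2 subjects)
    assert len(v_nodes) == 12
    assert "v(AB)" in model.node_names and "v_subj(EF).1" in model.node_names


def test_regression_model_nodes():
    table = make_table(covariates=("neural",))
    spec = ModelSpec(regressions=["a ~ neural"],
                     include=("a", "v", "t", "alpha"))
    model = build_model(table, spec)
    assert "a_Intercept" in model.node_names
    assert "a_neural" in model.node_names
    assert not any(n.startswith("a_subj") for n in model.node_names)
    # learning rate stays hierarchical
    assert "alpha_subj.0" in model.node_names


def test_regression_learning_rate_must_be_explicit():
    """Without an explicit include, regression models fix the learning rate
    (it has to be enabled explicitly), so no alpha nodes appear."""
    table = make_table(covariates=("neural",))
    model = build_model(table, ModelSpec(regressions=["a ~ neural"]))
    assert not any(n.startswith("alpha") for n in model.node_names)


def test_inconsistent_spec_rejected():
    table = make_table(covariates=("neural",))
    with pytest.raises(ConfigurationError, match="split by condition"):
        build_model(table, ModelSpec(regressions=["a ~ neural"],
                                     depends_on={"a": "split_by"},
                                     include=("a", "v", "t", "alpha")))
    with pytest.raises(ConfigurationError, match="dual"):
        build_model(table, ModelSpec(dual=True, include=("a", "v", "t")))
    rt_free = make_table(rt=False)
    with pytest.raises(ConfigurationError, match="rt"):
        build_model(rt_free)
    # while the softmax model accepts RT-free data
    model = build_model(rt_free, ModelSpec(likelihood="softmax"))
    assert {"v", "alpha"} <= {n.split("_")[0] for n in model.node_names}


def test_parse_formula_simple():
    spec = parse_formula("a ~ neural", ["neural"])
    assert spec.target == "a" and spec.terms == [("neural",)]
    assert spec.intercept


def test_parse_formula_three_way_expansion():
    cols = ["stn", "theta", "presma"]
    spec = parse_formula("a ~ stn*theta*conflict + presma*conflict", cols)
    assert ("stn",) in spec.terms
    assert ("stn", "theta") in spec.terms
    assert ("stn", "theta", "conflict") in spec.terms
    assert ("presma", "conflict") in spec.terms
    assert ("conflict",) in spec.terms
    # full expansion: 7 subsets of the first product + presma + presma:conflict
    assert len(spec.terms) == 9


def test_parse_formula_intercept_and_interaction_rules():
    assert not parse_formula("a ~ 0 + neural", ["neural"]).intercept
    only = parse_formula("a ~ x:y", ["x", "y"])
    assert only.terms == [("x", "y")]


def test_parse_formula_errors():
    with pytest.raises(FormulaError, match="target"):
        parse_formula("q ~ neural", ["neural"])
    with pytest.raises(FormulaError, match="nope"):
        parse_formula("a ~ nope", ["neural"])


def test_conflict_series_forms():
    traj = compute_q_trajectory([1, 1], [1.0, 1.0], 0.5, LearningParams(0.0))
    # equal values throughout: standardizes to all zeros
    np.testing.assert_array_equal(conflict_series(traj), [0.0, 0.0])

    class T:
        q_upper = np.array([0.55, 0.7])
        q_lower = np.array([0.45, 0.3])

    raw = conflict_series(T(), epsilon=0.01, standardize=False)
    np.testing.assert_allclose(raw, [1 / 0.11, 1 / 0.41])
    # monotone decreasing in |q_delta|
    assert raw[0] > raw[1]
    neg = conflict_series(T(), mode="negation", standardize=False)
    np.testing.assert_allclose(neg, [-0.1, -0.4])


def test_evaluate_trial_parameter_links():
    reg = RegressionSpec(target="a", terms=[("x",)], intercept=True)
    cov = {"x": np.array([0.0, 1.0, -10.0]), "__coef__x": 0.0}
    np.testing.assert_allclose(
        evaluate_trial_parameter(1.3, reg, cov), [1.3, 1.3, 1.3])
    cov["__coef__x"] = 0.5
    out = evaluate_trial_parameter(1.3, reg, cov)
    np.testing.assert_allclose(out[:2], [1.3, 1.8])
    assert out[2] == pytest.approx(1e-3)  # floored, not negative

    # v target: zero slope reduces exactly to the scaled drift rule
    regv = RegressionSpec(target="v", terms=[("x",)], intercept=True)
    qd = np.array([0.2, -0.4, 0.0])
    cov = {"x": np.zeros(3), "__coef__x": 0.0}
    np.testing.assert_allclose(
        evaluate_trial_parameter(2.0, regv, cov, q_delta=qd), qd * 2.0)


def test_evaluate_trial_parameter_moments():
    """Intercept 1, slope 0.2 on a standard-normal covariate: trial
    thresholds have mean 1 and SD 0.2 (linearity of expectation)."""
    rng = np.random.default_rng(8)
    x = rng.normal(size=20000)
    reg = RegressionSpec(target="a", terms=[("x",)], intercept=True)
    out = evaluate_trial_parameter(1.0, reg, {"x": x, "__coef__x": 0.2})
    assert out.mean() == pytest.approx(1.0, abs=3 * 0.2 / np.sqrt(x.size))
    assert out.std() == pytest.approx(0.2, abs=0.01)


def test_prior_monte_carlo_means():
    """Each default prior's sample mean matches its analytic mean."""
    rng = np.random.default_rng(123)
    priors = default_priors()
    dists = {f"mu_{k}": fp.mean_dist for k, fp in priors.families.items()}
    dists.update({f"sd_{k}": fp.sd_dist for k, fp in priors.families.items()})
    dists.update(priors.variability)
    n = 100_000
    for name, dist in dists.items():
        x = dist.rvs(rng, size=n)
        se = x.std(ddof=1) / np.sqrt(n)
        assert abs(x.mean() - dist.mean) < 3 * se, name


def test_regression_nesting_identity(tiny_table=None):
    """A regression with all slopes at zero gives the same log-likelihood
    as the plain model at matching base parameters."""
    table = make_table(n_subjects=3, n_trials=12, covariates=("neural",))
    base = build_model(table)
    reg = build_model(table, ModelSpec(regressions=["a ~ neural"],
                                       include=("a", "v", "t", "alpha")))
    rng = np.random.default_rng(0)
    sb = base.draw_initial_state(rng)
    sr = np.empty(reg.n_nodes)
    a_common = 1.8
    for i, name in enumerate(base.node_names):
        if name.startswith("a_subj"):
            sb[i] = a_common
    for i, name in enumerate(reg.node_names):
        if name == "a_Intercept":
            sr[i] = a_common
        elif name == "a_neural":
            sr[i] = 0.0
        else:
            sr[i] = sb[base.node_names.index(name)]
    ll_b = sum(base.loglik_subject(j, sb) for j in range(base.n_subjects))
    ll_r = sum(reg.loglik_subject(j, sr) for j in range(reg.n_subjects))
    assert ll_b == pytest.approx(ll_r, rel=1e-12)


def test_model_spec_from_dict_rejects_unknown_fields():
    with pytest.raises(ConfigurationError, match="unknown"):
        ModelSpec.from_dict({"includes": ["a"]})
    spec = ModelSpec.from_dict({"include": ["a", "v", "t", "alpha"],
                                "dual": True})
    assert "alpha_neg" in spec.resolved_include()


def test_v_regression_nesting_identity():
    """'v ~ neural' with a zero slope reduces to the plain scaled drift."""
    table = make_table(n_subjects=2, n_trials=10, covariates=("neural",))
    base = build_model(table)
    reg = build_model(table, ModelSpec(regressions=["v ~ neural"],
                                       include=("a", "v", "t", "alpha")))
    assert "v_Intercept" in reg.node_names and "v_neural" in reg.node_names
    rng = np.random.default_rng(1)
    sb = base.draw_initial_state(rng)
    v_common = 2.1
    for i, name in enumerate(base.node_names):
        if name.startswith("v_subj"):
            sb[i] = v_common
    sr = np.empty(reg.n_nodes)
    for i, name in enumerate(reg.node_names):
        if name == "v_Intercept":
            sr[i] = v_common
        elif name == "v_neural":
            sr[i] = 0.0
        else:
            sr[i] = sb[base.node_names.index(name)]
    ll_b = sum(base.loglik_subject(j, sb) for j in range(base.n_subjects))
    ll_r = sum(reg.loglik_subject(j, sr) for j in range(reg.n_subjects))
    assert ll_b == pytest.approx(ll_r, rel=1e-12)


def test_conflict_regression_likelihood_path():
    """The latent conflict term enters a threshold regression and responds
    to its coefficient (finite likelihood, coefficient-dependent)."""
    table = make_table(n_subjects=2, n_trials=15)
    model = build_model(table, ModelSpec(regressions=["a ~ conflict"],
                                         include=("a", "v", "t", "alpha")))
    assert "a_conflict" in model.node_names
    rng = np.random.default_rng(2)
    state = model.draw_initial_state(rng)
    i_int = model.node_names.index("a_Intercept")
    i_c = model.node_names.index("a_conflict")
    state[i_int] = 1.5
    state[i_c] = 0.0
    ll0 = sum(model.loglik_subject(j, state) for j in range(2))
    state[i_c] = 0.3
    ll1 = sum(model.loglik_subject(j, state) for j in range(2))
    assert np.isfinite(ll0) and np.isfinite(ll1)
    assert ll0 != ll1
    # negation form is a configuration switch
    m2 = build_model(table, ModelSpec(regressions=["a ~ conflict"],
                                      include=("a", "v", "t", "alpha"),
                                      conflict_mode="negation"))
    ll2 = sum(m2.loglik_subject(j, state) for j in range(2))
    assert np.isfinite(ll2) and ll2 != ll1
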