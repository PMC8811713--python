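import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from rlddm import (DDMParams, LearningParams, TrialTable, choice_prob_upper,
                   rl_softmax_loglik, rlddm_loglik, softmax_prob, wfpt_pdf)


def total_mass(params, tol=1e-4, upper_limit=60.0):
    lo = max(params.t - params.s_t / 2, 0.0)  # support starts at t - s_t/2
    out = 0.0
    for b in ("upper", "lower"):
        out += quad(lambda x: wfpt_pdf(x, b, params, tol=tol),
                    lo, upper_limit, limit=300)[0]
    return out


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        DDMParams(a=-1.0)
    with pytest.raises(ValueError):
        DDMParams(a=1.0, z=1.2)
    with pytest.raises(ValueError):
        DDMParams(a=1.0, z=0.5, s_z=1.2)  # z +/- s_z/2 leaves (0,1)
    with pytest.raises(ValueError):
        DDMParams(a=1.0, t=0.1, s_t=0.4)  # t - s_t/2 < 0


def test_density_zero_before_nondecision_time():
    p = DDMParams(a=1.5, v=1.0, t=0.4, z=0.5)
    assert wfpt_pdf(0.39, "upper", p) == 0.0
    assert wfpt_pdf(0.4, "upper", p) == 0.0  # rt == t is outside the support


def test_driftless_symmetric_mass_is_half():
    p = DDMParams(a=2.0, v=0.0, t=0.3, z=0.5)
    mass = quad(lambda x: wfpt_pdf(x, "upper", p), p.t, 80, limit=400)[0]
    assert mass == pytest.approx(0.5, abs=1e-3)


@pytest.mark.parametrize("a", [0.5, 1.5, 3.0])
@pytest.mark.parametrize("v", [-2.0, 0.0, 1.0, 4.0])
@pytest.mark.parametrize("z", [0.2, 0.5, 0.8])
def test_normalization_over_parameter_grid(a, v, z):
    """Absorption is certain: upper + lower mass integrate to 1."""
    p = DDMParams(a=a, v=v, t=0.2, z=z)
    assert total_mass(p) == pytest.approx(1.0, abs=1e-3)


@pytest.mark.parametrize("extra", [
    {"s_v": 1.5}, {"s_t": 0.2}, {"s_z": 0.3}, {"s_v": 1.0, "s_t": 0.2, "s_z": 0.2},
])
def test_normalization_with_between_trial_variability(extra):
    p = DDMParams(a=1.5, v=1.0, t=0.3, z=0.5, **extra)
    assert total_mass(p) == pytest.approx(1.0, abs=2e-3)


def test_series_accuracy_against_tight_tolerance():
    """The adaptive small-/large-time branch switch stays within tol."""
    p = DDMParams(a=2.0, v=1.0, t=0.0, z=0.5)
    for rt in np.linspace(0.01, 6.0, 300):
        coarse = wfpt_pdf(rt, "upper", p, tol=1e-4)
        fine = wfpt_pdf(rt, "upper", p, tol=1e-10)
        assert abs(coarse - fine) < 1e-4


def test_choice_prob_limits():
    assert choice_prob_upper(DDMParams(a=2.0, v=0.0, z=0.3)) == pytest.approx(0.3)
    # z = 0.5 reduces to a softmax with inverse temperature a*v
    for a in (0.5, 1.0, 2.5):
        for v in (-3.0, -0.5, 0.0, 1.0, 4.0):
            p = choice_prob_upper(DDMParams(a=a, v=v, z=0.5))
            assert p == pytest.approx(1.0 / (1.0 + np.exp(-a * v)), abs=1e-12)


def test_choice_prob_equals_upper_mass():
    p = DDMParams(a=1.7, v=0.8, t=0.0, z=0.35)
    mass = quad(lambda x: wfpt_pdf(x, "upper", p), 0, 80, limit=400)[0]
    assert mass == pytest.approx(choice_prob_upper(p), abs=1e-3)


def _one_block_table(resp, fb, rt, q_init=0.5):
    return TrialTable(pd.DataFrame({
        "rt": rt, "response": resp, "split_by": "AB", "subj_idx": 0,
        "feedback": fb, "q_init": q_init}))


def test_rlddm_loglik_reduces_to_static_ddm_when_alpha_zero():
    rng = np.random.default_rng(5)
    n = 20
    table = _one_block_table(rng.integers(0, 2, n), rng.integers(0, 2, n),
                             0.4 + rng.random(n))
    ddm = DDMParams(a=2.0, t=0.3, z=0.5)
    ll = rlddm_loglik(table, ddm, LearningParams(alpha=0.0), v_scale=3.0)
    # alpha=0 and equal q_init: drift stays 0 on every trial
    expected = sum(
        np.log(wfpt_pdf(rt, "upper" if r == 1 else "lower",
                        DDMParams(a=2.0, v=0.0, t=0.3, z=0.5)))
        for rt, r in zip(table.df["rt"], table.df["response"]))
    assert ll == pytest.approx(expected)


def test_rlddm_loglik_single_trial_equals_wfpt():
    table = _one_block_table([1], [1.0], [0.8])
    ddm = DDMParams(a=1.5, t=0.2, z=0.5)
    ll = rlddm_loglik(table, ddm, LearningParams(alpha=0.3), v_scale=2.0)
    assert ll == pytest.approx(np.log(wfpt_pdf(0.8, "upper", ddm)))


def test_rlddm_loglik_flags_rt_below_t():
    table = _one_block_table([1], [1.0], [0.2])
    ddm = DDMParams(a=1.5, t=0.5, z=0.5)
    ll = rlddm_loglik(table, ddm, LearningParams(alpha=0.3), v_scale=2.0)
    assert ll == -np.inf


def test_softmax_loglik_beta_zero():
    rng = np.random.default_rng(2)
    n = 17
    table = _one_block_table(rng.integers(0, 2, n), rng.integers(0, 2, n),
                             0.4 + rng.random(n))
    ll = rl_softmax_loglik(table, LearningParams(alpha=0.4), beta=0.0)
    assert ll == pytest.approx(n * np.log(0.5))


def test_marginal_choice_equivalence_with_softmax():
    """Integrating the wfpt over RT at z=0.5 gives softmax choice
    probabilities with inverse temperature a * v_scale, trial by trial."""
    from rlddm import compute_q_trajectory
    rng = np.random.default_rng(11)
    n = 12
    resp = rng.integers(0, 2, n)
    fb = rng.integers(0, 2, n).astype(float)
    table = _one_block_table(resp, fb, 0.4 + rng.random(n))
    a, v_scale, alpha = 1.6, 2.0, 0.35
    traj = compute_q_trajectory(resp, fb, 0.5, LearningParams(alpha))
    marginal = 0.0
    for i in range(n):
        p = DDMParams(a=a, v=traj.q_delta[i] * v_scale, t=0.0, z=0.5)
        mass = quad(lambda x: wfpt_pdf(x, "upper" if resp[i] else "lower", p),
                    0, 60, limit=300)[0]
        marginal += np.log(mass)
    soft = rl_softmax_loglik(table, LearningParams(alpha), beta=a * v_scale)
    assert marginal == pytest.approx(soft, abs=2e-3)


def test_likelihood_concentrates_at_true_parameters():
    """Simulated data are more likely under the generating parameters than
    under a joint +/-50% perturbation, in (nearly) every replicate."""
    from rlddm import TaskSchedule, simulate_rlddm_dataset
    truth = {"a": 2.0, "v": 2.25, "t": 0.3, "alpha": 0.3}
    schedule = TaskSchedule([("AB", 0.8, 0.2, 200)])
    wins_up = wins_dn = 0
    n_rep = 8
    for rep in range(n_rep):
        table = simulate_rlddm_dataset(truth, {}, schedule, 1, seed=100 + rep)

        def ll(f):
            return rlddm_loglik(
                table, DDMParams(a=truth["a"] * f, t=truth["t"] * f, z=0.5),
                LearningParams(min(truth["alpha"] * f, 1.0)),
                v_scale=truth["v"] * f)

        base = ll(1.0)
        wins_up += base > ll(1.5)
        wins_dn += base > ll(0.5)
    assert wins_up >= n_rep - 1
    assert wins_dn >= n_rep - 1
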