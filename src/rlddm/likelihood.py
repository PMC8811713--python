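"""Wiener first-passage-time density and composed RLDDM log-likelihoods.

The joint choice/RT likelihood of the drift diffusion model is the first
passage density of a unit-variance Wiener process with drift ``v`` between
absorbing boundaries 0 and ``a``, started at ``z * a``, shifted by the
non-decision time ``t``.  The "full" DDM additionally mixes over
between-trial variability in drift (``s_v``, normal), non-decision time
(``s_t``, uniform) and starting point (``s_z``, uniform).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _wfpt
from ._wfpt import _GL_W, _GL_X, DEFAULT_ERR
from .rl import LearningParams


@dataclass
class DDMParams:
    """Single-trial parameters of the (full) drift diffusion model."""

    a: float
    v: float = 0.0
    t: float = 0.0
    z: float = 0.5
    s_v: float = 0.0
    s_t: float = 0.0
    s_z: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"boundary separation a must be positive, got {self.a}")
        if not 0 < self.z < 1:
            raise ValueError(f"starting point z must be in (0, 1), got {self.z}")
        if self.t < 0:
            raise ValueError(f"non-decision time t must be >= 0, got {self.t}")
        if min(self.s_v, self.s_t, self.s_z) < 0:
            raise ValueError("variability parameters must be >= 0")
        if self.z - self.s_z / 2 <= 0 or self.z + self.s_z / 2 >= 1:
            raise ValueError("z +/- s_z/2 must stay inside (0, 1)")
        if self.t - self.s_t / 2 < 0:
            raise ValueError("t - s_t/2 must be >= 0")


def wfpt_pdf(rt: float, boundary: str, params: DDMParams,
             tol: float = DEFAULT_ERR) -> float:
    """First-passage density at time ``rt`` for the named boundary.

    Parameters
    ----------
    boundary
        "upper" or "lower".
    tol
        Absolute error bound of the series truncation.

    Returns 0 for ``rt <= t`` (outside the support).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    resp = 1 if boundary == "upper" else 0
    p = _wfpt.pdf_trial(float(rt), resp, params.a, params.v, params.t, params.z,
                        params.s_v, params.s_t, params.s_z, tol, _GL_X, _GL_W)
    if p < 0.0:
        raise ValueError("invalid DDM parameters")
    return p


def choice_prob_upper(params: DDMParams) -> float:
    """Probability that the process is absorbed at the upper boundary.

    Closed form (1 - exp(-2 a v z)) / (1 - exp(-2 a v)); for v -> 0 the
    limit is z.  With z = 0.5 this is the logistic 1 / (1 + exp(-a v)),
    i.e. a softmax with inverse temperature a * v -- the sense in which a
    DDM that ignores RT reduces to the softmax choice rule.
    """
    if params.s_v or params.s_t or params.s_z:
        raise ValueError("closed-form choice probability requires "
                         "s_v = s_t = s_z = 0")
    a, v, z = params.a, params.v, params.z
    x = a * v
    if abs(x) < 1e-9:
        return z
    # stable evaluation of expm1 ratio
    return np.expm1(-2.0 * x * z) / np.expm1(-2.0 * x)


def _block_arrays(block):
    rt = np.ascontiguousarray(block["rt"].to_numpy(), dtype=np.float64)
    resp = np.ascontiguousarray(block["response"].to_numpy(), dtype=np.int64)
    fb = np.ascontiguousarray(block["feedback"].to_numpy(), dtype=np.float64)
    q0 = float(block["q_init"].iloc[0])
    return rt, resp, fb, q0


def rlddm_loglik(table, ddm: DDMParams, learning: LearningParams,
                 v_scale: float, dual: bool = False,
                 tol: float = DEFAULT_ERR) -> float:
    """Joint RLDDM log-likelihood of a trial table at fixed parameters.

    For each subject x condition block the delta rule produces trial-wise
    expected values, the drift is (Q_upper - Q_lower) * v_scale, and the
    observed (response, rt) pair is scored by the wfpt density.  A
    non-finite result (e.g. any rt <= t) is returned as -inf.
    """
    a_neg = learning.alpha_neg if (dual and learning.alpha_neg is not None) \
        else learning.alpha
    total = 0.0
    for _subj, _cond, block in table.iter_blocks():
        rt, resp, fb, q0 = _block_arrays(block)
        n = np.array([0, len(rt)], dtype=np.int64)
        one = np.ones(1)
        ll = _wfpt.subject_loglik_basic(
            rt, resp, fb, n, np.array([q0]),
            one * ddm.a, one * v_scale, one * ddm.t, one * ddm.z,
            one * learning.alpha, one * a_neg,
            ddm.s_v, ddm.s_t, ddm.s_z, tol, _GL_X, _GL_W)
        total += ll
        if not np.isfinite(total):
            return -np.inf
    return total


def rl_softmax_loglik(table, learning: LearningParams, beta: float,
                      dual: bool = False) -> float:
    """Softmax-RL log-likelihood (choices only; the table may lack rt)."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    a_neg = learning.alpha_neg if (dual and learning.alpha_neg is not None) \
        else learning.alpha
    total = 0.0
    for _subj, _cond, block in table.iter_blocks():
        resp = np.ascontiguousarray(block["response"].to_numpy(), dtype=np.int64)
        fb = np.ascontiguousarray(block["feedback"].to_numpy(), dtype=np.float64)
        q0 = float(block["q_init"].iloc[0])
        n = np.array([0, len(resp)], dtype=np.int64)
        one = np.ones(1)
        total += _wfpt.softmax_loglik_kernel(
            resp, fb, n, np.array([q0]), one * beta,
            one * learning.alpha, one * a_neg)
    return total
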