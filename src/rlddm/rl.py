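"""Delta-rule value learning, softmax choice, and drift-rate construction.

These are the deterministic building blocks of the RLDDM: expected values
evolve by the delta rule Q <- Q + alpha * (reward - Q), choice without RTs
is softmax in the value difference, and the trial-wise drift rate is the
value difference scaled by a free parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._wfpt import q_trajectory_kernel


@dataclass
class LearningParams:
    """Learning rates on the probability scale.

    ``alpha`` applies to positive reward prediction errors (and to all of
    them in single-learning-rate models); ``alpha_neg``, when given, applies
    to negative prediction errors.  Raw (unconstrained) parameters map to
    (0, 1) through the inverse logit; use :func:`rlddm.diagnostics.invlogit`.
    """

    alpha: float
    alpha_neg: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.alpha_neg is not None and not 0.0 <= self.alpha_neg <= 1.0:
            raise ValueError(f"alpha_neg must be in [0, 1], got {self.alpha_neg}")


@dataclass
class QTrajectory:
    """Per-trial expected values of both options within one block.

    ``q_upper[i]`` / ``q_lower[i]`` are the values *before* the choice on
    trial i; ``rpe[i]`` is the prediction error of the chosen option on
    trial i.  Only the chosen option's value changes between trials.
    """

    q_upper: np.ndarray
    q_lower: np.ndarray
    rpe: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.q_upper)

    @property
    def q_delta(self) -> np.ndarray:
        """Value difference Q_upper - Q_lower per trial."""
        return self.q_upper - self.q_lower


def update_q(q: float, reward: float, alpha: float) -> float:
    """One delta-rule update: ``q + alpha * (reward - q)``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return q + alpha * (reward - q)


def compute_q_trajectory(response, feedback, q_init: float,
                         params: LearningParams, dual: bool = False) -> QTrajectory:
    """Run the delta rule over one ordered subject x condition block.

    Parameters
    ----------
    response, feedback
        Equal-length sequences; response codes 1 for the upper-boundary
        option, 0 for the lower.
    q_init
        Initial expected value of both options.
    dual
        Use ``params.alpha_neg`` for negative prediction errors (zero
        prediction errors take the positive branch).
    """
    resp = np.ascontiguousarray(response, dtype=np.int64)
    fb = np.ascontiguousarray(feedback, dtype=np.float64)
    if resp.shape != fb.shape:
        raise ValueError("response and feedback must have equal length")
    if resp.size == 0:
        raise ValueError("block must contain at least one trial")
    a_neg = params.alpha_neg if (dual and params.alpha_neg is not None) else params.alpha
    qu, ql, rpe = q_trajectory_kernel(resp, fb, float(q_init), params.alpha, a_neg)
    return QTrajectory(q_upper=qu, q_lower=ql, rpe=rpe)


def softmax_prob(q_values, beta: float) -> float:
    """Probability of choosing the upper option under softmax.

    Overflow-safe: computed as a logistic in beta * (q_upper - q_lower).
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    q_upper, q_lower = q_values
    d = beta * (q_upper - q_lower)
    if d >= 0:
        return 1.0 / (1.0 + np.exp(-d))
    e = np.exp(d)
    return e / (1.0 + e)


def drift_rate(q_values, v_scale: float) -> float:
    """Trial drift rate: value difference times the scaling parameter."""
    q_upper, q_lower = q_values
    return (q_upper - q_lower) * v_scale
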