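"""Effort-discounted reward rate and its analytic gradient.

The objective scores a (drift rate, threshold) configuration by the
expected net payoff per second, discounted by the effort cost of
maintaining the drift rate:

    RR(v, a) = [R*(1 - ER) - P*ER] / (DT + NDT) - E * cost(v)

where ER and DT are the closed-form DDM error rate and decision time,
R is the subjective reward per correct response and P the subjective
penalty per error (both in effort-cost units once E is normalised to 1).
The default cost is quadratic in drift rate; linear and exponential
alternatives, and no cost at all, are available for comparison.  The
threshold carries no effort cost by default (its cost is implicit in the
speed-accuracy tradeoff), but a hook exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ddm import DDMParams, _er_dt_arrays, _er_dt_derivs

__all__ = [
    "IncentiveWeights",
    "CostSpec",
    "NonDifferentiableError",
    "reward_rate",
    "reward_rate_gradient",
    "cost_value",
    "cost_derivative",
]

COST_FORMS = ("quadratic", "linear", "exponential", "none")


class NonDifferentiableError(ValueError):
    """Gradient requested at a kink of the cost function."""


@dataclass(frozen=True)
class IncentiveWeights:
    """Subjective reward (R, per correct) and penalty (P, per error).

    Both are expressed in effort-cost units: the cost weight E is
    conventionally normalised to 1, so only the ratios R/E and P/E matter
    for the optimal policy.
    """

    R: float
    P: float

    def __post_init__(self):
        if not (self.R > 0):
            raise ValueError(f"reward weight R must be > 0, got {self.R}")
        if self.P < 0:
            raise ValueError(f"penalty weight P must be >= 0, got {self.P}")


@dataclass(frozen=True)
class CostSpec:
    """Effort-cost term applied to the drift rate.

    form : 'quadratic' (default, E*v^2), 'linear' (E*|v|),
           'exponential' (E*(exp(v)-1); zero at v=0), or 'none'.
    weight : cost weight E >= 0 (default 1, the conventional normalisation).
    threshold_weight : optional cost weight on the threshold, quadratic in
           ``a``; defaults to 0 (no threshold cost).
    """

    form: str = "quadratic"
    weight: float = 1.0
    threshold_weight: float = 0.0

    def __post_init__(self):
        if self.form not in COST_FORMS:
            raise ValueError(f"unknown cost form {self.form!r}; expected one of {COST_FORMS}")
        if self.weight < 0:
            raise ValueError(f"cost weight E must be >= 0, got {self.weight}")
        if self.threshold_weight < 0:
            raise ValueError("threshold cost weight must be >= 0")


def cost_value(cost: CostSpec, v, a=0.0):
    """Effort-cost term at drift rate ``v`` (vectorised)."""
    v = np.asarray(v, dtype=float)
    E = cost.weight
    if cost.form == "quadratic":
        c = E * v * v
    elif cost.form == "linear":
        c = E * np.abs(v)
    elif cost.form == "exponential":
        c = E * (np.exp(v) - 1.0)
    else:
        c = np.zeros_like(v)
    return c + cost.threshold_weight * np.square(a)


def cost_derivative(cost: CostSpec, v):
    """d(cost)/dv; raises at the linear form's v=0 kink."""
    E = cost.weight
    if cost.form == "quadratic":
        return 2.0 * E * v
    if cost.form == "linear":
        if v == 0.0:
            raise NonDifferentiableError("linear cost is non-differentiable at v=0")
        return E * math.copysign(1.0, v)
    if cost.form == "exponential":
        return E * math.exp(v)
    return 0.0


def reward_rate(p: DDMParams, w: IncentiveWeights, cost: CostSpec = CostSpec()) -> float:
    """Effort-discounted reward rate (reward units per second).

    ``[R*(1-ER) - P*ER] / (DT + NDT)`` minus the effort-cost term.  With
    ``cost.form='none'`` the objective is unbounded in v; evaluating it is
    still legal, optimising it is not.
    """
    er, dt = _er_dt_arrays(p.v, p.a, p.sigma)
    total_time = float(dt) + p.ndt
    if total_time <= 0:
        raise ZeroDivisionError("DT + NDT must be > 0")
    numer = w.R * (1.0 - float(er)) - w.P * float(er)
    return numer / total_time - float(cost_value(cost, p.v, p.a))


def reward_rate_gradient(
    p: DDMParams, w: IncentiveWeights, cost: CostSpec = CostSpec()
):
    """Analytic (dRR/dv, dRR/da) at ``p``.

    Both components are affine in (R, P) at fixed (v, a) — the property the
    inverse-inference linear solve exploits.
    """
    er, dt, er_v, er_a, dt_v, dt_a = (float(x) for x in _er_dt_derivs(p.v, p.a, p.sigma))
    T = dt + p.ndt
    if T <= 0:
        raise ZeroDivisionError("DT + NDT must be > 0")
    numer = w.R - (w.R + w.P) * er
    numer_v = -(w.R + w.P) * er_v
    numer_a = -(w.R + w.P) * er_a
    d_dv = (numer_v * T - numer * dt_v) / (T * T) - cost_derivative(cost, p.v)
    d_da = (numer_a * T - numer * dt_a) / (T * T) - 2.0 * cost.threshold_weight * p.a
    return d_dv, d_da
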