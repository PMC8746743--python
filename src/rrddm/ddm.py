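"""Drift-diffusion performance: closed forms, sampling, and estimation.

The drift-diffusion model (DDM) describes a two-alternative decision as
noisy evidence accumulating from a starting point toward one of two
absorbing boundaries (error at 0, correct at ``a``).  With an unbiased
start at ``a/2`` and diffusion coefficient ``sigma``, the expected error
rate and mean decision time have closed forms in the drift rate ``v`` and
boundary separation ``a``:

    ER = 1 / (1 + exp(a*v / sigma^2))
    DT = (a / (2*v)) * tanh(a*v / (2*sigma^2))      (DT -> a^2/(4*sigma^2) as v -> 0)

This module provides those closed forms together with their partial
derivatives, a stochastic first-passage sampler (fine Euler-Maruyama), and
a deterministic moment-based estimator of (v, a, ndt) from trial data, with
an optional maximum-likelihood refinement using the Wiener first-passage
density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "DDMParams",
    "PerformanceStats",
    "InvalidParameterError",
    "EstimationError",
    "ddm_expected_performance",
    "ddm_performance_derivatives",
    "simulate_trial",
    "simulate_trials",
    "estimate_ddm",
    "wiener_logpdf",
]

#: Default Euler-Maruyama step (s).  Each step applies a Brownian-bridge
#: crossing check, which removes the leading-order O(sqrt(dt)) boundary
#: undershoot bias of plain Euler-Maruyama, so 1 ms steps are effectively
#: exact in distribution for the parameter ranges used here.
DEFAULT_STEP = 1e-3

#: Drift magnitudes below this use the analytic v -> 0 limits.
_V_EPS = 1e-6


class InvalidParameterError(ValueError):
    """A DDM parameter violates its domain constraint."""


class EstimationError(RuntimeError):
    """Moment inversion is impossible for the supplied data.

    Attributes
    ----------
    code : str
        Machine-readable reason: ``"all_correct"``, ``"all_error"``,
        ``"chance_accuracy"``, ``"too_few_trials"``, ``"nonpositive_rt"``
        or ``"degenerate_variance"``.
    """

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code


@dataclass(frozen=True)
class DDMParams:
    """Per-condition decision-process settings.

    Parameters
    ----------
    v : float
        Drift rate (evidence units / s), signed toward the correct boundary.
    a : float
        Boundary separation (evidence units); the start point is fixed at
        the midpoint ``a/2``.
    ndt : float
        Non-decision time (s): stimulus encoding plus motor execution.
    sigma : float
        Diffusion coefficient (evidence units / sqrt(s)).  Conventionally
        1.0, which puts ``a`` and ``v`` in noise units.
    """

    v: float
    a: float
    ndt: float = 0.0
    sigma: float = 1.0

    def __post_init__(self):
        if not math.isfinite(self.v):
            raise InvalidParameterError("drift rate v must be finite")
        if not (self.a > 0):
            raise InvalidParameterError(f"boundary separation a must be > 0, got {self.a}")
        if self.ndt < 0:
            raise InvalidParameterError(f"non-decision time ndt must be >= 0, got {self.ndt}")
        if not (self.sigma > 0):
            raise InvalidParameterError(f"noise scale sigma must be > 0, got {self.sigma}")

    def with_(self, **kw) -> "DDMParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class PerformanceStats:
    """Expected error rate (ER) and mean decision time (DT, seconds)."""

    er: float
    dt: float


# ---------------------------------------------------------------------------
# Closed forms and derivatives
# ---------------------------------------------------------------------------

def _er_dt_arrays(v, a, sigma):
    """Vectorised ER and DT; handles the v -> 0 removable singularity."""
    v = np.asarray(v, dtype=float)
    a = np.asarray(a, dtype=float)
    s2 = sigma * sigma
    er = expit(-a * v / s2)
    small = np.abs(v) < _V_EPS
    v_safe = np.where(small, 1.0, v)
    dt = np.where(
        small,
        a * a / (4.0 * s2),
        (a / (2.0 * v_safe)) * np.tanh(a * v_safe / (2.0 * s2)),
    )
    return er, dt


def ddm_expected_performance(p: DDMParams) -> PerformanceStats:
    """Closed-form expected error rate and decision time.

    ER is strictly decreasing in ``v*a``; DT is continuous in ``v`` with the
    zero-drift limit ``a^2 / (4*sigma^2)``.
    """
    er, dt = _er_dt_arrays(p.v, p.a, p.sigma)
    return PerformanceStats(er=float(er), dt=float(dt))


def _er_dt_derivs(v, a, sigma):
    """ER, DT and their partials w.r.t. v and a (vectorised).

    Returns (er, dt, er_v, er_a, dt_v, dt_a).
    """
    v = np.asarray(v, dtype=float)
    a = np.asarray(a, dtype=float)
    s2 = sigma * sigma
    er = expit(-a * v / s2)
    g = er * (1.0 - er)
    er_v = -g * a / s2
    er_a = -g * v / s2

    small = np.abs(v) < _V_EPS
    v_safe = np.where(small, 1.0, v)
    u = a * v_safe / (2.0 * s2)
    tanh_u = np.tanh(u)
    sech2_u = 1.0 - tanh_u * tanh_u

    dt = np.where(small, a * a / (4.0 * s2), (a / (2.0 * v_safe)) * tanh_u)
    dt_v = np.where(
        small,
        -(a ** 4) * v / (24.0 * s2 ** 3),
        -(a / (2.0 * v_safe ** 2)) * tanh_u + (a * a / (4.0 * v_safe * s2)) * sech2_u,
    )
    dt_a = np.where(
        small,
        a / (2.0 * s2),
        tanh_u / (2.0 * v_safe) + (a / (4.0 * s2)) * sech2_u,
    )
    return er, dt, er_v, er_a, dt_v, dt_a


def ddm_performance_derivatives(p: DDMParams):
    """Partial derivatives of ER and DT at ``p``.

    Returns a dict with keys ``er, dt, er_v, er_a, dt_v, dt_a``.
    """
    er, dt, er_v, er_a, dt_v, dt_a = _er_dt_derivs(p.v, p.a, p.sigma)
    return {
        "er": float(er), "dt": float(dt),
        "er_v": float(er_v), "er_a": float(er_a),
        "dt_v": float(dt_v), "dt_a": float(dt_a),
    }


# ---------------------------------------------------------------------------
# First-passage sampler
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _fpt_batch(v, a, sigma, dt, n, seed, max_steps):  # pragma: no cover - jitted
    np.random.seed(seed)
    rts = np.empty(n)
    correct = np.empty(n, np.bool_)
    sq = sigma * math.sqrt(dt)
    s2dt = sigma * sigma * dt
    for i in range(n):
        x = 0.5 * a
        step = 0
        hit_up = False
        absorbed = False
        while step < max_steps:
            x1 = x + v * dt + sq * np.random.normal()
            step += 1
            if x1 >= a:
                hit_up = True
                absorbed = True
                break
            if x1 <= 0.0:
                absorbed = True
                break
            # Brownian-bridge probability that the path crossed a boundary
            # within the step despite both endpoints being interior.
            p_up = math.exp(-2.0 * (a - x) * (a - x1) / s2dt)
            p_lo = math.exp(-2.0 * x * x1 / s2dt)
            u = np.random.random()
            if u < p_up:
                hit_up = True
                absorbed = True
                break
            elif u < p_up + p_lo:
                absorbed = True
                break
            x = x1
        if not absorbed:
            hit_up = x >= 0.5 * a
        # crossing occurred within the final step: mid-step time estimate
        rts[i] = (step - 0.5) * dt if absorbed else step * dt
        correct[i] = hit_up
    return rts, correct


def simulate_trials(
    p: DDMParams,
    n: int,
    rng_seed: int,
    step: float = DEFAULT_STEP,
    max_time: float = 120.0,
):
    """Sample ``n`` first-passage trials by Euler-Maruyama integration.

    Returns ``(rt, correct)`` arrays; ``rt`` includes the non-decision time.
    Paths still unabsorbed at ``max_time`` (vanishingly rare for sane
    parameters) are scored by their current side.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 < step <= 1e-3):
        raise ValueError("step must be in (0, 1e-3] seconds")
    max_steps = int(max_time / step)
    rts, correct = _fpt_batch(
        float(p.v), float(p.a), float(p.sigma), float(step), int(n),
        int(rng_seed) % (2 ** 32), max_steps,
    )
    return rts + p.ndt, correct


def simulate_trial(p: DDMParams, rng_seed: int, step: float = DEFAULT_STEP):
    """Sample a single (rt, correct) pair; deterministic for a given seed."""
    rt, correct = simulate_trials(p, 1, rng_seed, step=step)
    return float(rt[0]), bool(correct[0])


# ---------------------------------------------------------------------------
# Moment-based estimation (EZ-style), optional ML refinement
# ---------------------------------------------------------------------------

def _ez_point(acc, mrt, vrt, sigma):
    """Closed-form moment inversion from accuracy and correct-RT moments."""
    s2 = sigma * sigma
    L = math.log(acc / (1.0 - acc))
    x = L * (L * acc * acc - L * acc + acc - 0.5) / vrt
    v = math.copysign(1.0, acc - 0.5) * sigma * x ** 0.25
    a = s2 * L / v
    mdt = (a / (2.0 * v)) * math.tanh(v * a / (2.0 * s2))
    ndt = mrt - mdt
    return v, a, ndt


def estimate_ddm(
    trials: pd.DataFrame,
    sigma: float = 1.0,
    refine: bool = False,
    min_trials: int = 100,
) -> DDMParams:
    """Estimate (v, a, ndt) for one condition from trial data.

    Uses closed-form moment inversion from accuracy and the mean and
    variance of correct-trial RTs, with ``sigma`` fixed by convention.  The
    starting point is assumed unbiased (midpoint).  ``refine=True`` follows
    with a maximum-likelihood polish under the Wiener first-passage density.

    Parameters
    ----------
    trials : DataFrame with columns ``rt`` (s) and ``correct`` (0/1).
        All rows are assumed to come from a single condition.

    Raises
    ------
    EstimationError
        If the accuracy is exactly 0, 1 or 0.5 (moment inversion undefined),
        there are too few trials, or RTs are non-positive.
    """
    rt = np.asarray(trials["rt"], dtype=float)
    correct = np.asarray(trials["correct"], dtype=bool)
    n = rt.size
    if n < min_trials:
        raise EstimationError("too_few_trials", f"need >= {min_trials} trials, got {n}")
    if np.any(rt <= 0):
        raise EstimationError("nonpositive_rt", "all RTs must be > 0")

    acc = float(correct.mean())
    if acc == 1.0:
        raise EstimationError("all_correct", "accuracy is 1: drift/threshold not identifiable from moments")
    if acc == 0.0:
        raise EstimationError("all_error", "accuracy is 0: drift/threshold not identifiable from moments")
    if acc == 0.5:
        raise EstimationError("chance_accuracy", "accuracy exactly 0.5: drift sign and magnitude not identifiable")

    crt = rt[correct]
    if crt.size < 2 or float(np.var(crt, ddof=1)) <= 0:
        raise EstimationError("degenerate_variance", "correct-RT variance must be positive")

    mrt = float(np.mean(crt))
    vrt = float(np.var(crt, ddof=1))
    v, a, ndt = _ez_point(acc, mrt, vrt, sigma)
    ndt = max(ndt, 0.0)
    est = DDMParams(v=v, a=a, ndt=ndt, sigma=sigma)
    if refine:
        est = _ml_refine(rt, correct, est)
    return est


# --- Wiener first-passage density (series expansion) -----------------------

def wiener_logpdf(t, v, a, correct, sigma=1.0, n_terms=None):
    """Log density of a first passage at decision time ``t``.

    ``correct=True`` gives the density of absorption at the upper boundary
    ``a``; the start point is the midpoint.  Uses the small-time image
    expansion of the density at the lower boundary of a unit-variance
    process, applied to the reflected process for upper-boundary hits.
    """
    t_in = np.asarray(t, dtype=float)
    scalar = t_in.ndim == 0
    t = np.atleast_1d(t_in)
    # Rescale to unit variance: a' = a/sigma, v' = v/sigma.
    a_ = a / sigma
    v_ = -v / sigma if correct else v / sigma
    # Density of lower-boundary absorption with start w=1/2 (relative units):
    # f(t) = a'^{-2} exp(-v' a' w - v'^2 t / 2) * f_w(t / a'^2)
    w = 0.5
    lead = -v_ * a_ * w - 0.5 * v_ * v_ * t
    tt = t / (a_ * a_)  # normalised time
    if n_terms is None:
        # enough images that the truncated tail is < exp(-40)
        n_terms = int(min(60, max(7, math.ceil(math.sqrt(80.0 * float(np.max(tt))) / 2.0) + 1)))
    k = np.arange(-n_terms, n_terms + 1)
    # small-time image expansion: f_w(tt) = sum_k (w+2k) phi((w+2k)/sqrt(tt)) / tt^{3/2}
    z = (w + 2.0 * k)[None, :]
    tt_col = tt[:, None]
    terms = z * np.exp(-z * z / (2.0 * tt_col)) / np.sqrt(2.0 * np.pi * tt_col ** 3)
    f = np.sum(terms, axis=1) / (a_ * a_)
    f = np.maximum(f, 1e-300)
    out = lead + np.log(f)
    return float(out[0]) if scalar else out


def _ml_refine(rt, correct, start: DDMParams) -> DDMParams:
    """Maximum-likelihood polish of (v, a, ndt) from an EZ start."""
    rt_min = float(np.min(rt))

    def nll(theta):
        v, a, ndt = theta
        if a <= 0 or ndt < 0 or ndt >= rt_min:
            return 1e12
        t = rt - ndt
        ll = 0.0
        for flag in (True, False):
            m = correct == flag
            if m.any():
                ll += float(np.sum(wiener_logpdf(t[m], v, a, flag, sigma=start.sigma)))
        return -ll

    res = minimize(
        nll, x0=[start.v, start.a, start.ndt],
        method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 2000},
    )
    v, a, ndt = res.x
    if not res.success or a <= 0:
        return start
    return DDMParams(v=float(v), a=float(a), ndt=float(max(ndt, 0.0)), sigma=start.sigma)
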