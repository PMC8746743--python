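"""Inverse inference: recover incentive sensitivities from DDM parameters.

If an observed (v, a) configuration is assumed to be reward-rate optimal,
the two first-order conditions dRR/dv = 0 and dRR/da = 0 pin down the
subjective reward and penalty weights (R, P) that rationalise it.  Because
the reward-rate gradient is affine in (R, P) at fixed (v, a), the
stationarity conditions form a 2x2 linear system and the inversion is a
single linear solve — no optimisation required.

`run_recovery` validates the whole chain by simulation: draw ground-truth
(R, P) weights over a grid, derive the optimal (v, a) per cell, optionally
simulate trials and re-estimate the DDM parameters, invert, and correlate
recovered with true weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ddm import DDMParams, EstimationError, estimate_ddm, _er_dt_derivs, simulate_trials
from .optimize import DEFAULT_NDT, optimize_policy
from .reward_rate import CostSpec, IncentiveWeights, cost_derivative, reward_rate_gradient

__all__ = [
    "SensitivityEstimate",
    "RecoveryResult",
    "DegenerateGeometryError",
    "invert_sensitivities",
    "run_recovery",
    "default_weight_grid",
]

logger = logging.getLogger("rrddm")

#: Condition-number ceiling for the 2x2 stationarity solve.
COND_LIMIT = 1e10


class DegenerateGeometryError(RuntimeError):
    """The stationarity system at (v, a) is singular or ill-conditioned."""


@dataclass(frozen=True)
class SensitivityEstimate:
    """Recovered subjective reward/penalty weights for one condition.

    ``valid`` is False when a recovered weight is negative (the observed
    configuration cannot be rationalised by positive incentives); the raw
    values are reported, never clipped.
    """

    r_hat: float
    p_hat: float
    condition: str = ""
    residual_grad_norm: float = float("nan")
    condition_number: float = float("nan")
    valid: bool = True
    flag: str = "ok"


@dataclass(frozen=True)
class RecoveryResult:
    """True-vs-recovered incentive weights across a simulation grid."""

    table: pd.DataFrame
    corr_R: float
    corr_P: float
    regime: str
    n_cells: int
    n_failed: int
    meta: dict = field(default_factory=dict)


def _stationarity_system(p_hat: DDMParams, cost: CostSpec):
    """Coefficients (A, b) of the affine system A @ [R, P] = b.

    Row 1 is dRR/dv = 0, row 2 is dRR/da = 0, both multiplied through by
    (DT+NDT)^2 so the entries stay well-scaled.
    """
    er, dt, er_v, er_a, dt_v, dt_a = (float(x) for x in _er_dt_derivs(p_hat.v, p_hat.a, p_hat.sigma))
    T = dt + p_hat.ndt
    A = np.array([
        [-er_v * T - (1.0 - er) * dt_v, -er_v * T + er * dt_v],
        [-er_a * T - (1.0 - er) * dt_a, -er_a * T + er * dt_a],
    ])
    b = np.array([
        cost_derivative(cost, p_hat.v) * T * T,
        2.0 * cost.threshold_weight * p_hat.a * T * T,
    ])
    return A, b


def invert_sensitivities(
    p_hat: DDMParams,
    cost: CostSpec = CostSpec(),
    condition: str = "",
) -> SensitivityEstimate:
    """Solve the stationarity conditions for the incentive weights.

    Given estimated DDM parameters (v, a, ndt in ``p_hat``) assumed to be
    reward-rate optimal, returns the (R, P) for which dRR/dv and dRR/da
    both vanish at that point.  With the default quadratic drift cost both
    conditions are affine in (R, P), so this is an exact 2x2 linear solve.

    Raises
    ------
    DegenerateGeometryError
        If the system's condition number exceeds ``COND_LIMIT``.
    """
    if not (p_hat.v > 0):
        raise ValueError(f"inversion requires v > 0, got v={p_hat.v}")
    A, b = _stationarity_system(p_hat, cost)
    cond = float(np.linalg.cond(A))
    if not np.isfinite(cond) or cond > COND_LIMIT:
        raise DegenerateGeometryError(
            f"stationarity system is ill-conditioned at (v={p_hat.v:.4g}, a={p_hat.a:.4g}): "
            f"cond={cond:.3g}"
        )
    r_hat, p_hat_w = (float(x) for x in np.linalg.solve(A, b))

    valid, flag = True, "ok"
    residual = float("nan")
    if r_hat <= 0 or p_hat_w < 0:
        valid, flag = False, "negative_weights"
    else:
        g = reward_rate_gradient(p_hat, IncentiveWeights(R=r_hat, P=p_hat_w), cost)
        residual = max(abs(g[0]), abs(g[1]))
    return SensitivityEstimate(
        r_hat=r_hat, p_hat=p_hat_w, condition=condition,
        residual_grad_norm=residual, condition_number=cond, valid=valid, flag=flag,
    )


def default_weight_grid(n_r: int = 5, n_p: int = 5):
    """Log-spaced (R, P) grid over plausible incentive-weight ranges.

    R spans 8-20 a.u. (the range over which the normative optima are
    tabulated); P spans 5-125 a.u.  The penalty ceiling is set so that the
    error rate at every cell's optimal policy stays above ~0.5%: beyond
    that, a few thousand simulated trials routinely contain no errors at
    all and moment-based DDM estimation is undefined.  Log spacing matches
    the multiplicative structure of incentive magnitudes.
    """
    R_vals = np.geomspace(8.0, 20.0, n_r)
    P_vals = np.geomspace(5.0, 125.0, n_p)
    return [IncentiveWeights(R=float(R), P=float(P)) for R in R_vals for P in P_vals]


def run_recovery(
    weights,
    regime: str = "fitted",
    trials_per_condition: int = 2000,
    rng_seed: int = 0,
    ndt: float = DEFAULT_NDT,
    cost: CostSpec = CostSpec(),
    sigma: float = 1.0,
    min_success_frac: float = 0.9,
    refine: bool = True,
    shared_ndt: bool = True,
) -> RecoveryResult:
    """Parameter-recovery simulation for the incentive-weight inversion.

    For each ground-truth (R, P) pair: find the optimal (v*, a*); in the
    ``"noiseless"`` regime invert those exact optima, in the ``"fitted"``
    regime first simulate ``trials_per_condition`` trials and re-estimate
    the DDM (moment inversion, plus ML refinement when ``refine``), then
    invert the estimates.  With ``shared_ndt`` the inversion uses the
    session-level non-decision time rather than each cell's own noisy ndt
    estimate, mirroring per-condition (v, a) estimation with a shared ndt.
    Reports Pearson correlations between true and recovered weights across
    the grid.  Fully reproducible from ``rng_seed``.
    """
    if regime not in ("noiseless", "fitted"):
        raise ValueError(f"regime must be 'noiseless' or 'fitted', got {regime!r}")
    weights = list(weights)
    if len(weights) < 4:
        raise ValueError("need at least 4 grid points for a meaningful correlation")

    seeds = np.random.SeedSequence(rng_seed).generate_state(len(weights))
    rows = []
    n_failed = 0
    for i, w_true in enumerate(weights):
        row = {"R_true": w_true.R, "P_true": w_true.P,
               "R_rec": np.nan, "P_rec": np.nan, "ok": False, "note": ""}
        try:
            pol = optimize_policy(w_true, ndt=ndt, cost=cost, sigma=sigma)
            if not pol.converged:
                raise RuntimeError("optimizer did not converge")
            if regime == "noiseless":
                p_hat = DDMParams(v=pol.v_star, a=pol.a_star, ndt=ndt, sigma=sigma)
            else:
                truth = DDMParams(v=pol.v_star, a=pol.a_star, ndt=ndt, sigma=sigma)
                rt, correct = simulate_trials(truth, trials_per_condition, int(seeds[i]) % (2 ** 31))
                p_hat = estimate_ddm(
                    pd.DataFrame({"rt": rt, "correct": correct}), sigma=sigma, refine=refine
                )
                if shared_ndt:
                    p_hat = p_hat.with_(ndt=ndt)
            est = invert_sensitivities(p_hat, cost=cost)
            row.update(R_rec=est.r_hat, P_rec=est.p_hat, ok=True,
                       note="" if est.valid else est.flag)
        except (EstimationError, DegenerateGeometryError, RuntimeError, ValueError) as exc:
            n_failed += 1
            row["note"] = f"{type(exc).__name__}: {exc}"
            logger.warning("recovery cell (R=%.3g, P=%.3g) failed: %s", w_true.R, w_true.P, exc)
        rows.append(row)

    table = pd.DataFrame(rows)
    n_cells = len(weights)
    ok = table["ok"].to_numpy()
    if ok.sum() < min_success_frac * n_cells:
        corr_R = corr_P = float("nan")
        logger.error("only %d/%d recovery cells succeeded; correlations withheld", ok.sum(), n_cells)
    else:
        sub = table[table["ok"]]
        corr_R = float(stats.pearsonr(sub["R_true"], sub["R_rec"]).statistic)
        corr_P = float(stats.pearsonr(sub["P_true"], sub["P_rec"]).statistic)

    return RecoveryResult(
        table=table, corr_R=corr_R, corr_P=corr_P,
        regime=regime, n_cells=n_cells, n_failed=n_failed,
        meta={"trials_per_condition": trials_per_condition if regime == "fitted" else 0,
              "rng_seed": rng_seed, "ndt": ndt, "sigma": sigma, "refine": refine,
              "shared_ndt": shared_ndt, "cost_form": cost.form, "cost_weight": cost.weight},
    )
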