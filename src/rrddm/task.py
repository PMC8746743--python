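"""Synthetic interval-based incentivized Stroop experiment.

Emulates a self-paced task in which participants complete as many Stroop
trials as they can within fixed intervals of 8-12 s.  Each interval is
cued with a reward level (cents gained per correct response) and a penalty
level (cents lost per error).  Study design 1 crosses two levels
(1c, 10c) of each incentive with 20 intervals per condition; design 2
crosses three levels (1c, 5c, 10c) with 8 intervals per condition.
Congruent and incongruent trials are mixed 1:1 on average (i.i.d.
assignment, so the realised proportion varies slightly across intervals).

Trial RT and accuracy are generated from a DDM whose per-condition drift
rate and threshold typically come from reward-rate optimisation of
ground-truth incentive weights; incongruent trials get a drift decrement
and threshold increment (the Stroop interference signature).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ddm import DDMParams, simulate_trials
from .optimize import optimize_policy
from .reward_rate import CostSpec, IncentiveWeights

__all__ = [
    "Condition",
    "ExperimentDesign",
    "SubjectProfile",
    "build_profile",
    "generate_experiment",
    "summarize_behavior",
    "STUDY_LEVELS",
]

logger = logging.getLogger("rrddm")

#: Incentive levels (cents) per study design.
STUDY_LEVELS = {1: (1, 10), 2: (1, 5, 10)}

#: Intervals per condition per study design.
STUDY_INTERVALS = {1: 20, 2: 8}


@dataclass(frozen=True)
class Condition:
    """A cued incentive context: cents per correct and cents per error."""

    reward_level: int
    penalty_level: int

    @property
    def label(self) -> str:
        return f"R{self.reward_level}P{self.penalty_level}"


@dataclass(frozen=True)
class ExperimentDesign:
    """Structure of the interval task.

    The block/counterbalance descriptor is metadata only: one incentive is
    notionally fixed per block while the other varies, but no order effects
    enter the generative process.
    """

    study: int = 1
    n_subjects: int = 1
    intervals_per_condition: int | None = None
    interval_duration_range: tuple = (8.0, 12.0)
    congruent_fraction: float = 0.5
    boundary_policy: str = "discard"  # or "truncate_as_omission"
    counterbalance: str = "blocked-one-incentive-fixed"

    def __post_init__(self):
        if self.study not in STUDY_LEVELS:
            raise ValueError(f"study must be one of {sorted(STUDY_LEVELS)}, got {self.study}")
        lo, hi = self.interval_duration_range
        if not (8.0 <= lo <= hi <= 12.0):
            raise ValueError("interval durations must lie within [8, 12] s")
        if not (0.0 < self.congruent_fraction < 1.0):
            raise ValueError("congruent_fraction must be in (0, 1)")
        n = self.intervals_per_condition
        if n is not None and n < 1:
            raise ValueError("intervals_per_condition must be >= 1")
        if self.boundary_policy not in ("discard", "truncate_as_omission"):
            raise ValueError("boundary_policy must be 'discard' or 'truncate_as_omission'")

    @property
    def conditions(self):
        levels = STUDY_LEVELS[self.study]
        return [Condition(r, p) for r in levels for p in levels]

    @property
    def n_intervals(self) -> int:
        per = self.intervals_per_condition or STUDY_INTERVALS[self.study]
        return per * len(self.conditions)

    @property
    def n_blocks(self) -> int:
        return {1: 4, 2: 6}[self.study]


@dataclass(frozen=True)
class SubjectProfile:
    """Per-condition DDM parameters for one simulated participant.

    ``params`` maps (reward_level, penalty_level) -> {"congruent": DDMParams,
    "incongruent": DDMParams}.  Incongruent trials must not have a higher
    drift rate or a lower threshold than congruent ones.
    """

    subject: int
    params: dict
    ndt: float
    weights: dict = field(default_factory=dict)  # ground truth, if derived

    def __post_init__(self):
        for key, pair in self.params.items():
            c, i = pair["congruent"], pair["incongruent"]
            if i.v > c.v + 1e-12 or i.a < c.a - 1e-12:
                raise ValueError(
                    f"condition {key}: incongruent trials must have drift <= and "
                    f"threshold >= congruent trials"
                )


def build_profile(
    w_true: dict,
    subject: int = 0,
    congruence_offsets: tuple = (0.3, 0.1),
    ndt: float = 0.4,
    cost: CostSpec = CostSpec(),
    sigma: float = 1.0,
) -> SubjectProfile:
    """Derive a subject's per-condition DDM parameters from incentive weights.

    For each condition, the congruent-trial (v, a) is the reward-rate
    optimum for that condition's subjective weights; incongruent trials get
    a drift decrement ``dv`` and threshold increment ``da`` from
    ``congruence_offsets = (dv, da)``.

    Parameters
    ----------
    w_true : dict mapping (reward_level, penalty_level) -> IncentiveWeights.
    """
    dv, da = congruence_offsets
    if dv < 0 or da < 0:
        raise ValueError("congruence offsets must be >= 0 (drift decrement, threshold increment)")
    params = {}
    for key, w in w_true.items():
        pol = optimize_policy(w, ndt=ndt, cost=cost, sigma=sigma)
        if not pol.converged:
            raise RuntimeError(f"policy optimization did not converge for condition {key}")
        v_inc = pol.v_star - dv
        if v_inc <= 0:
            raise ValueError(
                f"condition {key}: drift decrement {dv} leaves incongruent drift "
                f"{v_inc:.3g} <= 0"
            )
        params[key] = {
            "congruent": DDMParams(v=pol.v_star, a=pol.a_star, ndt=ndt, sigma=sigma),
            "incongruent": DDMParams(v=v_inc, a=pol.a_star + da, ndt=ndt, sigma=sigma),
        }
    return SubjectProfile(subject=subject, params=params, ndt=ndt, weights=dict(w_true))


class _TrialPool:
    """Pre-sampled DDM trials for one (condition, congruency) stream.

    Sampling in batches keeps the jitted sampler hot while remaining fully
    deterministic: refills use consecutive child seeds.
    """

    def __init__(self, params: DDMParams, seed_seq: np.random.SeedSequence, batch: int = 512):
        self.params = params
        self.batch = batch
        self._seeds = iter(seed_seq.generate_state(4096))
        self._rt = np.empty(0)
        self._correct = np.empty(0, bool)
        self._i = 0

    def draw(self):
        if self._i >= self._rt.size:
            seed = int(next(self._seeds)) % (2 ** 31)
            self._rt, self._correct = simulate_trials(self.params, self.batch, seed)
            self._i = 0
        rt, ok = float(self._rt[self._i]), bool(self._correct[self._i])
        self._i += 1
        return rt, ok


def generate_experiment(
    design: ExperimentDesign,
    profiles,
    rng_seed: int,
):
    """Simulate the full experiment; returns (trial table, interval table).

    Trials are packed sequentially into each interval until the next
    trial's RT would overrun the interval end.  Under the default
    ``discard`` policy the in-flight trial is dropped; under
    ``truncate_as_omission`` it is recorded with no outcome (rt = time
    remaining, correct = NA, zero earnings).  Byte-identical output for a
    given seed.
    """
    profiles = list(profiles)
    cond_keys = {(c.reward_level, c.penalty_level) for c in design.conditions}
    for prof in profiles:
        missing = cond_keys - set(prof.params)
        if missing:
            raise ValueError(f"subject {prof.subject}: profile lacks conditions {sorted(missing)}")

    master = np.random.SeedSequence(rng_seed)
    subject_seqs = master.spawn(len(profiles))
    trial_rows, interval_rows = [], []

    per_cond = design.intervals_per_condition or STUDY_INTERVALS[design.study]
    for prof, sseq in zip(profiles, subject_seqs):
        order_seq, pool_seq, dur_seq = sseq.spawn(3)
        rng = np.random.default_rng(order_seq)
        durations_rng = np.random.default_rng(dur_seq)

        pools = {}
        pool_children = pool_seq.spawn(2 * len(cond_keys))
        for j, key in enumerate(sorted(cond_keys)):
            pools[key] = {
                "congruent": _TrialPool(prof.params[key]["congruent"], pool_children[2 * j]),
                "incongruent": _TrialPool(prof.params[key]["incongruent"], pool_children[2 * j + 1]),
            }

        schedule = [c for c in design.conditions for _ in range(per_cond)]
        rng.shuffle(schedule)
        block_size = max(1, len(schedule) // design.n_blocks)

        for interval_id, cond in enumerate(schedule):
            key = (cond.reward_level, cond.penalty_level)
            duration = float(durations_rng.uniform(*design.interval_duration_range))
            block = min(interval_id // block_size, design.n_blocks - 1)
            elapsed = 0.0
            trial_id = 0
            n_correct = n_error = n_omitted = 0
            earnings = 0
            while True:
                congruent = bool(rng.random() < design.congruent_fraction)
                pool = pools[key]["congruent" if congruent else "incongruent"]
                rt, ok = pool.draw()
                if elapsed + rt > duration:
                    if design.boundary_policy == "truncate_as_omission":
                        trial_rows.append({
                            "subject": prof.subject, "block": block, "interval": interval_id,
                            "trial": trial_id, "condition_reward": cond.reward_level,
                            "condition_penalty": cond.penalty_level,
                            "congruent": int(congruent), "rt": duration - elapsed,
                            "correct": np.nan, "earnings": 0,
                        })
                        n_omitted += 1
                    break
                delta = cond.reward_level if ok else -cond.penalty_level
                earnings += delta
                n_correct += int(ok)
                n_error += int(not ok)
                trial_rows.append({
                    "subject": prof.subject, "block": block, "interval": interval_id,
                    "trial": trial_id, "condition_reward": cond.reward_level,
                    "condition_penalty": cond.penalty_level,
                    "congruent": int(congruent), "rt": rt, "correct": int(ok),
                    "earnings": delta,
                })
                elapsed += rt
                trial_id += 1
            interval_rows.append({
                "subject": prof.subject, "block": block, "interval": interval_id,
                "condition_reward": cond.reward_level, "condition_penalty": cond.penalty_level,
                "duration": duration, "n_trials": trial_id, "n_correct": n_correct,
                "n_error": n_error, "n_omitted": n_omitted,
                "correct_per_second": n_correct / duration, "earnings": earnings,
            })

    trials = pd.DataFrame(trial_rows)
    intervals = pd.DataFrame(interval_rows)
    return trials, intervals


def summarize_behavior(
    trials: pd.DataFrame,
    intervals: pd.DataFrame,
    n_boot: int = 2000,
    rng_seed: int = 0,
):
    """Condition-level behavioural summary with within-subject contrasts.

    Returns a dict with:

    ``by_condition`` : per subject x condition mean correct-trial RT,
        accuracy, and correct responses per second.
    ``condition_means`` : the same averaged over subjects.
    ``contrasts`` : high-vs-low reward and penalty within-subject
        differences for each measure, with mean and bootstrap 95% CI
        (resampling subjects; seeded).
    """
    if trials.empty or intervals.empty:
        raise ValueError("trial and interval tables must be non-empty")
    scored = trials.dropna(subset=["correct"])
    grp = ["subject", "condition_reward", "condition_penalty"]
    by_cond = scored.groupby(grp).apply(
        lambda d: pd.Series({
            "mean_rt_correct": d.loc[d["correct"] == 1, "rt"].mean(),
            "accuracy": d["correct"].mean(),
        }),
        include_groups=False,
    ).reset_index()
    cps = intervals.groupby(grp)["correct_per_second"].mean().reset_index()
    by_cond = by_cond.merge(cps, on=grp, how="outer")

    subjects = sorted(by_cond["subject"].unique())
    r_levels = sorted(by_cond["condition_reward"].unique())
    p_levels = sorted(by_cond["condition_penalty"].unique())
    expected = len(subjects) * len(r_levels) * len(p_levels)
    if len(by_cond) < expected:
        warnings.warn(
            f"missing condition cells: {expected - len(by_cond)} of {expected}; "
            "contrasts computed on available cells", stacklevel=2,
        )

    measures = ["mean_rt_correct", "accuracy", "correct_per_second"]
    cond_means = by_cond.groupby(["condition_reward", "condition_penalty"])[measures].mean().reset_index()

    rng = np.random.default_rng(rng_seed)
    contrasts = []
    for axis, levels in (("reward", r_levels), ("penalty", p_levels)):
        col = f"condition_{axis}"
        hi, lo = max(levels), min(levels)
        hi_m = by_cond[by_cond[col] == hi].groupby("subject")[measures].mean()
        lo_m = by_cond[by_cond[col] == lo].groupby("subject")[measures].mean()
        diff = (hi_m - lo_m).dropna()
        for m in measures:
            d = diff[m].to_numpy()
            if d.size == 0:
                contrasts.append({"axis": axis, "measure": m, "mean_diff": np.nan,
                                  "ci_lo": np.nan, "ci_hi": np.nan, "n_subjects": 0})
                continue
            boots = np.array([
                d[rng.integers(0, d.size, d.size)].mean() for _ in range(n_boot)
            ])
            contrasts.append({
                "axis": axis, "measure": m, "mean_diff": float(d.mean()),
                "ci_lo": float(np.percentile(boots, 2.5)),
                "ci_hi": float(np.percentile(boots, 97.5)),
                "n_subjects": int(d.size),
            })
    return {
        "by_condition": by_cond,
        "condition_means": cond_means,
        "contrasts": pd.DataFrame(contrasts),
    }
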