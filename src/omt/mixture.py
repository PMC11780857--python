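"""Permutation-based mixture decomposition of localization responses.

Each correctly identified trial's response is attributed to one of three
sources by comparing distances from the response to (1) the target's true
location, (2) the nearest non-probed in-trial item, and (3) an item location
drawn from a randomly chosen other trial of the same participant. The
nearest of the three wins. Repeating the draw (default 5000 repetitions per
trial) yields per-trial attribution proportions: target detection,
misbinding and uniform guessing. The logic of the comparison draw: an error
that sits no closer to the trial's own distractor than to a random other-
trial location is not systematic misbinding.

`exact_attribution` enumerates the pool once and returns the exact
expectation of the permutation estimate; it serves as the analytic oracle
for the sampler and as a fast deterministic alternative.

Imprecision is the p_target-weighted standard deviation of the radial
response-to-target error over correct trials.

Misbinding is undefined at set size 1 (at least two objects are required);
1-item trials contribute to target/guess attribution and imprecision only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import TrialResponse
from .task_design import CONDITIONS, TrialSpec

Location = tuple[float, float]
Trials = list[tuple[TrialSpec, TrialResponse]]

MIXTURE_METRICS = ("target_detection", "misbinding", "guessing", "imprecision")
DEFAULT_N_REPS = 5000


@dataclass(frozen=True)
class TrialAttribution:
    """Attribution proportions for one trial (counts / n_reps)."""

    p_target_hat: float
    p_misbind_hat: float
    p_guess_hat: float
    n_reps: int
    d_target: float
    d_nearest_distractor: float | None  # None at set size 1


@dataclass(frozen=True)
class MixtureEstimate:
    """Per-participant mixture metrics, cumulative across conditions.

    target_detection and guessing average the four condition means;
    misbinding averages the two 3-item conditions only, so the three
    cumulative proportions need not sum exactly to one (normalization holds
    at the trial and condition level).
    """

    target_detection: float
    misbinding: float
    guessing: float
    imprecision: float
    n_trials_used: int
    by_condition: dict[tuple[int, float], dict[str, float]]


def _classify_distances(
    d1: float, d2: float, d3: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (target, misbind) masks per candidate pool distance d3.

    Tie-break priority: target over in-trial distractor over random draw
    (ties have measure zero for continuous responses; fixed for
    determinism). d2 is +inf when the trial has no in-trial distractors.
    """
    is_target = (d1 <= d2) & (d1 <= d3)
    is_misbind = (d2 < d1) & (d2 <= d3)
    return is_target, is_misbind


def _distances(
    response_loc: Location,
    target_loc: Location,
    in_trial_distractors: list[Location] | tuple[Location, ...],
    other_trial_pool: np.ndarray,
) -> tuple[float, float, np.ndarray]:
    r = np.asarray(response_loc, dtype=float)
    d1 = float(np.linalg.norm(r - np.asarray(target_loc, dtype=float)))
    if len(in_trial_distractors):
        ds = np.asarray(in_trial_distractors, dtype=float)
        d2 = float(np.min(np.linalg.norm(ds - r, axis=1)))
    else:
        d2 = float("inf")
    pool = np.asarray(other_trial_pool, dtype=float)
    if pool.ndim != 2 or pool.shape[0] == 0:
        raise ValueError("other_trial_pool must be a non-empty (n, 2) array")
    d3 = np.linalg.norm(pool - r, axis=1)
    return d1, d2, d3


def attribute_trial(
    response_loc: Location,
    target_loc: Location,
    in_trial_distractors: list[Location] | tuple[Location, ...],
    other_trial_pool: np.ndarray,
    n_reps: int = DEFAULT_N_REPS,
    rng: np.random.Generator | None = None,
) -> TrialAttribution:
    """Permutation attribution: n_reps independent draws from the pool."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    d1, d2, d3_all = _distances(
        response_loc, target_loc, in_trial_distractors, other_trial_pool
    )
    draws = rng.integers(len(d3_all), size=n_reps)
    is_t, is_m = _classify_distances(d1, d2, d3_all[draws])
    p_t = int(is_t.sum()) / n_reps
    p_m = int(is_m.sum()) / n_reps
    return TrialAttribution(
        p_target_hat=p_t,
        p_misbind_hat=p_m,
        # residual, so the three proportions sum to exactly 1.0 in floats
        p_guess_hat=1.0 - (p_t + p_m),
        n_reps=n_reps,
        d_target=d1,
        d_nearest_distractor=None if np.isinf(d2) else d2,
    )


def exact_attribution(
    response_loc: Location,
    target_loc: Location,
    in_trial_distractors: list[Location] | tuple[Location, ...],
    other_trial_pool: np.ndarray,
) -> TrialAttribution:
    """Exact expectation of `attribute_trial`: enumerate the pool once."""
    d1, d2, d3_all = _distances(
        response_loc, target_loc, in_trial_distractors, other_trial_pool
    )
    is_t, is_m = _classify_distances(d1, d2, d3_all)
    n = len(d3_all)
    p_t, p_m = int(is_t.sum()) / n, int(is_m.sum()) / n
    return TrialAttribution(
        p_target_hat=p_t,
        p_misbind_hat=p_m,
        p_guess_hat=1.0 - (p_t + p_m),
        n_reps=n,
        d_target=d1,
        d_nearest_distractor=None if np.isinf(d2) else d2,
    )


def _weighted_sd(values: np.ndarray, weights: np.ndarray) -> float:
    if weights.sum() <= 0:
        return float("nan")
    mean = float(np.average(values, weights=weights))
    var = float(np.average((values - mean) ** 2, weights=weights))
    return float(np.sqrt(var))


def participant_mixture(
    trials: Trials,
    n_reps: int = DEFAULT_N_REPS,
    rng: np.random.Generator | None = None,
    *,
    exact: bool = False,
) -> MixtureEstimate | None:
    """Mixture metrics for one participant-session.

    Attribution runs on correctly identified trials only; the comparison
    pool for a trial holds every item location from all *other* trials of
    the same session. Condition means are combined into cumulative values
    as the unweighted mean across conditions (misbinding: the two 3-item
    conditions).
    """
    rng = rng if rng is not None else np.random.default_rng()
    correct = [(t, r) for t, r in trials if r.identified_target]
    if not correct:
        warnings.warn("no correctly identified trials; mixture estimate missing")
        return None

    all_locs = []
    trial_of_loc = []
    for k, (t, _) in enumerate(trials):
        for _, loc in t.items:
            all_locs.append(loc)
            trial_of_loc.append(k)
    all_locs_arr = np.asarray(all_locs, dtype=float)
    trial_of_loc_arr = np.asarray(trial_of_loc)
    index_of = {id(t): k for k, (t, _) in enumerate(trials)}

    attributions: list[tuple[TrialSpec, TrialAttribution]] = []
    for t, r in correct:
        pool = all_locs_arr[trial_of_loc_arr != index_of[id(t)]]
        args = (r.response_location, t.target_location, t.distractor_locations, pool)
        att = exact_attribution(*args) if exact else attribute_trial(
            *args, n_reps=n_reps, rng=rng
        )
        attributions.append((t, att))

    by_condition: dict[tuple[int, float], dict[str, float]] = {}
    for ss, dl in CONDITIONS:
        cell = [a for t, a in attributions if t.set_size == ss and t.delay_s == dl]
        if not cell:
            continue
        by_condition[(ss, dl)] = {
            "target_detection": float(np.mean([a.p_target_hat for a in cell])),
            "misbinding": (
                float(np.mean([a.p_misbind_hat for a in cell])) if ss > 1 else float("nan")
            ),
            "guessing": float(np.mean([a.p_guess_hat for a in cell])),
            "imprecision": _weighted_sd(
                np.array([a.d_target for a in cell]),
                np.array([a.p_target_hat for a in cell]),
            ),
            "n_correct": float(len(cell)),
        }

    def _mean_over(name: str, conds) -> float:
        vals = [by_condition[c][name] for c in conds if c in by_condition]
        return float(np.mean(vals)) if vals else float("nan")

    three_item = [(3, 1.0), (3, 4.0)]
    return MixtureEstimate(
        target_detection=_mean_over("target_detection", CONDITIONS),
        misbinding=_mean_over("misbinding", three_item),
        guessing=_mean_over("guessing", CONDITIONS),
        imprecision=_mean_over("imprecision", CONDITIONS),
        n_trials_used=len(correct),
        by_condition=by_condition,
    )
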