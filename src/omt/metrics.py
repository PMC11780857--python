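"""Basic performance metrics per condition and their cumulative versions.

Four basic metrics per (set size, delay) condition:

* identification accuracy — proportion of trials with the target correctly
  identified (all trials of the condition);
* absolute localization error — mean Euclidean distance between response
  and target location, in screen fractions;
* identification time and localization time — mean times in seconds.

Error and times are computed over correctly identified trials only: the
task defines the times for "the correct object", and the same convention is
applied to localization error for coherence. The cumulative value of a
metric is the unweighted mean of its four condition values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import TrialResponse
from .task_design import CONDITIONS, TrialSpec

Trials = list[tuple[TrialSpec, TrialResponse]]

#: Cumulative metric column order used throughout the pipeline.
BASIC_METRICS = (
    "identification_accuracy",
    "abs_localization_error",
    "identification_time",
    "localization_time",
)


@dataclass(frozen=True)
class ConditionMetrics:
    set_size: int
    delay_s: float
    identification_accuracy: float
    abs_localization_error: float  # nan when no correct trials
    identification_time_s: float
    localization_time_s: float
    n_trials: int
    n_correct: int


def identification_accuracy(trials: Trials) -> float:
    """Proportion of trials with the target correctly identified."""
    if not trials:
        raise ValueError("identification_accuracy needs at least one trial")
    return sum(r.identified_target for _, r in trials) / len(trials)


def _correct(trials: Trials) -> Trials:
    return [(t, r) for t, r in trials if r.identified_target]


def absolute_localization_error(trials: Trials) -> float:
    """Mean Euclidean response-to-target distance over correct trials."""
    correct = _correct(trials)
    if not correct:
        warnings.warn("no correctly identified trials; localization error missing")
        return float("nan")
    d = [
        float(np.hypot(
            r.response_location[0] - t.target_location[0],
            r.response_location[1] - t.target_location[1],
        ))
        for t, r in correct
    ]
    return float(np.mean(d))


def response_times(trials: Trials) -> tuple[float, float]:
    """(mean identification time, mean localization time) on correct trials."""
    correct = _correct(trials)
    if not correct:
        warnings.warn("no correctly identified trials; response times missing")
        return float("nan"), float("nan")
    return (
        float(np.mean([r.identification_time_s for _, r in correct])),
        float(np.mean([r.localization_time_s for _, r in correct])),
    )


def per_condition(trials: Trials) -> list[ConditionMetrics]:
    """Basic metrics grouped by the four (set size, delay) conditions.

    Conditions absent from the input are omitted from the result.
    """
    out = []
    for ss, dl in CONDITIONS:
        cell = [(t, r) for t, r in trials if t.set_size == ss and t.delay_s == dl]
        if not cell:
            continue
        acc = identification_accuracy(cell)
        n_correct = sum(r.identified_target for _, r in cell)
        if n_correct:
            err = absolute_localization_error(cell)
            t_id, t_loc = response_times(cell)
        else:
            err = t_id = t_loc = float("nan")
        out.append(
            ConditionMetrics(ss, dl, acc, err, t_id, t_loc, len(cell), n_correct)
        )
    return out


def cumulative(condition_metrics: list[ConditionMetrics]) -> dict[str, float]:
    """Unweighted mean of each basic metric across the four conditions.

    A condition with a missing value (no correct trials) propagates NaN,
    with a warning, rather than silently reweighting the mean.
    """
    if not condition_metrics:
        raise ValueError("cumulative needs at least one condition")
    fields = {
        "identification_accuracy": [m.identification_accuracy for m in condition_metrics],
        "abs_localization_error": [m.abs_localization_error for m in condition_metrics],
        "identification_time": [m.identification_time_s for m in condition_metrics],
        "localization_time": [m.localization_time_s for m in condition_metrics],
    }
    out = {}
    for name, vals in fields.items():
        if np.any(np.isnan(vals)):
            warnings.warn(f"missing condition value propagates into cumulative {name}")
        out[name] = float(np.mean(vals))
    return out


def basic_metric_set(trials: Trials) -> dict[str, float]:
    """The four cumulative basic metrics for one participant-session."""
    return cumulative(per_condition(trials))
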