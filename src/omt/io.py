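"""Flat-file formats for cohorts and metric tables.

Two CSV tables carry a cohort: ``participants.csv`` (one row per
participant-session: group, demographics, ACE, HV and — for simulated
cohorts — the latent ground truth) and ``trials.csv`` (one row per trial:
schedule fields plus the behavioural response). Both round-trip losslessly
through :func:`cohort_to_tables` / :func:`tables_to_cohort`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import ParticipantRecord, TrialResponse
from .metrics import basic_metric_set, per_condition
from .mixture import participant_mixture
from .task_design import records_to_schedule, schedule_to_records

PARTICIPANT_COLUMNS = [
    "participant_id", "group", "age", "gender", "education", "session",
    "ace", "hv_mm3", "true_severity",
]

RESPONSE_COLUMNS = [
    "identified_target", "response_x", "response_y",
    "identification_time_s", "localization_time_s", "true_component",
]


def cohort_to_tables(
    records: list[ParticipantRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten ParticipantRecords into (participants, trials) DataFrames."""
    prows, trows = [], []
    for rec in records:
        prows.append(
            {
                "participant_id": rec.participant_id,
                "group": rec.group,
                "age": rec.age,
                "gender": rec.gender,
                "education": rec.education,
                "session": rec.session,
                "ace": rec.ace,
                "hv_mm3": rec.hv_mm3,
                "true_severity": rec.severity,
            }
        )
        sched_rows = schedule_to_records([t for t, _ in rec.trials])
        for row, (_, resp) in zip(sched_rows, rec.trials):
            trows.append(
                row
                | {
                    "participant_id": rec.participant_id,
                    "session": rec.session,
                    "identified_target": bool(resp.identified_target),
                    "response_x": resp.response_location[0],
                    "response_y": resp.response_location[1],
                    "identification_time_s": resp.identification_time_s,
                    "localization_time_s": resp.localization_time_s,
                    "true_component": resp.true_component,
                }
            )
    return pd.DataFrame(prows), pd.DataFrame(trows)


def tables_to_cohort(
    participants: pd.DataFrame, trials: pd.DataFrame
) -> list[ParticipantRecord]:
    """Rebuild ParticipantRecords from the two flat tables."""
    _validate_trials(trials)
    out = []
    grouped = trials.groupby(["participant_id", "session"], sort=False)
    for _, prow in participants.iterrows():
        key = (prow["participant_id"], prow["session"])
        sub = grouped.get_group(key)
        specs = records_to_schedule(sub.to_dict("records"))
        responses = [
            TrialResponse(
                identified_target=bool(r["identified_target"]),
                response_location=(float(r["response_x"]), float(r["response_y"])),
                identification_time_s=float(r["identification_time_s"]),
                localization_time_s=float(r["localization_time_s"]),
                true_component=str(r["true_component"]),
            )
            for _, r in sub.iterrows()
        ]
        ace = prow.get("ace")
        hv = prow.get("hv_mm3")
        sev = prow.get("true_severity")
        out.append(
            ParticipantRecord(
                participant_id=prow["participant_id"],
                group=prow["group"],
                age=float(prow["age"]),
                gender=prow["gender"],
                education=float(prow["education"]),
                session=int(prow["session"]),
                ace=None if pd.isna(ace) else float(ace),
                hv_mm3=None if pd.isna(hv) else float(hv),
                trials=list(zip(specs, responses)),
                severity=None if pd.isna(sev) else float(sev),
            )
        )
    return out


def _validate_trials(trials: pd.DataFrame) -> None:
    """Schema check with row-numbered diagnostics."""
    required = {
        "participant_id", "session", "trial_id", "block", "set_size", "delay_s",
        "target_index",
    } | set(RESPONSE_COLUMNS)
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trials table missing columns: {sorted(missing)}")
    bad_ss = ~trials["set_size"].isin([1, 3])
    if bad_ss.any():
        raise ValueError(
            f"invalid set_size at rows {trials.index[bad_ss].tolist()[:10]}"
        )
    for col in ("response_x", "response_y"):
        bad = (trials[col] < 0) | (trials[col] > 1)
        if bad.any():
            raise ValueError(
                f"{col} outside [0,1] at rows {trials.index[bad].tolist()[:10]}"
            )


def compute_metrics_table(
    records: list[ParticipantRecord],
    n_reps: int = 5000,
    seed: int = 0,
    exact: bool = False,
) -> pd.DataFrame:
    """One row per participant-session: covariates, the eight cumulative
    metrics, and per-condition columns (``<metric>_ss<set size>_d<delay>``).
    """
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(records))
    rows = []
    for rec, stream in zip(records, streams):
        rng = np.random.default_rng(stream)
        row: dict = {
            "participant_id": rec.participant_id,
            "group": rec.group,
            "session": rec.session,
            "age": rec.age,
            "gender": rec.gender,
            "education": rec.education,
            "ace": rec.ace,
            "hv_mm3": rec.hv_mm3,
        }
        row |= basic_metric_set(rec.trials)
        for cm in per_condition(rec.trials):
            tag = f"ss{cm.set_size}_d{int(cm.delay_s)}"
            row |= {
                f"identification_accuracy_{tag}": cm.identification_accuracy,
                f"abs_localization_error_{tag}": cm.abs_localization_error,
                f"identification_time_{tag}": cm.identification_time_s,
                f"localization_time_{tag}": cm.localization_time_s,
                f"n_trials_{tag}": cm.n_trials,
                f"n_correct_{tag}": cm.n_correct,
            }
        est = participant_mixture(rec.trials, n_reps=n_reps, rng=rng, exact=exact)
        if est is None:
            row |= {m: np.nan for m in
                    ("target_detection", "misbinding", "guessing", "imprecision")}
            row["n_trials_used"] = 0
        else:
            row |= {
                "target_detection": est.target_detection,
                "misbinding": est.misbinding,
                "guessing": est.guessing,
                "imprecision": est.imprecision,
                "n_trials_used": est.n_trials_used,
            }
            for (ss, dl), vals in est.by_condition.items():
                tag = f"ss{ss}_d{int(dl)}"
                for name in ("target_detection", "misbinding", "guessing", "imprecision"):
                    row[f"{name}_{tag}"] = vals[name]
        rows.append(row)
    return pd.DataFrame(rows)
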