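"""End-to-end orchestration: simulate -> score -> mixture -> stats -> classify.

All randomness flows from one root seed through named substreams
(schedule/responses, mixture, cross-validation), so re-running a config
reproduces the bundle bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import compare_feature_sets_per_class, fit_eval_classifier, pairwise_suite
from .cohort import GROUP_PRESETS, make_cohort
from .io import cohort_to_tables, compute_metrics_table
from .metrics import BASIC_METRICS
from .mixture import MIXTURE_METRICS
from .stats import ancova_groups, factorial_2x2, longitudinal_ancova, predict_decline

log = logging.getLogger("omt")

ALL_METRICS = tuple(BASIC_METRICS) + tuple(MIXTURE_METRICS)


@dataclass
class RunConfig:
    seed: int = 0
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {g: 20 for g in GROUP_PRESETS}
    )
    sessions: int = 1
    n_reps: int = 5000
    exact_mixture: bool = False
    cv_folds: int = 5
    outdir: str = "results/run"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**{k: v for k, v in d.items() if k in
                      {f.name for f in dataclasses.fields(cls)}})


def _substream(seed: int, name: str) -> int:
    tag = zlib.crc32(name.encode())  # stable across processes, unlike hash()
    return int(
        np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31)
    )


def cross_sectional_stats(table: pd.DataFrame) -> dict:
    """ANCOVA per cumulative metric plus the transdiagnostic 2x2 ANOVA."""
    base = table[table["session"] == 1]
    report: dict = {"ancova": {}, "factorial": {}}
    for metric in ALL_METRICS:
        res = ancova_groups(
            base[metric], base["group"], base[["age", "gender", "education"]],
            metric_name=metric,
        )
        report["ancova"][metric] = {
            "F": res.F,
            "p": res.p,
            "eta_squared": res.eta_squared,
            "pairwise": [dataclasses.asdict(c) for c in res.pairwise],
        }
        long_rows = []
        for ss in (1, 3):
            for dl in (1, 4):
                col = f"{metric}_ss{ss}_d{dl}"
                if col not in base:
                    continue
                for _, row in base.iterrows():
                    long_rows.append(
                        {
                            "participant_id": row["participant_id"],
                            "set_size": ss,
                            "delay_s": dl,
                            "value": row[col],
                        }
                    )
        if long_rows:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                effects = factorial_2x2(pd.DataFrame(long_rows))
            report["factorial"][metric] = [dataclasses.asdict(e) for e in effects]
    return report


def longitudinal_stats(table: pd.DataFrame) -> dict:
    """Group x Session models plus decline regressions per metric."""
    report: dict = {"group_by_session": {}, "decline": {}}
    base = table[table["session"] == 1].set_index("participant_id")
    follow = table[table["session"] == 2].set_index("participant_id")
    shared = base.index.intersection(follow.index)
    for metric in ALL_METRICS:
        res = longitudinal_ancova(table, metric)
        report["group_by_session"][metric] = {
            "terms": [dataclasses.asdict(t) for t in res.terms],
            "posthoc": [
                {"group": g, "t": t, "p_holm": p} for g, t, p in res.posthoc
            ],
            "n_participants": res.n_participants,
        }
        dec = predict_decline(
            base.loc[shared, metric],
            base.loc[shared, "ace"],
            follow.loc[shared, "ace"],
            predictor_name=metric,
        )
        report["decline"][metric] = dataclasses.asdict(dec)
    return report


def classification_report(table: pd.DataFrame, cv_folds: int, seed: int) -> dict:
    """Overall 4-class OMT-vs-ACE comparison and the pairwise suite."""
    base = table[table["session"] == 1]
    res_omt = fit_eval_classifier(base, "OMT", cv_folds=cv_folds, seed=seed)
    res_ace = fit_eval_classifier(base, "ACE", cv_folds=cv_folds, seed=seed)
    per_class = compare_feature_sets_per_class(res_ace, res_omt)
    report = {
        "overall": {
            "OMT": {"accuracy": res_omt.accuracy, "auc": res_omt.auc_per_class},
            "ACE": {"accuracy": res_ace.accuracy, "auc": res_ace.auc_per_class},
            "delong_ace_vs_omt": {
                c: {"auc_ace": r.auc_a, "auc_omt": r.auc_b, "Z": r.Z, "p": r.p}
                for c, r in per_class.items()
            },
        },
        "pairwise": [dataclasses.asdict(c) for c in pairwise_suite(
            base, cv_folds=cv_folds, seed=seed
        )],
    }
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the output bundle under config.outdir.

    Returns a dict of the in-memory artefacts (tables and reports).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("simulating cohort: %s, sessions=%d, seed=%d",
             config.n_per_group, config.sessions, config.seed)
    records = make_cohort(
        n_per_group=config.n_per_group,
        sessions=config.sessions,
        seed=_substream(config.seed, "cohort"),
    )
    participants, trials = cohort_to_tables(records)
    participants.to_csv(out / "participants.csv", index=False)
    trials.to_csv(out / "trials.csv", index=False)

    table = compute_metrics_table(
        records,
        n_reps=config.n_reps,
        seed=_substream(config.seed, "mixture"),
        exact=config.exact_mixture,
    )
    table.to_csv(out / "metrics.csv", index=False)
    mixture_cols = [
        "participant_id", "session", "target_detection", "misbinding",
        "guessing", "imprecision", "n_trials_used",
    ]
    mix = table[mixture_cols].copy()
    mix["n_reps"] = config.n_reps
    mix["seed"] = _substream(config.seed, "mixture")
    mix.to_csv(out / "mixture.csv", index=False)

    stats_report = cross_sectional_stats(table)
    if config.sessions == 2:
        stats_report["longitudinal"] = longitudinal_stats(table)
    (out / "stats_report.json").write_text(json.dumps(stats_report, indent=2))

    clf_report = classification_report(
        table, config.cv_folds, _substream(config.seed, "cv")
    )
    (out / "classification_report.json").write_text(json.dumps(clf_report, indent=2))

    (out / "manifest.json").write_text(json.dumps(asdict(config), indent=2))
    return {
        "participants": participants,
        "trials": trials,
        "metrics": table,
        "stats_report": stats_report,
        "classification_report": clf_report,
    }
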