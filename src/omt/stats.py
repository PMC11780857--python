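"""Group-comparison, factorial, longitudinal and correlation statistics.

The analyses mirror a standard clinical-stratification workflow:

* cross-sectional ANCOVA per cumulative metric with age, gender and
  education as covariates, Holm-corrected pairwise contrasts and partial
  eta squared;
* transdiagnostic 2 (set size) x 2 (delay) repeated-measures ANOVA with
  eta-squared magnitude classes (>0.01 small, >0.06 medium, >0.14 large);
* 4 (Group) x 2 (Session) ANCOVA with within-participant session factor;
* linear regression of one-year ACE change on baseline metrics;
* tests for equality of two dependent overlapping correlations
  (Hittner-May-Silver "h-test" default, Steiger's z selectable);
* linear model of hippocampal volume on a metric plus covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------- results

@dataclass(frozen=True)
class PairwiseContrast:
    group_a: str
    group_b: str
    t: float
    p_raw: float
    p_holm: float
    cohens_d: float


@dataclass(frozen=True)
class GroupComparisonResult:
    metric_name: str
    F: float
    p: float
    eta_squared: float  # partial eta squared for the group term
    pairwise: list[PairwiseContrast]


@dataclass(frozen=True)
class FactorialResult:
    effect_name: str  # set_size | delay | interaction
    F: float
    p: float
    eta_squared: float
    magnitude_class: str


@dataclass(frozen=True)
class LongitudinalTerm:
    effect_name: str  # group | session | interaction
    statistic: float
    df: float
    p: float


@dataclass(frozen=True)
class LongitudinalResult:
    metric_name: str
    terms: list[LongitudinalTerm]
    # per-group session contrast (paired t), Holm-adjusted across groups
    posthoc: list[tuple[str, float, float]]  # (group, t, p_holm)
    n_participants: int


@dataclass(frozen=True)
class DeclineRegressionResult:
    predictor_name: str
    slope: float
    t: float
    p: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class DependentCorrelationTest:
    r_jk: float
    r_jh: float
    r_kh: float
    n: int
    z: float
    p: float
    method: str


@dataclass(frozen=True)
class HVRegressionResult:
    metric_name: str
    slope: float
    t: float
    p: float
    r_squared_model: float  # overall model fit
    n: int


# ---------------------------------------------------------------- helpers

def encode_gender(g: pd.Series) -> pd.Series:
    """Binary indicator (F=1, M=0); numeric input passes through."""
    if g.dtype.kind in "ifb":
        return g.astype(float)
    return g.map({"M": 0.0, "F": 1.0}).astype(float)


def _check_full_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(np.asarray(X, dtype=float))
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank-deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns among: {list(X.columns)}"
        )


def classify_eta_squared(eta2: float) -> str:
    if eta2 > 0.14:
        return "large"
    if eta2 > 0.06:
        return "medium"
    if eta2 > 0.01:
        return "small"
    return "negligible"


def holm_adjust(p_values) -> np.ndarray:
    """Step-down Holm adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def cohens_d(a, b) -> float:
    """Standardized mean difference with pooled SD (raw scale)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    return float((a.mean() - b.mean()) / sp) if sp > 0 else float("nan")


def _prep_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    cov = covariates.copy()
    if "gender" in cov:
        cov["gender"] = encode_gender(cov["gender"])
    return cov


# ---------------------------------------------------------------- ANCOVA

def ancova_groups(
    metric,
    group,
    covariates: pd.DataFrame,
    metric_name: str = "metric",
) -> GroupComparisonResult:
    """ANCOVA of a cumulative metric on group with demographic covariates.

    Fits metric ~ group + age + gender + education, reports the omnibus
    group F with partial eta squared, and all pairwise covariate-adjusted
    group contrasts with Holm correction and (covariate-unadjusted,
    pooled-SD) Cohen's d.
    """
    df = pd.DataFrame(
        {"metric": np.asarray(metric, float), "group": np.asarray(group)}
    ).join(_prep_covariates(covariates.reset_index(drop=True)))
    df = df.dropna()
    levels = sorted(df["group"].unique())
    if len(levels) < 2:
        raise ValueError("ancova_groups needs >= 2 groups")
    if len(df) <= len(levels) + covariates.shape[1]:
        raise ValueError("too few observations for the design")

    model = smf.ols("metric ~ C(group) + age + gender + education", data=df)
    _check_full_rank(pd.DataFrame(model.exog, columns=model.exog_names))
    res = model.fit()
    aov = anova_lm(res, typ=2)
    ss_group = float(aov.loc["C(group)", "sum_sq"])
    ss_resid = float(aov.loc["Residual", "sum_sq"])

    # Pairwise covariate-adjusted contrasts from the full model.
    contrasts = []
    names = res.model.exog_names
    raw_p, rows = [], []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            vec = np.zeros(len(names))
            for j, nm in enumerate(names):
                if nm == f"C(group)[T.{a}]":
                    vec[j] = 1.0
                elif nm == f"C(group)[T.{b}]":
                    vec[j] = -1.0
            tt = res.t_test(vec)
            raw_p.append(float(np.squeeze(tt.pvalue)))
            rows.append((a, b, float(np.squeeze(tt.tvalue))))
    p_holm = holm_adjust(raw_p)
    for (a, b, t), pr, ph in zip(rows, raw_p, p_holm):
        d = cohens_d(
            df.loc[df["group"] == a, "metric"], df.loc[df["group"] == b, "metric"]
        )
        contrasts.append(PairwiseContrast(a, b, t, pr, float(ph), d))

    return GroupComparisonResult(
        metric_name=metric_name,
        F=float(aov.loc["C(group)", "F"]),
        p=float(aov.loc["C(group)", "PR(>F)"]),
        eta_squared=ss_group / (ss_group + ss_resid),
        pairwise=contrasts,
    )


# ------------------------------------------------------- 2x2 factorial

def factorial_2x2(
    long_df: pd.DataFrame,
    dv: str = "value",
    subject: str = "participant_id",
) -> list[FactorialResult]:
    """Repeated-measures 2 (set size) x 2 (delay) ANOVA on condition values.

    `long_df` holds one row per participant x condition with columns
    [subject, set_size, delay_s, dv]. Participants missing any cell are
    dropped with a warning. When only one set size is present (misbinding,
    defined for 3-item conditions only) a one-way repeated-measures ANOVA
    on delay is returned.
    """
    import pingouin as pg

    df = long_df.dropna(subset=[dv]).copy()
    cells_per = df.groupby(subject)[["set_size", "delay_s"]].nunique()
    n_cells = df["set_size"].nunique() * df["delay_s"].nunique()
    complete = df.groupby(subject).size() == n_cells
    incomplete = complete.index[~complete]
    if len(incomplete):
        warnings.warn(f"dropping {len(incomplete)} participants with missing cells")
        df = df[~df[subject].isin(incomplete)]
    del cells_per

    if df["set_size"].nunique() == 1:
        aov = pg.rm_anova(
            data=df, dv=dv, within="delay_s", subject=subject, detailed=True,
            effsize="np2",
        )
        row = aov[aov["Source"] == "delay_s"].iloc[0]
        eta2 = float(row["np2"])
        return [
            FactorialResult(
                "delay", float(row["F"]), float(row["p_unc"]), eta2,
                classify_eta_squared(eta2),
            )
        ]

    aov = pg.rm_anova(
        data=df, dv=dv, within=["set_size", "delay_s"], subject=subject,
        detailed=True, effsize="np2",
    )
    out = []
    mapping = {
        "set_size": "set_size",
        "delay_s": "delay",
        "set_size * delay_s": "interaction",
    }
    for src, name in mapping.items():
        row = aov[aov["Source"] == src].iloc[0]
        eta2 = float(row["np2"])
        out.append(
            FactorialResult(
                name, float(row["F"]), float(row["p_unc"]), eta2,
                classify_eta_squared(eta2),
            )
        )
    return out


# ---------------------------------------------------- longitudinal

def longitudinal_ancova(
    data: pd.DataFrame,
    metric: str,
    metric_name: str | None = None,
) -> LongitudinalResult:
    """4 (Group) x 2 (Session) ANCOVA with a within-participant session.

    `data` holds one row per participant-session with columns
    [participant_id, group, session, age, gender, education, <metric>].
    Fit as a linear mixed model with a random intercept per participant;
    Wald tests for the Group, Session and Group x Session terms. Post hoc:
    per-group paired t-tests across sessions, Holm-adjusted.
    """
    df = data.dropna(subset=[metric]).copy()
    df["gender"] = encode_gender(df["gender"])
    if df["session"].nunique() < 2:
        raise ValueError("longitudinal analysis needs two sessions")
    counts = df.groupby("participant_id")["session"].nunique()
    keep = counts.index[counts == 2]
    dropped = counts.size - keep.size
    if dropped:
        warnings.warn(f"dropping {dropped} participants without both sessions")
    df = df[df["participant_id"].isin(keep)]

    model = smf.mixedlm(
        f"{metric} ~ C(group) * C(session) + age + gender + education",
        data=df,
        groups=df["participant_id"],
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False)

    def _joint_test(pattern_check) -> LongitudinalTerm | None:
        names = [n for n in res.model.exog_names if pattern_check(n)]
        if not names:
            return None
        K = np.zeros((len(names), len(res.model.exog_names)))
        for i, nm in enumerate(names):
            K[i, res.model.exog_names.index(nm)] = 1.0
        # pad for random-effects params
        K_full = np.hstack([K, np.zeros((len(names), len(res.params) - K.shape[1]))])
        wt = res.wald_test(K_full, scalar=True)
        return (float(wt.statistic), float(len(names)), float(wt.pvalue))

    terms = []
    specs = {
        "group": lambda n: n.startswith("C(group)") and ":" not in n,
        "session": lambda n: n.startswith("C(session)") and ":" not in n,
        "interaction": lambda n: ":" in n and "C(group)" in n and "C(session)" in n,
    }
    for name, check in specs.items():
        stat = _joint_test(check)
        if stat is not None:
            terms.append(LongitudinalTerm(name, stat[0], stat[1], stat[2]))

    # Post hoc: session contrast within each group, paired on participant.
    groups = sorted(df["group"].unique())
    raw = []
    tvals = []
    for g in groups:
        sub = df[df["group"] == g].pivot_table(
            index="participant_id", columns="session", values=metric
        ).dropna()
        t, p = sps.ttest_rel(sub[2], sub[1])
        raw.append(float(p))
        tvals.append(float(t))
    adj = holm_adjust(raw)
    posthoc = [(g, t, float(p)) for g, t, p in zip(groups, tvals, adj)]

    return LongitudinalResult(
        metric_name=metric_name or metric,
        terms=terms,
        posthoc=posthoc,
        n_participants=int(df["participant_id"].nunique()),
    )


# ------------------------------------------------ decline prediction

def predict_decline(
    baseline_metric,
    ace_t0,
    ace_t1,
    predictor_name: str = "metric",
) -> DeclineRegressionResult:
    """Regress one-year ACE change (t1 - t0) on a baseline metric."""
    x = np.asarray(baseline_metric, float)
    delta = np.asarray(ace_t1, float) - np.asarray(ace_t0, float)
    ok = ~(np.isnan(x) | np.isnan(delta))
    x, delta = x[ok], delta[ok]
    if len(x) < 3:
        raise ValueError("predict_decline needs >= 3 paired observations")
    X = sm.add_constant(x)
    res = sm.OLS(delta, X).fit()
    return DeclineRegressionResult(
        predictor_name=predictor_name,
        slope=float(res.params[1]),
        t=float(res.tvalues[1]),
        p=float(res.pvalues[1]),
        r_squared=float(res.rsquared),
        n=len(x),
    )


# -------------------------------- dependent overlapping correlations

def compare_dependent_overlapping_correlations(
    r_jk: float,
    r_jh: float,
    r_kh: float,
    n: int,
    method: str = "hittner_h",
) -> DependentCorrelationTest:
    """Test H0: rho_jk = rho_jh for correlations sharing variable j.

    Fisher-z based statistic accounting for the correlation r_kh between
    the two non-shared variables. `hittner_h` (default) uses the
    backtransformed average of the two Fisher z's in the covariance term;
    `steiger_z` uses the plain average correlation.
    """
    for r in (r_jk, r_jh, r_kh):
        if not (-1.0 < r < 1.0):
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n <= 3:
        raise ValueError("n must exceed 3")
    z_jk, z_jh = np.arctanh(r_jk), np.arctanh(r_jh)
    if method == "hittner_h":
        r_m = float(np.tanh((z_jk + z_jh) / 2.0))
    elif method == "steiger_z":
        r_m = (r_jk + r_jh) / 2.0
    else:
        raise ValueError(f"unknown method {method!r}")
    c = (
        r_kh * (1.0 - 2.0 * r_m**2)
        - 0.5 * r_m**2 * (1.0 - 2.0 * r_m**2 - r_kh**2)
    ) / (1.0 - r_m**2) ** 2
    z = (z_jk - z_jh) * np.sqrt((n - 3.0) / (2.0 - 2.0 * c))
    p = 2.0 * sps.norm.sf(abs(z))
    return DependentCorrelationTest(
        r_jk=r_jk, r_jh=r_jh, r_kh=r_kh, n=n,
        z=float(z), p=float(p), method=method,
    )


# ------------------------------------------------------ HV regression

def glm_hv(
    hv,
    metric,
    covariates: pd.DataFrame,
    metric_name: str = "metric",
) -> HVRegressionResult:
    """Linear model HV ~ metric + age + gender + education.

    Reports the metric's t and p (its contribution to the regression) and
    the overall model R^2.
    """
    df = pd.DataFrame({"hv": np.asarray(hv, float), "m": np.asarray(metric, float)})
    df = df.join(_prep_covariates(covariates.reset_index(drop=True))).dropna()
    model = smf.ols("hv ~ m + age + gender + education", data=df)
    _check_full_rank(pd.DataFrame(model.exog, columns=model.exog_names))
    res = model.fit()
    return HVRegressionResult(
        metric_name=metric_name,
        slope=float(res.params["m"]),
        t=float(res.tvalues["m"]),
        p=float(res.pvalues["m"]),
        r_squared_model=float(res.rsquared),
        n=len(df),
    )
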