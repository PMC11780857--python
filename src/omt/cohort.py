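"""Generative simulator of task behaviour for four clinical strata.

Responses follow a mixture model mirroring the analysis: on each trial the
participant first identifies the probed item (Bernoulli, condition-specific
accuracy); given correct identification the placed location comes from one
of three sources — the target location plus isotropic Gaussian imprecision,
the location of another in-trial item plus the same imprecision (misbinding,
only possible with >= 2 items), or a uniform guess over the placement
region. Response times are lognormal.

Cohorts span the four strata EHC / SCD / MCI / AD. A latent severity score
per participant drives (a) jitter of the task parameters around the group
preset, (b) the ACE screening score and (c) hippocampal volume, so that
task metrics, ACE and HV are mutually correlated by construction. Two-
session cohorts apply an additive per-session drift to (p_target, sigma,
p_identify) and a severity-linked ACE decline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .task_design import (
    CONDITIONS,
    DEFAULT_MARGIN,
    TrialSpec,
    make_session_schedule,
)

GROUPS = ("EHC", "SCD", "MCI", "AD")

Condition = tuple[int, float]


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class SessionDrift:
    """Additive per-session change applied at session 2."""

    d_p_target: float = 0.0
    d_sigma: float = 0.0
    d_p_identify: float = 0.0


@dataclass(frozen=True)
class GenerativeParams:
    """Ground-truth behaviour of one simulated participant (or group preset).

    Mixture weights are conditional on correct identification; sigma is the
    SD of the isotropic Gaussian localization noise in screen fractions.
    """

    p_target: float
    p_misbind: float
    p_guess: float
    sigma: float
    p_identify: dict[Condition, float]
    rt_ident_mu: float = 0.40
    rt_ident_sigma: float = 0.35
    rt_loc_mu: float = 0.95
    rt_loc_sigma: float = 0.35
    session_drift: SessionDrift = field(default_factory=SessionDrift)

    def __post_init__(self) -> None:
        probs = (self.p_target, self.p_misbind, self.p_guess)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError(f"mixture weights outside [0,1]: {probs}")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValueError(f"mixture weights must sum to 1, got {sum(probs)!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        for cond, p in self.p_identify.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"p_identify[{cond}]={p} outside [0,1]")

    def with_drift(self) -> "GenerativeParams":
        """Session-2 parameters: additive drift, mass renormalized."""
        d = self.session_drift
        p_t = min(max(self.p_target + d.d_p_target, 1e-6), 1.0 - 1e-6)
        rest = 1.0 - p_t
        old_rest = self.p_misbind + self.p_guess
        if old_rest > 0:
            p_m = self.p_misbind * rest / old_rest
            p_g = self.p_guess * rest / old_rest
        else:
            p_m, p_g = 0.0, rest
        return replace(
            self,
            p_target=p_t,
            p_misbind=p_m,
            p_guess=p_g,
            sigma=max(self.sigma + d.d_sigma, 1e-4),
            p_identify={
                c: min(max(p + d.d_p_identify, 0.0), 1.0)
                for c, p in self.p_identify.items()
            },
        )


def _ident_table(p11: float, p14: float, p31: float, p34: float) -> dict[Condition, float]:
    return {(1, 1.0): p11, (1, 4.0): p14, (3, 1.0): p31, (3, 4.0): p34}


#: Group presets, ordered by designed disease severity: target detection and
#: identification accuracy fall, misbinding/guessing/imprecision rise, and
#: response times lengthen from EHC through AD. These are synthesis settings
#: for the simulator, not estimates from any real cohort.
GROUP_PRESETS: dict[str, GenerativeParams] = {
    "EHC": GenerativeParams(
        0.80, 0.08, 0.12, 0.040, _ident_table(0.98, 0.96, 0.92, 0.89),
        rt_ident_mu=0.34, rt_loc_mu=0.92,
    ),
    "SCD": GenerativeParams(
        0.78, 0.09, 0.13, 0.045, _ident_table(0.97, 0.95, 0.90, 0.87),
        rt_ident_mu=0.36, rt_loc_mu=0.94,
    ),
    "MCI": GenerativeParams(
        0.68, 0.14, 0.18, 0.055, _ident_table(0.93, 0.90, 0.82, 0.78),
        rt_ident_mu=0.42, rt_loc_mu=1.00,
    ),
    "AD": GenerativeParams(
        0.55, 0.18, 0.27, 0.070, _ident_table(0.86, 0.82, 0.70, 0.65),
        rt_ident_mu=0.64, rt_loc_mu=1.20,
        # One year of dementia progression: localization noise and target
        # loss worsen alongside identification, sized so the planted
        # decline is detectable at a two-session study's scale.
        session_drift=SessionDrift(d_p_target=-0.04, d_sigma=0.05, d_p_identify=-0.03),
    ),
}

#: Latent severity means per group (SD 1.0 within group, so adjacent strata
#: overlap the way clinical cohorts do).
SEVERITY_MEANS = {"EHC": 0.0, "SCD": 0.6, "MCI": 1.6, "AD": 3.2}
SEVERITY_SD = 1.0


@dataclass(frozen=True)
class SeverityLink:
    """Linear links from latent severity to ACE and hippocampal volume."""

    ace_intercept: float = 93.0
    ace_slope: float = 6.0
    ace_noise_sd: float = 3.0
    hv_intercept: float = 8000.0  # bilateral head-size-corrected, mm^3
    hv_slope: float = 450.0
    hv_noise_sd: float = 500.0
    hv_floor: float = 3000.0
    decline_intercept: float = 0.5  # ACE points lost per year at severity 0
    decline_slope: float = 1.2
    decline_noise_sd: float = 2.0


def latent_severity_link(
    severity: float,
    link: SeverityLink | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Map latent severity to (ACE score, hippocampal volume in mm^3)."""
    link = link or SeverityLink()
    ace = link.ace_intercept - link.ace_slope * severity
    hv = link.hv_intercept - link.hv_slope * severity
    if rng is not None:
        ace += rng.normal(0.0, link.ace_noise_sd)
        hv += rng.normal(0.0, link.hv_noise_sd)
    return float(np.clip(ace, 0.0, 100.0)), float(max(hv, link.hv_floor))


@dataclass(frozen=True)
class CovariateModel:
    """Demographics per group; SCD youngest so covariate adjustment matters."""

    age_means: dict[str, float] = field(
        default_factory=lambda: {"EHC": 68.0, "SCD": 64.0, "MCI": 71.0, "AD": 73.0}
    )
    age_sd: float = 7.0
    education_mean: float = 14.0
    education_sd: float = 3.0
    p_female: float = 0.5

    def sample(self, group: str, rng: np.random.Generator) -> tuple[float, str, float]:
        age = float(np.clip(rng.normal(self.age_means[group], self.age_sd), 45, 95))
        gender = "F" if rng.random() < self.p_female else "M"
        edu = float(np.clip(rng.normal(self.education_mean, self.education_sd), 6, 24))
        return age, gender, edu


@dataclass(frozen=True)
class TrialResponse:
    """Simulated behaviour on one trial, with ground-truth bookkeeping."""

    identified_target: bool
    response_location: tuple[float, float]
    identification_time_s: float
    localization_time_s: float
    true_component: str  # target | misbind | guess | none

    def __post_init__(self) -> None:
        x, y = self.response_location
        if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
            raise ValueError("response_location outside screen")
        if self.identification_time_s <= 0 or self.localization_time_s <= 0:
            raise ValueError("response times must be positive")


@dataclass
class ParticipantRecord:
    participant_id: str
    group: str
    age: float
    gender: str
    education: float
    session: int
    ace: float | None
    hv_mm3: float | None
    trials: list[tuple[TrialSpec, TrialResponse]]
    severity: float | None = None
    params: GenerativeParams | None = None


def _truncated_gaussian_2d(
    centre: tuple[float, float], sigma: float, rng: np.random.Generator
) -> tuple[float, float]:
    # Truncation to the screen handled by resampling.
    for _ in range(10_000):
        x, y = rng.normal(centre, sigma, size=2)
        if 0.0 <= x <= 1.0 and 0.0 <= y <= 1.0:
            return float(x), float(y)
    raise RuntimeError("truncated Gaussian resampling budget exhausted")


def sample_response(
    trial: TrialSpec,
    params: GenerativeParams,
    rng: np.random.Generator,
    *,
    margin: float = DEFAULT_MARGIN,
) -> TrialResponse:
    """Simulate one trial's behaviour under the generative mixture.

    At set size 1 misbinding is impossible (it needs >= 2 objects); its mass
    is reallocated proportionally to the target and guess components.
    """
    cond = (trial.set_size, trial.delay_s)
    if cond not in params.p_identify:
        raise ValueError(f"no p_identify entry for condition {cond}")
    identified = bool(rng.random() < params.p_identify[cond])

    lo, hi = margin, 1.0 - margin
    if not identified:
        component = "none"
        loc = (float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi)))
    else:
        w = np.array([params.p_target, params.p_misbind, params.p_guess])
        if trial.set_size == 1:
            w[1] = 0.0  # misbinding requires at least two objects
            w = w / w.sum()
        component = ("target", "misbind", "guess")[
            int(rng.choice(3, p=w))
        ]
        if component == "target":
            loc = _truncated_gaussian_2d(trial.target_location, params.sigma, rng)
        elif component == "misbind":
            ds = trial.distractor_locations
            centre = ds[int(rng.integers(len(ds)))]
            loc = _truncated_gaussian_2d(centre, params.sigma, rng)
        else:
            loc = (float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi)))

    t_ident = float(rng.lognormal(params.rt_ident_mu, params.rt_ident_sigma))
    t_loc = float(rng.lognormal(params.rt_loc_mu, params.rt_loc_sigma))
    return TrialResponse(identified, loc, t_ident, t_loc, component)


def _jitter_params(
    preset: GenerativeParams, severity_c: float, rng: np.random.Generator
) -> GenerativeParams:
    """Individual parameters: severity-linked logistic-scale perturbation.

    severity_c is the participant's severity centred on the group mean, so
    jitter creates within-group correlation with ACE / HV without moving
    the group-level means.
    """
    logits = np.log([preset.p_target, preset.p_misbind, preset.p_guess])
    logits += np.array([-0.5, 0.3, 0.3]) * severity_c
    logits += rng.normal(0.0, 0.35, size=3)
    w = np.exp(logits)
    w /= w.sum()
    sigma = preset.sigma * math.exp(0.15 * severity_c + rng.normal(0.0, 0.25))
    ident_shift = -0.35 * severity_c + rng.normal(0.0, 0.40)
    p_ident = {
        c: _expit(_logit(min(max(p, 1e-4), 1 - 1e-4)) + ident_shift)
        for c, p in preset.p_identify.items()
    }
    return replace(
        preset,
        p_target=float(w[0]),
        p_misbind=float(w[1]),
        p_guess=float(w[2]),
        sigma=float(sigma),
        p_identify=p_ident,
        rt_ident_mu=preset.rt_ident_mu + 0.05 * severity_c + rng.normal(0.0, 0.05),
        rt_loc_mu=preset.rt_loc_mu + 0.05 * severity_c + rng.normal(0.0, 0.05),
    )


def make_cohort(
    group_presets: dict[str, GenerativeParams] | None = None,
    n_per_group: dict[str, int] | int = 20,
    covariate_model: CovariateModel | None = None,
    sessions: int = 1,
    seed: int = 0,
    *,
    severity_link: SeverityLink | None = None,
    schedule_kwargs: dict | None = None,
) -> list[ParticipantRecord]:
    """Simulate a multi-group cohort; one ParticipantRecord per session.

    Each participant gets an independent seeded schedule per session;
    session 2 (if requested) applies the preset's session drift to the task
    parameters and a severity-linked decline to ACE.
    """
    presets = group_presets or GROUP_PRESETS
    if isinstance(n_per_group, int):
        n_per_group = {g: n_per_group for g in presets}
    for g, n in n_per_group.items():
        if g not in presets:
            raise ValueError(f"no preset for group {g!r}")
        if n < 1:
            raise ValueError(f"n_per_group[{g!r}] must be >= 1")
    if sessions not in (1, 2):
        raise ValueError("sessions must be 1 or 2")
    cov = covariate_model or CovariateModel()
    link = severity_link or SeverityLink()
    sched_kw = schedule_kwargs or {}

    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(sum(n_per_group.values())))
    records: list[ParticipantRecord] = []
    for group in n_per_group:
        preset = presets[group]
        for i in range(n_per_group[group]):
            rng = np.random.default_rng(next(children))
            pid = f"{group}{i:03d}"
            severity = float(
                rng.normal(SEVERITY_MEANS.get(group, 0.0), SEVERITY_SD)
            )
            severity_c = severity - SEVERITY_MEANS.get(group, 0.0)
            age, gender, edu = cov.sample(group, rng)
            params = _jitter_params(preset, severity_c, rng)
            ace, hv = latent_severity_link(severity, link, rng)

            ace_by_session = {1: ace}
            if sessions == 2:
                decline = link.decline_intercept + link.decline_slope * severity
                decline += rng.normal(0.0, link.decline_noise_sd)
                ace_by_session[2] = float(np.clip(ace - decline, 0.0, 100.0))

            for session in range(1, sessions + 1):
                p = params if session == 1 else params.with_drift()
                _, test = make_session_schedule(rng, **sched_kw)
                trials = [(tr, sample_response(tr, p, rng)) for tr in test]
                records.append(
                    ParticipantRecord(
                        participant_id=pid,
                        group=group,
                        age=age,
                        gender=gender,
                        education=edu,
                        session=session,
                        ace=ace_by_session[session],
                        hv_mm3=hv,
                        trials=trials,
                        severity=severity,
                        params=p,
                    )
                )
    return records
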