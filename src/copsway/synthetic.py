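"""Synthetic stabilometric cohort with a known psychometric structure.

No public COP dataset exists for the population of interest (ambulatory,
motor-incomplete spinal cord injury), so every downstream statistic is
exercised against a simulated cohort whose ground truth is known:

* Each subject stands on a virtual platform under up to four conditions
  (vision OE/CE x support base OF/CF) for repeated 51.2 s trials.
* Sway is a stationary Ornstein-Uhlenbeck process per axis (laterolateral,
  anteroposterior), discretised exactly, so stationary variance and hence
  the expected 90 %-ellipse area are available in closed form.
* A subject's sway magnitude is a log-normal random effect with nested
  session-level and trial-level log-normal perturbations; condition effects
  are scalar multipliers (closed eyes inflate sway, feet-together is a
  near-null factor).  The design-implied intraclass correlation of
  log-sway across sessions is therefore closed form:
  tau^2 / (tau^2 + sigma_session^2).
* Clinical balance scales (BBS, Tinetti equilibrium/locomotion, WISCI) are
  monotone decreasing functions of the session-level log sway plus bounded
  rounded noise; demographics are independent of sway by construction.
* Heel distance declines slowly over calendar time and is weakly coupled
  to sway magnitude.
* Harder conditions drop out at the low-ability end of the cohort, and the
  dropout pattern is fixed per subject across sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError
from .metrics import METRIC_NAMES, COPTrajectory, compute_metrics_batch

__all__ = [
    "OUParams",
    "ScaleModel",
    "SubjectProfile",
    "StudyDesign",
    "SimulatedStudy",
    "DEFAULT_OU",
    "DEFAULT_SCALE_MODELS",
    "CONDITIONS",
    "simulate_trial",
    "simulate_study",
]

#: canonical condition order: (vision, support)
CONDITIONS = (("OE", "OF"), ("CE", "OF"), ("OE", "CF"), ("CE", "CF"))


@dataclass(frozen=True)
class OUParams:
    """Ornstein-Uhlenbeck sway process, one (theta, sigma) pair per axis.

    ``theta`` is the mean-reversion rate in 1/s and ``sigma`` the diffusion
    scale in mm/sqrt(s), ordered (laterolateral, anteroposterior).  The
    stationary SD per axis is sigma / sqrt(2 theta).
    """

    theta: tuple[float, float] = (1.0, 0.8)
    sigma: tuple[float, float] = (5.0, 5.7)

    def __post_init__(self) -> None:
        if any(th <= 0 for th in self.theta):
            raise InvalidArgumentError("theta must be positive")
        if any(s < 0 for s in self.sigma):
            raise InvalidArgumentError("sigma must be non-negative")

    def stationary_sd(self) -> tuple[float, float]:
        return tuple(
            s / math.sqrt(2.0 * th) for s, th in zip(self.sigma, self.theta)
        )


#: OU parameters giving ~3.5 mm (LL) and ~4.5 mm (AP) stationary sway SD,
#: i.e. a 90 % ellipse of a few cm^2, typical of impaired stance
DEFAULT_OU = OUParams()


@dataclass(frozen=True)
class ScaleModel:
    """Linear-latent model of one ordinal clinical scale.

    score = clip(round(center - slope * log_sway + e_subj + e_sess),
                 minimum, maximum)

    where log_sway is the session-level log sway offset (subject + session
    random effects), ``e_subj`` is a stable per-subject deviation (drawn
    once) and ``e_sess`` per-session rater/administration noise.  The slope
    and total noise set the scale's expected validity correlation; the
    subject/session split sets its test-retest reliability (clinically
    stable cohorts score nearly the same two weeks apart, so most noise is
    subject-level).
    """

    name: str
    minimum: int
    maximum: int
    center: float
    slope: float
    noise_sd_subject: float
    noise_sd_session: float

    @property
    def total_noise_sd(self) -> float:
        return math.hypot(self.noise_sd_subject, self.noise_sd_session)


# Centres put the cohort in the upper half of each range (ambulatory
# subjects); slopes/noises chosen for strong BBS coupling, moderate
# equilibrium-subscale coupling and weak locomotion/WISCI coupling.
DEFAULT_SCALE_MODELS = (
    ScaleModel("bbs", 0, 56, center=44.0, slope=12.0,
               noise_sd_subject=5.0, noise_sd_session=2.3),
    ScaleModel("ts_e", 0, 24, center=17.0, slope=5.0,
               noise_sd_subject=2.4, noise_sd_session=1.4),
    ScaleModel("ts_l", 0, 16, center=12.0, slope=1.6,
               noise_sd_subject=2.5, noise_sd_session=1.7),
    ScaleModel("wisci", 0, 20, center=16.0, slope=1.2,
               noise_sd_subject=2.1, noise_sd_session=1.4),
)


@dataclass(frozen=True)
class SubjectProfile:
    """One simulated subject."""

    subject_id: str
    latent_ability: float  # standard-normal; higher = better balance
    base_sway_scale: float  # multiplier on the OU diffusion scale
    heel_distance_baseline: float  # cm
    heel_distance_slope: float  # cm/day, typically <= 0
    age: float
    height: float
    weight: float
    sex: str  # 'M' or 'F'
    drop_ce: bool = False
    drop_cf: bool = False

    def __post_init__(self) -> None:
        if self.base_sway_scale <= 0:
            raise InvalidArgumentError("base_sway_scale must be positive")
        if self.heel_distance_baseline <= 0:
            raise InvalidArgumentError("heel_distance_baseline must be positive")


@dataclass(frozen=True)
class StudyDesign:
    """Cohort-simulation parameter set.

    Defaults emulate the study conditions the pipeline is meant for: 23
    subjects assessed 1-12 times (~111 sessions in total) about 14 days
    apart, four vision x support conditions per session with harder
    conditions dropped by low-ability subjects, and 3 recorded trials of
    51.2 s per condition.
    """

    n_subjects: int = 23
    sessions_per_subject: int | tuple[int, ...] | None = None
    intersession_days: float = 14.0
    trials_per_condition: int = 3
    trial_duration: float = 51.2
    sampling_rate: float = 50.0
    subject_sd_log_sway: float = 0.5
    session_sd_log_sway: float = 0.15
    trial_sd_log_sway: float = 0.1
    ce_multiplier: float = 1.6
    cf_multiplier: float = 1.0
    dropout_prob_ce: float = 0.13
    dropout_prob_cf: float = 0.35
    single_session_frac: float = 6.0 / 23.0
    max_sessions: int = 12
    scale_models: tuple[ScaleModel, ...] = DEFAULT_SCALE_MODELS
    hd_mean: float = 20.0
    hd_between_sd: float = 3.0
    hd_sway_coupling: float = 2.0  # cm per subject log-sway SD
    hd_slope_mean: float = -0.02  # cm/day
    hd_slope_sd: float = 0.005
    hd_session_noise: float = 0.5
    ou: OUParams = DEFAULT_OU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidArgumentError("n_subjects must be >= 1")
        if self.trials_per_condition < 2:
            raise InvalidArgumentError(
                "trials_per_condition must be >= 2 (CV needs >= 2 values)"
            )
        if self.trial_duration <= 0 or self.sampling_rate <= 0:
            raise InvalidArgumentError("duration and sampling rate must be positive")
        for name in ("subject_sd_log_sway", "session_sd_log_sway", "trial_sd_log_sway"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if self.ce_multiplier <= 0 or self.cf_multiplier <= 0:
            raise InvalidArgumentError("condition multipliers must be positive")
        for name in ("dropout_prob_ce", "dropout_prob_cf", "single_session_frac"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InvalidArgumentError(f"{name} must be in [0, 1]")

    # ---- design-implied quantities (used by recovery tests) -------------

    def expected_session_icc(self) -> float:
        """Design-implied ICC of the session-level log sway scale,
        tau^2 / (tau^2 + sigma_session^2); exact as trial noise -> 0."""
        tau2 = self.subject_sd_log_sway**2
        s2 = self.session_sd_log_sway**2
        if tau2 + s2 == 0:
            raise InvalidArgumentError("no variance components")
        return tau2 / (tau2 + s2)

    def expected_scale_correlation(self, scale: str = "bbs") -> float:
        """Design-implied Spearman correlation between a scale score and
        session-mean sway magnitude (negative: more sway, lower score).

        Before rounding/clipping, (score, log sway) is bivariate normal
        with Pearson correlation r = -slope*s_l / sqrt(slope^2 s_l^2 + n^2)
        where s_l is the SD of the session log-sway offset; the Spearman
        correlation of a bivariate normal is (6/pi) asin(r/2).
        """
        model = next((m for m in self.scale_models if m.name == scale), None)
        if model is None:
            raise InvalidArgumentError(f"unknown scale {scale!r}")
        s_l = math.sqrt(self.subject_sd_log_sway**2 + self.session_sd_log_sway**2)
        denom = math.hypot(model.slope * s_l, model.total_noise_sd)
        if denom == 0:
            return 0.0
        r = -model.slope * s_l / denom
        return (6.0 / math.pi) * math.asin(r / 2.0)

    def with_seed(self, seed: int) -> "StudyDesign":
        return replace(self, seed=int(seed))


@dataclass
class SimulatedStudy:
    """Output of :func:`simulate_study`.

    ``study`` is the long-format trial table (one row per recorded trial,
    with the nine COP parameters, the session's scale scores, and heel
    distance for feet-apart conditions); ``subjects`` carries demographics
    and the dropout pattern; ``trajectories`` optionally maps
    (subject_id, session_index, vision, support, trial_index) to the raw
    :class:`COPTrajectory`.
    """

    study: pd.DataFrame
    subjects: pd.DataFrame
    design: StudyDesign
    trajectories: dict | None = None


# ---------------------------------------------------------------------------
# OU simulation


def _ou_batch(
    n_trials: int,
    n_samples: int,
    dt: float,
    ou: OUParams,
    scales: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact AR(1) discretisation of the OU sway process for a stack of
    trials; ``scales`` multiplies the diffusion scale per trial.

    Returns (x, y) arrays of shape (n_trials, n_samples) in mm.
    """
    from scipy.signal import lfilter

    eps = rng.standard_normal((2, n_trials, n_samples))
    out = []
    for axis in range(2):
        theta = ou.theta[axis]
        sigma = ou.sigma[axis] * scales  # (n_trials,)
        a = math.exp(-theta * dt)
        stat_sd = sigma / math.sqrt(2.0 * theta)
        innov_sd = stat_sd * math.sqrt(1.0 - a * a)
        # x_j = a x_{j-1} + u_j with u_0 the stationary draw: an IIR filter
        u = innov_sd[:, None] * eps[axis]
        u[:, 0] = stat_sd * eps[axis, :, 0]
        path = lfilter([1.0], [1.0, -a], u, axis=1)
        out.append(path)
    return out[0], out[1]


def simulate_trial(
    profile: SubjectProfile,
    ou: OUParams,
    condition: tuple[str, str],
    duration: float = 51.2,
    rate: float = 50.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    ce_multiplier: float = 1.0,
    cf_multiplier: float = 1.0,
    log_perturbation: float = 0.0,
) -> COPTrajectory:
    """One trial's COP trajectory for a subject under one condition.

    The effective sway scale is
    ``base_sway_scale * ce_multiplier^[vision=CE] * cf_multiplier^[support=CF]
    * exp(log_perturbation)`` where ``log_perturbation`` carries the
    session- and trial-level log-normal random effects.  The sample count
    is ``round(duration * rate) + 1``.
    """
    if duration <= 0 or rate <= 0:
        raise InvalidArgumentError("duration and rate must be positive")
    vision, support = condition
    if vision not in ("OE", "CE") or support not in ("OF", "CF"):
        raise InvalidArgumentError(f"unknown condition {condition!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    scale = profile.base_sway_scale * math.exp(log_perturbation)
    if vision == "CE":
        scale *= ce_multiplier
    if support == "CF":
        scale *= cf_multiplier
    n = int(round(duration * rate)) + 1
    x, y = _ou_batch(1, n, 1.0 / rate, ou, np.array([scale]), rng)
    t = np.arange(n) / rate
    return COPTrajectory(t=t, x=x[0], y=y[0])


# ---------------------------------------------------------------------------
# cohort simulation


def _draw_session_counts(design: StudyDesign, rng: np.random.Generator) -> np.ndarray:
    if isinstance(design.sessions_per_subject, int):
        return np.full(design.n_subjects, design.sessions_per_subject, dtype=int)
    if design.sessions_per_subject is not None:
        counts = np.asarray(design.sessions_per_subject, dtype=int)
        if len(counts) != design.n_subjects:
            raise InvalidArgumentError("sessions_per_subject list length mismatch")
        return counts
    # a fraction of the cohort is seen once; the rest 2..max_sessions with
    # a geometric tail calibrated so 23 subjects total ~111 sessions
    counts = np.empty(design.n_subjects, dtype=int)
    for i in range(design.n_subjects):
        if rng.random() < design.single_session_frac:
            counts[i] = 1
        else:
            counts[i] = min(1 + int(rng.geometric(0.18)), design.max_sessions)
            counts[i] = max(counts[i], 2)
    return counts


def _make_subjects(design: StudyDesign, rng: np.random.Generator) -> list[SubjectProfile]:
    profiles = []
    for i in range(design.n_subjects):
        z = rng.standard_normal()  # subject log-sway effect, standardised
        ability = -z
        u = stats.norm.cdf(ability)
        drop_ce = u < design.dropout_prob_ce
        drop_cf = u < design.dropout_prob_cf
        hd0 = design.hd_mean + design.hd_sway_coupling * z + design.hd_between_sd * rng.standard_normal()
        hd0 = max(hd0, 5.0)
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i + 1:02d}",
                latent_ability=ability,
                base_sway_scale=math.exp(design.subject_sd_log_sway * z),
                heel_distance_baseline=hd0,
                heel_distance_slope=design.hd_slope_mean
                + design.hd_slope_sd * rng.standard_normal(),
                age=float(np.clip(round(48 + 16 * rng.standard_normal()), 18, 85)),
                height=float(round(171 + 8 * rng.standard_normal(), 1)),
                weight=float(round(69 + 9 * rng.standard_normal(), 1)),
                sex="M" if rng.random() < 14.0 / 23.0 else "F",
                drop_ce=drop_ce,
                drop_cf=drop_cf,
            )
        )
    return profiles


def _surviving_conditions(p: SubjectProfile) -> list[tuple[str, str]]:
    out = []
    for vision, support in CONDITIONS:
        if vision == "CE" and p.drop_ce:
            continue
        if support == "CF" and p.drop_cf:
            continue
        out.append((vision, support))
    return out


def _scale_scores(
    design: StudyDesign,
    log_sway: float,
    subject_offsets: dict[str, float],
    rng: np.random.Generator,
) -> dict[str, int]:
    scores = {}
    for m in design.scale_models:
        raw = (
            m.center
            - m.slope * log_sway
            + subject_offsets[m.name]
            + m.noise_sd_session * rng.standard_normal()
        )
        scores[m.name] = int(np.clip(round(raw), m.minimum, m.maximum))
    scores["ts"] = scores["ts_e"] + scores["ts_l"]
    return scores


def simulate_study(
    design: StudyDesign, keep_trajectories: bool = False
) -> SimulatedStudy:
    """Simulate a full cohort: trajectories, COP metrics, scales, heel
    distance.

    Deterministic in ``design.seed``: the same design yields a bit-identical
    study table.  Row count equals
    sum over subjects of sessions x surviving conditions x trials.
    """
    rng = np.random.default_rng(design.seed)
    profiles = _make_subjects(design, rng)
    counts = _draw_session_counts(design, rng)

    n_samples = int(round(design.trial_duration * design.sampling_rate)) + 1
    t = np.arange(n_samples) / design.sampling_rate

    rows: list[dict] = []
    scales_per_trial: list[float] = []
    for p, n_sess in zip(profiles, counts):
        conds = _surviving_conditions(p)
        log_subject = math.log(p.base_sway_scale)
        subject_offsets = {
            m.name: m.noise_sd_subject * rng.standard_normal()
            for m in design.scale_models
        }
        for s_idx in range(n_sess):
            day = s_idx * design.intersession_days
            s_off = design.session_sd_log_sway * rng.standard_normal()
            scores = _scale_scores(
                design, log_subject + s_off, subject_offsets, rng
            )
            hd = max(
                p.heel_distance_baseline
                + p.heel_distance_slope * day
                + design.hd_session_noise * rng.standard_normal(),
                0.0,
            )
            for vision, support in conds:
                cond_mult = (design.ce_multiplier if vision == "CE" else 1.0) * (
                    design.cf_multiplier if support == "CF" else 1.0
                )
                for k in range(design.trials_per_condition):
                    t_off = design.trial_sd_log_sway * rng.standard_normal()
                    scale = p.base_sway_scale * cond_mult * math.exp(s_off + t_off)
                    scales_per_trial.append(scale)
                    rows.append(
                        {
                            "subject_id": p.subject_id,
                            "session_index": s_idx + 1,
                            "session_day": day,
                            "vision": vision,
                            "support": support,
                            "trial_index": k + 1,
                            "bbs": scores["bbs"],
                            "ts": scores["ts"],
                            "ts_e": scores["ts_e"],
                            "ts_l": scores["ts_l"],
                            "wisci": scores["wisci"],
                            "heel_distance_cm": hd if support == "OF" else np.nan,
                            "trajectory_file": "",
                        }
                    )

    n_trials = len(rows)
    x, y = _ou_batch(
        n_trials,
        n_samples,
        1.0 / design.sampling_rate,
        design.ou,
        np.asarray(scales_per_trial),
        rng,
    )
    batch = compute_metrics_batch(t, x, y)
    study = pd.DataFrame(rows)
    for name in METRIC_NAMES:
        study[name] = batch[name]
    # stable column order: keys, metrics, scales, extras
    study = study[
        [
            "subject_id",
            "session_index",
            "session_day",
            "vision",
            "support",
            "trial_index",
            *METRIC_NAMES,
            "bbs",
            "ts",
            "ts_e",
            "ts_l",
            "wisci",
            "heel_distance_cm",
            "trajectory_file",
        ]
    ]

    subjects = pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in profiles],
            "age": [p.age for p in profiles],
            "height": [p.height for p in profiles],
            "weight": [p.weight for p in profiles],
            "sex": [p.sex for p in profiles],
            "latent_ability": [p.latent_ability for p in profiles],
            "base_sway_scale": [p.base_sway_scale for p in profiles],
            "heel_distance_baseline": [p.heel_distance_baseline for p in profiles],
            "heel_distance_slope": [p.heel_distance_slope for p in profiles],
            "n_sessions": counts,
            "drop_ce": [p.drop_ce for p in profiles],
            "drop_cf": [p.drop_cf for p in profiles],
        }
    )

    trajectories = None
    if keep_trajectories:
        trajectories = {}
        for i, r in enumerate(rows):
            key = (
                r["subject_id"],
                r["session_index"],
                r["vision"],
                r["support"],
                r["trial_index"],
            )
            trajectories[key] = COPTrajectory(t=t, x=x[i], y=y[i])

    return SimulatedStudy(
        study=study, subjects=subjects, design=design, trajectories=trajectories
    )
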