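"""Synthetic cohort generator.

Produces cohorts with the statistical structure the downstream analysis
assumes: four latent trajectory classes with quadratic mean curves of
months-symptomatic-per-year bounded in [0, 12], subject-level random
intercepts and slopes, serially correlated monthly presence/absence
underlying the annual counts, whole-year missing-at-random blanking, and
class-conditional covariate distributions calibrated to configurable
persistent-vs-remitting odds-ratio targets.

The default class mean curves are calibration constants invented to satisfy
the verbal class descriptions (remitting: low and declining; late decline:
low rising to high; late improvement: high falling to low; persistent: high
throughout), with separation large enough for sharp posterior
classification.  They are not estimates of any published figure.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .cohort import (
    BaselineRecord,
    Cohort,
    MonthlyTimeline,
    OutcomeRecord,
    Status,
)

__all__ = [
    "CLASS_NAMES",
    "GeneratorConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_monthly_series",
    "simulate_covariates",
    "apply_missingness",
    "implied_odds_ratio",
    "class_mean_curve",
]

#: canonical latent class order, largest share first
CLASS_NAMES = ("remitting", "late_decline", "late_improvement", "persistent")


def _per_class(remitting, late_decline, late_improvement, persistent) -> dict:
    return {
        "remitting": remitting,
        "late_decline": late_decline,
        "late_improvement": late_improvement,
        "persistent": persistent,
    }


def _default_covariate_model() -> dict:
    """Class-conditional covariate distributions.

    Binary prevalences in the persistent class are derived from the remitting
    prevalence and the configured persistent-vs-remitting odds-ratio target;
    the late-decline class tracks the persistent profile and late-improvement
    the remitting profile.
    """
    return {
        # persistent-vs-remitting targets implied by the prevalences below:
        # male 1.89, London 1.58, black Caribbean (vs white British) ~1.96,
        # affective diagnosis 0.17, DUP ~1.05 per month
        "male_prob": _per_class(0.44, 0.58, 0.46, 0.5976),
        "centre_london_prob": _per_class(0.55, 0.62, 0.56, 0.6588),
        # (white_british, black_caribbean, other)
        "ethnicity_probs": _per_class(
            (0.45, 0.20, 0.35),
            (0.34, 0.29, 0.37),
            (0.44, 0.21, 0.35),
            (0.33, 0.2874, 0.3826),
        ),
        # (no_qualifications, school, university)
        "education_probs": _per_class(
            (0.20, 0.55, 0.25),
            (0.24, 0.66, 0.10),
            (0.21, 0.56, 0.23),
            (0.24, 0.68, 0.08),
        ),
        # probabilities over disadvantage index 0..4
        "disadvantage_probs": _per_class(
            (0.30, 0.25, 0.20, 0.15, 0.10),
            (0.22, 0.20, 0.20, 0.18, 0.20),
            (0.28, 0.25, 0.20, 0.16, 0.11),
            (0.22, 0.20, 0.20, 0.18, 0.20),
        ),
        # probabilities over premorbid IQ quartiles, lowest first
        "iq_quartile_probs": _per_class(
            (0.20, 0.25, 0.25, 0.30),
            (0.36, 0.25, 0.21, 0.18),
            (0.21, 0.25, 0.25, 0.29),
            (0.38, 0.25, 0.20, 0.17),
        ),
        "affective_prob": _per_class(0.35, 0.10, 0.33, 0.0839),
        # DUP drawn from a normal truncated at zero with common sd; the mean
        # shift ln(1.05) * dup_sd**2 implies ~1.05 odds per additional month
        "dup_mean": _per_class(6.0, 6.44, 5.0, 6.439),
        "dup_sd": 3.0,
        "age_mean": 28.0,
        "age_sd": 9.0,
        "mode_acute_prob": _per_class(0.60, 0.50, 0.55, 0.40),
        "gaf_mean": _per_class(63.7, 41.2, 49.8, 45.9),
        "gaf_sd": _per_class(17.9, 17.4, 12.4, 12.2),
        "relationship_prob": _per_class(0.38, 0.25, 0.30, 0.20),
        "employed_prob": _per_class(0.35, 0.10, 0.15, 0.08),
    }


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic cohort generator.

    ``class_curves`` are quadratic coefficients (b0, b1, b2) of the class
    mean number of months symptomatic per year as a function of follow-up
    year t = 1..T (uncentred time).
    """

    n_subjects: int = 326
    T: int = 10
    class_proportions: dict = field(
        default_factory=lambda: _per_class(0.585, 0.056, 0.054, 0.306)
    )
    class_curves: dict = field(
        default_factory=lambda: _per_class(
            (3.8, -0.55, 0.022),
            (0.3, 0.5, 0.105),
            (13.0, -0.8, -0.06),
            (11.0, 0.10, -0.006),
        )
    )
    random_effect_sds: tuple[float, float] = (0.5, 0.08)
    residual_sd: float = 0.4
    markov_persistence: float = 0.35
    missing_year_prob: float = 0.08
    #: additive log-odds of a missing year per observed covariate; keys are
    #: "field=value" for indicators or a numeric field name for linear terms
    missing_logodds: dict = field(default_factory=dict)
    covariate_model: dict = field(default_factory=_default_covariate_model)
    seed: int = 0

    def __post_init__(self) -> None:
        # rounding slack: percentage splits quoted to one decimal may sum to 100.1
        props = np.array([self.class_proportions[c] for c in CLASS_NAMES])
        if (props < 0).any() or abs(props.sum() - 1.0) > 5e-3:
            raise ValueError("class_proportions must be a simplex vector over the four classes")
        if any(sd < 0 for sd in self.random_effect_sds) or self.residual_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not (0.0 <= self.markov_persistence < 1.0):
            raise ValueError("markov_persistence must lie in [0, 1)")
        if not (0.0 <= self.missing_year_prob <= 1.0):
            raise ValueError("missing_year_prob must lie in [0, 1]")

    # -- structured-text round trip -------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["random_effect_sds"] = list(self.random_effect_sds)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["random_effect_sds"] = tuple(d["random_effect_sds"])
        for key in ("class_curves",):
            d[key] = {k: tuple(v) for k, v in d[key].items()}
        cm = d.get("covariate_model", {})
        for key in ("ethnicity_probs", "education_probs", "disadvantage_probs", "iq_quartile_probs"):
            if key in cm:
                cm[key] = {k: tuple(v) for k, v in cm[key].items()}
        return cls(**d)


@dataclass
class SimulatedCohort:
    """A generated cohort plus ground-truth class labels and config echo."""

    cohort: Cohort
    labels: dict[str, str]
    config: GeneratorConfig

    @property
    def timelines(self):
        return self.cohort.timelines

    @property
    def baselines(self):
        return self.cohort.baselines

    @property
    def outcomes(self):
        return self.cohort.outcomes


def implied_odds_ratio(p1: float, p0: float) -> float:
    """Odds ratio implied by two prevalences."""
    return (p1 / (1.0 - p1)) / (p0 / (1.0 - p0))


def class_mean_curve(cfg: GeneratorConfig, class_name: str, t: np.ndarray) -> np.ndarray:
    """Class mean months-per-year at (possibly fractional) year ``t``, clamped to [0, 12]."""
    b0, b1, b2 = cfg.class_curves[class_name]
    return np.clip(b0 + b1 * t + b2 * t**2, 0.0, 12.0)


def simulate_monthly_series(
    class_name: str,
    subject_effects: tuple[float, float],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    subject_id: str = "s",
) -> MonthlyTimeline:
    """Simulate one subject's monthly presence/absence sequence.

    Month m (0-based) sits at fractional year t = (m + 0.5)/12 + 0.5, so the
    months of follow-up year t average to the curve value at t.  The monthly
    presence probability is the subject's curve value divided by 12, with a
    per-year Gaussian jitter of sd ``residual_sd`` on the months-per-year
    scale.  Serial dependence follows a two-state chain: the presence
    probability in month m is ``rho * s_{m-1} + (1 - rho) * p_m``, whose
    stationary marginal equals ``p_m``.
    """
    b0, b1, b2 = cfg.class_curves[class_name]
    u0, u1 = subject_effects
    M = 12 * cfg.T
    m = np.arange(M)
    t = (m + 0.5) / 12.0 + 0.5
    year_idx = m // 12
    jitter = rng.normal(0.0, cfg.residual_sd, size=cfg.T)[year_idx]
    level = b0 + b1 * t + b2 * t**2 + u0 + u1 * t + jitter
    p = np.clip(level / 12.0, 0.0, 1.0)

    rho = cfg.markov_persistence
    u = rng.random(M)
    statuses = np.empty(M, dtype=np.int8)
    prev = 1 if u[0] < p[0] else 0
    statuses[0] = prev
    for i in range(1, M):
        pr = rho * prev + (1.0 - rho) * p[i]
        prev = 1 if u[i] < pr else 0
        statuses[i] = prev
    return MonthlyTimeline(subject_id=subject_id, statuses=statuses)


def _categorical(rng: np.random.Generator, labels: Sequence[str], probs: Sequence[float]) -> str:
    probs = np.asarray(probs, dtype=float)
    if abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError("category probabilities must sum to 1")
    return labels[int(rng.choice(len(labels), p=probs / probs.sum()))]


def _truncated_normal_nonneg(rng: np.random.Generator, mean: float, sd: float) -> float:
    # rejection sampling; acceptance is high for the configured means/sds
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= 0:
            return x
    return max(0.0, mean)


def simulate_covariates(
    class_name: str,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    subject_id: str = "s",
) -> tuple[BaselineRecord, OutcomeRecord]:
    """Draw one subject's baseline and outcome records given the latent class."""
    cm = cfg.covariate_model
    baseline = BaselineRecord(
        subject_id=subject_id,
        centre="London" if rng.random() < cm["centre_london_prob"][class_name] else "Nottingham",
        sex="male" if rng.random() < cm["male_prob"][class_name] else "female",
        age_at_onset=float(np.clip(rng.normal(cm["age_mean"], cm["age_sd"]), 16.0, 65.0)),
        ethnicity=_categorical(
            rng, ("white_british", "black_caribbean", "other"), cm["ethnicity_probs"][class_name]
        ),
        education=_categorical(
            rng, ("no_qualifications", "school", "university"), cm["education_probs"][class_name]
        ),
        disadvantage_index=int(rng.choice(5, p=np.asarray(cm["disadvantage_probs"][class_name]))),
        premorbid_iq_quartile=_categorical(
            rng, ("q1_lowest", "q2", "q3", "q4_highest"), cm["iq_quartile_probs"][class_name]
        ),
        diagnosis="affective" if rng.random() < cm["affective_prob"][class_name] else "non_affective",
        dup_months=_truncated_normal_nonneg(rng, cm["dup_mean"][class_name], cm["dup_sd"]),
        mode_of_onset="acute" if rng.random() < cm["mode_acute_prob"][class_name] else "insidious",
    )
    outcome = OutcomeRecord(
        subject_id=subject_id,
        gaf_d=float(np.clip(rng.normal(cm["gaf_mean"][class_name], cm["gaf_sd"][class_name]), 1.0, 100.0)),
        in_relationship=bool(rng.random() < cm["relationship_prob"][class_name]),
        employed=bool(rng.random() < cm["employed_prob"][class_name]),
    )
    return baseline, outcome


def _missing_logit_shift(baseline: BaselineRecord, logodds: Mapping[str, float]) -> float:
    shift = 0.0
    for key, coef in logodds.items():
        if "=" in key:
            fieldname, value = key.split("=", 1)
            if str(getattr(baseline, fieldname)) == value:
                shift += coef
        else:
            shift += coef * float(getattr(baseline, key))
    return shift


def apply_missingness(
    timelines: Mapping[str, MonthlyTimeline],
    baselines: Mapping[str, BaselineRecord],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> dict[str, MonthlyTimeline]:
    """Blank whole follow-up years to MISSING, missing-at-random.

    The blanking probability depends only on the baseline covariates (and a
    baseline rate), never on the symptom statuses being blanked, so the
    mechanism is MAR by construction.
    """
    if not (0.0 <= cfg.missing_year_prob <= 1.0):
        raise ValueError("missing_year_prob must lie in [0, 1]")
    if cfg.missing_year_prob == 0.0 and not cfg.missing_logodds:
        return {sid: tl for sid, tl in timelines.items()}

    base_logit = (
        np.inf
        if cfg.missing_year_prob == 1.0
        else (-np.inf if cfg.missing_year_prob == 0.0
              else np.log(cfg.missing_year_prob / (1.0 - cfg.missing_year_prob)))
    )
    out: dict[str, MonthlyTimeline] = {}
    for sid, tl in timelines.items():
        shift = _missing_logit_shift(baselines[sid], cfg.missing_logodds) if sid in baselines else 0.0
        logit = base_logit + shift
        p = 1.0 / (1.0 + np.exp(-logit)) if np.isfinite(logit) else (1.0 if logit > 0 else 0.0)
        n_years = int(np.ceil(tl.followup_months / 12))
        mask_years = rng.random(n_years) < p
        statuses = tl.statuses.copy()
        for yr in np.flatnonzero(mask_years):
            statuses[12 * yr: 12 * (yr + 1)] = int(Status.MISSING)
        out[sid] = MonthlyTimeline(subject_id=sid, statuses=statuses)
    return out


def simulate_cohort(cfg: GeneratorConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort.

    Reproducible given ``cfg.seed``; the ground-truth class of every subject
    is returned alongside the cohort for recovery testing.
    """
    rng = np.random.default_rng(cfg.seed)
    props = np.array([cfg.class_proportions[c] for c in CLASS_NAMES])
    props = props / props.sum()
    classes = rng.choice(len(CLASS_NAMES), size=cfg.n_subjects, p=props)
    sd0, sd1 = cfg.random_effect_sds

    cohort = Cohort()
    labels: dict[str, str] = {}
    for i in range(cfg.n_subjects):
        sid = f"s{i + 1:04d}"
        cname = CLASS_NAMES[int(classes[i])]
        labels[sid] = cname
        u0 = rng.normal(0.0, sd0)
        u1 = rng.normal(0.0, sd1)
        tl = simulate_monthly_series(cname, (u0, u1), cfg, rng, subject_id=sid)
        baseline, outcome = simulate_covariates(cname, cfg, rng, subject_id=sid)
        cohort.timelines[sid] = tl
        cohort.baselines[sid] = baseline
        cohort.outcomes[sid] = outcome

    cohort.timelines = apply_missingness(cohort.timelines, cohort.baselines, cfg, rng)
    return SimulatedCohort(cohort=cohort, labels=labels, config=copy.deepcopy(cfg))
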