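"""Synthetic two-group stress-test cohort with a latent-reserve tipping point.

The generator emulates the statistical structure the downstream analysis
assumes: a healthy group and a neurologically diagnosed group whose trial
performance declines with graded motor and cognitive load.  Each subject
carries an unobserved reserve capacity ``R`` (lower with age and with
diagnosis).  Latent performance in a grid cell with combined load
``L = w_m * m + w_c * c`` is

    P(m, c) = b - delta * L - lambda * max(0, L - R)

a gentle linear decline plus a hinge penalty once the load exceeds the
subject's reserve -- the "tipping point" beyond which performance collapses.
Observable trial features are monotone links of ``P`` with measurement noise:
logistic links for answer accuracy (with a 1/2 guessing floor, the task being
a two-button choice) and obstacle success, a log-linear model for reaction
time (capped at the stimulus display time), and bounded linear models for the
gait features.  Clinical proxies and TIV-adjusted brain-volume surrogates are
linear in ``R`` and age plus noise, oriented as in the study population
summaries they are calibrated to.

Observable tables never contain ``R`` or ``P``; those live in a separate
truth table for validation of the analysis itself.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import truncnorm

from . import protocol
from .exceptions import ConfigError, DomainError

AGE_BOUNDS = (18.0, 85.0)

#: Default 70/30 split sizes per group (training counts).
DEFAULT_TRAIN_COUNTS = {"healthy": 41, "diagnosed": 57}


@dataclass(frozen=True)
class AgeModel:
    """Per-group truncated-normal age model (years), truncated to 18-85."""

    healthy_mean: float = 51.1
    healthy_sd: float = 17.7
    diagnosed_mean: float = 66.2
    diagnosed_sd: float = 10.6


@dataclass(frozen=True)
class ReserveModel:
    """Latent reserve R = r0 - r_age*(age-50) - r_group*1[diagnosed] + N(0, sigma)."""

    r0: float = 4.5
    r_age: float = 0.015
    r_group: float = 1.35
    sigma: float = 0.80


@dataclass(frozen=True)
class LoadModel:
    """Latent cell performance P = b - delta*L - lambda*max(0, L - R)."""

    w_m: float = 1.0
    w_c: float = 1.0
    b: float = 0.0
    delta: float = 0.25
    lam: float = 13.0


@dataclass(frozen=True)
class FeatureLinks:
    """Monotone links from latent cell performance P to trial features.

    Accuracy: the subject knows the answer with probability
    ``expit(acc_a0 + acc_a1 * P)`` and otherwise guesses one of the two
    buttons, so per-expression accuracy has a floor of 1/2.  Reaction time is
    log-linear decreasing in P, capped at the display time.  Obstacle success
    is a binomial with logistic success probability.  Gait features are linear
    in P with physiologic floors/ceilings, which compresses group differences
    at crushing difficulty.
    """

    acc_a0: float = 1.6
    acc_a1: float = 1.1
    rt_t0: float = math.log(0.85)
    rt_t1: float = 0.30
    rt_sigma: float = 0.12
    rt_max_s: float = 2.5
    obs_o0: float = 2.2
    obs_o1: float = 1.0
    obs_floor: float = 0.08
    answer_window_s: float = 2.0
    obstacle_rate_per_min: float = 6.0
    # between-subject random intercepts (idiosyncrasy unrelated to reserve)
    subj_sigma_log_rt: float = 0.3375
    subj_sigma_acc: float = 0.81
    subj_sigma_obs: float = 0.81
    subj_gait_sigma: dict = field(default_factory=lambda: {
        "step_length_mean_cm": 5.4,
        "step_length_sd_cm": 0.45,
        "gyro_amp_midswing": 24.3,
        "gait_asymmetry_pct": 0.9,
    })
    # feature -> (intercept, slope per unit P, noise sd, lower clip, upper clip)
    gait: dict = field(default_factory=lambda: {
        "step_length_mean_cm": (60.0, 6.0, 3.0, 18.0, 90.0),
        "step_length_sd_cm": (3.0, -0.5, 0.45, 0.5, 6.5),
        "gyro_amp_midswing": (250.0, 25.0, 13.0, 75.0, 400.0),
        "gait_asymmetry_pct": (3.0, -1.2, 0.8, 0.0, 11.4),
    })


def _default_proxy_table() -> dict:
    # feature -> (intercept, slope per unit R, slope per (age-50) year,
    #             noise sd, lower clip, upper clip, round to int)
    return {
        "education_years": (15.0, 0.31, 0.0, 1.15, 8, 25, True),
        "MoCA": (23.6, 0.86, 0.0, 1.85, 10, 30, True),
        "TMT_A_s": (90.3, -10.9, 0.5, 26.0, 12.0, 300.0, False),
        "TMT_B_s": (135.1, -12.4, 0.6, 27.5, 30.0, 360.0, False),
        "stroop_word": (73.8, 4.7, 0.0, 14.4, 40.0, 135.0, False),
        "stroop_colour": (75.0, 4.5, 0.0, 14.0, 40.0, 135.0, False),
        "stroop_interference": (25.5, 4.3, 0.0, 10.6, 5.0, 100.0, False),
        "preferred_speed_kmh": (2.24, 0.156, -0.008, 0.50, 1.0, 4.0, False),
    }


def _default_mri_table() -> dict:
    # region -> (intercept, slope per unit R, slope per (age-50) year, noise sd)
    # TIV-adjusted volumes, ml; positive in R, shrinking with age.
    table = {
        "whole_brain_gm": (570.0, 8.0, -1.2, 22.0),
        "whole_brain_wm": (480.0, 6.0, -0.9, 22.0),
        "superior_medial_frontal_l": (13.0, 0.28, -0.03, 0.9),
        "superior_medial_frontal_r": (13.2, 0.28, -0.03, 0.9),
        "inferior_frontal_l": (11.5, 0.26, -0.025, 0.8),
        "inferior_frontal_r": (11.8, 0.26, -0.025, 0.8),
    }
    bilateral = {
        "caudate": (3.0, 0.12, -0.008, 0.22),
        "putamen": (4.2, 0.13, -0.01, 0.26),
        "hippocampus": (3.5, 0.11, -0.009, 0.22),
        "pallidum": (1.4, 0.05, -0.004, 0.10),
        "amygdala": (1.3, 0.045, -0.003, 0.10),
    }
    for region, coefs in bilateral.items():
        table[f"{region}_l"] = coefs
        table[f"{region}_r"] = coefs
    return table


@dataclass(frozen=True)
class GeneratorConfig:
    """Full configuration of the cohort generator.

    Defaults define the study conditions: group sizes 68 healthy / 76
    diagnosed, the published age distributions, and reserve/feature-link
    parameters calibrated once so the full pipeline lands near the published
    cohort MCR-index summaries (see docs/methods.md).
    """

    n_healthy: int = 68
    n_diagnosed: int = 76
    ages: AgeModel = field(default_factory=AgeModel)
    reserve: ReserveModel = field(default_factory=ReserveModel)
    load: LoadModel = field(default_factory=LoadModel)
    links: FeatureLinks = field(default_factory=FeatureLinks)
    proxies: dict = field(default_factory=_default_proxy_table)
    mri: dict = field(default_factory=_default_mri_table)
    noise_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.n_healthy <= 0:
            bad.append("n_healthy")
        if self.n_diagnosed <= 0:
            bad.append("n_diagnosed")
        for name in ("healthy_sd", "diagnosed_sd"):
            if getattr(self.ages, name) <= 0:
                bad.append(f"ages.{name}")
        for name in ("healthy_mean", "diagnosed_mean"):
            mean = getattr(self.ages, name)
            if not (AGE_BOUNDS[0] <= mean <= AGE_BOUNDS[1]):
                bad.append(f"ages.{name}")
        if self.reserve.sigma < 0:
            bad.append("reserve.sigma")
        if self.load.lam < 0:
            bad.append("load.lam")
        if self.links.rt_sigma < 0:
            bad.append("links.rt_sigma")
        if self.noise_scale < 0:
            bad.append("noise_scale")
        for feature, row in self.links.gait.items():
            if row[2] < 0:
                bad.append(f"links.gait.{feature}")
        for feature, row in self.proxies.items():
            if row[3] < 0:
                bad.append(f"proxies.{feature}")
        if bad:
            raise ConfigError(
                "invalid generator configuration, offending fields: " + ", ".join(bad),
                fields=bad,
            )

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        data = dict(data)
        for key, sub in (("ages", AgeModel), ("reserve", ReserveModel),
                         ("load", LoadModel), ("links", FeatureLinks)):
            if key in data and isinstance(data[key], dict):
                data[key] = sub(**data[key])
        for key in ("proxies", "mri"):
            if key in data:
                data[key] = {k: tuple(v) for k, v in data[key].items()}
        links = data.get("links")
        if isinstance(links, FeatureLinks) and isinstance(links.gait, dict):
            object.__setattr__(links, "gait",
                               {k: tuple(v) for k, v in links.gait.items()})
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as handle:
            payload = yaml.safe_load(handle) or {}
        cfg = cls.from_dict(payload)
        cfg.validate()
        return cfg


class Cohort(NamedTuple):
    """Generated tables: observables (subjects, trials, mri) and hidden truth."""

    subjects: pd.DataFrame
    trials: pd.DataFrame
    truth: pd.DataFrame
    mri: pd.DataFrame


def latent_cell_performance(R: float, m: int, c: int, cfg: GeneratorConfig):
    """Latent performance P = b - delta*L - lambda*max(0, L - R), L = w_m*m + w_c*c."""
    load = cfg.load
    L = load.w_m * np.asarray(m) + load.w_c * np.asarray(c)
    P = load.b - load.delta * L - load.lam * np.maximum(0.0, L - np.asarray(R))
    return float(P) if np.ndim(P) == 0 else P


def _truncated_ages(rng, mean, sd, n):
    lo, hi = AGE_BOUNDS
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _linear_feature(rng, coefs, R, age, noise_scale):
    intercept, b_r, b_age, sigma = coefs[:4]
    value = intercept + b_r * R + b_age * (age - 50.0)
    if noise_scale > 0:
        value += noise_scale * sigma * rng.standard_normal()
    return value


def _subject_offsets(rng, links, noise_scale):
    """Per-subject random intercepts of the feature links.

    Scaled by ``noise_scale`` together with the trial-level noise, so a
    noiseless cohort has fully deterministic links.
    """
    return {
        "log_rt": noise_scale * links.subj_sigma_log_rt * rng.standard_normal(),
        "acc": noise_scale * links.subj_sigma_acc * rng.standard_normal(),
        "obs": noise_scale * links.subj_sigma_obs * rng.standard_normal(),
        "gait": {feature: noise_scale * sd * rng.standard_normal()
                 for feature, sd in links.subj_gait_sigma.items()},
    }


def _trial_features(rng, P, trial_row, grid, links, noise_scale, offsets=None):
    """Emit the observable features of one trial from its latent performance."""
    if offsets is None:
        offsets = {"log_rt": 0.0, "acc": 0.0, "obs": 0.0, "gait": {}}
    out = {}
    for feature, (b0, slope, sigma, lo, hi) in links.gait.items():
        value = float(np.clip(b0 + offsets["gait"].get(feature, 0.0) + slope * P, lo, hi))
        if noise_scale > 0:
            value += noise_scale * sigma * rng.standard_normal()
        out[feature] = value

    c = trial_row["cognitive_level"]
    m = trial_row["motor_level"]
    duration_s = trial_row["duration_min"] * 60.0

    if c > 0:
        level = grid.cognitive_levels[c]
        n_expr = max(3, int(round(duration_s / (level.display_time_s + links.answer_window_s))))
        p_know = expit(links.acc_a0 + offsets["acc"] + links.acc_a1 * P)
        p_correct = 0.5 + 0.5 * p_know
        if noise_scale > 0:
            digits = rng.integers(1, 10, size=(n_expr, level.digits))
            answers = np.array([protocol.expression_answer(d) for d in digits])
            correct = rng.random(n_expr) < p_correct
            # responses flip the true answer on errors; accuracy is the
            # fraction of responses matching the truth, i.e. mean(correct)
            responses = np.where(correct, answers, ~answers)
            out["cognitive_accuracy"] = float(np.mean(responses == answers))
            log_rt = links.rt_t0 + offsets["log_rt"] - links.rt_t1 * P \
                + noise_scale * links.rt_sigma * rng.standard_normal(n_expr)
            rt_cap = min(level.display_time_s, links.rt_max_s)
            rts = rt_cap * np.tanh(np.exp(log_rt) / rt_cap)
        else:
            out["cognitive_accuracy"] = float(p_correct)
            rt_cap = min(level.display_time_s, links.rt_max_s)
            rts = rt_cap * math.tanh(math.exp(
                links.rt_t0 + offsets["log_rt"] - links.rt_t1 * P) / rt_cap)
        out["reaction_time_s"] = float(np.mean(rts))
    else:
        out["cognitive_accuracy"] = np.nan
        out["reaction_time_s"] = np.nan

    if m > 0:
        n_obs = max(4, int(round(links.obstacle_rate_per_min * trial_row["duration_min"])))
        p_pass = links.obs_floor + (1.0 - links.obs_floor) * \
            expit(links.obs_o0 + offsets["obs"] + links.obs_o1 * P)
        if noise_scale > 0:
            out["obstacle_success"] = float(rng.binomial(n_obs, p_pass) / n_obs)
        else:
            out["obstacle_success"] = float(p_pass)
    else:
        out["obstacle_success"] = np.nan
    return out


def generate_cohort(cfg: GeneratorConfig | None = None) -> Cohort:
    """Generate one full synthetic cohort, reproducibly from ``cfg.seed``.

    Returns subjects (one row per subject with clinical proxies), trials (the
    baseline walk as trial_index 0 plus the 16 scheduled trials, with feature
    fields missing where the challenge is absent), the hidden truth table
    (latent reserve and per-cell latent performance) and the MRI surrogate
    volumes.
    """
    cfg = cfg or GeneratorConfig()
    cfg.validate()
    grid = protocol.build_default_grid()
    root = np.random.SeedSequence(cfg.seed)
    groups = ["healthy"] * cfg.n_healthy + ["diagnosed"] * cfg.n_diagnosed

    subject_rows, trial_rows, truth_rows, mri_rows = [], [], [], []
    children = root.spawn(len(groups))
    for i, (group, child) in enumerate(zip(groups, children)):
        rng = np.random.default_rng(child)
        subject_id = f"S{i + 1:03d}"
        diagnosed = group == "diagnosed"
        if diagnosed:
            age = float(_truncated_ages(rng, cfg.ages.diagnosed_mean, cfg.ages.diagnosed_sd, 1)[0])
        else:
            age = float(_truncated_ages(rng, cfg.ages.healthy_mean, cfg.ages.healthy_sd, 1)[0])
        res = cfg.reserve
        R = res.r0 - res.r_age * (age - 50.0) - res.r_group * diagnosed \
            + res.sigma * rng.standard_normal()
        sex = "F" if rng.random() < 0.5 else "M"
        offsets = _subject_offsets(rng, cfg.links, cfg.noise_scale)

        row = {"subject_id": subject_id, "group": group, "age": round(age, 1), "sex": sex}
        for feature, coefs in cfg.proxies.items():
            value = _linear_feature(rng, coefs, R, age, cfg.noise_scale)
            value = float(np.clip(value, coefs[4], coefs[5]))
            row[feature] = float(round(value)) if coefs[6] else round(value, 2)
        subject_rows.append(row)

        mri_row = {"subject_id": subject_id}
        for region, coefs in cfg.mri.items():
            value = _linear_feature(rng, coefs, R, age, cfg.noise_scale)
            mri_row[region] = round(max(value, 1e-3), 3)
        mri_rows.append(mri_row)

        for m, c in grid.cells():
            truth_rows.append({
                "subject_id": subject_id,
                "latent_reserve": round(R, 6),
                "motor_level": m,
                "cognitive_level": c,
                "latent_performance": round(latent_cell_performance(R, m, c, cfg), 6),
            })

        schedule_seed = int(rng.integers(2 ** 31))
        schedule = protocol.build_schedule(grid, seed=schedule_seed)
        frame = schedule.to_frame(grid)
        baseline = {"trial_index": 0, "trial_type": "baseline", "motor_level": 0,
                    "cognitive_level": 0, "duration_min": 1.0}
        for trial_row in [baseline] + frame.to_dict(orient="records"):
            P = latent_cell_performance(R, trial_row["motor_level"],
                                        trial_row["cognitive_level"], cfg)
            features = _trial_features(rng, P, trial_row, grid, cfg.links,
                                       cfg.noise_scale, offsets)
            record = {
                "subject_id": subject_id,
                "trial_index": trial_row["trial_index"],
                "trial_type": trial_row["trial_type"],
                "motor_level": trial_row["motor_level"],
                "cognitive_level": trial_row["cognitive_level"],
            }
            record.update({k: (round(v, 4) if np.isfinite(v) else v)
                           for k, v in features.items()})
            trial_rows.append(record)

    return Cohort(
        subjects=pd.DataFrame(subject_rows),
        trials=pd.DataFrame(trial_rows),
        truth=pd.DataFrame(truth_rows),
        mri=pd.DataFrame(mri_rows),
    )


def split_cohort(subjects: pd.DataFrame, train_counts: dict | None = None,
                 seed: int = 0) -> tuple:
    """Seeded within-group split into training and test subject ids.

    Defaults reproduce the 70/30 study split: 41 healthy + 57 diagnosed in
    training, 27 + 19 held out.  The split is disjoint and exhaustive.
    """
    train_counts = dict(DEFAULT_TRAIN_COUNTS if train_counts is None else train_counts)
    rng = np.random.default_rng(seed)
    train_ids, test_ids = [], []
    for group, count in train_counts.items():
        ids = subjects.loc[subjects["group"] == group, "subject_id"].tolist()
        if count > len(ids):
            raise DomainError(
                f"requested {count} training subjects for group {group!r} "
                f"but only {len(ids)} exist"
            )
        chosen = set(rng.choice(len(ids), size=count, replace=False).tolist())
        train_ids.extend(sid for j, sid in enumerate(ids) if j in chosen)
        test_ids.extend(sid for j, sid in enumerate(ids) if j not in chosen)
    extra = subjects.loc[~subjects["group"].isin(train_counts), "subject_id"]
    test_ids.extend(extra.tolist())
    return sorted(train_ids), sorted(test_ids)
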