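"""Synthetic cohort generator.

Emulates a prospective breast-cancer cohort of women under 50 years of age
at enrollment, followed up to 25 years: six phase-I risk factors — age at enrollment (AGE), age at menarche
(AGEMEN), history of benign breast biopsy (BIOPSY), full-term pregnancy
(FTP), first-degree family history (REL), race (RACE, white = 1) — plus one
phase-II biomarker Z linearly linked to AGE so that corr(Z, AGE) is about
0.2.  Event times follow a Cox model with Weibull baseline cumulative
hazard Lambda_0(t) = lambda * t^k; censoring is the minimum of an
exponential dropout time and an administrative cut-off.

The covariate marginals are synthetic stand-ins (the motivating cohort's
individual-level values are not public) and are fully configurable through
:class:`CohortConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

COVARIATE_NAMES = ["age", "agemen", "biopsy", "ftp", "rel", "race"]

#: log hazard ratios for (AGE, AGEMEN, BIOPSY, FTP, REL, RACE)
DEFAULT_BETA = (0.028, -0.034, 0.431, -0.105, 0.541, 0.347)

#: AGE parent SD 4.8 gives a truncated-on-[30,50) SD of ~4.11, which makes
#: corr(Z, AGE) = 0.05*sd / sqrt(0.0025*sd^2 + 1) come out at ~0.20.
DEFAULT_COVARIATE_PARAMS = {
    "age_mean": 43.0,
    "age_sd": 4.8,
    "age_min": 30.0,
    "age_max": 50.0,
    "agemen_mean": 12.8,
    "agemen_sd": 1.5,
    "agemen_min": 9.0,
    "agemen_max": 17.0,
    "biopsy_prev": 0.15,
    "ftp_prev": 0.75,
    "rel_prev": 0.10,
    "race_prev": 0.80,
}


class CohortConfigError(ValueError):
    """Invalid data-generating parameters."""


class CensoringCalibrationError(ValueError):
    """Target event rate not attainable for any dropout rate."""


@dataclass
class CohortConfig:
    """All data-generating parameters for one synthetic cohort."""

    n_subjects: int = 2000
    beta_true: tuple = DEFAULT_BETA
    alpha_true: float = 0.2
    weibull_shape: float = 0.929
    weibull_scale: float = 0.002
    censor_rate_param: float | None = None
    admin_censor_time: float = 25.0
    target_event_rate: float = 0.05
    biomarker_intercept: float = -2.15
    biomarker_age_slope: float = 0.05
    biomarker_noise_sd: float = 1.0
    covariate_params: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_PARAMS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise CohortConfigError("n_subjects must be positive")
        if min(self.weibull_shape, self.weibull_scale, self.admin_censor_time) <= 0:
            raise CohortConfigError("Weibull and censoring parameters must be positive")
        if not 0 < self.target_event_rate < 1:
            raise CohortConfigError("target_event_rate must lie in (0, 1)")
        if len(self.beta_true) != len(COVARIATE_NAMES):
            raise CohortConfigError(
                f"beta_true must have {len(COVARIATE_NAMES)} entries"
            )
        if self.biomarker_noise_sd < 0:
            raise CohortConfigError("biomarker_noise_sd must be nonnegative")
        for key in ("age_sd", "agemen_sd"):
            if self.covariate_params[key] <= 0:
                raise CohortConfigError(f"{key} must be positive")
        for key in ("biopsy_prev", "ftp_prev", "rel_prev", "race_prev"):
            if not 0 <= self.covariate_params[key] <= 1:
                raise CohortConfigError(f"{key} must lie in [0, 1]")

    # -- flat key:value serialization ------------------------------------
    def to_file(self, path) -> None:
        lines = []
        for k, v in asdict(self).items():
            if k == "covariate_params":
                for ck, cv in v.items():
                    lines.append(f"covariate_params.{ck}: {cv!r}")
            else:
                lines.append(f"{k}: {v!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "CohortConfig":
        import ast

        kwargs: dict = {"covariate_params": {}}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            key, _, raw = line.partition(":")
            value = ast.literal_eval(raw.strip())
            key = key.strip()
            if key.startswith("covariate_params."):
                kwargs["covariate_params"][key.split(".", 1)[1]] = value
            else:
                kwargs[key] = value
        kwargs["beta_true"] = tuple(kwargs["beta_true"])
        return cls(**kwargs)


@dataclass
class Cohort:
    """Phase-I data for a full simulated cohort, plus the latent biomarker."""

    data: pd.DataFrame          # subject_id, time, event, <covariates>, z
    config: CohortConfig

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())

    @property
    def phase1_covariates(self) -> np.ndarray:
        return self.data[COVARIATE_NAMES].to_numpy()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, config: CohortConfig | None = None) -> "Cohort":
        return cls(pd.read_csv(path), config or CohortConfig())


def _truncnorm(mean, sd, lo, hi):
    return stats.truncnorm((lo - mean) / sd, (hi - mean) / sd, loc=mean, scale=sd)


def generate_phase1_covariates(
    config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw the six phase-I covariates for ``config.n_subjects`` subjects.

    AGE and AGEMEN are truncated normals; BIOPSY, FTP, REL and RACE are
    Bernoulli indicators coded 0/1.
    """
    cp = config.covariate_params
    n = config.n_subjects
    if cp["age_min"] >= cp["age_max"] or cp["agemen_min"] >= cp["agemen_max"]:
        raise CohortConfigError("truncation bounds must satisfy min < max")
    age = _truncnorm(cp["age_mean"], cp["age_sd"], cp["age_min"], cp["age_max"]).rvs(
        n, random_state=rng
    )
    agemen = _truncnorm(
        cp["agemen_mean"], cp["agemen_sd"], cp["agemen_min"], cp["agemen_max"]
    ).rvs(n, random_state=rng)
    return pd.DataFrame(
        {
            "age": age,
            "agemen": agemen,
            "biopsy": (rng.random(n) < cp["biopsy_prev"]).astype(float),
            "ftp": (rng.random(n) < cp["ftp_prev"]).astype(float),
            "rel": (rng.random(n) < cp["rel_prev"]).astype(float),
            "race": (rng.random(n) < cp["race_prev"]).astype(float),
        }
    )


def generate_biomarker(
    age: np.ndarray, config: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """Phase-II biomarker Z = intercept + slope * AGE + N(0, noise_sd^2)."""
    age = np.asarray(age, dtype=float)
    if age.size == 0:
        raise CohortConfigError("age vector is empty")
    eps = rng.standard_normal(age.size) * config.biomarker_noise_sd
    return config.biomarker_intercept + config.biomarker_age_slope * age + eps


def sample_event_times(
    linear_predictor: np.ndarray, shape: float, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Event times from a Cox model with Weibull baseline.

    Uses the inverse-cumulative-hazard transform: with E ~ Exponential(1),
    T* = (E / (scale * exp(lp)))^(1/shape), i.e. the baseline cumulative
    hazard is Lambda_0(t) = scale * t^shape (proportional-hazards
    shape/rate convention).
    """
    if shape <= 0 or scale <= 0:
        raise CohortConfigError("Weibull shape and scale must be positive")
    lp = np.asarray(linear_predictor, dtype=float)
    e = rng.exponential(size=lp.size)
    return (e / (scale * np.exp(lp))) ** (1.0 / shape)


_CALIBRATION_SEED = 714025  # internal stream: calibration is per-scenario
_CALIBRATION_N = 40000
_QUAD_NODES = 128


def expected_event_rate(config: CohortConfig, censor_rate: float) -> float:
    """Expected P(event observed) under exponential dropout ``censor_rate``.

    Marginalizes over a large fixed-seed covariate draw and integrates the
    event-time density against the censoring survival on [0, admin_censor]
    by Gauss-Legendre quadrature, so the result is smooth and monotone in
    the dropout rate (no Monte-Carlo noise in the event-time dimension).
    """
    rng = np.random.default_rng(_CALIBRATION_SEED)
    big = replace(config, n_subjects=_CALIBRATION_N, seed=_CALIBRATION_SEED)
    cov = generate_phase1_covariates(big, rng)
    z = generate_biomarker(cov["age"].to_numpy(), big, rng)
    lp = cov.to_numpy() @ np.asarray(config.beta_true) + config.alpha_true * z
    elp = np.exp(lp)
    k, lam, tau = config.weibull_shape, config.weibull_scale, config.admin_censor_time
    nodes, wts = np.polynomial.legendre.leggauss(_QUAD_NODES)
    t = 0.5 * tau * (nodes + 1.0)
    wq = 0.5 * tau * wts
    # f_{T*}(t | lp) = elp * lam * k * t^{k-1} * exp(-lam t^k elp)
    dens = elp[:, None] * lam * k * t[None, :] ** (k - 1.0) * np.exp(
        -lam * np.outer(elp, t**k)
    )
    return float(np.mean(dens @ (wq * np.exp(-censor_rate * t))))


def calibrate_censoring(config: CohortConfig, target_rate: float | None = None) -> float:
    """Find the exponential dropout rate lambda* hitting the target event rate.

    Solves ``expected_event_rate(config, lambda*) = target`` by bracketed
    root search; the left side is continuous and decreasing in lambda*.
    Raises :class:`CensoringCalibrationError`, reporting the achievable
    ceiling, when administrative censoring alone yields too few events.
    """
    target = config.target_event_rate if target_rate is None else target_rate
    if not 0 < target < 1:
        raise CohortConfigError("target_rate must lie in (0, 1)")
    ceiling = expected_event_rate(config, 0.0)
    if target > ceiling:
        raise CensoringCalibrationError(
            f"target event rate {target:.3f} exceeds the achievable ceiling "
            f"{ceiling:.4f} under administrative censoring alone"
        )
    hi = 1.0
    while expected_event_rate(config, hi) > target:
        hi *= 4.0
        if hi > 1e6:  # pragma: no cover
            raise CensoringCalibrationError("no bracket for censoring rate")
    return float(
        optimize.brentq(
            lambda s: expected_event_rate(config, s) - target, 0.0, hi, xtol=1e-10
        )
    )


def assemble_cohort(config: CohortConfig) -> Cohort:
    """Generate a full cohort: covariates, biomarker, event and censoring times.

    T = min(T*, C), delta = 1{T* <= C}, C = min(Exponential(lambda*),
    admin_censor_time).  If ``config.censor_rate_param`` is None, lambda* is
    calibrated to ``config.target_event_rate`` first.  Separate random
    streams drive covariates, event times and censoring, so cohorts with
    the same seed are reproducible draw-by-draw.
    """
    lam_star = config.censor_rate_param
    if lam_star is None:
        lam_star = calibrate_censoring(config)
    ss = np.random.SeedSequence(config.seed)
    rng_cov, rng_event, rng_cens = (np.random.default_rng(s) for s in ss.spawn(3))

    cov = generate_phase1_covariates(config, rng_cov)
    z = generate_biomarker(cov["age"].to_numpy(), config, rng_cov)
    lp = cov.to_numpy() @ np.asarray(config.beta_true) + config.alpha_true * z
    t_star = sample_event_times(lp, config.weibull_shape, config.weibull_scale, rng_event)
    drop = rng_cens.exponential(size=config.n_subjects) / max(lam_star, 1e-300)
    c = np.minimum(drop, config.admin_censor_time)
    data = pd.DataFrame({"subject_id": np.arange(config.n_subjects)})
    data["time"] = np.minimum(t_star, c)
    data["event"] = (t_star <= c).astype(int)
    data = pd.concat([data, cov], axis=1)
    data["z"] = z
    return Cohort(data=data, config=replace(config, censor_rate_param=lam_star))
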