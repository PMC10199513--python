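"""External working survival model on phase-I covariates.

The two-phase design needs a preliminary risk model that depends only on
the covariates available for the whole cohort.  In practice this can be a
published calculator (Gail model, Framingham score, ...); here it is built
by fitting a Cox model to a bootstrap-enlarged sample of the cohort's
phase-I data and pairing the coefficient vector eta with a Breslow
step-function baseline cumulative hazard, so that

    S_e(t | x) = exp(-Lambda_e0(t) * exp(eta' x)).

Any object exposing ``survival_at(t, x)`` can stand in for this class when
plugging in an externally published model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import COVARIATE_NAMES, Cohort
from .coxph import SurvivalData, breslow_baseline, fit_coxph


@dataclass
class ExternalModel:
    """Fitted working model: log-HRs eta and a step baseline cumulative hazard."""

    eta: np.ndarray
    jump_times: np.ndarray      # sorted event times of the fitting sample
    cumhaz: np.ndarray          # Lambda_e0 at each jump time (nondecreasing)
    names: list[str] = field(default_factory=lambda: list(COVARIATE_NAMES))
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.eta = np.asarray(self.eta, dtype=float)
        self.jump_times = np.asarray(self.jump_times, dtype=float)
        self.cumhaz = np.asarray(self.cumhaz, dtype=float)
        if np.any(np.diff(self.cumhaz) < 0) or (self.cumhaz.size and self.cumhaz[0] < 0):
            raise ValueError("baseline cumulative hazard must be nondecreasing from 0")

    def baseline_cumhaz_at(self, t) -> np.ndarray:
        """Right-continuous step evaluation of Lambda_e0; flat beyond last jump."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be nonnegative")
        idx = np.searchsorted(self.jump_times, t, side="right")
        padded = np.concatenate([[0.0], self.cumhaz])
        return padded[idx]

    def survival_at(self, t, x) -> np.ndarray | float:
        """S_e(t | x) = exp(-Lambda_e0(t) exp(eta'x)); vectorized over rows of x."""
        x = np.asarray(x, dtype=float)
        lp = x @ self.eta if x.ndim > 1 else float(x @ self.eta)
        out = np.exp(-self.baseline_cumhaz_at(t) * np.exp(lp))
        return out if np.ndim(out) else float(out)

    # -- two-part flat-file serialization --------------------------------
    def to_file(self, path) -> None:
        lines = ["[coefficients]"]
        lines += [f"{n}: {float(v)!r}" for n, v in zip(self.names, self.eta)]
        lines.append("[baseline]")
        lines += [
            f"{float(t)!r}\t{float(h)!r}"
            for t, h in zip(self.jump_times, self.cumhaz)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "ExternalModel":
        names, eta, jt, ch = [], [], [], []
        section = None
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("["):
                section = line
            elif section == "[coefficients]":
                n, _, v = line.partition(":")
                names.append(n.strip())
                eta.append(float(v))
            else:
                t, h = line.split("\t")
                jt.append(float(t))
                ch.append(float(h))
        return cls(eta=np.array(eta), jump_times=np.array(jt), cumhaz=np.array(ch),
                   names=names)


def fit_external(
    cohort: Cohort,
    bootstrap_size: int = 10000,
    seed: int | np.random.Generator = 0,
    resample: bool = True,
) -> ExternalModel:
    """Fit the working model on a bootstrap-enlarged phase-I sample.

    Draws ``bootstrap_size`` subjects with replacement from the cohort,
    fits an unweighted Cox model on the six phase-I covariates only (the
    biomarker is deliberately excluded: the working model must not depend
    on phase-II data), and estimates the Breslow baseline cumulative
    hazard from the same bootstrap sample.  With ``resample=False`` the
    cohort is used as-is (a degenerate identity "bootstrap").
    """
    if cohort.n_events < 1:
        raise ValueError("cohort has no events; cannot fit external model")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if resample:
        idx = rng.integers(0, cohort.n, size=bootstrap_size)
        boot = cohort.data.iloc[idx]
    else:
        boot = cohort.data
    data = SurvivalData(
        time=boot["time"].to_numpy(),
        event=boot["event"].to_numpy(),
        covariates=boot[COVARIATE_NAMES].to_numpy(),
        names=list(COVARIATE_NAMES),
    )
    fit = fit_coxph(data)
    times, ch = breslow_baseline(fit, data)
    return ExternalModel(
        eta=fit.coef,
        jump_times=times,
        cumhaz=ch,
        names=list(COVARIATE_NAMES),
        fit_meta={
            "bootstrap_size": bootstrap_size,
            "converged": fit.converged,
            "n_events": fit.n_events,
        },
    )
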