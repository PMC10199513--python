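"""Goodness-of-fit two-phase sampling design.

For each subject the design computes, from an external working model, the
lack-of-fit quantity

    D(T, delta, X) = | delta - 1 + S_e(T | X) |,

the absolute gap between the observed event status and the event
probability the working model predicts by the end of that subject's
follow-up.  D equals S_e(T|X) for cases and 1 - S_e(T|X) for controls:
subjects the external model describes poorly score high.  Phase-II
selection is independent Bernoulli with probability min{1, c_k D} (k = 0
controls, k = 1 cases); the constants c_k are calibrated so the expected
phase-II counts hit a prespecified case-control ratio.  By default all
cases are taken (probability 1) and only c_0 is calibrated on the
controls.  The balanced variant calibrates c_0 separately within strata of
phase-I covariates.  Selected subjects receive inverse-probability weights
for the downstream Cox fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .cohort import Cohort
from .external import ExternalModel


class GofDesignError(ValueError):
    """Infeasible calibration or degenerate strata."""


@dataclass
class GofDesignConfig:
    """Sampling targets for the GOF two-phase design.

    ``case_control_ratio`` is controls per case (1.0 for 1:1, 2.0 for 1:2).
    ``strata`` is an optional callable mapping a :class:`Cohort` to an
    integer/str label per subject (see :func:`median_age_strata`).
    ``case_target`` is only used when ``include_all_cases`` is False and
    sets the expected number of sampled cases (no default: the design
    normally keeps every case).  ``prob_floor`` optionally bounds selection
    probabilities away from 0 among subjects with positive D.
    """

    case_control_ratio: float = 1.0
    include_all_cases: bool = True
    strata: Callable[[Cohort], np.ndarray] | None = None
    case_target: float | None = None
    prob_floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.case_control_ratio <= 0:
            raise GofDesignError("case_control_ratio must be positive")
        if not 0 <= self.prob_floor < 1:
            raise GofDesignError("prob_floor must lie in [0, 1)")


@dataclass
class PhaseTwoSample:
    """Outcome of one phase-II selection draw."""

    selected: np.ndarray            # 0/1 per cohort subject
    prob: np.ndarray                # selection probability per subject
    weight: np.ndarray              # 1/prob for selected subjects, 0 otherwise
    constants: dict                 # {stratum: {"c0": ..., "c1": ...}}
    d_values: np.ndarray | None = None
    strata_labels: np.ndarray | None = None
    expected_controls: float = 0.0

    @property
    def realized_m(self) -> int:
        return int(self.selected.sum())

    def to_frame(self, cohort: Cohort) -> pd.DataFrame:
        lab = self.strata_labels
        return pd.DataFrame(
            {
                "subject_id": cohort.data["subject_id"],
                "selected": self.selected.astype(int),
                "prob": self.prob,
                "weight": self.weight,
                "stratum": lab if lab is not None else np.zeros(cohort.n, dtype=int),
                "D": self.d_values if self.d_values is not None else np.nan,
            }
        )


def gof_quantity(event, s_e):
    """Lack-of-fit D = |delta - 1 + S_e(T|X)|, elementwise."""
    event = np.asarray(event, dtype=float)
    s_e = np.asarray(s_e, dtype=float)
    if np.any(s_e <= 0) or np.any(s_e > 1):
        raise GofDesignError("external survival probabilities must lie in (0, 1]")
    return np.abs(event - 1.0 + s_e)


def calibrate_constant(d_values: np.ndarray, target_expected_size: float) -> float:
    """Solve ``sum_i min(1, c * d_i) = target`` for c > 0 by bisection.

    The left side is continuous, piecewise linear and nondecreasing in c,
    saturating at the number of positive d values; a target above that
    ceiling is infeasible.
    """
    d = np.asarray(d_values, dtype=float)
    if np.any(d < 0):
        raise GofDesignError("D values must be nonnegative")
    n_pos = int(np.sum(d > 0))
    if n_pos == 0:
        raise GofDesignError("all D values are zero; nothing selectable")
    if not 0 < target_expected_size <= n_pos:
        raise GofDesignError(
            f"target expected size {target_expected_size} infeasible; at most "
            f"{n_pos} subjects have positive D"
        )

    def expected(c):
        return float(np.minimum(1.0, c * d).sum())

    lo, hi = 0.0, 1.0 / max(d.max(), 1e-300)
    while expected(hi) < target_expected_size - 1e-12:
        hi *= 2.0
        if hi > 1e30:
            break
    # bisection on a monotone piecewise-linear function
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected(mid) < target_expected_size:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6 * max(hi, 1.0) and abs(expected(hi) - target_expected_size) < 1e-9:
            break
    c = hi
    if abs(expected(c) - target_expected_size) > 1e-5:
        # saturated exactly at the ceiling: any c capping all positives works
        if target_expected_size >= n_pos - 1e-9:
            return float(1.0 / d[d > 0].min())
        raise GofDesignError("calibration failed to meet target")  # pragma: no cover
    return float(c)


def compute_d(cohort: Cohort, external: ExternalModel) -> np.ndarray:
    """D for every cohort subject from the external model's survival."""
    s_e = external.survival_at(
        cohort.data["time"].to_numpy(), cohort.data[external.names].to_numpy()
    )
    return gof_quantity(cohort.data["event"].to_numpy(), s_e)


def _probabilities_one_stratum(
    event: np.ndarray, d: np.ndarray, config: GofDesignConfig
) -> tuple[np.ndarray, dict]:
    cases = event == 1
    n_cases = int(cases.sum())
    if n_cases == 0:
        raise GofDesignError("stratum contains no cases")
    prob = np.zeros(event.size)
    consts: dict = {}
    if config.include_all_cases:
        prob[cases] = 1.0
        consts["c1"] = np.inf
    else:
        if config.case_target is None:
            raise GofDesignError(
                "case_target is required when include_all_cases is False"
            )
        c1 = calibrate_constant(d[cases], config.case_target)
        prob[cases] = np.minimum(1.0, c1 * d[cases])
        consts["c1"] = c1
    expected_cases = float(prob[cases].sum())
    target_controls = config.case_control_ratio * expected_cases
    c0 = calibrate_constant(d[~cases], target_controls)
    prob[~cases] = np.minimum(1.0, c0 * d[~cases])
    if config.prob_floor > 0:
        positive = prob > 0
        prob[positive] = np.maximum(prob[positive], config.prob_floor)
    consts["c0"] = c0
    consts["expected_controls"] = float(prob[~cases].sum())
    return prob, consts


def select_phase2(
    cohort: Cohort,
    external: ExternalModel,
    config: GofDesignConfig,
    rng: np.random.Generator | None = None,
) -> PhaseTwoSample:
    """Draw one unstratified GOF phase-II sample.

    All cases enter with probability 1 (default); the control constant c_0
    is calibrated so the expected control count equals
    ``ratio * (number of cases)``.  Controls whose fit is perfect (D = 0)
    have selection probability exactly 0.
    """
    if config.strata is not None:
        return select_phase2_balanced(cohort, external, config, rng)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    d = compute_d(cohort, external)
    event = cohort.data["event"].to_numpy()
    prob, consts = _probabilities_one_stratum(event, d, config)
    selected = (rng.random(cohort.n) < prob).astype(int)
    weight = np.where(selected == 1, 1.0 / np.where(prob > 0, prob, np.inf), 0.0)
    return PhaseTwoSample(
        selected=selected,
        prob=prob,
        weight=weight,
        constants={"all": consts},
        d_values=d,
        strata_labels=None,
        expected_controls=consts["expected_controls"],
    )


def select_phase2_balanced(
    cohort: Cohort,
    external: ExternalModel,
    config: GofDesignConfig,
    rng: np.random.Generator | None = None,
) -> PhaseTwoSample:
    """Balanced (stratified) GOF selection: per-stratum calibration of c_0.

    Within each stratum the expected control count equals
    ``ratio * (stratum case count)``, so strata with different D
    distributions get different sampling constants.
    """
    if config.strata is None:
        raise GofDesignError("balanced selection requires a strata rule")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    labels = np.asarray(config.strata(cohort))
    d = compute_d(cohort, external)
    event = cohort.data["event"].to_numpy()
    prob = np.zeros(cohort.n)
    constants: dict = {}
    expected_controls = 0.0
    for lab in np.unique(labels):
        mask = labels == lab
        if not np.any(event[mask] == 1):
            raise GofDesignError(f"stratum {lab!r} contains no cases")
        prob[mask], consts = _probabilities_one_stratum(event[mask], d[mask], config)
        constants[lab] = consts
        expected_controls += consts["expected_controls"]
    selected = (rng.random(cohort.n) < prob).astype(int)
    weight = np.where(selected == 1, 1.0 / np.where(prob > 0, prob, np.inf), 0.0)
    return PhaseTwoSample(
        selected=selected,
        prob=prob,
        weight=weight,
        constants=constants,
        d_values=d,
        strata_labels=labels,
        expected_controls=expected_controls,
    )


def median_age_strata(cohort: Cohort) -> np.ndarray:
    """Two strata split at the cohort's median AGE (>= median is stratum 1)."""
    age = cohort.data["age"].to_numpy()
    return (age >= np.median(age)).astype(int)
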