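"""Comparator case-cohort designs.

A classic case-cohort study draws a simple random subcohort (optionally
within strata) and assays the phase-II covariate on the subcohort plus all
cases.  Analysis uses inverse-selection-probability weights: cases weight
1, non-case subcohort members weight 1/q with q the realized non-case
sampling fraction (per stratum when stratified).  This weighted form is
the common reduction of the Prentice (unstratified) and Borgan I
(stratified) estimators, so differences from the GOF design in simulation
reflect the sampling designs, not the estimation technique.  The
time-shifted Prentice pseudo-likelihood risk-set convention is deliberately
not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .cohort import Cohort
from .gof import PhaseTwoSample


class CCDesignError(ValueError):
    """Infeasible subcohort sizes."""


@dataclass
class CCDesignConfig:
    """Subcohort size(s) and optional stratification for a case-cohort draw.

    ``subcohort_size`` is either an int (unstratified SRS from the whole
    cohort) or a dict mapping stratum label to a per-stratum size.
    """

    subcohort_size: int | dict
    strata: Callable[[Cohort], np.ndarray] | None = None
    seed: int = 0


def sample_subcohort(
    cohort: Cohort, config: CCDesignConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw the subcohort indicator by SRS without replacement.

    Unstratified: ``subcohort_size`` subjects from the full cohort.
    Stratified: per-stratum sizes from each stratum.  The phase-II set is
    the union of the subcohort and all cases (see :func:`cc_weights`).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    indicator = np.zeros(cohort.n, dtype=int)
    if config.strata is None:
        size = int(config.subcohort_size)
        if not 0 <= size <= cohort.n:
            raise CCDesignError(f"subcohort size {size} outside [0, {cohort.n}]")
        indicator[rng.choice(cohort.n, size=size, replace=False)] = 1
    else:
        labels = np.asarray(config.strata(cohort))
        sizes = config.subcohort_size
        if not isinstance(sizes, dict):
            raise CCDesignError("stratified design needs per-stratum sizes (dict)")
        for lab in np.unique(labels):
            idx = np.nonzero(labels == lab)[0]
            size = int(sizes.get(lab, 0))
            if size > idx.size:
                raise CCDesignError(
                    f"stratum {lab!r}: requested {size} of {idx.size} subjects"
                )
            indicator[rng.choice(idx, size=size, replace=False)] = 1
    return indicator


def cc_weights(
    cohort: Cohort,
    subcohort: np.ndarray,
    strata: Callable[[Cohort], np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-subcohort-probability weights for the case-cohort analysis.

    Returns ``(selected, weight)`` over the full cohort: cases always
    selected with weight 1; non-case subcohort members weight 1/q with q
    the realized fraction of non-cases sampled (per stratum when a strata
    rule is given); other non-cases excluded (weight 0).
    """
    event = cohort.data["event"].to_numpy()
    subcohort = np.asarray(subcohort)
    labels = (
        np.zeros(cohort.n, dtype=int) if strata is None else np.asarray(strata(cohort))
    )
    selected = ((event == 1) | (subcohort == 1)).astype(int)
    weight = np.zeros(cohort.n)
    weight[event == 1] = 1.0
    for lab in np.unique(labels):
        mask = (labels == lab) & (event == 0)
        n_controls = int(mask.sum())
        m_controls = int((mask & (subcohort == 1)).sum())
        take = mask & (subcohort == 1)
        if m_controls == 0:
            if np.any(take):  # pragma: no cover - impossible by construction
                raise CCDesignError(f"stratum {lab!r}: selected controls with q = 0")
            continue
        weight[take] = n_controls / m_controls
    return selected, weight


def match_to_gof_size(gof_sample: PhaseTwoSample, cohort: Cohort) -> CCDesignConfig:
    """Size-match a case-cohort design to a realized GOF design.

    Sets ``subcohort_size = round(expected GOF controls / (1 - event
    proportion))`` so expected total phase-II sizes agree (the subcohort
    contains cases at the cohort event rate, and cases are added anyway).
    Matched per stratum when the GOF sample was stratified.
    """
    event = cohort.data["event"].to_numpy()
    if gof_sample.strata_labels is None:
        p = event.mean()
        size = int(round(gof_sample.expected_controls / (1.0 - p)))
        return CCDesignConfig(subcohort_size=min(size, cohort.n), strata=None)
    labels = gof_sample.strata_labels
    sizes = {}
    for lab in np.unique(labels):
        mask = labels == lab
        p = event[mask].mean()
        expected = gof_sample.constants[lab]["expected_controls"]
        sizes[lab] = min(int(round(expected / (1.0 - p))), int(mask.sum()))
    return CCDesignConfig(subcohort_size=sizes, strata=lambda c, _l=labels: _l)


def cc_sample_frame(
    cohort: Cohort, selected: np.ndarray, weight: np.ndarray, subcohort: np.ndarray
) -> pd.DataFrame:
    """Tabular export with the same schema as the GOF phase-II table."""
    q = np.where(weight > 0, 1.0 / np.where(weight > 0, weight, np.inf), 0.0)
    return pd.DataFrame(
        {
            "subject_id": cohort.data["subject_id"],
            "selected": np.asarray(selected, dtype=int),
            "prob": q,
            "weight": weight,
            "stratum": 0,
            "D": np.nan,
            "in_subcohort": np.asarray(subcohort, dtype=int),
        }
    )
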