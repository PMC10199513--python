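"""Monte-Carlo engine comparing sub-cohort sampling designs.

For each replicate one cohort is generated and every requested design is
applied to that same cohort: the full-cohort Cox fit (gold standard), the
GOF two-phase design with IPW estimation, and a size-matched case-cohort
design with inverse-subcohort-probability weights.  Across replicates the
engine reports the standard design-comparison measures: bias, empirical
SD, mean asymptotic (robust) SE, 95% CI coverage, rejection rate of the
Wald test (type-I error under a null biomarker, power otherwise), realized
phase-II sizes, and relative efficiency as the averaged ratio of robust
variances.  Monte-Carlo standard errors accompany every summary so
comparisons between designs are principled.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cc import CCDesignConfig, cc_weights, match_to_gof_size, sample_subcohort
from .cohort import (
    COVARIATE_NAMES,
    CohortConfig,
    DEFAULT_BETA,
    assemble_cohort,
    calibrate_censoring,
)
from .coxph import CoxEstimationError, SurvivalData, fit_coxph
from .external import ExternalModel, fit_external
from .gof import GofDesignConfig, median_age_strata, select_phase2

TERMS = COVARIATE_NAMES + ["z"]
DESIGNS = ("full_cohort", "gof_two_phase", "case_cohort")
_ALIAS = {"full": "full_cohort", "gof": "gof_two_phase", "cc": "case_cohort"}

_Z975 = 1.959963984540054


@dataclass
class ScenarioConfig:
    """One simulation scenario (a row block of the design-comparison study)."""

    name: str = "scenario"
    event_rate: float = 0.05
    alpha_true: float = 0.2
    ratio: float = 1.0                     # controls per case in the GOF design
    stratification: str = "unstratified"   # or "by_median_age"
    n_replicates: int = 500
    n_subjects: int = 2000
    designs: tuple = DESIGNS
    master_seed: int = 0
    beta_true: tuple = DEFAULT_BETA
    bootstrap_size: int = 10000
    refit_external: bool = True            # refit working model per replicate

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be at least 2")
        if self.stratification not in ("unstratified", "by_median_age"):
            raise ValueError(f"unknown stratification {self.stratification!r}")
        self.designs = tuple(_ALIAS.get(d, d) for d in self.designs)
        unknown = set(self.designs) - set(DESIGNS)
        if unknown:
            raise ValueError(f"unknown designs {sorted(unknown)}")

    def truth(self) -> dict:
        t = dict(zip(COVARIATE_NAMES, self.beta_true))
        t["z"] = self.alpha_true
        return t


def _strata_rule(scenario: ScenarioConfig):
    return median_age_strata if scenario.stratification == "by_median_age" else None


def calibrate_scenario(scenario: ScenarioConfig) -> float:
    """Censoring rate lambda* for this scenario (done once, not per replicate)."""
    config = CohortConfig(
        n_subjects=scenario.n_subjects,
        beta_true=tuple(scenario.beta_true),
        alpha_true=scenario.alpha_true,
        target_event_rate=scenario.event_rate,
    )
    return calibrate_censoring(config)


def _design_record(design: str, fit, m: int) -> dict:
    rec = {"design": design, "converged": bool(fit.converged), "m": m}
    for name, c, s in zip(fit.names, fit.coef, fit.se_robust):
        rec[f"coef_{name}"] = c
        rec[f"se_{name}"] = s
    return rec


def _failed_record(design: str, m: int = 0) -> dict:
    rec = {"design": design, "converged": False, "m": m}
    for name in TERMS:
        rec[f"coef_{name}"] = np.nan
        rec[f"se_{name}"] = np.nan
    return rec


def run_replicate(
    scenario: ScenarioConfig,
    replicate_index: int,
    censor_rate: float | None = None,
    external: ExternalModel | None = None,
) -> list[dict]:
    """Generate one cohort and apply every requested design to it.

    A per-replicate seed is derived from ``(master_seed, replicate_index)``
    and split into separate streams for the cohort draw, the external-model
    bootstrap, the GOF Bernoulli draw and the subcohort draw, so designs
    are compared on identical cohorts and the call is fully reproducible.
    Per-design estimation failures are recorded as non-converged rows; the
    replicate is retained for the other designs.
    """
    if censor_rate is None:
        censor_rate = calibrate_scenario(scenario)
    ss = np.random.SeedSequence(scenario.master_seed, spawn_key=(replicate_index,))
    s_cohort, s_ext, s_gof, s_cc = ss.spawn(4)
    config = CohortConfig(
        n_subjects=scenario.n_subjects,
        beta_true=tuple(scenario.beta_true),
        alpha_true=scenario.alpha_true,
        censor_rate_param=censor_rate,
        target_event_rate=scenario.event_rate,
        seed=int(s_cohort.generate_state(1)[0] & 0x7FFFFFFF),
    )
    cohort = assemble_cohort(config)
    df = cohort.data
    X_full = df[TERMS].to_numpy()
    records: list[dict] = []
    strata = _strata_rule(scenario)

    if "full_cohort" in scenario.designs:
        try:
            fit = fit_coxph(
                SurvivalData(df["time"], df["event"], X_full, names=TERMS)
            )
            records.append(_design_record("full_cohort", fit, cohort.n))
        except CoxEstimationError:
            records.append(_failed_record("full_cohort", cohort.n))

    need_gof = {"gof_two_phase", "case_cohort"} & set(scenario.designs)
    gof_sample = None
    if need_gof:
        try:
            ext = external
            if ext is None or scenario.refit_external:
                ext = fit_external(
                    cohort,
                    bootstrap_size=scenario.bootstrap_size,
                    seed=np.random.default_rng(s_ext),
                )
            gof_config = GofDesignConfig(
                case_control_ratio=scenario.ratio, strata=strata
            )
            gof_sample = select_phase2(
                cohort, ext, gof_config, rng=np.random.default_rng(s_gof)
            )
        except Exception:
            gof_sample = None

    if "gof_two_phase" in scenario.designs:
        if gof_sample is None:
            records.append(_failed_record("gof_two_phase"))
        else:
            sel = gof_sample.selected == 1
            try:
                fit = fit_coxph(
                    SurvivalData(
                        df["time"].to_numpy()[sel],
                        df["event"].to_numpy()[sel],
                        X_full[sel],
                        weights=gof_sample.weight[sel],
                        names=TERMS,
                    )
                )
                records.append(
                    _design_record("gof_two_phase", fit, int(sel.sum()))
                )
            except CoxEstimationError:
                records.append(_failed_record("gof_two_phase", int(sel.sum())))

    if "case_cohort" in scenario.designs:
        try:
            if gof_sample is not None:
                cc_config = match_to_gof_size(gof_sample, cohort)
            else:  # pragma: no cover - only if GOF selection failed
                n_cases = cohort.n_events
                p = n_cases / cohort.n
                cc_config = CCDesignConfig(
                    subcohort_size=int(round(scenario.ratio * n_cases / (1 - p)))
                )
            subcoh = sample_subcohort(
                cohort, cc_config, rng=np.random.default_rng(s_cc)
            )
            selected, weight = cc_weights(cohort, subcoh, strata=cc_config.strata)
            sel = selected == 1
            fit = fit_coxph(
                SurvivalData(
                    df["time"].to_numpy()[sel],
                    df["event"].to_numpy()[sel],
                    X_full[sel],
                    weights=weight[sel],
                    names=TERMS,
                )
            )
            records.append(_design_record("case_cohort", fit, int(sel.sum())))
        except (CoxEstimationError, ValueError):
            records.append(_failed_record("case_cohort"))

    for rec in records:
        rec["replicate"] = replicate_index
        rec["n_events"] = cohort.n_events
    return records


def run_scenario(
    scenario: ScenarioConfig,
    censor_rate: float | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run all replicates of one scenario; returns the per-replicate table."""
    if censor_rate is None:
        censor_rate = calibrate_scenario(scenario)
    rows: list[dict] = []
    for r in range(scenario.n_replicates):
        rows.extend(run_replicate(scenario, r, censor_rate=censor_rate))
        if progress and (r + 1) % 100 == 0:  # pragma: no cover
            print(f"  [{scenario.name}] replicate {r + 1}/{scenario.n_replicates}")
    out = pd.DataFrame(rows)
    out.insert(0, "scenario", scenario.name)
    return out


def summarize(
    replicates: pd.DataFrame, truth: dict, terms: list[str] | None = None
) -> pd.DataFrame:
    """Per-design performance measures over converged replicates.

    bias = mean(estimate) - truth; emp_sd = sample SD of estimates;
    mean_se / sd_se = moments of the robust SEs; coverage_95 = fraction of
    replicates whose 95% CI contains the truth; rejection_rate = fraction
    with two-sided Wald p < 0.05.  Binomial and emp_sd/sqrt(R) Monte-Carlo
    standard errors are attached to the proportion and bias columns.
    """
    terms = terms if terms is not None else [t for t in TERMS if f"coef_{t}" in replicates]
    rows = []
    for design, grp in replicates.groupby("design", sort=False):
        conv = grp[grp["converged"]]
        n_conv = len(conv)
        if n_conv < 2:
            raise ValueError(f"design {design!r}: fewer than 2 converged replicates")
        for term in terms:
            est = conv[f"coef_{term}"].to_numpy()
            se = conv[f"se_{term}"].to_numpy()
            tv = truth[term]
            cover = np.abs(est - tv) <= _Z975 * se
            reject = np.abs(est / se) > _Z975
            rows.append(
                {
                    "design": design,
                    "estimator": "ipw" if design != "full_cohort" else "cox",
                    "coefficient": term,
                    "truth": tv,
                    "bias": est.mean() - tv,
                    "bias_mc_se": est.std(ddof=1) / np.sqrt(n_conv),
                    "emp_sd": est.std(ddof=1),
                    "mean_se": se.mean(),
                    "sd_se": se.std(ddof=1),
                    "coverage_95": cover.mean(),
                    "coverage_mc_se": np.sqrt(cover.mean() * (1 - cover.mean()) / n_conv),
                    "rejection_rate": reject.mean(),
                    "rejection_mc_se": np.sqrt(
                        reject.mean() * (1 - reject.mean()) / n_conv
                    ),
                    "mean_realized_m": conv["m"].mean(),
                    "n_converged": n_conv,
                }
            )
    return pd.DataFrame(rows)


def relative_efficiency(variances_a, variances_b) -> float:
    """Averaged per-replicate ratio of asymptotic variances, mean(var_a / var_b)."""
    a = np.asarray(variances_a, dtype=float)
    b = np.asarray(variances_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("variance vectors must be paired by replicate")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("variances must be positive")
    return float(np.mean(a / b))


def scenario_from_dict(d: dict) -> ScenarioConfig:
    d = dict(d)
    if "designs" in d:
        d["designs"] = tuple(d["designs"])
    for key in ("beta_true",):
        if key in d:
            d[key] = tuple(d[key])
    return ScenarioConfig(**d)


def load_scenarios(path) -> list[ScenarioConfig]:
    """Read one scenario or a list of scenarios from a YAML file."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    if isinstance(raw, dict):
        raw = raw.get("scenarios", [raw])
    return [scenario_from_dict(d) for d in raw]


def run_study(
    scenarios: list[ScenarioConfig], out_dir, progress: bool = False
) -> pd.DataFrame:
    """Run a list of scenarios, writing per-scenario and combined tables.

    Writes ``<name>_replicates.csv`` and ``<name>_metrics.csv`` per
    scenario, a ``combined_metrics.csv`` across scenarios (rows indexed by
    stratification, event rate, true log HR and ratio, one block per
    design), and a flat ``manifest.txt`` recording configs, seeds and wall
    time.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = _time.time()
    combined = []
    manifest: list[str] = []
    for sc in scenarios:
        censor_rate = calibrate_scenario(sc)
        reps = run_scenario(sc, censor_rate=censor_rate, progress=progress)
        reps.to_csv(out / f"{sc.name}_replicates.csv", index=False)
        metrics = summarize(reps, sc.truth())
        for col, val in (
            ("stratification", sc.stratification),
            ("ratio", sc.ratio),
            ("alpha_true", sc.alpha_true),
            ("event_rate", sc.event_rate),
            ("scenario", sc.name),
        ):
            metrics.insert(0, col, val)
        metrics.to_csv(out / f"{sc.name}_metrics.csv", index=False)
        combined.append(metrics)
        for k, v in asdict(sc).items():
            manifest.append(f"{sc.name}.{k}: {v}")
        manifest.append(f"{sc.name}.censor_rate: {censor_rate!r}")
    combined_df = (
        pd.concat(combined, ignore_index=True) if combined else pd.DataFrame()
    )
    combined_df.to_csv(out / "combined_metrics.csv", index=False)
    import gofsurv

    manifest.append(f"gofsurv_version: {gofsurv.__version__}")
    manifest.append(f"wall_time_s: {_time.time() - t0:.1f}")
    (out / "manifest.txt").write_text("\n".join(manifest) + "\n")
    return combined_df


def summarize_study(results_dir) -> pd.DataFrame:
    """Regenerate metric tables from stored per-replicate fits."""
    out = Path(results_dir)
    combined = []
    for rep_file in sorted(out.glob("*_replicates.csv")):
        name = rep_file.name[: -len("_replicates.csv")]
        reps = pd.read_csv(rep_file)
        truth = _truth_from_manifest(out / "manifest.txt", name)
        metrics = summarize(reps, truth)
        metrics.insert(0, "scenario", name)
        combined.append(metrics)
    combined_df = (
        pd.concat(combined, ignore_index=True) if combined else pd.DataFrame()
    )
    combined_df.to_csv(out / "combined_metrics.csv", index=False)
    return combined_df


def _truth_from_manifest(manifest_path, scenario_name) -> dict:
    import ast

    alpha, beta = 0.2, DEFAULT_BETA
    for line in Path(manifest_path).read_text().splitlines():
        key, _, val = line.partition(":")
        if key.strip() == f"{scenario_name}.alpha_true":
            alpha = float(val)
        elif key.strip() == f"{scenario_name}.beta_true":
            beta = tuple(ast.literal_eval(val.strip()))
    truth = dict(zip(COVARIATE_NAMES, beta))
    truth["z"] = alpha
    return truth


def plot_se_comparison(combined: pd.DataFrame, path, coefficient: str = "z") -> None:
    """Bar chart of mean robust SE of one coefficient by design and scenario."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = combined[combined["coefficient"] == coefficient]
    fig, ax = plt.subplots(figsize=(7, 4))
    scen = sub["scenario"].unique() if "scenario" in sub else ["study"]
    width = 0.8 / max(len(sub["design"].unique()), 1)
    for i, design in enumerate(sub["design"].unique()):
        vals = [
            sub[(sub["design"] == design) & (sub.get("scenario", "study") == s)][
                "mean_se"
            ].mean()
            for s in scen
        ]
        ax.bar(np.arange(len(scen)) + i * width, vals, width, label=design)
    ax.set_xticks(np.arange(len(scen)) + width)
    ax.set_xticklabels(scen, rotation=30, ha="right")
    ax.set_ylabel(f"mean robust SE of {coefficient}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
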