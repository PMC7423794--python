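"""Pipeline orchestration: binds cohort simulation, longitudinal
prediction, survival fitting, the Markov cost-utility model and the
sensitivity analyses into reproducible staged runs with headered CSV
outputs."""

from __future__ import annotations

import logging
import pathlib
from dataclasses import replace

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .economics import CostTable, DiscountSpec, UtilityTable
from .icsurv import stepwise_select
from .longitudinal import fit_quadratic_mixed
from .markov import (
    CohortStratum,
    LifeTable,
    StrategySpec,
    TransitionModel,
    WeibullOnset,
    default_transition_tables,
    run_cohort,
    synthetic_life_table,
)
from .params import (
    load_cost_table,
    load_survival_fit,
    load_transition_tables,
    load_utility_table,
    save_survival_fit,
    write_default_parameter_files,
)
from .sensitivity import (
    ModelBundle,
    PSASpec,
    ScenarioGridSpec,
    ceac,
    evaluate_strategy_pair,
    prob_cost_effective,
    run_psa,
    run_scenarios,
)
from .synth import CohortDataset, GeneratorConfig, SchedulePolicy, generate_cohort, read_records_csv

log = logging.getLogger("drscreen")

#: Published cohort weights used to aggregate per-type results.
POPULATION_WEIGHTS = {"T1DM": 5003.0, "T2DM": 86390.0}
BASE_AGES = {"T1DM": 22.7, "T2DM": 62.3}
BASE_COVARIATES = {
    "T1DM": {"hba1c": 8.7, "duration": 7.8, "sbp": 121.7, "tchol": 4.5, "bmi": 24.1, "smoker": 0.038},
    "T2DM": {"hba1c": 7.5, "duration": 4.2, "sbp": 138.2, "tchol": 4.6, "bmi": 32.3, "smoker": 0.387},
}


def _write_csv(df: pd.DataFrame, path, cfg: RunConfig, seed: int) -> None:
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# drscreen {__version__} seed={seed} config_digest={cfg.digest()}\n")
        df.to_csv(fh, index=False)


def generator_config_from(cfg: RunConfig) -> GeneratorConfig:
    g = GeneratorConfig.default(n_t1dm=cfg.cohort.n_t1dm, n_t2dm=cfg.cohort.n_t2dm)
    g.schedule = SchedulePolicy(
        interval_years=cfg.cohort.screening_interval_years,
        jitter_years=cfg.cohort.jitter_years,
        followup_years=cfg.cohort.followup_years,
    )
    return g


def load_tables(cfg: RunConfig):
    """Load parameter tables from configured paths, falling back to the
    shipped defaults, logging the provenance of each."""
    p = cfg.paths
    costs = load_cost_table(p.costs) if p.costs else CostTable()
    log.info("cost table: %s", "user-supplied" if p.costs else "published-table defaults")
    utilities = load_utility_table(p.utilities) if p.utilities else UtilityTable()
    log.info("utility table: %s", "user-supplied" if p.utilities else "published RDR weights + non-study pre-RDR default")
    tables = load_transition_tables(p.transitions) if p.transitions else default_transition_tables()
    log.info("transition tables: %s", "user-supplied" if p.transitions else "synthetic fixture defaults")
    life = LifeTable.from_csv(p.life_table) if p.life_table else synthetic_life_table()
    log.info("life table: %s", "user-supplied" if p.life_table else "synthetic national-style table")
    return costs, utilities, tables, life


# ---------------------------------------------------------------------------
# stages


def simulate_stage(cfg: RunConfig, seed: int, outdir: pathlib.Path) -> CohortDataset:
    log.info("simulate: n_t1dm=%d n_t2dm=%d", cfg.cohort.n_t1dm, cfg.cohort.n_t2dm)
    cohort = generate_cohort(generator_config_from(cfg), seed)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.write_csv(outdir)
    log.info("simulate: %d subjects, %d screening events", len(cohort.profiles), len(cohort.events))
    return cohort


def _predict_hba1c_at_left(cohort: CohortDataset, max_subjects: int, seed: int) -> pd.Series:
    """Replace the HbA1c covariate with the multilevel-model prediction at
    the left censoring endpoint (the last event-free screen)."""
    meas = cohort.measurements
    hba = meas[meas["analyte"] == "hba1c"]
    subjects = hba["subject_id"].unique()
    rng = np.random.default_rng(seed)
    sample = (
        rng.choice(subjects, size=max_subjects, replace=False)
        if len(subjects) > max_subjects
        else subjects
    )
    fit = fit_quadratic_mixed(hba[hba["subject_id"].isin(sample)])
    log.info(
        "longitudinal: fitted on %d subjects; sigma2=%.4f converged=%s",
        len(sample), fit.residual_var, fit.converged,
    )
    grouped = {sid: g for sid, g in hba.groupby("subject_id")}
    preds = np.empty(len(cohort.records))
    lefts = cohort.records["left"].to_numpy()
    for i, (sid, left) in enumerate(zip(cohort.records["subject_id"], lefts)):
        g = grouped[sid]
        coef = fit.blup(g["time_years"].to_numpy(), g["value"].to_numpy())
        preds[i] = (fit.basis([left]) @ coef)[0]
    return pd.Series(preds, index=cohort.records.index)


def fit_stage(cfg: RunConfig, seed: int, outdir: pathlib.Path, cohort: CohortDataset | None = None):
    if cohort is None:
        rec_path = outdir / "records.csv"
        if not rec_path.exists():
            raise FileNotFoundError(f"no records file at {rec_path}; run simulate first")
        records = read_records_csv(rec_path)
        cohort = None
    else:
        records = cohort.records
    if cohort is not None and cfg.survival.use_longitudinal:
        records = records.copy()
        records["hba1c"] = _predict_hba1c_at_left(
            cohort, cfg.survival.longitudinal_max_subjects, seed + 101
        ).to_numpy()

    fits = {}
    for dtype in ("T1DM", "T2DM"):
        rec = records[records["diabetes_type"] == dtype]
        if len(rec) == 0:
            continue
        candidates = [c for c in cfg.survival.candidates if c in rec.columns]
        fit = stepwise_select(rec, candidates, cfg.survival.alpha, seed=seed)
        fits[dtype] = fit
        log.info(
            "fit-survival %s: p=%.3f covariates=%s loglik=%.1f",
            dtype, fit.p, fit.covariate_names, fit.loglik,
        )
        save_survival_fit(fit, outdir / f"survival_fit_{dtype.lower()}.yaml")
    return fits


def build_bundle(cfg: RunConfig, fits) -> ModelBundle:
    costs, utilities, tables, life = load_tables(cfg)
    onset = {dtype: WeibullOnset(fit) for dtype, fit in fits.items()}
    model = TransitionModel(onset=onset, tables=tables, life_table=life)
    strata = {
        dtype: CohortStratum(
            diabetes_type=dtype,
            age_at_entry=BASE_AGES[dtype],
            covariates=dict(BASE_COVARIATES[dtype]),
            weight=POPULATION_WEIGHTS[dtype],
        )
        for dtype in fits
    }
    annual = StrategySpec("annual", 1.0, cfg.analysis.eligibility_rule)
    biennial = StrategySpec("biennial", 2.0, cfg.analysis.eligibility_rule)
    return ModelBundle(
        model=model,
        costs=costs,
        utilities=utilities,
        discount=DiscountSpec(rate=cfg.analysis.discount_rate),
        strata=strata,
        annual=annual,
        biennial=biennial,
        horizon_age=cfg.analysis.horizon_age,
        threshold=cfg.analysis.threshold,
    )


def _load_fits(cfg: RunConfig, outdir: pathlib.Path):
    fits = {}
    for dtype in ("T1DM", "T2DM"):
        path = outdir / f"survival_fit_{dtype.lower()}.yaml"
        if path.exists():
            fits[dtype] = load_survival_fit(path)
    if not fits:
        raise FileNotFoundError(f"no survival fit files in {outdir}; run fit-survival first")
    return fits


def model_stage(cfg: RunConfig, seed: int, outdir: pathlib.Path, bundle: ModelBundle | None = None):
    if bundle is None:
        bundle = build_bundle(cfg, _load_fits(cfg, outdir))
    rows = []
    for dtype, stratum in bundle.strata.items():
        for rate_label, rate in [
            ("base", cfg.analysis.discount_rate),
            ("sensitivity", cfg.analysis.discount_rate_sensitivity),
        ]:
            b = bundle if rate == bundle.discount.rate else _with_rate(bundle, rate)
            result = evaluate_strategy_pair(b, dtype)
            rows.append(
                {"diabetes_type": dtype, "discount": rate_label, "discount_rate": rate, **result.as_dict()}
            )
            log.info(
                "run-model %s @%.1f%%: dC=%.2f dE=%.5f %s=%.0f ce=%s",
                dtype, 100 * rate, result.delta_cost, result.delta_qalys,
                result.kind, result.ratio or float("nan"), result.cost_effective,
            )
        for strategy in (bundle.annual, bundle.biennial):
            trace = run_cohort(bundle.model, strategy, stratum, bundle.horizon_age)
            _write_csv(trace.to_frame(), outdir / f"trace_{dtype.lower()}_{strategy.name}.csv", cfg, seed)
    base_case = pd.DataFrame(rows)
    _write_csv(base_case, outdir / "base_case.csv", cfg, seed)
    return base_case, bundle


def _with_rate(bundle: ModelBundle, rate: float) -> ModelBundle:
    import copy

    b = copy.copy(bundle)
    b.discount = replace(bundle.discount, rate=rate)
    return b


def scenarios_stage(cfg: RunConfig, seed: int, outdir: pathlib.Path, bundle: ModelBundle | None = None):
    if bundle is None:
        bundle = build_bundle(cfg, _load_fits(cfg, outdir))
    spec = ScenarioGridSpec(
        hba1c_percent=tuple(cfg.scenarios.hba1c_percent),
        duration_years={
            "T1DM": tuple(cfg.scenarios.t1dm_duration_years),
            "T2DM": tuple(cfg.scenarios.t2dm_duration_years),
        },
        discount_rates=(cfg.analysis.discount_rate, cfg.analysis.discount_rate_sensitivity),
    )
    grid = run_scenarios(spec, bundle)
    _write_csv(grid, outdir / "scenarios.csv", cfg, seed)
    return grid, bundle


def psa_stage(cfg: RunConfig, seed: int, outdir: pathlib.Path, bundle: ModelBundle | None = None):
    if bundle is None:
        bundle = build_bundle(cfg, _load_fits(cfg, outdir))
    spec = PSASpec(
        n_draws=cfg.psa.n_draws,
        seed=seed,
        cost_cv=cfg.psa.cost_cv,
        utility_cv=cfg.psa.utility_cv,
        sample_survival=cfg.psa.sample_survival,
        sample_hes=cfg.psa.sample_hes,
    )
    summaries = {}
    for dtype in bundle.strata:
        draws = run_psa(spec, bundle, dtype)
        _write_csv(draws, outdir / f"psa_draws_{dtype.lower()}.csv", cfg, seed)
        curve = ceac(draws, spec.thresholds)
        _write_csv(curve, outdir / f"ceac_{dtype.lower()}.csv", cfg, seed)
        summaries[dtype] = prob_cost_effective(draws, bundle.threshold)
        log.info("psa %s: P(cost-effective @ %.0f) = %.3f", dtype, bundle.threshold, summaries[dtype])
    return summaries, bundle


def full_pipeline(cfg: RunConfig, seed: int, outdir=None) -> dict:
    """simulate -> fit-survival -> run-model -> scenarios -> psa."""
    outdir = pathlib.Path(outdir or cfg.paths.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = write_default_parameter_files(outdir / "params")
    for fname, prov in provenance.items():
        log.info("parameter file %s: %s", fname, prov)
    cohort = simulate_stage(cfg, seed, outdir)
    fits = fit_stage(cfg, seed, outdir, cohort)
    bundle = build_bundle(cfg, fits)
    base_case, _ = model_stage(cfg, seed, outdir, bundle)
    grid, _ = scenarios_stage(cfg, seed, outdir, bundle)
    psa_summary, _ = psa_stage(cfg, seed, outdir, bundle)
    return {
        "cohort": cohort,
        "fits": fits,
        "bundle": bundle,
        "base_case": base_case,
        "scenarios": grid,
        "psa": psa_summary,
    }
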