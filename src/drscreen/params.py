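"""Parameter-file IO: text schemas for costs, utilities, transition
tables and fitted survival models, plus reference fits built from the
generator's defaults for fixture runs."""

from __future__ import annotations

import dataclasses
import pathlib

import numpy as np
import yaml

from . import states as st
from .economics import CostTable, UtilityTable
from .icsurv import WeibullPHFit
from .markov import LifeTable, TransitionTables, default_transition_tables, synthetic_life_table
from .synth import GeneratorConfig


def save_cost_table(costs: CostTable, path) -> None:
    pathlib.Path(path).write_text(yaml.safe_dump(dataclasses.asdict(costs), sort_keys=True))


def load_cost_table(path) -> CostTable:
    data = yaml.safe_load(pathlib.Path(path).read_text())
    c = CostTable(**data)
    c.validate()
    return c


def save_utility_table(utilities: UtilityTable, path) -> None:
    pathlib.Path(path).write_text(
        yaml.safe_dump(dataclasses.asdict(utilities), sort_keys=True)
    )


def load_utility_table(path) -> UtilityTable:
    data = yaml.safe_load(pathlib.Path(path).read_text())
    u = UtilityTable(**data)
    u.validate(strict=False)
    return u


def save_transition_tables(tables: TransitionTables, path) -> None:
    data = {
        "hes": tables.hes.tolist(),
        "rdr_entry": tables.rdr_entry.tolist(),
        "pre_rdr_minbdr": tables.pre_rdr_minbdr,
        "pre_rdr_modbdr": tables.pre_rdr_modbdr,
        "p_treat": tables.p_treat.tolist(),
        "treat_resources": tables.treat_resources.tolist(),
        "svl_home_fraction": tables.svl_home_fraction,
        "severity_order": list(st.RDR_SEVERITY),
    }
    pathlib.Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_transition_tables(path) -> TransitionTables:
    data = yaml.safe_load(pathlib.Path(path).read_text())
    order = data.pop("severity_order", list(st.RDR_SEVERITY))
    if tuple(order) != st.RDR_SEVERITY:
        raise ValueError("transition file severity order does not match the model's")
    return TransitionTables(
        hes=np.array(data["hes"]),
        rdr_entry=np.array(data["rdr_entry"]),
        pre_rdr_minbdr=data.get("pre_rdr_minbdr", 0.03),
        pre_rdr_modbdr=data.get("pre_rdr_modbdr", 0.03),
        p_treat=np.array(data["p_treat"]),
        treat_resources=np.array(data["treat_resources"]),
        svl_home_fraction=data.get("svl_home_fraction", 0.9),
    )


def save_survival_fit(fit: WeibullPHFit, path) -> None:
    data = {
        "family": "weibull",
        "p": float(fit.p),
        "beta0": float(fit.beta0),
        "beta": {n: float(b) for n, b in zip(fit.covariate_names, fit.beta)},
        "loglik": float(fit.loglik),
        "n_params": int(fit.n_params),
        "aic": float(2 * fit.n_params - 2 * fit.loglik),
        "converged": bool(fit.converged),
        "vcov_lower_triangle": [
            [float(fit.vcov[i, j]) for j in range(i + 1)] for i in range(len(fit.params))
        ]
        if fit.vcov is not None
        else None,
    }
    pathlib.Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_survival_fit(path) -> WeibullPHFit:
    data = yaml.safe_load(pathlib.Path(path).read_text())
    names = tuple(data["beta"].keys())
    beta = np.array([data["beta"][n] for n in names])
    vcov = None
    if data.get("vcov_lower_triangle") is not None:
        k = 2 + len(names)
        vcov = np.zeros((k, k))
        for i, row in enumerate(data["vcov_lower_triangle"]):
            for j, v in enumerate(row):
                vcov[i, j] = vcov[j, i] = v
    return WeibullPHFit(
        p=data["p"],
        beta0=data["beta0"],
        beta=beta,
        covariate_names=names,
        vcov=vcov,
        loglik=data.get("loglik", np.nan),
        converged=data.get("converged", True),
    )


def reference_fit(diabetes_type: str, config: GeneratorConfig | None = None) -> WeibullPHFit:
    """The generating Weibull law as a fit object (fixture runs and tests)."""
    config = config or GeneratorConfig.default()
    cfg = config.t1dm if diabetes_type == "T1DM" else config.t2dm
    names = tuple(cfg.weibull_betas.keys())
    return WeibullPHFit(
        p=cfg.weibull_p,
        beta0=cfg.weibull_beta0,
        beta=np.array([cfg.weibull_betas[n] for n in names]),
        covariate_names=names,
        vcov=None,
        loglik=np.nan,
    )


def write_default_parameter_files(outdir) -> dict[str, str]:
    """Write the default cost/utility/transition/life-table files.

    Returns a provenance map: which files hold published table values
    and which are synthetic fixtures.
    """
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_cost_table(CostTable(), outdir / "costs.yaml")
    save_utility_table(UtilityTable(), outdir / "utilities.yaml")
    save_transition_tables(default_transition_tables(), outdir / "transitions.yaml")
    synthetic_life_table().to_csv(outdir / "life_table.csv")
    return {
        "costs.yaml": "published-table defaults",
        "utilities.yaml": "published RDR weights; pre-RDR weight is a non-study default",
        "transitions.yaml": "synthetic fixture (non-study values)",
        "life_table.csv": "synthetic national-style life table",
    }
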