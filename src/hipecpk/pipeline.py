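"""End-to-end analysis: calibration → correction → fits → comparisons → LOA.

The functions here glue the library stages together for the command-line
interface and for scripted runs; all numeric work lives in the dedicated
modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .compare import compare_tissues, limits_of_agreement
from .model import fit_all_tissues
from .recovery import catheter_recoveries, correct_observations, pool_recovery
from .simulate import TISSUE_LAYOUT

__all__ = ["AnalysisConfig", "AnalysisResult", "run_analysis"]


@dataclass
class AnalysisConfig:
    """Options controlling a full pipeline run."""

    censored_handling: str = "drop"
    lloq: float = 0.030
    prediction: str = "interval_average"
    compare_parameters: tuple[str, ...] = ("auc_0_last", "c_max")
    loa_parameters: tuple[str, ...] = ("auc_0_last", "c_max", "t_half")
    t_last: float = 480.0
    n_boot: int = 200  # LOA bootstrap reps for pipeline runs; library default is 1000
    seed: int = 0


@dataclass
class AnalysisResult:
    """All pipeline tables, ready to serialize."""

    recovery_per_catheter: pd.DataFrame
    recovery_table: pd.DataFrame
    fits: dict
    pk_per_catheter: pd.DataFrame
    pk_population: pd.DataFrame
    comparisons: pd.DataFrame
    loa: pd.DataFrame


def _organ_of(tissue: str) -> str:
    return TISSUE_LAYOUT[tissue][0] if tissue in TISSUE_LAYOUT else str(tissue)


def run_analysis(
    observations: pd.DataFrame,
    calibration: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> AnalysisResult:
    """Run every analysis stage on dialysate + calibration tables.

    ``observations`` and ``calibration`` use the frozen CSV schemas (see
    :mod:`hipecpk.io`).  Tissues without enough data for a mixed fit are
    skipped with a warning rather than failing the run.
    """
    config = config or AnalysisConfig()

    rec = catheter_recoveries(calibration)
    rec_table = pool_recovery(rec, group_col="tissue")
    corrected = correct_observations(
        observations, rec, lloq=config.lloq, censored_handling=config.censored_handling
    )

    fits = fit_all_tissues(corrected, prediction=config.prediction)
    if not fits:
        raise RuntimeError("no tissue could be fitted; check input data")

    per_cath = []
    pop_rows = []
    for tissue, res in fits.items():
        pc = res.per_catheter_parameters(t_last=config.t_last)
        pc["organ"] = _organ_of(tissue)
        per_cath.append(pc)
        pop = res.population_derived(t_last=config.t_last)
        pop.insert(0, "tissue", tissue)
        pop["n"] = pc["catheter_id"].nunique()
        pop["converged"] = res.converged
        pop_rows.append(pop)
    pk_per_catheter = pd.concat(per_cath, ignore_index=True)
    pk_population = pd.concat(pop_rows, ignore_index=True)

    comp_rows = []
    tissues = sorted(fits)
    for param in config.compare_parameters:
        for a, b in combinations(tissues, 2):
            try:
                r = compare_tissues(pk_per_catheter, param, a, b, tissue_col="tissue")
            except ValueError as err:
                warnings.warn(f"comparison {b}/{a} on {param} skipped: {err}")
                continue
            comp_rows.append(
                {
                    "parameter": param,
                    "tissue_num": r.tissue_num,
                    "tissue_den": r.tissue_den,
                    "ratio": r.ratio,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p": r.p_value,
                }
            )
    comparisons = pd.DataFrame(comp_rows)

    loa_rows = []
    for organ in sorted(pk_per_catheter["organ"].unique()):
        for param in config.loa_parameters:
            try:
                l = limits_of_agreement(
                    pk_per_catheter, organ, param, tissue_col="organ", n_boot=config.n_boot, seed=config.seed
                )
            except ValueError as err:
                warnings.warn(f"LOA for {organ}/{param} skipped: {err}")
                continue
            loa_rows.append(
                {
                    "tissue": l.tissue,
                    "parameter": l.parameter,
                    "loa_factor": l.loa_factor,
                    "ci_low": l.ci_low,
                    "ci_high": l.ci_high,
                    "sigma_within": l.sigma_within,
                }
            )
    loa = pd.DataFrame(loa_rows)

    return AnalysisResult(rec, rec_table, fits, pk_per_catheter, pk_population, comparisons, loa)


def write_analysis(result: AnalysisResult, outdir: str | Path, *, seed=None, config=None) -> dict[str, Path]:
    """Serialize all result tables into ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["table2_recovery"] = io.write_table(result.recovery_table, outdir / "table2_recovery.csv", seed=seed, config=config)
    paths["recovery_per_catheter"] = io.write_table(
        result.recovery_per_catheter, outdir / "recovery_per_catheter.csv", seed=seed, config=config
    )
    paths["table3_pk"] = io.write_table(result.pk_population, outdir / "table3_pk.csv", seed=seed, config=config)
    paths["pk_per_catheter"] = io.write_table(
        result.pk_per_catheter, outdir / "pk_per_catheter.csv", seed=seed, config=config
    )
    paths["comparisons"] = io.write_table(result.comparisons, outdir / "comparisons.csv", seed=seed, config=config)
    paths["loa"] = io.write_table(result.loa, outdir / "loa.csv", seed=seed, config=config)
    import json

    fits_json = {t: r.to_dict() for t, r in result.fits.items()}
    p = outdir / "fits.json"
    p.write_text(json.dumps(fits_json, indent=1, default=float))
    paths["fits"] = p
    return paths
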