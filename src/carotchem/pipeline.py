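"""End-to-end pipeline: simulate -> preprocess -> calibrate -> validate -> stats.

``run_pipeline`` executes the full workflow for one seeded configuration
and writes a report bundle: the metabolite table, one calibration-model
JSON and one cross-validation report per analyte, an external-validation
report for the configured analytes, and composition / diversity / color
summary tables.  Outputs are byte-identical for identical (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from carotchem import io as cio
from carotchem.composition import (
    composition_table,
    correlation_matrix,
    group_summary,
    pca,
)
from carotchem.phenotype import she_diversity
from carotchem.pls import fit_pls1
from carotchem.preprocess import default_chains
from carotchem.spectra import GRID_STEP, default_grid
from carotchem.synthetic import (
    ANALYTES,
    PhenotypeGroupParams,
    ScatterNoiseModel,
    default_groups,
    generate_metabolite_profiles,
    purple_groups,
    simulate_extracts,
    simulate_pure_spectra,
    simulate_spectra,
)
from carotchem.validation import external_validation, kfold_cv

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("carotchem")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    out_dir: str = "carotchem_run"
    grid_step: float = GRID_STEP
    groups: list[PhenotypeGroupParams] | None = None
    replicates: int = 3
    cv_folds: int = 5
    max_rank: int = 10
    noiseless: bool = False          # exact Beer-Lambert limit, scatter chains off
    external_analytes: list[str] = field(default_factory=lambda: ["Total_ACN"])
    external_n_cal: int = 50
    external_n_val: int = 100
    analytes: list[str] = field(default_factory=lambda: list(ANALYTES))
    derivative_window: int = 17
    derivative_polyorder: int = 2
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.external_n_cal <= 0 or self.external_n_val <= 0:
            raise ValueError("external split sizes must be positive")
        unknown = [a for a in self.analytes if a not in ANALYTES]
        if unknown:
            raise ValueError(f"unknown analytes {unknown}; modeled responses are {ANALYTES}")

    def to_jsonable(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.groups is not None:
            d["groups"] = [dataclasses.asdict(g) for g in self.groups]
        return d

    @classmethod
    def from_mapping(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        if data.get("groups") is not None:
            data["groups"] = [PhenotypeGroupParams(**g) for g in data["groups"]]
        return cls(**data)


def _sized_purple_cohort(n_samples: int, seed: int) -> pd.DataFrame:
    """A purple-only cohort of exactly n_samples, group sizes kept proportional."""
    groups = purple_groups()
    total = sum(g.n_samples for g in groups)
    sizes = [max(1, round(g.n_samples * n_samples / total)) for g in groups]
    sizes[0] += n_samples - sum(sizes)  # absorb rounding in the largest group
    groups = [dataclasses.replace(g, n_samples=n) for g, n in zip(groups, sizes)]
    return generate_metabolite_profiles(groups, seed=seed)


def _y_for(profiles: pd.DataFrame, analyte: str, sample_ids: np.ndarray) -> np.ndarray:
    return profiles.set_index("sample_id")[analyte].loc[sample_ids].to_numpy(dtype=float)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run simulate -> preprocess -> calibrate -> validate -> stats/color.

    Returns a summary dict (also written to ``<out_dir>/summary.json``).
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cio.config_hash(config.to_jsonable())
    log.info("pipeline start: seed=%s config_hash=%s", config.seed, cfg_hash)

    grid = default_grid(config.grid_step)
    pure = simulate_pure_spectra(grid=grid)
    scatter = ScatterNoiseModel.off() if config.noiseless else ScatterNoiseModel()
    chains = default_chains(
        derivative_window=config.derivative_window,
        derivative_polyorder=config.derivative_polyorder,
        scatter_steps=not config.noiseless,
    )

    # --- simulate -----------------------------------------------------------
    groups = config.groups if config.groups is not None else default_groups()
    profiles = generate_metabolite_profiles(groups, seed=config.seed)
    purple = profiles[profiles["phenotype"] != ":0000"].reset_index(drop=True)
    spectra = simulate_spectra(
        purple, pure=pure, scatter=scatter, replicates=config.replicates,
        seed=config.seed + 1,
    )
    cio.write_table(out / "metabolites.csv", profiles)
    cio.write_spectra(out / "spectra.csv", spectra)
    log.info("simulated %d samples (%d purple scans) on %d-point grid",
             len(profiles), spectra.n_spectra, grid.size)

    # --- calibrate + cross-validate ----------------------------------------
    cv_rows = []
    for analyte in config.analytes:
        chain = chains[analyte]
        transformed = chain.fit_transform(spectra)
        y = _y_for(purple, analyte, transformed.sample_ids)
        report = kfold_cv(
            transformed.absorbance, y, sample_ids=transformed.sample_ids,
            k=config.cv_folds, max_rank=config.max_rank,
            seed=config.seed + 2, analyte=analyte,
        )
        model = fit_pls1(
            transformed.absorbance, y, rank=report.rank, analyte=analyte,
            wavenumbers=transformed.wavenumbers, chain=chain.to_dict(),
            metadata={"seed": config.seed, "config_hash": cfg_hash,
                      "n_samples": len(purple)},
        )
        cio.save_model(out / f"model_{analyte}.json", model)
        cv_rows.append(report.to_dict())
        log.info("%s: rank=%d R2=%.4f RMSECV=%.3g RPD=%.2f",
                 analyte, report.rank, report.r2, report.rmse, report.rpd)
    cv_table = pd.DataFrame(cv_rows)
    cio.write_table(out / "cv_reports.csv", cv_table)

    # --- external validation ------------------------------------------------
    ext_rows = []
    if config.external_analytes:
        cal = _sized_purple_cohort(config.external_n_cal, seed=config.seed + 3)
        val = _sized_purple_cohort(config.external_n_val, seed=config.seed + 4)
        cal["sample_id"] = "cal_" + cal["sample_id"]
        val["sample_id"] = "val_" + val["sample_id"]
        ss_cal = simulate_spectra(cal, pure=pure, scatter=scatter,
                                  replicates=config.replicates, seed=config.seed + 5)
        ss_val = simulate_spectra(val, pure=pure, scatter=scatter,
                                  replicates=config.replicates, seed=config.seed + 6)
        for analyte in config.external_analytes:
            chain = default_chains(scatter_steps=not config.noiseless)[analyte]
            t_cal = chain.fit_transform(ss_cal)
            t_val = chain.transform(ss_val)
            y_cal = _y_for(cal, analyte, t_cal.sample_ids)
            y_val = _y_for(val, analyte, t_val.sample_ids)
            cv_rep = kfold_cv(t_cal.absorbance, y_cal, sample_ids=t_cal.sample_ids,
                              k=config.cv_folds, max_rank=config.max_rank,
                              seed=config.seed + 7, analyte=analyte)
            model = fit_pls1(t_cal.absorbance, y_cal, rank=cv_rep.rank, analyte=analyte)
            ext = external_validation(model, t_val.absorbance, y_val,
                                      cal_sample_ids=t_cal.sample_ids,
                                      val_sample_ids=t_val.sample_ids)
            ext_rows.append(ext.to_dict())
            log.info("%s external: R2p=%.4f RMSEP=%.3g RPDp=%.2f",
                     analyte, ext.r2, ext.rmse, ext.rpd)
        cio.write_table(out / "external_reports.csv", pd.DataFrame(ext_rows))

    # --- composition / diversity / color ------------------------------------
    comp = composition_table(profiles)
    cio.write_table(out / "composition.csv", comp)
    summary = group_summary(profiles, analytes=[c for c in ANALYTES])
    summary.reset_index().to_csv(out / "group_summary.csv", index=False,
                                 float_format="%.10g")
    counts = profiles["phenotype"].value_counts().to_dict()
    div = she_diversity(counts)
    explained, _ = pca(profiles[[c for c in ANALYTES if not c.startswith("Total_")]
                                + ["Total_ACN", "Total_AcA", "Total_PHEN"]])
    corr_r, corr_p = correlation_matrix(
        comp, columns=[c for c in comp.columns if c.startswith("pct_")]
    )
    corr_r.to_csv(out / "composition_corr_r.csv", float_format="%.10g")
    corr_p.to_csv(out / "composition_corr_p.csv", float_format="%.10g")

    extracts = simulate_extracts(purple, seed=config.seed + 8)
    cio.write_table(out / "extracts.csv", extracts)

    summary_json = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "n_samples": len(profiles),
        "n_purple": len(purple),
        "grid_points": int(grid.size),
        "diversity": {"S": div.S, "H": div.H, "E": div.E},
        "pc1_variance_pct": float(explained[0]),
        "cv": cv_rows,
        "external": ext_rows,
    }
    (out / "summary.json").write_text(
        json.dumps(summary_json, sort_keys=True, indent=1), encoding="utf-8"
    )
    log.info("pipeline done: bundle in %s", out)
    return summary_json
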