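"""End-to-end orchestration: indices -> exposure -> growth sequence ->
selection -> mother-weight GAM -> predictions, plus the milk-energy
calculator.

The pipeline is deterministic given a RunConfig: the one seed drives all
randomness through named substreams, and rerunning the same config
rewrites byte-identical CSVs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gam, growth, herd, selection, weather as wx

logger = logging.getLogger(__name__)

KCAL_TO_KJ = 4.184


def milk_energy(weight_kg):
    """Daily milk-energy requirement from body weight: 226 * W^0.837 kcal/d.

    Returns (kcal_per_day, kj_per_day).  The allometric exponent < 1
    reflects metabolic scaling; energy is strictly increasing in weight.
    """
    w = np.asarray(weight_kg, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weight must be positive")
    kcal = 226.0 * w**0.837
    kj = KCAL_TO_KJ * kcal
    if kcal.ndim == 0:
        return float(kcal), float(kj)
    return kcal, kj


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run (CLI flags override files)."""

    out_dir: str = "deerheat_out"
    seed: int = 0
    weather_csv: str | None = None
    weighing_csv: str | None = None
    n_pairs: int = 583
    n_cohorts: int = 19
    n_mothers: int = 150
    exposure_mode: str = "interval-mean"
    index: str = "thi"  # heat covariate entering the growth sequence
    selection_criterion: str = "ML"
    report_criterion: str = "REML"
    fit_sequence: bool = True
    fit_gam: bool = True
    gam_index: str = "thiws"
    quantiles: tuple = (0.1, 0.5, 0.9)

    @classmethod
    def from_yaml(cls, path, **overrides):
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def growth_sequence_specs(index: str = "thi"):
    """The nested six-model calf-growth sequence (model 0 ... final).

    Base model: intercept + mother weight in each block; then sex, mother
    age and calf age enter all three blocks, and the heat index and its
    sex interaction enter the Asym and lrc blocks.
    """
    base = growth.GrowthModelSpec(
        asym_terms=("mother_wt_kg",),
        r0_terms=("mother_wt_kg",),
        lrc_terms=("mother_wt_kg",),
    )
    additions = [
        selection.TermAddition("sex"),
        selection.TermAddition("mother_age_yr"),
        selection.TermAddition("calf_age_d"),
        selection.TermAddition(index, blocks=("asym", "lrc")),
        selection.TermAddition(f"{index}:sex", blocks=("asym", "lrc")),
    ]
    specs = selection.build_model_sequence(base, additions)
    labels = [f"model {i}" for i in range(len(specs) - 1)] + ["final"]
    return specs, labels


def default_gam_smooths(index: str = "thiws"):
    return [
        gam.SmoothSpec("calf_age_d", k=3),
        gam.SmoothSpec("mother_age_yr", k=3),
        gam.SmoothSpec(index, k=3),
        gam.SmoothSpec("calf_age_d", k=3, type="by", by="sex"),
        gam.SmoothSpec("mother_id", type="re"),
        gam.SmoothSpec("cohort", type="re"),
        gam.SmoothSpec("calf_id", type="re"),
    ]


def _validate_config_covariates(records, config: RunConfig):
    """Fail fast: every referenced covariate must resolve before fitting."""
    specs, _ = growth_sequence_specs(config.index)
    needed = set()
    for spec in specs:
        for blk in growth.BLOCKS:
            for term in spec.block_terms(blk):
                for part in term.split(":"):
                    if part not in ("1", "sex"):
                        needed.add(part)
    if config.fit_gam:
        needed.add(config.gam_index)
    missing = sorted(n for n in needed if n not in records.columns)
    if missing:
        raise ValueError(f"config references unresolvable covariates {missing}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns a manifest dict (also written as run_manifest.json) listing
    outputs, the seed and the fitted-model summaries.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load-weather"
    try:
        if config.weather_csv:
            weather = wx.read_weather_csv(config.weather_csv)
            weather = wx.add_indices(weather)
            records = None
            manifest_sim = None
        else:
            stage = "simulate"
            design = herd.HerdDesign(
                n_pairs=config.n_pairs, n_cohorts=config.n_cohorts,
                n_mothers=config.n_mothers,
            )
            weather, records, manifest_sim = herd.simulate_study(
                design, seed=config.seed, exposure_mode=config.exposure_mode
            )
        if config.weighing_csv:
            stage = "load-weighings"
            records = pd.read_csv(config.weighing_csv, parse_dates=["date", "birth_date"])
            records = herd.validate_weigh_records(records)
            if "thi" not in records.columns:
                stage = "assign-exposure"
                records = wx.assign_exposure(records, weather, mode=config.exposure_mode)
        if records is None:
            raise ValueError("no weighing records: supply weighing_csv or simulate")
        herd.validate_weigh_records(records)

        stage = "validate-config"
        _validate_config_covariates(records, config)

        stage = "write-indices"
        wx.write_indices_csv(weather, out / "indices.csv")
        monthly = wx.monthly_summary(
            weather, variables=["t_mean", "t_max", "hr", "wind", "solar", "thi", "thiws"]
        )
        monthly.to_csv(out / "monthly_summary.csv", index=False)
        rec_out = records.copy()
        for c in ("date", "birth_date"):
            if c in rec_out.columns:
                rec_out[c] = pd.to_datetime(rec_out[c]).dt.strftime("%Y-%m-%d")
        rec_out.to_csv(out / "records.csv", index=False)

        manifest = {
            "seed": config.seed,
            "config": asdict(config),
            "n_records": int(len(records)),
            "outputs": ["indices.csv", "monthly_summary.csv", "records.csv"],
        }
        if manifest_sim:
            manifest["simulation"] = manifest_sim

        stage = "fit-growth"
        specs, labels = growth_sequence_specs(config.index)
        if config.fit_sequence:
            fits = [
                growth.fit_growth(records, s, criterion=config.selection_criterion,
                                  compute_lrc_se=False)
                for s in specs
            ]
            table = selection.compare_models(fits, labels)
            table.to_csv(out / "growth_selection.csv")
            manifest["outputs"].append("growth_selection.csv")
            manifest["growth_aic"] = dict(zip(labels, table.aic.tolist()))
        stage = "report-growth"
        final = growth.fit_growth(records, specs[-1], criterion=config.report_criterion)
        final.coef_table.to_csv(out / "growth_coefficients.csv", index=False)
        final.varcomp_table.to_csv(out / "growth_varcomp.csv", index=False)
        manifest["outputs"] += ["growth_coefficients.csv", "growth_varcomp.csv"]
        manifest["growth_varcomp"] = dict(
            zip(final.varcomp_table["group"], final.varcomp_table["sd"])
        )

        stage = "predict"
        qvals = wx.index_quantiles(records[config.index], config.quantiles)
        pred_frames = []
        for q, v in zip(config.quantiles, qvals):
            for sex in ("female", "male"):
                p = growth.predict_trajectory(final, {config.index: v, "sex": sex})
                p["quantile"] = q
                p[config.index] = v
                pred_frames.append(p)
        preds = pd.concat(pred_frames, ignore_index=True)
        preds.to_csv(out / "growth_predictions.csv", index=False)
        manifest["outputs"].append("growth_predictions.csv")

        if config.fit_gam:
            stage = "fit-mother"
            gfit = gam.fit_gam(
                records,
                parametric_terms=("sex",),
                smooth_specs=default_gam_smooths(config.gam_index),
                response="mother_wt_kg",
                seed=config.seed,
            )
            gsm = gfit.smooth_table.copy()
            gsm["coefficients"] = gsm["coefficients"].apply(
                lambda v: ";".join(f"{x:.6g}" for x in v)
            )
            gsm.to_csv(out / "gam_coefficients.csv", index=False)
            manifest["outputs"].append("gam_coefficients.csv")
            manifest["gam"] = {
                "deviance_explained": gfit.deviance_explained,
                "aic": gfit.aic,
                "variance_components": gfit.variance_components,
            }
            grid = pd.DataFrame(
                {config.gam_index: np.linspace(
                    float(records[config.gam_index].min()),
                    float(records[config.gam_index].max()), 25,
                )}
            )
            gp_frames = []
            for sex in ("female", "male"):
                g = grid.copy()
                g["sex"] = sex
                gp_frames.append(gam.predict_gam(gfit, g))
            gpred = pd.concat(gp_frames, ignore_index=True)
            gpred[[config.gam_index, "sex", "pred", "se"]].to_csv(
                out / "gam_predictions.csv", index=False
            )
            manifest["outputs"].append("gam_predictions.csv")

        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
        return manifest
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[stage {stage}] {cause}")
        self.stage = stage
        self.cause = cause
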