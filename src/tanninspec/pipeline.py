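"""End-to-end orchestration of the calibration workflow.

Stage order: load/generate scans -> average replicates -> Monte-Carlo
outlier scan and removal -> 12-form transform bank with correlation
summaries -> CWT of the four first-derivative-era sources at dyadic scales
-> per-scale profiling and optimal-scale choice -> 6:4 split -> random
forests for every (input definition, band mode) -> metrics comparison ->
Shapley attribution of the best validation model -> consolidated report.
Every stage writes its CSV artifacts under the output directory and the run
is fully deterministic for a fixed configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import RFConfig, compare_inputs
from .cwt import DEFAULT_SCALES, cwt_features
from .datagen import GeneratorConfig, generate_dataset
from .datasets import SampleSpectrumSet, TanninTable
from .io import average_replicates, read_spectra_csv, read_tannin_csv, write_spectra_csv, write_tannin_csv
from .outliers import MCConfig, apply_outlier_removal, mc_outlier_scan
from .selection import CorrelationBandSelector, pearson_profile, select_optimal_scale, summarize_profile
from .split import describe_sets, split
from .explain import rank_and_export, shapley_attribute
from .transforms import TRANSFORM_TAGS, apply_transform

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "report_summary"]

#: Sources carried into the CWT stage (raw reflectance + the three
#: first-derivative forms retained by the correlation screening).
DEFAULT_CWT_SOURCES = ("R", "R'", "lg'R", "lg'(1/R)")


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    mc: MCConfig = field(default_factory=MCConfig)
    rf: RFConfig = field(default_factory=RFConfig)
    alpha: float = 0.01
    critical_r: float = None  # override for the |r| gate; derived from n when None
    scales: tuple = DEFAULT_SCALES
    cwt_sources: tuple = DEFAULT_CWT_SOURCES
    wavelet_id: str = "gaus4"
    band_modes: tuple = ("full", "characteristic")
    transform_tags: tuple = TRANSFORM_TAGS
    split_ratio: float = 0.6
    overfit_margin: float = 0.15
    shap_method: str = "permutation"
    shap_permutations: int = 20
    shap_explain: int = 4
    shap_background: int = 30
    top_k: int = 10
    save_raw: bool = True
    seed: int = 0

    def child_seed(self, k: int) -> int:
        return int(np.random.SeedSequence([self.seed, k]).generate_state(1)[0] % (2**31 - 1))


def _feature_name(tag: str, scale, wavenumber: float) -> str:
    if scale is None:
        return f"{tag}@{wavenumber:.0f}"
    return f"{tag}_CWT_{int(scale)}@{wavenumber:.0f}"


def run_pipeline(config: PipelineConfig, outdir, spectra_csv=None, tannin_csv=None) -> dict:
    """Execute the full workflow; returns a dict of in-memory artifacts.

    Inputs are generated from ``config.generator`` unless ``spectra_csv`` and
    ``tannin_csv`` point at existing wide-CSV files.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"outdir": out}
    stage = "generate"
    try:
        if spectra_csv is not None:
            scans = read_spectra_csv(spectra_csv)
            tannins = read_tannin_csv(tannin_csv)
        else:
            gen_cfg = GeneratorConfig(**{**asdict_config(config.generator), "seed": config.child_seed(0)})
            scans, tannins = generate_dataset(gen_cfg)
            if config.save_raw:
                write_spectra_csv(scans, out / "spectra_raw.csv")
                write_tannin_csv(tannins, out / "tannin.csv")
        artifacts["scans"] = scans
        artifacts["tannins"] = tannins

        stage = "average_replicates"
        samples = average_replicates(scans)

        stage = "outlier_scan"
        mc_cfg = MCConfig(**{**asdict(config.mc), "seed": config.child_seed(1)})
        report = mc_outlier_scan(samples, tannins, mc_cfg)
        report.to_csv(out / "outlier_report.csv")
        artifacts["outlier_report"] = report
        samples, tannins = apply_outlier_removal(samples, tannins, report)
        artifacts["samples"] = samples
        artifacts["tannins_clean"] = tannins
        y_all = tannins.values_for(samples.sample_ids)

        stage = "transform_bank"
        transformed = {tag: apply_transform(samples, tag) for tag in config.transform_tags}
        table1_rows = []
        for tag in config.transform_tags:
            t = transformed[tag]
            prof = pearson_profile(t.values, y_all, alpha=config.alpha, critical_r=config.critical_r, axis=t.wavenumbers)
            s = summarize_profile(prof)
            table1_rows.append(
                {
                    "transform": tag,
                    "nfb": s.nfb,
                    "pos_extremum": s.pos_extremum,
                    "neg_extremum": s.neg_extremum,
                    "mean_abs_r": s.mean_abs_r,
                }
            )
        transform_summary = pd.DataFrame(table1_rows)
        transform_summary.to_csv(out / "transform_summary.csv", index=False)
        artifacts["transform_summary"] = transform_summary

        stage = "cwt"
        scale_tables = {}
        optimal_scales = {}
        wavelet_blocks = {}
        for tag in config.cwt_sources:
            feats = cwt_features(transformed[tag], scales=config.scales, wavelet_id=config.wavelet_id)
            wavelet_blocks[tag] = feats
            profiles = {
                a: pearson_profile(
                    feats.coefficients[a], y_all, alpha=config.alpha,
                    critical_r=config.critical_r, axis=feats.wavenumbers,
                )
                for a in feats.scales
            }
            best, table = select_optimal_scale(profiles)
            optimal_scales[tag] = best
            table.insert(0, "source", tag)
            scale_tables[tag] = table
        scale_summary = pd.concat(scale_tables.values(), ignore_index=True)
        scale_summary.to_csv(out / "cwt_scale_summary.csv", index=False)
        artifacts["scale_summary"] = scale_summary
        artifacts["optimal_scales"] = optimal_scales

        stage = "split"
        sp = split(samples.sample_ids, ratio=config.split_ratio, seed=config.child_seed(2))
        sp.to_frame().to_csv(out / "split.csv", index=False)
        desc = describe_sets(tannins, sp)
        desc.to_csv(out / "set_description.csv", index=False)
        artifacts["split"] = sp
        artifacts["set_description"] = desc

        stage = "models"
        feature_sets = {}
        feature_names = {}
        for tag in config.cwt_sources:
            t = transformed[tag]
            feature_sets[tag] = (t.values, samples.sample_ids)
            feature_names[tag] = np.array([_feature_name(tag, None, w) for w in t.wavenumbers])
            feats = wavelet_blocks[tag]
            a = optimal_scales[tag]
            cwt_name = f"{tag}_CWT_{int(a)}"
            feature_sets[cwt_name] = (feats.coefficients[a], samples.sample_ids)
            feature_names[cwt_name] = np.array([_feature_name(tag, a, w) for w in feats.wavenumbers])
        rf_cfg = RFConfig(**{**asdict(config.rf), "seed": config.child_seed(3)})
        comparison, models = compare_inputs(
            feature_sets,
            tannins,
            sp,
            rf_cfg=rf_cfg,
            selector_factory=lambda: CorrelationBandSelector(alpha=config.alpha, critical_r=config.critical_r),
            band_modes=config.band_modes,
            overfit_margin=config.overfit_margin,
            return_models=True,
        )
        comparison.to_csv(out / "model_comparison.csv", index=False)
        artifacts["comparison"] = comparison
        artifacts["models"] = models

        # reference-vs-predicted scatter data for every model and set
        scatter_rows = []
        for (name, mode), entry in models.items():
            pred = entry["model"].predict(entry["X"])
            in_train = np.isin(entry["ids"], sp.train_ids)
            for i, sid in enumerate(entry["ids"]):
                scatter_rows.append(
                    {
                        "input": name,
                        "band_mode": mode,
                        "set": "train" if in_train[i] else "val",
                        "sample_id": sid,
                        "reference": entry["y"][i],
                        "predicted": pred[i],
                    }
                )
        scatter = pd.DataFrame(scatter_rows)
        scatter.to_csv(out / "prediction_scatter.csv", index=False)
        artifacts["scatter"] = scatter

        stage = "best_model"
        val = comparison[comparison["set"] == "val"].copy()
        stable = val[~val["overfit_flag"]]
        pick_from = stable if not stable.empty else val
        best_row = pick_from.sort_values("rpd", ascending=False).iloc[0]
        best_key = (best_row["input"], best_row["band_mode"])
        artifacts["best_model_key"] = best_key
        artifacts["best_val_metrics"] = best_row[["r2", "rmse", "rpd"]].to_dict()
        logger.info("best model: %s (%s bands), val RPD %.3f", best_key[0], best_key[1], best_row["rpd"])

        stage = "shap"
        entry = models[best_key]
        entry["model"].save(out / "best_model.joblib")
        X, ids, y = entry["X"], entry["ids"], entry["y"]
        names = feature_names[best_key[0]]
        if entry["selector"] is not None:
            names = names[entry["selector"].support_]
        tr_mask = np.isin(ids, sp.train_ids)
        va_mask = np.isin(ids, sp.val_ids)
        rng = np.random.default_rng(config.child_seed(4))
        explain_idx = rng.choice(np.flatnonzero(va_mask), min(config.shap_explain, int(va_mask.sum())), replace=False)
        attribution = shapley_attribute(
            entry["model"],
            background=X[tr_mask],
            explain=X[explain_idx],
            method=config.shap_method,
            n_permutations=config.shap_permutations,
            seed=config.child_seed(5),
            feature_names=names,
            max_background=config.shap_background,
        )
        exports = rank_and_export(attribution, top_k=config.top_k, seed=config.child_seed(6))
        for key, frame in exports.items():
            frame.to_csv(out / f"shap_{key}.csv", index=False)
        artifacts["attribution"] = attribution
        artifacts["shap_exports"] = exports

        stage = "report"
        summary = report_summary(artifacts)
        (out / "report.txt").write_text(summary)
        artifacts["report_text"] = summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return artifacts


def asdict_config(cfg) -> dict:
    """dataclass -> dict preserving tuple-typed fields (asdict recurses)."""
    return {f: getattr(cfg, f) for f in cfg.__dataclass_fields__}


def report_summary(artifacts: dict) -> str:
    """Human-readable one-page run summary built from stage artifacts."""
    lines = ["# Tannin calibration pipeline report", ""]

    def have(key):
        return key in artifacts and artifacts[key] is not None

    if have("scans"):
        lines.append(f"scans: {artifacts['scans'].n_scans} rows x {artifacts['scans'].n_bands} bands")
    if have("outlier_report"):
        rep = artifacts["outlier_report"]
        lines.append(f"outliers flagged: {len(rep.flagged_ids)} -> {rep.flagged_ids}")
    if have("samples"):
        lines.append(f"samples retained: {artifacts['samples'].n_samples}")
    if have("set_description"):
        lines += ["", "## Tannin statistics per set", artifacts["set_description"].to_string(index=False)]
    else:
        lines.append("set description: absent")
    if have("transform_summary"):
        lines += ["", "## Transform correlation summary", artifacts["transform_summary"].to_string(index=False)]
    else:
        lines.append("transform summary: absent")
    if have("scale_summary"):
        lines += ["", "## CWT per-scale mean |r|", artifacts["scale_summary"].to_string(index=False)]
        lines.append(f"optimal scales: {artifacts.get('optimal_scales')}")
    if have("comparison"):
        lines += ["", "## Model comparison", artifacts["comparison"].to_string(index=False)]
    if have("best_model_key"):
        m = artifacts["best_val_metrics"]
        lines += [
            "",
            f"best model: input={artifacts['best_model_key'][0]} bands={artifacts['best_model_key'][1]} "
            f"val R2={m['r2']:.3f} RMSE={m['rmse']:.3f} RPD={m['rpd']:.3f}",
        ]
    if have("shap_exports"):
        lines += ["", "## Top attributions (mean |phi|)", artifacts["shap_exports"]["ranking"].to_string(index=False)]
    return "\n".join(lines) + "\n"
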