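# tanninspec

Near-infrared (NIR) calibration of tannin content in walnut kernels —
a complete, reproducible chemometrics pipeline with a synthetic benchmark.

Tannins are the polyphenols that make walnut kernels astringent; their
content (mg/g, assayed colorimetrically against a gallic-acid standard
curve) is a routine quality index. NIR diffuse reflectance over
4000–10000 cm⁻¹ carries that information in O–H combination bands
(4000–5000 cm⁻¹) and the first O–H stretching overtone (~7000 cm⁻¹), but
extracting it requires careful preprocessing. `tanninspec` implements the
full workflow:

1. **Spectral transforms** — reflectance R and 11 mathematical forms
   (1/R, lgR, lg(1/R) and their first/second divided-difference derivatives).
2. **Continuous wavelet transform** — gaus4 (fourth derivative of a
   Gaussian, unit L2 norm) at dyadic scales a = 2¹…2¹⁰:
   ω(a,b) = Σⱼ vⱼ·a^(−1/2)·ψ((j−b)/a).
3. **Monte-Carlo outlier screening** — repeated random 60/40 splits, each
   fitting a natively implemented NIPALS PLS1 model (20 latent variables,
   mean centering); samples with anomalous error mean/SD are flagged.
4. **Characteristic-band selection** — per-band Pearson r with a dual gate
   p < 0.01 and |r| > r_crit(n, α) from t = r√((n−2)/(1−r²)).
5. **Random-forest calibration** — 200 trees, minimum leaf 10, seeded
   random hyperparameter search (50 evaluations, 5-fold CV on RMSE);
   evaluated by R², RMSE and RPD = SD(y)/RMSE (RPD > 2 ⇒ robust).
6. **Shapley interpretation** — interventional Shapley values (exact subset
   enumeration ≤12 features, batched permutation sampling otherwise) with
   beeswarm/bar/waterfall CSV exports.

No spectra ship with the package: a first-class synthetic generator
reproduces the study's data structure (180 samples × 3 replicate scans,
three orchard-management strata, tannin-coupled absorption bands, tannin
4.73–20.17 mg/g with mean ≈13.2), so every stage is testable end to end.
See `docs/methods.md` for the model and all numerical choices.

## Worked example

```python
from tanninspec import (GeneratorConfig, MCConfig, PipelineConfig, RFConfig,
                        run_pipeline)

cfg = PipelineConfig(
    generator=GeneratorConfig(coupling_strength=0.006, scan_noise_sd=0.002),
    mc=MCConfig(n_iterations=300),
    rf=RFConfig(n_trees=60, tuning_iterations=3, cv_folds=3),
    shap_permutations=8, shap_explain=2, shap_background=15,
    save_raw=False, seed=0,
)
art = run_pipeline(cfg, "out")
print(art["best_model_key"], art["best_val_metrics"])
print(art["shap_exports"]["ranking"].head(3).to_string(index=False))
```

prints (exactly, for this seed):

```
('R_CWT_256', 'characteristic') {'r2': 0.9564138563440312, 'rmse': 0.6304471713922015, 'rpd': 4.823506308929302}
       feature  mean_abs_phi  rank
R_CWT_256@6256      0.136518     1
R_CWT_256@4829      0.090482     2
R_CWT_256@6129      0.085661     3
```

Reading this: the best calibration used wavelet coefficients of raw
reflectance at scale 2⁸ restricted to characteristic bands, reaching
validation R² = 0.956, RMSE = 0.63 mg/g, RPD = 4.8 (well above the 2.0
robustness bar) on this synthetic run. The top Shapley features sit at
4829 cm⁻¹ (inside the O–H combination region) and at 6129–6256 cm⁻¹ — the
scale-256 wavelet's side-lobe response to the 7050 cm⁻¹ overtone band, i.e.
both attribution clusters trace back to tannin-coupled absorption.
`out/` contains every stage artifact as CSV (outlier report, 12-transform
correlation summary, per-scale mean |r| table, 16-model comparison, SHAP
exports) plus a consolidated `report.txt`.

The same workflow is scriptable from the shell:

```bash
tanninspec simulate --seed 1 --out data/
tanninspec run --config pipeline.yaml --seed 1 --out out/
tanninspec report --outdir out/
```

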