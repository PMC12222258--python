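# oligopath

Pathomics-based risk modelling of post-treatment **oligometastasis** (≤5
metastatic lesions in ≤2 organs) from H&E histology, for researchers who
want a fully reproducible, end-to-end reference pipeline:

1. **Pathomics feature extraction** from 512×512 RGB patches: Beer-Lambert
   stain unmixing into hematoxylin/eosin optical-density channels, nucleus
   (primary) and cell (secondary) segmentation, and the shape/texture
   families that drive the model — central moments μ_pq, Zernike magnitudes
   |A_nm|, and granularity spectra (percent intensity removed per
   morphological scale). Patch vectors are averaged to slide level.
2. **Five-stage feature screening**: min-max normalisation → ICC(2,1)
   reproducibility filter (>0.75) → Mann-Whitney U association filter
   (P<0.05) → Spearman collinearity pruning (|ρ|>0.9) → mRMR ranking →
   L1-penalised logistic regression at λ_min (5-fold CV).
3. **DMS-PSO-tuned RBF-SVM**: a dynamic multi-swarm particle swarm
   optimiser searches (log₂C, log₂γ) minimising the cross-validated
   fitness **1 − AUC**, with velocity update
   `v ← ω v + c₁r₁(pbest − x) + c₂r₂(lbest − x)`, position clamping, and
   random sub-swarm regrouping every R iterations. The final SVM is Platt-
   calibrated and classifies high risk at a Youden-index probability cutoff.
4. **Evaluation**: ROC/AUC with DeLong 95% CIs and paired DeLong tests,
   accuracy/sensitivity/specificity at the cutoff, Hosmer-Lemeshow
   calibration with a bootstrap bias-corrected curve, decision-curve
   analysis (net benefit `TP/n − FP/n·p_t/(1−p_t)` vs treat-all/treat-none,
   NNT = 1/NB), and exact kernel SHAP attributions.

A seeded synthetic-data module generates H&E-like patches (irregular
nuclei, class-dependent texture grain) and labelled feature cohorts with
planted signal, so the whole pipeline is testable without clinical data.

## Worked example

```bash
oligopath run --simulate --out run/ --seed 7 --n-subjects 300 --n-features 60 --max-iter 20
```

prints

```
train AUC 0.864 | validation AUC 0.846 | cutoff 0.26 | summary: run/summary.json
```

The run directory contains the screening audit trail, the serialised model,
PSO history, decision curves and `summary.json`. For this seed the cascade
shrinks 60 features → 54 (ICC) → 8 (U test) → 8 → 6 (LASSO); the tuned
hyperparameters are C ≈ 4.0, γ ≈ 3.3e-5, and on the held-out 20% split the
tuned model reaches AUC 0.846 (DeLong 95% CI 0.70–1.00) with sensitivity
0.77 and specificity 0.81 at the Youden cutoff 0.26. A Hosmer-Lemeshow
p = 0.45 indicates no detectable miscalibration.

As a library, the same run is:

```python
from oligopath import OligoRiskModel, PsoConfig

model = OligoRiskModel.from_dataframe(table)      # "label" column + features
results = model.fit(method="dms-pso", seed=7)     # DMS-PSO over (log2 C, log2 gamma)
print(results.summary())                          # hyperparams, cutoff, train AUC
report = results.evaluate(X_val, y_val)           # ROC, calibration, decision curve
shap = results.shap_values(X_val)                 # exact kernel SHAP + ranking
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full synthetic pipeline at study scale (462 subjects, 20.6%
prevalence) and recomputes the package's worked decision-curve arithmetic —
the number needed to treat and the additional true positives per 100
patients implied by a net benefit of 0.16 at the 0.47 risk threshold, and
the simulated cohort prevalence — writing them as JSON.
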