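# danioscope

Attention-based classification of zebrafish embryo phenotypes and probit
LC50 estimation, with a built-in synthetic data generator for closed-loop
validation.

## What this is for

Developmental-toxicity screens expose zebrafish (*Danio rerio*) embryos to
a test compound and score each embryo's morphology — dead/coagulated,
pericardial edema, blood stasis, necrosed yolk sac, or normal — alongside
dose-dependent mortality. Scoring images by hand is slow and subjective;
`danioscope` automates both endpoints:

1. **Phenotype classification.** A convolutional network of the form
   *backbone → CBAM (channel + spatial attention) → global average pooling
   → dense-512 → dropout-0.5 → 5-way softmax*, trained with a three-phase
   transfer-learning schedule (head-only on an external-style corpus, then
   partial and full fine-tuning; Adam, batch 16, plateau learning-rate
   halving to a 1e-6 floor). Predictions are evaluated under Top-k
   (k = 1, 2, 3): a prediction is correct if the true class is among the k
   highest-probability classes — the accommodation for embryos whose final
   state spans several phenotypes.
2. **LC50 estimation.** Mortality fractions are mapped through the
   classical probit (Φ⁻¹(p) + 5), concentrations through log10, a straight
   line is fitted by least squares, and the LC50 is read at probit 5:
   LC50 = 10^((5 − intercept)/slope).

Real assay image sets are rarely public, so the package includes a
parametric generator of labelled synthetic embryo images and of binomial
dose-response tables with known ground truth; the whole pipeline is tested
against it. See `docs/methods.md` for the model, the training protocol and
the generator's scope.

## Worked example

```python
import danioscope as ds

# 1. synthetic corpora with known labels (64x64 px, 50 images/class)
counts = {c: 50 for c in ds.PhenotypeClass}
external = ds.generate_dataset(counts, image_size=64, seed=11)
own      = ds.generate_dataset(counts, image_size=64, seed=12)
test     = ds.generate_dataset({c: 20 for c in ds.PhenotypeClass}, image_size=64, seed=13)

# 2. three-phase training of the tiny backbone (about a minute on one core)
model = ds.train_three_phase(ds.BackboneSpec(), external, own, seed=1,
                             phase_overrides={"max_epochs": 15})

# 3. Top-k evaluation on held-out images
for k, report in ds.evaluate_model(model, test, ks=(1, 2, 3)).items():
    print(f"top-{k} accuracy: {report.accuracy:.2f}")

# 4. probit LC50 from a simulated mortality table
table = ds.generate_dose_response(lc50_true=0.64, slope_true=3.0,
                                  concentrations=[0.064, 0.14, 0.3, 0.64, 1.36, 2.9, 6.4],
                                  n_per_dose=10_000, seed=5)
lc50, fit = ds.estimate_lc50(table)
print(f"LC50 = {lc50:.3f} mg/mL  (slope {fit.slope:.2f}, r^2 {fit.r_squared:.3f})")
```

Output:

```
top-1 accuracy: 0.97
top-2 accuracy: 1.00
top-3 accuracy: 1.00
LC50 = 0.643 mg/mL  (slope 2.93, r^2 1.000)
```

Top-1 accuracy is the fraction of test embryos whose argmax prediction is
the true phenotype; Top-2/Top-3 relax this to the two or three
highest-probability classes, and are non-decreasing in k by construction.
The LC50 line recovers the simulator's ground truth (0.64 mg/mL, slope 3)
to within sampling error.

The same pipeline is available from the shell:

```bash
danioscope generate images --counts 50 --image-size 64 --seed 11 --out data/external
danioscope generate doseresponse --lc50 0.64 --slope 3 --out doses.csv
danioscope train --backbone tiny --external-dir data/external --own-dir data/own --seed 1 --out model
danioscope evaluate --model model --test-dir data/test --k 1 --k 2 --k 3
danioscope lc50 --input doses.csv --out fit.json --plot fit.png
danioscope run-all --seed 1 --out-dir runs   # generate -> train -> evaluate -> lc50
```

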