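# specblend

Multicomponent gas analysis from blended mid-infrared absorption spectra.

In broadband absorption spectroscopy of gas mixtures, the rovibrational
manifolds of different species overlap so strongly that no isolated line
identifies any one component. In the 2950–3150 cm⁻¹ window targeted here,
methane (CH₄), acetone (CH₃COCH₃) and water vapour blend into a single
absorbance vector, further distorted by source power drift, detector
noise, baseline miscalibration and absorption by unknown interlopers.
`specblend` implements an end-to-end treatment of this inverse problem
for people building laser gas sensors or doing chemometrics on broadband
spectra:

- **Forward simulation.** Beer–Lambert line-by-line synthesis
  (`alpha(nu) = S(T) phi(nu) P c L` with Voigt line shapes) from
  HITRAN-format line lists, plus cross-section-table ingestion for smooth
  broadband absorbers; mixture spectra are linear combinations of cached
  per-ppm unit spectra.
- **Corpus generation.** Seven mixture classes over the three gases with
  uniform concentration draws (0–50 ppm traces, 1000–2000 ppm humidity),
  six-digit labels (three binary component identifiers CI + three
  concentrations CR), and four stochastic perturbation channels.
- **The spectral analysis model (SAM).** A multi-task MLP
  (3321 → 196 → 74 → 211 → 6) trained with a joint loss
  `L = L_BCE(CI) + 100 · L_MSE(CR)` (Adam, β₁ = 0.5, β₂ = 0.999), exposed
  as a scikit-learn-style estimator. At inference a concentration is
  reported only when its presence probability exceeds 0.5 — the gating
  rule that separates "absent" from "present but low".
- **Evaluation.** Exact match ratio (EMR), Hamming accuracy (HA), an
  8-class composition confusion matrix, and per-gas R²/MAE/MRE.
- **Interpretability.** Gradient activation maps (GAM): last-hidden-layer
  activation maps fused with guided-backpropagation input gradients,
  `g_a = g_b · M↑`, rendered on the spectral grid.

A synthetic three-gas fixture generator stands in for the databases, so
everything — tests included — runs offline.

## Worked example

```python
from specblend import pipeline

cfg = pipeline.desk_config()          # synthetic fixture, m=1750, 100 epochs
model, dataset, split, report = pipeline.run_holdout_study(cfg, seed=1)

print(f"EMR {report.emr:.4f}  HA {report.ha:.4f}")
for gas, d in report.per_gas.items():
    print(f"{gas:8s} R2 {d['r2']:.4f}  MAE {d['mae']:.3f} ppm  MRE {d['mre']:.2%}")
```

prints (about a minute on one CPU core):

```
EMR 0.9657  HA 0.9886
methane  R2 0.9981  MAE 0.367 ppm  MRE 8.41%
acetone  R2 0.9975  MAE 0.488 ppm  MRE 8.71%
water    R2 0.9993  MAE 11.278 ppm  MRE 1.50%
```

EMR 0.966 means 96.6% of held-out samples had their full three-gas
composition identified exactly; HA counts individual presence flags.
R² ≥ 0.997 per gas says retrieved concentrations track the truth across
the full ranges; the trace-gas MREs are dominated by samples near the
detection limit (relative errors are averaged over truly-present samples
only), while the water MAE of ~11 ppm is small against its 1000–2000 ppm
range. The model then explains itself: `specblend gam` exports which
spectral regions drove any prediction.

The same pipeline runs from the shell:

```sh
specblend simulate --config study.yaml --seed 1 --out data.h5
specblend train    --config study.yaml --seed 1 --dataset data.h5 --out model.ckpt
specblend eval     --config study.yaml --seed 1 --checkpoint model.ckpt \
                   --dataset data.h5 --out metrics.json
specblend predict  --checkpoint model.ckpt --spectrum measured.txt --out pred.json
specblend gam      --checkpoint model.ckpt --spectrum measured.txt --out gam.tsv
specblend cv       --config study.yaml --seed 1 --k 10 --out cv.json
```

A config file overrides any subset of the defaults
(`pipeline.default_config()`); gas sources may be synthetic archetypes,
HITRAN `.par` files (`source: hitran`) or measured cross-section tables
(`source: cross_section`), so the full-scale study (m = 17500, 500
epochs) is one config away once line data are downloaded.

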