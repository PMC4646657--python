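# mgdfseg

Active-contour segmentation of blood vessels by **multi-feature Gaussian
distribution fitting (MGDF)**: a region-based level-set model that fits
local Gaussian statistics to *two* feature channels simultaneously — the
image intensity and a bounded local-phase **vesselness map** — so that
thin, low-contrast vessels survive the intensity inhomogeneity that
defeats single-feature region models.  The package is aimed at
researchers in retinal / vascular image analysis who want a complete,
testable reference implementation of this model family: the MGDF model,
its CV, LBF and LGDF baselines on the same engine, pixel-level
evaluation metrics, and seeded vessel phantoms so everything runs
without external data.

## The model

An image `I : Ω → ℝ` is enhanced by a bank of oriented quadrature
(log-Gabor) filter pairs.  With even/odd responses summed over
orientations into per-scale complex responses `q_m`, the scales are
merged and squashed into a bounded vesselness map

    P  = Re[ Σ_m q_m |q_m|^β / Σ_m |q_m|^β ],
    V  = P·|P| / (P² + α²)  ∈ (−1, 1),

positive inside bright tubular structures, ≈0 at their edges, negative
in background.

A contour is the zero set of `φ` (negative inside).  Around every pixel
`x`, a Gaussian window `ω` weighs a neighborhood in which both features
`F ∈ {I, V}` are modeled, per region `i ∈ {in, out}`, as Gaussians with
local means `u_i^F(x)` and deviations `σ_i^F(x)`.  The data energy is
the ω-weighted negative log-likelihood of both channels,

    E_data = ∫ Σ_i [ λ_i^I e_i^I(x) + λ_i^V e_i^V(x) ] H_i(φ(x)) dx,
    e_i^F(x) = ∫ ω(x−y) [ log 2π + log σ_i^F(y)
                          + (u_i^F(y) − F(x))² / 2σ_i^F(y)² ] dy,

regularized by a contour-length term (weight ν), a distance-
regularization term keeping `φ` near a signed distance function (μ), and
a small-|φ| penalty `η ∫ γ^κ/(γ^κ+|φ|^κ)` discouraging pixels that hover
undecided at the interface.  Minimization is explicit gradient descent;
with the vesselness weights `λ^V = 0` the model reduces *exactly* to
local Gaussian distribution fitting (LGDF).

## Worked example

```python
import mgdfseg as mg

pair = mg.default_phantom(noise_std=3.0, seed=1)   # 3 tubes, bias field, noise
lp = mg.enhance(pair.image)                        # bounded vesselness map
phi0 = mg.initialize_from_vesselness(lp)           # recommended initialization
result = mg.evolve(pair.image, lp, phi0=phi0)      # MGDF level-set evolution

report = mg.performance_metrics(mg.confusion_counts(result.mask, pair.truth))
print(f"iterations: {result.iterations} (converged: {result.converged})")
print(f"Se={report.se:.3f}  Sp={report.sp:.3f}  Acc={report.acc:.3f}  Auc={report.auc:.3f}")
print(f"Dice={mg.dice(result.mask, pair.truth):.3f}")
```

prints

```
iterations: 142 (converged: True)
Se=0.950  Sp=0.993  Acc=0.989  Auc=0.972
Dice=0.944
```

Sensitivity (Se) is the recovered fraction of true vessel pixels,
specificity (Sp) the recovered background fraction, Acc the overall
pixel accuracy, and Auc here is the (Se+Sp)/2 summary used throughout
this literature, not a threshold sweep.  The ~5 % of vessel pixels
missed are mostly on the thinnest (2 px) tube — exactly the failure mode
the vesselness channel mitigates relative to the LGDF baseline (Dice
0.925 on the same phantom and initialization; Chan–Vese and LBF are also
available via `mg.segment("cv" | "lbf" | "lgdf" | "mgdf", ...)`).

The same pipeline is scriptable from the shell:

```sh
mgdfseg phantom --seed 1 --out-image img.tif --out-truth truth.png
mgdfseg segment img.tif --model mgdf --init vesselness --out-mask mask.png
mgdfseg evaluate --pred mask.png --truth truth.png --out report.json
```

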