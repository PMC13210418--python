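# pcdspect

Simulation pipeline for **spectral chest radiography with CdTe photon-counting
detectors**: digital Al/PMMA phantoms, a parametric detector response model
with charge sharing and Poisson noise, basis material decomposition with
polynomial / MLP / SVR regressors, and quantitative + task-based image-quality
evaluation.

The package is aimed at medical imaging physicists who want a controlled,
fully self-contained testbed for comparing material decomposition algorithms
under matched calibration and acquisition conditions — sweeping dose,
calibration-grid density, and the number of energy thresholds — without
needing Monte Carlo tooling or measured detector data.

## The model

A 120 kVp filtered tungsten spectrum `I0(E)` is attenuated per pixel through
two basis materials (aluminum ~ bone, PMMA ~ soft tissue):

    I(E) = I0(E) exp(−μ_Al(E) x_Al − μ_PMMA(E) x_PMMA)

The transmitted spectrum passes through a detector response function (DRF)
matrix `R_ij` — an analytic CdTe model with photopeak, charge-sharing tail,
optional Cd/Te K-escape lines, and Gaussian energy broadening
`σ(E) = sqrt(σ_el² + F ε E)` — then through comparator thresholds into M
energy bins, a 3×3 charge-sharing convolution (on the means), independent
Poisson sampling at the native 0.1 mm pitch, and 10×10 rebinning to 1.0 mm
macro-pixels.

Per-pixel measurements are reduced to log-normalized features
`f_k = −log(n_k / n_k0)` and inverted to thickness estimates
`(t̂_Al, t̂_PMMA)` by one of three regressors trained on a noise-free G×G
calibration grid: a full second-degree polynomial, a 2×128 ReLU network
(Adam, dropout 0.01, smooth-L1 loss), or RBF support vector regression
(C=100, ε=0.010, per Eq. `ŷ(x) = Σ (α_i − α_i*) K(x_i, x) + b`).

Evaluation is twofold:

* **Quantitative** — per-insert bias `Δ = mean(t̂_i − t_true)` and
  `RMSE = sqrt(mean((t̂_i − t_true)²))` across noise realizations on a
  LucAl/IEC-style insert phantom (ten disks, five Al thickness steps and
  five PMMA steps).
* **Task-based** — low-contrast detectability of a 0.1 mm disk with a
  unit-sum disk matched filter and unknown-location scoring, summarized by
  the exponential free-response ROC area
  `A_FE = (1/I) Σ_i exp(−(1/N) Σ_j H(y_j − x_i))` with Hanley–McNeil
  standard errors.

## Worked example

```python
import pcdspect as p

spectrum = p.load_spectrum()                      # 120 kVp, 2 mm Al filtration
config = p.DetectorConfig()                       # 1 mm CdTe, 0.1 mm pixels
drf = p.build_drf(config)
thresholds = p.ThresholdConfig.equally_spaced(4)  # 20/40/60/80 keV

# train a decomposition model on a noise-free 8x8 calibration grid
grid = p.make_calibration_grid(8, spectrum, drf, thresholds)
poly = p.fit_poly2(grid)

# simulate one noisy acquisition of the quantitative phantom at 1.7 mAs
phantom = p.build_quant_phantom()
mean = p.expected_bin_counts(phantom.maps, spectrum, drf, thresholds,
                             exposure_mas=1.725)
shared = p.apply_sharing(mean, p.fit_sharing_kernel(config))
macro = p.rebin(p.sample_poisson(shared, seed=0))

maps = p.decompose(poly, p.to_features(macro, macro))
for rec in p.measure_inserts([maps], phantom)[:3]:
    print(f"insert {rec.insert_id} ({rec.material}, true {rec.t_true} mm): "
          f"bias {rec.bias:+.4f} mm, RMSE {rec.rmse:.4f} mm")

# low-contrast detectability of a 0.1 mm Al disk at the same dose
res = p.run_efroc_task("al_lcd", poly, dose_mas=1.725, spectrum=spectrum,
                       drf=drf, thresholds=thresholds, r=10, seed_base=0)
print(f"A_FE = {res.a_fe:.3f} +/- {res.sigma:.3f}")
```

prints

```
insert 0 (Al, true 4.6 mm): bias -0.0001 mm, RMSE 0.0001 mm
insert 1 (Al, true 5.1 mm): bias +0.0010 mm, RMSE 0.0010 mm
insert 2 (Al, true 5.6 mm): bias +0.0057 mm, RMSE 0.0057 mm
A_FE = 1.000 +/- 0.000
```

i.e. at 1.7 mAs the polynomial model recovers insert thicknesses with
sub-0.01 mm error and the 0.1 mm aluminum disk is detected essentially
perfectly (`A_FE = 1` means every signal-present score beats every
false-positive mark).

The full experiment sweeps are exposed both as library calls
(`run_accuracy_sweep`, `run_efroc_sweep`, `run_mlp_architecture_study`) and
as a CLI:

```bash
pcdspect phantom build --kind quant --out phantom.h5
pcdspect drf build --out drf.csv
pcdspect accuracy-sweep --out-dir runs/
pcdspect efroc-sweep --out-dir runs/
```

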