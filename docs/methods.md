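# Methods

## Signal model and fitting

Each voxel's measurement vector lives on an acquisition grid of (TE, b)
pairs, by default the Cartesian product TE ∈ {57, 70, 150, 200} ms ×
b ∈ {0, 150, 750, 1500} s/mm² (16 points). The five phenomenological
models describe the signal as one to three non-mixing water pools with
Gaussian diffusion (single D per pool, μm²/ms) and monoexponential T2
decay (ms); b·D is computed as (b/1000)·D so the exponent is
dimensionless with these units. The models are nested: 1 → 2 → 3 → 5 and
2 → 4 → 5, differing in pool count and in which pools share a T2 value.
Shared T2 is implemented by tying pools to one parameter slot, so the
fitted-parameter counts are exactly 2, 4, 5, 7, 8.

**Normalization convention.** Measured signals are divided voxelwise by
the (min TE, min b) intensity, and S0 is never fitted. A model with
absolute TE and fractions summing to 1 cannot equal 1 at the reference
point (its value there is Σf·e^(−TEmin/T2) < 1), so the fitted prediction
is the model normalized the same way as the data: S(θ)/S(θ)[ref]. This
keeps the reference residual identically zero, keeps absolute TE in the
exponent, and preserves the meaning of the fractions as TE = 0 signal
fractions. It is the only self-consistent reading of "normalize to the
reference image, don't fit S0", and it is load-bearing: fitting the
un-normalized model to normalized data forces a ~50% systematic misfit.

**Bounds.** D ∈ [0.05, 5.0] μm²/ms (the upper bound deliberately exceeds
the ≈3.1 μm²/ms free-water ceiling at body temperature so noise-driven
estimates remain representable), T2 ∈ [10, 1000] ms, fractions ∈
[0.001, 0.999]. All configurable via `ParameterBounds`.

**Optimization.** Voxelwise trust-region-reflective least squares
(`scipy.optimize.least_squares`) with analytic Jacobians, including the
quotient rule for the reference normalization. Three-pool fractions are
optimized in stick-breaking coordinates (f1 = g1, f2 = (1−g1)g2,
f3 = remainder) so the simplex constraint is a plain box constraint;
results are reported in natural fractions. Tolerances are 1e-10
(ftol/xtol/gtol) with at most 500 evaluations per start — generous for a
16-point problem. Pools are always reported sorted by ascending D, which
removes label-switching ambiguity.

**Cascade.** Models are fitted in ascending order. Each model's start list
contains (a) an exact embedding of the best lower-order solution — e.g.
model 2 started at D1 = D2 = D_model1 — which guarantees, since the
optimizer is monotone in cost, that SSE never increases along a nesting
chain; (b) a "spread" start that splits the duplicated coordinate to break
the embedding's degeneracy; and (c) three jittered restarts (log-normal
multiplicative jitter on D and T2, renormalized additive jitter on
fractions) drawn from a per-voxel RNG stream seeded by (config seed, voxel
index), so volume fits are bit-reproducible and independent of mask shape.
Model 1 starts from log-linear slope estimates of D (over b at minimum TE)
and T2 (over TE at minimum b). A start loop exits early once a start
reaches SSE < 1e-18 — an exact fit that restarts cannot improve. An
optimizer failure never raises; the best bound-clipped solution is
returned flagged `converged=False`. Fits whose pools collapse (D
separation < 1e-3 μm²/ms or a fraction at its bound) are flagged
`degenerate` but still scored.

**AICc.** Evaluated exactly as N ln(SSE/N) + 2(p+1)(1+(p+2)/(N−p−2)).
SSE = 0 maps to −∞ so a perfect fit wins outright (the formula's limit);
N − p − 2 ≤ 0 raises `InadmissibleModelError` — on the 16-point grid all
five models are admissible.

## Structure models

A structure model is ≥2 named compartments with independent Gaussian
(mean, sigma) plausibility distributions over D and T2. The score of a
pool under a compartment is the unit-peak product kernel
exp(−½((D−μ_D)/σ_D)²)·exp(−½((T2−μ_T2)/σ_T2)²) ∈ (0, 1], and pool
composition is the score vector normalized to sum 1. Two readings of a
"0–1 Z-score of a Gaussian distribution" were possible (kernel height vs
tail probability); the kernel height is the bounded, mean-peaked choice
and is what the package implements — it equals 1 exactly at the
compartment means and decays smoothly, with no thresholds anywhere. D and
T2 are treated as independent within a compartment (no covariance is
assumed). If every kernel underflows to exactly zero in double precision
(possible only for (D, T2) far outside all priors), the compartment
nearest in sigma-scaled distance takes fraction 1. Pools fitted at
parameter bounds still receive compositions.

Built-in presets: `esl` (epithelium D 0.3±0.2 μm²/ms, T2 60±30 ms; stroma
1.3±0.5, 220±90; lumen 2.5±0.5, 550±150) and `cellularity` (intracellular
0.5±0.3, 50±20; extracellular 1.2±0.3, 150±40). Custom models load from
YAML; a fourth (e.g. vascular) compartment is accepted without code
changes.

## Aggregation

Akaike weights are computed per voxel from Δ_m = AICc_m − min AICc before
exponentiation (shift-invariant and overflow-safe). A −∞ AICc takes all
the weight, split evenly among ties. Non-converged fits are excluded and
the remaining weights renormalized — a failed fit's AICc is meaningless;
if nothing usable remains the voxel gets uniform weights and a QC flag.
The aggregate X = ΣΣ W·f·x / ΣW is computed with the denominator as
written even though it is 1 by construction. P_Ca = E·(1−L) is a
demonstration score: it is written as its own map, never thresholded into
a binary call, and refuses structure models lacking epithelium/lumen
compartments.

## Synthetic phantoms

The generator assigns each region fixed compartment fractions; every
compartment present in a voxel becomes one water pool whose (D, T2) is
drawn from that compartment's prior truncated to the fitting bounds, so
the forward signal is an exact sample from the structure model's own
assumptions with a one-to-one pool/compartment correspondence (a
`merge_pools` mode fuses two compartments into one effective pool for
robustness experiments). Signals follow the three-pool forward model and
are optionally Rician-corrupted: sqrt((S+n₁)² + n₂²), n ~ N(0, σ²), with
σ = S_ref/SNR and S_ref the mean in-mask reference-image signal — SNR is
quoted where it is highest. Sigma estimation from real data defaults to a
user-supplied scalar; the optional background estimator inverts the
Rayleigh median relation (σ = median/√(2 ln 2)) over a declared
signal-free corner, preferring a robust closed form over a mode of
continuous data.

The default quadrant phantom emulates four prostate environments:
near-pure cystic lumen (E/S/L = 0.02/0.03/0.95), dense stroma
(0.05/0.90/0.05), benign glands (0.30/0.45/0.25) and a tumour-like region
of proliferating epithelium with occluded lumen (0.65/0.30/0.05). These
fractions, and the default SNR of 50 used in the recovery experiment,
were fixed as the study conditions before any recovery results were
inspected.

What the phantom does *not* emulate: realistic anatomy and partial-volume
geometry, spatially correlated noise, motion, exchange between pools, and
perfusion. Passing recovery tests therefore demonstrates internal
consistency of the three stages under the model's own assumptions — not
in vivo accuracy.

## Accuracy characteristics and limitations

Two effects dominate recovery error, and both are properties of the
method rather than of the implementation:

* **Kernel-overlap smear.** A pool drawn one sigma from its compartment
  mean is assigned appreciable mass to neighbouring compartments, so even
  noise-free recovery with the generating model carries per-compartment
  RMSE ≈ 0.09–0.14 when pools are drawn at the full prior widths.
* **Parsimony collapse at moderate SNR.** At SNR 50 on 16 points, a
  three-pool voxel's two-pool fit typically reaches the noise floor, so
  AICc correctly shifts weight toward one/two-pool models (mean model-1
  weight ≈ 0.6 in the quadrant phantom) whose single effective pool maps
  to biased compositions. Measured per-compartment RMSE at SNR 50 is
  ≈ 0.16–0.30; regional contrasts (e.g. highest mean P_Ca in the
  tumour-like region) survive. Biexponential fraction estimates are
  likewise variance-limited: their median absolute error falls below 0.05
  only around SNR 200. This is the averaging method's intended
  bias/variance trade-off, and it bounds what per-voxel accuracy one
  should expect from this protocol at clinical noise levels.

## Problem sizes

The shipped experiments use a 10×10×2 quadrant phantom (200 voxels) for
the SNR-50 recovery run and 500 random three-pool voxels for the
nesting-monotonicity check; both are comfortably large for the statistics
they support while keeping a full run to minutes on one CPU. Larger
phantoms change none of the qualitative conclusions, only the RMSE
standard errors.
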