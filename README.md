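# drmm — multi-model diffusion–relaxation MRI microstructure mapping

`drmm` analyses joint diffusion–relaxation MRI acquisitions of the prostate
(and, by configuration, other tissues): images acquired at all combinations
of several echo times TE and diffusion weightings b, so that every voxel
carries a small 2-D decay surface S(TE, b). From that surface it estimates
the tissue's microscopic composition — fractional volumes of epithelium,
stroma and lumen space — without committing to a single signal model. It is
aimed at quantitative-MRI researchers who want compartmental maps with the
model-selection uncertainty folded in, and who need a fully synthetic test
bed for such pipelines.

## The method

**Stage 1 — phenomenological water pools.** Each voxel's normalized signal
is fitted with five nested models of one to three non-mixing water pools,
each pool having a single apparent diffusivity and T2:

    S/S0 = Σᵢ fᵢ · exp(−b·Dᵢ) · exp(−TE/T2ᵢ),   Σᵢ fᵢ = 1

Model 1 is monoexponential (p = 2 parameters); models 2/3 are
biexponential with shared/distinct T2 (p = 4, 5); models 4/5 are
triexponential with partially shared/distinct T2 (p = 7, 8). S0 is not
fitted: signals are normalized to the minimum-TE, minimum-b image, and the
model prediction is normalized the same way. Models are fitted
progressively — each seeded from the models it nests — and scored with the
small-sample corrected Akaike information criterion

    AICc = N ln(SSE/N) + 2(p+1)(1 + (p+2)/(N−p−2))

with N the number of (TE, b) points (16 in the default protocol).

**Stage 2 — structure assignment.** Fitted pools are not equated with
anatomy. Instead each tissue compartment X ∈ {E, S, L} carries Gaussian
plausibility distributions for D and T2 (e.g. stroma: D 1.3 ± 0.5 μm²/ms,
T2 220 ± 90 ms); a pool at (D, T2) receives unit-peak kernel scores
Z_X ∈ (0, 1], and its composition is x_X = Z_X / (Z_E + Z_S + Z_L).

**Stage 3 — Akaike-weighted averaging.** Per-model predictions are blended
with Akaike weights W_m = e^(−Δ_m/2) / Σ e^(−Δ_m/2), Δ_m = AICc_m − AICc_min:

    X = Σₘ Σₚ W_m · f_mᵖ · x_mᵖ / Σₘ W_m

giving one composition map per compartment, plus a hypothetical
cancer-probability map P_Ca = E·(1−L) (epithelial proliferation with lumen
occlusion).

Because clinical diffusion-relaxation data are rarely shareable, the
package ships a digital phantom generator (`drmm.phantom`) that emulates
cystic, stromal and glandular prostate environments with known ground
truth, including Rician noise, so the whole pipeline is testable offline.

## Worked example

`python examples/01_fit_single_voxel.py` builds a noise-free biexponential
voxel (D = 0.4/1.8 μm²/ms, T2 = 60/300 ms, f1 = 0.5) on the 16-point
protocol and fits all five models:

```
model  p        SSE      AICc  pools (D, T2, fraction)
    1  2   1.26e-02    -106.3  (1.215, 160, 1.000)
    2  4   8.66e-03    -104.4  (0.341, 163, 0.225)  (1.742, 163, 0.775)
    3  5   7.97e-21    -763.5  (0.400, 60, 0.500)  (1.800, 300, 0.500)
    4  7   5.08e-21    -755.5  (0.400, 60, 0.319)  (0.400, 60, 0.181)  (1.800, 300, 0.500)
    5  8   7.97e-21    -736.8  (0.400, 60, 0.500)  (1.800, 300, 0.250)  (1.800, 300, 0.250)
```

The generating model (3) recovers its parameters exactly; richer models
match its fit only by duplicating pools, so the AICc penalty hands model 3
the win and it would carry essentially all the Akaike weight. Examples
02–04 walk through structure mapping, model averaging, and a full phantom
recovery experiment; `drmm --help` exposes the same pipeline as shell
commands (`simulate`, `run-all`, `render`).

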