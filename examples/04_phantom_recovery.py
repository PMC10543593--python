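"""End-to-end recovery on a digital prostate phantom.

Generates a quadrant phantom (cystic space, dense stroma, benign glands,
tumour-like glands), simulates its 16-point diffusion-relaxation signals,
runs preprocessing, the five-model cascade, structure mapping and Akaike
averaging, and reports per-compartment RMSE against the known ground truth
plus the mean cancer-probability score per region.

Noise-free and small (6x6x1) so it runs in well under a minute; raise the
shape and set a finite snr for a realistic experiment.
"""

from drmm import FitConfig, recovery_experiment, three_region_phantom

spec = three_region_phantom(shape=(6, 6, 1), snr=float("inf"), seed=0)
report = recovery_experiment(spec, fit_config=FitConfig(seed=0))

print(f"{report['n_voxels']} voxels, SNR = {report['snr']}")
print("\nOverall RMSE vs ground truth (fractional volume units):")
for name, rmse in report["rmse"].items():
    print(f"  {name:<11} {rmse:.3f}")

print("\nMean Akaike weight per model:")
for m, w in report["mean_weights"].items():
    print(f"  model {m}: {w:.3f}")

print(f"\n{'region':<14} {'P_Ca':>6}  mean predicted (E, S, L)")
for label, entry in report["regions"].items():
    mf = entry["mean_fraction"]
    print(
        f"{label:<14} {entry['mean_p_ca']:>6.3f}  "
        f"({mf['epithelium']:.2f}, {mf['stroma']:.2f}, {mf['lumen']:.2f})"
    )
print(
    "\nNoise-free, the three-pool model takes nearly all weight and the\n"
    "tumour-like region (high epithelium, occluded lumen) shows the highest\n"
    "P_Ca. Residual RMSE reflects kernel overlap between compartments, not\n"
    "fitting error."
)
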