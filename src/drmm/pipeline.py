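"""End-to-end pipeline: preprocess → fit cascade → compose → aggregate.

Stage 1 fits the five water-pool models per voxel; Stage 2 converts each
fitted pool's (D, T2) into compartment fractions under a structure model;
Stage 3 averages the per-model predictions with Akaike weights. The module
also provides the phantom recovery experiment (simulate → full pipeline →
error report against ground truth) and a file-driven `run_pipeline` used by
the command-line interface.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .acquisition import (
    AcquisitionGrid,
    NoiseEstimate,
    correct_rician_bias,
    estimate_sigma_background,
    load_volume,
    normalize_signal,
    write_map,
)
from .aggregate import akaike_weights, cancer_probability, voxel_composition
from .phantom import PhantomSpec, forward_signal, sample_pools
from .signal_models import FitConfig, VolumeFit, fit_volume
from .structure import ESL, StructureModel, load_structure_model

logger = logging.getLogger(__name__)


@dataclass
class CompositionResult:
    """Aggregated per-voxel composition maps plus per-model weight maps."""

    structure: StructureModel
    composition: dict[str, np.ndarray]  # compartment -> 3-D map
    weights: dict[int, np.ndarray]  # model_id -> 3-D map
    flagged: np.ndarray  # voxels where no model had usable AICc

    def cancer_probability_map(self) -> np.ndarray:
        names = self.structure.compartment_names
        if "epithelium" not in names or "lumen" not in names:
            raise ValueError(
                "cancer probability needs an epithelium/lumen structure model; "
                f"got compartments {list(names)}"
            )
        return cancer_probability(
            self.composition["epithelium"], self.composition["lumen"]
        )


def compose_volume(
    volfit: VolumeFit, structure: StructureModel = ESL
) -> CompositionResult:
    """Stages 2+3 over a fitted volume: per-pool composition, Akaike averaging."""
    shape = volfit.shape
    comp = {n: np.full(shape, np.nan) for n in structure.compartment_names}
    wmaps = {m: np.full(shape, np.nan) for m in volfit.model_ids}
    flagged = np.zeros(shape, dtype=bool)
    for idx, fits in zip(volfit.voxels, volfit.fits):
        weights = akaike_weights(
            {f.model_id: f.aicc for f in fits},
            include={f.model_id: f.converged for f in fits},
        )
        flagged[idx] = weights.flagged
        for m, w in weights.weights.items():
            wmaps[m][idx] = w
        vox = voxel_composition(fits, structure, weights)
        for name, value in vox.items():
            comp[name][idx] = value
    return CompositionResult(
        structure=structure, composition=comp, weights=wmaps, flagged=flagged
    )


def recovery_experiment(
    spec: PhantomSpec,
    grid: Optional[AcquisitionGrid] = None,
    fit_config: Optional[FitConfig] = None,
    structure: StructureModel = ESL,
) -> dict:
    """Simulate a phantom, run the full pipeline, score against ground truth.

    Returns a report with, per region and overall: RMSE between aggregated
    and true compartment fractions, mean Akaike weight per model, and mean
    P_Ca (when the structure model supports it).
    """
    grid = grid or AcquisitionGrid.from_product()
    fit_config = fit_config or FitConfig(seed=spec.seed)
    gt = sample_pools(spec, structure)
    vol, sigma = forward_signal(gt, grid)
    vol = correct_rician_bias(vol, NoiseEstimate(sigma=sigma))
    vol = normalize_signal(vol, grid)
    volfit = fit_volume(vol, grid, fit_config)
    result = compose_volume(volfit, structure)

    mask = vol.get_mask()
    names = structure.compartment_names
    report: dict = {
        "n_voxels": int(mask.sum()),
        "snr": spec.snr,
        "sigma": sigma,
        "rmse": {},
        "regions": {},
        "mean_weights": {},
    }
    for name in names:
        err = result.composition[name][mask] - gt.fractions[name][mask]
        report["rmse"][name] = float(np.sqrt(np.mean(err**2)))
    for m, wmap in result.weights.items():
        report["mean_weights"][m] = float(np.nanmean(wmap[mask]))
    has_pca = "epithelium" in names and "lumen" in names
    pca = result.cancer_probability_map() if has_pca else None
    for label, rmask in spec.region_masks().items():
        rmask = rmask & mask
        entry = {"n_voxels": int(rmask.sum()), "rmse": {}, "mean_fraction": {}}
        for name in names:
            err = result.composition[name][rmask] - gt.fractions[name][rmask]
            entry["rmse"][name] = float(np.sqrt(np.mean(err**2)))
            entry["mean_fraction"][name] = float(np.mean(result.composition[name][rmask]))
        if has_pca:
            entry["mean_p_ca"] = float(np.mean(pca[rmask]))
        report["regions"][label] = entry
    report["composition"] = result
    report["ground_truth"] = gt
    return report


@dataclass
class RunConfig:
    """File-driven pipeline configuration (mirrors the YAML config schema)."""

    input_path: Path
    grid_csv: Path
    output_dir: Path
    sigma: Optional[float] = None  # None -> estimate from background corner
    mask_path: Optional[Path] = None
    structure: str | Mapping = "esl"
    model_ids: tuple[int, ...] = (1, 2, 3, 4, 5)
    restarts: int = 3
    seed: int = 0
    write_csv: bool = True
    csv_voxel_limit: int = 20000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            input_path=Path(raw["input_path"]),
            grid_csv=Path(raw["grid_csv"]),
            output_dir=Path(raw["output_dir"]),
            sigma=raw.get("sigma"),
            mask_path=Path(raw["mask_path"]) if raw.get("mask_path") else None,
            structure=raw.get("structure", "esl"),
            model_ids=tuple(raw.get("model_ids", (1, 2, 3, 4, 5))),
            restarts=int(raw.get("restarts", 3)),
            seed=int(raw.get("seed", 0)),
        )

    def validate(self) -> None:
        for p in (self.input_path, self.grid_csv):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.mask_path is not None and not Path(self.mask_path).exists():
            raise FileNotFoundError(self.mask_path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline from files; returns the output manifest."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    grid = AcquisitionGrid.from_csv(config.grid_csv)
    vol = load_volume(config.input_path, grid, mask_path=config.mask_path)
    logger.info("loaded volume %s, %d in-mask voxels", vol.shape, vol.get_mask().sum())

    if config.sigma is not None:
        noise = NoiseEstimate(sigma=float(config.sigma))
    else:
        noise = estimate_sigma_background(vol)
        logger.info("estimated background sigma = %.3f", noise.sigma)
    vol = correct_rician_bias(vol, noise)
    vol = normalize_signal(vol, grid)
    logger.info("normalized; %d voxels remain in mask", vol.get_mask().sum())

    fit_config = FitConfig(
        model_ids=config.model_ids, restarts=config.restarts, seed=config.seed
    )
    volfit = fit_volume(vol, grid, fit_config)
    structure = load_structure_model(config.structure)
    result = compose_volume(volfit, structure)

    outputs: dict[str, str] = {}

    def save(name: str, arr: np.ndarray) -> None:
        path = outdir / f"{name}.nii"
        write_map(arr, vol, path)
        outputs[name] = str(path)

    for m in volfit.model_ids:
        save(f"aicc_model{m}", volfit.aicc_map(m))
        save(f"weight_model{m}", result.weights[m])
    for name, arr in result.composition.items():
        save(f"composition_{name}", arr)
    names = structure.compartment_names
    if "epithelium" in names and "lumen" in names:
        save("p_ca", result.cancer_probability_map())

    if config.write_csv and len(volfit.voxels) <= config.csv_voxel_limit:
        rows = []
        for idx, fits in zip(volfit.voxels, volfit.fits):
            for fit in fits:
                for p, pool in enumerate(fit.pools):
                    rows.append(
                        {
                            "x": idx[0],
                            "y": idx[1],
                            "z": idx[2],
                            "model": fit.model_id,
                            "pool": p + 1,
                            "d": pool.d,
                            "t2": pool.t2,
                            "fraction": pool.fraction,
                            "sse": fit.sse,
                            "aicc": fit.aicc,
                            "converged": fit.converged,
                        }
                    )
        csv_path = outdir / "voxel_fits.csv"
        pd.DataFrame(rows).to_csv(csv_path, index=False)
        outputs["voxel_fits"] = str(csv_path)

    manifest = {
        "inputs": {
            "input_path": str(config.input_path),
            "grid_csv": str(config.grid_csv),
            "mask_path": str(config.mask_path) if config.mask_path else None,
        },
        "settings": {
            "sigma": noise.sigma,
            "sigma_source": noise.source,
            "structure": structure.name,
            "model_ids": list(volfit.model_ids),
            "restarts": config.restarts,
            "seed": config.seed,
        },
        "n_voxels_fit": len(volfit.voxels),
        "outputs": outputs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
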