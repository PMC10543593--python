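"""Acquisition geometry, image I/O, and signal preprocessing.

A diffusion-relaxation acquisition samples the joint (TE, b) plane: every
voxel carries one magnitude intensity per (echo time, b-value) combination.
This module defines the :class:`AcquisitionGrid` that orders those samples,
the :class:`SignalVolume` container that holds the 4-D image aligned with
the grid, Rician noise-floor correction, and normalization of each voxel's
measurement vector to its (min TE, min b) intensity.

Units convention used throughout the package: TE and T2 in ms, b in s/mm²,
diffusivity D in μm²/ms. The product b·D is made dimensionless as
(b/1000)·D, matching the customary printed unit pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Exemplar protocol: all combinations of four echo times and four b-values,
#: giving 16 measurement points per voxel.
DEFAULT_TE_MS = (57.0, 70.0, 150.0, 200.0)
DEFAULT_B_S_PER_MM2 = (0.0, 150.0, 750.0, 1500.0)


class GridError(ValueError):
    """Invalid acquisition grid or grid/volume mismatch."""


@dataclass(frozen=True)
class AcquisitionGrid:
    """Ordered set of (TE, b) sampling points.

    Points are sorted lexicographically by (TE, b). The grid must contain a
    point at (min TE, min b): that image is the normalization reference.

    Parameters
    ----------
    points
        Sequence of (TE_ms, b_s_per_mm2) pairs. Duplicates are rejected.
    """

    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        pts = tuple((float(te), float(b)) for te, b in self.points)
        pts = tuple(sorted(pts))
        if len(set(pts)) != len(pts):
            raise GridError("duplicate (TE, b) points in grid")
        if not pts:
            raise GridError("empty acquisition grid")
        for te, b in pts:
            if te <= 0:
                raise GridError(f"TE must be positive, got {te}")
            if b < 0:
                raise GridError(f"b must be non-negative, got {b}")
        te_min = min(te for te, _ in pts)
        b_min = min(b for _, b in pts)
        if (te_min, b_min) not in pts:
            raise GridError(
                "grid has no (min TE, min b) point; normalization reference "
                f"({te_min}, {b_min}) must be acquired"
            )
        object.__setattr__(self, "points", pts)

    @classmethod
    def from_product(
        cls,
        te_values: Sequence[float] = DEFAULT_TE_MS,
        b_values: Sequence[float] = DEFAULT_B_S_PER_MM2,
    ) -> "AcquisitionGrid":
        """Full Cartesian product of TE and b values (the exemplar protocol)."""
        return cls(tuple((te, b) for te in te_values for b in b_values))

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def te_values(self) -> tuple[float, ...]:
        """Distinct echo times, ascending (ms)."""
        return tuple(sorted({te for te, _ in self.points}))

    @property
    def b_values(self) -> tuple[float, ...]:
        """Distinct b-values, ascending (s/mm²)."""
        return tuple(sorted({b for _, b in self.points}))

    @property
    def te(self) -> np.ndarray:
        """Echo time per point, shape (n_points,)."""
        return np.array([te for te, _ in self.points])

    @property
    def b(self) -> np.ndarray:
        """b-value per point, shape (n_points,)."""
        return np.array([b for _, b in self.points])

    @property
    def reference_index(self) -> int:
        """Index of the (min TE, min b) point used for normalization."""
        te_min = min(self.te_values)
        b_min = min(self.b_values)
        return self.points.index((te_min, b_min))

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "volume_index": np.arange(self.n_points),
                "TE_ms": self.te,
                "b_s_per_mm2": self.b,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_table().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AcquisitionGrid":
        """Read a sidecar table (columns volume_index, TE_ms, b_s_per_mm2).

        The stored volume order must already be the lexicographic (TE, b)
        order; vendor orderings must be resorted upstream.
        """
        df = pd.read_csv(path)
        required = {"volume_index", "TE_ms", "b_s_per_mm2"}
        if not required.issubset(df.columns):
            raise GridError(f"grid table must have columns {sorted(required)}")
        df = df.sort_values("volume_index")
        pts = tuple(zip(df["TE_ms"].astype(float), df["b_s_per_mm2"].astype(float)))
        grid = cls(pts)
        if grid.points != pts:
            raise GridError(
                "grid table rows are not in lexicographic (TE, b) order; "
                "reorder the volumes and table to the canonical order"
            )
        return grid


@dataclass
class SignalVolume:
    """4-D signal array aligned with an :class:`AcquisitionGrid`.

    ``data[x, y, z, i]`` is the magnitude intensity at grid point ``i``.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D data, got {self.data.ndim}-D")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match spatial "
                    f"dims {self.data.shape[:3]}"
                )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """Voxel edge lengths in mm, from the affine."""
        return tuple(np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0)))

    def get_mask(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.data.shape[:3], dtype=bool)
        return self.mask


@dataclass(frozen=True)
class NoiseEstimate:
    """Rician noise standard deviation in (raw) signal units."""

    sigma: float
    source: str = "user_supplied"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")


def load_volume(
    path: str | Path,
    grid: AcquisitionGrid,
    mask_path: str | Path | None = None,
) -> SignalVolume:
    """Load a 4-D NIfTI (or a directory of 3-D NIfTIs) aligned with *grid*.

    The 4th dimension (or the file count, in directory mode with files taken
    in sorted-name order) must equal ``grid.n_points``; volumes are assumed
    stored in the grid's lexicographic (TE, b) order as declared by the
    sidecar table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.name.endswith((".nii", ".nii.gz"))
        )
        if len(files) != grid.n_points:
            raise GridError(
                f"expected {grid.n_points} points, directory has {len(files)} volumes"
            )
        imgs = [nib.load(str(f)) for f in files]
        data = np.stack([np.asarray(img.dataobj, dtype=float) for img in imgs], axis=-1)
        affine = imgs[0].affine
    else:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise GridError(f"expected 4-D image, got {data.ndim}-D")
        if data.shape[3] != grid.n_points:
            raise GridError(
                f"expected {grid.n_points} points, volume has {data.shape[3]}"
            )
        affine = img.affine
    bad = ~np.isfinite(data)
    if bad.any():
        coords = np.argwhere(bad)[:10]
        raise ValueError(
            f"non-finite voxels in {path}: first offending coordinates "
            f"{[tuple(int(v) for v in c) for c in coords]}"
        )
    mask = None
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        mask = np.asarray(mimg.dataobj) > 0
    return SignalVolume(data=data, affine=affine, mask=mask)


def correct_rician_bias(vol: SignalVolume, noise: NoiseEstimate) -> SignalVolume:
    """Remove the Rician noise-floor bias from magnitude intensities.

    Each magnitude M is replaced by sqrt(max(M² − σ², 0)), the first-order
    magnitude-bias correction: at high SNR the magnitude expectation is
    approximately sqrt(signal² + σ²), so subtracting σ² in quadrature
    recovers the underlying signal. Values below the noise floor clamp to 0.
    """
    sigma = noise.sigma
    corrected = np.sqrt(np.maximum(vol.data**2 - sigma**2, 0.0))
    return replace(vol, data=corrected)


def estimate_sigma_background(
    vol: SignalVolume, corner: tuple[int, int, int] = (4, 4, 1)
) -> NoiseEstimate:
    """Estimate Rician sigma from a signal-free corner region.

    Background magnitudes are Rayleigh distributed with median σ·sqrt(2 ln 2);
    the estimator inverts that relation on the corner block (all grid points
    pooled), which is robust to stray bright voxels.
    """
    nx, ny, nz = corner
    block = vol.data[:nx, :ny, :nz, :]
    med = float(np.median(block))
    sigma = med / np.sqrt(2.0 * np.log(2.0))
    return NoiseEstimate(sigma=sigma, source="background_roi")


def normalize_signal(vol: SignalVolume, grid: AcquisitionGrid) -> SignalVolume:
    """Divide each voxel's vector by its (min TE, min b) intensity.

    After normalization the reference entry is exactly 1 for every in-mask
    voxel, which is what lets the signal models drop S0 as a fitted
    parameter. Voxels whose reference intensity is ≤ 0 cannot be normalized;
    they are removed from the mask and logged.
    """
    ref_idx = grid.reference_index
    if vol.data.shape[3] != grid.n_points:
        raise GridError(
            f"volume has {vol.data.shape[3]} points, grid has {grid.n_points}"
        )
    ref = vol.data[..., ref_idx]
    mask = vol.get_mask().copy()
    bad = mask & (ref <= 0)
    if bad.any():
        logger.warning(
            "normalize_signal: dropping %d voxel(s) with non-positive "
            "reference intensity from the mask",
            int(bad.sum()),
        )
        mask &= ~bad
    with np.errstate(divide="ignore", invalid="ignore"):
        data = vol.data / ref[..., None]
    data[~mask] = np.nan
    return SignalVolume(data=data, affine=vol.affine, mask=mask)


def write_map(map3d: np.ndarray, template: SignalVolume, path: str | Path) -> Path:
    """Write a 3-D parameter map as NIfTI using the template's geometry."""
    map3d = np.asarray(map3d, dtype=np.float64)
    if map3d.shape != template.data.shape[:3]:
        raise ValueError(
            f"map shape {map3d.shape} does not match template spatial dims "
            f"{template.data.shape[:3]}"
        )
    img = nib.Nifti1Image(map3d, template.affine)
    nib.save(img, str(path))
    return Path(path)


def write_volume(vol: SignalVolume, path: str | Path) -> Path:
    """Write a 4-D signal volume as NIfTI."""
    img = nib.Nifti1Image(vol.data.astype(np.float64), vol.affine)
    nib.save(img, str(path))
    return Path(path)
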