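"""Digital tissue phantoms with known ground truth.

A phantom assigns each voxel a set of compartment fractional volumes (e.g.
epithelium / stroma / lumen). Each compartment present in a voxel becomes
one water pool whose (D, T2) is drawn from that compartment's Gaussian
prior, truncated to the fitting bounds, so the forward signal is an honest
sample from the structure model's assumptions. Signals are laid on the
(TE, b) acquisition grid by the multi-pool forward model

    S(TE, b) = sum_p f_p * exp(-(b/1000) D_p) * exp(-TE / T2_p)

and optionally corrupted with Rician noise: sqrt((S + n1)^2 + n2^2) with
n1, n2 ~ N(0, sigma^2) and sigma = S_ref / SNR, where S_ref is the mean
in-mask signal of the (min TE, min b) image (the highest-SNR image).

The default preset emulates three distinct prostate environments —
an acellular cystic space, dense non-glandular stroma, loosely packed
benign glands — plus a tumour-like region of proliferating epithelium with
occluded lumen, arranged as quadrants of an axial slab.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import truncnorm

from .acquisition import AcquisitionGrid, SignalVolume
from .signal_models import ParameterBounds
from .structure import ESL, StructureModel


@dataclass(frozen=True)
class PhantomRegion:
    """A labelled voxel set with fixed compartment fractional volumes."""

    label: str
    fractions: dict[str, float]
    slices: tuple[slice, slice, slice]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"region {self.label!r}: fractions sum to {total}")
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError(f"region {self.label!r}: negative fraction")


@dataclass(frozen=True)
class PhantomSpec:
    """Phantom geometry + acquisition noise level.

    snr is the reference-image SNR; ``snr=inf`` means noise-free.
    """

    shape: tuple[int, int, int]
    regions: tuple[PhantomRegion, ...]
    snr: float = float("inf")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive (use inf for noise-free)")
        occupancy = np.zeros(self.shape, dtype=int)
        for r in self.regions:
            occupancy[r.slices] += 1
        if (occupancy > 1).any():
            raise ValueError("phantom regions overlap")

    def region_masks(self) -> dict[str, np.ndarray]:
        out = {}
        for r in self.regions:
            m = np.zeros(self.shape, dtype=bool)
            m[r.slices] = True
            out[r.label] = m
        return out

    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        for r in self.regions:
            m[r.slices] = True
        return m


def three_region_phantom(
    shape: tuple[int, int, int] = (32, 32, 4),
    snr: float = float("inf"),
    seed: int = 0,
) -> PhantomSpec:
    """Quadrant phantom: cyst, dense stroma, benign gland, tumour-like gland.

    Composition choices: the cyst is almost pure lumen water; dense stroma is
    stroma-dominated; the benign glandular region mixes all three
    compartments; the tumour-like region is epithelium-rich with occluded
    lumen, so it should light up in the P_Ca map.
    """
    nx, ny, nz = shape
    hx, hy = nx // 2, ny // 2
    regions = (
        PhantomRegion(
            "cyst",
            {"epithelium": 0.02, "stroma": 0.03, "lumen": 0.95},
            (slice(0, hx), slice(0, hy), slice(0, nz)),
        ),
        PhantomRegion(
            "stroma_dense",
            {"epithelium": 0.05, "stroma": 0.90, "lumen": 0.05},
            (slice(0, hx), slice(hy, ny), slice(0, nz)),
        ),
        PhantomRegion(
            "gland_benign",
            {"epithelium": 0.30, "stroma": 0.45, "lumen": 0.25},
            (slice(hx, nx), slice(0, hy), slice(0, nz)),
        ),
        PhantomRegion(
            "tumour",
            {"epithelium": 0.65, "stroma": 0.30, "lumen": 0.05},
            (slice(hx, nx), slice(hy, ny), slice(0, nz)),
        ),
    )
    return PhantomSpec(shape=shape, regions=regions, snr=snr, seed=seed)


@dataclass
class GroundTruth:
    """Per-voxel true compartment fractions and the pools used forward.

    ``fractions[name]`` is a 3-D map; ``pool_d/pool_t2/pool_f`` are 4-D
    arrays (x, y, z, compartment) with NaN where a compartment is absent.
    """

    spec: PhantomSpec
    compartment_names: tuple[str, ...]
    fractions: dict[str, np.ndarray]
    pool_d: np.ndarray
    pool_t2: np.ndarray
    pool_f: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = self.spec.mask()


def _truncated_normal(
    mean: float, sigma: float, lo: float, hi: float, size, rng: np.random.Generator
) -> np.ndarray:
    if sigma == 0.0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sigma, (hi - mean) / sigma
    return truncnorm.rvs(a, b, loc=mean, scale=sigma, size=size, random_state=rng)


def sample_pools(
    spec: PhantomSpec,
    structure: StructureModel = ESL,
    bounds: Optional[ParameterBounds] = None,
    merge_pools: Optional[Sequence[tuple[str, str]]] = None,
    scale_sigmas: float = 1.0,
) -> GroundTruth:
    """Draw each voxel's water pools from the structure model's priors.

    One pool per compartment with positive fraction; (D, T2) sampled from
    the compartment's Gaussian truncated to the fitting bounds, so the
    forward signal is always fittable. Deterministic given ``spec.seed``.
    ``scale_sigmas`` scales every prior sigma (0 collapses the draws to the
    prior means exactly — useful for fully deterministic phantoms).

    ``merge_pools`` lists compartment-name pairs to merge into a single pool
    ("meso-mixing"): the merged pool gets the fraction-weighted mean (D, T2)
    of its parents and their combined fraction, emulating voxels where
    structurally distinct tissue shares one effective water pool.
    """
    bounds = bounds or ParameterBounds()
    rng = np.random.default_rng(spec.seed)
    names = structure.compartment_names
    shape = spec.shape
    ncomp = len(names)
    fractions = {n: np.zeros(shape) for n in names}
    pool_d = np.full(shape + (ncomp,), np.nan)
    pool_t2 = np.full(shape + (ncomp,), np.nan)
    pool_f = np.full(shape + (ncomp,), np.nan)

    for region in spec.regions:
        m = np.zeros(shape, dtype=bool)
        m[region.slices] = True
        nvox = int(m.sum())
        for ci, name in enumerate(names):
            frac = region.fractions.get(name, 0.0)
            fractions[name][m] = frac
            if frac <= 0:
                continue
            prior = structure[name]
            pool_d[m, ci] = _truncated_normal(
                prior.d_mean, prior.d_sigma * scale_sigmas, *bounds.d, nvox, rng
            )
            pool_t2[m, ci] = _truncated_normal(
                prior.t2_mean, prior.t2_sigma * scale_sigmas, *bounds.t2, nvox, rng
            )
            pool_f[m, ci] = frac

    if merge_pools:
        for name_a, name_b in merge_pools:
            ia, ib = names.index(name_a), names.index(name_b)
            both = np.isfinite(pool_f[..., ia]) & np.isfinite(pool_f[..., ib])
            fa, fb = pool_f[..., ia], pool_f[..., ib]
            tot = np.where(both, fa + fb, np.nan)
            wa = np.where(both, fa / tot, np.nan)
            pool_d[both, ia] = (wa * pool_d[..., ia] + (1 - wa) * pool_d[..., ib])[both]
            pool_t2[both, ia] = (wa * pool_t2[..., ia] + (1 - wa) * pool_t2[..., ib])[
                both
            ]
            pool_f[both, ia] = tot[both]
            pool_d[both, ib] = np.nan
            pool_t2[both, ib] = np.nan
            pool_f[both, ib] = np.nan

    return GroundTruth(
        spec=spec,
        compartment_names=names,
        fractions=fractions,
        pool_d=pool_d,
        pool_t2=pool_t2,
        pool_f=pool_f,
    )


def forward_signal(
    gt: GroundTruth,
    grid: AcquisitionGrid,
    snr: Optional[float] = None,
    seed: Optional[int] = None,
    s0: float = 1000.0,
) -> tuple[SignalVolume, float]:
    """Simulate magnitude signals for a ground-truth phantom.

    Returns the (volume, sigma) pair; sigma is the Rician noise standard
    deviation actually applied (0 for noise-free), defined as S_ref / snr
    with S_ref the mean in-mask (min TE, min b) signal. ``s0`` is an
    arbitrary scanner intensity scale removed again by normalization.
    """
    snr = gt.spec.snr if snr is None else snr
    seed = gt.spec.seed + 1 if seed is None else seed
    bprime = grid.b / 1000.0
    te = grid.te
    shape = gt.spec.shape
    signal = np.zeros(shape + (grid.n_points,))
    d = gt.pool_d[..., None, :]  # (x, y, z, 1, ncomp)
    t2 = gt.pool_t2[..., None, :]
    f = gt.pool_f[..., None, :]
    with np.errstate(invalid="ignore"):
        decay = f * np.exp(-bprime[:, None] * d) * np.exp(-te[:, None] / t2)
    signal = np.nansum(decay, axis=-1) * s0
    mask = gt.mask
    signal[~mask] = 0.0

    ref = signal[..., grid.reference_index]
    s_ref = float(ref[mask].mean()) if mask.any() else s0
    if np.isinf(snr):
        sigma = 0.0
        noisy = signal
    else:
        sigma = s_ref / snr
        rng = np.random.default_rng(seed)
        n1 = rng.normal(0.0, sigma, signal.shape)
        n2 = rng.normal(0.0, sigma, signal.shape)
        noisy = np.sqrt((signal + n1) ** 2 + n2**2)
    return SignalVolume(data=noisy, mask=mask.copy()), sigma
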