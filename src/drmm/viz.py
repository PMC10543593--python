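"""Map renderers.

Two figure conventions for parameter maps:

* pool-property maps: colour encodes the pool's D or T2 value through a
  colormap, per-pixel brightness scales linearly with the pool's signal
  fraction (so a faint pool fades to black);
* ESL composition maps: per-voxel RGB channels proportional to the
  epithelium (red), stroma (green) and lumen (blue) fractional volumes.

Renderers take 3-D maps, pick one axial slice (middle by default) and write
PNG files.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import numpy as np
from matplotlib import colormaps
from PIL import Image

#: Default display ranges: D up to the ~3.1 μm²/ms free-water ceiling at
#: body temperature; T2 over the allowed fitting window.
D_RANGE = (0.0, 3.1)
T2_RANGE = (10.0, 1000.0)


def _pick_slice(arr: np.ndarray, z: int | None) -> np.ndarray:
    if arr.ndim != 3:
        raise ValueError(f"expected a 3-D map, got {arr.ndim}-D")
    zi = arr.shape[2] // 2 if z is None else z
    return arr[:, :, zi]


def _to_png(rgb: np.ndarray, path: str | Path) -> Path:
    img = Image.fromarray((np.clip(rgb, 0, 1) * 255).astype(np.uint8))
    img.save(str(path))
    return Path(path)


def render_pool_map(
    values: np.ndarray,
    fractions: np.ndarray,
    path: str | Path,
    value_range: tuple[float, float] = D_RANGE,
    cmap: str = "viridis",
    z: int | None = None,
) -> Path:
    """Render a pool property map with fraction-scaled brightness."""
    values = np.asarray(values, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    if values.shape != fractions.shape:
        raise ValueError(
            f"value shape {values.shape} != fraction shape {fractions.shape}"
        )
    v = _pick_slice(values, z)
    f = _pick_slice(fractions, z)
    lo, hi = value_range
    norm = np.clip((v - lo) / (hi - lo), 0, 1)
    norm = np.nan_to_num(norm)
    rgba = colormaps[cmap](norm)
    brightness = np.clip(np.nan_to_num(f), 0, 1)
    rgb = rgba[..., :3] * brightness[..., None]
    return _to_png(rgb, path)


def render_esl_rgb(
    composition: dict[str, np.ndarray], path: str | Path, z: int | None = None
) -> Path:
    """Render a three-compartment composition as an RGB image.

    Channels: epithelium → red, stroma → green, lumen → blue (any
    three-compartment model is accepted in its declared order).
    """
    if len(composition) != 3:
        raise ValueError(
            f"RGB rendering needs exactly 3 compartments, got "
            f"{len(composition)} ({sorted(composition)}); render scalar maps "
            "with render_pool_map instead"
        )
    order = ["epithelium", "stroma", "lumen"]
    names = (
        order if all(n in composition for n in order) else list(composition.keys())
    )
    channels = [np.nan_to_num(_pick_slice(np.asarray(composition[n]), z)) for n in names]
    rgb = np.stack(channels, axis=-1)
    return _to_png(rgb, path)
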