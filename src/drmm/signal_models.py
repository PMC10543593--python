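"""The five nested phenomenological water-pool models and their fitting.

Each model describes the normalized signal S/S0 on the (TE, b) grid as a sum
of one to three non-mixing water pools, each with Gaussian diffusion (single
diffusivity D) and monoexponential T2 relaxation:

    S/S0 = sum_i f_i * exp(-(b/1000) * D_i) * exp(-TE / T2_i)

with fractions summing to 1. The five models differ in pool count and in
which pools share a T2 value:

    Model 1: one pool                      (p = 2: D, T2)
    Model 2: two pools, common T2          (p = 4: D1, D2, T2, f1)
    Model 3: two pools, distinct T2        (p = 5: D1, D2, T2_1, T2_2, f1)
    Model 4: three pools, pools 1+2 share T2   (p = 7)
    Model 5: three pools, distinct T2      (p = 8)

S0 is never fitted: signals are pre-normalized to the (min TE, min b) image.

Fitting is voxelwise non-linear least squares, run as a cascade: each model
is seeded from the best fit of the model(s) it nests, including one start
that embeds the lower model's solution exactly (which guarantees the SSE is
non-increasing along each nesting chain), plus seeded jittered restarts.
Models are scored with the small-sample corrected Akaike information
criterion

    AICc = N ln(SSE/N) + 2(p+1) (1 + (p+2)/(N - p - 2)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .acquisition import AcquisitionGrid, SignalVolume

logger = logging.getLogger(__name__)


class InadmissibleModelError(ValueError):
    """Model has too many parameters for the grid (N - p - 2 <= 0)."""


@dataclass(frozen=True)
class ParameterBounds:
    """Box bounds for the fitted parameters.

    Diffusivity upper bound exceeds the ~3.1 μm²/ms free-water ceiling at
    body temperature so that noise-driven super-free estimates are still
    representable; the T2 window [10, 1000] ms is the allowed fitting range.
    """

    d: tuple[float, float] = (0.05, 5.0)
    t2: tuple[float, float] = (10.0, 1000.0)
    f: tuple[float, float] = (0.001, 0.999)

    def __post_init__(self) -> None:
        for lo, hi in (self.d, self.t2, self.f):
            if not (0 <= lo < hi):
                raise ValueError(f"invalid bound pair ({lo}, {hi})")


@dataclass(frozen=True)
class SignalModelSpec:
    """Layout of one phenomenological model.

    ``pool_t2_slot[i]`` maps pool *i* to its T2 parameter slot; shared-T2
    models tie two pools to one slot so the fitted-parameter count p is
    exact. Natural parameter order is (D_1..D_k, T2 slots, f_1..f_{k-1});
    the last pool fraction is 1 - sum(f).
    """

    model_id: int
    n_pools: int
    pool_t2_slot: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.pool_t2_slot) != self.n_pools:
            raise ValueError("pool_t2_slot length must equal n_pools")

    @property
    def n_t2_slots(self) -> int:
        return max(self.pool_t2_slot) + 1

    @property
    def n_params(self) -> int:
        """Fitted-parameter count p (S0 is never fitted)."""
        return self.n_pools + self.n_t2_slots + (self.n_pools - 1)

    @property
    def param_names(self) -> tuple[str, ...]:
        k, s = self.n_pools, self.n_t2_slots
        if k == 1:
            return ("D", "T2")
        d_names = tuple(f"D{i+1}" for i in range(k))
        t2_names = ("T2",) if s == 1 else tuple(f"T2_{j+1}" for j in range(s))
        f_names = tuple(f"f{i+1}" for i in range(k - 1))
        return d_names + t2_names + f_names


#: The five nested models, keyed by model id.
MODELS: dict[int, SignalModelSpec] = {
    1: SignalModelSpec(1, 1, (0,)),
    2: SignalModelSpec(2, 2, (0, 0)),
    3: SignalModelSpec(3, 2, (0, 1)),
    4: SignalModelSpec(4, 3, (0, 0, 1)),
    5: SignalModelSpec(5, 3, (0, 1, 2)),
}


@dataclass(frozen=True)
class PoolEstimate:
    """One fitted water pool: diffusivity (μm²/ms), T2 (ms), signal fraction."""

    d: float
    t2: float
    fraction: float


@dataclass
class ModelFitResult:
    """Per-voxel fit of one model: pools (ascending D), SSE, AICc, flags."""

    model_id: int
    pools: list[PoolEstimate]
    sse: float
    aicc: float
    converged: bool
    n_points: int
    degenerate: bool = False

    @property
    def params(self) -> np.ndarray:
        """Natural parameter vector in the model's canonical layout."""
        spec = MODELS[self.model_id]
        d = [p.d for p in self.pools]
        f = [p.fraction for p in self.pools]
        t2 = [0.0] * spec.n_t2_slots
        for i, pool in enumerate(self.pools):
            t2[spec.pool_t2_slot[i]] = pool.t2
        return np.array(d + t2 + f[:-1])


@dataclass
class FitConfig:
    """Cascade fitting controls: bounds, restarts, tolerances, seed."""

    bounds: ParameterBounds = field(default_factory=ParameterBounds)
    model_ids: tuple[int, ...] = (1, 2, 3, 4, 5)
    restarts: int = 3
    jitter: float = 0.3
    seed: int = 0
    ftol: float = 1e-10
    xtol: float = 1e-10
    gtol: float = 1e-10
    max_nfev: int = 500
    #: stop trying further starts once a start reaches this SSE (an
    #: essentially exact fit); restarts cannot improve on it.
    early_stop_sse: float = 1e-18


# ---------------------------------------------------------------------------
# Forward evaluation


def _fractions_from_partial(f_partial: np.ndarray, n_pools: int) -> np.ndarray:
    """Complete (f_1 .. f_{k-1}) with the residual last fraction."""
    f = np.empty(n_pools)
    f[:-1] = f_partial
    f[-1] = 1.0 - f_partial.sum()
    return f


def model_signal(
    spec: SignalModelSpec, params: Sequence[float], grid: AcquisitionGrid
) -> np.ndarray:
    """Evaluate S/S0 at every grid point for natural parameters.

    ``params`` follows ``spec.param_names``; raises on length mismatch.
    """
    params = np.asarray(params, dtype=float)
    if params.size != spec.n_params:
        raise ValueError(
            f"model {spec.model_id} expects {spec.n_params} parameters, "
            f"got {params.size}"
        )
    k, s = spec.n_pools, spec.n_t2_slots
    d = params[:k]
    t2 = params[k : k + s]
    f = _fractions_from_partial(params[k + s :], k)
    bprime = grid.b / 1000.0  # dimensionless b*D uses b in ms/μm²
    te = grid.te
    sig = np.zeros(grid.n_points)
    for i in range(k):
        sig += f[i] * np.exp(-bprime * d[i]) * np.exp(-te / t2[spec.pool_t2_slot[i]])
    return sig


def normalized_model_signal(
    spec: SignalModelSpec, params: Sequence[float], grid: AcquisitionGrid
) -> np.ndarray:
    """Model prediction normalized to its own (min TE, min b) value.

    This is the quantity actually compared with measured data, which are
    normalized to the reference image; it equals 1 at the reference point.
    """
    sig = model_signal(spec, params, grid)
    return sig / sig[grid.reference_index]


def compute_aicc(sse: float, n_points: int, p: int) -> float:
    """Small-sample corrected Akaike information criterion.

    AICc = N ln(SSE/N) + 2(p+1)(1 + (p+2)/(N-p-2)). A perfect fit (SSE = 0)
    returns -inf so the model wins outright, the limiting behaviour of the
    log term. Raises :class:`InadmissibleModelError` when N - p - 2 <= 0.
    """
    if n_points - p - 2 <= 0:
        raise InadmissibleModelError(
            f"model with p={p} is inadmissible on N={n_points} points "
            "(N - p - 2 must be positive)"
        )
    if sse < 0:
        raise ValueError(f"SSE must be non-negative, got {sse}")
    if sse == 0.0:
        return float("-inf")
    n = float(n_points)
    return float(n * np.log(sse / n) + 2 * (p + 1) * (1 + (p + 2) / (n - p - 2)))


# ---------------------------------------------------------------------------
# Optimizer internals
#
# The optimizer works in a transformed space: fractions are stick-breaking
# coordinates g in (0,1)^{k-1} (f1 = g1; f2 = (1-g1) g2; f3 = remainder) so
# the simplex constraint is a box constraint and three-pool fractions can
# never leave [0, 1].


def _stick_to_frac(g: np.ndarray, k: int) -> np.ndarray:
    if k == 1:
        return np.ones(1)
    if k == 2:
        return np.array([g[0], 1.0 - g[0]])
    return np.array([g[0], (1 - g[0]) * g[1], (1 - g[0]) * (1 - g[1])])


def _frac_to_stick(f: np.ndarray) -> np.ndarray:
    k = f.size
    if k == 1:
        return np.empty(0)
    if k == 2:
        return np.array([f[0]])
    denom = max(1.0 - f[0], 1e-12)
    return np.array([f[0], f[1] / denom])


def _stick_jacobian(g: np.ndarray, k: int) -> np.ndarray:
    """d f / d g, shape (k, k-1)."""
    if k == 2:
        return np.array([[1.0], [-1.0]])
    g1, g2 = g
    return np.array(
        [
            [1.0, 0.0],
            [-g2, 1.0 - g1],
            [-(1.0 - g2), -(1.0 - g1)],
        ]
    )


def _natural_to_theta(spec: SignalModelSpec, params: np.ndarray) -> np.ndarray:
    k, s = spec.n_pools, spec.n_t2_slots
    f = _fractions_from_partial(params[k + s :], k)
    return np.concatenate([params[: k + s], _frac_to_stick(f)])


def _theta_to_natural(spec: SignalModelSpec, theta: np.ndarray) -> np.ndarray:
    k, s = spec.n_pools, spec.n_t2_slots
    f = _stick_to_frac(theta[k + s :], k)
    return np.concatenate([theta[: k + s], f[:-1]])


def _theta_bounds(
    spec: SignalModelSpec, bounds: ParameterBounds
) -> tuple[np.ndarray, np.ndarray]:
    k, s = spec.n_pools, spec.n_t2_slots
    lo = [bounds.d[0]] * k + [bounds.t2[0]] * s + [bounds.f[0]] * (k - 1)
    hi = [bounds.d[1]] * k + [bounds.t2[1]] * s + [bounds.f[1]] * (k - 1)
    return np.array(lo), np.array(hi)


class _VoxelProblem:
    """Residuals and analytic Jacobian for one (model, voxel) fit.

    The data are normalized to the (min TE, min b) intensity, so the model
    prediction is normalized the same way before comparison: the fitted
    curve is S(theta)/S(theta)[ref], which equals 1 at the reference point
    exactly as the data do. Fractions therefore keep their meaning as TE=0
    pool signal fractions summing to 1.
    """

    def __init__(self, spec: SignalModelSpec, grid: AcquisitionGrid, signal: np.ndarray):
        self.spec = spec
        self.bprime = grid.b / 1000.0
        self.te = grid.te
        self.signal = signal
        self.ref = grid.reference_index
        self._slot_idx = np.array(spec.pool_t2_slot)
        self._bcol = self.bprime[:, None]
        self._tecol = self.te[:, None]
        self._cache_key: bytes | None = None
        self._cache_val = None

    def _pools(self, theta: np.ndarray):
        # residual and jacobian are called with the same theta within one
        # optimizer iteration; memoize the shared decay computation
        key = theta.tobytes()
        if key == self._cache_key:
            return self._cache_val
        spec = self.spec
        k, s = spec.n_pools, spec.n_t2_slots
        d = theta[:k]
        t2 = theta[k : k + s]
        g = theta[k + s :]
        f = _stick_to_frac(g, k)
        # per-pool decay curves, shape (N, k)
        E = np.exp(-self._bcol * d - self._tecol / t2[self._slot_idx])
        self._cache_key = key
        self._cache_val = (d, t2, g, f, E)
        return self._cache_val

    def _raw_jacobian(self, theta: np.ndarray, t2, g, f, E) -> np.ndarray:
        spec = self.spec
        k, s = spec.n_pools, spec.n_t2_slots
        n = self.te.size
        J = np.empty((n, k + s + (k - 1)))
        fE = E * f[None, :]
        for i in range(k):
            J[:, i] = -self.bprime * fE[:, i]
        for slot in range(s):
            members = [i for i in range(k) if spec.pool_t2_slot[i] == slot]
            J[:, k + slot] = (self.te / t2[slot] ** 2) * fE[:, members].sum(axis=1)
        if k > 1:
            Jf = _stick_jacobian(g, k)  # (k, k-1)
            J[:, k + s :] = E @ Jf
        return J

    def residual(self, theta: np.ndarray) -> np.ndarray:
        _, _, _, f, E = self._pools(theta)
        m = E @ f
        return m / m[self.ref] - self.signal

    def jacobian(self, theta: np.ndarray) -> np.ndarray:
        _, t2, g, f, E = self._pools(theta)
        m = E @ f
        J = self._raw_jacobian(theta, t2, g, f, E)
        m_ref = m[self.ref]
        # d(m_i/m_ref)/dtheta = J_i/m_ref - (m_i/m_ref^2) J_ref
        return J / m_ref - np.outer(m / m_ref**2, J[self.ref, :])


def _clip_theta(theta: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = hi - lo
    return np.clip(theta, lo + 1e-9 * span, hi - 1e-9 * span)


def _fit_one(
    problem: _VoxelProblem,
    theta0: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    config: FitConfig,
):
    theta0 = _clip_theta(theta0, lo, hi)
    spec = problem.spec
    k, s = spec.n_pools, spec.n_t2_slots
    # characteristic parameter scales (D ~ 1 μm²/ms, T2 ~ 100 ms, g ~ 0.5):
    # without these the trust region is dominated by the T2 axes.
    x_scale = np.concatenate(
        [np.ones(k), np.full(s, 100.0), np.full(k - 1, 0.3)]
    )
    return least_squares(
        problem.residual,
        theta0,
        jac=problem.jacobian,
        bounds=(lo, hi),
        method="trf",
        x_scale=x_scale,
        ftol=config.ftol,
        xtol=config.xtol,
        gtol=config.gtol,
        max_nfev=config.max_nfev,
    )


# ---------------------------------------------------------------------------
# Start-point construction


def _heuristic_start_m1(
    grid: AcquisitionGrid, signal: np.ndarray, bounds: ParameterBounds
) -> np.ndarray:
    """Log-linear slope estimates of D (over b at min TE) and T2 (over TE at min b)."""
    te, b = grid.te, grid.b
    eps = 1e-8
    logsig = np.log(np.maximum(signal, eps))
    te_min, b_min = te.min(), b.min()
    sel_b = te == te_min
    d_est = 1.0
    if sel_b.sum() >= 2 and np.ptp(b[sel_b]) > 0:
        slope = np.polyfit(b[sel_b] / 1000.0, logsig[sel_b], 1)[0]
        d_est = -slope
    sel_t = b == b_min
    t2_est = 100.0
    if sel_t.sum() >= 2 and np.ptp(te[sel_t]) > 0:
        slope = np.polyfit(te[sel_t], logsig[sel_t], 1)[0]
        if slope < -1e-12:
            t2_est = -1.0 / slope
    d_est = float(np.clip(d_est, *bounds.d))
    t2_est = float(np.clip(t2_est, *bounds.t2))
    return np.array([d_est, t2_est])


def _embed_starts(
    model_id: int, lower: dict[int, ModelFitResult], bounds: ParameterBounds
) -> list[np.ndarray]:
    """Natural-parameter starts for a model from the fits it nests.

    Each list includes one start that reproduces a lower model's solution
    exactly (pools duplicated / T2 slots tied as needed) and one that spreads
    the duplicated coordinate apart to break the degeneracy.
    """
    d_lo, d_hi = bounds.d
    t2_lo, t2_hi = bounds.t2
    starts: list[np.ndarray] = []

    def spread(x, factor, lo, hi):
        return float(np.clip(x * factor, lo, hi))

    if model_id == 2 and 1 in lower:
        d, t2 = lower[1].params
        starts.append(np.array([d, d, t2, 0.5]))  # exact embedding of model 1
        starts.append(
            np.array([spread(d, 0.5, d_lo, d_hi), spread(d, 1.5, d_lo, d_hi), t2, 0.5])
        )
    elif model_id == 3 and 2 in lower:
        d1, d2, t2, f1 = lower[2].params
        starts.append(np.array([d1, d2, t2, t2, f1]))  # exact embedding of model 2
        starts.append(
            np.array(
                [d1, d2, spread(t2, 0.6, t2_lo, t2_hi), spread(t2, 1.8, t2_lo, t2_hi), f1]
            )
        )
    elif model_id == 4 and 2 in lower:
        d1, d2, t2, f1 = lower[2].params
        # exact embedding: third pool duplicates pool 2 with the tied T2
        starts.append(np.array([d1, d2, d2, t2, t2, f1, (1 - f1) / 2]))
        starts.append(
            np.array(
                [
                    d1,
                    d2,
                    spread(d2, 1.5, d_lo, d_hi),
                    t2,
                    spread(t2, 1.8, t2_lo, t2_hi),
                    f1,
                    (1 - f1) / 2,
                ]
            )
        )
    elif model_id == 5:
        if 3 in lower:
            d1, d2, t21, t22, f1 = lower[3].params
            # exact embedding: duplicate pool 2
            starts.append(np.array([d1, d2, d2, t21, t22, t22, f1, (1 - f1) / 2]))
            starts.append(
                np.array(
                    [
                        d1,
                        d2,
                        spread(d2, 1.5, d_lo, d_hi),
                        t21,
                        t22,
                        spread(t22, 1.5, t2_lo, t2_hi),
                        f1,
                        (1 - f1) / 2,
                    ]
                )
            )
        if 4 in lower:
            d1, d2, d3, t21, t22, f1, f2 = lower[4].params
            # exact embedding: untie the shared slot
            starts.append(np.array([d1, d2, d3, t21, t21, t22, f1, f2]))
    return starts


def _jittered(
    start: np.ndarray,
    spec: SignalModelSpec,
    bounds: ParameterBounds,
    rng: np.random.Generator,
    scale: float,
) -> np.ndarray:
    """Multiplicative log-normal jitter on D and T2, additive on fractions."""
    k, s = spec.n_pools, spec.n_t2_slots
    out = start.copy()
    out[:k] = np.clip(out[:k] * np.exp(rng.normal(0, scale, k)), *bounds.d)
    out[k : k + s] = np.clip(
        out[k : k + s] * np.exp(rng.normal(0, scale, s)), *bounds.t2
    )
    if k > 1:
        f = _fractions_from_partial(out[k + s :], k)
        f = np.clip(f + rng.normal(0, scale * 0.3, k), 0.02, 0.98)
        f /= f.sum()
        out[k + s :] = f[:-1]
    return out


def _sort_pools(result: ModelFitResult) -> ModelFitResult:
    result.pools = sorted(result.pools, key=lambda p: p.d)
    return result


def fit_voxel_cascade(
    signal: np.ndarray,
    grid: AcquisitionGrid,
    config: Optional[FitConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[ModelFitResult]:
    """Fit all configured models to one voxel's normalized signal vector.

    Models are fitted in ascending id; each model's starts include the exact
    embedding of the best nested lower-order fit, so SSE is non-increasing
    along the nesting chains 1→2→3→5 and 2→4→5. The optimizer never raises:
    a failed fit is returned bound-clipped with ``converged=False``.
    """
    config = config or FitConfig()
    rng = rng or np.random.default_rng(config.seed)
    signal = np.asarray(signal, dtype=float)
    if signal.size != grid.n_points:
        raise ValueError(
            f"signal length {signal.size} does not match grid ({grid.n_points})"
        )
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite values")

    bounds = config.bounds
    best_by_model: dict[int, ModelFitResult] = {}
    results: list[ModelFitResult] = []
    for model_id in sorted(config.model_ids):
        spec = MODELS[model_id]
        problem = _VoxelProblem(spec, grid, signal)
        lo, hi = _theta_bounds(spec, bounds)

        natural_starts: list[np.ndarray] = []
        if spec.n_pools == 1:
            natural_starts.append(_heuristic_start_m1(grid, signal, bounds))
        natural_starts.extend(_embed_starts(model_id, best_by_model, bounds))
        if not natural_starts:  # cascade root missing (custom model list)
            mid = np.concatenate(
                [
                    np.full(spec.n_pools, 1.0),
                    np.full(spec.n_t2_slots, 150.0),
                    np.full(spec.n_pools - 1, 1.0 / spec.n_pools),
                ]
            )
            natural_starts.append(mid)
        base = natural_starts[-1]
        for _ in range(config.restarts):
            natural_starts.append(_jittered(base, spec, bounds, rng, config.jitter))

        best = None
        converged = False
        for nat in natural_starts:
            theta0 = _natural_to_theta(spec, np.asarray(nat, dtype=float))
            try:
                res = _fit_one(problem, theta0, lo, hi, config)
            except Exception:  # pragma: no cover - optimizer must not crash fits
                logger.exception("optimizer failure (model %d)", model_id)
                continue
            if best is None or res.cost < best.cost:
                best = res
            converged = converged or bool(res.success)
            if best is not None and 2.0 * best.cost < config.early_stop_sse:
                break

        if best is None:  # every start crashed: bound-clipped fallback
            theta = _clip_theta(_natural_to_theta(spec, natural_starts[0]), lo, hi)
            sse = float(np.sum(problem.residual(theta) ** 2))
            converged = False
        else:
            theta = best.x
            sse = float(np.sum(best.fun**2))

        k, s = spec.n_pools, spec.n_t2_slots
        d = theta[:k]
        t2 = theta[k : k + s]
        f = _stick_to_frac(theta[k + s :], k)
        pools = [
            PoolEstimate(float(d[i]), float(t2[spec.pool_t2_slot[i]]), float(f[i]))
            for i in range(k)
        ]
        degenerate = False
        if k > 1:
            dsorted = np.sort(d)
            degenerate = bool(
                np.min(np.diff(dsorted)) < 1e-3 or np.min(f) <= bounds.f[0] + 1e-6
            )
        try:
            aicc = compute_aicc(sse, grid.n_points, spec.n_params)
        except InadmissibleModelError:
            aicc = float("nan")
            converged = False
        result = _sort_pools(
            ModelFitResult(
                model_id=model_id,
                pools=pools,
                sse=sse,
                aicc=aicc,
                converged=converged,
                n_points=grid.n_points,
                degenerate=degenerate,
            )
        )
        results.append(result)
        cur = best_by_model.get(model_id)
        if cur is None or result.sse < cur.sse:
            best_by_model[model_id] = result
    return results


@dataclass
class VolumeFit:
    """Stack of per-voxel cascade fits over the in-mask voxels of a volume."""

    shape: tuple[int, int, int]
    voxels: list[tuple[int, int, int]]
    fits: list[list[ModelFitResult]]
    model_ids: tuple[int, ...]

    def map_of(self, fn) -> np.ndarray:
        """3-D map of ``fn(per-voxel fit list)``; NaN outside the mask."""
        out = np.full(self.shape, np.nan)
        for idx, res in zip(self.voxels, self.fits):
            out[idx] = fn(res)
        return out

    def aicc_map(self, model_id: int) -> np.ndarray:
        return self.map_of(
            lambda res: next(r.aicc for r in res if r.model_id == model_id)
        )

    def sse_map(self, model_id: int) -> np.ndarray:
        return self.map_of(
            lambda res: next(r.sse for r in res if r.model_id == model_id)
        )


def fit_volume(
    vol: SignalVolume,
    grid: AcquisitionGrid,
    config: Optional[FitConfig] = None,
) -> VolumeFit:
    """Run the model cascade over every in-mask voxel of a normalized volume.

    Deterministic for a given config seed: each voxel gets its own RNG stream
    derived from (seed, running voxel index), so results do not depend on
    mask shape elsewhere in the volume.
    """
    config = config or FitConfig()
    mask = vol.get_mask()
    idxs = np.argwhere(mask)
    if idxs.size == 0:
        raise ValueError("empty mask: no voxels to fit")
    voxels: list[tuple[int, int, int]] = []
    fits: list[list[ModelFitResult]] = []
    for counter, (i, j, k) in enumerate(idxs):
        sig = vol.data[i, j, k, :]
        rng = np.random.default_rng([config.seed, counter])
        fits.append(fit_voxel_cascade(sig, grid, config, rng))
        voxels.append((int(i), int(j), int(k)))
    return VolumeFit(
        shape=vol.data.shape[:3],
        voxels=voxels,
        fits=fits,
        model_ids=tuple(sorted(config.model_ids)),
    )
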