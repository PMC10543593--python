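"""Akaike-weighted aggregation of per-model structure predictions.

Each fitted model m contributes a composition prediction through its water
pools; models are combined by their Akaike weights

    W_m = exp(-Delta_m / 2) / sum_m' exp(-Delta_m' / 2),

where Delta_m = AICc_m - min_m' AICc_m'. The voxel's aggregated fraction of
compartment X is the double sum over models and pools

    X = sum_m sum_p W_m * f_m^p * x_m^p  /  sum_m W_m,

with f_m^p the pool's signal fraction and x_m^p the pool's predicted
fraction of X. The denominator is unity by construction but is carried as
written. A hypothetical cancer-probability score P_Ca = E * (1 - L) can be
derived from a three-compartment epithelium/stroma/lumen composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .signal_models import ModelFitResult
from .structure import StructureModel, pool_composition


@dataclass
class ModelWeights:
    """Per-model Akaike weights for one voxel; sums to 1."""

    weights: dict[int, float]
    flagged: bool = False  # True when no model had a finite AICc

    def as_array(self, model_ids: Sequence[int]) -> np.ndarray:
        return np.array([self.weights[m] for m in model_ids])


def akaike_weights(
    aiccs: Mapping[int, float], include: Mapping[int, bool] | None = None
) -> ModelWeights:
    """Akaike weights from per-model AICc values.

    Delta values are computed before exponentiation, so the result is
    invariant to any common shift of the AICc values and numerically safe
    for large spreads. A -inf AICc (perfect fit) takes all the weight,
    shared equally if several models achieve it. Models with ``include``
    False (e.g. non-converged fits) are dropped and the rest renormalized.
    If no usable finite value remains, the voxel gets uniform weights and
    is flagged.
    """
    ids = list(aiccs.keys())
    vals = np.array([float(aiccs[m]) for m in ids])
    ok = np.array([True if include is None else bool(include[m]) for m in ids])
    ok &= ~np.isnan(vals)
    if not ok.any():
        w = np.full(len(ids), 1.0 / len(ids))
        return ModelWeights(dict(zip(ids, w)), flagged=True)

    usable = np.where(ok, vals, np.inf)
    if np.isneginf(usable).any():
        w = np.isneginf(usable).astype(float)
    else:
        delta = usable - usable[ok].min()
        with np.errstate(over="ignore"):
            w = np.where(ok, np.exp(-delta / 2.0), 0.0)
    w = w / w.sum()
    return ModelWeights(dict(zip(ids, w.astype(float))))


def aggregate_composition(
    fits: Sequence[ModelFitResult],
    compositions: Mapping[int, Sequence[Mapping[str, float]]],
    weights: ModelWeights,
) -> dict[str, float]:
    """Weighted multi-model composition for one voxel.

    ``compositions[model_id][p]`` is pool p's compartment-fraction mapping
    (pools in the same order as ``fit.pools``). Output fractions sum to 1
    because pool fractions and pool compositions each do.
    """
    names: list[str] = []
    for fit in fits:
        for comp in compositions[fit.model_id]:
            for name in comp:
                if name not in names:
                    names.append(name)
    num = dict.fromkeys(names, 0.0)
    denom = 0.0
    for fit in fits:
        w = weights.weights[fit.model_id]
        denom += w
        comps = compositions[fit.model_id]
        if len(comps) != len(fit.pools):
            raise ValueError(
                f"model {fit.model_id}: {len(fit.pools)} pools but "
                f"{len(comps)} pool compositions"
            )
        for pool, comp in zip(fit.pools, comps):
            for name in names:
                num[name] += w * pool.fraction * comp.get(name, 0.0)
    if denom == 0.0:
        raise ValueError("total model weight is zero")
    return {name: num[name] / denom for name in names}


def voxel_composition(
    fits: Sequence[ModelFitResult],
    structure: StructureModel,
    weights: ModelWeights | None = None,
) -> dict[str, float]:
    """Convenience: compose pools, weight models, aggregate — one voxel."""
    if weights is None:
        weights = akaike_weights(
            {f.model_id: f.aicc for f in fits},
            include={f.model_id: f.converged for f in fits},
        )
    comps = {
        f.model_id: [pool_composition(structure, p) for p in f.pools] for f in fits
    }
    return aggregate_composition(fits, comps, weights)


def cancer_probability(composition: Mapping[str, float] | np.ndarray, lumen=None):
    """Hypothetical cancer probability P_Ca = E * (1 - L).

    Reflects epithelial proliferation and lumen occlusion in prostate
    adenocarcinoma; stroma is omitted (redundant given E + S + L = 1).
    Accepts either a per-voxel mapping with 'epithelium' and 'lumen' keys,
    or two aligned arrays (epithelium, lumen). This is a demonstration
    score, not a calibrated diagnostic probability.
    """
    if lumen is not None:
        e = np.asarray(composition, dtype=float)
        l = np.asarray(lumen, dtype=float)
        if e.shape != l.shape:
            raise ValueError("epithelium and lumen arrays must have equal shape")
        return e * (1.0 - l)
    try:
        e = composition["epithelium"]
        l = composition["lumen"]
    except (KeyError, IndexError):
        raise ValueError(
            "cancer probability requires an epithelium/lumen composition "
            f"(got compartments {sorted(composition)}); use the 'esl' "
            "structure model, not e.g. 'cellularity'"
        ) from None
    return float(e) * (1.0 - float(l))
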