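"""Weighted histogram equalization of feature maps to percentiles.

A feature map is remapped to percentile values in [0, 100] such that,
under a given spatial weight map, the distribution of output values is
uniform.  The weight map is the central-bias correction: weighting with
a control fixation density makes the percentile of a pixel the rank of
its feature value *as sampled by image-unspecific fixation behavior*,
so a purely spatial fixation bias produces a flat percentile
distribution at fixated locations.

Ties receive the average (midpoint) rank; the transform is invariant
under any strictly increasing function of the feature values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class PercentileMap:
    source: str
    values: np.ndarray  # percentiles in [0, 100]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def weighted_percentiles(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Midpoint-rank weighted percentiles of a flat array, in [0, 100]."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    total = w.sum()

    # group boundaries of tied values
    new_group = np.empty(v.size, dtype=bool)
    new_group[0] = True
    np.not_equal(v[1:], v[:-1], out=new_group[1:])
    group_id = np.cumsum(new_group) - 1
    group_start = np.flatnonzero(new_group)

    cumw = np.cumsum(w)
    below_group = np.concatenate(([0.0], cumw[group_start[1:] - 1]))
    group_end = np.concatenate((group_start[1:], [v.size])) - 1
    group_w = cumw[group_end] - below_group

    pct_sorted = 100.0 * (below_group[group_id] + 0.5 * group_w[group_id]) / total
    out = np.empty(values.size)
    out[order] = pct_sorted
    return out


def histogram_equalize(
    feature: np.ndarray,
    weights: np.ndarray | None = None,
    *,
    name: str = "feature",
) -> PercentileMap:
    """Equalize a feature map to percentiles under the given spatial weights.

    Parameters
    ----------
    feature:
        2D feature map.
    weights:
        Nonnegative weight map of the same shape (a control fixation
        density); ``None`` means uniform weights.
    """
    feature = np.asarray(feature, dtype=float)
    if weights is None:
        weights = np.ones_like(feature)
    else:
        weights = np.asarray(weights, dtype=float)
    if weights.shape != feature.shape:
        raise ValueError("weights must have the same shape as the feature map")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    total = weights.sum()
    if not total > 0:
        raise ValueError("weights must have nonzero total mass")
    if not np.all(np.isfinite(feature)):
        raise ValueError("feature map contains non-finite values")

    flat = feature.ravel()
    if flat.min() == flat.max():
        warnings.warn("constant feature map: all percentiles set to 50", stacklevel=2)
        return PercentileMap(name, np.full_like(feature, 50.0))

    pct = weighted_percentiles(flat, weights.ravel()).reshape(feature.shape)
    return PercentileMap(name, pct)
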