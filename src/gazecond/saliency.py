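"""Bayesian conditional-probability saliency functions and their D_KL scores.

The saliency of a feature is p(fixation | feature = X), obtained from
the Bayesian equality

    p(fixation=1 | X) = p(X | fixation=1) * p(fixation) / p(X).

After weighted histogram equalization (weights = a subject's control
fixation density, i.e. that subject's fixations on all *other* images
of the category), p(X) is uniform by construction, so the saliency
function is, up to the constant p(fixation), the histogram of feature
percentiles at actually fixated locations.  In 2D the joint control
distribution p(X1, X2) is not uniform (intrinsic feature correlations
remain) and is estimated from control-weighted pixels.

Deviations between the actual and control distributions are scored with
a symmetric Kullback-Leibler divergence in bits,

    D_sym(P, Q) = 1/2 [ sum P log2(P/Q) + sum Q log2(Q/P) ],

computed per subject (distributions averaged across images within a
subject first), then averaged across subjects with percentile-bootstrap
confidence intervals over the subject pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .equalize import histogram_equalize
from .gaze import FIXATION_MAP_FWHM_DEG
from .geometry import ViewingGeometry

N_BINS_1D = 64
BINS_PER_DIM_2D = 8
PSEUDO_COUNT = 0.5
DEFAULT_CI_LEVEL = 0.99
N_BOOT = 1000


@dataclass
class SaliencyFunction:
    """Binned estimate of p(fixation | feature percentile(s)), up to a constant.

    ``values`` is normalized to mean 1 over populated bins; unpopulated
    bins (no control mass) are NaN.  ``actual`` and ``control`` hold the
    averaged P and Q distributions the function is the ratio of.
    """

    dims: int
    bin_edges: np.ndarray
    values: np.ndarray
    actual: np.ndarray
    control: np.ndarray
    n_actual: int
    n_control: int
    features: tuple[str, ...] = ("feature",)

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


@dataclass
class DklScore:
    value_bits: float
    per_subject_values: list[float] = field(default_factory=list)
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    ci_level: float = DEFAULT_CI_LEVEL


# --------------------------------------------------------------------------
# divergence and bootstrap


def symmetric_dkl(p: np.ndarray, q: np.ndarray) -> float:
    """Symmetric Kullback-Leibler divergence in bits.

    Inputs are renormalized to unit sum.  Bins empty on exactly one side
    are floored to a tiny mass so the result is finite; bins empty on
    both sides contribute nothing.
    """
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    if p.shape != q.shape:
        raise ValueError("P and Q must share the same binning")
    one_sided = ((p == 0) & (q > 0)) | ((q == 0) & (p > 0))
    if one_sided.any():
        floor = 1e-12
        p = np.where((p == 0) & (q > 0), floor, p)
        q = np.where((q == 0) & (p > 0), floor, q)
    p = p / p.sum()
    q = q / q.sum()
    both = (p > 0) & (q > 0)
    pb, qb = p[both], q[both]
    # (p-q)(log p - log q) >= 0 termwise, and exactly symmetric in (P, Q)
    log_ratio = np.log2(pb) - np.log2(qb)
    return float(0.5 * np.sum((pb - qb) * log_ratio))


def bootstrap_ci(
    values: np.ndarray | list[float],
    n_boot: int = N_BOOT,
    level: float = DEFAULT_CI_LEVEL,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean of per-subject values."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        v = float(values.mean()) if values.size else float("nan")
        return (v, v)
    rng = np.random.default_rng(seed)
    draws = rng.choice(values, size=(n_boot, values.size), replace=True)
    means = draws.mean(axis=1)
    alpha = (1.0 - level) / 2.0
    return (
        float(np.quantile(means, alpha)),
        float(np.quantile(means, 1.0 - alpha)),
    )


# --------------------------------------------------------------------------
# binning helpers


def percentile_bin_edges(n_bins: int) -> np.ndarray:
    return np.linspace(0.0, 100.0, n_bins + 1)


def percentile_counts(pcts: np.ndarray, n_bins: int) -> np.ndarray:
    counts, _ = np.histogram(pcts, bins=percentile_bin_edges(n_bins))
    return counts.astype(float)


def weighted_percentile_counts(
    pcts: np.ndarray, n_bins: int, weights: np.ndarray | None = None
) -> np.ndarray:
    counts, _ = np.histogram(
        np.ravel(pcts), bins=percentile_bin_edges(n_bins),
        weights=None if weights is None else np.ravel(weights),
    )
    return counts.astype(float)


def joint_percentile_counts(
    pct1: np.ndarray, pct2: np.ndarray, n_bins: int, weights: np.ndarray | None = None
) -> np.ndarray:
    edges = percentile_bin_edges(n_bins)
    counts, _, _ = np.histogram2d(
        np.ravel(pct1), np.ravel(pct2), bins=(edges, edges),
        weights=None if weights is None else np.ravel(weights),
    )
    return counts.astype(float)


def _regularize(counts: np.ndarray, n_events: float, pseudo: float = PSEUDO_COUNT) -> np.ndarray:
    """Counts -> probabilities with a pseudo-count of ``pseudo`` per bin.

    Weighted (non-integer) histograms are first rescaled to ``n_events``
    total so the pseudo-count has the same relative strength as on the
    actual-fixation side.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total > 0 and n_events > 0:
        counts = counts * (n_events / total)
    out = counts + pseudo
    return out / out.sum()


def fixation_percentiles(pct_map: np.ndarray, fix: pd.DataFrame) -> np.ndarray:
    """Percentile values at fixation pixel positions."""
    h, w = pct_map.shape
    iy = np.clip(np.rint(fix["y"].to_numpy()).astype(int), 0, h - 1)
    ix = np.clip(np.rint(fix["x"].to_numpy()).astype(int), 0, w - 1)
    return pct_map[iy, ix]


# --------------------------------------------------------------------------
# single subject x image estimates


def saliency_1d(
    percentile_map: np.ndarray,
    actual: pd.DataFrame,
    n_bins: int = N_BINS_1D,
    pseudo: float = PSEUDO_COUNT,
    feature: str = "feature",
) -> SaliencyFunction:
    """1D saliency function for one subject and image.

    ``percentile_map`` must already be equalized against the control
    weights, which makes p(X) uniform up to ties; the function is the
    (regularized) histogram of percentiles at the actual fixations
    relative to the control histogram of the map itself (exactly
    uniform for tie-free maps, and correct when the feature has heavy
    ties, e.g. large constant regions).
    """
    if len(actual) == 0:
        raise ValueError("no actual fixations")
    counts = percentile_counts(fixation_percentiles(percentile_map, actual), n_bins)
    p = _regularize(counts, counts.sum(), pseudo)
    q = _regularize(weighted_percentile_counts(percentile_map, n_bins), counts.sum(), pseudo)
    values = p / q
    values = values / values.mean()
    return SaliencyFunction(
        dims=1, bin_edges=percentile_bin_edges(n_bins), values=values,
        actual=p, control=q, n_actual=int(counts.sum()),
        n_control=percentile_map.size, features=(feature,),
    )


def saliency_2d(
    map1: np.ndarray,
    map2: np.ndarray,
    actual: pd.DataFrame,
    control_weights: np.ndarray,
    bins_per_dim: int = BINS_PER_DIM_2D,
    pseudo: float = PSEUDO_COUNT,
    features: tuple[str, str] = ("f1", "f2"),
) -> SaliencyFunction:
    """Joint saliency function for one subject and image.

    Both maps must be equalized against the same control weights.  The
    control distribution p(X1, X2) keeps the intrinsic correlation of
    the two features and is estimated from control-weighted pixels.
    """
    if map1.shape != map2.shape:
        raise ValueError("the two percentile maps must share a shape")
    if len(actual) == 0:
        raise ValueError("no actual fixations")
    n = len(actual)
    p_counts = joint_percentile_counts(
        fixation_percentiles(map1, actual), fixation_percentiles(map2, actual), bins_per_dim
    )
    q_counts = joint_percentile_counts(map1, map2, bins_per_dim, weights=control_weights)
    p = _regularize(p_counts, n, pseudo)
    q = _regularize(q_counts, n, pseudo)
    values = np.where(q_counts > 0, p / q, np.nan)
    values = values / np.nanmean(values)
    return SaliencyFunction(
        dims=2, bin_edges=percentile_bin_edges(bins_per_dim), values=values,
        actual=p, control=q, n_actual=n, n_control=map1.size, features=features,
    )


# --------------------------------------------------------------------------
# category-level analysis across subjects and images


def control_density_maps(
    fixations: pd.DataFrame,
    geometry: ViewingGeometry,
    fwhm_deg: float = FIXATION_MAP_FWHM_DEG,
    by_rank: bool = False,
) -> dict:
    """Per-(subject, image) leave-one-image-out control densities.

    The control density for (subject s, image i) is built from s's
    fixations on all other images of the table.  With ``by_rank`` the
    keys become (subject, image, rank) and the controls are restricted
    to same-rank fixations (central bias is strongly rank-dependent).
    """
    h, w = geometry.image_size
    sigma = geometry.fwhm_sigma_px(fwhm_deg)

    def smooth_hist(df: pd.DataFrame) -> np.ndarray:
        grid = np.zeros((h, w))
        iy = np.clip(np.rint(df["y"].to_numpy()).astype(int), 0, h - 1)
        ix = np.clip(np.rint(df["x"].to_numpy()).astype(int), 0, w - 1)
        np.add.at(grid, (iy, ix), 1.0)
        return ndimage.gaussian_filter(grid, sigma, mode="reflect")

    controls: dict = {}
    grouped = fixations.groupby(["subject", "rank"]) if by_rank else fixations.groupby("subject")
    for key, sub_df in grouped:
        subject, rank = key if by_rank else (key, None)
        per_image = {
            img: smooth_hist(img_df) for img, img_df in sub_df.groupby("image")
        }
        total = np.sum(list(per_image.values()), axis=0)
        for img, own in per_image.items():
            ctrl = total - own
            mass = ctrl.sum()
            if mass <= 0:
                continue
            out_key = (subject, img, rank) if by_rank else (subject, img)
            controls[out_key] = ctrl / mass
    return controls


def _prepare_fixations(fixations: pd.DataFrame, exclude_first: bool) -> pd.DataFrame:
    if exclude_first and "rank" in fixations.columns:
        return fixations.loc[fixations["rank"] > 1]
    return fixations


@dataclass
class SaliencyResult:
    """Category-level saliency function plus its D_KL score."""

    function: SaliencyFunction
    dkl: DklScore


def feature_dkl(
    feature_maps: dict,
    fixations: pd.DataFrame,
    geometry: ViewingGeometry,
    *,
    maps2: dict | None = None,
    n_bins: int | None = None,
    pseudo: float = PSEUDO_COUNT,
    exclude_first: bool = True,
    correct_central_bias: bool = True,
    control_fwhm_deg: float = FIXATION_MAP_FWHM_DEG,
    controls: dict | None = None,
    feature: str = "feature",
    ci_level: float = DEFAULT_CI_LEVEL,
    seed: int = 0,
) -> SaliencyResult:
    """Full estimate of a feature's saliency function and D_KL for one category.

    ``feature_maps`` maps image id -> raw feature map.  If ``maps2`` is
    given, the joint 2D analysis of the two features is run instead
    (8 bins per dimension by default).  ``correct_central_bias=False``
    replaces the control-weighted equalization by uniform weights (the
    uncorrected estimator, for confound checks).

    Per subject and image the actual (and, in 2D, control) percentile
    distributions are computed, averaged across images within subject,
    scored per subject with the symmetric D_KL, and averaged across
    subjects; the CI is a percentile bootstrap over the subject pool.
    """
    dims = 2 if maps2 is not None else 1
    if n_bins is None:
        n_bins = BINS_PER_DIM_2D if dims == 2 else N_BINS_1D
    fix = _prepare_fixations(fixations, exclude_first)
    fix = fix.loc[fix["image"].isin(feature_maps.keys())]
    if len(fix) == 0:
        raise ValueError("no fixations left for this analysis")
    if controls is None:
        controls = control_density_maps(fix, geometry, control_fwhm_deg)

    shape = (n_bins, n_bins) if dims == 2 else (n_bins,)
    per_subject_dkl: list[float] = []
    subjects = []
    p_all = np.zeros(shape)
    q_all = np.zeros(shape)
    n_actual_total = 0

    for subject, sub_df in fix.groupby("subject"):
        p_list, q_list = [], []
        for img, img_df in sub_df.groupby("image"):
            key = (subject, img)
            if correct_central_bias:
                if key not in controls:
                    continue
                weights = controls[key]
            else:
                weights = None
            pm1 = histogram_equalize(feature_maps[img], weights).values
            if dims == 1:
                pcts = fixation_percentiles(pm1, img_df)
                p_list.append(_regularize(percentile_counts(pcts, n_bins), len(img_df), pseudo))
                q_counts = weighted_percentile_counts(pm1, n_bins, weights)
                q_list.append(_regularize(q_counts, len(img_df), pseudo))
            else:
                pm2 = histogram_equalize(maps2[img], weights).values
                w = weights if weights is not None else np.ones_like(pm1)
                p_counts = joint_percentile_counts(
                    fixation_percentiles(pm1, img_df),
                    fixation_percentiles(pm2, img_df),
                    n_bins,
                )
                q_counts = joint_percentile_counts(pm1, pm2, n_bins, weights=w)
                p_list.append(_regularize(p_counts, len(img_df), pseudo))
                q_list.append(_regularize(q_counts, len(img_df), pseudo))
            n_actual_total += len(img_df)
        if not p_list:
            continue
        p_s = np.mean(p_list, axis=0)
        q_s = np.mean(q_list, axis=0)
        per_subject_dkl.append(symmetric_dkl(p_s, q_s))
        subjects.append(subject)
        p_all += p_s
        q_all += q_s

    if not per_subject_dkl:
        raise ValueError("no subject had usable fixations")
    p_all /= p_all.sum()
    q_all /= q_all.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(q_all > 0, p_all / q_all, np.nan)
    values = values / np.nanmean(values)

    mean_dkl = float(np.mean(per_subject_dkl))
    low, high = bootstrap_ci(per_subject_dkl, level=ci_level, seed=seed)
    fn = SaliencyFunction(
        dims=dims, bin_edges=percentile_bin_edges(n_bins), values=values,
        actual=p_all, control=q_all, n_actual=n_actual_total,
        n_control=len(fix), features=(feature,) if dims == 1 else (feature, "f2"),
    )
    return SaliencyResult(
        function=fn,
        dkl=DklScore(mean_dkl, per_subject_dkl, low, high, ci_level),
    )


def upper_bound_dkl(
    fixations: pd.DataFrame,
    geometry: ViewingGeometry,
    *,
    map_fwhm_deg: float = FIXATION_MAP_FWHM_DEG,
    seed: int = 0,
    **kwargs,
) -> SaliencyResult:
    """Practical upper bound: the pooled actual fixation map as a feature.

    For each image, the cross-subject fixation density is treated as a
    feature map and run through the standard equalize -> saliency ->
    D_KL pipeline; no image-derived feature can systematically exceed it.
    """
    from .gaze import build_density_map

    fix = _prepare_fixations(fixations, kwargs.get("exclude_first", True))
    maps = {
        img: build_density_map(img_df, geometry, map_fwhm_deg).values
        for img, img_df in fix.groupby("image")
    }
    return feature_dkl(
        maps, fixations, geometry, feature="fixation_map", seed=seed, **kwargs
    )
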