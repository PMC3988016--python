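"""Fixation and click tables, density maps and their entropies.

Event tables are plain pandas DataFrames:

* fixations: ``subject, image, category, x, y, onset_ms, duration_ms, rank``
* clicks:    ``subject, image, x, y``

Coordinates are 0-based pixel indices, origin top-left, x rightward and
y downward.  Out-of-bounds events are dropped (and counted), never
clipped.  Density maps are sums of unit impulses smoothed with a
Gaussian kernel of a stated FWHM and normalized to unit integral;
``reflect`` boundary handling keeps each event's mass inside the image,
which makes map construction exactly linear in its events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import ViewingGeometry

logger = logging.getLogger(__name__)

FIXATION_COLUMNS = ["subject", "image", "category", "x", "y", "onset_ms", "duration_ms", "rank"]
CLICK_COLUMNS = ["subject", "image", "x", "y"]

FIXATION_MAP_FWHM_DEG = 1.0
CLICK_MAP_FWHM_DEG = 2.0
DEFAULT_ENTROPY_CELL_DEG = 2.0


@dataclass
class DensityMap:
    """Smoothed, unit-integral probability surface over image pixels."""

    values: np.ndarray
    kernel_fwhm_deg: float
    n_events: int
    scope: str = "image"  # "image" or "category"

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class EntropyResult:
    raw_bits: float
    normalized: float
    n_cells: int


# --------------------------------------------------------------------------
# event-table hygiene


def drop_out_of_bounds(events: pd.DataFrame, geometry: ViewingGeometry) -> pd.DataFrame:
    """Remove events outside the image bounds, logging the dropped count."""
    h, w = geometry.image_size
    keep = (
        (events["x"] >= 0) & (events["x"] <= w - 1)
        & (events["y"] >= 0) & (events["y"] <= h - 1)
    )
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d out-of-bounds events of %d", n_dropped, len(events))
    return events.loc[keep].reset_index(drop=True)


# --------------------------------------------------------------------------
# fixation parsing from raw gaze traces


@dataclass(frozen=True)
class SaccadeThresholds:
    """Event-detection heuristics (EyeLink-style defaults)."""

    acceleration_deg_s2: float = 8000.0
    velocity_deg_s: float = 30.0
    motion_deg: float = 0.1
    min_duration_ms: float = 4.0


def parse_fixations(
    t_ms: np.ndarray,
    x_deg: np.ndarray,
    y_deg: np.ndarray,
    thresholds: SaccadeThresholds | None = None,
) -> pd.DataFrame:
    """Segment a uniformly sampled gaze trace into fixations.

    Samples whose instantaneous velocity or acceleration exceed the
    saccade criteria are grouped into candidate saccades; a candidate is
    accepted if it moves at least ``motion_deg`` and lasts longer than
    ``min_duration_ms``.  The intervening episodes become fixations with
    centroid position (deg) and duration (ms).
    """
    if thresholds is None:
        thresholds = SaccadeThresholds()
    t = np.asarray(t_ms, dtype=float)
    x = np.asarray(x_deg, dtype=float)
    y = np.asarray(y_deg, dtype=float)
    if t.size < 2:
        raise ValueError("trace must contain at least 2 samples")
    dt_s = float(np.median(np.diff(t))) / 1000.0

    # per-segment velocity (deg/s) and acceleration (deg/s^2)
    disp = np.hypot(np.diff(x), np.diff(y))
    vel = disp / dt_s
    acc = np.abs(np.diff(vel, prepend=vel[0])) / dt_s
    candidate = (vel > thresholds.velocity_deg_s) | (acc > thresholds.acceleration_deg_s2)

    # accepted saccade segments
    is_saccade = np.zeros_like(candidate)
    idx = 0
    n_seg = candidate.size
    while idx < n_seg:
        if not candidate[idx]:
            idx += 1
            continue
        end = idx
        while end + 1 < n_seg and candidate[end + 1]:
            end += 1
        run_motion = np.hypot(x[end + 1] - x[idx], y[end + 1] - y[idx])
        run_ms = (end - idx + 1) * dt_s * 1000.0
        if run_motion >= thresholds.motion_deg and run_ms > thresholds.min_duration_ms:
            is_saccade[idx : end + 1] = True
        idx = end + 1

    # a sample lies inside a saccade iff every adjacent segment is a saccade
    left = np.concatenate(([is_saccade[0]], is_saccade))
    right = np.concatenate((is_saccade, [is_saccade[-1]]))
    sample_in_saccade = left & right

    rows = []
    idx = 0
    rank = 1
    n = t.size
    while idx < n:
        if sample_in_saccade[idx]:
            idx += 1
            continue
        end = idx
        while end + 1 < n and not sample_in_saccade[end + 1]:
            end += 1
        rows.append(
            {
                "x": float(x[idx : end + 1].mean()),
                "y": float(y[idx : end + 1].mean()),
                "onset_ms": float(t[idx]),
                "duration_ms": (end - idx + 1) * dt_s * 1000.0,
                "rank": rank,
            }
        )
        rank += 1
        idx = end + 1
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# density maps and entropy


def build_density_map(
    events: pd.DataFrame,
    geometry: ViewingGeometry,
    kernel_fwhm_deg: float,
    scope: str = "image",
) -> DensityMap:
    """Gaussian-smoothed, unit-integral density of event positions."""
    if len(events) == 0:
        raise ValueError("cannot build a density map from an empty event set")
    h, w = geometry.image_size
    grid = np.zeros((h, w))
    iy = np.clip(np.rint(events["y"].to_numpy()).astype(int), 0, h - 1)
    ix = np.clip(np.rint(events["x"].to_numpy()).astype(int), 0, w - 1)
    np.add.at(grid, (iy, ix), 1.0)
    sigma = geometry.fwhm_sigma_px(kernel_fwhm_deg)
    smoothed = ndimage.gaussian_filter(grid, sigma, mode="reflect")
    return DensityMap(
        values=smoothed / smoothed.sum(),
        kernel_fwhm_deg=kernel_fwhm_deg,
        n_events=len(events),
        scope=scope,
    )


def _cell_masses(values: np.ndarray, n_cells: tuple[int, int]) -> np.ndarray:
    ny, nx = n_cells
    h, w = values.shape
    y_edges = np.linspace(0, h, ny + 1).round().astype(int)
    x_edges = np.linspace(0, w, nx + 1).round().astype(int)
    rows = np.add.reduceat(values, y_edges[:-1], axis=0)
    cells = np.add.reduceat(rows, x_edges[:-1], axis=1)
    return cells


def map_entropy(
    density: DensityMap | np.ndarray,
    n_cells: tuple[int, int],
) -> EntropyResult:
    """Shannon entropy (bits) of a density map over a grid of equal cells.

    Normalized by the maximum attainable entropy ``log2(n_cells)`` so a
    uniform map scores 1 regardless of the binning.
    """
    values = density.values if isinstance(density, DensityMap) else np.asarray(density)
    ny, nx = n_cells
    total_cells = ny * nx
    if total_cells < 2:
        raise ValueError("entropy requires at least 2 cells")
    p = _cell_masses(values, n_cells).ravel()
    p = p / p.sum()
    p = p[p > 0]
    raw = float(-(p * np.log2(p)).sum())
    return EntropyResult(raw_bits=raw, normalized=raw / np.log2(total_cells), n_cells=total_cells)


def entropy_cells_for(geometry: ViewingGeometry, cell_deg: float = DEFAULT_ENTROPY_CELL_DEG) -> tuple[int, int]:
    """Number of entropy cells for a given cell size in degrees."""
    h, w = geometry.image_size
    ny = max(int(round(h / geometry.deg_to_px(cell_deg))), 2)
    nx = max(int(round(w / geometry.deg_to_px(cell_deg))), 2)
    return ny, nx


def exploration_summary(
    fixations: pd.DataFrame,
    geometry: ViewingGeometry,
    kernel_fwhm_deg: float = FIXATION_MAP_FWHM_DEG,
    cell_deg: float = DEFAULT_ENTROPY_CELL_DEG,
) -> pd.DataFrame:
    """Per-category exploration table.

    For each category: the mean normalized entropy of the image-specific
    fixation maps (inter-subject agreement) and the normalized entropy
    of the pooled category-specific map (inter-image agreement).
    """
    n_cells = entropy_cells_for(geometry, cell_deg)
    rows = []
    for category, cat_df in fixations.groupby("category", observed=True):
        image_entropies = []
        for _, img_df in cat_df.groupby("image"):
            dmap = build_density_map(img_df, geometry, kernel_fwhm_deg, scope="image")
            image_entropies.append(map_entropy(dmap, n_cells).normalized)
        cat_map = build_density_map(cat_df, geometry, kernel_fwhm_deg, scope="category")
        rows.append(
            {
                "category": category,
                "n_images": cat_df["image"].nunique(),
                "n_fixations": len(cat_df),
                "mean_image_entropy": float(np.mean(image_entropies)),
                "category_entropy": map_entropy(cat_map, n_cells).normalized,
            }
        )
    return pd.DataFrame(rows)
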