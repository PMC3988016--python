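"""Low- and mid-level feature maps.

Fifteen maps form the battery:

========  =======================================  ==========
name      definition                               window
========  =======================================  ==========
LM        local mean of luminance                  0.5 deg
RGM       local mean of red-green plane            2 deg
YBM       local mean of yellow-blue plane          2 deg
SATM      local mean of saturation                 1 deg
LC        local std of luminance                   1 deg
RGC       local std of red-green                   2 deg
YBC       local std of yellow-blue                 2 deg
SATC      local std of saturation                  1 deg
TC        local std of the LC map                  3.7 deg
S         surfaceness (intrinsic dim. 0)           6 deg patch
E         edgeness (intrinsic dim. 1)              6 deg patch
C         cornerness (intrinsic dim. 2)            6 deg patch
BiSymm    bilateral phase symmetry                 filter bank
RaSymmL   radial phase symmetry, low frequencies   filter bank
RaSymmH   radial phase symmetry, high frequencies  filter bank
========  =======================================  ==========

Local means/stds are taken over circular apertures whose pixel diameter
is the degree size rounded to the nearest odd count.  At image borders
the aperture shrinks to in-image pixels; no padding values are invented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .color import OpponentImage, rgb_to_opponent
from .geometry import ViewingGeometry
from .symmetry import phase_symmetry

FEATURE_NAMES = (
    "LM", "RGM", "YBM", "SATM",
    "LC", "RGC", "YBC", "SATC", "TC",
    "S", "E", "C",
    "BiSymm", "RaSymmH", "RaSymmL",
)

#: Aperture diameters (deg) for the windowed features.
DEFAULT_WINDOWS_DEG: dict[str, float] = {
    "LM": 0.5, "RGM": 2.0, "YBM": 2.0, "SATM": 1.0,
    "LC": 1.0, "RGC": 2.0, "YBC": 2.0, "SATC": 1.0, "TC": 3.7,
}

#: Intrinsic-dimensionality windows (deg).
ID_PATCH_DEG = 6.0        # Gaussian patch extent
ID_SIGMA_DEG = 1.0        # Gaussian patch standard deviation
ID_PRESMOOTH_DEG = 0.13   # pre-smoothing standard deviation
# Relative regularizer for the barycentric S/E/C decomposition.
ID_REG_FRACTION = 1e-3


@dataclass
class FeatureMap:
    name: str
    values: np.ndarray
    window_deg: float = float("nan")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def disk_footprint(diameter_px: int) -> np.ndarray:
    """Boolean mask of pixel centers within a circle of the given odd diameter."""
    if diameter_px < 1 or diameter_px % 2 == 0:
        raise ValueError("diameter_px must be a positive odd integer")
    r = diameter_px // 2
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= (diameter_px / 2.0) ** 2


def _disk_convolve(channel: np.ndarray, footprint: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Windowed sums and in-image aperture counts via FFT convolution."""
    kernel = footprint.astype(float)
    sums = signal.fftconvolve(channel, kernel, mode="same")
    counts = signal.fftconvolve(np.ones_like(channel), kernel, mode="same")
    return sums, np.maximum(counts, 1e-12)


def local_mean(
    channel: np.ndarray, diameter_deg: float, geometry: ViewingGeometry
) -> FeatureMap:
    """Mean of channel values inside a circular aperture at every pixel."""
    channel = np.asarray(channel, dtype=float)
    d = geometry.odd_diameter_px(diameter_deg)
    fp = disk_footprint(d)
    sums, counts = _disk_convolve(channel, fp)
    return FeatureMap("local_mean", sums / counts, diameter_deg)


def local_std(
    channel: np.ndarray, diameter_deg: float, geometry: ViewingGeometry
) -> FeatureMap:
    """Population standard deviation inside a circular aperture at every pixel."""
    channel = np.asarray(channel, dtype=float)
    d = geometry.odd_diameter_px(diameter_deg)
    fp = disk_footprint(d)
    # center on the global mean: identical in exact arithmetic, but avoids
    # the catastrophic cancellation of E[x^2] - E[x]^2 for near-constant input
    centered = channel - channel.mean()
    sums, counts = _disk_convolve(centered, fp)
    sq_sums, _ = _disk_convolve(centered**2, fp)
    mean = sums / counts
    var = sq_sums / counts - mean**2
    return FeatureMap("local_std", np.sqrt(np.maximum(var, 0.0)), diameter_deg)


def texture_contrast(
    lc_map: FeatureMap | np.ndarray,
    geometry: ViewingGeometry,
    diameter_deg: float = DEFAULT_WINDOWS_DEG["TC"],
) -> FeatureMap:
    """Contrast of contrast: local std applied to a luminance-contrast map."""
    values = lc_map.values if isinstance(lc_map, FeatureMap) else np.asarray(lc_map)
    out = local_std(values, diameter_deg, geometry)
    return FeatureMap("TC", out.values, diameter_deg)


def intrinsic_dimensionality(
    lum: np.ndarray,
    geometry: ViewingGeometry,
    *,
    patch_deg: float = ID_PATCH_DEG,
    sigma_deg: float = ID_SIGMA_DEG,
    presmooth_deg: float = ID_PRESMOOTH_DEG,
    reg_fraction: float = ID_REG_FRACTION,
) -> tuple[FeatureMap, FeatureMap, FeatureMap]:
    """Surfaceness, edgeness and cornerness from the gradient structure tensor.

    The luminance plane is pre-smoothed (``presmooth_deg`` std), its outer
    gradient products are integrated under a Gaussian patch of extent
    ``patch_deg`` with standard deviation ``sigma_deg``, and the tensor's
    eigenvalues lam1 >= lam2 >= 0 are turned into barycentric coordinates

        S = tau / (tr + tau),  E = (lam1 - lam2) / (tr + tau),
        C = 2 lam2 / (tr + tau),       tr = lam1 + lam2,

    which are nonnegative, sum to one, and classify each pixel by the
    number of dominant gradient orientations (0: surface, 1: edge,
    2: corner).  ``tau`` is ``reg_fraction`` of the image's maximum trace.
    """
    lum = np.asarray(lum, dtype=float)
    sigma_px = geometry.sigma_px(sigma_deg)
    patch_px = geometry.deg_to_px(patch_deg)
    truncate = max(patch_px / (2.0 * sigma_px), 0.5)
    import warnings

    if min(lum.shape) < patch_px:
        warnings.warn(
            "image smaller than the intrinsic-dimensionality integration window; "
            "the window is truncated at the image borders",
            stacklevel=2,
        )

    smooth = ndimage.gaussian_filter(lum, geometry.sigma_px(presmooth_deg))
    gy, gx = np.gradient(smooth)

    def integrate(a: np.ndarray) -> np.ndarray:
        return ndimage.gaussian_filter(a, sigma_px, truncate=truncate)

    jxx = integrate(gx * gx)
    jyy = integrate(gy * gy)
    jxy = integrate(gx * gy)

    trace = jxx + jyy
    disc = np.sqrt(((jxx - jyy) / 2.0) ** 2 + jxy**2)
    lam1 = trace / 2.0 + disc
    lam2 = np.maximum(trace / 2.0 - disc, 0.0)

    tau = reg_fraction * float(trace.max()) + np.finfo(float).tiny
    denom = trace + tau
    s_map = tau / denom
    e_map = (lam1 - lam2) / denom
    c_map = 2.0 * lam2 / denom
    return (
        FeatureMap("S", s_map, patch_deg),
        FeatureMap("E", e_map, patch_deg),
        FeatureMap("C", c_map, patch_deg),
    )


@dataclass
class BatteryConfig:
    """Window sizes and filter constants for :func:`compute_battery`."""

    windows_deg: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WINDOWS_DEG))
    id_patch_deg: float = ID_PATCH_DEG
    id_sigma_deg: float = ID_SIGMA_DEG
    id_presmooth_deg: float = ID_PRESMOOTH_DEG


def compute_battery(
    image: np.ndarray,
    geometry: ViewingGeometry,
    config: BatteryConfig | None = None,
    *,
    opponent: OpponentImage | None = None,
) -> dict[str, FeatureMap]:
    """Compute all 15 feature maps of an RGB image.

    Deterministic given image and config; returns a dict keyed by the
    canonical feature names, each map with the shape of the input image.
    """
    if config is None:
        config = BatteryConfig()
    if opponent is None:
        opponent = rgb_to_opponent(image)
    win = config.windows_deg

    maps: dict[str, FeatureMap] = {}
    for name, channel in (
        ("LM", opponent.lum), ("RGM", opponent.rg),
        ("YBM", opponent.yb), ("SATM", opponent.sat),
    ):
        fm = local_mean(channel, win[name], geometry)
        maps[name] = FeatureMap(name, fm.values, win[name])
    for name, channel in (
        ("LC", opponent.lum), ("RGC", opponent.rg),
        ("YBC", opponent.yb), ("SATC", opponent.sat),
    ):
        fm = local_std(channel, win[name], geometry)
        maps[name] = FeatureMap(name, fm.values, win[name])
    maps["TC"] = texture_contrast(maps["LC"], geometry, win["TC"])

    s_map, e_map, c_map = intrinsic_dimensionality(
        opponent.lum,
        geometry,
        patch_deg=config.id_patch_deg,
        sigma_deg=config.id_sigma_deg,
        presmooth_deg=config.id_presmooth_deg,
    )
    maps["S"], maps["E"], maps["C"] = s_map, e_map, c_map

    maps["BiSymm"] = FeatureMap(
        "BiSymm", phase_symmetry(opponent.lum, "bilateral", "low", geometry), float("nan")
    )
    maps["RaSymmH"] = FeatureMap(
        "RaSymmH", phase_symmetry(opponent.lum, "radial", "high", geometry), float("nan")
    )
    maps["RaSymmL"] = FeatureMap(
        "RaSymmL", phase_symmetry(opponent.lum, "radial", "low", geometry), float("nan")
    )
    return maps
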