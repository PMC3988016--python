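"""Synthetic stimuli, observers and events with planted ground truth.

The generator emulates the study's inputs so every analysis can be
validated against a known generative model:

* pink-noise images - a target amplitude spectrum (1/f^gamma or an
  arbitrary per-channel spectrum) combined with the phase spectrum of a
  white-noise image (which guarantees conjugate symmetry, hence a real
  image) and transformed back to pixel space per channel;
* deterministic test patterns for feature-map validation;
* fixations sampled from a planted saliency function composed with a
  central spatial bias, with ranks, onsets and durations from a planted
  linear duration model;
* interestingness clicks concentrated at planted loci.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .geometry import ViewingGeometry

# ---------------------------------------------------------------------------
# pink noise


@dataclass(frozen=True)
class PinkNoiseSpec:
    shape: tuple[int, int] = (192, 192)
    exponent: float = 1.0
    target_amplitude: np.ndarray | None = None  # overrides the exponent
    n_channels: int = 3
    seed: int = 0


def amplitude_spectrum(shape: tuple[int, int], exponent: float) -> np.ndarray:
    """1/f^gamma amplitude spectrum on the FFT grid; zero DC."""
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    f = np.sqrt(fy**2 + fx**2)
    with np.errstate(divide="ignore"):
        amp = np.where(f > 0, f ** (-exponent), 0.0)
    return amp


def pink_noise_field(amplitude: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Real-valued field whose FFT amplitude equals ``amplitude`` exactly.

    The phase comes from the FFT of a white-noise image with the
    amplitude information discarded, so conjugate symmetry (and thus a
    real result) is automatic.  The mean (DC) of the field is zero.
    """
    amplitude = np.asarray(amplitude, dtype=float)
    if np.any(amplitude < 0):
        raise ValueError("amplitude spectrum must be nonnegative")
    white = rng.standard_normal(amplitude.shape)
    spectrum = np.fft.fft2(white)
    mags = np.abs(spectrum)
    phase = np.where(mags > 0, spectrum / np.where(mags > 0, mags, 1.0), 1.0)
    field = np.fft.ifft2(amplitude * phase)
    return np.real(field)


def make_pink_noise(spec: PinkNoiseSpec) -> np.ndarray:
    """(H, W, C) pink-noise image, channels independently rescaled to [0, 1]."""
    rng = np.random.default_rng(spec.seed)
    if spec.target_amplitude is not None:
        amp = np.asarray(spec.target_amplitude, dtype=float)
        if amp.shape[-2:] != spec.shape:
            raise ValueError("target amplitude shape mismatch")
        per_channel = amp.ndim == 3
    else:
        amp = amplitude_spectrum(spec.shape, spec.exponent)
        per_channel = False

    channels = []
    for c in range(spec.n_channels):
        a = amp[c] if per_channel else amp
        field = pink_noise_field(a, rng)
        lo, hi = field.min(), field.max()
        scaled = (field - lo) / (hi - lo) if hi > lo else np.full(spec.shape, 0.5)
        channels.append(scaled)
    return np.stack(channels, axis=-1)


# ---------------------------------------------------------------------------
# test patterns


def make_test_pattern(
    kind: str,
    size: tuple[int, int] = (128, 128),
    seed: int = 0,
    *,
    ring_wavelength_px: float = 12.0,
    square_px: int = 16,
) -> np.ndarray:
    """Deterministic 2D test images in [0, 1].

    Geometry conventions: the step edge sits between columns
    ``w//2 - 1`` and ``w//2``; the corner (junction of two orthogonal
    step edges) is at pixel (h//2, w//2); the concentric rings are
    centered at ((h-1)/2, (w-1)/2); mirrored noise reflects the left
    half onto the right, mirror axis at column (w-1)/2.
    """
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    if kind == "uniform":
        return np.full(size, 0.5)
    if kind == "step_edge":
        return np.where(xx >= w // 2, 0.75, 0.25)
    if kind == "corner":
        # two orthogonal step edges meeting at (h//2, w//2): the polarity
        # flips across both edges, as at a checkerboard corner
        return np.where((yy >= h // 2) ^ (xx >= w // 2), 0.75, 0.25)
    if kind == "checkerboard":
        return np.where(((yy // square_px) + (xx // square_px)) % 2 == 0, 0.25, 0.75)
    if kind == "concentric_rings":
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        r = np.hypot(yy - cy, xx - cx)
        return 0.5 + 0.5 * np.cos(2.0 * np.pi * r / ring_wavelength_px)
    if kind == "mirrored_noise":
        rng = np.random.default_rng(seed)
        img = rng.random(size)
        img[:, w - w // 2 :] = img[:, : w // 2][:, ::-1]
        return img
    raise ValueError(f"unknown test pattern kind {kind!r}")


# ---------------------------------------------------------------------------
# observers: fixations, clicks, durations


@dataclass
class ObserverModel:
    """Generative model of a synthetic observer.

    Fixations are drawn with probability proportional to
    ``central_bias(x, y) * g(percentile(x, y))``.  ``saliency`` maps
    feature percentiles in [0, 100] to nonnegative preference values
    (None: flat).  ``bias_sigma_deg`` is the std of the isotropic
    central Gaussian bias (None: spatially uniform).  Durations follow

        duration_ms = base + w_interest * I + w_feature * F + sigma * eps

    with I, F the percentile values (0-100) at the fixated location.
    """

    saliency: Callable[[np.ndarray], np.ndarray] | None = None
    bias_sigma_deg: float | None = 5.0
    fixations_per_trial: int = 10
    duration_base_ms: float = 302.0
    duration_w_interest: float = 0.0
    duration_w_feature: float = 0.0
    duration_sigma_ms: float = 1.0
    #: optional rank -> saliency function; overrides ``saliency`` per rank
    rank_schedule: dict[int, Callable[[np.ndarray], np.ndarray]] | None = None


def central_bias_density(geometry: ViewingGeometry, sigma_deg: float) -> np.ndarray:
    h, w = geometry.image_size
    cy, cx = geometry.center
    sigma = geometry.sigma_px(sigma_deg)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    d = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2))
    return d / d.sum()


def _sampling_density(
    pct_map: np.ndarray,
    g: Callable[[np.ndarray], np.ndarray] | None,
    geometry: ViewingGeometry,
    bias_sigma_deg: float | None,
) -> np.ndarray:
    density = np.ones_like(pct_map, dtype=float)
    if g is not None:
        density = density * np.asarray(g(pct_map), dtype=float)
    if np.any(density < 0):
        raise ValueError("planted saliency g must be nonnegative")
    if bias_sigma_deg is not None:
        density = density * central_bias_density(geometry, bias_sigma_deg)
    total = density.sum()
    if not total > 0:
        raise ValueError("degenerate sampling density (g == 0 everywhere?)")
    return density / total


def sample_fixations(
    pct_map: np.ndarray,
    observer: ObserverModel,
    geometry: ViewingGeometry,
    n_fixations: int,
    rng: np.random.Generator,
    *,
    subject: str = "s01",
    image: str = "img01",
    category: str = "Natural",
    interest_pct_map: np.ndarray | None = None,
    density: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw fixations for one subject on one image.

    ``pct_map`` is the percentile map of the saliency-driving feature.
    Ranks are assigned sequentially within trials of
    ``observer.fixations_per_trial``; rank-1 fixations land at the image
    center (the drift-correction artifact the analysis excludes by
    default).  Durations follow the observer's linear model with the
    feature (and optionally interest) percentiles at the fixated pixel.
    """
    h, w = pct_map.shape
    flat_idx = np.arange(h * w)

    if density is not None:
        density = np.asarray(density, dtype=float).ravel()
        if np.any(density < 0) or not density.sum() > 0:
            raise ValueError("density must be nonnegative with positive mass")
        density = density / density.sum()
        densities = None
    elif observer.rank_schedule is None:
        density = _sampling_density(
            pct_map, observer.saliency, geometry, observer.bias_sigma_deg
        ).ravel()
        densities = None
    else:
        densities = {
            r: _sampling_density(pct_map, g_r, geometry, observer.bias_sigma_deg).ravel()
            for r, g_r in observer.rank_schedule.items()
        }
        default = _sampling_density(
            pct_map, observer.saliency, geometry, observer.bias_sigma_deg
        ).ravel()

    ranks = 1 + (np.arange(n_fixations) % observer.fixations_per_trial)
    ys = np.empty(n_fixations, dtype=int)
    xs = np.empty(n_fixations, dtype=int)
    cy, cx = geometry.center
    for r in np.unique(ranks):
        sel = ranks == r
        if r == 1:
            ys[sel] = int(round(cy))
            xs[sel] = int(round(cx))
            continue
        if densities is not None:
            dens = densities.get(int(r), default)
        else:
            dens = density
        drawn = rng.choice(flat_idx, size=int(sel.sum()), p=dens)
        ys[sel] = drawn // w
        xs[sel] = drawn % w

    f_pct = pct_map[ys, xs]
    i_pct = interest_pct_map[ys, xs] if interest_pct_map is not None else np.zeros(n_fixations)
    durations = (
        observer.duration_base_ms
        + observer.duration_w_interest * i_pct
        + observer.duration_w_feature * f_pct
        + observer.duration_sigma_ms * rng.standard_normal(n_fixations)
    )
    durations = np.maximum(durations, 1.0)
    onsets = np.concatenate(([0.0], np.cumsum(durations)[:-1]))

    return pd.DataFrame(
        {
            "subject": subject,
            "image": image,
            "category": category,
            "x": xs.astype(float),
            "y": ys.astype(float),
            "onset_ms": onsets,
            "duration_ms": durations,
            "rank": ranks,
            "feature_pct": f_pct,
            "interest_pct": i_pct,
        }
    )


def sample_clicks(
    centers: list[tuple[float, float]],
    spread_deg: float,
    geometry: ViewingGeometry,
    n_subjects: int,
    rng: np.random.Generator,
    *,
    image: str = "img01",
    clicks_per_subject: int = 5,
    weights: list[float] | None = None,
) -> pd.DataFrame:
    """Interestingness clicks from a Gaussian mixture at planted centers.

    ``centers`` are (y, x) pixel positions.  Exactly
    ``clicks_per_subject`` clicks per subject are produced; draws that
    land out of bounds are redrawn.
    """
    if not centers:
        raise ValueError("need at least one planted interest center")
    h, w = geometry.image_size
    spread_px = geometry.sigma_px(spread_deg)
    p = None
    if weights is not None:
        p = np.asarray(weights, dtype=float)
        p = p / p.sum()

    rows = []
    for s in range(n_subjects):
        subject = f"c{s + 1:02d}"
        for _ in range(clicks_per_subject):
            while True:
                k = rng.choice(len(centers), p=p)
                cy, cx = centers[k]
                y = cy + spread_px * rng.standard_normal()
                x = cx + spread_px * rng.standard_normal()
                if 0 <= y <= h - 1 and 0 <= x <= w - 1:
                    break
            rows.append({"subject": subject, "image": image, "x": x, "y": y})
    return pd.DataFrame(rows)
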