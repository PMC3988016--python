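"""Phase-based symmetry features (Kovesi-style phase congruency).

Local symmetry is scored from quadrature filter responses: at a point of
locally even (mirror- or blob-like) structure the even-symmetric filter
response dominates the odd-symmetric one across scales, so

    sym(x) = sum_scales [ |even| - |odd| - T ]_+  /  ( sum_scales A + eps )

with A the response amplitude and T a small noise floor proportional to
the image-wide mean amplitude.

Two modes are provided:

* ``radial`` - isotropic log-Gabor bandpass filters with the Riesz
  transform as odd (monogenic signal); scores centers of radially
  symmetric structure such as blobs and concentric rings.
* ``bilateral`` - oriented log-Gabor filters (one-sided in frequency, so
  the inverse transform yields an even/odd quadrature pair); responses
  are pooled over orientations and score mirror-symmetric structure.

Filter constants: 3 scales per band spaced by a factor 2.1, bandwidth
sigma_on_f = 0.55, 6 orientations for the bilateral mode.  The "high"
and "low" bands differ by a factor-of-4 shift of the shortest center
wavelength (0.25 deg vs 1.0 deg).
"""

from __future__ import annotations

import numpy as np

from .geometry import ViewingGeometry

N_SCALES = 3
SCALE_MULT = 2.1
SIGMA_ON_F = 0.55
N_ORIENTATIONS = 6
#: Shortest center wavelength (deg) of each band.
BAND_MIN_WAVELENGTH_DEG = {"high": 0.25, "low": 1.0}
#: Noise floor as a fraction of the image-wide mean amplitude sum.
NOISE_FLOOR_FRACTION = 1.0
_EPS = 1e-12


def _frequency_grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    radius = np.sqrt(fy**2 + fx**2)
    radius[0, 0] = 1.0  # avoid log(0); the DC gain is zeroed explicitly
    return radius, fy, fx


def _log_gabor(radius: np.ndarray, wavelength_px: float) -> np.ndarray:
    f0 = 1.0 / wavelength_px
    lg = np.exp(-(np.log(radius / f0) ** 2) / (2.0 * np.log(SIGMA_ON_F) ** 2))
    lg[0, 0] = 0.0
    return lg


def _band_wavelengths(band: str, geometry: ViewingGeometry) -> list[float]:
    if band not in BAND_MIN_WAVELENGTH_DEG:
        raise ValueError(f"unknown band {band!r}; expected 'low' or 'high'")
    base = geometry.deg_to_px(BAND_MIN_WAVELENGTH_DEG[band])
    return [base * SCALE_MULT**s for s in range(N_SCALES)]


def _oriented_responses(
    lum: np.ndarray, band: str, geometry: ViewingGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Per-orientation scale-summed symmetry energy and amplitude.

    Each filter is one-sided in the frequency plane, so the real and
    imaginary parts of its spatial response form the even/odd
    quadrature pair.  Returns arrays of shape (N_ORIENTATIONS, H, W).
    """
    wavelengths = _band_wavelengths(band, geometry)
    # pad with a linear ramp toward the mean so the periodic extension of
    # the FFT has no border discontinuity (wrap-around artifacts)
    pad = int(np.ceil(max(wavelengths)))
    shape = lum.shape
    padded = np.pad(lum - lum.mean(), pad, mode="linear_ramp", end_values=0.0)

    radius, fy, fx = _frequency_grid(padded.shape)
    theta_grid = np.arctan2(-fy, fx)  # image y runs downward
    F = np.fft.fft2(padded)
    crop = (slice(pad, pad + shape[0]), slice(pad, pad + shape[1]))

    energy = np.zeros((N_ORIENTATIONS,) + shape)
    amp = np.zeros((N_ORIENTATIONS,) + shape)
    dtheta_sigma = np.pi / N_ORIENTATIONS / 1.2
    for o in range(N_ORIENTATIONS):
        angle = o * np.pi / N_ORIENTATIONS
        dtheta = np.angle(np.exp(1j * (theta_grid - angle)))
        spread = np.exp(-(dtheta**2) / (2.0 * dtheta_sigma**2))
        for wl in wavelengths:
            filt = _log_gabor(radius, wl) * spread
            eo = np.fft.ifft2(F * filt)
            energy[o] += (np.abs(np.real(eo)) - np.abs(np.imag(eo)))[crop]
            amp[o] += np.abs(eo)[crop]
    return energy, amp


def _bilateral_symmetry(lum: np.ndarray, band: str, geometry: ViewingGeometry) -> np.ndarray:
    """Mirror symmetry: even-phase energy pooled over orientations."""
    energy, amp = _oriented_responses(lum, band, geometry)
    total_energy = energy.sum(axis=0)
    total_amp = amp.sum(axis=0)
    floor = NOISE_FLOOR_FRACTION * float(total_amp.mean()) / (N_SCALES * N_ORIENTATIONS)
    return np.maximum(total_energy - floor, 0.0) / (total_amp + _EPS)


def _radial_symmetry(lum: np.ndarray, band: str, geometry: ViewingGeometry) -> np.ndarray:
    """Radial symmetry: even-phase energy required in *every* orientation.

    A center of radially symmetric structure has an even phase profile
    along each direction, whereas straight ridges and edges are even
    along at most one; taking the minimum of the per-orientation
    symmetry energies therefore singles out radial centers.
    """
    energy, amp = _oriented_responses(lum, band, geometry)
    min_energy = energy.min(axis=0)
    total_amp = amp.sum(axis=0)
    floor = NOISE_FLOOR_FRACTION * float(total_amp.mean()) / (
        N_SCALES * N_ORIENTATIONS**2
    )
    return np.maximum(N_ORIENTATIONS * min_energy - floor, 0.0) / (total_amp + _EPS)


def phase_symmetry(
    lum: np.ndarray,
    mode: str,
    band: str,
    geometry: ViewingGeometry,
) -> np.ndarray:
    """Per-pixel symmetry energy (>= 0) of the luminance plane.

    Parameters
    ----------
    mode:
        ``"radial"`` (blob/ring centers) or ``"bilateral"`` (mirror axes).
    band:
        ``"low"`` or ``"high"`` spatial-frequency band.
    """
    lum = np.asarray(lum, dtype=float)
    if mode == "radial":
        return _radial_symmetry(lum, band, geometry)
    if mode == "bilateral":
        return _bilateral_symmetry(lum, band, geometry)
    raise ValueError(f"unknown mode {mode!r}; expected 'radial' or 'bilateral'")
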