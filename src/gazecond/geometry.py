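"""Viewing geometry: conversion between visual degrees and pixels.

All window and kernel sizes in this package are specified in degrees of
visual angle and converted to pixels through a :class:`ViewingGeometry`.
The default of 45 px/deg corresponds approximately to a 21" 4:3 CRT at
1280x960 viewed from 80 cm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_PIXELS_PER_DEGREE = 45.0

# Gaussian full-width-at-half-maximum to standard deviation.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class ViewingGeometry:
    """Pixel grid of the stimulus and its angular scale.

    Parameters
    ----------
    pixels_per_degree:
        Linear scale of the display, px per degree of visual angle (> 0).
    image_size:
        (height, width) of the stimulus in pixels.
    """

    pixels_per_degree: float = DEFAULT_PIXELS_PER_DEGREE
    image_size: tuple[int, int] = (960, 1280)

    def __post_init__(self) -> None:
        if not self.pixels_per_degree > 0:
            raise ValueError("pixels_per_degree must be positive")
        h, w = self.image_size
        if h < 1 or w < 1:
            raise ValueError("image_size must be at least 1x1")

    def deg_to_px(self, degrees: float) -> float:
        return float(degrees) * self.pixels_per_degree

    def px_to_deg(self, pixels: float) -> float:
        return float(pixels) / self.pixels_per_degree

    def odd_diameter_px(self, diameter_deg: float) -> int:
        """Aperture diameter in pixels, rounded to the nearest odd count (>= 1)."""
        d = self.deg_to_px(diameter_deg)
        # ties (even pixel sizes) round up
        odd = 2 * int(np.floor((d - 1.0) / 2.0 + 0.5)) + 1
        return max(odd, 1)

    def sigma_px(self, sigma_deg: float) -> float:
        return self.deg_to_px(sigma_deg)

    def fwhm_sigma_px(self, fwhm_deg: float) -> float:
        """Standard deviation in px of a Gaussian with the given FWHM in degrees."""
        return self.deg_to_px(fwhm_deg) * FWHM_TO_SIGMA

    @property
    def center(self) -> tuple[float, float]:
        """Image center (y, x) in pixel coordinates."""
        h, w = self.image_size
        return ((h - 1) / 2.0, (w - 1) / 2.0)
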