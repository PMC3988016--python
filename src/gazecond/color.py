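"""Cone-opponent color representation.

RGB stimuli are linearized (sRGB transfer), converted to LMS cone
responses and recombined into three opponent planes - luminance (L+M+S),
red-green (L-M) and yellow-blue ((L+M)/2 - S) - plus a saturation plane,
the chromatic magnitude sqrt(rg^2 + yb^2) in the isoluminant plane.

The LMS matrix is the Hunt-Pointer-Estevez fundamentals applied to the
sRGB/D65 primaries.  Rows are rescaled to sum to one so that achromatic
input (R=G=B) maps to L=M=S exactly, which zeroes both opponent planes
at the achromatic point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# sRGB (linear) -> XYZ, D65 white (IEC 61966-2-1).
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

# XYZ -> LMS, Hunt-Pointer-Estevez (D65 normalized).
_XYZ_TO_LMS = np.array(
    [
        [0.4002, 0.7076, -0.0808],
        [-0.2263, 1.1653, 0.0457],
        [0.0000, 0.0000, 0.9182],
    ]
)


def _achromatic_normalized(matrix: np.ndarray) -> np.ndarray:
    return matrix / matrix.sum(axis=1, keepdims=True)


#: Default linear-sRGB -> LMS conversion, rows normalized so gray -> L=M=S.
SRGB_TO_LMS = _achromatic_normalized(_XYZ_TO_LMS @ _SRGB_TO_XYZ)


@dataclass(frozen=True)
class OpponentImage:
    """Per-pixel opponent planes derived from an RGB image."""

    lum: np.ndarray
    rg: np.ndarray
    yb: np.ndarray
    sat: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.lum.shape


def linearize_srgb(image: np.ndarray) -> np.ndarray:
    """Invert the sRGB transfer function; input and output in [0, 1]."""
    image = np.asarray(image, dtype=float)
    low = image <= 0.04045
    out = np.where(low, image / 12.92, ((image + 0.055) / 1.055) ** 2.4)
    return out


def rgb_to_opponent(
    image: np.ndarray,
    matrix: np.ndarray | None = None,
    *,
    assume_linear: bool = False,
) -> OpponentImage:
    """Convert an (H, W, 3) RGB image in [0, 1] to opponent planes.

    Parameters
    ----------
    image:
        RGB array with values in [0, 1].
    matrix:
        3x3 RGB(linear) -> LMS conversion; defaults to :data:`SRGB_TO_LMS`.
    assume_linear:
        Skip sRGB gamma linearization when the input is already linear.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    if matrix is None:
        matrix = SRGB_TO_LMS
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3):
        raise ValueError("conversion matrix must be 3x3")

    linear = image if assume_linear else linearize_srgb(image)
    lms = np.einsum("ij,hwj->hwi", matrix, linear)
    L, M, S = lms[..., 0], lms[..., 1], lms[..., 2]

    lum = L + M + S
    rg = L - M
    yb = (L + M) / 2.0 - S
    sat = np.sqrt(rg**2 + yb**2)
    return OpponentImage(lum=lum, rg=rg, yb=yb, sat=sat)
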