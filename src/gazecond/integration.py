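"""Models of saliency integration across feature channels.

Two-dimensional saliency functions are modeled from their
one-dimensional marginals (linear and multiplicative-interaction fits),
sub/supra-additivity of D_KL is expressed as a percentage of the
additive prediction, and the interestingness-plus-feature model

    saliency ~ alpha * interest^x + beta * feature^x        x in {1, 2, 4}

is fit on percentile axes rescaled to [0, 1].  Goodness of fit is the
squared Pearson correlation between model and empirical surface over
populated bins, so it is invariant under affine rescaling of the
empirical surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .saliency import SaliencyFunction

DEFAULT_EXPONENT_GRID = (1, 2, 4)


@dataclass
class IntegrationFit:
    model: str
    coefficients: dict[str, float]
    r_squared: float
    n_bins_used: int
    rank_deficient: bool = False


@dataclass
class AdditivityResult:
    dkl_2d: float
    dkl_1d_a: float
    dkl_1d_b: float

    @property
    def percent_of_additive(self) -> float:
        denom = self.dkl_1d_a + self.dkl_1d_b
        return 100.0 * self.dkl_2d / denom if denom > 0 else float("nan")


@dataclass
class QuarterDecomposition:
    """Accumulative saliency (percent) in the four half-axis quadrants."""

    weak_weak: float
    strong_feature_weak_interest: float
    weak_feature_strong_interest: float
    strong_strong: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.weak_weak,
                self.strong_feature_weak_interest,
                self.weak_feature_strong_interest,
                self.strong_strong,
            ]
        )


def _surface_values(sal2d: SaliencyFunction | np.ndarray) -> np.ndarray:
    if isinstance(sal2d, SaliencyFunction):
        return np.asarray(sal2d.values, dtype=float)
    return np.asarray(sal2d, dtype=float)


def _r_squared(model: np.ndarray, empirical: np.ndarray) -> float:
    if np.std(model) == 0 or np.std(empirical) == 0:
        return 0.0
    return float(np.corrcoef(model, empirical)[0, 1] ** 2)


def _lstsq_fit(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool]:
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    return coef, rank < design.shape[1]


def fit_linear_integration(
    sal2d: SaliencyFunction | np.ndarray,
    with_interaction: bool = False,
    m1: np.ndarray | None = None,
    m2: np.ndarray | None = None,
) -> IntegrationFit:
    """Fit s(x, y) ~ c + a*m1(x) + b*m2(y) (+ g*m1(x)*m2(y)).

    ``m1``/``m2`` are the one-dimensional saliency functions of the two
    channels; when omitted they are taken as the empirical marginals of
    the surface (mean over the other axis, ignoring unpopulated bins).
    Unpopulated (NaN) bins are excluded from the fit.
    """
    surface = _surface_values(sal2d)
    with np.errstate(invalid="ignore"):
        if m1 is None:
            m1 = np.nanmean(surface, axis=1)
        if m2 is None:
            m2 = np.nanmean(surface, axis=0)
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)

    m1_grid, m2_grid = np.meshgrid(m1, m2, indexing="ij")
    mask = np.isfinite(surface) & np.isfinite(m1_grid) & np.isfinite(m2_grid)
    y = surface[mask]
    cols = [np.ones(y.size), m1_grid[mask], m2_grid[mask]]
    names = ["intercept", "a", "b"]
    if with_interaction:
        cols.append((m1_grid * m2_grid)[mask])
        names.append("gamma")
    design = np.column_stack(cols)
    coef, deficient = _lstsq_fit(design, y)
    pred = design @ coef
    return IntegrationFit(
        model="linear+interaction" if with_interaction else "linear",
        coefficients=dict(zip(names, coef.tolist())),
        r_squared=_r_squared(pred, y),
        n_bins_used=int(mask.sum()),
        rank_deficient=bool(deficient),
    )


def additivity_index(dkl_1d_a: float, dkl_1d_b: float, dkl_2d: float) -> AdditivityResult:
    """Joint D_KL as a percentage of the sum of the two 1D D_KL values.

    100% is exact additivity; below 100% the second feature adds
    sub-additively, above 100% synergistically.
    """
    if min(dkl_1d_a, dkl_1d_b, dkl_2d) < 0:
        raise ValueError("D_KL inputs must be nonnegative")
    return AdditivityResult(dkl_2d=dkl_2d, dkl_1d_a=dkl_1d_a, dkl_1d_b=dkl_1d_b)


def quarter_saliency(
    sal2d: SaliencyFunction | np.ndarray,
    interest_axis: int = 0,
) -> QuarterDecomposition:
    """Accumulative saliency per quadrant of a (interest x feature) surface.

    Both percentile axes are split at the 50th percentile; the saliency
    mass in each quadrant is expressed as a percentage of the total.
    Unpopulated bins contribute nothing.
    """
    surface = _surface_values(sal2d)
    if interest_axis == 1:
        surface = surface.T
    ny, nx = surface.shape
    hy, hx = ny // 2, nx // 2
    q = np.array(
        [
            np.nansum(surface[:hy, :hx]),               # weak interest, weak feature
            np.nansum(surface[:hy, hx:]),               # weak interest, strong feature
            np.nansum(surface[hy:, :hx]),               # strong interest, weak feature
            np.nansum(surface[hy:, hx:]),               # strong interest, strong feature
        ]
    )
    q = 100.0 * q / q.sum()
    return QuarterDecomposition(
        weak_weak=float(q[0]),
        strong_feature_weak_interest=float(q[1]),
        weak_feature_strong_interest=float(q[2]),
        strong_strong=float(q[3]),
    )


def fit_interest_feature_model(
    sal2d: SaliencyFunction | np.ndarray,
    exponent_grid: tuple[int, ...] = DEFAULT_EXPONENT_GRID,
    with_interaction: bool = False,
    interest_axis: int = 0,
) -> dict[int, IntegrationFit]:
    """Fit s ~ c + alpha*I^x + beta*F^x for each exponent in the grid.

    Axes are bin-center percentiles rescaled to [0, 1]; ``alpha`` is the
    weight of the interest axis and ``beta`` of the feature axis.
    """
    surface = _surface_values(sal2d)
    if interest_axis == 1:
        surface = surface.T
    ny, nx = surface.shape
    i_axis = (np.arange(ny) + 0.5) / ny
    f_axis = (np.arange(nx) + 0.5) / nx
    i_grid, f_grid = np.meshgrid(i_axis, f_axis, indexing="ij")
    mask = np.isfinite(surface)
    y = surface[mask]

    fits: dict[int, IntegrationFit] = {}
    for x in exponent_grid:
        cols = [np.ones(y.size), (i_grid**x)[mask], (f_grid**x)[mask]]
        names = ["intercept", "alpha", "beta"]
        if with_interaction:
            cols.append(((i_grid**x) * (f_grid**x))[mask])
            names.append("gamma")
        design = np.column_stack(cols)
        coef, deficient = _lstsq_fit(design, y)
        pred = design @ coef
        fits[x] = IntegrationFit(
            model=f"interest_feature_x{x}" + ("+interaction" if with_interaction else ""),
            coefficients=dict(zip(names, coef.tolist())),
            r_squared=_r_squared(pred, y),
            n_bins_used=int(mask.sum()),
            rank_deficient=bool(deficient),
        )
    return fits
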