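"""Temporal evolution of saliency and fixation-duration analysis.

``dkl_time_course`` scores the actual-vs-control percentile divergence
separately for each fixation rank (starting from the second fixation;
the first lands on the pre-trial central drift-correction point), with
rank-matched controls: the control set for rank r is built from rank-r
fixations on the other images, because the central bias is strongly
rank-dependent.

``duration_surface`` bins z-scored fixation durations jointly by
interestingness and feature percentile and fits the plane

    z(duration) ~ c + w_I * I + w_F * F,      I, F in percentile units,

per subject.  Coefficients are also reported back on the native
duration scale (ms per percentile) by unscaling with each subject's
duration standard deviation, which makes planted generator weights
directly recoverable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ViewingGeometry
from .saliency import SaliencyResult, control_density_maps, feature_dkl

MIN_EVENTS_PER_RANK = 50


@dataclass
class RankTimeCourse:
    ranks: list[int]
    dkl_bits: list[float]
    n_events: list[int]
    results: dict[int, SaliencyResult] = field(default_factory=dict)

    @property
    def normalized(self) -> np.ndarray:
        """Curve scaled so its peak equals 1."""
        arr = np.asarray(self.dkl_bits, dtype=float)
        peak = arr.max()
        return arr / peak if peak > 0 else arr

    @property
    def peak_rank(self) -> int:
        return self.ranks[int(np.argmax(self.dkl_bits))]


def dkl_time_course(
    feature_maps: dict,
    fixations: pd.DataFrame,
    geometry: ViewingGeometry,
    max_rank: int | None = None,
    min_events: int = MIN_EVENTS_PER_RANK,
    **kwargs,
) -> RankTimeCourse:
    """Per-rank D_KL between rank-restricted actual and control sets.

    Ranks run from 2 up to ``max_rank`` (default: the largest rank in
    the table); ranks with fewer than ``min_events`` fixations on the
    analyzed images are dropped.
    """
    fix = fixations.loc[fixations["image"].isin(feature_maps.keys())]
    if max_rank is None:
        max_rank = int(fix["rank"].max())
    rank_controls = control_density_maps(
        fix, geometry, kwargs.pop("control_fwhm_deg", 1.0), by_rank=True
    )

    ranks, dkls, counts, results = [], [], [], {}
    for r in range(2, max_rank + 1):
        fix_r = fix.loc[fix["rank"] == r]
        if len(fix_r) < min_events:
            continue
        controls_r = {
            (s, img): m for (s, img, rank), m in rank_controls.items() if rank == r
        }
        if not controls_r:
            continue
        res = feature_dkl(
            feature_maps, fix_r, geometry,
            exclude_first=False, controls=controls_r, **kwargs,
        )
        ranks.append(r)
        dkls.append(res.dkl.value_bits)
        counts.append(len(fix_r))
        results[r] = res
    if not ranks:
        raise ValueError("no rank had enough events")
    return RankTimeCourse(ranks=ranks, dkl_bits=dkls, n_events=counts, results=results)


# --------------------------------------------------------------------------
# fixation durations


def zscore_durations(fixations: pd.DataFrame) -> pd.DataFrame:
    """Standardize durations per subject and category (population SD).

    Adds ``duration_z`` and ``duration_sd`` (the per-group native SD,
    kept so fitted coefficients can be mapped back to ms).  Groups with
    constant durations get z = 0 with a warning.
    """
    out = fixations.copy()
    out["duration_z"] = 0.0
    out["duration_sd"] = 0.0
    for _, idx in out.groupby(["subject", "category"], observed=True).groups.items():
        d = out.loc[idx, "duration_ms"].to_numpy(dtype=float)
        sd = d.std()  # population convention
        if sd == 0:
            warnings.warn("constant durations in a subject x category group; z set to 0", stacklevel=2)
            continue
        out.loc[idx, "duration_z"] = (d - d.mean()) / sd
        out.loc[idx, "duration_sd"] = sd
    return out


@dataclass
class DurationSurface:
    """Binned mean z-scored duration over (interest, feature) percentiles."""

    mean_z: np.ndarray
    counts: np.ndarray
    bin_edges: np.ndarray
    w_interest_z: float       # z units per percentile
    w_feature_z: float
    w_interest_native: float  # ms per percentile
    w_feature_native: float
    r_squared: float

    @property
    def ratio(self) -> float:
        return self.w_interest_native / self.w_feature_native


def duration_surface(
    fixations: pd.DataFrame,
    bins_per_dim: int = 8,
    interest_col: str = "interest_pct",
    feature_col: str = "feature_pct",
) -> DurationSurface:
    """Joint duration analysis over interest and feature percentiles.

    Expects a table annotated with per-fixation percentiles and
    ``duration_z``/``duration_sd`` from :func:`zscore_durations`.  The
    plane fit uses the raw (unbinned) fixations per subject; reported
    coefficients are across-subject means.
    """
    required = {interest_col, feature_col, "duration_z", "duration_sd"}
    missing = required - set(fixations.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")

    edges = np.linspace(0.0, 100.0, bins_per_dim + 1)
    i_bin = np.clip(np.digitize(fixations[interest_col], edges) - 1, 0, bins_per_dim - 1)
    f_bin = np.clip(np.digitize(fixations[feature_col], edges) - 1, 0, bins_per_dim - 1)
    sums = np.zeros((bins_per_dim, bins_per_dim))
    counts = np.zeros((bins_per_dim, bins_per_dim))
    np.add.at(sums, (i_bin, f_bin), fixations["duration_z"].to_numpy(dtype=float))
    np.add.at(counts, (i_bin, f_bin), 1.0)
    with np.errstate(invalid="ignore"):
        mean_z = np.where(counts > 0, sums / counts, np.nan)

    wi_z, wf_z, wi_nat, wf_nat, r2s = [], [], [], [], []
    for _, sub in fixations.groupby("subject"):
        design = np.column_stack(
            [
                np.ones(len(sub)),
                sub[interest_col].to_numpy(dtype=float),
                sub[feature_col].to_numpy(dtype=float),
            ]
        )
        z = sub["duration_z"].to_numpy(dtype=float)
        coef, _, _, _ = np.linalg.lstsq(design, z, rcond=None)
        pred = design @ coef
        ss_res = np.sum((z - pred) ** 2)
        ss_tot = np.sum((z - z.mean()) ** 2)
        r2s.append(1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0)
        sd = float(sub["duration_sd"].mean())
        wi_z.append(coef[1])
        wf_z.append(coef[2])
        wi_nat.append(coef[1] * sd)
        wf_nat.append(coef[2] * sd)

    return DurationSurface(
        mean_z=mean_z,
        counts=counts,
        bin_edges=edges,
        w_interest_z=float(np.mean(wi_z)),
        w_feature_z=float(np.mean(wf_z)),
        w_interest_native=float(np.mean(wi_nat)),
        w_feature_native=float(np.mean(wf_nat)),
        r_squared=float(np.mean(r2s)),
    )
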