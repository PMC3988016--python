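"""End-to-end recovery scenarios: generator -> pipeline -> planted truth.

Each scenario builds a small synthetic study with known ground truth,
runs the full analysis pipeline on it and reports the recovered
quantities next to the planted ones.  Study conditions (image size
192x192 at 16 px/deg, 4 observers, 6 images per category, event counts
of 5e4 or 1e5) are fixed here; every stochastic step derives from the
single scenario seed.

Scenarios
---------
``null``          fixations independent of all features (calibration)
``linear``        planted linear saliency g(X) = X on one feature
``central_bias``  fixations from a central bias over a feature with a
                  planted central gradient (confound rejection)
``interest``      planted alpha*I + beta*F saliency with alpha/beta = 4.57
``rank``          planted saliency active only for fixation ranks 2-4
``duration``      planted linear duration model (w_I, w_F) = (0.1, 0.03)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .equalize import histogram_equalize
from .features import compute_battery
from .gaze import CLICK_MAP_FWHM_DEG, build_density_map
from .geometry import ViewingGeometry
from .integration import (
    additivity_index,
    fit_interest_feature_model,
    quarter_saliency,
)
from .saliency import (
    SaliencyResult,
    feature_dkl,
    fixation_percentiles,
    upper_bound_dkl,
)
from .synth import (
    ObserverModel,
    PinkNoiseSpec,
    make_pink_noise,
    pink_noise_field,
    amplitude_spectrum,
    sample_fixations,
    sample_clicks,
)
from .temporal import dkl_time_course, duration_surface, zscore_durations

IMAGE_SIZE = (192, 192)
PIXELS_PER_DEGREE = 16.0
N_SUBJECTS = 4
N_IMAGES = 6
N_FIXATIONS = 50_000
N_CLICK_SUBJECTS = 35

#: planted interest/feature weights, alpha/beta = 4.57
ALPHA_INTEREST = 0.28
BETA_FEATURE = ALPHA_INTEREST / 4.57
BASELINE_SALIENCY = 0.1

#: planted duration model, ms per percentile and ms of noise
DURATION_W_INTEREST = 0.1
DURATION_W_FEATURE = 0.03
DURATION_SIGMA = 1.0


def default_geometry() -> ViewingGeometry:
    return ViewingGeometry(PIXELS_PER_DEGREE, IMAGE_SIZE)


@dataclass
class ScenarioData:
    name: str
    seed: int
    geometry: ViewingGeometry
    images: dict[str, np.ndarray] = field(default_factory=dict)   # RGB stimuli
    feature_maps: dict[str, np.ndarray] = field(default_factory=dict)
    interest_maps: dict[str, np.ndarray] = field(default_factory=dict)
    fixations: pd.DataFrame | None = None
    clicks: pd.DataFrame | None = None
    truth: dict = field(default_factory=dict)


def _image_ids(n: int) -> list[str]:
    return [f"img{i + 1:02d}" for i in range(n)]


def _subject_ids(n: int) -> list[str]:
    return [f"s{i + 1:02d}" for i in range(n)]


def _smooth_field(geometry: ViewingGeometry, rng: np.random.Generator) -> np.ndarray:
    """A pink-spectrum scalar field used as a planted feature map."""
    return pink_noise_field(amplitude_spectrum(geometry.image_size, 1.0), rng)


def _sample_all(
    scn: ScenarioData,
    observer_for: dict[str, ObserverModel] | ObserverModel,
    n_fixations: int,
    rng: np.random.Generator,
    pct_maps: dict[str, np.ndarray],
    interest_pct: dict[str, np.ndarray] | None = None,
    density_maps: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    subjects = _subject_ids(N_SUBJECTS)
    images = list(pct_maps.keys())
    per_cell = int(round(n_fixations / (len(subjects) * len(images))))
    frames = []
    for s in subjects:
        obs = observer_for[s] if isinstance(observer_for, dict) else observer_for
        for img in images:
            frames.append(
                sample_fixations(
                    pct_maps[img],
                    obs,
                    scn.geometry,
                    per_cell,
                    rng,
                    subject=s,
                    image=img,
                    category="Synthetic",
                    interest_pct_map=None if interest_pct is None else interest_pct[img],
                    density=None if density_maps is None else density_maps[img],
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# scenario builders


def build_scenario(name: str, seed: int, n_fixations: int | None = None) -> ScenarioData:
    builders = {
        "null": _build_null,
        "linear": _build_linear,
        "central_bias": _build_central_bias,
        "interest": _build_interest,
        "rank": _build_rank,
        "duration": _build_duration,
    }
    if name not in builders:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(builders)}")
    return builders[name](seed, n_fixations)


def _base(name: str, seed: int) -> tuple[ScenarioData, np.random.Generator]:
    import zlib

    scn = ScenarioData(name=name, seed=seed, geometry=default_geometry())
    rng = np.random.default_rng([seed, zlib.crc32(name.encode()) % (2**31)])
    return scn, rng


def _planted_pink(scn: ScenarioData, rng: np.random.Generator, with_images: bool = False) -> None:
    for k, img_id in enumerate(_image_ids(N_IMAGES)):
        scn.feature_maps[img_id] = _smooth_field(scn.geometry, rng)
        if with_images:
            spec = PinkNoiseSpec(
                shape=scn.geometry.image_size,
                seed=int(rng.integers(2**31)),
            )
            scn.images[img_id] = make_pink_noise(spec)


def _uniform_pct(maps: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {img: histogram_equalize(m).values for img, m in maps.items()}


def _build_null(seed: int, n_fixations: int | None) -> ScenarioData:
    scn, rng = _base("null", seed)
    _planted_pink(scn, rng, with_images=True)
    pct = _uniform_pct(scn.feature_maps)
    observer = ObserverModel(saliency=None, bias_sigma_deg=None)
    scn.fixations = _sample_all(scn, observer, n_fixations or N_FIXATIONS, rng, pct)
    scn.truth = {"dkl_bits": 0.0}
    return scn


def _build_linear(seed: int, n_fixations: int | None) -> ScenarioData:
    scn, rng = _base("linear", seed)
    _planted_pink(scn, rng, with_images=True)
    pct = _uniform_pct(scn.feature_maps)
    observer = ObserverModel(saliency=lambda x: x, bias_sigma_deg=None)
    scn.fixations = _sample_all(scn, observer, n_fixations or N_FIXATIONS, rng, pct)
    scn.truth = {"g": "linear", "fraction_above_median": 0.75}
    return scn


def _build_central_bias(seed: int, n_fixations: int | None) -> ScenarioData:
    scn, rng = _base("central_bias", seed)
    geometry = scn.geometry
    h, w = geometry.image_size
    cy, cx = geometry.center
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    ramp_sigma = geometry.sigma_px(3.0)
    ramp = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * ramp_sigma**2))
    for img_id in _image_ids(N_IMAGES):
        # central gradient plus a weak image-specific texture
        scn.feature_maps[img_id] = ramp + 0.05 * _smooth_field(geometry, rng)
        scn.images[img_id] = make_pink_noise(
            PinkNoiseSpec(shape=geometry.image_size, seed=int(rng.integers(2**31)))
        )
    pct = _uniform_pct(scn.feature_maps)
    observer = ObserverModel(saliency=None, bias_sigma_deg=5.0)
    scn.fixations = _sample_all(scn, observer, n_fixations or N_FIXATIONS, rng, pct)
    scn.truth = {"feature_preference": None, "bias_sigma_deg": 5.0}
    return scn


#: image count for the interest/duration studies; the leave-one-image-out
#: control weighting needs enough images to be stable
N_IMAGES_INTEREST = 16


def _interest_like(
    name: str, seed: int
) -> tuple[ScenarioData, np.random.Generator, dict, dict]:
    """Shared setup: click-based interest maps plus pink feature maps."""
    scn, rng = _base(name, seed)
    geometry = scn.geometry
    h, w = geometry.image_size
    clicks = []
    for img_id in _image_ids(N_IMAGES_INTEREST):
        scn.feature_maps[img_id] = _smooth_field(geometry, rng)
        # centers uniform over the full image so that, across many images,
        # the pooled interest-driven fixation density is spatially unbiased
        n_centers = 2
        centers = [
            (rng.uniform(0, h - 1), rng.uniform(0, w - 1))
            for _ in range(n_centers)
        ]
        clicks.append(
            sample_clicks(
                centers, spread_deg=1.0, geometry=geometry,
                n_subjects=N_CLICK_SUBJECTS, rng=rng, image=img_id,
            )
        )
        scn.interest_maps[img_id] = build_density_map(
            clicks[-1], geometry, CLICK_MAP_FWHM_DEG
        ).values
    scn.clicks = pd.concat(clicks, ignore_index=True)
    f_pct = _uniform_pct(scn.feature_maps)
    i_pct = _uniform_pct(scn.interest_maps)
    return scn, rng, f_pct, i_pct


def planted_interest_surface(i: np.ndarray, f: np.ndarray) -> np.ndarray:
    """The planted saliency c0 + alpha*i + beta*f on [0, 1] axes."""
    return BASELINE_SALIENCY + ALPHA_INTEREST * i + BETA_FEATURE * f


def _build_interest(seed: int, n_fixations: int | None) -> ScenarioData:
    scn, rng, f_pct, i_pct = _interest_like("interest", seed)
    densities = {
        img: planted_interest_surface(i_pct[img] / 100.0, f_pct[img] / 100.0)
        for img in f_pct
    }
    observer = ObserverModel(bias_sigma_deg=None)
    scn.fixations = _sample_all(
        scn, observer, n_fixations or 100_000, rng, f_pct,
        interest_pct=i_pct, density_maps=densities,
    )
    scn.truth = {
        "alpha": ALPHA_INTEREST,
        "beta": BETA_FEATURE,
        "baseline": BASELINE_SALIENCY,
        "ratio": ALPHA_INTEREST / BETA_FEATURE,
    }
    return scn


def _build_rank(seed: int, n_fixations: int | None) -> ScenarioData:
    scn, rng = _base("rank", seed)
    _planted_pink(scn, rng)
    pct = _uniform_pct(scn.feature_maps)

    def strong(x: np.ndarray) -> np.ndarray:
        return 0.2 + 4.0 * (x / 100.0) ** 2

    observer = ObserverModel(
        saliency=None,
        bias_sigma_deg=None,
        fixations_per_trial=8,
        rank_schedule={2: strong, 3: strong, 4: strong},
    )
    scn.fixations = _sample_all(scn, observer, n_fixations or N_FIXATIONS, rng, pct)
    scn.truth = {"active_ranks": [2, 3, 4]}
    return scn


def _build_duration(seed: int, n_fixations: int | None) -> ScenarioData:
    scn, rng, f_pct, i_pct = _interest_like("duration", seed)
    observer = ObserverModel(
        saliency=None,
        bias_sigma_deg=None,
        duration_w_interest=DURATION_W_INTEREST,
        duration_w_feature=DURATION_W_FEATURE,
        duration_sigma_ms=DURATION_SIGMA,
    )
    scn.fixations = _sample_all(
        scn, observer, n_fixations or 100_000, rng, f_pct, interest_pct=i_pct
    )
    scn.truth = {
        "w_interest": DURATION_W_INTEREST,
        "w_feature": DURATION_W_FEATURE,
        "sigma": DURATION_SIGMA,
        "ratio": DURATION_W_INTEREST / DURATION_W_FEATURE,
    }
    return scn


# ---------------------------------------------------------------------------
# pipeline runners


def battery_feature_dkls(
    scn: ScenarioData, seed: int = 0
) -> dict[str, SaliencyResult]:
    """Run the 15-map battery on the scenario's stimuli and score each map."""
    if not scn.images:
        raise ValueError("scenario has no RGB stimuli; build one with with_images")
    batteries = {
        img: compute_battery(rgb, scn.geometry) for img, rgb in scn.images.items()
    }
    names = next(iter(batteries.values())).keys()
    out = {}
    for name in names:
        maps = {img: batteries[img][name].values for img in batteries}
        out[name] = feature_dkl(maps, scn.fixations, scn.geometry, feature=name, seed=seed)
    return out


def saliency_flatness_z(result: SaliencyResult) -> np.ndarray:
    """Per-bin z of the actual distribution against the control (null).

    Under the null each bin count is Binomial(n, q_b), so
    z_b = (p_b - q_b) / sqrt(q_b (1 - q_b) / n).
    """
    fn = result.function
    p, q, n = fn.actual.ravel(), fn.control.ravel(), fn.n_actual
    se = np.sqrt(q * (1.0 - q) / n)
    return (p - q) / se


def upper_bound_margin(
    scn: ScenarioData, feature_results: dict[str, SaliencyResult], seed: int = 0
) -> dict:
    """Upper-bound D_KL and its margin over every battery/planted feature."""
    ub = upper_bound_dkl(scn.fixations, scn.geometry, seed=seed)
    best = max(r.dkl.value_bits for r in feature_results.values())
    return {
        "upper_bound_bits": ub.dkl.value_bits,
        "best_feature_bits": best,
        "margin_bits": ub.dkl.value_bits - best,
        "all_below": all(
            r.dkl.value_bits <= ub.dkl.value_bits for r in feature_results.values()
        ),
    }


# ---------------------------------------------------------------------------
# end-to-end reports


def _report_null(scn: ScenarioData, seed: int) -> dict:
    results = battery_feature_dkls(scn, seed)
    ub = upper_bound_margin(scn, results, seed)
    dkls = {name: r.dkl.value_bits for name, r in results.items()}
    all_z = np.concatenate([saliency_flatness_z(r) for r in results.values()])
    return {
        "max_feature_dkl_bits": max(dkls.values()),
        "max_flatness_z": float(np.abs(all_z).max()),
        "n_bins_beyond_3se": int((np.abs(all_z) > 3).sum()),
        "n_bins_total": int(all_z.size),
        "feature_dkls": dkls,
        "upper_bound": ub,
    }


def _report_linear(scn: ScenarioData, seed: int) -> dict:
    battery = battery_feature_dkls(scn, seed)
    res = feature_dkl(scn.feature_maps, scn.fixations, scn.geometry, seed=seed)
    ub = upper_bound_margin(scn, battery, seed)
    fn = res.function
    centers = fn.bin_centers
    r2 = float(np.corrcoef(centers, fn.values)[0, 1] ** 2)

    fix = scn.fixations.loc[scn.fixations["rank"] > 1]
    pcts = np.concatenate(
        [
            fixation_percentiles(histogram_equalize(scn.feature_maps[img]).values, df)
            for img, df in fix.groupby("image")
        ]
    )
    frac = float(np.mean(pcts > 50.0))

    # duplicated-feature joint analysis: additivity must come out at 50%
    res_1d8 = feature_dkl(
        scn.feature_maps, scn.fixations, scn.geometry, n_bins=8, seed=seed
    )
    res_dup = feature_dkl(
        scn.feature_maps, scn.fixations, scn.geometry,
        maps2=scn.feature_maps, seed=seed,
    )
    add = additivity_index(
        res_1d8.dkl.value_bits, res_1d8.dkl.value_bits, res_dup.dkl.value_bits
    )
    return {
        "saliency_vs_planted_r2": r2,
        "fraction_above_median": frac,
        "dkl_bits": res.dkl.value_bits,
        "duplicate_additivity_percent": add.percent_of_additive,
        "upper_bound": ub,
    }


def _report_central_bias(scn: ScenarioData, seed: int) -> dict:
    corrected = feature_dkl(
        scn.feature_maps, scn.fixations, scn.geometry,
        correct_central_bias=True, seed=seed,
    )
    uncorrected = feature_dkl(
        scn.feature_maps, scn.fixations, scn.geometry,
        correct_central_bias=False, seed=seed,
    )
    battery = battery_feature_dkls(scn, seed)
    ub = upper_bound_margin(scn, battery, seed)
    return {
        "corrected_dkl_bits": corrected.dkl.value_bits,
        "uncorrected_dkl_bits": uncorrected.dkl.value_bits,
        "rejected": corrected.dkl.value_bits < uncorrected.dkl.value_bits,
        "upper_bound": ub,
    }


def _report_interest(scn: ScenarioData, seed: int) -> dict:
    joint = feature_dkl(
        scn.interest_maps, scn.fixations, scn.geometry,
        maps2=scn.feature_maps, feature="interest", seed=seed,
    )
    interest_1d = feature_dkl(
        scn.interest_maps, scn.fixations, scn.geometry, feature="interest", seed=seed
    )
    feature_1d = feature_dkl(
        scn.feature_maps, scn.fixations, scn.geometry, feature="feature", seed=seed
    )
    fits = fit_interest_feature_model(joint.function, exponent_grid=(1,))
    fit = fits[1]
    ratio = fit.coefficients["alpha"] / fit.coefficients["beta"]
    quarters = quarter_saliency(joint.function, interest_axis=0)

    # noise-free reference: the same fit on the analytically planted surface
    centers = (np.arange(8) + 0.5) / 8.0
    i_grid, f_grid = np.meshgrid(centers, centers, indexing="ij")
    planted = planted_interest_surface(i_grid, f_grid)
    exact_fit = fit_interest_feature_model(planted, exponent_grid=(1,))[1]
    exact_ratio = exact_fit.coefficients["alpha"] / exact_fit.coefficients["beta"]
    planted_quarters = quarter_saliency(planted, interest_axis=0)

    ub = upper_bound_margin(
        scn, {"interest": interest_1d, "feature": feature_1d}, seed
    )
    return {
        "ratio": ratio,
        "exact_ratio": exact_ratio,
        "planted_ratio": scn.truth["ratio"],
        "quarters": quarters.as_array().tolist(),
        "planted_quarters": planted_quarters.as_array().tolist(),
        "interest_dkl_bits": interest_1d.dkl.value_bits,
        "feature_dkl_bits": feature_1d.dkl.value_bits,
        "joint_dkl_bits": joint.dkl.value_bits,
        "r_squared": fit.r_squared,
        "upper_bound": ub,
    }


def _report_rank(scn: ScenarioData, seed: int) -> dict:
    tc = dkl_time_course(
        scn.feature_maps, scn.fixations, scn.geometry, seed=seed
    )
    pooled = feature_dkl(scn.feature_maps, scn.fixations, scn.geometry, seed=seed)
    ub = upper_bound_dkl(scn.fixations, scn.geometry, seed=seed)
    return {
        "planted_pooled_dkl_bits": pooled.dkl.value_bits,
        "upper_bound_bits": ub.dkl.value_bits,
        "ranks": tc.ranks,
        "dkl_bits": tc.dkl_bits,
        "normalized": tc.normalized.tolist(),
        "peak_rank": tc.peak_rank,
    }


def _report_duration(scn: ScenarioData, seed: int) -> dict:
    fix = zscore_durations(scn.fixations)
    # recompute percentiles through the analysis pipeline
    f_pct = _uniform_pct(scn.feature_maps)
    i_pct = _uniform_pct(scn.interest_maps)
    parts = []
    for img, df in fix.groupby("image"):
        df = df.copy()
        df["feature_pct"] = fixation_percentiles(f_pct[img], df)
        df["interest_pct"] = fixation_percentiles(i_pct[img], df)
        parts.append(df)
    fix = pd.concat(parts, ignore_index=True)
    surf = duration_surface(fix)
    interest_1d = feature_dkl(
        scn.interest_maps, scn.fixations, scn.geometry, feature="interest", seed=seed
    )
    feature_1d = feature_dkl(
        scn.feature_maps, scn.fixations, scn.geometry, feature="feature", seed=seed
    )
    ub = upper_bound_margin(
        scn, {"interest": interest_1d, "feature": feature_1d}, seed
    )
    return {
        "w_interest": surf.w_interest_native,
        "w_feature": surf.w_feature_native,
        "ratio": surf.ratio,
        "planted_w_interest": scn.truth["w_interest"],
        "planted_w_feature": scn.truth["w_feature"],
        "r_squared": surf.r_squared,
        "upper_bound": ub,
    }


_REPORTERS = {
    "null": _report_null,
    "linear": _report_linear,
    "central_bias": _report_central_bias,
    "interest": _report_interest,
    "rank": _report_rank,
    "duration": _report_duration,
}


def end_to_end_recovery(name: str, seed: int, n_fixations: int | None = None) -> dict:
    """Build a scenario, run the pipeline and report recovered vs planted."""
    scn = build_scenario(name, seed, n_fixations)
    report = _REPORTERS[name](scn, seed)
    report["scenario"] = name
    report["seed"] = seed
    return report
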