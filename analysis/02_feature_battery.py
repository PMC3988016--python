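"""Compute the 15-map feature battery on a pink-noise stimulus.

Converts the stimulus to the cone-opponent representation, computes the
full battery (intensity, contrast, intrinsic-dimensionality and
phase-symmetry maps) and the percentile (equalized) versions, and
tabulates summary statistics per map.  Also demonstrates the
exploration-entropy analysis on a synthetic study.
"""

from pathlib import Path

import pandas as pd

from gazecond.equalize import histogram_equalize
from gazecond.features import compute_battery
from gazecond.gaze import exploration_summary
from gazecond.scenarios import build_scenario, default_geometry
from gazecond.synth import PinkNoiseSpec, make_pink_noise

SEED = 1
results = Path(__file__).resolve().parents[1] / "results"
results.mkdir(exist_ok=True)

geometry = default_geometry()
img = make_pink_noise(PinkNoiseSpec(shape=geometry.image_size, seed=SEED))
battery = compute_battery(img, geometry)

rows = []
for name, fm in battery.items():
    pct = histogram_equalize(fm.values).values
    rows.append(
        {
            "feature": name,
            "window_deg": fm.window_deg,
            "min": fm.values.min(),
            "mean": fm.values.mean(),
            "max": fm.values.max(),
            "std": fm.values.std(),
            "pct_mean": pct.mean(),  # ~50 by construction
        }
    )
table = pd.DataFrame(rows)
table.to_csv(results / "feature_battery_stats.csv", index=False, float_format="%.6g")
print(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))

# exploration entropies: image-specific hotspots vs pooled category behavior
scn = build_scenario("interest", SEED)
ent = exploration_summary(scn.fixations, scn.geometry)
ent.to_csv(results / "exploration_entropy.csv", index=False, float_format="%.6g")
print("\nExploration entropy (interest-driven study):")
print(ent.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print("Category-level entropy exceeds the image-specific mean when "
      "fixations cluster at image-specific loci.")
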