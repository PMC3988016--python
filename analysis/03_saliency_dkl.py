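"""Saliency functions and D_KL scores: calibration and recovery.

Three questions, answered on synthetic studies:
  1. Does the estimator stay flat (D_KL ~ 0) when fixations ignore the
     image? (null calibration, full 15-map battery)
  2. Does it recover a planted linear saliency g(X) = X?
  3. Does control-weighted equalization reject a pure central-bias
     confound that the uncorrected estimator falls for?
"""

import json
from pathlib import Path

import pandas as pd

from gazecond.scenarios import (
    battery_feature_dkls,
    build_scenario,
    end_to_end_recovery,
)

SEED = 1
results = Path(__file__).resolve().parents[1] / "results"
results.mkdir(exist_ok=True)

# 1. null calibration across the whole battery
scn = build_scenario("null", SEED)
battery = battery_feature_dkls(scn, SEED)
rows = [
    {
        "feature": name,
        "dkl_bits": res.dkl.value_bits,
        "ci_low": res.dkl.ci_low,
        "ci_high": res.dkl.ci_high,
    }
    for name, res in battery.items()
]
table = pd.DataFrame(rows).sort_values("dkl_bits", ascending=False)
table.to_csv(results / "null_battery_dkl.csv", index=False, float_format="%.6g")
print("Null study (no feature preference): all battery D_KL values")
print(table.to_string(index=False, float_format=lambda v: f"{v:.5f}"))
print(f"max = {table['dkl_bits'].max():.5f} bits -> estimator is calibrated\n")

# 2 + 3. planted-saliency recovery and central-bias rejection
linear = end_to_end_recovery("linear", SEED)
central = end_to_end_recovery("central_bias", SEED)
summary = {
    "linear_r2": linear["saliency_vs_planted_r2"],
    "fraction_above_median": linear["fraction_above_median"],
    "linear_dkl_bits": linear["dkl_bits"],
    "central_corrected_dkl_bits": central["corrected_dkl_bits"],
    "central_uncorrected_dkl_bits": central["uncorrected_dkl_bits"],
}
(results / "saliency_recovery.json").write_text(json.dumps(summary, indent=2) + "\n")
print(f"Planted g(X)=X: saliency-vs-truth r^2 = {summary['linear_r2']:.3f}, "
      f"P(pct > 50) = {summary['fraction_above_median']:.3f} (theory 0.75)")
print(f"Central-bias confound: corrected {summary['central_corrected_dkl_bits']:.4f} bits "
      f"vs uncorrected {summary['central_uncorrected_dkl_bits']:.4f} bits -> "
      "the control weighting removes the spurious correlation")
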