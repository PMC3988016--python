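"""Behavioral relevance vs image content: the interest-dominated study.

Clicks from an independent synthetic cohort define interestingness maps;
fixations are sampled from a planted saliency alpha*I + beta*F with
alpha/beta = 4.57.  The pipeline builds the joint (interest x feature)
saliency function, fits the weighted model over an exponent grid, and
decomposes the surface into quarters.
"""

import json
from pathlib import Path

from gazecond.integration import fit_interest_feature_model
from gazecond.saliency import feature_dkl
from gazecond.scenarios import build_scenario, end_to_end_recovery

SEED = 1
results = Path(__file__).resolve().parents[1] / "results"
results.mkdir(exist_ok=True)

report = end_to_end_recovery("interest", SEED)

# exponent grid on the recovered joint surface
scn = build_scenario("interest", SEED)
joint = feature_dkl(
    scn.interest_maps, scn.fixations, scn.geometry,
    maps2=scn.feature_maps, feature="interest", seed=SEED,
)
fits = fit_interest_feature_model(joint.function)
report["r2_by_exponent"] = {str(x): f.r_squared for x, f in fits.items()}

(results / "interest_model.json").write_text(json.dumps(report, indent=2) + "\n")

print(f"Interest D_KL {report['interest_dkl_bits']:.3f} bits vs best feature "
      f"{report['feature_dkl_bits']:.3f} bits -> behavioral relevance dominates")
print(f"Recovered alpha/beta = {report['ratio']:.2f} (planted {report['planted_ratio']:.2f}; "
      f"exact-surface fit {report['exact_ratio']:.2f})")
print("Quarter shares (weak/weak, strongF/weakI, weakF/strongI, strong/strong):")
print("  recovered:", [f"{q:.1f}%" for q in report["quarters"]])
print("  planted:  ", [f"{q:.1f}%" for q in report["planted_quarters"]])
print("r^2 by exponent:", {k: round(v, 3) for k, v in report["r2_by_exponent"].items()})
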