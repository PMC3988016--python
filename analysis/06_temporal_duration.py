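"""Temporal evolution of saliency and the fixation-duration model.

(a) A saliency schedule planted only for fixation ranks 2-4 must appear
as a peak in the per-rank D_KL time course and collapse afterwards,
with rank-matched controls absorbing rank-dependent spatial bias.
(b) A planted linear duration model (w_I, w_F) = (0.1, 0.03) ms per
percentile must be recovered from z-scored durations.
"""

import json
from pathlib import Path

import pandas as pd

from gazecond.scenarios import end_to_end_recovery

SEED = 1
results = Path(__file__).resolve().parents[1] / "results"
results.mkdir(exist_ok=True)

rank = end_to_end_recovery("rank", SEED)
tc = pd.DataFrame(
    {
        "rank": rank["ranks"],
        "dkl_bits": rank["dkl_bits"],
        "normalized": rank["normalized"],
    }
)
tc.to_csv(results / "rank_timecourse.csv", index=False, float_format="%.6g")
print("Per-rank D_KL time course (planted schedule: ranks 2-4):")
print(tc.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(f"peak at rank {rank['peak_rank']}, final/peak = {rank['normalized'][-1]:.3f}\n")

duration = end_to_end_recovery("duration", SEED)
(results / "duration_model.json").write_text(json.dumps(duration, indent=2) + "\n")
print(f"Duration weights (ms per percentile): interest "
      f"{duration['w_interest']:.4f} (planted {duration['planted_w_interest']}), "
      f"feature {duration['w_feature']:.4f} (planted {duration['planted_w_feature']})")
print(f"ratio = {duration['ratio']:.2f}; per-subject fit r^2 = {duration['r_squared']:.3f}")
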