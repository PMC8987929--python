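"""Power Doppler formation: how the SVD clutter cut trades tissue rejection
against blood-signal preservation.

Sweeps the rank cut on the synthetic compound-frame stack (200 frames at
500 Hz, tissue clutter 40 dB above blood) and reports the correlation of the
resulting Power Doppler image with the generator's true blood-power map.
"""

import numpy as np
import pandas as pd

from common import CONFIG, RESULTS, RUN_DIR, ensure_dirs
from fuskit import io as fio
from fuskit.core import CompoundFrameStack
from fuskit.doppler import ClutterFilterConfig, power_doppler, svd_clutter_filter

ensure_dirs()
frames = np.load(RUN_DIR / "simulate" / "compound_stack.npy")
truth = np.load(RUN_DIR / "simulate" / "blood_power_truth.npy")
mask = fio.load_movie_nifti(RUN_DIR / "simulate" / "baseline.nii").mask
stack = CompoundFrameStack(frames=frames, frame_rate=CONFIG.compound_rate)

rows = []
for rank_cut in (0, 1, 2, 3, 5, 10, 20, 40):
    img = power_doppler(svd_clutter_filter(stack, ClutterFilterConfig(rank_cut)))
    r = float(np.corrcoef(img[mask], truth[mask])[0, 1])
    rows.append({"rank_cut": rank_cut, "corr_with_true_blood_power": r})
table = pd.DataFrame(rows)
table.to_csv(RESULTS / "doppler_rank_sweep.tsv", sep="\t", index=False)
print(table.to_string(index=False))
best = table.loc[table.corr_with_true_blood_power.idxmax()]
print(
    f"\nremoving the leading {int(best.rank_cut)} components recovers the blood map "
    f"best here (r = {best.corr_with_true_blood_power:.3f}); rank 0 leaves tissue "
    "clutter dominating, large cuts start discarding blood signal."
)
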