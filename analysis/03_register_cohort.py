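"""Groupwise registration exercise: recover injected inter-acquisition motion.

Builds the iterative linear template from eight copies of the phantom under
known rigid misalignments (<= 3 px translation, <= 2 deg rotation) and
reports per-acquisition recovery errors, measured after removing the
cohort-mean offset that defines the common space.
"""

import numpy as np
import pandas as pd

from common import RESULTS, ensure_dirs
from fuskit.registration import build_template
from fuskit.synthetic import default_phantom_spec, generate_misaligned_cohort, generate_phantom

ensure_dirs()
phantom = generate_phantom(default_phantom_spec((64, 64), vessel_density=0.1), seed=7)
images, truths = generate_misaligned_cohort(phantom, n_acquisitions=8, seed=8)
result = build_template(images)

est = np.array([tf.content_shift for tf in result.transforms])
rot = np.array([tf.rotation_deg for tf in result.transforms])
inj = np.array([[t["dy"], t["dx"]] for t in truths])
inj_rot = np.array([t["rotation_deg"] for t in truths])
resid = (est - est.mean(axis=0)) - (inj - inj.mean(axis=0))

table = pd.DataFrame(
    {
        "acquisition": range(len(images)),
        "injected_dy": inj[:, 0],
        "injected_dx": inj[:, 1],
        "injected_rot_deg": inj_rot,
        "recovered_dy": est[:, 0],
        "recovered_dx": est[:, 1],
        "recovered_rot_deg": rot,
        "translation_error_px": np.hypot(resid[:, 0], resid[:, 1]),
    }
)
table.to_csv(RESULTS / "registration_recovery.tsv", sep="\t", index=False)
print(table.round(3).to_string(index=False))
print(
    f"\ntemplate converged in {len(result.convergence_history)} iterations "
    f"(history: {[f'{h:.2e}' for h in result.convergence_history]}); "
    f"max translation error {table.translation_error_px.max():.3f} px."
)
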