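"""Group statistics across the three analysis families.

Two-way ANOVA (strain x region, Type-II) per family, per-ROI follow-up
contrasts, and Benjamini-Hochberg FDR at q = 0.1, as used for mean %CBV
changes, Fisher-Z connectivity and ReHo Z values.
"""

import shutil

import pandas as pd

from common import CONFIG, RESULTS, RUN_DIR, ensure_dirs
from fuskit.pipeline import run_pipeline

ensure_dirs()
run_pipeline(CONFIG, ["stats"], RUN_DIR)

for family in ("visual_pct", "connectivity_z", "reho_z"):
    comp = pd.read_csv(RUN_DIR / "stats" / f"comparisons_{family}.tsv", sep="\t")
    shutil.copy(RUN_DIR / "stats" / f"comparisons_{family}.tsv",
                RESULTS / f"comparisons_{family}.tsv")
    shutil.copy(RUN_DIR / "stats" / f"anova_{family}.tsv", RESULTS / f"anova_{family}.tsv")
    sig = comp[comp.significant]
    print(f"\n{family}: {len(sig)}/{len(comp)} ROI(s) significant at FDR q={CONFIG.fdr_q}")
    if len(sig):
        print(sig[["roi", "mean_a", "mean_b", "p", "q"]].round(4).to_string(index=False))
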