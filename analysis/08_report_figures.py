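"""Render the figure bundle for the simulated cohort.

Panels: ROI time-courses with SEM bands and stimulation-period shading, mean
%CBV bars, connectivity heatmaps, seed-based maps, ReHo/fALFF maps, Tmax and
activation maps.  Figures are written under scratch/ (binary artifacts); this
driver lists what was produced.
"""

from common import CONFIG, RUN_DIR, ensure_dirs
from fuskit.pipeline import run_pipeline

ensure_dirs()
manifest = run_pipeline(CONFIG, ["report"], RUN_DIR)
for entry in manifest["stages"]["report"]["outputs"]:
    print("wrote", RUN_DIR / entry["path"])
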