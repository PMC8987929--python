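"""Shared configuration for the numbered analysis drivers.

The cohort mirrors the study design at desk scale: two strains (SHR model
vs WKY control, three animals each here), the full 405 s visual-stimulation
protocol at 0.4 s frames, and 20-minute two-slice resting runs at 2.8 s per
slice.  Heavy per-stage products (movies, maps, figures) live under
``scratch/``; the summary tables each driver reports land in ``results/``.
"""

from pathlib import Path

from fuskit.pipeline import RunConfig

_ROOT = Path(__file__).resolve().parent.parent
RUN_DIR = _ROOT / "scratch" / "analysis_run"
RESULTS = _ROOT / "results"

CONFIG = RunConfig(seed=7, grid_shape=(48, 48), n_per_group=3, inject_motion=False)


def ensure_dirs() -> None:
    RUN_DIR.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
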