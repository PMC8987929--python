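"""End-to-end orchestration: simulate -> doppler -> register -> analyze ->
stats -> report, with a JSON run manifest and checksummed outputs.

Each stage writes its products under ``<out_dir>/<stage>/`` and records them
(with SHA-256 checksums) in ``manifest.json``.  Stages validate that their
upstream products exist on disk and fail explicitly — they never silently
recompute a deleted intermediate.  With a fixed seed a rerun is byte-identical
wherever the computation is deterministic.

The ``paper2022`` preset carries the study constants: 30 s initial rest +
5 x (30 s flicker + 45 s rest) at 0.4 s frames; resting runs of 2.8 s per
slice with a 1.4 s interleave and the first minute discarded; band presets
0.0025/0.0375 Hz (stim), 0.00067-0.13 Hz (fc), 0.01-0.08 Hz (ReHo/fALFF);
FDR q = 0.1; 0.3 mm FWHM smoothing; pixel threshold p < 0.001.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from . import __version__
from .connectivity import (
    correlation_matrix,
    extract_roi_timecourses,
    group_mean_matrix,
    seed_map,
    sync_slices,
)
from .core import PowerDopplerMovie, ROITimeCourse
from .doppler import ClutterFilterConfig, default_rank_cut, power_doppler, svd_clutter_filter
from .filters import BAND_PRESETS, temporal_filter
from .localcon import SpectralConfig, falff_map, group_reho_stat_map, reho_map, zscore_map
from .registration import apply_transform, build_template, denoise_for_registration, linear_register
from .stats import fdr_correct, per_roi_group_tests, two_way_anova
from .stimulus import activation_map, block_average, build_protocol, percent_cbv, tmax_map
from .synthetic import (
    GroundTruth,
    default_phantom_spec,
    generate_compound_stack,
    generate_misaligned_cohort,
    generate_phantom,
    generate_resting_movie,
    generate_stimulation_movie,
)

__all__ = ["RunConfig", "StageError", "STAGES", "run_pipeline", "report"]

STAGES = ["simulate", "doppler", "register", "stimresp", "fc", "reho", "falff", "stats", "report"]

_DEPS = {
    "simulate": [],
    "doppler": ["simulate"],
    "register": ["simulate"],
    "stimresp": ["simulate"],
    "fc": ["simulate"],
    "reho": ["simulate"],
    "falff": ["simulate"],
    "stats": ["stimresp", "fc", "reho"],
    "report": ["stats"],
}


class StageError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the ``paper2022`` study constants
    with a desk-scale synthetic cohort."""

    seed: int = 0
    grid_shape: tuple[int, int] = (48, 48)
    pixel_size: float = 0.1
    vessel_density: float = 0.1
    n_per_group: int = 3
    groups: tuple[str, str] = ("SHR", "WKY")
    # stimulation protocol (s); one Power Doppler image every 0.4 s, 405 s total
    initial_rest: float = 30.0
    stim_duration: float = 30.0
    post_rest: float = 45.0
    n_blocks: int = 5
    stim_dt: float = 0.4
    # programmed responses per group: region -> (amplitude %CBV, shape)
    responses: dict = field(
        default_factory=lambda: {
            "SHR": {"V1": (3.5, "initial-peak"), "V2ML": (3.6, "initial-peak"), "SC": (1.9, "late-peak")},
            "WKY": {"V1": (2.0, "sustained"), "V2ML": (2.0, "sustained"), "SC": (1.5, "sustained")},
        }
    )
    # resting-state: 2.8 s per slice, 1.4 s interleave, first minute discarded
    rest_n_frames: int = 407
    rest_dt: float = 2.8
    interleave_offset: float = 1.4
    discard_initial: float = 60.0
    rest_correlations: dict = field(
        default_factory=lambda: {
            "SHR": {("V1", "V2ML"): 0.6, ("SC", "Pt"): 0.2},
            "WKY": {("V1", "V2ML"): 0.6, ("SC", "Pt"): 0.6},
        }
    )
    noise_sd: float = 0.01
    fluct_amp: float = 0.02
    # compound-frame demo stack: 200 frames at 500 Hz -> one image per 0.4 s
    compound_frames: int = 200
    compound_rate: float = 500.0
    # synthetic tissue clutter is low-rank by construction; a small margin
    # above it suffices (real data would need the larger generic default)
    rank_cut: int = 5
    # registration exercise
    inject_motion: bool = False
    max_translation: float = 3.0
    max_rotation: float = 2.0
    # spectral / stats settings
    welch_window: int = 64
    fdr_q: float = 0.1
    fwhm_mm: float = 0.3
    p_pixel: float = 0.001
    seed_roi: str = "Pt"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            cur = getattr(cfg, k)
            if isinstance(cur, tuple):
                v = tuple(v)
            setattr(cfg, k, v)
        # YAML mappings cannot key on tuples: accept "A|B" pair syntax
        fixed = {}
        for g, pairs in cfg.rest_correlations.items():
            fixed[g] = {
                (tuple(k.split("|")) if isinstance(k, str) else tuple(k)): float(r)
                for k, r in pairs.items()
            }
        cfg.rest_correlations = fixed
        fixed_r = {}
        for g, resp in cfg.responses.items():
            fixed_r[g] = {reg: (float(a), str(s)) for reg, (a, s) in resp.items()}
        cfg.responses = fixed_r
        return cfg

    def protocol(self):
        return build_protocol(
            self.initial_rest, self.stim_duration, self.post_rest, self.n_blocks, self.stim_dt
        )

    def animals(self) -> list[tuple[str, str]]:
        return [(g, f"{g}_{i}") for g in self.groups for i in range(self.n_per_group)]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Run:
    """Bookkeeping for one pipeline invocation."""

    def __init__(self, config: RunConfig, out_dir: Path):
        self.config = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {"version": __version__, "seed": config.seed, "stages": {}}

    def stage_dir(self, stage: str) -> Path:
        d = self.out / stage
        d.mkdir(exist_ok=True)
        return d

    def record(self, stage: str, paths: list[Path]) -> None:
        self.manifest["stages"][stage] = {
            "outputs": [
                {"path": str(p.relative_to(self.out)), "sha256": _sha256(p)}
                for p in sorted(paths)
            ]
        }
        self.manifest["config"] = _jsonable(asdict(self.config))
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")

    def require(self, stage: str, needed: list[str]) -> None:
        for dep in needed:
            entry = self.manifest["stages"].get(dep)
            if entry is None:
                raise StageError(f"stage {stage!r} requires {dep!r}, which has not been run")
            for rec in entry["outputs"]:
                if not (self.out / rec["path"]).exists():
                    raise StageError(
                        f"stage {stage!r} requires {dep!r} product {rec['path']}, "
                        "which is missing on disk"
                    )

    def product(self, stage: str, name: str) -> Path:
        return self.out / stage / name


def _jsonable(obj):
    if isinstance(obj, dict):
        return {
            (k if isinstance(k, str) else "|".join(map(str, k))): _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return float(obj)
    return obj


def _seed_for(config: RunConfig, *tags: str) -> int:
    h = hashlib.sha256(("/".join(tags) + f"#{config.seed}").encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(run: _Run) -> list[Path]:
    cfg = run.config
    d = run.stage_dir("simulate")
    spec = default_phantom_spec(
        tuple(cfg.grid_shape), pixel_size=cfg.pixel_size, vessel_density=cfg.vessel_density
    )
    phantom = generate_phantom(spec, seed=_seed_for(cfg, "phantom"))
    paths = []
    fio.save_atlas(phantom.atlas, d / "atlas.nii", d / "atlas.tsv")
    paths += [d / "atlas.nii", d / "atlas.tsv"]
    base = PowerDopplerMovie(phantom.baseline[None], dt=1.0, mask=phantom.mask,
                             pixel_size=cfg.pixel_size)
    paths.append(fio.save_movie_nifti(base, d / "baseline.nii"))
    paths += [d / "baseline.json", d / "baseline_mask.nii"]
    protocol = cfg.protocol()
    gt_all = {}
    for group, animal in cfg.animals():
        truth = GroundTruth(
            programmed_response=cfg.responses[group],
            noise_sd=cfg.noise_sd,
            fluct_amp=cfg.fluct_amp,
            seed=_seed_for(cfg, "stim", animal),
        )
        movie, gt = generate_stimulation_movie(phantom, truth, protocol)
        if cfg.inject_motion:
            rng = np.random.default_rng(_seed_for(cfg, "motion", animal))
            from .synthetic import inject_motion as _inj

            dy, dx = rng.uniform(-cfg.max_translation, cfg.max_translation, 2)
            rot = rng.uniform(-cfg.max_rotation, cfg.max_rotation)
            movie = movie.with_data(_inj(movie.data, (dy, dx), rot))
            gt["_motion"] = {"dy": dy, "dx": dx, "rotation_deg": rot}
        p = fio.save_movie_nifti(movie, d / f"stim_{animal}.nii")
        paths += [p, d / f"stim_{animal}.json", d / f"stim_{animal}_mask.nii"]
        gt_all[f"stim_{animal}"] = gt
        for slice_id, t0 in ((1, 0.0), (2, cfg.interleave_offset)):
            truth_r = GroundTruth(
                programmed_correlations=cfg.rest_correlations[group],
                noise_sd=cfg.noise_sd,
                fluct_amp=cfg.fluct_amp,
                seed=_seed_for(cfg, "rest", animal, str(slice_id)),
            )
            rmovie = generate_resting_movie(
                phantom, truth_r, n_frames=cfg.rest_n_frames, dt=cfg.rest_dt,
                slice_id=slice_id, t0=t0,
            )
            p = fio.save_movie_nifti(rmovie, d / f"rest_{animal}_s{slice_id}.nii")
            paths += [p, d / f"rest_{animal}_s{slice_id}.json",
                      d / f"rest_{animal}_s{slice_id}_mask.nii"]
            gt_all[f"rest_{animal}_s{slice_id}"] = _jsonable(
                {"correlations": cfg.rest_correlations[group]}
            )
    stack, blood_power = generate_compound_stack(
        phantom, cfg.compound_frames, cfg.compound_rate, seed=_seed_for(cfg, "compound")
    )
    np.save(d / "compound_stack.npy", stack.frames)
    np.save(d / "blood_power_truth.npy", blood_power)
    paths += [d / "compound_stack.npy", d / "blood_power_truth.npy"]
    paths.append(fio.save_json(_jsonable(gt_all), d / "ground_truth.json"))
    return paths


def _stage_doppler(run: _Run) -> list[Path]:
    cfg = run.config
    d = run.stage_dir("doppler")
    frames = np.load(run.product("simulate", "compound_stack.npy"))
    from .core import CompoundFrameStack

    stack = CompoundFrameStack(frames=frames, frame_rate=cfg.compound_rate)
    rank_cut = cfg.rank_cut if cfg.rank_cut else default_rank_cut(stack.n_frames)
    filtered = svd_clutter_filter(stack, ClutterFilterConfig(rank_cut))
    img = power_doppler(filtered)
    truth = np.load(run.product("simulate", "blood_power_truth.npy"))
    mask = np.asarray(
        fio.load_movie_nifti(run.product("simulate", "baseline.nii")).mask
    )
    r = float(np.corrcoef(img[mask], truth[mask])[0, 1])
    np.save(d / "power_doppler.npy", img)
    fio.save_json({"rank_cut": rank_cut, "corr_with_true_blood_power": r},
                  d / "doppler_summary.json")
    return [d / "power_doppler.npy", d / "doppler_summary.json"]


def _registered_movies(run: _Run, names: list[str]) -> dict[str, PowerDopplerMovie]:
    """Load movies, applying the register stage's transforms when present."""
    d = run.out / "register"
    out = {}
    for n in names:
        movie = fio.load_movie_nifti(run.product("simulate", f"{n}.nii"))
        tf_path = d / f"transform_{n}.json"
        if tf_path.exists():
            from .registration import LinearTransform

            movie = apply_transform(movie, LinearTransform.from_json(tf_path.read_text()))
        out[n] = movie
    return out


def _stage_register(run: _Run) -> list[Path]:
    cfg = run.config
    d = run.stage_dir("register")
    names = [f"stim_{a}" for _, a in cfg.animals()]
    movies = {n: fio.load_movie_nifti(run.product("simulate", f"{n}.nii")) for n in names}
    denoised = {n: denoise_for_registration(m, k=min(8, m.n_frames)) for n, m in movies.items()}
    result = build_template(list(denoised.values()))
    paths = []
    for n, tf in zip(denoised, result.transforms):
        p = d / f"transform_{n}.json"
        p.write_text(tf.to_json())
        paths.append(p)
    np.save(d / "template.npy", result.template)
    fio.save_json(
        {"convergence_history": result.convergence_history, "converged": result.converged},
        d / "template_summary.json",
    )
    return paths + [d / "template.npy", d / "template_summary.json"]


def _stage_stimresp(run: _Run) -> list[Path]:
    cfg = run.config
    d = run.stage_dir("stimresp")
    protocol = cfg.protocol()
    atlas = fio.load_atlas(run.product("simulate", "atlas.nii"), run.product("simulate", "atlas.tsv"))
    names = [f"stim_{a}" for _, a in cfg.animals()]
    movies = _registered_movies(run, names)
    band = BAND_PRESETS["stim"]
    rows, tc_rows, pct_movies = [], [], []
    for (group, animal), name in zip(cfg.animals(), names):
        movie = movies[name]
        # smooth with the stim-band low-pass; the %CBV normalization below
        # supplies the baseline removal the 0.0025 Hz high-pass would do
        smoothed = temporal_filter(
            movie.data, movie.dt,
            type(band)(lowpass_cut=band.lowpass_cut, lowpass_kind=band.lowpass_kind),
        )
        pct = percent_cbv(smoothed, protocol)
        pct_movie = movie.with_data(pct)
        pct_movies.append(pct_movie)
        smask = protocol.stim_mask()
        for tc_name in atlas.region_names:
            roi = atlas.region_mask(tc_name) & movie.mask
            if not roi.any():
                continue
            series = pct[:, roi].mean(axis=1)
            rows.append(
                {
                    "group": group,
                    "animal": animal,
                    "roi": tc_name,
                    "mean_pct": float(series[smask].mean()),
                }
            )
            t_rel, avg = block_average(series, protocol)
            for t, v in zip(t_rel, avg):
                tc_rows.append(
                    {"group": group, "animal": animal, "roi": tc_name,
                     "time": float(t), "pct": float(v)}
                )
    pd.DataFrame(rows).to_csv(d / "roi_mean_pct.tsv", sep="\t", index=False)
    pd.DataFrame(tc_rows).to_csv(d / "roi_timecourses.tsv", sep="\t", index=False)
    paths = [d / "roi_mean_pct.tsv", d / "roi_timecourses.tsv"]
    for group in cfg.groups:
        cohort = [m for (g, _), m in zip(cfg.animals(), pct_movies) if g == group]
        zmap, sig = activation_map(cohort, protocol, p_threshold=cfg.p_pixel)
        paths.append(fio.save_map(zmap, d / f"activation_z_{group}.nii"))
        tmax = tmax_map(
            cohort[0].with_data(np.mean([m.data for m in cohort], axis=0)), protocol
        )
        paths.append(fio.save_map(tmax, d / f"tmax_{group}.nii"))
    return paths


def _rest_timecourses(run: _Run, animal: str, atlas) -> list[ROITimeCourse]:
    cfg = run.config
    tcs = []
    for slice_id in (1, 2):
        movie = fio.load_movie_nifti(run.product("simulate", f"rest_{animal}_s{slice_id}.nii"))
        filt = movie.with_data(temporal_filter(movie.data, movie.dt, BAND_PRESETS["fc"]))
        filt.t0 = movie.t0
        for tc in extract_roi_timecourses(filt, atlas):
            tc.roi_name = f"{tc.roi_name}_s{slice_id}"
            tcs.append(tc)
    # synchronize slice 2 onto slice 1's grid (t0 already encodes the 1.4 s lag)
    ref = next(tc for tc in tcs if tc.slice_id == 1)
    synced2 = [sync_slices(ref, tc, offset=0.0)[1] for tc in tcs if tc.slice_id == 2]
    t_common = synced2[0].timestamps if synced2 else ref.timestamps
    keep = (ref.timestamps >= t_common[0] - 1e-9) & (ref.timestamps <= t_common[-1] + 1e-9)
    synced1 = [
        ROITimeCourse(tc.roi_name, tc.values[keep], t_common, 1)
        for tc in tcs
        if tc.slice_id == 1
    ]
    return synced1 + synced2


def _stage_fc(run: _Run) -> list[Path]:
    cfg = run.config
    d = run.stage_dir("fc")
    atlas = fio.load_atlas(run.product("simulate", "atlas.nii"), run.product("simulate", "atlas.tsv"))
    per_group: dict[str, list] = {g: [] for g in cfg.groups}
    rows = []
    for group, animal in cfg.animals():
        tcs = _rest_timecourses(run, animal, atlas)
        cm = correlation_matrix(tcs, discard_initial=cfg.discard_initial)
        per_group[group].append(cm)
        tab = cm.to_long_table()
        tab.insert(0, "animal", animal)
        tab.insert(0, "group", group)
        rows.append(tab)
    pd.concat(rows, ignore_index=True).to_csv(d / "connectivity_long.tsv", sep="\t", index=False)
    paths = [d / "connectivity_long.tsv"]
    for group, mats in per_group.items():
        gm = group_mean_matrix(mats)
        square = pd.DataFrame(gm.r, index=gm.roi_names, columns=gm.roi_names)
        square.to_csv(d / f"matrix_{group}.tsv", sep="\t")
        paths.append(d / f"matrix_{group}.tsv")
    # seed maps on slice 1, group-averaged
    for group in cfg.groups:
        maps = []
        for g, animal in cfg.animals():
            if g != group:
                continue
            movie = fio.load_movie_nifti(run.product("simulate", f"rest_{animal}_s1.nii"))
            filt = movie.with_data(temporal_filter(movie.data, movie.dt, BAND_PRESETS["fc"]))
            maps.append(seed_map(filt, atlas, cfg.seed_roi, discard_initial=cfg.discard_initial))
        mean_map = maps[0]
        mean_map = type(maps[0])(
            values=np.mean([m.values for m in maps], axis=0),
            mask=np.logical_and.reduce([m.mask for m in maps]),
            units="r",
        )
        paths.append(fio.save_map(mean_map, d / f"seedmap_{cfg.seed_roi}_{group}.nii"))
    return paths


def _reho_falff_stage(run: _Run, which: str) -> list[Path]:
    cfg = run.config
    d = run.stage_dir(which)
    atlas = fio.load_atlas(run.product("simulate", "atlas.nii"), run.product("simulate", "atlas.tsv"))
    scfg = SpectralConfig(welch_window=min(cfg.welch_window, cfg.rest_n_frames // 2))
    rows, paths = [], []
    zmaps: dict[str, list] = {g: [] for g in cfg.groups}
    for group, animal in cfg.animals():
        movie = fio.load_movie_nifti(run.product("simulate", f"rest_{animal}_s1.nii"))
        if which == "reho":
            pmap = reho_map(movie, scfg)
            zmap = zscore_map(pmap)
            zmaps[group].append(zmap)
            paths.append(fio.save_map(zmap, d / f"reho_z_{animal}.nii"))
            values = zmap
        else:
            values = falff_map(movie, band=scfg.band)
            paths.append(fio.save_map(values, d / f"falff_{animal}.nii"))
        for name in atlas.region_names:
            roi = atlas.region_mask(name) & values.mask
            if roi.any():
                rows.append(
                    {"group": group, "animal": animal, "roi": name,
                     "value": float(values.values[roi].mean())}
                )
    pd.DataFrame(rows).to_csv(d / f"{which}_roi.tsv", sep="\t", index=False)
    paths.append(d / f"{which}_roi.tsv")
    if which == "reho":
        for group, maps in zmaps.items():
            if len(maps) >= 3:
                zstat, sig = group_reho_stat_map(
                    maps, fwhm_mm=cfg.fwhm_mm, pixel_size=cfg.pixel_size, p_threshold=cfg.p_pixel
                )
                paths.append(fio.save_map(zstat, d / f"reho_group_z_{group}.nii"))
    return paths


def _stage_stats(run: _Run) -> list[Path]:
    cfg = run.config
    d = run.stage_dir("stats")
    paths = []
    families = {
        "visual_pct": (run.product("stimresp", "roi_mean_pct.tsv"), "mean_pct"),
        "connectivity_z": (run.product("fc", "connectivity_long.tsv"), "z"),
        "reho_z": (run.product("reho", "reho_roi.tsv"), "value"),
    }
    for family, (path, col) in families.items():
        tab = pd.read_csv(path, sep="\t")
        if family == "connectivity_z":
            tab = tab.assign(roi=tab["roi_a"] + "~" + tab["roi_b"])
        tab = tab.rename(columns={col: "value"})[["group", "animal", "roi", "value"]]
        aov = two_way_anova(tab)
        aov.table.to_csv(d / f"anova_{family}.tsv", sep="\t")
        tests = per_roi_group_tests(tab)
        reject, qvals = fdr_correct(tests["p"].to_numpy(), q=cfg.fdr_q)
        tests["q"] = qvals
        tests["significant"] = reject
        tests.to_csv(d / f"comparisons_{family}.tsv", sep="\t", index=False)
        paths += [d / f"anova_{family}.tsv", d / f"comparisons_{family}.tsv"]
    return paths


def _stage_report(run: _Run) -> list[Path]:
    return report(run)


def run_pipeline(config: RunConfig, stages: list[str], out_dir: str | Path) -> dict:
    """Run the requested stages in order; returns the manifest dict.

    Stage names must be drawn from ``STAGES``; each stage's upstream products
    must already exist (from this call or a previous one on the same
    ``out_dir``) or a ``StageError`` naming the stage is raised.
    """
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise StageError(f"unknown stages: {unknown}")
    stages = sorted(set(stages), key=STAGES.index)
    run = _Run(config, Path(out_dir))
    impl = {
        "simulate": _stage_simulate,
        "doppler": _stage_doppler,
        "register": _stage_register,
        "stimresp": _stage_stimresp,
        "fc": _stage_fc,
        "reho": lambda r: _reho_falff_stage(r, "reho"),
        "falff": lambda r: _reho_falff_stage(r, "falff"),
        "stats": _stage_stats,
        "report": _stage_report,
    }
    for stage in stages:
        run.require(stage, _DEPS[stage])
        paths = impl[stage](run)
        run.record(stage, paths)
    return run.manifest


def report(run: "_Run") -> list[Path]:
    """Figure bundle: ROI time-courses with stimulation bars, %CBV bar plot,
    connectivity heatmaps, seed/ReHo/fALFF/Tmax maps.  Panels whose family was
    not computed are omitted with a note in the report manifest."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cfg = run.config
    d = run.stage_dir("report")
    paths: list[Path] = []
    notes = []
    protocol = cfg.protocol()

    tc_path = run.product("stimresp", "roi_timecourses.tsv")
    if tc_path.exists():
        tcs = pd.read_csv(tc_path, sep="\t")
        rois = sorted(tcs["roi"].unique())[:4]
        fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharex=True)
        for ax, roi in zip(axes.ravel(), rois):
            for group, sub in tcs[tcs["roi"] == roi].groupby("group"):
                agg = sub.groupby("time")["pct"]
                mean, sem = agg.mean(), agg.sem()
                ax.plot(mean.index, mean.values, label=group)
                ax.fill_between(mean.index, mean - sem, mean + sem, alpha=0.3)
            ax.axvspan(0, protocol.stim_duration, color="0.85", zorder=0)
            ax.set_title(roi)
            ax.set_xlabel("time from onset (s)")
            ax.set_ylabel("%CBV")
        axes[0, 0].legend()
        fig.tight_layout()
        fig.savefig(d / "roi_timecourses.png", dpi=110)
        plt.close(fig)
        paths.append(d / "roi_timecourses.png")

        means = pd.read_csv(run.product("stimresp", "roi_mean_pct.tsv"), sep="\t")
        fig, ax = plt.subplots(figsize=(8, 4))
        agg = means.groupby(["roi", "group"])["mean_pct"].agg(["mean", "sem"]).reset_index()
        rois = sorted(agg["roi"].unique())
        width = 0.38
        for gi, group in enumerate(sorted(agg["group"].unique())):
            sub = agg[agg["group"] == group].set_index("roi").reindex(rois)
            ax.bar(
                np.arange(len(rois)) + gi * width, sub["mean"], width,
                yerr=sub["sem"], label=group, capsize=3,
            )
        ax.set_xticks(np.arange(len(rois)) + width / 2)
        ax.set_xticklabels(rois, rotation=45, ha="right")
        ax.set_ylabel("mean %CBV during stimulation")
        ax.legend()
        fig.tight_layout()
        fig.savefig(d / "roi_mean_pct.png", dpi=110)
        plt.close(fig)
        paths.append(d / "roi_mean_pct.png")
    else:
        notes.append("stimulation panels omitted: stimresp not run")

    fig_done = False
    for group in cfg.groups:
        mpath = run.product("fc", f"matrix_{group}.tsv")
        if not mpath.exists():
            continue
        mat = pd.read_csv(mpath, sep="\t", index_col=0)
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(mat.values, vmin=-1, vmax=1, cmap="coolwarm")
        ax.set_xticks(range(len(mat)))
        ax.set_xticklabels(mat.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(len(mat)))
        ax.set_yticklabels(mat.index, fontsize=7)
        fig.colorbar(im, ax=ax, label="Pearson r")
        ax.set_title(f"connectivity, {group}")
        fig.tight_layout()
        fig.savefig(d / f"connectivity_{group}.png", dpi=110)
        plt.close(fig)
        paths.append(d / f"connectivity_{group}.png")
        fig_done = True
    if not fig_done:
        notes.append("connectivity panels omitted: fc not run")

    def _map_panel(stage: str, pattern: str, title: str, fname: str, cmap="viridis"):
        files = sorted((run.out / stage).glob(pattern)) if (run.out / stage).exists() else []
        if not files:
            notes.append(f"{title} panel omitted: no {stage} maps")
            return
        fig, axes = plt.subplots(1, len(files), figsize=(3.2 * len(files), 3))
        axes = np.atleast_1d(axes)
        for ax, f in zip(axes, files):
            pm = fio.load_map(f)
            im = ax.imshow(np.where(pm.mask, pm.values, np.nan), cmap=cmap)
            ax.set_title(f.stem, fontsize=8)
            ax.axis("off")
            fig.colorbar(im, ax=ax, shrink=0.8)
        fig.suptitle(title)
        fig.tight_layout()
        fig.savefig(d / fname, dpi=110)
        plt.close(fig)
        paths.append(d / fname)

    _map_panel("fc", "seedmap_*.nii", "seed-based connectivity", "seed_maps.png", "coolwarm")
    _map_panel("reho", "reho_group_z_*.nii", "ReHo group Z", "reho_maps.png")
    _map_panel("falff", "falff_*.nii", "fALFF", "falff_maps.png")
    _map_panel("stimresp", "tmax_*.nii", "Tmax (s)", "tmax_maps.png", "magma")
    _map_panel("stimresp", "activation_z_*.nii", "activation Z", "activation_maps.png", "coolwarm")

    fio.save_json({"notes": notes}, d / "report_notes.json")
    paths.append(d / "report_notes.json")
    return paths
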