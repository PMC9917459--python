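"""End-to-end orchestration: simulate -> detect -> extract -> peaks -> quantal.

A single YAML-serialisable :class:`RunConfig` drives the whole pipeline;
every run writes a manifest (stage status, files, seed, config hash) and a
log, and identical config + seed gives byte-identical numerical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sstats

from . import __version__
from .movie import FluorescenceMovie, read_movie_tiff, write_movie_tiff
from .peaks import AlsBaseline, extract_peaks_at_template, snr_and_exclusion
from .quantal import CvAnalysis, QuantalHistogramModel, classify_model, \
    usable_roi_fraction
from .roi import TileCriteria, TileRoiDetector, write_label_mask, write_roi_csv
from .synthetic import (GroundTruth, StimulusProtocol, read_traces_csv,
                        roi_rng, simulate_movie, simulate_release_counts,
                        simulate_trace, write_ground_truth_json,
                        write_traces_csv)
from .traces import TraceSet, extract_traces

logger = logging.getLogger(__name__)

STAGES = ("simulate", "detect", "extract", "peaks", "quantal")


@dataclass
class RunConfig:
    """Everything a pipeline run needs, round-trippable through YAML."""

    source: str = "simulate"          # "simulate" | "movie" | "traces"
    movie_path: str | None = None
    traces_path: str | None = None
    ground_truth: GroundTruth = field(default_factory=GroundTruth)
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    n_rois: int = 12
    render_movie: bool = False
    movie_shape: tuple[int, int] = (128, 128)
    movie_background: float = 100.0
    movie_pixel_size_um: float = 0.5
    spot_peak_counts: float = 3000.0
    tile: TileCriteria = field(default_factory=TileCriteria)
    als_smoothness: float = 1e4
    als_asymmetry: float = 0.01
    min_snr: float = 3.0
    rundown_cut: float = 0.5
    p_cut: float = 0.5
    low_ca_condition: str = "0.5"
    n_range: tuple[int, int] = (1, 12)
    bin_width: float | None = None
    restarts: int = 5
    write_plots: bool = False
    ignore_first_high_ca: bool = False
    include_rois: list[str] = field(default_factory=list)
    exclude_rois: list[str] = field(default_factory=list)
    seed: int = 0
    outdir: str = "gluquant_run"

    def __post_init__(self) -> None:
        sources = ("simulate", "movie", "traces")
        if self.source not in sources:
            raise ValueError(f"source must be one of {sources}")
        if self.source == "movie" and not self.movie_path:
            raise ValueError("movie source requires movie_path")
        if self.source == "traces" and not self.traces_path:
            raise ValueError("traces source requires traces_path")

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["ground_truth"]["p_release"] = dict(self.ground_truth.p_release)
        d["protocol"]["conditions"] = list(self.protocol.conditions)
        d["movie_shape"] = list(self.movie_shape)
        d["n_range"] = list(self.n_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "ground_truth" in d:
            d["ground_truth"] = GroundTruth(**d["ground_truth"])
        if "protocol" in d:
            proto = dict(d["protocol"])
            proto["conditions"] = tuple(proto.get("conditions", ()))
            d["protocol"] = StimulusProtocol(**proto)
        if "tile" in d:
            d["tile"] = TileCriteria(**d["tile"])
        if "movie_shape" in d:
            d["movie_shape"] = tuple(d["movie_shape"])
        if "n_range" in d:
            d["n_range"] = tuple(d["n_range"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _resolve_run_dir(outdir: str | Path) -> Path:
    """Never silently overwrite: version the run directory when occupied."""
    base = Path(outdir)
    if not base.exists() or not any(base.iterdir()):
        base.mkdir(parents=True, exist_ok=True)
        return base
    i = 1
    while (base / f"run-{i:03d}").exists():
        i += 1
    run_dir = base / f"run-{i:03d}"
    run_dir.mkdir(parents=True)
    return run_dir


def _simulate_stage(config: RunConfig, ctx: dict, run_dir: Path) -> list[str]:
    gt, proto = config.ground_truth, config.protocol
    seed = config.seed
    dffs, ids = [], []
    for i in range(config.n_rois):
        rng = roi_rng(seed, i)
        counts = simulate_release_counts(gt, proto, rng=rng)
        dffs.append(simulate_trace(counts, gt, proto, rng=rng))
        ids.append(f"roi_{i:03d}")
    dff = np.stack(dffs)
    files = []
    gt_path = run_dir / "ground_truth.json"
    write_ground_truth_json(gt, proto, gt_path)
    files.append(gt_path.name)
    if config.render_movie:
        H, W = config.movie_shape
        margin = 12
        n = config.n_rois
        cols = int(np.ceil(np.sqrt(n)))
        centres = []
        for i in range(n):
            r = margin + (i // cols) * max(8, (H - 2 * margin) // cols)
            c = margin + (i % cols) * max(8, (W - 2 * margin) // cols)
            centres.append((float(min(r, H - margin)),
                            float(min(c, W - margin))))
        movie = simulate_movie(
            dff, centres, gt, proto, shape=config.movie_shape,
            background=config.movie_background,
            pixel_size_um=config.movie_pixel_size_um,
            spot_peak_counts=config.spot_peak_counts)
        mpath = run_dir / "movie.tif"
        write_movie_tiff(movie, mpath)
        files += [mpath.name, mpath.name + ".json"]
        ctx["movie"] = movie
        ctx["spot_centres"] = centres
    else:
        tpath = run_dir / "simulated_traces.csv"
        write_traces_csv(dff, ids, proto, tpath)
        files.append(tpath.name)
        ctx["dff"] = dff
        ctx["roi_ids"] = ids
    ctx["stim_table"] = proto.stim_table()
    return files


def _detect_stage(config: RunConfig, ctx: dict, run_dir: Path) -> list[str]:
    movie: FluorescenceMovie = ctx["movie"]
    detector = TileRoiDetector(**asdict(config.tile))
    detector.fit(movie)
    ctx["roiset"] = detector.rois_
    mask_path = run_dir / "roi_labels.tif"
    csv_path = run_dir / "rois.csv"
    write_label_mask(detector.rois_, mask_path)
    write_roi_csv(detector.rois_, csv_path)
    return [mask_path.name, csv_path.name]


def _extract_stage(config: RunConfig, ctx: dict, run_dir: Path) -> list[str]:
    stim_table = ctx["stim_table"]
    if "movie" in ctx:
        roiset = ctx["roiset"]
        traceset = extract_traces(ctx["movie"], roiset.masks(), roiset.ids(),
                                  stim_table)
    else:
        dff = ctx["dff"]
        traceset = TraceSet(dff=dff, f0=np.ones(dff.shape[0]),
                            roi_ids=ctx["roi_ids"],
                            frame_rate_hz=config.protocol.frame_rate_hz,
                            stim_table=stim_table)
    ctx["traceset"] = traceset
    tpath = run_dir / "traces.csv"
    write_traces_csv(traceset.dff, traceset.roi_ids, config.protocol, tpath)
    qc = {"roi_ids": traceset.roi_ids,
          "valid": [bool(v) for v in traceset.valid],
          "f0": [float(v) for v in traceset.f0]}
    qpath = run_dir / "trace_qc.json"
    qpath.write_text(json.dumps(qc, indent=1))
    return [tpath.name, qpath.name]


def _peaks_stage(config: RunConfig, ctx: dict, run_dir: Path) -> list[str]:
    traceset: TraceSet = ctx["traceset"]
    baseline = AlsBaseline(smoothness=config.als_smoothness,
                           asymmetry=config.als_asymmetry)
    table = extract_peaks_at_template(
        traceset, baseline=baseline,
        ignore_first_high_ca=config.ignore_first_high_ca)
    table = snr_and_exclusion(table, min_snr=config.min_snr,
                              rundown_cut=config.rundown_cut)
    for roi in config.exclude_rois:
        table.loc[table["roi_id"] == roi,
                  ["excluded", "reason"]] = [True, "curated out"]
    for roi in config.include_rois:
        table.loc[table["roi_id"] == roi,
                  ["excluded", "reason"]] = [False, ""]
    ctx["peak_table"] = table
    ppath = run_dir / "peaks.csv"
    table.to_csv(ppath, index=False, float_format="%.8g")
    return [ppath.name]


def _quantal_stage(config: RunConfig, ctx: dict, run_dir: Path) -> list[str]:
    table: pd.DataFrame = ctx["peak_table"]
    usable = table[~table["excluded"]]
    fits = {}
    rows = []
    plot_files: list[str] = []
    for roi, grp in usable.groupby("roi_id", sort=False):
        amps = grp["amplitude"].to_numpy()
        conds = grp["condition"].astype(str).to_numpy()
        entry: dict = {"roi_id": roi}
        try:
            binom = QuantalHistogramModel(
                model="binomial", n_range=config.n_range,
                bin_width=config.bin_width, restarts=config.restarts,
                seed=config.seed).fit(amps, conds)
            entry["binomial"] = binom.fit_.to_dict()
            fits[roi] = binom.fit_
        except Exception as exc:
            entry["binomial"] = {"error": str(exc)}
            fits[roi] = None
        try:
            poisson = QuantalHistogramModel(
                model="poisson", bin_width=config.bin_width,
                restarts=config.restarts, seed=config.seed).fit(amps, conds)
            entry["poisson"] = poisson.fit_.to_dict()
        except Exception as exc:
            entry["poisson"] = {"error": str(exc)}
            poisson = None
        if fits[roi] is not None or poisson is not None:
            entry["model_choice"] = classify_model(
                fits[roi], poisson.fit_ if poisson is not None else None)
        if config.write_plots and fits[roi] is not None:
            from .plots import plot_roi_fit
            by_cond = {str(c): amps[conds == c]
                       for c in dict.fromkeys(conds.tolist())}
            ppath = run_dir / f"fit_{roi}.png"
            plot_roi_fit(by_cond, fits[roi], ppath)
            plot_files.append(ppath.name)
        rows.append(entry)

    cv_payload: dict = {}
    try:
        cv = CvAnalysis(n_range=(config.n_range[0],
                                 min(config.n_range[1], 8)),
                        low_ca_condition=config.low_ca_condition,
                        p_cut=config.p_cut).fit(usable)
        cv_payload = {"cv": cv.cv_, "r_squared": cv.r_squared_,
                      "n_sites": cv.n_sites_, "p_release": cv.p_release_}
    except Exception as exc:
        cv_payload = {"error": str(exc)}

    frac = usable_roi_fraction(table, fits)
    results = {"per_roi": rows, "cv_analysis": cv_payload,
               "usable_roi_fraction": frac}
    rpath = run_dir / "quantal_fits.json"
    rpath.write_text(json.dumps(results, indent=1, default=_json_default))

    tidy = []
    for entry in rows:
        b = entry.get("binomial", {})
        if "error" not in b:
            row = {"roi_id": entry["roi_id"], "model": "binomial",
                   "q": b["q"], "sigma": b["sigma_component"],
                   "n_sites": b["n_sites"], "min_ks_p": min(b["ks_p"].values())}
            for c, p in b["p_release"].items():
                row[f"p_release_{c}"] = p
            tidy.append(row)
    spath = run_dir / "quantal_summary.csv"
    pd.DataFrame(tidy).to_csv(spath, index=False, float_format="%.8g")
    ctx["quantal_results"] = results
    return [rpath.name, spath.name] + plot_files


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def run_pipeline(config: RunConfig, stages: tuple[str, ...] | None = None
                 ) -> dict:
    """Execute the configured stages in order and write a manifest.

    Stage failure keeps earlier outputs and records the failing stage in
    the manifest; later stages that depend on it are skipped.
    """
    run_dir = _resolve_run_dir(config.outdir)
    log_path = run_dir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("gluquant")
    root.addHandler(handler)

    config.to_yaml(run_dir / "config.yaml")
    wanted = list(stages or STAGES)
    plan = []
    for st in STAGES:
        if st not in wanted:
            continue
        if st == "simulate" and config.source != "simulate":
            continue
        plan.append(st)

    ctx: dict = {}
    if config.source == "movie":
        ctx["movie"] = read_movie_tiff(config.movie_path)
        ctx["stim_table"] = _stim_table_from_movie(ctx["movie"],
                                                   config.protocol)
    elif config.source == "traces":
        dff, roi_ids, _ = read_traces_csv(config.traces_path)
        ctx["dff"], ctx["roi_ids"] = dff, roi_ids
        ctx["stim_table"] = config.protocol.stim_table()

    stage_fns = {"simulate": _simulate_stage, "detect": _detect_stage,
                 "extract": _extract_stage, "peaks": _peaks_stage,
                 "quantal": _quantal_stage}
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "run_dir": str(run_dir),
        "stages": {},
        "files": ["config.yaml"],
    }
    failed = False
    for st in plan:
        if failed:
            manifest["stages"][st] = {"status": "skipped",
                                      "why": "earlier stage failed"}
            continue
        if st == "detect" and "movie" not in ctx:
            manifest["stages"][st] = {"status": "skipped",
                                      "why": "no movie input"}
            continue
        t0 = time.perf_counter()
        try:
            files = stage_fns[st](config, ctx, run_dir)
            manifest["stages"][st] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3)}
            manifest["files"] += files
            logger.info("stage %s ok (%d files)", st, len(files))
        except Exception as exc:
            logger.exception("stage %s failed", st)
            manifest["stages"][st] = {"status": "failed", "error": str(exc)}
            failed = True
    mpath = run_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    root.removeHandler(handler)
    handler.close()
    manifest["results"] = ctx.get("quantal_results")
    return manifest


def _stim_table_from_movie(movie: FluorescenceMovie,
                           protocol: StimulusProtocol) -> pd.DataFrame:
    """Stimulus annotation for a recorded movie.

    Uses the protocol's condition/train/stimulus layout but the movie's own
    stimulus frames when their counts agree; otherwise falls back to raw
    frame indices in a single condition.
    """
    table = protocol.stim_table()
    if len(table) == len(movie.stimulus_frames):
        table = table.copy()
        table["frame"] = movie.stimulus_frames
        return table
    warnings.warn("movie stimulus count does not match the protocol; "
                  "treating all stimuli as one condition")
    return pd.DataFrame({
        "frame": movie.stimulus_frames,
        "time_s": movie.stimulus_frames / movie.frame_rate_hz,
        "condition": "all",
        "train": 0,
        "stimulus_index": np.arange(len(movie.stimulus_frames)),
    })


def correlate_fluor_vs_epsc(
    depression_fluor: dict[str, float],
    depression_epsc: dict[str, float],
) -> tuple[float, pd.DataFrame]:
    """Pearson correlation of per-cell optical vs electrical depression.

    Pairs cells by identifier; unpaired entries are dropped with a warning.
    """
    keys = sorted(set(depression_fluor) & set(depression_epsc))
    dropped = (set(depression_fluor) | set(depression_epsc)) - set(keys)
    if dropped:
        warnings.warn(f"unpaired cells dropped: {sorted(dropped)}")
    if len(keys) < 3:
        raise ValueError("need >= 3 paired cells")
    f = np.array([depression_fluor[k] for k in keys])
    e = np.array([depression_epsc[k] for k in keys])
    r = float(sstats.pearsonr(f, e).statistic)
    table = pd.DataFrame({"cell": keys, "depression_fluor": f,
                          "depression_epsc": e})
    return r, table
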