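"""File formats, run configuration, and the end-to-end pipeline.

Formats: TIFF (ImageJ-style metadata carries the pixel size in µm and the
frame interval), tidy long-format CSV for trajectories and traces, JSON for
summary scalars and provenance, YAML for run configuration.  All lengths in
files are µm, times s, rates 1/s; pixel units never escape this layer.

Trajectory XML import covers a documented tracker-export subset: a root
element with a ``frameInterval`` attribute containing ``particle`` elements,
each holding ``detection`` elements with ``t`` (frame index), ``x`` and
``y`` (µm) attributes.  Unknown attributes are ignored with a warning;
anything else must be converted to CSV first.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import __version__
from .quant import (
    ChannelImage, ImageStack, RoiMask, area_under_curve,
    masked_intensity_timecourse, normalized_subtraction, normalize_timecourse,
    subtract_camera_offset,
)
from .simkit import (
    CellTrackSet, ConfocalPhantomConfig, SPTSimConfig, TimeSeriesPhantomConfig,
    Trajectory, resolve_roi, simulate_membrane_spt, synthesize_compartment_movie,
    synthesize_confocal_pair, synthesize_tirf_timecourse,
)
from .spt import (
    compute_msd, extrapolate_off_rate, fit_diffusion, fit_lifetime, grand_msd,
    relative_deviation_ratio,
)

__all__ = [
    "FormatError",
    "PipelineError",
    "RunConfig",
    "ResultBundle",
    "load_run_config",
    "run_pipeline",
    "read_image_stack",
    "write_image_stack",
    "write_label_stack",
    "read_roi",
    "read_trajectories",
    "write_trajectories",
    "setup_logging",
]

log = logging.getLogger("memprobe")

TRAJECTORY_COLUMNS = [
    "track_id", "cell_id", "power", "frame", "t_s", "x_um", "y_um", "censored",
]


class FormatError(ValueError):
    """A file does not conform to its documented schema."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[memprobe:%(levelname)s] %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(getattr(logging, level.upper(), logging.INFO))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

TaskName = Literal[
    "simulate_spt", "spt_analyze", "simulate_phantom",
    "quantify_confocal", "quantify_tirf", "quantify_compartments",
]


class SPTAnalysisParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    trajectories: Path
    dialect: Literal["csv", "tracking_xml"] = "csv"
    max_lag_frames: int = 10
    fit_lags: tuple[int, ...] = (2, 3, 4)
    test_lag: int = 10
    lifetime_method: Literal["grid_mle", "truncated_mle", "survival_lsq"] = "grid_mle"
    t_min: Optional[float] = None
    min_tracks: int = 10
    write_msd_curves: bool = True


class PhantomParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["confocal", "tirf", "compartments"]
    params: dict


class AucSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    t_start: float
    t_end: float
    baseline: float = 0.0
    series: str = "f_over_fpre"


class QuantifyParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    biosensor: Optional[Path] = None
    reference: Optional[Path] = None
    stack: Optional[Path] = None
    reporter: Optional[Path] = None
    marker: Optional[Path] = None
    roi: Path = Path("roi.json")
    pixel_size: Optional[float] = None        # µm, metadata override
    frame_interval: Optional[float] = None    # s, metadata override
    camera_offset: float = 0.0
    rim_width: int = 5
    pre_frames: Optional[list[int]] = None
    modes: list[str] = ["f_over_fpre"]
    mask_method: Literal["otsu", "fixed"] = "otsu"
    fixed_threshold: Optional[float] = None
    min_size: int = 4
    recompute_mask_per_frame: bool = True
    treatments: Optional[Path] = None         # CSV: time_s,label
    auc: list[AucSpec] = []


class RunConfig(BaseModel):
    """Schema-validated run configuration (unknown keys are rejected)."""

    model_config = ConfigDict(extra="forbid")
    config_version: str
    task: TaskName
    output_dir: Path
    seed: int = 0
    log_level: str = "INFO"
    spt_sim: Optional[dict] = None
    spt_analysis: Optional[SPTAnalysisParams] = None
    phantom: Optional[PhantomParams] = None
    quantify: Optional[QuantifyParams] = None


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration; fail before any I/O."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise FormatError(f"{path}: invalid run config:\n{exc}") from exc


@dataclass
class ResultBundle:
    """Outputs of one pipeline run: file paths, headline scalars, provenance."""

    outputs: dict[str, str] = field(default_factory=dict)
    scalars: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

def write_image_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as ImageJ-style TIFF with pixel size and frame interval.

    Float data is stored as float32.
    """
    path = Path(path)
    data = stack.frames
    if np.issubdtype(data.dtype, np.floating) and data.dtype != np.float32:
        data = data.astype(np.float32)
    tifffile.imwrite(
        path, data, imagej=True,
        resolution=(1.0 / stack.pixel_size, 1.0 / stack.pixel_size),
        metadata={"unit": "um", "finterval": stack.frame_interval, "axes": "TYX"},
    )
    return path


def write_label_stack(labels: np.ndarray, path: str | Path,
                      pixel_size: float = 1.0) -> Path:
    """Write a 16-bit label mask (stack) TIFF."""
    path = Path(path)
    labels = np.asarray(labels)
    if labels.ndim == 2:
        labels = labels[None]
    tifffile.imwrite(
        path, labels.astype(np.uint16), imagej=True,
        resolution=(1.0 / pixel_size, 1.0 / pixel_size),
        metadata={"unit": "um", "axes": "TYX"},
    )
    return path


def read_image_stack(
    path: str | Path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
    channel_label: str = "",
) -> ImageStack:
    """Read a single- or multi-page TIFF into an :class:`ImageStack`.

    Pixel size comes from the file's resolution tags unless overridden;
    missing from both is an error.  Frame interval comes from ImageJ
    metadata, an override, or defaults to 1 s with a warning.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = list(tif.pages)
        if not pages:
            raise FormatError(f"{path}: no pages")
        arrays = [p.asarray() for p in pages]
        shapes = {a.shape for a in arrays}
        if any(a.ndim != 2 for a in arrays):
            raise FormatError(f"{path}: non-2D page encountered")
        if len(shapes) > 1:
            raise FormatError(f"{path}: inconsistent page shapes {shapes}")
        frames = np.stack(arrays)
        meta_ps = None
        tags = pages[0].tags
        ij = tif.imagej_metadata or {}
        resunit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else 1
        # trust the resolution tag only when a physical unit is declared
        # (ImageJ metadata or a TIFF ResolutionUnit other than NONE)
        has_unit = bool(ij.get("unit")) or int(resunit) > 1
        if has_unit and "XResolution" in tags:
            num, den = tags["XResolution"].value
            if num:
                meta_ps = den / num
        meta_fi = ij.get("finterval")
    ps = pixel_size if pixel_size is not None else meta_ps
    if ps is None or not ps > 0:
        raise FormatError(f"{path}: no pixel size in metadata and no override")
    fi = frame_interval if frame_interval is not None else meta_fi
    if fi is None or not fi > 0:
        log.warning("%s: no frame interval; defaulting to 1 s", path)
        fi = 1.0
    return ImageStack(
        frames=frames, pixel_size=float(ps), frame_interval=float(fi),
        channel_label=channel_label or path.stem,
    )


def read_roi(path: str | Path, shape: tuple[int, int],
             pixel_size: float) -> RoiMask:
    """Read an ROI: polygon JSON ({"vertices_um": [[x, y], ...]}) or label TIFF."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        verts = data.get("vertices_um", data.get("vertices"))
        if verts is None:
            raise FormatError(f"{path}: no 'vertices_um' key")
        return RoiMask(resolve_roi(verts, shape, pixel_size), "user_polygon")
    mask = tifffile.imread(path)
    if mask.ndim == 3 and mask.shape[0] == 1:
        mask = mask[0]
    if mask.shape != tuple(shape):
        raise FormatError(f"{path}: ROI mask shape {mask.shape} != image {shape}")
    return RoiMask(mask > 0, "label_mask_file")


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------

def write_trajectories(cells: list[CellTrackSet], path: str | Path) -> Path:
    """Write track sets to the tidy trajectory CSV schema."""
    path = Path(path)
    rows = []
    for cell in cells:
        dt = cell.frame_interval
        for tr in cell.trajectories:
            for f, x, y in zip(tr.frames, tr.x, tr.y):
                rows.append((
                    tr.track_id, cell.cell_id, cell.power, int(f),
                    float(f) * dt, float(x), float(y), bool(tr.censored),
                ))
    pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS).to_csv(path, index=False)
    return path


def _split_at_gaps(
    frames: np.ndarray, x: np.ndarray, y: np.ndarray,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Split a track at frame gaps; segments shorter than 2 points are dropped."""
    order = np.argsort(frames)
    frames, x, y = frames[order], x[order], y[order]
    cuts = np.nonzero(np.diff(frames) != 1)[0] + 1
    segments = []
    for seg in np.split(np.arange(frames.size), cuts):
        if seg.size >= 2:
            segments.append((frames[seg], x[seg], y[seg]))
    return segments


def read_trajectories(
    path: str | Path,
    dialect: Literal["csv", "tracking_xml"] = "csv",
    cell_id: str | None = None,
    power: float = 0.0,
    frame_interval: float | None = None,
) -> list[CellTrackSet]:
    """Read trajectories grouped by (cell, power); tracks split at frame gaps."""
    path = Path(path)
    if dialect == "csv":
        return _read_trajectories_csv(path)
    if dialect == "tracking_xml":
        return _read_trajectories_xml(path, cell_id, power, frame_interval)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_trajectories_csv(path: Path) -> list[CellTrackSet]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    moving = df[df["frame"] > 0]
    if moving.empty:
        raise FormatError(f"{path}: cannot infer frame interval")
    dt = float(np.median(moving["t_s"] / moving["frame"]))
    cells: list[CellTrackSet] = []
    n_split = 0
    for (cid, pw), group in df.groupby(["cell_id", "power"], sort=True):
        trajectories = []
        for tid, tgroup in group.groupby("track_id", sort=True):
            segments = _split_at_gaps(
                tgroup["frame"].to_numpy(),
                tgroup["x_um"].to_numpy(float),
                tgroup["y_um"].to_numpy(float),
            )
            if len(segments) > 1:
                n_split += 1
            censored = bool(tgroup["censored"].iloc[0])
            for si, (fr, x, y) in enumerate(segments):
                name = str(tid) if len(segments) == 1 else f"{tid}_s{si}"
                # re-zero so frames stay contiguous from 0
                trajectories.append(Trajectory(
                    track_id=name, frame_interval=dt,
                    frames=fr - fr[0], x=x, y=y, censored=censored,
                ))
        if trajectories:
            cells.append(CellTrackSet(
                cell_id=str(cid), power=float(pw), trajectories=trajectories,
            ))
    if n_split:
        log.info("split %d tracks at frame gaps", n_split)
    if not cells:
        raise FormatError(f"{path}: no usable trajectories")
    return cells


_KNOWN_DETECTION_ATTRS = {"t", "x", "y", "z"}


def _read_trajectories_xml(
    path: Path, cell_id: str | None, power: float,
    frame_interval: float | None,
) -> list[CellTrackSet]:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"{path}: not well-formed XML: {exc}") from exc
    dt = frame_interval
    if dt is None and "frameInterval" in root.attrib:
        dt = float(root.attrib["frameInterval"])
    if dt is None or not dt > 0:
        raise FormatError(f"{path}: no frameInterval attribute and no override")
    warned = False
    trajectories = []
    for pi, particle in enumerate(root.iter("particle")):
        frames, xs, ys = [], [], []
        for det in particle.iter("detection"):
            extras = set(det.attrib) - _KNOWN_DETECTION_ATTRS
            if extras and not warned:
                log.warning("%s: ignoring unknown detection attributes %s",
                            path, sorted(extras))
                warned = True
            try:
                frames.append(int(round(float(det.attrib["t"]))))
                xs.append(float(det.attrib["x"]))
                ys.append(float(det.attrib["y"]))
            except KeyError as exc:
                raise FormatError(
                    f"{path}: particle {pi} detection missing attribute {exc}"
                ) from exc
        if len(frames) < 2:
            continue
        for si, (fr, x, y) in enumerate(_split_at_gaps(
            np.asarray(frames), np.asarray(xs, float), np.asarray(ys, float),
        )):
            trajectories.append(Trajectory(
                track_id=f"xml{pi:05d}_s{si}", frame_interval=dt,
                frames=fr - fr[0], x=x, y=y,
            ))
    if not trajectories:
        raise FormatError(f"{path}: no usable particles")
    return [CellTrackSet(
        cell_id=cell_id or path.stem, power=power, trajectories=trajectories,
    )]


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _write_json(obj, path: Path) -> Path:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
    return path


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _nan_to_none(x):
    if x is None:
        return None
    x = float(x)
    return None if not np.isfinite(x) else x


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute the configured task and write its :class:`ResultBundle`.

    Identical config and seed produce byte-identical outputs.  Any stage
    error raises :class:`PipelineError` naming the stage.
    """
    setup_logging(config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    dispatch = {
        "simulate_spt": _task_simulate_spt,
        "spt_analyze": _task_spt_analyze,
        "simulate_phantom": _task_simulate_phantom,
        "quantify_confocal": _task_quantify_confocal,
        "quantify_tirf": _task_quantify_tirf,
        "quantify_compartments": _task_quantify_compartments,
    }
    t0 = time.perf_counter()
    log.info("stage=%s status=start", config.task)
    try:
        bundle = dispatch[config.task](config, outdir)
    except (PipelineError, FormatError):
        raise
    except Exception as exc:
        raise PipelineError(f"stage={config.task}: {exc}") from exc
    bundle.provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "input_digests": bundle.provenance.get("input_digests", {}),
    }
    _write_json(bundle.provenance, outdir / "provenance.json")
    _write_json(bundle.scalars, outdir / "summary.json")
    bundle.outputs["provenance"] = str(outdir / "provenance.json")
    bundle.outputs["summary"] = str(outdir / "summary.json")
    log.info("stage=%s status=done elapsed_s=%.2f",
             config.task, time.perf_counter() - t0)
    return bundle


def _input_digests(*paths: Path | None) -> dict[str, str]:
    return {str(p): _digest(Path(p)) for p in paths if p is not None}


def _require(block, name: str):
    if block is None:
        raise PipelineError(f"stage=config: missing '{name}' parameter block")
    return block


def _task_simulate_spt(config: RunConfig, outdir: Path) -> ResultBundle:
    params = dict(_require(config.spt_sim, "spt_sim"))
    params.setdefault("seed", config.seed)
    sim_cfg = SPTSimConfig(**params)
    cells = simulate_membrane_spt(sim_cfg)
    traj_path = write_trajectories(cells, outdir / "trajectories.csv")
    (outdir / "config_echo.yaml").write_text(
        yaml.safe_dump(json.loads(sim_cfg.model_dump_json()), sort_keys=True)
    )
    n_tracks = sum(c.n_tracks for c in cells)
    log.info("stage=simulate_spt cells=%d tracks=%d", len(cells), n_tracks)
    return ResultBundle(
        outputs={"trajectories": str(traj_path),
                 "config_echo": str(outdir / "config_echo.yaml")},
        scalars={"n_cells": len(cells), "n_tracks": n_tracks,
                 "powers": list(sim_cfg.powers)},
    )


def _task_spt_analyze(config: RunConfig, outdir: Path) -> ResultBundle:
    p = _require(config.spt_analysis, "spt_analysis")
    cells = read_trajectories(p.trajectories, dialect=p.dialect)
    rows, msd_rows, lifetime_points, curves = [], [], [], []
    for cell in cells:
        curve = compute_msd(cell, max_lag_frames=p.max_lag_frames)
        curves.append(curve)
        for lf, lag, m, npair in zip(curve.lag_frames, curve.lags,
                                     curve.msd, curve.n_pairs):
            msd_rows.append((cell.cell_id, cell.power, int(lf), lag, m, int(npair)))
        try:
            dfit = fit_diffusion(curve, p.fit_lags)
            D, intercept, r2 = dfit.D, dfit.intercept, dfit.r_squared
        except ValueError:
            D = intercept = r2 = float("nan")
        try:
            rd = relative_deviation_ratio(curve, p.fit_lags, p.test_lag).rd
        except ValueError:
            rd = float("nan")
        try:
            lfit = fit_lifetime(cell, method=p.lifetime_method, t_min=p.t_min,
                                min_tracks=p.min_tracks)
            k_obs, tau = lfit.k_obs, lfit.mean_lifetime
            lifetime_points.append((cell.power, lfit, cell.cell_id))
        except ValueError:
            k_obs = tau = float("nan")
        rows.append((cell.cell_id, cell.power, cell.n_tracks,
                     D, intercept, r2, rd, k_obs, tau))
    per_cell = pd.DataFrame(rows, columns=[
        "cell_id", "power", "n_tracks", "D_um2_s", "msd_intercept_um2",
        "r_squared", "rd", "k_obs_per_s", "mean_lifetime_s",
    ])
    per_cell.to_csv(outdir / "per_cell.csv", index=False)
    outputs = {"per_cell": str(outdir / "per_cell.csv")}
    if p.write_msd_curves:
        pd.DataFrame(msd_rows, columns=[
            "cell_id", "power", "lag_frames", "lag_s", "msd_um2", "n_pairs",
        ]).to_csv(outdir / "msd_curves.csv", index=False)
        outputs["msd_curves"] = str(outdir / "msd_curves.csv")

    scalars: dict = {"n_cells": len(cells)}
    d_vals = per_cell["D_um2_s"].dropna()
    if len(d_vals):
        scalars["grand_D_um2_s"] = {
            "mean": float(d_vals.mean()),
            "sem": _nan_to_none(d_vals.sem()) if len(d_vals) > 1 else None,
        }
    rd_vals = per_cell["rd"].dropna()
    if len(rd_vals):
        scalars["mean_rd"] = {
            "mean": float(rd_vals.mean()),
            "sem": _nan_to_none(rd_vals.sem()) if len(rd_vals) > 1 else None,
        }
    if len(curves) >= 2:
        g = grand_msd(curves)
        try:
            gd = fit_diffusion(g, p.fit_lags)
            scalars["grand_curve_D_um2_s"] = gd.D
        except ValueError:
            pass
    n_powers = len({pw for pw, _, _ in lifetime_points})
    if n_powers >= 2:
        ext = extrapolate_off_rate(lifetime_points)
        scalars["off_rate_extrapolation"] = {
            "intercept_k_off_per_s": ext.intercept_k_off,
            "slope_per_s_per_power": ext.slope,
            "true_lifetime_ms": _nan_to_none(1000.0 * ext.true_lifetime),
            "valid": ext.valid,
        }
    return ResultBundle(
        outputs=outputs, scalars=scalars,
        provenance={"input_digests": _input_digests(p.trajectories)},
    )


def _stack_of(image: ChannelImage) -> ImageStack:
    return ImageStack(
        frames=image.pixels[None], pixel_size=image.pixel_size,
        frame_interval=1.0, channel_label=image.channel_label,
    )


def _task_simulate_phantom(config: RunConfig, outdir: Path) -> ResultBundle:
    p = _require(config.phantom, "phantom")
    params = dict(p.params)
    params.setdefault("seed", config.seed)
    if p.kind == "confocal":
        cfg = ConfocalPhantomConfig(**params)
        bio, ref, roi, rim = synthesize_confocal_pair(cfg)
        outputs = {
            "biosensor": str(write_image_stack(_stack_of(bio),
                                               outdir / "biosensor.tif")),
            "reference": str(write_image_stack(_stack_of(ref),
                                               outdir / "reference.tif")),
            "roi_mask": str(write_label_stack(roi.mask.astype(np.uint16),
                                              outdir / "roi_mask.tif",
                                              cfg.pixel_size)),
            "rim_mask": str(write_label_stack(rim.mask.astype(np.uint16),
                                              outdir / "rim_mask.tif",
                                              cfg.pixel_size)),
        }
        scalars = {"roi_area_px": roi.area, "rim_area_px": rim.area}
    elif p.kind == "tirf":
        cfg = TimeSeriesPhantomConfig(**params)
        stack, schedule, truth = synthesize_tirf_timecourse(cfg)
        pd.DataFrame(schedule, columns=["time_s", "label"]).to_csv(
            outdir / "schedule.csv", index=False)
        pd.DataFrame({
            "frame": np.arange(cfg.n_frames),
            "t_s": np.arange(cfg.n_frames) * cfg.frame_interval,
            "truth_roi_mean": truth,
        }).to_csv(outdir / "truth_trace.csv", index=False)
        outputs = {
            "stack": str(write_image_stack(stack, outdir / "stack.tif")),
            "schedule": str(outdir / "schedule.csv"),
            "truth_trace": str(outdir / "truth_trace.csv"),
        }
        scalars = {"n_frames": cfg.n_frames,
                   "treatment_time_s": schedule[0][0]}
    else:  # compartments
        cfg = TimeSeriesPhantomConfig(**params)
        reporter, marker, labels = synthesize_compartment_movie(cfg)
        outputs = {
            "reporter": str(write_image_stack(reporter, outdir / "reporter.tif")),
            "marker": str(write_image_stack(marker, outdir / "marker.tif")),
            "truth_labels": str(write_label_stack(labels,
                                                  outdir / "truth_labels.tif",
                                                  cfg.pixel_size)),
        }
        scalars = {"n_frames": cfg.n_frames,
                   "n_puncta": int(labels.max())}
    cfg_echo = json.loads(cfg.model_dump_json(exclude={"roi", "rim_mask_override"}))
    (outdir / "config_echo.yaml").write_text(
        yaml.safe_dump(cfg_echo, sort_keys=True))
    outputs["config_echo"] = str(outdir / "config_echo.yaml")
    return ResultBundle(outputs=outputs, scalars=scalars)


def _task_quantify_confocal(config: RunConfig, outdir: Path) -> ResultBundle:
    p = _require(config.quantify, "quantify")
    if p.biosensor is None or p.reference is None:
        raise PipelineError("stage=quantify_confocal: need biosensor+reference")
    bio_stack = read_image_stack(p.biosensor, p.pixel_size, channel_label="biosensor")
    ref_stack = read_image_stack(p.reference, p.pixel_size, channel_label="reference")
    bio = subtract_camera_offset(bio_stack.frame(0), p.camera_offset)
    ref = subtract_camera_offset(ref_stack.frame(0), p.camera_offset)
    roi = read_roi(p.roi, bio.pixels.shape, bio.pixel_size)
    result = normalized_subtraction(bio, ref, roi, rim_width=p.rim_width)
    sub_stack = ImageStack(
        frames=result.subtracted.astype(np.float32)[None],
        pixel_size=bio.pixel_size, frame_interval=1.0,
        channel_label="subtracted",
    )
    outputs = {
        "subtracted": str(write_image_stack(sub_stack, outdir / "subtracted.tif")),
    }
    scalars = {
        "rim_mean": result.rim_mean,
        "roi_mean": result.roi_mean,
        "roi_area_px": result.roi.area,
        "rim_area_px": result.rim_band.area,
    }
    return ResultBundle(
        outputs=outputs, scalars=scalars,
        provenance={"input_digests": _input_digests(p.biosensor, p.reference,
                                                    p.roi)},
    )


def _read_treatments(path: Path | None) -> list[tuple[float, str]]:
    if path is None:
        return []
    df = pd.read_csv(path)
    if not {"time_s", "label"} <= set(df.columns):
        raise FormatError(f"{path}: treatment schedule needs time_s,label columns")
    return [(float(t), str(l)) for t, l in zip(df["time_s"], df["label"])]


def _timecourse_frame(tc, modes: list[str]) -> pd.DataFrame:
    for mode in modes:
        if mode not in tc.normalized:
            tc.add_normalization(mode)
    data = {"frame": np.arange(tc.n_frames), "t_s": tc.times, "raw": tc.raw}
    for mode in modes:
        data[mode] = tc.normalized[mode]
    return pd.DataFrame(data)


def _auc_scalars(tc, specs: list[AucSpec]) -> dict:
    out = {}
    for spec in specs:
        out[spec.name] = area_under_curve(
            tc, (spec.t_start, spec.t_end), baseline=spec.baseline,
            series=spec.series,
        )
    return out


def _task_quantify_tirf(config: RunConfig, outdir: Path) -> ResultBundle:
    p = _require(config.quantify, "quantify")
    if p.stack is None:
        raise PipelineError("stage=quantify_tirf: need a stack path")
    if not p.pre_frames:
        raise PipelineError("stage=quantify_tirf: need pre_frames")
    stack = read_image_stack(p.stack, p.pixel_size, p.frame_interval)
    stack = subtract_camera_offset(stack, p.camera_offset)
    roi = read_roi(p.roi, stack.frames.shape[1:], stack.pixel_size)
    raw = stack.frames[:, roi.mask].mean(axis=1)
    treatments = _read_treatments(p.treatments)
    tc = normalize_timecourse(
        raw, p.pre_frames, mode=p.modes[0], times=stack.times,
        treatments=treatments,
    )
    df = _timecourse_frame(tc, p.modes)
    df.to_csv(outdir / "timecourse.csv", index=False)
    scalars = {"n_frames": tc.n_frames, "auc": _auc_scalars(tc, p.auc)}
    return ResultBundle(
        outputs={"timecourse": str(outdir / "timecourse.csv")},
        scalars=scalars,
        provenance={"input_digests": _input_digests(p.stack, p.roi,
                                                    p.treatments)},
    )


def _task_quantify_compartments(config: RunConfig, outdir: Path) -> ResultBundle:
    p = _require(config.quantify, "quantify")
    if p.reporter is None or p.marker is None:
        raise PipelineError("stage=quantify_compartments: need reporter+marker")
    if not p.pre_frames:
        raise PipelineError("stage=quantify_compartments: need pre_frames")
    reporter = subtract_camera_offset(
        read_image_stack(p.reporter, p.pixel_size, p.frame_interval),
        p.camera_offset)
    marker = subtract_camera_offset(
        read_image_stack(p.marker, p.pixel_size, p.frame_interval),
        p.camera_offset)
    roi = read_roi(p.roi, reporter.frames.shape[1:], reporter.pixel_size)
    tc = masked_intensity_timecourse(
        reporter, marker, roi, p.pre_frames,
        method=p.mask_method, min_size=p.min_size,
        fixed_threshold=p.fixed_threshold,
        recompute_mask_per_frame=p.recompute_mask_per_frame,
        treatments=_read_treatments(p.treatments),
    )
    df = _timecourse_frame(tc, p.modes)
    df.to_csv(outdir / "timecourse.csv", index=False)
    missing = int(np.sum(~np.isfinite(tc.raw)))
    scalars = {
        "n_frames": tc.n_frames,
        "n_missing_frames": missing,
        "auc": _auc_scalars(tc, p.auc),
        "mask_method": p.mask_method,
    }
    return ResultBundle(
        outputs={"timecourse": str(outdir / "timecourse.csv")},
        scalars=scalars,
        provenance={"input_digests": _input_digests(p.reporter, p.marker,
                                                    p.roi)},
    )
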