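"""Synthetic single-molecule trajectories and microscopy phantoms.

The generators here produce data with exactly the statistical structure the
downstream analyses assume, so every stage of the pipeline can be tested
against known ground truth:

* ``simulate_membrane_spt`` — 2D Brownian trajectories of membrane-bound
  probes observed at a fixed frame interval.  Each molecule's dwell on the
  membrane is exponential with observed rate k_obs = k_off + β·P (true
  dissociation plus power-proportional photobleaching); the dwell is
  quantized onto the frame grid and single-frame appearances are discarded,
  mirroring the shortest trackable event.  Reported positions carry i.i.d.
  Gaussian localization error.
* ``synthesize_confocal_pair`` — a two-channel confocal phantom: a uniform
  cytosolic reference and a biosensor channel enriched on a peripheral rim.
* ``synthesize_tirf_timecourse`` — a TIRF footprint whose ROI intensity
  follows a step or exponential kinetic change after a treatment frame.
* ``synthesize_compartment_movie`` — a marker channel with constant bright
  puncta plus a reporter channel that is recruited to the puncta after
  treatment.

All generators are fully deterministic given their seed; one master seed
spawns independent substreams per cell/channel/frame so outputs are stable
under parallel-friendly generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .quant import ChannelImage, ImageStack, RoiMask, erode_mask, rim_band

__all__ = [
    "ConfigurationError",
    "SPTSimConfig",
    "Trajectory",
    "CellTrackSet",
    "ConfocalPhantomConfig",
    "TimeSeriesPhantomConfig",
    "Kinetics",
    "PunctaSpec",
    "simulate_membrane_spt",
    "sample_dwell_times",
    "synthesize_confocal_pair",
    "synthesize_tirf_timecourse",
    "synthesize_compartment_movie",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is invalid."""


# ---------------------------------------------------------------------------
# trajectory containers
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """One molecule's time-stamped 2D positions on the membrane.

    ``frames`` are strictly increasing, contiguous integers; ``x``/``y`` are
    reported positions in µm.  ``censored`` marks tracks ended by leaving the
    field of view rather than by dissociation/bleaching.  ``dwell_s`` carries
    the ground-truth continuous dwell time when the track was simulated.
    """

    track_id: str
    frame_interval: float
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    censored: bool = False
    dwell_s: Optional[float] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.frames.size
        if n < 2:
            raise ValueError("a trajectory needs at least 2 points")
        if not (self.x.size == n and self.y.size == n):
            raise ValueError("frames, x, y must have equal length")
        d = np.diff(self.frames)
        if np.any(d != 1):
            raise ValueError("frame indices must be contiguous and increasing")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return int(self.frames.size)

    @property
    def duration_s(self) -> float:
        """Observed duration, (n_frames − 1)·Δt."""
        return (self.n_frames - 1) * self.frame_interval

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack((self.x, self.y))


@dataclass
class CellTrackSet:
    """All trajectories from one cell imaged at one illumination power."""

    cell_id: str
    power: float
    trajectories: list[Trajectory]
    ground_truth: Optional["SPTSimConfig"] = None

    def __post_init__(self) -> None:
        if self.trajectories:
            dt = self.trajectories[0].frame_interval
            if any(abs(t.frame_interval - dt) > 1e-12 for t in self.trajectories):
                raise ValueError("all trajectories in a cell share one frame_interval")

    @property
    def frame_interval(self) -> float:
        if not self.trajectories:
            raise ValueError("empty track set")
        return self.trajectories[0].frame_interval

    @property
    def n_tracks(self) -> int:
        return len(self.trajectories)


# ---------------------------------------------------------------------------
# SPT simulation
# ---------------------------------------------------------------------------

class SPTSimConfig(BaseModel):
    """Ground-truth parameters for the membrane SPT simulator.

    Defaults are the conditions of the experiment the simulator emulates:
    D = 0.3 µm²/s, membrane lifetime 140 ms, 16.7 Hz imaging (Δt = 60 ms),
    20 nm localization error, 16 µm square field of view.
    """

    model_config = ConfigDict(extra="forbid")

    diffusion_coeff: float = 0.3          # µm²/s
    k_off_true: float = 1.0 / 0.140       # 1/s
    bleach_coeff: float = 0.0             # 1/s per power-unit
    powers: tuple[float, ...] = (30.0,)   # arbitrary power units
    frame_interval: float = 0.060         # s
    localization_sigma: float = 0.020     # µm per axis
    fov_size: float = 16.0                # µm
    n_cells: int = 10
    tracks_per_cell: int = 300
    min_track_frames: int = 2
    boundary_mode: Literal["unbounded", "censor_at_fov", "reflecting_box"] = "unbounded"
    box_size: Optional[float] = None      # µm, reflecting_box only
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SPTSimConfig":
        if not (self.diffusion_coeff >= 0 and math.isfinite(self.diffusion_coeff)):
            raise ConfigurationError("diffusion_coeff must be finite and >= 0")
        if not (self.k_off_true > 0 and math.isfinite(self.k_off_true)):
            raise ConfigurationError("k_off_true must be finite and > 0")
        if not (self.bleach_coeff >= 0 and math.isfinite(self.bleach_coeff)):
            raise ConfigurationError("bleach_coeff must be finite and >= 0")
        if not self.frame_interval > 0:
            raise ConfigurationError("frame_interval must be > 0")
        if len(self.powers) == 0 or any(p < 0 for p in self.powers):
            raise ConfigurationError("powers must be non-empty and all >= 0")
        if self.min_track_frames < 2:
            raise ConfigurationError("min_track_frames must be >= 2")
        if self.localization_sigma < 0:
            raise ConfigurationError("localization_sigma must be >= 0")
        if self.fov_size <= 0:
            raise ConfigurationError("fov_size must be > 0")
        if self.n_cells < 1 or self.tracks_per_cell < 1:
            raise ConfigurationError("n_cells and tracks_per_cell must be >= 1")
        if self.boundary_mode == "reflecting_box" and not (
            self.box_size and self.box_size > 0
        ):
            raise ConfigurationError("reflecting_box requires box_size > 0")
        return self


def sample_dwell_times(k_obs: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` continuous membrane dwell times from Exponential(k_obs)."""
    if not (k_obs > 0 and math.isfinite(k_obs)):
        raise ConfigurationError("dwell rate must be finite and > 0")
    return rng.exponential(1.0 / k_obs, size=n)


def _reflect(p: np.ndarray, size: float) -> np.ndarray:
    # triangular fold of an unbounded walk into [0, size]
    period = 2.0 * size
    return size - np.abs(np.mod(p, period) - size)


def _render_track(
    rng: np.random.Generator, cfg: SPTSimConfig, n_frames: int, dwell: float,
    track_id: str,
) -> Optional[Trajectory]:
    step_sd = math.sqrt(2.0 * cfg.diffusion_coeff * cfg.frame_interval)
    if cfg.boundary_mode == "reflecting_box":
        start = rng.uniform(0.0, cfg.box_size, size=2)
    else:
        start = rng.uniform(0.0, cfg.fov_size, size=2)
    steps = rng.normal(0.0, step_sd, size=(n_frames - 1, 2)) if n_frames > 1 else \
        np.empty((0, 2))
    pos = np.vstack((start, start + np.cumsum(steps, axis=0)))
    censored = False
    if cfg.boundary_mode == "reflecting_box":
        pos = _reflect(pos, cfg.box_size)
    elif cfg.boundary_mode == "censor_at_fov":
        outside = np.any((pos < 0.0) | (pos > cfg.fov_size), axis=1)
        if outside.any():
            first = int(np.argmax(outside))
            if first < cfg.min_track_frames:
                return None
            pos = pos[:first]
            n_frames = first
            censored = True
    noise = rng.normal(0.0, cfg.localization_sigma, size=pos.shape) \
        if cfg.localization_sigma > 0 else 0.0
    obs = pos + noise
    return Trajectory(
        track_id=track_id,
        frame_interval=cfg.frame_interval,
        frames=np.arange(n_frames),
        x=obs[:, 0],
        y=obs[:, 1],
        censored=censored,
        dwell_s=dwell,
    )


def simulate_membrane_spt(config: SPTSimConfig) -> list[CellTrackSet]:
    """Simulate membrane-bound single-molecule trajectories.

    For every (power, cell) pair, dwell times are drawn from
    Exponential(k_off_true + bleach_coeff·power), converted to observed frame
    counts ``floor(dwell/Δt) + 1`` and redrawn while shorter than
    ``min_track_frames`` until ``tracks_per_cell`` tracks are retained.
    Positions start uniform in the field of view, evolve by per-axis Gaussian
    steps of variance 2·D·Δt and are reported with additive Gaussian
    localization error.

    Returns one :class:`CellTrackSet` per cell per power, ordered by power
    then cell.  Bit-identical output for identical config (the master seed
    spawns one substream per cell).
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(config.powers) * config.n_cells)
    cells: list[CellTrackSet] = []
    idx = 0
    for pi, power in enumerate(config.powers):
        k_obs = config.k_off_true + config.bleach_coeff * power
        if not (k_obs > 0 and math.isfinite(k_obs)):
            raise ConfigurationError(f"observed rate at power {power} is invalid")
        for ci in range(config.n_cells):
            rng = np.random.default_rng(children[idx])
            idx += 1
            trajectories: list[Trajectory] = []
            attempts = 0
            limit = 10_000 * config.tracks_per_cell + 10_000
            while len(trajectories) < config.tracks_per_cell:
                attempts += 1
                if attempts > limit:
                    raise RuntimeError(
                        "could not retain enough tracks; dwell times almost "
                        "always shorter than min_track_frames"
                    )
                dwell = float(rng.exponential(1.0 / k_obs))
                n_frames = int(math.floor(dwell / config.frame_interval)) + 1
                if n_frames < config.min_track_frames:
                    continue
                traj = _render_track(
                    rng, config, n_frames, dwell,
                    track_id=f"t{len(trajectories):05d}",
                )
                if traj is None:
                    continue
                trajectories.append(traj)
            cells.append(CellTrackSet(
                cell_id=f"p{pi}c{ci:02d}",
                power=power,
                trajectories=trajectories,
                ground_truth=config,
            ))
    return cells


# ---------------------------------------------------------------------------
# confocal two-channel phantom
# ---------------------------------------------------------------------------

class ConfocalPhantomConfig(BaseModel):
    """Two-channel confocal phantom: cytosolic reference + rim-enriched biosensor.

    ``roi`` is either a polygon (list of [x_um, y_um] vertices) or an explicit
    boolean mask congruent with ``image_shape``.  The rim defaults to the ROI
    minus the ROI eroded by ``rim_width``; ``rim_mask_override`` substitutes an
    arbitrary in-ROI rim geometry.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True, extra="forbid")

    image_shape: tuple[int, int] = (128, 128)
    pixel_size: float = 0.1               # µm
    roi: object = None                    # polygon vertices (µm) or bool mask
    rim_width: int = 5                    # px
    cytosol_level: float = 100.0          # counts
    rim_enrichment: float = 2.0
    background_level: float = 0.0         # counts
    camera_offset: float = 0.0            # counts
    noise_model: Literal["none", "poisson", "gaussian"] = "none"
    noise_sigma: float = 0.0              # counts, gaussian only
    rim_mask_override: Optional[np.ndarray] = None
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ConfocalPhantomConfig":
        if self.rim_enrichment < 0:
            raise ConfigurationError("rim_enrichment must be >= 0")
        if self.rim_width < 1:
            raise ConfigurationError("rim_width must be >= 1")
        for name in ("cytosol_level", "background_level", "camera_offset"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not self.pixel_size > 0:
            raise ConfigurationError("pixel_size must be > 0")
        return self


def resolve_roi(roi, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    """Turn a polygon ([x_um, y_um] vertices) or boolean mask into a mask.

    Polygons are rasterized with pixel-center inclusion; x maps to columns,
    y to rows, physical coordinates at pixel centers.
    """
    if roi is None:
        raise ConfigurationError("an ROI is required")
    arr = np.asarray(roi)
    if arr.dtype == bool or (arr.ndim == 2 and arr.shape == tuple(shape)):
        mask = arr.astype(bool)
        if mask.shape != tuple(shape):
            raise ConfigurationError("ROI mask shape does not match image_shape")
    else:
        from skimage.draw import polygon2mask
        verts = np.asarray(roi, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2:
            raise ConfigurationError("polygon ROI must be an (N, 2) vertex list")
        rc = np.column_stack((verts[:, 1], verts[:, 0])) / pixel_size
        mask = polygon2mask(tuple(shape), rc)
    if not mask.any():
        raise ConfigurationError("ROI area is zero")
    return mask


def _apply_noise(signal: np.ndarray, cfg, rng: np.random.Generator) -> np.ndarray:
    """Noise on the offset-free signal; the camera offset is added after."""
    if cfg.noise_model == "none":
        return signal
    if cfg.noise_model == "poisson":
        return rng.poisson(signal).astype(float)
    return signal + rng.normal(0.0, cfg.noise_sigma, size=signal.shape)


def synthesize_confocal_pair(
    config: ConfocalPhantomConfig,
) -> tuple[ChannelImage, ChannelImage, RoiMask, RoiMask]:
    """Render the (biosensor, reference) confocal pair with ground-truth masks.

    Reference channel: ``cytosol_level`` inside the ROI, ``background_level``
    outside, plus ``camera_offset``.  Biosensor channel: identical except rim
    pixels carry ``cytosol_level × rim_enrichment``.
    """
    roi = resolve_roi(config.roi, config.image_shape, config.pixel_size)
    if config.rim_mask_override is not None:
        rim = np.asarray(config.rim_mask_override, dtype=bool)
        if rim.shape != roi.shape or np.any(rim & ~roi):
            raise ConfigurationError("rim_mask_override must lie inside the ROI")
    else:
        rim = rim_band(roi, config.rim_width)
    base = np.where(roi, config.cytosol_level, config.background_level).astype(float)
    bio = base.copy()
    bio[rim] *= config.rim_enrichment
    ss = np.random.SeedSequence(config.seed)
    rng_b, rng_r = (np.random.default_rng(s) for s in ss.spawn(2))
    bio = _apply_noise(bio, config, rng_b) + config.camera_offset
    ref = _apply_noise(base, config, rng_r) + config.camera_offset
    mk = lambda px, label: ChannelImage(
        pixels=px.astype(np.float32), pixel_size=config.pixel_size,
        channel_label=label, camera_offset=config.camera_offset,
    )
    return (
        mk(bio, "biosensor"),
        mk(ref, "reference"),
        RoiMask(roi, "ground_truth"),
        RoiMask(rim, "ground_truth", allow_empty=True),
    )


# ---------------------------------------------------------------------------
# time-series phantoms (TIRF footprint and compartment movies)
# ---------------------------------------------------------------------------

class Kinetics(BaseModel):
    """Kinetic model of the post-treatment intensity change.

    The relative level r(t) multiplying the pre-treatment intensity is::

        step:                r = plateau                     (t >= t_treat)
        exponential_decay:   r = plateau + (1-plateau)·exp(-k·(t-t_treat))
        exponential_rise:    same expression with plateau > 1

    so r(t_treat) = 1 and r(∞) = plateau in all cases.
    """

    model_config = ConfigDict(extra="forbid")
    kind: Literal["step", "exponential_decay", "exponential_rise"]
    k: Optional[float] = None             # 1/s
    plateau: float = 0.0                  # fraction of the pre level

    @model_validator(mode="after")
    def _check(self) -> "Kinetics":
        if self.plateau < 0:
            raise ConfigurationError("plateau must be >= 0")
        if self.kind != "step" and not (self.k and self.k > 0):
            raise ConfigurationError("exponential kinetics require k > 0")
        return self

    def relative_level(self, t_after: np.ndarray) -> np.ndarray:
        """r(t) for times measured from the treatment (t_after >= 0)."""
        t_after = np.asarray(t_after, dtype=float)
        if self.kind == "step":
            return np.full_like(t_after, self.plateau)
        return self.plateau + (1.0 - self.plateau) * np.exp(-self.k * t_after)


class PunctaSpec(BaseModel):
    """Punctate-compartment layout and reporter recruitment."""

    model_config = ConfigDict(extra="forbid")
    n_puncta: int = 12
    radius_px: int = 3
    marker_level: float = 200.0
    recruitment: float = 3.0              # reporter multiplier at plateau
    kinetics: Kinetics = Kinetics(kind="step", plateau=1.0)

    @model_validator(mode="after")
    def _check(self) -> "PunctaSpec":
        if self.n_puncta < 1 or self.radius_px < 1:
            raise ConfigurationError("n_puncta and radius_px must be >= 1")
        if self.recruitment < 0 or self.marker_level < 0:
            raise ConfigurationError("levels must be >= 0")
        return self


class TimeSeriesPhantomConfig(ConfocalPhantomConfig):
    """Confocal phantom extended with a time axis and a treatment event."""

    n_frames: int = 40
    frame_interval: float = 2.0           # s
    treatment_frame: int = 10
    kinetics: Kinetics = Kinetics(kind="exponential_decay", k=0.05, plateau=0.2)
    puncta: Optional[PunctaSpec] = None

    @model_validator(mode="after")
    def _check_time(self) -> "TimeSeriesPhantomConfig":
        if not (0 < self.treatment_frame < self.n_frames):
            raise ConfigurationError("need 0 < treatment_frame < n_frames")
        return self

    def relative_trace(self) -> np.ndarray:
        """Ground-truth relative ROI level per frame (1 before treatment)."""
        r = np.ones(self.n_frames)
        post = np.arange(self.treatment_frame, self.n_frames)
        r[post] = self.kinetics.relative_level(
            (post - self.treatment_frame) * self.frame_interval
        )
        return r


def synthesize_tirf_timecourse(
    config: TimeSeriesPhantomConfig,
) -> tuple[ImageStack, list[tuple[float, str]], np.ndarray]:
    """Render a TIRF footprint movie with a kinetic change after treatment.

    Returns the stack, the treatment schedule ``[(time_s, label)]`` and the
    ground-truth offset-free per-frame ROI mean.
    """
    roi = resolve_roi(config.roi, config.image_shape, config.pixel_size)
    rel = config.relative_trace()
    truth = config.cytosol_level * rel
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(config.n_frames)
    frames = np.empty((config.n_frames, *config.image_shape), dtype=np.float32)
    for t in range(config.n_frames):
        base = np.where(roi, truth[t], config.background_level).astype(float)
        rng = np.random.default_rng(streams[t])
        frames[t] = (_apply_noise(base, config, rng) + config.camera_offset)
    stack = ImageStack(
        frames=frames, pixel_size=config.pixel_size,
        frame_interval=config.frame_interval, channel_label="biosensor",
        camera_offset=config.camera_offset,
    )
    schedule = [(config.treatment_frame * config.frame_interval, "treatment")]
    return stack, schedule, truth


def _place_puncta(
    roi: np.ndarray, spec: PunctaSpec, rng: np.random.Generator,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Label image of non-overlapping disks inside the ROI (rejection sampling)."""
    h, w = roi.shape
    r = spec.radius_px
    interior = erode_mask(roi, r) if r >= 1 else roi
    rows, cols = np.nonzero(interior)
    if rows.size == 0:
        raise ConfigurationError("ROI too small for the requested puncta radius")
    yy, xx = np.mgrid[0:h, 0:w]
    labels = np.zeros(roi.shape, dtype=np.uint16)
    centers: list[tuple[int, int]] = []
    tries = 0
    while len(centers) < spec.n_puncta:
        tries += 1
        if tries > max_tries:
            raise ConfigurationError(
                f"could not place {spec.n_puncta} non-overlapping puncta "
                f"after {max_tries} tries"
            )
        i = rng.integers(rows.size)
        cy, cx = int(rows[i]), int(cols[i])
        if any((cy - y) ** 2 + (cx - x) ** 2 <= (2 * r + 1) ** 2 for y, x in centers):
            continue
        centers.append((cy, cx))
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        labels[disk] = len(centers)
    return labels


def synthesize_compartment_movie(
    config: TimeSeriesPhantomConfig,
) -> tuple[ImageStack, ImageStack, np.ndarray]:
    """Render (reporter, marker) stacks plus per-frame ground-truth labels.

    The marker channel shows constant bright puncta (``puncta.marker_level``)
    on the dim in-ROI level (``cytosol_level``).  The reporter is uniform at
    ``cytosol_level`` inside the ROI; after the treatment frame its puncta
    pixels are multiplied by a recruitment factor that follows
    ``puncta.kinetics`` from 1 toward ``puncta.recruitment``.
    """
    if config.puncta is None:
        raise ConfigurationError("puncta spec required for a compartment movie")
    spec = config.puncta
    roi = resolve_roi(config.roi, config.image_shape, config.pixel_size)
    ss = np.random.SeedSequence(config.seed)
    place_stream, *frame_streams = ss.spawn(1 + 2 * config.n_frames)
    labels = _place_puncta(roi, spec, np.random.default_rng(place_stream))
    puncta_mask = labels > 0

    # recruitment multiplier per frame: 1 pre-treatment, kinetics-driven after
    mult = np.ones(config.n_frames)
    post = np.arange(config.treatment_frame, config.n_frames)
    kin = spec.kinetics.model_copy(update={"plateau": spec.recruitment}) \
        if spec.kinetics.kind != "step" else \
        Kinetics(kind="step", plateau=spec.recruitment)
    mult[post] = kin.relative_level(
        (post - config.treatment_frame) * config.frame_interval
    )

    marker_base = np.where(roi, config.cytosol_level, config.background_level)
    marker_base = marker_base.astype(float)
    marker_base[puncta_mask] = spec.marker_level
    rep_base = np.where(roi, config.cytosol_level, config.background_level)
    rep_base = rep_base.astype(float)

    shape = (config.n_frames, *config.image_shape)
    reporter = np.empty(shape, dtype=np.float32)
    marker = np.empty(shape, dtype=np.float32)
    for t in range(config.n_frames):
        rep_t = rep_base.copy()
        rep_t[puncta_mask] *= mult[t]
        rng_rep = np.random.default_rng(frame_streams[2 * t])
        rng_mark = np.random.default_rng(frame_streams[2 * t + 1])
        reporter[t] = _apply_noise(rep_t, config, rng_rep) + config.camera_offset
        marker[t] = _apply_noise(marker_base, config, rng_mark) + config.camera_offset
    mk = lambda fr, label: ImageStack(
        frames=fr, pixel_size=config.pixel_size,
        frame_interval=config.frame_interval, channel_label=label,
        camera_offset=config.camera_offset,
    )
    truth_labels = np.broadcast_to(labels, shape).copy()
    return mk(reporter, "reporter"), mk(marker, "marker"), truth_labels
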