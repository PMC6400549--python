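"""Fluorescence image and time-course quantification for lipid biosensors.

This module quantifies where a biosensor sits in a cell and how that changes
after an acute perturbation:

* **Normalized channel subtraction** — each channel (biosensor and a cytosolic
  reference) is divided by its own mean over the cell ROI, and the normalized
  reference is subtracted from the normalized biosensor.  Plasma-membrane
  enrichment then shows up as a positive rim at the cell periphery while the
  ROI mean of the difference is zero by construction.
* **Compartment masks** — an organelle marker channel is auto-thresholded
  (Otsu by default) inside the ROI to build a mask, and the biosensor
  intensity inside that mask, ratioed to the whole-ROI mean, tracks
  recruitment to the compartment over time.
* **Time-course normalizations** — per-frame ROI intensities are expressed as
  F_t/F_pre (ratio to the pre-treatment baseline), min–max scaled, or as
  ΔF/|ΔF|_max, and summarized by baseline-referenced area under the curve.

All intensities are camera-offset subtracted before any ratio is formed, so
every output is invariant to multiplying a channel by a positive scalar
(exposure, gain, expression level).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

__all__ = [
    "ChannelImage",
    "ImageStack",
    "RoiMask",
    "SubtractionResult",
    "TimeCourse",
    "subtract_camera_offset",
    "normalized_subtraction",
    "compartment_mask",
    "masked_intensity_timecourse",
    "normalize_timecourse",
    "area_under_curve",
]

NORMALIZATION_MODES = ("f_over_fpre", "minmax", "delta_over_deltamax")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ChannelImage:
    """A single calibrated 2D fluorescence frame.

    Parameters
    ----------
    pixels
        2D array of counts.
    pixel_size
        Physical pixel edge length in µm.
    channel_label
        Free-text channel name (e.g. ``"EGFP-cPHx3"``).
    camera_offset
        Offset that was (or is to be) subtracted, in counts.
    offset_subtracted
        True once :func:`subtract_camera_offset` has been applied.
    """

    pixels: np.ndarray
    pixel_size: float
    channel_label: str = ""
    camera_offset: float = 0.0
    offset_subtracted: bool = False
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("ChannelImage.pixels must be a non-empty 2D array")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")


@dataclass
class ImageStack:
    """An ordered stack of frames from one channel (T, H, W)."""

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    channel_label: str = ""
    camera_offset: float = 0.0
    offset_subtracted: bool = False
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.size == 0:
            raise ValueError("ImageStack.frames must be a non-empty (T, H, W) array")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def frame(self, index: int) -> ChannelImage:
        return ChannelImage(
            pixels=self.frames[index],
            pixel_size=self.pixel_size,
            channel_label=self.channel_label,
            camera_offset=self.camera_offset,
            offset_subtracted=self.offset_subtracted,
        )


@dataclass
class RoiMask:
    """A binary region mask congruent with its image.

    ``provenance`` records where the mask came from (``user_polygon``,
    ``label_mask_file``, ``ground_truth``, ``autothreshold``).  An empty mask
    is only representable when ``allow_empty`` is set (compartment masks can
    legitimately be empty on a frame; ROIs cannot).
    """

    mask: np.ndarray
    provenance: str = "user_polygon"
    allow_empty: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("RoiMask.mask must be 2D")
        if not self.allow_empty and not self.mask.any():
            raise ValueError("RoiMask must contain at least one pixel")

    @property
    def empty(self) -> bool:
        return not bool(self.mask.any())

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class SubtractionResult:
    """Output of :func:`normalized_subtraction`.

    ``subtracted`` is dimensionless (difference of per-ROI-normalized
    channels); ``roi_mean`` is ≈ 0 by construction and reported as a
    self-check.
    """

    subtracted: np.ndarray
    roi: RoiMask
    rim_band: RoiMask
    rim_mean: float
    roi_mean: float


@dataclass
class TimeCourse:
    """Per-frame ROI intensity trace with its normalization variants.

    ``raw`` holds offset-subtracted mean ROI counts (or a mask/ROI intensity
    ratio for compartment traces); ``normalized`` maps mode name →
    dimensionless per-frame series.  Missing frames (e.g. empty compartment
    masks) are NaN, never zero.
    """

    times: np.ndarray
    raw: np.ndarray
    pre_frames: np.ndarray
    normalized: dict[str, np.ndarray] = field(default_factory=dict)
    treatments: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        self.pre_frames = np.asarray(self.pre_frames, dtype=int)
        if self.times.shape != self.raw.shape:
            raise ValueError("times and raw must have equal length")
        if self.pre_frames.size == 0:
            raise ValueError("pre_frames must be non-empty")
        if self.pre_frames.max() >= self.raw.size:
            raise ValueError("pre_frames out of range")
        for t_treat, _ in self.treatments:
            if np.any(self.times[self.pre_frames] >= t_treat):
                raise ValueError("pre_frames must precede all treatments")

    @property
    def n_frames(self) -> int:
        return int(self.raw.size)

    def add_normalization(self, mode: str) -> np.ndarray:
        """Compute and store one normalization mode; returns the series."""
        series = _normalize(self.raw, self.pre_frames, mode)
        self.normalized[mode] = series
        return series


# ---------------------------------------------------------------------------
# camera offset
# ---------------------------------------------------------------------------

def subtract_camera_offset(image, offset: float):
    """Subtract the camera offset (dark level) from an image or stack.

    Pixels that would go negative are floored at 0 and counted in
    ``n_clipped``.  Applying the subtraction twice is an error.

    Parameters
    ----------
    image : ChannelImage or ImageStack
    offset : counts, ≥ 0

    Returns
    -------
    A new object of the same type with ``offset_subtracted`` set.
    """
    if offset < 0:
        raise ValueError("camera offset must be >= 0")
    if image.offset_subtracted:
        raise ValueError("camera offset already subtracted from this image")
    if isinstance(image, ImageStack):
        data = image.frames
    else:
        data = image.pixels
    out = np.asarray(data, dtype=float) - offset
    n_clipped = int((out < 0).sum())
    np.clip(out, 0.0, None, out=out)
    if isinstance(image, ImageStack):
        return ImageStack(
            frames=out, pixel_size=image.pixel_size,
            frame_interval=image.frame_interval,
            channel_label=image.channel_label, camera_offset=offset,
            offset_subtracted=True, n_clipped=n_clipped,
        )
    return ChannelImage(
        pixels=out, pixel_size=image.pixel_size,
        channel_label=image.channel_label, camera_offset=offset,
        offset_subtracted=True, n_clipped=n_clipped,
    )


# ---------------------------------------------------------------------------
# normalized channel subtraction
# ---------------------------------------------------------------------------

def erode_mask(mask: np.ndarray, width: int) -> np.ndarray:
    """Binary erosion by ``width`` pixels (3×3 full structuring element)."""
    if width < 1:
        raise ValueError("erosion width must be >= 1")
    return ndimage.binary_erosion(
        mask, structure=np.ones((3, 3), dtype=bool), iterations=int(width)
    )


def rim_band(roi: np.ndarray, rim_width: int) -> np.ndarray:
    """Peripheral band of a mask: ROI minus ROI eroded by ``rim_width``."""
    return roi & ~erode_mask(roi, rim_width)


def normalized_subtraction(
    biosensor: ChannelImage,
    reference: ChannelImage,
    roi: RoiMask,
    rim_width: int = 5,
) -> SubtractionResult:
    """Subtract the normalized cytosolic reference from the biosensor channel.

    Each channel is divided by its own mean over the ROI, then the reference
    is subtracted from the biosensor.  A uniformly distributed (cytosolic)
    biosensor gives 0 everywhere; plasma-membrane enrichment shows up as a
    positive peripheral rim.  ``rim_mean`` — the mean of the subtracted image
    over a morphological rim band of width ``rim_width`` — is the headline
    scalar for peripheral enrichment.

    The ROI mean of the subtracted image is 0 by construction and is reported
    as a numerical self-check.

    Raises
    ------
    ValueError
        If shapes differ, either channel is not offset-subtracted, an ROI
        mean is ≤ 0, or the rim erosion empties the ROI.
    """
    if biosensor.pixels.shape != reference.pixels.shape:
        raise ValueError("channel shapes differ")
    if roi.mask.shape != biosensor.pixels.shape:
        raise ValueError("ROI mask not congruent with image")
    if not (biosensor.offset_subtracted and reference.offset_subtracted):
        raise ValueError("subtract the camera offset from both channels first")
    m = roi.mask
    mean_b = float(biosensor.pixels[m].mean())
    mean_r = float(reference.pixels[m].mean())
    if mean_b <= 0 or mean_r <= 0:
        raise ValueError("ROI mean must be > 0 in both channels")
    sub = biosensor.pixels / mean_b - reference.pixels / mean_r
    interior = erode_mask(m, rim_width)
    if not interior.any():
        raise ValueError(f"rim erosion by {rim_width} px empties the ROI")
    band = m & ~interior
    if not band.any():
        raise ValueError("rim band is empty")
    return SubtractionResult(
        subtracted=sub,
        roi=roi,
        rim_band=RoiMask(band, provenance="ground_truth"),
        rim_mean=float(sub[band].mean()),
        roi_mean=float(sub[m].mean()),
    )


# ---------------------------------------------------------------------------
# compartment masks and masked traces
# ---------------------------------------------------------------------------

def compartment_mask(
    marker: ChannelImage,
    roi: RoiMask,
    method: str = "otsu",
    min_size: int = 4,
    fixed_threshold: float | None = None,
) -> RoiMask:
    """Auto-threshold a marker channel inside the ROI to build a mask.

    ``method="otsu"`` (default) maximizes between-class variance of the
    in-ROI marker histogram; ``method="fixed"`` uses ``fixed_threshold``.
    Pixels strictly above the threshold are foreground.  Connected
    components (8-connectivity) smaller than ``min_size`` pixels are
    removed.  An empty result is returned flagged, not raised: downstream
    trace operations record a missing value for that frame.
    """
    if not marker.offset_subtracted:
        raise ValueError("subtract the camera offset from the marker first")
    if roi.mask.shape != marker.pixels.shape:
        raise ValueError("ROI mask not congruent with marker image")
    vals = marker.pixels[roi.mask]
    if method == "otsu":
        if np.ptp(vals) == 0:
            # uniform marker: nothing to threshold
            return RoiMask(np.zeros_like(roi.mask), "autothreshold", allow_empty=True)
        iv = np.round(vals).astype(np.int64)
        if np.allclose(vals, iv) and 0 < np.ptp(iv) < 65536:
            # integer-valued data: exact per-value histogram, so the
            # threshold respects the image > t foreground convention
            lo = int(iv.min())
            counts = np.bincount(iv - lo)
            centers = (np.arange(counts.size) + lo).astype(float)
            thresh = float(threshold_otsu(hist=(counts, centers)))
        else:
            thresh = float(threshold_otsu(vals))
    elif method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed_threshold required for method='fixed'")
        thresh = float(fixed_threshold)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    mask = (marker.pixels > thresh) & roi.mask
    if min_size > 1 and mask.any():
        # max_size removes components of size <= value, i.e. < min_size
        mask = remove_small_objects(mask, max_size=int(min_size) - 1, connectivity=2)
    return RoiMask(mask, "autothreshold", allow_empty=True)


def masked_intensity_timecourse(
    reporter: ImageStack,
    marker: ImageStack,
    roi: RoiMask,
    pre_frames: Sequence[int] | np.ndarray,
    method: str = "otsu",
    min_size: int = 4,
    fixed_threshold: float | None = None,
    recompute_mask_per_frame: bool = True,
    treatments: Iterable[tuple[float, str]] = (),
) -> TimeCourse:
    """Reporter intensity in a marker-derived mask, ratioed to the ROI mean.

    Per frame, ``raw`` = mean(reporter | mask) / mean(reporter | ROI); the
    ratio cancels expression level and photobleaching.  The series is then
    baseline-normalized as F_t/F_pre over ``pre_frames``.  Frames whose mask
    is empty carry NaN.

    By default the mask is recomputed on every marker frame (compartments
    move); ``recompute_mask_per_frame=False`` freezes the first frame's mask.
    """
    if reporter.frames.shape != marker.frames.shape:
        raise ValueError("reporter and marker stacks must be congruent")
    n = reporter.n_frames
    ratios = np.full(n, np.nan)
    frozen: RoiMask | None = None
    for t in range(n):
        if recompute_mask_per_frame or frozen is None:
            cmask = compartment_mask(
                marker.frame(t), roi, method=method, min_size=min_size,
                fixed_threshold=fixed_threshold,
            )
            if not recompute_mask_per_frame:
                frozen = cmask
        else:
            cmask = frozen
        if cmask.empty:
            continue
        rep = reporter.frames[t]
        roi_mean = float(rep[roi.mask].mean())
        if roi_mean <= 0:
            continue
        ratios[t] = float(rep[cmask.mask].mean()) / roi_mean
    return normalize_timecourse(
        ratios, pre_frames, mode="f_over_fpre", times=reporter.times,
        treatments=treatments,
    )


# ---------------------------------------------------------------------------
# time-course normalization and AUC
# ---------------------------------------------------------------------------

def _normalize(raw: np.ndarray, pre: np.ndarray, mode: str) -> np.ndarray:
    if mode == "f_over_fpre":
        f_pre = np.nanmean(raw[pre])
        if not np.isfinite(f_pre) or f_pre == 0:
            raise ValueError("pre-treatment mean is zero or undefined")
        return raw / f_pre
    if mode == "minmax":
        lo, hi = np.nanmin(raw), np.nanmax(raw)
        if not hi > lo:
            raise ValueError("constant trace: min-max normalization is degenerate")
        return (raw - lo) / (hi - lo)
    if mode == "delta_over_deltamax":
        f_pre = np.nanmean(raw[pre])
        if not np.isfinite(f_pre):
            raise ValueError("pre-treatment mean undefined")
        delta = raw - f_pre
        dmax = np.nanmax(np.abs(delta))
        if not dmax > 0:
            raise ValueError("no change from baseline: ΔF/ΔF_max is degenerate")
        return delta / dmax
    raise ValueError(f"unknown normalization mode {mode!r}")


def normalize_timecourse(
    raw: Sequence[float] | np.ndarray,
    pre_frames: Sequence[int] | np.ndarray,
    mode: str = "f_over_fpre",
    times: np.ndarray | None = None,
    frame_interval: float = 1.0,
    treatments: Iterable[tuple[float, str]] = (),
) -> TimeCourse:
    """Normalize a raw intensity trace.

    Modes
    -----
    ``f_over_fpre``
        F_t divided by the mean over the pre-treatment frames (the primary
        normalization: a trace that stays at the baseline reads 1).
    ``minmax``
        (F_t − min)/(max − min); attains exactly 0 and 1.
    ``delta_over_deltamax``
        (F_t − F_pre)/max|F_t − F_pre|; emphasizes kinetics by scaling the
        maximal excursion to ±1.

    Parameters
    ----------
    raw
        Per-frame trace; NaN marks missing frames.
    pre_frames
        Indices of the pre-treatment baseline window.
    times
        Frame times in s; defaults to ``arange(n) * frame_interval``.
    """
    raw = np.asarray(raw, dtype=float)
    if times is None:
        times = np.arange(raw.size) * frame_interval
    tc = TimeCourse(
        times=times, raw=raw, pre_frames=np.asarray(pre_frames, dtype=int),
        treatments=list(treatments),
    )
    tc.add_normalization(mode)
    return tc


def area_under_curve(
    trace: TimeCourse,
    window: tuple[float, float],
    baseline: float = 0.0,
    series: str = "f_over_fpre",
) -> float:
    """Trapezoidal integral of (series − baseline) over a time window.

    Window endpoints inside the trace span are linearly interpolated.
    Units: (dimensionless)·s.

    Raises
    ------
    ValueError
        If the window is empty, outside the trace span, or spans NaN frames.
    """
    t_start, t_end = window
    if not t_end > t_start:
        raise ValueError("empty AUC window")
    t = trace.times
    if t_start < t[0] or t_end > t[-1]:
        raise ValueError("AUC window outside trace span")
    if series == "raw":
        y = trace.raw
    else:
        if series not in trace.normalized:
            y = trace.add_normalization(series)
        else:
            y = trace.normalized[series]
    inside = (t > t_start) & (t < t_end)
    tt = np.concatenate(([t_start], t[inside], [t_end]))
    yy = np.concatenate((
        [np.interp(t_start, t, y)], y[inside], [np.interp(t_end, t, y)]
    ))
    if np.any(~np.isfinite(yy)):
        raise ValueError("AUC window contains missing frames")
    return float(np.trapezoid(yy - baseline, tt))
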