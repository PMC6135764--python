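"""Video tracking of a single dark fly on a light arena.

The tracker converts a grayscale frame stack into a :class:`Trajectory`:

1. a background image is estimated as the per-pixel temporal median over an
   even subsample of frames;
2. each frame is segmented by thresholded background subtraction (the fly is
   darker than the backlit arena floor), keeping the largest connected
   component, with centroid and ellipse from image moments;
3. instantaneous speed is the per-frame path length times the frame rate;
4. motion energy is the number of pixels in a fly-centered region of interest
   whose intensity changed by strictly more than a fixed number of gray
   levels between consecutive frames.

Coordinates: arena-centered millimeters, x rightward, y toward the stimulus
screen (the screen sits at azimuth 90 degrees).  Pixel indexing is 0-based
with rows increasing downward, so ``y_mm = (center_row - row) / px_per_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure

__all__ = [
    "ArenaConfig",
    "TrackingConfig",
    "Trajectory",
    "FlyEllipse",
    "TrackingError",
    "estimate_background",
    "segment_fly",
    "pixel_motion",
    "track_video",
    "load_frames",
]


class TrackingError(RuntimeError):
    """Raised when a video cannot be tracked reliably."""


@dataclass(frozen=True)
class ArenaConfig:
    """Arena geometry and acquisition parameters.

    ``px_per_mm`` is derived from an arena-circle annotation (center and
    radius in pixels) against the known physical diameter.
    """

    diameter_mm: float = 30.0
    frame_rate: float = 60.0
    image_size: tuple[int, int] = (1104, 1040)  # (width, height)
    center_px: tuple[float, float] | None = None  # (col, row)
    radius_px: float | None = None

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0 or self.frame_rate <= 0:
            raise ValueError("diameter and frame rate must be positive")
        if self.center_px is None:
            object.__setattr__(
                self,
                "center_px",
                ((self.image_size[0] - 1) / 2.0, (self.image_size[1] - 1) / 2.0),
            )
        if self.radius_px is None:
            object.__setattr__(self, "radius_px", 0.45 * min(self.image_size))
        cx, cy = self.center_px
        r = self.radius_px
        if r <= 0:
            raise ValueError("radius_px must be positive")
        if (
            cx - r < -0.5
            or cy - r < -0.5
            or cx + r > self.image_size[0] - 0.5
            or cy + r > self.image_size[1] - 0.5
        ):
            raise ValueError("arena circle does not fit in the image")

    @property
    def px_per_mm(self) -> float:
        return 2.0 * self.radius_px / self.diameter_mm

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0

    def px_to_mm(self, col, row):
        """Pixel (col, row) -> arena-centered (x_mm, y_mm), y toward screen."""
        cx, cy = self.center_px
        return (
            (np.asarray(col, float) - cx) / self.px_per_mm,
            (cy - np.asarray(row, float)) / self.px_per_mm,
        )

    def mm_to_px(self, x_mm, y_mm):
        cx, cy = self.center_px
        return (
            cx + np.asarray(x_mm, float) * self.px_per_mm,
            cy - np.asarray(y_mm, float) * self.px_per_mm,
        )


@dataclass(frozen=True)
class TrackingConfig:
    roi_size_px: int = 100
    pixel_delta_thresh: int = 10
    seg_offset: int = 25  # intensity levels below background
    min_blob_area_px: int = 20
    background_subsample: int = 200
    max_invalid_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.roi_size_px < 2 or self.roi_size_px % 2:
            raise ValueError("roi_size_px must be an even integer >= 2")
        if self.pixel_delta_thresh < 1:
            raise ValueError("pixel_delta_thresh must be >= 1")
        if self.seg_offset < 1 or self.min_blob_area_px < 1:
            raise ValueError("seg_offset and min_blob_area_px must be >= 1")


@dataclass(frozen=True)
class FlyEllipse:
    """Segmented fly: centroid (pixel col/row) and moment-fit ellipse."""

    centroid_px: tuple[float, float]  # (col, row)
    major_axis_px: float
    minor_axis_px: float
    orientation_rad: float
    area_px: int


@dataclass
class Trajectory:
    """Per-frame time series for one fly, in arena-centered millimeters."""

    time_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    speed_mm_s: np.ndarray
    motion_px: np.ndarray
    valid: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in ("x_mm", "y_mm", "speed_mm_s", "motion_px", "valid"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if n >= 2:
            dt = np.diff(self.time_s)
            if not np.allclose(dt, 1.0 / self.frame_rate, atol=1e-6):
                raise ValueError("time steps must be uniform at 1/frame_rate")
        if np.any(self.speed_mm_s < 0):
            raise ValueError("speed must be non-negative")

    @property
    def n(self) -> int:
        return len(self.time_s)

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x_mm, self.y_mm])

    def frame_index(self, t_s: float) -> int:
        return int(round((t_s - self.time_s[0]) * self.frame_rate))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "x_mm": self.x_mm,
                "y_mm": self.y_mm,
                "speed_mm_s": self.speed_mm_s,
                "motion_px": self.motion_px,
                "valid": self.valid.astype(int),
            }
        )

    def to_csv(self, path_or_buf) -> None:
        self.to_dataframe().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, frame_rate: float | None = None) -> "Trajectory":
        df = pd.read_csv(path_or_buf)
        t = df["time_s"].to_numpy(float)
        if frame_rate is None:
            if len(t) < 2:
                raise ValueError("cannot infer frame rate from a single row")
            frame_rate = 1.0 / float(np.median(np.diff(t)))
        return cls(
            time_s=t,
            x_mm=df["x_mm"].to_numpy(float),
            y_mm=df["y_mm"].to_numpy(float),
            speed_mm_s=df["speed_mm_s"].to_numpy(float),
            motion_px=df["motion_px"].to_numpy(float),
            valid=df["valid"].to_numpy(bool)
            if "valid" in df
            else np.ones(len(t), bool),
            frame_rate=float(frame_rate),
        )

    @classmethod
    def from_positions(
        cls,
        x_mm: np.ndarray,
        y_mm: np.ndarray,
        frame_rate: float,
        motion_px: np.ndarray | None = None,
        valid: np.ndarray | None = None,
        t0_s: float = 0.0,
    ) -> "Trajectory":
        """Build a trajectory from positions; speed from per-frame path length."""
        x = np.asarray(x_mm, float)
        y = np.asarray(y_mm, float)
        n = len(x)
        speed = np.zeros(n)
        if n > 1:
            speed[1:] = np.hypot(np.diff(x), np.diff(y)) * frame_rate
        return cls(
            time_s=t0_s + np.arange(n) / frame_rate,
            x_mm=x,
            y_mm=y,
            speed_mm_s=speed,
            motion_px=np.zeros(n) if motion_px is None else np.asarray(motion_px, float),
            valid=np.ones(n, bool) if valid is None else np.asarray(valid, bool),
            frame_rate=frame_rate,
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def estimate_background(frames, subsample: int = 200, min_frames: int = 10):
    """Per-pixel temporal median over an even subsample of frames.

    Robust for a mostly-moving fly: any pixel the fly occupies in fewer than
    half of the sampled frames recovers the clean background value.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("expected a (n_frames, height, width) stack")
    n = frames.shape[0]
    if n < min_frames:
        raise ValueError(f"need at least {min_frames} frames, got {n}")
    idx = np.unique(np.linspace(0, n - 1, min(n, subsample)).astype(int))
    return np.median(frames[idx], axis=0).astype(frames.dtype)


def segment_fly(frame, background, cfg: TrackingConfig) -> FlyEllipse | None:
    """Segment the fly as the largest dark blob under the background.

    Pixels at least ``seg_offset`` levels darker than the background are
    foreground; the largest connected component of area >=
    ``min_blob_area_px`` is kept and an ellipse fitted from second-order
    image moments.  Returns None when no acceptable blob exists (the frame is
    flagged invalid and interpolated by the caller).
    """
    frame = np.asarray(frame)
    background = np.asarray(background)
    if frame.shape != background.shape:
        raise ValueError("frame and background must have the same shape")
    diff = background.astype(np.int32) - frame.astype(np.int32)
    mask = diff >= cfg.seg_offset
    if not mask.any():
        return None
    labels = measure.label(mask, connectivity=2)
    props = measure.regionprops(labels)
    props = [p for p in props if p.area >= cfg.min_blob_area_px]
    if not props:
        return None
    best = max(props, key=lambda p: p.area)
    # intensity-weighted centroid over the blob: sub-pixel on soft-edged flies
    blob = labels == best.label
    weights = np.where(blob, diff, 0).astype(float)
    total = weights.sum()
    rows_idx, cols_idx = np.nonzero(blob)
    w = weights[rows_idx, cols_idx]
    row = float((rows_idx * w).sum() / total)
    col = float((cols_idx * w).sum() / total)
    return FlyEllipse(
        centroid_px=(col, row),
        major_axis_px=best.axis_major_length,
        minor_axis_px=best.axis_minor_length,
        orientation_rad=best.orientation,
        area_px=int(best.area),
    )


def pixel_motion(prev_frame, cur_frame, center_px, cfg: TrackingConfig) -> int:
    """Active-pixel count in a square ROI centered on the fly.

    A pixel is active when its absolute intensity change between consecutive
    frames is strictly greater than ``pixel_delta_thresh``.  The ROI is
    clipped silently at image borders.
    """
    prev_frame = np.asarray(prev_frame)
    cur_frame = np.asarray(cur_frame)
    if prev_frame.shape != cur_frame.shape:
        raise ValueError("frames must have the same shape")
    h, w = cur_frame.shape
    col, row = center_px
    half = cfg.roi_size_px // 2
    r0 = max(0, int(round(row)) - half)
    r1 = min(h, int(round(row)) + half)
    c0 = max(0, int(round(col)) - half)
    c1 = min(w, int(round(col)) + half)
    if r1 <= r0 or c1 <= c0:
        return 0
    delta = np.abs(
        cur_frame[r0:r1, c0:c1].astype(np.int32)
        - prev_frame[r0:r1, c0:c1].astype(np.int32)
    )
    return int(np.count_nonzero(delta > cfg.pixel_delta_thresh))


def _interp_nan(values: np.ndarray) -> np.ndarray:
    """Linear interpolation over NaN runs, edge-filled with nearest values."""
    out = values.copy()
    bad = np.isnan(out)
    if bad.all():
        raise TrackingError("no valid frames to interpolate from")
    if bad.any():
        idx = np.arange(len(out))
        out[bad] = np.interp(idx[bad], idx[~bad], out[~bad])
    return out


def track_video(
    frames,
    arena: ArenaConfig,
    cfg: TrackingConfig | None = None,
    t0_s: float = 0.0,
    background=None,
) -> Trajectory:
    """Track a frame stack into a :class:`Trajectory`.

    The background defaults to the temporal median of the stack; pass an
    explicit ``background`` image when the fly barely moves (a median cannot
    separate a stationary fly from the floor).  Invalid frames (no acceptable
    blob) are gap-filled by linear interpolation and flagged; more than
    ``max_invalid_frac`` invalid frames aborts.  The motion ROI is centered
    on the previous frame's centroid so that a jump out of the ROI still
    registers maximal change.
    """
    cfg = cfg or TrackingConfig()
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a stack of at least 2 frames")
    n = frames.shape[0]
    if background is None:
        background = estimate_background(frames, subsample=cfg.background_subsample)

    cols = np.full(n, np.nan)
    rows = np.full(n, np.nan)
    for k in range(n):
        seg = segment_fly(frames[k], background, cfg)
        if seg is not None:
            cols[k], rows[k] = seg.centroid_px
    valid = ~np.isnan(cols)
    invalid_frac = 1.0 - valid.mean()
    if invalid_frac > cfg.max_invalid_frac:
        raise TrackingError(
            f"{invalid_frac:.0%} of frames could not be segmented (limit "
            f"{cfg.max_invalid_frac:.0%}); video unusable"
        )
    cols = _interp_nan(cols)
    rows = _interp_nan(rows)

    motion = np.zeros(n)
    for k in range(1, n):
        motion[k] = pixel_motion(
            frames[k - 1], frames[k], (cols[k - 1], rows[k - 1]), cfg
        )

    x_mm, y_mm = arena.px_to_mm(cols, rows)
    return Trajectory.from_positions(
        x_mm, y_mm, arena.frame_rate, motion_px=motion, valid=valid, t0_s=t0_s
    )


# ---------------------------------------------------------------------------
# Frame IO
# ---------------------------------------------------------------------------

_IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff")


def load_frames(source) -> np.ndarray:
    """Load a grayscale frame stack from a TIFF, frame directory, or video.

    Accepts an ndarray (returned as-is), a multi-page TIFF path, a directory
    of image frames read in lexicographic order, or a video file readable by
    imageio.  Color input is converted to grayscale by channel averaging.
    """
    if isinstance(source, np.ndarray):
        return source
    path = Path(source)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            raise FileNotFoundError(f"no image frames found in {path}")
        stack = np.stack([iio.imread(f) for f in files])
    elif path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        stack = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        stack = iio.imread(path)
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim == 4:  # color -> grayscale
        stack = stack.mean(axis=-1).astype(stack.dtype)
    return stack
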