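"""Threshold ethogram classification of freeze / flee / jump / pause.

Speed and motion traces are averaged into 500 ms bins and labeled with fixed
thresholds determined for this assay:

* **walk** — bin-average speed strictly above 4 mm/s;
* **freeze** — not walking and bin-average motion strictly below 50 px/s
  (complete immobility; roughly 5% of the fly's pixel area per second);
* **groom** — not walking but motion at or above 50 px/s (low-translation,
  high local motion).

Jumps are detected on the raw, un-binned speed as strict crossings of
75 mm/s, with consecutive supra-threshold frames merged into one event; any
bin containing a jump is labeled walk (a jump bin is never freeze).

Per-looming trial responses follow the precedence jump > freeze >
flee (split into flee_pause / flee_no_pause by the 10-consecutive-frame pause
criterion) > none.  A freezing response is credited even when the fly
initiated freezing on a prior looming (frozen flies still startle to each
stimulus, showing they continue to respond).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracking import Trajectory

__all__ = [
    "EthogramConfig",
    "BinnedActivity",
    "Ethogram",
    "TrialResponse",
    "StartleProfile",
    "bin_trajectory",
    "classify_bins",
    "detect_jumps",
    "detect_pause",
    "build_ethogram",
    "window_state",
    "classify_looming_trial",
    "classify_trials",
    "path_orientation",
    "startle_profile",
    "opto_success",
]

LABELS = ("walk", "freeze", "groom")
RESPONSES = ("freeze", "jump", "flee_pause", "flee_no_pause", "none")


@dataclass(frozen=True)
class EthogramConfig:
    bin_ms: float = 500.0
    walk_thresh_mm_s: float = 4.0
    freeze_motion_thresh_px_s: float = 50.0
    jump_thresh_mm_s: float = 75.0
    pause_min_frames: int = 10
    pause_window_s: float = 1.0
    opto_success_frac: float = 0.25
    min_orient_disp_mm: float = 0.5
    looming_duration_ms: float = 500.0

    def __post_init__(self) -> None:
        for name in (
            "bin_ms",
            "walk_thresh_mm_s",
            "freeze_motion_thresh_px_s",
            "jump_thresh_mm_s",
            "pause_window_s",
            "opto_success_frac",
            "min_orient_disp_mm",
            "looming_duration_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pause_min_frames < 1:
            raise ValueError("pause_min_frames must be >= 1")

    def frames_per_bin(self, frame_rate: float) -> int:
        fpb = self.bin_ms / 1000.0 * frame_rate
        if abs(fpb - round(fpb)) > 1e-9:
            raise ValueError("bin must be a whole number of frames")
        return int(round(fpb))


@dataclass(frozen=True)
class BinnedActivity:
    """Per-bin mean speed (mm/s) and motion rate (px/s)."""

    bin_start_s: np.ndarray
    speed_mm_s: np.ndarray
    motion_px_s: np.ndarray
    bin_s: float


@dataclass(frozen=True)
class Ethogram:
    """Per-bin behavioral labels plus the jump event list for one fly."""

    bin_start_s: np.ndarray
    labels: np.ndarray
    jump_times_s: np.ndarray
    bin_s: float

    @property
    def n_bins(self) -> int:
        return len(self.bin_start_s)

    def label_at(self, t_s: float) -> str:
        """Label of the bin containing time ``t_s``."""
        i = int(math.floor((t_s - self.bin_start_s[0]) / self.bin_s))
        if not 0 <= i < self.n_bins:
            raise IndexError(f"time {t_s} s outside the ethogram")
        return str(self.labels[i])

    def freeze_fraction(self, t0_s: float | None = None, t1_s: float | None = None) -> float:
        """Fraction of bins labeled freeze within [t0, t1)."""
        sel = np.ones(self.n_bins, bool)
        if t0_s is not None:
            sel &= self.bin_start_s >= t0_s - 1e-9
        if t1_s is not None:
            sel &= self.bin_start_s < t1_s - 1e-9
        if not sel.any():
            return float("nan")
        return float(np.mean(self.labels[sel] == "freeze"))

    def to_dataframe(self, binned: BinnedActivity | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"bin_start_s": self.bin_start_s, "label": self.labels})
        if binned is not None:
            df["speed_mm_s"] = binned.speed_mm_s
            df["motion_px_s"] = binned.motion_px_s
        return df


@dataclass(frozen=True)
class TrialResponse:
    """Classification of one looming presentation for one fly."""

    looming_index: int
    onset_s: float
    pre_speed_mm_s: float
    pre_state: str
    post_state: str
    response: str
    paused: bool
    pause_onset_s: float | None
    orientation_pre_deg: float
    orientation_post_deg: float


@dataclass(frozen=True)
class StartleProfile:
    """Frame-wise mean +/- s.e.m. motion around looming, over qualifying trials."""

    rel_time_s: np.ndarray
    mean_motion_px: np.ndarray
    sem_motion_px: np.ndarray
    n_trials: int


# ---------------------------------------------------------------------------


def bin_trajectory(traj: Trajectory, cfg: EthogramConfig) -> BinnedActivity:
    """Average speed and motion into consecutive bins (default 500 ms).

    Bin k covers frames [k*fpb, (k+1)*fpb); a partial trailing bin is
    dropped.  Motion rate is the mean per-frame active-pixel count times the
    frame rate, giving px/s.
    """
    fpb = cfg.frames_per_bin(traj.frame_rate)
    n_bins = traj.n // fpb
    if n_bins < 1:
        raise ValueError("trajectory shorter than one bin")
    speed = traj.speed_mm_s[: n_bins * fpb].reshape(n_bins, fpb).mean(axis=1)
    motion = (
        traj.motion_px[: n_bins * fpb].reshape(n_bins, fpb).mean(axis=1)
        * traj.frame_rate
    )
    starts = traj.time_s[0] + np.arange(n_bins) * fpb / traj.frame_rate
    return BinnedActivity(starts, speed, motion, fpb / traj.frame_rate)


def classify_bins(binned: BinnedActivity, cfg: EthogramConfig) -> np.ndarray:
    """Label bins walk / freeze / groom with walk-over-freeze precedence."""
    labels = np.where(
        binned.speed_mm_s > cfg.walk_thresh_mm_s,
        "walk",
        np.where(
            binned.motion_px_s < cfg.freeze_motion_thresh_px_s, "freeze", "groom"
        ),
    )
    return labels.astype("<U6")


def detect_jumps(traj: Trajectory, cfg: EthogramConfig) -> np.ndarray:
    """Jump event times: strict crossings of the jump threshold on raw speed.

    Consecutive supra-threshold frames are merged into a single event whose
    time is that of the first frame.
    """
    above = traj.speed_mm_s > cfg.jump_thresh_mm_s
    starts = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
    return traj.time_s[starts]


def detect_pause(
    traj: Trajectory, looming_onset_s: float, cfg: EthogramConfig
) -> tuple[bool, float | None]:
    """Pause detection in the post-looming search window.

    The fly paused iff within [onset, onset + pause_window] there are at
    least ``pause_min_frames`` consecutive frames with speed strictly below
    the walking threshold; the pause onset is the first frame of the first
    such run.  A window extending past the recording is truncated.
    """
    i0 = max(0, traj.frame_index(looming_onset_s))
    i1 = min(traj.n, i0 + int(round(cfg.pause_window_s * traj.frame_rate)))
    below = traj.speed_mm_s[i0:i1] < cfg.walk_thresh_mm_s
    run = 0
    for j, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= cfg.pause_min_frames:
            start = i0 + j - cfg.pause_min_frames + 1
            return True, float(traj.time_s[start])
    return False, None


def build_ethogram(traj: Trajectory, cfg: EthogramConfig | None = None) -> Ethogram:
    """Bin, classify and jump-detect a trajectory in one step.

    Bins containing a jump event are forced to walk: a jump bin is never
    freeze, whatever the bin averages say.
    """
    cfg = cfg or EthogramConfig()
    binned = bin_trajectory(traj, cfg)
    labels = classify_bins(binned, cfg)
    jumps = detect_jumps(traj, cfg)
    for t in jumps:
        i = int(math.floor((t - binned.bin_start_s[0]) / binned.bin_s))
        if 0 <= i < len(labels):
            labels[i] = "walk"
    return Ethogram(binned.bin_start_s, labels, jumps, binned.bin_s)


def window_state(traj: Trajectory, t0_s: float, t1_s: float, cfg: EthogramConfig) -> str:
    """Classify an arbitrary [t0, t1) window with the bin rules.

    Used for the 500 ms windows flanking each looming, which need not align
    with the ethogram's fixed bin grid.
    """
    i0 = max(0, traj.frame_index(t0_s))
    i1 = min(traj.n, traj.frame_index(t1_s))
    if i1 <= i0:
        raise ValueError("empty classification window")
    speed = float(traj.speed_mm_s[i0:i1].mean())
    motion = float(traj.motion_px[i0:i1].mean() * traj.frame_rate)
    if np.any(traj.speed_mm_s[i0:i1] > cfg.jump_thresh_mm_s):
        return "walk"
    if speed > cfg.walk_thresh_mm_s:
        return "walk"
    if motion < cfg.freeze_motion_thresh_px_s:
        return "freeze"
    return "groom"


def path_orientation(
    traj: Trajectory, t0_s: float, t1_s: float, min_disp_mm: float = 0.5
) -> float:
    """Orientation (degrees in [0, 360)) of the net displacement over a window.

    The stimulus screen sits at 90 degrees (positive y); a path straight away
    from the screen reads 270.  Returns NaN when the net displacement is at
    or below ``min_disp_mm`` (direction undefined).
    """
    if t1_s <= t0_s:
        raise ValueError("t1 must exceed t0")
    i0 = max(0, traj.frame_index(t0_s))
    i1 = min(traj.n - 1, traj.frame_index(t1_s))
    dx = traj.x_mm[i1] - traj.x_mm[i0]
    dy = traj.y_mm[i1] - traj.y_mm[i0]
    if math.hypot(dx, dy) <= min_disp_mm:
        return float("nan")
    return float(np.degrees(np.arctan2(dy, dx)) % 360.0)


def classify_looming_trial(
    traj: Trajectory,
    ethogram: Ethogram,
    onset_s: float,
    cfg: EthogramConfig,
    looming_index: int = 0,
) -> TrialResponse:
    """Classify one looming presentation.

    Pre-stimulus speed is averaged over the 500 ms before onset.  The pre and
    post states are the 500 ms windows immediately before onset and starting
    at looming offset, classified with the bin rules.  Response precedence:
    a jump event inside the looming window wins; otherwise a frozen post
    state is a freezing response (including freezes continued from earlier
    loomings); otherwise a walking post state is a flee, split by the pause
    criterion (pauses are only defined for flies walking before the
    stimulus); anything else is none.
    """
    bin_s = cfg.bin_ms / 1000.0
    dur_s = cfg.looming_duration_ms / 1000.0
    offset_s = onset_s + dur_s
    if onset_s - traj.time_s[0] < max(1.0, bin_s) - 1e-9 or (
        traj.time_s[-1] - onset_s
    ) < max(1.0, dur_s + bin_s) - 1e-9:
        raise ValueError(
            f"looming at {onset_s} s lacks the 1 s margin needed on both sides"
        )
    i0 = traj.frame_index(onset_s - bin_s)
    i1 = traj.frame_index(onset_s)
    pre_speed = float(traj.speed_mm_s[i0:i1].mean())
    pre_state = window_state(traj, onset_s - bin_s, onset_s, cfg)
    post_state = window_state(traj, offset_s, offset_s + bin_s, cfg)

    jumped = bool(
        np.any(
            (ethogram.jump_times_s >= onset_s - 1e-9)
            & (ethogram.jump_times_s <= offset_s + 1e-9)
        )
    )
    paused, pause_onset = False, None
    if jumped:
        response = "jump"
    elif post_state == "freeze":
        response = "freeze"
    elif post_state == "walk":
        if pre_state == "walk":
            paused, pause_onset = detect_pause(traj, onset_s, cfg)
        response = "flee_pause" if paused else "flee_no_pause"
    else:
        response = "none"
    return TrialResponse(
        looming_index=looming_index,
        onset_s=onset_s,
        pre_speed_mm_s=pre_speed,
        pre_state=pre_state,
        post_state=post_state,
        response=response,
        paused=paused,
        pause_onset_s=pause_onset,
        orientation_pre_deg=path_orientation(
            traj, onset_s - bin_s, onset_s, cfg.min_orient_disp_mm
        ),
        orientation_post_deg=path_orientation(
            traj, offset_s, offset_s + bin_s, cfg.min_orient_disp_mm
        ),
    )


def classify_trials(
    traj: Trajectory,
    onsets_s,
    cfg: EthogramConfig | None = None,
    ethogram: Ethogram | None = None,
) -> list[TrialResponse]:
    """Classify every looming of a session, skipping trials without margin."""
    cfg = cfg or EthogramConfig()
    ethogram = ethogram or build_ethogram(traj, cfg)
    out = []
    for i, onset in enumerate(np.asarray(onsets_s, float)):
        try:
            out.append(classify_looming_trial(traj, ethogram, onset, cfg, i))
        except ValueError:
            continue  # insufficient margin; trial skipped
    return out


def trials_to_dataframe(trials: list[TrialResponse]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "looming_idx": [t.looming_index for t in trials],
            "onset_s": [t.onset_s for t in trials],
            "pre_speed": [t.pre_speed_mm_s for t in trials],
            "pre_state": [t.pre_state for t in trials],
            "post_state": [t.post_state for t in trials],
            "response": [t.response for t in trials],
            "paused": [t.paused for t in trials],
            "orient_pre": [t.orientation_pre_deg for t in trials],
            "orient_post": [t.orientation_post_deg for t in trials],
        }
    )


def startle_profile(
    trajs,
    onsets_s,
    cfg: EthogramConfig | None = None,
    pre_s: float = 0.5,
    post_s: float = 0.5,
) -> StartleProfile:
    """Peri-looming motion profile over trials with freezing on both flanks.

    ``trajs`` is a list of trajectories and ``onsets_s`` either one onset
    list shared by all flies or one list per fly.  Only trials where the fly
    was freezing in the 500 ms windows before onset and after offset are
    included (these flies are still responding: they startle, with a motion
    spike peaking at the end of the expansion).  Returns an empty profile
    when no trial qualifies; a single trial has s.e.m. zero by convention.
    """
    cfg = cfg or EthogramConfig()
    if np.ndim(onsets_s[0]) == 0:
        onsets_s = [onsets_s] * len(trajs)
    bin_s = cfg.bin_ms / 1000.0
    dur_s = cfg.looming_duration_ms / 1000.0
    segments = []
    n_pre = None
    for traj, onsets in zip(trajs, onsets_s):
        n_pre = int(round(pre_s * traj.frame_rate))
        n_post = int(round(post_s * traj.frame_rate))
        for onset in onsets:
            i = traj.frame_index(onset)
            if i - n_pre < 0 or i + n_post > traj.n:
                continue
            if onset - bin_s < traj.time_s[0] or onset + dur_s + bin_s > traj.time_s[-1]:
                continue
            if (
                window_state(traj, onset - bin_s, onset, cfg) == "freeze"
                and window_state(traj, onset + dur_s, onset + dur_s + bin_s, cfg)
                == "freeze"
            ):
                segments.append(traj.motion_px[i - n_pre : i + n_post])
    if not segments:
        return StartleProfile(np.array([]), np.array([]), np.array([]), 0)
    stack = np.stack(segments)
    rel = (np.arange(stack.shape[1]) - n_pre) / trajs[0].frame_rate
    mean = stack.mean(axis=0)
    if stack.shape[0] > 1:
        sem = stack.std(axis=0, ddof=1) / math.sqrt(stack.shape[0])
    else:
        sem = np.zeros(stack.shape[1])
    return StartleProfile(rel, mean, sem, stack.shape[0])


def opto_success(
    ethogram: Ethogram, stim_onset_s: float, stim_dur_s: float, cfg: EthogramConfig
) -> bool:
    """Did a light stimulation drive freezing?

    Success iff the time classified frozen within [onset, onset + dur] is
    strictly more than ``opto_success_frac`` of the stimulation period
    (e.g. > 0.5 s of a 2 s pulse).
    """
    t_end = stim_onset_s + stim_dur_s
    if stim_onset_s < ethogram.bin_start_s[0] - 1e-9 or t_end > (
        ethogram.bin_start_s[-1] + ethogram.bin_s + 1e-9
    ):
        raise ValueError("stimulation must lie fully inside the recording")
    frozen = 0.0
    for start, label in zip(ethogram.bin_start_s, ethogram.labels):
        if label != "freeze":
            continue
        overlap = min(start + ethogram.bin_s, t_end) - max(start, stim_onset_s)
        if overlap > 0:
            frozen += overlap
    return frozen > cfg.opto_success_frac * stim_dur_s
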