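"""Looming-stimulus model, protocol schedules and closed-loop trigger logic.

A looming stimulus is a dark disk whose angular size follows

    theta(t) = 2 * arctan(l / (v * t))

where ``l`` is half the virtual object length, ``v`` its approach speed and
``t`` the remaining time to collision.  The ratio ``l/v`` (units of time)
fully determines the angular expansion profile, so the profile generator is
parameterized by ``l/v`` directly; ``l`` and ``v`` are optional convenience
inputs.  The defaults reproduce the standard protocol: l/v = 40 ms, 450 ms
expansion to a maximum angle of 78 deg, a 50 ms hold, 144 Hz monitor refresh.

Closed-loop stimulation is modeled as a per-frame state machine that fires
when the displacement of the fly over a trailing 500 ms window satisfies a
mode-dependent inequality (low: < 1 mm; high: > 7.5 mm; very high: > 10 mm),
subject to a 15 s refractory period and a re-arming rule (the threshold must
be crossed anew; see :class:`ClosedLoopDetector`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LoomingParams",
    "LoomingProfile",
    "StimulusEvent",
    "StimulusSchedule",
    "TriggerConfig",
    "ClosedLoopDetector",
    "visual_angle",
    "collision_anchor_ms",
    "build_looming_profile",
    "luminance_decrease",
    "build_schedule",
    "closed_loop_triggers",
    "PROTOCOLS",
]


class StimulusConfigError(ValueError):
    """Raised for inconsistent stimulus parameterizations."""


@dataclass(frozen=True)
class LoomingParams:
    """Parameters of one looming presentation.

    ``l_over_v_ms`` is the ratio of half object size to approach speed,
    expressed in milliseconds; it is the only geometric quantity the angular
    profile depends on.
    """

    l_over_v_ms: float = 40.0
    expansion_ms: float = 450.0
    hold_ms: float = 50.0
    max_angle_deg: float = 78.0
    refresh_hz: float = 144.0
    half_size_cm: float | None = None
    approach_speed_cm_s: float | None = None

    def __post_init__(self) -> None:
        if self.l_over_v_ms <= 0:
            raise StimulusConfigError("l_over_v_ms must be positive")
        if self.expansion_ms <= 0:
            raise StimulusConfigError("expansion_ms must be positive")
        if self.hold_ms < 0:
            raise StimulusConfigError("hold_ms must be non-negative")
        if not 0 < self.max_angle_deg < 180:
            raise StimulusConfigError("max_angle_deg must lie in (0, 180)")
        if self.refresh_hz <= 0:
            raise StimulusConfigError("refresh_hz must be positive")

    @classmethod
    def from_geometry(
        cls, half_size_cm: float, approach_speed_cm_s: float, **kwargs
    ) -> "LoomingParams":
        """Build params from object geometry; l/v in ms = 1000 * l / v."""
        if half_size_cm <= 0 or approach_speed_cm_s <= 0:
            raise StimulusConfigError("half size and approach speed must be positive")
        return cls(
            l_over_v_ms=1000.0 * half_size_cm / approach_speed_cm_s,
            half_size_cm=half_size_cm,
            approach_speed_cm_s=approach_speed_cm_s,
            **kwargs,
        )

    @property
    def total_ms(self) -> float:
        return self.expansion_ms + self.hold_ms


@dataclass(frozen=True)
class LoomingProfile:
    """Sampled visual-angle-vs-time curve of one looming presentation."""

    sample_times_ms: np.ndarray
    angles_deg: np.ndarray

    def to_csv(self, path_or_buf) -> None:
        pd.DataFrame(
            {"time_ms": self.sample_times_ms, "angle_deg": self.angles_deg}
        ).to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "LoomingProfile":
        df = pd.read_csv(path_or_buf)
        return cls(df["time_ms"].to_numpy(float), df["angle_deg"].to_numpy(float))


def visual_angle(t_to_collision_ms, l_over_v_ms):
    """Visual angle (degrees) of an approaching object, 2*arctan(l / (v t)).

    Strictly decreasing in time-to-collision and increasing in l/v.
    Accepts scalars or arrays; time-to-collision must be positive.
    """
    t = np.asarray(t_to_collision_ms, dtype=float)
    if np.any(t <= 0):
        raise ValueError("time to collision must be positive")
    if l_over_v_ms <= 0:
        raise ValueError("l_over_v_ms must be positive")
    out = np.degrees(2.0 * np.arctan(l_over_v_ms / t))
    return float(out) if np.isscalar(t_to_collision_ms) else out


def collision_anchor_ms(l_over_v_ms: float, max_angle_deg: float) -> float:
    """Time-to-collision at which the angle reaches ``max_angle_deg``.

    Inverts theta = 2*arctan(l/v / t):  t* = (l/v) / tan(theta/2).
    """
    if not 0 < max_angle_deg < 180:
        raise StimulusConfigError("max_angle_deg must lie in (0, 180)")
    return l_over_v_ms / math.tan(math.radians(max_angle_deg) / 2.0)


def build_looming_profile(params: LoomingParams) -> LoomingProfile:
    """Sample the angular profile of one looming presentation.

    The virtual collision time is anchored so the angle reaches
    ``max_angle_deg`` exactly at the end of the expansion; the disk then holds
    at maximum size for ``hold_ms``.  Samples are spaced at the monitor
    refresh interval, with the expansion end and the presentation end always
    included; angles never exceed ``max_angle_deg``.
    """
    t_star = collision_anchor_ms(params.l_over_v_ms, params.max_angle_deg)
    if t_star <= 0:
        raise StimulusConfigError("max_angle unreachable for given l/v")
    dt = 1000.0 / params.refresh_hz
    t_exp = np.arange(0.0, params.expansion_ms, dt)
    if not np.isclose(t_exp[-1], params.expansion_ms):
        t_exp = np.append(t_exp, params.expansion_ms)
    else:
        t_exp[-1] = params.expansion_ms
    # time-to-collision decreases from t* + expansion down to t*
    angles_exp = visual_angle(t_star + params.expansion_ms - t_exp, params.l_over_v_ms)
    angles_exp = np.minimum(angles_exp, params.max_angle_deg)
    if params.hold_ms > 0:
        t_hold = np.arange(params.expansion_ms + dt, params.total_ms, dt)
        if t_hold.size == 0 or not np.isclose(t_hold[-1], params.total_ms):
            t_hold = np.append(t_hold, params.total_ms)
        times = np.concatenate([t_exp, t_hold])
        angles = np.concatenate(
            [angles_exp, np.full(t_hold.size, params.max_angle_deg)]
        )
    else:
        times, angles = t_exp, angles_exp
    return LoomingProfile(times, angles)


def luminance_decrease(
    base_lux: float, final_lux: float, ndigits: int | None = None
) -> float:
    """Percent luminance decrease, 100 * (1 - final/base).

    ``ndigits`` optionally rounds the reported percentage (0 for the nearest
    integer, 1 for one decimal).
    """
    if base_lux <= 0:
        raise ValueError("base_lux must be positive")
    if not 0 <= final_lux <= base_lux:
        raise ValueError("final_lux must lie in [0, base_lux]")
    pct = 100.0 * (1.0 - final_lux / base_lux)
    return round(pct, ndigits) if ndigits is not None else pct


# ---------------------------------------------------------------------------
# Protocol schedules
# ---------------------------------------------------------------------------

EVENT_KINDS = ("looming", "control_dots", "light")


@dataclass(frozen=True)
class StimulusEvent:
    onset_s: float
    kind: str
    duration_ms: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise StimulusConfigError(f"unknown event kind {self.kind!r}")
        if self.duration_ms <= 0:
            raise StimulusConfigError("event duration must be positive")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_ms / 1000.0


@dataclass(frozen=True)
class StimulusSchedule:
    events: tuple[StimulusEvent, ...]

    def __post_init__(self) -> None:
        onsets = [e.onset_s for e in self.events]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise StimulusConfigError("events must be sorted by onset")
        by_kind: dict[str, list[StimulusEvent]] = {}
        for e in self.events:
            by_kind.setdefault(e.kind, []).append(e)
        for kind, evs in by_kind.items():
            for a, b in zip(evs, evs[1:]):
                if b.onset_s < a.offset_s:
                    raise StimulusConfigError(f"overlapping {kind} events")

    def onsets(self, kind: str | None = None) -> np.ndarray:
        return np.array(
            [e.onset_s for e in self.events if kind is None or e.kind == kind]
        )

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def to_csv(self, path_or_buf) -> None:
        pd.DataFrame(
            {
                "onset_s": [e.onset_s for e in self.events],
                "kind": [e.kind for e in self.events],
                "duration_ms": [e.duration_ms for e in self.events],
                "param_json": [json.dumps(e.params, sort_keys=True) for e in self.events],
            }
        ).to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "StimulusSchedule":
        df = pd.read_csv(path_or_buf)
        events = tuple(
            StimulusEvent(
                onset_s=float(r.onset_s),
                kind=str(r.kind),
                duration_ms=float(r.duration_ms),
                params=json.loads(r.param_json) if isinstance(r.param_json, str) else {},
            )
            for r in df.itertuples()
        )
        return cls(events)


#: Protocol presets.  Open-loop looming: a 5 min baseline then 20 loomings
#: evenly spaced (15 s period, onset at the start of each period) over a 5 min
#: stimulation block.  The control protocol swaps looming for luminance-matched
#: random dots.  Short looming: 5 stimuli within one minute of stimulation
#: onset.  Opto: 2 min baseline then 10 repetitions of 2 s light on / 20 s off.
PROTOCOLS = {
    "open_loop_looming": dict(
        kind="looming", baseline_s=300.0, n_events=20, period_s=15.0, duration_ms=500.0
    ),
    "open_loop_control": dict(
        kind="control_dots", baseline_s=300.0, n_events=20, period_s=15.0,
        duration_ms=500.0,
    ),
    "short_looming": dict(
        kind="looming", baseline_s=300.0, n_events=5, period_s=12.0, duration_ms=500.0
    ),
    "opto": dict(
        kind="light", baseline_s=120.0, n_events=10, period_s=22.0, duration_ms=2000.0
    ),
}


def build_schedule(protocol: str, **overrides) -> StimulusSchedule:
    """Build a deterministic stimulus schedule from a named protocol preset.

    Overridable keys: ``baseline_s``, ``n_events``, ``period_s``,
    ``duration_ms``, ``kind`` and an ``event_params`` dict attached to every
    event.
    """
    if protocol not in PROTOCOLS:
        raise StimulusConfigError(
            f"unknown protocol {protocol!r}; choose from {sorted(PROTOCOLS)}"
        )
    cfg = dict(PROTOCOLS[protocol])
    event_params = overrides.pop("event_params", {})
    unknown = set(overrides) - set(cfg)
    if unknown:
        raise StimulusConfigError(f"unknown schedule overrides: {sorted(unknown)}")
    cfg.update(overrides)
    events = tuple(
        StimulusEvent(
            onset_s=cfg["baseline_s"] + i * cfg["period_s"],
            kind=cfg["kind"],
            duration_ms=cfg["duration_ms"],
            params=dict(event_params),
        )
        for i in range(int(cfg["n_events"]))
    )
    return StimulusSchedule(events)


# ---------------------------------------------------------------------------
# Closed-loop trigger logic
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TriggerConfig:
    """Displacement-threshold trigger for closed-loop stimulation.

    ``mode`` selects the inequality applied to the displacement over the
    trailing ``window_ms``: ``low`` fires below ``low_thresh_mm`` (near-still
    fly), ``high``/``very_high`` fire above their thresholds (running fly).
    """

    window_ms: float = 500.0
    low_thresh_mm: float = 1.0
    high_thresh_mm: float = 7.5
    very_high_thresh_mm: float = 10.0
    refractory_s: float = 15.0
    mode: str = "low"

    def __post_init__(self) -> None:
        if min(self.low_thresh_mm, self.high_thresh_mm, self.very_high_thresh_mm) <= 0:
            raise StimulusConfigError("trigger thresholds must be positive")
        if not self.low_thresh_mm < self.high_thresh_mm < self.very_high_thresh_mm:
            raise StimulusConfigError(
                "thresholds must satisfy low < high < very_high"
            )
        if self.mode not in ("low", "high", "very_high"):
            raise StimulusConfigError(f"unknown trigger mode {self.mode!r}")
        if self.window_ms <= 0 or self.refractory_s <= 0:
            raise StimulusConfigError("window and refractory must be positive")

    def condition(self, displacement_mm: float) -> bool:
        if self.mode == "low":
            return displacement_mm < self.low_thresh_mm
        if self.mode == "high":
            return displacement_mm > self.high_thresh_mm
        return displacement_mm > self.very_high_thresh_mm


class ClosedLoopDetector:
    """Incremental trigger state machine, fed one position per frame.

    A trigger fires at frame ``k`` when the displacement between the current
    position and the position ``window`` earlier satisfies the mode
    inequality, at least ``refractory`` has elapsed since the previous
    trigger, and the condition has re-armed.  Re-arming means the condition
    went false and came true again (a rising edge); if the condition has been
    continuously true across the refractory period, the detector re-arms one
    frame after the refractory expires, so a perfectly still fly in ``low``
    mode triggers with a spacing of exactly refractory + one frame.
    """

    def __init__(self, cfg: TriggerConfig, frame_rate: float):
        self.cfg = cfg
        self.window_frames = int(round(cfg.window_ms / 1000.0 * frame_rate))
        if self.window_frames < 1:
            raise StimulusConfigError("window shorter than one frame")
        self.refractory_frames = int(round(cfg.refractory_s * frame_rate))
        self._positions: list[tuple[float, float]] = []
        self._k = -1
        self._prev_cond = False
        self._last_trigger: int | None = None

    def step(self, x_mm: float, y_mm: float) -> bool:
        """Advance one frame; return True when a trigger fires this frame."""
        self._k += 1
        self._positions.append((x_mm, y_mm))
        if len(self._positions) <= self.window_frames:
            return False
        x0, y0 = self._positions[-self.window_frames - 1]
        if len(self._positions) > self.window_frames + 1:
            self._positions.pop(0)
        disp = math.hypot(x_mm - x0, y_mm - y0)
        cond = self.cfg.condition(disp)
        fired = False
        if self._last_trigger is None:
            fired = cond and not self._prev_cond
        elif self._k > self._last_trigger + self.refractory_frames:
            rearmed = (not self._prev_cond) or (
                self._k == self._last_trigger + self.refractory_frames + 1
            )
            fired = cond and rearmed
        if fired:
            self._last_trigger = self._k
        self._prev_cond = cond
        return fired


def closed_loop_triggers(traj, cfg: TriggerConfig) -> np.ndarray:
    """Trigger times (s) for a whole trajectory, replaying the online detector.

    Returns an empty array when the trajectory is shorter than one window.
    """
    det = ClosedLoopDetector(cfg, traj.frame_rate)
    if traj.n <= det.window_frames:
        return np.array([])
    times = [
        traj.time_s[k]
        for k in range(traj.n)
        if det.step(traj.x_mm[k], traj.y_mm[k])
    ]
    return np.asarray(times)
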