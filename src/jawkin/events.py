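"""Gape computation, feeding-event detection and across-trial summaries.

Event logic follows the suction-feeding conventions for these data:

* **peak gape** (the maximum landmark-pair distance) defines time zero for
  the trial; all timings are in milliseconds relative to it, negative
  before;
* **initial jaw depression** is the frame after the last ventilatory jaw
  closure before peak gape (closure = gape at or below a small threshold,
  by default 2% of the trial's maximum gape);
* **expansive-phase onset** is the first frame at/after initial depression
  where gape reaches 10% (configurable) of maximum gape, which excludes
  ventilatory motions;
* per-channel rotation extrema: eversion is the minimum of the long-axis
  (x) channel, inversion the maximum *after* the eversion extremum (the
  jaws invert with closing, so this avoids picking a pre-strike maximum),
  depression the minimum of the hinge (z) channel.

Across-trial summaries report mean and s.e.m. (sample s.d. with the n-1
denominator divided by sqrt(n)) per quantity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError
from .io import GapeLandmark
from .jcs import AngleSeries
from .rigid import PoseSeries

__all__ = [
    "GapeSeries",
    "ChannelExtremum",
    "EventTable",
    "compute_gape",
    "find_peak_gape",
    "find_initial_depression",
    "expansive_onset_10pct",
    "find_angle_extrema",
    "summarize_across_trials",
    "MAGNITUDE_QUANTITIES",
    "TIMING_QUANTITIES",
]

logger = logging.getLogger(__name__)

#: the five rotation magnitudes reported per trial (deg)
MAGNITUDE_QUANTITIES = (
    "lower_jaw_eversion_deg",
    "lower_jaw_inversion_deg",
    "upper_jaw_eversion_deg",
    "lower_jaw_depression_deg",
    "upper_jaw_depression_deg",
)
#: their timings relative to peak gape (ms)
TIMING_QUANTITIES = (
    "lower_jaw_eversion_time_ms",
    "lower_jaw_inversion_time_ms",
    "upper_jaw_eversion_time_ms",
    "lower_jaw_depression_time_ms",
    "upper_jaw_depression_time_ms",
)


@dataclass
class GapeSeries:
    """Per-frame gape distance (mm) between two body-attached landmarks."""

    gape_mm: np.ndarray
    sample_rate_hz: float

    @property
    def frames(self) -> int:
        return self.gape_mm.shape[0]


def compute_gape(
    upper: PoseSeries, lower: PoseSeries, upper_landmark: GapeLandmark, lower_landmark: GapeLandmark
) -> GapeSeries:
    """Euclidean distance between the world positions of the two landmarks.

    Frames with either pose missing have missing gape.
    """
    if upper.frames != lower.frames:
        raise AlignmentError(
            f"gape: upper has {upper.frames} frames, lower {lower.frames}"
        )
    pu = upper.apply_to_point(upper_landmark.point)
    pl = lower.apply_to_point(lower_landmark.point)
    return GapeSeries(np.linalg.norm(pu - pl, axis=1), upper.sample_rate_hz)


def find_peak_gape(g: GapeSeries, window: tuple[int, int] | None = None) -> tuple[int, float]:
    """Frame of maximum gape in ``window`` (inclusive start, exclusive end).

    Ties are broken by the earliest frame; this frame defines t = 0 ms.
    Returns (frame, gape_mm).
    """
    lo, hi = window if window is not None else (0, g.frames)
    seg = g.gape_mm[lo:hi]
    if seg.size == 0 or not np.isfinite(seg).any():
        raise ValueError("find_peak_gape: no non-missing frames in window")
    frame = lo + int(np.nanargmax(seg))  # nanargmax returns the first maximum
    return frame, float(g.gape_mm[frame])


def find_initial_depression(
    g: GapeSeries, peak_frame: int, closure_threshold_mm: float, *, window_start: int = 0
) -> tuple[int, bool]:
    """Frame after the last ventilatory jaw closure before peak gape.

    Closure means gape at or below ``closure_threshold_mm``.  If the gape
    never closes before the peak the window start is returned with a
    ``never_closed`` flag.
    """
    seg = g.gape_mm[window_start:peak_frame]
    closed = np.flatnonzero(seg <= closure_threshold_mm)  # NaN compares False
    if closed.size == 0:
        return window_start, True
    return window_start + int(closed[-1]) + 1, False


def expansive_onset_10pct(
    g: GapeSeries,
    peak_frame: int,
    initial_depression_frame: int,
    fraction: float = 0.10,
) -> int:
    """First frame at/after initial depression with gape >= fraction * max.

    ``fraction = 0`` degenerates to the initial depression frame itself.
    """
    thresh = fraction * g.gape_mm[peak_frame]
    seg = g.gape_mm[initial_depression_frame : peak_frame + 1]
    hit = np.flatnonzero(seg >= thresh)
    if hit.size == 0:  # cannot happen for fraction <= 1 with finite peak
        return peak_frame
    return initial_depression_frame + int(hit[0])


@dataclass(frozen=True)
class ChannelExtremum:
    value_deg: float
    frame: int
    time_ms: float
    zero_range: bool = False


def _extremum(
    x: np.ndarray, lo: int, hi: int, kind: str, peak_frame: int, rate: float
) -> ChannelExtremum:
    seg = x[lo:hi]
    if seg.size == 0 or not np.isfinite(seg).any():
        raise ValueError("find_angle_extrema: empty window")
    f = lo + int(np.nanargmin(seg) if kind == "min" else np.nanargmax(seg))
    rng = float(np.nanmax(seg) - np.nanmin(seg))
    return ChannelExtremum(
        value_deg=float(x[f]),
        frame=f,
        time_ms=(f - peak_frame) / rate * 1000.0,
        zero_range=rng == 0.0,
    )


def find_angle_extrema(
    lower: AngleSeries,
    upper: AngleSeries,
    peak_frame: int,
    window: tuple[int, int],
) -> dict[str, ChannelExtremum]:
    """Per-channel extremum value (deg) and timing (ms relative to peak gape).

    The window must cover the peak-gape frame; ties go to the earliest
    frame.  Lower-jaw inversion is the maximum of the long-axis channel
    *after* the eversion extremum.
    """
    lo, hi = window
    if not (lo <= peak_frame < hi):
        raise ValueError(f"window {window} does not cover peak gape frame {peak_frame}")
    rate = lower.sample_rate_hz
    lar_low = lower.channel("inversion")
    lar_up = upper.channel("inversion")
    z_low = lower.channel("elevation")
    z_up = upper.channel("elevation")

    out: dict[str, ChannelExtremum] = {}
    ev = _extremum(lar_low, lo, hi, "min", peak_frame, rate)
    out["lower_jaw_eversion"] = ev
    out["lower_jaw_inversion"] = _extremum(lar_low, ev.frame, hi, "max", peak_frame, rate)
    out["upper_jaw_eversion"] = _extremum(lar_up, lo, hi, "min", peak_frame, rate)
    out["lower_jaw_depression"] = _extremum(z_low, lo, hi, "min", peak_frame, rate)
    out["upper_jaw_depression"] = _extremum(z_up, lo, hi, "min", peak_frame, rate)
    return out


@dataclass
class EventTable:
    """Per-trial feeding events and channel extrema.

    ``channels`` maps quantity stems (e.g. ``lower_jaw_eversion``) to their
    extremum; timing at peak gape is exactly 0 ms by construction.
    """

    trial_id: str
    peak_gape_frame: int
    max_gape_mm: float
    initial_depression_frame: int
    never_closed: bool
    expansive_onset_frame: int
    channels: dict[str, ChannelExtremum]
    sample_rate_hz: float

    def quantities(self) -> dict[str, float]:
        """Flat name -> value mapping used for summaries and CSV output."""
        rate = self.sample_rate_hz
        out: dict[str, float] = {
            "max_gape_mm": self.max_gape_mm,
            "initial_depression_time_ms": (self.initial_depression_frame - self.peak_gape_frame) / rate * 1000.0,
            "expansive_onset_time_ms": (self.expansive_onset_frame - self.peak_gape_frame) / rate * 1000.0,
        }
        for stem, ext in self.channels.items():
            out[f"{stem}_deg"] = ext.value_deg
            out[f"{stem}_time_ms"] = ext.time_ms
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"quantity": "peak_gape_frame", "value": self.peak_gape_frame, "units": "frame"},
            {"quantity": "initial_depression_frame", "value": self.initial_depression_frame, "units": "frame"},
            {"quantity": "never_closed", "value": int(self.never_closed), "units": "flag"},
            {"quantity": "expansive_onset_frame", "value": self.expansive_onset_frame, "units": "frame"},
        ]
        for name, value in self.quantities().items():
            units = "mm" if name.endswith("_mm") else ("ms" if name.endswith("_ms") else "deg")
            rows.append({"quantity": name, "value": value, "units": units})
        df = pd.DataFrame(rows)
        df.insert(0, "trial_id", self.trial_id)
        return df


def summarize_across_trials(tables: list[EventTable]) -> pd.DataFrame:
    """Mean and s.e.m. per quantity over trials.

    Returns a DataFrame with columns quantity, units, n, mean, sem; with a
    single trial the s.e.m. is NaN (flagged unavailable).  Raises
    :class:`ValueError` listing the mismatch if trials disagree on their
    quantity sets.
    """
    if not tables:
        raise ValueError("no event tables to summarize")
    per_trial = [t.quantities() for t in tables]
    keys = list(per_trial[0])
    for t, q in zip(tables, per_trial):
        if list(q) != keys:
            raise ValueError(
                f"trial {t.trial_id!r} quantity set {sorted(q)} does not match "
                f"{sorted(keys)}"
            )
    rows = []
    for key in keys:
        vals = np.array([q[key] for q in per_trial], dtype=float)
        n = len(vals)
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        units = "mm" if key.endswith("_mm") else ("ms" if key.endswith("_ms") else "deg")
        rows.append(
            {"quantity": key, "units": units, "n": n, "mean": float(vals.mean()), "sem": sem}
        )
    return pd.DataFrame(rows)
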