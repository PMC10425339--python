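"""Multi-rate biosignal harmonization and emergence-episode segmentation.

Intraoperative monitors record at heterogeneous native rates: airway-pressure
(AWP) and capnography (EtCO2) waveforms at 62.5 Hz, patient-monitor vitals
(HR, SpO2, SBP) at 2 Hz, and ventilator scalars (PIP, tidal volume, RR,
PEEP, compliance, FiO2, agent concentrations) at 0.14 Hz.  This module
brings every channel onto a common 10 Hz grid (linear interpolation with
forward/backward edge fill for slow channels, last-observation-carried-
forward for fast channels), collapses the grid to per-second frames by
taking the within-second maximum, and then detects the clinically defined
landmarks of the emergence phase:

* emergence start -- the first second with FiO2 >= 70%;
* spontaneous-breathing (SB) onset -- the earliest AWP excursion at least
  5 cmH2O above the maximum AWP seen 15-30 s earlier, or an AWP dip at
  least 3 cmH2O below the PEEP setting;
* cumulative apnea -- seconds with EtCO2 < 2 mmHg counted from the first
  ventilator-off second onward, never reset within an episode.

Cases failing any of ten exclusion criteria (age, ventilation mode, airway
device, missing tracks, no FiO2 rise, emergence duration outside 2-20 min,
no outcome track, no OR extubation) are dropped with a per-criterion
attrition count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: channels that must be present to build the state space (criterion 6)
CRITICAL_CHANNELS = ("awp", "etco2", "fio2", "action", "pip")
#: channels that must be present to evaluate the primary outcome (criterion 10)
OUTCOME_CHANNELS = ("spo2", "hr", "sbp")

EXCLUSION_REASONS = (
    "age <18",
    "pressure-controlled ventilation",
    "no general anesthesia",
    "laryngeal mask airway",
    "double-lumen tube",
    "missing critical tracks",
    "no OR extubation",
    "no FiO2 rise",
    "emergence <2 min or >20 min",
    "no outcome track",
)


class MissingChannelError(KeyError):
    """A channel required downstream is absent from the raw recording."""


@dataclass
class Channel:
    """A single monitor track sampled at a fixed rate.

    ``step`` marks piecewise-constant signals (the recorded ventilation
    action) that must never be linearly interpolated.
    """

    name: str
    rate: float
    timestamps: np.ndarray
    values: np.ndarray
    step: bool = False

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError(f"channel {self.name}: rate must be positive")
        if self.timestamps.ndim != 1 or self.timestamps.shape != self.values.shape:
            raise ValueError(f"channel {self.name}: timestamp/value shape mismatch")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError(f"channel {self.name}: timestamps must strictly increase")

    @property
    def end(self) -> float:
        """Time of the last recorded sample (s)."""
        return float(self.timestamps[-1])


@dataclass
class RawSignalSet:
    """Per-case collection of multi-rate channels plus case metadata."""

    channels: dict[str, Channel]
    meta: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> Channel:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels


@dataclass
class HarmonizedSeries:
    """All channels on per-second frames (via an intermediate 10 Hz grid)."""

    frames: pd.DataFrame           # one row per second, 0-based
    channel_end: dict[str, float]  # last *recorded* sample time per channel

    @property
    def n_seconds(self) -> int:
        return len(self.frames)


@dataclass
class EmergenceEpisode:
    """Per-second view of one emergence phase, ``[start, end)`` half-open.

    ``frames`` is indexed by absolute second and includes the recorded
    action channel; ``sb_flag``/``apnea_cum`` are aligned with it.
    """

    start: int
    end: int
    frames: pd.DataFrame
    sb_onset: int | None
    sb_flag: np.ndarray
    apnea_cum: np.ndarray
    extubation: int | None
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> int:
        return self.end - self.start

    @property
    def actions(self) -> np.ndarray:
        return self.frames["action"].to_numpy().astype(int)


# ---------------------------------------------------------------------------
# harmonization


def _to_10hz(ch: Channel, grid: np.ndarray) -> np.ndarray:
    """Resample one channel onto the common 10 Hz grid.

    Channels slower than 10 Hz are linearly interpolated (np.interp clamps at
    the ends, which is exactly forward/backward fill); channels at or above
    10 Hz, and step signals, take the sample at or immediately before each
    tick.  Channels already at 1 Hz are carried forward unchanged: they sit
    at frame resolution, and interpolating them would let the within-second
    max borrow from the next frame.
    """
    if ch.rate < 10.0 and not ch.step and not np.isclose(ch.rate, 1.0):
        return np.interp(grid, ch.timestamps, ch.values)
    idx = np.searchsorted(ch.timestamps, grid, side="right") - 1
    idx = np.clip(idx, 0, len(ch.values) - 1)
    return ch.values[idx]


def harmonize(raw: RawSignalSet) -> HarmonizedSeries:
    """Bring all channels to 10 Hz, then to per-second frames (max rule).

    Raises :class:`MissingChannelError` if a critical channel is absent or
    empty, so the caller can map the failure to the exclusion report.
    """
    for name in CRITICAL_CHANNELS:
        if name not in raw.channels or len(raw.channels[name].values) == 0:
            raise MissingChannelError(name)
    t_max = max(ch.end for ch in raw.channels.values())
    n_sec = max(1, int(math.floor(t_max)) + 1)
    grid = np.arange(n_sec * 10) / 10.0
    cols = {}
    for name, ch in raw.channels.items():
        dense = _to_10hz(ch, grid)
        cols[name] = dense.reshape(n_sec, 10).max(axis=1)
    frames = pd.DataFrame(cols, index=pd.RangeIndex(n_sec, name="second"))
    ends = {name: ch.end for name, ch in raw.channels.items()}
    return HarmonizedSeries(frames=frames, channel_end=ends)


# ---------------------------------------------------------------------------
# detectors (all operate on 1 Hz frames)


def detect_emergence_start(fio2: np.ndarray, thresh: float = 70.0) -> int | None:
    """Earliest second with FiO2 at or above ``thresh`` percent."""
    fio2 = np.asarray(fio2, dtype=float)
    hits = np.flatnonzero(fio2 >= thresh)
    return int(hits[0]) if hits.size else None


def detect_spontaneous_breathing(
    awp: np.ndarray,
    peep: float,
    rise_thresh: float = 5.0,
    dip_thresh: float = 3.0,
    window: tuple[int, int] = (15, 30),
    earliest: int = 0,
) -> tuple[int | None, np.ndarray]:
    """Detect the return of spontaneous breathing from per-second AWP.

    Trigger A fires at second ``t`` (with at least ``window[1]`` seconds of
    history) when ``awp[t] >= max(awp[t-30 .. t-15]) + 5``; trigger B fires
    whenever ``awp[t] <= peep - 3``.  The onset is the earliest trigger at or
    after ``earliest``; the returned flag latches to 1 from onset onward.
    """
    awp = np.asarray(awp, dtype=float)
    n = len(awp)
    near, far = window
    onset = None
    for t in range(earliest, n):
        if awp[t] <= peep - dip_thresh:
            onset = t
            break
        if t >= far:
            prev_max = awp[t - far : t - near + 1].max()
            if awp[t] >= prev_max + rise_thresh:
                onset = t
                break
    flag = np.zeros(n, dtype=int)
    if onset is not None:
        flag[onset:] = 1
    return onset, flag


def accumulate_apnea(etco2: np.ndarray, actions: np.ndarray) -> np.ndarray:
    """Cumulative apnea seconds (EtCO2 < 2 mmHg) after the first vent-off.

    The counter starts at the first second with action 0 and adds one for
    every subsequent second with EtCO2 below 2 mmHg.  It never resets: the
    cumulated total is itself the state feature and the penalty argument.
    """
    etco2 = np.asarray(etco2, dtype=float)
    actions = np.asarray(actions)
    if etco2.shape != actions.shape:
        raise ValueError("etco2 and action series must be aligned")
    off = np.flatnonzero(actions == 0)
    counting = np.zeros(len(etco2), dtype=bool)
    if off.size:
        counting[off[0] :] = True
    return np.cumsum(counting & (etco2 < 2.0)).astype(float)


# ---------------------------------------------------------------------------
# exclusions and segmentation


def segment_episode(h: HarmonizedSeries, start: int) -> tuple[int, int]:
    """Episode bounds ``[start, end)``; end = second past the last recorded
    EtCO2 sample (capnography stops shortly after extubation)."""
    end = int(math.floor(h.channel_end["etco2"])) + 1
    end = min(end, h.n_seconds)
    if end <= start:
        raise ValueError("EtCO2 recording ends before emergence start")
    return start, end


def apply_exclusions(
    raw: RawSignalSet,
    duration: int | None,
    start: int | None,
    has_critical: bool = True,
    min_dur: int = 120,
    max_dur: int = 1200,
) -> str | None:
    """Return the first matching exclusion reason, or None to keep the case.

    Metadata criteria come from flags in ``raw.meta``; signal criteria
    (missing tracks, FiO2 rise, duration bounds, outcome track) from the
    harmonized candidate.
    """
    m = raw.meta
    if m.get("age", 50) < 18:
        return EXCLUSION_REASONS[0]
    if m.get("pressure_controlled", False):
        return EXCLUSION_REASONS[1]
    if not m.get("general_anesthesia", True):
        return EXCLUSION_REASONS[2]
    if m.get("laryngeal_mask", False):
        return EXCLUSION_REASONS[3]
    if m.get("double_lumen_tube", False):
        return EXCLUSION_REASONS[4]
    if not has_critical:
        return EXCLUSION_REASONS[5]
    if not m.get("or_extubation", True):
        return EXCLUSION_REASONS[6]
    if start is None:
        return EXCLUSION_REASONS[7]
    if duration is None or duration < min_dur or duration > max_dur:
        return EXCLUSION_REASONS[8]
    if any(name not in raw.channels for name in OUTCOME_CHANNELS):
        return EXCLUSION_REASONS[9]
    return None


def preprocess_case(
    raw: RawSignalSet,
    min_dur: int = 120,
    max_dur: int = 1200,
    fio2_thresh: float = 70.0,
) -> tuple[EmergenceEpisode | None, str | None]:
    """Run the full per-case preprocessing chain.

    Returns ``(episode, None)`` for kept cases and ``(None, reason)`` for
    excluded ones.
    """
    try:
        h = harmonize(raw)
        has_critical = True
    except MissingChannelError:
        h, has_critical = None, False
    start = None
    duration = None
    if h is not None:
        start = detect_emergence_start(h.frames["fio2"].to_numpy(), fio2_thresh)
        if start is not None:
            try:
                start, end = segment_episode(h, start)
                duration = end - start
            except ValueError:
                duration = None
    reason = apply_exclusions(raw, duration, start, has_critical, min_dur, max_dur)
    if reason is not None:
        return None, reason

    frames = h.frames.iloc[start : start + duration].copy()
    frames["action"] = frames["action"].round().clip(0, 1).astype(int)
    peep = float(np.median(frames["peep"])) if "peep" in frames else 5.0
    onset, flag = detect_spontaneous_breathing(
        h.frames["awp"].to_numpy(), peep, earliest=start
    )
    if onset is not None and onset >= start + duration:
        onset = None
    sb_flag = flag[start : start + duration]
    apnea = accumulate_apnea(
        frames["etco2"].to_numpy(), frames["action"].to_numpy()
    )
    extub = raw.meta.get("extubation_s")
    return (
        EmergenceEpisode(
            start=start,
            end=start + duration,
            frames=frames,
            sb_onset=onset,
            sb_flag=sb_flag,
            apnea_cum=apnea,
            extubation=int(extub) if extub is not None else None,
            meta=dict(raw.meta),
        ),
        None,
    )


def preprocess_cohort(
    raws: list[RawSignalSet],
    min_dur: int = 120,
    max_dur: int = 1200,
    fio2_thresh: float = 70.0,
) -> tuple[list[EmergenceEpisode], pd.DataFrame]:
    """Preprocess a cohort and tally attrition per exclusion criterion."""
    episodes: list[EmergenceEpisode] = []
    counts = {reason: 0 for reason in EXCLUSION_REASONS}
    kept = 0
    for raw in raws:
        ep, reason = preprocess_case(raw, min_dur, max_dur, fio2_thresh)
        if ep is None:
            counts[reason] += 1
        else:
            kept += 1
            episodes.append(ep)
    rows = [{"reason": "kept", "n": kept}]
    rows += [{"reason": r, "n": n} for r, n in counts.items()]
    return episodes, pd.DataFrame(rows)
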