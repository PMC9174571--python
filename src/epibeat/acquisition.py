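"""Temporal alignment, band-pass preprocessing and beat segmentation.

Stand-alone acquisition devices share only a broadcast synchronization
pulse.  Matching the rising edges of that pulse across devices gives a
piecewise-linear map from each device clock onto the reference clock
(the fastest device), which simultaneously removes static offsets,
constant rate mismatch, and locally dropped/duplicated samples.  All
channels are then linearly resampled onto one common timebase.

Cardiac cycles are cut on atrial pacing spikes (ECG and acceleration)
and — independently of the ECG annotation — at mid-diastole for the
pressure channel, defined as the midpoint between successive diastolic
pressure minima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .simulate import MultiChannelRecording, PacingConfig

__all__ = [
    "AlignedRecording",
    "Beat",
    "AlignmentError",
    "detect_sync_pulses",
    "align_and_resample",
    "bandpass_filter",
    "detect_pacing_spikes",
    "segment_beats",
    "segment_pressure_beats",
]

log = logging.getLogger(__name__)

ECG_BAND_HZ = (0.5, 150.0)
ACCEL_BAND_HZ = (10.0, 250.0)
SPIKE_REFRACTORY_S = 0.020       # candidate (spike-width) refractory
ATRIAL_REFRACTORY_S = 0.200      # atrial-train refractory
SPIKE_MAD_FACTOR = 5.0
AV_PAIR_TOL_S = 0.010
MIN_BEAT_S = 0.200
MAX_BEAT_S = 3.0


class AlignmentError(RuntimeError):
    """Sync-pulse trains cannot be matched across devices."""


@dataclass
class AlignedRecording:
    """All devices' channels on one common timebase."""

    channels: dict[str, np.ndarray]
    fs_common: float
    t0: float                               # absolute time of sample 0
    offset_applied: dict[str, float]        # per device, seconds
    repairs: list[tuple[str, tuple[float, float], str]]
    metadata: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs_common


@dataclass
class Beat:
    """One cardiac cycle of a single signal kind."""

    signal_kind: str                        # "ecg" | "accel" | "pressure"
    samples: np.ndarray
    fs: float
    a_spike_time: float | None              # seconds, segment-relative
    v_spike_time: float | None
    beat_index: int
    pacing: PacingConfig | None = None
    t_start: float = 0.0                    # absolute start time
    channel: str | None = None

    def __post_init__(self) -> None:
        if self.a_spike_time is not None and self.v_spike_time is not None:
            dur = len(self.samples) / self.fs
            if not (0 <= self.a_spike_time < self.v_spike_time <= dur):
                raise ValueError(
                    "require 0 <= a_spike_time < v_spike_time <= duration"
                )

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


def detect_sync_pulses(channel: np.ndarray, fs: float) -> np.ndarray:
    """Rising-edge onset times of a square pulse train.

    Threshold is half the pulse amplitude (midpoint of the channel's
    range); a flat channel yields an empty array.
    """
    x = np.asarray(channel, float)
    if x.size == 0:
        raise ValueError("empty channel")
    lo, hi = x.min(), x.max()
    if hi - lo < 1e-9:
        return np.array([])
    thr = lo + 0.5 * (hi - lo)
    above = x >= thr
    onsets = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:  # train already high at the first sample
        onsets = np.concatenate(([0], onsets))
    return onsets / fs


def _pulse_map(dev_onsets: np.ndarray, ref_onsets: np.ndarray):
    """Pair pulse onsets between a device and the reference.

    Pairing is by order with a small shift search (tolerates a missing
    pulse at either end); the static offset is the median pairwise onset
    difference.  Returns (offset, dev_matched, ref_matched).
    """
    if len(dev_onsets) < 2 or len(ref_onsets) < 2:
        raise AlignmentError("need at least 2 sync pulses on every device")
    period = float(np.median(np.diff(ref_onsets)))
    # A periodic train only identifies the offset modulo its period.  A
    # pulse-count mismatch of >=2 means the devices' overlap differs by
    # more than one period and order-matching would alias the offset.
    if abs(len(dev_onsets) - len(ref_onsets)) >= 2:
        raise AlignmentError(
            "ambiguous sync matching: pulse counts differ by "
            f"{abs(len(dev_onsets) - len(ref_onsets))} (offset likely "
            "exceeds half the pulse period)"
        )
    best = None
    for shift in range(-2, 3):
        if shift >= 0:
            d, r = dev_onsets[shift:], ref_onsets[: len(dev_onsets) - shift]
        else:
            d, r = dev_onsets[: len(ref_onsets) + shift], ref_onsets[-shift:]
        m = min(len(d), len(r))
        if m < 2:
            continue
        diffs = r[:m] - d[:m]
        offset = float(np.median(diffs))
        spread = float(np.median(np.abs(diffs - offset)))
        # A periodic train ties on spread for every shift; prefer the
        # pairing implying the smallest clock offset.
        key = (round(spread, 6), abs(offset))
        if best is None or key < best[0]:
            best = (key, offset, d[:m], r[:m])
    if best is None:
        raise AlignmentError("no common sync pulses")
    _, offset, d, r = best
    if abs(offset) > 0.5 * period:
        raise AlignmentError(
            f"ambiguous sync matching: offset {offset:.3f}s exceeds half "
            f"the pulse period ({period:.3f}s)"
        )
    if spread > 0.25 * period:
        raise AlignmentError("sync pulse trains do not match")
    return offset, d, r


def align_and_resample(
    recording: MultiChannelRecording,
    fs_common: float | None = None,
) -> AlignedRecording:
    """Map every device onto the reference clock and resample all channels.

    The reference device is the fastest one; ``fs_common`` defaults to its
    rate.  Device time is mapped to reference time piecewise-linearly
    through the matched sync-pulse onsets (linear extrapolation at the
    ends), which corrects offset, constant skew, and locally irregular
    sampling; irregular pulse spacings are logged as repairs.
    """
    sync = recording.sync_channel
    for name, dev in recording.devices.items():
        if sync not in dev.channels:
            raise AlignmentError(f"device {name!r} lacks sync channel")
    ref_name = max(recording.devices, key=lambda n: recording.devices[n].fs)
    ref_dev = recording.devices[ref_name]
    if fs_common is None:
        fs_common = ref_dev.fs
    ref_onsets = detect_sync_pulses(ref_dev.channels[sync].samples,
                                    ref_dev.fs)
    if len(ref_onsets) < 2:
        raise AlignmentError("reference device has <2 sync pulses")
    period = float(np.median(np.diff(ref_onsets)))

    offsets: dict[str, float] = {}
    repairs: list[tuple[str, tuple[float, float], str]] = []
    maps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    spans: list[tuple[float, float]] = []
    for name, dev in recording.devices.items():
        onsets = detect_sync_pulses(dev.channels[sync].samples, dev.fs)
        offset, d, r = _pulse_map(onsets, ref_onsets)
        offsets[name] = offset
        # Irregular spacing inside a device betrays dropped/duplicated
        # samples; the piecewise map through the pulse pairs repairs them.
        spacing = np.diff(d)
        bad = np.flatnonzero(np.abs(spacing - period) > 2.0 / dev.fs)
        for b in bad:
            repairs.append(
                (name, (float(d[b]), float(d[b + 1])), "local_resample")
            )
        maps[name] = (d, r)
        dur = len(dev.channels[sync].samples) / dev.fs
        # Mapped span of this device on the reference clock.
        lo = float(np.interp(0.0, d, r, left=r[0] - (d[0] - 0.0)))
        hi = float(r[-1] + (dur - d[-1]))
        spans.append((lo, hi))

    t_start = max(lo for lo, _ in spans)
    t_end = min(hi for _, hi in spans)
    if t_end <= t_start:
        raise AlignmentError("devices share no overlapping time span")
    n = int(np.floor((t_end - t_start) * fs_common))
    t_common = t_start + np.arange(n) / fs_common

    channels: dict[str, np.ndarray] = {}
    for name, dev in recording.devices.items():
        d, r = maps[name]
        dur = len(dev.channels[sync].samples) / dev.fs
        # Extend the piecewise map linearly beyond the outermost pulses.
        slope0 = (r[1] - r[0]) / (d[1] - d[0])
        slope1 = (r[-1] - r[-2]) / (d[-1] - d[-2])
        dk = np.concatenate(([0.0], d, [dur]))
        rk = np.concatenate(
            ([r[0] - slope0 * d[0]], r, [r[-1] + slope1 * (dur - d[-1])])
        )
        dev_times = np.arange(
            len(dev.channels[sync].samples)) / dev.fs
        mapped = np.interp(dev_times, dk, rk)
        for ch_name, ch in dev.channels.items():
            if ch_name == sync and name != ref_name:
                continue  # keep a single sync trace (the reference's)
            channels[ch_name] = np.interp(t_common, mapped, ch.samples)
    return AlignedRecording(
        channels=channels,
        fs_common=float(fs_common),
        t0=t_start,
        offset_applied=offsets,
        repairs=repairs,
        metadata=dict(recording.metadata),
    )


def bandpass_filter(x: np.ndarray, fs: float, kind: str) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass.

    ``kind="accel"`` uses the fixed 10–250 Hz heart-sound analysis band;
    ``kind="ecg"`` uses 0.5–150 Hz (DC and respiration drift removed,
    pacing-spike slope preserved).
    """
    if kind == "accel":
        band = ACCEL_BAND_HZ
        if fs <= 2 * band[1]:
            raise ValueError(
                f"fs={fs} Hz too low for the {band[1]} Hz accel band edge"
            )
    elif kind == "ecg":
        band = (ECG_BAND_HZ[0], min(ECG_BAND_HZ[1], 0.45 * fs))
    else:
        raise ValueError(f"unknown filter kind {kind!r}")
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, float))


def detect_pacing_spikes(
    ecg: np.ndarray,
    fs: float,
    pacing: PacingConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Atrial and ventricular pacing-spike times from a filtered ECG.

    Candidates are peaks of the absolute differentiated ECG above
    5x its median absolute deviation (20 ms candidate refractory).
    Candidates are then paired at the programmed AV delay (±10 ms):
    the earlier spike of a pair is atrial, the later ventricular; a
    200 ms refractory is enforced on the atrial train.  Unpaired
    candidates are dropped.
    """
    x = np.asarray(ecg, float)
    if x.size < 3:
        return np.array([]), np.array([])
    d = np.abs(np.diff(x))
    mad = np.median(np.abs(d - np.median(d)))
    thr = SPIKE_MAD_FACTOR * 1.4826 * mad
    if thr <= 0:
        return np.array([]), np.array([])
    peaks, _ = sps.find_peaks(
        d, height=thr, distance=max(1, int(SPIKE_REFRACTORY_S * fs))
    )
    if peaks.size == 0:
        return np.array([]), np.array([])
    # The |diff| peak sits on the spike's steepest edge; back-track to
    # the rise onset so reported times match the stimulus onset.
    onsets = peaks.copy()
    for i, p in enumerate(peaks):
        j = p
        floor_h = 0.3 * d[p]
        while j > 0 and d[j - 1] >= floor_h and p - j < int(0.005 * fs):
            j -= 1
        onsets[i] = j
    cand = onsets / fs
    av = pacing.av_delay_s
    a_times, v_times = [], []
    used = np.zeros(len(cand), bool)
    last_a = -np.inf
    for i, t in enumerate(cand):
        if used[i]:
            continue
        lag = cand - t
        j = np.flatnonzero(~used & (np.abs(lag - av) <= AV_PAIR_TOL_S))
        if j.size == 0:
            continue
        if t - last_a < ATRIAL_REFRACTORY_S:
            continue
        a_times.append(t)
        v_times.append(float(cand[j[0]]))
        used[i] = used[j[0]] = True
        last_a = t
    a_arr, v_arr = np.array(a_times), np.array(v_times)
    n_unpaired = int(np.sum(~used))
    if n_unpaired:
        # Routine: broad depolarization waves also cross the slope
        # threshold but never find a partner at the AV delay.
        log.debug("pacing-spike detection: %d unpaired candidates dropped",
                  n_unpaired)
    if a_arr.size and n_unpaired > 3 * a_arr.size:
        log.warning("pacing-spike detection: unpaired candidates (%d) far "
                    "exceed paired beats (%d)", n_unpaired, a_arr.size)
    return a_arr, v_arr


def segment_beats(
    aligned: AlignedRecording,
    atrial_spikes: np.ndarray,
    v_spikes: np.ndarray | None = None,
    channels: dict[str, str] | None = None,
    pacing: PacingConfig | None = None,
) -> dict[str, list[Beat]]:
    """Cut ECG/acceleration channels into beats on atrial pacing spikes.

    ``channels`` maps an output signal kind (e.g. ``"ecg"``,
    ``"accel_mitral_valve_z"``) to the channel label in ``aligned``.
    Beat k spans [spike_k, spike_{k+1}); implausible spacings
    (< 200 ms or > 3 s) are dropped and logged.  Spike times are
    absolute (same clock as ``aligned.times()``).
    """
    atrial_spikes = np.asarray(atrial_spikes, float)
    if len(atrial_spikes) < 2:
        raise ValueError("need at least 2 atrial spikes to segment")
    if channels is None:
        channels = {name: name for name in aligned.channels
                    if name not in ("sync", "pressure")}
    fs = aligned.fs_common
    if v_spikes is not None:
        v_spikes = np.asarray(v_spikes, float)
    out: dict[str, list[Beat]] = {kind: [] for kind in channels}
    for k, i0, i1 in _beat_windows(aligned, atrial_spikes):
        a_rel = atrial_spikes[k] - (aligned.t0 + i0 / fs)
        v_rel = None
        if v_spikes is not None:
            inside = v_spikes[(v_spikes > atrial_spikes[k])
                              & (v_spikes < atrial_spikes[k + 1])]
            if inside.size:
                v_rel = float(inside[0] - (aligned.t0 + i0 / fs))
        for kind, label in channels.items():
            sig_kind = "ecg" if label == "ecg" else "accel"
            out[kind].append(Beat(
                signal_kind=sig_kind,
                samples=aligned.channels[label][i0:i1].copy(),
                fs=fs,
                a_spike_time=max(0.0, float(a_rel)),
                v_spike_time=v_rel,
                beat_index=k,
                pacing=pacing,
                t_start=aligned.t0 + i0 / fs,
                channel=label,
            ))
    return out


def _beat_windows(
    aligned: AlignedRecording, atrial_spikes: np.ndarray
) -> list[tuple[int, int, int]]:
    """(beat_index, start sample, stop sample) for plausible spacings."""
    fs = aligned.fs_common
    windows = []
    for k in range(len(atrial_spikes) - 1):
        span = atrial_spikes[k + 1] - atrial_spikes[k]
        if not (MIN_BEAT_S <= span <= MAX_BEAT_S):
            log.info("beat %d dropped: implausible spacing %.3fs", k, span)
            continue
        i0 = int(round((atrial_spikes[k] - aligned.t0) * fs))
        i1 = int(round((atrial_spikes[k + 1] - aligned.t0) * fs))
        if i0 < 0 or i1 > aligned.n_samples:
            log.info("beat %d dropped: outside aligned span", k)
            continue
        windows.append((k, i0, i1))
    return windows


def segment_pressure_beats(
    aligned: AlignedRecording,
    atrial_spikes: np.ndarray,
    channel: str = "pressure",
) -> list[Beat]:
    """Cut the pressure channel at mid-diastole, independent of the ECG.

    Diastolic minima are located on a lightly smoothed copy of the
    pressure trace; each beat spans the midpoints between successive
    minima.  A beat is assigned the cycle index of the atrial spike
    interval its systolic peak falls into, so pressure beats can be
    cross-referenced with ECG/acceleration beats.
    """
    p = aligned.channels[channel]
    fs = aligned.fs_common
    smooth = sps.savgol_filter(p, max(5, int(0.02 * fs) | 1), 2)
    amp = smooth.max() - smooth.min()
    minima, _ = sps.find_peaks(
        -smooth, prominence=0.3 * amp, distance=int(MIN_BEAT_S * fs)
    )
    beats: list[Beat] = []
    if len(minima) < 3:
        return beats
    mids = ((minima[:-1] + minima[1:]) // 2)
    atrial = np.asarray(atrial_spikes, float)
    for j in range(len(mids) - 1):
        i0, i1 = int(mids[j]), int(mids[j + 1])
        seg = p[i0:i1]
        peak_t = aligned.t0 + (i0 + int(np.argmax(seg))) / fs
        k = int(np.searchsorted(atrial, peak_t, side="right")) - 1
        if k < 0 or k >= len(atrial) - 1:
            continue
        if not (atrial[k] <= peak_t < atrial[k + 1]):
            continue
        beats.append(Beat(
            signal_kind="pressure",
            samples=seg.copy(),
            fs=fs,
            a_spike_time=None,
            v_spike_time=None,
            beat_index=k,
            t_start=aligned.t0 + i0 / fs,
            channel=channel,
        ))
    return beats
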