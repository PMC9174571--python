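"""S1/S2 localization and the 17 heart-sound training features.

Each retained Z-axis acceleration beat yields one feature vector built
from two regions of interest (ROIs) centred on the first and second
heart sound.  ROIs are found on the smoothed Shannon-energy envelope of
the beat, computed after normalizing the signal by the maximum absolute
amplitude of its *pacing setting* (not the single beat) so that
beat-to-beat amplitude ordering — which carries the hemodynamic
information — survives normalization.

Feature codes (suffix 1 = S1 ROI, suffix 2 = S2 ROI):

====  =======================================================  ========
code  definition                                               units
====  =======================================================  ========
A     max - min of the raw signal in the ROI                   g
B     max - min of the first difference in the ROI             g
C     integral of the rectified signal over the ROI            g*s
D     maximum Shannon energy in the ROI                        -
E     integral of the Shannon energy over the ROI              s
F     maximum Shannon entropy in the ROI                       -
G     integral of the Shannon entropy over the ROI             s
H     rectified-max(S1) to rectified-max(S2) interval          s
I     ventricular spike to rectified max of S1                 s
J     ventricular spike to negative peak of S1                 s
====  =======================================================  ========
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .acquisition import Beat

__all__ = [
    "FEATURE_CODES",
    "RoiPair",
    "FeatureVector",
    "FeatureIncompleteError",
    "shannon_transform",
    "shannon_envelope",
    "locate_rois",
    "extract_feature_vector",
]

log = logging.getLogger(__name__)

FEATURE_CODES = (
    "A1", "A2", "B1", "B2", "C1", "C2", "D1", "D2",
    "E1", "E2", "F1", "F2", "G1", "G2", "H", "I", "J",
)

ENVELOPE_WINDOW_S = 0.020
S1_SEARCH_S = (0.0, 0.200)       # after the ventricular spike
S2_SEARCH_S = (0.250, 0.500)
ROI_HALF_WIDTH_S = 0.075
ENVELOPE_PEAK_FLOOR = 5.0        # peak must exceed floor x median envelope


class FeatureIncompleteError(RuntimeError):
    """A heart-sound ROI could not be located; beat is excluded."""


@dataclass
class RoiPair:
    s1_window: tuple[float, float]   # seconds, beat-relative
    s2_window: tuple[float, float]
    s1_peak_time: float
    s2_peak_time: float

    def __post_init__(self) -> None:
        if not (self.s1_window[0] <= self.s1_peak_time <= self.s1_window[1]):
            raise ValueError("S1 peak outside its window")
        if not (self.s2_window[0] <= self.s2_peak_time <= self.s2_window[1]):
            raise ValueError("S2 peak outside its window")
        if self.s1_window[1] > self.s2_window[0]:
            raise ValueError("S1 and S2 windows overlap")


@dataclass
class FeatureVector:
    values: dict[str, float]
    sensor_location: str
    beat_index: int
    setting: str = ""

    def __post_init__(self) -> None:
        missing = set(FEATURE_CODES) - set(self.values)
        if missing:
            raise ValueError(f"missing features: {sorted(missing)}")
        bad = [c for c in FEATURE_CODES
               if not np.isfinite(self.values[c])]
        if bad:
            raise ValueError(f"non-finite features: {bad}")
        if self.values["H"] <= 0:
            raise ValueError("H must be positive")

    def as_array(self, codes=FEATURE_CODES) -> np.ndarray:
        return np.array([self.values[c] for c in codes])


def shannon_transform(x: np.ndarray, mode: str = "energy") -> np.ndarray:
    """Pointwise Shannon energy ``-x^2 ln(x^2)`` or entropy ``-|x| ln|x|``.

    Requires ``max |x| <= 1`` (normalize upstream); uses the limit
    convention ``0 * ln 0 = 0``.  Output is non-negative: the energy
    form de-emphasizes the loudest content, the entropy form emphasizes
    medium-strength amplitudes.
    """
    x = np.asarray(x, float)
    a = np.abs(x)
    if a.size and a.max() > 1.0 + 1e-12:
        raise ValueError("shannon_transform requires max|x| <= 1")
    a = np.minimum(a, 1.0)
    out = np.zeros_like(a)
    nz = a > 0
    if mode == "energy":
        # -x^2 ln(x^2) = -2 x^2 ln|x|; the factored form keeps tiny
        # amplitudes from underflowing x^2 inside the logarithm.
        out[nz] = -2.0 * (a[nz] ** 2) * np.log(a[nz])
    elif mode == "entropy":
        out[nz] = -a[nz] * np.log(a[nz])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return np.maximum(out, 0.0)


def shannon_envelope(x_norm: np.ndarray, fs: float,
                     window_s: float = ENVELOPE_WINDOW_S) -> np.ndarray:
    """Moving-average smoothed Shannon-energy envelope."""
    e = shannon_transform(x_norm, "energy")
    w = max(1, int(round(window_s * fs)))
    return uniform_filter1d(e, size=w, mode="nearest")


def _window_peak(env: np.ndarray, fs: float, lo: float, hi: float,
                 floor: float) -> float:
    """Time of the largest envelope peak in (lo, hi]; None-equivalent error."""
    i0 = max(0, int(np.floor(lo * fs)) + 1)
    i1 = min(len(env), int(np.floor(hi * fs)) + 1)
    if i1 <= i0:
        raise FeatureIncompleteError("empty ROI search window")
    seg = env[i0:i1]
    peak = int(np.argmax(seg))
    if seg[peak] < floor:
        raise FeatureIncompleteError("no envelope peak in search window")
    return (i0 + peak) / fs


def locate_rois(
    accel_beat: Beat,
    v_spike_time: float | None = None,
    *,
    norm_scale: float | None = None,
    s1_search: tuple[float, float] = S1_SEARCH_S,
    s2_search: tuple[float, float] = S2_SEARCH_S,
    roi_half_width: float = ROI_HALF_WIDTH_S,
) -> RoiPair:
    """Locate the S1/S2 regions of interest on one acceleration beat.

    The S1 peak is the largest smoothed Shannon-energy envelope peak in
    ``(v, v+200 ms]``, the S2 peak the largest in ``(v+250, v+500 ms]``;
    windows extend ±75 ms around each peak, clipped to the beat and to
    non-overlap.  Raises :class:`FeatureIncompleteError` when a window
    holds no envelope peak clearly above the beat's median envelope.
    """
    v = accel_beat.v_spike_time if v_spike_time is None else v_spike_time
    if v is None:
        raise FeatureIncompleteError("no ventricular spike anchor")
    x = np.asarray(accel_beat.samples, float)
    scale = norm_scale if norm_scale else np.max(np.abs(x))
    if scale <= 0:
        raise FeatureIncompleteError("silent beat")
    env = shannon_envelope(np.clip(x / scale, -1, 1), accel_beat.fs)
    floor = ENVELOPE_PEAK_FLOOR * float(np.median(env))
    dur = accel_beat.duration
    s1_t = _window_peak(env, accel_beat.fs, v + s1_search[0],
                        min(v + s1_search[1], dur), floor)
    s2_t = _window_peak(env, accel_beat.fs, v + s2_search[0],
                        min(v + s2_search[1], dur), floor)
    s1_lo = max(0.0, s1_t - roi_half_width)
    s1_hi = min(s1_t + roi_half_width, dur)
    s2_lo = max(0.0, s2_t - roi_half_width)
    s2_hi = min(s2_t + roi_half_width, dur)
    if s1_hi > s2_lo:  # clip to non-overlap at the midpoint
        mid = 0.5 * (s1_t + s2_t)
        s1_hi = min(s1_hi, mid)
        s2_lo = max(s2_lo, mid)
    return RoiPair((s1_lo, s1_hi), (s2_lo, s2_hi), s1_t, s2_t)


def _roi_slice(n: int, fs: float, window: tuple[float, float]) -> slice:
    return slice(int(np.floor(window[0] * fs)),
                 min(n, int(np.ceil(window[1] * fs)) + 1))


def extract_feature_vector(
    accel_beat: Beat,
    rois: RoiPair,
    v_spike_time: float | None = None,
    *,
    norm_scale: float | None = None,
    sensor_location: str = "",
    setting: str = "",
) -> FeatureVector:
    """Compute the 17 amplitude/energy/temporal features for one beat.

    ``norm_scale`` is the pacing setting's max |signal| used for the
    Shannon transforms; amplitude features A–C are computed on the raw
    signal.  The temporal features I and J are measured on S1 (the
    rectified-maximum and negative-peak locations relative to the
    ventricular pacing spike).
    """
    v = accel_beat.v_spike_time if v_spike_time is None else v_spike_time
    if v is None:
        raise FeatureIncompleteError("no ventricular spike anchor")
    x = np.asarray(accel_beat.samples, float)
    fs = accel_beat.fs
    scale = norm_scale if norm_scale else np.max(np.abs(x))
    if scale <= 0:
        raise FeatureIncompleteError("silent beat")
    xn = np.clip(x / scale, -1.0, 1.0)
    dt = 1.0 / fs
    vals: dict[str, float] = {}
    peaks_abs: dict[str, int] = {}
    for suffix, window in (("1", rois.s1_window), ("2", rois.s2_window)):
        sl = _roi_slice(len(x), fs, window)
        seg = x[sl]
        if seg.size < 3:
            raise FeatureIncompleteError(f"ROI S{suffix} too short")
        segn = xn[sl]
        energy = shannon_transform(segn, "energy")
        entropy = shannon_transform(segn, "entropy")
        vals[f"A{suffix}"] = float(seg.max() - seg.min())
        d = np.diff(seg)
        vals[f"B{suffix}"] = float(d.max() - d.min())
        vals[f"C{suffix}"] = float(np.trapezoid(np.abs(seg), dx=dt))
        vals[f"D{suffix}"] = float(energy.max())
        vals[f"E{suffix}"] = float(np.trapezoid(energy, dx=dt))
        vals[f"F{suffix}"] = float(entropy.max())
        vals[f"G{suffix}"] = float(np.trapezoid(entropy, dx=dt))
        peaks_abs[suffix] = sl.start + int(np.argmax(np.abs(seg)))
    t_max_s1 = peaks_abs["1"] * dt
    t_max_s2 = peaks_abs["2"] * dt
    vals["H"] = float(t_max_s2 - t_max_s1)
    vals["I"] = float(t_max_s1 - v)
    s1_sl = _roi_slice(len(x), fs, rois.s1_window)
    t_min_s1 = (s1_sl.start + int(np.argmin(x[s1_sl]))) * dt
    vals["J"] = float(t_min_s1 - v)
    return FeatureVector(
        values=vals,
        sensor_location=sensor_location,
        beat_index=accel_beat.beat_index,
        setting=setting,
    )
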