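"""Synthetic paced-heart recordings with known ground-truth hemodynamics.

This module emulates the statistical structure of an acute paced-pig
experiment: an AV-blocked heart driven in DDD mode (RV or biventricular
pacing, programmable AV/VV delays) under three inotropic states
(baseline, dobutamine, isoflurane), recorded by two stand-alone devices
— a hemodynamic recorder (ECG + LV pressure, 2 kHz) and an epicardial
accelerometer unit (1 kHz, 16-bit, ±4 g, up to five sensor locations) —
that share nothing but a broadcast synchronization pulse.

Every beat's maximum LV pressure (LVPmax, mmHg) and maximum rate of
pressure rise (dP/dtmax, mmHg/s) are realized exactly in the pressure
trace, and are encoded into the acceleration signal through documented
monotone couplings: the S1 burst's peak-to-peak amplitude follows
dP/dtmax and the S2 burst's amplitude follows LVPmax (burst timing is
load-independent; see :func:`s2_delay`).
The generator is therefore a complete oracle for alignment,
segmentation, QC, feature extraction and model validation downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "SubjectSpec",
    "PacingConfig",
    "Channel",
    "DeviceRecording",
    "MultiChannelRecording",
    "GroundTruth",
    "synth_pressure_beat",
    "synth_accel_beat",
    "simulate_dataset",
    "default_subjects",
    "default_configs",
    "write_dataset",
    "load_dataset",
    "DEFAULT_LOCATIONS",
    "STATES",
]

STATES = ("baseline", "dobutamine", "isoflurane")

#: (LVPmax multiplier, dP/dtmax multiplier) per inotropic state.
#: Dobutamine is titrated to ~2x baseline dP/dtmax; the isoflurane
#: depression is limited to 0.75x so that generated dP/dtmax stays
#: inside the 600-1,600 mmHg/s measurement range covered by the
#: default binning schemes (see docs/methods.md).
STATE_SCALE = {
    "baseline": (1.00, 1.00),
    "dobutamine": (1.25, 1.95),
    "isoflurane": (0.70, 0.75),
}

DEFAULT_LOCATIONS = (
    "mitral_valve",
    "lv_apex",
    "rv_apex",
    "right_atrium",
    "tricuspid_valve",
)

#: Location-specific signatures: Gabor carrier frequency (Hz), extra S1
#: delay (s), extra S2 delay (s), relative amplitude. The atrial and
#: right-sided sensors see slightly later, lower-frequency vibrations.
LOCATION_TRAITS = {
    "mitral_valve": (45.0, 0.000, 0.000, 1.00),
    "lv_apex": (40.0, 0.004, 0.003, 0.90),
    "rv_apex": (38.0, 0.006, 0.005, 0.80),
    "right_atrium": (32.0, 0.010, 0.008, 0.60),
    "tricuspid_valve": (35.0, 0.008, 0.006, 0.70),
}

ACCEL_RANGE_G = 4.0
ADC_BITS = 16
ATRIAL_SPIKE_OFFSET_S = 0.020  # atrial pacing spike after cycle start
EM_DELAY_S = 0.030             # ventricular spike -> pressure onset
S1_DELAY_S = 0.040             # ventricular spike -> S1 burst centre
S2_BASE_DELAY_S = 0.300        # ventricular spike -> S2 burst centre
S1_JITTER_S = 0.0003           # beat-to-beat burst-timing jitter (sd)
S2_JITTER_S = 0.0005
SYNC_PULSE_START_S = 0.5
SYNC_PULSE_WIDTH_S = 0.05

# Linear acoustic couplings (defaults; see docs/methods.md).
S1_GAIN_PER_DPDT = 1.0e-3      # g peak-to-peak per (mmHg/s)
S2_GAIN_PER_LVP = 8.0e-3       # g peak-to-peak per mmHg


class ParameterError(ValueError):
    """Raised for physiologically infeasible generator parameters."""


@dataclass(frozen=True)
class PacingConfig:
    """One pacemaker programme held for ``duration_s`` seconds."""

    mode: str                      # "RV" or "BiV"
    av_delay_ms: float
    vv_delay_ms: float = 0.0
    state: str = "baseline"
    duration_s: float = 60.0
    heart_rate_bpm: float = 100.0

    def __post_init__(self) -> None:
        if self.mode not in ("RV", "BiV"):
            raise ParameterError(f"unknown pacing mode {self.mode!r}")
        if not 50.0 <= self.av_delay_ms <= 300.0:
            raise ParameterError("av_delay_ms must lie in [50, 300]")
        if not -150.0 <= self.vv_delay_ms <= 150.0:
            raise ParameterError("vv_delay_ms must lie in [-150, 150]")
        if self.state not in STATES:
            raise ParameterError(f"unknown state {self.state!r}")
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be positive")
        if self.heart_rate_bpm <= 0:
            raise ParameterError("heart_rate_bpm must be positive")

    @property
    def av_delay_s(self) -> float:
        return self.av_delay_ms / 1000.0

    @property
    def cycle_len_s(self) -> float:
        return 60.0 / self.heart_rate_bpm

    @property
    def name(self) -> str:
        return (
            f"{self.state}_{self.mode}_av{self.av_delay_ms:g}"
            f"_vv{self.vv_delay_ms:g}"
        )


@dataclass
class SubjectSpec:
    """Per-animal baseline hemodynamics and sensor gains."""

    subject_id: str
    baseline_lvpmax: float         # mmHg
    baseline_dpdtmax: float        # mmHg/s
    sensor_gains: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.005        # g, accelerometer noise
    seed: int = 0

    def __post_init__(self) -> None:
        if not 60.0 <= self.baseline_lvpmax <= 130.0:
            raise ParameterError("baseline_lvpmax must lie in [60, 130] mmHg")
        if not 600.0 <= self.baseline_dpdtmax <= 1600.0:
            raise ParameterError(
                "baseline_dpdtmax must lie in [600, 1600] mmHg/s"
            )
        if any(g <= 0 for g in self.sensor_gains.values()):
            raise ParameterError("sensor_gains must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")


@dataclass
class Channel:
    samples: np.ndarray
    fs: float
    units: str


@dataclass
class DeviceRecording:
    """One stand-alone acquisition device: channels on a common clock."""

    name: str
    fs: float
    channels: dict[str, Channel]
    clock_offset_s: float = 0.0    # true offset (oracle; not used downstream)
    clock_skew_ppm: float = 0.0


@dataclass
class MultiChannelRecording:
    devices: dict[str, DeviceRecording]
    sync_channel: str
    metadata: dict

    def device_of(self, channel: str) -> str:
        for name, dev in self.devices.items():
            if channel in dev.channels:
                return name
        raise KeyError(channel)


@dataclass
class GroundTruth:
    """Per-beat oracle for one recording (times in absolute seconds)."""

    beat_times: np.ndarray         # atrial spike times
    v_times: np.ndarray            # ventricular spike times
    lvpmax: np.ndarray             # mmHg
    dpdtmax: np.ndarray            # mmHg/s
    artifact_flags: np.ndarray     # bool
    s1_times: dict[str, np.ndarray] = field(default_factory=dict)
    s2_times: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.beat_times)
        for arr in (self.v_times, self.lvpmax, self.dpdtmax,
                    self.artifact_flags):
            if len(arr) != n:
                raise ValueError("ground-truth arrays must share a length")
        if np.any(self.lvpmax <= 0):
            raise ValueError("lvpmax must be positive")


# ---------------------------------------------------------------------------
# Single-beat templates
# ---------------------------------------------------------------------------

def synth_pressure_beat(
    lvpmax: float,
    dpdtmax: float,
    cycle_len: float,
    fs: float,
    edp: float = 8.0,
    onset_s: float | None = None,
) -> np.ndarray:
    """One cycle of LV pressure realizing ``lvpmax`` and ``dpdtmax`` exactly.

    The template is a pre-systolic diastolic dip to ``edp``, a raised-cosine
    upstroke whose analytic maximum slope equals ``dpdtmax`` and whose crest
    equals ``lvpmax``, a gently decaying systolic dome (so the pressure
    maximum is unique and interior), a raised-cosine relaxation and a slow
    late-diastolic drift.  Cycles chain continuously at ``edp + 2``.

    Raises :class:`ParameterError` when the upstroke cannot reach
    ``lvpmax`` at slope ``dpdtmax`` within the systolic portion of the cycle.
    """
    if not (lvpmax > edp >= 0):
        raise ParameterError("require lvpmax > edp >= 0")
    if dpdtmax <= 0:
        raise ParameterError("dpdtmax must be positive")
    if cycle_len <= 0 or fs <= 0:
        raise ParameterError("cycle_len and fs must be positive")

    t_on = 0.15 * cycle_len if onset_s is None else onset_s
    t_sys = 0.15 * cycle_len
    t_fall = 0.12 * cycle_len
    # Raised-cosine upstroke: max slope = pi*(lvpmax-edp)/(2*T_r).
    t_rise = np.pi * (lvpmax - edp) / (2.0 * dpdtmax)
    if t_on + t_rise + t_sys + t_fall > cycle_len:
        raise ParameterError(
            f"infeasible beat: rising from {edp} to {lvpmax} mmHg at "
            f"{dpdtmax} mmHg/s needs {t_rise:.3f}s, which does not fit a "
            f"{cycle_len:.3f}s cycle"
        )

    n = int(round(cycle_len * fs))
    t = np.arange(n) / fs
    p = np.empty(n)

    pre = t < t_on
    p[pre] = edp + 1.0 + np.cos(np.pi * t[pre] / t_on)

    rise = (t >= t_on) & (t < t_on + t_rise)
    p[rise] = edp + 0.5 * (lvpmax - edp) * (
        1.0 - np.cos(np.pi * (t[rise] - t_on) / t_rise)
    )

    t1 = t_on + t_rise
    dome = (t >= t1) & (t < t1 + t_sys)
    p[dome] = lvpmax - 0.12 * (lvpmax - edp) * ((t[dome] - t1) / t_sys) ** 2

    p_sys_end = lvpmax - 0.12 * (lvpmax - edp)
    t2 = t1 + t_sys
    fall = (t >= t2) & (t < t2 + t_fall)
    p[fall] = edp + 2.5 + 0.5 * (p_sys_end - edp - 2.5) * (
        1.0 + np.cos(np.pi * (t[fall] - t2) / t_fall)
    )

    t3 = t2 + t_fall
    late = t >= t3
    if cycle_len - t3 > 0:
        p[late] = edp + 2.5 - 0.5 * (t[late] - t3) / (cycle_len - t3)
    else:  # pragma: no cover - excluded by feasibility check
        p[late] = edp + 2.0
    return p


def _gabor_burst(
    t: np.ndarray, centre: float, freq: float, sigma: float, pp: float
) -> np.ndarray:
    """Gaussian-windowed sinusoid rescaled to an exact peak-to-peak span."""
    w = np.exp(-0.5 * ((t - centre) / sigma) ** 2) * np.sin(
        2.0 * np.pi * freq * (t - centre)
    )
    span = w.max() - w.min()
    if span <= 0:
        return np.zeros_like(t)
    return w * (pp / span)


def s1_amplitude(dpdtmax: float, coupling: str = "linear") -> float:
    """Peak-to-peak S1 amplitude (g) at unit gain; strictly increasing."""
    if coupling == "linear":
        return S1_GAIN_PER_DPDT * dpdtmax
    if coupling == "sigmoid":
        return 2.0 / (1.0 + np.exp(-(dpdtmax - 1100.0) / 350.0))
    raise ParameterError(f"unknown coupling {coupling!r}")


def s2_amplitude(lvpmax: float, coupling: str = "linear") -> float:
    """Peak-to-peak S2 amplitude (g) at unit gain; strictly increasing."""
    if coupling == "linear":
        return S2_GAIN_PER_LVP * lvpmax
    if coupling == "sigmoid":
        return 1.2 / (1.0 + np.exp(-(lvpmax - 95.0) / 25.0))
    raise ParameterError(f"unknown coupling {coupling!r}")


def s2_delay(lvpmax: float) -> float:
    """Ventricular spike -> S2 centre delay (s).

    Load-dependence of the ejection time is deliberately not modelled:
    the hemodynamic targets are encoded in burst *amplitudes* only, so
    the temporal features act as uninformative controls that the
    feature-selection stage is expected to neglect.
    """
    return S2_BASE_DELAY_S + 0.0 * lvpmax


def synth_accel_beat(
    dpdtmax: float,
    lvpmax: float,
    gain: float,
    fs: float,
    pacing: PacingConfig,
    rng: np.random.Generator | None = None,
    *,
    noise_sd: float = 0.0,
    location: str = "mitral_valve",
    coupling: str = "linear",
    quantize: bool = True,
) -> tuple[np.ndarray, float, float]:
    """One cycle of Z-axis epicardial acceleration.

    Returns ``(trace, s1_centre, s2_centre)`` with times relative to the
    cycle start (the atrial spike sits at ``ATRIAL_SPIKE_OFFSET_S``).
    With ``noise_sd = 0`` the S1 peak-to-peak amplitude equals
    ``gain * s1_amplitude(dpdtmax)`` exactly and the S2 amplitude equals
    ``gain * s2_amplitude(lvpmax)``; samples are clipped to ±4 g and,
    when ``quantize`` is on, rounded to the 16-bit ADC grid.
    """
    if gain <= 0:
        raise ParameterError("gain must be positive")
    if rng is None:
        rng = np.random.default_rng(0)
    freq, s1_off, s2_off, rel = LOCATION_TRAITS[location]
    n = int(round(pacing.cycle_len_s * fs))
    t = np.arange(n) / fs
    v_time = ATRIAL_SPIKE_OFFSET_S + pacing.av_delay_s
    s1_c = v_time + S1_DELAY_S + s1_off
    s2_c = v_time + s2_delay(lvpmax) + s2_off
    sigma = 0.008  # ~50 ms burst support
    x = _gabor_burst(t, s1_c, freq, sigma, gain * rel *
                     s1_amplitude(dpdtmax, coupling))
    x += _gabor_burst(t, s2_c, 0.9 * freq, sigma, gain * rel *
                      s2_amplitude(lvpmax, coupling))
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, n)
    x = np.clip(x, -ACCEL_RANGE_G, ACCEL_RANGE_G)
    if quantize:
        lsb = 2.0 * ACCEL_RANGE_G / 2**ADC_BITS
        x = np.round(x / lsb) * lsb
    return x, s1_c, s2_c


# ---------------------------------------------------------------------------
# Whole-dataset simulation
# ---------------------------------------------------------------------------

def _config_modifiers(cfg: PacingConfig) -> tuple[float, float]:
    """Mild hemodynamic effect of the pacing programme (LVP, dP/dt)."""
    av_pen = abs(cfg.av_delay_ms - 120.0) / 180.0
    vv_pen = abs(cfg.vv_delay_ms) / 150.0
    mode_lvp = 0.97 if cfg.mode == "RV" else 1.0
    mode_dpdt = 0.93 if cfg.mode == "RV" else 1.0
    lvp_mod = (1.0 - 0.06 * av_pen) * (1.0 - 0.04 * vv_pen) * mode_lvp
    dpdt_mod = (1.0 - 0.10 * av_pen) * (1.0 - 0.06 * vv_pen) * mode_dpdt
    return lvp_mod, dpdt_mod


def default_subjects(
    n: int = 5,
    seed: int = 0,
    locations: tuple[str, ...] = DEFAULT_LOCATIONS,
    gain_spread: float = 0.15,
    noise_sd: float = 0.005,
) -> list[SubjectSpec]:
    """Five-animal cohort with subject-specific baselines and gains."""
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n):
        lvp = float(np.clip(rng.normal(97.0, 5.0), 88.0, 108.0))
        dpdt = float(np.clip(rng.normal(830.0, 45.0), 740.0, 920.0))
        gains = {
            loc: float(rng.uniform(1.0 - gain_spread, 1.0 + gain_spread))
            for loc in locations
        }
        subjects.append(
            SubjectSpec(
                subject_id=f"animal_{i + 1}",
                baseline_lvpmax=lvp,
                baseline_dpdtmax=dpdt,
                sensor_gains=gains,
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return subjects


def default_configs(duration_s: float = 60.0,
                    heart_rate_bpm: float = 100.0) -> list[PacingConfig]:
    """Seven pacing programmes spanning the three inotropic states."""
    mk = lambda mode, av, vv, state: PacingConfig(  # noqa: E731
        mode, av, vv, state, duration_s, heart_rate_bpm
    )
    return [
        mk("BiV", 150, 0, "baseline"),
        mk("RV", 100, 0, "baseline"),
        mk("BiV", 50, 50, "baseline"),
        mk("BiV", 150, 0, "dobutamine"),
        mk("RV", 100, 0, "dobutamine"),
        mk("BiV", 150, 0, "isoflurane"),
        mk("RV", 150, -50, "isoflurane"),
    ]


def _sync_trace(t_abs: np.ndarray, period: float = 1.0) -> np.ndarray:
    """1 Hz broadcast square pulse train evaluated at absolute times."""
    phase = np.mod(t_abs - SYNC_PULSE_START_S, period)
    on = (phase >= 0) & (phase < SYNC_PULSE_WIDTH_S) & (
        t_abs >= SYNC_PULSE_START_S
    )
    return on.astype(float)


def _simulate_one(
    subject: SubjectSpec,
    cfg: PacingConfig,
    locations: tuple[str, ...],
    artifact_rate: float,
    rng: np.random.Generator,
    fs_hemo: float,
    fs_accel: float,
    accel_offset_s: float,
    accel_skew_ppm: float,
) -> tuple[MultiChannelRecording, GroundTruth]:
    T = cfg.cycle_len_s
    n_beats = int(np.floor(cfg.duration_s / T))
    beat_starts = np.arange(n_beats) * T
    a_times = beat_starts + ATRIAL_SPIKE_OFFSET_S
    v_times = a_times + cfg.av_delay_s

    lvp_mod, dpdt_mod = _config_modifiers(cfg)
    s_lvp, s_dpdt = STATE_SCALE[cfg.state]
    lvp_centre = subject.baseline_lvpmax * s_lvp * lvp_mod
    dpdt_centre = subject.baseline_dpdtmax * s_dpdt * dpdt_mod

    resp_phase = rng.uniform(0, 2 * np.pi)
    resp = np.sin(2 * np.pi * 0.2 * beat_starts + resp_phase)
    lvp_b = lvp_centre + 1.0 * resp + rng.normal(0.0, 1.2, n_beats)
    dpdt_b = dpdt_centre + 10.0 * resp + rng.normal(0.0, 12.0, n_beats)
    # Truth targets stay inside the documented measurement ranges.
    lvp_b = np.clip(lvp_b, 60.0, 130.0)
    dpdt_b = np.clip(dpdt_b, 600.0, 1600.0)

    artifacts = rng.random(n_beats) < artifact_rate

    # --- hemodynamic device: ECG + pressure + sync at fs_hemo -------------
    n_hemo = int(round(cfg.duration_s * fs_hemo))
    t_hemo = np.arange(n_hemo) / fs_hemo
    pressure = np.zeros(n_hemo)
    onset = ATRIAL_SPIKE_OFFSET_S + cfg.av_delay_s + EM_DELAY_S
    for k in range(n_beats):
        beat = synth_pressure_beat(
            float(lvp_b[k]), float(dpdt_b[k]), T, fs_hemo, onset_s=onset
        )
        i0 = int(round(beat_starts[k] * fs_hemo))
        pressure[i0:i0 + len(beat)] = beat[: n_hemo - i0]
    pressure += rng.normal(0.0, 0.01, n_hemo)

    ecg = 0.15 * np.sin(2 * np.pi * 0.25 * t_hemo + resp_phase)
    ecg += rng.normal(0.0, 0.01, n_hemo)
    spike_w = max(2, int(round(0.002 * fs_hemo)))
    for times, amp in ((a_times, 1.0), (v_times, 1.2)):
        for tt in times:
            i0 = int(round(tt * fs_hemo))
            if i0 + 2 * spike_w < n_hemo:
                ecg[i0:i0 + spike_w] += amp
                ecg[i0 + spike_w:i0 + 2 * spike_w] -= 0.6 * amp
    # Broad ventricular depolarization wave after each V spike.
    qrs_c = v_times[:, None] + 0.06
    ecg += 0.35 * np.sum(
        np.exp(-0.5 * ((t_hemo[None, :] - qrs_c) / 0.02) ** 2), axis=0
    )

    hemo = DeviceRecording(
        name="hemo",
        fs=fs_hemo,
        channels={
            "ecg": Channel(ecg, fs_hemo, "mV"),
            "pressure": Channel(pressure, fs_hemo, "mmHg"),
            "sync": Channel(_sync_trace(t_hemo), fs_hemo, "V"),
        },
    )

    # --- accelerometer device: own clock (offset + ppm skew) --------------
    rate = 1.0 + accel_skew_ppm * 1e-6
    n_acc = int(round(cfg.duration_s * fs_accel))
    tau = np.arange(n_acc) / fs_accel          # device clock
    t_abs = accel_offset_s + tau * rate        # true time of each sample

    accel_channels: dict[str, Channel] = {
        "sync": Channel(_sync_trace(t_abs), fs_accel, "V")
    }
    s1_truth: dict[str, np.ndarray] = {}
    s2_truth: dict[str, np.ndarray] = {}
    lsb = 2.0 * ACCEL_RANGE_G / 2**ADC_BITS
    for loc in locations:
        freq, s1_off, s2_off, rel = LOCATION_TRAITS[loc]
        gain = subject.sensor_gains.get(loc, 1.0) * rel
        z = np.zeros(n_acc)
        s1_t = v_times + S1_DELAY_S + s1_off
        s2_t = v_times + np.array([s2_delay(l) for l in lvp_b]) + s2_off
        s1_t = s1_t + rng.normal(0.0, S1_JITTER_S, n_beats)
        s2_t = s2_t + rng.normal(0.0, S2_JITTER_S, n_beats)
        for k in range(n_beats):
            pp1 = gain * s1_amplitude(float(dpdt_b[k]))
            pp2 = gain * s2_amplitude(float(lvp_b[k]))
            c1, c2 = s1_t[k], s2_t[k]
            flip = 1.0
            if artifacts[k]:
                # Motion artifact: inverted or late, caught by coherence QC.
                if rng.random() < 0.5:
                    flip = -1.0
                else:
                    c1, c2 = c1 + 0.08, c2 + 0.08
            sel = slice(
                max(0, int((c1 - 0.1 - accel_offset_s) * fs_accel)),
                min(n_acc, int((c2 + 0.1 - accel_offset_s) * fs_accel)),
            )
            tt = t_abs[sel]
            z[sel] += flip * _gabor_burst(tt, c1, freq, 0.008, pp1)
            z[sel] += flip * _gabor_burst(tt, c2, 0.9 * freq, 0.008, pp2)
        # Respiration drift sits below the 10 Hz analysis band.
        z += 0.05 * np.sin(2 * np.pi * 0.25 * t_abs + resp_phase)
        if subject.noise_sd > 0:
            z = z + rng.normal(0.0, subject.noise_sd, n_acc)
        z = np.round(np.clip(z, -ACCEL_RANGE_G, ACCEL_RANGE_G) / lsb) * lsb
        x_axis = 0.3 * z + rng.normal(0.0, subject.noise_sd + 1e-4, n_acc)
        y_axis = 0.25 * z + rng.normal(0.0, subject.noise_sd + 1e-4, n_acc)
        accel_channels[f"accel_{loc}_z"] = Channel(z, fs_accel, "g")
        accel_channels[f"accel_{loc}_x"] = Channel(
            np.clip(x_axis, -4, 4), fs_accel, "g"
        )
        accel_channels[f"accel_{loc}_y"] = Channel(
            np.clip(y_axis, -4, 4), fs_accel, "g"
        )
        s1_truth[loc] = s1_t
        s2_truth[loc] = s2_t

    accel_dev = DeviceRecording(
        name="accel",
        fs=fs_accel,
        channels=accel_channels,
        clock_offset_s=accel_offset_s,
        clock_skew_ppm=accel_skew_ppm,
    )

    rec = MultiChannelRecording(
        devices={"hemo": hemo, "accel": accel_dev},
        sync_channel="sync",
        metadata={
            "subject": subject.subject_id,
            "pacing": asdict(cfg),
            "locations": list(locations),
            "setting": f"{subject.subject_id}/{cfg.name}",
        },
    )
    truth = GroundTruth(
        beat_times=a_times,
        v_times=v_times,
        lvpmax=lvp_b,
        dpdtmax=dpdt_b,
        artifact_flags=artifacts,
        s1_times=s1_truth,
        s2_times=s2_truth,
    )
    return rec, truth


def simulate_dataset(
    subjects: list[SubjectSpec],
    configs: list[PacingConfig],
    locations: tuple[str, ...] | list[str] = DEFAULT_LOCATIONS,
    artifact_rate: float = 0.02,
    seed: int = 0,
    *,
    fs_hemo: float = 2000.0,
    fs_accel: float = 1000.0,
    accel_offset_s: float = 0.25,
    accel_skew_ppm: float = 30.0,
) -> tuple[list[MultiChannelRecording], list[GroundTruth]]:
    """Simulate one recording per (subject, pacing configuration).

    The two emulated devices run at different rates; the accelerometer
    clock starts ``accel_offset_s`` late and drifts by ``accel_skew_ppm``
    so the sync-pulse alignment stage has real work to do.  Deterministic
    for a fixed argument set and ``seed``.
    """
    if not subjects or not configs:
        raise ParameterError("need at least one subject and one config")
    if not 0.0 <= artifact_rate < 1.0:
        raise ParameterError("artifact_rate must lie in [0, 1)")
    locations = tuple(locations)
    recordings: list[MultiChannelRecording] = []
    truths: list[GroundTruth] = []
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(subjects) * len(configs))
    i = 0
    for subject in subjects:
        for cfg in configs:
            rng = np.random.default_rng(streams[i])
            i += 1
            rec, truth = _simulate_one(
                subject, cfg, locations, artifact_rate, rng,
                fs_hemo, fs_accel, accel_offset_s, accel_skew_ppm,
            )
            recordings.append(rec)
            truths.append(truth)
    return recordings, truths


# ---------------------------------------------------------------------------
# On-disk format: one CSV per device + JSON manifest + ground-truth CSV
# ---------------------------------------------------------------------------

def write_dataset(
    outdir: str | Path,
    recordings: list[MultiChannelRecording],
    truths: list[GroundTruth],
    seed: int | None = None,
) -> Path:
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    index = []
    for rec, truth in zip(recordings, truths):
        name = rec.metadata["setting"].replace("/", "__")
        rdir = outdir / name
        rdir.mkdir(exist_ok=True)
        manifest: dict = {
            "metadata": rec.metadata,
            "sync_channel": rec.sync_channel,
            "devices": {},
        }
        if seed is not None:
            manifest["seed"] = seed
        for dev_name, dev in rec.devices.items():
            cols = {"sample_index": np.arange(
                len(next(iter(dev.channels.values())).samples))}
            units = {}
            for ch_name, ch in dev.channels.items():
                cols[ch_name] = ch.samples
                units[ch_name] = ch.units
            pd.DataFrame(cols).to_csv(rdir / f"{dev_name}.csv", index=False,
                                      float_format="%.6g")
            manifest["devices"][dev_name] = {"fs": dev.fs, "units": units}
        (rdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
        pd.DataFrame({
            "beat_time_s": truth.beat_times,
            "v_time_s": truth.v_times,
            "lvpmax_mmhg": truth.lvpmax,
            "dpdtmax_mmhg_s": truth.dpdtmax,
            "artifact": truth.artifact_flags.astype(int),
        }).to_csv(rdir / "ground_truth.csv", index=False)
        index.append(name)
    (outdir / "index.json").write_text(json.dumps(index, indent=2))
    return outdir


def load_dataset(
    indir: str | Path,
) -> tuple[list[MultiChannelRecording], list[GroundTruth]]:
    import pandas as pd

    indir = Path(indir)
    names = json.loads((indir / "index.json").read_text())
    recordings, truths = [], []
    for name in names:
        rdir = indir / name
        manifest = json.loads((rdir / "manifest.json").read_text())
        devices = {}
        for dev_name, info in manifest["devices"].items():
            df = pd.read_csv(rdir / f"{dev_name}.csv")
            channels = {
                c: Channel(df[c].to_numpy(float), info["fs"],
                           info["units"][c])
                for c in df.columns if c != "sample_index"
            }
            devices[dev_name] = DeviceRecording(dev_name, info["fs"],
                                                channels)
        recordings.append(MultiChannelRecording(
            devices=devices,
            sync_channel=manifest["sync_channel"],
            metadata=manifest["metadata"],
        ))
        gt = pd.read_csv(rdir / "ground_truth.csv")
        truths.append(GroundTruth(
            beat_times=gt["beat_time_s"].to_numpy(),
            v_times=gt["v_time_s"].to_numpy(),
            lvpmax=gt["lvpmax_mmhg"].to_numpy(),
            dpdtmax=gt["dpdtmax_mmhg_s"].to_numpy(),
            artifact_flags=gt["artifact"].to_numpy().astype(bool),
        ))
    return recordings, truths
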