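"""Synthetic FMCW baseband data cubes for vital-sign and occupancy studies.

The chest–radar distance is modelled as
``R(τ) = d0 + A·sin(2π f_r τ) + B_h·sin(2π f_h τ) + m(τ)`` where ``m`` is a
band-limited motion artifact derived from cabin acceleration noise.  Each
frame's fast-time samples carry the beat tone ``f_b = 2·B·R/(c·T_c)`` and a
slow-time phase ``4π·R/λ``; complex white noise sets the per-sample SNR.

Three driving conditions (standby / driving / bumpy) are parameterized by
their RMS cabin accelerations, with separate values for operation with and
without the focusing lens; the lens additionally contributes an SNR offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.constants import c as C0

__all__ = [
    "RadarConfig",
    "VitalScenario",
    "SlowTimeCube",
    "OccupancyScript",
    "scenario",
    "displacement_series",
    "motion_displacement",
    "beat_signal",
    "occupancy_cube",
    "SCENARIO_TABLE",
]


@dataclass(frozen=True)
class RadarConfig:
    """FMCW front-end parameters (defaults: the 60 GHz seatbelt system)."""

    n_adc_samples: int = 64
    n_chirps: int = 1
    chirp_time: float = 32e-6
    n_tx: int = 1
    n_rx: int = 3
    bandwidth: float = 5e9
    frame_time: float = 75.476e-3
    fov_azimuth_deg: float = 70.0
    center_frequency: float = 60e9

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.frame_time <= self.chirp_time:
            raise ValueError("frame_time must exceed chirp_time")

    @property
    def wavelength(self) -> float:
        return C0 / self.center_frequency

    @property
    def fast_rate(self) -> float:
        """ADC sampling rate within a chirp, Hz."""
        return self.n_adc_samples / self.chirp_time

    @property
    def slow_rate(self) -> float:
        """Frame (slow-time) sampling rate, Hz."""
        return 1.0 / self.frame_time

    @property
    def range_bin(self) -> float:
        """Range resolution / FFT bin spacing, c/(2B) metres."""
        return C0 / (2 * self.bandwidth)

    @property
    def max_unambiguous_range(self) -> float:
        """Range at which the beat frequency reaches the fast-time sample rate."""
        return self.fast_rate * C0 * self.chirp_time / (2 * self.bandwidth)

    def beat_frequency(self, distance) -> np.ndarray | float:
        return 2 * self.bandwidth * np.asarray(distance) / (C0 * self.chirp_time)


# Per-condition study parameters: RMS cabin acceleration (m/s², Table of driving
# conditions) and the carrier rates observed in each condition.
SCENARIO_TABLE = {
    "standby": {"rms_acc_lens": 0.030, "rms_acc_nolens": 0.037, "f_r": 0.45, "f_h": 1.12},
    "driving": {"rms_acc_lens": 0.200, "rms_acc_nolens": 0.325, "f_r": 0.53, "f_h": 1.20},
    "bumpy": {"rms_acc_lens": 0.310, "rms_acc_nolens": 0.470, "f_r": 0.52, "f_h": 1.18},
}

SNR_WITH_LENS_DB = 20.0
SNR_WITHOUT_LENS_DB = 10.0  # lens benefit modelled as a +10 dB offset


@dataclass(frozen=True)
class VitalScenario:
    """One simulated occupant under one driving condition.

    ``motion_rms_acc`` is the cabin acceleration RMS; only a fraction
    ``motion_coupling`` of the doubly-integrated motion appears as radial
    chest–radar displacement (sensor and occupant share the cabin frame).
    """

    d0: float = 0.6
    resp_amplitude: float = 4e-3
    heart_amplitude: float = 0.3e-3
    resp_freq: float = 0.45
    heart_freq: float = 1.12
    duration: float = 300.0
    motion_rms_acc: float = 0.030
    motion_coupling: float = 0.1
    motion_band: tuple[float, float] = (0.5, 4.0)
    snr_db: float = SNR_WITH_LENS_DB
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.resp_amplitude > self.heart_amplitude > 0):
            raise ValueError("require resp_amplitude > heart_amplitude > 0")
        if not (0.1 <= self.resp_freq <= 0.7):
            raise ValueError(f"resp_freq {self.resp_freq} outside the 0.1–0.7 Hz band")
        if not (0.7 <= self.heart_freq <= 2.5):
            raise ValueError(f"heart_freq {self.heart_freq} outside the 0.7–2.5 Hz band")
        if not (0.5 <= self.d0 <= 0.8):
            raise ValueError(f"d0 {self.d0} outside the 0.5–0.8 m acquisition gate")
        # slow-time Nyquist for the default frame rate (≈ 6.62 Hz) must cover f_h
        if self.heart_freq >= 0.5 / RadarConfig().frame_time:
            raise ValueError("heart_freq at or above the slow-time Nyquist rate")


def scenario(condition: str, with_lens: bool = True, **overrides) -> VitalScenario:
    """Preset scenario for ``condition`` in {standby, driving, bumpy}."""
    try:
        row = SCENARIO_TABLE[condition]
    except KeyError:
        raise ValueError(f"unknown condition {condition!r}; choose from {sorted(SCENARIO_TABLE)}")
    params = dict(
        resp_freq=row["f_r"],
        heart_freq=row["f_h"],
        motion_rms_acc=row["rms_acc_lens"] if with_lens else row["rms_acc_nolens"],
        snr_db=SNR_WITH_LENS_DB if with_lens else SNR_WITHOUT_LENS_DB,
    )
    params.update(overrides)
    return VitalScenario(**params)


def motion_displacement(
    n: int,
    dt: float,
    rms_acc: float,
    band: tuple[float, float] = (0.5, 4.0),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Displacement whose second derivative is band-limited white noise.

    White Gaussian acceleration is restricted to ``band`` in the frequency
    domain, scaled so its sample RMS equals ``rms_acc`` exactly, and
    integrated twice spectrally (division by −(2πf)², no secular drift).
    Returns displacement in metres.
    """
    if rng is None:
        rng = np.random.default_rng()
    if rms_acc <= 0 or n < 4:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, dt)
    spec = np.fft.rfft(rng.standard_normal(n))
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        return np.zeros(n)
    spec = spec * mask
    acc = np.fft.irfft(spec, n)
    scale = rms_acc / np.sqrt(np.mean(acc**2))
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_spec = np.where(mask, -spec * scale / (2 * np.pi * freqs) ** 2, 0.0)
    return np.fft.irfft(disp_spec, n)


def displacement_series(scn: VitalScenario, timestamps: np.ndarray) -> np.ndarray:
    """Chest–radar distance R(τ) at the given (sorted) slow-time stamps."""
    t = np.asarray(timestamps, float)
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ValueError("timestamps must be sorted")
    r = (
        scn.d0
        + scn.resp_amplitude * np.sin(2 * np.pi * scn.resp_freq * t)
        + scn.heart_amplitude * np.sin(2 * np.pi * scn.heart_freq * t)
    )
    if scn.motion_rms_acc > 0 and t.size > 3:
        dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
        rng = np.random.default_rng(scn.seed)
        r = r + scn.motion_coupling * motion_displacement(
            t.size, dt, scn.motion_rms_acc, scn.motion_band, rng
        )
    return r


@dataclass
class SlowTimeCube:
    """Complex baseband samples ``iq[rx, frame, fast]`` with ground truth."""

    iq: np.ndarray
    config: RadarConfig
    timestamps: np.ndarray
    truth_displacement: np.ndarray | None = None
    truth_state: np.ndarray | None = None  # per-frame {"empty","object","person"}
    scenario: VitalScenario | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.iq = np.asarray(self.iq, dtype=complex)
        if self.iq.ndim == 2:
            self.iq = self.iq[None]
        if self.iq.shape[-1] != self.config.n_adc_samples:
            raise ValueError("fast-time length must equal n_adc_samples")

    @property
    def n_frames(self) -> int:
        return self.iq.shape[1]


def _frame_times(config: RadarConfig, duration: float) -> np.ndarray:
    n_frames = int(np.floor(duration / config.frame_time))
    return np.arange(n_frames) * config.frame_time


def _synthesize(
    config: RadarConfig,
    distances: np.ndarray,
    amplitudes: np.ndarray,
    noise_sigma: float,
    rng: np.random.Generator,
    n_rx: int,
) -> np.ndarray:
    """Cube samples for per-frame target distance and amplitude."""
    if np.any(distances <= 0) or np.any(distances >= config.max_unambiguous_range):
        raise ValueError(
            f"target distance outside the unambiguous range "
            f"(0, {config.max_unambiguous_range:.3f}) m"
        )
    t_fast = np.arange(config.n_adc_samples) / config.fast_rate
    f_b = np.asarray(config.beat_frequency(distances))
    phase_slow = 4 * np.pi * distances / config.wavelength
    signal = amplitudes[:, None] * np.exp(
        1j * (2 * np.pi * f_b[:, None] * t_fast[None, :] + phase_slow[:, None])
    )
    shape = (n_rx,) + signal.shape
    noise = np.zeros(shape, dtype=complex)
    if noise_sigma > 0:
        noise = (noise_sigma / np.sqrt(2)) * (
            rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        )
    return signal[None, :, :] + noise


def beat_signal(
    scn: VitalScenario, config: RadarConfig | None = None, seed: int | None = None
) -> SlowTimeCube:
    """Simulate one vital-sign recording as a slow-time cube.

    The per-sample SNR (signal power over complex-noise power) follows
    ``scn.snr_db``; the three RX channels share the signal and carry
    independent noise.
    """
    if config is None:
        config = RadarConfig()
    if seed is None:
        seed = scn.seed
    rng = np.random.default_rng(seed)
    t = _frame_times(config, scn.duration)
    r = displacement_series(scn, t)
    noise_sigma = 10 ** (-scn.snr_db / 20)
    iq = _synthesize(config, r, np.ones(t.size), noise_sigma, rng, config.n_rx)
    return SlowTimeCube(
        iq=iq,
        config=config,
        timestamps=t,
        truth_displacement=r,
        scenario=scn,
        meta={"seed": seed, "snr_db": scn.snr_db},
    )


@dataclass(frozen=True)
class Segment:
    state: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.state not in ("empty", "object", "person"):
            raise ValueError(f"unknown segment state {self.state!r}")
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")


@dataclass
class OccupancyScript:
    """Contiguous, non-overlapping timeline of seat states."""

    segments: list[Segment]

    def __post_init__(self) -> None:
        segs = sorted(self.segments, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end - 1e-12:
                raise ValueError(f"segments overlap at t={b.start}")
            if abs(b.start - a.end) > 1e-9:
                raise ValueError(f"segments must be contiguous; gap at t={a.end}")
        self.segments = segs

    @property
    def duration(self) -> float:
        return self.segments[-1].end

    def states_at(self, times: np.ndarray) -> np.ndarray:
        out = np.empty(len(times), dtype=object)
        for seg in self.segments:
            sel = (times >= seg.start) & (times < seg.end)
            out[sel] = seg.state
        out[times >= self.duration - 1e-12] = self.segments[-1].state
        return out.astype(str)

    @classmethod
    def standard(cls) -> "OccupancyScript":
        """The 120 s empty / bag / person / empty demonstration timeline."""
        return cls(
            [
                Segment("empty", 0.0, 20.0),
                Segment("object", 20.0, 40.0),
                Segment("person", 40.0, 80.0),
                Segment("empty", 80.0, 120.0),
            ]
        )


# State-dependent envelope model for occupancy scenes.  The empty seat gives a
# static surface return; a bag raises it; a person adds respiration-correlated
# amplitude modulation and band-limited body micro-motion on top of the phase
# modulation of the vital-sign displacement.
DEFAULT_STATE_AMPLITUDE = {"empty": 0.2, "object": 0.35, "person": 0.5}
DEFAULT_ENV_FLUCT_STD = {"empty": 0.02, "object": 0.02, "person": 0.15}


def occupancy_cube(
    script: OccupancyScript,
    config: RadarConfig | None = None,
    seed: int = 0,
    *,
    state_amplitude: dict | None = None,
    env_fluct_std: dict | None = None,
    env_band: tuple[float, float] = (0.3, 2.0),
    breath_am: float = 0.1,
    envelope_noise: float = 0.01,
    seat_range: float = 0.65,
    vitals: VitalScenario | None = None,
) -> SlowTimeCube:
    """Simulate the scripted seat-occupancy scene.

    ``envelope_noise`` is the post-range-FFT thermal noise level on the
    envelope (signal-amplitude units); the per-sample cube noise is scaled
    so a Hann-windowed FFT reaches that level.
    """
    if config is None:
        config = RadarConfig()
    amp_map = dict(DEFAULT_STATE_AMPLITUDE, **(state_amplitude or {}))
    env_map = dict(DEFAULT_ENV_FLUCT_STD, **(env_fluct_std or {}))
    if vitals is None:
        vitals = VitalScenario(
            d0=0.6, resp_freq=0.3, heart_freq=1.1, duration=script.duration,
            motion_rms_acc=0.0, seed=seed,
        )
    rng = np.random.default_rng(seed)
    t = _frame_times(config, script.duration)
    states = script.states_at(t)

    distances = np.full(t.size, seat_range)
    amplitudes = np.zeros(t.size)
    truth_disp = np.zeros(t.size)

    person = states == "person"
    if person.any():
        r_person = displacement_series(replace(vitals, seed=seed + 1), t)
        distances[person] = r_person[person]
        truth_disp[person] = r_person[person] - vitals.d0

    for st in ("empty", "object", "person"):
        sel = states == st
        if not sel.any():
            continue
        base = amp_map[st]
        fluct = env_map[st] * _bandlimited_noise(t.size, config.frame_time, env_band, rng)
        amp = base * np.ones(t.size) + fluct
        if st == "person":
            amp = amp + base * breath_am * np.sin(2 * np.pi * vitals.resp_freq * t)
        amplitudes[sel] = np.clip(amp[sel], 0.0, None)

    # Hann-window processing gain: envelope noise σ_env = σ_s·√Σw² / Σw
    n = config.n_adc_samples
    w = np.hanning(n)
    noise_sigma = envelope_noise * w.sum() / np.sqrt((w**2).sum())
    iq = _synthesize(config, distances, amplitudes, noise_sigma, rng, config.n_rx)
    return SlowTimeCube(
        iq=iq,
        config=config,
        timestamps=t,
        truth_displacement=truth_disp,
        truth_state=states,
        scenario=vitals,
        meta={"seed": seed, "script": [(s.state, s.start, s.end) for s in script.segments]},
    )


def _bandlimited_noise(
    n: int, dt: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian noise restricted to a frequency band."""
    freqs = np.fft.rfftfreq(n, dt)
    spec = np.fft.rfft(rng.standard_normal(n))
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        return np.zeros(n)
    x = np.fft.irfft(spec * mask, n)
    return x / np.sqrt(np.mean(x**2))
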