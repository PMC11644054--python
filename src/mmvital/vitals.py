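"""Vital-sign processing chain: range FFT → bin selection → phase → VMD → rates.

The slow-time phase of the selected range bin encodes chest displacement as
``φ_b = 4π·R(τ)/λ``; after unwrapping and linear detrending, VMD separates
respiration (0.1–0.7 Hz) and heartbeat (0.8–2.5 Hz) modes.  Rates come from
parabolic-interpolated spectral peaks of each mode; beat-to-beat (IBI, ms)
and breath-to-breath (BBI, s) intervals from time-domain peak spacing.
Agreement statistics (Bland–Altman limits, coefficient of variation,
error %) compare interval or rate series against a reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.constants import c as C0

from .radar import SlowTimeCube
from .vmd import VMDResult, vmd

__all__ = [
    "RangeProfile",
    "PhaseSeries",
    "BinSelection",
    "ModeAssignment",
    "VitalsEstimate",
    "AgreementReport",
    "range_fft",
    "select_bin",
    "extract_phase",
    "assign_modes",
    "estimate_rates",
    "spectral_peak",
    "agreement",
    "process_cube",
    "windowed_rates",
    "RESP_BAND",
    "HEART_BAND",
]

RESP_BAND = (0.1, 0.7)
HEART_BAND = (0.8, 2.5)


class GateError(ValueError):
    """Range gate empty or outside the profile."""


@dataclass
class RangeProfile:
    """Range bins per frame: ``data[rx, frame, bin]`` complex, Hann-windowed FFT.

    ``phase_sensitivity`` is the slow-time phase change per metre of target
    displacement.  Besides the carrier term 4π/λ, the beat tone contributes
    2π·(2B/(c·T_c))·t̄ where t̄ is the fast-time window centroid — the bin
    phase effectively references the chirp frequency at the centroid, not
    the nominal carrier.
    """

    data: np.ndarray
    bin_spacing: float
    frame_time: float
    wavelength: float
    phase_sensitivity: float = 0.0
    gate: tuple[float, float] = (0.5, 0.8)

    @property
    def n_bins(self) -> int:
        return self.data.shape[-1]

    @property
    def ranges(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_spacing


def range_fft(cube: SlowTimeCube, window: str = "hann") -> RangeProfile:
    """Windowed fast-time FFT per frame; bin spacing c/(2B).

    The FFT is normalized by the window sum so a bin-centred unit-amplitude
    tone yields unit envelope.
    """
    n = cube.config.n_adc_samples
    if n < 2:
        raise ValueError("fast-time length must be >= 2")
    w = sps.get_window(window, n, fftbins=True) if window else np.ones(n)
    data = np.fft.fft(cube.iq * w, axis=-1) / w.sum()
    cfg = cube.config
    t_centroid = float((w * np.arange(n)).sum() / w.sum()) / cfg.fast_rate
    sensitivity = 4 * np.pi / cfg.wavelength + 2 * np.pi * (
        2 * cfg.bandwidth / (C0 * cfg.chirp_time)
    ) * t_centroid
    return RangeProfile(
        data=data,
        bin_spacing=cfg.range_bin,
        frame_time=cfg.frame_time,
        wavelength=cfg.wavelength,
        phase_sensitivity=sensitivity,
    )


@dataclass(frozen=True)
class BinSelection:
    index: int
    mean_power: float
    no_target: bool


def select_bin(profile: RangeProfile, gate: tuple[float, float] | None = None) -> BinSelection:
    """Bin of maximum mean power within the range gate (ties → lowest bin).

    Flags ``no_target`` when the in-gate peak does not stand clear of the
    out-of-gate noise floor (5× the median bin power).
    """
    if gate is None:
        gate = profile.gate
    lo = int(np.ceil(gate[0] / profile.bin_spacing))
    hi = int(np.floor(gate[1] / profile.bin_spacing))
    if lo > hi or lo >= profile.n_bins:
        raise GateError(f"gate {gate} selects no bins of the {profile.n_bins}-bin profile")
    hi = min(hi, profile.n_bins - 1)
    power = np.mean(np.abs(profile.data) ** 2, axis=tuple(range(profile.data.ndim - 1)))
    in_gate = power[lo : hi + 1]
    idx = lo + int(np.argmax(in_gate))
    floor = float(np.median(power))
    return BinSelection(
        index=idx,
        mean_power=float(power[idx]),
        no_target=bool(power[idx] < 5 * floor),
    )


@dataclass
class PhaseSeries:
    """Unwrapped slow-time phase of one range bin (channels fused)."""

    phase: np.ndarray
    dt: float
    bin_index: int
    wavelength: float
    phase_sensitivity: float = 0.0  # rad per metre; 0 -> fall back to 4pi/lambda

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.phase.size) * self.dt

    @property
    def displacement(self) -> np.ndarray:
        """Relative displacement estimate (zero-mean, metres).

        Uses the full phase sensitivity when known, otherwise φ·λ/(4π).
        """
        k = self.phase_sensitivity or 4 * np.pi / self.wavelength
        rel = self.phase - self.phase.mean()
        return rel / k


def _wrap_pi(x):
    return np.mod(x + np.pi, 2 * np.pi) - np.pi


def predictive_unwrap(wrapped: np.ndarray, damping: float = 0.9) -> np.ndarray:
    """Slip-robust unwrapping with a damped constant-velocity predictor.

    Chest displacement is smooth, so the per-frame phase *increment* varies
    slowly even when it approaches ±π; each new sample is unwrapped relative
    to the predicted value ``φ[n−1] + damping·(φ[n−1] − φ[n−2])`` instead of
    the previous sample.  The innovation (phase acceleration plus noise) is
    far smaller than the raw increment, which pushes wrap errors out to many
    standard deviations.  Reduces to plain unwrapping for ``damping=0``.
    """
    theta = np.asarray(wrapped, float)
    out = np.empty_like(theta)
    out[0] = theta[0]
    velocity = 0.0
    for i in range(1, theta.size):
        pred = out[i - 1] + damping * velocity
        out[i] = pred + _wrap_pi(theta[i] - pred)
        velocity = out[i] - out[i - 1]
    return out


def extract_phase(profile: RangeProfile, bin_index: int, fuse: str = "mean") -> PhaseSeries:
    """Unwrapped angle of the selected bin over slow time, RX channels averaged.

    Each channel is unwrapped independently (predictive unwrapper) and
    referenced to its first sample before fusion, so channel-constant phase
    offsets cancel.
    """
    if not (0 <= bin_index < profile.n_bins):
        raise ValueError(f"bin {bin_index} outside profile with {profile.n_bins} bins")
    series = profile.data[..., bin_index]
    if series.ndim == 1:
        series = series[None]
    phases = np.stack([predictive_unwrap(np.angle(ch)) for ch in series])
    phases = phases - phases[:, :1]
    fused = phases.mean(axis=0) if fuse == "mean" else phases[0]
    return PhaseSeries(
        phase=fused,
        dt=profile.frame_time,
        bin_index=bin_index,
        wavelength=profile.wavelength,
        phase_sensitivity=profile.phase_sensitivity,
    )


@dataclass(frozen=True)
class ModeAssignment:
    resp_index: int | None
    heart_index: int | None

    @property
    def missing_resp(self) -> bool:
        return self.resp_index is None

    @property
    def missing_heart(self) -> bool:
        return self.heart_index is None


def assign_modes(
    result: VMDResult,
    resp_band: tuple[float, float] = RESP_BAND,
    heart_band: tuple[float, float] = HEART_BAND,
) -> ModeAssignment:
    """Highest-power mode with center frequency in each vital band.

    A band containing no mode yields ``None`` for that vital (missing flag).
    """
    if result.k < 2:
        raise ValueError("mode assignment requires at least 2 modes")
    powers = result.modes.var(axis=1)
    freqs = result.center_frequencies

    def pick(band):
        in_band = np.where((freqs >= band[0]) & (freqs <= band[1]))[0]
        if in_band.size == 0:
            return None
        return int(in_band[np.argmax(powers[in_band])])

    return ModeAssignment(resp_index=pick(resp_band), heart_index=pick(heart_band))


def spectral_peak(x: np.ndarray, fs: float, pad: int = 8) -> float:
    """Frequency of the dominant spectral peak, Hann window + parabolic interpolation."""
    x = np.asarray(x, float)
    x = x - x.mean()
    if np.allclose(x, 0):
        return 0.0
    w = np.hanning(x.size)
    spec = np.abs(np.fft.rfft(x * w, n=pad * x.size))
    if spec.size < 3:
        return 0.0
    i = int(np.argmax(spec[1:])) + 1
    df = fs / (pad * x.size)
    if 0 < i < spec.size - 1 and spec[i] > 0:
        with np.errstate(divide="ignore"):
            a, b, c = np.log(spec[i - 1] + 1e-300), np.log(spec[i] + 1e-300), np.log(spec[i + 1] + 1e-300)
        denom = a - 2 * b + c
        delta = 0.5 * (a - c) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return (i + delta) * df


def _peak_times(mode: np.ndarray, dt: float, min_interval: float) -> np.ndarray:
    """Times of prominent maxima, spaced at least ``min_interval`` apart.

    Peak locations are refined to sub-sample precision with a parabolic fit
    through each maximum and its neighbours; otherwise interval estimates
    are quantized to the frame time (75 ms — far coarser than the beat
    timing the slow-time phase supports).
    """
    distance = max(1, int(round(min_interval / dt)))
    rms = float(np.sqrt(np.mean((mode - mode.mean()) ** 2)))
    if rms == 0:
        return np.array([])
    peaks, _ = sps.find_peaks(mode, distance=distance, prominence=0.5 * rms)
    refined = []
    for p in peaks:
        if 0 < p < mode.size - 1:
            a, b, c = mode[p - 1], mode[p], mode[p + 1]
            denom = a - 2 * b + c
            delta = 0.5 * (a - c) / denom if denom != 0 else 0.0
            refined.append((p + float(np.clip(delta, -0.5, 0.5))) * dt)
        else:
            refined.append(p * dt)
    return np.asarray(refined)


@dataclass
class VitalsEstimate:
    """Per-mode rates, intervals and spectra for one recording or window."""

    resp_hz: float | None
    heart_hz: float | None
    resp_mode_index: int | None
    heart_mode_index: int | None
    ibi_ms: np.ndarray = field(default_factory=lambda: np.array([]))
    bbi_s: np.ndarray = field(default_factory=lambda: np.array([]))
    ibi_times: np.ndarray = field(default_factory=lambda: np.array([]))
    bbi_times: np.ndarray = field(default_factory=lambda: np.array([]))
    flags: list[str] = field(default_factory=list)
    vmd_result: VMDResult | None = None

    @property
    def resp_bpm(self) -> float | None:
        return None if self.resp_hz is None else 60.0 * self.resp_hz

    @property
    def heart_bpm(self) -> float | None:
        return None if self.heart_hz is None else 60.0 * self.heart_hz


def estimate_rates(result: VMDResult, assignment: ModeAssignment, fs: float) -> VitalsEstimate:
    """Rates from spectral peaks; IBI/BBI series from time-domain peak spacing.

    IBI entries below 300 ms are physiologically impossible and discarded
    (and flagged); an interval series with fewer than 3 detected peaks is
    flagged short.
    """
    flags: list[str] = []
    dt = 1.0 / fs

    resp_hz = heart_hz = None
    ibi = np.array([])
    bbi = np.array([])
    ibi_t = np.array([])
    bbi_t = np.array([])

    if assignment.missing_resp:
        flags.append("missing-resp-mode")
    else:
        mode = result.modes[assignment.resp_index]
        resp_hz = spectral_peak(mode, fs)
        t_pk = _peak_times(mode, dt, min_interval=1.0 / RESP_BAND[1])
        if t_pk.size < 3:
            flags.append("bbi-series-short")
        if t_pk.size >= 2:
            bbi = np.diff(t_pk)
            bbi_t = t_pk[1:]

    if assignment.missing_heart:
        flags.append("missing-heart-mode")
    else:
        mode = result.modes[assignment.heart_index]
        heart_hz = spectral_peak(mode, fs)
        t_pk = _peak_times(mode, dt, min_interval=0.3)
        if t_pk.size < 3:
            flags.append("ibi-series-short")
        if t_pk.size >= 2:
            iv = np.diff(t_pk) * 1000.0
            keep = iv > 300.0
            if not keep.all():
                flags.append("ibi-below-300ms-discarded")
            ibi = iv[keep]
            ibi_t = t_pk[1:][keep]

    return VitalsEstimate(
        resp_hz=resp_hz,
        heart_hz=heart_hz,
        resp_mode_index=assignment.resp_index,
        heart_mode_index=assignment.heart_index,
        ibi_ms=ibi,
        bbi_s=bbi,
        ibi_times=ibi_t,
        bbi_times=bbi_t,
        flags=flags,
        vmd_result=result,
    )


@dataclass
class AgreementReport:
    """Bland–Altman agreement between two paired series."""

    mean_difference: float
    loa_low: float
    loa_high: float
    sd_difference: float
    cv_a: float
    cv_b: float
    error_percent: float | None
    n: int
    labels: tuple[str, str] = ("a", "b")
    flags: list[str] = field(default_factory=list)


def agreement(series_a, series_b, labels: tuple[str, str] = ("a", "b")) -> AgreementReport:
    """Bland–Altman limits (±1.96·SD), per-series CV and |mean error| %.

    ``series_b`` is the reference for the error percentage; a zero-mean
    reference leaves it undefined (flagged).
    """
    a = np.asarray(series_a, float)
    b = np.asarray(series_b, float)
    if a.size != b.size:
        raise ValueError("series must have equal length")
    if a.size < 3:
        raise ValueError("agreement needs at least 3 paired points")
    d = a - b
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    flags = []
    err = None
    if b.mean() == 0:
        flags.append("zero-mean-reference")
    else:
        err = float(abs(a.mean() - b.mean()) / abs(b.mean()) * 100.0)
    cv = lambda s: float(s.std(ddof=1) / s.mean()) if s.mean() != 0 else np.nan
    return AgreementReport(
        mean_difference=mean_d,
        loa_low=mean_d - 1.96 * sd_d,
        loa_high=mean_d + 1.96 * sd_d,
        sd_difference=sd_d,
        cv_a=cv(a),
        cv_b=cv(b),
        error_percent=err,
        n=int(a.size),
        labels=labels,
        flags=flags,
    )


def process_cube(
    cube: SlowTimeCube,
    *,
    k: int = 4,
    alpha: float = 2000.0,
    tau: float = 0.0,
    tol: float = 1e-7,
    gate: tuple[float, float] = (0.5, 0.8),
) -> VitalsEstimate:
    """Full chain on one cube: range FFT, gate, phase, detrend, VMD, rates."""
    profile = range_fft(cube)
    sel = select_bin(profile, gate)
    ph = extract_phase(profile, sel.index)
    detrended = sps.detrend(ph.phase, type="linear")
    result = vmd(detrended, k, alpha=alpha, tau=tau, tol=tol, fs=ph.fs)
    est = estimate_rates(result, assign_modes(result), ph.fs)
    if sel.no_target:
        est.flags.append("no-target-in-gate")
    return est


def windowed_rates(
    phase: PhaseSeries,
    *,
    window_s: float = 30.0,
    overlap: float = 0.5,
    k: int = 4,
    alpha: float = 2000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window (resp_hz, heart_hz) over fixed-length sliding windows.

    Windows with a missing vital mode are skipped.  Returns two arrays of
    equal length (one entry per usable window).
    """
    n_win = int(round(window_s * phase.fs))
    if n_win < 2 * k:
        raise ValueError("window too short for the requested mode count")
    step = max(1, int(round(n_win * (1 - overlap))))
    resp, heart = [], []
    for start in range(0, phase.phase.size - n_win + 1, step):
        seg = sps.detrend(phase.phase[start : start + n_win], type="linear")
        result = vmd(seg, k, alpha=alpha, fs=phase.fs)
        asn = assign_modes(result)
        if asn.missing_resp or asn.missing_heart:
            continue
        resp.append(spectral_peak(result.modes[asn.resp_index], phase.fs))
        heart.append(spectral_peak(result.modes[asn.heart_index], phase.fs))
    return np.asarray(resp), np.asarray(heart)
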