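"""Seat-occupancy detection from the range-bin envelope amplitude.

A person on the seat produces micro-motion that continually perturbs the
envelope ``y[n]`` of the occupied range bin, while an empty seat or a static
object yields an almost constant return.  The detector tracks the EWMA of
the squared finite-difference derivative,

    σ²[n] = α·((y[n] − y[n−1])/T_s)² + (1 − α)·σ²[n−1],   σ²[0] = 0,

and declares a person present whenever σ exceeds a threshold σ_th.  The
smoothing coefficient follows from the desired low-pass cutoff via the
single-pole identity α = cos Ω − 1 + √(cos²Ω − 4·cos Ω + 3), Ω = 2π·f_c·T_s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .radar import SlowTimeCube
from .vitals import range_fft, select_bin

__all__ = [
    "EwmaConfig",
    "OccupancyTrace",
    "CalibrationError",
    "alpha_from_cutoff",
    "ewma_sigma",
    "classify",
    "calibrate_threshold",
    "run_occupancy",
]


class CalibrationError(RuntimeError):
    """Person and empty σ distributions overlap; no separating threshold."""


def alpha_from_cutoff(f_c: float, t_s: float) -> float:
    """EWMA smoothing coefficient for a −3 dB cutoff at ``f_c``.

    Requires ``0 < f_c < 1/(2·T_s)``.  The result lies in (0, 1]; the
    filter ``H(Ω) = α/(1 − (1−α)e^{−jΩ})`` then satisfies |H(Ω_c)|² = 1/2.
    """
    if t_s <= 0:
        raise ValueError("sample interval must be positive")
    nyquist = 0.5 / t_s
    if not (0 < f_c < nyquist):
        raise ValueError(f"cutoff {f_c} Hz must lie in (0, {nyquist:.4g}) Hz")
    omega = 2 * np.pi * f_c * t_s
    cos_w = np.cos(omega)
    alpha = cos_w - 1 + np.sqrt(cos_w**2 - 4 * cos_w + 3)
    return float(alpha)


@dataclass(frozen=True)
class EwmaConfig:
    """Cutoff-derived smoothing and decision threshold for the σ² tracker."""

    cutoff_hz: float = 0.5
    sample_interval: float = 75.476e-3
    sigma_th: float | None = None
    hold_s: float = 1.0

    @property
    def alpha(self) -> float:
        return alpha_from_cutoff(self.cutoff_hz, self.sample_interval)


def ewma_sigma(envelope: np.ndarray, config: EwmaConfig) -> np.ndarray:
    """Exact σ² recursion over the envelope series (σ²[0] = 0)."""
    y = np.asarray(envelope, float)
    if y.size < 2:
        raise ValueError("envelope must contain at least 2 samples")
    a = config.alpha
    ts = config.sample_interval
    deriv2 = ((y[1:] - y[:-1]) / ts) ** 2
    # σ²[n] = a·d²[n] + (1−a)·σ²[n−1] — a first-order IIR, evaluated directly
    sigma2 = np.empty(y.size)
    sigma2[0] = 0.0
    acc = 0.0
    for i, d in enumerate(deriv2, start=1):
        acc = a * d + (1 - a) * acc
        sigma2[i] = acc
    return sigma2


def classify(
    sigma2: np.ndarray,
    sigma_th: float,
    *,
    hold_s: float = 1.0,
    sample_interval: float = 75.476e-3,
) -> np.ndarray:
    """Person / not-person per frame with run-length hysteresis.

    The raw rule is strict: person iff ``√σ² > σ_th``.  A state change is
    accepted only once the new raw state persists for ``hold_s`` seconds
    (chatter suppression); the change is then back-dated to the first frame
    of the confirmed run, so offline traces carry no hysteresis lag.
    Returns a boolean array (True = person).
    """
    if sigma_th <= 0:
        raise ValueError("sigma_th must be positive")
    raw = np.sqrt(np.asarray(sigma2, float)) > sigma_th
    hold = max(1, int(round(hold_s / sample_interval)))
    out = np.empty_like(raw)
    current = raw[0]
    out[0] = current
    run_state = raw[0]
    run_start = 0
    for i in range(1, raw.size):
        if raw[i] != run_state:
            run_state = raw[i]
            run_start = i
        if run_state != current and i - run_start + 1 >= hold:
            current = run_state
            out[run_start : i + 1] = current
        out[i] = current
    return out


def calibrate_threshold(
    person_runs: Sequence[np.ndarray], empty_runs: Sequence[np.ndarray]
) -> float:
    """σ_th = geometric mean of (mean person σ, max empty/object σ).

    Raises :class:`CalibrationError` with the margin when the classes
    overlap (max empty σ ≥ mean person σ).
    """
    if len(person_runs) < 1 or len(empty_runs) < 1:
        raise ValueError("need at least one run of each class")
    person_mean = float(np.mean([np.mean(r) for r in person_runs]))
    empty_max = float(np.max([np.max(r) for r in empty_runs]))
    if empty_max >= person_mean:
        raise CalibrationError(
            f"classes overlap: max empty sigma {empty_max:.4g} >= "
            f"mean person sigma {person_mean:.4g} (margin {person_mean - empty_max:.4g})"
        )
    return float(np.sqrt(person_mean * empty_max))


@dataclass
class OccupancyTrace:
    """EWMA variance series with the decided per-frame state."""

    times: np.ndarray
    envelope: np.ndarray
    sigma2: np.ndarray
    person: np.ndarray  # bool per frame
    sigma_th: float
    config: EwmaConfig

    @property
    def state_labels(self) -> np.ndarray:
        return np.where(self.person, "person", "empty-or-object")


def run_occupancy(
    cube: SlowTimeCube,
    *,
    cutoff_hz: float = 0.5,
    sigma_th: float | None = None,
    hold_s: float = 1.0,
    gate: tuple[float, float] = (0.5, 0.8),
    transition_guard_s: float = 3.0,
) -> OccupancyTrace:
    """End-to-end occupancy detection on one cube.

    The envelope is the RX-averaged magnitude of the gated range bin.  With
    ``sigma_th=None`` the threshold is calibrated from the cube's ground-
    truth labels.  Frames within ``transition_guard_s`` of a state change
    are excluded from calibration: an amplitude step excites the σ² tracker
    and the excitation takes a few EWMA time constants (≈2 s at the default
    cutoff) to decay, which would otherwise contaminate the empty-class
    maximum.
    """
    profile = range_fft(cube)
    sel = select_bin(profile, gate)
    env = np.abs(profile.data[..., sel.index])
    if env.ndim > 1:
        env = env.mean(axis=0)
    config = EwmaConfig(
        cutoff_hz=cutoff_hz,
        sample_interval=cube.config.frame_time,
        sigma_th=sigma_th,
        hold_s=hold_s,
    )
    sigma2 = ewma_sigma(env, config)
    sigma = np.sqrt(sigma2)

    if sigma_th is None:
        if cube.truth_state is None:
            raise ValueError("automatic calibration requires ground-truth state labels")
        person = cube.truth_state == "person"
        guard = int(round(transition_guard_s / cube.config.frame_time))
        # exclude every scripted state change (any amplitude step spikes σ²)
        changes = np.flatnonzero(cube.truth_state[1:] != cube.truth_state[:-1]) + 1
        valid = np.ones(person.size, bool)
        valid[: guard]  = False  # EWMA warm-up
        for cix in changes:
            valid[max(0, cix - guard) : cix + guard] = False
        p_sel = person & valid
        e_sel = (~person) & valid
        if not p_sel.any() or not e_sel.any():
            raise ValueError("labelled segments too short for calibration")
        sigma_th = calibrate_threshold([sigma[p_sel]], [sigma[e_sel]])

    person_series = classify(
        sigma2, sigma_th, hold_s=hold_s, sample_interval=cube.config.frame_time
    )
    return OccupancyTrace(
        times=cube.timestamps,
        envelope=env,
        sigma2=sigma2,
        person=person_series,
        sigma_th=float(sigma_th),
        config=config,
    )
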