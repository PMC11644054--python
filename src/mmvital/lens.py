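"""Transmitarray lens phase design.

A flat metasurface lens focuses a 60 GHz wavefront by imposing a hyperbolic
phase profile across a square grid of sub-wavelength unit cells.  Each cell's
transmission phase is set by its patch side length ``L``; a lookup table
(measured or synthetic) maps achievable phases to cell dimensions.  This
module computes the target phase map, quantizes it onto realizable cells and
evaluates beam-tilt geometry from phase-delay gradients.

Units: SI throughout (m, rad, Hz) except lookup-table cell dimensions, which
follow fabrication convention (mm) and transmission magnitude (dB).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.constants import c as C0

__all__ = [
    "UnitCellSpec",
    "PhaseLookup",
    "ApertureLayout",
    "TiltConfig",
    "guided_wavelength",
    "hyperbolic_phase",
    "element_phase_map",
    "quantize_phases",
    "beam_angles",
    "zero_tilt_residual",
    "design_lens",
]

TWO_PI = 2.0 * np.pi


class EvanescentWaveError(ValueError):
    """Transverse wavenumber exceeds k0: the wave does not propagate."""


def guided_wavelength(frequency: float, permittivity: float) -> float:
    """Guided wavelength ``λ0/√εr`` in a dielectric substrate.

    Parameters
    ----------
    frequency : float
        Operating frequency in Hz (> 0).
    permittivity : float
        Relative permittivity of the substrate (≥ 1).

    Returns
    -------
    float
        Guided wavelength in metres.
    """
    if frequency <= 0:
        raise ValueError(f"frequency must be positive, got {frequency!r}")
    if permittivity < 1:
        raise ValueError(f"relative permittivity must be >= 1, got {permittivity!r}")
    return (C0 / frequency) / np.sqrt(permittivity)


def hyperbolic_phase(x, focal_length: float, wavelength: float):
    """Hyperbolic focusing phase ``(2π/λ)(√(x²+F²) − F)``.

    The profile equalizes the optical path from every aperture point to the
    focal point at distance ``F`` on axis; it is non-negative and even in x.
    Accepts scalars or arrays.
    """
    if focal_length <= 0:
        raise ValueError(f"focal_length must be positive, got {focal_length!r}")
    if wavelength <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength!r}")
    x = np.asarray(x, dtype=float)
    out = (TWO_PI / wavelength) * (np.hypot(x, focal_length) - focal_length)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class UnitCellSpec:
    """Geometry of one metasurface unit cell.

    ``L`` is the square patch side (the phase-controlling dimension), ``W``
    the cell pitch and ``R`` the via-hole radius, all in mm.
    """

    L: float
    W: float = 1.6
    R: float = 0.6
    substrate_permittivity: float = 3.5
    frequency: float = 60e9

    def __post_init__(self) -> None:
        if not (0 < self.L < self.W):
            raise ValueError(f"patch size L must satisfy 0 < L < W, got L={self.L}, W={self.W}")
        if not (self.R < self.W / 2):
            raise ValueError(f"hole radius R must be < W/2, got R={self.R}, W={self.W}")
        if self.substrate_permittivity < 1:
            raise ValueError("substrate_permittivity must be >= 1")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")

    @property
    def guided_wavelength_m(self) -> float:
        return guided_wavelength(self.frequency, self.substrate_permittivity)

    @property
    def electrical_size(self) -> float:
        """Cell pitch in units of the guided wavelength (≈ 0.6 for the default cell)."""
        return (self.W * 1e-3) / self.guided_wavelength_m


@dataclass
class PhaseLookup:
    """Transmission phase/magnitude vs patch size, at a stated frequency.

    Stands in for full-wave unit-cell data: entries are ``(L [mm],
    magnitude [dB], phase [deg in [0,360)])`` with strictly increasing L.
    """

    L_mm: np.ndarray
    mag_db: np.ndarray
    phase_deg: np.ndarray
    frequency: float = 60e9

    def __post_init__(self) -> None:
        self.L_mm = np.asarray(self.L_mm, dtype=float)
        self.mag_db = np.asarray(self.mag_db, dtype=float)
        self.phase_deg = np.asarray(self.phase_deg, dtype=float)
        if self.L_mm.size == 0:
            raise ValueError("phase lookup must contain at least one entry")
        if not (self.L_mm.size == self.mag_db.size == self.phase_deg.size):
            raise ValueError("lookup columns must have equal length")
        if np.any(np.diff(self.L_mm) <= 0):
            raise ValueError("L values must be strictly increasing")
        if np.any(self.mag_db > 1e-9):
            raise ValueError("transmission magnitude cannot exceed 0 dB")
        if np.any((self.phase_deg < 0) | (self.phase_deg >= 360)):
            raise ValueError("phases must lie in [0, 360) degrees")

    def __len__(self) -> int:
        return int(self.L_mm.size)

    @property
    def phase_rad(self) -> np.ndarray:
        return np.deg2rad(self.phase_deg)

    @property
    def phase_span_deg(self) -> float:
        """Covered phase span: 360° minus the largest wrap-aware gap between entries."""
        ph = np.sort(self.phase_deg)
        gaps = np.diff(np.concatenate([ph, [ph[0] + 360.0]]))
        return 360.0 - float(gaps.max())

    @classmethod
    def synthetic(cls, n: int = 128, frequency: float = 60e9) -> "PhaseLookup":
        """Monotone synthetic lookup: phase spanning 350° over L ∈ [0.2, 1.2] mm,
        magnitude between −3 and 0 dB.  Used when no full-wave CSV is supplied."""
        L = np.linspace(0.2, 1.2, n)
        phase = np.linspace(0.0, 350.0, n) % 360.0
        # gentle resonance-like dip, never below the −3 dB design floor
        mag = -1.5 + 1.5 * np.cos(2 * np.pi * (L - 0.2) / 1.0)
        mag = np.clip(mag, -3.0, 0.0)
        return cls(L_mm=L, mag_db=mag, phase_deg=phase, frequency=frequency)

    @classmethod
    def from_csv(cls, path, frequency: float = 60e9) -> "PhaseLookup":
        """Read a lookup from CSV with required header ``L_mm, mag_dB, phase_deg``."""
        df = pd.read_csv(path)
        required = {"L_mm", "mag_dB", "phase_deg"}
        if not required.issubset(df.columns):
            raise ValueError(f"lookup CSV must have columns {sorted(required)}, got {list(df.columns)}")
        return cls(
            L_mm=df["L_mm"].to_numpy(),
            mag_db=df["mag_dB"].to_numpy(),
            phase_deg=df["phase_deg"].to_numpy() % 360.0,
            frequency=frequency,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"L_mm": self.L_mm, "mag_dB": self.mag_db, "phase_deg": self.phase_deg}
        ).to_csv(path, index=False)


@dataclass
class ApertureLayout:
    """Square grid of lens elements with target and realized phases.

    Coordinates are aperture-centered metres; element (i, j) sits at
    ``x = (j − (n−1)/2)·pitch``, ``y = (i − (n−1)/2)·pitch`` with 0-based
    indices.  Phases are stored in radians in [0, 2π).
    """

    n_elements_per_side: int = 37
    pitch: float = 1.6e-3
    focal_length: float = 0.150
    frequency: float = 60e9
    target_phase: np.ndarray | None = None
    chosen_L_mm: np.ndarray | None = None
    realized_phase: np.ndarray | None = None
    residual_phase: np.ndarray | None = None
    two_way: bool = False

    def __post_init__(self) -> None:
        if self.n_elements_per_side < 1:
            raise ValueError("n_elements_per_side must be >= 1")
        if self.pitch <= 0 or self.focal_length <= 0 or self.frequency <= 0:
            raise ValueError("pitch, focal_length and frequency must be positive")

    @property
    def side_length(self) -> float:
        """Physical aperture side, n × pitch (59.2 mm for the default layout)."""
        return self.n_elements_per_side * self.pitch

    @property
    def wavelength(self) -> float:
        return C0 / self.frequency

    @property
    def element_centers(self) -> tuple[np.ndarray, np.ndarray]:
        n = self.n_elements_per_side
        coords = (np.arange(n) - (n - 1) / 2) * self.pitch
        return np.meshgrid(coords, coords, indexing="xy")

    @property
    def effective_phase(self) -> np.ndarray:
        """Realized (quantized) phase if available, else the continuous target."""
        if self.realized_phase is not None:
            return self.realized_phase
        if self.target_phase is None:
            raise ValueError("layout has no phases; call element_phase_map first")
        return self.target_phase

    def to_json(self, path) -> None:
        meta = {
            "n_elements_per_side": self.n_elements_per_side,
            "pitch_m": self.pitch,
            "focal_length_m": self.focal_length,
            "frequency_hz": self.frequency,
            "side_length_m": self.side_length,
            "two_way": self.two_way,
        }
        Path(path).write_text(json.dumps(meta, indent=2))

    def to_element_csv(self, path) -> None:
        x, y = self.element_centers
        n = self.n_elements_per_side
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        df = pd.DataFrame(
            {
                "i": ii.ravel(),
                "j": jj.ravel(),
                "x_m": x.ravel(),
                "y_m": y.ravel(),
                "phase_rad": (self.target_phase.ravel() if self.target_phase is not None else np.nan),
                "L_mm": (self.chosen_L_mm.ravel() if self.chosen_L_mm is not None else np.nan),
                "residual_rad": (self.residual_phase.ravel() if self.residual_phase is not None else np.nan),
            }
        )
        df.to_csv(path, index=False)


def element_phase_map(layout: ApertureLayout, two_way: bool | None = None) -> np.ndarray:
    """Target focusing phase per element, reduced modulo 2π.

    For element radius ``R_i = √(x²+y²)`` the phase is
    ``f·k·(√(R_i²+F²) − F)`` with ``f = 2`` when ``two_way`` (round-trip
    convention) and ``f = 1`` otherwise (one-way hyperbolic profile, the
    default).  The centre element has phase 0 by construction.
    """
    if two_way is None:
        two_way = layout.two_way
    x, y = layout.element_centers
    r = np.hypot(x, y)
    k = TWO_PI / layout.wavelength
    factor = 2.0 if two_way else 1.0
    phase = factor * k * (np.hypot(r, layout.focal_length) - layout.focal_length)
    phase = np.mod(phase, TWO_PI)
    layout.target_phase = phase
    layout.two_way = bool(two_way)
    return phase


def _wrapped_difference(a, b):
    """Signed wrap-aware phase difference a − b in (−π, π]."""
    d = np.mod(a - b + np.pi, TWO_PI) - np.pi
    # put exactly-opposite phases at +π, not −π, for a deterministic tie rule
    return np.where(d == -np.pi, np.pi, d)


def quantize_phases(
    target_phase: np.ndarray, lookup: PhaseLookup
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each element the lookup entry nearest in wrap-aware phase distance.

    Ties break toward the smaller L (entries are L-sorted, first match wins).

    Returns
    -------
    chosen_L_mm : ndarray
        Patch size per element, mm.
    residual : ndarray
        Signed phase error (realized − target) in (−π, π] radians.
    """
    if len(lookup) == 0:  # defensive; the dataclass already forbids this
        raise ValueError("phase lookup is empty")
    target = np.asarray(target_phase, dtype=float)
    entry_phase = lookup.phase_rad
    diff = _wrapped_difference(entry_phase.reshape(-1, *([1] * target.ndim)), target[None])
    idx = np.argmin(np.abs(diff), axis=0)
    chosen = lookup.L_mm[idx]
    residual = np.take_along_axis(diff, idx[None], axis=0)[0]
    return chosen, residual


@dataclass(frozen=True)
class TiltConfig:
    """Phase-delay gradients and rotation angles of a two-surface beam tilter."""

    p1: float
    p2: float
    alpha1: float
    alpha2: float
    k0: float
    delta_i: float = 0.0

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ValueError("k0 must be positive")


def beam_angles(tilt: TiltConfig) -> tuple[float, float]:
    """Elevation/azimuth of the output beam from the combined phase gradients.

    ``k_x = p1·cosα1 + p2·cosα2``, ``k_y = p1·sinα1 + p2·sinα2``;
    ``θ = asin(√(kx²+ky²)/k0)``, ``φ = atan2(ky, kx)``.  Raises
    :class:`EvanescentWaveError` when the transverse wavenumber exceeds k0.
    """
    kx = tilt.p1 * np.cos(tilt.alpha1) + tilt.p2 * np.cos(tilt.alpha2)
    ky = tilt.p1 * np.sin(tilt.alpha1) + tilt.p2 * np.sin(tilt.alpha2)
    kt = float(np.hypot(kx, ky))
    if kt > tilt.k0 * (1 + 1e-12):
        raise EvanescentWaveError(
            f"transverse wavenumber {kt:.6g} rad/m exceeds k0={tilt.k0:.6g} rad/m: "
            "the requested gradients produce an evanescent (non-propagating) wave"
        )
    theta = float(np.arcsin(min(kt / tilt.k0, 1.0)))
    phi = float(np.arctan2(ky, kx))
    return theta, phi


def zero_tilt_residual(tilt: TiltConfig) -> float:
    """Broadside condition residual ``p1² + p2² + 2·p1·p2·cos(α1−α2)``.

    Zero iff the two phase-delay gradients cancel and the beam leaves at θ=0.
    """
    return float(
        tilt.p1**2 + tilt.p2**2 + 2 * tilt.p1 * tilt.p2 * np.cos(tilt.alpha1 - tilt.alpha2)
    )


def design_lens(
    frequency: float = 60e9,
    n: int = 37,
    pitch: float = 1.6e-3,
    focal_length: float = 0.150,
    lookup: PhaseLookup | None = None,
    two_way: bool = False,
) -> ApertureLayout:
    """Full design pass: layout → phase map → quantization against a lookup."""
    layout = ApertureLayout(
        n_elements_per_side=n, pitch=pitch, focal_length=focal_length, frequency=frequency
    )
    element_phase_map(layout, two_way=two_way)
    if lookup is None:
        lookup = PhaseLookup.synthetic(frequency=frequency)
    chosen, residual = quantize_phases(layout.target_phase, lookup)
    layout.chosen_L_mm = chosen
    layout.residual_phase = residual
    layout.realized_phase = np.mod(layout.target_phase + residual, TWO_PI)
    return layout
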