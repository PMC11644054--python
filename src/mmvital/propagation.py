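"""Scalar diffraction and layered-media evaluation of the designed aperture.

The lens is many wavelengths wide and only power patterns are of interest,
so a scalar plane-wave-spectrum (angular spectrum) propagator is exact
enough: ``U(kx,ky;z) = U(kx,ky;0)·exp(i·kz·z)`` with
``kz = √(k² − kx² − ky²)`` (imaginary → evanescent decay).  Bending of the
flexible sheet is modelled as an inextensible cylindrical wrap: element arc
positions are preserved, projected laterally, and the out-of-plane sag adds
a per-element phase advance ``k0·sag``.

Layered-media reflection/transmission (seatbelt matching layers, tissue
stack) uses the standard characteristic-matrix (transfer-matrix) method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.constants import c as C0

from .lens import ApertureLayout

__all__ = [
    "ApertureField",
    "BendState",
    "Layer",
    "LayerStack",
    "FocusMetrics",
    "propagate_angular_spectrum",
    "rasterize_layout",
    "bend_aperture",
    "focus_metrics",
    "tmm_reflection",
    "matching_sweep",
]


class AliasingError(ValueError):
    """Grid spacing too coarse for alias-free angular-spectrum propagation."""


@dataclass
class ApertureField:
    """Complex scalar field sampled on a square x–y grid.

    ``u[iy, ix]`` with spacing ``dx`` (m); x = (ix − nx//2)·dx, same for y.
    """

    u: np.ndarray
    dx: float
    wavelength: float

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=complex)
        if self.u.ndim != 2:
            raise ValueError("field must be a 2-D array")
        if self.dx <= 0 or self.wavelength <= 0:
            raise ValueError("dx and wavelength must be positive")

    @property
    def power(self) -> float:
        return float(np.sum(np.abs(self.u) ** 2) * self.dx**2)

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.u.shape
        x = (np.arange(nx) - nx // 2) * self.dx
        y = (np.arange(ny) - ny // 2) * self.dx
        return x, y


def _spectrum_kz(field: ApertureField):
    ny, nx = field.u.shape
    k = 2 * np.pi / field.wavelength
    kx = 2 * np.pi * np.fft.fftfreq(nx, field.dx)
    ky = 2 * np.pi * np.fft.fftfreq(ny, field.dx)
    kx2 = kx[None, :] ** 2 + ky[:, None] ** 2
    kz2 = k**2 - kx2
    kz = np.sqrt(np.abs(kz2))
    return np.where(kz2 >= 0, kz, 0.0), np.where(kz2 < 0, kz, 0.0), kz2 >= 0


def propagate_angular_spectrum(field: ApertureField, z: float) -> ApertureField:
    """Exact free-space scalar propagation over distance ``z ≥ 0``.

    Propagating plane-wave components acquire phase ``kz·z`` (energy
    conserved); evanescent components decay as ``exp(−|kz|·z)``.
    """
    if z < 0:
        raise ValueError("z must be non-negative")
    if field.dx > field.wavelength / 2:
        raise AliasingError(
            f"grid spacing {field.dx:.3g} m exceeds λ/2 = {field.wavelength / 2:.3g} m; "
            "the angular spectrum would alias"
        )
    kz_prop, kz_evan, _ = _spectrum_kz(field)
    spectrum = np.fft.fft2(field.u)
    h = np.exp(1j * kz_prop * z) * np.exp(-kz_evan * z)
    out = np.fft.ifft2(spectrum * h)
    return ApertureField(out, field.dx, field.wavelength)


def _onaxis_intensity(field: ApertureField, zs: np.ndarray) -> np.ndarray:
    """|u(0,0,z)|² along the optical axis, one inverse-transform dot product per z."""
    kz_prop, kz_evan, _ = _spectrum_kz(field)
    spectrum = np.fft.fft2(field.u)
    ny, nx = field.u.shape
    # phase factors selecting the grid centre of the inverse transform
    ex = np.exp(2j * np.pi * np.fft.fftfreq(nx) * (nx // 2))
    ey = np.exp(2j * np.pi * np.fft.fftfreq(ny) * (ny // 2))
    base = spectrum * ey[:, None] * ex[None, :]
    out = np.empty(zs.size)
    for i, z in enumerate(zs):
        h = np.exp(1j * kz_prop * z - kz_evan * z)
        out[i] = np.abs(np.mean(base * h)) ** 2
    return out


@dataclass(frozen=True)
class BendState:
    """Cylindrical bend of the flexible lens sheet.

    ``angle_deg`` is the total subtended angle (0–40°); ``axis`` names the
    in-plane coordinate along which curvature develops (sag varies with it).
    """

    angle_deg: float
    axis: str = "x"

    def __post_init__(self) -> None:
        if not (0 <= self.angle_deg <= 40):
            raise ValueError("bend angle must lie in [0, 40] degrees (studied range)")
        if self.axis not in ("x", "y"):
            raise ValueError("bend axis must be 'x' or 'y'")

    def radius_of_curvature(self, sheet_width: float) -> float:
        """Arc length preserved: R = width / angle.  Infinite for a flat sheet."""
        theta = np.deg2rad(self.angle_deg)
        return np.inf if theta == 0 else sheet_width / theta


def bend_aperture(layout: ApertureLayout, bend: BendState):
    """Projected element positions and bend-induced phase per element.

    Returns ``(x', y', sag, extra_phase)`` arrays.  The wrap is isometric:
    an element at arc coordinate s maps to ``x' = R·sin(s/R)`` with sag
    ``R·(1 − cos(s/R))`` toward the propagation direction; the extra phase is
    ``+k0·sag`` (the displaced element's wavefront is advanced at the flat
    reference plane).
    """
    x, y = layout.element_centers
    k0 = 2 * np.pi / layout.wavelength
    if bend.angle_deg == 0:
        zeros = np.zeros_like(x)
        return x, y, zeros, zeros
    r_c = bend.radius_of_curvature(layout.side_length)
    s = x if bend.axis == "x" else y
    beta = s / r_c
    proj = r_c * np.sin(beta)
    sag = r_c * (1 - np.cos(beta))
    if bend.axis == "x":
        xb, yb = proj, y
    else:
        xb, yb = x, proj
    return xb, yb, sag, k0 * sag


def rasterize_layout(
    layout: ApertureLayout,
    bend: BendState | None = None,
    spacing: float = 2.5e-4,
    window: float | None = None,
) -> ApertureField:
    """Sample the transmitted field just behind the lens on a regular grid.

    Each element is a uniform-amplitude square patch carrying
    ``exp(−i·φ_element)`` (converging convention: the hyperbolic profile then
    focuses at z ≈ F under ``exp(+i·kz·z)`` propagation).  A bend remaps the
    patch footprints through the inverse cylindrical projection and adds the
    sag phase.
    """
    phases = layout.effective_phase
    side = layout.side_length
    if window is None:
        window = 2.2 * side
    n = int(np.ceil(window / spacing))
    n += n % 2  # even grid, centre at n//2
    coords = (np.arange(n) - n // 2) * spacing
    xg, yg = np.meshgrid(coords, coords, indexing="xy")

    k0 = 2 * np.pi / layout.wavelength
    u = np.zeros((n, n), dtype=complex)

    if bend is None or bend.angle_deg == 0:
        inside = (np.abs(xg) < side / 2) & (np.abs(yg) < side / 2)
        sx, sy = xg, yg
        sag = np.zeros_like(xg)
    else:
        r_c = bend.radius_of_curvature(side)
        half_proj = r_c * np.sin(side / (2 * r_c))
        b = xg if bend.axis == "x" else yg
        t = yg if bend.axis == "x" else xg
        with np.errstate(invalid="ignore"):
            s_arc = r_c * np.arcsin(np.clip(b / r_c, -1, 1))
        inside = (np.abs(b) < half_proj) & (np.abs(t) < side / 2)
        sag = np.where(inside, r_c * (1 - np.cos(s_arc / r_c)), 0.0)
        if bend.axis == "x":
            sx, sy = s_arc, yg
        else:
            sx, sy = xg, s_arc

    nel = layout.n_elements_per_side
    ix = np.clip(np.floor((sx + side / 2) / layout.pitch).astype(int), 0, nel - 1)
    iy = np.clip(np.floor((sy + side / 2) / layout.pitch).astype(int), 0, nel - 1)
    u[inside] = np.exp(-1j * phases[iy[inside], ix[inside]] + 1j * k0 * sag[inside])
    return ApertureField(u, spacing, layout.wavelength)


@dataclass
class FocusMetrics:
    """Summary of a z-scan and focal-plane analysis of one aperture state."""

    zs: np.ndarray
    on_axis_profile: np.ndarray  # normalized to peak 1
    peak_z: float
    fwhm_x: float
    focal_shift: float
    snr_db: float
    boundary_peak: bool = False


def _fwhm_from_profile(x: np.ndarray, intensity: np.ndarray) -> float:
    """Full width at half maximum with linear interpolation of the crossings."""
    i_pk = int(np.argmax(intensity))
    half = intensity[i_pk] / 2.0
    left = right = np.nan
    for i in range(i_pk, 0, -1):
        if intensity[i - 1] < half <= intensity[i]:
            frac = (half - intensity[i - 1]) / (intensity[i] - intensity[i - 1])
            left = x[i - 1] + frac * (x[i] - x[i - 1])
            break
    for i in range(i_pk, len(x) - 1):
        if intensity[i + 1] < half <= intensity[i]:
            frac = (intensity[i] - half) / (intensity[i] - intensity[i + 1])
            right = x[i] + frac * (x[i + 1] - x[i])
            break
    if np.isnan(left) or np.isnan(right):
        raise ValueError("half-maximum crossings not found within the grid window")
    return float(right - left)


def focus_metrics(
    layout: ApertureLayout,
    bend: BendState | None = None,
    *,
    spacing: float = 2.5e-4,
    z_range: tuple[float, float] = (0.010, 0.300),
    z_step: float = 1e-3,
    window: float | None = None,
) -> FocusMetrics:
    """Z-scan of on-axis power plus focal-plane FWHM and sidelobe SNR.

    SNR is defined as the focal-plane peak intensity over the mean intensity
    outside twice the FWHM radius from the peak, in dB.
    """
    field = rasterize_layout(layout, bend=bend, spacing=spacing, window=window)
    zs = np.arange(z_range[0], z_range[1] + z_step / 2, z_step)
    profile = _onaxis_intensity(field, zs)
    i_pk = int(np.argmax(profile))
    boundary = i_pk in (0, zs.size - 1)
    if boundary:
        warnings.warn("on-axis peak at the edge of the z-scan range", stacklevel=2)
    peak_z = float(zs[i_pk])

    focal = propagate_angular_spectrum(field, peak_z)
    inten = np.abs(focal.u) ** 2
    x, y = focal.axes()
    iy_pk, ix_pk = np.unravel_index(int(np.argmax(inten)), inten.shape)
    fwhm = _fwhm_from_profile(x, inten[iy_pk, :])

    rr = np.hypot(x[None, :] - x[ix_pk], y[:, None] - y[iy_pk])
    # cap the exclusion radius so a degenerate (astigmatism-spread) focus
    # still leaves a non-empty sidelobe region inside the window
    r_excl = min(2 * fwhm, (x[-1] - x[0]) / 4)
    outside = rr > r_excl
    peak_power = float(inten.max())
    sidelobe = float(inten[outside].mean()) if outside.any() else np.nan
    snr_db = 10 * np.log10(peak_power / sidelobe) if sidelobe > 0 else np.inf

    return FocusMetrics(
        zs=zs,
        on_axis_profile=profile / profile.max(),
        peak_z=peak_z,
        fwhm_x=fwhm,
        focal_shift=peak_z - layout.focal_length,
        snr_db=float(snr_db),
        boundary_peak=boundary,
    )


# ---------------------------------------------------------------------------
# Layered media (transfer-matrix method)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Layer:
    name: str
    thickness: float  # m
    eps_r: float
    tan_delta: float = 0.0

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError(f"layer {self.name!r}: thickness must be positive")
        if self.eps_r < 1:
            raise ValueError(f"layer {self.name!r}: eps_r must be >= 1")

    @property
    def n_complex(self) -> complex:
        # e^{-iωt} convention: lossy index has positive imaginary part removed
        return complex(np.sqrt(self.eps_r * (1 - 1j * self.tan_delta)))


@dataclass
class LayerStack:
    """Ordered finite layers between two declared semi-infinite media."""

    layers: list[Layer] = field(default_factory=list)
    incident_eps: float = 1.0
    exit_eps: float = 1.0

    @classmethod
    def tissue(cls) -> "LayerStack":
        """Four-layer human tissue model behind the seatbelt (skin/fat/muscle/bone)."""
        return cls(
            layers=[
                Layer("skin", 10e-3, 35.0),
                Layer("fat", 20e-3, 9.0),
                Layer("muscle", 20e-3, 52.0),
                Layer("bone", 15e-3, 14.0),
            ],
            incident_eps=1.0,
            exit_eps=1.0,
        )

    @classmethod
    def from_yaml(cls, path) -> "LayerStack":
        spec = yaml.safe_load(open(path))
        layers = [
            Layer(
                d["name"],
                float(d["thickness_m"]),
                float(d["eps_r"]),
                float(d.get("tan_delta", 0.0)),
            )
            for d in spec["layers"]
        ]
        return cls(
            layers=layers,
            incident_eps=float(spec.get("incident_eps", 1.0)),
            exit_eps=float(spec.get("exit_eps", 1.0)),
        )

    def to_yaml(self, path) -> None:
        spec = {
            "incident_eps": self.incident_eps,
            "exit_eps": self.exit_eps,
            "layers": [
                {
                    "name": l.name,
                    "thickness_m": l.thickness,
                    "eps_r": l.eps_r,
                    "tan_delta": l.tan_delta,
                }
                for l in self.layers
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(spec, fh)


def tmm_reflection(
    stack: LayerStack,
    frequency: float,
    incidence: float = 0.0,
    polarization: str = "te",
) -> tuple[complex, complex]:
    """Amplitude reflection and transmission of the layered stack.

    Characteristic-matrix method; oblique incidence via Snell-continued
    transverse wavevector, TE ("s") or TM ("p").  For lossless stacks
    ``|r|² + (Re γ_out/γ_in)·|t|² = 1``.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    if polarization not in ("te", "tm"):
        raise ValueError("polarization must be 'te' or 'tm'")
    k0 = 2 * np.pi * frequency / C0
    n_in = np.sqrt(stack.incident_eps)
    n_out = np.sqrt(stack.exit_eps)
    sin_t = n_in * np.sin(incidence)  # conserved transverse slowness

    def admittance(n: complex) -> complex:
        cos_t = np.sqrt(1 - (sin_t / n) ** 2 + 0j)
        return n * cos_t if polarization == "te" else n / cos_t

    m = np.eye(2, dtype=complex)
    for layer in stack.layers:
        n_l = layer.n_complex
        cos_l = np.sqrt(1 - (sin_t / n_l) ** 2 + 0j)
        delta = k0 * n_l * layer.thickness * cos_l
        g = admittance(n_l)
        m = m @ np.array(
            [
                [np.cos(delta), 1j * np.sin(delta) / g],
                [1j * g * np.sin(delta), np.cos(delta)],
            ]
        )
    g_in = admittance(n_in)
    g_out = admittance(n_out)
    b, c_ = m @ np.array([1.0, g_out])
    r = (g_in * b - c_) / (g_in * b + c_)
    t = 2 * g_in / (g_in * b + c_)
    return complex(r), complex(t)


def matching_sweep(
    stack_template: LayerStack,
    permittivity_range: np.ndarray,
    thickness_range: np.ndarray,
    frequency: float = 60e9,
    layer_index: int = 0,
):
    """|R| over a (permittivity × thickness) grid of one matching layer.

    Returns ``(grid, eps_opt, thickness_opt)`` where ``grid[i, j]`` is |R|
    at ``permittivity_range[i]``, ``thickness_range[j]`` and the optimum is
    the grid argmin.
    """
    eps_vals = np.atleast_1d(np.asarray(permittivity_range, float))
    th_vals = np.atleast_1d(np.asarray(thickness_range, float))
    if eps_vals.size == 0 or th_vals.size == 0:
        raise ValueError("sweep ranges must be non-empty")
    grid = np.empty((eps_vals.size, th_vals.size))
    base = stack_template.layers[layer_index]
    for i, eps in enumerate(eps_vals):
        for j, th in enumerate(th_vals):
            layers = list(stack_template.layers)
            layers[layer_index] = Layer(base.name, float(th), float(eps), base.tan_delta)
            trial = LayerStack(layers, stack_template.incident_eps, stack_template.exit_eps)
            r, _ = tmm_reflection(trial, frequency)
            grid[i, j] = abs(r)
    i_opt, j_opt = np.unravel_index(int(np.argmin(grid)), grid.shape)
    return grid, float(eps_vals[i_opt]), float(th_vals[j_opt])
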