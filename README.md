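# mmvital

A toolkit for seatbelt-integrated metasurface radar sensing of vital signs.
It targets engineers and researchers studying non-contact in-car health
monitoring: a flexible transmitarray lens woven into the seatbelt focuses a
60 GHz FMCW radar beam on the occupant's chest, and the slow-time phase of
the reflected signal carries respiration and heartbeat displacement.

The package covers the whole chain in software:

- **Lens design** (`mmvital.lens`) — hyperbolic focusing phase
  φ(x) = (2π/λ)(√(x²+F²) − F) over a 37×37 grid of 1.6 mm unit cells,
  quantized against a transmission-phase lookup (synthetic or user CSV),
  plus beam-tilt geometry from phase-delay gradients
  (k_x = p₁cosα₁ + p₂cosα₂, θ = asin(√(k_x²+k_y²)/k₀)).
- **Diffraction evaluation** (`mmvital.propagation`) — angular-spectrum
  scalar propagation, focal z-scans, FWHM and sidelobe SNR, cylindrical
  bending of the flexible sheet (10–40°), and transfer-matrix reflection of
  seatbelt/tissue layer stacks.
- **FMCW simulator** (`mmvital.radar`) — chest displacement
  R(τ) = d₀ + A·sin(2πf_r τ) + B_h·sin(2πf_h τ) plus a band-limited motion
  artifact scaled to per-condition cabin accelerations (standby / driving /
  bumpy, with or without the lens's SNR benefit); beat frequency
  f_b = 2BR/(cT_c) and slow-time phase 4πR/λ per frame.
- **Extraction pipeline** (`mmvital.vitals`, `mmvital.vmd`) — Hann-windowed
  range FFT, 0.5–0.8 m gate, slip-robust phase unwrapping, variational mode
  decomposition (ADMM, implemented here), band-based mode assignment
  (respiration 0.1–0.7 Hz, heart 0.8–2.5 Hz), rate and inter-beat /
  breath-to-breath interval estimation, Bland–Altman agreement statistics.
- **Seat occupancy** (`mmvital.occupancy`) — EWMA variance of the range-bin
  envelope, σ²[n] = α((y[n]−y[n−1])/T_s)² + (1−α)σ²[n−1], with the cutoff
  identity α = cosΩ − 1 + √(cos²Ω − 4cosΩ + 3) and threshold classification.

Everything runs on synthetic data generated by the package itself; no
hardware or recordings are required.

## Worked example

Design the lens and run a 120 s standby-condition recording end to end:

```sh
$ mmvital design-lens --out lens_out
aperture side 59.2 mm, quantization residual RMS 0.81 deg

$ mmvital end-to-end --scenario standby --seed 42 --duration 120 --out e2e_out
{"condition": "standby", "resp_hz": 0.45012057580176634, "heart_hz": 1.1198753857416877}
```

The lens line confirms the 37 × 1.6 mm aperture (59.2 mm side) and that the
synthetic 350°-span lookup realizes the hyperbolic profile to within a
degree RMS.  The end-to-end line shows the pipeline recovering the
scenario's generating rates (0.45 Hz respiration, 1.12 Hz ≈ 67 bpm heart)
to about a millihertz from the simulated baseband cube.  `e2e_out/report.json`
additionally contains the Bland–Altman agreement of the radar inter-beat
intervals against the generating rhythm and the seat-occupancy trace of a
scripted empty → bag → person → empty scene.

The same stages are available as library calls:

```python
from mmvital import scenario, beat_signal, process_cube

cube = beat_signal(scenario("bumpy", with_lens=True, duration=300, seed=7), seed=7)
est = process_cube(cube)          # range FFT -> gate -> phase -> VMD -> rates
print(est.resp_hz, est.heart_bpm, est.ibi_ms.mean())
```

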