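# Methods

This note records the models behind `mmvital`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical choices that matter when reproducing results.

## Lens design

The transmitarray imposes the hyperbolic profile
φ(x) = (2π/λ)(√(x² + F²) − F), which equalizes the path length from every
element to the focal point.  A round-trip variant with an extra factor of 2
is available (`two_way=True`) for configurations where the wave traverses
the phase structure twice; the one-way profile is the default because it
matches standard lens-phase theory and the observed focal behaviour.
Phases are stored in radians in [0, 2π), element indices are 0-based, and
coordinates are aperture-centred metres.  Defaults: 37 elements per side,
1.6 mm pitch (59.2 mm aperture), F = 150 mm, 60 GHz.

The guided wavelength in the polyimide substrate is λ_g = λ₀/√ε_r
(2.67 mm at 60 GHz with ε_r = 3.5), making the 1.6 mm cell ≈ 0.6 λ_g —
small enough to suppress grating lobes.

Full-wave unit-cell curves are out of scope; quantization runs against a
pluggable lookup table (`L_mm, mag_dB, phase_deg` CSV).  The shipped
synthetic lookup spans 350° of phase over L ∈ [0.2, 1.2] mm with
magnitude ≥ −3 dB, the design envelope a realizable cell family provides.
Quantization picks the wrap-aware nearest entry; ties break toward the
smaller L for determinism.  With the 128-entry synthetic lookup the
residual is ≈ 0.8° RMS, i.e. quantization is not the limiting error.

## Diffraction evaluation

Propagation is scalar (the aperture is ~12λ wide and only power patterns
are needed) via the plane-wave spectrum: U(k_x,k_y;z) = U₀·exp(i k_z z)
with k_z = √(k² − k_x² − k_y²); evanescent components decay.  Energy in
propagating components is conserved to numerical precision.  Default
sampling is 0.25 mm (λ/20) with a window 2.2× the aperture; the on-axis
scan runs 10–300 mm.

Two numerical caveats learned the hard way, encoded in the tests:

- **Window wraparound**, not propagator error, dominates far-field widths
  when the window is tight: the closed-form sinc² check uses a 1.02 m
  window.  The 0.886·λ·z/D width law is itself paraxial, so that check runs
  at NA = 0.1 where it is valid to ≲1%.
- The default lens has Fresnel number N = (D/2)²/(λF) ≈ 1.2; a uniformly
  illuminated aperture at this N peaks on axis ~20% inside the design F
  (here ≈ 120 mm) with a focal-plane FWHM near the diffraction limit
  (≈ 9–11 mm).  This is genuine low-N physics, not an implementation
  artifact; measured systems with tapered feed illumination report broader
  spots and peaks nearer F.

Bending is modelled as an inextensible cylindrical wrap (fabric bending is
near-isometric): element arc positions are preserved, lateral positions
projected, and the out-of-plane sag adds phase k₀·sag.  The sag is
cylindrical, so large bends introduce astigmatism; the sidelobe-SNR metric
(focal-plane peak over mean power outside twice the FWHM, exclusion radius
capped at a quarter window so degenerate foci keep a sidelobe region)
decreases monotonically from 0° to 40°, while the focal position stays
within a ±25%·F band for bends ≤ 20°.

Layered media use the characteristic-matrix method with complex
permittivity ε_r(1 − j·tanδ), normal incidence by default, TE/TM at
oblique incidence.  The four-layer tissue model (10 mm skin ε_r=35, 20 mm
fat ε_r=9, 20 mm muscle ε_r=52, 15 mm bone ε_r=14) ships as a factory;
matching-layer sweeps report |R| over a permittivity × thickness grid.

## FMCW simulator

Radar defaults follow the production sensor configuration: 64 ADC samples
per 32 µs chirp, one chirp per frame, 5 GHz bandwidth, 75.476 ms frame
time (13.25 Hz slow-time rate), 1 TX / 3 RX, 60 GHz carrier.  Range bins
are c/(2B) ≈ 30 mm; a 0.6 m target lands in bin 20.  The three RX channels
share the signal with independent noise; no angle processing is modelled.

Chest displacement: R(τ) = d₀ + A·sin(2πf_r τ) + B_h·sin(2πf_h τ) + m(τ).
Defaults A = 4 mm, B_h = 0.3 mm are typical adult chest-wall values from
the displacement-measurement literature.  Per-condition rates are the
spectral peaks observed under each driving condition (standby 0.45/1.12 Hz,
driving 0.53/1.20 Hz, bumpy 0.52/1.18 Hz).

The motion artifact m(τ) starts from the measured RMS cabin accelerations
(with lens 0.030/0.200/0.310 m/s², without 0.037/0.325/0.470 m/s² for
standby/driving/bumpy).  White Gaussian acceleration is band-limited to
0.5–4 Hz (road and body-motion band; the lower edge avoids the unphysical
secular drift of integrating acceleration noise through DC), scaled to the
stated RMS exactly, and integrated twice spectrally.  Because radar and
occupant share the cabin frame, only a fraction of cabin acceleration
appears as *differential* chest–radar displacement; the scenario applies a
radial coupling factor of 0.1.  This is the one free constant of the
generator: it was fixed once at a value consistent with a system that
still resolves heart rate on rough roads, which is the operating premise
of a seatbelt-mounted focusing lens.

The lens's benefit is modelled as a +10 dB per-sample SNR offset
(with-lens 20 dB, without 10 dB) on top of the lower coupled vibration.

Occupancy scenes script contiguous `empty | object | person` segments
(default timeline: empty 0–20 s, bag 20–40 s, person 40–80 s, empty
80–120 s).  The empty seat is a static surface return (amplitude 0.2) with
small band-limited environmental fluctuation (std 0.02); a bag raises the
level to 0.35; a person reflects at 0.5 with respiration-correlated
amplitude modulation (±10%) and band-limited body micro-motion
(0.3–2 Hz, std 30% of amplitude) on top of the vital-sign phase
modulation.  Post-FFT thermal envelope noise defaults to 0.01.

**What the generator does not emulate:** harmonic-rich chest waveforms
(pure sinusoids only, so the pipeline never faces respiration harmonics
inside the heart band), heart-rate variability (the synthetic rhythm is
strictly periodic, so interval errors measure pipeline noise, not HRV
tracking), RCS scintillation, multipath, multiple occupants, and
electromagnetic body scattering.  Passing tests therefore demonstrate the
processing chain's correctness and noise robustness under the stated
conditions, not clinical accuracy on real subjects.

## Extraction pipeline

Fast-time processing: Hann window, FFT normalized by the window sum (a
bin-centred unit tone gives unit envelope), 0.5–0.8 m gate, maximum
mean-power bin (ties to the lowest bin; a `no_target` flag is raised when
the in-gate peak is under 5× the median bin power).

The slow-time phase sensitivity is slightly larger than 4π/λ: the beat
tone contributes 2π·(2B/(cT_c))·t̄, with t̄ the fast-time window centroid
— the bin phase references the chirp frequency at the centroid, not the
nominal carrier (≈ +4% here).  Displacement conversion uses the full
sensitivity.

Unwrapping uses a damped constant-velocity predictor: each sample is
unwrapped relative to φ[n−1] + 0.9·(φ[n−1] − φ[n−2]).  At 13.25 Hz frames,
4 mm breathing alone produces per-frame increments up to ≈ 2.5 rad; with
motion artifact the raw increment crosses π on a few percent of frames and
plain unwrapping accumulates 2π slips.  The predictor's innovation is the
phase *acceleration* (≈ 0.7 rad RMS worst case), pushing slips out to many
standard deviations.  Channels are unwrapped independently, referenced to
their first sample, and averaged.

VMD is the standard ADMM iteration in the frequency domain on a mirrored
signal: Wiener-filter mode updates, power-centroid frequency updates,
optional dual ascent.  Defaults K = 4, α = 2000, τ = 0 (relaxed
reconstruction — the robust choice in noise), tol = 1e−7, ≤ 500
iterations.  Center frequencies are initialized at the K most prominent
spectral peaks of the input: with a respiration line ~50× stronger than
the heart line, uniform initialization lets several modes collapse onto
the dominant component and can miss the heart tone entirely on shorter
records.  Uniform and zero initialization remain available.

Mode assignment takes the highest-power mode with center frequency in
0.1–0.7 Hz (respiration) and 0.8–2.5 Hz (heart); these bands cover all
rates the system is expected to report.  Rates are parabolic-interpolated
spectral peaks of each mode (Hann window, 8× zero padding).  Intervals
come from time-domain peaks (prominence ≥ 0.5·RMS, minimum spacing 300 ms
for beats) with parabolic sub-sample refinement — without it, interval
estimates quantize to the 75 ms frame time, which would dominate every
error statistic.  IBIs below 300 ms are physiologically impossible and
discarded with a flag.

Windowed rate series (default 30 s windows, 50% overlap) feed the
coefficient-of-variation statistics; Bland–Altman reports mean difference
and ±1.96·SD limits, with error % = |mean_a − mean_b|/mean_b·100 against
the reference series.  Synthetic reference intervals are constant
(periodic rhythm), so pairing is nearest-in-time.

## Occupancy detector

The statistic is the EWMA of the squared finite-difference derivative of
the gated-bin envelope (σ²[0] = 0).  α follows from the −3 dB cutoff via
α = cosΩ − 1 + √(cos²Ω − 4cosΩ + 3), Ω = 2π·f_c·T_s; default f_c = 0.5 Hz
(α ≈ 0.21, |H(f_c)|² = 1/2 verified in tests).  Classification is strict
(person iff σ > σ_th; ties are not-person) with 1 s run-length hysteresis;
because processing is offline, a confirmed state change is back-dated to
the first frame of its run, so the trace carries no hysteresis lag.

Auto-calibration sets σ_th = √(mean person σ · max empty σ).  Frames
within ±3 s of a scripted amplitude step are excluded from calibration:
a step excites σ² by orders of magnitude and the excitation needs
≈ 2 s to decay below the empty-class ceiling at the default α; including
it would inflate the threshold past the person class's lower quantiles.
On seeded scripted scenes the classifier agrees with ground truth on
≥ 99% of frames outside ±1 s of transitions.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng` seeded per run;
cubes are bit-reproducible for a fixed seed.  Standard evaluation sizes:
300 s recordings (3974 frames) for rate recovery, a 10-seed ensemble for
the condition-ordering statistics, 120 s (1589 frames) for occupancy
scenes, 0.5 mm grids with 2 mm z-steps for routine focus metrics (0.25 mm
and 1 mm respectively for fine studies).
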