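# Methods

## Measurement principle

A card printed with dark and light regions is fixed to a vertically
oscillating surface; a laser spot (2 mm diameter, 632.8 nm, ~3 mW)
illuminates it and a fibre-coupled spectrometer records the reflected
light continuously at 10 frames/s. Vertical motion moves the printed
pattern through the spot, modulating the reflected power, so the
intensity-time section of the recording at the laser wavelength is a
surrogate for the displacement waveform. The oscillation frequency — the
respiratory rate when the moving surface is a chest wall — is the
dominant spectral line of that section.

The displacement model is

    b(t) = b_max · sin(2π f t + φ),      b_max = displacement / 2,

with `displacement` the peak-to-peak travel in cm (1–5 cm covers normal
adult breathing, ~1.2 cm, up to irregular excursions of 4–5 cm). A
triangle waveform with the same period and range is available because a
constant-speed stepper stage really produces constant-velocity travel;
the pipeline must and does recover the same fundamental from either
shape.

## Benchmark grid

The package embeds a 35-condition grid of pre-set platform frequencies —
7 motor speeds (10–70 RPM) × 5 displacement steps (1–5 cm), spanning
0.06993–2.286 Hz. The grid values are stored constants (ground truth for
every experiment), not recomputed from kinematics: the convenience
formula `f = rpm·lead/(120·step)` with the best-fit lead of 4 cm
reproduces the first column but deviates in cells such as (10 RPM, 4 cm)
(0.0833 vs 0.07683 Hz), so no single screw-lead model explains the whole
table and `nominal_frequency` is documented as approximate and never
used for validation. Frequencies outside the closed 0.1–1 Hz normal
band (6–60 bpm) are flagged abnormal; exactly 7 of the 35 are.

## Card optics

The stripes span the card's width, so the transverse dimension
integrates out and the card reduces to a 1-D piecewise-constant
reflectance field along the travel axis (white 0.90, black 0.05, zero
off-card; 100 mm extent). The circular spot becomes a 1-D kernel over
that axis: the chord length `2√(r²−u²)` for a top-hat beam, a Gaussian
with FWHM equal to the spot diameter for a Gaussian beam. Both kernels
are integrated analytically over each constant segment (arcsine terms
for the chord, error functions for the Gaussian), so `reflected_fraction`
is exact up to floating point; the test suite checks it against a
brute-force 2-D rasterized footprint at a few-µm pitch to 1e-3.

**Default card geometry.** The simulator's default card places one wide
dark band over exactly the lower half of the travel range, boundary at
mid-travel. The spot then spends half of every cycle on dark and half on
white — a 50 %-duty square modulation whose even harmonics cancel and
whose strongest overtone (3f) is a third of the fundamental, so the
largest spectral line is the platform frequency for every displacement,
phase and waveform shape. This choice is deliberate: narrow-bar
geometries are spectrally fragile. A narrow bar crossed twice per cycle
at fractional spacing αT weights harmonic n by |cos(πnα)| — α = 1/2
cancels the fundamental outright in favour of 2f, and α = 1/3 doubles
3f. Even a narrow bar at a turning point (crossed once per cycle)
produces a near-impulsive dip train whose 2nd harmonic comes within
5–8 % of the fundamental at 3–5 cm travels; with ~4 cycles in a 60 s
record, spectral leakage plus noise then flips occasional recordings to
2f. Narrow-bar cards remain fully expressible through `StripedCard`
(bar width, count, offset are free parameters) for studying exactly
those failure modes.

The 15° tilt of the source in the physical geometry only keeps the
reflection inside the collection cone; it is absorbed into a
dimensionless `geometry_factor` (default 1.0) scaling spot travel per
unit platform travel. Speckle, polarization, BRDF and fibre-NA effects
are out of scope.

## Synthetic acquisition

Each frame is a flat detector baseline (150 counts) plus a Gaussian
spectral line at 632.8 nm (1.5 nm FWHM — an instrument-broadened line a
few detector pixels wide; only the band-integrated amplitude matters to
the pipeline) whose peak pixel reads `baseline + 10000 × reflected
fraction`. The default wavelength grid is 3648 linear pixels over
345–1040 nm; frames are rendered at the displacement sampled at
10 frames/s, comfortably above twice the highest benchmark frequency
(2.286 Hz); sub-Nyquist configurations raise an error naming both rates.

The noise model adds, in order: Gaussian read noise (SD 200 counts = 2 %
of full scale), Gaussian signal-proportional noise (SD = 2 % of the
clean counts, a shot-noise stand-in), and a sinusoidal baseline drift
(500 counts = 5 % of full scale, 120 s period, random phase) emulating
slow source-power wander; counts are clamped at the physical zero floor.
Everything derives from one integer seed: the same seed gives
bit-identical cubes, and all-zero parameters return the input unchanged.

This preset perturbs amplitudes by a few percent, but the recovered
quantity is a *frequency*: DFT peak location is famously insensitive to
amplitude noise, so the grid experiment's mean percent uncertainty under
this preset is ~0.05 %, far below the ≤5 % headline bound it is checked
against. Driving the *frequency* error into the several-percent range
would require qualitatively different disturbances (non-stationary
motion, dropped frames, mechanical error of the stage) that the noise
model deliberately does not include; the per-displacement uncertainties
are therefore reported, not asserted, and real-bench uncertainties in
the 2–5 % range should be read as dominated by effects outside this
simulator. That is the main caveat on what passing tests show about
real data.

Per-recording duration defaults to 60 s — a deliberately desk-scale
choice giving a raw DFT resolution of 1/60 Hz and ~4 cycles of the
slowest benchmark condition, the regime where leakage actually
stresses the peak picker.

## Recovery pipeline

1. **Slice**: per-frame mean intensity over 632 ± 2 nm (≈ 21 pixels).
2. **Detrend**: subtract the least-squares line. This removes baseline
   and the bulk of slow drift so the near-DC peak cannot mask the
   physiological one. Note a linear detrender necessarily absorbs a
   small part of the oscillation itself over few-cycle records (~0.5/k²
   of the amplitude over k whole periods); this biases amplitudes, not
   the peak location.
3. **Smooth**: 3-sample centered moving average (0.3 s at 10 frames/s);
   its first spectral null at 3.33 Hz keeps the highest benchmark
   frequency (2.286 Hz) in the passband. Edges use a shrinking window —
   no phantom zeros biasing short records; constants pass unchanged and
   window 1 is the identity.
4. **DFT**: magnitude of the real FFT, zero-padded 4× (resolution
   10/(600·4) ≈ 0.0042 Hz for the default record). Zero padding refines
   the frequency sampling without adding information; Parseval's
   identity holds exactly.
5. **Pick**: largest magnitude in 0.05–2.5 Hz (covers all benchmark
   frequencies with margin; the floor plus detrending excludes DC and
   drift), refined by a three-point parabolic fit clamped to ±half a
   bin; ties break toward the lower frequency; the refined estimate is
   clipped into the search band. `bpm = 60 × Hz` exactly.

Noiselessly, the full 35-condition sweep recovers every grid frequency
within one interpolated bin (worst case ≈ 0.0007 Hz); this sweep is the
pipeline's primary oracle, and recovery is invariant to motion phase and
to sine-vs-triangle shape within the same tolerance.

## Scoring and the grid experiment

Accuracy: `U(%) = 100·|f_est − f_true|/f_true` (zero iff exact, invariant
under common rescaling — the same number whether computed in Hz or bpm).
Classification: abnormal (outside closed 0.1–1 Hz) is the positive
class, the clinically alarmed condition; sensitivity, specificity,
positive predictivity and accuracy are derived exactly from the four
confusion counts, with zero-denominator ratios reported as NaN rather
than 0. `run_grid` simulates every condition × repeats (default 3 →
105 recordings), scoring and classifying each; per-recording noise seeds
and motion phases are drawn from one master seed, so reports are exactly
reproducible. Aggregates: per-displacement mean ± SD uncertainty,
overall mean, confusion metrics; written as `grid_report.tsv` +
`summary.tsv`.

## File formats

Per-frame tab-delimited text (`frame_000000.tsv`, …: '#' headers with
frame index, time in seconds and an ISO timestamp; wavelength/intensity
columns at 17 significant digits for bit-exact round trips; zero-padded
names make lexicographic order time order) mirrors vendor exports and
stays greppable; an HDF5 cube (matrix + both axes + JSON metadata) is
the fast lossless container. Readers validate identical wavelength grids
across frames and monotone timestamps, and fall back to a uniform time
axis at a stated rate when timestamps are absent. Vendor-proprietary
binary formats are not parsed.

## Numerical choices and degenerate inputs

- Time axis must be uniform to 1e-9 s; non-uniform sampling is an error
  (resampling is out of scope), as is an even or oversized smoothing
  window, an empty wavelength band, a search band including DC, or a
  wavelength grid that does not cover the laser line.
- Phase is normalised into [0, 2π); frame count is ⌊duration × rate⌋.
- The parabolic peak offset is clamped to ±0.5 bin and the denominator
  guarded against exact flatness (offset 0 in that case).
- Reflected fractions are exact analytic integrals, continuous in
  displacement and bounded by the field's extreme values.

## Known limitations

- The simulator omits stage acceleration profiles, backlash, speckle,
  detector non-uniformity and wavelength-calibration error; it cannot
  reproduce hardware-specific uncertainty levels, only the pipeline's
  behaviour under the stated noise.
- Instantaneous (time-varying) rate tracking and harmonic
  disambiguation beyond band-limited peak picking are out of scope.
- The normal band's endpoints are taken as inclusive; no benchmark
  frequency lies exactly on a boundary, so the choice does not affect
  the grid partition.
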