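# respispec

Simulation and spectral recovery of respiratory rate from a laser beam
reflected off a striped card on a moving platform.

Non-contact respiratory-rate monitors matter most where contact sensors
fail: neonates with fragile skin, long-term monitoring in intensive care,
subjects who move. One optical approach points a low-power He-Ne laser at
a black/white striped card attached to the moving surface (a chest wall,
or a mechanical platform standing in for one) and records the reflected
light with a fibre-coupled spectrometer running continuously. As the card
oscillates vertically, the bar pattern sweeps through the laser spot and
modulates the reflected power, so the breathing motion is encoded as an
intensity-time signal at the laser wavelength — independent of skin tone
and requiring no attached electrodes.

`respispec` implements that measurement end to end as software, for
people developing or evaluating the recovery pipeline without the bench:

- **forward model** — chest-wall/platform displacement
  `b(t) = b_max sin(2πft + φ)` (or a constant-speed triangle), a 1-D
  reflectance field for the striped card, an exact chord-weighted overlap
  integral for the circular laser spot, and a synthetic spectrometer
  (3648-pixel, 345–1040 nm, 10 frames/s) with seeded read noise,
  signal-proportional noise and slow baseline drift;
- **recovery pipeline** — slice the intensity–wavelength–time cube at
  632 nm, linear detrend, 3-sample moving average, zero-padded magnitude
  DFT `B(ω) = ∫ b(t) e^{-jωt} dt`, and parabolic-interpolated peak
  picking in the 0.05–2.5 Hz physiological band (bpm = 60 × Hz);
- **evaluation** — percent uncertainty
  `U = 100·|f_est − f_true|/f_true`, normal/abnormal classification
  against the 0.1–1 Hz band, confusion metrics, and a 35-condition
  benchmark grid (7 motor speeds × 5 displacements, 0.07–2.29 Hz, of
  which 7 conditions are pathological rates) run with repeats.

## Worked example

Simulate one benchmark condition (0.3291 Hz, 2 cm travel, 60 s at
10 frames/s, default noise) and recover its frequency:

```python
from respispec import (MotionSpec, NoiseModel, simulate_acquisition,
                       recover, absolute_uncertainty, classify_rate)

spec = MotionSpec(frequency=0.3291, displacement=2.0, duration=60.0)
cube = simulate_acquisition(spec, noise=NoiseModel(seed=7))
est = recover(cube)
print(f"recovered frequency: {est.frequency:.4f} Hz ({est.bpm:.2f} bpm)")
print(f"bin resolution:      {est.bin_resolution:.5f} Hz")
print(f"uncertainty vs true: {absolute_uncertainty(est.frequency, 0.3291):.3f}%")
print(f"classification:      {classify_rate(est.frequency)}")
```

prints

```
recovered frequency: 0.3290 Hz (19.74 bpm)
bin resolution:      0.00417 Hz
uncertainty vs true: 0.017%
classification:      normal
```

The recovered 0.3290 Hz is the DFT peak of the 632 nm intensity slice
after detrending and smoothing, refined to sub-bin precision; 19.74 bpm
is the same number as a breathing rate, and 0.017 % is its relative error
against the condition's true frequency — well inside one interpolated
frequency bin (0.00417 Hz). The rate lies inside the 0.1–1 Hz normal
band, so the condition is classified as a normal respiratory rate.

The same operations are available from a shell:

```bash
respispec simulate --config run.yaml --out recording.h5
respispec recover recording.h5
respispec convert recording.h5 frames/ --fmt frames
respispec grid --repeats 3 --seed 0 --out report/
```

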