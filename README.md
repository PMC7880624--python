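# thzpellet

Terahertz time-domain spectroscopy (THz-TDS) of lyophilized blood-plasma
pellets: forward simulation of transmission measurements, extraction of the
absorption coefficient and refractive index from waveform pairs, density
normalization, and PCA + linear-SVM class separability between diabetic and
non-diabetic specimens.

## The problem

Freeze-dried blood plasma pressed into millimetre-scale pellets can be stored
at room temperature and probed repeatedly with THz pulses; because free water
is removed, the pellets are transparent enough for transmission spectroscopy
over 0.2–1.4 THz. A THz-TDS instrument records the transmitted electric-field
waveform, so one measurement yields both spectral amplitude `A(ω)` and phase
`φ(ω)`, hence both optical constants of the pellet:

- phase → refractive index: `n(f) = 1 + Δφ·c / (2π f d)`, where
  `Δφ = φ_sam − φ_ref` is the (unwrapped, zero-frequency-corrected) phase
  difference and `d` the pellet thickness;
- amplitude → power absorption:
  `α(f) = (2/d)·ln[ 4n·A_ref / ((n+1)²·A_sam) ]`,
  the `4n/(n+1)²` factor being the two-surface Fresnel transmission.

Pellets pressed at different pressures differ in density `ρ = m/(π D²/4·d)`,
so the comparable material quantities are the density-normalized forms
`α/ρ` (a molar-extinction analogue) and `(n−1)/ρ`. In the underlying study
the normalized refractive index of diabetic pellets exceeds the non-diabetic
one by ~9–12%, and amplitude-ratio spectra of the two classes separate
linearly in the space of their first two principal components.

The raw cohort waveforms were never published, so this package treats
**parameter recovery on synthetic data** as its verification surface: a
forward simulator (single-cycle pulse through a dispersive absorbing slab
with Fabry–Perot echoes and instrument noise) produces measurement pairs
with known ground truth, and the extraction/classification pipeline must
recover it.

## Worked example

```python
import numpy as np
from thzpellet import (MaterialModel, NoiseSpec, PulseSpec,
                       make_reference_pulse, simulate_measurement,
                       thickness_from_echo)
from thzpellet.extraction import ExtractionConfig, extract_pipeline

ref = make_reference_pulse(PulseSpec())                  # single-cycle pulse
slab = MaterialModel(n0=1.8, n_slope=0.0,
                     alpha_coeffs=(0.0, 0.0, 80/1.4**2))  # alpha ~ 80 cm^-1 at 1.4 THz
pair = simulate_measurement(ref, slab, d=1.0, noise=NoiseSpec(1e3, seed=1),
                            n_echoes=1)

d_hat = thickness_from_echo(pair.sample, n_est=1.8)
props = extract_pipeline(pair, config=ExtractionConfig(thickness_source="echo"))
band = (props.frequencies >= 0.3) & (props.frequencies <= 1.2)
print(f"echo thickness: {d_hat*1e3:.1f} um (true 1000.0)")
print(f"n at 1 THz: {np.interp(1.0, props.frequencies, props.n):.4f} (true 1.8000)")
print(f"alpha at 1 THz: {np.interp(1.0, props.frequencies, props.alpha_cm):.1f} cm^-1"
      f" (true {slab.alpha_cm(1.0):.1f})")
```

prints

```
echo thickness: 1002.1 um (true 1000.0)
n at 1 THz: 1.7975 (true 1.8000)
alpha at 1 THz: 40.7 cm^-1 (true 40.8)
```

i.e. at an amplitude SNR of 10³ the echo-based thickness is good to a few
micrometres and the recovered optical constants to a fraction of a percent —
the pellet's index and absorption are read off a single waveform pair.

The numbered scripts under `analysis/` run the full study-shaped analyses
(pellet-table densities and biochemistry fold changes, thickness accuracy,
round-trip parameter recovery, cohort classification) and write their tables
under `results/`. The same stages are available as a CLI:

```
thztds run-all --out runs/demo --seed 7
```

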