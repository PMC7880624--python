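# Methods

This note documents the models, estimators and design choices behind
`thzpellet`, and states what the synthetic-data experiments do and do not
establish.

## Units and conventions

Internally all lengths are mm, times ps, frequencies THz (`c =
0.299792458 mm/ps`); absorption coefficients cross module boundaries in
cm⁻¹ (10× their mm⁻¹ value), matching how THz spectra are conventionally
plotted. The Fourier convention is a forward kernel `e^{+iωt}`, chosen so
that a slab of index n > 1 *delays* the pulse and produces a positive
spectral phase difference `Δφ = (ω/c)(n−1)d`; with that sign, the complex
index is `ñ = n + iκ` with `κ = α·c/(4πf)` and the field decays as
`e^{−αd/2}`. In code this is `conj(rfft(x))`.

## Forward model

A measurement pair is a reference waveform (free-space path) and a sample
waveform (pulse through the pellet). The reference pulse is the first
derivative of a Gaussian — a generic single-cycle THz transient; the
extraction is deliberately shape-agnostic (it uses only ratio and difference
quantities), so the precise shape is immaterial. Defaults: width 0.25 ps,
centre 10 ps, grid 0–80 ps in 0.05 ps steps. These give a spectral peak near
0.64 THz, usable amplitude across 0.2–1.4 THz, a frequency resolution of
12.5 GHz, and room for etalon echoes (a 1.8 mm pellet of n ≈ 2.1 puts its
first echo ~25 ps after the main pulse).

The slab transfer function is the standard normal-incidence expression: a
Fresnel factor `4ñ/(ñ+1)²`, a propagation factor `e^{i(k̃−ω/c)d}` with
`k̃ = (ω/c)ñ`, and a finite geometric sum of Fabry–Pérot echo terms
`[((ñ−1)/(ñ+1))² e^{i2k̃d}]^p`, p = 0…n_echoes. The truncated sum matches
the closed-form etalon denominator to 1e-10 by 50 terms (tested), and
`|H| < 1` for any absorbing slab (passivity, property-tested). At the DC bin
the `1/f` singularity of κ cancels in the products the simulator needs
(`(ω/c)κd → αd/2`), and the limit is evaluated explicitly.

Materials are parametric: `n(f) = n0 + n_slope·(f−1)` and polynomial `α(f)`.
Real lyophilized-plasma spectra are smooth and featureless over the band, so
low-order forms suffice. One artefact of the *linear* dispersion model is a
kink at f = 0 (a physical n(f) is even in f), which leaves acausal time-
domain tails at the 1e-6 level; the exact gating-equivalence test therefore
uses a dispersion-free material, and the dispersive case is checked at the
level the tails permit.

Noise is additive, white and stationary in the time domain, applied
independently to both channels. Its scale is set spectrally: the reference
amplitude at 1 THz divided by the RMS spectral noise floor equals the
configured SNR (10³ and 10⁴ are the realistic instrument classes). All
randomness flows from one integer seed.

## Extraction

1. **Gate.** The sample trace is zeroed outside `[t_start, t_peak + 0.8·
   (2 n_est d/c)]` with a raised-cosine taper over 10% of the gate length at
   each edge, removing echoes while keeping the transmitted pulse. Gate
   placement, window shape and taper are this package's choices; with no
   echoes present, gating is a no-op to ~1e-9.
2. **FFT + unwrap.** One-sided spectra; the phase is unwrapped along
   ascending frequency starting from the first nonzero bin (the DC bin of a
   near-zero-mean pulse has a random sign and would poison the unwrap).
3. **Phase correction.** A line is least-squares fit to `Δφ(f)` over
   0.3–1.0 THz (the high-SNR interior, a package default) and the intercept
   is snapped to the nearest multiple of 2π and subtracted, so `Δφ`
   extrapolates to zero at f = 0. This removes the arbitrary unwrapping
   branch without touching the physical slope.
4. **Inversion.** `n = 1 + Δφ·c/(2πfd)`; then
   `α = (2/d)·ln[4n·A_ref/((n+1)²·A_sam)]`. The Fresnel factor uses the real
   index only (first-order approximation, kept deliberately): for
   α ≤ 100 cm⁻¹ its phase contributes ≲1e-3 relative to n−1 and its modulus
   ≲4e-4 to ln-amplitude, bounds the round-trip tests confirm directly.
   Mildly negative α values are legitimate noise excursions; anything below
   −1 cm⁻¹ is flagged in the output metadata.
5. **Normalization.** `ρ = m/(πD²/4·d)`; `α_norm = α/ρ`, `n_norm = (n−1)/ρ`
   — exact bijections for ρ > 0.

Round-trip accuracy (d = 1 mm, n ≈ 1.8, α up to 80 cm⁻¹, 0.3–1.2 THz):
noiseless ≤0.05% in n and ≤0.1% in α; at SNR 10³ with a gated echo, ≤0.1%
in n (worst seed) with thickness given.

## Thickness from the etalon echo

The first internal re-reflection lags the transmitted pulse by `2nd/c`, so
`d = c·Δt/(2 n_est)`. Both pulses are located at the sub-sample level by
3-point quadratic interpolation of |amplitude| around **both lobes** of the
single-cycle waveform (polarity-matched between main pulse and echo), and
the two lobe-to-lobe delays are averaged. The averaging matters: the echo
crosses the absorbing slab twice more than the main pulse and is therefore
low-pass filtered and broadened; a symmetrically broadened odd pulse moves
its two lobes *apart*, so either single lobe is biased by half the
broadening (≈15 μm at d = 1 mm under the default absorption) while the pair
average cancels the effect to first order (residual ≈ +2 μm). An echo must
exceed 3× the pre-pulse peak excursion (a peak-noise floor — an RMS floor
would be crossed by the maximum of ~10³ noise samples even without an
echo). At SNR 10³ the mean absolute error on a 1.000 mm non-dispersive slab
is ~2.7 μm over 20 seeds.

Known limitation: with dispersion the echo travels at the *group* velocity
of its filtered spectrum. For dn/df = −0.02/THz the estimator `d =
cΔt/(2n(1 THz))` acquires a ~+10 μm systematic bias at d = 1 mm
(`analysis/02` quantifies it). The phase-based index extraction is far less
sensitive: a 0.3% thickness error moves n by only ~0.13%, so the 1%
refraction accuracy holds with echo-estimated thickness even in the
dispersive case.

## Synthetic cohorts and what they show

A cohort draws per-pellet geometry (diameter 5 mm; thickness and density
uniform over the measured ranges 0.52–1.81 mm and 1.000–1.358 mg/mm³ by
default), gives class A a baseline density-normalized index of 0.73 at
1 THz (≈(1.8−1)/1.1) and class B that baseline scaled by (1 + contrast),
with both classes sharing one normalized absorption curve (quadratic,
≈72.7 cm⁻¹ per mg/mm³ at 1.4 THz) — mirroring the observation that the
classes differ in normalized index but not normalized absorption. Each
pellet's actual `n0` and `α` follow from its sampled density, so extraction
plus normalization recovers the imposed contrast (10% imposed → 9.9%
recovered across the full geometry spread; tested).

**The separability experiment holds geometry fixed** (d = 1.1 mm, ρ =
1.1 mg/mm³, within-class variation from measurement noise only). Reason: the
classifier's features are raw amplitude ratios `A_sam/A_ref`, which scale as
`e^{−αd/2}`; across the full measured thickness range that exponent varies
by an order of magnitude, while a 10% index contrast leaves only a ~1.3%
frequency-flat Fresnel signature. With geometry mixed, PCA spends its first
components on α·d spread and the classes are *not* linearly separable
(`analysis/04` demonstrates this at training accuracy ≈0.53) — the
classification analogue of why optical properties must be density-normalized
before pellets are comparable. At fixed geometry the contrast separates
cleanly (accuracy 1.0, permutation p ≈ 0.005) and a zero-contrast control
stays at chance (p ≈ 0.5). Incidentally, the most informative PC1 frequency
falls at the low end of the band (~0.22 THz), where absorption is weakest
and the Fresnel signature is clearest against noise.

What this does not show: real cohorts add biological within-class variation,
pellet surface roughness, spot-to-spot inhomogeneity and instrument drift,
none of which are modelled; training-set separability of 15-per-class
synthetic spectra is an illustration of detectability, not a validated
classifier. The published explained-variance percentages and informative
frequencies depend on the unpublished raw spectra and are intentionally not
reproduction targets.

## PCA/SVM choices

Mean-centering without per-column scaling (columns share units); component
signs fixed so each loading's largest-magnitude entry is positive; ties in
the informative-frequency argmax break toward the lower frequency. With two
classes the one-versus-rest linear SVM reduces to one binary hyperplane,
fitted at C = 1.0 on the first two component scores; accuracy is reported on
training data, with a 199-shuffle label-permutation control (add-one
smoothed p-value) to distinguish structure from overfitting.

## Problem sizes

Default grids (1601 samples), 20-seed accuracy loops and 30-spectrum
cohorts keep every analysis script and the full test suite in the seconds
range on one core while leaving each estimate's Monte-Carlo scatter well
inside the tolerances quoted above.
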