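"""Optical-constant extraction from reference/sample waveform pairs.

Pipeline (transmission THz-TDS, thin-slab inversion):

1. time-gate the sample trace so only the directly transmitted pulse remains
   (Fabry-Perot echoes removed instead of modelled);
2. FFT both traces (forward kernel ``e^{+i omega t}``) to amplitude A(omega)
   and unwrapped phase phi(omega);
3. correct the phase difference for the arbitrary 2 pi branch left by
   unwrapping: fit a straight line over a high-SNR band and snap its
   intercept to the nearest multiple of 2 pi, so delta-phi extrapolates to 0
   at zero frequency;
4. invert the first-order slab equations:

       n(f)      = 1 + delta_phi * c / (2 pi f d)
       alpha(f)  = (2/d) ln[ 4 n A_ref / ((n+1)^2 A_sam) ]        (-> cm^-1)

5. normalize by pellet density rho_o = m/(pi D^2/4 d):
   alpha_norm = alpha/rho_o and n_norm = (n-1)/rho_o, which removes the
   pressing-pressure dependence (alpha/rho_o plays the role of a molar
   extinction).

The first-order Fresnel factor uses the real index only (4n/(n+1)^2); for
alpha < 100 cm^-1 the imaginary part contributes well below the other error
terms, which the round-trip recovery tests bound directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import C_MM_PS
from .dataio import PelletGeometry, Waveform, density_from_dimensions
from .errors import DetectionError, DomainError, FitError
from .synthetic import MeasurementPair, _forward_fft


@dataclass
class Spectrum:
    """One-sided spectrum: amplitude and unwrapped phase on a THz grid."""

    frequencies: np.ndarray  # THz, strictly increasing, starts at 0
    amplitude: np.ndarray  # a.u., >= 0
    phase: np.ndarray  # rad, unwrapped along frequency


@dataclass(frozen=True)
class GateConfig:
    """A time gate [start, end] ps with a cosine taper at both edges.

    ``taper_fraction`` is the fraction of the gate length tapered at each
    edge (0 = hard rectangle, up to 0.5 = full Hann).
    """

    start: float
    end: float
    taper_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise DomainError("gate end must exceed gate start")
        if not (0.0 <= self.taper_fraction <= 0.5):
            raise DomainError("taper_fraction must lie in [0, 0.5]")


@dataclass
class OpticalProperties:
    """Extracted n(f), alpha(f) and their density-normalized forms."""

    frequencies: np.ndarray  # THz
    n: np.ndarray  # dimensionless
    alpha_cm: np.ndarray  # cm^-1
    density_mg_mm3: float | None = None
    n_norm: np.ndarray | None = None  # (n-1)/rho, per (mg/mm^3)
    alpha_norm: np.ndarray | None = None  # alpha/rho, cm^-1 per (mg/mm^3)
    meta: dict = field(default_factory=dict)


def gate_first_pulse(w: Waveform, g: GateConfig) -> Waveform:
    """Zero the trace outside the gate, cosine-tapering inside both edges."""
    t = w.times
    eps = 1e-9 * max(1.0, abs(float(t[-1])))
    if g.start < t[0] - eps or g.end > t[-1] + eps:
        raise DomainError(
            f"gate [{g.start}, {g.end}] ps outside waveform span "
            f"[{t[0]}, {t[-1]}] ps"
        )
    window = np.zeros_like(t)
    inside = (t >= g.start) & (t <= g.end)
    window[inside] = 1.0
    taper = g.taper_fraction * (g.end - g.start)
    if taper > 0:
        rise = inside & (t < g.start + taper)
        window[rise] = 0.5 * (1.0 - np.cos(math.pi * (t[rise] - g.start) / taper))
        fall = inside & (t > g.end - taper)
        window[fall] = 0.5 * (1.0 - np.cos(math.pi * (g.end - t[fall]) / taper))
    return w.copy(amplitudes=w.amplitudes * window)


def compute_spectrum(w: Waveform) -> Spectrum:
    """One-sided FFT spectrum with phase unwrapped along frequency.

    Frequencies are f_k = k/(N dt).  Unwrapping starts at the first nonzero
    frequency: the DC bin of a near-zero-mean pulse has an essentially random
    sign, and anchoring the unwrap there would toggle every phase by pi.
    """
    freqs = np.fft.rfftfreq(w.n, w.dt)
    spec = _forward_fft(w.amplitudes)
    phase = np.angle(spec)
    unwrapped = np.concatenate(([phase[0]], np.unwrap(phase[1:])))
    return Spectrum(freqs, np.abs(spec), unwrapped)


def phase_difference(
    ref: Spectrum,
    sam: Spectrum,
    fit_band: tuple[float, float] = (0.3, 1.0),
) -> np.ndarray:
    """phi_sam - phi_ref with the 2 pi unwrapping branch removed.

    A straight line is least-squares fit to the raw difference on
    ``fit_band``; the fitted intercept is rounded to the nearest multiple of
    2 pi and subtracted everywhere, so the corrected difference extrapolates
    to zero at f = 0 (a pure delay leaves no offset).
    """
    if ref.frequencies.shape != sam.frequencies.shape or not np.allclose(
        ref.frequencies, sam.frequencies
    ):
        raise DomainError("reference and sample spectra must share one grid")
    f = ref.frequencies
    dphi = sam.phase - ref.phase
    dphi = np.concatenate(([dphi[0]], np.unwrap(dphi[1:])))
    mask = (f >= fit_band[0]) & (f <= fit_band[1])
    if int(mask.sum()) < 4:
        raise FitError(
            f"fewer than 4 grid points in fit band [{fit_band[0]}, {fit_band[1]}] THz"
        )
    slope, intercept = np.polyfit(f[mask], dphi[mask], 1)
    shift = 2.0 * math.pi * round(intercept / (2.0 * math.pi))
    return dphi - shift


def refractive_index(
    dphi: np.ndarray | float, d: float, f: np.ndarray | float
) -> np.ndarray | float:
    """n = 1 + delta_phi * c / (2 pi f d); f in THz, d in mm."""
    f = np.asarray(f, dtype=float)
    if d <= 0:
        raise DomainError("thickness d must be positive")
    if np.any(f <= 0):
        raise DomainError("refractive_index requires f > 0")
    out = 1.0 + np.asarray(dphi, dtype=float) * C_MM_PS / (2.0 * math.pi * f * d)
    return float(out) if out.ndim == 0 else out


#: extracted alpha below this value (cm^-1) is flagged as beyond the noise floor
ALPHA_FLOOR_CM = -1.0


def absorption(
    a_ref: np.ndarray | float,
    a_sam: np.ndarray | float,
    n: np.ndarray | float,
    d: float,
) -> np.ndarray | float:
    """alpha = (2/d) ln[4 n A_ref / ((n+1)^2 A_sam)], returned in cm^-1.

    Mildly negative values are legitimate noise excursions and are returned
    as-is; callers flag anything below :data:`ALPHA_FLOOR_CM`.
    """
    a_ref = np.asarray(a_ref, dtype=float)
    a_sam = np.asarray(a_sam, dtype=float)
    n = np.asarray(n, dtype=float)
    if d <= 0:
        raise DomainError("thickness d must be positive")
    if np.any(a_ref <= 0) or np.any(a_sam <= 0):
        raise DomainError("spectral amplitudes must be positive")
    if np.any(n < 1.0):
        raise DomainError("absorption requires n >= 1")
    alpha_mm = (2.0 / d) * np.log(4.0 * n * a_ref / ((n + 1.0) ** 2 * a_sam))
    out = 10.0 * alpha_mm  # mm^-1 -> cm^-1
    return float(out) if out.ndim == 0 else out


def _refine_peak(t: np.ndarray, y: np.ndarray, i: int) -> float:
    """Sub-sample peak location by local quadratic interpolation of y."""
    if i <= 0 or i >= y.size - 1:
        return float(t[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0.0:
        return float(t[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(t[i] + delta * (t[1] - t[0]))


def thickness_from_echo(
    sam: Waveform,
    n_est: float,
    min_delay_ps: float = 3.0,
    lobe_window_ps: float = 2.0,
) -> float:
    """Slab thickness from the first Fabry-Perot echo: d = c dt / (2 n_est).

    ``dt`` is the delay between the main transmitted pulse and its first
    internal re-reflection.  Each pulse is located at the sub-sample level by
    quadratic interpolation of |amplitude| around *both* lobes of the
    single-cycle waveform, and the two lobe-to-lobe delays are averaged:
    absorption low-pass-filters the echo, and a symmetrically broadened odd
    pulse moves its two lobes apart in opposite directions, so the single-lobe
    delay is biased by half the broadening while the lobe-pair average cancels
    it to first order.  An echo must rise above 3x the pre-pulse noise floor.
    """
    if n_est <= 1.0:
        raise DomainError("n_est must exceed 1")
    t = sam.times
    amp = sam.amplitudes
    i_main = int(np.argmax(np.abs(amp)))
    sign = 1.0 if amp[i_main] >= 0 else -1.0

    def opposite_lobe(i: int) -> int:
        lo = int(np.searchsorted(t, t[i] - lobe_window_ps))
        hi = int(np.searchsorted(t, t[i] + lobe_window_ps))
        return lo + int(np.argmax(-sign * amp[lo:hi]))

    after = np.nonzero(t > t[i_main] + min_delay_ps)[0]
    if after.size < 3:
        raise DetectionError("no samples beyond the main pulse to search for an echo")
    j = int(after[np.argmax(sign * amp[after])])

    # peak-noise floor: the largest pre-pulse excursion, i.e. what pure noise
    # reaches over a window of this length (an RMS floor would be crossed by
    # the max of ~10^3 noise samples even without an echo)
    before = np.nonzero(t < t[i_main] - min_delay_ps)[0]
    noise_floor = float(np.max(np.abs(amp[before]))) if before.size >= 8 else 0.0
    threshold = max(3.0 * noise_floor, 1e-6 * abs(amp[i_main]))
    if sign * amp[j] < threshold:
        raise DetectionError(
            f"no echo above 3x noise floor (peak {sign * amp[j]:.3g} vs "
            f"threshold {threshold:.3g})"
        )
    i_main2 = opposite_lobe(i_main)
    j2 = opposite_lobe(j)
    delay = 0.5 * (
        (_refine_peak(t, sign * amp, j) - _refine_peak(t, sign * amp, i_main))
        + (_refine_peak(t, -sign * amp, j2) - _refine_peak(t, -sign * amp, i_main2))
    )
    return C_MM_PS * delay / (2.0 * n_est)


def pellet_density(g: PelletGeometry) -> float:
    """rho_o = m / (pi D^2/4 * d), mg/mm^3."""
    return density_from_dimensions(g.mass_mg, g.diameter_mm, g.thickness_mm)


def normalize_properties(p: OpticalProperties, rho: float) -> OpticalProperties:
    """Density-normalize: alpha_norm = alpha/rho, n_norm = (n-1)/rho."""
    if rho <= 0:
        raise DomainError("density must be positive")
    return replace(
        p,
        density_mg_mm3=rho,
        n_norm=(p.n - 1.0) / rho,
        alpha_norm=p.alpha_cm / rho,
    )


@dataclass
class SpectraStats:
    """Pointwise mean and sample standard deviation over several spectra."""

    frequencies: np.ndarray
    n_mean: np.ndarray
    n_sd: np.ndarray
    alpha_mean: np.ndarray
    alpha_sd: np.ndarray
    count: int
    n_norm_mean: np.ndarray | None = None
    alpha_norm_mean: np.ndarray | None = None


def average_spectra(props: list[OpticalProperties]) -> SpectraStats:
    """Average a list of OpticalProperties sharing one frequency grid.

    With a single spectrum the standard deviation is reported as zeros and
    ``count == 1`` flags it as degenerate.
    """
    if not props:
        raise DomainError("cannot average an empty list of spectra")
    f = props[0].frequencies
    for p in props[1:]:
        if p.frequencies.shape != f.shape or not np.allclose(p.frequencies, f):
            raise DomainError("all spectra must share one frequency grid")
    n_stack = np.stack([p.n for p in props])
    a_stack = np.stack([p.alpha_cm for p in props])
    count = len(props)
    ddof = 1 if count > 1 else 0
    sd_n = np.std(n_stack, axis=0, ddof=ddof) if count > 1 else np.zeros_like(f)
    sd_a = np.std(a_stack, axis=0, ddof=ddof) if count > 1 else np.zeros_like(f)
    stats = SpectraStats(
        frequencies=f.copy(),
        n_mean=n_stack.mean(axis=0),
        n_sd=sd_n,
        alpha_mean=a_stack.mean(axis=0),
        alpha_sd=sd_a,
        count=count,
    )
    if all(p.n_norm is not None for p in props):
        stats.n_norm_mean = np.stack([p.n_norm for p in props]).mean(axis=0)
        stats.alpha_norm_mean = np.stack([p.alpha_norm for p in props]).mean(axis=0)
    return stats


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable extraction parameters and their defaults.

    ``thickness_source``: "given" uses the micrometer value from the pellet
    table (or the simulation ground truth); "echo" estimates thickness from
    the etalon-echo delay.  The gate, when not set explicitly, runs from the
    trace start to the main-peak time plus 0.8 x the echo round-trip
    (2 n_est d / c), ending safely before the first echo.
    """

    band: tuple[float, float] = (0.2, 1.4)  # THz, output band
    fit_band: tuple[float, float] = (0.3, 1.0)  # THz, phase-correction fit
    taper_fraction: float = 0.1
    thickness_source: str = "given"  # "given" | "echo"
    thickness_mm: float | None = None  # explicit override
    echo_n_est: float = 1.8
    min_echo_delay_ps: float = 3.0
    gate: GateConfig | None = None
    apply_gate: bool = True

    def __post_init__(self) -> None:
        if self.thickness_source not in ("given", "echo"):
            raise DomainError("thickness_source must be 'given' or 'echo'")


def _resolve_thickness(
    pair: MeasurementPair,
    geometry: PelletGeometry | None,
    config: ExtractionConfig,
) -> float:
    if config.thickness_mm is not None:
        d = config.thickness_mm
    elif config.thickness_source == "echo":
        d = thickness_from_echo(pair.sample, config.echo_n_est, config.min_echo_delay_ps)
    elif geometry is not None:
        d = geometry.thickness_mm
    else:
        d = pair.true_thickness
    if d is None or d <= 0:
        raise DomainError("no positive thickness available")
    return float(d)


def pair_spectra(
    pair: MeasurementPair,
    config: ExtractionConfig = ExtractionConfig(),
    thickness_mm: float | None = None,
) -> tuple[Spectrum, Spectrum]:
    """(reference, gated-sample) spectra of a pair, as the pipeline sees them.

    The auto gate runs from the trace start to the main-peak time plus 0.8 x
    the estimated echo round trip, removing Fabry-Perot echoes while keeping
    the directly transmitted pulse intact.
    """
    d = thickness_mm
    if d is None:
        d = _resolve_thickness(pair, pair.geometry, config)
    sample = pair.sample
    if config.apply_gate:
        gate = config.gate
        if gate is None:
            t = sample.times
            i_main = int(np.argmax(np.abs(sample.amplitudes)))
            end = float(t[i_main]) + 0.8 * (2.0 * config.echo_n_est * d / C_MM_PS)
            gate = GateConfig(float(t[0]), min(end, float(t[-1])), config.taper_fraction)
        sample = gate_first_pulse(sample, gate)
    return compute_spectrum(pair.reference), compute_spectrum(sample)


def extract_pipeline(
    pair: MeasurementPair,
    geometry: PelletGeometry | None = None,
    config: ExtractionConfig = ExtractionConfig(),
) -> OpticalProperties:
    """Full inversion of a measurement pair to (normalized) optical properties.

    Gate -> FFT -> phase correction -> n(f) -> alpha(f), restricted to the
    configured band, then density-normalized when a pellet geometry is
    available.
    """
    geometry = geometry if geometry is not None else pair.geometry
    d = _resolve_thickness(pair, geometry, config)
    spec_ref, spec_sam = pair_spectra(pair, config, thickness_mm=d)
    dphi = phase_difference(spec_ref, spec_sam, config.fit_band)

    f = spec_ref.frequencies
    mask = (f >= config.band[0]) & (f <= config.band[1])
    fb = f[mask]
    n = refractive_index(dphi[mask], d, fb)
    n_for_alpha = np.maximum(n, 1.0)  # guard noise excursions below vacuum
    alpha = absorption(spec_ref.amplitude[mask], spec_sam.amplitude[mask], n_for_alpha, d)

    props = OpticalProperties(
        frequencies=fb,
        n=np.asarray(n),
        alpha_cm=np.asarray(alpha),
        meta={
            "thickness_mm": d,
            "thickness_source": config.thickness_source
            if config.thickness_mm is None
            else "explicit",
            "alpha_below_floor": bool(np.any(np.asarray(alpha) < ALPHA_FLOOR_CM)),
        },
    )
    if geometry is not None:
        props = normalize_properties(props, pellet_density(geometry))
    return props
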