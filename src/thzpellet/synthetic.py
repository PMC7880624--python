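"""Forward simulation of THz-TDS transmission measurements of pressed pellets.

The simulator produces reference/sample waveform pairs with a known ground
truth, which is the package's main verification surface: the extraction
pipeline must recover the material parameters that generated a pair.

Model
-----
A single-cycle THz pulse (Gaussian first derivative) propagates at normal
incidence through a plane-parallel slab of thickness ``d`` with complex
refractive index ``n~ = n + i*kappa``.  Relative to the free-space reference
path the field transfer function is a Fresnel factor, a propagation factor,
and a finite sum of Fabry-Perot (etalon) echo terms:

    H(f) = 4 n~/(n~+1)^2 * sum_{p=0}^{P} [((n~-1)/(n~+1))^2 e^{i 2 k~ d}]^p
           * e^{i (k~ - omega/c) d},      k~ = (omega/c) n~,  omega = 2 pi f.

The sign convention is a forward Fourier kernel ``e^{+i omega t}`` so that a
slab with n > 1 delays the pulse and produces a *positive* spectral phase
difference (omega/c)(n-1)d, making the extraction equations hold sign for
sign.  With that convention, ``kappa = alpha * c / (4 pi f)`` (power
absorption alpha) attenuates the field as ``e^{-alpha d / 2}``.

Noise is additive, white and stationary in the time domain, and is quoted as
an amplitude signal-to-noise ratio on the *spectral* amplitude at 1 THz — the
figure of merit THz spectrometer builders quote (10^3–10^4 for the
photoconductive and electro-optic instruments this emulates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from pathlib import Path

from .constants import C_MM_PS
from .dataio import (
    PelletGeometry,
    Waveform,
    density_from_dimensions,
    read_waveform,
    write_waveform,
)
from .errors import ConfigurationError, DomainError, FormatError

_BAND = (0.2, 1.4)  # usable band, THz


@dataclass(frozen=True)
class PulseSpec:
    """Reference-pulse shape and sampling grid.

    The grid step must resolve 1.4 THz content comfortably (step <= 0.25 ps,
    i.e. Nyquist >= 2 THz) and the span must leave room for etalon echoes
    (span >= 20 x width).
    """

    center_time: float = 10.0  # ps
    width: float = 0.25  # ps, characteristic (Gaussian) scale
    amplitude: float = 1.0  # a.u., peak |field|
    t_start: float = 0.0  # ps
    t_stop: float = 80.0  # ps
    dt: float = 0.05  # ps

    def __post_init__(self) -> None:
        if self.dt > 0.25:
            raise ConfigurationError(
                f"grid step {self.dt} ps too coarse for 1.4 THz content (max 0.25 ps)"
            )
        if self.dt <= 0 or self.width <= 0:
            raise ConfigurationError("dt and width must be positive")
        if self.t_stop - self.t_start < 20 * self.width:
            raise ConfigurationError(
                "grid span must be at least 20 x pulse width so echoes fit"
            )

    @property
    def times(self) -> np.ndarray:
        n = int(round((self.t_stop - self.t_start) / self.dt)) + 1
        return self.t_start + self.dt * np.arange(n)


@dataclass(frozen=True)
class MaterialModel:
    """Parametric n(f), alpha(f) of a slab; ground truth for recovery tests.

    ``n(f) = n0 + n_slope * (f - 1 THz)`` (linear dispersion about 1 THz) and
    ``alpha(f) = polyval(alpha_coeffs, f)`` in cm^-1 with f in THz
    (``alpha_coeffs`` ascending, numpy.polynomial convention).  Low-order
    parametric forms suffice because lyophilized-plasma spectra are smooth and
    featureless over 0.2-1.4 THz.
    """

    n0: float = 1.8
    n_slope: float = -0.02  # per THz
    alpha_coeffs: tuple[float, ...] = (0.0, 0.0, 80.0 / 1.4**2)  # cm^-1, ~80 at 1.4 THz

    def __post_init__(self) -> None:
        f = np.linspace(*_BAND, 25)
        if np.any(self.n_of(f) <= 1.0):
            raise DomainError("material must have n(f) > 1 over 0.2-1.4 THz")
        if np.any(self.alpha_cm(f) < 0.0):
            raise DomainError("material must have alpha(f) >= 0 over 0.2-1.4 THz")

    def n_of(self, f: np.ndarray | float) -> np.ndarray | float:
        """Real refractive index at frequency f (THz)."""
        return self.n0 + self.n_slope * (np.asarray(f, dtype=float) - 1.0)

    def alpha_cm(self, f: np.ndarray | float) -> np.ndarray | float:
        """Power absorption coefficient at f (THz), cm^-1."""
        return np.polynomial.polynomial.polyval(
            np.asarray(f, dtype=float), np.asarray(self.alpha_coeffs, dtype=float)
        )

    def group_index(self, f: np.ndarray | float) -> np.ndarray | float:
        """n_g = n + f dn/df; what a pulse-envelope delay actually measures."""
        return self.n_of(f) + self.n_slope * np.asarray(f, dtype=float)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white time-domain noise, quoted as spectral-amplitude SNR at 1 THz."""

    snr_at_1thz: float = 1e3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr_at_1thz <= 0:
            raise ConfigurationError("snr_at_1thz must be positive")


@dataclass(frozen=True)
class MeasurementPair:
    """A reference/sample waveform pair with its generating ground truth."""

    reference: Waveform
    sample: Waveform
    true_material: MaterialModel
    true_thickness: float  # mm
    geometry: PelletGeometry | None = None


def make_reference_pulse(spec: PulseSpec) -> Waveform:
    """Single-cycle reference pulse: first derivative of a Gaussian.

    Normalised so max |amplitude| equals ``spec.amplitude``; the spectral
    amplitude is ~ f exp(-(2 pi f w)^2 / 2), nonzero across 0.2-1.4 THz for
    the default width.
    """
    t = spec.times
    u = (t - spec.center_time) / spec.width
    amp = -spec.amplitude * u * np.exp(0.5 - 0.5 * u**2)
    return Waveform(t, amp, {"channel": "reference"})


def complex_index(m: MaterialModel, f: np.ndarray | float) -> np.ndarray | complex:
    """Complex refractive index n~ = n + i*kappa at frequency f (THz).

    kappa follows from the power absorption coefficient via
    (omega/c) kappa = alpha/2, i.e. kappa = alpha_mm * c / (4 pi f).
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise DomainError("complex_index requires f > 0")
    alpha_mm = np.asarray(m.alpha_cm(f)) / 10.0  # cm^-1 -> mm^-1
    kappa = alpha_mm * C_MM_PS / (4.0 * math.pi * f)
    out = m.n_of(f) + 1j * kappa
    return complex(out) if out.ndim == 0 else out


def transfer_function(
    m: MaterialModel,
    d: float,
    f_grid: np.ndarray,
    n_echoes: int | None = 1,
) -> np.ndarray:
    """Sample/reference field ratio H(f) for a slab of thickness d (mm).

    ``n_echoes`` counts Fabry-Perot echo terms beyond the directly
    transmitted pulse (0 = no echoes); ``None`` sums the full geometric
    series in closed form.
    """
    f = np.asarray(f_grid, dtype=float)
    if np.any(f <= 0) or np.any(f > 5.0):
        raise DomainError("transfer_function requires 0 < f <= 5 THz")
    return _transfer(m, d, f, n_echoes)


def _transfer(
    m: MaterialModel, d: float, f: np.ndarray, n_echoes: int | None
) -> np.ndarray:
    """transfer_function without the instrument-band domain check.

    The simulator evaluates H on the full FFT grid (up to Nyquist), where the
    polynomial alpha(f) drives H smoothly to zero well above the band.
    """
    if d <= 0:
        raise DomainError("thickness d must be positive")
    if n_echoes is not None and n_echoes < 0:
        raise DomainError("n_echoes must be >= 0 (or None for the closed form)")
    nc = complex_index(m, f)
    kd = (2.0 * math.pi * f / C_MM_PS) * nc * d  # k~ d
    fresnel = 4.0 * nc / (nc + 1.0) ** 2
    q = ((nc - 1.0) / (nc + 1.0)) ** 2 * np.exp(2j * kd)
    if n_echoes is None:
        etalon = 1.0 / (1.0 - q)
    else:
        # finite geometric sum; |q| < 1 for any passive slab so this is stable
        etalon = (1.0 - q ** (n_echoes + 1)) / (1.0 - q)
    phase = np.exp(1j * (kd - 2.0 * math.pi * f * d / C_MM_PS))
    return fresnel * etalon * phase


def _transfer_dc(m: MaterialModel, d: float, n_echoes: int | None) -> float:
    """omega -> 0 limit of H; (omega/c)kappa -> alpha/2 keeps it finite."""
    n = float(m.n_of(0.0))
    a0 = float(m.alpha_cm(0.0)) / 10.0  # mm^-1
    r2 = ((n - 1.0) / (n + 1.0)) ** 2
    q = r2 * math.exp(-a0 * d)
    if n_echoes is None:
        etalon = 1.0 / (1.0 - q)
    else:
        etalon = (1.0 - q ** (n_echoes + 1)) / (1.0 - q) if q != 1.0 else n_echoes + 1.0
    return 4.0 * n / (n + 1.0) ** 2 * etalon * math.exp(-a0 * d / 2.0)


def _forward_fft(x: np.ndarray) -> np.ndarray:
    """One-sided forward transform with the e^{+i omega t} kernel."""
    return np.conj(np.fft.rfft(x))


def _inverse_fft(X: np.ndarray, n: int) -> np.ndarray:
    return np.fft.irfft(np.conj(X), n=n)


def simulate_measurement(
    ref: Waveform,
    m: MaterialModel,
    d: float,
    noise: NoiseSpec,
    n_echoes: int = 1,
    geometry: PelletGeometry | None = None,
    echo_margin_ps: float = 3.0,
) -> MeasurementPair:
    """Propagate a reference pulse through a slab and add measurement noise.

    The sample trace is the inverse transform of H(f) * FFT(ref); independent
    white Gaussian noise is then added to both channels, scaled so the
    reference spectral amplitude at 1 THz divided by the RMS noise-floor
    spectral amplitude equals ``noise.snr_at_1thz``.  Deterministic given
    ``noise.seed``.
    """
    if d <= 0:
        raise DomainError("thickness d must be positive")
    t = ref.times
    n_samp = ref.n
    dt = ref.dt
    # every simulated echo (plus a pulse-tail margin) must land on the grid
    t_peak = float(t[int(np.argmax(np.abs(ref.amplitudes)))])
    n_high = float(np.max(m.n_of(np.linspace(*_BAND, 9))))
    t_last = t_peak + (n_high - 1.0) * d / C_MM_PS + n_echoes * 2.0 * n_high * d / C_MM_PS
    if t_last + echo_margin_ps > float(t[-1]):
        raise ConfigurationError(
            f"last echo at ~{t_last:.1f} ps (+{echo_margin_ps} ps margin) falls "
            f"outside the {t[-1]:.1f} ps grid"
        )
    freqs = np.fft.rfftfreq(n_samp, dt)
    spec_ref = _forward_fft(ref.amplitudes)
    h = np.empty_like(spec_ref)
    h[0] = _transfer_dc(m, d, n_echoes)
    h[1:] = _transfer(m, d, freqs[1:], n_echoes)
    clean_sample = _inverse_fft(spec_ref * h, n_samp)

    a1 = float(np.interp(1.0, freqs, np.abs(spec_ref)))
    sigma = a1 / (noise.snr_at_1thz * math.sqrt(n_samp))
    rng = np.random.default_rng(noise.seed)
    sample = clean_sample + rng.normal(0.0, sigma, n_samp)
    reference = ref.amplitudes + rng.normal(0.0, sigma, n_samp)
    tags = {**ref.meta, "seed": str(noise.seed)}
    return MeasurementPair(
        reference=Waveform(t.copy(), reference, {**tags, "channel": "reference"}),
        sample=Waveform(t.copy(), sample, {**tags, "channel": "sample"}),
        true_material=m,
        true_thickness=d,
        geometry=geometry,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Two-class cohort design: geometry sampler plus class contrast.

    ``contrast`` is the relative offset of the density-normalized refractive
    index (n-1)/rho of class B ("diabetic") above class A ("non_diabetic");
    the observed between-class difference of that quantity is the study's
    discriminator.  Geometry defaults span the measured pellet ranges
    (thickness 0.52-1.81 mm, density 1.000-1.358 mg/mm^3, diameter 5 mm).
    """

    n_per_class: int = 15
    diameter_mm: float = 5.0
    thickness_range: tuple[float, float] = (0.52, 1.81)
    density_range: tuple[float, float] = (1.000, 1.358)
    contrast: float = 0.10
    base_nnorm: float = 0.73  # (n-1)/rho of class A at 1 THz
    n_slope: float = -0.02  # per THz
    alpha_norm_coeffs: tuple[float, ...] = (0.0, 0.0, 72.7 / 1.4**2)  # cm^-1 per (mg/mm^3)
    n_echoes: int = 1
    pulse: PulseSpec = field(default_factory=PulseSpec)

    def __post_init__(self) -> None:
        if not (0.0 <= self.contrast <= 0.2):
            raise ConfigurationError("contrast must lie in [0, 0.2]")
        lo, hi = self.thickness_range
        if not (0.5 <= lo <= hi <= 1.9):
            raise ConfigurationError("thickness range must lie within [0.5, 1.9] mm")
        if self.n_per_class < 1:
            raise ConfigurationError("n_per_class must be >= 1")


#: class labels emitted by simulate_cohort, in emission order
COHORT_CLASSES = ("non_diabetic", "diabetic")


def simulate_cohort(spec: CohortSpec, noise: NoiseSpec) -> list[MeasurementPair]:
    """Simulate ``2 * n_per_class`` labelled measurement pairs.

    Class A pellets carry the baseline normalized index, class B pellets the
    baseline scaled by (1 + contrast); each pellet's actual n0 follows from
    its sampled density, and its absorption from the shared normalized
    absorption curve (the two classes are spectroscopically identical in
    alpha/rho, as observed for real pellets).  Reproducible given the seed.
    """
    rng = np.random.default_rng(noise.seed)
    ref = make_reference_pulse(spec.pulse)
    pairs: list[MeasurementPair] = []
    for label, nnorm in zip(
        COHORT_CLASSES, (spec.base_nnorm, spec.base_nnorm * (1.0 + spec.contrast))
    ):
        for _ in range(spec.n_per_class):
            d = float(rng.uniform(*spec.thickness_range))
            rho = float(rng.uniform(*spec.density_range))
            mass = rho * math.pi * spec.diameter_mm**2 / 4.0 * d
            geometry = PelletGeometry(
                diameter_mm=spec.diameter_mm,
                thickness_mm=d,
                mass_mg=mass,
                class_label=label,
            )
            material = MaterialModel(
                n0=1.0 + nnorm * rho,
                n_slope=spec.n_slope,
                alpha_coeffs=tuple(rho * c for c in spec.alpha_norm_coeffs),
            )
            pair_seed = int(rng.integers(0, 2**31 - 1))
            pairs.append(
                simulate_measurement(
                    ref,
                    material,
                    d,
                    replace(noise, seed=pair_seed),
                    n_echoes=spec.n_echoes,
                    geometry=geometry,
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# cohort persistence: a manifest table plus per-pair waveform files

_MANIFEST_COLUMNS = (
    "pair_id",
    "class",
    "diameter_mm",
    "thickness_mm",
    "mass_mg",
    "density_mg_mm3",
    "seed",
    "n0",
    "n_slope",
    "alpha_coeffs",
)


def save_cohort(
    pairs: list[MeasurementPair],
    outdir: str | Path,
    header_meta: dict[str, object] | None = None,
) -> Path:
    """Write a cohort as ``manifest.tsv`` + ``waveforms/<id>_{ref,sam}.txt``.

    The manifest carries each pair's class label, geometry, per-pair noise
    seed (when present in the waveform metadata) and ground-truth material,
    so a run is reproducible bit for bit from the files alone.
    """
    outdir = Path(outdir)
    wavedir = outdir / "waveforms"
    wavedir.mkdir(parents=True, exist_ok=True)
    lines = [f"# {k} = {v}" for k, v in (header_meta or {}).items()]
    lines.append("\t".join(_MANIFEST_COLUMNS))
    for i, pair in enumerate(pairs):
        pid = f"pair_{i:03d}"
        geom = pair.geometry
        if geom is None:
            raise DomainError(f"{pid}: cohort pairs must carry a geometry")
        mat = pair.true_material
        coeffs = ";".join(repr(c) for c in mat.alpha_coeffs)
        lines.append(
            "\t".join(
                [
                    pid,
                    geom.class_label,
                    repr(geom.diameter_mm),
                    repr(geom.thickness_mm),
                    repr(geom.mass_mg),
                    repr(geom.density_mg_mm3),
                    str(pair.sample.meta.get("seed", "")),
                    repr(mat.n0),
                    repr(mat.n_slope),
                    coeffs,
                ]
            )
        )
        for channel, wave in (("ref", pair.reference), ("sam", pair.sample)):
            write_waveform(wave, wavedir / f"{pid}_{channel}.txt")
    manifest = outdir / "manifest.tsv"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


def load_cohort(indir: str | Path) -> list[MeasurementPair]:
    """Read back a cohort written by :func:`save_cohort`."""
    import pandas as pd

    indir = Path(indir)
    manifest = indir / "manifest.tsv"
    if not manifest.exists():
        raise FormatError(f"no manifest.tsv under {indir}")
    df = pd.read_csv(manifest, sep="\t", comment="#")
    missing = set(_MANIFEST_COLUMNS) - {"seed"} - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing column(s): {sorted(missing)}")
    pairs: list[MeasurementPair] = []
    for _, row in df.iterrows():
        pid = str(row["pair_id"])
        waves = {}
        for channel in ("ref", "sam"):
            path = indir / "waveforms" / f"{pid}_{channel}.txt"
            if not path.exists():
                raise FormatError(f"missing waveform file for {pid}: {path.name}")
            waves[channel] = read_waveform(path)
        geometry = PelletGeometry(
            diameter_mm=float(row["diameter_mm"]),
            thickness_mm=float(row["thickness_mm"]),
            mass_mg=float(row["mass_mg"]),
            class_label=str(row["class"]),
        )
        material = MaterialModel(
            n0=float(row["n0"]),
            n_slope=float(row["n_slope"]),
            alpha_coeffs=tuple(
                float(c) for c in str(row["alpha_coeffs"]).split(";") if c
            ),
        )
        pairs.append(
            MeasurementPair(
                reference=waves["ref"],
                sample=waves["sam"],
                true_material=material,
                true_thickness=geometry.thickness_mm,
                geometry=geometry,
            )
        )
    return pairs
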