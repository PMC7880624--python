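"""Shared fixtures: reference pulses, materials, simulated pairs, cohorts."""

import numpy as np
import pytest

from thzpellet import (
    CohortSpec,
    MaterialModel,
    NoiseSpec,
    PulseSpec,
    make_reference_pulse,
    simulate_cohort,
    simulate_measurement,
)
from thzpellet.extraction import ExtractionConfig, pair_spectra

#: interior of the usable band where recovery claims are evaluated, THz
INTERIOR_BAND = (0.3, 1.2)


@pytest.fixture(scope="session")
def ref_pulse():
    return make_reference_pulse(PulseSpec())


@pytest.fixture(scope="session")
def absorbing_material():
    """Non-dispersive slab, quadratic absorption reaching 80 cm^-1 at 1.4 THz."""
    return MaterialModel(n0=1.8, n_slope=0.0, alpha_coeffs=(0.0, 0.0, 80.0 / 1.4**2))


@pytest.fixture(scope="session")
def dispersive_material():
    """Same absorption with a linear index slope of -0.02/THz about 1 THz."""
    return MaterialModel(n0=1.8, n_slope=-0.02, alpha_coeffs=(0.0, 0.0, 80.0 / 1.4**2))


@pytest.fixture(scope="session")
def noiseless_pair(ref_pulse, dispersive_material):
    """Echo-free noiseless measurement of the dispersive slab, d = 1 mm."""
    return simulate_measurement(
        ref_pulse, dispersive_material, 1.0, NoiseSpec(1e12, seed=1), n_echoes=0
    )


@pytest.fixture(scope="session")
def echo_pair(ref_pulse, dispersive_material):
    """Noiseless measurement with one etalon echo, d = 1 mm."""
    return simulate_measurement(
        ref_pulse, dispersive_material, 1.0, NoiseSpec(1e12, seed=1), n_echoes=1
    )


def fixed_geometry_cohort(contrast: float, seed: int, n_per_class: int = 15) -> CohortSpec:
    """Cohort spec with pellet geometry held fixed (noise-only within-class
    variation), isolating the imposed normalized-index contrast."""
    return CohortSpec(
        n_per_class=n_per_class,
        thickness_range=(1.1, 1.1),
        density_range=(1.1, 1.1),
        contrast=contrast,
    )


def cohort_ratio_spectra(spec: CohortSpec, noise: NoiseSpec):
    """Simulate a cohort and return its gated (ref, sample) spectrum pairs + labels."""
    pairs = simulate_cohort(spec, noise)
    config = ExtractionConfig()
    spectra = [pair_spectra(p, config) for p in pairs]
    labels = [p.geometry.class_label for p in pairs]
    return spectra, labels, pairs


def max_rel_n_error_pct(props, material, band=INTERIOR_BAND) -> float:
    """max over band of |n_hat - n_true| / n_true, in percent."""
    f = props.frequencies
    mask = (f >= band[0]) & (f <= band[1])
    n_true = material.n_of(f[mask])
    return float(100.0 * np.max(np.abs(props.n[mask] - n_true) / n_true))
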