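"""Inversion tests: gating, FFT phases, slab equations, thickness, normalization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thzpellet import (
    C_MM_PS,
    MaterialModel,
    NoiseSpec,
    PulseSpec,
    absorption,
    average_spectra,
    compute_spectrum,
    gate_first_pulse,
    make_reference_pulse,
    normalize_properties,
    pellet_density,
    phase_difference,
    refractive_index,
    simulate_measurement,
    thickness_from_echo,
)
from thzpellet.dataio import PelletGeometry, Waveform
from thzpellet.errors import DetectionError, DomainError, FitError
from thzpellet.extraction import (
    ExtractionConfig,
    GateConfig,
    OpticalProperties,
    extract_pipeline,
)

from conftest import INTERIOR_BAND, max_rel_n_error_pct


# ---------------------------------------------------------------------------
# gating


def test_full_span_gate_with_no_taper_is_identity(ref_pulse):
    g = GateConfig(float(ref_pulse.times[0]), float(ref_pulse.times[-1]), 0.0)
    gated = gate_first_pulse(ref_pulse, g)
    assert np.array_equal(gated.amplitudes, ref_pulse.amplitudes)


def test_gate_removes_echo_and_matches_echo_free_extraction(ref_pulse, dispersive_material):
    """Gating 5 ps past the main peak strips the +12 ps echo; the result
    matches extraction of an echo-free simulation of the same slab to 0.5%."""
    with_echo = simulate_measurement(
        ref_pulse, dispersive_material, 1.0, NoiseSpec(1e12, seed=2), n_echoes=1
    )
    t = with_echo.sample.times
    i_main = int(np.argmax(np.abs(with_echo.sample.amplitudes)))
    gate = GateConfig(float(t[0]), float(t[i_main]) + 5.0, 0.1)
    gated = extract_pipeline(with_echo, config=ExtractionConfig(gate=gate))
    no_echo = simulate_measurement(
        ref_pulse, dispersive_material, 1.0, NoiseSpec(1e12, seed=2), n_echoes=0
    )
    plain = extract_pipeline(no_echo, config=ExtractionConfig(apply_gate=False))
    f = gated.frequencies
    mask = (f >= INTERIOR_BAND[0]) & (f <= INTERIOR_BAND[1])
    assert np.max(np.abs(gated.n[mask] - plain.n[mask]) / plain.n[mask]) < 5e-3


def test_inverted_gate_is_a_domain_error():
    with pytest.raises(DomainError):
        GateConfig(10.0, 5.0)


def test_gate_outside_span_is_a_domain_error(ref_pulse):
    with pytest.raises(DomainError, match="outside"):
        gate_first_pulse(ref_pulse, GateConfig(-5.0, 20.0))


def test_gating_is_a_noop_for_echo_free_extraction(ref_pulse, absorbing_material):
    """With no echoes the auto gate only multiplies zeros: results identical.

    (Dispersion-free slab: the toy linear n(f) has a kink at DC that leaves
    ~1e-6 acausal tails, so exact equivalence is checked without it.)"""
    pair = simulate_measurement(
        ref_pulse, absorbing_material, 1.0, NoiseSpec(1e12, seed=1), n_echoes=0
    )
    gated = extract_pipeline(pair, config=ExtractionConfig())
    plain = extract_pipeline(pair, config=ExtractionConfig(apply_gate=False))
    assert np.allclose(gated.n, plain.n, rtol=0, atol=1e-9)
    assert np.allclose(gated.alpha_cm, plain.alpha_cm, rtol=1e-9, atol=1e-8)


# ---------------------------------------------------------------------------
# spectra


def test_pure_delay_adds_positive_linear_phase():
    """FFT of w(t - tau) differs by +2 pi f tau under the e^{+i omega t} kernel."""
    tau = 2.0
    a = make_reference_pulse(PulseSpec(center_time=10.0))
    b = make_reference_pulse(PulseSpec(center_time=10.0 + tau))
    sa, sb = compute_spectrum(a), compute_spectrum(b)
    f = sa.frequencies
    band = (f >= 0.1) & (f <= 1.8)
    dphi = sb.phase[band] - sa.phase[band]
    assert np.allclose(dphi, 2 * math.pi * f[band] * tau, atol=1e-6)


def test_parseval_energy_is_conserved(ref_pulse):
    spec = compute_spectrum(ref_pulse)
    n = ref_pulse.n
    time_energy = np.sum(ref_pulse.amplitudes**2)
    coeffs = spec.amplitude**2
    spec_energy = (coeffs[0] + 2 * coeffs[1:-1].sum() + (coeffs[-1] if n % 2 == 0 else 2 * coeffs[-1])) / n
    assert spec_energy == pytest.approx(time_energy, rel=1e-9)


def test_nonuniform_grid_rejected_by_spectrum():
    t = np.array([0.0, 0.05, 0.11, 0.15, 0.2, 0.25, 0.3, 0.35])
    with pytest.raises((DomainError, Exception)):
        compute_spectrum(Waveform(t, np.zeros(8)))


# ---------------------------------------------------------------------------
# phase difference


def test_identical_spectra_give_zero_phase_difference(ref_pulse):
    s = compute_spectrum(ref_pulse)
    assert np.allclose(phase_difference(s, s), 0.0, atol=1e-12)


def test_known_delay_survives_wrapping_and_correction():
    """A 3 ps delay wraps the raw phase many times; the corrected difference
    is exactly 2 pi f tau."""
    tau = 3.0
    a = make_reference_pulse(PulseSpec(center_time=10.0))
    b = make_reference_pulse(PulseSpec(center_time=10.0 + tau))
    dphi = phase_difference(compute_spectrum(a), compute_spectrum(b))
    f = compute_spectrum(a).frequencies
    band = (f >= 0.2) & (f <= 1.4)
    assert np.allclose(dphi[band], 2 * math.pi * f[band] * tau, atol=1e-6)


def test_global_two_pi_offset_is_removed():
    a = make_reference_pulse(PulseSpec(center_time=10.0))
    b = make_reference_pulse(PulseSpec(center_time=12.0))
    sa, sb = compute_spectrum(a), compute_spectrum(b)
    base = phase_difference(sa, sb)
    sb.phase = sb.phase + 2 * math.pi
    shifted = phase_difference(sa, sb)
    assert np.allclose(base, shifted, atol=1e-12)


def test_too_few_fit_points_is_a_fit_error(ref_pulse):
    s = compute_spectrum(ref_pulse)
    with pytest.raises(FitError):
        phase_difference(s, s, fit_band=(0.50, 0.51))


# ---------------------------------------------------------------------------
# slab equations


def test_zero_phase_difference_means_vacuum():
    assert refractive_index(0.0, 1.0, 1.0) == 1.0


def test_refractive_index_inverts_the_slab_phase():
    """Forward phase (omega/c)(n-1)d for n = 1.8 maps back to n = 1.8."""
    d, f, n = 1.0, 1.0, 1.8
    dphi = 2 * math.pi * f * (n - 1) * d / C_MM_PS
    assert dphi == pytest.approx(16.765, abs=5e-3)
    assert refractive_index(dphi, d, f) == pytest.approx(n, rel=1e-12)


def test_doubling_thickness_halves_n_minus_one():
    dphi = 5.0
    n1 = refractive_index(dphi, 1.0, 0.8)
    n2 = refractive_index(dphi, 2.0, 0.8)
    assert (n2 - 1.0) == pytest.approx((n1 - 1.0) / 2.0, rel=1e-12)


def test_pure_fresnel_loss_means_zero_absorption():
    n = 1.8
    assert absorption(1.0, 4 * n / (n + 1) ** 2, n, 1.0) == pytest.approx(0.0, abs=1e-12)
    assert absorption(0.7, 0.7, 1.0, 2.0) == pytest.approx(0.0, abs=1e-12)


def test_absorption_inverts_the_forward_amplitude_ratio():
    """Amplitudes synthesized with alpha = 40 cm^-1 recover exactly 40."""
    n, d, alpha_cm = 1.8, 1.0, 40.0
    ratio = 4 * n / (n + 1) ** 2 * math.exp(-alpha_cm / 10.0 * d / 2.0)
    assert absorption(1.0, ratio, n, d) == pytest.approx(alpha_cm, abs=1e-9)


def test_nonpositive_amplitude_is_a_domain_error():
    with pytest.raises(DomainError):
        absorption(0.0, 1.0, 1.5, 1.0)


# ---------------------------------------------------------------------------
# thickness from echo


def test_thickness_from_synthetic_ten_picosecond_echo():
    """dt = 10 ps with n_est = 2 -> d = c*10/4 ~ 0.7495 mm."""
    t = np.arange(0.0, 60.0, 0.05)
    main = -(t - 10.0) / 0.25 * np.exp(0.5 - 0.5 * ((t - 10.0) / 0.25) ** 2)
    echo = -(t - 20.0) / 0.25 * np.exp(0.5 - 0.5 * ((t - 20.0) / 0.25) ** 2)
    w = Waveform(t, main + 0.1 * echo)
    d = thickness_from_echo(w, 2.0)
    assert d == pytest.approx(C_MM_PS * 10.0 / 4.0, abs=1e-4)
    assert d == pytest.approx(0.7495, abs=1e-3)


def test_echo_free_trace_raises_detection_error(ref_pulse):
    with pytest.raises(DetectionError):
        thickness_from_echo(ref_pulse, 1.8)


def test_noisy_echo_free_trace_raises_detection_error(ref_pulse, absorbing_material):
    pair = simulate_measurement(
        ref_pulse, absorbing_material, 1.0, NoiseSpec(1e3, seed=4), n_echoes=0
    )
    with pytest.raises(DetectionError, match="noise floor"):
        thickness_from_echo(pair.sample, 1.8)


def test_echo_thickness_accurate_to_three_microns_over_twenty_seeds(
    ref_pulse, absorbing_material
):
    """At SNR 10^3 the echo-based thickness lands within ~3 um of truth on
    average (d = 1.000 mm)."""
    errors = []
    for seed in range(1, 21):
        pair = simulate_measurement(
            ref_pulse, absorbing_material, 1.0, NoiseSpec(1e3, seed=seed), n_echoes=1
        )
        errors.append(abs(thickness_from_echo(pair.sample, 1.8) - 1.0) * 1e3)
    assert np.mean(errors) <= 3.0


# ---------------------------------------------------------------------------
# density and normalization


@pytest.mark.parametrize(
    "mass, diameter, thickness, expected",
    [(13.4, 5.0, 0.52, 1.31), (17.5, 5.0, 0.85, 1.05)],
)
def test_pellet_density_matches_printed_values(mass, diameter, thickness, expected):
    g = PelletGeometry(diameter, thickness, mass, "x")
    assert round(pellet_density(g), 2) == expected


def test_density_identity_for_unit_ratio():
    d, diam = 1.3, 7.0
    g = PelletGeometry(diam, d, math.pi * diam**2 / 4 * d, "x")
    assert pellet_density(g) == pytest.approx(1.0, abs=1e-15)


def _props(n, alpha):
    f = np.linspace(0.2, 1.4, n.size)
    return OpticalProperties(frequencies=f, n=n, alpha_cm=alpha)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    rho=st.floats(min_value=1e-3, max_value=10.0),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_normalization_is_an_exact_bijection(rho, seed):
    """n_norm*rho + 1 == n and alpha_norm*rho == alpha to machine precision."""
    rng = np.random.default_rng(seed)
    p = _props(1.0 + rng.uniform(0.5, 1.5, 16), rng.uniform(0.0, 90.0, 16))
    q = normalize_properties(p, rho)
    assert np.allclose(q.n_norm * rho + 1.0, p.n, rtol=1e-12, atol=1e-12)
    assert np.allclose(q.alpha_norm * rho, p.alpha_cm, rtol=1e-12, atol=1e-12)


def test_unit_density_normalization_is_trivial():
    p = _props(np.full(8, 1.8), np.full(8, 40.0))
    q = normalize_properties(p, 1.0)
    assert np.array_equal(q.n_norm, p.n - 1.0)
    assert np.array_equal(q.alpha_norm, p.alpha_cm)


def test_vacuum_normalizes_to_zero():
    q = normalize_properties(_props(np.ones(8), np.zeros(8)), 2.0)
    assert np.all(q.n_norm == 0.0)


def test_nonpositive_density_is_a_domain_error():
    with pytest.raises(DomainError):
        normalize_properties(_props(np.ones(8), np.zeros(8)), 0.0)


# ---------------------------------------------------------------------------
# averaging


def test_average_of_identical_spectra_has_zero_sd():
    p = _props(np.full(8, 1.8), np.full(8, 40.0))
    stats = average_spectra([p, _props(p.n.copy(), p.alpha_cm.copy())])
    assert np.all(stats.n_sd == 0.0)
    assert stats.count == 2


def test_average_of_shifted_pair_is_midpoint():
    p = _props(np.full(8, 1.8), np.full(8, 40.0))
    q = _props(p.n + 0.2, p.alpha_cm + 4.0)
    stats = average_spectra([p, q])
    assert np.allclose(stats.n_mean, 1.9)
    assert np.allclose(stats.alpha_mean, 42.0)


def test_single_spectrum_average_is_itself_flagged_degenerate():
    p = _props(np.full(8, 1.8), np.full(8, 40.0))
    stats = average_spectra([p])
    assert np.array_equal(stats.n_mean, p.n)
    assert stats.count == 1
    assert np.all(stats.n_sd == 0.0)


def test_mismatched_grids_and_empty_lists_are_domain_errors():
    p = _props(np.full(8, 1.8), np.full(8, 40.0))
    q = _props(np.full(9, 1.8), np.full(9, 40.0))
    with pytest.raises(DomainError):
        average_spectra([p, q])
    with pytest.raises(DomainError):
        average_spectra([])


# ---------------------------------------------------------------------------
# full pipeline


def test_noisy_refraction_error_stays_below_one_percent(ref_pulse, dispersive_material):
    """SNR 10^3, thickness given: max relative n error over the interior band
    is within the 1% claimed for the method."""
    worst = 0.0
    for seed in range(1, 21):
        pair = simulate_measurement(
            ref_pulse, dispersive_material, 1.0, NoiseSpec(1e3, seed=seed), n_echoes=1
        )
        props = extract_pipeline(pair)
        worst = max(worst, max_rel_n_error_pct(props, dispersive_material))
    assert worst <= 1.0


def test_band_configuration_confines_output():
    pair = simulate_measurement(
        make_reference_pulse(PulseSpec()),
        MaterialModel(),
        1.0,
        NoiseSpec(1e3, seed=1),
        n_echoes=0,
    )
    props = extract_pipeline(pair, config=ExtractionConfig(band=(0.5, 1.0)))
    assert props.frequencies.min() >= 0.5
    assert props.frequencies.max() <= 1.0


def test_pipeline_normalizes_against_the_pellet_geometry(ref_pulse, absorbing_material):
    geom = PelletGeometry(5.0, 1.0, math.pi * 5**2 / 4 * 1.0 * 1.1, "diabetic")
    pair = simulate_measurement(
        ref_pulse, absorbing_material, 1.0, NoiseSpec(1e3, seed=8), geometry=geom
    )
    props = extract_pipeline(pair)
    assert props.density_mg_mm3 == pytest.approx(1.1, rel=1e-12)
    assert np.allclose(props.n_norm * 1.1 + 1.0, props.n, rtol=1e-12)


def test_increasing_absorption_strictly_darkens_every_frequency(ref_pulse):
    """Monotone contrast: scaling alpha up lowers A_sam/A_ref at every band
    frequency (noiseless, echo-free)."""
    ratios = []
    for scale in (1.0, 1.3):
        m = MaterialModel(n0=1.8, n_slope=0.0, alpha_coeffs=(0.0, 0.0, scale * 40.0))
        pair = simulate_measurement(ref_pulse, m, 1.0, NoiseSpec(1e12, seed=0), n_echoes=0)
        sr = compute_spectrum(pair.reference)
        ss = compute_spectrum(pair.sample)
        f = sr.frequencies
        band = (f >= 0.2) & (f <= 1.4)
        ratios.append(ss.amplitude[band] / sr.amplitude[band])
    assert np.all(ratios[1] < ratios[0])
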