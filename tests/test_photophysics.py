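"""Unit and property tests for the five-state photophysical model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from riscbleach.photophysics import (
    HC_J_NM,
    Illumination,
    SolverError,
    TripletSpectrum,
    build_generator,
    cross_section_from_molar_absorptivity,
    integrated_emission,
    photon_flux,
    rp_model,
    scan_rp,
    simulate_ensemble_mc,
    simulate_trace,
)

from helpers import (
    bleach_probability,
    fast_test_params,
    photon_budget_rp,
    qss_generator,
)


# ---------------------------------------------------------------- photon flux

@pytest.mark.parametrize(
    "intensity,wavelength",
    [(0.0, 900.0), (32.0, 470.0), (2000.0, 900.0), (1e-3, 750.0)],
)
def test_photon_flux_closed_form(intensity, wavelength):
    """Flux equals I / (hc/lambda), zero iff the intensity is zero."""
    expected = intensity / (6.62607015e-34 * 2.99792458e8 / (wavelength * 1e-9))
    got = photon_flux(intensity, wavelength)
    assert got == pytest.approx(expected, rel=1e-12)
    assert (got == 0) == (intensity == 0)


def test_photon_flux_reference_values():
    assert photon_flux(32, 470) == pytest.approx(7.57e19, rel=1e-3)
    assert photon_flux(2000, 900) == pytest.approx(9.06e21, rel=1e-3)


@pytest.mark.parametrize("bad", [(-1.0, 470.0), (10.0, 0.0), (10.0, -5.0)])
def test_photon_flux_domain_errors(bad):
    with pytest.raises(ValueError):
        photon_flux(*bad)


def test_molar_absorptivity_conversion():
    """sigma = ln(10)*1000*eps/N_A, recomputed independently."""
    eps = 55_900.0
    expected = math.log(10) * 1000 * eps / 6.02214076e23
    assert cross_section_from_molar_absorptivity(eps) == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------- spectrum

def test_spectrum_peak_and_tail():
    sp = TripletSpectrum.synthetic_egfp_like(1e-17)
    peak_wl = sp.wavelengths_nm[np.argmax(sp.relative)]
    assert peak_wl == pytest.approx(900.0, abs=2.0)
    assert sp.cross_section(900.0) == pytest.approx(1e-17, rel=1e-3)
    assert 0 < sp.cross_section(470.0) < 0.05 * sp.cross_section(900.0)


def test_spectrum_out_of_support_errors():
    sp = TripletSpectrum.synthetic_egfp_like(1e-17)
    with pytest.raises(ValueError):
        sp.cross_section(1200.0)


# ---------------------------------------------------------------- generator

def _illum_strategy():
    return st.builds(
        Illumination,
        lambda_vis=st.sampled_from([450.0, 470.0, 517.0]),
        I_vis=st.floats(0.0, 5000.0),
        lambda_nir=st.sampled_from([700.0, 885.0, 900.0, 1000.0]),
        I_nir=st.floats(0.0, 50_000.0),
    )


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    illum=_illum_strategy(),
    phi_isc=st.floats(0.0, 1.0),
    phi_risc=st.floats(0.0, 0.6),
    phi_bn=st.floats(0.0, 0.4),
    k_b1=st.floats(0.0, 100.0),
)
def test_generator_is_a_generator(illum, phi_isc, phi_risc, phi_bn, k_b1):
    """Off-diagonals >= 0, columns sum to zero, bleached column zero."""
    p = fast_test_params(phi_isc=phi_isc, phi_risc=phi_risc, phi_bn=phi_bn, k_b1=k_b1)
    Q = build_generator(p, illum)
    off = Q - np.diag(np.diag(Q))
    assert np.all(off >= 0)
    assert np.allclose(Q.sum(axis=0), 0.0, atol=1e-9 * max(1.0, np.abs(Q).max()))
    assert np.all(Q[:, 4] == 0)


def test_generator_dark_stationary_state():
    """No light: only spontaneous decays; S0 is stationary when k_b1 = 0."""
    p = fast_test_params(k_b1=0.0)
    Q = build_generator(p, Illumination(I_vis=0.0, I_nir=0.0))
    assert Q[1, 0] == 0  # no excitation
    e0 = np.array([1.0, 0, 0, 0, 0])
    assert np.allclose(Q @ e0, 0.0)


def test_generator_no_pumping_reduces_to_three_state():
    """With sigma_T = 0 at the visible line and NIR off, Tn is unreachable."""
    sp = TripletSpectrum(
        np.array([400.0, 600.0, 900.0, 1000.0]),
        np.array([0.0, 0.0, 1.0, 0.5]),
        1e-17,
    )
    p = fast_test_params(sigma_T=sp)
    Q = build_generator(p, Illumination(470.0, 32.0, 900.0, 0.0))
    inflow = Q[3].copy()
    inflow[3] = 0.0  # ignore the diagonal (outflow) entry
    assert np.all(inflow == 0)  # no inflow into Tn: classical 3-state bleaching


def test_generator_wavelength_outside_support_errors():
    p = fast_test_params()
    with pytest.raises(ValueError):
        build_generator(p, Illumination(470.0, 32.0, 1100.0, 100.0))


# ---------------------------------------------------------------- trace

def test_trace_matches_one_shot_matrix_exponential():
    """Stepped propagation equals expm(Q t) @ p0 at every grid point (1e-8 rel)."""
    p = fast_test_params()
    illum = Illumination(470.0, 32.0, 900.0, 50.0)
    t = np.linspace(0.0, 0.5, 101)
    trace, states = simulate_trace(p, illum, t)
    Q = build_generator(p, illum)
    p0 = np.array([1.0, 0, 0, 0, 0])
    for i in (1, 10, 50, 100):
        oracle = expm(Q * t[i]) @ p0
        assert states[i] == pytest.approx(oracle, rel=1e-8, abs=1e-12)


def test_trace_probability_conserved_and_nonnegative(egfp_params, ref_illum):
    t = np.linspace(0.0, 2000.0, 201)
    _, states = simulate_trace(egfp_params, ref_illum, t)
    assert np.abs(states.sum(axis=1) - 1.0).max() < 1e-9
    assert states.min() >= -1e-12


def test_trace_no_sink_reaches_plateau():
    """Without any bleaching channel the signal settles at a constant."""
    p = fast_test_params(k_b1=0.0, phi_bn=0.0)
    t = np.linspace(0.0, 2.0, 101)
    trace, _ = simulate_trace(p, Illumination(470.0, 32.0, 900.0, 100.0), t)
    assert trace.signal[-1] == pytest.approx(trace.signal[50], rel=1e-6)
    assert trace.signal[0] == pytest.approx(1.0)


def test_trace_normalized_to_first_sample(egfp_params, ref_illum):
    t = np.linspace(0.0, 100.0, 51)
    trace, _ = simulate_trace(egfp_params, ref_illum, t)
    assert trace.signal[0] == 1.0
    # decays overall; only the sub-permille RISC-driven rise above the
    # singlet-equilibrated reference is allowed before bleaching takes over
    assert np.all(trace.signal <= 1.0 + 1e-3)
    assert trace.signal[-1] < 0.9 * trace.signal[0]


def test_trace_rejects_bad_grid(egfp_params, ref_illum):
    with pytest.raises(ValueError):
        simulate_trace(egfp_params, ref_illum, np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        simulate_trace(egfp_params, Illumination(I_vis=0.0), np.linspace(0, 1, 10))


def test_full_model_matches_qss_reduction(egfp_params, ref_illum):
    """5-state vs adiabatic 4-state solutions agree within 1% (tau_Tn <= 1 ns)."""
    for illum in (ref_illum, ref_illum.without_nir()):
        t = np.linspace(0.0, 1500.0, 101)
        trace, _ = simulate_trace(egfp_params, illum, t)
        Q4 = qss_generator(egfp_params, illum)
        p0 = np.array([1.0, 0, 0, 0])
        t_norm = min(100.0 * max(egfp_params.tau_S1, egfp_params.tau_Tn), t[1])
        eval_t = np.maximum(t, t_norm)
        s1 = np.array([(expm(Q4 * ti) @ p0)[1] for ti in eval_t])
        oracle = s1 / s1[0]
        assert np.allclose(trace.signal, oracle, rtol=0.01)


def test_ode_matches_gillespie_ensemble():
    """Jump-process MC average within 3 binomial SE of the ODE solution."""
    p = fast_test_params()
    illum = Illumination(470.0, 32.0, 900.0, 50.0)
    t = np.linspace(0.0, 0.2, 9)[1:]  # skip t=0 (deterministic)
    occ, se = simulate_ensemble_mc(p, illum, t, n_molecules=100_000, seed=42)
    Q = build_generator(p, illum)
    p0 = np.array([1.0, 0, 0, 0, 0])
    for i, ti in enumerate(t):
        exact = expm(Q * ti) @ p0
        tol = 3.0 * np.maximum(se[i], 1e-5)
        assert np.all(np.abs(occ[i] - exact) <= tol), (
            f"t={ti}: {occ[i]} vs {exact} (tol {tol})"
        )
        # survival (= 1 - bleached fraction) specifically
        assert abs((1 - occ[i, 4]) - (1 - exact[4])) <= tol[4]


# ---------------------------------------------------------------- emission

def test_emission_zero_without_excitation(egfp_params):
    assert integrated_emission(egfp_params, Illumination(I_vis=0.0)) == 0.0


def test_emission_infinite_window_requires_sink():
    p = fast_test_params(k_b1=0.0, phi_bn=0.0)
    with pytest.raises(ValueError, match="diverges"):
        integrated_emission(p, Illumination(470.0, 32.0))


def test_emission_finite_window_converges_to_infinite(egfp_params, ref_illum):
    """Once the trace has decayed below 1e-4, the finite AUC is within 0.1%."""
    illum = ref_illum.without_nir()
    t_long = 2500.0  # many decay times for the calibrated set
    trace, _ = simulate_trace(egfp_params, illum, np.linspace(0, t_long, 201))
    assert trace.signal[-1] < 1e-4
    e_fin = integrated_emission(egfp_params, illum, window=t_long, n_points=4001)
    e_inf = integrated_emission(egfp_params, illum)
    assert e_fin == pytest.approx(e_inf, rel=1e-3)


def test_emission_linear_in_radiative_yield(egfp_params, ref_illum):
    e1 = integrated_emission(egfp_params, ref_illum)
    e2 = integrated_emission(egfp_params.evolve(phi_f=egfp_params.phi_f / 2), ref_illum)
    assert e1 == pytest.approx(2 * e2, rel=1e-12)


# ---------------------------------------------------------------- RP

def test_rp_is_one_without_nir(egfp_params, ref_illum):
    res = rp_model(egfp_params, ref_illum.without_nir())
    assert res.rp == pytest.approx(1.0, rel=1e-12)
    assert res.rp == pytest.approx(res.auc_with / res.auc_without, rel=1e-12)


def test_rp_null_when_tn_loops_back():
    """phi_risc = phi_bn = 0: NIR pumping is a closed loop back to T1."""
    p = fast_test_params(phi_risc=0.0, phi_bn=0.0)
    res = rp_model(p, Illumination(470.0, 32.0, 900.0, 2000.0))
    assert res.rp == pytest.approx(1.0, rel=1e-9)


def test_rp_mismatched_visible_settings_error(egfp_params):
    with pytest.raises(ValueError):
        rp_model(
            egfp_params,
            Illumination(470.0, 32.0, 900.0, 2000.0),
            Illumination(470.0, 64.0, 900.0, 0.0),
        )


def test_rp_matches_photon_budget_oracle(egfp_params, ref_illum):
    """Transient linear solve equals the closed-form branching-probability RP."""
    for illum in (
        ref_illum,
        Illumination(470.0, 5.0, 900.0, 300.0),
        Illumination(470.0, 200.0, 800.0, 1000.0),
    ):
        assert rp_model(egfp_params, illum).rp == pytest.approx(
            photon_budget_rp(egfp_params, illum), rel=1e-9
        )
    p = fast_test_params()
    illum = Illumination(470.0, 32.0, 900.0, 100.0)
    assert rp_model(p, illum).rp == pytest.approx(photon_budget_rp(p, illum), rel=1e-9)


def test_rp_invariant_to_fluorescence_yield(egfp_params, ref_illum):
    rp1 = rp_model(egfp_params, ref_illum).rp
    rp2 = rp_model(egfp_params.evolve(phi_f=0.21), ref_illum).rp
    assert rp1 == pytest.approx(rp2, rel=1e-12)


# ---------------------------------------------------------------- scans

def test_scan_rp_monotone_and_saturating(egfp_params, ref_illum):
    """RP(0) = 1, non-decreasing in I_nir, bounded by the branching limit."""
    grid = [0.0, 100.0, 500.0, 1000.0, 2000.0, 5000.0, 20_000.0, 100_000.0]
    table = scan_rp(egfp_params, I_nir_values=grid, base=ref_illum)
    rp = table["rp"].to_numpy()
    assert rp[0] == pytest.approx(1.0, rel=1e-12)
    assert np.all(np.diff(rp) >= -1e-12)
    # saturation bound: P_B(no NIR) / (phi_bn / (phi_risc + phi_bn))
    p = egfp_params
    bound = bleach_probability(p, ref_illum.without_nir()) / (
        p.phi_bn / (p.phi_risc + p.phi_bn)
    )
    assert rp[-1] <= bound * (1 + 1e-9)
    assert rp[-1] >= 0.98 * rp[-2]  # approaching an asymptote


def test_scan_action_spectrum_tracks_triplet_spectrum(egfp_params, ref_illum):
    """(RP(lambda) - 1) is proportional to sigma_T(lambda) at low NIR dose.

    First-order perturbation: the T1 -> Tn pumping rate is
    sigma_T(lambda) times the photon flux, so the scan holds the photon
    flux (not the irradiance) constant across wavelengths.
    """
    lambdas = np.arange(700.0, 1001.0, 20.0)
    flux0 = photon_flux(0.5, 850.0)
    rp = np.array([
        rp_model(
            egfp_params,
            Illumination(470.0, 32.0, l, flux0 * HC_J_NM / l),
        ).rp
        for l in lambdas
    ])
    sigma = np.array([egfp_params.sigma_T.cross_section(l) for l in lambdas])
    r = np.corrcoef(rp - 1.0, sigma)[0, 1]
    assert r > 0.999


def test_scan_visible_turnover(egfp_params, ref_illum):
    """At 2 kW/cm2 NIR the RP maximum sits at low visible intensity and
    the curve decreases beyond ~100 W/cm2, approaching 1 at high I_vis."""
    I_vis = np.array([1.0, 5.0, 20.0, 50.0, 100.0, 300.0, 1000.0, 5000.0])
    table = scan_rp(egfp_params, I_vis_values=I_vis, base=ref_illum)
    rp = table.sort_values("I_vis_W_cm2")["rp"].to_numpy()
    assert I_vis[int(np.argmax(rp))] <= 100.0
    assert rp[-1] < rp[4]  # decreased beyond the turnover
    assert rp[-1] < 1.5  # visible pumping alone erases the NIR advantage


def test_solver_failure_reports_stiffness():
    """A non-conservative propagation fails loudly and names the stiffness ratio."""
    from riscbleach.photophysics import _propagate

    Q = np.diag([-1e9, -1.0, -1e-3, -1.0, 0.0])  # leaks probability: not a generator
    with pytest.raises(SolverError, match="stiffness"):
        _propagate(Q, np.linspace(0.0, 1.0, 5)[1:])
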