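"""Spatial plasticity kernel construction and its spectrum."""

import numpy as np
import pytest

from wavestdp.kernels import BurstProfile, EPSPKernel, STDPRule, stdp_integral, stdp_sample
from wavestdp.theory import (
    build_kappa,
    conjugation_check,
    iwi_critical,
    periodic_spectrum,
    phase_landscape,
    predict_k_star,
    spectrum,
    theoretical_robustness,
)

RES = 0.002  # mm; coarse grid for fast tests (k* moves < 1% vs 0.6 um)


def analytic_re_kappa(k, rule, burst, epsp, v):
    """Independent oracle: closed-form Fourier transforms of each factor,
    evaluated at temporal frequency f = v k."""
    f = v * np.asarray(k)
    w = 2j * np.pi * f
    if rule.shape == "asymmetric":
        K = rule.A_plus * rule.tau_plus / (1 - w * rule.tau_plus) - (
            rule.A_minus * rule.tau_minus / (1 + w * rule.tau_minus)
        )
    else:
        K = np.sqrt(2 * np.pi) * (
            rule.A_plus * rule.tau_plus * np.exp(-2 * (np.pi * f * rule.tau_plus) ** 2)
            - rule.A_minus * rule.tau_minus * np.exp(-2 * (np.pi * f * rule.tau_minus) ** 2)
        )
    out = K
    if burst is not None:
        out = out * np.sinc(f * burst.duration) ** 2
    if epsp is not None:
        out = out / ((1 + w * epsp.tau_d) * (1 + w * epsp.tau_r))
    return out.real


class TestBuildKappa:
    def test_delta_burst_and_epsp_reduces_to_bare_rule(self, asym_rule):
        kern = build_kappa(asym_rule, None, None, 3.0, resolution=RES)
        expect = np.asarray(stdp_sample(asym_rule, kern.x / 3.0)) / 3.0
        assert np.allclose(kern.values, expect)

    def test_kernel_support_about_one_mm(self, asym_rule, boxcar_burst, epsp):
        # v = 3 mm/s with a 0.1 s burst spreads the rule over ~1 mm
        kern = build_kappa(asym_rule, boxcar_burst, epsp, 3.0, resolution=RES)
        amax = np.max(np.abs(kern.values))
        support = kern.x[np.abs(kern.values) > 0.01 * amax]
        width = support.max() - support.min()
        assert 0.7 < width < 1.8

    def test_reversed_wave_mirrors_kernel(self, asym_rule, boxcar_burst, epsp):
        fwd = build_kappa(asym_rule, boxcar_burst, epsp, 3.0, resolution=RES)
        bwd = build_kappa(asym_rule, boxcar_burst, epsp, -3.0, resolution=RES)
        assert np.allclose(fwd.values, bwd.values[::-1], atol=1e-12)

    def test_epsp_resolution_guard(self, asym_rule, boxcar_burst, epsp):
        with pytest.raises(ValueError):
            build_kappa(asym_rule, boxcar_burst, epsp, 0.1, resolution=0.01)


class TestSpectrum:
    def test_matches_analytic_transform(self, asym_rule, boxcar_burst, epsp):
        sp = spectrum(build_kappa(asym_rule, boxcar_burst, epsp, 3.0, resolution=RES))
        sel = sp.k < 5.0
        expect = analytic_re_kappa(sp.k[sel], asym_rule, boxcar_burst, epsp, 3.0)
        assert np.allclose(sp.re[sel], expect, atol=2e-3 * np.max(np.abs(expect)))

    def test_delta_case_matches_exponential_lobe_transform(self, asym_rule):
        sp = spectrum(build_kappa(asym_rule, None, None, 3.0, resolution=RES))
        sel = sp.k < 5.0
        expect = analytic_re_kappa(sp.k[sel], asym_rule, None, None, 3.0)
        assert np.allclose(sp.re[sel], expect, atol=2e-3 * np.max(np.abs(expect)))

    def test_dc_equals_stdp_integral(self, asym_rule, boxcar_burst, epsp):
        sp = spectrum(build_kappa(asym_rule, boxcar_burst, epsp, 4.0, resolution=RES))
        assert sp.re[0] == pytest.approx(stdp_integral(asym_rule), rel=2e-3)

    def test_parseval(self, asym_rule, boxcar_burst, epsp):
        kern = build_kappa(asym_rule, boxcar_burst, epsp, 3.0, resolution=RES)
        sp = spectrum(kern)
        # one-sided sum doubled, DC and Nyquist once
        spec_power = (2 * np.sum(np.abs(sp.re[1:-1] + 1j * sp.im[1:-1]) ** 2)
                      + np.abs(sp.re[0]) ** 2 + np.abs(sp.re[-1] + 1j * sp.im[-1]) ** 2)
        dk = sp.k[1] - sp.k[0]
        real_power = np.sum(kern.values**2) * kern.dx
        assert spec_power * dk == pytest.approx(real_power, rel=1e-6)

    def test_kstar_halves_when_speed_doubles_delta_burst(self, asym_rule):
        k1 = spectrum(build_kappa(asym_rule, None, None, 2.0, resolution=RES)).k_star
        k2 = spectrum(build_kappa(asym_rule, None, None, 4.0, resolution=RES)).k_star
        assert k1 / k2 == pytest.approx(2.0, rel=1e-3)

    def test_symmetric_rule_spectrum_is_real(self, sym_rule, boxcar_burst, epsp):
        # exactly even kernel (delta EPSP): strictly real spectrum
        sp = spectrum(build_kappa(sym_rule, boxcar_burst, None, 3.0, resolution=RES))
        assert np.max(np.abs(sp.im)) < 1e-9 * np.max(np.abs(sp.re))
        # the causal EPSP adds only a small odd component
        sp2 = spectrum(build_kappa(sym_rule, boxcar_burst, epsp, 3.0, resolution=RES))
        assert np.max(np.abs(sp2.im)) < 0.25 * np.max(np.abs(sp2.re))

    def test_grid_refinement_stability(self, asym_rule, boxcar_burst, epsp):
        k_coarse = predict_k_star(asym_rule, boxcar_burst, epsp, 3.0, resolution=RES)
        k_fine = predict_k_star(asym_rule, boxcar_burst, epsp, 3.0, resolution=RES / 2)
        assert abs(k_fine - k_coarse) / k_coarse < 0.01

    def test_all_zero_kernel_rejected(self, asym_rule):
        kern = build_kappa(asym_rule, None, None, 3.0, resolution=RES)
        kern.values[:] = 0.0
        with pytest.raises(ValueError):
            spectrum(kern)


class TestConjugation:
    def test_opposite_speeds_conjugate(self, asym_rule, boxcar_burst, epsp):
        fwd = build_kappa(asym_rule, boxcar_burst, epsp, 3.0, resolution=RES)
        bwd = build_kappa(asym_rule, boxcar_burst, epsp, -3.0, resolution=RES)
        assert conjugation_check(fwd, bwd)

    def test_mismatched_rules_fail(self, asym_rule, boxcar_burst, epsp):
        fwd = build_kappa(asym_rule, boxcar_burst, epsp, 3.0, resolution=RES)
        other = STDPRule.asymmetric(tau_plus=0.03)
        bwd = build_kappa(other, boxcar_burst, epsp, -3.0, resolution=RES)
        assert not conjugation_check(fwd, bwd)

    def test_grid_mismatch_raises(self, asym_rule, boxcar_burst, epsp):
        fwd = build_kappa(asym_rule, boxcar_burst, epsp, 3.0, resolution=RES)
        bwd = build_kappa(asym_rule, boxcar_burst, epsp, -3.0, resolution=RES / 2)
        with pytest.raises(ValueError):
            conjugation_check(fwd, bwd)


class TestPeriodicWaves:
    def test_single_tooth_equals_isolated_wave(self, asym_rule, boxcar_burst, epsp):
        iso = spectrum(build_kappa(asym_rule, boxcar_burst, epsp, 4.0, resolution=RES))
        per = periodic_spectrum(asym_rule, boxcar_burst, epsp, 4.0, iwi=1.0, n_waves=1, resolution=RES)
        assert per.k_star == pytest.approx(iso.k_star)

    def test_short_iwi_raises_dominant_frequency(self, asym_rule, boxcar_burst):
        # comb teeth at multiples of 1/(v*iwi) push k* above the isolated value
        iso = spectrum(build_kappa(asym_rule, boxcar_burst, None, 4.0, resolution=RES))
        per = periodic_spectrum(
            asym_rule, boxcar_burst, None, 4.0, iwi=0.15, n_waves=16, resolution=RES
        )
        assert per.k_star > iso.k_star
        assert per.k_star == pytest.approx(1.0 / (4.0 * 0.15), rel=0.1)

    def test_iwi_shorter_than_burst_rejected(self, asym_rule, boxcar_burst, epsp):
        with pytest.raises(ValueError):
            periodic_spectrum(asym_rule, boxcar_burst, epsp, 4.0, iwi=0.05, n_waves=4)

    def test_critical_interval(self):
        assert iwi_critical(4.0, 0.905) == pytest.approx(0.276, abs=0.01)


class TestPhaseLandscape:
    def test_scaling_regime(self, boxcar_burst):
        """Scaling either v or tau+/- by f scales k* by 1/f when tau+ > d."""
        tmpl = lambda tp: STDPRule.asymmetric(tau_plus=tp)
        burst = BurstProfile("boxcar", 50.0, 0.02)  # short burst so tau+ > d
        grid = phase_landscape(tmpl, burst, None, [2.0, 4.0], [0.05, 0.1], resolution=RES)
        assert grid[1, 0] == pytest.approx(grid[0, 0] / 2.0, rel=0.02)  # v scaled
        assert grid[0, 1] == pytest.approx(grid[0, 0] / 2.0, rel=0.02)  # tau scaled

    def test_landscape_monotone_in_speed(self, boxcar_burst, epsp):
        tmpl = lambda tp: STDPRule.asymmetric(tau_plus=tp)
        grid = phase_landscape(tmpl, boxcar_burst, epsp, [1.0, 3.0, 9.0], [0.02])
        assert grid[0, 0] > grid[1, 0] > grid[2, 0]


class TestTheoreticalRobustness:
    def test_two_bin_spectrum_gives_half(self, asym_rule):
        kern = build_kappa(asym_rule, None, None, 3.0, resolution=RES)
        sp = spectrum(kern)
        sp.re[:] = 0.0
        sp.im[:] = 0.0
        i = 50
        sp.re[i] = 2.5  # one +/-k pair holds all power; one side = half
        sp.k_star = sp.k[i]
        assert theoretical_robustness(sp) == pytest.approx(0.5)

    def test_burst_duration_profile(self, epsp):
        """Concentration of spectral power at k* peaks for bursts of
        0.1-0.5 s and collapses for bursts of a second or more."""
        rule = STDPRule.asymmetric()
        v = 3.0
        durations = [0.03, 0.1, 0.3, 0.5, 1.0, 3.0]
        psis = []
        for d in durations:
            sp = spectrum(
                build_kappa(rule, BurstProfile("boxcar", 50.0, d), epsp, v, resolution=RES)
            )
            psis.append(theoretical_robustness(sp))
        ref = psis[1]
        rel = np.array(psis) / ref
        assert max(rel[1:4]) == max(rel)  # peak within 0.1-0.5 s
        assert rel[durations.index(3.0)] < 0.5 * max(rel)
        assert rel[durations.index(0.03)] < max(rel)

    def test_wider_rule_stays_robust_at_long_bursts(self, epsp):
        psi = {}
        for tp in (0.02, 0.05):
            rule = STDPRule.asymmetric(tau_plus=tp)
            vals = []
            for d in (0.1, 1.5):
                sp = spectrum(
                    build_kappa(rule, BurstProfile("boxcar", 50.0, d), epsp, 3.0, resolution=RES)
                )
                vals.append(theoretical_robustness(sp))
            psi[tp] = vals[1] / vals[0]  # long-burst robustness, referenced
        assert psi[0.05] > psi[0.02]
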