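"""Spiking feedforward simulation: output models, online STDP, invariants."""

import numpy as np
import pytest

from wavestdp.kernels import BurstProfile, EPSPKernel, STDPRule, eval_stdp
from wavestdp.meanfield import ArborSpec
from wavestdp.netsim import (
    OutputNeuronConfig,
    PlasticityConfig,
    apply_stdp,
    lif_membrane,
    output_rate_linear,
    run_simulation,
)
from wavestdp.analysis import dominant_frequency
from wavestdp.theory import build_kappa, spectrum
from wavestdp.wavegen import InputLayer, build_schedule, spikes_from_schedule


def make_raster(layer, n_waves, v=3.0, seed=1, **kw):
    sched = build_schedule(layer, n_waves, speed=v, seed=seed, **kw)
    return spikes_from_schedule(layer, sched, BurstProfile("boxcar", 50.0, 0.1), seed=seed + 1)


class TestOutputModels:
    def test_no_epsps_no_rate(self):
        w = np.full(10, 0.5)
        assert output_rate_linear(w, np.array([], dtype=int), np.array([]), 100.0) == 0.0

    def test_single_spike_rate_integrates_to_gain(self, epsp):
        # unit-integral EPSP at w = 1: integral of lambda equals R_out
        w = np.ones(1)
        t = np.linspace(0, 0.1, 100001)
        lam = np.array([
            output_rate_linear(w, np.array([0]), np.array([tt]), 70.0, epsp) for tt in t[:: 100]
        ])
        integral = np.trapezoid(lam, t[::100])
        assert integral == pytest.approx(70.0, rel=1e-3)

    def test_rate_linear_in_weights(self, epsp):
        nrn = np.array([0, 1, 1])
        el = np.array([0.002, 0.004, 0.009])
        w = np.array([0.3, 0.6])
        r1 = output_rate_linear(w, nrn, el, 50.0, epsp)
        r2 = output_rate_linear(2 * w, nrn, el, 50.0, epsp)
        assert r2 == pytest.approx(2 * r1)

    def test_negative_weight_rejected(self, epsp):
        with pytest.raises(ValueError):
            output_rate_linear(np.array([-0.1]), np.array([0]), np.array([0.01]), 50.0, epsp)

    def test_lif_absolute_refractory_blocks_spikes(self):
        assert lif_membrane(0.001, 1e9, theta=1.0) == -np.inf
        # just after the absolute period the reset current still suppresses
        u = lif_membrane(0.0025, 0.0, theta=1.0)
        assert u < 0

    def test_lif_threshold_strict(self):
        u = lif_membrane(np.inf, 1.0, theta=1.0)
        assert u == 1.0  # equality at threshold must NOT spike (strict >)


class TestApplySTDP:
    def test_single_pair_potentiation(self, asym_rule):
        """Pre 10 ms before post changes the synapse by eta * A+ e^{-1/2}."""
        plast = PlasticityConfig(asym_rule, eta=1e-3)
        w = np.full(3, 0.5)
        w2 = apply_stdp(w, ("out", 0, 0.01), [(1, 0.0)], [], plast)
        assert w2[1] == pytest.approx(0.5 + 1e-3 * np.exp(-0.01 / 0.02))
        assert w2[0] == 0.5 and w2[2] == 0.5

    def test_hard_upper_bound(self, asym_rule):
        plast = PlasticityConfig(asym_rule, eta=0.5)
        w = np.array([1.0])
        w2 = apply_stdp(w, ("out", 0, 0.01), [(0, 0.0)], [], plast)
        assert w2[0] == 1.0

    def test_pairing_window_cutoff(self, asym_rule):
        plast = PlasticityConfig(asym_rule, eta=1e-3)
        w = np.array([0.5])
        dt_outside = 5 * asym_rule.tau_minus + 0.01
        w2 = apply_stdp(w, ("in", 0, dt_outside), [], [0.0], plast)
        assert w2[0] == 0.5

    def test_arbor_blocks_updates(self, asym_rule):
        plast = PlasticityConfig(asym_rule, eta=1e-3)
        w = np.array([0.5, 0.5])
        mask = np.array([True, False])
        w2 = apply_stdp(w, ("out", 0, 0.01), [(1, 0.0)], [], plast, arbor_mask=mask)
        assert w2[1] == 0.5


class TestRunSimulation:
    def test_null_plasticity_control(self):
        layer = InputLayer(1, 100, 0.02)
        raster = make_raster(layer, 5)
        res = run_simulation(
            layer, raster, OutputNeuronConfig(),
            PlasticityConfig(STDPRule.asymmetric(), eta=0.0), seed=0,
        )
        assert np.all(res.weights.w == 0.5)
        assert res.calibration["n_out_spikes"] > 0

    def test_weight_bounds_all_snapshots(self):
        layer = InputLayer(1, 150, 0.02)
        raster = make_raster(layer, 40)
        res = run_simulation(
            layer, raster, OutputNeuronConfig(),
            PlasticityConfig(STDPRule.asymmetric(), eta=0.02),
            seed=0, snapshot_every=20.0,
        )
        for _, w in res.weights.history:
            assert w.min() >= 0.0 and w.max() <= 1.0

    def test_arbor_weights_stay_zero_outside(self):
        layer = InputLayer(1, 200, 0.02)
        raster = make_raster(layer, 30, v=4.0)
        arbor = ArborSpec(0.0, 0.6)
        res = run_simulation(
            layer, raster, OutputNeuronConfig(),
            PlasticityConfig(STDPRule.asymmetric(A_minus=0.55), eta=5e-3),
            init_mode="rf_block", rf0=0.8, arbor=arbor, seed=0,
        )
        outside = np.abs(layer.positions) > 0.6
        assert np.all(res.weights.w[outside] == 0.0)

    def test_output_rate_calibrated_to_realistic_range(self):
        layer = InputLayer(1, 200, 0.02)
        raster = make_raster(layer, 10)
        res = run_simulation(
            layer, raster, OutputNeuronConfig(model="linear", target_rate=40.0),
            PlasticityConfig(STDPRule.asymmetric(), eta=0.0), seed=0,
        )
        # rate during wave passages (waves occupy ~2/8.4 of the run)
        active_frac = 0.35
        rate = res.calibration["n_out_spikes"] / (raster.duration * active_frac)
        assert 10.0 < rate < 100.0

    def test_periodic_pattern_emerges_near_prediction(self):
        layer = InputLayer(1, 500, 0.02)
        raster = make_raster(layer, 300, v=3.0)
        res = run_simulation(
            layer, raster, OutputNeuronConfig(),
            PlasticityConfig(STDPRule.asymmetric(), eta=5e-3), seed=0,
        )
        fit = dominant_frequency(res.weights.w, 0.02)
        k_star = spectrum(
            build_kappa(STDPRule.asymmetric(), BurstProfile("boxcar", 50.0, 0.1),
                        EPSPKernel(), 3.0, resolution=0.002)
        ).k_star
        assert fit.dominant_k == pytest.approx(k_star, rel=0.35)
        assert np.mean((res.weights.w < 0.1) | (res.weights.w > 0.9)) > 0.3

    def test_lif_and_linear_share_frequency_trend(self):
        """Both output models produce patterns whose frequency falls as the
        pairing window widens (reduced-scale parity check)."""
        layer = InputLayer(1, 300, 0.02)
        freqs = {}
        for model in ("linear", "lif"):
            for tp in (0.02, 0.05):
                raster = make_raster(layer, 250, v=3.0, seed=11)
                res = run_simulation(
                    layer, raster, OutputNeuronConfig(model=model),
                    PlasticityConfig(STDPRule.asymmetric(tau_plus=tp), eta=5e-3),
                    seed=7,
                )
                freqs[(model, tp)] = dominant_frequency(res.weights.w, 0.02).dominant_k
        assert freqs[("linear", 0.02)] > freqs[("linear", 0.05)]
        assert freqs[("lif", 0.02)] > freqs[("lif", 0.05)]
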