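"""Single-node dynamics, integrator contracts and frequency estimation."""

import numpy as np
import pytest
from scipy import signal as sps

from perturbscape.hopf import (
    Connectome,
    DimensionMismatchError,
    Forcing,
    HopfParams,
    SimulatedSignals,
    SimulationConfig,
    SimulationDivergedError,
    estimate_natural_frequencies,
    integrate_hopf,
)

TWO_NODES = Connectome(np.zeros((2, 2)))


def _single_node(a, omega=2 * np.pi * 0.05, beta=0.0, **cfg):
    params = HopfParams(a=[a, a], omega=[omega, omega], G=0.0, beta=beta)
    return integrate_hopf(params, TWO_NODES, SimulationConfig(**cfg))


class TestSingleNodeDynamics:
    def test_subcritical_decay_to_fixed_point(self):
        sig = _single_node(-0.2, duration=200.0, transient=0.0, seed=1)
        final = np.abs(sig.x[:, -1] + 1j * sig.y[:, -1])
        assert final.max() < 1e-3

    def test_subcritical_amplitude_nonincreasing(self):
        sig = _single_node(-0.1, duration=300.0, transient=50.0, seed=2)
        r = np.hypot(sig.x[0], sig.y[0])
        assert np.all(np.diff(r) <= 1e-12)

    def test_limit_cycle_radius_and_frequency(self):
        # finer step for the noiseless accuracy check: explicit Euler at
        # dt=0.1 carries a known radius bias ~ dt*omega^2/2
        sig = _single_node(0.09, dt=0.02, duration=600.0, transient=200.0, seed=3)
        radius = np.hypot(sig.x, sig.y).mean()
        assert radius == pytest.approx(np.sqrt(0.09), rel=0.02)
        freqs, power = sps.periodogram(sig.x[0], fs=1.0 / sig.sampling_interval)
        assert freqs[np.argmax(power)] == pytest.approx(0.05, rel=0.01)

    def test_halving_dt_changes_radius_below_one_percent(self):
        radii = []
        for dt in (0.05, 0.025):
            sig = _single_node(0.09, dt=dt, duration=600.0, transient=200.0, seed=4)
            radii.append(np.hypot(sig.x, sig.y).mean())
        assert abs(radii[1] - radii[0]) / radii[0] < 0.01


class TestIntegratorContracts:
    def test_identical_seed_identical_output(self, world20):
        params = HopfParams(a=np.zeros(20), omega=world20["omega"], G=0.5)
        cfg = SimulationConfig(duration=120.0, transient=10.0, seed=11)
        a = integrate_hopf(params, world20["conn"], cfg)
        b = integrate_hopf(params, world20["conn"], cfg)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)

    def test_zero_amplitude_forcing_bitwise_identical(self, world20):
        params = HopfParams(a=np.zeros(20), omega=world20["omega"], G=0.5)
        cfg = SimulationConfig(duration=120.0, transient=10.0, seed=12)
        plain = integrate_hopf(params, world20["conn"], cfg)
        forced = integrate_hopf(
            params,
            world20["conn"],
            cfg,
            Forcing(amplitude=np.zeros(20), omega0=world20["omega"]),
        )
        np.testing.assert_array_equal(plain.x, forced.x)

    def test_output_length_and_finiteness(self, world20):
        cfg = SimulationConfig(duration=100.0, transient=20.0, seed=5)
        params = HopfParams(a=np.zeros(20), omega=world20["omega"], G=0.5)
        sig = integrate_hopf(params, world20["conn"], cfg)
        assert sig.n_samples == int(np.floor((100.0 - 20.0) / 0.1))
        assert np.all(np.isfinite(sig.x)) and np.all(np.isfinite(sig.y))

    def test_exchange_symmetry_of_equivalent_nodes(self):
        # nodes 0 and 1 are structurally equivalent in a symmetric 4-node motif
        w = np.array(
            [
                [0.0, 0.1, 0.2, 0.2],
                [0.1, 0.0, 0.2, 0.2],
                [0.2, 0.2, 0.0, 0.1],
                [0.2, 0.2, 0.1, 0.0],
            ]
        )
        conn = Connectome(w)
        omega = np.full(4, 2 * np.pi * 0.05)
        params = HopfParams(a=np.full(4, 0.05), omega=omega, G=0.5, beta=0.0)
        z0 = np.array([0.05 + 0.02j, -0.03 + 0.01j, 0.02 - 0.04j, 0.06 + 0.0j])
        swapped = z0[[1, 0, 2, 3]]
        out = integrate_hopf(params, conn, SimulationConfig(duration=60.0, transient=0.0, initial_state=z0))
        out_sw = integrate_hopf(
            params, conn, SimulationConfig(duration=60.0, transient=0.0, initial_state=swapped)
        )
        np.testing.assert_allclose(out.x[[1, 0, 2, 3]], out_sw.x, atol=1e-12)

    def test_dimension_mismatch_raises(self, world20):
        params = HopfParams(a=np.zeros(10), omega=np.full(10, 0.3), G=0.5)
        with pytest.raises(DimensionMismatchError):
            integrate_hopf(params, world20["conn"], SimulationConfig(duration=30.0, transient=0.0))

    def test_divergence_reports_step_and_region(self):
        params = HopfParams(a=[5.0, 5.0], omega=[0.3, 0.3], G=0.0, beta=0.0)
        cfg = SimulationConfig(duration=50.0, transient=0.0, initial_state=np.array([30 + 0j, 0.1 + 0j]))
        with pytest.raises(SimulationDivergedError, match="step"):
            integrate_hopf(params, TWO_NODES, cfg)


class TestConnectome:
    def test_from_weights_rescales_to_max(self):
        rng = np.random.default_rng(0)
        raw = np.abs(rng.standard_normal((6, 6)))
        conn = Connectome.from_weights(raw)
        assert conn.weights.max() == pytest.approx(0.2, abs=1e-15)
        assert np.all(np.diag(conn.weights) == 0)
        np.testing.assert_array_equal(conn.weights, conn.weights.T)

    def test_odd_region_count_rejected_for_auto_pairing(self):
        with pytest.raises(ValueError, match="even"):
            Connectome(np.zeros((3, 3)))

    def test_asymmetric_weights_rejected(self):
        w = np.zeros((4, 4))
        w[0, 1] = 0.1
        with pytest.raises(ValueError, match="symmetric"):
            Connectome(w)


class TestNaturalFrequencies:
    def test_pure_sinusoid_peak_within_one_bin(self):
        t = np.arange(512) * 2.0
        series = np.sin(2 * np.pi * 0.05 * t)[None, :]
        omega = estimate_natural_frequencies(series, 2.0)
        bin_width = 1.0 / (512 * 2.0)
        assert abs(omega[0] / (2 * np.pi) - 0.05) <= bin_width

    def test_band_restriction_picks_in_band_component(self):
        t = np.arange(1024) * 2.0
        series = (2.0 * np.sin(2 * np.pi * 0.02 * t) + np.sin(2 * np.pi * 0.06 * t))[None, :]
        omega = estimate_natural_frequencies(series, 2.0)
        bin_width = 1.0 / (1024 * 2.0)
        assert abs(omega[0] / (2 * np.pi) - 0.06) <= bin_width

    def test_estimates_lie_inside_requested_band(self, world20):
        params = HopfParams(a=np.full(20, 0.05), omega=world20["omega"], G=0.5)
        sig = integrate_hopf(params, world20["conn"], SimulationConfig(duration=400.0, transient=20.0, seed=8))
        omega = estimate_natural_frequencies(sig.x[:, ::20], 2.0, band=(0.04, 0.07))
        f = omega / (2 * np.pi)
        assert np.all((f >= 0.04) & (f <= 0.07))

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            estimate_natural_frequencies(np.random.default_rng(0).standard_normal((2, 128)), 2.0, band=(0.1, 0.3))

    def test_flat_signal_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            estimate_natural_frequencies(np.ones((1, 128)), 2.0)
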