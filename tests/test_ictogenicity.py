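"""Theta-network dynamics, BNI curves, normalization, calibration, resection."""

import numpy as np
import pytest
from scipy import stats

import ictonet as ic
from ictonet.errors import (
    CalibrationError,
    DegenerateTimecourseError,
    GridExhaustedError,
    InvalidParameterError,
    InvalidResectionError,
    NoFixedPointError,
)

FAST = dict(n_steps=50_000)


def random_network(n, density, weight, seed):
    rng = np.random.default_rng(seed)
    a = (rng.random((n, n)) < density).astype(float) * weight
    a = np.triu(a, 1)
    return a + a.T


class TestSteadyState:
    def test_closed_form_values(self):
        assert ic.theta_steady_state(-1.2) == pytest.approx(
            -np.arccos(-1.0 / 11.0), abs=1e-12
        )
        assert ic.theta_steady_state(-1.0) == pytest.approx(-np.pi / 2, abs=1e-12)

    def test_approaches_zero_at_bifurcation(self):
        assert abs(ic.theta_steady_state(-1e-9)) < 1e-4

    def test_no_fixed_point_beyond_snic(self):
        with pytest.raises(NoFixedPointError):
            ic.theta_steady_state(0.0)
        with pytest.raises(NoFixedPointError):
            ic.theta_steady_state(0.5)


class TestSimulation:
    def test_snic_boundary_controls_spiking(self):
        a = np.zeros((1, 1))
        quiet = ic.simulate_theta_network(
            a, ic.ThetaParams(i0=-0.1, noise_sd=0.0, **FAST), 0.0, seed=1
        )
        active = ic.simulate_theta_network(
            a, ic.ThetaParams(i0=0.1, noise_sd=0.0, **FAST), 0.0, seed=1
        )
        assert len(quiet[0]) == 0
        assert len(active[0]) > 10

    @pytest.mark.parametrize("i0", [0.1, 0.5, 1.0])
    def test_spiking_period_matches_closed_form(self, i0):
        p = ic.ThetaParams(i0=i0, noise_sd=0.0, dt=0.01, n_steps=20_000)
        trains = ic.simulate_theta_network(np.zeros((1, 1)), p, 0.0, seed=0)
        isi = np.diff(trains[0])[2:]
        assert abs(isi.mean() - np.pi / np.sqrt(i0)) <= 2 * p.dt

    def test_identical_seed_identical_spikes(self):
        a = random_network(5, 0.5, 0.2, 0)
        p = ic.ThetaParams(**FAST)
        t1 = ic.simulate_theta_network(a, p, 10.0, seed=4)
        t2 = ic.simulate_theta_network(a, p, 10.0, seed=4)
        for u, v in zip(t1, t2):
            np.testing.assert_array_equal(u, v)

    def test_invalid_weights_rejected(self):
        p = ic.ThetaParams(**FAST)
        with pytest.raises(ic.errors.InvalidInputError):
            ic.simulate_theta_network(np.full((2, 2), np.nan), p, 1.0)
        with pytest.raises(ic.errors.InvalidInputError):
            ic.simulate_theta_network(np.zeros((0, 0)), p, 1.0)


class TestSeizureFraction:
    def test_no_spikes_gives_zero(self):
        assert ic.seizure_fraction([np.array([])], horizon=100.0) == 0.0

    def test_continuous_spiking_saturates(self):
        spikes = np.arange(0.0, 1000.0, 1.0)  # ISI 1 << window
        frac = ic.seizure_fraction([spikes], horizon=1000.0)
        assert frac == pytest.approx(1.0, abs=0.02)

    def test_one_of_two_nodes_spiking(self):
        w = ic.ictogenicity.DEFAULT_WINDOW
        spikes = np.arange(0.0, 100.0, 1.0)
        frac = ic.seizure_fraction([spikes, np.array([])], horizon=100.0)
        assert frac == pytest.approx(0.5, abs=w / 100.0)

    def test_window_union_not_double_counted(self):
        # two overlapping windows cover [0, w + 1], not 2w
        w = 5.0
        frac = ic.seizure_fraction([np.array([0.0, 1.0])], horizon=100.0, window=w)
        assert frac == pytest.approx((w + 1.0) / 100.0, abs=1e-9)


class TestBNICurve:
    def test_empty_network_stays_at_baseline(self):
        p = ic.ThetaParams(**FAST)
        curve = ic.bni_curve(np.zeros((5, 5)), p, np.array([0.0, 50.0, 500.0]), seed=1)
        assert np.all(curve.values <= 0.05)

    def test_zero_coupling_ignores_network(self):
        p = ic.ThetaParams(**FAST)
        a = random_network(6, 0.5, 0.3, 1)
        v1 = ic.bni_star(a, p, 0.0, seed=9)
        v2 = ic.bni_star(np.zeros((6, 6)), p, 0.0, seed=9)
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_monotone_in_coupling_on_dense_network(self):
        a = np.full((8, 8), 0.3)
        np.fill_diagonal(a, 0.0)
        p = ic.ThetaParams(**FAST)
        grid = np.concatenate([[0.0], np.geomspace(1.0, 300.0, 19)])
        curve = ic.bni_curve(a, p, grid, seed=2)
        rho, _ = stats.spearmanr(curve.k_grid, curve.values)
        assert rho >= 0.8
        assert curve.values.min() >= 0.0 and curve.values.max() <= 1.0

    def test_extra_edges_do_not_reduce_ictogenicity(self):
        """Coupling is excitatory: a denser network is at least as ictogenic."""
        p = ic.ThetaParams(**FAST)
        k = 60.0
        wins = 0
        n_rep = 20
        for rep in range(n_rep):
            sparse = random_network(8, 0.2, 0.3, rep)
            extra = random_network(8, 0.2, 0.3, 1000 + rep)
            dense = np.maximum(sparse, np.maximum(extra, sparse))
            dense = sparse + extra  # strictly more/stronger edges
            v_sparse = ic.bni_star(sparse, p, k, seed=rep, n_realizations=2)
            v_dense = ic.bni_star(dense, p, k, seed=rep, n_realizations=2)
            wins += v_dense >= v_sparse - 0.02
        # sign test against "denser is less ictogenic half the time"
        assert stats.binomtest(wins, n_rep, 0.5, alternative="greater").pvalue < 0.05


class TestKIntervalAndIntegral:
    @staticmethod
    def curve(ks, vals):
        return ic.BNICurve(k_grid=np.array(ks, float), values=np.array(vals, float))

    def test_single_curve_margin(self):
        c = self.curve([0, 1, 2, 3, 4], [0, 0.2, 0.6, 1.0, 1.0])
        assert ic.select_k_interval([c]) == (0.0, pytest.approx(3.6))

    def test_two_curves_take_latest_saturation(self):
        c1 = self.curve([0, 1, 2, 3, 4, 5], [0, 0.5, 0.96, 1, 1, 1])
        c2 = self.curve([0, 1, 2, 3, 4, 5], [0, 0.1, 0.3, 0.6, 0.9, 0.97])
        assert ic.select_k_interval([c1, c2]) == (0.0, pytest.approx(6.0))

    def test_no_saturating_curve_errors(self):
        c = self.curve([0, 1, 2], [0.1, 0.5, 0.7])
        with pytest.raises(GridExhaustedError):
            ic.select_k_interval([c])

    def test_nonsaturating_curve_contributes_grid_max(self):
        c1 = self.curve([0, 1, 2, 3], [0, 0.96, 1, 1])
        c2 = self.curve([0, 1, 2, 3], [0, 0.2, 0.4, 0.6])  # ceiling below 0.95
        assert ic.select_k_interval([c1, c2])[1] == pytest.approx(3.6)

    @pytest.mark.parametrize(
        "ks,vals,k1,k2,expected",
        [
            ([0, 1, 2], [1, 1, 1], 0, 2, 2.0),
            ([1, 2, 3], [0.5, 0.5, 0.5], 1, 3, 1.0),
            ([0, 0.5, 1], [0, 0.5, 1], 0, 1, 0.5),
        ],
    )
    def test_integral_examples(self, ks, vals, k1, k2, expected):
        assert ic.bni_integral(self.curve(ks, vals), k1, k2) == pytest.approx(expected)

    def test_integral_extends_saturated_tail(self):
        c = self.curve([0, 1, 2], [0, 1, 1])
        assert ic.bni_integral(c, 0, 4) == pytest.approx(3.5)

    def test_invalid_bounds(self):
        c = self.curve([0, 1, 2], [0, 1, 1])
        with pytest.raises(InvalidParameterError):
            ic.bni_integral(c, 2, 1)


class TestNormalizeTimecourse:
    @staticmethod
    def tc(values, labels, times=None):
        times = np.arange(len(values), dtype=float) if times is None else times
        return ic.BNITimecourse(times=times, values=np.array(values, float),
                                labels=list(labels))

    def test_divides_by_epoch_maximum(self):
        tc = self.tc([2.0, 4.0, 1.0], ["preictal", "ictal", "postictal"])
        out = ic.normalize_timecourse(tc)
        assert out.values.max() == pytest.approx(1.0)
        assert out.epoch_values("preictal")[0] == pytest.approx(0.5)
        assert out.epoch_values("postictal")[0] == pytest.approx(0.25)

    @pytest.mark.parametrize("n_ictal", [3, 10, 11, 25])
    def test_ictal_resampled_to_ten_points(self, n_ictal):
        values = [1.0] * 5 + list(np.linspace(1, 2, n_ictal)) + [1.0] * 5
        labels = ["preictal"] * 5 + ["ictal"] * n_ictal + ["postictal"] * 5
        out = ic.normalize_timecourse(self.tc(values, labels))
        assert out.epoch_values("ictal").size == 10
        assert out.epoch_values("preictal").size == 5
        assert out.epoch_values("postictal").size == 5

    def test_ten_point_ictal_series_unchanged(self):
        ictal = np.linspace(0.5, 1.0, 10)
        labels = ["ictal"] * 10
        out = ic.normalize_timecourse(self.tc(ictal, labels))
        np.testing.assert_allclose(out.epoch_values("ictal"), ictal / ictal.max())

    def test_degenerate_cases(self):
        with pytest.raises(DegenerateTimecourseError):
            ic.normalize_timecourse(self.tc([0.0, 0.0], ["preictal", "ictal"]))
        with pytest.raises(DegenerateTimecourseError):
            ic.normalize_timecourse(self.tc([1.0, 2.0], ["preictal", "postictal"]))


class TestCalibrationAndResection:
    def test_calibration_reaches_target_on_small_network(self):
        a = random_network(10, 0.3, 0.2, 3)
        p = ic.ThetaParams(n_steps=100_000)
        calib = ic.calibrate_reference_coupling(a, p, n_realizations=2, seed=11)
        assert abs(calib.achieved - 0.5) <= 0.05 * 2
        check = ic.bni_star(a, p, calib.k_ref, seed=999, n_realizations=3)
        assert abs(check - 0.5) <= 0.15  # fresh noise, generous MC slack

    def test_silent_network_cannot_calibrate(self):
        with pytest.raises(CalibrationError):
            ic.calibrate_reference_coupling(
                np.zeros((4, 4)), ic.ThetaParams(**FAST), k_max=8.0, seed=0
            )

    def test_delta_bni_formula_and_guards(self):
        res = ic.ResectionResult(removed_nodes=(0,), bni_pre=0.5, bni_post=0.3)
        assert res.delta_bni == pytest.approx(0.4)
        assert ic.ResectionResult((0,), 0.5, 0.5).delta_bni == 0.0
        assert ic.ResectionResult((0,), 0.5, 0.0).delta_bni == 1.0
        a = random_network(6, 0.5, 0.2, 1)
        p = ic.ThetaParams(**FAST)
        with pytest.raises(InvalidResectionError):
            ic.delta_bni(a, range(6), p, 10.0)
        with pytest.raises(InvalidResectionError):
            ic.delta_bni(a, [7], p, 10.0)

    def test_resecting_hub_nodes_reduces_bni(self):
        """Removing a strongly connected core drops BNI more than removing
        peripheral nodes (the virtual-surgery rationale)."""
        rng = np.random.default_rng(21)
        n, core = 12, [0, 1, 2, 3]
        a = random_network(n, 0.15, 0.1, 22)
        for i in core:
            for j in core:
                if i != j:
                    a[i, j] = 0.8
        p = ic.ThetaParams(n_steps=100_000)
        calib = ic.calibrate_reference_coupling(a, p, n_realizations=2, seed=23)
        periph = [8, 9, 10, 11]
        d_core = ic.delta_bni(a, core, p, calib.k_ref, seed=1, n_realizations=2)
        d_periph = ic.delta_bni(a, periph, p, calib.k_ref, seed=2, n_realizations=2)
        assert d_core.delta_bni > d_periph.delta_bni
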