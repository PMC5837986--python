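"""FC inference: IAAFT surrogates, association measures, significance, correction."""

import itertools

import numpy as np
import pytest

import ictonet as ic
from ictonet.errors import (
    DegenerateSignalError,
    InvalidInputError,
    InvalidParameterError,
    UndefinedCorrelationError,
)
from ictonet.fc import AssociationSample, build_association_samples, mannwhitney_u

from .conftest import make_segment


class TestIaaft:
    def test_amplitude_multiset_preserved_exactly(self):
        rng = np.random.default_rng(0)
        x = np.cumsum(rng.standard_normal(512))
        for s in ic.iaaft_surrogates(x, 5, seed=1):
            np.testing.assert_array_equal(np.sort(s), np.sort(x))

    def test_power_spectrum_close(self):
        rng = np.random.default_rng(1)
        t = np.arange(2048) / 512.0
        x = np.sin(2 * np.pi * 11 * t) + 0.5 * rng.standard_normal(t.size)
        amp = np.abs(np.fft.rfft(x))
        for s in ic.iaaft_surrogates(x, 5, seed=2):
            err = np.linalg.norm(np.abs(np.fft.rfft(s)) - amp) / np.linalg.norm(amp)
            assert err <= 0.05

    def test_lag_one_autocorrelation_matched_on_noise(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(1024)

        def ac1(v):
            v = v - v.mean()
            return float(v[:-1] @ v[1:] / (v @ v))

        for s in ic.iaaft_surrogates(x, 10, seed=3):
            assert abs(ac1(s) - ac1(x)) <= 0.1

    def test_deterministic_per_seed(self):
        x = np.random.default_rng(3).standard_normal(256)
        a = ic.iaaft_surrogates(x, 3, seed=7)
        b = ic.iaaft_surrogates(x, 3, seed=7)
        c = ic.iaaft_surrogates(x, 3, seed=8)
        for u, v in zip(a, b):
            np.testing.assert_array_equal(u, v)
        assert any(not np.array_equal(u, w) for u, w in zip(a, c))

    def test_constant_signal_rejected(self):
        with pytest.raises(DegenerateSignalError):
            ic.iaaft_surrogates(np.ones(256), 3, seed=0)


class TestPearson:
    def test_self_and_sign_convention(self):
        x = np.random.default_rng(0).standard_normal(100)
        assert ic.pearson_zero_lag(x, x) == pytest.approx(1.0)
        assert ic.pearson_zero_lag(x, -x) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # centered cross-product 6.5, variances 5 and 8.75 -> r = 6.5/sqrt(43.75)
        assert ic.pearson_zero_lag([1, 2, 3, 4], [1, 2, 3, 5]) == pytest.approx(
            6.5 / np.sqrt(43.75), abs=1e-12
        )

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            ic.pearson_zero_lag(np.ones(10), np.arange(10))


class TestH2:
    def test_linear_dependence_explained(self):
        x = np.linspace(-1, 1, 1000)
        assert ic.h2_association(x, x) >= 0.999

    def test_quadratic_dependence_detected(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(-1, 1, 1000)
        y = x**2
        assert abs(ic.pearson_zero_lag(x, y)) < 0.2  # Pearson blind to the parabola
        assert ic.h2_association(x, y) >= 0.9

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(5)
        vals = [
            ic.h2_association(rng.standard_normal(1024), rng.standard_normal(1024))
            for _ in range(100)
        ]
        assert np.mean(vals) <= 0.1
        assert np.quantile(vals, 0.99) <= 0.15

    def test_degenerate_inputs(self):
        x = np.linspace(0, 1, 200)
        with pytest.raises(InvalidParameterError):
            ic.h2_association(x, x, n_bins=1)
        assert ic.h2_association(x, np.zeros_like(x)) == 0.0


def exact_u_pvalue(x, y, alternative):
    """Exhaustive-enumeration oracle for the Mann-Whitney U test (no ties)."""
    combined = np.concatenate([x, y])
    n = len(x)

    def u_of(idx):
        xs = combined[list(idx)]
        ys = np.delete(combined, list(idx))
        return sum((xi > ys).sum() + 0.5 * (xi == ys).sum() for xi in xs)

    u_obs = u_of(range(n))
    us = np.array(
        [u_of(idx) for idx in itertools.combinations(range(len(combined)), n)]
    )
    if alternative == "greater":
        return np.mean(us >= u_obs)
    if alternative == "less":
        return np.mean(us <= u_obs)
    return min(1.0, 2 * min(np.mean(us >= u_obs), np.mean(us <= u_obs)))


@pytest.mark.parametrize("alternative", ["greater", "less", "two-sided"])
def test_mannwhitney_matches_exhaustive_enumeration(alternative):
    rng = np.random.default_rng(6)
    for n, m in [(3, 3), (3, 5), (4, 4), (5, 5)]:
        for _ in range(5):
            x = rng.standard_normal(n)
            y = rng.standard_normal(m) + rng.uniform(-1, 1)
            _, p = mannwhitney_u(x, y, alternative=alternative)
            assert p == pytest.approx(exact_u_pvalue(x, y, alternative), abs=1e-9)


class TestSurrogateSignificance:
    @staticmethod
    def _samples_for(n_channels, fill):
        return [
            AssociationSample((i, j), *fill(i, j))
            for i in range(n_channels)
            for j in range(i + 1, n_channels)
        ]

    def test_clear_separation_rejected(self):
        rng = np.random.default_rng(7)
        samples = self._samples_for(
            3,
            lambda i, j: (
                0.9 + 1e-3 * rng.standard_normal(10),
                0.1 + 1e-3 * rng.standard_normal(100),
            ),
        )
        s = ic.surrogate_significance(samples, alpha=0.05)
        assert s.sum() == 6  # all 3 pairs, symmetric
        np.testing.assert_array_equal(s, s.T)

    def test_null_rejection_rate_controlled(self):
        rng = np.random.default_rng(8)
        n_rej = 0
        n_pairs = 200
        for _ in range(n_pairs):
            r0 = rng.uniform(0, 1, 10)
            rs = rng.uniform(0, 1, 100)
            _, p = mannwhitney_u(r0, rs, alternative="greater")
            n_rej += p <= 0.05
        rate = n_rej / n_pairs
        assert rate <= 0.05 + 2.6 * np.sqrt(0.05 * 0.95 / n_pairs)

    def test_missing_pairs_rejected(self):
        samples = self._samples_for(
            3, lambda i, j: (np.ones(10) * 0.5, np.ones(100) * 0.5)
        )[:2]
        with pytest.raises(InvalidInputError):
            ic.surrogate_significance(samples, alpha=0.05, n_channels=3)


class TestCorrectedFC:
    @staticmethod
    def _one_pair_network(rho0, rhosurr, significant):
        samples = [
            AssociationSample(
                (0, 1), np.full(10, rho0), np.full(100, rhosurr)
            )
        ]
        s = np.zeros((2, 2), int)
        if significant:
            s[0, 1] = s[1, 0] = 1
        return ic.corrected_fc(samples, s)

    def test_nonsignificant_pair_zeroed(self):
        net = self._one_pair_network(0.9, 0.1, significant=False)
        assert net.weights[0, 1] == 0.0

    @pytest.mark.parametrize(
        "rho0,rhosurr,expected", [(1.0, 0.3, 1.0), (0.6, 0.2, 0.5), (0.1, 0.3, 0.0)]
    )
    def test_correction_formula(self, rho0, rhosurr, expected):
        net = self._one_pair_network(rho0, rhosurr, significant=True)
        assert net.weights[0, 1] == pytest.approx(expected)

    def test_output_invariants(self):
        rng = np.random.default_rng(9)
        seg = make_segment(rng.standard_normal((4, 4096)))
        net = ic.infer_fc(seg, seed=0)
        np.testing.assert_array_equal(net.weights, net.weights.T)
        assert np.all(np.diag(net.weights) == 0)
        assert net.weights.min() >= 0 and net.weights.max() <= 1
        assert not np.any((net.weights > 0) & (net.significance_mask == 0))


def test_shared_signal_detected_reliably():
    """Two channels sharing 70% of their variance: the pair tests significant."""
    rng = np.random.default_rng(10)
    hits = 0
    n_rep = 50
    for _ in range(n_rep):
        g = rng.standard_normal(4096)
        x = np.sqrt(0.7) * g + np.sqrt(0.3) * rng.standard_normal(4096)
        y = np.sqrt(0.7) * g + np.sqrt(0.3) * rng.standard_normal(4096)
        seg = make_segment(np.vstack([x, y]))
        net = ic.infer_fc(seg, seed=int(rng.integers(2**31)))
        hits += net.significance_mask[0, 1] == 1
    assert hits >= 0.95 * n_rep


def test_h2_measure_pipeline_detects_coupling():
    rng = np.random.default_rng(11)
    g = rng.standard_normal(4096)
    x = np.sqrt(0.7) * g + np.sqrt(0.3) * rng.standard_normal(4096)
    y = np.sqrt(0.7) * g + np.sqrt(0.3) * rng.standard_normal(4096)
    seg = make_segment(np.vstack([x, y]))
    net = ic.infer_fc(seg, measure="h2", seed=1)
    assert net.measure == "h2"
    assert net.weights[0, 1] > 0.2


def test_association_sample_counts():
    rng = np.random.default_rng(12)
    seg = make_segment(rng.standard_normal((3, 4096)))
    surr = ic.fc.channelwise_surrogates(seg.data, 10, seed=0)
    ens = ic.make_subsegments(seg, surr)
    samples = build_association_samples(ens)
    assert len(samples) == 3
    for s in samples:
        assert s.rho0_values.shape == (10,)
        assert s.rhosurr_values.shape == (100,)
        assert np.nanmin(s.rho0_values) >= 0 and np.nanmax(s.rho0_values) <= 1
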