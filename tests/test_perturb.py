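"""Tests of the artifact models: spike trains, distributed and
consecutive sample loss."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import egmentropy as eg
from egmentropy.entropy import EntropyParams
from egmentropy.perturb import (
    DegenerateReferenceError,
    SpikeTrain,
    apply_perturbation,
    make_spike_train,
    spike_entropy_reference,
)
from egmentropy.signal import Signal


class TestPeakToPeak:
    def test_constant_is_zero(self):
        assert eg.peak_to_peak(Signal(np.full(10, 2.5))) == 0.0

    def test_symmetric_sine_spans_two(self):
        t = np.linspace(0, 2 * np.pi, 1001)
        assert eg.peak_to_peak(Signal(np.sin(t))) == pytest.approx(2.0, abs=1e-6)

    def test_direct_example(self):
        assert eg.peak_to_peak(Signal(np.array([-0.4, 1.3, 0.2]))) == pytest.approx(1.7)


class TestMakeSpikeTrain:
    def test_zero_probability_empty(self):
        train = make_spike_train(100, 0.0, 1.0, seed=0)
        assert train.n == 0

    def test_unit_probability_full(self):
        train = make_spike_train(100, 1.0, 1.0, seed=0)
        assert train.n == 100

    def test_binomial_occurrence_statistics(self):
        counts = [make_spike_train(1500, 0.1, 1.0, seed=s).n for s in range(200)]
        expected_sd = np.sqrt(1500 * 0.1 * 0.9)
        assert abs(np.mean(counts) - 150) < 3 * expected_sd

    @given(p_s=st.floats(0.0, 1.0), lam=st.floats(0.0, 10.0), seed=st.integers(0, 2**20))
    @settings(max_examples=50, deadline=None)
    def test_amplitudes_bounded_and_locations_sorted(self, p_s, lam, seed):
        train = make_spike_train(200, p_s, lam, seed=seed)
        if train.n:
            assert np.all(np.abs(train.amplitudes) <= 3 * lam)
            assert np.all(np.diff(train.locations) > 0)
        assert train.n <= 200

    def test_out_of_bound_amplitude_rejected(self):
        with pytest.raises(ValueError):
            SpikeTrain(np.array([3]), np.array([4.0]), p_s=0.1, lambda_pp=1.0)


class TestAddSpikes:
    def test_empty_train_is_identity(self, rng):
        x = Signal(rng.normal(size=50))
        y = eg.add_spikes(x, make_spike_train(50, 0.0, eg.peak_to_peak(x), seed=1))
        assert np.array_equal(y.samples, x.samples)

    def test_single_spike_on_null_host(self):
        x = Signal(np.zeros(10))
        train = SpikeTrain(np.array([5]), np.array([2.0]), p_s=0.1, lambda_pp=1.0)
        y = eg.add_spikes(x, train)
        expected = np.zeros(10)
        expected[5] = 2.0
        assert np.array_equal(y.samples, expected)

    def test_superposition_is_sparse_and_additive(self, rng):
        x = Signal(rng.normal(size=300))
        train = make_spike_train(300, 0.1, eg.peak_to_peak(x), seed=4)
        y = eg.add_spikes(x, train)
        diff = y.samples - x.samples
        assert np.count_nonzero(diff) == train.n
        assert np.allclose(diff[train.locations], train.amplitudes)

    def test_out_of_range_location_raises(self):
        x = Signal(np.zeros(5))
        train = SpikeTrain(np.array([9]), np.array([0.5]), p_s=0.1, lambda_pp=1.0)
        with pytest.raises(IndexError):
            eg.add_spikes(x, train)


class TestSampleLoss:
    @pytest.mark.parametrize("op", [eg.remove_samples_distributed,
                                    eg.remove_samples_consecutive])
    def test_zero_eta_is_exact_identity(self, rng, op):
        x = Signal(rng.normal(size=100))
        assert np.array_equal(op(x, 0.0, seed=0).samples, x.samples)

    @pytest.mark.parametrize("op", [eg.remove_samples_distributed,
                                    eg.remove_samples_consecutive])
    @pytest.mark.parametrize("eta,expected", [(0.1, 1350), (0.5, 750)])
    def test_output_length_exact(self, rng, op, eta, expected):
        x = Signal(rng.normal(size=1500))
        assert op(x, eta, seed=3).n == expected

    def test_rounding_half_up(self, rng):
        x = Signal(rng.normal(size=10))
        # 0.25 * 10 = 2.5 -> 3 samples removed
        assert eg.remove_samples_distributed(x, 0.25, seed=0).n == 7

    def test_distributed_output_is_ordered_subsequence(self, rng):
        x = Signal(rng.normal(size=200))
        y = eg.remove_samples_distributed(x, 0.3, seed=9)
        it = iter(x.samples.tolist())
        assert all(any(u == v for u in it) for v in y.samples.tolist())

    def test_consecutive_output_is_prefix_plus_suffix(self, rng):
        x = Signal(rng.normal(size=200))
        seed = 13
        y = eg.remove_samples_consecutive(x, 0.1, seed=seed)
        k = 20
        start = int(np.random.default_rng(seed).integers(0, x.n - k + 1))
        expected = np.concatenate([x.samples[:start], x.samples[start + k:]])
        assert np.array_equal(y.samples, expected)

    @pytest.mark.parametrize("op", [eg.remove_samples_distributed,
                                    eg.remove_samples_consecutive])
    def test_removing_everything_rejected(self, rng, op):
        with pytest.raises(ValueError):
            op(Signal(rng.normal(size=10)), 1.0, seed=0)

    @pytest.mark.parametrize("kind", ["spikes", "loss_distributed", "loss_consecutive"])
    def test_operators_pure_in_seed(self, rng, kind):
        x = Signal(rng.normal(size=300))
        a = apply_perturbation(x, kind, 0.2, np.random.default_rng(5))
        b = apply_perturbation(x, kind, 0.2, np.random.default_rng(5))
        assert np.array_equal(a.samples, b.samples)


class TestSpikeEntropyReference:
    def test_no_spikes_zero_entropy_in_absolute_mode(self):
        mean, n_undef = spike_entropy_reference(
            500, 0.0, 1.0, EntropyParams(r=0.2, r_mode="absolute"),
            n_realisations=5, seed=0,
        )
        assert mean == 0.0
        assert n_undef == 0

    def test_deterministic(self):
        a = spike_entropy_reference(500, 0.1, 1.0, n_realisations=5, seed=3)
        b = spike_entropy_reference(500, 0.1, 1.0, n_realisations=5, seed=3)
        assert a == b

    def test_all_undefined_raises(self):
        # empty trains are constant signals: SD-relative tolerance degenerates
        with pytest.raises(DegenerateReferenceError):
            spike_entropy_reference(500, 0.0, 1.0, n_realisations=3, seed=0)

    def test_curve_stable_across_seed_sets(self):
        grid = [0.05, 0.1, 0.2]
        a = [spike_entropy_reference(1000, p, 1.0, n_realisations=20, seed=1)[0]
             for p in grid]
        b = [spike_entropy_reference(1000, p, 1.0, n_realisations=20, seed=2)[0]
             for p in grid]
        assert np.allclose(a, b, atol=0.1)
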