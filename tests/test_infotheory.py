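"""Entropies, entropy rate, transition spectra, AIF and sequence tests."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import microstates as ms

LOG4 = np.log(4)


def _cycle(n):
    return ms.LabelSequence(np.tile([0, 1, 2, 3], n // 4 + 1)[:n], 4)


class TestShannonEntropy:
    def test_uniform_four_symbols(self):
        seq = ms.LabelSequence(np.tile([0, 1, 2, 3], 1000), 4)
        assert ms.shannon_entropy(seq) == pytest.approx(LOG4)

    def test_single_symbol_zero(self):
        assert ms.shannon_entropy(ms.LabelSequence(np.zeros(100, int), 4)) == 0.0

    def test_two_of_four_symbols(self):
        seq = ms.LabelSequence(np.tile([0, 1], 500), 4)
        assert ms.shannon_entropy(seq) == pytest.approx(np.log(2))


class TestJointEntropy:
    def test_n1_reduces_to_shannon(self):
        rng = np.random.default_rng(0)
        seq = ms.LabelSequence(rng.integers(0, 4, 5000), 4)
        assert ms.joint_entropy(seq, 1) == pytest.approx(ms.shannon_entropy(seq))

    @pytest.mark.parametrize("n", [1, 2, 3, 5])
    def test_deterministic_cycle_stays_log4(self, n):
        assert ms.joint_entropy(_cycle(4000), n) == pytest.approx(LOG4)

    def test_matches_brute_force_trigram_count(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, 500)
        got = ms.joint_entropy(ms.LabelSequence(x, 3), 3)
        from collections import Counter

        counts = Counter(tuple(x[i : i + 3]) for i in range(len(x) - 2))
        p = np.array(list(counts.values())) / sum(counts.values())
        assert got == pytest.approx(-np.sum(p * np.log(p)))

    def test_rejects_overlong_history(self):
        with pytest.raises(ValueError):
            ms.joint_entropy(ms.LabelSequence([0, 1, 0], 2), 3)


class TestEntropyRate:
    def test_iid_uniform_near_log4(self):
        rng = np.random.default_rng(2)
        seq = ms.LabelSequence(rng.integers(0, 4, 100_000), 4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = ms.entropy_rate(seq, n_max=8)
        assert est.slope == pytest.approx(LOG4, rel=0.05)

    def test_deterministic_cycle_rate_zero(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = ms.entropy_rate(_cycle(5000), n_max=6)
        # h_n = log 4 for every n, so the OLS slope vanishes (up to the
        # float accumulation error of the plug-in sums)
        assert est.slope == pytest.approx(0.0, abs=1e-6)

    def test_markov_chain_within_5pct_of_closed_form(self):
        T = ms.dwell_transition_matrix(4, 4.0)
        pi = np.full(4, 0.25)
        labels = ms.generate_markov_labels(pi, T, 30_000, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = ms.entropy_rate(ms.LabelSequence(labels, 4), n_max=8)
        h_mc = ms.mc_entropy_rate(pi, T)
        assert abs(est.slope - h_mc) / h_mc < 0.05

    def test_h_n_monotone_and_rate_below_entropy(self, backfit_sequence):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = ms.entropy_rate(backfit_sequence, n_max=8)
        assert np.all(np.diff(est.h_n) >= -1e-12)
        assert est.slope <= ms.shannon_entropy(backfit_sequence) + 1e-12


class TestMCEntropyRate:
    def test_uniform_matrix_gives_log4(self):
        assert ms.mc_entropy_rate(np.full(4, 0.25), np.full((4, 4), 0.25)) == pytest.approx(LOG4)

    def test_permutation_matrix_gives_zero(self):
        T = np.roll(np.eye(4), 1, axis=1)
        assert ms.mc_entropy_rate(np.full(4, 0.25), T) == 0.0

    def test_two_state_numeric(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        pi = np.array([2 / 3, 1 / 3])  # stationary vector of T
        direct = -sum(
            pi[i] * T[i, j] * np.log(T[i, j]) for i in range(2) for j in range(2)
        )
        assert ms.mc_entropy_rate(pi, T) == pytest.approx(direct)


class TestCalibration:
    def test_realistic_chains_calibrate_to_8(self):
        """Chains with microstate-like entropy rate support history length 8."""
        T = ms.dwell_transition_matrix(4, 1 / 0.35)
        seqs = [
            ms.LabelSequence(
                ms.generate_markov_labels(np.full(4, 0.25), T, 30_000, 100 + s), 4
            )
            for s in range(20)
        ]
        n_hat, eps = ms.calibrate_history(seqs, seed=0)
        assert n_hat == 8
        assert eps[8] < 0.05

    def test_short_sequences_calibrate_lower(self):
        T = ms.dwell_transition_matrix(4, 1 / 0.35)
        seqs = [
            ms.LabelSequence(
                ms.generate_markov_labels(np.full(4, 0.25), T, 500, 200 + s), 4
            )
            for s in range(10)
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            n_hat, _ = ms.calibrate_history(seqs, seed=1)
        assert n_hat < 8

    def test_infinite_tolerance_returns_range_max(self):
        T = ms.dwell_transition_matrix(4, 5.0)
        seqs = [
            ms.LabelSequence(ms.generate_markov_labels(np.full(4, 0.25), T, 3000, 7), 4)
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            n_hat, _ = ms.calibrate_history(seqs, eps_max=np.inf, seed=2)
        assert n_hat == 10


class TestTransitionMatrix:
    def test_alternating_sequence(self):
        tm = ms.transition_matrix(ms.LabelSequence(np.tile([0, 1], 50), 2))
        assert np.allclose(tm.T, [[0, 1], [1, 0]])

    def test_hand_counted_four_samples(self):
        tm = ms.transition_matrix(ms.LabelSequence([0, 0, 1, 1], 2))
        assert np.allclose(tm.T, [[0.5, 0.5], [0, 1]])

    def test_perron_eigenvalue_is_one(self, backfit_sequence):
        tm = ms.transition_matrix(backfit_sequence)
        assert abs(tm.eigenvalues[0]) == pytest.approx(1.0, abs=1e-9)

    def test_unvisited_symbol_row_flagged(self):
        tm = ms.transition_matrix(ms.LabelSequence([0, 1, 0, 1], 3))
        assert 2 in tm.zero_rows
        assert np.allclose(tm.T.sum(axis=1), 1.0)


class TestMixingTime:
    def test_two_state_hand_case(self):
        labels = ms.generate_markov_labels(
            np.array([0.5, 0.5]), np.array([[0.75, 0.25], [0.25, 0.75]]), 200_000, 4
        )
        tm = ms.transition_matrix(ms.LabelSequence(labels, 2))
        assert tm.mixing_time == pytest.approx(2.0, rel=0.05)

    def test_uniform_chain_mixes_instantly(self):
        tm = ms.transition_matrix(
            ms.LabelSequence(np.random.default_rng(5).integers(0, 4, 100_000), 4)
        )
        assert tm.mixing_time == pytest.approx(1.0, abs=0.05)

    def test_matches_eigen_oracle(self):
        T = ms.dwell_transition_matrix(4, 1 / 0.3)  # diag 0.7 -> lambda_1 = 0.6
        labels = ms.generate_markov_labels(np.full(4, 0.25), T, 200_000, 6)
        tm = ms.transition_matrix(ms.LabelSequence(labels, 4))
        lam1 = np.sort(np.abs(np.linalg.eigvals(T)))[-2]
        assert lam1 == pytest.approx(0.6)
        assert tm.mixing_time == pytest.approx(1 / (1 - 0.6), rel=0.05)

    def test_periodic_chain_flagged_infinite(self):
        tm = ms.transition_matrix(ms.LabelSequence(np.tile([0, 1], 100), 2))
        assert np.isinf(tm.mixing_time)


class TestAIF:
    def test_deterministic_cycle_period(self):
        # X_{t+k} is a deterministic function of X_t at EVERY lag of a pure
        # cycle, so I(k) = log 4 throughout (in particular at k = 0 mod 4)
        curve = ms.aif(_cycle(8000), 12)
        for k in (0, 4, 8, 12):
            assert curve.values[k] == pytest.approx(LOG4, abs=1e-3)
        assert np.all(curve.values > LOG4 - 1e-3)

    def test_iid_decays_to_bias_floor(self):
        rng = np.random.default_rng(7)
        curve = ms.aif(ms.LabelSequence(rng.integers(0, 4, 100_000), 4), 20)
        # plug-in MI bias ~ (M-1)^2 / (2n) nats
        assert np.all(curve.values[1:] < 0.001)

    def test_lag_zero_equals_entropy(self, backfit_sequence):
        curve = ms.aif(backfit_sequence, 5)
        assert curve.values[0] == pytest.approx(ms.shannon_entropy(backfit_sequence))


class TestFirstAIFPeak:
    def test_planted_peak_location(self):
        # triangular bump on a flat baseline: smoothing keeps a unique
        # maximum at the planted location, so detection is exact
        v = np.full(40, 0.1)
        v[14:17] += [0.1, 0.3, 0.1]
        curve = ms.AIFCurve(np.arange(40), v, fs=250.0)
        assert ms.first_aif_peak(curve) == pytest.approx(15 * 4.0)

    def test_monotone_curve_returns_none(self):
        curve = ms.AIFCurve(np.arange(40), np.exp(-np.arange(40) / 5.0), fs=250.0)
        assert ms.first_aif_peak(curve) is None

    def test_peaks_at_or_below_min_lag_ignored(self):
        v = np.full(40, 0.1)
        v[5:8] += [0.2, 0.5, 0.2]    # below the exclusion threshold
        v[19:22] += [0.1, 0.3, 0.1]
        curve = ms.AIFCurve(np.arange(40), v, fs=250.0)
        assert ms.first_aif_peak(curve, min_lag=8) == pytest.approx(20 * 4.0)


class TestMarkovTests:
    def test_order0_type_i_rate(self):
        rng = np.random.default_rng(8)
        alpha, n_rep = 0.01, 500
        rej = sum(
            ms.markov_test(ms.LabelSequence(rng.integers(0, 4, 5000), 4), 0)[2] < alpha
            for _ in range(n_rep)
        )
        assert rej / n_rep <= 2 * alpha

    def test_periodic_sequence_rejected(self):
        x = np.tile([0, 1, 2, 3, 0, 2, 1, 3], 500)
        assert ms.markov_test(ms.LabelSequence(x, 4), 0)[2] < 1e-10
        assert ms.markov_test(ms.LabelSequence(x, 4), 1)[2] < 1e-10

    def test_first_order_chain_retains_order1_null(self):
        rng = np.random.default_rng(9)
        T = ms.dwell_transition_matrix(4, 4.0)
        alpha, n_rep = 0.01, 500
        rej = 0
        for _ in range(n_rep):
            x = ms.generate_markov_labels(np.full(4, 0.25), T, 5000, rng)
            rej += ms.markov_test(ms.LabelSequence(x, 4), 1)[2] < alpha
        assert rej / n_rep <= 2 * alpha

    def test_microstate_sequence_rejects_all_orders(self, backfit_sequence):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for order in (0, 1, 2):
                _, _, p = ms.markov_test(backfit_sequence, order)
                assert p < 0.01 / 20  # survives Bonferroni over 20 subjects

    def test_degenerate_sequence_rejected(self):
        with pytest.raises(ValueError, match="single-symbol"):
            ms.markov_test(ms.LabelSequence(np.zeros(100, int), 4), 0)


class TestStationarity:
    def test_type_i_rate_on_homogeneous_chain(self):
        rng = np.random.default_rng(10)
        T = ms.dwell_transition_matrix(4, 4.0)
        alpha, n_rep = 0.01, 500
        rej = 0
        for _ in range(n_rep):
            x = ms.generate_markov_labels(np.full(4, 0.25), T, 2000, rng)
            rej += ms.stationarity_test(ms.LabelSequence(x, 4), 500)[2] < alpha
        assert rej / n_rep <= 2 * alpha

    def test_glued_chains_rejected(self):
        Ta = ms.dwell_transition_matrix(4, 4.0)
        Tb = np.roll(np.eye(4), 1, axis=1) * 0.8 + 0.05
        a = ms.generate_markov_labels(np.full(4, 0.25), Ta, 2000, 11)
        b = ms.generate_markov_labels(np.full(4, 0.25), Tb, 2000, 12)
        _, _, p = ms.stationarity_test(ms.LabelSequence(np.r_[a, b], 4), 500)
        assert p < 1e-10

    def test_rejects_single_block(self):
        with pytest.raises(ValueError):
            ms.stationarity_test(ms.LabelSequence(np.tile([0, 1], 300), 2), 500)


class TestLabelPermutationInvariance:
    """Everything downstream of the labels is symmetric in the labeling."""

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.permutations(list(range(4))))
    def test_invariance_under_relabeling(self, perm):
        rng = np.random.default_rng(12)
        T = ms.dwell_transition_matrix(4, 6.0)
        x = ms.generate_markov_labels(np.full(4, 0.25), T, 4000, rng)
        seq = ms.LabelSequence(x, 4)
        pseq = ms.LabelSequence(np.array(perm)[x], 4)

        assert ms.shannon_entropy(pseq) == pytest.approx(ms.shannon_entropy(seq))
        assert ms.joint_entropy(pseq, 3) == pytest.approx(ms.joint_entropy(seq, 3))
        tm, ptm = ms.transition_matrix(seq), ms.transition_matrix(pseq)
        assert np.allclose(np.abs(ptm.eigenvalues), np.abs(tm.eigenvalues))
        assert ptm.mixing_time == pytest.approx(tm.mixing_time)
        assert np.allclose(ms.aif(pseq, 10).values, ms.aif(seq, 10).values)
        for order in (0, 1):
            g1, _, _ = ms.markov_test(seq, order)
            g2, _, _ = ms.markov_test(pseq, order)
            assert g2 == pytest.approx(g1)
        s1 = ms.stationarity_test(seq, 500)[0]
        s2 = ms.stationarity_test(pseq, 500)[0]
        assert s2 == pytest.approx(s1)
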