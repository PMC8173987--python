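"""Oracle and contract tests for the left-right HMM machinery."""

import numpy as np
import pytest
from scipy.special import logsumexp

from strideseg.hmm import (CombinedHmm, GmmEmission, LeftRightHmm, baum_welch,
                           combine_models, init_left_right_model,
                           left_right_mask, loglik, predict_strides,
                           viterbi_decode)

from conftest import enumerate_paths_log_scores, random_toy_model


class TestInitialization:
    def test_equal_split_segments_pool_into_state_means(self):
        """With one component, each state's mean is the pooled segment mean."""
        rng = np.random.default_rng(3)
        seqs = [rng.normal(size=(50, 2)), rng.normal(size=(53, 2))]
        model = init_left_right_model(seqs, n_states=5, n_components=1, seed=0)
        for i in range(5):
            pooled = np.concatenate(
                [np.array_split(s, 5, axis=0)[i] for s in seqs], axis=0)
            np.testing.assert_allclose(model.emissions[i].means[0],
                                       pooled.mean(axis=0), atol=1e-12)

    def test_interior_rows_are_uniform_over_allowed_edges(self):
        rng = np.random.default_rng(4)
        model = init_left_right_model([rng.normal(size=(40, 1))], 5, seed=0)
        for i in range(4):
            row = model.transitions[i]
            assert row[i] == 0.5 and row[i + 1] == 0.5
            assert np.count_nonzero(row) == 2
        assert model.transitions[4, 4] == 1.0

    def test_wrap_edge_row(self):
        rng = np.random.default_rng(5)
        model = init_left_right_model([rng.normal(size=(40, 1))], 4,
                                      wrap_edge=True, free_ends=True, seed=0)
        assert model.transitions[3, 3] == 0.5 and model.transitions[3, 0] == 0.5

    def test_sequence_shorter_than_states_is_an_error(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError, match="sequence 1"):
            init_left_right_model([rng.normal(size=(20, 1)),
                                   rng.normal(size=(3, 1))], 5, seed=0)

    def test_stride_variant_start_end_constraints(self):
        rng = np.random.default_rng(7)
        model = init_left_right_model([rng.normal(size=(30, 1))], 5, seed=0)
        assert model.start_probs[0] == 1.0 and model.start_probs[1:].sum() == 0
        assert model.end_probs[-1] == 1.0 and model.end_probs[:-1].sum() == 0


class TestForwardViterbiOracle:
    @pytest.mark.parametrize("case", range(30))
    def test_loglik_equals_exhaustive_enumeration(self, case):
        rng = np.random.default_rng(100 + case)
        n = int(rng.integers(1, 5))
        T = int(rng.integers(max(1, n - 2), 9))
        model = random_toy_model(rng, n, d=1, n_components=int(rng.integers(1, 3)),
                                 wrap_edge=bool(rng.integers(0, 2)))
        X = rng.normal(size=(T, 1))
        _, scores = enumerate_paths_log_scores(model, X)
        expected = logsumexp(scores)
        if not np.isfinite(expected):
            assert loglik(model, X) == -np.inf
        else:
            assert loglik(model, X) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("case", range(30))
    def test_viterbi_equals_exhaustive_maximization(self, case):
        rng = np.random.default_rng(200 + case)
        n = int(rng.integers(2, 5))
        T = int(rng.integers(2, 9))
        model = random_toy_model(rng, n, wrap_edge=bool(rng.integers(0, 2)))
        X = rng.normal(size=(T, 1))
        paths, scores = enumerate_paths_log_scores(model, X)
        if not np.isfinite(scores.max()):
            return  # structurally impossible sequence for this toy
        best = paths[int(np.argmax(scores))]
        np.testing.assert_array_equal(viterbi_decode(model, X), best)

    def test_single_state_model_constant_path(self):
        model = LeftRightHmm(transitions=np.ones((1, 1)), start_probs=np.ones(1),
                             end_probs=np.ones(1),
                             emissions=[GmmEmission([1.0], [[0.0]], [[1.0]])])
        path = viterbi_decode(model, np.zeros((6, 1)))
        np.testing.assert_array_equal(path, np.zeros(6, dtype=int))

    def test_exact_tie_breaks_toward_lowest_state_index(self):
        """A fully symmetric cyclic model ties on every path; the
        lexicographically smallest (all-zeros) path must be returned."""
        emis = [GmmEmission([1.0], [[0.0]], [[1.0]]) for _ in range(2)]
        model = LeftRightHmm(
            transitions=np.full((2, 2), 0.5),
            start_probs=np.array([0.5, 0.5]), end_probs=np.array([0.5, 0.5]),
            emissions=emis, wrap_edge=True, free_ends=True)
        path = viterbi_decode(model, np.zeros((4, 1)))
        np.testing.assert_array_equal(path, [0, 0, 0, 0])

    def test_single_state_loglik_is_sum_of_gaussian_logpdfs(self):
        from scipy.stats import norm
        model = LeftRightHmm(transitions=np.ones((1, 1)), start_probs=np.ones(1),
                             end_probs=np.ones(1),
                             emissions=[GmmEmission([1.0], [[0.5]], [[2.0]])])
        X = np.array([[0.1], [1.2], [-0.7]])
        expected = norm(0.5, np.sqrt(2.0)).logpdf(X[:, 0]).sum()
        assert loglik(model, X) == pytest.approx(expected, abs=1e-9)

    def test_loglik_invariant_under_component_permutation(self):
        rng = np.random.default_rng(9)
        model = random_toy_model(rng, 3, n_components=3)
        X = rng.normal(size=(6, 1))
        permuted = LeftRightHmm(
            transitions=model.transitions, start_probs=model.start_probs,
            end_probs=model.end_probs,
            emissions=[GmmEmission(e.weights[::-1], e.means[::-1],
                                   e.variances[::-1]) for e in model.emissions],
            wrap_edge=model.wrap_edge, free_ends=model.free_ends)
        assert loglik(model, X) == pytest.approx(loglik(permuted, X), abs=1e-12)

    def test_loglik_matches_hmmlearn_forward(self):
        """Independent cross-check of the forward recursion (free ends ->
        uniform end weights differ from a plain HMM by exactly log n)."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(12)
        n = 3
        model = random_toy_model(rng, n, n_components=1, free_ends=True)
        # force uniform start/end so the end term is a known constant
        model.start_probs = np.full(n, 1.0 / n)
        model.end_probs = np.full(n, 1.0 / n)
        X = rng.normal(size=(7, 1))
        ref = hmmlearn.GaussianHMM(n_components=n, covariance_type="diag",
                                   init_params="")
        ref.startprob_ = model.start_probs
        ref.transmat_ = model.transitions
        ref.means_ = np.concatenate([e.means for e in model.emissions])
        ref.covars_ = np.concatenate([e.variances for e in model.emissions])
        expected = ref.score(X) - np.log(n)
        assert loglik(model, X) == pytest.approx(expected, abs=1e-8)


def _bw_one_iteration_oracle(model, X):
    """Exact EM re-estimation for one sequence via path enumeration.

    Computes posterior path probabilities exhaustively and derives expected
    transition counts and state occupancies, independently of the
    forward-backward code.
    """
    paths, scores = enumerate_paths_log_scores(model, X)
    post = np.exp(scores - logsumexp(scores))
    n = model.n_states
    T = len(X)
    xi = np.zeros((n, n))
    gamma = np.zeros((T, n))
    for p, w in zip(paths, post):
        for t in range(T - 1):
            xi[p[t], p[t + 1]] += w
        for t in range(T):
            gamma[t, p[t]] += w
    A = np.where(model.structure_mask, xi, 0.0)
    rows = A.sum(axis=1)
    for i in range(n):
        A[i] = A[i] / rows[i] if rows[i] > 0 else model.transitions[i]
    occ = gamma.sum(axis=0)
    means = (gamma.T @ X) / occ[:, None]
    second = (gamma.T @ X ** 2) / occ[:, None]
    return A, means, np.maximum(second - means ** 2, 1e-6)


class TestBaumWelch:
    def test_single_iteration_matches_enumeration_oracle(self):
        """One EM iteration on a 2-state, 1-component toy equals exact
        re-estimation from exhaustively enumerated path posteriors."""
        rng = np.random.default_rng(21)
        model = random_toy_model(rng, 2, n_components=1, free_ends=True)
        X = rng.normal(size=(5, 1))
        A_exp, means_exp, vars_exp = _bw_one_iteration_oracle(model, X)
        trained, report = baum_welch(model, [X], max_iter=1)
        np.testing.assert_allclose(trained.transitions, A_exp, atol=1e-10)
        got_means = np.concatenate([e.means for e in trained.emissions])
        got_vars = np.concatenate([e.variances for e in trained.emissions])
        np.testing.assert_allclose(got_means, means_exp, atol=1e-10)
        np.testing.assert_allclose(got_vars, vars_exp, atol=1e-10)
        assert report.n_iterations == 1

    @pytest.mark.parametrize("case", range(20))
    def test_loglikelihood_monotone_and_structure_preserved(self, case):
        rng = np.random.default_rng(300 + case)
        n = int(rng.integers(2, 5))
        wrap = bool(rng.integers(0, 2))
        free = bool(rng.integers(0, 2))
        model = random_toy_model(rng, n, n_components=int(rng.integers(1, 3)),
                                 wrap_edge=wrap, free_ends=free)
        seqs = [rng.normal(size=(int(rng.integers(n, 15)), 1)) for _ in range(4)]
        trained, report = baum_welch(model, seqs, max_iter=10)
        ll = np.array(report.log_likelihood_per_iteration)
        assert np.all(np.diff(ll) >= -1e-6), f"log-likelihood decreased: {ll}"
        assert report.n_iterations <= 10
        mask = trained.structure_mask
        assert np.all(trained.transitions[~mask] == 0.0)
        np.testing.assert_allclose(trained.transitions.sum(axis=1), 1.0,
                                   atol=1e-9)
        np.testing.assert_array_equal(trained.start_probs, model.start_probs)
        np.testing.assert_array_equal(trained.end_probs, model.end_probs)

    def test_fixed_point_stops_after_one_iteration(self):
        rng = np.random.default_rng(33)
        model = random_toy_model(rng, 2, free_ends=True)
        seqs = [rng.normal(size=(8, 1)) for _ in range(3)]
        trained, _ = baum_welch(model, seqs, max_iter=500, tol=1e-13)
        again, report = baum_welch(trained, seqs, max_iter=10, tol=1e-4)
        assert report.n_iterations == 1 and report.converged
        np.testing.assert_allclose(again.transitions, trained.transitions,
                                   atol=1e-6)

    def test_iteration_cap_is_respected(self):
        rng = np.random.default_rng(44)
        model = random_toy_model(rng, 3, free_ends=True)
        seqs = [rng.normal(size=(12, 1)) for _ in range(5)]
        _, report = baum_welch(model, seqs, max_iter=10, tol=0.0)
        assert report.n_iterations <= 10


class TestCombination:
    def _toy_pair(self, rng, m=2, n=3):
        trans = random_toy_model(rng, m, wrap_edge=True, free_ends=True)
        stride = random_toy_model(rng, n, free_ends=False)
        return trans, stride

    def test_combined_layout_and_stochasticity(self):
        rng = np.random.default_rng(55)
        trans, stride = self._toy_pair(rng, m=2, n=3)
        bout = [("transition", rng.normal(size=(5, 1))),
                ("stride", rng.normal(size=(6, 1))),
                ("transition", rng.normal(size=(5, 1)))]
        combined = combine_models(trans, stride, [bout])
        assert combined.n_states == 5
        assert combined.state_class == ["transition"] * 2 + ["stride"] * 3
        assert combined.stride_first_state == 2
        assert combined.stride_last_state == 4
        np.testing.assert_allclose(combined.transitions.sum(axis=1), 1.0,
                                   atol=1e-12)

    def test_back_to_back_strides_create_wrap_edge(self):
        """Consecutive strides in a training bout must put mass on the
        stride-last -> stride-first edge of the combined matrix."""
        rng = np.random.default_rng(66)
        trans, stride = self._toy_pair(rng, m=2, n=3)
        bout = [("transition", rng.normal(size=(4, 1))),
                ("stride", rng.normal(size=(7, 1))),
                ("stride", rng.normal(size=(7, 1))),
                ("transition", rng.normal(size=(4, 1)))]
        combined = combine_models(trans, stride, [bout])
        assert combined.transitions[combined.stride_last_state,
                                    combined.stride_first_state] > 0

    def test_emissions_copied_unchanged(self):
        rng = np.random.default_rng(77)
        trans, stride = self._toy_pair(rng)
        bout = [("transition", rng.normal(size=(4, 1))),
                ("stride", rng.normal(size=(6, 1)))]
        combined = combine_models(trans, stride, [bout])
        for got, src in zip(combined.emissions,
                            list(trans.emissions) + list(stride.emissions)):
            np.testing.assert_array_equal(got.means, src.means)
            np.testing.assert_array_equal(got.variances, src.variances)

    def test_bout_without_stride_segment_is_an_error(self):
        rng = np.random.default_rng(88)
        trans, stride = self._toy_pair(rng)
        with pytest.raises(ValueError, match="stride segment"):
            combine_models(trans, stride,
                           [[("transition", rng.normal(size=(4, 1)))]])


class TestStridePrediction:
    def _combined_toy(self, m=2, n=3, d=1):
        """Deterministic combined model whose emissions pin the state path."""
        total = m + n
        A = np.full((total, total), 1.0 / total)  # ergodic: emissions pin the path
        emissions = [GmmEmission([1.0], [[float(i)]], [[0.05]])
                     for i in range(total)]
        return CombinedHmm(transitions=A,
                           state_class=["transition"] * m + ["stride"] * n,
                           emissions=emissions,
                           start_probs=np.full(total, 1.0 / total),
                           end_probs=np.full(total, 1.0 / total))

    def test_all_transition_path_yields_no_strides(self):
        model = self._combined_toy()
        X = np.zeros((6, 1))  # emissions pin state 0 (transition class)
        gyr = np.zeros(6)
        strides, path = predict_strides(model, X, gyr, fs=51.2)
        assert strides == []
        assert all(model.state_class[s] == "transition" for s in path)

    def test_single_stride_with_borders_at_negative_peaks(self):
        """A T..T S..S T..T path over a one-stride signal must produce one
        stride whose borders sit on the signal's two negative peaks."""
        model = self._combined_toy(m=2, n=3)
        # observation sequence forcing T T S0 S1 S2 T T (states 0,0,2,3,4,1,1)
        obs = np.array([0, 0, 2, 3, 4, 1, 1], dtype=float)[:, None]
        gyr = np.array([5, 1, -8, 7, -9, 2, 5], dtype=float)
        strides, path = predict_strides(model, obs, gyr, fs=51.2)
        np.testing.assert_array_equal(path, [0, 0, 2, 3, 4, 1, 1])
        # borders snap to the minima inside the flanking run unions
        assert strides == [(2, 4)]

    def test_two_strides_share_one_border_via_wrap(self):
        model = self._combined_toy(m=1, n=2)
        # states: 0=T, 1=S_first, 2=S_last; wrap 2->1 allowed by cyclic A
        obs = np.array([0, 1, 2, 1, 2, 0], dtype=float)[:, None]
        gyr = np.array([4, -5, 3, -6, -2, 6], dtype=float)
        strides, path = predict_strides(model, obs, gyr, fs=51.2)
        np.testing.assert_array_equal(path, [0, 1, 2, 1, 2, 0])
        assert len(strides) == 2
        assert strides[0][1] == strides[1][0]  # shared border sample

    def test_offset_shifts_reported_intervals(self):
        model = self._combined_toy(m=2, n=3)
        obs = np.array([0, 0, 2, 3, 4, 1, 1], dtype=float)[:, None]
        gyr = np.array([5, 1, -8, 7, -9, 2, 5], dtype=float)
        strides, _ = predict_strides(model, obs, gyr, fs=51.2, offset=100)
        assert strides == [(102, 104)]


class TestSerialization:
    def test_left_right_round_trip(self):
        rng = np.random.default_rng(99)
        model = random_toy_model(rng, 3, n_components=2, wrap_edge=True)
        clone = LeftRightHmm.from_dict(model.to_dict())
        np.testing.assert_allclose(clone.transitions, model.transitions)
        np.testing.assert_allclose(clone.emissions[1].means,
                                   model.emissions[1].means)

    def test_combined_round_trip(self):
        rng = np.random.default_rng(111)
        trans = random_toy_model(rng, 2, wrap_edge=True, free_ends=True)
        stride = random_toy_model(rng, 3)
        bout = [("transition", rng.normal(size=(4, 1))),
                ("stride", rng.normal(size=(6, 1)))]
        combined = combine_models(trans, stride, [bout])
        clone = CombinedHmm.from_dict(combined.to_dict())
        np.testing.assert_allclose(clone.transitions, combined.transitions)
        assert clone.state_class == combined.state_class
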