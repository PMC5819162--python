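"""HMM correctness: oracle equivalence, EM behaviour, decoding, selection."""

import itertools

import numpy as np
import pytest
from sklearn.base import clone

from chromasig.hmm import (
    BernoulliChromatinHMM,
    ChromatinStateModel,
    baum_welch,
    decode,
    emission_logprob,
    forward_loglik,
    load_model,
    match_states,
    min_emission_distance,
    posterior_marginals,
    save_model,
    select_model,
)


def random_model(rng, K, M):
    E = rng.uniform(0.05, 0.95, size=(K, M))
    A = rng.dirichlet(np.ones(K), size=K)
    pi = rng.dirichlet(np.ones(K))
    return ChromatinStateModel(E, A, pi, [f"m{i}" for i in range(M)])


def enumerate_paths(model, X):
    """Brute-force oracle: sum/argmax over all K**T state paths."""
    K = model.n_states
    T = len(X)
    total = 0.0
    best_lp, best_path = -np.inf, None
    marginals = np.zeros((T, K))
    for path in itertools.product(range(K), repeat=T):
        lp = np.log(model.start[path[0]])
        for t, k in enumerate(path):
            for m in range(model.n_marks):
                p = model.emission[k, m]
                lp += np.log(p if X[t, m] else 1 - p)
            if t > 0:
                lp += np.log(model.transition[path[t - 1], k])
        total += np.exp(lp)
        for t, k in enumerate(path):
            marginals[t, k] += np.exp(lp)
        if lp > best_lp:
            best_lp, best_path = lp, path
    return np.log(total), best_path, marginals / total


def sample_from(model, T, rng):
    states = np.empty(T, dtype=int)
    states[0] = rng.choice(model.n_states, p=model.start)
    for t in range(1, T):
        states[t] = rng.choice(model.n_states, p=model.transition[states[t - 1]])
    X = (rng.random((T, model.n_marks)) < model.emission[states]).astype(np.int8)
    return states, X


class TestEmission:
    def test_single_state_single_mark(self):
        model = ChromatinStateModel([[0.5]], [[1.0]], [1.0], ["m"])
        assert emission_logprob(model, [1])[0] == pytest.approx(np.log(0.5))

    def test_hand_product(self):
        model = ChromatinStateModel([[0.9, 0.1]], [[1.0]], [1.0], ["a", "b"])
        assert emission_logprob(model, [1, 0])[0] == pytest.approx(np.log(0.9 * 0.9))

    def test_normalization_over_observation_space(self, rng):
        model = random_model(rng, K=3, M=4)
        total = np.zeros(3)
        for bits in itertools.product((0, 1), repeat=4):
            total += np.exp(emission_logprob(model, list(bits)))
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_non_binary_rejected(self, rng):
        model = random_model(rng, 2, 2)
        with pytest.raises(ValueError):
            emission_logprob(model, [1, 2])


class TestForwardViterbiPosterior:
    def test_k1_is_sum_of_emissions(self, rng):
        model = random_model(rng, 1, 3)
        X = rng.integers(0, 2, size=(10, 3))
        expected = sum(emission_logprob(model, x)[0] for x in X)
        assert forward_loglik(model, X) == pytest.approx(expected, abs=1e-9)

    def test_matches_enumeration(self, rng):
        for _ in range(25):
            K = int(rng.integers(2, 4))
            M = int(rng.integers(1, 3))
            T = int(rng.integers(2, 7))
            model = random_model(rng, K, M)
            X = rng.integers(0, 2, size=(T, M))
            ll_oracle, path_oracle, marg_oracle = enumerate_paths(model, X)
            assert forward_loglik(model, X) == pytest.approx(ll_oracle, abs=1e-10)
            got_path = tuple(decode(model, X, "viterbi"))
            if got_path != path_oracle:  # ties: paths must be equally probable
                lp = lambda p: sum(
                    emission_logprob(model, X[t])[k]
                    + (np.log(model.transition[p[t - 1], k]) if t else np.log(model.start[k]))
                    for t, k in enumerate(p)
                )
                assert lp(got_path) == pytest.approx(lp(path_oracle), abs=1e-10)
            np.testing.assert_allclose(
                posterior_marginals(model, X), marg_oracle, atol=1e-10
            )

    def test_permutation_symmetry(self, rng):
        model = random_model(rng, 3, 2)
        X = rng.integers(0, 2, size=(50, 2))
        perm = np.array([2, 0, 1])
        assert forward_loglik(model, X) == pytest.approx(
            forward_loglik(model.permuted(perm), X), abs=1e-8
        )

    def test_posterior_rows_sum_to_one(self, rng):
        model = random_model(rng, 4, 3)
        X = rng.integers(0, 2, size=(200, 3))
        gamma = posterior_marginals(model, X)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_viterbi_beats_random_paths(self, rng):
        model = random_model(rng, 3, 2)
        _, X = sample_from(model, 30, rng)

        def path_lp(path):
            lp = np.log(model.start[path[0]])
            for t, k in enumerate(path):
                lp += emission_logprob(model, X[t])[k]
                if t:
                    lp += np.log(model.transition[path[t - 1], k])
            return lp

        best = path_lp(decode(model, X, "viterbi"))
        for _ in range(1000):
            assert best >= path_lp(rng.integers(0, 3, size=30)) - 1e-9

    def test_viterbi_ties_break_low(self):
        # fully symmetric two-state model: every path has equal probability
        model = ChromatinStateModel(
            [[0.5], [0.5]], [[0.5, 0.5], [0.5, 0.5]], [0.5, 0.5], ["m"]
        )
        path = decode(model, np.ones((5, 1), dtype=int), "viterbi")
        np.testing.assert_array_equal(path, 0)

    def test_k1_decodes_constant(self, rng):
        model = random_model(rng, 1, 2)
        assert np.all(decode(model, rng.integers(0, 2, (20, 2)), "viterbi") == 0)

    def test_matches_hmmlearn_forward(self, rng):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        from chromasig.hmm import encode_symbols, symbol_emission

        model = random_model(rng, 3, 4)
        _, X = sample_from(model, 300, rng)
        ref = hmmlearn.CategoricalHMM(n_components=3, n_features=16)
        ref.startprob_ = model.start
        ref.transmat_ = model.transition
        ref.emissionprob_ = symbol_emission(model.emission)
        sym = encode_symbols(X).reshape(-1, 1)
        assert forward_loglik(model, X) == pytest.approx(ref.score(sym), abs=1e-6)


class TestBaumWelch:
    def test_k1_closed_form(self, rng):
        X = rng.integers(0, 2, size=(500, 3))
        model, _ = baum_welch([X], 1, seed=0, max_iter=5)
        np.testing.assert_allclose(model.emission[0], X.mean(axis=0), atol=1e-9)

    def test_loglik_trace_monotone(self, rng):
        gen = random_model(rng, 3, 3)
        _, X = sample_from(gen, 2000, rng)
        est = BernoulliChromatinHMM(3, random_state=0, n_init=1, max_iter=50).fit(X)
        assert np.all(np.diff(est.loglik_trace_) >= -1e-8)

    def test_same_seed_identical(self, rng):
        X = rng.integers(0, 2, size=(1000, 2))
        m1, t1 = baum_welch([X], 3, seed=5, max_iter=20)
        m2, t2 = baum_welch([X], 3, seed=5, max_iter=20)
        np.testing.assert_array_equal(m1.emission, m2.emission)
        np.testing.assert_array_equal(t1, t2)

    def test_degenerate_input_warns_not_crashes(self):
        X = np.ones((200, 2), dtype=int)
        with pytest.warns(UserWarning, match="identical"):
            model, _ = baum_welch([X], 2, seed=0, max_iter=10)
        assert model.n_states == 2

    def test_parameter_recovery_small(self, rng):
        gen = ChromatinStateModel(
            [[0.95, 0.05], [0.05, 0.95], [0.95, 0.95]],
            np.full((3, 3), 0.05) + np.eye(3) * 0.85,
            np.full(3, 1 / 3),
            ["a", "b"],
        )
        _, X = sample_from(gen, 20_000, rng)
        model, _ = baum_welch([X], 3, seed=0)
        order = match_states(gen.emission, model.emission)
        assert np.abs(model.emission[order] - gen.emission).max() < 0.05

    def test_near_deterministic_round_trip(self, rng):
        # 5-mark patterns with pairwise Hamming distance >= 3 at 0.995/0.005:
        # a single flipped mark can never make another state as likely, so
        # decoding recovers the sampled path exactly
        lo, hi = 0.005, 0.995
        E = np.array(
            [
                [lo, lo, lo, lo, lo],
                [hi, hi, hi, lo, lo],
                [lo, lo, hi, hi, hi],
            ]
        )
        gen = ChromatinStateModel(
            E, np.full((3, 3), 0.05) + np.eye(3) * 0.85, np.full(3, 1 / 3), list("abcde")
        )
        states, X = sample_from(gen, 1000, rng)
        np.testing.assert_array_equal(decode(gen, X, "viterbi"), states)
        np.testing.assert_array_equal(decode(gen, X, "posterior"), states)


class TestEstimatorInterface:
    def test_clone_and_params(self):
        est = BernoulliChromatinHMM(5, tol=1e-3)
        est2 = clone(est)
        assert est2.get_params()["n_states"] == 5
        est2.set_params(n_states=7)
        assert est2.n_states == 7

    def test_predict_shapes(self, rng):
        X = rng.integers(0, 2, size=(300, 2))
        est = BernoulliChromatinHMM(2, random_state=0, n_init=1, max_iter=10).fit(
            X, lengths=[100, 200]
        )
        assert est.predict(X, lengths=[100, 200]).shape == (300,)
        proba = est.predict_proba(X)
        assert proba.shape == (300, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_bad_lengths(self, rng):
        X = rng.integers(0, 2, size=(10, 2))
        with pytest.raises(ValueError):
            BernoulliChromatinHMM(2).fit(X, lengths=[4, 4])


class TestModelSelection:
    def test_k_range_of_one(self, rng):
        X = rng.integers(0, 2, size=(500, 2))
        model, diag = select_model([X], [3], seed=0, max_iter=10, n_init=1)
        assert model.n_states == 3
        assert list(diag.index) == [3]
        assert diag.loc[3, "chosen"]

    def test_loglik_non_decreasing_in_k(self, rng):
        gen = random_model(rng, 2, 3)
        _, X = sample_from(gen, 5000, rng)
        _, diag = select_model([X], [1, 2, 3], seed=0, max_iter=100, n_init=5)
        lls = diag.loglik.to_numpy()
        assert np.all(np.diff(lls) >= -1e-6 * np.abs(lls[:-1]))

    def test_min_emission_distance(self):
        assert min_emission_distance(np.array([[0.0, 0.0], [0.3, 0.4]])) == pytest.approx(0.5)
        assert min_emission_distance(np.array([[0.1, 0.1]])) == np.inf


class TestModelIO:
    def test_save_load_round_trip(self, rng, tmp_path):
        model = random_model(rng, 4, 3)
        model.state_labels = ["A", "B", "C", "D"]
        save_model(model, tmp_path / "e.tsv", tmp_path / "t.tsv")
        back = load_model(tmp_path / "e.tsv", tmp_path / "t.tsv")
        np.testing.assert_allclose(back.emission, model.emission, atol=1e-6)
        np.testing.assert_allclose(back.transition, model.transition, atol=2e-6)
        assert back.state_labels == model.state_labels
        assert back.mark_names == model.mark_names
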