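"""Multivariate Bernoulli hidden Markov model over binarized histone marks.

Each genomic bin carries an M-vector of 0/1 mark calls; a hidden chromatin
state k emits the marks as independent Bernoullis with parameters
``E[k, m]``. Training is Baum-Welch over the concatenated per-cell-line,
per-chromosome sequences (no transitions across sequence boundaries; the
initial distribution applies at each sequence start). Since observations are
binary M-vectors, each bin is encoded as one of 2**M symbols and the
forward/backward/Viterbi recursions run on a K x 2**M symbol-likelihood
table (numba-compiled, scaled linear space).

The estimator :class:`BernoulliChromatinHMM` follows the hmmlearn/sklearn
convention: ``fit(X, lengths)`` with X a (sum(lengths), M) binary matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

EMISSION_FLOOR = 1e-6


# ----------------------------------------------------------------- model type

@dataclass
class ChromatinStateModel:
    """Trained (or generating) chromatin-state HMM parameters.

    emission : (K, M) Bernoulli parameters, state x mark
    transition : (K, K) row-stochastic
    start : (K,) initial state distribution
    """

    emission: np.ndarray
    transition: np.ndarray
    start: np.ndarray
    mark_names: list[str]
    state_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.emission = np.asarray(self.emission, dtype=np.float64)
        self.transition = np.asarray(self.transition, dtype=np.float64)
        self.start = np.asarray(self.start, dtype=np.float64)
        K, M = self.emission.shape
        if self.transition.shape != (K, K):
            raise ValueError("transition matrix shape mismatch")
        if self.start.shape != (K,):
            raise ValueError("initial distribution shape mismatch")
        if len(self.mark_names) != M:
            raise ValueError("mark_names length mismatch")
        if np.any(self.emission < 0) or np.any(self.emission > 1):
            raise ValueError("emission parameters outside [0, 1]")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.start.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")
        if self.state_labels is not None and len(self.state_labels) != K:
            raise ValueError("state_labels length mismatch")

    @property
    def n_states(self) -> int:
        return self.emission.shape[0]

    @property
    def n_marks(self) -> int:
        return self.emission.shape[1]

    def labels_or_default(self) -> list[str]:
        return self.state_labels or [f"E{k + 1}" for k in range(self.n_states)]

    def permuted(self, order: np.ndarray) -> "ChromatinStateModel":
        """The same model with states re-indexed by ``order``."""
        order = np.asarray(order)
        labels = None
        if self.state_labels is not None:
            labels = [self.state_labels[i] for i in order]
        return ChromatinStateModel(
            self.emission[order],
            self.transition[np.ix_(order, order)],
            self.start[order],
            list(self.mark_names),
            labels,
        )


def save_model(model: ChromatinStateModel, emissions_path, transitions_path) -> None:
    """Write emission/transition tables in the ChromHMM TSV layout."""
    labels = model.labels_or_default()
    pd.DataFrame(model.emission, index=labels, columns=model.mark_names).to_csv(
        emissions_path, sep="\t", float_format="%.6f"
    )
    trans = pd.DataFrame(model.transition, index=labels, columns=labels)
    trans.insert(0, "initial", model.start)
    trans.to_csv(transitions_path, sep="\t", float_format="%.6f")


def load_model(emissions_path, transitions_path) -> ChromatinStateModel:
    em = pd.read_csv(emissions_path, sep="\t", index_col=0)
    tr = pd.read_csv(transitions_path, sep="\t", index_col=0)
    start = tr.pop("initial").to_numpy()
    return ChromatinStateModel(
        em.to_numpy(), tr.to_numpy(), start, list(em.columns), list(em.index)
    )


# ------------------------------------------------------------- symbol encoding

def encode_symbols(X: np.ndarray) -> np.ndarray:
    """Pack a (T, M) binary matrix into per-bin symbol indices in [0, 2**M)."""
    X = np.ascontiguousarray(X)
    if X.ndim != 2:
        raise ValueError("observations must be a (T, M) matrix")
    if X.size and not np.isin(X, (0, 1)).all():
        raise ValueError("observations must be binary")
    M = X.shape[1]
    if M > 20:
        raise ValueError(f"{M} marks exceed the 2**M symbol encoding limit")
    weights = (1 << np.arange(M)).astype(np.int64)
    return (X.astype(np.int64) @ weights).astype(np.int64)


def symbol_emission(emission: np.ndarray, floor: float = EMISSION_FLOOR) -> np.ndarray:
    """(K, 2**M) table of P(symbol | state) from Bernoulli parameters."""
    E = np.clip(emission, floor, 1.0 - floor)
    K, M = E.shape
    S = 1 << M
    bits = ((np.arange(S)[:, None] >> np.arange(M)[None, :]) & 1).astype(np.float64)
    logB = bits @ np.log(E).T + (1.0 - bits) @ np.log1p(-E).T  # (S, K)
    return np.exp(logB.T)


# ------------------------------------------------------------- numba kernels

@njit(cache=True)
def _forward_ll(sym, B, A, pi):
    T = sym.shape[0]
    K = B.shape[0]
    alpha = np.empty(K)
    prev = np.empty(K)
    ll = 0.0
    tot = 0.0
    for k in range(K):
        alpha[k] = pi[k] * B[k, sym[0]]
        tot += alpha[k]
    ll += np.log(tot)
    for k in range(K):
        alpha[k] /= tot
    for t in range(1, T):
        for k in range(K):
            prev[k] = alpha[k]
        tot = 0.0
        for k in range(K):
            a = 0.0
            for j in range(K):
                a += prev[j] * A[j, k]
            a *= B[k, sym[t]]
            alpha[k] = a
            tot += a
        ll += np.log(tot)
        for k in range(K):
            alpha[k] /= tot
    return ll


@njit(cache=True)
def _fb_accumulate_pairs(sym, B, A, pi, Gsym, Xi, gamma0, Pair):
    """E-step pass that also accumulates within-state symbol-pair counts.

    Pair[j, s, s'] += P(state_t = j, state_{t+1} = j | obs) for consecutive
    bins with symbols (s, s') — the statistic that exposes hidden
    substructure inside a state (a true state emits i.i.d. given the state,
    so its lag-1 symbol covariance vanishes).
    """
    T = sym.shape[0]
    K = B.shape[0]
    alpha = np.empty((T, K))
    c = np.empty(T)
    tot = 0.0
    for k in range(K):
        alpha[0, k] = pi[k] * B[k, sym[0]]
        tot += alpha[0, k]
    c[0] = tot
    for k in range(K):
        alpha[0, k] /= tot
    for t in range(1, T):
        tot = 0.0
        st = sym[t]
        for k in range(K):
            a = 0.0
            for j in range(K):
                a += alpha[t - 1, j] * A[j, k]
            a *= B[k, st]
            alpha[t, k] = a
            tot += a
        c[t] = tot
        for k in range(K):
            alpha[t, k] /= tot
    ll = 0.0
    for t in range(T):
        ll += np.log(c[t])
    beta = np.ones(K)
    for k in range(K):
        Gsym[k, sym[T - 1]] += alpha[T - 1, k]
    if T == 1:
        for k in range(K):
            gamma0[k] += alpha[0, k]
        return ll
    newbeta = np.empty(K)
    for t in range(T - 2, -1, -1):
        st1 = sym[t + 1]
        st = sym[t]
        for j in range(K):
            b = 0.0
            for k in range(K):
                w = A[j, k] * B[k, st1] * beta[k]
                b += w
                xi = alpha[t, j] * w / c[t + 1]
                Xi[j, k] += xi
                if j == k:
                    Pair[j, st, st1] += xi
            newbeta[j] = b / c[t + 1]
        for j in range(K):
            g = alpha[t, j] * newbeta[j]
            Gsym[j, st] += g
            if t == 0:
                gamma0[j] += g
        for k in range(K):
            beta[k] = newbeta[k]
    return ll


@njit(cache=True)
def _fb_accumulate(sym, B, A, pi, Gsym, Xi, gamma0):
    """One E-step pass; accumulates sufficient statistics in-place.

    Gsym[k, s] += sum_t gamma_t[k] over bins with symbol s;
    Xi[j, k]   += expected j->k transition counts;
    gamma0[k]  += posterior state distribution at t=0.
    Returns the sequence log-likelihood.
    """
    T = sym.shape[0]
    K = B.shape[0]
    alpha = np.empty((T, K))
    c = np.empty(T)
    tot = 0.0
    for k in range(K):
        alpha[0, k] = pi[k] * B[k, sym[0]]
        tot += alpha[0, k]
    c[0] = tot
    for k in range(K):
        alpha[0, k] /= tot
    for t in range(1, T):
        tot = 0.0
        st = sym[t]
        for k in range(K):
            a = 0.0
            for j in range(K):
                a += alpha[t - 1, j] * A[j, k]
            a *= B[k, st]
            alpha[t, k] = a
            tot += a
        c[t] = tot
        for k in range(K):
            alpha[t, k] /= tot
    ll = 0.0
    for t in range(T):
        ll += np.log(c[t])

    beta = np.ones(K)
    for k in range(K):
        Gsym[k, sym[T - 1]] += alpha[T - 1, k]
    if T == 1:
        for k in range(K):
            gamma0[k] += alpha[0, k]
        return ll
    newbeta = np.empty(K)
    for t in range(T - 2, -1, -1):
        st1 = sym[t + 1]
        for j in range(K):
            b = 0.0
            for k in range(K):
                w = A[j, k] * B[k, st1] * beta[k]
                b += w
                Xi[j, k] += alpha[t, j] * w / c[t + 1]
            newbeta[j] = b / c[t + 1]
        st = sym[t]
        for j in range(K):
            g = alpha[t, j] * newbeta[j]
            Gsym[j, st] += g
            if t == 0:
                gamma0[j] += g
        for k in range(K):
            beta[k] = newbeta[k]
    return ll


@njit(cache=True)
def _posterior(sym, B, A, pi):
    T = sym.shape[0]
    K = B.shape[0]
    alpha = np.empty((T, K))
    c = np.empty(T)
    tot = 0.0
    for k in range(K):
        alpha[0, k] = pi[k] * B[k, sym[0]]
        tot += alpha[0, k]
    c[0] = tot
    for k in range(K):
        alpha[0, k] /= tot
    for t in range(1, T):
        tot = 0.0
        st = sym[t]
        for k in range(K):
            a = 0.0
            for j in range(K):
                a += alpha[t - 1, j] * A[j, k]
            a *= B[k, st]
            alpha[t, k] = a
            tot += a
        c[t] = tot
        for k in range(K):
            alpha[t, k] /= tot
    gamma = np.empty((T, K))
    beta = np.ones(K)
    for k in range(K):
        gamma[T - 1, k] = alpha[T - 1, k]
    newbeta = np.empty(K)
    for t in range(T - 2, -1, -1):
        st1 = sym[t + 1]
        for j in range(K):
            b = 0.0
            for k in range(K):
                b += A[j, k] * B[k, st1] * beta[k]
            newbeta[j] = b / c[t + 1]
        for j in range(K):
            gamma[t, j] = alpha[t, j] * newbeta[j]
            beta[j] = newbeta[j]
    return gamma


@njit(cache=True)
def _viterbi(sym, logB, logA, logpi):
    T = sym.shape[0]
    K = logB.shape[0]
    delta = np.empty((T, K))
    back = np.zeros((T, K), dtype=np.int32)
    for k in range(K):
        delta[0, k] = logpi[k] + logB[k, sym[0]]
    for t in range(1, T):
        st = sym[t]
        for k in range(K):
            best = delta[t - 1, 0] + logA[0, k]
            arg = 0
            for j in range(1, K):
                v = delta[t - 1, j] + logA[j, k]
                if v > best:  # strict: ties keep the lowest state index
                    best = v
                    arg = j
            delta[t, k] = best + logB[k, st]
            back[t, k] = arg
    path = np.empty(T, dtype=np.int32)
    best = delta[T - 1, 0]
    arg = 0
    for k in range(1, K):
        if delta[T - 1, k] > best:
            best = delta[T - 1, k]
            arg = k
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def _em_loop(syms, M, E, A, pi, tol, max_iter, floor=EMISSION_FLOOR):
    """Baum-Welch iterations over encoded sequences until the per-observation
    log-likelihood gain drops below ``tol``."""
    K = E.shape[0]
    S = 1 << M
    T_total = sum(len(s) for s in syms)
    bits = ((np.arange(S)[:, None] >> np.arange(M)[None, :]) & 1).astype(np.float64)
    trace = []
    prev_ll = -np.inf
    converged = False
    for it in range(max_iter):
        B = symbol_emission(E, floor)
        Gsym = np.zeros((K, S))
        Xi = np.zeros((K, K))
        gamma0 = np.zeros(K)
        ll = 0.0
        for sym in syms:
            ll += _fb_accumulate(sym, B, A, pi, Gsym, Xi, gamma0)
        trace.append(ll)
        state_mass = Gsym.sum(axis=1)
        safe = np.maximum(state_mass, 1e-300)
        E = np.clip((Gsym @ bits) / safe[:, None], floor, 1 - floor)
        rows = Xi.sum(axis=1)
        A = np.where(rows[:, None] > 0, Xi / np.maximum(rows, 1e-300)[:, None], 1.0 / K)
        A /= A.sum(axis=1, keepdims=True)
        pi = gamma0 / gamma0.sum()
        if it > 0 and (ll - prev_ll) / T_total < tol:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    return E, A, pi, np.array(trace), converged


# ----------------------------------------------------------- free functions

def emission_logprob(model: ChromatinStateModel, obs_vector) -> np.ndarray:
    """log P(mark vector | state) for every state, length K."""
    x = np.asarray(obs_vector, dtype=np.float64)
    if x.shape != (model.n_marks,) or not np.isin(x, (0, 1)).all():
        raise ValueError("observation must be a binary vector of length M")
    E = np.clip(model.emission, EMISSION_FLOOR, 1 - EMISSION_FLOOR)
    return (np.log(E) * x + np.log1p(-E) * (1 - x)).sum(axis=1)


def forward_loglik(model: ChromatinStateModel, sequence) -> float:
    """Total log-likelihood of one (T, M) binary sequence under the model."""
    sym = encode_symbols(np.asarray(sequence))
    B = symbol_emission(model.emission)
    return float(_forward_ll(sym, B, model.transition, model.start))


def decode(model: ChromatinStateModel, sequence, mode: str = "viterbi") -> np.ndarray:
    """Per-bin state indices for one sequence (``viterbi`` or ``posterior``)."""
    sym = encode_symbols(np.asarray(sequence))
    B = symbol_emission(model.emission)
    if mode == "viterbi":
        with np.errstate(divide="ignore"):
            logA = np.log(model.transition)
            logpi = np.log(model.start)
        return np.asarray(_viterbi(sym, np.log(B), logA, logpi))
    if mode == "posterior":
        gamma = _posterior(sym, B, model.transition, model.start)
        return np.asarray(gamma).argmax(axis=1).astype(np.int32)
    raise ValueError(f"unknown decode mode {mode!r}")


def posterior_marginals(model: ChromatinStateModel, sequence) -> np.ndarray:
    """(T, K) posterior state probabilities per bin."""
    sym = encode_symbols(np.asarray(sequence))
    B = symbol_emission(model.emission)
    return np.asarray(_posterior(sym, B, model.transition, model.start))


# --------------------------------------------------------------- estimator

class BernoulliChromatinHMM(BaseEstimator):
    """Chromatin-state HMM with Bernoulli-product emissions (sklearn-style).

    Parameters
    ----------
    n_states : number of hidden chromatin states K.
    self_transition : initial self-transition boost; the starting transition
        matrix is ``self_transition * I + (1 - self_transition)/K``.
    n_init : independent random restarts (of the base fit); the fit with
        the best final log-likelihood is kept.
    fit_strategy : ``split`` (default) grows the model from K=2 by
        repeatedly splitting the state with the most within-state excess
        covariance and re-running EM — markedly more robust against
        state-merging local optima than restarts at K around 13;
        ``restart`` fits the full K directly from ``n_init`` random
        initializations.
    tol : EM stopping rule, per-observation log-likelihood gain.
    max_iter : EM iteration cap.
    random_state : seed for the emission initialization.
    emission_floor : emissions are clipped to [floor, 1-floor] each M-step.

    Attributes (after fit)
    ----------------------
    emissionprob_ : (K, M) Bernoulli emission parameters.
    transmat_ : (K, K) transition matrix.
    startprob_ : (K,) initial distribution.
    loglik_trace_ : per-iteration total log-likelihood (non-decreasing).
    n_iter_, converged_ : EM bookkeeping of the selected restart.
    """

    def __init__(
        self,
        n_states: int = 13,
        *,
        self_transition: float = 0.5,
        n_init: int = 3,
        fit_strategy: str = "split",
        tol: float = 1e-6,
        max_iter: int = 300,
        random_state: int | None = None,
        emission_floor: float = EMISSION_FLOOR,
    ):
        self.n_states = n_states
        self.self_transition = self_transition
        self.n_init = n_init
        self.fit_strategy = fit_strategy
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state
        self.emission_floor = emission_floor

    # -- data plumbing ------------------------------------------------------
    @staticmethod
    def _split(X, lengths):
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be (T_total, M)")
        if lengths is None:
            return [X]
        lengths = list(lengths)
        if sum(lengths) != X.shape[0]:
            raise ValueError("lengths do not sum to X rows")
        out, pos = [], 0
        for L in lengths:
            out.append(X[pos : pos + L])
            pos += L
        return out

    def _prepare(self, X, lengths):
        seqs = self._split(X, lengths)
        return [encode_symbols(s) for s in seqs], seqs[0].shape[1]

    # -- EM -----------------------------------------------------------------
    def _init_params(self, rng, mark_freq, M, K=None):
        K = K or self.n_states
        E = mark_freq[None, :] + rng.uniform(-0.3, 0.3, size=(K, M))
        E = np.clip(E, 0.02, 0.98)
        A = np.full((K, K), (1.0 - self.self_transition) / K)
        A[np.diag_indices(K)] += self.self_transition
        pi = np.full(K, 1.0 / K)
        return E, A, pi

    def _em(self, syms, M, E, A, pi):
        return _em_loop(syms, M, E, A, pi, self.tol, self.max_iter, self.emission_floor)

    def fit(self, X, lengths=None):
        syms, M = self._prepare(X, lengths)
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.fit_strategy not in ("split", "restart"):
            raise ValueError(f"unknown fit_strategy {self.fit_strategy!r}")
        Xall = np.asarray(X, dtype=np.float64)
        mark_freq = Xall.mean(axis=0)
        if np.all(Xall == Xall[0]):
            warnings.warn("all observations identical; EM will converge trivially")
        ss = np.random.SeedSequence(self.random_state)
        base_k = self.n_states if self.fit_strategy == "restart" else min(2, self.n_states)
        best = None
        for child in ss.spawn(max(1, self.n_init)):
            rng = np.random.default_rng(child)
            E0, A0, pi0 = self._init_params(rng, mark_freq, M, K=base_k)
            fitted = self._em(syms, M, E0, A0, pi0)
            if best is None or fitted[3][-1] > best[3][-1]:
                best = fitted
        E, A, pi, trace, converged = best
        if base_k < self.n_states:
            rng = np.random.default_rng(ss.spawn(max(1, self.n_init) + 1)[-1])
            for K in range(base_k + 1, self.n_states + 1):
                mass, scores, axes = _split_scores(E, A, pi, syms, M, self.emission_floor)
                j = int((mass * scores).argmax())
                E, A, pi = _split_state(E, A, pi, j, axes[j], scores[j], rng)
                E, A, pi, trace, converged = self._em(syms, M, E, A, pi)
            # split-merge refinement: while one state still hides structure
            # and another pair is redundant, swap them and keep the move if
            # the likelihood improves
            for _ in range(5):
                if self.n_states < 3:
                    break
                mass, scores, axes = _split_scores(E, A, pi, syms, M, self.emission_floor)
                d = np.linalg.norm(E[:, None, :] - E[None, :, :], axis=-1)
                d[np.diag_indices(self.n_states)] = np.inf
                a, b = np.unravel_index(d.argmin(), d.shape)
                ranked = np.argsort(-(mass * scores))
                j = int(next(k for k in ranked if k not in (a, b)))
                accepted = False
                for magnify in (1.0, 9.0, 36.0):  # displacement ~ sqrt(scale)
                    E2, A2, pi2 = _merge_states(E, A, pi, a, b, mass)
                    j2 = j - (j > b)
                    E2, A2, pi2 = _split_state(
                        E2, A2, pi2, j2, axes[j], magnify * scores[j], rng
                    )
                    E2, A2, pi2, trace2, conv2 = self._em(syms, M, E2, A2, pi2)
                    if trace2[-1] > trace[-1]:
                        E, A, pi, trace, converged = E2, A2, pi2, trace2, conv2
                        accepted = True
                        break
                if not accepted:
                    break  # merging a genuinely distinct pair always loses
        self.emissionprob_ = E
        self.transmat_ = A
        self.startprob_ = pi
        self.loglik_trace_ = trace
        self.n_iter_ = len(trace)
        self.converged_ = converged
        self.n_features_in_ = M
        return self

    # -- inference ----------------------------------------------------------
    def to_model(self, mark_names=None, state_labels=None) -> ChromatinStateModel:
        check_is_fitted(self, "emissionprob_")
        marks = mark_names or [f"mark{m + 1}" for m in range(self.n_features_in_)]
        return ChromatinStateModel(
            self.emissionprob_, self.transmat_, self.startprob_, list(marks), state_labels
        )

    def score(self, X, lengths=None) -> float:
        check_is_fitted(self, "emissionprob_")
        syms, _ = self._prepare(X, lengths)
        B = symbol_emission(self.emissionprob_, self.emission_floor)
        return float(sum(_forward_ll(s, B, self.transmat_, self.startprob_) for s in syms))

    def predict(self, X, lengths=None, algorithm: str = "viterbi") -> np.ndarray:
        check_is_fitted(self, "emissionprob_")
        model = self.to_model()
        seqs = self._split(X, lengths)
        return np.concatenate([decode(model, s, mode=algorithm) for s in seqs])

    def predict_proba(self, X, lengths=None) -> np.ndarray:
        check_is_fitted(self, "emissionprob_")
        model = self.to_model()
        seqs = self._split(X, lengths)
        return np.vstack([posterior_marginals(model, s) for s in seqs])


# ---------------------------------------------------------------- train API

def baum_welch(
    sequences: list[np.ndarray],
    n_states: int,
    *,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 300,
    n_init: int = 3,
    fit_strategy: str = "split",
    mark_names: list[str] | None = None,
) -> tuple[ChromatinStateModel, np.ndarray]:
    """Train on a list of (T, M) binary sequences; returns (model, loglik trace)."""
    X = np.vstack(sequences)
    lengths = [len(s) for s in sequences]
    est = BernoulliChromatinHMM(
        n_states,
        tol=tol,
        max_iter=max_iter,
        n_init=n_init,
        fit_strategy=fit_strategy,
        random_state=seed,
    ).fit(X, lengths)
    return est.to_model(mark_names), est.loglik_trace_


def min_emission_distance(emission: np.ndarray) -> float:
    """Minimum pairwise Euclidean distance between state emission rows.

    Small values flag redundant (near-duplicate) states, the symptom of an
    over-specified K.
    """
    K = emission.shape[0]
    if K < 2:
        return np.inf
    d = np.linalg.norm(emission[:, None, :] - emission[None, :, :], axis=-1)
    return float(d[np.triu_indices(K, 1)].min())


def _split_scores(E, A, pi, syms, M, floor=EMISSION_FLOOR):
    """Per-state hidden-substructure diagnostics from one E-step.

    Given the state, a true Bernoulli-product HMM state emits marks i.i.d.:
    its within-state static mark covariance is diagonal mu(1-mu) and its
    lag-1 mark covariance is zero. A state covering two real mark
    combinations violates one or both — instantaneous cross-covariance when
    the hidden patterns differ in several marks, lag-1 autocovariance when
    they differ in as little as one (the substructure persists over runs of
    bins). Returns per state: posterior mass fraction, top eigenvalue of
    the combined excess-covariance matrix, and its eigenvector (the axis
    along which to split the state).
    """
    K = E.shape[0]
    S = 1 << M
    bits = ((np.arange(S)[:, None] >> np.arange(M)[None, :]) & 1).astype(np.float64)
    B = symbol_emission(E, floor)
    Gsym = np.zeros((K, S))
    Xi = np.zeros((K, K))
    gamma0 = np.zeros(K)
    Pair = np.zeros((K, S, S))
    for sym in syms:
        _fb_accumulate_pairs(sym, B, A, pi, Gsym, Xi, gamma0, Pair)
    mass = Gsym.sum(axis=1)
    scores, axes = np.zeros(K), np.zeros((K, M))
    for j in range(K):
        if mass[j] <= 0:
            continue
        q = Gsym[j] / mass[j]
        mu = q @ bits
        static = (bits * q[:, None]).T @ bits - np.outer(mu, mu)
        np.fill_diagonal(static, 0.0)  # binary marginals: diagonal carries no signal
        w_pair = Pair[j].sum()
        lagged = np.zeros((M, M))
        if w_pair > 0:
            p = Pair[j] / w_pair
            mu_row = p.sum(axis=1) @ bits
            mu_col = p.sum(axis=0) @ bits
            cross = bits.T @ p @ bits - np.outer(mu_row, mu_col)
            lagged = 0.5 * (cross + cross.T)
        w, v = np.linalg.eigh(static + lagged)
        scores[j] = w[-1]
        axes[j] = v[:, -1]
    return mass / mass.sum(), scores, axes


def _merge_states(E, A, pi, a, b, mass):
    """Collapse state b into state a (mass-weighted); returns a K-1 model."""
    wa, wb = max(mass[a], 1e-12), max(mass[b], 1e-12)
    E2 = E.copy()
    E2[a] = (wa * E[a] + wb * E[b]) / (wa + wb)
    A2 = A.copy()
    A2[a] = (wa * A[a] + wb * A[b]) / (wa + wb)
    A2[:, a] += A2[:, b]
    keep = [k for k in range(E.shape[0]) if k != b]
    E2 = E2[keep]
    A2 = A2[np.ix_(keep, keep)]
    A2 /= A2.sum(axis=1, keepdims=True)
    pi2 = pi.copy()
    pi2[a] += pi2[b]
    pi2 = pi2[keep]
    return E2, A2, pi2 / pi2.sum()


def _split_state(E, A, pi, j, axis, scale, rng, floor=EMISSION_FLOOR):
    """Split state j into two copies displaced along ``axis``."""
    K, M = E.shape
    d = np.sqrt(max(scale, 1e-4)) * axis + rng.uniform(-0.02, 0.02, size=M)
    E2 = np.vstack([E, E[j]])
    E2[j] = np.clip(E[j] - d, 0.02, 0.98)
    E2[K] = np.clip(E[j] + d, 0.02, 0.98)
    A2 = np.zeros((K + 1, K + 1))
    A2[:K, :K] = A
    A2[:K, K] = A[:K, j] / 2.0
    A2[:K, j] /= 2.0
    A2[K, :K] = A[j, :]
    A2[K, j] = A[j, j] / 2.0
    A2[K, K] = A[j, j] / 2.0
    A2[j] = A2[K]
    pi2 = np.append(pi, pi[j] / 2.0)
    pi2[j] /= 2.0
    return E2, A2 / A2.sum(axis=1, keepdims=True), pi2 / pi2.sum()


def select_model(
    sequences: list[np.ndarray],
    k_range=range(10, 21),
    *,
    criterion: str = "bic",
    seed: int | None = None,
    redundancy_threshold: float = 0.2,
    mark_names: list[str] | None = None,
    scan: str = "ladder",
    tol: float = 1e-6,
    max_iter: int = 300,
    n_init: int = 3,
) -> tuple[ChromatinStateModel, pd.DataFrame]:
    """Train one model per K in ``k_range`` and pick one by ``criterion``.

    Scan strategies
    ---------------
    ``ladder`` (default): fit the smallest K with restarts, then grow one
    state at a time by splitting the heaviest state and refitting — every K
    is converged from a warm start, so log-likelihoods are comparable and
    nested (non-decreasing in K), and once K exceeds the number of real
    mark combinations the added state collapses onto an existing one, which
    the emission-redundancy diagnostic (minimum pairwise distance between
    emission rows) flags. ``independent``: fresh restarts per K.

    Diagnostics per K (log-likelihood, parameter count, BIC, redundancy
    score, iterations) are returned so a user can override the choice.
    criterion: ``bic`` (default, minimum BIC), ``loglik`` (maximum), or
    ``redundancy`` (largest K with redundancy score >= threshold).
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("K range is empty")
    T_total = sum(len(s) for s in sequences)
    M = sequences[0].shape[1]
    syms = [encode_symbols(np.asarray(s)) for s in sequences]
    models: dict[int, ChromatinStateModel] = {}

    best: dict[int, dict] = {}

    def record(K, E, A, pi, trace):
        ll = trace[-1]
        if K in best and best[K]["loglik"] >= ll:
            return
        models[K] = ChromatinStateModel(
            E, A, pi, mark_names or [f"mark{m + 1}" for m in range(M)]
        )
        p = K * M + K * (K - 1) + (K - 1)
        best[K] = {
            "K": K,
            "loglik": ll,
            "n_params": p,
            "bic": -2.0 * ll + p * np.log(T_total),
            "min_emission_distance": min_emission_distance(E),
            "n_iter": len(trace),
        }

    ss = np.random.SeedSequence(seed)
    if scan == "ladder":
        base_seed = int(ss.generate_state(1)[0] % (2**31))
        est = BernoulliChromatinHMM(
            ks[0], tol=tol, max_iter=max_iter, n_init=n_init, random_state=base_seed
        ).fit(np.vstack(sequences), [len(s) for s in sequences])
        E, A, pi = est.emissionprob_, est.transmat_, est.startprob_
        record(ks[0], E, A, pi, est.loglik_trace_)
        rng = np.random.default_rng(ss.spawn(1)[0])
        # up pass: grow by splitting the most overdispersed state
        for K in range(ks[0] + 1, ks[-1] + 1):
            mass, scores, axes = _split_scores(E, A, pi, syms, M)
            j = int((mass * scores).argmax())
            E, A, pi = _split_state(E, A, pi, j, axes[j], scores[j], rng)
            E, A, pi, trace, _ = _em_loop(syms, M, E, A, pi, tol, max_iter)
            if K in ks:
                record(K, E, A, pi, trace)
        # down pass: from the richest model (every real mark combination is
        # represented, surplus states are duplicates) merge the closest
        # emission pair and refit — duplicate merges are near-lossless, so
        # the descent passes through clean models at every K
        for K in range(ks[-1] - 1, ks[0] - 1, -1):
            mass, _, _ = _split_scores(E, A, pi, syms, M)
            d = np.linalg.norm(E[:, None, :] - E[None, :, :], axis=-1)
            d[np.diag_indices(K + 1)] = np.inf
            a, b = np.unravel_index(d.argmin(), d.shape)
            E, A, pi = _merge_states(E, A, pi, a, b, mass)
            E, A, pi, trace, _ = _em_loop(syms, M, E, A, pi, tol, max_iter)
            if K in ks:
                record(K, E, A, pi, trace)
    elif scan == "independent":
        for K, child in zip(ks, ss.spawn(len(ks))):
            sub_seed = int(child.generate_state(1)[0] % (2**31))
            model, trace = baum_welch(
                sequences,
                K,
                seed=sub_seed,
                mark_names=mark_names,
                tol=tol,
                max_iter=max_iter,
                n_init=n_init,
            )
            record(K, model.emission, model.transition, model.start, trace)
    else:
        raise ValueError(f"unknown scan strategy {scan!r}")

    diag = pd.DataFrame(list(best.values())).set_index("K").sort_index()
    if criterion == "bic":
        chosen = int(diag.bic.idxmin())
    elif criterion == "loglik":
        chosen = int(diag.loglik.idxmax())
    elif criterion == "redundancy":
        ok = diag.index[diag.min_emission_distance >= redundancy_threshold]
        chosen = int(ok.max()) if len(ok) else int(diag.index.min())
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    diag["chosen"] = diag.index == chosen
    return models[chosen], diag


def match_states(reference_emission: np.ndarray, other_emission: np.ndarray) -> np.ndarray:
    """Optimal 1-1 state matching by emission distance (Hungarian assignment).

    Returns ``order`` such that other_emission[order[i]] corresponds to
    reference state i.
    """
    from scipy.optimize import linear_sum_assignment

    cost = np.linalg.norm(
        reference_emission[:, None, :] - other_emission[None, :, :], axis=-1
    )
    _, cols = linear_sum_assignment(cost)
    return cols
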