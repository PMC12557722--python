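"""Photon-by-photon hidden Markov modeling of burst photon streams.

The model is a discrete-time hidden Markov chain on the timestamp clock:
``A`` is the per-clock-tick transition matrix, ``B`` the per-state
emission distribution over the three detection channels, and ``pi`` the
state distribution at the first photon of a burst.  Photons are observed
only at their arrival ticks; over an inter-photon gap of ``g`` ticks the
state propagates by ``A**g``.  The forward/backward recursions, the
Baum-Welch E-step and the Viterbi decoder all work directly on the
variable gaps, with matrix powers and the expected within-gap transition
counts evaluated in closed form through the eigendecomposition of ``A``
(for eigenvalues ``u, v`` the sum over tick placements of a transition
inside a gap reduces to the divided difference ``(u**g - v**g)/(u - v)``).

Model selection over the number of states uses an integrated-complete-
likelihood style score: the complete-data log-likelihood along the
Viterbi path minus a BIC penalty ``(d/2) * ln(n_photons)``.  Fitted
states are classified as FRET, donor-only or acceptor-only from their
emission stoichiometry, and conformational transition rates are obtained
from the principal matrix logarithm of ``A``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.vq import kmeans2
from scipy.linalg import expm, logm

from .simkit import Channel, N_CHANNELS

_EPS = 1e-300


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------


@dataclass
class StateModel:
    """K-state hidden Markov model over photon channels."""

    trans: np.ndarray  # (K, K) per-tick transition matrix
    emis: np.ndarray  # (K, C) channel emission probabilities
    init: np.ndarray  # (K,) initial distribution
    clock_period_s: float

    def __post_init__(self):
        self.trans = np.asarray(self.trans, dtype=float)
        self.emis = np.asarray(self.emis, dtype=float)
        self.init = np.asarray(self.init, dtype=float)
        self.validate()

    @property
    def n_states(self) -> int:
        return self.trans.shape[0]

    def validate(self, atol: float = 1e-8):
        K = self.trans.shape[0]
        if self.trans.shape != (K, K):
            raise ValueError("transition matrix must be square")
        if self.emis.shape != (K, N_CHANNELS):
            raise ValueError("emission matrix must be (K, 3)")
        if self.init.shape != (K,):
            raise ValueError("initial distribution must have length K")
        for name, M, s in (
            ("trans", self.trans, self.trans.sum(axis=1)),
            ("emis", self.emis, self.emis.sum(axis=1)),
            ("init", self.init, np.atleast_1d(self.init.sum())),
        ):
            if np.any(M < -atol):
                raise ValueError(f"{name} has negative entries")
            if np.any(np.abs(s - 1.0) > 1e-6):
                raise ValueError(f"{name} rows must sum to 1")

    def to_dict(self) -> dict:
        return {
            "trans": self.trans.tolist(),
            "emis": self.emis.tolist(),
            "init": self.init.tolist(),
            "clock_period_s": self.clock_period_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StateModel":
        return cls(
            trans=np.asarray(d["trans"]),
            emis=np.asarray(d["emis"]),
            init=np.asarray(d["init"]),
            clock_period_s=float(d["clock_period_s"]),
        )


@dataclass
class FitResult:
    """Outcome of one EM fit."""

    model: StateModel
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    occupancy: np.ndarray  # posterior photon-weighted state occupancy
    degenerate_states: list
    icl: float | None = None
    states: pd.DataFrame | None = None  # classification table

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


@dataclass
class RateEstimate:
    """Conformational transition rates between FRET states."""

    state_index: np.ndarray  # model state indices, sorted by E ascending
    E_state: np.ndarray
    rates: np.ndarray  # (Kd, Kd) 1/s, diagonal = -sum(offdiag)
    occupancy: np.ndarray  # renormalized over FRET states
    method: str = "matrix-log"
    rate_err: np.ndarray | None = None  # bootstrap standard error
    rate_ci: tuple | None = None  # (lo, hi) percentile matrices


# ---------------------------------------------------------------------------
# packing photon sequences
# ---------------------------------------------------------------------------


class _Packed:
    """Burst photon sequences flattened and sorted by length (descending)."""

    def __init__(self, seqs):
        if not seqs:
            raise ValueError("need at least one photon sequence")
        lengths = np.array([len(t) for t, _ in seqs], dtype=np.int64)
        if np.any(lengths < 1):
            raise ValueError("empty photon sequence")
        self.order = np.argsort(-lengths, kind="stable")
        self.lengths = lengths[self.order]
        self.n_bursts = len(seqs)
        self.ptr = np.concatenate([[0], np.cumsum(self.lengths)])[:-1]
        self.n_photons = int(self.lengths.sum())
        times = np.concatenate([np.asarray(seqs[i][0], dtype=np.int64) for i in self.order])
        chans = np.concatenate([np.asarray(seqs[i][1], dtype=np.int64) for i in self.order])
        self.channels = chans
        gaps = np.ones(self.n_photons, dtype=np.int64)
        for b in range(self.n_bursts):
            a, L = self.ptr[b], self.lengths[b]
            if L > 1:
                g = np.diff(times[a : a + L])
                if np.any(g < 1):
                    raise ValueError("inter-photon gaps must be >= 1 tick")
                gaps[a : a + L - 1] = g
        self.gaps = gaps  # aligned with the left photon of each gap
        self.last = self.ptr + self.lengths - 1
        # active burst count per photon position within burst
        maxT = int(self.lengths.max())
        asc = np.sort(self.lengths)
        self.n_active = self.n_bursts - np.searchsorted(asc, np.arange(maxT), side="right")
        self.maxT = maxT
        self.gap_mask = np.ones(self.n_photons, dtype=bool)
        self.gap_mask[self.last] = False


def _pack(seqs) -> _Packed:
    return _Packed(seqs)


# ---------------------------------------------------------------------------
# spectral helpers
# ---------------------------------------------------------------------------


def _eig(A: np.ndarray):
    w, V = np.linalg.eig(A)
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > 1e12:
        # nudge away from a defective transition matrix
        rng = np.random.default_rng(12345)
        K = A.shape[0]
        J = A + rng.uniform(0, 1e-12, size=(K, K))
        J /= J.sum(axis=1, keepdims=True)
        w, V = np.linalg.eig(J)
    Vinv = np.linalg.inv(V)
    return w, V, Vinv


def _lam_pow(w: np.ndarray, g: np.ndarray) -> np.ndarray:
    """w**g for complex eigenvalues, elementwise over gaps: (n, K)."""
    logw = np.log(np.where(np.abs(w) < _EPS, _EPS, w).astype(complex))
    return np.exp(g[:, None] * logw[None, :])


def _gap_trans_matrices(w, V, Vinv, gaps) -> np.ndarray:
    """A**g for each gap, shape (n, K, K), real."""
    lam_g = _lam_pow(w, gaps)
    Ag = np.einsum("ik,nk,kj->nij", V, lam_g, Vinv).real
    np.clip(Ag, 0.0, None, out=Ag)
    return Ag


def _divided_difference(w, gaps):
    """f[n, k, m] = (w_k**g - w_m**g) / (w_k - w_m), with the derivative
    g * w**(g-1) on (near-)coincident eigenvalues; shape (n, K, K)."""
    K = w.size
    lam_g = _lam_pow(w, gaps)  # (n, K)
    num = lam_g[:, :, None] - lam_g[:, None, :]
    den = w[None, :, None] - w[None, None, :]
    near = np.abs(den) < 1e-12
    safe_den = np.where(near, 1.0, den)
    f = num / safe_den
    wk = np.where(np.abs(w) < _EPS, _EPS, w)
    deriv = gaps[:, None] * lam_g / wk[None, :]  # g * w**(g-1)
    davg = 0.5 * (deriv[:, :, None] + deriv[:, None, :])
    return np.where(near, davg, f)


# ---------------------------------------------------------------------------
# forward-backward
# ---------------------------------------------------------------------------


def _forward_backward(packed: _Packed, model: StateModel, want_estep: bool = True):
    K = model.n_states
    A, B, pi = model.trans, model.emis, model.init
    w, V, Vinv = _eig(A)
    N = packed.n_photons
    x = packed.channels

    Ag = _gap_trans_matrices(w, V, Vinv, packed.gaps)

    alpha = np.empty((N, K))
    c = np.empty(N)

    # t = 0 over all bursts
    idx0 = packed.ptr
    a = pi[None, :] * B[:, x[idx0]].T
    s = a.sum(axis=1)
    s = np.where(s <= 0, _EPS, s)
    alpha[idx0] = a / s[:, None]
    c[idx0] = s

    for t in range(1, packed.maxT):
        nact = packed.n_active[t]
        idx = packed.ptr[:nact] + t
        a = np.einsum("ni,nij->nj", alpha[idx - 1], Ag[idx - 1]) * B[:, x[idx]].T
        s = a.sum(axis=1)
        s = np.where(s <= 0, _EPS, s)
        alpha[idx] = a / s[:, None]
        c[idx] = s

    ll = float(np.log(c).sum())
    if not want_estep:
        return ll, None, None, None

    beta = np.empty((N, K))
    beta[packed.last] = 1.0
    for t in range(packed.maxT - 2, -1, -1):
        nact = packed.n_active[t + 1]  # bursts that have a photon at t+1
        idx = packed.ptr[:nact] + t
        wv = B[:, x[idx + 1]].T * beta[idx + 1] / c[idx + 1][:, None]
        beta[idx] = np.einsum("nij,nj->ni", Ag[idx], wv)

    gamma = alpha * beta
    gamma /= np.where(gamma.sum(axis=1) <= 0, _EPS, gamma.sum(axis=1))[:, None]

    # expected within-gap transition counts, spectral closed form
    left = np.nonzero(packed.gap_mask)[0]
    M = np.zeros((K, K), dtype=complex)
    chunk = 100_000
    for a0 in range(0, left.size, chunk):
        li = left[a0 : a0 + chunk]
        u = alpha[li]
        wv = B[:, x[li + 1]].T * beta[li + 1] / c[li + 1][:, None]
        uf = u.astype(complex) @ V
        wf = wv.astype(complex) @ Vinv.T
        F = _divided_difference(w, packed.gaps[li])
        M += np.einsum("nk,nm,nkm->km", uf, wf, F)
    S = Vinv.T @ M @ V.T
    C = A * S.real
    np.clip(C, 0.0, None, out=C)

    init_post = gamma[packed.ptr].sum(axis=0)
    return ll, gamma, C, init_post


def loglik(seqs, model: StateModel) -> float:
    """Total log-likelihood of burst photon sequences under ``model``.

    ``seqs`` is a list of ``(timestamps_ticks, channels)`` pairs with
    strictly increasing integer timestamps within each burst.
    """
    model.validate()
    packed = _pack(seqs)
    ll, *_ = _forward_backward(packed, model, want_estep=False)
    return ll


def loglik_bruteforce(seq, model: StateModel) -> float:
    """Exhaustive path-sum likelihood of one short sequence (oracle)."""
    times, chans = np.asarray(seq[0]), np.asarray(seq[1])
    K = model.n_states
    gaps = np.diff(times)
    Ags = [np.linalg.matrix_power(model.trans, int(g)) for g in gaps]
    total = 0.0
    for path in itertools.product(range(K), repeat=len(times)):
        p = model.init[path[0]] * model.emis[path[0], chans[0]]
        for t in range(1, len(times)):
            p *= Ags[t - 1][path[t - 1], path[t]] * model.emis[path[t], chans[t]]
        total += p
    return float(np.log(total))


# ---------------------------------------------------------------------------
# Viterbi
# ---------------------------------------------------------------------------


def viterbi(seqs, model: StateModel):
    """Most probable state path per burst under gap-aware transitions.

    Returns ``(paths, logprobs)`` in the input sequence order.
    """
    model.validate()
    packed = _pack(seqs)
    K = model.n_states
    B, pi = model.emis, model.init
    x = packed.channels
    w, V, Vinv = _eig(model.trans)
    logAg = np.log(np.maximum(_gap_trans_matrices(w, V, Vinv, packed.gaps), _EPS))
    logB = np.log(np.maximum(B, _EPS))
    logpi = np.log(np.maximum(pi, _EPS))

    N = packed.n_photons
    delta = np.empty((N, K))
    psi = np.zeros((N, K), dtype=np.int8)
    idx0 = packed.ptr
    delta[idx0] = logpi[None, :] + logB[:, x[idx0]].T
    for t in range(1, packed.maxT):
        nact = packed.n_active[t]
        idx = packed.ptr[:nact] + t
        cand = delta[idx - 1][:, :, None] + logAg[idx - 1]  # (n, from, to)
        psi[idx] = np.argmax(cand, axis=1).astype(np.int8)
        delta[idx] = np.max(cand, axis=1) + logB[:, x[idx]].T

    paths_sorted = []
    logps = np.empty(packed.n_bursts)
    for b in range(packed.n_bursts):
        a0, L = packed.ptr[b], packed.lengths[b]
        path = np.empty(L, dtype=np.int64)
        path[-1] = np.argmax(delta[a0 + L - 1])
        logps[b] = delta[a0 + L - 1, path[-1]]
        for t in range(L - 2, -1, -1):
            path[t] = psi[a0 + t + 1, path[t + 1]]
        paths_sorted.append(path)

    paths = [None] * packed.n_bursts
    out_logp = np.empty(packed.n_bursts)
    for sorted_pos, orig in enumerate(packed.order):
        paths[orig] = paths_sorted[sorted_pos]
        out_logp[orig] = logps[sorted_pos]
    return paths, out_logp


def viterbi_bruteforce(seq, model: StateModel):
    """Exhaustive argmax over all state paths of one short sequence."""
    times, chans = np.asarray(seq[0]), np.asarray(seq[1])
    K = model.n_states
    gaps = np.diff(times)
    Ags = [np.linalg.matrix_power(model.trans, int(g)) for g in gaps]
    best, best_lp = None, -np.inf
    for path in itertools.product(range(K), repeat=len(times)):
        lp = np.log(max(model.init[path[0]], _EPS)) + np.log(
            max(model.emis[path[0], chans[0]], _EPS)
        )
        for t in range(1, len(times)):
            lp += np.log(max(Ags[t - 1][path[t - 1], path[t]], _EPS))
            lp += np.log(max(model.emis[path[t], chans[t]], _EPS))
        if lp > best_lp:
            best_lp, best = lp, np.asarray(path)
    return best, float(best_lp)


def path_logprob(seqs, paths, model: StateModel) -> float:
    """Complete-data log-likelihood of given state paths."""
    K = model.n_states
    w, V, Vinv = _eig(model.trans)
    logB = np.log(np.maximum(model.emis, _EPS))
    logpi = np.log(np.maximum(model.init, _EPS))
    total = 0.0
    for (times, chans), path in zip(seqs, paths):
        times = np.asarray(times)
        chans = np.asarray(chans)
        gaps = np.diff(times)
        Ag = _gap_trans_matrices(w, V, Vinv, gaps)
        total += logpi[path[0]] + logB[path, chans].sum()
        total += np.log(np.maximum(Ag[np.arange(gaps.size), path[:-1], path[1:]], _EPS)).sum()
    return float(total)


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------


def _init_model(seqs, K, clock_period_s, seed, init_exit_rate=100.0):
    """K-means seeding on per-burst (E, S) plus seed-dependent jitter."""
    rng = np.random.default_rng(seed)
    counts = np.zeros((len(seqs), N_CHANNELS))
    for i, (_, ch) in enumerate(seqs):
        counts[i] = np.bincount(np.asarray(ch), minlength=N_CHANNELS)
    dd, da, aa = counts.T
    tot = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(dd + da > 0, da / (dd + da), 0.5)
        s = np.where(tot > 0, (dd + da) / tot, 0.5)
    feats = np.column_stack([e, s])
    if len(seqs) >= K:
        try:
            cent, _ = kmeans2(feats, K, minit="++", seed=seed)
        except Exception:
            cent = rng.uniform(0.05, 0.95, size=(K, 2))
    else:
        cent = rng.uniform(0.05, 0.95, size=(K, 2))
    cent = np.clip(cent + rng.normal(0, 0.03, size=cent.shape), 0.02, 0.98)
    B = np.column_stack(
        [cent[:, 1] * (1 - cent[:, 0]), cent[:, 1] * cent[:, 0], 1 - cent[:, 1]]
    )
    B = np.maximum(B, 1e-3)
    B /= B.sum(axis=1, keepdims=True)

    if K == 1:
        A = np.ones((1, 1))
    else:
        Q = np.full((K, K), init_exit_rate / (K - 1))
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        A = expm(Q * clock_period_s)
    pi = np.full(K, 1.0 / K)
    return StateModel(trans=A, emis=B, init=pi, clock_period_s=clock_period_s)


def em_fit(
    seqs,
    K: int,
    clock_period_s: float,
    init: StateModel | None = None,
    max_iter: int = 300,
    tol: float = 1e-8,
    seed: int = 0,
) -> FitResult:
    """Baum-Welch fit adapted to variable inter-photon gaps.

    Expected within-gap transition counts are accumulated through the
    spectral factorization of ``A``, so the E-step is exact and the
    log-likelihood is nondecreasing across iterations.  Deterministic for
    a fixed ``seed`` (or explicit ``init`` model).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    packed = _pack(seqs)
    model = init if init is not None else _init_model(seqs, K, clock_period_s, seed)
    if model.n_states != K:
        raise ValueError("init model has wrong number of states")

    trace = []
    converged = False
    gamma = None
    for it in range(max_iter):
        ll, gamma, C, init_post = _forward_backward(packed, model)
        trace.append(ll)
        if it > 0 and abs(trace[-1] - trace[-2]) <= tol * abs(trace[-2]):
            converged = True
            break
        # M-step
        emis = np.zeros((K, N_CHANNELS))
        for ch in range(N_CHANNELS):
            sel = packed.channels == ch
            if sel.any():
                emis[:, ch] = gamma[sel].sum(axis=0)
        state_mass = emis.sum(axis=1)
        safe = np.where(state_mass <= 0, 1.0, state_mass)
        emis = np.maximum(emis, 1e-12) / np.maximum(safe, 1e-12)[:, None]
        emis /= emis.sum(axis=1, keepdims=True)

        if K == 1:
            A = np.ones((1, 1))
        else:
            row = C.sum(axis=1)
            A = model.trans.copy()
            ok = row > 0
            A[ok] = C[ok] / row[ok, None]
        pi = init_post / init_post.sum() if init_post.sum() > 0 else model.init
        model = StateModel(trans=A, emis=emis, init=pi, clock_period_s=clock_period_s)

    occupancy = (
        gamma.sum(axis=0) / packed.n_photons if gamma is not None else np.full(K, np.nan)
    )
    state_mass = gamma.sum(axis=0) if gamma is not None else np.ones(K)
    degenerate = [int(k) for k in range(K) if state_mass[k] < 1.0]
    if degenerate:
        warnings.warn(
            f"states {degenerate} capture <1 expected photon; consider refitting",
            stacklevel=2,
        )
    res = FitResult(
        model=model,
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iter=len(trace),
        occupancy=occupancy,
        degenerate_states=degenerate,
    )
    res.states = classify_states(res)
    return res


def em_fit_multistart(
    seqs,
    K: int,
    clock_period_s: float,
    n_starts: int = 3,
    seed: int = 0,
    **em_kwargs,
) -> FitResult:
    """Best-of-``n_starts`` EM fit (highest final log-likelihood).

    The K-means (E, S) seeding can land in label-collapsed local optima on
    heterogeneous burst populations; a few jittered restarts make the fit
    robust.
    """
    best = None
    for j in range(n_starts):
        fit = em_fit(seqs, K, clock_period_s, seed=seed + 1000 * j, **em_kwargs)
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------


def icl_score(seqs, fit: FitResult) -> float:
    """Integrated-complete-likelihood style score of a fitted model.

    Complete-data log-likelihood along the Viterbi path minus the BIC
    penalty ``(d/2) ln N`` with ``d = K(K-1) + K(C-1) + (K-1)`` free
    parameters.
    """
    K = fit.model.n_states
    n_photons = sum(len(t) for t, _ in seqs)
    paths, _ = viterbi(seqs, fit.model)
    cll = path_logprob(seqs, paths, fit.model)
    d = K * (K - 1) + K * (N_CHANNELS - 1) + (K - 1)
    return cll - 0.5 * d * np.log(n_photons)


def icl_select(
    seqs,
    K_range,
    clock_period_s: float,
    n_starts: int = 2,
    seed: int = 0,
    **em_kwargs,
):
    """Fit each candidate K (best of ``n_starts`` seeds) and pick the
    ICL-maximizing state count.  Returns ``(best_K, {K: FitResult})``."""
    K_range = list(K_range)
    if not K_range:
        raise ValueError("K_range must be nonempty")
    fits = {}
    for K in K_range:
        best = None
        for j in range(n_starts):
            fit = em_fit(
                seqs, K, clock_period_s, seed=seed + 1000 * j + K, **em_kwargs
            )
            if best is None or fit.loglik > best.loglik:
                best = fit
        best.icl = icl_score(seqs, best)
        fits[K] = best
    usable = {K: f for K, f in fits.items() if np.isfinite(f.icl)}
    if not usable:
        raise RuntimeError("all candidate fits degenerate")
    best_K = max(usable, key=lambda K: usable[K].icl)
    return best_K, fits


# ---------------------------------------------------------------------------
# state classification and rates
# ---------------------------------------------------------------------------


def classify_states(
    fit_or_model,
    duty_ratio: float = 1.0,
    s_thresholds: tuple = (0.2, 0.8),
    ambiguity_margin: float = 0.02,
) -> pd.DataFrame:
    """Label fitted states as FRET, donor-only or acceptor-only.

    The emission stoichiometry of state k is
    ``S_k = (B[k,DD] + B[k,DA]) / (B[k,DD] + B[k,DA] + B[k,AA] * duty_ratio)``
    (``duty_ratio`` rescales the acceptor-excitation channel when laser
    duties differ).  States with S above the upper threshold are
    donor-only, below the lower acceptor-only, the rest FRET with
    ``E_k = B[k,DA] / (B[k,DD] + B[k,DA])``.  States within
    ``ambiguity_margin`` of a threshold are flagged.
    """
    model = fit_or_model.model if isinstance(fit_or_model, FitResult) else fit_or_model
    occ = (
        fit_or_model.occupancy
        if isinstance(fit_or_model, FitResult)
        else np.full(model.n_states, np.nan)
    )
    B = model.emis
    lo, hi = s_thresholds
    dex = B[:, Channel.DexDem] + B[:, Channel.DexAem]
    s_state = dex / (dex + B[:, Channel.AexAem] * duty_ratio)
    with np.errstate(invalid="ignore", divide="ignore"):
        e_state = np.where(dex > 0, B[:, Channel.DexAem] / dex, np.nan)
    labels = np.where(s_state > hi, "donor-only", np.where(s_state < lo, "acceptor-only", "FRET"))
    ambiguous = (np.abs(s_state - lo) <= ambiguity_margin) | (
        np.abs(s_state - hi) <= ambiguity_margin
    )
    return pd.DataFrame(
        {
            "state": np.arange(model.n_states),
            "E_state": e_state,
            "S_state": s_state,
            "label": labels,
            "ambiguous": ambiguous,
            "occupancy": occ,
        }
    )


def transition_rates(
    model: StateModel,
    fret_states,
    occupancy=None,
    allow_fallback: bool = True,
) -> RateEstimate:
    """Transition rate matrix (1/s) between FRET states.

    Computes the principal matrix logarithm of the per-tick transition
    matrix divided by the clock period and restricts it to the FRET
    states (transitions through donor-only / acceptor-only label states
    reflect labeling, not conformation, and are excluded).  Falls back to
    the first-order estimate ``(A - I) / dt`` when the logarithm is not
    real (non-embeddable ``A``).
    """
    fret_states = np.asarray(list(fret_states), dtype=int)
    A = model.trans
    dt = model.clock_period_s
    method = "matrix-log"
    L = logm(A)
    if np.max(np.abs(L.imag)) > 1e-8 * max(np.max(np.abs(L.real)), 1.0):
        if not allow_fallback:
            raise ValueError("transition matrix has no real matrix logarithm")
        Q = (A - np.eye(A.shape[0])) / dt
        method = "first-order"
    else:
        Q = L.real / dt
    sub = Q[np.ix_(fret_states, fret_states)].copy()
    off = ~np.eye(sub.shape[0], dtype=bool)
    sub[off] = np.clip(sub[off], 0.0, None)
    np.fill_diagonal(sub, 0.0)
    np.fill_diagonal(sub, -sub.sum(axis=1))

    if occupancy is None:
        occ = np.full(fret_states.size, np.nan)
    else:
        occ = np.asarray(occupancy, dtype=float)[fret_states]
        occ = occ / occ.sum() if occ.sum() > 0 else occ

    # order by E ascending
    B = model.emis
    dex = B[fret_states, Channel.DexDem] + B[fret_states, Channel.DexAem]
    e = np.where(dex > 0, B[fret_states, Channel.DexAem] / dex, np.nan)
    order = np.argsort(e, kind="stable")
    return RateEstimate(
        state_index=fret_states[order],
        E_state=e[order],
        rates=sub[np.ix_(order, order)],
        occupancy=occ[order],
        method=method,
    )


def bootstrap_rates(
    seqs,
    fit: FitResult,
    fret_states,
    n_boot: int = 100,
    seed: int = 0,
    max_iter: int = 30,
) -> RateEstimate:
    """Burst bootstrap of the conformational rates.

    Resamples bursts with replacement, refits from the point estimate
    (warm start) and reports percentile intervals and standard errors on
    each off-diagonal rate.
    """
    rng = np.random.default_rng(seed)
    point = transition_rates(fit.model, fret_states, fit.occupancy)
    reps = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(seqs), size=len(seqs))
        sub = [seqs[i] for i in idx]
        refit = em_fit(
            sub,
            fit.model.n_states,
            fit.model.clock_period_s,
            init=fit.model,
            max_iter=max_iter,
            seed=0,
        )
        reps.append(transition_rates(refit.model, fret_states, refit.occupancy).rates)
    reps = np.asarray(reps)
    point.rate_err = reps.std(axis=0, ddof=1)
    point.rate_ci = (
        np.percentile(reps, 2.5, axis=0),
        np.percentile(reps, 97.5, axis=0),
    )
    return point


def viterbi_transition_counts(paths, n_states: int) -> np.ndarray:
    """Count state-to-state switches along Viterbi paths."""
    counts = np.zeros((n_states, n_states), dtype=np.int64)
    for path in paths:
        a, b = path[:-1], path[1:]
        sw = a != b
        np.add.at(counts, (a[sw], b[sw]), 1)
    return counts


def viterbi_dwell_rates(seqs, paths, model: StateModel, fret_states) -> np.ndarray:
    """First-order rate estimate from Viterbi dwell statistics.

    k_ij = (number of i->j switches) / (total time assigned to state i),
    restricted to FRET states.  Secondary to the matrix-log estimate.
    """
    n = model.n_states
    counts = viterbi_transition_counts(paths, n)
    time_in = np.zeros(n)
    for (times, _), path in zip(seqs, paths):
        gaps = np.diff(np.asarray(times)) * model.clock_period_s
        np.add.at(time_in, path[:-1], gaps)
    fret_states = np.asarray(list(fret_states), dtype=int)
    sub = np.zeros((fret_states.size, fret_states.size))
    for a, i in enumerate(fret_states):
        for b, j in enumerate(fret_states):
            if i != j and time_in[i] > 0:
                sub[a, b] = counts[i, j] / time_in[i]
    np.fill_diagonal(sub, 0.0)
    np.fill_diagonal(sub, -sub.sum(axis=1))
    return sub
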