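"""Photon-by-photon HMM: exhaustive-enumeration oracles, EM properties,
state classification and rate extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from alexfret import hmm
from alexfret.hmm import (
    StateModel,
    classify_states,
    em_fit,
    icl_select,
    loglik,
    loglik_bruteforce,
    path_logprob,
    transition_rates,
    viterbi,
    viterbi_bruteforce,
)
from alexfret import simkit

DT = 12.5e-9


def random_model(K, rng, dt=1e-6):
    A = rng.dirichlet(np.ones(K) * 5, size=K)
    B = rng.dirichlet(np.ones(3), size=K)
    pi = rng.dirichlet(np.ones(K))
    return StateModel(A, B, pi, dt)


def random_seq(n, rng, max_gap=1000):
    times = np.cumsum(rng.integers(1, max_gap, size=n)).astype(np.int64)
    chans = rng.integers(0, 3, size=n)
    return times, chans


class TestLoglik:
    def test_single_state_closed_form(self):
        rng = np.random.default_rng(0)
        m = random_model(1, rng)
        seq = random_seq(20, rng)
        expected = np.log(m.emis[0, seq[1]]).sum()
        assert loglik([seq], m) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("K", [1, 2, 3])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, K, seed):
        rng = np.random.default_rng(100 * K + seed)
        m = random_model(K, rng)
        seq = random_seq(rng.integers(2, 9), rng)
        assert loglik([seq], m) == pytest.approx(
            loglik_bruteforce(seq, m), abs=1e-8
        )

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_enumeration_property_random_models(self, data):
        seed = data.draw(st.integers(0, 2**16))
        n = data.draw(st.integers(2, 6))
        rng = np.random.default_rng(seed)
        m = random_model(int(rng.integers(1, 3)), rng)
        seq = random_seq(n, rng, max_gap=500)
        assert loglik([seq], m) == pytest.approx(
            loglik_bruteforce(seq, m), abs=1e-8
        )

    def test_identity_transitions_pin_initial_state(self):
        rng = np.random.default_rng(3)
        B = rng.dirichlet(np.ones(3), size=2)
        m = StateModel(np.eye(2), B, np.array([1.0, 0.0]), 1e-6)
        seq = random_seq(15, rng)
        expected = np.log(B[0, seq[1]]).sum()
        assert loglik([seq], m) == pytest.approx(expected, abs=1e-9)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            StateModel(np.array([[0.5, 0.6], [0.5, 0.5]]),
                       np.full((2, 3), 1 / 3), np.array([0.5, 0.5]), 1e-6)


class TestViterbi:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_argmax(self, seed):
        rng = np.random.default_rng(seed)
        m = random_model(2, rng)
        seq = random_seq(8, rng)
        paths, lps = viterbi([seq], m)
        bf_path, bf_lp = viterbi_bruteforce(seq, m)
        assert np.array_equal(paths[0], bf_path)
        assert lps[0] == pytest.approx(bf_lp, abs=1e-9)

    def test_single_state_constant_path(self):
        rng = np.random.default_rng(1)
        m = random_model(1, rng)
        paths, _ = viterbi([random_seq(30, rng)], m)
        assert np.all(paths[0] == 0)

    def test_beats_random_alternative_paths(self):
        rng = np.random.default_rng(2)
        m = random_model(3, rng)
        seqs = [random_seq(40, rng) for _ in range(5)]
        paths, lps = viterbi(seqs, m)
        vit = path_logprob(seqs, paths, m)
        for _ in range(100):
            alt = [rng.integers(0, 3, size=len(t)) for t, _ in seqs]
            assert path_logprob(seqs, alt, m) <= vit + 1e-9


class TestEM:
    def test_single_state_emissions_match_empirical(self):
        rng = np.random.default_rng(4)
        seqs = [random_seq(200, rng) for _ in range(5)]
        fit = em_fit(seqs, 1, DT, max_iter=5)
        allch = np.concatenate([c for _, c in seqs])
        emp = np.bincount(allch, minlength=3) / allch.size
        assert np.allclose(fit.model.emis[0], emp, atol=1e-6)

    def test_loglik_monotone_nondecreasing(self):
        rng = np.random.default_rng(5)
        # structured two-state data so EM actually moves
        seqs = []
        for _ in range(30):
            n = 60
            s = rng.integers(0, 2)
            p = [[0.8, 0.1, 0.1], [0.1, 0.8, 0.1]][s]
            seqs.append(
                (np.cumsum(rng.integers(1, 2000, n)).astype(np.int64),
                 rng.choice(3, size=n, p=p))
            )
        fit = em_fit(seqs, 2, DT, max_iter=40, seed=1)
        d = np.diff(fit.loglik_trace)
        assert np.all(d >= -1e-9 * np.abs(fit.loglik_trace[:-1]))

    def test_fitted_model_row_stochastic(self):
        rng = np.random.default_rng(6)
        seqs = [random_seq(80, rng) for _ in range(10)]
        fit = em_fit(seqs, 2, DT, max_iter=15, seed=0)
        assert np.allclose(fit.model.trans.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(fit.model.emis.sum(axis=1), 1.0, atol=1e-12)
        assert fit.model.init.sum() == pytest.approx(1.0, abs=1e-12)

    def test_recovers_two_state_kinetics_from_exact_generator(self):
        # photons generated from the discrete-gap model itself
        rng = np.random.default_rng(7)
        Q = np.array([[-50.0, 50.0], [202.0, -202.0]])
        B = np.array([[0.81, 0.19, 0.0], [0.27, 0.73, 0.0]]) + 1e-9
        B /= B.sum(1, keepdims=True)
        pi = np.array([202 / 252, 50 / 252])
        seqs = []
        for _ in range(300):
            gaps = rng.geometric(1 / 1800, size=119)
            times = np.concatenate([[0], np.cumsum(gaps)]).astype(np.int64)
            s = rng.choice(2, p=pi)
            states = [s]
            for g in gaps:
                P = expm(Q * DT * g)
                s = rng.choice(2, p=P[s])
                states.append(s)
            states = np.array(states)
            u = rng.uniform(size=120)
            cum = B.cumsum(axis=1)
            chans = (u[:, None] > cum[states]).sum(axis=1)
            seqs.append((times, chans))
        init = StateModel(
            expm(np.array([[-100.0, 100.0], [100.0, -100.0]]) * DT),
            np.array([[0.65, 0.349, 0.001], [0.35, 0.649, 0.001]]),
            np.array([0.5, 0.5]),
            DT,
        )
        fit = em_fit(seqs, 2, DT, init=init, max_iter=300, tol=1e-11)
        re = transition_rates(fit.model, [0, 1], fit.occupancy)
        assert re.E_state == pytest.approx([0.19, 0.73], abs=0.03)
        assert re.rates[0, 1] == pytest.approx(50.0, rel=0.25)
        assert re.rates[1, 0] == pytest.approx(202.0, rel=0.25)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            em_fit([(np.array([0, 10]), np.array([0, 1]))], 0, DT)


class TestModelSelection:
    def test_static_single_population_selects_one_state(self):
        rng = np.random.default_rng(8)
        p = [0.3, 0.2, 0.5]
        seqs = [
            (np.cumsum(rng.integers(1, 2000, 50)).astype(np.int64),
             rng.choice(3, size=50, p=p))
            for _ in range(60)
        ]
        best_K, fits = icl_select(seqs, [1, 2, 3], DT, n_starts=2, max_iter=50)
        assert best_K == 1

    def test_icl_requires_candidates(self):
        with pytest.raises(ValueError):
            icl_select([(np.array([0, 5]), np.array([0, 1]))], [], DT)


class TestClassification:
    def test_pure_donor_state_labeled(self):
        m = StateModel(
            np.eye(3) * 0.97 + 0.01,
            np.array([[0.98, 0.01, 0.01], [0.01, 0.01, 0.98], [0.25, 0.25, 0.5]]),
            np.full(3, 1 / 3),
            DT,
        )
        tab = classify_states(m)
        assert tab.loc[0, "label"] == "donor-only"
        assert tab.loc[1, "label"] == "acceptor-only"
        assert tab.loc[2, "label"] == "FRET"
        assert tab.loc[2, "E_state"] == pytest.approx(0.5)

    def test_high_fret_state_efficiency_from_emissions(self):
        # a state emitting 73% acceptor among donor-excitation photons
        m = StateModel(
            np.eye(1),
            np.array([[0.27 * 0.5, 0.73 * 0.5, 0.5]]),
            np.ones(1),
            DT,
        )
        assert classify_states(m).loc[0, "E_state"] == pytest.approx(0.73)

    def test_e_state_invariant_to_acceptor_duty_scaling(self):
        B = np.array([[0.3, 0.3, 0.4]])
        m = StateModel(np.eye(1), B, np.ones(1), DT)
        e1 = classify_states(m, duty_ratio=1.0).loc[0, "E_state"]
        e2 = classify_states(m, duty_ratio=2.0).loc[0, "E_state"]
        assert e1 == e2 == pytest.approx(0.5)


class TestRates:
    def test_identity_transitions_give_zero_rates(self):
        m = StateModel(np.eye(2), np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1]]),
                       np.array([0.5, 0.5]), DT)
        re = transition_rates(m, [0, 1])
        assert np.allclose(re.rates, 0.0, atol=1e-6)

    def test_matrix_exponential_roundtrip(self):
        Q = np.array([[-50.0, 50.0], [202.0, -202.0]])
        A = expm(Q * DT)
        m = StateModel(A, np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1]]),
                       np.array([0.5, 0.5]), DT)
        re = transition_rates(m, [0, 1])
        assert re.rates[0, 1] == pytest.approx(50.0, rel=1e-6)
        assert re.rates[1, 0] == pytest.approx(202.0, rel=1e-6)

    def test_no_direct_transition_through_on_pathway_intermediate(self):
        # L <-> M <-> H chain with no direct L-H rate: the Viterbi decoder
        # should route essentially all L-H traffic through M
        sc = simkit.SimScenario(
            state_efficiencies=(0.15, 0.4, 0.7),
            rate_matrix=((0.0, 150.0, 0.0), (150.0, 0.0, 150.0), (0.0, 150.0, 0.0)),
            frac_dual=1.0,
            frac_donly=0.0,
            frac_aonly=0.0,
            n_bursts=700,
            seed=11,
        )
        stream = simkit.simulate_experiment(sc)
        t = stream.times_s
        seqs = []
        for _, r in stream.truth_bursts.iterrows():
            i0, i1 = np.searchsorted(t, [r["start_s"], r["stop_s"]])
            if i1 - i0 < 30:
                continue
            ts = stream.timestamps[i0:i1].copy()
            for k in range(1, ts.size):
                if ts[k] <= ts[k - 1]:
                    ts[k] = ts[k - 1] + 1
            seqs.append((ts, stream.channels[i0:i1].astype(np.int64)))
        E = np.array(sc.state_efficiencies)
        B = np.column_stack([0.5 * (1 - E), 0.5 * E, np.full(3, 0.5)])
        model = StateModel(
            expm(sc.Q * stream.clock_period_s),
            B,
            simkit.stationary_distribution(sc.Q),
            stream.clock_period_s,
        )
        paths, _ = viterbi(seqs, model)
        counts = hmm.viterbi_transition_counts(paths, 3)
        direct = counts[0, 2] + counts[2, 0]
        total = counts.sum()
        assert total > 50
        assert direct / total <= 0.01
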