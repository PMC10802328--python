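"""HMM construction and the unique-state Viterbi decoder."""

import itertools
import math

import numpy as np
import pytest

from catrace.candidates import CaCandidate
from catrace.constants import AA_ALPHABET
from catrace.hmm import (InsufficientStatesError, Observation,
                         TransitionParams, align_chains,
                         build_emission_matrix, build_hmm,
                         build_transition_matrix, constrained_viterbi,
                         initial_distribution, traces_to_model,
                         transition_density)

MU = 3.8047
SIGMA = 0.036


def _cand(coord, aa=None, p=0.9):
    if aa is None:
        aa = np.full(20, 1 / 20)
    return CaCandidate(coord=np.asarray(coord, float), p_ca=p, aa_probs=aa)


def _random_hmm(rng, k):
    coords = rng.uniform(0, 12, (k, 3))
    aa = rng.dirichlet(np.ones(20) * 0.5, size=k)
    return build_hmm([_cand(coords[i], aa[i]) for i in range(k)])


def _brute_force_viterbi(model, obs):
    """Enumerate all K^T state sequences; return (best score, best path).

    Ties resolved toward the lexicographically smallest sequence, matching
    the decoder's lowest-predecessor-index rule.
    """
    k, t_len = model.n_states, len(obs)
    with np.errstate(divide="ignore"):
        lg = np.log(build_transition_matrix(model.coords, model.params))
        ld = np.log(model.delta)
        lp = np.log(initial_distribution(model.delta, obs.symbols[0],
                                         np.arange(k)))
    best, best_seq = -np.inf, None
    for seq in itertools.product(range(k), repeat=t_len):
        s = lp[seq[0]] + ld[seq[0], obs.symbols[0]]
        for t in range(1, t_len):
            s += lg[seq[t - 1], seq[t]] + ld[seq[t], obs.symbols[t]]
        if s > best:
            best, best_seq = s, seq
    return best, best_seq


class TestTransitionDensity:
    def test_value_at_mode(self):
        f_mu = transition_density(MU)
        assert f_mu == pytest.approx(
            1.0 / (10 * SIGMA * math.sqrt(2 * math.pi)), rel=1e-12)
        assert f_mu == pytest.approx(1.10817, abs=1e-4)

    def test_one_sigma_ratio(self):
        p = TransitionParams()
        ratio = transition_density(MU + 10 * SIGMA, p) / transition_density(MU, p)
        assert ratio == pytest.approx(math.exp(-0.5), rel=1e-12)

    def test_symmetry_about_mode(self):
        for d in (0.1, 1.0, 5.0):
            assert transition_density(MU - d) == pytest.approx(
                transition_density(MU + d), rel=1e-12)


class TestTransitionMatrix:
    def test_two_states(self):
        g = build_transition_matrix([[0, 0, 0], [5, 0, 0]])
        assert np.allclose(g, [[0, 1], [1, 0]])

    def test_equidistant_targets_split_evenly(self):
        g = build_transition_matrix([[0, 0, 0], [4, 0, 0], [-4, 0, 0]])
        assert g[0] == pytest.approx([0, 0.5, 0.5])

    def test_collinear_ratio_matches_scalar_density(self):
        coords = [[0, 0, 0], [MU, 0, 0], [2 * MU, 0, 0]]
        g = build_transition_matrix(coords)
        expected = transition_density(MU) / transition_density(2 * MU)
        assert g[0][1] / g[0][2] == pytest.approx(expected, rel=1e-9)

    def test_rows_normalized_diag_zero(self, rng):
        g = build_transition_matrix(rng.uniform(0, 20, (10, 3)))
        assert np.allclose(g.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(np.diag(g), 0.0)

    def test_duplicate_coordinates_allowed(self):
        g = build_transition_matrix([[0, 0, 0], [0, 0, 0], [MU, 0, 0]])
        assert np.allclose(g.sum(axis=1), 1.0)
        assert np.all(np.isfinite(g))


class TestEmissionMatrix:
    def test_uniform_inputs_give_uniform_row(self):
        d = build_emission_matrix(np.full((3, 20), 1 / 20), np.full(20, 1 / 20))
        assert np.allclose(d, 1 / 20)

    def test_one_hot_prediction_dominates_background(self, rng):
        a = np.zeros((1, 20))
        a[0, 0] = 1.0
        bg = rng.dirichlet(np.ones(20))
        d = build_emission_matrix(a, bg)
        assert d[0, 0] == pytest.approx(1.0)
        assert np.all(d[0, 1:] == 0)

    def test_hand_arithmetic_example(self):
        a = np.zeros((1, 20))
        a[0, :2] = [0.64, 0.36]
        b = np.full(20, 1e-12)
        b[:2] = [0.25, 0.75]
        b /= b.sum()
        d = build_emission_matrix(a, b)
        # sqrt(0.64*0.25)=0.4, sqrt(0.36*0.75)=0.519615 -> (0.4350, 0.5650)
        assert d[0, 0] == pytest.approx(0.4350, abs=2e-4)
        assert d[0, 1] == pytest.approx(0.5650, abs=2e-4)

    def test_all_zero_state_rejected(self):
        with pytest.raises(ValueError):
            build_emission_matrix(np.zeros((1, 20)), np.full(20, 1 / 20))

    def test_rows_sum_to_one(self, rng):
        d = build_emission_matrix(rng.dirichlet(np.ones(20), 8))
        assert np.allclose(d.sum(axis=1), 1.0, atol=1e-12)


class TestInitialDistribution:
    def test_single_active_state(self):
        delta = np.full((3, 20), 1 / 20)
        pi = initial_distribution(delta, 0, [2])
        assert pi[2] == 1.0 and pi[:2].sum() == 0.0

    def test_equal_emissions_split(self):
        delta = np.full((2, 20), 1 / 20)
        assert initial_distribution(delta, 3, [0, 1]) == pytest.approx([0.5, 0.5])

    def test_proportional_to_emission(self):
        delta = np.zeros((3, 20))
        delta[:, 4] = [0.2, 0.3, 0.5]
        delta[:, 5] = 1 - delta[:, 4]
        pi = initial_distribution(delta, 4, [0, 1, 2])
        assert pi == pytest.approx([0.2, 0.3, 0.5])

    def test_zero_emission_falls_back_to_uniform(self):
        delta = np.zeros((2, 20))
        delta[:, 0] = 1.0
        pi = initial_distribution(delta, 7, [0, 1])
        assert pi == pytest.approx([0.5, 0.5])


def _perfect_chain(seq, start=(0.0, 0.0, 0.0), direction=(1.0, 0.0, 0.0),
                   soft=0.0):
    """Candidates on an ideal 3.8047 A line with (near-)one-hot emissions.

    ``soft`` > 0 smooths the one-hot vectors so that mismatched
    state-symbol pairs keep a small nonzero emission (strict one-hot
    makes any forced mismatch impossible, log 0 = -inf)."""
    start = np.asarray(start)
    direction = np.asarray(direction)
    cands = []
    for i, ch in enumerate(seq):
        aa = np.full(20, soft / 20)
        aa[AA_ALPHABET.index(ch)] += 1.0 - soft
        cands.append(_cand(start + i * MU * direction, aa))
    return cands


class TestConstrainedViterbi:
    def test_recovers_forced_chain(self):
        seq = "ACD"
        model = build_hmm(_perfect_chain(seq))
        trace = constrained_viterbi(model, Observation.from_sequence(seq))
        assert list(trace.path) == [0, 1, 2]
        assert trace.residues == list(seq)

    def test_single_symbol_reduces_to_argmax(self, rng):
        model = _random_hmm(rng, 5)
        obs = Observation([7])
        trace = constrained_viterbi(model, obs)
        pi = initial_distribution(model.delta, 7, np.arange(5))
        expected = int(np.argmax(pi * model.delta[:, 7]))
        assert trace.path[0] == expected

    def test_path_always_simple(self, rng):
        for _ in range(30):
            k = int(rng.integers(3, 8))
            t = int(rng.integers(1, min(k, 5) + 1))
            model = _random_hmm(rng, k)
            trace = constrained_viterbi(model, Observation(rng.integers(0, 20, t)))
            assert len(set(trace.path)) == len(trace.path) == t

    def test_matches_brute_force_when_optimum_simple(self, rng):
        matched = 0
        for _ in range(60):
            k = int(rng.integers(3, 7))
            t = int(rng.integers(2, min(k, 4) + 1))
            model = _random_hmm(rng, k)
            obs = Observation(rng.integers(0, 20, t))
            best, best_seq = _brute_force_viterbi(model, obs)
            if len(set(best_seq)) != t:
                continue
            trace = constrained_viterbi(model, obs)
            assert list(trace.path) == list(best_seq)
            assert trace.log_score == pytest.approx(best, abs=1e-9)
            matched += 1
        assert matched >= 20  # sanity: the comparison actually exercised

    def test_constrained_never_beats_unconstrained(self, rng):
        for _ in range(20):
            model = _random_hmm(rng, 6)
            obs = Observation(rng.integers(0, 20, 4))
            con = constrained_viterbi(model, obs, unique=True)
            unc = constrained_viterbi(model, obs, unique=False)
            assert con.log_score <= unc.log_score + 1e-9

    def test_unconstrained_matches_hmmlearn(self, rng):
        """Independent library oracle for the standard Viterbi decoder."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        for _ in range(10):
            model = _random_hmm(rng, 5)
            obs = Observation(rng.integers(0, 20, 4))
            gamma = build_transition_matrix(model.coords, model.params)
            pi = initial_distribution(model.delta, obs.symbols[0], np.arange(5))
            ref = hmmlearn.CategoricalHMM(n_components=5)
            ref.startprob_ = pi
            ref.transmat_ = gamma
            ref.emissionprob_ = model.delta
            score, path = ref.decode(obs.symbols.reshape(-1, 1),
                                     algorithm="viterbi")
            ours = constrained_viterbi(model, obs, unique=False)
            assert ours.log_score == pytest.approx(score, abs=1e-8)
            assert list(ours.path) == list(path)

    def test_insufficient_states_error_names_chain(self, rng):
        model = _random_hmm(rng, 3)
        obs = Observation(rng.integers(0, 20, 4), name="chain_B")
        with pytest.raises(InsufficientStatesError, match="chain_B"):
            constrained_viterbi(model, obs)

    def test_log_linear_agreement_tiny(self, rng):
        """Log-space DP equals direct linear-space evaluation of its path."""
        for _ in range(10):
            model = _random_hmm(rng, 5)
            obs = Observation(rng.integers(0, 20, 3))
            trace = constrained_viterbi(model, obs)
            gamma = build_transition_matrix(model.coords, model.params)
            pi = initial_distribution(model.delta, obs.symbols[0], np.arange(5))
            p = pi[trace.path[0]] * model.delta[trace.path[0], obs.symbols[0]]
            for t in range(1, 3):
                p *= (gamma[trace.path[t - 1], trace.path[t]]
                      * model.delta[trace.path[t], obs.symbols[t]])
            assert math.log(p) == pytest.approx(trace.log_score, rel=1e-9)


class TestAlignChains:
    def test_two_disjoint_perfect_chains(self):
        seq_a, seq_b = "ACDEF", "GHIKL"
        cands = (_perfect_chain(seq_a)
                 + _perfect_chain(seq_b, start=(0, 50, 0)))
        model = build_hmm(cands)
        traces = align_chains(model, [Observation.from_sequence(seq_a, "A"),
                                      Observation.from_sequence(seq_b, "B")])
        assert list(traces[0].path) == [0, 1, 2, 3, 4]
        assert list(traces[1].path) == [5, 6, 7, 8, 9]
        assert traces[0].residues == list(seq_a)
        assert traces[1].residues == list(seq_b)

    def test_states_removed_between_chains(self):
        seq = "ACDEF"
        model = build_hmm(_perfect_chain(seq))
        with pytest.raises(InsufficientStatesError):
            align_chains(model, [Observation.from_sequence(seq),
                                 Observation.from_sequence("A")])

    def test_chain_order_changes_state_claims(self, rng):
        # two chains competing for the same states: input order wins first
        seq = "AC"
        cands = _perfect_chain("ACDE", soft=0.05)
        model = build_hmm(cands)
        obs = [Observation.from_sequence(seq, "x"),
               Observation.from_sequence(seq, "y")]
        traces = align_chains(model, obs)
        assert set(traces[0].path).isdisjoint(traces[1].path)
        # regression: deterministic claims under the default input order
        again = align_chains(model, obs)
        assert list(traces[0].path) == list(again[0].path)
        assert list(traces[1].path) == list(again[1].path)

    def test_longest_first_order(self):
        cands = _perfect_chain("ACDEF", soft=0.05)
        model = build_hmm(cands)
        obs = [Observation.from_sequence("AC", "short"),
               Observation.from_sequence("CDE", "long")]
        traces = align_chains(model, obs, order="longest_first")
        assert len(traces[0].path) == 2 and len(traces[1].path) == 3
        assert set(traces[0].path).isdisjoint(traces[1].path)


class TestTracesToModel:
    def test_empty(self):
        assert traces_to_model([]).n_residues == 0

    def test_three_residue_numbering(self):
        seq = "ACD"
        model = build_hmm(_perfect_chain(seq))
        trace = constrained_viterbi(model, Observation.from_sequence(seq))
        bm = traces_to_model([trace])
        assert bm.chains[0].chain_id == "A"
        assert bm.chains[0].residues == ["A", "C", "D"]
        assert bm.n_residues == 3
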