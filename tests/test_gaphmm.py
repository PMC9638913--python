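"""Gap-HMM topology, frozen-emission training, forward scoring, RF combiner."""

import itertools

import numpy as np
import pytest

from conftest import consensus_pfm, make_pfm, random_pfm
from ssmotif.alphabets import get_alphabet
from ssmotif.gaphmm import (
    GapHMM,
    HMMError,
    build_gap_hmm,
    combine_hmm_scores,
    log_probabilities,
    log_probability,
    train_transitions,
    training_subsample,
)


def brute_force_logprob(hmm: GapHMM, symbols: list[int]) -> float:
    """Oracle: sum P(path, observations) over every state path."""
    S = hmm.n_states
    total = 0.0
    for path in itertools.product(range(S), repeat=len(symbols)):
        p = hmm.startprob[path[0]] * hmm.emissions[path[0], symbols[0]]
        for a, b, sym in zip(path, path[1:], symbols[1:]):
            p *= hmm.transmat[a, b] * hmm.emissions[b, sym]
        total += p
    return float(np.log(total))


def sample_from(hmm: GapHMM, rng, length: int) -> str:
    symbols = get_alphabet(hmm.alphabet).symbols
    state = rng.choice(hmm.n_states, p=hmm.startprob)
    out = []
    for _ in range(length):
        out.append(symbols[rng.choice(len(symbols), p=hmm.emissions[state])])
        state = rng.choice(hmm.n_states, p=hmm.transmat[state])
    return "".join(out)


class TestTopology:
    def test_state_count_single_pfm(self):
        pfm = random_pfm(np.random.default_rng(0), "sequence", 4)
        hmm = build_gap_hmm([pfm], "sequence")
        # 4 PFM-position states + begin + end + 1 self-pair gap state
        assert hmm.n_states == 7

    def test_state_count_two_pfms(self, rng):
        pfms = [random_pfm(rng, "sequence", 4, "a"), random_pfm(rng, "sequence", 5, "b")]
        hmm = build_gap_hmm(pfms, "sequence")
        # 4 + 5 PFM states + 4 ordered-pair gap states + begin + end
        assert hmm.n_states == 15

    def test_emissions_equal_pfm_columns(self, rng):
        pfm = random_pfm(rng, "sequence", 5)
        hmm = build_gap_hmm([pfm], "sequence")
        start = hmm.state_names.index("pfm0_pos0")
        np.testing.assert_array_equal(hmm.emissions[start : start + 5], pfm.matrix)
        # non-PFM states emit uniformly
        for name in ("begin", "end", "gap_0_to_0"):
            i = hmm.state_names.index(name)
            np.testing.assert_allclose(hmm.emissions[i], 0.25)

    def test_topology_constraints(self, rng):
        pfms = [random_pfm(rng, "sequence", 4, "a"), random_pfm(rng, "sequence", 4, "b")]
        hmm = build_gap_hmm(pfms, "sequence")
        names = hmm.state_names
        ix = {n: i for i, n in enumerate(names)}
        T = hmm.transmat
        # rows stochastic
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-9)
        # begin recursive and feeding both PFM starts
        assert T[ix["begin"], ix["begin"]] > 0
        assert T[ix["begin"], ix["pfm0_pos0"]] > 0
        assert T[ix["begin"], ix["pfm1_pos0"]] > 0
        # mid-PFM states chain strictly forward
        row = T[ix["pfm0_pos1"]]
        assert row[ix["pfm0_pos2"]] == 1.0
        # final position reaches starts, its gap states, and end
        final = ix["pfm0_pos3"]
        for target in ("pfm0_pos0", "pfm1_pos0", "gap_0_to_0", "gap_0_to_1", "end"):
            assert T[final, ix[target]] > 0
        # gap state is recursive and enters only its target PFM
        g = ix["gap_0_to_1"]
        assert T[g, g] > 0 and T[g, ix["pfm1_pos0"]] > 0
        assert T[g].sum() == pytest.approx(T[g, g] + T[g, ix["pfm1_pos0"]])
        # end absorbing
        assert T[ix["end"], ix["end"]] == 1.0

    def test_too_many_pfms_rejected(self, rng):
        pfms = [random_pfm(rng, "sequence", 4, f"p{i}") for i in range(11)]
        with pytest.raises(HMMError):
            build_gap_hmm(pfms, "sequence")

    def test_mixed_alphabets_rejected(self, rng):
        pfms = [random_pfm(rng, "sequence", 4, "a"), random_pfm(rng, "structure2", 4, "b")]
        with pytest.raises(HMMError):
            build_gap_hmm(pfms, "sequence")


class TestForward:
    def test_matches_path_enumeration(self, rng):
        """Forward log-probability equals brute-force path summation."""
        pfm = random_pfm(rng, "structure2", 2)  # 5 states over a 2-letter alphabet
        hmm = build_gap_hmm([pfm], "structure2")
        assert hmm.n_states == 5
        symbols = get_alphabet("structure2").symbols
        for obs in itertools.product(range(2), repeat=4):
            ann = "".join(symbols[i] for i in obs)
            assert log_probability(hmm, ann) == pytest.approx(
                brute_force_logprob(hmm, list(obs)), abs=1e-10
            )

    def test_probability_mass_bounded(self, rng):
        pfm = random_pfm(rng, "structure2", 2)
        hmm = build_gap_hmm([pfm], "structure2")
        symbols = get_alphabet("structure2").symbols
        total = sum(
            np.exp(log_probability(hmm, "".join(symbols[i] for i in obs)))
            for obs in itertools.product(range(2), repeat=3)
        )
        assert total <= 1.0 + 1e-9

    def test_bad_symbol_rejected(self, rng):
        hmm = build_gap_hmm([random_pfm(rng, "sequence", 4)], "sequence")
        from ssmotif.scan import ScanError

        with pytest.raises(ScanError):
            log_probability(hmm, "ACGX")

    def test_empty_rejected(self, rng):
        hmm = build_gap_hmm([random_pfm(rng, "sequence", 4)], "sequence")
        with pytest.raises(HMMError):
            log_probability(hmm, "")


class TestTraining:
    def _training_data(self, rng, n=60):
        letters = np.array(list("ACGU"))
        seqs = []
        for _ in range(n):
            s = "".join(letters[rng.integers(0, 4, size=30)])
            off = rng.integers(0, 25)
            seqs.append(s[:off] + "UGCAU" + s[off + 5:])
        return seqs

    def test_loglik_nondecreasing(self, rng):
        pfm = consensus_pfm("sequence", "UGCAU", name="m")
        hmm = build_gap_hmm([pfm], "sequence")
        trained = train_transitions(hmm, self._training_data(rng), max_iter=15)
        hist = trained.loglik_history
        assert len(hist) >= 2
        assert all(b >= a - 1e-6 for a, b in zip(hist, hist[1:]))

    def test_emissions_frozen(self, rng):
        pfm = consensus_pfm("sequence", "UGCAU", name="m")
        hmm = build_gap_hmm([pfm], "sequence")
        trained = train_transitions(hmm, self._training_data(rng), max_iter=10)
        np.testing.assert_array_equal(trained.emissions, hmm.emissions)

    def test_structural_zeros_stay_zero(self, rng):
        pfm = consensus_pfm("sequence", "UGCAU", name="m")
        hmm = build_gap_hmm([pfm], "sequence")
        trained = train_transitions(hmm, self._training_data(rng), max_iter=10)
        assert np.all(trained.transmat[~hmm.allowed] == 0.0)
        np.testing.assert_allclose(trained.transmat.sum(axis=1), 1.0, atol=1e-9)

    def test_single_string_monotone(self, rng):
        pfm = consensus_pfm("sequence", "UGCAU", name="m")
        hmm = build_gap_hmm([pfm], "sequence")
        trained = train_transitions(hmm, ["ACGUGCAUACGU"], max_iter=10)
        hist = trained.loglik_history
        assert all(b >= a - 1e-6 for a, b in zip(hist, hist[1:]))

    def test_empty_training_rejected(self, rng):
        hmm = build_gap_hmm([random_pfm(rng, "sequence", 4)], "sequence")
        with pytest.raises(HMMError):
            train_transitions(hmm, [])

    def test_training_recovers_in_family_model(self, rng):
        """Training a uniform-initialized model on data drawn from a
        non-uniform model of the same topology improves held-out
        log-likelihood (median over seeded replicates)."""
        pfm = consensus_pfm("structure2", "PPU", name="m")
        base = build_gap_hmm([pfm], "structure2")
        truth = GapHMM(
            alphabet=base.alphabet,
            pfms=base.pfms,
            state_names=base.state_names,
            startprob=base.startprob,
            transmat=base.transmat.copy(),
            emissions=base.emissions,
            allowed=base.allowed,
        )
        skew = np.where(base.allowed, np.exp(rng.normal(scale=1.0, size=base.transmat.shape)), 0.0)
        truth.transmat = skew / skew.sum(axis=1, keepdims=True)
        deltas = []
        for rep in range(10):
            gen = np.random.default_rng(500 + rep)
            train = [sample_from(truth, gen, 15) for _ in range(60)]
            heldout = [sample_from(truth, gen, 15) for _ in range(60)]
            before = log_probabilities(base, heldout).sum()
            trained = train_transitions(base, train, max_iter=10)
            after = log_probabilities(trained, heldout).sum()
            deltas.append(after - before)
        assert np.median(deltas) > 0

    def test_subsample_rule(self):
        assert training_subsample(30_000) == 10_000
        assert training_subsample(19_999) == 9_999
        assert training_subsample(8_000) == 4_000


class TestCombiner:
    def test_identical_features_near_chance(self, rng):
        base = rng.normal(size=(100, 7))
        X = np.vstack([base, base])  # both classes share the same feature rows
        y = np.repeat([0, 1], 100)
        _, auroc = combine_hmm_scores(X, y, seed=0)
        assert 0.4 <= auroc <= 0.6

    def test_perfect_feature_resubstitution(self, rng):
        n = 100
        y = np.repeat([0, 1], n)
        X = rng.normal(size=(2 * n, 7))
        X[:, 2] = y * 10.0
        _, auroc = combine_hmm_scores(X, y, seed=0)
        assert auroc == pytest.approx(1.0)

    def test_single_class_rejected(self, rng):
        with pytest.raises(HMMError):
            combine_hmm_scores(rng.normal(size=(10, 7)), np.ones(10))


class TestBipartiteRecovery:
    def test_gap_hmm_separates_bipartite_binders(self):
        """Two planted sub-motifs with variable spacing: HMM log-probabilities
        fed to the RF combiner separate bound from background probes."""
        from ssmotif.annotate import annotate_probe
        from ssmotif.discover import discover_motifs
        from ssmotif.simulate import GeneratorConfig, generate_dataset

        config = GeneratorConfig(
            n_probes=300, structure_mode="bipartite", seed=11,
            motif_consensus="ACUAAC", motif_consensus_2="UAAC",
        )
        ds = generate_dataset(config)
        pos = [p.sequence for p in ds.positives]
        neg = [p.sequence for p in ds.negatives]
        pfms = discover_motifs(pos[:150], neg[:150], "sequence")
        assert pfms, "discovery found nothing on bipartite data"
        hmm = build_gap_hmm(pfms[:4], "sequence")
        trained = train_transitions(hmm, pos[150:225], max_iter=20)
        test_pos, test_neg = pos[225:], neg[150:]
        lp = np.concatenate(
            [log_probabilities(trained, test_pos), log_probabilities(trained, test_neg)]
        ).reshape(-1, 1)
        y = np.array([1] * len(test_pos) + [0] * len(test_neg))
        _, auroc = combine_hmm_scores(lp, y, seed=0)
        assert auroc > 0.7
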