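"""Gapped k-mer enumeration, counting and Markov-background scoring."""

import itertools

import numpy as np
import pytest
from collections import Counter

from selexpress import simulate as sim
from selexpress.kmers import (
    GappedKmer,
    MarkovBackground,
    UnsupportedPatternError,
    count_patterns,
    enrichment_table,
    enumerate_gapped_kmers,
    expected_count,
)

from conftest import random_reads


def brute_force_patterns(read, l_values=(4, 5), n_values=(4, 5)):
    """Independent sliding-window enumerator (test oracle)."""
    out = set()
    N = len(read)
    for l in l_values:
        for n in n_values:
            for m in range(0, N - l - n + 1):
                for off in range(0, N - (l + m + n) + 1):
                    out.add(
                        read[off : off + l]
                        + "x" * m
                        + read[off + l + m : off + l + m + n]
                    )
    return out


class TestEnumeration:
    def test_read_shorter_than_minimal_span_yields_nothing(self):
        assert enumerate_gapped_kmers("ACGT") == set()

    def test_worked_example_pattern_is_emitted(self):
        # a read containing ACTACGGGACGC instantiates the 5-3-4 pattern
        # ACTACxxxACGC (spacers match any base)
        read = "TTACTACGGGACGCAA"
        assert "ACTACxxxACGC" in enumerate_gapped_kmers(read)

    def test_matches_bruteforce_on_random_reads(self, rng):
        for read in random_reads(rng, 200, lengths=(8, 19)):
            assert enumerate_gapped_kmers(read) == brute_force_patterns(read)

    def test_rejects_ambiguous_bases(self):
        with pytest.raises(ValueError):
            enumerate_gapped_kmers("ACGTNACGTACGT")


class TestCounting:
    def test_threshold_boundary_is_inclusive(self, rng):
        reads = ["ACGTACGTACGTACGT"] * 49 + ["TTTTGGGGCCCCAAAA"] * 50
        counts = count_patterns(reads, count_threshold=50)
        assert "ACGTACGTACGTACGT".startswith("ACGT")  # sanity
        assert all(c >= 50 for c in counts.values())
        # a pattern only present in the 49-read group is dropped
        assert "ACGTxxxxxxxxACGT" not in counts
        assert "TTTTxxxxxxxxAAAA" in counts

    def test_pattern_twice_in_one_read_counts_once(self):
        # ACGTACGT at offsets 0 and 8 -> 4-0-4 pattern ACGTACGT occurs twice
        read = "ACGTACGTACGTACGT"
        counts = count_patterns([read], count_threshold=1)
        assert counts["ACGTACGT"] == 1

    def test_counts_equal_per_read_enumeration(self, rng):
        reads = random_reads(rng, 250, lengths=(10, 19))
        vec = count_patterns(reads, count_threshold=1)
        ref = Counter()
        for r in reads:
            ref.update(enumerate_gapped_kmers(r))
        assert vec == dict(ref)

    def test_planted_pattern_bookkeeping(self, rng):
        carriers = ["AAAACCGGTTGGCCAA"] * 73
        others = random_reads(rng, 200, lengths=(16, 16))
        others = [r for r in others if "AAAACCGGTTGGCCAA" != r]
        counts = count_patterns(carriers + others, count_threshold=1)
        expected = 73 + sum(
            "AAAAxxxxxxGGCC" in enumerate_gapped_kmers(r) for r in others
        )
        assert counts["AAAAxxxxxxGGCC"] == expected

    def test_mapping_input_weights_counts(self):
        counts = count_patterns({"ACGTACGTACGTACGT": 60}, count_threshold=50)
        assert counts["ACGTACGT"] == 60


class TestMarkovBackground:
    def test_all_A_corpus_is_deterministic(self):
        model = MarkovBackground.train(["A" * 16] * 5, pseudocount=0.0)
        ctx = 0  # AAAAA
        assert model.conditional[ctx, 0] == pytest.approx(1.0)

    def test_conditionals_normalize_exactly(self, small_library):
        model = MarkovBackground.train(small_library[:2000])
        np.testing.assert_allclose(model.conditional.sum(axis=1), 1.0, atol=1e-12)
        assert model.initial.sum() == pytest.approx(1.0, abs=1e-9)

    def test_uniform_corpus_conditionals_near_quarter(self, rng):
        reads = random_reads(rng, 30_000, lengths=(16, 16))
        model = MarkovBackground.train(reads)
        # ~330k transition windows over 4096 cells -> ~80 per cell; pool
        # over contexts for a tight binomial check on the marginal
        marginal = model.conditional.mean(axis=0)
        n_windows = 30_000 * 11
        se = np.sqrt(0.25 * 0.75 / (n_windows / 4))
        assert np.all(np.abs(marginal - 0.25) < 3 * se + 0.01)

    def test_no_reads_is_an_error(self):
        with pytest.raises(ValueError):
            MarkovBackground.train([])


class TestPatternProbability:
    def test_uniform_model_worked_example(self, uniform_bg):
        # ACTACxxxACGC: initial 5-mer (1/4)^5, wildcards contribute 1,
        # four right-side bases (1/4)^4 -> (1/4)^9
        p = uniform_bg.pattern_probability("ACTACxxxACGC")
        assert p == pytest.approx(0.25**9, rel=1e-12)

    def test_wildcard_tail_equals_initial_probability(self, biased_bg):
        p_full = biased_bg.pattern_probability("ACGTAxxxx")
        p_init = biased_bg.pattern_probability("ACGTAx")
        assert p_full == pytest.approx(p_init, rel=1e-12)

    def test_hand_computed_factor_product(self):
        # context-independent per-base table so the factor list can be
        # multiplied by hand exactly as the chain decomposition prescribes
        freqs = np.array([0.4, 0.3, 0.2, 0.1])
        S = 4**5
        cond = np.tile(freqs, (S, 1))
        states = np.arange(S)
        init = np.ones(S)
        for t in range(5):
            init *= freqs[(states >> (2 * (4 - t))) & 3]
        model = MarkovBackground(cond, init, order=5)
        # ACTACxxxACGC: init P(ACTAC) * 1*1*1 * P(A)P(C)P(G)P(C)
        expected = (
            freqs[0] * freqs[1] * freqs[3] * freqs[0] * freqs[1]
        ) * (freqs[0] * freqs[1] * freqs[2] * freqs[1])
        assert model.pattern_probability("ACTACxxxACGC") == pytest.approx(
            expected, rel=1e-12
        )

    def test_marginalization_over_one_position(self, biased_bg):
        base = "ACGTAxxCA"
        for pos in (2, 8):
            total = sum(
                biased_bg.pattern_probability(base[:pos] + b + base[pos + 1 :])
                for b in "ACGT"
            )
            wild = biased_bg.pattern_probability(base[:pos] + "x" + base[pos + 1 :])
            assert total == pytest.approx(wild, rel=1e-9)

    def test_full_marginalization_sums_to_wildcard_template(self, biased_bg):
        # all 4^7 completions of a 7-position template sum to the
        # all-wildcard probability (= 1 for span >= order + 1)
        total = sum(
            biased_bg.pattern_probability("".join(letters))
            for letters in itertools.product("ACGT", repeat=7)
        )
        assert total == pytest.approx(1.0, rel=1e-9)

    def test_short_pattern_is_unsupported(self, uniform_bg):
        with pytest.raises(UnsupportedPatternError):
            uniform_bg.pattern_probability("ACGTA")


class TestExpectedCount:
    def test_degenerate_probability_one(self):
        model = MarkovBackground.train(["A" * 16] * 10, pseudocount=0.0)
        e = expected_count(model, GappedKmer("AAAA", 0, "AAAA"), {16: 10_000})
        assert e == pytest.approx(10_000, rel=1e-9)

    def test_uniform_single_position_scales_probability(self, uniform_bg):
        e = expected_count(
            uniform_bg, GappedKmer.from_text("ACTACxxxACGC"), {16: 10**6},
            convention="single-position",
        )
        assert e == pytest.approx(0.25**9 * 10**6, rel=1e-9)

    def test_any_offset_matches_monte_carlo(self, rng):
        reads = random_reads(rng, 100_000, lengths=(19, 19))
        model = sim.uniform_background()
        pat = "ACGTxxCCAT"
        counts = count_patterns(reads, count_threshold=1)
        obs = counts.get(pat, 0)
        exp = expected_count(
            model, GappedKmer.from_text(pat), {19: len(reads)},
            convention="per-read-any-offset",
        )
        assert abs(obs - exp) < 3 * np.sqrt(exp) + 1

    def test_span_exceeding_reads_gives_zero_any_offset(self, uniform_bg):
        e = expected_count(
            uniform_bg, GappedKmer("ACGTA", 12, "ACGTA"), {16: 1000},
            convention="per-read-any-offset",
        )
        assert e == 0.0


class TestEnrichmentTable:
    def test_observed_equals_expected_gives_unity(self, uniform_bg):
        pat = "ACTACxxxACGC"
        exp = expected_count(
            uniform_bg, GappedKmer.from_text(pat), {16: 10**6},
            convention="single-position",
        )
        tab = enrichment_table(
            {pat: int(round(exp))}, uniform_bg, {16: 10**6},
            convention="single-position",
        )
        assert tab.iloc[0]["enrichment"] == pytest.approx(1.0, rel=0.15)

    def test_invariant_under_sample_duplication(self, small_library):
        model = MarkovBackground.train(small_library)
        reads = small_library[:4000]
        counts = count_patterns(reads, count_threshold=20)
        lc = Counter(len(s) for s in reads)
        t1 = enrichment_table(counts, model, dict(lc), convention="per-read-any-offset")
        counts2 = {p: 2 * c for p, c in counts.items()}
        lc2 = {L: 2 * n for L, n in lc.items()}
        t2 = enrichment_table(counts2, model, lc2, convention="per-read-any-offset")
        m1 = t1.set_index("pattern")["enrichment"]
        m2 = t2.set_index("pattern")["enrichment"]
        # per-read-any-offset is slightly sublinear in reads through the
        # (1-(1-p)^k) term, but p is tiny here: agreement to 1e-6 relative
        assert np.allclose(m1.sort_index(), m2.sort_index(), rtol=1e-6)

    def test_sorted_by_descending_enrichment(self, small_library):
        model = MarkovBackground.train(small_library)
        counts = count_patterns(small_library[:4000], count_threshold=20)
        lc = Counter(len(s) for s in small_library[:4000])
        tab = enrichment_table(counts, model, dict(lc))
        e = tab["enrichment"].to_numpy()
        assert np.all(np.diff(e) <= 1e-12)
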