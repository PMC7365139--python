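"""sgRNA:promoter library design: construction, screening, diversity selection."""

import itertools

import numpy as np
import pytest

from csmux import guides
from csmux.guides import (
    GenomeTarget,
    MatchGraph,
    PreSequence,
    RejectedDesign,
    SCAFFOLDS,
    build_pair,
    expand_diverse_sets,
    generate_insulator,
    generate_presequences,
    insulate_promoter,
    match_weight,
    offtarget_screen,
    revcomp,
    score_and_pick,
    select_core_subset,
)


class TestPreSequences:
    def test_length_and_alphabet(self):
        for p in generate_presequences(50, 1):
            assert len(p.seq) == 15
            assert set(p.seq) <= set("ACGT")

    def test_gc_bias_near_forty_percent(self):
        pres = generate_presequences(10_000, 3)
        gc = np.mean([sum(c in "GC" for c in p.seq) / 15 for p in pres])
        assert 0.38 <= gc <= 0.42

    def test_seed_determinism(self):
        a = generate_presequences(20, 9)
        b = generate_presequences(20, 9)
        assert [p.seq for p in a] == [p.seq for p in b]


class TestBuildPair:
    def test_operator_construction(self):
        # hand-assembled fixture: a pre-sequence known to pass the filters
        pre = PreSequence("ATTATCATCTACATT")
        d = build_pair(pre, "apFAB126")
        sc = SCAFFOLDS["apFAB126"]
        assert d.sgrna_operator == sc.minus35 + pre.seq[:14]
        assert len(d.sgrna_operator) == 20
        assert (sc.minus35 + pre.seq + "GG" + sc.minus10) in d.promoter_core
        assert d.operator_pam.endswith(pre.seq[14] + "GG")

    def test_round_trip_operator_reproduces_promoter_operator(self):
        pres = [p for p in generate_presequences(200, 5)]
        built = 0
        for p in pres:
            try:
                d = build_pair(p)
            except RejectedDesign:
                continue
            built += 1
            sc = SCAFFOLDS[d.scaffold]
            # reverse-engineer: the 20-nt operator re-locates its promoter site
            idx = d.promoter_core.find(d.sgrna_operator)
            assert idx == len(sc.upstream)
            pam = d.promoter_core[idx + 20 : idx + 23]
            assert pam == d.pre.pam_first + "GG"
        assert built > 0

    def test_extra_ngg_rejected(self):
        # operator engineered to end in G + appended GG -> two NGG windows
        pre = PreSequence("ATTATCATCTACAGG")
        with pytest.raises(RejectedDesign, match="NGG"):
            build_pair(pre, "apFAB126")

    def test_bsai_site_rejected(self):
        # GGTCTC formed entirely within the insert
        pre = PreSequence("ATGGTCTCTCTAATT")
        with pytest.raises(RejectedDesign, match="BsaI"):
            build_pair(pre, "apFAB126")

    def test_unknown_scaffold(self):
        with pytest.raises(ValueError, match="scaffold"):
            build_pair(PreSequence("A" * 15), "nope")


class TestOfftargetScreen:
    def oracle(self, d, g):
        """Naive sliding-window re-implementation of the screening rules."""
        genome = g.genome.upper()
        L = len(genome)
        op = d.operator_pam
        strands = ((genome, False), (revcomp(genome), True))

        def fwd_window(pos, ln, rc):
            return (L - pos - ln, L - pos) if rc else (pos, pos + ln)

        hit10 = []
        for seq, rc in strands:
            for i in range(L - 9):
                if seq[i : i + 10] == op[-10:]:
                    hit10.append(fwd_window(i, 10, rc))
        for s, e in hit10:
            if any(s < fe and fs < e for fs, fe, _ in g.essential_features):
                return "fail_10nt_essential"
        for seq, rc in strands:
            for i in range(L - 11):
                if seq[i : i + 12] == op[-12:]:
                    return "fail_12nt_anywhere"
        seed = d.sgrna_operator[-13:]
        for seq, rc in strands:
            for i in range(L - 15):
                window = seq[i : i + 13]
                mism = sum(a != b for a, b in zip(window, seed))
                if mism <= 1 and seq[i + 14 : i + 16] in ("GG", "AG"):
                    return "fail_seed_mismatch"
        return "pass"

    def test_clean_genome_passes(self, accepted_design, random_genome_50kb):
        verdict = offtarget_screen(accepted_design, GenomeTarget(random_genome_50kb))
        assert verdict == self.oracle(accepted_design, GenomeTarget(random_genome_50kb))

    def test_planted_12nt_suffix(self, accepted_design, random_genome_50kb):
        g = random_genome_50kb
        planted = g[:30_000] + accepted_design.operator_pam[-12:] + g[30_000:]
        assert offtarget_screen(accepted_design, GenomeTarget(planted)) == "fail_12nt_anywhere"

    def test_planted_10nt_in_essential(self, accepted_design, random_genome_50kb):
        g = random_genome_50kb
        planted = g[:10_000] + accepted_design.operator_pam[-10:] + g[10_000:]
        target = GenomeTarget(planted, ((9_900, 10_100, "+"),))
        assert offtarget_screen(accepted_design, target) == "fail_10nt_essential"

    def test_planted_seed_one_mismatch_with_nag(self, accepted_design, random_genome_50kb):
        seed = accepted_design.sgrna_operator[-13:]
        mutated = ("A" if seed[5] != "A" else "C") + ""  # one mismatch at pos 5
        bad = seed[:5] + mutated + seed[6:]
        g = random_genome_50kb
        planted = g[:20_000] + bad + "TAG" + g[20_000:]
        assert offtarget_screen(accepted_design, GenomeTarget(planted)) == "fail_seed_mismatch"

    def test_planted_on_reverse_strand(self, accepted_design, random_genome_50kb):
        g = random_genome_50kb
        planted = g[:15_000] + revcomp(accepted_design.operator_pam[-12:]) + g[15_000:]
        assert offtarget_screen(accepted_design, GenomeTarget(planted)) == "fail_12nt_anywhere"

    def test_agrees_with_oracle_on_planted_genomes(self, accepted_design, random_genome_50kb):
        g = random_genome_50kb
        cases = [
            GenomeTarget(g[:5_000]),
            GenomeTarget(g[:5_000] + accepted_design.operator_pam[-12:] + g[5_000:10_000]),
            GenomeTarget(
                g[:3_000] + accepted_design.sgrna_operator[-13:] + "CGG" + g[3_000:8_000]
            ),
        ]
        for target in cases:
            assert offtarget_screen(accepted_design, target) == self.oracle(
                accepted_design, target
            )


class TestMatchGraph:
    def test_identical_is_fifteen(self):
        p = PreSequence("ACGTACGTACGTACG")
        assert match_weight(p, p) == 15

    def test_single_difference_is_fourteen(self):
        a = PreSequence("ACGTACGTACGTACG")
        b = PreSequence("ACGTACGTACGTACC")
        assert match_weight(a, b) == 14

    def test_matches_positionwise_oracle(self, rng):
        pres = generate_presequences(100, 17)
        pairs = rng.integers(0, 100, size=(1000, 2))
        for i, j in pairs:
            expected = sum(
                1 for x, y in zip(pres[i].seq, pres[j].seq) if x == y
            )
            assert match_weight(pres[i], pres[j]) == expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            match_weight("ACGT", "ACGTA")

    def test_edge_count_formula(self):
        g = MatchGraph(generate_presequences(200, 1))
        assert g.n_edges == 200 * 199 // 2


class TestCoreSubset:
    def test_heuristic_within_125_percent_of_exhaustive(self):
        pres = generate_presequences(12, 23)
        g = MatchGraph(pres)
        w = g.weight_matrix()
        best = min(
            sum(w[i, j] for i, j in itertools.combinations(s, 2))
            for s in itertools.combinations(range(12), 4)
        )
        _, total = select_core_subset(pres, core_size=4)
        assert total <= 1.25 * best

    def test_beats_random_subsets(self, rng):
        pres = generate_presequences(60, 29)
        g = MatchGraph(pres)
        w = g.weight_matrix()
        _, total = select_core_subset(pres, core_size=15)
        worse = 0
        for _ in range(100):
            idx = rng.choice(60, size=15, replace=False)
            rand_total = int(w[np.ix_(idx, idx)].sum() // 2)
            if total <= rand_total:
                worse += 1
        assert worse >= 95  # heuristic beats chance essentially always

    def test_refinement_never_increases_total(self):
        pres = generate_presequences(40, 31)
        g = MatchGraph(pres)
        w = g.weight_matrix().astype(np.int64)
        totals = []
        for loops in range(4):
            idx, total = select_core_subset(pres, core_size=10, refinement_loops=loops)
            totals.append(total)
        assert all(b <= a for a, b in zip(totals, totals[1:]))

    def test_too_few_sequences(self):
        with pytest.raises(ValueError):
            select_core_subset(generate_presequences(5, 0), core_size=10)

    def test_zero_weight_graph(self):
        # pairwise disjoint at every position -> any subset has weight 0
        pres = [
            PreSequence("A" * 15),
            PreSequence("C" * 15),
            PreSequence("G" * 15),
            PreSequence("T" * 15),
        ]
        _, total = select_core_subset(pres, core_size=2)
        assert total == 0


class TestDiverseSets:
    def test_no_qualifying_pair_gives_empty(self):
        pres = [PreSequence("A" * 15), PreSequence("A" * 14 + "C")]
        assert expand_diverse_sets(pres, max_pair_weight=5, min_size=2) == []

    def test_constructed_unique_triple_found(self):
        """Six sequences engineered so exactly one 3-set is mutually compatible."""
        a = PreSequence("AAAAACCCCCGGGGG")
        b = PreSequence("CCCCCGGGGGTTTTT")
        c = PreSequence("GGGGGTTTTTAAAAA")
        # near-duplicates of a, incompatible with everything but blocked pairs
        d = PreSequence("AAAAACCCCCGGGGT")
        e = PreSequence("AAAAACCCCCGGGTT")
        f = PreSequence("AAAAACCCCCGGTTT")
        pres = [a, b, c, d, e, f]
        w = {(i, j): match_weight(pres[i], pres[j]) for i in range(6) for j in range(i + 1, 6)}
        valid = [
            s
            for s in itertools.combinations(range(6), 3)
            if all(w[(i, j)] <= 0 for i, j in itertools.combinations(s, 2))
        ]
        assert valid == [(0, 1, 2)]  # exhaustive oracle: one valid triple
        sets = expand_diverse_sets(pres, max_pair_weight=0, min_size=3, seed=1, budget=200)
        assert sets == [(0, 1, 2)]

    def test_all_returned_sets_satisfy_cap(self):
        pres = generate_presequences(30, 37)
        sets = expand_diverse_sets(pres, max_pair_weight=5, min_size=3, seed=2, budget=500)
        for s in sets:
            for i, j in itertools.combinations(s, 2):
                assert match_weight(pres[i], pres[j]) <= 5


class TestScoring:
    def test_single_candidate_returned(self):
        pres = generate_presequences(5, 3)
        assert score_and_pick([(0, 1, 2)], pres) == (0, 1, 2)

    def test_five_prime_matches_preferred(self):
        # two 2-sets with one match each: at the 5' end vs at the 3' end
        base = "ACGTACGTACGTACG"
        five = PreSequence("A" + "".join("C" if c != "C" else "G" for c in base[1:]))
        three = PreSequence("".join("C" if c != "C" else "G" for c in base[:-1]) + "G")
        ref = PreSequence(base)
        pres = [ref, five, three]
        assert match_weight(ref, five) == 1 and match_weight(ref, three) == 1
        chosen = score_and_pick([(0, 1), (0, 2)], pres)
        assert chosen == (0, 1)  # the 5'-matching pair scores lower

    def test_tie_breaks_lexicographically(self):
        pres = [PreSequence("A" * 15), PreSequence("C" * 15), PreSequence("G" * 15), PreSequence("T" * 15)]
        assert score_and_pick([(2, 3), (0, 1)], pres) == (0, 1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            score_and_pick([], [])


class TestInsulation:
    def test_length_and_motif_freedom(self):
        ins = generate_insulator(seed=5)
        assert len(ins) == 70
        rc = revcomp(ins)
        for motif in guides.DEFAULT_FORBIDDEN_MOTIFS:
            assert motif not in ins and motif not in rc

    def test_determinism(self):
        assert generate_insulator(seed=8) == generate_insulator(seed=8)

    def test_unsatisfiable_motifs_fail(self):
        with pytest.raises(RuntimeError):
            generate_insulator(length=10, forbidden_motifs=("A", "C", "G", "T"), max_attempts=50)

    @pytest.mark.parametrize(
        "core_len, expected_insulator_used", [(35, 70), (40, 65), (105, 0)]
    )
    def test_truncation_arithmetic(self, core_len, expected_insulator_used):
        core = "A" * core_len
        ins = "C" * 35 + "G" * 35
        result = insulate_promoter(core, ins)
        assert len(result) == 105
        assert result.endswith(core)
        used = result[: 105 - core_len]
        assert len(used) == expected_insulator_used
        # truncation removes the 5' end of the insulator
        assert used == ins[70 - expected_insulator_used :]

    def test_oversized_core_rejected(self):
        with pytest.raises(ValueError):
            insulate_promoter("A" * 106, "C" * 70)


def test_full_pipeline_pairs_within_cap(random_genome_50kb):
    """End-to-end library design yields mutually dissimilar, 105-bp promoters."""
    report = guides.design_library(
        GenomeTarget(random_genome_50kb),
        n_candidates=400,
        core_size=30,
        min_set_size=4,
        seed=2,
        expansion_budget=1000,
    )
    chosen = report["chosen_set"]
    assert len(chosen) >= 4
    core_idx = report["core_indices"]
    lib = report["library"]
    assert all(len(entry["promoter"]) == 105 for entry in lib)
    pres = [entry["pre"] for entry in lib]
    for a, b in itertools.combinations(pres, 2):
        assert match_weight(a, b) <= 5
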