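"""GC, Tm, IUPAC handling, coverage matching, and pair compatibility."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbcprimer.errors import AlphabetError, DegeneracyError, GeometryError
from mbcprimer.msa import EXCLUSION, TARGET
from mbcprimer.primers import (
    CoverageResult,
    PrimerRecord,
    apply_selection_criteria,
    approximate_occurrence,
    collapse_to_iupac,
    coverage_profile,
    degeneracy,
    expand_degenerate,
    gc_content,
    longest_complementary_run,
    melting_temperature,
    pair_compatibility,
    propose_degenerate_consensus,
    reverse_complement,
    three_prime_anchored_run,
    three_prime_mismatch_check,
)
from mbcprimer.scan import WindowVariants

PLAIN = st.text(alphabet="ACGT", min_size=1, max_size=30)
IUPAC = st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=25)


class TestGcContent:
    @pytest.mark.parametrize(
        "seq, expected",
        [("GGCC", 1.0), ("ATAT", 0.0), ("ACGT", 0.5), ("AYGT", 0.375), ("SNSN", 0.75)],
    )
    def test_known_values(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_invalid_character(self):
        with pytest.raises(AlphabetError):
            gc_content("ACGX")

    @settings(max_examples=50, derandomize=True)
    @given(IUPAC.filter(lambda s: degeneracy(s) <= 64))
    def test_equals_mean_over_expansions(self, seq):
        expansions = expand_degenerate(seq)
        mean = sum(gc_content(e) for e in expansions) / len(expansions)
        assert gc_content(seq) == pytest.approx(mean)


def tm_nn_oracle(seq, Na=50.0, dnac1=25.0, dnac2=25.0):
    """Independent nearest-neighbor Tm: Allawi & SantaLucia (1997) unified
    parameters with the SantaLucia (1998) entropy salt correction."""
    nn = {
        "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
        "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
        "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
        "GG": (-8.0, -19.9),
    }
    comp = str.maketrans("ACGT", "TGCA")
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        dh, ds = (dh + 0.1, ds - 2.8) if end in "GC" else (dh + 2.3, ds + 4.1)
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        h, s = nn.get(pair) or nn[pair.translate(comp)[::-1]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(Na / 1000.0)
    k = (dnac1 - dnac2 / 2.0) * 1e-9
    return dh * 1000.0 / (ds + 1.987 * math.log(k)) - 273.15


class TestMeltingTemperature:
    @pytest.mark.parametrize("seq, expected", [("AAAAAAAA", 16.0), ("GGGGGGGG", 32.0)])
    def test_wallace_rule(self, seq, expected):
        assert melting_temperature(seq, "wallace") == pytest.approx(expected)

    @pytest.mark.parametrize(
        "seq",
        ["ACGTACGTACGTACGTACGT", "GCATTGCAATTCGGATCCAA", "TTGACAGGTCCATGAAACGA"],
    )
    def test_nn_matches_independent_oracle(self, seq):
        assert melting_temperature(seq, "nn") == pytest.approx(tm_nn_oracle(seq), abs=0.5)

    def test_degenerate_tm_averages_expansions(self):
        tm = melting_temperature("ACGTACGTACGTACGTACGY", "nn")
        exp = [melting_temperature(s, "nn") for s in expand_degenerate("ACGTACGTACGTACGTACGY")]
        assert tm == pytest.approx(sum(exp) / len(exp))


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq, expected", [("ACGT", "ACGT"), ("AAC", "GTT"), ("AYG", "CRT"), ("NSD", "HSN")]
    )
    def test_known_values(self, seq, expected):
        assert reverse_complement(seq) == expected

    def test_invalid_character(self):
        with pytest.raises(AlphabetError):
            reverse_complement("AC-T")

    @settings(max_examples=100, derandomize=True)
    @given(IUPAC)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq


class TestExpandDegenerate:
    @pytest.mark.parametrize(
        "seq, expected",
        [("AY", ["AC", "AT"]), ("AD", ["AA", "AG", "AT"]), ("ACGT", ["ACGT"])],
    )
    def test_known_expansions(self, seq, expected):
        assert expand_degenerate(seq) == expected

    def test_cap_enforced(self):
        with pytest.raises(DegeneracyError):
            expand_degenerate("NNNN", cap=64)

    @settings(max_examples=50, derandomize=True)
    @given(IUPAC.filter(lambda s: degeneracy(s) <= 64))
    def test_size_and_collapse_round_trip(self, seq):
        expansions = expand_degenerate(seq)
        assert len(expansions) == degeneracy(seq)
        assert collapse_to_iupac(expansions) == seq


class TestDegenerateConsensus:
    def _wv(self, variants):
        return WindowVariants(0, len(next(iter(variants))),
                              {TARGET: variants, EXCLUSION: {}},
                              {TARGET: sum(variants.values()), EXCLUSION: 0})

    def test_single_substitution_goal(self):
        rec = propose_degenerate_consensus(self._wv({"ACGT": 9, "ATGT": 1}), 1.0)
        assert rec.sequence == "AYGT"
        assert rec.coverage_goal_met

    def test_single_variant_unchanged(self):
        rec = propose_degenerate_consensus(self._wv({"ACGT": 10}), 1.0)
        assert rec.sequence == "ACGT"

    def test_goal_already_met_is_noop(self):
        rec = propose_degenerate_consensus(self._wv({"ACGT": 9, "ATGT": 1}), 0.9)
        assert rec.sequence == "ACGT"

    def test_unreachable_goal_flags_best_effort(self):
        variants = {"AAAA": 4, "CCCC": 1, "GGGG": 1, "TTTT": 1}
        rec = propose_degenerate_consensus(self._wv(variants), 1.0, degeneracy_cap=2)
        assert rec.coverage_goal_met is False
        assert rec.target_coverage < 1.0

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.text(alphabet="ACGT", min_size=6, max_size=6), min_size=2, max_size=8),
           st.floats(0.5, 1.0))
    def test_never_decreases_coverage_nor_touches_agreed_positions(self, seqs, goal):
        variants = {}
        for s in seqs:
            variants[s] = variants.get(s, 0) + 1
        wv = self._wv(variants)
        base = max(variants.values()) / sum(variants.values())
        rec = propose_degenerate_consensus(wv, goal)
        assert rec.target_coverage >= base - 1e-12
        for pos in range(6):
            if len({s[pos] for s in variants}) == 1:
                assert rec.sequence[pos] == seqs[0][pos]


class TestThreePrimeCheck:
    def test_terminal_mismatch_everywhere_passes(self):
        rep = three_prime_mismatch_check("ACGTACAAG", ["ACGTACAAT", "ACGTACAAT"])
        assert rep.terminal_fraction == 1.0 and rep.passes

    def test_identical_to_exclusion_fails(self):
        rep = three_prime_mismatch_check("ACGTACAAG", {"ACGTACAAG": 5})
        assert rep.terminal_fraction == 0.0 and not rep.passes

    def test_half_mismatching_fails_at_default(self):
        rep = three_prime_mismatch_check("ACGTACAAG", {"ACGTACAAG": 5, "ACGTACAAT": 5})
        assert rep.terminal_fraction == 0.5 and not rep.passes
        assert three_prime_mismatch_check(
            "ACGTACAAG", {"ACGTACAAG": 5, "ACGTACAAT": 5}, required_fraction=0.5
        ).passes

    def test_per_position_map_counts_from_terminus(self):
        rep = three_prime_mismatch_check("AAACCG", ["AAATCG"], k=3)
        assert rep.fractions == (0.0, 0.0, 1.0)

    def test_length_divergent_variants_refused(self):
        rep = three_prime_mismatch_check("ACGTACAAG", {"ACGTACAAT": 1, "ACG": 1})
        assert rep.refused_variants == 1
        assert rep.terminal_fraction == 1.0

    def test_reverse_primer_compared_on_primer_strand(self):
        # site on the alignment strand: CTTGTACGT; reverse primer is its
        # reverse complement; exclusion variant differs at the site's first
        # base, which is the reverse primer's 3' terminus
        rv = PrimerRecord(name="r", sequence=reverse_complement("CTTGTACGTAGC"),
                          orientation="reverse")
        rep = three_prime_mismatch_check(rv, ["ATTGTACGTAGC"])
        assert rep.terminal_fraction == 1.0 and rep.passes


class TestApproximateOccurrence:
    def test_verbatim_hit(self):
        occ = approximate_occurrence("ACGTTGCA", "TTT" + "ACGTTGCA" + "GGG")
        assert (occ.position, occ.mismatches, occ.strand) == (3, 0, "+")

    def test_degenerate_base_matches_its_set(self):
        occ = approximate_occurrence("AYGCAYGC", "TTATGCACGCTT")
        assert occ.mismatches == 0

    def test_reverse_strand_hit_flagged(self):
        primer = "ACGTTGCACC"
        ref = "TTT" + reverse_complement(primer) + "GGG"
        occ = approximate_occurrence(primer, ref)
        assert occ.strand == "-" and occ.mismatches == 0

    def test_reference_shorter_than_primer(self):
        assert approximate_occurrence("ACGTACGTACGT", "ACGT") is None

    def test_beyond_max_mm_is_no_hit(self):
        assert approximate_occurrence("AAAAAAAAAA", "CCCCCCCCCCCC", max_mm=2) is None

    @settings(max_examples=50, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=8, max_size=15),
           st.text(alphabet="ACGT", min_size=20, max_size=60))
    def test_strand_symmetry(self, primer, ref):
        occ_f = approximate_occurrence(primer, ref)
        occ_r = approximate_occurrence(primer, reverse_complement(ref))
        assert (occ_f is None) == (occ_r is None)
        if occ_f is not None:
            assert occ_f.mismatches == occ_r.mismatches


class TestCoverageProfile:
    def test_primer_in_every_reference(self):
        refs = ["AAA" + "ACGTTGCAGG" + "TTT"] * 4
        assert coverage_profile("ACGTTGCAGG", refs).fractions == (1, 1, 1)

    def test_primer_absent_everywhere(self):
        refs = ["C" * 30] * 4
        assert coverage_profile("AGAGAGAGAGAG", refs).fractions == (0, 0, 0)

    def test_mixed_mutation_loads(self):
        from mbcprimer.simulate import generate_reference_set

        primer = "ACGTTGCAACGTAGCTAGCT"
        refs = generate_reference_set(primer, mismatch_counts=[0] * 8 + [1] + [3], seed=5)
        cov = coverage_profile(primer, [str(r.seq) for r in refs])
        assert cov.fractions == pytest.approx((0.8, 0.9, 0.9))

    def test_cumulative_and_strand_invariant(self):
        from mbcprimer.simulate import generate_reference_set

        primer = "ACGTTGCAACGTAGCTAGCT"
        refs = [str(r.seq) for r in
                generate_reference_set(primer, mismatch_counts=[0, 1, 1, 2, 3, 0], seed=9)]
        cov = coverage_profile(primer, refs)
        assert cov.at(0) <= cov.at(1) <= cov.at(2)
        flipped = coverage_profile(primer, [reverse_complement(r) for r in refs])
        assert flipped.fractions == cov.fractions


class TestSelectionCriteria:
    def _primer(self, seq="ACGTTGCAACGTAGCTAGCT"):
        return PrimerRecord(name="p", sequence=seq)

    def test_all_pass(self):
        v = apply_selection_criteria(self._primer(), CoverageResult((0.80, 0.83, 0.9)), True)
        assert v.passed

    def test_coverage_below_80_fails(self):
        v = apply_selection_criteria(self._primer(), CoverageResult((0.5, 0.79, 0.9)), True)
        assert not v.coverage_ok and not v.passed

    def test_gc_boundaries_inclusive(self):
        p40 = self._primer("ATATGCGCGCGCATATATAT")  # GC 0.40
        v = apply_selection_criteria(p40, CoverageResult((1, 1, 1)), True)
        assert v.gc_ok

    def test_length_tolerance(self):
        short = self._primer("ACGTTGCAACGTAGCTA")  # 17 bp: inside 20 +/- 3
        v = apply_selection_criteria(short, CoverageResult((1, 1, 1)), True)
        assert v.length_ok
        tiny = self._primer("ACGTTGCAACGTAGCT")  # 16 bp: outside
        assert not apply_selection_criteria(tiny, CoverageResult((1, 1, 1)), True).length_ok


def complementary_run_oracle(a: str, b: str):
    """Enumerate all substring pairs; returns (longest run, longest run
    ending at a's 3' terminus)."""
    rb = reverse_complement(b)
    best = anchored = 0
    for i in range(len(a)):
        for j in range(len(rb)):
            k = 0
            while i + k < len(a) and j + k < len(rb) and a[i + k] == rb[j + k]:
                k += 1
                best = max(best, k)
                if i + k == len(a):
                    anchored = max(anchored, k)
    return best, anchored


class TestPairCompatibility:
    def test_identical_tm_primers(self):
        p = PrimerRecord(name="f", sequence="ACGTTGCAACGTAGCTAGCT")
        rep = pair_compatibility(p, p, 1, 500)
        assert rep.delta_tm == 0.0

    def test_amplicon_span_arithmetic(self):
        fw = PrimerRecord(name="f", sequence="ACGTTGCAACGTAGCTAGCT")
        rv = PrimerRecord(name="r", sequence="TGCATGCATGCATGCATGCA", orientation="reverse")
        rep = pair_compatibility(fw, rv, fw_site_start=1, rv_site_end=3500)
        assert rep.predicted_amplicon_bp == 3500

    def test_reverse_upstream_is_geometry_error(self):
        fw = PrimerRecord(name="f", sequence="ACGTTGCAACGTAGCTAGCT")
        with pytest.raises(GeometryError):
            pair_compatibility(fw, fw, fw_site_start=100, rv_site_end=50)

    def test_three_prime_anchored_five_fails_default(self):
        # fw 3' suffix ACGTT pairs with AACGT inside rv
        fw = PrimerRecord(name="f", sequence="GGGGGGGGGGGGGGGACGTT")
        rv = PrimerRecord(name="r", sequence="TTTTTAACGTTTTTTTTTTT", orientation="reverse")
        rep = pair_compatibility(fw, rv, 1, 500)
        assert rep.three_prime_anchored >= 5
        assert not rep.passes

    @settings(max_examples=40, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=5, max_size=15),
           st.text(alphabet="ACGT", min_size=5, max_size=15))
    def test_runs_match_enumeration_oracle(self, a, b):
        best, anchored = complementary_run_oracle(a, b)
        assert longest_complementary_run(a, b) == best
        assert three_prime_anchored_run(a, b) == anchored
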