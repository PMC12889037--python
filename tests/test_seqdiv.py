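import math
from functools import lru_cache

import pytest
from Bio.Align import substitution_matrices

from wmkdiv.seqdiv import (
    DomainAnnotation, charge_profile, classify_homologs, conservation_differential,
    conservation_profile, domain_arithmetic, indel_blocks, motif_scan, pairwise_identity,
    positions_in_ranges,
)
from wmkdiv.structio import MSA

BLOSUM = substitution_matrices.load("BLOSUM62")


def dp_identity(a, b, open_=-11.0, extend=-1.0):
    """Oracle: exhaustive recursion over all affine-gap alignments of tiny
    sequences, returning the identity of the best-scoring alignment."""

    @lru_cache(maxsize=None)
    def go(i, j, state):
        # state: 0 match-ready, 1 gap-in-a open, 2 gap-in-b open
        if i == len(a) and j == len(b):
            return 0.0, 0, 0
        options = []
        if i < len(a) and j < len(b):
            s, m, c = go(i + 1, j + 1, 0)
            options.append((s + BLOSUM[a[i], b[j]], m + (a[i] == b[j]), c + 1))
        if j < len(b):  # gap in a
            s, m, c = go(i, j + 1, 1)
            pen = extend if state == 1 else open_
            options.append((s + pen, m, c + 1))
        if i < len(a):  # gap in b
            s, m, c = go(i + 1, j, 2)
            pen = extend if state == 2 else open_
            options.append((s + pen, m, c + 1))
        return max(options)

    score, matches, cols = go(0, 0, 0)
    return matches / cols


class TestPairwiseIdentity:
    def test_examples(self):
        assert pairwise_identity("ACDE", "ACDE") == 1.0
        assert pairwise_identity("ACDE", "ACDF") == 0.75
        assert pairwise_identity("ACDE", "ACE") == 0.75

    @pytest.mark.parametrize(
        "a,b", [("ACDEFG", "ACDG"), ("MKLV", "MKV"), ("WYYW", "WW"), ("HKRDE", "HKRE")]
    )
    def test_matches_exhaustive_dp_oracle(self, a, b):
        assert pairwise_identity(a, b) == pytest.approx(dp_identity(a, b))

    def test_symmetry_and_identity_condition(self):
        a, b = "MKTAYIAKQR", "MKTAYIAQQR"
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))
        assert pairwise_identity(a, a) == 1.0
        assert pairwise_identity(a, b) < 1.0

    def test_nonstandard_residues_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("ACXE", "ACDE")
        with pytest.raises(ValueError):
            pairwise_identity("", "ACDE")


class TestClassification:
    def test_band_rules(self):
        idents = {"close": 0.99, "wzbi_like": 0.33, "orphan": 0.46}
        to_distant = {"close": [0.3], "wzbi_like": [0.48], "orphan": [0.34]}
        labels = classify_homologs(idents, to_distant)
        assert labels == {"close": "type-I", "wzbi_like": "distant", "orphan": "unassigned"}

    def test_boundary_is_inclusive(self):
        labels = classify_homologs({"x": 0.72}, {})
        assert labels["x"] == "type-I"
        labels = classify_homologs({"y": 0.7199}, {"y": [0.35]})
        assert labels["y"] == "distant"

    def test_family_labels_recovered(self, family):
        hs = family.homolog_set
        truth = family.truth["groups"]
        ref = hs.reference
        idents = {r.id: pairwise_identity(ref.sequence, r.sequence) for r in hs}
        seeds = [h for h, g in truth.items() if g == "distant"]
        to_distant = {
            r.id: [pairwise_identity(hs.get(s).sequence, r.sequence) for s in seeds if s != r.id]
            for r in hs
        }
        labels = classify_homologs(idents, to_distant)
        for hid, g in truth.items():
            if g in ("type-I", "distant"):
                assert labels[hid] == g, hid


class TestConservation:
    def test_column_scores(self):
        msa = MSA(("a", "b"), ("AA", "AV"))
        scores, flagged = conservation_profile(msa)
        assert scores[0] == pytest.approx(1.0)
        assert scores[1] == pytest.approx(1.0 - 1.0 / math.log2(20))
        assert flagged == [False, False]

    def test_uniform_column_scores_zero(self):
        rows = tuple("ACDEFGHIKLMNPQRSTVWY"[i] for i in range(20))
        msa = MSA(tuple(f"s{i}" for i in range(20)), rows)
        scores, _ = conservation_profile(msa)
        assert scores[0] == pytest.approx(0.0, abs=1e-12)

    def test_all_gap_column_flagged_nan(self):
        msa = MSA(("a", "b"), ("A-", "C-"))
        scores, flagged = conservation_profile(msa)
        assert math.isnan(scores[1]) and flagged[1]

    def test_row_order_invariance(self):
        msa1 = MSA(("a", "b", "c"), ("AC", "AV", "GC"))
        msa2 = MSA(("c", "a", "b"), ("GC", "AC", "AV"))
        assert conservation_profile(msa1)[0] == conservation_profile(msa2)[0]


class TestConservationDifferential:
    def test_same_msa_zero_delta(self):
        msa = MSA(("r", "x", "y"), ("ACDEF", "ACDEF", "AVDEF"))
        prof = conservation_differential(msa, msa, "r", (1, 5))
        assert all(d == 0.0 for d in prof.delta)

    def test_toy_subset_localizes_divergence(self):
        # the removed pair carries the only substitutions, at reference pos 3
        msa_all = MSA(
            ("r", "a", "b", "p", "q"),
            ("ACDEF", "ACDEF", "ACDEF", "ACWEF", "ACWEF"),
        )
        msa_sub = MSA(("r", "a", "b"), ("ACDEF", "ACDEF", "ACDEF"))
        prof = conservation_differential(msa_all, msa_sub, "r", (1, 5))
        score_all = conservation_profile(msa_all)[0][2]
        expect = 1.0 - score_all
        for p, d in zip(prof.positions, prof.delta):
            assert d == pytest.approx(expect if p == 3 else 0.0)

    def test_window_clipping(self):
        msa = MSA(("r", "x"), ("ACDEF", "ACDEF"))
        prof = conservation_differential(msa, msa, "r", (2, 100))
        assert prof.positions == (2, 3, 4, 5)


class TestIndelBlocks:
    def test_identical_rows_empty(self):
        msa = MSA(("r", "q"), ("ACDEF", "ACDEF"))
        assert indel_blocks(msa, "r", "q") == []

    def test_long_deletion_positioned_in_reference(self):
        ref = "A" * 210
        qry = "A" * 99 + "-" * 36 + "A" * 75
        msa = MSA(("r", "q"), (ref, qry))
        blocks = indel_blocks(msa, "r", "q")
        assert len(blocks) == 1
        b = blocks[0]
        assert (b.kind, b.reference_position, b.length) == ("deletion", 100, 36)

    def test_insertion_anchored_to_preceding_position(self):
        ref = "A" * 192 + "-" * 8 + "A" * 20
        qry = "A" * 220
        msa = MSA(("r", "q"), (ref, qry))
        blocks = indel_blocks(msa, "r", "q")
        assert [(b.kind, b.reference_position, b.length) for b in blocks] == [
            ("insertion", 192, 8)
        ]

    def test_min_length_filters_short_runs(self):
        msa = MSA(("r", "q"), ("ACDEFG", "AC--FG"))
        assert indel_blocks(msa, "r", "q", min_length=3) == []
        assert len(indel_blocks(msa, "r", "q", min_length=2)) == 1

    def test_mirror_property(self):
        ref = "ACDEFGHIKLMNPQRS" + "-" * 4 + "TVWY"
        qry = "ACDEF" + "-" * 5 + "MNPQRSACDETVWY"
        msa = MSA(("r", "q"), (ref, qry))
        fwd = indel_blocks(msa, "r", "q")
        rev = indel_blocks(msa, "q", "r")
        kinds_fwd = sorted((b.kind, b.length) for b in fwd)
        kinds_rev = sorted(
            ({"deletion": "insertion", "insertion": "deletion"}[b.kind], b.length) for b in rev
        )
        assert kinds_fwd == kinds_rev

    def test_family_planted_indels_recovered(self, family):
        hs = family.homolog_set
        for hid, planted in family.truth["indels"].items():
            if hid == "ref":
                continue
            got = [
                (b.kind, b.reference_position, b.length)
                for b in indel_blocks(hs.msa, "ref", hid)
            ]
            assert got == [tuple(p) for p in planted], hid


class TestMotifScan:
    def test_canonical_triplets(self):
        assert motif_scan("GIS", "shs") == [(1, "GIS", 0)]
        assert motif_scan("ELS", "shs") == [(1, "ELS", 1)]
        assert motif_scan("QAE", "phs") == [(1, "QAE", 1)]

    def test_all_violating_triplet_excluded(self):
        assert motif_scan("KKK", "shs", max_violations=1) == []

    def test_sorted_by_violations_then_position(self):
        seq = "KKGISKKGLSKK"
        hits = motif_scan(seq, "shs")
        assert hits[0][2] == 0
        assert [h[0] for h in hits] == sorted(
            [h[0] for h in hits if h[2] == 0]
        ) + [h[0] for h in hits if h[2] == 1]

    def test_region_bounds(self):
        with pytest.raises(ValueError):
            motif_scan("GIS", "shs", region=(0, 3))


class TestChargeAndDomains:
    def test_charge_windows(self):
        assert charge_profile("KKKKK", window=5) == [5]
        assert charge_profile("KDKDK", window=5) == [1]
        assert charge_profile("AAAAA", window=5) == [0]
        assert charge_profile("KRDEH", window=1) == [1, 1, -1, -1, 0]

    def test_domain_arithmetic_lengths_and_gaps(self):
        n = DomainAnnotation("N-HTH", 21, 75)
        c = DomainAnnotation("C-HTH", 138, 192)
        out = domain_arithmetic([n, c])
        assert out["lengths"] == {"N-HTH": 55, "C-HTH": 55}
        assert out["gaps"] == {"N-HTH..C-HTH": 62}

    def test_adjacent_domains_zero_gap_and_overlap_error(self):
        a = DomainAnnotation("a", 1, 10)
        b = DomainAnnotation("b", 11, 20)
        assert domain_arithmetic([a, b])["gaps"]["a..b"] == 0
        with pytest.raises(ValueError):
            domain_arithmetic([a, DomainAnnotation("c", 10, 15)])

    def test_positions_in_ranges_union(self):
        assert len(positions_in_ranges([(8, 51), (53, 70)])) == 62
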