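import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lineaburst import seqdist
from lineaburst.seqdist import (Alignment, AlignmentFormatError,
                                DistanceMatrix, NoOverlapError,
                                SaturatedPairWarning, dedup_longest, k2p,
                                k2p_matrix, read_fasta, saturation_profile,
                                threshold_clusters, write_fasta)
from oracles import k2p_brute

K2P_HAND = 0.17018116514773364  # -0.5 ln(0.75) - 0.25 ln(0.90)


def _pair_with_counts(m=100, s=10, v=5):
    """Two length-m sequences with exactly s transitions and v transversions."""
    a = ["A"] * m
    b = ["A"] * m
    for i in range(s):
        b[i] = "G"          # A<->G transition
    for i in range(s, s + v):
        b[i] = "C"          # A<->C transversion
    return "".join(a), "".join(b)


class TestFastaIO:
    def test_read_two_records(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1 first\nACGT\n>s2\nAC-T\n")
        aln = read_fasta(p)
        assert aln.ids == ["s1", "s2"]
        assert aln.records[1][1] == "AC-T"

    def test_normalization_u_and_ambiguity(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nacgu\n>s2\nacgr\n")
        with pytest.warns(UserWarning, match="mapped to N"):
            aln = read_fasta(p)
        assert aln.records[0][1] == "ACGT"
        assert aln.records[1][1] == "ACGN"

    def test_round_trip(self, tmp_path):
        aln = Alignment([("a", "ACGTN-AC"), ("b", "ACGTTTAC")])
        p = tmp_path / "out.fasta"
        write_fasta(aln, p)
        assert read_fasta(p).records == aln.records

    def test_unequal_lengths_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nACGT\n>s2\nACG\n")
        with pytest.raises(AlignmentFormatError):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.raises(AlignmentFormatError):
            read_fasta(p)


class TestDedup:
    def test_wildcard_collapse_keeps_most_determinate(self):
        aln = Alignment([("s1", "ACGTACGT"), ("s2", "ACGTACGN"),
                         ("s3", "ACCTACGT")])
        out, report = dedup_longest(aln)
        assert out.ids == ["s1", "s3"]
        assert dict(report.groups)["s1"] == ["s1", "s2"]

    def test_all_distinct_unchanged(self):
        aln = Alignment([("a", "AAAA"), ("b", "CCCC"), ("c", "GGGG")])
        out, report = dedup_longest(aln)
        assert out.records == aln.records
        assert all(len(m) == 1 for _, m in report.groups)

    def test_nontransitive_component_tie_break_by_input_order(self):
        aln = Alignment([("a", "ACGN"), ("b", "ACNT"), ("c", "ANGT")])
        out, report = dedup_longest(aln)
        assert out.ids == ["a"]
        assert report.groups == [("a", ["a", "b", "c"])]

    def test_idempotent_and_partition(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGTN"))
        recs = [(f"s{i}", "".join(rng.choice(bases, size=30,
                                             p=[.22, .22, .22, .22, .12])))
                for i in range(40)]
        aln = Alignment(recs)
        out1, report = dedup_longest(aln)
        out2, _ = dedup_longest(out1)
        assert out2.records == out1.records
        assert len(out1) <= len(aln)
        seen = [m for _, members in report.groups for m in members]
        assert sorted(seen) == sorted(aln.ids)


class TestK2P:
    def test_identical_sequences_zero(self):
        d, P, Q, m = k2p("ACGTACGT", "ACGTACGT")
        assert (d, P, Q, m) == (0.0, 0.0, 0.0, 8)

    def test_hand_computed_value(self):
        a, b = _pair_with_counts(100, 10, 5)
        d, P, Q, m = k2p(a, b)
        assert d == pytest.approx(K2P_HAND, abs=1e-9)
        assert (P, Q, m) == (0.10, 0.05, 100)

    def test_saturated_pair_flagged(self):
        a, b = _pair_with_counts(100, 50, 25)  # P=0.5, Q=0.25
        with pytest.warns(SaturatedPairWarning):
            d, P, Q, m = k2p(a, b)
        assert np.isnan(d)

    def test_no_overlap_raises(self):
        with pytest.raises(NoOverlapError):
            k2p("NNNN", "ACGT")

    def test_matches_brute_force_oracle(self, rng):
        bases = np.array(list("ACGTN-"))
        for _ in range(50):
            L = int(rng.integers(20, 120))
            a = "".join(rng.choice(bases, size=L))
            b = "".join(rng.choice(bases, size=L))
            try:
                expected = k2p_brute(a, b)
            except ZeroDivisionError:
                with pytest.raises(NoOverlapError):
                    k2p(a, b)
                continue
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d, P, Q, m = k2p(a, b)
            if expected[0] is None:
                assert np.isnan(d)
            else:
                assert d == pytest.approx(expected[0], abs=1e-15)
            assert (P, Q, m) == expected[1:]


class TestK2PMatrix:
    @pytest.fixture
    def random_alignment(self, rng):
        bases = np.array(list("ACGTN"))
        recs = [(f"s{i}", "".join(rng.choice(
            bases, size=60, p=[.24, .24, .24, .24, .04])))
            for i in range(12)]
        return Alignment(recs)

    def test_symmetry_and_diagonal(self, random_alignment):
        dm = k2p_matrix(random_alignment)
        np.testing.assert_allclose(np.diag(dm.d), 0)
        defined = dm.defined & dm.defined.T
        np.testing.assert_allclose(dm.d[defined], dm.d.T[defined])
        assert ((dm.P + dm.Q)[defined] <= 1 + 1e-12).all()

    def test_matches_scalar_k2p(self, random_alignment):
        import warnings
        dm = k2p_matrix(random_alignment)
        recs = random_alignment.records
        for i in range(0, 12, 3):
            for j in range(i + 1, 12, 4):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    d, P, Q, m = k2p(recs[i][1], recs[j][1])
                if np.isnan(d):
                    assert not dm.defined[i, j]
                else:
                    assert dm.d[i, j] == pytest.approx(d, abs=1e-15)

    def test_p_distance_metric(self):
        aln = Alignment([("a", "AAAA"), ("b", "AAAG")])
        dm = k2p_matrix(aln, metric="p")
        assert dm.d[0, 1] == pytest.approx(0.25)


def _dm_from_square(ids, d):
    d = np.asarray(d, dtype=float)
    n = len(ids)
    z = np.zeros((n, n))
    return DistanceMatrix(list(ids), d, z, z, np.full((n, n), 100, dtype=int),
                          z.astype(int), z.astype(int),
                          np.ones((n, n), dtype=bool))


class TestThresholdClusters:
    def test_single_sequence(self):
        dm = _dm_from_square(["a"], [[0.0]])
        assert threshold_clusters(dm) == [["a"]]

    def test_single_linkage_chaining(self):
        d = [[0, 0.005, 0.012], [0.005, 0, 0.008], [0.012, 0.008, 0]]
        dm = _dm_from_square(list("abc"), d)
        assert threshold_clusters(dm, cutoff=0.01) == [["a", "b", "c"]]

    def test_complete_linkage_does_not_chain(self):
        d = [[0, 0.005, 0.012], [0.005, 0, 0.008], [0.012, 0.008, 0]]
        dm = _dm_from_square(list("abc"), d)
        out = threshold_clusters(dm, cutoff=0.01, linkage="complete")
        assert len(out) == 2

    def test_two_blocks(self):
        d = np.full((4, 4), 0.05)
        d[:2, :2] = 0.002
        d[2:, 2:] = 0.002
        np.fill_diagonal(d, 0)
        dm = _dm_from_square(list("abcd"), d)
        assert threshold_clusters(dm, cutoff=0.01) == [["a", "b"], ["c", "d"]]

    def test_monotone_in_cutoff(self, rng):
        n = 10
        d = rng.uniform(0, 0.05, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dm = _dm_from_square([f"s{i}" for i in range(n)], d)
        counts = [len(threshold_clusters(dm, cutoff=c))
                  for c in (0.005, 0.01, 0.02, 0.04)]
        assert counts == sorted(counts, reverse=True)

    def test_order_invariance(self, rng):
        bases = np.array(list("ACGT"))
        recs = [(f"s{i}", "".join(rng.choice(bases, size=50)))
                for i in range(8)]
        aln = Alignment(recs)
        perm = list(rng.permutation(8))
        aln_p = Alignment([recs[i] for i in perm])
        part1 = {frozenset(c) for c in threshold_clusters(
            k2p_matrix(aln), cutoff=0.3)}
        part2 = {frozenset(c) for c in threshold_clusters(
            k2p_matrix(aln_p), cutoff=0.3)}
        assert part1 == part2

    def test_saturated_pairs_have_no_edges(self):
        dm = _dm_from_square(list("ab"), [[0, 0.001], [0.001, 0]])
        dm.defined[0, 1] = dm.defined[1, 0] = False
        assert threshold_clusters(dm, cutoff=0.01) == [["a"], ["b"]]


class TestSaturationProfile:
    def test_identical_pair_row(self):
        aln = Alignment([("a", "ACGT"), ("b", "ACGT")])
        row = saturation_profile(aln).iloc[0]
        assert (row.s, row.v, row.d) == (0, 0, 0)

    def test_hand_pair_row(self):
        a, b = _pair_with_counts(100, 10, 5)
        aln = Alignment([("x", a), ("y", b)])
        row = saturation_profile(aln).iloc[0]
        assert row.s == 10 and row.v == 5
        assert row.d == pytest.approx(K2P_HAND)
        assert row.flag == ""

    def test_no_overlap_flagged(self):
        aln = Alignment([("a", "NNNN"), ("b", "ACGT"), ("c", "ACGG")])
        prof = saturation_profile(aln)
        flagged = prof[(prof.id_a == "a") & (prof.id_b == "b")]
        assert flagged.iloc[0].flag == "no_overlap"


@settings(max_examples=25, deadline=None)
@given(st.lists(st.text(alphabet="ACGTN-", min_size=12, max_size=12),
                min_size=2, max_size=8))
def test_dedup_properties_hold_for_arbitrary_alignments(seqs):
    aln = Alignment([(f"s{i}", s) for i, s in enumerate(seqs)])
    out, report = dedup_longest(aln)
    assert len(out) <= len(aln)
    seen = sorted(m for _, members in report.groups for m in members)
    assert seen == sorted(aln.ids)
    again, _ = dedup_longest(out)
    assert again.records == out.records
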