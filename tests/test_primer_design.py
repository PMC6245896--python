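import itertools
import random

import pytest
from hypothesis import given, strategies as st

from ampliseek.primer_design import (
    DEFAULT_FORWARD_TAIL,
    DEFAULT_REVERSE_TAIL,
    AmpliconPrediction,
    ConservedWindow,
    DesignError,
    GappedSeq,
    RegionAlignment,
    attach_tail,
    cluster_by_identity,
    column_base_sets,
    find_binding_site,
    global_identity,
    make_degenerate,
    pick_primer_position,
    predict_amplicons,
    scan_windows,
)
from ampliseek.seqcore import NucSeq, degeneracy, iupac_expand, iupac_match
from conftest import random_dna


def _mutate(rng, seq, n_sub):
    bases = list(seq)
    for pos in rng.sample(range(len(seq)), n_sub):
        bases[pos] = rng.choice([b for b in "ACGT" if b != bases[pos]])
    return "".join(bases)


class TestClustering:
    def test_identical_sequences_one_cluster(self):
        seqs = [NucSeq(f"s{i}", "ACGTACGTACGT") for i in range(3)]
        clusters = cluster_by_identity(seqs, 0.8)
        assert len(clusters) == 1
        assert len(clusters[0].members) == 3

    def test_distant_sequences_singletons(self):
        a = NucSeq("a", "AAAAAAAAAACCCCCCCCCC")
        b = NucSeq("b", "AAAAAAAAAAGGGGGGGGGG")  # 50% identity
        clusters = cluster_by_identity([a, b], 0.8)
        assert len(clusters) == 2
        assert all(len(c.members) == 1 for c in clusters)

    def test_member_identity_invariant(self, rng):
        base = random_dna(rng, 60)
        seqs = [NucSeq("r", base)] + [
            NucSeq(f"m{i}", _mutate(rng, base, 4)) for i in range(4)
        ]
        for cluster in cluster_by_identity(seqs, 0.8):
            for m in cluster.members:
                assert global_identity(m.bases, cluster.representative.bases) >= 0.8

    def test_against_independent_greedy_oracle(self):
        # families of indel-free mutants: the optimal global alignment is the
        # ungapped one, so Hamming identity is an independent oracle
        rng = random.Random(3)
        seqs = []
        for fam in range(4):
            base = random_dna(rng, 40)
            for i in range(5):
                seqs.append(NucSeq(f"f{fam}_{i}", _mutate(rng, base, rng.randint(0, 3))))

        def hamming_identity(a, b):
            return sum(1 for x, y in zip(a, b) if x == y) / len(a)

        # oracle: same greedy rule, brute-force identity matrix
        order = sorted(seqs, key=lambda s: -len(s.bases))
        oracle_clusters: list[list[NucSeq]] = []
        for s in order:
            for cl in oracle_clusters:
                if hamming_identity(s.bases, cl[0].bases) >= 0.8:
                    cl.append(s)
                    break
            else:
                oracle_clusters.append([s])

        got = cluster_by_identity(seqs, 0.8)
        assert [[m.id for m in c.members] for c in got] == [
            [m.id for m in c] for c in oracle_clusters
        ]

    def test_empty_input(self):
        assert cluster_by_identity([], 0.8) == []

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            cluster_by_identity([], 1.5)


def _make_alignment(rows):
    return RegionAlignment(tuple(GappedSeq(f"s{i}", r) for i, r in enumerate(rows)))


class TestScanWindows:
    def test_identical_members_all_windows(self, rng):
        row = random_dna(rng, 30)
        aln = _make_alignment([row] * 4)
        windows = scan_windows(aln, window_len=20, max_polymorphic=3)
        assert len(windows) == 30 - 20 + 1
        assert all(len(w.polymorphic_columns) == 0 for w in windows)
        assert all(w.consensus.bases == row[w.start : w.start + 20] for w in windows)

    def test_dense_polymorphism_yields_nothing(self, rng):
        # a polymorphic column every 5 positions -> every 20-column window
        # spans at least 4 of them
        row = random_dna(rng, 40)
        other = list(row)
        for c in range(0, 40, 5):
            other[c] = {"A": "G", "G": "A", "C": "T", "T": "C"}[row[c]]
        aln = _make_alignment([row, "".join(other)])
        assert scan_windows(aln, window_len=20, max_polymorphic=3) == []

    def test_gap_columns_excluded(self):
        rows = ["ACGTACGTACGTACGTACGTACGT", "ACGTACGTAC-TACGTACGTACGT"]
        windows = scan_windows(_make_alignment(rows), window_len=20)
        for w in windows:
            assert not (w.start <= 10 < w.start + 20)

    def test_against_bruteforce_window_oracle(self):
        rng = random.Random(11)
        base = random_dna(rng, 60)
        rows = [_mutate(rng, base, rng.randint(0, 6)) for _ in range(10)]
        aln = _make_alignment(rows)
        got = scan_windows(aln, window_len=20, max_polymorphic=3)
        # oracle: enumerate all starts, recount polymorphic columns directly
        expected = []
        for start in range(60 - 20 + 1):
            poly = [
                c
                for c in range(start, start + 20)
                if len({r[c] for r in rows}) >= 2
            ]
            if len(poly) <= 3:
                expected.append((start, tuple(poly)))
        assert [(w.start, w.polymorphic_columns) for w in got] == expected

    def test_short_alignment_empty(self):
        aln = _make_alignment(["ACGTACGT", "ACGTACGT"])
        assert scan_windows(aln, window_len=20) == []

    def test_minor_freq_floor_suppresses_rare_variant(self):
        rows = ["AAAAAAAAAAAAAAAAAAAA"] * 9 + ["AAAAAAAAAACAAAAAAAAA"]
        aln = _make_alignment(rows)
        with_floor = scan_windows(aln, window_len=20, minor_freq_floor=0.15)
        without = scan_windows(aln, window_len=20, minor_freq_floor=0.0)
        assert with_floor[0].polymorphic_columns == ()
        assert without[0].polymorphic_columns == (10,)


class TestMakeDegenerate:
    def test_single_base(self):
        assert make_degenerate([{"A"}]).bases == "A"

    def test_two_bases(self):
        assert make_degenerate([{"A", "G"}]).bases == "R"

    @given(
        st.lists(
            st.sets(st.sampled_from("ACGT"), min_size=1, max_size=3),
            min_size=1,
            max_size=25,
        )
    )
    def test_expansion_recovers_base_sets(self, columns):
        consensus = make_degenerate(columns)
        for code, col in zip(consensus.bases, columns):
            assert iupac_expand(code) == col

    def test_all_four_bases_emits_n(self):
        assert make_degenerate([{"A", "C", "G", "T"}]).bases == "N"

    def test_gap_rejected(self):
        with pytest.raises(ValueError):
            make_degenerate([{"A", "-"}])


class TestAttachTail:
    def test_tp1_full_sequence(self):
        primer = attach_tail(
            NucSeq("sp", "ATGTTCACCTTGAAGRAATC"),
            NucSeq("tail", DEFAULT_FORWARD_TAIL),
            name="TP1",
        )
        assert primer.full_sequence == "CAGGACCAGGGTACGGTGATGTTCACCTTGAAGRAATC"
        assert primer.degeneracy == 2

    def test_poly_dt_reverse_primer(self):
        primer = attach_tail(
            NucSeq("polyT", "T" * 19), NucSeq("trP1", DEFAULT_REVERSE_TAIL), name="rev"
        )
        assert primer.full_sequence == "CCTCTCTATGGGCAGTCGGTGATTTTTTTTTTTTTTTTTTTT"

    def test_nondegenerate_primer_degeneracy_one(self):
        primer = attach_tail(NucSeq("sp", "ACGTACGT"), NucSeq("t", "GG"))
        assert primer.degeneracy == 1


class TestPickPrimerPosition:
    def _win(self, start, n_poly):
        return ConservedWindow(start, 20, tuple(range(n_poly)), NucSeq("c", "A" * 20))

    def test_single_window(self):
        w = self._win(5, 1)
        assert pick_primer_position([w]) is w

    def test_propeptide_mode_prefers_3prime(self):
        w1, w2 = self._win(3, 0), self._win(9, 2)
        assert pick_primer_position([w1, w2], mode="propeptide_3prime") is w2

    def test_empty_list_raises(self):
        with pytest.raises(DesignError):
            pick_primer_position([])

    def test_against_bruteforce_ordering_oracle(self):
        rng = random.Random(5)
        windows = [self._win(rng.randrange(50), rng.randrange(4)) for _ in range(8)]
        got = pick_primer_position(windows, mode="signal_any")
        expected = sorted(windows, key=lambda w: (len(w.polymorphic_columns), w.start))[0]
        assert got is expected
        got3 = pick_primer_position(windows, mode="propeptide_3prime")
        assert got3 is max(windows, key=lambda w: w.start)


class TestPredictAmplicons:
    def _primer(self, specific):
        return attach_tail(
            NucSeq("sp", specific), NucSeq("tail", DEFAULT_FORWARD_TAIL), name="TPx"
        )

    def test_no_binding_site_empty(self, rng):
        template = NucSeq("t", random_dna(rng, 100) + "A" * 20)
        primer = self._primer("G" * 20)
        assert predict_amplicons([template], [primer], max_mismatches=0) == []

    def test_oversize_product_flagged(self, rng):
        # engineered 573-nt product against a 450-nt platform cap
        specific = random_dna(rng, 20)
        insert_len = 573 - len(DEFAULT_FORWARD_TAIL) - len(DEFAULT_REVERSE_TAIL)
        template = NucSeq("t", specific + random_dna(rng, insert_len - 20 - 25) + "A" * 25)
        preds = predict_amplicons([template], [self._primer(specific)], platform_max=450)
        assert len(preds) == 1
        assert preds[0].product_length == 573
        assert preds[0].exceeds_platform_limit

    def test_in_range_product_not_flagged(self, rng):
        specific = random_dna(rng, 20)
        template = NucSeq("t", specific + random_dna(rng, 200) + "A" * 25)
        preds = predict_amplicons([template], [self._primer(specific)], platform_max=450)
        assert len(preds) == 1
        assert not preds[0].exceeds_platform_limit

    def test_against_bruteforce_offset_oracle(self, rng):
        specific = "ATGTTCACCWTGARKAAAYC"
        primer = self._primer(specific)
        for _ in range(10):
            template = NucSeq("t", random_dna(rng, 150) + specific.replace("W", "A")
                              .replace("R", "G").replace("K", "T").replace("Y", "C")
                              + random_dna(rng, 80) + "A" * 20)
            preds = predict_amplicons([template], [primer], max_mismatches=2)
            # oracle: scan every offset, count IUPAC-aware mismatches
            best = None
            for start in range(len(template.bases) - 20 + 1):
                mm = sum(
                    0 if iupac_match(specific[i], template.bases[start + i]) else 1
                    for i in range(20)
                )
                if mm <= 2 and (best is None or mm < best[1]):
                    best = (start, mm)
            assert len(preds) == 1
            assert preds[0].forward_site == best[0]
            expected_len = (
                len(template.bases) - best[0]
                + len(DEFAULT_FORWARD_TAIL) + len(DEFAULT_REVERSE_TAIL)
            )
            assert preds[0].product_length == expected_len


class TestDesignInvariants:
    def test_primer_matches_all_members_with_zero_floor(self):
        rng = random.Random(13)
        base = random_dna(rng, 40)
        rows = [_mutate(rng, base, rng.randint(0, 2)) for _ in range(8)]
        aln = _make_alignment(rows)
        windows = scan_windows(aln, window_len=20, max_polymorphic=3,
                               minor_freq_floor=0.0)
        for w in windows:
            for row in rows:
                segment = row[w.start : w.start + 20]
                mismatches = sum(
                    0 if iupac_match(c, b) else 1
                    for c, b in zip(w.consensus.bases, segment)
                )
                assert mismatches == 0

    def test_window_degeneracy_counts_distinct_kmers(self):
        rows = ["ACGTACGTACGTACGTACGT",
                "ACGTACGTACGTACGTACGA",
                "ACGTACGTACGTACGTACGT",
                "TCGTACGTACGTACGTACGA"]
        aln = _make_alignment(rows)
        (w,) = scan_windows(aln, window_len=20, max_polymorphic=3)
        concrete = {
            "".join(c)
            for c in itertools.product(*(iupac_expand(b) for b in w.consensus.bases))
        }
        assert degeneracy(w.consensus) == len(concrete)
        assert set(rows) <= concrete

    def test_clustering_deterministic(self, rng):
        seqs = [NucSeq(f"s{i}", random_dna(rng, 30)) for i in range(12)]
        a = cluster_by_identity(seqs, 0.8)
        b = cluster_by_identity(seqs, 0.8)
        assert [[m.id for m in c.members] for c in a] == [
            [m.id for m in c.members] for c in b
        ]


class TestAmpliconPredictionType:
    def test_flag_invariant(self):
        p = AmpliconPrediction("t", 0, 500, True)
        assert p.exceeds_platform_limit == (p.product_length > 450)
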