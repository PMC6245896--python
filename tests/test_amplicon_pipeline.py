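import random

import pytest

from ampliseek.amplicon_pipeline import (
    Contig,
    TrimConfig,
    assemble_olc,
    demultiplex,
    filter_support,
    mott_segment,
    remap_and_flag,
    trim_read,
)
from ampliseek.seqcore import NucSeq, QualRead, reverse_complement
from conftest import random_dna, tile_template


def mott_oracle(quals, limit):
    """Brute-force max-sum segment over all O(L^2) candidates; ties to the
    leftmost start, then the longest extent."""
    weights = [limit - 10.0 ** (-q / 10.0) for q in quals]
    best = (0, 0)
    best_sum = 0.0
    for i in range(len(weights)):
        total = 0.0
        for j in range(i, len(weights)):
            total += weights[j]
            if total > best_sum + 1e-9:
                best_sum = total
                best = (i, j + 1)
            elif total > 1e-9 and abs(total - best_sum) <= 1e-9:
                if i < best[0] or (i == best[0] and j + 1 > best[1]):
                    best = (i, j + 1)
    return best


class TestMottTrimming:
    def test_high_quality_read_unchanged(self):
        read = QualRead("r", "ACGT" * 30, (40,) * 120)
        cfg = TrimConfig(min_length=100)
        out = trim_read(read, cfg)
        assert out is not None
        assert out.bases == read.bases

    def test_short_after_trim_discarded(self, rng):
        read = QualRead("r", random_dna(rng, 80), (40,) * 80)
        assert trim_read(read, TrimConfig(min_length=100)) is None

    def test_low_quality_tail_removed(self):
        bases = "ACGT" * 50
        quals = (40,) * 150 + (3,) * 50
        out = trim_read(QualRead("r", bases, quals), TrimConfig(min_length=100))
        assert out is not None
        assert len(out) == 150

    def test_against_bruteforce_oracle(self):
        rng = random.Random(99)
        for _ in range(200):
            n = rng.randint(5, 60)
            quals = tuple(rng.randint(2, 40) for _ in range(n))
            assert mott_segment(quals, 0.05) == mott_oracle(quals, 0.05)

    def test_trimming_never_lengthens(self, rng):
        cfg = TrimConfig(min_length=10)
        for _ in range(50):
            n = rng.randint(20, 120)
            read = QualRead(
                "r", random_dna(rng, n), tuple(rng.randint(2, 40) for _ in range(n))
            )
            out = trim_read(read, cfg)
            if out is not None:
                assert len(out) <= len(read)
                assert len(out) >= cfg.min_length

    def test_adapter_clipped(self):
        adapter = "ATCACCGACTGCCCATAGAGAGG"
        insert = "ACGTACGTACGT" * 12
        read = QualRead("r", insert + adapter + "GGGG",
                        (38,) * (len(insert) + len(adapter) + 4))
        out = trim_read(read, TrimConfig(min_length=50, adapters=(adapter,)))
        assert out is not None
        assert out.bases == insert

    def test_partial_adapter_at_3prime_clipped(self):
        adapter = "ATCACCGACTGCCCATAGAGAGG"
        insert = "ACGTACGTACGT" * 12
        read = QualRead("r", insert + adapter[:10], (38,) * (len(insert) + 10))
        out = trim_read(read, TrimConfig(min_length=50, adapters=(adapter,)))
        assert out is not None
        assert out.bases == insert

    def test_leading_trailing_n_stripped(self):
        bases = "N" * 3 + "ACGT" * 30 + "NN"
        read = QualRead("r", bases, (35,) * len(bases))
        out = trim_read(read, TrimConfig(min_length=50))
        assert out is not None
        assert not out.bases.startswith("N") and not out.bases.endswith("N")

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrimConfig(error_prob_limit=1.5)
        with pytest.raises(ValueError):
            TrimConfig(min_length=0)


class TestDemultiplex:
    BARCODES = {"s1": "AAAAAAAAAA", "s2": "GGGGGGGGGG", "s3": "CCCCCCCCCC"}

    def _read(self, bases):
        return QualRead("r", bases, (30,) * len(bases))

    def test_exact_prefix_assigned_and_stripped(self):
        bins = demultiplex([self._read("AAAAAAAAAA" + "ACGT" * 5)], self.BARCODES)
        assert len(bins["s1"]) == 1
        assert bins["s1"][0].bases == "ACGT" * 5

    def test_unmatched_goes_undetermined(self):
        bins = demultiplex([self._read("ATGATGATGA" + "ACGT" * 5)], self.BARCODES)
        assert len(bins["undetermined"]) == 1

    def test_close_barcodes_rejected(self):
        with pytest.raises(ValueError):
            demultiplex([], {"a": "AAAAAAAAAA", "b": "AAAAAAAAAC"}, max_mismatch=1)

    def test_one_mismatch_accuracy(self):
        rng = random.Random(7)
        reads, labels = [], {}
        for i in range(60):
            sample = rng.choice(list(self.BARCODES))
            bc = list(self.BARCODES[sample])
            pos = rng.randrange(10)
            bc[pos] = rng.choice([b for b in "ACGT" if b != bc[pos]])
            bases = "".join(bc) + random_dna(rng, 40)
            reads.append(QualRead(f"r{i}", bases, (30,) * len(bases)))
            labels[f"r{i}"] = sample
        bins = demultiplex(reads, self.BARCODES, max_mismatch=1)
        assert not bins["undetermined"]
        # every read landed in its true sample
        for sample in self.BARCODES:
            for r in bins[sample]:
                assert labels[r.id] == sample
        assert sum(len(bins[s]) for s in self.BARCODES) == 60


class TestAssembly:
    def test_single_read_single_contig(self):
        reads = [NucSeq("r1", "ACGT" * 20)]
        contigs = assemble_olc(reads, min_overlap=20)
        assert len(contigs) == 1
        assert contigs[0].supporting_reads == 1
        assert contigs[0].consensus.bases == "ACGT" * 20

    def test_error_free_tiling_reconstructs_template(self, rng):
        template = random_dna(rng, 350)
        reads = tile_template(template, read_len=120, step=40)
        contigs = assemble_olc(reads, min_overlap=50, min_overlap_identity=0.95)
        assert len(contigs) == 1
        assert contigs[0].consensus.bases == template
        assert contigs[0].supporting_reads == len(reads)

    def test_two_disjoint_templates_two_contigs(self, rng):
        t1 = random_dna(rng, 300)
        t2 = random_dna(rng, 300)
        reads = tile_template(t1, 120, 40) + [
            NucSeq(f"b{r.id}", r.bases) for r in tile_template(t2, 120, 40)
        ]
        contigs = assemble_olc(reads, min_overlap=50)
        assert len(contigs) == 2
        assert {c.consensus.bases for c in contigs} == {t1, t2}

    def test_reverse_orientation_reads_merge(self, rng):
        template = random_dna(rng, 200)
        fwd = NucSeq("f", template[:120])
        rev = NucSeq("r", reverse_complement(template[60:]))
        contigs = assemble_olc([fwd, rev], min_overlap=50)
        assert len(contigs) == 1
        got = contigs[0].consensus.bases
        assert got == template or got == reverse_complement(template)

    def test_read_conservation(self, rng):
        template = random_dna(rng, 300)
        reads = tile_template(template, 100, 60) + [NucSeq("lone", random_dna(rng, 80))]
        contigs = assemble_olc(reads, min_overlap=50)
        assert sum(c.supporting_reads for c in contigs) == len(reads)
        all_ids = sorted(i for c in contigs for i in c.read_ids)
        assert all_ids == sorted(r.id for r in reads)

    def test_empty_input(self):
        assert assemble_olc([]) == []


class TestSupportFilter:
    def _contig(self, support):
        return Contig(consensus=NucSeq("c", "ACGT" * 30), supporting_reads=support)

    def test_support_two_discarded(self):
        assert filter_support([self._contig(2)], min_reads=3) == []

    def test_support_three_retained(self):
        contigs = [self._contig(3)]
        assert filter_support(contigs, min_reads=3) == contigs

    def test_empty_input(self):
        assert filter_support([], min_reads=3) == []


class TestRemapAndFlag:
    def test_single_haplotype_zero_polymorphism(self, rng):
        template = random_dna(rng, 250)
        reads = tile_template(template, 100, 50)
        contigs = assemble_olc(reads, min_overlap=50)
        assert len(contigs) == 1
        result = remap_and_flag(contigs, reads)
        assert result.flagged == []
        assert result.contigs[0].polymorphism_rate == 0.0

    def test_mixture_flagged_and_resolved(self, rng):
        # two templates differing at 5 spread positions: collapses into one
        # contig at 0.95 overlap identity, flags, then resolves at 0.99
        t1 = random_dna(rng, 200)
        t2 = list(t1)
        for pos in (20, 60, 100, 140, 180):
            t2[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[t2[pos]]
        t2 = "".join(t2)
        reads = [
            NucSeq(f"a{r.id}", r.bases) for r in tile_template(t1, 120, 40)
        ] + [NucSeq(f"b{r.id}", r.bases) for r in tile_template(t2, 120, 40)]
        contigs = assemble_olc(reads, min_overlap=50, min_overlap_identity=0.95)
        assert len(contigs) == 1  # collapsed mixture
        result = remap_and_flag(contigs, reads, flag_threshold=0.02,
                                stringent_identity=0.99)
        assert len(result.flagged) == 1
        variants = {c.consensus.bases for c in result.contigs}
        assert variants == {t1, t2}

    def test_allele_counts_match_bruteforce_recount(self, rng):
        template = random_dna(rng, 200)
        reads = tile_template(template, 100, 50)
        contigs = assemble_olc(reads, min_overlap=50)
        result = remap_and_flag(contigs, reads)
        counts = result.allele_counts[contigs[0].consensus.id]
        # oracle: recount from known tiling offsets
        expected = [0] * len(template)
        for r in reads:
            off = template.find(r.bases)
            for i in range(len(r.bases)):
                expected[off + i] += 1
        for pos, (col, exp) in enumerate(zip(counts, expected)):
            assert sum(col.values()) == exp
            # error-free reads: only the template base is ever observed
            assert list(col) == [template[pos]]
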