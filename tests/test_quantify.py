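"""Gene lengths, k-mer assignment and RPKM computation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import seqsat
from seqsat import (
    CountTable,
    ExpressionProfile,
    GeneLengthTable,
    KmerIndex,
    ReadSet,
    assign_reads,
    average_profiles,
    build_index,
    compute_rpkm,
    gene_lengths_from_gtf,
)


def write_gtf(path, rows):
    with open(path, "w") as fh:
        for gene, start, end in rows:
            fh.write(
                f"chr1\tsrc\texon\t{start}\t{end}\t.\t+\t.\t"
                f'gene_id "{gene}"; transcript_id "{gene}.1";\n'
            )


class TestGeneLengthsFromGtf:
    def test_overlapping_exons_are_merged(self, tmp_path):
        p = tmp_path / "a.gtf"
        write_gtf(p, [("g", 1, 100), ("g", 51, 150)])
        assert gene_lengths_from_gtf(p) == {"g": 150}

    def test_disjoint_exons_sum(self, tmp_path):
        p = tmp_path / "a.gtf"
        write_gtf(p, [("g", 1, 100), ("g", 201, 300)])
        assert gene_lengths_from_gtf(p) == {"g": 200}

    def test_matches_per_base_bitmap_oracle(self, tmp_path, rng):
        # randomized exon sets vs an independent per-base coverage count
        rows, truth = [], {}
        for gi in range(50):
            gene = f"g{gi}"
            bitmap = np.zeros(2000, dtype=bool)
            for _ in range(int(rng.integers(1, 8))):
                s = int(rng.integers(1, 1900))
                e = s + int(rng.integers(0, 100))
                rows.append((gene, s, e))
                bitmap[s - 1 : e] = True  # GTF is 1-based end-inclusive
            truth[gene] = int(bitmap.sum())
        p = tmp_path / "rand.gtf"
        write_gtf(p, rows)
        assert dict(gene_lengths_from_gtf(p)) == truth

    def test_reversed_exon_coordinates_error_with_line_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        write_gtf(p, [("g", 1, 100), ("g", 300, 200)])
        with pytest.raises(ValueError, match="line 2"):
            gene_lengths_from_gtf(p)

    def test_gene_without_exons_absent(self, tmp_path):
        p = tmp_path / "a.gtf"
        with open(p, "w") as fh:
            fh.write('chr1\tsrc\tgene\t1\t500\t.\t+\t.\tgene_id "g";\n')
            fh.write('chr1\tsrc\texon\t1\t100\t.\t+\t.\tgene_id "h"; transcript_id "h.1";\n')
        assert set(gene_lengths_from_gtf(p)) == {"h"}


class TestGeneLengthTable:
    def test_tsv_round_trip(self, tmp_path):
        t = GeneLengthTable({"a": 100, "b": 2500})
        t.to_tsv(tmp_path / "l.tsv")
        assert GeneLengthTable.from_tsv(tmp_path / "l.tsv") == t

    def test_duplicate_ids_rejected(self, tmp_path):
        (tmp_path / "l.tsv").write_text("a\t100\na\t200\n")
        with pytest.raises(ValueError, match="duplicate"):
            GeneLengthTable.from_tsv(tmp_path / "l.tsv")

    def test_non_positive_length_rejected(self):
        with pytest.raises(ValueError):
            GeneLengthTable({"a": 0})


def reads_from(seqs: list[str]) -> ReadSet:
    return ReadSet([f"r{i}" for i in range(len(seqs))], seqs, ["I" * len(s) for s in seqs])


class TestKmerIndex:
    def test_single_gene_every_kmer_maps_to_it(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 200))
        idx = build_index({"g": seq}, k=31)
        for start in range(0, len(seq) - 31 + 1, 13):
            assert idx.lookup(seq[start : start + 31]) == {"g"}

    def test_duplicate_gene_sequences_share_kmers(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 120))
        idx = build_index({"a": seq, "b": seq}, k=31)
        assert idx.lookup(seq[:31]) == {"a", "b"}

    def test_lookup_agrees_with_brute_force_substring_scan(self, rng):
        genes = {f"g{i}": "".join(rng.choice(list("ACGT"), 80)) for i in range(10)}
        idx = build_index(genes, k=15)
        for gid, seq in genes.items():
            for start in range(0, len(seq) - 15 + 1, 7):
                kmer = seq[start : start + 15]
                truth = {g for g, s in genes.items() if kmer in s}
                assert idx.lookup(kmer) == truth
                assert gid in truth

    def test_k_longer_than_a_transcript_errors_naming_it(self):
        with pytest.raises(ValueError, match="short"):
            KmerIndex(["short"], ["ACGTACGT"], k=31)


class TestAssignReads:
    @pytest.fixture()
    def genes(self, rng):
        return {f"g{i}": "".join(rng.choice(list("ACGT"), 300)) for i in range(5)}

    def test_verbatim_read_assigned_to_its_gene(self, genes):
        idx = build_index(genes)
        reads = reads_from([genes["g2"][40:140]])
        ct = assign_reads(reads, idx)
        assert ct.counts["g2"] == 1 and ct.total_assigned == 1

    def test_all_n_read_is_unassigned(self, genes):
        idx = build_index(genes)
        ct = assign_reads(reads_from(["N" * 75]), idx)
        assert ct.n_unassigned == 1 and ct.total_assigned == 0

    def test_read_shorter_than_k_is_unassigned(self, genes):
        idx = build_index(genes, k=31)
        ct = assign_reads(reads_from([genes["g0"][:20]]), idx)
        assert ct.n_unassigned == 1

    def test_foreign_read_is_unassigned(self, genes, rng):
        idx = build_index(genes)
        foreign = "".join(rng.choice(list("ACGT"), 75))
        ct = assign_reads(reads_from([foreign]), idx)
        assert ct.n_unassigned == 1

    def test_read_from_duplicated_gene_is_ambiguous(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 200))
        idx = build_index({"a": seq, "b": seq})
        ct = assign_reads(reads_from([seq[10:85]]), idx)
        assert ct.n_ambiguous == 1 and ct.total_assigned == 0

    def test_non_acgtn_characters_error(self, genes):
        idx = build_index(genes)
        with pytest.raises(ValueError, match="non-ACGTN"):
            assign_reads(reads_from(["ACGTX" + "A" * 70]), idx)

    def test_accounting_identity(self, genes, rng):
        idx = build_index(genes)
        seqs = [genes[f"g{i % 5}"][i : i + 75] for i in range(40)]
        seqs += ["N" * 75, "".join(rng.choice(list("ACGT"), 75))]
        ct = assign_reads(reads_from(seqs), idx)
        assert ct.total_assigned + ct.n_unassigned + ct.n_ambiguous == len(seqs)
        assert ct.total_assigned == int(ct.counts.sum())


class TestComputeRpkm:
    def test_hand_checked_case(self):
        # C=100 reads, N=1e6 mapped, L=1000 bp -> 1e9*100/(1e6*1000) = 100
        counts = CountTable(
            counts=pd.Series({"g": 100, "rest": 999_900}), n_unassigned=0, n_ambiguous=0
        )
        prof = compute_rpkm(counts, GeneLengthTable({"g": 1000, "rest": 5000}))
        assert prof.rpkm["g"] == pytest.approx(100.0)

    def test_zero_count_gives_zero_rpkm_and_undefined_log2(self):
        counts = CountTable(
            counts=pd.Series({"a": 0, "b": 10}), n_unassigned=0, n_ambiguous=0
        )
        prof = compute_rpkm(counts, GeneLengthTable({"a": 500, "b": 500}))
        assert prof.rpkm["a"] == 0.0
        assert np.isnan(prof.log2_rpkm["a"])
        assert np.isfinite(prof.log2_rpkm["b"])

    def test_no_assigned_reads_errors(self):
        counts = CountTable(counts=pd.Series({"a": 0}), n_unassigned=5, n_ambiguous=0)
        with pytest.raises(ValueError, match="denominator|no assigned"):
            compute_rpkm(counts, GeneLengthTable({"a": 100}))

    def test_counted_gene_missing_from_lengths_errors(self):
        counts = CountTable(counts=pd.Series({"a": 3}), n_unassigned=0, n_ambiguous=0)
        with pytest.raises(ValueError, match="a"):
            compute_rpkm(counts, GeneLengthTable({"b": 100}))

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.integers(min_value=0, max_value=10_000), min_size=1, max_size=30),
        st.lists(st.integers(min_value=1, max_value=50_000), min_size=30, max_size=30),
    )
    def test_rpkm_conservation(self, raw_counts, lengths):
        # sum over genes of rpkm * L_kb is exactly 1e6 whenever N = sum(counts)
        if sum(raw_counts) == 0:
            raw_counts = [1] + raw_counts[1:]
        gids = [f"g{i}" for i in range(len(raw_counts))]
        counts = CountTable(
            counts=pd.Series(raw_counts, index=gids), n_unassigned=0, n_ambiguous=0
        )
        lt = GeneLengthTable(dict(zip(gids, lengths)))
        prof = compute_rpkm(counts, lt)
        total = sum(prof.rpkm[g] * lt[g] / 1000 for g in gids)
        assert total == pytest.approx(1e6, rel=1e-9)

    def test_scale_invariance(self):
        gids = ["a", "b", "c"]
        lt = GeneLengthTable({"a": 100, "b": 2000, "c": 700})
        c1 = CountTable(counts=pd.Series([3, 10, 7], index=gids), n_unassigned=0, n_ambiguous=0)
        c2 = CountTable(counts=pd.Series([6, 20, 14], index=gids), n_unassigned=0, n_ambiguous=0)
        p1, p2 = compute_rpkm(c1, lt), compute_rpkm(c2, lt)
        assert np.allclose(p1.rpkm, p2.rpkm)


class TestAverageProfiles:
    def mk(self, vals, depth=10, rep=0):
        return ExpressionProfile(
            rpkm=pd.Series(vals, index=[f"g{i}" for i in range(len(vals))]),
            depth=depth,
            replicate=rep,
        )

    def test_identical_replicates_average_to_themselves(self):
        p = self.mk([1.0, 2.0, 0.0])
        avg = average_profiles([p, p, p])
        assert np.allclose(avg.rpkm, p.rpkm)

    def test_two_and_four_average_to_three(self):
        avg = average_profiles([self.mk([2.0]), self.mk([4.0], rep=1)])
        assert avg.rpkm.iloc[0] == pytest.approx(3.0)

    def test_matches_brute_force_mean(self, rng):
        profs = [self.mk(rng.random(20), rep=r) for r in range(4)]
        avg = average_profiles(profs)
        brute = np.mean([p.rpkm.to_numpy() for p in profs], axis=0)
        assert np.allclose(avg.rpkm.to_numpy(), brute)

    def test_mismatched_gene_sets_error(self):
        a = self.mk([1.0, 2.0])
        b = ExpressionProfile(rpkm=pd.Series({"x": 1.0, "y": 2.0}), depth=10, replicate=1)
        with pytest.raises(ValueError, match="gene"):
            average_profiles([a, b])

    def test_expression_tsv_round_trip(self, tmp_path):
        p = self.mk([1.5, 0.0, 3.25], depth=100, rep=2)
        p.to_tsv(tmp_path / "e.tsv")
        q = ExpressionProfile.from_tsv(tmp_path / "e.tsv")
        assert q.depth == 100 and q.replicate == 2
        assert np.allclose(q.rpkm.to_numpy(), p.rpkm.to_numpy())
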