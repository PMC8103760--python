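"""Reference index construction, projection, and overlap annotation."""

import numpy as np
import pytest

from umivar.reference import (
    TranscriptModel,
    annotate_overlap,
    build_index,
    project_to_genome,
    union_intervals,
)


def _write_toy_reference(tmp_path, transcripts, contig_len=10000):
    """transcripts: list of (tid, gid, strand, exons, biotype)."""
    rng = np.random.default_rng(0)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=contig_len))
    fasta = tmp_path / "ref.fa"
    with open(fasta, "w") as fh:
        fh.write(">chrT\n")
        for i in range(0, contig_len, 70):
            fh.write(seq[i : i + 70] + "\n")
    gtf = tmp_path / "ref.gtf"
    with open(gtf, "w") as fh:
        for tid, gid, strand, exons, biotype in transcripts:
            for s, e in exons:
                attrs = (
                    f'gene_id "{gid}"; transcript_id "{tid}"; '
                    f'transcript_biotype "{biotype}";'
                )
                fh.write(
                    f"chrT\ttest\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}\n"
                )
    return str(gtf), str(fasta)


class TestBuildIndexFilters:
    @pytest.mark.parametrize(
        "length,biotype,expect_kept",
        [
            (99, "protein_coding", False),   # below the minimum length
            (100, "protein_coding", True),   # boundary: kept
            (5000, "retained_intron", False),  # excluded biotype
            (5000, "protein_coding", True),
        ],
    )
    def test_length_and_biotype_filters(self, tmp_path, length, biotype, expect_kept):
        gtf, fasta = _write_toy_reference(
            tmp_path, [("tx1", "g1", "+", [(100, 100 + length)], biotype)]
        )
        idx = build_index(gtf, fasta)
        assert ("tx1" in idx.transcripts) is expect_kept

    def test_unknown_contig_is_hard_error(self, tmp_path):
        gtf, fasta = _write_toy_reference(
            tmp_path, [("tx1", "g1", "+", [(100, 400)], "protein_coding")]
        )
        with open(gtf, "a") as fh:
            fh.write(
                'chrMISSING\ttest\texon\t1\t200\t.\t+\t.\t'
                'gene_id "g2"; transcript_id "tx2"; transcript_biotype "protein_coding";\n'
            )
        with pytest.raises(ValueError, match="unknown contig"):
            build_index(gtf, fasta)

    def test_exon_beyond_contig_is_hard_error(self, tmp_path):
        gtf, fasta = _write_toy_reference(
            tmp_path,
            [("tx1", "g1", "+", [(9990, 10500)], "protein_coding")],
        )
        with pytest.raises(ValueError, match="outside contig bounds"):
            build_index(gtf, fasta)

    def test_shrinking_exclusions_is_monotone(self, tmp_path):
        txs = [
            ("tx1", "g1", "+", [(100, 400)], "protein_coding"),
            ("tx2", "g2", "+", [(600, 900)], "retained_intron"),
            ("tx3", "g3", "+", [(1100, 1400)], "nonsense_mediated_decay"),
        ]
        gtf, fasta = _write_toy_reference(tmp_path, txs)
        full = build_index(gtf, fasta)
        relaxed = build_index(gtf, fasta, excluded_biotypes={"retained_intron"})
        assert set(full.transcripts) <= set(relaxed.transcripts)


def _brute_force_tx_to_genome(tx: TranscriptModel) -> list[int]:
    """Per-base transcript->genome map built by walking exons base by base."""
    positions = []
    for s, e in tx.exons:
        positions.extend(range(s, e))
    if tx.strand == "-":
        positions = positions[::-1]
    return positions


class TestProjection:
    tx_plus = TranscriptModel(
        "t+", "g", "chrT", "+", [(1000, 1200), (2200, 2400), (3000, 3100)], "pc"
    )
    tx_minus = TranscriptModel(
        "t-", "g", "chrT", "-", [(1000, 1200), (2200, 2400)], "pc"
    )

    def test_single_exon_identity(self):
        blocks, strand = project_to_genome(10, 60, self.tx_plus)
        assert blocks == [(1010, 1060)]
        assert strand == "+"

    def test_junction_split_inserts_skip(self):
        # alignment spanning exon1/exon2 junction; 1000 bp intron between
        blocks, _ = project_to_genome(150, 260, self.tx_plus)
        assert blocks == [(1150, 1200), (2200, 2260)]
        assert blocks[1][0] - blocks[0][1] == 1000

    @pytest.mark.parametrize("tx", [tx_plus, tx_minus])
    def test_per_base_agreement_with_exon_walk(self, tx, rng):
        oracle = _brute_force_tx_to_genome(tx)
        for _ in range(50):
            a = int(rng.integers(0, tx.length - 1))
            b = int(rng.integers(a + 1, tx.length + 1))
            blocks, strand = project_to_genome(a, b, tx)
            got = sorted(p for s, e in blocks for p in range(s, e))
            assert got == sorted(oracle[a:b])
            assert strand == tx.strand
            assert sum(e - s for s, e in blocks) == b - a

    def test_minus_strand_orientation_flip(self):
        _, strand = project_to_genome(0, 50, self.tx_minus, reverse=True)
        assert strand == "+"

    def test_out_of_bounds_is_error(self):
        with pytest.raises(ValueError):
            project_to_genome(0, self.tx_plus.length + 1, self.tx_plus)


class TestOverlapAnnotation:
    def test_fully_exonic_block(self, small_index, small_reference):
        gene = next(iter(small_index.genes.values()))
        s, e = gene.exons[0]
        hits = annotate_overlap([(s, s + min(98, e - s))], gene.contig, gene.strand, small_index)
        assert hits[gene.gene_id]["exon"] == min(98, e - s)
        assert not hits[gene.gene_id]["antisense"]

    def test_straddling_block_counts_per_base(self, small_index):
        gene = next(
            g for g in small_index.genes.values() if g.introns
        )
        s, e = gene.exons[0]
        # 26 bp in the exon, remainder in the intron
        block = (e - 26, e + 40)
        hits = annotate_overlap([block], gene.contig, gene.strand, small_index)
        assert hits[gene.gene_id]["exon"] == 26
        assert hits[gene.gene_id]["intron"] == 40

    def test_intergenic_block_is_empty(self, small_index):
        contig = next(iter(small_index.contig_lengths))
        ln = small_index.contig_lengths[contig]
        hits = annotate_overlap([(ln - 50, ln - 1)], contig, "+", small_index)
        assert hits == {}

    def test_overlap_conservation(self, small_index, rng):
        """exon + intron + intergenic bases == aligned bases, any alignment."""
        contig = next(iter(small_index.contig_lengths))
        ln = small_index.contig_lengths[contig]
        etree = small_index.exon_lookup[contig]
        itree = small_index.intron_lookup[contig]
        for _ in range(100):
            s = int(rng.integers(0, ln - 200))
            block = (s, s + int(rng.integers(30, 200)))
            hits = annotate_overlap([block], contig, "+", small_index)
            # genic bases counted per position via brute-force union over genes
            exonic = set()
            intronic = set()
            for p in range(*block):
                if etree.overlap(p, p + 1):
                    exonic.add(p)
                if itree.overlap(p, p + 1):
                    intronic.add(p)
            # per-gene totals match the brute-force per-base intersection
            for gid, d in hits.items():
                g = small_index.genes[gid]
                ex = sum(
                    max(0, min(block[1], e) - max(block[0], es))
                    for es, e in g.exons
                )
                assert d["exon"] == ex


def test_union_intervals_merges_and_sorts():
    assert union_intervals([(5, 10), (1, 3), (9, 12), (3, 5)]) == [(1, 12)]
    assert union_intervals([]) == []


def test_index_roundtrip_through_hdf5(tmp_path, small_reference, small_index):
    path = tmp_path / "index.h5"
    small_index.save(str(path))
    from umivar.reference import ReferenceIndex

    loaded = ReferenceIndex.load(str(path))
    assert set(loaded.genes) == set(small_index.genes)
    assert set(loaded.transcripts) == set(small_index.transcripts)
    assert loaded.junction_set == small_index.junction_set
    for tid, tx in small_index.transcripts.items():
        assert loaded.transcripts[tid].exons == tx.exons
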