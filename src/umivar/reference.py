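"""Gene-model reference index.

Parses an Ensembl-dialect GTF plus genome FASTA into gene/transcript/exon
interval structures, applies the full-length transcript filters (biotype
exclusion list and minimum transcript length), and provides the coordinate
machinery the rest of the pipeline relies on:

* projection of transcript-space alignments to genomic coordinates, with
  reference-skip (``N``) operations inserted across introns;
* per-gene exonic/intronic overlap annotation for genomic alignments.

Coordinates are 0-based half-open throughout; VCF export elsewhere converts
to 1-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import h5py
import numpy as np
from intervaltree import IntervalTree
from pyfaidx import Fasta

#: transcript biotypes removed from the full-length index by default
DEFAULT_EXCLUDED_BIOTYPES = frozenset(
    {"retained_intron", "nonsense_mediated_decay", "non_stop_decay"}
)

#: transcripts shorter than this many bases are dropped from the index
DEFAULT_MIN_TX_LENGTH = 100

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


@dataclass
class TranscriptModel:
    """One transcript: an ordered exon chain on the genome.

    ``exons`` are genomic intervals sorted by start; for minus-strand
    transcripts the 5' end of the transcript is the *last* interval's end.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def exon_chain_5to3(self) -> list[tuple[int, int]]:
        """Exon intervals ordered 5'->3' in transcript orientation."""
        if self.strand == "+":
            return list(self.exons)
        return list(reversed(self.exons))


@dataclass
class GeneModel:
    """A gene: the union of exons over its retained transcripts.

    ``exons`` is the per-gene union (sorted, non-overlapping); ``introns``
    is the complement of that union within the gene span.
    """

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    introns: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = ""

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


def union_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals into a sorted union."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _gaps(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    return [
        (intervals[i][1], intervals[i + 1][0])
        for i in range(len(intervals) - 1)
        if intervals[i + 1][0] > intervals[i][1]
    ]


class ReferenceIndex:
    """Filtered transcript set plus interval-query structures per contig."""

    def __init__(
        self,
        genes: dict[str, GeneModel],
        transcripts: dict[str, TranscriptModel],
        contig_lengths: dict[str, int],
    ):
        self.genes = genes
        self.transcripts = transcripts
        self.contig_lengths = contig_lengths
        # (contig, donor_end, acceptor_start) for every intron of every
        # retained transcript; donor_end == intron start, acceptor == end
        self.junction_set: set[tuple[str, int, int]] = set()
        for tx in transcripts.values():
            for i in range(len(tx.exons) - 1):
                self.junction_set.add(
                    (tx.contig, tx.exons[i][1], tx.exons[i + 1][0])
                )
        self.exon_lookup: dict[str, IntervalTree] = {}
        self.intron_lookup: dict[str, IntervalTree] = {}
        self.gene_lookup: dict[str, IntervalTree] = {}
        for g in genes.values():
            et = self.exon_lookup.setdefault(g.contig, IntervalTree())
            it = self.intron_lookup.setdefault(g.contig, IntervalTree())
            gt = self.gene_lookup.setdefault(g.contig, IntervalTree())
            for s, e in g.exons:
                et.addi(s, e, g.gene_id)
            for s, e in g.introns:
                it.addi(s, e, g.gene_id)
            gt.addi(g.start, g.end, g.gene_id)
        # per-contig sorted arrays of junction boundaries for overhang trimming
        self.donor_sites: dict[str, np.ndarray] = {}
        self.acceptor_sites: dict[str, np.ndarray] = {}
        donors: dict[str, set[int]] = {}
        acceptors: dict[str, set[int]] = {}
        for contig, d, a in self.junction_set:
            donors.setdefault(contig, set()).add(d)
            acceptors.setdefault(contig, set()).add(a)
        for contig in contig_lengths:
            self.donor_sites[contig] = np.array(
                sorted(donors.get(contig, ())), dtype=np.int64
            )
            self.acceptor_sites[contig] = np.array(
                sorted(acceptors.get(contig, ())), dtype=np.int64
            )

    # ------------------------------------------------------------------
    def save(self, path: str) -> None:
        """Serialize the index (without sequence) to a single HDF5 file."""
        with h5py.File(path, "w") as h5:
            sg = h5.create_group("contigs")
            for name, length in self.contig_lengths.items():
                sg.attrs[name] = length
            tg = h5.create_group("transcripts")
            for tx in self.transcripts.values():
                g = tg.create_group(tx.transcript_id)
                g.attrs["gene_id"] = tx.gene_id
                g.attrs["contig"] = tx.contig
                g.attrs["strand"] = tx.strand
                g.attrs["biotype"] = tx.biotype
                g.create_dataset("exons", data=np.asarray(tx.exons, dtype=np.int64))
            gg = h5.create_group("genes")
            for gene in self.genes.values():
                g = gg.create_group(gene.gene_id)
                g.attrs["contig"] = gene.contig
                g.attrs["strand"] = gene.strand
                g.attrs["biotype"] = gene.biotype
                g.create_dataset("exons", data=np.asarray(gene.exons, dtype=np.int64))

    @classmethod
    def load(cls, path: str) -> "ReferenceIndex":
        with h5py.File(path, "r") as h5:
            contig_lengths = {k: int(v) for k, v in h5["contigs"].attrs.items()}
            transcripts = {}
            for tid, g in h5["transcripts"].items():
                exons = [tuple(map(int, row)) for row in g["exons"][...]]
                transcripts[tid] = TranscriptModel(
                    transcript_id=tid,
                    gene_id=g.attrs["gene_id"],
                    contig=g.attrs["contig"],
                    strand=g.attrs["strand"],
                    exons=exons,
                    biotype=g.attrs["biotype"],
                )
            genes = {}
            for gid, g in h5["genes"].items():
                exons = [tuple(map(int, row)) for row in g["exons"][...]]
                genes[gid] = GeneModel(
                    gene_id=gid,
                    contig=g.attrs["contig"],
                    strand=g.attrs["strand"],
                    exons=exons,
                    introns=_gaps(exons),
                    biotype=g.attrs["biotype"],
                )
        return cls(genes, transcripts, contig_lengths)


# ----------------------------------------------------------------------
# GTF parsing


def _parse_attrs(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf_exons(gtf_path: str):
    """Yield (transcript_id, gene_id, contig, strand, start0, end, biotype)
    for every exon record of an Ensembl-dialect GTF."""
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"malformed GTF line {lineno}: {line!r}")
            contig, _src, feat, start, end, _score, strand, _frame, attrs = parts[:9]
            if feat != "exon":
                continue
            a = _parse_attrs(attrs)
            biotype = a.get("transcript_biotype") or a.get("gene_biotype") or ""
            yield (
                a["transcript_id"],
                a["gene_id"],
                contig,
                strand,
                int(start) - 1,
                int(end),
                biotype,
            )


def build_index(
    gtf_path: str,
    fasta_path: str,
    excluded_biotypes: frozenset[str] | set[str] = DEFAULT_EXCLUDED_BIOTYPES,
    min_tx_length: int = DEFAULT_MIN_TX_LENGTH,
    transcript_fasta_out: str | None = None,
) -> ReferenceIndex:
    """Build the filtered full-length transcript index.

    Transcripts with an excluded biotype or total exonic length below
    ``min_tx_length`` are removed; gene exon sets are the union over the
    retained transcripts.  Optionally writes the transcript FASTA consumed
    by an external aligner.
    """
    fasta = Fasta(fasta_path)
    contig_lengths = {name: len(fasta[name]) for name in fasta.keys()}

    tx_exons: dict[str, list[tuple[int, int]]] = {}
    tx_meta: dict[str, tuple[str, str, str, str]] = {}
    for tid, gid, contig, strand, s, e, biotype in read_gtf_exons(gtf_path):
        if contig not in contig_lengths:
            raise ValueError(f"transcript {tid} references unknown contig {contig}")
        if s < 0 or e > contig_lengths[contig]:
            raise ValueError(f"exon of {tid} outside contig bounds: {s}-{e}")
        tx_exons.setdefault(tid, []).append((s, e))
        tx_meta[tid] = (gid, contig, strand, biotype)

    transcripts: dict[str, TranscriptModel] = {}
    for tid, exons in tx_exons.items():
        gid, contig, strand, biotype = tx_meta[tid]
        tx = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            contig=contig,
            strand=strand,
            exons=sorted(exons),
            biotype=biotype,
        )
        if biotype in excluded_biotypes or tx.length < min_tx_length:
            continue
        transcripts[tid] = tx

    genes: dict[str, GeneModel] = {}
    per_gene: dict[str, list[tuple[int, int]]] = {}
    gene_meta: dict[str, tuple[str, str, str]] = {}
    for tx in transcripts.values():
        per_gene.setdefault(tx.gene_id, []).extend(tx.exons)
        gene_meta[tx.gene_id] = (tx.contig, tx.strand, tx.biotype)
    for gid, exons in per_gene.items():
        contig, strand, biotype = gene_meta[gid]
        u = union_intervals(exons)
        genes[gid] = GeneModel(
            gene_id=gid,
            contig=contig,
            strand=strand,
            exons=u,
            introns=_gaps(u),
            biotype=biotype,
        )

    index = ReferenceIndex(genes, transcripts, contig_lengths)
    if transcript_fasta_out is not None:
        write_transcript_fasta(index, fasta, transcript_fasta_out)
    return index


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def transcript_sequence(tx: TranscriptModel, fasta: Fasta) -> str:
    """Spliced transcript sequence, 5'->3' in transcript orientation."""
    seq = "".join(str(fasta[tx.contig][s:e]) for s, e in tx.exons)
    return revcomp(seq) if tx.strand == "-" else seq


def write_transcript_fasta(index: ReferenceIndex, fasta: Fasta, out_path: str) -> None:
    with open(out_path, "w") as out:
        for tid in sorted(index.transcripts):
            tx = index.transcripts[tid]
            seq = transcript_sequence(tx, fasta)
            out.write(f">{tid}\n")
            for i in range(0, len(seq), 70):
                out.write(seq[i : i + 70] + "\n")


# ----------------------------------------------------------------------
# Projection of transcript-space alignments to genomic coordinates


def project_to_genome(
    tx_start: int, tx_end: int, tx: TranscriptModel, reverse: bool = False
) -> tuple[list[tuple[int, int]], str]:
    """Project the transcript interval [tx_start, tx_end) onto the genome.

    Returns (blocks, strand): sorted genomic match blocks, with implied
    reference skips between consecutive blocks spanning introns, and the
    genomic strand (transcript strand composed with alignment orientation,
    ``reverse=True`` meaning the alignment was to the transcript's reverse
    complement).
    """
    if not tx.exons:
        raise ValueError("zero-length exon chain")
    if tx_start < 0 or tx_end > tx.length or tx_start >= tx_end:
        raise ValueError(
            f"alignment [{tx_start},{tx_end}) outside transcript bounds [0,{tx.length})"
        )
    blocks: list[tuple[int, int]] = []
    offset = 0  # transcript-coordinate offset of the current exon's 5' edge
    for s, e in tx.exon_chain_5to3():
        elen = e - s
        lo = max(tx_start, offset)
        hi = min(tx_end, offset + elen)
        if lo < hi:
            if tx.strand == "+":
                blocks.append((s + (lo - offset), s + (hi - offset)))
            else:
                # transcript coords run 3'->5' along the genome
                blocks.append((e - (hi - offset), e - (lo - offset)))
        offset += elen
    blocks.sort()
    strand = tx.strand
    if reverse:
        strand = "-" if strand == "+" else "+"
    return blocks, strand


def annotate_overlap(
    blocks: list[tuple[int, int]],
    contig: str,
    strand: str,
    index: ReferenceIndex,
) -> dict[str, dict]:
    """Per-gene exon/intron overlap (in aligned reference bases) for an
    alignment given by its genomic match ``blocks``.

    Returns ``{gene_id: {"exon": bp, "intron": bp, "antisense": bool}}``;
    genes with no overlap are absent.  Antisense is judged from the
    alignment strand against the gene strand.
    """
    out: dict[str, dict] = {}
    etree = index.exon_lookup.get(contig)
    itree = index.intron_lookup.get(contig)
    for bs, be in blocks:
        if etree is not None:
            for iv in etree.overlap(bs, be):
                gid = iv.data
                d = out.setdefault(gid, {"exon": 0, "intron": 0})
                d["exon"] += min(be, iv.end) - max(bs, iv.begin)
        if itree is not None:
            for iv in itree.overlap(bs, be):
                gid = iv.data
                d = out.setdefault(gid, {"exon": 0, "intron": 0})
                d["intron"] += min(be, iv.end) - max(bs, iv.begin)
    for gid, d in out.items():
        d["antisense"] = index.genes[gid].strand != strand
    return out
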