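"""Consensus collapsing of UMI groups into molecules.

All reads of a UMI group derive from one mRNA molecule, so their aligned
bases can be merged into a single consensus record covering the union of
their aligned reference positions.  At each column the modal base must be
supported by at least 60% of the overlapping reads (otherwise N), with
quality set to the maximum quality among reads supporting the consensus
base; indels need 60% of locus-overlapping reads to carry the identical
indel sequence.  Groups whose reads do not lay out as a single linear
chain across the genome (conflicting junction structure) are not
collapsed and are passed through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignproc import AlignedTag
from .reference import union_intervals
from .umidedup import UMIGroup

N_CODE = 4
N_QUALITY = 2  # quality assigned to ambiguous consensus columns


@dataclass
class ConsensusParams:
    consensus_fraction: float = 0.60
    indel_fraction: float = 0.60

    def __post_init__(self):
        for f in (self.consensus_fraction, self.indel_fraction):
            if not (0.5 < f <= 1.0):
                raise ValueError("consensus fractions must be in (0.5, 1]")


@dataclass
class CollapsedMolecule:
    """Consensus record over one UMI group."""

    barcode: str
    umi: str
    gene_id: str
    contig: str
    strand: str
    blocks: list[tuple[int, int]]  # union of aligned reference intervals
    seq: np.ndarray  # consensus base codes over the blocks, concatenated
    qual: np.ndarray
    depth: np.ndarray  # reads covering each consensus column
    n_source_reads: int = 1
    n_pcr_duplicates: int = 0
    internal_read_ends: list[int] = field(default_factory=list)
    splice_status: str = "spliced"
    collapsed: bool = True

    @property
    def mapped_bases(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]


def is_linear_group(group: UMIGroup) -> bool:
    """True iff the group's reads can be laid out as one non-branching
    chain of aligned blocks: single contig and strand, and every pair of
    span-overlapping reads agrees on covered-vs-skipped status at every
    reference position inside their span overlap."""
    reads = group.reads
    contigs = {r.contig for r in reads}
    strands = {r.strand for r in reads}
    if len(contigs) > 1 or len(strands) > 1:
        return False
    for i in range(len(reads)):
        for j in range(i + 1, len(reads)):
            a, b = reads[i], reads[j]
            lo = max(a.start, b.start)
            hi = min(a.end, b.end)
            if lo >= hi:
                continue
            if _covered_within(a, lo, hi) != _covered_within(b, lo, hi):
                return False
    return True


def _covered_within(read: AlignedTag, lo: int, hi: int) -> tuple:
    out = []
    for s, e in read.blocks:
        s2, e2 = max(s, lo), min(e, hi)
        if s2 < e2:
            out.append((s2, e2))
    return tuple(out)


def consensus_base(column: list[tuple[int, int]], params: ConsensusParams | None = None):
    """Consensus over one column of (base_code, quality) observations.

    Returns (base_code, quality): the modal base with max supporting
    quality when its fraction reaches the consensus threshold, else (N, 2).
    Ties on the modal count fail the threshold unless a single base
    reaches it.
    """
    params = params or ConsensusParams()
    counts = np.zeros(5, dtype=np.int64)
    maxq = np.zeros(5, dtype=np.int64)
    for base, q in column:
        counts[base] += 1
        maxq[base] = max(maxq[base], q)
    total = counts.sum()
    modal = int(np.argmax(counts))
    if counts[modal] >= params.consensus_fraction * total and (
        (counts == counts[modal]).sum() == 1 or counts[modal] == total
    ):
        return modal, int(maxq[modal])
    return N_CODE, N_QUALITY


def consensus_indel(
    indel_observations: list, n_overlapping: int, params: ConsensusParams | None = None
):
    """Keep an indel iff >= 60% of the reads overlapping its locus carry
    the identical indel sequence; otherwise emit the reference allele
    (None).  ``indel_observations`` is one entry per read carrying an
    indel at the locus, e.g. ("I", "AG") or ("D", 3)."""
    params = params or ConsensusParams()
    if n_overlapping < 1:
        return None
    best, best_n = None, 0
    seen: dict = {}
    for obs in indel_observations:
        seen[obs] = seen.get(obs, 0) + 1
        if seen[obs] > best_n:
            best, best_n = obs, seen[obs]
    if best is not None and best_n >= params.indel_fraction * n_overlapping:
        return best
    return None


def collapse_group(
    group: UMIGroup, params: ConsensusParams | None = None
) -> list[CollapsedMolecule]:
    """Collapse one UMI group into a consensus molecule.

    Non-linear groups are passed through uncollapsed: each unique-position
    read is emitted as its own record flagged ``collapsed=False`` so
    pileup coverage is preserved.
    """
    params = params or ConsensusParams()
    reads = group.reads
    if not is_linear_group(group):
        out = []
        seen_positions = set()
        for r in reads:
            key = r.position_key()
            if key in seen_positions:
                continue
            seen_positions.add(key)
            out.append(
                CollapsedMolecule(
                    barcode=group.barcode,
                    umi=group.umi,
                    gene_id=group.gene_id,
                    contig=r.contig,
                    strand=r.strand,
                    blocks=list(r.blocks),
                    seq=r.seq.copy(),
                    qual=r.qual.copy(),
                    depth=np.ones(len(r.seq), dtype=np.int32),
                    n_source_reads=group.n_reads,
                    n_pcr_duplicates=group.n_pcr_duplicates,
                    splice_status=group.splice_status,
                    collapsed=False,
                )
            )
        return out

    first = reads[0]
    if len(reads) == 1:
        mol = CollapsedMolecule(
            barcode=group.barcode,
            umi=group.umi,
            gene_id=group.gene_id,
            contig=first.contig,
            strand=first.strand,
            blocks=list(first.blocks),
            seq=first.seq.copy(),
            qual=first.qual.copy(),
            depth=np.ones(len(first.seq), dtype=np.int32),
            n_source_reads=1,
            n_pcr_duplicates=group.n_pcr_duplicates,
            splice_status=group.splice_status,
        )
        return [mol]

    union = union_intervals([b for r in reads for b in r.blocks])
    # map reference position -> consensus column index
    starts = np.array([s for s, _ in union], dtype=np.int64)
    offsets = np.concatenate(
        [[0], np.cumsum([e - s for s, e in union])]
    ).astype(np.int64)
    n_cols = int(offsets[-1])

    counts = np.zeros((5, n_cols), dtype=np.int32)
    maxq = np.zeros((5, n_cols), dtype=np.int32)
    for r in reads:
        qoff = 0
        for s, e in r.blocks:
            ln = e - s
            seg = int(np.searchsorted(starts, s, side="right") - 1)
            cols = offsets[seg] + (s - starts[seg]) + np.arange(ln)
            bases = r.seq[qoff : qoff + ln]
            quals = r.qual[qoff : qoff + ln]
            np.add.at(counts, (bases, cols), 1)
            np.maximum.at(maxq, (bases, cols), quals)
            qoff += ln

    total = counts.sum(axis=0)
    modal = counts.argmax(axis=0)
    modal_count = counts[modal, np.arange(n_cols)]
    unique_modal = (counts == modal_count).sum(axis=0) == 1
    ok = (modal_count >= params.consensus_fraction * total) & (
        unique_modal | (modal_count == total)
    )
    seq = np.where(ok, modal, N_CODE).astype(np.uint8)
    qual = np.where(ok, maxq[modal, np.arange(n_cols)], N_QUALITY).astype(np.uint8)

    span_start, span_end = union[0][0], union[-1][1]
    internal = sorted(
        {
            p
            for r in reads
            for p in (r.start, r.end - 1)
            if span_start < p < span_end - 1
        }
    )
    mol = CollapsedMolecule(
        barcode=group.barcode,
        umi=group.umi,
        gene_id=group.gene_id,
        contig=first.contig,
        strand=first.strand,
        blocks=union,
        seq=seq,
        qual=qual,
        depth=total.astype(np.int32),
        n_source_reads=len(reads),
        n_pcr_duplicates=group.n_pcr_duplicates,
        internal_read_ends=internal,
        splice_status=group.splice_status,
    )
    return [mol]
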