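"""Directional UMI collapsing, PCR-duplicate counting, and per-barcode
quantification.

A UMI group is the set of countable reads sharing (cell barcode, gene,
corrected UMI); reads in a group are molecular duplicates of one mRNA
molecule and need not share a mapping position (fragmentation happens
after first-round amplification).  Reads that *do* share an identical
mapping position within a group are PCR duplicates.  UMI sequencing
errors are absorbed by the directional adjacency algorithm: an edge
a -> b exists when Hamming(a, b) == 1 and count(a) >= 2 * count(b) - 1,
and groups are the sets reachable from unabsorbed root UMIs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .alignproc import AlignedTag, ReadAnnotation


def hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > 1:
                return False
    return mism == 1


def directional_umi_collapse(umi_counts: dict[str, int]) -> list[list[str]]:
    """Partition UMIs of one (barcode, gene) into molecule groups.

    Returns a list of groups, each a list of UMIs with the representative
    (root) UMI first.  Roots are visited in descending read-count order
    (ties broken lexicographically for determinism); traversal follows
    directed edges a -> b with Hamming distance 1 and
    count(a) >= 2*count(b) - 1.
    """
    order = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
    # neighbor index: bucket UMIs by (position, base-removed) signature so
    # candidate Hamming-1 pairs are found without all-pairs scans
    buckets: dict[tuple[int, str], list[str]] = defaultdict(list)
    for u in umi_counts:
        for i in range(len(u)):
            buckets[(i, u[:i] + u[i + 1 :])].append(u)
    assigned: set[str] = set()
    groups: list[list[str]] = []
    for root in order:
        if root in assigned:
            continue
        group = [root]
        assigned.add(root)
        stack = [root]
        while stack:
            a = stack.pop()
            ca = umi_counts[a]
            cands: set[str] = set()
            for i in range(len(a)):
                cands.update(buckets[(i, a[:i] + a[i + 1 :])])
            for b in sorted(cands, key=lambda u: (-umi_counts[u], u)):
                if b in assigned or b == a:
                    continue
                if hamming1(a, b) and ca >= 2 * umi_counts[b] - 1:
                    assigned.add(b)
                    group.append(b)
                    stack.append(b)
        groups.append(group)
    return groups


@dataclass
class UMIGroup:
    """Reads sharing (barcode, gene, corrected UMI)."""

    barcode: str
    gene_id: str
    umi: str  # representative (root) UMI after directional collapse
    reads: list[AlignedTag] = field(default_factory=list)
    splice_status: str = "spliced"
    n_pcr_duplicates: int = 0
    n_unique_positions: int = 0

    @property
    def n_reads(self) -> int:
        return len(self.reads)


def count_pcr_duplicates(group: UMIGroup) -> tuple[int, int]:
    """Partition member reads by identical (contig, start, blocks, strand);
    duplicates are members beyond the first of each partition."""
    positions = {r.position_key() for r in group.reads}
    n_unique = len(positions)
    return n_unique, group.n_reads - n_unique


def assign_splice_status(group: UMIGroup) -> str:
    """Unspliced iff at least one member read is annotated intronic."""
    for r in group.reads:
        if r.annotation == ReadAnnotation.INTRONIC:
            return "unspliced"
    return "spliced"


def build_umi_groups(reads: list[AlignedTag]) -> list[UMIGroup]:
    """Group countable reads into molecules: directional UMI collapse per
    (barcode, gene), then PCR-duplicate counting and splice status."""
    by_bg: dict[tuple[str, str], dict[str, list[AlignedTag]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for r in reads:
        if r.annotation.countable:
            by_bg[(r.barcode, r.gene)][r.umi].append(r)
    groups: list[UMIGroup] = []
    for (bc, gene), umi_reads in by_bg.items():
        counts = {u: len(rs) for u, rs in umi_reads.items()}
        for members in directional_umi_collapse(counts):
            g = UMIGroup(barcode=bc, gene_id=gene, umi=members[0])
            for u in members:
                g.reads.extend(umi_reads[u])
            g.n_unique_positions, g.n_pcr_duplicates = count_pcr_duplicates(g)
            g.splice_status = assign_splice_status(g)
            groups.append(g)
    return groups


def resolve_umi_gene_conflicts(groups: list[UMIGroup]) -> list[UMIGroup]:
    """Within each barcode, a corrected UMI mapping to more than one gene
    keeps only the gene with the most supporting reads; ties discard all
    contenders (likely mapping errors)."""
    by_bu: dict[tuple[str, str], list[UMIGroup]] = defaultdict(list)
    for g in groups:
        by_bu[(g.barcode, g.umi)].append(g)
    kept: list[UMIGroup] = []
    for contenders in by_bu.values():
        if len(contenders) == 1:
            kept.append(contenders[0])
            continue
        best = max(c.n_reads for c in contenders)
        winners = [c for c in contenders if c.n_reads == best]
        if len(winners) == 1:
            kept.append(winners[0])
        # tie: all discarded
    return kept


@dataclass
class BarcodeMetrics:
    barcode: str
    annotation_counts: dict[str, int] = field(default_factory=dict)
    countable_reads: int = 0
    spliced_molecules: int = 0
    unspliced_molecules: int = 0
    saturation: float = float("nan")
    pcr_duplicate_rate: float = float("nan")
    corrected_read_fraction: float = float("nan")
    gene_list_counts: dict[str, int] = field(default_factory=dict)

    @property
    def molecules(self) -> int:
        return self.spliced_molecules + self.unspliced_molecules

    @property
    def defined(self) -> bool:
        return self.countable_reads > 0


def compute_barcode_metrics(
    reads_by_annotation: dict[str, int],
    groups: list[UMIGroup],
    n_corrected: int,
    n_total_reads: int,
    gene_lists: dict[str, set[str]] | None = None,
    barcode: str = "",
) -> BarcodeMetrics:
    """Per-barcode summary used by cell calling.

    Sequencing saturation is molecular duplicates over countable reads:
    (countable_reads - molecules) / countable_reads.  The PCR-duplicate
    rate shares that denominator.
    """
    m = BarcodeMetrics(barcode=barcode, annotation_counts=dict(reads_by_annotation))
    m.countable_reads = sum(g.n_reads for g in groups)
    m.spliced_molecules = sum(1 for g in groups if g.splice_status == "spliced")
    m.unspliced_molecules = sum(1 for g in groups if g.splice_status == "unspliced")
    if m.countable_reads > 0:
        m.saturation = (m.countable_reads - len(groups)) / m.countable_reads
        m.pcr_duplicate_rate = (
            sum(g.n_pcr_duplicates for g in groups) / m.countable_reads
        )
    if n_total_reads > 0:
        m.corrected_read_fraction = n_corrected / n_total_reads
    if gene_lists:
        for name, genes in gene_lists.items():
            m.gene_list_counts[name] = sum(1 for g in groups if g.gene_id in genes)
    return m


@dataclass
class CountMatrix:
    """Sparse spliced/unspliced molecule counts, barcodes x genes."""

    barcodes: list[str]
    genes: list[str]
    spliced: sparse.csr_matrix
    unspliced: sparse.csr_matrix


def build_count_matrix(
    groups: list[UMIGroup],
    barcodes: list[str] | None = None,
    genes: list[str] | None = None,
) -> CountMatrix:
    if barcodes is None:
        barcodes = sorted({g.barcode for g in groups})
    if genes is None:
        genes = sorted({g.gene_id for g in groups})
    b_idx = {b: i for i, b in enumerate(barcodes)}
    g_idx = {g: i for i, g in enumerate(genes)}
    rows_s, cols_s, rows_u, cols_u = [], [], [], []
    for g in groups:
        if g.barcode not in b_idx or g.gene_id not in g_idx:
            continue
        if g.splice_status == "spliced":
            rows_s.append(b_idx[g.barcode])
            cols_s.append(g_idx[g.gene_id])
        else:
            rows_u.append(b_idx[g.barcode])
            cols_u.append(g_idx[g.gene_id])
    shape = (len(barcodes), len(genes))
    spliced = sparse.coo_matrix(
        (np.ones(len(rows_s), dtype=np.int64), (rows_s, cols_s)), shape=shape
    ).tocsr()
    unspliced = sparse.coo_matrix(
        (np.ones(len(rows_u), dtype=np.int64), (rows_u, cols_u)), shape=shape
    ).tocsr()
    return CountMatrix(barcodes=barcodes, genes=genes, spliced=spliced, unspliced=unspliced)
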