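"""Alignment merging, trimming, and read-type classification.

Each mRNA tag is aligned both to the genome and to the full-length
transcript set; transcript alignments are projected back to genomic
coordinates upstream of this module.  Here the candidate alignments of a
tag are merged, score-filtered, trimmed at splice overhangs, and the tag
is classified by a six-type alignment schema collapsed into one read-level
annotation.  Only exonic and intronic reads are countable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .reference import ReferenceIndex

# score gates applied to every candidate alignment
MIN_ALIGN_SCORE = 45
SCORE_WINDOW = 3
# classification thresholds: exonic needs >25 bp exon overlap, intronic
# needs >5 bp intron overlap with no exon overlap
MIN_EXON_OVERLAP = 25
MIN_INTRON_OVERLAP = 5
# terminal blocks overhanging an annotated splice site by <= this many
# bases are soft-clipped back
MAX_SPLICE_OVERHANG = 5


class AlignmentType(Enum):
    UNMAPPED = "unmapped"
    ANTISENSE = "antisense"
    EXONIC = "exonic"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    AMBIGUOUS = "ambiguous"


class ReadAnnotation(Enum):
    MULTI_MAPPED = "multi_mapped"
    ANTISENSE = "antisense"
    AMBIGUOUS = "ambiguous"
    EXONIC = "exonic"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    UNMAPPED = "unmapped"

    @property
    def countable(self) -> bool:
        return self in (ReadAnnotation.EXONIC, ReadAnnotation.INTRONIC)


@dataclass
class CandidateAlignment:
    """One candidate placement of a tag.

    ``ops`` is a CIGAR-like list of (op, length) with op in "MIDNS"; M/D
    consume reference, M/I/S consume query, N is a reference skip.
    """

    contig: str
    start: int
    ops: list[tuple[str, int]]
    strand: str
    score: int
    source: str  # "genome" | "transcriptome"
    gene_hint: str | None = None  # gene of origin for transcriptome projections
    gene_hits: dict = field(default_factory=dict)

    def ref_blocks(self) -> list[tuple[int, int]]:
        """Maximal reference-consuming blocks (split at N skips)."""
        blocks = []
        pos = self.start
        cur = pos
        open_block = False
        for op, ln in self.ops:
            if op in "MD":
                if not open_block:
                    cur = pos
                    open_block = True
                pos += ln
            elif op == "N":
                if open_block:
                    blocks.append((cur, pos))
                    open_block = False
                pos += ln
        if open_block:
            blocks.append((cur, pos))
        return blocks

    @property
    def ref_end(self) -> int:
        return self.start + sum(ln for op, ln in self.ops if op in "MDN")

    def location_key(self) -> tuple:
        return (self.contig, self.start, tuple(self.ops), self.strand)


def trim_splice_overhang(
    aln: CandidateAlignment, index: ReferenceIndex, max_overhang: int = MAX_SPLICE_OVERHANG
) -> CandidateAlignment:
    """Soft-clip a terminal aligned block that extends past an annotated
    splice junction by at most ``max_overhang`` bases; both ends checked."""
    donors = index.donor_sites.get(aln.contig)
    acceptors = index.acceptor_sites.get(aln.contig)
    if donors is None and acceptors is None:
        return aln
    ops = list(aln.ops)
    start = aln.start
    blocks = aln.ref_blocks()
    if not blocks:
        return aln

    # right end: last block crossing an intron-start (donor) site
    bs, be = blocks[-1]
    if donors is not None and len(donors):
        i = np.searchsorted(donors, be, side="left") - 1
        if i >= 0:
            d = int(donors[i])
            if bs < d < be and be - d <= max_overhang:
                ops = _clip_right(ops, be - d)
    # left end: first block crossing an intron-end (acceptor) site
    bs, be = blocks[0]
    if acceptors is not None and len(acceptors):
        i = np.searchsorted(acceptors, bs, side="right")
        if i < len(acceptors):
            a = int(acceptors[i])
            if bs < a < be and a - bs <= max_overhang:
                ops, delta = _clip_left(ops, a - bs)
                start += delta
    if ops == list(aln.ops) and start == aln.start:
        return aln
    return replace(aln, start=start, ops=ops)


def _clip_right(ops: list[tuple[str, int]], n: int) -> list[tuple[str, int]]:
    """Convert the last n reference bases (must fall inside a terminal M)
    into a soft clip."""
    out = list(ops)
    tail_s = 0
    if out and out[-1][0] == "S":
        tail_s = out[-1][1]
        out.pop()
    if not out or out[-1][0] != "M" or out[-1][1] <= n:
        # do not trim across non-match ops
        if tail_s:
            out.append(("S", tail_s))
        return list(ops)
    out[-1] = ("M", out[-1][1] - n)
    out.append(("S", tail_s + n))
    return out


def _clip_left(ops: list[tuple[str, int]], n: int) -> tuple[list[tuple[str, int]], int]:
    out = list(ops)
    head_s = 0
    i = 0
    if out and out[0][0] == "S":
        head_s = out[0][1]
        out.pop(0)
    if not out or out[0][0] != "M" or out[0][1] <= n:
        return list(ops), 0
    out[0] = ("M", out[0][1] - n)
    out.insert(0, ("S", head_s + n))
    return out, n


def merge_and_filter(
    candidates: list[CandidateAlignment],
    min_score: int = MIN_ALIGN_SCORE,
    score_window: int = SCORE_WINDOW,
) -> list[CandidateAlignment]:
    """Drop candidates below the absolute score cutoff, then keep those
    within ``score_window`` of the best; duplicates by exact placement are
    merged first (transcriptome copy preferred).  Intergenic candidates
    participate fully so multi-mapping detection sees them."""
    seen: dict[tuple, CandidateAlignment] = {}
    for c in candidates:
        key = c.location_key()
        prev = seen.get(key)
        if prev is None or (prev.source == "genome" and c.source == "transcriptome"):
            seen[key] = c
    passing = [c for c in seen.values() if c.score >= min_score]
    if not passing:
        return []
    best = max(c.score for c in passing)
    return [c for c in passing if c.score >= best - score_window]


def classify_alignment(
    aln: CandidateAlignment, index: ReferenceIndex
) -> tuple[AlignmentType, str | None]:
    """Assign the per-alignment type.

    Transcriptome-sourced alignments are exonic by construction; genomic
    alignments are typed from their exon/intron overlap, requiring a
    single sense gene (two genes -> ambiguous, opposite strand only ->
    antisense, nothing -> intergenic)."""
    from .reference import annotate_overlap

    if aln.source == "transcriptome":
        return AlignmentType.EXONIC, aln.gene_hint
    hits = aln.gene_hits or annotate_overlap(
        aln.ref_blocks(), aln.contig, aln.strand, index
    )
    aln.gene_hits = hits
    sense = {
        g: d
        for g, d in hits.items()
        if not d["antisense"]
        and (d["exon"] > MIN_EXON_OVERLAP or d["intron"] > MIN_INTRON_OVERLAP)
    }
    if len(sense) > 1:
        return AlignmentType.AMBIGUOUS, None
    if len(sense) == 1:
        (g, d), = sense.items()
        if d["exon"] > MIN_EXON_OVERLAP:
            return AlignmentType.EXONIC, g
        if d["intron"] > MIN_INTRON_OVERLAP and d["exon"] == 0:
            return AlignmentType.INTRONIC, g
        return AlignmentType.INTERGENIC, None
    antisense = {
        g: d
        for g, d in hits.items()
        if d["antisense"]
        and (d["exon"] > MIN_EXON_OVERLAP or d["intron"] > MIN_INTRON_OVERLAP)
    }
    if antisense:
        return AlignmentType.ANTISENSE, None
    return AlignmentType.INTERGENIC, None


def _same_location(a: CandidateAlignment, b: CandidateAlignment) -> bool:
    """Two retained alignments count as one location when they share a
    contig and their reference spans overlap by >= 50% reciprocally."""
    if a.contig != b.contig:
        return False
    lo = max(a.start, b.start)
    hi = min(a.ref_end, b.ref_end)
    if hi <= lo:
        return False
    ov = hi - lo
    return ov * 2 >= (a.ref_end - a.start) and ov * 2 >= (b.ref_end - b.start)


def annotate_read(
    typed: list[tuple[CandidateAlignment, AlignmentType, str | None]],
) -> tuple[ReadAnnotation, str | None, CandidateAlignment | None]:
    """Collapse a tag's retained alignments into one read annotation.

    Returns (annotation, gene_id, chosen alignment); gene_id is set only
    for countable (exonic/intronic) reads."""
    if not typed:
        return ReadAnnotation.UNMAPPED, None, None
    # connected components under the same-location relation
    n = len(typed)
    comp = list(range(n))

    def find(i):
        while comp[i] != i:
            comp[i] = comp[comp[i]]
            i = comp[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _same_location(typed[i][0], typed[j][0]):
                comp[find(i)] = find(j)
    roots = {find(i) for i in range(n)}
    if len(roots) > 1:
        return ReadAnnotation.MULTI_MAPPED, None, None

    types = [t for _, t, _ in typed]
    if all(t == AlignmentType.ANTISENSE for t in types):
        return ReadAnnotation.ANTISENSE, None, None
    if all(t == AlignmentType.AMBIGUOUS for t in types):
        return ReadAnnotation.AMBIGUOUS, None, None
    exonic = [(a, g) for a, t, g in typed if t == AlignmentType.EXONIC]
    intronic = [(a, g) for a, t, g in typed if t == AlignmentType.INTRONIC]
    if exonic:
        genes = {g for _, g in exonic}
        if len(genes) > 1:
            return ReadAnnotation.AMBIGUOUS, None, None
        gene = next(iter(genes))
        if intronic and any(g == gene for _, g in intronic):
            # intronic and exonic alignment within the same gene
            return ReadAnnotation.AMBIGUOUS, None, None
        if intronic:
            return ReadAnnotation.AMBIGUOUS, None, None
        return ReadAnnotation.EXONIC, gene, exonic[0][0]
    if intronic:
        genes = {g for _, g in intronic}
        if len(genes) == 1 and len(intronic) == 1:
            return ReadAnnotation.INTRONIC, intronic[0][1], intronic[0][0]
        return ReadAnnotation.AMBIGUOUS, None, None
    if any(t == AlignmentType.INTERGENIC for t in types):
        return ReadAnnotation.INTERGENIC, None, typed[0][0]
    return ReadAnnotation.AMBIGUOUS, None, None


# ----------------------------------------------------------------------
# the resolved record downstream modules consume


_BASE2CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _BASE2CODE[_b] = _i
CODE2BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode A/C/G/T/N as 0..4 (uint8)."""
    return _BASE2CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    return CODE2BASE[codes].tobytes().decode()


@dataclass
class AlignedTag:
    """A countable read after QA, alignment, and classification.

    ``seq``/``qual`` cover exactly the aligned (reference-consuming match)
    bases, concatenated block by block; soft clips are already removed.
    """

    read_id: str
    barcode: str
    umi: str
    gene: str
    contig: str
    strand: str
    blocks: list[tuple[int, int]]
    seq: np.ndarray  # uint8 codes, 0..4
    qual: np.ndarray  # uint8 phred
    annotation: ReadAnnotation
    was_corrected: bool = False

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    def position_key(self) -> tuple:
        return (self.contig, self.start, tuple(self.blocks), self.strand)

    def skip_intervals(self) -> list[tuple[int, int]]:
        return [
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        ]
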