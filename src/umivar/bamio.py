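"""SAM/BAM round-tripping via pysam.

Tag conventions (10x-compatible where one exists):

* ``CB`` corrected barcode, ``CR`` raw barcode, ``UB`` UMI, ``GX`` gene,
  ``XT`` read-annotation code;
* collapsed records additionally carry ``NR`` (source reads), ``PD``
  (PCR duplicates), ``IE`` (internal read-end positions, integer array),
  ``XC`` (1 collapsed / 0 passthrough) and ``XS`` splice status.
"""

from __future__ import annotations

import numpy as np
import pysam

from .alignproc import AlignedTag, ReadAnnotation, codes_to_seq, seq_to_codes
from .collapse import CollapsedMolecule


def _blocks_to_cigar(blocks):
    cig = []
    prev = None
    for s, e in blocks:
        if prev is not None and s > prev:
            cig.append((3, s - prev))  # N
        cig.append((0, e - s))  # M
        prev = e
    return cig


def _cigar_to_blocks(start, cigartuples):
    blocks = []
    pos = start
    cur = pos
    open_block = False
    for op, ln in cigartuples:
        if op in (0, 2, 7, 8):  # M, D, =, X consume reference
            if not open_block:
                cur = pos
                open_block = True
            pos += ln
        elif op == 3:  # N
            if open_block:
                blocks.append((cur, pos))
                open_block = False
            pos += ln
    if open_block:
        blocks.append((cur, pos))
    return blocks


def _header(contig_lengths: dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": name, "LN": int(ln)}
                for name, ln in sorted(contig_lengths.items())
            ],
        }
    )


def write_tag_bam(tags: list[AlignedTag], contig_lengths: dict[str, int], path: str) -> None:
    """Coordinate-sorted BAM (or SAM, by extension) of classified tags."""
    header = _header(contig_lengths)
    mode = "w" if str(path).endswith(".sam") else "wb"
    ordered = sorted(tags, key=lambda t: (t.contig, t.start))
    with pysam.AlignmentFile(path, mode, header=header) as out:
        for t in ordered:
            a = pysam.AlignedSegment(header)
            a.query_name = t.read_id
            a.reference_name = t.contig
            a.reference_start = t.start
            a.cigartuples = _blocks_to_cigar(t.blocks)
            a.query_sequence = codes_to_seq(t.seq)
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in t.qual)
            )
            a.flag = 16 if t.strand == "-" else 0
            a.mapping_quality = 60
            a.set_tag("CB", t.barcode)
            a.set_tag("UB", t.umi)
            if t.gene:
                a.set_tag("GX", t.gene)
            a.set_tag("XT", t.annotation.value)
            out.write(a)


def read_tag_bam(path: str) -> list[AlignedTag]:
    tags = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            tags.append(
                AlignedTag(
                    read_id=a.query_name,
                    barcode=a.get_tag("CB"),
                    umi=a.get_tag("UB"),
                    gene=a.get_tag("GX") if a.has_tag("GX") else "",
                    contig=a.reference_name,
                    strand="-" if a.is_reverse else "+",
                    blocks=_cigar_to_blocks(a.reference_start, a.cigartuples),
                    seq=_aligned_seq_codes(a),
                    qual=_aligned_quals(a),
                    annotation=ReadAnnotation(a.get_tag("XT"))
                    if a.has_tag("XT")
                    else ReadAnnotation.EXONIC,
                )
            )
    return tags


def _aligned_seq_codes(a: pysam.AlignedSegment) -> np.ndarray:
    """Sequence codes over reference-consuming bases only (clips and
    insertions dropped, deletions filled with N)."""
    seq = a.query_sequence
    out = []
    qpos = 0
    for op, ln in a.cigartuples:
        if op in (0, 7, 8):
            out.append(seq[qpos : qpos + ln])
            qpos += ln
        elif op in (1, 4):  # I, S consume query only
            qpos += ln
        elif op == 2:  # D
            out.append("N" * ln)
    return seq_to_codes("".join(out))


def _aligned_quals(a: pysam.AlignedSegment) -> np.ndarray:
    quals = a.query_qualities
    out = []
    qpos = 0
    for op, ln in a.cigartuples:
        if op in (0, 7, 8):
            out.extend(quals[qpos : qpos + ln])
            qpos += ln
        elif op in (1, 4):
            qpos += ln
        elif op == 2:
            out.extend([0] * ln)
    return np.array(out, dtype=np.uint8)


def write_collapsed_bam(
    molecules: list[CollapsedMolecule], contig_lengths: dict[str, int], path: str
) -> None:
    header = _header(contig_lengths)
    mode = "w" if str(path).endswith(".sam") else "wb"
    ordered = sorted(molecules, key=lambda m: (m.contig, m.start))
    with pysam.AlignmentFile(path, mode, header=header) as out:
        for i, m in enumerate(ordered):
            a = pysam.AlignedSegment(header)
            a.query_name = f"{m.barcode}:{m.umi}:{i}"
            a.reference_name = m.contig
            a.reference_start = m.start
            a.cigartuples = _blocks_to_cigar(m.blocks)
            a.query_sequence = codes_to_seq(m.seq)
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(int(q) + 33) for q in m.qual)
            )
            a.flag = 16 if m.strand == "-" else 0
            a.mapping_quality = 60
            a.set_tag("CB", m.barcode)
            a.set_tag("UB", m.umi)
            a.set_tag("GX", m.gene_id)
            a.set_tag("NR", int(m.n_source_reads))
            a.set_tag("PD", int(m.n_pcr_duplicates))
            a.set_tag("XC", 1 if m.collapsed else 0)
            a.set_tag("XS", m.splice_status)
            if m.internal_read_ends:
                import array as _array

                a.set_tag("IE", _array.array("i", m.internal_read_ends))
            out.write(a)


def read_collapsed_bam(path: str) -> list[CollapsedMolecule]:
    mols = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            seq = _aligned_seq_codes(a)
            mols.append(
                CollapsedMolecule(
                    barcode=a.get_tag("CB"),
                    umi=a.get_tag("UB"),
                    gene_id=a.get_tag("GX") if a.has_tag("GX") else "",
                    contig=a.reference_name,
                    strand="-" if a.is_reverse else "+",
                    blocks=_cigar_to_blocks(a.reference_start, a.cigartuples),
                    seq=seq,
                    qual=_aligned_quals(a),
                    depth=np.ones(len(seq), dtype=np.int32),
                    n_source_reads=a.get_tag("NR") if a.has_tag("NR") else 1,
                    n_pcr_duplicates=a.get_tag("PD") if a.has_tag("PD") else 0,
                    internal_read_ends=list(map(int, a.get_tag("IE")))
                    if a.has_tag("IE")
                    else [],
                    splice_status=a.get_tag("XS") if a.has_tag("XS") else "spliced",
                    collapsed=bool(a.get_tag("XC")) if a.has_tag("XC") else True,
                )
            )
    return mols


def load_external_bam(
    path: str,
    unique_mapq: int = 255,
    barcode_tag: str = "CB",
    umi_tag: str = "UB",
    gene_tag: str = "GX",
) -> list[AlignedTag]:
    """Third-party (Cell Ranger / STARsolo style) dialect.

    Keeps uniquely mapped reads (mapping quality == ``unique_mapq``) with
    a single-gene annotation; duplicate-flagged reads are retained on
    purpose — dropping them discards most molecular evidence in these
    BAMs."""
    tags = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                continue
            if a.mapping_quality < unique_mapq:
                continue
            if not (a.has_tag(barcode_tag) and a.has_tag(umi_tag)):
                continue
            gene = a.get_tag(gene_tag) if a.has_tag(gene_tag) else ""
            if ";" in gene:  # multi-gene annotation
                continue
            tags.append(
                AlignedTag(
                    read_id=a.query_name,
                    barcode=a.get_tag(barcode_tag),
                    umi=a.get_tag(umi_tag),
                    gene=gene,
                    contig=a.reference_name,
                    strand="-" if a.is_reverse else "+",
                    blocks=_cigar_to_blocks(a.reference_start, a.cigartuples),
                    seq=_aligned_seq_codes(a),
                    qual=_aligned_quals(a),
                    annotation=ReadAnnotation.EXONIC,
                )
            )
    return tags
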