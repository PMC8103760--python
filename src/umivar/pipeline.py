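"""End-to-end driver chaining the pipeline stages.

The driver consumes gold (true-placement) alignments from the synthetic
generator or tag records loaded from BAM, and runs: barcode correction ->
score filtering and splice-overhang trimming -> read classification ->
directional UMI collapse -> consensus molecule collapse -> per-barcode
metrics and count matrices -> cell calling -> pileup and SNV calling.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .alignproc import (
    AlignedTag,
    CandidateAlignment,
    ReadAnnotation,
    annotate_read,
    classify_alignment,
    merge_and_filter,
    trim_splice_overhang,
)
from .cells import CellCallParams, CellCallResult, call_cells
from .collapse import CollapsedMolecule, ConsensusParams, collapse_group
from .pileup import (
    PileupSite,
    SNVCall,
    SNVFilterParams,
    annotate_call,
    call_snvs,
    pileup,
)
from .readqa import BarcodeCounter, correct_barcode
from .reference import ReferenceIndex
from .umidedup import (
    BarcodeMetrics,
    CountMatrix,
    UMIGroup,
    build_count_matrix,
    build_umi_groups,
    compute_barcode_metrics,
    resolve_umi_gene_conflicts,
)


@dataclass
class PipelineParams:
    consensus: ConsensusParams = field(default_factory=ConsensusParams)
    snv: SNVFilterParams = field(default_factory=SNVFilterParams)
    cell_call: CellCallParams = field(default_factory=CellCallParams)
    gene_lists: dict[str, set[str]] = field(default_factory=dict)
    trim_overhangs: bool = True


@dataclass
class PipelineResult:
    tags: list[AlignedTag]
    annotation_counts: Counter
    groups: list[UMIGroup]
    molecules: list[CollapsedMolecule]
    metrics: dict[str, BarcodeMetrics]
    matrix: CountMatrix
    cell_call: CellCallResult
    sites: list[PileupSite] = field(default_factory=list)
    calls: list[SNVCall] = field(default_factory=list)
    n_rejected_barcode: int = 0
    n_noncollapsible_groups: int = 0

    @property
    def cells(self) -> set[str]:
        return set(self.cell_call.passing)


def correct_read_barcodes(reads, whitelist: set[str], counter: BarcodeCounter):
    """Assign corrected barcodes to gold reads; drops uncorrectable ones.
    Returns (tag records, n_rejected)."""
    from .synth import gold_to_tag

    tags: list[AlignedTag] = []
    n_rej = 0
    for r in reads:
        corrected = correct_barcode(r.observed_barcode, whitelist, counter)
        if corrected is None:
            n_rej += 1
            continue
        tag = gold_to_tag(r, corrected_barcode=corrected)
        tag.was_corrected = corrected != r.observed_barcode
        tags.append(tag)
    return tags, n_rej


def classify_tags(
    tags: list[AlignedTag], index: ReferenceIndex, trim_overhangs: bool = True
) -> Counter:
    """Score-filter, trim, and classify every tag in place; returns the
    read-annotation tally.  Each tag here carries a single gold placement;
    reads loaded from multi-candidate sources should pass their candidate
    sets through :func:`classify_candidates` instead."""
    counts: Counter = Counter()
    for tag in tags:
        ops = _blocks_to_ops(tag.blocks)
        cand = CandidateAlignment(
            contig=tag.contig,
            start=tag.start,
            ops=ops,
            strand=tag.strand,
            score=sum(ln for op, ln in ops if op == "M"),
            source="genome",
        )
        annotation, gene = classify_candidates([cand], index, trim_overhangs)
        tag.annotation = annotation
        tag.gene = gene or ""
        counts[annotation] += 1
    return counts


def classify_candidates(
    candidates: list[CandidateAlignment],
    index: ReferenceIndex,
    trim_overhangs: bool = True,
) -> tuple[ReadAnnotation, str | None]:
    retained = merge_and_filter(candidates)
    if trim_overhangs:
        retained = [trim_splice_overhang(a, index) for a in retained]
    typed = []
    for a in retained:
        t, g = classify_alignment(a, index)
        typed.append((a, t, g))
    annotation, gene, _chosen = annotate_read(typed)
    return annotation, gene


def _blocks_to_ops(blocks: list[tuple[int, int]]) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    prev_end = None
    for s, e in blocks:
        if prev_end is not None and s > prev_end:
            ops.append(("N", s - prev_end))
        ops.append(("M", e - s))
        prev_end = e
    return ops


def run_pipeline(
    reads,
    index: ReferenceIndex,
    reference_codes: dict,
    whitelist: set[str],
    params: PipelineParams | None = None,
    annotations: dict | None = None,
) -> PipelineResult:
    """Run the full pipeline on gold reads.

    ``annotations`` may carry "edit_catalogue", "repeat_lookup",
    "common_snps", "germline_calls" for SNV annotation.
    """
    from .readqa import count_barcodes

    params = params or PipelineParams()
    counter = count_barcodes((r.observed_barcode for r in reads), whitelist)
    tags, n_rej = correct_read_barcodes(reads, whitelist, counter)
    annotation_counts = classify_tags(tags, index, params.trim_overhangs)

    groups = build_umi_groups(tags)
    groups = resolve_umi_gene_conflicts(groups)

    molecules: list[CollapsedMolecule] = []
    n_noncollapsible = 0
    for g in groups:
        out = collapse_group(g, params.consensus)
        if out and not out[0].collapsed:
            n_noncollapsible += 1
        molecules.extend(out)

    # per-barcode bookkeeping
    by_bc_groups: dict[str, list[UMIGroup]] = defaultdict(list)
    for g in groups:
        by_bc_groups[g.barcode].append(g)
    by_bc_ann: dict[str, Counter] = defaultdict(Counter)
    by_bc_corrected: dict[str, int] = defaultdict(int)
    by_bc_total: dict[str, int] = defaultdict(int)
    for t in tags:
        by_bc_ann[t.barcode][t.annotation.value] += 1
        by_bc_total[t.barcode] += 1
        if t.was_corrected:
            by_bc_corrected[t.barcode] += 1
    metrics = {
        bc: compute_barcode_metrics(
            by_bc_ann[bc],
            by_bc_groups.get(bc, []),
            by_bc_corrected[bc],
            by_bc_total[bc],
            gene_lists=params.gene_lists,
            barcode=bc,
        )
        for bc in by_bc_total
    }

    matrix = build_count_matrix(groups)
    cell_result = call_cells(metrics, params.cell_call)
    cells = set(cell_result.passing)

    sites = pileup(molecules, reference_codes, cells, params.snv, dialect="collapsed")
    calls = call_snvs(sites, params.snv)
    ann = annotations or {}
    for c in calls:
        annotate_call(
            c,
            edit_catalogue=ann.get("edit_catalogue"),
            repeat_lookup=ann.get("repeat_lookup"),
            common_snps=ann.get("common_snps"),
            germline_calls=ann.get("germline_calls"),
            params=params.snv,
        )
    return PipelineResult(
        tags=tags,
        annotation_counts=annotation_counts,
        groups=groups,
        molecules=molecules,
        metrics=metrics,
        matrix=matrix,
        cell_call=cell_result,
        sites=sites,
        calls=calls,
        n_rejected_barcode=n_rej,
        n_noncollapsible_groups=n_noncollapsible,
    )
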