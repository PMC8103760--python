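"""Accuracy benchmarking against matched DNA evidence, and reference
modification for homozygous-SNV simulation.

Single-cell RNA calls are labelled against DNA pileup evidence: a site
counts as present in DNA when it carries at least 2 alternative bases
(mapping and base quality >= 20); TP/FP/FN follow from that together
with coverage gates on both the scRNA (>= 1X counted bases) and DNA
(>= 15X) side.  Per-cell accuracy distinguishes two false-negative
notions: FN[bulk] counts truth sites a cell shows only reference counts
or no coverage for, FN[cell] only those the cell actually covers.

The homozygous-SNV simulator substitutes reference bases at positions
with adequate expression coverage and at least 10 bp away from every
pre-existing call, writes the modified FASTA plus a truth VCF, and a
re-run of the pipeline against the modified genome measures per-cell
recovery of variants that must be present on every molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pileup import SNVCall


@dataclass
class DNAEvidence:
    """Per-site DNA pileup evidence (filters applied upstream)."""

    coverage: dict[tuple[str, int], int] = field(default_factory=dict)
    alt_counts: dict[tuple[str, int, str], int] = field(default_factory=dict)
    called: set[tuple[str, int, str]] = field(default_factory=set)  # DNA caller VCF

    MIN_DNA_COVERAGE = 15
    MIN_DNA_ALT = 2

    def dna_present(self, contig: str, pos: int, alt: str) -> bool:
        return self.alt_counts.get((contig, pos, alt), 0) >= self.MIN_DNA_ALT

    def dna_called(self, contig: str, pos: int, alt: str) -> bool:
        """Called in DNA: the caller's VCF when provided, else the
        >= 2-alt-read evidence rule."""
        if self.called:
            return (contig, pos, alt) in self.called
        return self.dna_present(contig, pos, alt)


@dataclass
class BulkAccuracy:
    n_tp: int
    n_fp: int
    n_fn: int

    @property
    def tpr(self) -> float:
        d = self.n_tp + self.n_fn
        return self.n_tp / d if d else float("nan")

    @property
    def fdr(self) -> float:
        d = self.n_tp + self.n_fp
        return self.n_fp / d if d else 0.0

    @property
    def f1(self) -> float:
        d = 2 * self.n_tp + self.n_fp + self.n_fn
        return 2 * self.n_tp / d if d else float("nan")


def label_sites(
    calls: list[SNVCall],
    dna: DNAEvidence,
    dsc_coverage: dict[str, np.ndarray],
    dsc_barcode_coverage: dict[tuple[str, int], int] | None = None,
    capture_intervals=None,
    capture_flank: int = 100,
) -> dict[tuple[str, int, str], str]:
    """Label each comparable site TP / FP / FN.

    Sites must have >= 1X counted scRNA coverage and >= 15X DNA coverage
    to enter the comparison; with exome evidence, ``capture_intervals``
    (contig -> intervaltree) restricts to capture regions +- flank.
    FN additionally requires at least 5 cell barcodes covering the
    position (``dsc_barcode_coverage``: (contig, pos) -> n barcodes).
    """

    def in_scope(contig: str, pos: int) -> bool:
        track = dsc_coverage.get(contig)
        if track is None or pos >= len(track) or track[pos] < 1:
            return False
        if dna.coverage.get((contig, pos), 0) < DNAEvidence.MIN_DNA_COVERAGE:
            return False
        if capture_intervals is not None:
            tree = capture_intervals.get(contig)
            if tree is None or not tree.overlaps(pos - capture_flank, pos + capture_flank + 1):
                return False
        return True

    labels: dict[tuple[str, int, str], str] = {}
    called_keys = set()
    for c in calls:
        if not in_scope(c.contig, c.pos):
            continue
        called_keys.add(c.key)
        if dna.dna_present(c.contig, c.pos, c.alt):
            labels[c.key] = "TP"
        else:
            labels[c.key] = "FP"
    # FN: present in DNA, in scope, not called, enough cells covering
    dna_truth = dna.called if dna.called else {
        k for k, n in dna.alt_counts.items() if n >= DNAEvidence.MIN_DNA_ALT
    }
    for contig, pos, alt in dna_truth:
        key = (contig, pos, alt)
        if key in called_keys or not in_scope(contig, pos):
            continue
        if dna.called and not dna.dna_present(contig, pos, alt):
            continue
        n_bc = (dsc_barcode_coverage or {}).get((contig, pos), 0)
        if n_bc >= 5:
            labels[key] = "FN"
    return labels


def bulk_accuracy(labels: dict[tuple, str]) -> BulkAccuracy:
    vals = list(labels.values())
    return BulkAccuracy(
        n_tp=vals.count("TP"), n_fp=vals.count("FP"), n_fn=vals.count("FN")
    )


def maf_sweep(
    calls: list[SNVCall],
    dna: DNAEvidence,
    dsc_coverage: dict[str, np.ndarray],
    cutoffs,
    **kwargs,
) -> dict[float, BulkAccuracy]:
    """Bulk accuracy at a series of MAF cutoffs (strictly-greater)."""
    out = {}
    for cutoff in cutoffs:
        subset = [c for c in calls if c.maf > cutoff]
        out[float(cutoff)] = bulk_accuracy(
            label_sites(subset, dna, dsc_coverage, **kwargs)
        )
    return out


@dataclass
class CellAccuracy:
    barcode: str
    n_tp: int
    fn_bulk: int
    fn_cell: int
    n_called_nontruth: int = 0
    n_ag_edits: int = 0

    @property
    def tpr_bulk(self) -> float:
        d = self.n_tp + self.fn_bulk
        return self.n_tp / d if d else float("nan")

    @property
    def tpr_cell(self) -> float:
        d = self.n_tp + self.fn_cell
        return self.n_tp / d if d else float("nan")

    @property
    def fdr(self) -> float:
        d = self.n_tp + self.n_called_nontruth
        return self.n_called_nontruth / d if d else float("nan")


def per_cell_accuracy(
    per_cell_counts: dict[tuple[str, int, str], dict[str, list[int]]],
    truth_sites: set[tuple[str, int, str]],
    cells: set[str],
    calls: list[SNVCall] | None = None,
) -> dict[str, CellAccuracy]:
    """Per-cell TP / FN[bulk] / FN[cell] over truth sites.

    TP: >= 1 alt molecule at the site; FN[bulk]: only reference counts or
    no coverage at all; FN[cell]: covered (>= 1 counted base) but zero
    alt.  FDR uses called-and-expressed non-truth sites when calls are
    supplied.  A>G edit molecules per cell are tallied from annotated
    calls.
    """
    out: dict[str, CellAccuracy] = {
        bc: CellAccuracy(barcode=bc, n_tp=0, fn_bulk=0, fn_cell=0) for bc in cells
    }
    for key in truth_sites:
        counts = per_cell_counts.get(key, {})
        for bc, acc in out.items():
            c = counts.get(bc)
            n_ref = (c[0] + c[2]) if c else 0
            n_alt = (c[1] + c[3]) if c else 0
            if n_alt >= 1:
                acc.n_tp += 1
            else:
                acc.fn_bulk += 1
                if n_ref >= 1:
                    acc.fn_cell += 1
    if calls:
        for c in calls:
            is_truth = c.key in truth_sites
            for bc, (n_ref, n_alt) in c.per_cell.items():
                if bc not in out or n_alt < 1:
                    continue
                if not is_truth:
                    out[bc].n_called_nontruth += 1
                if c.flags.get("AG_edit"):
                    out[bc].n_ag_edits += 1
    return out


# ----------------------------------------------------------------------
# homozygous-SNV simulation by reference substitution


@dataclass
class SimTruth:
    """Planted homozygous substitutions: (contig, pos0, ref, alt)."""

    sites: list[tuple[str, int, str, str]]

    def keys(self) -> set[tuple[str, int, str]]:
        return {(c, p, a) for c, p, _r, a in self.sites}


_BASES = "ACGT"


def simulate_homozygous_snvs(
    reference: dict[str, str],
    coverage: dict[str, np.ndarray],
    exclusion_calls: list[tuple[str, int]],
    n: int = 25000,
    min_distance: int = 10,
    min_coverage: int = 5,
    seed: int = 0,
) -> tuple[dict[str, str], SimTruth]:
    """Plant ``n`` homozygous SNVs in the reference.

    Eligible positions have coverage >= ``min_coverage`` and are at least
    ``min_distance`` bp away from every exclusion call; sampling is
    uniform without replacement and deterministic under ``seed``; the
    planted base is drawn uniformly among the three non-reference bases.
    Returns (modified reference, truth).
    """
    rng = np.random.default_rng(seed)
    excl: dict[str, list[int]] = {}
    for contig, pos in exclusion_calls:
        excl.setdefault(contig, []).append(pos)

    eligible: list[tuple[str, int]] = []
    for contig in sorted(reference):
        cov = coverage.get(contig)
        if cov is None:
            continue
        ok = cov >= min_coverage
        ex = np.array(sorted(excl.get(contig, [])), dtype=np.int64)
        if len(ex):
            mask = np.ones(len(cov), dtype=bool)
            for pos in ex:
                lo = max(0, pos - (min_distance - 1))
                hi = min(len(cov), pos + min_distance)
                mask[lo:hi] = False
            ok &= mask
        # never plant on an ambiguous reference base
        seq = reference[contig]
        for pos in np.flatnonzero(ok):
            if seq[int(pos)] in _BASES:
                eligible.append((contig, int(pos)))
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} eligible positions available, need {n}"
        )
    idx = rng.choice(len(eligible), size=n, replace=False)
    chosen = sorted(eligible[i] for i in idx)
    modified = {c: list(s) for c, s in reference.items()}
    sites = []
    for contig, pos in chosen:
        ref_b = reference[contig][pos]
        alts = [b for b in _BASES if b != ref_b]
        alt_b = alts[int(rng.integers(0, 3))]
        modified[contig][pos] = alt_b
        sites.append((contig, pos, ref_b, alt_b))
    return {c: "".join(s) for c, s in modified.items()}, SimTruth(sites=sites)


def sim_truth_labels(
    per_cell_counts: dict[tuple[str, int, str], dict[str, list[int]]],
    coverage_modified: dict[str, np.ndarray],
    coverage_unmodified: dict[str, np.ndarray],
    truth: SimTruth,
    cells: set[str],
    per_cell_coverage: dict[tuple[str, int], dict[str, int]] | None = None,
) -> dict[str, dict[str, int]]:
    """Per-cell TP/FN for simulated homozygous SNVs.

    TP: the cell expresses >= 1 alternative molecule at the site.  FN:
    zero alt but the locus has detectable coverage in the modified-genome
    alignment or the original unmodified one (soft-clipping near planted
    variants can hide coverage in the modified run only).  Pass
    ``per_cell_coverage`` ((contig,pos) -> barcode -> depth) to resolve
    coverage per cell; otherwise the bulk tracks gate FN calls.
    """
    out = {bc: {"tp": 0, "fn": 0} for bc in cells}
    for contig, pos, _ref, alt in truth.sites:
        key = (contig, pos, alt)
        counts = per_cell_counts.get(key, {})
        cov_mod = coverage_modified.get(contig)
        cov_orig = coverage_unmodified.get(contig)
        bulk_covered = bool(
            (cov_mod is not None and pos < len(cov_mod) and cov_mod[pos] > 0)
            or (cov_orig is not None and pos < len(cov_orig) and cov_orig[pos] > 0)
        )
        for bc in cells:
            c = counts.get(bc)
            n_alt = (c[1] + c[3]) if c else 0
            n_ref = (c[0] + c[2]) if c else 0
            if n_alt >= 1:
                out[bc]["tp"] += 1
            else:
                if per_cell_coverage is not None:
                    covered = per_cell_coverage.get((contig, pos), {}).get(bc, 0) > 0
                else:
                    covered = (n_ref > 0) or bulk_covered
                if covered:
                    out[bc]["fn"] += 1
    return out
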