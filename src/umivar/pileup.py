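"""Strand- and barcode-aware pileup, SNV calling, annotation, and
single-molecule co-expression extraction.

The pileup walks collapsed molecules (one count per molecule) or raw
aligned tags (one count per read) and tallies, at every mismatched
position, per-strand and per-cell-barcode allele counts restricted to
bases with quality >= 20.  Droplet 3' libraries are strand-specific, so
the strand of the supporting molecules both identifies the transcribed
strand of a variant and orients A>G RNA-edit annotation.

Candidate SNVs pass when covered by at least 5 unique cell barcodes, at
least 2 barcodes support the alternative allele, the minor allele
fraction (alt bases / total bases over all cells) reaches 0.01, and at
least one supporting mismatch sits strictly outside the first and last
5 bases of its read — where, for collapsed molecules, the ends of the
source reads *internal* to the molecule count as read ends too, since a
mis-spliced member read can plant false mismatches at its own ends.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .alignproc import CODE2BASE, seq_to_codes

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G


@dataclass
class SNVFilterParams:
    min_base_quality: int = 20
    min_barcodes: int = 5
    min_alt_barcodes: int = 2
    min_maf: float = 0.01
    end_exclusion: int = 5
    af_cutoff: float = 0.25
    strand_fraction: float = 0.90
    biallelic_fraction: float = 0.95

    def __post_init__(self):
        if self.min_alt_barcodes > self.min_barcodes:
            raise ValueError("min_alt_barcodes must be <= min_barcodes")
        if not (0 <= self.min_maf <= self.af_cutoff <= 1):
            raise ValueError("need 0 <= min_maf <= af_cutoff <= 1")


@dataclass
class PileupSite:
    """Per-position allele evidence across cell barcodes."""

    contig: str
    pos: int
    ref_code: int
    base_counts: np.ndarray  # (5,) counted bases by code, both strands
    strand_counts: np.ndarray  # (2,) covering units by strand (+, -)
    barcode_counts: dict[str, np.ndarray]  # barcode -> (5,) counts
    max_end_distance: dict[int, int] = field(default_factory=dict)  # alt code -> bp

    @property
    def ref_base(self) -> str:
        return chr(CODE2BASE[self.ref_code])

    @property
    def n_barcodes_covered(self) -> int:
        return len(self.barcode_counts)

    def n_barcodes_alt(self, alt_code: int) -> int:
        return sum(1 for c in self.barcode_counts.values() if c[alt_code] > 0)


@dataclass
class SNVCall:
    contig: str
    pos: int
    ref: str
    alt: str
    maf: float
    n_barcodes: int
    n_alt_barcodes: int
    total_bases: int
    ref_bases: int
    alt_bases: int
    strand_counts: tuple[int, int]
    max_end_distance: int
    per_cell: dict[str, tuple[int, int]]  # barcode -> (ref, alt) counted bases
    inferred_strand: str = "unknown"
    biallelic_ok: bool = True
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.pos, self.alt)

    @property
    def primary_class(self) -> str:
        """Annotation class used for co-expression typing: matched-DNA or
        common-SNP evidence marks a germline variant, else A>G edit, else
        unknown."""
        if self.flags.get("germline"):
            return "germline"
        if self.flags.get("AG_edit"):
            return "AG_edit"
        if self.flags.get("thousand_genomes"):
            return "germline"
        return "unknown"


def load_reference_codes(fasta) -> dict[str, np.ndarray]:
    """Encode a pyfaidx.Fasta (or {name: str} mapping) as uint8 code arrays."""
    out = {}
    items = fasta.items() if isinstance(fasta, dict) else ((k, str(fasta[k])) for k in fasta.keys())
    for name, seq in items:
        out[name] = seq_to_codes(str(seq).upper())
    return out


def _record_ends(rec) -> list[int]:
    ends = [rec.start, rec.end - 1]
    ends.extend(getattr(rec, "internal_read_ends", ()) or ())
    return ends


def pileup(
    records,
    reference: dict[str, np.ndarray],
    cells: set[str] | None,
    params: SNVFilterParams | None = None,
    dialect: str = "collapsed",
) -> list[PileupSite]:
    """Build pileup sites at every position carrying a counted mismatch.

    ``records`` are collapsed molecules (dialect "collapsed") or aligned
    tags (dialect "tags"/"external"); each record contributes one count.
    Only barcodes in ``cells`` are counted when a cell set is given.
    """
    params = params or SNVFilterParams()
    if dialect not in ("collapsed", "tags", "external"):
        raise ValueError(f"unknown pileup dialect {dialect!r}")
    minq = params.min_base_quality

    by_contig: dict[str, list] = defaultdict(list)
    for r in records:
        if cells is not None and r.barcode not in cells:
            continue
        by_contig[r.contig].append(r)

    sites: list[PileupSite] = []
    for contig, recs in sorted(by_contig.items()):
        ref = reference[contig]
        # candidate positions: any counted mismatch to a real base
        candidates: set[int] = set()
        for r in recs:
            qoff = 0
            for s, e in r.blocks:
                ln = e - s
                bases = r.seq[qoff : qoff + ln]
                quals = r.qual[qoff : qoff + ln]
                mism = (bases != ref[s:e]) & (bases < 4) & (quals >= minq)
                if mism.any():
                    candidates.update((s + np.flatnonzero(mism)).tolist())
                qoff += ln
        if not candidates:
            continue
        # block interval arrays for covering-record queries
        bstarts, bends, brec, bqoff = [], [], [], []
        for ri, r in enumerate(recs):
            qoff = 0
            for s, e in r.blocks:
                bstarts.append(s)
                bends.append(e)
                brec.append(ri)
                bqoff.append(qoff)
                qoff += e - s
        bstarts = np.array(bstarts, dtype=np.int64)
        bends = np.array(bends, dtype=np.int64)
        brec = np.array(brec, dtype=np.int64)
        bqoff = np.array(bqoff, dtype=np.int64)

        for pos in sorted(candidates):
            cover = np.flatnonzero((bstarts <= pos) & (bends > pos))
            base_counts = np.zeros(5, dtype=np.int64)
            strand_counts = np.zeros(2, dtype=np.int64)
            bc_counts: dict[str, np.ndarray] = {}
            max_end: dict[int, int] = {}
            ref_code = int(ref[pos])
            for bi in cover:
                r = recs[brec[bi]]
                off = int(bqoff[bi] + (pos - bstarts[bi]))
                base = int(r.seq[off])
                if base >= 4 or r.qual[off] < minq:
                    continue
                base_counts[base] += 1
                strand_counts[0 if r.strand == "+" else 1] += 1
                arr = bc_counts.get(r.barcode)
                if arr is None:
                    arr = np.zeros(5, dtype=np.int64)
                    bc_counts[r.barcode] = arr
                arr[base] += 1
                if base != ref_code:
                    d = min(abs(pos - e) for e in _record_ends(r))
                    if d > max_end.get(base, -1):
                        max_end[base] = d
            if not bc_counts:
                continue
            sites.append(
                PileupSite(
                    contig=contig,
                    pos=pos,
                    ref_code=ref_code,
                    base_counts=base_counts,
                    strand_counts=strand_counts,
                    barcode_counts=bc_counts,
                    max_end_distance=max_end,
                )
            )
    return sites


def call_snvs(sites: list[PileupSite], params: SNVFilterParams | None = None) -> list[SNVCall]:
    """Apply the SNV filters to pileup sites; one call per alt allele."""
    params = params or SNVFilterParams()
    calls: list[SNVCall] = []
    for site in sites:
        total = int(site.base_counts.sum())
        if total == 0:
            continue
        for alt_code in range(4):
            if alt_code == site.ref_code or site.base_counts[alt_code] == 0:
                continue
            n_cov = site.n_barcodes_covered
            n_alt = site.n_barcodes_alt(alt_code)
            maf = site.base_counts[alt_code] / total
            end_d = site.max_end_distance.get(alt_code, -1)
            if (
                n_cov >= params.min_barcodes
                and n_alt >= params.min_alt_barcodes
                and maf >= params.min_maf
                and end_d >= params.end_exclusion
            ):
                per_cell = {
                    bc: (int(c[site.ref_code]), int(c[alt_code]))
                    for bc, c in site.barcode_counts.items()
                }
                calls.append(
                    SNVCall(
                        contig=site.contig,
                        pos=site.pos,
                        ref=site.ref_base,
                        alt=chr(CODE2BASE[alt_code]),
                        maf=float(maf),
                        n_barcodes=n_cov,
                        n_alt_barcodes=n_alt,
                        total_bases=total,
                        ref_bases=int(site.base_counts[site.ref_code]),
                        alt_bases=int(site.base_counts[alt_code]),
                        strand_counts=(int(site.strand_counts[0]), int(site.strand_counts[1])),
                        max_end_distance=int(end_d),
                        per_cell=per_cell,
                    )
                )
    return calls


def apply_af_cutoff(calls: list[SNVCall], cutoff: float = 0.25) -> list[SNVCall]:
    """Strictly-greater allele-fraction cutoff, meant for germline-focused
    analyses (edit discovery should not use it)."""
    return [c for c in calls if c.maf > cutoff]


def refine_biallelic(call: SNVCall, fraction: float = 0.95) -> bool:
    """Site is effectively bi-allelic when ref+alt bases make up at least
    ``fraction`` of all counted bases."""
    if call.total_bases == 0:
        return False
    return (call.ref_bases + call.alt_bases) / call.total_bases >= fraction


def infer_strand(call: SNVCall, fraction: float = 0.90) -> str:
    plus, minus = call.strand_counts
    total = plus + minus
    if total == 0:
        return "unknown"
    if plus / total >= fraction:
        return "+"
    if minus / total >= fraction:
        return "-"
    return "unknown"


_COMP_BASE = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def annotate_call(
    call: SNVCall,
    edit_catalogue: set[tuple[str, int]] | None = None,
    repeat_lookup=None,
    common_snps: dict[tuple[str, int], set[str]] | None = None,
    germline_calls: dict[tuple[str, int], set[str]] | None = None,
    params: SNVFilterParams | None = None,
) -> SNVCall:
    """Bi-allelic/strand refinement plus annotation flags.

    A call is a potential A-to-I RNA edit iff its strand-oriented change
    is A>G *and* it is either in the edit catalogue or inside an
    (Alu-like) repeat interval.  ``repeat_lookup`` maps contig to an
    intervaltree-style object answering ``overlaps(pos)``.
    """
    params = params or SNVFilterParams()
    call.biallelic_ok = refine_biallelic(call, params.biallelic_fraction)
    call.inferred_strand = infer_strand(call, params.strand_fraction)

    if call.inferred_strand == "-":
        oriented = (_COMP_BASE[call.ref], _COMP_BASE[call.alt])
    else:
        oriented = (call.ref, call.alt)
    is_ag = call.inferred_strand != "unknown" and oriented == ("A", "G")
    in_catalogue = bool(edit_catalogue) and (call.contig, call.pos) in edit_catalogue
    in_repeat = False
    if repeat_lookup is not None:
        tree = repeat_lookup.get(call.contig)
        in_repeat = tree is not None and bool(tree.overlaps(call.pos))
    call.flags["AG_edit"] = is_ag and (in_catalogue or in_repeat)
    call.flags["thousand_genomes"] = bool(common_snps) and call.alt in common_snps.get(
        (call.contig, call.pos), set()
    )
    call.flags["germline"] = bool(germline_calls) and call.alt in germline_calls.get(
        (call.contig, call.pos), set()
    )
    return call


def quantify_known(
    records,
    known_sites: list[tuple[str, int, str, str]],
    reference: dict[str, np.ndarray],
    cells: set[str] | None = None,
    min_base_quality: int = 20,
) -> dict[tuple[str, int, str], dict[str, list[int]]]:
    """Unfiltered per-barcode, per-strand ref/alt counts at known sites.

    ``known_sites`` are (contig, pos0, ref, alt).  Returns, per site, a
    sparse mapping barcode -> [ref+, alt+, ref-, alt-]; uncovered
    barcodes are absent, uncovered sites map to empty dicts.
    """
    by_contig: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
    for i, (contig, pos, ref, alt) in enumerate(known_sites):
        by_contig[contig].append((pos, i, 0))
    out: dict[tuple[str, int, str], dict[str, list[int]]] = {
        (c, p, a): {} for c, p, r, a in known_sites
    }
    site_info: dict[tuple[str, int], list] = defaultdict(list)
    for c, p, r, a in known_sites:
        site_info[(c, p)].append((r, a, (c, p, a)))
    recs_by_contig: dict[str, list] = defaultdict(list)
    for r in records:
        if cells is not None and r.barcode not in cells:
            continue
        recs_by_contig[r.contig].append(r)
    for contig, site_list in by_contig.items():
        positions = np.array(sorted(p for p, _i, _ in site_list), dtype=np.int64)
        for r in recs_by_contig.get(contig, []):
            qoff = 0
            for s, e in r.blocks:
                lo = int(np.searchsorted(positions, s, side="left"))
                hi = int(np.searchsorted(positions, e, side="left"))
                for pos in positions[lo:hi]:
                    pos = int(pos)
                    off = qoff + (pos - s)
                    if r.qual[off] < min_base_quality:
                        continue
                    base = chr(CODE2BASE[int(r.seq[off])])
                    col = 0 if r.strand == "+" else 2
                    for ref_b, alt_b, key in site_info[(contig, pos)]:
                        d = out[key].setdefault(r.barcode, [0, 0, 0, 0])
                        if base == alt_b:
                            d[col + 1] += 1
                        elif base == ref_b:
                            d[col] += 1
                qoff += e - s
    return out


def coverage_track(
    records,
    reference: dict[str, np.ndarray],
    cells: set[str] | None = None,
    min_base_quality: int = 20,
) -> dict[str, np.ndarray]:
    """Per-contig coverage of counted bases (quality >= threshold)."""
    tracks = {c: np.zeros(len(seq), dtype=np.int32) for c, seq in reference.items()}
    for r in records:
        if cells is not None and r.barcode not in cells:
            continue
        track = tracks[r.contig]
        qoff = 0
        for s, e in r.blocks:
            ln = e - s
            ok = r.qual[qoff : qoff + ln] >= min_base_quality
            if ok.all():
                track[s:e] += 1
            else:
                track[s:e][ok] += 1
            qoff += ln
    return tracks


@dataclass
class CoexpressionSet:
    """A unique set of called SNVs observed together on single molecules."""

    snvs: frozenset  # of (contig, pos, alt)
    n_molecules: int
    type_counts: dict[str, int]
    dominant_type: str | None
    purity: float


def extract_coexpression(
    records,
    calls: list[SNVCall],
    min_snvs: int = 5,
    min_base_quality: int = 20,
) -> list[CoexpressionSet]:
    """Per-molecule sets of co-expressed called SNVs.

    For each record the set of called alt alleles it carries (counted
    bases only) is collected; unique sets with at least ``min_snvs``
    variants are kept.  A set's dominant annotation class is assigned
    only when one class holds more than half of its SNVs."""
    call_by_site: dict[tuple[str, int], list[SNVCall]] = defaultdict(list)
    for c in calls:
        call_by_site[(c.contig, c.pos)].append(c)
    pos_by_contig = {
        contig: np.array(sorted({p for c2, p in call_by_site if c2 == contig}), dtype=np.int64)
        for contig in {c.contig for c in calls}
    }
    sets: dict[frozenset, int] = defaultdict(int)
    for r in records:
        positions = pos_by_contig.get(r.contig)
        if positions is None or not len(positions):
            continue
        carried = set()
        qoff = 0
        for s, e in r.blocks:
            lo = int(np.searchsorted(positions, s, side="left"))
            hi = int(np.searchsorted(positions, e, side="left"))
            for pos in positions[lo:hi]:
                pos = int(pos)
                off = qoff + (pos - s)
                if r.qual[off] < min_base_quality:
                    continue
                base = chr(CODE2BASE[int(r.seq[off])])
                for c in call_by_site[(r.contig, pos)]:
                    if base == c.alt:
                        carried.add(c.key)
            qoff += e - s
        if len(carried) >= min_snvs:
            sets[frozenset(carried)] += 1

    class_of = {c.key: c.primary_class for c in calls}
    out = []
    for snvs, n_mol in sets.items():
        counts: dict[str, int] = defaultdict(int)
        for key in snvs:
            counts[class_of[key]] += 1
        total = len(snvs)
        dominant, dom_n = None, 0
        for cls, n in sorted(counts.items()):
            if n > dom_n:
                dominant, dom_n = cls, n
        if dom_n * 2 <= total:
            dominant = None
        out.append(
            CoexpressionSet(
                snvs=snvs,
                n_molecules=n_mol,
                type_counts=dict(counts),
                dominant_type=dominant,
                purity=dom_n / total if dominant else max(counts.values()) / total,
            )
        )
    out.sort(key=lambda s: (-len(s.snvs), sorted(s.snvs)))
    return out
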