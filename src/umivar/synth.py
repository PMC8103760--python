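"""Deterministic synthetic droplet scRNA-seq data.

The generator builds a toy genome with multi-exon genes on both strands
(including antisense-overlapping pairs, excluded-biotype transcripts and
Alu-like repeat annotations), then emulates a 3' droplet library:

* each cell barcode receives a Poisson number of molecules, assigned to
  genes by a lognormal expression profile;
* a molecule carries one UMI and 1..8 distinct fragment positions
  (molecular/UMI duplicates — fragmentation happens after first-round
  amplification, so duplicates differ in mapping position), with a
  truncated-exponential 3' bias;
* second-round PCR adds copies at identical positions (PCR duplicates);
* germline hom/het SNVs and clustered A>G edits are planted on the
  molecules; sequencing, UMI, and barcode errors are injected at
  configurable rates.

Reads can be emitted as FASTQ pairs for an external aligner or as "gold"
alignments (the true placements) that bypass alignment entirely.  All
bookkeeping needed to verify the pipeline — per-molecule records, the
expected count matrix, per-barcode saturation and PCR-duplicate rates,
and the variant truth table — is recorded in :class:`SynthTruth`.

UMIs are drawn to be unique per barcode and at least Hamming distance 2
apart within a (barcode, gene): UMI collisions would make molecule
identity ambiguous even to a perfect deduplicator and are not part of
the clean-library model; planted UMI errors exercise the directional
collapser instead.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .alignproc import AlignedTag, ReadAnnotation, seq_to_codes
from .reference import (
    GeneModel,
    ReferenceIndex,
    TranscriptModel,
    project_to_genome,
    revcomp,
    transcript_sequence,
    union_intervals,
    _gaps,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SynthConfig:
    seed: int = 0
    # reference
    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_length: tuple[int, int] = (130, 280)
    intron_length: tuple[int, int] = (200, 600)
    intergenic_gap: tuple[int, int] = (300, 800)
    n_contigs: int = 2
    antisense_overlap_fraction: float = 0.1
    excluded_biotype_fraction: float = 0.05
    # library
    n_cells: int = 500
    n_ambient_barcodes: int = 200
    ambient_molecules: tuple[int, int] = (1, 5)
    barcode_length: int = 16
    umi_length: int = 10
    molecules_per_cell: float = 200.0
    umi_duplicates: tuple = ("geometric", 0.6, 8)  # or ("fixed", u)
    pcr_duplicate_rate: float = 0.2
    read_length: int = 98
    base_quality: int = 37
    base_error_rate: float = 0.0
    umi_error_rate: float = 0.0
    barcode_error_rate: float = 0.0
    fraction_intronic_molecules: float = 0.15
    three_prime_bias_scale: float = 150.0
    # variants
    n_hom_snvs: int = 50
    n_het_snvs: int = 50
    het_allele_fraction: float = 0.5
    n_edit_clusters: int = 3
    edit_cluster_size: int = 10
    edit_cluster_span: int = 120
    edited_molecule_fraction: float = 0.5

    def __post_init__(self):
        if self.read_length < 30:
            raise ValueError("read_length must be >= 30")
        for p in (
            self.base_error_rate,
            self.umi_error_rate,
            self.barcode_error_rate,
            self.fraction_intronic_molecules,
            self.pcr_duplicate_rate,
            self.het_allele_fraction,
            self.edited_molecule_fraction,
        ):
            if not (0 <= p <= 1):
                raise ValueError("rates and fractions must lie in [0, 1]")


@dataclass
class VariantTruth:
    contig: str
    pos: int  # 0-based genomic
    ref: str
    alt: str
    kind: str  # hom | het | edit
    gene_id: str
    allele_fraction: float = 1.0
    cluster_id: int | None = None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.pos, self.alt)


@dataclass
class MoleculeTruth:
    molecule_id: int
    barcode: str
    gene_id: str
    umi: str
    splice_status: str
    fragment_starts: list[int]
    n_reads: int = 0
    n_pcr_duplicates: int = 0
    variant_keys: frozenset = frozenset()


@dataclass
class SynthTruth:
    molecules: list[MoleculeTruth]
    variants: list[VariantTruth]
    cell_barcodes: list[str]
    ambient_barcodes: list[str]
    whitelist: list[str]
    n_reads: int = 0
    n_barcode_errors: int = 0
    n_umi_errors: int = 0

    def expected_counts(self) -> dict[tuple[str, str], dict[str, int]]:
        """(barcode, gene) -> {"spliced": n, "unspliced": n}."""
        out: dict[tuple[str, str], dict[str, int]] = defaultdict(
            lambda: {"spliced": 0, "unspliced": 0}
        )
        for m in self.molecules:
            out[(m.barcode, m.gene_id)][m.splice_status] += 1
        return dict(out)

    def expected_barcode_rates(self) -> dict[str, tuple[float, float]]:
        """barcode -> (saturation, pcr_duplicate_rate) from bookkeeping."""
        reads = defaultdict(int)
        mols = defaultdict(int)
        dups = defaultdict(int)
        for m in self.molecules:
            reads[m.barcode] += m.n_reads
            mols[m.barcode] += 1
            dups[m.barcode] += m.n_pcr_duplicates
        return {
            bc: ((reads[bc] - mols[bc]) / reads[bc], dups[bc] / reads[bc])
            for bc in reads
            if reads[bc] > 0
        }


@dataclass
class SynthReference:
    """In-memory toy reference plus its annotation side files."""

    contigs: dict[str, str]
    genes: dict[str, GeneModel]
    transcripts: dict[str, TranscriptModel]  # retained (post-filter) set
    all_transcripts: dict[str, TranscriptModel]  # including excluded ones
    repeats: list[tuple[str, int, int]]  # Alu-like intervals

    def index(self) -> ReferenceIndex:
        return ReferenceIndex(
            self.genes,
            self.transcripts,
            {c: len(s) for c, s in self.contigs.items()},
        )

    def write_fasta(self, path: str) -> None:
        with open(path, "w") as out:
            for name in sorted(self.contigs):
                out.write(f">{name}\n")
                seq = self.contigs[name]
                for i in range(0, len(seq), 70):
                    out.write(seq[i : i + 70] + "\n")

    def write_gtf(self, path: str) -> None:
        lines = []
        for tx in self.all_transcripts.values():
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'gene_biotype "protein_coding"; transcript_biotype "{tx.biotype}";'
            )
            for s, e in tx.exons:
                lines.append(
                    (tx.contig, s, "\t".join(
                        [tx.contig, "synth", "exon", str(s + 1), str(e),
                         ".", tx.strand, ".", attrs]
                    ))
                )
        lines.sort()
        with open(path, "w") as out:
            for _, _, line in lines:
                out.write(line + "\n")

    def write_repeats_bed(self, path: str) -> None:
        with open(path, "w") as out:
            for contig, s, e in sorted(self.repeats):
                out.write(f"{contig}\t{s}\t{e}\tAlu\n")


def _random_seq(rng, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def generate_reference(config: SynthConfig, rng=None) -> SynthReference:
    """Build the toy genome and gene models; deterministic under seed."""
    rng = rng or np.random.default_rng(config.seed)
    contigs: dict[str, list[str]] = {}
    genes: dict[str, GeneModel] = {}
    retained: dict[str, TranscriptModel] = {}
    all_tx: dict[str, TranscriptModel] = {}
    repeats: list[tuple[str, int, int]] = []

    per_contig = int(np.ceil(config.n_genes / config.n_contigs))
    gi = 0
    for ci in range(config.n_contigs):
        contig = f"chrS{ci + 1}"
        cursor = int(rng.integers(*config.intergenic_gap))
        parts: list[str] = []
        length = cursor
        gene_spans: list[tuple[int, int, str]] = []
        for _ in range(per_contig):
            if gi >= config.n_genes:
                break
            gid = f"G{gi:04d}"
            tid = f"T{gi:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            exons = []
            pos = cursor
            for k in range(n_ex):
                elen = int(rng.integers(*config.exon_length))
                exons.append((pos, pos + elen))
                pos += elen
                if k < n_ex - 1:
                    pos += int(rng.integers(*config.intron_length))
            tx = TranscriptModel(
                transcript_id=tid, gene_id=gid, contig=contig,
                strand=strand, exons=exons, biotype="protein_coding",
            )
            retained[tid] = tx
            all_tx[tid] = tx
            u = union_intervals(exons)
            genes[gid] = GeneModel(
                gene_id=gid, contig=contig, strand=strand,
                exons=u, introns=_gaps(u), biotype="protein_coding",
            )
            gene_spans.append((exons[0][0], exons[-1][1], strand))
            # occasionally an excluded-biotype sibling transcript covering
            # the whole span (retained_intron-like)
            if rng.random() < config.excluded_biotype_fraction:
                all_tx[tid + "_ri"] = TranscriptModel(
                    transcript_id=tid + "_ri", gene_id=gid, contig=contig,
                    strand=strand, exons=[(exons[0][0], exons[-1][1])],
                    biotype="retained_intron",
                )
            # occasionally an antisense gene overlapping the 3' exon
            if rng.random() < config.antisense_overlap_fraction:
                anti_strand = "-" if strand == "+" else "+"
                s3, e3 = exons[-1] if strand == "+" else exons[0]
                a_start = max(0, s3 + (e3 - s3) // 2)
                a_exon = (a_start, a_start + int(rng.integers(*config.exon_length)))
                agid, atid = f"G{gi:04d}A", f"T{gi:04d}A"
                atx = TranscriptModel(
                    transcript_id=atid, gene_id=agid, contig=contig,
                    strand=anti_strand, exons=[a_exon], biotype="protein_coding",
                )
                retained[atid] = atx
                all_tx[atid] = atx
                genes[agid] = GeneModel(
                    gene_id=agid, contig=contig, strand=anti_strand,
                    exons=[a_exon], introns=[], biotype="protein_coding",
                )
                pos = max(pos, a_exon[1])
            gi += 1
            cursor = pos + int(rng.integers(*config.intergenic_gap))
            length = cursor
        # a sub-length transcript exercising the 100 bp filter
        tiny_id = f"TINY{ci}"
        tiny_exon = (length, length + 80)
        all_tx[tiny_id] = TranscriptModel(
            transcript_id=tiny_id, gene_id=f"GTINY{ci}", contig=contig,
            strand="+", exons=[tiny_exon], biotype="protein_coding",
        )
        length = tiny_exon[1] + int(rng.integers(*config.intergenic_gap))
        contigs[contig] = [length]

    sequences = {c: _random_seq(rng, ln[0]) for c, ln in contigs.items()}
    return SynthReference(
        contigs=sequences,
        genes=genes,
        transcripts=retained,
        all_transcripts=all_tx,
        repeats=repeats,
    )


def _tx_to_genome_pos(tx: TranscriptModel, t: int) -> int:
    """Genomic position of transcript coordinate t (0 = 5' end)."""
    offset = 0
    for s, e in tx.exon_chain_5to3():
        elen = e - s
        if t < offset + elen:
            return s + (t - offset) if tx.strand == "+" else e - 1 - (t - offset)
        offset += elen
    raise ValueError("transcript coordinate out of range")


def plant_variants(
    ref: SynthReference, config: SynthConfig, rng
) -> tuple[list[VariantTruth], dict[str, list[VariantTruth]], list]:
    """Choose variant positions inside the deeply covered 3' windows of
    distinct expressed genes.  Returns (variants, variants by gene,
    edit clusters as lists of VariantTruth)."""
    rl = config.read_length
    eligible = [
        tx for tx in ref.transcripts.values()
        if tx.length >= rl + 60 and not tx.transcript_id.endswith("A")
    ]
    order = rng.permutation(len(eligible))
    variants: list[VariantTruth] = []
    by_gene: dict[str, list[VariantTruth]] = defaultdict(list)
    clusters: list[list[VariantTruth]] = []
    used = 0

    def sense_base(tx, t):
        g = _tx_to_genome_pos(tx, t)
        b = ref.contigs[tx.contig][g]
        return g, (b if tx.strand == "+" else revcomp(b))

    # point variants: one per gene, in [L - rl + 10, L - 15)
    n_point = config.n_hom_snvs + config.n_het_snvs
    for i in range(n_point):
        if used >= len(eligible):
            raise ValueError("not enough eligible genes for planted variants")
        tx = eligible[order[used]]
        used += 1
        L = tx.length
        t = int(rng.integers(L - rl + 10, L - 15))
        gpos = _tx_to_genome_pos(tx, t)
        ref_b = ref.contigs[tx.contig][gpos]
        alt_b = str(rng.choice([b for b in "ACGT" if b != ref_b]))
        kind = "hom" if i < config.n_hom_snvs else "het"
        v = VariantTruth(
            contig=tx.contig, pos=gpos, ref=ref_b, alt=alt_b, kind=kind,
            gene_id=tx.gene_id,
            allele_fraction=1.0 if kind == "hom" else config.het_allele_fraction,
        )
        variants.append(v)
        by_gene[tx.gene_id].append(v)

    # clustered A>G edits on the sense strand within a 3' window
    for ci in range(config.n_edit_clusters):
        placed = False
        while used < len(eligible) and not placed:
            tx = eligible[order[used]]
            used += 1
            L = tx.length
            span = min(config.edit_cluster_span, L - rl)
            win_lo, win_hi = L - rl - span + 10, L - 15
            a_pos = [
                t for t in range(win_lo, win_hi)
                if sense_base(tx, t)[1] == "A"
            ]
            if len(a_pos) < config.edit_cluster_size:
                continue
            # anchor the cluster at both window edges so it spans more
            # than one fragment length (hyper-edited region wider than a
            # single read)
            middle = rng.choice(
                range(1, len(a_pos) - 1),
                size=config.edit_cluster_size - 2,
                replace=False,
            )
            chosen = sorted({0, len(a_pos) - 1, *middle.tolist()})
            cluster = []
            for j in chosen:
                t = a_pos[j]
                gpos = _tx_to_genome_pos(tx, t)
                ref_b = ref.contigs[tx.contig][gpos]  # A on + genes, T on -
                alt_b = "G" if tx.strand == "+" else "C"
                v = VariantTruth(
                    contig=tx.contig, pos=gpos, ref=ref_b, alt=alt_b,
                    kind="edit", gene_id=tx.gene_id,
                    allele_fraction=config.edited_molecule_fraction,
                    cluster_id=ci,
                )
                cluster.append(v)
                by_gene[tx.gene_id].append(v)
            variants.extend(cluster)
            clusters.append(cluster)
            # annotate an Alu-like repeat over the cluster's genomic span
            g_lo = min(v.pos for v in cluster)
            g_hi = max(v.pos for v in cluster) + 1
            ref.repeats.append((tx.contig, max(0, g_lo - 10), g_hi + 10))
            placed = True
        if not placed:
            raise ValueError("could not place an edit cluster")
    return variants, dict(by_gene), clusters


@dataclass
class SynthRead:
    """One emitted tag read with its gold (true) alignment."""

    read_id: str
    true_barcode: str
    observed_barcode: str
    umi: str  # observed (possibly with a planted error)
    molecule_id: int
    contig: str
    strand: str
    blocks: list[tuple[int, int]]
    seq: str  # genome-forward orientation over the blocks
    qual: np.ndarray
    gene_id: str
    splice_status: str


def _mutate_one_base(rng, s: str) -> str:
    i = int(rng.integers(0, len(s)))
    b = str(rng.choice([c for c in "ACGT" if c != s[i]]))
    return s[: i] + b + s[i + 1 :]


def _sample_umi(rng, length: int, used: set[str], same_gene: list[str]) -> str:
    while True:
        u = _random_seq(rng, length)
        if u in used:
            continue
        if any(sum(a != b for a, b in zip(u, v)) <= 1 for v in same_gene):
            continue
        return u


def generate_library(
    ref: SynthReference, config: SynthConfig, rng=None
) -> tuple[list[SynthRead], SynthTruth]:
    """Emit reads with gold alignments plus complete truth bookkeeping."""
    rng = rng or np.random.default_rng(config.seed + 1)
    rl = config.read_length
    variants, by_gene, _clusters = plant_variants(ref, config, rng)

    # barcodes: cells + ambient, all whitelisted, plus unused extras
    n_bc = config.n_cells + config.n_ambient_barcodes + 50
    barcodes: list[str] = []
    seen = set()
    while len(barcodes) < n_bc:
        b = _random_seq(rng, config.barcode_length)
        if b not in seen:
            seen.add(b)
            barcodes.append(b)
    cell_bcs = barcodes[: config.n_cells]
    ambient_bcs = barcodes[config.n_cells : config.n_cells + config.n_ambient_barcodes]

    # lognormal expression profile over genes with usable transcripts
    gene_tx: dict[str, TranscriptModel] = {}
    for tx in ref.transcripts.values():
        if tx.length >= rl + 20 and not tx.transcript_id.endswith("A"):
            gene_tx[tx.gene_id] = tx
    gene_ids = sorted(gene_tx)
    weights = rng.lognormal(0.0, 0.5, size=len(gene_ids))
    weights /= weights.sum()

    molecules: list[MoleculeTruth] = []
    reads: list[SynthRead] = []
    truth = SynthTruth(
        molecules=molecules,
        variants=variants,
        cell_barcodes=cell_bcs,
        ambient_barcodes=ambient_bcs,
        whitelist=barcodes,
    )
    mol_id = 0
    read_id = 0

    def n_fragments() -> int:
        kind = config.umi_duplicates[0]
        if kind == "fixed":
            return int(config.umi_duplicates[1])
        p, cap = config.umi_duplicates[1], config.umi_duplicates[2]
        return min(int(rng.geometric(p)), cap)

    for bc_i, bc in enumerate(cell_bcs + ambient_bcs):
        if bc_i < config.n_cells:
            n_mol = int(rng.poisson(config.molecules_per_cell))
        else:
            n_mol = int(rng.integers(config.ambient_molecules[0], config.ambient_molecules[1] + 1))
        used_umis: set[str] = set()
        gene_umis: dict[str, list[str]] = defaultdict(list)
        gene_choices = rng.choice(len(gene_ids), size=n_mol, p=weights)
        for gj in gene_choices:
            gene = gene_ids[int(gj)]
            tx = gene_tx[gene]
            umi = _sample_umi(rng, config.umi_length, used_umis, gene_umis[gene])
            used_umis.add(umi)
            gene_umis[gene].append(umi)

            intronic = (
                ref.genes[gene].introns
                and rng.random() < config.fraction_intronic_molecules
                and any(e - s >= rl + 8 for s, e in ref.genes[gene].introns)
            )
            # carried variants for this molecule
            carried: set[tuple[str, int, str]] = set()
            if not intronic:
                for v in by_gene.get(gene, ()):  # genomic-position edits
                    if v.kind == "hom":
                        carried.add(v.key)
                    elif v.kind == "het":
                        if rng.random() < v.allele_fraction:
                            carried.add(v.key)
                if by_gene.get(gene) and any(v.kind == "edit" for v in by_gene[gene]):
                    if rng.random() < config.edited_molecule_fraction:
                        carried.update(
                            v.key for v in by_gene[gene] if v.kind == "edit"
                        )
            u = n_fragments()
            if intronic:
                introns = [iv for iv in ref.genes[gene].introns if iv[1] - iv[0] >= rl + 8]
                s0, e0 = introns[int(rng.integers(0, len(introns)))]
                max_start = e0 - rl
                starts = set()
                tries = 0
                while len(starts) < u and tries < 50:
                    starts.add(int(rng.integers(s0, max_start + 1)))
                    tries += 1
                frag_list = sorted(starts)
                frag_blocks = [([(f, f + rl)], tx.strand) for f in frag_list]
                splice = "unspliced"
            else:
                L = tx.length
                starts = set()
                tries = 0
                while len(starts) < u and tries < 50:
                    bias = rng.exponential(config.three_prime_bias_scale)
                    f = int(max(0, L - rl - bias))
                    starts.add(f)
                    tries += 1
                frag_list = sorted(starts)
                frag_blocks = [
                    project_to_genome(f, f + rl, tx) for f in frag_list
                ]
                splice = "spliced"

            mol = MoleculeTruth(
                molecule_id=mol_id,
                barcode=bc,
                gene_id=gene,
                umi=umi,
                splice_status=splice,
                fragment_starts=frag_list,
                variant_keys=frozenset(carried),
            )
            alt_at = {(c, p): a for c, p, a in carried}
            for blocks, strand in frag_blocks:
                n_copies = 1 + (1 if rng.random() < config.pcr_duplicate_rate else 0)
                for _copy in range(n_copies):
                    seq_parts = []
                    for s, e in blocks:
                        part = list(ref.contigs[tx.contig][s:e])
                        for k in range(s, e):
                            a = alt_at.get((tx.contig, k))
                            if a is not None:
                                part[k - s] = a
                        seq_parts.append("".join(part))
                    seq = "".join(seq_parts)
                    if config.base_error_rate > 0:
                        arr = list(seq)
                        errs = np.flatnonzero(
                            rng.random(len(arr)) < config.base_error_rate
                        )
                        for i in errs:
                            arr[i] = str(rng.choice([c for c in "ACGT" if c != arr[i]]))
                        seq = "".join(arr)
                    obs_umi = umi
                    if config.umi_error_rate > 0 and rng.random() < config.umi_error_rate:
                        obs_umi = _mutate_one_base(rng, umi)
                        truth.n_umi_errors += 1
                    obs_bc = bc
                    if (
                        config.barcode_error_rate > 0
                        and rng.random() < config.barcode_error_rate
                    ):
                        obs_bc = _mutate_one_base(rng, bc)
                        truth.n_barcode_errors += 1
                    reads.append(
                        SynthRead(
                            read_id=f"r{read_id}",
                            true_barcode=bc,
                            observed_barcode=obs_bc,
                            umi=obs_umi,
                            molecule_id=mol_id,
                            contig=tx.contig,
                            strand=strand,
                            blocks=list(blocks),
                            seq=seq,
                            qual=np.full(rl, config.base_quality, dtype=np.uint8),
                            gene_id=gene,
                            splice_status=splice,
                        )
                    )
                    read_id += 1
                    mol.n_reads += 1
                mol.n_pcr_duplicates += n_copies - 1
            molecules.append(mol)
            mol_id += 1
    truth.n_reads = read_id
    return reads, truth


def write_fastq(reads: list[SynthRead], r1_path: str, r2_path: str) -> None:
    """R1 = barcode + UMI, R2 = the tag in sequencing orientation (reverse
    complemented for minus-strand gold placements)."""
    with open(r1_path, "w") as r1, open(r2_path, "w") as r2:
        for r in reads:
            q1 = "F" * (len(r.observed_barcode) + len(r.umi))
            r1.write(f"@{r.read_id}\n{r.observed_barcode}{r.umi}\n+\n{q1}\n")
            seq = r.seq if r.strand == "+" else revcomp(r.seq)
            qual = "".join(chr(q + 33) for q in r.qual)
            r2.write(f"@{r.read_id}\n{seq}\n+\n{qual}\n")


def gold_to_tag(read: SynthRead, corrected_barcode: str | None = None) -> AlignedTag:
    """Convert a gold read into the pipeline's aligned-tag record
    (classification fields filled in by the alignment stage)."""
    return AlignedTag(
        read_id=read.read_id,
        barcode=corrected_barcode or read.true_barcode,
        umi=read.umi,
        gene="",
        contig=read.contig,
        strand=read.strand,
        blocks=list(read.blocks),
        seq=seq_to_codes(read.seq),
        qual=read.qual.copy(),
        annotation=ReadAnnotation.UNMAPPED,
        was_corrected=corrected_barcode is not None
        and corrected_barcode != read.observed_barcode,
    )
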