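# Methods

## Library model and why collapsing matters

A 3' droplet scRNA-seq read pair carries a cell barcode (CB) and UMI on
read 1 and a cDNA tag on read 2. Amplification happens in two rounds:
first-round PCR duplicates whole molecules *before* fragmentation, so
reads from the same molecule map to different positions (molecular/UMI
duplicates); second-round PCR after fragmentation yields copies at
identical positions (PCR duplicates). Collapsing a whole UMI group into
one consensus record therefore produces a *longer* effective molecule
than any single read, averages away independent sequencing errors, and
lets a pileup count evidence per molecule and per cell rather than per
read. Sequencing saturation is defined as molecular duplicates over
countable reads, `(countable_reads − molecules) / countable_reads`; the
PCR-duplicate rate shares the same denominator (the denominator is a
package choice — the natural one given that both numerators are read
subsets of the countable pool).

## Reference index

Transcripts with biotype `retained_intron`, `nonsense_mediated_decay` or
`non_stop_decay`, and transcripts shorter than 100 bases, are excluded
from the full-length transcript set (both lists overridable). A gene's
exon set is the union of exons over its retained transcripts and its
introns are the within-span complement of that union; whether the
original dichotomy is per-gene or per-transcript is not documented
anywhere we could find, and the per-gene union matches the downstream
exonic/intronic read dichotomy. Coordinates are 0-based half-open
internally; VCF output is 1-based.

## Alignment classification

Candidate alignments below score 45 are dropped; the survivors within 3
of the best score are retained, intergenic candidates included — a read
with equally good genic and intergenic placements is multi-mapped, not
quietly assigned to the gene. Terminal blocks overhanging an annotated
splice junction by ≤ 5 bases are soft-clipped (both ends), removing the
classic mis-spliced-overhang source of false mismatches. Classification:
projected transcriptome alignments are exonic by construction; genomic
alignments are exonic with > 25 bases of exon overlap with a single sense
gene, intronic with > 5 bases of intron overlap and no exon overlap,
antisense when only opposite-strand genes are hit, ambiguous with more
than one sense gene, intergenic otherwise. Read-level annotation follows
(multi-mapped / antisense / ambiguous / exonic / intronic), with one
addition: a uniquely placed read hitting no gene at all is annotated
`intergenic`, so annotation counts partition the input exactly. "More
than one location" is decided by a < 50% reciprocal-span-overlap rule
after merging exact duplicate placements; the original tool's criterion
is not published, and this rule avoids false multi-mapping from a genome
and a projected transcriptome alignment of the same locus.

## UMI collapse and consensus

Directional collapsing per (barcode, gene): directed edge a→b when
Hamming(a, b) = 1 and count(a) ≥ 2·count(b) − 1; groups are reachability
closures taken from unabsorbed roots in descending count order (ties
lexicographic), and the root is the group's representative UMI. The same
corrected UMI mapping to two genes in one barcode keeps the gene with
more supporting reads; ties discard all contenders (the mapping-error
interpretation). PCR duplicates are counted after the directional merge,
within the merged group.

Consensus: over the union of aligned reference positions, the modal base
must reach ≥ 60% of overlapping reads, with consensus quality the maximum
quality among supporting reads; otherwise `N` with quality 2 (a value we
chose; any quality below the pileup threshold of 20 behaves identically).
Indels require 60% of locus-overlapping reads to carry the identical
indel sequence. Groups whose reads do not lay out as one linear chain —
judged by pairwise agreement of covered-versus-skipped status inside span
overlaps — are passed through uncollapsed and flagged, preserving their
pileup coverage; the original tool's exact linearity rule is unpublished
and this chain-compatibility rule is our reconstruction. On clean
synthetic data non-collapsible groups are < 0.01% of groups.

## Cell calling

Barcodes need ≥ 1 spliced molecule. The knee estimate takes the
99th-percentile spliced count among the top `expected_cells` barcodes,
divided by 10, as the candidate threshold (`expected_cells` defaults to
3000; at desk scale pass the true expected count — the knee needs the
cell population to sit an order of magnitude above ambient). MAD filters
(unscaled MAD, percent units, computed over the candidates only):
mitochondrial percent ≤ median + min(5·MAD, 20); saturation and
PCR-duplicate percent ≥ median − min(3·MAD, 10); corrected-read percent
≤ median + max(10·MAD, 1.5). Filters are conjunctive and individually
disableable. Note these are one-sided outlier filters: on a perfectly
clean library they still trim the extreme ~2% tail of each metric, which
is visible in the synthetic fixtures as a handful of true cells failing.

## Pileup and SNV filters

One count per collapsed molecule (or per read in tags/external dialects),
restricted to bases with quality ≥ 20, strand taken from the alignment
strand (3' chemistry reads are sense). A call requires: ≥ 5 unique cell
barcodes covering, ≥ 2 barcodes with the alternative allele, minor allele
fraction (alt bases / total bases over all cells) ≥ 0.01, and ≥ 1
supporting mismatch strictly outside the first/last 5 bases of its read,
where internal read ends of a collapsed molecule count as ends (a
mis-spliced member read fakes mismatches at its own termini). The
optional allele-fraction cutoff (> 0.25, strict — strictness is our
choice, configurable) is meant for germline-focused analyses and not for
edit discovery. Strand is inferred at ≥ 90% same-strand support,
bi-allelic refinement requires ref+alt ≥ 95% of all bases. A call is a
potential A-to-I edit iff its strand-oriented change is A>G *and* it is
in the edit catalogue or inside an Alu-like repeat interval. The
`max_end_distance` statistic is computed over mismatch-bearing records
only (the open alternative — all covering records — would not gate
anything).

## Benchmarking and simulation

DNA evidence: a site is present in DNA with ≥ 2 alternative bases at
mapping/base quality ≥ 20; comparison is restricted to sites with ≥ 1X
counted scRNA coverage and ≥ 15X DNA coverage (exome mode intersects
capture intervals ± 100 bp). TP = called in both; FP = called in RNA,
covered but unsupported in DNA; FN = present in DNA, uncalled, with ≥ 5
barcodes covering. Per-cell accuracy uses two FN notions: FN[bulk]
(ref-only *or* uncovered) and FN[cell] (covered ≥ 1X, zero alt); the
per-cell FDR denominator is called-and-expressed sites in that cell (the
alternative bulk-denominator reading is ambiguous in the original
description). The homozygous-SNV simulator samples positions uniformly
without replacement among positions with coverage ≥ 5 and ≥ 10 bp from
every exclusion call, substitutes a uniformly chosen non-reference base,
and is deterministic under its seed.

## Synthetic data generator

Defaults are the study conditions used throughout the acceptance checks:
200 genes (2–4 exons, both strands, ~10% with an antisense-overlapping
neighbor, excluded-biotype siblings and a sub-100-bp transcript to
exercise the index filters), 500 cells plus 200 ambient barcodes,
Poisson(200) molecules per cell with a lognormal(0, 0.5) expression
profile, read length 98, truncated-exponential 3' bias (scale 150 bases),
geometric(0.6) unique fragment positions per molecule capped at 8, PCR
duplication probability 0.2 per fragment, zero sequencing/UMI/barcode
error, and 50 homozygous + 50 heterozygous (allele fraction 0.5) SNVs
plus three 10-edit A>G clusters planted in the deeply covered 3' windows
of distinct genes. Edit clusters are anchored to both edges of a window
wider than one read length, so a hyper-edited region spans multiple
fragment positions and only a *collapsed* molecule can carry all ten
edits. Gold-alignment mode emits the true placements and is the default
test path (no aligner needed); FASTQ emission supports end-to-end runs
with a real aligner.

Two deliberate idealizations: (i) UMIs are drawn unique per barcode and
Hamming ≥ 2 apart within a (barcode, gene) — a UMI collision makes
molecule identity ambiguous to *any* deduplicator, so collisions are
excluded from the clean-library model and UMI errors are exercised via
`umi_error_rate` instead; (ii) base qualities are constant (37). The
generator also does not model doublets, ambient cross-contamination, or
empirical error profiles, so passing tests demonstrate correctness of
the bookkeeping and filters, not robustness to real-data noise.

## Problem sizes and numerics

The acceptance checks run the full 200-gene/500-cell fixture (~200,000
reads, ~100,000 molecules) end to end in well under a minute; the
heterozygous-dropout check uses a dedicated deep-coverage fixture (16
genes, 300 cells, 200 molecules/cell, 12 het sites) because per-cell
per-site depth on the 200-gene fixture cannot reach the 1–10 coverage
range the curve is evaluated over, and the monotonicity of an empirical
conditional mean needs a few thousand (cell, site) pairs of statistical
power. All thresholds compare inclusively exactly as printed (≥ 0.60
consensus, ≥ 0.01 MAF, score ≥ 45, window ≥ max − 3, distance-5 end
exclusion meaning offsets 0–4 are excluded); the single deliberate strict
comparison is the > 0.25 allele-fraction cutoff. Ties: modal-base ties
cannot reach 60% and yield `N`; barcode-correction ties and UMI-gene
conflict ties reject rather than guess.

## Known limitations

No indel calling, genotype likelihoods, doublet detection or ambient-RNA
deconvolution; the external-aligner path consumes SAM/BAM rather than
running an aligner; the external-BAM dialect trusts the producer's CB/UB
tags; per-cell FDR and the linearity rule implement documented
reconstructions of under-specified behavior (see above).
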