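"""HDF5 and VCF output containers.

One HDF5 file per run carries the per-barcode metrics table and the
spliced/unspliced count matrices as CSR triplets; pileup results go to a
site table plus per-cell sparse ref/alt matrices.  SNV calls can also be
exported as a minimal VCF (1-based positions).
"""

from __future__ import annotations

import h5py
import numpy as np

from .pileup import SNVCall
from .umidedup import BarcodeMetrics, CountMatrix

_STR = h5py.string_dtype()


def write_metrics_h5(
    path: str, metrics: dict[str, BarcodeMetrics], matrix: CountMatrix
) -> None:
    barcodes = matrix.barcodes
    with h5py.File(path, "w") as h5:
        g = h5.create_group("barcodes")
        g.create_dataset("barcode", data=np.array(barcodes, dtype=object), dtype=_STR)
        for name in (
            "countable_reads",
            "spliced_molecules",
            "unspliced_molecules",
        ):
            g.create_dataset(
                name,
                data=np.array(
                    [getattr(metrics[b], name) if b in metrics else 0 for b in barcodes],
                    dtype=np.int64,
                ),
            )
        for name in ("saturation", "pcr_duplicate_rate", "corrected_read_fraction"):
            # persisted on a percent scale, matching the MAD filter units
            g.create_dataset(
                name + "_pct",
                data=np.array(
                    [
                        100.0 * getattr(metrics[b], name) if b in metrics else np.nan
                        for b in barcodes
                    ]
                ),
            )
        mg = h5.create_group("matrix")
        mg.create_dataset("genes", data=np.array(matrix.genes, dtype=object), dtype=_STR)
        for layer in ("spliced", "unspliced"):
            csr = getattr(matrix, layer)
            lg = mg.create_group(layer)
            lg.create_dataset("data", data=csr.data)
            lg.create_dataset("indices", data=csr.indices)
            lg.create_dataset("indptr", data=csr.indptr)
            lg.attrs["shape"] = csr.shape


def read_metrics_h5(path: str):
    from scipy import sparse

    with h5py.File(path, "r") as h5:
        g = h5["barcodes"]
        barcodes = [b.decode() for b in g["barcode"][...]]
        metrics = {}
        for i, b in enumerate(barcodes):
            m = BarcodeMetrics(barcode=b)
            m.countable_reads = int(g["countable_reads"][i])
            m.spliced_molecules = int(g["spliced_molecules"][i])
            m.unspliced_molecules = int(g["unspliced_molecules"][i])
            m.saturation = float(g["saturation_pct"][i]) / 100.0
            m.pcr_duplicate_rate = float(g["pcr_duplicate_rate_pct"][i]) / 100.0
            m.corrected_read_fraction = float(g["corrected_read_fraction_pct"][i]) / 100.0
            metrics[b] = m
        mg = h5["matrix"]
        genes = [x.decode() for x in mg["genes"][...]]
        layers = {}
        for layer in ("spliced", "unspliced"):
            lg = mg[layer]
            layers[layer] = sparse.csr_matrix(
                (lg["data"][...], lg["indices"][...], lg["indptr"][...]),
                shape=tuple(lg.attrs["shape"]),
            )
    return metrics, CountMatrix(
        barcodes=barcodes, genes=genes,
        spliced=layers["spliced"], unspliced=layers["unspliced"],
    )


def write_calls_h5(path: str, calls: list[SNVCall]) -> None:
    with h5py.File(path, "w") as h5:
        g = h5.create_group("calls")
        g.create_dataset("contig", data=np.array([c.contig for c in calls], dtype=object), dtype=_STR)
        g.create_dataset("pos", data=np.array([c.pos for c in calls], dtype=np.int64))
        g.create_dataset("ref", data=np.array([c.ref for c in calls], dtype=object), dtype=_STR)
        g.create_dataset("alt", data=np.array([c.alt for c in calls], dtype=object), dtype=_STR)
        g.create_dataset("maf", data=np.array([c.maf for c in calls]))
        g.create_dataset("n_barcodes", data=np.array([c.n_barcodes for c in calls], dtype=np.int64))
        g.create_dataset(
            "n_alt_barcodes", data=np.array([c.n_alt_barcodes for c in calls], dtype=np.int64)
        )
        g.create_dataset(
            "strand", data=np.array([c.inferred_strand for c in calls], dtype=object), dtype=_STR
        )
        g.create_dataset(
            "annotation",
            data=np.array([c.primary_class for c in calls], dtype=object),
            dtype=_STR,
        )
        # per-cell sparse ref/alt counts: one triplet block over all calls
        rows, bcs, refs, alts = [], [], [], []
        for i, c in enumerate(calls):
            for bc, (r, a) in sorted(c.per_cell.items()):
                rows.append(i)
                bcs.append(bc)
                refs.append(r)
                alts.append(a)
        pg = h5.create_group("per_cell")
        pg.create_dataset("call_idx", data=np.array(rows, dtype=np.int64))
        pg.create_dataset("barcode", data=np.array(bcs, dtype=object), dtype=_STR)
        pg.create_dataset("ref_count", data=np.array(refs, dtype=np.int64))
        pg.create_dataset("alt_count", data=np.array(alts, dtype=np.int64))


def write_calls_vcf(path: str, calls: list[SNVCall], contig_lengths: dict[str, int]) -> None:
    """Minimal VCF export of passing calls; positions are 1-based."""
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        for name, ln in sorted(contig_lengths.items()):
            out.write(f"##contig=<ID={name},length={ln}>\n")
        out.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele fraction">\n')
        out.write('##INFO=<ID=NB,Number=1,Type=Integer,Description="Barcodes covering">\n')
        out.write('##INFO=<ID=NAB,Number=1,Type=Integer,Description="Barcodes with alt">\n')
        out.write('##INFO=<ID=STR,Number=1,Type=String,Description="Inferred strand">\n')
        out.write('##INFO=<ID=ANN,Number=1,Type=String,Description="Annotation class">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.contig, c.pos)):
            info = (
                f"MAF={c.maf:.4f};NB={c.n_barcodes};NAB={c.n_alt_barcodes};"
                f"STR={c.inferred_strand};ANN={c.primary_class}"
            )
            out.write(
                f"{c.contig}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}\n"
            )


def read_sites_vcf(path: str) -> list[tuple[str, int, str, str]]:
    """(contig, pos0, ref, alt) records from a VCF (SNVs only)."""
    sites = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            contig, pos, _id, ref, alts = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            for alt in alts.split(","):
                if len(ref) == 1 and len(alt) == 1 and alt in "ACGT":
                    sites.append((contig, pos - 1, ref, alt))
    return sites
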