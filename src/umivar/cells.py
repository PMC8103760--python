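"""Cell identification: elbow estimate plus MAD outlier filters.

Only barcodes with at least one spliced molecule are considered.  A rough
cell count comes from the knee of the ranked spliced-molecule counts (the
99th-percentile count among the top ``expected_cells`` barcodes, divided
by 10, as the threshold).  Elbow candidates are then filtered by median
absolute deviation (MAD, unscaled) cutoffs on quality metrics expressed
in percent units:

* mitochondrial-molecule percent: maximum of median + min(5*MAD, 20)
* sequencing saturation and PCR-duplicate rate: minimum of
  median - min(3*MAD, 10)
* barcode-corrected read percent: maximum of median + max(10*MAD, 1.5)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .umidedup import BarcodeMetrics


@dataclass
class CellCallParams:
    expected_cells: int = 3000
    mt_gene_list_name: str = "MT"
    apply_mt: bool = True
    apply_saturation: bool = True
    apply_pcr: bool = True
    apply_corrected: bool = True

    def __post_init__(self):
        if self.expected_cells < 1:
            raise ValueError("expected_cells must be >= 1")


@dataclass
class CellCallResult:
    passing: list[str]
    candidates: list[str]
    elbow_threshold: float
    cutoffs: dict[str, float] = field(default_factory=dict)
    fail_reasons: dict[str, list[str]] = field(default_factory=dict)


def elbow_estimate(
    spliced_counts: dict[str, int], expected_cells: int
) -> tuple[list[str], float]:
    """Barcodes whose spliced-molecule count reaches the knee threshold:
    (99th-percentile count of the top ``expected_cells`` barcodes) / 10.
    Barcodes with zero spliced molecules are never candidates."""
    eligible = {b: c for b, c in spliced_counts.items() if c >= 1}
    if not eligible:
        return [], float("inf")
    counts = np.sort(np.array(list(eligible.values()), dtype=float))[::-1]
    top = counts[: min(expected_cells, len(counts))]
    threshold = np.percentile(top, 99) / 10.0
    passing = [b for b, c in eligible.items() if c >= threshold]
    return sorted(passing), float(threshold)


def mad(values: np.ndarray) -> float:
    """Unscaled median absolute deviation."""
    med = np.median(values)
    return float(np.median(np.abs(values - med)))


def mad_cutoff(values: np.ndarray, kind: str) -> float:
    """Cutoff for one metric (percent scale).

    kind: "mt" (max), "saturation"/"pcr" (min), "corrected" (max).
    """
    med = float(np.median(values))
    m = mad(values)
    if kind == "mt":
        return med + min(5 * m, 20.0)
    if kind in ("saturation", "pcr"):
        return med - min(3 * m, 10.0)
    if kind == "corrected":
        return med + max(10 * m, 1.5)
    raise ValueError(f"unknown metric kind {kind!r}")


def call_cells(
    metrics: dict[str, BarcodeMetrics], params: CellCallParams | None = None
) -> CellCallResult:
    """Elbow candidates filtered conjunctively by the four MAD cutoffs
    (cutoffs computed over the candidates only)."""
    params = params or CellCallParams()
    spliced = {
        b: m.spliced_molecules for b, m in metrics.items() if m.defined
    }
    candidates, threshold = elbow_estimate(spliced, params.expected_cells)
    result = CellCallResult(
        passing=[], candidates=candidates, elbow_threshold=threshold
    )
    if not candidates:
        return result

    def pct(x: float) -> float:
        return 100.0 * x

    mt_pct = {}
    for b in candidates:
        m = metrics[b]
        n_mt = m.gene_list_counts.get(params.mt_gene_list_name, 0)
        mt_pct[b] = 100.0 * n_mt / m.molecules if m.molecules else 0.0
    sat = {b: pct(metrics[b].saturation) for b in candidates}
    pcr = {b: pct(metrics[b].pcr_duplicate_rate) for b in candidates}
    corr = {b: pct(metrics[b].corrected_read_fraction) for b in candidates}

    cutoffs = {}
    if params.apply_mt:
        cutoffs["mt_max"] = mad_cutoff(np.array(list(mt_pct.values())), "mt")
    if params.apply_saturation:
        cutoffs["saturation_min"] = mad_cutoff(np.array(list(sat.values())), "saturation")
    if params.apply_pcr:
        cutoffs["pcr_min"] = mad_cutoff(np.array(list(pcr.values())), "pcr")
    if params.apply_corrected:
        cutoffs["corrected_max"] = mad_cutoff(np.array(list(corr.values())), "corrected")
    result.cutoffs = cutoffs

    for b in candidates:
        reasons = []
        if params.apply_mt and mt_pct[b] > cutoffs["mt_max"]:
            reasons.append("mt")
        if params.apply_saturation and sat[b] < cutoffs["saturation_min"]:
            reasons.append("saturation")
        if params.apply_pcr and pcr[b] < cutoffs["pcr_min"]:
            reasons.append("pcr")
        if params.apply_corrected and corr[b] > cutoffs["corrected_max"]:
            reasons.append("corrected")
        if reasons:
            result.fail_reasons[b] = reasons
        else:
            result.passing.append(b)
    result.passing.sort()
    return result
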