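"""Per-read quality gates and cell-barcode correction.

Reads from droplet 3' libraries come in pairs: a barcode read carrying the
cell barcode (CB) and unique molecular identifier (UMI), and a cDNA tag
read used for mapping.  Before alignment each tag passes four gates, in
order:

1. the CB must match the whitelist exactly, or be correctable to a single
   best whitelisted barcode at Hamming distance 1 (highest exact-match
   count wins; ties reject);
2. the UMI must contain no ambiguous bases;
3. trailing poly(A) is trimmed and at least half the original read length
   must survive;
4. an optional DUST low-complexity score must not exceed its threshold.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from enum import Enum


class Rejection(Enum):
    BAD_BARCODE = "bad_barcode"
    AMBIGUOUS_UMI = "ambiguous_umi"
    SHORT_AFTER_POLYA = "short_after_polya"
    LOW_COMPLEXITY = "low_complexity"


@dataclass
class QAParams:
    dust_threshold: float | None = None  # disabled unless set; 4.0 typical
    min_fraction_after_polya: float = 0.5
    # poly(A) run definition: scan from the 3' end allowing at most one
    # non-A per this many bases, minimum run length to trim at all
    polya_max_miss_per: int = 8
    polya_min_run: int = 6

    def __post_init__(self):
        if not (0 < self.min_fraction_after_polya <= 1):
            raise ValueError("min_fraction_after_polya must be in (0, 1]")


@dataclass
class TaggedRead:
    """One sequencing unit: CB + UMI + tag sequence/qualities."""

    raw_barcode: str
    umi: str
    tag_seq: str
    tag_qual: str
    corrected_barcode: str | None = None
    was_corrected: bool = False


@dataclass
class BarcodeCounter:
    """Exact-match read counts per whitelisted barcode."""

    counts: dict[str, int] = field(default_factory=dict)

    def get(self, bc: str) -> int:
        return self.counts.get(bc, 0)


def _open_maybe_gz(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_whitelist(path: str) -> set[str]:
    with _open_maybe_gz(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def iter_fastq(path: str):
    """Yield (name, seq, qual) records; raises on truncated records."""
    with _open_maybe_gz(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual or not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record at index {idx} in {path}")
            yield header[1:].split()[0], seq.strip(), qual.strip()
            idx += 1


def count_barcodes(barcodes, whitelist: set[str]) -> BarcodeCounter:
    """Tally exact whitelist matches over an iterable of observed barcodes
    (strings, or FASTQ records whose sequence prefix is the barcode)."""
    counter = BarcodeCounter()
    for bc in barcodes:
        if bc in whitelist:
            counter.counts[bc] = counter.counts.get(bc, 0) + 1
    return counter


_AMBIG = set("ACGT")


def _hamming1_neighbors(bc: str):
    for i, c in enumerate(bc):
        for b in "ACGT":
            if b != c:
                yield bc[: i] + b + bc[i + 1 :]


def correct_barcode(
    observed: str, whitelist: set[str], counter: BarcodeCounter
) -> str | None:
    """Exact match returns itself; otherwise the Hamming-1 whitelisted
    barcode with the highest exact-match count (requiring count >= 1);
    ambiguous bases or ties reject (None)."""
    if observed in whitelist:
        return observed
    if any(c not in _AMBIG for c in observed):
        return None
    best: str | None = None
    best_count = 0
    tied = False
    for cand in _hamming1_neighbors(observed):
        if cand in whitelist:
            c = counter.get(cand)
            if c < 1:
                continue
            if c > best_count:
                best, best_count, tied = cand, c, False
            elif c == best_count and c > 0:
                tied = True
    if best is None or tied:
        return None
    return best


def trim_polya(
    tag_seq: str, tag_qual: str, params: QAParams | None = None
) -> tuple[str, str] | None:
    """Trim the maximal 3' poly(A) run; None if fewer than half the
    original bases survive.  The run tolerates one non-A per
    ``polya_max_miss_per`` bases and must reach ``polya_min_run`` to trim."""
    params = params or QAParams()
    L = len(tag_seq)
    best_cut = L  # index where the trimmed tail starts
    misses = 0
    run = 0
    for i in range(L - 1, -1, -1):
        run += 1
        if tag_seq[i] != "A":
            misses += 1
            if misses * params.polya_max_miss_per > run:
                break
        else:
            best_cut = i
    if L - best_cut < params.polya_min_run:
        best_cut = L
    trimmed_seq = tag_seq[:best_cut]
    if len(trimmed_seq) * 2 < L:
        return None
    return trimmed_seq, tag_qual[:best_cut]


def dust_score(seq: str) -> float:
    """DUST low-complexity score over overlapping 3-mers:
    sum c_t (c_t - 1) / 2 over triplet counts, divided by (k - 1) where k
    is the number of 3-mers; sequences shorter than 3 score 0."""
    k = len(seq) - 2
    if k < 1:
        return 0.0
    counts: dict[str, int] = {}
    for i in range(k):
        t = seq[i : i + 3]
        counts[t] = counts.get(t, 0) + 1
    s = sum(c * (c - 1) / 2 for c in counts.values())
    return s / (k - 1) if k > 1 else 0.0


def qa_read(
    read: TaggedRead,
    params: QAParams,
    whitelist: set[str],
    counter: BarcodeCounter,
) -> TaggedRead | Rejection:
    """Apply the four QA gates in order; returns the (possibly trimmed)
    accepted read or the first rejection reason."""
    corrected = correct_barcode(read.raw_barcode, whitelist, counter)
    if corrected is None:
        return Rejection.BAD_BARCODE
    if any(c not in _AMBIG for c in read.umi):
        return Rejection.AMBIGUOUS_UMI
    trimmed = trim_polya(read.tag_seq, read.tag_qual, params)
    if trimmed is None:
        return Rejection.SHORT_AFTER_POLYA
    seq, qual = trimmed
    if params.dust_threshold is not None and dust_score(seq) > params.dust_threshold:
        return Rejection.LOW_COMPLEXITY
    return TaggedRead(
        raw_barcode=read.raw_barcode,
        umi=read.umi,
        tag_seq=seq,
        tag_qual=qual,
        corrected_barcode=corrected,
        was_corrected=corrected != read.raw_barcode,
    )
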