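"""DNA-evidence labelling, accuracy metrics, and the SNV simulator."""

import numpy as np
import pytest

from umivar.benchmark import (
    BulkAccuracy,
    DNAEvidence,
    bulk_accuracy,
    label_sites,
    maf_sweep,
    per_cell_accuracy,
    sim_truth_labels,
    simulate_homozygous_snvs,
    SimTruth,
)
from umivar.pileup import SNVCall


def _call(contig="chr1", pos=100, alt="G", maf=0.3):
    return SNVCall(
        contig=contig, pos=pos, ref="A", alt=alt, maf=maf, n_barcodes=10,
        n_alt_barcodes=5, total_bases=50, ref_bases=35, alt_bases=15,
        strand_counts=(48, 2), max_end_distance=20, per_cell={},
    )


def _coverage(n=1000, depth=10):
    return {"chr1": np.full(n, depth, dtype=np.int32)}


class TestLabelSites:
    def test_called_with_dna_support_is_tp(self):
        dna = DNAEvidence(
            coverage={("chr1", 100): 30}, alt_counts={("chr1", 100, "G"): 10}
        )
        labels = label_sites([_call()], dna, _coverage())
        assert labels == {("chr1", 100, "G"): "TP"}

    def test_called_without_dna_alt_is_fp(self):
        dna = DNAEvidence(coverage={("chr1", 100): 20})
        labels = label_sites([_call()], dna, _coverage())
        assert labels == {("chr1", 100, "G"): "FP"}

    def test_one_alt_read_in_dna_still_fp(self):
        dna = DNAEvidence(
            coverage={("chr1", 100): 20}, alt_counts={("chr1", 100, "G"): 1}
        )
        assert label_sites([_call()], dna, _coverage())[("chr1", 100, "G")] == "FP"

    def test_uncalled_dna_variant_with_barcode_support_is_fn(self):
        dna = DNAEvidence(
            coverage={("chr1", 200): 30}, alt_counts={("chr1", 200, "T"): 8}
        )
        labels = label_sites(
            [], dna, _coverage(), dsc_barcode_coverage={("chr1", 200): 6}
        )
        assert labels == {("chr1", 200, "T"): "FN"}

    def test_fn_requires_five_barcodes(self):
        dna = DNAEvidence(
            coverage={("chr1", 200): 30}, alt_counts={("chr1", 200, "T"): 8}
        )
        labels = label_sites(
            [], dna, _coverage(), dsc_barcode_coverage={("chr1", 200): 4}
        )
        assert labels == {}

    def test_shallow_dna_site_excluded(self):
        dna = DNAEvidence(
            coverage={("chr1", 100): 14}, alt_counts={("chr1", 100, "G"): 10}
        )
        assert label_sites([_call()], dna, _coverage()) == {}

    def test_no_scrna_coverage_excluded(self):
        dna = DNAEvidence(
            coverage={("chr1", 100): 30}, alt_counts={("chr1", 100, "G"): 10}
        )
        cov = {"chr1": np.zeros(1000, dtype=np.int32)}
        assert label_sites([_call()], dna, cov) == {}


class TestBulkAccuracy:
    def test_formula_plugin(self):
        acc = BulkAccuracy(n_tp=9, n_fp=1, n_fn=1)
        assert acc.tpr == pytest.approx(0.9)
        assert acc.fdr == pytest.approx(0.1)
        assert acc.f1 == pytest.approx(0.9)

    def test_no_false_positives(self):
        assert BulkAccuracy(n_tp=5, n_fp=0, n_fn=5).fdr == 0.0

    def test_random_labels_match_direct_recount(self, rng):
        for _ in range(20):
            labels = {
                ("chr1", int(p), "G"): ["TP", "FP", "FN"][int(rng.integers(0, 3))]
                for p in rng.choice(10_000, size=50, replace=False)
            }
            acc = bulk_accuracy(labels)
            vals = list(labels.values())
            assert (acc.n_tp, acc.n_fp, acc.n_fn) == (
                vals.count("TP"), vals.count("FP"), vals.count("FN")
            )

    def test_maf_sweep_monotone_in_cutoff(self):
        dna = DNAEvidence(
            coverage={("chr1", p): 30 for p in range(100, 130)},
            alt_counts={("chr1", p, "G"): 5 for p in range(100, 115)},
        )
        calls = [_call(pos=p, maf=0.05 + 0.03 * (p - 100)) for p in range(100, 130)]
        sweep = maf_sweep(calls, dna, _coverage(), cutoffs=[0.0, 0.2, 0.4, 0.8])
        tps = [sweep[c].n_tp for c in (0.0, 0.2, 0.4, 0.8)]
        fps = [sweep[c].n_fp for c in (0.0, 0.2, 0.4, 0.8)]
        assert tps == sorted(tps, reverse=True)
        assert fps == sorted(fps, reverse=True)


class TestPerCellAccuracy:
    def test_tpr_with_mixed_evidence(self):
        truth = {("chr1", p, "G") for p in range(10)}
        counts = {}
        for i, key in enumerate(sorted(truth)):
            if i < 8:
                counts[key] = {"c1": [0, 1, 0, 0]}  # alt expressed
            else:
                counts[key] = {"c1": [2, 0, 0, 0]}  # ref only
        table = per_cell_accuracy(counts, truth, {"c1"})
        acc = table["c1"]
        assert acc.n_tp == 8
        assert acc.fn_bulk == 2
        assert acc.fn_cell == 2
        assert acc.tpr_cell == pytest.approx(0.8)

    def test_uncovered_truth_counts_fn_bulk_only(self):
        truth = {("chr1", 5, "G")}
        table = per_cell_accuracy({}, truth, {"c1"})
        assert table["c1"].fn_bulk == 1
        assert table["c1"].fn_cell == 0

    def test_fn_cell_bounded_by_fn_bulk(self, rng):
        truth = {("chr1", int(p), "G") for p in range(30)}
        counts = {}
        for key in truth:
            per = {}
            for c in ("c1", "c2"):
                r = int(rng.integers(0, 3))
                a = int(rng.integers(0, 2))
                if r or a:
                    per[c] = [r, a, 0, 0]
            counts[key] = per
        table = per_cell_accuracy(counts, truth, {"c1", "c2"})
        for acc in table.values():
            assert acc.fn_cell <= acc.fn_bulk


class TestSimulator:
    REFERENCE = {"chrZ": "ACGTACGTAC" * 10}

    def test_only_eligible_positions_sampled(self):
        cov = {"chrZ": np.zeros(100, dtype=np.int32)}
        cov["chrZ"][40:43] = 5  # exactly three eligible positions
        modified, truth = simulate_homozygous_snvs(
            self.REFERENCE, cov, [], n=3, seed=1
        )
        assert sorted(p for _c, p, _r, _a in truth.sites) == [40, 41, 42]
        for contig, pos, ref_b, alt_b in truth.sites:
            assert self.REFERENCE[contig][pos] == ref_b
            assert modified[contig][pos] == alt_b
            assert alt_b != ref_b

    def test_exclusion_distance_boundary(self):
        cov = {"chrZ": np.full(100, 10, dtype=np.int32)}
        exclusions = [("chrZ", 50)]
        _m, truth = simulate_homozygous_snvs(
            self.REFERENCE, cov, exclusions, n=50, seed=2
        )
        for _c, pos, _r, _a in truth.sites:
            assert abs(pos - 50) >= 10  # 9 bp away is never sampled

    def test_deterministic_under_seed(self):
        cov = {"chrZ": np.full(100, 10, dtype=np.int32)}
        a = simulate_homozygous_snvs(self.REFERENCE, cov, [], n=20, seed=7)
        b = simulate_homozygous_snvs(self.REFERENCE, cov, [], n=20, seed=7)
        assert a[0] == b[0]
        assert a[1].sites == b[1].sites

    def test_insufficient_positions_reports_count(self):
        cov = {"chrZ": np.zeros(100, dtype=np.int32)}
        cov["chrZ"][10:12] = 9
        with pytest.raises(ValueError, match="2 eligible"):
            simulate_homozygous_snvs(self.REFERENCE, cov, [], n=5, seed=0)


class TestSimTruthLabels:
    def test_coverage_in_either_run_gates_fn(self):
        truth = SimTruth(sites=[("chr1", 10, "A", "G"), ("chr1", 50, "A", "G")])
        cov_mod = {"chr1": np.zeros(100, dtype=np.int32)}
        cov_orig = {"chr1": np.zeros(100, dtype=np.int32)}
        cov_orig[ "chr1"][10] = 3  # covered only in the unmodified run
        out = sim_truth_labels({}, cov_mod, cov_orig, truth, {"c1"})
        assert out["c1"] == {"tp": 0, "fn": 1}  # site 50 uncovered anywhere

    def test_alt_expression_is_tp(self):
        truth = SimTruth(sites=[("chr1", 10, "A", "G")])
        counts = {("chr1", 10, "G"): {"c1": [0, 2, 0, 0]}}
        cov = {"chr1": np.zeros(100, dtype=np.int32)}
        out = sim_truth_labels(counts, cov, cov, truth, {"c1"})
        assert out["c1"] == {"tp": 1, "fn": 0}
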