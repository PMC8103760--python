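"""Pileup counting, SNV filters, annotation, and co-expression."""

from collections import defaultdict

import numpy as np
import pytest
from intervaltree import IntervalTree

from umivar.alignproc import AlignedTag, ReadAnnotation, seq_to_codes
from umivar.collapse import CollapsedMolecule
from umivar.pileup import (
    SNVCall,
    SNVFilterParams,
    annotate_call,
    apply_af_cutoff,
    call_snvs,
    extract_coexpression,
    infer_strand,
    pileup,
    quantify_known,
    refine_biallelic,
)

REF = {"chrP": seq_to_codes("ACGT" * 250)}  # 1 kb toy contig


def _mol(barcode, seq, start=0, strand="+", qual=37, internal_ends=(), blocks=None):
    codes = seq_to_codes(seq)
    blocks = blocks or [(start, start + len(codes))]
    return CollapsedMolecule(
        barcode=barcode, umi="u", gene_id="g", contig="chrP", strand=strand,
        blocks=blocks, seq=codes,
        qual=np.full(len(codes), qual, dtype=np.uint8),
        depth=np.ones(len(codes), dtype=np.int32),
        internal_read_ends=list(internal_ends),
    )


def _ref_str(start, length):
    from umivar.alignproc import codes_to_seq

    return codes_to_seq(REF["chrP"][start : start + length])


def _with_alt(seq, offset, alt):
    return seq[:offset] + alt + seq[offset + 1 :]


class TestPileupCounting:
    def test_simple_site_counts(self):
        mols = [
            _mol("b1", _ref_str(0, 30)),
            _mol("b2", _ref_str(0, 30)),
            _mol("b3", _with_alt(_ref_str(0, 30), 15, "G")),
        ]
        sites = pileup(mols, REF, cells=None)
        assert len(sites) == 1
        site = sites[0]
        assert site.pos == 15
        assert site.base_counts[2] == 1  # G
        assert int(site.base_counts.sum()) == 3
        assert site.n_barcodes_covered == 3

    def test_low_quality_alt_not_counted(self):
        mols = [
            _mol("b1", _ref_str(0, 30)),
            _mol("b2", _with_alt(_ref_str(0, 30), 10, "T"), qual=19),
        ]
        assert pileup(mols, REF, cells=None) == []

    def test_unknown_dialect_rejected(self):
        with pytest.raises(ValueError):
            pileup([], REF, None, dialect="bogus")

    def test_random_records_match_naive_walk(self, rng):
        """Per-site counts equal a brute-force per-base pileup."""
        mols = []
        for i in range(60):
            start = int(rng.integers(0, 900))
            length = int(rng.integers(20, 90))
            seq = list(_ref_str(start, length))
            for j in range(len(seq)):
                if rng.random() < 0.02:
                    seq[j] = "ACGT"[int(rng.integers(0, 4))]
            mols.append(
                _mol(f"b{i % 10}", "".join(seq), start=start,
                     strand="+" if rng.random() < 0.5 else "-",
                     qual=int(rng.integers(15, 41)))
            )
        sites = {s.pos: s for s in pileup(mols, REF, cells=None)}
        # oracle: walk every molecule base by base
        counts = defaultdict(lambda: np.zeros(5, dtype=int))
        mismatch_pos = set()
        for m in mols:
            for off, p in enumerate(range(m.blocks[0][0], m.blocks[0][1])):
                if m.qual[off] < 20:
                    continue
                b = int(m.seq[off])
                counts[p][b] += 1
                if b != int(REF["chrP"][p]) and b < 4:
                    mismatch_pos.add(p)
        assert set(sites) == mismatch_pos
        for p in mismatch_pos:
            assert (sites[p].base_counts == counts[p]).all()


def _make_site_mols(n_ref_barcodes, n_alt_barcodes, alt_offset=15, length=31,
                    alt="G", alt_qual=37, alt_count_per_barcode=1):
    """Molecules covering [0, length) with an alt at alt_offset."""
    mols = [
        _mol(f"ref{i}", _ref_str(0, length)) for i in range(n_ref_barcodes)
    ]
    for i in range(n_alt_barcodes):
        for _ in range(alt_count_per_barcode):
            mols.append(
                _mol(f"alt{i}", _with_alt(_ref_str(0, length), alt_offset, alt),
                     qual=alt_qual)
            )
    return mols


class TestSNVFilters:
    def test_boundary_site_passes_all_filters(self):
        mols = _make_site_mols(3, 2)  # 5 barcodes, 2 alt, maf 0.4, central
        calls = call_snvs(pileup(mols, REF, None))
        assert len(calls) == 1
        assert calls[0].pos == 15

    def test_four_barcodes_rejected(self):
        mols = _make_site_mols(2, 2)
        assert call_snvs(pileup(mols, REF, None)) == []

    def test_single_alt_barcode_rejected(self):
        mols = _make_site_mols(4, 1)
        assert call_snvs(pileup(mols, REF, None)) == []

    def test_maf_below_minimum_rejected(self):
        # 2 alt bases over 202 total = 0.0099 < 0.01
        mols = _make_site_mols(3, 2)
        mols += [_mol("deep", _ref_str(0, 31)) for _ in range(197)]
        sites = pileup(mols, REF, None)
        assert call_snvs(sites) == []
        # two fewer reference molecules: 2/200 = 0.01 exactly, inclusive
        calls = call_snvs(pileup(mols[:-2], REF, None))
        assert len(calls) == 1

    def test_all_mismatches_near_read_ends_rejected(self):
        mols = _make_site_mols(3, 2, alt_offset=4)  # 4 bp from the 5' end
        assert call_snvs(pileup(mols, REF, None)) == []
        mols = _make_site_mols(3, 2, alt_offset=5)  # exactly outside
        assert len(call_snvs(pileup(mols, REF, None))) == 1

    def test_internal_read_end_counts_as_end(self):
        """A mismatch adjacent to an internal (collapsed) read end fails
        the end-exclusion filter even when central in the molecule."""
        ref31 = _ref_str(0, 31)
        mols = [_mol(f"ref{i}", ref31) for i in range(3)]
        mols += [
            _mol(f"alt{i}", _with_alt(ref31, 15, "G"), internal_ends=[14])
            for i in range(2)
        ]
        assert call_snvs(pileup(mols, REF, None)) == []

    def test_filter_survivors_match_exhaustive_enumeration(self, rng):
        """Constructed site tables: surviving set equals filtering the
        pileup evidence by brute force."""
        params = SNVFilterParams()
        for _ in range(20):
            mols = _make_site_mols(
                int(rng.integers(0, 7)), int(rng.integers(0, 5)),
                alt_offset=int(rng.integers(0, 31)),
            )
            sites = pileup(mols, REF, None, params)
            calls = call_snvs(sites, params)
            expected = []
            for s in sites:
                for alt_code in range(4):
                    if alt_code == s.ref_code or not s.base_counts[alt_code]:
                        continue
                    if (
                        s.n_barcodes_covered >= 5
                        and s.n_barcodes_alt(alt_code) >= 2
                        and s.base_counts[alt_code] / s.base_counts.sum() >= 0.01
                        and s.max_end_distance.get(alt_code, -1) >= 5
                    ):
                        expected.append((s.pos, alt_code))
            assert [(c.pos, "ACGT".index(c.alt)) for c in calls] == expected


def _call(**kw):
    base = dict(
        contig="chrP", pos=100, ref="A", alt="G", maf=0.3, n_barcodes=10,
        n_alt_barcodes=5, total_bases=100, ref_bases=70, alt_bases=26,
        strand_counts=(95, 5), max_end_distance=20, per_cell={},
    )
    base.update(kw)
    return SNVCall(**base)


class TestRefinement:
    @pytest.mark.parametrize("maf,kept", [(0.30, True), (0.25, False), (0.01, False)])
    def test_af_cutoff_is_strict(self, maf, kept):
        out = apply_af_cutoff([_call(maf=maf)])
        assert bool(out) is kept

    @pytest.mark.parametrize(
        "ref_b,alt_b,total,ok", [(70, 26, 100, True), (70, 24, 100, False), (1, 0, 1, True)]
    )
    def test_biallelic_fraction(self, ref_b, alt_b, total, ok):
        c = _call(ref_bases=ref_b, alt_bases=alt_b, total_bases=total)
        assert refine_biallelic(c) is ok

    @pytest.mark.parametrize(
        "plus,minus,expected", [(95, 5, "+"), (5, 95, "-"), (60, 40, "unknown"), (1, 0, "+")]
    )
    def test_strand_inference(self, plus, minus, expected):
        assert infer_strand(_call(strand_counts=(plus, minus))) == expected


class TestAnnotation:
    repeats = {"chrP": IntervalTree([__import__("intervaltree").Interval(90, 120)])}

    def test_plus_strand_ag_in_repeat(self):
        c = annotate_call(_call(), repeat_lookup=self.repeats)
        assert c.flags["AG_edit"]
        assert c.primary_class == "AG_edit"

    def test_minus_strand_tc_is_oriented_ag(self):
        c = annotate_call(
            _call(ref="T", alt="C", strand_counts=(5, 95)),
            edit_catalogue={("chrP", 100)},
        )
        assert c.inferred_strand == "-"
        assert c.flags["AG_edit"]

    def test_ag_outside_catalogue_and_repeats_not_edit(self):
        c = annotate_call(_call())
        assert not c.flags["AG_edit"]

    def test_non_ag_change_unknown(self):
        c = annotate_call(_call(ref="C", alt="T"), repeat_lookup=self.repeats)
        assert not c.flags["AG_edit"]
        assert c.primary_class == "unknown"

    def test_germline_beats_edit_class(self):
        c = annotate_call(
            _call(),
            repeat_lookup=self.repeats,
            germline_calls={("chrP", 100): {"G"}},
        )
        assert c.flags["germline"]
        assert c.primary_class == "germline"

    def test_unknown_strand_never_edit(self):
        c = annotate_call(
            _call(strand_counts=(60, 40)), repeat_lookup=self.repeats
        )
        assert not c.flags["AG_edit"]


class TestQuantifyKnown:
    def test_het_site_counts(self):
        mols = [
            _mol("cell1", _ref_str(0, 31)),
            _mol("cell1", _with_alt(_ref_str(0, 31), 15, "G")),
            _mol("cell2", _ref_str(0, 31), strand="-"),
        ]
        out = quantify_known(mols, [("chrP", 15, "T", "G")], REF)
        assert out[("chrP", 15, "G")]["cell1"] == [1, 1, 0, 0]
        assert out[("chrP", 15, "G")]["cell2"] == [1, 0, 0, 0] or out[
            ("chrP", 15, "G")
        ]["cell2"] == [0, 0, 1, 0]

    def test_uncovered_site_absent(self):
        mols = [_mol("cell1", _ref_str(0, 31))]
        out = quantify_known(mols, [("chrP", 500, "A", "G")], REF)
        assert out[("chrP", 500, "G")] == {}

    def test_counts_match_generator_truth(self, small_library, small_result, small_codes):
        """Per-cell alt counts at planted hom sites equal the number of
        truth molecules of that (cell, gene) covering the site."""
        _reads, truth = small_library
        hom = [v for v in truth.variants if v.kind == "hom"][:3]
        sites = [(v.contig, v.pos, v.ref, v.alt) for v in hom]
        out = quantify_known(small_result.molecules, sites, small_codes)
        for v in hom:
            per_bc = out[(v.contig, v.pos, v.alt)]
            for bc, (rp, ap, rm, am) in per_bc.items():
                assert rp + rm == 0  # hom: no reference molecules
                assert ap + am >= 1


class TestCoexpression:
    def _calls(self, n, cls="AG_edit"):
        calls = []
        for i in range(n):
            c = _call(pos=10 + i * 3, ref=_ref_str(10 + i * 3, 1), alt="G")
            if _ref_str(10 + i * 3, 1) == "G":
                c.alt = "T"
            c.flags = {"AG_edit": cls == "AG_edit", "germline": cls == "germline"}
            calls.append(c)
        return calls

    def test_molecule_with_five_snvs_dominant_type(self):
        calls = self._calls(3) + [
            c for c in self._calls(5)[3:]
        ]
        for c in calls[3:]:
            c.flags = {}
        seq = _ref_str(0, 40)
        for c in calls:
            seq = _with_alt(seq, c.pos, c.alt)
        mols = [_mol("b1", seq)]
        sets = extract_coexpression(mols, calls, min_snvs=5)
        assert len(sets) == 1
        s = sets[0]
        assert len(s.snvs) == 5
        assert s.dominant_type == "AG_edit"
        assert s.purity == pytest.approx(0.6)

    def test_four_snvs_excluded(self):
        calls = self._calls(4)
        seq = _ref_str(0, 40)
        for c in calls:
            seq = _with_alt(seq, c.pos, c.alt)
        assert extract_coexpression([_mol("b1", seq)], calls, min_snvs=5) == []

    def test_identical_sets_deduplicated(self):
        calls = self._calls(5)
        seq = _ref_str(0, 40)
        for c in calls:
            seq = _with_alt(seq, c.pos, c.alt)
        mols = [_mol("b1", seq), _mol("b2", seq)]
        sets = extract_coexpression(mols, calls, min_snvs=5)
        assert len(sets) == 1
        assert sets[0].n_molecules == 2


def test_per_cell_counts_conserve_pseudobulk(small_result):
    """Summing per-cell counts of every call reproduces the bulk counts."""
    for c in small_result.calls:
        total_ref = sum(r for r, _a in c.per_cell.values())
        total_alt = sum(a for _r, a in c.per_cell.values())
        assert total_ref == c.ref_bases
        assert total_alt == c.alt_bases
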