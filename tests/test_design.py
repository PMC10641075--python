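"""Library-construction rules: windows, shuffles, barcodes, oligos."""

from collections import Counter
from math import comb

import numpy as np
import pytest

from utrmpra.design import (
    Barcode,
    CapacityError,
    Element,
    MismatchError,
    OligoLayout,
    VariantRecord,
    assemble_oligo,
    build_library,
    colony_coverage,
    extract_window,
    generate_barcodes,
    shuffle_control,
)
from conftest import make_reference


class TestExtractWindow:
    def test_snv_centered(self):
        ref = {"chr1": "A" * 300}
        v = VariantRecord("v1", "chr1", 150, "A", "T")
        rc, ac = extract_window(ref, v, window=120)
        assert rc == "A" * 120
        assert len(ac) == 120 and ac[60] == "T"
        assert ac[:60] == "A" * 60 and ac[61:] == "A" * 59

    def test_left_clip_keeps_variant_offset(self):
        ref = {"chr1": "A" * 300}
        v = VariantRecord("v2", "chr1", 10, "A", "G")
        rc, ac = extract_window(ref, v, window=120)
        # brute-force slice of the toy string: flanks clipped at the start
        assert rc == "A" * 69 and len(rc) < 120
        assert ac[9] == "G"

    def test_ref_mismatch_names_variant(self):
        ref = {"chr1": "G" * 100}
        v = VariantRecord("bad1", "chr1", 50, "C", "T")
        with pytest.raises(MismatchError, match="bad1"):
            extract_window(ref, v)

    def test_indel_contexts_fit_window(self):
        rng = np.random.default_rng(0)
        chrom = "".join(rng.choice(list("ACGT"), size=400))
        ref_allele = chrom[199:204]  # 5-nt deletion
        v = VariantRecord("del1", "chr1", 200, ref_allele, chrom[199])
        rc, ac = extract_window({"chr1": chrom}, v, window=120)
        assert len(rc) <= 120 and len(ac) <= 120
        assert len(rc) - len(ac) == 4
        # both contexts share the flanks
        assert rc[:60] == ac[:60]
        assert rc[60 + 5:] == ac[60 + 1:]


class TestShuffleControl:
    def test_composition_conserved(self):
        el = Element("e1_ref", "ref", "ACGTACGTTTGC")
        shuf = shuffle_control(el, seed=3)
        assert Counter(shuf.sequence) == Counter(el.sequence)
        assert shuf.element_class == "shuf"
        assert shuf.paired_element_id == "e1_ref"
        assert shuf.gc_content == el.gc_content

    def test_monomorphic_sequence_unchanged(self):
        el = Element("e2_ref", "ref", "AAAA")
        assert shuffle_control(el, seed=11).sequence == "AAAA"

    def test_identity_fraction_matches_multiset_count(self):
        # P(shuffle == input) for AAACCC is 1 / (6!/(3!3!)) = 0.05
        el = Element("e3_ref", "ref", "AAACCC")
        n = 1000
        hits = sum(
            shuffle_control(el, seed=s).sequence == el.sequence
            for s in range(n)
        )
        p = 1 / comb(6, 3)
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 4 * sd


class TestBarcodes:
    def test_emitted_set_satisfies_all_invariants(self):
        bcs = generate_barcodes(500, seed=2)
        seqs = [b.sequence for b in bcs]
        assert len(set(seqs)) == 500
        arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
            500, 9
        )
        for i in range(500):
            d = (arr[i + 1:] != arr[i]).sum(axis=1)
            assert d.size == 0 or d.min() >= 2
        for s in seqs:
            assert "GCTAGC" not in s and "GGTACC" not in s
            assert not any(b * 4 in s for b in "ACGT")

    def test_deterministic(self):
        a = generate_barcodes(50, seed=9)
        b = generate_barcodes(50, seed=9)
        assert [x.sequence for x in a] == [x.sequence for x in b]

    def test_single_barcode(self):
        (bc,) = generate_barcodes(1, seed=0)
        assert len(bc.sequence) == 9

    def test_capacity_error_reports_found(self):
        with pytest.raises(CapacityError) as exc:
            generate_barcodes(300_000, seed=0, max_attempts=50_000)
        assert 0 < len(exc.value.found) < 300_000


class TestAssembleOligo:
    def test_full_length_element_gives_210(self):
        el = Element("e", "ref", "C" * 120)
        bc = Barcode("b", "ACGTACGTA")
        o = assemble_oligo(el, bc)
        assert len(o.full_sequence) == 210

    def test_layout_contiguous_and_round_trips(self):
        el = Element("e", "ref", "ACGT" * 30)
        bc = Barcode("b", "ACGTACGTA")
        o = assemble_oligo(el, bc)
        cursor = 0
        for name, start, end in o.layout:
            assert start == cursor and end > start
            cursor = end
        assert cursor == len(o.full_sequence) == 210
        assert o.segment("barcode") == bc.sequence
        assert o.segment("utr_context") == el.sequence
        assert o.segment("linker") == OligoLayout().linker

    def test_short_element_padded_to_total(self):
        el = Element("e", "ref", "ACGT" * 20)  # 80 nt indel context
        o = assemble_oligo(el, Barcode("b", "ACGTACGTA"))
        assert len(o.full_sequence) == 210
        assert o.segment("pad5") == ("AT" * 20)
        assert o.segment("utr_context") == el.sequence

    def test_oversized_element_rejected(self):
        el = Element("e", "ref", "A" * 121)
        with pytest.raises(ValueError, match="slot"):
            assemble_oligo(el, Barcode("b", "ACGTACGTA"))


class TestBuildLibrary:
    @pytest.mark.parametrize(
        "n_var,n_shuf,n_ctrl,bpe,n_el,n_oligo",
        [(1, 0, 0, 1, 2, 2), (2, 2, 0, 3, 6, 18), (3, 1, 1, 2, 8, 16)],
    )
    def test_element_and_oligo_arithmetic(
        self, n_var, n_shuf, n_ctrl, bpe, n_el, n_oligo
    ):
        reference, variants = make_reference(n_var)
        controls = [(f"c{i}", "ACGT" * 30) for i in range(n_ctrl)]
        man = build_library(
            variants,
            reference,
            n_shuffle=n_shuf,
            controls=controls,
            barcodes_per_element=bpe,
            seed=5,
        )
        assert len(man.elements) == n_el
        assert len(man.oligos) == n_oligo

    def test_duplicate_variant_ids_rejected(self):
        reference, variants = make_reference(2)
        dupe = variants + [variants[0]]
        with pytest.raises(ValueError, match="duplicate"):
            build_library(dupe, reference, seed=0)

    def test_shuffle_partners_composition_conserved(self, small_design):
        by_id = {e.element_id: e for e in small_design.elements}
        shufs = [
            e for e in small_design.elements if e.element_class == "shuf"
        ]
        assert shufs
        for s in shufs:
            ref = by_id[s.paired_element_id]
            assert Counter(s.sequence) == Counter(ref.sequence)

    def test_barcode_mapping_is_a_function(self, small_design):
        mapping = small_design.barcode_to_element()
        assert len(mapping) == len(small_design.oligos)

    def test_deterministic_manifest(self):
        reference, variants = make_reference(3)
        a = build_library(variants, reference, n_shuffle=1, seed=13)
        b = build_library(variants, reference, n_shuffle=1, seed=13)
        assert [o.full_sequence for o in a.oligos] == [
            o.full_sequence for o in b.oligos
        ]
        assert [e.sequence for e in a.elements] == [
            e.sequence for e in b.elements
        ]


class TestColonyCoverage:
    def test_examples(self):
        assert colony_coverage(100, 0, 0.5) == 0.0
        assert colony_coverage(1, 10, 0.0) == 1.0
        assert colony_coverage(9744, 71000, 0.5) == pytest.approx(
            1 - (1 - 1 / 9744) ** 35500
        )

    def test_error_rate_validated(self):
        with pytest.raises(ValueError):
            colony_coverage(10, 10, 1.5)
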