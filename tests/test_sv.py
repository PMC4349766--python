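"""SV engine: planning, placement mechanics, sequence surgery, junctions."""

import numpy as np
import pytest
from Bio import Align

from somaticsim import (
    ReferenceGenome,
    apply_germline,
    junction_homology,
    make_foreign_insertion,
    place_homologous,
    place_nonhomologous,
    plan_events,
    set_base_ploidy,
)
from somaticsim.model import initial_model
from somaticsim.reference import revcomp
from somaticsim.repeats import RepeatCatalog, RepeatElement
from somaticsim.sv import (
    MAX_MICROHOM,
    PlacementError,
    StaleEventError,
    SVEvent,
    SVEventSpec,
    apply_event,
    realize_spec,
)
from somaticsim.synthetic import random_sequence

from _oracles import binom_interval, string_kmers


def mini_model(*seqs):
    ref = ReferenceGenome([(f"T{i}", s) for i, s in enumerate(seqs)])
    pg = apply_germline(ref, [])
    return initial_model(pg)


class TestApplyEventStrings:
    def test_deletion_excises(self):
        model = mini_model("ACGTACGT")
        copy = model.copies["T0"][0]
        ev = SVEvent("e", SVEventSpec("DEL", "NONHOM", 4), copy.copy_id, interval=(2, 6))
        apply_event(model, ev)
        assert copy.sequence == "ACGT"

    def test_tandem_duplication_adjacent(self):
        model = mini_model("ACGTAC")
        copy = model.copies["T0"][0]
        ev = SVEvent("e", SVEventSpec("TDUP", "NONHOM", 2), copy.copy_id, interval=(1, 3))
        apply_event(model, ev)
        assert copy.sequence == "ACGCGTAC"

    def test_inversion_reverse_complements(self):
        model = mini_model("ACGTAC")
        copy = model.copies["T0"][0]
        ev = SVEvent("e", SVEventSpec("INV", "NONHOM", 4), copy.copy_id, interval=(1, 5))
        apply_event(model, ev)
        assert copy.sequence == "ATACGC"

    def test_foreign_insertion_payload(self):
        model = mini_model("ACGTACGT")
        copy = model.copies["T0"][0]
        ev = SVEvent(
            "e", SVEventSpec("INS", "FOREIGN", 4), copy.copy_id,
            insert_pos=2, inserted_sequence="TTTT",
        )
        before = model.total_bases()
        apply_event(model, ev)
        assert copy.sequence == "ACTTTTGTACGT"
        assert model.total_bases() == before + 4

    def test_itx_moves_inverted(self):
        s = "AACCGGTTAACC"
        model = mini_model(s)
        copy = model.copies["T0"][0]
        # excise [2, 6) = "CCGG", invert -> "CCGG", reinsert at post-excision 4
        ev = SVEvent("e", SVEventSpec("ITX", "NONHOM", 4), copy.copy_id,
                     interval=(2, 6), insert_pos=4)
        apply_event(model, ev)
        trunk = s[:2] + s[6:]
        expected = trunk[:4] + revcomp(s[2:6]) + trunk[4:]
        assert copy.sequence == expected
        assert len(copy.sequence) == len(s)

    def test_balanced_translocation_exchanges_tails(self):
        model = mini_model("AAAAAATTTTTT", "CCCCCCGGGGGG")
        c1 = model.copies["T0"][0]
        c2 = model.copies["T1"][0]
        ev = SVEvent(
            "e", SVEventSpec("CTX_BAL", "NONHOM", 1), c1.copy_id,
            partner_copy_id=c2.copy_id, insert_pos=6, partner_pos=6,
        )
        before = model.total_bases()
        apply_event(model, ev)
        assert c1.sequence == "AAAAAAGGGGGG"
        assert c2.sequence == "CCCCCCTTTTTT"
        assert model.total_bases() == before

    def test_unbalanced_translocation_loses_acceptor_tail(self):
        model = mini_model("AAAAAATTTTTT", "CCCCCCGGGGGG")
        c1 = model.copies["T0"][0]
        c2 = model.copies["T1"][0]
        ev = SVEvent(
            "e", SVEventSpec("CTX_UNBAL", "NONHOM", 6), c1.copy_id,
            partner_copy_id=c2.copy_id, insert_pos=6, partner_pos=6,
            balanced=False, expected_len=12, partner_expected_len=12,
        )
        before = model.total_bases()
        apply_event(model, ev)
        assert c1.sequence == "AAAAAAGGGGGG"
        assert c2.sequence == "CCCCCC"
        assert model.total_bases() == before - 6  # the acceptor tail is lost


class TestPlanEvents:
    def test_zero_events(self):
        assert plan_events(0, seed=1) == []

    def test_concentrated_type_weights(self):
        specs = plan_events(50, type_weights={"DEL": 1.0}, seed=2)
        assert all(s.sv_type == "DEL" for s in specs)

    def test_foreign_only_with_insertions(self):
        specs = plan_events(
            300, mechanism_weights={"NONHOM": 0.2, "HOM": 0.2, "FOREIGN": 0.6}, seed=3
        )
        assert all(s.mechanism != "FOREIGN" or s.sv_type == "INS" for s in specs)
        assert any(s.mechanism == "FOREIGN" for s in specs)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            plan_events(5, type_weights={t: 0.0 for t in
                        ("INS", "DEL", "INV", "TDUP", "CTX_BAL", "CTX_UNBAL", "ITX")})

    def test_uniform_type_frequencies_multinomial(self):
        n = 10_000
        specs = plan_events(n, type_weights=None, seed=4)
        counts = {}
        for s in specs:
            counts[s.sv_type] = counts.get(s.sv_type, 0) + 1
        lo, hi = binom_interval(n, 1 / 7, alpha=0.001 / 7)
        for t in ("INS", "DEL", "INV", "TDUP", "CTX_BAL", "CTX_UNBAL", "ITX"):
            assert lo <= counts.get(t, 0) <= hi

    def test_deterministic(self):
        assert plan_events(20, seed=7) == plan_events(20, seed=7)


class TestJunctionHomologyOracle:
    def test_blunt_junction(self):
        assert junction_homology("AAAATTTT", 4, ("CCCC", "GGGG")) == 0

    def test_engineered_forward_tract(self):
        lc = "GATTACAGAT"
        seq = "CCCC" + lc[:7] + "T" + "CCCC"
        assert seq[4 + 7] != lc[7]
        assert junction_homology(seq, 4, (lc, "GGGG")) == 7

    def test_backward_tract(self):
        rc = "ACGTACGT"
        seq = "TT" + rc[-3:] + "GGGG"  # last 3 bases before pos 5 match rc's tail
        assert junction_homology(seq, 5, ("TTTT", rc)) == 3

    def test_bounded_by_context_lengths(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            seq = random_sequence(40, 0.5, rng)
            lc = random_sequence(8, 0.5, rng)
            rc = random_sequence(5, 0.5, rng)
            h = junction_homology(seq, 20, (lc, rc))
            assert 0 <= h <= max(len(lc), len(rc))


class TestNonHomologousPlacement:
    TYPES = ("DEL", "INV", "TDUP", "INS", "ITX", "CTX_BAL", "CTX_UNBAL")

    def test_microhomology_engineered_and_bounded(self, diploid_model):
        rng = np.random.default_rng(11)
        model = diploid_model
        n_checked = 0
        for i in range(60):
            t = self.TYPES[i % len(self.TYPES)]
            spec = SVEventSpec(t, "NONHOM", int(rng.integers(1000, 2500)))
            try:
                ev = place_nonhomologous(model, spec, rng)
            except PlacementError:
                continue
            ev.event_id = f"e{i}"
            apply_event(model, ev, rng)
            for bp in ev.breakpoints:
                if not (bp.left_context or bp.right_context):
                    continue  # broken end, not a junction
                seq = model.get(bp.copy_id).sequence
                h = junction_homology(seq, bp.position, (bp.left_context, bp.right_context))
                assert h == len(bp.microhomology)
                assert h <= MAX_MICROHOM
                n_checked += 1
        assert n_checked >= 60

    def test_deletion_respects_size(self, diploid_model):
        rng = np.random.default_rng(5)
        spec = SVEventSpec("DEL", "NONHOM", 5000)
        ev = place_nonhomologous(diploid_model, spec, rng)
        a, b = ev.interval
        assert b - a == 5000
        assert 0 < a < b < len(diploid_model.get(ev.copy_id))

    def test_base_count_ledger_per_event(self, diploid_model):
        rng = np.random.default_rng(23)
        model = diploid_model
        sign = {"DEL": -1, "TDUP": +1, "INS": +1, "CTX_UNBAL": -1,
                "INV": 0, "ITX": 0, "CTX_BAL": 0}
        for i, t in enumerate(self.TYPES * 3):
            spec = SVEventSpec(t, "NONHOM", int(rng.integers(1000, 3000)))
            before = model.total_bases()
            try:
                ev = place_nonhomologous(model, spec, rng)
            except PlacementError:
                continue
            apply_event(model, ev, rng)
            expected = sign[t] * (ev.size_realized or 0)
            assert model.total_bases() - before == expected

    def test_stale_coordinates_rejected(self, diploid_model):
        rng = np.random.default_rng(31)
        model = diploid_model
        spec = SVEventSpec("DEL", "NONHOM", 2000)
        for _ in range(50):
            e1 = place_nonhomologous(model, spec, rng)
            e2 = place_nonhomologous(model, spec, rng)
            if e1.copy_id == e2.copy_id:
                apply_event(model, e1, rng)
                with pytest.raises(StaleEventError):
                    apply_event(model, e2, rng)
                return
        pytest.fail("never drew two placements on the same copy")


class TestForeignInsertion:
    def test_no_shared_30mer_with_either_strand(self):
        rng = np.random.default_rng(2)
        seq = random_sequence(100_000, 0.5, rng)
        model = mini_model(seq)
        payload = make_foreign_insertion(1000, model, rng)
        ref_kmers = string_kmers(seq, 30) | string_kmers(revcomp(seq), 30)
        assert not (string_kmers(payload, 30) & ref_kmers)

    def test_single_base_is_trivially_novel(self):
        model = mini_model("ACGT" * 100)
        payload = make_foreign_insertion(1, model, np.random.default_rng(0))
        assert len(payload) == 1

    def test_deterministic_under_seed(self):
        model = mini_model("ACGT" * 1000)
        a = make_foreign_insertion(500, model, np.random.default_rng(7))
        b = make_foreign_insertion(500, model, np.random.default_rng(7))
        assert a == b


def planted_model(element_specs, elem_len=400, seq_len=30_000, seed=5, divergence=0.05):
    """Reference with repeat elements implanted at controlled strands/positions.

    ``element_specs``: list of (chrom_idx, start, strand) tuples, one family.
    """
    rng = np.random.default_rng(seed)
    n_chroms = max(c for c, _, _ in element_specs) + 1
    seqs = [bytearray(random_sequence(seq_len, 0.5, rng), "ascii") for _ in range(n_chroms)]
    cons = random_sequence(elem_len, 0.5, rng)
    elements = []
    for k, (ci, start, strand) in enumerate(element_specs):
        copy = list(cons)
        for i in range(elem_len):
            if rng.random() < divergence:
                copy[i] = "ACGT"[rng.integers(4)]
        copy = "".join(copy)
        if strand == "-":
            copy = revcomp(copy)
        seqs[ci][start : start + elem_len] = copy.encode()
        elements.append(RepeatElement(f"T{ci}", start, start + elem_len, strand, "fam", f"fam.{k}"))
    ref = ReferenceGenome([(f"T{i}", s.decode()) for i, s in enumerate(seqs)])
    pg = apply_germline(ref, [])
    model = initial_model(pg)
    return model, RepeatCatalog(elements, consensus={"fam": cons})


class TestHomologousPlacement:
    def test_deletion_between_same_strand_elements(self):
        model, cat = planted_model([(0, 5000, "+"), (0, 20000, "+")])
        rng = np.random.default_rng(1)
        spec = SVEventSpec("DEL", "HOM", 5000)
        ev = place_homologous(model, cat, spec, rng, min_shared=200)
        a, b = ev.interval
        e1, e2 = ev.mediating_elements
        assert 5000 <= a <= 5400 and 20000 <= b <= 20400
        assert (e1.name, e2.name) == ("fam.0", "fam.1")
        apply_event(model, ev, rng)

    def test_strand_rule_inversion_needs_opposite(self):
        model, cat = planted_model([(0, 5000, "+"), (0, 20000, "+")])
        rng = np.random.default_rng(2)
        with pytest.raises(PlacementError):
            place_homologous(model, cat, SVEventSpec("INV", "HOM", 5000), rng,
                             min_shared=200)
        # and with an opposite-strand pair, inversion works but deletion fails
        model2, cat2 = planted_model([(0, 5000, "+"), (0, 20000, "-")])
        ev = place_homologous(model2, cat2, SVEventSpec("INV", "HOM", 5000),
                              np.random.default_rng(3), min_shared=200)
        assert ev.interval is not None
        with pytest.raises(PlacementError):
            place_homologous(model2, cat2, SVEventSpec("DEL", "HOM", 5000),
                             np.random.default_rng(4), min_shared=200)

    @pytest.mark.parametrize("strands,svtype", [
        (("+", "+"), "DEL"),
        (("-", "-"), "DEL"),
        (("+", "-"), "INV"),
        (("+", "+"), "TDUP"),
    ])
    def test_junction_is_homologous_to_consensus(self, strands, svtype):
        model, cat = planted_model([(0, 5000, strands[0]), (0, 20000, strands[1])])
        rng = np.random.default_rng(6)
        ev = place_homologous(model, cat, SVEventSpec(svtype, "HOM", 5000), rng,
                              min_shared=200)
        apply_event(model, ev, rng)
        cons = cat.consensus["fam"]
        aligner = Align.PairwiseAligner(mode="local", match_score=1,
                                        mismatch_score=-1, open_gap_score=-2,
                                        extend_gap_score=-2)
        for bp in ev.breakpoints:
            seq = model.get(bp.copy_id).sequence
            window = seq[max(0, bp.position - 100) : bp.position + 100]
            score = max(aligner.score(window, cons), aligner.score(window, revcomp(cons)))
            # a ~200 bp junction window should align to the family consensus
            # as one high-identity homologous tract
            assert score >= 120

    def test_translocation_needs_elements_on_distinct_chromosomes(self):
        model, cat = planted_model([(0, 5000, "+"), (1, 9000, "+")])
        rng = np.random.default_rng(8)
        ev = place_homologous(model, cat, SVEventSpec("CTX_BAL", "HOM", 5000), rng,
                              min_shared=200)
        assert model.get(ev.copy_id).chrom != model.get(ev.partner_copy_id).chrom
        apply_event(model, ev, rng)
        # same-chromosome-only catalog cannot host a translocation
        model2, cat2 = planted_model([(0, 5000, "+"), (0, 20000, "+")])
        with pytest.raises(PlacementError):
            place_homologous(model2, cat2, SVEventSpec("CTX_BAL", "HOM", 5000),
                             np.random.default_rng(9), min_shared=200)

    def test_itx_advises_fallback(self, diploid_model, small_catalog):
        with pytest.raises(PlacementError, match="fall back"):
            place_homologous(diploid_model, small_catalog,
                             SVEventSpec("ITX", "HOM", 1000),
                             np.random.default_rng(0))

    def test_realize_spec_falls_back_when_no_pair(self):
        model = mini_model(random_sequence(20_000, 0.5, np.random.default_rng(3)))
        cat = RepeatCatalog([])
        rng = np.random.default_rng(10)
        ev = realize_spec(model, SVEventSpec("DEL", "HOM", 2000), rng, catalog=cat,
                          event_id="x")
        assert ev.applied
        assert ev.spec.mechanism == "NONHOM"
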