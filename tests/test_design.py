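"""Primer grammar: construction, parsing, junction arithmetic, QC."""

import random

import pytest

from adrecon.design import (AnchorPair, PrimerSpec, default_anchors,
                            design_deletion_primers, design_primer_pairs,
                            junction_overlap, parse_primer, plan_partition,
                            tm, validate_plan)
from adrecon.errors import DesignError, PlanningError
from adrecon.insilico import gibson, pcr
from adrecon.seqcore import NucSeq, Span, revcomp
from adrecon.synthfix import released_cassette

from conftest import random_clean_bases


class TestJunctionOverlap:
    """String arithmetic on the reference fragment-junction primers."""

    @pytest.mark.parametrize("rev,fwd,seed,overlap", [
        ("ADV-1-R", "ADV-2-F", 19, 40),
        ("ADV-3-R", "ADV-4-F", 21, 40),
        ("ADV-5-R", "ADV-6-F", 16, 35),
    ])
    def test_reference_junctions(self, bundle, rev, fwd, seed, overlap):
        r, f = bundle.table1[rev], bundle.table1[fwd]
        assert junction_overlap(r, f) == overlap == len(r) + len(f) - seed

    def test_all_reference_overlaps_inside_design_window(self, bundle):
        ovs = [junction_overlap(bundle.table1[f"ADV-{i}-R"],
                                bundle.table1[f"ADV-{i + 1}-F"])
               for i in (1, 3, 5)]
        assert min(ovs) == 35 and max(ovs) == 40
        assert all(30 <= o <= 40 for o in ovs)

    def test_unrelated_primers_raise(self, bundle):
        with pytest.raises(DesignError):
            junction_overlap(bundle.table1["ADV-1-R"], bundle.table1["ADV-6-F"])


class TestAnchors:
    def test_default_anchor_sequences(self, bundle):
        a = default_anchors()
        assert (a.upstream, a.downstream) == bundle.anchors
        assert len(a.upstream) == len(a.downstream) == 25

    def test_bad_anchor_length_rejected(self):
        with pytest.raises(DesignError):
            AnchorPair("ACGT", "ACGT")

    @pytest.mark.parametrize("name", ["ADV-1-F", "ADV-3-F", "ADV-5-F"])
    def test_forward_primers_carry_full_upstream_anchor(self, bundle, name):
        assert bundle.table1[name].startswith(bundle.anchors[0])

    @pytest.mark.parametrize("name", ["ADV-2-R", "ADV-4-R", "ADV-6-R"])
    def test_reverse_primers_carry_downstream_anchor_rc(self, bundle, name):
        assert bundle.table1[name].startswith(revcomp(bundle.anchors[1]))


class TestParsePrimer:
    def test_fused_noti_forward_primer(self, bundle):
        p = parse_primer(bundle.table1["ADV-1-F"])
        assert p.anchor_kind == "upstream"
        assert p.re_name == "NotI"
        assert p.re_span == (24, 31)      # overlaps the anchor's final GC
        assert len(p.anneal) == 31

    @pytest.mark.parametrize("name,re_name", [
        ("ADV-2-R", "EcoRI"), ("ADV-4-R", "EcoRV"), ("ADV-6-R", "ClaI")])
    def test_reverse_release_sites(self, bundle, name, re_name):
        p = parse_primer(bundle.table1[name])
        assert p.anchor_kind == "downstream_rc" and p.re_name == re_name

    def test_internal_primer_fully_genomic(self, bundle):
        p = parse_primer(bundle.table1["ADV-2-F"])
        assert p.anchor is None and p.re_name is None
        assert p.role == "internal_fwd"
        assert p.anneal == bundle.table1["ADV-2-F"]

    def test_deletion_primer_sapi_position(self, bundle):
        p = parse_primer(bundle.table2["ADV14forLG-F"])
        assert p.re_name == "SapI"
        assert p.re_span == (4, 10)       # GCTCTTC after the 3-nt pad
        assert p.pad == "ATC"
        assert p.role == "deletion_fwd"

    def test_subclone_primers(self, bundle):
        f = parse_primer(bundle.table2["ADV-5-F'"])
        r = parse_primer(bundle.table2["ADV-5-R'"])
        assert (f.re_name, f.role) == ("NotI", "subclone_fwd")
        assert r.re_name == "SrfI"

    def test_too_short_rejected(self):
        with pytest.raises(DesignError):
            parse_primer("ACGTACGT")


class TestTm:
    def test_wallace_rule_below_14(self):
        assert tm("ACGT" * 3) == 2 * 6 + 4 * 6  # 12 nt, 6 GC

    def test_gc_formula_at_20(self):
        assert tm("G" * 20) == pytest.approx(64.9 + 41 * (20 - 16.4) / 20)

    def test_too_short(self):
        with pytest.raises(DesignError):
            tm("ACGTAC")


class TestPlanPartition:
    def test_six_fragment_plan(self, plan):
        assert len(plan.fragments) == 6
        assert all(30 <= o <= 40 for o in plan.junction_overlaps())
        assert all(30 <= o <= 40 for o in plan.arm_overlaps())
        lens = [s.end - s.start + 1 for s in plan.fragments]
        assert max(lens) - min(lens) <= 0.10 * max(lens)
        # coverage: fragment 1 starts inside the left arm, 6 ends in the right
        assert plan.fragments[0].start <= plan.left_arm.end
        assert plan.fragments[-1].end >= plan.right_arm.start

    def test_two_fragment_toy_splits_near_midpoint(self):
        rng = random.Random(1)
        g = NucSeq("toy", random_clean_bases(rng, 1000))
        plan = plan_partition(g, (Span(1, 100), Span(901, 1000)), 2)
        assert len(plan.fragments) == 2
        mid = (plan.fragments[0].end + plan.fragments[1].start) / 2
        assert abs(mid - 500) < 120

    def test_saturated_genome_raises(self, enzymes):
        rng = random.Random(2)
        # every ~40 bp an EcoRI site: release digest cannot avoid the insert
        unit = lambda: random_clean_bases(rng, 34, avoid=("GAATTC",)) + "GAATTC"
        g = NucSeq("sat", "".join(unit() for _ in range(100)))
        rel = [(enzymes["NotI"], enzymes["EcoRI"])]
        with pytest.raises(PlanningError):
            plan_partition(g, (Span(1, 400), Span(3601, 4000)), 2, rel,
                           overlap_range=(30, 40))

    def test_odd_fragment_count_rejected(self, genome):
        with pytest.raises(PlanningError):
            plan_partition(genome, (Span(1, 2566), Span(34616, 34776)), 5)


class TestDesignParseRoundTrip:
    def test_designed_primers_reparse_exactly(self, genome, plan, primers):
        for p in primers:
            q = parse_primer(p.bases, genome=genome)
            assert q.anneal == p.anneal, p.name
            got = q.anneal_span_genome
            want = p.anneal_span_genome
            assert (got.start, got.end, got.strand) == \
                (want.start, want.end, want.strand), p.name

    def test_designed_overlaps_match_plan(self, plan, primers):
        by_name = {p.name: p for p in primers}
        for j in (0, 2, 4):
            ov = junction_overlap(by_name[f"ADV-{j + 1}-R"].bases,
                                  by_name[f"ADV-{j + 2}-F"].bases)
            assert ov == plan.junction_overlaps()[j]
            assert 30 <= ov <= 40

    def test_round_trip_on_fresh_seeds(self, enzymes):
        from adrecon.synthfix import SynthGenomeSpec, synth_genome
        from adrecon.workflow import WORKFLOW_FORBIDDEN
        for seed in (101, 202):
            g = synth_genome(SynthGenomeSpec(forbidden=list(WORKFLOW_FORBIDDEN),
                                             seed=seed))
            rel = [(enzymes["NotI"], enzymes["EcoRI"]),
                   (enzymes["NotI"], enzymes["EcoRV"]),
                   (enzymes["NotI"], enzymes["ClaI"])]
            plan = plan_partition(g, (Span(1, 2566), Span(34616, 34776)), 6, rel)
            for p in design_primer_pairs(g, plan):
                q = parse_primer(p.bases, genome=g)
                assert q.anneal == p.anneal, (seed, p.name)


class TestDeletionPrimers:
    def test_inverse_pcr_deletes_exactly_the_interval(self, cassette_donor):
        rng = random.Random(42)
        cassette = released_cassette(cassette_donor)
        body = random_clean_bases(rng, 3000, avoid=("GCTCTTC", "GAGAAGC"))
        plasmid = NucSeq("toy5", body, "circular")
        span = Span(1001, 2000)
        f, r = design_deletion_primers(
            plasmid, span, cassette_ends=(cassette.bases[:24], cassette.bases[-24:]))
        amp = pcr(plasmid, f, r)
        kept = body[2000:] + body[:1000]
        assert kept in amp.bases
        assert len(amp) == len(kept) + f.bases.__len__() - len(f.anneal) \
            + len(r.bases) - len(r.anneal)
        # joining cassette and amplicon restores plasmid - span + cassette
        prod = gibson([amp.to_nucseq("del"), cassette], expect="circular",
                      end_slack=16)
        assert len(prod.seq) == len(plasmid) - span.length(len(plasmid)) + len(cassette)

    def test_parse_finds_sapi_in_designed_primer(self, cassette_donor):
        rng = random.Random(43)
        cassette = released_cassette(cassette_donor)
        plasmid = NucSeq("toy5", random_clean_bases(rng, 2500,
                                                    avoid=("GCTCTTC", "GAGAAGC")),
                         "circular")
        f, _ = design_deletion_primers(
            plasmid, Span(500, 900),
            cassette_ends=(cassette.bases[:24], cassette.bases[-24:]))
        parsed = parse_primer(f.bases)
        assert parsed.re_name == "SapI" and parsed.role == "deletion_fwd"

    def test_short_cassette_ends_rejected(self):
        plasmid = NucSeq("p", "ACGT" * 200, "circular")
        with pytest.raises(DesignError):
            design_deletion_primers(plasmid, Span(100, 200),
                                    cassette_ends=("ACGT", "ACGT"))


class TestValidatePlan:
    def test_designed_plan_passes(self, genome, plan, primers):
        rep = validate_plan(genome, primers, plan)
        assert rep.passed, str(rep)

    def test_reference_primer_junctions_pass_against_table(self, bundle):
        """The reference primers validate as a set: overlaps {40, 40, 35}."""
        ovs = {}
        for i in (1, 3, 5):
            ovs[i] = junction_overlap(bundle.table1[f"ADV-{i}-R"],
                                      bundle.table1[f"ADV-{i + 1}-F"])
        assert sorted(ovs.values(), reverse=True) == [40, 40, 35]

    def test_corrupted_anchor_fails_naming_the_primer(self, genome, plan, primers):
        mutated = []
        for p in primers:
            bases = p.bases
            if p.name == "ADV-5-F":
                bases = "T" + bases[1:]   # break anchor base 1
            mutated.append(PrimerSpec(p.name, bases, p.role,
                                      anneal_span_primer=p.anneal_span_primer,
                                      anneal_span_genome=p.anneal_span_genome))
        rep = validate_plan(genome, mutated, plan)
        assert not rep.passed
        failing = {r.subject for r in rep.rows if r.status == "FAIL"}
        assert "ADV-5-F" in failing

    def test_duplicated_anneal_site_fails_uniqueness(self, genome, plan, primers):
        dup = primers[2].anneal  # ADV-2-F genomic anneal
        g2 = NucSeq("dup", genome.bases + dup, "linear")
        rep = validate_plan(g2, primers, plan)
        bad = [r for r in rep.rows
               if r.check == "anneal_unique" and r.status == "FAIL"]
        assert any(r.subject == "ADV-2-F" for r in bad)
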