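"""Reaction simulators: PCR, ligation, isothermal assembly."""

import random

import pytest

from adrecon.errors import (AmbiguousAssemblyError, LigationError,
                            MisprimingError, NoAmplificationError,
                            NoSolutionError, OrientationError, UncutError)
from adrecon.insilico import gibson, ligate, linearize, pcr
from adrecon.restriction import digest
from adrecon.seqcore import NucSeq, canonical_equal, revcomp

from conftest import random_clean_bases


class TestPcr:
    def _toy(self, rng, tail_f="GGG", tail_r="TT"):
        F = random_clean_bases(rng, 22)
        mid = random_clean_bases(rng, 40)
        R = random_clean_bases(rng, 22)
        tpl = NucSeq("tpl", random_clean_bases(rng, 15) + F + mid + R
                     + random_clean_bases(rng, 15))
        return tpl, tail_f + F, tail_r + revcomp(R), F + mid + R

    def test_tailed_amplicon_length_and_content(self):
        rng = random.Random(1)
        tpl, fwd, rev, inner = self._toy(rng)
        amp = pcr(tpl, fwd, rev)
        assert amp.bases == "GGG" + inner + "AA"   # rc of the 2-nt rev tail
        assert len(amp) == len(inner) + 3 + 2
        assert (amp.fwd_tail, amp.rev_tail) == (3, 2)

    def test_tail_free_primers_on_termini_reproduce_template(self):
        rng = random.Random(2)
        s = random_clean_bases(rng, 120)
        tpl = NucSeq("t", s)
        amp = pcr(tpl, s[:20], revcomp(s[-20:]))
        assert amp.bases == s

    def test_inverse_pcr_on_circle_matches_rotation_oracle(self):
        rng = random.Random(3)
        keep = random_clean_bases(rng, 300)
        drop = random_clean_bases(rng, 80)
        ring = NucSeq("ring", keep + drop, "circular")
        amp = pcr(ring, keep[:25], revcomp(keep[-25:]))
        # oracle: rotate so the kept arc is contiguous, then slice
        assert amp.bases == (ring.bases + ring.bases)[0:300]
        for k in (10, 200):  # rotation invariance of the product
            assert pcr(ring.rotated(k), keep[:25], revcomp(keep[-25:])).bases == keep

    def test_no_annealing_site(self):
        rng = random.Random(4)
        tpl = NucSeq("t", random_clean_bases(rng, 100))
        with pytest.raises(NoAmplificationError):
            pcr(tpl, "A" * 25, revcomp(tpl.bases[-20:]))

    def test_mispriming_on_duplicated_site(self):
        rng = random.Random(5)
        site = random_clean_bases(rng, 25)
        tpl = NucSeq("t", site + random_clean_bases(rng, 50) + site
                     + random_clean_bases(rng, 50))
        with pytest.raises(MisprimingError):
            pcr(tpl, site, revcomp(tpl.bases[-20:]))

    def test_divergent_on_linear_is_orientation_error(self):
        rng = random.Random(6)
        s = random_clean_bases(rng, 200)
        with pytest.raises(OrientationError):
            pcr(NucSeq("t", s), s[150:175], revcomp(s[25:50]))


class TestLigate:
    def test_incompatible_chemistry_no_join(self, enzymes):
        rng = random.Random(7)
        s = random_clean_bases(rng, 200, avoid=("GCGGCCGC", "GCCCGGGC"))
        a = digest(NucSeq("a", s[:60] + "GCGGCCGC" + s[60:100]), enzymes["NotI"])[0]
        b = digest(NucSeq("b", s[100:140] + "GCCCGGGC" + s[140:]), enzymes["SrfI"])[1]
        with pytest.raises(LigationError):
            ligate([a, b], circularize=False)

    def test_vector_insert_orientation_forced_by_asymmetric_ends(self, enzymes):
        rng = random.Random(8)
        avoid = ("GCGGCCGC", "GCCCGGGC")
        vec_body = random_clean_bases(rng, 400, avoid)
        ins_body = random_clean_bases(rng, 250, avoid)
        vec = NucSeq("vec", "GCGGCCGC" + vec_body + "GCCCGGGC", "circular")
        ins = NucSeq("ins", "GCGGCCGC" + ins_body + "GCCCGGGC", "circular")
        vfrag = digest(vec, [enzymes["NotI"], enzymes["SrfI"]])
        ifrag = digest(ins, [enzymes["NotI"], enzymes["SrfI"]])
        big_v = max(vfrag, key=len)
        big_i = max(ifrag, key=len)
        prods = ligate([big_v, big_i], circularize=True, allow_blunt=True,
                       enumerate_all=True)
        assert len(prods) == 1  # one sticky + one blunt end: single orientation
        assert ins_body in prods[0].bases or ins_body in revcomp(prods[0].bases)

    def test_religation_of_single_cut_plasmid(self, enzymes):
        rng = random.Random(9)
        body = random_clean_bases(rng, 300, avoid=("GAATTC",))
        plas = NucSeq("p", "GAATTC" + body, "circular")
        frags = digest(plas, enzymes["EcoRI"])
        prods = ligate(frags, circularize=True, enumerate_all=True)
        assert any(canonical_equal(p, plas) for p in prods)


class TestGibson:
    def test_two_fragments_sharing_both_termini(self):
        rng = random.Random(10)
        o1, o2 = random_clean_bases(rng, 20), random_clean_bases(rng, 20)
        A = o1 + random_clean_bases(rng, 60) + o2
        B = o2 + random_clean_bases(rng, 60) + o1
        prod = gibson([A, B], expect="circular")
        assert len(prod.seq) == 160
        assert sorted(j.overlap for j in prod.junctions) == [20, 20]

    def test_order_and_orientation_invariance(self):
        rng = random.Random(11)
        plasmid = random_clean_bases(rng, 900)
        cuts = sorted(rng.sample(range(900), 4))
        pieces = []
        for i in range(4):
            s, e = cuts[i], cuts[(i + 1) % 4]
            arc = plasmid[s:e] if e > s else plasmid[s:] + plasmid[:e]
            pieces.append(arc + (plasmid + plasmid)[e:e + rng.randint(15, 60)])
        ref = gibson(pieces, expect="circular").seq.bases
        for trial in range(4):
            shuffled = pieces[:]
            rng.shuffle(shuffled)
            shuffled = [revcomp(p) if rng.random() < 0.5 else p for p in shuffled]
            assert gibson(shuffled, expect="circular").seq.bases == ref

    @pytest.mark.parametrize("k", [2, 3, 4, 6])
    def test_reassembly_identity_for_synthetic_splits(self, k):
        """Splitting any circle into overlapping pieces reassembles it."""
        rng = random.Random(100 + k)
        plasmid = random_clean_bases(rng, 400 * k)
        # pieces must be longer than the overlap extension: keep cuts apart
        while True:
            cuts = sorted(rng.sample(range(len(plasmid)), k))
            gaps = [(cuts[(i + 1) % k] - cuts[i]) % len(plasmid) for i in range(k)]
            if min(gaps) > 130:
                break
        pieces = []
        for i in range(k):
            s, e = cuts[i], cuts[(i + 1) % k]
            arc = plasmid[s:e] if e > s else plasmid[s:] + plasmid[:e]
            pieces.append(arc + (plasmid + plasmid)[e:e + rng.randint(15, 60)])
        prod = gibson(pieces, expect="circular")
        assert canonical_equal(prod.seq, NucSeq("p", plasmid, "circular"))
        # product length law: |product| = sum(|pieces|) - sum(overlap+trims)
        used = sum(j.overlap + j.trimmed_left + j.trimmed_right
                   for j in prod.junctions)
        assert len(prod.seq) == sum(map(len, pieces)) - used

    def test_repeated_overlap_is_ambiguous(self):
        # every terminus carries the same overlap: two distinct circular
        # orders (a-b-c and a-c-b) both close, which must be rejected
        rng = random.Random(12)
        o = random_clean_bases(rng, 25)
        a = o + random_clean_bases(rng, 80) + o
        b = o + random_clean_bases(rng, 80) + o
        c = o + random_clean_bases(rng, 80) + o
        with pytest.raises(AmbiguousAssemblyError):
            gibson([a, b, c], expect="circular")

    def test_undersized_overlap_reports_near_miss(self):
        rng = random.Random(13)
        o = random_clean_bases(rng, 10)  # below min_overlap=15
        a = random_clean_bases(rng, 60) + o
        b = o + random_clean_bases(rng, 60)
        with pytest.raises(NoSolutionError, match="best overlap seen: 10"):
            gibson([a, b], expect="linear")

    def test_scarred_termini_are_chewed_back(self):
        """Restriction-site remnants outside the homology do not block joining."""
        rng = random.Random(14)
        core = random_clean_bases(rng, 200)
        left = random_clean_bases(rng, 120) + core[:35] + "G"       # EcoRI scar
        right = "GGCCGC" + core[:60] + random_clean_bases(rng, 120)  # NotI scar
        prod = gibson([left, right], expect="linear")
        j = prod.junctions[0]
        assert j.overlap >= 35
        assert j.trimmed_left + j.trimmed_right <= 7   # at most the two scars
        assert core[:60] in prod.seq.bases
        assert len(prod.seq) == (len(left) + len(right)
                                 - j.overlap - j.trimmed_left - j.trimmed_right)

    def test_disconnected_fragments_fail(self):
        rng = random.Random(15)
        with pytest.raises(NoSolutionError):
            gibson([random_clean_bases(rng, 100),
                    random_clean_bases(rng, 100)], expect="any")


class TestLinearize:
    def test_single_cut_opens_circle(self, enzymes):
        rng = random.Random(16)
        body = random_clean_bases(rng, 200, avoid=("GTTTAAAC",))
        plas = NucSeq("p", "GTTTAAAC" + body, "circular")
        frag = linearize(plas, enzymes["PmeI"])
        assert len(frag) == len(plas)

    def test_double_cut_keeps_selected_piece(self, enzymes):
        rng = random.Random(17)
        avoid = ("GCTCTTC", "GAGAAGC")
        big = random_clean_bases(rng, 500, avoid)
        stuffer = random_clean_bases(rng, 40, avoid)
        plas = NucSeq("p", "GCTCTTC" + stuffer + "GCTCTTC" + big, "circular")
        kept = linearize(plas, enzymes["SapI"], keep="largest")
        # SapI cuts 1 nt downstream of each recognition: the kept piece is
        # the big region (shifted by the 1-nt offset), the stuffer discarded
        assert big[1:] in kept.bases
        assert stuffer not in kept.bases

    def test_absent_enzyme_raises(self, enzymes):
        with pytest.raises(UncutError):
            linearize(NucSeq("p", "ACGT" * 30, "circular"), enzymes["PmeI"])
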