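"""Genome partitioning and the tailed-primer grammar.

A large linear dsDNA genome is split into an even number of ~6-kb fragments
between two synthesized terminal "arms".  Adjacent fragments share a 30-40 bp
genomic overlap so that pairs can be fused by isothermal assembly; the pairs
are cloned into a vector and later released by a NotI + second-enzyme digest.
Primers come in two grammars:

* vector-adjacent: 25-bp vector anchor + restriction-site tail + genomic
  anneal (>=25 nt).  In the forward primers the NotI recognition *fuses* with
  the anchor's terminal GC (anchor ...AATTGC + GGCCGC reconstitutes
  GCGGCCGC), so the parser tolerates a <=2 nt anchor/site overlap and the
  designer reproduces it.
* internal-junction: fully genomic; the two primers of a junction overlap on
  the genome so that |rev| + |fwd| - seed equals the planned 30-40 bp
  amplicon overlap.

A third grammar covers inverse-PCR deletion primers (E3 replacement): short
pad + SapI recognition + spacer + cassette-matching tail + genomic anneal.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

from .errors import DesignError, PlanningError, PrimerResolutionError
from .restriction import Enzyme, find_sites, get_enzyme
from .seqcore import NucSeq, Span, revcomp

__all__ = [
    "AnchorPair", "PartitionPlan", "PrimerSpec", "ParsedPrimer",
    "default_anchors", "plan_partition", "design_primer_pairs",
    "parse_primer", "junction_overlap", "tm", "design_deletion_primers",
    "validate_plan", "read_primers_tsv", "write_primers_tsv",
]

PRIMER_ROLES = (
    "vector_adjacent_fwd", "vector_adjacent_rev", "internal_fwd",
    "internal_rev", "subclone_fwd", "subclone_rev", "deletion_fwd",
    "deletion_rev",
)


@dataclass(frozen=True)
class AnchorPair:
    """The two 25-bp vector-homologous primer prefixes."""

    upstream: str = "AGGCCCTTTCGTCTTCAAGAATTGC"
    downstream: str = "GGGCGACGCGAGGCTGGATGGCCTT"

    def __post_init__(self) -> None:
        if len(self.upstream) != 25 or len(self.downstream) != 25:
            raise DesignError("anchors must be exactly 25 nt")


def default_anchors() -> AnchorPair:
    text = resources.files("adrecon.data").joinpath("anchors.tsv").read_text()
    rows = {r["name"]: r["sequence"]
            for r in csv.DictReader(text.splitlines(), delimiter="\t")}
    return AnchorPair(rows["upstream"], rows["downstream"])


@dataclass
class PartitionPlan:
    left_arm: Span
    right_arm: Span
    fragments: list[Span]
    pairings: list[tuple[int, int]]
    release_enzymes: list[tuple[Enzyme, Enzyme]]
    junction_overlap_range: tuple[int, int] = (30, 40)
    vector_cut_enzymes: tuple[Enzyme, Enzyme] = None  # set in plan_partition

    def junction_overlaps(self) -> list[int]:
        """Genomic overlap at each of the n-1 inter-fragment junctions."""
        return [self.fragments[i].end - self.fragments[i + 1].start + 1
                for i in range(len(self.fragments) - 1)]

    def arm_overlaps(self) -> tuple[int, int]:
        return (self.left_arm.end - self.fragments[0].start + 1,
                self.fragments[-1].end - self.right_arm.start + 1)


@dataclass
class PrimerSpec:
    name: str
    bases: str
    role: str
    anchor_span: tuple[int, int] | None = None   # 1-based inclusive, primer coords
    re_name: str | None = None
    re_span: tuple[int, int] | None = None
    cassette_span: tuple[int, int] | None = None
    anneal_span_primer: tuple[int, int] | None = None
    anneal_span_genome: Span | None = None       # on the target, strand-aware

    def __post_init__(self) -> None:
        if self.role not in PRIMER_ROLES:
            raise DesignError(f"unknown primer role {self.role!r}")

    @property
    def anneal(self) -> str:
        if self.anneal_span_primer is None:
            return self.bases
        s, e = self.anneal_span_primer
        return self.bases[s - 1:e]


# ---------------------------------------------------------------------------
# Melting temperature
# ---------------------------------------------------------------------------

def tm(bases: str) -> float:
    """Primer melting temperature, degrees C.

    Wallace rule 2(A+T)+4(G+C) below 14 nt, otherwise the GC-fraction formula
    64.9 + 41*(GC - 16.4)/N.  Deliberately simple and deterministic; the
    package needs a reproducible ranking, not thermodynamic accuracy.
    """
    if len(bases) < 8:
        raise DesignError(f"primer too short for tm: {len(bases)} nt")
    gc = sum(bases.count(c) for c in "GC")
    if len(bases) < 14:
        return 2.0 * (len(bases) - gc) + 4.0 * gc
    return 64.9 + 41.0 * (gc - 16.4) / len(bases)


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------

def _count_matches(genome: str, probe: str) -> int:
    """Exact occurrences of ``probe`` on either strand."""
    n, i = 0, 0
    for hay in (genome,):
        for needle in (probe, revcomp(probe)):
            i = hay.find(needle)
            while i != -1:
                n += 1
                i = hay.find(needle, i + 1)
    return n


def _window_unique(genome: str, start0: int, length: int) -> bool:
    return _count_matches(genome, genome[start0:start0 + length]) == 1


def plan_partition(genome: NucSeq, arms: tuple[Span, Span],
                   n_fragments: int = 6,
                   release_enzymes: list[tuple[Enzyme, Enzyme]] | None = None,
                   target_len: int = 6000,
                   overlap_range: tuple[int, int] = (30, 40),
                   search_window: int = 200,
                   anneal_len: int = 25) -> PartitionPlan:
    """Partition the inter-arm interval into overlapping fragment spans.

    Fragments are near-equal in length (spread <= 10%), every junction
    (including the two arm junctions) carries an overlap inside
    ``overlap_range``, no release enzyme cuts inside its own released insert,
    and every boundary's ``anneal_len``-bp windows are unique in the genome.
    Boundaries may shift by up to ``search_window`` bp to satisfy the site
    and uniqueness constraints.
    """
    if genome.circular:
        raise PlanningError("partitioning expects a linear genome")
    if n_fragments % 2 or n_fragments < 2:
        raise PlanningError("n_fragments must be even and >= 2")
    left, right = arms
    L = len(genome)
    left.validate(L, False)
    right.validate(L, False)
    if left.start != 1 or right.end != L:
        raise PlanningError("arms must sit at the genome termini")
    ov_lo, ov_hi = overlap_range
    ov = (ov_lo + ov_hi) // 2
    pairings = [(i, i + 1) for i in range(0, n_fragments, 2)]
    if release_enzymes is None:
        release_enzymes = [(None, None)] * len(pairings)
    if len(release_enzymes) != len(pairings):
        raise PlanningError("one release-enzyme pair per fragment pairing")

    s1 = left.end - ov + 1
    en = right.start + ov - 1
    total = en - s1 + 1
    if total < n_fragments * (2 * anneal_len + ov_lo):
        raise PlanningError("inter-arm region too short for requested split")

    # ideal interior boundaries, then per-boundary local adjustment
    edges = [s1 + round(i * (total / n_fragments)) for i in range(1, n_fragments)]

    def boundary_ok(e: int, j: int) -> bool:
        """Junction j: fragment j ends at e, fragment j+1 starts at e-ov+1."""
        nxt = e - ov + 1
        if nxt <= s1 or e >= en:
            return False
        # anneal windows flanking the junction must be unique on both strands
        return (_window_unique(genome.bases, e - anneal_len, anneal_len)
                and _window_unique(genome.bases, nxt - 1, anneal_len))

    placed: list[int] = []
    bad: list[int] = []
    for j, e0 in enumerate(edges):
        for delta in sorted(range(-search_window, search_window + 1), key=abs):
            if boundary_ok(e0 + delta, j):
                placed.append(e0 + delta)
                break
        else:
            bad.append(j + 1)
    if bad:
        raise PlanningError(f"no valid boundary near junctions {bad}")

    spans: list[Span] = []
    starts = [s1] + [e - ov + 1 for e in placed]
    ends = placed + [en]
    for s, e in zip(starts, ends):
        spans.append(Span(s, e))

    # release enzymes must not cut inside their released insert
    # (insert = paired fragments, boundaries adjustable within the window)
    for (a, b), (e1, e2) in zip(pairings, release_enzymes):
        if e1 is None:
            continue
        ins_s, ins_e = spans[a].start, spans[b].end
        region = NucSeq("ins", genome.bases[ins_s - 1:ins_e])
        offenders = [enz.name for enz in (e1, e2) if find_sites(region, enz)]
        if offenders:
            shifted = _shift_pair(genome, spans, a, b, (e1, e2), search_window, ov)
            if shifted is None:
                raise PlanningError(
                    f"release enzyme(s) {offenders} cut inside insert "
                    f"of fragments {a + 1}-{b + 1}")
            spans[a], spans[b] = shifted

    lens = [sp.end - sp.start + 1 for sp in spans]
    if (max(lens) - min(lens)) > 0.10 * max(lens):
        raise PlanningError(f"fragment length spread exceeds 10%: {lens}")

    return PartitionPlan(left, right, spans, pairings, release_enzymes,
                         overlap_range,
                         (get_enzyme("NotI"), get_enzyme("SbfI")))


def _shift_pair(genome, spans, a, b, pair, window, ov):
    """Try shrinking the pair's outer boundaries away from internal sites."""
    for delta in range(1, window + 1):
        s = spans[a].start + delta
        e = spans[b].end - delta
        if e - s < 2 * ov:
            return None
        region = genome.bases[s - 1:e]
        if not any(find_sites(NucSeq("r", region), enz) for enz in pair):
            return (Span(s, spans[a].end), Span(spans[b].start, e))
    return None


# ---------------------------------------------------------------------------
# Primer construction
# ---------------------------------------------------------------------------

def _fuse_site(prefix: str, recognition: str, max_fusion: int = 2) -> str:
    """Append ``recognition`` to ``prefix``, merging a <=2 nt suffix/prefix
    duplication (the anchor/NotI fusion seen in the reference primer set)."""
    for k in range(min(max_fusion, len(prefix), len(recognition)), 0, -1):
        if prefix.endswith(recognition[:k]):
            return prefix + recognition[k:]
    return prefix + recognition


def _extend_anneal(genome: str, start0: int, min_len: int, max_len: int,
                   tm_floor: float, reverse: bool) -> str:
    """Genomic anneal from a fixed 5' coordinate, grown 3'-ward to a Tm floor.

    ``reverse`` anneals are built on the minus strand ending at ``start0``
    (0-based index of the last top-strand base covered).
    """
    min_len = min(min_len, max_len)
    cand = ""
    for n in range(min_len, max_len + 1):
        if reverse:
            s = genome[start0 - n + 1: start0 + 1]
            cand = revcomp(s)
        else:
            cand = genome[start0: start0 + n]
        if len(cand) < n:
            break
        if tm(cand) >= tm_floor or n == max_len:
            return cand
    return cand


def design_primer_pairs(genome: NucSeq, plan: PartitionPlan,
                        anchors: AnchorPair | None = None,
                        fwd_site: Enzyme | None = None,
                        tm_floor: float = 58.0,
                        anneal_len: int = 25,
                        max_anneal: int = 35,
                        min_seed: int = 10) -> list[PrimerSpec]:
    """Forward and reverse primers for every fragment of ``plan``.

    Vector-adjacent primers carry anchor + restriction-site tails; the primers
    facing a within-pair junction are fully genomic with lengths chosen so the
    implied amplicon overlap equals the planned junction overlap.
    """
    anchors = anchors or default_anchors()
    fwd_site = fwd_site or get_enzyme("NotI")
    g = genome.bases
    primers: list[PrimerSpec] = []
    n = len(plan.fragments)
    overlaps = plan.junction_overlaps()

    for i, frag in enumerate(plan.fragments):
        pair_index = i // 2
        first_of_pair = i % 2 == 0
        rel = plan.release_enzymes[pair_index]
        # ---- forward primer
        if first_of_pair:
            anneal = _extend_anneal(g, frag.start - 1, anneal_len, max_anneal,
                                    tm_floor, reverse=False)
            tail = _fuse_site(anchors.upstream, fwd_site.recognition)
            bases = tail + anneal
            a_end = len(anchors.upstream)
            re_start = len(tail) - len(fwd_site.recognition) + 1
            primers.append(PrimerSpec(
                f"ADV-{i + 1}-F", bases, "vector_adjacent_fwd",
                anchor_span=(1, a_end), re_name=fwd_site.name,
                re_span=(re_start, len(tail)),
                anneal_span_primer=(len(tail) + 1, len(bases)),
                anneal_span_genome=Span(frag.start, frag.start + len(anneal) - 1)))
        else:
            ov = overlaps[i - 1]
            # cap at the junction overlap so the seed arithmetic stays exact
            anneal = _extend_anneal(g, frag.start - 1, anneal_len,
                                    min(max_anneal, ov), tm_floor, reverse=False)
            bases = anneal
            primers.append(PrimerSpec(
                f"ADV-{i + 1}-F", bases, "internal_fwd",
                anneal_span_primer=(1, len(bases)),
                anneal_span_genome=Span(frag.start, frag.start + len(bases) - 1)))
        # ---- reverse primer
        if not first_of_pair:
            rev_enz = rel[1] if rel[1] is not None else get_enzyme("EcoRI")
            anneal = _extend_anneal(g, frag.end - 1, anneal_len, max_anneal,
                                    tm_floor, reverse=True)
            tail = _fuse_site(revcomp(anchors.downstream), rev_enz.recognition)
            bases = tail + anneal
            re_start = len(tail) - len(rev_enz.recognition) + 1
            primers.append(PrimerSpec(
                f"ADV-{i + 1}-R", bases, "vector_adjacent_rev",
                anchor_span=(1, 25), re_name=rev_enz.name,
                re_span=(re_start, len(tail)),
                anneal_span_primer=(len(tail) + 1, len(bases)),
                anneal_span_genome=Span(frag.end - len(anneal) + 1, frag.end, "-")))
        else:
            ov = overlaps[i]
            anneal = _extend_anneal(g, frag.end - 1, anneal_len,
                                    min(max_anneal, ov), tm_floor, reverse=True)
            bases = anneal
            primers.append(PrimerSpec(
                f"ADV-{i + 1}-R", bases, "internal_rev",
                anneal_span_primer=(1, len(bases)),
                anneal_span_genome=Span(frag.end - len(bases) + 1, frag.end, "-")))

    # verify the grammar closes: seeds and implied overlaps, then uniqueness
    for j, (a, b) in enumerate(zip(plan.fragments, plan.fragments[1:])):
        if j % 2 == 0:  # within-pair junction: check the implied overlap
            rev = next(p for p in primers if p.name == f"ADV-{j + 1}-R")
            fwd = next(p for p in primers if p.name == f"ADV-{j + 2}-F")
            got = junction_overlap(rev.bases, fwd.bases, min_seed)
            want = overlaps[j]
            if got != want:
                raise DesignError(
                    f"junction {j + 1}/{j + 2}: implied overlap {got} != planned {want}")
    for p in primers:
        if _count_matches(g, p.anneal if p.anneal_span_genome is None
                          or p.anneal_span_genome.strand == "+"
                          else revcomp(p.anneal)) != 1:
            raise DesignError(f"{p.name}: anneal not unique on genome")
    return primers


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

@dataclass
class ParsedPrimer:
    bases: str
    role: str
    anchor: str | None = None
    anchor_kind: str | None = None        # upstream | downstream_rc
    re_name: str | None = None
    re_span: tuple[int, int] | None = None
    pad: str | None = None
    anneal: str = ""
    anneal_span_genome: Span | None = None


def _lcp(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def parse_primer(bases: str, anchors: AnchorPair | None = None,
                 enzymes: dict[str, Enzyme] | None = None,
                 genome: NucSeq | None = None,
                 min_anneal: int = 15) -> ParsedPrimer:
    """Decompose a primer into anchor / restriction-site / anneal segments.

    The anchor is accepted only as a full 25-nt prefix match against the
    upstream anchor or the reverse complement of the downstream anchor.  The
    restriction site may overlap the anchor's final two bases (anchor/NotI
    fusion).  With a genome, the anneal is resolved to the longest unique
    exact 3'-terminal match (>= ``min_anneal``) on either strand.
    """
    from .restriction import default_enzymes
    if len(bases) < 15:
        raise DesignError(f"primer too short to parse: {len(bases)} nt")
    bases = bases.upper()
    anchors = anchors or default_anchors()
    enzymes = enzymes or default_enzymes()

    out = ParsedPrimer(bases, "internal_fwd")
    body_start = 0
    if _lcp(bases, anchors.upstream) == 25:
        out.anchor, out.anchor_kind = anchors.upstream, "upstream"
        out.role = "vector_adjacent_fwd"
        body_start = 25
    elif _lcp(bases, revcomp(anchors.downstream)) == 25:
        out.anchor, out.anchor_kind = revcomp(anchors.downstream), "downstream_rc"
        out.role = "vector_adjacent_rev"
        body_start = 25

    # Restriction-site tail.  Anchored primers carry the site immediately at
    # the anchor boundary (a <=2 nt fusion overlap tolerated); unanchored
    # tailed primers carry a short 5' pad (<=6 nt) before a site from the
    # sub-cloning tail set.  Fully genomic primers match neither grammar.
    if out.anchor is not None:
        window_lo, window_hi = body_start - 2, body_start
        candidates = list(enzymes.values())
    else:
        window_lo, window_hi = 0, 6
        tail_set = {"NotI", "SrfI", "SapI"}
        candidates = [e for e in enzymes.values() if e.name in tail_set]
    hit: tuple[int, Enzyme] | None = None
    for enz in sorted(candidates, key=lambda e: (-len(e.recognition), e.name)):
        pat = enz.recognition
        idx = bases.find(pat, max(window_lo, 0), window_hi + len(pat))
        if idx != -1 and idx <= window_hi:
            if hit is None or idx < hit[0]:
                hit = (idx, enz)
    if hit is not None:
        idx, enz = hit
        out.re_name = enz.name
        out.re_span = (idx + 1, idx + len(enz.recognition))
        if out.anchor is None:
            out.pad = bases[:idx]
            out.role = ("deletion_fwd" if enz.name == "SapI" else "subclone_fwd")
        body_start = idx + len(enz.recognition)
        if enz.name == "SapI":
            body_start += 1  # 1-nt spacer between site and tail (cut position)
    out.anneal = bases[body_start:]

    if genome is not None:
        _resolve_anneal(out, genome, min_anneal)
    return out


def _resolve_anneal(out: ParsedPrimer, genome: NucSeq, min_anneal: int) -> None:
    """Locate the anneal on the genome.

    The grammar-determined anneal (everything after the recognized tail) is
    tried first; if it is not a unique exact match the longest unique
    3'-terminal match >= ``min_anneal`` is used instead (this covers primers
    whose 5' segment was not recognized).
    """
    g = genome.bases
    lengths = [len(out.anneal)] if len(out.anneal) >= min_anneal else []
    lengths += [n for n in range(len(out.bases), min_anneal - 1, -1)
                if n != len(out.anneal)]
    best: tuple[int, int, str] | None = None  # (length, start0, strand)
    for n in lengths:
        probe = out.bases[-n:]
        fwd_hits = _find_all(g, probe)
        rev_hits = _find_all(g, revcomp(probe))
        if len(fwd_hits) + len(rev_hits) == 1:
            best = (n, fwd_hits[0], "+") if fwd_hits else (n, rev_hits[0], "-")
            break
    if best is None:
        raise PrimerResolutionError(
            "no unique 3'-terminal genome match >= "
            f"{min_anneal} nt for primer {out.bases[:12]}...")
    n, s0, strand = best
    out.anneal = out.bases[-n:]
    out.anneal_span_genome = Span(s0 + 1, s0 + n, strand)


def _find_all(hay: str, needle: str) -> list[int]:
    hits, i = [], 0
    while True:
        j = hay.find(needle, i)
        if j == -1:
            return hits
        hits.append(j)
        i = j + 1


# ---------------------------------------------------------------------------
# Junction arithmetic
# ---------------------------------------------------------------------------

def junction_overlap(rev_primer: str, next_fwd_primer: str,
                     min_seed: int = 10) -> int:
    """Amplicon overlap implied by two fully-genomic junction primers.

    With RCR the reverse complement of the reverse primer, the longest suffix
    of the next forward primer equal to a prefix of RCR is the seed ``s``; the
    two amplicons then share ``|rev| + |fwd| - s`` genomic bases.
    """
    rev_primer = rev_primer.upper()
    next_fwd_primer = next_fwd_primer.upper()
    rcr = revcomp(rev_primer)
    s = 0
    for k in range(min(len(next_fwd_primer), len(rcr)), 0, -1):
        if next_fwd_primer[-k:] == rcr[:k]:
            s = k
            break
    if s < min_seed:
        raise DesignError(
            f"no junction: best fwd-suffix/rev-prefix seed is {s} nt "
            f"(min_seed={min_seed})")
    return len(rev_primer) + len(next_fwd_primer) - s


# ---------------------------------------------------------------------------
# Deletion (inverse-PCR) primers
# ---------------------------------------------------------------------------

def design_deletion_primers(plasmid: NucSeq, delete_span: Span,
                            tail_site: Enzyme | None = None,
                            cassette_ends: tuple[str, str] = ("", ""),
                            pads: tuple[str, str] = ("ATC", "CGCGT"),
                            tail_len: int = 24,
                            anneal_len: int = 20,
                            max_anneal: int = 35,
                            tm_floor: float = 58.0) -> tuple[PrimerSpec, PrimerSpec]:
    """Outward-facing primer pair deleting ``delete_span`` from a circular
    plasmid and appending cassette-matching tails behind a SapI handle.

    ``cassette_ends`` is (first >=15 nt of the cassette, last >=15 nt); each
    primer is pad + SapI recognition + 1-nt spacer + cassette tail + genomic
    anneal, mirroring the reference deletion-primer layout.
    """
    if not plasmid.circular:
        raise DesignError("deletion primers require a circular template")
    tail_site = tail_site or get_enzyme("SapI")
    head, tail = cassette_ends
    if len(head) < 15 or len(tail) < 15:
        raise DesignError("cassette_ends must each be >= 15 nt")
    delete_span.validate(len(plasmid), True)
    g = plasmid.bases
    L = len(g)

    def arc(start0: int, n: int) -> str:
        start0 %= L
        if start0 + n <= L:
            return g[start0:start0 + n]
        return g[start0:] + g[:start0 + n - L]

    # forward: anneals immediately downstream of the deletion, pointing away
    f_anneal = None
    for n in range(anneal_len, max_anneal + 1):
        cand = arc(delete_span.end % L, n)
        if tm(cand) >= tm_floor or n == max_anneal:
            f_anneal = cand
            break
    r_anneal = None
    for n in range(anneal_len, max_anneal + 1):
        cand = revcomp(arc((delete_span.start - 1 - n) % L, n))
        if tm(cand) >= tm_floor or n == max_anneal:
            r_anneal = cand
            break
    for name, ann in (("forward", f_anneal), ("reverse", r_anneal)):
        probe = ann if name == "forward" else revcomp(ann)
        if _count_matches(g + g[:len(probe) - 1], probe) != 1:
            raise DesignError(f"{name} deletion-primer anneal not unique on plasmid")

    spacer = "G"
    fwd = PrimerSpec(
        "del-F", pads[0] + tail_site.recognition + spacer + tail[-tail_len:] + f_anneal,
        "deletion_fwd", re_name=tail_site.name,
        re_span=(len(pads[0]) + 1, len(pads[0]) + len(tail_site.recognition)),
        cassette_span=(len(pads[0]) + len(tail_site.recognition) + 2,
                       len(pads[0]) + len(tail_site.recognition) + 1 + len(tail[-tail_len:])))
    rev = PrimerSpec(
        "del-R", pads[1] + tail_site.recognition + spacer + revcomp(head[:tail_len]) + r_anneal,
        "deletion_rev", re_name=tail_site.name,
        re_span=(len(pads[1]) + 1, len(pads[1]) + len(tail_site.recognition)),
        cassette_span=(len(pads[1]) + len(tail_site.recognition) + 2,
                       len(pads[1]) + len(tail_site.recognition) + 1 + len(head[:tail_len])))
    for p, ann in ((fwd, f_anneal), (rev, r_anneal)):
        p.anneal_span_primer = (len(p.bases) - len(ann) + 1, len(p.bases))
    return fwd, rev


# ---------------------------------------------------------------------------
# Plan validation
# ---------------------------------------------------------------------------

@dataclass
class CheckRow:
    check: str
    subject: str
    status: str      # PASS | FAIL
    detail: str = ""


@dataclass
class PlanReport:
    rows: list[CheckRow] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(r.status == "PASS" for r in self.rows)

    def add(self, check, subject, ok, detail=""):
        self.rows.append(CheckRow(check, subject, "PASS" if ok else "FAIL", detail))

    def to_tsv(self) -> str:
        lines = ["check\tsubject\tstatus\tdetail"]
        lines += [f"{r.check}\t{r.subject}\t{r.status}\t{r.detail}" for r in self.rows]
        return "\n".join(lines) + "\n"

    def __str__(self) -> str:
        head = "PASS" if self.passed else "FAIL"
        body = "\n".join(f"  [{r.status}] {r.check} {r.subject} {r.detail}".rstrip()
                         for r in self.rows)
        return f"plan validation: {head}\n{body}"


def validate_plan(genome: NucSeq, primers: list[PrimerSpec],
                  plan: PartitionPlan, anchors: AnchorPair | None = None,
                  min_seed: int = 10) -> PlanReport:
    """Pre-flight QC: junction overlaps, anchor integrity, restriction tails,
    anneal uniqueness, and Tm spread.  PASS only if every check passes."""
    anchors = anchors or default_anchors()
    rep = PlanReport()
    by_name = {p.name: p for p in primers}
    lo, hi = plan.junction_overlap_range

    for j in range(0, len(plan.fragments) - 1, 2):
        rname, fname = f"ADV-{j + 1}-R", f"ADV-{j + 2}-F"
        try:
            ov = junction_overlap(by_name[rname].bases, by_name[fname].bases, min_seed)
            rep.add("junction_overlap", f"{rname}/{fname}", lo <= ov <= hi, f"{ov} bp")
        except (KeyError, DesignError) as exc:
            rep.add("junction_overlap", f"{rname}/{fname}", False, str(exc))

    tms = []
    for p in primers:
        parsed = parse_primer(p.bases, anchors)
        if p.role == "vector_adjacent_fwd":
            rep.add("anchor", p.name, parsed.anchor_kind == "upstream",
                    f"LCP={_lcp(p.bases, anchors.upstream)}")
            rep.add("re_site", p.name, parsed.re_name is not None,
                    parsed.re_name or "missing")
        elif p.role == "vector_adjacent_rev":
            rep.add("anchor", p.name, parsed.anchor_kind == "downstream_rc",
                    f"LCP={_lcp(p.bases, revcomp(anchors.downstream))}")
            rep.add("re_site", p.name, parsed.re_name is not None,
                    parsed.re_name or "missing")
        probe = parsed.anneal
        strand_probe = probe if (p.anneal_span_genome is None
                                 or p.anneal_span_genome.strand == "+") else revcomp(probe)
        n = _count_matches(genome.bases, strand_probe)
        rep.add("anneal_unique", p.name, n == 1, f"{n} matches")
        tms.append(tm(parsed.anneal))
    spread = max(tms) - min(tms) if tms else 0.0
    rep.add("tm_spread", "all", spread <= 12.0, f"{spread:.1f} C")
    return rep


# ---------------------------------------------------------------------------
# Primer TSV I/O
# ---------------------------------------------------------------------------

def read_primers_tsv(path_or_text, from_text: bool = False) -> list[PrimerSpec]:
    if from_text:
        rows = list(csv.DictReader(path_or_text.splitlines(), delimiter="\t"))
    else:
        with open(path_or_text) as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
    return [PrimerSpec(r["name"], r["sequence"].upper(),
                       r.get("role") or "internal_fwd") for r in rows]


def write_primers_tsv(path, primers: list[PrimerSpec]) -> None:
    with open(path, "w") as fh:
        fh.write("name\tsequence\trole\n")
        for p in primers:
            fh.write(f"{p.name}\t{p.bases}\t{p.role}\n")
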