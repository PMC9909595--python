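"""Seeded synthetic sequences and packaged fixtures.

The generators emulate the *structural* constraints of the study system — an
adenovirus-scale (~35 kb) linear genome with inverted terminal repeats, an
E3-like dispensable interval, restriction sites guaranteed absent, and unique
primer landing windows — without any claim of biological gene content.  They
make the whole reconstruction pipeline testable offline and deterministically.

Packaged fixtures (byte-exact): the twelve fragment-amplification
primers, the six sub-cloning/E3-deletion primers, the two 25-nt vector
anchors, the 64-nt multiple cloning site, and the enzyme table.  The bundled
pBR322 is a deterministic *synthetic stand-in* for the real 4,361-bp vector
(no network access is assumed anywhere in the package): it reproduces the
landmarks the workflow relies on — the anchor sequences flanking the region
that the MCS replaces, and a backbone free of workflow-enzyme sites — not the
true pBR322 base sequence.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field
from importlib import resources

from .errors import GenerationError
from .restriction import Enzyme, default_enzymes, find_sites
from .seqcore import Feature, NucSeq, Span, revcomp

__all__ = ["SynthGenomeSpec", "synth_genome", "synth_cassette",
           "synth_pbr322", "fixtures", "FixtureBundle"]

PBR322_LENGTH = 4361
PBR322_REPLACE_SPAN = (3, 973)


@dataclass
class SynthGenomeSpec:
    """Parameters of a synthetic adenovirus-scale genome.

    Defaults follow the serotype-55 scale (34,776 bp, terminal arms at
    1..2,566 and 34,616..34,776).  The E3-like interval keeps the real
    region's ~3 kb scale but is placed at 25,000..28,200 so that it falls
    wholly inside the fifth of six near-equal fragments, as the workflow
    requires (the natural E3 coordinates are genome-specific).  The ITR
    length is a realistic adenovirus scale (137 bp), configurable.
    """

    length: int = 34776
    itr_len: int = 137
    e3_span: Span = field(default_factory=lambda: Span(25000, 28200))
    forbidden: list[str] = field(default_factory=lambda: ["PmeI"])
    unique_windows: list[Span] = field(default_factory=list)
    seed: int = 1

    def validate(self) -> None:
        if self.length <= 2 * self.itr_len + self.e3_span.length(self.length):
            raise GenerationError("length too short for ITRs + E3 interval")
        if self.e3_span.start <= self.itr_len or self.e3_span.end > self.length - self.itr_len:
            raise GenerationError("E3 interval must lie between the ITRs")


def _rand_bases(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _strip_sites(bases: str, enzymes: list[Enzyme], rng: random.Random,
                 mirror_itr: int = 0, protected=(), max_rounds: int = 60) -> str:
    """Remove every recognition site of ``enzymes`` by minimal substitution.

    A patch replaces one base inside the site with a different base.  With
    ``mirror_itr`` > 0 the first and last ``mirror_itr`` bases are kept as
    exact reverse complements of each other (a patch inside either terminus is
    mirrored).  ``protected`` spans (0-based, half-open) are never edited.
    """
    L = len(bases)
    seq = list(bases)

    def protected_pos(i: int) -> bool:
        return any(a <= i < b for a, b in protected)

    for _ in range(max_rounds):
        s = "".join(seq)
        hits = []
        for enz in enzymes:
            for site in find_sites(s, enz):
                hits.append((site.position - 1, len(enz.recognition)))
        if not hits:
            return s
        for p0, rl in hits:
            # patch a middle base of the site (least likely to recreate it)
            order = sorted(range(rl), key=lambda k: abs(k - rl // 2))
            for k in order:
                i = p0 + k
                if i >= L or protected_pos(i):
                    continue
                old = seq[i]
                seq[i] = rng.choice([c for c in "ACGT" if c != old])
                if mirror_itr and i < mirror_itr:
                    seq[L - 1 - i] = revcomp(seq[i])
                elif mirror_itr and i >= L - mirror_itr:
                    seq[L - 1 - i] = revcomp(seq[i])
                break
    raise GenerationError("could not clear forbidden sites; constraints too tight")


def synth_genome(spec: SynthGenomeSpec | None = None, **kw) -> NucSeq:
    """Deterministic linear genome with ITRs and guaranteed-absent sites.

    The first ``itr_len`` bases equal the reverse complement of the last
    ``itr_len`` (inverted terminal repeats); every enzyme named in
    ``spec.forbidden`` has zero sites; the E3 interval is annotated; any
    requested ``unique_windows`` are checked for exact-match uniqueness on
    both strands.  The same seed always yields the same genome.
    """
    spec = spec or SynthGenomeSpec(**kw)
    spec.validate()
    rng = random.Random(spec.seed)
    table = default_enzymes()
    try:
        enzymes = [table[n] for n in spec.forbidden]
    except KeyError as exc:
        raise GenerationError(f"unknown forbidden enzyme: {exc}") from exc

    core = _rand_bases(rng, spec.length - 2 * spec.itr_len)
    itr = _rand_bases(rng, spec.itr_len)
    bases = itr + core + revcomp(itr)
    bases = _strip_sites(bases, enzymes, rng, mirror_itr=spec.itr_len)

    for w in spec.unique_windows:
        probe = bases[w.start - 1:w.end]
        hits = bases.count(probe) + bases.count(revcomp(probe))
        if hits != 1:
            raise GenerationError(f"window {w.start}..{w.end} not unique ({hits} hits)")

    feats = [
        Feature("ITR-L", Span(1, spec.itr_len), "ITR"),
        Feature("packaging", Span(spec.itr_len + 1, spec.itr_len + 160), "packaging"),
        Feature("E3", spec.e3_span, "E3"),
        Feature("ITR-R", Span(spec.length - spec.itr_len + 1, spec.length), "ITR"),
    ]
    g = NucSeq(f"synth_genome_seed{spec.seed}", bases, "linear", feats)
    # self-verification: the generator's own contract, re-checked by scanning
    assert g.bases[:spec.itr_len] == revcomp(g.bases[-spec.itr_len:])
    for enz in enzymes:
        assert not find_sites(g, enz), enz.name
    return g


def synth_cassette(length: int = 3000, end_enzyme: str = "EcoRV",
                   forbidden: list[str] | None = None,
                   seed: int = 1) -> NucSeq:
    """Circular donor plasmid carrying a reporter-cassette stand-in.

    The cassette core (~``length`` bp) sits between two ``end_enzyme`` sites;
    a third site inside the donor backbone mimics a three-site
    EcoRV release, so digestion yields three fragments of which the cassette
    is the largest.  The core is free of every enzyme in ``forbidden``
    (default: the workflow set) and of internal ``end_enzyme`` sites.
    """
    if length < 200:
        raise GenerationError("cassette length must be >= 200")
    rng = random.Random(seed ^ 0x5EED)
    table = default_enzymes()
    forbidden = forbidden if forbidden is not None else [
        "PmeI", "NotI", "EcoRI", "ClaI", "SrfI", "SapI", "SbfI"]
    enz = table[end_enzyme]
    clean_set = [table[n] for n in forbidden] + [enz]

    core = _strip_sites(_rand_bases(rng, length), clean_set, rng)
    back1 = _strip_sites(_rand_bases(rng, 500), clean_set, rng)
    back2 = _strip_sites(_rand_bases(rng, 300), clean_set, rng)
    site = enz.recognition
    bases = site + core + site + back1 + site + back2
    donor = NucSeq(f"synth_cassette_donor_seed{seed}", bases, "circular", [
        Feature("cassette", Span(len(site) + 1, len(site) + length), "cassette")])
    assert len(find_sites(donor, enz)) == 3
    return donor


def released_cassette(donor: NucSeq, end_enzyme: str = "EcoRV") -> NucSeq:
    """The cassette fragment released from the donor (largest digest piece)."""
    from .restriction import digest, select_fragment
    frags = digest(donor, default_enzymes()[end_enzyme])
    frag = select_fragment(frags, "largest")
    return NucSeq("cassette", frag.bases, "linear")


# ---------------------------------------------------------------------------
# Synthetic pBR322 stand-in
# ---------------------------------------------------------------------------

def synth_pbr322(seed: int = 2322) -> NucSeq:
    """Deterministic synthetic stand-in for the pBR322 cloning vector.

    4,361 bp circular, with the landmarks the reconstruction workflow uses:

    * positions 1-2 are ``TT`` and the 23 bases ending at position 2
      (wrapping the origin) spell the upstream primer anchor minus its final
      ``GC`` — so that after the 3..973 -> MCS swap, a NotI cut leaves the
      full 25-nt anchor at the backbone terminus;
    * positions 974-996 spell the downstream anchor minus its leading ``GG``
      — the SbfI cut's ``GG`` remnant completes it;
    * the retained backbone (974..4361 + 1..2) contains no site for any
      enzyme in the packaged table, keeping every workflow site unique.

    This reproduces the vector's *role*, not the real vector's base sequence.
    """
    from .design import default_anchors
    rng = random.Random(seed)
    anchors = default_anchors()
    table = default_enzymes()
    all_enzymes = list(table.values())

    up23 = anchors.upstream[:23]     # ...AAGAATT; positions 4339..4361+1..2
    down23 = anchors.downstream[2:]  # GCGACG...; positions 974..996

    stuffer = _strip_sites(_rand_bases(rng, 971), all_enzymes, rng)  # 3..973
    backbone = _strip_sites(
        _rand_bases(rng, PBR322_LENGTH - 971 - len(down23) - len(up23)),
        all_enzymes, rng)
    bases = up23[-2:] + stuffer + down23 + backbone + up23[:-2]
    assert len(bases) == PBR322_LENGTH
    plas = NucSeq("pBR322_synthetic", bases, "circular")
    # the seams could recreate a site; re-scan and regenerate if so
    retained = bases[973:] + bases[:2]
    for enz in all_enzymes:
        if find_sites(NucSeq("ret", retained), enz):
            return synth_pbr322(seed + 1)
    return plas


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    table1: dict[str, str]          # the 12 fragment-amplification primers
    table2: dict[str, str]          # sub-cloning + E3-deletion primers
    anchors: tuple[str, str]        # (upstream, downstream), 25 nt each
    mcs: str                        # the 64-nt multiple cloning site
    enzymes: dict[str, Enzyme]
    pbr322: NucSeq                  # synthetic stand-in (see synth_pbr322)


def _read_tsv(name: str) -> dict[str, str]:
    text = resources.files("adrecon.data").joinpath(name).read_text()
    return {r["name"]: r["sequence"]
            for r in csv.DictReader(text.splitlines(), delimiter="\t")}


def fixtures() -> FixtureBundle:
    """The packaged fixture bundle, loaded fresh (callers may mutate)."""
    from .seqcore import read_fasta
    anchors = _read_tsv("anchors.tsv")
    mcs = resources.files("adrecon.data").joinpath("mcs.txt").read_text().strip()
    with resources.as_file(resources.files("adrecon.data")
                           .joinpath("pbr322_synthetic.fa")) as p:
        pbr = read_fasta(p)[0]
    pbr.topology = "circular"
    return FixtureBundle(
        table1=_read_tsv("table1_primers.tsv"),
        table2=_read_tsv("table2_primers.tsv"),
        anchors=(anchors["upstream"], anchors["downstream"]),
        mcs=mcs,
        enzymes=default_enzymes(),
        pbr322=pbr,
    )
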