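"""End-to-end reconstruction workflow.

Orchestrates the full cloning strategy for rebuilding a large linear viral
genome inside a low-copy plasmid:

1.  ``build_backbone`` — replace vector positions 3..973 with a 64-nt MCS.
2.  ``build_pbr322lr`` — insert PmeI / left arm / SapI-stuffer-SapI /
    right arm / PmeI between the backbone's NotI and SrfI sites.
3.  ``build_intermediates`` — PCR the six genome fragments and fuse each pair
    with the NotI/SbfI-linearized backbone by isothermal assembly.
4.  ``subclone_fragment5`` + ``replace_e3`` — clone fragment 5 alone
    (NotI/SrfI ligation), delete the E3 interval by inverse PCR and insert
    the reporter cassette.
5.  ``final_assembly`` — release the three double-fragment inserts, then
    assemble them with the SapI-linearized arm plasmid into one circle.
6.  ``rescue_linearize`` — PmeI digestion liberates the recombinant genome.
7.  ``verify_reconstruction`` — compare against the directly spliced
    expectation and emit a digest table.

Every step is deterministic given the configuration and seed, and every
intermediate is retained in the :class:`BuildRecord`.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .design import (PartitionPlan, PrimerSpec, design_deletion_primers,
                     design_primer_pairs, plan_partition, validate_plan)
from .errors import ConfigError, CoordinateError
from .insilico import AssemblyProduct, gibson, ligate, linearize, pcr
from .restriction import (DigestFragment, Enzyme, band_sizes, default_enzymes,
                          digest, find_sites, select_fragment)
from .seqcore import Feature, NucSeq, Span, revcomp, subseq
from .synthfix import (SynthGenomeSpec, released_cassette, synth_cassette,
                       synth_genome)

__all__ = [
    "ReconstructionConfig", "BuildRecord", "ReconstructionResult",
    "default_mcs", "build_backbone", "build_pbr322lr", "build_intermediates",
    "subclone_fragment5", "replace_e3", "final_assembly", "rescue_linearize",
    "verify_reconstruction", "digest_report", "run_reconstruction",
]

#: Enzymes whose sites the synthetic study genome must not contain: the
#: terminal (rescue) enzyme, the vector sub-cloning enzymes that cut released
#: inserts, and the stuffer enzyme (which must not cut the arms).  The real
#: genomes satisfy the release-set absence by deliberate enzyme choice.
WORKFLOW_FORBIDDEN = ["PmeI", "NotI", "EcoRI", "EcoRV", "ClaI", "SrfI", "SapI"]


def default_mcs() -> str:
    return resources.files("adrecon.data").joinpath("mcs.txt").read_text().strip()


@dataclass
class ReconstructionConfig:
    """Parameters of one reconstruction run (fully serializable)."""

    genome_length: int = 34776
    itr_len: int = 137
    left_arm: tuple[int, int] = (1, 2566)
    right_arm: tuple[int, int] = (34616, 34776)
    n_fragments: int = 6
    release_pairs: list[tuple[str, str]] = field(default_factory=lambda: [
        ("NotI", "EcoRI"), ("NotI", "EcoRV"), ("NotI", "ClaI")])
    vector_cut: tuple[str, str] = ("NotI", "SbfI")
    terminal_enzyme: str = "PmeI"
    stuffer_enzyme: str = "SapI"
    subclone_pair: tuple[str, str] = ("NotI", "SrfI")
    cassette_release_enzyme: str = "EcoRV"
    e3_span: tuple[int, int] = (25000, 28200)
    cassette_length: int = 3000
    overlap_range: tuple[int, int] = (30, 40)
    replace_span: tuple[int, int] = (3, 973)
    seed: int = 1

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ReconstructionConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise ConfigError(f"unknown config key {k!r}")
            cur = getattr(cfg, k)
            if isinstance(cur, tuple):
                v = tuple(v)
            elif k == "release_pairs":
                v = [tuple(p) for p in v]
            setattr(cfg, k, v)
        return cfg


@dataclass
class BuildStep:
    label: str
    inputs: list[str]
    operation: str
    output: str
    checks: list[str] = field(default_factory=list)


@dataclass
class BuildRecord:
    steps: list[BuildStep] = field(default_factory=list)
    sequences: dict[str, NucSeq] = field(default_factory=dict)

    def add(self, label, inputs, operation, output: NucSeq | str,
            checks=()) -> None:
        out_id = output if isinstance(output, str) else output.id
        if isinstance(output, NucSeq):
            self.sequences[out_id] = output
        self.steps.append(BuildStep(label, list(inputs), operation, out_id,
                                    list(checks)))

    def to_json(self) -> str:
        return json.dumps([s.__dict__ for s in self.steps], indent=2)


# ---------------------------------------------------------------------------
# Step 1: backbone MCS swap
# ---------------------------------------------------------------------------

def build_backbone(pbr322: NucSeq, replace_span: tuple[int, int] = (3, 973),
                   mcs: str | None = None) -> NucSeq:
    """Replace ``replace_span`` of the circular vector with the MCS.

    The product must carry each MCS enzyme site exactly as many times as the
    MCS itself does (the sub-cloning sites stay unique); otherwise the vector
    sequence conflicts with the workflow and a ConfigError is raised.
    """
    if not pbr322.circular:
        raise ConfigError("build_backbone expects a circular vector")
    s, e = replace_span
    if s >= e:
        raise CoordinateError(f"replace_span reversed: {replace_span}")
    Span(s, e).validate(len(pbr322), True)
    mcs = mcs or default_mcs()
    bases = pbr322.bases[:s - 1] + mcs + pbr322.bases[e:]
    out = NucSeq("pBR322-MCS", bases, "circular",
                 [Feature("MCS", Span(s, s + len(mcs) - 1), "MCS")])
    table = default_enzymes()
    for enz in table.values():
        in_mcs = len(find_sites(NucSeq("m", mcs), enz))
        if in_mcs and len(find_sites(out, enz)) != in_mcs:
            raise ConfigError(
                f"{enz.name}: site count in product differs from MCS "
                f"(vector sequence conflicts)")
    return out


# ---------------------------------------------------------------------------
# Step 2: the arm plasmid (pBR322LR)
# ---------------------------------------------------------------------------

def build_pbr322lr(backbone: NucSeq, left_arm: str, right_arm: str,
                   seed: int = 1) -> NucSeq:
    """Insert NotI - PmeI - left arm - SapI..stuffer..SapI - right arm -
    PmeI - SrfI between the backbone's NotI and SrfI sites.

    The two SapI recognitions sit inside the stuffer and point outward so
    that their cuts fall exactly on the arm boundaries: SapI linearization
    drops the stuffer and leaves the arm termini scar-free for assembly.
    Minimal deterministic spacers separate the sites; they are re-drawn (same
    seed stream) if a spacer would create an extra site.
    """
    table = default_enzymes()
    sap, pme, noti, srfi = (table[n] for n in ("SapI", "PmeI", "NotI", "SrfI"))
    for arm, name in ((left_arm, "left"), (right_arm, "right")):
        for enz in (sap, pme):
            if find_sites(NucSeq("a", arm), enz):
                raise ConfigError(f"{name} arm contains a {enz.name} site")
    n_sites = find_sites(backbone, noti)
    s_sites = find_sites(backbone, srfi)
    if len(n_sites) != 1 or len(s_sites) != 1:
        raise ConfigError("backbone must carry exactly one NotI and one SrfI site")
    not_end = n_sites[0].position + len(noti.recognition) - 1   # keep recognition
    srf_start = s_sites[0].position
    if not_end >= srf_start:
        raise ConfigError("NotI site must precede SrfI site in the backbone")

    rng = random.Random(seed)
    pme_site = pme.recognition
    # stuffer grammar: [4-nt spacer][GAAGAGC][mid][GCTCTTC][1-nt spacer]
    # (minus-strand SapI cuts at the left-arm end, plus-strand at the
    #  right-arm start; offsets follow the 8/11 cut geometry)
    for _ in range(50):
        sp_a = "".join(rng.choice("ACGT") for _ in range(4))
        mid = "".join(rng.choice("ACGT") for _ in range(6))
        sp_b = rng.choice("ACGT")
        stuffer = sp_a + revcomp(sap.recognition) + mid + sap.recognition + sp_b
        insert = pme_site + left_arm + stuffer + right_arm + pme_site
        bases = (backbone.bases[:not_end] + insert + backbone.bases[srf_start - 1:])
        cand = NucSeq("pBR322LR", bases, "circular")
        if (len(find_sites(cand, sap)) == 2 and len(find_sites(cand, pme)) == 2
                and len(find_sites(cand, noti)) == 1
                and len(find_sites(cand, srfi)) == 1):
            break
    else:
        raise ConfigError("could not place SapI stuffer without site conflicts")

    o = not_end
    feats = [
        Feature("PmeI-L", Span(o + 1, o + 8), "RE_site"),
        Feature("left_arm", Span(o + 9, o + 8 + len(left_arm)), "arm"),
        Feature("stuffer", Span(o + 9 + len(left_arm),
                                o + 8 + len(left_arm) + len(stuffer)), "stuffer"),
        Feature("right_arm", Span(o + 9 + len(left_arm) + len(stuffer),
                                  o + 8 + len(left_arm) + len(stuffer) + len(right_arm)),
                "arm"),
        Feature("PmeI-R", Span(o + 9 + len(left_arm) + len(stuffer) + len(right_arm),
                               o + 16 + len(left_arm) + len(stuffer) + len(right_arm)),
                "RE_site"),
    ]
    cand.features = feats
    # contract: SapI linearization must expose the exact arm termini
    piece = linearize(cand, sap, keep="largest")
    if not (piece.bases.startswith(right_arm) and piece.bases.endswith(left_arm)):
        raise ConfigError("SapI cuts do not fall on the arm boundaries")
    return cand


# ---------------------------------------------------------------------------
# Step 3: intermediates
# ---------------------------------------------------------------------------

def linearized_backbone(backbone: NucSeq, cut: tuple[Enzyme, Enzyme]) -> NucSeq:
    """The large piece of the backbone after the double sub-cloning digest."""
    frags = digest(backbone, list(cut))
    piece = select_fragment(frags, "largest")
    return NucSeq("backbone_linear", piece.bases, "linear")


def build_intermediates(genome: NucSeq, plan: PartitionPlan,
                        primers: list[PrimerSpec], backbone: NucSeq,
                        templates: dict[int, NucSeq] | None = None,
                        record: BuildRecord | None = None,
                        ) -> tuple[list[NucSeq], list]:
    """PCR each fragment and fuse the pairs with the linearized backbone.

    ``templates`` may redirect a fragment index to an alternative template
    (the engineered fragment-5 plasmid, in the full workflow).  Returns the
    intermediates and the list of amplicons.  Each intermediate must carry
    exactly one site for each of its release enzymes.
    """
    templates = templates or {}
    by_name = {p.name: p for p in primers}
    vec = linearized_backbone(backbone, plan.vector_cut_enzymes)
    amplicons = []
    for i in range(len(plan.fragments)):
        tpl = templates.get(i, genome)
        amp = pcr(tpl, by_name[f"ADV-{i + 1}-F"], by_name[f"ADV-{i + 1}-R"])
        amplicons.append(amp)
        if record:
            record.add(f"amplify fragment {i + 1}", [tpl.id], "pcr",
                       amp.to_nucseq(f"fragment_{i + 1}_amplicon"),
                       [f"{len(amp)} bp"])
    intermediates = []
    for k, (a, b) in enumerate(plan.pairings):
        prod = gibson([vec, amplicons[a].to_nucseq(f"frag{a + 1}"),
                       amplicons[b].to_nucseq(f"frag{b + 1}")], expect="circular")
        inter = prod.seq
        inter.id = f"pBR322-{a + 1},{b + 1}"
        rel = plan.release_enzymes[k]
        for enz in rel:
            if enz is not None and len(find_sites(inter, enz)) != 1:
                raise ConfigError(
                    f"{inter.id}: release enzyme {enz.name} does not cut exactly once")
        intermediates.append(inter)
        if record:
            record.add(f"assemble pair {a + 1}+{b + 1}",
                       [vec.id, f"frag{a + 1}", f"frag{b + 1}"], "gibson", inter,
                       [f"{len(prod.junctions)} junctions", f"{len(inter)} bp"])
    return intermediates, amplicons


# ---------------------------------------------------------------------------
# Step 4: fragment-5 engineering
# ---------------------------------------------------------------------------

def subclone_fragment5(genome: NucSeq, plan: PartitionPlan, backbone: NucSeq,
                       pads: tuple[str, str] = ("CGATAA", "AATAGC"),
                       anneal_len: int = 25) -> NucSeq:
    """Clone fragment 5 alone into the backbone via NotI/SrfI ligation.

    The amplification primers carry short pads plus NotI (forward) and SrfI
    (reverse) recognitions; the amplicon is digested and ligated into the
    backbone opened with the same enzymes, which forces the orientation
    (one sticky NotI end, one blunt SrfI end).
    """
    table = default_enzymes()
    noti, srfi = table["NotI"], table["SrfI"]
    frag5 = plan.fragments[4]
    g = genome.bases
    fwd = pads[0] + noti.recognition + g[frag5.start - 1: frag5.start - 1 + anneal_len]
    rev = pads[1] + srfi.recognition + revcomp(g[frag5.end - anneal_len: frag5.end])
    amp = pcr(genome, fwd, rev)
    insert = select_fragment(digest(amp.to_nucseq("frag5_amplicon"),
                                    [noti, srfi]), "largest")
    vector = select_fragment(digest(backbone, [noti, srfi]), "largest")
    prods = ligate([vector, insert], circularize=True, allow_blunt=True)
    out = prods[0]
    out.id = "pBR322-5"
    return out


def replace_e3(pbr322_5: NucSeq, e3_bases: str, cassette_donor: NucSeq,
               cassette_release_enzyme: str = "EcoRV",
               record: BuildRecord | None = None) -> NucSeq:
    """Delete the E3 interval by inverse PCR and insert the reporter cassette.

    ``e3_bases`` is the exact interval to remove (genome coordinates mapped
    into the plasmid by sequence match); the cassette is released from its
    donor and joined to the deletion amplicon by isothermal assembly using
    the cassette-matching primer tails.
    """
    plasmid = pbr322_5
    idx = plasmid.bases.find(e3_bases)
    if idx == -1 and e3_bases in (plasmid.bases + plasmid.bases):
        idx = (plasmid.bases + plasmid.bases).find(e3_bases)
    if idx == -1:
        flipped = plasmid.revcomp()
        if e3_bases in flipped.bases + flipped.bases:
            plasmid = flipped
            idx = (plasmid.bases + plasmid.bases).find(e3_bases)
    if idx == -1:
        raise ConfigError("E3 interval not found in the fragment-5 plasmid")
    if idx + len(e3_bases) > len(plasmid):   # wraps the origin: rotate it away
        plasmid = plasmid.rotated(idx)
        idx = 0
    delete_span = Span(idx + 1, idx + len(e3_bases))

    cassette = released_cassette(cassette_donor, cassette_release_enzyme)
    del_f, del_r = design_deletion_primers(
        plasmid, delete_span,
        cassette_ends=(cassette.bases[:24], cassette.bases[-24:]))
    amp = pcr(plasmid, del_f, del_r)
    prod = gibson([amp.to_nucseq("pBR322-5_delE3"), cassette],
                  expect="circular", end_slack=16)
    out = prod.seq
    out.id = "pBR322-5LG"
    if e3_bases in out.bases + out.bases:
        raise ConfigError("E3 interval still present after replacement")
    if cassette.bases not in out.bases + out.bases:
        raise ConfigError("cassette absent from the replacement product")
    if record:
        record.add("replace E3 with cassette",
                   [pbr322_5.id, cassette_donor.id], "inverse_pcr+gibson", out,
                   [f"deleted {len(e3_bases)} bp", f"inserted {len(cassette)} bp"])
    return out


# ---------------------------------------------------------------------------
# Steps 5-6: final assembly and rescue
# ---------------------------------------------------------------------------

def final_assembly(pbr322lr: NucSeq, intermediates: list[NucSeq],
                   release_enzymes: list[tuple[Enzyme, Enzyme]],
                   stuffer_enzyme: Enzyme | None = None,
                   ) -> tuple[AssemblyProduct, list[DigestFragment]]:
    """Release the double-fragment inserts and assemble the final circle.

    Exactly four linear pieces enter the reaction: the SapI-linearized arm
    plasmid plus the three released inserts.  Returns the assembly product
    (with its junction report) and the released fragments.
    """
    stuffer_enzyme = stuffer_enzyme or default_enzymes()["SapI"]
    lr_piece = linearize(pbr322lr, stuffer_enzyme, keep="largest")
    pieces = [NucSeq("pBR322LR_linear", lr_piece.bases, "linear")]
    released = [lr_piece]
    for inter, pair in zip(intermediates, release_enzymes):
        frags = digest(inter, [e for e in pair if e is not None])
        ins = select_fragment(frags, "largest")
        released.append(ins)
        pieces.append(NucSeq(f"{inter.id}_insert", ins.bases, "linear"))
    prod = gibson(pieces, expect="circular")
    prod.seq.id = "pBR322-rAdV"
    if len(prod.junctions) != len(pieces):
        raise ConfigError(
            f"expected {len(pieces)} junctions, got {len(prod.junctions)}")
    return prod, released


def rescue_linearize(final_plasmid: NucSeq, terminal_enzyme: Enzyme | None = None,
                     cassette_probe: str = "") -> NucSeq:
    """PmeI digestion liberating the recombinant genome.

    The plasmid must carry exactly two terminal-enzyme sites flanking the
    genome; the genome fragment is selected as the piece containing the
    cassette probe and keeps <=4-nt blunt scars outside the ITRs.
    """
    terminal_enzyme = terminal_enzyme or default_enzymes()["PmeI"]
    sites = find_sites(final_plasmid, terminal_enzyme)
    if len(sites) != 2:
        raise ConfigError(
            f"{terminal_enzyme.name}: need exactly 2 sites, found {len(sites)}")
    frags = digest(final_plasmid, terminal_enzyme)
    frag = (select_fragment(frags, ("contains", cassette_probe))
            if cassette_probe else select_fragment(frags, "largest"))
    return NucSeq("rescued_genome", frag.bases, "linear")


# ---------------------------------------------------------------------------
# Step 7: verification
# ---------------------------------------------------------------------------

@dataclass
class VerificationReport:
    status: str                      # PASS | FAIL
    detail: str = ""
    scars: tuple[int, int] = (0, 0)
    cassette_span: Span | None = None
    region_identity: dict[str, bool] = field(default_factory=dict)
    bands: dict[str, list[int]] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return self.status == "PASS"

    def to_tsv(self) -> str:
        lines = ["field\tvalue",
                 f"status\t{self.status}",
                 f"detail\t{self.detail}",
                 f"scar_left\t{self.scars[0]}",
                 f"scar_right\t{self.scars[1]}"]
        if self.cassette_span:
            lines.append(f"cassette\t{self.cassette_span.start}..{self.cassette_span.end}")
        for name, ok in self.region_identity.items():
            lines.append(f"region_{name}\t{'identical' if ok else 'DIVERGENT'}")
        for enz, sizes in self.bands.items():
            lines.append(f"bands_{enz}\t{','.join(map(str, sizes))}")
        return "\n".join(lines) + "\n"


def verify_reconstruction(linear_genome: NucSeq, wildtype: NucSeq,
                          e3_span: Span, cassette: NucSeq,
                          max_scar: int = 4,
                          digest_enzymes: list[Enzyme] | None = None,
                          ) -> VerificationReport:
    """PASS iff the rescued genome equals wildtype - E3 + cassette.

    Up to ``max_scar`` blunt terminal-enzyme scar bases are tolerated at each
    end.  On failure the report carries the first divergence coordinate and,
    where the cassette is present in reverse complement, an orientation
    diagnostic.  A simulated digest table is attached for the given enzymes.
    """
    expected = (wildtype.bases[:e3_span.start - 1] + cassette.bases
                + wildtype.bases[e3_span.end:])
    rep = VerificationReport("FAIL")
    # a linear dsDNA molecule has no intrinsic strand: accept either
    candidates = [linear_genome.bases, revcomp(linear_genome.bases)]
    got = linear_genome.bases
    for bases in candidates:
        for k1 in range(max_scar + 1):
            for k2 in range(max_scar + 1):
                if len(bases) - k1 - k2 == len(expected) and \
                        bases[k1:len(bases) - k2] == expected:
                    rep.status = "PASS"
                    rep.scars = (k1, k2)
                    cs = e3_span.start + k1
                    rep.cassette_span = Span(cs, cs + len(cassette) - 1)
                    rep.region_identity = {"upstream": True, "cassette": True,
                                           "downstream": True}
                    break
            if rep.passed:
                break
        if rep.passed:
            break
    if not rep.passed:
        # orient by longest matching prefix (the ITR makes both strands
        # begin identically, so a fixed-width probe cannot decide)
        def aligned(bases):
            k = next((k for k in range(max_scar + 1)
                      if bases[k:k + 50] == expected[:50]), 0)
            body = bases[k:]
            div = next((i for i, (x, y) in enumerate(zip(body, expected))
                        if x != y), min(len(body), len(expected)))
            return div, body

        (diva, bodya), (divb, bodyb) = aligned(candidates[0]), aligned(candidates[1])
        div, body = (diva, bodya) if diva >= divb else (divb, bodyb)
        got = body
        if revcomp(cassette.bases) in got and cassette.bases not in got:
            rep.detail = "cassette present in reverse orientation"
        else:
            rep.detail = f"first divergence at position {div + 1}"
            rep.region_identity = {
                "upstream": body[:e3_span.start - 1] == expected[:e3_span.start - 1],
                "cassette": body[e3_span.start - 1:e3_span.start - 1 + len(cassette)]
                            == cassette.bases,
                "downstream": body[e3_span.start - 1 + len(cassette):]
                              [:len(expected) - e3_span.start + 1 - len(cassette)]
                              == expected[e3_span.start - 1 + len(cassette):],
            }
    if digest_enzymes:
        for enz in digest_enzymes:
            frs = digest(linear_genome, enz)
            rep.bands[enz.name] = band_sizes(frs)
    return rep


def digest_report(seq: NucSeq, enzymes: list[Enzyme]) -> str:
    """TSV digest table labelled with the substrate topology."""
    frags = digest(seq, enzymes)
    lines = [f"# substrate\t{seq.id}\t{seq.topology}\t{len(seq)} bp",
             "fragment\tlength\tleft_end\tright_end\tsource_span"]
    for i, f in enumerate(sorted(frags, key=len, reverse=True), 1):
        sp = f"{f.source_span.start}..{f.source_span.end}" if f.source_span else ""
        lines.append(f"{i}\t{len(f)}\t{f.left_end.kind}\t{f.right_end.kind}\t{sp}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# The full pipeline
# ---------------------------------------------------------------------------

@dataclass
class ReconstructionResult:
    config: ReconstructionConfig
    genome: NucSeq
    plan: PartitionPlan
    primers: list[PrimerSpec]
    backbone: NucSeq
    pbr322lr: NucSeq
    pbr322_5: NucSeq
    pbr322_5lg: NucSeq
    intermediates: list[NucSeq]
    amplicons: list
    final: AssemblyProduct
    rescued: NucSeq
    verification: VerificationReport
    record: BuildRecord


def run_reconstruction(config: ReconstructionConfig | None = None,
                       genome: NucSeq | None = None,
                       cassette_donor: NucSeq | None = None,
                       pbr322: NucSeq | None = None) -> ReconstructionResult:
    """Execute the whole reconstruction on a (by default synthetic) genome.

    Inputs not supplied are generated deterministically from ``config.seed``:
    a genome free of the workflow enzyme set, a cassette donor, and the
    bundled vector stand-in.
    """
    cfg = config or ReconstructionConfig()
    table = default_enzymes()
    record = BuildRecord()

    if genome is None:
        genome = synth_genome(SynthGenomeSpec(
            length=cfg.genome_length, itr_len=cfg.itr_len,
            e3_span=Span(*cfg.e3_span), forbidden=list(WORKFLOW_FORBIDDEN),
            seed=cfg.seed))
    if cassette_donor is None:
        cassette_donor = synth_cassette(cfg.cassette_length,
                                        cfg.cassette_release_enzyme,
                                        seed=cfg.seed)
    if pbr322 is None:
        from .synthfix import fixtures
        pbr322 = fixtures().pbr322
    record.add("inputs", [], "load/generate", genome,
               [f"{len(genome)} bp genome"])

    e3 = Span(*cfg.e3_span)
    term = table[cfg.terminal_enzyme]
    for probe, name in ((genome, "genome"), (cassette_donor, "cassette donor")):
        if find_sites(probe, term):
            raise ConfigError(f"terminal enzyme {term.name} cuts the {name}")

    backbone = build_backbone(pbr322, cfg.replace_span)
    record.add("MCS swap", [pbr322.id], "build_backbone", backbone,
               [f"{len(backbone)} bp"])

    left_arm = subseq(genome, Span(*cfg.left_arm))
    right_arm = subseq(genome, Span(*cfg.right_arm))
    lr = build_pbr322lr(backbone, left_arm, right_arm, seed=cfg.seed)
    record.add("arm plasmid", [backbone.id], "build_pbr322lr", lr,
               [f"{len(lr)} bp", "SapI x2", "PmeI x2"])

    release = [(table[a], table[b]) for a, b in cfg.release_pairs]
    plan = plan_partition(genome, (Span(*cfg.left_arm), Span(*cfg.right_arm)),
                          cfg.n_fragments, release,
                          overlap_range=cfg.overlap_range)
    primers = design_primer_pairs(genome, plan)
    qc = validate_plan(genome, primers, plan)
    if not qc.passed:
        raise ConfigError(f"primer QC failed:\n{qc}")
    record.add("partition+primers", [genome.id], "plan_partition",
               "partition_plan",
               [f"overlaps {plan.junction_overlaps()}"])

    frag5 = plan.fragments[4]
    if not (frag5.start < e3.start and e3.end < frag5.end):
        raise ConfigError(
            f"E3 interval {e3.start}..{e3.end} not inside fragment 5 "
            f"({frag5.start}..{frag5.end})")

    p5 = subclone_fragment5(genome, plan, backbone)
    record.add("fragment-5 subclone", [genome.id, backbone.id],
               "pcr+digest+ligate", p5, [f"{len(p5)} bp"])
    e3_bases = genome.bases[e3.start - 1:e3.end]
    p5lg = replace_e3(p5, e3_bases, cassette_donor,
                      cfg.cassette_release_enzyme, record)

    intermediates, amplicons = build_intermediates(
        genome, plan, primers, backbone, templates={4: p5lg}, record=record)

    prod, _ = final_assembly(lr, intermediates, release,
                             stuffer_enzyme=table[cfg.stuffer_enzyme])
    record.add("final assembly", [lr.id] + [i.id for i in intermediates],
               "gibson", prod.seq,
               [f"{len(prod.junctions)} junctions", f"{len(prod.seq)} bp"])

    cassette = released_cassette(cassette_donor, cfg.cassette_release_enzyme)
    probe = cassette.bases[len(cassette) // 2: len(cassette) // 2 + 40]
    rescued = rescue_linearize(prod.seq, term, cassette_probe=probe)
    record.add("rescue linearization", [prod.seq.id], "digest+select",
               rescued, [f"{len(rescued)} bp"])

    verification = verify_reconstruction(
        rescued, genome, e3, cassette,
        digest_enzymes=[table["NheI"], table["XbaI"]])
    record.add("verification", [rescued.id, genome.id],
               "verify_reconstruction", "report",
               [verification.status, verification.detail])

    return ReconstructionResult(cfg, genome, plan, primers, backbone, lr, p5,
                                p5lg, intermediates, amplicons, prod, rescued,
                                verification, record)
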