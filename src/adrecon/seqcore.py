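"""Core sequence model: double-stranded DNA with explicit topology.

Coordinate convention
---------------------
External coordinates are 1-based and inclusive at both ends, matching the way
plasmid maps and the adenovirus literature count positions ("sites 1 to
2,566").  Internally everything is 0-based half-open; the conversion lives in
:class:`Span` and nowhere else.  On a circular sequence ``start > end``
denotes a span that wraps the origin.

Construct sequences are restricted to the unambiguous alphabet {A,C,G,T}:
overlap detection and digestion semantics would be ill-defined under ambiguity
codes, which are therefore allowed only inside enzyme recognition patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, CoordinateError, ParseError, TopologyError

DNA_ALPHABET = frozenset("ACGT")

#: IUPAC nucleotide complements; used for recognition patterns as well as
#: concrete sequences.
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

FEATURE_KINDS = (
    "ITR", "arm", "packaging", "E3", "cassette", "RE_site", "anneal",
    "MCS", "backbone", "junction", "stuffer",
)


def _check_alphabet(bases: str, allow_iupac: bool = False) -> str:
    if not bases:
        raise AlphabetError("empty sequence")
    allowed = IUPAC_CODES.keys() if allow_iupac else DNA_ALPHABET
    bad = set(bases) - set(allowed)
    if bad:
        raise AlphabetError(f"non-DNA characters: {sorted(bad)!r}")
    return bases


def normalize_bases(raw: str) -> str:
    """Uppercase ``raw`` and validate it against {A,C,G,T}; U is rejected."""
    bases = raw.upper()
    if "U" in bases:
        raise AlphabetError("RNA base U not accepted")
    return _check_alphabet(bases)


def revcomp(bases: str) -> str:
    """Reverse complement (IUPAC-aware, length-preserving involution)."""
    if not bases:
        raise AlphabetError("cannot reverse-complement an empty sequence")
    _check_alphabet(bases.upper(), allow_iupac=True)
    return bases.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Span:
    """1-based inclusive interval with strand; ``start > end`` wraps a circle."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise CoordinateError(f"positions are 1-based: {self}")
        if self.strand not in "+-":
            raise CoordinateError(f"strand must be + or -: {self.strand!r}")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def length(self, parent_length: int) -> int:
        if self.wraps:
            return parent_length - self.start + 1 + self.end
        return self.end - self.start + 1

    def validate(self, parent_length: int, circular: bool) -> None:
        if self.end > parent_length or self.start > parent_length:
            raise CoordinateError(
                f"span {self.start}..{self.end} exceeds length {parent_length}")
        if self.wraps and not circular:
            raise CoordinateError(
                f"wrapping span {self.start}..{self.end} on a linear sequence")

    def shift(self, offset: int, parent_length: int) -> "Span":
        """Span after rotating the parent left by ``offset`` (circular only)."""
        s = (self.start - 1 - offset) % parent_length + 1
        e = (self.end - 1 - offset) % parent_length + 1
        return Span(s, e, self.strand)


@dataclass
class Feature:
    label: str
    span: Span
    kind: str = "backbone"

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise CoordinateError(f"unknown feature kind {self.kind!r}")


@dataclass
class NucSeq:
    """A named dsDNA sequence with declared topology.

    The top strand alone is stored; the bottom strand is implied.  Circular
    sequences have no semantically meaningful origin — operations either treat
    rotations as equivalent or canonicalize explicitly.
    """

    id: str
    bases: str
    topology: str = "linear"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bases = normalize_bases(self.bases)
        if self.topology not in ("linear", "circular"):
            raise TopologyError(f"topology must be linear|circular: {self.topology!r}")
        for f in self.features:
            f.span.validate(len(self.bases), self.circular)

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def circular(self) -> bool:
        return self.topology == "circular"

    def revcomp(self) -> "NucSeq":
        return NucSeq(self.id, revcomp(self.bases), self.topology)

    def rotated(self, k: int) -> "NucSeq":
        """Rotate a circular sequence left by ``k`` (features follow)."""
        if not self.circular:
            raise TopologyError("rotation requires a circular sequence")
        k %= len(self.bases)
        feats = [Feature(f.label, f.span.shift(k, len(self.bases)), f.kind)
                 for f in self.features]
        return NucSeq(self.id, self.bases[k:] + self.bases[:k], "circular", feats)


def subseq(seq: NucSeq, span: Span) -> str:
    """Extract ``span`` from ``seq``; strand '-' returns the reverse complement."""
    span.validate(len(seq), seq.circular)
    if span.wraps:
        out = seq.bases[span.start - 1:] + seq.bases[:span.end]
    else:
        out = seq.bases[span.start - 1:span.end]
    return revcomp(out) if span.strand == "-" else out


def _least_rotation(s: str) -> int:
    """Booth's algorithm: index of the lexicographically least rotation."""
    ss = s + s
    f = [-1] * len(ss)
    k = 0
    for j in range(1, len(ss)):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def canonical_rotation(seq: NucSeq) -> NucSeq:
    """Deterministic representative of a circular sequence.

    The lexicographically smallest string over all rotations of both strands;
    ties broken toward the forward strand.  Features are dropped (their
    coordinates are origin-dependent).
    """
    if not seq.circular:
        raise TopologyError("canonical_rotation requires a circular sequence")
    fwd = seq.bases
    rev = revcomp(fwd)
    kf, kr = _least_rotation(fwd), _least_rotation(rev)
    best_f = fwd[kf:] + fwd[:kf]
    best_r = rev[kr:] + rev[:kr]
    bases = best_f if best_f <= best_r else best_r
    return NucSeq(seq.id, bases, "circular")


def canonical_equal(a: NucSeq, b: NucSeq) -> bool:
    """Equality of circular sequences up to rotation and strand."""
    return canonical_rotation(a).bases == canonical_rotation(b).bases


# ---------------------------------------------------------------------------
# File I/O.  Biopython does the parsing; this layer enforces the package's
# alphabet/topology contract and translates failures into ParseError.
# ---------------------------------------------------------------------------

def _to_record(seq: NucSeq) -> SeqRecord:
    rec = SeqRecord(Seq(seq.bases), id=seq.id, name=seq.id[:16] or "SEQ",
                    description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = seq.topology
    for f in seq.features:
        if f.span.wraps:
            # split an origin-wrapping feature into its two arcs
            locs = [FeatureLocation(f.span.start - 1, len(seq.bases)),
                    FeatureLocation(0, f.span.end)]
        else:
            locs = [FeatureLocation(f.span.start - 1, f.span.end)]
        for loc in locs:
            sf = SeqFeature(loc, type="misc_feature",
                            qualifiers={"label": [f.label], "note": [f.kind]})
            sf.location = FeatureLocation(loc.start, loc.end,
                                          strand=1 if f.span.strand == "+" else -1)
            rec.features.append(sf)
    return rec


def _from_record(rec: SeqRecord, default_topology: str) -> NucSeq:
    topology = rec.annotations.get("topology", default_topology)
    if topology not in ("linear", "circular"):
        topology = default_topology
    feats: list[Feature] = []
    for sf in rec.features:
        if sf.type != "misc_feature":
            continue
        label = (sf.qualifiers.get("label") or ["feature"])[0]
        kind = (sf.qualifiers.get("note") or ["backbone"])[0]
        if kind not in FEATURE_KINDS:
            kind = "backbone"
        strand = "-" if sf.location.strand == -1 else "+"
        feats.append(Feature(label, Span(int(sf.location.start) + 1,
                                         int(sf.location.end), strand), kind))
    return NucSeq(rec.id, str(rec.seq), topology, feats)


def read_fasta(path) -> list[NucSeq]:
    """Read a multi-record FASTA; features are not represented in FASTA."""
    try:
        recs = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, Exception) as exc:  # Biopython raises plain ValueError
        raise ParseError(f"{path}: {exc}") from exc
    if not recs:
        raise ParseError(f"{path}: no FASTA records found")
    out = []
    for i, rec in enumerate(recs, 1):
        try:
            out.append(NucSeq(rec.id, str(rec.seq), "linear"))
        except AlphabetError as exc:
            raise ParseError(f"{path}: record {i} ({rec.id}): {exc}") from exc
    return out


def write_fasta(path, seqs: Iterable[NucSeq]) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.bases), 70):
                fh.write(s.bases[i:i + 70] + "\n")


def read_genbank(path) -> list[NucSeq]:
    """Read GenBank flat file(s); the LOCUS circular/linear token is honored."""
    try:
        recs = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not recs:
        raise ParseError(f"{path}: no GenBank records found")
    out = []
    for i, rec in enumerate(recs, 1):
        if not rec.seq or len(rec.seq) == 0:
            raise ParseError(f"{path}: record {i} has no sequence")
        try:
            out.append(_from_record(rec, "linear"))
        except AlphabetError as exc:
            raise ParseError(f"{path}: record {i} ({rec.id}): {exc}") from exc
    return out


def write_genbank(path, seqs: Iterable[NucSeq]) -> None:
    SeqIO.write([_to_record(s) for s in seqs], str(path), "genbank")


def iter_kmers(bases: str, k: int, circular: bool) -> Iterator[tuple[int, str]]:
    """Yield (1-based position, k-mer); wraps the origin on circular input."""
    src = bases + bases[:k - 1] if circular else bases
    for i in range(len(bases) if circular else len(bases) - k + 1):
        yield i + 1, src[i:i + k]
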