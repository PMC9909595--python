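"""Restriction-enzyme model: site scanning and digestion with end chemistry.

An enzyme is its recognition pattern plus two cut offsets measured from the
start of the recognition match on the top strand: the top strand is cut after
``cut_top`` bases, the bottom strand after ``cut_bottom`` (in top-strand
coordinates).  ``cut_bottom - cut_top`` is the overhang: 0 blunt, positive a
5' overhang, negative a 3' overhang.  Type-IIS enzymes such as SapI simply
have offsets beyond the recognition length.

Overhangs are stored as the single-stranded bases of the strand that
protrudes, always written 5'->3'.  Two ends are ligation-compatible exactly
when one overhang is the reverse complement of the other (blunt/blunt needs an
explicit opt-in at ligation time).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

from .errors import (SelectionError, UncutError, UnsupportedConfigurationError)
from .seqcore import IUPAC_CODES, NucSeq, Span, revcomp

__all__ = [
    "Enzyme", "CutSite", "End", "DigestFragment", "load_enzymes",
    "default_enzymes", "find_sites", "absent_enzymes", "digest",
    "band_sizes", "select_fragment",
]


@dataclass(frozen=True)
class Enzyme:
    name: str
    recognition: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self) -> None:
        if len(self.recognition) < 4:
            raise ValueError(f"{self.name}: recognition shorter than 4 nt")
        bad = set(self.recognition) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC {bad!r}")

    @property
    def overhang_length(self) -> int:
        return self.cut_bottom - self.cut_top

    @property
    def overhang_class(self) -> str:
        d = self.overhang_length
        return "blunt" if d == 0 else ("five_prime" if d > 0 else "three_prime")

    @property
    def palindromic(self) -> bool:
        return self.recognition == revcomp(self.recognition)

    @property
    def span_length(self) -> int:
        """Total top-strand extent touched by recognition + both cuts."""
        return max(len(self.recognition), self.cut_top, self.cut_bottom)

    def _regex(self, pattern: str | None = None) -> re.Pattern:
        pat = pattern if pattern is not None else self.recognition
        return re.compile("".join(
            c if len(IUPAC_CODES[c]) == 1 else f"[{IUPAC_CODES[c]}]" for c in pat))


@dataclass(frozen=True)
class CutSite:
    """Recognition match; position is the 1-based start on the forward strand.

    ``strand`` is '-' only for non-palindromic patterns found on the bottom
    strand (the match span on the top strand is still position..position+L-1).
    """

    position: int
    strand: str = "+"


@dataclass(frozen=True)
class End:
    """End chemistry of a fragment terminus."""

    kind: str = "blunt"  # blunt | five_prime | three_prime
    overhang: str = ""   # protruding single-strand bases, 5'->3'

    def compatible(self, other: "End", allow_blunt: bool = False) -> bool:
        if self.kind != other.kind:
            return False
        if self.kind == "blunt":
            return allow_blunt
        return revcomp(self.overhang) == other.overhang


BLUNT = End()


@dataclass
class DigestFragment:
    """Digestion product: top strand left-to-right plus explicit end chemistry.

    ``bases`` follows the top-strand length convention: the single-stranded
    overhang region at a junction is counted once, in the fragment whose top
    strand carries it.
    """

    bases: str
    left_end: End = BLUNT
    right_end: End = BLUNT
    source_id: str = ""
    source_span: Span | None = None

    def __len__(self) -> int:
        return len(self.bases)

    def flipped(self) -> "DigestFragment":
        """The same physical molecule read from the other strand."""
        return DigestFragment(revcomp(self.bases), self.right_end,
                              self.left_end, self.source_id, self.source_span)

    def to_nucseq(self, id: str) -> NucSeq:
        return NucSeq(id, self.bases, "linear")


# ---------------------------------------------------------------------------
# Enzyme table
# ---------------------------------------------------------------------------

def load_enzymes(path=None) -> dict[str, Enzyme]:
    """Load an enzyme TSV (name, recognition, cut_top, cut_bottom).

    Without ``path`` the packaged table is used; it covers every enzyme the
    reconstruction workflow names (SmaI and XmaI listed separately).
    """
    if path is None:
        text = resources.files("adrecon.data").joinpath("enzymes.tsv").read_text()
        rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    else:
        with open(path) as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
    table = {}
    for r in rows:
        table[r["name"]] = Enzyme(r["name"], r["recognition"].upper(),
                                  int(r["cut_top"]), int(r["cut_bottom"]))
    return table


_DEFAULTS: dict[str, Enzyme] | None = None


def default_enzymes() -> dict[str, Enzyme]:
    global _DEFAULTS
    if _DEFAULTS is None:
        _DEFAULTS = load_enzymes()
    return dict(_DEFAULTS)


def get_enzyme(name: str) -> Enzyme:
    try:
        return default_enzymes()[name]
    except KeyError:
        raise KeyError(f"unknown enzyme {name!r}; extend the enzyme TSV") from None


# ---------------------------------------------------------------------------
# Site scanning
# ---------------------------------------------------------------------------

def find_sites(seq: NucSeq | str, enzyme: Enzyme) -> list[CutSite]:
    """All recognition matches, both strands, sorted by position.

    Minus-strand sites are reported only for non-palindromic patterns (a
    palindromic match is the same physical site).  On circular input,
    origin-spanning matches are found by scanning the sequence extended with a
    prefix of length (recognition + max cut offset) - 1 and de-duplicating by
    modular position.
    """
    bases = seq.bases if isinstance(seq, NucSeq) else seq
    circular = isinstance(seq, NucSeq) and seq.circular
    L = len(bases)
    ext = bases + bases[:enzyme.span_length - 1] if circular else bases
    sites: list[CutSite] = []
    seen: set[tuple[int, str]] = set()
    patterns = [(enzyme.recognition, "+")]
    if not enzyme.palindromic:
        patterns.append((revcomp(enzyme.recognition), "-"))
    for pat, strand in patterns:
        rx = enzyme._regex(pat)
        for m in _finditer_all(rx, ext):
            pos = m % L + 1 if circular else m + 1
            if pos + len(pat) - 1 > L and not circular:
                continue
            key = (pos, strand)
            if key not in seen:
                seen.add(key)
                sites.append(CutSite(pos, strand))
    sites.sort(key=lambda s: (s.position, s.strand))
    return sites


def _finditer_all(rx: re.Pattern, s: str) -> Iterable[int]:
    """Overlapping match start indices (0-based)."""
    i = 0
    while True:
        m = rx.search(s, i)
        if m is None:
            return
        yield m.start()
        i = m.start() + 1


def absent_enzymes(seq: NucSeq, enzymes: Sequence[Enzyme]) -> list[Enzyme]:
    """Subset of ``enzymes`` with zero sites in ``seq`` (order preserved)."""
    return [e for e in enzymes if not find_sites(seq, e)]


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------

def _cuts_for(seq: NucSeq, enzyme: Enzyme) -> list[tuple[int, int, str]]:
    """All cuts as (top_boundary, overhang_delta, enzyme_name).

    Boundary ``t`` (0-based) lies between top-strand characters t-1 and t; the
    bottom strand is cut at boundary ``t + delta`` where
    ``delta = cut_bottom - cut_top`` for either strand orientation (the
    geometry is mirror-symmetric, so the signed overhang is strand-invariant).
    On circular substrates ``t`` is reduced mod L; on linear substrates cuts
    whose window would fall off the molecule are discarded.
    """
    L = len(seq)
    rl = len(enzyme.recognition)
    delta = enzyme.cut_bottom - enzyme.cut_top
    out = []
    for site in find_sites(seq, enzyme):
        p = site.position - 1
        t = p + enzyme.cut_top if site.strand == "+" else p + rl - enzyme.cut_bottom
        if seq.circular:
            out.append((t % L, delta, enzyme.name))
        elif 0 <= min(t, t + delta) and max(t, t + delta) <= L:
            out.append((t, delta, enzyme.name))
    return out


def digest(seq: NucSeq, enzymes: Sequence[Enzyme] | Enzyme) -> list[DigestFragment]:
    """Complete digestion with one or more enzymes.

    Circular substrate with n cuts yields n fragments, linear n+1.  Top-strand
    fragment lengths always sum to the substrate length.  Two sites whose cut
    windows overlap make complete digestion ill-defined and raise
    UnsupportedConfigurationError.
    """
    if isinstance(enzymes, Enzyme):
        enzymes = [enzymes]
    L = len(seq)
    cuts: list[tuple[int, int, str]] = []
    for enz in enzymes:
        cuts.extend(_cuts_for(seq, enz))
    if not cuts:
        if seq.circular:
            raise UncutError(f"{seq.id}: no site for "
                             f"{'/'.join(e.name for e in enzymes)} on circular substrate")
        return [DigestFragment(seq.bases, BLUNT, BLUNT, seq.id, Span(1, L))]

    cuts.sort()
    # reject duplicate or overlapping cut windows (window = [t, t+delta] sorted)
    windows = sorted((min(t, t + d), max(t, t + d), name) for t, d, name in cuts)
    pairs = list(zip(windows, windows[1:]))
    if seq.circular and len(windows) > 1:
        a0, a1, n0 = windows[0]
        pairs.append(((a0 + L, a1 + L, n0), windows[-1]))
    for (a0, a1, n0), (b0, b1, n1) in pairs:
        lo, hi = sorted([(a0, a1, n0), (b0, b1, n1)])[0], sorted([(a0, a1, n0), (b0, b1, n1)])[1]
        if hi[0] < lo[1] or (lo[0], lo[1]) == (hi[0], hi[1]):
            raise UnsupportedConfigurationError(
                f"{seq.id}: cut windows of {lo[2]} and {hi[2]} overlap "
                f"({lo[0]}..{lo[1]} vs {hi[0]}..{hi[1]})")

    def junction_ends(t: int, d: int) -> tuple[End, End]:
        """(right_end of left fragment, left_end of right fragment)."""
        if d == 0:
            return BLUNT, BLUNT
        if d > 0:          # 5' overhang: protruding bases are top[t .. t+d)
            s = _arc(seq.bases, t, t + d)
            return End("five_prime", revcomp(s)), End("five_prime", s)
        s = _arc(seq.bases, t + d, t)  # 3' overhang: top[t+d .. t)
        return End("three_prime", s), End("three_prime", revcomp(s))

    frags: list[DigestFragment] = []
    if seq.circular:
        n = len(cuts)
        for i in range(n):
            t0, d0, _ = cuts[i]
            t1, d1, _ = cuts[(i + 1) % n]
            bases = _arc(seq.bases, t0, t1)  # start == stop -> full turn
            _, left = junction_ends(t0, d0)
            right, _ = junction_ends(t1, d1)
            frags.append(DigestFragment(bases, left, right, seq.id,
                                        Span(t0 % L + 1, t1 % L if t1 % L else L)))
    else:
        bounds = [(0, 0)] + [(t, d) for t, d, _ in cuts] + [(L, 0)]
        for i in range(len(bounds) - 1):
            t0, d0 = bounds[i]
            t1, d1 = bounds[i + 1]
            left = BLUNT if i == 0 else junction_ends(t0, d0)[1]
            right = BLUNT if i == len(bounds) - 2 else junction_ends(t1, d1)[0]
            frags.append(DigestFragment(seq.bases[t0:t1], left, right, seq.id,
                                        Span(t0 + 1, max(t1, t0 + 1))))
    return frags


def _arc(bases: str, start: int, stop: int) -> str:
    """Top strand from boundary ``start`` to ``stop`` (0-based, mod length)."""
    L = len(bases)
    start %= L
    stop = stop % L or (L if stop else 0)
    if stop > start:
        return bases[start:stop]
    return bases[start:] + bases[:stop]


def band_sizes(fragments: Sequence[DigestFragment]) -> list[int]:
    """Gel-style band list: top-strand lengths, descending."""
    return sorted((len(f) for f in fragments), reverse=True)


def select_fragment(fragments: Sequence[DigestFragment], criterion) -> DigestFragment:
    """Pick exactly one fragment.

    ``criterion`` is ``"largest"``, ``("contains", bases)`` (substring on
    either strand), or ``("excludes", enzyme)``.  Zero or multiple matches
    raise SelectionError.
    """
    if criterion == "largest":
        top = max(len(f) for f in fragments)
        hits = [f for f in fragments if len(f) == top]
    elif isinstance(criterion, tuple) and criterion[0] == "contains":
        probe = criterion[1]
        hits = [f for f in fragments
                if probe in f.bases or revcomp(probe) in f.bases]
    elif isinstance(criterion, tuple) and criterion[0] == "excludes":
        enz = criterion[1]
        hits = [f for f in fragments if not find_sites(f.bases, enz)]
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    if len(hits) != 1:
        raise SelectionError(
            f"criterion {criterion!r} matched {len(hits)} of {len(fragments)} fragments")
    return hits[0]
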