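"""Reaction simulators: PCR (incl. inverse PCR), ligation, isothermal assembly.

The isothermal (Gibson) model treats a junction as an exact terminal
sequence-identity match between two fragments.  Because the exonuclease
chew-back resects fragment ends regardless of chemistry, a short
non-homologous scar at a terminus (e.g. the half restriction site left by a
release digest) does not block joining in vitro; the simulator mirrors this
with a bounded "end slack": up to ``end_slack`` bases may be trimmed from the
abutting termini before the suffix-prefix identity is evaluated.  Exact
(zero-trim) junctions always win; among trimmed candidates the minimal total
trim and then the longest overlap is chosen, so the model stays deterministic
and mismatch-free at junction resolution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .errors import (AmbiguousAssemblyError, LigationError, MisprimingError,
                     NoAmplificationError, NoSolutionError, OrientationError,
                     UncutError)
from .restriction import DigestFragment, Enzyme, digest, select_fragment
from .seqcore import NucSeq, Span, canonical_rotation, revcomp

__all__ = ["Amplicon", "Junction", "AssemblyProduct", "pcr", "ligate",
           "gibson", "linearize"]


@dataclass
class Amplicon:
    """PCR product: linear, blunt-ended, with provenance."""

    bases: str
    template_id: str
    fwd_name: str
    rev_name: str
    fwd_anneal: Span        # template top-strand span matched by the fwd primer
    rev_anneal: Span        # template top-strand image of the rev primer anneal
    fwd_tail: int           # 5' tail lengths carried in from the primers
    rev_tail: int

    def __len__(self) -> int:
        return len(self.bases)

    def to_nucseq(self, id: str | None = None) -> NucSeq:
        return NucSeq(id or f"amplicon_{self.fwd_name}_{self.rev_name}",
                      self.bases, "linear")


def _occurrences(hay: str, needle: str, circular: bool) -> list[int]:
    """0-based start positions of ``needle`` (wrapping the origin if circular)."""
    L = len(hay)
    ext = hay + hay[:len(needle) - 1] if circular else hay
    out, i = [], 0
    while True:
        j = ext.find(needle, i)
        if j == -1 or j >= L:
            return out
        out.append(j)
        i = j + 1


def _primer_bases(primer) -> tuple[str, str]:
    if hasattr(primer, "bases"):
        return primer.name, primer.bases
    return "primer", str(primer)


def pcr(template: NucSeq, fwd, rev, min_anneal: int = 18) -> Amplicon:
    """Simulate error-free PCR with tailed primers.

    Each primer's 3'-terminal ``min_anneal`` bases must match the template
    exactly and uniquely (forward primer on the top strand, reverse primer on
    the bottom).  On a linear template the pair must converge; on a circular
    template a divergent pair performs inverse PCR across the retained arc.
    The amplicon is the spanned template flanked by the full primer sequences
    (tails included); ends are blunt.
    """
    fwd_name, fwd_seq = _primer_bases(fwd)
    rev_name, rev_seq = _primer_bases(rev)
    top = template.bases
    L = len(top)
    circ = template.circular
    if min_anneal > min(len(fwd_seq), len(rev_seq)):
        raise NoAmplificationError("primer shorter than min_anneal")

    def locate(primer: str, label: str) -> tuple[int, int]:
        """Return (anneal_start_0based_on_top, anneal_len) for a primer whose
        3' end matches the top strand left-to-right."""
        seed = primer[-min_anneal:]
        hits = _occurrences(top, seed, circ)
        if not hits:
            raise NoAmplificationError(
                f"{label}: no perfect {min_anneal}-nt 3' match on {template.id}")
        if len(hits) > 1:
            raise MisprimingError(
                f"{label}: {len(hits)} annealing sites on {template.id}")
        seed_start = hits[0]
        # extend the match 5'-ward as far as it stays exact
        m = min_anneal
        while m < len(primer):
            pos = seed_start - (m - min_anneal) - 1
            if not circ and pos < 0:
                break
            if top[pos % L] != primer[len(primer) - m - 1]:
                break
            m += 1
        return (seed_start - (m - min_anneal)) % L if circ else seed_start - (m - min_anneal), m

    fa, fm = locate(fwd_seq, fwd_name)                 # fwd anneal on top strand
    ra, rm = _locate_rev(rev_seq, top, circ, min_anneal, rev_name, template.id)

    fwd_tail = len(fwd_seq) - fm
    rev_tail = len(rev_seq) - rm
    f_end = fa + fm - 1          # last top index covered by fwd anneal
    r_start, r_end = ra, ra + rm - 1  # top-strand image of rev anneal

    if circ:
        inner = (r_end - f_end) % L    # top bases after fwd anneal through rev image end
        if inner < rm:
            raise OrientationError("primer annealing regions overlap incoherently")
        body = _take(top, (f_end + 1) % L, inner)
    else:
        if r_end < f_end:
            raise OrientationError(
                f"{fwd_name}/{rev_name} do not converge on linear {template.id}")
        body = top[f_end + 1:r_end + 1]
    bases = fwd_seq + body + revcomp(rev_seq)[rm:]
    return Amplicon(bases, template.id, fwd_name, rev_name,
                    Span(fa + 1, (f_end % L) + 1),
                    Span((r_start % L) + 1, (r_end % L) + 1, "-"),
                    fwd_tail, rev_tail)


def _locate_rev(rev_seq: str, top: str, circ: bool, min_anneal: int,
                name: str, template_id: str) -> tuple[int, int]:
    """Anneal start/len of the reverse primer's top-strand image."""
    L = len(top)
    seed = revcomp(rev_seq[-min_anneal:])   # top-strand image of the 3' seed
    hits = _occurrences(top, seed, circ)
    if not hits:
        raise NoAmplificationError(
            f"{name}: no perfect {min_anneal}-nt 3' match on {template_id}")
    if len(hits) > 1:
        raise MisprimingError(f"{name}: {len(hits)} annealing sites on {template_id}")
    start = hits[0]
    m = min_anneal
    # extending the primer anneal 5'-ward grows the top-strand image rightward
    while m < len(rev_seq):
        pos = start + m
        if not circ and pos >= L:
            break
        if top[pos % L] != revcomp(rev_seq[len(rev_seq) - m - 1]):
            break
        m += 1
    return start, m


def _take(bases: str, start: int, n: int) -> str:
    """n bases from 0-based ``start``, wrapping."""
    L = len(bases)
    start %= L
    if start + n <= L:
        return bases[start:start + n]
    return bases[start:] + bases[:start + n - L]


# ---------------------------------------------------------------------------
# Ligation
# ---------------------------------------------------------------------------

def ligate(fragments: list[DigestFragment], circularize: bool = True,
           allow_blunt: bool = False, enumerate_all: bool = False) -> list[NucSeq]:
    """Join fragments whose end chemistries are reverse-complement compatible.

    All fragments are used exactly once; each may flip orientation.  With
    ``circularize`` the chain must also close on itself.  Returns the distinct
    products (circular ones canonicalized, sorted deterministically).  More
    than one distinct product raises LigationError unless ``enumerate_all``.
    """
    if not fragments:
        raise LigationError("no fragments")
    n = len(fragments)
    if n > 8:
        raise LigationError("ligation enumeration limited to 8 fragments")
    oriented = [(f, f.flipped()) for f in fragments]
    products: dict[str, NucSeq] = {}

    for perm in itertools.permutations(range(n)):
        if n > 1 and perm[0] != 0:
            continue  # fix the first fragment: rotations/reflections are duplicates
        for flips in itertools.product((0, 1), repeat=n):
            chain = [oriented[i][flips[k]] for k, i in enumerate(perm)]
            ok = all(chain[i].right_end.compatible(chain[i + 1].left_end, allow_blunt)
                     for i in range(n - 1))
            if not ok:
                continue
            bases = "".join(c.bases for c in chain)
            if circularize:
                if not chain[-1].right_end.compatible(chain[0].left_end, allow_blunt):
                    continue
                prod = canonical_rotation(NucSeq("ligation", bases, "circular"))
                products[prod.bases] = prod
            else:
                key = min(bases, revcomp(bases))
                products[key] = NucSeq("ligation", bases, "linear")
    if not products:
        raise LigationError("no compatible end joining exists")
    out = [products[k] for k in sorted(products)]
    for i, p in enumerate(out):
        p.id = f"ligation_{i + 1}" if len(out) > 1 else "ligation"
    if len(out) > 1 and not enumerate_all:
        raise LigationError(
            f"{len(out)} distinct ligation products; pass enumerate_all=True")
    return out


# ---------------------------------------------------------------------------
# Isothermal (Gibson) assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Junction:
    left: str               # participant id contributing the upstream side
    right: str
    overlap: int            # shared bases, counted once in the product
    position: int           # 1-based start of the overlap in the product
    trimmed_left: int = 0   # chewed-back scar bases on the upstream terminus
    trimmed_right: int = 0


@dataclass
class AssemblyProduct:
    seq: NucSeq
    junctions: list[Junction] = field(default_factory=list)

    @property
    def circular(self) -> bool:
        return self.seq.circular


def _best_junction(a: str, b: str, min_overlap: int, max_overlap: int,
                   end_slack: int):
    """Best (trim_a, trim_b, overlap) joining a's 3' end to b's 5' end.

    Minimal total trim first (exact suffix-prefix preferred), then maximal
    overlap.  Returns None if nothing in [min_overlap, max_overlap] exists.
    Also returns the best undersized overlap for near-miss diagnostics.
    """
    best = None
    for total in range(0, 2 * end_slack + 1):
        for ta in range(max(0, total - end_slack), min(total, end_slack) + 1):
            tb = total - ta
            kmax = min(max_overlap, len(a) - ta, len(b) - tb)
            for k in range(kmax, min_overlap - 1, -1):
                if a[len(a) - ta - k: len(a) - ta] == b[tb: tb + k]:
                    if best is None or k > best[2]:
                        best = (ta, tb, k)
                    break
        if best is not None:
            break  # minimal total trim found; larger trims cannot beat it
    near = 0
    if best is None:
        for k in range(min_overlap - 1, 0, -1):
            if a[len(a) - k:] == b[:k]:
                near = k
                break
    return best, near


def gibson(fragments: list, min_overlap: int = 15, max_overlap: int = 80,
           expect: str = "any", end_slack: int = 12) -> AssemblyProduct:
    """Assemble 1-12 linear fragments by terminal sequence overlaps.

    Builds the junction graph over all ordered fragment pairs and both
    orientations, then searches exhaustively (sorted enumeration, so
    deterministic) for a Hamiltonian cycle (``expect='circular'``), path
    (``'linear'``), or either (``'any'``: cycles preferred).  Exactly one
    distinct product must exist; zero raises NoSolutionError (with a near-miss
    hint if an undersized overlap was seen) and several raise
    AmbiguousAssemblyError listing the competing products.
    """
    if not 1 <= len(fragments) <= 12:
        raise NoSolutionError("gibson accepts 1-12 fragments")
    seqs: list[tuple[str, str]] = []   # (id, bases)
    for i, f in enumerate(fragments):
        if isinstance(f, NucSeq):
            if f.circular:
                raise NoSolutionError(f"{f.id}: circular input to gibson")
            seqs.append((f.id, f.bases))
        elif isinstance(f, DigestFragment):
            seqs.append((f.source_id or f"frag{i + 1}", f.bases))
        else:
            seqs.append((f"frag{i + 1}", str(f).upper()))
    n = len(seqs)
    ids = [s[0] for s in seqs]
    orient = [(s[1], revcomp(s[1])) for s in seqs]

    # junction graph: edge[(i,oi),(j,oj)] = (trim_a, trim_b, overlap)
    edge: dict[tuple[int, int, int, int], tuple[int, int, int]] = {}
    near_best = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            for oi in (0, 1):
                for oj in (0, 1):
                    best, near = _best_junction(orient[i][oi], orient[j][oj],
                                                min_overlap, max_overlap, end_slack)
                    near_best = max(near_best, near)
                    if best:
                        edge[(i, oi, j, oj)] = best

    def chain_product(order: list[tuple[int, int]], circular: bool):
        pieces, juncs = [], []
        pos = 0
        m = len(order)
        limit = m if circular else m - 1
        for k in range(m):
            i, oi = order[k]
            bases = orient[i][oi]
            start_cut = 0
            if circular or k > 0:
                pj, poj = order[k - 1]
                ta, tb, ov = edge[(pj, poj, i, oi)]
                start_cut = tb + ov
            end_cut = 0
            if k < m - 1 or circular:
                nj, noj = order[(k + 1) % m]
                ta, tb, ov = edge[(i, oi, nj, noj)]
                end_cut = ta
            piece = bases[start_cut: len(bases) - end_cut]
            pieces.append(piece)
            pos += len(piece)
            if k < limit:
                nj, noj = order[(k + 1) % m]
                ta, tb, ov = edge[(i, oi, nj, noj)]
                # the overlap is retained as the suffix of this piece
                juncs.append(Junction(ids[i], ids[nj], ov, pos - ov + 1, ta, tb))
        seq = "".join(pieces)
        return seq, juncs

    def search(circular: bool) -> dict[str, tuple[list[tuple[int, int]], str, list[Junction]]]:
        found: dict[str, tuple[list, str, list]] = {}
        if n == 1:
            if circular:
                i = 0
                b = orient[0][0]
                best, _ = _best_junction(b, b, min_overlap, max_overlap, end_slack)
                if best:
                    ta, tb, ov = best
                    body = b[tb + ov: len(b) - ta]
                    circ = b[tb: tb + ov] + body
                    key = canonical_rotation(NucSeq("x", circ, "circular")).bases
                    found[key] = ([(0, 0)], circ,
                                  [Junction(ids[0], ids[0], ov, 1, ta, tb)])
            return found

        def dfs(order: list[tuple[int, int]], used: set[int]):
            if len(order) == n:
                if circular:
                    i, oi = order[-1]
                    j, oj = order[0]
                    if (i, oi, j, oj) not in edge:
                        return
                seq, juncs = chain_product(order, circular)
                if circular:
                    key = canonical_rotation(NucSeq("x", seq, "circular")).bases
                else:
                    key = min(seq, revcomp(seq))
                found.setdefault(key, (list(order), seq, juncs))
                return
            i, oi = order[-1]
            for j in range(n):
                if j in used:
                    continue
                for oj in (0, 1):
                    if (i, oi, j, oj) in edge:
                        dfs(order + [(j, oj)], used | {j})

        starts = [(0, 0)] if circular else [(i, oi) for i in range(n) for oi in (0, 1)]
        if circular:
            starts = [(0, 0), (0, 1)]
        for s in starts:
            dfs([s], {s[0]})
        return found

    sols = {}
    topology = "circular"
    if expect in ("circular", "any"):
        sols = search(True)
    if not sols and expect in ("linear", "any"):
        sols = search(False)
        topology = "linear"
    if not sols:
        hint = (f" (best overlap seen: {near_best} nt, below min_overlap="
                f"{min_overlap})" if near_best else "")
        raise NoSolutionError(f"no assembly uses all {n} fragments{hint}")
    if len(sols) > 1:
        raise AmbiguousAssemblyError(
            f"{len(sols)} distinct products: " +
            "; ".join(f"{len(k)} bp" for k in sorted(sols)[:4]))
    key, (order, seq, juncs) = next(iter(sols.items()))
    if topology == "circular":
        product = NucSeq("assembly", seq, "circular")
        canon = canonical_rotation(product)
        juncs = _remap_junctions(juncs, seq, canon.bases)
        product = canon
    else:
        product = NucSeq("assembly", seq, "linear")
    product.id = "assembly"
    return AssemblyProduct(product, juncs)


def _remap_junctions(juncs: list[Junction], raw: str, canon: str) -> list[Junction]:
    """Re-express junction positions after canonical rotation/flip."""
    L = len(raw)
    doubled = raw + raw
    if canon in doubled:
        r = doubled.index(canon)
        flip = False
    else:
        rc = revcomp(raw)
        r = (rc + rc).index(canon)
        flip = True
    out = []
    for j in juncs:
        p0 = j.position - 1
        if not flip:
            p = (p0 - r) % L
            out.append(Junction(j.left, j.right, j.overlap, p + 1,
                                j.trimmed_left, j.trimmed_right))
        else:
            # overlap region [p0, p0+ov) maps to rc coordinates, then rotate
            q = (L - (p0 + j.overlap)) % L
            p = (q - r) % L
            out.append(Junction(j.right, j.left, j.overlap, p + 1,
                                j.trimmed_right, j.trimmed_left))
    return sorted(out, key=lambda j: j.position)


# ---------------------------------------------------------------------------
# Linearization
# ---------------------------------------------------------------------------

def linearize(plasmid: NucSeq, enzyme: Enzyme, keep="largest") -> DigestFragment:
    """Cut a circular plasmid and keep one piece.

    A single cut returns the opened circle; with several cuts the piece is
    chosen by a :func:`select_fragment` criterion (default ``largest``) and
    the rest (stuffer) is discarded.
    """
    if not plasmid.circular:
        raise UncutError(f"{plasmid.id} is already linear")
    frags = digest(plasmid, enzyme)
    if len(frags) == 1:
        return frags[0]
    return select_fragment(frags, keep)
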