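# Methods

This note records the models, conventions and defaults behind `adrecon`, and
what the synthetic test system does and does not establish about real data.

## Sequence model and coordinates

Sequences are double-stranded DNA stored as the top strand over {A,C,G,T};
IUPAC ambiguity codes are allowed only in enzyme recognition patterns,
because overlap detection and digestion semantics are ill-defined on
ambiguous construct sequences. External coordinates are 1-based inclusive
(`sites 1 to 2,566` style); internally everything is 0-based half-open, with
the conversion confined to `Span`. On circular sequences `start > end`
denotes an origin-wrapping span. Circular molecules have no meaningful
origin: every operation is either rotation-invariant or canonicalizes
explicitly (lexicographic minimum over all rotations of both strands, ties
to the forward strand, computed with Booth's least-rotation algorithm so
35-kb plasmids canonicalize in linear time). Lowercase input is uppercased;
U is rejected.

## Restriction model

An enzyme is `(recognition, cut_top, cut_bottom)`: the top strand is cut
after `cut_top` bases from the recognition start, the bottom strand at
top-strand coordinate `cut_bottom`. The signed difference is the overhang
class; the geometry is mirror-symmetric, so a recognition found on the
bottom strand (relevant only for non-palindromic enzymes such as SapI) cuts
at mirrored offsets upstream. Overhangs are stored as the protruding
strand's bases written 5′→3′, which reduces ligation compatibility to a
reverse-complement equality test. Digestion is always complete; two sites
whose cut windows overlap are rejected as an unsupported configuration
rather than silently producing a partial digest. Origin-spanning sites on
circles are found by scanning the sequence extended with a prefix of length
(recognition + max offset − 1) and de-duplicating modulo the length. The
enzyme table is packaged data (TSV: name, recognition, cut_top, cut_bottom)
and user-extensible; SmaI and XmaI are listed separately because they share
a recognition but differ in chemistry. Methylation sensitivity, star
activity and partial-digest kinetics are out of scope.

## PCR

A primer anneals where its 3′-terminal `min_anneal` bases (default 18) match
the template exactly; zero matches is a no-amplification error and more than
one is mispriming. The match is then extended 5′-ward as far as it stays
exact; everything beyond is tail and is copied into the amplicon verbatim.
On linear templates the pair must converge; on circular templates a
divergent pair performs inverse PCR across the retained arc — this is how
the E3 deletion is modelled. Amplification is error-free by assumption
(high-fidelity polymerase); polymerase error models are a non-goal.

## Isothermal assembly

A junction between two fragment termini is the longest exact suffix-prefix
match with length in `[min_overlap, max_overlap]` (defaults 15 and 80 bp;
the designed junctions are 30-40 bp, so 15 leaves margin for
digestion-trimmed junctions). Matching is exact — the enzymatic chew-back
and anneal mechanism tolerates no mismatches at this scale, and mismatch
tolerance would introduce ambiguity with no ground truth. Because the
exonuclease resects fragment ends regardless of chemistry, a released
fragment's terminal restriction-site remnant (e.g. `GGCCGC` after a NotI
release, or the pad+SapI handle on a deletion amplicon) sits *outside* the
genomic homology; the matcher therefore allows up to `end_slack` bases
(default 12; 16 in the cassette-insertion step, whose reverse-primer handle
is 13 nt) to be trimmed from the abutting termini before matching. Exact
zero-trim junctions always take precedence, then minimal total trim, then
maximal overlap, so the procedure is deterministic. End chemistry is ignored
by assembly (chew-back destroys it) but enforced strictly by ligation.

Assembly builds the directed junction graph over all ordered fragment pairs
in both orientations and searches it exhaustively (≤12 fragments, sorted
enumeration). It succeeds only when exactly one distinct product uses every
fragment — no solution and multiple solutions are distinct, diagnosable
errors, and an overlap found just below `min_overlap` is reported as a
near-miss hint. Circular products are canonicalized and the junction report
(participants, overlap, trims, product position) is remapped accordingly.

## Partitioning and the primer grammar

The inter-arm interval is split into an even number of near-equal fragments
(length spread ≤ 10%); every junction, including the two arm junctions,
carries an overlap drawn from the 30-40 bp window (default: the 35-bp
midpoint). Boundaries may shift by ≤ 200 bp to keep release-enzyme sites out
of their own inserts and to keep each boundary's 25-bp annealing windows
unique on both strands (exact-match count = 1).

Primers follow three grammars:

* vector-adjacent: 25-bp vector anchor + restriction site + genomic anneal.
  In the reference forward primers the NotI recognition overlaps the
  anchor's final `GC` (`...AATTGC` + `GGCCGC` reconstitutes `GCGGCCGC`);
  the parser tolerates a ≤2-nt anchor/site fusion and the designer
  reproduces it, so regenerated primers are byte-compatible with the
  reference layout.
* internal-junction: fully genomic; lengths are chosen so that
  `|rev| + |fwd| − seed` equals the planned junction overlap, with the seed
  required to be ≥ 10 nt (the smallest value that uniquely identifies all
  three reference junctions without false positives on shuffled controls).
* deletion (inverse PCR): short pad + SapI recognition + 1-nt spacer +
  24-nt cassette-matching tail + ≥20-nt genomic anneal, mirroring the
  reference E3-deletion primers (their SapI handle sits after a 3-5 nt pad).

Genomic anneals start at 25 nt and extend to at most 35 nt to reach a Tm
floor of 58 °C under a deliberately simple, documented formula (Wallace rule
below 14 nt, else `64.9 + 41·(GC − 16.4)/N`): the package needs a
reproducible ranking, not thermodynamic accuracy, and the reference primer
set itself shows the "25-bp" rule being stretched (one genomic portion is
31 nt). Secondary-structure screening (hairpins, dimers) is a non-goal.
Parsing recovers a primer's decomposition from its sequence alone; with a
genome supplied, the grammar-determined anneal is located by unique exact
match (falling back to the longest unique 3′-terminal match ≥ 15 nt for
unrecognized layouts). For unanchored primers, tail detection is restricted
to the sub-cloning tail set {NotI, SrfI, SapI} behind a ≤6-nt pad — without
this restriction a fully genomic primer would occasionally be misparsed when
a random recognition string appears near its 5′ end.

## The reconstruction workflow

The pipeline follows the reference workflow exactly: vector positions 3..973
are replaced by the 64-nt MCS (every MCS enzyme must remain exactly as
frequent in the product as in the MCS itself); the arm plasmid inserts
PmeI — left arm — SapI-stuffer-SapI — right arm — PmeI between the NotI and
SrfI sites. The two SapI recognitions sit inside the stuffer pointing
outward, placed so that the 8/11 cut offsets land exactly on the arm
boundaries: linearization drops the stuffer and exposes scar-free arm
termini. The stuffer spacers (4 + 6 + 1 nt) are minimal deterministic
sequences, re-drawn from the seeded stream if they would create a site; the
reference construct's synthesized spacers are not public, so these are the
package's own choice, recorded in the emitted GenBank.

Fragment 5 is first cloned alone (pad+NotI / pad+SrfI primers, digest,
ligation into the backbone — one sticky and one blunt end force the
orientation), the E3 interval is excised by inverse PCR and replaced by the
cassette released from its donor (three EcoRV sites; the cassette is the
largest piece). The engineered plasmid then serves as the PCR template for
fragment 5 in the intermediate build. Release digests must cut exactly once
per enzyme per intermediate. The final assembly takes exactly four pieces;
rescue requires exactly two terminal-enzyme sites and selects the genome
piece by cassette content. PmeI's blunt cut (`GTTT^AAAC`) leaves 4-nt scars
(`AAAC...GTTT`) outside the ITRs; verification treats ≤4-nt terminal scars
as documented, and — because a linear dsDNA molecule has no intrinsic
strand and circular canonicalization may pick either — accepts the rescued
genome in either orientation. A genuine inverted-cassette fault is still
detected and named. Verification failure reports the first divergence
coordinate and per-region identity; a digest band table (descending
top-strand lengths) accompanies the report for any chosen enzymes. Reference
gel band values are not reproduced: they depend on an unavailable cassette
sequence, so the *procedure* (digest table, conservation, determinism) is
what the package validates.

## Synthetic data

`synth_genome` emulates the structural constraints of an adenovirus genome
at serotype-55 scale: 34,776 bp, 137-bp inverted terminal repeats (a
realistic adenovirus ITR scale; the true AdV14/55 ITR lengths are not fixed
by the workflow, and the parameter is configurable), arms at 1..2,566 and
34,616..34,776, and an E3-like dispensable interval. The interval defaults
to 25,000..28,200 — the ~3-kb scale of the real E3 — placed wholly inside
the fifth of six near-equal fragments, as the engineering route requires
(real genomes meet this by choosing fragment boundaries around their E3).
Forbidden sites are removed by local patching (one-base substitutions at
site centres, mirrored inside the ITRs to preserve their complementarity)
rather than whole-genome rejection, which would be intractable at 35 kb.
The generator's default forbidden set is the terminal enzyme (PmeI) alone;
the workflow's synthetic runs extend it to the full working set
{PmeI, NotI, EcoRI, EcoRV, ClaI, SrfI, SapI}, because a uniform random 35-kb
sequence contains ~8 copies of any 6-mer and the release digests would
otherwise cut inside their own inserts — real genomes satisfy this by the
deliberate enzyme choice, which requires the sites to be absent. Every
generated artifact re-scans its own constraints after generation; the same
seed always yields the same bases.

The bundled pBR322 is a deterministic **synthetic stand-in** (4,361 bp)
reproducing the landmarks the workflow uses — `TT` at positions 1-2, the
upstream-anchor 23-mer ending at position 2 across the origin, the
downstream-anchor 23-mer at 974-996, and a backbone free of all
workflow-enzyme sites — not the true vector sequence. Anchors, MCS, enzyme
offsets and the two reference primer tables are byte-exact packaged data.

What passing tests show: that the route's logic is sound — the grammar,
digests, assemblies and verifications compose to exact identity for any
genome satisfying the stated constraints. What they do not show: behaviour
on real genomes with repeats, biased composition, near-duplicate anneal
windows, or enzyme sites that force non-uniform fragment boundaries; none
of the biology (transfection, replication, reporter expression) is modelled.

## Problem sizes and determinism

All shipped analyses run at full scale (34,776-bp genomes, 38-kb final
plasmids); a complete pipeline run takes well under a second, and the
acceptance script's twenty-seed identity property a few seconds. Every
source of randomness flows from a single integer seed through `random.Random`
streams; replaying a configuration and seed reproduces byte-identical
sequences, and the build record retains every intermediate.
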