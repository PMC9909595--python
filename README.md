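# adrecon

In-silico planner and simulator for rebuilding large viral genomes — in
particular adenovirus genomes (~26-45 kb linear dsDNA) — inside a low-copy
plasmid by overlap-based isothermal (Gibson) assembly.

## The problem

Cloning a whole adenovirus genome by classical restriction cloning is limited
by the scarcity of usable sites in any given serotype. A sequence-independent
alternative partitions the genome into ~6-kb PCR fragments whose termini are
programmed, through primer tails, to share 30-40 bp of sequence with their
neighbours; the fragments are sub-cloned pairwise into a vector, engineered
at will (here: the dispensable E3 region is swapped for a reporter cassette),
released by restriction digestion, and fused in one pot into a single plasmid
carrying the complete recombinant genome between the two inverted terminal
repeats (ITRs). A rare-cutter (PmeI) placed at both termini, absent from the
genome itself, then liberates the genome for virus rescue.

`adrecon` is for people designing or debugging such builds: it checks primer
grammars, predicts every intermediate product base-by-base, and proves (or
refutes) that a planned route reproduces the intended genome exactly.

## The model

* **Digestion** — an enzyme is a recognition pattern plus two cut offsets
  (`cut_top`, `cut_bottom`); the signed difference is the overhang (0 blunt,
  >0 a 5′ overhang, <0 a 3′ overhang; type-IIS enzymes such as SapI
  (GCTCTTC(1/4)) cut outside the pattern). Fragments carry explicit end
  chemistry; ligation joins ends whose protruding strands are reverse
  complements.
* **Junction arithmetic** — for a fully genomic primer pair flanking a
  fragment junction, the amplicon overlap is `|rev| + |fwd| − s`, where `s`
  is the longest suffix of the forward primer equal to a prefix of the
  reverse complement of the reverse primer.
* **Isothermal assembly** — a junction is the longest exact suffix-prefix
  match between two fragment termini within `[min_overlap, max_overlap]`
  (default 15-80 bp); because the exonuclease chew-back resects ends, up to
  `end_slack` (12) terminal scar bases (restriction-site remnants) may be
  trimmed before matching. Assembly succeeds only when the junction graph
  admits exactly one Hamiltonian cycle (circular) or path (linear).
* **Circular sequences** have no distinguished origin: products are
  canonicalized (lexicographic minimum over all rotations of both strands)
  and all comparisons are rotation/strand-invariant.

## Worked example

```bash
python examples/04_full_reconstruction.py
```

```
genome: 34776 bp; cassette replaces E3 at 25000..28200
fragment spans: [(2532, 7885), (7851, 13238), (13204, 18592), (18558, 23945), (23911, 29298), (29264, 34650)]
designed junction overlaps: [35, 35, 35, 35, 35] bp
amplicons: 6, intermediates: 3, final pieces: 4
final construct: 38017 bp circular
rescued genome: 34589 bp linear
verification: PASS (terminal scars (4, 4))
```

The run generates a seeded 34,776-bp synthetic ITR-bearing genome, splits it
into six fragments of ~5.4 kb with 35-bp junction overlaps, simulates all six
PCRs, the three pairwise sub-clonings, the E3→cassette replacement
(inverse PCR + assembly), the release digests, the final four-piece assembly
(38,017 bp plasmid) and the PmeI rescue. The rescued genome (34,589 bp =
34,776 − 3,201 bp E3 + 3,006 bp cassette + 2×4 nt scars) is compared
base-by-base against the directly spliced expectation: `PASS` means they are
identical apart from the documented 4-nt blunt scars outside the ITRs.

Checking a primer set against the grammar (here the packaged reference set):

```bash
adrecon fixtures --out-dir fx && adrecon check-primers --primers fx/table1_primers.tsv
...
ADV-1-R/ADV-2-F    40
ADV-3-R/ADV-4-F    40
ADV-5-R/ADV-6-F    35
overall            PASS
```

The other examples (`examples/01`-`05`) each demonstrate one capability:
digestion band tables, primer parsing, split-and-reassemble, and the
partition/design/QC layer. The same functionality is scriptable through the
`adrecon` CLI (`scan-sites`, `digest`, `partition`, `design-primers`,
`check-primers`, `pcr`, `assemble`, `reconstruct`, `verify`, `synth-genome`,
`synth-cassette`, `fixtures`).

## Layout

```
src/adrecon/
  seqcore.py      sequences, spans, topology, FASTA/GenBank I/O
  restriction.py  enzyme model, site scanning, digestion, end chemistry
  design.py       partitioning, primer grammar, junction arithmetic, QC
  insilico.py     PCR / inverse PCR, ligation, isothermal assembly
  workflow.py     the full reconstruction pipeline + verification
  synthfix.py     seeded synthetic genomes/cassettes + packaged fixtures
  cli.py          thin command-line interface
  data/           primer tables, anchors, MCS, enzyme TSV, vector stand-in
```

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
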