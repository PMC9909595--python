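"""Partition a genome and design its amplification primers.

Shows the planning layer on its own: split the inter-arm interval into six
near-equal fragments with 30-40 bp junction overlaps, design the tailed
primer set, and run the pre-flight QC report (junction overlaps, anchor
integrity, restriction tails, anneal uniqueness, Tm spread).
"""

from adrecon import (Span, SynthGenomeSpec, default_enzymes,
                     design_primer_pairs, plan_partition, synth_genome,
                     validate_plan)
from adrecon.workflow import WORKFLOW_FORBIDDEN

enzymes = default_enzymes()
genome = synth_genome(SynthGenomeSpec(forbidden=list(WORKFLOW_FORBIDDEN), seed=1))

release = [(enzymes["NotI"], enzymes["EcoRI"]),
           (enzymes["NotI"], enzymes["EcoRV"]),
           (enzymes["NotI"], enzymes["ClaI"])]
plan = plan_partition(genome, (Span(1, 2566), Span(34616, 34776)), 6, release)
primers = design_primer_pairs(genome, plan)

print("fragment spans (~5.4 kb each):")
for i, s in enumerate(plan.fragments, 1):
    print(f"  fragment {i}: {s.start:>6}..{s.end:<6} ({s.end - s.start + 1} bp)")
print(f"junction overlaps: {plan.junction_overlaps()} bp")
print(f"arm overlaps: {plan.arm_overlaps()} bp")
print("\nprimers:")
for p in primers:
    print(f"  {p.name:<9} {p.role:<20} {len(p.bases):>2} nt")
print()
print(validate_plan(genome, primers, plan))
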