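"""Digest a plasmid and read the band table.

Builds the MCS-bearing backbone from the bundled vector stand-in, digests it
with NotI + SbfI (the sub-cloning pair), and prints the fragment table.  The
two bands are the linearized vector (the cloning recipient) and the short
MCS stuffer that the digest discards; their lengths sum to the plasmid size.
"""

from adrecon import band_sizes, build_backbone, default_enzymes, digest, fixtures

enzymes = default_enzymes()
backbone = build_backbone(fixtures().pbr322)   # 4,361 - 971 + 64 = 3,454 bp

frags = digest(backbone, [enzymes["NotI"], enzymes["SbfI"]])
print(f"substrate: {backbone.id}, {len(backbone)} bp circular")
print(f"bands: {band_sizes(frags)} (sum {sum(band_sizes(frags))})")
for f in frags:
    print(f"  {len(f):>5} bp  left={f.left_end.kind:<11} right={f.right_end.kind}")
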