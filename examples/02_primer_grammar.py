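"""Parse the reference fragment-amplification primers.

The twelve bundled primers follow a strict grammar: vector-adjacent primers
are 25-bp vector anchor + restriction-site tail + genomic anneal, while the
primers facing a fragment junction are fully genomic.  The arithmetic on each
junction pair (|rev| + |fwd| - seed) gives the genomic overlap the two
amplicons will share — the quantity isothermal assembly relies on, which the
design keeps inside the 30-40 bp window.
"""

from adrecon import fixtures, junction_overlap, parse_primer

fx = fixtures()
print("primer        role                 anchor         site   anneal")
for name, seq in fx.table1.items():
    p = parse_primer(seq)
    print(f"{name:<13} {p.role:<20} {p.anchor_kind or '-':<14} "
          f"{p.re_name or '-':<6} {len(p.anneal)} nt")

print("\njunction overlaps implied by the primer pairs:")
for i in (1, 3, 5):
    ov = junction_overlap(fx.table1[f"ADV-{i}-R"], fx.table1[f"ADV-{i + 1}-F"])
    print(f"  fragments {i}/{i + 1}: {ov} bp")
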