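"""Encode one ORF into the six frame-aware feature blocks.

Builds a short ORF, encodes each measurement, and prints the non-zero
entries of the small blocks by name.  The six widths (12, 48, 64, 4096,
21, 441) concatenate to the full 4682-dimensional vector used by the
classifier.
"""

from orfsvm import assemble, feature_names

orf = "ATG" + "GCT" + "AAA" + "TCT" + "GGA" + "TAA"  # M A K S G *

vec = assemble(orf)
print(f"ORF: {orf} ({len(orf)} bp, {len(orf) // 3} codons)")
print(f"full feature vector width: {vec.total_width}")
for block in vec.blocks:
    print(f"  measurement {block.measurement_id}: width {block.width}")

names = feature_names((1, 3, 5))
values = assemble(orf, (1, 3, 5)).values
print("\nnon-zero entries of blocks 1 (positional bases), 3 (codons), 5 (residues):")
for name, value in zip(names, values):
    if value:
        print(f"  {name:>14s} = {value:.4f}")
print(
    "\nEach frequency is normalised within its own group (codon position,\n"
    "pair group, or whole block), so groups sum to 1 over counted windows."
)
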