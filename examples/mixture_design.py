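"""Trimer-mixture design: incorporation probabilities and exchange
statistics for the packaged 26-position randomization scheme.

Builds the 19-trimer standard mixture (cysteine excluded), spikes the
resident trimer at 0.7 at each randomized position, and prints what the
design implies: the per-position codon probabilities, the average
exchange probability, and the expected number of codon exchanges per
gene.
"""

from trimerlib import apply_coupling_corrections, exchange_probabilities, position_mixture
from trimerlib.thisf import standard_mixture, thisf_scheme

scheme = thisf_scheme()
mixture = standard_mixture()

print("standard mixture (19 trimers, protein-level fractions):")
for e in mixture.entries:
    print(f"  {e.amino_acid}  {e.codon}  f={e.protein_fraction:.3f}  c={e.coupling_correction}")

pm = position_mixture(scheme, 179)  # Lys179, resident codon AAA
print("\ncodon probabilities at position 179 (resident AAA, f_K=0.101):")
print(f"  P(AAA) = {pm['AAA']:.4f}   # 0.7 spike + 0.3*0.101 from the mix")
print(f"  P(any foreign codon) = {sum(v for c, v in pm.items() if c != 'AAA'):.4f}")

per_pos, mean, total = exchange_probabilities(scheme)
print(f"\nexchange probability: min {min(per_pos):.3f}, max {max(per_pos):.3f}, "
      f"mean {mean:.2f}")
print(f"expected codon exchanges per gene: {total:.2f}")
print("(a library member therefore carries ~7 amino acid changes on average)")

amounts = apply_coupling_corrections(mixture, renormalize=True)
print(f"\nphysical molar share of the slowest-coupling trimer (W, TGG): "
      f"{amounts['TGG']:.4f}")
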