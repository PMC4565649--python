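"""Library-diversity arithmetic: mutant classes, unique species and the
comparison against degenerate-codon randomization.

Reproduces the headline numbers of the packaged design: the actual
diversity of a 1.8e8-clone library with 26 randomized positions, the
frameshift-free fraction, the expected wild-type frequency, and the
gene:protein redundancy of NNS randomization.
"""

from trimerlib.diversity import (
    binomial_classes,
    degenerate_codon_stats,
    frameshift_free_probability,
    unique_species,
    wildtype_frequency,
)

n, p, L, m = 26, 0.27, 1.8e8, 18
stats = binomial_classes(n, p, L, m)

print(f"library: n={n} randomized positions, p={p}, L={L:.1e} clones, "
      f"m={m} foreign residues")
print("\nk   P_k        N_k        L_k        C_k")
for k in range(0, 11):
    print(f"{k:<3} {stats.P_k[k]:<10.3g} {float(stats.N_k[k]):<10.3g} "
          f"{stats.L_k[k]:<10.3g} {stats.C_k[k]:<10.3g}")

S = unique_species(stats)
ff = round(frameshift_free_probability(), 1)
print(f"\nunique species S: {S:.3g}")
print(f"frameshift-free probability: {frameshift_free_probability():.3f} "
      f"(reported as {ff})")
print(f"actual diversity (S * {ff}): {S * ff:.2e}  # ~0.89e8 unique proteins")
print(f"frameshift-free genes (L * {ff}): {L * ff:.2e}")
# ratio of the two quantities as reported, i.e. at two significant figures
genes = round(L * ff / 1e7) * 1e7
proteins = round(S * ff / 1e6) * 1e6
print(f"gene:protein ratio: {genes / proteins:.2f}  # every gene ~1 protein")

d = degenerate_codon_stats("NNS", n)
print(f"\nNNS over {n} positions: {d['gene_count']:.2g} genes for "
      f"{d['protein_count']:.2g} proteins, ratio {d['ratio']:.0e}")
print("(trimer randomization removes that 2e5-fold codon redundancy)")

wt = wildtype_frequency(n, p, frameshift_free_fraction=ff)
print(f"\nexpected wild-type frequency: {wt:.2e} "
      f"-> >100 wild types among 1e6 transformants")
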