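# trimerlib

Design and quality control of **trinucleotide-randomized gene libraries**.

Combinatorial protein engineering needs gene libraries whose diversity is
spent where it matters. Randomizing codons with mixtures of trinucleotide
phosphoramidites — one pre-assembled trimer per allowed amino acid, the
wild-type ("resident") trimer spiked in at a controlled molar fraction —
gives position-wise control over both the exchange probability and the
residue spectrum, with no stop codons and no codon redundancy. The genes
are then built by splitting the sequence into short synthesizable modules
whose Type-IIS (BsaI/Esp3I) junction overhangs direct a one-pot
sticky-end ligation to a single product, and the realized library is
checked by sequencing clones and calling mutations against the reference.

`trimerlib` implements this whole loop as a Python library with a thin
CLI:

| module | what it does |
|---|---|
| `trimerlib.mixtures` | trimer mixture composition, per-position codon probabilities, expected exchange statistics, coupling corrections |
| `trimerlib.planner` | split a gene into 40–90 nt modules with pairwise-unique, non-palindromic junction overhangs; emit synthesis oligos, fill-in primers and PCR primers |
| `trimerlib.duplex`, `trimerlib.assembly` | simulate Klenow fill-in, BsaI/Esp3I/SmiI digestion and sticky-end ligation; verify that a module set assembles into exactly one full-length open reading frame |
| `trimerlib.analyzer` | call mutations from aligned clone sequences at nucleotide/codon/amino-acid level; five report tables; exchange-rate and mutant-class summaries |
| `trimerlib.diversity` | binomial mutant classes, unique-species counts, frameshift-free probability, NNN/NNK/NNS comparisons, practical diversity |
| `trimerlib.simulate` | synthetic sequenced clones with exact ground truth, for validating the analysis end to end |
| `trimerlib.thisf` | the packaged demonstration dataset: the tHisF (β/α)₈ scaffold with 26 randomized substrate-cleft codons, its 14 modules and all primers |

## The model in brief

At each of *n* randomized positions the resident trimer is added at molar
fraction 0.7 on top of 0.3 equivalents of a standard 19-trimer mixture
(cysteine excluded; fractions fᵢ blended 3:1 from surface and catalytic
residue frequencies). The exchange probability at position *j* is

&nbsp;&nbsp;&nbsp;&nbsp;p_j = 0.3 · (1 − f_resident(j)),

so a gene carries on average Σ p_j exchanges, binomially distributed over
mutant classes k = 0…n. With m = 18 foreign residues per position, class
k holds N_k = C(n,k)·18ᵏ species, of which a library of L clones is
expected to realize N_k when the per-species copy number C_k = P_k·L/N_k
is ≥ 1 and L_k = P_k·L otherwise; the sum is the actual diversity S.
Synthesis errors (Δ1/Δ2/Δ3 deletions and substitutions) reduce this by
the frameshift-free fraction P = (1−r_nr)^c_nr · (1−r_r)^c_r.

## Worked example

```sh
python examples/diversity_statistics.py
```

prints, for the packaged full-size library (n = 26, observed exchange
rate p = 0.27, L = 1.8×10⁸ clones):

```
unique species S: 1.77e+08
frameshift-free probability: 0.475 (reported as 0.5)
actual diversity (S * 0.5): 8.87e+07  # ~0.89e8 unique proteins
frameshift-free genes (L * 0.5): 9.00e+07
gene:protein ratio: 1.01  # every gene ~1 protein
NNS over 26 positions: 1.4e+39 genes for 6.7e+33 proteins, ratio 2e+05
expected wild-type frequency: 1.40e-04 -> >100 wild types among 1e6 transformants
```

The `1.01` is the point of the method: with trimer randomization nearly
every frameshift-free gene encodes a distinct protein, whereas NNS
randomization of the same 26 positions wastes a factor of 2×10⁵ on codon
redundancy. The other examples each exercise one capability —
`mixture_design.py` (expected 7.31 exchanges per gene at a mean
probability 0.28), `plan_assembly.py`, `verify_assembly.py` (one
260-codon ORF ending in His₆-stop from the 14 packaged modules), and
`simulate_and_analyze.py` (parameter recovery from simulated clones).

The same functionality is available from the shell, e.g.:

```sh
trimerlib diversity --n 26 --p 0.27 --L 1.8e8 --frameshift-free 0.5
trimerlib assemble
trimerlib simulate --clones 100 --seed 1 --out-dir sim/
trimerlib analyze --alignment sim/alignment.fasta --mask sim/mask.fasta --out-dir reports/
```

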