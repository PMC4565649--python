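# Methods

This note documents the models behind `trimerlib`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic-clone
generator does and does not emulate.

## Randomization model

A randomized codon position is synthesized from a trimer mixture: the
resident (wild-type) trimer at molar fraction `resident_fraction`
(default 0.7) plus `mixture_fraction` (default 0.3) equivalents of a
standard mixture with one codon per allowed amino acid. The packaged
standard mixture contains 19 trimers — cysteine is excluded to avoid
disulfide/oxidation artifacts on the protein surface — with protein-level
fractions fᵢ blended from surface-residue frequencies (weight 0.75) and
catalytic-residue frequencies (weight 0.25), renormalized after the
exclusion. The packaged table is the published mixture itself, stored as
data; `build_standard_mixture` re-derives a mixture from user-supplied
source tables (which may be unnormalized occurrence counts — each source
is normalized before blending, so the blend is scale-invariant).

Incorporation probabilities at a position are
`P(resident) = resident_fraction + mixture_fraction·f_resident` and
`P(codon i) = mixture_fraction·fᵢ` otherwise. The exchange probability is
`p_j = mixture_fraction·(1 − f_resident(j))`: drawing the resident
residue's own trimer from the mixture is not an exchange, and a silent
codon variant of the resident residue is likewise not counted. For the
packaged 26-position scheme this gives Σp_j = 7.31 expected exchanges per
gene and a mean p̄ = 0.2813, which reports as 0.28. Note that summing the
same expression over the 24-position subset gives 6.76, slightly above
the historically quoted 6.69 for that library; the package reports the
value its own formula produces.

Supplier-side coupling corrections cᵢ convert protein-level fractions to
physical molar amounts (`amount_i = fᵢ·cᵢ`, optionally renormalized).
They affect only the synthesis order export, not exchange expectations —
the corrections exist precisely to make the realized protein-level
fractions equal fᵢ.

## Fragmentation and oligo design

Genes are split at borders whose 4-nt junction windows avoid randomized
codons. Junction overhangs must be pairwise distinct, non-palindromic,
and not reverse complements of one another (including the two terminal
vector-cloning overhangs); `validate_plan` also rejects a module whose
body contains a recognition site of one of its own flank enzymes. Border
search scans each feasible window outward from its midpoint and accepts
the first candidate satisfying all rules (deterministic, reproducible
plans); a `borders=` argument forces an exact border set instead.

Module length is constrained through the synthesis-oligo length
(`min_len`/`max_len`, defaults 40/90 nt, the practical window of chemical
synthesis; the two-flank budget of 14 nt is included, SmiI-terminal
oligos may exceed the cap by the 8-nt SmiI site). A stretch without
randomized codons that cannot fit the cap is emitted as a PCR fragment
with a primer pair instead of a synthesis oligo.

Flank grammar: interior junctions carry Esp3I (CGTCTC N1/N5); modules at
the edges of an intermediate (B-level) group carry SmiI (blunt,
ATTT^AAAT) plus BsaI (GGTCTC N1/N5), the BsaI site being reserved for the
final gene-level digestion. A module whose body contains an Esp3I site
switches its interior flanks to BsaI (and vice versa; both sites present
is a planning error). The spacer base between recognition site and cut
window is C on the strand carrying the recognition sequence, matching
synthesis practice. Fill-in primers are the reverse complement of the
oligo's 3'-terminal 20 nt, extended up to 27 nt until the annealing site
is unique.

B-level grouping defaults to packing consecutive modules into groups of
at most four; `group_sizes` overrides it.

## In-silico assembly

Duplexes are modelled with full top/bottom strands and 5' protrusions at
the ends (the only end chemistry Type-IIS digestion produces). Cut
geometry: BsaI and Esp3I cut 1 nt downstream of the recognition site on
the cut strand and 5 nt downstream on the other, leaving 4-nt 5'
protrusions; SmiI cuts bluntly at its center. Sites are only cleaved when
the site and both cut positions lie in the double-stranded core.
Digestion conserves nucleotides and returns products left to right.

Ligation joins two ends when their protrusions are reverse complements
of each other, in either fragment orientation; blunt ends join only
blunt ends, and any covalent join requires both 5' phosphates — which is
how the bench protocol terminates B-level ligations: SmiI-linearized
ends are dephosphorylated before the sticky digestion. An end with more
than one compatible partner is an ambiguity; with `require_unique` it is
an error naming the fragments, otherwise ambiguous ends stay open and
are reported. Chains whose outer ends join each other are detected and
reported as circular products but not pursued further.

`assemble_hierarchy` replays the full protocol: fill-in → staged
digestion (blunt cutters first, with dephosphorylation) → directed
ligation per group → gene-level digestion and ligation → verification
(single product, length, one open reading frame found as the longest
ATG..stop frame on the top strand). A missing module leaves its
junctions open and the report names them.

## Mutation calling

Targets must be pre-aligned to the reference; the package computes no
alignments. Gap runs in a target are grouped into maximal runs before
classification: runs of length 1–3 are Δ1/Δ2/Δ3 events (assigned
inside/outside by the codon containing the run start), longer runs are
counted as anomalous and excluded from the Δ rates. Δ rates are per
targeted triplet inside the mask and per nucleotide outside. A codon
containing both a substitution and a gap is classified by the gap and
excluded from the exchange-rate numerator (avoids double counting).
Silent codon changes produce nucleotide- and codon-level records but no
amino-acid record. Ambiguity codes (N) flag the record; N-containing
codons are excluded from rate numerators and denominators. Insertions
(target bases opposite reference gaps) are reported at nucleotide level
only. The classic 250-target cap is enforced only in strict mode and
otherwise downgraded to a warning, since it is a limitation of the
original implementation rather than of the method.

The observed exchange rate at a position is the number of non-wild-type
codons there divided by the clones sequenced — deleted codons stay in
the denominator. The five report tables are TSV-first (bit-stable for
diffing), with an optional single-workbook XLSX export; the exact column
layouts are this package's own.

## Diversity mathematics

Mutant-class probabilities are binomial in the scalar mean p (the
published convention); a Poisson-binomial variant over the per-position
vector is available (`p_vector=`) but non-default, because the scalar
form is what the reported numbers use and the difference is negligible
at the packaged spread of p_j (0.26–0.29). Unique-species counting uses
the saturation cap: class k contributes its full species count N_k when
the per-species copy number C_k ≥ 1 and its expected clone count L_k
otherwise. This rule reproduces the reported diversities (0.89×10⁸ and
0.6×10⁶ after the ×0.5 frameshift correction, stable for p anywhere in
0.27–0.28) but deliberately overestimates near C_k ≈ 1, where true
occupancy is 1−e^{−C_k}; the alternative
`method="expected_distinct"` (Σ N_k·(1−(1−1/N_k)^{L_k})) agrees with
Monte-Carlo simulation to better than 2 % and is the right choice when
the absolute count matters more than comparability with the reported
convention.

The frameshift-free probability multiplies per-codon survival over the
two site classes; the defaults (236 non-randomized codons at 0.0026,
24 randomized at 0.0054, the cumulative Δ1+Δ2 frequencies per codon)
give 0.475, reported at one decimal as 0.5, and downstream quantities
carry the one-decimal value as reported. The expected wild-type
frequency is the binomial zero term times the frameshift-free fraction;
a stable-protein fraction is exposed as a separate optional factor and
defaults to 1, because (1−0.27)²⁶·0.5 alone reproduces the reported
1.4×10⁻⁴.

## Synthetic clones

`simulate_clones` draws, per clone and randomized position, a codon from
the position mixture, then plants synthesis errors independently:
per-triplet rates at randomized sites (substitution 4.9×10⁻³, Δ1 5×10⁻³,
Δ2 4×10⁻⁴, Δ3 1.8×10⁻², the packaged observed rates) and per-nucleotide
rates outside (4.3×10⁻⁴, 8.4×10⁻⁴, 4.5×10⁻⁵, 1.8×10⁻⁵). When several
events hit one site the largest deletion wins, matching the analyzer's
classification. Substitution errors pick a uniform non-identical base;
transition bias is not modelled. Output is gap-aligned against the
reference with exact per-event ground truth, and a fixed seed gives
byte-identical output.

What the generator does **not** emulate, hence what passing tests do not
show about real data: sequencing/basecalling errors, chimeric or
misassembled clones, coupling-efficiency drift across positions (all
positions share one mixture), insertions, and alignment errors (targets
are emitted pre-aligned; real pipelines must align first). Two further
detectability caveats: adjacent planted deletions can merge into one
longer run in the alignment, so at the default rates a small fraction of
Δ3 pairs at neighbouring positions is classified as an anomalous run;
and a substitution error inside a randomized triplet is only visible as
an "unplanned" event when the resulting codon falls outside the
position's allowed codon set — roughly a third of single-base variants
of a drawn codon are themselves mixture codons — which is why
substitution-rate recovery is checked against the generator's ground
truth while deletion rates are recovered through the analyzer.

## Problem sizes and numerical choices

The validation suite simulates 400 clones for exchange-rate recovery
(~10⁴ randomized triplets), 4 000 clones (104 000 triplets) for
error-rate recovery at three binomial standard errors, and 10⁴ clones
for the mutant-class histogram, tested against the matched binomial by
chi-square at α = 0.01 with tail bins merged to an expected count of at
least 5. These sizes keep every check well inside a minute on one CPU
while leaving the statistical bands meaningful. All randomness flows
through explicit integer seeds. Tolerances on reported quantities follow
their printed precision (two decimals for rates, one to two significant
figures for diversities). Degenerate inputs are rejected with messages
naming the offending element (position, residue, fragment or overhang);
violations found by `validate_plan` are returned as data, not raised.

## Known limitations

- Overhang rules are purely combinatorial; ligase-fidelity scoring of
  near-cognate overhangs and primer melting-temperature optimization are
  out of scope.
- The assembly simulation is deterministic: no kinetics, stoichiometry,
  partial digestion or vector cloning.
- The diversity model assumes equal probability for all species within a
  mutant class; real per-position and per-residue biases make S an upper
  bound within classes.
- The planner is greedy without backtracking: a feasible plan can in
  principle be missed when early border choices exhaust the overhang
  space, in which case the error names the infeasible window and the
  border set can be forced explicitly.
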