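"""Fragmentation planning: split a gene into Type-IIS modules whose
junction overhangs direct a one-pot ligation to a single product.

Plans the packaged tHisF gene around its 26 randomized codons, validates
the overhang uniqueness rules, and prints the module table plus one
designed synthesis oligo with its fill-in primer.
"""

from trimerlib import plan_fragments, validate_plan
from trimerlib.thisf import RANDOMIZED_RESIDUES, coding_sequence

gene = coding_sequence()
plan = plan_fragments(gene, sorted(RANDOMIZED_RESIDUES))

print(f"{len(plan.fragments)} modules over {len(gene)} nt "
      f"({len(plan.junctions)} junctions):")
for f in plan.fragments:
    kind = "PCR" if f.pcr else "synthesis"
    print(f"  {f.id:>4}  {f.interval[0]:>3}..{f.interval[1]:<3} {kind:9} "
          f"overhangs {f.upstream_protrusion}/{f.downstream_protrusion} "
          f"randomized codons {f.randomized_codons or '-'}")

violations = validate_plan(plan)
print(f"\noverhang/uniqueness violations: {violations or 'none'}")
print("(empty means every junction is distinct, non-palindromic and not the"
      " reverse complement of another, so the ligation is unambiguous)")

frag = next(f for f in plan.fragments if not f.pcr)
print(f"\n{frag.id} synthesis oligo ({len(frag.synthesis_oligo)} nt):")
print(f"  {frag.synthesis_oligo}")
print(f"{frag.id} fill-in primer: {frag.fill_in_primer}")
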