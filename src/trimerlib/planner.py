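"""Splitting a gene into synthesizable Type-IIS modules.

A gene is divided at borders outside the randomized codons; each border
defines a 4-nt junction overhang shared by the two neighbouring modules.
Overhangs must be pairwise distinct, non-palindromic and not reverse
complements of one another, so that a one-pot sticky-end ligation is
directed to a single full-length product.  Modules are emitted as
top-strand synthesis oligos with enzyme flanks plus a fill-in primer;
wild-type stretches too long for chemical synthesis become PCR fragments
with a primer pair instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .duplex import revcomp
from .enzymes import ENZYMES

__all__ = [
    "FragmentSpec",
    "AssemblyPlan",
    "PlanError",
    "plan_fragments",
    "validate_plan",
    "design_oligos",
    "design_pcr_primers",
    "assembly_inputs",
]


class PlanError(ValueError):
    """No feasible border: the message names the window and the violated
    constraint instead of silently relaxing it."""


@dataclass
class FragmentSpec:
    """One gene module.

    ``interval`` is 0-based half-open on the extended sequence
    (5' extension + gene + 3' extension) and includes both junction
    overhang windows.  ``upstream_protrusion`` is the left 5' overhang on
    the top strand, ``downstream_protrusion`` the right 5' overhang on the
    bottom strand (both 5'->3').
    """

    id: str
    level: str  # "C", "B" or "gene"
    interval: tuple[int, int]
    body: str
    upstream_protrusion: str
    downstream_protrusion: str
    flank_plan: tuple[list[str], list[str]] = field(default_factory=lambda: ([], []))
    randomized_codons: list[int] = field(default_factory=list)
    pcr: bool = False
    synthesis_oligo: str | None = None
    fill_in_primer: str | None = None
    pcr_primers: tuple[str, str] | None = None


@dataclass
class AssemblyPlan:
    """Ordered modules, their junctions and the hierarchical grouping."""

    gene: str  # coding sequence as given
    extended: str  # 5' extension + gene + 3' extension
    ext5: str
    ext3: str
    fragments: list[FragmentSpec]
    junctions: list[tuple[str, str, str]]  # (left id, right id, top-strand overhang)
    b_groups: dict[str, list[str]]

    def fragment(self, fid: str) -> FragmentSpec:
        for f in self.fragments:
            if f.id == fid:
                return f
        raise KeyError(fid)


def _is_palindrome(ov: str) -> bool:
    return ov == revcomp(ov)


def _overhang_ok(ov: str, chosen: list[str]) -> str | None:
    """None if acceptable, else the violated rule."""
    if _is_palindrome(ov):
        return "palindromic overhang"
    for other in chosen:
        if ov == other:
            return f"duplicate of overhang {other}"
        if ov == revcomp(other):
            return f"reverse complement of overhang {other}"
    return None


def plan_fragments(
    gene: str,
    randomized_codons: list[int],
    min_len: int = 40,
    max_len: int = 90,
    borders: list[int] | None = None,
    ext5: str = "A",
    ext3: str = "ATAGC",
    max_group: int = 4,
    group_sizes: list[int] | None = None,
) -> AssemblyPlan:
    """Divide ``gene`` into modules whose junctions avoid the randomized
    codons.

    ``randomized_codons`` are 1-based protein positions.  ``min_len`` /
    ``max_len`` bound the synthesis-oligo length (module body plus enzyme
    flanks); a module without randomized codons may exceed ``max_len`` and
    is then flagged as a PCR fragment.  ``borders`` (1-based gene
    coordinates of junction starts) forces the border set instead of
    searching; candidate borders are otherwise scanned outward from the
    midpoint of each feasible window, first acceptable wins.  ``ext5`` /
    ``ext3`` are vector-side bases extending the terminal overhang windows
    beyond the coding sequence.
    """
    gene = gene.upper()
    ext = (ext5 + gene + ext3).upper()
    off = len(ext5)  # gene coordinate g (1-based) sits at ext index off+g-1
    flank_budget = 14  # two Type-IIS flanks (recognition + spacer)
    rand_nt = set()
    for p in randomized_codons:
        rand_nt.update(range(off + 3 * (p - 1), off + 3 * p))  # ext indices

    def junction_clear(j: int) -> bool:
        return not any(i in rand_nt for i in range(j, j + 4))

    chosen: list[str] = [ext[:4].upper(), ext[-4:].upper()]  # terminal overhangs
    if borders is not None:
        cut_sites = [off + b - 1 for b in borders]
        for j in cut_sites:
            if not junction_clear(j):
                raise PlanError(
                    f"forced border at gene position {j - off + 1}: junction "
                    f"window overlaps a randomized codon"
                )
            why = _overhang_ok(ext[j : j + 4], chosen)
            if why:
                raise PlanError(
                    f"forced border at gene position {j - off + 1}: {why}"
                )
            chosen.append(ext[j : j + 4])
    else:
        cut_sites = []
        s = 0
        while True:
            if len(ext) - s + flank_budget <= max_len:
                break  # final fragment fits
            lo_j = s + max(min_len - flank_budget, 8) - 4
            hi_j = min(s + max_len - flank_budget - 4, len(ext) - 5)
            found = None
            candidates = _outward(lo_j, hi_j)
            for j in candidates:
                if not junction_clear(j):
                    continue
                if _overhang_ok(ext[j : j + 4], chosen) is not None:
                    continue
                found = j
                break
            if found is None:
                # a module with no randomized codon may run long (PCR)
                widened = [
                    j
                    for j in range(hi_j + 1, len(ext) - 4)
                    if junction_clear(j)
                    and _overhang_ok(ext[j : j + 4], chosen) is None
                ]
                region_has_rand = any(
                    s <= i < hi_j + 4 for i in rand_nt
                )
                if widened and not region_has_rand:
                    found = widened[0]
                else:
                    raise PlanError(
                        f"no feasible border in window gene positions "
                        f"{lo_j - off + 1}..{hi_j - off + 1}: every junction "
                        f"overlaps a randomized codon or violates the "
                        f"overhang uniqueness rules"
                    )
            chosen.append(ext[found : found + 4])
            cut_sites.append(found)
            s = found
    # build fragments
    bounds = [0] + cut_sites + [len(ext) - 4]
    fragments: list[FragmentSpec] = []
    for i in range(len(bounds) - 1):
        a, b = bounds[i], bounds[i + 1]
        body = ext[a : b + 4]
        codons = sorted(
            p
            for p in randomized_codons
            if a <= off + 3 * (p - 1) and off + 3 * p <= b + 4
        )
        frag = FragmentSpec(
            id=f"C{i + 1}",
            level="C",
            interval=(a, b + 4),
            body=body,
            upstream_protrusion=ext[a : a + 4],
            downstream_protrusion=revcomp(ext[b : b + 4]),
            randomized_codons=codons,
            pcr=(not codons) and len(body) + flank_budget > max_len,
        )
        fragments.append(frag)
    junctions = [
        (fragments[i].id, fragments[i + 1].id, ext[j : j + 4])
        for i, j in enumerate(cut_sites)
    ]
    b_groups = _group(fragments, group_sizes, max_group)
    _assign_flanks(fragments, b_groups)
    plan = AssemblyPlan(
        gene=gene,
        extended=ext,
        ext5=ext5.upper(),
        ext3=ext3.upper(),
        fragments=fragments,
        junctions=junctions,
        b_groups=b_groups,
    )
    for frag in fragments:
        if frag.pcr:
            frag.pcr_primers = design_pcr_primers(frag, plan)
        else:
            frag.synthesis_oligo, frag.fill_in_primer = design_oligos(frag, plan)
    return plan


def _outward(lo: int, hi: int) -> list[int]:
    """Positions of [lo, hi] ordered from the midpoint outward
    (deterministic: the smaller index first on ties)."""
    if hi < lo:
        return []
    mid = (lo + hi) // 2
    order = [mid]
    for d in range(1, hi - lo + 1):
        if mid - d >= lo:
            order.append(mid - d)
        if mid + d <= hi:
            order.append(mid + d)
    return order


def _group(
    fragments: list[FragmentSpec],
    group_sizes: list[int] | None,
    max_group: int,
) -> dict[str, list[str]]:
    ids = [f.id for f in fragments]
    if group_sizes is None:
        import math

        n_groups = max(1, math.ceil(len(ids) / max_group))
        base, extra = divmod(len(ids), n_groups)
        group_sizes = [base + (1 if i < extra else 0) for i in range(n_groups)]
    if sum(group_sizes) != len(ids):
        raise PlanError(
            f"group sizes {group_sizes} do not cover {len(ids)} fragments"
        )
    groups, at = {}, 0
    for i, size in enumerate(group_sizes):
        groups[f"B{i + 1}"] = ids[at : at + size]
        at += size
    return groups


def _assign_flanks(
    fragments: list[FragmentSpec], b_groups: dict[str, list[str]]
) -> None:
    """Esp3I at interior junctions, SmiI+BsaI at B-fragment edges; a module
    whose body contains an Esp3I site switches its interior flanks to BsaI
    (and vice versa)."""
    edges_left = {members[0] for members in b_groups.values()}
    edges_right = {members[-1] for members in b_groups.values()}
    for frag in fragments:
        interior = _interior_enzyme(frag)
        left = ["SmiI", "BsaI"] if frag.id in edges_left else [interior]
        right = ["BsaI", "SmiI"] if frag.id in edges_right else [interior]
        frag.flank_plan = (left, right)


def _interior_enzyme(frag: FragmentSpec) -> str:
    body = frag.body.upper()

    def has_site(name: str) -> bool:
        rec = ENZYMES[name].recognition_seq
        return rec in body or revcomp(rec) in body

    if not has_site("Esp3I"):
        return "Esp3I"
    if not has_site("BsaI"):
        return "BsaI"
    raise PlanError(
        f"fragment {frag.id}: body contains both Esp3I and BsaI sites; no "
        f"Type-IIS flank enzyme available"
    )


def design_oligos(frag: FragmentSpec, plan: AssemblyPlan) -> tuple[str, str]:
    """Top-strand synthesis oligo and Klenow fill-in primer for a C module.

    Layout: [SmiI site if terminal] [recognition + C spacer] body
    [G spacer + reversed recognition] [SmiI site if terminal]; the spacer
    is C on whichever strand carries the recognition sequence.  The fill-in
    primer is the reverse complement of the oligo's 3'-terminal stretch
    (>=12 nt, extended until it anneals uniquely).
    """
    if frag.level != "C":
        raise ValueError("oligos are designed for C-level fragments")
    body = frag.body
    left, right = frag.flank_plan
    for name in set(left + right):
        enz = ENZYMES[name]
        if enz.end_type == "blunt":
            continue
        rec = enz.recognition_seq
        if rec in body.upper() or revcomp(rec) in body.upper():
            raise PlanError(
                f"fragment {frag.id}: body contains an internal "
                f"{name} recognition site"
            )
    left_sticky = next(n for n in left if ENZYMES[n].end_type != "blunt")
    right_sticky = next(n for n in reversed(right) if ENZYMES[n].end_type != "blunt")
    oligo = ""
    if "SmiI" in left:
        oligo += ENZYMES["SmiI"].recognition_seq
    oligo += ENZYMES[left_sticky].recognition_seq + "C"
    oligo += body
    oligo += "G" + revcomp(ENZYMES[right_sticky].recognition_seq)
    if "SmiI" in right:
        oligo += ENZYMES["SmiI"].recognition_seq
    n = 20
    while n < min(27, len(oligo)) and oligo.upper().count(
        oligo.upper()[-n:]
    ) > 1:
        n += 1
    primer = revcomp(oligo[-n:]).upper()
    return oligo, primer


def design_pcr_primers(frag: FragmentSpec, plan: AssemblyPlan) -> tuple[str, str]:
    """Forward/reverse amplification primers for a PCR module: the flanked
    oligo's first and last ~27 nt."""
    oligo, _ = design_oligos(replace(frag, pcr=False), plan)
    return oligo[:27].upper(), revcomp(oligo[-27:]).upper()


def validate_plan(plan: AssemblyPlan) -> list[str]:
    """Overhang-uniqueness and internal-site violations; empty iff valid.

    Checks: (a) junction overhangs pairwise distinct, (b) none palindromic,
    (c) none the reverse complement of another, (d) no fragment body
    contains a recognition site of one of its own flank enzymes.
    """
    violations = []
    overhangs = [(f"{l}/{r}", ov.upper()) for l, r, ov in plan.junctions]
    if plan.fragments:
        overhangs.insert(0, ("5'-terminus", plan.fragments[0].upstream_protrusion.upper()))
        overhangs.append(
            ("3'-terminus", revcomp(plan.fragments[-1].downstream_protrusion).upper())
        )
    for i, (where, ov) in enumerate(overhangs):
        if _is_palindrome(ov):
            violations.append(f"palindromic overhang {ov} at {where}")
        for where2, ov2 in overhangs[i + 1 :]:
            if ov == ov2:
                violations.append(
                    f"duplicate overhang {ov} at {where} and {where2}"
                )
            elif ov == revcomp(ov2):
                violations.append(
                    f"overhang {ov} at {where} is the reverse complement of "
                    f"{ov2} at {where2}"
                )
    for frag in plan.fragments:
        body = frag.body.upper()
        for name in set(frag.flank_plan[0] + frag.flank_plan[1]):
            enz = ENZYMES[name]
            if enz.end_type == "blunt":
                continue
            rec = enz.recognition_seq
            if rec in body or revcomp(rec) in body:
                violations.append(
                    f"fragment {frag.id}: internal {name} site in body"
                )
    return violations


def assembly_inputs(plan: AssemblyPlan):
    """Bridge to the in-silico assembly: per-fragment inputs, flank plans
    and B grouping ready for ``assembly.assemble_hierarchy``."""
    from .duplex import Duplex

    inputs: dict[str, Duplex | tuple[str, str]] = {}
    flanks = {}
    for frag in plan.fragments:
        flanks[frag.id] = frag.flank_plan
        if frag.pcr:
            oligo, _ = design_oligos(replace(frag, pcr=False), plan)
            inputs[frag.id] = Duplex.from_sequence(oligo.upper(), name=frag.id)
        else:
            inputs[frag.id] = (
                (frag.synthesis_oligo or design_oligos(frag, plan)[0]).upper(),
                (frag.fill_in_primer or design_oligos(frag, plan)[1]).upper(),
            )
    return inputs, flanks, plan.b_groups
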