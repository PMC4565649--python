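"""Hierarchical Type-IIS gene assembly, simulated end to end.

Chemically synthesized single-stranded modules are converted to blunt
duplexes by primer fill-in, liberated with the enzymes named in their
flank plan (blunt cutter first, with dephosphorylation of the blunt ends,
then the Type-IIS cutter), ligated into intermediate (B-level) fragments,
re-digested, and ligated into the full-length gene.  The verification
report checks that every ligation is directed to a single product and that
the final product carries one intact open reading frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

from .duplex import Duplex, digest, fill_in, ligate
from .enzymes import ENZYMES, EnzymeSpec

__all__ = [
    "liberate",
    "assemble_hierarchy",
    "AssemblyReport",
    "find_orf",
]


def liberate(
    duplex: Duplex,
    enzymes: list[EnzymeSpec],
    dephosphorylate_blunt: bool = True,
) -> Duplex:
    """Digest with the given enzymes and return the gene-body fragment.

    Blunt cutters are applied first and the resulting blunt ends
    dephosphorylated (the bench protocol's CIAP step) before the sticky
    cutters act, so that blunt ends cannot religate later.  The body is the
    product spanning the midpoint of the input molecule; the released
    flank pieces are discarded, mirroring gel purification.
    """
    mid = duplex.length / 2
    pieces = [duplex]
    blunt_first = sorted(enzymes, key=lambda e: 0 if e.end_type == "blunt" else 1)
    for enzyme in blunt_first:
        pieces = [prod for piece in pieces for prod in digest(piece, enzyme)]
        if enzyme.end_type == "blunt" and dephosphorylate_blunt:
            pieces = [
                p.dephosphorylated(left=p.blunt_left, right=p.blunt_right)
                for p in pieces
            ]
    # digestion preserves left-to-right order; adjacent products overlap by
    # the junction overhang in alignment coordinates
    start = 0.0
    for piece in pieces:
        end = start + piece.length
        if start <= mid <= end:
            return piece
        start = end - piece.right_overhang
    raise AssertionError("no product spans the molecule midpoint")


@dataclass
class AssemblyReport:
    """Verification summary of a hierarchical assembly."""

    gene: str  # top strand of the final product
    n_products: int
    length: int  # alignment extent of the final product
    orf_start: int  # 0-based on the top strand; -1 if no ORF found
    orf_codons: int
    protein: str
    junctions: list[tuple[str, str, str]] = field(default_factory=list)
    b_products: dict[str, Duplex] = field(default_factory=dict)
    ok: bool = True
    messages: list[str] = field(default_factory=list)


def find_orf(top: str) -> tuple[int, str]:
    """Longest ATG..stop reading frame on the given strand.

    Returns (0-based start, in-frame sequence including the stop codon);
    (-1, "") if none is found.
    """
    top = top.upper()
    best = (-1, "")
    for start in range(len(top) - 2):
        if top[start : start + 3] != "ATG":
            continue
        for end in range(start + 3, len(top) - 2, 3):
            codon = top[end : end + 3]
            if codon in ("TAA", "TAG", "TGA"):
                orf = top[start : end + 3]
                if len(orf) > len(best[1]):
                    best = (start, orf)
                break
    return best


def assemble_hierarchy(
    fragments: dict[str, Duplex | tuple[str, str]],
    flank_plans: dict[str, tuple[list[str], list[str]]],
    b_groups: dict[str, list[str]],
    gene_level_enzyme: str = "BsaI",
) -> AssemblyReport:
    """Simulate the full C -> B -> gene assembly.

    ``fragments`` maps C-fragment ids to either a finished duplex (PCR
    product) or a ``(template, fill_in_primer)`` pair; ``flank_plans`` maps
    ids to (left enzymes, right enzymes); ``b_groups`` maps B-fragment ids
    to ordered lists of their C members.  A missing fragment leaves its
    junctions open, which the report names; ligation ambiguity propagates
    as an error.
    """
    report = AssemblyReport(
        gene="", n_products=0, length=0, orf_start=-1, orf_codons=0, protein=""
    )
    needed = [c for members in b_groups.values() for c in members]
    missing = [c for c in needed if c not in fragments]
    if missing:
        report.ok = False
        report.messages.append(f"missing fragment(s): {', '.join(missing)}")

    # C level: fill-in (synthetic modules) and liberation
    bodies: dict[str, Duplex] = {}
    for cid in needed:
        if cid in missing:
            continue
        entry = fragments[cid]
        if isinstance(entry, Duplex):
            dup = entry
        else:
            template, primer = entry
            dup = fill_in(template, primer, name=cid)
        left, right = flank_plans[cid]
        # at the first assembly stage a SmiI-flanked end is only linearized
        # blunt (and dephosphorylated); its Type-IIS site is reserved for
        # the gene-level digestion
        stage = [
            "SmiI" if "SmiI" in side else side[0] for side in (left, right)
        ]
        enz = [ENZYMES[n] for n in dict.fromkeys(stage)]
        bodies[cid] = replace(liberate(dup, enz), name=cid)

    # B level: directed ligation within each group
    b_bodies: dict[str, Duplex] = {}
    for bid, members in b_groups.items():
        present = [bodies[c] for c in members if c in bodies]
        if len(present) < 2:
            result_products = present
        else:
            result = ligate(present, require_unique=True)
            if result.circular:
                report.ok = False
                report.messages.append(f"{bid}: circular ligation product")
                continue
            result_products = result.products
        if len(result_products) != 1:
            report.ok = False
            pieces = ", ".join(p.name or "?" for p in result_products)
            report.messages.append(
                f"{bid}: ligation yielded {len(result_products)} pieces "
                f"({pieces}); open junction at the missing/unmatched overhang"
            )
            continue
        report.b_products[bid] = result_products[0]
        b_bodies[bid] = replace(
            liberate(result_products[0], [ENZYMES[gene_level_enzyme]]), name=bid
        )
    if not report.ok:
        return report

    # gene level
    result = ligate(list(b_bodies.values()), require_unique=True)
    report.n_products = len(result.products) + len(result.circular)
    if len(result.products) != 1 or result.circular:
        report.ok = False
        report.messages.append("gene-level ligation is not a single product")
        return report
    gene_dup = result.products[0]
    report.gene = gene_dup.top
    report.length = gene_dup.length
    start, orf = find_orf(gene_dup.top)
    report.orf_start = start
    report.orf_codons = len(orf) // 3
    if orf:
        report.protein = str(Seq(orf).translate())
    for left_id, right_id in zip(needed, needed[1:]):
        if _b_of(left_id, b_groups) == _b_of(right_id, b_groups):
            ov = bodies[right_id].left_protrusion
        else:
            ov = b_bodies[_b_of(right_id, b_groups)].left_protrusion
        report.junctions.append((left_id, right_id, ov))
    return report


def _b_of(cid: str, b_groups: dict[str, list[str]]) -> str:
    for bid, members in b_groups.items():
        if cid in members:
            return bid
    raise KeyError(cid)
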