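"""Packaged demonstration dataset: the tHisF library design.

The thermostable (beta/alpha)8 protein HisF of *Thermotoga maritima*
("tHisF", with a C9A exchange and a C-terminal His6 tag) is the worked
example shipped with this package: 26 substrate-cleft codons randomized
with trimer mixtures, the gene split into 14 modules (C1..C14) assembled
hierarchically via Esp3I/BsaI sticky ends into four intermediate fragments
(B1..B4) and then the full 260-codon gene.

Everything here is plain data: the 19-trimer standard mixture, the
randomized positions, the synthesis oligos T1..T13 with their fill-in
primers, the two PCR-derived modules C2/C14, the junction-overhang table
and the observed synthesis-error rates.  The wild-type coding sequence is
not stored; it is reconstructed by running the in-silico assembly of the
packaged modules (see :func:`coding_sequence`).

Note: oligo T8 is stored verbatim with the lower-case stretch "ttgtg" at
the start of its body, an anomaly of the published listing; all sequence
operations are case-insensitive.
"""

from __future__ import annotations

from functools import lru_cache

from .assembly import AssemblyReport, assemble_hierarchy
from .duplex import Duplex
from .mixtures import (
    MixtureEntry,
    RandomizationScheme,
    SchemePosition,
    StandardMixture,
)

__all__ = [
    "STANDARD_MIXTURE_TABLE",
    "STANDARD_MIXTURE_CODONS",
    "standard_mixture",
    "RANDOMIZED_RESIDUES",
    "L24_EXCLUDED_POSITIONS",
    "OLIGOS",
    "FILL_IN_PRIMERS",
    "PCR_PRODUCTS",
    "PCR_PRIMERS",
    "JUNCTION_TABLE",
    "FLANK_PLANS",
    "B_GROUPS",
    "ERROR_RATES_RANDOMIZED",
    "ERROR_RATES_OUTSIDE",
    "FRAMESHIFT_MODEL_DEFAULTS",
    "fragment_inputs",
    "assemble",
    "coding_sequence",
    "thisf_scheme",
]

#: amino acid -> (codon, protein-level fraction, supplier coupling correction)
STANDARD_MIXTURE_TABLE: dict[str, tuple[str, float, float]] = {
    "A": ("GCT", 0.053, 1.5),
    "D": ("GAC", 0.137, 1.3),
    "E": ("GAA", 0.093, 1.9),
    "F": ("TTC", 0.018, 1.3),
    "G": ("GGT", 0.071, 1.1),
    "H": ("CAT", 0.067, 1.9),
    "I": ("ATC", 0.022, 1.2),
    "K": ("AAA", 0.101, 1.1),
    "L": ("CTG", 0.037, 1.2),
    "M": ("ATG", 0.017, 1.3),
    "N": ("AAC", 0.053, 1.0),
    "P": ("CCG", 0.038, 1.8),
    "Q": ("CAG", 0.046, 2.0),
    "R": ("CGT", 0.081, 1.1),
    "S": ("TCT", 0.052, 1.3),
    "T": ("ACT", 0.048, 1.3),
    "V": ("GTT", 0.028, 1.9),
    "W": ("TGG", 0.007, 2.4),
    "Y": ("TAC", 0.031, 1.6),
}

STANDARD_MIXTURE_CODONS: dict[str, str] = {
    aa: codon for aa, (codon, _, _) in STANDARD_MIXTURE_TABLE.items()
}


def standard_mixture() -> StandardMixture:
    """The packaged 19-trimer standard mixture (cysteine excluded)."""
    return StandardMixture(
        entries=tuple(
            MixtureEntry(aa, codon, f, c)
            for aa, (codon, f, c) in STANDARD_MIXTURE_TABLE.items()
        ),
        excluded_residues=frozenset({"C"}),
    )


#: 1-based protein position -> wild-type residue, for the 26 randomized
#: substrate-cleft positions.
RANDOMIZED_RESIDUES: dict[int, str] = {
    8: "A", 11: "D", 50: "L", 52: "I", 54: "A", 55: "S",
    80: "G", 84: "H", 101: "S", 103: "N", 104: "T", 105: "A",
    128: "A", 130: "D", 144: "S", 171: "T", 173: "I", 176: "D",
    177: "G", 179: "K", 201: "S", 204: "A", 222: "L", 223: "A",
    224: "A", 225: "S",
}

#: the two positions carried by module C5; the L24 library uses the
#: wild-type version of C5 and randomizes only the remaining 24.
L24_EXCLUDED_POSITIONS: frozenset[int] = frozenset({80, 84})

#: chemically synthesized single-stranded modules (top strands, 5'->3').
OLIGOS: dict[str, str] = {
    "T1": "ATTTAAATGGTCTCCAATGGTCGCTAAACGTATAATCGCTGCTCTCGACGTGAAGGATGGTCGTGTGGAGACG",
    "T3": "CGTCTCCCGTATTTCTGGATATCACTGCTTCTGTTGAGAAGCGTAAGACTATGGAGACCATTTAAAT",
    "T4": "ATTTAAATGGTCTCCCTATGCTGGAACTGGTTGAGAAGGTGGCCGAGCAGGGAGACG",
    "T5": "GGTCTCCGCAGATTGATATTCCGTTCACTGTTGGTGGTGGTATCCATGACTTTGAGACGGCCTCTGAACTGATTCGGAGACC",
    "T6": "CGTCTCCATTCTGCGTGGTGCTGACAAGGTGTCTATTAACACTGCTGCTGTGGAAAATCCTTCTCTGGGAGACCATTTAAAT",
    "T7": "ATTTAAATGGTCTCCTCTGATTACACAGATCGCTCAAACCTTCGGGAGTCAGGCTGTTGTTGTGGAGACG",
    "T8": "CGTCTCCttgtgGCTATAGACGCTAAGCGTGTGGATGGAGAGTTTATGGTATTCACCTACTCTGGTAAGAAGAACGGAGACG",
    "T9": "CGTCTCCGAACACGGGTATCCTGCTTCGTGACTGGGTGGTTGAAGTAGAGAAGCGTGGAGCAGGAGAGATTCTTCGGAGACG",
    "T10": "CGTCTCCCTTCTTACTAGTATCGACCGTGACGGTACAAAATCGGGTTATGATAGGAGACCTATTTAAAT",
    "T11": "ATTTAAATGGTCTCCGATACTGAGATGATTCGTTTCGTGCGTCCACTGACCACACTTCCGATCATTGCTGGAGACG",
    "T12": "CGTCTCCTGCTTCTGGTGGTGCTGGTAAGATGGAACATTTCCTTGAGGCATTTCTGGGGAGACG",
    "T13": "CGTCTCCCTGGCAGGTGCTGATGCTGCGCTGGCTGCTTCTGTGTTCCACTTTCGTGGAGACG",
}

#: Klenow fill-in primers converting T1..T13 to blunt dsDNA.
FILL_IN_PRIMERS: dict[str, str] = {
    "T1": "CGTCTCCACACGACCATCCT",
    "T3": "ATTTAAATGGTCTCCATAGTCTTAC",
    "T4": "CGTCTCCCTGCTCGGCCAC",
    "T5": "GGTCTCCGAATCAGTTCAGAG",
    "T6": "ATTTAAATGGTCTCCCAGAGAAGGAT",
    "T7": "CGTCTCCACAACAACAGCCT",
    "T8": "CGTCTCCGTTCTTCTTACC",
    "T9": "CGTCTCCGAAGAATCTCTCCT",
    "T10": "ATTTAAATAGGTCTCCTATCATAACCC",
    "T11": "CGTCTCCAGCAATGATCGGAAGTG",
    "T12": "CGTCTCCCCAGAAATGCCTC",
    "T13": "CGTCTCCACGAAAGTGGAACAC",
}

#: PCR-derived wild-type modules (double-stranded; top strands).  C14
#: carries the C-terminal His6 tag and the stop codon.
PCR_PRODUCTS: dict[str, str] = {
    "C2": (
        "CGTCTCCGTGTGGTGAAGGGCACTAACTTTGAGAACCTGCGTGACAGCGGCGATCCTGTG"
        "GAACTGGGTAAATTCTACTCTGAGATTGGTATAGATGAACTCGTAGGAGACG"
    ),
    "C14": (
        "CGTCTCCTCGTGAGATTGATGTTCGTGAACTGAAAGAGTATCTGAAGAAGCACGGAGTGA"
        "ATGTACGTCTGGAGGGTTTGCACCACCACCACCACCACTAGATAGCAGAGACCATTTAAAT"
    ),
}

PCR_PRIMERS: dict[str, tuple[str, str]] = {
    "C2": ("CGTCTCCGTGTGGTGAAGGGCACTAAC", "CGTCTCCTACGAGTTCATCTATACCAAT"),
    "C14": ("CGTCTCCTCGTGAGATTGATGTTCG", "ATTTAAATGGTCTCTGCTATCTAGTGG"),
}

#: junction-overhang table: fragment -> (upstream position, upstream
#: protrusion on the top strand 5'->3', downstream position, downstream
#: protrusion on the bottom strand 5'->3').  Positions are 1-based gene
#: coordinates; "-1" is the single vector base preceding the start codon
#: and the downstream entry of C14 refers to the vector side of the stop.
JUNCTION_TABLE: dict[str, tuple[str, str, str, str]] = {
    "C1": ("-1 to 3", "AATG", "50 to 47", "ACAC"),
    "C2": ("47 to 50", "GTGT", "144 to 141", "TACG"),
    "C3": ("141 to 144", "CGTA", "185 to 182", "ATAG"),
    "C4": ("182 to 185", "CTAT", "216 to 213", "CTGC"),
    "C5": ("213 to 216", "GCAG", "280 to 277", "GAAT"),
    "C6": ("277 to 280", "ATTC", "336 to 333", "CAGA"),
    "C7": ("333 to 336", "TCTG", "380 to 377", "ACAA"),
    "C8": ("377 to 380", "TTGT", "444 to 441", "GTTC"),
    "C9": ("441 to 444", "GAAC", "508 to 505", "GAAG"),
    "C10": ("505 to 508", "CTTC", "550 to 547", "TATC"),
    "C11": ("547 to 550", "GATA", "600 to 597", "AGCA"),
    "C12": ("597 to 600", "TGCT", "646 to 643", "CCAG"),
    "C13": ("643 to 646", "CTGG", "690 to 687", "ACGA"),
    "C14": ("687 to 690", "TCGT", "+1 to 778", "GCTA"),
}

#: per-module flank enzymes (left, right): SmiI+BsaI at B-fragment edges
#: (the blunt SmiI cut is used at the C->B step, the BsaI site at the
#: B->gene step), Esp3I at interior junctions; C5 uses BsaI because its
#: body contains an Esp3I site.
FLANK_PLANS: dict[str, tuple[list[str], list[str]]] = {
    "C1": (["SmiI", "BsaI"], ["Esp3I"]),
    "C2": (["Esp3I"], ["Esp3I"]),
    "C3": (["Esp3I"], ["BsaI", "SmiI"]),
    "C4": (["SmiI", "BsaI"], ["Esp3I"]),
    "C5": (["BsaI"], ["BsaI"]),
    "C6": (["Esp3I"], ["BsaI", "SmiI"]),
    "C7": (["SmiI", "BsaI"], ["Esp3I"]),
    "C8": (["Esp3I"], ["Esp3I"]),
    "C9": (["Esp3I"], ["Esp3I"]),
    "C10": (["Esp3I"], ["BsaI", "SmiI"]),
    "C11": (["SmiI", "BsaI"], ["Esp3I"]),
    "C12": (["Esp3I"], ["Esp3I"]),
    "C13": (["Esp3I"], ["Esp3I"]),
    "C14": (["Esp3I"], ["BsaI", "SmiI"]),
}

#: hierarchical grouping: each B fragment is the ligation product of the
#: listed C modules.
B_GROUPS: dict[str, list[str]] = {
    "B1": ["C1", "C2", "C3"],
    "B2": ["C4", "C5", "C6"],
    "B3": ["C7", "C8", "C9", "C10"],
    "B4": ["C11", "C12", "C13", "C14"],
}

#: observed synthesis-error rates at randomized sites (per triplet).
ERROR_RATES_RANDOMIZED: dict[str, float] = {
    "substitution": 4.9e-3,
    "d1": 5e-3,
    "d2": 4e-4,
    "d3": 1.8e-2,
}

#: observed synthesis-error rates outside randomized sites (per nucleotide).
ERROR_RATES_OUTSIDE: dict[str, float] = {
    "substitution": 4.3e-4,
    "d1": 8.4e-4,
    "d2": 4.5e-5,
    "d3": 1.8e-5,
}

#: frameshift model for the 260-codon gene: (non-randomized codons,
#: per-codon frameshift rate, randomized codons, per-codon rate).  The
#: rates are the cumulative single- and double-deletion frequencies per
#: codon outside and at randomized sites.
FRAMESHIFT_MODEL_DEFAULTS: tuple[int, float, int, float] = (236, 0.0026, 24, 0.0054)


def fragment_inputs() -> dict[str, Duplex | tuple[str, str]]:
    """Assembly inputs: (template, primer) pairs for the synthetic modules
    and finished duplexes for the PCR-derived ones, keyed by C-fragment id."""
    inputs: dict[str, Duplex | tuple[str, str]] = {}
    oligo_of = {f"C{name[1:]}": name for name in OLIGOS}
    for cid in FLANK_PLANS:
        if cid in PCR_PRODUCTS:
            inputs[cid] = Duplex.from_sequence(PCR_PRODUCTS[cid].upper(), name=cid)
        else:
            t = oligo_of[cid]
            inputs[cid] = (OLIGOS[t].upper(), FILL_IN_PRIMERS[t].upper())
    return inputs


@lru_cache(maxsize=1)
def assemble() -> AssemblyReport:
    """Run the packaged hierarchical assembly and return its report."""
    report = assemble_hierarchy(fragment_inputs(), FLANK_PLANS, B_GROUPS)
    if not report.ok:
        raise RuntimeError(
            "packaged assembly failed: " + "; ".join(report.messages)
        )
    return report


@lru_cache(maxsize=1)
def coding_sequence() -> str:
    """The 780-nt wild-type coding sequence (ATG .. His6 .. stop),
    reconstructed by in-silico assembly of the packaged modules."""
    report = assemble()
    return report.gene[report.orf_start : report.orf_start + 3 * report.orf_codons]


def thisf_scheme(n_positions: int = 26) -> RandomizationScheme:
    """The packaged randomization scheme (26 positions; 24 drops the two
    codons of module C5), with resident codons read off the gene."""
    if n_positions == 26:
        keep = set(RANDOMIZED_RESIDUES)
    elif n_positions == 24:
        keep = set(RANDOMIZED_RESIDUES) - L24_EXCLUDED_POSITIONS
    else:
        raise ValueError("the packaged scheme has 26 or 24 positions")
    cds = coding_sequence()
    positions = []
    for pp in sorted(keep):
        codon = cds[3 * (pp - 1) : 3 * pp]
        positions.append(
            SchemePosition(
                protein_position=pp,
                resident_codon=codon,
                resident_aa=RANDOMIZED_RESIDUES[pp],
            )
        )
    return RandomizationScheme(
        positions=tuple(positions), mixture=standard_mixture()
    )
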