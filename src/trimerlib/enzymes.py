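"""Restriction enzyme cut models.

Type-IIS enzymes are described by recognition sequence, the spacer between
the recognition end and the top-strand cut, and the length of the 5'
protrusion they leave.  Blunt cutters carry the cut offset inside the
recognition site instead.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["EnzymeSpec", "BSAI", "ESP3I", "SMII", "ENZYMES"]


@dataclass(frozen=True)
class EnzymeSpec:
    """Cut geometry of a restriction endonuclease.

    For ``five_prime_protrusion`` enzymes the top strand is cut
    ``spacer_top`` nt downstream of the recognition sequence and the bottom
    strand ``spacer_top + overhang_len`` nt downstream, leaving a 5'
    protrusion of ``overhang_len`` nt.  For ``blunt`` enzymes both strands
    are cut ``cut_offset`` nt into the recognition sequence.
    """

    name: str
    recognition_seq: str
    spacer_top: int = 0
    overhang_len: int = 0
    end_type: str = "five_prime_protrusion"  # or "blunt"
    cut_offset: int = 0  # blunt only: cut position within the site

    def __post_init__(self) -> None:
        if self.end_type not in ("five_prime_protrusion", "blunt"):
            raise ValueError(f"unknown end type {self.end_type!r}")
        if self.end_type == "five_prime_protrusion":
            rc = _revcomp(self.recognition_seq)
            if rc == self.recognition_seq:
                raise ValueError(
                    "Type-IIS recognition sequence must be non-palindromic"
                )

    @property
    def site_len(self) -> int:
        return len(self.recognition_seq)


_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


#: BsaI: GGTCTC(1/5), 4-nt 5' protrusion.
BSAI = EnzymeSpec("BsaI", "GGTCTC", spacer_top=1, overhang_len=4)
#: Esp3I (BsmBI isoschizomer): CGTCTC(1/5), 4-nt 5' protrusion.
ESP3I = EnzymeSpec("Esp3I", "CGTCTC", spacer_top=1, overhang_len=4)
#: SmiI (SwaI isoschizomer): ATTT^AAAT, blunt.
SMII = EnzymeSpec("SmiI", "ATTTAAAT", end_type="blunt", cut_offset=4)

ENZYMES: dict[str, EnzymeSpec] = {e.name: e for e in (BSAI, ESP3I, SMII)}
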