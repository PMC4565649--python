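"""Readers and writers shared by all modules.

FASTA handling goes through Biopython; reports are tab-separated tables
with a version-stamped header comment; schemes, mixtures and error models
round-trip through YAML.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .analyzer import ReportBundle
from .mixtures import (
    MixtureEntry,
    RandomizationScheme,
    SchemePosition,
    StandardMixture,
)
from .simulate import ErrorModel

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_tables",
    "write_xlsx",
    "scheme_to_yaml",
    "scheme_from_yaml",
    "error_model_from_yaml",
    "synthesis_order_table",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """All records of a FASTA file as (id, sequence) pairs.

    Wrapped records and CRLF line endings are accepted; duplicate ids and
    empty files are rejected.
    """
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seen = set()
    for rid, _ in records:
        if rid in seen:
            raise ValueError(f"duplicate FASTA record id: {rid}")
        seen.add(rid)
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records],
        str(path),
        "fasta",
    )


def _version() -> str:
    from . import __version__

    return __version__


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# trimerlib {_version()}\n")
        df.to_csv(fh, sep="\t", index=index)


def write_tables(bundle: ReportBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the five report sheets as TSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df, index in (
        ("sheet1_nucleotide", bundle.sheet1_nt, False),
        ("sheet2_codon", bundle.sheet2_codon, False),
        ("sheet3_amino_acid", bundle.sheet3_aa, False),
        ("sheet4_substitutions", bundle.sheet4_substitution_matrix, True),
        ("sheet5_titv", bundle.sheet5_titv, False),
    ):
        path = out / f"{name}.tsv"
        _write_tsv(df, path, index=index)
        paths[name] = path
    dpath = out / "sheet4_deletion_totals.tsv"
    _write_tsv(bundle.sheet4_deletion_totals.rename("count").to_frame(), dpath, index=True)
    paths["sheet4_deletion_totals"] = dpath
    return paths


def write_xlsx(bundle: ReportBundle, path: str | Path) -> None:
    """Optional single-workbook export mirroring the five-sheet layout
    (requires openpyxl)."""
    with pd.ExcelWriter(str(path)) as xl:
        bundle.sheet1_nt.to_excel(xl, sheet_name="nucleotide", index=False)
        bundle.sheet2_codon.to_excel(xl, sheet_name="codon", index=False)
        bundle.sheet3_aa.to_excel(xl, sheet_name="amino_acid", index=False)
        bundle.sheet4_substitution_matrix.to_excel(xl, sheet_name="substitutions")
        bundle.sheet5_titv.to_excel(xl, sheet_name="titv", index=False)


def scheme_to_yaml(scheme: RandomizationScheme, path: str | Path) -> None:
    doc = {
        "resident_fraction": scheme.resident_fraction,
        "mixture_fraction": scheme.mixture_fraction,
        "positions": [
            {
                "position": p.protein_position,
                "codon": p.resident_codon,
                "residue": p.resident_aa,
            }
            for p in scheme.positions
        ],
        "mixture": {
            e.amino_acid: {
                "codon": e.codon,
                "fraction": e.protein_fraction,
                "correction": e.coupling_correction,
            }
            for e in scheme.mixture.entries
        },
        "excluded": sorted(scheme.mixture.excluded_residues),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def scheme_from_yaml(path: str | Path) -> RandomizationScheme:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    known = {"resident_fraction", "mixture_fraction", "positions", "mixture", "excluded"}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown keys in scheme config: {sorted(unknown)}")
    mixture = StandardMixture(
        entries=tuple(
            MixtureEntry(aa, v["codon"], v["fraction"], v.get("correction", 1.0))
            for aa, v in doc["mixture"].items()
        ),
        excluded_residues=frozenset(doc.get("excluded", [])),
    )
    return RandomizationScheme(
        positions=tuple(
            SchemePosition(p["position"], p["codon"], p["residue"])
            for p in doc["positions"]
        ),
        mixture=mixture,
        resident_fraction=doc.get("resident_fraction", 0.7),
        mixture_fraction=doc.get("mixture_fraction", 0.3),
    )


def error_model_from_yaml(path: str | Path) -> ErrorModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    fields = set(ErrorModel.__dataclass_fields__)
    unknown = set(doc) - fields
    if unknown:
        raise ValueError(f"unknown keys in error model config: {sorted(unknown)}")
    return ErrorModel(**doc)


def synthesis_order_table(scheme: RandomizationScheme) -> pd.DataFrame:
    """Supplier-facing table: per position and codon, the physical molar
    amount after coupling correction (resident spike plus standard mix)."""
    from .mixtures import position_mixture

    rows = []
    corrections = {
        e.codon: e.coupling_correction for e in scheme.mixture.entries
    }
    for p in scheme.positions:
        pm = position_mixture(scheme, p.protein_position)
        for codon in sorted(pm):
            rows.append(
                {
                    "position": p.protein_position,
                    "resident_codon": p.resident_codon,
                    "codon": codon,
                    "molar_amount": pm[codon] * corrections.get(codon, 1.0),
                }
            )
    return pd.DataFrame(rows)
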