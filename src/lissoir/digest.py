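"""In-silico tryptic digestion and peptide mass library construction.

Trypsin cleaves C-terminal to K or R except when the next residue is
proline. The library enumerates, for each retained peptide, every
modification variant (hydroxylations up to the proline count, deamidations
up to the N+Q count, both within configured bounds) and records its
neutral mass and singly protonated m/z, sorted ascending by m/z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .masses import PeptideSpecies, monoisotopic_mass, mz_protonated, _validate_sequence

__all__ = [
    "ProteinRecord",
    "MassLibrary",
    "read_fasta",
    "tryptic_digest",
    "build_library",
]

LIBRARY_COLUMNS = ["protein_id", "sequence", "n_hyd", "n_deam", "neutral_mass", "mz"]


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its identifier and source taxon."""

    identifier: str
    sequence: str
    description: str = ""
    taxon: str = ""

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence)


@dataclass
class MassLibrary:
    """Peptide mass reference library as a DataFrame plus provenance.

    Columns: protein_id, sequence, n_hyd, n_deam, neutral_mass, mz.
    Rows are sorted ascending by m/z and unique per
    (protein_id, sequence, n_hyd, n_deam).
    """

    entries: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(LIBRARY_COLUMNS) - set(self.entries.columns)
        if missing:
            raise ValueError(f"library missing columns: {sorted(missing)}")
        if not self.entries["mz"].is_monotonic_increasing:
            raise ValueError("library must be sorted ascending by m/z")

    def __len__(self) -> int:
        return len(self.entries)

    def write_tsv(self, path: str | Path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MassLibrary":
        df = pd.read_csv(path, sep="\t")
        return cls(entries=df.sort_values("mz", kind="stable").reset_index(drop=True))


def read_fasta(path: str | Path, taxa: dict[str, str] | None = None) -> list[ProteinRecord]:
    """Read protein records from a (possibly line-wrapped) FASTA file.

    ``taxa`` optionally maps identifiers to taxon labels carried through
    to the library for the contamination screen.
    """
    taxa = taxa or {}
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(
                identifier=rec.id,
                sequence=str(rec.seq).upper(),
                description=rec.description,
                taxon=taxa.get(rec.id, ""),
            )
        )
    return records


def tryptic_digest(protein: ProteinRecord | str, missed_cleavages: int = 0) -> list[str]:
    """Tryptic peptides of a protein, in N-to-C order.

    Cleaves after K or R unless followed by P; returns all products with
    0..missed_cleavages internal uncleaved sites. Fully cleaved fragments
    come first, then 1-missed products, etc., each group in sequence
    order.
    """
    sequence = protein.sequence if isinstance(protein, ProteinRecord) else protein
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")

    # Fully cleaved fragments.
    fragments: list[str] = []
    start = 0
    for i, ch in enumerate(sequence):
        if ch in "KR" and (i + 1 == len(sequence) or sequence[i + 1] != "P"):
            fragments.append(sequence[start : i + 1])
            start = i + 1
    if start < len(sequence):
        fragments.append(sequence[start:])

    peptides: list[str] = []
    for m in range(missed_cleavages + 1):
        for i in range(len(fragments) - m):
            peptides.append("".join(fragments[i : i + m + 1]))
    return peptides


def build_library(
    proteins: Sequence[ProteinRecord],
    max_hydroxylations: int = 99,
    max_deamidations: int = 2,
    min_length: int = 6,
    max_length: int = 40,
    missed_cleavages: int = 1,
) -> MassLibrary:
    """Digest proteins and enumerate modification variants into a library.

    Hydroxylation variants run from 0 to min(max_hydroxylations, #P in
    the peptide); deamidation variants from 0 to min(max_deamidations,
    #N + #Q). Defaults reflect common ZooMS practice: peptides of 6-40
    residues, up to one missed cleavage, at most two deamidations.
    """
    if min_length > max_length:
        raise ValueError("min_length must not exceed max_length")
    rows = []
    for protein in proteins:
        seen: set[tuple[str, int, int]] = set()
        for pep in tryptic_digest(protein, missed_cleavages):
            if not (min_length <= len(pep) <= max_length):
                continue
            n_p = pep.count("P")
            n_nq = pep.count("N") + pep.count("Q")
            for h in range(min(max_hydroxylations, n_p) + 1):
                for d in range(min(max_deamidations, n_nq) + 1):
                    key = (pep, h, d)
                    if key in seen:
                        continue
                    seen.add(key)
                    species = PeptideSpecies(pep, n_hydroxylations=h, n_deamidations=d)
                    rows.append(
                        {
                            "protein_id": protein.identifier,
                            "sequence": pep,
                            "n_hyd": h,
                            "n_deam": d,
                            "neutral_mass": monoisotopic_mass(species),
                            "mz": mz_protonated(species),
                        }
                    )
    df = pd.DataFrame(rows, columns=LIBRARY_COLUMNS)
    df = df.sort_values("mz", kind="stable").reset_index(drop=True)
    provenance = {
        "max_hydroxylations": max_hydroxylations,
        "max_deamidations": max_deamidations,
        "min_length": min_length,
        "max_length": max_length,
        "missed_cleavages": missed_cleavages,
        "n_proteins": len(proteins),
    }
    return MassLibrary(entries=df, provenance=provenance)
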