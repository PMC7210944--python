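#!/usr/bin/env python
"""Build the in-silico peptide mass reference library.

Digests the packaged protein set (bovine/human collagens, porcine
trypsin, keratins, bovine serum albumin and hemoglobins — synthetic
stand-in fragments) with tryptic rules, one missed cleavage, peptides of
6-40 residues, full hydroxylation enumeration and up to two
deamidations, and writes the sorted library to results/library.tsv.
"""

from pathlib import Path

from lissoir.digest import build_library
from lissoir.simulate import fixtures

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    proteins = fixtures()["proteins"]
    library = build_library(proteins)
    OUT.mkdir(exist_ok=True)
    library.write_tsv(OUT / "library.tsv")
    print(f"{len(proteins)} proteins -> {len(library)} library entries")
    print(f"m/z range {library.entries['mz'].min():.3f} - {library.entries['mz'].max():.3f}")
    in_range = library.entries["mz"].between(1000, 3500).sum()
    print(f"{in_range} entries inside the instrument's 1000-3500 m/z window")
    print(f"written to {OUT / 'library.tsv'}")


if __name__ == "__main__":
    main()
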