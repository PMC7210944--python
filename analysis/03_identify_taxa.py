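#!/usr/bin/env python
"""Identify the taxon of each simulated extract and screen contaminants.

For every spectrum under results/spectra/: pick monoisotopic peaks at
S/N > 3, match collagen markers at 50 ppm (excluding musk ox, absent
from the region and period), match the peptide library with the
two-peptide rule, and classify accepted proteins as endogenous, process
contaminants or usage-derived. Writes results/identifications.json.
"""

import json
from pathlib import Path

from lissoir.digest import MassLibrary
from lissoir.identify import MatchConfig, assign_taxon, contamination_screen, match_library
from lissoir.simulate import fixtures
from lissoir.spectra import pick_peaks, read_spectrum, select_monoisotopic

ROOT = Path(__file__).resolve().parents[1] / "results"

CONFIG = MatchConfig(
    ppm_tolerance=50.0,
    min_peptides_per_protein=2,
    min_markers_per_taxon=2,
    excluded_taxa=("Ovibos moschatus",),
    exclusion_reason="not known from southwest France during MIS 5-3",
)


def main() -> None:
    markers = fixtures()["markers"]
    library = MassLibrary.read_tsv(ROOT / "library.tsv")
    report = {}
    for path in sorted((ROOT / "spectra").glob("*.txt")):
        peaks = select_monoisotopic(pick_peaks(read_spectrum(path)))
        assignment = assign_taxon(peaks, markers, CONFIG)
        accepted = match_library(peaks, library, CONFIG)
        screen = contamination_screen(accepted)
        report[path.stem] = {
            "n_monoisotopic_peaks": len(peaks),
            "taxon": json.loads(assignment.to_json()),
            "accepted_proteins": {k: len(v) for k, v in accepted.items()},
            "contamination_flagged": screen["flagged"],
        }
        label = assignment.clade or "unidentifiable"
        print(f"{path.stem}: {label} ({assignment.status}), "
              f"{len(assignment.matched_markers)} markers, "
              f"{len(accepted)} accepted proteins")
    (ROOT / "identifications.json").write_text(json.dumps(report, indent=2) + "\n")
    print(f"written to {ROOT / 'identifications.json'}")


if __name__ == "__main__":
    main()
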