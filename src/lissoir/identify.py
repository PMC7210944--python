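"""Marker matching and clade-level taxonomic assignment.

Picked monoisotopic peaks are matched against (a) an in-silico peptide
mass library for protein-level identification and contamination
screening, and (b) a collagen peptide-marker database for taxonomic
assignment. Matching uses a relative (ppm) tolerance, 50 ppm by default,
and protein identifications require at least two distinct matching
peptides.

Some taxa are indistinguishable on collagen markers (aurochs vs bison);
the database therefore carries merge rules that collapse such taxa into
a clade label like "Bos sp./Bison sp.". A biogeographic exclusion list
removes taxa absent from the region and period under study (e.g. musk
ox), with the exclusion recorded in the assignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .digest import MassLibrary
from .spectra import Peak

__all__ = [
    "MarkerDatabase",
    "MatchConfig",
    "TaxonAssignment",
    "ppm_error",
    "match_library",
    "assign_taxon",
    "contamination_screen",
]


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if observed <= 0 or theoretical <= 0:
        raise ValueError("m/z values must be positive")
    return 1e6 * (observed - theoretical) / theoretical


@dataclass(frozen=True)
class MarkerDatabase:
    """Taxon marker-mass series plus clade merge rules.

    ``records`` columns: taxon, marker, mz, note. ``merge_rules`` maps a
    clade label to the set of taxa it pools (taxa indistinguishable on
    the available markers).
    """

    records: pd.DataFrame
    merge_rules: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"taxon", "marker", "mz"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"marker database missing columns: {sorted(missing)}")
        if (self.records["mz"] <= 0).any():
            raise ValueError("marker m/z values must be positive")
        if self.records.duplicated(["taxon", "marker"]).any():
            raise ValueError("duplicate (taxon, marker) pairs in database")
        known = set(self.records["taxon"])
        for label, taxa in self.merge_rules.items():
            unknown = set(taxa) - known
            if unknown:
                raise ValueError(f"merge rule {label!r} references unknown taxa {sorted(unknown)}")

    @property
    def taxa(self) -> list[str]:
        return sorted(self.records["taxon"].unique())

    def series(self, taxon: str) -> pd.DataFrame:
        sub = self.records[self.records["taxon"] == taxon]
        if sub.empty:
            raise KeyError(f"unknown taxon {taxon!r}")
        return sub

    def merged_label(self, taxa: set[str]) -> str | None:
        """Clade label if ``taxa`` all fall inside one merge group."""
        if len(taxa) == 1:
            return next(iter(taxa))
        for label, group in self.merge_rules.items():
            if taxa <= group:
                return label
        return None

    @classmethod
    def read_tsv(
        cls,
        path: str | Path,
        merge_rules: Mapping[str, Sequence[str]] | None = None,
    ) -> "MarkerDatabase":
        df = pd.read_csv(path, sep="\t")
        rules = {k: frozenset(v) for k, v in (merge_rules or {}).items()}
        return cls(records=df, merge_rules=rules)


@dataclass(frozen=True)
class MatchConfig:
    """Matching parameters: tolerance, evidence minima, exclusions."""

    ppm_tolerance: float = 50.0
    min_peptides_per_protein: int = 2
    min_markers_per_taxon: int = 2
    excluded_taxa: tuple[str, ...] = ()
    exclusion_reason: str = "not present in the study region/period"

    def __post_init__(self) -> None:
        if self.ppm_tolerance <= 0:
            raise ValueError("ppm tolerance must be positive")
        if self.min_peptides_per_protein < 1 or self.min_markers_per_taxon < 1:
            raise ValueError("evidence minima must be >= 1")


@dataclass(frozen=True)
class TaxonAssignment:
    """Clade-level call with its marker evidence and exclusions.

    ``status`` is "identified" (>= min markers, single clade after
    merging), "less-specific" (enough markers but several clades remain
    compatible), or "unidentifiable".
    """

    clade: str
    status: str
    matched_markers: tuple[dict, ...] = ()
    excluded_alternatives: tuple[dict, ...] = ()

    def to_json(self) -> str:
        return json.dumps(
            {
                "clade": self.clade,
                "status": self.status,
                "matched_markers": list(self.matched_markers),
                "excluded_alternatives": list(self.excluded_alternatives),
            },
            indent=2,
        )


def match_library(
    peaks: Sequence[Peak],
    library: MassLibrary,
    config: MatchConfig = MatchConfig(),
) -> dict[str, list[dict]]:
    """Protein-level matches: accepted proteins with peptide evidence.

    Each monoisotopic peak is assigned to its nearest library entry
    within the ppm tolerance (ties broken by smaller absolute ppm, then
    lower library m/z). A protein is accepted only with at least
    ``min_peptides_per_protein`` distinct matching peptide sequences.
    """
    if len(library) == 0:
        raise ValueError("empty mass library")
    entries = library.entries
    evidence: dict[str, dict[str, dict]] = {}
    for peak in peaks:
        if not peak.is_monoisotopic:
            continue
        errors = 1e6 * (peak.mz - entries["mz"]) / entries["mz"]
        ok = errors.abs() <= config.ppm_tolerance
        if not ok.any():
            continue
        cand = entries[ok].assign(ppm=errors[ok])
        cand = cand.assign(abs_ppm=cand["ppm"].abs())
        cand = cand.sort_values(["abs_ppm", "mz"], kind="stable")
        best = cand.iloc[0]
        rec = {
            "sequence": best["sequence"],
            "observed_mz": peak.mz,
            "theoretical_mz": float(best["mz"]),
            "ppm": float(best["ppm"]),
            "n_hyd": int(best["n_hyd"]),
            "n_deam": int(best["n_deam"]),
        }
        prot = evidence.setdefault(best["protein_id"], {})
        prev = prot.get(best["sequence"])
        if prev is None or abs(rec["ppm"]) < abs(prev["ppm"]):
            prot[best["sequence"]] = rec

    accepted: dict[str, list[dict]] = {}
    for protein_id, peptides in evidence.items():
        if len(peptides) >= config.min_peptides_per_protein:
            accepted[protein_id] = sorted(peptides.values(), key=lambda r: r["theoretical_mz"])
    return accepted


def _match_markers(
    peaks: Sequence[Peak],
    series: pd.DataFrame,
    ppm_tolerance: float,
) -> list[dict]:
    """Greedy nearest assignment of peaks to one taxon's marker series.

    One peak supports at most one marker (and vice versa), preventing
    double counting; pairs are taken in order of increasing |ppm|.
    """
    pairs = []
    mono = [p for p in peaks if p.is_monoisotopic]
    for _, row in series.iterrows():
        for i, peak in enumerate(mono):
            err = ppm_error(peak.mz, float(row["mz"]))
            if abs(err) <= ppm_tolerance:
                pairs.append((abs(err), err, row["marker"], float(row["mz"]), i, peak.mz))
    pairs.sort(key=lambda t: (t[0], t[3]))
    used_markers: set[str] = set()
    used_peaks: set[int] = set()
    matches = []
    for abs_err, err, marker, theo, peak_idx, obs in pairs:
        if marker in used_markers or peak_idx in used_peaks:
            continue
        used_markers.add(marker)
        used_peaks.add(peak_idx)
        matches.append(
            {"marker": marker, "theoretical_mz": theo, "observed_mz": obs, "ppm": err}
        )
    matches.sort(key=lambda m: m["theoretical_mz"])
    return matches


def assign_taxon(
    peaks: Sequence[Peak],
    markers: MarkerDatabase,
    config: MatchConfig = MatchConfig(),
) -> TaxonAssignment:
    """Clade-level taxonomic call from matched marker counts.

    For each taxon the markers matched within tolerance are counted;
    the candidate set is the taxa achieving the maximal count, provided
    it reaches ``min_markers_per_taxon``. Excluded taxa are removed with
    a recorded reason. If the survivors collapse under a merge rule the
    merged clade label is reported as "identified"; survivors spanning
    several clades give a "less-specific" joint label; anything below
    the marker minimum is "unidentifiable".
    """
    per_taxon = {
        taxon: _match_markers(peaks, markers.series(taxon), config.ppm_tolerance)
        for taxon in markers.taxa
    }
    counts = {t: len(m) for t, m in per_taxon.items()}

    # Biogeographically excluded taxa never compete for the call; record
    # the ones that would otherwise have been credible alternatives.
    eligible = {t: c for t, c in counts.items() if t not in config.excluded_taxa}
    best = max(eligible.values(), default=0)
    excluded = [
        {
            "taxon": taxon,
            "reason": config.exclusion_reason,
            "matched_markers": counts[taxon],
        }
        for taxon in sorted(set(config.excluded_taxa) & set(counts))
        if counts[taxon] >= max(best, config.min_markers_per_taxon)
    ]
    if best < config.min_markers_per_taxon:
        return TaxonAssignment(
            clade="", status="unidentifiable", excluded_alternatives=tuple(excluded)
        )
    candidates = {t for t, c in eligible.items() if c == best}

    label = markers.merged_label(candidates)
    if label is not None:
        status = "identified"
    else:
        # candidates span several clades: report the joint label
        status = "less-specific"
        label = "/".join(sorted(candidates))
    evidence = per_taxon[sorted(candidates)[0]]
    return TaxonAssignment(
        clade=label,
        status=status,
        matched_markers=tuple(evidence),
        excluded_alternatives=tuple(excluded),
    )


# Protein roles for the contamination screen. Collagens can be endogenous
# to the bone; trypsin and human keratins enter during processing; blood
# and skin proteins would indicate hide-working residue or other usage.
_ENDOGENOUS_KEYWORDS = ("COL1", "CO1A", "COLLAGEN")
_PROCESS_KEYWORDS = ("TRYP", "K1C10_HUMAN", "K2C1_HUMAN", "KRT1_HUMAN", "KRT10_HUMAN")
_USAGE_KEYWORDS = ("ALBU", "HBA", "HBB")


def contamination_screen(accepted: Mapping[str, Sequence[dict]]) -> dict:
    """Classify accepted proteins and flag usage-derived candidates.

    Collagens are endogenous candidates; porcine trypsin and human
    keratins are known process contaminants; albumins, hemoglobins and
    non-human keratins would derive from use (hide working) or handling
    and raise a flag.
    """
    report: dict = {
        "endogenous_candidates": [],
        "process_contaminants": [],
        "usage_derived_candidates": [],
        "flagged": False,
    }
    for protein_id in sorted(accepted):
        upper = protein_id.upper()
        if any(k in upper for k in _ENDOGENOUS_KEYWORDS):
            report["endogenous_candidates"].append(protein_id)
        elif any(k in upper for k in _PROCESS_KEYWORDS):
            report["process_contaminants"].append(protein_id)
        elif any(k in upper for k in _USAGE_KEYWORDS) or "KERATIN" in upper or "K1C" in upper or "K2C" in upper:
            report["usage_derived_candidates"].append(protein_id)
        else:
            report["usage_derived_candidates"].append(protein_id)
    report["flagged"] = bool(report["usage_derived_candidates"])
    return report
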