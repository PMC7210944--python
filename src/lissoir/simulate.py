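"""Synthetic inputs: MALDI spectra, faunal assemblages, packaged fixtures.

The pipeline's real inputs (instrument spectra, excavation tallies) are
not distributable, so everything it consumes can be generated here under
a fixed seed:

* ``simulate_spectrum`` renders a taxon's collagen marker series as
  Gaussian peaks on a noisy baseline — with proper isotope ladders where
  a marker has peptide provenance, deamidated satellites at +0.984 Da,
  and the low-mass bias of non-destructive extraction (markers above a
  cutoff, 2500 m/z by default, are simply absent).
* ``simulate_assemblage`` draws rib tallies and tool observations under
  either the opportunistic (multinomial) or selective
  (Dirichlet-multinomial) model, for calibration and recovery tests.
* ``fixtures`` loads the packaged layer tables (NISP and rib counts per
  taxon category), the marker database, the body-mass table and the test
  protein sequences. The NISP tallies are transcribed from published
  excavation tables; per-category rib counts are reconstructed from the
  published rib percentages. Marker masses, body masses and protein
  sequences are synthetic stand-ins (see the data files' names).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .digest import ProteinRecord, read_fasta
from .identify import MarkerDatabase
from .masses import (
    DEAMIDATION,
    PeptideSpecies,
    isotope_envelope,
    mz_protonated,
    peptide_composition,
)
from .selectivity import FaunalAssemblage, ObservationCounts, read_assemblages, read_mass_table
from .spectra import Spectrum

__all__ = [
    "SpectrumSimConfig",
    "AssemblageSimConfig",
    "simulate_spectrum",
    "simulate_assemblage",
    "fixtures",
    "CLADE_MERGE_RULES",
]

#: Taxa indistinguishable on the packaged marker series.
CLADE_MERGE_RULES: dict[str, tuple[str, ...]] = {
    "Bos sp./Bison sp.": ("Bos sp.", "Bison sp."),
}


@dataclass(frozen=True)
class SpectrumSimConfig:
    """Parameters of one simulated MALDI-TOF fingerprint.

    ``snr`` is the apex-to-noise ratio of each marker's tallest peak;
    ``resolving_power`` sets the Gaussian peak width (FWHM = m/z / R);
    ``cutoff`` suppresses markers above that m/z (None disables the
    low-mass bias); ``deamidation_fraction`` moves that fraction of each
    provenance-bearing marker's signal to its deamidated form;
    ``intensity_decay`` (Da) optionally attenuates markers as
    exp(-(m/z - mz_start)/decay).
    """

    taxon: str
    snr: float = 10.0
    resolving_power: float = 5000.0
    cutoff: float | None = 2500.0
    deamidation_fraction: float = 0.0
    noise_scale: float = 1.0
    intensity_decay: float | None = None
    mz_start: float = 1000.0
    mz_stop: float = 3500.0
    step: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr < 0:
            raise ValueError("snr must be non-negative")
        if self.cutoff is not None and self.cutoff <= 1000:
            raise ValueError("cutoff must exceed 1000 m/z")
        if not 0.0 <= self.deamidation_fraction <= 1.0:
            raise ValueError("deamidation_fraction must lie in [0, 1]")
        if self.step <= 0 or self.mz_stop <= self.mz_start:
            raise ValueError("invalid m/z grid")


def _marker_profile(
    row: pd.Series, fraction_deamidated: float
) -> list[tuple[float, float]]:
    """(m/z, relative height) stick pattern for one marker.

    With peptide provenance the full isotope envelope is used, plus the
    deamidated form's envelope weighted by the deamidation fraction;
    otherwise a single stick at the marker mass.
    """
    peptide = row.get("peptide")
    if isinstance(peptide, str) and peptide:
        n_hyd = int(row["n_hyd"]) if pd.notna(row.get("n_hyd")) else 0
        base = PeptideSpecies(peptide, n_hydroxylations=n_hyd)
        env0 = isotope_envelope(peptide_composition(base))
        # anchor the envelope on the database mass, not the rebuilt one
        shift = float(row["mz"]) - mz_protonated(base)
        sticks = [(mz + shift, (1 - fraction_deamidated) * ab) for mz, ab in env0.peaks]
        n_nq = peptide.count("N") + peptide.count("Q")
        if fraction_deamidated > 0 and n_nq > 0:
            deam = PeptideSpecies(peptide, n_hydroxylations=n_hyd, n_deamidations=1)
            env1 = isotope_envelope(peptide_composition(deam))
            shift1 = float(row["mz"]) + DEAMIDATION - mz_protonated(deam)
            sticks += [(mz + shift1, fraction_deamidated * ab) for mz, ab in env1.peaks]
        return sticks
    return [(float(row["mz"]), 1.0)]


def simulate_spectrum(config: SpectrumSimConfig, markers: MarkerDatabase) -> Spectrum:
    """Render a taxon's marker series into a profile-mode spectrum.

    Deterministic for a given config (the seed drives all noise); marker
    peaks are Gaussians whose apex equals ``snr x noise_scale`` above
    the baseline (or ``snr`` in arbitrary units when noise_scale is 0).
    """
    series = markers.series(config.taxon)  # raises KeyError on unknown taxon
    rng = np.random.default_rng(config.seed)
    mz = np.arange(config.mz_start, config.mz_stop + config.step / 2, config.step)
    baseline = 5.0 * config.noise_scale
    intensity = np.full_like(mz, baseline)
    if config.noise_scale > 0:
        intensity = intensity + rng.normal(0.0, config.noise_scale, size=mz.shape)

    unit = config.noise_scale if config.noise_scale > 0 else 1.0
    for _, row in series.iterrows():
        marker_mz = float(row["mz"])
        if config.cutoff is not None and marker_mz > config.cutoff:
            continue
        amp = config.snr * unit
        if config.intensity_decay:
            amp *= np.exp(-(marker_mz - config.mz_start) / config.intensity_decay)
        sticks = _marker_profile(row, config.deamidation_fraction)
        tallest = max(h for _, h in sticks)
        if tallest <= 0:
            continue
        for pos, height in sticks:
            sigma = pos / config.resolving_power / 2.3548
            window = (mz >= pos - 6 * sigma) & (mz <= pos + 6 * sigma)
            intensity[window] += (
                amp * (height / tallest) * np.exp(-0.5 * ((mz[window] - pos) / sigma) ** 2)
            )
    return Spectrum(mz, np.clip(intensity, 0.0, None), metadata=f"simulated {config.taxon}")


@dataclass(frozen=True)
class AssemblageSimConfig:
    """Parameters for a simulated layer and its tool observations.

    Ribs are drawn multinomially from ``rib_frequencies``; the ``n_tools``
    tool observations are drawn under the hypothesis named in
    ``hypothesis``: "H0" uses the same frequencies, "HA" draws category
    probabilities from a Dirichlet with the given ``alphas`` first.
    """

    categories: tuple[str, ...]
    rib_frequencies: tuple[float, ...]
    total_ribs: int
    total_nisp: int
    n_tools: int = 0
    hypothesis: str = "H0"
    alphas: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.categories) != len(self.rib_frequencies):
            raise ValueError("categories and rib_frequencies must align")
        if abs(sum(self.rib_frequencies) - 1.0) > 1e-9:
            raise ValueError("rib frequencies must sum to 1")
        if self.total_nisp < self.total_ribs:
            raise ValueError("total NISP cannot be below total ribs")
        if self.hypothesis not in ("H0", "HA"):
            raise ValueError("hypothesis must be 'H0' or 'HA'")
        if self.hypothesis == "HA" and len(self.alphas) != len(self.categories):
            raise ValueError("HA draws need one alpha per category")


def simulate_assemblage(
    config: AssemblageSimConfig,
) -> tuple[FaunalAssemblage, ObservationCounts]:
    """Draw one synthetic layer and its tool counts (seeded)."""
    rng = np.random.default_rng(config.seed)
    p = np.asarray(config.rib_frequencies, dtype=float)
    ribs = rng.multinomial(config.total_ribs, p)
    extra = rng.multinomial(config.total_nisp - config.total_ribs, p)
    records = pd.DataFrame(
        {
            "category": list(config.categories),
            "nisp": ribs + extra,
            "ribs": ribs,
        }
    )
    assemblage = FaunalAssemblage(layer="simulated", records=records)

    if config.n_tools == 0:
        tool_counts = np.zeros(len(config.categories), dtype=int)
    elif config.hypothesis == "H0":
        tool_counts = rng.multinomial(config.n_tools, p)
    else:
        theta = rng.dirichlet(np.asarray(config.alphas, dtype=float))
        tool_counts = rng.multinomial(config.n_tools, theta)
    obs = ObservationCounts(
        {cat: int(k) for cat, k in zip(config.categories, tool_counts)}
    )
    return assemblage, obs


def _data_path(name: str) -> Path:
    return Path(str(resources.files("lissoir").joinpath("data", name)))


def fixtures() -> dict:
    """Load the packaged tables the analyses run on.

    Returns a dict with keys ``assemblages`` (layer label ->
    FaunalAssemblage for Pech I 4, L-3A, L-3B), ``masses`` (model
    category -> body mass in kg; synthetic stand-ins), ``markers``
    (MarkerDatabase with clade merge rules; synthetic stand-ins) and
    ``proteins`` (synthetic test protein records).
    """
    assemblages = read_assemblages(_data_path("assemblages.tsv"))
    masses = read_mass_table(_data_path("body_masses_synthetic.tsv"))
    markers = MarkerDatabase.read_tsv(
        _data_path("markers_synthetic.tsv"), merge_rules=CLADE_MERGE_RULES
    )
    taxa = {
        "CO1A1_BOVIN_SYNTH": "Bos sp.",
        "CO1A2_BOVIN_SYNTH": "Bos sp.",
        "CO1A1_HUMAN_SYNTH": "Homo sapiens",
        "TRYP_PIG_SYNTH": "Sus scrofa",
        "K2C1_HUMAN_SYNTH": "Homo sapiens",
        "K1C10_HUMAN_SYNTH": "Homo sapiens",
        "K2C1_BOVIN_SYNTH": "Bos sp.",
        "K1C10_BOVIN_SYNTH": "Bos sp.",
        "ALBU_BOVIN_SYNTH": "Bos sp.",
        "HBA_BOVIN_SYNTH": "Bos sp.",
        "HBB_BOVIN_SYNTH": "Bos sp.",
    }
    proteins = read_fasta(_data_path("proteins_synthetic.fasta"), taxa=taxa)
    return {
        "assemblages": assemblages,
        "masses": masses,
        "markers": markers,
        "proteins": proteins,
    }
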