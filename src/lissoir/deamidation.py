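"""Glutamine/asparagine deamidation extent from isotope envelopes.

Deamidation (+0.984016 Da) of ancient collagen accumulates with time and
degradation, so the fraction of a peptide still in its non-deamidated
form separates degraded (old) collagen from modern contamination. At
MALDI-TOF resolution the deamidated form's envelope is not resolved from
the parent's isotopologues (+1.00336 Da), so the extent is estimated by
fitting the observed envelope region as a non-negative mixture of the
theoretical envelopes of the 0-, 1-, ... deamidation forms.

The standard assessment peptide is P1105 (GVQGPPGPAGPR with one
hydroxyproline; one Q, hence a two-component fit). The reported value
follows the field convention: 1.0 = fully non-deamidated (fresh
collagen); archaeological bone typically falls well below.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
import dataclasses
import json

import numpy as np
from scipy.optimize import nnls

from .masses import (
    NEUTRON_SPACING,
    P1105,
    PeptideSpecies,
    isotope_envelope,
    mz_protonated,
    peptide_composition,
)
from .spectra import Spectrum, estimate_noise

__all__ = ["DeamidationResult", "InsufficientSignalError", "fit_deamidation"]


class InsufficientSignalError(ValueError):
    """Raised when the envelope region holds no signal above noise."""


@dataclass(frozen=True)
class DeamidationResult:
    """Mixture-fit outcome: value in [0, 1], 1.0 = non-deamidated."""

    value: float
    residual: float
    n_points: int
    peptide: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError("deamidation value must lie in [0, 1]")
        if self.residual < 0:
            raise ValueError("residual must be non-negative")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _component_envelopes(peptide: PeptideSpecies, max_extra: int | None = None):
    """Theoretical envelopes for 0..n_NQ additional deamidations."""
    n_nq = peptide.sequence.count("N") + peptide.sequence.count("Q")
    room = n_nq - peptide.n_deamidations
    if max_extra is not None:
        room = min(room, max_extra)
    components = []
    for extra in range(room + 1):
        species = dc_replace(peptide, n_deamidations=peptide.n_deamidations + extra)
        env = isotope_envelope(peptide_composition(species), charge=peptide.charge)
        components.append((extra, species, env))
    return components


def fit_deamidation(
    spectrum: Spectrum,
    peptide: PeptideSpecies = P1105,
    window: float = 0.05,
    charge: int = 1,
    n_positions: int = 6,
    noise_window: float = 100.0,
) -> DeamidationResult:
    """Extent of deamidation of ``peptide`` from its envelope region.

    Observed intensity is integrated within +/- ``window`` Da of the
    parent's isotopologue positions (monoisotopic m/z + k x 1.00336 /
    charge, k = 0..n_positions-1); each deamidation component's
    theoretical envelope is binned onto the same positions (the
    j-deamidated form's peaks fall 0.0194 Da below parent position k+j,
    inside the bin). Non-negative least squares gives mixture weights
    w_0, w_1, ...; the value is w_0 / sum(w).

    Raises :class:`InsufficientSignalError` when the region's apex does
    not exceed three times the local noise level.
    """
    if peptide.charge != charge:
        peptide = dc_replace(peptide, charge=charge)
    base_mz = mz_protonated(peptide)
    spacing = NEUTRON_SPACING / charge
    lo_needed, hi_needed = base_mz - 1.0, base_mz + n_positions * spacing
    if spectrum.mz[0] > lo_needed or spectrum.mz[-1] < hi_needed:
        raise ValueError(
            f"spectrum must cover [{lo_needed:.2f}, {hi_needed:.2f}] m/z "
            f"to fit deamidation of {peptide.sequence}"
        )

    positions = base_mz + spacing * np.arange(n_positions)
    region = (spectrum.mz >= positions[0] - 0.5) & (spectrum.mz <= positions[-1] + 0.5)
    noise = estimate_noise(spectrum, noise_window)
    noise_level = float(np.median(noise[region])) if region.any() else 0.0
    region_baseline = float(np.median(spectrum.intensity[region])) if region.any() else 0.0
    # signal must appear where the peptide itself would: at the parent's
    # monoisotopic position or the deamidated form's (bin 0 or 1)
    signal_zone = (np.abs(spectrum.mz[:, None] - positions[:2][None, :]) <= window).any(axis=1)
    apex = (
        float(spectrum.intensity[signal_zone].max()) - region_baseline
        if signal_zone.any()
        else 0.0
    )
    if apex <= 3.0 * noise_level:
        raise InsufficientSignalError(
            f"insufficient signal in the {peptide.sequence} envelope region"
        )

    # baseline-subtracted integrated intensity at each isotopologue
    # position; negatives are kept so noise stays zero-mean
    y = np.empty(n_positions)
    for j, p in enumerate(positions):
        mask = (spectrum.mz >= p - window) & (spectrum.mz <= p + window)
        y[j] = (spectrum.intensity[mask] - region_baseline).sum()

    components = _component_envelopes(peptide)
    A = np.zeros((n_positions, len(components)))
    for c, (extra, _species, env) in enumerate(components):
        for mz_k, ab in env.peaks:
            j = int(round((mz_k - base_mz) / spacing))
            if 0 <= j < n_positions:
                A[j, c] += ab

    weights, rnorm = nnls(A, y)
    total = weights.sum()
    if total <= 0:
        raise InsufficientSignalError(
            f"mixture fit found no envelope signal for {peptide.sequence}"
        )
    value = float(weights[0] / total)
    return DeamidationResult(
        value=value,
        residual=float(rnorm),
        n_points=n_positions,
        peptide=peptide.sequence,
    )
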