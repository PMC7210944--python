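"""Peptide mass chemistry for collagen fingerprinting.

Monoisotopic masses, protonated m/z, post-translational modification
shifts, and aggregated isotope envelopes for tryptic peptides. Everything
downstream (the in-silico library, marker matching, deamidation fitting,
the spectrum simulator) builds on this module.

Masses are computed from an embedded residue table (values to five
decimals) rather than a live dependency so that results are bit-stable.
Modifications are counted, not positioned: a MALDI-TOF fingerprint cannot
distinguish which proline carries a hydroxylation, so neither do we.

Conventions
-----------
* ``monoisotopic_mass`` returns the *neutral* mass in Da.
* ``mz_protonated`` returns (M + z·1.007276)/z for positive-mode MALDI
  (z = 1 by default).
* Integer marker labels ("P1 at 1105") follow the nominal-mass
  convention: the sum of integer nominal residue masses plus water,
  modifications and one proton. This reproduces the labels used on
  published marker series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PeptideSpecies",
    "ElementalComposition",
    "IsotopeEnvelope",
    "monoisotopic_mass",
    "mz_protonated",
    "nominal_mz",
    "peptide_composition",
    "isotope_envelope",
    "WATER_MONO",
    "PROTON",
    "HYDROXYLATION",
    "DEAMIDATION",
    "NEUTRON_SPACING",
    "P1105",
]

# Monoisotopic residue masses (Da), standard 20 amino acids, 5 decimals.
RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

# Nominal (integer) residue masses for marker labels.
RESIDUE_NOMINAL: dict[str, int] = {
    "G": 57, "A": 71, "S": 87, "P": 97, "V": 99, "T": 101, "C": 103,
    "L": 113, "I": 113, "N": 114, "D": 115, "Q": 128, "K": 128,
    "E": 129, "M": 131, "H": 137, "F": 147, "R": 156, "Y": 163, "W": 186,
}

# Residue elemental compositions (residue = amino acid minus water).
RESIDUE_COMPOSITION: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

WATER_MONO = 18.010565
PROTON = 1.007276
HYDROXYLATION = 15.994915  # +O on hydroxyproline
DEAMIDATION = 0.984016  # N->D / Q->E: +O -N -H
# Mean spacing between adjacent isotopologue peaks of a peptide.
NEUTRON_SPACING = 1.00336

# Per-element isotope abundance by integer neutron shift (terrestrial).
ELEMENT_ISOTOPES: dict[str, list[float]] = {
    "C": [0.9893, 0.0107],
    "H": [0.999885, 0.000115],
    "N": [0.99636, 0.00364],
    "O": [0.99757, 0.00038, 0.00205],
    "S": [0.9499, 0.0075, 0.0425, 0.0, 0.0001],
}


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    for ch in sequence:
        if ch not in RESIDUE_MASS:
            raise ValueError(f"unknown residue symbol {ch!r} in sequence")


@dataclass(frozen=True)
class PeptideSpecies:
    """A peptide with counted modifications and a charge state.

    ``n_hydroxylations`` counts proline hydroxylations (+15.994915 Da
    each); ``n_deamidations`` counts N/Q deamidations (+0.984016 Da
    each). Counts are validated against the sequence: you cannot
    deamidate more N+Q, or hydroxylate more P, than the peptide holds.
    """

    sequence: str
    n_hydroxylations: int = 0
    n_deamidations: int = 0
    charge: int = 1

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence)
        if self.n_hydroxylations < 0 or self.n_deamidations < 0:
            raise ValueError("modification counts must be non-negative")
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")
        n_p = self.sequence.count("P")
        n_nq = self.sequence.count("N") + self.sequence.count("Q")
        if self.n_hydroxylations > n_p:
            raise ValueError(
                f"{self.n_hydroxylations} hydroxylations exceed "
                f"{n_p} prolines in {self.sequence}"
            )
        if self.n_deamidations > n_nq:
            raise ValueError(
                f"{self.n_deamidations} deamidations exceed "
                f"{n_nq} N+Q residues in {self.sequence}"
            )

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self)

    @property
    def mz(self) -> float:
        return mz_protonated(self)


@dataclass(frozen=True)
class ElementalComposition:
    """Element counts (C, H, N, O, S) of a neutral molecule."""

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        for element, n in self.counts:
            if element not in ELEMENT_ISOTOPES:
                raise ValueError(f"unknown element {element!r}")
            if n < 0:
                raise ValueError(f"negative count for element {element}")

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "ElementalComposition":
        return cls(tuple(sorted((k, v) for k, v in d.items() if v)))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def n_atoms(self) -> int:
        return sum(n for _, n in self.counts)


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Aggregated isotopologue peaks A0, A1, A2, ... of one species.

    ``peaks`` holds (m/z, relative abundance) pairs; abundances are
    normalised over the *full* envelope, so after truncation they sum to
    slightly less than one.
    """

    peaks: tuple[tuple[float, float], ...]
    threshold: float

    @property
    def mzs(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def abundances(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])


def monoisotopic_mass(peptide: PeptideSpecies) -> float:
    """Neutral monoisotopic mass in Da: residues + water + modifications."""
    mass = sum(RESIDUE_MASS[ch] for ch in peptide.sequence) + WATER_MONO
    mass += peptide.n_hydroxylations * HYDROXYLATION
    mass += peptide.n_deamidations * DEAMIDATION
    return mass


def mz_protonated(peptide: PeptideSpecies) -> float:
    """[M + zH]^z+ m/z for positive-mode MALDI (z = 1 by default)."""
    return (monoisotopic_mass(peptide) + peptide.charge * PROTON) / peptide.charge


def nominal_mz(peptide: PeptideSpecies) -> int:
    """Integer marker label by the nominal-mass convention.

    Sum of nominal residue masses + 18 (water) + 16 per hydroxylation +
    1 per deamidation + 1 (proton), for singly charged species. This is
    the convention behind marker names such as "P1 (1105 m/z)".
    """
    if peptide.charge != 1:
        raise ValueError("nominal marker labels are defined for charge 1")
    nominal = sum(RESIDUE_NOMINAL[ch] for ch in peptide.sequence) + 18
    nominal += 16 * peptide.n_hydroxylations + 1 * peptide.n_deamidations
    return nominal + 1


def peptide_composition(peptide: PeptideSpecies) -> ElementalComposition:
    """Elemental composition: residue sum + one water + modifications.

    Hydroxylation adds one O; deamidation swaps an amide for a carboxyl
    (+O, -N, -H).
    """
    totals: dict[str, int] = {"C": 0, "H": 2, "N": 0, "O": 1, "S": 0}
    for ch in peptide.sequence:
        for element, n in RESIDUE_COMPOSITION[ch].items():
            totals[element] += n
    totals["O"] += peptide.n_hydroxylations
    totals["O"] += peptide.n_deamidations
    totals["N"] -= peptide.n_deamidations
    totals["H"] -= peptide.n_deamidations
    return ElementalComposition.from_dict(totals)


def _element_envelope(element: str, n: int) -> np.ndarray:
    """Neutron-shift distribution of n atoms of one element.

    n-fold convolution of the single-atom distribution, by binary
    exponentiation so large peptides stay cheap.
    """
    base = np.asarray(ELEMENT_ISOTOPES[element], dtype=float)
    result = np.array([1.0])
    power = base
    while n:
        if n & 1:
            result = np.convolve(result, power)
        n >>= 1
        if n:
            power = np.convolve(power, power)
    return result


def isotope_envelope(
    composition: ElementalComposition,
    charge: int = 1,
    threshold: float = 1e-4,
    monoisotopic: float | None = None,
) -> IsotopeEnvelope:
    """Aggregated isotope envelope of a composition.

    The abundance of the k-th isotopologue peak (k extra neutrons) is
    obtained by convolving per-element neutron-shift distributions at
    standard terrestrial abundances. Peaks below ``threshold`` relative
    abundance are dropped after normalisation (but trailing low-mass
    peaks before the last retained one are kept so m/z spacing stays
    regular — in practice the envelope is unimodal so this rarely
    matters).

    If ``monoisotopic`` (neutral Da) is not given it is reconstructed
    from exact isotope masses of the composition.
    """
    if composition.n_atoms == 0:
        raise ValueError("composition must contain at least one atom")
    if charge < 1:
        raise ValueError("charge must be >= 1")

    dist = np.array([1.0])
    for element, n in composition.counts:
        dist = np.convolve(dist, _element_envelope(element, n))
    dist = dist / dist.sum()

    if monoisotopic is None:
        monoisotopic = _composition_monoisotopic(composition)

    peaks = []
    for k, ab in enumerate(dist):
        if ab < threshold:
            continue
        mz = (monoisotopic + k * NEUTRON_SPACING + charge * PROTON) / charge
        peaks.append((mz, float(ab)))
    return IsotopeEnvelope(peaks=tuple(peaks), threshold=threshold)


# Exact monoisotopic atom masses for reconstructing envelope positions.
_ATOM_MONO = {"C": 12.0, "H": 1.0078250319, "N": 14.0030740052,
              "O": 15.9949146221, "S": 31.97207069}


def _composition_monoisotopic(composition: ElementalComposition) -> float:
    return sum(_ATOM_MONO[el] * n for el, n in composition.counts)


#: The deamidation-assessment peptide: collagen alpha-1(I) GVQGPPGPAGPR
#: with one hydroxyproline, nominal marker P1 at 1105 m/z.
P1105 = PeptideSpecies("GVQGPPGPAGPR", n_hydroxylations=1)
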