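"""Peptide chemistry: masses, modifications, isotope envelopes."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lissoir.masses import (
    DEAMIDATION,
    ELEMENT_ISOTOPES,
    HYDROXYLATION,
    NEUTRON_SPACING,
    P1105,
    PROTON,
    RESIDUE_MASS,
    WATER_MONO,
    ElementalComposition,
    PeptideSpecies,
    isotope_envelope,
    monoisotopic_mass,
    mz_protonated,
    nominal_mz,
    peptide_composition,
)

SEQ = st.text(alphabet=sorted(RESIDUE_MASS), min_size=1, max_size=30)


@pytest.mark.parametrize(
    "peptide, expected",
    [
        (PeptideSpecies("GVQGPPGPAGPR"), 1088.573),
        (PeptideSpecies("G"), 75.032),
        (PeptideSpecies("GVQGPPGPAGPR", n_hydroxylations=1), 1104.568),
    ],
)
def test_monoisotopic_mass_reference_values(peptide, expected):
    assert monoisotopic_mass(peptide) == pytest.approx(expected, abs=5e-4)


def test_monoisotopic_matches_independent_mass_calculator():
    # cross-check the embedded residue table against pyteomics
    from pyteomics import mass as pmass

    for seq in ["GVQGPPGPAGPR", "LVNELTEFAK", "WYCHMISTK"]:
        assert monoisotopic_mass(PeptideSpecies(seq)) == pytest.approx(
            pmass.fast_mass(seq), abs=1e-3
        )


@pytest.mark.parametrize(
    "peptide, expected_mz",
    [
        (PeptideSpecies("GVQGPPGPAGPR", n_hydroxylations=1), 1105.575),
        (PeptideSpecies("GVQGPPGPAGPR", n_hydroxylations=1, n_deamidations=1), 1106.559),
    ],
)
def test_protonated_mz(peptide, expected_mz):
    assert mz_protonated(peptide) == pytest.approx(expected_mz, abs=5e-4)


def test_marker_label_follows_nominal_mass_convention():
    assert nominal_mz(P1105) == 1105


def test_unknown_residue_is_named_in_error():
    with pytest.raises(ValueError, match="'Z'"):
        PeptideSpecies("GZG")


def test_modification_counts_bounded_by_sequence():
    with pytest.raises(ValueError):
        PeptideSpecies("GAG", n_deamidations=1)  # no N/Q
    with pytest.raises(ValueError):
        PeptideSpecies("GAG", n_hydroxylations=1)  # no P
    with pytest.raises(ValueError):
        PeptideSpecies("GAG", charge=0)


@given(a=SEQ, b=SEQ)
@settings(deadline=None, max_examples=60)
def test_mass_additivity_on_concatenation(a, b):
    lhs = monoisotopic_mass(PeptideSpecies(a + b))
    rhs = (
        monoisotopic_mass(PeptideSpecies(a))
        + monoisotopic_mass(PeptideSpecies(b))
        - WATER_MONO
    )
    assert lhs == pytest.approx(rhs, abs=1e-9)


@given(seq=st.sampled_from(["GPNGQPGR", "NQNQPPK", "GVQGPPGPAGPR"]),
       h=st.integers(0, 2), d=st.integers(0, 2))
@settings(deadline=None, max_examples=30)
def test_modification_shifts_are_positional_blind_constants(seq, h, d):
    h = min(h, seq.count("P"))
    d = min(d, seq.count("N") + seq.count("Q"))
    base = monoisotopic_mass(PeptideSpecies(seq))
    modified = monoisotopic_mass(PeptideSpecies(seq, n_hydroxylations=h, n_deamidations=d))
    assert modified - base == pytest.approx(h * HYDROXYLATION + d * DEAMIDATION, abs=1e-9)


# --- isotope envelopes ---------------------------------------------------


def brute_force_envelope(composition: ElementalComposition) -> np.ndarray:
    """Exhaustive multinomial expansion over per-element isotopologues.

    Independent oracle: enumerates, for every element, all ways its n
    atoms distribute over the element's isotopes, with multinomial
    coefficients, and accumulates probability by total neutron shift.
    """
    total = {0: 1.0}
    for element, n in composition.counts:
        probs = ELEMENT_ISOTOPES[element]
        shifts = range(len(probs))
        elem_dist: dict[int, float] = {}
        for combo in itertools.product(shifts, repeat=0):
            pass
        # partitions of n atoms over isotopes
        def partitions(n, k):
            if k == 1:
                yield (n,)
                return
            for first in range(n + 1):
                for rest in partitions(n - first, k - 1):
                    yield (first,) + rest

        for part in partitions(n, len(probs)):
            coef = math.factorial(n)
            p = 1.0
            shift = 0
            for count, prob, s in zip(part, probs, shifts):
                coef //= math.factorial(count)
                p *= prob**count
                shift += count * s
            elem_dist[shift] = elem_dist.get(shift, 0.0) + coef * p
        new_total: dict[int, float] = {}
        for s1, p1 in total.items():
            for s2, p2 in elem_dist.items():
                new_total[s1 + s2] = new_total.get(s1 + s2, 0.0) + p1 * p2
        total = new_total
    out = np.zeros(max(total) + 1)
    for s, p in total.items():
        out[s] = p
    return out


def test_single_carbon_envelope():
    env = isotope_envelope(ElementalComposition.from_dict({"C": 1}), threshold=0.0)
    assert env.abundances[:2] == pytest.approx([0.9893, 0.0107], abs=1e-9)


def test_water_a0_abundance():
    env = isotope_envelope(ElementalComposition.from_dict({"H": 2, "O": 1}), threshold=0.0)
    expected = 0.999885**2 * 0.99757  # brute-force product for A0
    assert env.abundances[0] == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize(
    "comp",
    [
        {"C": 10, "H": 20, "N": 5, "O": 8},
        {"C": 20, "H": 30, "O": 5, "S": 2},
        {"C": 47, "H": 73, "N": 13, "O": 14},  # GVQGPPGPAGPR-sized, capped to <=60 atoms below
    ],
)
def test_convolution_matches_exhaustive_expansion(comp):
    # cap at <=60 atoms to keep the oracle exhaustive yet fast
    capped = {k: min(v, 60 - 0) for k, v in comp.items()}
    while sum(capped.values()) > 60:
        biggest = max(capped, key=capped.get)
        capped[biggest] -= 1
    composition = ElementalComposition.from_dict(capped)
    oracle = brute_force_envelope(composition)
    env = isotope_envelope(composition, threshold=0.0)
    assert len(env.abundances) == len(oracle)
    assert np.max(np.abs(env.abundances - oracle)) < 1e-8


@given(
    c=st.integers(1, 60), h=st.integers(0, 100), n=st.integers(0, 20),
    o=st.integers(0, 20), s=st.integers(0, 3),
)
@settings(deadline=None, max_examples=40)
def test_envelope_normalises_before_truncation(c, h, n, o, s):
    comp = ElementalComposition.from_dict({"C": c, "H": h, "N": n, "O": o, "S": s})
    env = isotope_envelope(comp, threshold=0.0)
    assert env.abundances.sum() == pytest.approx(1.0, abs=1e-9)


def test_envelope_spacing_is_one_neutron_per_charge():
    comp = peptide_composition(P1105)
    for charge in (1, 2):
        env = isotope_envelope(comp, charge=charge)
        spacings = np.diff(env.mzs)
        assert spacings == pytest.approx(NEUTRON_SPACING / charge, abs=1e-6)


def test_p1105_composition_accounts_for_hydroxylation():
    base = peptide_composition(PeptideSpecies("GVQGPPGPAGPR"))
    hyd = peptide_composition(P1105)
    assert hyd.as_dict()["O"] == base.as_dict()["O"] + 1
    deam = peptide_composition(
        PeptideSpecies("GVQGPPGPAGPR", n_hydroxylations=1, n_deamidations=1)
    )
    d, h = deam.as_dict(), hyd.as_dict()
    assert (d["O"] - h["O"], d["N"] - h["N"], d["H"] - h["H"]) == (1, -1, -1)


def test_proton_constant_used_for_charge():
    # hypothetical neutral mass 0: m/z is exactly one proton
    assert PROTON == pytest.approx(1.007276, abs=1e-6)
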