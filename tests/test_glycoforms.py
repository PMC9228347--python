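"""Glycan nomenclature parsing and monoisotopic-mass computations."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycowin.glycoforms import (
    FUC,
    HEX,
    HEXNAC,
    NEUAC,
    PROTON,
    GlycanComposition,
    GlycoformError,
    Glycopeptide,
    Peptide,
    format_glycoform,
    glycan_residue_mass,
    n_glycosylation_sequons,
    oxonium_mz,
    parse_glycoform_code,
    peptide_monoisotopic_mass,
    precursor_mz,
    transition_list,
)

HYPO = settings(derandomize=True, database=None, deadline=None)


def enumerate_complex_glycan(antennae, galactoses, sialic_acids, fucoses):
    """Independent residue-enumeration oracle for complex-type N-glycans.

    Builds the composition residue by residue: the chitobiose core
    (2 GlcNAc), the trimannosyl branch point (3 Man), one GlcNAc per
    antenna, one Gal (hexose) per galactose, plus terminal NeuAc and Fuc.
    """
    counts = {"hexnac": 0, "hex": 0, "fuc": 0, "neuac": 0}
    for _ in range(2):  # chitobiose core
        counts["hexnac"] += 1
    for _ in range(3):  # trimannosyl core
        counts["hex"] += 1
    for _ in range(antennae):
        counts["hexnac"] += 1
    for _ in range(galactoses):
        counts["hex"] += 1
    for _ in range(sialic_acids):
        counts["neuac"] += 1
    for _ in range(fucoses):
        counts["fuc"] += 1
    return GlycanComposition(**counts)


@pytest.mark.parametrize(
    "code, agsf",
    [
        ("A2G2", (2, 2, 0, 0)),
        ("A2G2F1", (2, 2, 0, 1)),
        ("A2G2S1", (2, 2, 1, 0)),
        ("A2G2S1F1", (2, 2, 1, 1)),
        ("A2G2S2F1", (2, 2, 2, 1)),
        ("A3G3", (3, 3, 0, 0)),
        ("A3G3S3", (3, 3, 3, 0)),
        ("A4G4S4F2", (4, 4, 4, 2)),
    ],
)
def test_parse_matches_residue_enumeration_oracle(code, agsf):
    assert parse_glycoform_code(code) == enumerate_complex_glycan(*agsf)


def test_parse_frozen_examples():
    assert parse_glycoform_code("A2G2") == GlycanComposition(4, 5, 0, 0)
    assert parse_glycoform_code("A2G2S1F1") == GlycanComposition(4, 5, 1, 1)
    assert parse_glycoform_code("A3G3S3") == GlycanComposition(5, 6, 0, 3)


@pytest.mark.parametrize(
    "bad",
    [
        "G2A2",  # token order
        "A2F1S1",  # S after F
        "A2",  # missing G
        "G2",  # missing A
        "AG2",  # A without count
        "A1G1",  # fewer than two antennae
        "A2G3",  # more Gal than antennae
        "A2G2S3",  # more NeuAc than Gal
        "A2G2S0",  # explicit zero count breaks round-trip
        "A2G2F0",
        "A2G2X1",  # unknown token
        "A2G2S1S1",  # duplicate token
        "a2g2",  # case-sensitive
        "",
        "A2G2 ",
    ],
)
def test_parse_rejects_malformed_codes(bad):
    with pytest.raises(GlycoformError):
        parse_glycoform_code(bad)


def test_parse_error_names_offending_token():
    with pytest.raises(GlycoformError, match="order"):
        parse_glycoform_code("G2A2")
    with pytest.raises(GlycoformError, match="X"):
        parse_glycoform_code("A2G2X1")


def test_all_packaged_codes_parse_and_round_trip(inventory, reference_model, fetuin_records):
    codes = {g for entry in inventory for g in entry["glycoforms"]}
    codes |= set(reference_model.entries)
    codes |= {r.glycoform for r in fetuin_records}
    assert len(codes) == 11
    for code in codes:
        assert format_glycoform(parse_glycoform_code(code)) == code


@st.composite
def valid_codes(draw):
    a = draw(st.integers(2, 6))
    g = draw(st.integers(0, a))
    s = draw(st.integers(0, g))
    f = draw(st.integers(0, 3))
    code = f"A{a}G{g}"
    if s:
        code += f"S{s}"
    if f:
        code += f"F{f}"
    return code


@HYPO
@given(valid_codes())
def test_parse_format_round_trip_property(code):
    assert format_glycoform(parse_glycoform_code(code)) == code


@pytest.mark.parametrize("suffix", ["", "S1", "F1", "S1F1", "S2F1"])
def test_triantennary_dominates_biantennary_componentwise(suffix):
    small = parse_glycoform_code(f"A2G2{suffix}")
    # S2 needs G >= 2, satisfied by both A2G2 and A3G3 stems
    big = parse_glycoform_code(f"A3G3{suffix}")
    assert big.hexnac > small.hexnac and big.hex > small.hex
    assert big.fuc == small.fuc and big.neuac == small.neuac


def brute_force_mass(comp):
    total = 0.0
    for _ in range(comp.hexnac):
        total += HEXNAC
    for _ in range(comp.hex):
        total += HEX
    for _ in range(comp.fuc):
        total += FUC
    for _ in range(comp.neuac):
        total += NEUAC
    return total


def test_glycan_mass_examples():
    assert glycan_residue_mass(GlycanComposition()) == 0.0
    assert glycan_residue_mass(parse_glycoform_code("A2G2")) == pytest.approx(1622.5816, abs=1e-3)


@HYPO
@given(
    st.builds(GlycanComposition, st.integers(0, 8), st.integers(0, 8), st.integers(0, 4), st.integers(0, 4)),
    st.builds(GlycanComposition, st.integers(0, 8), st.integers(0, 8), st.integers(0, 4), st.integers(0, 4)),
)
def test_glycan_mass_additivity_and_positivity(a, b):
    assert glycan_residue_mass(a) == pytest.approx(brute_force_mass(a), abs=1e-9)
    assert glycan_residue_mass(a + b) == pytest.approx(
        glycan_residue_mass(a) + glycan_residue_mass(b), abs=1e-9
    )
    if (a.hexnac, a.hex, a.fuc, a.neuac) != (0, 0, 0, 0):
        assert glycan_residue_mass(a) > 0


@pytest.mark.parametrize(
    "seq, expected",
    [("G", 75.03203), ("GG", 132.05349), ("C", 178.04121)],
)
def test_peptide_masses_match_standard_table(seq, expected):
    assert peptide_monoisotopic_mass(seq) == pytest.approx(expected, abs=5e-4)


def test_peptide_mass_without_carbamidomethyl():
    assert peptide_monoisotopic_mass("C", fixed_mods={}) == pytest.approx(121.01975, abs=5e-4)


def test_unknown_residue_error_names_position():
    with pytest.raises(ValueError, match="position 3"):
        peptide_monoisotopic_mass("GGZG")
    with pytest.raises(ValueError):
        Peptide("")


def test_precursor_mz_examples_and_monotonicity():
    assert precursor_mz(1000.0, 0.0, 1) == pytest.approx(1001.007276, abs=1e-6)
    # (1000 + 2 * 1.007276) / 2, by hand
    assert precursor_mz(1000.0, 0.0, 2) == pytest.approx(501.007276, abs=1e-6)
    values = [precursor_mz(1500.0, 2000.0, z) for z in range(1, 7)]
    assert values == sorted(values, reverse=True)
    with pytest.raises(ValueError):
        precursor_mz(1000.0, 0.0, 0)


def test_oxonium_registry():
    assert oxonium_mz("HexNAc") == pytest.approx(204.0867, abs=1e-3)
    assert oxonium_mz("NeuAc-H2O") == pytest.approx(274.0921, abs=1e-3)
    assert oxonium_mz("Hex") == pytest.approx(163.0601, abs=1e-3)
    # the registry matches residue + proton - n*H2O by construction
    assert oxonium_mz("NeuAc") - oxonium_mz("NeuAc-H2O") == pytest.approx(18.010565, abs=1e-9)
    with pytest.raises(KeyError, match="HexNAc"):
        oxonium_mz("NotASugar")


def test_transition_list_pairs_precursors_with_oxonium_fragments():
    gps = [Glycopeptide.from_codes("LDVDQALNR", code) for code in ("A2G2", "A2G2S1")]
    table = transition_list(gps)
    assert list(table.columns) == [
        "peptide", "glycoform", "charge", "precursor_mz", "fragment_name", "fragment_mz",
    ]
    assert len(table) == 2 * 2 * 2  # glycoforms x charges x fragments
    frag = table.set_index("fragment_name")["fragment_mz"]
    assert round(frag["HexNAc"].iloc[0], 1) == 204.1
    assert round(frag["NeuAc-H2O"].iloc[0], 1) == 274.1
    z3 = table[(table.glycoform == "A2G2") & (table.charge == 3)].precursor_mz.iloc[0]
    z4 = table[(table.glycoform == "A2G2") & (table.charge == 4)].precursor_mz.iloc[0]
    assert z4 < z3


def test_double_sequon_peptide_is_flagged():
    assert n_glycosylation_sequons("SHEIWTHSCPQSPGNGTDASHLDVDQALNR") == 2
    with pytest.warns(UserWarning, match="sequon"):
        Glycopeptide.from_codes("SHEIWTHSCPQSPGNGTDASHLDVDQALNR", "A2G2")


def test_glycopeptide_composition_must_match_code():
    with pytest.raises(ValueError, match="does not match"):
        Glycopeptide(Peptide("LDVDQALNR"), "A2G2", GlycanComposition(5, 6, 0, 0))
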