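"""Glycan nomenclature and monoisotopic-mass utilities.

Glycoforms are written in the compact AxGySzFw notation for complex-type
N-glycans: ``A`` antennae (GlcNAc branches on the trimannosyl-chitobiose
core), ``G`` galactoses, ``S`` sialic acids (NeuAc), ``F`` fucoses, in that
order.  ``A2G2`` is the bi-antennary digalactosylated asialo glycan used as
the retention anchor.  The notation maps onto monosaccharide counts as

    HexNAc = 2 (core GlcNAc) + A        Hex = 3 (core Man) + G
    NeuAc  = S                          Fuc = F

Only complex-type glycans are representable; hybrid and high-mannose
structures are rejected rather than guessed.

Mass utilities cover what is needed to design an SRM method for intact
glycopeptides: glycan residue masses, peptide monoisotopic masses with
carbamidomethyl-Cys as a default fixed modification, multiply charged
precursor m/z, and the diagnostic oxonium fragment ions (HexNAc at m/z
204.1, NeuAc - H2O at m/z 274.1).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyteomics import mass as _pyteomics_mass

__all__ = [
    "GlycanComposition",
    "Peptide",
    "Glycopeptide",
    "GlycoformError",
    "parse_glycoform_code",
    "format_glycoform",
    "glycan_residue_mass",
    "peptide_monoisotopic_mass",
    "precursor_mz",
    "oxonium_mz",
    "OXONIUM_IONS",
    "transition_list",
    "n_glycosylation_sequons",
]

# Monoisotopic residue masses (Da) of glycan building blocks, i.e. the mass
# added to a chain per incorporated monosaccharide (free sugar minus water).
HEXNAC = 203.07937
HEX = 162.05282
FUC = 146.05791
NEUAC = 291.09542

PROTON = 1.007276
WATER = 18.010565
CARBAMIDOMETHYL = 57.02146

#: Default fixed modifications: carbamidomethylation of every cysteine
#: (iodoacetamide alkylation during sample preparation).
DEFAULT_FIXED_MODS: Mapping[str, float] = {"C": CARBAMIDOMETHYL}

_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")


class GlycoformError(ValueError):
    """Malformed or chemically invalid glycoform code."""


@dataclass(frozen=True)
class GlycanComposition:
    """Monosaccharide counts of an N-glycan.

    ``hex`` counts all hexoses (mannose + galactose); ``fuc`` counts
    deoxyhexoses; ``neuac`` counts N-acetylneuraminic acids.
    """

    hexnac: int = 0
    hex: int = 0
    fuc: int = 0
    neuac: int = 0

    def __post_init__(self) -> None:
        for name in ("hexnac", "hex", "fuc", "neuac"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} count must be a nonnegative integer, got {v!r}")

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            self.hexnac + other.hexnac,
            self.hex + other.hex,
            self.fuc + other.fuc,
            self.neuac + other.neuac,
        )

    @property
    def mass(self) -> float:
        return glycan_residue_mass(self)


_TOKEN = re.compile(r"([A-Za-z])(\d*)")
_ORDER = "AGSF"


def parse_glycoform_code(code: str) -> GlycanComposition:
    """Parse an AxGySzFw glycoform code into monosaccharide counts.

    The grammar is ``A<a>G<g>[S<s>][F<f>]`` with a >= 2, g <= a, s <= g,
    and, when present, s >= 1 and f >= 1 (explicit zero counts are not
    written, so parse/format round-trips).

    >>> parse_glycoform_code("A2G2S1F1")
    GlycanComposition(hexnac=4, hex=5, fuc=1, neuac=1)
    """
    if not isinstance(code, str) or not code:
        raise GlycoformError(f"glycoform code must be a non-empty string, got {code!r}")
    pos = 0
    counts: dict[str, int] = {}
    seen_order: list[str] = []
    while pos < len(code):
        m = _TOKEN.match(code, pos)
        if m is None:
            raise GlycoformError(f"{code!r}: unexpected character {code[pos]!r} at position {pos}")
        letter, digits = m.group(1), m.group(2)
        if letter not in _ORDER:
            raise GlycoformError(f"{code!r}: unknown token {letter!r} (expected one of A, G, S, F)")
        if letter in counts:
            raise GlycoformError(f"{code!r}: duplicate token {letter!r}")
        if not digits:
            raise GlycoformError(f"{code!r}: token {letter!r} has no count")
        counts[letter] = int(digits)
        seen_order.append(letter)
        pos = m.end()
    canonical = [t for t in _ORDER if t in counts]
    if seen_order != canonical:
        raise GlycoformError(
            f"{code!r}: tokens must appear in A, G, S, F order, got {''.join(seen_order)}"
        )
    if "A" not in counts or "G" not in counts:
        missing = "A" if "A" not in counts else "G"
        raise GlycoformError(f"{code!r}: mandatory token {missing!r} is missing")
    a, g = counts["A"], counts["G"]
    s, f = counts.get("S", 0), counts.get("F", 0)
    if a < 2:
        raise GlycoformError(f"{code!r}: at least 2 antennae required, got A{a}")
    if g > a:
        raise GlycoformError(f"{code!r}: more galactoses than antennae (G{g} > A{a})")
    if s > g:
        raise GlycoformError(f"{code!r}: more sialic acids than galactoses (S{s} > G{g})")
    if "S" in counts and s < 1:
        raise GlycoformError(f"{code!r}: explicit S token requires a count >= 1")
    if "F" in counts and f < 1:
        raise GlycoformError(f"{code!r}: explicit F token requires a count >= 1")
    return GlycanComposition(hexnac=2 + a, hex=3 + g, fuc=f, neuac=s)


def format_glycoform(comp: GlycanComposition) -> str:
    """Format a composition back into its AxGySzFw code.

    Inverse of :func:`parse_glycoform_code`; raises :class:`GlycoformError`
    for compositions that are not complex-type (hexnac < 4 or hex < 3) or
    violate the antenna/galactose/sialic-acid ordering constraints.
    """
    a = comp.hexnac - 2
    g = comp.hex - 3
    if a < 2 or g < 0:
        raise GlycoformError(
            f"composition {comp} is not a complex-type N-glycan (need hexnac >= 4, hex >= 3)"
        )
    if g > a or comp.neuac > g:
        raise GlycoformError(f"composition {comp} violates G <= A and S <= G constraints")
    code = f"A{a}G{g}"
    if comp.neuac:
        code += f"S{comp.neuac}"
    if comp.fuc:
        code += f"F{comp.fuc}"
    return code


def glycan_residue_mass(comp: GlycanComposition) -> float:
    """Monoisotopic mass (Da) added by the glycan to a peptide."""
    return HEXNAC * comp.hexnac + HEX * comp.hex + FUC * comp.fuc + NEUAC * comp.neuac


def n_glycosylation_sequons(sequence: str) -> int:
    """Count potential N-glycosylation sequons in a peptide sequence.

    Counts complete N-X-S/T motifs (X != P) plus any Asn within the last
    two residues, whose motif extends past the cleavage site and cannot be
    excluded from the peptide alone (common for tryptic ...N-R/K termini).
    """
    complete = len(re.findall(r"N(?=[^P][ST])", sequence))
    tail = sequence[-2:]
    truncated = sum(
        1
        for i, aa in enumerate(tail)
        if aa == "N" and not re.match(r"N[^P][ST]", sequence[len(sequence) - len(tail) + i :])
    )
    return complete + truncated


@dataclass(frozen=True)
class Peptide:
    """A peptide backbone with fixed modifications applied to every
    occurrence of the given residues (carbamidomethyl-Cys by default)."""

    sequence: str
    fixed_mods: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FIXED_MODS))

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        for i, aa in enumerate(self.sequence):
            if aa not in _AA_LETTERS:
                raise ValueError(
                    f"unknown amino-acid letter {aa!r} at position {i + 1} of {self.sequence!r}"
                )

    @property
    def monoisotopic_mass(self) -> float:
        return peptide_monoisotopic_mass(self.sequence, self.fixed_mods)


def peptide_monoisotopic_mass(
    sequence: str, fixed_mods: Mapping[str, float] | None = None
) -> float:
    """Neutral monoisotopic mass (Da) of a peptide with fixed modifications.

    ``fixed_mods`` maps residue letters to mass deltas applied to every
    occurrence; the default carbamidomethylates cysteine (+57.02146 Da).
    """
    if fixed_mods is None:
        fixed_mods = DEFAULT_FIXED_MODS
    Peptide(sequence, dict(fixed_mods))  # validates sequence
    base = _pyteomics_mass.fast_mass(sequence)
    return base + sum(sequence.count(res) * delta for res, delta in fixed_mods.items())


@dataclass(frozen=True)
class Glycopeptide:
    """A peptide carrying one N-glycan, identified by its glycoform code."""

    peptide: Peptide
    glycoform: str
    composition: GlycanComposition

    def __post_init__(self) -> None:
        if self.composition != parse_glycoform_code(self.glycoform):
            raise ValueError(
                f"composition {self.composition} does not match glycoform {self.glycoform!r}"
            )
        if n_glycosylation_sequons(self.peptide.sequence) > 1:
            warnings.warn(
                f"peptide {self.peptide.sequence!r} carries more than one N-glycosylation "
                "sequon; masses assume a single attached glycan",
                stacklevel=2,
            )

    @classmethod
    def from_codes(
        cls, sequence: str, glycoform: str, fixed_mods: Mapping[str, float] | None = None
    ) -> "Glycopeptide":
        pep = Peptide(sequence) if fixed_mods is None else Peptide(sequence, fixed_mods)
        return cls(pep, glycoform, parse_glycoform_code(glycoform))

    @property
    def monoisotopic_mass(self) -> float:
        return self.peptide.monoisotopic_mass + self.composition.mass

    def precursor_mz(self, charge: int) -> float:
        return precursor_mz(self.peptide.monoisotopic_mass, self.composition.mass, charge)


def precursor_mz(peptide_mass: float, glycan_mass: float, charge: int) -> float:
    """m/z of a protonated glycopeptide precursor at the given charge."""
    if not isinstance(charge, int) or charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge!r}")
    if peptide_mass < 0 or glycan_mass < 0:
        raise ValueError("masses must be nonnegative")
    return (peptide_mass + glycan_mass + charge * PROTON) / charge


# Oxonium ion registry: (summed residue masses, number of water losses).
_OXONIUM_DEFS: Mapping[str, tuple[float, int]] = {
    "HexNAc": (HEXNAC, 0),
    "HexNAc-H2O": (HEXNAC, 1),
    "HexNAc-2H2O": (HEXNAC, 2),
    "Hex": (HEX, 0),
    "Fuc": (FUC, 0),
    "NeuAc": (NEUAC, 0),
    "NeuAc-H2O": (NEUAC, 1),
    "HexHexNAc": (HEX + HEXNAC, 0),
}

#: Registered oxonium ion names -> m/z (singly protonated).
OXONIUM_IONS: Mapping[str, float] = {
    name: residues + PROTON - n_h2o * WATER for name, (residues, n_h2o) in _OXONIUM_DEFS.items()
}


def oxonium_mz(ion_name: str) -> float:
    """m/z of a diagnostic glycan oxonium fragment ion.

    The two SRM workhorses are ``HexNAc`` (204.087, printed 204.1) and
    ``NeuAc-H2O`` (274.092, printed 274.1).
    """
    try:
        return OXONIUM_IONS[ion_name]
    except KeyError:
        known = ", ".join(sorted(OXONIUM_IONS))
        raise KeyError(f"unknown oxonium ion {ion_name!r}; registry: {known}") from None


def transition_list(
    glycopeptides: Iterable[Glycopeptide],
    charges: Sequence[int] = (3, 4),
    fragments: Sequence[str] = ("HexNAc", "NeuAc-H2O"),
) -> pd.DataFrame:
    """SRM transition table pairing each multiply charged precursor with
    diagnostic oxonium fragments.

    Columns: peptide, glycoform, charge, precursor_mz, fragment_name,
    fragment_mz — ready for CSV export.
    """
    rows = []
    for gp in glycopeptides:
        for z in charges:
            pmz = gp.precursor_mz(z)
            for frag in fragments:
                rows.append(
                    {
                        "peptide": gp.peptide.sequence,
                        "glycoform": gp.glycoform,
                        "charge": z,
                        "precursor_mz": pmz,
                        "fragment_name": frag,
                        "fragment_mz": oxonium_mz(frag),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["peptide", "glycoform", "charge", "precursor_mz", "fragment_name", "fragment_mz"],
    )
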