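"""Residue hydrophobicity scales.

Two widely used scales are bundled: Kyte-Doolittle (the package default for
face assignment and belt measurement) and the Wimley-White interface scale,
which ranks membrane-interface partitioning. Values are per residue,
dimensionless (KD) or kcal/mol transfer free energies with the sign flipped
so that larger always means more hydrophobic (WW).
"""

from __future__ import annotations

from dataclasses import dataclass, field

_STANDARD_AA3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

_AA1_TO_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

KYTE_DOOLITTLE_VALUES = {
    "ALA": 1.8, "ARG": -4.5, "ASN": -3.5, "ASP": -3.5, "CYS": 2.5,
    "GLN": -3.5, "GLU": -3.5, "GLY": -0.4, "HIS": -3.2, "ILE": 4.5,
    "LEU": 3.8, "LYS": -3.9, "MET": 1.9, "PHE": 2.8, "PRO": -1.6,
    "SER": -0.8, "THR": -0.7, "TRP": -0.9, "TYR": -1.3, "VAL": 4.2,
}

# Wimley-White interface free energies (kcal/mol, water -> POPC interface),
# sign-flipped so hydrophobic residues score positive.
WIMLEY_WHITE_VALUES = {
    "ALA": -0.17, "ARG": -0.81, "ASN": -0.42, "ASP": -1.23, "CYS": 0.24,
    "GLN": -0.58, "GLU": -2.02, "GLY": -0.01, "HIS": -0.96, "ILE": 0.31,
    "LEU": 0.56, "LYS": -0.99, "MET": 0.23, "PHE": 1.13, "PRO": -0.45,
    "SER": -0.13, "THR": -0.14, "TRP": 1.85, "TYR": 0.94, "VAL": -0.07,
}


@dataclass(frozen=True)
class HydrophobicityScale:
    """A named per-residue hydrophobicity scale covering the 20 standard residues."""

    name: str
    values: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [aa for aa in _STANDARD_AA3 if aa not in self.values]
        if missing:
            raise ValueError(f"scale {self.name!r} is missing residues: {missing}")

    def of3(self, res_name: str) -> float:
        """Hydrophobicity of a 3-letter residue code."""
        try:
            return self.values[res_name.upper()]
        except KeyError:
            raise KeyError(f"non-standard residue {res_name!r}") from None

    def of1(self, letter: str) -> float:
        """Hydrophobicity of a 1-letter residue code."""
        aa3 = _AA1_TO_AA3.get(letter.upper())
        if aa3 is None:
            raise KeyError(f"non-standard residue letter {letter!r}")
        return self.values[aa3]


KYTE_DOOLITTLE = HydrophobicityScale("kyte-doolittle", KYTE_DOOLITTLE_VALUES)
WIMLEY_WHITE = HydrophobicityScale("wimley-white-interface", WIMLEY_WHITE_VALUES)

SCALES = {"kd": KYTE_DOOLITTLE, "ww": WIMLEY_WHITE}


def get_scale(name: str) -> HydrophobicityScale:
    """Look up a bundled scale by short name ('kd' or 'ww')."""
    try:
        return SCALES[name.lower()]
    except KeyError:
        raise KeyError(f"unknown scale {name!r}; available: {sorted(SCALES)}") from None
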