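"""Amino-acid reference data shared across the package.

The tables here are standard published values: mean residue volumes
(Zamyatnin, 1972) used for the Heaviside volume terms, and theoretical
maximal solvent-accessible surface areas of extended Gly-X-Gly tripeptides
(Tien et al., 2013) used to normalise absolute ASA into a relative solvent
accessibility in percent.  Both tables are swappable through the descriptor
configuration.
"""

from __future__ import annotations

#: Canonical amino acids, one-letter codes, fixed alphabetical order.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

#: Mean amino-acid residue volumes in cubic angstroms (Zamyatnin, 1972).
RESIDUE_VOLUME: dict[str, float] = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

#: Theoretical maximal accessible surface areas, A^2 (Tien et al., 2013).
MAX_ASA_THEORETICAL: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "K": 236.0, "L": 201.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Kyte-Doolittle hydropathy, rescaled to [-1, 1]; used only by the
#: synthetic corpus generator to couple residue type to burial.
HYDROPATHY: dict[str, float] = {
    "A": 0.40, "R": -1.00, "N": -0.78, "D": -0.78, "C": 0.56,
    "Q": -0.78, "E": -0.78, "G": -0.09, "H": -0.71, "I": 1.00,
    "L": 0.84, "K": -0.87, "M": 0.42, "F": 0.62, "P": -0.36,
    "S": -0.18, "T": -0.16, "W": -0.20, "Y": -0.29, "V": 0.93,
}

#: Crude helix propensity signs used by the synthetic generator.
HELIX_PREFERENCE: dict[str, float] = {
    "A": 0.8, "L": 0.6, "M": 0.5, "E": 0.5, "K": 0.4, "Q": 0.3,
    "R": 0.2, "H": 0.0, "I": 0.1, "F": 0.1, "W": 0.0, "Y": -0.1,
    "D": -0.1, "S": -0.2, "T": -0.3, "C": -0.2, "N": -0.3,
    "V": -0.2, "P": -0.9, "G": -0.7,
}

CELSIUS_OFFSET = 273.15


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + CELSIUS_OFFSET


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - CELSIUS_OFFSET
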