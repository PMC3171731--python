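"""Embedded reference tables shared across the package.

All per-residue tables are keyed by the 20 canonical three-letter codes in
alphabetical order; vector-valued features (residue-type one-hots, CDV, CSV,
EDM) use this order everywhere.
"""

from __future__ import annotations

import numpy as np

#: Canonical residue types, alphabetical by three-letter code.
AMINO_ACIDS: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

#: Common chemically modified residues mapped to their parent type.
MODIFIED_RESIDUE_PARENT: dict[str, str] = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",  # selenocysteine
    "CSO": "CYS",  # s-hydroxycysteine
    "HYP": "PRO",  # hydroxyproline
    "MLY": "LYS",  # n-dimethyl-lysine
    "PYL": "LYS",  # pyrrolysine
    "SEP": "SER",  # phosphoserine
    "TPO": "THR",  # phosphothreonine
    "PTR": "TYR",  # phosphotyrosine
}

#: Maximal residue solvent accessibility (A^2) in an extended Gly-X-Gly
#: tripeptide; theoretical values of Tien et al. 2013 (PLoS ONE 8:e80635).
MAX_ASA_GXG: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE: dict[str, float] = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
    "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
    "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
    "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

#: Background amino-acid frequencies (Robinson & Robinson 1991), normalised.
_BG = {
    "ALA": 0.0780, "ARG": 0.0512, "ASN": 0.0448, "ASP": 0.0536,
    "CYS": 0.0192, "GLN": 0.0426, "GLU": 0.0629, "GLY": 0.0738,
    "HIS": 0.0219, "ILE": 0.0514, "LEU": 0.0901, "LYS": 0.0574,
    "MET": 0.0224, "PHE": 0.0385, "PRO": 0.0520, "SER": 0.0712,
    "THR": 0.0584, "TRP": 0.0132, "TYR": 0.0321, "VAL": 0.0644,
}
_total = sum(_BG.values())
BACKGROUND_FREQUENCIES: dict[str, float] = {k: v / _total for k, v in _BG.items()}

#: Van der Waals radii (A) used for sphere-sampling SASA.
VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "H": 1.20, "D": 1.20,
}
DEFAULT_VDW_RADIUS = 1.70


def contact_potential() -> np.ndarray:
    """Pairwise residue contact pseudo-energy table (20 x 20, symmetric).

    Additive hydrophobicity approximation to knowledge-based contact
    potentials: contacts between hydrophobic residues score favourably
    (negative), contacts between hydrophilic ones unfavourably, in
    dimensionless units of half the summed Kyte-Doolittle values scaled
    by the scale's half-range (4.5).
    """
    kd = np.array([KYTE_DOOLITTLE[aa] for aa in AMINO_ACIDS])
    return -(kd[:, None] + kd[None, :]) / (2.0 * 4.5)


CONTACT_POTENTIAL: np.ndarray = contact_potential()
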