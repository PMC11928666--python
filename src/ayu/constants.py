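"""Packaged physicochemical constant tables.

All tables are keyed by the 20 canonical one-letter amino-acid codes.
Provenance:

* ``KYTE_DOOLITTLE`` — Kyte & Doolittle hydropathy index.
* ``HOPP_WOODS`` — Hopp & Woods hydrophilicity scale (the scale classically
  used for the hydrophilicity axis of pseudo amino-acid composition).
* ``RESIDUE_MASS`` — monoisotopic residue masses (residue = amino acid minus
  one water, i.e. the mass contributed inside a peptide chain).
* ``EMBOSS_PKA`` — the pKa set shipped with EMBOSS ``iep``.
* ``ATP_COST`` — Akashi & Gojobori aerobic biosynthetic costs in high-energy
  phosphate bonds per molecule.
* ``RESIDUE_FORMULA`` — elemental composition (C, H, N, O, S) of each residue
  as incorporated in a peptide chain (backbone included; add one water for a
  whole protein).

The default physicochemical distance matrix used by the quasi-sequence-order
descriptor is a reconstruction, not the originally published table: it is the
Euclidean distance over the three standardized scales above, normalized so the
largest pairwise distance is 1.  See ``docs/methods.md`` for the rationale;
any 20x20 symmetric matrix with zero diagonal can be injected instead.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Letters accepted in input sequences but excluded from descriptor math.
AMBIGUOUS = set("XBZUO")

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

HOPP_WOODS = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0,
    "Q": 0.2, "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8,
    "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5, "P": 0.0,
    "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5,
}

RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER_MASS = 18.01056

EMBOSS_PKA = {
    "Nterm": 8.6, "Cterm": 3.6,
    "K": 10.8, "R": 12.5, "H": 6.5,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
}

ATP_COST = {
    "A": 11.7, "R": 27.3, "N": 14.7, "D": 12.7, "C": 24.7,
    "Q": 16.3, "E": 15.3, "G": 11.7, "H": 38.3, "I": 32.3,
    "L": 27.3, "K": 30.3, "M": 34.3, "F": 52.0, "P": 20.3,
    "S": 11.7, "T": 18.7, "W": 74.3, "Y": 50.0, "V": 23.3,
}

# (C, H, N, O, S) atoms per residue inside a peptide chain.
RESIDUE_FORMULA = {
    "A": (3, 5, 1, 1, 0), "R": (6, 12, 4, 1, 0), "N": (4, 6, 2, 2, 0),
    "D": (4, 5, 1, 3, 0), "C": (3, 5, 1, 1, 1), "E": (5, 7, 1, 3, 0),
    "Q": (5, 8, 2, 2, 0), "G": (2, 3, 1, 1, 0), "H": (6, 7, 3, 1, 0),
    "I": (6, 11, 1, 1, 0), "L": (6, 11, 1, 1, 0), "K": (6, 12, 2, 1, 0),
    "M": (5, 9, 1, 1, 1), "F": (9, 9, 1, 1, 0), "P": (5, 7, 1, 1, 0),
    "S": (3, 5, 1, 2, 0), "T": (4, 7, 1, 2, 0), "W": (11, 10, 2, 1, 0),
    "Y": (9, 9, 1, 2, 0), "V": (5, 9, 1, 1, 0),
}


def _standardize(scale: dict[str, float]) -> np.ndarray:
    v = np.array([scale[a] for a in AMINO_ACIDS], dtype=float)
    return (v - v.mean()) / v.std()


def standardized_scales() -> np.ndarray:
    """The three propensity scales (hydrophobicity, hydrophilicity, residue
    mass) as a (3, 20) array, each standardized to zero mean / unit variance
    over the 20 canonical letters (indexed by :data:`AMINO_ACIDS`)."""
    return np.vstack([
        _standardize(KYTE_DOOLITTLE),
        _standardize(HOPP_WOODS),
        _standardize(RESIDUE_MASS),
    ])


def default_distance_matrix() -> np.ndarray:
    """Reconstructed physicochemical distance matrix (20x20, symmetric, zero
    diagonal, max distance 1) used as the quasi-sequence-order default."""
    s = standardized_scales()           # (3, 20)
    diff = s[:, :, None] - s[:, None, :]
    d = np.sqrt((diff ** 2).sum(axis=0))
    return d / d.max()
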