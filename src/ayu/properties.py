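"""Residue-derived physicochemical and biosynthetic-economy properties.

Secreted proteins are metabolically "lost" to the cell, so their average
biosynthetic cost and elemental content (nitrogen, sulphur) are of direct
ecological interest; these per-residue means back the descriptive secretome
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import (AA_INDEX, ATP_COST, RESIDUE_FORMULA, RESIDUE_MASS,
                        WATER_MASS)
from .descriptors import DescriptorError


@dataclass(frozen=True)
class ResidueProperties:
    mean_atp: float
    mean_C: float
    mean_N: float
    mean_S: float
    length: int
    mol_weight: float


def residue_properties(seq: str, atp_table: dict[str, float] | None = None
                       ) -> ResidueProperties:
    """Per-residue mean ATP cost and C/N/S atom content, plus canonical
    length and molecular weight (sum of residue masses + one water).

    Elemental counts are whole-residue (backbone included): e.g. arginine
    contributes 4 nitrogen atoms, lysine 2, methionine and cysteine 1
    sulphur each.  Ambiguity letters are excluded throughout.
    """
    if atp_table is None:
        atp_table = ATP_COST
    canonical = [c for c in seq if c in AA_INDEX]
    n = len(canonical)
    if n == 0:
        raise DescriptorError("no canonical residues in sequence")
    atp = carbon = nitrogen = sulphur = mass = 0.0
    for c in canonical:
        atp += atp_table[c]
        fC, _fH, fN, _fO, fS = RESIDUE_FORMULA[c]
        carbon += fC
        nitrogen += fN
        sulphur += fS
        mass += RESIDUE_MASS[c]
    return ResidueProperties(
        mean_atp=atp / n, mean_C=carbon / n, mean_N=nitrogen / n,
        mean_S=sulphur / n, length=n, mol_weight=mass + WATER_MASS)
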