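"""Physicochemical property tables for the 20 canonical amino acids.

The impact score compares a reference and a substituted residue on four
properties: molecular weight (average free-amino-acid mass in Da),
hydrophobicity (Kyte-Doolittle index), polarity class and charge class.
Weights and the hydrophobicity scale come from biopython's curated data
tables; the polarity and charge partitions are the standard textbook
classes (histidine counted positive, cysteine polar).

Two constants are contractual for the scoring formulas and are therefore
fixed rather than recomputed from the table: the weight-difference
denominator ``WEIGHT_RANGE = 130`` (the Trp-Gly span, 204 - 75 Da, rounded)
and the hydrophobicity denominator ``HYDRO_RANGE = 9`` (the Ile-Arg span,
+4.5 - (-4.5)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

from Bio.SeqUtils import IUPACData
from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE

from .errors import UnsupportedResidue

__all__ = [
    "CANONICAL_RESIDUES",
    "WEIGHT_RANGE",
    "HYDRO_RANGE",
    "ResidueProperties",
    "AminoAcidPropertyTable",
    "DEFAULT_TABLE",
    "lookup",
    "three_to_one",
]

#: The 20 canonical one-letter residue codes.
CANONICAL_RESIDUES: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Fixed denominator of the normalized weight difference (Da).
WEIGHT_RANGE: float = 130.0

#: Fixed denominator of the normalized hydrophobicity difference.
HYDRO_RANGE: float = 9.0

PolarityClass = Literal["polar", "nonpolar"]
ChargeClass = Literal["positive", "negative", "neutral"]

# Standard partitions; every charged residue is also polar.
_POLAR: frozenset[str] = frozenset("STCYNQDEKRH")
_POSITIVE: frozenset[str] = frozenset("KRH")
_NEGATIVE: frozenset[str] = frozenset("DE")

_THREE_TO_ONE: Mapping[str, str] = {
    code3.upper(): code1 for code3, code1 in IUPACData.protein_letters_3to1.items()
}


@dataclass(frozen=True)
class ResidueProperties:
    """The four scored properties of one residue."""

    weight: float
    hydrophobicity: float
    polarity_class: PolarityClass
    charge_class: ChargeClass


class AminoAcidPropertyTable:
    """Property lookup over the 20 canonical residues.

    A custom ``weights`` or ``hydrophobicity`` mapping may be supplied
    (keyed by one-letter code, covering all 20 residues) to audit
    alternative scales; the scoring denominators stay fixed regardless.
    """

    def __init__(
        self,
        weights: Mapping[str, float] | None = None,
        hydrophobicity: Mapping[str, float] | None = None,
        polar: frozenset[str] = _POLAR,
        positive: frozenset[str] = _POSITIVE,
        negative: frozenset[str] = _NEGATIVE,
    ):
        weights = weights or IUPACData.protein_weights
        hydrophobicity = hydrophobicity or _KYTE_DOOLITTLE
        self._table: dict[str, ResidueProperties] = {}
        for aa in sorted(CANONICAL_RESIDUES):
            if aa not in weights or aa not in hydrophobicity:
                raise ValueError(f"property mapping missing residue {aa!r}")
            charge: ChargeClass = (
                "positive" if aa in positive
                else "negative" if aa in negative
                else "neutral"
            )
            self._table[aa] = ResidueProperties(
                weight=float(weights[aa]),
                hydrophobicity=float(hydrophobicity[aa]),
                polarity_class="polar" if aa in polar else "nonpolar",
                charge_class=charge,
            )

    def lookup(self, residue: str) -> ResidueProperties:
        """Return the properties of a canonical one-letter residue code."""
        props = self._table.get(residue.upper())
        if props is None:
            raise UnsupportedResidue(f"not a canonical residue: {residue!r}")
        return props

    def __getitem__(self, residue: str) -> ResidueProperties:
        return self.lookup(residue)

    def __iter__(self):
        return iter(self._table)

    def __len__(self) -> int:
        return len(self._table)

    def items(self):
        return self._table.items()

    def to_frame(self):
        """Export the table as a DataFrame (for documentation/audit)."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "residue": aa,
                    "weight_da": p.weight,
                    "kyte_doolittle": p.hydrophobicity,
                    "polarity": p.polarity_class,
                    "charge": p.charge_class,
                }
                for aa, p in self.items()
            ]
        ).set_index("residue")


#: Shared default table (biopython weights, Kyte-Doolittle hydrophobicity).
DEFAULT_TABLE = AminoAcidPropertyTable()


def lookup(residue: str) -> ResidueProperties:
    """Property lookup against the default table."""
    return DEFAULT_TABLE.lookup(residue)


def three_to_one(code3: str) -> str:
    """Map a three-letter residue code to its one-letter code.

    Case-insensitive; codes outside the canonical 20 (``Ter``, ``Xaa``,
    ``Sec``...) raise :class:`UnsupportedResidue`.
    """
    one = _THREE_TO_ONE.get(code3.upper())
    if one is None:
        raise UnsupportedResidue(f"not a canonical three-letter code: {code3!r}")
    return one
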