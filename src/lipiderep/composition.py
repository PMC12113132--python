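"""Sum-composition arithmetic and species-level shorthand names.

A lipid species is modelled as a class backbone plus one or two radyl
chains described at sum-composition level: total chain carbons, total
C=C double bonds and extra oxygens beyond the linkage itself.  The
mapping between composition and elemental formula is exact integer
arithmetic:

* acyl residue  C:D;O(x)  ->  C_c H_(2c-2d-2) O_(1+x)   (fatty acid - H2O)
* ether residue C:D;O(x)  ->  C_c H_(2c-2d)   O_(x)     (fatty alcohol - H2O)
* ceramide      C:D;O(x)  ->  C_c H_(2c-2d+1) N O_(x+1) (sphingoid + N-acyl)
* free fatty acid C:D;O(x) -> C_c H_(2c-2d)   O_(2+x)

Double bonds count carbon-carbon unsaturations only; hydroxy/oxo
substituents are carried by the ``;O`` suffix.  Both conventions are the
species-level (sum composition) shorthand of the LIPID MAPS nomenclature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

from .chem import ElementalFormula, FormulaError, parse_formula

__all__ = [
    "ACYL", "ETHER", "DIACYL", "ETHER_ACYL", "SPHINGOID", "FREE_FA",
    "BACKBONES", "ChainComposition", "acyl_residue", "ether_residue",
    "ketene", "carboxylate_anion", "neutral_formula", "ion_formula",
    "shorthand_name", "sum_composition_key",
]

# linkage profiles
ACYL = "acyl"
ETHER = "ether"
DIACYL = "diacyl"
ETHER_ACYL = "ether-acyl"
SPHINGOID = "sphingoid-pair"
FREE_FA = "fa"

# chain bounds at species level (totals over all chains)
MIN_C, MAX_C = 10, 44
MAX_DB = 8
MAX_EXTRA_O = 4

#: Neutral headgroup+glycerol residue left after removing all radyl
#: chains (for IPC: the inositol-phosphate residue added to a ceramide).
BACKBONES: Dict[str, ElementalFormula] = {
    "GPI": parse_formula("C9H19O11P"),   # glycerophosphoinositol
    "GPG": parse_formula("C6H15O8P"),    # glycerophosphoglycerol
    "GPE": parse_formula("C5H14NO6P"),   # glycerophosphoethanolamine
    "GPA": parse_formula("C3H9O6P"),     # glycerophosphoric acid
    "cGPA": parse_formula("C3H7O5P"),    # cyclic glycerophosphate
    "GPS": parse_formula("C6H14NO8P"),   # glycerophosphoserine
    "GPC": parse_formula("C8H20NO6P"),   # glycerophosphocholine
    "IPC": parse_formula("C6H11O8P"),    # inositol phosphate - H2O
}

_LYSO_PREFIX = {"GPI": "LPI", "GPG": "LPG", "GPE": "LPE", "GPA": "LPA",
                "cGPA": "CPA", "GPS": "LPS", "GPC": "LPC"}
_TWO_CHAIN_PREFIX = {"GPI": "PI"}

_H = parse_formula("H")


def acyl_residue(c: int, d: int, o: int = 0) -> ElementalFormula:
    """Esterified fatty-acyl residue (fatty acid minus water)."""
    return ElementalFormula({"C": c, "H": 2 * c - 2 * d - 2, "O": 1 + o})


def ether_residue(c: int, d: int, o: int = 0) -> ElementalFormula:
    """O-alkyl/alkenyl residue (fatty alcohol minus water)."""
    return ElementalFormula({"C": c, "H": 2 * c - 2 * d, "O": o})


#: The neutral lost when an acyl chain leaves as a ketene (R-CH=C=O) has
#: the same element counts as the esterified residue itself.
ketene = acyl_residue


def carboxylate_anion(c: int, d: int, o: int = 0) -> ElementalFormula:
    """Fatty carboxylate anion formula (as printed, charge carriers included)."""
    return ElementalFormula({"C": c, "H": 2 * c - 2 * d - 1, "O": 2 + o})


@dataclass(frozen=True)
class ChainComposition:
    """Species-level chain composition: totals over all radyl chains.

    ``split`` optionally resolves the totals into (chain1, chain2)
    triples when a chain-release fragment pinned one chain; for the
    sphingoid pair chain1 is the long-chain base, chain2 the N-acyl.
    """

    carbons: int
    double_bonds: int
    extra_oxygens: int = 0
    linkage: str = ACYL
    split: Optional[Tuple[Tuple[int, int, int], Tuple[int, int, int]]] = None

    def __post_init__(self) -> None:
        if self.linkage not in (ACYL, ETHER, DIACYL, ETHER_ACYL, SPHINGOID, FREE_FA):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if not (MIN_C <= self.carbons <= MAX_C):
            raise ValueError(f"total chain carbons {self.carbons} outside "
                             f"[{MIN_C}, {MAX_C}]")
        if not (0 <= self.double_bonds <= MAX_DB):
            raise ValueError(f"double bonds {self.double_bonds} outside [0, {MAX_DB}]")
        if not (0 <= self.extra_oxygens <= MAX_EXTRA_O):
            raise ValueError(f"extra oxygens {self.extra_oxygens} outside "
                             f"[0, {MAX_EXTRA_O}]")
        if self.split is not None:
            (c1, d1, o1), (c2, d2, o2) = self.split
            if (c1 + c2, d1 + d2, o1 + o2) != (self.carbons, self.double_bonds,
                                               self.extra_oxygens):
                raise ValueError("chain split does not add up to the totals")

    @property
    def n_chains(self) -> int:
        return 2 if self.linkage in (DIACYL, ETHER_ACYL, SPHINGOID) else 1


def chains_formula(comp: ChainComposition) -> ElementalFormula:
    """Combined elemental contribution of all radyl chains."""
    c, d, o = comp.carbons, comp.double_bonds, comp.extra_oxygens
    if comp.linkage == ACYL:
        return acyl_residue(c, d, o)
    if comp.linkage == ETHER:
        return ether_residue(c, d, o)
    if comp.linkage == DIACYL:
        # two esterified residues: sum formula loses two waters
        return ElementalFormula({"C": c, "H": 2 * c - 2 * d - 4, "O": 2 + o})
    if comp.linkage == ETHER_ACYL:
        return ElementalFormula({"C": c, "H": 2 * c - 2 * d - 2, "O": 1 + o})
    if comp.linkage == SPHINGOID:
        # ceramide: sphingoid base + amide-linked acyl
        return ElementalFormula({"C": c, "H": 2 * c - 2 * d + 1, "N": 1, "O": o + 1})
    if comp.linkage == FREE_FA:
        return ElementalFormula({"C": c, "H": 2 * c - 2 * d, "O": 2 + o})
    raise ValueError(comp.linkage)


def neutral_formula(class_id: str, comp: ChainComposition) -> ElementalFormula:
    """Elemental formula of the neutral lipid species."""
    if class_id == "PG":
        if comp.linkage != FREE_FA:
            raise ValueError("prostaglandin-type species are free fatty acids")
        return chains_formula(comp)
    if class_id not in BACKBONES:
        raise ValueError(f"unknown lipid class {class_id!r}")
    if class_id == "IPC" and comp.linkage != SPHINGOID:
        raise ValueError("IPC requires a sphingoid-pair composition")
    return BACKBONES[class_id] + chains_formula(comp)


def ion_formula(class_id: str, comp: ChainComposition, polarity: str) -> ElementalFormula:
    """Formula of the [M+H]+ or [M-H]- ion, charge carriers included."""
    neutral = neutral_formula(class_id, comp)
    if polarity == "positive":
        return neutral + _H
    if polarity == "negative":
        try:
            return neutral - _H
        except FormulaError as exc:  # pragma: no cover - no H-free lipids exist
            raise ValueError(f"cannot deprotonate {neutral}") from exc
    raise ValueError(f"polarity must be positive/negative, got {polarity!r}")


def _o_suffix(o: int) -> str:
    return "" if o == 0 else (";O" if o == 1 else f";O{o}")


def shorthand_name(class_id: str, comp: ChainComposition) -> str:
    """Species-level shorthand, e.g. ``LPI 18:0``, ``PI O-18:0/5:1;O2``,
    ``IPC (d18:1/16:0)``, ``FA 20:4;O3``.

    Two-chain species print the resolved split when one is known,
    otherwise the summed composition.  A sphingoid pair with two extra
    oxygens prints the classic ``d`` (dihydroxy base) notation.
    """
    c, d, o = comp.carbons, comp.double_bonds, comp.extra_oxygens
    if class_id == "PG":
        return f"FA {c}:{d}{_o_suffix(o)}"
    if class_id == "IPC":
        if comp.split is not None and o == 2:
            (c1, d1, _), (c2, d2, o2) = comp.split
            return f"IPC (d{c1}:{d1}/{c2}:{d2}{_o_suffix(o2)})"
        return f"IPC {c}:{d}{_o_suffix(o)}"
    if comp.linkage in (ACYL, ETHER):
        prefix = _LYSO_PREFIX[class_id]
        ether_mark = "O-" if comp.linkage == ETHER else ""
        return f"{prefix} {ether_mark}{c}:{d}{_o_suffix(o)}"
    prefix = _TWO_CHAIN_PREFIX.get(class_id, class_id)
    ether_mark = "O-" if comp.linkage == ETHER_ACYL else ""
    if comp.split is not None:
        (c1, d1, o1), (c2, d2, o2) = comp.split
        return (f"{prefix} {ether_mark}{c1}:{d1}{_o_suffix(o1)}"
                f"/{c2}:{d2}{_o_suffix(o2)}")
    return f"{prefix} {ether_mark}{c}:{d}{_o_suffix(o)}"


def sum_composition_key(class_id: str, comp: ChainComposition) -> Tuple[str, int, int, int]:
    """Canonical species-level identity, ignoring chain-split detail.

    Two annotations agree at species level when these keys are equal;
    positional or sphingoid/acyl-split detail is deliberately dropped.
    """
    return (class_id, comp.carbons, comp.double_bonds, comp.extra_oxygens)
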