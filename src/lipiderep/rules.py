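"""Loading and validation of the diagnostic-ion rulebook.

The built-in rulebook (``data/rules.yaml``) encodes, per lipid class and
ionisation polarity, the diagnostic fragment ions and neutral losses
that identify the class in an MS² spectrum, the class backbone, the
chain-linkage profiles the class may adopt, and the neutral losses whose
complementary fragment carries the radyl chain.  Users can extend or
replace it with :func:`load_rules`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import yaml

from .chem import ElementalFormula, parse_formula
from .composition import BACKBONES, FREE_FA

__all__ = ["RuleItem", "LipidClassRule", "AnnotationParams",
           "builtin_rules", "load_rules", "CLASS_PRIORITY",
           "CHEMICAL_CLASS", "chemical_class"]

REQUIRED = "required"
SUPPORTING = "supporting"

#: Deterministic tie-break order when several classes score equally.
CLASS_PRIORITY: Tuple[str, ...] = (
    "GPI", "IPC", "GPG", "GPE", "GPS", "GPC", "GPA", "cGPA", "PG")

#: Reporting-level chemical classes: cyclic glycerophosphates count
#: within the glycerophosphate (GP) family, giving eight classes overall.
CHEMICAL_CLASS: Dict[str, str] = {
    "GPI": "GPI", "GPG": "GPG", "GPE": "GPE", "GPS": "GPS", "GPC": "GPC",
    "GPA": "GP", "cGPA": "GP", "IPC": "IPC", "PG": "PG"}


def chemical_class(class_id: str) -> str:
    """Reporting-level class for a rulebook class id."""
    return CHEMICAL_CLASS.get(class_id, class_id)


@dataclass(frozen=True)
class RuleItem:
    """One diagnostic entry: a fragment-ion formula or a neutral loss."""

    kind: str                       # "ion" | "loss"
    formula: ElementalFormula
    role: str                       # "required" | "supporting"
    reference_mz: Optional[float] = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("ion", "loss"):
            raise ValueError(f"rule item kind must be ion/loss, got {self.kind!r}")
        if self.role not in (REQUIRED, SUPPORTING):
            raise ValueError(f"rule item role must be required/supporting, "
                             f"got {self.role!r}")


@dataclass(frozen=True)
class LipidClassRule:
    """Rulebook entry for one lipid class in one polarity."""

    class_id: str
    polarity: str
    adduct: str
    backbone: Optional[ElementalFormula]
    linkages: Tuple[str, ...]
    items: Tuple[RuleItem, ...]
    chain_release_losses: Tuple[ElementalFormula, ...]
    min_required: int = 1
    min_supporting: int = 0

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"bad polarity {self.polarity!r}")
        if self.min_required < 1:
            raise ValueError("min_required must be >= 1")
        n_req = sum(1 for i in self.items if i.role == REQUIRED)
        if n_req < self.min_required:
            raise ValueError(f"rule {self.class_id}/{self.polarity} declares "
                             f"min_required={self.min_required} but only "
                             f"{n_req} required items")

    @property
    def required_items(self) -> List[RuleItem]:
        return [i for i in self.items if i.role == REQUIRED]

    @property
    def supporting_items(self) -> List[RuleItem]:
        return [i for i in self.items if i.role == SUPPORTING]


@dataclass(frozen=True)
class AnnotationParams:
    """Matching tolerances and search bounds for the annotator.

    Fragment matching accepts the larger of an absolute and a relative
    window (printed fragment values deviate by up to ~2 mDa at low m/z);
    precursor-formula assignment is a strict ppm criterion.
    """

    fragment_tol_da: float = 0.005
    fragment_tol_ppm: float = 10.0
    precursor_tol_ppm: float = 5.0
    min_chain_c: int = 10
    max_chain_c: int = 44
    max_double_bonds: int = 8
    max_extra_oxygens: int = 4
    class_priority: Tuple[str, ...] = CLASS_PRIORITY

    def __post_init__(self) -> None:
        if min(self.fragment_tol_da, self.fragment_tol_ppm,
               self.precursor_tol_ppm) <= 0:
            raise ValueError("tolerances must be positive")

    def fragment_window(self, mz: float) -> float:
        """Absolute matching window at a given m/z."""
        return max(self.fragment_tol_da, self.fragment_tol_ppm * 1e-6 * mz)


def _parse_items(entry: dict) -> List[RuleItem]:
    items: List[RuleItem] = []
    for kind, key in (("ion", "diagnostic_ions"), ("loss", "neutral_losses")):
        for raw in entry.get(key) or []:
            items.append(RuleItem(
                kind=kind,
                formula=parse_formula(raw["formula"]),
                role=raw.get("role", SUPPORTING),
                reference_mz=raw.get("reference_mz"),
                note=raw.get("note", "")))
    return items


def load_rules(source: Union[str, Path]) -> List[LipidClassRule]:
    """Load a rulebook from a YAML file (see ``data/rules.yaml`` for the schema)."""
    data = yaml.safe_load(Path(source).read_text())
    return _rules_from_dict(data)


def _rules_from_dict(data: dict) -> List[LipidClassRule]:
    rules: List[LipidClassRule] = []
    seen = set()
    for entry in data["classes"]:
        key = (entry["class_id"], entry["polarity"])
        if key in seen:
            raise ValueError(f"duplicate rule for {key}")
        seen.add(key)
        backbone_txt = entry.get("backbone") or ""
        backbone = parse_formula(backbone_txt) if backbone_txt else None
        linkages = tuple(entry.get("linkages") or ())
        if backbone is None and linkages != (FREE_FA,):
            raise ValueError(f"rule {key}: only free-fatty-acid classes may "
                             f"omit a backbone")
        rules.append(LipidClassRule(
            class_id=entry["class_id"],
            polarity=entry["polarity"],
            adduct=entry.get("adduct", ""),
            backbone=backbone,
            linkages=linkages,
            items=tuple(_parse_items(entry)),
            chain_release_losses=tuple(
                parse_formula(f) for f in entry.get("chain_release_losses") or ()),
            min_required=int(entry.get("min_required", 1)),
            min_supporting=int(entry.get("min_supporting", 0)),
        ))
    return rules


def builtin_rules() -> List[LipidClassRule]:
    """The built-in rulebook: nine class ids across both polarities."""
    text = resources.files("lipiderep").joinpath("data/rules.yaml").read_text()
    return _rules_from_dict(yaml.safe_load(text))


def rules_by_key(rules: List[LipidClassRule]) -> Dict[Tuple[str, str], LipidClassRule]:
    return {(r.class_id, r.polarity): r for r in rules}
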