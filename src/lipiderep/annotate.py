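"""Rule-based lipid-class annotation of MS² spectra.

The dereplication logic proceeds in four stages, mirroring how a
spectroscopist reads a product-ion spectrum:

1. **Class detection** — match every diagnostic fragment ion and
   neutral loss of every class rulebook entry against the peak list; a
   class is a candidate when enough *required* items match.
2. **Precursor formula assignment** — enumerate sum compositions over
   the class template (backbone + chains within bounds) and keep ion
   formulas within the precursor ppm tolerance.
3. **Chain inference** — look for chain-release fragments (the
   complement of a headgroup loss carries the radyl chain); these
   confirm a composition, resolve two-chain splits and the
   sphingoid/N-acyl split, and raise the confidence from ``class-only``
   to ``species``.
4. **Shorthand naming** — deterministic species-level grammar.

Mass coincidences are broken deterministically: candidates confirmed by
chain evidence outrank unconfirmed ones, then smaller |ppm|, then a
fixed linkage preference (acyl before ether), then fewer extra oxygens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

from .chem import (ElementalFormula, FormulaError, IonSpecies, ion_mz,
                   monoisotopic_mass, ppm_error)
from .composition import (ACYL, DIACYL, ETHER, ETHER_ACYL, FREE_FA, SPHINGOID,
                          ChainComposition, ketene, ion_formula,
                          shorthand_name, sum_composition_key)
from .rules import (AnnotationParams, CLASS_PRIORITY, LipidClassRule,
                    builtin_rules)
from .spectra import Spectrum

__all__ = [
    "Evidence", "ClassCandidate", "FormulaCandidate", "LipidAnnotation",
    "detect_class", "infer_precursor_formula", "infer_chain",
    "annotate_spectrum",
]

_LINKAGE_PREFERENCE = {ACYL: 0, DIACYL: 1, ETHER: 2, ETHER_ACYL: 3,
                       SPHINGOID: 4, FREE_FA: 5}


@dataclass(frozen=True)
class Evidence:
    """One matched rule item or chain fragment."""

    description: str
    expected_mz: float
    matched_mz: float
    ppm: float
    intensity: float


@dataclass(frozen=True)
class ClassCandidate:
    rule: LipidClassRule
    n_required: int
    n_supporting: int
    matched_intensity: float
    evidence: Tuple[Evidence, ...]

    @property
    def class_id(self) -> str:
        return self.rule.class_id


@dataclass(frozen=True)
class FormulaCandidate:
    """One (composition, ion formula) explanation of the precursor m/z."""

    composition: ChainComposition
    ion: ElementalFormula
    mz: float
    ppm: float


@dataclass(frozen=True)
class LipidAnnotation:
    feature_id: str
    class_id: str
    shorthand: str
    composition: ChainComposition
    precursor_ion_formula: ElementalFormula
    precursor_ppm: float
    evidence: Tuple[Evidence, ...]
    confidence: str                       # "species" | "class-only"

    @property
    def sum_composition(self) -> Tuple[str, int, int, int]:
        return sum_composition_key(self.class_id, self.composition)

    @property
    def chemical_class(self) -> str:
        """Reporting-level class (cyclic GPA folds into the GP family)."""
        from .rules import chemical_class
        return chemical_class(self.class_id)


def _charge(polarity: str) -> int:
    return +1 if polarity == "positive" else -1


def _find_peak(spectrum: Spectrum, target: float, window: float):
    """Closest peak within ``window`` Da of ``target``, or None."""
    best = None
    for p in spectrum.peaks:          # peak lists are short; linear scan is fine
        d = abs(p.mz - target)
        if d <= window and (best is None or d < abs(best.mz - target)):
            best = p
    return best


def detect_class(spectrum: Spectrum,
                 rules: Optional[Sequence[LipidClassRule]] = None,
                 params: Optional[AnnotationParams] = None) -> List[ClassCandidate]:
    """Rank lipid-class candidates for one spectrum by diagnostic evidence.

    A class qualifies when at least ``min_required`` of its required
    items match (a fragment ion at its theoretical m/z, or a peak at
    precursor minus a neutral loss, within the fragment tolerance).
    Candidates are ordered by (required matched, supporting matched,
    summed matched intensity) with the fixed class priority as the final
    tie-break.  An empty list is a valid outcome.
    """
    rules = list(rules) if rules is not None else builtin_rules()
    params = params or AnnotationParams()
    charge = _charge(spectrum.polarity)
    out: List[ClassCandidate] = []
    for rule in rules:
        if rule.polarity != spectrum.polarity:
            continue
        n_req = n_sup = 0
        intensity = 0.0
        evidence: List[Evidence] = []
        for item in rule.items:
            if item.kind == "ion":
                target = ion_mz(IonSpecies(item.formula, charge))
                desc = f"ion {item.formula}"
            else:
                target = spectrum.precursor_mz - monoisotopic_mass(item.formula)
                desc = f"loss {item.formula}"
            if target <= 0:
                continue
            peak = _find_peak(spectrum, target, params.fragment_window(target))
            if peak is None or peak.intensity <= 0:
                continue
            if item.role == "required":
                n_req += 1
            else:
                n_sup += 1
            intensity += peak.intensity
            evidence.append(Evidence(desc, target, peak.mz,
                                     ppm_error(peak.mz, target), peak.intensity))
        if n_req >= rule.min_required and n_sup >= rule.min_supporting:
            out.append(ClassCandidate(rule, n_req, n_sup, intensity,
                                      tuple(evidence)))
    prio = {c: i for i, c in enumerate(params.class_priority)}
    out.sort(key=lambda c: (-c.n_required, -c.n_supporting,
                            -c.matched_intensity, prio.get(c.class_id, 99)))
    return out


# ---------------------------------------------------------------------------
# Precursor formula enumeration (cached per class/polarity/bounds)

@lru_cache(maxsize=None)
def _enumerate_species(class_id: str, polarity: str, linkages: Tuple[str, ...],
                       bounds: Tuple[int, int, int, int]
                       ) -> Tuple[Tuple[float, str, int, int, int, str], ...]:
    """All (mz, hill, c, d, o, linkage) species ions for one class/polarity."""
    min_c, max_c, max_db, max_o = bounds
    charge = _charge(polarity)
    rows = []
    for linkage in linkages:
        for c in range(min_c, max_c + 1):
            for d in range(0, max_db + 1):
                for o in range(0, max_o + 1):
                    try:
                        comp = ChainComposition(c, d, o, linkage)
                        f = ion_formula(class_id, comp, polarity)
                    except (ValueError, FormulaError):
                        continue
                    rows.append((ion_mz(IonSpecies(f, charge)), f.hill(),
                                 c, d, o, linkage))
    return tuple(rows)


def infer_precursor_formula(precursor_mz: float, polarity: str, class_id: str,
                            params: Optional[AnnotationParams] = None,
                            rule: Optional[LipidClassRule] = None,
                            ) -> List[FormulaCandidate]:
    """Enumerate class-template compositions whose ion matches the precursor.

    Candidates within ``precursor_tol_ppm`` are returned sorted by
    |ppm|, then linkage preference (acyl first), then fewer extra
    oxygens, then fewer double bonds — a deterministic order that puts
    the chemically conventional reading first among exact-mass ties.
    """
    params = params or AnnotationParams()
    if rule is None:
        match = [r for r in builtin_rules()
                 if r.class_id == class_id and r.polarity == polarity]
        if not match:
            raise ValueError(f"no rule for class {class_id!r} / {polarity}")
        rule = match[0]
    bounds = (params.min_chain_c, params.max_chain_c,
              params.max_double_bonds, params.max_extra_oxygens)
    out = []
    for mz, hill, c, d, o, linkage in _enumerate_species(
            class_id, polarity, tuple(rule.linkages), bounds):
        ppm = ppm_error(precursor_mz, mz)
        if abs(ppm) <= params.precursor_tol_ppm:
            comp = ChainComposition(c, d, o, linkage)
            out.append(FormulaCandidate(comp, ion_formula(class_id, comp, polarity),
                                        mz, ppm))
    out.sort(key=lambda fc: (abs(fc.ppm),
                             _LINKAGE_PREFERENCE[fc.composition.linkage],
                             fc.composition.extra_oxygens,
                             fc.composition.double_bonds))
    return out


# ---------------------------------------------------------------------------
# Chain inference

@dataclass(frozen=True)
class ChainInference:
    composition: ChainComposition        # possibly with a resolved split
    confirmed: bool
    evidence: Tuple[Evidence, ...]


def _loss_peak(spectrum: Spectrum, prec_ion: ElementalFormula,
               loss: ElementalFormula, charge: int,
               params: AnnotationParams, desc: str) -> Optional[Evidence]:
    """Evidence for a fragment at (precursor ion - neutral loss), if present."""
    if not prec_ion.contains(loss):
        return None
    frag = prec_ion - loss
    if not frag:
        return None
    target = ion_mz(IonSpecies(frag, charge))
    peak = _find_peak(spectrum, target, params.fragment_window(target))
    if peak is None:
        return None
    return Evidence(desc, target, peak.mz, ppm_error(peak.mz, target),
                    peak.intensity)


def infer_chain(spectrum: Spectrum, class_id: str,
                candidate: FormulaCandidate,
                rule: LipidClassRule,
                params: Optional[AnnotationParams] = None) -> ChainInference:
    """Chain composition from chain-release fragments, with fallback.

    Single-chain species: any of the class's chain-release losses whose
    complementary fragment is present confirms the composition.
    Two-chain species: a peak at precursor minus the ketene of the
    modified chain pins the split (searched over the unmodified chain's
    carbons/double bonds).  Sphingoid pairs (positive mode): a peak at
    precursor minus (water + inositol monophosphate + N-acyl ketene)
    resolves the base/N-acyl split.  With no release fragment the
    composition falls back to precursor arithmetic alone.
    """
    params = params or AnnotationParams()
    comp = candidate.composition
    charge = _charge(spectrum.polarity)
    c, d, o = comp.carbons, comp.double_bonds, comp.extra_oxygens

    if comp.linkage in (DIACYL, ETHER_ACYL):
        # pin the modified (oxidised) chain by its ketene loss
        for c1 in range(min(c - 2, params.max_chain_c),
                        params.min_chain_c - 1, -1):
            for d1 in range(0, min(d, 2) + 1):
                c2, d2 = c - c1, d - d1
                if c2 < 2 or d2 < 0 or 2 * c2 - 2 * d2 - 2 < 0:
                    continue
                ev = _loss_peak(spectrum, candidate.ion, ketene(c2, d2, o),
                                charge, params,
                                f"ketene loss {c2}:{d2};O{o}")
                if ev is not None:
                    split = ((c1, d1, 0), (c2, d2, o))
                    return ChainInference(
                        ChainComposition(c, d, o, comp.linkage, split),
                        True, (ev,))
        return ChainInference(comp, False, ())

    if comp.linkage == SPHINGOID and spectrum.polarity == "positive":
        # sphingoid ion: [M+H - H2O - C6H13O9P - N-acyl ketene]+
        combined = ElementalFormula({"C": 6, "H": 15, "O": 10, "P": 1})
        for c2 in range(min(c - 14, 30), 9, -1):
            for d2 in range(0, 3):
                c1, d1 = c - c2, d - d2
                if c1 < 12 or d1 < 0:
                    continue
                ev = _loss_peak(spectrum, candidate.ion,
                                combined + ketene(c2, d2, 0), charge, params,
                                f"sphingoid ion (N-acyl {c2}:{d2})")
                if ev is not None:
                    split = ((c1, d1, o), (c2, d2, 0))
                    return ChainInference(
                        ChainComposition(c, d, o, SPHINGOID, split),
                        True, (ev,))
        return ChainInference(comp, False, ())

    if comp.linkage in (SPHINGOID, FREE_FA):
        # negative-mode IPC and free fatty acids have no chain-release
        # fragment in the rulebook; composition is fixed by the formula
        return ChainInference(comp, False, ())

    # single-chain glycerophospholipid
    for loss in rule.chain_release_losses:
        ev = _loss_peak(spectrum, candidate.ion, loss, charge, params,
                        f"chain-release loss {loss}")
        if ev is not None:
            return ChainInference(comp, True, (ev,))
    return ChainInference(comp, False, ())


# ---------------------------------------------------------------------------
# Full annotation

def _is_linkage_ambiguous(candidate: FormulaCandidate,
                          all_candidates: Sequence[FormulaCandidate]) -> bool:
    """True when another linkage explains the identical ion formula."""
    return any(fc.ion == candidate.ion
               and fc.composition.linkage != candidate.composition.linkage
               for fc in all_candidates)


def annotate_spectrum(spectrum: Spectrum,
                      rules: Optional[Sequence[LipidClassRule]] = None,
                      params: Optional[AnnotationParams] = None,
                      ) -> Optional[LipidAnnotation]:
    """Classify, assign a precursor formula, infer chains and name a spectrum.

    Class candidates are tried in evidence order; the first class for
    which a precursor formula fits within tolerance wins.  Among formula
    candidates, chain-confirmed ones outrank unconfirmed; confidence is
    ``species`` unless the composition is unconfirmed *and* another
    linkage explains the same ion formula, in which case it drops to
    ``class-only`` (the conventional acyl reading is still reported).
    Returns None when no class passes or no formula fits.
    """
    if spectrum.is_empty:
        return None
    params = params or AnnotationParams()
    rules = list(rules) if rules is not None else builtin_rules()
    for cand in detect_class(spectrum, rules, params):
        fcands = infer_precursor_formula(spectrum.precursor_mz,
                                         spectrum.polarity, cand.class_id,
                                         params, rule=cand.rule)
        if not fcands:
            continue
        scored = []
        for fc in fcands:
            inf = infer_chain(spectrum, cand.class_id, fc, cand.rule, params)
            scored.append((not inf.confirmed, abs(fc.ppm),
                           _LINKAGE_PREFERENCE[fc.composition.linkage],
                           fc.composition.extra_oxygens,
                           fc.composition.double_bonds, fc, inf))
        scored.sort(key=lambda t: t[:5])
        _, _, _, _, _, best, inf = scored[0]
        ambiguous = (not inf.confirmed
                     and _is_linkage_ambiguous(best, fcands))
        confidence = "class-only" if ambiguous else "species"
        assert abs(best.ppm) <= params.precursor_tol_ppm
        return LipidAnnotation(
            feature_id=spectrum.feature_id,
            class_id=cand.class_id,
            shorthand=shorthand_name(cand.class_id, inf.composition),
            composition=inf.composition,
            precursor_ion_formula=best.ion,
            precursor_ppm=best.ppm,
            evidence=cand.evidence + inf.evidence,
            confidence=confidence)
    return None
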