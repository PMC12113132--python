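"""Rule-table audit, class detection, formula/chain inference, naming."""

import pytest

from lipiderep.annotate import (annotate_spectrum, detect_class, infer_chain,
                                infer_precursor_formula)
from lipiderep.chem import IonSpecies, ion_mz, parse_formula, ppm_error
from lipiderep.composition import (ACYL, ETHER, FREE_FA, SPHINGOID,
                                   ChainComposition, shorthand_name)
from lipiderep.spectra import Peak, Spectrum
from lipiderep.synth import SimulationConfig, simulate_spectrum

# Every fragment m/z quoted in the fragmentation-rule description, with
# the class/polarity context it was quoted for.  kind "ion" entries are
# charged-fragment formulas; "loss" entries are neutral losses (no m/z
# quoted, presence in the rulebook is what is audited).
QUOTED_FRAGMENTS = [
    ("GPI", "positive", "ion", "C9H20O11P", 335.0738),
    ("GPI", "positive", "ion", "C6H14O9P", 261.0370),
    ("GPI", "positive", "loss", "C6H13O9P", None),
    ("GPI", "positive", "loss", "C9H19O11P", None),
    ("GPI", "negative", "ion", "C6H12O9P", 259.0224),
    ("GPI", "negative", "ion", "C9H18O11P", 333.0592),
    ("GPI", "negative", "ion", "C9H16O10P", 315.0487),
    ("GPI", "negative", "ion", "C3H8O6P", 171.0064),
    ("GPI", "negative", "ion", "C3H6O5P", 152.9958),
    ("GPI", "negative", "loss", "C9H17O10P", None),
    ("GPG", "positive", "ion", "C6H16O8P", 247.0577),
    ("GPG", "positive", "ion", "C3H10O6P", 173.0210),
    ("GPG", "positive", "loss", "C3H7O5P", None),
    ("GPG", "positive", "loss", "C3H6O2", None),
    ("GPG", "negative", "ion", "C6H14O8P", 245.0432),
    ("GPG", "negative", "ion", "C3H8O6P", 171.0064),
    ("GPG", "negative", "loss", "C6H13O7P", None),
    ("GPG", "negative", "loss", "C3H6O2", None),
    ("GPE", "positive", "loss", "C2H8NO4P", None),
    ("GPE", "positive", "loss", "C2H5N", None),
    ("GPE", "positive", "loss", "C2H7NO", None),
    ("GPE", "positive", "loss", "C3H9O6P", None),
    ("GPE", "negative", "loss", "C5H12NO5P", None),
    ("GPE", "negative", "ion", "C5H13NO6P", 214.0486),
    ("GPE", "negative", "ion", "C2H7NO4P", 140.0118),
    ("GPE", "negative", "ion", "C3H6O5P", 152.9958),
    ("GPA", "positive", "loss", "H3PO4", None),
    ("GPA", "positive", "ion", "C3H10O6P", 173.0210),
    ("GPA", "negative", "ion", "H2O4P", 96.9696),
    ("GPA", "negative", "ion", "C3H8O6P", 171.0064),
    ("GPA", "negative", "loss", "C3H7O5P", None),
    ("cGPA", "negative", "ion", "C3H6O5P", 152.9958),
    ("cGPA", "negative", "loss", "C3H5O4P", None),
    ("GPS", "positive", "ion", "C6H15NO8P", 260.0530),
    ("GPS", "positive", "ion", "C3H8NO3", 106.0499),
    ("GPS", "positive", "ion", "C3H6NO2", 88.0393),
    ("GPS", "positive", "loss", "C3H8NO6P", None),
    ("GPS", "positive", "loss", "C3H7NO3", None),
    ("GPS", "negative", "loss", "C3H5NO2", None),
    ("GPS", "negative", "loss", "C6H12NO7P", None),
    ("GPS", "negative", "ion", "C3H8O6P", 171.0064),
    ("GPC", "positive", "ion", "C5H15NO4P", 184.0733),
    ("GPC", "positive", "ion", "C5H14NO", 104.1070),
    ("GPC", "positive", "ion", "C8H21NO6P", 258.1101),
    ("GPC", "positive", "loss", "C5H14NO4P", None),
    ("IPC", "positive", "loss", "C6H15O10P", None),   # H2O + C6H13O9P
    ("IPC", "negative", "ion", "C6H12O9P", 259.0224),
    ("IPC", "negative", "ion", "C6H10O8P", 241.0119),
    ("IPC", "negative", "loss", "C6H10O5", None),
    ("PG", "negative", "loss", "H2O", None),
    ("PG", "negative", "loss", "CH2O3", None),        # H2O + CO2
]


def test_every_quoted_fragment_appears_in_exactly_one_rule_entry(rules):
    by_key = {(r.class_id, r.polarity): r for r in rules}
    for class_id, polarity, kind, formula_txt, quoted_mz in QUOTED_FRAGMENTS:
        rule = by_key[(class_id, polarity)]
        f = parse_formula(formula_txt)
        if kind == "ion":
            hits = [i for i in rule.items if i.kind == "ion" and i.formula == f]
        else:
            hits = [i for i in rule.items if i.kind == "loss" and i.formula == f]
            hits += [1 for g in rule.chain_release_losses if g == f
                     and not any(i.kind == "loss" and i.formula == f
                                 for i in rule.items)]
        assert len(hits) == 1, (class_id, polarity, kind, formula_txt)
        if quoted_mz is not None:
            charge = +1 if polarity == "positive" else -1
            theory = ion_mz(IonSpecies(f, charge))
            assert abs(ppm_error(quoted_mz, theory)) <= 5.0, \
                (formula_txt, quoted_mz, theory)


def template(name, polarity, specs_by_name, **config_kw):
    return simulate_spectrum(specs_by_name[name], polarity,
                             SimulationConfig(**config_kw))


# ---------------------------------------------------------------------------
# class detection

def test_lpi_negative_template_detected_as_gpi(specs_by_name, rules):
    s = template("LPI 18:0", "negative", specs_by_name)
    cands = detect_class(s, rules)
    assert cands and cands[0].class_id == "GPI"
    assert cands[0].n_required >= 2


def test_empty_spectrum_yields_no_candidates(rules):
    s = Spectrum("E", 500.0, "negative")
    assert detect_class(s, rules) == []
    assert annotate_spectrum(s, rules) is None


def test_ipc_outranks_gpi_despite_shared_inositol_phosphate(specs_by_name, rules):
    """IPC and GPI share the 259.0224/241.0119 anions; the IPC template's
    inositol-loss ions and the nitrogen-containing precursor settle it."""
    ipc = template("IPC (d18:1/16:0)", "negative", specs_by_name)
    cands = detect_class(ipc, rules)
    assert cands[0].class_id == "IPC"
    ann = annotate_spectrum(ipc, rules)
    assert ann.class_id == "IPC"
    assert ann.precursor_ion_formula["N"] == 1

    lpi = template("LPI 18:0", "negative", specs_by_name)
    ann2 = annotate_spectrum(lpi, rules)
    assert ann2.class_id == "GPI"
    assert ann2.precursor_ion_formula["N"] == 0


# ---------------------------------------------------------------------------
# precursor formula inference

def test_infer_formula_lpi_18_0():
    cands = infer_precursor_formula(601.3344, "positive", "GPI")
    assert cands
    top = cands[0]
    assert top.ion.hill() == "C27H54O12P"
    assert top.composition.linkage == ACYL
    assert (top.composition.carbons, top.composition.double_bonds) == (18, 0)


def test_infer_formula_ether_only_solution():
    # LPG O-14:0 [M+H]+ has no acyl solution within tolerance
    cands = infer_precursor_formula(443.2779, "positive", "GPG")
    assert cands
    assert cands[0].ion.hill() == "C20H44O8P"
    assert all(fc.composition.linkage == ETHER for fc in cands)


def test_infer_formula_prostaglandin():
    cands = infer_precursor_formula(351.2178, "negative", "PG")
    assert cands
    top = cands[0]
    assert top.ion.hill() == "C20H31O5"
    assert (top.composition.carbons, top.composition.double_bonds,
            top.composition.extra_oxygens) == (20, 4, 3)
    assert top.composition.linkage == FREE_FA


def test_infer_formula_respects_tolerance():
    assert infer_precursor_formula(601.40, "positive", "GPI") == []


# ---------------------------------------------------------------------------
# chain inference

def test_lps_chain_release_at_serine_loss(specs_by_name, rules, ann_params):
    s = template("LPS 18:0", "positive", specs_by_name)
    rule = next(r for r in rules
                if r.class_id == "GPS" and r.polarity == "positive")
    fc = infer_precursor_formula(s.precursor_mz, "positive", "GPS",
                                 ann_params, rule)[0]
    inf = infer_chain(s, "GPS", fc, rule, ann_params)
    assert inf.confirmed
    # the serine-loss fragment sits within 5 ppm of 421.2714
    target = ion_mz(IonSpecies(parse_formula("C24H49NO9P")
                               - parse_formula("C3H7NO3"), +1))
    assert abs(ppm_error(421.2714, target)) <= 5.0
    assert any(abs(p.mz - target) < 0.005 for p in s.peaks)


def test_precursor_only_spectrum_falls_back_to_arithmetic(rules):
    """No chain fragments: composition comes from mass arithmetic and the
    confidence drops to class-only when acyl and ether readings tie."""
    prec = 599.3202          # LPI 18:0 [M-H]-
    peaks = [Peak(ion_mz(IonSpecies(parse_formula(f), -1)), 50.0)
             for f in ("C6H12O9P", "C6H10O8P")]
    s = Spectrum("X", prec, "negative", peaks=tuple(peaks))
    ann = annotate_spectrum(s, rules)
    assert ann is not None and ann.class_id == "GPI"
    assert ann.sum_composition == ("GPI", 18, 0, 0)
    assert ann.confidence == "class-only"


def test_full_template_reaches_species_confidence(specs_by_name, rules):
    s = template("LPI 18:0", "negative", specs_by_name)
    ann = annotate_spectrum(s, rules)
    assert ann.confidence == "species"
    assert ann.shorthand == "LPI 18:0"


# ---------------------------------------------------------------------------
# shorthand naming

@pytest.mark.parametrize("class_id, comp, expected", [
    ("GPI", ChainComposition(18, 0, 0, ACYL), "LPI 18:0"),
    ("GPG", ChainComposition(14, 0, 0, ETHER), "LPG O-14:0"),
    ("PG", ChainComposition(20, 4, 3, FREE_FA), "FA 20:4;O3"),
    ("GPG", ChainComposition(18, 1, 1, ACYL), "LPG 18:1;O"),
    ("GPC", ChainComposition(11, 1, 1, ACYL), "LPC 11:1;O"),
    ("cGPA", ChainComposition(16, 0, 0, ACYL), "CPA 16:0"),
    ("IPC", ChainComposition(34, 3, 2, SPHINGOID), "IPC 34:3;O2"),
    ("IPC", ChainComposition(34, 1, 2, SPHINGOID,
                             ((18, 1, 2), (16, 0, 0))), "IPC (d18:1/16:0)"),
    ("GPI", ChainComposition(24, 1, 2, "diacyl",
                             ((18, 0, 0), (6, 1, 2))), "PI 18:0/6:1;O2"),
    ("GPI", ChainComposition(23, 1, 2, "ether-acyl",
                             ((18, 0, 0), (5, 1, 2))), "PI O-18:0/5:1;O2"),
])
def test_shorthand_grammar(class_id, comp, expected):
    assert shorthand_name(class_id, comp) == expected


# ---------------------------------------------------------------------------
# end-to-end annotation behaviour

def test_lpc_16_0_annotates_as_gpc(specs_by_name, rules):
    s = template("LPC 16:0", "positive", specs_by_name)
    ann = annotate_spectrum(s, rules)
    assert ann.class_id == "GPC" and ann.shorthand == "LPC 16:0"


def test_pure_noise_spectrum_annotates_to_none(rules):
    import numpy as np
    rng = np.random.default_rng(5)
    peaks = tuple(Peak(float(m), float(i)) for m, i in
                  zip(sorted(rng.uniform(100, 500, 20)),
                      rng.uniform(1, 100, 20)))
    s = Spectrum("noise", 512.345, "negative", peaks=peaks)
    assert annotate_spectrum(s, rules) is None


def test_annotation_survives_seeded_noise(specs_by_name, rules):
    clean = template("LPE 16:1", "negative", specs_by_name)
    noisy = template("LPE 16:1", "negative", specs_by_name,
                     seed=3, n_noise_peaks=10, noise_rel_intensity_max=0.05,
                     mz_jitter_sd=0.001)
    a, b = annotate_spectrum(clean, rules), annotate_spectrum(noisy, rules)
    assert a.sum_composition == b.sum_composition == ("GPE", 16, 1, 0)


def test_no_annotation_exceeds_precursor_tolerance(ref_fixture, rules,
                                                   ann_params):
    spectra, _ = ref_fixture
    for s in spectra:
        ann = annotate_spectrum(s, rules, ann_params)
        assert ann is not None
        assert abs(ann.precursor_ppm) <= ann_params.precursor_tol_ppm
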