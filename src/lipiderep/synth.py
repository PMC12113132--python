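"""In-silico MS² spectra and feature tables for pipeline testing.

This module inverts the interpretation step: starting from a lipid
species (class + sum composition) it emits the product-ion spectrum the
class fragmentation template predicts — every diagnostic ion and
neutral loss of the rulebook, at theoretical m/z, with tiered relative
intensities (dominant 100 / diagnostic 60 / supporting 20-40 / minor
10) — optionally degraded with Gaussian m/z jitter, multiplicative
intensity noise and uniform-random noise peaks.

``reference_species`` is a curated table of the 55 sea-pen lipid
species used throughout the test-suite: lysophospholipids of seven
glycerophospholipid classes, oxidised di-radyl phosphoinositols,
ceramide phosphoinositols and prostaglandin-type oxylipins, each with
its reported retention time and [M+H]+/[M-H]- ion m/z.  Three table
entries carry formula misprints in the source material (the reported
m/z matches the composition-derived formula, the reported formula text
does not); both readings are kept so audits can treat them explicitly.

Extract abundance profiles are synthetic: phospholipids and IPCs are
weighted to the hexane extract (0.70/0.20/0.10 over hexane/CHCl3/MeOH)
and prostaglandins to the chloroform extract (0.15/0.70/0.15), a
qualitative encoding of the observed distribution, not measured data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .chem import ElementalFormula, IonSpecies, ion_mz, parse_formula
from .composition import (ACYL, DIACYL, ETHER, ETHER_ACYL, FREE_FA, SPHINGOID,
                          ChainComposition, carboxylate_anion, ion_formula,
                          ketene)
from .spectra import (FeatureRecord, Peak, Spectrum, write_feature_table,
                      write_mgf)

__all__ = [
    "EXTRACTS", "SpeciesSpec", "SimulationConfig", "ReferenceIon",
    "fragment_template", "simulate_spectrum", "reference_species",
    "reference_fixture", "simulate_dataset", "reference_printed_ions",
    "FORMULA_MISPRINTS",
]

EXTRACTS: Tuple[str, ...] = ("hexane", "CHCl3", "MeOH")

_PHOSPHOLIPID_PROFILE = {"hexane": 0.70, "CHCl3": 0.20, "MeOH": 0.10}
_PROSTAGLANDIN_PROFILE = {"hexane": 0.15, "CHCl3": 0.70, "MeOH": 0.15}


@dataclass(frozen=True)
class SpeciesSpec:
    """One lipid species to simulate: identity, RT, extract profile."""

    name: str
    class_id: str
    composition: ChainComposition
    polarities: Tuple[str, ...]
    retention_time: float
    extract_profile: Mapping[str, float] = field(
        default_factory=lambda: dict(_PHOSPHOLIPID_PROFILE))
    total_area: float = 1e6

    def __post_init__(self) -> None:
        if not self.polarities:
            raise ValueError(f"species {self.name!r} lists no polarity")
        total = sum(self.extract_profile.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"extract profile of {self.name!r} sums to {total}")
        if self.total_area <= 0:
            raise ValueError("total_area must be positive")
        object.__setattr__(self, "extract_profile", dict(self.extract_profile))


@dataclass(frozen=True)
class SimulationConfig:
    """Noise model for simulated spectra; defaults are noise-free.

    The same (config, species, polarity) always yields byte-identical
    output: per-spectrum RNG streams are derived from the seed and a
    CRC32 of the species name, never from Python's randomized hash.
    """

    seed: int = 0
    n_noise_peaks: int = 0
    noise_rel_intensity_max: float = 0.05
    mz_jitter_sd: float = 0.0
    intensity_sigma: float = 0.0          # lognormal sigma on tier intensities
    base_intensity: float = 1e4

    def __post_init__(self) -> None:
        if self.n_noise_peaks < 0 or self.mz_jitter_sd < 0 or self.intensity_sigma < 0:
            raise ValueError("noise parameters must be non-negative")
        if not 0.0 <= self.noise_rel_intensity_max < 1.0:
            raise ValueError("noise_rel_intensity_max must lie in [0, 1)")


# ---------------------------------------------------------------------------
# Fragmentation templates

_F = parse_formula


def fragment_template(class_id: str, polarity: str, comp: ChainComposition,
                      ) -> List[Tuple[str, ElementalFormula, float]]:
    """Template fragments for one class/polarity as (label, ion formula, tier).

    Every diagnostic ion and neutral loss of the class rulebook appears
    exactly once; relative tiers follow the qualitative intensity
    language of the source spectra (dominant head-group losses at 100).
    Raises ``ValueError`` for a class/polarity with no defined
    fragmentation chemistry.
    """
    prec = ion_formula(class_id, comp, polarity)
    out: List[Tuple[str, ElementalFormula, float]] = [("precursor", prec, 15.0)]

    def ion(label: str, text: str, tier: float) -> None:
        out.append((label, _F(text), tier))

    def loss(label: str, f: Union[str, ElementalFormula], tier: float) -> None:
        f = _F(f) if isinstance(f, str) else f
        if prec.contains(f) and (prec - f):
            out.append((label, prec - f, tier))

    key = (class_id, polarity)
    link = comp.linkage

    if key == ("GPI", "positive"):
        loss("-H2O", "H2O", 30)
        loss("-inositol phosphate", "C6H13O9P", 100)
        ion("glycerylphosphorylinositol", "C9H20O11P", 60)
        ion("glycerylphosphorylinositol -H2O", "C9H18O10P", 30)
        ion("phosphorylinositol", "C6H14O9P", 60)
        ion("phosphorylinositol -H2O", "C6H12O8P", 30)
        loss("-glycerylphosphorylinositol (chain)", "C9H19O11P", 40)
        loss("-H2O -anhydroinositol (chain)", "C6H12O6", 30)
    elif key == ("GPI", "negative"):
        ion("phosphorylinositol", "C6H12O9P", 60)
        ion("phosphorylinositol -H2O", "C6H10O8P", 40)
        loss("-H2O", "H2O", 10)
        if link == ACYL:
            ion("phosphorylinositol -2H2O", "C6H8O7P", 10)
            ion("glycerylphosphorylinositol (ketene loss)", "C9H18O11P", 60)
            ion("glycerylphosphorylinositol -H2O", "C9H16O10P", 30)
            ion("glycerol phosphate", "C3H8O6P", 30)
            ion("glycerol phosphate -H2O", "C3H6O5P", 20)
            loss("-glycerylphosphorylinositol (carboxylate)", "C9H17O10P", 100)
        elif link == ETHER:
            ion("glycerol phosphate", "C3H8O6P", 30)
            ion("glycerol phosphate -H2O", "C3H6O5P", 20)
        elif link in (DIACYL, ETHER_ACYL):
            if comp.split is None:
                raise ValueError(f"two-chain GPI template needs a chain split "
                                 f"({comp})")
            (_, _, _), (c2, d2, o2) = comp.split
            loss(f"-ketene {c2}:{d2};O{o2}", ketene(c2, d2, o2), 100)
            ion("glycerol phosphate", "C3H8O6P", 20)
            ion("glycerol phosphate -H2O", "C3H6O5P", 10)
            if link == DIACYL:
                c1, d1, _ = comp.split[0]
                out.append((f"carboxylate {c1}:{d1}",
                            carboxylate_anion(c1, d1), 50))
    elif key == ("GPG", "positive"):
        loss("-H2O", "H2O", 30)
        ion("glycerylphosphorylglycerol", "C6H16O8P", 60)
        ion("glycerylphosphorylglycerol -H2O", "C6H14O7P", 30)
        ion("glycerophosphoric acid", "C3H10O6P", 60)
        ion("glycerophosphoric acid -H2O", "C3H8O5P", 30)
        loss("-glycerophosphate (chain)", "C3H7O5P", 100)
        loss("-glycerol (chain)", "C3H6O2", 50)
    elif key == ("GPG", "negative"):
        if link == ACYL:
            ion("glycerylphosphorylglycerol", "C6H14O8P", 60)
            ion("glycerylphosphorylglycerol -H2O", "C6H12O7P", 30)
            loss("-glycerylphosphorylglycerol (carboxylate)", "C6H13O7P", 100)
            ion("glycerol phosphate", "C3H8O6P", 60)
            ion("glycerol phosphate -H2O", "C3H6O5P", 20)
            loss("-H2O", "H2O", 10)
        else:
            loss("-glycerol", "C3H6O2", 100)
            ion("glycerol phosphate", "C3H8O6P", 60)
            ion("glycerol phosphate -H2O", "C3H6O5P", 30)
            loss("-H2O", "H2O", 20)
    elif key == ("GPE", "positive"):
        loss("-H2O", "H2O", 40)
        loss("-phosphoethanolamine (chain)", "C2H8NO4P", 100)
        loss("-aziridine", "C2H5N", 30)
        loss("-ethanolamine", "C2H7NO", 30)
        loss("-glycerophosphoric acid", "C3H9O6P", 30)
    elif key == ("GPE", "negative"):
        loss("-glycerophosphoethanolamine (carboxylate)", "C5H12NO5P", 100)
        ion("glycerophosphoethanolamine", "C5H13NO6P", 30)
        ion("glycerophosphoethanolamine -H2O", "C5H11NO5P", 10)
        ion("phosphoethanolamine", "C2H7NO4P", 30)
        ion("glycerol phosphate -H2O", "C3H6O5P", 20)
    elif key == ("GPA", "positive"):
        loss("-H2O", "H2O", 60)
        loss("-phosphoric acid (chain)", "H3PO4", 100)
        ion("glycerophosphoric acid", "C3H10O6P", 60)
    elif key == ("GPA", "negative"):
        ion("phosphate", "H2O4P", 60)
        ion("glycerophosphoric acid", "C3H8O6P", 60)
        loss("-glycerophosphate (carboxylate)", "C3H7O5P", 100)
    elif key == ("cGPA", "negative"):
        ion("cyclic glycerophosphate", "C3H6O5P", 60)
        loss("-cyclic glycerophosphoric acid (carboxylate)", "C3H5O4P", 100)
    elif key == ("GPS", "positive"):
        loss("-H2O", "H2O", 30)
        ion("glycerophosphoserine", "C6H15NO8P", 60)
        ion("glycerophosphoserine -H2O", "C6H13NO7P", 20)
        ion("serine fragment", "C3H8NO3", 40)
        ion("serine fragment -H2O", "C3H6NO2", 20)
        loss("-phosphoserine (chain)", "C3H8NO6P", 100)
        loss("-serine (chain)", "C3H7NO3", 60)
    elif key == ("GPS", "negative"):
        loss("-serine residue", "C3H5NO2", 100)
        loss("-serine residue -H2O", "C3H7NO3", 30)
        loss("-glycerophosphoserine (carboxylate)", "C6H12NO7P", 60)
        ion("glycerol phosphate", "C3H8O6P", 30)
    elif key == ("GPC", "positive"):
        ion("phosphocholine", "C5H15NO4P", 100)
        ion("choline", "C5H14NO", 40)
        ion("glycerylphosphorylcholine", "C8H21NO6P", 40)
        ion("glycerylphosphorylcholine -H2O", "C8H19NO5P", 20)
        loss("-phosphocholine (chain)", "C5H14NO4P", 60)
        loss("-H2O", "H2O", 20)
    elif key == ("IPC", "positive"):
        loss("-H2O", "H2O", 30)
        loss("-H2O -inositol monophosphate", "C6H15O10P", 100)
        loss("-2H2O -inositol monophosphate", "C6H17O11P", 40)
        if comp.split is not None:
            (_, _, _), (c2, d2, _) = comp.split
            loss(f"sphingoid ion (-N-acyl ketene {c2}:{d2})",
                 _F("C6H15O10P") + ketene(c2, d2, 0), 40)
    elif key == ("IPC", "negative"):
        ion("inositol monophosphate", "C6H12O9P", 100)
        ion("inositol cyclic phosphate", "C6H10O8P", 80)
        loss("-anhydroinositol", "C6H10O5", 40)
        loss("-anhydroinositol -H2O", "C6H12O6", 20)
        loss("-H2O", "H2O", 20)
    elif key == ("PG", "negative"):
        loss("-H2O", "H2O", 100)
        loss("-2H2O", "H4O2", 60)
        loss("-H2O -CO2", "CH2O3", 60)
        loss("-2H2O -CO2", "CH4O4", 30)
    else:
        raise ValueError(f"no fragmentation template for {class_id}/{polarity}")
    return out


# ---------------------------------------------------------------------------
# Spectrum simulation

def _species_rng(config: SimulationConfig, name: str, polarity: str) -> np.random.Generator:
    tag = zlib.crc32(f"{name}|{polarity}".encode())
    return np.random.default_rng([config.seed & 0x7FFFFFFF, tag])


def simulate_spectrum(spec: SpeciesSpec, polarity: str,
                      config: Optional[SimulationConfig] = None,
                      feature_id: Optional[str] = None) -> Spectrum:
    """Simulate one MS² spectrum for a species in a given polarity.

    With the default (noise-free) config every peak sits at its exact
    theoretical m/z and the template tier intensities are scaled by
    ``base_intensity``.  Noise peaks never land within 0.02 Da of a
    template peak, so tolerance behaviour can be tested without
    accidental collisions.
    """
    config = config or SimulationConfig()
    charge = +1 if polarity == "positive" else -1
    rng = _species_rng(config, spec.name, polarity)
    template = fragment_template(spec.class_id, polarity, spec.composition)
    prec_formula = ion_formula(spec.class_id, spec.composition, polarity)
    prec_mz = ion_mz(IonSpecies(prec_formula, charge))

    peaks: List[Peak] = []
    for _, frag, tier in template:
        mz = ion_mz(IonSpecies(frag, charge))
        if config.mz_jitter_sd > 0:
            mz += rng.normal(0.0, config.mz_jitter_sd)
        inten = tier * config.base_intensity / 100.0
        if config.intensity_sigma > 0:
            inten *= float(np.exp(rng.normal(0.0, config.intensity_sigma)))
        peaks.append(Peak(mz, inten))

    if config.n_noise_peaks:
        base = max(p.intensity for p in peaks)
        template_mzs = np.array([p.mz for p in peaks])
        lo, hi = 100.0, max(200.0, prec_mz - 20.0)
        placed = 0
        while placed < config.n_noise_peaks:
            mz = float(rng.uniform(lo, hi))
            if np.abs(template_mzs - mz).min() < 0.02:
                continue
            inten = float(rng.uniform(0.05, 1.0)) * config.noise_rel_intensity_max * base
            peaks.append(Peak(mz, inten))
            placed += 1

    obs_prec = prec_mz + (rng.normal(0.0, config.mz_jitter_sd)
                          if config.mz_jitter_sd > 0 else 0.0)
    return Spectrum(
        feature_id=feature_id or f"{spec.name}|{polarity}",
        precursor_mz=obs_prec,
        polarity=polarity,
        retention_time=spec.retention_time,
        peaks=tuple(peaks),
        metadata={"name": spec.name})


# ---------------------------------------------------------------------------
# Reference species table
#
# (name, class_id, linkage, chains, rt_min, printed +ion, printed -ion);
# chains are (carbons, double bonds, extra oxygens) per chain; printed
# ions are (formula text as reported, reported m/z) or None.

_ROWS: List[tuple] = [
    # monoacyl / monoalkyl / oxidised glycerophosphoinositols
    ("LPI 16:0", "GPI", ACYL, [(16, 0, 0)], 20.8, None, ("C25H48O12P", 571.2888)),
    ("LPI 17:0", "GPI", ACYL, [(17, 0, 0)], 21.9, None, ("C26H50O12P", 585.3048)),
    ("LPI 18:0", "GPI", ACYL, [(18, 0, 0)], 23.0, ("C27H54O12P", 601.3344), ("C27H52O12P", 599.3202)),
    ("LPI 18:1", "GPI", ACYL, [(18, 1, 0)], 21.2, None, ("C27H50O12P", 597.3049)),
    ("LPI 19:0", "GPI", ACYL, [(19, 0, 0)], 24.2, None, ("C28H54O12P", 613.3360)),
    ("LPI 20:0", "GPI", ACYL, [(20, 0, 0)], 25.4, None, ("C29H56O12P", 627.3517)),
    ("LPI 20:1", "GPI", ACYL, [(20, 1, 0)], 23.3, None, ("C29H54O12P", 625.3359)),
    ("LPI O-16:0", "GPI", ETHER, [(16, 0, 0)], 21.2, ("C25H52O11P", 559.3239), ("C25H50O11P", 557.3096)),
    ("LPI O-17:0", "GPI", ETHER, [(17, 0, 0)], 22.4, ("C26H54O11P", 573.3395), ("C26H52O11P", 571.3252)),
    ("LPI O-18:0", "GPI", ETHER, [(18, 0, 0)], 23.5, ("C27H56O11P", 587.3554), ("C27H54O11P", 585.3412)),
    ("LPI O-18:1", "GPI", ETHER, [(18, 1, 0)], 22.2, None, ("C27H52O11P", 583.3256)),
    ("PI 18:0/5:1;O2", "GPI", DIACYL, [(18, 0, 0), (5, 1, 2)], 23.6, None, ("C33H62O14P", 713.352)),
    ("PI 18:0/6:1;O", "GPI", DIACYL, [(18, 0, 0), (6, 1, 1)], 24.6, None, ("C33H60O14P", 711.3727)),
    ("PI 18:0/6:1;O2", "GPI", DIACYL, [(18, 0, 0), (6, 1, 2)], 23.8, None, ("C33H60O15P", 727.3677)),
    ("PI 18:0/7:1;O", "GPI", DIACYL, [(18, 0, 0), (7, 1, 1)], 25.1, None, ("C34H62O14P", 725.3888)),
    ("PI 19:0/6:1;O2", "GPI", DIACYL, [(19, 0, 0), (6, 1, 2)], 24.1, None, ("C34H62O15P", 741.3835)),
    ("PI 20:0/6:1;O2", "GPI", DIACYL, [(20, 0, 0), (6, 1, 2)], 26.1, None, ("C35H64O15P", 755.3991)),
    ("PI 20:1/6:1;O2", "GPI", DIACYL, [(20, 1, 0), (6, 1, 2)], 23.9, None, ("C35H62O16P", 753.3829)),
    ("PI 18:0/9:2;O3", "GPI", DIACYL, [(18, 0, 0), (9, 2, 3)], 23.2, None, ("C36H64O16P", 783.3939)),
    ("PI O-18:0/5:1;O2", "GPI", ETHER_ACYL, [(18, 0, 0), (5, 1, 2)], 24.2, None, ("C32H60O14P", 699.3730)),
    ("PI O-18:0/6:1;O2", "GPI", ETHER_ACYL, [(18, 0, 0), (6, 1, 2)], 24.5, None, ("C33H62O14P", 713.3882)),
    # glycerophosphoglycerols
    ("LPG 16:0", "GPG", ACYL, [(16, 0, 0)], 22.3, None, ("C22H44O9P", 483.2732)),
    ("LPG 18:0", "GPG", ACYL, [(18, 0, 0)], 24.9, None, ("C24H48O9P", 511.3046)),
    ("LPG 18:1", "GPG", ACYL, [(18, 1, 0)], 22.6, None, ("C24H46O9P", 509.2887)),
    ("LPG O-14:0", "GPG", ETHER, [(14, 0, 0)], 20.5, ("C20H44O8P", 443.2779), ("C20H42O8P", 441.2623)),
    ("LPG O-15:0", "GPG", ETHER, [(15, 0, 0)], 21.8, ("C21H46O8P", 457.2930), ("C21H44O8P", 455.2783)),
    ("LPG O-16:0", "GPG", ETHER, [(16, 0, 0)], 23.1, ("C22H48O8P", 471.3095), ("C22H46O8P", 469.2936)),
    ("LPG O-16:1", "GPG", ETHER, [(16, 1, 0)], 21.0, None, ("C22H44O8P", 467.2781)),
    ("LPG O-17:0", "GPG", ETHER, [(17, 0, 0)], 24.5, ("C23H50O8P", 485.3252), ("C23H48O8P", 483.3097)),
    ("LPG O-18:0", "GPG", ETHER, [(18, 0, 0)], 26.1, ("C24H52O8P", 499.3394), ("C24H50O8P", 497.3255)),
    ("LPG 18:1;O", "GPG", ACYL, [(18, 1, 1)], 17.9, None, ("C24H46O10P", 525.2834)),
    # glycerophosphoethanolamines
    ("LPE 16:1", "GPE", ACYL, [(16, 1, 0)], 27.6, ("C21H43NO7P", 452.2768), ("C21H41NO7P", 450.2627)),
    ("LPE 18:1", "GPE", ACYL, [(18, 1, 0)], 25.0, None, ("C23H45NO7P", 478.2939)),
    # glycerophosphates (incl. cyclic)
    ("LPA 16:1", "GPA", ACYL, [(16, 1, 0)], 26.0, None, ("C16H36O7P", 407.2204)),
    ("LPA 18:0", "GPA", ACYL, [(18, 0, 0)], 31.1, None, ("C21H42O7P", 437.2674)),
    ("LPA 18:1", "GPA", ACYL, [(18, 1, 0)], 30.5, None, ("C21H40O7P", 435.2515)),
    ("LPA 20:1", "GPA", ACYL, [(20, 1, 0)], 31.7, None, ("C23H44O7P", 463.2830)),
    ("LPA O-16:0", "GPA", ETHER, [(16, 0, 0)], 29.2, ("C19H42O6P", 397.2717), None),
    ("CPA 16:0", "cGPA", ACYL, [(16, 0, 0)], 24.7, None, ("C19H36O6P", 391.2256)),
    ("CPA 16:1", "cGPA", ACYL, [(16, 1, 0)], 23.9, None, ("C19H34O6P", 389.2098)),
    ("CPA 18:0", "cGPA", ACYL, [(18, 0, 0)], 30.0, None, ("C21H40O6P", 419.2569)),
    # glycerophosphoserine
    ("LPS 18:0", "GPS", ACYL, [(18, 0, 0)], 29.6, ("C24H49NO9P", 526.3139), ("C24H47NO9P", 524.2994)),
    # glycerophosphocholines
    ("LPC 16:0", "GPC", ACYL, [(16, 0, 0)], 19.5, ("C24H51NO7P", 496.3401), None),
    ("LPC 18:0", "GPC", ACYL, [(18, 0, 0)], 22.6, ("C26H55NO7P", 524.3713), None),
    ("LPC 11:1;O", "GPC", ACYL, [(11, 1, 1)], 14.0, ("C19H39NO8P", 440.2411), None),
    ("LPC 18:1;O", "GPC", ACYL, [(18, 1, 1)], 21.8, ("C26H53NO8P", 538.3503), None),
    # ceramide phosphoinositols (chains = (sphingoid base, N-acyl) where split)
    ("IPC 24:2;O3", "IPC", SPHINGOID, [(24, 2, 3)], 31.1, None, ("C30H55NO12P", 652.3469)),
    ("IPC 33:1;O2", "IPC", SPHINGOID, [(33, 1, 2)], 30.9, None, ("C39H75NO11P", 764.5082)),
    ("IPC (d18:1/16:0)", "IPC", SPHINGOID, [(18, 1, 2), (16, 0, 0)], 32.8, ("C40H79NO11P", 780.5378), ("C40H77NO11P", 778.5240)),
    ("IPC (d18:2/16:0)", "IPC", SPHINGOID, [(18, 2, 2), (16, 0, 0)], 31.0, ("C40H77NO11P", 778.5229), ("C40H75NO11P", 776.5082)),
    ("IPC 34:3;O2", "IPC", SPHINGOID, [(34, 3, 2)], 29.7, None, ("C40H73NO11P", 774.4928)),
    ("IPC 35:2;O2", "IPC", SPHINGOID, [(35, 2, 2)], 32.3, None, ("C41H77NO11P", 790.5240)),
    # prostaglandin-type oxylipins
    ("FA 20:5;O2", "PG", FREE_FA, [(20, 5, 2)], 23.8, None, ("C20H29O4", 333.2073)),
    ("FA 20:4;O2", "PG", FREE_FA, [(20, 4, 2)], 25.8, None, ("C20H31O4", 335.2232)),
    ("FA 20:4;O3", "PG", FREE_FA, [(20, 4, 3)], 19.0, None, ("C20H31O5", 351.2178)),
]

#: Species whose reported ion-formula text disagrees with the reported
#: m/z; the m/z matches the composition-derived formula in every case.
FORMULA_MISPRINTS: Dict[Tuple[str, str], str] = {
    ("LPA 16:1", "negative"): "C16H36O7P",
    ("PI 18:0/5:1;O2", "negative"): "C33H62O14P",
    ("PI 20:1/6:1;O2", "negative"): "C35H62O16P",
}


def _row_composition(linkage: str, chains: List[Tuple[int, int, int]]
                     ) -> ChainComposition:
    c = sum(ch[0] for ch in chains)
    d = sum(ch[1] for ch in chains)
    o = sum(ch[2] for ch in chains)
    split = (chains[0], chains[1]) if len(chains) == 2 else None
    return ChainComposition(c, d, o, linkage, split)


def reference_species() -> List[SpeciesSpec]:
    """The curated 55-species reference list with RTs and extract profiles."""
    specs = []
    for i, (name, class_id, linkage, chains, rt, pos, neg) in enumerate(_ROWS):
        polarities = tuple(p for p, printed in
                           (("positive", pos), ("negative", neg)) if printed)
        profile = (_PROSTAGLANDIN_PROFILE if class_id == "PG"
                   else _PHOSPHOLIPID_PROFILE)
        specs.append(SpeciesSpec(
            name=name,
            class_id=class_id,
            composition=_row_composition(linkage, chains),
            polarities=polarities,
            retention_time=rt,
            extract_profile=profile,
            total_area=(1.0 + 0.15 * (i % 8)) * 1e6))
    return specs


@dataclass(frozen=True)
class ReferenceIon:
    """One reported precursor ion: species row x polarity."""

    species: SpeciesSpec
    polarity: str
    printed_formula: str
    printed_mz: float

    @property
    def derived_formula(self) -> ElementalFormula:
        return ion_formula(self.species.class_id, self.species.composition,
                           self.polarity)

    @property
    def theoretical_mz(self) -> float:
        charge = +1 if self.polarity == "positive" else -1
        return ion_mz(IonSpecies(self.derived_formula, charge))

    @property
    def is_known_misprint(self) -> bool:
        return (self.species.name, self.polarity) in FORMULA_MISPRINTS


def reference_printed_ions() -> List[ReferenceIon]:
    """All reported (species, polarity, formula, m/z) precursor entries."""
    specs = {s.name: s for s in reference_species()}
    out = []
    for name, _, _, _, _, pos, neg in _ROWS:
        for polarity, printed in (("positive", pos), ("negative", neg)):
            if printed is not None:
                out.append(ReferenceIon(specs[name], polarity,
                                        printed[0], printed[1]))
    return out


def reference_fixture(config: Optional[SimulationConfig] = None,
                      species: Optional[Sequence[SpeciesSpec]] = None,
                      ) -> Tuple[List[Spectrum], List[FeatureRecord]]:
    """Simulated spectra + feature table for the reference species list.

    One feature (spectrum + quantification row) per species x reported
    polarity; ids are stable (``F<row><P|N>``).  Defaults to noise-free
    simulation so the emitted peak sets equal the fragmentation
    templates exactly.
    """
    config = config or SimulationConfig()
    species = list(species) if species is not None else reference_species()
    spectra: List[Spectrum] = []
    records: List[FeatureRecord] = []
    for i, spec in enumerate(species):
        for polarity in spec.polarities:
            fid = f"F{i + 1:03d}{'P' if polarity == 'positive' else 'N'}"
            s = simulate_spectrum(spec, polarity, config, feature_id=fid)
            spectra.append(s)
            records.append(FeatureRecord(
                feature_id=fid,
                precursor_mz=s.precursor_mz,
                retention_time=spec.retention_time,
                abundances={e: spec.total_area * spec.extract_profile[e]
                            for e in EXTRACTS}))
    return spectra, records


def simulate_dataset(specs: Sequence[SpeciesSpec],
                     config: Optional[SimulationConfig],
                     mgf_path: Union[str, Path],
                     csv_path: Union[str, Path]) -> Tuple[Path, Path]:
    """Serialize a simulated dataset to MGF + feature-table CSV files."""
    spectra, records = reference_fixture(config, species=specs)
    mgf_path, csv_path = Path(mgf_path), Path(csv_path)
    write_mgf(spectra, mgf_path)
    write_feature_table(records, csv_path, samples=list(EXTRACTS))
    return mgf_path, csv_path
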