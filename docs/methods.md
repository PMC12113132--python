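# Methods

`lipiderep` re-implements, as a tested library, the dereplication
workflow used to profile the lipidome of the sea pen *Pennatula
phosphorea*: feature-based molecular networking (FBMN) of LC-MS²
spectra combined with manual-style interpretation of diagnostic
fragment ions, expressed here as an explicit rulebook.  This note
documents the models, the tunable parameters, the numerical choices,
and what the synthetic data do and do not establish.

## Exact-mass arithmetic

All mass computation reduces to integer element counts.  Monoisotopic
masses are most-abundant-isotope masses (CODATA/IUPAC, hard-coded to at
least seven decimals: H 1.0078250319, C 12 exactly, N 14.0030740052,
O 15.9949146221, P 30.97376151, ...).  Ion m/z subtracts (cations) or
adds (anions) the electron mass, 0.000548579909 Da.  The correction
matters at the precision in play: at m/z 171 it is 3.2 ppm, and several
low-mass diagnostic anions (171.0064, 259.0224, 152.9958) only agree
with their reported values once it is applied.  Reported table m/z are
treated as *measured* quantities; agreement is asserted at 5 ppm rather
than decimal equality, since a handful of entries (e.g. the LPG O-14:0
cation at 443.2779) deviate from theory by ~2.4 ppm.  Isotope
envelopes, multiple charging and average masses are out of scope.

Three reference-table entries carry internally inconsistent
formula/m-z pairs (`synth.FORMULA_MISPRINTS`).  In each case the
reported m/z matches the formula derived from the species' sum
composition, so the composition-derived formula is used for simulation
and annotation while the reported text is retained for auditing.

## Sum-composition model

A species is a class backbone plus one or two radyl chains at
species-level (sum composition) resolution:

* acyl residue C:D;Ox → C_c H_(2c−2d−2) O_(1+x)
* O-alkyl/alkenyl residue → C_c H_(2c−2d) O_x
* ceramide (sphingoid base + N-acyl) → C_c H_(2c−2d+1) N O_(x+1)
* free fatty acid (prostaglandin-type) → C_c H_(2c−2d) O_(2+x)

Double-bond counts cover carbon–carbon unsaturation only; oxidation is
carried in the `;O` suffix.  Backbones (glycerophosphoinositol
C9H19O11P, glycerophosphoglycerol C6H15O8P, glycerophosphoethanolamine
C5H14NO6P, glycerophosphate C3H9O6P, cyclic glycerophosphate C3H7O5P,
glycerophosphoserine C6H14NO8P, glycerophosphocholine C8H20NO6P,
inositol-phosphate residue C6H11O8P for IPC) were derived by
subtracting the chain contribution from the reported ion formulas and
are consistent across every homologous series.  Chain bounds: total
carbons 10–44, double bonds 0–8, extra oxygens 0–4.  sn-positions,
double-bond positions and cyclopentane-ring isomers (PGE₂ vs PGD₂)
are expressly not resolved; those isomers share parent masses and
near-identical MS² spectra, hence the species-level shorthand.

## Modified cosine and network construction

Peaks are preprocessed by a window filter (top 6 peaks per 50 Da
non-overlapping window) and a square-root intensity transform; the two
preprocessing constants are not part of the published parameter set and
are exposed as configuration with these conventional defaults.  The
modified cosine then allows a peak pair to match either directly
(|Δm/z| ≤ fragment tolerance) or offset by the precursor-mass
difference, and scores the best one-to-one assignment with
L2-normalised weights.  The assignment is solved exactly with the
Hungarian algorithm (`scipy.optimize.linear_sum_assignment`) at every
problem size; an exhaustive-enumeration oracle pins its optimality in
the tests, and the `matchms` implementation — whose greedy assignment
is a lower bound on the exact optimum — serves as an independent
cross-check.

Networking thresholds default to the FBMN parameter set used for the
sea-pen data: precursor tolerance 0.02 Da, fragment tolerance 0.05 Da,
edge cosine ≥ 0.7, ≥ 4 matched peaks, ≤ 10 retained neighbours per
node, ≤ 100 nodes per connected component.  Topology is enforced
neighbours-first: an edge survives only if each endpoint ranks the
other in its top-10 by cosine (ties broken by neighbour id), after
which any oversized component repeatedly loses its lowest-cosine edge
(ties broken by the lexicographically smallest node pair).  The
neighbour-then-component order and both tie-breaks are fixed choices
made for determinism; the upstream tooling leaves them unspecified.
Library matching requires cosine strictly above 0.7 with ≥ 6 matched
peaks; because homologues produce precursor-shifted copies of the same
template, cosine ties are broken toward the smaller precursor
difference.  Positive- and negative-mode spectra are never scored
against each other, giving one network per polarity.

## Annotation engine

Annotation composes four stages:

1. **Class detection.**  Each rulebook entry lists diagnostic fragment
   ions and neutral losses, tagged `required` or `supporting`.  A class
   qualifies when ≥ `min_required` required items match; candidates are
   ranked by (required matched, supporting matched, summed matched
   intensity) with a fixed class-priority tie-break.  `min_required` is
   2 for every class — a calibration of this package (the source
   describes the ions but never a minimum count), set so that all
   reference templates pass while cross-class templates fail.
2. **Precursor formula assignment.**  Sum compositions are enumerated
   over the class template (cached per class/polarity) and kept when
   the [M+H]⁺/[M−H]⁻ m/z lies within 5 ppm of the precursor.
3. **Chain inference.**  Chain-release fragments (complements of
   head-group losses, e.g. the stearate anion at 283.2643 from LPS
   18:0, or the 421.2714 serine-loss cation) confirm a composition.
   For two-chain phosphoinositols a peak at precursor − ketene of the
   oxidised chain pins the split (`PI 18:0/6:1;O2` style); in positive
   mode a sphingoid ion (loss of water + inositol monophosphate +
   N-acyl ketene) resolves the IPC base/N-acyl split.  Without such a
   fragment the composition falls back to precursor arithmetic and the
   confidence drops to `class-only` whenever an alternative linkage
   explains the same ion formula (an acyl C:D;Ox reading is mass-
   identical to an ether C:(D+1);O(x+1) reading; the conventional acyl
   reading is reported).
4. **Naming.**  A deterministic species-level grammar (`LPI 18:0`,
   `LPG O-14:0`, `PI O-18:0/5:1;O2`, `IPC (d18:1/16:0)`, `FA 20:4;O3`).

Fragment matching accepts max(0.005 Da, 10 ppm) — wide enough for the
~2 mDa deviations seen in reported low-mass fragments, narrow enough to
separate neighbouring lipid classes.  The shared inositol-phosphate
anions (259.0224/241.0119) make GPI and IPC mutual candidates in
negative mode; the inositol-loss ions, the evidence ranking and
ultimately the precursor formula (nitrogen-free for GPI,
nitrogen-containing for IPC) disambiguate.  The annotator asserts, on
every output, that the reported precursor deviation is within
tolerance.

Two readings in the source chemistry required a decision.  The IPC
positive-mode combined loss is implemented as H₂O + inositol
monophosphate C6H13O9P (consistent with the sphingoid-ion expression
and the published rearrangement mechanism); an O8 variant appearing
once in the text is treated as a typographical slip.  The IPC
negative-mode inositol loss is implemented as anhydro-inositol C6H10O5
(162.0528 Da), since the quoted C6H11O5 radical has odd hydrogen
parity.

Prostaglandin-type oxylipins are recognised from ≥ 2 of the water /
2×water / water+CO₂ losses plus a C20 fatty-acid precursor formula
(O4–O5); series typing (A/D/E/F) is out of scope.

## Synthetic data

The generator inverts the annotation rules: for a species it emits
every template fragment at its exact theoretical m/z with tiered
relative intensities (100 for ions described as dominant, 60 for
primary diagnostics, 20–40 for supporting ions, ~10 for minor ones,
plus a 15% residual precursor peak).  Only presence, tolerance and rank
structure are simulated — the source publishes no full peak lists with
intensities, so absolute intensity realism is explicitly not a goal.
Optional degradation: Gaussian m/z jitter, log-normal multiplicative
intensity noise, and uniform-random noise peaks that are kept ≥ 0.02 Da
away from template peaks so robustness tests measure tolerance
behaviour, not collisions.  Per-spectrum RNG streams derive from the
seed plus a CRC32 of the species name, making outputs byte-stable.

The reference list carries all 55 species with their reported retention
times and ion m/z, yielding 68 spectra (both polarities where
reported).  Extract profiles are qualitative stand-ins: 0.70/0.20/0.10
(hexane/CHCl₃/MeOH) for phospholipids and IPCs, 0.15/0.70/0.15 for
prostaglandins; per-species total areas vary deterministically over a
small grid.  Consequently, passing round-trip tests show that the
annotation logic inverts the encoded fragmentation chemistry under
realistic tolerances — they do not show performance on real spectra,
which add co-isolation chimeras, in-source fragments, isotope peaks and
intensity variation the generator does not model.

## Pipeline

`run_pipeline` loads (or simulates) the MGF + feature-table pair, joins
by feature id (id-only, by design: tolerance joining silently mispairs
isobars), annotates every spectrum, builds one network per polarity,
and writes GraphML, node/edge/annotation/summary CSVs and a JSON run
report.  Node attributes carry class, shorthand and per-extract
abundance proportions (the pie-chart quantities); per-node and
per-class proportions always sum to 1.  Unannotated nodes remain in the
network as `unknown`.  For reporting, cyclic glycerophosphates fold
into the glycerophosphate family, giving the eight chemical classes;
the annotation CSV retains the finer rule-level class.  Retention times
are minutes internally; `RTINSECONDS` is converted on read.  Features
lacking MS² spectra are simply absent from the MGF, mirroring the
upstream export, and are reported as unmatched rows rather than errors.

## Problem sizes in the test-suite

The suite exercises the full 55-species/68-spectrum fixture end to end
(sub-second per pipeline run), 500 random ≤ 8-peak spectrum pairs
against the exhaustive assignment oracle, and 50 random 150-node graphs
for the topology bounds — sizes chosen so the whole suite completes in
well under a minute while still covering every rule entry (a coverage
audit asserts this) and every degenerate-input path (empty spectra,
empty files, all-zero areas, mixed polarity, unmatched joins).

## Known limitations

* Only [M+H]⁺/[M−H]⁻ singly charged adducts; no sodiated species,
  no charge deconvolution, no isotope patterns.
* Acyl-vs-ether assignment for oxidised single-chain species relies on
  a documented convention when no chain fragment is present.
* The rulebook encodes one literature fragmentation scheme per class;
  real spectra of unusual species may fragment differently.
* Library matching scores against user-supplied spectra only; no
  public-repository search.
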