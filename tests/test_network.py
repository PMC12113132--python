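"""Modified cosine, network topology enforcement, library matching, export."""

import io
import math

import networkx as nx
import numpy as np
import pytest

from lipiderep.network import (MolecularNetwork, NetworkEdge, NetworkParams,
                               build_network, enforce_topology, export_graph,
                               match_library, modified_cosine,
                               preprocess_spectrum)
from lipiderep.spectra import Peak, Spectrum
from lipiderep.synth import SimulationConfig, reference_species, simulate_spectrum


def spectrum(fid, prec, mzs, intens, polarity="positive", **kw):
    return Spectrum(fid, prec, polarity,
                    peaks=tuple(Peak(m, i) for m, i in zip(mzs, intens)), **kw)


def random_spectrum(rng, fid, n_peaks, polarity="positive", related_to=None):
    """Random spectrum; optionally shares peaks with another (direct or
    precursor-shifted) so the modified cosine has real matches."""
    prec = float(rng.uniform(300, 900))
    mzs, intens = [], []
    if related_to is not None:
        shift = prec - related_to.precursor_mz
        for p in related_to.peaks:
            if len(mzs) >= n_peaks or rng.random() < 0.4:
                continue
            offset = float(rng.uniform(-0.03, 0.03))
            mzs.append(p.mz + offset + (shift if rng.random() < 0.5 else 0.0))
            intens.append(float(rng.uniform(0.1, 1.0)))
    while len(mzs) < n_peaks:
        mzs.append(float(rng.uniform(100, 900)))
        intens.append(float(rng.uniform(0.1, 1.0)))
    mzs = [m for m in mzs if m > 0]
    return spectrum(fid, prec, mzs, intens[: len(mzs)], polarity)


def brute_force_modified_cosine(a, b, fragment_tol):
    """Exhaustive maximum over all one-to-one candidate-pair matchings."""
    wa = np.asarray(a.intensities, float)
    wb = np.asarray(b.intensities, float)
    wa = wa / np.linalg.norm(wa)
    wb = wb / np.linalg.norm(wb)
    mza, mzb = np.asarray(a.mzs), np.asarray(b.mzs)
    shift = a.precursor_mz - b.precursor_mz
    pairs = [(i, j) for i in range(len(mza)) for j in range(len(mzb))
             if abs(mza[i] - mzb[j]) <= fragment_tol
             or abs(mza[i] - mzb[j] - shift) <= fragment_tol]
    best = 0.0

    def rec(k, used_a, used_b, acc):
        nonlocal best
        if acc > best:
            best = acc
        if k == len(pairs):
            return
        rec(k + 1, used_a, used_b, acc)
        i, j = pairs[k]
        if i not in used_a and j not in used_b:
            rec(k + 1, used_a | {i}, used_b | {j}, acc + wa[i] * wb[j])

    rec(0, frozenset(), frozenset(), 0.0)
    return best


# ---------------------------------------------------------------------------
# preprocessing

def test_preprocess_single_peak_sqrt():
    s = spectrum("X", 500.0, [200.0], [9.0])
    out = preprocess_spectrum(s)
    assert out.peaks[0].intensity == pytest.approx(3.0)
    assert out.peaks[0].mz == 200.0


def test_preprocess_window_top_k():
    mzs = [100.0 + i * 0.5 for i in range(10)]       # all in one 50-Da window
    s = spectrum("X", 500.0, mzs, [float(i + 1) for i in range(10)])
    out = preprocess_spectrum(s, window=50.0, top_k=6)
    assert len(out.peaks) == 6
    # the six most intense survive
    assert {p.mz for p in out.peaks} == set(mzs[4:])


def test_preprocess_keeps_template_peaks_under_noise():
    spec = next(s for s in reference_species() if s.name == "LPI 18:0")
    noisy = simulate_spectrum(spec, "negative",
                              SimulationConfig(seed=7, n_noise_peaks=20))
    clean = simulate_spectrum(spec, "negative", SimulationConfig())
    kept = {round(p.mz, 4) for p in preprocess_spectrum(noisy).peaks}
    assert all(round(p.mz, 4) in kept for p in clean.peaks)


# ---------------------------------------------------------------------------
# modified cosine

def test_identical_spectra_score_one():
    s = preprocess_spectrum(
        spectrum("X", 500.0, [100.0, 200.0, 300.0, 400.0], [1, 5, 2, 8]))
    score, n = modified_cosine(s, s)
    assert score == pytest.approx(1.0, abs=1e-9)
    assert n == 4


def test_disjoint_spectra_score_zero():
    a = spectrum("A", 500.0, [100.0, 200.0], [1.0, 1.0])
    b = spectrum("B", 500.0, [150.0, 250.0], [1.0, 1.0])
    assert modified_cosine(a, b) == (0.0, 0)


def test_mixed_polarity_rejected():
    a = spectrum("A", 500.0, [100.0], [1.0], "positive")
    b = spectrum("B", 500.0, [100.0], [1.0], "negative")
    with pytest.raises(ValueError):
        modified_cosine(a, b)


def test_modified_cosine_matches_brute_force_and_is_symmetric():
    rng = np.random.default_rng(42)
    for _ in range(60):
        a = random_spectrum(rng, "A", int(rng.integers(2, 8)))
        b = random_spectrum(rng, "B", int(rng.integers(2, 8)), related_to=a)
        s_ab, _ = modified_cosine(a, b)
        s_ba, _ = modified_cosine(b, a)
        assert s_ab == pytest.approx(s_ba, abs=1e-12)
        assert -1e-12 <= s_ab <= 1.0 + 1e-12
        assert s_ab == pytest.approx(
            brute_force_modified_cosine(a, b, 0.05), abs=1e-9)


def test_modified_cosine_agrees_with_matchms():
    """Independent cross-check against the reference FBMN implementation.

    matchms assigns candidate pairs greedily, so its score is a lower
    bound on the exact assignment; on conflict-free pairs they coincide.
    """
    from matchms import Spectrum as MSpectrum
    from matchms.similarity import ModifiedCosine as MMModifiedCosine

    def to_matchms(s):
        return MSpectrum(mz=np.array(s.mzs), intensities=np.array(s.intensities),
                         metadata={"precursor_mz": s.precursor_mz},
                         metadata_harmonization=False)

    mm = MMModifiedCosine(tolerance=0.05)
    rng = np.random.default_rng(3)
    n_equal = 0
    for _ in range(30):
        a = random_spectrum(rng, "A", 6)
        b = random_spectrum(rng, "B", 6, related_to=a)
        ours, _ = modified_cosine(a, b)
        theirs = float(mm.pair(to_matchms(a), to_matchms(b))["score"])
        assert ours >= theirs - 1e-9          # exact assignment dominates
        if math.isclose(ours, theirs, abs_tol=1e-9):
            n_equal += 1
    assert n_equal >= 25                      # near-universal agreement


# ---------------------------------------------------------------------------
# network construction and topology

def test_build_network_single_spectrum():
    s = spectrum("A", 500.0, [100.0, 200.0], [1.0, 1.0])
    net = build_network([s])
    assert set(net.nodes) == {"A"} and net.edges == []


def test_build_network_duplicate_spectra_edge():
    mzs = [100.0, 150.0, 200.0, 250.0, 300.0]
    a = spectrum("A", 500.0, mzs, [1, 2, 3, 4, 5])
    b = spectrum("B", 500.0, mzs, [1, 2, 3, 4, 5])
    net = build_network([a, b])
    assert len(net.edges) == 1
    assert net.edges[0].cosine == pytest.approx(1.0, abs=1e-9)
    assert net.edges[0].n_matched >= 4


def test_ipc_species_form_single_component():
    specs = [s for s in reference_species() if s.class_id == "IPC"]
    spectra = [simulate_spectrum(s, "negative", SimulationConfig(),
                                 feature_id=s.name) for s in specs]
    net = build_network(spectra)
    comps = net.components()
    big = max(comps, key=len)
    assert len(big) == 6                    # shared diagnostic peaks connect all


def test_enforce_topology_star_tiebreak():
    edges = [NetworkEdge("center", f"n{i:02d}", 0.9, 5, 0.0) for i in range(12)]
    nodes = {e.node_b: None for e in edges} | {"center": None}
    net = enforce_topology(MolecularNetwork(nodes, edges), max_neighbors=10)
    kept = sorted(e.node_b for e in net.edges)
    assert kept == [f"n{i:02d}" for i in range(10)]   # lexicographic tie-break


def test_enforce_topology_splits_chain():
    edges = [NetworkEdge("a", "b", 0.9, 5, 0.0),
             NetworkEdge("b", "c", 0.8, 5, 0.0)]
    net = enforce_topology(MolecularNetwork({"a": None, "b": None, "c": None},
                                            edges), max_component=2)
    assert len(net.edges) == 1
    assert net.edges[0].key() == ("a", "b")           # weakest edge removed


def test_enforce_topology_random_graph_properties():
    rng = np.random.default_rng(11)
    nodes = {f"n{i:02d}": None for i in range(30)}
    names = sorted(nodes)
    edges = []
    seen = set()
    for _ in range(200):
        i, j = rng.integers(0, 30, size=2)
        if i == j:
            continue
        key = tuple(sorted((names[i], names[j])))
        if key in seen:
            continue
        seen.add(key)
        edges.append(NetworkEdge(key[0], key[1], float(rng.uniform(0.7, 1.0)),
                                 5, 0.0))
    net = enforce_topology(MolecularNetwork(nodes, edges),
                           max_neighbors=4, max_component=10)
    for node in net.nodes:
        assert net.degree(node) <= 4
    assert max(len(c) for c in net.components()) <= 10


# ---------------------------------------------------------------------------
# library matching

def library_of_reference_spectra():
    out = []
    for spec in reference_species():
        for pol in spec.polarities:
            out.append(simulate_spectrum(spec, pol, SimulationConfig(),
                                         feature_id=spec.name))
    return out


def test_match_library_self_hit_and_best_hit():
    library = library_of_reference_spectra()
    lpc = next(s for s in library
               if s.metadata["name"] == "LPC 16:0" and s.polarity == "positive")
    hits = match_library(lpc, library)
    assert hits and hits[0].library_name == "LPC 16:0"
    assert hits[0].cosine == pytest.approx(1.0, abs=1e-9)


def test_match_library_too_few_shared_peaks():
    a = spectrum("Q", 500.0, [100, 150, 200, 250, 300], [1] * 5)
    b = spectrum("L", 500.0, [100, 150, 200, 250, 300], [1] * 5,
                 metadata={"name": "five-peaks"})
    assert match_library(a, [b]) == []      # 5 matches < 6 required
    assert match_library(a, []) == []


# ---------------------------------------------------------------------------
# export

def test_export_graph_empty_network():
    graphml, nodes, edges = export_graph(MolecularNetwork({}, []))
    g = nx.parse_graphml(graphml)
    assert len(g) == 0 and nodes.empty and edges.empty


def test_export_graph_attribute_round_trip():
    a = spectrum("A", 500.0, [100.0], [1.0])
    b = spectrum("B", 510.0, [100.0], [1.0])
    net = MolecularNetwork({"A": a, "B": b},
                           [NetworkEdge("A", "B", 0.85, 6, -10.0)])
    graphml, _, _ = export_graph(
        net,
        annotations={"A": {"lipid_class": "GPI", "shorthand": "LPI 18:0"}},
        proportions={"A": {"hexane": 0.7, "CHCl3": 0.2, "MeOH": 0.1}},
        total_areas={"A": 1e6})
    g = nx.parse_graphml(graphml)
    assert g.nodes["A"]["lipid_class"] == "GPI"
    assert g.nodes["A"]["proportion_hexane"] == pytest.approx(0.7)
    assert g.nodes["B"]["lipid_class"] == "unknown"
    assert g.edges["A", "B"]["cosine"] == pytest.approx(0.85)


def test_export_graph_rejects_bad_proportions():
    a = spectrum("A", 500.0, [100.0], [1.0])
    net = MolecularNetwork({"A": a}, [])
    with pytest.raises(ValueError):
        export_graph(net, proportions={"A": {"hexane": 0.5, "CHCl3": 0.2,
                                             "MeOH": 0.1}})
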