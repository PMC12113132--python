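"""Modified-cosine spectral similarity and molecular-network construction.

The similarity is the modified cosine used by feature-based molecular
networking: peaks of two spectra may match either directly (|Δm/z| ≤
fragment tolerance) or shifted by the precursor-mass difference, and a
maximum-weight one-to-one assignment over all candidate pairs gives the
score.  Peak weights are the (preprocessed, typically square-rooted)
intensities, L2-normalised per spectrum, so identical spectra score 1.

Network construction applies the standard FBMN defaults: cosine ≥ 0.7,
≥ 4 matched peaks, then a mutual top-K neighbour filter (K = 10) and an
iterative split of components larger than 100 nodes by removal of their
weakest edges.  Networks are built within one ionisation polarity.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .spectra import Peak, Spectrum

__all__ = [
    "NetworkParams",
    "NetworkEdge",
    "MolecularNetwork",
    "LibraryMatch",
    "preprocess_spectrum",
    "modified_cosine",
    "build_network",
    "enforce_topology",
    "match_library",
    "export_graph",
]


@dataclass(frozen=True)
class NetworkParams:
    """FBMN networking thresholds (defaults as used for the sea-pen data)."""

    precursor_tol: float = 0.02      # Da
    fragment_tol: float = 0.05       # Da
    min_cosine: float = 0.7
    min_matched_peaks: int = 4
    max_neighbors: int = 10
    max_component: int = 100
    library_min_cosine: float = 0.7
    library_min_peaks: int = 6
    # peak preprocessing (GNPS-style window filter); not part of the
    # published parameter set, exposed with conventional defaults
    window: float = 50.0
    top_k: int = 6

    def __post_init__(self) -> None:
        if self.precursor_tol <= 0 or self.fragment_tol <= 0 or self.window <= 0:
            raise ValueError("tolerances and window must be positive")
        if not 0.0 <= self.min_cosine <= 1.0:
            raise ValueError("min_cosine must lie in [0, 1]")
        if min(self.min_matched_peaks, self.max_neighbors,
               self.max_component, self.top_k) < 1:
            raise ValueError("counts must be >= 1")


@dataclass(frozen=True)
class NetworkEdge:
    node_a: str
    node_b: str
    cosine: float
    n_matched: int
    delta_mz: float

    def key(self) -> Tuple[str, str]:
        return tuple(sorted((self.node_a, self.node_b)))  # type: ignore[return-value]


@dataclass
class MolecularNetwork:
    """Nodes (feature ids with attached spectra) and scored edges."""

    nodes: Dict[str, Spectrum]
    edges: List[NetworkEdge] = field(default_factory=list)

    def degree(self, node: str) -> int:
        return sum(1 for e in self.edges if node in (e.node_a, e.node_b))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.node_a, e.node_b, cosine=e.cosine,
                       n_matched=e.n_matched, delta_mz=e.delta_mz)
        return g

    def components(self) -> List[set]:
        return [set(c) for c in nx.connected_components(self.to_networkx())]


def preprocess_spectrum(s: Spectrum, window: float = 50.0, top_k: int = 6) -> Spectrum:
    """Window filter + square-root intensity transform.

    Keeps the ``top_k`` most intense peaks in each non-overlapping
    ``window``-Da m/z bin, then replaces intensities by their square
    roots (de-emphasising single dominant fragments, as GNPS does).
    """
    if window <= 0 or top_k < 1:
        raise ValueError("window must be > 0 and top_k >= 1")
    bins: Dict[int, List[Peak]] = {}
    for p in s.peaks:
        bins.setdefault(int(p.mz // window), []).append(p)
    kept: List[Peak] = []
    for _, peaks in sorted(bins.items()):
        top = sorted(peaks, key=lambda p: (-p.intensity, p.mz))[:top_k]
        kept.extend(top)
    kept = [Peak(p.mz, math.sqrt(p.intensity)) for p in kept]
    return s.with_peaks(sorted(kept, key=lambda p: p.mz))


def modified_cosine(a: Spectrum, b: Spectrum,
                    fragment_tol: float = 0.05,
                    precursor_tol: float = 0.02) -> Tuple[float, int]:
    """Modified cosine score and matched-peak count for two spectra.

    Candidate peak pairs are those matching directly or shifted by the
    precursor difference; the score is the maximum over one-to-one
    assignments of Σ wᵃ·wᵇ with L2-normalised weights, computed exactly
    via the Hungarian algorithm.  Spectra must share a polarity.
    ``precursor_tol`` is accepted for interface symmetry with the
    network parameters; the precursor shift is always allowed.
    """
    if a.polarity != b.polarity:
        raise ValueError("modified cosine is undefined across polarities")
    if a.is_empty or b.is_empty:
        return 0.0, 0
    wa = np.asarray(a.intensities, dtype=float)
    wb = np.asarray(b.intensities, dtype=float)
    na = np.linalg.norm(wa)
    nb = np.linalg.norm(wb)
    if na == 0 or nb == 0:
        return 0.0, 0
    wa /= na
    wb /= nb
    mza = np.asarray(a.mzs)
    mzb = np.asarray(b.mzs)
    shift = a.precursor_mz - b.precursor_mz
    diff = mza[:, None] - mzb[None, :]
    cand = (np.abs(diff) <= fragment_tol) | (np.abs(diff - shift) <= fragment_tol)
    if not cand.any():
        return 0.0, 0
    score_matrix = np.where(cand, wa[:, None] * wb[None, :], 0.0)
    rows, cols = linear_sum_assignment(score_matrix, maximize=True)
    pair_scores = score_matrix[rows, cols]
    matched = pair_scores > 0
    score = float(pair_scores[matched].sum())
    return min(score, 1.0), int(matched.sum())


def build_network(spectra: Sequence[Spectrum],
                  params: Optional[NetworkParams] = None,
                  preprocess: bool = True) -> MolecularNetwork:
    """Score all same-polarity pairs and keep edges over the thresholds.

    Every spectrum becomes a node regardless of connectivity.  Edges
    require cosine ≥ ``min_cosine`` and ≥ ``min_matched_peaks`` matched
    peaks, then :func:`enforce_topology` is applied.
    """
    if not spectra:
        raise ValueError("build_network requires at least one spectrum")
    params = params or NetworkParams()
    ids = [s.feature_id for s in spectra]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate feature ids among spectra")
    prepped = ([preprocess_spectrum(s, params.window, params.top_k) for s in spectra]
               if preprocess else list(spectra))
    net = MolecularNetwork(nodes={s.feature_id: s for s in spectra})
    for i in range(len(prepped)):
        for j in range(i + 1, len(prepped)):
            si, sj = prepped[i], prepped[j]
            if si.polarity != sj.polarity:
                continue
            score, n = modified_cosine(si, sj, params.fragment_tol,
                                       params.precursor_tol)
            if score >= params.min_cosine and n >= params.min_matched_peaks:
                net.edges.append(NetworkEdge(si.feature_id, sj.feature_id,
                                             score, n,
                                             si.precursor_mz - sj.precursor_mz))
    return enforce_topology(net, params.max_neighbors, params.max_component)


def enforce_topology(net: MolecularNetwork,
                     max_neighbors: int = 10,
                     max_component: int = 100) -> MolecularNetwork:
    """Mutual top-K neighbour filter, then component-size splitting.

    An edge survives the first stage only if each endpoint ranks the
    other within its ``max_neighbors`` best neighbours by cosine (ties
    broken by neighbour id, ascending).  The second stage repeatedly
    removes the lowest-cosine edge (tie-break: lexicographically
    smallest node pair) of any component larger than ``max_component``.
    Filtering order — neighbours first, components second — is fixed.
    """
    # stage 1: mutual top-K by cosine
    ranked: Dict[str, List[str]] = {}
    by_node: Dict[str, List[NetworkEdge]] = {}
    for e in net.edges:
        by_node.setdefault(e.node_a, []).append(e)
        by_node.setdefault(e.node_b, []).append(e)
    for node, edges in by_node.items():
        nbrs = sorted(((e.cosine, e.node_b if e.node_a == node else e.node_a)
                       for e in edges), key=lambda t: (-t[0], t[1]))
        ranked[node] = [n for _, n in nbrs[:max_neighbors]]
    kept = [e for e in net.edges
            if e.node_b in ranked.get(e.node_a, [])
            and e.node_a in ranked.get(e.node_b, [])]

    # stage 2: split oversized components from their weakest edges
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for e in kept:
        g.add_edge(*e.key(), edge=e)
    while True:
        oversized = [c for c in nx.connected_components(g) if len(c) > max_component]
        if not oversized:
            break
        comp = min(oversized, key=lambda c: sorted(c)[0])
        edges_in = [g.edges[u, v]["edge"] for u, v in g.subgraph(comp).edges]
        victim = min(edges_in, key=lambda e: (e.cosine, e.key()))
        g.remove_edge(*victim.key())
    surviving = {e.key() for e in kept} & {tuple(sorted(uv)) for uv in g.edges}
    return MolecularNetwork(nodes=dict(net.nodes),
                            edges=[e for e in kept if e.key() in surviving])


@dataclass(frozen=True)
class LibraryMatch:
    query_id: str
    library_name: str
    cosine: float
    n_matched: int
    precursor_delta: float = 0.0


def match_library(s: Spectrum, library: Sequence[Spectrum],
                  params: Optional[NetworkParams] = None,
                  preprocess: bool = True) -> List[LibraryMatch]:
    """Match one query spectrum against an annotated spectral library.

    Keeps hits with cosine strictly above ``library_min_cosine`` and at
    least ``library_min_peaks`` matched peaks, sorted by cosine
    descending.  Cosine ties (common between homologues, whose spectra
    are precursor-shifted copies) break toward the smaller precursor
    difference.  Library entries of the other polarity are skipped.
    """
    params = params or NetworkParams()
    query = preprocess_spectrum(s, params.window, params.top_k) if preprocess else s
    hits = []
    for entry in library:
        if entry.polarity != query.polarity:
            continue
        lib = (preprocess_spectrum(entry, params.window, params.top_k)
               if preprocess else entry)
        score, n = modified_cosine(query, lib, params.fragment_tol,
                                   params.precursor_tol)
        if score > params.library_min_cosine and n >= params.library_min_peaks:
            name = entry.metadata.get("name", entry.feature_id)
            hits.append(LibraryMatch(s.feature_id, name, score, n,
                                     s.precursor_mz - entry.precursor_mz))
    return sorted(hits, key=lambda h: (-h.cosine, -h.n_matched,
                                       abs(h.precursor_delta), h.library_name))


def export_graph(net: MolecularNetwork,
                 annotations: Optional[Mapping[str, Mapping[str, object]]] = None,
                 proportions: Optional[Mapping[str, Mapping[str, float]]] = None,
                 total_areas: Optional[Mapping[str, float]] = None,
                 ) -> Tuple[str, "pd.DataFrame", "pd.DataFrame"]:
    """Serialize a network to GraphML text plus node/edge tables.

    Node attributes: precursor m/z, RT, lipid class and shorthand (or
    ``unknown``), per-extract abundance proportions and total area.
    Edge attributes: cosine, matched-peak count, precursor Δm/z.
    Per-node proportions must sum to 1 within 1e-9.
    """
    import pandas as pd

    g = nx.Graph()
    node_rows = []
    for fid, s in sorted(net.nodes.items()):
        ann = dict(annotations.get(fid, {})) if annotations else {}
        attrs = {
            "precursor_mz": float(s.precursor_mz),
            "retention_time": float(s.retention_time),
            "polarity": s.polarity,
            "lipid_class": str(ann.get("lipid_class", "unknown")),
            "shorthand": str(ann.get("shorthand", "")),
        }
        if proportions and fid in proportions:
            props = proportions[fid]
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ValueError(f"proportions for node {fid} do not sum to 1")
            for extract, frac in sorted(props.items()):
                attrs[f"proportion_{extract}"] = float(frac)
        if total_areas and fid in total_areas:
            attrs["total_area"] = float(total_areas[fid])
        g.add_node(fid, **attrs)
        node_rows.append({"feature_id": fid, **attrs})
    edge_rows = []
    for e in sorted(net.edges, key=lambda e: e.key()):
        g.add_edge(e.node_a, e.node_b, cosine=float(e.cosine),
                   n_matched=int(e.n_matched), delta_mz=float(e.delta_mz))
        edge_rows.append({"node_a": e.node_a, "node_b": e.node_b,
                          "cosine": e.cosine, "n_matched": e.n_matched,
                          "delta_mz": e.delta_mz})
    buf = io.BytesIO()
    nx.write_graphml(g, buf)
    graphml = buf.getvalue().decode()
    return graphml, pd.DataFrame(node_rows), pd.DataFrame(edge_rows)
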