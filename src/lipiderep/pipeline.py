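"""End-to-end orchestration: read or simulate data, build per-polarity
molecular networks, annotate nodes, aggregate per-extract abundances,
and export GraphML, CSV tables and a JSON run report.

Positive- and negative-mode spectra are never mixed in one network;
each polarity present in the input yields its own graph.  Unannotated
nodes stay in the network with class ``unknown``.  Two runs with the
same inputs and configuration produce identical artifacts (timestamps
are confined to the log).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .annotate import LipidAnnotation, annotate_spectrum
from .network import MolecularNetwork, NetworkParams, build_network, export_graph
from .rules import AnnotationParams, LipidClassRule, builtin_rules
from .spectra import (FeatureRecord, LinkedDataset, Spectrum, link_features,
                      read_feature_table, read_mgf)
from .synth import SimulationConfig, reference_fixture

__all__ = ["PipelineConfig", "ExtractSummary", "RunResult",
           "run_pipeline", "summarize_by_extract", "annotations_table"]

log = logging.getLogger("lipiderep")


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs, thresholds and output location for one pipeline run."""

    mgf_path: Optional[Path] = None
    feature_table_path: Optional[Path] = None
    use_reference_fixture: bool = False
    network: NetworkParams = field(default_factory=NetworkParams)
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    output_dir: Path = Path("lipiderep_out")
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.use_reference_fixture and (
                self.mgf_path is None or self.feature_table_path is None):
            raise ValueError("provide an MGF and a feature table, or enable "
                             "the reference fixture")


@dataclass
class ExtractSummary:
    """Per-class totals and abundance proportions across extracts."""

    table: pd.DataFrame       # class x (extract areas, node count, proportions)

    def class_proportions(self, class_id: str) -> Dict[str, float]:
        row = self.table.loc[self.table["lipid_class"] == class_id]
        if row.empty:
            raise KeyError(class_id)
        return {c.removeprefix("proportion_"): float(row.iloc[0][c])
                for c in self.table.columns if c.startswith("proportion_")}


@dataclass
class RunResult:
    networks: Dict[str, MolecularNetwork]
    annotations: Dict[str, Optional[LipidAnnotation]]
    summary: ExtractSummary
    report: dict
    linked: LinkedDataset


def summarize_by_extract(annotations: Mapping[str, Optional[LipidAnnotation]],
                         features: Mapping[str, FeatureRecord],
                         ) -> ExtractSummary:
    """Aggregate feature areas per lipid class and extract.

    Per-node proportions are area/total-area; per-class proportions are
    the area-weighted aggregate over the class's nodes.  Features with
    zero total area are excluded with a warning; unannotated features
    aggregate under ``unknown``.  Proportions sum to 1 per class.
    """
    extracts = sorted({e for r in features.values() for e in r.abundances})
    rows: Dict[str, Dict[str, float]] = {}
    counts: Dict[str, int] = {}
    for fid, rec in features.items():
        if rec.total_area <= 0:
            log.warning("feature %s has zero total area; excluded from summary",
                        fid)
            continue
        ann = annotations.get(fid)
        class_id = ann.chemical_class if ann is not None else "unknown"
        acc = rows.setdefault(class_id, {e: 0.0 for e in extracts})
        for e in extracts:
            acc[e] += rec.abundances.get(e, 0.0)
        counts[class_id] = counts.get(class_id, 0) + 1
    table_rows = []
    for class_id in sorted(rows):
        areas = rows[class_id]
        total = sum(areas.values())
        row = {"lipid_class": class_id, "n_nodes": counts[class_id],
               "total_area": total}
        for e in extracts:
            row[f"area_{e}"] = areas[e]
            row[f"proportion_{e}"] = areas[e] / total if total else 0.0
        table_rows.append(row)
    return ExtractSummary(pd.DataFrame(table_rows))


def annotations_table(annotations: Mapping[str, Optional[LipidAnnotation]],
                      spectra: Mapping[str, Spectrum]) -> pd.DataFrame:
    """Flat annotation table (one row per feature) for CSV export."""
    rows = []
    for fid in sorted(annotations):
        ann = annotations[fid]
        s = spectra[fid]
        rows.append({
            "feature_id": fid,
            "precursor_mz": s.precursor_mz,
            "retention_time": s.retention_time,
            "polarity": s.polarity,
            "lipid_class": ann.class_id if ann else "unknown",
            "chemical_class": ann.chemical_class if ann else "unknown",
            "shorthand": ann.shorthand if ann else "",
            "ion_formula": ann.precursor_ion_formula.hill() if ann else "",
            "precursor_ppm": round(ann.precursor_ppm, 3) if ann else float("nan"),
            "confidence": ann.confidence if ann else "",
            "n_evidence": len(ann.evidence) if ann else 0,
        })
    return pd.DataFrame(rows)


def _load_inputs(config: PipelineConfig
                 ) -> Tuple[List[Spectrum], List[FeatureRecord]]:
    if config.use_reference_fixture:
        log.info("generating reference fixture (seed=%d)", config.seed)
        return reference_fixture(SimulationConfig(seed=config.seed))
    assert config.mgf_path is not None and config.feature_table_path is not None
    for path in (config.mgf_path, config.feature_table_path):
        if not Path(path).exists():
            raise FileNotFoundError(f"pipeline input not found: {path}")
    return read_mgf(Path(config.mgf_path)), read_feature_table(
        Path(config.feature_table_path))


def run_pipeline(config: PipelineConfig,
                 rules: Optional[Sequence[LipidClassRule]] = None) -> RunResult:
    """Run the full dereplication pipeline and write all artifacts.

    Outputs under ``config.output_dir``: ``network_<polarity>.graphml``
    plus node/edge CSVs per polarity present, ``annotations.csv``,
    ``extract_summary.csv`` and ``run_report.json``.
    """
    rules = list(rules) if rules is not None else builtin_rules()
    spectra, records = _load_inputs(config)
    linked = link_features(spectra, records, warn=False)
    for fid in linked.unmatched_spectra:
        log.warning("spectrum %s has no feature-table row", fid)
    for fid in linked.unmatched_records:
        log.warning("feature-table row %s has no spectrum", fid)
    log.info("loaded %d spectra, %d features, %d joined",
             len(spectra), len(records), linked.n_joined)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    spectra_by_id = {s.feature_id: s for s in spectra}
    features_by_id = {r.feature_id: r for _, r in linked.pairs}

    annotations: Dict[str, Optional[LipidAnnotation]] = {}
    for s in spectra:
        annotations[s.feature_id] = annotate_spectrum(s, rules,
                                                      config.annotation)
    n_annotated = sum(1 for a in annotations.values() if a)
    log.info("annotated %d/%d spectra", n_annotated, len(spectra))

    networks: Dict[str, MolecularNetwork] = {}
    for polarity in ("positive", "negative"):
        subset = [s for s in spectra if s.polarity == polarity]
        if not subset:
            log.warning("no %s-mode spectra; skipping that network", polarity)
            continue
        net = build_network(subset, config.network)
        networks[polarity] = net
        log.info("%s network: %d nodes, %d edges", polarity,
                 len(net.nodes), len(net.edges))
        ann_attrs = {fid: {"lipid_class": a.chemical_class,
                           "shorthand": a.shorthand}
                     for fid, a in annotations.items() if a is not None}
        proportions = {fid: features_by_id[fid].proportions()
                       for fid in net.nodes if fid in features_by_id
                       and features_by_id[fid].total_area > 0}
        areas = {fid: features_by_id[fid].total_area
                 for fid in net.nodes if fid in features_by_id}
        graphml, node_df, edge_df = export_graph(net, ann_attrs, proportions,
                                                 areas)
        tag = polarity
        (out / f"network_{tag}.graphml").write_text(graphml)
        node_df.to_csv(out / f"nodes_{tag}.csv", index=False)
        edge_df.to_csv(out / f"edges_{tag}.csv", index=False)

    ann_df = annotations_table(annotations, spectra_by_id)
    ann_df.to_csv(out / "annotations.csv", index=False)

    summary = summarize_by_extract(annotations, features_by_id)
    summary.table.to_csv(out / "extract_summary.csv", index=False)

    class_counts = (ann_df["lipid_class"].value_counts().to_dict()
                    if not ann_df.empty else {})
    report = {
        "seed": config.seed,
        "n_spectra": len(spectra),
        "n_features": len(records),
        "n_joined": linked.n_joined,
        "n_annotated": n_annotated,
        "n_unannotated": len(spectra) - n_annotated,
        "classes": {k: int(v) for k, v in sorted(class_counts.items())},
        "networks": {p: {"nodes": len(n.nodes), "edges": len(n.edges)}
                     for p, n in networks.items()},
        "params": {
            "network": dataclasses.asdict(config.network),
            "annotation": {k: v for k, v in
                           dataclasses.asdict(config.annotation).items()
                           if not isinstance(v, tuple)},
        },
    }
    (out / "run_report.json").write_text(json.dumps(report, indent=2,
                                                    sort_keys=True) + "\n")
    return RunResult(networks, annotations, summary, report, linked)
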