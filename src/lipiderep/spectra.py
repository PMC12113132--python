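"""Spectrum / feature-table data model and MGF + CSV readers and writers.

The pipeline consumes the two files an FBMN-style preprocessing step
hands over: an MGF with one MS² spectrum per LC-MS feature, and a CSV
quantification table with one row per feature and one peak-area column
per sample.  MGF parsing is delegated to :mod:`pyteomics.mgf`; the
quantification table goes through pandas.  Retention times are minutes
internally (RTINSECONDS is converted on read).
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
from pyteomics import mgf as _mgf

__all__ = [
    "Peak",
    "Spectrum",
    "FeatureRecord",
    "LinkedDataset",
    "SpectrumError",
    "read_mgf",
    "write_mgf",
    "read_feature_table",
    "write_feature_table",
    "link_features",
]

POSITIVE = "positive"
NEGATIVE = "negative"


class SpectrumError(ValueError):
    """Malformed spectrum block or feature-table row."""


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mz) and math.isfinite(self.intensity)):
            raise SpectrumError(f"non-finite peak ({self.mz}, {self.intensity})")
        if self.mz <= 0 or self.intensity < 0:
            raise SpectrumError(f"invalid peak ({self.mz}, {self.intensity})")


@dataclass(frozen=True)
class Spectrum:
    """A precursor-annotated MS² peak list.

    Peaks are stored sorted by m/z; duplicates closer than 1e-6 Da are
    merged on construction (intensities summed).  ``metadata`` carries
    optional fields such as a library compound name.
    """

    feature_id: str
    precursor_mz: float
    polarity: str
    retention_time: float = 0.0
    peaks: Tuple[Peak, ...] = ()
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.polarity not in (POSITIVE, NEGATIVE):
            raise SpectrumError(f"polarity must be positive/negative, got {self.polarity!r}")
        if self.precursor_mz <= 0:
            raise SpectrumError(f"precursor m/z must be > 0, got {self.precursor_mz}")
        if self.retention_time < 0:
            raise SpectrumError(f"retention time must be >= 0, got {self.retention_time}")
        ordered = sorted(self.peaks, key=lambda p: p.mz)
        merged: List[Peak] = []
        for p in ordered:
            if merged and abs(p.mz - merged[-1].mz) < 1e-6:
                merged[-1] = Peak(merged[-1].mz, merged[-1].intensity + p.intensity)
            else:
                merged.append(p)
        object.__setattr__(self, "peaks", tuple(merged))
        object.__setattr__(self, "metadata", dict(self.metadata))

    @property
    def mzs(self) -> List[float]:
        return [p.mz for p in self.peaks]

    @property
    def intensities(self) -> List[float]:
        return [p.intensity for p in self.peaks]

    @property
    def is_empty(self) -> bool:
        return not self.peaks

    def base_peak_intensity(self) -> float:
        return max((p.intensity for p in self.peaks), default=0.0)

    def with_peaks(self, peaks: Iterable[Peak]) -> "Spectrum":
        return replace(self, peaks=tuple(peaks))


@dataclass(frozen=True)
class FeatureRecord:
    """One quantified LC-MS feature: id, m/z, RT and per-sample peak areas."""

    feature_id: str
    precursor_mz: float
    retention_time: float
    abundances: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ab = {str(k): float(v) for k, v in self.abundances.items()}
        for name, area in ab.items():
            if area < 0:
                raise SpectrumError(f"negative area {area} for sample {name!r} "
                                    f"(feature {self.feature_id})")
        if ab and not any(v > 0 for v in ab.values()):
            raise SpectrumError(f"feature {self.feature_id} has all-zero areas")
        object.__setattr__(self, "abundances", ab)

    @property
    def total_area(self) -> float:
        return sum(self.abundances.values())

    def proportions(self) -> Dict[str, float]:
        """Per-sample share of the total area; sums to 1 for non-zero features."""
        tot = self.total_area
        if tot <= 0:
            return {k: 0.0 for k in self.abundances}
        return {k: v / tot for k, v in self.abundances.items()}


# ---------------------------------------------------------------------------
# MGF I/O

def _infer_polarity(params: Mapping) -> Optional[str]:
    charge = params.get("charge")
    if charge:
        try:
            c = int(charge[0]) if isinstance(charge, (list, tuple)) else int(charge)
            return POSITIVE if c > 0 else NEGATIVE
        except (TypeError, ValueError):
            pass
    mode = str(params.get("ion_mode", params.get("ionmode", ""))).lower()
    if mode.startswith("pos"):
        return POSITIVE
    if mode.startswith("neg"):
        return NEGATIVE
    return None


def read_mgf(source: Union[str, Path, io.TextIOBase]) -> List[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum`.

    Polarity comes from ``CHARGE`` (``1+``/``1-``) or ``ION_MODE``;
    retention time from ``RTINSECONDS`` (converted to minutes) or
    ``RTINMINUTES``; the feature id from ``FEATURE_ID`` falling back to
    ``SCANS`` then the block index.  A block without ``PEPMASS`` raises
    :class:`SpectrumError` naming the block; an empty peak list is kept
    and flagged via ``metadata["empty"]``.
    """
    spectra: List[Spectrum] = []
    with _mgf.read(str(source) if isinstance(source, Path) else source,
                   use_index=False, convert_arrays=0) as reader:
        for i, block in enumerate(reader):
            params = block.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                raise SpectrumError(f"MGF block {i} has no PEPMASS")
            precursor = float(pepmass[0] if isinstance(pepmass, (list, tuple)) else pepmass)
            polarity = _infer_polarity(params)
            if polarity is None:
                raise SpectrumError(f"MGF block {i} has neither CHARGE nor ION_MODE")
            if "rtinseconds" in params:
                rt = float(params["rtinseconds"]) / 60.0
            elif "rtinminutes" in params:
                rt = float(params["rtinminutes"])
            else:
                rt = 0.0
            fid = str(params.get("feature_id", params.get("scans", i)))
            peaks = [Peak(float(mz), float(it))
                     for mz, it in zip(block.get("m/z array", []),
                                       block.get("intensity array", []))]
            meta = {}
            if "name" in params:
                meta["name"] = str(params["name"])
            if not peaks:
                meta["empty"] = "true"
            spectra.append(Spectrum(feature_id=fid, precursor_mz=precursor,
                                    polarity=polarity, retention_time=rt,
                                    peaks=tuple(peaks), metadata=meta))
    return spectra


def write_mgf(spectra: Sequence[Spectrum],
              dest: Union[str, Path, io.TextIOBase, None] = None) -> str:
    """Serialize spectra to MGF text (and optionally to ``dest``).

    Inverse of :func:`read_mgf` on the canonical dialect.  Fixed six-
    decimal formatting keeps repeated runs byte-identical.
    """
    buf = io.StringIO()
    for s in spectra:
        buf.write("BEGIN IONS\n")
        buf.write(f"FEATURE_ID={s.feature_id}\n")
        buf.write(f"PEPMASS={s.precursor_mz:.6f}\n")
        buf.write(f"CHARGE=1{'+' if s.polarity == POSITIVE else '-'}\n")
        buf.write(f"RTINSECONDS={s.retention_time * 60.0:.4f}\n")
        if "name" in s.metadata:
            buf.write(f"NAME={s.metadata['name']}\n")
        for p in s.peaks:
            buf.write(f"{p.mz:.6f} {p.intensity:.6f}\n")
        buf.write("END IONS\n\n")
    text = buf.getvalue()
    if dest is not None:
        if isinstance(dest, (str, Path)):
            Path(dest).write_text(text)
        else:
            dest.write(text)
    return text


# ---------------------------------------------------------------------------
# Quantification-table I/O (MZmine/FBMN export dialect)

_ID_COL = "row ID"
_MZ_COL = "row m/z"
_RT_COL = "row retention time"
_AREA_SUFFIX = " Peak area"


def read_feature_table(source: Union[str, Path, io.TextIOBase]) -> List[FeatureRecord]:
    """Read an FBMN-style quantification CSV into feature records.

    Expects columns ``row ID``, ``row m/z``, ``row retention time`` and
    one ``<sample> Peak area`` column per sample.  Duplicate feature
    ids, negative areas and all-zero rows raise :class:`SpectrumError`.
    """
    df = pd.read_csv(source)
    missing = [c for c in (_ID_COL, _MZ_COL, _RT_COL) if c not in df.columns]
    if missing:
        raise SpectrumError(f"feature table lacks required columns: {missing}")
    area_cols = [c for c in df.columns if c.endswith(_AREA_SUFFIX)]
    if not area_cols:
        raise SpectrumError("feature table has no '<sample> Peak area' columns")
    samples = [c[: -len(_AREA_SUFFIX)] for c in area_cols]
    ids = df[_ID_COL].astype(str)
    dupes = ids[ids.duplicated()].tolist()
    if dupes:
        raise SpectrumError(f"duplicate feature ids in table: {sorted(set(dupes))}")
    records = []
    for _, row in df.iterrows():
        abundances = {s: float(row[c]) for s, c in zip(samples, area_cols)}
        records.append(FeatureRecord(feature_id=str(row[_ID_COL]),
                                     precursor_mz=float(row[_MZ_COL]),
                                     retention_time=float(row[_RT_COL]),
                                     abundances=abundances))
    return records


def write_feature_table(records: Sequence[FeatureRecord],
                        dest: Union[str, Path, io.TextIOBase, None] = None,
                        samples: Optional[Sequence[str]] = None) -> str:
    """Serialize feature records to the same CSV dialect; returns the text."""
    if samples is None:
        samples = sorted({s for r in records for s in r.abundances})
    rows = []
    for r in records:
        row = {_ID_COL: r.feature_id,
               _MZ_COL: f"{r.precursor_mz:.6f}",
               _RT_COL: f"{r.retention_time:.4f}"}
        for s in samples:
            row[f"{s}{_AREA_SUFFIX}"] = f"{r.abundances.get(s, 0.0):.6f}"
        rows.append(row)
    cols = [_ID_COL, _MZ_COL, _RT_COL] + [f"{s}{_AREA_SUFFIX}" for s in samples]
    df = pd.DataFrame(rows, columns=cols)
    text = df.to_csv(index=False)
    if dest is not None:
        if isinstance(dest, (str, Path)):
            Path(dest).write_text(text)
        else:
            dest.write(text)
    return text


# ---------------------------------------------------------------------------
# Joining

@dataclass
class LinkedDataset:
    """Spectra joined to feature records by feature id."""

    pairs: List[Tuple[Spectrum, FeatureRecord]]
    unmatched_spectra: List[str]
    unmatched_records: List[str]

    @property
    def n_joined(self) -> int:
        return len(self.pairs)


def link_features(spectra: Sequence[Spectrum],
                  records: Sequence[FeatureRecord],
                  warn: bool = True) -> LinkedDataset:
    """Pair each spectrum with at most one feature record by id.

    Id-only matching is deliberate: the FBMN handoff guarantees shared
    ids, and m/z-RT tolerance matching silently mispairs isobaric
    features.  Unmatched items are reported (warnings), never an error.
    """
    by_id = {r.feature_id: r for r in records}
    if len(by_id) != len(records):
        raise SpectrumError("duplicate feature ids among records")
    sids = [s.feature_id for s in spectra]
    if len(set(sids)) != len(sids):
        raise SpectrumError("duplicate feature ids among spectra")
    pairs, unmatched_spectra = [], []
    for s in spectra:
        rec = by_id.pop(s.feature_id, None)
        if rec is None:
            unmatched_spectra.append(s.feature_id)
        else:
            pairs.append((s, rec))
    unmatched_records = sorted(by_id)
    if warn:
        for fid in unmatched_spectra:
            warnings.warn(f"spectrum {fid} has no feature-table row", stacklevel=2)
        for fid in unmatched_records:
            warnings.warn(f"feature-table row {fid} has no spectrum", stacklevel=2)
    return LinkedDataset(pairs, unmatched_spectra, unmatched_records)
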