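"""Reading and writing of feature tables and consensus outputs.

Two input dialects are supported: the OpenMS featureXML format (the output of
upstream feature detection) and a plain TSV peak table (columns ``feature_id``,
``rt``, ``mz``, ``intensity``; one row per peak).  Retention times are always
seconds and are never rescaled on read or write.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from lxml import etree

logger = logging.getLogger("gwalign")

TSV_COLUMNS = ("feature_id", "rt", "mz", "intensity")
CONSENSUS_COLUMNS = ("consensus_id", "source_id", "feature_id",
                     "centroid_rt", "centroid_mz")


class FormatError(ValueError):
    """Malformed or schema-violating input file."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peak:
    """A single weighted signal point in the (RT, m/z) plane.

    Parameters
    ----------
    rt : float
        Retention time in seconds.
    mz : float
        Mass-to-charge ratio in Da.
    intensity : float
        Nonnegative signal abundance (arbitrary units).
    """

    rt: float
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.rt) and math.isfinite(self.mz)):
            raise ValueError(f"peak position not finite: rt={self.rt}, mz={self.mz}")
        if not (self.intensity >= 0):
            raise ValueError(f"negative peak intensity: {self.intensity}")


@dataclass
class Feature:
    """A detected LC-MS feature: a finite set of peaks attributed to one analyte."""

    id: str
    peaks: list[Peak]
    charge: int | None = None
    annotations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError(f"feature {self.id!r} has no peaks")
        if not any(p.intensity > 0 for p in self.peaks):
            raise ValueError(f"feature {self.id!r} has zero total intensity")

    @property
    def total_intensity(self) -> float:
        return sum(p.intensity for p in self.peaks)

    def rt_span(self) -> float:
        rts = [p.rt for p in self.peaks]
        return max(rts) - min(rts)

    def mz_span(self) -> float:
        mzs = [p.mz for p in self.peaks]
        return max(mzs) - min(mzs)


@dataclass
class FeatureSet:
    """All detected features of one chromatogram.  RT unit is seconds."""

    source_id: str
    features: list[Feature]

    def __post_init__(self) -> None:
        if not self.source_id:
            raise ValueError("source_id must be nonempty")
        ids = [f.id for f in self.features]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate feature id {dup!r} in {self.source_id!r}")

    def __len__(self) -> int:
        return len(self.features)


@dataclass
class GroundTruth:
    """Reference consensus features: sets of (source_id, feature_id) pairs."""

    consensus_sets: list[set[tuple[str, str]]]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for s in self.consensus_sets:
            if len({src for src, _ in s}) < 2:
                raise ValueError(
                    f"ground-truth consensus {sorted(s)} references < 2 chromatograms")
            for member in s:
                if member in seen:
                    raise ValueError(f"feature {member} appears in two consensus sets")
                seen.add(member)


# ---------------------------------------------------------------------------
# featureXML
# ---------------------------------------------------------------------------

def _localname(el: etree._Element) -> str:
    if not isinstance(el.tag, str):
        return ""  # comment or processing instruction
    return etree.QName(el).localname


def read_featurexml(path: str | Path) -> FeatureSet:
    """Read an OpenMS featureXML file into a :class:`FeatureSet`.

    Each ``<feature>`` becomes one :class:`Feature`; its peaks are the
    convex-hull points of the feature (all ``<convexhull>`` elements pooled),
    with the feature's total intensity apportioned uniformly over them, since
    hull points carry no per-point intensity of their own.  Hull point ``x`` is
    RT in seconds and ``y`` is m/z, following the OpenMS convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path}: malformed XML: {exc}") from exc

    features: list[Feature] = []
    for el in tree.iter():
        if _localname(el) != "feature":
            continue
        if any(_localname(a) == "feature" for a in el.iterancestors()):
            continue  # subordinate features belong to their parent
        fid = el.get("id") or f"feature_{len(features)}"
        positions: dict[int, float] = {}
        intensity = None
        charge = None
        pts: list[tuple[float, float]] = []
        for child in el.iter():
            name = _localname(child)
            if name == "position":
                positions[int(child.get("dim"))] = float(child.text)
            elif name == "intensity" and intensity is None:
                intensity = float(child.text)
            elif name == "charge" and charge is None:
                charge = int(child.text)
            elif name == "pt":
                pts.append((float(child.get("x")), float(child.get("y"))))
        if not pts:
            if 0 not in positions or 1 not in positions:
                raise FormatError(
                    f"{path}: feature {fid!r} has neither hull points nor a "
                    f"complete <position> pair")
            pts = [(positions[0], positions[1])]
        total = intensity if intensity is not None else 1.0
        if total <= 0:
            total = 1.0
        per_point = total / len(pts)
        peaks = [Peak(rt=x, mz=y, intensity=per_point) for x, y in pts]
        features.append(Feature(id=fid, peaks=peaks, charge=charge))

    if not features:
        logger.warning("featureXML file %s contains no features", path)
    return FeatureSet(source_id=path.stem, features=features)


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------

def read_feature_tsv(path: str | Path) -> FeatureSet:
    """Read the plain TSV peak-table dialect (one row per peak)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    for col in ("rt", "mz", "intensity"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, after header
            raise FormatError(f"{path}: non-numeric {col!r} at line {row}")
        if vals.isna().any():
            row = int(vals.isna().idxmax()) + 2
            raise FormatError(f"{path}: empty {col!r} at line {row}")
        df[col] = vals
    features = []
    for fid, grp in df.groupby("feature_id", sort=False):
        peaks = [Peak(rt=r.rt, mz=r.mz, intensity=r.intensity)
                 for r in grp.itertuples()]
        features.append(Feature(id=str(fid), peaks=peaks))
    if not features:
        logger.warning("feature TSV %s contains no rows", path)
    return FeatureSet(source_id=path.stem, features=features)


def write_feature_tsv(fset: FeatureSet, path: str | Path) -> None:
    """Write a FeatureSet in the TSV peak-table dialect (inverse of read)."""
    rows = [(f.id, p.rt, p.mz, p.intensity)
            for f in fset.features for p in f.peaks]
    df = pd.DataFrame(rows, columns=list(TSV_COLUMNS))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_consensus(consensus: Sequence, path: str | Path) -> None:
    """Write consensus features as TSV, one row per member feature.

    Rows are ordered by (consensus_id, source_id) so identical inputs yield
    byte-identical files.
    """
    rows = []
    for cf in consensus:
        for (src, fid) in sorted(cf.members):
            rows.append((cf.consensus_id, src, fid,
                         round(cf.centroid_rt, 6), round(cf.centroid_mz, 6)))
    rows.sort(key=lambda r: (str(r[0]), r[1], r[2]))
    df = pd.DataFrame(rows, columns=list(CONSENSUS_COLUMNS))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    """Read a TSV of (consensus_id, source_id, feature_id) into GroundTruth."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("consensus_id", "source_id", "feature_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if df.duplicated(subset=["source_id", "feature_id"]).any():
        dup = df[df.duplicated(subset=["source_id", "feature_id"])].iloc[0]
        raise ValueError(
            f"{path}: ({dup.source_id}, {dup.feature_id}) appears twice")
    sets = [
        {(r.source_id, r.feature_id) for r in grp.itertuples()}
        for _, grp in df.groupby("consensus_id", sort=False)
    ]
    return GroundTruth(consensus_sets=sets)


def read_consensus_tsv(path: str | Path) -> list[tuple[str, set[tuple[str, str]]]]:
    """Read a consensus TSV back as (consensus_id, membership set) pairs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for cid, grp in df.groupby("consensus_id", sort=False):
        out.append((str(cid), {(r.source_id, r.feature_id) for r in grp.itertuples()}))
    return out


def read_annotations(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    """Read identification annotations: TSV columns label, source_id, feature_id."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    for col in ("label", "source_id", "feature_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    out: dict[str, list[tuple[str, str]]] = {}
    for r in df.itertuples():
        out.setdefault(r.label, []).append((r.source_id, r.feature_id))
    return out
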