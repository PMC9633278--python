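"""Feature preprocessing: centroids, RT scaling, unit-mass measures.

RT varies over hundreds to thousands of seconds while m/z envelopes span a few
Da, so distances mixing the two axes are meaningless until RT is rescaled.  The
scaling factor is proportional to the ratio of the average feature extent along
RT to the average extent along m/z, which brings the two axes to a comparable
order of magnitude.  After scaling, each feature is normalised to a unit-mass
discrete measure — the operand of all transport computations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import Feature, FeatureSet, Peak

logger = logging.getLogger("gwalign")


@dataclass(frozen=True)
class ScalingInfo:
    """RT scaling: scaled_rt = rt / factor.

    ``factor`` has units of seconds per m/z-equivalent unit;
    ``proportionality_constant`` is the user-tunable multiplier applied to the
    span ratio (default 1.0).
    """

    factor: float
    proportionality_constant: float = 1.0

    def __post_init__(self) -> None:
        if not self.factor > 0:
            raise ValueError(f"scaling factor must be positive, got {self.factor}")


@dataclass(frozen=True)
class Measure:
    """A unit-mass discrete measure over scaled (rt, mz) points."""

    points: np.ndarray   # (n, 2): columns rt_scaled, mz
    weights: np.ndarray  # (n,), nonnegative, sums to 1

    def __post_init__(self) -> None:
        if self.points.shape[0] != self.weights.shape[0] or self.points.shape[0] < 1:
            raise ValueError("points and weights must be nonempty and congruent")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if abs(float(self.weights.sum()) - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {self.weights.sum()}, expected 1")


def compute_centroid(f: Feature) -> tuple[float, float]:
    """Intensity-weighted mean peak position (rt, mz) of a feature."""
    w = np.array([p.intensity for p in f.peaks], dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError(f"feature {f.id!r} has zero total intensity")
    rt = float(np.dot(w, [p.rt for p in f.peaks]) / total)
    mz = float(np.dot(w, [p.mz for p in f.peaks]) / total)
    return rt, mz


def estimate_rt_scaling(sets: list[FeatureSet], k: float = 1.0) -> ScalingInfo:
    """Estimate the RT scaling factor from feature spans.

    factor = k * mean(RT spans) / mean(m/z spans), spans taken max-min over
    each feature's peaks.  Features with zero m/z span (single-m/z features)
    are excluded from the width average to avoid biasing it toward zero;
    zero-RT-span features are likewise excluded from the length average.
    """
    rt_spans = []
    mz_spans = []
    n_features = 0
    for s in sets:
        for f in s.features:
            n_features += 1
            rs, ms = f.rt_span(), f.mz_span()
            if rs > 0:
                rt_spans.append(rs)
            if ms > 0:
                mz_spans.append(ms)
    if n_features == 0:
        raise ValueError("no features to estimate RT scaling from")
    if not mz_spans:
        raise ValueError(
            "all features have zero m/z span; supply an explicit scaling factor")
    mean_rt = float(np.mean(rt_spans)) if rt_spans else 0.0
    if mean_rt == 0:
        raise ValueError(
            "all features have zero RT span; supply an explicit scaling factor")
    factor = k * mean_rt / float(np.mean(mz_spans))
    logger.info("estimated RT scaling factor %.6g (k=%g)", factor, k)
    return ScalingInfo(factor=factor, proportionality_constant=k)


def apply_scaling(s: FeatureSet, info: ScalingInfo) -> FeatureSet:
    """Return a copy of the set with every peak's RT divided by the factor."""
    scaled = [
        Feature(
            id=f.id,
            peaks=[Peak(rt=p.rt / info.factor, mz=p.mz, intensity=p.intensity)
                   for p in f.peaks],
            charge=f.charge,
            annotations=list(f.annotations),
        )
        for f in s.features
    ]
    return FeatureSet(source_id=s.source_id, features=scaled)


def to_measure(f: Feature) -> Measure:
    """Normalise a (scaled) feature to a unit-mass measure."""
    pts = np.array([[p.rt, p.mz] for p in f.peaks], dtype=float)
    w = np.array([p.intensity for p in f.peaks], dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError(f"feature {f.id!r} has zero total intensity")
    return Measure(points=pts, weights=w / total)
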