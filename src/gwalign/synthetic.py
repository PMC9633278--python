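"""Synthetic chromatograms with isotopic-envelope-like features.

The generator emulates what upstream feature detection hands to the aligner: a
feature is a grid of peaks at m/z values mz0 + k/z (isotopologues of a
z-charged analyte), each isotope trace sampled along RT at the scan interval
with a Gaussian elution profile, and intensity falling off geometrically
across the envelope.  It makes no attempt at chemically accurate isotope
abundances or sequence-based RT prediction — it reproduces the geometry the
aligner exploits, not the chemistry.

The drift simulator applies the protocol used to study elution-order swaps:
every feature is rigidly shifted by an independent uniform draw within
(-rt_range, +rt_range) seconds and (-mz_range, +mz_range) Da, with the true
feature pairing retained as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import Feature, FeatureSet, Peak


@dataclass(frozen=True)
class DriftParams:
    """Uniform per-feature drift: half-widths of the RT and m/z shifts."""

    rt_range: float = 150.0   # seconds
    mz_range: float = 0.3     # Da
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rt_range < 0 or self.mz_range < 0:
            raise ValueError("drift ranges must be nonnegative")


@dataclass(frozen=True)
class GeneratorParams:
    """Defaults describe a moderately dense nanoflow-style run."""

    n_features: int = 200
    mz_min: float = 300.0     # Da
    mz_max: float = 1100.0
    rt_min: float = 0.0       # seconds
    rt_max: float = 2000.0
    charge_min: int = 1
    charge_max: int = 3
    n_isotopes: int = 4
    envelope_decay: float = 0.7   # geometric ratio across isotopes
    elution_sigma: float = 10.0   # seconds; nanoflow peptide peaks ~40 s wide
    scan_interval: float = 3.0    # seconds; typical MS1 survey cycle
    intensity_scale: float = 1e4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1 or self.n_isotopes < 1:
            raise ValueError("n_features and n_isotopes must be positive")
        if not (self.mz_max > self.mz_min and self.rt_max > self.rt_min):
            raise ValueError("windows must be nonempty")
        if min(self.envelope_decay, self.elution_sigma, self.scan_interval,
               self.intensity_scale) <= 0:
            raise ValueError("decay, sigma, scan interval, scale must be positive")


def _build_feature(fid: str, mz0: float, rt_center: float, charge: int,
                   p: GeneratorParams, envelope: np.ndarray | None = None,
                   scale: float = 1.0) -> Feature:
    if envelope is None:
        envelope = p.envelope_decay ** np.arange(p.n_isotopes)
    half = 2.0 * p.elution_sigma
    n_scans = int(np.floor(2 * half / p.scan_interval)) + 1
    rts = rt_center - half + p.scan_interval * np.arange(n_scans)
    elution = np.exp(-0.5 * ((rts - rt_center) / p.elution_sigma) ** 2)
    peaks = []
    for k, env in enumerate(envelope):
        mz = mz0 + k / charge
        for rt, el in zip(rts, elution):
            peaks.append(Peak(rt=float(rt), mz=float(mz),
                              intensity=float(p.intensity_scale * scale * env * el)))
    return Feature(id=fid, peaks=peaks, charge=charge)


def generate_chromatogram(
    p: GeneratorParams | None = None,
) -> tuple[FeatureSet, list[dict]]:
    """Generate one chromatogram plus a catalog of the true feature parameters."""
    p = p or GeneratorParams()
    rng = np.random.default_rng(p.seed)
    features = []
    catalog = []
    for i in range(p.n_features):
        mz0 = float(rng.uniform(p.mz_min, p.mz_max))
        rt_center = float(rng.uniform(p.rt_min, p.rt_max))
        charge = int(rng.integers(p.charge_min, p.charge_max + 1))
        scale = float(rng.uniform(0.5, 2.0))
        fid = f"f{i}"
        features.append(_build_feature(fid, mz0, rt_center, charge, p, scale=scale))
        catalog.append({"feature_id": fid, "mz0": mz0, "rt_center": rt_center,
                        "charge": charge, "scale": scale})
    return FeatureSet(source_id=f"synthetic_seed{p.seed}", features=features), catalog


def simulate_drift(
    s: FeatureSet, d: DriftParams
) -> tuple[FeatureSet, list[tuple[str, str]]]:
    """Rigidly shift every feature by independent uniform RT and m/z draws.

    Returns the drifted set (source_id suffixed ``_drifted``, feature ids
    preserved) and the true pairing as (original id, drifted id) tuples.
    """
    rng = np.random.default_rng(d.seed)
    drifted = []
    pairing = []
    for f in s.features:
        drt = float(rng.uniform(-d.rt_range, d.rt_range)) if d.rt_range else 0.0
        dmz = float(rng.uniform(-d.mz_range, d.mz_range)) if d.mz_range else 0.0
        peaks = [Peak(rt=p.rt + drt, mz=p.mz + dmz, intensity=p.intensity)
                 for p in f.peaks]
        drifted.append(Feature(id=f.id, peaks=peaks, charge=f.charge))
        pairing.append((f.id, f.id))
    return (FeatureSet(source_id=s.source_id + "_drifted", features=drifted),
            pairing)


def make_swap_scenario(
    gap: float = 30.0,
    p: GeneratorParams | None = None,
) -> tuple[FeatureSet, FeatureSet, list[tuple[str, str]]]:
    """Two same-m/z features whose elution order reverses between runs.

    Run A holds feature ``f1`` at rt0 and ``f2`` at rt0 + gap; in run B, f1
    stays put and f2 shifts by -2*gap, reversing the order.  The two features
    sit on the same m/z grid with *symmetric but differently shaped* isotope
    envelopes (peaked vs. broad), so their intensity-weighted centroids
    coincide up to the RT offset and any centroid-based cost (Euclidean or
    l1) is exactly ambiguous between the correct and crossed pairings:
    0 + 2*gap versus gap + gap.  The transport distance sees the envelope
    shapes and is not ambiguous.

    Returns run A, run B, and the true (swapped) pairing.
    """
    if gap == 0:
        raise ValueError("gap must be nonzero")
    p = p or GeneratorParams()
    rt0 = (p.rt_min + p.rt_max) / 2.0
    mz0 = (p.mz_min + p.mz_max) / 2.0
    charge = max(p.charge_min, 1)
    peaked = np.array([0.1, 0.2, 0.4, 0.2, 0.1])
    broad = np.array([0.3, 0.15, 0.1, 0.15, 0.3])
    a = FeatureSet(source_id="swapA", features=[
        _build_feature("f1", mz0, rt0, charge, p, envelope=peaked),
        _build_feature("f2", mz0, rt0 + gap, charge, p, envelope=broad),
    ])
    b = FeatureSet(source_id="swapB", features=[
        _build_feature("f1", mz0, rt0, charge, p, envelope=peaked),
        _build_feature("f2", mz0, rt0 - gap, charge, p, envelope=broad),
    ])
    return a, b, [("f1", "f1"), ("f2", "f2")]
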