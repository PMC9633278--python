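"""Alignment quality metrics.

Alignment precision and recall generalize classification precision/recall to
consensus features.  For each ground-truth consensus set G, the tool consensus
t* with the largest intersection with G is selected (ties broken toward the
smaller t*); recall(G) = |t* ∩ G| / |G| measures how completely G was
recovered, precision(G) = |t* ∩ G| / |t*| measures how much foreign signal was
admixed.  Both are averaged arithmetically over all ground-truth sets, and the
F-score is their harmonic mean.

Identification recall (IR) scores alignments against MS/MS identifications: an
identification repeating over >= 2 chromatograms of a subset counts as
properly aligned when all its annotated features in the subset fall into a
single tool consensus.

Swap statistics quantify elution-order reversals between two runs: a pair of
true correspondences is swapped when the RT order of the two features differs
between the runs, and a swapped pair is resolved when the matcher recovers
both of its correspondences.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .io_formats import GroundTruth


@dataclass
class EvalReport:
    precision: float
    recall: float
    f_score: float
    per_consensus: list[dict]
    identification_recall: float | None = None
    swap_fraction: float | None = None


def f_score(p: float, r: float) -> float:
    """Harmonic mean of alignment precision and recall; 0 when both are 0."""
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


def _membership_sets(tool) -> list[set[tuple[str, str]]]:
    out = []
    for t in tool:
        out.append(t.members if hasattr(t, "members") else set(t))
    return out


def alignment_precision_recall(
    gt: GroundTruth, tool: Sequence
) -> tuple[float, float, list[dict]]:
    """Mean per-ground-truth-set precision and recall against tool consensus.

    ``tool`` may be ConsensusFeature objects or plain membership sets.
    A ground-truth set intersected by no tool consensus scores (0, 0).
    """
    if not gt.consensus_sets:
        raise ValueError("empty ground truth")
    tool_sets = _membership_sets(tool)
    per = []
    for g in gt.consensus_sets:
        best, best_inter = None, 0
        for t in tool_sets:
            inter = len(t & g)
            if inter > best_inter or (
                    inter == best_inter and inter > 0 and best is not None
                    and len(t) < len(best)):
                best, best_inter = t, inter
        if best is None:
            per.append({"gt": sorted(g), "precision": 0.0, "recall": 0.0})
        else:
            per.append({
                "gt": sorted(g),
                "precision": best_inter / len(best),
                "recall": best_inter / len(g),
            })
    p = sum(d["precision"] for d in per) / len(per)
    r = sum(d["recall"] for d in per) / len(per)
    return p, r, per


def evaluate(gt: GroundTruth, tool: Sequence) -> EvalReport:
    p, r, per = alignment_precision_recall(gt, tool)
    return EvalReport(precision=p, recall=r, f_score=f_score(p, r),
                      per_consensus=per)


def identification_recall(
    annotated: dict[str, list[tuple[str, str]]],
    tool: Sequence,
    subset: set[str],
) -> float | None:
    """Fraction of repeating identifications grouped into one tool consensus.

    An identification repeats over ``subset`` when it annotates features in at
    least two of its chromatograms; it is properly aligned when all those
    features lie within a single tool consensus.  Returns None when no
    identification repeats (the ratio is undefined).
    """
    if len(subset) < 2:
        raise ValueError("subset must contain >= 2 chromatograms")
    tool_sets = _membership_sets(tool)
    repeating = 0
    aligned = 0
    for label, feats in annotated.items():
        within = {(src, fid) for src, fid in feats if src in subset}
        if len({src for src, _ in within}) < 2:
            continue
        repeating += 1
        if any(within <= t for t in tool_sets):
            aligned += 1
    if repeating == 0:
        return None
    return aligned / repeating


def swap_fraction(pairing: Sequence[tuple[float, float]]) -> float:
    """Fraction of correspondence pairs whose RT order reverses between runs.

    ``pairing`` holds (rt in run A, rt in run B) per true correspondence.
    Over all unordered pairs of correspondences, a pair is swapped when the
    sign of the A-side RT difference differs from the B-side sign; exact ties
    count as non-swaps.
    """
    if len(pairing) < 2:
        raise ValueError("need >= 2 correspondences to count swaps")
    swapped = 0
    total = 0
    for (a1, b1), (a2, b2) in combinations(pairing, 2):
        total += 1
        da, db = a1 - a2, b1 - b2
        if da * db < 0:
            swapped += 1
    return swapped / total


def swapped_pairs(
    pairing: Sequence[tuple[str, str, float, float]]
) -> list[tuple[int, int]]:
    """Indices of swapped correspondence pairs.

    ``pairing`` rows are (feature id A, feature id B, rt A, rt B).
    """
    out = []
    for (i, (_, _, a1, b1)), (j, (_, _, a2, b2)) in combinations(
            enumerate(pairing), 2):
        if (a1 - a2) * (b1 - b2) < 0:
            out.append((i, j))
    return out


def swap_resolution_rate(
    true_pairing: Sequence[tuple[str, str]],
    tool_pairs: Iterable[tuple[str, str]],
    swapped: Sequence[tuple[int, int]],
) -> float | None:
    """Fraction of swapped pairs whose both correspondences were recovered.

    ``true_pairing`` lists the true (A feature, B feature) correspondences,
    ``tool_pairs`` the matcher's output, ``swapped`` index pairs into
    ``true_pairing`` as returned by :func:`swapped_pairs`.  Returns None when
    no pair is swapped.
    """
    if not swapped:
        return None
    recovered = set(tool_pairs)
    resolved = sum(
        1 for i, j in swapped
        if true_pairing[i] in recovered and true_pairing[j] in recovered)
    return resolved / len(swapped)
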