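"""Consensus-feature construction by clustering plus min-cost-flow matching.

With more than two chromatograms the pipeline is: scale RT, cluster all
feature centroids into consensus candidates (mini-batch k-means overclusters,
then agglomerative merging with a distance threshold), and iterate over
chromatograms; in each iteration the current chromatogram's features (L side)
are matched against the pooled features of all other chromatograms (R side)
through their clusters by a minimum-cost maximum-flow computation.  A trash
node lets any feature stay unmatched at fixed cost c, which bounds how bad a
match the optimizer will accept.  Consensus features are the per-cluster
unions of matched features across iterations.

With exactly two chromatograms the cluster layer is unnecessary and features
are matched directly (optimal bipartite matching with a trash option).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.cluster import AgglomerativeClustering, MiniBatchKMeans

from .io_formats import Feature, FeatureSet
from .preprocess import apply_scaling, compute_centroid, estimate_rt_scaling
from .transport import DistanceCache, GWDParams, pairwise_costs

logger = logging.getLogger("gwalign")


@dataclass
class AlignConfig:
    """All tunables of the alignment pipeline.

    Derived defaults (resolved at run time): trash_cost = 1.9*lam (just under
    the 2*lam GWD saturation), window = 2*lam, cluster_cut = lam/4.  The
    cluster cut approximates the typical centroid drift between replicate
    runs in scaled l1 units; cutting much wider merges distinct analytes into
    one cluster, and because every cluster admits at most one match per
    iteration, overmerged clusters directly cap how many features can be
    matched.
    """

    lam: float = 15.0
    eps: float | None = None
    tol: float = 1e-6
    max_iter: int = 5000
    trash_cost: float | None = None
    rt_scale_k: float = 1.0
    window: float | None = None
    overcluster: float = 2.0
    cluster_cut: float | None = None
    cost_scale: float = 1e4
    seed: int = 42
    keep_singletons: bool = False

    @property
    def gwd_params(self) -> GWDParams:
        return GWDParams(lam=self.lam, eps=self.eps, tol=self.tol,
                         max_iter=self.max_iter)

    @property
    def c(self) -> float:
        return self.trash_cost if self.trash_cost is not None else 1.9 * self.lam

    @property
    def cut(self) -> float:
        return self.cluster_cut if self.cluster_cut is not None else self.lam / 4.0


@dataclass
class ClusterAssignment:
    """Feature -> cluster labels, cluster indices contiguous in 0..s-1."""

    labels: dict[tuple[str, str], int]
    s: int


@dataclass
class Matching:
    """Result of one min-cost-flow iteration for a single L chromatogram."""

    pairs: list[tuple[str, int]]          # (L feature id, cluster index)
    costs: dict[str, float]               # realized GWD per matched L feature
    unmatched: list[str]                  # trashed L feature ids
    flow_cost: int = 0                    # integer network objective


@dataclass
class ConsensusFeature:
    """A set of mutually corresponding features, at most one per chromatogram."""

    consensus_id: str
    members: set[tuple[str, str]]
    cluster: int | None = None
    centroid_rt: float = 0.0
    centroid_mz: float = 0.0

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("consensus feature must have >= 1 member")
        sources = [src for src, _ in self.members]
        if len(sources) != len(set(sources)):
            raise ValueError(
                f"consensus {self.consensus_id}: two features from one chromatogram")


@dataclass
class FlowNetwork:
    """The matching flow network around one target chromatogram.

    Node names: "S" (source), "T" (sink), "Tr" (trash), ("L", fid),
    ("R", src, fid), ("C", k).  Costs are integers (GWD scaled by
    ``cost_scale`` and rounded) as required by the network simplex.
    """

    graph: nx.DiGraph
    n: int
    m: int
    s: int
    c_scaled: int
    cost_scale: float
    cluster_of_r: dict[tuple[str, str], int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Centroid clustering
# ---------------------------------------------------------------------------

def cluster_centroids(
    centroids: list[tuple[np.ndarray, str, str]],
    cfg: AlignConfig,
    n_chromatograms: int,
) -> ClusterAssignment:
    """Two-stage clustering of scaled feature centroids.

    Stage 1 overclusters with mini-batch k-means,
    k = ceil(total / n_chromatograms) * overcluster (clamped to the point
    count); stage 2 merges the k-means centers by average-linkage
    agglomerative clustering with Manhattan distance threshold cluster_cut.
    """
    if not centroids:
        raise ValueError("no centroids to cluster")
    pts = np.array([c[0] for c in centroids], dtype=float)
    n_pts = pts.shape[0]
    k = int(np.ceil(n_pts / max(n_chromatograms, 1)) * cfg.overcluster)
    if k > n_pts:
        logger.warning("k-means k=%d exceeds point count %d; clamping", k, n_pts)
        k = n_pts
    k = max(k, 1)

    if n_pts == 1 or k == 1:
        km_labels = np.zeros(n_pts, dtype=int)
        centers = pts.mean(axis=0, keepdims=True)
    else:
        km = MiniBatchKMeans(n_clusters=k, random_state=cfg.seed, n_init=3,
                             batch_size=max(256, min(1024, n_pts)))
        km_labels = km.fit_predict(pts)
        centers = km.cluster_centers_
    used = np.unique(km_labels)
    centers = centers[used]
    remap = {int(old): i for i, old in enumerate(used)}
    km_labels = np.array([remap[int(l)] for l in km_labels])

    if centers.shape[0] == 1:
        merge = np.zeros(1, dtype=int)
    else:
        agg = AgglomerativeClustering(
            n_clusters=None, distance_threshold=cfg.cut,
            metric="manhattan", linkage="average")
        merge = agg.fit_predict(centers)

    final = merge[km_labels]
    uniq = np.unique(final)
    relabel = {int(old): i for i, old in enumerate(uniq)}
    labels = {
        (src, fid): relabel[int(final[i])]
        for i, (_, src, fid) in enumerate(centroids)
    }
    return ClusterAssignment(labels=labels, s=len(uniq))


# ---------------------------------------------------------------------------
# Flow network
# ---------------------------------------------------------------------------

def _scale_cost(value: float, scale: float) -> int:
    return int(round(value * scale))


def build_flow_network(
    L: FeatureSet,
    pool: list[tuple[Feature, str]],
    clusters: ClusterAssignment,
    cache: DistanceCache,
    c: float,
    cost_scale: float = 1e4,
) -> FlowNetwork:
    """Build the matching network for one target chromatogram.

    Edges: S->L_i (cap 1, cost 0); L_i->R_j (cap 1, cost scaled GWD) for every
    cached candidate pair; R_j->C_k (cap 1, cost 0) to the pool feature's own
    cluster; C_k->T (cap 1, cost 0); L_i->Tr (cap 1, cost scaled c);
    Tr->T (cap n, cost 0).  The per-cluster sink capacity enforces "at most
    one feature matched per cluster"; the trash route guarantees feasibility
    at flow value n regardless of how poor the candidates are.
    """
    g = nx.DiGraph()
    n = len(L.features)
    c_scaled = _scale_cost(c, cost_scale)
    g.add_node("S", demand=-n)
    g.add_node("T", demand=n)
    if n == 0:
        return FlowNetwork(graph=g, n=0, m=len(pool), s=clusters.s,
                           c_scaled=c_scaled, cost_scale=cost_scale)
    g.add_node("Tr")
    g.add_edge("Tr", "T", capacity=n, weight=0)

    cluster_of_r: dict[tuple[str, str], int] = {}
    used_clusters: set[int] = set()
    for f, src in pool:
        key = (src, f.id)
        k = clusters.labels[key]
        cluster_of_r[key] = k
        g.add_edge(("R",) + key, ("C", k), capacity=1, weight=0)
        used_clusters.add(k)
    for k in sorted(used_clusters):
        g.add_edge(("C", k), "T", capacity=1, weight=0)

    for f in L.features:
        ln = ("L", f.id)
        g.add_edge("S", ln, capacity=1, weight=0)
        g.add_edge(ln, "Tr", capacity=1, weight=c_scaled)
    for (tfid, pool_key), cost in sorted(cache.entries.items()):
        g.add_edge(("L", tfid), ("R",) + pool_key, capacity=1,
                   weight=_scale_cost(cost, cost_scale))
    return FlowNetwork(graph=g, n=n, m=len(pool), s=clusters.s,
                       c_scaled=c_scaled, cost_scale=cost_scale,
                       cluster_of_r=cluster_of_r)


def solve_matching(net: FlowNetwork) -> Matching:
    """Solve the network by network simplex and decode (feature, cluster) pairs."""
    if net.n == 0:
        return Matching(pairs=[], costs={}, unmatched=[], flow_cost=0)
    flow_cost, flow = nx.network_simplex(net.graph)
    pairs: list[tuple[str, int]] = []
    costs: dict[str, float] = {}
    unmatched: list[str] = []
    for node, out in flow.items():
        if not (isinstance(node, tuple) and node[0] == "L"):
            continue
        fid = node[1]
        matched = False
        for tgt, units in out.items():
            if units <= 0:
                continue
            if tgt == "Tr":
                unmatched.append(fid)
                matched = True
            elif isinstance(tgt, tuple) and tgt[0] == "R":
                key = (tgt[1], tgt[2])
                pairs.append((fid, net.cluster_of_r[key]))
                costs[fid] = net.graph[node][tgt]["weight"] / net.cost_scale
                matched = True
        assert matched, f"L feature {fid!r} carries no flow"
    # Flow conservation / capacity sanity on the solved network.
    for u, out in flow.items():
        for v, units in out.items():
            assert 0 <= units <= net.graph[u][v]["capacity"]
    pairs.sort()
    unmatched.sort()
    return Matching(pairs=pairs, costs=costs, unmatched=unmatched,
                    flow_cost=flow_cost)


def match_two(
    a: FeatureSet,
    b: FeatureSet,
    p: GWDParams,
    c: float,
    window: float | None = None,
    cost_scale: float = 1e4,
) -> list[tuple[str, str]]:
    """Optimal matching between two (scaled) feature sets with a trash option.

    The cluster layer is omitted: L features connect straight to R features
    and each R feature connects to the sink with capacity 1.  Returns the
    matched (a feature id, b feature id) pairs.
    """
    cache = pairwise_costs(a, b, p, window=window)
    g = nx.DiGraph()
    n = len(a.features)
    g.add_node("S", demand=-n)
    g.add_node("T", demand=n)
    if n == 0:
        return []
    g.add_edge("Tr", "T", capacity=n, weight=0)
    c_scaled = _scale_cost(c, cost_scale)
    for f in a.features:
        g.add_edge("S", ("L", f.id), capacity=1, weight=0)
        g.add_edge(("L", f.id), "Tr", capacity=1, weight=c_scaled)
    for f in b.features:
        g.add_edge(("R", f.id), "T", capacity=1, weight=0)
    for (tfid, (_, pfid)), cost in sorted(cache.entries.items()):
        g.add_edge(("L", tfid), ("R", pfid), capacity=1,
                   weight=_scale_cost(cost, cost_scale))
    _, flow = nx.network_simplex(g)
    pairs = []
    for node, out in flow.items():
        if isinstance(node, tuple) and node[0] == "L":
            for tgt, units in out.items():
                if units > 0 and isinstance(tgt, tuple) and tgt[0] == "R":
                    pairs.append((node[1], tgt[1]))
    return sorted(pairs)


# ---------------------------------------------------------------------------
# Consensus assembly and the full pipeline
# ---------------------------------------------------------------------------

def assemble_consensus(
    matchings: list[tuple[str, Matching]],
    clusters: ClusterAssignment,
    keep_singletons: bool = False,
) -> list[ConsensusFeature]:
    """Union matched features per cluster across all per-chromatogram matchings.

    Each chromatogram served as the L side exactly once, and per-iteration
    cluster capacity is 1, so no source can contribute two features to one
    cluster.  Consensus features with fewer than two members are dropped
    unless ``keep_singletons``.
    """
    members_by_cluster: dict[int, set[tuple[str, str]]] = {}
    for source_id, matching in matchings:
        for fid, k in matching.pairs:
            members = members_by_cluster.setdefault(k, set())
            assert not any(src == source_id for src, _ in members), (
                f"chromatogram {source_id!r} matched twice to cluster {k}")
            members.add((source_id, fid))
    out = []
    for k in sorted(members_by_cluster):
        members = members_by_cluster[k]
        if len(members) < 2 and not keep_singletons:
            continue
        out.append(ConsensusFeature(
            consensus_id=f"c{len(out)}", members=members, cluster=k))
    return out


def _fill_centroids(consensus: list[ConsensusFeature],
                    sets: list[FeatureSet]) -> None:
    lookup = {(s.source_id, f.id): f for s in sets for f in s.features}
    for cf in consensus:
        cents = np.array([compute_centroid(lookup[m]) for m in sorted(cf.members)])
        cf.centroid_rt = float(cents[:, 0].mean())
        cf.centroid_mz = float(cents[:, 1].mean())


def align(sets: list[FeatureSet],
          cfg: AlignConfig | None = None) -> tuple[list[ConsensusFeature], dict]:
    """Run the full alignment pipeline over two or more chromatograms.

    Returns the consensus features (centroids in original, unscaled
    coordinates) and a run report with the scaling factor, cluster count, and
    per-iteration matching statistics.
    """
    cfg = cfg or AlignConfig()
    if len(sets) < 2:
        raise ValueError("alignment needs at least 2 chromatograms")
    empties = [s.source_id for s in sets if not s.features]
    if empties:
        logger.warning("chromatogram(s) with no features: %s", empties)
    nonempty = [s for s in sets if s.features]

    scaling = estimate_rt_scaling(nonempty, k=cfg.rt_scale_k)
    scaled = [apply_scaling(s, scaling) for s in nonempty]
    params = cfg.gwd_params
    report: dict = {
        "scaling_factor": scaling.factor,
        "lam": cfg.lam,
        "trash_cost": cfg.c,
        "n_chromatograms": len(sets),
        "iterations": [],
    }

    if len(scaled) == 2:
        pairs = match_two(scaled[0], scaled[1], params, cfg.c, window=cfg.window,
                          cost_scale=cfg.cost_scale)
        consensus = [
            ConsensusFeature(
                consensus_id=f"c{i}",
                members={(scaled[0].source_id, fa), (scaled[1].source_id, fb)})
            for i, (fa, fb) in enumerate(pairs)
        ]
        report["s"] = None
        report["iterations"].append(
            {"target": scaled[0].source_id, "matched": len(pairs),
             "trashed": len(scaled[0].features) - len(pairs)})
    else:
        centroids = [
            (np.array(compute_centroid(f)), s.source_id, f.id)
            for s in scaled for f in s.features
        ]
        clusters = cluster_centroids(centroids, cfg, n_chromatograms=len(scaled))
        report["s"] = clusters.s
        matchings: list[tuple[str, Matching]] = []
        for target in scaled:
            pool = [(f, s.source_id) for s in scaled
                    if s.source_id != target.source_id for f in s.features]
            cache = pairwise_costs(target, pool, params, window=cfg.window)
            net = build_flow_network(target, pool, clusters, cache, cfg.c,
                                     cost_scale=cfg.cost_scale)
            matching = solve_matching(net)
            matchings.append((target.source_id, matching))
            report["iterations"].append(
                {"target": target.source_id, "matched": len(matching.pairs),
                 "trashed": len(matching.unmatched),
                 "flow_cost": matching.flow_cost})
        consensus = assemble_consensus(matchings, clusters,
                                       keep_singletons=cfg.keep_singletons)

    _fill_centroids(consensus, nonempty)
    report["n_consensus"] = len(consensus)
    return consensus, report
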