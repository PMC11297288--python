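"""Evaluation metrics for batch-correction quality.

Four batch-removal metrics — batch average silhouette width (ASW), graph
connectivity, batch LISI (iLISI) and kBET — and six bio-conservation
metrics — label ASW, label LISI (cLISI), Leiden ARI, Leiden NMI, and mean
average precision of replicate retrieval against two negative sets
(mAP nonrep / mAP control).  Every metric is reported raw and normalized
to [0, 1], with 0 the worst and 1 the best performance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist
from scipy.stats import chi2, rankdata
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    silhouette_samples,
)
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "NeighborGraph",
    "MetricResult",
    "BATCH_METRICS",
    "BIO_METRICS",
    "build_knn_graph",
    "silhouette_label",
    "silhouette_batch",
    "graph_connectivity",
    "lisi_score",
    "kbet_score",
    "leiden_cluster_scores",
    "average_precision",
    "mean_average_precision",
]

BATCH_METRICS = ("silhouette_batch", "graph_connectivity", "ilisi", "kbet")
BIO_METRICS = ("silhouette_label", "clisi", "leiden_ari", "leiden_nmi",
               "map_nonrep", "map_control")


@dataclass
class MetricResult:
    """One (method, metric) score."""

    method_name: str
    metric_name: str
    category: str  # batch | bio
    raw_value: float
    normalized_value: float
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.normalized_value <= 1 + 1e-9):
            raise ValueError(
                f"{self.metric_name}: normalized value {self.normalized_value} "
                "outside [0, 1]"
            )
        self.normalized_value = float(np.clip(self.normalized_value, 0.0, 1.0))


@dataclass
class NeighborGraph:
    """Exact k-nearest-neighbor graph (no self-neighbors)."""

    indices: np.ndarray   # (n, k) neighbor indices
    distances: np.ndarray  # (n, k)
    k: int
    metric: str = "euclidean"

    @property
    def n(self) -> int:
        return self.indices.shape[0]

    def adjacency(self) -> sparse.csr_matrix:
        """Symmetrized (union) unweighted adjacency matrix."""
        n, k = self.indices.shape
        rows = np.repeat(np.arange(n), k)
        a = sparse.csr_matrix(
            (np.ones(n * k), (rows, self.indices.ravel())), shape=(n, n)
        )
        a = a.maximum(a.T)
        a.data[:] = 1.0
        return a


def _as_matrix(x) -> np.ndarray:
    if hasattr(x, "matrix"):
        return x.matrix()
    return np.asarray(x, dtype=float)


def build_knn_graph(x, k: int = 15, metric: str = "euclidean") -> NeighborGraph:
    """Exact k nearest neighbors of every well (self excluded)."""
    x = _as_matrix(x)
    n = x.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of wells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1, metric=metric).fit(x)
    dist, idx = nn.kneighbors(x)
    # drop self; with exact duplicates self may not be first, so remove by index
    out_idx = np.empty((n, k), dtype=int)
    out_dist = np.empty((n, k))
    for i in range(n):
        mask = idx[i] != i
        if mask.sum() == k + 1:  # self never returned (duplicate points)
            mask[-1] = False
        out_idx[i] = idx[i][mask][:k]
        out_dist[i] = dist[i][mask][:k]
    return NeighborGraph(out_idx, out_dist, k, metric)


# -- silhouette-based ------------------------------------------------------


def _safe_silhouette(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-sample silhouette; degenerate (zero-distance) cases score 0."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s = silhouette_samples(x, labels)
    return np.nan_to_num(s, nan=0.0)


def silhouette_label(x, labels, method_name: str = "") -> MetricResult:
    """Compound-cluster ASW; normalized as (ASW + 1) / 2."""
    x = _as_matrix(x)
    labels = np.asarray(labels, dtype=object).astype(str)
    counts = pd.Series(labels).value_counts()
    singletons = counts[counts < 2]
    if len(singletons):
        warnings.warn(
            f"{len(singletons)} label(s) with a single well excluded from "
            "silhouette_label", stacklevel=2,
        )
    keep = np.isin(labels, counts[counts >= 2].index.to_numpy())
    if len(set(labels[keep])) < 2:
        raise ValueError("silhouette_label needs >= 2 labels with >= 2 members")
    raw = float(np.mean(_safe_silhouette(x[keep], labels[keep])))
    return MetricResult(method_name, "silhouette_label", "bio",
                        raw, (raw + 1.0) / 2.0)


def silhouette_batch(x, batches, labels, method_name: str = "") -> MetricResult:
    """Within-label batch ASW, scored per well as 1 - |s| and averaged.

    A well whose batch is well mixed among the other batches of the same
    compound scores near 1.  Labels observed in a single batch are skipped.
    """
    x = _as_matrix(x)
    batches = np.asarray(batches, dtype=object).astype(str)
    labels = np.asarray(labels, dtype=object).astype(str)
    if len(set(batches)) < 2:
        raise ValueError("silhouette_batch needs >= 2 batches")
    per_label = {}
    for lab in sorted(set(labels)):
        rows = np.flatnonzero(labels == lab)
        grp_batches = batches[rows]
        uniq = set(grp_batches)
        if len(uniq) < 2 or len(rows) <= len(uniq):
            warnings.warn(
                f"label {lab!r} skipped in silhouette_batch (needs >=2 batches "
                "and more wells than batches)", stacklevel=2,
            )
            continue
        s = _safe_silhouette(x[rows], grp_batches)
        per_label[lab] = float(np.mean(1.0 - np.abs(s)))
    if not per_label:
        raise ValueError("no label group usable for silhouette_batch")
    raw = float(np.mean(list(per_label.values())))
    return MetricResult(method_name, "silhouette_batch", "batch", raw, raw,
                        details={"per_label": per_label})


# -- graph connectivity ----------------------------------------------------


def graph_connectivity(graph: NeighborGraph, labels,
                       method_name: str = "") -> MetricResult:
    """Mean over labels of the largest-connected-component fraction.

    For each label, the kNN graph is restricted to that label's wells; the
    score is the size of the largest connected component divided by the
    label size.  Size-1 labels contribute 1.
    """
    labels = np.asarray(labels, dtype=object).astype(str)
    if labels.shape[0] != graph.n:
        raise ValueError("labels length does not match graph size")
    adj = graph.adjacency()
    per_label = {}
    for lab in sorted(set(labels)):
        rows = np.flatnonzero(labels == lab)
        if len(rows) == 1:
            per_label[lab] = 1.0
            continue
        sub = adj[rows][:, rows]
        n_comp, comp = connected_components(sub, directed=False)
        largest = np.bincount(comp).max()
        per_label[lab] = float(largest / len(rows))
    raw = float(np.mean(list(per_label.values())))
    return MetricResult(method_name, "graph_connectivity", "batch", raw, raw,
                        details={"per_label": per_label})


# -- LISI ------------------------------------------------------------------


def _perplexity_weights(dists: np.ndarray, perplexity: float,
                        tol: float = 1e-5, max_iter: int = 64) -> np.ndarray:
    """Gaussian kernel weights over one well's neighbors, calibrated so the
    weight entropy matches log(perplexity) (t-SNE-style binary search)."""
    d2 = dists ** 2
    d2 = d2 - d2.min()
    target = np.log(perplexity)
    lo, hi = 0.0, np.inf
    beta = 1.0 / max(np.mean(d2), 1e-12)
    for _ in range(max_iter):
        w = np.exp(-beta * d2)
        sw = w.sum()
        if sw <= 0:
            h = 0.0
            p = np.zeros_like(w)
        else:
            p = w / sw
            nz = p > 0
            h = -np.sum(p[nz] * np.log(p[nz]))
        diff = h - target
        if abs(diff) < tol:
            break
        if diff > 0:  # entropy too high -> sharpen
            lo = beta
            beta = beta * 2 if not np.isfinite(hi) else (beta + hi) / 2
        else:
            hi = beta
            beta = beta / 2 if lo == 0 else (beta + lo) / 2
    return p


def lisi_score(x, labels, key_kind: str, perplexity: float = 30.0,
               method_name: str = "") -> MetricResult:
    """Local inverse Simpson's index of a categorical variable.

    ``key_kind='batch'`` gives iLISI (higher diversity of batches in each
    neighborhood is better, normalized as (LISI-1)/(B-1));
    ``key_kind='label'`` gives cLISI (lower diversity of compounds is
    better, normalized as (L-LISI)/(L-1)).
    """
    x = _as_matrix(x)
    labels = np.asarray(labels, dtype=object).astype(str)
    n = x.shape[0]
    cats = sorted(set(labels))
    c = len(cats)
    if c < 2:
        raise ValueError("LISI is undefined with a single category")
    if not perplexity < n / 3:
        raise ValueError(f"perplexity must be < n/3 = {n / 3:.1f}")
    k = min(n - 1, int(3 * perplexity))
    graph = build_knn_graph(x, k=k)
    code = np.searchsorted(cats, labels)
    inv_simpson = np.empty(n)
    for i in range(n):
        p = _perplexity_weights(graph.distances[i], perplexity)
        mass = np.bincount(code[graph.indices[i]], weights=p, minlength=c)
        inv_simpson[i] = 1.0 / max(np.sum(mass ** 2), 1e-12)
    raw = float(np.mean(inv_simpson))
    if key_kind == "batch":
        norm = (raw - 1.0) / (c - 1.0)
        return MetricResult(method_name, "ilisi", "batch", raw,
                            float(np.clip(norm, 0, 1)))
    elif key_kind == "label":
        norm = (c - raw) / (c - 1.0)
        return MetricResult(method_name, "clisi", "bio", raw,
                            float(np.clip(norm, 0, 1)))
    raise ValueError("key_kind must be 'batch' or 'label'")


# -- kBET ------------------------------------------------------------------


def _kbet_rejection(x: np.ndarray, batches: np.ndarray, nn: int,
                    alpha: float) -> float:
    """Rejection rate of the local-vs-global batch composition test."""
    cats = sorted(set(batches))
    code = np.searchsorted(cats, batches)
    global_freq = np.bincount(code, minlength=len(cats)) / len(code)
    graph = build_knn_graph(x, k=nn - 1)
    neigh = np.concatenate([np.arange(len(code))[:, None], graph.indices], axis=1)
    expected = global_freq * nn
    rejected = 0
    for i in range(len(code)):
        observed = np.bincount(code[neigh[i]], minlength=len(cats))
        stat = np.sum((observed - expected) ** 2 / expected)
        if chi2.sf(stat, df=len(cats) - 1) < alpha:
            rejected += 1
    return rejected / len(code)


def kbet_score(x, batches, labels=None, neighborhood_size: int | None = None,
               alpha: float = 0.05, method_name: str = "") -> MetricResult:
    """k-nearest-neighbor batch effect test.

    Each well's neighborhood batch composition is chi-square-tested against
    the global composition; the score is 1 minus the rejection rate.  When
    compound labels are given, the test runs within each sufficiently large
    label group and the scores are averaged over groups (falling back to a
    single global test if no group is usable).
    """
    x = _as_matrix(x)
    batches = np.asarray(batches, dtype=object).astype(str)
    b = len(set(batches))
    if b < 2:
        raise ValueError("kBET needs >= 2 batches")
    n = x.shape[0]
    mean_batch = n / b
    default_nn = int(min(50, max(10, mean_batch // 4)))
    if neighborhood_size is not None and neighborhood_size < b:
        raise ValueError("neighborhood_size must be >= number of batches")

    groups: list[np.ndarray] = []
    if labels is not None:
        labels = np.asarray(labels, dtype=object).astype(str)
        for lab in sorted(set(labels)):
            rows = np.flatnonzero(labels == lab)
            grp_b = len(set(batches[rows]))
            nn = neighborhood_size or int(min(default_nn, max(10, len(rows) // 4)))
            # a group must hold at least two disjoint neighborhoods, else the
            # chi-square test has no power and the score is vacuous
            if grp_b < 2 or len(rows) < 2 * nn or nn < grp_b:
                continue
            groups.append(rows)
    if not groups:
        nn = neighborhood_size or default_nn
        if n <= nn:
            raise ValueError("too few wells for the kBET neighborhood size")
        groups = [np.arange(n)]

    rates = []
    for rows in groups:
        nn = neighborhood_size or int(min(default_nn, max(10, len(rows) // 4)))
        nn = min(nn, len(rows) - 1)
        rates.append(_kbet_rejection(x[rows], batches[rows], nn, alpha))
    raw = float(np.mean(rates))
    return MetricResult(method_name, "kbet", "batch", raw, 1.0 - raw,
                        details={"n_groups": len(groups)})


# -- Leiden clustering agreement ------------------------------------------


def leiden_cluster_scores(x, labels, resolutions=(0.1, 0.25, 0.5, 1.0, 2.0),
                          k: int = 15, seed: int = 0,
                          method_name: str = "") -> tuple[MetricResult, MetricResult]:
    """ARI and NMI between Leiden communities and compound labels.

    Leiden community detection runs on the symmetrized kNN graph at each
    resolution; the resolution maximizing NMI is selected and both scores
    are reported for that clustering.  ARI is clipped at 0 for the
    normalized value.
    """
    import igraph
    import leidenalg

    x = _as_matrix(x)
    labels = np.asarray(labels, dtype=object).astype(str)
    graph = build_knn_graph(x, k=min(k, x.shape[0] - 1))
    adj = graph.adjacency().tocoo()
    mask = adj.row < adj.col
    g = igraph.Graph(
        n=graph.n, edges=list(zip(adj.row[mask], adj.col[mask])), directed=False
    )
    best = None
    for res in resolutions:
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=res, seed=int(seed), n_iterations=2,
        )
        assign = np.asarray(part.membership)
        nmi = normalized_mutual_info_score(labels, assign)
        if best is None or nmi > best[1]:
            best = (res, nmi, assign)
    res, nmi, assign = best
    if len(set(assign)) == 1:
        warnings.warn("Leiden found a single community at every resolution",
                      stacklevel=2)
    ari = adjusted_rand_score(labels, assign)
    ari_res = MetricResult(method_name, "leiden_ari", "bio", float(ari),
                           float(np.clip(ari, 0, 1)),
                           details={"resolution": res})
    nmi_res = MetricResult(method_name, "leiden_nmi", "bio", float(nmi),
                           float(nmi), details={"resolution": res})
    return ari_res, nmi_res


# -- mean average precision ------------------------------------------------


def _cosine_similarity(query: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    qn = np.linalg.norm(query)
    cn = np.linalg.norm(candidates, axis=1)
    if qn == 0 or (cn == 0).any():
        raise ValueError("zero-norm vector in cosine similarity")
    return (candidates @ query) / (cn * qn)


def average_precision(query: np.ndarray, positives: np.ndarray,
                      negatives: np.ndarray) -> float:
    """AP of retrieving the positives above the negatives by cosine similarity.

    Candidates are ranked by descending similarity to the query (ties broken
    by stable candidate order, positives first); AP is the sum over ranks of
    (recall increment x precision at rank), which equals the mean precision
    at the positives' ranks.
    """
    positives = np.atleast_2d(np.asarray(positives, dtype=float))
    negatives = np.atleast_2d(np.asarray(negatives, dtype=float))
    query = np.asarray(query, dtype=float)
    if positives.shape[0] < 1 or negatives.shape[0] < 1:
        raise ValueError("need >= 1 positive and >= 1 negative candidate")
    candidates = np.vstack([positives, negatives])
    sims = _cosine_similarity(query, candidates)
    order = np.argsort(-sims, kind="stable")
    is_pos = np.zeros(len(candidates), dtype=bool)
    is_pos[: positives.shape[0]] = True
    hits = is_pos[order]
    tp = np.cumsum(hits)
    ranks = np.arange(1, len(candidates) + 1)
    precision = tp / ranks
    return float(precision[hits].mean())


def mean_average_precision(x, meta: pd.DataFrame, label_key: str = "compound_id",
                           negatives_mode: str = "nonrep",
                           method_name: str = "") -> MetricResult:
    """Replicate-retrieval mAP with per-plate negative candidates.

    Every treated well of a compound with >= 2 replicates is a query; its
    positives are the compound's other replicates anywhere in the dataset.
    Negatives come from the query's own plate: treated wells of other
    compounds (``nonrep``) or the plate's negative controls (``control``).
    AP is averaged per compound, then over compounds.
    """
    if negatives_mode not in ("nonrep", "control"):
        raise ValueError("negatives_mode must be 'nonrep' or 'control'")
    x = _as_matrix(x)
    meta = meta.reset_index(drop=True)
    labels = meta[label_key].astype(str).to_numpy()
    plates = meta["plate_id"].astype(str).to_numpy()
    is_neg_ctrl = (meta["control_type"] == "negative").to_numpy()
    treated = ~is_neg_ctrl
    counts = pd.Series(labels[treated]).value_counts()
    eligible = set(counts[counts >= 2].index)
    skipped_single = len(counts) - len(eligible)
    if skipped_single:
        warnings.warn(
            f"{skipped_single} compound(s) with a single replicate excluded "
            "from mAP", stacklevel=2,
        )
    if not eligible:
        raise ValueError("no compound has >= 2 replicates")
    ap_by_compound: dict[str, list[float]] = {}
    warned_plates = set()
    for i in np.flatnonzero(treated):
        lab = labels[i]
        if lab not in eligible:
            continue
        pos_rows = np.flatnonzero(treated & (labels == lab))
        pos_rows = pos_rows[pos_rows != i]
        on_plate = plates == plates[i]
        if negatives_mode == "nonrep":
            neg_rows = np.flatnonzero(treated & on_plate & (labels != lab))
        else:
            neg_rows = np.flatnonzero(is_neg_ctrl & on_plate)
            if len(neg_rows) == 0 and plates[i] not in warned_plates:
                warnings.warn(
                    f"plate {plates[i]!r} has no negative controls; its queries "
                    "are skipped in mAP control", stacklevel=2,
                )
                warned_plates.add(plates[i])
        if len(pos_rows) == 0 or len(neg_rows) == 0:
            continue
        ap = average_precision(x[i], x[pos_rows], x[neg_rows])
        ap_by_compound.setdefault(lab, []).append(ap)
    if not ap_by_compound:
        raise ValueError("no query produced a valid ranked list")
    per_compound = {c: float(np.mean(v)) for c, v in ap_by_compound.items()}
    raw = float(np.mean(list(per_compound.values())))
    name = f"map_{negatives_mode}"
    return MetricResult(method_name, name, "bio", raw, raw,
                        details={"per_compound": per_compound})
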