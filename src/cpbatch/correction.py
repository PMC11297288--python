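"""Batch-correction methods with a uniform fit/apply contract.

Built-in desk-scale methods:

* ``baseline`` — identity; the no-correction reference.
* ``sphering`` — ZCA whitening fitted on negative-control wells with
  eigenvalue regularization; assumes control variation is purely technical.
* ``combat`` — empirical-Bayes location/scale adjustment per batch
  (additive + multiplicative batch-effect model on normal features).
* ``mnn`` — mutual-nearest-neighbor pairing across batches with
  Gaussian-kernel-smoothed correction vectors, batches merged onto a
  reference in descending size order.
* ``harmony`` — a compact re-implementation of the iterative
  soft-clustering approach: alternate between diversity-penalized soft
  k-means in a PCA embedding and per-cluster, per-batch linear
  corrections (``harmony_lite``); returns an embedding, not features.

External methods (deep-learning or R-ecosystem tools) plug in through
:func:`register_method` and are then addressable from the benchmark by
name.  Every correction preserves well count, order and metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .profile_io import ProfileTable

__all__ = [
    "BatchDesign",
    "CorrectionModel",
    "baseline_identity",
    "fit_sphering",
    "apply_sphering",
    "sphering_correct",
    "combat_correct",
    "mnn_correct",
    "harmony_lite",
    "register_method",
    "get_method",
    "list_methods",
    "RegisteredMethod",
]


@dataclass
class BatchDesign:
    """Per-well batch labels derived from one metadata column."""

    batch_key: str
    labels: np.ndarray  # string label per well

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=object)
        empty = pd.isna(labels) | (labels == "")
        if empty.any():
            raise ValueError(
                f"{int(empty.sum())} well(s) have an empty {self.batch_key!r} label"
            )
        self.labels = labels.astype(str)

    @classmethod
    def from_table(cls, table: ProfileTable, batch_key: str) -> "BatchDesign":
        if batch_key not in table.meta.columns:
            raise KeyError(f"unknown batch key {batch_key!r}")
        return cls(batch_key, table.meta[batch_key].to_numpy())

    @property
    def batches(self) -> list[str]:
        return sorted(set(self.labels))

    @property
    def n_batches(self) -> int:
        return len(set(self.labels))


@dataclass
class CorrectionModel:
    """A fitted, reapplicable correction transformation."""

    method_name: str
    batch_key: str | None
    params: dict = field(default_factory=dict)
    output_space: str = "feature"  # feature | embedding


# -- baseline --------------------------------------------------------------


def baseline_identity(table: ProfileTable) -> ProfileTable:
    """The no-correction reference every method is compared against."""
    return table.with_features(table.matrix())


# -- sphering --------------------------------------------------------------


def fit_sphering(table: ProfileTable, regularization: float = 0.1) -> CorrectionModel:
    """Fit a ZCA whitening transform on negative-control wells.

    Eigenvalues of the control covariance are shrunk by ``regularization``
    (added before the inverse square root), which keeps the transform
    stable when controls are fewer than features.
    """
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    ctrl_mask = (table.meta["control_type"] == "negative").to_numpy()
    n_ctrl = int(ctrl_mask.sum())
    if n_ctrl < 2:
        raise ValueError("sphering needs >= 2 negative-control wells")
    x = table.matrix()[ctrl_mask]
    mu = x.mean(axis=0)
    cov = np.cov(x - mu, rowvar=False)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    if regularization == 0 and evals.min() <= 1e-10 * max(evals.max(), 1.0):
        raise ValueError(
            "control covariance is (near-)singular with regularization=0; "
            "use regularization > 0 or more control wells"
        )
    w = evecs @ np.diag(1.0 / np.sqrt(evals + regularization)) @ evecs.T
    return CorrectionModel(
        method_name="sphering",
        batch_key=None,
        params={"W": w, "mean": mu, "regularization": regularization},
        output_space="feature",
    )


def apply_sphering(model: CorrectionModel, table: ProfileTable) -> ProfileTable:
    if model.method_name != "sphering":
        raise ValueError("model is not a sphering model")
    w, mu = model.params["W"], model.params["mean"]
    if table.n_features != w.shape[0]:
        raise ValueError("feature count does not match fitted sphering model")
    return table.with_features((table.matrix() - mu) @ w)


def sphering_correct(table: ProfileTable, regularization: float = 0.1) -> ProfileTable:
    return apply_sphering(fit_sphering(table, regularization), table)


# -- Combat ----------------------------------------------------------------


def combat_correct(table: ProfileTable, design: BatchDesign) -> ProfileTable:
    """Empirical-Bayes per-batch location/scale adjustment.

    Models each feature's batch effect as additive + multiplicative noise
    on a normal signal, shrinks per-batch estimates across features, and
    restores the grand location/scale.
    """
    if design.n_batches < 2:
        raise ValueError("Combat requires >= 2 batches")
    counts = pd.Series(design.labels).value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"batch(es) with a single well: {list(small.index)}")
    import anndata as ad
    import scanpy as sc

    adata = ad.AnnData(
        X=table.matrix(),
        obs=pd.DataFrame({"batch": pd.Categorical(design.labels)},
                         index=[str(i) for i in range(table.n_wells)]),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.combat(adata, key="batch")
    return table.with_features(np.asarray(adata.X, dtype=float))


# -- MNN -------------------------------------------------------------------


def _mutual_pairs(a: np.ndarray, b: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices (into a, into b) of mutual nearest-neighbor pairs."""
    nn_ab = NearestNeighbors(n_neighbors=k).fit(b)
    _, ab = nn_ab.kneighbors(a)  # for each a-cell, k nearest in b
    nn_ba = NearestNeighbors(n_neighbors=k).fit(a)
    _, ba = nn_ba.kneighbors(b)
    in_ba = {(int(j), int(i)) for j in range(b.shape[0]) for i in ba[j]}
    ia, ib = [], []
    for i in range(a.shape[0]):
        for j in ab[i]:
            if (int(j), int(i)) in in_ba:
                ia.append(i)
                ib.append(int(j))
    return np.asarray(ia, dtype=int), np.asarray(ib, dtype=int)


def mnn_correct(table: ProfileTable, design: BatchDesign, k: int = 5,
                bandwidth: float | None = None) -> ProfileTable:
    """Mutual-nearest-neighbor correction, merging batches by size.

    Batches are merged sequentially onto a reference (largest first).  Each
    mutual pair defines a correction vector (reference minus incoming);
    incoming wells receive a Gaussian-kernel-weighted average of the pair
    vectors.  The kernel width ``bandwidth`` defaults to the median norm of
    the pair correction vectors — corrections are smoothed over the spatial
    scale of the displacement they remove, which suppresses per-well noise
    in the pairs without blurring corrections across distant phenotypes.
    """
    if design.n_batches < 2:
        raise ValueError("MNN requires >= 2 batches")
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = pd.Series(design.labels).value_counts()
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the smallest batch size ({int(counts.min())})"
        )
    x = table.matrix()
    order = sorted(counts.index, key=lambda b: (-counts[b], b))
    corrected = x.copy()
    ref_rows = np.flatnonzero(design.labels == order[0])
    for batch in order[1:]:
        new_rows = np.flatnonzero(design.labels == batch)
        ref = corrected[ref_rows]
        new = corrected[new_rows]
        ia, ib = _mutual_pairs(ref, new, k)
        if len(ia) == 0:
            raise ValueError(
                f"no mutual nearest-neighbor pairs between reference and batch {batch!r}"
            )
        vectors = ref[ia] - new[ib]  # per-pair correction
        anchors = new[ib]
        d = cdist(new, anchors)
        if bandwidth is None:
            sigma = float(np.median(np.linalg.norm(vectors, axis=1)))
        else:
            sigma = float(bandwidth)
        if sigma < 1e-8:
            # batches already coincide on the pair set; the global mean
            # correction (zero up to pair symmetry) applies everywhere
            wgt = np.ones_like(d)
        else:
            wgt = np.exp(-(d ** 2) / (2.0 * sigma ** 2))
        rowsum = wgt.sum(axis=1)
        # numerically dead rows fall back to the nearest anchor's vector
        dead = rowsum <= 1e-300
        if dead.any():
            nearest = d[dead].argmin(axis=1)
            wgt[dead] = 0.0
            wgt[np.flatnonzero(dead), nearest] = 1.0
            rowsum = wgt.sum(axis=1)
        corrected[new_rows] = new + (wgt @ vectors) / rowsum[:, None]
        ref_rows = np.concatenate([ref_rows, new_rows])
    return table.with_features(corrected)


# -- Harmony-lite ----------------------------------------------------------


def harmony_lite(table: ProfileTable, design: BatchDesign,
                 n_clusters: int | None = None, theta: float = 1.0,
                 max_iter: int = 20, tol: float = 1e-3, seed: int = 0,
                 n_pcs: int = 20, sigma: float = 0.1) -> ProfileTable:
    """Diversity-penalized soft clustering with per-cluster batch correction.

    A compact variant of the iterative mixture-model approach: wells are
    soft-assigned to clusters in a PCA embedding (assignments of batches
    under-represented in a cluster are up-weighted by a ``theta``-powered
    diversity factor), then each cluster's per-batch centroid offset is
    subtracted.  Iterates until the mean correction step falls below
    ``tol`` (relative to the embedding RMS) or ``max_iter``.  Returns the
    corrected embedding (output space: ``embedding``).
    """
    if design.n_batches < 2:
        raise ValueError("harmony_lite requires >= 2 batches")
    x = table.matrix()
    n = x.shape[0]
    d = min(n_pcs, x.shape[1], n - 1)
    z = PCA(n_components=d, random_state=seed).fit_transform(x)
    if n_clusters is None:
        n_clusters = max(2, min(20, n // 30))
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")

    batches = np.asarray(design.labels)
    batch_names = sorted(set(batches))
    b_idx = {b: np.flatnonzero(batches == b) for b in batch_names}
    pi = np.array([len(b_idx[b]) / n for b in batch_names])

    def unit(a: np.ndarray) -> np.ndarray:
        nrm = np.linalg.norm(a, axis=1, keepdims=True)
        return a / np.maximum(nrm, 1e-12)

    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=4)
    km.fit(unit(z))
    centroids = unit(km.cluster_centers_)

    z_corr = z.copy()
    rms = float(np.sqrt((z ** 2).mean()))
    converged = False
    for _ in range(max_iter):
        zn = unit(z_corr)
        d2 = cdist(zn, centroids, metric="sqeuclidean")
        r = np.exp(-d2 / max(sigma, 1e-6))
        if theta > 0:
            o = np.stack([r[b_idx[b]].sum(axis=0) for b in batch_names])  # B x K
            e = np.outer(pi, r.sum(axis=0))
            factor = ((e + 1.0) / (o + 1.0)) ** theta
            for bi, b in enumerate(batch_names):
                r[b_idx[b]] *= factor[bi]
        r /= np.maximum(r.sum(axis=1, keepdims=True), 1e-12)
        centroids = unit((r.T @ zn) / np.maximum(r.sum(axis=0)[:, None], 1e-12))

        # per-cluster global and per-batch weighted centroids in raw space
        w_all = r.sum(axis=0)  # K
        mu_all = (r.T @ z_corr) / np.maximum(w_all[:, None], 1e-12)
        delta = np.zeros_like(z_corr)
        for b in batch_names:
            rows = b_idx[b]
            w_b = r[rows].sum(axis=0)
            mu_b = (r[rows].T @ z_corr[rows]) / np.maximum(w_b[:, None], 1e-12)
            usable = w_b > 1e-8
            offset = np.zeros_like(mu_all)
            offset[usable] = mu_b[usable] - mu_all[usable]
            delta[rows] = r[rows] @ offset
        z_corr = z_corr - delta
        step = float(np.linalg.norm(delta, axis=1).mean())
        if step < tol * max(rms, 1e-12):
            converged = True
            break
    if not converged:
        warnings.warn(
            f"harmony_lite did not converge in {max_iter} iterations", stacklevel=2
        )
    names = [f"harmony_{i}" for i in range(z_corr.shape[1])]
    return table.with_features(z_corr, feature_names=names)


# -- registry --------------------------------------------------------------


@dataclass
class RegisteredMethod:
    """A correction method invocable from the benchmark by name.

    ``func(table, *, batch_key, seed, **params) -> ProfileTable`` must
    preserve well count, order and metadata, and declare whether it
    returns corrected features or a low-dimensional embedding.
    """

    name: str
    func: Callable[..., ProfileTable]
    output_space: str = "feature"
    requires_batch: bool = True


_REGISTRY: dict[str, RegisteredMethod] = {}


def register_method(name: str, func: Callable[..., ProfileTable],
                    output_space: str = "feature",
                    requires_batch: bool = True) -> None:
    if name in _REGISTRY:
        raise ValueError(f"method {name!r} is already registered")
    if output_space not in ("feature", "embedding"):
        raise ValueError("output_space must be 'feature' or 'embedding'")
    _REGISTRY[name] = RegisteredMethod(name, func, output_space, requires_batch)


def get_method(name: str) -> RegisteredMethod:
    if name not in _REGISTRY:
        raise KeyError(f"unknown method {name!r}; available: {list_methods()}")
    return _REGISTRY[name]


def list_methods() -> list[str]:
    return sorted(_REGISTRY)


def _run_baseline_method(table, *, batch_key=None, seed=0):
    if batch_key is not None:
        BatchDesign.from_table(table, batch_key)  # validates labels
    return baseline_identity(table)


def _run_sphering(table, *, batch_key=None, seed=0, regularization: float = 0.1):
    return sphering_correct(table, regularization)


def _run_combat(table, *, batch_key, seed=0):
    return combat_correct(table, BatchDesign.from_table(table, batch_key))


def _run_mnn(table, *, batch_key, seed=0, k: int = 5, bandwidth=None):
    return mnn_correct(table, BatchDesign.from_table(table, batch_key), k, bandwidth)


def _run_harmony(table, *, batch_key, seed=0, **params):
    return harmony_lite(table, BatchDesign.from_table(table, batch_key),
                        seed=seed, **params)


register_method("baseline", _run_baseline_method, "feature", requires_batch=False)
register_method("sphering", _run_sphering, "feature", requires_batch=False)
register_method("combat", _run_combat, "feature")
register_method("mnn", _run_mnn, "feature")
register_method("harmony", _run_harmony, "embedding")
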