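"""Brain-state discovery by k-means with correlation distance.

Frames (rows of the concatenated scans-by-ROI matrix) are clustered with
distance d(x, c) = 1 - r(x, c), where r is the Pearson correlation of the
two vectors across ROIs. The semantics replicate the MATLAB ``kmeans``
``'correlation'`` contract as a compatibility requirement: points are
row-standardized, assignment is to the maximum-correlation centroid, and
each centroid is the member mean re-centered to zero row mean. The number
of states is selected by the elbow of the explained-variance curve, and a
final partition is chosen among replicate runs by cumulative adjusted
mutual information (AMI).
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_mutual_info_score

from .types import (
    NETWORKS,
    ClusteringResult,
    ElbowResult,
    NetworkTemplates,
    RoiTimeSeries,
    StateCatalog,
)


# ---------------------------------------------------------------------------
# concatenation

def concatenate_scans(scans: list[RoiTimeSeries]) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack kept frames of all scans into one frames x ROIs matrix.

    Returns the matrix and a ``scan_index`` frame with one row per kept
    frame: (scan, subject_id, condition, frame), where ``frame`` is the
    original within-scan frame number, so the concatenation is invertible.
    """
    if not scans:
        raise ValueError("no scans to concatenate")
    n = scans[0].n_rois
    blocks, idx = [], []
    for s_i, ts in enumerate(scans):
        if ts.n_rois != n:
            raise ValueError(f"scan {s_i} has {ts.n_rois} ROIs, expected {n}")
        kept = np.flatnonzero(ts.censor_mask)
        blocks.append(ts.data[kept])
        idx.append(pd.DataFrame({
            "scan": s_i, "subject_id": ts.subject_id,
            "condition": ts.condition, "frame": kept,
        }))
    X = np.vstack(blocks)
    scan_index = pd.concat(idx, ignore_index=True)
    return X, scan_index


# ---------------------------------------------------------------------------
# correlation-distance k-means

def _standardize_rows(X: np.ndarray) -> np.ndarray:
    """Center each row and scale to unit norm; error on zero-variance rows."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(f"zero-variance frame(s) at row(s) {bad[:5].tolist()}")
    return Xc / norms[:, None]


def correlation_distance(x: np.ndarray, c: np.ndarray) -> float:
    """d(x, c) = 1 - Pearson correlation across components."""
    xn = _standardize_rows(np.atleast_2d(x))[0]
    cn = _standardize_rows(np.atleast_2d(c))[0]
    return float(1.0 - xn @ cn)


def _lloyd_once(Xn: np.ndarray, init_idx: np.ndarray, max_iter: int) -> tuple[np.ndarray, np.ndarray, float]:
    """One restart of Lloyd's algorithm on row-standardized data.

    Returns (labels, centroids, inertia); centroids are zero-mean rows.
    """
    F = Xn.shape[0]
    C = Xn[init_idx].copy()
    labels = np.full(F, -1)
    for _ in range(max_iter):
        Cc = C - C.mean(axis=1, keepdims=True)
        Cn = Cc / np.linalg.norm(Cc, axis=1)[:, None]
        corr = Xn @ Cn.T
        new_labels = np.argmax(corr, axis=1)
        # empty-cluster repair: reseed with the frame farthest from its centroid
        assigned_corr = corr[np.arange(F), new_labels].copy()
        for j in range(C.shape[0]):
            if not (new_labels == j).any():
                far = int(np.argmin(assigned_corr))
                new_labels[far] = j
                assigned_corr[far] = np.inf  # cannot be stolen by another repair
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(C.shape[0]):
            C[j] = Xn[labels == j].mean(axis=0)
    Cc = C - C.mean(axis=1, keepdims=True)
    Cn = Cc / np.linalg.norm(Cc, axis=1)[:, None]
    corr = Xn @ Cn.T
    inertia = float(np.sum(1.0 - corr[np.arange(F), labels]))
    return labels, Cc, inertia


def _global_inertia(Xn: np.ndarray) -> float:
    g = Xn.mean(axis=0)
    g = g - g.mean()
    norm = np.linalg.norm(g)
    if norm == 0:
        # perfectly balanced data (e.g. exact +/- pattern pairs): every frame
        # is uncorrelated with the degenerate global centroid, distance 1 each
        return float(Xn.shape[0])
    return float(np.sum(1.0 - Xn @ (g / norm)))


def kmeans_correlation(
    X: np.ndarray,
    k: int,
    n_restarts: int = 50,
    seed: int | np.random.Generator = 0,
    scan_index: pd.DataFrame | None = None,
    max_iter: int = 100,
) -> ClusteringResult:
    """Best-of-``n_restarts`` correlation-distance k-means.

    Each restart initializes centroids at ``k`` distinct frames drawn
    uniformly without replacement; the restart with the lowest total
    within-cluster correlation distance wins. Deterministic under a fixed
    seed.
    """
    X = np.asarray(X, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= X.shape[0]:
        raise ValueError("k must be smaller than the number of frames")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Xn = _standardize_rows(X)
    best = None
    for _ in range(n_restarts):
        init_idx = rng.choice(X.shape[0], size=k, replace=False)
        labels, centroids, inertia = _lloyd_once(Xn, init_idx, max_iter)
        if best is None or inertia < best[2]:
            best = (labels, centroids, inertia)
    labels, centroids, inertia = best
    ev = 1.0 - inertia / _global_inertia(Xn)
    if scan_index is None:
        scan_index = pd.DataFrame({
            "scan": 0, "subject_id": "", "condition": "",
            "frame": np.arange(X.shape[0]),
        })
    return ClusteringResult(k=k, centroids=centroids, labels=labels,
                            scan_index=scan_index, inertia=inertia,
                            explained_variance=float(ev))


def explained_variance_curve(
    X: np.ndarray,
    k_min: int = 3,
    k_max: int = 22,
    n_restarts: int = 50,
    seed: int | np.random.Generator = 0,
    max_iter: int = 100,
) -> pd.Series:
    """EV(k) = 1 - sum d(frame, centroid) / sum d(frame, global centroid),
    for k in [k_min, k_max]."""
    X = np.asarray(X, dtype=float)
    if k_max >= X.shape[0]:
        raise ValueError("k_max must be below the number of frames")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    evs = {}
    for k in range(k_min, k_max + 1):
        evs[k] = kmeans_correlation(X, k, n_restarts, rng, max_iter=max_iter).explained_variance
    return pd.Series(evs, name="explained_variance")


def select_k_elbow(curve: pd.Series, gain_threshold: float = 0.01) -> ElbowResult:
    """Smallest k whose next step gains less than ``gain_threshold`` EV.

    Falls back to the largest k in the curve (with a warning flag) when
    every one-step gain meets the threshold.
    """
    if len(curve) < 3:
        raise ValueError("curve needs at least 3 points")
    curve = curve.sort_index()
    ks = curve.index.to_numpy()
    gains = np.diff(curve.to_numpy())
    for i, g in enumerate(gains):
        if g < gain_threshold:
            return ElbowResult(k=int(ks[i]), fell_back=False)
    warnings.warn("no EV gain fell below the threshold; returning k_max")
    return ElbowResult(k=int(ks[-1]), fell_back=True)


# ---------------------------------------------------------------------------
# partition agreement and replicate selection

def adjusted_mutual_information(p1: np.ndarray, p2: np.ndarray) -> float:
    """Chance-corrected agreement between two labelings:
    AMI = (MI - E[MI]) / (mean(H1, H2) - E[MI]), with the standard
    hypergeometric expectation of MI under fixed marginals."""
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    if p1.shape != p2.shape:
        raise ValueError("labelings must have equal length")
    return float(adjusted_mutual_info_score(p1, p2, average_method="arithmetic"))


def select_partition_ami(replicates: list[ClusteringResult]) -> ClusteringResult:
    """Among replicate clusterings, return the one with the highest
    cumulative AMI to the others; ties break to lowest inertia, then
    lowest replicate index."""
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates")
    k0, f0 = replicates[0].k, replicates[0].n_frames
    for r in replicates[1:]:
        if r.k != k0 or r.n_frames != f0:
            raise ValueError("replicates must share k and frame count")
    m = len(replicates)
    ami = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            ami[i, j] = ami[j, i] = adjusted_mutual_information(
                replicates[i].labels, replicates[j].labels)
    cum = ami.sum(axis=1)
    order = sorted(range(m), key=lambda i: (-cum[i], replicates[i].inertia, i))
    return replicates[order[0]]


def replicated_clustering(
    X: np.ndarray,
    k: int,
    n_replicates: int = 10,
    n_restarts: int = 50,
    seed: int | np.random.Generator = 0,
    scan_index: pd.DataFrame | None = None,
    max_iter: int = 100,
) -> ClusteringResult:
    """Run ``n_replicates`` independent best-of-restarts clusterings and
    keep the replicate with the highest cumulative AMI."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reps = [kmeans_correlation(X, k, n_restarts, rng, scan_index, max_iter)
            for _ in range(n_replicates)]
    return select_partition_ami(reps)


# ---------------------------------------------------------------------------
# naming and grouping

def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def name_states(centroids: np.ndarray, templates: NetworkTemplates,
                method: str = "signed_parts") -> StateCatalog:
    """Name each centroid after the network it most resembles.

    ``signed_parts`` (default): split c into its positive part c+ and the
    magnitude of its negative part c-, compute the cosine of each part with
    every network's indicator vector, and name the state "NET+" or "NET-"
    after the single largest similarity. ``whole`` compares the full signed
    centroid instead, with the sign taken from the winning similarity's
    sign.
    """
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    if centroids.shape[1] != templates.n_rois:
        raise ValueError("centroid length must equal the number of ROIs")
    indicators = np.array([templates.indicator(net) for net in NETWORKS])
    names: list[str] = []
    table = np.zeros((centroids.shape[0], len(NETWORKS), 2))
    for i, c in enumerate(centroids):
        if np.allclose(c, 0):
            raise ValueError(f"centroid {i} is identically zero and cannot be named")
        if method == "signed_parts":
            pos, neg = np.maximum(c, 0.0), np.maximum(-c, 0.0)
            for j, ind in enumerate(indicators):
                table[i, j, 0] = _cosine(pos, ind)
                table[i, j, 1] = _cosine(neg, ind)
            j, s = np.unravel_index(np.argmax(table[i]), table[i].shape)
            names.append(f"{NETWORKS[j]}{'+' if s == 0 else '-'}")
        elif method == "whole":
            sims = np.array([_cosine(c, ind) for ind in indicators])
            table[i, :, 0] = np.maximum(sims, 0.0)
            table[i, :, 1] = np.maximum(-sims, 0.0)
            j = int(np.argmax(np.abs(sims)))
            names.append(f"{NETWORKS[j]}{'+' if sims[j] >= 0 else '-'}")
        else:
            raise ValueError(f"unknown naming method {method!r}")
    return StateCatalog(names=names, similarity_table=table)


def centroid_dendrogram(centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average-linkage hierarchical clustering of centroids on
    1 - Pearson correlation; returns (two-group labels in {1, 2}, the
    k x k correlation matrix, the linkage matrix)."""
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    k = centroids.shape[0]
    if k < 2:
        raise ValueError("need at least 2 centroids")
    corr = np.corrcoef(centroids)
    dist = 1.0 - corr
    condensed = dist[np.triu_indices(k, 1)]
    Z = hierarchy.linkage(condensed, method="average")
    groups = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    return groups, corr, Z
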