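"""Enterotype discovery: PAM clustering on Jensen-Shannon distances with
Calinski-Harabasz model selection and driver-genus identification.

The workflow mirrors the classic enterotyping recipe: genus-level relative
abundances -> pairwise Jensen-Shannon distances -> partition-around-medoids
for each candidate k -> pick k maximising a medoid-form CH index -> name
each cluster by the genus that dominates it significantly.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio
from scipy.special import comb
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceTable, ConfigError

__all__ = [
    "jsd_matrix",
    "pam",
    "PAMResult",
    "ch_index",
    "ch_index_centroid",
    "select_k",
    "EnterotypeModel",
    "kmeans_wss_curve",
    "driver_taxa",
    "MIN_CLUSTER_SIZE",
]

#: clusters smaller than this are kept in assignments but flagged and
#: excluded from downstream group statistics
MIN_CLUSTER_SIZE = 3

#: above this many candidate medoid sets PAM uses BUILD+SWAP local search;
#: below it the optimum is found exactly by enumeration
_EXACT_ENUMERATION_LIMIT = 10_000


# ---------------------------------------------------------------------------
# Jensen-Shannon distance
# ---------------------------------------------------------------------------

def jsd_matrix(rel_table: AbundanceTable, pseudocount: float = 0.0) -> skbio.DistanceMatrix:
    """Pairwise Jensen-Shannon distances between samples.

    distance(i, j) = sqrt(0.5*KL(p_i || m) + 0.5*KL(p_j || m)) with
    m = (p_i + p_j)/2, natural log, and 0*log 0 = 0. Entries lie in
    [0, sqrt(ln 2)]. ``pseudocount`` (added to every entry, rows then
    renormalised) exists only for parity with legacy scripts and defaults
    to 0: m is positive wherever either term is nonzero, so no epsilon is
    needed.
    """
    if rel_table.kind != "relative":
        raise ConfigError("jsd_matrix requires a relative-abundance table")
    P = rel_table.values.astype(float)
    if pseudocount:
        P = P + pseudocount
        P = P / P.sum(axis=1, keepdims=True)
    n = P.shape[0]
    div = np.zeros((n, n))
    logP = np.where(P > 0, np.log(P, where=P > 0, out=np.zeros_like(P)), 0.0)
    for i in range(n):
        m = 0.5 * (P[i] + P)
        with np.errstate(divide="ignore", invalid="ignore"):
            logm = np.where(m > 0, np.log(m, where=m > 0, out=np.zeros_like(m)), 0.0)
        kl_i = np.where(P[i] > 0, P[i] * (logP[i] - logm), 0.0).sum(axis=1)
        kl_j = np.where(P > 0, P * (logP - logm), 0.0).sum(axis=1)
        div[i] = 0.5 * (kl_i + kl_j)
    np.fill_diagonal(div, 0.0)
    div = np.clip(div, 0.0, None)
    d = np.sqrt(div)
    d = 0.5 * (d + d.T)  # symmetrise away float noise
    return skbio.DistanceMatrix(d, ids=rel_table.sample_ids)


# ---------------------------------------------------------------------------
# PAM (k-medoids)
# ---------------------------------------------------------------------------

@dataclass
class PAMResult:
    medoids: list[str]
    assignments: pd.Series  # sample id -> medoid id
    cost: float


def _total_cost(D: np.ndarray, medoids: list[int]) -> float:
    return float(D[:, medoids].min(axis=1).sum())


def _pam_build_swap(D: np.ndarray, k: int, order: np.ndarray) -> tuple[list[int], float]:
    """Classic BUILD then best-improving SWAP; candidates scanned in
    lexicographic-id order so ties resolve toward the smallest id."""
    n = D.shape[0]
    medoids: list[int] = []
    for _ in range(k):
        best, best_cost = None, np.inf
        for c in order:
            c = int(c)
            if c in medoids:
                continue
            cost = _total_cost(D, medoids + [c])
            if cost < best_cost - 1e-12:
                best, best_cost = c, cost
        medoids.append(best)
    cost = _total_cost(D, medoids)
    while True:
        best_swap, best_cost = None, cost
        for mi, _m in enumerate(medoids):
            for h in order:
                h = int(h)
                if h in medoids:
                    continue
                cand = medoids[:mi] + medoids[mi + 1:] + [h]
                c = _total_cost(D, cand)
                if c < best_cost - 1e-12:
                    best_swap, best_cost = (mi, h), c
        if best_swap is None:
            break
        mi, h = best_swap
        medoids = medoids[:mi] + medoids[mi + 1:] + [h]
        cost = best_cost
    return medoids, cost


def _pam_exact(D: np.ndarray, k: int, order: np.ndarray) -> tuple[list[int], float]:
    best, best_cost = None, np.inf
    for combo in itertools.combinations([int(i) for i in order], k):
        c = _total_cost(D, list(combo))
        if c < best_cost - 1e-12:
            best, best_cost = list(combo), c
    return best, best_cost


def pam(dist: skbio.DistanceMatrix, k: int) -> PAMResult:
    """Partition around medoids minimising total distance to nearest medoid.

    Small instances (at most ``10_000`` candidate medoid sets) are solved
    exactly by enumeration; larger ones use the classic BUILD phase
    followed by best-improving SWAP exchanges until no swap lowers the
    cost. Deterministic; ties break toward the lexicographically smallest
    sample id.
    """
    ids = list(dist.ids)
    n = len(ids)
    if not 1 <= k <= n:
        raise ConfigError(f"k must be in [1, {n}], got {k}")
    D = dist.data
    order = np.array(sorted(range(n), key=lambda i: ids[i]))
    if comb(n, k) <= _EXACT_ENUMERATION_LIMIT:
        medoid_idx, cost = _pam_exact(D, k, order)
    else:
        medoid_idx, cost = _pam_build_swap(D, k, order)
    medoid_idx = sorted(medoid_idx, key=lambda i: ids[i])
    # assign each sample to its nearest medoid; ties -> smallest medoid id
    sub = D[:, medoid_idx]
    nearest = sub.argmin(axis=1)
    assignments = pd.Series([ids[medoid_idx[j]] for j in nearest],
                            index=ids, name="medoid")
    return PAMResult(medoids=[ids[i] for i in medoid_idx],
                     assignments=assignments, cost=cost)


# ---------------------------------------------------------------------------
# Calinski-Harabasz index (medoid form)
# ---------------------------------------------------------------------------

def _sq_medoid(D2: np.ndarray, members: np.ndarray, order: np.ndarray) -> int:
    """Index minimising the sum of squared distances to ``members``;
    candidates restricted to members, ties toward smallest id."""
    best, best_val = None, np.inf
    member_set = set(int(m) for m in members)
    for c in order:
        c = int(c)
        if c not in member_set:
            continue
        v = D2[members, c].sum()
        if v < best_val - 1e-12:
            best, best_val = c, v
    return best


def ch_index(dist: skbio.DistanceMatrix, assignments: pd.Series) -> float:
    """Calinski-Harabasz score in a distance-only (medoid) formulation.

    W = sum over clusters of squared distances to the cluster medoid;
    B = sum over clusters of n_c * d(cluster medoid, global medoid)^2;
    CH = [B/(k-1)] / [W/(n-k)]. W = 0 (perfectly duplicated points)
    yields +inf, a degenerate maximum.
    """
    ids = list(dist.ids)
    n = len(ids)
    labels = assignments.loc[ids]
    uniq = labels.unique()
    k = len(uniq)
    if k < 2:
        raise ConfigError("ch_index requires at least 2 clusters")
    if k >= n:
        raise ConfigError("ch_index requires n > k")
    D2 = dist.data ** 2
    order = np.array(sorted(range(n), key=lambda i: ids[i]))
    g = _sq_medoid(D2, np.arange(n), order)
    W = 0.0
    B = 0.0
    for lab in uniq:
        members = np.flatnonzero((labels == lab).to_numpy())
        if len(members) == 0:
            raise ConfigError(f"empty cluster {lab!r}")
        m = _sq_medoid(D2, members, order)
        W += D2[members, m].sum()
        B += len(members) * D2[m, g]
    if W <= 0:
        warnings.warn("within-cluster dispersion is 0; CH is degenerate (+inf)",
                      stacklevel=2)
        return np.inf
    return float((B / (k - 1)) / (W / (n - k)))


def ch_index_centroid(coords: np.ndarray, assignments) -> float:
    """Calinski-Harabasz score from coordinates (the classic centroid form).

    CH = [B/(k-1)] / [W/(n-k)] with W the within-cluster sum of squared
    distances to cluster centroids and B the size-weighted squared
    distances of centroids to the grand mean. Used by :func:`select_k` on
    the PCoA embedding of the distance matrix: unlike the medoid form of
    :func:`ch_index`, every cluster contributes to B (the medoid form
    zeroes out the cluster holding the global medoid, which biases model
    selection toward merging nearby clusters).
    """
    X = np.asarray(coords, dtype=float)
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    k, n = len(uniq), X.shape[0]
    if k < 2 or k >= n:
        raise ConfigError("centroid CH requires 2 <= k < n")
    grand = X.mean(axis=0)
    W = 0.0
    B = 0.0
    for lab in uniq:
        members = X[labels == lab]
        c = members.mean(axis=0)
        W += ((members - c) ** 2).sum()
        B += len(members) * ((c - grand) ** 2).sum()
    if W <= 0:
        warnings.warn("within-cluster dispersion is 0; CH is degenerate (+inf)",
                      stacklevel=2)
        return np.inf
    return float((B / (k - 1)) / (W / (n - k)))


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

@dataclass
class EnterotypeModel:
    """A fitted enterotype clustering over one distance matrix."""

    k_range: list[int]
    ch_scores: dict[int, float]
    chosen_k: int
    medoids: dict[int, str]          # cluster label (1-based) -> medoid id
    assignments: pd.Series           # sample id -> cluster label
    wss_scores: dict[int, float] | None = None
    elbow_k: int | None = None
    drivers: dict[int, list] | None = None
    small_clusters: list[int] = field(default_factory=list)

    def cluster_sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()

    def to_dict(self) -> dict:
        return {
            "k_range": [int(k) for k in self.k_range],
            "ch_scores": {int(k): float(v) for k, v in self.ch_scores.items()},
            "wss_scores": None if self.wss_scores is None else
                {int(k): float(v) for k, v in self.wss_scores.items()},
            "chosen_k": int(self.chosen_k),
            "elbow_k": None if self.elbow_k is None else int(self.elbow_k),
            "medoids": {int(k): v for k, v in self.medoids.items()},
            "cluster_sizes": {int(k): int(v) for k, v in
                              self.cluster_sizes().items()},
            "small_clusters": [int(c) for c in self.small_clusters],
            "drivers": None if self.drivers is None else {
                int(c): [[g, float(a), None if p is None else float(p)]
                         for g, a, p in lst]
                for c, lst in self.drivers.items()},
        }


def _relabel(result: PAMResult) -> tuple[dict[int, str], pd.Series]:
    """1-based labels ordered by decreasing cluster size, ties by smallest
    medoid id."""
    sizes = result.assignments.value_counts()
    ordered = sorted(sizes.index, key=lambda m: (-sizes[m], m))
    label_of = {m: i + 1 for i, m in enumerate(ordered)}
    labels = result.assignments.map(label_of).rename("enterotype")
    medoids = {label_of[m]: m for m in ordered}
    return medoids, labels


def select_k(dist: skbio.DistanceMatrix, k_range=None,
             criterion: str = "centroid") -> EnterotypeModel:
    """Fit PAM for each k, score with the CH index, keep the argmax
    (ties -> smallest k).

    ``criterion='centroid'`` (default) scores each partition with the
    classic centroid CH on the PCoA embedding of the distances;
    ``'medoid'`` uses the distance-only medoid form of :func:`ch_index`
    (biased toward merging close clusters; kept for comparison).
    """
    if criterion not in ("centroid", "medoid"):
        raise ConfigError(f"unknown criterion {criterion!r}")
    n = len(dist.ids)
    if k_range is None:
        k_range = range(2, min(7, n))
    k_range = [int(k) for k in k_range]
    if not k_range or min(k_range) < 2 or max(k_range) > n - 1:
        raise ConfigError(f"k_range must lie within [2, {n - 1}]")
    if criterion == "centroid":
        from .diversity import pcoa
        coords = pcoa(dist).coordinates.to_numpy()
    ch_scores: dict[int, float] = {}
    fits: dict[int, PAMResult] = {}
    for k in k_range:
        fit = pam(dist, k)
        fits[k] = fit
        if criterion == "centroid":
            ch_scores[k] = ch_index_centroid(
                coords, fit.assignments.loc[list(dist.ids)].to_numpy())
        else:
            ch_scores[k] = ch_index(dist, fit.assignments)
    chosen_k = max(sorted(ch_scores), key=lambda k: (ch_scores[k], -k))
    medoids, labels = _relabel(fits[chosen_k])
    sizes = labels.value_counts()
    small = sorted(int(c) for c in sizes.index[sizes < MIN_CLUSTER_SIZE])
    return EnterotypeModel(k_range=k_range, ch_scores=ch_scores,
                           chosen_k=chosen_k, medoids=medoids,
                           assignments=labels, small_clusters=small)


# ---------------------------------------------------------------------------
# k-means WSS elbow curve (companion diagnostic)
# ---------------------------------------------------------------------------

def kmeans_wss_curve(dist: skbio.DistanceMatrix, k_range=None,
                     seed: int = 0) -> tuple[dict[int, float], int]:
    """Total within-cluster sum of squares per k from k-means in PCoA space.

    k-means needs coordinates, so samples are embedded on the
    positive-eigenvalue PCoA axes first. Ten random restarts per k plus a
    warm start from the previous k's solution (its centres plus the point
    farthest from its centre), which guarantees a non-increasing curve.
    The elbow is the k maximising the perpendicular distance of the curve
    from the chord joining its endpoints.
    """
    from sklearn.cluster import KMeans

    from .diversity import pcoa

    n = len(dist.ids)
    if k_range is None:
        k_range = range(2, min(7, n))
    k_range = sorted(int(k) for k in k_range)
    X = pcoa(dist).coordinates.to_numpy()
    wss: dict[int, float] = {}
    prev_labels = None
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        inertia, labels = km.inertia_, km.labels_
        if prev_labels is not None:
            centers = np.vstack([X[prev_labels == c].mean(axis=0)
                                 for c in np.unique(prev_labels)])
            resid = ((X - centers[prev_labels]) ** 2).sum(axis=1)
            extra = X[resid.argmax()]
            init = np.vstack([centers, extra])[:k]
            if init.shape[0] == k:
                km2 = KMeans(n_clusters=k, init=init, n_init=1).fit(X)
                if km2.inertia_ < inertia:
                    inertia, labels = km2.inertia_, km2.labels_
        wss[k] = float(inertia)
        prev_labels = labels
    ks = np.array(k_range, dtype=float)
    ws = np.array([wss[k] for k in k_range])
    # perpendicular distance from the chord between curve endpoints
    p0 = np.array([ks[0], ws[0]])
    p1 = np.array([ks[-1], ws[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    if norm == 0:
        elbow = k_range[0]
    else:
        pts = np.column_stack([ks, ws]) - p0
        dists = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / norm
        elbow = k_range[int(dists.argmax())]
    return wss, int(elbow)


# ---------------------------------------------------------------------------
# driver taxa
# ---------------------------------------------------------------------------

def driver_taxa(rel_table: AbundanceTable, assignments: pd.Series,
                alpha: float = 0.05,
                min_cluster_size: int = MIN_CLUSTER_SIZE) -> dict[int, list]:
    """Identify the genera that define each enterotype.

    Within each cluster, genera are ranked by mean relative abundance. The
    leading genus is a driver if every one-sided Mann-Whitney comparison
    (focal cluster greater than each other cluster) stays significant
    after Benjamini-Hochberg correction at ``alpha``; further genera are
    reported while that criterion keeps holding down the ranking. Clusters
    smaller than ``min_cluster_size`` are flagged undetermined (empty list).
    """
    if rel_table.kind != "relative":
        raise ConfigError("driver_taxa requires a relative-abundance table")
    labels = assignments.loc[rel_table.sample_ids]
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ConfigError("driver_taxa requires at least 2 clusters")
    sizes = labels.value_counts()
    eligible = [c for c in clusters if sizes[c] >= min_cluster_size]
    drivers: dict[int, list] = {}
    data = rel_table.data
    for c in clusters:
        if c not in eligible or len(eligible) < 2:
            drivers[c] = []
            continue
        focal = data.loc[(labels == c).to_numpy()]
        means = focal.mean(axis=0).sort_values(ascending=False)
        others = [o for o in eligible if o != c]
        pvals, keys = [], []
        for genus in means.index:
            x = focal[genus].to_numpy()
            for o in others:
                y = data.loc[(labels == o).to_numpy(), genus].to_numpy()
                if np.all(x == x[0]) and np.all(y == x[0]):
                    p = 1.0  # completely tied -> no evidence
                else:
                    p = mannwhitneyu(x, y, alternative="greater").pvalue
                pvals.append(p)
                keys.append((genus, o))
        adj = multipletests(pvals, method="fdr_bh")[1]
        adj_of = dict(zip(keys, adj))
        found = []
        for genus in means.index:
            genus_adj = [adj_of[(genus, o)] for o in others]
            if all(p < alpha for p in genus_adj):
                found.append((genus, float(means[genus]), float(max(genus_adj))))
            else:
                break
        drivers[c] = found
    return drivers
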