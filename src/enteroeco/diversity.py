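"""Alpha diversity, Bray-Curtis beta diversity, PCoA and PERMANOVA.

These estimators are written out from their defining formulas (they are
the quantities the downstream contrasts feed on); the scipy/scikit-bio
equivalents serve as independent cross-checks in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio

from .containers import AbundanceTable, ConfigError, SchemaError, TestResult

__all__ = [
    "shannon",
    "chao1",
    "observed_taxa",
    "alpha_diversity",
    "bray_curtis_matrix",
    "pcoa",
    "OrdinationResult",
    "permanova",
]


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def shannon(counts, base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i log p_i over nonzero p_i.

    Defaults to natural log (nats); pass ``base=2`` for bits. Works on
    counts or relative abundances.
    """
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise SchemaError("negative abundances")
    total = x.sum()
    if total <= 0:
        raise SchemaError("shannon is undefined for an all-zero vector")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return max(h, 0.0)


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1)).

    F1/F2 are singleton/doubleton counts; the +1 in the denominator keeps
    the estimator defined when no doubletons are observed. Requires
    integer counts.
    """
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise SchemaError("negative counts")
    if not np.allclose(x, np.rint(x)):
        raise SchemaError("chao1 requires integer counts")
    x = np.rint(x).astype(np.int64)
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def observed_taxa(counts) -> int:
    return int((np.asarray(counts) > 0).sum())


def alpha_diversity(table: AbundanceTable, base: float | None = None) -> pd.DataFrame:
    """Per-sample Shannon, Chao1 and observed richness on a counts table."""
    rows = {}
    for sid in table.sample_ids:
        x = table.data.loc[sid].to_numpy()
        rows[sid] = {
            "shannon": shannon(x, base=base),
            "chao1": chao1(x),
            "observed_taxa": observed_taxa(x),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis_matrix(table: AbundanceTable) -> skbio.DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity 1 - 2*sum(min)/ (sum_x + sum_y)."""
    X = table.values.astype(float)
    sums = X.sum(axis=1)
    if (sums == 0).sum() >= 2:
        raise SchemaError("Bray-Curtis is undefined between two all-zero samples")
    n = X.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        mins = np.minimum(X[i], X).sum(axis=1)
        denom = sums[i] + sums
        with np.errstate(invalid="ignore", divide="ignore"):
            d[i] = np.where(denom > 0, 1.0 - 2.0 * mins / denom, 0.0)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return skbio.DistanceMatrix(np.clip(d, 0.0, 1.0), ids=table.sample_ids)


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame        # samples x retained axes
    eigenvalues: np.ndarray          # positive, non-increasing
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray


def pcoa(dist: skbio.DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical scaling (principal coordinates analysis).

    Gower-centres -0.5*D^2, eigendecomposes, and embeds on the
    positive-eigenvalue axes only; negative eigenvalues (from non-Euclidean
    distances) are reported but never embedded. Axis signs are fixed so
    the largest-magnitude loading on each axis is positive.
    """
    D = dist.data
    n = D.shape[0]
    A = -0.5 * D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    B = 0.5 * (B + B.T)
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-10 if n else 0.0
    pos = eigvals > tol
    lam = eigvals[pos]
    vec = eigvecs[:, pos]
    neg = eigvals[eigvals < -tol]
    if n_axes is not None and n_axes > len(lam):
        warnings.warn(
            f"requested {n_axes} axes but only {len(lam)} positive eigenvalues; "
            "truncating", stacklevel=2)
        n_axes = len(lam)
    if n_axes is not None:
        lam, vec = lam[:n_axes], vec[:, :n_axes]
    coords = vec * np.sqrt(lam)
    for j in range(coords.shape[1]):  # deterministic sign convention
        col = coords[:, j]
        if len(col) and col[np.abs(col).argmax()] < 0:
            coords[:, j] = -col
    denom = lam.sum() if lam.size else 1.0
    prop = lam / denom if lam.size else lam
    cdf = pd.DataFrame(coords, index=list(dist.ids),
                       columns=[f"PCo{j + 1}" for j in range(coords.shape[1])])
    return OrdinationResult(coordinates=cdf, eigenvalues=lam,
                            proportion_explained=prop,
                            negative_eigenvalues=neg)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _ss_within(D2: np.ndarray, groups: list[np.ndarray]) -> float:
    return sum(D2[np.ix_(g, g)].sum() / (2.0 * len(g)) for g in groups)


def permanova(dist: skbio.DistanceMatrix, labels, n_perm: int = 999,
              seed: int = 0) -> TestResult:
    """One-way PERMANOVA on a distance matrix.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within sums the analogous
    within-group terms; pseudo-F = [(SS_total - SS_within)/(g-1)] /
    [SS_within/(n-g)]. The p-value counts whole-label permutations with
    F at least the observed, with the +1 correction.
    """
    ids = list(dist.ids)
    n = len(ids)
    lab = pd.Series(labels).loc[ids] if isinstance(labels, pd.Series) \
        else pd.Series(list(labels), index=ids)
    uniq = lab.unique()
    g = len(uniq)
    if g < 2:
        raise ConfigError("PERMANOVA requires at least 2 groups")
    counts = lab.value_counts()
    if (counts < 2).any():
        raise ConfigError("every group needs at least 2 samples")
    D2 = dist.data ** 2
    if not D2.any():
        raise ConfigError("all distances are zero; pseudo-F undefined")
    ss_total = D2.sum() / (2.0 * n)
    codes = pd.factorize(lab)[0]
    groups = [np.flatnonzero(codes == c) for c in range(g)]
    ss_within = _ss_within(D2, groups)
    df_between, df_within = g - 1, n - g
    f_obs = ((ss_total - ss_within) / df_between) / (ss_within / df_within)
    rng = np.random.default_rng(seed)
    hits = 0
    idx = np.arange(n)
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        pg = [perm[gidx] for gidx in groups]
        ssw = _ss_within(D2, pg)
        f = ((ss_total - ssw) / df_between) / (ssw / df_within)
        if f >= f_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    r2 = 1.0 - ss_within / ss_total
    return TestResult(method="PERMANOVA", statistic=float(f_obs), p_value=float(p),
                      df=df_between, permutations=n_perm, effect_size=float(r2))
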