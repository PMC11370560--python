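"""Unsupervised behavioural phenotyping.

Twelve open-field / elevated-zero-maze parameters per animal are z-scored,
reduced by PCA (keeping the leading components that explain more than a
variance threshold, 75% by default), and clustered with k-means.  The number
of clusters is chosen by a bootstrap stability analysis: for each candidate
k, replicate fits on resampled rows (with fresh random centroid
initialisations) are compared against the full-data fit with five label
agreement metrics — homogeneity, completeness, V-measure, adjusted Rand
index, adjusted mutual information — and the k with the highest mean ARI is
recommended.

PCA, k-means (Lloyd's algorithm) and the agreement metrics are implemented
here from the defining formulas so every number in the stability table is
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import stats_engine

__all__ = [
    "BEHAVIOR_PARAMS",
    "PCAModel",
    "ClusterModel",
    "StabilityResult",
    "AgreementScores",
    "standardize",
    "pca_reduce",
    "select_components",
    "kmeans_fit",
    "agreement_metrics",
    "stability_table",
    "cluster_by_group_table",
    "phenotype_pipeline",
]

#: the 12 behaviour-battery parameters, in canonical column order:
#: open-field distance, speed, centre time/entries/latency/distance, then
#: elevated-zero-maze distance, speed, open-arm time/entries/latency/distance
BEHAVIOR_PARAMS = (
    "OFB distance",
    "OFB speed",
    "OFB CT",
    "OFB CE",
    "OFB CL",
    "OFB CD",
    "EZM distance",
    "EZM speed",
    "EZM OAT",
    "EZM OAE",
    "EZM OAL",
    "EZM OAD",
)


@dataclass
class PCAModel:
    """Standardization stats plus the full loading matrix.

    ``loadings`` columns are unit eigenvectors of the correlation matrix,
    variance-sorted descending, signed so each component's largest-magnitude
    loading is positive.  ``explained_variance_ratio`` sums to 1.
    """

    feature_names: tuple
    means: np.ndarray
    sds: np.ndarray  # population SDs (ddof=0)
    loadings: np.ndarray  # p x p, columns = components
    explained_variance_ratio: np.ndarray

    def transform(self, table: pd.DataFrame, n_components: int | None = None) -> np.ndarray:
        z = (table[list(self.feature_names)].to_numpy(dtype=float) - self.means) / self.sds
        scores = z @ self.loadings
        return scores if n_components is None else scores[:, :n_components]

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
        }


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray
    labels: np.ndarray
    inertia: float
    seed: int | None
    n_init: int


class AgreementScores(NamedTuple):
    """Label-agreement metrics in the conventional reporting order."""

    homogeneity: float
    completeness: float
    v_measure: float
    ari: float
    ami: float


@dataclass
class StabilityResult:
    table: pd.DataFrame  # index k, columns = AgreementScores fields
    recommended_k: int


def standardize(table: pd.DataFrame):
    """Z-score the 12-parameter table (population SD); returns (Z, model).

    The returned :class:`PCAModel` has identity loadings until
    :func:`pca_reduce` fills them in; its means/SDs already define the
    reusable transform.  A zero-variance column is a hard error naming the
    parameter, since it cannot be scaled to unit variance.
    """
    cols = [c for c in BEHAVIOR_PARAMS if c in table.columns]
    if len(cols) < 1:
        raise ValueError("no recognised behaviour parameter columns")
    x = table[cols].to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 animals to standardize")
    if np.isnan(x).any():
        raise ValueError("behaviour table contains missing values")
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=0)
    dead = np.where(sds == 0)[0]
    if dead.size:
        raise ValueError(f"zero-variance parameter(s): {[cols[i] for i in dead]}")
    z = (x - means) / sds
    model = PCAModel(
        feature_names=tuple(cols),
        means=means,
        sds=sds,
        loadings=np.eye(len(cols)),
        explained_variance_ratio=np.full(len(cols), np.nan),
    )
    return z, model


def pca_reduce(z: np.ndarray, model: PCAModel | None = None):
    """PCA via eigendecomposition of the covariance of the z-scored matrix.

    Components are sorted by explained variance (descending); each is signed
    so its largest-magnitude loading is positive.  Returns
    (model, scores) where scores = z @ loadings.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    n, p = z.shape
    cov = (z.T @ z) / n  # population covariance of already-centred data
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: dominant loading of each component positive
    for j in range(p):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    ratios = evals / evals.sum()
    if model is None:
        model = PCAModel(
            feature_names=tuple(f"x{i}" for i in range(p)),
            means=np.zeros(p),
            sds=np.ones(p),
            loadings=evecs,
            explained_variance_ratio=ratios,
        )
    else:
        model.loadings = evecs
        model.explained_variance_ratio = ratios
    return model, z @ evecs


def select_components(ratios, threshold: float = 0.75) -> int:
    """Smallest m whose cumulative explained-variance ratio exceeds threshold."""
    r = np.asarray(ratios, dtype=float)
    if r.size == 0:
        raise ValueError("empty ratio sequence")
    cum = np.cumsum(r)
    above = np.where(cum > threshold)[0]
    if above.size == 0:
        return int(r.size)
    return int(above[0]) + 1


def _lloyd_once(x: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 300):
    n = x.shape[0]
    centroids = x[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        # revive empty clusters at the point farthest from its own centroid,
        # never stealing the sole member of another cluster
        for c in range(k):
            if not (new_labels == c).any():
                sizes = np.bincount(new_labels, minlength=k)
                dist_own = d2[np.arange(n), new_labels].copy()
                dist_own[sizes[new_labels] <= 1] = -np.inf
                far = int(dist_own.argmax())
                centroids[c] = x[far]
                new_labels[far] = c
                d2[:, c] = ((x - centroids[c]) ** 2).sum(axis=1)
        new_centroids = np.vstack(
            [x[new_labels == c].mean(axis=0) if (new_labels == c).any() else centroids[c]
             for c in range(k)]
        )
        shift = np.abs(new_centroids - centroids).max()
        converged = (new_labels == labels).all() or shift < 1e-6
        centroids, labels = new_centroids, new_labels
        if converged:
            break
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    inertia = float(d2[np.arange(n), labels].sum())
    return centroids, labels, inertia


def kmeans_fit(
    x: np.ndarray, k: int, n_init: int = 10, seed: int | None = None
) -> ClusterModel:
    """Lloyd's k-means, best of ``n_init`` random initialisations by inertia.

    Initial centroids are distinct data points; iteration stops when the
    assignment is unchanged or the maximum centroid shift is < 1e-6.  A
    cluster emptied during iteration is re-seeded at the point farthest from
    its current centroid, so every returned cluster is non-empty.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} must be in 1..{n}")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        centroids, labels, inertia = _lloyd_once(x, k, rng)
        if best is None or inertia < best[2]:
            best = (centroids, labels, inertia)
    return ClusterModel(
        k=k,
        centroids=best[0],
        labels=best[1],
        inertia=best[2],
        seed=seed,
        n_init=n_init,
    )


def _entropy(counts: np.ndarray) -> float:
    c = counts[counts > 0].astype(float)
    n = c.sum()
    p = c / n
    return float(-(p * np.log(p)).sum())


def _comb2(x: np.ndarray) -> np.ndarray:
    return x * (x - 1) / 2.0


def _expected_mi(a_counts: np.ndarray, b_counts: np.ndarray, n: int) -> float:
    """Expected mutual information under the permutation (hypergeometric) model."""
    emi = 0.0
    log_n = np.log(n)
    lg = gammaln
    for ai in a_counts:
        for bj in b_counts:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                term_log_weight = (
                    lg(ai + 1)
                    + lg(bj + 1)
                    + lg(n - ai + 1)
                    + lg(n - bj + 1)
                    - lg(n + 1)
                    - lg(nij + 1)
                    - lg(ai - nij + 1)
                    - lg(bj - nij + 1)
                    - lg(n - ai - bj + nij + 1)
                )
                emi += (
                    (nij / n)
                    * (np.log(nij) + log_n - np.log(ai) - np.log(bj))
                    * np.exp(term_log_weight)
                )
    return float(emi)


def agreement_metrics(labels_a, labels_b) -> AgreementScores:
    """Five clustering-agreement scores from the label contingency table.

    Homogeneity/completeness/V are the conditional-entropy scores (V = their
    harmonic mean); ARI is the pair-counting index adjusted for chance; AMI
    is mutual information adjusted by its permutation-model expectation with
    an arithmetic-mean normaliser.  Treating ``labels_a`` as the reference
    classes, homogeneity asks whether each found cluster contains a single
    class.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labelings must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ct = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(ct, (ai, bi), 1)
    a_counts = ct.sum(axis=1)
    b_counts = ct.sum(axis=0)

    h_a = _entropy(a_counts)
    h_b = _entropy(b_counts)
    # conditional entropies from the joint table
    nz = ct > 0
    joint = ct[nz] / n
    h_a_given_b = float(-(joint * (np.log(ct[nz]) - np.log(b_counts[np.where(nz)[1]]))).sum())
    h_b_given_a = float(-(joint * (np.log(ct[nz]) - np.log(a_counts[np.where(nz)[0]]))).sum())
    homogeneity = 1.0 if h_a == 0 else 1.0 - h_a_given_b / h_a
    completeness = 1.0 if h_b == 0 else 1.0 - h_b_given_a / h_b
    if homogeneity + completeness == 0:
        v = 0.0
    else:
        v = 2 * homogeneity * completeness / (homogeneity + completeness)

    # adjusted Rand: pair counting
    sum_ij = _comb2(ct).sum()
    sum_a = _comb2(a_counts).sum()
    sum_b = _comb2(b_counts).sum()
    total = _comb2(np.array([n]))[0]
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    ari = 1.0 if max_index == expected else float((sum_ij - expected) / (max_index - expected))

    # adjusted mutual information
    mi = float((joint * (np.log(ct[nz] * n)
                         - np.log(a_counts[np.where(nz)[0]])
                         - np.log(b_counts[np.where(nz)[1]]))).sum())
    if h_a == 0 and h_b == 0:
        ami = 1.0
    else:
        emi = _expected_mi(a_counts.astype(int), b_counts.astype(int), n)
        denom = (h_a + h_b) / 2.0 - emi
        if abs(denom) < np.finfo(float).eps:
            denom = np.copysign(np.finfo(float).eps, denom if denom != 0 else 1.0)
        ami = float((mi - emi) / denom)

    return AgreementScores(
        homogeneity=float(np.clip(homogeneity, 0.0, 1.0)),
        completeness=float(np.clip(completeness, 0.0, 1.0)),
        v_measure=float(np.clip(v, 0.0, 1.0)),
        ari=float(min(ari, 1.0)),
        ami=float(min(ami, 1.0)),
    )


def stability_table(
    scores: np.ndarray,
    k_range=range(3, 7),
    n_boot: int = 100,
    n_init: int = 10,
    seed: int = 0,
) -> StabilityResult:
    """Bootstrap stability of k-means over a range of k.

    For each k: fit a reference model on the full score matrix, then
    ``n_boot`` replicate fits on bootstrap resamples of the rows (each with
    fresh random centroid initialisations); compare replicate labels with
    reference labels on the unique resampled rows via
    :func:`agreement_metrics` and report each metric's mean.  The
    recommended k maximises mean ARI (ties go to the smaller k).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    rng = np.random.default_rng(seed)
    rows = {}
    for k in k_range:
        ref = kmeans_fit(scores, k, n_init=n_init, seed=int(rng.integers(2**31)))
        reps = np.zeros((n_boot, 5))
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            rep = kmeans_fit(
                scores[idx], k, n_init=n_init, seed=int(rng.integers(2**31))
            )
            shared, first_pos = np.unique(idx, return_index=True)
            reps[b] = agreement_metrics(ref.labels[shared], rep.labels[first_pos])
        rows[k] = reps.mean(axis=0)
    table = pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=list(AgreementScores._fields),
    )
    table.index.name = "k"
    best_k = int(table["ari"].idxmax())  # idxmax returns the first (smallest) argmax
    return StabilityResult(table=table, recommended_k=best_k)


def cluster_by_group_table(labels, roster: pd.DataFrame, group: str = "sex"):
    """Cluster x group contingency table with its chi-square test.

    ``labels`` is a Series indexed by tag or an array aligned with the
    roster.  Returns (table DataFrame, TestResult).
    """
    if isinstance(labels, pd.Series):
        aligned = labels.reindex(roster["tag"])
        if aligned.isna().any():
            raise ValueError("labels do not cover the roster")
        lab = aligned.to_numpy()
    else:
        lab = np.asarray(labels)
        if lab.size != len(roster):
            raise ValueError("labels must align with the roster")
    table = pd.crosstab(pd.Series(lab, name="cluster"),
                        roster[group].to_numpy())
    result = stats_engine.chi_square_test(table.to_numpy())
    return table, result


def phenotype_pipeline(
    behavior: pd.DataFrame,
    k: int | str = "auto",
    variance_threshold: float = 0.75,
    k_range=range(3, 7),
    n_boot: int = 100,
    n_init: int = 10,
    seed: int = 0,
):
    """standardize -> PCA -> component selection -> (stability) -> k-means.

    ``k="auto"`` runs the bootstrap stability analysis and clusters at the
    recommended k; an integer k skips the recommendation but still reports
    the stability table.  Returns a dict with the PCA model, scores, number
    of retained components, stability result, and the final ClusterModel.
    """
    z, model = standardize(behavior)
    model, all_scores = pca_reduce(z, model)
    m = select_components(model.explained_variance_ratio, variance_threshold)
    scores = all_scores[:, :m]
    stability = stability_table(
        scores, k_range=k_range, n_boot=n_boot, n_init=n_init, seed=seed
    )
    k_used = stability.recommended_k if k == "auto" else int(k)
    fit = kmeans_fit(scores, k_used, n_init=n_init, seed=seed)
    labels = pd.Series(fit.labels, index=behavior["tag"], name="cluster")
    return {
        "pca": model,
        "scores": scores,
        "n_components": m,
        "stability": stability,
        "model": fit,
        "labels": labels,
    }
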