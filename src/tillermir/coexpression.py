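"""DEG screening, trend profiles, k-means co-expression clusters, and
generic term enrichment.

Profiles are per-feature z-scores of log2(tissue mean + 1) across the three
tissues, so clustering groups genes by expression *trend* regardless of
absolute level. Clustering is Lloyd's algorithm with k-means++-style
seeding from a seeded RNG; k defaults to 6, the number of trend groups the
three-tissue design supports. Enrichment is an upper-tail hypergeometric
test over a user-supplied feature->term map with BH correction across
terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import DeRecord
from .io import AnnotationMap, ExpressionMatrix, TillermirError

DEFAULT_K = 6
SCREEN_LFC = 2.0


def screen_degs(de_records: Iterable[DeRecord], lfc_screen: float = SCREEN_LFC) -> set[str]:
    """Features with |log2FC| >= lfc_screen (inclusive) in at least one of
    the supplied comparisons. Pass the concatenation of all pairwise
    comparisons to take the union."""
    if lfc_screen <= 0:
        raise TillermirError("lfc_screen must be > 0")
    return {r.feature_id for r in de_records if abs(r.log2fc) >= lfc_screen}


@dataclass
class ProfileMatrix:
    """Normalized per-feature trend profiles over the tissue order."""

    tissue_order: tuple[str, ...]
    raw_means: pd.DataFrame  # features x tissues, arithmetic replicate means
    profiles: pd.DataFrame  # z-scored log2(mean+1), constant features dropped
    constant_features: frozenset[str] = field(default_factory=frozenset)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.profiles.index)


def build_profiles(matrix: ExpressionMatrix, features: Iterable[str] | None = None) -> ProfileMatrix:
    """Tissue means -> log2(mean+1) -> per-feature z-score (population sd).

    Features whose three tissue means are equal have zero variance; they
    are flagged constant and excluded from clustering.
    """
    means = matrix.tissue_means()
    if features is not None:
        features = list(features)
        unknown = set(features) - set(means.index)
        if unknown:
            raise TillermirError(f"unknown features requested: {sorted(unknown)[:3]}")
        means = means.loc[[f for f in means.index if f in set(features)]]
    log_means = np.log2(means + 1.0)
    mu = log_means.mean(axis=1)
    sd = log_means.std(axis=1, ddof=0)
    constant = sd == 0
    profiles = log_means.loc[~constant].sub(mu[~constant], axis=0).div(sd[~constant], axis=0)
    return ProfileMatrix(
        tissue_order=tuple(means.columns),
        raw_means=means,
        profiles=profiles,
        constant_features=frozenset(log_means.index[constant]),
    )


@dataclass
class ClusterResult:
    k: int
    assignments: dict[str, int]  # feature -> cluster label 1..k
    centroids: np.ndarray  # k x n_tissues
    inertia: float
    inertia_history: list[float]
    seed: int

    def members(self, label: int) -> set[str]:
        return {f for f, c in self.assignments.items() if c == label}


def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: first centre uniform, then proportional to
    squared distance from the nearest chosen centre."""
    n = x.shape[0]
    centres = [x[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(
            ((x[:, None, :] - np.asarray(centres)[None, :, :]) ** 2).sum(axis=2), axis=1
        )
        total = d2.sum()
        if total == 0:
            centres.append(x[rng.integers(n)])
            continue
        centres.append(x[rng.choice(n, p=d2 / total)])
    return np.asarray(centres)


def kmeans_cluster(
    profiles: ProfileMatrix,
    k: int = DEFAULT_K,
    seed: int = 0,
    max_iter: int = 300,
) -> ClusterResult:
    """Lloyd's k-means with Euclidean distance on the trend profiles.

    Deterministic given the seed; distance ties break toward the lowest
    cluster index; an emptied cluster is repaired by re-seeding it with the
    point farthest from its current centroid. All k clusters are non-empty
    at return, and the recorded inertia history is non-increasing.
    """
    x = profiles.profiles.to_numpy(dtype=float)
    ids = profiles.feature_ids
    n = x.shape[0]
    if k < 1:
        raise TillermirError("k must be >= 1")
    if k > n:
        raise TillermirError(f"k={k} exceeds the {n} clusterable profiles")
    rng = np.random.default_rng(seed)
    centroids = _kmeanspp_init(x, k, rng)
    labels = np.zeros(n, dtype=int)
    history: list[float] = []
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)  # argmin takes the lowest index on ties
        # repair empty clusters with the globally worst-fitted point
        for c in range(k):
            if not (new_labels == c).any():
                worst = d2[np.arange(n), new_labels].argmax()
                new_labels[worst] = c
                d2[worst, :] = np.inf
        inertia = float(((x - centroids[new_labels]) ** 2).sum())
        history.append(inertia)
        converged = (new_labels == labels).all() and len(history) > 1
        labels = new_labels
        for c in range(k):
            centroids[c] = x[labels == c].mean(axis=0)
        if converged:
            break
    final_inertia = float(((x - centroids[labels]) ** 2).sum())
    history.append(final_inertia)
    return ClusterResult(
        k=k,
        assignments={fid: int(lab) + 1 for fid, lab in zip(ids, labels)},
        centroids=centroids,
        inertia=final_inertia,
        inertia_history=history,
        seed=seed,
    )


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    label: str
    k_hits: int  # term members in the cluster
    K_term: int  # term members in the background
    n_cluster: int
    N_background: int
    p_value: float  # upper tail P(X >= k_hits)
    fdr: float


def enrich(
    cluster_features: set[str],
    background: set[str],
    annotations: AnnotationMap,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each term in the cluster
    against the background; BH across terms; sorted by p ascending.

    Terms with no member in the background are skipped with a warning.
    """
    if not cluster_features <= background:
        raise TillermirError("cluster features must be a subset of the background")
    N = len(background)
    n = len(cluster_features)
    rows: list[tuple[str, int, int, float]] = []
    for term in sorted(annotations.all_terms()):
        members = annotations.features_for(term) & background
        K = len(members)
        if K == 0:
            warnings.warn(f"term {term!r} has no members in the background; skipped")
            continue
        k_hits = len(members & cluster_features)
        # P(X >= k_hits) under Hypergeom(N, K, n); sf(k-1) is the upper tail
        p = float(stats.hypergeom.sf(k_hits - 1, N, K, n))
        rows.append((term, k_hits, K, min(p, 1.0)))
    if not rows:
        return []
    pvals = [r[3] for r in rows]
    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(
            term_id=term,
            label=annotations.labels.get(term, ""),
            k_hits=k_hits,
            K_term=K,
            n_cluster=n,
            N_background=N,
            p_value=p,
            fdr=float(f),
        )
        for (term, k_hits, K, p), f in zip(rows, fdrs)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def assignments_to_frame(result: ClusterResult) -> pd.DataFrame:
    return pd.DataFrame(
        sorted(result.assignments.items()), columns=["feature_id", "cluster"]
    )


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.term_id, r.label, r.k_hits, r.K_term, r.n_cluster, r.N_background,
             r.p_value, r.fdr)
            for r in results
        ],
        columns=["term", "label", "k", "K", "n", "N", "p_value", "fdr"],
    )
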