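"""Subgroup discovery: PCA, Ward clustering, elbow cut and ROC cut-point.

The initial and follow-up FMA scores are strongly correlated, so before
clustering they are replaced by their principal components (an orthogonal
rotation of the standardized pair — decorrelation, not dimension
reduction; both components are kept by default).  Agglomerative
hierarchical clustering with Ward's minimum-variance criterion on squared
Euclidean distances groups the patients; the number of clusters is chosen
where the within-cluster sum-of-squares (WSS) profile has its sharpest
kink (maximal second forward difference), and the high-scoring cluster is
converted into a clinical cut-point on the initial score by maximizing
Youden's J over an exhaustive ROC search.

All steps are deterministic given the input order: Ward merges break cost
ties toward the lexicographically smallest cluster-index pair, the elbow
breaks ties toward the smaller k, and the ROC search breaks J ties toward
the lower threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filters import stratify_by_threshold
from .regression import ALPHA, limb_battery

__all__ = [
    "PCAScores",
    "ClusterSolution",
    "CutpointResult",
    "pca_scores",
    "ward_cluster",
    "elbow_k",
    "roc_cutoff",
    "stratified_reanalysis",
    "discover_subgroups",
]


# ---------------------------------------------------------------------------
# PCA on the (initial, follow-up) pair
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCAScores:
    """Principal-component scores of the standardized score pair."""

    scores: np.ndarray          # (n, 2) component scores
    loadings: np.ndarray        # (2, 2) columns = components
    explained_shares: np.ndarray  # sums to 1


def pca_scores(initial: np.ndarray, followup: np.ndarray) -> PCAScores:
    """PCA of the standardized (initial, follow-up) score pair.

    Columns are z-scored (ddof=1) before the eigendecomposition of their
    correlation matrix, so the component variances are the eigenvalues
    (1 + r, 1 - r).  Sign convention: the largest-magnitude loading of each
    component is positive.
    """
    initial = np.asarray(initial, dtype=float)
    followup = np.asarray(followup, dtype=float)
    if len(initial) < 3:
        raise ValueError("need n >= 3")
    Z = np.empty((len(initial), 2))
    for j, col in enumerate((initial, followup)):
        sd = col.std(ddof=1)
        if sd == 0:
            raise ValueError(f"column {j} is constant; PCA undefined")
        Z[:, j] = (col - col.mean()) / sd
    corr = (Z.T @ Z) / (len(Z) - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        if eigvecs[np.argmax(np.abs(eigvecs[:, j])), j] < 0:
            eigvecs[:, j] *= -1
    return PCAScores(
        scores=Z @ eigvecs,
        loadings=eigvecs,
        explained_shares=np.clip(eigvals, 0, None) / eigvals.sum(),
    )


# ---------------------------------------------------------------------------
# Ward's method on squared Euclidean distances
# ---------------------------------------------------------------------------

@dataclass
class ClusterSolution:
    """Ward linkage with per-k within-cluster sum of squares.

    ``merges`` has one row per merge: (cluster_a, cluster_b, delta_ess,
    new_size), clusters numbered scipy-style (originals 0..n-1, merge i
    creates cluster n+i).  Merge heights (the increase in total
    within-cluster sum of squares, delta ESS) are nondecreasing.
    """

    n: int
    merges: np.ndarray
    wss: np.ndarray  # WSS for k = 1..n (index k-1)
    chosen_k: int | None = None
    labels: np.ndarray | None = field(default=None)

    def labels_for_k(self, k: int) -> np.ndarray:
        """Cluster labels in {1..k}, numbered by first member index."""
        if not 1 <= k <= self.n:
            raise ValueError(f"k must be in 1..{self.n}")
        parent = list(range(2 * self.n - 1))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for step, (a, b, _, _) in enumerate(self.merges[: self.n - k]):
            u = self.n + step
            parent[find(int(a))] = u
            parent[find(int(b))] = u
        roots = [find(i) for i in range(self.n)]
        seen: dict[int, int] = {}
        labels = np.empty(self.n, dtype=int)
        for i, r in enumerate(roots):
            if r not in seen:
                seen[r] = len(seen) + 1
            labels[i] = seen[r]
        return labels


def ward_cluster(scores: np.ndarray) -> ClusterSolution:
    """Agglomerative Ward clustering of row vectors.

    At each step the pair of clusters whose merge least increases the total
    within-cluster sum of squares is united (Lance-Williams update on the
    ESS-increase matrix, initialized with half the squared Euclidean
    distances).  Cost ties are broken toward the lowest cluster-index pair,
    so zero-distance (duplicate point) merges happen first and the result
    is fully deterministic.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    if n < 3:
        raise ValueError("need n >= 3 points")

    total = 2 * n - 1
    D = np.full((total, total), np.inf)
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=-1)
    D[:n, :n] = sq / 2.0
    np.fill_diagonal(D, np.inf)
    sizes = np.zeros(total, dtype=int)
    sizes[:n] = 1
    active = list(range(n))

    merges = np.empty((n - 1, 4))
    for step in range(n - 1):
        act = np.array(active)
        sub = D[np.ix_(act, act)]
        flat = int(np.argmin(sub))  # row-major: lexicographically smallest pair
        i_, j_ = divmod(flat, len(act))
        if i_ > j_:
            i_, j_ = j_, i_
        a, b = int(act[i_]), int(act[j_])
        height = float(D[a, b])
        u = n + step
        na, nb = sizes[a], sizes[b]
        merges[step] = (a, b, height, na + nb)
        # Lance-Williams update of the ESS-increase to every other cluster
        rest = [c for c in active if c not in (a, b)]
        if rest:
            rest_arr = np.array(rest)
            nk = sizes[rest_arr]
            duv = ((na + nk) * D[a, rest_arr] + (nb + nk) * D[b, rest_arr] - nk * height) / (
                na + nb + nk
            )
            D[u, rest_arr] = duv
            D[rest_arr, u] = duv
        sizes[u] = na + nb
        active = rest + [u]

    heights = merges[:, 2]
    wss = np.zeros(n)
    # WSS(k) = sum of the first n-k merge costs; WSS(1) = total SS
    cum = np.concatenate([[0.0], np.cumsum(heights)])
    for k in range(1, n + 1):
        wss[k - 1] = cum[n - k]
    return ClusterSolution(n=n, merges=merges, wss=wss)


def elbow_k(wss: np.ndarray, k_max: int | None = None, method: str = "distance") -> int:
    """Choose k at the elbow of the WSS profile.

    ``wss[k-1]`` is the within-cluster sum of squares at k clusters.  Two
    documented rules are available:

    * ``"distance"`` (default): k = 2..k_max-1 maximizing the perpendicular
      distance between (k, wss[k-1]) and the chord joining the profile's
      endpoints (the classic knee-point construction).  This locates the
      kink of nested cluster structures reliably; the second-difference
      rule systematically returns k = 2 on convexly decaying profiles
      because the first merge's drop dominates the curvature.
    * ``"second_difference"``: k maximizing the second forward difference
      ``wss[k-1] - 2 wss[k] + wss[k+1]``.

    Ties break toward the smaller k.  A flat or linear profile has no
    elbow; the smallest candidate (k = 2) is returned with a warning.
    """
    wss = np.asarray(wss, dtype=float)
    if k_max is None:
        k_max = len(wss)
    if k_max < 3 or len(wss) < 3:
        raise ValueError("need a WSS profile over at least k = 1..3")
    k_max = min(k_max, len(wss))
    ks = np.arange(2, k_max)
    if method == "second_difference":
        score = wss[ks - 2] - 2 * wss[ks - 1] + wss[ks]
    elif method == "distance":
        # how far the profile dips below the chord (1, wss[0]) ->
        # (k_max, wss[k_max-1]); the perpendicular distance differs only by
        # a constant factor, so the argmax is identical
        chord = np.interp(ks.astype(float), [1.0, float(k_max)], [wss[0], wss[k_max - 1]])
        score = chord - wss[ks - 1]
    else:
        raise ValueError(f"unknown elbow method {method!r}")
    best = int(ks[np.argmax(score)])
    if np.max(score) <= 1e-9 * max(abs(wss[0]), 1.0):
        warnings.warn("no clear elbow in the WSS profile; returning smallest candidate k")
        return int(ks[0])
    return best


# ---------------------------------------------------------------------------
# ROC cut-point on the initial score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CutpointResult:
    """ROC-derived threshold separating the high cluster.

    Classification rule: ``initial >= threshold`` predicts membership of
    the high cluster.  The threshold maximizes Youden's J over all observed
    score values (exhaustive search), ties broken toward the lower value.
    """

    threshold: float
    youden_j: float
    table: pd.DataFrame  # threshold, sensitivity, specificity, J


def roc_cutoff(initial_scores: np.ndarray, is_high_cluster: np.ndarray) -> CutpointResult:
    scores = np.asarray(initial_scores, dtype=float)
    high = np.asarray(is_high_cluster, dtype=bool)
    if high.all() or (~high).all():
        raise ValueError("ROC cut-point needs both classes nonempty")
    thresholds = np.unique(scores)
    sens = np.array([np.mean(scores[high] >= t) for t in thresholds])
    spec = np.array([np.mean(scores[~high] < t) for t in thresholds])
    J = sens + spec - 1
    best = int(np.argmax(J))  # first occurrence = lowest threshold on ties
    if J[best] <= 0.1:
        warnings.warn("classes are barely separable (Youden J ~ 0)")
    return CutpointResult(
        threshold=float(thresholds[best]),
        youden_j=float(J[best]),
        table=pd.DataFrame(
            {"threshold": thresholds, "sensitivity": sens, "specificity": spec, "J": J}
        ),
    )


# ---------------------------------------------------------------------------
# end-to-end subgroup discovery and stratified reanalysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubgroupResult:
    pca: PCAScores
    solution: ClusterSolution
    cutpoint: CutpointResult
    high_cluster_label: int


def discover_subgroups(
    initial: np.ndarray, followup: np.ndarray, k_max: int = 8
) -> SubgroupResult:
    """PCA -> Ward -> elbow -> ROC cut-point on the initial score.

    The "high" cluster is the one with the largest mean initial score; the
    returned cut-point converts its membership into a rule on the observed
    initial-score grid.
    """
    pca = pca_scores(initial, followup)
    solution = ward_cluster(pca.scores)
    k = elbow_k(solution.wss, k_max=min(k_max, solution.n))
    labels = solution.labels_for_k(k)
    solution.chosen_k = k
    solution.labels = labels
    means = {lab: np.mean(np.asarray(initial)[labels == lab]) for lab in np.unique(labels)}
    high_label = max(means, key=means.get)
    cut = roc_cutoff(np.asarray(initial), labels == high_label)
    return SubgroupResult(pca=pca, solution=solution, cutpoint=cut, high_cluster_label=int(high_label))


def stratified_reanalysis(
    cohort: pd.DataFrame, cutpoint: float, limb: str, alpha: float = ALPHA
) -> dict:
    """Re-run the correlation/regression battery below the cut-point.

    Returns the full-cohort battery and the severe-stratum (initial <
    cut-point) battery for comparison; the high stratum (initial >=
    cut-point) is the ceiling-prone cluster excluded from reanalysis.
    """
    below, above = stratify_by_threshold(cohort, limb, int(cutpoint))
    if below.empty or above.empty:
        raise ValueError("both strata must be nonempty for a stratified reanalysis")
    return {
        "full": limb_battery(cohort, limb, alpha=alpha),
        "severe": limb_battery(below, limb, alpha=alpha),
        "n_full": len(cohort),
        "n_severe": len(below),
        "n_high": len(above),
    }
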