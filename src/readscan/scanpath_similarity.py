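"""Duration-weighted scanpath dissimilarity (Scasim), embedding, clustering.

The dissimilarity of two scanpaths is the minimal total cost of a global
sequence alignment where deleting or inserting a fixation costs its
duration and substituting fixation ``a`` for ``b`` costs

    (dur_a + dur_b) - 2 * min(dur_a, dur_b) * modulator ** d(a, b)

with ``d`` the angular distance between the two fixation positions in
degrees of visual angle and ``modulator`` (default 0.83 per degree) the
spatial decay.  Identical scanpaths score 0; aligning against the empty
scanpath costs the total fixation duration.  Scores are optionally
normalized by the summed total fixation duration of the two trials, giving
a unitless fraction interpretable as the proportion of viewing time spent
dissimilarly.

Downstream, per text-font pair: the score matrix is re-distanced
(Euclidean distances between its rows), embedded in 2-D by non-metric MDS,
the cluster count is chosen by the best BIC over Gaussian mixtures with
1..k_max components, trials are clustered by k-means with that k, and the
cluster-by-group contingency is tested by chi-square (all expected counts
above 5) or an exact Freeman-Halton/Fisher test otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from .event_io import DisplayGeometry, TrialRecord, px_to_deg

try:  # DP kernel is compiled when numba is available
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@dataclass(frozen=True)
class ScasimConfig:
    modulator: float = 0.83          # per-degree decay of the duration credit
    normalize: bool = True
    geometry: DisplayGeometry = field(default_factory=DisplayGeometry)

    def __post_init__(self) -> None:
        if not 0.0 < self.modulator < 1.0:
            raise ValueError("modulator must be in (0, 1)")


def _as_scanpath(obj) -> np.ndarray:
    """(n, 3) float array of x_px, y_px, duration_ms."""
    if isinstance(obj, TrialRecord):
        return np.array([[f.x, f.y, f.duration] for f in obj.fixations],
                        dtype=float).reshape(-1, 3)
    arr = np.asarray(obj, dtype=float).reshape(-1, 3)
    return arr


@njit(cache=False)
def _align(dur_a, dur_b, sub):  # pragma: no cover - exercised via wrapper
    n, m = dur_a.shape[0], dur_b.shape[0]
    d = np.empty((n + 1, m + 1))
    d[0, 0] = 0.0
    for i in range(1, n + 1):
        d[i, 0] = d[i - 1, 0] + dur_a[i - 1]
    for j in range(1, m + 1):
        d[0, j] = d[0, j - 1] + dur_b[j - 1]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = d[i - 1, j] + dur_a[i - 1]
            alt = d[i, j - 1] + dur_b[j - 1]
            if alt < best:
                best = alt
            alt = d[i - 1, j - 1] + sub[i - 1, j - 1]
            if alt < best:
                best = alt
            d[i, j] = best
    return d[n, m]


def scasim_pair(a, b, config: ScasimConfig | None = None) -> float:
    """Raw Scasim dissimilarity (ms) between two scanpaths."""
    config = config or ScasimConfig()
    pa, pb = _as_scanpath(a), _as_scanpath(b)
    if len(pa) == 0 and len(pb) == 0:
        return 0.0
    if len(pa) == 0:
        return float(pb[:, 2].sum())
    if len(pb) == 0:
        return float(pa[:, 2].sum())
    dx = pa[:, 0:1] - pb[:, 0].reshape(1, -1)
    dy = pa[:, 1:2] - pb[:, 1].reshape(1, -1)
    dist_deg = px_to_deg(np.hypot(dx, dy), config.geometry)
    da, db = pa[:, 2], pb[:, 2]
    sub = (da[:, None] + db[None, :]
           - 2.0 * np.minimum(da[:, None], db[None, :])
           * config.modulator ** dist_deg)
    return float(_align(da, db, sub))


@dataclass
class SimilarityMatrix:
    trial_ids: list[str]
    matrix: np.ndarray
    normalized: bool
    text_id: str
    font: str

    def validate(self) -> None:
        m = self.matrix
        if not np.allclose(m, m.T) or np.any(np.diag(m) != 0) or np.any(m < 0):
            raise ValueError("similarity matrix must be symmetric, "
                             "non-negative, zero-diagonal")


class GroupingError(ValueError):
    """Trials of mixed text or font passed to a per-pair computation."""


def scasim_matrix(
    trials: Sequence[TrialRecord], config: ScasimConfig | None = None,
) -> SimilarityMatrix:
    """All pairwise scores among trials sharing one text and font."""
    config = config or ScasimConfig()
    if len(trials) < 2:
        raise GroupingError("need at least 2 trials")
    texts = {t.text_id for t in trials}
    fonts = {t.font for t in trials}
    if len(texts) > 1 or len(fonts) > 1:
        raise GroupingError(f"mixed text/font ids: {texts} x {fonts}")
    paths = [_as_scanpath(t) for t in trials]
    totals = [p[:, 2].sum() for p in paths]
    n = len(trials)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            score = scasim_pair(paths[i], paths[j], config)
            if config.normalize:
                denom = totals[i] + totals[j]
                score = score / denom if denom > 0 else 0.0
            m[i, j] = m[j, i] = score
    out = SimilarityMatrix([t.trial_id for t in trials], m,
                           config.normalize, texts.pop(), fonts.pop())
    out.validate()
    return out


@dataclass
class ClusterResult:
    coordinates: np.ndarray       # (n, 2) embedded trial positions
    k: int
    assignments: np.ndarray
    stress: float
    degenerate: bool = False


def embed_and_cluster(
    sim: SimilarityMatrix,
    k_max: int = 9,
    seed: int = 0,
    double_distance: bool = True,
) -> ClusterResult:
    """Non-metric MDS embedding + BIC-selected Gaussian-mixture k + k-means.

    ``double_distance=True`` first converts the score matrix to Euclidean
    distances between its rows (mirroring a dist -> isoMDS sequencing);
    ``False`` feeds the scores to the embedding directly.
    """
    from sklearn.cluster import KMeans
    from sklearn.manifold import MDS
    from sklearn.metrics import euclidean_distances
    from sklearn.mixture import GaussianMixture

    m = sim.matrix
    n = m.shape[0]
    if n < 4:
        raise ValueError("need at least 4 trials to embed and cluster")
    if np.allclose(m, 0):
        return ClusterResult(np.zeros((n, 2)), 1, np.zeros(n, dtype=int),
                             0.0, degenerate=True)
    d = euclidean_distances(m) if double_distance else m
    import warnings
    with warnings.catch_warnings():
        # sklearn 1.9 emits FutureWarnings for the non-metric MDS spelling
        warnings.simplefilter("ignore", FutureWarning)
        mds = MDS(n_components=2, metric=False, dissimilarity="precomputed",
                  random_state=seed, n_init=4, max_iter=300,
                  normalized_stress="auto")
        coords = mds.fit_transform(d)
    if not np.isfinite(mds.stress_):
        raise RuntimeError(f"non-convergent embedding, stress={mds.stress_}")

    ks = range(1, min(k_max, n - 1) + 1)
    bics = []
    for k in ks:
        gmm = GaussianMixture(n_components=k, random_state=seed, n_init=3,
                              reg_covar=1e-4)
        gmm.fit(coords)
        bics.append(gmm.bic(coords))
    best_k = list(ks)[int(np.argmin(bics))]
    if best_k == 1:
        return ClusterResult(coords, 1, np.zeros(n, dtype=int),
                             float(mds.stress_), degenerate=True)
    km = KMeans(n_clusters=best_k, n_init=50, random_state=seed)
    assignments = km.fit_predict(coords)
    return ClusterResult(coords, best_k, assignments, float(mds.stress_))


@dataclass
class AssociationResult:
    table: np.ndarray             # k x 2 contingency (clusters x groups)
    method: str                   # "chi2" | "fisher_exact" | "undefined"
    statistic: float
    p: float


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def freeman_halton_exact(table: np.ndarray) -> float:
    """Exact conditional p for a k x 2 table (generalizes Fisher's test).

    Enumerates all tables with the observed margins; the p-value is the
    total multivariate-hypergeometric probability of tables no more
    probable than the observed one.
    """
    table = np.asarray(table, dtype=int)
    rows = table.sum(axis=1)
    c1 = int(table[:, 0].sum())
    n = int(rows.sum())
    log_denom = _log_comb(n, c1)
    obs_logp = sum(_log_comb(r, a) for r, a in zip(rows, table[:, 0]))
    tail_rows = np.concatenate([np.cumsum(rows[::-1])[::-1][1:], [0]])

    total = 0.0
    stack = [(0, c1, 0.0)]
    while stack:
        i, rem, logp = stack.pop()
        if i == len(rows):
            if rem == 0 and logp <= obs_logp + 1e-9:
                total += math.exp(logp - log_denom)
            continue
        lo = max(0, rem - int(tail_rows[i]))
        hi = min(int(rows[i]), rem)
        for a in range(lo, hi + 1):
            stack.append((i + 1, rem - a, logp + _log_comb(rows[i], a)))
    return min(total, 1.0)


def association_test(
    assignments: Sequence[int], groups: Sequence[str],
) -> AssociationResult:
    """Cluster-by-group association: chi-square when every expected count
    exceeds 5, exact test otherwise; undefined with a single cluster."""
    assignments = np.asarray(assignments)
    groups = np.asarray(groups)
    clusters = np.unique(assignments)
    glabels = np.unique(groups)
    if len(glabels) != 2:
        raise ValueError("exactly two groups required")
    table = np.array([
        [int(np.sum((assignments == c) & (groups == g))) for g in glabels]
        for c in clusters
    ])
    if len(clusters) < 2:
        return AssociationResult(table, "undefined", math.nan, math.nan)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if np.all(expected > 5):
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
        return AssociationResult(table, "chi2", float(chi2), float(p))
    p = freeman_halton_exact(table)
    return AssociationResult(table, "fisher_exact", math.nan, float(p))
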