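"""Per-gene differential expression, DE fractions, signed significance and clustering.

DE testing is a two-group linear model per gene. With moderation on, gene
variances are shrunk toward a common prior in the empirical-Bayes style of
moderated t statistics: the posterior variance is a prior-df-weighted mix of
the gene's residual variance and a global prior variance, and the t test
gains the prior degrees of freedom. The prior (d0, s0^2) is estimated by
moment matching on the log residual variances. With moderation off the test
is the ordinary pooled-variance t, which doubles as an independent oracle.

The clustering toolset covers the figure-level analyses: Euclidean
hierarchical clustering for heatmap ordering, k-means with median silhouette
width, and ordinary bootstrap support for cluster memberships.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.special import digamma, polygamma
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = [
    "de_test",
    "bh_adjust",
    "de_fraction",
    "signed_significance",
    "hierarchical_order",
    "kmeans_silhouette",
    "bootstrap_support",
    "ClusterReport",
]


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def _group_stats(values: np.ndarray, mask: np.ndarray):
    n1, n2 = int(mask.sum()), int((~mask).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per condition")
    m1 = values[:, mask].mean(axis=1)
    m2 = values[:, ~mask].mean(axis=1)
    ss1 = ((values[:, mask] - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((values[:, ~mask] - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    s2 = (ss1 + ss2) / df
    return m1 - m2, s2, df, n1, n2


def _fit_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (d0, s0^2) to gene variances.

    Works on z = log(s2): under the model, var(z) = trigamma(df/2) + trigamma(d0/2).
    Returns (inf, s0^2) when the observed spread is at or below the sampling
    floor, i.e. complete shrinkage to a common variance.
    """
    pos = s2[s2 > 0]
    if pos.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(pos)
    excess = z.var(ddof=1) - polygamma(1, df / 2.0)
    if excess <= 1e-8:
        d0 = np.inf
        e_offset = 0.0
    else:
        # invert trigamma(d0/2) = excess by bisection on d0
        lo, hi = 1e-3, 1e8
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if polygamma(1, mid / 2.0) > excess:
                lo = mid
            else:
                hi = mid
        d0 = float(np.sqrt(lo * hi))
        e_offset = float(np.log(d0 / 2.0) - digamma(d0 / 2.0))
    # E[log s2] = log s0^2 + digamma(df/2) - log(df/2) + e_offset
    log_s02 = float(z.mean() - (digamma(df / 2.0) - np.log(df / 2.0)) - e_offset)
    return d0, float(np.exp(log_s02))


def de_test(expr: ExpressionMatrix, labels, moderation: bool = True) -> pd.DataFrame:
    """Two-group DE test per gene; returns gene_id, effect, p, p_adj.

    ``effect`` is tumor minus normal mean; moderation applies empirical-Bayes
    variance shrinkage, otherwise the ordinary pooled t is used. Genes with
    zero pooled variance get effect-consistent p = 1 when the effect is also
    zero; a zero variance with non-zero effect is driven to the test's floor
    by the shrunken variance (moderation) or reported p = 1 with a warning
    (plain t, degenerate).
    """
    values = expr.values.to_numpy(dtype=float)
    lab = np.asarray(labels)
    mask = lab == "tumor"
    effect, s2, df, n1, n2 = _group_stats(values, mask)
    c = 1.0 / n1 + 1.0 / n2
    if moderation:
        d0, s02 = _fit_prior(s2, df)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s02)
            df_total = np.inf
        else:
            s2_post = (d0 * s02 + df * s2) / (d0 + df)
            df_total = d0 + df
        se = np.sqrt(s2_post * c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = effect / se
        t = np.where(se == 0, 0.0, t)
        if np.isinf(df_total):
            p = 2 * sps.norm.sf(np.abs(t))
        else:
            p = 2 * sps.t.sf(np.abs(t), df_total)
    else:
        se = np.sqrt(s2 * c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = effect / se
        degen = se == 0
        if degen.any():
            log.warning("%d gene(s) with degenerate variance; p set to 1", degen.sum())
        t = np.where(degen, 0.0, t)
        p = 2 * sps.t.sf(np.abs(t), df)
    out = pd.DataFrame({
        "gene_id": expr.values.index,
        "effect": effect,
        "p": p,
        "p_adj": bh_adjust(p),
    })
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any()):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def de_fraction(results: pd.DataFrame, gene_set, alpha: float = 0.05) -> float:
    """Fraction of set genes with BH-adjusted p < alpha."""
    genes = list(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    sub = results.set_index("gene_id").loc[genes]
    return float((sub["p_adj"] < alpha).mean())


def signed_significance(expr: ExpressionMatrix, labels, gene) -> float:
    """sign(effect) * (1 - p) for a single gene's two-group t test, in [-1, +1]."""
    sub = ExpressionMatrix(expr.values.loc[[gene]], expr.centered, expr.centering_scope)
    res = de_test(sub, labels, moderation=False).iloc[0]
    if res["effect"] == 0:
        return 0.0
    return float(np.sign(res["effect"]) * (1.0 - res["p"]))


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterReport:
    labels: np.ndarray
    median_silhouette: float
    linkage: np.ndarray | None = None
    bootstrap: dict[int, float] | None = None


def hierarchical_order(matrix, metric: str = "euclidean",
                       linkage: str = "average") -> tuple[list[int], np.ndarray]:
    """Leaf order and linkage tree for hierarchical clustering of rows."""
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise ValueError("matrix must be 2-D")
    if np.isnan(arr).any():
        raise ValueError("matrix contains NaN")
    if arr.shape[0] == 1:
        return [0], np.empty((0, 4))
    Z = hierarchy.linkage(arr, method=linkage, metric=metric)
    return list(hierarchy.leaves_list(Z)), Z


def kmeans_silhouette(points, k: int = 2, n_init: int = 50,
                      seed: int = 0) -> ClusterReport:
    """k-means (best of ``n_init`` restarts) with the median silhouette width."""
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if k > arr.shape[0]:
        raise ValueError(f"k={k} exceeds number of points {arr.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(arr)
    sil = silhouette_samples(arr, km.labels_)
    return ClusterReport(labels=km.labels_, median_silhouette=float(np.median(sil)))


def bootstrap_support(matrix, k: int = 2, n_boot: int = 100,
                      seed: int = 0, n_init: int = 10) -> dict[int, float]:
    """Ordinary bootstrap support for k-means clusters of the rows.

    Columns (features) are resampled with replacement ``n_boot`` times; a
    cluster's support is the fraction of resamples in which some cluster of
    the re-fitted partition has exactly the same member set.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    arr = np.asarray(matrix, dtype=float)
    if np.ptp(arr) == 0:
        raise ValueError("constant matrix: bootstrap support undefined")
    base = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(arr)
    base_sets = [frozenset(np.flatnonzero(base.labels_ == c)) for c in range(k)]
    rng = np.random.default_rng(seed)
    hits = np.zeros(k)
    for _ in range(n_boot):
        cols = rng.integers(0, arr.shape[1], size=arr.shape[1])
        boot = KMeans(n_clusters=k, n_init=n_init,
                      random_state=seed).fit(arr[:, cols])
        boot_sets = {frozenset(np.flatnonzero(boot.labels_ == c)) for c in range(k)}
        for c, s in enumerate(base_sets):
            if s in boot_sets:
                hits[c] += 1
    return {c: float(hits[c] / n_boot) for c in range(k)}
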