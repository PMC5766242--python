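"""Gene Set Analysis with the maxmean statistic, restandardization and ΔGSA scores.

For each (tissue, gene set) pair the tumor-vs-normal change of the set is
summarized by the maxmean statistic — the mean of the positive or of the
negative per-gene scores over the set, whichever is larger in magnitude —
and calibrated two ways at once: condition labels are permuted to build a
permutation null, and that null is restandardized against the moments of
maxmean over random gene sets of the same size drawn from all scored genes.
Restandardization guards against gene sets that would look extreme merely
because per-gene scores are globally shifted or inflated.

The two one-sided permutation p-values are combined into a signed score

    ΔGSA = (1 - p_up) - (1 - p_down) = p_down - p_up  ∈ [-1, +1],

+1 meaning maximal upregulation of the set in tumors.

Permutations and random gene-set draws are generated label-independently
(index shuffles only), which makes the label-swap antisymmetry
ΔGSA(swapped) = -ΔGSA exact for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, SampleAnnotation, select_paired_tissues
from .ontology import GeneSetCollection

log = logging.getLogger(__name__)

__all__ = [
    "gene_scores",
    "maxmean",
    "gsa_pvalues",
    "delta_gsa",
    "run_gsa_matrix",
    "chaperome_vs_background",
    "GsaResult",
]


@dataclass(frozen=True)
class GsaResult:
    tissue: str
    set_label: str
    p_up: float
    p_down: float
    delta_gsa: float
    n_permutations: int


# ---------------------------------------------------------------------------
# per-gene scores
# ---------------------------------------------------------------------------

def _tumor_mask(labels) -> np.ndarray:
    lab = np.asarray(labels)
    bad = set(lab) - {"tumor", "normal"}
    if bad:
        raise ValueError(f"labels must be tumor/normal; got {sorted(bad)}")
    return lab == "tumor"


def _pooled_t(values: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t for each gene under each tumor mask.

    values: genes x samples; masks: B x samples boolean. Returns B x genes.
    Genes with zero pooled variance score 0 (degenerate rule).

    Each mask is canonicalized on its first element before the arithmetic, so
    swapping the two condition labels negates every t bit-exactly (the
    label-swap antisymmetry contract).
    """
    masks = np.asarray(masks, dtype=bool)
    flip = ~masks[:, 0]
    canon = np.where(flip[:, None], ~masks, masks)
    t = _pooled_t_raw(values, canon)
    t[flip] = -t[flip]
    return t


def _pooled_t_raw(values: np.ndarray, masks: np.ndarray) -> np.ndarray:
    masks = masks.astype(float)
    n = values.shape[1]
    n1 = masks.sum(axis=1)          # tumor counts, per mask
    n2 = n - n1
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("need at least 2 samples per condition")
    sums = masks @ values.T                      # B x genes (tumor sums)
    sumsq = masks @ (values ** 2).T
    tot = values.sum(axis=1)                     # genes
    totsq = (values ** 2).sum(axis=1)
    m1 = sums / n1[:, None]
    m2 = (tot[None, :] - sums) / n2[:, None]
    ss1 = sumsq - n1[:, None] * m1 ** 2
    ss2 = (totsq[None, :] - sumsq) - n2[:, None] * m2 ** 2
    df = n1 + n2 - 2
    sp2 = (ss1 + ss2) / df[:, None]
    sp2 = np.maximum(sp2, 0.0)                   # numeric guard
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
    return np.where(se == 0, 0.0, t)


def gene_scores(expr: ExpressionMatrix, labels) -> pd.Series:
    """Per-gene pooled-variance two-sample t statistic, tumor minus normal.

    Genes with zero variance in both arms score 0 (logged).
    """
    values = expr.values.to_numpy(dtype=float)
    mask = _tumor_mask(labels)
    t = _pooled_t(values, mask[None, :])[0]
    n_zero = int(np.sum(t == 0.0))
    if n_zero:
        log.debug("%d gene(s) with degenerate variance scored 0", n_zero)
    return pd.Series(t, index=expr.values.index, name="score")


# ---------------------------------------------------------------------------
# maxmean
# ---------------------------------------------------------------------------

def maxmean(scores, gene_set=None) -> float:
    """Mean of positive or of negative scores over the set, whichever is larger
    in absolute value; ties return the positive side."""
    if gene_set is not None:
        scores = pd.Series(scores).loc[list(gene_set)]
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("maxmean of an empty gene set")
    s_plus = arr.clip(min=0).sum() / arr.size
    s_minus = arr.clip(max=0).sum() / arr.size
    return float(s_plus if s_plus >= -s_minus else s_minus)


def _maxmean_rows(score_rows: np.ndarray) -> np.ndarray:
    """Row-wise maxmean for a B x m matrix of set member scores."""
    m = score_rows.shape[1]
    s_plus = np.clip(score_rows, 0, None).sum(axis=1) / m
    s_minus = np.clip(score_rows, None, 0).sum(axis=1) / m
    return np.where(s_plus >= -s_minus, s_plus, s_minus)


# ---------------------------------------------------------------------------
# permutation + restandardization
# ---------------------------------------------------------------------------

def _permutation_masks(mask: np.ndarray, n_perm: int, rng: np.random.Generator
                       ) -> tuple[np.ndarray, int]:
    """Tumor masks for the permutation null, label-independent.

    If the number of distinct label assignments is at most ``n_perm`` the
    assignments are enumerated exhaustively (logged); otherwise index shuffles
    are drawn. Returns (B x n boolean, B).
    """
    n = mask.size
    n1 = int(mask.sum())
    n_distinct = comb(n, n1)
    if n_distinct <= n_perm:
        log.info("exhaustive enumeration: %d distinct assignments <= %d requested",
                 n_distinct, n_perm)
        masks = np.zeros((n_distinct, n), dtype=bool)
        for b, idx in enumerate(combinations(range(n), n1)):
            masks[b, list(idx)] = True
        return masks, n_distinct
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    return mask[perms], n_perm


def _restandardized_null(m_perm: np.ndarray, r_rand: np.ndarray) -> np.ndarray:
    """Rescale permutation maxmean values by random-gene-set moments."""
    mu_p, sd_p = m_perm.mean(), m_perm.std(ddof=1) if m_perm.size > 1 else 0.0
    mu_r, sd_r = r_rand.mean(), r_rand.std(ddof=1) if r_rand.size > 1 else 0.0
    # degenerate spreads (e.g. the set is the whole gene universe, so every
    # random draw reproduces it up to float noise): plain permutation null
    tol_p = 1e-9 * max(1.0, abs(mu_p))
    tol_r = 1e-9 * max(1.0, abs(mu_r))
    if sd_p <= tol_p or sd_r <= tol_r:
        return m_perm
    return mu_r + sd_r * (m_perm - mu_p) / sd_p


def _gsa_core(values: np.ndarray, mask: np.ndarray, set_idx: np.ndarray,
              n_perm: int, seed_seq: np.random.SeedSequence,
              n_rand: int | None = None) -> tuple[float, float]:
    """p_up/p_down for one gene set given a genes x samples matrix."""
    ss_perm, ss_rand = seed_seq.spawn(2)
    rng_perm = np.random.default_rng(ss_perm)
    rng_rand = np.random.default_rng(ss_rand)

    obs = _pooled_t(values, mask[None, :])[0]
    m_obs = _maxmean_rows(obs[set_idx][None, :])[0]

    masks, n_eff = _permutation_masks(mask, n_perm, rng_perm)
    perm_scores = _pooled_t(values, masks)              # B x genes
    m_perm = _maxmean_rows(perm_scores[:, set_idx])

    n_rand = n_perm if n_rand is None else n_rand
    n_genes, m = values.shape[0], set_idx.size
    rand_idx = np.stack([rng_rand.choice(n_genes, size=m, replace=False)
                         for _ in range(n_rand)])
    r_rand = _maxmean_rows(obs[rand_idx])

    null = _restandardized_null(m_perm, r_rand)
    p_up = (1 + int(np.sum(null >= m_obs))) / (n_eff + 1)
    p_down = (1 + int(np.sum(null <= m_obs))) / (n_eff + 1)
    return p_up, p_down


def gsa_pvalues(expr: ExpressionMatrix, labels, gene_set, n_perm: int = 100,
                seed: int = 0, n_rand: int | None = None) -> tuple[float, float]:
    """One-sided upregulation/downregulation permutation p-values for one set.

    Uses the add-one estimator p = (1 + #{null >= obs}) / (n_perm + 1), so the
    smallest attainable p is 1/(n_perm+1) and p = 0 never occurs.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = expr.values.to_numpy(dtype=float)
    mask = _tumor_mask(labels)
    index = pd.Index(expr.values.index)
    set_idx = index.get_indexer(list(gene_set))
    if (set_idx < 0).any():
        missing = [g for g, i in zip(gene_set, set_idx) if i < 0]
        raise KeyError(f"gene set member(s) not in matrix: {missing}")
    return _gsa_core(values, mask, set_idx, n_perm,
                     np.random.SeedSequence(seed), n_rand)


def delta_gsa(p_up: float, p_down: float) -> float:
    """ΔGSA = (1 - p_up) - (1 - p_down) = p_down - p_up, in [-1, +1]."""
    for p in (p_up, p_down):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {p}")
    return p_down - p_up


# ---------------------------------------------------------------------------
# cohort-level drivers
# ---------------------------------------------------------------------------

def run_gsa_matrix(expr: ExpressionMatrix, annotation: SampleAnnotation,
                   collection: GeneSetCollection, n_perm: int = 100,
                   seed: int = 0, min_per_arm: int = 2,
                   n_rand: int | None = None) -> pd.DataFrame:
    """ΔGSA for every (paired tissue, gene set); permuted scores are shared
    across sets within a tissue.

    Returns a tidy frame (tissue, set, p_up, p_down, delta_gsa, n_perm).
    """
    tissues = select_paired_tissues(annotation, min_per_arm=min_per_arm)
    index = pd.Index(expr.values.index)
    cond = annotation.condition_series()
    root = np.random.SeedSequence(seed)
    tissue_seqs = root.spawn(len(tissues))
    rows = []
    for t, t_seq in zip(tissues, tissue_seqs):
        samples = annotation.samples_of(t)
        values = expr.values[samples].to_numpy(dtype=float)
        mask = _tumor_mask(cond[samples].to_numpy())
        set_seqs = t_seq.spawn(len(collection.sets))
        for (label, genes), s_seq in zip(collection.sets.items(), set_seqs):
            set_idx = index.get_indexer(genes)
            if (set_idx < 0).any():
                missing = [g for g, i in zip(genes, set_idx) if i < 0]
                raise KeyError(f"set {label!r}: gene(s) not in matrix: {missing}")
            p_up, p_down = _gsa_core(values, mask, set_idx, n_perm, s_seq, n_rand)
            rows.append(GsaResult(t, label, p_up, p_down,
                                  delta_gsa(p_up, p_down), n_perm))
    df = pd.DataFrame([r.__dict__ for r in rows])
    return df.rename(columns={"set_label": "set", "n_permutations": "n_perm"})


def set_means(results: pd.DataFrame) -> pd.Series:
    """Group-mean ΔGSA per set across tissues (the bar-graph summary)."""
    return results.groupby("set")["delta_gsa"].mean()


def chaperome_vs_background(expr: ExpressionMatrix, annotation: SampleAnnotation,
                            chaperome_genes, n_samplings: int = 100,
                            n_perm: int = 100, seed: int = 0,
                            min_per_arm: int = 2) -> pd.Series:
    """Mean ΔGSA of the chaperome against size-matched random non-chaperome sets.

    For each of ``n_samplings`` draws, as many non-chaperome genes as there
    are chaperome genes are sampled from the matrix; the chaperome's ΔGSA is
    computed within that reduced universe (so restandardization references the
    matched background), and the per-tissue mean over draws is returned.
    """
    index = pd.Index(expr.values.index)
    chap = [g for g in chaperome_genes if g in index]
    chap_idx = index.get_indexer(chap)
    non_chap = np.setdiff1d(np.arange(len(index)), chap_idx)
    if non_chap.size < 2 * len(chap):
        raise ValueError(
            f"need > {2 * len(chap)} non-chaperome genes, have {non_chap.size}")
    tissues = select_paired_tissues(annotation, min_per_arm=min_per_arm)
    cond = annotation.condition_series()
    root = np.random.SeedSequence(seed)
    out = {}
    for t, t_seq in zip(tissues, root.spawn(len(tissues))):
        samples = annotation.samples_of(t)
        values = expr.values[samples].to_numpy(dtype=float)
        mask = _tumor_mask(cond[samples].to_numpy())
        draw_rng = np.random.default_rng(t_seq.spawn(1)[0])
        samp_seqs = t_seq.spawn(n_samplings)
        deltas = []
        for s_seq in samp_seqs:
            bg = draw_rng.choice(non_chap, size=len(chap), replace=False)
            universe = np.concatenate([chap_idx, bg])
            sub = values[universe]
            set_in_sub = np.arange(len(chap))
            p_up, p_down = _gsa_core(sub, mask, set_in_sub, n_perm, s_seq)
            deltas.append(delta_gsa(p_up, p_down))
        out[t] = float(np.mean(deltas))
    return pd.Series(out, name="mean_delta_gsa")
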