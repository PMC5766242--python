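"""Meta-PCA: universal per-family weight vectors and per-sample M-scores.

The method assumes each chaperome functional family has low intrinsic
dimensionality, so its tumor/normal expression change in one tissue is
captured by the first principal component of the family's centered
expression. The algorithm:

  1. Per tissue t and family x, fit PC1 of the samples x family-genes
     matrix; the unit-norm loading vector W_x^t plays the role of the
     tissue-level scoring function, and sample scores are projections.
  2. Keep only tissues where PC1 scores separate tumor from normal by a
     Student's t test at p <= 1e-4 (PC1 of a non-responding family is noise).
  3. Sign-align the retained loading vectors across tissues (PCA signs are
     arbitrary): the tissue with the smallest separation p-value is the
     reference, other tissues are flipped to positive dot product with it,
     and the global orientation anchors the weight vector to the expression
     axis (positive loading mass), so an M-score increase means increased
     family expression. The per-gene mean of the aligned vectors,
     renormalized to unit length, is the universal Meta-PC W_x.

An M-score is then the dot product W_x . G of the universal weights with a
sample's centered expression over the family genes, comparable across
samples and tissues. Step 3' validates the scores by holding out 20% of
samples and predicting tumor/normal from M-score profiles with a
random-forest classifier.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .expression import ExpressionMatrix, SampleAnnotation, select_paired_tissues
from .ontology import GeneSetCollection

log = logging.getLogger(__name__)

__all__ = [
    "TissueLoadings",
    "MetaPC",
    "fit_tissue_pc1",
    "separation_filter",
    "align_and_orient",
    "combine_meta_pc",
    "fit_meta_pca",
    "score_samples",
    "polar_summary",
    "validate_mscores",
]


@dataclass
class TissueLoadings:
    """PC1 loadings of one family in one tissue, plus separation diagnostics."""

    family: str
    tissue: str
    genes: list[int]                  # family genes present in the matrix
    loadings: np.ndarray              # unit norm, aligned with `genes`
    scores: pd.Series                 # per-sample PC1 projections
    separation_p: float | None = None
    retained: bool = False
    missing_genes: list[int] = field(default_factory=list)


@dataclass
class MetaPC:
    """Universal weight vector of one family (unit norm) with provenance."""

    family: str
    genes: list[int]
    weights: np.ndarray
    tissues: list[str]
    orientation_reference: str

    def to_dict(self) -> dict:
        return {
            "genes": list(map(int, self.genes)),
            "weights": [float(w) for w in self.weights],
            "tissues": list(self.tissues),
            "orientation_reference": self.orientation_reference,
        }


def fit_tissue_pc1(expr_tissue: ExpressionMatrix, family: str, genes,
                   tissue: str = "") -> TissueLoadings:
    """PC1 loadings of one family's centered expression in one tissue."""
    index = pd.Index(expr_tissue.values.index)
    present = [g for g in genes if g in index]
    missing = [g for g in genes if g not in index]
    if missing:
        log.warning("family %s: %d gene(s) absent from matrix", family, len(missing))
    if len(present) < 2:
        raise ValueError(f"family {family}: fewer than 2 genes present")
    if expr_tissue.values.shape[1] < 3:
        raise ValueError(f"tissue {tissue or '?'}: need at least 3 samples")
    X = expr_tissue.values.loc[present].to_numpy(dtype=float).T   # samples x genes
    X = X - X.mean(axis=0)                                        # per-gene center
    # PC1 via SVD; deterministic sign fixed below in align_and_orient
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    w = vt[0]
    w = w / np.linalg.norm(w)
    scores = pd.Series(X @ w, index=expr_tissue.values.columns, name="pc1")
    return TissueLoadings(family=family, tissue=tissue, genes=present,
                          loadings=w, scores=scores, missing_genes=missing)


def separation_filter(loadings: TissueLoadings, labels,
                      threshold: float = 1e-4) -> TissueLoadings:
    """Student's t on PC1 scores, tumor vs normal; retained iff p <= threshold."""
    lab = np.asarray(labels)
    tum = loadings.scores.to_numpy()[lab == "tumor"]
    nor = loadings.scores.to_numpy()[lab == "normal"]
    if tum.size == 0 or nor.size == 0:
        log.info("family %s tissue %s: one-armed, not retained",
                 loadings.family, loadings.tissue)
        loadings.separation_p = None
        loadings.retained = False
        return loadings
    p = float(sps.ttest_ind(tum, nor, equal_var=True).pvalue)
    loadings.separation_p = p
    loadings.retained = bool(p <= threshold)
    return loadings


def align_and_orient(retained: list[TissueLoadings], gene_order: list[int]
                     ) -> tuple[list[np.ndarray], str]:
    """Make retained loading vectors sign-consistent and expression-anchored.

    Vectors are expanded onto ``gene_order`` (missing genes -> NaN), flipped
    to agree with the reference tissue (smallest separation p), and finally
    the whole bundle is flipped, if needed, so the reference vector's loading
    mass is positive: an increase of family expression then raises the
    M-score, preserving the observed direction of change (a family
    downregulated in tumors keeps tumor scores below normal scores).
    """
    if not retained:
        raise ValueError("no retained tissue loadings to align")
    ref = min(retained, key=lambda tl: (tl.separation_p, tl.tissue))
    pos = {g: i for i, g in enumerate(gene_order)}

    def expand(tl: TissueLoadings) -> np.ndarray:
        v = np.full(len(gene_order), np.nan)
        for g, w in zip(tl.genes, tl.loadings):
            v[pos[g]] = w
        return v

    ref_v = expand(ref)
    out = []
    for tl in retained:
        v = expand(tl)
        both = ~np.isnan(v) & ~np.isnan(ref_v)
        dot = float(np.nansum(v[both] * ref_v[both]))
        if dot < 0:
            v = -v
        elif dot == 0 and tl is not ref:
            log.warning("family %s tissue %s: loadings orthogonal to reference; "
                        "sign kept", tl.family, tl.tissue)
        out.append(v)
    # global orientation: anchor the reference to the expression axis
    if np.nansum(ref_v) < 0:
        out = [-v for v in out]
    return out, ref.tissue


def combine_meta_pc(aligned: list[np.ndarray], family: str,
                    gene_order: list[int], tissues: list[str],
                    orientation_reference: str) -> MetaPC:
    """Per-gene mean of aligned loadings (tissues where the gene was present),
    renormalized to unit norm."""
    stack = np.vstack(aligned)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    mean = np.nan_to_num(mean, nan=0.0)
    norm = np.linalg.norm(mean)
    if norm == 0:
        raise ValueError(f"family {family}: degenerate (zero) mean loading vector")
    return MetaPC(family=family, genes=list(gene_order), weights=mean / norm,
                  tissues=list(tissues), orientation_reference=orientation_reference)


def fit_meta_pca(expr: ExpressionMatrix, annotation: SampleAnnotation,
                 families: GeneSetCollection, p_threshold: float = 1e-4,
                 min_per_arm: int = 3) -> dict[str, MetaPC]:
    """Full fit: per-tissue PC1 -> separation filter -> align -> Meta-PC.

    Families with no retained tissue are absent from the result (logged);
    callers must handle missing families.
    """
    tissues = select_paired_tissues(annotation, min_per_arm=min_per_arm)
    cond = annotation.condition_series()
    out: dict[str, MetaPC] = {}
    for family, genes in families.sets.items():
        retained: list[TissueLoadings] = []
        for t in tissues:
            samples = annotation.samples_of(t)
            sub = expr.subset_samples(samples)
            try:
                tl = fit_tissue_pc1(sub, family, genes, tissue=t)
            except ValueError as exc:
                log.info("skipping %s/%s: %s", family, t, exc)
                continue
            tl = separation_filter(tl, cond[samples].to_numpy(), p_threshold)
            if tl.retained:
                retained.append(tl)
        if not retained:
            log.info("family %s: no tissue passed the separation filter", family)
            continue
        aligned, ref = align_and_orient(retained, list(genes))
        out[family] = combine_meta_pc(aligned, family, list(genes),
                                      [tl.tissue for tl in retained], ref)
    return out


def score_samples(expr: ExpressionMatrix, meta_pcs: dict[str, MetaPC],
                  missing_warn_frac: float = 0.5) -> pd.DataFrame:
    """M-scores: samples x families, M = W_x . G over family genes.

    Family genes absent from the matrix contribute 0; families with more than
    ``missing_warn_frac`` of genes missing are flagged in the ``.attrs``
    quality map.
    """
    index = pd.Index(expr.values.index)
    cols = {}
    quality = {}
    for family, mpc in meta_pcs.items():
        idx = index.get_indexer(mpc.genes)
        present = idx >= 0
        frac_missing = 1.0 - present.mean()
        quality[family] = "ok" if frac_missing <= missing_warn_frac else "low-coverage"
        if frac_missing > missing_warn_frac:
            log.warning("family %s: %.0f%% of genes missing at scoring time",
                        family, 100 * frac_missing)
        w = np.asarray(mpc.weights)[present]
        G = expr.values.to_numpy(dtype=float)[idx[present]]
        cols[family] = G.T @ w
    out = pd.DataFrame(cols, index=expr.values.columns)
    out.attrs["quality"] = quality
    return out


def polar_summary(mscores: pd.DataFrame, labels,
                  quantiles: tuple[float, float] = (0.05, 0.95)) -> pd.DataFrame:
    """Per-family arm means and empirical 5%/95% quantiles (linear/type-7).

    Rows: family; columns: normal_mean, tumor_mean, normal_q05, normal_q95,
    tumor_q05, tumor_q95 — the polar-plot lines and halos.
    """
    lab = np.asarray(labels)
    rows = {}
    for arm in ("normal", "tumor"):
        sub = mscores.loc[lab == arm]
        if sub.empty:
            raise ValueError(f"no samples in arm {arm!r}")
        if len(sub) < 2:
            log.warning("arm %s has <2 samples; quantiles collapse to the value", arm)
        rows[f"{arm}_mean"] = sub.mean(axis=0)
        rows[f"{arm}_q{int(quantiles[0] * 100):02d}"] = sub.quantile(
            quantiles[0], interpolation="linear")
        rows[f"{arm}_q{int(quantiles[1] * 100):02d}"] = sub.quantile(
            quantiles[1], interpolation="linear")
    return pd.DataFrame(rows)


def validate_mscores(mscores: pd.DataFrame, labels, tissues=None,
                     train_frac: float = 0.8, seed: int = 0,
                     n_estimators: int = 200) -> dict:
    """Held-out validation: predict tumor/normal from M-score profiles.

    Stratified 80/20 split, random-forest classifier; reports overall and
    (optionally) per-tissue held-out accuracy.
    """
    lab = np.asarray(labels)
    counts = pd.Series(lab).value_counts()
    if (counts < 10).any():
        raise ValueError("need at least 10 samples per arm for validation")
    X = mscores.to_numpy(dtype=float)
    idx = np.arange(len(lab))
    idx_tr, idx_te = train_test_split(
        idx, train_size=train_frac, random_state=seed, stratify=lab)
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    clf.fit(X[idx_tr], lab[idx_tr])
    pred = clf.predict(X[idx_te])
    report = {
        "accuracy": float(np.mean(pred == lab[idx_te])),
        "n_train": int(idx_tr.size),
        "n_test": int(idx_te.size),
    }
    if tissues is not None:
        tis = np.asarray(tissues)[idx_te]
        per = {}
        for t in sorted(set(tis)):
            m = tis == t
            per[t] = float(np.mean(pred[m] == lab[idx_te][m]))
        report["per_tissue_accuracy"] = per
    return report


def meta_pcs_to_json(meta_pcs: dict[str, MetaPC]) -> str:
    return json.dumps({f: m.to_dict() for f, m in meta_pcs.items()},
                      indent=2, sort_keys=True)


def meta_pcs_from_json(text: str) -> dict[str, MetaPC]:
    raw = json.loads(text)
    return {
        f: MetaPC(family=f, genes=[int(g) for g in d["genes"]],
                  weights=np.asarray(d["weights"], dtype=float),
                  tissues=list(d["tissues"]),
                  orientation_reference=d["orientation_reference"])
        for f, d in raw.items()
    }
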