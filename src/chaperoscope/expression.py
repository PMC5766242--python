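"""Count-matrix ingestion and logCPM normalization for multi-tissue tumor/normal cohorts.

Raw RNA-seq counts (genes x samples) plus a sample annotation (tissue cohort,
tumor/normal condition) are transformed to log2 counts-per-million with the
small-count offsets of the voom convention,

    logCPM(g, s) = log2( (count(g,s) + 0.5) / (libsize(s) + 1) * 1e6 ),

then centered gene-wise (per tissue by default) so that downstream gene-set
scores and principal components measure deviations, not absolute abundance.
Precision weights of the full voom pipeline are deliberately not computed:
nothing downstream consumes them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "SampleAnnotation",
    "CountMatrix",
    "ExpressionMatrix",
    "read_counts",
    "read_annotation",
    "log_cpm",
    "center_genes",
    "select_paired_tissues",
]

CONDITIONS = ("tumor", "normal")


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample tissue cohort and tumor/normal condition."""

    table: pd.DataFrame  # columns: sample_id, tissue, condition

    def __post_init__(self) -> None:
        need = {"sample_id", "tissue", "condition"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing column(s): {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table["sample_id"][self.table["sample_id"].duplicated()]
            raise ValueError(f"duplicate sample id(s): {sorted(set(dup))}")
        bad = set(self.table["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"condition must be one of {CONDITIONS}; got {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def tissues(self) -> list[str]:
        return sorted(set(self.table["tissue"]))

    def samples_of(self, tissue: str, condition: str | None = None) -> list[str]:
        t = self.table[self.table["tissue"] == tissue]
        if condition is not None:
            t = t[t["condition"] == condition]
        return t["sample_id"].tolist()

    def condition_series(self) -> pd.Series:
        return self.table.set_index("sample_id")["condition"]

    def tissue_series(self) -> pd.Series:
        return self.table.set_index("sample_id")["tissue"]


@dataclass(frozen=True)
class CountMatrix:
    """Non-negative integer counts, genes (Entrez ids) x samples."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        lib = vals.sum(axis=0)
        if (lib <= 0).any():
            empty = [self.counts.columns[i] for i in np.flatnonzero(lib <= 0)]
            raise ValueError(f"sample(s) with empty library: {empty}")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Real-valued genes x samples matrix (logCPM), optionally centered.

    ``centering_scope`` records the grouping within which per-gene means were
    removed ('global', or 'per-tissue' with the tissue of each sample).
    """

    values: pd.DataFrame
    centered: bool = False
    centering_scope: str | None = None

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return replace(self, values=self.values[sample_ids])


def read_annotation(path) -> SampleAnnotation:
    return SampleAnnotation(pd.read_csv(path, sep="\t", dtype=str))


def read_counts(matrix_path, annotation_path) -> tuple[CountMatrix, SampleAnnotation]:
    """Read a TSV count matrix (rows=genes, header=samples) and its annotation.

    Sample sets must agree; genes are sorted by Entrez id.
    """
    annot = read_annotation(annotation_path)
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    df.index = df.index.astype(int)
    df = df.sort_index()
    matrix_samples = list(df.columns)
    missing = [s for s in matrix_samples if s not in set(annot.sample_ids)]
    if missing:
        raise ValueError(f"sample(s) in matrix absent from annotation: {missing}")
    extra = [s for s in annot.sample_ids if s not in set(matrix_samples)]
    if extra:
        raise ValueError(f"annotated sample(s) absent from matrix: {extra}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("count matrix contains non-integer values")
        df = df.round().astype(np.int64)
    # align annotation row order to matrix column order
    order = annot.table.set_index("sample_id").loc[matrix_samples].reset_index()
    return CountMatrix(df), SampleAnnotation(order)


def log_cpm(counts: CountMatrix) -> ExpressionMatrix:
    """log2 counts-per-million with +0.5 count / +1 library-size offsets."""
    lib = counts.library_sizes.to_numpy(dtype=float)
    vals = counts.counts.to_numpy(dtype=float)
    out = np.log2((vals + 0.5) / (lib + 1.0) * 1e6)
    return ExpressionMatrix(
        pd.DataFrame(out, index=counts.counts.index, columns=counts.counts.columns)
    )


def center_genes(
    expr: ExpressionMatrix,
    annotation: SampleAnnotation | None = None,
    scope: str = "per-tissue",
) -> ExpressionMatrix:
    """Remove per-gene means, either globally or within each tissue cohort.

    Centering twice at the same scope is a no-op by construction (means are
    already zero); groups with a single sample collapse to zero with a warning.
    """
    if scope not in ("per-tissue", "global"):
        raise ValueError(f"unknown centering scope: {scope!r}")
    vals = expr.values.copy()
    if scope == "global":
        vals = vals.sub(vals.mean(axis=1), axis=0)
    else:
        if annotation is None:
            raise ValueError("per-tissue centering requires a sample annotation")
        tissue = annotation.tissue_series()
        for t in annotation.tissues():
            cols = [s for s in vals.columns if tissue[s] == t]
            if len(cols) == 1:
                log.warning("tissue %s has a single sample; centered values are 0", t)
            block = vals[cols]
            vals[cols] = block.sub(block.mean(axis=1), axis=0)
    return ExpressionMatrix(vals, centered=True, centering_scope=scope)


def select_paired_tissues(
    annotation: SampleAnnotation, min_per_arm: int = 1
) -> list[str]:
    """Tissues with at least ``min_per_arm`` samples in both tumor and normal arms."""
    kept = []
    for t in annotation.tissues():
        n_tum = len(annotation.samples_of(t, "tumor"))
        n_nor = len(annotation.samples_of(t, "normal"))
        if n_tum >= min_per_arm and n_nor >= min_per_arm:
            kept.append(t)
        else:
            log.info("tissue %s dropped (%d tumor / %d normal)", t, n_tum, n_nor)
    return kept
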