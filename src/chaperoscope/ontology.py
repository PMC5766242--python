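"""Chaperome functional gene ontology: loading, validation and gene-set derivation.

The chaperome is modelled as an annotation table with one row per gene:
HGNC symbol, Entrez id, up to six functional-ontology levels of increasing
detail, a chaperone/co-chaperone role flag and an ATP-dependence flag.
Families (sHSP, HSP40, HSP70, HSP90, HSP60, HSP100, PFD, TPR, ER, MITO)
partition the chaperome at the canonical family level; functional subsets
(chaperones vs co-chaperones, ATP-dependent vs -independent chaperones)
cut across families.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "CANONICAL_FAMILIES",
    "LEVEL_COLUMNS",
    "ChaperomeAnnotation",
    "GeneSetCollection",
    "OntologyFormatError",
    "OntologyValidationError",
    "load_ontology",
    "load_builtin_chaperome",
    "load_builtin_proteasome",
    "detect_family_level",
    "family_gene_sets",
    "functional_subsets",
]

#: The ten top-level chaperome functional families.
CANONICAL_FAMILIES: tuple[str, ...] = (
    "sHSP", "HSP40", "HSP70", "HSP90", "HSP60",
    "HSP100", "PFD", "TPR", "ER", "MITO",
)

LEVEL_COLUMNS: tuple[str, ...] = tuple(f"level{i}" for i in range(1, 7))
REQUIRED_COLUMNS: tuple[str, ...] = ("symbol", "entrez_id", "level1", "role", "atp")

ROLES = frozenset({"chaperone", "co-chaperone"})
ATP_FLAGS = frozenset({"dependent", "independent", "not-applicable"})


class OntologyFormatError(ValueError):
    """The annotation table is structurally malformed (missing columns, bad types)."""


class OntologyValidationError(ValueError):
    """The annotation table violates a semantic invariant (duplicates, flag clashes)."""


@dataclass(frozen=True)
class ChaperomeAnnotation:
    """Validated per-gene annotation table.

    ``table`` has columns symbol, entrez_id, level1..level6 (deeper levels may
    be empty), role and atp; ``family_level`` is the ontology level whose
    labels form the family partition used downstream.
    """

    table: pd.DataFrame
    family_level: int

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> list[int]:
        return self.table["entrez_id"].tolist()

    @property
    def family_column(self) -> str:
        return f"level{self.family_level}"

    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for label in self.table[self.family_column]:
            seen.setdefault(label)
        return list(seen)

    def symbol_of(self, gene_id: int) -> str:
        row = self.table.loc[self.table["entrez_id"] == gene_id, "symbol"]
        if row.empty:
            raise KeyError(gene_id)
        return row.iloc[0]

    def family_of(self, gene_id: int) -> str:
        row = self.table.loc[self.table["entrez_id"] == gene_id, self.family_column]
        if row.empty:
            raise KeyError(gene_id)
        return row.iloc[0]


@dataclass
class GeneSetCollection:
    """Named mapping from set label to a list of Entrez gene ids."""

    name: str
    sets: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, genes in self.sets.items():
            if len(genes) == 0:
                raise OntologyValidationError(f"gene set {label!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def sizes(self) -> dict[str, int]:
        return {label: len(genes) for label, genes in self.sets.items()}

    def all_genes(self) -> set[int]:
        out: set[int] = set()
        for genes in self.sets.values():
            out.update(genes)
        return out

    def to_json(self) -> str:
        return json.dumps(self.sets, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str, name: str = "collection") -> "GeneSetCollection":
        return cls(name=name, sets={k: [int(g) for g in v] for k, v in json.loads(text).items()})


def _read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise OntologyFormatError(f"annotation table missing required column(s): {missing}")
    try:
        df["entrez_id"] = df["entrez_id"].astype(int)
    except ValueError as exc:
        raise OntologyFormatError(f"non-integer entrez_id in annotation table: {exc}") from exc
    for col in LEVEL_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    return df


def detect_family_level(table: pd.DataFrame) -> int:
    """Return the ontology level whose label set is exactly the ten canonical families.

    Annotation sources disagree on whether the family partition sits at level 1
    or level 2; resolving it by content avoids guessing.
    """
    wanted = set(CANONICAL_FAMILIES)
    for i, col in enumerate(LEVEL_COLUMNS, start=1):
        labels = set(table[col]) - {""}
        if labels == wanted:
            return i
    raise OntologyValidationError(
        "no ontology level carries exactly the ten canonical chaperome families; "
        "pass family_level explicitly"
    )


def load_ontology(path: str | Path, family_level: int | None = None) -> ChaperomeAnnotation:
    """Load and validate a chaperome-style annotation table from TSV.

    ``family_level=None`` auto-detects the level holding the canonical
    10-family partition, falling back to level 1 for non-chaperome tables
    (e.g. the proteasome list).
    """
    df = _read_table(path)
    dup = df["entrez_id"][df["entrez_id"].duplicated()]
    if not dup.empty:
        raise OntologyValidationError(
            f"duplicate Entrez id(s) in annotation table: {sorted(set(dup.tolist()))}"
        )
    bad_role = sorted(set(df["role"]) - ROLES)
    if bad_role:
        raise OntologyFormatError(f"unknown role value(s): {bad_role}")
    bad_atp = sorted(set(df["atp"]) - ATP_FLAGS)
    if bad_atp:
        raise OntologyFormatError(f"unknown atp value(s): {bad_atp}")
    clash = df[(df["role"] == "co-chaperone") & (df["atp"] != "not-applicable")]
    if not clash.empty:
        raise OntologyValidationError(
            "co-chaperones must have atp=not-applicable; offenders: "
            f"{clash['entrez_id'].tolist()}"
        )
    if family_level is None:
        try:
            family_level = detect_family_level(df)
        except OntologyValidationError:
            family_level = 1
    col = f"level{family_level}"
    unlabeled = df[df[col] == ""]
    if not unlabeled.empty:
        raise OntologyValidationError(
            f"gene(s) without a label at level {family_level}: "
            f"{unlabeled['entrez_id'].tolist()}"
        )
    return ChaperomeAnnotation(table=df, family_level=family_level)


def _builtin(name: str) -> Path:
    return Path(str(resources.files("chaperoscope").joinpath("data", name)))


def load_builtin_chaperome() -> ChaperomeAnnotation:
    """The shipped 332-gene chaperome annotation table (synthetic stand-in)."""
    return load_ontology(_builtin("chaperome_ontology_synthetic.tsv"))


def load_builtin_proteasome() -> ChaperomeAnnotation:
    """The shipped 43-gene proteasome annotation table (synthetic stand-in)."""
    return load_ontology(_builtin("proteasome_synthetic.tsv"))


def family_gene_sets(
    annotations: ChaperomeAnnotation, family_level: int | None = None
) -> GeneSetCollection:
    """Partition the annotated genes into family gene sets at the requested level."""
    level = annotations.family_level if family_level is None else family_level
    col = f"level{level}"
    df = annotations.table
    unlabeled = df[df[col] == ""]
    if not unlabeled.empty:
        raise OntologyValidationError(
            f"gene(s) without a label at level {level}: {unlabeled['entrez_id'].tolist()}"
        )
    sets: dict[str, list[int]] = {}
    for label, sub in df.groupby(col, sort=False):
        sets[str(label)] = sub["entrez_id"].tolist()
    return GeneSetCollection(name=f"families@level{level}", sets=sets)


def functional_subsets(annotations: ChaperomeAnnotation) -> GeneSetCollection:
    """Chaperone/co-chaperone and ATP-dependent/-independent gene subsets.

    ATP flags apply to chaperones only, so the two ATP sets partition the
    chaperone set.
    """
    df = annotations.table
    clash = df[(df["role"] == "chaperone") & (df["atp"] == "not-applicable")]
    if not clash.empty:
        raise OntologyValidationError(
            f"chaperone(s) with atp=not-applicable: {clash['entrez_id'].tolist()}"
        )
    sets = {
        "chaperones": df.loc[df["role"] == "chaperone", "entrez_id"].tolist(),
        "co-chaperones": df.loc[df["role"] == "co-chaperone", "entrez_id"].tolist(),
        "atp-dependent": df.loc[df["atp"] == "dependent", "entrez_id"].tolist(),
        "atp-independent": df.loc[df["atp"] == "independent", "entrez_id"].tolist(),
    }
    return GeneSetCollection(name="functional-subsets", sets=sets)


def summary_counts(annotations: ChaperomeAnnotation) -> dict[str, int]:
    """Convenience head-counts used in reports: genes, roles, ATP classes, families."""
    df = annotations.table
    return {
        "genes": len(df),
        "chaperones": int((df["role"] == "chaperone").sum()),
        "co-chaperones": int((df["role"] == "co-chaperone").sum()),
        "atp-dependent": int((df["atp"] == "dependent").sum()),
        "atp-independent": int((df["atp"] == "independent").sum()),
        "families": len(set(df[annotations.family_column]) - {""}),
    }
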