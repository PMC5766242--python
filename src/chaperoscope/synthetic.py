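"""Synthetic data generators: cohorts, PPI evidence corpora, PSI-MI ontologies.

Everything here is a controlled surrogate with programmed ground truth:

* ``simulate_cohort`` draws negative-binomial RNA-seq counts for a
  multi-tissue tumor/normal cohort in which each functional family carries a
  programmed log2 effect per tissue — the truth table against which gene-set
  scores and M-scores are checked.
* ``simulate_ppi_corpus`` draws per-pair evidence profiles (how many PMIDs,
  which method terms) and reports the tier composition implied by its own
  draws, an exact bookkeeping oracle for the curation pipeline.
* ``simulate_mi_ontology`` builds toy PSI-MI trees (optionally with one
  multi-parent cross-link) with known levels.
* ``make_chaperome_table`` / ``make_proteasome_table`` build the shipped
  synthetic stand-ins for the curated chaperome/proteasome annotation
  tables: 332 genes = 88 chaperones (50 ATP-dependent + 38 ATP-independent)
  + 244 co-chaperones in the 10 canonical families, and 43 proteasome
  genes. Symbols and Entrez ids are synthetic placeholders.
* ``chaperome_ppi_fixture`` builds a deterministic synthetic evidence corpus
  whose curated tiers have the documented structure of the curated chaperome
  interactome: SE 666 edges / 220 nodes, ME 222 / 128, MM 132 / 96, with
  every family represented and the ME meta-network connected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import CountMatrix, SampleAnnotation
from .interactome import EvidenceRecord, MiOntology, PHYSICAL_ASSOCIATION
from .ontology import CANONICAL_FAMILIES, GeneSetCollection

__all__ = [
    "CohortSpec",
    "simulate_cohort",
    "PpiCorpusSpec",
    "simulate_ppi_corpus",
    "simulate_mi_ontology",
    "ontology_to_obo",
    "toy_method_ontology",
    "make_chaperome_table",
    "make_proteasome_table",
    "chaperome_ppi_fixture",
    "write_fixture_files",
    "default_cohort_spec",
]


# ---------------------------------------------------------------------------
# expression cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Study conditions for a simulated multi-tissue tumor/normal cohort.

    ``effects[family]`` is either one log2 shift applied in every tissue or a
    per-tissue mapping; ``dispersion`` is the NB overdispersion alpha
    (variance = mu + alpha * mu^2). Family genes occupy the first gene ids,
    the remainder is unprogrammed background.
    """

    tissues: list[str]
    n_tumor: int
    n_normal: int
    n_genes: int
    families: dict[str, int]
    effects: dict[str, float | dict[str, float]] = field(default_factory=dict)
    baseline_log2_range: tuple[float, float] = (3.0, 9.0)
    dispersion: float = 0.15
    gene_jitter_sd: float = 0.0
    seed: int = 0
    gene_id_start: int = 10001

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_tumor < 2 or self.n_normal < 2:
            raise ValueError("need at least 2 samples per arm")
        if sum(self.families.values()) > self.n_genes:
            raise ValueError("family genes exceed n_genes")
        for fam, n in self.families.items():
            if n < 1:
                raise ValueError(f"family {fam!r} has no genes")

    def effect(self, family: str, tissue: str) -> float:
        e = self.effects.get(family, 0.0)
        if isinstance(e, dict):
            return float(e.get(tissue, 0.0))
        return float(e)


def default_cohort_spec(seed: int = 0, deltas=(-2.0, -1.0, 0.0, 1.0, 2.0),
                        n_tissues: int = 5, n_per_arm: int = 30,
                        n_families: int = 10, genes_per_family: int = 12,
                        n_genes: int = 400) -> CohortSpec:
    """The reference simulation conditions: 5 tissues, 30+30 samples per arm,
    10 families x 12 genes, programmed shifts cycling through ``deltas``."""
    families = {f"F{i + 1:02d}": genes_per_family for i in range(n_families)}
    effects = {f"F{i + 1:02d}": float(deltas[i % len(deltas)])
               for i in range(n_families)}
    return CohortSpec(
        tissues=[f"T{i + 1}" for i in range(n_tissues)],
        n_tumor=n_per_arm, n_normal=n_per_arm,
        n_genes=n_genes, families=families, effects=effects, seed=seed,
    )


def simulate_cohort(spec: CohortSpec) -> tuple[CountMatrix, SampleAnnotation,
                                               pd.DataFrame, GeneSetCollection]:
    """Draw a cohort; returns counts, annotation, truth table and family sets."""
    rng = np.random.default_rng(spec.seed)
    gene_ids = np.arange(spec.gene_id_start, spec.gene_id_start + spec.n_genes)
    baseline = rng.uniform(*spec.baseline_log2_range, size=spec.n_genes)

    fam_sets: dict[str, list[int]] = {}
    cursor = 0
    gene_family = np.array([""] * spec.n_genes, dtype=object)
    for fam, n in spec.families.items():
        fam_sets[fam] = [int(g) for g in gene_ids[cursor:cursor + n]]
        gene_family[cursor:cursor + n] = fam
        cursor += n

    jitter = (rng.normal(0.0, spec.gene_jitter_sd, size=spec.n_genes)
              if spec.gene_jitter_sd > 0 else np.zeros(spec.n_genes))

    cols, rows_annot, truth = {}, [], []
    size = 1.0 / spec.dispersion          # NB shape parameter
    for t in spec.tissues:
        for fam in spec.families:
            truth.append({"tissue": t, "family": fam,
                          "delta_log2": spec.effect(fam, t)})
        for arm, n_arm in (("tumor", spec.n_tumor), ("normal", spec.n_normal)):
            shift = np.zeros(spec.n_genes)
            if arm == "tumor":
                for fam in spec.families:
                    d = spec.effect(fam, t)
                    sel = gene_family == fam
                    shift[sel] = d + jitter[sel]
            mu = 2.0 ** (baseline + shift)
            for i in range(n_arm):
                sid = f"{t}_{arm[0].upper()}{i + 1:03d}"
                p = size / (size + mu)
                cols[sid] = rng.negative_binomial(size, p)
                rows_annot.append({"sample_id": sid, "tissue": t,
                                   "condition": arm})
    counts = pd.DataFrame(cols, index=gene_ids)
    counts.index.name = "entrez_id"
    annot = SampleAnnotation(pd.DataFrame(rows_annot))
    return (CountMatrix(counts), annot, pd.DataFrame(truth),
            GeneSetCollection(name="simulated-families", sets=fam_sets))


# ---------------------------------------------------------------------------
# PSI-MI ontologies
# ---------------------------------------------------------------------------

def simulate_mi_ontology(depth: int, branching: int,
                         dag_crosslink: bool = False) -> MiOntology:
    """Rooted tree with ``depth`` levels (root = level 0) and fixed branching.

    ``dag_crosslink`` adds one extra parent to the last leaf, one level above
    its tree parent, for multi-parent up-propagation tests.
    """
    if depth < 2:
        raise ValueError("depth must be >= 2")
    parents: dict[str, set[str]] = {}
    counter = [0]

    def new_term() -> str:
        counter[0] += 1
        return f"MI:{counter[0]:04d}"

    root = new_term()
    parents[root] = set()
    frontier = [root]
    for _ in range(depth - 1):
        nxt = []
        for p in frontier:
            for _ in range(branching):
                c = new_term()
                parents[c] = {p}
                nxt.append(c)
        frontier = nxt
    if dag_crosslink and depth >= 3:
        leaf = frontier[-1]
        tree_parent = next(iter(parents[leaf]))
        grandparent = next(iter(parents[tree_parent]))
        parents[leaf] = parents[leaf] | {grandparent}
    return MiOntology(parents)


#: Toy interaction-detection-method vocabulary used by the shipped fixtures.
#: Levels: MI:0001 root (0); MI:0045 experimental (1); MI:0401 biochemical,
#: MI:0013 biophysical, MI:0018 two hybrid, MI:0090 complementation (2);
#: MI:0004 affinity chromatography, MI:0017 cross-linking, MI:0397 two hybrid
#: array, MI:0112 ubiquitin reconstruction (3); MI:0006 / MI:0007 anti-bait /
#: anti-tag coimmunoprecipitation, MI:0096 pull down (4).
_TOY_METHOD_PARENTS: dict[str, tuple[str, str]] = {
    # term: (name, parent or "")
    "MI:0001": ("interaction detection method", ""),
    "MI:0045": ("experimental interaction detection", "MI:0001"),
    "MI:0401": ("biochemical", "MI:0045"),
    "MI:0013": ("biophysical", "MI:0045"),
    "MI:0018": ("two hybrid", "MI:0045"),
    "MI:0090": ("protein complementation assay", "MI:0045"),
    "MI:0004": ("affinity chromatography technology", "MI:0401"),
    "MI:0017": ("classical fluorescence spectroscopy", "MI:0013"),
    "MI:0397": ("two hybrid array", "MI:0018"),
    "MI:0112": ("ubiquitin reconstruction", "MI:0090"),
    "MI:0006": ("anti bait coimmunoprecipitation", "MI:0004"),
    "MI:0007": ("anti tag coimmunoprecipitation", "MI:0004"),
    "MI:0096": ("pull down", "MI:0004"),
    # interaction types (separate branch, unused for method levels)
    "MI:0190": ("interaction type", ""),
    "MI:0914": ("association", "MI:0190"),
    "MI:0915": ("physical association", "MI:0914"),
}


def toy_method_ontology() -> MiOntology:
    return MiOntology({t: ({p} if p else set())
                       for t, (_, p) in _TOY_METHOD_PARENTS.items()})


def ontology_to_obo(terms: dict[str, tuple[str, str]] | None = None) -> str:
    """Render the toy vocabulary (or any {id: (name, parent)} map) as OBO text."""
    terms = _TOY_METHOD_PARENTS if terms is None else terms
    chunks = ["format-version: 1.2", "ontology: mi-synthetic", ""]
    for tid, (name, parent) in terms.items():
        chunks.append("[Term]")
        chunks.append(f"id: {tid}")
        chunks.append(f"name: {name}")
        if parent:
            chunks.append(f"is_a: {parent} ! {terms[parent][0]}")
        chunks.append("")
    return "\n".join(chunks)


# ---------------------------------------------------------------------------
# random PPI corpora with bookkeeping oracle
# ---------------------------------------------------------------------------

@dataclass
class PpiCorpusSpec:
    """Evidence-profile distribution for random pair corpora.

    Each profile is {'prob': float, 'pmids': int, 'methods': [terms]};
    probabilities must sum to 1.
    """

    nodes: list[int]
    n_pairs: int
    profiles: list[dict]
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(p["prob"] for p in self.profiles)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"profile probabilities sum to {total}, not 1")
        max_pairs = len(self.nodes) * (len(self.nodes) - 1) // 2
        if self.n_pairs > max_pairs:
            raise ValueError("more pairs requested than distinct pairs exist")


def simulate_ppi_corpus(spec: PpiCorpusSpec, ontology: MiOntology
                        ) -> tuple[list[EvidenceRecord], dict[str, int]]:
    """Draw evidence per random pair; returns records plus the tier counts
    implied by the generator's own draws (the bookkeeping oracle)."""
    from .interactome import effective_methods

    rng = np.random.default_rng(spec.seed)
    nodes = np.asarray(spec.nodes)
    pairs: set[tuple[int, int]] = set()
    while len(pairs) < spec.n_pairs:
        a, b = rng.choice(nodes, size=2, replace=False)
        pairs.add((int(min(a, b)), int(max(a, b))))
    probs = [p["prob"] for p in spec.profiles]
    records: list[EvidenceRecord] = []
    truth = {"SE": 0, "ME": 0, "MM": 0}
    pmid_counter = 0
    for pair in sorted(pairs):
        prof = spec.profiles[rng.choice(len(spec.profiles), p=probs)]
        pmids = []
        for _ in range(prof["pmids"]):
            pmid_counter += 1
            pmids.append(f"P{pmid_counter:06d}")
        for m in prof["methods"]:
            for p in pmids:
                records.append(EvidenceRecord(pair[0], pair[1], m, p,
                                              "synthetic", PHYSICAL_ASSOCIATION))
        n_eff = len(effective_methods(set(prof["methods"]), ontology))
        truth["SE"] += 1
        if len(pmids) > 1 or n_eff > 1:
            truth["ME"] += 1
        if n_eff > 1:
            truth["MM"] += 1
    return records, truth


# ---------------------------------------------------------------------------
# shipped annotation tables (synthetic stand-ins)
# ---------------------------------------------------------------------------

# family -> (total, atp-dependent chaperones, atp-independent chaperones)
_FAMILY_PLAN: dict[str, tuple[int, int, int]] = {
    "sHSP":   (10, 0, 10),
    "HSP40":  (49, 0, 10),
    "HSP70":  (25, 17, 0),
    "HSP90":  (25, 6, 0),
    "HSP60":  (22, 22, 0),
    "HSP100": (10, 5, 0),
    "PFD":    (10, 0, 10),
    "TPR":    (91, 0, 0),
    "ER":     (45, 0, 8),
    "MITO":   (45, 0, 0),
}

CHAPEROME_ID_START = 500001
PROTEASOME_ID_START = 600001


def make_chaperome_table() -> pd.DataFrame:
    """Synthetic 332-gene chaperome annotation table.

    Reproduces the documented head-counts (10 families; 88 chaperones =
    50 ATP-dependent + 38 ATP-independent; 244 co-chaperones) with synthetic
    symbols and Entrez ids.
    """
    rows = []
    next_id = CHAPEROME_ID_START
    for fam in CANONICAL_FAMILIES:
        total, n_dep, n_indep = _FAMILY_PLAN[fam]
        for i in range(total):
            if i < n_dep:
                role, atp = "chaperone", "dependent"
            elif i < n_dep + n_indep:
                role, atp = "chaperone", "independent"
            else:
                role, atp = "co-chaperone", "not-applicable"
            sub = "A" if i < total // 2 else "B"
            rows.append({
                "symbol": f"{fam.upper()}{i + 1:03d}",
                "entrez_id": next_id,
                "level1": fam,
                "level2": f"{fam}-{sub}",
                "role": role,
                "atp": atp,
            })
            next_id += 1
    return pd.DataFrame(rows)


def make_proteasome_table() -> pd.DataFrame:
    """Synthetic 43-gene proteasome annotation table (HGNC family layout:
    PSMA1-7, PSMB1-11, PSMC1-6, PSMD1-14, PSME1-4, PSMF1); role/atp columns
    carry structural placeholders only."""
    plan = [("PSMA", 7, "20S-alpha"), ("PSMB", 11, "20S-beta"),
            ("PSMC", 6, "19S-ATPase"), ("PSMD", 14, "19S-non-ATPase"),
            ("PSME", 4, "activator"), ("PSMF", 1, "inhibitor")]
    rows = []
    next_id = PROTEASOME_ID_START
    for prefix, n, sub in plan:
        for i in range(n):
            rows.append({
                "symbol": f"{prefix}{i + 1}",
                "entrez_id": next_id,
                "level1": "proteasome",
                "level2": sub,
                "role": "co-chaperone",
                "atp": "not-applicable",
            })
            next_id += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# curated-interactome fixture (synthetic stand-in for the curated edge lists)
# ---------------------------------------------------------------------------

# per-family node counts drawn into the MM / extra-ME / extra-SE node pools
_MM_NODES = {"sHSP": 3, "HSP40": 14, "HSP70": 7, "HSP90": 7, "HSP60": 6,
             "HSP100": 3, "PFD": 3, "TPR": 26, "ER": 13, "MITO": 14}     # 96
_ME_EXTRA = {"sHSP": 1, "HSP40": 5, "HSP70": 2, "HSP90": 2, "HSP60": 2,
             "HSP100": 1, "PFD": 1, "TPR": 9, "ER": 4, "MITO": 5}        # 32
_SE_EXTRA = {"sHSP": 2, "HSP40": 13, "HSP70": 7, "HSP90": 7, "HSP60": 6,
             "HSP100": 3, "PFD": 3, "TPR": 25, "ER": 12, "MITO": 14}     # 92


def _fixture_node_pools() -> tuple[list[int], list[int], list[int]]:
    table = make_chaperome_table()
    by_family = {f: table.loc[table["level1"] == f, "entrez_id"].tolist()
                 for f in CANONICAL_FAMILIES}
    mm, me_extra, se_extra = [], [], []
    for f in CANONICAL_FAMILIES:
        genes = by_family[f]
        a = _MM_NODES[f]
        b = a + _ME_EXTRA[f]
        c = b + _SE_EXTRA[f]
        mm += genes[:a]
        me_extra += genes[a:b]
        se_extra += genes[b:c]
    return mm, me_extra, se_extra


def chaperome_ppi_fixture() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic synthetic evidence corpus for the chaperome interactome.

    Returns (mitab-like evidence table, uniprot->entrez mapping table). When
    parsed with :func:`chaperoscope.interactome.read_evidence` against the
    332-gene synthetic chaperome and curated with :func:`build_tiers` over
    :func:`toy_method_ontology`, the tiers come out at SE 666 edges / 220
    nodes, ME 222 / 128, MM 132 / 96, with all ten families present in the
    ME network and its family meta-network connected. Includes decoy rows
    (wrong interaction type, unmappable id, non-chaperome partner, exact
    duplicates) that the parsing/curation pipeline must remove.
    """
    mm_nodes, me_extra, se_extra = _fixture_node_pools()
    me_nodes = mm_nodes + me_extra
    all_nodes = me_nodes + se_extra
    n_mm = len(mm_nodes)

    used: set[tuple[int, int]] = set()

    def pair(a: int, b: int) -> tuple[int, int]:
        key = (min(a, b), max(a, b))
        if key in used or a == b:
            raise AssertionError("fixture construction produced a duplicate pair")
        used.add(key)
        return key

    mm_edges = [pair(mm_nodes[i], mm_nodes[(i + 1) % n_mm]) for i in range(n_mm)]
    mm_edges += [pair(mm_nodes[i], mm_nodes[i + 2]) for i in range(0, 72, 2)]

    me_edges = [pair(me_extra[j], mm_nodes[(7 * j) % n_mm]) for j in range(len(me_extra))]
    me_edges += [pair(mm_nodes[i], mm_nodes[i + 5]) for i in range(58)]

    se_edges = [pair(se_extra[j], all_nodes[(11 * j) % len(me_nodes)])
                for j in range(len(se_extra))]
    needed = 444 - len(se_edges)
    offset = 7
    i = 0
    while needed > 0:
        a, b = all_nodes[i % len(all_nodes)], all_nodes[(i + offset) % len(all_nodes)]
        i += 1
        if i % len(all_nodes) == 0:
            offset += 2
            i = 0
        key = (min(a, b), max(a, b))
        if a == b or key in used:
            continue
        used.add(key)
        se_edges.append(key)
        needed -= 1

    rows = []
    pmid = [0]

    def next_pmid() -> str:
        pmid[0] += 1
        return f"9{pmid[0]:06d}"

    def emit(e, methods, n_pmids):
        pmids = [next_pmid() for _ in range(n_pmids)]
        for m in methods:
            for p in pmids:
                rows.append((e[0], e[1], m, p))

    # MM edges: >= 2 effective methods, cycling through L5-L8 patterns
    mm_patterns = [
        (["MI:0006", "MI:0007"], 1),   # same-level distinct, non-binary -> L6
        (["MI:0004", "MI:0018"], 2),   # one binary -> L7
        (["MI:0018", "MI:0090"], 1),   # both binary -> L8
        (["MI:0004", "MI:0017"], 2),   # distinct levels-3 non-binary -> L5
    ]
    for k, e in enumerate(mm_edges):
        emit(e, *mm_patterns[k % len(mm_patterns)])

    # ME-only edges: 1 effective method, > 1 PMID (L1/L2); every third edge
    # carries an ancestor/descendant method pair that must collapse to one
    me_patterns = [
        (["MI:0006"], 2),              # L1
        (["MI:0018"], 2),              # L2
        (["MI:0004", "MI:0006"], 2),   # collapses to MI:0004 -> L1
    ]
    for k, e in enumerate(me_edges):
        emit(e, *me_patterns[k % len(me_patterns)])

    # SE-only edges: 1 method, 1 PMID (L3/L4)
    for k, e in enumerate(se_edges):
        emit(e, ["MI:0018"] if k % 3 == 2 else ["MI:0096"], 1)

    mapping = pd.DataFrame({
        "uniprot": [f"U{g}" for g in sorted({n for e in used for n in e} |
                                            set(all_nodes))],
    })
    mapping["entrez_id"] = mapping["uniprot"].str[1:].astype(int)

    table = pd.DataFrame(rows, columns=["id_a", "id_b", "method", "pmid"])
    table["id_a"] = "uniprotkb:U" + table["id_a"].astype(str)
    table["id_b"] = "uniprotkb:U" + table["id_b"].astype(str)
    table["source"] = "synthetic-db"
    table["type"] = PHYSICAL_ASSOCIATION

    decoys = pd.DataFrame([
        # wrong interaction type
        {"id_a": f"uniprotkb:U{mm_nodes[0]}", "id_b": f"uniprotkb:U{mm_nodes[3]}",
         "method": "MI:0006", "pmid": "9999901", "source": "synthetic-db",
         "type": "MI:0914"},
        # unmappable identifier
        {"id_a": "uniprotkb:UNKNOWN1", "id_b": f"uniprotkb:U{mm_nodes[1]}",
         "method": "MI:0006", "pmid": "9999902", "source": "synthetic-db",
         "type": PHYSICAL_ASSOCIATION},
        # non-chaperome partner (maps fine, filtered by node set)
        {"id_a": "777001", "id_b": f"uniprotkb:U{mm_nodes[2]}",
         "method": "MI:0006", "pmid": "9999903", "source": "synthetic-db",
         "type": PHYSICAL_ASSOCIATION},
        # exact duplicate of the first evidence row
        table.iloc[0].to_dict(),
    ])
    table = pd.concat([table, decoys], ignore_index=True)
    return table, mapping


def write_fixture_files(outdir) -> dict[str, str]:
    """Write the synthetic evidence corpus, id mapping, toy OBO and annotation
    tables into ``outdir``; returns the path map."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    evidence, mapping = chaperome_ppi_fixture()
    paths = {
        "mitab": str(outdir / "chaperome_ppi_synthetic.tsv"),
        "mapping": str(outdir / "uniprot_entrez_synthetic.tsv"),
        "obo": str(outdir / "psimi_synthetic.obo"),
        "chaperome": str(outdir / "chaperome_ontology_synthetic.tsv"),
        "proteasome": str(outdir / "proteasome_synthetic.tsv"),
    }
    evidence.to_csv(paths["mitab"], sep="\t", index=False)
    mapping.to_csv(paths["mapping"], sep="\t", index=False)
    with open(paths["obo"], "w") as fh:
        fh.write(ontology_to_obo())
    make_chaperome_table().to_csv(paths["chaperome"], sep="\t", index=False)
    make_proteasome_table().to_csv(paths["proteasome"], sep="\t", index=False)
    return paths
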