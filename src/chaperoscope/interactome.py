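"""PPI evidence curation: PSI-MI up-propagation, L1-L8 levels, SE/ME/MM tiers.

Raw interaction records (node pair, detection-method PSI-MI term, PubMed id,
source database, interaction-type term) are filtered to physical
associations between genes of interest, grouped by unordered node pair, and
each edge's method annotations are deduplicated against the PSI-MI ontology:
two method terms count as one piece of evidence if, after up-propagating the
deeper term to the shallower term's level along a minimum-depth path, the
ids coincide. The surviving "effective methods" together with the PubMed
count place each edge in one of eight curation levels:

    L1  1 method (not binary), >1 PubMed
    L2  1 method (binary),     >1 PubMed
    L3  1 method (binary),      1 PubMed
    L4  1 method (not binary),  1 PubMed
    L5  >1 method (none binary), >1 PubMed
    L6  >1 method (none binary),  1 PubMed
    L7  >1 method (>=1 binary),  >1 PubMed
    L8  >1 method (>=1 binary),   1 PubMed

from which three nested interactome tiers derive: SE (any evidence),
ME (>1 PubMed or >1 effective method), MM (>1 effective method).

A method is "binary" when its up-propagated lineage meets a configurable
set of PSI-MI branch roots (default: the two-hybrid and complementation-
assay branches); the vocabulary is formally a DAG, so "level" means minimum
depth from the root.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import networkx as nx
import obonet
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "EvidenceRecord",
    "MiOntology",
    "CuratedEdge",
    "PHYSICAL_ASSOCIATION",
    "DEFAULT_BINARY_ROOTS",
    "read_obo",
    "read_mapping",
    "read_evidence",
    "up_propagate",
    "effective_methods",
    "classify_edge",
    "build_tiers",
    "TierNetworks",
]

#: PSI-MI term for the 'physical association' interaction type.
PHYSICAL_ASSOCIATION = "MI:0915"

#: Branch roots whose descendants count as binary interaction-detection
#: methods: two hybrid (MI:0018) and protein complementation assay (MI:0090).
DEFAULT_BINARY_ROOTS = frozenset({"MI:0018", "MI:0090"})


@dataclass(frozen=True)
class EvidenceRecord:
    node_a: int
    node_b: int
    method: str
    pmid: str
    source_db: str
    interaction_type: str

    @property
    def pair(self) -> tuple[int, int]:
        a, b = self.node_a, self.node_b
        return (a, b) if a <= b else (b, a)


class MiOntology:
    """PSI-MI controlled vocabulary as a parent DAG with min-depth levels."""

    def __init__(self, parents: dict[str, set[str]]):
        self.parents = {t: set(p) for t, p in parents.items()}
        self._levels: dict[str, int] = {}
        roots = [t for t, p in self.parents.items() if not p]
        if not roots:
            raise ValueError("ontology has no root term")
        # BFS from roots along child edges for min depth
        children: dict[str, set[str]] = defaultdict(set)
        for t, ps in self.parents.items():
            for p in ps:
                children[p].add(t)
        frontier = list(roots)
        for r in roots:
            self._levels[r] = 0
        while frontier:
            nxt = []
            for t in frontier:
                for c in children[t]:
                    if c not in self._levels:
                        self._levels[c] = self._levels[t] + 1
                        nxt.append(c)
            frontier = nxt
        unreachable = set(self.parents) - set(self._levels)
        if unreachable:
            raise ValueError(f"term(s) unreachable from root: {sorted(unreachable)}")

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def level(self, term: str) -> int:
        if term not in self._levels:
            raise KeyError(f"unknown PSI-MI term: {term}")
        return self._levels[term]

    def ancestors(self, term: str) -> set[str]:
        """All root-ward ancestors of ``term``, including itself."""
        out, stack = {term}, [term]
        while stack:
            for p in self.parents[stack.pop()]:
                if p not in out:
                    out.add(p)
                    stack.append(p)
        return out


def read_obo(path) -> MiOntology:
    """Load a PSI-MI ontology from OBO (is_a edges only)."""
    graph = obonet.read_obo(path)
    parents: dict[str, set[str]] = {t: set() for t in graph.nodes}
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents[child].add(parent)
    return MiOntology(parents)


def up_propagate(ontology: MiOntology, term: str, target_level: int) -> str:
    """Ancestor of ``term`` at exactly ``target_level`` along a min-depth path.

    With multiple parents, the parent of smallest level is followed (ties
    broken by term id for determinism).
    """
    lvl = ontology.level(term)
    if lvl < target_level:
        raise ValueError(
            f"term {term} is at level {lvl}, above target level {target_level}")
    cur = term
    while ontology.level(cur) > target_level:
        candidates = [p for p in ontology.parents[cur]
                      if ontology.level(p) >= target_level]
        if not candidates:
            raise ValueError(f"no ancestor of {term} at level {target_level}")
        cur = min(candidates, key=lambda p: (ontology.level(p), p))
    if ontology.level(cur) != target_level:
        raise ValueError(f"no ancestor of {term} at exactly level {target_level}")
    return cur


def effective_methods(raw_methods, ontology: MiOntology) -> set[str]:
    """Deduplicate method terms against the ontology.

    Pairwise: same level + different id -> distinct; different levels -> the
    deeper term is up-propagated to the shallower level and discarded if the
    ids then coincide (the shallower annotation subsumes it). Applied until
    stable; the survivors are pairwise-distinct evidence.
    """
    methods = set(raw_methods)
    for m in methods:
        if m not in ontology:
            raise KeyError(f"unknown PSI-MI method term: {m}")
    changed = True
    while changed:
        changed = False
        ordered = sorted(methods, key=lambda t: (ontology.level(t), t))
        for i, a in enumerate(ordered):          # a is shallower or equal
            for b in ordered[i + 1:]:
                la, lb = ontology.level(a), ontology.level(b)
                if la == lb:
                    continue                     # same level, different id: distinct
                if up_propagate(ontology, b, la) == a:
                    methods.discard(b)           # b collapses onto a
                    changed = True
                    break
            if changed:
                break
    return methods


def _is_binary(method: str, ontology: MiOntology, binary_roots) -> bool:
    return bool(ontology.ancestors(method) & set(binary_roots))


@dataclass
class CuratedEdge:
    pair: tuple[int, int]
    pmids: set[str]
    raw_methods: set[str]
    effective: set[str]
    n_binary: int
    curation_level: str
    tiers: set[str] = field(default_factory=set)


def classify_edge(pmids, raw_methods, ontology: MiOntology,
                  binary_roots=DEFAULT_BINARY_ROOTS,
                  pair: tuple[int, int] = (0, 0)) -> CuratedEdge:
    """Assign the L1-L8 curation level and SE/ME/MM tier membership."""
    pmids = set(pmids)
    raw = set(raw_methods)
    if not pmids or not raw:
        raise ValueError("an edge needs at least one PMID and one method")
    eff = effective_methods(raw, ontology)
    n_binary = sum(_is_binary(m, ontology, binary_roots) for m in eff)
    multi_pub = len(pmids) > 1
    multi_met = len(eff) > 1
    if not multi_met:
        binary = n_binary > 0
        level = ("L2" if binary else "L1") if multi_pub else ("L3" if binary else "L4")
    else:
        any_binary = n_binary > 0
        if any_binary:
            level = "L7" if multi_pub else "L8"
        else:
            level = "L5" if multi_pub else "L6"
    tiers = {"SE"}
    if multi_pub or multi_met:
        tiers.add("ME")
    if multi_met:
        tiers.add("MM")
    return CuratedEdge(pair=pair, pmids=pmids, raw_methods=raw, effective=eff,
                       n_binary=n_binary, curation_level=level, tiers=tiers)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_mapping(path) -> dict[str, int]:
    """UniProt -> Entrez mapping table (TSV: uniprot, entrez_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    need = {"uniprot", "entrez_id"}
    if not need <= set(df.columns):
        raise ValueError(f"mapping table needs columns {sorted(need)}")
    return dict(zip(df["uniprot"], df["entrez_id"].astype(int)))


def _resolve_id(raw: str, mapping: dict[str, int] | None) -> int | None:
    token = raw.split(":", 1)[1] if ":" in raw else raw
    if mapping and token in mapping:
        return mapping[token]
    if mapping and raw in mapping:
        return mapping[raw]
    try:
        return int(token)
    except ValueError:
        return None


def read_evidence(mitab_paths, id_mapping: dict[str, int] | None = None,
                  node_filter=None,
                  interaction_type: str = PHYSICAL_ASSOCIATION,
                  ) -> tuple[list[EvidenceRecord], Counter]:
    """Read MITAB-like TSV evidence (id_a, id_b, method, pmid, source, type).

    Records are kept only when both nodes resolve to Entrez ids inside
    ``node_filter`` (if given) and the interaction type matches. Duplicate
    rows are kept: deduplication happens at edge level. Returns the records
    and a Counter of parse/filter events per source file.
    """
    if isinstance(mitab_paths, (str, bytes)) or hasattr(mitab_paths, "read"):
        mitab_paths = [mitab_paths]
    node_filter = set(node_filter) if node_filter is not None else None
    records: list[EvidenceRecord] = []
    stats: Counter = Counter()
    for path in mitab_paths:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
        need = ["id_a", "id_b", "method", "pmid", "source", "type"]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing column(s) {missing}")
        for row in df.itertuples(index=False):
            stats["rows"] += 1
            if not row.method or not row.pmid:
                stats["malformed"] += 1
                continue
            if row.type != interaction_type:
                stats["type_filtered"] += 1
                continue
            a = _resolve_id(row.id_a, id_mapping)
            b = _resolve_id(row.id_b, id_mapping)
            if a is None or b is None:
                stats["unmapped"] += 1
                continue
            if node_filter is not None and (a not in node_filter or b not in node_filter):
                stats["node_filtered"] += 1
                continue
            records.append(EvidenceRecord(a, b, row.method, row.pmid,
                                          row.source, row.type))
            stats["kept"] += 1
    log.info("evidence parsing: %s", dict(stats))
    return records, stats


# ---------------------------------------------------------------------------
# tier assembly
# ---------------------------------------------------------------------------

@dataclass
class TierNetworks:
    edges: dict[str, list[CuratedEdge]]     # tier -> curated edges

    def graph(self, tier: str) -> nx.Graph:
        g = nx.Graph()
        for e in self.edges[tier]:
            g.add_edge(*e.pair, level=e.curation_level,
                       n_pmids=len(e.pmids), n_methods=len(e.effective))
        return g

    def counts(self) -> dict[str, dict[str, int]]:
        out = {}
        for tier, es in self.edges.items():
            nodes = {n for e in es for n in e.pair}
            out[tier] = {"edges": len(es), "nodes": len(nodes)}
        return out

    def edge_table(self, tier: str) -> pd.DataFrame:
        rows = [{
            "node_a": e.pair[0], "node_b": e.pair[1],
            "level": e.curation_level,
            "pmids": ";".join(sorted(e.pmids)),
            "effective_methods": ";".join(sorted(e.effective)),
        } for e in sorted(self.edges[tier], key=lambda e: e.pair)]
        return pd.DataFrame(rows,
                            columns=["node_a", "node_b", "level",
                                     "pmids", "effective_methods"])


def build_tiers(records: list[EvidenceRecord], ontology: MiOntology,
                binary_roots=DEFAULT_BINARY_ROOTS,
                drop_self: bool = False) -> TierNetworks:
    """Group evidence by unordered pair, classify, and emit SE/ME/MM tiers."""
    by_pair: dict[tuple[int, int], list[EvidenceRecord]] = defaultdict(list)
    for r in records:
        if drop_self and r.node_a == r.node_b:
            continue
        by_pair[r.pair].append(r)
    tiers: dict[str, list[CuratedEdge]] = {"SE": [], "ME": [], "MM": []}
    for pair in sorted(by_pair):
        rs = by_pair[pair]
        edge = classify_edge({r.pmid for r in rs}, {r.method for r in rs},
                             ontology, binary_roots, pair=pair)
        for tier in edge.tiers:
            tiers[tier].append(edge)
    return TierNetworks(edges=tiers)
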