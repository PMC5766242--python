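"""Family meta-networks, force-directed layout and 3-D topographic surfaces.

Gene-level interactome edges are collapsed onto functional-family
meta-nodes: meta-node size is the number of family members in the network,
intra-family edges accumulate on the meta-node as a self-weight, and the
number of edges between members of two different families becomes the
weight of one meta-edge. The conservation invariant
sum(meta-edge weights) + sum(intra-family counts) = |E| always holds.

Layout is Kamada-Kawai with target distances from shortest paths over edge
lengths 1/weight (strongly coupled families sit closer). The topographic
surface places a Gaussian bump of height value_f (an M-score or ΔGSA) at
each family's layout coordinate:

    z(x, y) = sum_f value_f * exp(-||(x,y) - (x_f,y_f)||^2 / (2 bw^2)).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "FamilyMetaNetwork",
    "TopographicSurface",
    "collapse_to_meta",
    "layout_meta",
    "topographic_surface",
    "export_network",
    "import_network",
]


@dataclass
class FamilyMetaNetwork:
    """Collapsed family-level network."""

    meta_nodes: dict[str, dict]               # family -> {size, intra_edges, value}
    meta_edges: dict[tuple[str, str], int]    # sorted family pair -> weight
    layout: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def families(self) -> list[str]:
        return list(self.meta_nodes)

    def total_edges(self) -> int:
        return sum(self.meta_edges.values()) + sum(
            n["intra_edges"] for n in self.meta_nodes.values())

    def set_values(self, values: dict[str, float]) -> None:
        for fam, node in self.meta_nodes.items():
            node["value"] = float(values.get(fam, 0.0))

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for fam, node in self.meta_nodes.items():
            attrs = {"size": node["size"], "intra_edges": node["intra_edges"],
                     "value": node.get("value", 0.0)}
            if fam in self.layout:
                attrs["x"], attrs["y"] = self.layout[fam]
            g.add_node(fam, **attrs)
        for (a, b), w in self.meta_edges.items():
            g.add_edge(a, b, weight=w)
        return g


def collapse_to_meta(edges, annotations, family_level: int | None = None,
                     families: list[str] | None = None) -> FamilyMetaNetwork:
    """Collapse gene-level edges onto family meta-nodes and meta-edges.

    ``edges`` is an iterable of (node_a, node_b) gene-id pairs; ``annotations``
    is either a gene->family mapping or a ChaperomeAnnotation. ``families``
    optionally forces the full family list so edge-less families appear as
    isolated meta-nodes.
    """
    if hasattr(annotations, "table"):
        level = annotations.family_level if family_level is None else family_level
        col = f"level{level}"
        fam_of = dict(zip(annotations.table["entrez_id"],
                          annotations.table[col]))
    else:
        fam_of = dict(annotations)
    edges = [tuple(e) for e in edges]
    nodes = {n for e in edges for n in e}
    unannotated = sorted(n for n in nodes if n not in fam_of)
    if unannotated:
        raise ValueError(f"unannotated node(s): {unannotated}")
    fam_list = list(families) if families is not None else sorted(
        {fam_of[n] for n in nodes})
    meta_nodes = {f: {"size": 0, "intra_edges": 0, "value": 0.0} for f in fam_list}
    members: dict[str, set] = {f: set() for f in fam_list}
    meta_edges: dict[tuple[str, str], int] = {}
    for a, b in edges:
        fa, fb = fam_of[a], fam_of[b]
        for f, n in ((fa, a), (fb, b)):
            if f not in meta_nodes:
                meta_nodes[f] = {"size": 0, "intra_edges": 0, "value": 0.0}
                members[f] = set()
        members[fa].add(a)
        members[fb].add(b)
        if fa == fb:
            meta_nodes[fa]["intra_edges"] += 1
        else:
            key = tuple(sorted((fa, fb)))
            meta_edges[key] = meta_edges.get(key, 0) + 1
    for f in meta_nodes:
        meta_nodes[f]["size"] = len(members.get(f, ()))
    return FamilyMetaNetwork(meta_nodes=meta_nodes, meta_edges=meta_edges)


def layout_meta(meta: FamilyMetaNetwork, seed: int = 0) -> FamilyMetaNetwork:
    """Kamada-Kawai coordinates; edge length 1/weight, components laid out
    independently and offset (logged when more than one)."""
    g = nx.Graph()
    g.add_nodes_from(meta.families)
    for (a, b), w in meta.meta_edges.items():
        g.add_edge(a, b, length=1.0 / max(w, 1))
    pos: dict[str, tuple[float, float]] = {}
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: c[0])
    if len(components) > 1:
        log.info("meta-network has %d components; independent layouts",
                 len(components))
    offset = 0.0
    for comp in components:
        sub = g.subgraph(comp)
        if len(comp) == 1:
            pos[comp[0]] = (offset, 0.0)
            offset += 3.0
            continue
        # deterministic circular initialization keyed only to node order
        init = nx.circular_layout(sub)
        dist = dict(nx.all_pairs_dijkstra_path_length(sub, weight="length"))
        p = nx.kamada_kawai_layout(sub, dist=dist, pos=init)
        for n, (x, y) in p.items():
            pos[n] = (float(x) + offset, float(y))
        offset += 3.0
    meta.layout = pos
    return meta


@dataclass
class TopographicSurface:
    x: np.ndarray           # grid_n
    y: np.ndarray           # grid_n
    z: np.ndarray           # grid_n x grid_n, z[j, i] at (x[i], y[j])
    bandwidth: float

    def to_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame({"x": xx.ravel(), "y": yy.ravel(),
                             "z": self.z.ravel()})


def default_bandwidth(layout: dict[str, tuple[float, float]]) -> float:
    """0.25 x median pairwise inter-node distance (1.0 for a single node)."""
    pts = np.asarray(list(layout.values()), dtype=float)
    if len(pts) < 2:
        return 1.0
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    upper = d[np.triu_indices(len(pts), k=1)]
    med = float(np.median(upper))
    return 0.25 * med if med > 0 else 1.0


def topographic_surface(layout: dict[str, tuple[float, float]],
                        values: dict[str, float],
                        bandwidth: float | None = None,
                        grid_n: int = 80, pad: float = 1.0) -> TopographicSurface:
    """Gaussian radial-basis mixture surface over the layout."""
    missing = set(values) ^ set(layout)
    if missing:
        raise ValueError(f"layout and values disagree on families: {sorted(missing)}")
    if bandwidth is None:
        bandwidth = default_bandwidth(layout)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    pts = np.asarray([layout[f] for f in layout], dtype=float)
    vals = np.asarray([values[f] for f in layout], dtype=float)
    x = np.linspace(pts[:, 0].min() - pad, pts[:, 0].max() + pad, grid_n)
    y = np.linspace(pts[:, 1].min() - pad, pts[:, 1].max() + pad, grid_n)
    xx, yy = np.meshgrid(x, y)
    z = np.zeros_like(xx)
    for (px, py), v in zip(pts, vals):
        z += v * np.exp(-((xx - px) ** 2 + (yy - py) ** 2) / (2 * bandwidth ** 2))
    return TopographicSurface(x=x, y=y, z=z, bandwidth=float(bandwidth))


def surface_at(surface_args: tuple[dict, dict, float], point) -> float:
    """Closed-form surface value at an arbitrary point (no grid)."""
    layout, values, bandwidth = surface_args
    px, py = point
    z = 0.0
    for f, (x, y) in layout.items():
        z += values[f] * np.exp(-((px - x) ** 2 + (py - y) ** 2)
                                / (2 * bandwidth ** 2))
    return float(z)


# ---------------------------------------------------------------------------
# import/export
# ---------------------------------------------------------------------------

def export_network(meta: FamilyMetaNetwork, path, fmt: str = "graphml") -> None:
    """Write the meta-network as graphml, json or csv (edge list)."""
    if fmt == "graphml":
        nx.write_graphml(meta.to_graph(), path)
    elif fmt == "json":
        doc = {
            "meta_nodes": meta.meta_nodes,
            "meta_edges": [{"a": a, "b": b, "weight": w}
                           for (a, b), w in sorted(meta.meta_edges.items())],
            "layout": {f: list(xy) for f, xy in meta.layout.items()},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
    elif fmt == "csv":
        rows = [{"family_a": a, "family_b": b, "weight": w}
                for (a, b), w in sorted(meta.meta_edges.items())]
        pd.DataFrame(rows, columns=["family_a", "family_b", "weight"]).to_csv(
            path, index=False)
    else:
        raise ValueError(f"unknown export format: {fmt!r}")


def import_network(path, fmt: str = "graphml") -> FamilyMetaNetwork:
    """Inverse of export_network for graphml and json."""
    if fmt == "graphml":
        g = nx.read_graphml(path)
        meta_nodes, layout = {}, {}
        for n, d in g.nodes(data=True):
            meta_nodes[n] = {"size": int(d["size"]),
                             "intra_edges": int(d["intra_edges"]),
                             "value": float(d.get("value", 0.0))}
            if "x" in d:
                layout[n] = (float(d["x"]), float(d["y"]))
        meta_edges = {tuple(sorted((a, b))): int(d["weight"])
                      for a, b, d in g.edges(data=True)}
        return FamilyMetaNetwork(meta_nodes, meta_edges, layout)
    if fmt == "json":
        with open(path) as fh:
            doc = json.load(fh)
        return FamilyMetaNetwork(
            meta_nodes=doc["meta_nodes"],
            meta_edges={(e["a"], e["b"]): e["weight"] for e in doc["meta_edges"]},
            layout={f: tuple(xy) for f, xy in doc["layout"].items()},
        )
    raise ValueError(f"unknown import format: {fmt!r}")
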