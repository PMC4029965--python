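"""Signed bipartite miRNA → gene-set networks from a CoMi profile.

Each significant CoMi index becomes a directed edge from its miRNA to its
gene-set term.  miRNAs carry out-edges (they act on the set), terms carry
in-edges.  Edge weight is -log10 of the index p-value; the sign (direction)
records whether the targets were up- or down-regulated relative to the
non-targets.  Exports are Cytoscape-friendly (GraphML / SIF) plus a flat TSV.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .data_model import CoMiProfile

EDGE_COLUMNS = ["mirna", "term", "statistic", "p_value", "weight", "direction"]


@dataclass(frozen=True)
class NetworkEdge:
    mirna: str
    term: str
    statistic: float
    p_value: float
    weight: float
    direction: str


@dataclass
class CoMiNetwork:
    """Edge list plus the two node sides of the bipartite graph."""

    edges: list[NetworkEdge]
    mirna_nodes: frozenset[str] = field(default=frozenset())
    term_nodes: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        if not self.mirna_nodes:
            self.mirna_nodes = frozenset(e.mirna for e in self.edges)
        if not self.term_nodes:
            self.term_nodes = frozenset(e.term for e in self.edges)
        seen = set()
        for e in self.edges:
            if (e.mirna, e.term) in seen:
                raise ValueError(f"duplicate edge ({e.mirna}, {e.term})")
            seen.add((e.mirna, e.term))
            if e.mirna not in self.mirna_nodes or e.term not in self.term_nodes:
                raise ValueError("edge endpoint missing from node sets")

    def __len__(self) -> int:
        return len(self.edges)

    def edge_keys(self) -> set[tuple[str, str]]:
        return {(e.mirna, e.term) for e in self.edges}


def build_network(profile: CoMiProfile, alpha: float = 0.05) -> CoMiNetwork:
    """Keep indices with p < alpha as edges, weighted by -log10(p)."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    if len(profile) == 0:
        raise ValueError("empty profile")
    edges = []
    for key in profile.keys():
        idx = profile.indices[key]
        if idx.p_value < alpha:
            edges.append(
                NetworkEdge(
                    mirna=idx.pattern.mirna,
                    term=idx.pattern.term,
                    statistic=idx.statistic,
                    p_value=idx.p_value,
                    weight=-math.log10(idx.p_value),
                    direction=idx.direction,
                )
            )
    return CoMiNetwork(edges=edges)


def degree_table(net: CoMiNetwork) -> pd.DataFrame:
    """Out-degree per miRNA, in-degree per term; descending, then lexicographic."""
    out_deg = Counter(e.mirna for e in net.edges)
    in_deg = Counter(e.term for e in net.edges)
    rows = [("mir", node, out_deg.get(node, 0)) for node in net.mirna_nodes]
    rows += [("term", node, in_deg.get(node, 0)) for node in net.term_nodes]
    df = pd.DataFrame(rows, columns=["kind", "node", "degree"])
    df = df.sort_values(
        ["degree", "kind", "node"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return df[["node", "kind", "degree"]]


def degree_distribution(net: CoMiNetwork) -> dict[str, dict[int, int]]:
    """Histogram {degree: node count} for each side of the bipartite graph."""
    out_deg = Counter(e.mirna for e in net.edges)
    in_deg = Counter(e.term for e in net.edges)
    return {
        "mirna": dict(sorted(Counter(out_deg.values()).items())),
        "term": dict(sorted(Counter(in_deg.values()).items())),
    }


def to_networkx(net: CoMiNetwork) -> nx.DiGraph:
    """Directed graph with namespaced node ids (``mir:``/``go:`` prefixes)."""
    g = nx.DiGraph()
    for node in sorted(net.mirna_nodes):
        g.add_node(f"mir:{node}", kind="mirna", label=node)
    for node in sorted(net.term_nodes):
        g.add_node(f"go:{node}", kind="term", label=node)
    for e in net.edges:
        g.add_edge(
            f"mir:{e.mirna}",
            f"go:{e.term}",
            statistic=e.statistic,
            p=e.p_value,
            weight=e.weight,
            direction=e.direction,
        )
    return g


def import_graphml(path: str | Path) -> CoMiNetwork:
    """Rebuild a network from a GraphML export (round-trip check)."""
    g = nx.read_graphml(Path(path))
    edges = []
    for u, v, attrs in g.edges(data=True):
        edges.append(
            NetworkEdge(
                mirna=g.nodes[u]["label"],
                term=g.nodes[v]["label"],
                statistic=float(attrs["statistic"]),
                p_value=float(attrs["p"]),
                weight=float(attrs["weight"]),
                direction=str(attrs["direction"]),
            )
        )
    edges.sort(key=lambda e: (e.mirna, e.term))
    mirnas = frozenset(d["label"] for _, d in g.nodes(data=True) if d["kind"] == "mirna")
    terms = frozenset(d["label"] for _, d in g.nodes(data=True) if d["kind"] == "term")
    return CoMiNetwork(edges=edges, mirna_nodes=mirnas, term_nodes=terms)


def export_network(net: CoMiNetwork, path: str | Path, format: str = "graphml") -> None:
    """Write the network as graphml, sif (Cytoscape) or a flat TSV edge list."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(to_networkx(net), path)
    elif format == "sif":
        with open(path, "w") as fh:
            for e in sorted(net.edges, key=lambda e: (e.mirna, e.term)):
                fh.write(f"{e.mirna}\tregulates\t{e.term}\n")
    elif format == "tsv":
        rows = [
            (e.mirna, e.term, e.statistic, e.p_value, e.weight, e.direction)
            for e in sorted(net.edges, key=lambda e: (e.mirna, e.term))
        ]
        pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(
            path, sep="\t", index=False, float_format="%.12g"
        )
    else:
        raise ValueError(f"unknown export format {format!r}")
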