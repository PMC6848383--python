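"""Telomere-maintenance pathway topologies and pathway signal flow (PSF).

Two curated directed signed pathway graphs ship with the package: the
telomerase pathway (TEL; TERT, TERC/hTR and DKC1/dyskerin branches feeding
telomerase complex assembly, nuclear localisation and the TEL sink) and the
alternative-lengthening pathway (ALT; chromatin decompaction, APB
formation, TERRA/telomeric instability and the three homologous
recombination steps feeding the ALT sink).  Genes act as activators or
suppressors via signed edges; several boxes are composite (multi-gene)
nodes.

The PSF algorithm propagates per-sample expression fold changes (relative
to the reference-group mean) through the topology in topological order:

* a source node's signal is its fold change;
* an activating edge passes the parent signal ``s``, an inhibiting edge
  passes ``1/s``;
* a node's combined input is the mean of its parents' passed signals
  (configurable: mean, sum, min or product), multiplied by the node's own
  fold change (composite nodes use the geometric mean of member fold
  changes; process and sink nodes have unit fold change);
* the sink score summarises the pathway: with all-unity input every node
  scores exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib.resources import files
from typing import Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NODE_KINDS = ("gene", "process", "sink")
EDGE_SIGNS = ("activate", "inhibit")
COMBINE_RULES = ("mean", "sum", "min", "product")


@dataclass
class PathwayGraph:
    """Directed signed pathway graph of gene/process nodes and one sink."""

    graph: nx.DiGraph
    name: str = "pathway"
    removed_edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def sink(self) -> str:
        return next(n for n, d in self.graph.nodes(data=True) if d["kind"] == "sink")

    @property
    def branches(self) -> set[str]:
        return {d["branch"] for n, d in self.graph.nodes(data=True)
                if d["kind"] != "sink"}

    @property
    def genes(self) -> set[str]:
        out = set()
        for n, d in self.graph.nodes(data=True):
            if d["kind"] == "gene":
                out.update(d["members"])
        return out

    def members(self, node: str) -> tuple[str, ...]:
        return self.graph.nodes[node]["members"]

    def nodes_of_gene(self, gene: str) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True)
                if d["kind"] == "gene" and gene in d["members"]]

    def branch_terminals(self) -> dict[str, str]:
        """The last node of each branch: a branch node all of whose
        successors lie outside the branch (topologically last on ties)."""
        topo = {n: i for i, n in enumerate(nx.lexicographical_topological_sort(self.graph))}
        out: dict[str, str] = {}
        for b in sorted(self.branches):
            cands = [n for n, d in self.graph.nodes(data=True)
                     if d["kind"] != "sink" and d["branch"] == b
                     and all(self.graph.nodes[s]["branch"] != b
                             or self.graph.nodes[s]["kind"] == "sink"
                             for s in self.graph.successors(n))]
            if cands:
                out[b] = max(cands, key=lambda n: (topo[n], n))
        return out

    def validate(self) -> None:
        g = self.graph
        sinks = [n for n, d in g.nodes(data=True) if d.get("kind") == "sink"]
        if len(sinks) != 1:
            raise ValueError(f"{self.name}: expected exactly one sink, found {sinks}")
        for n, d in g.nodes(data=True):
            if d.get("kind") not in NODE_KINDS:
                raise ValueError(f"{self.name}: node {n!r} has unknown kind {d.get('kind')!r}")
        for u, v, d in g.edges(data=True):
            if d.get("sign") not in EDGE_SIGNS:
                raise ValueError(f"{self.name}: edge {u}->{v} has unknown sign {d.get('sign')!r}")
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError(f"{self.name}: graph is cyclic after preprocessing")


@dataclass
class PSFResult:
    """PSF node activities for one sample."""

    node_scores: dict[str, float]
    branch_scores: dict[str, float]
    sink_score: float


def _parse_table(path, expected: list[str]) -> list[dict]:
    rows = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if header is None:
                header = parts
                miss = [c for c in expected if c not in header]
                if miss:
                    raise ValueError(f"{path}: missing column(s) {miss}")
                continue
            rows.append((lineno, dict(zip(header, parts))))
    return rows


def load_pathway(edge_path, node_path=None, name: Optional[str] = None) -> PathwayGraph:
    """Load a pathway from an edge-list TSV (and optional node-table TSV).

    Edge columns: source, target, sign in {activate, inhibit}, priority
    (integer; lower-priority edges are removed first when breaking cycles).
    Node columns: node, kind in {gene, process, sink}, branch, members
    (semicolon-separated genes for composite nodes).  Without a node table,
    all nodes are genes in one branch except the unique node with no
    outgoing edges, which becomes the sink.
    """
    name = name or str(edge_path)
    g = nx.DiGraph()
    declared = None
    if node_path is not None:
        declared = {}
        for lineno, row in _parse_table(node_path, ["node", "kind"]):
            kind = row["kind"]
            if kind not in NODE_KINDS:
                raise ValueError(f"{node_path}:{lineno}: unknown node kind {kind!r} "
                                 f"for node {row['node']!r}")
            members = tuple(x for x in row.get("members", "").split(";") if x)
            if kind == "gene" and not members:
                members = (row["node"],)
            declared[row["node"]] = dict(kind=kind, branch=row.get("branch", ""),
                                         members=members)
        g.add_nodes_from((n, d) for n, d in declared.items())

    for lineno, row in _parse_table(edge_path, ["source", "target", "sign"]):
        sign = row["sign"]
        if sign not in EDGE_SIGNS:
            raise ValueError(f"{edge_path}:{lineno}: unknown edge sign {sign!r}")
        for endpoint in (row["source"], row["target"]):
            if declared is not None and endpoint not in declared:
                raise ValueError(f"{edge_path}:{lineno}: edge references "
                                 f"undeclared node {endpoint!r}")
        g.add_edge(row["source"], row["target"], sign=sign,
                   priority=int(row.get("priority", 0) or 0))

    if declared is None:
        sinks = [n for n in g if g.out_degree(n) == 0]
        if len(sinks) != 1:
            raise ValueError(f"{name}: cannot infer sink; nodes with no "
                             f"outgoing edges: {sinks}")
        for n in g:
            kind = "sink" if n == sinks[0] else "gene"
            g.nodes[n].update(kind=kind, branch="" if kind == "sink" else "main",
                              members=(n,) if kind == "gene" else ())

    removed = []
    while not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        u, v = min(((u, v) for u, v, *_ in cycle),
                   key=lambda e: (g.edges[e].get("priority", 0), e))
        logger.warning("%s: breaking cycle by removing edge %s -> %s", name, u, v)
        removed.append((u, v))
        g.remove_edge(u, v)
    return PathwayGraph(graph=g, name=name, removed_edges=removed)


def builtin_tmm_pathways() -> tuple[PathwayGraph, PathwayGraph]:
    """The curated TEL and ALT telomere-maintenance pathway graphs."""
    data = files("telomaint.data")
    tel = load_pathway(data.joinpath("tel_edges.tsv"), data.joinpath("tel_nodes.tsv"),
                       name="TEL")
    alt = load_pathway(data.joinpath("alt_edges.tsv"), data.joinpath("alt_nodes.tsv"),
                       name="ALT")
    return tel, alt


def _node_fc(g: nx.DiGraph, node: str, fc: Mapping[str, float]) -> float:
    d = g.nodes[node]
    if d["kind"] != "gene":
        return 1.0
    vals = np.array([float(fc.get(m, 1.0)) for m in d["members"]], dtype=float)
    if (vals <= 0).any():
        raise ValueError(f"fold changes must be strictly positive (node {node!r})")
    return float(np.exp(np.log(vals).mean()))   # geometric mean keeps neutrality


def compute_psf(pathway: PathwayGraph, fc: Mapping[str, float],
                combine: str = "mean") -> PSFResult:
    """Propagate fold changes through the pathway; see the module docstring.

    ``fc`` maps gene -> linear fold change (genes absent default to 1).
    """
    if combine not in COMBINE_RULES:
        raise ValueError(f"combine must be one of {COMBINE_RULES}")
    if hasattr(fc, "items"):
        bad = [g_ for g_, v in fc.items() if not np.isfinite(v) or v <= 0]
        if bad:
            raise ValueError(f"fold changes must be strictly positive; offending "
                             f"genes: {bad[:5]}")
    g = pathway.graph
    scores: dict[str, float] = {}
    for node in nx.lexicographical_topological_sort(g):
        own = _node_fc(g, node, fc)
        parents = list(g.predecessors(node))
        if not parents:
            scores[node] = own
            continue
        inputs = []
        for p in parents:
            s = scores[p]
            inputs.append(1.0 / s if g.edges[p, node]["sign"] == "inhibit" else s)
        inputs = np.array(inputs, dtype=float)
        if combine == "mean":
            agg = inputs.mean()
        elif combine == "sum":
            agg = inputs.sum()
        elif combine == "min":
            agg = inputs.min()
        else:
            agg = inputs.prod()
        scores[node] = float(agg * own)
    terminals = pathway.branch_terminals()
    return PSFResult(node_scores=scores,
                     branch_scores={b: scores[t] for b, t in terminals.items()},
                     sink_score=scores[pathway.sink])


def psf_profiles(pathway: PathwayGraph, fc_matrix: pd.DataFrame,
                 combine: str = "mean") -> pd.DataFrame:
    """PSF node scores for every sample (columns of ``fc_matrix``)."""
    cols = {}
    for sample in fc_matrix.columns:
        res = compute_psf(pathway, fc_matrix[sample], combine=combine)
        cols[sample] = res.node_scores
    out = pd.DataFrame(cols)
    out.index.name = "node"
    return out
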