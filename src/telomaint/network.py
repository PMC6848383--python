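"""Co-expression correlation networks and betweenness centrality.

Vertices are telomere-maintenance genes (expression rows) plus the TEL/ALT
pathway sink scores as pseudo-genes; edges connect pairs whose Pearson
correlation across samples is significant at ``alpha`` (two-sided t test,
t = r sqrt((n-2)/(1-r^2))).  Anti-correlated pairs are retained with their
sign.  Interconnectivity is summarised by shortest-path betweenness
centrality on the unweighted edge set (Brandes algorithm via networkx),
endpoints excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

from statsmodels.stats.multitest import multipletests


@dataclass
class CorrelationNetwork:
    """Significance-thresholded Pearson correlation graph."""

    graph: nx.Graph           # vertices with edge attrs r, p, sign
    alpha: float
    n_samples: int

    @property
    def edges(self) -> pd.DataFrame:
        rows = [dict(v1=u, v2=v, r=d["r"], p=d["p"], sign=d["sign"])
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["v1", "v2", "r", "p", "sign"])


def pearson_pvalues(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson r and two-sided p for rows of ``x`` (features x
    samples) via the t transform with n-2 degrees of freedom."""
    n = x.shape[1]
    r = np.corrcoef(x)
    rr = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = rr * np.sqrt((n - 2) / (1 - rr ** 2))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    return r, p


def correlation_network(matrix: pd.DataFrame, alpha: float = 0.05,
                        bh_adjust: bool = False) -> CorrelationNetwork:
    """Build the correlation network over the rows of ``matrix``.

    ``matrix`` holds one row per vertex (gene expression or pathway sink
    score) and one column per sample; rows with zero variance are excluded
    with a warning.  ``bh_adjust`` applies BH correction to the edge
    p-values before thresholding (off by default: the conventional edge
    rule is a raw p < alpha).
    """
    n = matrix.shape[1]
    if n < 4:
        raise ValueError(f"need >= 4 samples for a correlation network, got {n}")
    x = matrix.to_numpy(dtype=float)
    keep = x.std(axis=1) > 0
    if not keep.all():
        dropped = list(matrix.index[~keep])
        warnings.warn(f"excluding zero-variance rows: {dropped}")
    names = list(matrix.index[keep])
    r, p = pearson_pvalues(x[keep])

    g = nx.Graph()
    g.add_nodes_from(names)
    iu, ju = np.triu_indices(len(names), k=1)
    pv = p[iu, ju]
    if bh_adjust and len(pv):
        pv = multipletests(pv, method="fdr_bh")[1]
    sig = pv < alpha
    for a, b, rv, pval in zip(iu[sig], ju[sig], r[iu, ju][sig], pv[sig]):
        g.add_edge(names[a], names[b], r=float(rv), p=float(pval),
                   sign=1 if rv >= 0 else -1)
    return CorrelationNetwork(graph=g, alpha=alpha, n_samples=n)


def betweenness(net: CorrelationNetwork | nx.Graph) -> pd.DataFrame:
    """Betweenness centrality table: unnormalised and normalised BC plus
    degree per vertex; isolated vertices get BC = 0."""
    g = net.graph if isinstance(net, CorrelationNetwork) else net
    bc = nx.betweenness_centrality(g, normalized=False)
    bcn = nx.betweenness_centrality(g, normalized=True)
    out = pd.DataFrame({
        "bc": pd.Series(bc),
        "bc_normalized": pd.Series(bcn),
        "degree": pd.Series(dict(g.degree())),
    })
    out.index.name = "vertex"
    return out.sort_values("bc", ascending=False)


def network_summary(net: CorrelationNetwork, centrality: pd.DataFrame,
                    membership: dict[str, str]) -> dict:
    """Degree distribution and pathway-annotated BC ranking.

    ``membership`` maps vertex -> pathway label (e.g. TEL / ALT).  Returns
    the degree histogram, the BC ranking annotated with membership, and the
    membership counts within the top BC decile.
    """
    g = net.graph
    degrees = pd.Series(dict(g.degree()), dtype=int)
    hist = degrees.value_counts().sort_index()
    hist.index.name = "degree"

    ranking = centrality.copy()
    ranking["membership"] = [membership.get(v, "unassigned") for v in ranking.index]

    n_top = max(1, int(np.ceil(len(ranking) / 10))) if len(ranking) else 0
    top = ranking.head(n_top)
    counts = top["membership"].value_counts().to_dict() if n_top else {}
    return dict(degree_histogram=hist, ranking=ranking,
                top_decile_membership=counts, n_top=n_top)


def write_graphml(net: CorrelationNetwork, path) -> None:
    nx.write_graphml(net.graph, path)
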