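"""Partial-influence (PI) scores of genes on pathway node activities.

The PI of a gene on a pathway node is the node's differential PSF score
when the gene is neutralised, i.e. its expression fold change set to unity:

    PI(gene, node) = PSF(node | fc) - PSF(node | fc with fc[gene] := 1)

Genes acting as activators of the node have PI > 0, inhibitors PI < 0, and
genes with no directed path to the node have PI = 0 exactly.  For composite
nodes the member gene is neutralised inside the composite (the node fold
change is re-aggregated with that member at 1), not removed.  Cohort-level
influencer rankings aggregate per-sample PIs by their mean (or median) and
sort by absolute aggregated PI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tmm_pathway import PathwayGraph, compute_psf


@dataclass
class PIScore:
    """Partial influence of one gene on one pathway node."""

    gene: str
    node: str
    per_sample: pd.Series    # sample -> PI
    mean_pi: float


def _check_node(pathway: PathwayGraph, node: str) -> None:
    if node not in pathway.graph:
        raise ValueError(f"unknown pathway node {node!r}")


def _neutralized(fc, gene: str):
    out = dict(fc.items()) if hasattr(fc, "items") else dict(fc)
    out[gene] = 1.0
    return out


def partial_influence(pathway: PathwayGraph, fc, gene: str, node: str,
                      combine: str = "mean") -> float:
    """PI of ``gene`` on ``node`` for a single fold-change vector."""
    _check_node(pathway, node)
    if gene not in pathway.genes:
        warnings.warn(f"gene {gene!r} is not part of pathway {pathway.name}; PI = 0")
        return 0.0
    full = compute_psf(pathway, fc, combine=combine).node_scores[node]
    neut = compute_psf(pathway, _neutralized(fc, gene), combine=combine).node_scores[node]
    return full - neut


def partial_influence_cohort(pathway: PathwayGraph, fc_matrix: pd.DataFrame,
                             gene: str, node: str, combine: str = "mean",
                             aggregate: str = "mean") -> PIScore:
    """PI of one gene on one node across a cohort of samples."""
    vals = {s: partial_influence(pathway, fc_matrix[s], gene, node, combine=combine)
            for s in fc_matrix.columns}
    per_sample = pd.Series(vals, name=f"PI({gene}->{node})")
    agg = per_sample.median() if aggregate == "median" else per_sample.mean()
    return PIScore(gene=gene, node=node, per_sample=per_sample, mean_pi=float(agg))


def rank_influencers(pathway: PathwayGraph, fc_matrix: pd.DataFrame, node: str,
                     genes=None, combine: str = "mean",
                     aggregate: str = "mean") -> pd.DataFrame:
    """Rank genes by group-aggregated |PI| on a node, descending.

    Efficient cohort evaluation: the full-model PSF is computed once per
    sample and each gene's neutralised model once per sample.  Ties in
    |aggregated PI| are broken by gene id.
    """
    if fc_matrix.shape[1] == 0:
        raise ValueError("empty cohort")
    _check_node(pathway, node)
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate must be 'mean' or 'median'")
    genes = sorted(pathway.genes) if genes is None else list(genes)

    full = {s: compute_psf(pathway, fc_matrix[s], combine=combine).node_scores[node]
            for s in fc_matrix.columns}
    rows = []
    per_sample_cols = {}
    for gene in genes:
        if gene not in pathway.genes:
            warnings.warn(f"gene {gene!r} is not part of pathway {pathway.name}; PI = 0")
            pis = pd.Series(0.0, index=fc_matrix.columns)
        else:
            pis = pd.Series({
                s: full[s] - compute_psf(pathway, _neutralized(fc_matrix[s], gene),
                                         combine=combine).node_scores[node]
                for s in fc_matrix.columns})
        agg = pis.median() if aggregate == "median" else pis.mean()
        rows.append(dict(gene=gene, node=node, mean_pi=float(agg)))
        per_sample_cols[gene] = pis
    table = pd.DataFrame(rows).set_index("gene")
    per_sample = pd.DataFrame(per_sample_cols).T
    per_sample.index.name = "gene"
    table = table.join(per_sample)
    # descending |aggregated PI|; stable sort after index sort breaks ties by gene id
    table = table.sort_index()
    table = table.iloc[np.argsort(-table["mean_pi"].abs().to_numpy(), kind="stable")]
    return table
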