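"""Count normalisation, fold changes, NB Wald differential expression, GSZ.

Differential expression follows the standard bulk RNA-seq negative-binomial
GLM route: median-of-ratios size factors, a per-gene moment estimate of the
NB dispersion (with a residual-degrees-of-freedom correction), a log-link
GLM with a group contrast fitted per gene, and a Wald test on the group
coefficient with Benjamini-Hochberg adjustment across genes.  This is a
self-contained implementation in the spirit of DESeq2's Wald test; exact
numerical concordance with DESeq2 (which shrinks dispersions and fold
changes) is not claimed — correctness is established by simulation
calibration against the in-repo count simulator.

Gene-set activity is scored per sample with a gene set enrichment z-score
(GSZ): the standardised sum of the set's (log, per-gene-centred) expression
scores under the finite-population null of drawing ``k`` of the sample's
``N`` gene scores without replacement,

    GSZ = (T - k mu) / sqrt(k sigma^2 (N - k)/(N - 1))

with ``T`` the sum of scores over the set and ``mu``, ``sigma^2`` the mean
and (population) variance of all gene scores in that sample.  This equals
the z-score of a random-set permutation null with infinitely many draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

LOG2 = np.log(2.0)


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with group labels."""

    counts: pd.DataFrame           # genes x samples, non-negative integers
    groups: pd.Series              # sample -> group label
    reference_group: str = "reference"

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        if self.reference_group not in set(self.groups):
            raise ValueError(f"reference group {self.reference_group!r} absent")
        self.groups = self.groups.loc[self.counts.columns]

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


@dataclass
class DEResult:
    """Per-gene Wald differential expression results for one contrast."""

    table: pd.DataFrame      # log2fc, se, wald_stat, pvalue, padj per gene
    contrast: tuple[str, str] = ("tumor", "reference")

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["padj"] < alpha]


def normalize_counts(m: CountMatrix) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalised matrix.

    The per-sample factor is the median ratio of the sample's counts to the
    per-gene geometric mean over samples, computed on genes expressed in all
    samples.
    """
    counts = m.counts.to_numpy(dtype=float)
    if counts.sum() == 0:
        raise ValueError("all-zero count matrix")
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    allpos = np.isfinite(logc).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene is expressed in every sample; cannot "
                         "compute median-of-ratios size factors")
    loggm = logc[allpos].mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logc[allpos] - loggm, axis=0))
    size_factors = pd.Series(sf, index=m.counts.columns, name="size_factor")
    normalized = m.counts / size_factors
    return size_factors, normalized


def fold_changes(m: CountMatrix, reference_group: Optional[str] = None,
                 pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-sample fold change of each gene vs the reference-group mean.

    fc(g, s) = (norm(g, s) + pc) / (mean_ref norm(g, .) + pc); strictly
    positive (linear scale), the input expected by pathway signal flow.
    """
    reference_group = reference_group or m.reference_group
    ref_samples = m.samples_in(reference_group)
    if not ref_samples:
        raise ValueError(f"reference group {reference_group!r} has no samples")
    _, norm = normalize_counts(m)
    ref_mean = norm[ref_samples].mean(axis=1)
    fc = (norm.add(pseudocount)).div(ref_mean + pseudocount, axis=0)
    return fc


def _moment_dispersion(y: np.ndarray, sf: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Per-gene NB dispersion by the method of moments on normalised counts,
    pooled within groups with a residual-dof correction."""
    z = y / sf                          # genes x samples, normalised
    n = z.shape[1]
    p = design.shape[1]
    groups = design[:, 1].astype(bool)
    resid = np.empty_like(z)
    mu_hat = np.empty_like(z)
    for mask in (groups, ~groups):
        gm = z[:, mask].mean(axis=1, keepdims=True)
        resid[:, mask] = z[:, mask] - gm
        mu_hat[:, mask] = gm
    s2 = (resid ** 2).sum(axis=1) / (n - p)
    mu_bar = z.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mu_bar) / np.where(mu_bar > 0, mu_bar, np.nan) ** 2
    return np.clip(np.nan_to_num(alpha, nan=0.0), 1e-8, 100.0)


def nb_wald_test(m: CountMatrix, tumor_group: str,
                 reference_group: Optional[str] = None) -> DEResult:
    """Negative-binomial Wald test of a tumor group against the reference.

    Per gene: a log-link NB GLM with design [intercept, group] and
    log-size-factor offset; the Wald statistic is beta/SE on the group
    coefficient; two-sided normal p-values are BH-adjusted across tested
    genes.  Genes with all-zero counts in the contrast samples are reported
    as NaN and excluded from the adjustment.
    """
    reference_group = reference_group or m.reference_group
    t_samples = m.samples_in(tumor_group)
    r_samples = m.samples_in(reference_group)
    if len(t_samples) < 2 or len(r_samples) < 2:
        raise ValueError(
            f"need >= 2 samples per group for the Wald test; got "
            f"{len(t_samples)} in {tumor_group!r} and {len(r_samples)} in "
            f"{reference_group!r}")

    sub = CountMatrix(m.counts[r_samples + t_samples],
                      m.groups.loc[r_samples + t_samples], reference_group)
    sf, _ = normalize_counts(sub)
    sf = sf.to_numpy()
    y = sub.counts.to_numpy(dtype=float)
    design = np.column_stack([np.ones(y.shape[1]),
                              np.r_[np.zeros(len(r_samples)), np.ones(len(t_samples))]])
    offset = np.log(sf)
    alphas = _moment_dispersion(y, sf, design)

    n_genes = y.shape[0]
    beta = np.full(n_genes, np.nan)
    se = np.full(n_genes, np.nan)
    for i in range(n_genes):
        yi = y[i]
        if yi.sum() == 0:
            continue
        fam = sm.families.NegativeBinomial(alpha=float(alphas[i]))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(yi, design, family=fam, offset=offset).fit(maxiter=100)
            if res.converged:
                beta[i] = res.params[1]
                se[i] = res.bse[1]
        except Exception:
            pass

    wald = beta / se
    pval = 2.0 * scipy.stats.norm.sf(np.abs(wald))
    padj = np.full(n_genes, np.nan)
    tested = np.isfinite(pval)
    if tested.any():
        padj[tested] = multipletests(pval[tested], method="fdr_bh")[1]
    table = pd.DataFrame(dict(log2fc=beta / LOG2, se=se / LOG2, wald_stat=wald,
                              pvalue=pval, padj=padj), index=m.counts.index)
    return DEResult(table=table, contrast=(tumor_group, reference_group))


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values (monotone, capped at 1)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


@dataclass
class GSZProfile:
    """Per-sample gene-set enrichment z-scores (samples x gene sets)."""

    scores: pd.DataFrame


def gene_scores(normalized: pd.DataFrame, pseudocount: float = 1.0,
                center: str = "gene") -> pd.DataFrame:
    """Log2 expression scores, centred per gene across samples (default) or
    per sample across genes."""
    logx = np.log2(normalized + pseudocount)
    if center == "gene":
        return logx.sub(logx.mean(axis=1), axis=0)
    if center == "sample":
        return logx.sub(logx.mean(axis=0), axis=1)
    raise ValueError("center must be 'gene' or 'sample'")


def gsz_from_scores(scores: pd.DataFrame, gene_sets: dict[str, list[str]]) -> GSZProfile:
    """GSZ from a precomputed gene-score matrix (genes x samples)."""
    N = scores.shape[0]
    x = scores.to_numpy()
    mu = x.mean(axis=0)
    var = x.var(axis=0)            # population variance, finite-population null
    out = {}
    for name, genes in gene_sets.items():
        members = scores.index.intersection(pd.Index(genes).unique())
        k = len(members)
        if k == 0:
            raise ValueError(f"gene set {name!r} has no genes in the matrix")
        T = x[scores.index.get_indexer(members)].sum(axis=0)
        denom2 = k * var * (N - k) / (N - 1) if N > 1 else np.zeros_like(var)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (T - k * mu) / np.sqrt(denom2)
        out[name] = np.where(denom2 > 0, z, 0.0)
    return GSZProfile(scores=pd.DataFrame(out, index=scores.columns))


def gsz_score(normalized: pd.DataFrame, gene_sets: dict[str, list[str]],
              pseudocount: float = 1.0) -> GSZProfile:
    """Per-sample GSZ profile of one or more gene sets.

    ``normalized`` is a genes x samples matrix of normalised expression
    (see :func:`normalize_counts`).
    """
    return gsz_from_scores(gene_scores(normalized, pseudocount), gene_sets)


def load_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (set name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def builtin_gene_sets() -> dict[str, list[str]]:
    """Curated gene sets for telomere-maintenance analysis (editable lists
    shipped with the package)."""
    from importlib.resources import files

    return load_gmt(files("telomaint.data").joinpath("gene_sets.gmt"))
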