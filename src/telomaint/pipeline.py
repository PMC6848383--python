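"""End-to-end orchestration: reads -> MTL/TRV; counts -> FC/DE/GSZ -> PSF ->
PI -> correlation network, from a single YAML config with a fixed seed.

Every stage writes TSV outputs into the configured output directory and the
run finishes with a provenance manifest (seed, config hash, package
versions, per-stage status).  A fixed seed makes the outputs byte
identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synth_data import (TelomereProfile, SequencingParams, ExpressionDesign,
                         simulate_telomere_readset, simulate_count_matrix)
from . import telomere_metrics as tmet
from .diffexpr import (CountMatrix, normalize_counts, fold_changes, nb_wald_test,
                       gsz_score, builtin_gene_sets)
from .tmm_pathway import builtin_tmm_pathways, psf_profiles
from .influence import rank_influencers
from .network import correlation_network, betweenness, network_summary, write_graphml

logger = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.10g"

# planted tumor log2 fold changes of the demo cohort: telomerase-branch
# activation with weaker ALT activation and SP100 loss
DEMO_PLANTED = {
    "TERT": 1.0, "DKC1": 1.2, "NHP2": 0.9, "GAR1": 0.8, "RUVBL1": 0.9,
    "RUVBL2": 0.8, "HSP90AA1": 0.6, "HSP90AB1": 0.7, "IPO7": 0.5,
    "HSPA1A": -0.5, "STUB1": -0.4,
    "RAD51": 0.6, "MND1": 0.9, "POLD3": 0.5, "RFC1": 0.4, "PML": 0.5,
    "CHEK1": 0.8, "BRCA1": 0.6, "SP100": -1.2, "ATRX": -0.3,
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run (parsed from YAML)."""

    seed: int = 0
    output_dir: str = "telomaint_out"
    telomere: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw[k] for k in ("seed", "output_dir", "telomere",
                                     "expression", "thresholds") if k in raw}
        return cls(**known)

    def to_dict(self) -> dict:
        return dict(seed=self.seed, output_dir=self.output_dir,
                    telomere=self.telomere, expression=self.expression,
                    thresholds=self.thresholds)

    @property
    def config_hash(self) -> str:
        # the output location is not part of the scientific configuration
        d = self.to_dict()
        d.pop("output_dir")
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def demo_config(seed: int = 17, output_dir: str = "telomaint_demo") -> RunConfig:
    """The shipped demo cohort: 3 tumor/reference pairs with telomere
    shortening plus an NB count cohort with TEL-dominant activation."""
    return RunConfig(
        seed=seed,
        output_dir=output_dir,
        telomere=dict(
            n_ends=92, read_length=100, coverage=4.0, error_rate=0.001,
            background_genome_length=100_000,
            variant_mix={"TGAGGG": 0.05, "TTAGGGG": 0.02},
            pairs=[dict(id="P1", reference_length=3000, tumor_length=1600),
                   dict(id="P2", reference_length=2800, tumor_length=1500),
                   dict(id="P3", reference_length=3200, tumor_length=1700)],
        ),
        expression=dict(
            n_genes=400,
            group_sizes={"reference": 10, "tumor": 10},
            nb_dispersion=0.05,
            planted_log2fc={g: {"tumor": v} for g, v in DEMO_PLANTED.items()},
        ),
        thresholds=dict(de_alpha=0.05, edge_alpha=0.05,
                        min_repeat_fraction=0.8, max_mismatch_per_unit=1),
    )


def _write(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT, **kwargs)


def _telomere_stage(cfg: RunConfig, outdir: Path, seeds) -> dict:
    t = cfg.telomere
    th = cfg.thresholds
    classify_kwargs = dict(
        min_repeat_fraction=th.get("min_repeat_fraction", 0.8),
        max_mismatch_per_unit=th.get("max_mismatch_per_unit", 1))
    n_ends = t.get("n_ends", 92)
    cov = t.get("coverage", 4.0)
    estimates, profiles, deltas = {}, {}, []
    for i, pair in enumerate(t.get("pairs", [])):
        mtls = {}
        for j, (role, length) in enumerate(
                [("reference", pair["reference_length"]),
                 ("tumor", pair["tumor_length"])]):
            prof = TelomereProfile(n_ends=n_ends, end_lengths=float(length),
                                   variant_mix=t.get("variant_mix", {}))
            params = SequencingParams(
                read_length=t.get("read_length", 100), genome_coverage=cov,
                substitution_error_rate=t.get("error_rate", 0.001),
                background_genome_length=t.get("background_genome_length", 100_000),
                seed=int(seeds[2 * i + j]))
            reads = simulate_telomere_readset(prof, params)
            telo = tmet.classify_reads(reads, **classify_kwargs)
            est = tmet.estimate_mtl(telo, cov, n_ends)
            name = f"{pair['id']}_{role}"
            estimates[name] = est
            profiles[name] = tmet.profile_trv(telo, est)
            mtls[role] = est.mtl
        deltas.append(tmet.PairedDelta(pair_id=pair["id"],
                                       reference_mtl=mtls["reference"],
                                       tumor_mtl=mtls["tumor"]))
    _write(tmet.mtl_table(estimates), outdir / "mtl.tsv", index=False)
    _write(tmet.trv_table(profiles), outdir / "trv.tsv", index=False)
    dtab = pd.DataFrame([dict(pair=d.pair_id, reference_mtl=d.reference_mtl,
                              tumor_mtl=d.tumor_mtl, delta=d.delta) for d in deltas])
    if len(dtab):
        dtab.loc[len(dtab)] = dict(pair="mean", reference_mtl=dtab.reference_mtl.mean(),
                                   tumor_mtl=dtab.tumor_mtl.mean(),
                                   delta=dtab.delta.mean())
    _write(dtab, outdir / "paired_deltas.tsv", index=False)
    return dict(n_pairs=len(deltas),
                mean_delta=float(np.mean([d.delta for d in deltas])) if deltas else None)


def _expression_stage(cfg: RunConfig, outdir: Path, seed: int) -> dict:
    e = cfg.expression
    th = cfg.thresholds
    tel, alt = builtin_tmm_pathways()
    tmm_genes = sorted(tel.genes | alt.genes)
    n_genes = e.get("n_genes", 400)
    if n_genes < len(tmm_genes):
        raise ValueError("n_genes must cover the TMM gene panel")
    gene_names = tmm_genes + [f"GENE{i:05d}" for i in range(n_genes - len(tmm_genes))]
    design = ExpressionDesign(
        n_genes=n_genes, group_sizes=e.get("group_sizes", {"reference": 10, "tumor": 10}),
        planted_log2fc=e.get("planted_log2fc", {}),
        nb_dispersion=e.get("nb_dispersion", 0.05), seed=seed)
    counts, groups, truth = simulate_count_matrix(design, gene_names=gene_names)
    _write(counts, outdir / "counts.tsv", index_label="gene")
    _write(groups.to_frame(), outdir / "groups.tsv", index_label="sample")
    m = CountMatrix(counts, groups, "reference")

    _, norm = normalize_counts(m)
    fc = fold_changes(m)
    _write(fc, outdir / "fold_changes.tsv", index_label="gene")

    tumor_groups = [g for g in groups.unique() if g != "reference"]
    de_tables = []
    for tg in tumor_groups:
        res = nb_wald_test(m, tg)
        tab = res.table.copy()
        tab.insert(0, "contrast", f"{tg}_vs_reference")
        de_tables.append(tab)
    de = pd.concat(de_tables)
    _write(de, outdir / "de.tsv", index_label="gene")

    sets = {name: genes for name, genes in builtin_gene_sets().items()
            if len(set(genes) & set(counts.index))}
    gsz = gsz_score(norm, sets)
    _write(gsz.scores, outdir / "gsz.tsv", index_label="sample")

    psf_tel = psf_profiles(tel, fc)
    psf_alt = psf_profiles(alt, fc)
    psf = pd.concat([psf_tel.assign(pathway="TEL"), psf_alt.assign(pathway="ALT")])
    _write(psf, outdir / "psf.tsv", index_label="node")

    tumor_samples = [s for s in counts.columns if groups[s] != "reference"]
    fc_tum = fc[tumor_samples]
    pi_tel = rank_influencers(tel, fc_tum, tel.sink)
    pi_alt = rank_influencers(alt, fc_tum, alt.sink)
    _write(pi_tel, outdir / "pi_tel.tsv")
    _write(pi_alt, outdir / "pi_alt.tsv")

    sinks = pd.DataFrame({"TEL": psf_tel.loc[tel.sink], "ALT": psf_alt.loc[alt.sink]}).T
    expr_rows = np.log2(norm.loc[norm.index.intersection(tmm_genes)] + 1)
    netmat = pd.concat([expr_rows[tumor_samples], sinks[tumor_samples]])
    net = correlation_network(netmat, alpha=th.get("edge_alpha", 0.05))
    cent = betweenness(net)
    membership = {g: "TEL" for g in tel.genes}
    membership.update({g: "ALT" for g in alt.genes})
    membership.update({"TEL": "TEL", "ALT": "ALT"})
    summary = network_summary(net, cent, membership)
    _write(net.edges, outdir / "network_edges.tsv", index=False)
    _write(summary["ranking"], outdir / "centrality.tsv")
    write_graphml(net, outdir / "network.graphml")

    n_sig = int((de["padj"] < th.get("de_alpha", 0.05)).sum())
    return dict(n_genes=n_genes, n_significant_de=n_sig,
                n_network_edges=len(net.graph.edges),
                mean_tel_sink_tumor=float(psf_tel.loc[tel.sink, tumor_samples].mean()),
                mean_alt_sink_tumor=float(psf_alt.loc[alt.sink, tumor_samples].mean()))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all configured stages in dependency order; returns the
    manifest (also written to ``manifest.json``).  A stage failure aborts
    the run with a stage-named error; outputs of finished stages remain."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    child = ss.generate_state(64, dtype=np.uint32) % (2 ** 31)

    config_record = cfg.to_dict()
    config_record.pop("output_dir")
    manifest = dict(package="telomaint", version=__version__, seed=cfg.seed,
                    config_hash=cfg.config_hash, config=config_record, stages={})
    stages = []
    if cfg.telomere.get("pairs"):
        stages.append(("telomere", lambda: _telomere_stage(cfg, outdir, child[:32])))
    if cfg.expression:
        stages.append(("expression", lambda: _expression_stage(cfg, outdir, int(child[32]))))
    for name, fn in stages:
        t0 = time.time()
        logger.info("stage %s: starting", name)
        try:
            info = fn()
        except Exception as exc:
            manifest["stages"][name] = dict(status="failed", error=str(exc))
            _write_manifest(manifest, outdir)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        logger.info("stage %s: done in %.1fs", name, time.time() - t0)
        manifest["stages"][name] = dict(status="ok", **info)
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
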