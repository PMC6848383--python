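"""Synthetic sequencing reads and RNA-seq count matrices with ground truth.

Every simulator emits its ground truth alongside the data (read origin
coordinates, per-tract repeat-unit counts, planted fold changes) so that
each downstream estimator has a parameter-recovery oracle.

The read simulator emulates whole-genome sequencing of a diploid genome
with telomeres: per-end telomeric tracts are assembled unit-by-unit from
the canonical TTAGGG hexamer and a configurable mix of repeat variants
(optionally biased toward the proximal, centromere-facing part of the
tract), embedded with non-telomeric flanks into a background genome of
i.i.d. uniform ACGT sequence.  Single-end reads of fixed length are drawn
uniformly from the genome, reverse-complemented with probability 1/2
(double-stranded sequencing), and subjected to uniform substitution errors.

The count simulator draws gene x sample matrices from a negative binomial
with per-gene baselines, per-sample library-size factors and planted
per-group log2 fold changes, emulating tumor-vs-reference bulk RNA-seq
cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._tiling import _BASES
from .readset import ReadSet

_PURINE_TAIL = ("G", "A")


@dataclass
class TelomereProfile:
    """Ground-truth telomere configuration of one simulated sample.

    Parameters
    ----------
    n_ends : int
        Telomere ends; 92 for a diploid human genome (2 x 46 chromosomes).
    end_lengths : array-like
        Target telomere length per end, bp.  A scalar is broadcast.
    variant_mix : dict
        Map repeat-variant (5-7-mer edit-distance-1 neighbour of TTAGGG)
        to its fraction of repeat units; the canonical hexamer gets the
        remainder.
    proximal_bias : float or None
        When set, variants are placed only within this proximal fraction of
        each tract (emulating sub-telomeric accumulation of variants);
        ``None`` places variants uniformly.
    """

    n_ends: int = 92
    end_lengths: object = 5000.0
    variant_mix: dict[str, float] = field(default_factory=dict)
    proximal_bias: Optional[float] = 0.3

    def __post_init__(self):
        self.end_lengths = np.broadcast_to(
            np.asarray(self.end_lengths, dtype=float), (self.n_ends,)).copy()
        if (self.end_lengths < 0).any():
            raise ValueError("end_lengths must be >= 0")
        tot = 0.0
        for key, f in self.variant_mix.items():
            if not (0 <= f <= 1):
                raise ValueError(f"variant fraction out of [0,1]: {key}={f}")
            if not (5 <= len(key) <= 7) or any(c not in _BASES for c in key):
                raise ValueError(f"variant key must be a 5-7-mer over ACGT: {key}")
            if key[-1] not in _PURINE_TAIL:
                raise ValueError(f"variant key must end in a purine tail: {key}")
            tot += f
        if tot > 1 + 1e-12:
            raise ValueError("variant fractions sum to more than 1")
        if self.proximal_bias is not None and not (0 < self.proximal_bias <= 1):
            raise ValueError("proximal_bias must be in (0, 1] or None")


@dataclass
class SequencingParams:
    """Sequencing instrument and genome-context parameters."""

    read_length: int = 100
    genome_coverage: float = 10.0
    substitution_error_rate: float = 0.001
    background_genome_length: int = 1_000_000
    n_interstitial_units: int = 50   # lone TTAGGG singletons in the background
    seed: int = 0

    def __post_init__(self):
        if self.read_length < 36:
            raise ValueError("read_length must be >= 36")
        if self.genome_coverage < 0:
            raise ValueError("coverage must be >= 0")
        if not (0 <= self.substitution_error_rate <= 0.05):
            raise ValueError("substitution error rate must be in [0, 0.05]")


@dataclass
class ExpressionDesign:
    """Design of a simulated tumor-vs-reference count matrix.

    ``planted_log2fc`` maps gene -> {group -> log2 fold change vs the
    reference group mean}; unlisted genes/groups are unchanged.
    """

    n_genes: int = 1000
    group_sizes: dict[str, int] = field(default_factory=lambda: {"reference": 20, "tumor": 20})
    reference_group: str = "reference"
    planted_log2fc: dict[str, dict[str, float]] = field(default_factory=dict)
    nb_dispersion: float = 0.05
    library_size_range: tuple[float, float] = (8e5, 1.2e6)
    baseline_log_mean: float = math.log(100.0)
    baseline_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.reference_group not in self.group_sizes:
            raise ValueError("group_sizes must include the reference group")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("empty groups are not allowed")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _encode_str(s: str) -> np.ndarray:
    return np.fromiter((_BASES.index(c) for c in s), dtype=np.uint8, count=len(s))


def _build_tract(rng: np.random.Generator, target_length: float,
                 variant_mix: dict[str, float], proximal_bias: Optional[float],
                 canonical: str = "TTAGGG") -> tuple[np.ndarray, dict[str, int]]:
    """Assemble one telomeric tract from repeat units; returns the encoded
    G-strand tract and the construction-time unit counts per variant."""
    if target_length <= 0:
        return np.empty(0, dtype=np.uint8), {}
    mean_len = sum(f * len(v) for v, f in variant_mix.items())
    mean_len += (1 - sum(variant_mix.values())) * len(canonical)
    n_units = max(1, round(target_length / mean_len))
    counts = {v: round(f * n_units) for v, f in variant_mix.items()}
    n_var = sum(counts.values())
    if n_var > n_units:
        raise ValueError("variant fractions leave no room for canonical units")
    units = [canonical] * n_units
    window = n_units if proximal_bias is None else max(n_var, math.ceil(proximal_bias * n_units))
    slots = rng.choice(window, size=n_var, replace=False)
    i = 0
    for v in sorted(counts):
        for _ in range(counts[v]):
            units[slots[i]] = v
            i += 1
    counts[canonical] = n_units - n_var
    tract = _encode_str("".join(units))
    return tract, counts


def simulate_telomere_readset(profile: TelomereProfile,
                              params: SequencingParams) -> ReadSet:
    """Simulate single-end WGS reads of a genome with telomeres.

    Reads are drawn uniformly from the synthetic genome (background plus
    flanked telomeric tracts), so the expected telomeric base yield is
    ``coverage x sum(end_lengths)``.  The returned ReadSet's ``truth``
    carries per-read origins/strands/telomeric overlaps, per-tract emitted
    lengths and construction-time repeat-unit counts.
    """
    rng = np.random.default_rng(params.seed)
    L = params.read_length
    flank = L  # non-telomeric context on both sides of each tract

    segments = [_random_sequence(rng, params.background_genome_length)]
    # interstitial lone canonical units to stress classification specificity
    canon = _encode_str("TTAGGG")
    for _ in range(params.n_interstitial_units):
        pos = rng.integers(0, max(1, params.background_genome_length - 6))
        segments[0][pos:pos + 6] = canon

    tract_rows = []
    unit_totals: dict[str, int] = {}
    offset = len(segments[0])
    for e in range(profile.n_ends):
        tract, counts = _build_tract(rng, profile.end_lengths[e],
                                     profile.variant_mix, profile.proximal_bias)
        segments.append(_random_sequence(rng, flank))
        offset += flank
        tract_rows.append(dict(end=e, start=offset, stop=offset + len(tract),
                               true_length=len(tract)))
        segments.append(tract)
        offset += len(tract)
        segments.append(_random_sequence(rng, flank))
        offset += flank
        for v, c in counts.items():
            unit_totals[v] = unit_totals.get(v, 0) + c

    genome = np.concatenate(segments)
    G = len(genome)
    tracts = pd.DataFrame(tract_rows)

    n_reads = int(round(params.genome_coverage * G / L))
    if n_reads == 0 or G < L:
        return ReadSet([], [], truth=dict(
            tracts=tracts, unit_counts=unit_totals, params=params, profile=profile,
            reads=pd.DataFrame(columns=["start", "strand", "telo_overlap"])))

    starts = rng.integers(0, G - L + 1, size=n_reads)
    mat = genome[starts[:, None] + np.arange(L)]

    # strand: reverse-complement half of the reads
    flip = rng.random(n_reads) < 0.5
    comp = np.array([3, 2, 1, 0], dtype=np.uint8)
    mat[flip] = comp[mat[flip][:, ::-1]]

    # uniform substitution errors to a different base
    if params.substitution_error_rate > 0:
        err = rng.random((n_reads, L)) < params.substitution_error_rate
        shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
        mat[err] = (mat[err] + shift) % 4

    # per-read telomeric overlap from origin coordinates (the recovery oracle)
    overlap = np.zeros(n_reads, dtype=np.int64)
    if len(tracts):
        ts = tracts["start"].to_numpy()
        te = tracts["stop"].to_numpy()
        j = np.searchsorted(ts, starts, side="right") - 1
        for cand in (j, j + 1):
            ok = (cand >= 0) & (cand < len(ts))
            lo = np.maximum(starts, np.where(ok, ts[np.clip(cand, 0, len(ts) - 1)], 0))
            hi = np.minimum(starts + L, np.where(ok, te[np.clip(cand, 0, len(ts) - 1)], 0))
            overlap += np.where(ok, np.maximum(0, hi - lo), 0)

    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    raw = lut[mat].tobytes().decode("ascii")
    seqs = [raw[i * L:(i + 1) * L] for i in range(n_reads)]
    names = [f"read{i}" for i in range(n_reads)]
    reads_truth = pd.DataFrame(dict(start=starts, strand=np.where(flip, "-", "+"),
                                    telo_overlap=overlap))
    return ReadSet(names, seqs, truth=dict(
        reads=reads_truth, tracts=tracts, unit_counts=unit_totals,
        params=params, profile=profile, genome_length=G))


def simulate_count_matrix(design: ExpressionDesign,
                          gene_names: Optional[list[str]] = None):
    """Simulate an NB gene x sample count matrix with planted fold changes.

    Returns ``(counts, groups, truth)``: an integer DataFrame (genes x
    samples), a sample -> group Series, and a truth dict with the baseline
    means, size factors, dispersion and planted log2 fold changes.
    """
    rng = np.random.default_rng(design.seed)
    if gene_names is None:
        gene_names = [f"GENE{i:05d}" for i in range(design.n_genes)]
    if len(gene_names) != design.n_genes:
        raise ValueError("gene_names length must equal n_genes")

    groups, samples = [], []
    for g, n in design.group_sizes.items():
        for i in range(n):
            samples.append(f"{g}_{i:02d}")
            groups.append(g)
    groups = pd.Series(groups, index=samples, name="group")

    baseline = rng.lognormal(design.baseline_log_mean, design.baseline_log_sd,
                             size=design.n_genes)
    # scale baselines so expected per-sample totals match library_size_range
    lib_target = 0.5 * (design.library_size_range[0] + design.library_size_range[1])
    baseline *= lib_target / baseline.sum()
    lfc = np.zeros((design.n_genes, len(samples)))
    gene_index = {g: i for i, g in enumerate(gene_names)}
    for gene, per_group in design.planted_log2fc.items():
        gi = gene_index[gene]
        for grp, v in per_group.items():
            lfc[gi, (groups == grp).to_numpy()] = v

    lib = rng.uniform(*design.library_size_range, size=len(samples))
    size_factors = lib / lib.mean()
    mu = baseline[:, None] * size_factors[None, :] * 2.0 ** lfc

    alpha = design.nb_dispersion
    if alpha < 1e-8:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / alpha
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)

    counts = pd.DataFrame(counts.astype(np.int64), index=gene_names, columns=samples)
    truth = dict(baseline=pd.Series(baseline, index=gene_names),
                 size_factors=pd.Series(size_factors, index=samples),
                 dispersion=alpha,
                 planted_log2fc=design.planted_log2fc)
    return counts, groups, truth


def write_ground_truth(readset: ReadSet, path) -> None:
    """Write the per-read ground-truth sidecar as TSV."""
    reads = readset.truth.get("reads")
    if reads is None:
        raise ValueError("readset carries no ground truth")
    reads.to_csv(path, sep="\t", index_label="read")
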