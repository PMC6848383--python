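"""Mean telomere length and telomeric repeat-variant estimation from reads.

The estimator follows the coverage-normalisation principle used by
read-alignment telomere-length tools: telomere-derived bases are identified
in the read set, summed, and converted to a mean telomere length (MTL) per
chromosome end by

    MTL = telomeric_base_count / (genome_coverage * n_ends)

so that at coverage ``c`` a genome with ``n_ends`` telomeres of mean length
``T`` yields ``c * n_ends * T`` telomeric bases.  ``n_ends`` defaults to 92
(diploid human: 46 chromosomes x 2 ends) and is configurable for other
ploidies.

A read is telomeric when the best tiling of the read by repeat units —
rotations of the canonical hexamer ``TTAGGG`` with a per-unit mismatch
budget, plus exact single-base insertion/deletion variants — covers at least
``min_repeat_fraction`` of its bases on either strand.  Reads spanning the
telomere-subtelomere junction carry an exactly-tiled telomeric prefix or
suffix; by default these are admitted too (``min_edge_bases`` or more tiled
bases at a read edge) and contribute only their tiled bases, which removes
the boundary bias a hard repeat-fraction cut-off would otherwise introduce.

The same tiling decomposes telomeric bases into canonical and variant repeat
units, giving the telomeric repeat-variant (TRV) spectrum: substitution
variants such as TGAGGG, insertion variants such as TTAGGGG/TTAAGGG and
deletion variants such as TAGGG/TTGGG.  Canonical plus variant lengths add
up to the MTL exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _tiling
from .readset import ReadSet

CANONICAL_PATTERN = "TTAGGG"
DEFAULT_N_ENDS = 92           # diploid human: 2 ends x 46 chromosomes
DEFAULT_MIN_REPEAT_FRACTION = 0.8
DEFAULT_MAX_MISMATCH = 1
DEFAULT_MIN_EDGE_BASES = 24   # >= 4 clean units at a read edge


@dataclass
class TelomereEstimate:
    """Mean telomere length estimate for one sample."""

    mtl: float                   # mean telomere length per end, bp
    telomeric_base_count: float  # telomere-matched bases in the read set
    genome_coverage: float       # mean fold coverage of the genome
    n_ends: int                  # telomere ends used for normalisation

    def __post_init__(self):
        expect = self.telomeric_base_count / (self.genome_coverage * self.n_ends)
        if not math.isclose(self.mtl, expect, rel_tol=1e-12, abs_tol=1e-9):
            raise ValueError("mtl does not satisfy the normalisation identity")


@dataclass
class TRVProfile:
    """Telomeric repeat-variant composition of one sample.

    ``cum_length`` is the total length contributed by each variant across all
    ends (bp); ``per_end_mean`` is the same normalised per chromosome end (so
    the values add up to the MTL); ``fraction`` is each variant's share of
    the total telomeric length.
    """

    cum_length: dict[str, float]
    per_end_mean: dict[str, float]
    fraction: dict[str, float]
    canonical: str = CANONICAL_PATTERN

    @property
    def noncanonical_total(self) -> float:
        return sum(v for k, v in self.per_end_mean.items() if k != self.canonical)


@dataclass
class PairedDelta:
    """Tumor-vs-reference MTL difference for one sample pair."""

    pair_id: str
    reference_mtl: float
    tumor_mtl: float
    delta: float = field(init=False)

    def __post_init__(self):
        self.delta = self.tumor_mtl - self.reference_mtl


def build_telomeric_reference(pattern: str = CANONICAL_PATTERN, target_length: int = 1000) -> str:
    """Tandem concatenation of a repeat unit, at least ``target_length`` bp.

    The returned reference is conceptually circular: every rotation of the
    unit occurs as a substring.
    """
    pattern = pattern.upper()
    if not pattern or any(c not in "ACGT" for c in pattern):
        raise ValueError(f"pattern must be a non-empty ACGT string, got {pattern!r}")
    n_units = max(1, math.ceil(target_length / len(pattern)))
    return pattern * n_units


def _analyze(reads: ReadSet, pattern: str, min_repeat_fraction: float,
             max_mismatch_per_unit: int, min_edge_bases: int,
             include_junctions: bool, collect_units: bool):
    """Tile every read on both strands; return classification mask, per-read
    telomeric base counts and (optionally) per-variant base totals."""
    tables = _tiling.build_unit_tables(pattern, max_mismatch_per_unit)
    n = len(reads)
    telo_bases = np.zeros(n, dtype=np.int64)
    is_telo = np.zeros(n, dtype=bool)
    unit_bases = np.zeros(len(tables.vocab), dtype=np.int64)

    for idx, mat in reads.length_batches():
        L = mat.shape[1]
        if L < tables.k:
            continue
        fwd = _tiling.tile_batch(mat, tables, want_choices=collect_units)
        rev = _tiling.tile_batch(_tiling.revcomp_matrix(mat), tables, want_choices=collect_units)

        def _contrib(rt):
            full = rt.anch_bases >= min_repeat_fraction * L
            junc = rt.anch_bases >= min_edge_bases if include_junctions else False
            telo = full | junc
            return np.where(telo, rt.anch_bases, 0), telo

        cf, telo_f = _contrib(fwd)
        cr, telo_r = _contrib(rev)
        use_rev = cr > cf
        contrib = np.where(use_rev, cr, cf)
        telo = contrib > 0
        telo_bases[idx] = contrib
        is_telo[idx] = telo

        if collect_units:
            for j in np.flatnonzero(telo):
                rt = rev if use_rev[j] else fwd
                units, _ = _tiling.backtrack_run(rt, j)
                # variant composition is estimated from run-interior units
                # only.  A terminus at the read boundary is a uniform cut
                # point: dropping exactly one unit keeps the interior
                # composition unbiased.  A terminus inside the read borders
                # non-telomeric sequence, where junction frame artefacts
                # can masquerade as variant chains: peel down to (and
                # including) the first exact canonical unit.
                if rt.anch_end[j] + rt.anch_ext[j] == L:
                    lo = 1
                else:
                    lo = 0
                    while lo < len(units) and units[lo][0] != 0:
                        lo += 1
                    lo += 1
                if rt.anch_start[j] == 0:
                    hi = len(units) - 1
                else:
                    hi = len(units) - 1
                    while hi >= 0 and units[hi][0] != 0:
                        hi -= 1
                for vid, k in units[lo:hi]:
                    unit_bases[vid] += k
    return is_telo, telo_bases, unit_bases, tables


def classify_reads(reads: ReadSet,
                   min_repeat_fraction: float = DEFAULT_MIN_REPEAT_FRACTION,
                   max_mismatch_per_unit: int = DEFAULT_MAX_MISMATCH,
                   pattern: str = CANONICAL_PATTERN,
                   min_edge_bases: int = DEFAULT_MIN_EDGE_BASES,
                   include_junctions: bool = True) -> ReadSet:
    """Select telomeric reads.

    A read is telomeric if on either strand its best repeat-unit tiling
    covers at least ``min_repeat_fraction`` of the read, or (default
    behaviour, ``include_junctions``) if at least ``min_edge_bases`` of a
    read edge are exactly tiled by repeat units, as happens for reads
    spanning the telomere boundary.  The returned ReadSet carries per-read
    telomere-matched base counts used by :func:`estimate_mtl`.
    """
    is_telo, telo_bases, _, _ = _analyze(
        reads, pattern, min_repeat_fraction, max_mismatch_per_unit,
        min_edge_bases, include_junctions, collect_units=False)
    out = reads.subset(is_telo)
    out.telo_bases = telo_bases[is_telo]
    out.truth = dict(out.truth)
    out.truth["classify_params"] = dict(
        pattern=pattern, min_repeat_fraction=min_repeat_fraction,
        max_mismatch_per_unit=max_mismatch_per_unit,
        min_edge_bases=min_edge_bases, include_junctions=include_junctions)
    return out


def estimate_mtl(telomeric: ReadSet, genome_coverage: float,
                 n_ends: int = DEFAULT_N_ENDS) -> TelomereEstimate:
    """Mean telomere length from classified telomeric reads.

    ``telomeric_base_count`` is the total of telomere-matched bases of the
    classified reads (tiled bases; junction-spanning reads contribute only
    their telomeric portion).
    """
    if genome_coverage <= 0:
        raise ValueError("genome_coverage must be positive")
    if n_ends <= 0:
        raise ValueError("n_ends must be positive")
    if telomeric.telo_bases is not None:
        count = int(telomeric.telo_bases.sum())
    else:
        p = telomeric.truth.get("classify_params", {})
        _, tb, _, _ = _analyze(
            telomeric, p.get("pattern", CANONICAL_PATTERN),
            p.get("min_repeat_fraction", DEFAULT_MIN_REPEAT_FRACTION),
            p.get("max_mismatch_per_unit", DEFAULT_MAX_MISMATCH),
            p.get("min_edge_bases", DEFAULT_MIN_EDGE_BASES),
            p.get("include_junctions", True), collect_units=False)
        count = int(tb.sum())
    mtl = count / (genome_coverage * n_ends)
    return TelomereEstimate(mtl=mtl, telomeric_base_count=count,
                            genome_coverage=genome_coverage, n_ends=n_ends)


def profile_trv(telomeric: ReadSet, mtl_context: TelomereEstimate) -> TRVProfile:
    """Decompose the telomeric length into canonical and variant repeats.

    The variant composition is estimated from run-interior repeat units
    (see the classification docs) and the total telomeric mass of the MTL
    estimate is allocated by those fractions, so canonical plus variant
    per-end lengths equal the MTL exactly.
    """
    p = telomeric.truth.get("classify_params", {})
    _, _, unit_bases, tables = _analyze(
        telomeric, p.get("pattern", CANONICAL_PATTERN),
        p.get("min_repeat_fraction", DEFAULT_MIN_REPEAT_FRACTION),
        p.get("max_mismatch_per_unit", DEFAULT_MAX_MISMATCH),
        p.get("min_edge_bases", DEFAULT_MIN_EDGE_BASES),
        p.get("include_junctions", True), collect_units=True)
    total = unit_bases.sum()
    cum, per_end, frac = {}, {}, {}
    for vid, name in enumerate(tables.vocab):
        b = int(unit_bases[vid])
        if b == 0 and name != tables.pattern:
            continue
        f = b / total if total > 0 else (1.0 if name == tables.pattern else 0.0)
        frac[name] = f
        per_end[name] = f * mtl_context.mtl
        cum[name] = f * mtl_context.mtl * mtl_context.n_ends
    return TRVProfile(cum_length=cum, per_end_mean=per_end, fraction=frac,
                      canonical=tables.pattern)


def paired_mtl_deltas(pairs: list[tuple[str, ReadSet, ReadSet]],
                      coverages: dict[str, tuple[float, float]],
                      n_ends: int = DEFAULT_N_ENDS,
                      **classify_kwargs) -> tuple[list[PairedDelta], float]:
    """Per-pair tumor-minus-reference MTL differences and their mean.

    Parameters
    ----------
    pairs : list of (pair_id, reference ReadSet, tumor ReadSet)
    coverages : map pair_id -> (reference coverage, tumor coverage)
        Every pair id must have a coverage entry; telomere shortening in the
        tumor gives a negative delta.
    """
    missing = [pid for pid, _, _ in pairs if pid not in coverages]
    if missing:
        raise ValueError(f"no coverage given for pair(s): {missing}")
    deltas = []
    for pid, ref, tum in pairs:
        cov_r, cov_t = coverages[pid]
        mtl_r = estimate_mtl(classify_reads(ref, **classify_kwargs), cov_r, n_ends).mtl
        mtl_t = estimate_mtl(classify_reads(tum, **classify_kwargs), cov_t, n_ends).mtl
        deltas.append(PairedDelta(pair_id=pid, reference_mtl=mtl_r, tumor_mtl=mtl_t))
    mean_delta = float(np.mean([d.delta for d in deltas])) if deltas else float("nan")
    return deltas, mean_delta


def mtl_table(estimates: dict[str, TelomereEstimate]) -> pd.DataFrame:
    """Per-sample MTL summary table."""
    rows = [dict(sample=s, mtl_bp=e.mtl, telomeric_bases=e.telomeric_base_count,
                 coverage=e.genome_coverage, n_ends=e.n_ends)
            for s, e in estimates.items()]
    return pd.DataFrame(rows)


def trv_table(profiles: dict[str, TRVProfile]) -> pd.DataFrame:
    """Long-format per-sample TRV table (sample, variant, cum_length_bp, fraction)."""
    rows = []
    for s, p in profiles.items():
        for v in p.cum_length:
            rows.append(dict(sample=s, variant=v, cum_length_bp=p.cum_length[v],
                             per_end_bp=p.per_end_mean[v], fraction=p.fraction[v]))
    return pd.DataFrame(rows)
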