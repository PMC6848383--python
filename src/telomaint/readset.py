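"""Container for sequencing reads with optional simulator ground truth."""

from __future__ import annotations

import gzip
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from . import _tiling


class ReadSet:
    """A set of single-end sequencing reads.

    Parameters
    ----------
    names : list of str
        Read identifiers.
    sequences : list of str
        Read sequences over ACGTN.
    qualities : list of str, optional
        Phred+33 quality strings; a constant high quality is assumed when
        absent.
    truth : dict, optional
        Simulator ground truth travelling with the reads.  Recognised keys:
        ``reads`` (per-read DataFrame: origin, strand, telomeric overlap),
        ``tracts`` (per-end DataFrame of emitted tract coordinates/lengths),
        ``unit_counts`` (per-variant repeat-unit counts at construction time)
        and ``params`` (simulation inputs).
    telo_bases : numpy array, optional
        Per-read telomere-matched base counts; attached by
        :func:`telomaint.telomere_metrics.classify_reads`.
    """

    def __init__(self, names, sequences, qualities=None, truth: Optional[dict] = None,
                 telo_bases: Optional[np.ndarray] = None):
        if len(names) != len(sequences):
            raise ValueError("names and sequences differ in length")
        self.names = list(names)
        self.sequences = list(sequences)
        self.qualities = list(qualities) if qualities is not None else None
        self.truth = truth or {}
        self.telo_bases = telo_bases

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self.names, self.sequences))

    def __repr__(self) -> str:
        return f"ReadSet(n_reads={len(self)})"

    @property
    def total_bases(self) -> int:
        return sum(len(s) for s in self.sequences)

    def subset(self, index) -> "ReadSet":
        """Subset by boolean mask or integer index array; truth per-read
        tables are subset alongside, per-sample truth is carried over."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        names = [self.names[i] for i in index]
        seqs = [self.sequences[i] for i in index]
        quals = [self.qualities[i] for i in index] if self.qualities else None
        truth = dict(self.truth)
        if isinstance(truth.get("reads"), pd.DataFrame):
            truth["reads"] = truth["reads"].iloc[index].reset_index(drop=True)
        tb = self.telo_bases[index] if self.telo_bases is not None else None
        return ReadSet(names, seqs, quals, truth=truth, telo_bases=tb)

    def length_batches(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        """Yield (read indices, encoded matrix) per distinct read length."""
        lens = np.fromiter((len(s) for s in self.sequences), dtype=np.int64,
                           count=len(self.sequences))
        for L in np.unique(lens):
            idx = np.flatnonzero(lens == L)
            mat = _tiling.encode([self.sequences[i] for i in idx])
            yield idx, mat

    def write_fastq(self, path) -> None:
        """Write standard 4-line FASTQ (phred+33; constant quality 'I' when
        no qualities are stored)."""
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            for i, (name, seq) in enumerate(self):
                qual = self.qualities[i] if self.qualities else "I" * len(seq)
                fh.write(f"@{name}\n{seq}\n+\n{qual}\n")

    @classmethod
    def from_fastq(cls, path) -> "ReadSet":
        import pysam

        names, seqs, quals = [], [], []
        with pysam.FastxFile(str(path)) as fh:
            for rec in fh:
                names.append(rec.name)
                seqs.append(rec.sequence.upper())
                quals.append(rec.quality if rec.quality is not None else "I" * len(rec.sequence))
        return cls(names, seqs, quals)

    @classmethod
    def concat(cls, readsets: list["ReadSet"]) -> "ReadSet":
        names, seqs = [], []
        for rs in readsets:
            names.extend(rs.names)
            seqs.extend(rs.sequences)
        return cls(names, seqs)
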