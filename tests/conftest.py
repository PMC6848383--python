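import numpy as np
import pandas as pd
import pytest

from telomaint.readset import ReadSet
from telomaint.synth_data import (TelomereProfile, SequencingParams,
                                  ExpressionDesign, simulate_telomere_readset,
                                  simulate_count_matrix)
from telomaint.diffexpr import CountMatrix


def make_random_reads(n: int, length: int = 100, seed: int = 0) -> ReadSet:
    """i.i.d. uniform ACGT reads (telomere-free background)."""
    rng = np.random.default_rng(seed)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    raw = lut[rng.integers(0, 4, size=(n, length), dtype=np.uint8)].tobytes().decode()
    return ReadSet([f"r{i}" for i in range(n)],
                   [raw[i * length:(i + 1) * length] for i in range(n)])


@pytest.fixture(scope="session")
def small_telomere_readset():
    """46 ends x 1 kbp pure-canonical sample at 5x, error-free."""
    prof = TelomereProfile(n_ends=46, end_lengths=1000.0, variant_mix={})
    params = SequencingParams(read_length=100, genome_coverage=5.0,
                              substitution_error_rate=0.0,
                              background_genome_length=50_000, seed=23)
    return simulate_telomere_readset(prof, params)


@pytest.fixture(scope="session")
def spiked_telomere_readset():
    """92 ends x 2 kbp with 10% TGAGGG and 5% TTAGGGG variant units."""
    prof = TelomereProfile(n_ends=92, end_lengths=2000.0,
                           variant_mix={"TGAGGG": 0.10, "TTAGGGG": 0.05})
    params = SequencingParams(read_length=120, genome_coverage=10.0,
                              substitution_error_rate=0.001,
                              background_genome_length=150_000, seed=11)
    return simulate_telomere_readset(prof, params)


@pytest.fixture(scope="session")
def null_count_matrix():
    """No planted fold changes: 500 genes, 10 vs 10 samples."""
    design = ExpressionDesign(n_genes=500,
                              group_sizes={"reference": 10, "tumor": 10},
                              nb_dispersion=0.05, seed=5)
    counts, groups, truth = simulate_count_matrix(design)
    return CountMatrix(counts, groups, "reference"), truth
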