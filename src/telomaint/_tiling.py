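"""Vectorized repeat-unit tiling of sequencing reads.

The engine behind telomeric read classification and repeat-variant
decomposition.  Reads are scanned on both strands for the best *contiguous
run* of repeat units drawn from the edit-distance-1 neighbourhood of a
repeat pattern (canonical hexamer ``TTAGGG`` by default): k-mers within a
mismatch budget of any rotation of the pattern, plus exact rotations of its
single-base insertion and deletion variants.  Telomeric tracts are tandem
arrays, so a gapless run is the right model; a gapped (coverage-maximizing)
tiling would happily absorb random sequence near tract boundaries.

Runs are scored ``bases - 3 x edits`` (an exact canonical unit costs 0
edits, any variant or mismatched unit costs 1).  The penalty of 3 makes the
parser prefer an exact segmentation over re-segmenting leftovers with
spurious indel units (which would trade 2 edits for <= 4 bases) while still
accepting genuine variant units (5-7 bases for 1 edit).  Partial units cut
by the read boundary are matched exactly against cyclic substrings of the
canonical pattern and extend a run at zero cost, so fully telomeric reads
are counted base-exactly.

Everything operates on batches of equal-length reads encoded as uint8
matrices (A=0, C=1, G=2, T=3, other=4) so that unit membership reduces to
integer table lookups and the dynamic program loops only over read
positions, not reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

_BASES = "ACGT"
BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    BASE_CODE[ord(_b)] = _i
    BASE_CODE[ord(_b.lower())] = _i

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

EDIT_PENALTY = 3     # score = bases - EDIT_PENALTY * edits per unit
EDGE_MARGIN = 5      # runs within this many bases of a read edge are edge-anchored


def encode(seqs: list[str]) -> np.ndarray:
    """Encode equal-length sequences as an (n, L) uint8 matrix."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    L = len(seqs[0])
    buf = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return BASE_CODE[buf].reshape(len(seqs), L)


def revcomp_matrix(mat: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[mat[:, ::-1]]


def _rotations(s: str) -> list[str]:
    return [s[r:] + s[:r] for r in range(len(s))]


def _rotate_back(s: str, r: int) -> str:
    n = len(s)
    return s[n - r:] + s[:n - r]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _seq_to_int(s: str) -> int:
    v = 0
    for ch in s:
        v = v * 4 + _BASES.index(ch)
    return v


def _int_to_seq(code: int, k: int) -> str:
    s = ""
    for _ in range(k):
        s = _BASES[code % 4] + s
        code //= 4
    return s


@dataclass(frozen=True)
class UnitTables:
    """Lookup tables mapping k-mer integer codes to repeat-variant ids."""

    pattern: str
    max_mismatch: int
    vocab: tuple[str, ...]                       # variant names, canonical first
    tables: dict[int, np.ndarray] = field(compare=False)   # k -> int16[4**k] variant id or -1
    costs: dict[int, np.ndarray] = field(compare=False)    # k -> int16[4**k] edit count
    partials: dict[str, dict[int, np.ndarray]] = field(compare=False)  # edge partial-unit tables

    @property
    def k(self) -> int:
        return len(self.pattern)

    def variant_id(self, name: str) -> int:
        return self.vocab.index(name)


def _deletion_variants(pattern: str) -> list[str]:
    return sorted({pattern[:i] + pattern[i + 1:] for i in range(len(pattern))})


def _insertion_variants(pattern: str) -> list[str]:
    out = set()
    for i in range(len(pattern) + 1):
        for b in _BASES:
            out.add(pattern[:i] + b + pattern[i:])
    return sorted(out)


def _substitution_variants(pattern: str) -> list[str]:
    out = set()
    for i in range(len(pattern)):
        for b in _BASES:
            if b != pattern[i]:
                out.add(pattern[:i] + b + pattern[i + 1:])
    return sorted(out)


@lru_cache(maxsize=8)
def build_unit_tables(pattern: str = "TTAGGG", max_mismatch: int = 1) -> UnitTables:
    """Build variant vocabulary and k-mer lookup tables for a repeat pattern.

    Units are matched in the canonical frame: a complete unit inside a
    tandem tract always appears unrotated, and a read starting mid-unit
    simply begins with a *partial* unit (a proper suffix of the pattern),
    handled by the edge-partial tables.  The vocabulary is the canonical
    pattern plus its edit-distance-1 neighbours: substitutions anywhere
    (k-mers at hamming distance 1), exact single-base deletions (e.g.
    TAGGG, TTAGG, TTGGG) and exact single-base insertions (e.g. TTAGGGG,
    TTAAGGG).  k-mers at hamming distance 2..max_mismatch are accepted as
    degraded canonical units, not as named variants.
    """
    pattern = pattern.upper()
    if not pattern or any(c not in _BASES for c in pattern):
        raise ValueError(f"pattern must be a non-empty ACGT string, got {pattern!r}")
    k = len(pattern)
    if k > 8:
        raise ValueError("repeat unit longer than 8 bp is not supported")

    subs = _substitution_variants(pattern)
    dels = _deletion_variants(pattern) if k >= 2 else []
    ins = _insertion_variants(pattern)
    vocab = tuple([pattern] + subs + dels + ins)
    vid = {name: i for i, name in enumerate(vocab)}

    table_k = np.full(4 ** k, -1, dtype=np.int16)
    cost_k = np.zeros(4 ** k, dtype=np.int16)
    for code in range(4 ** k):
        s = _int_to_seq(code, k)
        d = _hamming(s, pattern)
        if d <= max_mismatch:
            table_k[code] = vid[s] if d == 1 else 0
            cost_k[code] = d

    def _exact_table(variants: list[str], length: int) -> tuple[np.ndarray, np.ndarray]:
        tab = np.full(4 ** length, -1, dtype=np.int16)
        for name in variants:
            tab[_seq_to_int(name)] = vid[name]
        return tab, np.ones(4 ** length, dtype=np.int16)

    tables = {k: table_k}
    costs = {k: cost_k}
    if dels:
        tables[k - 1], costs[k - 1] = _exact_table(dels, k - 1)
    tables[k + 1], costs[k + 1] = _exact_table(ins, k + 1)

    # read-edge partial units: a run may begin with a proper suffix of the
    # pattern and end with a proper prefix, matched exactly
    start_partials, end_partials = {}, {}
    for m in range(1, min(k, EDGE_MARGIN + 1)):
        s_tab = np.zeros(4 ** m, dtype=bool)
        s_tab[_seq_to_int(pattern[k - m:])] = True
        e_tab = np.zeros(4 ** m, dtype=bool)
        e_tab[_seq_to_int(pattern[:m])] = True
        start_partials[m] = s_tab
        end_partials[m] = e_tab
    return UnitTables(pattern=pattern, max_mismatch=max_mismatch, vocab=vocab,
                      tables=tables, costs=costs,
                      partials={"start": start_partials, "end": end_partials})


@dataclass
class RunTiling:
    """Best contiguous repeat-unit runs for a batch of reads, one strand."""

    L: int
    best_bases: np.ndarray      # (n,) bases of the best run anywhere in the read
    anch_bases: np.ndarray      # (n,) bases of the best edge-anchored run
    anch_start: np.ndarray      # (n,) start of that run (before start-partial)
    anch_end: np.ndarray        # (n,) end of that run (before end-partial)
    anch_ext: np.ndarray        # (n,) end-partial bases appended at the read edge
    choices: np.ndarray | None  # (n, L+1) int8 backtrack (unit length, 0 at run start)
    ids: dict[int, np.ndarray]  # unit length -> (n, L-k+1) variant id or -1
    starts: np.ndarray          # (n, L+1) run start per end position


def _window_ids(codes, valid, k, table, cost):
    n, L = codes.shape
    if L < k:
        e = np.full((n, 0), -1, dtype=np.int16)
        return e, e.copy()
    w = L - k + 1
    code = np.zeros((n, w), dtype=np.int64)
    okall = np.ones((n, w), dtype=bool)
    for j in range(k):
        code = code * 4 + np.where(valid[:, j:j + w], codes[:, j:j + w], 0)
        okall &= valid[:, j:j + w]
    ids = table[code]
    ids[~okall] = -1
    return ids, cost[code]


def tile_batch(mat: np.ndarray, tables: UnitTables, want_choices: bool = True) -> RunTiling:
    """Find the best contiguous repeat-unit run per read on one strand."""
    n, L = mat.shape
    valid = mat < 4
    unit_lengths = sorted(tables.tables)
    ids, cost = {}, {}
    for k in unit_lengths:
        ids[k], cost[k] = _window_ids(mat, valid, k, tables.tables[k], tables.costs[k])
    ok = {k: ids[k] >= 0 for k in unit_lengths}
    # deterministic tie-break order: native unit length first
    order = [tables.k] + [k for k in unit_lengths if k != tables.k]
    # per-unit score, floored at 1 so a unit never reads as "no run"
    uscore = {k: np.maximum(k - EDIT_PENALTY * cost[k], 1).astype(np.int32)
              for k in unit_lengths}

    NEG = np.int32(-1)
    E = np.full((n, L + 1), NEG, dtype=np.int32)     # best run score ending at i
    S = np.zeros((n, L + 1), dtype=np.int32)         # its start position
    choices = np.zeros((n, L + 1), dtype=np.int8) if want_choices else None

    for i in range(1, L + 1):
        best = np.full(n, NEG, dtype=np.int32)
        bstart = np.zeros(n, dtype=np.int32)
        bch = np.zeros(n, dtype=np.int8)
        for k in order:
            if i >= k and ids[k].shape[1] > i - k:
                o = ok[k][:, i - k]
                prevE = E[:, i - k]
                ext = prevE > 0
                cand = np.where(ext, prevE, 0) + uscore[k][:, i - k]
                cand = np.where(o, cand, NEG)
                sstart = np.where(ext, S[:, i - k], i - k)
                take = cand > best
                best = np.where(take, cand, best)
                bstart = np.where(take, sstart, bstart)
                if want_choices:
                    bch = np.where(take, np.int8(k), bch)
        if i <= EDGE_MARGIN and i in tables.partials["start"]:
            # partial unit cut by the read start (pattern suffix), exact
            pc = np.zeros(n, dtype=np.int64)
            for j in range(i):
                pc = pc * 4 + np.where(valid[:, j], mat[:, j], 0)
            pok = tables.partials["start"][i][pc] & valid[:, :i].all(axis=1)
            cand = np.where(pok, np.int32(i), NEG)
            take = cand > best
            best = np.where(take, cand, best)
            bstart = np.where(take, 0, bstart)
            if want_choices:
                bch = np.where(take, np.int8(0), bch)
        E[:, i] = best
        S[:, i] = bstart
        if want_choices:
            choices[:, i] = bch

    # end-partial extension at the read edge (pattern prefix), exact
    ext = np.zeros((n, L + 1), dtype=np.int32)
    for m in range(1, min(EDGE_MARGIN, L, tables.k - 1) + 1):
        if m not in tables.partials["end"]:
            continue
        i = L - m
        pc = np.zeros(n, dtype=np.int64)
        for j in range(m):
            pc = pc * 4 + np.where(valid[:, i + j], mat[:, i + j], 0)
        pok = tables.partials["end"][m][pc] & valid[:, i:].all(axis=1) & (E[:, i] > 0)
        ext[:, i] = np.where(pok, np.int32(m), 0)

    Epos = np.where(E > 0, E + ext, 0)
    bases = np.where(E > 0, (np.arange(L + 1)[None, :] - S) + ext, 0)

    best_idx = Epos.argmax(axis=1)
    rows = np.arange(n)
    best_bases = bases[rows, best_idx]

    anchored = (S <= EDGE_MARGIN) | (np.arange(L + 1)[None, :] >= L - EDGE_MARGIN)
    Eanch = np.where(anchored, Epos, 0)
    anch_idx = Eanch.argmax(axis=1)
    anch_bases = np.where(Eanch[rows, anch_idx] > 0, bases[rows, anch_idx], 0)

    return RunTiling(L=L, best_bases=best_bases.astype(np.int64),
                     anch_bases=anch_bases.astype(np.int64),
                     anch_start=S[rows, anch_idx].astype(np.int64),
                     anch_end=anch_idx.astype(np.int64),
                     anch_ext=ext[rows, anch_idx].astype(np.int64),
                     choices=choices, ids=ids, starts=S)


def backtrack_run(rt: RunTiling, i_read: int) -> tuple[list[tuple[int, int]], int]:
    """Units (variant_id, length) of the anchored run of one read, innermost
    first from the run end, plus the number of exact partial-canonical bases
    (read-edge cut units and start partial)."""
    if rt.choices is None:
        raise ValueError("tiling was computed without backtrack bookkeeping")
    units = []
    partial = int(rt.anch_ext[i_read])
    j = int(rt.anch_end[i_read])
    s = int(rt.anch_start[i_read])
    while j > s:
        k = int(rt.choices[i_read, j])
        if k == 0:       # start partial: bases [s, j) matched a cyclic substring
            partial += j - s
            break
        units.append((int(rt.ids[k][i_read, j - k]), k))
        j -= k
    return units, partial
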