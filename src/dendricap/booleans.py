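"""Positive Boolean functions: representation, enumeration, and separability.

A Boolean function of ``n`` binary variables is stored as a truth table
packed into a single integer: bit ``k`` (least-significant bit first) holds
the output for the input whose binary encoding is ``k``, where bit ``j - 1``
of ``k`` is the value of variable ``x_j``.  This convention is shared by all
modules and by the serialization layer.

The module provides:

* monotonicity (positivity) testing and the recursive pair construction that
  enumerates every positive function of ``n`` variables exactly once;
* canonical representatives under permutation of the input variables
  (NP-equivalence classes), with batch canonicalization for large sweeps;
* independent class/function counting via order-ideal recursion and
  Burnside's lemma, used as a cross-check on the enumeration route;
* an exact linear-separability decision with integer witnesses;
* complete positive DNF/CNF extraction (prime implicants and prime clauses)
  and duality.
"""

from __future__ import annotations

import heapq
import os
import tempfile
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from math import factorial
from typing import Iterator, Optional, Sequence

import numpy as np

MAX_VARS = 7

__all__ = [
    "BooleanFunction",
    "Term",
    "Clause",
    "NormalForm",
    "SeparabilityWitness",
    "inputs_matrix",
    "is_positive",
    "canonical_representative",
    "canonical_table",
    "canonicalize_tables",
    "generate_positive_functions",
    "representatives",
    "count_positive_functions",
    "count_positive_functions_ideals",
    "count_positive_classes",
    "is_linearly_separable",
    "prime_implicants",
    "prime_clauses",
    "reconstruct",
    "dual",
    "fbp_family",
    "and_function",
    "or_function",
    "nand2",
    "xor2",
]


# --------------------------------------------------------------------------
# Truth-table representation
# --------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class BooleanFunction:
    """A Boolean function of ``n_vars`` variables as a packed truth table.

    Parameters
    ----------
    n_vars : int
        Number of input variables, between 1 and 7.
    table : int
        Packed truth table; bit ``k`` is the output for input index ``k``.
    """

    n_vars: int
    table: int

    def __post_init__(self) -> None:
        if not 1 <= self.n_vars <= MAX_VARS:
            raise ValueError(f"n_vars must be in 1..{MAX_VARS}, got {self.n_vars}")
        if not 0 <= self.table < (1 << (1 << self.n_vars)):
            raise ValueError("table does not fit in 2**n_vars bits")

    @property
    def n_points(self) -> int:
        return 1 << self.n_vars

    @classmethod
    def from_bits(cls, bits: Sequence[int]) -> "BooleanFunction":
        """Build from an explicit output sequence ``[f(0), f(1), ...]``."""
        n = (len(bits) - 1).bit_length()
        if len(bits) != 1 << n:
            raise ValueError("truth table length must be a power of two")
        table = 0
        for k, b in enumerate(bits):
            if b not in (0, 1, False, True):
                raise ValueError("table entries must be 0/1")
            table |= int(b) << k
        return cls(n, table)

    @classmethod
    def from_hex(cls, n_vars: int, table_hex: str) -> "BooleanFunction":
        return cls(n_vars, int(table_hex, 16))

    def to_hex(self) -> str:
        return format(self.table, "x")

    def bits(self) -> np.ndarray:
        """Truth table as a uint8 vector of length ``2**n_vars``."""
        ks = np.arange(self.n_points, dtype=np.int64)
        return np.array(
            [(self.table >> int(k)) & 1 for k in ks], dtype=np.uint8
        )

    def evaluate(self, x: Sequence[int]) -> int:
        """Evaluate on a binary input vector (``x[j]`` is variable ``x_{j+1}``)."""
        if len(x) != self.n_vars:
            raise ValueError(
                f"input length {len(x)} != n_vars {self.n_vars}"
            )
        k = 0
        for j, v in enumerate(x):
            if v not in (0, 1, False, True):
                raise ValueError("inputs must be binary")
            k |= int(v) << j
        return (self.table >> k) & 1

    __call__ = evaluate


@dataclass(frozen=True)
class Term:
    """A positive term (conjunction) over 1-based variable indices."""

    variables: frozenset

    def __post_init__(self) -> None:
        if not self.variables:
            raise ValueError("a term must reference at least one variable")
        if any(v < 1 for v in self.variables):
            raise ValueError("variable indices are 1-based")


@dataclass(frozen=True)
class Clause:
    """A positive clause (disjunction) over 1-based variable indices."""

    variables: frozenset

    def __post_init__(self) -> None:
        if not self.variables:
            raise ValueError("a clause must reference at least one variable")
        if any(v < 1 for v in self.variables):
            raise ValueError("variable indices are 1-based")


@dataclass(frozen=True)
class NormalForm:
    """A complete positive DNF or CNF: pairwise non-implying prime parts."""

    kind: str  # "DNF" | "CNF"
    parts: tuple

    def __post_init__(self) -> None:
        if self.kind not in ("DNF", "CNF"):
            raise ValueError("kind must be 'DNF' or 'CNF'")
        sets = [p.variables for p in self.parts]
        for i, a in enumerate(sets):
            for b in sets[i + 1:]:
                if a <= b or b <= a:
                    raise ValueError("normal-form parts must be pairwise non-implying")


@dataclass(frozen=True)
class SeparabilityWitness:
    """Non-negative integer weights and threshold realizing a function."""

    weights: tuple
    threshold: int


# --------------------------------------------------------------------------
# Shared index machinery
# --------------------------------------------------------------------------

@lru_cache(maxsize=None)
def inputs_matrix(n: int) -> np.ndarray:
    """All ``2**n`` binary input vectors as an ``(2**n, n)`` int64 matrix."""
    ks = np.arange(1 << n, dtype=np.int64)
    return ((ks[:, None] >> np.arange(n)) & 1).astype(np.int64)


@lru_cache(maxsize=None)
def _low_masks(n: int) -> tuple:
    """For each variable j: packed mask of input indices with bit j clear."""
    masks = []
    for j in range(n):
        m = 0
        for k in range(1 << n):
            if not (k >> j) & 1:
                m |= 1 << k
        masks.append(m)
    return tuple(masks)


@lru_cache(maxsize=None)
def _perm_maps(n: int) -> np.ndarray:
    """Index maps for all variable permutations, shape ``(n!, 2**n)``.

    Row ``p`` holds sigma such that the relabelled table is
    ``new[k] = old[sigma[k]]``.
    """
    ks = np.arange(1 << n, dtype=np.int64)
    bit = [(ks >> j) & 1 for j in range(n)]
    rows = []
    for p in permutations(range(n)):
        sigma = np.zeros(1 << n, dtype=np.int64)
        for j in range(n):
            sigma |= bit[j] << p[j]
        rows.append(sigma)
    return np.array(rows)


def _pow2(n_points: int) -> np.ndarray:
    return np.uint64(1) << np.arange(n_points, dtype=np.uint64)


# --------------------------------------------------------------------------
# Positivity and canonical representatives
# --------------------------------------------------------------------------

def is_positive(f: BooleanFunction) -> bool:
    """True iff the function is monotone non-decreasing in every variable.

    Uses the pairing of each input index ``k`` (variable j clear) with
    ``k + 2**j`` (variable j set): positivity fails exactly when some pair
    has output 1 at the lower point and 0 at the upper point.
    """
    t = f.table
    for j, mask0 in enumerate(_low_masks(f.n_vars)):
        if (t & mask0) & ~(t >> (1 << j)) & mask0:
            return False
    return True


def canonical_table(table: int, n: int) -> int:
    """Lexicographically smallest packed table over all variable relabellings."""
    if n > 6:
        return _canonical_table_bigint(table, n)
    bits = np.array([(table >> k) & 1 for k in range(1 << n)], dtype=np.uint8)
    cands = bits[_perm_maps(n)].astype(np.uint64)
    return int((cands * _pow2(1 << n)).sum(axis=1).min())


def _canonical_table_bigint(table: int, n: int) -> int:
    # 2**n exceeds 64 bits: fall back to per-permutation Python integers.
    bits = np.array([(table >> k) & 1 for k in range(1 << n)], dtype=np.uint8)
    best = None
    for sigma in _perm_maps(n):
        packed = np.packbits(bits[sigma], bitorder="little").tobytes()
        val = int.from_bytes(packed, "little")
        if best is None or val < best:
            best = val
    return best


def canonical_representative(f: BooleanFunction) -> BooleanFunction:
    """Canonical member of the permutation-equivalence class of ``f``."""
    return BooleanFunction(f.n_vars, canonical_table(f.table, f.n_vars))


def canonicalize_tables(tables: np.ndarray, n: int, chunk: int = 512) -> np.ndarray:
    """Canonicalize an array of packed tables (uint64, ``n <= 6``) in chunks."""
    if n > 6:
        return np.array(
            [_canonical_table_bigint(int(t), n) for t in tables], dtype=object
        )
    tables = np.asarray(tables, dtype=np.uint64)
    pmaps = _perm_maps(n)
    pow2 = _pow2(1 << n)
    shifts = np.arange(1 << n, dtype=np.uint64)
    out = np.empty(len(tables), dtype=np.uint64)
    for lo in range(0, len(tables), chunk):
        batch = tables[lo:lo + chunk]
        bits = ((batch[:, None] >> shifts) & np.uint64(1)).astype(np.uint8)
        cands = bits[:, pmaps].astype(np.uint64)  # (m, n!, 2**n)
        out[lo:lo + chunk] = (cands * pow2).sum(axis=2).min(axis=1)
    return out


# --------------------------------------------------------------------------
# Enumeration of positive functions
# --------------------------------------------------------------------------

def _monotone_tables(n: int) -> list:
    """All packed tables of positive functions of ``n`` variables (n <= 6)."""
    if n == 0:
        return [0, 1]
    prev = _monotone_tables(n - 1)
    half = 1 << (n - 1)
    arr = np.array(prev, dtype=np.uint64)
    out = []
    for t1 in prev:
        # f = f0 or (x_n and f1) with f0 <= f1; then the upper half is f1.
        subs = arr[(arr & ~np.uint64(t1)) == 0]
        out.extend(int(t0) | (t1 << half) for t0 in subs)
    return out


def generate_positive_functions(n: int) -> Iterator[BooleanFunction]:
    """Yield every positive function of ``n`` variables exactly once.

    A positive function ``f`` of ``n`` variables decomposes uniquely as
    ``f = f0 or (x_n and f1)`` where ``f0 <= f1`` pointwise are positive
    functions of ``n - 1`` variables (``f0`` and ``f1`` are the restrictions
    at ``x_n = 0`` and ``x_n = 1``).  Enumerating the ordered subset pairs is
    therefore a bijection onto the positive functions of ``n`` variables: no
    duplicates are ever produced and no deduplication pass is needed.

    The output is a stream; only the level ``n - 1`` list is materialized.
    """
    if not 1 <= n <= MAX_VARS:
        raise ValueError(f"n must be in 1..{MAX_VARS}, got {n}")
    prev = _monotone_tables(n - 1)
    half = 1 << (n - 1)
    arr = np.array(prev, dtype=np.uint64)
    for t1 in prev:
        for t0 in arr[(arr & ~np.uint64(t1)) == 0]:
            yield BooleanFunction(n, int(t0) | (t1 << half))


def count_positive_functions(n: int) -> int:
    """Number of positive functions of ``n`` variables via subset-pair counting.

    Counts the ordered pairs ``f0 <= f1`` of positive functions of ``n - 1``
    variables without materializing the level-``n`` list.  Supported for
    ``n <= 6`` (the level-6 count already requires the 7.8M-entry level-6
    list for ``n = 7``, whose pair count is out of reach here).
    """
    if not 1 <= n <= 6:
        raise ValueError("supported for n in 1..6")
    prev = np.array(_monotone_tables(n - 1), dtype=np.uint64)
    total = 0
    for lo in range(0, len(prev), 4096):
        block = prev[lo:lo + 4096]
        total += int(((block[:, None] & ~prev[None, :]) == 0).sum())
    return total


# --------------------------------------------------------------------------
# Independent counting: order-ideal recursion and Burnside's lemma
# --------------------------------------------------------------------------

def _count_downsets(rel_up: list, rel_down: list, elems: int, memo: dict) -> int:
    """Count downsets of a poset given up-set/down-set bitmasks per element.

    Classic divide on a pivot element x: downsets not containing x are the
    downsets of P minus up(x); downsets containing x contain down(x) and are
    otherwise free on P minus down(x).
    """
    if elems == 0:
        return 1
    cached = memo.get(elems)
    if cached is not None:
        return cached
    best, pivot = -1, -1
    m = elems
    while m:
        i = (m & -m).bit_length() - 1
        m &= m - 1
        span = bin(rel_up[i] & elems).count("1") + bin(rel_down[i] & elems).count("1")
        if span > best:
            best, pivot = span, i
    result = _count_downsets(rel_up, rel_down, elems & ~rel_up[pivot], memo) + \
        _count_downsets(rel_up, rel_down, elems & ~rel_down[pivot], memo)
    memo[elems] = result
    return result


def count_positive_functions_ideals(n: int) -> int:
    """Number of positive functions of ``n <= 6`` variables, counted as the
    order ideals of the Boolean lattice -- an algorithm independent of the
    pair-construction enumerator, used to cross-check it."""
    if not 1 <= n <= 6:
        raise ValueError("supported for n in 1..6")
    N = 1 << n
    rel_up = [0] * N
    rel_down = [0] * N
    for a in range(N):
        for b in range(N):
            if a & b == a:
                rel_up[a] |= 1 << b
                rel_down[b] |= 1 << a
    return _count_downsets(rel_up, rel_down, (1 << N) - 1, {})


def _apply_bit_perm(k: int, p: tuple, n: int) -> int:
    out = 0
    for j in range(n):
        if (k >> j) & 1:
            out |= 1 << p[j]
    return out


def _fixed_monotone_count(p: tuple, n: int) -> int:
    """Positive functions invariant under the variable permutation ``p``.

    These are in bijection with the downsets of the quotient poset of input
    orbits under the cyclic group generated by ``p`` (the order descends to
    the quotient because bit permutations preserve popcount).
    """
    N = 1 << n
    orbit_of = [-1] * N
    reps = []
    for k in range(N):
        if orbit_of[k] < 0:
            o = len(reps)
            cur = k
            while orbit_of[cur] < 0:
                orbit_of[cur] = o
                cur = _apply_bit_perm(cur, p, n)
            reps.append(k)
    no = len(reps)
    rel_up = [0] * no
    rel_down = [0] * no
    for A, a in enumerate(reps):
        for b in range(N):
            if a & b == a:
                B = orbit_of[b]
                rel_up[A] |= 1 << B
                rel_down[B] |= 1 << A
    return _count_downsets(rel_up, rel_down, (1 << no) - 1, {})


def count_positive_classes(n: int) -> int:
    """Number of permutation-equivalence classes of positive functions.

    Burnside's lemma over the symmetric group acting on variable labels:
    the class count is the average, over all permutations, of the number of
    positive functions each permutation fixes.  Fixed counts depend only on
    the cycle type, so one quotient-poset ideal count per cycle type
    suffices.  Supported for ``n <= 6``; at ``n = 7`` the ideal-count memo
    for the 128-point lattice exceeds practical memory.
    """
    if not 1 <= n <= 6:
        raise ValueError("supported for n in 1..6")
    total = 0
    by_type: dict = {}
    for p in permutations(range(n)):
        ct = []
        seen = [False] * n
        for i in range(n):
            if not seen[i]:
                c, j = 0, i
                while not seen[j]:
                    seen[j] = True
                    j = p[j]
                    c += 1
                ct.append(c)
        key = tuple(sorted(ct))
        if key not in by_type:
            by_type[key] = _fixed_monotone_count(p, n)
        total += by_type[key]
    return total // factorial(n)


# --------------------------------------------------------------------------
# Representatives (canonical classes)
# --------------------------------------------------------------------------

def representatives(
    n: int,
    shard_dir: Optional[str] = None,
    shard_limit: int = 1 << 22,
) -> list:
    """Canonical representatives of all positive functions of ``n`` variables.

    Returns a sorted list of :class:`BooleanFunction`, one per
    NP-equivalence class.  For ``n <= 5`` the canonical tables are collected
    in memory.  For larger ``n`` (or when ``shard_dir`` is given) canonical
    tables are flushed to sorted on-disk shards every ``shard_limit``
    entries and merged at the end, so the non-canonical stream is never
    materialized at once.  ``n = 6`` takes tens of minutes; ``n = 7``
    (490,013,148 classes) is supported by the same streaming path but runs
    far beyond an interactive session.
    """
    if not 1 <= n <= MAX_VARS:
        raise ValueError(f"n must be in 1..{MAX_VARS}, got {n}")
    use_shards = shard_dir is not None or n >= 6
    if not use_shards:
        tables = np.array(
            [f.table for f in generate_positive_functions(n)], dtype=np.uint64
        )
        canon = np.unique(canonicalize_tables(tables, n))
        return [BooleanFunction(n, int(t)) for t in canon]

    tmp_ctx = None
    if shard_dir is None:
        tmp_ctx = tempfile.TemporaryDirectory(prefix="dendricap_reps_")
        shard_dir = tmp_ctx.name
    os.makedirs(shard_dir, exist_ok=True)
    shards: list = []
    buf: set = set()
    try:
        batch: list = []
        for f in generate_positive_functions(n):
            batch.append(f.table)
            if len(batch) == 8192:
                buf.update(canonicalize_tables(np.array(batch, np.uint64), n).tolist())
                batch = []
                if len(buf) >= shard_limit:
                    shards.append(_flush_shard(shard_dir, len(shards), buf))
                    buf = set()
        if batch:
            buf.update(canonicalize_tables(np.array(batch, np.uint64), n).tolist())
        if buf:
            shards.append(_flush_shard(shard_dir, len(shards), buf))
        merged = _merge_shards(shards)
        return [BooleanFunction(n, int(t)) for t in merged]
    finally:
        if tmp_ctx is not None:
            tmp_ctx.cleanup()


def _flush_shard(shard_dir: str, idx: int, buf: set) -> str:
    path = os.path.join(shard_dir, f"shard_{idx:04d}.npy")
    np.save(path, np.array(sorted(buf), dtype=np.uint64))
    return path


def _merge_shards(paths: list) -> np.ndarray:
    arrays = [np.load(p) for p in paths]
    if len(arrays) == 1:
        return arrays[0]
    merged = np.fromiter(
        heapq.merge(*[a.tolist() for a in arrays]), dtype=np.uint64
    )
    return np.unique(merged)


# --------------------------------------------------------------------------
# Linear separability
# --------------------------------------------------------------------------

# Sufficient maximal integer weights for threshold functions of n variables
# (Muroga's bounds; the n = 4..6 rows match the published linear-model
# search ranges).  Any separable function of n variables has an integer
# realization with weights within these bounds, so the grid decision below
# is exact.
_SUFFICIENT_W_MAX = {1: 1, 2: 2, 3: 2, 4: 3, 5: 5, 6: 9}


def is_linearly_separable(f: BooleanFunction, return_witness: bool = False):
    """Exact linear-separability decision, optionally with an integer witness.

    A function is linearly separable iff there are non-negative weights
    ``w`` and a threshold ``Theta`` with ``w . x >= Theta`` exactly on the
    true inputs.  Because inputs and weights are integers, separation with
    margin 1 (``w . x <= Theta - 1`` on false inputs) loses no generality,
    and it suffices to scan weights up to a bound proven sufficient for each
    ``n <= 6``.  For a given weight vector the best threshold is simply the
    minimum weighted sum over true inputs, so no threshold grid is needed.

    For ``n = 7`` no practical sufficient grid exists; the decision falls
    back to linear-programming feasibility with exact verification of a
    rationalized witness (see :func:`_separable_lp`).
    """
    n = f.n_vars
    bits = f.bits().astype(bool)
    if bits.all():
        w = SeparabilityWitness((0,) * n, 0)
        return (True, w) if return_witness else True
    if not bits.any():
        w = SeparabilityWitness((0,) * n, 1)
        return (True, w) if return_witness else True
    if n > 6:
        return _separable_lp(f, return_witness)
    X = inputs_matrix(n)
    wmax = _SUFFICIENT_W_MAX[n]
    grid = _weight_grid(n, wmax)
    for lo in range(0, len(grid), 65536):
        W = grid[lo:lo + 65536]
        S = W @ X.T
        mins = S[:, bits].min(axis=1)
        maxs = S[:, ~bits].max(axis=1)
        ok = np.nonzero(mins > maxs)[0]
        if len(ok):
            i = int(ok[0])
            witness = SeparabilityWitness(
                tuple(int(v) for v in W[i]), int(mins[i])
            )
            return (True, witness) if return_witness else True
    return (False, None) if return_witness else False


@lru_cache(maxsize=8)
def _weight_grid(n: int, wmax: int) -> np.ndarray:
    """All weight vectors with entries in 0..wmax, odometer order
    (last variable fastest), shape ``((wmax+1)**n, n)``."""
    ranges = [np.arange(wmax + 1)] * n
    mesh = np.meshgrid(*ranges, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1).astype(np.int64)


def _separable_lp(f: BooleanFunction, return_witness: bool):
    from fractions import Fraction

    from scipy.optimize import linprog

    n = f.n_vars
    X = inputs_matrix(n)
    bits = f.bits().astype(bool)
    A, b = [], []
    for k in range(f.n_points):
        if bits[k]:
            A.append(list(-X[k].astype(float)) + [1.0])
            b.append(0.0)
        else:
            A.append(list(X[k].astype(float)) + [-1.0])
            b.append(-1.0)
    res = linprog(
        [0.0] * (n + 1), A_ub=A, b_ub=b,
        bounds=[(0, None)] * n + [(None, None)], method="highs",
    )
    if res.status != 0:
        return (False, None) if return_witness else False
    if not return_witness:
        return True
    fracs = [Fraction(v).limit_denominator(10_000) for v in res.x]
    den = 1
    for fr in fracs:
        den = den * fr.denominator // _gcd(den, fr.denominator)
    ints = [int(fr * den) for fr in fracs]
    w, theta = ints[:n], ints[n]
    sums = X @ np.array(w)
    theta = int(sums[bits].min())
    if sums[~bits].max() < theta:
        return True, SeparabilityWitness(tuple(max(v, 0) for v in w), theta)
    raise RuntimeError("LP found a separation but no exact integer witness")


def _gcd(a: int, b: int) -> int:
    while b:
        a, b = b, a % b
    return a


# --------------------------------------------------------------------------
# Normal forms and duality
# --------------------------------------------------------------------------

def prime_implicants(f: BooleanFunction) -> NormalForm:
    """Complete positive DNF: one prime term per minimal true input.

    For a positive function the prime implicants are exactly the supports of
    the minimal true points (true inputs all of whose strict subsets are
    false).
    """
    _require_positive_nonconstant(f, forbid="zero")
    terms = []
    for k in range(f.n_points):
        if not (f.table >> k) & 1:
            continue
        minimal = all(
            not (f.table >> (k & ~(1 << j))) & 1
            for j in range(f.n_vars)
            if (k >> j) & 1
        )
        if minimal:
            terms.append(Term(frozenset(
                j + 1 for j in range(f.n_vars) if (k >> j) & 1
            )))
    return NormalForm("DNF", tuple(terms))


def prime_clauses(f: BooleanFunction) -> NormalForm:
    """Complete positive CNF: one prime clause per maximal false input.

    The prime clauses of a positive function are the complements of the
    supports of the maximal false points.
    """
    _require_positive_nonconstant(f, forbid="one")
    full = f.n_points - 1
    clauses = []
    for k in range(f.n_points):
        if (f.table >> k) & 1:
            continue
        maximal = all(
            (f.table >> (k | (1 << j))) & 1
            for j in range(f.n_vars)
            if not (k >> j) & 1
        )
        if maximal:
            comp = full ^ k
            clauses.append(Clause(frozenset(
                j + 1 for j in range(f.n_vars) if (comp >> j) & 1
            )))
    return NormalForm("CNF", tuple(clauses))


def _require_positive_nonconstant(f: BooleanFunction, forbid: str) -> None:
    if not is_positive(f):
        raise ValueError("normal forms are defined here for positive functions only")
    if forbid == "zero" and f.table == 0:
        raise ValueError("the constant-0 function has no positive DNF")
    if forbid == "one" and f.table == (1 << f.n_points) - 1:
        raise ValueError("the constant-1 function has no positive CNF")


def reconstruct(nf: NormalForm, n_vars: int) -> BooleanFunction:
    """Rebuild the truth table from a positive DNF or CNF."""
    table = 0
    for k in range(1 << n_vars):
        on = {j + 1 for j in range(n_vars) if (k >> j) & 1}
        if nf.kind == "DNF":
            val = any(p.variables <= on for p in nf.parts)
        else:
            val = all(p.variables & on for p in nf.parts)
        table |= int(val) << k
    return BooleanFunction(n_vars, table)


def dual(f: BooleanFunction) -> BooleanFunction:
    """The dual function ``f^d(x) = not f(not x)`` (an involution)."""
    N = f.n_points
    table = 0
    for k in range(N):
        table |= (1 - ((f.table >> (N - 1 - k)) & 1)) << k
    return BooleanFunction(f.n_vars, table)


# --------------------------------------------------------------------------
# Named functions
# --------------------------------------------------------------------------

def and_function(n: int) -> BooleanFunction:
    """The n-input AND."""
    return BooleanFunction(n, 1 << ((1 << n) - 1))


def or_function(n: int) -> BooleanFunction:
    """The n-input OR."""
    return BooleanFunction(n, ((1 << (1 << n)) - 1) ^ 1)


def nand2() -> BooleanFunction:
    return BooleanFunction(2, 0b0111)


def xor2() -> BooleanFunction:
    return BooleanFunction(2, 0b0110)


def fbp_family() -> dict:
    """The three linearly non-separable positive functions of 4 variables.

    ``fbp``  -- feature binding problem, ``(x1 & x2) | (x3 & x4)``: fires
    only when a disjoint feature pair is fully active.
    ``dfbp`` -- its dual, ``(x1 | x2) & (x3 | x4)``.
    ``pfbp`` -- the overlapping-feature chain,
    ``(x1 & x2) | (x2 & x3) | (x3 & x4)``.
    """
    def build(pred) -> BooleanFunction:
        return BooleanFunction.from_bits([int(pred(k)) for k in range(16)])

    fbp = build(lambda k: (k & 0b0011) == 0b0011 or (k & 0b1100) == 0b1100)
    dfbp = build(lambda k: bool(k & 0b0011) and bool(k & 0b1100))
    pfbp = build(
        lambda k: (k & 0b0011) == 0b0011
        or (k & 0b0110) == 0b0110
        or (k & 0b1100) == 0b1100
    )
    return {"fbp": fbp, "dfbp": dfbp, "pfbp": pfbp}
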