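"""Exhaustive capacity searches over integer parameter grids.

For a model condition -- ``lin`` (purely linear integration), ``spk``
(linear plus one spiking dendritic sub-unit) or ``sat`` (linear plus one
saturating sub-unit) -- the search enumerates every integer parameter set
within the given ranges, computes the resulting Boolean function, and
counts the distinct representative (permutation-canonical) positive
functions.  The published sufficient ranges per condition and input count
are available through :func:`table1_space`.

The enumeration is memoized: all distinct dendritic output vectors over the
``2**n`` inputs are precomputed and deduplicated before being crossed with
the somatic weight/threshold grid.  This is mathematically identical to the
naive product grid (the neuron output depends on the dendritic parameters
only through the output vector) but orders of magnitude faster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .booleans import (
    BooleanFunction,
    canonicalize_tables,
    inputs_matrix,
    is_linearly_separable,
)
from .neuron import (
    Activation,
    Subunit,
    TwoStageNeuron,
    activation_output_vec,
    is_valid_subunit_activation,
    truth_table,
)

logger = logging.getLogger(__name__)

MODEL_KINDS = ("lin", "spk", "sat")
_ACTIVATION_OF = {"spk": "spiking", "sat": "saturating"}

# Published sufficient parameter ranges per input count and condition:
# (w_max_soma, w_max_dend, theta_max, h_max, soma_threshold_max).
_TABLE1 = {
    (4, "lin"): (3, 0, 0, 0, 5),
    (4, "sat"): (2, 2, 2, 2, 4),
    (4, "spk"): (2, 2, 2, 3, 6),
    (5, "lin"): (5, 0, 0, 0, 9),
    (5, "sat"): (3, 3, 3, 4, 8),
    (5, "spk"): (3, 3, 3, 7, 12),
    (6, "lin"): (9, 0, 0, 0, 18),
    (6, "sat"): (4, 4, 8, 12, 20),
    (6, "spk"): (4, 4, 8, 12, 20),
}

# Refuse grids whose memoized dendritic stage would not fit in memory.
_MAX_DEND_GRID = 50_000_000
_MAX_SOMA_GRID = 5_000_000

__all__ = [
    "SearchSpace",
    "CapacityResult",
    "CapacityDiff",
    "table1_space",
    "enumerate_capacity",
    "diff_capacity",
    "capacity_report",
    "range_sufficiency_scan",
]


@dataclass(frozen=True)
class SearchSpace:
    """Integer parameter ranges for one model condition.

    All bounds are inclusive maxima; every parameter starts at 0.  For
    ``model_kind="lin"`` the dendritic fields are ignored.  When
    ``validate_activations`` is set (the default) the nonlinear sub-unit is
    kept only if it operationally matches its family (spiking: supra- and
    sub-linear; saturating: strictly sub-linear; both non-decreasing) on its
    reachable input range; disabling the flag mimics an unfiltered grid.
    """

    n_vars: int
    model_kind: str
    w_max_soma: int
    w_max_dend: int = 0
    theta_max: int = 0
    h_max: int = 0
    soma_threshold_max: int = 0
    validate_activations: bool = True

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        for name in ("w_max_soma", "w_max_dend", "theta_max", "h_max",
                     "soma_threshold_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def table1_space(n: int, model_kind: str, validate_activations: bool = True) -> SearchSpace:
    """The published sufficient search ranges for ``n`` in 4..6."""
    try:
        ws, wd, th, h, T = _TABLE1[(n, model_kind)]
    except KeyError:
        raise ValueError(
            f"no published ranges for n={n}, model={model_kind}"
        ) from None
    return SearchSpace(n, model_kind, ws, wd, th, h, T,
                       validate_activations=validate_activations)


@dataclass
class CapacityResult:
    """Outcome of one exhaustive search.

    ``found`` holds the canonical packed truth tables (sorted); ``witnesses``
    maps each canonical table to the first parameter set encountered, under
    the documented iteration order, that computes a function in its class.
    """

    space: SearchSpace
    found: tuple
    witnesses: dict
    _separable: Optional[int] = field(default=None, repr=False)

    @property
    def n_found(self) -> int:
        return len(self.found)

    @property
    def n_separable(self) -> int:
        if self._separable is None:
            n = self.space.n_vars
            self._separable = sum(
                is_linearly_separable(BooleanFunction(n, int(t)))
                for t in self.found
            )
        return self._separable

    @property
    def n_non_separable(self) -> int:
        return self.n_found - self.n_separable

    def non_separable_tables(self) -> tuple:
        n = self.space.n_vars
        return tuple(
            t for t in self.found
            if not is_linearly_separable(BooleanFunction(n, int(t)))
        )


@dataclass(frozen=True)
class CapacityDiff:
    only_a: frozenset
    only_b: frozenset
    both: frozenset


def _weight_grid(n: int, wmax: int) -> np.ndarray:
    # odometer order: variable n varies fastest
    ranges = [np.arange(wmax + 1)] * n
    mesh = np.meshgrid(*ranges, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1).astype(np.int64)


def _dendritic_patterns(space: SearchSpace) -> tuple:
    """Distinct dendritic output vectors with first-config bookkeeping.

    Iterates (w_dend odometer, theta, h) in order, applies the activation to
    the local sums over all inputs, and deduplicates the resulting output
    vectors.  Returns (Dmat, configs) where ``Dmat[i]`` is the i-th distinct
    vector, in first-appearance order, and ``configs[i]`` the parameters
    that first produced it.
    """
    n = space.n_vars
    X = inputs_matrix(n)
    Wd = _weight_grid(n, space.w_max_dend)
    SD = Wd @ X.T
    kind = _ACTIVATION_OF[space.model_kind]
    patterns: dict = {}
    validity_cache: dict = {}
    total = len(Wd) * (space.theta_max + 1) * (space.h_max + 1)
    done = 0
    for i in range(len(Wd)):
        s_max = int(Wd[i].sum())
        for theta in range(space.theta_max + 1):
            for h in range(space.h_max + 1):
                done += 1
                if done % 1_000_000 == 0:
                    logger.info("dendritic grid: %d / %d", done, total)
                if space.validate_activations:
                    key = (theta, h, s_max)
                    ok = validity_cache.get(key)
                    if ok is None:
                        ok = is_valid_subunit_activation(
                            Activation(kind, theta, h), s_max
                        )
                        validity_cache[key] = ok
                    if not ok:
                        continue
                a = Activation(kind, theta, h)
                vec = tuple(activation_output_vec(a, SD[i]).tolist())
                if vec not in patterns:
                    patterns[vec] = (tuple(int(w) for w in Wd[i]), theta, h)
    Dmat = np.array(list(patterns.keys()), dtype=np.int64)
    configs = list(patterns.values())
    return Dmat, configs


def enumerate_capacity(space: SearchSpace) -> CapacityResult:
    """Enumerate all parameter sets in ``space`` and collect the computable
    representative functions.

    Iteration order for witness selection, soma-major odometer:
    (w_soma odometer, somatic threshold ascending, dendritic pattern in
    (w_dend odometer, theta, h) first-appearance order).  The first
    parameter set that computes a function in a class is kept as that
    class's witness; the result is deterministic given the space.

    Raises ``ValueError`` when the grid is estimated not to fit in memory;
    shrink the weight ranges or the input count in that case.
    """
    n = space.n_vars
    N = 1 << n
    if (space.w_max_soma + 1) ** n > _MAX_SOMA_GRID:
        raise ValueError(
            "somatic weight grid too large to enumerate; reduce w_max_soma or n_vars"
        )
    if space.model_kind != "lin":
        dend_grid = (space.w_max_dend + 1) ** n \
            * (space.theta_max + 1) * (space.h_max + 1)
        if dend_grid > _MAX_DEND_GRID:
            raise ValueError(
                "dendritic grid too large to enumerate; reduce w_max_dend, "
                "theta_max or h_max"
            )
    X = inputs_matrix(n)
    pow2 = np.uint64(1) << np.arange(N, dtype=np.uint64)
    Wsoma = _weight_grid(n, space.w_max_soma)
    SM = Wsoma @ X.T

    if space.model_kind == "lin":
        Dmat = np.zeros((1, N), dtype=np.int64)
        configs = [None]
    else:
        Dmat, configs = _dendritic_patterns(space)
    logger.info(
        "search %s n=%d: %d somatic weight vectors x %d thresholds x %d "
        "dendritic patterns",
        space.model_kind, n, len(Wsoma), space.soma_threshold_max + 1, len(Dmat),
    )

    first_seen: dict = {}  # raw table -> (soma_idx, Theta, dend_idx)
    for i in range(len(Wsoma)):
        S = SM[i][None, :] + Dmat  # (n_patterns, N)
        for Theta in range(space.soma_threshold_max + 1):
            tabs = ((S >= Theta).astype(np.uint64) * pow2).sum(axis=1)
            uniq, idx = np.unique(tabs, return_index=True)
            for t, j in zip(uniq.tolist(), idx.tolist()):
                if t not in first_seen:
                    first_seen[t] = (i, Theta, j)

    raw = np.fromiter(first_seen.keys(), dtype=np.uint64, count=len(first_seen))
    canon = canonicalize_tables(raw, n)
    witnesses: dict = {}
    # first_seen preserves insertion order == iteration priority, so the
    # first raw table mapping to a class provides its witness.
    for rt, ct in zip(raw.tolist(), canon.tolist()):
        if ct in witnesses:
            continue
        i, Theta, j = first_seen[rt]
        witnesses[ct] = _build_witness(space, Wsoma[i], configs[j], Theta)
    found = tuple(sorted(witnesses))
    logger.info("search %s n=%d: %d representative classes found",
                space.model_kind, n, len(found))
    result = CapacityResult(space=space, found=found, witnesses=witnesses)
    _check_witnesses(result)
    return result


def _build_witness(space, wsoma, dend_config, Theta) -> TwoStageNeuron:
    subunits = [Subunit(tuple(int(w) for w in wsoma), Activation("linear"))]
    if dend_config is not None:
        wd, theta, h = dend_config
        subunits.append(
            Subunit(wd, Activation(_ACTIVATION_OF[space.model_kind], theta, h))
        )
    return TwoStageNeuron(space.n_vars, tuple(subunits), int(Theta))


def _check_witnesses(result: CapacityResult) -> None:
    # soundness: every stored witness must reproduce its canonical class
    n = result.space.n_vars
    for ct, neuron in result.witnesses.items():
        t = truth_table(neuron).table
        if int(canonicalize_tables(np.array([t], np.uint64), n)[0]) != ct:
            raise AssertionError(
                "witness does not reproduce its canonical table; "
                "this is a bug in the enumeration"
            )


def diff_capacity(a: CapacityResult, b: CapacityResult) -> CapacityDiff:
    """Exact set algebra on the canonical tables of two searches."""
    if a.space.n_vars != b.space.n_vars:
        raise ValueError("capacity results have different n_vars")
    sa, sb = set(a.found), set(b.found)
    return CapacityDiff(
        only_a=frozenset(sa - sb),
        only_b=frozenset(sb - sa),
        both=frozenset(sa & sb),
    )


def capacity_report(n: int, spaces: dict):
    """Run each condition and tabulate against the full representative count.

    ``spaces`` maps condition names to :class:`SearchSpace`.  Returns a
    pandas DataFrame with one row per condition (classes found, separable,
    non-separable) plus an ``all_representatives`` row giving the total
    number of representative positive functions of ``n`` variables and how
    many of them are separable.
    """
    import pandas as pd

    from .booleans import representatives

    reps = representatives(n)
    n_sep = sum(is_linearly_separable(f) for f in reps)
    rows = [{
        "condition": "all_representatives",
        "classes": len(reps),
        "separable": n_sep,
        "non_separable": len(reps) - n_sep,
    }]
    for name, space in spaces.items():
        res = enumerate_capacity(space)
        rows.append({
            "condition": name,
            "classes": res.n_found,
            "separable": res.n_separable,
            "non_separable": res.n_non_separable,
        })
    return pd.DataFrame(rows)


def range_sufficiency_scan(space: SearchSpace, steps: int = 1) -> bool:
    """True iff enlarging every range bound by ``steps`` leaves the number of
    computable classes unchanged (the published ranges claim this)."""
    base = enumerate_capacity(space)
    if space.model_kind == "lin":
        bigger = replace(
            space,
            w_max_soma=space.w_max_soma + steps,
            soma_threshold_max=space.soma_threshold_max + steps,
        )
    else:
        bigger = replace(
            space,
            w_max_soma=space.w_max_soma + steps,
            w_max_dend=space.w_max_dend + steps,
            theta_max=space.theta_max + steps,
            h_max=space.h_max + steps,
            soma_threshold_max=space.soma_threshold_max + steps,
        )
    enlarged = enumerate_capacity(bigger)
    return enlarged.n_found == base.n_found
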