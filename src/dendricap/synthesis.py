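"""Constructive neuron synthesis and implementation-strategy analysis.

Any positive Boolean function can be implemented by a two-stage neuron in
two canonical ways:

* DNF synthesis -- one spiking sub-unit per prime implicant, somatic
  threshold 1.  Each sub-unit alone can trigger the neuron: a *local*
  strategy.
* CNF synthesis -- one sub-unit (spiking or saturating; they coincide at
  dendritic threshold 1) per prime clause, somatic threshold equal to the
  clause count.  With two or more clauses no single sub-unit can reach the
  somatic threshold: a *global* strategy.

A strictly sub-linear (saturating) unit can never implement a
multi-variable term, so saturating dendrites admit only the global route;
:func:`verify_no_local_sat_fbp` checks this exhaustively for the feature
binding problem on a finite parameter grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from typing import Optional

import numpy as np

from .booleans import (
    BooleanFunction,
    Term,
    fbp_family,
    inputs_matrix,
    prime_clauses,
    prime_implicants,
)
from .neuron import (
    Activation,
    Subunit,
    TwoStageNeuron,
    activation_output,
    activation_output_vec,
    is_valid_subunit_activation,
    subunit_max_output,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StrategyReport",
    "build_dnf_neuron",
    "build_cnf_neuron",
    "classify_strategy",
    "term_implementability",
    "find_fbp_implementations",
    "verify_no_local_sat_fbp",
]


@dataclass(frozen=True)
class StrategyReport:
    """Local/global classification of a neuron's implementation strategy.

    ``local_degree`` counts the nonlinear sub-units whose maximal achievable
    output alone reaches the somatic threshold; the neuron is classified
    ``local`` when at least one can, ``global`` otherwise.  The linear
    (peri-somatic) path is reported separately via ``soma_alone`` because
    the formal local/global definitions speak of dendritic sub-units only,
    while a somatic-path-triggered spike is a distinct phenomenon.
    """

    local_degree: int
    classification: str
    soma_alone: bool
    subunit_max_outputs: tuple


def _indicator(variables: frozenset, n: int) -> tuple:
    return tuple(1 if (j + 1) in variables else 0 for j in range(n))


def build_dnf_neuron(f: BooleanFunction) -> TwoStageNeuron:
    """Implement a positive non-constant function from its complete DNF.

    One spiking sub-unit per prime term T: unit weights are the indicator
    of T, dendritic threshold |T|, height 1; somatic threshold 1.  The
    sub-unit fires exactly when all of T's variables are active, so the
    disjunction over terms is realized with somatic threshold 1.
    """
    nf = prime_implicants(f)
    subunits = tuple(
        Subunit(
            _indicator(t.variables, f.n_vars),
            Activation("spiking", theta=len(t.variables), height=1),
        )
        for t in nf.parts
    )
    return TwoStageNeuron(f.n_vars, subunits, 1)


def build_cnf_neuron(f: BooleanFunction, kind: str = "saturating") -> TwoStageNeuron:
    """Implement a positive non-constant function from its complete CNF.

    One sub-unit of the requested kind per prime clause C: weights are the
    indicator of C, dendritic threshold 1, height 1; somatic threshold =
    number of clauses, so every clause must be satisfied at once.  Spiking
    and saturating activations coincide at dendritic threshold 1, so both
    kinds produce identical truth tables.
    """
    if kind not in ("spiking", "saturating"):
        raise ValueError("kind must be 'spiking' or 'saturating'")
    nf = prime_clauses(f)
    subunits = tuple(
        Subunit(
            _indicator(c.variables, f.n_vars),
            Activation(kind, theta=1, height=1),
        )
        for c in nf.parts
    )
    return TwoStageNeuron(f.n_vars, subunits, len(nf.parts))


def classify_strategy(m: TwoStageNeuron) -> StrategyReport:
    """Count the nonlinear sub-units able to trigger the neuron alone."""
    maxima = tuple(subunit_max_output(su) for su in m.subunits)
    k = sum(
        1
        for su, mx in zip(m.subunits, maxima)
        if su.activation.kind != "linear" and mx >= m.soma_threshold
    )
    soma_alone = any(
        su.activation.kind == "linear" and mx >= m.soma_threshold
        for su, mx in zip(m.subunits, maxima)
    )
    return StrategyReport(
        local_degree=k,
        classification="local" if k >= 1 else "global",
        soma_alone=soma_alone,
        subunit_max_outputs=maxima,
    )


def term_implementability(a: Activation, term: Term, w_max: int,
                          n_vars: Optional[int] = None) -> bool:
    """Whether a single sub-unit with activation ``a`` can compute the term.

    A sub-unit implements a term when its output is zero on every input
    where the term is false and at least 1 on every input where it is true.
    The zero requirement is not cosmetic: inside a DNF neuron all sub-units
    feed the same soma, so a sub-unit whose term is unsatisfied must
    contribute nothing, or partially-activated terms could sum to a false
    positive.  Searches all weight vectors with entries in 0..w_max.

    For a strictly sub-linear activation and a term of two or more
    variables the search must come back empty: vanishing on every
    single-variable input while firing on the full term would make the
    activation super-additive on the weight tuple.
    """
    n = n_vars if n_vars is not None else max(term.variables)
    if max(term.variables) > n:
        raise ValueError("term references a variable beyond n_vars")
    X = inputs_matrix(n)
    want = np.array(
        [all((k >> (v - 1)) & 1 for v in term.variables) for k in range(1 << n)],
        dtype=bool,
    )
    for w in product(range(w_max + 1), repeat=n):
        sums = X @ np.array(w, dtype=np.int64)
        out = activation_output_vec(a, sums)
        if int(out[want].min()) >= 1 and int(out[~want].max()) == 0:
            return True
    return False


def find_fbp_implementations(
    kind: str,
    w_max: int,
    theta_max: int,
    h_max: int,
    soma_threshold_max: int,
    target: Optional[BooleanFunction] = None,
) -> dict:
    """Exhaustive sweep of the linear-plus-one-subunit model for a target.

    Counts, over all validated parameter sets within the bounds, the
    implementations of ``target`` (default: the FBP) classified local
    (dendritic maximum alone reaches the somatic threshold) vs global, and
    keeps the first witness of each, iterating dendritic configurations in
    (weights odometer, theta, h) order and somatic ones in (weights
    odometer, threshold) order.
    """
    if kind not in ("spiking", "saturating"):
        raise ValueError("kind must be 'spiking' or 'saturating'")
    if target is None:
        target = fbp_family()["fbp"]
    n = target.n_vars
    N = 1 << n
    X = inputs_matrix(n)
    pow2 = np.uint64(1) << np.arange(N, dtype=np.uint64)
    Wg = np.array(list(product(range(w_max + 1), repeat=n)), dtype=np.int64)
    SM = Wg @ X.T

    # Deduplicate dendritic configs by (output vector, max output): the
    # target-match and the locality test depend on nothing else.
    dset: dict = {}
    for i in range(len(Wg)):
        s_max = int(Wg[i].sum())
        for theta in range(theta_max + 1):
            for h in range(h_max + 1):
                a = Activation(kind, theta, h)
                if not is_valid_subunit_activation(a, s_max):
                    continue
                d = activation_output_vec(a, SM[i])
                dmax = activation_output(a, s_max)
                key = (tuple(d.tolist()), dmax)
                if key not in dset:
                    dset[key] = (tuple(int(w) for w in Wg[i]), theta, h)

    counts = {"local": 0, "global": 0}
    first: dict = {"local": None, "global": None}
    for (d, dmax), (wd, theta, h) in dset.items():
        S = SM + np.array(d, dtype=np.int64)
        for Theta in range(soma_threshold_max + 1):
            tabs = ((S >= Theta).astype(np.uint64) * pow2).sum(axis=1)
            hits = np.nonzero(tabs == np.uint64(target.table))[0]
            if not len(hits):
                continue
            label = "local" if dmax >= Theta else "global"
            counts[label] += len(hits)
            if first[label] is None:
                first[label] = TwoStageNeuron(
                    n,
                    (
                        Subunit(tuple(int(v) for v in Wg[hits[0]]),
                                Activation("linear")),
                        Subunit(wd, Activation(kind, theta, h)),
                    ),
                    int(Theta),
                )
    logger.info("%s sweep for table %s: %d local, %d global",
                kind, target.to_hex(), counts["local"], counts["global"])
    return {"counts": counts, "first_local": first["local"],
            "first_global": first["global"]}


def verify_no_local_sat_fbp(
    w_max: int, theta_max: int, h_max: int, soma_threshold_max: int
) -> bool:
    """True iff no validated saturating parameter set within the bounds
    implements the FBP with a local strategy (expected for all bounds)."""
    if min(w_max, soma_threshold_max) < 0:
        raise ValueError("bounds must be non-negative")
    if w_max == 0 and theta_max == 0 and h_max == 0 and soma_threshold_max == 0:
        return True  # vacuous: the only neuron is constant
    sweep = find_fbp_implementations(
        "saturating", w_max, theta_max, h_max, soma_threshold_max
    )
    return sweep["counts"]["local"] == 0
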