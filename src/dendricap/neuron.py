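"""Binary two-stage neuron model with nonlinear dendritic sub-units.

Each dendritic sub-unit applies an activation function ``D`` to its local
weighted input sum ``w . x``; the soma sums the sub-unit outputs and fires
when the total reaches the somatic threshold ``Theta``:

    y(x) = 1  iff  sum_j D_j(w_j . x) >= Theta

With one linear sub-unit (the peri-somatic path) plus one nonlinear
sub-unit this is the search model used in the capacity sweeps; with an
arbitrary list of nonlinear sub-units it is the generic two-stage model
behind the DNF/CNF synthesis results.

Two dendritic activation families are modeled, both parameterized by a
threshold ``theta`` and a height ``h``:

* spiking (dendritic spike):  ``D(s) = 0`` if ``s < theta`` else ``h`` --
  both supra- and sub-linear;
* saturating (passive dendrite): ``D(s) = s`` if ``s < theta`` else ``h``
  -- strictly sub-linear when valid.

Whether a given ``(theta, h)`` pair really behaves as its nominal family is
decided operationally by :func:`check_linearity` on the reachable input
range, not by closed-form constraints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .booleans import BooleanFunction, inputs_matrix

KINDS = ("linear", "spiking", "saturating")

__all__ = [
    "Activation",
    "Subunit",
    "TwoStageNeuron",
    "activation_output",
    "activation_output_vec",
    "check_linearity",
    "is_valid_subunit_activation",
    "neuron_output",
    "truth_table",
    "subunit_max_output",
]


@dataclass(frozen=True)
class Activation:
    """Dendritic activation function: kind plus threshold/height parameters.

    ``theta`` and ``height`` are ignored for ``kind="linear"``.
    """

    kind: str
    theta: int = 0
    height: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.theta < 0 or self.height < 0:
            raise ValueError("theta and height must be non-negative")


@dataclass(frozen=True)
class Subunit:
    """A dendritic sub-unit: non-negative integer weights plus an activation."""

    weights: tuple
    activation: Activation

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "weights", tuple(int(w) for w in self.weights))


@dataclass(frozen=True)
class TwoStageNeuron:
    """A two-stage neuron: dendritic sub-units plus a somatic threshold.

    The neuron fires (output 1) when the summed sub-unit outputs reach
    ``soma_threshold`` (rule: sum >= Theta).  ``soma_threshold = 0`` encodes
    the always-firing neuron, matching the published search ranges that
    start the somatic threshold at zero.
    """

    n_vars: int
    subunits: tuple
    soma_threshold: int

    def __post_init__(self) -> None:
        if not self.subunits:
            raise ValueError("a neuron needs at least one subunit")
        if self.soma_threshold < 0:
            raise ValueError("soma_threshold must be >= 0")
        for su in self.subunits:
            if len(su.weights) != self.n_vars:
                raise ValueError("subunit weight length must equal n_vars")


def activation_output(a: Activation, s: int) -> int:
    """Output of the activation for an integer input sum ``s >= 0``."""
    if s < 0:
        raise ValueError("activation input must be non-negative")
    if a.kind == "linear":
        return s
    if a.kind == "spiking":
        return a.height if s >= a.theta else 0
    return a.height if s >= a.theta else s


def activation_output_vec(a: Activation, sums: np.ndarray) -> np.ndarray:
    if a.kind == "linear":
        return sums
    if a.kind == "spiking":
        return np.where(sums >= a.theta, a.height, 0)
    return np.where(sums >= a.theta, a.height, sums)


def check_linearity(a: Activation, s_max: int) -> dict:
    """Operational supra/sub-linearity probe on the interval ``[0, s_max]``.

    Scans all integer pairs ``x, y`` in ``[0, s_max]``:

    * ``supra``: some pair has ``D(x + y) > D(x) + D(y)``;
    * ``sub``:   some pair has ``D(x + y) < D(x) + D(y)``;
    * ``strictly_sub``: sub and not supra;
    * ``nondecreasing``: pointwise on ``[0, 2 * s_max]`` (the range the pair
      scan evaluates).

    Pairs are sufficient even though the formal definitions extend to
    k-tuples: if no pair violates super-additivity (resp. sub-additivity),
    induction on k shows no tuple does either, so a tuple witness implies a
    pair witness.
    """
    if s_max < 1:
        raise ValueError("s_max must be >= 1")
    supra = sub = False
    for x in range(s_max + 1):
        dx = activation_output(a, x)
        for y in range(x, s_max + 1):
            gap = activation_output(a, x + y) - dx - activation_output(a, y)
            if gap > 0:
                supra = True
            elif gap < 0:
                sub = True
    nondec = all(
        activation_output(a, s) <= activation_output(a, s + 1)
        for s in range(2 * s_max)
    )
    return {
        "supra": supra,
        "sub": sub,
        "strictly_sub": sub and not supra,
        "nondecreasing": nondec,
    }


def is_valid_subunit_activation(a: Activation, s_max: int) -> bool:
    """Whether the activation behaves as its nominal family on ``[0, s_max]``.

    Spiking units must be supra- and sub-linear; saturating units strictly
    sub-linear; both must be non-decreasing.  A sub-unit whose reachable sum
    is 0 (all-zero weights) is inert and accepted for any family, so purely
    linear configurations remain inside every searched model.  Linear
    activations are always valid.
    """
    if a.kind == "linear" or s_max == 0:
        return True
    r = check_linearity(a, s_max)
    if not r["nondecreasing"]:
        return False
    if a.kind == "spiking":
        return r["supra"] and r["sub"]
    return r["strictly_sub"]


def neuron_output(m: TwoStageNeuron, x: Sequence[int]) -> int:
    """Neuron output for one binary input vector."""
    if len(x) != m.n_vars:
        raise ValueError(f"input length {len(x)} != n_vars {m.n_vars}")
    total = 0
    for su in m.subunits:
        s = sum(w * int(v) for w, v in zip(su.weights, x))
        total += activation_output(su.activation, s)
    return int(total >= m.soma_threshold)


def truth_table(m: TwoStageNeuron) -> BooleanFunction:
    """The Boolean function computed by the neuron over all ``2**n`` inputs."""
    X = inputs_matrix(m.n_vars)
    total = np.zeros(1 << m.n_vars, dtype=np.int64)
    for su in m.subunits:
        sums = X @ np.array(su.weights, dtype=np.int64)
        total += activation_output_vec(su.activation, sums)
    return BooleanFunction.from_bits((total >= m.soma_threshold).astype(int).tolist())


def subunit_max_output(su: Subunit) -> int:
    """Maximum achievable output of a sub-unit (at the all-ones input).

    Valid (non-decreasing) activations attain their maximum at the maximal
    reachable sum, which is the sum of the weights.
    """
    return activation_output(su.activation, sum(su.weights))
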