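"""DNF/CNF neuron synthesis, strategy classification, and the saturating
local-strategy impossibility."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dendricap import (
    Activation,
    BooleanFunction,
    Term,
    and_function,
    build_cnf_neuron,
    build_dnf_neuron,
    classify_strategy,
    fbp_family,
    find_fbp_implementations,
    is_valid_subunit_activation,
    or_function,
    prime_clauses,
    prime_implicants,
    representatives,
    term_implementability,
    truth_table,
    verify_no_local_sat_fbp,
    xor2,
)
from dendricap.io import EXAMPLE_WITNESSES


class TestDnfSynthesis:
    def test_fbp_two_subunits(self, fam):
        m = build_dnf_neuron(fam["fbp"])
        assert len(m.subunits) == 2
        assert m.soma_threshold == 1
        assert truth_table(m) == fam["fbp"]

    def test_and_single_subunit(self):
        m = build_dnf_neuron(and_function(2))
        assert len(m.subunits) == 1
        assert m.subunits[0].activation.theta == 2
        assert truth_table(m) == and_function(2)

    def test_subunit_count_equals_term_count(self, reps4):
        full = (1 << 16) - 1
        for f in reps4:
            if f.table in (0, full):
                continue
            m = build_dnf_neuron(f)
            assert len(m.subunits) == len(prime_implicants(f).parts)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            build_dnf_neuron(xor2())


class TestCnfSynthesis:
    def test_fbp_four_clauses(self, fam):
        m = build_cnf_neuron(fam["fbp"], "saturating")
        assert len(m.subunits) == 4
        assert m.soma_threshold == 4
        assert truth_table(m) == fam["fbp"]

    def test_dfbp_two_clauses(self, fam):
        m = build_cnf_neuron(fam["dfbp"], "saturating")
        assert len(m.subunits) == 2
        assert m.soma_threshold == 2
        assert truth_table(m) == fam["dfbp"]

    def test_or_single_clause(self):
        m = build_cnf_neuron(or_function(2), "spiking")
        assert len(m.subunits) == 1 and m.soma_threshold == 1
        assert truth_table(m) == or_function(2)

    def test_both_kinds_coincide(self, fam):
        for f in fam.values():
            spk = build_cnf_neuron(f, "spiking")
            sat = build_cnf_neuron(f, "saturating")
            assert truth_table(spk) == truth_table(sat) == f


@pytest.mark.parametrize("n", [4, 5])
def test_round_trip_all_representatives(n):
    """Both constructive implementations reproduce every representative
    positive function exactly."""
    full = (1 << (1 << n)) - 1
    for f in representatives(n):
        if f.table in (0, full):
            continue
        assert truth_table(build_dnf_neuron(f)) == f
        assert truth_table(build_cnf_neuron(f, "saturating")) == f
        assert truth_table(build_cnf_neuron(f, "spiking")) == f


class TestClassification:
    def test_dnf_neurons_are_local_with_full_degree(self, fam):
        rep = classify_strategy(build_dnf_neuron(fam["fbp"]))
        assert rep.classification == "local"
        assert rep.local_degree == 2

    def test_multi_clause_cnf_neurons_are_global(self, fam):
        rep = classify_strategy(build_cnf_neuron(fam["fbp"], "saturating"))
        assert rep.classification == "global"
        assert rep.local_degree == 0

    def test_eq1_saturating_witness_is_global(self):
        rep = classify_strategy(EXAMPLE_WITNESSES["fbp_saturating"])
        assert rep.classification == "global"
        assert rep.local_degree == 0  # dendritic max 4 < soma threshold 6

    def test_eq1_spiking_witness_is_local_with_somatic_path(self):
        rep = classify_strategy(EXAMPLE_WITNESSES["fbp_spiking"])
        assert rep.classification == "local"
        assert rep.local_degree == 1
        assert rep.soma_alone  # linear path max 4 >= threshold 4

    def test_all_representatives_classify_consistently(self, reps4):
        full = (1 << 16) - 1
        for f in reps4:
            if f.table in (0, full):
                continue
            assert classify_strategy(build_dnf_neuron(f)).local_degree == \
                len(prime_implicants(f).parts)
            if len(prime_clauses(f).parts) >= 2:
                rep = classify_strategy(build_cnf_neuron(f, "saturating"))
                assert rep.classification == "global"


class TestTermImplementability:
    def test_saturating_cannot_compute_a_pair_term(self):
        assert not term_implementability(
            Activation("saturating", 4, 4), Term(frozenset({1, 2})), w_max=6
        )

    def test_spiking_computes_a_pair_term(self):
        assert term_implementability(
            Activation("spiking", 2, 1), Term(frozenset({1, 2})), w_max=1
        )

    def test_single_variable_term_is_always_linear(self):
        for a in (Activation("saturating", 4, 4), Activation("spiking", 2, 3),
                  Activation("linear")):
            assert term_implementability(a, Term(frozenset({1})), w_max=2,
                                         n_vars=2)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.data())
    def test_strictly_sublinear_units_never_compute_multivariable_terms(
        self, data
    ):
        theta = data.draw(st.integers(1, 4))
        h = data.draw(st.integers(max(theta - 1, 0), theta))
        a = Activation("saturating", theta, h)
        n = data.draw(st.integers(2, 3))
        size = data.draw(st.integers(2, n))
        term = Term(frozenset(range(1, size + 1)))
        if is_valid_subunit_activation(a, 3 * n):
            assert not term_implementability(a, term, w_max=3, n_vars=n)


class TestNoLocalSaturatingFbp:
    def test_exhaustive_grid_has_no_local_saturating_fbp(self):
        assert verify_no_local_sat_fbp(4, 4, 4, 8)

    def test_same_grid_contains_global_saturating_fbp(self):
        sweep = find_fbp_implementations("saturating", 4, 4, 4, 8)
        assert sweep["counts"]["local"] == 0
        assert sweep["counts"]["global"] > 0
        assert truth_table(sweep["first_global"]) == fbp_family()["fbp"]

    def test_spiking_grid_contains_local_fbp(self):
        sweep = find_fbp_implementations("spiking", 4, 4, 4, 8)
        assert sweep["counts"]["local"] > 0
        m = sweep["first_local"]
        assert truth_table(m) == fbp_family()["fbp"]
        assert classify_strategy(m).local_degree >= 1

    def test_empty_bounds_vacuously_true(self):
        assert verify_no_local_sat_fbp(0, 0, 0, 0)
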