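"""Truth tables, positivity, canonical classes, separability, normal forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dendricap import (
    BooleanFunction,
    Term,
    and_function,
    canonical_representative,
    count_positive_classes,
    count_positive_functions,
    count_positive_functions_ideals,
    dual,
    generate_positive_functions,
    is_linearly_separable,
    is_positive,
    nand2,
    or_function,
    prime_clauses,
    prime_implicants,
    reconstruct,
    representatives,
    xor2,
)
from dendricap.booleans import canonical_table, inputs_matrix

from conftest import brute_force_monotone


class TestEvaluation:
    @pytest.mark.parametrize(
        "f, x, expected",
        [
            (and_function(2), (1, 1), 1),
            (and_function(2), (1, 0), 0),
            (xor2(), (1, 1), 0),
            (xor2(), (0, 1), 1),
            (nand2(), (0, 0), 1),
        ],
    )
    def test_named_functions(self, f, x, expected):
        assert f.evaluate(x) == expected

    def test_all_zero_input_reads_entry_zero(self, fam):
        for f in fam.values():
            assert f.evaluate((0,) * f.n_vars) == (f.table & 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            and_function(2).evaluate((1, 0, 1))

    def test_hex_round_trip(self, fam):
        for f in fam.values():
            assert BooleanFunction.from_hex(f.n_vars, f.to_hex()) == f


class TestPositivity:
    def test_fbp_family_is_positive(self, fam):
        assert all(is_positive(f) for f in fam.values())

    def test_nand_and_xor_are_not(self):
        assert not is_positive(nand2())
        assert not is_positive(xor2())

    def test_constants_are_positive(self):
        assert is_positive(BooleanFunction(3, 0))
        assert is_positive(BooleanFunction(3, 0xFF))

    @pytest.mark.parametrize("n", [2, 3])
    def test_matches_definition_exhaustively(self, n):
        expected = {f.table for f in brute_force_monotone(n)}
        got = {
            t for t in range(1 << (1 << n)) if is_positive(BooleanFunction(n, t))
        }
        assert got == expected


class TestCanonical:
    def test_single_variable_projections_merge(self):
        x1 = BooleanFunction.from_bits([0, 1, 0, 1])
        x2 = BooleanFunction.from_bits([0, 0, 1, 1])
        assert canonical_representative(x1) == canonical_representative(x2)

    def test_idempotent(self, fam):
        for f in fam.values():
            c = canonical_representative(f)
            assert canonical_representative(c) == c

    def test_invariant_under_pair_swap(self, fam):
        # relabel (x1 x3)(x2 x4): FBP is symmetric under swapping its pairs
        fbp = fam["fbp"]
        swapped = BooleanFunction.from_bits(
            [fbp.evaluate(((k >> 2) & 1, (k >> 3) & 1, k & 1, (k >> 1) & 1))
             for k in range(16)]
        )
        assert canonical_representative(swapped) == canonical_representative(fbp)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 16 - 1), st.permutations(range(4)))
    def test_any_relabelling_preserves_canonical_table(self, table, perm):
        n = 4
        relabelled = 0
        for k in range(1 << n):
            src = 0
            for j in range(n):
                src |= ((k >> perm[j]) & 1) << j
            relabelled |= ((table >> src) & 1) << k
        assert canonical_table(table, n) == canonical_table(relabelled, n)


class TestEnumeration:
    @pytest.mark.parametrize("n, count", [(1, 3), (2, 6), (3, 20), (4, 168)])
    def test_counts_match_brute_force(self, n, count):
        got = list(generate_positive_functions(n))
        assert len(got) == count
        if n <= 3:
            assert {f.table for f in got} == {
                f.table for f in brute_force_monotone(n)
            }

    def test_no_duplicates_and_all_positive_n5(self):
        tables = [f.table for f in generate_positive_functions(5)]
        assert len(tables) == len(set(tables)) == 7581
        sample = [BooleanFunction(5, t) for t in tables[::97]]
        assert all(is_positive(f) for f in sample)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            list(generate_positive_functions(0))
        with pytest.raises(ValueError):
            list(generate_positive_functions(8))

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5, 6])
    def test_pair_count_agrees_with_ideal_count(self, n):
        # two independent counting algorithms must agree; at n = 6 this is
        # the scaled stand-in for the full streaming enumeration
        assert count_positive_functions(n) == count_positive_functions_ideals(n)

    def test_n6_function_count(self):
        assert count_positive_functions(6) == 7_828_354


class TestRepresentatives:
    @pytest.mark.parametrize("n, count", [(1, 3), (2, 5), (3, 10), (4, 30)])
    def test_class_counts(self, n, count):
        reps = representatives(n)
        assert len(reps) == count
        assert all(canonical_representative(f) == f for f in reps)

    def test_n5_class_count(self):
        assert len(representatives(5)) == 210

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5])
    def test_burnside_count_matches_enumeration(self, n):
        assert count_positive_classes(n) == len(representatives(n))

    def test_n6_class_count_via_burnside(self):
        # cross-checked against the enumeration route for n <= 5 above
        assert count_positive_classes(6) == 16_353

    def test_streaming_shard_path_matches_in_memory(self, tmp_path):
        direct = representatives(4)
        sharded = representatives(4, shard_dir=str(tmp_path), shard_limit=7)
        assert sharded == direct


class TestSeparability:
    def test_and_witness(self):
        ok, w = is_linearly_separable(and_function(2), return_witness=True)
        assert ok
        X = inputs_matrix(2)
        sums = X @ np.array(w.weights)
        fires = sums >= w.threshold
        assert fires.tolist() == [False, False, False, True]

    def test_xor_and_fbp_family_not_separable(self, fam):
        assert not is_linearly_separable(xor2())
        for f in fam.values():
            assert not is_linearly_separable(f)

    def test_witnesses_realize_their_functions(self, reps4):
        for f in reps4:
            ok, w = is_linearly_separable(f, return_witness=True)
            if ok:
                sums = inputs_matrix(4) @ np.array(w.weights)
                assert ((sums >= w.threshold).astype(int) == f.bits()).all()
                assert all(v >= 0 for v in w.weights)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_agrees_with_lp_oracle(self, n):
        from scipy.optimize import linprog

        X = inputs_matrix(n)
        for f in generate_positive_functions(n):
            bits = f.bits().astype(bool)
            A, b = [], []
            for k in range(1 << n):
                if bits[k]:
                    A.append(list(-X[k].astype(float)) + [1.0])
                    b.append(0.0)
                else:
                    A.append(list(X[k].astype(float)) + [-1.0])
                    b.append(-1.0)
            res = linprog([0.0] * (n + 1), A_ub=A, b_ub=b,
                          bounds=[(0, None)] * n + [(None, None)],
                          method="highs")
            assert is_linearly_separable(f) == (res.status == 0), f.to_hex()


class TestNormalForms:
    def test_fbp_prime_implicants(self, fam):
        nf = prime_implicants(fam["fbp"])
        assert {p.variables for p in nf.parts} == {
            frozenset({1, 2}), frozenset({3, 4})
        }

    def test_fbp_prime_clauses(self, fam):
        nf = prime_clauses(fam["fbp"])
        assert {p.variables for p in nf.parts} == {
            frozenset({1, 3}), frozenset({1, 4}),
            frozenset({2, 3}), frozenset({2, 4}),
        }

    def test_single_variable_function(self):
        x1 = BooleanFunction.from_bits([0, 1, 0, 1])
        assert {p.variables for p in prime_implicants(x1).parts} == {frozenset({1})}

    def test_round_trip_all_representatives(self, reps4):
        full = (1 << 16) - 1
        for f in reps4:
            if f.table not in (0, full):
                assert reconstruct(prime_implicants(f), 4) == f
                assert reconstruct(prime_clauses(f), 4) == f

    def test_rejects_non_positive_and_constants(self):
        with pytest.raises(ValueError):
            prime_implicants(xor2())
        with pytest.raises(ValueError):
            prime_implicants(BooleanFunction(2, 0))
        with pytest.raises(ValueError):
            prime_clauses(BooleanFunction(2, 0b1111))


class TestDuality:
    def test_fbp_dual_is_dfbp(self, fam):
        assert dual(fam["fbp"]) == fam["dfbp"]

    def test_involution(self, reps4):
        for f in reps4:
            assert dual(dual(f)) == f

    def test_and_or(self):
        assert dual(and_function(2)) == or_function(2)

    def test_dual_preserves_separability_at_n4(self, reps4):
        for f in reps4:
            assert is_linearly_separable(f) == is_linearly_separable(dual(f))

    def test_term_validation(self):
        with pytest.raises(ValueError):
            Term(frozenset())
        with pytest.raises(ValueError):
            Term(frozenset({0}))
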