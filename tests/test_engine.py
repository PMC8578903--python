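"""Reachability, closure, partitioning, conical matrix, digraph."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ismkit.engine import (
    ABSENT,
    DIRECT,
    TRANSITIVE,
    audit_closure_consistency,
    build_conical_matrix,
    build_digraph,
    compute_powers,
    partition_levels,
    ssim_to_initial_rm,
    to_roman,
    transitive_closure,
)
from ismkit.errors import StallError, ValidationError
from ismkit.ssim import SSIM, upper_triangle_pairs

from conftest import make_rm, random_rm


def boolean_power_closure(b: np.ndarray) -> np.ndarray:
    """Independent oracle: ∨_{k=1..n} M^k over the boolean semiring."""
    n = b.shape[0]
    acc = np.zeros_like(b, dtype=bool)
    power = np.eye(n, dtype=bool)
    for _ in range(n):
        power = (power.astype(int) @ b.astype(int)) > 0
        acc |= power
    return acc | np.eye(n, dtype=bool)


def rm_strategy(max_n=8):
    return st.integers(0, 10_000).flatmap(
        lambda seed: st.integers(2, max_n).map(
            lambda n: random_rm(np.random.default_rng(seed), n)
        )
    )


class TestSsimDecoding:
    def test_symbol_semantics_on_case_study_pairs(self, study):
        rm = ssim_to_initial_rm(study.ssim)
        assert rm[1, 2] == DIRECT and rm[2, 1] == ABSENT  # V
        assert rm[2, 4] == ABSENT and rm[4, 2] == DIRECT  # A
        assert rm[7, 11] == DIRECT and rm[11, 7] == DIRECT  # X

    def test_case_study_ssim_decodes_to_packaged_initial_matrix(self, study):
        rm = ssim_to_initial_rm(study.ssim)
        assert rm.codes == study.initial_rm.codes
        assert np.array_equal(rm.cells, study.initial_rm.cells)

    def test_all_O_ssim_gives_identity(self):
        codes = (1, 2, 3, 4)
        ssim = SSIM(codes, {p: "O" for p in upper_triangle_pairs(codes)})
        rm = ssim_to_initial_rm(ssim)
        assert np.array_equal(rm.binary, np.eye(4, dtype=np.int8))


class TestTransitiveClosure:
    def test_chain_adds_transitive_cell(self):
        m = make_rm([[1, 1, 0], [0, 1, 1], [0, 0, 1]])
        full = transitive_closure(m, mode="full")
        assert full[1, 3] == TRANSITIVE
        assert full[1, 2] == DIRECT  # provenance conserved

    def test_one_pass_on_case_study_row_8(self, study):
        one = transitive_closure(study.initial_rm, mode="one_pass")
        assert one[8, 6] == TRANSITIVE and one[8, 7] == TRANSITIVE
        assert int(one.binary[one.index(8)].sum()) == 4

    def test_full_strictly_contains_one_pass_on_case_study(self, study):
        one = transitive_closure(study.initial_rm, mode="one_pass")
        full = transitive_closure(study.initial_rm, mode="full")
        assert (one.binary <= full.binary).all()
        assert full.reaches(8, 2) and not one.reaches(8, 2)

    def test_as_given_is_identity(self, study):
        out = transitive_closure(study.final_rm, mode="as_given")
        assert np.array_equal(out.cells, study.final_rm.cells)
        assert out.flavor == "as_given"

    @given(rm_strategy())
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_full_equals_boolean_power_oracle_and_is_idempotent(self, m):
        full = transitive_closure(m, mode="full")
        assert np.array_equal(
            full.binary.astype(bool), boolean_power_closure(m.binary.astype(bool))
        )
        again = transitive_closure(full, mode="full")
        assert np.array_equal(again.cells, full.cells)

    @given(rm_strategy())
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_containment_chain_and_provenance(self, m):
        one = transitive_closure(m, mode="one_pass")
        full = transitive_closure(m, mode="full")
        assert (m.binary <= one.binary).all()
        assert (one.binary <= full.binary).all()
        for out in (one, full):
            assert ((m.cells == DIRECT) <= (out.cells == DIRECT)).all()

    def test_full_agrees_with_networkx_closure(self, study):
        g = study.initial_rm.to_digraph()
        nx_closed = nx.transitive_closure(g, reflexive=True)
        full = transitive_closure(study.initial_rm, mode="full")
        for i in study.initial_rm.codes:
            for j in study.initial_rm.codes:
                assert full.reaches(i, j) == nx_closed.has_edge(i, j) or i == j


class TestPowers:
    def test_case_study_margins(self, study):
        p = compute_powers(study.final_rm)
        assert p.driving[1] == 11 and p.dependence[1] == 2
        assert p.driving[8] == 4 and p.dependence[8] == 11
        assert p.driving[7] == 11 and p.dependence[7] == 11
        assert sum(p.driving.values()) == sum(p.dependence.values()) == 103

    def test_identity_matrix_powers(self):
        m = make_rm([[1, 0, 0], [0, 1, 0], [0, 0, 1]])
        p = compute_powers(m)
        assert all(v == 1 for v in p.driving.values())
        assert all(v == 1 for v in p.dependence.values())

    @given(rm_strategy())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_driving_sum_equals_dependence_sum(self, m):
        p = compute_powers(m)
        assert sum(p.driving.values()) == sum(p.dependence.values()) == int(m.binary.sum())


class TestLevelPartitioning:
    def test_case_study_levels_match_published_iterations(self, study):
        part = partition_levels(study.final_rm)
        assert part.as_dict() == study.published_levels

    def test_case_study_iteration_one_set_triples(self, study):
        part = partition_levels(study.final_rm)
        recs = {r.code: r for r in part.trace if r.iteration == 1}
        for code, pub in study.published_iteration_1.items():
            assert recs[code].reachability == pub["reachability"], code
            assert recs[code].antecedent == pub["antecedent"], code
            assert recs[code].intersection == pub["intersection"], code
            assert recs[code].leveled == pub["leveled"], code

    def test_all_ones_matrix_is_single_level(self):
        m = make_rm([[1] * 4 for _ in range(4)])
        part = partition_levels(m)
        assert part.levels == ((1, 2, 3, 4),)

    def test_stall_on_non_closed_matrix_names_residual(self):
        # 1→2, 2→3, no 1→3: factor ordering has no top under set equality
        m = make_rm([[1, 1, 0], [0, 1, 1], [1, 0, 1]])
        with pytest.raises(StallError, match="transitively closed"):
            partition_levels(m)

    @given(rm_strategy(max_n=7))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_levels_equal_condensation_longest_path_strata(self, m):
        from ismkit.synthetic import oracle_strata

        full = transitive_closure(m, mode="full")
        part = partition_levels(full)
        relation = frozenset(
            (i, j) for i in m.codes for j in m.codes if i != j and full.reaches(i, j)
        )
        assert part.levels == oracle_strata(m.codes, relation)
        assert part.depth <= m.n

    @given(rm_strategy(max_n=7))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_cross_scc_monotonicity(self, m):
        full = transitive_closure(m, mode="full")
        part = partition_levels(full)
        for i in m.codes:
            for j in m.codes:
                if i != j and full.reaches(i, j) and not full.reaches(j, i):
                    assert part.level_of(j) < part.level_of(i)


class TestConicalMatrix:
    def test_case_study_order(self, study):
        part = partition_levels(study.final_rm)
        con = build_conical_matrix(study.final_rm, part)
        assert con.order == (6, 7, 8, 10, 2, 5, 9, 11, 3, 4, 1)

    def test_cell_multiset_preserved(self, study):
        part = partition_levels(study.final_rm)
        con = build_conical_matrix(study.final_rm, part)
        assert sorted(con.cells.ravel()) == sorted(study.final_rm.cells.ravel())
        # spot-check via explicit permutation application
        idx = [study.final_rm.codes.index(c) for c in con.order]
        assert np.array_equal(con.cells, study.final_rm.cells[np.ix_(idx, idx)])

    def test_single_level_system_is_identity_permutation(self):
        m = make_rm([[1] * 3 for _ in range(3)])
        con = build_conical_matrix(m, partition_levels(m))
        assert con.order == (1, 2, 3)

    def test_partition_mismatch_rejected(self, study):
        part = partition_levels(study.final_rm)
        small = make_rm([[1, 1], [0, 1]])
        with pytest.raises(ValidationError):
            build_conical_matrix(small, part)


class TestStructuralDigraph:
    def test_closed_chain_reduces_to_chain(self):
        m = make_rm([[1, 1, 1], [0, 1, 1], [0, 0, 1]], flavor="full_closure")
        d = build_digraph(m, partition_levels(m))
        edges = {
            (d.members[u][0], d.members[v][0]) for u, v in d.edges
        }
        assert edges == {(1, 2), (2, 3)}

    def test_mutual_pair_lands_in_one_scc(self, study):
        part = partition_levels(study.final_rm)
        d = build_digraph(study.initial_rm, part)
        scc_of = {c: mem for mem in d.members for c in mem}
        assert scc_of[7] == scc_of[11]
        assert (7, 11) in d.mutual_pairs

    @given(rm_strategy(max_n=7))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_reduction_preserves_reachability(self, m):
        """closure(reduced condensation) equals closure(input relation)."""
        full = transitive_closure(m, mode="full")
        d = build_digraph(full, partition_levels(full))
        g = d.to_networkx()
        node_of = {c: nid for nid, mem in enumerate(d.members) for c in mem}
        for u in full.codes:
            for v in full.codes:
                if u == v:
                    continue
                got = node_of[u] == node_of[v] or nx.has_path(g, node_of[u], node_of[v])
                assert got == full.reaches(u, v)

    def test_every_factor_in_exactly_one_node(self, study):
        d = build_digraph(study.final_rm, partition_levels(study.final_rm))
        flat = [c for mem in d.members for c in mem]
        assert sorted(flat) == sorted(study.final_rm.codes)


class TestClosureAudit:
    def test_case_study_one_pass_discrepancy_is_exactly_7_1(self, study):
        audit = audit_closure_consistency(study.final_rm, study.initial_rm)
        assert audit.one_pass_unsupported == ((7, 1),)
        assert audit.one_pass_missing == ()

    def test_full_closure_changes_the_level_structure(self, study):
        audit = audit_closure_consistency(study.final_rm, study.initial_rm)
        full_levels = audit.levels_by_mode["full"]
        assert len(full_levels) == 2
        assert full_levels[-1] == (1,)
        assert audit.levels_by_mode["as_given"] == partition_levels(study.final_rm).levels

    def test_self_comparison_is_empty(self, study):
        one = transitive_closure(study.initial_rm, mode="one_pass")
        audit = audit_closure_consistency(one, study.initial_rm)
        assert audit.one_pass_unsupported == () and audit.one_pass_missing == ()


def test_roman_numerals():
    assert [to_roman(k) for k in (1, 2, 4, 9, 11)] == ["I", "II", "IV", "IX", "XI"]
    with pytest.raises(ValueError):
        to_roman(0)
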