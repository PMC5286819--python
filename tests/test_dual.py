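import numpy as np
import pytest

from psomcs import (
    CutSet,
    LinearRegion,
    build_dual,
    build_intervention,
    check_minimality,
    enumerate_minimum_cmcs,
    solve_cmcs,
    validate_cutset,
)
from psomcs.design import InterventionProblem
from psomcs.dual import DualError
from psomcs.synth import brute_force_cmcs
from .conftest import make_random_net


def _chain_mcs_problem(chain_net):
    """Plain MCS instance: eliminate 'P secretion >= 0.5 at unit uptake',
    no desired region."""
    n = chain_net.n_reactions
    ref = np.zeros(n)
    ref[chain_net.index("UP")] = 1.0
    sec = np.zeros(n)
    sec[chain_net.index("SEC")] = 1.0
    target = LinearRegion(np.vstack([ref, -ref, -sec]), np.array([1.0, -1.0, -0.5]))
    return InterventionProblem(target=target, desired=LinearRegion.empty(n), x=[0.5])


class TestBuildDual:
    def test_dimension_bookkeeping(self, toy_net, toy_problem_x1):
        dual = build_dual(toy_net, toy_problem_x1, max_cardinality=5)
        m, n = toy_net.n_metabolites, toy_net.n_reactions
        t_rows, d_rows = toy_problem_x1.target.n_rows, toy_problem_x1.desired.n_rows
        assert dual.n_continuous == m + 2 * n + t_rows + n
        assert dual.n_binary == 2 * n
        assert dual.core_row_count == n + m + d_rows + 1

    def test_disallowed_reactions_fix_indicators(self, toy_net, toy_problem_x1):
        net = toy_net.copy()
        net.knockout_allowed[net.index("R2")] = False
        dual = build_dual(net, toy_problem_x1, max_cardinality=5)
        _, hi = dual._variable_bounds()
        j = net.index("R2")
        assert hi[dual.off_zp + j] == 0.0
        assert hi[dual.off_zn + j] == 0.0

    def test_zero_cardinality_with_nonempty_target(self, toy_net, toy_spec):
        prob = build_intervention(toy_spec, [0.5], toy_net)
        dual = build_dual(toy_net, prob, max_cardinality=0)
        assert solve_cmcs(dual) is None

    def test_dimension_mismatch(self, toy_net, chain_net, toy_problem_x1):
        with pytest.raises(DualError):
            build_dual(chain_net, toy_problem_x1, max_cardinality=2)

    def test_negative_cap(self, toy_net, toy_problem_x1):
        with pytest.raises(DualError):
            build_dual(toy_net, toy_problem_x1, max_cardinality=-1)


class TestSolveCmcs:
    def test_chain_single_cut(self, chain_net):
        prob = _chain_mcs_problem(chain_net)
        dual = build_dual(chain_net, prob, max_cardinality=3)
        cs = solve_cmcs(dual)
        assert cs.cardinality == 1
        # oracle: every singleton chain reaction is a minimal cut set
        catalogue = brute_force_cmcs(chain_net, prob, max_k=3)
        assert {frozenset(c.reactions) for c in catalogue} == {
            frozenset({"UP"}), frozenset({"CONV"}), frozenset({"SEC"})
        }
        assert cs.reactions in {c.reactions for c in catalogue}

    def test_toy_x1_gives_r2_r9(self, toy_net, toy_problem_x1):
        dual = build_dual(toy_net, toy_problem_x1, max_cardinality=5)
        cs = solve_cmcs(dual, tie_break="lex")
        assert cs.sorted() == ["R2", "R9"]

    def test_exclusion_moves_to_next_solution(self, toy_net, toy_problem_x1):
        dual = build_dual(toy_net, toy_problem_x1, max_cardinality=5)
        first = solve_cmcs(dual, tie_break="lex")
        second = solve_cmcs(dual, exclusions=[first], tie_break="lex")
        assert second is not None
        assert second.reactions != first.reactions
        assert second.cardinality >= 2

    def test_lex_tie_break_is_lexicographic_minimum(self, toy_net, toy_problem_x1):
        stratum = enumerate_minimum_cmcs(toy_net, toy_problem_x1, 5)
        lex_min = min(tuple(c.sorted()) for c in stratum)
        dual = build_dual(toy_net, toy_problem_x1, max_cardinality=5)
        assert tuple(solve_cmcs(dual, tie_break="lex").sorted()) == lex_min

    def test_bad_tie_break(self, toy_net, toy_problem_x1):
        dual = build_dual(toy_net, toy_problem_x1, max_cardinality=5)
        with pytest.raises(ValueError):
            solve_cmcs(dual, tie_break="first")

    def test_every_solution_is_valid(self, toy_net, toy_spec):
        # duality soundness: each MILP support passes the two LP checks
        for x in (0.25, 0.5, 0.75, 1.0):
            prob = build_intervention(toy_spec, [x], toy_net)
            dual = build_dual(toy_net, prob, max_cardinality=5)
            cs = solve_cmcs(dual)
            assert cs is not None
            validate_cutset(toy_net, prob, cs)
            assert cs.valid, (x, cs.sorted())


class TestValidateAndMinimality:
    def test_empty_set_invalid_when_target_nonempty(self, toy_net, toy_problem_x1):
        cs = validate_cutset(toy_net, toy_problem_x1, CutSet(frozenset()))
        assert cs.valid is False

    def test_r2_r9_valid_with_witness(self, toy_net, toy_problem_x1):
        cs = validate_cutset(toy_net, toy_problem_x1, CutSet({"R2", "R9"}))
        assert cs.valid
        r = cs.witness_flux
        assert r[toy_net.index("R4")] >= 1.0 - 1e-6  # redirected through R4
        np.testing.assert_allclose(toy_net.stoich @ r, 0, atol=1e-9)

    def test_cut_killing_desired_is_invalid(self, toy_net, toy_problem_x1):
        # cutting the product secretion eliminates the target region but
        # also the desired one: a plain MCS, not a cMCS
        cs = validate_cutset(toy_net, toy_problem_x1, CutSet({"R2", "R9", "R4"}))
        assert cs.valid is False

    def test_singleton_minimal(self, chain_net):
        prob = _chain_mcs_problem(chain_net)
        cs = validate_cutset(chain_net, prob, CutSet({"CONV"}))
        cs = check_minimality(chain_net, prob, cs)
        assert cs.minimal

    def test_r2_r9_minimal(self, toy_net, toy_problem_x1):
        cs = validate_cutset(toy_net, toy_problem_x1, CutSet({"R2", "R9"}))
        cs = check_minimality(toy_net, toy_problem_x1, cs)
        assert cs.minimal

    def test_padded_set_not_minimal(self, toy_net, toy_problem_x1):
        cs = validate_cutset(toy_net, toy_problem_x1, CutSet({"R2", "R9", "R5"}))
        assert cs.valid  # R5 carries no flux after the cut anyway
        cs = check_minimality(toy_net, toy_problem_x1, cs)
        assert cs.minimal is False

    def test_minimality_requires_valid(self, toy_net, toy_problem_x1):
        cs = CutSet({"R1"})
        cs.valid = False
        with pytest.raises(DualError):
            check_minimality(toy_net, toy_problem_x1, cs)


class TestEnumeration:
    def test_toy_stratum_matches_oracle(self, toy_net, toy_problem_x1):
        stratum = enumerate_minimum_cmcs(toy_net, toy_problem_x1, 5)
        oracle = brute_force_cmcs(toy_net, toy_problem_x1, max_k=2)
        assert {c.reactions for c in stratum} == {c.reactions for c in oracle}
        assert all(c.valid for c in stratum)

    def test_zero_threshold_gives_empty_cut(self, toy_net, toy_spec):
        prob = build_intervention(toy_spec, [0.0], toy_net)
        stratum = enumerate_minimum_cmcs(toy_net, prob, 5)
        assert len(stratum) == 1
        assert stratum[0].cardinality == 0
        assert stratum[0].valid

    @pytest.mark.parametrize("seed", [1, 6, 21])
    def test_random_instances_agree_with_oracle(self, seed):
        net = make_random_net(seed)
        from psomcs.synth import random_design

        spec = random_design(net)
        from psomcs import yield_bounds

        (fr,) = yield_bounds(net, spec.ratios())
        if fr.max <= 1e-6:
            pytest.skip("degenerate design")
        x = fr.min + 0.7 * (fr.max - fr.min)
        prob = build_intervention(spec, [x], net)
        oracle = brute_force_cmcs(net, prob, max_k=3)
        stratum = enumerate_minimum_cmcs(net, prob, 3)
        oracle_min = min((c.cardinality for c in oracle), default=None)
        if oracle_min is None:
            assert stratum == []
        else:
            assert {c.reactions for c in stratum} == {
                c.reactions for c in oracle if c.cardinality == oracle_min
            }
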