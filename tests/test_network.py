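import numpy as np
import pytest

from psomcs import (
    apply_knockout_exclusions,
    compress_subsets,
    fba_optimize,
    loads_tabular,
    reduce_to_condition,
)
from psomcs.network import NetworkError, dumps_tabular
from .conftest import CHAIN, DIAMOND, make_random_net


class TestLoadTabular:
    def test_chain_dimensions(self):
        net = loads_tabular(CHAIN)
        assert net.n_metabolites == 2
        assert net.n_reactions == 3
        assert net.reaction_ids == ["UP", "CONV", "SEC"]

    def test_toy_exchange_flags(self, toy_net):
        exch = {r for r, e in zip(toy_net.reaction_ids, toy_net.is_exchange) if e}
        # three inputs and three secretions
        assert exch == {"R1", "R2", "R3", "R4", "R7", "R8"}
        assert toy_net.n_reactions == 9

    def test_duplicate_reaction_id(self):
        with pytest.raises(NetworkError, match="duplicate"):
            loads_tabular("R1 irr A:1\nR1 irr A:-1\n")

    def test_bad_reversibility_token(self):
        with pytest.raises(NetworkError):
            loads_tabular("R1 maybe A:1\n")

    def test_irreversible_negative_lb_rejected(self):
        with pytest.raises(NetworkError, match="negative lower bound"):
            loads_tabular("R1 irr A:1 -5 10\n")

    def test_spontaneous_annotation(self):
        net = loads_tabular(CHAIN, spontaneous=["CONV"])
        assert net.is_spontaneous[net.index("CONV")]

    def test_sbml_dialect(self, tmp_path):
        cobra = pytest.importorskip("cobra")
        from psomcs import load_network

        model = cobra.Model("mini")
        a = cobra.Metabolite("A", compartment="c")
        up = cobra.Reaction("UP", lower_bound=0, upper_bound=10)
        up.add_metabolites({a: 1})
        conv = cobra.Reaction("SEC", lower_bound=-5, upper_bound=10)
        conv.add_metabolites({a: -1})
        model.add_reactions([up, conv])
        path = tmp_path / "mini.xml"
        cobra.io.write_sbml_model(model, str(path))

        net = load_network(path, dialect="sbml")
        assert net.reaction_ids == ["UP", "SEC"]
        assert net.n_metabolites == 1
        assert not net.reversible[net.index("UP")]
        assert net.reversible[net.index("SEC")]
        assert net.is_exchange.all()

    def test_roundtrip_through_dump(self, toy_net):
        again = loads_tabular(dumps_tabular(toy_net))
        assert again.reaction_ids == toy_net.reaction_ids
        np.testing.assert_allclose(again.stoich, toy_net.stoich)
        np.testing.assert_array_equal(again.reversible, toy_net.reversible)


class TestReduce:
    def test_closing_uptake_removes_branch(self, toy_net):
        # without R2, metabolite B is only reachable via R9; closing R2
        # keeps the B branch alive, but closing R1+R3 starves A entirely
        reduced = reduce_to_condition(toy_net, {"R2", "R4", "R7", "R8"})
        # A cannot be made: R1/R3 closed, so R4 and R9 are blocked
        assert "R4" not in reduced.reaction_ids
        assert "R9" not in reduced.reaction_ids
        # the R2 -> B -> {R5,R6} -> {R7,R8} branch survives
        assert {"R2", "R5", "R6", "R7", "R8"} <= set(reduced.reaction_ids)

    def test_full_medium_is_identity(self, toy_net):
        exch = [r for r, e in zip(toy_net.reaction_ids, toy_net.is_exchange) if e]
        reduced = reduce_to_condition(toy_net, set(exch))
        assert reduced.reaction_ids == toy_net.reaction_ids

    def test_empty_medium_removes_everything(self, toy_net):
        reduced = reduce_to_condition(toy_net, set())
        assert reduced.n_reactions == 0

    def test_unknown_medium_reaction(self, toy_net):
        with pytest.raises(NetworkError, match="unknown"):
            reduce_to_condition(toy_net, {"NOPE"})

    def test_reduction_soundness(self):
        # any flux feasible in the reduced network is feasible in the
        # original with the closed uptakes
        for seed in range(5):
            net = make_random_net(seed, m=5, n=10)
            exch = [r for r, e in zip(net.reaction_ids, net.is_exchange) if e]
            medium = set(exch[: max(2, len(exch) - 1)])
            reduced = reduce_to_condition(net, medium)
            if reduced.n_reactions == 0:
                continue
            res = fba_optimize(reduced, reduced.reaction_ids[0], sense="max")
            if res.status != "optimal":
                continue
            full = np.zeros(net.n_reactions)
            for rid, v in zip(reduced.reaction_ids, res.fluxes):
                full[net.index(rid)] = v
            np.testing.assert_allclose(net.stoich @ full, 0, atol=1e-6)


class TestCompression:
    def test_linear_chain_merges(self, chain_net):
        compressed, cmap = compress_subsets(chain_net)
        assert compressed.n_reactions == 1
        (members,) = cmap.subset_members.values()
        assert {rid for rid, _ in members} == {"UP", "CONV", "SEC"}
        assert all(abs(c - 1.0) < 1e-9 for _, c in members)

    def test_branch_point_not_merged(self, diamond_net):
        compressed, _ = compress_subsets(diamond_net)
        # TOP and BOT are not proportional to each other or to UP/SEC
        assert compressed.n_reactions == 3

    def test_every_reaction_mapped_once(self, toy_net):
        compressed, cmap = compress_subsets(toy_net)
        seen = [rid for members in cmap.subset_members.values() for rid, _ in members]
        assert sorted(seen) == sorted(toy_net.reaction_ids)
        assert cmap.removed_blocked == []

    @pytest.mark.parametrize("seed", range(20))
    def test_compression_preserves_fba_optimum(self, seed):
        net = make_random_net(seed, m=6, n=11)
        compressed, cmap = compress_subsets(net)
        uptake, product = net.reaction_ids[0], net.reaction_ids[1]
        ref = fba_optimize(net, product, sense="max", fixed={uptake: 1.0})

        def locate(rid):
            for cid, members in cmap.subset_members.items():
                for mid, lam in members:
                    if mid == rid:
                        return cid, lam
            raise AssertionError(rid)

        cid_u, lam_u = locate(uptake)
        cid_p, lam_p = locate(product)
        res = fba_optimize(
            compressed, {cid_p: lam_p}, sense="max", fixed={cid_u: 1.0 / lam_u}
        )
        assert res.status == ref.status
        if ref.status == "optimal":
            assert res.objective == pytest.approx(ref.objective, abs=1e-6)

    def test_decompress_prefers_allowed(self, chain_net):
        _, cmap = compress_subsets(chain_net)
        cid = next(iter(cmap.subset_members))
        assert cmap.decompress([cid], allowed={"CONV"}) == {"CONV"}

    def test_map_json_roundtrip(self, toy_net):
        from psomcs.network import CompressionMap

        _, cmap = compress_subsets(toy_net)
        again = CompressionMap.from_json(cmap.to_json())
        assert again.subset_members == cmap.subset_members


class TestExclusions:
    def test_chain_all_essential(self, chain_net):
        out = apply_knockout_exclusions(chain_net, protect_essential_for=["SEC"])
        assert not out.knockout_allowed.any()

    def test_only_exchanges_excluded_by_default(self, chain_net):
        out = apply_knockout_exclusions(chain_net)
        assert not out.knockout_allowed[out.index("UP")]
        assert not out.knockout_allowed[out.index("SEC")]
        assert out.knockout_allowed[out.index("CONV")]

    def test_diamond_branches_not_essential(self, diamond_net):
        out = apply_knockout_exclusions(diamond_net, protect_essential_for=["SEC"])
        assert out.knockout_allowed[out.index("TOP")]
        assert out.knockout_allowed[out.index("BOT")]

    def test_unknown_reaction(self, chain_net):
        with pytest.raises(NetworkError):
            apply_knockout_exclusions(chain_net, extra_excluded=["NOPE"])

    def test_spontaneous_excluded(self):
        net = loads_tabular(DIAMOND, spontaneous=["TOP"])
        out = apply_knockout_exclusions(net)
        assert not out.knockout_allowed[out.index("TOP")]
        assert out.knockout_allowed[out.index("BOT")]

    def test_exclusion_monotonicity(self, toy_net):
        small = apply_knockout_exclusions(toy_net, protect_essential_for=["R4"])
        large = apply_knockout_exclusions(toy_net, protect_essential_for=["R4", "R7"])
        # enlarging the protected set never re-enables a knockout
        assert not np.any(large.knockout_allowed & ~small.knockout_allowed)
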