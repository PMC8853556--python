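"""Model containers, SBML round-tripping and the irreversible split."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog

from fluxcord._lp import build_system
from fluxcord.model import (
    LinearConstraint,
    MetabolicModel,
    ModelError,
    Reaction,
    Species,
    flag_exchanges,
    make_irreversible,
    net_flux,
    read_sbml,
    write_sbml,
)


def three_reaction_model() -> MetabolicModel:
    model = MetabolicModel(
        species=[Species("A_e", "A", "e"), Species("A_c", "A", "c"), Species("B_c", "B", "c")],
        reactions=[
            Reaction("EX_A", {"A_e": -1}, -10, 0),
            Reaction("T_A", {"A_e": -1, "A_c": 1}, 0, 1000),
            Reaction("R1", {"A_c": -1, "B_c": 2}, -5, 10, gpr=None),
        ],
        id="tiny",
    )
    flag_exchanges(model)
    model.validate()
    return model


class TestContainers:
    def test_invariants_enforced(self):
        with pytest.raises(ModelError):
            Reaction("r", {}, 0, 10)                       # empty stoichiometry
        with pytest.raises(ModelError):
            Reaction("r", {"a": -1}, 5, 1)                 # lb > ub
        with pytest.raises(ModelError):
            Reaction("r", {"a": -1}, float("nan"), 1)      # missing bound
        with pytest.raises(ModelError):
            Species("s", compartment="")

    def test_validate_unknown_species(self):
        model = three_reaction_model()
        model.reactions[0].stoichiometry["ghost"] = 1.0
        with pytest.raises(ModelError, match="ghost"):
            model.validate()

    def test_exchange_detection_structural_and_override(self):
        model = three_reaction_model()
        assert [r.id for r in model.exchanges] == ["EX_A"]
        flag_exchanges(model, explicit=["R1"])
        assert [r.id for r in model.exchanges] == ["R1"]

    def test_stoichiometric_matrix_shape(self, toy_model):
        S, species, reactions = toy_model.stoichiometric_matrix()
        assert S.shape == (len(species), len(reactions))
        assert set(toy_model.genes) >= {"G_GLS", "G_BR1"}


class TestSbmlRoundTrip:
    def test_three_reaction_fixture(self, tmp_path):
        model = three_reaction_model()
        path = tmp_path / "tiny.xml"
        write_sbml(model, path)
        loaded = read_sbml(path)
        assert len(loaded.reactions) == 3
        assert len(loaded.species) == 3

    def test_round_trip_preserves_structure(self, toy_model, tmp_path):
        path = tmp_path / "toy.xml"
        write_sbml(toy_model, path)
        loaded = read_sbml(path)
        assert loaded.reaction_ids == toy_model.reaction_ids
        for orig, new in zip(toy_model.reactions, loaded.reactions):
            assert new.stoichiometry == orig.stoichiometry
            assert new.lower_bound == orig.lower_bound
            assert new.upper_bound == orig.upper_bound
            assert (new.gpr is None) == (orig.gpr is None)
            if orig.gpr is not None:
                assert new.gpr.genes == orig.gpr.genes
        # second round trip is byte-stable on the parsed structures
        path2 = tmp_path / "toy2.xml"
        write_sbml(loaded, path2)
        again = read_sbml(path2)
        assert again.reaction_ids == loaded.reaction_ids

    def test_constraint_sidecar_round_trip(self, tmp_path):
        model = three_reaction_model()
        model.extra_constraints.append(
            LinearConstraint("row", {"EX_A": 1.0, "R1": 2.0}, -0.5, 0.5)
        )
        path = tmp_path / "tiny.xml"
        write_sbml(model, path)
        loaded = read_sbml(path)
        (row,) = loaded.extra_constraints
        assert row.coefficients == {"EX_A": 1.0, "R1": 2.0}
        assert (row.lower, row.upper) == (-0.5, 0.5)

    def test_empty_file_is_parse_error(self, tmp_path):
        path = tmp_path / "empty.xml"
        path.write_text("")
        with pytest.raises(ModelError):
            read_sbml(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_sbml(tmp_path / "nope.xml")


class TestIrreversible:
    def test_split_bounds(self):
        model = three_reaction_model()
        irr = make_irreversible(model)
        by_id = irr.reactions_by_id()
        assert (by_id["R1"].lower_bound, by_id["R1"].upper_bound) == (0, 10)
        assert (by_id["R1_reverse"].lower_bound, by_id["R1_reverse"].upper_bound) == (0, 5)
        assert by_id["R1_reverse"].stoichiometry == {"A_c": 1, "B_c": -2}

    def test_irreversible_model_unchanged_count(self):
        model = three_reaction_model()
        for r in model.reactions:
            r.lower_bound = max(r.lower_bound, 0.0)
            r.reversible = False
        assert len(make_irreversible(model).reactions) == 3

    def test_two_of_five_reversible_gives_seven(self):
        species = [Species(f"s{i}", compartment="c") for i in range(6)]
        reactions = [
            Reaction(f"r{i}", {f"s{i}": -1, f"s{i+1}": 1},
                     -5 if i < 2 else 0, 10)
            for i in range(5)
        ]
        model = MetabolicModel(species=species, reactions=reactions)
        assert len(make_irreversible(model).reactions) == 7

    def test_constraint_rewrite_onto_split_variables(self):
        model = three_reaction_model()
        model.extra_constraints.append(LinearConstraint("row", {"R1": 2.0}, -1, 1))
        irr = make_irreversible(model)
        (row,) = irr.extra_constraints
        assert row.coefficients == {"R1": 2.0, "R1_reverse": -2.0}

    def test_ordering_guard(self):
        with pytest.raises(ModelError, match="type 2"):
            make_irreversible(three_reaction_model(), require_ratio_rows=True)

    def test_net_flux_polytope_preserved(self):
        """Every net-flux extreme of the reversible model is attainable in
        the split model and vice versa (LP check per reaction)."""
        model = three_reaction_model()
        irr = make_irreversible(model)
        orig = build_system(model)
        split = build_system(irr)

        for rid in model.reaction_ids:
            j = orig.reaction_ids.index(rid)
            c = np.zeros(orig.n)
            fwd, rev = irr.split_map[rid]
            c2 = np.zeros(split.n)
            c2[split.reaction_ids.index(fwd)] = 1.0
            if rev is not None:
                c2[split.reaction_ids.index(rev)] = -1.0
            for sign in (1.0, -1.0):
                c[j] = sign
                a = linprog(c, A_eq=orig.S, b_eq=np.zeros(orig.S.shape[0]),
                            bounds=list(zip(orig.lb, orig.ub)), method="highs")
                b = linprog(sign * c2, A_eq=split.S, b_eq=np.zeros(split.S.shape[0]),
                            bounds=list(zip(split.lb, split.ub)), method="highs")
                c[j] = 0.0
                assert a.fun == pytest.approx(b.fun, abs=1e-8)


class TestNetFlux:
    class _Stub:
        def __init__(self, fluxes, split_map):
            self.fluxes = fluxes
            self.split_map = split_map

    def test_forward_minus_reverse(self):
        fluxes = pd.DataFrame(
            {"s0": [4.0, 1.5, 3.0], "s1": [0.0, 2.0, 3.0]},
            index=["R1", "R1_reverse", "R2"],
        )
        stub = self._Stub(fluxes, {"R1": ("R1", "R1_reverse"), "R2": ("R2", None)})
        assert net_flux(stub, "R1").tolist() == [2.5, -2.0]
        assert net_flux(stub, "R2").tolist() == [3.0, 3.0]
        with pytest.raises(ModelError):
            net_flux(stub, "nope")
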