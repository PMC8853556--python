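"""Constraint layers: medium scaling, spent-medium ratios, the growth
yield bracket, FVA, and RAS-scaled bounds."""

import numpy as np
import pandas as pd
import pytest

from fluxcord.constraints import (
    GrowthYieldConstraint,
    LayerConfig,
    MediumDefinition,
    apply_medium_constraints,
    apply_ras_bounds,
    attach_constraints,
    build_cell_relative_models,
    derive_ratio_constraints,
    run_fva,
)
from fluxcord.model import (
    MetabolicModel,
    ModelError,
    Reaction,
    Species,
    flag_exchanges,
    make_irreversible,
)
from fluxcord.ras import compute_ras_table


def chain_model() -> MetabolicModel:
    """A_ex -> A -> B -> B_ex linear chain, uptake bound 10."""
    model = MetabolicModel(
        species=[
            Species("A_e", "A", "e"), Species("A_c", "A", "c"),
            Species("B_c", "B", "c"), Species("B_e", "B", "e"),
        ],
        reactions=[
            Reaction("EX_A", {"A_e": -1}, -10, 0),
            Reaction("T_A", {"A_e": -1, "A_c": 1}, 0, 1000),
            Reaction("R_AB", {"A_c": -1, "B_c": 1}, 0, 1000),
            Reaction("T_B", {"B_c": -1, "B_e": 1}, 0, 1000),
            Reaction("EX_B", {"B_e": -1}, 0, 1000),
        ],
    )
    flag_exchanges(model)
    return model


class TestMedium:
    def test_concentration_ratio_scales_uptake(self):
        model = chain_model()
        medium = MediumDefinition({"grpA": {"A_e": 25.0}, "grpB": {"A_e": 17.5}})
        out = apply_medium_constraints(model, medium, base_uptake=10.0)
        assert out["grpA"].get_reaction("EX_A").lower_bound == -10.0
        assert out["grpB"].get_reaction("EX_A").lower_bound == pytest.approx(-7.0)

    def test_absent_metabolite_closes_uptake(self):
        model = chain_model()
        medium = MediumDefinition({"grpA": {"A_e": 10.0}, "grpB": {}})
        out = apply_medium_constraints(model, medium)
        assert out["grpB"].get_reaction("EX_A").lower_bound == 0.0

    def test_equal_concentrations_equal_bounds(self):
        model = chain_model()
        medium = MediumDefinition({"g1": {"A_e": 5.0}, "g2": {"A_e": 5.0}})
        out = apply_medium_constraints(model, medium)
        assert (
            out["g1"].get_reaction("EX_A").lower_bound
            == out["g2"].get_reaction("EX_A").lower_bound
            == -10.0
        )

    def test_secretion_bound_untouched(self):
        model = chain_model()
        out = apply_medium_constraints(model, MediumDefinition({"g": {"A_e": 1.0}}))
        assert out["g"].get_reaction("EX_B").upper_bound == 1000

    def test_species_without_exchange_is_an_error(self):
        model = chain_model()
        with pytest.raises(ModelError, match="A_c"):
            apply_medium_constraints(model, MediumDefinition({"g": {"A_c": 1.0}}))

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            MediumDefinition({"g": {"A_e": -1.0}})


def _spent(rows):
    return pd.DataFrame(
        rows, columns=["group", "metabolite", "bio_rep", "tech_rep", "t0", "t48"]
    )


EXCHANGE_MAP = {"lactate": "EX_lac", "glucose": "EX_glc",
                "glutamine": "EX_gln", "glutamate": "EX_glu"}


class TestRatioDerivation:
    def _table(self, ratios_by_bio):
        rows = []
        for bio, ratio in enumerate(ratios_by_bio, start=1):
            rows += [
                ("g", "glucose", bio, 1, 25.0, 15.0),           # consumed 10
                ("g", "lactate", bio, 1, 0.0, 10.0 * ratio),    # produced 10*ratio
                ("g", "glutamine", bio, 1, 4.0, 2.0),
                ("g", "glutamate", bio, 1, 0.0, 1.6),
            ]
        return _spent(rows)

    def test_mean_and_sample_sd_over_biological_replicates(self):
        constraints = derive_ratio_constraints(self._table([0.9, 1.1]), EXCHANGE_MAP)
        lac_glc = constraints["g"][0]
        assert lac_glc.mean == pytest.approx(1.0)
        assert lac_glc.sigma == pytest.approx(np.std([0.9, 1.1], ddof=1))
        assert lac_glc.sigma == pytest.approx(0.14142, rel=1e-3)

    def test_identical_replicates_collapse_to_equality(self):
        constraints = derive_ratio_constraints(self._table([1.0, 1.0]), EXCHANGE_MAP)
        assert constraints["g"][0].sigma == 0.0

    def test_concentration_difference_ratio(self):
        rows = [
            ("g", "glucose", b, 1, 25.0, 15.0) for b in (1, 2)
        ] + [
            ("g", "lactate", b, 1, 0.0, 18.0) for b in (1, 2)
        ] + [
            ("g", "glutamine", b, 1, 4.0, 2.0) for b in (1, 2)
        ] + [
            ("g", "glutamate", b, 1, 0.0, 1.0) for b in (1, 2)
        ]
        constraints = derive_ratio_constraints(_spent(rows), EXCHANGE_MAP)
        assert constraints["g"][0].mean == pytest.approx(1.8)   # (18-0)/(25-15)

    def test_single_bio_replicate_needs_sigma_default(self):
        table = self._table([1.0])
        with pytest.raises(ValueError, match="replicates"):
            derive_ratio_constraints(table, EXCHANGE_MAP)
        constraints = derive_ratio_constraints(table, EXCHANGE_MAP, sigma_default=0.2)
        assert constraints["g"][0].sigma == 0.2

    def test_tech_replicates_averaged_within_bio(self):
        rows = []
        for bio, techs in ((1, (0.8, 1.0, 1.2)), (2, (1.0, 1.0, 1.0))):
            for tech, ratio in enumerate(techs, start=1):
                rows += [
                    ("g", "glucose", bio, tech, 25.0, 15.0),
                    ("g", "lactate", bio, tech, 0.0, 10.0 * ratio),
                    ("g", "glutamine", bio, tech, 4.0, 2.0),
                    ("g", "glutamate", bio, tech, 0.0, 1.6),
                ]
        constraints = derive_ratio_constraints(_spent(rows), EXCHANGE_MAP)
        lac_glc = constraints["g"][0]
        assert lac_glc.mean == pytest.approx(1.0)     # bio means 1.0 and 1.0
        assert lac_glc.sigma == pytest.approx(0.0)


class TestAttach:
    def test_ratio_row_form(self, toy_model):
        from fluxcord.constraints import RatioConstraint

        out = attach_constraints(
            toy_model,
            [RatioConstraint("EX_lac_e", "EX_glc_e", mean=1.0, sigma=0.1)],
        )
        (row,) = out.extra_constraints
        assert row.coefficients == {"EX_lac_e": 1.0, "EX_glc_e": 1.0}
        assert (row.lower, row.upper) == (-0.1, 0.1)

    def test_yield_rows_use_printed_constants(self, toy_model):
        yc = GrowthYieldConstraint("BIOMASS", "EX_glc_e")
        out = attach_constraints(toy_model, [], yc)
        lo_row, hi_row = out.extra_constraints
        scale = 180.16 * 0.001
        assert lo_row.coefficients["BIOMASS"] == pytest.approx(0.131972)
        assert lo_row.coefficients["EX_glc_e"] == pytest.approx(3.90762e-5 * scale)
        assert hi_row.coefficients["EX_glc_e"] == pytest.approx(1.67998e-4 * scale)
        assert lo_row.lower == 0.0 and hi_row.upper == 0.0

    def test_no_ratios_leaves_only_yield_rows(self, toy_model):
        out = attach_constraints(toy_model, [], GrowthYieldConstraint("BIOMASS", "EX_glc_e"))
        assert len(out.extra_constraints) == 2
        assert len(toy_model.extra_constraints) == 0      # input untouched

    def test_unknown_flux_id(self, toy_model):
        with pytest.raises(ModelError):
            attach_constraints(toy_model, [], GrowthYieldConstraint("NOPE", "EX_glc_e"))


class TestFva:
    def test_linear_chain_everything_spans_uptake(self):
        irr = make_irreversible(chain_model())
        bounds = run_fva(irr)
        for rid in ["T_A", "R_AB", "T_B", "EX_B", "EX_A_reverse"]:
            assert bounds.loc[rid, "minimum"] == pytest.approx(0.0, abs=1e-9)
            assert bounds.loc[rid, "maximum"] == pytest.approx(10.0, abs=1e-6)

    def test_blocked_reaction_is_zero(self):
        model = chain_model()
        model.species.append(Species("D_c", "dead end", "c"))
        model.reactions.append(Reaction("R_dead", {"A_c": -1, "D_c": 1}, 0, 1000))
        bounds = run_fva(make_irreversible(model))
        assert bounds.loc["R_dead"].tolist() == [0.0, 0.0]

    def test_two_branches_share_uptake(self):
        model = chain_model()
        model.species.append(Species("C_c", "C", "c"))
        model.species.append(Species("C_e", "C", "e"))
        model.reactions += [
            Reaction("R_AC", {"A_c": -1, "C_c": 1}, 0, 1000),
            Reaction("T_C", {"C_c": -1, "C_e": 1}, 0, 1000),
            Reaction("EX_C", {"C_e": -1}, 0, 1000),
        ]
        flag_exchanges(model)
        bounds = run_fva(make_irreversible(model))
        assert bounds.loc["R_AB", "maximum"] == pytest.approx(10.0, abs=1e-6)
        assert bounds.loc["R_AC", "maximum"] == pytest.approx(10.0, abs=1e-6)

    def test_infeasible_model_reports(self):
        from fluxcord._lp import InfeasibleModelError
        from fluxcord.model import LinearConstraint

        model = make_irreversible(chain_model())
        model.extra_constraints.append(
            LinearConstraint("force", {"R_AB": 1.0}, lower=20.0, upper=30.0)
        )
        with pytest.raises(InfeasibleModelError):
            run_fva(model)


class TestRasBounds:
    def test_scaling_and_exemptions(self):
        from fluxcord.gpr import parse_gpr

        model = chain_model()
        model.reactions[2].gpr = parse_gpr("G1")        # R_AB
        irr = make_irreversible(model)
        fva_bounds = run_fva(irr)
        ras = pd.Series({"R_AB": 0.5})
        out = apply_ras_bounds(irr, ras, fva_bounds)
        assert out.get_reaction("R_AB").upper_bound == pytest.approx(5.0)
        assert out.get_reaction("T_A").upper_bound == pytest.approx(10.0)  # no GPR

        exempt = apply_ras_bounds(irr, pd.Series({"R_AB": 0.0}), fva_bounds,
                                  exempt_list=["R_AB"])
        assert exempt.get_reaction("R_AB").upper_bound == pytest.approx(10.0)

    def test_out_of_range_score_rejected(self):
        irr = make_irreversible(chain_model())
        with pytest.raises(ValueError):
            apply_ras_bounds(irr, pd.Series({"R_AB": 1.5}), run_fva(irr))

    def test_type3_never_widens(self, toy_model, planted, planted_run):
        """Feasible region after the transcriptomic layer is nested in
        the type-1+2 region for every group."""
        for group, cell in planted_run.cell_models.items():
            fva_bounds = cell.fva_bounds
            for rxn in cell.model.reactions:
                assert rxn.lower_bound >= fva_bounds.loc[rxn.id, "minimum"] - 1e-9
                assert rxn.upper_bound <= fva_bounds.loc[rxn.id, "maximum"] + 1e-9

    def test_all_ones_ras_is_noop(self, toy_model, planted):
        """With every normalized score forced to 1 the transcriptomic
        layer reproduces the type-1+2 region exactly."""
        _, data = planted
        ras_table = compute_ras_table(toy_model, data.expression)
        ras_table.normalized.loc[:, :] = 1.0
        cells = build_cell_relative_models(
            toy_model, ["A"], medium=data.medium, ras_table=ras_table,
            config=LayerConfig(type2=False),
        )
        cell = cells["A"]
        refva = run_fva(cell.model)
        pd.testing.assert_frame_equal(refva, cell.fva_bounds, atol=1e-6, check_exact=False)


class TestOrchestration:
    def test_type1_only_differs_in_exchange_bounds(self, toy_model, planted):
        _, data = planted
        ras_table = compute_ras_table(toy_model, data.expression)
        cells = build_cell_relative_models(
            toy_model, ["A", "B"], medium=data.medium, ras_table=ras_table,
            config=LayerConfig(type2=False, type3=False),
        )
        a, b = cells["A"].model, cells["B"].model
        assert a.reaction_ids == b.reaction_ids
        assert not a.extra_constraints and not b.extra_constraints

    def test_type3_without_type2_allowed(self, toy_model, planted):
        _, data = planted
        ras_table = compute_ras_table(toy_model, data.expression)
        cells = build_cell_relative_models(
            toy_model, ["A"], medium=data.medium, ras_table=ras_table,
            config=LayerConfig(type2=False, type3=True),
        )
        assert "A" in cells
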