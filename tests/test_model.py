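"""Constraint-based kernel: I/O, FBA, FVA, carbon accounting."""

import numpy as np
import pytest

from methylopath import model as mm
from methylopath.synthetic import CoreModelParams, generate_core_model
from conftest import make_toy_model
from _oracles import vertex_enumeration_lp


class TestEquationParsing:
    @pytest.mark.parametrize(
        "eq,expected,reversible",
        [
            ("2 A + B -> C", {"A": -2.0, "B": -1.0, "C": 1.0}, False),
            ("A <-> B", {"A": -1.0, "B": 1.0}, True),
            ("glc ->", {"glc": -1.0}, False),
            ("-> A", {"A": 1.0}, False),
            ("0.5 A + 0.5 A -> B", {"A": -1.0, "B": 1.0}, False),
        ],
    )
    def test_parse(self, eq, expected, reversible):
        stoich, rev = mm.parse_equation(eq)
        assert stoich == expected
        assert rev == reversible

    def test_parse_errors(self):
        with pytest.raises(mm.ModelError):
            mm.parse_equation("A + B")  # no arrow
        with pytest.raises(mm.ModelError):
            mm.parse_equation("two A -> B")

    def test_format_parse_round_trip(self):
        stoich = {"A": -2.0, "B": -1.0, "C": 1.5}
        eq = mm.format_equation(stoich, False)
        back, _ = mm.parse_equation(eq)
        assert back == stoich


class TestModelIO:
    def test_tabular_round_trip(self, tmp_path, core_model):
        mm.write_model(core_model, tmp_path / "core")
        back = mm.read_model(tmp_path / "core", format="tabular")
        assert back == core_model

    def test_dangling_metabolite_reported(self, tmp_path):
        d = tmp_path / "bad"
        d.mkdir()
        (d / "metabolites.tsv").write_text(
            "id\tname\tcompartment\tcarbon\tformula\nA\tA\tc\t1\t\n"
        )
        (d / "reactions.tsv").write_text(
            "id\tequation\tlb\tub\tname\nR1\tA -> Zmissing\t0\t10\t\n"
        )
        with pytest.raises(mm.ModelError, match="Zmissing"):
            mm.read_model(d, format="tabular")

    def test_duplicate_ids_rejected(self, tmp_path):
        d = tmp_path / "dup"
        d.mkdir()
        (d / "metabolites.tsv").write_text(
            "id\tname\tcompartment\tcarbon\tformula\nA\tA\tc\t1\t\nA\tA\tc\t1\t\n"
        )
        (d / "reactions.tsv").write_text("id\tequation\tlb\tub\tname\n")
        with pytest.raises(mm.ModelError, match="duplicate"):
            mm.read_model(d, format="tabular")

    def test_bad_bounds_rejected(self):
        with pytest.raises(mm.ModelError, match="bound"):
            mm.ModelReaction(id="R", stoichiometry={}, lower_bound=5, upper_bound=1)

    def test_stoichiometric_matrix_shape(self, linear_chain_model):
        S = linear_chain_model.stoichiometric_matrix()
        assert S.shape == (2, 3)
        assert S.loc["A", "EX_in"] == 1.0
        assert S.loc["A", "GROW"] == -1.0

    def test_sbml_round_trip_via_cobra(self, tmp_path, core_model):
        """Independent cross-check: serialise through COBRApy and confirm
        the FBA optimum is preserved by the SBML path."""
        cobra = pytest.importorskip("cobra")
        from cobra import Metabolite as CMet, Model as CModel, Reaction as CRxn

        cm = CModel("core")
        for met in core_model.metabolites.values():
            m = CMet(met.id, compartment=met.compartment or "c")
            cm.add_metabolites([m])
        for rxn in core_model.reactions.values():
            r = CRxn(rxn.id, lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound)
            cm.add_reactions([r])
            r.add_metabolites(
                {cm.metabolites.get_by_id(m): c for m, c in rxn.stoichiometry.items()}
            )
        cm.objective = "BIOMASS"
        path = tmp_path / "core.xml"
        cobra.io.write_sbml_model(cm, str(path))
        back = mm.read_model(path, format="sbml")
        sol = mm.fba(back, "BIOMASS", uptake={"EX_glc": 10.0})
        ref = mm.fba(core_model, "BIOMASS", uptake={"EX_glc": 10.0})
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(ref.objective_value, abs=1e-6)


class TestFBA:
    def test_starvation_gives_zero(self):
        # conventional exchange: A <- external, uptake is negative flux
        model = make_toy_model(
            reactions=[
                ("EX_in", {"A": -1.0}, -10.0, 0.0),
                ("GROW", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
                ("EX_out", {"B": -1.0}, 0.0, 1000.0),
            ],
            metabolites={"A": 1, "B": 1},
            objective={"GROW": 1.0},
        )
        sol = mm.fba(model, "GROW", uptake={"EX_in": 0.0})
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)
        fed = mm.fba(model, "GROW", uptake={"EX_in": 4.0})
        assert fed.objective_value == pytest.approx(4.0, abs=1e-9)

    def test_linear_chain_optimum_is_uptake(self, linear_chain_model):
        sol = mm.fba(linear_chain_model, "GROW")
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)
        S = linear_chain_model.stoichiometric_matrix().to_numpy()
        assert np.max(np.abs(S @ sol.fluxes.to_numpy())) < 1e-6

    def test_branch_with_carbon_loss_matches_vertex_oracle(self):
        # A splits to product (keeps carbon) or waste; waste route yields
        # cofactor required by the product route -> interior trade-off
        model = make_toy_model(
            reactions=[
                ("EX_in", {"A": 1.0}, 0.0, 10.0),
                ("TO_P", {"A": -1.0, "E": -1.0, "P": 1.0}, 0.0, 1000.0),
                ("BURN", {"A": -1.0, "E": 2.0, "W": 1.0}, 0.0, 1000.0),
                ("EX_p", {"P": -1.0}, 0.0, 1000.0),
                ("EX_w", {"W": -1.0}, 0.0, 1000.0),
            ],
            metabolites={"A": 1, "P": 1, "W": 1, "E": 0},
            objective={"EX_p": 1.0},
        )
        sol = mm.fba(model, "EX_p")
        S = model.stoichiometric_matrix().to_numpy()
        lb = [model.reactions[r].lower_bound for r in model.reaction_ids]
        ub = [model.reactions[r].upper_bound for r in model.reaction_ids]
        c = [0, 0, 0, 1, 0]
        want = vertex_enumeration_lp(S, lb, ub, c)
        assert sol.objective_value == pytest.approx(want, abs=1e-6)
        # analytic: uptake 10 = p + b, e balance 2b = p -> p = 20/3
        assert sol.objective_value == pytest.approx(20.0 / 3.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_toys_match_vertex_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_mets, n_rxns = 2, 5
        S = rng.integers(-2, 3, size=(n_mets, n_rxns)).astype(float)
        lb = np.where(rng.random(n_rxns) < 0.5, 0.0, -5.0)
        ub = np.full(n_rxns, 5.0)
        c = rng.integers(-1, 2, size=n_rxns).astype(float)
        mets = {f"M{i}": 0 for i in range(n_mets)}
        reactions = [
            (
                f"R{j}",
                {f"M{i}": S[i, j] for i in range(n_mets) if S[i, j] != 0},
                lb[j],
                ub[j],
            )
            for j in range(n_rxns)
        ]
        model = make_toy_model(reactions=reactions, metabolites=mets,
                               objective={f"R{j}": c[j] for j in range(n_rxns)})
        sol = mm.fba(model)
        want = vertex_enumeration_lp(S, lb, ub, c)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(want, abs=1e-6)

    def test_infeasible_returned_not_raised(self):
        model = make_toy_model(
            reactions=[
                ("EX_in", {"A": 1.0}, 0.0, 0.0),
                ("DRAIN", {"A": -1.0}, 1.0, 10.0),
            ],
            metabolites={"A": 1},
            objective={"DRAIN": 1.0},
        )
        sol = mm.fba(model, "DRAIN")
        assert sol.status == "infeasible"
        assert sol.objective_value is None

    def test_unknown_objective_or_uptake_raise(self, linear_chain_model):
        with pytest.raises(mm.ModelError):
            mm.fba(linear_chain_model, "NOPE")
        with pytest.raises(mm.ModelError):
            mm.fba(linear_chain_model, "GROW", uptake={"GROW": 1.0})

    def test_objective_invariant_under_reaction_permutation(self, core_model):
        ref = mm.fba(core_model, "BIOMASS", uptake={"EX_glc": 10.0})
        reordered = mm.MetabolicModel(
            metabolites=list(core_model.metabolites.values()),
            reactions=list(core_model.reactions.values())[::-1],
            objective=core_model.objective,
            biomass_reaction_id=core_model.biomass_reaction_id,
            tag_reaction_id=core_model.tag_reaction_id,
        )
        sol = mm.fba(reordered, "BIOMASS", uptake={"EX_glc": 10.0})
        assert sol.objective_value == pytest.approx(ref.objective_value, abs=1e-8)

    @pytest.mark.parametrize("k", [0.5, 2.0, 3.7])
    def test_lp_homogeneity_in_uptake(self, core_model, k):
        """Scaling the single substrate bound scales growth linearly once
        the constant maintenance demand is removed."""
        params = CoreModelParams(atp_maintenance=1e-9)
        model = generate_core_model(params)
        base = mm.fba(model, "BIOMASS", uptake={"EX_glc": 10.0})
        scaled = mm.fba(model, "BIOMASS", uptake={"EX_glc": 10.0 * k})
        assert scaled.objective_value == pytest.approx(
            k * base.objective_value, rel=1e-6
        )

    def test_steady_state_and_bounds_respected(self, core_model):
        sol = mm.fba(core_model, "BIOMASS", uptake={"EX_glyc": 10.0})
        S = core_model.stoichiometric_matrix().to_numpy()
        v = sol.fluxes.to_numpy()
        assert np.max(np.abs(S @ v)) < 1e-6
        for rid in core_model.reaction_ids:
            r = core_model.reactions[rid]
            lo = -10.0 if rid == "EX_glyc" else r.lower_bound
            assert lo - 1e-9 <= sol[rid] <= r.upper_bound + 1e-9


class TestFVA:
    def test_unique_optimum_gives_zero_width(self, linear_chain_model):
        ranges = mm.fva(linear_chain_model, "GROW", fraction=1.0)
        assert np.allclose(ranges["max"] - ranges["min"], 0.0, atol=1e-6)
        assert ranges.loc["GROW", "min"] == pytest.approx(10.0, abs=1e-6)

    def test_redundant_parallel_paths_span_full_range(self, parallel_paths_model):
        ranges = mm.fva(parallel_paths_model, "EX_out", fraction=1.0)
        for rid in ("P1", "P2"):
            assert ranges.loc[rid, "min"] == pytest.approx(0.0, abs=1e-6)
            assert ranges.loc[rid, "max"] == pytest.approx(10.0, abs=1e-6)

    def test_fraction_zero_equals_bounds_constrained_extremes(
        self, parallel_paths_model
    ):
        ranges = mm.fva(parallel_paths_model, "EX_out", fraction=0.0)
        assert ranges.loc["EX_out", "min"] == pytest.approx(0.0, abs=1e-6)
        assert ranges.loc["EX_out", "max"] == pytest.approx(10.0, abs=1e-6)

    def test_fba_flux_inside_fva_range(self, core_model):
        uptake = {"EX_glc": 10.0}
        sol = mm.fba(core_model, "BIOMASS", uptake=uptake)
        ranges = mm.fva(core_model, "BIOMASS", fraction=1.0, uptake=uptake,
                        reactions=["BIOMASS", "PGI", "OXPHOS", "EX_o2"])
        for rid in ranges.index:
            assert ranges.loc[rid, "min"] - 1e-6 <= sol[rid] <= ranges.loc[rid, "max"] + 1e-6

    def test_infeasible_base_raises(self):
        model = make_toy_model(
            reactions=[
                ("EX_in", {"A": 1.0}, 0.0, 0.0),
                ("DRAIN", {"A": -1.0}, 1.0, 10.0),
            ],
            metabolites={"A": 1},
            objective={"DRAIN": 1.0},
        )
        with pytest.raises(mm.ModelError):
            mm.fva(model, "DRAIN")


class TestAccounting:
    def test_full_conversion_gives_unit_yield(self):
        model = make_toy_model(
            reactions=[
                ("EX_s", {"S": -1.0}, -10.0, 0.0),
                ("CONV", {"S": -1.0, "P": 1.0}, 0.0, 1000.0),
                ("EX_p", {"P": -1.0}, 0.0, 1000.0),
                ("EX_o2", {"O": -1.0}, -1000.0, 1000.0),
            ],
            metabolites={"S": 2, "P": 2, "O": 0},
            objective={"EX_p": 1.0},
        )
        sol = mm.fba(model, "EX_p")
        cy, o2 = mm.yield_and_oxygen(sol, model, "EX_s", "EX_p")
        assert cy == pytest.approx(1.0)
        assert o2 == pytest.approx(0.0)

    def test_half_carbon_lost_as_co2(self):
        model = make_toy_model(
            reactions=[
                ("EX_s", {"S": -1.0}, -10.0, 0.0),
                ("SPLIT", {"S": -1.0, "P": 1.0, "C": 1.0}, 0.0, 1000.0),
                ("EX_p", {"P": -1.0}, 0.0, 1000.0),
                ("EX_c", {"C": -1.0}, 0.0, 1000.0),
            ],
            metabolites={"S": 2, "P": 1, "C": 1},
            objective={"EX_p": 1.0},
        )
        sol = mm.fba(model, "EX_p")
        cy, _ = mm.yield_and_oxygen(sol, model, "EX_s", "EX_p", oxygen_exchange="none")
        assert cy == pytest.approx(0.5)

    def test_zero_substrate_flux_raises(self, core_model):
        sol = mm.fba(core_model, "BIOMASS", uptake={"EX_glc": 10.0})
        with pytest.raises(mm.ModelError, match="zero"):
            mm.yield_and_oxygen(sol, core_model, "EX_meoh", "BIOMASS")

    def test_carbon_balance_flags_constructed_imbalance(self):
        model = make_toy_model(
            reactions=[
                ("EX_a", {"A": 1.0}, 0.0, 10.0),
                ("LOSS", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
                ("EX_b", {"B": -1.0}, 0.0, 1000.0),
            ],
            metabolites={"A": 3, "B": 2},
        )
        assert mm.carbon_balance_check(model) == ["LOSS"]

    def test_balanced_toy_is_clean(self, linear_chain_model):
        assert mm.carbon_balance_check(linear_chain_model) == []

    def test_yield_bounded_by_one_on_random_balanced_models(self, core_model):
        """On a carbon-balanced network no product can exceed 1 cmol/cmol."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            uptake = float(rng.uniform(2.0, 20.0))
            sol = mm.fba(core_model, "BIOMASS", uptake={"EX_glc": uptake})
            if sol.status != "optimal" or sol.objective_value < 1e-9:
                continue
            cy, _ = mm.yield_and_oxygen(sol, core_model, "EX_glc", "BIOMASS")
            assert 0.0 <= cy <= 1.0 + 1e-9
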