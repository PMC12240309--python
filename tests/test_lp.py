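import numpy as np
import pytest

from colongem import (
    FluxRange,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    classify_exchange,
    delete_genes,
    find_blocked,
    fva,
    knockout_screen,
    optimize,
)
from oracles import brute_force_fba_max, random_network


class TestOptimize:
    def test_chain_bottleneck(self, chain_model):
        sol = optimize(chain_model)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(10.0)

    def test_invalid_bounds_raise_before_solve(self, chain_model):
        chain_model.reactions["AB"].lower_bound = 5
        chain_model.reactions["AB"].upper_bound = 1
        with pytest.raises(ModelValidationError):
            optimize(chain_model)

    def test_infeasible_surfaces_as_status(self):
        m = MetabolicModel()
        m.add_metabolite(Metabolite("A[c]"))
        m.add_reaction(Reaction("force", stoichiometry={"A[c]": 1},
                                lower_bound=1, upper_bound=2, kind="sink"))
        sol = optimize(m, objective={"force": 1.0})
        assert sol.status == "infeasible" and sol.fluxes == {}

    def test_scfa_oxidation_yield(self, template):
        """One unit of luminal butyrate powers 5 units of ATP hydrolysis."""
        m = template.copy()
        from colongem import apply_medium

        apply_medium(m, {"but[lu]": 1.0, "h2o[e]": 1000.0}, inplace=True)
        sol = optimize(m, objective={"ATPM": 1.0})
        assert sol.objective_value == pytest.approx(5.0, abs=1e-6)

    def test_objective_invariant_under_permutation(self, template, branch_model):
        rng = np.random.default_rng(1)
        for model in (template, branch_model):
            base = optimize(model).objective_value
            shuffled = MetabolicModel(id=model.id, unit=model.unit)
            mets = list(model.metabolites.values())
            rxns = list(model.reactions.values())
            for met in [mets[i] for i in rng.permutation(len(mets))]:
                shuffled.add_metabolite(met.copy())
            for rxn in [rxns[i] for i in rng.permutation(len(rxns))]:
                shuffled.add_reaction(rxn.copy())
            shuffled.objective = dict(model.objective)
            assert optimize(shuffled).objective_value == pytest.approx(base, abs=1e-8)

    def test_matches_vertex_enumeration_oracle(self):
        """LP optimum equals brute-force vertex enumeration on small nets."""
        rng = np.random.default_rng(7)
        from colongem.core import StoichiometricSystem
        from colongem.lp import _solve_lp

        for _ in range(15):
            S, lb, ub, c = random_network(rng)
            sys_ = StoichiometricSystem(S, lb, ub, c, {}, {}, [], [])
            res = _solve_lp(sys_, c, maximize=True)
            assert res.status == 0
            assert -res.fun == pytest.approx(brute_force_fba_max(S, lb, ub, c),
                                             abs=1e-6)

    def test_matches_cobra_fba(self, template):
        """Independent cross-check of the template optimum against cobra."""
        from colongem.core import to_cobra

        cm = to_cobra(template)
        assert cm.slim_optimize() == pytest.approx(
            optimize(template).objective_value, abs=1e-6
        )


class TestFVA:
    def test_unique_optimum_pins_interval(self, chain_model):
        (rng,) = fva(chain_model, ["AB"], fraction_of_optimum=1.0)
        assert rng.min_flux == pytest.approx(10.0, abs=1e-6)
        assert rng.max_flux == pytest.approx(10.0, abs=1e-6)

    def test_unconstrained_interval(self, chain_model):
        (rng,) = fva(chain_model, ["AB"], fraction_of_optimum=0.0)
        assert (rng.min_flux, rng.max_flux) == pytest.approx((0.0, 10.0), abs=1e-6)

    def test_parallel_branches_split_freely(self, branch_model):
        for rid in ("AB1", "AB2"):
            (rng,) = fva(branch_model, [rid], fraction_of_optimum=1.0)
            assert (rng.min_flux, rng.max_flux) == pytest.approx((0.0, 10.0), abs=1e-6)

    def test_fba_flux_within_fva_interval(self, template):
        sol = optimize(template)
        for rng in fva(template, fraction_of_optimum=1.0):
            v = sol.fluxes[rng.reaction_id]
            assert rng.min_flux - 1e-6 <= v <= rng.max_flux + 1e-6

    def test_matches_cobra_fva(self, branch_model):
        from cobra.flux_analysis import flux_variability_analysis

        from colongem.core import to_cobra

        ours = {r.reaction_id: r for r in fva(branch_model, fraction_of_optimum=1.0)}
        theirs = flux_variability_analysis(to_cobra(branch_model),
                                           fraction_of_optimum=1.0)
        for rid, row in theirs.iterrows():
            assert ours[rid].min_flux == pytest.approx(row["minimum"], abs=1e-6)
            assert ours[rid].max_flux == pytest.approx(row["maximum"], abs=1e-6)


class TestClassifyExchange:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [
            (-1.0, 0.0, "uptake_only"),
            (-1.0, 42.15, "both"),
            (0.0, 24.50, "secretion_only"),
            (0.0, 0.0, "inactive"),
            (-1e-9, 1e-9, "inactive"),
        ],
    )
    def test_direction_rule(self, lo, hi, expected):
        assert classify_exchange(FluxRange("EX", lo, hi)) == expected


class TestGeneDeletion:
    def test_sole_gene_disables_chain(self, chain_model):
        ko = delete_genes(chain_model, {"g1"})
        assert ko.reactions["AB"].upper_bound == 0
        assert optimize(ko).objective_value == pytest.approx(0.0, abs=1e-9)
        # original untouched
        assert chain_model.reactions["AB"].upper_bound == 1000

    def test_isozyme_survives_single_deletion(self):
        m = MetabolicModel()
        m.add_metabolite(Metabolite("A[c]"))
        m.add_reaction(Reaction("r", stoichiometry={"A[c]": -1}, gpr="g1 or g2",
                                upper_bound=10, kind="sink"))
        assert delete_genes(m, {"g1"}).reactions["r"].upper_bound == 10
        assert delete_genes(m, {"g1", "g2"}).reactions["r"].upper_bound == 0

    def test_complex_fails_on_any_subunit(self):
        m = MetabolicModel()
        m.add_metabolite(Metabolite("A[c]"))
        m.add_reaction(Reaction("r", stoichiometry={"A[c]": -1}, gpr="g1 and g2",
                                upper_bound=10, kind="sink"))
        assert delete_genes(m, {"g1"}).reactions["r"].upper_bound == 0

    def test_empty_deletion_is_identity(self, template):
        assert delete_genes(template, set()).equal_ids(template)

    def test_monotone_in_deleted_set(self, template):
        genes = sorted(template.genes)
        prev = optimize(template).objective_value
        deleted = set()
        for g in genes[:6]:
            deleted.add(g)
            val = optimize(delete_genes(template, deleted)).objective_value
            assert val <= prev + 1e-9
            prev = val


class TestKnockoutScreen:
    def test_full_loss_gives_ratio_one(self, chain_model):
        rec = {r.gene_id: r for r in knockout_screen(chain_model,
                                                     target_reaction="BIOMASS")}
        assert rec["g1"].ratio == pytest.approx(1.0)
        assert rec["g1"].wt_flux == pytest.approx(10.0)

    def test_uninvolved_gene_has_zero_ratio(self, branch_model):
        rec = {r.gene_id: r for r in knockout_screen(
            branch_model, ["g_hi"], target_reaction="BIOMASS")}
        assert rec["g_hi"].ratio == pytest.approx(0.0)  # parallel branch covers

    def test_zero_wildtype_flagged_undefined(self, chain_model):
        chain_model.reactions["EX_A_e"].lower_bound = 0  # starve the chain
        rec = knockout_screen(chain_model, ["g1"], target_reaction="BIOMASS")[0]
        assert rec.undefined and rec.ratio is None


class TestFindBlocked:
    def test_open_chain_has_no_blocked(self, chain_model):
        assert find_blocked(chain_model) == []

    def test_dead_end_detected(self, chain_model):
        chain_model.add_metabolite(Metabolite("C[c]"))
        chain_model.add_reaction(
            Reaction("BC", stoichiometry={"B[c]": -1, "C[c]": 1}, upper_bound=1000)
        )
        assert find_blocked(chain_model) == ["BC"]

    def test_closed_model_blocks_everything(self, chain_model):
        chain_model.reactions["EX_A_e"].lower_bound = 0
        chain_model.reactions["BIOMASS"].upper_bound = 0
        blocked = set(find_blocked(chain_model))
        assert blocked == set(chain_model.reactions)
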