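import numpy as np
import pandas as pd
import pytest

from colongem import (
    ExpressionMatrix,
    SyntheticSpec,
    expression_cutoff,
    gene_activity,
    imat_extract,
    load_expression,
    make_expression,
    make_toy_template,
    optimize,
    reaction_scores,
    ubiquity_scores,
)
from colongem.core import StoichiometricSystem
from colongem.extraction import _imat_milp
from colongem.lp import find_blocked
from colongem.synth import PLANTED_REACTIONS
from oracles import brute_force_imat_objective, random_network


def _matrix(values, genes=None, samples=None, groups=None):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples),
                            groups or {})


class TestExpressionPreprocessing:
    def test_percentile_interpolation(self):
        m = _matrix([[v] for v in range(1, 11)])
        # rank = 1 + 0.3 * 9 = 3.7 on sorted 1..10
        assert expression_cutoff(m, 30) == pytest.approx(3.7)

    def test_constant_matrix_and_p0(self):
        m = _matrix([[5.0, 5.0], [5.0, 5.0]])
        assert expression_cutoff(m, 30) == 5.0
        m2 = _matrix([[1.0], [9.0]])
        assert expression_cutoff(m2, 0) == 1.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            expression_cutoff(_matrix(np.empty((0, 0))))

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            _matrix([[-1.0]])

    @pytest.mark.parametrize("row,expected", [([5, 5, 5, 1], 0.75),
                                              ([1, 1, 1, 1], 0.0),
                                              ([5, 5, 5, 5], 1.0)])
    def test_ubiquity_fraction_above_cutoff(self, row, expected):
        m = _matrix([row])
        assert ubiquity_scores(m, cutoff=2.0).iloc[0] == pytest.approx(expected)

    @pytest.mark.parametrize("median,cutoff,expected",
                             [(8.0, 4.0, 3.0), (3.0, 4.0, 0.0), (4.0, 4.0, 2.0)])
    def test_activity_log2_with_cutoff(self, median, cutoff, expected):
        m = _matrix([[median]])
        assert gene_activity(m, cutoff).iloc[0] == pytest.approx(expected)

    def test_activity_zero_iff_below_cutoff(self):
        m = _matrix([[2.0], [8.0]])
        act = gene_activity(m, cutoff=4.0)
        assert act.iloc[0] == 0.0 and act.iloc[1] > 0.0

    def test_expression_tsv_round_trip(self, expression, tmp_path):
        vpath, gpath = tmp_path / "expr.tsv", tmp_path / "groups.tsv"
        expression.values.to_csv(vpath, sep="\t")
        pd.DataFrame({"sample": list(expression.groups),
                      "group": list(expression.groups.values())}
                     ).to_csv(gpath, sep="\t", index=False)
        loaded = load_expression(vpath, gpath)
        pd.testing.assert_frame_equal(loaded.values, expression.values)
        assert loaded.groups == expression.groups


class TestReactionScores:
    def test_gpr_folding(self, branch_model):
        scores = reaction_scores(branch_model, {"g_hi": 3.0, "g_lo": 1.0})
        assert scores.scores["AB1"] == 3.0 and scores.scores["AB2"] == 1.0

    def test_and_or_folding(self):
        m = make_toy_template(SyntheticSpec(seed=0))
        acts = dict.fromkeys(m.genes, 0.0)
        acts.update({"g_glct": 3.0, "g_mid1": 1.0})
        scores = reaction_scores(m, acts, high_threshold=0.5)
        assert scores.scores["GLCt"] == 3.0  # OR takes the max

    def test_empty_gpr_unscored(self, chain_model):
        scores = reaction_scores(chain_model, {"g1": 2.0, "g_t": 2.0})
        assert "EX_A_e" not in scores.scores
        assert "EX_A_e" not in scores.high_set | scores.low_set

    def test_partition_disjoint_and_low_is_zero_score(self, template, expression):
        col = expression.sample_column("D1")
        act = gene_activity(col, expression_cutoff(col))
        scores = reaction_scores(template, act)
        assert not scores.high_set & scores.low_set
        assert all(scores.scores[r] == 0.0 for r in scores.low_set)


class TestImat:
    def test_parallel_branch_prefers_high_scoring_route(self, branch_model):
        scores = reaction_scores(branch_model, {"g_hi": 5.0, "g_lo": 0.0},
                                 high_threshold=1.0)
        assert scores.high_set == {"AB1"} and scores.low_set == {"AB2"}
        result = imat_extract(branch_model, scores, eps=1.0)
        assert result.objective == pytest.approx(2.0)  # AB1 active + AB2 silenced
        assert "AB1" in result.context.reactions
        assert "AB2" not in result.context.reactions

    def test_no_scored_reactions_keeps_consistent_subset(self, branch_model):
        scores = reaction_scores(branch_model, {}, high_threshold=1.0)
        scores.high_set.clear()
        scores.low_set.clear()
        result = imat_extract(branch_model, scores)
        assert set(result.context.reactions) == set(branch_model.reactions)

    def test_structurally_blocked_high_reaction_loses_its_binary(self, branch_model):
        blocked = branch_model.copy()
        blocked.reactions["AB1"].upper_bound = 0.0  # can never reach eps
        scores = reaction_scores(blocked, {"g_hi": 5.0, "g_lo": 5.0},
                                 high_threshold=1.0)
        assert scores.high_set == {"AB1", "AB2"}
        result = imat_extract(blocked, scores)
        assert result.objective == pytest.approx(1.0)
        assert "AB1" not in result.active_high

    def test_milp_matches_enumeration_oracle(self):
        """MILP objective equals exhaustive binary enumeration (small nets)."""
        rng = np.random.default_rng(11)
        for _ in range(8):
            S, lb, ub, c = random_network(rng)
            n = S.shape[1]
            k = min(n, 4)
            idx = [int(j) for j in rng.permutation(n)[:k]]
            high, low = idx[: k // 2], idx[k // 2:]
            sys_ = StoichiometricSystem(S, lb, ub, c, {},
                                        {str(j): j for j in range(n)},
                                        [str(j) for j in range(n)], [])
            res = _imat_milp(sys_, high, low, eps=1.0)
            assert res.success
            assert -res.fun == pytest.approx(
                brute_force_imat_objective(S, lb, ub, high, low, 1.0), abs=1e-6
            )

    def test_context_is_flux_consistent_and_feasible(self, study):
        for model in study.context_models.values():
            assert find_blocked(model) == []
            assert optimize(model).objective_value > 0

    def test_ground_truth_recovery_across_seeds(self):
        """Disease models drop the planted pathway; healthy models keep it."""
        from colongem import build_context_models

        excluded = kept = total_d = total_h = 0
        for seed in range(5):
            spec = SyntheticSpec(seed=seed)
            template = make_toy_template(spec)
            study = build_context_models(template, make_expression(spec, template))
            for sample, model in study.context_models.items():
                in_model = sum(r in model.reactions for r in PLANTED_REACTIONS)
                if study.groups[sample] == "disease":
                    excluded += len(PLANTED_REACTIONS) - in_model
                    total_d += len(PLANTED_REACTIONS)
                else:
                    kept += in_model
                    total_h += len(PLANTED_REACTIONS)
        assert excluded / total_d >= 0.9
        assert kept / total_h >= 0.9
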