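import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colongem import (
    MergeConflictError,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    add_lumen_module,
    apply_medium,
    build_system,
    evaluate_gpr,
    load_model,
    merge_consensus,
    model_overlap,
    score_gpr,
    write_model,
)
from colongem.core import parse_equation


class TestGPR:
    @pytest.mark.parametrize(
        "rule,states,expected",
        [
            ("g1 and g2", {"g1": True, "g2": False}, False),
            ("g1 and g2", {"g1": True, "g2": True}, True),
            ("g1 or g2", {"g1": True, "g2": False}, True),
            ("g1 or g2", {"g1": False, "g2": False}, False),
            ("", {"g1": False}, True),  # empty rule: not gene-controlled
            ("(g1 and g2) or g3", {"g3": True}, True),  # missing genes are off
            ("g1 and (g2 or g3)", {"g1": True, "g3": True}, True),
        ],
    )
    def test_boolean_semantics(self, rule, states, expected):
        assert evaluate_gpr(rule, states) is expected

    def test_malformed_rule_raises(self):
        from colongem import GPRSyntaxError

        for bad in ["g1 and", "(g1 or g2", "and g1", "g1 g2"]:
            with pytest.raises(GPRSyntaxError):
                evaluate_gpr(bad, {})

    @pytest.mark.parametrize(
        "rule,acts,expected",
        [
            ("g1 and g2", {"g1": 3.0, "g2": 1.0}, 1.0),  # complex: min
            ("g1 or g2", {"g1": 3.0, "g2": 1.0}, 3.0),  # isozymes: max
            ("g1 and g2", {"g1": 3.0}, 0.0),  # missing gene scores 0
        ],
    )
    def test_activity_folding(self, rule, acts, expected):
        assert score_gpr(rule, acts) == expected

    def test_empty_rule_is_unscored(self):
        assert score_gpr("", {"g1": 3.0}) is None

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=6))
    def test_conjunction_matches_python_all(self, states):
        genes = {f"g{i}": s for i, s in enumerate(states)}
        rule = " and ".join(genes)
        assert evaluate_gpr(rule, genes) == all(states)


class TestModelTypes:
    def test_compartment_from_id_suffix(self):
        met = Metabolite("ac[lu]")
        assert met.compartment == "lu" and met.base_id == "ac"

    def test_compartment_mismatch_raises(self):
        with pytest.raises(ModelValidationError):
            Metabolite("ac[lu]", compartment="c")

    def test_bounds_violation_rejected(self, chain_model):
        chain_model.reactions["AB"].lower_bound = 5
        chain_model.reactions["AB"].upper_bound = 1
        with pytest.raises(ModelValidationError):
            chain_model.validate()

    def test_dangling_reference_rejected(self):
        m = MetabolicModel()
        m.add_metabolite(Metabolite("A[c]"))
        with pytest.raises(ModelValidationError):
            m.add_reaction(Reaction("r", stoichiometry={"A[c]": -1, "Z[c]": 1}))

    def test_exchange_kind_requires_boundary_compartment(self):
        m = MetabolicModel()
        m.add_metabolite(Metabolite("A[c]"))
        with pytest.raises(ModelValidationError):
            m.add_reaction(
                Reaction("EX", stoichiometry={"A[c]": -1}, kind="exchange")
            )

    def test_genes_derived_from_gprs(self, chain_model):
        assert chain_model.genes == {"g_t", "g1"}


class TestBuildSystem:
    def test_conversion_column_signs(self, chain_model):
        sys_ = build_system(chain_model)
        j = sys_.col_index["AB"]
        assert sys_.S[sys_.row_index["A[c]"], j] == -1
        assert sys_.S[sys_.row_index["B[c]"], j] == 1

    def test_exchange_single_negative_entry(self, chain_model):
        sys_ = build_system(chain_model)
        col = sys_.S[:, sys_.col_index["EX_A_e"]]
        assert np.count_nonzero(col) == 1 and col[sys_.row_index["A[e]"]] == -1

    def test_template_shape_matches_construction(self, template):
        sys_ = build_system(template)
        assert sys_.S.shape == (len(template.metabolites), len(template.reactions))


class TestMergeConsensus:
    def _draft(self, rids):
        m = MetabolicModel()
        m.add_metabolite(Metabolite("A[c]"))
        m.add_metabolite(Metabolite("B[c]"))
        for rid in rids:
            m.add_reaction(
                Reaction(rid, stoichiometry={"A[c]": -1, "B[c]": 1}, upper_bound=1000)
            )
        return m

    def test_excludes_reactions_unique_to_one_draft(self):
        drafts = [
            ("P", self._draft(["r1", "r2"])),
            ("I", self._draft(["r1", "r3"])),
            ("T", self._draft(["r1", "r4"])),
            ("C", self._draft(["r2", "r3"])),
        ]
        merged = merge_consensus(drafts, exclude_unique_from="T")
        assert set(merged.reactions) == {"r1", "r2", "r3"}

    def test_identical_drafts_merge_to_same_set(self):
        drafts = [(lab, self._draft(["r1", "r2"])) for lab in "ABCD"]
        assert set(merge_consensus(drafts, "D").reactions) == {"r1", "r2"}

    def test_empty_excluded_draft_gives_plain_union(self):
        drafts = [
            ("A", self._draft(["r1"])),
            ("B", self._draft(["r2"])),
            ("T", self._draft([])),
        ]
        assert set(merge_consensus(drafts, "T").reactions) == {"r1", "r2"}

    def test_order_invariance_of_non_excluded_drafts(self):
        a = [("A", self._draft(["r1"])), ("B", self._draft(["r2"])),
             ("T", self._draft(["r3"]))]
        b = [a[1], a[0], a[2]]
        assert merge_consensus(a, "T").equal_ids(merge_consensus(b, "T"))

    def test_conflicting_stoichiometry_raises(self):
        d1 = self._draft(["r1"])
        d2 = MetabolicModel()
        d2.add_metabolite(Metabolite("A[c]"))
        d2.add_metabolite(Metabolite("B[c]"))
        d2.add_reaction(
            Reaction("r1", stoichiometry={"A[c]": -2, "B[c]": 1}, upper_bound=1000)
        )
        with pytest.raises(MergeConflictError):
            merge_consensus([("a", d1), ("b", d2)])

    def test_template_supplies_bounds_and_gpr(self):
        template = self._draft(["r1", "r2"])
        template.reactions["r1"].gpr = "gT"
        template.reactions["r1"].lower_bound = -7
        merged = merge_consensus(
            [("a", self._draft(["r1"])), ("b", self._draft(["r1"]))],
            template=template,
        )
        assert merged.reactions["r1"].gpr == "gT"
        assert merged.reactions["r1"].lower_bound == -7


class TestLumenModule:
    def test_adds_species_transport_and_exchange(self, chain_model):
        before = (len(chain_model.metabolites), len(chain_model.reactions))
        out = add_lumen_module(chain_model, ["A[e]"])
        assert len(out.metabolites) == before[0] + 1
        assert len(out.reactions) == before[1] + 2
        assert out.reactions["T_A_lu"].stoichiometry == {"A[lu]": -1.0, "A[e]": 1.0}
        assert out.reactions["EX_A_lu"].kind == "exchange"

    def test_idempotent(self, chain_model):
        once = add_lumen_module(chain_model, ["A[e]"])
        twice = add_lumen_module(once, ["A[e]"])
        assert once.equal_ids(twice)

    def test_empty_list_is_identity(self, chain_model):
        assert add_lumen_module(chain_model, []).equal_ids(chain_model)

    def test_missing_extracellular_species_raises(self, chain_model):
        with pytest.raises(ModelValidationError):
            add_lumen_module(chain_model, ["xyz[e]"])

    def test_transport_is_mass_balanced(self, chain_model):
        out = add_lumen_module(chain_model, ["A[e]"])
        assert sum(out.reactions["T_A_lu"].stoichiometry.values()) == 0


class TestApplyMedium:
    def test_listed_metabolite_sets_uptake_bound(self, chain_model):
        out = apply_medium(chain_model, {"A[e]": 1.0})
        assert out.reactions["EX_A_e"].lower_bound == -1.0
        assert out.reactions["EX_A_e"].upper_bound == 1000

    def test_empty_medium_closes_all_uptake(self, template):
        out = apply_medium(template, {})
        assert all(r.lower_bound == 0 for r in out.exchanges())

    def test_custom_bound(self, chain_model):
        out = apply_medium(chain_model, {"A[e]": 10})
        assert out.reactions["EX_A_e"].lower_bound == -10

    def test_metabolite_without_exchange_raises(self, chain_model):
        with pytest.raises(ModelValidationError):
            apply_medium(chain_model, {"B[c]": 1.0})


class TestOverlap:
    def test_self_overlap_is_complete(self, template):
        ov = model_overlap(template, template)
        assert all(v == 100.0 for v in ov.pct_of_A.values())

    def test_subset_and_disjoint(self, chain_model, template):
        sub = chain_model.subset(["EX_A_e", "At"])
        ov = model_overlap(sub, chain_model)
        assert ov.pct_of_A["reactions"] == 100.0
        assert model_overlap(chain_model, template).shared_reactions == 0

    def test_partial_counts(self):
        def mk(rids):
            m = MetabolicModel()
            m.add_metabolite(Metabolite("A[c]"))
            for rid in rids:
                m.add_reaction(Reaction(rid, stoichiometry={"A[c]": -1}, kind="sink"))
            return m

        ov = model_overlap(mk(["r1", "r2", "r3"]), mk(["r2", "r3", "r4"]))
        assert ov.shared_reactions == 2
        assert ov.pct_of_A["reactions"] == pytest.approx(66.7, abs=0.05)


class TestIO:
    def test_minimal_json_model(self, tmp_path):
        doc = {
            "id": "mini",
            "metabolites": [{"id": "A[c]"}, {"id": "B[c]"}],
            "reactions": [
                {"id": "r1", "stoichiometry": {"A[c]": -1}, "lower_bound": -1,
                 "upper_bound": 1, "kind": "sink"},
                {"id": "r2", "stoichiometry": {"A[c]": -1, "B[c]": 1},
                 "upper_bound": 10},
                {"id": "r3", "stoichiometry": {"B[c]": -1}, "upper_bound": 10,
                 "kind": "demand"},
            ],
        }
        path = tmp_path / "mini.json"
        path.write_text(json.dumps(doc))
        model = load_model(path)
        assert len(model.reactions) == 3 and len(model.metabolites) == 2

    @pytest.mark.parametrize("fmt,name", [("json", "m.json"), ("sbml", "m.xml"),
                                          ("tables", "tables")])
    def test_round_trip_identity(self, template, tmp_path, fmt, name):
        path = tmp_path / name
        write_model(template, path, format=fmt)
        assert load_model(path, format=fmt).equal_ids(template)

    def test_json_stable_under_reserialization(self, template, tmp_path):
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_model(template, p1)
        write_model(load_model(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_sbml_is_fbc_v2(self, template, tmp_path):
        path = tmp_path / "m.xml"
        write_model(template, path, format="sbml")
        text = path.read_text()
        assert "fbc/version2" in text and "geneProductAssociation" in text

    def test_unresolved_reference_raises(self, tmp_path):
        doc = {"id": "bad", "metabolites": [],
               "reactions": [{"id": "r", "stoichiometry": {"A[c]": -1}}]}
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelValidationError):
            load_model(path)

    def test_tables_row_count_matches_reactions(self, template, tmp_path):
        import pandas as pd

        out = tmp_path / "tables"
        write_model(template, out, format="tables")
        rows = pd.read_csv(out / "reactions.tsv", sep="\t")
        assert len(rows) == len(template.reactions)
        assert len(load_model(out).reactions) == len(rows)

    @pytest.mark.parametrize(
        "eq,expected",
        [
            ("A[c]:-1;B[c]:1", {"A[c]": -1, "B[c]": 1}),
            ("2 A[c] + B[c] -> C[c]", {"A[c]": -2, "B[c]": -1, "C[c]": 1}),
            ("A[e] ->", {"A[e]": -1}),
            ("A[c] <-> B[c]", {"A[c]": -1, "B[c]": 1}),
        ],
    )
    def test_equation_parsing(self, eq, expected):
        assert parse_equation(eq) == expected
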