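import numpy as np
import pytest

from oracles import floyd_warshall  # noqa: F401  (used by topology tests too)
from rhizomod.network_model import (
    CURRENCY_METABOLITES, MetabolicModel, ModelValidationError, Reaction,
    ReactionParseError, active_subnetwork, parse_reaction_equation,
    project_metabolite_graph, read_model, stoichiometric_matrix, write_model,
)


class TestParseReactionEquation:
    @pytest.mark.parametrize("text,stoich,reversible", [
        ("atp[c] + h2o[c] -> adp[c] + pi[c]",
         {"atp[c]": -1, "h2o[c]": -1, "adp[c]": 1, "pi[c]": 1}, False),
        ("a[c] <=> a[e]", {"a[c]": -1, "a[e]": 1}, True),
        ("2 h[c] + x[c] -> y[c]", {"h[c]": -2, "x[c]": -1, "y[c]": 1}, False),
        ("a[c] + a[c] -> b[c]", {"a[c]": -2, "b[c]": 1}, False),
        ("-> a[c]", {"a[c]": 1}, False),           # exchange/source
        ("a[c] -> ", {"a[c]": -1}, False),          # sink
        ("a[c] + b[c] -> a[c] + c[c]", {"b[c]": -1, "c[c]": 1}, False),  # net-summed
    ])
    def test_dialect(self, text, stoich, reversible):
        got_stoich, got_rev = parse_reaction_equation(text)
        assert got_stoich == pytest.approx(stoich)
        assert got_rev is reversible

    @pytest.mark.parametrize("text", [
        "a[c] b[c]",                 # no arrow
        "a[c] -> b[c] -> c[c]",      # duplicate arrow
        "a[c] <=> b[c] -> c[c]",     # mixed arrows
        "two a[c] -> b[c]",          # non-numeric coefficient
    ])
    def test_malformed_equations_raise(self, text):
        with pytest.raises(ReactionParseError):
            parse_reaction_equation(text)


class TestModelValidation:
    def test_currency_membership_is_pure_function_of_id(self):
        model = MetabolicModel.from_reactions([
            Reaction(id="R1", stoichiometry={"h2o[c]": -1.0, "mal-L[c]": 1.0})])
        by_id = {m.id: m for m in model.metabolites}
        assert by_id["h2o[c]"].is_currency
        assert not by_id["mal-L[c]"].is_currency

    def test_validation_collects_all_offenders(self):
        reactions = [
            Reaction(id="R1", stoichiometry={"a[c]": -1.0, "b[c]": 1.0},
                     lower_bound=5.0, upper_bound=1.0),
            Reaction(id="R1", stoichiometry={"a[c]": -1.0, "b[c]": 1.0}),
        ]
        model = MetabolicModel(
            metabolites=[type(m)(**vars(m)) for m in
                         MetabolicModel.from_reactions(
                             [reactions[1]]).metabolites],
            reactions=reactions)
        with pytest.raises(ModelValidationError) as err:
            model.validate()
        text = str(err.value)
        assert "duplicate reaction ids" in text and "lower bound" in text

    def test_compartment_suffix_is_required(self):
        with pytest.raises(ModelValidationError, match="compartment"):
            MetabolicModel.from_reactions([
                Reaction(id="R1", stoichiometry={"naked": -1.0, "b[c]": 1.0})])


class TestStoichiometricMatrix:
    def test_single_and_reversible_columns(self):
        model = MetabolicModel.from_reactions([
            Reaction(id="R1", stoichiometry={"a[c]": -1.0, "b[c]": 1.0}),
            Reaction(id="R2", stoichiometry={"a[c]": -1.0, "b[c]": 1.0},
                     reversible=True, lower_bound=-10.0),
        ])
        S = stoichiometric_matrix(model)
        # reversibility lives in bounds: both columns are (-1, +1)
        ia, ib = model.metabolite_index("a[c]"), model.metabolite_index("b[c]")
        assert S[ia, 0] == S[ia, 1] == -1.0
        assert S[ib, 0] == S[ib, 1] == 1.0

    def test_toy_chain_matches_term_enumeration_oracle(self):
        equations = {"R1": "2 a[c] + b[c] -> c[c]",
                     "R2": "c[c] -> d[c]",
                     "R3": "d[c] + b[c] <=> e[c]"}
        reactions = []
        for rid, eq in equations.items():
            stoich, rev = parse_reaction_equation(eq)
            reactions.append(Reaction(id=rid, stoichiometry=stoich, reversible=rev,
                                      lower_bound=-10.0 if rev else 0.0))
        model = MetabolicModel.from_reactions(reactions)
        S = stoichiometric_matrix(model)
        # oracle: re-enumerate the terms of each equation string by hand
        expected = np.zeros_like(S)
        for j, (rid, eq) in enumerate(equations.items()):
            sides = eq.replace("<=>", "->").split("->")
            for sign, side in zip((-1.0, 1.0), sides):
                for term in side.split("+"):
                    tokens = term.split()
                    coeff = float(tokens[0]) if len(tokens) == 2 else 1.0
                    met = tokens[-1]
                    expected[model.metabolite_index(met), j] += sign * coeff
        np.testing.assert_array_equal(S, expected)


class TestProjection:
    def test_reactants_link_to_products_only(self):
        model = MetabolicModel.from_reactions([
            Reaction(id="R1", stoichiometry={"a[c]": -1.0, "b[c]": -1.0,
                                             "c[c]": 1.0})])
        g = project_metabolite_graph(model)
        assert set(map(frozenset, g.edges)) == {frozenset({"a[c]", "c[c]"}),
                                                frozenset({"b[c]", "c[c]"})}

    def test_currency_exclusion_removes_incident_edges(self):
        model = MetabolicModel.from_reactions([
            Reaction(id="R1", stoichiometry={"a[c]": -1.0, "h[c]": -1.0,
                                             "b[c]": 1.0})])
        g = project_metabolite_graph(model)
        assert set(map(frozenset, g.edges)) == {frozenset({"a[c]", "b[c]"})}
        assert "h[c]" not in g

    def test_all_currency_reaction_projects_to_nothing(self):
        stoich = {"h2o[c]": -1.0, "nad[c]": -1.0, "nadh[c]": 1.0, "h[c]": 1.0}
        assert set(stoich) <= CURRENCY_METABOLITES
        model = MetabolicModel.from_reactions([
            Reaction(id="R1", stoichiometry=stoich)])
        g = project_metabolite_graph(model)
        assert g.number_of_edges() == 0

    def test_two_reactions_make_a_path_and_isolated_nodes_are_kept(self):
        model = MetabolicModel.from_reactions([
            Reaction(id="R1", stoichiometry={"a[c]": -1.0, "b[c]": 1.0}),
            Reaction(id="R2", stoichiometry={"b[c]": -1.0, "c[c]": 1.0}),
            Reaction(id="R3", stoichiometry={"z[c]": -1.0, "h2o[c]": 1.0}),
        ])
        g = project_metabolite_graph(model)
        assert sorted(map(tuple, map(sorted, g.edges))) == [
            ("a[c]", "b[c]"), ("b[c]", "c[c]")]
        assert "z[c]" in g.nodes  # isolated after exclusion, still a node

    def test_projection_is_monotone_in_reactions(self, clique_block_model):
        model, _, _ = clique_block_model
        g_all = project_metabolite_graph(model)
        g_part = project_metabolite_graph(
            model, reactions=model.reactions[: len(model.reactions) // 2])
        assert set(g_part.edges) <= set(g_all.edges)

    def test_duplicate_edges_collapse_with_provenance(self):
        model = MetabolicModel.from_reactions([
            Reaction(id="R1", stoichiometry={"a[c]": -1.0, "b[c]": 1.0}),
            Reaction(id="R2", stoichiometry={"a[c]": -2.0, "b[c]": 1.0}),
        ])
        g = project_metabolite_graph(model)
        assert g.number_of_edges() == 1
        assert sorted(g["a[c]"]["b[c]"]["reactions"]) == ["R1", "R2"]


class TestActiveSubnetwork:
    def test_zero_fluxes_give_empty_graph(self, chain_model):
        g = active_subnetwork(chain_model, np.zeros(2))
        assert g.number_of_nodes() == 0

    def test_single_active_reaction(self):
        model = MetabolicModel.from_reactions([
            Reaction(id="R1", stoichiometry={"a[c]": -1.0, "b[c]": -1.0,
                                             "c[c]": 1.0}),
            Reaction(id="R2", stoichiometry={"c[c]": -1.0, "d[c]": 1.0}),
        ])
        g = active_subnetwork(model, [1.0, 0.0])
        assert set(g.nodes) == {"a[c]", "b[c]", "c[c]"}

    def test_active_subgraph_of_full_projection(self, clique_block_model, rng):
        model, _, _ = clique_block_model
        full = project_metabolite_graph(model)
        fluxes = rng.uniform(-1, 1, len(model.reactions))
        fluxes[rng.random(len(fluxes)) < 0.5] = 0.0
        sub = active_subnetwork(model, fluxes, epsilon=1e-6)
        assert set(sub.nodes) <= set(full.nodes)
        assert set(map(frozenset, sub.edges)) <= set(map(frozenset, full.edges))

    def test_length_mismatch_raises(self, chain_model):
        with pytest.raises(ValueError, match="length"):
            active_subnetwork(chain_model, [1.0])


class TestTableRoundTrip:
    def test_write_then_read_reproduces_model(self, tmp_path, clique_block_model):
        model, _, _ = clique_block_model
        path = tmp_path / "model.tsv"
        write_model(model, path)
        back = read_model(path)
        assert back.reaction_ids == model.reaction_ids
        assert back.metabolite_ids == model.metabolite_ids
        for r1, r2 in zip(model.reactions, back.reactions):
            assert r1.stoichiometry == pytest.approx(r2.stoichiometry)
            assert (r1.lower_bound, r1.upper_bound) == (r2.lower_bound, r2.upper_bound)
            assert r1.genes == r2.genes and r1.pathways == r2.pathways

    def test_bound_violation_names_the_reaction(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("reaction_id\tname\tequation\tlower_bound\tupper_bound"
                        "\tgenes\tenzymes\tpathways\n"
                        "RBAD\t\ta[c] -> b[c]\t5\t1\t\t\t\n")
        with pytest.raises(ModelValidationError, match="RBAD"):
            read_model(path)

    def test_sbml_import_matches_table_import(self, tmp_path, chain_model):
        cobra = pytest.importorskip("cobra")
        cb = cobra.Model("toy")
        a = cobra.Metabolite("a[c]", compartment="c")
        b = cobra.Metabolite("b[c]", compartment="c")
        ex = cobra.Reaction("EX_a", lower_bound=0.0, upper_bound=10.0)
        ex.add_metabolites({a: 1.0})
        r = cobra.Reaction("R_ab", lower_bound=0.0, upper_bound=1000.0)
        r.add_metabolites({a: -1.0, b: 1.0})
        cb.add_reactions([ex, r])
        path = tmp_path / "toy.xml"
        cobra.io.write_sbml_model(cb, str(path))
        model = read_model(path, format="sbml")
        assert sorted(model.reaction_ids) == sorted(chain_model.reaction_ids)
        for rid in model.reaction_ids:
            assert (model.reaction(rid).stoichiometry
                    == pytest.approx(chain_model.reaction(rid).stoichiometry))
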