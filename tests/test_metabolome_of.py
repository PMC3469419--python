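import math

import numpy as np
import pytest

from oracles import welch_one_sided_greater
from rhizomod.metabolome_of import (
    MetabolomeFormatError, MetabolomeRecord, RefinementError,
    differential_analysis, read_metabolome, refine_objective,
    select_candidates, write_metabolome,
)
from rhizomod.network_model import MetabolicModel, Reaction
from rhizomod.optimization import ObjectiveFunction


def _rec(name, bac, vl, ion="cation"):
    return MetabolomeRecord(metabolite=name, ion_mode=ion,
                            bac=tuple(bac), vl=tuple(vl))


class TestReadMetabolome:
    def test_statuses_from_blank_cells(self, tmp_path):
        path = tmp_path / "metabolome.tsv"
        path.write_text(
            "metabolite\tion_mode\tbac_1\tbac_2\tbac_3\tvl_1\tvl_2\tvl_3\n"
            "both_met\tcation\t8\t9\t10\t2\t2.2\t1.9\n"
            "fix_only\tanion\t5\t6\t7\t\t\t\n"
            "free_only\tcation\t\t\t\t3\t4\t5\n")
        records = read_metabolome(path)
        assert [r.status for r in records] == ["both", "bac_only", "vl_only"]
        assert records[0].detected_bac and records[0].detected_vl

    def test_missing_replicate_columns_raise(self, tmp_path):
        path = tmp_path / "short.tsv"
        path.write_text("metabolite\tion_mode\tbac_1\tbac_2\tvl_1\tvl_2\n"
                        "m\tcation\t1\t2\t3\t4\n")
        with pytest.raises(MetabolomeFormatError, match="missing"):
            read_metabolome(path)

    def test_empty_table_gives_empty_collection(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("metabolite\tion_mode\tbac_1\tbac_2\tbac_3"
                        "\tvl_1\tvl_2\tvl_3\n")
        assert read_metabolome(path) == []

    def test_round_trip(self, tmp_path):
        records = [_rec("a", (8, 9, 10), (2, 2.2, 1.9)),
                   _rec("b", (5, 6, 7), ())]
        path = tmp_path / "rt.tsv"
        write_metabolome(records, path)
        back = read_metabolome(path)
        assert [(r.metabolite, r.status) for r in back] == [("a", "both"),
                                                            ("b", "bac_only")]
        assert back[0].bac == pytest.approx(records[0].bac)


class TestDifferentialAnalysis:
    def test_identical_groups_are_null(self):
        res = differential_analysis([_rec("m", (4, 5, 6), (4, 5, 6))])[0]
        assert res.log_ratio == pytest.approx(0.0)
        assert res.p_value >= 0.5

    def test_matches_hand_computed_welch_statistic(self):
        bac, vl = (8, 9, 10), (2, 2.2, 1.9)
        res = differential_analysis([_rec("m", bac, vl)])[0]
        # frozen from the textbook Welch computation on log2 replicates
        # (t = 19.17696, Welch-Satterthwaite df = 3.48388)
        assert res.p_value == pytest.approx(5.8677e-05, rel=1e-4)
        t, df, p = welch_one_sided_greater(np.log2(bac), np.log2(vl))
        assert res.p_value == pytest.approx(p, rel=1e-12)
        assert res.log_ratio == pytest.approx(math.log2(9.0 / (6.1 / 3)))

    def test_exclusive_records_are_flagged_not_tested(self):
        res = differential_analysis([_rec("m", (), (3, 4, 5))])[0]
        assert res.status == "vl_only"
        assert math.isnan(res.p_value) and math.isnan(res.log_ratio)

    def test_nonpositive_detected_area_raises(self):
        with pytest.raises(MetabolomeFormatError, match="non-positive"):
            differential_analysis([_rec("m", (1, 0, 2), (1, 1, 1))])

    def test_p_value_invariant_under_rescaling(self):
        bac, vl = (8.0, 9.0, 10.0), (2.0, 2.2, 1.9)
        base = differential_analysis([_rec("m", bac, vl)])[0]
        scaled = differential_analysis(
            [_rec("m", tuple(37.5 * b for b in bac),
                  tuple(37.5 * v for v in vl))])[0]
        assert scaled.p_value == pytest.approx(base.p_value, rel=1e-9)
        assert scaled.log_ratio == pytest.approx(base.log_ratio, rel=1e-9)


class TestSelectCandidates:
    @pytest.fixture
    def results(self):
        return differential_analysis([
            _rec("strong", (8, 9, 10), (2, 2.2, 1.9)),      # fold ~4.4, tiny p
            _rec("low_fold", (3.0, 3.05, 2.95), (2.0, 2.02, 1.98)),  # fold 1.5
            _rec("noisy", (9, 1, 30), (2, 2.2, 1.9)),        # fold > 2, large p
            _rec("fix_only", (5, 6, 7), ()),
        ])

    def test_both_gates_must_pass(self, results):
        names = [r.metabolite for r in select_candidates(results)]
        assert names == ["strong"]

    def test_gates_wide_open_return_all_both(self, results):
        got = select_candidates(results, min_fold=1.0, max_p=1.0)
        assert {r.metabolite for r in got} == {"strong", "low_fold", "noisy"}

    def test_gates_are_monotone(self, results):
        loose = {r.metabolite for r in select_candidates(results, 1.0, 1.0)}
        tighter_fold = {r.metabolite for r in select_candidates(results, 3.0, 1.0)}
        tighter_p = {r.metabolite for r in select_candidates(results, 1.0, 1e-4)}
        assert tighter_fold <= loose and tighter_p <= loose

    def test_ordered_by_decreasing_log_ratio(self, results):
        got = select_candidates(results, min_fold=1.0, max_p=1.0)
        ratios = [r.log_ratio for r in got]
        assert ratios == sorted(ratios, reverse=True)


def _refinement_model():
    """EX(<=10) -> a -> b; making x costs 4 a/unit, making y costs 8 a/unit,
    and z has no producing route at all.

    With base objective {b}: Z = 10.  Forcing one unit of x gives
    Z = (10 - 4) + 1 = 7 (70% of previous, accepted at the 1/3 rule);
    forcing one unit of y gives Z = (10 - 8) + 1 = 3 < 10/3 (rejected);
    z's drain can never run (rejected as unproducible).
    """
    return MetabolicModel.from_reactions([
        Reaction(id="EX", stoichiometry={"a[c]": 1.0}, upper_bound=10.0),
        Reaction(id="Rab", stoichiometry={"a[c]": -1.0, "b[c]": 1.0}),
        Reaction(id="Rax", stoichiometry={"a[c]": -4.0, "x[c]": 1.0}),
        Reaction(id="Ray", stoichiometry={"a[c]": -8.0, "y[c]": 1.0}),
        Reaction(id="Rz", stoichiometry={"w[c]": -1.0, "z[c]": 1.0},
                 upper_bound=0.0),
        Reaction(id="EXw", stoichiometry={"w[c]": 1.0}, upper_bound=0.0),
    ])


IDENTITY_MAP = {n: f"{n}[c]" for n in "abxyz"}


class TestRefineObjective:
    def test_threshold_straddling_toys(self):
        model = _refinement_model()
        base = ObjectiveFunction({"b[c]": 1.0})
        refined, audit = refine_objective(model, base, ["x", "y"],
                                          IDENTITY_MAP)
        by_name = {e.candidate: e for e in audit.entries}
        assert by_name["x"].accepted
        assert by_name["x"].z_after == pytest.approx(7.0)
        assert not by_name["y"].accepted
        assert by_name["y"].z_after == pytest.approx(3.0)
        assert set(refined.components) == {"b[c]", "x[c]"}

    def test_unproducible_candidate_rejected_as_infeasible(self):
        model = _refinement_model()
        _, audit = refine_objective(model, ObjectiveFunction({"b[c]": 1.0}),
                                    ["z"], IDENTITY_MAP)
        entry = audit.entries[0]
        assert not entry.accepted
        assert "no steady-state production" in entry.reason
        assert math.isnan(entry.z_after)

    def test_unmapped_candidate_leaves_objective_unchanged(self):
        model = _refinement_model()
        base = ObjectiveFunction({"b[c]": 1.0})
        refined, audit = refine_objective(model, base, ["unknown_met"],
                                          IDENTITY_MAP)
        assert audit.entries[0].reason == "unmapped"
        assert refined.components == base.components

    def test_accepted_entries_respect_retention_invariant(self):
        model = _refinement_model()
        _, audit = refine_objective(model, ObjectiveFunction({"b[c]": 1.0}),
                                    ["x", "y", "z"], IDENTITY_MAP)
        for e in audit.entries:
            if e.accepted:
                assert e.z_after >= e.z_before / 3.0 - 1e-9

    def test_deterministic_and_objective_never_shrinks(self):
        model = _refinement_model()
        base = ObjectiveFunction({"b[c]": 1.0})
        r1, a1 = refine_objective(model, base, ["x", "y"], IDENTITY_MAP)
        r2, a2 = refine_objective(model, base, ["x", "y"], IDENTITY_MAP)
        assert r1.components == r2.components
        assert [vars(e) for e in a1.entries] == [vars(e) for e in a2.entries]
        assert len(r1) >= len(base)

    def test_unsolvable_base_objective_raises_before_trials(self):
        # forced feed with a blocked outlet: no steady state for any objective
        model = MetabolicModel.from_reactions([
            Reaction(id="EX", stoichiometry={"a[c]": 1.0},
                     lower_bound=5.0, upper_bound=5.0),
            Reaction(id="Rab", stoichiometry={"a[c]": -1.0, "b[c]": 1.0},
                     upper_bound=0.0),
        ])
        with pytest.raises(RefinementError):
            refine_objective(model, ObjectiveFunction({"b[c]": 1.0}),
                             ["x"], IDENTITY_MAP)
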