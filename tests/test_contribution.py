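"""Contribution scoring, chi-square validation, ATC mapping."""

from fractions import Fraction

import pandas as pd
import pytest
from hypothesis import given, strategies as st

import tptnp
from tptnp.contribution import ContributionMatrix, _chisquare_on_table
from tptnp.errors import EmptyInputError, InvalidCodeError, LookupError_
from tptnp.errors import TestInfeasibleError as InfeasibleError
from tptnp.io_model import AnnotationTable, DrugTargetTable, PathwayDiseaseTable
from tptnp.tpt_network import ModulePartition


def cs_brute_force(assignment, ann_pairs, pd_pairs):
    """Independent triple loop over (module, disease, pathway) in floats."""
    modules = sorted(set(assignment.values()))
    diseases = sorted({d for _, d in pd_pairs})
    out = {}
    for d in diseases:
        relevant = {p for p, dd in pd_pairs if dd == d}
        v = len(relevant)
        for m in modules:
            total = 0.0
            for p in relevant:
                incident_modules = {
                    assignment[t]
                    for t, pp in ann_pairs
                    if pp == p and t in assignment
                }
                if m in incident_modules:
                    total += 1.0 / len(incident_modules) / v
            out[(m, d)] = total
    return out


class TestContributionScores:
    def test_worked_example_exact_values(self, fig7_cm):
        cm = fig7_cm
        assert cm.v["d1"] == 5
        assert cm.cs[(1, "d1")] == Fraction(2, 3)
        assert cm.cs[(2, "d1")] == Fraction(1, 6)
        assert cm.cs[(3, "d1")] == Fraction(1, 6)
        assert cm.X[(1, "d1")] == frozenset({"p1", "p2", "p3", "p4", "p5"})
        assert cm.X[(2, "d1")] == frozenset({"p3", "p5"})
        assert cm.X[(3, "d1")] == frozenset({"p4", "p5"})

    def test_single_module_pathway_disease_concentrates_fully(self):
        part = ModulePartition(
            assignment={"A": 1, "B": 1}, resolution=1.0, seed=0, modularity=0.0
        )
        ann = AnnotationTable(pairs=frozenset({("A", "p1"), ("B", "p1")}))
        pdt = PathwayDiseaseTable(pairs=frozenset({("p1", "d1")}))
        cm = tptnp.contribution_scores(
            tptnp.module_pathway_incidence(part, ann), pdt
        )
        assert cm.cs[(1, "d1")] == 1

    def test_empty_pathway_disease_gives_empty_matrix(self, fig7, fig7_partition):
        cm = tptnp.contribution_scores(
            tptnp.module_pathway_incidence(fig7_partition, fig7.annotation),
            PathwayDiseaseTable(pairs=frozenset()),
        )
        assert cm.diseases == ()
        assert cm.cs == {}

    def test_disease_with_only_unmapped_pathways_is_omitted(self, fig7, fig7_partition):
        pairs = set(fig7.pathway_disease.pairs) | {("p-unknown", "d-ghost")}
        cm = tptnp.contribution_scores(
            tptnp.module_pathway_incidence(fig7_partition, fig7.annotation),
            PathwayDiseaseTable(pairs=frozenset(pairs)),
        )
        assert "d-ghost" not in cm.diseases
        assert "d1" in cm.diseases

    @given(st.integers(0, 100))
    def test_matches_brute_force_on_random_instances(self, seed):
        inst = tptnp.generate_planted(
            n_modules=4, targets_per_module=6, pathways_per_module=4,
            cross_pathway_rate=0.25, diseases=5, propensity=0.8, seed=seed,
        )
        net = tptnp.build_tpt(inst.annotation)
        part = tptnp.detect_modules(net, seed=seed)
        cm = tptnp.contribution_scores(
            tptnp.module_pathway_incidence(part, inst.annotation),
            inst.pathway_disease,
        )
        brute = cs_brute_force(
            part.assignment, inst.annotation.pairs, inst.pathway_disease.pairs
        )
        for d in cm.diseases:
            for m in cm.modules:
                assert float(cm.cs[(m, d)]) == pytest.approx(
                    brute[(m, d)], abs=1e-12
                )

    @given(st.integers(0, 100))
    def test_conservation_per_disease(self, seed):
        """All modules together contribute exactly 1 to every disease whose
        pathways are present in the network."""
        inst = tptnp.generate_planted(
            n_modules=5, targets_per_module=8, pathways_per_module=4,
            cross_pathway_rate=0.2, diseases=6, propensity=0.9, seed=seed,
        )
        net = tptnp.build_tpt(inst.annotation)
        part = tptnp.detect_modules(net, seed=seed)
        cm = tptnp.contribution_scores(
            tptnp.module_pathway_incidence(part, inst.annotation),
            inst.pathway_disease,
        )
        for d in cm.diseases:
            assert sum(cm.cs[(m, d)] for m in cm.modules) == 1

    def test_additivity_under_merging_disjoint_modules(self):
        """Coarsening two modules that share no pathway adds their CS
        (u is unchanged by such a merge, so the sums coincide exactly)."""
        ann = AnnotationTable(
            pairs=frozenset(
                {("A1", "pa"), ("A2", "pa"), ("B1", "pb"), ("B2", "pb"),
                 ("C1", "pc"), ("C2", "pc"), ("A1", "px"), ("C1", "px")}
            )
        )
        pdt = PathwayDiseaseTable(
            pairs=frozenset({("pa", "d1"), ("pb", "d1"), ("pc", "d1"), ("px", "d1")})
        )
        fine = ModulePartition(
            assignment={"A1": 1, "A2": 1, "B1": 2, "B2": 2, "C1": 3, "C2": 3},
            resolution=1.0, seed=0, modularity=0.0,
        )
        # merge modules 1 and 2 (they share no pathway; px joins 1 and 3)
        coarse = ModulePartition(
            assignment={"A1": 1, "A2": 1, "B1": 1, "B2": 1, "C1": 3, "C2": 3},
            resolution=1.0, seed=0, modularity=0.0,
        )
        cm_fine = tptnp.contribution_scores(
            tptnp.module_pathway_incidence(fine, ann), pdt
        )
        cm_coarse = tptnp.contribution_scores(
            tptnp.module_pathway_incidence(coarse, ann), pdt
        )
        assert (
            cm_coarse.cs[(1, "d1")]
            == cm_fine.cs[(1, "d1")] + cm_fine.cs[(2, "d1")]
        )
        assert cm_coarse.cs[(3, "d1")] == cm_fine.cs[(3, "d1")]


class TestModuleDiseaseChisquare:
    def test_identical_rows_give_zero_statistic(self):
        table = pd.DataFrame([[3, 4], [3, 4]], index=[1, 2], columns=["d1", "d2"])
        res = _chisquare_on_table(table)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_diagonal_2x2_hand_computed(self):
        """Pearson on [[10,0],[0,10]]: every expected cell is 5, so
        X^2 = 4 * 25/5 = 20 with (2-1)(2-1) = 1 dof."""
        table = pd.DataFrame([[10, 0], [0, 10]], index=[1, 2], columns=["a", "b"])
        res = _chisquare_on_table(table)
        assert res.statistic == pytest.approx(20.0)
        assert res.dof == 1

    def test_fig7_with_second_disease_builds_link_count_table(
        self, fig7, fig7_partition
    ):
        pairs = set(fig7.pathway_disease.pairs) | {("p3", "d2")}
        cm = tptnp.contribution_scores(
            tptnp.module_pathway_incidence(fig7_partition, fig7.annotation),
            PathwayDiseaseTable(pairs=frozenset(pairs)),
        )
        res = tptnp.module_disease_chisquare(cm)
        # direct count oracle: |X(m,d)| per cell; d2 only reaches m1 and m2
        expected = pd.DataFrame(
            {"d1": [5, 2, 2], "d2": [1, 1, 0]}, index=[1, 2, 3]
        )
        pd.testing.assert_frame_equal(res.table, expected)
        assert res.dof == 2

    def test_single_column_is_infeasible(self, fig7_cm):
        with pytest.raises(InfeasibleError):
            tptnp.module_disease_chisquare(fig7_cm)  # only d1

    def test_unknown_builder_rejected(self, fig7_cm):
        with pytest.raises(InfeasibleError):
            tptnp.module_disease_chisquare(fig7_cm, table_builder="cs_matrix")


class TestAtcLevel1:
    @pytest.mark.parametrize(
        "code,letter", [("L01XE06", "L"), ("n02ba01", "N"), ("A", "A"), ("V03", "V")]
    )
    def test_first_character_uppercased(self, code, letter):
        assert tptnp.atc_level1(code) == letter

    @pytest.mark.parametrize("code", ["9XX", "ZZZ", "", "  "])
    def test_invalid_codes_rejected(self, code):
        with pytest.raises(InvalidCodeError):
            tptnp.atc_level1(code)


class TestDrugTargetValidation:
    @staticmethod
    def _partition():
        assignment = {f"A{i}": 1 for i in range(5)} | {f"B{i}": 2 for i in range(5)}
        return ModulePartition(
            assignment=assignment, resolution=1.0, seed=0, modularity=0.0
        )

    def test_class_counts_land_in_home_module(self):
        drugs = DrugTargetTable(
            rows=tuple((f"A{i}", f"drug{i}", "N02BA01") for i in range(4))
        )
        counts, _ = tptnp.drug_target_validation(self._partition(), drugs, {"N"})
        assert counts["N"] == {1: 4, 2: 0}

    def test_target_with_two_classes_counts_once_per_class(self):
        drugs = DrugTargetTable(
            rows=(
                ("A0", "aspirin", "N02BA01"),
                ("A0", "dasatinib", "L01XE06"),
                ("A0", "other-n", "N05BA01"),
            )
        )
        counts, _ = tptnp.drug_target_validation(self._partition(), drugs, {"N", "L"})
        assert counts["N"] == {1: 1, 2: 0}
        assert counts["L"] == {1: 1, 2: 0}

    def test_counts_match_set_count_oracle_on_planted_classes(self):
        """Planted propensity: class N drugs hit module-1 targets, class L
        drugs hit module-2 targets, with a little cross-talk."""
        part = self._partition()
        rows = []
        for i in range(5):
            rows.append((f"A{i}", f"ndrug{i}", "N02BA01"))
        for i in range(4):
            rows.append((f"B{i}", f"ldrug{i}", "L01XE06"))
        rows.append(("B4", "ncross", "N06AB01"))
        drugs = DrugTargetTable(rows=tuple(rows))
        counts, test = tptnp.drug_target_validation(part, drugs, {"N", "L"})
        # independent set-count
        for cls in ("N", "L"):
            for module in (1, 2):
                expected = len(
                    {
                        t
                        for t, _d, code in rows
                        if code[0] == cls and part.assignment[t] == module
                    }
                )
                assert counts[cls][module] == expected
        assert counts["N"][1] == 5 and counts["L"][2] == 4  # majority in home module
        assert test is not None and test.dof == 1

    def test_targets_outside_network_ignored_and_empty_warns(self, caplog):
        import logging

        drugs = DrugTargetTable(rows=(("ZZ9", "drugx", "N02BA01"),))
        with caplog.at_level(logging.WARNING, logger="tptnp.contribution"):
            counts, test = tptnp.drug_target_validation(
                self._partition(), drugs, {"N"}
            )
        assert test is None
        assert all(v == 0 for v in counts["N"].values())

    def test_empty_partition_rejected(self):
        part = ModulePartition(assignment={}, resolution=1.0, seed=0, modularity=0.0)
        with pytest.raises(EmptyInputError):
            tptnp.drug_target_validation(part, DrugTargetTable(rows=()), {"N"})


class TestRelevantDiseaseRatio:
    def test_fig7_selects_module_one(self, fig7_cm):
        frame, selected = tptnp.relevant_disease_ratio(fig7_cm, {"d1"})
        assert selected == 1
        assert frame["d1"].tolist() == pytest.approx([2 / 3, 1 / 6, 1 / 6])

    def test_single_disease_argmax_is_column_argmax(self, fig7_cm):
        frame, selected = tptnp.relevant_disease_ratio(fig7_cm, {"d1"})
        assert selected == frame["d1"].idxmax()

    def test_opposite_argmax_ties_resolve_to_smallest_module(self):
        cm = ContributionMatrix(
            cs={
                (1, "d1"): Fraction(7, 10), (2, "d1"): Fraction(3, 10),
                (1, "d2"): Fraction(3, 10), (2, "d2"): Fraction(7, 10),
            },
            modules=(1, 2),
            diseases=("d1", "d2"),
            u={}, v={"d1": 1, "d2": 1},
            X={(m, d): frozenset() for m in (1, 2) for d in ("d1", "d2")},
        )
        _, selected = tptnp.relevant_disease_ratio(cm, {"d1", "d2"})
        assert selected == 1  # means tie at 0.5; smallest module id wins

    def test_unknown_disease_is_named_in_error(self, fig7_cm):
        with pytest.raises(LookupError_, match="d9"):
            tptnp.relevant_disease_ratio(fig7_cm, {"d1", "d9"})
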