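import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from proximap.errors import ConfigurationError
from proximap.filters import (
    FilterThresholds,
    compare_groups,
    landmark_check,
    presence_filter,
    replicate_correlation,
    sequential_filter,
)
from proximap.quant_io import CONTROL_GROUPS, Group, QuantTable, SampleDesign
from proximap.synthetic import (
    SimulationParams,
    TrueClass,
    default_design,
    generate_proteome,
    landmark_sets,
    simulate_experiment,
)

from conftest import (
    oracle_presence_ids,
    oracle_stage_pass_ids,
    random_quant_table,
)


def _table_from_rows(rows, design):
    """rows: protein_id -> list of (intensity, msms) per sample."""
    ids = list(rows)
    intens = np.array([[v[0] for v in rows[p]] for p in ids], dtype=float)
    msms = np.array([[v[1] for v in rows[p]] for p in ids], dtype=np.int64)
    flags = pd.DataFrame(
        {
            "is_contaminant": [False] * len(ids),
            "is_decoy": [False] * len(ids),
            "only_by_site": [False] * len(ids),
        }
    )
    return QuantTable(ids, [s.sample_id for s in design], intens, msms, flags)


def _uniform_row(value, msms, design):
    return [(value, msms)] * len(design)


class TestThresholdDefaults:
    def test_published_criteria(self):
        # detection in >= 2 target replicates, MS/MS count > 1 (i.e. >= 2),
        # p < 0.05, two-fold change, three controls
        t = FilterThresholds()
        assert t.min_target_replicates == 2
        assert t.min_msms_total == 2
        assert t.p_cutoff == 0.05
        assert t.fold_change == 2.0
        assert t.control_order == CONTROL_GROUPS

    @pytest.mark.parametrize(
        "kw",
        [
            {"p_cutoff": 0.0},
            {"p_cutoff": 1.0},
            {"fold_change": 1.0},
            {"min_target_replicates": 0},
            {"missing_policy": "nope"},
        ],
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            FilterThresholds(**kw)


class TestPresenceFilter:
    def test_one_of_three_replicates_removed(self, design):
        rows = {"P1": [(0.0, 0)] * 12}
        # detected in exactly one target replicate, plenty of MS/MS
        ti = [i for i, s in enumerate(design) if s.group is Group.TARGET]
        rows["P1"][ti[0]] = (1000.0, 5)
        table = _table_from_rows(rows, design)
        assert presence_filter(table, design).n_proteins == 0

    def test_total_msms_one_removed(self, design):
        ti = [i for i, s in enumerate(design) if s.group is Group.TARGET]
        row = [(0.0, 0)] * 12
        for j in ti:
            row[j] = (1000.0, 0)
        row[ti[0]] = (1000.0, 1)  # detected 3/3 but summed MS/MS = 1
        table = _table_from_rows({"P1": row}, design)
        assert presence_filter(table, design).n_proteins == 0

    def test_min_criteria_kept(self, design):
        ti = [i for i, s in enumerate(design) if s.group is Group.TARGET]
        row = [(0.0, 0)] * 12
        row[ti[0]] = (1000.0, 1)
        row[ti[1]] = (900.0, 1)  # 2 replicates, summed MS/MS = 2
        table = _table_from_rows({"P1": row}, design)
        assert presence_filter(table, design).protein_ids == ["P1"]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed, design):
        rng = np.random.default_rng(seed)
        table = random_quant_table(rng, n_proteins=80, design=design)
        got = set(presence_filter(table, design).protein_ids)
        assert got == oracle_presence_ids(table, design)

    def test_too_many_required_replicates(self, design):
        rng = np.random.default_rng(0)
        table = random_quant_table(rng, n_proteins=5, design=design)
        with pytest.raises(ConfigurationError):
            presence_filter(table, design, FilterThresholds(min_target_replicates=4))

    def test_per_replicate_msms_rule(self, design):
        ti = [i for i, s in enumerate(design) if s.group is Group.TARGET]
        row = [(0.0, 0)] * 12
        for j in ti:
            row[j] = (1000.0, 1)  # summed = 3, per-replicate max = 1
        table = _table_from_rows({"P1": row}, design)
        thr = FilterThresholds(msms_rule="per_replicate")
        assert presence_filter(table, design, thr).n_proteins == 0
        assert presence_filter(table, design).n_proteins == 1


class TestCompareGroups:
    def test_identical_groups(self, design):
        table = _table_from_rows({"P1": _uniform_row(2.0**10, 3, design)}, design)
        stage = compare_groups(
            table, design, Group.TARGET, Group.CTRL_WILDTYPE
        )
        row = stage.frame.iloc[0]
        assert row["log2_ratio"] == 0.0
        assert row["p_value"] == 1.0
        assert not row["passed"]

    def test_two_log2_units_apart(self, design):
        row = []
        for s in design:
            if s.group is Group.TARGET:
                row.append((2.0 ** [12.0, 12.1, 11.9][s.replicate - 1], 3))
            elif s.group is Group.CTRL_WILDTYPE:
                row.append((2.0 ** [10.0, 10.1, 9.9][s.replicate - 1], 3))
            else:
                row.append((0.0, 0))
        table = _table_from_rows({"P1": row}, design)
        stage = compare_groups(table, design, Group.TARGET, Group.CTRL_WILDTYPE)
        r = stage.frame.iloc[0]
        assert r["log2_ratio"] == pytest.approx(2.0, abs=1e-9)
        expected = st.ttest_ind(
            [12.0, 12.1, 11.9], [10.0, 10.1, 9.9], equal_var=True
        ).pvalue
        assert r["p_value"] == pytest.approx(expected, rel=1e-12)
        assert r["passed"]

    def test_permutation_oracle_ranks_observed_extreme(self):
        # the observed assignment gives the most extreme mean difference of
        # all 20 label permutations, so the t-test's small p is consistent
        tvals, cvals = [12.0, 12.1, 11.9], [10.0, 10.1, 9.9]
        pooled = tvals + cvals
        observed = abs(np.mean(tvals) - np.mean(cvals))
        diffs = []
        for combo in itertools.combinations(range(6), 3):
            a = [pooled[i] for i in combo]
            b = [pooled[i] for i in range(6) if i not in combo]
            diffs.append(abs(np.mean(a) - np.mean(b)))
        perm_p = sum(d >= observed - 1e-12 for d in diffs) / len(diffs)
        assert perm_p == pytest.approx(2 / 20)
        assert max(diffs) == pytest.approx(observed)

    def test_absent_in_control_rule(self, design):
        row = []
        for s in design:
            if s.group is Group.TARGET:
                row.append((1000.0, 3))
            else:
                row.append((0.0, 0))
        table = _table_from_rows({"P1": row}, design)
        stage = compare_groups(table, design, Group.TARGET, Group.CTRL_WILDTYPE)
        r = stage.frame.iloc[0]
        assert r["passed"]
        assert np.isinf(r["log2_ratio"])
        assert np.isnan(r["p_value"])

    def test_insufficient_detection_is_sentinel(self, design):
        row = []
        for s in design:
            if s.group is Group.TARGET:
                row.append((1000.0, 3) if s.replicate < 3 else (0.0, 0))
            elif s.group is Group.CTRL_WILDTYPE:
                row.append((10.0, 1) if s.replicate == 1 else (0.0, 0))
            else:
                row.append((0.0, 0))
        table = _table_from_rows({"P1": row}, design)
        stage = compare_groups(table, design, Group.TARGET, Group.CTRL_WILDTYPE)
        r = stage.frame.iloc[0]
        assert np.isnan(r["p_value"])
        assert not r["passed"]  # absent rule needs detection in every target rep

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scipy_per_protein(self, seed, design):
        rng = np.random.default_rng(100 + seed)
        table = random_quant_table(rng, n_proteins=60, design=design, p_zero=0.2)
        stage = compare_groups(table, design, Group.TARGET, Group.CTRL_CYTO_BAIT)
        got = set(stage.frame.loc[stage.frame["passed"], "protein_id"])
        assert got == oracle_stage_pass_ids(table, design, Group.CTRL_CYTO_BAIT)

    def test_welch_flag(self, design):
        rng = np.random.default_rng(7)
        table = random_quant_table(rng, n_proteins=40, design=design, p_zero=0.0)
        stage = compare_groups(
            table, design, Group.TARGET, Group.CTRL_WILDTYPE,
            FilterThresholds(welch=True),
        )
        ti = table.sample_indices(design, Group.TARGET)
        ci = table.sample_indices(design, Group.CTRL_WILDTYPE)
        expected = st.ttest_ind(
            np.log2(table.intensities[:, ti]),
            np.log2(table.intensities[:, ci]),
            axis=1,
            equal_var=False,
        ).pvalue
        np.testing.assert_allclose(stage.frame["p_value"], expected, rtol=1e-10)

    def test_impute_policy_deterministic(self, design):
        rng = np.random.default_rng(3)
        table = random_quant_table(rng, n_proteins=50, design=design, p_zero=0.4)
        thr = FilterThresholds(missing_policy="impute", imputation_seed=5)
        a = compare_groups(table, design, Group.TARGET, Group.CTRL_WILDTYPE, thr)
        b = compare_groups(table, design, Group.TARGET, Group.CTRL_WILDTYPE, thr)
        pd.testing.assert_frame_equal(a.frame, b.frame)


class TestSequentialFilter:
    def _strong_simulation(self, seed=0):
        params = SimulationParams(
            target_enrichment_log2fc=4.0,
            replicate_sd=0.2,
            n_per_class={
                "bait_proximal_luminal": 30,
                "bait_proximal_imp": 17,
                "oec_like_landmark": 3,
                "cytoplasmic": 180,
                "phycobilisome_like_landmark": 6,
                "endogenous_biotinylated": 10,
                "distal_luminal": 4,
            },
            seed=seed,
        )
        proteome = generate_proteome(params)
        design = default_design()
        table, truth = simulate_experiment(proteome, design, params)
        return proteome, design, table, truth

    def test_landmarks_on_strong_synthetic(self):
        proteome, design, table, truth = self._strong_simulation()
        report = sequential_filter(table, design)
        pos, neg = landmark_sets(proteome)
        final = set(report.final_set)
        assert pos <= final
        assert not (neg & final)

    def test_unattainable_fold_change(self, design):
        rng = np.random.default_rng(5)
        table = random_quant_table(rng, n_proteins=30, design=design, p_zero=0.0)
        # p_zero=0 means the absent-in-control escape can't trigger, so an
        # astronomically large fold-change empties the final set
        thr = FilterThresholds(fold_change=1e300)
        report = sequential_filter(table, design, thr)
        assert report.final_set == []

    @pytest.mark.parametrize("seed", range(3))
    def test_order_invariance(self, seed, design):
        rng = np.random.default_rng(200 + seed)
        table = random_quant_table(rng, n_proteins=60, design=design)
        finals = set()
        for order in itertools.permutations(CONTROL_GROUPS):
            thr = FilterThresholds(control_order=order)
            finals.add(frozenset(sequential_filter(table, design, thr).final_set))
        assert len(finals) == 1

    def test_final_is_intersection_of_single_stages(self, design):
        rng = np.random.default_rng(42)
        table = random_quant_table(rng, n_proteins=80, design=design)
        report = sequential_filter(table, design)
        filtered = presence_filter(table, design)
        expected = set(filtered.protein_ids)
        for control in CONTROL_GROUPS:
            stage = compare_groups(filtered, design, Group.TARGET, control)
            expected &= stage.passed_ids
        assert set(report.final_set) == expected

    def test_monotone_in_thresholds(self, design):
        rng = np.random.default_rng(9)
        table = random_quant_table(rng, n_proteins=80, design=design)
        base = set(sequential_filter(table, design).final_set)
        stricter_fc = set(
            sequential_filter(table, design, FilterThresholds(fold_change=4.0)).final_set
        )
        stricter_p = set(
            sequential_filter(table, design, FilterThresholds(p_cutoff=0.01)).final_set
        )
        assert stricter_fc <= base
        assert stricter_p <= base

    def test_report_counts_nested(self, design):
        rng = np.random.default_rng(8)
        table = random_quant_table(rng, n_proteins=70, design=design)
        report = sequential_filter(table, design)
        assert len(report.final_set) <= report.n_after_presence <= report.n_input
        counts = report.stage_counts
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] == len(report.final_set)

    def test_missing_control_group_rejected(self):
        design = [s for s in default_design() if s.group is not Group.CTRL_CYTO_BAIT]
        rng = np.random.default_rng(0)
        table = random_quant_table(rng, n_proteins=10, design=design)
        with pytest.raises(ConfigurationError, match="ctrl_cyto_bait"):
            sequential_filter(table, design)

    def test_null_simulation_calibration_small(self):
        # all effects zero, no missingness: single-stage pass rate is bounded
        # by the nominal level (the FC criterion only adds stringency)
        params = SimulationParams(
            target_enrichment_log2fc=0.0,
            peroxidase_background_log2=0.0,
            endogenous_biotin_log2=0.0,
            cyto_leak_log2fc=0.0,
            missing_values=False,
            n_per_class={"cytoplasmic": 300},
            seed=0,
        )
        proteome = generate_proteome(params)
        design = default_design()
        n_pass = n_total = 0
        for seed in range(10):
            params.seed = seed
            table, _ = simulate_experiment(proteome, design, params)
            stage = compare_groups(table, design, Group.TARGET, Group.CTRL_WILDTYPE)
            n_pass += int(stage.frame["passed"].sum())
            n_total += len(stage.frame)
        assert n_pass / n_total <= 0.05


class TestLandmarkCheck:
    def _report(self, final):
        from proximap.filters import FilterReport

        return FilterReport(
            n_input=10, n_after_presence=8, presence_ids=[], stages=[], final_set=final
        )

    def test_all_positives_retained(self):
        summary = landmark_check(self._report(["A", "B", "C"]), {"A", "B"}, set())
        assert summary["positives_retained"] == 1.0

    def test_three_of_four_negatives_removed(self):
        summary = landmark_check(
            self._report(["N1", "X"]), set(), {"N1", "N2", "N3", "N4"}
        )
        assert summary["negatives_removed"] == 0.75

    def test_empty_sets_default_to_one(self):
        summary = landmark_check(self._report(["A"]), set(), set())
        assert summary["positives_retained"] == 1.0
        assert summary["negatives_removed"] == 1.0

    @pytest.mark.parametrize("seed", range(3))
    def test_counting_identity(self, seed):
        rng = np.random.default_rng(seed)
        pool = [f"P{i}" for i in range(30)]
        final = [p for p in pool if rng.random() < 0.5]
        neg = {p for p in pool if rng.random() < 0.3}
        summary = landmark_check(self._report(final), set(), neg)
        leaked = len(neg & set(final))
        removed = round(summary["negatives_removed"] * len(neg)) if neg else 0
        assert removed + leaked == len(neg)


class TestReplicateCorrelation:
    def test_duplicated_replicate_r2_one(self, design):
        rng = np.random.default_rng(0)
        table = random_quant_table(rng, n_proteins=30, design=design, p_zero=0.0)
        ti = table.sample_indices(design, Group.TARGET)
        table.intensities[:, ti[1]] = table.intensities[:, ti[0]]
        r2 = replicate_correlation(table, design, Group.TARGET)
        names = [table.sample_ids[i] for i in ti]
        assert r2.loc[names[0], names[1]] == pytest.approx(1.0)

    def test_hand_computed_pair(self, design):
        table = random_quant_table(np.random.default_rng(1), 4, design, p_zero=0.0)
        ti = table.sample_indices(design, Group.TARGET)
        x = np.log2(table.intensities[:, ti[0]])
        y = np.log2(table.intensities[:, ti[1]])
        # closed-form Pearson
        r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        r2 = replicate_correlation(table, design, Group.TARGET)
        names = [table.sample_ids[i] for i in ti[:2]]
        assert r2.loc[names[0], names[1]] == pytest.approx(r * r, rel=1e-12)

    def test_few_codetected_gives_nan(self, design):
        table = random_quant_table(np.random.default_rng(2), 10, design, p_zero=0.0)
        ti = table.sample_indices(design, Group.TARGET)
        table.intensities[2:, ti[0]] = 0.0  # only 2 co-detected with others
        r2 = replicate_correlation(table, design, Group.TARGET)
        names = [table.sample_ids[i] for i in ti]
        assert np.isnan(r2.loc[names[0], names[1]])

    def test_symmetric_unit_diagonal(self, design):
        table = random_quant_table(np.random.default_rng(3), 40, design)
        r2 = replicate_correlation(table, design, Group.CTRL_WILDTYPE).to_numpy()
        np.testing.assert_allclose(np.diag(r2), 1.0)
        np.testing.assert_allclose(r2, r2.T, equal_nan=True)

    def test_single_sample_group_rejected(self):
        design = default_design() + [
            SampleDesign("lonely", Group.TARGET, 9)
        ]
        # build a 1-sample pseudo group via a fresh design
        d = [SampleDesign("a", Group.TARGET, 1), SampleDesign("b", Group.TARGET, 2),
             SampleDesign("c", Group.CTRL_WILDTYPE, 1)]
        table = random_quant_table(np.random.default_rng(0), 5, d)
        with pytest.raises(ConfigurationError):
            replicate_correlation(table, d, Group.CTRL_WILDTYPE)
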