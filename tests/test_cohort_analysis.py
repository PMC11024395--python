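"""Cohort procedures: index selection, washout, windows, scoring, statistics."""

import itertools
from datetime import date, timedelta

import numpy as np
import pytest
from scipy import stats as sps

from wearsurv.corpus import ClinicalNote
from wearsurv.cohort_analysis import (
    CohortConfig,
    PatientRecord,
    af_diagnosis_within,
    assign_index,
    build_comparison_table,
    chads_vasc,
    chi_square,
    descendants,
    exclude_prior_af,
    percent_of,
    records_from_tables,
    relative_risk,
    welch_t_one_tailed,
)
from wearsurv.synthetic_ehr import (
    AF_HIERARCHY_EDGES,
    AF_ROOT_CODE,
    COMORBIDITY_CODES,
    GeneratorConfig,
    generate_dataset,
)


def note(nid, pid, d):
    return ClinicalNote(nid, pid, d, "wearable mentioned")


class TestAssignIndex:
    def test_oldest_positive_note_is_index(self):
        notes = {"P1": [note("N1", "P1", date(2020, 5, 1)),
                        note("N2", "P1", date(2019, 3, 2))]}
        (a,) = assign_index(notes, {"N1": 1, "N2": 1})
        assert a.group == "prediagnosis" and a.index_date == date(2019, 3, 2)

    def test_oldest_wearable_note_when_no_positive(self):
        notes = {"P1": [note(f"N{i}", "P1", date(2020, i + 1, 1)) for i in range(3)]}
        (a,) = assign_index(notes, {})
        assert a.group == "no_prediagnosis" and a.index_note_id == "N0"

    def test_date_tie_breaks_to_smaller_note_id(self):
        d = date(2021, 7, 7)
        notes = {"P1": [note("N9", "P1", d), note("N2", "P1", d)]}
        (a,) = assign_index(notes, {"N9": 1, "N2": 1})
        assert a.index_note_id == "N2"


class TestDescendants:
    def test_leaf_concept_is_itself(self):
        assert descendants(45768480, AF_HIERARCHY_EDGES) == {45768480}

    def test_root_closure_matches_bfs_oracle(self):
        children = {}
        for p, c in AF_HIERARCHY_EDGES:
            children.setdefault(p, []).append(c)
        seen, queue = {AF_ROOT_CODE}, [AF_ROOT_CODE]
        while queue:
            for c in children.get(queue.pop(), []):
                if c not in seen:
                    seen.add(c)
                    queue.append(c)
        assert descendants(AF_ROOT_CODE, AF_HIERARCHY_EDGES) == seen

    def test_absent_concept_warns_and_returns_itself(self):
        with pytest.warns(UserWarning):
            assert descendants(999, AF_HIERARCHY_EDGES) == {999}

    def test_cycle_detected(self):
        with pytest.raises(ValueError, match="cycle"):
            descendants(1, [(1, 2), (2, 3), (3, 1)])


def record(pid="P1", birth=date(1950, 1, 1), sex="male", race="White",
           conditions=(), drugs=(), procedures=()):
    return PatientRecord(pid, birth, sex, race, tuple(conditions),
                         tuple(drugs), tuple(procedures))


class TestWashoutAndWindow:
    AF = {AF_ROOT_CODE}
    IDX = date(2020, 6, 1)

    def _assign(self, pid="P1"):
        from wearsurv.cohort_analysis import IndexAssignment
        return IndexAssignment(pid, "prediagnosis", "N1", self.IDX)

    def test_af_day_before_index_excluded(self):
        rec = record(conditions=[(AF_ROOT_CODE, self.IDX - timedelta(days=1), "inpatient")])
        assert exclude_prior_af([self._assign()], {"P1": rec}, self.AF) == []

    def test_af_on_index_date_retained(self):
        rec = record(conditions=[(AF_ROOT_CODE, self.IDX, "inpatient")])
        assert len(exclude_prior_af([self._assign()], {"P1": rec}, self.AF)) == 1

    def test_other_setting_never_triggers_washout(self):
        rec = record(conditions=[(AF_ROOT_CODE, self.IDX - timedelta(days=9), "other")])
        assert len(exclude_prior_af([self._assign()], {"P1": rec}, self.AF)) == 1

    def test_window_inclusive_at_60_exclusive_at_61(self):
        for lag, expected in ((60, True), (61, False)):
            rec = record(conditions=[(AF_ROOT_CODE, self.IDX + timedelta(days=lag),
                                      "ambulatory")])
            flags, _ = af_diagnosis_within([self._assign()], {"P1": rec}, self.AF)
            assert bool(flags.diagnosed.iloc[0]) is expected, lag

    def test_panel_matches_bruteforce_scan(self):
        # 500 synthetic patients: washout + window flags equal per-patient scans
        rng = np.random.default_rng(8)
        assigns, records = [], {}
        from wearsurv.cohort_analysis import IndexAssignment
        for i in range(500):
            pid = f"P{i}"
            idx = date(2020, 1, 1) + timedelta(days=int(rng.integers(0, 300)))
            conds = []
            for _ in range(int(rng.integers(0, 4))):
                conds.append((int(rng.choice([AF_ROOT_CODE, 4154290, 777])),
                              idx + timedelta(days=int(rng.integers(-90, 121))),
                              str(rng.choice(["ambulatory", "inpatient", "other"]))))
            assigns.append(IndexAssignment(pid, "prediagnosis", "N", idx))
            records[pid] = record(pid=pid, conditions=conds)
        af = {AF_ROOT_CODE, 4154290}
        kept = exclude_prior_af(assigns, records, af)
        expected_kept = [a for a in assigns if not any(
            c in af and s in ("ambulatory", "inpatient") and d < a.index_date
            for c, d, s in records[a.patient_id].conditions)]
        assert kept == expected_kept
        flags, _ = af_diagnosis_within(kept, records, af, 60)
        for row in flags.itertuples(index=False):
            a = next(x for x in kept if x.patient_id == row.patient_id)
            dates = [d for c, d, s in records[row.patient_id].conditions
                     if c in af and a.index_date <= d <= a.index_date + timedelta(days=60)]
            assert row.diagnosed == bool(dates)
            if dates:
                assert row.diagnosis_date == min(dates)


class TestChadsVasc:
    def test_young_healthy_male_scores_zero(self):
        rec = record(birth=date(1990, 6, 1), sex="male")
        assert chads_vasc(rec, date(2020, 6, 1)).total == 0

    def test_standard_rubric_example(self):
        # 80-year-old woman with hypertension: 2 (age) + 1 (sex) + 1 (HTN) = 4
        rec = record(birth=date(1940, 1, 1), sex="female",
                     conditions=[(COMORBIDITY_CODES["hypertension"],
                                  date(2010, 1, 1), "ambulatory")])
        assert chads_vasc(rec, date(2020, 6, 1)).total == 4

    def test_rubric_maximum_is_nine(self):
        conds = [(code, date(2000, 1, 1), "ambulatory")
                 for code in COMORBIDITY_CODES.values()]
        rec = record(birth=date(1940, 1, 1), sex="female", conditions=conds)
        assert chads_vasc(rec, date(2020, 6, 1)).total == 9

    def test_exhaustive_rubric_sweep(self):
        # all 2^5 comorbidity combinations x 3 age bands x 2 sexes against a
        # directly coded standard-instrument oracle
        names = list(COMORBIDITY_CODES)
        points = {"congestive_heart_failure": 1, "hypertension": 1, "diabetes": 1,
                  "vascular_disease": 1, "stroke": 2}
        as_of = date(2020, 6, 1)
        for flags in itertools.product((0, 1), repeat=5):
            for age_band, birth in (("lt65", date(1980, 1, 1)),
                                    ("65_74", date(1950, 6, 10)),
                                    ("ge75", date(1940, 1, 1))):
                for sex in ("male", "female"):
                    conds = [(COMORBIDITY_CODES[n], date(2001, 1, 1), "ambulatory")
                             for n, f in zip(names, flags) if f]
                    got = chads_vasc(record(birth=birth, sex=sex, conditions=conds),
                                     as_of).total
                    expected = sum(points[n] * f for n, f in zip(names, flags))
                    expected += {"lt65": 0, "65_74": 1, "ge75": 2}[age_band]
                    expected += int(sex == "female")
                    assert got == expected, (flags, age_band, sex)

    def test_conditions_after_as_of_ignored(self):
        rec = record(birth=date(1980, 1, 1), sex="male",
                     conditions=[(COMORBIDITY_CODES["hypertension"],
                                  date(2021, 1, 1), "ambulatory")])
        assert chads_vasc(rec, date(2020, 6, 1)).total == 0

    def test_missing_sex_flagged_and_scores_zero_sex_points(self):
        rec = record(birth=date(1940, 1, 1), sex="missing")
        score = chads_vasc(rec, date(2020, 6, 1))
        assert score.missing_sex and score.components["female_sex"] == 0


class TestStatistics:
    def test_identical_groups_give_half(self):
        a = [1.0, 2.0, 3.0, 4.0]
        _, p = welch_t_one_tailed(a, list(a), "a_greater")
        assert p == pytest.approx(0.5)

    def test_one_tailed_is_half_two_tailed_in_direction(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 1.0, 30)
        b = rng.normal(0.0, 2.0, 40)
        _, p_one = welch_t_one_tailed(a, b, "a_greater")
        t2, p_two = sps.ttest_ind(a, b, equal_var=False)
        assert p_one == pytest.approx(p_two / 2, abs=1e-12)

    def test_welch_matches_reference_implementation(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            a = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), int(rng.integers(5, 60)))
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), int(rng.integers(5, 60)))
            t, p = welch_t_one_tailed(a, b, "a_greater")
            ref_t, ref_p = sps.ttest_ind(a, b, equal_var=False, alternative="greater")
            assert t == pytest.approx(float(ref_t), abs=1e-8)
            assert p == pytest.approx(float(ref_p), abs=1e-8)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_t_one_tailed([1.0, 1.0], [1.0, 1.0])

    def test_chi_square_identical_proportions(self):
        stat, p = chi_square([[10, 20], [10, 20]])
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_chi_square_textbook_2x2(self):
        # hand formula on (10,20 / 20,10): expected 15 everywhere,
        # stat = 4 * 25/15 = 20/3
        stat, p = chi_square([[10, 20], [20, 10]])
        assert stat == pytest.approx(20 / 3)
        ref = sps.chi2_contingency([[10, 20], [20, 10]], correction=False)
        assert stat == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_chi_square_race_table_df(self):
        table = [[10 + i, 20 + i] for i in range(6)]  # 6x2 -> df 5
        stat, p = chi_square(table)
        assert p == pytest.approx(float(sps.chi2.sf(stat, 5)))

    def test_chi_square_matches_reference_on_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            r, c = int(rng.integers(2, 6)), int(rng.integers(2, 4))
            table = rng.integers(1, 60, (r, c))
            stat, p = chi_square(table)
            ref = sps.chi2_contingency(table, correction=False)
            assert stat == pytest.approx(ref.statistic, abs=1e-8)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_zero_expected_cell_reported(self):
        with pytest.raises(ValueError, match="cell"):
            chi_square([[0, 0], [5, 5]])


class TestRelativeRisk:
    def test_printed_percent_convention(self):
        assert relative_risk(305, 1037, 262, 16560, "printed_percent") == 18.61

    def test_raw_quotient(self):
        assert relative_risk(305, 1037, 262, 16560, "raw") == pytest.approx(
            (305 / 1037) / (262 / 16560))
        assert round(relative_risk(305, 1037, 262, 16560, "raw"), 2) == 18.59

    def test_equal_risks_give_one(self):
        assert relative_risk(5, 50, 20, 200, "raw") == pytest.approx(1.0)

    def test_scaling_invariance(self):
        base = relative_risk(7, 100, 3, 80, "raw")
        assert relative_risk(21, 300, 9, 240, "raw") == pytest.approx(base)

    def test_zero_reference_events_rejected(self):
        with pytest.raises(ValueError):
            relative_risk(5, 50, 0, 200)

    def test_percent_formatting_examples(self):
        assert percent_of(525, 1037) == 50.63
        assert percent_of(5936, 16560) == 35.85
        assert percent_of(2371, 21327) == 11.12


@pytest.fixture(scope="module")
def cohort():
    ds = generate_dataset(GeneratorConfig(n_patients=2500, seed=23))
    records = records_from_tables(ds.tables)
    by_patient = {}
    for n in ds.notes:
        by_patient.setdefault(n.patient_id, []).append(n)
    assignments = assign_index(by_patient, ds.truth.note_labels)
    return ds, records, assignments


class TestComparisonTable:
    def test_counts_match_bruteforce_tabulation(self, cohort):
        ds, records, assignments = cohort
        table = build_comparison_table(assignments, records, "all")
        work = [a for a in assignments if records[a.patient_id].sex != "missing"]
        grp_a = [a for a in work if a.group == "prediagnosis"]
        male = sum(records[a.patient_id].sex == "male" for a in grp_a)
        row = table.rows.set_index("characteristic")
        assert row.loc["sex_male", "prediagnosis"] == \
            f"{male} ({percent_of(male, len(grp_a))}%)"
        white = sum(records[a.patient_id].race_ethnicity == "White" for a in grp_a)
        assert row.loc["race_White", "prediagnosis"].startswith(f"{white} (")

    def test_partition_and_missing_sex_exclusion(self, cohort):
        ds, records, assignments = cohort
        table = build_comparison_table(assignments, records, "all")
        n_missing = sum(records[a.patient_id].sex == "missing" for a in assignments)
        assert table.n_prediagnosis + table.n_no_prediagnosis == \
            len(assignments) - n_missing

    def test_stage_monotonicity(self, cohort):
        ds, records, assignments = cohort
        sizes = {}
        for stage in ("all", "no_prior_af", "diagnosed"):
            t = build_comparison_table(assignments, records, stage)
            sizes[stage] = t.n_prediagnosis + t.n_no_prediagnosis
        assert sizes["diagnosed"] <= sizes["no_prior_af"] <= sizes["all"]

    def test_categorical_percentages_sum_to_100(self, cohort):
        ds, records, assignments = cohort
        table = build_comparison_table(assignments, records, "all")
        race = table.rows[table.rows.characteristic.str.startswith("race_")]
        for col in ("prediagnosis", "no_prediagnosis"):
            pct = [float(v.split("(")[1].rstrip("%)")) for v in race[col]]
            assert sum(pct) == pytest.approx(100, abs=0.1)

    def test_diagnosed_stage_omits_unprescribed_drugs(self, cohort):
        ds, records, assignments = cohort
        t = build_comparison_table(assignments, records, "diagnosed")
        drug_rows = t.rows[t.rows.characteristic.str.contains("anticoagulant_|rhythm_")]
        for col in ("prediagnosis", "no_prediagnosis"):
            counts = [int(v.split(" ")[0]) for v in drug_rows[col]]
        # every listed row has at least one prescription across groups
        totals = [int(a.split(" ")[0]) + int(b.split(" ")[0])
                  for a, b in zip(drug_rows.prediagnosis, drug_rows.no_prediagnosis)]
        assert all(t > 0 for t in totals)

    def test_empty_group_rejected(self, cohort):
        ds, records, assignments = cohort
        only_neg = [a for a in assignments if a.group == "no_prediagnosis"]
        with pytest.raises(ValueError):
            build_comparison_table(only_neg, records, "all")

    def test_unknown_stage_rejected(self, cohort):
        ds, records, assignments = cohort
        with pytest.raises(ValueError):
            build_comparison_table(assignments, records, "bogus")
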