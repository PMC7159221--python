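"""Cohort pipeline tests: exclusion cascade, first-admission selection,
rare-code filtering, comorbidity mapping, and stratified splitting."""

import numpy as np
import pandas as pd
import pytest

from readmit.cohort import (ComorbidityMap, ConditionConfig, apply_exclusions,
                            build_cohort, filter_rare_codes, map_comorbidities,
                            select_first_admission, split_cohort,
                            synthetic_comorbidity_map)


def _base_record(**kw):
    rec = {
        "patient_id": 0, "hospital_id": 0, "age": 60.0, "female": 0,
        "admission_month": 5, "length_of_stay": 3, "died": 0, "ama": 0,
        "transfer_out": 0, "principal_dx": "AMI1", "secondary_dx": [],
        "procedures": [], "readmit_30d": 0, "planned_readmit": 0,
    }
    rec.update(kw)
    return rec


AMI_CONDITION = ConditionConfig("ami", frozenset({"AMI1", "AMI2"}),
                                exclude_zero_los=True)


class TestExclusions:
    def test_empty_input(self):
        df = pd.DataFrame([_base_record()]).iloc[:0]
        out, log = apply_exclusions(df, AMI_CONDITION)
        assert len(out) == 0
        assert all(n == 0 for _, n in log.steps)

    def test_each_rule_removes_exactly_one_on_toy_table(self):
        # ten records: one per exclusion condition, the rest clean.
        # the 'small hospital' rule then removes the under-10 leftovers.
        rows = [
            _base_record(patient_id=0, length_of_stay=0),     # zero LOS
            _base_record(patient_id=1, died=1),               # died
            _base_record(patient_id=2, ama=1),                # AMA
            _base_record(patient_id=3, admission_month=12),   # December
            _base_record(patient_id=4, transfer_out=1),       # transfer
            _base_record(patient_id=5, age=15.0),             # minor
            _base_record(patient_id=6, principal_dx="OTHER"),  # not cohort
        ]
        rows += [_base_record(patient_id=10 + i) for i in range(3)]
        out, log = apply_exclusions(pd.DataFrame(rows), AMI_CONDITION,
                                    min_hospital_admissions=2)
        steps = dict(log.steps)
        assert log.n_input == 9  # OTHER principal never enters
        for rule in ("zero_los", "died", "ama", "december", "transfer",
                     "age_under_18"):
            assert steps[rule] == 1, rule
        assert steps["small_hospital"] == 0
        assert len(out) == 3

    def test_rule_order_is_the_listed_cascade(self):
        df = pd.DataFrame([_base_record()])
        _, log = apply_exclusions(df, AMI_CONDITION)
        assert [r for r, _ in log.steps] == [
            "zero_los", "died", "ama", "december", "transfer",
            "age_under_18", "small_hospital"]

    def test_zero_los_rule_skipped_for_non_ami(self):
        cond = ConditionConfig("hf", frozenset({"AMI1"}), exclude_zero_los=False)
        df = pd.DataFrame([_base_record(length_of_stay=0),
                           _base_record(patient_id=1)])
        out, log = apply_exclusions(df, cond, min_hospital_admissions=1)
        assert dict(log.steps)["zero_los"] == 0
        assert len(out) == 2

    def test_small_hospital_rule(self):
        rows = [_base_record(patient_id=i, hospital_id=0) for i in range(12)]
        rows += [_base_record(patient_id=100 + i, hospital_id=1)
                 for i in range(4)]
        out, log = apply_exclusions(pd.DataFrame(rows), AMI_CONDITION)
        assert dict(log.steps)["small_hospital"] == 4
        assert set(out["hospital_id"]) == {0}

    def test_log_conservation(self, small_dataset):
        cfg, hospitals, universe, table = small_dataset
        cond = ConditionConfig.from_universe(universe, "ami")
        out, log = apply_exclusions(table, cond)
        assert log.n_input - sum(n for _, n in log.steps) == len(out)


class TestFirstAdmission:
    def test_earliest_month_kept(self):
        df = pd.DataFrame([_base_record(patient_id=1, admission_month=7,
                                        length_of_stay=9),
                           _base_record(patient_id=1, admission_month=3)])
        out = select_first_admission(df)
        assert len(out) == 1
        assert out.iloc[0]["admission_month"] == 3

    def test_unique_patients_identity(self, tiny_records):
        out = select_first_admission(tiny_records)
        pd.testing.assert_frame_equal(out, tiny_records)

    def test_matches_groupby_min_oracle(self):
        rng = np.random.default_rng(0)
        rows = [_base_record(patient_id=int(rng.integers(0, 40)),
                             admission_month=int(rng.integers(1, 13)),
                             length_of_stay=int(i))
                for i in range(300)]
        df = pd.DataFrame(rows)
        out = select_first_admission(df)
        oracle = df.groupby("patient_id")["admission_month"].min()
        assert len(out) == df["patient_id"].nunique()
        got = out.set_index("patient_id")["admission_month"]
        assert (got.sort_index() == oracle.sort_index()).all()

    def test_same_month_tie_keeps_first_in_input_order(self):
        df = pd.DataFrame([_base_record(patient_id=1, admission_month=4,
                                        length_of_stay=11),
                           _base_record(patient_id=1, admission_month=4,
                                        length_of_stay=22)])
        out = select_first_admission(df)
        assert out.iloc[0]["length_of_stay"] == 11


class TestRareCodeFilter:
    def test_min_count_one_keeps_everything(self, tiny_records):
        dx, proc, out = filter_rare_codes(tiny_records, min_count=1)
        assert out["secondary_dx"].tolist() == tiny_records["secondary_dx"].tolist()
        observed = set()
        for p, s, pr in zip(tiny_records["principal_dx"],
                            tiny_records["secondary_dx"],
                            tiny_records["procedures"]):
            observed |= {p, *s, *pr}
        assert set(dx) | set(proc) == observed

    def test_code_below_threshold_removed_everywhere(self):
        rows = [_base_record(patient_id=i, secondary_dx=["Z"])
                for i in range(9)]
        rows += [_base_record(patient_id=9 + i, secondary_dx=["D1"])
                 for i in range(10)]
        df = pd.DataFrame(rows)
        dx, proc, out = filter_rare_codes(df, min_count=10)
        assert "Z" not in dx
        assert all("Z" not in s for s in out["secondary_dx"])
        assert "D1" in dx
        assert len(out) == len(df)  # records never removed

    def test_counts_are_per_record_presence(self, tiny_records):
        # brute-force counter: +1 per record containing the code
        counts: dict[str, int] = {}
        for _, r in tiny_records.iterrows():
            for c in {r["principal_dx"], *r["secondary_dx"], *r["procedures"]}:
                counts[c] = counts.get(c, 0) + 1
        dx, proc, _ = filter_rare_codes(tiny_records, min_count=25)
        expected = {c for c, n in counts.items() if n >= 25}
        assert set(dx) | set(proc) == expected

    def test_invalid_min_count(self, tiny_records):
        with pytest.raises(ValueError):
            filter_rare_codes(tiny_records, min_count=0)


class TestComorbidityMap:
    def test_unmapped_codes_give_zero_row(self):
        cmap = ComorbidityMap({"D1": 0})
        df = pd.DataFrame([_base_record(secondary_dx=["X", "Y"])])
        M = map_comorbidities(df, cmap)
        assert M.shape == (1, 29)
        assert M.sum() == 0

    def test_binary_not_count(self):
        cmap = ComorbidityMap({"D1": 3, "D2": 3})
        df = pd.DataFrame([_base_record(secondary_dx=["D1", "D2"])])
        M = map_comorbidities(df, cmap)
        assert M[0, 3] == 1
        assert M.sum() == 1

    def test_matches_double_loop_oracle(self, tiny_records):
        rng = np.random.default_rng(3)
        codes = sorted({c for s in tiny_records["secondary_dx"] for c in s})
        cmap = ComorbidityMap({c: int(rng.integers(0, 29))
                               for c in codes if rng.random() < 0.7})
        M = map_comorbidities(tiny_records, cmap)
        for i, (_, r) in enumerate(tiny_records.iterrows()):
            for k in range(29):
                expected = any(cmap.mapping.get(c) == k
                               for c in r["secondary_dx"])
                assert M[i, k] == int(expected)

    def test_synthetic_map_has_29_category_space(self, small_dataset):
        _, _, universe, _ = small_dataset
        cmap = synthetic_comorbidity_map(universe)
        assert all(0 <= v < 29 for v in cmap.mapping.values())
        table = cmap.to_table()
        back = ComorbidityMap.from_table(table)
        assert back.mapping == cmap.mapping

    def test_category_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ComorbidityMap({"D1": 29})


class TestSplit:
    def test_hospital_of_ten_gets_8_1_1(self):
        df = pd.DataFrame([_base_record(patient_id=i) for i in range(10)])
        split = split_cohort(df, seed=0)
        vals, counts = np.unique(split, return_counts=True)
        got = dict(zip(vals, counts))
        assert got == {"train": 8, "validation": 1, "test": 1}

    def test_partition_and_per_hospital_bound(self, small_dataset):
        _, _, _, table = small_dataset
        split = split_cohort(table, seed=1)
        assert set(np.unique(split)) <= {"train", "validation", "test"}
        for h in table["hospital_id"].unique():
            mask = table["hospital_id"].to_numpy() == h
            n = mask.sum()
            for part, p in (("train", 0.8), ("validation", 0.1), ("test", 0.1)):
                got = (split[mask] == part).sum()
                assert abs(got - p * n) < 1.0

    def test_seed_determinism_and_sensitivity(self, tiny_records):
        a = split_cohort(tiny_records, seed=4)
        b = split_cohort(tiny_records, seed=4)
        c = split_cohort(tiny_records, seed=5)
        assert (a == b).all()
        assert (a != c).any()

    def test_bad_proportions_rejected(self, tiny_records):
        with pytest.raises(ValueError):
            split_cohort(tiny_records, proportions=(0.5, 0.2, 0.2))


class TestBuildCohort:
    def test_end_to_end_invariants(self, small_dataset):
        cfg, hospitals, universe, table = small_dataset
        cond = ConditionConfig.from_universe(universe, "ami")
        coh = build_cohort(table, cond, seed=3)
        # one record per patient
        assert coh.records["patient_id"].is_unique
        # every hospital has >= 10 records
        assert coh.records.groupby("hospital_id").size().min() >= 10
        # all retained codes are in vocabulary
        vocab = set(coh.dx_vocabulary) | set(coh.proc_vocabulary)
        for s, p in zip(coh.records["secondary_dx"], coh.records["procedures"]):
            assert set(s) <= vocab
            assert set(p) <= vocab
        # outcome excludes planned readmissions
        y = coh.y
        planned = coh.records["planned_readmit"].to_numpy() == 1
        assert (y[planned] == 0).all()

    def test_unknown_condition_rejected(self, small_dataset):
        _, _, universe, _ = small_dataset
        with pytest.raises(ValueError):
            ConditionConfig.from_universe(universe, "copd")
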