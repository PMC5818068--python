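import numpy as np
import pytest

from lungcad import (
    CaseInventory,
    CaseRecord,
    EmptyCompositionError,
    PhantomSpec,
    compose_training,
    generate_cohort,
    kfold_split,
    run_regime_experiment,
)
from lungcad.volume_io import downsample_slices


def _records(n_thin_train, n_thick_train, n_test, test_thickness):
    recs = []
    for i in range(n_thin_train):
        recs.append(CaseRecord(f"thin{i}", 1.25, 1.25, "train"))
    for i in range(n_thick_train):
        recs.append(CaseRecord(f"thick{i}", 2.5, 2.5, "train"))
    for i in range(n_test):
        recs.append(CaseRecord(f"test{i}", test_thickness, test_thickness, "test"))
    return CaseInventory(recs)


class TestComposeTraining:
    """Composition counts are pure functions of the inventory; the
    screening-study training tables are reproduced exactly."""

    def test_thin_test_compositions(self):
        inv = _records(112, 283, 80, 1.25)

        agg = compose_training(inv, "aggregate", 1.25)
        assert len(agg.entries) == 395
        assert agg.count(1.25, resampled=False) == 112
        assert agg.count(2.5, resampled=False) == 283
        assert agg.count(1.25, resampled=False, test=True) == 80

        hom = compose_training(inv, "homogeneous", 1.25)
        assert len(hom.entries) == 112
        assert all(e.native_thickness_mm == 1.25 for e in hom.entries)

        com = compose_training(inv, "common", 1.25, common_thickness_mm=2.5)
        assert com.count(2.5, resampled=False) == 283
        assert com.count(1.25, resampled=True) == 112
        assert all(
            e.resample_ratio == 2
            for e in com.entries
            if e.native_thickness_mm == 1.25
        )
        # the thin test cases are flagged for resampling too
        assert com.count(1.25, resampled=True, test=True) == 80

    def test_thick_test_compositions(self):
        inv = _records(192, 183, 100, 2.5)

        agg = compose_training(inv, "aggregate", 2.5)
        assert len(agg.entries) == 375
        assert agg.count(1.25, resampled=False) == 192
        assert agg.count(2.5, resampled=False) == 183

        hom = compose_training(inv, "homogeneous", 2.5)
        assert len(hom.entries) == 183

        com = compose_training(inv, "common", 2.5, common_thickness_mm=2.5)
        assert com.count(2.5, resampled=False) == 183
        assert com.count(1.25, resampled=True) == 192
        # thick test cases are never resampled at the 2.5-mm common thickness
        assert com.count(2.5, resampled=False, test=True) == 100
        assert com.count(2.5, resampled=True, test=True) == 0

    def test_no_test_case_ever_trains(self):
        inv = _records(5, 5, 3, 1.25)
        for regime in ("aggregate", "homogeneous", "common"):
            comp = compose_training(inv, regime, 1.25)
            assert not {f"test{i}" for i in range(3)} & set(comp.train_case_ids)

    def test_homogeneous_without_matches_fails_loudly(self):
        inv = _records(0, 10, 3, 1.25)
        with pytest.raises(EmptyCompositionError):
            compose_training(inv, "homogeneous", 1.25)

    def test_indivisible_native_thickness_excluded_with_warning(self):
        recs = [
            CaseRecord("a", 1.25, 1.25, "train"),
            CaseRecord("b", 2.0, 2.0, "train"),
            CaseRecord("t", 2.5, 2.5, "test"),
        ]
        with pytest.warns(UserWarning, match="does not divide"):
            comp = compose_training(CaseInventory(recs), "common", 2.5, 2.5)
        assert [e.case_id for e in comp.entries] == ["a"]

    def test_mixed_thickness_spacing_rejected(self):
        with pytest.raises(ValueError, match="thickness"):
            CaseRecord("x", 2.5, 1.25, "train")

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CaseInventory([
                CaseRecord("x", 1.25, 1.25, "train"),
                CaseRecord("x", 1.25, 1.25, "test"),
            ])


class TestKFold:
    def test_even_partition(self):
        ids = [f"c{i}" for i in range(100)]
        folds = kfold_split(ids, k=10, seed=3)
        assert len(folds) == 10
        assert all(len(f) == 10 for f in folds)
        assert sorted(x for f in folds for x in f) == sorted(ids)

    def test_seed_reproducibility(self):
        ids = [f"c{i}" for i in range(30)]
        assert kfold_split(ids, 10, seed=4) == kfold_split(ids, 10, seed=4)
        assert kfold_split(ids, 10, seed=4) != kfold_split(ids, 10, seed=5)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(["a", "b"], k=10)


class TestRegimeExperiment:
    @pytest.fixture(scope="class")
    def two_thickness_inventory(self):
        """Small in-memory inventory: 2.5-mm test cases plus train cases at
        both thicknesses (thick cases are slab-averaged phantoms)."""
        cases = generate_cohort(9, PhantomSpec(), (1, 2), seed=314)
        records = []
        for i, case in enumerate(cases):
            if i < 3:  # test at 2.5-mm native
                case.volume = downsample_slices(case.volume, 2)
                records.append(
                    CaseRecord(case.case_id, 2.5, 2.5, "test", case=case)
                )
            elif i < 6:  # thin training
                records.append(
                    CaseRecord(case.case_id, 1.25, 1.25, "train", case=case)
                )
            else:  # thick training
                case.volume = downsample_slices(case.volume, 2)
                records.append(
                    CaseRecord(case.case_id, 2.5, 2.5, "train", case=case)
                )
        return CaseInventory(records)

    def test_all_regimes_report_and_share_detector_sensitivity(
        self, two_thickness_inventory
    ):
        report = run_regime_experiment(
            two_thickness_inventory, seed=0, max_features=4
        )
        assert list(report["regime"]) == ["aggregate", "homogeneous", "common"]
        assert (report["status"] == "ok").all()
        # test volumes are used unresampled in every regime (2.5-mm test,
        # 2.5-mm common thickness), so the pre-classifier sensitivity is
        # classifier-independent and identical across rows
        sens = report["candidate_sensitivity"].to_numpy()
        assert np.allclose(sens, sens[0])
        assert report["n_train_cases"].tolist() == [6, 3, 6]
        assert report["n_train_resampled"].tolist() == [0, 0, 3]

    def test_single_regime_gives_single_row(self, two_thickness_inventory):
        report = run_regime_experiment(
            two_thickness_inventory, regimes=("aggregate",), seed=0, max_features=3
        )
        assert len(report) == 1

    def test_impossible_homogeneous_regime_reports_failure_row(self):
        cases = generate_cohort(4, PhantomSpec(), (1, 1), seed=11)
        records = []
        for i, case in enumerate(cases):
            if i < 2:
                case.volume = downsample_slices(case.volume, 2)
                records.append(CaseRecord(case.case_id, 2.5, 2.5, "test", case=case))
            else:
                records.append(CaseRecord(case.case_id, 1.25, 1.25, "train", case=case))
        report = run_regime_experiment(
            CaseInventory(records), regimes=("homogeneous",), seed=0
        )
        assert len(report) == 1
        assert report.loc[0, "status"].startswith("failed")


class TestThicknessStudy:
    def test_report_covers_requested_ratios(self):
        from lungcad.harness import run_thickness_study

        cases = generate_cohort(6, PhantomSpec(), (1, 2), seed=99)
        report = run_thickness_study(
            cases, ratios=(1, 2), test_fraction=0.34, seed=0, max_features=3
        )
        assert report["ratio"].tolist() == [1, 2]
        assert report["thickness_mm"].tolist() == [1.25, 2.5]
        assert report["auc_0_10"].notna().all()
        assert report["candidate_sensitivity"].notna().all()
        assert report["n_features_selected"].between(1, 3).all()

    def test_nonstandard_ratio_accepted_with_warning(self):
        from lungcad.harness import run_thickness_study

        cases = generate_cohort(3, PhantomSpec(), (1, 1), seed=100)
        with pytest.warns(UserWarning, match="non-standard"):
            report = run_thickness_study(
                cases, ratios=(3,), test_fraction=0.34, seed=0, max_features=2
            )
        assert report["thickness_mm"].tolist() == [3.75]
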