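import hashlib

import numpy as np
import pandas as pd
import pytest

import pinenir as pn
from pinenir.model_selection import all_region_combos
from pinenir.preprocess import PreprocessSpec


class TestSplits:
    @pytest.mark.parametrize("seed", [0, 1, 7, 123])
    def test_proportional_discrimination_split_sizes(self, default_set, seed):
        plan = pn.make_split(default_set, "discrimination", seed=seed)
        cal, val = plan.rows(default_set)
        sp = np.asarray(default_set.species)
        cal_counts = pd.Series(sp[cal]).value_counts()
        val_counts = pd.Series(sp[val]).value_counts()
        assert cal_counts["Aleppo"] == 33 and val_counts["Aleppo"] == 15
        assert cal_counts["Maritime"] == 4 and val_counts["Maritime"] == 2
        assert cal_counts["Brutia"] == 4 and val_counts["Brutia"] == 2

    def test_split_is_partition(self, default_set):
        plan = pn.make_split(default_set, "discrimination", seed=5)
        ids = set(plan.calibration_ids) | set(plan.validation_ids)
        assert ids == set(default_set.spectrum_id)
        assert not set(plan.calibration_ids) & set(plan.validation_ids)

    def test_seed_determinism(self, default_set):
        a = pn.make_split(default_set, "regression", "TotalFat", seed=3)
        b = pn.make_split(default_set, "regression", "TotalFat", seed=3)
        c = pn.make_split(default_set, "regression", "TotalFat", seed=4)
        assert a == b
        assert set(a.calibration_ids) != set(c.calibration_ids)
        assert len(c.calibration_ids) == len(a.calibration_ids)

    @pytest.mark.parametrize("seed", range(5))
    def test_regression_range_constraint(self, default_set, seed):
        plan = pn.make_split(default_set, "regression", "TotalFat", seed=seed)
        y = default_set.reference_values("TotalFat")
        cal, val = plan.rows(default_set)
        assert y[val].min() >= y[cal].min()
        assert y[val].max() <= y[cal].max()
        # calibration must carry the global extremes (otherwise a validation
        # value would fall outside the calibration range)
        assert y[cal].max() == y.max() and y[cal].min() == y.min()

    def test_group_replicates_keeps_samples_together(self, default_set):
        plan = pn.make_split(default_set, "discrimination", seed=2,
                             group_replicates=True)
        cal, val = plan.rows(default_set)
        cal_samples = set(default_set.sample_id[cal])
        val_samples = set(default_set.sample_id[val])
        assert not cal_samples & val_samples


class TestCrossValidation:
    def _toy(self, rng, n_samples=8, reps=2, p=4, noise=0.0):
        sample_ids = np.repeat([f"s{i}" for i in range(n_samples)], reps)
        X = rng.normal(size=(n_samples * reps, p))
        beta = rng.normal(size=p)
        y = X @ beta + noise * rng.normal(size=X.shape[0])
        return X, y, sample_ids

    def test_noiseless_linear_response_chooses_small_lv(self, rng):
        X, y, sids = self._toy(rng)
        cv = pn.cross_validate(X, y, sids, PreprocessSpec(()), max_lv=4)
        # exact linear signal: RMSECV collapses once enough LVs are in
        assert cv.curve.min() < 1e-6 * np.std(y)
        assert cv.chosen_n_lv == int(np.argmin(cv.curve)) + 1

    def test_pure_noise_no_better_than_null_model(self, rng):
        sample_ids = np.repeat([f"s{i}" for i in range(10)], 2)
        X = rng.normal(size=(20, 15))
        y = rng.normal(size=20)
        cv = pn.cross_validate(X, y, sample_ids, PreprocessSpec(()), max_lv=5)
        assert cv.null_score is not None
        assert np.all(cv.curve >= cv.null_score * 0.9)

    def test_folds_group_by_sample(self, default_set):
        # a fold leaves out all replicates of one sample: predictions for
        # replicates of the same sample come from the same training set
        sub = pn.subset_regions(default_set, ("R1",))
        y = default_set.reference_values("TotalFat")
        cv = pn.cross_validate(sub.absorbance, y, sub.sample_id,
                               PreprocessSpec(()), max_lv=3)
        assert cv.curve.shape == (3,)

    def test_max_lv_truncated_with_warning(self, rng):
        X, y, sids = self._toy(rng, n_samples=4, reps=1, p=3)
        with pytest.warns(UserWarning, match="truncated"):
            cv = pn.cross_validate(X, y, sids, PreprocessSpec(()), max_lv=10)
        assert cv.curve.size <= 3

    def test_too_few_samples_rejected(self, rng):
        X, y, sids = self._toy(rng, n_samples=2, reps=3)
        with pytest.raises(ValueError, match="3 distinct"):
            pn.cross_validate(X, y, sids, PreprocessSpec(()), max_lv=2)

    def test_tie_breaks_to_smallest_lv(self):
        curve = np.array([1.0, 0.5, 0.5, 0.7])
        assert int(np.argmin(curve)) + 1 == 2  # documents the argmin rule


class TestGridSearch:
    def test_default_grid_combinatorics(self):
        assert len(all_region_combos()) == 31
        assert len(all_region_combos()) * len(pn.DEFAULT_SPEC_GRID) == 186

    def test_table_has_one_row_per_candidate(self, default_set):
        plan = pn.make_split(default_set, "regression", "TotalFat", seed=0)
        cal, _ = plan.rows(default_set)
        res = pn.grid_search(default_set, cal, "regression", "TotalFat",
                             region_combos=[("R1",), ("R3",)],
                             specs=["none", "SNV"], max_lv=4)
        assert len(res.table) == 4
        best = res.table.sort_values(["rmsecv", "rmsec"]).iloc[0]
        assert res.criterion == pytest.approx(best["rmsecv"])

    def test_validation_rows_untouched(self, default_set):
        plan = pn.make_split(default_set, "regression", "TotalFat", seed=0)
        cal, val = plan.rows(default_set)
        before = hashlib.sha256(
            default_set.absorbance[val].tobytes()).hexdigest()
        pn.grid_search(default_set, cal, "regression", "TotalFat",
                       region_combos=[("R1",)], specs=["none"], max_lv=3)
        after = hashlib.sha256(
            default_set.absorbance[val].tobytes()).hexdigest()
        assert before == after

    def test_winner_found_where_signal_lives(self):
        # construct spectra whose only y-dependent structure sits in bands
        # inside R1 and R3; the winning combination must not need more
        rng = np.random.default_rng(7)
        grid = pn.default_grid()
        band_r1 = np.exp(-((grid - 4500.0) ** 2) / (2 * 30.0 ** 2))
        band_r3 = np.exp(-((grid - 5800.0) ** 2) / (2 * 30.0 ** 2))
        n_samples = 12
        y = rng.uniform(0.0, 1.0, n_samples)
        rows, sids, reps = [], [], []
        for i in range(n_samples):
            for r in (1, 2):
                rows.append(y[i] * (band_r1 + band_r3)
                            + 0.01 * rng.normal(size=grid.size))
                sids.append(f"s{i}")
                reps.append(r)
        ref = pd.DataFrame({"target": y},
                           index=[f"s{i}" for i in range(n_samples)])
        s = pn.SpectraSet(grid, np.asarray(rows),
                          [f"s{i}r{r}" for i, r in zip(sids, reps)],
                          sids, reps, reference=ref)
        res = pn.grid_search(s, np.arange(s.n_spectra), "regression", "target",
                             region_combos=[("R1",), ("R3",), ("R1", "R3"),
                                            ("R2", "R4"), tuple(pn.REGION_NAMES)],
                             specs=["none"], max_lv=3)
        assert set(res.best_combo) <= {"R1", "R3"}

    def test_criterion_permutation_invariant(self, default_set):
        plan = pn.make_split(default_set, "regression", "TotalFat", seed=0)
        cal, _ = plan.rows(default_set)
        kwargs = dict(specs=["none", "SNV"], max_lv=3)
        a = pn.grid_search(default_set, cal, "regression", "TotalFat",
                           region_combos=[("R1",), ("R3",)], **kwargs)
        b = pn.grid_search(default_set, cal, "regression", "TotalFat",
                           region_combos=[("R3",), ("R1",)], **kwargs)
        assert a.best_combo == b.best_combo
        assert a.criterion == pytest.approx(b.criterion)
        merged = a.table.merge(b.table, on=["combo_label", "spec_label"])
        np.testing.assert_allclose(merged["rmsecv_x"], merged["rmsecv_y"])

    def test_rmsec_nonincreasing_for_nested_combos(self, default_set):
        # at full rank, adding columns cannot worsen the calibration fit
        plan = pn.make_split(default_set, "regression", "TotalFat", seed=0)
        cal, _ = plan.rows(default_set)
        y = default_set.reference_values("TotalFat")[cal]

        def full_rank_rmsec(combo):
            sub = pn.subset_regions(default_set.take(cal), combo)
            Xc = sub.absorbance - sub.absorbance.mean(axis=0)
            yc = y - y.mean()
            resid = yc - Xc @ np.linalg.lstsq(Xc, yc, rcond=None)[0]
            return float(np.sqrt(np.mean(resid ** 2)))

        assert full_rank_rmsec(("R1", "R3")) <= full_rank_rmsec(("R1",)) + 1e-8
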