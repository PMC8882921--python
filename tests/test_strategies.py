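"""The five strategy orchestrations, random grouping, rating binarization."""

import numpy as np
import pytest

import microstates as m
from microstates.exceptions import ConfigError, NoSplitError
from microstates.strategies import Dataset, extract_all_candidates


@pytest.fixture(scope="module")
def params():
    return m.ClusteringParams(seed=1, restarts=5)


class TestCase1:
    def test_step2_input_is_subjects_times_k(self, small_ds, small_candidates, params):
        res = m.run_case1(small_ds, params, small_candidates)
        assert res.banks["step1"].pooled_maps.shape[0] == 4 * 4  # 4 subjects x K=4

    def test_single_subject_degenerates_to_recluster(self, small_dataset, params):
        recs = [r for r in small_dataset.recordings if r.subject_id == "S01"]
        mani = small_dataset.manifest.query("subject_id == 'S01'")
        ds = Dataset(recs, mani)
        res = m.run_case1(ds, params)
        step1 = next(iter(res.banks["step1"].units.values()))
        assert m.match_templates(res.final, step1).mean_r == pytest.approx(1.0, abs=1e-6)

    def test_recovery_on_synthetic(self, small_ds, small_candidates, small_dataset, params):
        res = m.run_case1(small_ds, params, small_candidates)
        truth = m.MicrostateSet(small_dataset.truth.templates)
        assert m.match_templates(res.final, truth).mean_r >= 0.99


class TestCase2:
    def test_groups_by_video(self, small_ds, small_candidates, params):
        res = m.run_case2(small_ds, params, small_candidates)
        n_videos = small_ds.manifest["video_id"].nunique()
        assert len(res.banks["step1"].units) == n_videos
        assert res.banks["step1"].pooled_maps.shape[0] == n_videos * 4

    def test_recovery_on_synthetic(self, small_ds, small_candidates, small_dataset, params):
        res = m.run_case2(small_ds, params, small_candidates)
        truth = m.MicrostateSet(small_dataset.truth.templates)
        assert m.match_templates(res.final, truth).mean_r >= 0.99


class TestCase3:
    def test_one_unit_per_trial(self, small_ds, small_candidates, params):
        res = m.run_case3(small_ds, params, small_candidates)
        assert len(res.banks["step1"].units) == len(small_ds.recordings)

    def test_single_trial_dataset_final_matches_trial_templates(self, small_dataset, params):
        rec = small_dataset.recordings[0]
        mani = small_dataset.manifest.iloc[[0]]
        ds = Dataset([rec], mani)
        res = m.run_case3(ds, params)
        trial_set = next(iter(res.banks["step1"].units.values()))
        assert m.match_templates(res.final, trial_set).mean_r == pytest.approx(1.0, abs=1e-6)

    def test_recovery_on_synthetic(self, small_ds, small_candidates, small_dataset, params):
        res = m.run_case3(small_ds, params, small_candidates)
        truth = m.MicrostateSet(small_dataset.truth.templates)
        assert m.match_templates(res.final, truth).mean_r >= 0.99


class TestRandomGrouping:
    def test_dealing_sizes(self):
        rng = np.random.default_rng(0)
        parts = m.random_grouping(list(range(10)), 3, rng)
        assert sorted(len(p) for p in parts) == [3, 3, 4]
        assert sorted(x for p in parts for x in p) == list(range(10))

    def test_every_trial_exactly_once(self):
        rng = np.random.default_rng(1)
        keys = [f"t{i}" for i in range(37)]
        parts = m.random_grouping(keys, 5, rng)
        flat = [x for p in parts for x in p]
        assert sorted(flat) == sorted(keys) and len(flat) == 37

    def test_deterministic_by_seed(self):
        a = m.random_grouping(list(range(20)), 4, np.random.default_rng(42))
        b = m.random_grouping(list(range(20)), 4, np.random.default_rng(42))
        assert a == b

    def test_too_many_groups_rejected(self):
        with pytest.raises(ConfigError):
            m.random_grouping(list(range(3)), 4, np.random.default_rng(0))


class TestCase4:
    def test_group_count_and_pool_size(self, small_ds, small_candidates, params):
        res = m.run_case4(small_ds, 4, params, small_candidates)
        assert len(res.banks["step1"].units) == 4
        assert res.banks["step1"].pooled_maps.shape[0] == 4 * 4

    def test_n_groups_equal_trials_reduces_to_case3(self, small_ds, small_candidates, params):
        n = len(small_ds.recordings)
        res4 = m.run_case4(small_ds, n, params, small_candidates)
        assert len(res4.banks["step1"].units) == n
        sizes = sorted(len(u.provenance.get("unit", "")) for u in res4.banks["step1"].units.values())
        res3 = m.run_case3(small_ds, params, small_candidates)
        assert m.match_templates(res4.final, res3.final).mean_r >= 0.99

    def test_recovery_on_synthetic(self, small_ds, small_candidates, small_dataset, params):
        res = m.run_case4(small_ds, 4, params, small_candidates)
        truth = m.MicrostateSet(small_dataset.truth.templates)
        assert m.match_templates(res.final, truth).mean_r >= 0.99


class TestBinarizeRatings:
    @pytest.mark.parametrize(
        "ratings,threshold,expected_high",
        [
            ([2, 3, 7, 8], 5.0, [False, False, True, True]),
            ([1, 9], 5.0, [False, True]),
            ([1, 1, 1, 2], 1.5, [False, False, False, True]),
        ],
    )
    def test_exhaustive_two_means_examples(self, ratings, threshold, expected_high):
        high, thr = m.binarize_ratings(ratings)
        assert thr == pytest.approx(threshold)
        assert list(high) == expected_high

    def test_identical_ratings_rejected(self):
        with pytest.raises(NoSplitError):
            m.binarize_ratings([5, 5, 5])

    def test_threshold_between_centroids(self, rng):
        for _ in range(50):
            r = rng.integers(1, 10, size=10)
            if np.unique(r).size < 2:
                continue
            high, thr = m.binarize_ratings(r)
            assert r[high].min() > thr >= r[~high].max()


class TestCase5:
    def test_pool_size_subjects_by_levels(self, small_ds, small_candidates, params):
        res = m.run_case5(small_ds, "valence", params, small_candidates)
        n_low = len(res.banks["step2_low"].units)
        n_high = len(res.banks["step2_high"].units)
        pooled = sum(
            res.banks[f"step2_{lvl}"].pooled_maps.shape[0] for lvl in ("low", "high")
        )
        assert pooled == (n_low + n_high) * 4

    def test_reuses_trial_bank(self, small_ds, small_candidates, params):
        res3 = m.run_case3(small_ds, params, small_candidates)
        res5 = m.run_case5(
            small_ds, "valence", params, small_candidates, trial_bank=res3.banks["step1"]
        )
        assert res5.timings["step1"] == 0.0
        assert res5.banks["step1"] is res3.banks["step1"]

    def test_recovery_on_synthetic(self, small_ds, small_candidates, small_dataset, params):
        truth = m.MicrostateSet(small_dataset.truth.templates)
        for dim in ("valence", "arousal"):
            res = m.run_case5(small_ds, dim, params, small_candidates)
            assert m.match_templates(res.final, truth).mean_r >= 0.99

    def test_four_plus_timing_entries(self, small_ds, small_candidates, params):
        res = m.run_case5(small_ds, "valence", params, small_candidates)
        step_keys = [k for k in res.timings if k != "total"]
        assert len(step_keys) >= 4  # step1, step2_low, step2_high, step3
        assert res.timings["total"] == pytest.approx(sum(res.timings[k] for k in step_keys))


class TestConservation:
    def test_each_trial_enters_exactly_one_step1_unit(self, small_ds, small_candidates, params):
        n_maps = sum(v.shape[0] for v in small_candidates.values())
        for name in ("case1", "case2", "case3"):
            res = m.run_strategy(name, small_ds, params, small_candidates)
            used = 0
            for key, ms in res.banks["step1"].units.items():
                used += ms.provenance["n_maps"]
            assert used == n_maps
        res4 = m.run_case4(small_ds, 4, params, small_candidates)
        used = sum(ms.provenance["n_maps"] for ms in res4.banks["step1"].units.values())
        assert used == n_maps
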