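"""Effect sizes, median splits, latent distances and pipeline error handling."""

import numpy as np
import pytest

from perturbscape.fitting import FitResult
from perturbscape.priors import GroupingMatrix
from perturbscape.reporting import (
    EffectSize,
    cohens_d,
    compare_parameter_ensembles,
    latent_distance_distributions,
    run_pipeline,
    split_by_median,
)
from perturbscape.vae import LatentPoint


def _fit_result(delta, seed=0):
    return FitResult(
        best_delta=np.asarray(delta, float),
        best_gof=0.1,
        best_fc=None,
        history={"best": np.array([0.1]), "mean": np.array([0.1])},
        halting_reason="max_generations",
        seed=seed,
    )


class TestCohensD:
    def test_textbook_worked_example(self):
        # means 2 and 3, both sample variances 1 -> pooled SD 1, d = -1
        assert cohens_d([1, 2, 3], [2, 3, 4]) == pytest.approx(-1.0, abs=1e-12)

    def test_large_sample_standardized_shift(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(10_000)
        b = rng.standard_normal(10_000) + 1.0
        assert cohens_d(b, a) == pytest.approx(1.0, abs=0.05)

    def test_antisymmetry_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(40), rng.standard_normal(40) + 0.5
        assert cohens_d(a, b) == -cohens_d(b, a)
        assert cohens_d(3.0 * a, 3.0 * b) == pytest.approx(cohens_d(a, b), abs=1e-12)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d([1.0, 1.0], [1.0, 1.0])

    def test_hedges_correction_shrinks_magnitude(self):
        d = cohens_d([1, 2, 3], [2, 3, 4])
        g = cohens_d([1, 2, 3], [2, 3, 4], hedges=True)
        assert abs(g) < abs(d)


class TestEffectFlags:
    def _samples_with_exact_d(self, d):
        # b = {-1, 0, 1} has sample variance exactly 1; shifting by a
        # binary-exact d gives Cohen's d equal to d with no rounding
        b = np.array([-1.0, 0.0, 1.0])
        return b + d, b

    @pytest.mark.parametrize(
        "d,large,very_large",
        [(0.75, False, False), (0.8125, True, False), (1.25, True, False), (1.3125, True, True)],
    )
    def test_thresholds_are_strict(self, d, large, very_large):
        a, b = self._samples_with_exact_d(d)
        eff = EffectSize.from_samples(a, b)
        assert eff.d == d
        assert eff.large is large and eff.very_large is very_large

    def test_direction_of_shift(self):
        a, b = self._samples_with_exact_d(-1.5)
        assert EffectSize.from_samples(a, b).direction == "toward_fixed_point"


class TestEnsembleComparison:
    @pytest.fixture
    def prior(self):
        M = np.zeros((6, 3), dtype=int)
        M[[0, 1], 0] = 1
        M[[2, 3], 1] = 1
        M[[4, 5], 2] = 1
        return GroupingMatrix(M, ["g0", "g1", "g2"])

    def _ensemble(self, offset, seed, n=12):
        rng = np.random.default_rng(seed)
        return [
            _fit_result(offset + 0.01 * rng.standard_normal(3), seed=i) for i in range(n)
        ]

    def test_only_shifted_coefficient_flagged(self, prior):
        ensembles = {
            "CNT": self._ensemble(np.zeros(3), seed=1),
            "PAT": self._ensemble(np.array([-0.2, 0.0, 0.0]), seed=2),
        }
        report = compare_parameter_ensembles(ensembles, prior)["PAT"]
        assert report.delta_level["g0"].large
        assert not report.delta_level["g1"].large
        assert not report.delta_level["g2"].large
        assert report.delta_level["g0"].direction == "toward_fixed_point"
        assert set(report.flagged_regions) == {"R000", "R001"}

    def test_matched_ensembles_produce_no_flags(self, prior):
        ensembles = {
            "CNT": self._ensemble(np.zeros(3), seed=3, n=30),
            "PAT": self._ensemble(np.zeros(3), seed=4, n=30),
        }
        report = compare_parameter_ensembles(ensembles, prior)["PAT"]
        assert not any(e.large for e in report.delta_level.values())

    def test_missing_control_rejected(self, prior):
        with pytest.raises(KeyError):
            compare_parameter_ensembles({"PAT": self._ensemble(np.zeros(3), 5)}, prior)


class TestMedianSplit:
    def test_even_count_splits_in_half(self):
        low, high = split_by_median([1, 2, 3, 4], ["a", "b", "c", "d"])
        assert (low, high) == (["a", "b"], ["c", "d"])

    def test_odd_count_sizes_differ_by_one_with_ties_high(self):
        low, high = split_by_median([10, 20, 30], ["a", "b", "c"])
        assert low == ["a"] and high == ["b", "c"]

    def test_permutation_leaves_sets_unchanged(self):
        scores = [5, 1, 4, 2, 3]
        labels = ["a", "b", "c", "d", "e"]
        low1, high1 = split_by_median(scores, labels)
        perm = [3, 0, 4, 1, 2]
        low2, high2 = split_by_median([scores[i] for i in perm], [labels[i] for i in perm])
        assert set(low1) == set(low2) and set(high1) == set(high2)

    def test_all_equal_rejected(self):
        with pytest.raises(ValueError, match="median"):
            split_by_median([2.0, 2.0, 2.0])


class TestLatentDistances:
    def test_rigid_translation_leaves_distances_unchanged(self):
        rng = np.random.default_rng(2)
        pts = {g: [LatentPoint(*rng.standard_normal(2)) for _ in range(6)] for g in ("CNT", "X")}
        moved = {
            g: [LatentPoint(p.z1 + 3.0, p.z2 - 1.5) for p in ps] for g, ps in pts.items()
        }
        d1, _ = latent_distance_distributions(pts, "CNT")
        d2, _ = latent_distance_distributions(moved, "CNT")
        for g in pts:
            np.testing.assert_allclose(d1[g], d2[g], atol=1e-12)

    def test_severity_graded_groups_are_ordered(self):
        rng = np.random.default_rng(3)
        pts = {"CNT": [LatentPoint(*(0.05 * rng.standard_normal(2))) for _ in range(10)]}
        for name, shift in (("mild", 1.0), ("severe", 2.5)):
            pts[name] = [
                LatentPoint(shift + 0.05 * rng.standard_normal(), 0.05 * rng.standard_normal())
                for _ in range(10)
            ]
        dists, effects = latent_distance_distributions(pts, "CNT")
        assert dists["CNT"].mean() < dists["mild"].mean() < dists["severe"].mean()
        assert effects["severe"] > effects["mild"] > 0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            latent_distance_distributions({"CNT": [], "X": [LatentPoint(0, 0)]}, "CNT")


class TestPipelineFailureHandling:
    def test_bad_stage_marks_failed_and_skips_downstream(self, tmp_path):
        config = {
            "seed": 1,
            "synthetic": {"n_regions": 12, "subjects_per_group": 2, "duration": 280.0},
            "fit": {"groups": ["NOT_A_GROUP"], "n_runs": 2,
                    "ga": {"max_generations": 2, "stall_generations": 50}},
        }
        manifest = run_pipeline(config, tmp_path / "run")
        assert manifest["stages"]["synth"]["status"] == "done"
        assert manifest["stages"]["fit"]["status"] == "failed"
        assert manifest["stages"]["vae"]["status"] == "skipped"
        assert manifest["stages"]["report"]["status"] == "skipped"
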