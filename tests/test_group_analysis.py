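"""Group-level statistics: summaries, correlations, FDR, bootstrap curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from cvrkit.cvr_mapping import CVRMap
from cvrkit.group_analysis import (
    SubjectCVRSet,
    across_subject_correlation,
    bh_fdr,
    coefficient_of_variation,
    fisher_z,
    gm_summary,
    inverse_fisher_z,
    roi_fisher_maps,
    second_level_tmap,
    spatial_correlation_vs_n,
    steiger_test,
    threshold_curves,
)
from cvrkit.pipeline import process_synthetic_subject
from cvrkit.synthetic import GroundTruth, gen_cohort

SHAPE = (4, 4, 2)


def make_map(beta, z=None, weighting="asl"):
    beta = np.broadcast_to(np.asarray(beta, float), SHAPE).copy()
    z = beta * 0 + 5.0 if z is None else np.broadcast_to(np.asarray(z, float), SHAPE).copy()
    return CVRMap(beta=beta, z=z, lag=np.zeros(SHAPE), weighting=weighting)


def uniform_set(n_subjects=4, asl=5.0, ge=0.2, se=0.1):
    maps = [
        {"asl": make_map(asl), "ge": make_map(ge, weighting="ge"),
         "se": make_map(se, weighting="se")}
        for _ in range(n_subjects)
    ]
    return SubjectCVRSet(maps=maps, gm_mask=np.ones(SHAPE, dtype=bool))


class TestCoV:
    def test_constant_is_zero(self):
        assert coefficient_of_variation([5, 5, 5]) == 0.0

    def test_two_point_closed_form(self):
        assert coefficient_of_variation([1, 3]) == pytest.approx(np.sqrt(2) / 2)

    def test_group_value_scale(self):
        # mean 5.3, sample SD 1.8 -> CoV 0.3396 (~34%)
        d = 1.8 / np.sqrt(2)
        vals = [5.3 - d, 5.3 + d]
        assert coefficient_of_variation(vals) == pytest.approx(0.3396, abs=2e-4)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])


def test_fisher_round_trip():
    r = np.linspace(-0.999, 0.999, 41)
    assert np.allclose(inverse_fisher_z(fisher_z(r)), r, atol=1e-12)


class TestAcrossSubjectCorrelation:
    def test_identical_vectors(self):
        r, p = across_subject_correlation([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert r == pytest.approx(1.0)

    def test_anticorrelated(self):
        a = np.array([1.0, 2, 3, 4])
        r, _ = across_subject_correlation(a, -a)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            across_subject_correlation([1.0, 1, 1], [1.0, 2, 3])

    def test_monte_carlo_rho_recovery_and_null_rate(self):
        """n=20 bivariate normal: mean r near atanh-biased 0.7; ~5% false
        positives at rho=0."""
        rng = np.random.default_rng(8)
        rho = 0.7
        rs, null_p = [], []
        for _ in range(2000):
            z = rng.normal(size=(2, 20))
            a = z[0]
            b = rho * z[0] + np.sqrt(1 - rho**2) * z[1]
            rs.append(across_subject_correlation(a, b)[0])
            null_p.append(across_subject_correlation(z[0], rng.normal(size=20))[1])
        assert np.mean(rs) == pytest.approx(0.69, abs=0.01)
        rate = np.mean(np.asarray(null_p) < 0.05)
        assert rate == pytest.approx(0.05, abs=0.015)

    def test_spearman_available(self):
        r, _ = across_subject_correlation([1.0, 2, 3, 10], [1.0, 4, 9, 11], "spearman")
        assert r == pytest.approx(1.0)


def fdr_oracle(p, q=0.05):
    """Brute-force BH step-up: largest k with p_(k) <= k q / m rejects all
    p <= p_(k)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.sort(p)
    thresh = 0.0
    for k in range(m, 0, -1):
        if order[k - 1] <= k * q / m:
            thresh = order[k - 1]
            break
    return p <= thresh if thresh > 0 else np.zeros(m, bool)


@given(st.integers(0, 5000), st.integers(1, 48))
def test_bh_fdr_matches_step_up_oracle(seed, m):
    rng = np.random.default_rng(seed)
    # mix of null and signal p-values
    p = np.concatenate([rng.uniform(size=m // 2 + 1), rng.beta(0.3, 8, size=m // 2)])[:m]
    assert np.array_equal(bh_fdr(p), fdr_oracle(p))


class TestSecondLevel:
    def test_hand_computed_t(self):
        maps = [make_map(v) for v in (1.0, 2.0, 3.0)]
        t = second_level_tmap(maps)
        assert np.allclose(t, 2 * np.sqrt(3))

    def test_identical_nonzero_gives_infinite(self):
        t = second_level_tmap([make_map(2.0), make_map(2.0)])
        assert np.all(np.isposinf(t))

    def test_null_maps_nominal_rate(self):
        rng = np.random.default_rng(5)
        n = 12
        maps = [make_map(rng.normal(size=SHAPE)) for _ in range(n)]
        # few voxels here; aggregate over many replicates
        hits, total = 0, 0
        for _ in range(200):
            maps = [make_map(rng.normal(size=SHAPE)) for _ in range(n)]
            t = second_level_tmap(maps)
            tcrit = stats.t.ppf(0.975, n - 1)
            hits += np.sum(np.abs(t) > tcrit)
            total += t.size
        assert hits / total == pytest.approx(0.05, abs=0.01)

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            second_level_tmap([make_map(1.0)])


class TestGmSummary:
    def test_uniform_maps_any_threshold(self):
        s = uniform_set()
        for thr in (-np.inf, 0.0, 4.9):
            df = gm_summary(s, thr)
            assert np.allclose(df["asl"], 5.0)
            assert np.allclose(df["ge"], 0.2)

    def test_threshold_above_max_z_flags_all(self):
        df = gm_summary(uniform_set(), 100.0)
        assert df.isna().all().all()

    def test_same_voxel_set_for_all_weightings(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=SHAPE)
        maps = [{
            "asl": CVRMap(beta=np.ones(SHAPE), z=z, lag=np.zeros(SHAPE), weighting="asl"),
            "ge": make_map(rng.normal(size=SHAPE), weighting="ge"),
            "se": make_map(rng.normal(size=SHAPE), weighting="se"),
        }]
        s = SubjectCVRSet(maps=maps, gm_mask=np.ones(SHAPE, bool))
        sel = z > 0.5
        df = gm_summary(s, 0.5)
        assert df.loc[0, "ge"] == pytest.approx(maps[0]["ge"].beta[sel].mean())


class TestThresholdCurves:
    def test_single_neginf_threshold_reduces_to_unthresholded(self):
        s = uniform_set()
        curve = threshold_curves(s, np.array([-np.inf]))
        base = gm_summary(s, -np.inf)
        assert curve.group_mean.iloc[0]["asl"] == pytest.approx(base["asl"].mean())

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            threshold_curves(uniform_set(), np.array([2.0, 1.0]))

    def test_nested_voxel_sets(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=SHAPE)
        counts = [(z > thr).sum() for thr in (-1, 0, 1, 2)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_asl_selection_bias_nondecreasing_on_ensemble(self, protocol):
        """Mean recovered ASL CVR rises with the ASL z threshold (selection
        bias on a noisy cohort, averaged over subjects)."""
        subjects, cohort = gen_cohort(8, protocol, GroundTruth(), seed=5)
        maps = [process_synthetic_subject(s, mask=cohort.gm_mask)[0] for s in subjects]
        s = SubjectCVRSet(maps=maps, gm_mask=cohort.gm_mask)
        grid = np.array([-np.inf, 0.0, 4.0, 8.0])
        curve = threshold_curves(s, grid)
        means = curve.group_mean["asl"].to_numpy()
        assert means[-1] > means[0]
        assert np.all(np.diff(means) > -0.05)


class TestRoiFisher:
    def _set_from_cohort(self, protocol, truth, seed, n=8):
        subjects, cohort = gen_cohort(n, protocol, truth, seed=seed)
        maps = [process_synthetic_subject(s, mask=cohort.gm_mask)[0] for s in subjects]
        return SubjectCVRSet(
            maps=maps, gm_mask=cohort.gm_mask, roi_labels=cohort.roi_labels,
            venous_density=cohort.venous_density,
        ), cohort

    def test_null_cohort_few_discoveries(self):
        """Independent noise in all ROIs: expected FDR-significant count ~ 0."""
        rng = np.random.default_rng(9)
        labels = np.zeros(SHAPE, int)
        labels.ravel()[: 30] = np.repeat(np.arange(1, 11), 3)
        maps = [{
            "asl": make_map(rng.normal(size=SHAPE)),
            "ge": make_map(rng.normal(size=SHAPE), weighting="ge"),
            "se": make_map(rng.normal(size=SHAPE), weighting="se"),
        } for _ in range(10)]
        s = SubjectCVRSet(
            maps=maps, gm_mask=np.ones(SHAPE, bool), roi_labels=labels,
            venous_density={i: float(i) for i in range(1, 11)},
        )
        out = roi_fisher_maps(s)
        assert out["sig_diff"].sum() <= 1

    def test_venous_contamination_signature(self, protocol):
        """GE-specific macrovascular variance: the SE-vs-ASL minus GE-vs-ASL
        Fisher-z difference is larger in high-venous-density ROIs."""
        truth = GroundTruth(macro_subject_sd=1.2, tau_ge=0.6)
        diffs_hi, diffs_lo = [], []
        for seed in (1, 2, 3):
            s, cohort = self._set_from_cohort(protocol, truth, seed, n=10)
            out = roi_fisher_maps(s).dropna(subset=["fisher_diff"])
            diffs_hi.append(out.loc[out["high_venous"], "fisher_diff"].mean())
            diffs_lo.append(out.loc[~out["high_venous"], "fisher_diff"].mean())
        assert np.mean(diffs_hi) > np.mean(diffs_lo)
        assert np.mean(diffs_hi) > 0

    def test_steiger_zero_for_equal_correlations(self):
        z, p = steiger_test(0.5, 0.5, 0.3, 20)
        assert z == 0.0 and p == pytest.approx(1.0)


class TestSpatialCorrelationVsN:
    def test_identical_maps_give_r_one(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=SHAPE)
        maps = [{
            "asl": make_map(base), "ge": make_map(base, weighting="ge"),
            "se": make_map(base, weighting="se"),
        } for _ in range(4)]
        s = SubjectCVRSet(maps=maps, gm_mask=np.ones(SHAPE, bool))
        out = spatial_correlation_vs_n(s, n_iters=10, seed=0)
        assert np.allclose(out["r_mean"], 1.0)

    def test_bit_reproducible_under_seed(self):
        s = uniform_set()
        for subj in s.maps:  # add variation so r is defined
            rng = np.random.default_rng(id(subj) % 1000)
        rng = np.random.default_rng(3)
        maps = [{
            w: make_map(rng.normal(size=SHAPE), weighting=w)
            for w in ("asl", "ge", "se")
        } for _ in range(5)]
        s = SubjectCVRSet(maps=maps, gm_mask=np.ones(SHAPE, bool))
        a = spatial_correlation_vs_n(s, n_iters=20, seed=7)
        b = spatial_correlation_vs_n(s, n_iters=20, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_mean_r_increases_with_k(self, default_cohort):
        """Shared spatial pattern + independent noise: averaging more
        subjects raises the spatial correlation (ensemble assertion)."""
        subjects, cohort = default_cohort
        maps = [process_synthetic_subject(s, mask=cohort.gm_mask)[0] for s in subjects]
        s = SubjectCVRSet(maps=maps, gm_mask=cohort.gm_mask)
        out = spatial_correlation_vs_n(s, n_iters=40, seed=1)
        for pair in ("ge_vs_asl", "se_vs_asl"):
            r = out[out["pair"] == pair].sort_values("k")["r_mean"].to_numpy()
            assert r[-1] > r[0]

    def test_noise_free_limit_equals_truth_correlation(self, protocol, noiseless_subject):
        """k = N with zero noise: r equals the correlation of the true
        coupling fields."""
        subject, cohort = noiseless_subject
        maps, _ = process_synthetic_subject(subject, mask=cohort.gm_mask)
        s = SubjectCVRSet(maps=[maps], gm_mask=cohort.gm_mask)
        out = spatial_correlation_vs_n(s, n_iters=1, seed=0)
        gm = cohort.gm_mask
        t = subject.truth
        expected = np.corrcoef(t.cvr_ge_true[gm], t.cvr_asl_true[gm])[0, 1]
        got = out[out["pair"] == "ge_vs_asl"]["r_mean"].iloc[0]
        assert got == pytest.approx(expected, abs=0.02)
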