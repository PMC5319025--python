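import numpy as np
import pytest
from dataclasses import replace

from mircrosstalk.phenotypes import (
    bimodal_params,
    classify_phase,
    fold_repression,
    limiting_curve_g2_inf,
    reference_params,
    sweep_competitor,
    sweep_p0,
    unregulated_sweep,
)

GRID = np.geomspace(2, 500, 40)
FINE = np.geomspace(2, 500, 120)


@pytest.fixture(scope="module")
def ref_sweep():
    return sweep_p0(reference_params(), GRID, method="moments")


class TestSweepP0:
    def test_unregulated_sweep_is_identity_line(self):
        sw = sweep_p0(replace(reference_params(), g_1=0.0), GRID)
        np.testing.assert_allclose(sw.mean_p1, GRID, rtol=1e-9)
        np.testing.assert_allclose(sw.pearson_p1p2, 0.0, atol=1e-6)

    def test_correlation_peaks_at_threshold_and_vanishes_at_ends(self, ref_sweep):
        rho = ref_sweep.pearson_p1p2
        i_max = int(np.argmax(rho))
        assert 0 < i_max < len(GRID) - 1
        assert abs(i_max - ref_sweep.threshold().index) <= 2
        assert rho[0] < 0.05 and rho[-1] < 0.05
        assert rho[i_max] > 0.2

    def test_noise_profile_has_local_maximum_only_when_regulated(self, ref_sweep):
        def local_maxima(v):
            return [i for i in range(1, len(v) - 1)
                    if v[i] > v[i - 1] and v[i] > v[i + 1]]

        loc = local_maxima(ref_sweep.cv_p1)
        assert loc, "regulated noise profile must have an interior maximum"
        assert any(abs(i - ref_sweep.threshold().index) <= 2 for i in loc)
        un = sweep_p0(replace(reference_params(), g_1=0.0), GRID)
        assert not local_maxima(un.cv_p1)

    def test_noise_responds_to_interaction_strengths(self):
        # at fixed p0, stronger own-binding raises CV_p1, stronger
        # competitor binding lowers it
        base = reference_params().with_p0(90.0)
        from mircrosstalk.moments import stationary_covariance

        cv = stationary_covariance(base).cv_of("p1")
        cv_g1 = stationary_covariance(replace(base, g_1=base.g_1 * 3)).cv_of("p1")
        cv_g2 = stationary_covariance(replace(base, g_2=1.0)).cv_of("p1")
        assert cv_g1 > cv
        assert cv_g2 < cv

    def test_ssa_method_confirms_moments_at_three_points(self):
        pts = np.array([10.0, 91.0, 400.0])  # below / at / above threshold
        mom = sweep_p0(reference_params(), pts, method="moments")
        ssa = sweep_p0(reference_params(), pts, method="ssa",
                       n_cells=500, seed=31)
        # away from the threshold the Gaussian means are accurate ...
        assert ssa.mean_p1[0] == pytest.approx(mom.mean_p1[0], rel=0.3, abs=0.1)
        assert ssa.mean_p1[2] == pytest.approx(mom.mean_p1[2], rel=0.1)
        # ... at the threshold fluctuations raise the exact mean above the
        # mean-field value (the curve is convex in the miRNA pool), but the
        # two stay within a factor ~2
        assert mom.mean_p1[1] < ssa.mean_p1[1] < 2.5 * mom.mean_p1[1]

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep_p0(reference_params(), np.array([3.0, 2.0, 5.0]))
        with pytest.raises(ValueError):
            sweep_p0(reference_params(), GRID, method="exact")


class TestFoldRepression:
    def test_identical_sweeps_give_unity(self, ref_sweep):
        f = fold_repression(ref_sweep, ref_sweep)
        np.testing.assert_allclose(f.values, 1.0)

    def test_repression_only_and_decay_to_one(self, ref_sweep):
        un = unregulated_sweep(reference_params(), GRID)
        f = fold_repression(ref_sweep, un)
        assert np.all(f.values >= 1.0 - 1e-9)
        # repression saturates below threshold and decays above it
        thr = ref_sweep.threshold().index
        assert np.all(np.diff(f.values[thr:]) <= 1e-9)
        # the decay reaches F ~ 1 far above threshold
        tail = np.geomspace(2, 20000, 40)
        f_tail = fold_repression(sweep_p0(reference_params(), tail),
                                 unregulated_sweep(reference_params(), tail))
        assert f_tail.values[-1] == pytest.approx(1.0, abs=0.02)

    def test_stronger_competitor_lowers_max_repression(self):
        un = unregulated_sweep(reference_params(), GRID)
        f_lo = fold_repression(sweep_p0(reference_params(), GRID), un)
        more_g2 = replace(reference_params(), g_2=1.0)
        f_hi = fold_repression(
            sweep_p0(more_g2, GRID), unregulated_sweep(more_g2, GRID))
        assert np.nanmax(f_hi.values) < np.nanmax(f_lo.values)

    def test_grid_mismatch_rejected(self, ref_sweep):
        other = sweep_p0(reference_params(), np.geomspace(2, 400, 40))
        with pytest.raises(ValueError):
            fold_repression(ref_sweep, other)


class TestCompetitorInterplay:
    def test_threshold_decreases_with_competitor_transcription(self):
        # within the sponging regime (alpha*k_r2 < k_s) the threshold moves
        # to lower p0 as the competitor is transcribed more strongly
        base = replace(reference_params(), g_2=0.3)
        family = sweep_competitor(base, "k_r2", np.array([2.0, 4.0, 6.0, 10.0]),
                                  FINE)
        thresholds = [family[v].threshold().p0_star for v in [2.0, 4.0, 6.0, 10.0]]
        assert all(np.diff(thresholds) < 1e-9)

    def test_threshold_decreases_with_g2_increases_with_ks(self):
        t = {}
        for g2 in [0.0, 0.3, 1.0]:
            t[g2] = sweep_p0(replace(reference_params(), g_2=g2), FINE).threshold().p0_star
        assert t[0.0] > t[0.3] > t[1.0]
        s = {}
        for ks in [5.0, 10.0, 20.0]:
            s[ks] = sweep_p0(replace(reference_params(), k_s=ks), FINE).threshold().p0_star
        assert s[5.0] < s[10.0] < s[20.0]

    def test_g2_limit_excess_targets_recovers_unregulated_line(self):
        # alpha*k_r2 > k_s: the competitor sponges the whole miRNA pool
        p = replace(reference_params(), k_r2=30.0)  # 0.5*30 > k_s=10
        lim = limiting_curve_g2_inf(p, GRID)
        un = unregulated_sweep(reference_params(), GRID)
        np.testing.assert_allclose(lim.mean_p1, un.mean_p1, rtol=1e-9)
        big = sweep_p0(replace(p, g_2=100.0), GRID)
        assert np.max(np.abs(big.mean_p1 / un.mean_p1 - 1)) < 0.1

    def test_g2_limit_excess_mirna_keeps_threshold(self):
        # alpha*k_r2 < k_s: even infinite competitor binding leaves miRNA
        # over, so the limiting curve is ultrasensitive and distinct
        p = replace(reference_params(), k_r2=6.0)  # 0.5*6 < k_s=10
        lim = limiting_curve_g2_inf(p, GRID)
        est = lim.threshold()
        assert not est.absent and est.max_slope > 1.5
        un = unregulated_sweep(reference_params(), GRID)
        assert np.max(np.abs(lim.mean_p1 / un.mean_p1 - 1)) > 0.5
        big = sweep_p0(replace(p, g_2=100.0), GRID)
        assert np.max(np.abs(big.mean_p1 / lim.mean_p1 - 1)) < 0.1


class TestClassifyPhase:
    def test_unregulated_point_low_crosstalk_unimodal(self):
        pt = classify_phase(replace(reference_params(), g_1=0.0), GRID,
                            seed=41, n_cells_bimodality=600)
        assert pt.crosstalk == "low"
        assert not pt.bimodal

    def test_reference_point_high_crosstalk(self):
        pt = classify_phase(reference_params(), GRID, seed=42,
                            n_cells_bimodality=600)
        assert pt.crosstalk == "high"
        assert pt.max_pearson > 0.3

    def test_strong_repression_corner_is_bimodal_low_crosstalk(self):
        pt = classify_phase(bimodal_params(), np.geomspace(5, 2000, 40),
                            seed=43)
        assert pt.bimodal
        assert pt.crosstalk == "low"
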