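import numpy as np
import pandas as pd
import pytest

from mircrosstalk.analysis import (
    background_correct,
    bin_and_summarize,
    empirical_fold_repression,
    gate_positive,
    null_self_ratios,
    pearson_ratio,
    ratio_pvalue,
)
from mircrosstalk.cytometry import CHANNELS, CellTable


def toy_table(ctrl_mean=100.0, ctrl_sd=10.0, values=(150.0,), n_ctrl=400,
              replicate=0, rng=None):
    rng = rng or np.random.default_rng(0)
    rows = []
    for v in values:
        rows.append({"replicate": replicate, "population": "transfected",
                     **{c: v for c in CHANNELS}})
    ctrl = rng.normal(ctrl_mean, ctrl_sd, size=(n_ctrl, len(CHANNELS)))
    for r in ctrl:
        rows.append({"replicate": replicate, "population": "control",
                     **dict(zip(CHANNELS, r))})
    return CellTable(cells=pd.DataFrame(rows))


class TestBackgroundCorrect:
    def test_subtracts_mean_plus_two_sd(self):
        # deterministic control: mean 100, sd 10 -> cutoff 120; 150 -> 30
        ctrl_vals = np.array([90.0, 110.0])  # mean 100, sd (ddof=1) ~14.14
        rows = [{"replicate": 0, "population": "transfected",
                 **{c: 150.0 for c in CHANNELS}}]
        for v in ctrl_vals:
            rows.append({"replicate": 0, "population": "control",
                         **{c: v for c in CHANNELS}})
        tab = CellTable(cells=pd.DataFrame(rows))
        out = background_correct(tab)
        cutoff = 100.0 + 2 * np.std(ctrl_vals, ddof=1)
        assert out["eYFP"].iloc[0] == pytest.approx(150.0 - cutoff)

    def test_below_cutoff_goes_negative_and_is_retained(self):
        tab = toy_table(values=(50.0,))
        out = background_correct(tab)
        assert out["eYFP"].iloc[0] < 0
        assert len(out) == 1

    def test_per_replicate_cutoffs_differ(self):
        rng = np.random.default_rng(1)
        a = toy_table(ctrl_mean=100, replicate=0, rng=rng).cells
        b = toy_table(ctrl_mean=200, replicate=1, rng=rng).cells
        tab = CellTable(cells=pd.concat([a, b], ignore_index=True))
        out = background_correct(tab)
        cuts = out.attrs["cutoffs"]
        assert cuts[(1, "eYFP")] - cuts[(0, "eYFP")] == pytest.approx(100.0, abs=5.0)


class TestGatePositive:
    def test_all_negative_table_errors(self):
        tab = toy_table(values=(50.0, 60.0))
        corrected = background_correct(tab)
        with pytest.raises(ValueError, match="gating removed all cells"):
            gate_positive(corrected)

    def test_mixed_table_counts(self):
        tab = toy_table(values=(150.0, 50.0, 200.0))
        out = gate_positive(background_correct(tab))
        assert len(out) == 2

    def test_eyfp_only_rule_is_superset(self, binned_pair):
        reg, _ = binned_pair
        # reuse the gated cells' source: both-rule cells all pass eyfp-only
        both = set(map(tuple, reg.cells[["eYFP", "mKOrange"]].round(6).to_numpy()))
        assert all(e > 0 for e, _ in both)


class TestBinAndSummarize:
    def test_bin_bookkeeping_conserves_cells(self, binned_pair):
        reg, _ = binned_pair
        assert reg.per_replicate["n"].sum() == len(reg.cells)
        # every retained cell sits in exactly one bin
        assert reg.cells["bin"].between(0, reg.n_bins - 1).all()

    def test_equal_width_bins(self, binned_pair):
        reg, _ = binned_pair
        widths = np.diff(reg.edges)
        np.testing.assert_allclose(widths, widths[0])

    def test_replicate_error_much_smaller_than_dispersion(self, binned_pair):
        # the replicate SD of a bin mean is ~ sqrt(N_cells_in_bin) below the
        # within-bin SD
        reg, _ = binned_pair
        ok = reg.aggregated[~reg.aggregated["masked"]]
        row = ok.iloc[len(ok) // 2]
        pr = reg.per_replicate
        sub = pr[pr["bin"] == row["bin"]]
        within_sd = (sub["cv_mCherry"] * sub["mean_mCherry"]).mean()
        assert row["mean_mCherry_err"] < within_sd / np.sqrt(sub["n"].min()) * 6
        assert row["mean_mCherry_err"] < 0.2 * within_sd

    def test_too_few_bins_rejected(self, binned_pair):
        reg, _ = binned_pair
        with pytest.raises(ValueError):
            bin_and_summarize(reg.cells.drop(columns="bin"), n_bins=2)

    def test_degenerate_constant_bin_has_zero_cv_and_undefined_pearson(self):
        rng = np.random.default_rng(3)
        rows = []
        for rep in range(2):
            for v in rng.uniform(0, 30, 300):
                if 10 <= v < 20:
                    # identical cells throughout the middle bin
                    ch, ce = 7.0, 3.0
                else:
                    ch, ce = rng.uniform(1, 10), rng.uniform(1, 10)
                rows.append({"replicate": rep, "population": "transfected",
                             "eYFP": v, "mCherry": ch, "mCerulean": ce,
                             "mKOrange": 1.0})
        binned = bin_and_summarize(pd.DataFrame(rows), n_bins=3, min_cells=5,
                                   upper_quantile=1.0)
        mid = binned.aggregated.set_index("bin").loc[1]
        assert mid["cv_mCherry"] == 0.0
        assert np.isnan(mid["pearson"])


class TestEmpiricalFoldRepression:
    def test_identical_datasets_give_unity_and_zero_error(self, binned_pair):
        reg, _ = binned_pair
        fr = empirical_fold_repression(reg, reg)
        ok = fr[~fr["masked"]]
        np.testing.assert_allclose(ok["F"], 1.0, rtol=1e-9)
        np.testing.assert_allclose(ok["F_err"], 0.0, atol=1e-9)

    def test_jackknife_matches_hand_computation(self):
        # three replicates with known per-replicate bin means
        reg_means = {0: 10.0, 1: 12.0, 2: 20.0}
        un_means = {0: 30.0, 1: 30.0, 2: 30.0}

        def synth(means):
            rng = np.random.default_rng(5)
            rows = []
            for rep, m in means.items():
                for _ in range(200):
                    e = rng.uniform(0, 30)
                    rows.append({"replicate": rep, "population": "transfected",
                                 "eYFP": e, "mCherry": m, "mCerulean": 1.0,
                                 "mKOrange": 1.0})
            return pd.DataFrame(rows)

        breg = bin_and_summarize(synth(reg_means), n_bins=3, min_cells=10,
                                 upper_quantile=1.0)
        bun = bin_and_summarize(synth(un_means), edges=breg.edges, min_cells=10)
        fr = empirical_fold_repression(breg, bun)
        # hand jackknife: leave-one-out F values
        f_loo = []
        for drop in range(3):
            r = np.mean([v for k, v in reg_means.items() if k != drop])
            u = np.mean([v for k, v in un_means.items() if k != drop])
            f_loo.append(u / r)
        f_loo = np.array(f_loo)
        err = np.sqrt(2 / 3 * np.sum((f_loo - f_loo.mean()) ** 2))
        ok = fr[~fr["masked"]]
        assert ok["F_err"].iloc[0] == pytest.approx(err, rel=1e-6)
        assert ok["F"].iloc[0] == pytest.approx(30.0 / np.mean(list(reg_means.values())), rel=1e-6)

    def test_bin_mismatch_rejected(self, binned_pair):
        reg, ref = binned_pair
        other = bin_and_summarize(ref.cells.drop(columns="bin"),
                                  n_bins=reg.n_bins, upper_quantile=0.9)
        with pytest.raises(ValueError):
            empirical_fold_repression(reg, other)


class TestPearsonRatio:
    def test_self_ratio_is_unity(self, binned_pair):
        reg, _ = binned_pair
        thr = reg.threshold_bin()
        res = pearson_ratio(reg, reg, thr)
        for region, r in res.items():
            if len(r.replicate_ratios):
                assert r.ratio == pytest.approx(1.0, abs=1e-9)

    def test_reference_floor_flags_unstable(self, binned_pair):
        reg, ref = binned_pair
        thr = reg.threshold_bin()
        res = pearson_ratio(reg, ref, thr, reference_floor=0.9)
        assert all(r.unstable for r in res.values() if np.isfinite(r.ratio))

    def test_pvalue_normal_tail(self):
        from mircrosstalk.analysis import PearsonRatioResult

        null = np.array([0.9, 1.0, 1.1])
        mu, sd = null.mean(), null.std(ddof=1)
        mk = lambda v: PearsonRatioResult(
            region="around", ratio=v, replicate_error=0.1,
            replicate_ratios=np.array([v]), reference_pearson=0.5,
            unstable=False)
        assert ratio_pvalue(mk(mu), null).p_value == pytest.approx(0.5)
        assert ratio_pvalue(mk(mu + 3 * sd), null).p_value == pytest.approx(
            0.00135, abs=2e-4)
        two = ratio_pvalue(mk(mu + 3 * sd), null, sided="two-sided").p_value
        assert two == pytest.approx(0.0027, abs=4e-4)

    def test_pvalue_needs_replicates_and_spread(self):
        from mircrosstalk.analysis import PearsonRatioResult

        r = PearsonRatioResult(region="around", ratio=2.0, replicate_error=0.1,
                               replicate_ratios=np.array([2.0]),
                               reference_pearson=0.5, unstable=False)
        with pytest.raises(ValueError):
            ratio_pvalue(r, np.array([1.0, 1.0]))
        out = ratio_pvalue(r, np.array([1.0, 1.0, 1.0]))
        assert np.isnan(out.p_value)

    def test_null_self_ratios_center_on_one(self, binned_pair):
        _, ref = binned_pair
        thr = ref.threshold_bin(slope_tol=0.0)
        nulls = null_self_ratios(ref, thr)
        for region, vals in nulls.items():
            if len(vals) >= 2:
                assert vals.mean() == pytest.approx(1.0, abs=1e-9)


class TestPipelineDeterminism:
    def test_identical_input_identical_output(self, small_populations):
        reg_tab, _ = small_populations
        a = bin_and_summarize(gate_positive(background_correct(reg_tab)),
                              n_bins=10, min_cells=40)
        b = bin_and_summarize(gate_positive(background_correct(reg_tab)),
                              n_bins=10, min_cells=40)
        pd.testing.assert_frame_equal(a.aggregated, b.aggregated)
        np.testing.assert_array_equal(a.edges, b.edges)
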