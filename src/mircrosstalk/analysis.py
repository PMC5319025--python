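"""Single-cell cytometry statistics pipeline.

Stages, mirroring how the two-color/two-plasmid experiment is processed:

1. background correction — subtract, per replicate and channel, the mean plus
   two standard deviations of the untransfected control population;
2. positivity gating on the constitutive channels of both plasmids;
3. equal-width binning on corrected eYFP, then per-bin, per-replicate mean,
   CV and Pearson(mCherry, mCerulean); replicate aggregation reports the mean
   over replicates with the SD over replicates as error bar (a root-N_cells-
   in-bin smaller quantity than the within-bin dispersion);
4. fold-repression F (unregulated/regulated mean per bin) with leave-one-
   replicate-out jackknife errors;
5. the Pearson-ratio statistic: region-pooled (below/around/above threshold)
   correlation of the regulated pair divided by the same measure on the N=0
   reference, with a Gaussian-tail p-value against the N=0 self-ratio null.

The Pearson ratio discounts correlation that transfection co-uptake injects
into *any* pair of reporters, isolating the component induced by competition
for the shared miRNA pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cytometry import CHANNELS, CellTable

__all__ = [
    "BinnedStats",
    "PearsonRatioResult",
    "background_correct",
    "gate_positive",
    "bin_and_summarize",
    "empirical_fold_repression",
    "pearson_ratio",
    "null_self_ratios",
    "ratio_pvalue",
]

REGIONS = ("below", "around", "above")


@dataclass
class BinnedStats:
    """Equal-width eYFP binning of a gated population.

    ``per_replicate``: one row per (replicate, bin) with n, per-channel mean
    and CV, and Pearson(mCherry, mCerulean).  ``aggregated``: one row per bin,
    each statistic reported as mean over replicates with SD over replicates;
    bins where any replicate has fewer than ``min_cells`` cells are masked.
    ``cells`` retains the gated table with its bin assignment so that
    region-pooled statistics can be recomputed downstream.
    """

    edges: np.ndarray
    per_replicate: pd.DataFrame
    aggregated: pd.DataFrame
    cells: pd.DataFrame
    min_cells: int

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def populated_bins(self) -> np.ndarray:
        return self.aggregated.loc[~self.aggregated["masked"], "bin"].to_numpy()

    def threshold_bin(self, slope_tol: float = 1.05) -> int:
        """Bin of maximal log-log slope of mean mCherry vs bin-mean eYFP."""
        from .model import sensitivity_threshold

        ok = self.aggregated[~self.aggregated["masked"]]
        x = ok["mean_eYFP"].to_numpy()
        y = ok["mean_mCherry"].to_numpy()
        keep = (x > 0) & (y > 0)
        if keep.sum() < 3:
            raise ValueError("fewer than 3 usable bins for threshold location")
        est = sensitivity_threshold(x[keep], y[keep], slope_tol=slope_tol)
        return int(ok["bin"].to_numpy()[keep][est.index])


@dataclass(frozen=True)
class PearsonRatioResult:
    region: str
    ratio: float
    replicate_error: float
    replicate_ratios: np.ndarray
    reference_pearson: float
    unstable: bool
    p_value: float | None = None


def background_correct(table: CellTable) -> pd.DataFrame:
    """Subtract the per-replicate control cutoff (mean + 2 SD) per channel.

    Returns the transfected rows with corrected intensities; values below the
    cutoff go negative and are retained for the gating stage.  Cutoffs are
    recorded in ``df.attrs['cutoffs']``.
    """
    df = table.cells
    out = []
    cutoffs = {}
    for rep, grp in df.groupby("replicate"):
        ctrl = grp[grp["population"] == "control"]
        if len(ctrl) == 0:
            raise ValueError(f"replicate {rep} has no control population")
        trans = grp[grp["population"] == "transfected"].copy()
        for c in CHANNELS:
            cut = float(ctrl[c].mean() + 2.0 * ctrl[c].std(ddof=1))
            cutoffs[(int(rep), c)] = cut
            trans[c] = trans[c] - cut
        out.append(trans)
    res = pd.concat(out, ignore_index=True)
    res.attrs["cutoffs"] = cutoffs
    return res


def gate_positive(cells: pd.DataFrame, rule: str = "both") -> pd.DataFrame:
    """Retain cells positive on the constitutive channels after correction.

    ``both`` (default) requires corrected eYFP > 0 and mKOrange > 0, i.e.
    detectable expression from both plasmids; ``eyfp-only`` relaxes to the
    first plasmid.
    """
    if rule == "both":
        mask = (cells["eYFP"] > 0) & (cells["mKOrange"] > 0)
    elif rule == "eyfp-only":
        mask = cells["eYFP"] > 0
    else:
        raise ValueError(f"unknown gating rule {rule!r}")
    gated = cells[mask].reset_index(drop=True)
    if len(gated) == 0:
        raise ValueError(
            f"gating removed all cells ({len(cells)} in, 0 out, rule={rule!r})"
        )
    gated.attrs = dict(cells.attrs)
    return gated


def _auto_n_bins(n_cells: int, target_occupancy: int = 1000) -> int:
    return int(np.clip(n_cells // (2 * target_occupancy), 3, 40))


def bin_and_summarize(
    cells: pd.DataFrame,
    n_bins: int | None = None,
    bin_width: float | None = None,
    edges: np.ndarray | None = None,
    min_cells: int = 100,
    upper_quantile: float = 0.995,
) -> BinnedStats:
    """Equal-width eYFP binning with per-replicate and aggregated statistics.

    The binning domain is [0, ``upper_quantile`` of pooled gated eYFP] so a
    handful of extreme-load cells cannot stretch the bins; the bin count
    defaults to whatever keeps median occupancy around a thousand cells.
    Pass ``edges`` explicitly to reuse another dataset's binning (required
    for fold-repression and Pearson-ratio comparisons).  Bins whose occupancy
    falls below ``min_cells`` in any replicate are masked (their statistics
    would be replicate-noise dominated).
    """
    if len(cells) == 0:
        raise ValueError("empty cell table")
    if edges is not None:
        edges = np.asarray(edges, dtype=float)
        widths = np.diff(edges)
        if len(edges) < 4 or np.any(widths <= 0) or not np.allclose(widths, widths[0]):
            raise ValueError("edges must define >= 3 consecutive equal-width bins")
    else:
        hi = float(cells["eYFP"].quantile(upper_quantile))
        if bin_width is not None:
            edges = np.arange(0.0, hi + bin_width, bin_width)
        else:
            if n_bins is None:
                n_bins = _auto_n_bins(len(cells))
            edges = np.linspace(0.0, hi, n_bins + 1)
    if len(edges) < 4:
        raise ValueError("need at least 3 bins")

    work = cells.copy()
    work["bin"] = pd.cut(work["eYFP"], bins=edges, labels=False, right=False)
    work = work.dropna(subset=["bin"])
    work["bin"] = work["bin"].astype(int)

    rows = []
    for (rep, b), grp in work.groupby(["replicate", "bin"]):
        row = {"replicate": int(rep), "bin": int(b), "n": len(grp)}
        for c in CHANNELS:
            m = grp[c].mean()
            row[f"mean_{c}"] = m
            row[f"cv_{c}"] = grp[c].std(ddof=1) / m if len(grp) > 1 and m != 0 else np.nan
        if len(grp) > 1 and grp["mCherry"].std() > 0 and grp["mCerulean"].std() > 0:
            row["pearson"] = float(np.corrcoef(grp["mCherry"], grp["mCerulean"])[0, 1])
        else:
            row["pearson"] = np.nan
        rows.append(row)
    per_rep = pd.DataFrame(rows)
    if per_rep.empty:
        raise ValueError("no populated bins")

    reps = sorted(work["replicate"].unique())
    stats = [f"mean_{c}" for c in CHANNELS] + [f"cv_{c}" for c in CHANNELS] + ["pearson"]
    agg_rows = []
    for b in range(len(edges) - 1):
        sub = per_rep[per_rep["bin"] == b]
        row = {"bin": b, "bin_left": edges[b], "bin_right": edges[b + 1],
               "n_total": int(sub["n"].sum()) if len(sub) else 0}
        underfull = (len(sub) < len(reps)) or (sub["n"].min() < min_cells)
        row["masked"] = bool(underfull)
        row["few_replicates"] = bool(len(sub) < 2)
        for s in stats:
            vals = sub[s].to_numpy(dtype=float)
            row[s] = float(np.nanmean(vals)) if len(vals) else np.nan
            row[f"{s}_err"] = (
                float(np.nanstd(vals, ddof=1)) if len(vals) >= 2 else np.nan
            )
        agg_rows.append(row)
    aggregated = pd.DataFrame(agg_rows)
    if (~aggregated["masked"]).sum() < 3:
        raise ValueError("fewer than 3 populated bins survive masking")

    return BinnedStats(edges=edges, per_replicate=per_rep,
                       aggregated=aggregated, cells=work, min_cells=min_cells)


def empirical_fold_repression(binned_reg: BinnedStats,
                              binned_unreg: BinnedStats) -> pd.DataFrame:
    """Per-bin F = unregulated mean mCherry / regulated mean mCherry, with
    leave-one-replicate-out jackknife errors.

    Requires identical bin edges; bins masked in either dataset are masked in
    the output.
    """
    if not np.allclose(binned_reg.edges, binned_unreg.edges):
        raise ValueError("bin edges differ between the two datasets")
    reps_r = sorted(binned_reg.per_replicate["replicate"].unique())
    reps_u = sorted(binned_unreg.per_replicate["replicate"].unique())
    if len(reps_r) != len(reps_u):
        raise ValueError("replicate counts differ between the two datasets")
    n_rep = len(reps_r)

    def mean_curve(binned: BinnedStats, drop=None) -> np.ndarray:
        pr = binned.per_replicate
        if drop is not None:
            pr = pr[pr["replicate"] != drop]
        curve = np.full(binned.n_bins, np.nan)
        for b, grp in pr.groupby("bin"):
            curve[b] = grp["mean_mCherry"].mean()
        return curve

    reg = mean_curve(binned_reg)
    unreg = mean_curve(binned_unreg)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = unreg / reg

    jack = np.full((n_rep, binned_reg.n_bins), np.nan)
    for i, (rr, ru) in enumerate(zip(reps_r, reps_u)):
        with np.errstate(divide="ignore", invalid="ignore"):
            jack[i] = mean_curve(binned_unreg, drop=ru) / mean_curve(binned_reg, drop=rr)
    jack_mean = np.nanmean(jack, axis=0)
    err = np.sqrt((n_rep - 1) / n_rep * np.nansum((jack - jack_mean) ** 2, axis=0))

    # a fully repressed bin has mean corrected mCherry <= 0 (pure background
    # after the mean+2SD subtraction): the ratio is undefined there
    nonpositive = ~((reg > 0) & (unreg > 0))
    masked = ((binned_reg.aggregated["masked"] | binned_unreg.aggregated["masked"]).to_numpy()
              | nonpositive)
    out = pd.DataFrame({
        "bin": np.arange(binned_reg.n_bins),
        "F": np.where(masked, np.nan, f),
        "F_err": np.where(masked, np.nan, err),
        "masked": masked,
    })
    return out


def _region_bins(binned: BinnedStats, threshold_bin: int, halfwidth: int = 1) -> dict[str, np.ndarray]:
    pop = binned.populated_bins()
    around = pop[(pop >= threshold_bin - halfwidth) & (pop <= threshold_bin + halfwidth)]
    below = pop[pop < threshold_bin - halfwidth]
    above = pop[pop > threshold_bin + halfwidth]
    return {"below": below, "around": around, "above": above}


def _region_pearsons(binned: BinnedStats, bins: np.ndarray) -> dict[int, float]:
    """Pearson(mCherry, mCerulean) pooling the region's cells, per replicate."""
    out = {}
    sub = binned.cells[binned.cells["bin"].isin(bins)]
    for rep, grp in sub.groupby("replicate"):
        if len(grp) > 2 and grp["mCherry"].std() > 0 and grp["mCerulean"].std() > 0:
            out[int(rep)] = float(np.corrcoef(grp["mCherry"], grp["mCerulean"])[0, 1])
    return out


def pearson_ratio(
    binned_reg: BinnedStats,
    binned_unreg: BinnedStats,
    threshold_bin: int,
    halfwidth: int = 1,
    reference_floor: float = 0.05,
) -> dict[str, PearsonRatioResult]:
    """Region-wise ratio of regulated to N=0 Pearson(mCherry, mCerulean).

    Regions relative to the supplied threshold bin: ``around`` is the
    threshold bin +/- ``halfwidth``; ``below``/``above`` are everything
    outside it.  The ratio is computed per replicate (region-pooled cells)
    and averaged, the error bar being the SD over replicates.  When the
    reference correlation falls below ``reference_floor`` the ratio is
    flagged unstable.
    """
    if not np.allclose(binned_reg.edges, binned_unreg.edges):
        raise ValueError("bin edges differ between the two datasets")
    regions_reg = _region_bins(binned_reg, threshold_bin, halfwidth)
    regions_ref = _region_bins(binned_unreg, threshold_bin, halfwidth)

    results = {}
    for region in REGIONS:
        rho_reg = _region_pearsons(binned_reg, regions_reg[region])
        rho_ref = _region_pearsons(binned_unreg, regions_ref[region])
        common = sorted(set(rho_reg) & set(rho_ref))
        if not common:
            results[region] = PearsonRatioResult(
                region=region, ratio=np.nan, replicate_error=np.nan,
                replicate_ratios=np.array([]), reference_pearson=np.nan,
                unstable=True)
            continue
        ref_mean = float(np.mean([rho_ref[r] for r in common]))
        ratios = np.array([rho_reg[r] / rho_ref[r] for r in common])
        results[region] = PearsonRatioResult(
            region=region,
            ratio=float(ratios.mean()),
            replicate_error=float(ratios.std(ddof=1)) if len(ratios) >= 2 else np.nan,
            replicate_ratios=ratios,
            reference_pearson=ref_mean,
            unstable=bool(abs(ref_mean) < reference_floor),
        )
    return results


def null_self_ratios(binned_unreg: BinnedStats, threshold_bin: int,
                     halfwidth: int = 1) -> dict[str, np.ndarray]:
    """Replicate-level self-ratios of the N=0 reference.

    Each replicate's region-pooled Pearson divided by the replicate-mean
    value: a sample from the ratio's null distribution (mean ~ 1), whose
    spread is the biological-replicate error the p-value is measured against.
    """
    out = {}
    regions = _region_bins(binned_unreg, threshold_bin, halfwidth)
    for region in REGIONS:
        rho = _region_pearsons(binned_unreg, regions[region])
        vals = np.array(list(rho.values()))
        out[region] = vals / vals.mean() if len(vals) else np.array([])
    return out


def ratio_pvalue(
    ratio: PearsonRatioResult,
    null_ratios: np.ndarray,
    sided: str = "greater",
) -> PearsonRatioResult:
    """Gaussian tail probability of the observed ratio under the N=0 null.

    The null is Normal(mean of the N=0 replicate ratios, SD of the same);
    one-sided (correlation enrichment) by default.  Fewer than 3 null
    replicates or zero spread leaves the p-value undefined (NaN).
    """
    null_ratios = np.asarray(null_ratios, dtype=float)
    if len(null_ratios) < 3:
        raise ValueError("need >= 3 replicate null ratios")
    mu0 = float(null_ratios.mean())
    sd0 = float(null_ratios.std(ddof=1))
    if sd0 == 0 or not np.isfinite(ratio.ratio):
        p = np.nan
    else:
        z = (ratio.ratio - mu0) / sd0
        if sided == "greater":
            p = float(norm.sf(z))
        elif sided == "two-sided":
            p = float(2.0 * norm.sf(abs(z)))
        else:
            raise ValueError(f"unknown sidedness {sided!r}")
    return PearsonRatioResult(
        region=ratio.region, ratio=ratio.ratio,
        replicate_error=ratio.replicate_error,
        replicate_ratios=ratio.replicate_ratios,
        reference_pearson=ratio.reference_pearson,
        unstable=ratio.unstable, p_value=p,
    )
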