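"""Parameter sweeps and derived readouts of the titration model.

The central experiment-facing curves are statistics of the regulated reporter
(p1) as a function of its constitutive expression p0 — the level p1 would
reach with no miRNA (g_1 -> 0).  p0 is swept via the target transcription
rate k_r1 with translation and degradation fixed, mirroring the experimental
situation where per-cell plasmid load varies while protein chemistry does not.

Readouts: the titration threshold (point of maximal log-log slope), the noise
profile CV_p1, the target-target correlation rho(p1, p2), fold-repression
F = unregulated/regulated mean, the competitor regimes in (k_r2, g_2), and a
phase classification (crosstalk strength, bimodality) over the plane of
interaction-strength ratio g_2/g_1 versus mean target molecule number.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import (
    ModelParams,
    ThresholdEstimate,
    constitutive_levels,
    meanfield_steady_state,
    sensitivity_threshold,
    validate_params,
)
from .moments import stationary_covariance

__all__ = [
    "SweepResult",
    "FoldRepressionCurve",
    "PhasePoint",
    "reference_params",
    "bimodal_params",
    "sweep_p0",
    "fold_repression",
    "sweep_competitor",
    "limiting_curve_g2_inf",
    "classify_phase",
    "phase_diagram",
]

#: Crosstalk buckets on max rho(p1,p2); boundaries are package conventions,
#: configurable through classify_phase.
CROSSTALK_BUCKETS = (0.1, 0.3)


def reference_params() -> ModelParams:
    """Canonical strongly titrating parameter set used across examples/tests.

    Time unit = target mRNA lifetime (g_r1 = 1).  The miRNA is longer-lived
    (g_s = 0.1) so its pool is set by titration rather than decay; g_1 >> g_2
    gives reporter 1 a sharp threshold; alpha = 0.5 splits interactions evenly
    between co-degradation and recycling.  Protein numbers sit in the
    10-1000 molecules/cell range where crosstalk is physiologically relevant.
    """
    return ModelParams(
        k_s=10.0, k_r1=10.0, k_r2=6.0,
        g_s=0.1, g_r1=1.0, g_r2=1.0,
        g_1=2.0, g_2=0.05, alpha=0.5,
        k_p1=5.0, k_p2=5.0, g_p1=1.0, g_p2=1.0,
    )


def bimodal_params() -> ModelParams:
    """Strong-repression regime where the population splits into two
    phenotypes near the threshold.

    Relative to :func:`reference_params`: much stronger binding (g_1 = 50),
    no competitor sites (g_2 = 0), and a long-lived miRNA (g_s = 0.01) whose
    free pool therefore fluctuates slowly and, near the threshold, gates the
    target between an off state and an expressing state; the translational
    burst (k_p1 = 20) amplifies the gating into two phenotypes that separate
    on the log intensity scale.  The two-phenotype window sits at and just
    above the threshold estimate and is a few percent of p0 wide.
    """
    return ModelParams(
        k_s=15.0, k_r1=10.0, k_r2=6.0,
        g_s=0.01, g_r1=1.0, g_r2=1.0,
        g_1=50.0, g_2=0.0, alpha=0.5,
        k_p1=20.0, k_p2=5.0, g_p1=1.0, g_p2=1.0,
    )


@dataclass(frozen=True)
class SweepResult:
    """Statistics of the regulated pair along a sweep variable."""

    variable: str
    grid: np.ndarray
    table: pd.DataFrame     # columns: variable, mean_p1, mean_p2, cv_p1, pearson_p1p2, ok
    method: str
    params_base: ModelParams

    @property
    def mean_p1(self) -> np.ndarray:
        return self.table["mean_p1"].to_numpy()

    @property
    def cv_p1(self) -> np.ndarray:
        return self.table["cv_p1"].to_numpy()

    @property
    def pearson_p1p2(self) -> np.ndarray:
        return self.table["pearson_p1p2"].to_numpy()

    def threshold(self, slope_tol: float = 1.05) -> ThresholdEstimate:
        return sensitivity_threshold(self.grid, self.mean_p1, slope_tol=slope_tol)

    def to_csv(self, path) -> None:
        tidy = self.table.melt(id_vars=[self.variable], var_name="statistic",
                               value_name="value")
        tidy.to_csv(path, index=False)


@dataclass(frozen=True)
class FoldRepressionCurve:
    """Per-grid-point ratio of unregulated to regulated mean p1."""

    grid: np.ndarray
    values: np.ndarray

    def argmax_index(self) -> int:
        return int(np.nanargmax(self.values))


@dataclass(frozen=True)
class PhasePoint:
    g2_over_g1: float
    mean_target_molecules: float
    max_pearson: float
    crosstalk: str
    bimodal: bool
    threshold_p0: float


def _point_stats_moments(params: ModelParams) -> dict[str, float]:
    mom = stationary_covariance(params)
    return {
        "mean_p1": mom["p1"], "mean_p2": mom["p2"],
        "cv_p1": mom.cv_of("p1"), "pearson_p1p2": mom.rho("p1", "p2"),
    }


def _point_stats_ssa(params: ModelParams, n_cells: int, seed: int) -> dict[str, float]:
    from .ssa import sample_stationary

    smp = sample_stationary(params, n_cells=n_cells, seed=seed,
                            check_stationarity=False)
    p1 = smp.states[:, 3].astype(float)
    p2 = smp.states[:, 4].astype(float)
    sd1, sd2 = p1.std(ddof=1), p2.std(ddof=1)
    rho = (np.cov(p1, p2, ddof=1)[0, 1] / (sd1 * sd2)) if sd1 > 0 and sd2 > 0 else 0.0
    return {
        "mean_p1": p1.mean(), "mean_p2": p2.mean(),
        "cv_p1": sd1 / p1.mean() if p1.mean() > 0 else np.inf,
        "pearson_p1p2": rho,
    }


def sweep_p0(
    params_base: ModelParams,
    p0_grid: np.ndarray,
    method: str = "moments",
    n_cells: int = 1000,
    seed: int = 0,
) -> SweepResult:
    """Evaluate mean/CV/correlation of the regulated pair along a p0 grid.

    Each p0 sets k_r1 = p0*g_r1*g_p1/k_p1; statistics come either from the
    Gaussian approximation (``moments``) or from stationary SSA samples of
    ``n_cells`` virtual cells per grid point (``ssa``).  Per-point solver
    failures are flagged in the ``ok`` column rather than aborting the sweep.
    """
    if method not in ("moments", "ssa"):
        raise ValueError(f"method must be 'moments' or 'ssa', got {method!r}")
    grid = np.asarray(p0_grid, dtype=float)
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("p0_grid must be positive and strictly increasing")
    validate_params(params_base)

    rows = []
    for i, p0 in enumerate(grid):
        params = params_base.with_p0(p0)
        try:
            if method == "moments":
                st = _point_stats_moments(params)
            else:
                st = _point_stats_ssa(params, n_cells, seed + 7919 * i)
            rows.append({"p0": p0, **st, "ok": True})
        except ArithmeticError:
            rows.append({"p0": p0, "mean_p1": np.nan, "mean_p2": np.nan,
                         "cv_p1": np.nan, "pearson_p1p2": np.nan, "ok": False})
    return SweepResult(variable="p0", grid=grid, table=pd.DataFrame(rows),
                       method=method, params_base=params_base)


def fold_repression(sweep_reg: SweepResult,
                    sweep_unreg: SweepResult) -> FoldRepressionCurve:
    """Pointwise fold-repression F = unregulated mean p1 / regulated mean p1.

    F >= 1 wherever the miRNA only represses; F -> 1 far above threshold.
    """
    if not np.array_equal(sweep_reg.grid, sweep_unreg.grid):
        raise ValueError("sweeps must share an identical grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        f = sweep_unreg.mean_p1 / sweep_reg.mean_p1
    return FoldRepressionCurve(grid=sweep_reg.grid, values=f)


def unregulated_sweep(params_base: ModelParams, p0_grid: np.ndarray,
                      **kwargs) -> SweepResult:
    """Same sweep with g_1 = 0 (no MREs on reporter 1)."""
    return sweep_p0(replace(params_base, g_1=0.0), p0_grid, **kwargs)


def limiting_curve_g2_inf(params_base: ModelParams,
                          p0_grid: np.ndarray) -> SweepResult:
    """Mean-field p1 curve in the g_2 -> infinity limit.

    With infinitely strong competitor binding the free r2 pool vanishes and
    every r2 transcript immediately consumes a miRNA with probability alpha
    (flux alpha*k_r2), as long as miRNA remains.  The limit is therefore the
    single-target model with effective miRNA supply k_s' = max(k_s -
    alpha*k_r2, 0): excess miRNA (alpha*k_r2 < k_s) keeps a genuine threshold,
    excess targets (alpha*k_r2 >= k_s) removes regulation entirely.
    """
    p = validate_params(params_base)
    k_s_eff = max(p.k_s - p.alpha * p.k_r2, 0.0)
    limit_params = replace(p, k_s=k_s_eff, k_r2=0.0, g_2=0.0)
    return sweep_p0(limit_params, p0_grid, method="moments")


def sweep_competitor(
    params_base: ModelParams,
    variable: str,
    grid: np.ndarray,
    p0_grid: np.ndarray,
    method: str = "moments",
    **kwargs,
) -> dict[float, SweepResult]:
    """Family of p1-vs-p0 curves while stepping the competitor's k_r2 or g_2.

    Returns a mapping {competitor value -> SweepResult}; the g_2 -> infinity
    member is available separately via :func:`limiting_curve_g2_inf`.
    """
    if variable not in ("k_r2", "g_2"):
        raise ValueError("variable must be 'k_r2' or 'g_2'")
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("competitor grid must be non-negative")
    family = {}
    for v in grid:
        params = replace(params_base, **{variable: float(v)})
        family[float(v)] = sweep_p0(params, p0_grid, method=method, **kwargs)
    return family


def _bucket(rho_max: float, bounds=CROSSTALK_BUCKETS) -> str:
    if rho_max < bounds[0]:
        return "low"
    if rho_max < bounds[1]:
        return "medium"
    return "high"


def classify_phase(
    params: ModelParams,
    p0_grid: np.ndarray,
    seed: int = 0,
    n_cells_bimodality: int = 3000,
    level: float = 0.01,
    bucket_bounds=CROSSTALK_BUCKETS,
) -> PhasePoint:
    """Phase-diagram label for one operating condition.

    Crosstalk is the maximum of rho(p1, p2) along the p0 sweep (Gaussian
    approximation), bucketed low/medium/high.  Bimodality is probed with SSA
    samples of p1 at the threshold operating point and just above it (+5%,
    +10%) — the two-phenotype window is a few percent of p0 wide and a
    grid-snapped threshold estimate can sit just off it; the dip level is
    Bonferroni-split across the three probes.  An unregulated reporter with
    no threshold is probed at the sweep midpoint only.
    """
    from .bimodality import bimodality_test
    from .ssa import sample_stationary

    sweep = sweep_p0(params, p0_grid, method="moments")
    rho_max = float(np.nanmax(sweep.pearson_p1p2))
    thr = sweep.threshold()
    if thr.absent:
        probes = [float(np.sqrt(p0_grid[0] * p0_grid[-1]))]
    else:
        probes = [thr.p0_star, thr.p0_star * 1.05, thr.p0_star * 1.1]
    p0_op = probes[0]

    report = None
    for j, p0 in enumerate(probes):
        sample = sample_stationary(params.with_p0(p0),
                                   n_cells=n_cells_bimodality, seed=seed + j,
                                   check_stationarity=False)
        rep = bimodality_test(sample.states[:, 3].astype(float),
                              level=level / len(probes), n_boot=1000,
                              seed=seed + 17 * j + 1,
                              min_n=min(500, n_cells_bimodality))
        if report is None or rep.p_value < report.p_value:
            report = rep

    levels = constitutive_levels(params.with_p0(p0_op))
    mean_targets = levels.r0_1 + levels.r0_2
    return PhasePoint(
        g2_over_g1=(params.g_2 / params.g_1) if params.g_1 > 0 else np.inf,
        mean_target_molecules=float(mean_targets),
        max_pearson=rho_max,
        crosstalk=_bucket(rho_max, bucket_bounds),
        bimodal=bool(report.verdict),
        threshold_p0=p0_op,
    )


def phase_diagram(
    params_base: ModelParams,
    g2_over_g1_grid: np.ndarray,
    p0_grid: np.ndarray,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Tabulate classify_phase over a grid of interaction-strength ratios."""
    rows = []
    for i, ratio in enumerate(np.asarray(g2_over_g1_grid, dtype=float)):
        params = replace(params_base, g_2=ratio * params_base.g_1)
        pt = classify_phase(params, p0_grid, seed=seed + 104729 * i, **kwargs)
        rows.append({
            "g2_over_g1": pt.g2_over_g1,
            "mean_target_molecules": pt.mean_target_molecules,
            "max_pearson": pt.max_pearson,
            "crosstalk": pt.crosstalk,
            "bimodal": pt.bimodal,
            "threshold_p0": pt.threshold_p0,
        })
    return pd.DataFrame(rows)
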