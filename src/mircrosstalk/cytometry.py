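"""Synthetic two-plasmid cotransfection populations with known ground truth.

Emulates the experimental design the analysis pipeline was built for: two
bidirectional reporter plasmids per cell, each driving one miRNA-regulated
fluorophore (mCherry with N MREs, mCerulean with N MREs) and one unregulated
transcription reporter (eYFP, mKOrange).  Transient cotransfection gives every
cell a different plasmid load, drawn log-normally with positive inter-plasmid
correlation (co-uptake); the load scales the transcription rates of both genes
on that plasmid, so eYFP/mKOrange trace constitutive activity while
mCherry/mCerulean additionally feel the shared miRNA pool.

Molecule counts per cell come either from the Gaussian (linear-noise)
stationary law of the titration model (fast, default) or from exact SSA runs;
fluorescence is a linear per-channel gain times molecules plus additive
Gaussian autofluorescence background, truncated at instrument zero.  An
untransfected control population (background only) is appended per replicate,
as required by the background-correction rule downstream.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelParams, constitutive_levels, validate_params
from .moments import stationary_covariance

__all__ = ["PopulationConfig", "CellTable", "mre_interaction_strength",
           "generate_population", "write_cells", "read_cells"]

CHANNELS = ("eYFP", "mCherry", "mCerulean", "mKOrange")
REQUIRED_COLUMNS = ("replicate", "population") + CHANNELS
_ALLOWED_MRE = (0, 1, 4, 7)


@dataclass(frozen=True)
class PopulationConfig:
    """Study design of one synthetic cotransfection experiment.

    Plasmid loads are log-normal: ``log D_i ~ Normal(copy_log_mean,
    copy_log_sd)`` with correlation ``copy_corr`` between the two plasmids of
    a cell.  ``n_mre_*`` are the MRE counts on the regulated fluorophores;
    they map to interaction strengths via ``g_unit`` (per-site, linear by
    default, optionally saturating with scale ``mre_saturation``).
    ``premir_boost >= 1`` multiplies the miRNA transcription rate, emulating
    pre-miR cotransfection.
    """

    n_cells: int = 50_000
    n_replicates: int = 3
    copy_log_mean: float = 1.1
    copy_log_sd: float = 0.8
    copy_corr: float = 0.5
    n_mre_cherry: int = 4
    n_mre_cerulean: int = 0
    g_unit: float = 0.5
    mre_saturation: float | None = None
    premir_boost: float = 1.0
    gain: dict = field(default_factory=lambda: {c: 2.0 for c in CHANNELS})
    background_mean: dict = field(default_factory=lambda: {c: 100.0 for c in CHANNELS})
    background_sd: dict = field(default_factory=lambda: {c: 25.0 for c in CHANNELS})
    n_control: int = 10_000
    sampler: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_control < 1:
            raise ValueError("n_control must be >= 1")
        if self.copy_log_sd <= 0:
            raise ValueError("copy_log_sd must be > 0")
        if not (-1.0 < self.copy_corr < 1.0):
            raise ValueError("copy_corr must lie in (-1, 1)")
        if self.n_mre_cherry not in _ALLOWED_MRE or self.n_mre_cerulean not in _ALLOWED_MRE:
            raise ValueError(f"MRE counts must be one of {_ALLOWED_MRE}")
        if self.g_unit < 0:
            raise ValueError("g_unit must be >= 0")
        if self.premir_boost < 1.0:
            raise ValueError("premir_boost must be >= 1")
        if self.sampler not in ("gaussian", "ssa"):
            raise ValueError("sampler must be 'gaussian' or 'ssa'")
        for c in CHANNELS:
            if self.gain[c] <= 0:
                raise ValueError(f"gain[{c}] must be > 0")
            if self.background_sd[c] < 0:
                raise ValueError(f"background_sd[{c}] must be >= 0")


@dataclass
class CellTable:
    """Per-cell four-channel intensities plus hidden generator ground truth.

    ``cells`` carries what a cytometer would export (replicate id, population
    tag, channel intensities); ``truth`` (same row order, transfected rows
    only) carries plasmid loads and molecule counts; ``meta`` echoes the
    generating config and model parameters.
    """

    cells: pd.DataFrame
    truth: pd.DataFrame | None = None
    meta: dict | None = None

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.cells.columns]
        if missing:
            raise ValueError(f"cell table is missing columns: {missing}")
        if self.cells[list(CHANNELS)].isna().any().any():
            raise ValueError("cell table contains NaN intensities")
        pops = set(self.cells["population"].unique())
        if not pops <= {"transfected", "control"}:
            raise ValueError(f"unknown population tags: {sorted(pops - {'transfected', 'control'})}")
        for rep, grp in self.cells.groupby("replicate"):
            if "control" not in set(grp["population"]):
                raise ValueError(f"replicate {rep} has no 'control' population")

    def replicates(self) -> list[int]:
        return sorted(self.cells["replicate"].unique())


def mre_interaction_strength(n_mre: int, g_unit: float,
                             saturation: float | None = None) -> float:
    """Map an MRE count to an effective interaction strength.

    Linear by default, ``g = N * g_unit``.  With ``saturation`` set, a
    saturating map ``g = g_unit * saturation * (1 - exp(-N/saturation))`` is
    used instead, expressing that many adjacent sites mostly raise the binding
    probability per encounter rather than acting independently.
    """
    if saturation is None:
        return n_mre * g_unit
    return g_unit * saturation * (1.0 - np.exp(-n_mre / saturation))


def _cell_params(base: ModelParams, config: PopulationConfig,
                 d1: float, d2: float) -> ModelParams:
    return replace(
        base,
        k_s=base.k_s * config.premir_boost,
        k_r1=base.k_r1 * d1,
        k_r2=base.k_r2 * d2,
        g_1=mre_interaction_strength(config.n_mre_cherry, config.g_unit,
                                     config.mre_saturation),
        g_2=mre_interaction_strength(config.n_mre_cerulean, config.g_unit,
                                     config.mre_saturation),
    )


def _constitutive_sample(rng: np.ndarray, mean: float, k_p: float,
                         g_r: float, g_p: float) -> float:
    """Two-stage (mRNA burst) protein law: var = mean*(1 + k_p/(g_r+g_p))."""
    if mean <= 0:
        return 0.0
    var = mean * (1.0 + k_p / (g_r + g_p))
    return max(rng.normal(mean, np.sqrt(var)), 0.0)


class _MomentCache:
    """Memoise Gaussian stationary moments on a log-quantised load grid.

    Plasmid loads are continuous; quantising log D to steps of ``h`` (default
    2%) lets one Lyapunov solve serve many cells with negligible distortion
    relative to the decade-wide load spread.
    """

    def __init__(self, base: ModelParams, config: PopulationConfig, h: float = 0.02):
        self.base = base
        self.config = config
        self.h = h
        self._cache: dict[tuple[int, int], tuple] = {}

    def get(self, d1: float, d2: float):
        key = (int(round(np.log(d1) / self.h)), int(round(np.log(d2) / self.h)))
        hit = self._cache.get(key)
        if hit is None:
            q1, q2 = np.exp(key[0] * self.h), np.exp(key[1] * self.h)
            mom = stationary_covariance(_cell_params(self.base, self.config, q1, q2))
            idx = [3, 4]  # p1, p2
            mean = mom.mean[idx]
            cov = mom.cov[np.ix_(idx, idx)]
            # guard tiny negative eigenvalues from round-off
            w, v = np.linalg.eigh(cov)
            cov_sqrt = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
            hit = (mean, cov_sqrt)
            self._cache[key] = hit
        return hit


def generate_population(config: PopulationConfig,
                        params_base: ModelParams) -> CellTable:
    """Generate a seeded synthetic cotransfection experiment.

    ``params_base`` holds the per-unit-plasmid-load rates: a cell with loads
    (D1, D2) transcribes target 1 at ``D1*k_r1`` and target 2 at ``D2*k_r2``;
    its interaction strengths come from the configured MRE counts (the g_1,
    g_2 of ``params_base`` are ignored).  eYFP shares D1 with mCherry and
    mKOrange shares D2 with mCerulean; both are unregulated.
    """
    base = validate_params(params_base)
    rng = np.random.default_rng(config.seed)

    cell_rows = []
    truth_rows = []
    cov_log = np.array([[1.0, config.copy_corr], [config.copy_corr, 1.0]])
    cov_log *= config.copy_log_sd**2
    chol = np.linalg.cholesky(cov_log)

    cache = _MomentCache(base, config) if config.sampler == "gaussian" else None

    for rep in range(config.n_replicates):
        z = rng.standard_normal((config.n_cells, 2)) @ chol.T + config.copy_log_mean
        loads = np.exp(z)
        for i in range(config.n_cells):
            d1, d2 = loads[i]
            params = _cell_params(base, config, d1, d2)
            if config.sampler == "gaussian":
                mean, cov_sqrt = cache.get(d1, d2)
                p1, p2 = np.maximum(mean + cov_sqrt @ rng.standard_normal(2), 0.0)
            else:
                from .ssa import default_burn_in, sample_stationary

                smp = sample_stationary(
                    params, n_cells=1,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    burn_in=default_burn_in(params),
                    check_stationarity=False,
                )
                p1, p2 = float(smp.states[0, 3]), float(smp.states[0, 4])
            lv = constitutive_levels(params)
            yfp = _constitutive_sample(rng, lv.p0_1, base.k_p1, base.g_r1, base.g_p1)
            kor = _constitutive_sample(rng, lv.p0_2, base.k_p2, base.g_r2, base.g_p2)

            molecules = {"eYFP": yfp, "mCherry": p1, "mCerulean": p2, "mKOrange": kor}
            row = {"replicate": rep, "population": "transfected"}
            for c in CHANNELS:
                bg = rng.normal(config.background_mean[c], config.background_sd[c])
                row[c] = max(config.gain[c] * molecules[c] + bg, 0.0)
            cell_rows.append(row)
            truth_rows.append({"replicate": rep, "D1": d1, "D2": d2, **{
                f"mol_{c}": molecules[c] for c in CHANNELS}})

        for _ in range(config.n_control):
            row = {"replicate": rep, "population": "control"}
            for c in CHANNELS:
                bg = rng.normal(config.background_mean[c], config.background_sd[c])
                row[c] = max(bg, 0.0)
            cell_rows.append(row)

    meta = {"config": _config_dict(config), "params_base": base.to_dict()}
    return CellTable(cells=pd.DataFrame(cell_rows),
                     truth=pd.DataFrame(truth_rows), meta=meta)


def _config_dict(config: PopulationConfig) -> dict:
    d = asdict(config)
    return d


def ground_truth_threshold(config: PopulationConfig, params_base: ModelParams,
                           p0_span: tuple[float, float] = (2.0, 2000.0),
                           n_grid: int = 120) -> dict[str, float]:
    """Model-predicted titration threshold for a generated population.

    Sweeps p0 at the population's effective parameters (MRE-mapped
    interaction strengths, pre-miR boost) and converts the threshold to the
    analysis pipeline's axis: corrected eYFP intensity = gain * p0 minus the
    2-sigma background offset the correction stage subtracts.
    """
    from .phenotypes import sweep_p0

    base = validate_params(params_base)
    eff = _cell_params(base, config, 1.0, 1.0)
    grid = np.geomspace(p0_span[0], p0_span[1], n_grid)
    thr = sweep_p0(eff, grid, method="moments").threshold()
    eyfp_corrected = (config.gain["eYFP"] * thr.p0_star
                      - 2.0 * config.background_sd["eYFP"])
    return {"p0_star": thr.p0_star, "max_slope": thr.max_slope,
            "eyfp_corrected": eyfp_corrected, "absent": float(thr.absent)}


def write_cells(table: CellTable, path: str | Path) -> None:
    """Write a cell table as CSV plus a JSON sidecar (config echo + ground
    truth in a companion CSV).  Lossless round-trip with :func:`read_cells`."""
    path = Path(path)
    table.cells.to_csv(path, index=False)
    sidecar = dict(table.meta or {})
    if table.truth is not None:
        truth_path = path.with_suffix(".truth.csv")
        table.truth.to_csv(truth_path, index=False)
        sidecar["truth_file"] = truth_path.name
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_cells(path: str | Path) -> CellTable:
    """Read a cell table written by :func:`write_cells`; schema-validated.

    Raises a descriptive error when required columns, intensities, or the
    per-replicate control population are missing.
    """
    path = Path(path)
    cells = pd.read_csv(path)
    meta = None
    truth = None
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        tf = meta.get("truth_file")
        if tf and (path.parent / tf).exists():
            truth = pd.read_csv(path.parent / tf)
    return CellTable(cells=cells, truth=truth, meta=meta)


def regenerate(table: CellTable) -> CellTable:
    """Rebuild a population from its own sidecar config; byte-identical given
    the recorded seed."""
    if not table.meta:
        raise ValueError("table carries no sidecar config")
    config = PopulationConfig(**{k: v for k, v in table.meta["config"].items()})
    params = ModelParams.from_mapping(table.meta["params_base"])
    return generate_population(config, params)
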