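# Methods

## The model

Two mRNA species, `r1` and `r2`, are transcribed at rates `k_r1`, `k_r2` and
degraded at rates `g_r1`, `g_r2`. A shared miRNA `s` is transcribed at `k_s`
and degraded free at `g_s`. A free miRNA binds a free target in one effective
bimolecular step with strength `g_1` or `g_2` (units 1/(molecules·time)); the
bound target is always lost, while the miRNA is co-degraded with probability
`alpha` and recycled with probability `1 − alpha`. Unbound targets are
translated at `k_p1`, `k_p2` into proteins `p1`, `p2` that decay at `g_p1`,
`g_p2`. The state is the 5-vector of copy numbers `(s, r1, r2, p1, p2)`;
no explicit miRNA–mRNA complex species is kept, so the interaction appears as
14 elementary channels (3 transcriptions, 3 free decays, 2 joint degradations,
2 recyclings, 2 translations, 2 protein decays), each with a mass-action
propensity. Splitting each interaction into a joint-degradation channel
(rate `alpha·g_i·s·r_i`, removes both molecules) and a recycling channel
(rate `(1−alpha)·g_i·s·r_i`, removes only the target) keeps every propensity a
simple product and makes the miRNA bookkeeping auditable from event counts.

Because both targets draw on the same finite miRNA pool, they are coupled:
raising either `k_r2` or `g_2` sequesters miRNA away from `r1`. Near the
stoichiometric balance point — where the target transcription flux matches
the effective miRNA supply — the response of `p1` to its constitutive level
`p0` is ultrasensitive (titration threshold), the noise of `p1` develops a
local maximum, and the two target proteins become positively correlated
(retroactivity: the intrinsic noise of one target couples, through the shared
pool, to the other).

Units: time is measured in target-mRNA lifetimes (`g_r1 = 1` in the default
parameter sets) and molecule numbers are absolute copies per cell, kept in
the 10–1000 range where crosstalk is physiologically relevant.

## Deterministic layer

At stationarity the rate equations reduce to one scalar equation for the free
miRNA: substituting `r_i(s) = k_ri/(g_ri + g_i s)` into the miRNA balance
leaves `f(s) = k_s − g_s s − alpha·s·Σ g_i r_i(s) = 0`, with `f` strictly
decreasing on `[0, k_s/g_s]`. The root is therefore unique and is found by
bracketed Brent iteration at machine precision (residual tolerance 1e−10
relative); the remaining species follow in closed form. This replaces any
damped-Newton/ODE-continuation scheme: the scalar reduction cannot fail to
converge, even where the full Jacobian is ill-conditioned near the threshold.

The threshold itself is operationalised as the point of maximal logarithmic
slope `d log⟨p1⟩ / d log p0` along a `p0` sweep (central differences,
interior grid points only). An unregulated reporter has slope identically 1;
a curve whose maximal slope does not exceed 1.05 is reported as having no
threshold. The 1.05 margin is a package convention: finite grids on smooth
curves produce slopes within a percent of 1 without any regulation.

## Gaussian (linear-noise) layer

The stationary fluctuations are computed by linearising around the mean-field
fixed point: the covariance `C` solves `A C + C Aᵀ + B = 0`, where `A` is the
drift Jacobian and `B = Σ_channels rate·(stoichiometry outer product)`, both
evaluated at the fixed point. The 5×5 Lyapunov system is solved densely
(residual ≤ 1e−8 relative). Means are the mean-field values, uncorrected.
For the decoupled network (`g_1 = g_2 = 0`) all propensities are linear and
the first two moments are exact: mRNAs are Poisson and the protein noise
obeys the two-stage cascade law `CV² = (1 + k_p/(g_r + g_p))/⟨p⟩`, which the
test suite uses as a closed-form anchor.

Validity: the approximation degrades exactly where the model is most
interesting. At the threshold the exact stochastic mean of `p1` exceeds the
mean-field value (the response is convex in the miRNA pool), by up to ~50%
for the default parameters, and in the strong-repression corner the marginal
law becomes bimodal, which no Gaussian summary captures. The package treats
the Gaussian curves as smooth trend predictors — the use made of them
throughout — and flags Gaussian summaries computed where an SSA sample of
`p1` rejects unimodality.

## Exact stochastic layer

The direct-method Gillespie simulator realises the 14 channels exactly
(numba-compiled; seeded, hence reproducible). Stationary "cells" are drawn
as independent replicas by default: one seeded run per cell from the rounded
mean-field state, recorded after a burn-in of 20 linear relaxation times
(slowest eigenvalue of `A`). A thinned single-run mode exists for cheap
autocorrelated draws. An auto-check reruns a 200-cell pilot at twice the
burn-in and compares means (4-sigma rule); failure sets a flag rather than
raising, because near-critical parameter sets mix slowly yet remain usable
with a longer explicit burn-in. In the metastable (bimodal) corner the
linear relaxation time underestimates the state-switching time, so samples
there should be read as the population a cytometer would see at a fixed
observation time rather than a converged stationary ensemble; the bimodality
verdicts below are insensitive to this distinction.

## Bimodality

The primary statistic is Hartigan's dip — the sup-norm distance from the
empirical CDF to the nearest unimodal CDF — computed by the greatest-convex-
minorant / least-concave-majorant interval-shrinking algorithm (AS 217). The
implementation is validated two ways: against an exact small-n oracle that
minimises the distance over unimodal CDFs by linear programming
(`tests/dip_oracle.py`), and against reference values computed with the R
`diptest` implementation, frozen into the unit tests.

Calibration and scale conventions, both of which matter in practice:

* The Monte-Carlo p-value uses the uniform null (the least favourable
  unimodal law), which presumes continuous data. Molecule counts are heavily
  tied, and ties alone inflate the dip; tied samples are therefore spread by
  seeded one-sided uniform noise, x + U[0, h) with h the smallest observed
  spacing — the standard continuity randomisation for counts. One-sided
  noise matters: centred noise clipped at zero re-creates an atom at the
  origin, which masquerades as a second mode on the log axis.
* Expression distributions are examined on the log1p axis, the scale on
  which cytometry histograms are read. The off/on phenotypes of a strongly
  repressed target separate on that axis, while on the linear axis the
  off-state is a monotone tail and no valley exists; unimodality of a
  density is not preserved under nonlinear monotone transforms, so the scale
  choice is part of the statistic's definition, not a numerical detail.

A Silverman-bandwidth KDE mode count (same log scale, 5%-prominence filter)
is reported as a descriptive cross-check; the verdict rests on the dip
p-value alone, because with a few thousand cells the KDE oversmooths heavily
unbalanced mixtures the dip still resolves.

The packaged bimodal operating point (`bimodal_params`) uses strong binding
(`g_1 = 50`), no competitor sites, a long-lived miRNA (`g_s = 0.01`) whose
pool gates the target slowly, partial recycling (`alpha = 0.5`), and a
translational burst (`k_p1 = 20`). The two-phenotype window is only a few
percent of `p0` wide, sitting at and just above the threshold; detection at
the 1% level needs about 3000 cells at this effect size. Both the phase
classifier and the acceptance checks therefore probe the threshold estimate
and +5%/+10% above it, Bonferroni-splitting the level across the probes,
because a grid-snapped threshold estimate can sit just off the window.

## Phenotype sweeps and the competitor limit

`p0` is swept via `k_r1` with translation and degradation fixed, mirroring
the experiment where plasmid load varies but protein chemistry does not.
Fold-repression `F(p0)` is the unregulated/regulated mean ratio. In the pure
model `F` is a saturating-then-decaying curve: `F = 1 + g_1 s(p0)/g_r1` with
`s` monotone in `p0`, so its maximum is the whole repressed plateau ending at
the threshold, not an interior peak. An interior `F` maximum at the
threshold emerges in the *measured* curves, where background correction and
positivity gating suppress the fully repressed bins — this is the form in
which the statistic is defined and tested downstream (and the only form in
which it is observable).

The infinite-competitor limit is computed exactly: with `g_2 → ∞` the free
`r2` pool vanishes and every `r2` transcript consumes a miRNA with
probability `alpha`, so the system reduces to a single-target model with
effective supply `k_s' = max(k_s − alpha·k_r2, 0)`. Two regimes follow:
`alpha·k_r2 < k_s` leaves excess miRNA and a genuine threshold in the
limiting curve; `alpha·k_r2 ≥ k_s` exhausts the pool and returns the
unregulated line. The monotone shift of the threshold with `k_r2` is a
statement about the sponging regime (`alpha·k_r2 < k_s`): beyond it the
threshold dissolves (maximal slope drifts to 1) and its location ceases to
be meaningful, which is the model's own version of "the curve tends to the
unregulated case".

## Synthetic cotransfection populations

The generator emulates the two-plasmid, four-fluorophore design: per cell,
plasmid loads `(D1, D2)` are drawn log-normally (`log D ~ N(1.1, 0.8²)`,
inter-plasmid correlation 0.5, emulating co-uptake in transient
transfection); `D1` scales the transcription rate of mCherry and eYFP, `D2`
that of mCerulean and mKOrange; MRE counts `N ∈ {0,1,4,7}` map to
interaction strengths `g_i = N·g_unit` (default `g_unit = 0.5`; an optional
saturating map expresses that 4 and 7 sites repress almost equally);
a pre-miR cotransfection is a multiplicative boost on `k_s`. Molecule counts
come from the Gaussian stationary law by default (one Lyapunov solve per
quantised load pair, 2% log-quantisation; exact SSA per cell available via
`sampler="ssa"`), the unregulated reporters from the two-stage closed form.
Fluorescence is `gain·molecules` plus additive Gaussian autofluorescence
(default 100 ± 25 a.u.), truncated at instrument zero; an untransfected
control population carries background only.

Default design: miRNA supply `k_s = 40` (per unit load the titration
threshold then sits ~0.9 log-units above the median load, inside the
measurable window, with enough molecules at threshold that reporter noise
does not blur the binned curve); 50 000 cells and 3 replicates per
condition. What the generator does *not* emulate: scatter gating, spectral
spillover, cell-cycle/size effects, autofluorescence heterogeneity beyond a
Gaussian, or endogenous competitor targets. Passing the end-to-end tests
therefore shows that the pipeline recovers the model's predictions from data
with realistic load spread, reporter noise and background — not that it is
robust to every artifact of a real cytometer.

## Analysis pipeline conventions

Background correction subtracts, per replicate and channel, the control mean
plus two control SDs; negative corrected values are kept until gating.
Gating keeps cells positive on both constitutive channels. Binning is
equal-width on corrected eYFP over `[0, 99.5th percentile]`; the default bin
count targets ~1000 cells median occupancy; bins with fewer than `min_cells`
cells in any replicate are masked. Reported per-bin values are means over
replicates with the SD over replicates as error bar (≈ √N_cells_in_bin
smaller than the within-bin dispersion). Fold-repression errors are
leave-one-replicate-out jackknife; bins whose corrected regulated mean is
non-positive (pure background, fully repressed) are masked. The Pearson
ratio pools cells per region — threshold bin ±1 is "around", the rest
"below"/"above" — computes the regulated/reference correlation ratio per
replicate, and averages; its p-value is the Gaussian tail of the observed
ratio under a null whose mean and SD come from the N=0 self-ratios
(one-sided, enrichment, by default; the ratio is flagged unstable when the
reference correlation falls below 0.05). Crosstalk buckets in the phase
diagram (low < 0.1 ≤ medium < 0.3 ≤ high, on the maximal sweep correlation)
are package conventions and configurable.

## Problem sizes used by the tests and the acceptance script

Exact-law checks use 10⁴ stationary cells; the Gaussian-vs-SSA comparison
five parameter sets × 1500 cells with 150 bootstrap resamples; sweeps 40
(readouts) or 120 (threshold-shift directions) grid points; bimodality 3000
cells per probe with 1000-boot p-values; the end-to-end recovery 3 replicates × 50 000
cells per condition with 20 eYFP bins. These sizes put every Monte-Carlo
margin comfortably beyond its decision boundary while keeping a full run in
minutes on one core.

## Known limitations

* Gaussian means are mean-field: biased high-side at the threshold and in
  strong-coupling/small-number regimes (the comparison report measures this).
* The dip test's p-value is Monte-Carlo (resolution 1/(n_boot+1)); verdicts
  at level 0.01 need n_boot ≥ 300.
* The max-log-slope threshold estimator snaps to the sweep grid; directional
  comparisons use 120-point grids for that reason.
* No tau-leaping: SSA cost grows linearly with propensity mass, so very
  large copy-number regimes (≫10³ molecules) are slow.
* The two-target network is hard-coded; more competitors require extending
  the state and channel tables.
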