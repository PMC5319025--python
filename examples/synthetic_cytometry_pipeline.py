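"""End-to-end: synthetic cotransfection experiment -> analysis pipeline.

Generates a two-plasmid population (mCherry with 4 MREs, mCerulean with 4
MREs, plus their unregulated transcription reporters and an untransfected
control), then runs the full pipeline: background correction, positivity
gating, equal-width eYFP binning, threshold location, fold-repression
against an N=0 reference, and the Pearson-ratio statistic with p-values.
The recovered threshold is compared against the generator's ground truth.
"""

import numpy as np
from dataclasses import replace

from mircrosstalk import (
    PopulationConfig,
    background_correct,
    bin_and_summarize,
    empirical_fold_repression,
    gate_positive,
    generate_population,
    null_self_ratios,
    pearson_ratio,
    ratio_pvalue,
    reference_params,
)
from mircrosstalk.cytometry import ground_truth_threshold

base = replace(reference_params(), k_s=40.0)  # large miRNA pool
kw = dict(n_cells=20_000, n_replicates=3, n_control=8_000, g_unit=0.5)

reg_tab = generate_population(
    PopulationConfig(n_mre_cherry=4, n_mre_cerulean=4, seed=1, **kw), base)
ref_tab = generate_population(
    PopulationConfig(n_mre_cherry=0, n_mre_cerulean=0, seed=2, **kw), base)

reg = bin_and_summarize(gate_positive(background_correct(reg_tab)),
                        n_bins=20, min_cells=60)
ref = bin_and_summarize(gate_positive(background_correct(ref_tab)),
                        edges=reg.edges, min_cells=60)

thr_bin = reg.threshold_bin()
truth = ground_truth_threshold(
    PopulationConfig(n_mre_cherry=4, n_mre_cerulean=4, seed=1, **kw), base)
truth_bin = int(np.digitize(truth["eyfp_corrected"], reg.edges) - 1)
print(f"threshold: measured in bin {thr_bin}, model ground truth in bin "
      f"{truth_bin} (corrected eYFP = {truth['eyfp_corrected']:.0f} a.u.)")

fr = empirical_fold_repression(reg, ref)
ok = fr[~fr["masked"]]
fmax = ok.loc[ok["F"].idxmax()]
print(f"fold-repression: max F = {fmax['F']:.1f} +- {fmax['F_err']:.1f} "
      f"in bin {int(fmax['bin'])} (threshold bin {thr_bin})")

ratios = pearson_ratio(reg, ref, thr_bin)
nulls = null_self_ratios(ref, thr_bin)
print("\nPearson ratio (regulated vs N=0 correlation of mCherry-mCerulean):")
for region in ("below", "around", "above"):
    res = ratio_pvalue(ratios[region], nulls[region])
    print(f"  {region:>6}: ratio = {res.ratio:5.2f} +- {res.replicate_error:.2f}, "
          f"p = {res.p_value:.2e}"
          f"{'  (reference correlation below floor)' if res.unstable else ''}")
print("\nA ratio > 1 measures correlation injected by competition for the "
      "shared miRNA,\nover and above what plasmid co-uptake alone produces; "
      "it peaks around the threshold.")
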