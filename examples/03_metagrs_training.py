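"""Select p-value thresholds and combine component scores into a metaGRS.

A prevalent case-control training set (all prevalent cases plus 2000 random
controls) drives both decisions: the winning threshold per summary source is
the candidate with the smallest age-adjusted logistic p-value, and the
metaGRS weight of each component is its marginal log odds ratio per SD from
the same training model.
"""

import numpy as np
import pandas as pd

from metagrs import (
    EffectModel, LDBlockSpec, OnsetModel, ScoreSet, combine, compute_scores,
    fit_metagrs, ld_prune, select_best_threshold, simulate_cohort,
    simulate_effects, simulate_genotypes, simulate_gwas_sumstats,
    threshold_subsets, true_scores,
)

panel = simulate_genotypes(12_000, LDBlockSpec(60, 8, 0.35), seed=1)
truth = simulate_effects(panel, EffectModel(120, per_sd_hr=1.65), seed=2)
cohort = simulate_cohort(panel, truth, OnsetModel(), seed=3)

stats = simulate_gwas_sumstats(truth, panel, 122_977, 105_974, seed=4)
kept = ld_prune(stats, panel)
subsets = threshold_subsets(stats, kept, provenance="ONCO")

# training set: prevalent cases + 2000 random controls
rng = np.random.default_rng(5)
prevalent = cohort[cohort["prevalent"] == 1]
pool = cohort[(cohort["prevalent"] == 0) & (cohort["bc_event"] == 0)]
controls = pool.iloc[rng.choice(len(pool), 2000, replace=False)]
train_ids = np.r_[prevalent["sample_id"], controls["sample_id"]]
labels = pd.Series(np.r_[np.ones(len(prevalent)), np.zeros(2000)],
                   index=train_ids)
age = pd.Series(np.r_[prevalent["entry_age"], controls["entry_age"]],
                index=train_ids)

scoreset = ScoreSet(panel.sample_ids)
names = []
for ws in subsets:
    name = f"ONCO@{ws.p_threshold:g}"
    if ws.n_variants == 0:
        scoreset.add(name, np.zeros(panel.n_samples), n_variants=0)
    else:
        scoreset.add(name, compute_scores(panel, ws).values,
                     n_variants=ws.n_variants)
        scoreset.standardize(name, train_ids)
    names.append(name)

sel = select_best_threshold(scoreset, labels, age, names)
row = sel.table.set_index("label").loc[sel.winner]
print(f"training set: {len(prevalent)} prevalent cases, 2000 controls")
print(f"winning threshold: {sel.winner} ({int(row['n_variants'])} SNPs), "
      f"OR per SD = {row['or_per_sd']:.2f} "
      f"(95% CI {row['ci_low']:.2f}-{row['ci_high']:.2f}), "
      f"p = {row['pvalue']:.2g}")

# a second, noisier component: the same score rebuilt from a small GWAS
stats2 = simulate_gwas_sumstats(truth, panel, 7_480, 30_000, seed=6)
ws2 = threshold_subsets(stats2, ld_prune(stats2, panel), grid=(5e-5,),
                        provenance="UK")[0]
scoreset.add("UK@5e-05", compute_scores(panel, ws2).values,
             n_variants=ws2.n_variants)
scoreset.standardize("UK@5e-05", train_ids)

mw = fit_metagrs(scoreset, labels, age, [sel.winner, "UK@5e-05"])
combine(scoreset, mw, name="metaGRS_2", reference_ids=train_ids)
print("metaGRS_2 component weights (log OR per SD on the training set):")
for c, w in zip(mw.components, mw.weights):
    print(f"  {c:<14s} {w:+.3f}")
g = true_scores(panel, truth)
r = np.corrcoef(scoreset.table["metaGRS_2"], g)[0, 1]
print(f"metaGRS_2 correlates {r:.3f} with the true genetic score")
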