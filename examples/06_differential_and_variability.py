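"""Differential methylation and differential variability between groups.

Moderated-t tables with worst-rank scoring: a CpG ranks well only if its
adjusted p-value, effect size, and log-quotient all rank well. The
automatic cutoff (the number of units passing BH FDR) sizes the selected
set.
"""

import methworks as mw
import methworks.differential as diff

fx = mw.generate_fixture(mw.FixtureSpec(seed=3))
ds = mw.impute_missing(fx.dataset, "knn", k=5, seed=0)
comp = mw.GroupComparison.from_sheet(ds.samples, "group")

dm = diff.differential_methylation(ds.beta_frame(), comp)
cutoff = diff.auto_rank_cutoff(dm, fdr=0.05)
selected = diff.select_units(dm, fdr=0.05)
truth = fx.truth_sites
planted = set(truth.index[truth["role"] == "dmc"])
hit = len(planted & set(selected))
print(f"differential methylation: auto rank cutoff {cutoff}; "
      f"{hit}/{len(planted)} planted DMCs recovered")
print(dm.head(5)[["mean0", "mean1", "diff", "p_adj", "combined_rank"]])

dv = diff.differential_variability(ds.beta_frame(), comp, method="diffvar")
planted_v = set(truth.index[truth["role"] == "dvc"])
sel_v = set(diff.select_units(dv, fdr=0.05))
print(f"\ndifferential variability (diffVar): {len(sel_v)} selected; "
      f"{len(planted_v & sel_v)}/{len(planted_v)} planted DVCs among them "
      "(variance changes need larger cohorts than mean changes)")
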