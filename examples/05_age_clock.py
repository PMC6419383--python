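"""Train and apply a methylation age clock.

Elastic-net regression of chronological age on single-CpG betas with
cross-validated penalty selection; model CpGs missing at prediction time
are substituted by their training means.
"""

import numpy as np

import methworks as mw

ds, ages, causal = mw.simulate_age_cohort(n_samples=200, n_sites=1000, seed=0)
keep = np.arange(ds.n_samples) < 150
train = mw.MethylationDataset(
    sites=ds.sites, samples=ds.samples.loc[keep], beta=ds.beta[:, keep],
    platform=ds.platform,
)
test = mw.MethylationDataset(
    sites=ds.sites, samples=ds.samples.loc[~keep], beta=ds.beta[:, ~keep],
    platform=ds.platform,
)

model = mw.train_age_model(train, alpha=0.5, cv_folds=5, seed=0)
print(
    f"selected penalty {model.lam:.4g}; {len(model.coefficients)} CpGs with "
    "nonzero weight (the clock's methylation signature)"
)

pred = mw.predict_age(model, test)
r = np.corrcoef(pred["predicted_age"], ages[~keep])[0, 1]
mad = np.abs(pred["predicted_age"] - ages[~keep]).median()
print(f"held-out: Pearson r = {r:.3f}, median abs error = {mad:.2f} years")
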