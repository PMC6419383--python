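"""Infer sample covariates from methylation data alone.

Sex from sex-chromosome coverage ratios, sample quality from genotyping
probes, tumor purity from leukocyte-unmethylated CpGs, and cell-type
composition by constrained least squares against reference profiles.
"""

import numpy as np

import methworks as mw

fx = mw.generate_fixture(mw.FixtureSpec(seed=2))
ds = fx.dataset

# sex: fX/fY are log2 ratios of sex-chromosome to autosomal coverage
feats = mw.sex_features(ds)
model = mw.train_sex_model(feats, ds.samples["sex"], seed=0)
pred = mw.predict_sex(model, feats)
acc = (pred["predicted_sex"] == ds.samples["sex"]).mean()
print(f"sex prediction accuracy on the cohort: {acc:.1%}")

noise = mw.genetic_noise(ds)
print(f"genetic noise (0 = ideal diploid, max 0.25): mean {noise.mean():.4f}")

purity = mw.lump_purity(ds, fx.lump_sites)
err = np.abs(purity["purity"] - fx.truth_samples["purity"]).mean()
print(f"LUMP purity vs planted truth: mean abs error {err:.3f}")

imputed = mw.impute_missing(ds, "knn", k=5, seed=0)
weights = mw.deconvolve_celltypes(imputed, fx.reference, "sum_eq_one")
truth = fx.truth_samples[[f"w_{t}" for t in fx.reference.cell_types]].to_numpy()
mae = np.abs(weights[fx.reference.cell_types].to_numpy() - truth).mean()
print(f"cell-type weight recovery: mean abs error {mae:.4f} (weights sum to 1)")
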