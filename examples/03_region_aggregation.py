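"""Aggregate single-CpG methylation into region-level values.

Tiles the genome into fixed windows and averages member-CpG betas per
sample; regions with too few CpGs are reported missing.
"""

import methworks as mw

fx = mw.generate_fixture(mw.FixtureSpec(seed=1, n_sites=1000))
ds = fx.dataset

tiles = mw.tile_genome({c: 21000 for c in ds.sites["chrom"].unique()}, window=2000)
rm = mw.aggregate_regions(ds, tiles, mode="mean", min_cpgs=3)
frame = rm.to_frame()
shown = frame[["n_cpgs", "g0_000", "g0_001", "g1_000", "g1_001"]]
print(shown.head(8).to_string(float_format=lambda v: f"{v:.3f}"))
# one row per 2 kb tile: n_cpgs counts member CpGs in the dataset, the
# sample columns hold the mean beta of the observed member CpGs

cw = mw.aggregate_regions(ds, tiles, mode="coverage_weighted", min_cpgs=3)
print(
    "\ncoverage-weighted vs plain mean, first region, first sample: "
    f"{cw.meth[0, 0]:.4f} vs {rm.meth[0, 0]:.4f} "
    "(they coincide only when member coverages are equal)"
)
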