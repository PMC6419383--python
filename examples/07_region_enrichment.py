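"""Region-set enrichment of differential regions.

Selected DMRs are compared against a catalogue of region sets over a
background universe using one-sided Fisher exact tests; entries are
ranked by the worst of their p-value, odds-ratio, and support ranks.
"""

import methworks as mw
import methworks.differential as diff
from methworks.explore import EnrichmentCatalog, region_enrichment

fx = mw.generate_fixture(mw.FixtureSpec(seed=4))
ds = mw.impute_missing(fx.dataset, "knn", k=5, seed=0)
comp = mw.GroupComparison.from_sheet(ds.samples, "group")

universe = fx.region_sets["blocks"]
rm = mw.aggregate_regions(ds, universe, min_cpgs=3)
import pandas as pd

vals = pd.DataFrame(rm.meth, index=universe.keys(), columns=rm.samples.index)
dmr_table = diff.differential_methylation(vals, comp)
selected = diff.select_units(dmr_table, fdr=0.05)
print(f"{len(selected)} regions selected at FDR 0.05")

reg = universe.regions.copy()
reg.index = universe.keys()
query = mw.RegionSet("selected", reg.loc[list(selected)].reset_index(drop=True))
catalog = EnrichmentCatalog(
    universe=universe,
    entries=[fx.region_sets["planted_dmrs"], fx.region_sets["planted_dvrs"]],
)
res = region_enrichment(query, catalog)
print(res[["a", "b", "c", "d", "odds_ratio", "log_odds", "fisher_p", "max_rank"]])
# the planted-DMR set should dominate: high odds ratio, tiny Fisher p,
# best (lowest) max_rank; the DVR set is background
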