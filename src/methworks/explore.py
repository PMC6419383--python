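"""Exploratory analysis and region-set enrichment.

PCA of samples over methylation units, statistical association of
principal components with sample annotations, and Fisher-exact enrichment
of a query region set against a catalogue of reference region sets over a
fixed background universe (each universe region is the counting unit; a
region is a hit when any base pair overlaps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import infer_column_types
from .errors import DataError
from .regions import RegionSet


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_embed(matrix, n_components: int = 8):
    """Principal components of samples over units.

    ``matrix`` is units x samples; each unit is centred, then the sample
    coordinates are computed by SVD. Components are ordered by explained
    variance and the sign convention makes the largest-magnitude unit
    loading of each component positive. Returns (coords, explained_variance,
    explained_variance_ratio); coords is a samples x components DataFrame
    when the input carries sample names.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise DataError("need a units x samples matrix with >= 2 samples")
    if np.isnan(X).any():
        raise DataError("missing values present; impute first (impute_missing)")
    Xc = (X - X.mean(axis=1, keepdims=True)).T  # samples x units, unit-centred
    n_samples = Xc.shape[0]
    k = min(n_components, n_samples, Xc.shape[1])
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| positive
    for c in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    coords = U[:, :k] * S[:k]
    explained = S ** 2 / (n_samples - 1)
    ratio = explained / explained.sum() if explained.sum() > 0 else explained
    cols = [f"PC{i + 1}" for i in range(k)]
    if isinstance(matrix, pd.DataFrame):
        coords = pd.DataFrame(coords, index=matrix.columns, columns=cols)
    else:
        coords = pd.DataFrame(coords, columns=cols)
    return coords, explained[:k], ratio[:k]


def associate_components(
    coords: pd.DataFrame, sheet: pd.DataFrame, alpha: float = 0.01
) -> pd.DataFrame:
    """Test each principal component against each sample annotation.

    Numeric annotations: Pearson correlation test. Categorical annotations
    with >= 2 populated levels: Kruskal-Wallis across levels. Annotations
    with a single populated level are skipped with a notice. Returns a
    component x annotation p-value DataFrame; the boolean significance
    mask at ``alpha`` is in ``result.attrs['significant']`` and skipped
    annotations in ``attrs['skipped']``.
    """
    sheet = sheet.loc[coords.index] if set(coords.index) <= set(sheet.index) else sheet
    types = infer_column_types(sheet)
    pvals = {}
    skipped = []
    for col in sheet.columns:
        vals = sheet[col]
        ok = vals.notna().to_numpy()
        if types[col] == "numeric":
            x = vals.astype(float).to_numpy()
            if ok.sum() < 3 or np.nanstd(x[ok]) == 0:
                skipped.append(col)
                continue
            ps = []
            for pc in coords.columns:
                c = coords[pc].to_numpy()[ok]
                ps.append(stats.pearsonr(c, x[ok]).pvalue)
            pvals[col] = ps
        else:
            levels = vals[ok].astype(str)
            uniq = pd.unique(levels)
            if len(uniq) < 2 or any((levels == u).sum() < 2 for u in uniq):
                skipped.append(col)
                continue
            ps = []
            for pc in coords.columns:
                c = coords[pc].to_numpy()[ok]
                groups = [c[(levels == u).to_numpy()] for u in uniq]
                ps.append(stats.kruskal(*groups).pvalue)
            pvals[col] = ps
    if not pvals:
        raise DataError("no testable annotations in the sample sheet")
    if skipped:
        warnings.warn(f"annotations skipped (single populated level): {skipped}", stacklevel=2)
    out = pd.DataFrame(pvals, index=coords.columns).T
    out.index.name = "annotation"
    out.attrs["significant"] = out < alpha
    out.attrs["skipped"] = skipped
    return out


# ---------------------------------------------------------------------------
# Region-set enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentCatalog:
    """A universe (background region set) plus named reference region sets."""

    universe: RegionSet
    entries: list[RegionSet]
    metadata: pd.DataFrame | None = None  # optional: name, collection, description

    def __post_init__(self):
        if len(self.universe) == 0:
            raise DataError("empty enrichment universe")
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise DataError("duplicate catalogue entry names")


def _overlap_flags(universe: RegionSet, other: RegionSet) -> np.ndarray:
    """For each universe region: does any region of `other` overlap it
    (any shared base pair)? Sweep over per-chromosome sorted intervals."""
    flags = np.zeros(len(universe), dtype=bool)
    uni = universe.regions
    oth = other.regions
    for chrom, ogrp in oth.groupby("chrom"):
        sel = uni["chrom"] == chrom
        if not sel.any():
            continue
        u_idx = np.nonzero(sel.to_numpy())[0]
        u_start = uni["start"].to_numpy()[u_idx]
        u_end = uni["end"].to_numpy()[u_idx]
        o_start = ogrp["start"].to_numpy()
        o_end = ogrp["end"].to_numpy()
        # overlap iff o_start < u_end and o_end > u_start for some o
        order = np.argsort(o_start, kind="stable")
        o_start, o_end = o_start[order], o_end[order]
        cummax_end = np.maximum.accumulate(o_end)
        # for each universe region, consider others with o_start < u_end
        hi = np.searchsorted(o_start, u_end, side="left")
        hit = (hi > 0) & (np.where(hi > 0, cummax_end[np.maximum(hi - 1, 0)], 0) > u_start)
        flags[u_idx[hit]] = True
    return flags


def fisher_enrichment_p(a, b, c, d) -> np.ndarray:
    """One-sided (enrichment) Fisher exact p for 2x2 tables [[a,b],[c,d]].

    Identical to the upper hypergeometric tail P(X >= a) with
    X ~ Hypergeom(N = a+b+c+d, K = a+c, n = a+b).
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    N = a + b + c + d
    K = a + c
    n = a + b
    p = stats.hypergeom.sf(a - 1, N, K, n)
    return np.minimum(np.maximum(p, np.finfo(float).tiny), 1.0)


def odds_ratio_haldane(a, b, c, d):
    """Odds ratio (a*d)/(b*c); when any cell is 0, 0.5 is added to every
    cell (Haldane-Anscombe correction)."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    aa = np.where(zero, a + 0.5, a)
    bb = np.where(zero, b + 0.5, b)
    cc = np.where(zero, c + 0.5, c)
    dd = np.where(zero, d + 0.5, d)
    return (aa * dd) / (bb * cc)


def region_enrichment(
    query: RegionSet,
    catalog: EnrichmentCatalog,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Fisher-exact enrichment of a query region set against a catalogue.

    The counting unit is the universe region. A universe region is "in the
    query" (resp. "in a catalogue set") when any base pair overlaps. Query
    regions that overlap no universe region are dropped (count reported in
    ``attrs['n_query_dropped']``). Entries are ranked by the worst
    (maximum) of three ranks — Fisher p (smaller better), odds ratio and
    overlap support (larger better) — and returned in that order.
    """
    in_query = _overlap_flags(catalog.universe, query)
    q_flags = _overlap_flags(query, catalog.universe)
    n_dropped = int((~q_flags).sum())
    if not in_query.any():
        raise DataError("query is empty after restriction to the universe")

    N = len(catalog.universe)
    nq = int(in_query.sum())
    rows = []
    for entry in catalog.entries:
        in_set = _overlap_flags(catalog.universe, entry)
        a = int((in_query & in_set).sum())
        b = nq - a
        c = int((~in_query & in_set).sum())
        d = N - a - b - c
        if two_sided:
            p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
        else:
            p = float(fisher_enrichment_p(a, b, c, d))
        orr = float(odds_ratio_haldane(a, b, c, d))
        rows.append(
            {
                "name": entry.name,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "odds_ratio": orr,
                "log_odds": float(np.log2(orr)),
                "fisher_p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("name")
    out["rank_p"] = stats.rankdata(out["fisher_p"], method="min").astype(int)
    out["rank_or"] = stats.rankdata(-out["odds_ratio"], method="min").astype(int)
    out["rank_support"] = stats.rankdata(-out["a"], method="min").astype(int)
    out["max_rank"] = out[["rank_p", "rank_or", "rank_support"]].max(axis=1)
    out = out.sort_values(["max_rank", "fisher_p"], kind="stable")
    if catalog.metadata is not None:
        meta = catalog.metadata.set_index("name") if "name" in catalog.metadata.columns else catalog.metadata
        for col in meta.columns:
            out[col] = meta[col].reindex(out.index)
    out.attrs["n_query_dropped"] = n_dropped
    out.attrs["n_universe"] = N
    out.attrs["n_query"] = nq
    return out


def load_catalog(directory, universe: RegionSet) -> EnrichmentCatalog:
    """Load a catalogue from a directory of BED files plus an optional
    ``index.tsv`` (columns: name, file, collection, description)."""
    from pathlib import Path

    from .regions import load_region_set

    directory = Path(directory)
    index_path = directory / "index.tsv"
    entries, meta = [], None
    if index_path.exists():
        meta = pd.read_csv(index_path, sep="\t")
        for _, row in meta.iterrows():
            entries.append(load_region_set(directory / row["file"], name=row["name"]))
        meta = meta.drop(columns=["file"])
    else:
        for bed in sorted(directory.glob("*.bed")):
            entries.append(load_region_set(bed, name=bed.stem))
    if not entries:
        raise DataError(f"no catalogue entries found in {directory}")
    return EnrichmentCatalog(universe=universe, entries=entries, metadata=meta)
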