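"""Region sets and aggregation of CpG-level methylation to regions.

Regions are 0-based half-open intervals (the BED convention); CpG sites
are 1-based point positions, so a site at position p belongs to region
[s, e) iff s <= p-1 < e. A CpG may fall in several (overlapping) regions
and contributes to each independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MethylationDataset
from .errors import DataError


@dataclass
class RegionSet:
    """Named, sorted collection of genomic intervals."""

    name: str
    regions: pd.DataFrame  # columns: chrom, start, end[, label]
    source: str = ""

    def __post_init__(self):
        df = self.regions.copy()
        required = ["chrom", "start", "end"]
        for col in required:
            if col not in df.columns:
                raise DataError(f"region set {self.name!r}: missing column {col!r}")
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        bad = df["start"] >= df["end"]
        if bad.any():
            i = int(df.index[bad][0])
            raise DataError(
                f"region set {self.name!r}: start >= end at input row {i} "
                f"({df.loc[df.index[bad][0], 'chrom']}:{df.loc[df.index[bad][0], 'start']})"
            )
        if "label" in df.columns and df["label"].notna().all():
            if df["label"].duplicated().any():
                dup = df["label"][df["label"].duplicated()].iloc[0]
                raise DataError(f"region set {self.name!r}: duplicate label {dup!r}")
        df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
        self.regions = df

    def __len__(self) -> int:
        return len(self.regions)

    def keys(self) -> pd.Index:
        r = self.regions
        return pd.Index(
            r["chrom"].astype(str) + ":" + r["start"].astype(str) + "-" + r["end"].astype(str)
        )

    def to_bed(self, path) -> None:
        cols = ["chrom", "start", "end"] + (["label"] if "label" in self.regions.columns else [])
        self.regions[cols].to_csv(path, sep="\t", header=False, index=False)


@dataclass
class RegionMethylome:
    """Per-region aggregated methylation (regions x samples)."""

    region_set: RegionSet
    samples: pd.DataFrame
    meth: np.ndarray
    n_cpgs: np.ndarray
    mode: str

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.meth, index=self.region_set.keys(), columns=self.samples.index)
        df.insert(0, "n_cpgs", self.n_cpgs)
        df.index.name = "region"
        return df


def tile_genome(chrom_sizes, window: int, step: int | None = None) -> RegionSet:
    """Tile each chromosome with windows of the given width and stride.

    ``step`` defaults to ``window`` (non-overlapping tiles); ``window >=
    step >= 1``. The last partial tile is retained, so for window == step
    the tile count per chromosome is ceil(length / step).
    """
    step = window if step is None else step
    if not (window >= step >= 1):
        raise DataError("need window >= step >= 1")
    if hasattr(chrom_sizes, "items"):
        items = list(chrom_sizes.items())
    else:
        items = list(chrom_sizes)
    if not items:
        raise DataError("empty chrom_sizes")
    rows = []
    for chrom, length in items:
        length = int(length)
        if length <= 0:
            raise DataError(f"non-positive length for chromosome {chrom!r}")
        for start in range(0, length, step):
            rows.append((str(chrom), start, min(start + window, length)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return RegionSet(name=f"tiles_{window}bp", regions=df, source="tile_genome")


def load_region_set(path, name: str | None = None) -> RegionSet:
    """Load a BED3+ file (0-based half-open). Zero-length intervals are an
    error with their line number; output is coordinate-sorted."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}: line {lineno}: need at least 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise DataError(f"{path}: line {lineno}: non-integer coordinates") from None
            if start >= end:
                raise DataError(f"{path}: line {lineno}: start >= end")
            rows.append((parts[0], start, end, parts[3] if len(parts) > 3 else None))
    if not rows:
        raise DataError(f"{path}: no regions")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    if df["label"].isna().all():
        df = df.drop(columns=["label"])
    name = name if name is not None else str(path)
    return RegionSet(name=name, regions=df, source=str(path))


def aggregate_regions(
    dataset: MethylationDataset,
    region_set: RegionSet,
    mode: str = "mean",
    min_cpgs: int = 1,
) -> RegionMethylome:
    """Aggregate per-CpG betas into one value per (region, sample).

    ``mean`` averages the non-missing betas of member CpGs;
    ``coverage_weighted`` weights each cell by its read coverage (cells
    with missing coverage or beta are skipped). ``n_cpgs`` counts member
    sites in the dataset regardless of missingness, and a region with
    n_cpgs < min_cpgs is reported all-missing, as is a (region, sample)
    cell with zero observed member CpGs.
    """
    if mode not in ("mean", "coverage_weighted"):
        raise DataError(f"unknown aggregation mode {mode!r}")
    if min_cpgs < 1:
        raise DataError("min_cpgs must be >= 1")
    if mode == "coverage_weighted" and dataset.coverage is None:
        raise DataError("coverage_weighted aggregation needs a coverage matrix")

    reg = region_set.regions
    ds_chroms = set(dataset.sites["chrom"].unique())
    if ds_chroms.isdisjoint(set(reg["chrom"].unique())):
        warnings.warn(
            "dataset and region set share no chromosome names; result is empty",
            stacklevel=2,
        )

    n_regions, n_samples = len(reg), dataset.n_samples
    meth = np.full((n_regions, n_samples), np.nan)
    n_cpgs = np.zeros(n_regions, dtype=np.int64)

    # per-chromosome sorted position arrays for range queries
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    chrom_arr = dataset.sites["chrom"].to_numpy()
    pos_arr = dataset.sites["pos"].to_numpy()
    for chrom in ds_chroms:
        idx = np.nonzero(chrom_arr == chrom)[0]
        by_chrom[chrom] = (pos_arr[idx], idx)  # pos already sorted within chrom

    beta = dataset.beta
    cov = dataset.coverage
    triples = list(zip(reg["chrom"].to_numpy(), reg["start"].to_numpy(), reg["end"].to_numpy()))
    for r, (chrom, start, end) in enumerate(triples):
        start, end = int(start), int(end)
        if chrom not in by_chrom:
            continue
        pos, idx = by_chrom[chrom]
        lo = np.searchsorted(pos, start + 1, side="left")  # p >= start+1 <=> p-1 >= start
        hi = np.searchsorted(pos, end, side="right")  # p <= end <=> p-1 < end
        members = idx[lo:hi]
        n_cpgs[r] = members.size
        if members.size == 0 or members.size < min_cpgs:
            continue
        b = beta[members]
        obs = ~np.isnan(b)
        if mode == "mean":
            cnt = obs.sum(axis=0)
            with np.errstate(invalid="ignore"):
                vals = np.where(cnt > 0, np.nansum(b, axis=0) / np.maximum(cnt, 1), np.nan)
        else:
            w = cov[members]
            ok = obs & ~np.isnan(w)
            wsum = np.where(ok, w, 0.0).sum(axis=0)
            num = np.where(ok, w * np.where(obs, b, 0.0), 0.0).sum(axis=0)
            with np.errstate(invalid="ignore"):
                vals = np.where(wsum > 0, num / np.maximum(wsum, 1e-300), np.nan)
        meth[r] = vals
    # enforce the min_cpgs all-missing contract
    meth[n_cpgs < min_cpgs] = np.nan
    return RegionMethylome(
        region_set=region_set,
        samples=dataset.samples,
        meth=meth,
        n_cpgs=n_cpgs,
        mode=mode,
    )


def default_min_cpgs(platform: str) -> int:
    """Sequencing platforms default to 3 member CpGs per region (sparse
    RRBS coverage makes 1-2 CpG regions unstable); arrays to 1."""
    return 3 if platform in ("wgbs", "rrbs") else 1
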