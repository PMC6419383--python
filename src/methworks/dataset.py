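"""Methylation dataset model and file ingestion.

The central container is :class:`MethylationDataset`: a site table
(one row per CpG, keyed ``chrom:pos:strand``), a sample sheet, and two
aligned sites x samples matrices — ``beta`` (methylation level in [0,1],
NaN = missing) and ``coverage`` (read counts; ``None`` for array-derived
data that has no notion of sequencing depth).

Supported on-disk formats: Bismark coverage files (``.cov``/``.cov.gz``),
bedGraph, tabular beta matrices (TSV/CSV), and TSV sample sheets.
Coordinates are 1-based cytosine positions internally; bedGraph export
uses 0-based half-open intervals.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

#: strings recognised as missing in tabular input (configurable per call)
MISSING_TOKENS = ("NA", "NaN", "nan", "")

SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})

SITE_COLUMNS = ["chrom", "pos", "strand", "is_snp", "is_snp_probe"]


def site_ids(chrom, pos, strand) -> pd.Index:
    """Stable site key ``chrom:pos:strand``."""
    c = pd.Series(chrom).astype(str)
    p = pd.Series(pos).astype(int).astype(str)
    s = pd.Series(strand).astype(str)
    return pd.Index(c.values + ":" + p.values + ":" + s.values)


def make_site_table(chrom, pos, strand="*", is_snp=False, is_snp_probe=False) -> pd.DataFrame:
    """Build a validated, (chrom, pos)-sorted CpG site table."""
    n = len(pos)
    df = pd.DataFrame(
        {
            "chrom": pd.Series(chrom, dtype=str) if not np.isscalar(chrom) else np.repeat(chrom, n),
            "pos": np.asarray(pos, dtype=np.int64),
            "strand": np.repeat(strand, n) if np.isscalar(strand) else pd.Series(strand, dtype=str),
            "is_snp": np.repeat(is_snp, n) if np.isscalar(is_snp) else np.asarray(is_snp, bool),
            "is_snp_probe": (
                np.repeat(is_snp_probe, n) if np.isscalar(is_snp_probe) else np.asarray(is_snp_probe, bool)
            ),
        }
    )
    if (df["pos"] < 1).any():
        bad = int(df.index[df["pos"] < 1][0])
        raise DataError(f"site position < 1 at input row {bad}")
    bad_strand = ~df["strand"].isin(["+", "-", "*"])
    if bad_strand.any():
        raise DataError(f"invalid strand value {df.loc[bad_strand, 'strand'].iloc[0]!r}")
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    df.index = site_ids(df["chrom"], df["pos"], df["strand"])
    df.index.name = "site_id"
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise DataError(f"duplicate site key {dup!r}")
    return df


@dataclass
class MethylationDataset:
    """Per-CpG methylation levels and read coverage for a sample cohort.

    Attributes
    ----------
    sites:
        DataFrame indexed by ``site_id`` with columns chrom, pos, strand,
        is_snp, is_snp_probe; sorted by (chrom, pos).
    samples:
        Sample sheet indexed by ``sample_id``; arbitrary annotation columns.
        ``samples.attrs['column_types']`` records the declared/inferred type
        of every annotation column ('numeric' or 'categorical').
    beta:
        float64 matrix, sites x samples, values in [0,1] or NaN.
    coverage:
        float64 matrix of non-negative integer counts (NaN = missing), or
        ``None`` for array-derived data.
    platform:
        one of wgbs, rrbs, array27k, array450k, arrayEPIC, merged, synthetic.
    """

    sites: pd.DataFrame
    samples: pd.DataFrame
    beta: np.ndarray
    coverage: np.ndarray | None = None
    platform: str = "synthetic"

    PLATFORMS = ("wgbs", "rrbs", "array27k", "array450k", "arrayEPIC", "merged", "synthetic")

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=np.float64)
        if self.coverage is not None:
            self.coverage = np.asarray(self.coverage, dtype=np.float64)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.platform not in self.PLATFORMS:
            raise DataError(f"unknown platform {self.platform!r}")
        ns, nk = len(self.sites), len(self.samples)
        if self.beta.shape != (ns, nk):
            raise DataError(f"beta shape {self.beta.shape} != (sites, samples) = ({ns}, {nk})")
        if self.sites.index.has_duplicates:
            raise DataError("duplicate site_id")
        if self.samples.index.has_duplicates:
            raise DataError("duplicate sample_id")
        pos_sorted = self.sites.sort_values(["chrom", "pos"], kind="stable")
        if not (pos_sorted.index == self.sites.index).all():
            raise DataError("site table is not sorted by (chrom, pos)")
        with np.errstate(invalid="ignore"):
            if ((self.beta < 0) | (self.beta > 1)).any():
                raise DataError("beta values outside [0, 1]")
        if self.coverage is not None:
            if self.coverage.shape != self.beta.shape:
                raise DataError("coverage shape differs from beta shape")
            with np.errstate(invalid="ignore"):
                if (self.coverage < 0).any():
                    raise DataError("negative coverage")
                obs = ~np.isnan(self.coverage)
                if not np.allclose(self.coverage[obs], np.round(self.coverage[obs])):
                    raise DataError("non-integer coverage")
                zero_cov_with_beta = (self.coverage == 0) & ~np.isnan(self.beta)
            if zero_cov_with_beta.any():
                raise DataError("beta present at a zero-coverage cell")

    # -- conveniences -----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def site_ids(self) -> pd.Index:
        return self.sites.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.samples.index

    def beta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.beta, index=self.sites.index, columns=self.samples.index)

    def subset_sites(self, mask_or_ids) -> "MethylationDataset":
        """Restrict to a boolean mask / list of site_ids, preserving order."""
        if isinstance(mask_or_ids, (pd.Index, list)):
            keep = self.sites.index.isin(mask_or_ids)
        else:
            keep = np.asarray(mask_or_ids, bool)
        return MethylationDataset(
            sites=self.sites.loc[keep].copy(),
            samples=self.samples.copy(),
            beta=self.beta[keep].copy(),
            coverage=None if self.coverage is None else self.coverage[keep].copy(),
            platform=self.platform,
        )

    def copy(self) -> "MethylationDataset":
        return MethylationDataset(
            sites=self.sites.copy(),
            samples=self.samples.copy(),
            beta=self.beta.copy(),
            coverage=None if self.coverage is None else self.coverage.copy(),
            platform=self.platform,
        )


# ---------------------------------------------------------------------------
# Bismark coverage / bedGraph ingestion
# ---------------------------------------------------------------------------

def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_bismark_cov(path, sample_id: str | None = None) -> pd.DataFrame:
    """Read one Bismark coverage file into per-site records.

    Expected columns: chrom, start, end, methylation percentage,
    count_methylated, count_unmethylated; tab-separated, 1-based with
    start == end for CpGs. Beta is recomputed from the counts
    (``meth / (meth + unmeth)``); the percentage column is only used as a
    consistency check and a warning is raised when it disagrees with the
    recomputed value by more than 0.5 percentage points. Zero-coverage
    rows yield missing beta.

    Returns a DataFrame with columns chrom, pos, strand, beta, coverage.
    """
    try:
        raw = pd.read_csv(
            path, sep="\t", header=None, comment=None, dtype=str,
            names=["chrom", "start", "end", "pct", "n_meth", "n_unmeth"],
        )
    except pd.errors.ParserError as exc:
        raise DataError(f"{path}: malformed coverage file: {exc}") from exc
    if raw.empty:
        raise DataError(f"{path}: empty coverage file")

    def _numeric(col, kind=float):
        try:
            return raw[col].astype(kind)
        except (TypeError, ValueError):
            conv = pd.to_numeric(raw[col], errors="coerce")
            line = int(conv.index[conv.isna()][0]) + 1
            raise DataError(f"{path}: malformed line {line}: bad value in column {col!r}") from None

    start = _numeric("start")
    end = _numeric("end")
    n_meth = _numeric("n_meth")
    n_unmeth = _numeric("n_unmeth")
    pct = _numeric("pct")
    for name, col in (("start", start), ("end", end)):
        if col.isna().any():
            line = int(col.index[col.isna()][0]) + 1
            raise DataError(f"{path}: malformed line {line}: missing {name}")
    if (n_meth < 0).any() or (n_unmeth < 0).any():
        bad = ((n_meth < 0) | (n_unmeth < 0))
        line = int(bad.index[bad][0]) + 1
        raise DataError(f"{path}: malformed line {line}: negative count")

    coverage = (n_meth + n_unmeth).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(coverage > 0, n_meth.to_numpy() / np.where(coverage > 0, coverage, 1), np.nan)
    # counts win over the percentage column; warn on material disagreement
    with np.errstate(invalid="ignore"):
        disagree = np.abs(beta * 100.0 - pct.to_numpy()) > 0.5
    disagree &= coverage > 0
    if disagree.any():
        line = int(np.nonzero(disagree)[0][0]) + 1
        warnings.warn(
            f"{path}: line {line}: percentage column disagrees with counts by "
            ">0.5 percentage points; recomputed beta from counts is used",
            stacklevel=2,
        )
    rec = pd.DataFrame(
        {
            "chrom": raw["chrom"].astype(str),
            "pos": start.astype(np.int64),
            "strand": "*",
            "beta": beta,
            "coverage": coverage,
        }
    )
    if sample_id is not None:
        rec.attrs["sample_id"] = sample_id
    return rec


def read_bedgraph(path, sample_id: str | None = None) -> pd.DataFrame:
    """Read a bedGraph of per-CpG betas (0-based half-open) into records."""
    raw = pd.read_csv(
        path, sep="\t", header=None, dtype=str,
        names=["chrom", "start", "end", "value"],
        comment="#",
    )
    raw = raw[~raw["chrom"].str.startswith(("track", "browser"))]
    if raw.empty:
        raise DataError(f"{path}: empty bedGraph")
    start = pd.to_numeric(raw["start"], errors="coerce")
    try:
        # float() parsing is correctly rounded, keeping re-import lossless
        value = raw["value"].map(float)
    except (TypeError, ValueError):
        value = pd.to_numeric(raw["value"], errors="coerce")
    if start.isna().any():
        line = int(start.index[start.isna()][0]) + 1
        raise DataError(f"{path}: malformed line {line}")
    if ((value < 0) | (value > 1)).any():
        line = int(value.index[(value < 0) | (value > 1)][0]) + 1
        raise DataError(f"{path}: line {line}: beta outside [0, 1]")
    rec = pd.DataFrame(
        {
            "chrom": raw["chrom"].astype(str),
            "pos": start.astype(np.int64) + 1,  # back to 1-based cytosine
            "strand": "*",
            "beta": value.to_numpy(),
            "coverage": np.nan,
        }
    )
    if sample_id is not None:
        rec.attrs["sample_id"] = sample_id
    return rec


def merge_strand_records(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse a −strand record at pos p+1 onto the +strand CpG at pos p.

    Counts are summed and beta recomputed; only meaningful for
    strand-resolved sequencing input. Records on '*' strand pass through.
    """
    rec = records.copy()
    minus = rec["strand"] == "-"
    if not minus.any():
        return rec
    rec.loc[minus, "pos"] = rec.loc[minus, "pos"] - 1
    rec.loc[minus, "strand"] = "+"
    cov = rec["coverage"].fillna(0.0)
    meth = (rec["beta"].fillna(0.0) * cov).to_numpy()
    rec = rec.assign(_meth=meth, _cov=cov.to_numpy())
    agg = rec.groupby(["chrom", "pos"], as_index=False).agg(
        strand=("strand", "first"), _meth=("_meth", "sum"), _cov=("_cov", "sum")
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(agg["_cov"] > 0, agg["_meth"] / agg["_cov"].where(agg["_cov"] > 0, 1), np.nan)
    return pd.DataFrame(
        {
            "chrom": agg["chrom"],
            "pos": agg["pos"].astype(np.int64),
            "strand": agg["strand"],
            "beta": beta,
            "coverage": agg["_cov"].to_numpy(),
        }
    )


def dataset_from_records(
    records: dict[str, pd.DataFrame],
    samples: pd.DataFrame | None = None,
    platform: str = "rrbs",
    merge_strands: bool = False,
) -> MethylationDataset:
    """Assemble per-sample site records (from :func:`read_bismark_cov` /
    :func:`read_bedgraph`) into one dataset over the union of sites."""
    if not records:
        raise DataError("no sample records given")
    if merge_strands:
        records = {sid: merge_strand_records(r) for sid, r in records.items()}
    keyed = {}
    for sid, rec in records.items():
        r = rec.set_index(site_ids(rec["chrom"], rec["pos"], rec["strand"]))
        if r.index.has_duplicates:
            dup = r.index[r.index.duplicated()][0]
            raise DataError(f"sample {sid!r}: duplicate site {dup!r}")
        keyed[sid] = r
    all_sites = pd.concat(
        [r[["chrom", "pos", "strand"]] for r in keyed.values()]
    ).groupby(level=0).first()
    sites = make_site_table(all_sites["chrom"], all_sites["pos"], all_sites["strand"])
    sample_order = list(records)
    beta = np.full((len(sites), len(sample_order)), np.nan)
    coverage = np.full_like(beta, np.nan)
    for j, sid in enumerate(sample_order):
        r = keyed[sid].reindex(sites.index)
        beta[:, j] = r["beta"].to_numpy()
        coverage[:, j] = r["coverage"].to_numpy()
    has_cov = ~np.isnan(coverage)
    beta[(coverage == 0) & ~np.isnan(beta)] = np.nan
    if samples is None:
        samples = pd.DataFrame(index=pd.Index(sample_order, name="sample_id"))
    else:
        missing = [s for s in sample_order if s not in samples.index]
        if missing:
            raise DataError(f"samples absent from sample sheet: {missing}")
        samples = samples.loc[sample_order]
    return MethylationDataset(
        sites=sites,
        samples=samples,
        beta=beta,
        coverage=coverage if has_cov.any() else None,
        platform=platform,
    )


# ---------------------------------------------------------------------------
# Tabular beta matrices and sample sheets
# ---------------------------------------------------------------------------

def read_beta_table(
    path,
    platform: str = "array450k",
    missing_tokens=MISSING_TOKENS,
    sep: str | None = None,
) -> MethylationDataset:
    """Read a sites x samples beta matrix with coordinate key columns.

    The first columns must identify sites — either (chrom, pos[, strand])
    or a single ``site_id`` column of the form ``chrom:pos:strand``. All
    remaining columns are samples. Values must be in [0,1] or one of the
    missing tokens; anything else is rejected with its row and column.
    """
    sep = sep if sep is not None else ("," if str(path).endswith(".csv") else "\t")
    raw = pd.read_csv(path, sep=sep, dtype=str)
    cols = [c.lower() for c in raw.columns]
    if "chrom" in cols and "pos" in cols:
        chrom = raw.iloc[:, cols.index("chrom")].astype(str)
        pos = pd.to_numeric(raw.iloc[:, cols.index("pos")]).astype(np.int64)
        strand = (
            raw.iloc[:, cols.index("strand")].astype(str) if "strand" in cols
            else pd.Series(["*"] * len(raw))
        )
        key_cols = {raw.columns[cols.index(c)] for c in ("chrom", "pos", "strand") if c in cols}
    elif "site_id" in cols:
        parts = raw.iloc[:, cols.index("site_id")].str.rsplit(":", n=2, expand=True)
        if parts.shape[1] != 3:
            raise DataError(f"{path}: site_id values must look like chrom:pos:strand")
        chrom, pos, strand = parts[0], pd.to_numeric(parts[1]).astype(np.int64), parts[2]
        key_cols = {raw.columns[cols.index("site_id")]}
    else:
        raise DataError(f"{path}: need (chrom, pos) columns or a site_id column")

    sample_cols = [c for c in raw.columns if c not in key_cols]
    if not sample_cols:
        raise DataError(f"{path}: no sample columns")
    vals = raw[sample_cols].copy()
    for tok in missing_tokens:
        vals = vals.replace(tok, np.nan)
    try:
        mat = vals.astype(float).to_numpy()
    except (TypeError, ValueError):
        for col in sample_cols:
            conv = pd.to_numeric(vals[col], errors="coerce")
            bad = conv.isna() & vals[col].notna()
            if bad.any():
                row = int(bad.index[bad][0])
                raise DataError(
                    f"{path}: non-numeric value {vals[col][row]!r} at row {row + 2}, column {col!r}"
                ) from None
        raise
    with np.errstate(invalid="ignore"):
        out_of_range = (mat < 0) | (mat > 1)
    if out_of_range.any():
        i, j = np.argwhere(out_of_range)[0]
        raise DataError(
            f"{path}: beta value {mat[i, j]} outside [0, 1] at row {i + 2}, column {sample_cols[j]!r}"
        )
    sites = make_site_table(chrom, pos, strand)
    order = site_ids(chrom, pos, strand)
    mat = pd.DataFrame(mat, index=order).loc[sites.index].to_numpy()
    samples = pd.DataFrame(index=pd.Index(sample_cols, name="sample_id"))
    return MethylationDataset(sites=sites, samples=samples, beta=mat, coverage=None, platform=platform)


def read_sample_sheet(path, sep: str | None = None, missing_tokens=MISSING_TOKENS) -> pd.DataFrame:
    """Read a delimited sample sheet; first column (or ``sample_id``) keys it.

    A column is typed numeric iff every non-missing entry parses as a
    number; otherwise categorical. The inferred type of each column is
    recorded in ``sheet.attrs['column_types']``.
    """
    sep = sep if sep is not None else ("," if str(path).endswith(".csv") else "\t")
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if raw.empty or raw.shape[1] == 0:
        raise DataError(f"{path}: empty sample sheet")
    id_col = "sample_id" if "sample_id" in raw.columns else raw.columns[0]
    sheet = raw.set_index(raw[id_col].astype(str)).drop(columns=[id_col])
    sheet.index.name = "sample_id"
    if sheet.index.has_duplicates:
        dup = sheet.index[sheet.index.duplicated()][0]
        raise DataError(f"{path}: duplicate sample_id {dup!r}")
    for tok in missing_tokens:
        sheet = sheet.replace(tok, np.nan)
    types: dict[str, str] = {}
    for col in sheet.columns:
        conv = pd.to_numeric(sheet[col], errors="coerce")
        nonmissing = sheet[col].notna()
        if nonmissing.any() and bool((conv.notna() | ~nonmissing).all()):
            sheet[col] = conv
            types[col] = "numeric"
        else:
            types[col] = "categorical"
    sheet.attrs["column_types"] = types
    return sheet


def infer_column_types(sheet: pd.DataFrame) -> dict[str, str]:
    """Numeric iff the pandas dtype is numeric; recorded, never silent."""
    types = dict(sheet.attrs.get("column_types", {}))
    for col in sheet.columns:
        if col not in types:
            types[col] = "numeric" if pd.api.types.is_numeric_dtype(sheet[col]) else "categorical"
    return types


# ---------------------------------------------------------------------------
# Cross-platform merge
# ---------------------------------------------------------------------------

def _merge_keys(sites: pd.DataFrame) -> pd.Index:
    # strand '*' is treated as '+' for cross-platform identity
    strand = sites["strand"].replace("*", "+")
    return site_ids(sites["chrom"], sites["pos"], strand)


def merge_datasets(datasets: list[MethylationDataset], mode: str = "intersect") -> MethylationDataset:
    """Merge >=2 datasets on shared CpGs (keyed by chrom, pos, strand; '*'
    matches '+'). ``intersect`` keeps sites present in every input;
    ``union`` keeps all sites, missing where absent. Beta values are copied
    unchanged from their source; a ``source_platform`` sample annotation
    records provenance."""
    if len(datasets) < 2:
        raise DataError("merge needs at least two datasets")
    if mode not in ("intersect", "union"):
        raise DataError(f"unknown merge mode {mode!r}")
    all_samples = [sid for ds in datasets for sid in ds.sample_ids]
    if len(set(all_samples)) != len(all_samples):
        seen, dup = set(), None
        for s in all_samples:
            if s in seen:
                dup = s
                break
            seen.add(s)
        raise DataError(f"sample_id {dup!r} occurs in more than one dataset")

    keys = [_merge_keys(ds.sites) for ds in datasets]
    if mode == "intersect":
        shared = keys[0]
        for k in keys[1:]:
            shared = shared.intersection(k)
        if len(shared) == 0:
            counts = ", ".join(f"input {i}: {len(k)} sites" for i, k in enumerate(keys))
            raise DataError(f"empty site intersection across inputs ({counts})")
        merged_keys = shared
    else:
        merged_keys = keys[0]
        for k in keys[1:]:
            merged_keys = merged_keys.union(k)

    parts = merged_keys.to_series().str.rsplit(":", n=2, expand=True)
    sites = make_site_table(
        parts[0].to_numpy(), parts[1].astype(np.int64).to_numpy(), parts[2].to_numpy()
    )
    n, m = len(sites), len(all_samples)
    beta = np.full((n, m), np.nan)
    coverage = np.full((n, m), np.nan)
    any_cov = False
    sample_frames = []
    col = 0
    for ds, k in zip(datasets, keys):
        idx = pd.Index(k)
        take = sites.index.get_indexer(idx)  # merged '*'->'+' keys align exactly
        present = take >= 0
        for j in range(ds.n_samples):
            beta[take[present], col] = ds.beta[present, j]
            if ds.coverage is not None:
                coverage[take[present], col] = ds.coverage[present, j]
                any_cov = True
            col += 1
        sf = ds.samples.copy()
        sf["source_platform"] = ds.platform
        sample_frames.append(sf)
    samples = pd.concat(sample_frames)
    samples.index.name = "sample_id"
    return MethylationDataset(
        sites=sites,
        samples=samples,
        beta=beta,
        coverage=coverage if any_cov else None,
        platform="merged",
    )


# ---------------------------------------------------------------------------
# Export and on-disk serialization
# ---------------------------------------------------------------------------

def export_tracks(dataset: MethylationDataset, outdir, fmt: str = "bedGraph") -> list[Path]:
    """Write one bedGraph per sample: 0-based half-open ``[pos-1, pos)``
    with the beta value; missing sites omitted; sorted by (chrom, pos).

    Beta values are printed with ``repr`` so re-import is lossless.
    """
    if fmt != "bedGraph":
        raise DataError(f"unsupported track format {fmt!r}")
    if dataset.n_sites == 0 or dataset.n_samples == 0:
        raise DataError("cannot export an empty dataset")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    chroms = dataset.sites["chrom"].to_numpy()
    pos = dataset.sites["pos"].to_numpy()
    for j, sid in enumerate(dataset.sample_ids):
        path = outdir / f"{sid}.bedGraph"
        b = dataset.beta[:, j]
        keep = ~np.isnan(b)
        with open(path, "w") as fh:
            for c, p, v in zip(chroms[keep], pos[keep], b[keep]):
                fh.write(f"{c}\t{p - 1}\t{p}\t{float(v)!r}\n")
        written.append(path)
    return written


def save_dataset(dataset: MethylationDataset, outdir) -> Path:
    """Serialize a dataset to a directory: sites.tsv, samples.tsv,
    beta.tsv (+ coverage.tsv), platform.txt. All text; floats printed with
    ``repr`` so the round-trip is exact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.sites.to_csv(outdir / "sites.tsv", sep="\t")
    dataset.samples.to_csv(outdir / "samples.tsv", sep="\t")
    _write_matrix(outdir / "beta.tsv", dataset.beta, dataset.sites.index, dataset.sample_ids)
    if dataset.coverage is not None:
        _write_matrix(outdir / "coverage.tsv", dataset.coverage, dataset.sites.index, dataset.sample_ids)
    (outdir / "platform.txt").write_text(dataset.platform + "\n")
    return outdir


def _write_matrix(path, mat, index, columns):
    with open(path, "w") as fh:
        fh.write("site_id\t" + "\t".join(map(str, columns)) + "\n")
        for i, sid in enumerate(index):
            row = "\t".join("NA" if np.isnan(v) else repr(float(v)) for v in mat[i])
            fh.write(f"{sid}\t{row}\n")


def load_dataset(indir) -> MethylationDataset:
    """Inverse of :func:`save_dataset`."""
    indir = Path(indir)
    sites = pd.read_csv(indir / "sites.tsv", sep="\t", index_col=0)
    sites["chrom"] = sites["chrom"].astype(str)
    samples = pd.read_csv(indir / "samples.tsv", sep="\t", index_col=0)
    samples.index = samples.index.astype(str)
    beta = pd.read_csv(
        indir / "beta.tsv", sep="\t", index_col=0, na_values=["NA"],
        float_precision="round_trip",
    ).to_numpy(float)
    cov_path = indir / "coverage.tsv"
    coverage = (
        pd.read_csv(
            cov_path, sep="\t", index_col=0, na_values=["NA"], float_precision="round_trip"
        ).to_numpy(float)
        if cov_path.exists() else None
    )
    platform = (indir / "platform.txt").read_text().strip()
    samples.attrs["column_types"] = infer_column_types(samples)
    return MethylationDataset(sites=sites, samples=samples, beta=beta, coverage=coverage, platform=platform)
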