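"""Site filtering, coverage masking, and missing-value imputation.

The coverage filter implements the sequencing QC rule "keep a CpG if it is
covered by at least ``min_coverage`` reads in more than ``min_fraction_covered``
of the samples": the depth comparison is non-strict (>=, "at least") and the
sample-fraction comparison is strict (>, "more than").

Imputation strategies: sample-wise mean/median, CpG-wise mean/median,
random replacement from the observed values of the same CpG, and k-nearest
neighbour imputation over site rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataset import SEX_CHROMOSOMES, MethylationDataset
from .errors import DataError

logger = logging.getLogger(__name__)

STRATEGIES = ("sample_mean", "sample_median", "cpg_mean", "cpg_median", "random", "knn")


@dataclass
class FilterReport:
    """Per-rule accounting of removed sites/samples, in application order."""

    n_sites_in: int
    n_samples_in: int
    stages: list[dict] = field(default_factory=list)

    def add(self, rule: str, sites_removed: int, sites_after: int, note: str = ""):
        self.stages.append(
            {
                "rule": rule,
                "sites_removed": int(sites_removed),
                "sites_after": int(sites_after),
                "note": note,
            }
        )

    @property
    def n_sites_retained(self) -> int:
        return self.stages[-1]["sites_after"] if self.stages else self.n_sites_in

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.stages)

    def check(self) -> None:
        before = self.n_sites_in
        for st in self.stages:
            if st["sites_removed"] + st["sites_after"] != before:
                raise AssertionError("filter report stage does not balance")
            before = st["sites_after"]


def filter_sites(
    dataset: MethylationDataset,
    remove_sex_chromosomes: bool = False,
    remove_snp_sites: bool = False,
    min_coverage: int | None = None,
    min_fraction_covered: float | None = None,
) -> tuple[MethylationDataset, FilterReport]:
    """Apply site filters in fixed order: annotation rules first (sex
    chromosomes, SNP-overlapping sites), then the coverage rule.

    A site passes the coverage rule iff strictly more than
    ``min_fraction_covered`` of the samples have coverage >= ``min_coverage``.
    The rule is applied only when both parameters are set; on array-derived
    data (no coverage matrix) it is skipped with a logged notice.
    Site order is preserved. Raises if nothing survives.
    """
    if min_fraction_covered is not None and not (0.0 <= min_fraction_covered <= 1.0):
        raise DataError("min_fraction_covered must be in [0, 1]")
    report = FilterReport(dataset.n_sites, dataset.n_samples)
    keep = np.ones(dataset.n_sites, dtype=bool)

    if remove_sex_chromosomes:
        on_sex = dataset.sites["chrom"].isin(SEX_CHROMOSOMES).to_numpy()
        removed = int((keep & on_sex).sum())
        keep &= ~on_sex
        report.add("remove_sex_chromosomes", removed, int(keep.sum()))
    if remove_snp_sites:
        snp = dataset.sites["is_snp"].to_numpy(bool)
        removed = int((keep & snp).sum())
        keep &= ~snp
        report.add("remove_snp_sites", removed, int(keep.sum()))
    if min_coverage is not None and min_fraction_covered is not None:
        if dataset.coverage is None:
            logger.info("coverage rule skipped: dataset has no coverage matrix")
            report.add("min_coverage", 0, int(keep.sum()), note="skipped: no coverage matrix")
        else:
            with np.errstate(invalid="ignore"):
                covered = dataset.coverage >= min_coverage  # NaN compares False
            frac = covered.mean(axis=1)
            ok = frac > min_fraction_covered  # strict: "more than"
            removed = int((keep & ~ok).sum())
            keep &= ok
            report.add(
                f"coverage>={min_coverage} in >{min_fraction_covered:.0%} samples",
                removed,
                int(keep.sum()),
            )
    report.check()
    if not keep.any():
        err = DataError("all sites removed by filtering")
        err.report = report
        raise err
    return dataset.subset_sites(keep), report


def mask_low_coverage(dataset: MethylationDataset, min_coverage: int) -> MethylationDataset:
    """Set beta to missing wherever cell coverage < ``min_coverage``.

    Coverage itself is unchanged; cells with missing coverage are untouched.
    """
    if min_coverage < 1:
        raise DataError("min_coverage must be >= 1")
    out = dataset.copy()
    if out.coverage is None:
        return out
    with np.errstate(invalid="ignore"):
        out.beta[out.coverage < min_coverage] = np.nan
    return out


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute_matrix(
    beta: np.ndarray,
    strategy: str,
    k: int = 10,
    seed: int | None = None,
) -> np.ndarray:
    """Impute missing entries of a sites x samples beta matrix.

    Non-missing cells are never modified and all imputed values lie in
    [0, 1] (they are means/medians/copies of observed betas).

    knn semantics: rows are CpG sites. The distance between two rows is the
    Euclidean distance over the columns observed in both, scaled by
    1/sqrt(m) where m is the number of shared columns. A missing cell is
    filled with the unweighted mean of the values of the k nearest rows
    that are observed in that column; nearer rows missing the column are
    skipped in favour of the next nearest.
    """
    if strategy not in STRATEGIES:
        raise DataError(f"unknown imputation strategy {strategy!r}")
    X = np.asarray(beta, dtype=float).copy()
    miss = np.isnan(X)
    if not miss.any():
        return X

    if strategy in ("sample_mean", "sample_median"):
        fn = np.nanmean if strategy == "sample_mean" else np.nanmedian
        empty = miss.all(axis=0)
        if empty.any():
            raise DataError(f"sample column {int(np.nonzero(empty)[0][0])} has no observed values")
        fill = fn(X, axis=0)
        idx = np.nonzero(miss)
        X[idx] = fill[idx[1]]
        return X

    if strategy in ("cpg_mean", "cpg_median"):
        fn = np.nanmean if strategy == "cpg_mean" else np.nanmedian
        empty = miss.all(axis=1)
        if empty.any():
            raise DataError(f"site row {int(np.nonzero(empty)[0][0])} has no observed values")
        fill = fn(X, axis=1)
        idx = np.nonzero(miss)
        X[idx] = fill[idx[0]]
        return X

    if strategy == "random":
        if seed is None:
            raise DataError("random imputation requires an explicit seed")
        empty = miss.all(axis=1)
        if empty.any():
            raise DataError(f"site row {int(np.nonzero(empty)[0][0])} has no observed values")
        rng = np.random.default_rng(seed)
        for i in np.nonzero(miss.any(axis=1))[0]:
            observed = X[i, ~miss[i]]
            X[i, miss[i]] = rng.choice(observed, size=int(miss[i].sum()), replace=True)
        return X

    # knn
    n = X.shape[0]
    if k < 1:
        raise DataError("k must be >= 1")
    if k >= n:
        raise DataError(f"k = {k} must be smaller than the number of site rows ({n})")
    empty = miss.all(axis=1)
    if empty.any():
        raise DataError(f"site row {int(np.nonzero(empty)[0][0])} has no observed values")
    D = _pairwise_scaled_distances(X, miss)
    obs = ~miss
    for i in np.nonzero(miss.any(axis=1))[0]:
        order = np.argsort(D[i], kind="stable")
        order = order[order != i]
        order = order[np.isfinite(D[i][order])]
        for j in np.nonzero(miss[i])[0]:
            donors = order[obs[order, j]][:k]
            if donors.size == 0:
                raise DataError(f"no donor row observed at column {j} for site row {i}")
            X[i, j] = X[donors, j].mean()
    return X


def _pairwise_scaled_distances(X: np.ndarray, miss: np.ndarray) -> np.ndarray:
    """All-pairs Euclidean distance over pairwise-complete columns, each
    pair's distance scaled by 1/sqrt(shared column count)."""
    M = (~miss).astype(float)
    X0 = np.where(miss, 0.0, X)
    A = X0 * X0
    shared = M @ M.T
    sq = A @ M.T + M @ A.T - 2.0 * (X0 @ X0.T)
    np.clip(sq, 0.0, None, out=sq)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.sqrt(sq) / np.sqrt(shared)
    D[shared == 0] = np.inf
    return D


def impute_missing(
    dataset: MethylationDataset,
    strategy: str = "knn",
    k: int = 10,
    seed: int | None = None,
) -> MethylationDataset:
    """Dataset-level wrapper around :func:`impute_matrix`.

    Note: imputed cells may sit on zero-coverage positions; the coverage
    matrix is therefore dropped to keep the (coverage==0 -> beta missing)
    invariant, which matches downstream use (statistics on betas only).
    """
    out_beta = impute_matrix(dataset.beta, strategy, k=k, seed=seed)
    return MethylationDataset(
        sites=dataset.sites.copy(),
        samples=dataset.samples.copy(),
        beta=out_beta,
        coverage=None,
        platform=dataset.platform,
    )
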