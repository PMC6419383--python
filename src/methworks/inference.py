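"""DNA-methylation-based covariate inference.

Implements five predictors commonly used to recover or sanity-check sample
annotations from methylation data alone:

* **Epigenetic age** — elastic-net regression of chronological age on
  single-CpG beta values, with cross-validated penalty selection. Models
  store only their nonzero coefficients plus the training mean of each
  model CpG, which substitutes for CpGs absent (or missing) at prediction
  time.
* **Sex** — log2 ratios of mean sex-chromosome coverage (or array signal
  intensity) to mean autosomal coverage, fed into a logistic regression.
  Males show reduced chrX signal and clear chrY signal; females the
  opposite.
* **Genetic noise** — mean deviation of autosomal genotyping-probe betas
  from the diploid targets {0, 0.5, 1}; elevated values flag contamination
  or aneuploidy.
* **LUMP purity** — leukocytes are unmethylated at a preselected CpG set,
  so the mean beta there, divided by a scale constant (default 0.85) and
  capped at 1, estimates non-immune (tumor) purity.
* **Cell-type deconvolution** — non-negative least squares of each
  sample's betas onto reference profiles of purified cell populations,
  with the weights constrained to sum to at most (or exactly) one.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.linear_model import ElasticNet

from .dataset import SEX_CHROMOSOMES, MethylationDataset
from .errors import DataError

EPS_COVERAGE = 0.01  # pseudo-count in the sex-feature log ratios


# ---------------------------------------------------------------------------
# Age
# ---------------------------------------------------------------------------

@dataclass
class AgeModel:
    """Serializable elastic-net age predictor (nonzero coefficients only)."""

    intercept: float
    coefficients: pd.Series  # site_id -> years per beta unit
    training_site_means: pd.Series  # site_id -> mean training beta
    alpha: float  # elastic-net mixing (l1_ratio)
    lam: float  # selected penalty strength
    platform: str = "synthetic"
    n_samples: int = 0

    def __post_init__(self):
        if not self.coefficients.index.equals(self.training_site_means.index):
            raise DataError("every coefficient needs a training mean for its site")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#intercept\t{self.intercept!r}\n")
            fh.write(f"#alpha\t{self.alpha!r}\n")
            fh.write(f"#lambda\t{self.lam!r}\n")
            fh.write(f"#platform\t{self.platform}\n")
            fh.write(f"#n_samples\t{self.n_samples}\n")
            fh.write("site_id\tweight\ttraining_mean\n")
            for sid in self.coefficients.index:
                fh.write(
                    f"{sid}\t{float(self.coefficients[sid])!r}\t{float(self.training_site_means[sid])!r}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "AgeModel":
        meta = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, val = line[1:].split("\t", 1)
                    meta[key] = val
                elif line and not line.startswith("site_id"):
                    sid, w, m = line.split("\t")
                    rows.append((sid, float(w), float(m)))
        coef = pd.Series({r[0]: r[1] for r in rows}, dtype=float)
        means = pd.Series({r[0]: r[2] for r in rows}, dtype=float)
        coef.index.name = means.index.name = "site_id"
        return cls(
            intercept=float(meta["intercept"]),
            coefficients=coef,
            training_site_means=means,
            alpha=float(meta["alpha"]),
            lam=float(meta["lambda"]),
            platform=meta.get("platform", "synthetic"),
            n_samples=int(meta.get("n_samples", 0)),
        )


def _fold_of(sample_id: str, cv_folds: int) -> int:
    # hash-based fold assignment: invariant under sample reordering
    digest = hashlib.sha256(str(sample_id).encode()).hexdigest()
    return int(digest, 16) % cv_folds


def train_age_model(
    dataset: MethylationDataset,
    ages=None,
    alpha: float = 0.5,
    lambda_grid=None,
    cv_folds: int = 5,
    seed: int = 0,
) -> AgeModel:
    """Fit an elastic net of age on the beta matrix at single-CpG level.

    The penalty is chosen from ``lambda_grid`` by K-fold cross-validated
    mean squared error; folds are assigned by a hash of each sample_id, so
    the selected penalty and coefficients do not depend on sample order.
    Missing betas must be imputed beforehand.
    """
    if ages is None:
        if "age" not in dataset.samples.columns:
            raise DataError("no ages given and no 'age' column in the sample sheet")
        ages = dataset.samples["age"]
    y = pd.Series(ages).astype(float)
    if len(y) != dataset.n_samples:
        y = y.reindex(dataset.sample_ids)
    y = y.to_numpy()
    known = ~np.isnan(y)
    if known.sum() < 10:
        raise DataError("need at least 10 samples with known age")
    X = dataset.beta.T[known]
    y = y[known]
    if np.isnan(X).any():
        raise DataError("missing betas in training data; run impute_missing first")
    if np.ptp(y) == 0:
        raise DataError("age is constant across training samples")
    if lambda_grid is None:
        lambda_grid = np.logspace(-4, 0, 9)
    lambda_grid = np.asarray(sorted(lambda_grid), dtype=float)

    ids = np.asarray(dataset.sample_ids)[known]
    folds = np.array([_fold_of(s, cv_folds) for s in ids])
    cv_mse = np.full(len(lambda_grid), np.nan)
    for li, lam in enumerate(lambda_grid):
        errs = []
        for f in range(cv_folds):
            tr, te = folds != f, folds == f
            if te.sum() == 0 or tr.sum() < 2:
                continue
            net = ElasticNet(
                alpha=lam, l1_ratio=alpha, max_iter=50_000, tol=1e-6, random_state=seed
            )
            net.fit(X[tr], y[tr])
            pred = net.predict(X[te])
            errs.append(float(np.mean((pred - y[te]) ** 2)))
        cv_mse[li] = float(np.mean(errs)) if errs else np.inf
    best = int(np.nanargmin(cv_mse))
    lam = float(lambda_grid[best])

    net = ElasticNet(alpha=lam, l1_ratio=alpha, max_iter=50_000, tol=1e-6, random_state=seed)
    net.fit(X, y)
    nz = np.nonzero(net.coef_)[0]
    coef = pd.Series(net.coef_[nz], index=dataset.site_ids[nz], name="weight")
    means = pd.Series(X[:, nz].mean(axis=0), index=dataset.site_ids[nz], name="training_mean")
    return AgeModel(
        intercept=float(net.intercept_),
        coefficients=coef,
        training_site_means=means,
        alpha=alpha,
        lam=lam,
        platform=dataset.platform,
        n_samples=int(known.sum()),
    )


def predict_age(
    model: AgeModel, dataset: MethylationDataset, min_overlap: float = 0.5
) -> pd.DataFrame:
    """Predict age: intercept + sum(weight * beta) over model CpGs.

    Model CpGs absent from the dataset — or missing in a given sample —
    are substituted by their stored training mean; the per-sample count of
    substitutions is returned. Errors out when the site overlap fraction
    falls below ``min_overlap``.
    """
    sites = model.coefficients.index
    present = sites.isin(dataset.site_ids)
    overlap = present.mean() if len(sites) else 1.0
    if overlap < min_overlap:
        raise DataError(
            f"only {overlap:.1%} of model CpGs present in the dataset "
            f"(minimum {min_overlap:.0%})"
        )
    n_samples = dataset.n_samples
    values = np.tile(model.training_site_means.to_numpy()[:, None], (1, n_samples))
    substituted = np.tile((~present)[:, None], (1, n_samples))
    if present.any():
        rows = dataset.site_ids.get_indexer(sites[present])
        b = dataset.beta[rows]
        obs = ~np.isnan(b)
        vals = np.where(obs, b, model.training_site_means.to_numpy()[present][:, None])
        values[present.nonzero()[0]] = vals
        substituted[present.nonzero()[0]] = ~obs
    pred = model.intercept + model.coefficients.to_numpy() @ values
    return pd.DataFrame(
        {
            "predicted_age": pred,
            "n_substituted": substituted.sum(axis=0).astype(int),
        },
        index=dataset.sample_ids,
    )


# ---------------------------------------------------------------------------
# Sex
# ---------------------------------------------------------------------------

def sex_features(
    dataset: MethylationDataset,
    intensity: np.ndarray | None = None,
    eps: float = EPS_COVERAGE,
) -> pd.DataFrame:
    """Per-sample (fX, fY) log2 ratios of sex-chromosome signal to autosomes.

    For sequencing data the signal is read coverage; for arrays a per-cell
    mean signal-intensity matrix (sites x samples) must be supplied. Both
    follow fX = log2((mean signal on chrX + eps) / (mean on autosomes + eps)).
    """
    signal = dataset.coverage if dataset.coverage is not None else intensity
    if signal is None:
        raise DataError(
            "sex features need read coverage or (for arrays) a supplied intensity matrix"
        )
    signal = np.asarray(signal, dtype=float)
    chrom = dataset.sites["chrom"].to_numpy()
    on_x = np.isin(chrom, ["chrX", "X"])
    on_y = np.isin(chrom, ["chrY", "Y"])
    on_auto = ~(on_x | on_y)
    if not on_x.any() or not on_y.any():
        raise DataError("dataset has no sex-chromosome (chrX/chrY) sites")
    if not on_auto.any():
        raise DataError("dataset has no autosomal sites")
    with np.errstate(invalid="ignore"):
        mean_auto = np.nanmean(signal[on_auto], axis=0)
        mean_x = np.nanmean(signal[on_x], axis=0)
        mean_y = np.nanmean(signal[on_y], axis=0)
    fx = np.log2((mean_x + eps) / (mean_auto + eps))
    fy = np.log2((mean_y + eps) / (mean_auto + eps))
    return pd.DataFrame({"fX": fx, "fY": fy}, index=dataset.sample_ids)


@dataclass
class SexModel:
    """Logistic regression on (fX, fY); two classes exactly."""

    intercept: float
    weight_fX: float
    weight_fY: float
    classes: tuple[str, str]  # (negative, positive) w.r.t. the logit
    feature_kind: str = "sequencing-coverage"

    def probabilities(self, features: pd.DataFrame) -> pd.DataFrame:
        logit = (
            self.intercept
            + self.weight_fX * features["fX"].to_numpy()
            + self.weight_fY * features["fY"].to_numpy()
        )
        p1 = 1.0 / (1.0 + np.exp(-logit))
        return pd.DataFrame(
            {self.classes[0]: 1.0 - p1, self.classes[1]: p1}, index=features.index
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#feature_kind\t{self.feature_kind}\n")
            fh.write(f"#classes\t{self.classes[0]}\t{self.classes[1]}\n")
            fh.write("term\tweight\n")
            fh.write(f"intercept\t{self.intercept!r}\n")
            fh.write(f"fX\t{self.weight_fX!r}\n")
            fh.write(f"fY\t{self.weight_fY!r}\n")

    @classmethod
    def from_tsv(cls, path) -> "SexModel":
        meta, weights = {}, {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if line.startswith("#"):
                    meta[parts[0][1:]] = parts[1:]
                elif parts[0] not in ("term", ""):
                    weights[parts[0]] = float(parts[1])
        return cls(
            intercept=weights["intercept"],
            weight_fX=weights["fX"],
            weight_fY=weights["fY"],
            classes=tuple(meta["classes"]),
            feature_kind=meta.get("feature_kind", ["sequencing-coverage"])[0],
        )


def train_sex_model(features: pd.DataFrame, labels, seed: int = 0) -> SexModel:
    """Logistic regression of known sex on (fX, fY)."""
    from sklearn.linear_model import LogisticRegression

    y = pd.Series(labels)
    if len(y) == len(features) and not y.index.equals(features.index):
        y.index = features.index
    y = y.reindex(features.index)
    keep = y.notna() & ~y.isin(["unknown"])
    y = y[keep].astype(str)
    X = features.loc[keep.index[keep], ["fX", "fY"]].to_numpy()
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise DataError(f"sex model needs exactly two classes in training; got {classes}")
    clf = LogisticRegression(random_state=seed)
    clf.fit(X, (y == classes[1]).astype(int))
    return SexModel(
        intercept=float(clf.intercept_[0]),
        weight_fX=float(clf.coef_[0][0]),
        weight_fY=float(clf.coef_[0][1]),
        classes=(classes[0], classes[1]),
    )


def predict_sex(
    model: SexModel, features: pd.DataFrame, confidence: float = 0.8
) -> pd.DataFrame:
    """Argmax class, or 'unknown' when the winning probability is below
    the confidence threshold."""
    probs = model.probabilities(features)
    best = probs.to_numpy().argmax(axis=1)
    label = np.asarray(model.classes, dtype=object)[best]
    pmax = probs.to_numpy().max(axis=1)
    label = np.where(pmax < confidence, "unknown", label)
    out = probs.copy()
    out["predicted_sex"] = label
    return out


# ---------------------------------------------------------------------------
# Genetic noise, LUMP, deconvolution
# ---------------------------------------------------------------------------

def genetic_noise(dataset: MethylationDataset) -> pd.Series:
    """Mean deviation of autosomal SNP-probe betas from {0, 0.5, 1}.

    Scores lie in [0, 0.25]; 0 is an ideal diploid sample. Missing betas
    are skipped.
    """
    flags = dataset.sites["is_snp_probe"].to_numpy(bool)
    autosomal = ~dataset.sites["chrom"].isin(SEX_CHROMOSOMES).to_numpy()
    use = flags & autosomal
    if not use.any():
        raise DataError("no autosomal SNP-probe sites flagged in the dataset")
    b = dataset.beta[use]
    dev = np.minimum(np.minimum(np.abs(b), np.abs(b - 0.5)), np.abs(b - 1.0))
    with np.errstate(invalid="ignore"):
        score = np.nanmean(dev, axis=0)
    return pd.Series(score, index=dataset.sample_ids, name="genetic_noise")


def lump_purity(
    dataset: MethylationDataset, lump_sites, scale: float = 0.85
) -> pd.DataFrame:
    """Purity from CpGs exclusively unmethylated in leukocytes.

    purity = min(1, mean beta over present LUMP sites / scale);
    immune_fraction = 1 - purity. The number of LUMP sites actually found
    in the dataset is reported alongside.
    """
    lump_sites = pd.Index(lump_sites)
    present = lump_sites[lump_sites.isin(dataset.site_ids)]
    if len(present) == 0:
        raise DataError("none of the LUMP sites are present in the dataset")
    rows = dataset.site_ids.get_indexer(present)
    with np.errstate(invalid="ignore"):
        mean_beta = np.nanmean(dataset.beta[rows], axis=0)
    purity = np.minimum(1.0, mean_beta / scale)
    return pd.DataFrame(
        {
            "purity": purity,
            "immune_fraction": 1.0 - purity,
            "n_lump_sites_used": len(present),
        },
        index=dataset.sample_ids,
    )


@dataclass
class ReferenceProfiles:
    """Mean methylation profiles of purified cell populations."""

    cell_types: list[str]
    profiles: pd.DataFrame  # sites x cell types, betas in [0,1], no missing

    def __post_init__(self):
        if len(self.cell_types) < 2:
            raise DataError("need at least two reference cell types")
        self.profiles = self.profiles[self.cell_types]
        if self.profiles.isna().any().any():
            raise DataError("reference profiles contain missing values")

    def to_tsv(self, path) -> None:
        self.profiles.to_csv(path, sep="\t", index_label="site_id")

    @classmethod
    def from_tsv(cls, path) -> "ReferenceProfiles":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(cell_types=list(df.columns), profiles=df)


def deconvolve_celltypes(
    dataset: MethylationDataset,
    reference: ReferenceProfiles,
    constraint: str = "sum_le_one",
) -> pd.DataFrame:
    """Constrained least squares of sample betas onto reference profiles.

    Per sample, minimises ||b - R w||^2 over the CpGs shared between the
    dataset and the reference, subject to w >= 0 and sum(w) <= 1 (or == 1).
    Returns the per-type weights and the residual norm.
    """
    if constraint not in ("sum_le_one", "sum_eq_one"):
        raise DataError(f"unknown constraint {constraint!r}")
    shared = reference.profiles.index.intersection(dataset.site_ids)
    T = len(reference.cell_types)
    if len(shared) < T:
        raise DataError(
            f"only {len(shared)} CpGs shared with the reference; need at least {T}"
        )
    R = reference.profiles.loc[shared].to_numpy(float)
    # rank check: duplicated reference columns make weights unidentifiable
    for i in range(T):
        for j in range(i + 1, T):
            if np.allclose(R[:, i], R[:, j], atol=1e-12):
                raise DataError(
                    "reference profiles are rank-deficient: cell types "
                    f"{reference.cell_types[i]!r} and {reference.cell_types[j]!r} are identical"
                )
    rows = dataset.site_ids.get_indexer(shared)
    B = dataset.beta[rows]
    if np.isnan(B).any():
        raise DataError("missing betas at shared CpGs; run impute_missing first")

    RtR = R.T @ R
    weights = np.empty((dataset.n_samples, T))
    resid = np.empty(dataset.n_samples)
    ones = np.ones(T)
    for j in range(dataset.n_samples):
        b = B[:, j]
        Rtb = R.T @ b
        fun = lambda w: 0.5 * w @ RtR @ w - Rtb @ w
        jac = lambda w: RtR @ w - Rtb
        if constraint == "sum_eq_one":
            cons = [{"type": "eq", "fun": lambda w: ones @ w - 1.0, "jac": lambda w: ones}]
            x0 = ones / T
        else:
            cons = [{"type": "ineq", "fun": lambda w: 1.0 - ones @ w, "jac": lambda w: -ones}]
            x0 = ones / (2 * T)
        res = optimize.minimize(
            fun,
            x0,
            jac=jac,
            bounds=[(0.0, 1.0)] * T,
            constraints=cons,
            method="SLSQP",
            options={"maxiter": 1000, "ftol": 1e-14},
        )
        w = np.clip(res.x, 0.0, None)
        weights[j] = w
        resid[j] = float(np.linalg.norm(b - R @ w))
    out = pd.DataFrame(weights, index=dataset.sample_ids, columns=reference.cell_types)
    out["residual"] = resid
    return out
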