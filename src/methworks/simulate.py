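"""Synthetic methylation cohorts with known ground truth.

The generator emulates a two-group bisulfite-sequencing (or array) cohort
at single-CpG resolution with planted, recorded effects:

* differentially methylated CpGs in contiguous blocks (mean shift ``delta``
  in group 1), forming known DMRs;
* differentially variable CpGs (variance inflated by ``var_ratio`` in
  group 1), forming known DVRs;
* age-informative CpGs whose realised betas define chronological age
  through a linear rule plus noise;
* sex-linked coverage structure (reduced chrX and present chrY coverage in
  males, the reverse in females);
* LUMP sites whose mean beta tracks a planted tumor-purity value;
* genotyping (SNP) probe sites with betas near {0, 0.5, 1};
* optional cell-type mixture sites built from reference profiles and
  Dirichlet mixing weights.

Per-cell betas are Beta-distributed around the planted means (a Beta(m*k,
(1-m)*k) observation model, so variance ~ m(1-m)/(k+1)); read counts
follow a negative binomial. Everything derives from a single seed, and all
planted truths are returned in ground-truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import MethylationDataset, make_site_table
from .errors import DataError
from .inference import ReferenceProfiles
from .regions import RegionSet

AUTOSOMES = ("chr1", "chr2", "chr3", "chr4", "chr5")
SITE_SPACING = 100  # bp between consecutive synthetic CpGs


@dataclass
class FixtureSpec:
    """Study conditions of a synthetic cohort; defaults describe the
    standard two-group sequencing fixture used throughout the test suite."""

    n_per_group: tuple[int, int] = (20, 20)
    n_sites: int = 5000
    platform: str = "rrbs"
    # planted differential methylation / variability (contiguous blocks)
    n_dmc: int = 100
    dmc_delta: float = 0.3
    n_dvc: int = 100
    dvc_var_ratio: float = 4.0
    sites_per_region: int = 5
    # age signal: (number of causal CpGs, slope in years per beta unit,
    # noise sd in years); age = 20 + slope * mean(causal betas) + noise
    age_signal: tuple[int, float, float] | None = (10, 100.0, 2.0)
    age_baseline: float = 20.0
    # sex structure
    female_fraction: float = 0.5
    n_chrx_sites: int = 60
    n_chry_sites: int = 40
    # purity / quality markers
    n_lump_sites: int = 50
    lump_scale: float = 0.85
    n_snp_probes: int = 20
    snp_noise_sd: float = 0.02
    # cell-type mixtures
    n_celltypes: int = 3
    n_mixture_sites: int = 200
    mixture_noise_sd: float = 0.02
    # observation model
    baseline_kappa: float = 50.0
    mean_coverage: float = 30.0
    coverage_dispersion: float = 10.0
    missing_rate: float = 0.0
    seed: int = 0

    def n_special(self) -> int:
        n_age = self.age_signal[0] if self.age_signal else 0
        return self.n_dmc + self.n_dvc + n_age + self.n_lump_sites + self.n_snp_probes + (
            self.n_mixture_sites if self.n_celltypes >= 2 else 0
        )


def null_spec(n_sites: int = 5000, n_per_group=(20, 20), seed: int = 0) -> FixtureSpec:
    """A fixture with no planted effects: pure baseline autosomal CpGs."""
    return FixtureSpec(
        n_per_group=tuple(n_per_group),
        n_sites=n_sites,
        n_dmc=0,
        n_dvc=0,
        age_signal=None,
        n_chrx_sites=0,
        n_chry_sites=0,
        n_lump_sites=0,
        n_snp_probes=0,
        n_celltypes=0,
        n_mixture_sites=0,
        seed=seed,
    )


@dataclass
class Fixture:
    """A generated cohort plus every planted truth."""

    spec: FixtureSpec
    dataset: MethylationDataset
    truth_sites: pd.DataFrame
    truth_samples: pd.DataFrame
    region_sets: dict[str, RegionSet]
    lump_sites: list[str] = field(default_factory=list)
    reference: ReferenceProfiles | None = None


def _beta_draw(rng, mean, kappa):
    mean = np.clip(mean, 0.02, 0.98)
    return rng.beta(mean * kappa, (1.0 - mean) * kappa)


def _negbin(rng, mean, dispersion, size):
    mean = np.broadcast_to(np.asarray(mean, float), size)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size).astype(float)


def _baseline_means(rng, n):
    # bimodal methylome: mostly-methylated and mostly-unmethylated modes
    lo = rng.beta(3, 9, size=n)
    hi = rng.beta(9, 3, size=n)
    pick = rng.random(n) < 0.45
    return np.clip(np.where(pick, lo, hi), 0.05, 0.95)


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate the cohort described by ``spec`` (deterministic per seed)."""
    if spec.n_special() > spec.n_sites:
        raise DataError(
            f"infeasible spec: {spec.n_special()} planted sites exceed n_sites = {spec.n_sites}"
        )
    for blk, nm in ((spec.n_dmc, "n_dmc"), (spec.n_dvc, "n_dvc")):
        if blk % spec.sites_per_region:
            raise DataError(f"{nm} must be a multiple of sites_per_region")
    rng = np.random.default_rng(spec.seed)
    n0, n1 = spec.n_per_group
    n_samples = n0 + n1
    group = np.array(["g0"] * n0 + ["g1"] * n1)
    sample_ids = [f"{g}_{i:03d}" for g, i in zip(group, list(range(n0)) + list(range(n1)))]
    is_g1 = group == "g1"

    # -- site layout ------------------------------------------------------
    n_auto = spec.n_sites
    n_age = spec.age_signal[0] if spec.age_signal else 0
    n_mix = spec.n_mixture_sites if spec.n_celltypes >= 2 else 0
    roles = np.array(["baseline"] * n_auto, dtype=object)
    cursor = 0
    for count, role in (
        (spec.n_dmc, "dmc"),
        (spec.n_dvc, "dvc"),
        (n_age, "age"),
        (spec.n_lump_sites, "lump"),
        (spec.n_snp_probes, "snp"),
        (n_mix, "mixture"),
    ):
        roles[cursor : cursor + count] = role
        cursor += count

    n_sex = spec.n_chrx_sites + spec.n_chry_sites
    n_total = n_auto + n_sex
    per_chrom = int(np.ceil(n_auto / len(AUTOSOMES)))
    chroms = np.concatenate(
        [
            np.repeat(AUTOSOMES, per_chrom)[:n_auto],
            np.repeat("chrX", spec.n_chrx_sites),
            np.repeat("chrY", spec.n_chry_sites),
        ]
    )
    pos = np.concatenate(
        [
            np.tile(SITE_SPACING * (1 + np.arange(per_chrom)), len(AUTOSOMES))[:n_auto],
            SITE_SPACING * (1 + np.arange(spec.n_chrx_sites)),
            SITE_SPACING * (1 + np.arange(spec.n_chry_sites)),
        ]
    )
    roles = np.concatenate([roles, np.array(["sex"] * n_sex, dtype=object)])

    # -- planted means and dispersions -----------------------------------
    base_mean = _baseline_means(rng, n_total)
    base_mean[roles == "dmc"] = rng.uniform(0.2, 0.6, size=(roles == "dmc").sum())
    base_mean[roles == "dvc"] = rng.uniform(0.3, 0.7, size=(roles == "dvc").sum())
    mean = np.tile(base_mean[:, None], (1, n_samples))
    kappa = np.full((n_total, n_samples), spec.baseline_kappa)

    delta = np.zeros(n_total)
    delta[roles == "dmc"] = spec.dmc_delta
    mean[:, is_g1] += delta[:, None]

    var_ratio = np.ones(n_total)
    var_ratio[roles == "dvc"] = spec.dvc_var_ratio
    kappa_dv = (spec.baseline_kappa + 1.0) / spec.dvc_var_ratio - 1.0
    kappa[np.ix_(roles == "dvc", is_g1)] = kappa_dv

    # age signal
    ages = np.full(n_samples, np.nan)
    if spec.age_signal:
        _, slope, noise_sd = spec.age_signal
        u = rng.uniform(0.2, 0.8, size=n_samples)
        mean[roles == "age"] = u[None, :]
        kappa[roles == "age"] = 200.0

    # purity / LUMP
    purity = rng.uniform(0.3, 1.0, size=n_samples)
    if spec.n_lump_sites:
        mean[roles == "lump"] = (spec.lump_scale * purity)[None, :]
        kappa[roles == "lump"] = 300.0

    # sample betas
    beta = _beta_draw(rng, mean, kappa)

    # SNP probes: discrete diploid genotypes plus tight noise
    if spec.n_snp_probes:
        snp_rows = np.nonzero(roles == "snp")[0]
        geno = rng.choice([0.0, 0.5, 1.0], size=(len(snp_rows), n_samples), p=[0.25, 0.5, 0.25])
        beta[snp_rows] = np.clip(
            geno + rng.normal(0.0, spec.snp_noise_sd, size=geno.shape), 0.0, 1.0
        )

    # cell-type mixtures
    reference = None
    weights = None
    if n_mix:
        mix_rows = np.nonzero(roles == "mixture")[0]
        types = [f"type{k}" for k in range(spec.n_celltypes)]
        R = rng.uniform(0.1, 0.9, size=(len(mix_rows), spec.n_celltypes))
        weights = rng.dirichlet(np.ones(spec.n_celltypes), size=n_samples)
        clean = R @ weights.T
        beta[mix_rows] = np.clip(
            clean + rng.normal(0.0, spec.mixture_noise_sd, size=clean.shape), 0.0, 1.0
        )

    # realised age from causal betas
    if spec.age_signal:
        causal = beta[roles == "age"]
        ages = spec.age_baseline + slope * causal.mean(axis=0) + rng.normal(0, noise_sd, n_samples)

    # -- sex-linked coverage ----------------------------------------------
    sex = np.where(rng.random(n_samples) < spec.female_fraction, "female", "male")
    coverage = None
    if spec.platform in ("wgbs", "rrbs", "synthetic"):
        mu = np.full((n_total, n_samples), spec.mean_coverage)
        male = sex == "male"
        x_rows = chroms == "chrX"
        y_rows = chroms == "chrY"
        mu[np.ix_(x_rows, male)] = spec.mean_coverage / 2.0
        mu[np.ix_(y_rows, male)] = spec.mean_coverage / 2.0
        mu[np.ix_(y_rows, ~male)] = 0.3
        coverage = _negbin(rng, mu, spec.coverage_dispersion, (n_total, n_samples))
        beta[coverage == 0] = np.nan

    if spec.missing_rate > 0:
        drop = rng.random(beta.shape) < spec.missing_rate
        beta[drop] = np.nan

    # -- assemble ----------------------------------------------------------
    sites = make_site_table(chroms, pos, "*", is_snp=False, is_snp_probe=(roles == "snp"))
    # make_site_table sorts by (chrom, pos); realign matrices to that order
    raw_ids = (
        pd.Series(chroms).astype(str) + ":" + pd.Series(pos).astype(str) + ":*"
    ).to_numpy()
    order = pd.Index(raw_ids).get_indexer(sites.index)
    beta = beta[order]
    if coverage is not None:
        coverage = coverage[order]
    roles = roles[order]
    delta = delta[order]
    var_ratio = var_ratio[order]

    samples = pd.DataFrame(
        {"group": group, "sex": sex, "age": ages, "purity": purity},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    samples.attrs["column_types"] = {
        "group": "categorical", "sex": "categorical", "age": "numeric", "purity": "numeric",
    }
    dataset = MethylationDataset(
        sites=sites, samples=samples, beta=beta, coverage=coverage, platform=spec.platform
    )

    truth_sites = pd.DataFrame(
        {"role": roles, "delta": delta, "var_ratio": var_ratio}, index=sites.index
    )
    truth_sites.index.name = "site_id"
    truth_samples = samples.copy()
    if weights is not None:
        for k, t in enumerate(types):
            truth_samples[f"w_{t}"] = weights[:, k]

    region_sets = _planted_region_sets(dataset, truth_sites, spec)
    lump_ids = list(sites.index[roles == "lump"])
    if n_mix:
        # R rows were generated in pre-sort site order; realign to sorted ids
        mix_ids = sites.index[roles == "mixture"]
        reference = ReferenceProfiles(
            cell_types=types,
            profiles=pd.DataFrame(
                R[_mixture_row_order(raw_ids, sites.index, mix_ids)],
                index=pd.Index(mix_ids, name="site_id"),
                columns=types,
            ),
        )
    return Fixture(
        spec=spec,
        dataset=dataset,
        truth_sites=truth_sites,
        truth_samples=truth_samples,
        region_sets=region_sets,
        lump_sites=lump_ids,
        reference=reference,
    )


def _mixture_row_order(raw_ids, sorted_index, mix_ids) -> np.ndarray:
    """Map reference rows (generated in pre-sort site order) onto the
    sorted mixture site ids."""
    raw_pos = {sid: i for i, sid in enumerate(raw_ids)}
    mix_raw = [raw_pos[s] for s in mix_ids]
    mix_rank = {i: k for k, i in enumerate(sorted(set(mix_raw)))}
    return np.array([mix_rank[i] for i in mix_raw], dtype=int)


def _planted_region_sets(dataset, truth_sites, spec) -> dict[str, RegionSet]:
    """BED-style region sets covering the planted DMC/DVC blocks, plus a
    universe tiling every block of ``sites_per_region`` consecutive CpGs."""
    out = {}
    chrom = dataset.sites["chrom"].to_numpy()
    pos = dataset.sites["pos"].to_numpy()
    role = truth_sites["role"].to_numpy()

    def blocks_for(mask):
        rows = []
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            return rows
        run = [idx[0]]
        for i in idx[1:]:
            if i == run[-1] + 1 and chrom[i] == chrom[run[0]]:
                run.append(i)
            else:
                rows.append(run)
                run = [i]
        rows.append(run)
        regions = []
        for run in rows:
            for i in range(0, len(run), spec.sites_per_region):
                blk = run[i : i + spec.sites_per_region]
                regions.append((chrom[blk[0]], int(pos[blk[0]] - 1), int(pos[blk[-1]])))
        return regions

    for role_name, set_name in (("dmc", "planted_dmrs"), ("dvc", "planted_dvrs")):
        regs = blocks_for(role == role_name)
        if regs:
            out[set_name] = RegionSet(
                name=set_name,
                regions=pd.DataFrame(regs, columns=["chrom", "start", "end"]),
                source="generate_fixture",
            )
    # universe: every autosomal block of sites_per_region consecutive CpGs
    auto = ~np.isin(chrom, ["chrX", "chrY"])
    rows = []
    for c in pd.unique(chrom[auto]):
        cpos = pos[chrom == c]
        for i in range(0, len(cpos), spec.sites_per_region):
            blk = cpos[i : i + spec.sites_per_region]
            rows.append((c, int(blk[0] - 1), int(blk[-1])))
    out["blocks"] = RegionSet(
        name="blocks", regions=pd.DataFrame(rows, columns=["chrom", "start", "end"]),
        source="generate_fixture",
    )
    return out


def write_fixture(fixture: Fixture, outdir) -> Path:
    """Serialize a fixture: dataset directory, ground-truth TSVs, BED
    region sets, LUMP site list, reference profiles."""
    from .dataset import save_dataset

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_dataset(fixture.dataset, outdir / "dataset")
    fixture.truth_sites.to_csv(outdir / "truth_sites.tsv", sep="\t")
    fixture.truth_samples.to_csv(outdir / "truth_samples.tsv", sep="\t")
    for name, rs in fixture.region_sets.items():
        rs.to_bed(outdir / f"{name}.bed")
    if fixture.lump_sites:
        (outdir / "lump_sites.txt").write_text("\n".join(fixture.lump_sites) + "\n")
    if fixture.reference is not None:
        fixture.reference.to_tsv(outdir / "reference_profiles.tsv")
    return outdir


# ---------------------------------------------------------------------------
# Focused simulators for individual predictors
# ---------------------------------------------------------------------------

def simulate_sex_feature_cohort(
    n_per_class: int = 100, noise_sd: float = 0.05, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Separable (fX, fY) cohort: males around (-1, -1), females around
    (0, -6), Gaussian feature noise."""
    rng = np.random.default_rng(seed)
    fx = np.concatenate(
        [rng.normal(-1.0, noise_sd, n_per_class), rng.normal(0.0, noise_sd, n_per_class)]
    )
    fy = np.concatenate(
        [rng.normal(-1.0, noise_sd, n_per_class), rng.normal(-6.0, noise_sd, n_per_class)]
    )
    labels = pd.Series(["male"] * n_per_class + ["female"] * n_per_class)
    idx = pd.Index([f"s{i:03d}" for i in range(2 * n_per_class)], name="sample_id")
    features = pd.DataFrame({"fX": fx, "fY": fy}, index=idx)
    labels.index = idx
    return features, labels


def simulate_mixtures(
    n_samples: int = 100,
    n_sites: int = 2000,
    n_celltypes: int = 3,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[MethylationDataset, ReferenceProfiles, pd.DataFrame]:
    """Dirichlet cell-type mixtures over reference profiles.

    Sample betas are clip(R w + Gaussian noise, [0, 1]); returns the
    dataset, the reference, and the true weights.
    """
    rng = np.random.default_rng(seed)
    types = [f"type{k}" for k in range(n_celltypes)]
    sites = make_site_table("chr1", SITE_SPACING * (1 + np.arange(n_sites)), "*")
    R = rng.uniform(0.05, 0.95, size=(n_sites, n_celltypes))
    W = rng.dirichlet(np.ones(n_celltypes), size=n_samples)
    beta = np.clip(R @ W.T + rng.normal(0.0, noise_sd, size=(n_sites, n_samples)), 0.0, 1.0)
    idx = pd.Index([f"mix{i:03d}" for i in range(n_samples)], name="sample_id")
    samples = pd.DataFrame(index=idx)
    ds = MethylationDataset(
        sites=sites, samples=samples, beta=beta, coverage=None, platform="synthetic"
    )
    ref = ReferenceProfiles(
        cell_types=types, profiles=pd.DataFrame(R, index=sites.index, columns=types)
    )
    truth = pd.DataFrame(W, index=idx, columns=types)
    return ds, ref, truth


def simulate_age_cohort(
    n_samples: int = 300,
    n_sites: int = 2000,
    n_causal: int = 10,
    slope: float = 100.0,
    noise_sd: float = 2.0,
    baseline: float = 20.0,
    seed: int = 0,
) -> tuple[MethylationDataset, pd.Series, pd.Index]:
    """Cohort whose age is a linear function of the mean of a few causal
    CpG betas plus Gaussian noise. Returns (dataset, true ages, causal ids)."""
    rng = np.random.default_rng(seed)
    sites = make_site_table("chr1", SITE_SPACING * (1 + np.arange(n_sites)), "*")
    base = _baseline_means(rng, n_sites)
    mean = np.tile(base[:, None], (1, n_samples))
    kappa = np.full((n_sites, n_samples), 50.0)
    causal_rows = np.arange(n_causal)  # positions 1..n_causal are already sorted
    u = rng.uniform(0.2, 0.8, size=n_samples)
    mean[causal_rows] = u[None, :]
    kappa[causal_rows] = 200.0
    beta = _beta_draw(rng, mean, kappa)
    ages = baseline + slope * beta[causal_rows].mean(axis=0) + rng.normal(0, noise_sd, n_samples)
    idx = pd.Index([f"a{i:03d}" for i in range(n_samples)], name="sample_id")
    samples = pd.DataFrame({"age": ages}, index=idx)
    samples.attrs["column_types"] = {"age": "numeric"}
    ds = MethylationDataset(
        sites=sites, samples=samples, beta=beta, coverage=None, platform="synthetic"
    )
    return ds, pd.Series(ages, index=idx, name="age"), sites.index[causal_rows]
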