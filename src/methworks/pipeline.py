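"""End-to-end analysis runs: configuration, stage orchestration, outputs.

A run executes enabled stages in fixed order — import, preprocess,
regions, inference, exploratory, differential, enrichment, report — each
writing its outputs (TSV tables, BED files) and a log line into the run
directory. Optional stages (inference, exploratory, enrichment) record
failures without aborting the run; import and preprocessing failures are
fatal. Given the same configuration and seed, every numeric output is
reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import differential as diff
from . import explore, inference, preprocess, simulate
from .dataset import MethylationDataset, load_dataset, save_dataset
from .errors import DataError, UserError
from .regions import RegionSet, aggregate_regions, default_min_cpgs, load_region_set

STAGE_ORDER = (
    "import", "preprocess", "regions", "inference", "exploratory",
    "differential", "enrichment", "report",
)


@dataclass
class RunConfig:
    """Fully serializable run configuration; the effective config is
    embedded verbatim in the report."""

    seed: int = 0
    resource_profile: str = "medium"  # gates optional extras only, never numerics
    stages: dict = field(
        default_factory=lambda: {s: True for s in STAGE_ORDER}
    )
    # input: either a fixture spec (synthetic run) or explicit paths
    fixture: dict | None = None
    inputs: dict | None = None  # {"dataset_dir": ...} or {"beta_table": ..., "sheet": ...}
    preprocess: dict = field(
        default_factory=lambda: {
            "remove_sex_chromosomes": True,
            "remove_snp_sites": False,
            "min_coverage": 5,
            "min_fraction_covered": 0.5,
            "impute": "knn",
            "knn_k": 5,
        }
    )
    regions: dict = field(
        default_factory=lambda: {"mode": "mean", "min_cpgs": None, "bed_files": {}}
    )
    inference: dict = field(
        default_factory=lambda: {"sex": True, "genetic_noise": True, "lump": True}
    )
    exploratory: dict = field(default_factory=lambda: {"n_components": 6, "alpha": 0.01})
    differential: dict = field(
        default_factory=lambda: {
            "group_column": "group",
            "variability_method": "diffvar",
            "fdr": 0.05,
            "prior": True,
        }
    )
    enrichment: dict = field(default_factory=lambda: {"catalog_dir": None})

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise UserError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise UserError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls()
        for key, val in raw.items():
            default = getattr(cfg, key)
            if isinstance(default, dict) and isinstance(val, dict):
                merged = dict(default)
                merged.update(val)
                setattr(cfg, key, merged)
            else:
                setattr(cfg, key, val)
        return cfg


def _log(run_dir: Path, stage: str, message: str) -> None:
    with open(run_dir / "log.txt", "a") as fh:
        fh.write(f"[{stage}] {message}\n")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute a full run into ``out_dir``; returns the run directory."""
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "log.txt").write_text("")
    config.to_yaml(run_dir / "config.yaml")
    state: dict = {"config": config}

    for stage in STAGE_ORDER:
        if not config.stages.get(stage, True):
            _log(run_dir, stage, "skipped (disabled in config)")
            continue
        fatal = stage in ("import", "preprocess")
        try:
            _STAGES[stage](config, run_dir, state)
            _log(run_dir, stage, "ok")
        except Exception as exc:  # noqa: BLE001 - optional stages must not abort
            if fatal:
                _log(run_dir, stage, f"FATAL: {exc}")
                raise
            _log(run_dir, stage, f"failed (continuing): {exc}")
            state.setdefault("failures", {})[stage] = traceback.format_exc()
    return run_dir


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_import(config: RunConfig, run_dir: Path, state: dict) -> None:
    out = run_dir / "import"
    out.mkdir(exist_ok=True)
    if config.fixture is not None:
        spec_kwargs = dict(config.fixture)
        spec_kwargs.setdefault("seed", config.seed)
        for key in ("n_per_group", "age_signal"):
            if key in spec_kwargs and isinstance(spec_kwargs[key], list):
                spec_kwargs[key] = tuple(spec_kwargs[key])
        spec = simulate.FixtureSpec(**spec_kwargs)
        fixture = simulate.generate_fixture(spec)
        simulate.write_fixture(fixture, out / "fixture")
        state["fixture"] = fixture
        state["dataset"] = fixture.dataset
    elif config.inputs is not None:
        if "dataset_dir" in config.inputs:
            state["dataset"] = load_dataset(config.inputs["dataset_dir"])
        elif "beta_table" in config.inputs:
            from .dataset import read_beta_table, read_sample_sheet

            ds = read_beta_table(config.inputs["beta_table"])
            if config.inputs.get("sheet"):
                sheet = read_sample_sheet(config.inputs["sheet"])
                missing = [s for s in ds.sample_ids if s not in sheet.index]
                if missing:
                    raise DataError(f"samples missing from sheet: {missing}")
                ds = MethylationDataset(
                    sites=ds.sites, samples=sheet.loc[list(ds.sample_ids)],
                    beta=ds.beta, coverage=ds.coverage, platform=ds.platform,
                )
            state["dataset"] = ds
        else:
            raise UserError("inputs must provide dataset_dir or beta_table")
    else:
        raise UserError("config needs either a fixture spec or explicit inputs")
    save_dataset(state["dataset"], out / "dataset")


def _stage_preprocess(config: RunConfig, run_dir: Path, state: dict) -> None:
    out = run_dir / "preprocess"
    out.mkdir(exist_ok=True)
    ds = state["dataset"]
    p = config.preprocess
    state["dataset_raw"] = ds  # pre-filter dataset kept for coverage-based inference
    filtered, report = preprocess.filter_sites(
        ds,
        remove_sex_chromosomes=bool(p.get("remove_sex_chromosomes", False)),
        remove_snp_sites=bool(p.get("remove_snp_sites", False)),
        min_coverage=p.get("min_coverage"),
        min_fraction_covered=p.get("min_fraction_covered"),
    )
    _write_tsv(report.to_frame(), out / "filter_report.tsv")
    strategy = p.get("impute")
    if strategy:
        imputed = preprocess.impute_missing(
            filtered, strategy=strategy, k=int(p.get("knn_k", 5)), seed=config.seed
        )
    else:
        imputed = filtered
    state["dataset_filtered"] = filtered
    state["dataset"] = imputed
    save_dataset(imputed, out / "dataset")


def _stage_regions(config: RunConfig, run_dir: Path, state: dict) -> None:
    out = run_dir / "regions"
    out.mkdir(exist_ok=True)
    ds = state["dataset"]
    sets: dict[str, RegionSet] = {}
    if "fixture" in state:
        sets.update(state["fixture"].region_sets)
    for name, path in (config.regions.get("bed_files") or {}).items():
        sets[name] = load_region_set(path, name=name)
    if not sets:
        _log(run_dir, "regions", "no region sets configured; stage is a no-op")
        return
    min_cpgs = config.regions.get("min_cpgs")
    if min_cpgs is None:
        min_cpgs = default_min_cpgs(ds.platform)
    meths = {}
    for name, rs in sets.items():
        rm = aggregate_regions(ds, rs, mode=config.regions.get("mode", "mean"), min_cpgs=min_cpgs)
        _write_tsv(rm.to_frame(), out / f"{name}.tsv")
        meths[name] = rm
    state["region_sets"] = sets
    state["region_meth"] = meths


def _stage_inference(config: RunConfig, run_dir: Path, state: dict) -> None:
    out = run_dir / "inference"
    out.mkdir(exist_ok=True)
    raw = state.get("dataset_raw", state["dataset"])
    cfg = config.inference
    tables = []
    if cfg.get("sex", True) and raw.coverage is not None:
        feats = inference.sex_features(raw)
        known = raw.samples.get("sex")
        if known is not None and known.astype(str).isin(["male", "female"]).sum() >= 4:
            model = inference.train_sex_model(feats, known, seed=config.seed)
            pred = inference.predict_sex(model, feats)
            model.to_tsv(out / "sex_model.tsv")
            tables.append(feats.join(pred))
        else:
            tables.append(feats)
    if cfg.get("genetic_noise", True) and state["dataset_raw"].sites["is_snp_probe"].any():
        tables.append(inference.genetic_noise(state["dataset_raw"]).to_frame())
    if cfg.get("lump", True) and state.get("fixture") and state["fixture"].lump_sites:
        tables.append(
            inference.lump_purity(
                state["dataset_raw"], state["fixture"].lump_sites,
                scale=state["fixture"].spec.lump_scale,
            )
        )
    if not tables:
        _log(run_dir, "inference", "nothing to infer (no coverage, SNP probes, or LUMP sites)")
        return
    covars = tables[0]
    for t in tables[1:]:
        covars = covars.join(t)
    _write_tsv(covars, out / "covariates.tsv")
    state["covariates"] = covars


def _stage_exploratory(config: RunConfig, run_dir: Path, state: dict) -> None:
    out = run_dir / "exploratory"
    out.mkdir(exist_ok=True)
    ds = state["dataset"]
    coords, explained, ratio = explore.pca_embed(
        ds.beta_frame(), n_components=int(config.exploratory.get("n_components", 6))
    )
    _write_tsv(coords, out / "pca_coords.tsv")
    _write_tsv(
        pd.DataFrame(
            {"explained_variance": explained, "explained_variance_ratio": ratio},
            index=coords.columns,
        ),
        out / "pca_variance.tsv",
    )
    try:
        assoc = explore.associate_components(
            coords, ds.samples, alpha=float(config.exploratory.get("alpha", 0.01))
        )
        _write_tsv(assoc, out / "component_associations.tsv")
        state["associations"] = assoc
    except DataError as exc:
        _log(run_dir, "exploratory", f"association test skipped: {exc}")
    state["pca"] = (coords, explained, ratio)


def _stage_differential(config: RunConfig, run_dir: Path, state: dict) -> None:
    out = run_dir / "differential"
    out.mkdir(exist_ok=True)
    ds = state["dataset"]
    dcfg = config.differential
    comparison = diff.GroupComparison.from_sheet(ds.samples, dcfg.get("group_column", "group"))
    fdr = float(dcfg.get("fdr", 0.05))
    prior = bool(dcfg.get("prior", True))

    dm = diff.differential_methylation(ds.beta_frame(), comparison, prior=prior)
    dv = diff.differential_variability(
        ds.beta_frame(), comparison, method=dcfg.get("variability_method", "diffvar"),
        prior=prior,
    )
    _write_tsv(dm, out / "dm_cpg.tsv")
    _write_tsv(dv, out / "dv_cpg.tsv")
    state["dm_cpg"], state["dv_cpg"] = dm, dv
    state["dm_selected"] = diff.select_units(dm, fdr=fdr)
    state["dv_selected"] = diff.select_units(dv, fdr=fdr)

    for name, rm in (state.get("region_meth") or {}).items():
        vals = pd.DataFrame(rm.meth, index=rm.region_set.keys(), columns=rm.samples.index)
        dmr = diff.differential_methylation(vals, comparison, prior=prior)
        dvr = diff.differential_variability(
            vals, comparison, method=dcfg.get("variability_method", "diffvar"), prior=prior
        )
        _write_tsv(dmr, out / f"dm_region_{name}.tsv")
        _write_tsv(dvr, out / f"dv_region_{name}.tsv")
        state.setdefault("dm_region", {})[name] = dmr
        state.setdefault("dv_region", {})[name] = dvr


def _stage_enrichment(config: RunConfig, run_dir: Path, state: dict) -> None:
    out = run_dir / "enrichment"
    out.mkdir(exist_ok=True)
    sets = state.get("region_sets") or {}
    dm_region = state.get("dm_region") or {}
    universe_name = "blocks" if "blocks" in sets else (next(iter(sets)) if sets else None)
    cat_dir = config.enrichment.get("catalog_dir")
    if universe_name is None and cat_dir is None:
        _log(run_dir, "enrichment", "no universe region set available; stage is a no-op")
        return
    universe = sets[universe_name]
    if cat_dir:
        catalog = explore.load_catalog(cat_dir, universe)
    else:
        entries = [rs for name, rs in sets.items() if name != universe_name]
        if not entries:
            _log(run_dir, "enrichment", "no catalogue entries; stage is a no-op")
            return
        catalog = explore.EnrichmentCatalog(universe=universe, entries=entries)
    if universe_name not in dm_region:
        _log(run_dir, "enrichment", "no region-level differential table for the universe")
        return
    table = dm_region[universe_name]
    fdr = float(config.differential.get("fdr", 0.05))
    selected = diff.select_units(table, fdr=fdr)
    if len(selected) == 0:
        _log(run_dir, "enrichment", "no regions selected at the FDR cutoff")
        return
    reg = universe.regions.copy()
    reg.index = universe.keys()
    query = RegionSet(
        name="selected_dmrs", regions=reg.loc[list(selected)].reset_index(drop=True),
        source="differential",
    )
    query.to_bed(out / "query_regions.bed")
    result = explore.region_enrichment(query, catalog)
    _write_tsv(result, out / "enrichment.tsv")
    state["enrichment"] = result


def _stage_report(config: RunConfig, run_dir: Path, state: dict) -> None:
    from .report import render_report

    render_report(run_dir)


_STAGES = {
    "import": _stage_import,
    "preprocess": _stage_preprocess,
    "regions": _stage_regions,
    "inference": _stage_inference,
    "exploratory": _stage_exploratory,
    "differential": _stage_differential,
    "enrichment": _stage_enrichment,
    "report": _stage_report,
}
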