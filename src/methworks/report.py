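"""Self-contained HTML run reports.

One HTML file per run: a section per executed stage with its result
tables, the verbatim effective configuration, embedded figures (PCA
scatter, group mean/mean and variance/variance scatters with top-ranked
units highlighted, enrichment log-odds bars), and links to the TSV
outputs. Regenerating a report from the same run directory is byte-stable
except for the timestamp field.
"""

from __future__ import annotations

import base64
import html
import io
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def _fig_to_data_uri(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=110, bbox_inches="tight", metadata={"Software": None})
    plt.close(fig)
    return "data:image/png;base64," + base64.b64encode(buf.getvalue()).decode()


def _table_html(df: pd.DataFrame, max_rows: int = 20) -> str:
    shown = df.head(max_rows)
    return shown.to_html(float_format=lambda v: f"{v:.4g}", border=0, classes="tbl")


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def render_report(run_dir, out_name: str = "report.html") -> Path:
    """Render the report for an existing run directory."""
    run_dir = Path(run_dir)
    stage_dirs = [d for d in run_dir.iterdir() if d.is_dir()]
    if not stage_dirs:
        raise DataError(f"{run_dir}: empty run directory, nothing to report")

    parts: list[str] = []
    parts.append("<!DOCTYPE html><html><head><meta charset='utf-8'>")
    parts.append("<title>methworks run report</title><style>")
    parts.append(
        "body{font-family:sans-serif;max-width:1000px;margin:2em auto;padding:0 1em}"
        ".tbl{border-collapse:collapse;font-size:13px}"
        ".tbl td,.tbl th{padding:2px 8px;border-bottom:1px solid #ddd}"
        "pre{background:#f6f6f6;padding:1em;overflow-x:auto}"
        "h2{border-bottom:2px solid #444;padding-bottom:4px}"
        "img{max-width:100%}"
    )
    parts.append("</style></head><body>")
    parts.append("<h1>methworks run report</h1>")
    parts.append(
        f"<p id='timestamp'>generated: {datetime.now(timezone.utc).isoformat(timespec='seconds')}</p>"
    )

    cfg_path = run_dir / "config.yaml"
    if cfg_path.exists():
        parts.append("<h2>Effective configuration</h2>")
        parts.append(f"<pre>{html.escape(cfg_path.read_text())}</pre>")

    log_path = run_dir / "log.txt"
    if log_path.exists():
        # the report stage's own log line lands after rendering; excluding
        # it keeps regeneration byte-stable
        lines = [l for l in log_path.read_text().splitlines() if not l.startswith("[report]")]
        parts.append("<h2>Stage log</h2>")
        parts.append(f"<pre>{html.escape(chr(10).join(lines))}</pre>")

    _section_preprocess(run_dir, parts)
    _section_regions(run_dir, parts)
    _section_inference(run_dir, parts)
    _section_exploratory(run_dir, parts)
    _section_differential(run_dir, parts)
    _section_enrichment(run_dir, parts)

    parts.append("</body></html>")
    out = run_dir / out_name
    out.write_text("\n".join(parts))
    return out


def _link(path: Path, run_dir: Path) -> str:
    rel = path.relative_to(run_dir)
    return f"<p><a href='{rel}'>{rel}</a></p>"


def _section_preprocess(run_dir: Path, parts: list[str]) -> None:
    path = run_dir / "preprocess" / "filter_report.tsv"
    if not path.exists():
        return
    parts.append("<h2>Preprocessing</h2>")
    parts.append(_table_html(_read_tsv(path)))
    parts.append(_link(path, run_dir))


def _section_regions(run_dir: Path, parts: list[str]) -> None:
    rdir = run_dir / "regions"
    if not rdir.is_dir():
        return
    tsvs = sorted(rdir.glob("*.tsv"))
    if not tsvs:
        return
    parts.append("<h2>Region aggregation</h2>")
    for path in tsvs:
        parts.append(f"<h3>{path.stem}</h3>")
        parts.append(_table_html(_read_tsv(path), max_rows=8))
        parts.append(_link(path, run_dir))


def _section_inference(run_dir: Path, parts: list[str]) -> None:
    path = run_dir / "inference" / "covariates.tsv"
    if not path.exists():
        return
    parts.append("<h2>Covariate inference</h2>")
    parts.append(_table_html(_read_tsv(path), max_rows=12))
    parts.append(_link(path, run_dir))


def _section_exploratory(run_dir: Path, parts: list[str]) -> None:
    edir = run_dir / "exploratory"
    coords_path = edir / "pca_coords.tsv"
    if not coords_path.exists():
        return
    parts.append("<h2>Exploratory analysis</h2>")
    coords = _read_tsv(coords_path)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1], s=18)
    ax.set_xlabel(coords.columns[0])
    ax.set_ylabel(coords.columns[1])
    ax.set_title("PCA of samples")
    parts.append(f"<img src='{_fig_to_data_uri(fig)}' alt='PCA scatter'>")
    assoc_path = edir / "component_associations.tsv"
    if assoc_path.exists():
        parts.append("<h3>Component-annotation association p-values</h3>")
        parts.append(_table_html(_read_tsv(assoc_path)))
    for path in sorted(edir.glob("*.tsv")):
        parts.append(_link(path, run_dir))


def _section_differential(run_dir: Path, parts: list[str]) -> None:
    ddir = run_dir / "differential"
    if not ddir.is_dir():
        return
    dm_path = ddir / "dm_cpg.tsv"
    if dm_path.exists():
        parts.append("<h2>Differential methylation and variability</h2>")
        dm = _read_tsv(dm_path)
        n_top = int((dm["p_adj"] < 0.05).sum()) if "p_adj" in dm else 0
        fig, ax = plt.subplots(1, 2, figsize=(9, 4))
        ax[0].scatter(dm["mean0"], dm["mean1"], s=4, alpha=0.3, color="steelblue")
        if n_top:
            top = dm.nsmallest(n_top, "combined_rank")
            ax[0].scatter(top["mean0"], top["mean1"], s=8, color="purple")
        ax[0].set_xlabel("group 0 mean")
        ax[0].set_ylabel("group 1 mean")
        ax[0].set_title(f"group means (top {n_top} ranked highlighted)")
        dv_path = ddir / "dv_cpg.tsv"
        if dv_path.exists():
            dv = _read_tsv(dv_path)
            ax[1].scatter(dv["var0"], dv["var1"], s=4, alpha=0.3, color="darkseagreen")
            n_dv = int((dv["p_adj"] < 0.05).sum()) if "p_adj" in dv else 0
            if n_dv:
                topv = dv.nsmallest(n_dv, "combined_rank")
                ax[1].scatter(topv["var0"], topv["var1"], s=8, color="saddlebrown")
            ax[1].set_xlabel("group 0 variance")
            ax[1].set_ylabel("group 1 variance")
            ax[1].set_title("group variances")
        fig.tight_layout()
        parts.append(f"<img src='{_fig_to_data_uri(fig)}' alt='differential scatters'>")
        parts.append("<h3>Top differentially methylated units</h3>")
        parts.append(_table_html(dm.sort_values("combined_rank").head(10)))
    for path in sorted(ddir.glob("*.tsv")):
        parts.append(_link(path, run_dir))


def _section_enrichment(run_dir: Path, parts: list[str]) -> None:
    path = run_dir / "enrichment" / "enrichment.tsv"
    if not path.exists():
        return
    parts.append("<h2>Region-set enrichment</h2>")
    res = _read_tsv(path).sort_values("max_rank").head(20)
    fig, ax = plt.subplots(figsize=(6, 0.4 * max(len(res), 4) + 1))
    ax.barh(np.arange(len(res)), res["log_odds"], color="indianred")
    ax.set_yticks(np.arange(len(res)))
    ax.set_yticklabels(res.index, fontsize=8)
    ax.invert_yaxis()
    ax.set_xlabel("log2 odds ratio")
    ax.set_title("top 20 enriched region sets (by worst rank)")
    fig.tight_layout()
    parts.append(f"<img src='{_fig_to_data_uri(fig)}' alt='enrichment log-odds'>")
    parts.append(_table_html(res))
    parts.append(_link(path, run_dir))
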