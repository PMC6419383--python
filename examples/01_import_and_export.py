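"""Import Bismark coverage files and export per-sample bedGraph tracks.

Builds a two-sample dataset from small coverage files written on the fly,
then round-trips it through bedGraph export.
"""

import tempfile
from pathlib import Path

import methworks as mw

tmp = Path(tempfile.mkdtemp())

# Bismark coverage dialect: chrom, start(=end, 1-based), %meth, n_meth, n_unmeth
(tmp / "tumor.cov").write_text(
    "chr1\t100\t100\t75\t3\t1\nchr1\t250\t250\t0\t0\t5\nchr2\t40\t40\t100\t8\t0\n"
)
(tmp / "normal.cov").write_text(
    "chr1\t100\t100\t25\t1\t3\nchr1\t250\t250\t60\t3\t2\nchr2\t40\t40\t50\t4\t4\n"
)

records = {name: mw.read_bismark_cov(tmp / f"{name}.cov") for name in ("tumor", "normal")}
ds = mw.dataset_from_records(records, platform="rrbs")
print(f"dataset: {ds.n_sites} CpGs x {ds.n_samples} samples ({ds.platform})")
print(ds.beta_frame())
# each cell is methylated reads / total reads at that CpG; beta is
# recomputed from the counts, never trusted from the percentage column

paths = mw.export_tracks(ds, tmp / "tracks")
print("\nfirst bedGraph lines (0-based half-open intervals):")
print(paths[0].read_text().splitlines()[0])
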