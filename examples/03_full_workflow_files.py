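"""The file-based workflow: BED/text inputs in, TSV + heatmap out.

Writes a synthetic dataset to disk in the exact formats a real analysis
would use (refGene-style table, peak BED, TAD BED, gene lists), builds the
reusable TSS reference BED, and runs the full enrichment workflow.
"""

import tempfile
from pathlib import Path

import pandas as pd

from peakgene import RunConfig, run
from peakgene.workflow import make_fixture_files, make_tss

tmp = Path(tempfile.mkdtemp(prefix="peakgene_demo_"))
fxdir = tmp / "fixture"
make_fixture_files(seed=0, out_dir=fxdir)

# Build the TSS reference once per genome from a refGene-style table.
tss_bed = make_tss(fxdir / "refgene.tsv", tmp / "tss.bed")

result = run(
    RunConfig(
        tss_reference=tss_bed,
        peaks=[("demo_peaks", fxdir / "peaks.bed")],
        gene_sets=[("planted", fxdir / "planted.txt"), ("random", fxdir / "random.txt")],
        distances=["5k", "50k", "500k", "tads"],
        tad_file=fxdir / "tads.bed",
        out_dir=tmp / "results",
    )
)

print(pd.read_csv(result.tsv_path, sep="\t").to_string(index=False))
print()
print(f"table:   {result.tsv_path}")
print(f"heatmap: {result.heatmap_path}")
print(
    "The heatmap has one panel per peak set; colour is -log10(p) shared\n"
    "across panels, rows are the expansions (TAD last) and the number in\n"
    "each cell is n_pc, the genes common to the gene set and the peaks."
)
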