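"""Multi-distance enrichment of two gene sets in one synthetic peak set.

Builds a toy genome (one 10 Mb chromosome, 500 genes, 100 peaks of which 50
sit within 5 kb of a "planted" gene's TSS), then asks: at which expansion
distance λ is each gene set enriched among the genes whose TSS falls inside
the expanded peaks?
"""

from peakgene import ExpansionSpec, FixtureSpec, make_fixture, run_enrichment

fx = make_fixture(FixtureSpec(seed=0))
matrix = run_enrichment(
    gene_sets=[fx.planted, fx.random],
    peak_sets=[fx.peaks],
    expansions=[ExpansionSpec.distance(d) for d in (1_000, 5_000, 50_000)],
    ref=fx.reference,
)

print(matrix.to_frame().to_string(index=False))
print()
print(
    "Each row is one (gene set, peak set, distance) test: M genes in the\n"
    "universe, Nc in the gene set, Np with a TSS inside a peak expanded by\n"
    "±λ, and n_pc in both. The planted set peaks at λ = 5 kb (the planting\n"
    "distance) with an upper-tail hypergeometric p around 1e-47, while the\n"
    "random set stays near p = 1 everywhere."
)
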