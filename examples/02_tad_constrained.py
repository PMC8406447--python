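"""TAD-constrained expansion versus fixed distances.

Instead of a fixed λ, each peak can be expanded to the outermost boundaries
of the topologically associated domains (TADs) it overlaps — the domain
within which regulatory contacts preferentially occur.  A peak overlapping
no TAD has no regulatory domain and contributes nothing in TAD mode.
"""

from peakgene import (
    ExpansionSpec,
    GenomicInterval,
    PeakSet,
    TadSet,
    TssRecord,
    TssReference,
    expand_peak_set,
    overlapping_genes,
)

ref = TssReference(
    [
        TssRecord("chr1", 1_000, "t1"),
        TssRecord("chr1", 3_000, "t2"),
        TssRecord("chr1", 7_000, "t3"),
        TssRecord("chr1", 9_500, "t4"),
        TssRecord("chr1", 60_000, "far"),
    ]
)
tads = TadSet([GenomicInterval("chr1", 0, 10_000)])
peaks = PeakSet("demo", (GenomicInterval("chr1", 4_000, 4_200),))

for spec in (ExpansionSpec.distance(500), ExpansionSpec.distance(5_000), ExpansionSpec.tads()):
    regions = expand_peak_set(peaks, spec, tads)
    genes = overlapping_genes(regions, ref)
    print(f"expansion {spec.display_label:>6}: regions={[(r.start, r.end) for r in regions]} "
          f"genes={sorted(genes)}")

print()
print(
    "At λ = 500 the peak reaches no TSS; at λ = 5 kb it reaches three of\n"
    "them; in TAD mode it captures all four TSSs inside its TAD [0, 10 kb)\n"
    "— including those beyond any tested λ — and never the TSS outside it."
)
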