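# Methods

## Model

`peakgene` tests whether a gene set is over-represented among the genes a
peak set could plausibly regulate, separately for each of several notions of
"could regulate":

* **distance mode** — a peak regulates every gene whose TSS lies within λ bp
  of the peak centre, i.e. inside `[c − λ, c + λ)` with
  `c = floor((start + end) / 2)`;
* **TAD mode** — a peak regulates every gene whose TSS lies inside the span
  of the topologically associated domains the peak overlaps, from the
  leftmost start to the rightmost end of all overlapping TADs.  A peak
  overlapping no TAD has no regulatory domain and is dropped (counted and
  logged).

Given the universe of `M` unique gene symbols in the TSS reference, the
effective gene set of size `Nc` (input symbols absent from the universe are
dropped, with a logged count — the test is only coherent when the cluster is
a subset of the universe), the `Np` unique genes with a TSS inside the
expanded peaks, and the overlap `n_pc`, the p-value is the upper tail of the
hypergeometric distribution:

```
p = sum_{x = n_pc}^{min(Np, Nc)}  C(Np, x) C(M − Np, Nc − x) / C(M, Nc)
```

One cell is computed for every (gene set, peak set, expansion) triple; the
grid is written as a tidy TSV and drawn as a heatmap (colour = −log10(p),
cell annotation = `n_pc`, one panel per peak set, shared colour scale).

### Assumptions

* Genes are exchangeable under the null: every `Nc`-subset of the universe
  is equally likely.  Gene length, GC content and clustering biases are not
  modelled; the background-restriction option is the provided mitigation.
* A gene "overlaps the peaks" if **any** of its TSSs does; genes with
  multiple TSSs count once in `M`, `Np` and `n_pc`.
* Peaks are unstranded and unweighted; summit/score columns are ignored.
* No multiple-testing correction is applied to the reported p-values — the
  heatmap shows raw −log10(p).  A clearly-labelled Benjamini–Hochberg `bh_q`
  column (over all cells of a run) is appended to the TSV as supplementary
  information only.

## Parameters

| parameter | units | default | rationale |
| --- | --- | --- | --- |
| λ (expansion distance) | bp | none; user list, `k`/`M` suffixes accepted | scales of interest range from promoter-proximal (1–5 kb) to distal (50–500 kb); λ = 0 keeps the raw peak |
| TAD mode | — | off | replaces (not adds to) distance expansion; produces its own result row |
| background | gene list | full reference universe | restricting to e.g. expressed genes changes `M`, `Nc`, `Np` coherently (all sets are intersected with it) |
| `fold` (tissue specificity) | — | 5.0 | a gene is tissue-specific when its median TPM exceeds `fold ×` the arithmetic mean of its medians in the remaining tissues, strict inequality |
| heatmap display cap | −log10(p) | 300 | double-precision underflow limit; the TSV keeps the exact log-space value |

## Coordinate and strand conventions

All coordinates are 0-based half-open (BED).  A TSS occupies `[pos, pos+1)`.
From a refGene-style transcript row the TSS is `txStart` on "+" and
`txEnd − 1` on "−" — the last base inside the half-open span, since `txEnd`
itself is outside the transcript.  Expanded intervals are clamped at 0 on
the left; no right clamp is applied (chromosome sizes are not an input), as
overhanging regions simply overlap no TSS.  Gene symbols are compared
case-sensitively after stripping surrounding whitespace, because silent
case-folding can merge distinct symbols.

TADs are merged at load time if they overlap (warning logged);
boundary-touching TADs stay distinct, and a peak must strictly overlap a
TAD's half-open span to join it.  A peak spanning several TADs expands to
the outermost boundaries of all of them — the most inclusive reading of a
TAD-constrained regulatory domain.

## Numerical choices

* The tail sum is evaluated in log-space with `scipy.special.gammaln` and
  `logsumexp`, never with explicit factorials, and is clipped to log p ≤ 0.
  Against exact integer-fraction enumeration over every valid
  `(M ≤ 60, Nc, Np, n_pc)` the worst relative error is ~1e−13 (asserted at
  1e−12 in the tests).  For identities checked at `M` up to 2000 the
  accumulated log-sum-exp rounding grows to ~1e−12, so those property tests
  assert at 1e−10.
* Terms with a zero binomial (`Nc − x > M − Np`) are excluded analytically
  rather than evaluated.
* `EnrichmentCell` stores the natural-log p-value exactly; `p_value` is its
  exponential (which may underflow to 0 in double precision for extreme
  cells) and `neg_log10_p` is derived from the log value, so the TSV never
  loses significance to underflow.
* Degenerate cells — a gene set empty within the universe, or peaks
  overlapping no TSS — report `p = 1`, `n_pc = 0` with a warning instead of
  failing the run.
* TSS intersection uses per-chromosome binary search over the sorted TSS
  positions (`O((R + T) log T)`); a brute-force all-pairs scan exists only
  in the test suite as the independent oracle.

## Synthetic data generator

`FixtureSpec` / `make_fixture` produce a toy genome whose defaults are the
stated test world: one 10 Mb chromosome, 500 uniformly placed genes
(1 gene / 20 kb, a mammalian-like density at toy scale), 100 peaks of width
200 bp, of which 50 are "planted": each planted peak's centre sits at a
signed uniform offset within ±5 kb of a distinct planted gene's TSS, so
expansion at λ ≥ 5 kb recovers every planted gene.  The remaining peaks are
uniform background.  TADs tile each chromosome in 1 Mb blocks.  A
size-matched **random** gene set is drawn from the non-planted genes,
independent of peak placement — it is an exact null draw, and is what the
null-calibration test measures (the generator refuses
`planted_gene_fraction = 0`, since an empty planted set is a degenerate
spec).  All randomness flows from one `numpy.random.default_rng(seed)`;
equal seeds give byte-identical output files, written through the production
writers so that tests exercise the I/O layer.

What the generator does **not** emulate: realistic peak-width and
inter-peak-distance distributions, gene clustering, multiple TSSs per gene
(each synthetic gene has one), chromosome-size heterogeneity, or symbol
aliasing.  A green planted-recovery test therefore establishes that the
pipeline recovers a distance-localised association signal against a uniform
background — not that real ChIP-seq biases are handled.

## Design choices where the design was open

* **Centre-based expansion**: λ is measured from the peak centre, not the
  peak edges; the centre convention matches the regulatory-domain picture of
  a focal binding event and makes 1-bp SNP "peaks" behave identically to
  wide peaks.
* **Strand-aware TSS**: transcript orientation decides which end of the
  transcript is the TSS.  An orientation-blind alternative (always
  `txStart`) was rejected as biologically wrong for "−"-strand genes.
* **Dropped unknown symbols**: input genes missing from the reference reduce
  `Nc` rather than inflate it (logged).
* **"Average of the remaining tissues"** in the tissue-specificity rule is
  the arithmetic mean of the per-tissue medians.  Genes with zero mean
  elsewhere are included when expressed in the target tissue — excluding
  them would discard exactly the most tissue-specific genes.
* **Random gene set drawn from non-planted genes** in fixtures, so the
  planted-vs-random comparison is not diluted by accidental sharing.

## Known limitations

* No permutation or empirical null; the statistic is the hypergeometric tail
  only, and p-values for overlapping λ values are strongly dependent across
  rows (the BH column treats them as a flat family).
* No right-clamping at chromosome ends and no strand-aware peak expansion.
* The heatmap is static (PNG/SVG/PDF); no interactive output.
* Reference building accepts refGene-style tables and TSS BEDs from local
  files only; no annotation download.
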