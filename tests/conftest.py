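import pytest

from peakgene import (
    FixtureSpec,
    GenomicInterval,
    TssRecord,
    TssReference,
    make_fixture,
)


@pytest.fixture
def toy_reference():
    """Six TSSs / five genes on two chromosomes (geneA has two TSSs)."""
    return TssReference(
        [
            TssRecord("chr1", 150, "geneA", "+"),
            TssRecord("chr1", 900, "geneA", "+"),
            TssRecord("chr1", 200, "geneB", "-"),
            TssRecord("chr1", 5000, "geneC", "+"),
            TssRecord("chr2", 300, "geneD", "-"),
            TssRecord("chr2", 7000, "geneE", "+"),
        ]
    )


@pytest.fixture
def default_fixture():
    return make_fixture(FixtureSpec(seed=0))


def brute_force_overlap(regions, ref):
    """Naive O(R*T) all-pairs oracle for overlapping_genes."""
    genes = set()
    for region in regions:
        for rec in ref.records:
            if rec.chrom == region.chrom and region.start <= rec.pos < region.end:
                genes.add(rec.gene)
    return genes


def random_instance(rng, n_regions, n_tss, n_chroms=3, length=100_000):
    chroms = [f"chr{i+1}" for i in range(n_chroms)]
    regions = []
    for _ in range(n_regions):
        start = int(rng.integers(0, length - 1))
        end = int(rng.integers(start + 1, min(length, start + 5_000) + 1))
        regions.append(GenomicInterval(chroms[int(rng.integers(n_chroms))], start, end))
    records = [
        TssRecord(
            chroms[int(rng.integers(n_chroms))],
            int(rng.integers(0, length)),
            f"g{i}",
            "+" if rng.integers(2) else "-",
        )
        for i in range(n_tss)
    ]
    return regions, TssReference(records)
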