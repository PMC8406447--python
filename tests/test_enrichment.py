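import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from peakgene import (
    ConfigError,
    ExpansionSpec,
    FixtureSpec,
    GeneSet,
    effective_counts,
    hypergeom_tail,
    make_fixture,
    run_enrichment,
)


def exact_tail(M, Nc, Np, n_pc):
    """Exact-rational upper-tail hypergeometric (the independent oracle)."""
    num = sum(comb(Np, x) * comb(M - Np, Nc - x) for x in range(n_pc, min(Np, Nc) + 1))
    return Fraction(num, comb(M, Nc))


@st.composite
def valid_counts(draw, max_m=500):
    M = draw(st.integers(1, max_m))
    Nc = draw(st.integers(0, M))
    Np = draw(st.integers(0, M))
    n_pc = draw(st.integers(0, min(Nc, Np)))
    return M, Nc, Np, n_pc


class TestHypergeomTail:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((20, 5, 5, 0), Fraction(1)),
            ((20, 5, 5, 3), Fraction(1126, 15504)),
            ((20, 5, 5, 5), Fraction(1, 15504)),
        ],
        ids=["tail-from-zero-is-one", "worked-mid-tail", "worked-extreme-tail"],
    )
    def test_worked_examples(self, counts, expected):
        assert expected == exact_tail(*counts)  # oracle self-check
        assert hypergeom_tail(*counts) == pytest.approx(float(expected), rel=1e-12)

    @given(valid_counts())
    @settings(max_examples=300, derandomize=True)
    def test_matches_exact_fraction_oracle(self, counts):
        expected = float(exact_tail(*counts))
        got = hypergeom_tail(*counts)
        assert got == pytest.approx(expected, rel=1e-11, abs=0.0)

    @given(valid_counts())
    @settings(max_examples=200, derandomize=True)
    def test_matches_scipy_survival_function(self, counts):
        M, Nc, Np, n_pc = counts
        expected = hypergeom.sf(n_pc - 1, M, Np, Nc)
        assert hypergeom_tail(*counts) == pytest.approx(expected, rel=1e-9, abs=1e-300)

    @given(valid_counts())
    @settings(max_examples=200, derandomize=True)
    def test_symmetry_under_role_swap(self, counts):
        M, Nc, Np, n_pc = counts
        assert hypergeom_tail(M, Nc, Np, n_pc) == pytest.approx(
            hypergeom_tail(M, Np, Nc, n_pc), rel=1e-12
        )

    @given(valid_counts(max_m=120))
    @settings(max_examples=150, derandomize=True)
    def test_non_increasing_in_overlap(self, counts):
        M, Nc, Np, _ = counts
        values = [hypergeom_tail(M, Nc, Np, k) for k in range(min(Nc, Np) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(values, values[1:]))

    def test_full_overlap_with_saturated_universe(self):
        # Np = M: every drawn gene is a success, so P(X >= Nc) = 1.
        assert hypergeom_tail(50, 10, 50, 10) == pytest.approx(1.0)

    def test_genome_scale_no_underflow_to_garbage(self):
        # M ~ 2.5e4 with a huge overlap: log-space must stay finite & tiny.
        p = hypergeom_tail(25_000, 500, 800, 400)
        assert 0.0 <= p < 1e-200
        expected = hypergeom.logsf(399, 25_000, 800, 500)
        from peakgene import hypergeom_log_tail

        assert hypergeom_log_tail(25_000, 500, 800, 400) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize(
        "counts",
        [(10, 11, 5, 0), (10, 5, 11, 0), (10, 5, 5, 6), (10, -1, 5, 0)],
        ids=["Nc>M", "Np>M", "n_pc>min", "negative"],
    )
    def test_invalid_counts_rejected(self, counts):
        with pytest.raises(ValueError):
            hypergeom_tail(*counts)


class TestEffectiveCounts:
    def test_set_arithmetic(self):
        gs = GeneSet("s", {"A", "B", "C"})
        assert effective_counts(gs, {"B", "D"}, {"A", "B", "D"}) == (2, 2, 1)

    def test_symbols_outside_universe_dropped_and_logged(self, caplog):
        gs = GeneSet("s", {"A", "X", "Y"})
        with caplog.at_level("INFO", logger="peakgene.enrichment"):
            Nc, Np, n_pc = effective_counts(gs, set(), {"A", "B"})
        assert (Nc, Np, n_pc) == (1, 0, 0)
        assert "dropped" in caplog.text

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            effective_counts(GeneSet("s", {"A"}), set(), set())


class TestRunEnrichment:
    @pytest.fixture
    def fx(self):
        return make_fixture(FixtureSpec(seed=0))

    def test_cell_cardinality_and_order(self, fx):
        m = run_enrichment(
            [fx.planted, fx.random],
            [fx.peaks],
            [ExpansionSpec.distance(5_000), ExpansionSpec.distance(50_000)],
            fx.reference,
        )
        assert len(m.cells) == 4
        assert [c.expansion for c in m.cells] == ["5000", "5000", "50000", "50000"]

    def test_identical_peak_set_twice_gives_identical_blocks(self, fx):
        from dataclasses import replace

        twin = replace(fx.peaks, name="twin")
        m = run_enrichment(
            [fx.planted], [fx.peaks, twin], [ExpansionSpec.distance(5_000)], fx.reference
        )
        a, b = m.cells
        assert (a.M, a.Nc, a.Np, a.n_pc, a.p_value) == (b.M, b.Nc, b.Np, b.n_pc, b.p_value)

    def test_overlap_equals_universe_gives_p_one(self, fx):
        m = run_enrichment(
            [fx.planted], [fx.peaks], [ExpansionSpec.distance(20_000_000)], fx.reference
        )
        cell = m.cells[0]
        assert cell.Np == cell.M
        assert cell.p_value == pytest.approx(1.0)
        assert cell.n_pc == cell.Nc

    def test_gene_set_outside_universe_degenerates_to_p_one(self, fx, caplog):
        alien = GeneSet("alien", {"NOT_A_GENE_1", "NOT_A_GENE_2"})
        with caplog.at_level("WARNING", logger="peakgene.enrichment"):
            m = run_enrichment(
                [alien], [fx.peaks], [ExpansionSpec.distance(5_000)], fx.reference
            )
        cell = m.cells[0]
        assert (cell.Nc, cell.n_pc, cell.p_value) == (0, 0, 1.0)

    def test_background_full_universe_is_noop(self, fx):
        kwargs = dict(
            gene_sets=[fx.planted, fx.random],
            peak_sets=[fx.peaks],
            expansions=[ExpansionSpec.distance(5_000)],
            ref=fx.reference,
        )
        base = run_enrichment(**kwargs)
        with_bg = run_enrichment(**kwargs, background=set(fx.reference.universe))
        assert base.cells == with_bg.cells

    def test_background_restriction_shrinks_M(self, fx):
        bg = set(sorted(fx.reference.universe)[:200]) | set(fx.planted.genes)
        m = run_enrichment(
            [fx.planted], [fx.peaks], [ExpansionSpec.distance(5_000)], fx.reference,
            background=bg,
        )
        assert m.cells[0].M == len(bg & fx.reference.universe)

    def test_np_and_npc_monotone_in_lambda(self, fx):
        m = run_enrichment(
            [fx.planted],
            [fx.peaks],
            [ExpansionSpec.distance(d) for d in (1_000, 5_000, 50_000, 500_000)],
            fx.reference,
        )
        nps = [c.Np for c in m.cells]
        npcs = [c.n_pc for c in m.cells]
        assert nps == sorted(nps) and npcs == sorted(npcs)

    def test_tads_requested_without_tadset_is_config_error(self, fx):
        with pytest.raises(ConfigError):
            run_enrichment(
                [fx.planted], [fx.peaks], [ExpansionSpec.tads()], fx.reference, tads=None
            )

    def test_tsv_frame_columns_and_bh(self, fx):
        m = run_enrichment(
            [fx.planted, fx.random],
            [fx.peaks],
            [ExpansionSpec.distance(5_000)],
            fx.reference,
        )
        df = m.to_frame()
        assert list(df.columns) == [
            "gene_set", "peak_set", "expansion", "M", "Nc", "Np", "n_pc",
            "p_value", "neg_log10_p", "bh_q",
        ]
        assert (df["bh_q"] >= df["p_value"] - 1e-15).all()
        assert (df["bh_q"] <= 1.0).all()

    def test_neg_log10_matches_p(self, fx):
        m = run_enrichment(
            [fx.planted], [fx.peaks], [ExpansionSpec.distance(5_000)], fx.reference
        )
        c = m.cells[0]
        assert c.neg_log10_p == pytest.approx(-math.log10(c.p_value), rel=1e-9)
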