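"""Fold-change classification, Fisher/BH statistics, and end-to-end enrichment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinmotif.enrichment import (
    ContingencyTable,
    DifferentialSite,
    KinaseEnrichment,
    bh_adjust,
    classify_sites,
    fisher_one_sided,
    frequency_factor,
    run_enrichment,
)
from kinmotif.errors import ValidationError
from kinmotif.scoring import PhosphoSite
from kinmotif.synthetic import gen_differential_study, gen_substrates_from_pssm


def enumeration_fisher(a, b, c, d):
    """Upper-tail hypergeometric p by exhaustive enumeration (math.comb only)."""
    N, K, n = a + b + c + d, a + b, a + c
    denom = math.comb(N, n)
    num = sum(
        math.comb(K, k) * math.comb(N - K, n - k)
        for k in range(a, min(K, n) + 1)
        if n - k <= N - K
    )
    return num / denom


def site(i, window="PLARTSVAAL", fc=0.0, mult=1):
    return DifferentialSite(
        site=PhosphoSite(f"s{i}", window), log2fc=fc, multiplicity=mult
    )


class TestClassify:
    def test_boundary_is_regulated(self):
        """|log2 fc| equal to the threshold counts as regulated."""
        parts = classify_sites(
            [site(0, fc=1.5), site(1, "AAAAATAAAA", fc=-1.5),
             site(2, "CCCCCSCCCC", fc=-1.49)],
            fc_threshold=1.5,
        )
        assert len(parts.up) == 1 and len(parts.down) == 1
        assert len(parts.unchanged) == 1

    def test_drops_multiphospho_and_duplicates(self):
        """10 sites with 2 duplicate windows and 1 multi-phospho -> 7 classified."""
        windows = [
            "AAAAASAAAA", "CCCCCSCCCC", "DDDDDSDDDD", "EEEEESEEEE",
            "FFFFFSFFFF", "GGGGGSGGGG", "HHHHHSHHHH",
        ]
        sites = [site(i, w) for i, w in enumerate(windows)]
        sites.append(site(7, "AAAAASAAAA"))        # duplicate
        sites.append(site(8, "CCCCCSCCCC"))        # duplicate
        sites.append(site(9, "IIIIISIIII", mult=2))  # multi-phospho
        parts = classify_sites(sites)
        assert parts.n_retained == 7
        assert parts.n_dropped_duplicate == 2
        assert parts.n_dropped_multiphospho == 1

    def test_threshold_monotonicity(self):
        """Lowering the threshold only moves sites out of the unchanged class."""
        rng = np.random.default_rng(0)
        sites = [site(i, fc=float(rng.normal(0, 1.2)))
                 for i in range(50)]
        hi = classify_sites(sites, fc_threshold=1.5)
        lo = classify_sites(sites, fc_threshold=0.5)
        assert {s.site.site_id for s in hi.up} <= {s.site.site_id for s in lo.up}
        assert {s.site.site_id for s in hi.down} <= {s.site.site_id for s in lo.down}

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValidationError):
            classify_sites([site(0)], fc_threshold=0.0)


class TestContingency:
    def test_haldane_applied_iff_zero_cell(self):
        plain = ContingencyTable.from_counts(3, 1, 1, 3)
        assert not plain.haldane_applied
        corrected = ContingencyTable.from_counts(0, 10, 5, 5)
        assert corrected.haldane_applied
        assert (corrected.a, corrected.b, corrected.c, corrected.d) == (
            0.5, 10.5, 5.5, 5.5
        )

    def test_raw_cells_strip_correction(self):
        t = ContingencyTable.from_counts(0, 10, 5, 5)
        assert t.raw_cells == (0, 10, 5, 5)


class TestFisher:
    def test_worked_table(self):
        """a=3,b=1,c=1,d=3 -> upper tail 17/70."""
        p = fisher_one_sided(ContingencyTable.from_counts(3, 1, 1, 3))
        assert p == pytest.approx(17 / 70, abs=1e-12)

    def test_minimal_evidence_has_large_p(self):
        """a=0 sits at the bottom of the upper tail: p >= 0.5 and = full tail."""
        p = fisher_one_sided(ContingencyTable.from_counts(0, 4, 4, 4))
        assert p >= 0.5
        assert p == pytest.approx(enumeration_fisher(0, 4, 4, 4), abs=1e-12)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        p = fisher_one_sided(ContingencyTable.from_counts(a, b, c, d))
        assert p == pytest.approx(enumeration_fisher(a, b, c, d), abs=1e-12)

    def test_p_decreases_as_a_increases(self):
        """At fixed margins, more favoured-regulated sites -> smaller p."""
        ps = [enumeration_fisher(a, 10 - a, 10 - a, a) for a in range(5, 10)]
        assert all(x > y for x, y in zip(ps, ps[1:]))
        impl = [
            fisher_one_sided(ContingencyTable.from_counts(a, 10 - a, 10 - a, a))
            for a in range(5, 10)
        ]
        assert np.allclose(impl, ps, atol=1e-12)

    def test_degenerate_margins_warn_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            p = fisher_one_sided(ContingencyTable.from_counts(0, 0, 3, 4))
        assert p == 1.0


class TestFrequencyFactor:
    def test_equal_proportions_give_zero(self):
        assert frequency_factor(ContingencyTable.from_counts(2, 8, 4, 16)) == 0.0

    def test_worked_example(self):
        t = ContingencyTable.from_counts(8, 2, 10, 40)
        assert frequency_factor(t) == pytest.approx(2.0)

    def test_haldane_corrected_example(self):
        t = ContingencyTable.from_counts(0, 10, 5, 5)
        assert frequency_factor(t) == pytest.approx(math.log2(0.5 / 5.5))
        assert frequency_factor(t) == pytest.approx(-3.459, abs=1e-3)


class TestBH:
    def test_worked_stepup(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.2])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.2])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])

    def test_empty_list(self):
        assert bh_adjust([]).size == 0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=40))
    def test_adjusted_at_least_raw_and_capped(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)

    def test_order_preserving_permutation(self):
        rng = np.random.default_rng(2)
        ps = rng.uniform(0.001, 1.0, size=20)
        adj = bh_adjust(ps)
        perm = rng.permutation(20)
        assert np.allclose(bh_adjust(ps[perm]), adj[perm])


class TestRunEnrichment:
    def test_margins_partition_sites(self, small_atlas):
        """a+b = #regulated and c+d = #unchanged for every kinase and side."""
        study = gen_differential_study(
            small_atlas, "KIN001", n_background=300, n_planted=40, seed=4
        )
        parts = classify_sites(study)
        rows = run_enrichment(study, small_atlas, top_k=3)
        for r in rows:
            a, b, c, d = r.table.raw_cells
            n_reg = len(parts.up) if r.side == "up" else len(parts.down)
            assert a + b == n_reg
            assert c + d == len(parts.unchanged)

    def test_planted_kinase_dominant_up(self, small_atlas):
        study = gen_differential_study(
            small_atlas, "KIN003", n_background=800, n_planted=80, seed=5
        )
        results = KinaseEnrichment(study, small_atlas, top_k=3).fit()
        top = results.dominant().query("side == 'up'").sort_values("adj_p").iloc[0]
        assert top["kinase"] == "KIN003"
        assert top["adj_p"] <= 0.1
        assert top["freq_factor_log2"] > 0

    def test_both_sides_enriched_kinase_excluded(self, small_atlas):
        """A kinase regulated in both directions is excluded, with no dominant side."""
        pssm, _ = small_atlas[0]
        rng = np.random.default_rng(6)
        subs = gen_substrates_from_pssm(pssm, 120, seed=7)
        study = gen_differential_study(
            small_atlas, "KIN005", n_background=600, n_planted=1, seed=8,
            effect_log2fc=0.0,
        )
        study = [s for s in study if s.site.site_id.startswith("bg")]
        study += [
            DifferentialSite(site=s, log2fc=2.0 if i % 2 else -2.0)
            for i, s in enumerate(subs)
        ]
        rows = run_enrichment(study, small_atlas, top_k=3)
        mine = [r for r in rows if r.kinase_id == pssm.kinase_id]
        assert all(r.excluded for r in mine)
        assert not any(r.dominant for r in mine)

    def test_exactly_one_dominant_side_unless_excluded(self, small_atlas):
        study = gen_differential_study(
            small_atlas, "KIN002", n_background=400, n_planted=40, seed=9
        )
        rows = run_enrichment(study, small_atlas, top_k=3)
        by_kinase = {}
        for r in rows:
            by_kinase.setdefault(r.kinase_id, []).append(r)
        for pair in by_kinase.values():
            if any(r.excluded for r in pair):
                assert all(r.excluded for r in pair)
            else:
                assert sum(r.dominant for r in pair) == 1

    def test_null_with_populated_regulated_classes(self, small_atlas):
        """Wide null noise populates both regulated classes without creating
        a systematic excess of significant kinases."""
        fractions = []
        for seed in range(10):
            study = gen_differential_study(
                small_atlas, "KIN000", n_background=800, n_planted=50,
                effect_log2fc=0.0, noise_sd=0.8, seed=600 + seed,
            )
            parts = classify_sites(study)
            assert parts.up and parts.down  # the point: non-degenerate null
            rows = run_enrichment(study, small_atlas, top_k=3)
            dom = [r for r in rows if r.dominant]
            fractions.append(
                np.mean([r.adj_p <= 0.1 for r in dom]) if dom else 0.0
            )
        assert float(np.mean(fractions)) <= 0.1

    def test_no_unchanged_sites_rejected(self, small_atlas):
        study = [site(i, fc=3.0) for i in range(5)]
        with pytest.raises(ValidationError, match="unchanged"):
            run_enrichment(study, small_atlas)

    def test_output_covers_every_kinase_twice(self, small_atlas):
        study = gen_differential_study(
            small_atlas, "KIN000", n_background=200, n_planted=20, seed=10
        )
        rows = run_enrichment(study, small_atlas, top_k=3)
        assert len(rows) == 2 * len(small_atlas)
        assert {r.side for r in rows} == {"up", "down"}
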