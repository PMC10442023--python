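"""PTM overlap tests, site-level intersections, and the anchor-centric
positional phosphorylation profile."""

import math

import numpy as np
import pandas as pd
import pytest

from acetylome import crosstalk as ct
from acetylome import synthetic
from acetylome.io_tables import (AnnotationTable, Protein, Proteome,
                                 SiteCatalog, SiteKey)


def _cat(rows, proteome):
    frame = pd.DataFrame(rows, columns=["protein_id", "position", "residue",
                                        "ptm_type"])
    return SiteCatalog.from_frame(frame, proteome)


def _brute_hypergeom_sf(k, N, K, n):
    return sum(math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
               for i in range(k, min(K, n) + 1))


class TestProteinOverlap:
    def test_enumeration_example(self):
        # N=10, K=5, n=4, k=4 -> C(5,4)C(5,0)/C(10,4) = 5/210
        sets = {"acetyl": {f"P{i}" for i in range(5)},
                "phospho": {f"P{i}" for i in range(4)}}
        tests, _ = ct.protein_overlap(sets, 10)
        (t,) = tests
        assert t.intersection == 4
        assert t.p_value == pytest.approx(5 / 210, abs=1e-12)

    def test_disjoint_sets_zero_percent(self):
        sets = {"acetyl": {"P1"}, "sumo": {"P2"}}
        tests, regions = ct.protein_overlap(sets, 10)
        assert tests[0].percent_of_a == 0.0
        assert regions[frozenset({"acetyl"})] == 1

    def test_identical_sets_full_percent(self):
        s = {"P1", "P2", "P3"}
        tests, _ = ct.protein_overlap({"a": s, "b": set(s)}, 10)
        assert tests[0].percent_of_a == 100.0
        # p is the minimum over all achievable k for these set sizes
        assert tests[0].p_value == pytest.approx(
            _brute_hypergeom_sf(3, 10, 3, 3), abs=1e-12)

    def test_set_exceeding_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            ct.protein_overlap({"a": {"P1", "P2"}}, 1)

    def test_region_counts_partition_union(self):
        sets = {"a": {"P1", "P2"}, "b": {"P2", "P3"}, "c": {"P4"}}
        _, regions = ct.protein_overlap(sets, 10)
        assert sum(regions.values()) == 4

    def test_tail_matches_enumeration_small_universe(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            N = int(rng.integers(2, 51))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            from acetylome.enrichment import hypergeom_upper_tail
            assert hypergeom_upper_tail(k, N, K, n) == pytest.approx(
                _brute_hypergeom_sf(k, N, K, n), abs=1e-12)


class TestSiteOverlap:
    def test_shared_and_unshared(self):
        proteome = Proteome([Protein("P1", "A" * 55 + "KK")])
        kac = _cat([("P1", 56, "K", "acetyl")], proteome)
        other = _cat([("P1", 56, "K", "ubiquitin"),
                      ("P1", 57, "K", "sumo")], proteome)
        res = ct.site_overlap(kac, other)
        assert res["ubiquitin"][0] == 1
        assert res["sumo"][0] == 0

    def test_exclusion_zero_shares_nothing(self):
        cfg = synthetic.SyntheticConfig(seed=41, n_proteins=200,
                                        ack_exclusion=0.0, ub_rate=0.3)
        proteome = synthetic.generate_proteome(cfg)
        res = synthetic.generate_acetylome(proteome, cfg)
        others = synthetic.generate_ptm_sites(
            res.proteome, res.truth_keys_by_protein(), cfg)
        shared = ct.site_overlap(res.catalog, others)
        assert shared["ubiquitin"][0] == 0


class TestPositionalProfile:
    def test_no_phospho_all_zero(self):
        proteome = Proteome([Protein("P", "KSKTY")])
        prof = ct.positional_profile(proteome, {SiteKey("P", 1)}, set(),
                                     d_max=3, n_boot=10, seed=0)
        observed = prof[prof.denominator > 0]
        assert (observed.fraction == 0).all()

    def test_single_protein_enumeration(self):
        # "KSK": acK at 1, pS at 2 -> acK fraction at d=1 is 1.0
        proteome = Proteome([Protein("P", "KSK")])
        prof = ct.positional_profile(proteome, {SiteKey("P", 1)},
                                     {SiteKey("P", 2)}, d_max=2,
                                     n_boot=10, seed=0)
        row = prof.query("anchor_class == 'acK' and residue == 'S' "
                         "and d == 1")
        assert row.fraction.iloc[0] == 1.0
        # the non-acK anchor (position 3) sees the same pS at d=1
        row = prof.query("anchor_class == 'non-acK' and residue == 'S' "
                         "and d == 1")
        assert row.fraction.iloc[0] == 1.0

    def test_invariant_under_protein_reordering(self):
        cfg = synthetic.SyntheticConfig(seed=43, n_proteins=60)
        proteome = synthetic.generate_proteome(cfg)
        res = synthetic.generate_acetylome(proteome, cfg)
        others = synthetic.generate_ptm_sites(
            res.proteome, res.truth_keys_by_protein(), cfg)
        kac = res.catalog.site_keys(ptm_type="acetyl")
        phos = others.site_keys(ptm_type="phospho")
        a = ct.positional_profile(res.proteome, kac, phos, n_boot=50, seed=1)
        reordered = Proteome([res.proteome[p]
                              for p in sorted(res.proteome, reverse=True)])
        b = ct.positional_profile(reordered, kac, phos, n_boot=50, seed=1)
        pd.testing.assert_frame_equal(a, b)

    def test_bootstrap_reproducible(self):
        proteome = Proteome([Protein("P", "KSKTYSSK"),
                             Protein("Q", "KSSTYK")])
        kw = dict(d_max=4, n_boot=200, seed=7)
        a = ct.positional_profile(proteome, {SiteKey("P", 1)},
                                  {SiteKey("P", 2)}, **kw)
        b = ct.positional_profile(proteome, {SiteKey("P", 1)},
                                  {SiteKey("P", 2)}, **kw)
        pd.testing.assert_frame_equal(a, b)

    def test_ci_brackets_point_estimate(self):
        cfg = synthetic.SyntheticConfig(seed=47, n_proteins=150)
        proteome = synthetic.generate_proteome(cfg)
        res = synthetic.generate_acetylome(proteome, cfg)
        others = synthetic.generate_ptm_sites(
            res.proteome, res.truth_keys_by_protein(), cfg)
        prof = ct.positional_profile(
            res.proteome, res.catalog.site_keys(ptm_type="acetyl"),
            others.site_keys(ptm_type="phospho"), n_boot=200, seed=2)
        ok = prof.dropna(subset=["fraction"])
        assert (ok.ci_lo <= ok.fraction + 1e-12).all()
        assert (ok.ci_hi >= ok.fraction - 1e-12).all()

    def test_clustering_signal_recovered(self):
        """acK curve exceeds the non-acK curve at short range and decays
        toward the baseline rate p0."""
        cfg = synthetic.SyntheticConfig(seed=53, n_proteins=1200,
                                        frac_acetylated=0.8)
        proteome = synthetic.generate_proteome(cfg)
        res = synthetic.generate_acetylome(proteome, cfg)
        others = synthetic.generate_ptm_sites(
            res.proteome, res.truth_keys_by_protein(), cfg)
        # profile anchored on the truth (detection noise only thins organs)
        kac = {SiteKey(r.protein_id, r.position)
               for r in res.truth.itertuples()}
        prof = ct.positional_profile(
            res.proteome, kac, others.site_keys(ptm_type="phospho"),
            d_max=15, n_boot=100, seed=3)
        comb = prof[prof.residue == "combined"].set_index(
            ["anchor_class", "d"])
        for d in range(1, 6):
            assert comb.loc[("acK", d), "fraction"] > \
                comb.loc[("non-acK", d), "fraction"]
        f1 = comb.loc[("acK", 1), "fraction"]
        expected = cfg.phospho_base + cfg.phospho_boost * math.exp(
            -1 / cfg.phospho_decay)
        den = comb.loc[("acK", 1), "denominator"]
        se = math.sqrt(expected * (1 - expected) / den)
        assert abs(f1 - expected) < 3 * se
        assert abs(comb.loc[("acK", 15), "fraction"]
                   - cfg.phospho_base) < 0.05


class TestDualModificationEnrichment:
    def test_exclusive_term_ranks_first(self):
        ann = AnnotationTable({"P1": {"bromo"}, "P2": {"bromo"},
                               "P3": {"other"}, "P4": {"other"}})
        uni = {"P1", "P2", "P3", "P4", "P5"}
        res = ct.dual_modification_enrichment(
            ann, {"P1", "P2"}, {"P1", "P2"}, uni)
        assert res.iloc[0]["term"] == "bromo"

    def test_same_frequency_term_not_significant(self):
        # fg frequency equals bg frequency -> Fisher tail >= 0.5
        ann = AnnotationTable({f"P{i}": {"t"} for i in range(0, 10, 2)})
        uni = {f"P{i}" for i in range(10)}
        fg = {"P0", "P1", "P2", "P3"}  # two of four carry t, like universe
        res = ct.dual_modification_enrichment(ann, fg, fg, uni)
        assert res.iloc[0]["p"] >= 0.5

    def test_empty_foreground_flagged(self):
        res = ct.dual_modification_enrichment(
            AnnotationTable({}), {"P1"}, {"P2"}, {"P1", "P2"})
        assert res.empty and res.attrs["empty_foreground"]

    def test_bh_stepwise_by_hand(self):
        from acetylome.enrichment import bh_qvalues
        q = bh_qvalues([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_bh_matches_brute_force_step_up(self):
        from acetylome.enrichment import bh_qvalues
        rng = np.random.default_rng(11)
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            order = np.argsort(p)
            brute = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                brute[i] = running
            assert np.allclose(bh_qvalues(p), brute, atol=1e-12)
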