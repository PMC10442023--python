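"""Behaviour of the seeded synthetic-data generator: determinism,
consistency with the validated data model, and recovery of the configured
statistical structure."""

import numpy as np
import pandas as pd
import pytest

from acetylome import synthetic
from acetylome.catalog_stats import pairwise_replicate_overlaps
from acetylome.conservation import classify_all, conservation_contrast
from acetylome.expression import entropy_table
from acetylome.io_tables import AA20, SiteKey
from acetylome.synthetic import SyntheticConfig


def small_config(**kw):
    base = dict(seed=11, n_proteins=120, length_mean=200.0)
    base.update(kw)
    return SyntheticConfig(**base)


class TestConfig:
    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            SyntheticConfig(detection_prob=1.5)

    def test_degenerate_length_law_rejected(self):
        with pytest.raises(ValueError, match="length"):
            SyntheticConfig(length_mean=5.0)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(entropy_alpha_non=0.0)


class TestProteome:
    def test_empty(self):
        assert len(synthetic.generate_proteome(
            small_config(n_proteins=0))) == 0

    def test_deterministic_under_seed(self):
        cfg = small_config()
        a = synthetic.generate_proteome(cfg)
        b = synthetic.generate_proteome(small_config())
        assert {p: a[p].sequence for p in a} == {p: b[p].sequence for p in b}

    def test_uniform_frequencies_recovered(self):
        """With uniform aa_frequencies each residue frequency lands within
        3 binomial standard errors of 0.05 over ~1e5 residues."""
        cfg = SyntheticConfig(seed=3, n_proteins=500, length_mean=200.0,
                              aa_frequencies={a: 0.05 for a in AA20})
        proteome = synthetic.generate_proteome(cfg)
        joined = "".join(p.sequence for p in proteome.values())
        n = len(joined)
        assert n > 9e4
        se = np.sqrt(0.05 * 0.95 / n)
        for a in AA20:
            assert abs(joined.count(a) / n - 0.05) < 3 * se


class TestAcetylome:
    def test_full_detection_gives_full_replicate_overlap(self):
        res = synthetic.generate_acetylome(
            synthetic.generate_proteome(small_config()),
            small_config(detection_prob=1.0))
        ov = pairwise_replicate_overlaps(res.catalog)
        assert len(ov) > 0
        assert (ov.ratio_jaccard == 1.0).all()

    def test_pi_one_gives_single_site_per_protein(self):
        res = synthetic.generate_acetylome(
            synthetic.generate_proteome(small_config()),
            small_config(site_count_pi=1.0))
        per = res.truth.drop_duplicates(["protein_id", "position"]) \
                       .groupby("protein_id").size()
        assert (per == 1).all()

    def test_jaccard_overlap_matches_closed_form(self):
        """Independent per-replicate detection at rate q gives an expected
        Jaccard replicate overlap of q/(2-q)."""
        q = 0.9
        cfg = SyntheticConfig(seed=5, n_proteins=1200, frac_acetylated=0.8,
                              detection_prob=q)
        res = synthetic.generate_acetylome(
            synthetic.generate_proteome(cfg), cfg)
        assert res.truth.drop_duplicates(
            ["protein_id", "position"]).shape[0] >= 500
        ov = pairwise_replicate_overlaps(res.catalog)
        expected = q / (2 - q)
        mean = ov.ratio_jaccard.mean()
        se = ov.ratio_jaccard.std(ddof=1) / np.sqrt(len(ov))
        assert abs(mean - expected) < 3 * max(se, 1e-3)

    def test_observed_sites_subset_of_truth_per_organ(self):
        res = synthetic.generate_acetylome(
            synthetic.generate_proteome(small_config()), small_config())
        truth = {(r.protein_id, r.position, r.organ)
                 for r in res.truth.itertuples()}
        obs = {(r.protein_id, r.position, r.organ)
               for r in res.catalog.frame.itertuples()}
        assert obs <= truth

    def test_catalog_validates_against_edited_proteome(self):
        # SiteCatalog.from_frame inside the generator enforces residue
        # identity, so flank editing must never clobber a chosen K
        res = synthetic.generate_acetylome(
            synthetic.generate_proteome(small_config()), small_config())
        for key in res.catalog.site_keys():
            assert res.proteome[key.protein_id].sequence[key.position - 1] == "K"

    def test_byte_identical_catalog_under_seed(self):
        cfg = small_config()
        r1 = synthetic.generate_acetylome(
            synthetic.generate_proteome(cfg), cfg)
        r2 = synthetic.generate_acetylome(
            synthetic.generate_proteome(small_config()), small_config())
        pd.testing.assert_frame_equal(r1.catalog.frame, r2.catalog.frame)

    def test_plus_one_bias_present(self):
        """The +1 flank of chosen sites is enriched for R/K/N/H."""
        cfg = small_config(n_proteins=400)
        res = synthetic.generate_acetylome(
            synthetic.generate_proteome(cfg), cfg)
        plus1 = []
        for key in res.catalog.site_keys():
            seq = res.proteome[key.protein_id].sequence
            if key.position < len(seq):
                plus1.append(seq[key.position])
        frac = sum(c in "RKNH" for c in plus1) / len(plus1)
        background = sum(cfg.aa_frequencies[c] for c in "RKNH")
        assert frac > 1.5 * background


class TestExpression:
    def test_huge_alpha_approaches_max_entropy(self):
        cfg = small_config(entropy_alpha_kac=1e6, n_samples=158)
        expr = synthetic.generate_expression(["g1", "g2"], [True, True], cfg)
        table = entropy_table(expr, {"g1", "g2"})
        assert np.allclose(table.entropy, np.log2(158), atol=0.01)
        assert round(float(table.entropy.iloc[0]), 1) == 7.3

    def test_alpha_contrast_separates_groups(self):
        from scipy.stats import mannwhitneyu
        cfg = small_config(entropy_alpha_kac=5.0, entropy_alpha_non=0.5)
        genes = [f"g{i}" for i in range(400)]
        flags = [i < 200 for i in range(400)]
        expr = synthetic.generate_expression(genes, flags, cfg)
        table = entropy_table(expr, set(genes[:200]))
        kac = table[table.is_kac].entropy
        non = table[~table.is_kac].entropy
        assert kac.median() > non.median()
        assert mannwhitneyu(kac, non).pvalue < 0.01

    def test_flag_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_expression(["g1"], [True, False],
                                          small_config())


class TestPtmSites:
    def test_zero_exclusion_factor_blocks_coacetylation(self):
        cfg = small_config(ack_exclusion=0.0, ub_rate=0.3, sumo_rate=0.3)
        proteome = synthetic.generate_proteome(cfg)
        res = synthetic.generate_acetylome(proteome, cfg)
        others = synthetic.generate_ptm_sites(
            res.proteome, res.truth_keys_by_protein(), cfg)
        ack = {SiteKey(r.protein_id, r.position)
               for r in res.truth.itertuples()}
        for ptm in ("ubiquitin", "sumo"):
            assert not (others.site_keys(ptm_type=ptm) & ack)

    def test_phospho_rate_at_d1_matches_formula(self):
        """Empirical phospho rate next to an acK matches p0 + a*exp(-1/lam)."""
        cfg = SyntheticConfig(seed=7, n_proteins=1500, frac_acetylated=0.9,
                              phospho_base=0.05, phospho_boost=0.3,
                              phospho_decay=3.0)
        proteome = synthetic.generate_proteome(cfg)
        res = synthetic.generate_acetylome(proteome, cfg)
        truth = res.truth_keys_by_protein()
        others = synthetic.generate_ptm_sites(res.proteome, truth, cfg)
        phos = others.site_keys(ptm_type="phospho")
        num = den = 0
        for pid, positions in truth.items():
            seq = res.proteome[pid].sequence
            for pos in positions:
                for j in (pos - 1, pos + 1):
                    if 1 <= j <= len(seq) and seq[j - 1] in "STY":
                        den += 1
                        num += SiteKey(pid, j) in phos
        expected = 0.05 + 0.3 * np.exp(-1 / 3.0)
        se = np.sqrt(expected * (1 - expected) / den)
        assert den > 200
        assert abs(num / den - expected) < 3 * se

    def test_no_boost_means_flat_rate(self):
        cfg = small_config(phospho_boost=0.0, phospho_base=0.2,
                           n_proteins=300)
        proteome = synthetic.generate_proteome(cfg)
        res = synthetic.generate_acetylome(proteome, cfg)
        others = synthetic.generate_ptm_sites(
            res.proteome, res.truth_keys_by_protein(), cfg)
        sty = sum(p.sequence.count(c) for p in res.proteome.values()
                  for c in "STY")
        rate = len(others.site_keys(ptm_type="phospho")) / sty
        assert abs(rate - 0.2) < 3 * np.sqrt(0.2 * 0.8 / sty)


class TestAlignments:
    def test_rho_one_conserves_every_ack_column(self):
        cfg = small_config(rho_ac=1.0, gap_rate=0.0)
        proteome = synthetic.generate_proteome(cfg)
        res = synthetic.generate_acetylome(proteome, cfg)
        truth = res.truth_keys_by_protein()
        alns = synthetic.generate_alignments(res.proteome, truth, cfg,
                                             protein_ids=sorted(truth))
        records = classify_all(alns, truth)
        assert all(r.conserved for r in records if r.is_ack)

    def test_substitution_alphabet_respected(self):
        cfg = small_config(k_subst_alphabet=("Q",))
        proteome = synthetic.generate_proteome(cfg)
        res = synthetic.generate_acetylome(proteome, cfg)
        truth = res.truth_keys_by_protein()
        alns = synthetic.generate_alignments(res.proteome, truth, cfg,
                                             protein_ids=sorted(truth))
        records = classify_all(alns, truth)
        seen = set()
        for r in records:
            seen |= set(r.substitutions)
        assert seen <= {"Q"}

    def test_conserved_fractions_recovered(self):
        """rho_ac / rho_non are recovered within +-0.03 at >= 2000 lysines
        per class."""
        cfg = SyntheticConfig(seed=13, n_proteins=1500, frac_acetylated=0.9,
                              site_count_pi=0.4)
        proteome = synthetic.generate_proteome(cfg)
        res = synthetic.generate_acetylome(proteome, cfg)
        truth = res.truth_keys_by_protein()
        alns = synthetic.generate_alignments(res.proteome, truth, cfg,
                                             protein_ids=sorted(truth))
        records = classify_all(alns, truth)
        contrast = conservation_contrast(records)
        n_ack = contrast.table[0].sum()
        n_non = contrast.table[1].sum()
        assert n_ack >= 2000 and n_non >= 2000
        assert abs(contrast.frac_ack_conserved - cfg.rho_ac) < 0.03
        assert abs(contrast.frac_non_conserved - cfg.rho_non) < 0.03
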