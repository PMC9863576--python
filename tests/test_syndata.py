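"""Generator properties: divergence, determinism, planted-effect recovery."""

import numpy as np
import pandas as pd
import pytest

from medscan.genio import MISSING
from medscan.syndata import (InvalidConfigError, PlantedEffect, SimConfig,
                             simulate_annotation_expression, simulate_climate,
                             simulate_phenology, simulate_population)


def weir_cockerham_fst(calls, subpops):
    """Textbook two-level Weir-Cockerham theta over markers (oracle).

    Direct implementation of the variance-component estimator for
    haplotype counts from diploid genotype codes, independent of the
    generator internals.
    """
    labels = np.unique(subpops)
    r = len(labels)
    a_sum = b_sum = 0.0
    for j in range(calls.shape[1]):
        c = calls[:, j]
        ns, ps = [], []
        for lab in labels:
            cc = c[(subpops == lab) & (c != MISSING)]
            if len(cc) == 0:
                continue
            ns.append(2 * len(cc))
            ps.append(cc.sum() / (2 * len(cc)))
        if len(ns) < 2:
            continue
        ns = np.array(ns, float)
        ps = np.array(ps, float)
        n_bar = ns.mean()
        p_bar = (ns * ps).sum() / ns.sum()
        nc = (ns.sum() - (ns**2).sum() / ns.sum()) / (r - 1)
        s2 = (ns * (ps - p_bar) ** 2).sum() / ((r - 1) * n_bar)
        # Weir-Cockerham components at the allele (haplotype) level
        a = (n_bar / nc) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - (r - 1) / r * s2)
        a_sum += a
        b_sum += b
    return a_sum / (a_sum + b_sum)


class TestSimulatePopulation:
    def test_determinism(self):
        cfg = SimConfig(n_accessions=40, n_markers=120, seed=7)
        G1, m1, map1 = simulate_population(cfg)
        G2, m2, map2 = simulate_population(cfg)
        assert G1 == G2
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(map1, map2)

    def test_fst_zero_no_divergence(self):
        cfg = SimConfig(n_accessions=600, n_markers=300, fst=0.0,
                        admix_fraction=0.0, seed=5)
        G, meta, _ = simulate_population(cfg)
        sp = meta["subpop"].to_numpy()
        diffs = []
        for j in range(G.n_markers):
            fr = [G.calls[sp == s, j].mean() / 2 for s in np.unique(sp)]
            diffs.append(np.ptp(fr))
        assert np.mean(diffs) < 0.08  # sampling noise only at n=600

    def test_fst_matches_weir_cockerham_oracle(self):
        cfg = SimConfig(n_accessions=150, n_markers=5000, fst=0.10,
                        admix_fraction=0.0, seed=13)
        G, meta, _ = simulate_population(cfg)
        est = weir_cockerham_fst(G.calls, meta["subpop"].to_numpy())
        assert est == pytest.approx(0.10, abs=0.02)

    def test_map_strictly_increasing(self):
        cfg = SimConfig(n_accessions=10, n_markers=200, seed=3)
        _, _, mmap = simulate_population(cfg)
        for _, sub in mmap.groupby("chrom"):
            assert (np.diff(sub["cm"]) > 0).all()
            assert (np.diff(sub["bp"]) > 0).all()

    def test_countries_come_from_subpop_pool(self):
        from medscan.syndata import DEFAULT_COUNTRY_POOLS
        cfg = SimConfig(n_accessions=60, n_markers=60, seed=1)
        _, meta, _ = simulate_population(cfg)
        for sp, pool in DEFAULT_COUNTRY_POOLS.items():
            got = set(meta.loc[meta["subpop"] == sp, "country"])
            assert got <= set(pool)

    def test_too_few_markers_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimConfig(n_accessions=10, n_markers=5, n_chromosomes=21)

    def test_invalid_fst_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimConfig(fst=1.0)

    def test_ld_mode_neighbour_correlation(self):
        cfg = SimConfig(n_accessions=200, n_markers=300, n_chromosomes=3,
                        fst=0.0, admix_fraction=0.0, ld_scale_cm=50.0, seed=9)
        G, _, mmap = simulate_population(cfg)
        x = G.dosage()
        cors = []
        for _, sub in mmap.groupby("chrom"):
            idx = sub.index.to_numpy()
            for a, b in zip(idx[:-1], idx[1:]):
                if mmap.loc[b, "cm"] - mmap.loc[a, "cm"] < 2.0:
                    va, vb = x[:, a], x[:, b]
                    if va.std() > 0 and vb.std() > 0:
                        cors.append(np.corrcoef(va, vb)[0, 1])
        assert np.mean(cors) > 0.5  # close markers strongly correlated


class TestSimulatePhenology:
    def test_h2_one_no_field_effects_equals_genetic_score(self, small_panel):
        G, _, _ = small_panel
        eff = [PlantedEffect(G.marker_ids[10], "D65", effect_size=2.0)]
        plots = simulate_phenology(G, eff, h2=1.0, years=1, seed=0,
                                   year_sd=0.0, row_sd=0.0, col_sd=0.0)
        x = G.dosage()[:, 10]
        score = 2.0 * (x - x.mean())
        acc = plots[~plots["is_check"]].set_index("genotype_id")
        got = acc.loc[G.accession_ids, "value"].to_numpy()
        np.testing.assert_allclose(got, score, atol=1e-10)

    def test_ols_recovers_planted_beta(self, small_panel):
        """OLS slope of phenotype on the planted marker averages to beta
        over replicate seeds (Monte-Carlo oracle)."""
        G, _, _ = small_panel
        j = 20
        beta = 1.5
        x = G.dosage()[:, j]
        slopes = []
        for seed in range(100):
            plots = simulate_phenology(
                G, [PlantedEffect(G.marker_ids[j], "t", effect_size=beta)],
                h2=0.5, years=1, seed=seed, year_sd=0.0, row_sd=0.0, col_sd=0.0)
            y = plots[~plots["is_check"]].set_index("genotype_id") \
                .loc[G.accession_ids, "value"].to_numpy()
            slopes.append(np.polyfit(x, y, 1)[0])
        se = np.std(slopes) / np.sqrt(len(slopes))
        assert np.mean(slopes) == pytest.approx(beta, abs=4 * se + 0.02)

    def test_zero_effects_uncorrelated_with_markers(self, small_panel):
        """With no planted or background genetics the phenotype is pure
        noise: max |r| stays below a Bonferroni-style null envelope."""
        G, _, _ = small_panel
        plots = simulate_phenology(G, [], h2=0.5, years=1, seed=4,
                                   n_background=0, year_sd=0.0,
                                   row_sd=0.0, col_sd=0.0)
        y = plots[~plots["is_check"]].set_index("genotype_id") \
            .loc[G.accession_ids, "value"].to_numpy()
        x = G.dosage()
        xc = (x - x.mean(0))
        sd = xc.std(0)
        ok = sd > 0
        r = (xc[:, ok] / sd[ok]).T @ ((y - y.mean()) / y.std()) / len(y)
        # null envelope: |r| < z_{1 - 0.5*0.05/m} / sqrt(n)
        from scipy.stats import norm
        bound = norm.isf(0.5 * 0.05 / ok.sum()) / np.sqrt(len(y))
        assert np.abs(r).max() < bound

    def test_check_ratio_and_layout_error(self, small_panel):
        G, _, _ = small_panel
        plots = simulate_phenology(G, [], h2=0.5, years=2, seed=0)
        per_year = plots[plots["year"] == plots["year"].min()]
        assert per_year["is_check"].sum() == G.n_accessions // 5
        with pytest.raises(InvalidConfigError, match="too small"):
            simulate_phenology(G, [], h2=0.5, years=1, field_layout=(2, 2), seed=0)


class TestSimulateClimate:
    @pytest.fixture
    def meta(self, small_panel):
        return small_panel[1]

    def test_zero_noise_identical_within_subpop(self, meta):
        clim = simulate_climate(meta, country_noise_sd=0.0, seed=0)
        merged = clim.merge(meta[["country", "subpop"]].drop_duplicates(), on="country")
        for (_, _, _), sub in merged.groupby(["subpop", "variable", "period"]):
            assert sub["value"].nunique() == 1

    def test_subpop_separation_significant(self, meta):
        from scipy.stats import f_oneway
        clim = simulate_climate(meta, country_noise_sd=0.2, seed=1)
        merged = clim.merge(meta[["country", "subpop"]].drop_duplicates(), on="country")
        sub = merged[(merged["variable"] == "Tmax") & (merged["period"] == "SA")]
        groups = [g["value"].to_numpy() for _, g in sub.groupby("subpop")]
        stat = f_oneway(*groups)
        assert stat.pvalue < 1e-3

    def test_determinism(self, meta):
        c1 = simulate_climate(meta, seed=42)
        c2 = simulate_climate(meta, seed=42)
        pd.testing.assert_frame_equal(c1, c2)

    def test_unknown_period_rejected(self, meta):
        bad = pd.DataFrame({"subpop": ["SP1"], "variable": ["Tmax"],
                            "period": ["WINTER"], "value": [1.0]})
        with pytest.raises(ValueError, match="unknown period"):
            simulate_climate(meta, sp_means=bad)


class TestAnnotationExpression:
    def test_planted_degs_exactly_recovered(self, small_panel):
        from medscan.candgenes import deg_filter
        _, _, mmap = small_panel
        ann, expr = simulate_annotation_expression(
            mmap, n_genes=100, stress_up_fraction=0.10,
            delta_tpm_range=(5.0, 5.0), seed=21)
        cands = deg_filter(ann, expr)
        # exactly the ten genes planted with delta 5 pass the > 2 tpm rule
        planted = set()
        wide = expr.pivot_table(index=["gene_id", "tissue"], columns="condition",
                                values="tpm")
        planted = set(wide[wide["stress"] - wide["control"] > 2.0]
                      .index.get_level_values(0))
        assert {c.gene_id for c in cands} == planted
        assert len(planted) == 10

    def test_zero_up_fraction_selects_nothing(self, small_panel):
        from medscan.candgenes import deg_filter
        _, _, mmap = small_panel
        ann, expr = simulate_annotation_expression(
            mmap, n_genes=50, stress_up_fraction=0.0, seed=2)
        assert deg_filter(ann, expr) == []

    def test_gene_intervals_valid(self, small_panel):
        _, _, mmap = small_panel
        ann, _ = simulate_annotation_expression(mmap, n_genes=80, seed=3)
        assert (ann["start"] >= 1).all()
        assert (ann["start"] <= ann["end"]).all()
        for _, sub in ann.groupby("chrom"):
            assert sub["start"].is_monotonic_increasing

    def test_invalid_n_genes(self, small_panel):
        _, _, mmap = small_panel
        with pytest.raises(InvalidConfigError):
            simulate_annotation_expression(mmap, n_genes=0)
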