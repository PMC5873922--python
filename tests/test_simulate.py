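"""Synthetic panel generator: determinism, inbreeding behavior, depth
artifacts, phenotype planting, and neutral-theory sanity checks."""

import numpy as np
import pytest

from inbredpanel import (
    MISSING,
    MonomorphicSimulationError,
    PanelError,
    SimConfig,
    effect_for_variance_fraction,
    found_and_inbreed_lines,
    het_depth_association,
    per_line_heterozygosity,
    per_site_heterozygosity,
    plant_phenotypes,
    simulate_base_population,
    simulate_depth_and_artifacts,
    simulate_panel,
    window_tajimas_d,
)
from inbredpanel.diversity import folded_sfs


def small_cfg(**kw):
    base = dict(n_lines=20, sequence_length=10_000, seed=1)
    base.update(kw)
    return SimConfig(**base)


class TestBasePopulation:
    def test_zero_mutation_rate_errors(self):
        with pytest.raises(MonomorphicSimulationError, match="theta"):
            simulate_base_population(small_cfg(mutation_rate=0.0))

    def test_fixed_seed_determinism(self):
        a = simulate_base_population(small_cfg())
        b = simulate_base_population(small_cfg())
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.haplotypes, b.haplotypes)

    def test_different_seeds_differ(self):
        a = simulate_base_population(small_cfg())
        b = simulate_base_population(small_cfg(seed=2))
        assert not (
            a.haplotypes.shape == b.haplotypes.shape
            and np.array_equal(a.haplotypes, b.haplotypes)
        )

    def test_constant_size_sfs_singleton_dominated_and_d_near_zero(self):
        """Stationary constant-size variation: singletons are the largest
        folded-SFS class and replicate-mean windowed Tajima's D ≈ 0."""
        ds = []
        single_frac = []
        for s in range(6):
            cfg = SimConfig(
                n_lines=30, sequence_length=20_000, seed=100 + s,
                expansion_factor=1.0, inbreeding_generations=0,
            )
            pool = simulate_base_population(cfg)
            gm, _ = found_and_inbreed_lines(pool, cfg)
            td = window_tajimas_d(gm, window_bp=20_000)["value"]
            ds.append(np.nanmean(td))
            sfs = folded_sfs(gm)
            singles = sfs.loc[sfs["singleton"], "count"].sum()
            counts = sfs.loc[~sfs["singleton"]].groupby("maf_low")["count"].sum()
            single_frac.append(singles >= counts.max())
        mean_d, se = np.mean(ds), np.std(ds, ddof=1) / np.sqrt(len(ds))
        assert abs(mean_d) < max(2 * se, 0.3)
        assert all(single_frac)

    def test_subpopulation_labels_cover_pool(self):
        cfg = small_cfg(n_subpops=2, divergence_generations=300)
        pool = simulate_base_population(cfg)
        assert set(pool.pop_labels) == {0, 1}


class TestInbreedLines:
    def test_zero_generations_emits_founder_heterozygosity(self):
        cfg = small_cfg(inbreeding_generations=0)
        pool = simulate_base_population(cfg)
        gm, truth = found_and_inbreed_lines(pool, cfg, drop_monomorphic=False)
        # founder females are outbred draws from the pool: het well above
        # anything surviving 20 generations of sib mating
        h0 = np.nanmean(per_line_heterozygosity(gm))
        cfg20 = small_cfg(inbreeding_generations=20)
        gm20, _ = found_and_inbreed_lines(pool, cfg20, drop_monomorphic=False)
        h20 = np.nanmean(per_line_heterozygosity(gm20))
        assert h0 > 20 * h20 > 0

    def test_determinism(self):
        cfg = small_cfg()
        pool = simulate_base_population(cfg)
        a, _ = found_and_inbreed_lines(pool, cfg)
        b, _ = found_and_inbreed_lines(pool, cfg)
        assert np.array_equal(a.genotypes, b.genotypes)

    def test_retention_matches_fullsib_recurrence(self):
        """Mean het(t=20)/het(t=0) ≈ 1 - F_20 within Monte-Carlo CI."""
        from inbredpanel import fullsib_inbreeding_coefficient

        cfg0 = SimConfig(n_lines=120, sequence_length=20_000, seed=9,
                         inbreeding_generations=0)
        pool = simulate_base_population(cfg0)
        gm0, _ = found_and_inbreed_lines(pool, cfg0, drop_monomorphic=False)
        cfg20 = SimConfig(n_lines=120, sequence_length=20_000, seed=9,
                          inbreeding_generations=20)
        gm20, _ = found_and_inbreed_lines(pool, cfg20, drop_monomorphic=False)
        h0 = per_line_heterozygosity(gm0)
        h20 = per_line_heterozygosity(gm20)
        retention = np.nanmean(h20) / np.nanmean(h0)
        se = np.nanstd(h20, ddof=1) / np.sqrt(len(h20)) / np.nanmean(h0)
        expected = 1 - fullsib_inbreeding_coefficient(20)
        assert abs(retention - expected) < max(4 * se, 0.006)

    def test_per_line_generations(self):
        gens = [17] * 5 + [20] * 15
        cfg = small_cfg(inbreeding_generations=gens)
        pool = simulate_base_population(cfg)
        _, truth = found_and_inbreed_lines(pool, cfg)
        assert truth.generations == gens

    def test_negative_generations_rejected(self):
        with pytest.raises(PanelError):
            small_cfg(inbreeding_generations=-1)

    def test_monomorphic_sites_dropped_by_default(self):
        cfg = small_cfg()
        pool = simulate_base_population(cfg)
        gm, _ = found_and_inbreed_lines(pool, cfg)
        maf = gm.maf()
        het_only = (gm.genotypes == 1).any(axis=0)
        assert np.all((maf[np.isfinite(maf)] > 0) | het_only[np.isfinite(maf)])


class TestDepthAndArtifacts:
    def test_depth_reproducible_and_near_target(self):
        cfg = small_cfg()
        pool = simulate_base_population(cfg)
        gm, _ = found_and_inbreed_lines(pool, cfg)
        a = simulate_depth_and_artifacts(gm, cfg)
        b = simulate_depth_and_artifacts(gm, cfg)
        assert np.array_equal(a.depths, b.depths)
        assert a.depths.mean() == pytest.approx(23.5, rel=0.05)

    def test_no_artifacts_no_het_depth_association(self):
        cfg = SimConfig(n_lines=60, sequence_length=30_000, seed=4)
        pool = simulate_base_population(cfg)
        gm, _ = found_and_inbreed_lines(pool, cfg)
        gm = simulate_depth_and_artifacts(gm, cfg)
        rho, _ = het_depth_association(
            per_site_heterozygosity(gm), gm.depth_summary("mean")
        )
        assert abs(rho) < 0.1

    def test_artifact_interval_creates_positive_association(self):
        cfg = SimConfig(
            n_lines=60, sequence_length=30_000, seed=4,
            duplication_artifact=[(0, 1500, 2.0)], artifact_het_fraction=0.3,
        )
        pool = simulate_base_population(cfg)
        gm, truth = found_and_inbreed_lines(pool, cfg)
        gm = simulate_depth_and_artifacts(gm, cfg, truth=truth)
        rho, p = het_depth_association(
            per_site_heterozygosity(gm), gm.depth_summary("mean")
        )
        assert rho > 0 and p < 0.05
        assert truth.artifact_sites is not None and truth.artifact_sites.any()

    def test_negative_multiplier_rejected(self):
        with pytest.raises(PanelError):
            small_cfg(duplication_artifact=[(0, 100, -1.0)])


class TestPhenotypes:
    def test_null_phenotypes_iid(self):
        cfg = small_cfg(h2_polygenic=0.0)
        pool = simulate_base_population(cfg)
        gm, truth = found_and_inbreed_lines(pool, cfg)
        ph = plant_phenotypes(gm, truth, cfg)
        y = np.log(ph.data["focal"] / ph.data["divisor"])
        assert truth.sigma2_a == 0.0
        assert y.std() == pytest.approx(1.0, rel=0.25)

    def test_causal_below_maf_floor_rejected(self):
        cfg = small_cfg()
        pool = simulate_base_population(cfg)
        gm, truth = found_and_inbreed_lines(pool, cfg)
        maf = gm.maf()
        rare = int(np.argmin(np.where(np.isfinite(maf), maf, np.inf)))
        assert maf[rare] < 0.05
        cfg.causal_snps = [(rare, 0.5, "focal")]
        with pytest.raises(PanelError, match="MAF floor"):
            plant_phenotypes(gm, truth, cfg)

    def test_causal_snp_recorded_in_truth(self):
        cfg = small_cfg()
        pool = simulate_base_population(cfg)
        gm, truth = found_and_inbreed_lines(pool, cfg)
        cfg.causal_snps = [("random", 0.4, "focal")]
        plant_phenotypes(gm, truth, cfg)
        assert len(truth.causal) == 1
        assert truth.causal[0]["pos"] in set(gm.sites["pos"])

    def test_determinism(self):
        cfg = small_cfg()
        panel_a = simulate_panel(cfg)
        panel_b = simulate_panel(cfg)
        assert panel_a.phenotypes.data.equals(panel_b.phenotypes.data)
        assert np.array_equal(panel_a.gm.genotypes, panel_b.gm.genotypes)

    def test_effect_sizing_helper(self):
        gm, _ = found_and_inbreed_lines(
            simulate_base_population(small_cfg()), small_cfg()
        )
        maf = gm.maf()
        site = int(np.nanargmax(maf))
        beta = effect_for_variance_fraction(gm, site, 0.5)
        g = gm.genotypes[:, site].astype(float)
        g = g[g != MISSING]
        assert (beta**2) * g.var() == pytest.approx(0.5, rel=1e-9)


def test_truth_tsv_roundtrippable_text(tmp_path):
    panel = simulate_panel(SimConfig(n_lines=5, sequence_length=4_000, seed=3,
                                     causal_snps=[("random", 0.3, "focal")]))
    path = tmp_path / "truth.tsv"
    panel.truth.to_tsv(path)
    text = path.read_text()
    assert "#section\tlines" in text and "#section\tcausal" in text
    assert "line001" in text
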