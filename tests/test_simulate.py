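"""The synthetic RRBS generator: genome, coverage, counts and truth."""

import numpy as np
import pandas as pd
import pytest

from rrbsdiff.annotation import assign_contexts
from rrbsdiff.dms import ComparisonSpec, call_dms
from rrbsdiff.io import assemble_matrix, read_coverage_file, read_design
from rrbsdiff.simulate import (
    CapacityError,
    EffectSpec,
    SimulationConfig,
    SizingError,
    build_design,
    build_genome,
    emit_dataset,
    fragment_covered_mask,
    simulate_dataset,
    simulate_methylation,
    simulate_rrbs_coverage,
)


class TestConfigValidation:
    def test_fragment_window_outside_detectable_range(self):
        with pytest.raises(ValueError, match="50-1200"):
            SimulationConfig(seed=1, fragment_size_window=(40, 1200))
        with pytest.raises(ValueError, match="50-1200"):
            SimulationConfig(seed=1, fragment_size_window=(50, 1500))

    def test_depth_floor(self):
        with pytest.raises(ValueError, match="mean_depth"):
            SimulationConfig(seed=1, mean_depth=5)

    def test_effect_bounds(self):
        with pytest.raises(ValueError, match="delta"):
            SimulationConfig(
                seed=1, effect_table=(EffectSpec("LDOPA", -140.0, "any", 1),)
            )
        with pytest.raises(ValueError, match="unknown groups"):
            SimulationConfig(
                seed=1, effect_table=(EffectSpec("NOPE", -40.0, "any", 1),)
            )


class TestBuildGenome:
    def test_no_features_means_all_intergenic_open_sea(self):
        cfg = SimulationConfig(seed=3, n_genes=0, n_cgis=0)
        genome = build_genome(cfg)
        ctx = assign_contexts(genome.cpgs, genome.annotation)
        assert (ctx["gene_context"] == "intergenic").all()
        assert (ctx["cpg_context"] == "other").all()

    def test_deterministic_under_seed(self, tmp_path):
        ds1 = simulate_dataset(SimulationConfig(seed=17))
        ds2 = simulate_dataset(SimulationConfig(seed=17))
        emit_dataset(ds1, tmp_path / "a")
        emit_dataset(ds2, tmp_path / "b")
        for f in sorted((tmp_path / "a").rglob("*")):
            if f.is_file():
                twin = tmp_path / "b" / f.relative_to(tmp_path / "a")
                assert f.read_bytes() == twin.read_bytes(), f.name

    def test_default_config_populates_all_six_context_classes(self):
        genome = build_genome(SimulationConfig(seed=4))
        ctx = assign_contexts(genome.cpgs, genome.annotation)
        for cls in ("promoter", "exon", "intron", "intergenic"):
            assert (ctx["gene_context"] == cls).any(), cls
        for cls in ("cpg_island", "cpg_shore", "other"):
            assert (ctx["cpg_context"] == cls).any(), cls

    def test_chromosome_too_short_raises_sizing_error(self):
        with pytest.raises(SizingError, match="too short"):
            build_genome(SimulationConfig(seed=1, chrom_length=50_000, n_genes=20))

    def test_genes_have_tss_exons_strand(self):
        genome = build_genome(SimulationConfig(seed=4))
        genes = genome.annotation.genes
        assert genes["strand"].isin(["+", "-"]).all()
        assert set(genome.annotation.exons["gene_id"]) == set(genes["gene_id"])
        exp_tss = np.where(genes["strand"] == "-", genes["end"] - 1, genes["start"])
        np.testing.assert_array_equal(genes["tss"], exp_tss)


class TestCoverage:
    def test_size_selection_window(self):
        cfg = SimulationConfig(seed=6)
        genome = build_genome(cfg)
        cov = simulate_rrbs_coverage(genome, cfg, 4)
        covered = ~np.isnan(cov).all(axis=1)
        mask = fragment_covered_mask(genome, cfg)
        np.testing.assert_array_equal(covered, mask)
        # CpGs on out-of-window fragments carry zero coverage in all samples
        lo, hi = cfg.fragment_size_window
        for chrom, sub in genome.cpgs.groupby("chrom"):
            cc = genome.ccgg[chrom]
            pos = sub["pos"].to_numpy()
            idx = np.searchsorted(cc, pos, side="right") - 1
            interior = (idx >= 0) & (idx < len(cc) - 1)
            safe = np.clip(idx, 0, len(cc) - 2)
            frag_len = np.where(interior, cc[safe + 1] - cc[safe], -1)
            off_window = interior & ((frag_len < lo) | (frag_len > hi))
            assert not mask[sub.index[off_window]].any()
            in_window = interior & (frag_len >= lo) & (frag_len <= hi)
            assert mask[sub.index[in_window]].all()

    def test_long_fragment_interior_uncovered(self):
        """A fragment longer than the selection window yields no reads."""
        cfg = SimulationConfig(seed=6)
        genome = build_genome(cfg)
        # fabricate a 1500 bp fragment by thinning CCGG sites on chr1
        cc = genome.ccgg["chr1"]
        keep = [cc[0]]
        for c in cc[1:]:
            if c - keep[-1] >= 1500:
                keep.append(c)
        genome.ccgg["chr1"] = np.array(keep)
        mask = fragment_covered_mask(genome, cfg)
        chr1 = genome.cpgs["chrom"] == "chr1"
        interior = (
            (genome.cpgs["pos"] >= keep[0]) & (genome.cpgs["pos"] < keep[-1]) & chr1
        )
        assert not mask[interior.to_numpy()].any()

    def test_mean_depth_within_ten_percent(self):
        cfg = SimulationConfig(seed=8, mean_depth=30)
        genome = build_genome(cfg)
        cov = simulate_rrbs_coverage(genome, cfg, 2)
        observed = np.nanmean(cov)
        assert observed == pytest.approx(30, rel=0.10)
        assert np.nanmin(cov) >= 1  # covered fragments always yield a read


class TestMethylation:
    def test_null_simulation_empty_truth_equal_group_means(self, null_dataset):
        assert len(null_dataset.truth) == 0
        m = null_dataset.matrix
        d = null_dataset.design
        with np.errstate(invalid="ignore"):
            level = np.nansum(m.meth, axis=0) / np.nansum(m.cov, axis=0)
        by_group = pd.Series(level, index=m.samples).groupby(
            d.table.set_index("sample")["group"]
        ).mean()
        assert by_group.max() - by_group.min() < 0.02

    def test_conservation_meth_bounded_by_coverage(self, effects_dataset):
        m = effects_dataset.matrix
        obs = ~np.isnan(m.cov)
        assert (m.meth[obs] >= 0).all()
        assert (m.meth[obs] <= m.cov[obs]).all()

    def test_effect_spec_respected_in_truth(self):
        cfg = SimulationConfig(
            seed=12,
            effect_table=(EffectSpec("LDOPA", -40.0, "open_sea", 50),),
        )
        ds = simulate_dataset(cfg)
        truth = ds.truth
        assert len(truth) == 50
        assert (truth["cpg_context"] == "other").all()
        assert (truth["delta"] < 0).all()
        # every truth position exists in the CpG map
        key = set(zip(ds.genome.cpgs["chrom"], ds.genome.cpgs["pos"]))
        assert all((c, p) in key for c, p in zip(truth["chrom"], truth["pos"]))

    def test_capacity_error_when_region_exhausted(self):
        cfg = SimulationConfig(seed=12)
        genome = build_genome(cfg)
        cov = simulate_rrbs_coverage(genome, cfg)
        big = SimulationConfig(
            seed=12,
            effect_table=(EffectSpec("LDOPA", -40.0, "promoter", 10_000),),
        )
        with pytest.raises(CapacityError, match="10000 sites"):
            simulate_methylation(genome, cov, big)

    def test_hemispheres_are_near_identical_replicates(self, effects_dataset):
        """Both striata of an animal share latent levels: tiny side difference."""
        m = effects_dataset.matrix
        d = effects_dataset.design.table.set_index("sample")
        with np.errstate(invalid="ignore"):
            frac = m.meth / m.cov
        for animal in d["animal"].unique():
            pair = d.index[d["animal"] == animal]
            i, j = (m.samples.index(s) for s in pair)
            both = ~np.isnan(frac[:, i]) & ~np.isnan(frac[:, j])
            r = np.corrcoef(frac[both, i], frac[both, j])[0, 1]
            assert r > 0.9

    def test_neighbor_sites_share_effect_direction(self):
        """Injected CpGs 60 bp apart in one latent region co-direct in
        almost all replicates, mirroring co-methylation of close CpGs."""
        import rrbsdiff.simulate as sim

        same_sign = 0
        n_rep = 200
        for s in range(n_rep):
            rng = np.random.default_rng(s)
            # two CpGs, one region, baseline 0.8, delta -40 on group B
            region_p = 0.8
            rho = 0.01
            deltas = np.array([-0.4, -0.4])
            diffs = []
            for grp, shift in (("A", 0.0), ("B", None)):
                means = []
                for _animal in range(3):
                    a = region_p * (1 - rho) / rho
                    b = (1 - region_p) * (1 - rho) / rho
                    lat = rng.beta(a, b)
                    mu = np.clip(
                        lat + (deltas if shift is None else 0.0), 1e-3, 1 - 1e-3
                    )
                    mu = np.broadcast_to(mu, (2,))
                    means.append(rng.binomial(30, mu) / 30)
                diffs.append(np.mean(means, axis=0))
            realized = diffs[1] - diffs[0]
            if np.sign(realized[0]) == np.sign(realized[1]):
                same_sign += 1
        assert same_sign / n_rep >= 0.95


class TestEmit:
    def test_eighteen_sample_design_emits_eighteen_files(self, tmp_path, null_dataset):
        paths = emit_dataset(null_dataset, tmp_path)
        cov_files = list((tmp_path / "counts").glob("*.cov"))
        assert len(cov_files) == 18  # 3 groups x 3 animals x 2 hemispheres
        design = read_design(tmp_path / "design.tsv")
        assert len(design.samples) == 18

    def test_round_trip_reproduces_matrix(self, tmp_path, effects_dataset):
        emit_dataset(effects_dataset, tmp_path)
        per_sample = {
            p.stem: read_coverage_file(p)
            for p in sorted((tmp_path / "counts").glob("*.cov"))
        }
        design = read_design(tmp_path / "design.tsv")
        back = assemble_matrix(per_sample, design)
        m = effects_dataset.matrix
        covered = ~np.isnan(m.cov).all(axis=1)
        pd.testing.assert_frame_equal(
            back.sites, m.sites.loc[covered].reset_index(drop=True)
        )
        np.testing.assert_array_equal(back.meth, m.meth[covered])
        np.testing.assert_array_equal(back.cov, m.cov[covered])

    def test_percentage_column_consistent_with_counts(self, tmp_path, null_dataset):
        emit_dataset(null_dataset, tmp_path)
        f = sorted((tmp_path / "counts").glob("*.cov"))[0]
        raw = pd.read_csv(
            f, sep="\t", header=None,
            names=["chrom", "start", "end", "pct", "meth", "unmeth"],
        )
        expect = 100.0 * raw["meth"] / (raw["meth"] + raw["unmeth"])
        np.testing.assert_allclose(raw["pct"], expect, atol=5e-6)


def test_recovery_of_large_effects_3v3(effects_dataset):
    """Injected 40-point effects at 30x depth are mostly recovered with
    the correct sign in a 3-vs-3 comparison."""
    ds = effects_dataset
    d = ds.design
    spec = ComparisonSpec(
        "LDOPA_vs_UNT_ctrl",
        d.samples_of("UNT", "control"),
        d.samples_of("LDOPA", "control"),
    )
    rec = call_dms(ds.matrix, spec)
    truth = ds.truth[ds.truth["target_group"] == "LDOPA"]
    merged = truth.merge(rec, on=["chrom", "pos"], how="left")
    detected = merged["is_dms"].fillna(False)
    assert detected.mean() >= 0.70
    sign_ok = np.sign(merged.loc[detected, "delta"]) == np.sign(
        merged.loc[detected, "meth_diff"]
    )
    assert sign_ok.mean() >= 0.95
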