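"""F2 simulator: segregation ratios, linkage, bulk selection, read sampling."""

import numpy as np
import pytest
from scipy import stats

from bsaqtl import simdata
from bsaqtl.variants import filter_sites

from conftest import make_individuals


def test_no_variance_degenerate_case(small_genome):
    """With zero effects and zero noise every phenotype equals the baseline."""
    cfg = simdata.SimConfig(
        n_f2=50, qtl_chromosome="chr01", qtl_position=1_000_000,
        additive_effect=0.0, dominance_effect=0.0,
        polygenic_sd=0.0, env_sd=0.0, baseline=35.0, seed=7,
    )
    inds = simdata.simulate_f2(small_genome, cfg)
    assert all(ind.phenotype == 35.0 for ind in inds)


def test_selfing_segregation_ratio(small_genome):
    """QTL doses in a large F2 follow the 1:2:1 selfing expectation."""
    cfg = simdata.SimConfig(
        n_f2=10_000, qtl_chromosome="chr02", qtl_position=2_000_000,
        additive_effect=20.0, dominance_effect=0.0, seed=11,
    )
    inds = simdata.simulate_f2(small_genome, cfg)
    doses = np.array([ind.qtl_dose for ind in inds])
    counts = np.bincount(doses, minlength=3)
    chi2 = stats.chisquare(counts, f_exp=np.array([0.25, 0.5, 0.25]) * len(inds))
    assert chi2.pvalue > 0.01
    # an ordinary marker segregates the same way
    marker_doses = np.array([ind.genotype_at_markers["chr03"][5] for ind in inds])
    counts_m = np.bincount(marker_doses, minlength=3)
    assert stats.chisquare(counts_m, f_exp=np.array([0.25, 0.5, 0.25]) * len(inds)).pvalue > 0.01


def test_seed_determinism(small_genome, tmp_path):
    """Identical seeds give byte-identical simulated output (incl. the VCF)."""
    cfg = simdata.SimConfig(n_f2=40, qtl_chromosome="chr01", qtl_position=500_000, seed=5)
    runs = []
    for name in ("a.vcf", "b.vcf"):
        inds, L, S, sites = simdata.simulate_experiment(small_genome, cfg)
        simdata.write_vcf(sites, small_genome, tmp_path / name, cfg)
        runs.append((inds, (tmp_path / name).read_bytes()))
    (inds_a, vcf_a), (inds_b, vcf_b) = runs
    assert vcf_a == vcf_b
    assert [i.phenotype for i in inds_a] == [i.phenotype for i in inds_b]
    assert all(
        np.array_equal(a.genotype_at_markers[c], b.genotype_at_markers[c])
        for a, b in zip(inds_a, inds_b) for c in a.genotype_at_markers
    )


def test_invalid_configs_rejected(small_genome):
    with pytest.raises(ValueError):
        simdata.SimConfig(n_f2=0)
    with pytest.raises(ValueError):
        simdata.SimConfig(seq_error=0.7)
    cfg = simdata.SimConfig(qtl_chromosome="chr99")
    with pytest.raises(ValueError, match="QTL chromosome"):
        simdata.simulate_f2(small_genome, cfg)
    off = simdata.SimConfig(qtl_chromosome="chr01", qtl_position=10**9)
    with pytest.raises(ValueError, match="off chromosome"):
        simdata.simulate_f2(small_genome, off)


class TestSelectBulks:
    def _pop(self, phenos):
        return make_individuals({"chr01": (3, 1)}, phenos)

    def test_threshold_mode_filters_tails(self):
        inds = self._pop([10, 50, 15, 60, 30])
        long_ids, short_ids = simdata.select_bulks(inds, (20, 45), "threshold")
        phenos = {i.id: i.phenotype for i in inds}
        assert sorted(phenos[i] for i in short_ids) == [10, 15]
        assert sorted(phenos[i] for i in long_ids) == [50, 60]

    def test_top_n_mode(self):
        inds = self._pop([1, 2, 3])
        long_ids, short_ids = simdata.select_bulks(inds, (1, 1), "top_n")
        assert short_ids == [inds[0].id] and long_ids == [inds[2].id]

    def test_top_n_ties_break_by_id_order(self):
        inds = self._pop([5.0, 5.0, 5.0, 5.0])
        long_ids, short_ids = simdata.select_bulks(inds, (2, 2), "top_n")
        assert short_ids == [inds[0].id, inds[1].id]
        assert long_ids == [inds[2].id, inds[3].id]
        assert not set(long_ids) & set(short_ids)

    def test_errors(self):
        inds = self._pop([1, 2, 3])
        with pytest.raises(ValueError, match="overlap"):
            simdata.select_bulks(inds, (45, 20), "threshold")
        with pytest.raises(ValueError, match="population"):
            simdata.select_bulks(inds, (2, 2), "top_n")


class TestBulkReads:
    def test_fixed_bulk_all_reads_one_allele(self, small_genome):
        """A bulk fixed for dose 2 with no error puts every read on KG1."""
        n_markers = {c.name: len(small_genome.marker_positions[c.name])
                     for c in small_genome.chromosomes}
        fixed = make_individuals({c: (n, 2) for c, n in n_markers.items()}, [50.0] * 5)
        others = make_individuals({c: (n, 0) for c, n in n_markers.items()}, [10.0] * 5)
        for j, ind in enumerate(others):  # re-id the short bulk so ids are unique
            ind.id = f"S-{j}"
        pop = fixed + others
        cfg = simdata.SimConfig(n_f2=10, seq_error=0.0, depth_mean=20,
                                qtl_chromosome="chr01", qtl_position=100_000, seed=2)
        sites = simdata.simulate_bulk_reads(
            pop, [i.id for i in fixed], [i.id for i in others], small_genome, cfg
        )
        assert all(s.long_bulk_depths[1] == 0 for s in sites)
        assert all(s.short_bulk_depths[0] == 0 for s in sites)
        assert all(sum(s.long_bulk_depths) >= 1 for s in sites)

    def test_heterozygous_bulk_mean_index_near_half(self):
        """p = 0.5 with high depth: law of large numbers pins the mean index."""
        genome = simdata.GenomeMap(
            [simdata.Chromosome("chr01", 10_000_000, 100.0)],
            {"chr01": np.arange(1_000, 10_000_001, 1_000)[:10_000]},
        )
        het = make_individuals({"chr01": (10_000, 1)}, [30.0] * 20)
        short = make_individuals({"chr01": (10_000, 1)}, [30.0] * 20)
        for j, ind in enumerate(short):
            ind.id = f"S-{j}"
        cfg = simdata.SimConfig(n_f2=40, depth_mean=1_000, seq_error=0.0,
                                qtl_chromosome="chr01", qtl_position=5_000, seed=3)
        sites = simdata.simulate_bulk_reads(
            het + short, [i.id for i in het], [i.id for i in short], genome, cfg
        )
        idx = np.array([s.long_bulk_depths[0] / sum(s.long_bulk_depths) for s in sites])
        assert 0.49 < idx.mean() < 0.51

    def test_empty_bulk_rejected(self, small_genome):
        cfg = simdata.SimConfig(seed=1)
        with pytest.raises(ValueError, match="non-empty"):
            simdata.simulate_bulk_reads([], [], ["x"], small_genome, cfg)


def test_linkage_decay_with_genetic_distance():
    """Dose correlation between markers falls monotonically at 1, 10, 50 cM."""
    # 100 cM chromosome, markers at 0/1/10/50 cM equivalents
    genome = simdata.GenomeMap(
        [simdata.Chromosome("chr01", 10_000_000, 100.0)],
        {"chr01": np.array([100_000, 200_000, 1_100_000, 5_100_000])},
    )
    cfg = simdata.SimConfig(n_f2=5_000, additive_effect=0.0, qtl_chromosome="chr01",
                            qtl_position=100_000, seed=13)
    inds = simdata.simulate_f2(genome, cfg)
    doses = np.array([ind.genotype_at_markers["chr01"] for ind in inds])
    corr = [np.corrcoef(doses[:, 0], doses[:, j])[0, 1] for j in (1, 2, 3)]
    assert corr[0] > corr[1] > corr[2]
    assert corr[0] > 0.9  # 1 cM: near-perfect linkage


def test_bulk_enrichment_at_qtl(small_genome):
    """Long bulks are enriched for the KG1 allele at the QTL whenever the
    additive effect dominates the noise (a >= 2 * residual SD)."""
    for seed in range(5):
        cfg = simdata.SimConfig(
            n_f2=200, qtl_chromosome="chr02", qtl_position=2_000_000,
            additive_effect=2.0 * np.hypot(5.0, 3.0), polygenic_sd=5.0, env_sd=3.0,
            bulk_rule=(20, 20), bulk_mode="top_n", seed=seed,
        )
        inds, long_ids, short_ids, _ = simdata.simulate_experiment(small_genome, cfg)
        by_id = {i.id: i for i in inds}
        freq = lambda ids: np.mean([by_id[i].qtl_dose for i in ids]) / 2.0
        assert freq(long_ids) > freq(short_ids)


def test_config_file_roundtrip(tmp_path):
    path = tmp_path / "sim.cfg"
    path.write_text(
        "n_f2 = 120\nadditive_effect = 9.5\nbulk_rule = 18, 42\nseed = 99\n"
        "# comment line\nqtl_chromosome = chr03\n"
    )
    cfg = simdata.read_config_file(path)
    assert cfg.n_f2 == 120 and cfg.additive_effect == 9.5
    assert cfg.bulk_rule == (18.0, 42.0) and cfg.seed == 99
    assert cfg.qtl_chromosome == "chr03"
    bad = tmp_path / "bad.cfg"
    bad.write_text("nope = 1\n")
    with pytest.raises(ValueError, match="unknown config key"):
        simdata.read_config_file(bad)


def test_filtered_sim_sites_keep_structure(small_genome):
    """Simulated sites survive the scan-readiness filter (opposite-hom parents)."""
    cfg = simdata.SimConfig(n_f2=60, qtl_chromosome="chr01", qtl_position=500_000,
                            depth_mean=30, seed=21)
    _, _, _, sites = simdata.simulate_experiment(small_genome, cfg)
    kept = filter_sites(sites, min_depth_per_bulk=10)
    assert len(kept) > 0.8 * len(sites)
    assert all(s.opposite_homozygous for s in kept)
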