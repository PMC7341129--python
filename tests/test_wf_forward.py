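import numpy as np
import pytest

from usfsdfe import (
    ChromosomeGeometry,
    SimulationConfig,
    WrightFisherSimulation,
    build_chromosome,
    make_dfe,
    full_scale_config,
    pi_from_sfs,
    rescale_config,
    run_replicate,
    sample_usfs_from_replicates,
)
from usfsdfe.wf_forward import EXON, INTRON, SPACER, ReplicateResult, Variant

from _oracles import brute_force_pi


# effectively neutral: |2Ns| ~ 1e-6 for every mutation
NEUTRAL = make_dfe(0.3, -1e-6, 0.0, 0.0)
STD_DDFE = make_dfe(0.3, -2000.0, 0.0, 0.0)


def tiny_config(**kw):
    geom = kw.pop("geometry", ChromosomeGeometry(n_genes=1, spacer_bp=100))
    base = dict(N=60, mu=1e-5, rec=1e-5, geometry=geom, dfe=NEUTRAL,
                burnin_gens=50, divergence_gens=30, sample_n=10)
    base.update(kw)
    return SimulationConfig(**base)


class TestGeometry:
    def test_default_layout_counts(self):
        geom = ChromosomeGeometry()
        assert geom.gene_bp == 1900
        assert geom.exonic_bp == 10_500
        assert geom.L_sel == pytest.approx(7000.0)
        assert geom.L_neut == pytest.approx(3500.0)

    def test_full_study_site_totals(self):
        # 2000 replicates: 21 Mbp coding, 14 Mbp nonsyn, 7 Mbp syn
        geom = ChromosomeGeometry()
        assert 2000 * geom.exonic_bp == 21_000_000
        assert 2000 * geom.L_sel == pytest.approx(14e6)
        assert 2000 * geom.L_neut == pytest.approx(7e6)

    def test_class_map_structure(self):
        geom = ChromosomeGeometry()
        cmap = build_chromosome(geom)
        assert cmap.size == geom.total_bp
        assert np.sum(cmap == EXON) == geom.exonic_bp
        assert np.sum(cmap == INTRON) == geom.n_genes * 4 * 100
        assert np.sum(cmap == SPACER) == geom.n_genes * geom.spacer_bp
        assert np.all(cmap[:300] == EXON) and np.all(cmap[300:400] == INTRON)


class TestRescaling:
    def test_identity(self):
        cfg = full_scale_config(NEUTRAL)
        assert rescale_config(cfg, 1.0) == cfg

    def test_q10_algebra(self):
        cfg = rescale_config(full_scale_config(NEUTRAL), 10.0)
        assert cfg.N == 1000
        assert cfg.mu == pytest.approx(2.5e-6)
        assert cfg.theta_site == pytest.approx(0.01)
        assert cfg.rho_site == pytest.approx(0.01)
        assert cfg.burnin_gens == 8500
        assert cfg.divergence_gens == 20_000

    def test_too_aggressive_q_rejected(self):
        with pytest.raises(ValueError):
            rescale_config(full_scale_config(NEUTRAL), 500.0)


class TestSimulationCore:
    def test_determinism(self):
        cfg = tiny_config()
        a = run_replicate(cfg, seed=7)
        b = run_replicate(cfg, seed=7)
        assert a.variants == b.variants
        assert a.substitutions == b.substitutions

    def test_counts_within_population_bounds(self):
        cfg = tiny_config()
        rng = np.random.default_rng(3)
        sim = WrightFisherSimulation(cfg, rng)
        sim.run(150)
        counts = np.count_nonzero(sim.G, axis=0)
        assert np.all(counts >= 1) and np.all(counts <= 2 * cfg.N - 1)

    def test_pi_formula_matches_brute_force(self):
        # exact oracle: mean pairwise difference over all genome pairs
        cfg = tiny_config(N=50)
        rng = np.random.default_rng(11)
        sim = WrightFisherSimulation(cfg, rng)
        sim.run(120)
        n = 2 * cfg.N
        counts = np.count_nonzero(sim.G, axis=0)
        sfs = np.bincount(counts, minlength=n + 1)[1:n]
        L = cfg.geometry.total_bp
        pi = pi_from_sfs(sfs, L, n)
        assert pi * L == pytest.approx(brute_force_pi(sim.G), rel=1e-12)

    def test_neutral_diversity_matches_theta(self):
        # theta = 4*N*mu; pooled over replicates with an empirical SE
        cfg = tiny_config(N=100, mu=0.01 / (4 * 100), rec=0.01 / (4 * 100),
                          geometry=ChromosomeGeometry(n_genes=1, spacer_bp=2000),
                          burnin_gens=1200, divergence_gens=0)
        pis = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            sim = WrightFisherSimulation(cfg, rng)
            sim.run(cfg.burnin_gens)
            n = 2 * cfg.N
            counts = np.count_nonzero(sim.G, axis=0)
            sfs = np.bincount(counts, minlength=n + 1)[1:n]
            pis.append(pi_from_sfs(sfs, cfg.geometry.total_bp, n))
        se = np.std(pis, ddof=1) / np.sqrt(len(pis))
        assert abs(np.mean(pis) - 0.01) < 3 * se

    def test_neutral_divergence_rate(self):
        # substitutions accumulate at mu per site over the scoring window
        cfg = tiny_config(N=60, mu=2e-4, rec=0.0,
                          geometry=ChromosomeGeometry(n_genes=1, spacer_bp=3000),
                          burnin_gens=600, divergence_gens=400)
        n_subs = []
        for seed in range(5):
            rep = run_replicate(cfg, seed=seed)
            n_subs.append(sum(1 for s in rep.substitutions
                              if s.phase == "divergence-window"))
        expected = cfg.mu * cfg.divergence_gens * cfg.geometry.total_bp
        se = np.std(n_subs, ddof=1) / np.sqrt(len(n_subs))
        assert abs(np.mean(n_subs) - expected) < 3.5 * se

    def test_selected_mutations_only_in_exons(self):
        dfe = make_dfe(0.3, -50.0, 0.5, 5.0)
        cfg = tiny_config(dfe=dfe, N=60)
        rng = np.random.default_rng(1)
        sim = WrightFisherSimulation(cfg, rng)
        sim.run(80)
        cmap = build_chromosome(cfg.geometry)
        sel = sim.gammas != 0.0
        assert np.all(cmap[sim.positions[sel]] == EXON)

    def test_infinite_sites_no_duplicate_positions(self):
        cfg = tiny_config(N=60, mu=5e-4)
        rng = np.random.default_rng(2)
        sim = WrightFisherSimulation(cfg, rng)
        sim.run(100)
        assert np.unique(sim.positions).size == sim.positions.size


class TestSampling:
    def test_single_variant_lands_in_its_class(self):
        rep = ReplicateResult(
            variants=[Variant(5, "syn", 0.0, 3)], substitutions=[],
            L_sel=700.0, L_neut=350.0, sample_n=20)
        ds = sample_usfs_from_replicates([rep])
        expected = np.zeros(39, dtype=int)
        expected[2] = 1
        assert np.array_equal(ds.neutral_sfs, expected)
        assert ds.selected_sfs.sum() == 0

    def test_vector_length_for_20_diploids(self):
        cfg = tiny_config(sample_n=20, N=60)
        rep = run_replicate(cfg, seed=5)
        ds = sample_usfs_from_replicates([rep])
        assert ds.neutral_sfs.size == 39 and ds.n_chrom == 40

    def test_sample_fixed_variants_join_divergence(self):
        rep = ReplicateResult(
            variants=[Variant(5, "nonsyn", 4.0, 40), Variant(9, "syn", 0.0, 40)],
            substitutions=[], L_sel=700.0, L_neut=350.0, sample_n=20)
        ds = sample_usfs_from_replicates([rep])
        assert ds.div_sel == 1 and ds.div_neut == 1
        assert ds.selected_sfs.sum() == 0 and ds.neutral_sfs.sum() == 0
        nodiv = sample_usfs_from_replicates([rep], with_divergence=False)
        assert not nodiv.has_divergence

    def test_inconsistent_sample_sizes_rejected(self):
        r1 = ReplicateResult([], [], 700.0, 350.0, sample_n=20)
        r2 = ReplicateResult([], [], 700.0, 350.0, sample_n=10)
        with pytest.raises(ValueError):
            sample_usfs_from_replicates([r1, r2])

    def test_pooled_neutral_usfs_follows_one_over_i(self):
        # many neutral replicates: pooled synonymous uSFS ~ 1/i
        cfg = tiny_config(N=80, mu=1e-4, burnin_gens=700, divergence_gens=0,
                          geometry=ChromosomeGeometry(n_genes=1, spacer_bp=100),
                          sample_n=10)
        reps = [run_replicate(cfg, seed=s) for s in range(16)]
        ds = sample_usfs_from_replicates(reps)
        allneut = np.zeros(19, dtype=int)  # all neutral variants, all classes
        for rep in reps:
            for v in rep.variants:
                if v.count < 20 and v.gamma == 0.0:
                    allneut[v.count - 1] += 1
        i = np.arange(1, 20)
        law = (1.0 / i) / np.sum(1.0 / i)
        # binned comparison: linkage correlates neighbouring frequency
        # classes, so per-class chi-square would be overdispersed
        bins = [(0, 1), (1, 3), (3, 7), (7, 19)]
        obs = np.array([allneut[a:b].sum() for a, b in bins]) / allneut.sum()
        exp = np.array([law[a:b].sum() for a, b in bins])
        assert np.all(np.abs(obs / exp - 1.0) < 0.35)
        assert ds.neutral_sfs.sum() <= allneut.sum()

def test_simulation_config_file_and_replicate_tables(tmp_path):
    from usfsdfe.wf_forward import read_simulation_config, write_replicate_tables

    p = tmp_path / "sim.cfg"
    p.write_text(
        "N = 200\nmu = 1e-6\nrec = 1e-6\nburnin_gens = 100\n"
        "divergence_gens = 50\nsample_n = 5\n"
        "beta = 0.3\nmean_gamma_d = -100\np_a = 0.1\ngamma_a = 5\n"
        "n_genes = 2\nspacer_bp = 500\n"
    )
    cfg = read_simulation_config(p)
    assert cfg.N == 200 and cfg.sample_n == 5
    assert cfg.dfe.gamma_a == 5.0
    assert cfg.geometry.n_genes == 2 and cfg.geometry.spacer_bp == 500

    rep = run_replicate(cfg, seed=3)
    vpath, spath = tmp_path / "variants.tsv", tmp_path / "subs.tsv"
    write_replicate_tables(rep, vpath, spath)
    vlines = [l for l in vpath.read_text().splitlines() if not l.startswith("#")]
    assert vlines[0].split("\t") == ["position", "site_class", "gamma", "count"]
    assert len(vlines) - 1 == len(rep.variants)
    slines = [l for l in spath.read_text().splitlines() if not l.startswith("#")]
    assert len(slines) - 1 == len(rep.substitutions)
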