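import numpy as np
import pytest

from rohscan.data import HET, HOM_A, HOM_B, MISSING
from rohscan.detect import (
    RunConfig,
    TargetState,
    default_roh_config,
    default_rohet_config,
    detect_runs_all,
    detect_runs_one,
)
from rohscan.simulate import SimulationConfig, Tract, simulate_planted

from conftest import make_dataset, random_genotype_vector, random_positions
from oracles import brute_force_runs


def run_tuples(runs):
    return {(r.start_bp, r.end_bp, r.n_snps, r.n_opposite, r.n_missing)
            for r in runs}


class TestPresets:
    def test_roh_preset(self):
        cfg = default_roh_config()
        assert (cfg.target_state, cfg.min_snps, cfg.min_length_bp,
                cfg.max_gap_bp, cfg.max_opposite, cfg.max_missing) == (
            TargetState.HOMOZYGOUS, 30, 500_000, 1_000_000, 1, 1)

    def test_rohet_preset(self):
        cfg = default_rohet_config()
        assert (cfg.target_state, cfg.min_snps, cfg.min_length_bp,
                cfg.max_gap_bp, cfg.max_opposite, cfg.max_missing) == (
            TargetState.HETEROZYGOUS, 15, 1_000_000, 1_000_000, 3, 2)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            RunConfig(TargetState.HOMOZYGOUS, 0, 1, 1, 0, 0)
        with pytest.raises(ValueError):
            RunConfig(TargetState.HOMOZYGOUS, 1, 1, 0, 0, 0)


class TestDetectOne:
    def test_single_clean_run(self):
        pos = np.arange(35) * 17_000 + 1
        g = np.full(35, HOM_B, dtype=np.int8)
        (run,) = detect_runs_one(g, pos, default_roh_config())
        assert (run.start_bp, run.end_bp, run.n_snps) == (1, 578_001, 35)

    def test_all_het_chromosome_has_no_roh(self):
        pos = np.arange(100) * 20_000 + 1
        g = np.full(100, HET, dtype=np.int8)
        assert detect_runs_one(g, pos, default_roh_config()) == []

    def test_het_allowance_budget(self):
        # 40 hom SNPs with 2 interior hets: allowance 1 -> split at 2nd het
        pos = np.arange(40) * 20_000 + 1
        g = np.full(40, HOM_A, dtype=np.int8)
        g[10] = HET
        g[25] = HET
        runs = detect_runs_one(g, pos, default_roh_config())
        oracle = brute_force_runs(g, pos, default_roh_config())
        assert run_tuples(runs) == oracle

    def test_gap_terminates_run(self):
        # 35 hom SNPs with one 1.2 Mb gap: each side judged independently
        pos = np.concatenate([np.arange(18) * 20_000,
                              np.arange(18, 35) * 20_000 + 1_200_000]) + 1
        g = np.full(35, HOM_A, dtype=np.int8)
        runs = detect_runs_one(g, pos, default_roh_config())
        # neither side reaches 30 SNPs
        assert runs == []
        oracle = brute_force_runs(g, pos, default_roh_config())
        assert run_tuples(runs) == oracle

    def test_tolerated_markers_never_terminal(self):
        # het/missing flanks are trimmed: run starts/ends on called targets
        pos = np.arange(40) * 20_000 + 1
        g = np.full(40, HOM_A, dtype=np.int8)
        g[0] = HET
        g[-1] = MISSING
        (run,) = detect_runs_one(g, pos, default_roh_config())
        assert run.start_bp == pos[1] and run.end_bp == pos[-2]
        assert run.n_opposite == 0 and run.n_missing == 0

    def test_position_errors(self):
        g = np.full(5, HOM_A, dtype=np.int8)
        with pytest.raises(ValueError, match="strictly increasing"):
            detect_runs_one(g, np.array([1, 2, 2, 3, 4]), default_roh_config())
        with pytest.raises(ValueError, match="length"):
            detect_runs_one(g, np.arange(4), default_roh_config())

    @pytest.mark.parametrize("config", [default_roh_config(),
                                        default_rohet_config()],
                             ids=["roh", "rohet"])
    def test_oracle_equivalence_random(self, config, rng):
        """Scanner equals the brute-force consecutive-method oracle on
        random vectors with gaps, opposite calls and missingness."""
        for _ in range(300):
            n = int(rng.integers(5, 200))
            target_is_hom = config.target_state == TargetState.HOMOZYGOUS
            g = random_genotype_vector(rng, n, target_is_hom=target_is_hom)
            pos = random_positions(rng, n)
            runs = detect_runs_one(g, pos, config)
            assert run_tuples(runs) == brute_force_runs(g, pos, config)

    def test_hom_het_symmetry(self, rng):
        """Relabeling HOM<->HET genotypes swaps ROH and ROHet detections."""
        cfg_h = RunConfig(TargetState.HOMOZYGOUS, 10, 100_000, 1_000_000, 2, 1)
        cfg_t = RunConfig(TargetState.HETEROZYGOUS, 10, 100_000, 1_000_000, 2, 1)
        for _ in range(50):
            n = int(rng.integers(20, 150))
            g = random_genotype_vector(rng, n, target_is_hom=True)
            pos = random_positions(rng, n)
            swapped = g.copy()
            swapped[g == HET] = HOM_A
            swapped[(g == HOM_A) | (g == HOM_B)] = HET
            a = run_tuples(detect_runs_one(g, pos, cfg_h))
            b = run_tuples(detect_runs_one(swapped, pos, cfg_t))
            assert a == b

    def test_runs_disjoint_and_deterministic(self, rng):
        cfg = default_roh_config()
        for _ in range(50):
            n = int(rng.integers(30, 200))
            g = random_genotype_vector(rng, n)
            pos = random_positions(rng, n, mean_spacing=25_000)
            runs = detect_runs_one(g, pos, cfg)
            runs2 = detect_runs_one(g, pos, cfg)
            assert runs == runs2
            for a, b in zip(runs, runs[1:]):
                assert a.end_bp < b.start_bp    # sorted, disjoint
            for r in runs:
                assert r.n_snps >= cfg.min_snps
                assert r.length_bp >= cfg.min_length_bp
                assert r.n_opposite <= cfg.max_opposite
                assert r.n_missing <= cfg.max_missing


class TestDetectAll:
    def test_one_run_per_chromosome(self):
        pos = {"1": list(range(1, 700_000, 20_000)),
               "2": list(range(1, 700_000, 20_000))}
        g = np.full((1, 70), HOM_A, dtype=np.int8)
        ds = make_dataset(pos, g)
        runs = detect_runs_all(ds, default_roh_config())
        assert len(runs) == 2
        assert sorted(runs["chromosome"]) == ["1", "2"]

    def test_empty_dataset_warns(self):
        pos = {"1": [100]}
        ds = make_dataset(pos, np.zeros((0, 1), dtype=np.int8),
                          populations=[])
        with pytest.warns(UserWarning, match="empty"):
            runs = detect_runs_all(ds, default_roh_config())
        assert len(runs) == 0

    def test_planted_tracts_recovered_snp_exact(self):
        """With no noise, detected boundaries equal the first/last map SNP
        of each planted autozygous tract."""
        cfg = SimulationConfig(n_chromosomes=2, chromosome_length_bp=30_000_000,
                               n_snps_per_chromosome=1_500, seed=11)
        tracts = [Tract(0, "1", 5_000_000, 10_000_000, "autozygous"),
                  Tract(0, "2", 12_000_000, 14_000_000, "autozygous"),
                  Tract(1, "2", 20_000_000, 26_000_000, "autozygous")]
        ds, truth = simulate_planted(cfg, tracts, 2)
        runs = detect_runs_all(ds, default_roh_config())
        for t in tracts:
            idx = ds.map.chromosome_indices(t.chromosome)
            pos = ds.map.positions[idx]
            inside = pos[(pos >= t.start_bp) & (pos <= t.end_bp)]
            sid = ds.samples["sample_id"].iloc[t.sample_index]
            match = runs[(runs.sample_id == sid)
                         & (runs.chromosome == t.chromosome)
                         & (runs.start_bp == inside[0])
                         & (runs.end_bp == inside[-1])]
            assert len(match) == 1
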