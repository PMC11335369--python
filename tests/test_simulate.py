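import numpy as np
import pytest

from wfdms.frequencies import counts_to_frequencies, error_correct
from wfdms.io import read_dms_tools_codon_counts, read_mavedb_counts, SampleKey
from wfdms.simulate import (
    SimulationConfig,
    error_control_tables,
    replicator_update,
    sample_reads,
    simulate_wf,
    write_fixture,
)


class TestReplicatorUpdate:
    def test_two_variant_closed_form(self):
        z = replicator_update(np.array([0.1, 0.9]), np.array([1.1, 1.0]))
        assert z[0] == pytest.approx(0.11 / 1.01, abs=1e-12)

    def test_neutral_update_is_identity(self):
        z0 = np.array([0.2, 0.3, 0.5])
        assert replicator_update(z0, np.ones(3)) == pytest.approx(z0, abs=1e-15)


class TestSimulateWf:
    def test_population_counts_conserved_every_round(self):
        config = SimulationConfig(n_sites=2, alleles_per_site=3, rounds=4,
                                  population_size=500, replicates=2, seed=1)
        ds = simulate_wf(config)
        for counts in ds.population_counts.values():
            assert np.all(counts.sum(axis=0) == config.population_size)

    def test_same_seed_bit_identical(self):
        config = SimulationConfig(n_sites=2, alleles_per_site=3,
                                  population_size=300, seed=9)
        a = sample_reads(simulate_wf(config))
        b = sample_reads(simulate_wf(config))
        for rep in a.replicate_ids:
            assert np.array_equal(a.population_counts[rep], b.population_counts[rep])
            assert np.array_equal(a.read_counts[rep], b.read_counts[rep])

    def test_different_seeds_differ_but_share_explicit_truth(self):
        truth = {(1, "C"): 0.2, (1, "D"): -0.1, (2, "D"): 0.0, (2, "E"): 0.05}
        kw = dict(n_sites=2, alleles_per_site=3, population_size=300, true_s=truth)
        a = simulate_wf(SimulationConfig(seed=1, **kw))
        b = simulate_wf(SimulationConfig(seed=2, **kw))
        assert a.true_s.equals(b.true_s)
        assert not np.array_equal(a.population_counts["rep1"],
                                  b.population_counts["rep1"])

    def test_neutral_truth_has_no_mean_drift(self):
        deltas = []
        truth = {(1, "C"): 0.0, (1, "D"): 0.0}
        for seed in range(200):
            config = SimulationConfig(n_sites=1, alleles_per_site=3, rounds=1,
                                      population_size=1000, replicates=1,
                                      seed=seed, true_s=truth)
            ds = simulate_wf(config)
            z = ds.population_freqs["rep1"]
            deltas.append(z[1, -1] - z[1, 0])
        mean, se = np.mean(deltas), np.std(deltas) / np.sqrt(len(deltas))
        assert abs(mean) < 3 * se + 1e-12

    def test_beneficial_mutant_rises_in_expectation(self):
        truth = {(1, "C"): 0.3, (1, "D"): 0.0}
        final = []
        for seed in range(50):
            config = SimulationConfig(n_sites=1, alleles_per_site=3, rounds=5,
                                      population_size=5000, replicates=1,
                                      seed=seed, true_s=truth)
            z = simulate_wf(config).population_freqs["rep1"]
            final.append(z[1])
        mean_traj = np.mean(final, axis=0)
        assert np.all(np.diff(mean_traj) > 0)

    def test_deterministic_mode_matches_replicator(self):
        truth = {(1, "C"): 0.1}
        config = SimulationConfig(n_sites=1, alleles_per_site=2, rounds=1,
                                  replicates=1, deterministic=True,
                                  fraction_wt=0.9, true_s=truth)
        z = simulate_wf(config).population_freqs["rep1"]
        assert z[1, 1] == pytest.approx(0.1 * 1.1 / (1 + 0.1 * 0.1), abs=1e-12)


class TestSampleReads:
    def _freq_dataset(self, z):
        config = SimulationConfig(n_sites=1, alleles_per_site=2, rounds=1,
                                  replicates=1, deterministic=True,
                                  fraction_wt=1 - z, seed=0,
                                  true_s={(1, "C"): 0.0})
        return simulate_wf(config)

    def test_negative_binomial_mean(self):
        means = []
        for seed in range(200):
            ds = sample_reads(self._freq_dataset(0.1), depth=1000,
                              dispersion=10.0, seed=seed)
            means.append(ds.read_counts["rep1"][1, 0])
        sd = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means) - 100) < 3 * sd + 1

    def test_poisson_limit_variance_equals_mean(self):
        draws = [sample_reads(self._freq_dataset(0.1), depth=1000,
                              dispersion=np.inf, seed=s).read_counts["rep1"][1, 0]
                 for s in range(2000)]
        assert np.var(draws) == pytest.approx(np.mean(draws), rel=0.15)

    def test_overdispersed_variance(self):
        draws = [sample_reads(self._freq_dataset(0.1), depth=1000,
                              dispersion=1.0, seed=s).read_counts["rep1"][1, 0]
                 for s in range(3000)]
        # variance = mean + mean^2 / r = 100 + 10000
        assert np.var(draws) == pytest.approx(10100, rel=0.2)


class TestWriteFixture:
    def test_dms_tools_fixture_parses_and_round_trips(self, small_dataset, tmp_path):
        paths = write_fixture(small_dataset, tmp_path, format="dms_tools")
        n_times = small_dataset.config.rounds + 1
        assert len(paths["samples"]) == small_dataset.config.replicates * n_times
        tables = {}
        for path in paths["samples"]:
            table = read_dms_tools_codon_counts(path, SampleKey("x", "t", 0.0))
            tables[path.name] = table
        # counts round-trip exactly: site depth equals total sampled reads
        rep = small_dataset.replicate_ids[0]
        expected = small_dataset.read_counts[rep][:, 0].sum()
        first = tables[f"counts_{rep}_t0.csv"]
        assert first.depth(first.sites[0]) == expected

    def test_mavedb_fixture_round_trips_substitutions(self, tmp_path):
        config = SimulationConfig(n_sites=3, alleles_per_site=3, rounds=2,
                                  population_size=2000, depth=2000,
                                  dispersion=np.inf, replicates=1,
                                  fraction_double=0.2, seed=4)
        ds = sample_reads(simulate_wf(config))
        paths = write_fixture(ds, tmp_path, format="mavedb")
        manifest_samples = [e for e in __import__("yaml").safe_load(
            paths["manifest"].read_text())["samples"]]
        columns = {e["column"]: SampleKey(e["replicate"], e["timepoint"], e["time"])
                   for e in manifest_samples}
        tables = read_mavedb_counts(tmp_path / "counts.csv", columns)
        by_sample = {t.sample: t.as_dict() for t in tables}
        orig = ds.to_variant_tables("rep1")[0]
        read_back = by_sample[orig.sample]
        for subs, count in orig.variants:
            assert read_back.get(subs, 0) == count

    def test_whole_chain_seed_reproducible(self, tmp_path):
        config = SimulationConfig(n_sites=2, alleles_per_site=3, rounds=2,
                                  population_size=500, depth=500, seed=21,
                                  replicates=2)
        out = []
        for sub in ("a", "b"):
            ds = sample_reads(simulate_wf(config))
            paths = write_fixture(ds, tmp_path / sub, format="dms_tools")
            out.append(b"".join(sorted(p.read_bytes() for p in paths["samples"])))
        assert out[0] == out[1]


class TestErrorControl:
    def test_error_correction_recovers_clean_frequencies(self):
        # rare-mutant regime: subtractive correction assumes most
        # miscalls flow out of the abundant wild type
        config = SimulationConfig(n_sites=2, alleles_per_site=3, rounds=3,
                                  population_size=10**4, depth=10**6,
                                  dispersion=np.inf, replicates=1, seed=5,
                                  fraction_wt=0.9,
                                  true_s={(1, "C"): 0.2, (1, "D"): -0.1,
                                          (2, "D"): 0.1, (2, "E"): 0.0})
        ds = sample_reads(simulate_wf(config))
        clean = counts_to_frequencies(ds.to_aa_count_tables("rep1"),
                                      pseudocount=0.0)
        control, corrupted = error_control_tables(ds, miscall_rate=0.02,
                                                  depth=10**6)
        noisy = counts_to_frequencies(corrupted["rep1"], pseudocount=0.0)
        ctrl_traj = counts_to_frequencies(control, pseudocount=0.0)
        fixed = error_correct(noisy, ctrl_traj)
        site = 1
        err_before = np.abs(noisy.z[site] - clean.z[site]).max()
        err_after = np.abs(fixed.z[site] - clean.z[site]).max()
        assert err_after < err_before
        assert err_after < 5e-3
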