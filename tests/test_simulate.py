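import numpy as np
import pytest

from slopespam import (
    JCPairSpec,
    LocalHomologySpec,
    embed_local_homology,
    homology_ratio_experiment,
    recovery_experiment,
    simulate_jc_pair,
)
from slopespam.simulate import substitution_probability


def mismatch_fraction(a, b):
    x = np.frombuffer("".join(a.records).encode(), dtype=np.uint8)
    y = np.frombuffer("".join(b.records).encode(), dtype=np.uint8)
    return float((x != y).mean())


class TestJCPair:
    def test_zero_distance_identical(self):
        a, b = simulate_jc_pair(JCPairSpec(10_000, 0.0, seed=1))
        assert a.records == b.records

    def test_mismatch_fraction_concentrates(self):
        L, d = 100_000, 0.3
        m = substitution_probability(d)  # 0.75*(1-e^(-0.4)) ~ 0.2473
        assert m == pytest.approx(0.2473, abs=5e-4)
        a, b = simulate_jc_pair(JCPairSpec(L, d, seed=7))
        assert abs(mismatch_fraction(a, b) - m) < 4 * np.sqrt(m * (1 - m) / L)

    def test_saturation_limit(self):
        a, b = simulate_jc_pair(JCPairSpec(100_000, 10.0, seed=7))
        assert abs(mismatch_fraction(a, b) - 0.75) < 0.01

    def test_bit_reproducible_and_seed_sensitive(self):
        p1 = simulate_jc_pair(JCPairSpec(5_000, 0.2, seed=42))
        p2 = simulate_jc_pair(JCPairSpec(5_000, 0.2, seed=42))
        p3 = simulate_jc_pair(JCPairSpec(5_000, 0.2, seed=43))
        assert p1[0].records == p2[0].records and p1[1].records == p2[1].records
        assert p1[0].records != p3[0].records

    def test_base_composition_uniform(self):
        a, _ = simulate_jc_pair(JCPairSpec(200_000, 0.1, seed=5))
        s = a.records[0]
        counts = np.array([s.count(c) for c in "ACGT"])
        # multinomial: each count ~ N(L/4, L*3/16)
        assert np.abs(counts - 50_000).max() < 5 * np.sqrt(200_000 * 3 / 16)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            JCPairSpec(0, 0.1)
        with pytest.raises(ValueError):
            JCPairSpec(100, -0.1)


class TestEmbedLocalHomology:
    def test_rho_one_returns_core_unchanged(self):
        core = simulate_jc_pair(JCPairSpec(2_000, 0.1, seed=1))
        out = embed_local_homology(LocalHomologySpec(core, 1.0, seed=2))
        assert out[0] is core[0] and out[1] is core[1]

    def test_flank_arithmetic_half_homology(self):
        core = simulate_jc_pair(JCPairSpec(165_000, 0.05, seed=1))
        out = embed_local_homology(LocalHomologySpec(core, 0.5, seed=2))
        assert out[0].total_length == out[1].total_length == 330_000

    def test_flank_arithmetic_low_homology_and_independence(self):
        core = simulate_jc_pair(JCPairSpec(1_000, 0.05, seed=1))
        out = embed_local_homology(LocalHomologySpec(core, 0.1, seed=2))
        for seq, c in zip(out, core):
            assert seq.total_length == 10_000
            # core embedded intact: left flank 4500, right flank 4500
            assert seq.records[0][4500:5500] == c.records[0]
        left_a = out[0].records[0][:4500]
        left_b = out[1].records[0][:4500]
        # unrelated flanks: mismatch fraction near 3/4
        frac = np.mean([x != y for x, y in zip(left_a, left_b)])
        assert abs(frac - 0.75) < 0.05

    def test_invalid_rho(self):
        core = simulate_jc_pair(JCPairSpec(100, 0.1, seed=1))
        for rho in (0.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                LocalHomologySpec(core, rho)


class TestExperiments:
    def test_recovery_zero_distance_point(self):
        tab = recovery_experiment([0.0], 20_000, 5, mode="kmer", seed=3)
        assert tab.mean_estimate[0] < 1e-3
        assert tab.std_estimate[0] < 1e-3
        assert tab.n_failed[0] == 0

    def test_recovery_reports_grid_and_is_reproducible(self):
        grid = [0.1, 0.3]
        t1 = recovery_experiment(grid, 20_000, 4, mode="spaced", seed=3)
        t2 = recovery_experiment(grid, 20_000, 4, mode="spaced", seed=3)
        assert list(t1.d_true) == grid
        assert (t1.mean_estimate == t2.mean_estimate).all()
        assert ((t1.mean_estimate - t1.d_true).abs() < 0.05).all()

    def test_recovery_more_accurate_at_longer_sequences(self):
        grid = [0.1, 0.3]
        short = recovery_experiment(grid, 50_000, 12, mode="spaced", seed=3)
        long_ = recovery_experiment(grid, 500_000, 12, mode="spaced", seed=3)
        bias_s = (short.mean_estimate - short.d_true).abs()
        bias_l = (long_.mean_estimate - long_.d_true).abs()
        assert (bias_l <= bias_s + 0.005).all()

    def test_homology_ratio_rho_one_is_exactly_one(self):
        tab = homology_ratio_experiment(JCPairSpec(10_000, 0.1), [1.0, 0.5], 3, seed=4)
        row = tab[tab.rho == 1.0].iloc[0]
        assert row.mean_ratio == 1.0
        assert row.std_ratio == 0.0

    def test_replicate_guard(self):
        with pytest.raises(ValueError):
            recovery_experiment([0.1], 1000, 1)
        with pytest.raises(ValueError):
            homology_ratio_experiment(JCPairSpec(1000, 0.1), [1.0], 1)

    def test_write_table_round_trip(self, tmp_path):
        import pandas as pd

        from slopespam.simulate import write_table

        tab = recovery_experiment([0.1], 10_000, 3, mode="kmer", seed=3)
        path = tmp_path / "tab.tsv"
        write_table(tab, path)
        back = pd.read_csv(path, sep="\t")
        assert list(back.columns) == list(tab.columns)
        assert back.mean_estimate[0] == pytest.approx(tab.mean_estimate[0])
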