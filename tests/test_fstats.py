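"""f3/f4 estimators, weighted block jackknife, bootstrap distance matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mouflon import fstats, simulate
from mouflon.fstats import AlleleFreqTable, BlockScheme, allele_frequencies, f3, f4
from conftest import make_gm


def _table(freq, count=None, spacing=1000):
    freq = np.asarray(freq, dtype=float)
    n_pops, n_sites = freq.shape
    count = (
        np.full((n_pops, n_sites), 4, dtype=np.int32)
        if count is None
        else np.asarray(count, dtype=np.int32)
    )
    sites = pd.DataFrame(
        {"chrom": ["chr1"] * n_sites, "pos": spacing * (np.arange(n_sites) + 1)}
    )
    labels = [chr(ord("O") + i) for i in range(n_pops)]
    return AlleleFreqTable(labels, freq, count, sites)


def brute_force_jackknife(terms, block_id):
    """Independent delete-one-block weighted jackknife (naive loops)."""
    terms = np.asarray(terms, float)
    ids = np.unique(block_id)
    g, n = len(ids), terms.size
    est = terms.mean()
    loo = np.array([terms[block_id != j].mean() for j in ids])
    m = np.array([(block_id == j).sum() for j in ids], float)
    h = n / m
    theta_j = g * est - ((1 - m / n) * loo).sum()
    tau = h * est - (h - 1) * loo
    return est, float(np.sqrt(np.sum((tau - theta_j) ** 2 / (h - 1)) / g))


class TestAlleleFrequencies:
    def test_single_diploid_het(self):
        gm = make_gm([[1]], samples=["a"])
        ft = allele_frequencies(gm, {"a": "A"})
        assert ft.freq[0, 0] == 0.5 and ft.count[0, 0] == 2

    def test_two_diploids(self):
        gm = make_gm([[0, 2]], samples=["a", "b"])
        ft = allele_frequencies(gm, {"a": "P", "b": "P"})
        assert ft.freq[0, 0] == 0.5 and ft.count[0, 0] == 4

    def test_pseudohaploid_counts_one_allele(self):
        gm = make_gm([[2, 0]], samples=["a", "b"], ploidy="pseudohaploid")
        ft = allele_frequencies(gm, {"a": "P", "b": "P"})
        assert ft.freq[0, 0] == 0.5 and ft.count[0, 0] == 2

    def test_matches_brute_force_tally_with_missing(self):
        rng = np.random.default_rng(0)
        d = rng.integers(-1, 3, (100, 6))
        gm = make_gm(d)
        grouping = {f"s{i}": ("P" if i < 4 else "Q") for i in range(6)}
        ft = allele_frequencies(gm, grouping)
        for s in range(100):
            vals = [d[s, i] for i in range(4) if d[s, i] != -1]
            if vals:
                assert ft.freq[0, s] == pytest.approx(sum(vals) / (2 * len(vals)))
                assert ft.count[0, s] == 2 * len(vals)
            else:
                assert ft.count[0, s] == 0


class TestF3:
    def test_closed_form_one(self):
        ft = _table([[1.0] * 6, [0.0] * 6, [0.0] * 6])
        res = f3(ft, "O", "P", "Q", BlockScheme.by_snp_count(6, 2))
        assert res.estimate == 1.0

    def test_identity_zero(self):
        rng = np.random.default_rng(1)
        f = rng.uniform(0, 1, 6)
        ft = _table([f, f, f])
        res = f3(ft, "O", "P", "Q", BlockScheme.by_snp_count(6, 2))
        assert res.estimate == 0.0

    def test_symmetry_exact(self):
        rng = np.random.default_rng(2)
        ft = _table(rng.uniform(0, 1, (3, 30)))
        b = BlockScheme.by_snp_count(30, 7)
        r1 = f3(ft, "O", "P", "Q", b)
        r2 = f3(ft, "O", "Q", "P", b)
        assert r1.estimate == r2.estimate and r1.se == r2.se

    @pytest.mark.parametrize("n_sites,chunk", [(6, 2), (23, 3), (40, 7)])
    def test_jackknife_matches_brute_force(self, n_sites, chunk):
        rng = np.random.default_rng(n_sites)
        freq = rng.uniform(0.05, 0.95, (3, n_sites))
        count = np.full((3, n_sites), 6, dtype=np.int32)
        count[1, n_sites // 2] = 0  # one unusable site
        ft = _table(freq, count)
        blocks = BlockScheme.by_snp_count(n_sites, chunk)
        res = f3(ft, "O", "P", "Q", blocks)
        used = np.all(count > 0, axis=0)
        terms = ((freq[0] - freq[1]) * (freq[0] - freq[2]))[used]
        est, se = brute_force_jackknife(terms, blocks.block_id[used])
        assert res.estimate == pytest.approx(est, abs=1e-14)
        assert res.se == pytest.approx(se, abs=1e-12)

    def test_corrected_subtracts_target_noise(self):
        # o = 0.5 from a single diploid het: h_O = 2*1*1/(2*1) = 1, n_O = 2
        freq = np.array([[0.5] * 4, [0.0] * 4, [0.0] * 4])
        count = np.full((3, 4), 2, dtype=np.int32)
        ft = _table(freq, count)
        b = BlockScheme.by_snp_count(4, 2)
        plain = f3(ft, "O", "P", "Q", b).estimate
        corr = f3(ft, "O", "P", "Q", b, corrected=True).estimate
        assert plain == pytest.approx(0.25)
        assert corr == pytest.approx(0.25 - 1.0 / 2.0)

    def test_corrected_rejects_haploid_target(self):
        ft = _table([[0.5] * 4, [0.1] * 4, [0.2] * 4],
                    np.full((3, 4), 1, dtype=np.int32))
        with pytest.raises(ValueError):
            f3(ft, "O", "P", "Q", BlockScheme.by_snp_count(4, 2), corrected=True)

    def test_single_block_flags_undefined_se(self):
        ft = _table(np.random.default_rng(3).uniform(0, 1, (3, 5)))
        with pytest.warns(UserWarning):
            res = f3(ft, "O", "P", "Q", BlockScheme.by_snp_count(5, 5))
        assert np.isnan(res.se)


class TestF4:
    def test_algebraic_zero_when_a_equals_b(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 1, 12)
        ft = _table([a, a, rng.uniform(0, 1, 12), rng.uniform(0, 1, 12)])
        res = f4(ft, "O", "P", "Q", "R", BlockScheme.by_snp_count(12, 4))
        assert res.estimate == 0.0

    def test_antisymmetry_in_cd(self):
        rng = np.random.default_rng(5)
        ft = _table(rng.uniform(0, 1, (4, 20)))
        b = BlockScheme.by_snp_count(20, 5)
        r1 = f4(ft, "O", "P", "Q", "R", b)
        r2 = f4(ft, "O", "P", "R", "Q", b)
        assert r1.estimate == -r2.estimate

    def test_null_calibration_small(self):
        # tree-concordant quadruple ((A,B),(C,D)): |Z| <= 3 nearly always
        ok = 0
        for seed in range(25):
            ft, blocks = _sim_concordant(seed, n_sites=10_000)
            ok += abs(f4(ft, "A", "B", "C", "D", blocks).z) <= 3
        assert ok >= 23


def _sim_concordant(seed, n_sites=10_000, n_dip=5, F=0.05):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, n_sites)

    def bn(parent, Fb):
        return rng.beta(parent * (1 - Fb) / Fb, (1 - parent) * (1 - Fb) / Fb)

    pab, pcd = bn(p, F), bn(p, F)
    freqs, counts = [], []
    for pp in (bn(pab, F), bn(pab, F), bn(pcd, F), bn(pcd, F)):
        ac = rng.binomial(2 * n_dip, pp)
        freqs.append(ac / (2 * n_dip))
        counts.append(np.full(n_sites, 2 * n_dip, dtype=np.int32))
    sites = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, n_sites + 1) * 1000}
    )
    ft = AlleleFreqTable(["A", "B", "C", "D"], np.array(freqs),
                         np.array(counts), sites)
    return ft, BlockScheme.by_physical_span(sites, 1_000_000)


class TestDistanceMatrix:
    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(6)
        ft = _table(rng.uniform(0.2, 0.8, (4, 30)))
        D = fstats.distance_matrix(ft, ["P", "Q", "R"], "O",
                                   BlockScheme.by_snp_count(30, 10))
        np.testing.assert_array_equal(D.matrix, D.matrix.T)
        np.testing.assert_array_equal(np.diag(D.matrix), 0)

    def test_identical_populations_are_closest(self):
        rng = np.random.default_rng(7)
        f = rng.uniform(0.2, 0.8, 40)
        ft = _table([rng.uniform(0.2, 0.8, 40), f, f.copy(),
                     rng.uniform(0.2, 0.8, 40)])
        D = fstats.distance_matrix(ft, ["P", "Q", "R"], "O",
                                   BlockScheme.by_snp_count(40, 10))
        d = D.to_frame()
        off = D.matrix[~np.eye(3, dtype=bool)]
        assert d.loc["P", "Q"] == off.min()

    def test_shared_drift_monotonicity(self):
        # clades ((A,B),C) with outgroup: f3(O;A,B) > f3(O;A,C) usually
        wins = 0
        for seed in range(20):
            cfg = simulate.SimConfig(
                tree={
                    "name": "r", "F": 0.0, "children": [
                        {"name": "AB", "F": 0.08, "children": [
                            {"name": "A", "F": 0.08, "children": []},
                            {"name": "B", "F": 0.08, "children": []},
                        ]},
                        {"name": "C", "F": 0.08, "children": []},
                    ],
                },
                n_sites=8000, samples_per_pop=3, seed=seed,
            )
            freqs = simulate.simulate_frequencies(cfg)
            gm, _ = simulate.simulate_genotypes(freqs, cfg)
            grouping = {s: s.rsplit("_", 1)[0] for s in gm.samples
                        if s != cfg.outgroup_name}
            grouping[cfg.outgroup_name] = "O"
            ft = allele_frequencies(gm, grouping)
            b = BlockScheme.by_snp_count(gm.n_sites, 1000)
            f_ab = f3(ft, "O", "A", "B", b).estimate
            f_ac = f3(ft, "O", "A", "C", b).estimate
            wins += f_ab > f_ac
        assert wins >= 19


class TestBootstrap:
    def test_identity_draw_equals_point_estimate(self):
        rng = np.random.default_rng(8)
        gm = make_gm(rng.integers(0, 3, (300, 4)))
        grouping = {"s0": "P", "s1": "Q", "s2": "R", "s3": "O"}
        reps = fstats.bootstrap_distance_matrices(
            gm, grouping, ["P", "Q", "R"], "O", chunk_size=50, reps=1,
            seed=0, resample=False,
        )
        ft = allele_frequencies(gm, grouping)
        D = fstats.distance_matrix(ft, ["P", "Q", "R"], "O",
                                   BlockScheme.by_snp_count(300, 50))
        np.testing.assert_allclose(reps[0].matrix, D.matrix, atol=1e-12)

    def test_seed_determinism(self):
        rng = np.random.default_rng(9)
        gm = make_gm(rng.integers(0, 3, (200, 4)))
        grouping = {"s0": "P", "s1": "Q", "s2": "R", "s3": "O"}
        args = (gm, grouping, ["P", "Q", "R"], "O")
        r1 = fstats.bootstrap_distance_matrices(*args, chunk_size=40, reps=5, seed=42)
        r2 = fstats.bootstrap_distance_matrices(*args, chunk_size=40, reps=5, seed=42)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_chunk_size_too_large_errors(self):
        gm = make_gm(np.zeros((10, 4), dtype=np.int8))
        with pytest.raises(ValueError):
            fstats.bootstrap_distance_matrices(
                gm, {"s0": "P", "s1": "Q", "s2": "R", "s3": "O"},
                ["P", "Q", "R"], "O", chunk_size=100, reps=1, seed=0,
            )

    def test_replicate_mean_near_point_estimate(self):
        cfg = simulate.SimConfig(n_sites=20_000, samples_per_pop=2, seed=11)
        freqs = simulate.simulate_frequencies(cfg)
        gm, _ = simulate.simulate_genotypes(freqs, cfg)
        pops = cfg.leaf_pops()[:4]
        grouping = {f"{p}_{i + 1}": p for p in pops for i in range(2)}
        grouping[cfg.outgroup_name] = cfg.outgroup_name
        keep = [s for s in gm.samples if s in grouping]
        gm = gm.subset_samples(keep)
        reps = fstats.bootstrap_distance_matrices(
            gm, grouping, pops, cfg.outgroup_name, chunk_size=2000, reps=60,
            seed=1,
        )
        ft = allele_frequencies(gm, grouping)
        D = fstats.distance_matrix(ft, pops, cfg.outgroup_name,
                                   BlockScheme.by_snp_count(gm.n_sites, 2000))
        stack = np.stack([r.matrix for r in reps])
        mean, sd = stack.mean(axis=0), stack.std(axis=0, ddof=1)
        boot_se = sd / np.sqrt(len(reps))
        off = ~np.eye(len(pops), dtype=bool)
        assert np.all(np.abs(mean[off] - D.matrix[off]) <= 3 * sd[off] + 1e-9)


@given(st.integers(0, 2**31 - 1))
def test_f3_symmetry_property(seed):
    rng = np.random.default_rng(seed)
    ft = _table(rng.uniform(0, 1, (3, 12)))
    b = BlockScheme.by_snp_count(12, 4)
    assert f3(ft, "O", "P", "Q", b).estimate == f3(ft, "O", "Q", "P", b).estimate
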