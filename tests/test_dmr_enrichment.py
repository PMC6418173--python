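"""Element-density ratios, the count-based hypergeometric test, overlaps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gestarch.dmr import DMRSet, call_dmrs
from gestarch.dmr_enrichment import (
    count_set_test,
    count_set_test_all,
    dmr_overlap,
    element_density_enrichment,
    sign_concordance,
)


def _dmrset(starts, chrom="1", width=2000, diffs=None):
    starts = list(starts)
    frame = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": [s + width for s in starts],
            "diff": diffs if diffs is not None else [10.0] * len(starts),
            "p": 1e-6,
            "q": 1e-4,
            "direction": "Gain",
        }
    )
    return DMRSet(q_cutoff=0.01, min_abs_diff=5, members=frame)


def _universe(n, chrom="1", width=2000):
    return pd.DataFrame(
        {"chrom": chrom, "start": np.arange(n) * width, "end": (np.arange(n) + 1) * width}
    )


class TestElementDensity:
    def test_worked_ratio(self):
        # 30 of 100 DMRs inside a 1e5 bp class on a 1e6 bp genome -> 3.0
        dmrs = _dmrset(list(range(0, 60_000, 2000)) + list(range(200_000, 340_000, 2000)))
        assert len(dmrs.members) == 100
        elements = {"klass": pd.DataFrame({"chrom": ["1"], "start": [0], "end": [100_000]})}
        out = element_density_enrichment(dmrs, elements, genome_size=1_000_000)
        row = out.iloc[0]
        assert row["n_dmr"] == 30 and row["enrichment"] == pytest.approx(3.0)

    def test_whole_genome_identity(self):
        dmrs = _dmrset(range(0, 40_000, 2000))
        elements = {"genome": pd.DataFrame({"chrom": ["1"], "start": [0], "end": [1_000_000]})}
        out = element_density_enrichment(dmrs, elements, genome_size=1_000_000)
        assert out["enrichment"].iloc[0] == pytest.approx(1.0)

    def test_doubling_span_halves_enrichment(self):
        dmrs = _dmrset(range(0, 20_000, 2000))
        e1 = {"a": pd.DataFrame({"chrom": ["1"], "start": [0], "end": [50_000]})}
        e2 = {"a": pd.DataFrame({"chrom": ["1"], "start": [0], "end": [100_000]})}
        r1 = element_density_enrichment(dmrs, e1, 1_000_000)["enrichment"].iloc[0]
        r2 = element_density_enrichment(dmrs, e2, 1_000_000)["enrichment"].iloc[0]
        assert r1 == pytest.approx(2 * r2)

    def test_zero_span_class_excluded(self):
        dmrs = _dmrset([0])
        with pytest.warns(UserWarning, match="zero span"):
            out = element_density_enrichment(
                dmrs, {"bad": pd.DataFrame({"chrom": ["1"], "start": [5], "end": [5]})}, 1_000_000
            )
        assert len(out) == 0


def _tile_results(n, sig_idx, chrom="1", width=2000):
    q = np.full(n, 0.5)
    q[list(sig_idx)] = 1e-4
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * width,
            "end": (np.arange(n) + 1) * width,
            "diff": 10.0,
            "p": q,
            "q": q,
        }
    )


class TestCountSetTest:
    def test_worked_hypergeometric_value(self):
        # m = 10, m_g = 4, m_f = 3, T = 3 -> C(4,3)/C(10,3) = 1/30
        tiles = _tile_results(10, sig_idx=[0, 1, 2, 7])
        genes = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [6000]})
        res = count_set_test(tiles, genes, gene_flank=0, q0=0.01)
        assert (res.m, res.m_g, res.m_f, res.t_count) == (10, 4, 3, 3)
        assert res.p == pytest.approx(1 / 30)

    def test_zero_count_p_one(self):
        tiles = _tile_results(10, sig_idx=[7, 8])
        genes = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [4000]})
        res = count_set_test(tiles, genes, gene_flank=0)
        assert res.t_count == 0 and res.p == 1.0

    def test_equals_fisher_exact_battery(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            m = int(rng.integers(10, 200))
            m_g = int(rng.integers(1, m))
            m_f = int(rng.integers(1, m))
            t = int(rng.integers(max(0, m_g + m_f - m), min(m_g, m_f) + 1))
            hyper = stats.hypergeom.sf(t - 1, m, m_g, m_f)
            table = [[t, m_f - t], [m_g - t, m - m_f - m_g + t]]
            _, fisher = stats.fisher_exact(table, alternative="greater")
            assert hyper == pytest.approx(fisher, abs=1e-12)

    def test_no_overlap_pathway_skipped(self):
        tiles = _tile_results(10, sig_idx=[0])
        genes = pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["2"], "start": [0], "end": [1000]}
        )
        with pytest.warns(UserWarning, match="skipped"):
            out = count_set_test_all(tiles, genes, {"path": ["g"]}, gene_flank=0)
        assert len(out) == 0

    def test_calibration_under_random_placement(self):
        # random significant tiles, random pathways: adjusted-significance
        # rate at 0.05 stays near or below nominal
        rng = np.random.default_rng(9)
        n = 400
        hits = 0
        trials = 200
        tiles = _tile_results(n, sig_idx=rng.choice(n, 40, replace=False))
        gene_rows, sets = [], {}
        for k in range(trials):
            starts = rng.choice(n, 8, replace=False) * 2000
            for i, s in enumerate(starts):
                gene_rows.append((f"p{k}_g{i}", "1", s, s + 1500))
            sets[f"p{k}"] = [f"p{k}_g{i}" for i in range(8)]
        genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end"])
        out = count_set_test_all(tiles, genes, sets, gene_flank=0, q0=0.01)
        assert out["significant"].mean() <= 0.05


class TestOverlap:
    def test_worked_two_by_two(self):
        uni = _universe(1000)
        a = _dmrset(np.arange(100) * 2000)
        b = _dmrset(np.concatenate([np.arange(80, 100), np.arange(200, 230)]) * 2000)
        res = dmr_overlap(a, b, uni)
        assert (res.n_both, res.n_a_only, res.n_b_only, res.n_neither) == (20, 80, 30, 870)
        assert res.odds_ratio == pytest.approx((20 * 870) / (80 * 30))
        _, p_or = stats.fisher_exact([[20, 80], [30, 870]], alternative="greater")
        assert res.p == pytest.approx(p_or)
        assert res.table.sum() == 1000

    def test_identical_sets_minimal_p(self):
        uni = _universe(200)
        a = _dmrset(np.arange(40) * 2000)
        res = dmr_overlap(a, a, uni)
        assert res.n_both == 40 and res.n_a_only == 0
        _, p_min = stats.fisher_exact([[40, 0], [0, 160]], alternative="greater")
        assert res.p == pytest.approx(p_min)

    def test_independent_sets_calibrated(self):
        rng = np.random.default_rng(11)
        uni = _universe(500)
        ps = []
        for _ in range(200):
            a = _dmrset(rng.choice(500, 60, replace=False) * 2000)
            b = _dmrset(rng.choice(500, 40, replace=False) * 2000)
            ps.append(dmr_overlap(a, b, uni).p)
        # Fisher P is conservative/discrete; require no anti-conservative excess
        assert np.mean(np.array(ps) < 0.05) <= 0.08

    def test_foreign_tiles_rejected(self):
        uni = _universe(10)
        a = _dmrset([100_000])
        with pytest.raises(ValueError, match="universe"):
            dmr_overlap(a, a, uni)


class TestSignConcordance:
    def _keys(self, starts):
        return pd.Index([f"1:{s}-{s + 2000}" for s in starts])

    def test_counting_example(self):
        shared = _universe(3)
        keys = self._keys([0, 2000, 4000])
        a = pd.Series([1.0, -2.0, 3.0], index=keys)
        b = pd.Series([2.0, 1.0, 4.0], index=keys)
        frac, excluded = sign_concordance(shared, a, b)
        assert frac == pytest.approx(2 / 3)
        assert excluded == 0

    def test_identity_and_antisymmetry(self):
        shared = _universe(4)
        keys = self._keys([0, 2000, 4000, 6000])
        a = pd.Series([1.0, -1.0, 2.0, -2.0], index=keys)
        assert sign_concordance(shared, a, a)[0] == 1.0
        assert sign_concordance(shared, a, -a)[0] == 0.0

    def test_zero_differences_excluded_and_counted(self):
        shared = _universe(2)
        keys = self._keys([0, 2000])
        a = pd.Series([0.0, 1.0], index=keys)
        b = pd.Series([1.0, 1.0], index=keys)
        frac, excluded = sign_concordance(shared, a, b)
        assert frac == 1.0 and excluded == 1

    def test_empty_shared_set_undefined(self):
        with pytest.raises(ValueError, match="empty"):
            sign_concordance(_universe(0), pd.Series(dtype=float), pd.Series(dtype=float))
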