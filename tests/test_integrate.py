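"""Effect correlations, sign comparisons and the DMR-grid enrichment bridge."""

import warnings

import numpy as np
import pandas as pd
import pytest

from gestarch.data import AssociationColumns as C
from gestarch.dmr import DMRSet
from gestarch.gwas import association_scan, compute_grm, fit_null_model, variant_qc
from gestarch.integrate import (
    effect_correlation,
    gwas_in_dmr_enrichment,
    sign_comparison,
)
from gestarch.simulate import SimConfig, simulate_correlated_effects, simulate_genotypes


def _assoc(effects, positions=None, chroms=None):
    k = len(effects)
    return pd.DataFrame(
        {
            C.ID: [f"v{j}" for j in range(k)],
            C.CHROM: chroms if chroms is not None else ["1"] * k,
            C.POS: positions if positions is not None else np.arange(1, k + 1) * 10,
            C.REF: "A",
            C.ALT: "G",
            C.MAF: 0.3,
            C.BETA: effects,
            C.SE: 0.1,
            C.P: 0.5,
        }
    )


class TestEffectCorrelation:
    def test_identity_and_antisymmetry(self):
        a = _assoc(np.random.default_rng(0).standard_normal(50))
        assert effect_correlation(a, a).correlation == pytest.approx(1.0)
        b = a.copy()
        b[C.BETA] = -b[C.BETA]
        assert effect_correlation(a, b).correlation == pytest.approx(-1.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        a = _assoc(rng.standard_normal(80))
        b = _assoc(rng.standard_normal(80))
        assert effect_correlation(a, b).correlation == pytest.approx(
            effect_correlation(b, a).correlation
        )

    def test_subset_restriction_all_reproduces_genomewide(self):
        rng = np.random.default_rng(2)
        a = _assoc(rng.standard_normal(100))
        b = _assoc(rng.standard_normal(100))
        full = effect_correlation(a, b)
        covering = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [10_000]})
        sub = effect_correlation(a, b, subset_intervals=covering)
        assert sub.correlation == pytest.approx(full.correlation)
        assert sub.n_variants == full.n_variants

    def test_small_subset_warns(self):
        rng = np.random.default_rng(3)
        a = _assoc(rng.standard_normal(5))
        b = _assoc(rng.standard_normal(5))
        with pytest.warns(UserWarning, match="only"):
            effect_correlation(a, b)

    def test_bootstrap_interval_brackets_estimate(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(300)
        a = _assoc(x)
        b = _assoc(x + rng.standard_normal(300))
        res = effect_correlation(a, b, seed=5)
        assert res.ci_low < res.correlation < res.ci_high

    def test_simulated_rg_sign_recovered(self):
        cfg = SimConfig(n_individuals=600, n_variants=2000, seed=61)
        geno = simulate_genotypes(cfg)
        for rg in (0.5, -0.5):
            _, _, pa, pb = simulate_correlated_effects(
                geno, rg=rg, h2_a=0.5, h2_b=0.5, seed=62, n_causal=300
            )
            gq, _ = variant_qc(geno)
            grm = compute_grm(gq)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ra = association_scan(gq, pa, fit_null_model(pa, grm))
                rb = association_scan(gq, pb, fit_null_model(pb, grm))
            r = effect_correlation(ra, rb).correlation
            assert np.sign(r) == np.sign(rg)
            assert abs(r) > 0.2


class TestSignComparison:
    def test_identical_and_negated(self):
        a = _assoc([1.0, -2.0, 0.5])
        table, verdict = sign_comparison(a, a, ("1", 1, 100))
        assert (table["sign"] == "+").all() and verdict == "+"
        b = a.copy()
        b[C.BETA] = -b[C.BETA]
        table, verdict = sign_comparison(a, b, ("1", 1, 100))
        assert (table["sign"] == "-").all() and verdict == "-"

    def test_mixed_toy_effects(self):
        a = _assoc([1.0, -1.0, 2.0])
        b = _assoc([2.0, 1.0, -1.0])
        table, verdict = sign_comparison(a, b, ("1", 1, 100))
        assert table["sign"].tolist() == ["+", "-", "-"]
        assert verdict == "-"


class TestDmrGrid:
    def _dmr_sets(self, geno):
        # build three q cutoffs of nested interval sets around real variants
        pos = geno.variants[C.POS].to_numpy()
        mk = lambda starts: pd.DataFrame(
            {
                "chrom": "1",
                "start": starts,
                "end": np.asarray(starts) + 2000,
                "diff": np.where(np.arange(len(starts)) % 2 == 0, 10.0, -10.0),
                "p": 1e-6,
                "q": 1e-4,
            }
        )
        sets = {}
        for q, k in ((0.05, 30), (0.01, 20), (1e-5, 10)):
            starts = (pos[:: max(1, len(pos) // k)][:k] // 2000) * 2000
            members = mk(sorted(set(starts)))
            members["direction"] = np.where(members["diff"] > 0, "Gain", "Loss")
            sets[q] = DMRSet(q_cutoff=q, min_abs_diff=5, members=members)
        return sets

    def test_grid_shape_and_partition(self, fitted_gwas):
        geno, _, _, _, _, assoc = fitted_gwas
        sets = self._dmr_sets(geno)
        grid = gwas_in_dmr_enrichment(assoc, sets, n_perm=2000, seed=0)
        assert len(grid) == 9  # 3 cutoffs x 3 directions
        assert len(grid) <= 15
        for q in sets:
            both = grid[(grid.q_cutoff == q) & (grid.direction == "Both")]["m_f"].iloc[0]
            gain = grid[(grid.q_cutoff == q) & (grid.direction == "Gain")]["m_f"].iloc[0]
            loss = grid[(grid.q_cutoff == q) & (grid.direction == "Loss")]["m_f"].iloc[0]
            assert gain + loss >= both  # Gain/Loss masks may overlap variants? never: tiles disjoint
            assert gain <= both and loss <= both

    def test_empty_cell_reported_untestable(self, fitted_gwas):
        _, _, _, _, _, assoc = fitted_gwas
        empty = DMRSet(
            q_cutoff=0.01,
            min_abs_diff=5,
            members=pd.DataFrame(columns=["chrom", "start", "end", "diff", "p", "q", "direction"]),
        )
        grid = gwas_in_dmr_enrichment(assoc, {0.01: empty}, n_perm=100, seed=0)
        assert grid["p"].isna().all()

    def test_causal_loaded_direction_enriches(self):
        # place causal variants inside "Loss" tiles: Loss cells must give
        # smaller P than size-matched Gain cells in most replicates
        wins = 0
        reps = 10
        for rep in range(reps):
            cfg = SimConfig(n_individuals=500, n_variants=2000, seed=700 + rep)
            geno = simulate_genotypes(cfg)
            pos = geno.variants[C.POS].to_numpy()
            rng = np.random.default_rng(800 + rep)
            loss_tiles = np.sort(rng.choice(450, 15, replace=False)) * 2000
            gain_tiles = np.sort(rng.choice(np.setdiff1d(np.arange(450), loss_tiles // 2000), 15)) * 2000
            in_loss = np.zeros(len(pos), bool)
            for s in loss_tiles:
                in_loss |= (pos >= s) & (pos < s + 2000)
            causal = np.flatnonzero(in_loss)
            if len(causal) < 3:
                reps -= 1
                continue
            from conftest import plain_null_model, unit_phenotypes

            g = np.zeros(500)
            for idx in causal:
                x = geno.dosages[:, idx].astype(float)
                if x.var() > 0:
                    g = g + x * np.sqrt(0.03 / x.var())
            y = g + rng.standard_normal(500)
            assoc = association_scan(geno, unit_phenotypes(y, geno.individuals),
                                     plain_null_model(y, geno.individuals))
            members = pd.DataFrame(
                {
                    "chrom": "1",
                    "start": np.concatenate([loss_tiles, gain_tiles]),
                    "end": np.concatenate([loss_tiles, gain_tiles]) + 2000,
                    "diff": [-10.0] * 15 + [10.0] * 15,
                    "p": 1e-6,
                    "q": 1e-4,
                }
            )
            members["direction"] = np.where(members["diff"] > 0, "Gain", "Loss")
            sets = {0.01: DMRSet(0.01, 5, members)}
            grid = gwas_in_dmr_enrichment(assoc, sets, n_perm=3000, seed=rep)
            p_loss = grid[grid.direction == "Loss"]["p"].iloc[0]
            p_gain = grid[grid.direction == "Gain"]["p"].iloc[0]
            if p_loss < p_gain:
                wins += 1
        assert wins >= 0.8 * reps
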