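"""Genetic-epigenetic integration across traits.

Genetic correlations between traits are approximated by the Pearson
correlation of per-variant GWAS effects (b), genome-wide or restricted to
variant subsets such as shared-DMR tiles split by the sign of their
methylation change. The module also bridges the two data layers by testing
GWAS-signal enrichment inside DMR sets across the full grid of q-value
cutoffs and methylation-change directions (Both / Gain / Loss).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gestarch.data import AssociationColumns as C
from gestarch.dmr import DMRSet
from gestarch.enrichment import (
    build_stat_vector,
    cyclical_permutation_p,
    intervals_to_mask,
)


@dataclass
class EffectCorrelation:
    """Pearson correlation of two traits' effect vectors over a subset."""

    subset_label: str
    n_variants: int
    correlation: float
    ci_low: float
    ci_high: float


def _aligned_effects(
    assoc_a: pd.DataFrame,
    assoc_b: pd.DataFrame,
    standardized: bool = False,
) -> pd.DataFrame:
    a = assoc_a.set_index(C.ID)
    b = assoc_b.set_index(C.ID)
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("association tables share no variant")
    out = pd.DataFrame(
        {
            "chrom": a.loc[common, C.CHROM].astype(str),
            "pos": a.loc[common, C.POS],
            "b_a": a.loc[common, C.BETA],
            "b_b": b.loc[common, C.BETA],
        }
    ).dropna()
    if standardized:
        # scale effects by sqrt(2p(1-p)) so each variant contributes on the
        # per-standardised-genotype scale
        p = a.loc[out.index, C.MAF].to_numpy(float)
        s = np.sqrt(2.0 * p * (1.0 - p))
        out["b_a"] *= s
        out["b_b"] *= s
    return out


def effect_correlation(
    assoc_a: pd.DataFrame,
    assoc_b: pd.DataFrame,
    subset_intervals: pd.DataFrame | None = None,
    subset_label: str = "all",
    n_boot: int = 1000,
    seed: int = 0,
    standardized: bool = False,
) -> EffectCorrelation:
    """Pearson correlation of effects over shared (optionally subset) variants.

    ``subset_intervals`` restricts to variants inside BED-style intervals
    (start <= pos < end), e.g. shared-DMR tiles. The confidence interval is
    a seeded percentile bootstrap over variants. Subsets below 10 variants
    are reported with a small-sample warning.
    """
    eff = _aligned_effects(assoc_a, assoc_b, standardized)
    if subset_intervals is not None:
        keep = np.zeros(len(eff), dtype=bool)
        chroms = eff["chrom"].to_numpy()
        pos = eff["pos"].to_numpy()
        for chrom, sub in subset_intervals.groupby("chrom"):
            on_c = chroms == str(chrom)
            for s, e in sub[["start", "end"]].to_numpy(float):
                keep |= on_c & (pos >= s) & (pos < e)
        eff = eff[keep]
    n = len(eff)
    if n < 2:
        raise ValueError(f"subset {subset_label!r} has fewer than 2 variants")
    if n < 10:
        warnings.warn(f"subset {subset_label!r} has only {n} variants", stacklevel=2)
    x = eff["b_a"].to_numpy(float)
    y = eff["b_b"].to_numpy(float)
    r = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        with np.errstate(invalid="ignore"):
            boots[i] = np.corrcoef(x[idx], y[idx])[0, 1]
    boots = boots[np.isfinite(boots)]
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if len(boots) else (np.nan, np.nan))
    return EffectCorrelation(subset_label, n, r, float(lo), float(hi))


def sign_comparison(
    assoc_a: pd.DataFrame,
    assoc_b: pd.DataFrame,
    region: tuple[str, int, int],
) -> tuple[pd.DataFrame, str]:
    """Per-variant sign agreement of effects within a region.

    ``region`` is (chrom, start, end), 1-based inclusive. Each variant is
    labelled "+" when sign(b_a) * sign(b_b) > 0 and "-" otherwise; variants
    with a zero effect in either trait are excluded but counted. Returns
    the per-variant table and the majority verdict.
    """
    chrom, start, end = region
    eff = _aligned_effects(assoc_a, assoc_b)
    eff = eff[(eff["chrom"] == str(chrom)) & (eff["pos"] >= start) & (eff["pos"] <= end)]
    nonzero = (eff["b_a"] != 0) & (eff["b_b"] != 0)
    n_zero = int((~nonzero).sum())
    eff = eff[nonzero].copy()
    if len(eff) == 0:
        raise ValueError("no variant with nonzero effects in region")
    eff["sign"] = np.where(np.sign(eff["b_a"]) == np.sign(eff["b_b"]), "+", "-")
    eff["n_zero_excluded"] = n_zero
    majority = "+" if (eff["sign"] == "+").mean() > 0.5 else "-"
    return eff.reset_index()[["id", "chrom", "pos", "sign"]], majority


def gwas_in_dmr_enrichment(
    associations: pd.DataFrame,
    dmr_sets: dict[float, DMRSet],
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """GWAS-signal enrichment across the (q-cutoff x direction) DMR grid.

    For every q cutoff and each direction subset (Both, Gain, Loss), the
    member tiles form an interval feature and the sum-based statistic is
    tested with the cyclical permutation null. Empty cells are reported
    untestable (NaN P). The grid has at most 5 x 3 testable cells.
    """
    stat = build_stat_vector(associations)
    ss = np.random.SeedSequence(seed)
    rows = []
    cells = [
        (q_cut, direction)
        for q_cut in dmr_sets
        for direction in ("Both", "Gain", "Loss")
    ]
    for (q_cut, direction), child in zip(cells, ss.spawn(len(cells))):
        dmrs = dmr_sets[q_cut]
        members = {
            "Both": dmrs.members,
            "Gain": dmrs.gain,
            "Loss": dmrs.loss,
        }[direction]
        label = f"q<{q_cut:g}|{direction}"
        if len(members) == 0:
            rows.append((q_cut, direction, 0, np.nan, 0, np.nan, False))
            continue
        mask = intervals_to_mask(members[["chrom", "start", "end"]], stat, feature_id=label)
        if mask.m_f == 0:
            rows.append((q_cut, direction, 0, np.nan, 0, np.nan, False))
            continue
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        res = cyclical_permutation_p(stat, mask, n_perm=n_perm, seed=sub_seed)
        rows.append((q_cut, direction, res.m_f, res.t_sum, res.n_perm, res.p, res.enumerated))
    return pd.DataFrame(
        rows, columns=["q_cutoff", "direction", "m_f", "t_sum", "n_perm", "p", "enumerated"]
    )
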