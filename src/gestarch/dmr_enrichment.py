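"""Set-level and positional enrichment statistics on DMRs.

Three complementary views of where DMRs land:

* element-density enrichment — ratio of the DMR density inside a genomic
  element class to the genome-wide DMR density;
* the count-based pathway test — T_count = number of significant tiles
  (q < q0) among the tiles overlapping a pathway's genes (+-10 kb), tested
  against Hyper(m, m_g, m_f) where m is the number of tested tiles genome
  wide, m_g the number of significant tiles genome wide and m_f the number
  of tested tiles in the pathway; equivalently the one-sided Fisher exact
  test on the induced 2x2 table;
* cross-trait DMR overlap on a shared tile universe, with a one-sided
  Fisher exact P and sign-concordance of the shared tiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gestarch.dmr import DMRSet, adjust_q


def _merge_per_chrom(intervals: pd.DataFrame) -> dict[str, np.ndarray]:
    out = {}
    for chrom, sub in intervals.groupby("chrom"):
        iv = sub[["start", "end"]].to_numpy(float)
        iv = iv[np.argsort(iv[:, 0])]
        merged = [list(iv[0])]
        for s, e in iv[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[str(chrom)] = np.asarray(merged)
    return out


def _overlaps_any(intervals: pd.DataFrame, targets: dict[str, np.ndarray]) -> np.ndarray:
    """Per interval: does it intersect (>= 1 bp) any merged target interval?"""
    hit = np.zeros(len(intervals), dtype=bool)
    chroms = intervals["chrom"].to_numpy(str)
    starts = intervals["start"].to_numpy(float)
    ends = intervals["end"].to_numpy(float)
    for chrom, merged in targets.items():
        on_c = chroms == chrom
        if not on_c.any():
            continue
        t_start, t_end = merged[:, 0], merged[:, 1]
        # candidate target: the one with the largest start <= interval end - 1
        j = np.searchsorted(t_start, ends[on_c], side="left") - 1
        ok = j >= 0
        jj = np.clip(j, 0, None)
        ok &= t_end[jj] > starts[on_c]
        hit[np.flatnonzero(on_c)[ok]] = True
    return hit


def element_density_enrichment(
    dmrs: DMRSet | pd.DataFrame,
    elements: dict[str, pd.DataFrame],
    genome_size: int,
) -> pd.DataFrame:
    """Observed-over-expected DMR density per genomic element class.

    The observed density is the count of DMRs intersecting the class
    (>= 1 bp) divided by the class's merged span in bp; the expected
    density is the genome-wide DMR count divided by ``genome_size``.
    An element class spanning the whole genome has enrichment exactly 1.
    """
    iv = dmrs.intervals() if isinstance(dmrs, DMRSet) else dmrs[["chrom", "start", "end"]]
    n_total = len(iv)
    expected = n_total / genome_size
    rows = []
    for name, elem in elements.items():
        merged = _merge_per_chrom(elem)
        span = sum(float((m[:, 1] - m[:, 0]).sum()) for m in merged.values())
        if span <= 0:
            warnings.warn(f"element class {name!r} has zero span; excluded", stacklevel=2)
            continue
        n_in = int(_overlaps_any(iv, merged).sum())
        density = n_in / span
        rows.append((name, n_in, span, density, density / expected if expected > 0 else np.nan))
    return pd.DataFrame(rows, columns=["element", "n_dmr", "span", "density", "enrichment"])


@dataclass
class HyperResult:
    """Count-based pathway enrichment under the hypergeometric null."""

    pathway_id: str
    m: int  # tested tiles genome-wide
    m_g: int  # significant tiles genome-wide
    m_f: int  # tested tiles in the pathway
    t_count: int  # significant tiles in the pathway
    p: float
    q0: float
    adjusted_p: float = np.nan


def count_set_test(
    tile_results: pd.DataFrame,
    pathway_genes: pd.DataFrame,
    pathway_id: str = "pathway",
    gene_flank: int = 10_000,
    q0: float = 0.01,
) -> HyperResult:
    """Hypergeometric upper-tail test of significant-tile count in a pathway.

    A tile belongs to the pathway if it intersects (>= 1 bp) any pathway
    gene extended ``gene_flank`` bp both sides. T_count is the number of
    such tiles with q < ``q0``; P = P(X >= T_count) for
    X ~ Hyper(m, m_g, m_f).
    """
    tested = tile_results.dropna(subset=["q"])
    m = len(tested)
    sig = tested["q"].to_numpy() < q0
    m_g = int(sig.sum())
    ext = pathway_genes[["chrom", "start", "end"]].copy()
    ext["start"] = np.maximum(ext["start"] - gene_flank, 0)
    ext["end"] = ext["end"] + gene_flank
    in_path = _overlaps_any(tested[["chrom", "start", "end"]], _merge_per_chrom(ext))
    m_f = int(in_path.sum())
    if m_f == 0:
        raise ValueError(f"pathway {pathway_id!r} overlaps no tested tile")
    t_count = int((sig & in_path).sum())
    p = float(stats.hypergeom.sf(t_count - 1, m, m_g, m_f))
    return HyperResult(pathway_id, m, m_g, m_f, t_count, min(p, 1.0), q0)


def count_set_test_all(
    tile_results: pd.DataFrame,
    genes: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    gene_flank: int = 10_000,
    q0: float = 0.01,
) -> pd.DataFrame:
    """Run :func:`count_set_test` for every gene set, BH-adjusted across sets."""
    results = []
    for pid, members in gene_sets.items():
        sub = genes[genes["gene_id"].isin(members)]
        if len(sub) == 0:
            warnings.warn(f"pathway {pid!r} has no resolvable gene; skipped", stacklevel=2)
            continue
        try:
            results.append(count_set_test(tile_results, sub, pid, gene_flank, q0))
        except ValueError:
            warnings.warn(f"pathway {pid!r} overlaps no tested tile; skipped", stacklevel=2)
    if not results:
        return pd.DataFrame(
            columns=["pathway", "m", "m_g", "m_f", "t_count", "p", "adjusted_p", "significant"]
        )
    adj = adjust_q(np.array([r.p for r in results]))
    rows = []
    for r, a in zip(results, adj):
        r.adjusted_p = float(a)
        rows.append((r.pathway_id, r.m, r.m_g, r.m_f, r.t_count, r.p, r.adjusted_p, a < 0.05))
    return pd.DataFrame(
        rows, columns=["pathway", "m", "m_g", "m_f", "t_count", "p", "adjusted_p", "significant"]
    )


@dataclass
class OverlapResult:
    """Cross-trait DMR overlap on a shared tile universe."""

    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int
    odds_ratio: float
    p: float
    shared_tiles: pd.DataFrame

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.n_both, self.n_a_only], [self.n_b_only, self.n_neither]])


def _tile_keys(frame: pd.DataFrame) -> pd.Index:
    return pd.Index(
        frame["chrom"].astype(str) + ":" + frame["start"].astype(str) + "-" + frame["end"].astype(str)
    )


def dmr_overlap(
    dmrs_a: DMRSet,
    dmrs_b: DMRSet,
    universe: pd.DataFrame,
) -> OverlapResult:
    """Fisher-exact overlap of two DMR sets called on the same tile universe.

    Tiles are cross-classified by membership in each set; the P-value is
    the one-sided (greater) Fisher exact test for over-representation of
    shared tiles. Raises if either set contains tiles outside the universe.
    """
    uni = _tile_keys(universe)
    keys_a = _tile_keys(dmrs_a.members)
    keys_b = _tile_keys(dmrs_b.members)
    if not keys_a.isin(uni).all() or not keys_b.isin(uni).all():
        raise ValueError("DMR sets must be called on the given tile universe")
    in_a = uni.isin(keys_a)
    in_b = uni.isin(keys_b)
    n_both = int((in_a & in_b).sum())
    n_a = int((in_a & ~in_b).sum())
    n_b = int((~in_a & in_b).sum())
    n_none = int((~in_a & ~in_b).sum())
    odds, p = stats.fisher_exact([[n_both, n_a], [n_b, n_none]], alternative="greater")
    shared = universe[np.asarray(in_a & in_b)].reset_index(drop=True)
    return OverlapResult(n_both, n_a, n_b, n_none, float(odds), float(p), shared)


def sign_concordance(
    shared_tiles: pd.DataFrame,
    diffs_a: pd.Series,
    diffs_b: pd.Series,
) -> tuple[float, int]:
    """Fraction of shared tiles whose methylation differences agree in sign.

    ``diffs_a``/``diffs_b`` are indexed by tile key (chrom:start-end).
    Tiles with a zero difference in either trait are excluded; the count of
    exclusions is returned alongside the fraction. Raises when the shared
    set is empty (concordance undefined).
    """
    keys = _tile_keys(shared_tiles)
    if len(keys) == 0:
        raise ValueError("sign concordance undefined for an empty shared set")
    a = diffs_a.loc[keys].to_numpy(float)
    b = diffs_b.loc[keys].to_numpy(float)
    nonzero = (a != 0) & (b != 0)
    excluded = int((~nonzero).sum())
    if not nonzero.any():
        raise ValueError("all shared tiles have a zero difference")
    frac = float(np.mean(np.sign(a[nonzero]) == np.sign(b[nonzero])))
    return frac, excluded
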