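"""Tile-based differential methylation between trait-extreme groups.

Per-CpG counts are coverage-filtered (>= 10 reads by default), symmetric
CpG strands merged, and the genome tiled into 2000-bp windows with 2000-bp
step. Per tile, a binomial logistic regression of methylated fraction on
the group indicator is compared with the intercept-only model by a
likelihood-ratio chi-square test (1 df); with a single binary covariate the
maximum-likelihood fit has a closed form (group-pooled proportions), so the
LRT is computed exactly without iterative fitting, and a per-sample
statsmodels GLM gives the same statistic (this identity is exercised in the
test suite). P-values are adjusted to q-values by Benjamini-Hochberg, and a
tile is a DMR when q is below the chosen cutoff and the absolute group
difference exceeds 5 percentage points; Gain/Loss follow the sign of the
difference (high-group minus low-group).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

Q_CUTOFF_GRID = (0.05, 0.01, 1e-5, 1e-8, 1e-10)


def filter_cpg_coverage(records: pd.DataFrame, min_reads: int = 10) -> pd.DataFrame:
    """Keep CpG records covered by at least ``min_reads`` clean reads."""
    return records[records["coverage"] >= min_reads].reset_index(drop=True)


def destrand(records: pd.DataFrame) -> pd.DataFrame:
    """Merge symmetric CpG strand counts onto the plus-strand coordinate.

    Minus-strand cytosines (at pos) pair with the plus-strand cytosine at
    pos - 1; counts at the shifted coordinate are summed. CpG methylation is
    strand-symmetric, so destranding doubles the effective coverage without
    changing proportions.
    """
    df = records.copy()
    minus = df["strand"] == "-"
    df.loc[minus, "pos"] = df.loc[minus, "pos"] - 1
    out = (
        df.groupby(["chrom", "pos"], as_index=False)[["coverage", "numCs", "numTs"]]
        .sum()
        .assign(strand="+")
    )
    return out[["chrom", "pos", "strand", "coverage", "numCs", "numTs"]]


@dataclass
class MethylTiles:
    """Fixed-width tiles with per-sample methylated/unmethylated totals."""

    intervals: pd.DataFrame  # chrom, start, end (BED-style)
    samples: list[str]
    meth: np.ndarray  # (tiles, samples)
    unmeth: np.ndarray
    n_cpg: np.ndarray  # covered CpGs per (tile, sample)

    @property
    def n_tiles(self) -> int:
        return len(self.intervals)

    def tile_ids(self) -> pd.Series:
        iv = self.intervals
        return iv["chrom"].astype(str) + ":" + iv["start"].astype(str) + "-" + iv["end"].astype(str)


def tile_counts(
    samples: dict[str, pd.DataFrame],
    window: int = 2000,
    step: int = 2000,
    min_cpgs: int = 3,
    chrom_sizes: dict[str, int] | None = None,
    merge_strands: bool = True,
) -> MethylTiles:
    """Summarise per-CpG counts onto a fixed 2000-bp tiling.

    Tiles start at 0, ``step`` bp apart, each ``window`` bp long (the last
    tile of a chromosome is truncated at the chromosome end when sizes are
    given). CpG positions are 1-based; tiles are BED-style. Tiles with
    fewer than ``min_cpgs`` covered CpGs in any sample are dropped (and
    counted in a warning), so every retained tile is testable in every
    sample.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    names = list(samples)
    prepared = {}
    for name, df in samples.items():
        if merge_strands:
            df = destrand(df)
        prepared[name] = df

    # aggregate per (chrom, tile start) per sample; a CpG can fall in
    # several tiles when step < window (phase loop), exactly one otherwise
    n_phase = -(-window // step)
    per_sample = []
    for name in names:
        df = prepared[name]
        pos0 = df["pos"].to_numpy() - 1
        frames = []
        for ph in range(n_phase):
            t = pos0 // step - ph
            start = t * step
            valid = (t >= 0) & (pos0 < start + window)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": df["chrom"].to_numpy()[valid],
                        "start": start[valid],
                        "m": df["numCs"].to_numpy()[valid],
                        "u": df["numTs"].to_numpy()[valid],
                    }
                )
            )
        agg = (
            pd.concat(frames)
            .groupby(["chrom", "start"])
            .agg(m=("m", "sum"), u=("u", "sum"), n=("m", "size"))
        )
        per_sample.append(agg)

    idx = per_sample[0].index
    for a in per_sample[1:]:
        idx = idx.union(a.index)
    if len(idx) == 0:
        raise ValueError("no CpG records to tile")
    idx = idx.sortlevel()[0]
    aligned = [a.reindex(idx, fill_value=0) for a in per_sample]
    meth = np.column_stack([a["m"].to_numpy(float) for a in aligned])
    unmeth = np.column_stack([a["u"].to_numpy(float) for a in aligned])
    ncpg = np.column_stack([a["n"].to_numpy() for a in aligned])
    keys = list(idx)

    keep = (ncpg >= min_cpgs).all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"{dropped} tiles dropped with < {min_cpgs} covered CpGs in a sample", stacklevel=2)
    keys = [k for k, kp in zip(keys, keep) if kp]
    intervals = pd.DataFrame(
        {
            "chrom": [k[0] for k in keys],
            "start": [k[1] for k in keys],
            "end": [
                k[1] + window
                if chrom_sizes is None
                else min(k[1] + window, chrom_sizes.get(k[0], k[1] + window))
                for k in keys
            ],
        }
    )
    return MethylTiles(
        intervals=intervals,
        samples=names,
        meth=meth[keep],
        unmeth=unmeth[keep],
        n_cpg=ncpg[keep].astype(int),
    )


def _binom_loglik(m: np.ndarray, u: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood kernel sum(m log p + u log(1-p)), 0 log 0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        lm = np.where(m > 0, m * np.log(p), 0.0)
        lu = np.where(u > 0, u * np.log(1.0 - p), 0.0)
    return lm + lu


def diff_meth_all(
    tiles: MethylTiles,
    group_labels: dict[str, str] | pd.Series,
    overdispersion: bool = False,
) -> pd.DataFrame:
    """Group-difference test for every tile.

    ``group_labels`` maps sample name to "high"/"low". The per-tile
    likelihood-ratio statistic compares the logistic model with a group
    covariate to the intercept-only model over per-sample binomial
    observations; the closed-form MLE makes this the G-test on pooled group
    totals. The reported difference is 100 x (coverage-weighted methylation
    proportion in high group - low group). Tiles with zero coverage in
    either group get NaN and a warning.

    With ``overdispersion=True`` the LRT is deflated by a Pearson
    dispersion factor estimated from per-sample residuals around the group
    fits (floored at 1), a standard correction when biological replicates
    are more variable than binomial.
    """
    labels = pd.Series(group_labels)
    high = np.array([labels[s] == "high" for s in tiles.samples])
    low = np.array([labels[s] == "low" for s in tiles.samples])
    if not high.any() or not low.any():
        raise ValueError("both groups need at least one sample")

    Mh = tiles.meth[:, high].sum(axis=1)
    Uh = tiles.unmeth[:, high].sum(axis=1)
    Ml = tiles.meth[:, low].sum(axis=1)
    Ul = tiles.unmeth[:, low].sum(axis=1)
    nh, nl = Mh + Uh, Ml + Ul
    bad = (nh == 0) | (nl == 0)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} tiles skipped with zero coverage in a group", stacklevel=2)

    with np.errstate(divide="ignore", invalid="ignore"):
        ph = Mh / nh
        pl = Ml / nl
        pp = (Mh + Ml) / (nh + nl)
    lrt = 2.0 * (
        _binom_loglik(Mh, Uh, ph)
        + _binom_loglik(Ml, Ul, pl)
        - _binom_loglik(Mh + Ml, Uh + Ul, pp)
    )
    lrt = np.clip(lrt, 0.0, None)

    if overdispersion:
        p_fit = np.where(high, ph[:, None], pl[:, None])
        n_s = tiles.meth + tiles.unmeth
        with np.errstate(divide="ignore", invalid="ignore"):
            pearson = (tiles.meth - n_s * p_fit) ** 2 / (n_s * p_fit * (1 - p_fit))
        pearson = np.where(np.isfinite(pearson), pearson, 0.0)
        dof = max(len(tiles.samples) - 2, 1)
        phi = np.maximum(pearson.sum(axis=1) / dof, 1.0)
        lrt = lrt / phi

    p = stats.chi2.sf(lrt, df=1)
    p = np.where(lrt == 0, 1.0, p)
    out = tiles.intervals.copy()
    out["n_cpg"] = tiles.n_cpg.min(axis=1)
    out["diff"] = np.where(bad, np.nan, 100.0 * (ph - pl))
    out["p"] = np.where(bad, np.nan, np.clip(p, np.finfo(float).tiny, 1.0))
    return out


def diff_meth_test(
    meth_high: np.ndarray,
    unmeth_high: np.ndarray,
    meth_low: np.ndarray,
    unmeth_low: np.ndarray,
) -> tuple[float, float]:
    """(difference in percentage points, P) for one tile from raw counts.

    Convenience wrapper around the closed-form likelihood-ratio test; the
    arrays hold per-sample counts within each group.
    """
    tiles = MethylTiles(
        intervals=pd.DataFrame({"chrom": ["0"], "start": [0], "end": [1]}),
        samples=[f"h{i}" for i in range(len(np.atleast_1d(meth_high)))]
        + [f"l{i}" for i in range(len(np.atleast_1d(meth_low)))],
        meth=np.concatenate([np.atleast_1d(meth_high), np.atleast_1d(meth_low)])[None, :].astype(float),
        unmeth=np.concatenate([np.atleast_1d(unmeth_high), np.atleast_1d(unmeth_low)])[None, :].astype(float),
        n_cpg=np.ones((1, len(np.atleast_1d(meth_high)) + len(np.atleast_1d(meth_low))), dtype=int),
    )
    labels = {s: ("high" if s.startswith("h") else "low") for s in tiles.samples}
    res = diff_meth_all(tiles, labels)
    return float(res["diff"].iloc[0]), float(res["p"].iloc[0])


def adjust_q(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in P, q >= P)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    ok = np.isfinite(p)
    q = np.full_like(p, np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


@dataclass
class DMRSet:
    """Tiles passing both the q and the absolute-difference thresholds."""

    q_cutoff: float
    min_abs_diff: float
    members: pd.DataFrame  # tile rows with diff, p, q, direction

    @property
    def gain(self) -> pd.DataFrame:
        return self.members[self.members["direction"] == "Gain"]

    @property
    def loss(self) -> pd.DataFrame:
        return self.members[self.members["direction"] == "Loss"]

    def intervals(self) -> pd.DataFrame:
        return self.members[["chrom", "start", "end"]].reset_index(drop=True)


def call_dmrs(
    results: pd.DataFrame,
    q_cutoff: float = 0.01,
    min_abs_diff: float = 5.0,
) -> DMRSet:
    """Call DMRs: q < ``q_cutoff`` and |difference| > ``min_abs_diff``.

    Direction is Gain for difference > +min_abs_diff (higher methylation in
    the high-trait group) and Loss for difference < -min_abs_diff; the two
    subsets partition the member set exactly.
    """
    if "q" not in results.columns:
        raise ValueError("q-values must be computed before DMR calling (adjust_q)")
    sel = (results["q"] < q_cutoff) & (results["diff"].abs() > min_abs_diff)
    members = results[sel].copy()
    members["direction"] = np.where(members["diff"] > 0, "Gain", "Loss")
    return DMRSet(q_cutoff=q_cutoff, min_abs_diff=min_abs_diff, members=members.reset_index(drop=True))
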