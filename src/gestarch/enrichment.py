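"""Sum-based GWAS-signal enrichment with an LD-preserving permutation null.

The test statistic for a genomic feature is T_sum = sum of squared marker
effects (b^2) over the variants the feature contains. Its null distribution
is obtained by cyclical permutation: the genome-ordered b^2 vector is
rotated by a random offset while feature positions stay fixed, which
preserves the local correlation (LD) structure of the statistics, and the
empirical P is the one-tailed proportion of rotated statistics at least as
large as the observed one. When the number of requested permutations covers
all m - 1 non-identity rotations the null is enumerated exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gestarch.data import AssociationColumns as C, sort_by_genome

_FFT_THRESHOLD = 5_000_000  # direct-gather work limit before switching to FFT


@dataclass
class StatVector:
    """Squared effects in fixed genome order (the rotation circle).

    Chromosomes are concatenated ascending by numeric label then
    lexicographically; the order is immutable after construction.
    """

    values: np.ndarray  # b^2, genome order
    chrom: np.ndarray
    pos: np.ndarray
    variant_id: np.ndarray

    @property
    def m(self) -> int:
        return len(self.values)


@dataclass
class FeatureMask:
    """Boolean inclusion of each stat-vector position in one feature."""

    feature_id: str
    mask: np.ndarray

    @property
    def m_f(self) -> int:
        return int(self.mask.sum())


@dataclass
class EnrichmentResult:
    feature_id: str
    t_sum: float
    m_f: int
    n_perm: int
    p: float
    enumerated: bool


def build_stat_vector(associations: pd.DataFrame) -> StatVector:
    """Order squared effects by (chromosome, position).

    Raises on duplicate (chrom, pos) pairs, listing the offenders.
    """
    frame = sort_by_genome(associations[[C.ID, C.CHROM, C.POS, C.BETA]])
    dup = frame.duplicated(subset=[C.CHROM, C.POS], keep=False)
    if dup.any():
        offenders = frame.loc[dup, [C.CHROM, C.POS]].drop_duplicates()
        raise ValueError(f"duplicate variant positions: {offenders.to_dict('records')}")
    b = frame[C.BETA].to_numpy(float)
    return StatVector(
        values=b * b,
        chrom=frame[C.CHROM].to_numpy(),
        pos=frame[C.POS].to_numpy(),
        variant_id=frame[C.ID].to_numpy(),
    )


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Merge possibly overlapping (start, end) rows; input need not be sorted."""
    if len(iv) == 0:
        return iv.reshape(0, 2)
    iv = iv[np.argsort(iv[:, 0])]
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged)


def feature_to_mask(
    feature_id: str,
    member_genes: list[str],
    genes: pd.DataFrame,
    stat: StatVector,
    gene_flank: int = 0,
) -> FeatureMask:
    """Mask of stat-vector positions inside any member gene +- ``gene_flank``.

    Gene intervals are BED-style 0-based half-open; a 1-based variant
    position p falls inside gene [start, end) extended by f bp iff
    start - f < p <= end + f. A variant shared by two member genes is
    counted once (the mask is boolean).
    """
    member = genes[genes["gene_id"].isin(member_genes)]
    mask = np.zeros(stat.m, dtype=bool)
    for chrom, sub in member.groupby("chrom"):
        on_c = stat.chrom == chrom
        if not on_c.any():
            continue
        iv = sub[["start", "end"]].to_numpy(float)
        iv[:, 0] -= gene_flank
        iv[:, 1] += gene_flank
        for s, e in _merge_intervals(iv):
            mask |= on_c & (stat.pos > s) & (stat.pos <= e)
    return FeatureMask(feature_id=feature_id, mask=mask)


def intervals_to_mask(
    intervals: pd.DataFrame,
    stat: StatVector,
    feature_id: str = "intervals",
) -> FeatureMask:
    """Mask of stat-vector positions falling inside BED-style intervals.

    A variant at position p is included in [start, end) iff
    start <= p < end.
    """
    mask = np.zeros(stat.m, dtype=bool)
    for chrom, sub in intervals.groupby("chrom"):
        on_c = stat.chrom == chrom
        if not on_c.any():
            continue
        for s, e in _merge_intervals(sub[["start", "end"]].to_numpy(float)):
            mask |= on_c & (stat.pos >= s) & (stat.pos < e)
    return FeatureMask(feature_id=feature_id, mask=mask)


def sum_statistic(stat: StatVector, mask: FeatureMask) -> float:
    """T_sum = sum of squared effects at masked positions."""
    if len(mask.mask) != stat.m:
        raise ValueError("mask length does not match stat vector")
    return float(stat.values[mask.mask].sum())


def _rotation_sums(values: np.ndarray, idx: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """T_k = sum over feature indices i of values[(i + k) mod m], per offset."""
    m = len(values)
    if len(offsets) * len(idx) <= _FFT_THRESHOLD:
        out = np.empty(len(offsets))
        chunk = max(1, _FFT_THRESHOLD // max(len(idx), 1))
        for lo in range(0, len(offsets), chunk):
            offs = offsets[lo : lo + chunk]
            out[lo : lo + chunk] = values[(idx[None, :] + offs[:, None]) % m].sum(axis=1)
        return out
    # full circular cross-correlation via FFT, then pick the requested offsets
    mask = np.zeros(m)
    mask[idx] = 1.0
    all_sums = np.fft.ifft(np.fft.fft(values) * np.conj(np.fft.fft(mask))).real
    return all_sums[offsets]


def cyclical_permutation_p(
    stat: StatVector,
    mask: FeatureMask,
    n_perm: int = 10_000,
    seed: int | None = None,
    tie: str = "ge",
    add_one: bool = True,
) -> EnrichmentResult:
    """Empirical enrichment P by cyclical rotation of the statistic vector.

    Each permutation rotates the genome-ordered b^2 vector by an offset
    k in {1, ..., m-1} while the feature's positions stay fixed, preserving
    the order (and hence the LD correlation) of the statistics. When
    ``n_perm`` >= m - 1 all non-identity rotations are enumerated exactly;
    otherwise offsets are sampled uniformly without replacement.

    By default P = (1 + #{T_perm >= T_obs}) / (1 + n_perm) (add-one
    smoothing, ">=" tie handling); ``add_one=False`` recovers the plain
    proportion and ``tie="gt"`` the strict comparison.
    """
    m = stat.m
    if m < 2:
        raise ValueError("stat vector must have length >= 2")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tie not in ("ge", "gt"):
        raise ValueError("tie must be 'ge' or 'gt'")
    idx = np.flatnonzero(mask.mask)
    if len(idx) == 0:
        raise ValueError(f"feature {mask.feature_id!r} covers no variant")
    t_obs = float(stat.values[idx].sum())
    if len(idx) == m:
        warnings.warn(
            f"feature {mask.feature_id!r} covers the whole genome; "
            "statistic invariant under rotation",
            stacklevel=2,
        )
        return EnrichmentResult(mask.feature_id, t_obs, m, 0, 1.0, True)

    if n_perm >= m - 1:
        offsets = np.arange(1, m)
        enumerated = True
    else:
        rng = np.random.default_rng(seed)
        offsets = rng.choice(m - 1, size=n_perm, replace=False) + 1
        enumerated = False
    t_perm = _rotation_sums(stat.values, idx, offsets)

    tol = 1e-9 * max(1.0, abs(t_obs))
    if tie == "ge":
        count = int(np.sum(t_perm >= t_obs - tol))
    else:
        count = int(np.sum(t_perm > t_obs + tol))
    n_used = len(offsets)
    p = (1 + count) / (1 + n_used) if add_one else count / n_used
    return EnrichmentResult(mask.feature_id, t_obs, len(idx), n_used, float(p), enumerated)


def enrich_all(
    associations: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    gene_sets: dict[str, list[str]] | None = None,
    interval_sets: dict[str, pd.DataFrame] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    gene_flank: int = 0,
    **perm_kwargs,
) -> pd.DataFrame:
    """Run the enrichment test for every feature over one shared stat vector.

    Features may be gene sets (resolved through the gene interval table) or
    named BED-style interval collections. Features overlapping no variant
    are excluded and logged with a warning. Per-feature permutation seeds
    derive deterministically from ``seed``.
    """
    stat = build_stat_vector(associations)
    masks: list[FeatureMask] = []
    if gene_sets:
        if genes is None:
            raise ValueError("gene interval table required with gene sets")
        for fid, members in gene_sets.items():
            masks.append(feature_to_mask(fid, members, genes, stat, gene_flank))
    if interval_sets:
        for fid, iv in interval_sets.items():
            masks.append(intervals_to_mask(iv, stat, feature_id=fid))

    ss = np.random.SeedSequence(seed)
    rows = []
    for mask, child in zip(masks, ss.spawn(len(masks))):
        if mask.m_f == 0:
            warnings.warn(f"feature {mask.feature_id!r} overlaps no variant; skipped", stacklevel=2)
            continue
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        res = cyclical_permutation_p(stat, mask, n_perm=n_perm, seed=sub_seed, **perm_kwargs)
        rows.append(
            (res.feature_id, res.m_f, res.t_sum, res.n_perm, res.p, res.enumerated)
        )
    return pd.DataFrame(rows, columns=["feature", "m_f", "t_sum", "n_perm", "p", "enumerated"])
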