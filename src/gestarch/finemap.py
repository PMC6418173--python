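"""Simplified Bayesian fine-mapping and gene-level PPC aggregation.

Significant regions are the minimal spans of genome-wide-significant
variants extended by 1 Mb both sides (merged when the extended spans
overlap). Within a region, per-variant evidence is a Wakefield-style
approximate Bayes factor computed from the marginal (or conditional)
effect and standard error; under a single-causal-variant model with a
uniform prior, the posterior probability of causality (PPC) of variant i
is ABF_i / sum_j ABF_j. Independent signals are found by forward
conditioning: the lead variant is added as a fixed covariate and the
remaining variants re-tested until no conditional P reaches the stopping
threshold. The PPC of a gene is the sum of variant PPCs within 2 kb of the
gene, reported per signal and totalled; genes exceeding a PPC cutoff of
0.05 are flagged as candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from gestarch.data import AssociationColumns as C, GenotypeMatrix, PhenotypeTable
from gestarch.gwas import NullModel

DEFAULT_PRIOR_VAR = 0.04
DEFAULT_P_STOP = 1e-6
REGION_FLANK = 1_000_000


@dataclass
class CandidateRegion:
    """Minimal span of significant variants, extended 1 Mb both sides."""

    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    significant_ids: list[str] = field(default_factory=list)

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        return (chrom == self.chrom) & (pos >= self.start) & (pos <= self.end)


@dataclass
class SignalPPC:
    """Per-variant posterior probabilities of causality for one signal."""

    signal_index: int
    variant_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ppc: np.ndarray
    lead_id: str

    def __post_init__(self) -> None:
        total = float(np.sum(self.ppc))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"signal PPCs must sum to 1, got {total!r}")


def define_candidate_regions(
    associations: pd.DataFrame,
    threshold: float,
    chrom_sizes: dict[str, int] | None = None,
    flank: int = REGION_FLANK,
) -> list[CandidateRegion]:
    """Cluster genome-wide-significant variants into flanked regions.

    Per chromosome, each significant variant spawns the interval
    [pos - flank, pos + flank]; overlapping intervals merge into one
    region, clipped at chromosome bounds (start >= 1). Returns an empty
    list when nothing is significant.
    """
    sig = associations[associations[C.P] < threshold]
    regions: list[CandidateRegion] = []
    for chrom, sub in sig.groupby(C.CHROM, sort=False):
        pos = np.sort(sub[C.POS].to_numpy())
        ids_by_pos = sub.sort_values(C.POS)[C.ID].to_numpy()
        size = None if chrom_sizes is None else chrom_sizes.get(str(chrom))
        start, end = pos[0] - flank, pos[0] + flank
        members = [ids_by_pos[0]]
        for p, vid in zip(pos[1:], ids_by_pos[1:]):
            if p - flank <= end:
                end = p + flank
                members.append(vid)
            else:
                regions.append(_clip_region(str(chrom), start, end, members, size))
                start, end, members = p - flank, p + flank, [vid]
        regions.append(_clip_region(str(chrom), start, end, members, size))
    return regions


def _clip_region(chrom, start, end, members, size) -> CandidateRegion:
    start = max(1, int(start))
    end = int(end) if size is None else min(int(end), int(size))
    return CandidateRegion(chrom=chrom, start=start, end=end, significant_ids=list(members))


def variant_abf(b, se, prior_var: float = DEFAULT_PRIOR_VAR):
    """Wakefield approximate Bayes factor (alternative over null).

    ABF = sqrt(se^2 / (se^2 + W)) * exp(W b^2 / (2 se^2 (se^2 + W))) for
    prior effect variance W. Strictly increasing in |b| at fixed se and W.
    Accepts scalars or arrays.
    """
    b = np.asarray(b, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if prior_var <= 0:
        raise ValueError("prior variance must be positive")
    v = se * se
    log_abf = 0.5 * np.log(v / (v + prior_var)) + prior_var * b * b / (2.0 * v * (v + prior_var))
    out = np.exp(log_abf)
    return out.item() if out.ndim == 0 else out


def _normalized_ppc(b: np.ndarray, se: np.ndarray, prior_var: float) -> np.ndarray:
    """Single-causal posterior over a region, computed in log space."""
    v = se * se
    log_abf = 0.5 * np.log(v / (v + prior_var)) + prior_var * b * b / (2.0 * v * (v + prior_var))
    log_abf -= log_abf.max()
    w = np.exp(log_abf)
    return w / w.sum()


def signal_ppc(
    region: CandidateRegion,
    associations: pd.DataFrame,
    prior_var: float = DEFAULT_PRIOR_VAR,
    signal_index: int = 0,
) -> SignalPPC:
    """Single-causal-variant PPCs over a region from marginal statistics."""
    sub = associations[
        region.contains(associations[C.CHROM].to_numpy(str), associations[C.POS].to_numpy())
    ]
    sub = sub.dropna(subset=[C.BETA, C.SE])
    if len(sub) == 0:
        raise ValueError("region contains no variant with association results")
    ppc = _normalized_ppc(sub[C.BETA].to_numpy(float), sub[C.SE].to_numpy(float), prior_var)
    return SignalPPC(
        signal_index=signal_index,
        variant_id=sub[C.ID].to_numpy(),
        chrom=sub[C.CHROM].to_numpy(str),
        pos=sub[C.POS].to_numpy(),
        ppc=ppc,
        lead_id=str(sub[C.ID].to_numpy()[int(np.argmax(ppc))]),
    )


def forward_select_signals(
    region: CandidateRegion,
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    null_model: NullModel,
    p_stop: float = DEFAULT_P_STOP,
    prior_var: float = DEFAULT_PRIOR_VAR,
    max_signals: int = 10,
) -> list[SignalPPC]:
    """Iteratively condition on lead variants to isolate independent signals.

    Round k tests every region variant conditionally on the k - 1 leads
    selected so far (as fixed covariates, under the null-model covariance);
    if the minimum conditional P is below ``p_stop``, a signal is emitted
    whose PPCs are computed from the conditional statistics, and its lead
    joins the covariates. Collinear leads are skipped with a warning.
    """
    in_region = region.contains(
        genotypes.variants[C.CHROM].to_numpy(str), genotypes.variants[C.POS].to_numpy()
    )
    sub = genotypes.subset_variants(in_region)
    if sub.n_variants == 0:
        raise ValueError("region contains no genotyped variant")
    if not np.array_equal(phenotypes.individual_id, null_model.individual_id):
        raise ValueError("phenotypes and null model refer to different individuals")

    # Pre-whiten once: in the rotated, weight-scaled basis GLS becomes OLS.
    sw = np.sqrt(null_model.marker_weights)
    Xs = null_model.rotate(sub.dosages.astype(float)) * sw[:, None]
    ys = null_model.y_rot * sw
    cov = [null_model.x0_rot * sw]  # intercept column

    ids = sub.variants[C.ID].to_numpy()
    chrom = sub.variants[C.CHROM].to_numpy(str)
    pos = sub.variants[C.POS].to_numpy()
    active = np.ones(sub.n_variants, dtype=bool)
    signals: list[SignalPPC] = []

    for round_idx in range(max_signals):
        Q, _ = np.linalg.qr(np.column_stack(cov))
        y_res = ys - Q @ (Q.T @ ys)
        X_res = Xs - Q @ (Q.T @ Xs)
        ssq = np.einsum("ij,ij->j", X_res, X_res)
        ok = active & (ssq > 1e-10 * max(1.0, float(ssq.max(initial=0.0))))
        if not ok.any():
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            b = (X_res.T @ y_res) / ssq
            se = 1.0 / np.sqrt(ssq)
        z = np.where(ok, b / se, 0.0)
        p = 2.0 * stats.norm.sf(np.abs(z))
        lead = int(np.argmin(np.where(ok, p, np.inf)))
        if p[lead] >= p_stop:
            break
        ppc = _normalized_ppc(b[ok], se[ok], prior_var)
        signals.append(
            SignalPPC(
                signal_index=round_idx,
                variant_id=ids[ok],
                chrom=chrom[ok],
                pos=pos[ok],
                ppc=ppc,
                lead_id=str(ids[lead]),
            )
        )
        lead_col = X_res[:, lead]
        if np.dot(lead_col, lead_col) <= 1e-10:
            warnings.warn(f"lead variant {ids[lead]} collinear with covariates; stopping", stacklevel=2)
            break
        cov.append(Xs[:, lead])
        active[lead] = False
    return signals


def gene_ppc(
    signals: list[SignalPPC],
    genes: pd.DataFrame,
    flank: int = 2000,
    candidate_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Aggregate variant PPCs to genes (gene +- ``flank`` bp), per signal.

    Gene intervals are BED-style; a 1-based variant position p belongs to a
    gene iff start - flank < p <= end + flank. Returns one row per
    (gene, signal) with the summed PPC, plus the per-gene total; the
    candidate flag marks genes whose best per-signal sum exceeds
    ``candidate_cutoff``.
    """
    rows = []
    for _, g in genes.iterrows():
        for sig in signals:
            sel = (
                (sig.chrom == str(g["chrom"]))
                & (sig.pos > g["start"] - flank)
                & (sig.pos <= g["end"] + flank)
            )
            s = float(sig.ppc[sel].sum())
            if s > 0:
                rows.append((g["gene_id"], sig.signal_index, s))
    per_signal = pd.DataFrame(rows, columns=["gene_id", "signal_index", "ppc_sum"])
    if len(per_signal) == 0:
        return pd.DataFrame(
            columns=["gene_id", "signal_index", "ppc_sum", "ppc_total", "candidate"]
        )
    totals = per_signal.groupby("gene_id")["ppc_sum"].sum().rename("ppc_total")
    best = per_signal.groupby("gene_id")["ppc_sum"].max()
    out = per_signal.join(totals, on="gene_id")
    out["candidate"] = out["gene_id"].map(best > candidate_cutoff)
    return out.reset_index(drop=True)
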