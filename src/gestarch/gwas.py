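"""Variant QC and single-marker association under a reliability-weighted LMM.

The model is  y = mu + X b + g + e  with g ~ N(0, sigma_g^2 G) for a genomic
relationship matrix G (VanRaden method 1) and e ~ N(0, sigma_e^2 R), where R
is diagonal with R_ii = 1/r_i^2 - 1 and r_i^2 is the reliability of the
de-regressed proof of individual i. The null model (no marker) is fitted by
REML: the data are whitened with R^(-1/2), the whitened relationship matrix
is eigendecomposed once, and the likelihood is profiled over the variance
ratio lambda = sigma_g^2 / sigma_e^2 on a log grid refined by golden-section
search. Per-marker tests are generalized least squares with the covariance
held at the null estimates and a two-sided Wald P from the normal
approximation — the estimates (b, SE, P) form the summary-statistic exchange
table all downstream stages consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gestarch.data import GRM, AssociationColumns as C, GenotypeMatrix, PhenotypeTable

_RELIABILITY_CEIL = 1.0 - 1e-6


def reliability_to_weight(reliability):
    """Residual weight R_ii = 1/r^2 - 1 for reliability r^2 in (0, 1].

    Reliabilities of exactly 1 are floored at 1 - 1e-6 to keep R invertible.
    Accepts scalars or arrays.
    """
    r2 = np.asarray(reliability, dtype=float)
    if np.any(r2 <= 0) or np.any(r2 > 1):
        raise ValueError("reliability must lie in (0, 1]")
    r2 = np.minimum(r2, _RELIABILITY_CEIL)
    out = 1.0 / r2 - 1.0
    return out.item() if np.isscalar(reliability) or out.ndim == 0 else out


def hwe_test(counts_AA: int, counts_Aa: int, counts_aa: int) -> float:
    """Chi-square (1 df) Hardy-Weinberg goodness-of-fit P-value.

    Expected genotype proportions are computed at the sample allele
    frequency; monomorphic variants are defined to have P = 1.
    """
    n = counts_AA + counts_Aa + counts_aa
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    p = (2 * counts_AA + counts_Aa) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    expected = np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)]) * n
    observed = np.array([counts_AA, counts_Aa, counts_aa], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def variant_qc(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Filter variants by MAF > ``maf_min`` and HWE P > ``hwe_p_min``.

    Returns the filtered matrix and a per-variant QC log with the computed
    MAF, HWE P and the retention decision. Idempotent by construction.
    """
    D = genotypes.dosages
    maf = genotypes.maf()
    n_aa = (D == 2).sum(axis=0)
    n_het = (D == 1).sum(axis=0)
    n_ref = (D == 0).sum(axis=0)
    hwe_p = np.array([hwe_test(a, h, r) for a, h, r in zip(n_aa, n_het, n_ref)])
    keep = (maf > maf_min) & (hwe_p > hwe_p_min)
    log = pd.DataFrame(
        {
            "id": genotypes.variants[C.ID],
            "maf": maf,
            "hwe_p": hwe_p,
            "kept": keep,
        }
    )
    if not keep.any():
        warnings.warn("variant QC removed every variant", stacklevel=2)
    return genotypes.subset_variants(keep), log


def compute_grm(genotypes: GenotypeMatrix, maf_min: float = 0.01) -> GRM:
    """VanRaden method-1 genomic relationship matrix.

    Dosages are centered by twice the observed allele frequency and
    G = Z Z^T / (2 * sum p(1-p)) over variants with MAF > ``maf_min``.
    """
    p = genotypes.allele_freq()
    maf = np.minimum(p, 1 - p)
    keep = maf > maf_min
    if not keep.any():
        raise ValueError("no polymorphic variant passes the GRM MAF filter")
    p = p[keep]
    Z = genotypes.dosages[:, keep].astype(float) - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom == 0:
        raise ValueError("GRM undefined: all retained variants monomorphic")
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)  # enforce exact symmetry
    return GRM(matrix=G, ids=genotypes.individuals)


@dataclass
class NullModel:
    """Fitted null mixed model y = mu + g + e with its whitening cache.

    Stores the eigen-decomposition of A = R^(-1/2) G R^(-1/2) so that any
    later marker test only needs one matrix-vector product. ``eigvecs`` is
    None when A is diagonal (e.g. identity G with homogeneous weights), in
    which case the rotation is the identity.
    """

    mu: float
    sigma2_g: float
    sigma2_e: float
    individual_id: np.ndarray
    inv_sqrt_R: np.ndarray  # diagonal of R^(-1/2)
    eigvals: np.ndarray  # d of A = U diag(d) U^T
    eigvecs: np.ndarray | None  # U, or None for identity rotation
    y_rot: np.ndarray  # U^T R^(-1/2) y
    x0_rot: np.ndarray  # U^T R^(-1/2) 1
    reml_loglik: float = np.nan
    boundary: bool = False

    @property
    def h2_ratio(self) -> float:
        """sigma_g^2 / (sigma_g^2 + sigma_e^2)."""
        tot = self.sigma2_g + self.sigma2_e
        return 0.0 if tot == 0 else self.sigma2_g / tot

    @property
    def marker_weights(self) -> np.ndarray:
        """1 / (sigma_g^2 d_i + sigma_e^2): GLS weights in the rotated basis."""
        return 1.0 / (self.sigma2_g * self.eigvals + self.sigma2_e)

    def rotate(self, x: np.ndarray) -> np.ndarray:
        """Apply U^T R^(-1/2) to a vector or (n, k) matrix of covariates."""
        x = np.asarray(x, dtype=float)
        wx = self.inv_sqrt_R * x if x.ndim == 1 else self.inv_sqrt_R[:, None] * x
        return wx if self.eigvecs is None else self.eigvecs.T @ wx


def _reml_neg2ll(lam: float, d: np.ndarray, y: np.ndarray, x0: np.ndarray) -> float:
    """Profiled REML -2 log-likelihood at variance ratio ``lam`` (const dropped)."""
    v = lam * d + 1.0
    xvx = np.sum(x0 * x0 / v)
    xvy = np.sum(x0 * y / v)
    mu = xvy / xvx
    resid = y - mu * x0
    ssr = np.sum(resid * resid / v)
    n = len(y)
    s2 = ssr / (n - 1)
    return (n - 1) * np.log(s2) + np.sum(np.log(v)) + np.log(xvx)


def fit_null_model(
    phenotypes: PhenotypeTable,
    grm: GRM,
    n_grid: int = 81,
    log_lambda_range: tuple[float, float] = (-6.0, 6.0),
) -> NullModel:
    """REML fit of (mu, sigma_g^2, sigma_e^2) under y = mu + g + e.

    The residual covariance is sigma_e^2 R with R_ii = 1/r_i^2 - 1. The
    whitened relationship matrix A = R^(-1/2) G R^(-1/2) is eigendecomposed
    once; the likelihood is profiled over lambda = sigma_g^2/sigma_e^2 on a
    log grid (plus the lambda = 0 boundary) and refined by golden-section
    search around the grid optimum. Deterministic: repeated fits on the same
    inputs give identical estimates.
    """
    G = grm.align(phenotypes.individual_id)
    w = 1.0 / np.sqrt(reliability_to_weight(phenotypes.reliability))
    A = w[:, None] * G * w[None, :]
    n = len(phenotypes)

    off = A - np.diag(np.diag(A))
    if np.max(np.abs(off)) < 1e-12:
        d = np.diag(A).copy()
        U = None
        y_rot = w * phenotypes.y
        x0_rot = w * np.ones(n)
    else:
        d, U = np.linalg.eigh(A)
        if d[0] < -1e-8 * max(1.0, d[-1]):
            raise np.linalg.LinAlgError("whitened GRM is not PSD")
        d = np.clip(d, 0.0, None)
        y_rot = U.T @ (w * phenotypes.y)
        x0_rot = U.T @ (w * np.ones(n))

    grid = np.concatenate([[0.0], 10.0 ** np.linspace(*log_lambda_range, n_grid)])
    vals = np.array([_reml_neg2ll(l, d, y_rot, x0_rot) for l in grid])
    k = int(np.argmin(vals))
    boundary = k in (0, len(grid) - 1)
    if boundary:
        lam = grid[k]
        if k == len(grid) - 1:
            warnings.warn("REML estimate at upper lambda boundary", stacklevel=2)
    else:
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda t: _reml_neg2ll(10.0 ** t, d, y_rot, x0_rot),
            bracket=None,
            bounds=(np.log10(grid[k - 1] if grid[k - 1] > 0 else grid[k] / 10), np.log10(grid[k + 1])),
            method="bounded",
            options={"xatol": 1e-8},
        )
        lam = 10.0 ** res.x

    v = lam * d + 1.0
    xvx = np.sum(x0_rot * x0_rot / v)
    mu_rot = np.sum(x0_rot * y_rot / v) / xvx
    resid = y_rot - mu_rot * x0_rot
    s2e = float(np.sum(resid * resid / v) / (n - 1))
    s2g = float(lam * s2e)

    # mu on the original scale: the whitened intercept column is w, so the
    # rotated-coefficient equals the original intercept.
    return NullModel(
        mu=float(mu_rot),
        sigma2_g=s2g,
        sigma2_e=s2e,
        individual_id=phenotypes.individual_id,
        inv_sqrt_R=w,
        eigvals=d,
        eigvecs=U,
        y_rot=y_rot,
        x0_rot=x0_rot,
        reml_loglik=-0.5 * _reml_neg2ll(lam, d, y_rot, x0_rot),
        boundary=boundary,
    )


def _gls_marker(null_model: NullModel, x_rot: np.ndarray) -> tuple[float, float, float]:
    """(b, SE, P) for one rotated marker column by weighted 2x2 GLS."""
    wts = null_model.marker_weights
    x0 = null_model.x0_rot
    y = null_model.y_rot
    a11 = np.sum(wts * x0 * x0)
    a12 = np.sum(wts * x0 * x_rot)
    a22 = np.sum(wts * x_rot * x_rot)
    b1 = np.sum(wts * x0 * y)
    b2 = np.sum(wts * x_rot * y)
    det = a11 * a22 - a12 * a12
    if det <= 0 or a22 - a12 * a12 / a11 <= 1e-12 * max(a22, 1.0):
        raise ZeroDivisionError("marker has (near-)zero variance; effect undefined")
    beta = (a11 * b2 - a12 * b1) / det
    se = float(np.sqrt(a11 / det))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(beta), se, max(p, np.finfo(float).tiny)


def single_marker_test(
    phenotypes: PhenotypeTable,
    dosage: np.ndarray,
    null_model: NullModel,
) -> tuple[float, float, float]:
    """Effect, SE and two-sided Wald P for one marker.

    Generalized least squares with covariance sigma_g^2 G + sigma_e^2 R held
    at the null REML estimates. With G = I, equal reliabilities and
    sigma_g^2 = 0 this reduces exactly to ordinary simple regression.
    """
    if not np.array_equal(phenotypes.individual_id, null_model.individual_id):
        raise ValueError("phenotypes and null model refer to different individuals")
    x = np.asarray(dosage, dtype=float)
    if np.var(x) == 0:
        raise ZeroDivisionError("marker has zero variance; effect undefined")
    return _gls_marker(null_model, null_model.rotate(x))


def association_scan(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    null_model: NullModel,
) -> pd.DataFrame:
    """Vectorised single-marker scan over every variant in the matrix.

    Returns the association exchange table (id, chrom, pos, ref, alt, maf,
    b, se, p). Zero-variance markers get NaN estimates and are warned about.
    """
    X = genotypes.dosages.astype(float)
    Xr = null_model.rotate(X)  # (n, m)
    wts = null_model.marker_weights
    x0 = null_model.x0_rot
    y = null_model.y_rot

    a11 = np.sum(wts * x0 * x0)
    b1 = np.sum(wts * x0 * y)
    a12 = (wts * x0) @ Xr
    a22 = wts @ (Xr * Xr)
    b2 = (wts * y) @ Xr
    det = a11 * a22 - a12 * a12
    cond_var = a22 - a12 * a12 / a11
    bad = (det <= 0) | (cond_var <= 1e-12 * np.maximum(a22, 1.0))
    if bad.any():
        warnings.warn(f"{int(bad.sum())} zero-variance markers skipped", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(bad, np.nan, (a11 * b2 - a12 * b1) / det)
        se = np.where(bad, np.nan, np.sqrt(a11 / det))
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    out = genotypes.variants[[C.ID, C.CHROM, C.POS, C.REF, C.ALT]].copy()
    out[C.MAF] = genotypes.maf()
    out[C.BETA] = beta
    out[C.SE] = se
    out[C.P] = np.where(bad, np.nan, p)
    return out


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Genome-wide significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def maf_by_cohort(
    genotypes: GenotypeMatrix,
    variant_id: str,
    cohort_labels: np.ndarray,
) -> pd.DataFrame:
    """Minor-allele frequency of one variant within each cohort (e.g. birth year).

    The minor allele is defined on the full sample so the trajectory tracks
    one fixed allele across cohorts.
    """
    labels = np.asarray(cohort_labels)
    if len(labels) != genotypes.n_individuals:
        raise ValueError("one cohort label per individual required")
    dose = genotypes.dosage_of(variant_id)
    overall_alt = dose.mean() / 2.0
    track_alt = overall_alt <= 0.5  # minor allele on the full sample
    rows = []
    for cohort in pd.unique(labels):
        sel = labels == cohort
        if not sel.any():  # pragma: no cover - pd.unique precludes this
            warnings.warn(f"empty cohort {cohort!r} omitted", stacklevel=2)
            continue
        freq_alt = dose[sel].mean() / 2.0
        rows.append((cohort, freq_alt if track_alt else 1.0 - freq_alt, int(sel.sum())))
    return pd.DataFrame(rows, columns=["cohort", "maf", "n"]).sort_values("cohort").reset_index(drop=True)
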