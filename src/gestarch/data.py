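"""Core in-memory containers shared across pipeline stages.

Conventions used throughout the package:

* variant positions are 1-based (VCF convention);
* interval files (genes, tiles, DMRs) are BED-style 0-based half-open;
* dosages count copies of the alternate allele and live in {0, 1, 2};
* association tables are plain :class:`pandas.DataFrame` objects with the
  column set in :class:`AssociationColumns` — the exchange format every
  downstream stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class AssociationColumns:
    """Column names of the per-variant association exchange table."""

    ID = "id"
    CHROM = "chrom"
    POS = "pos"
    REF = "ref"
    ALT = "alt"
    MAF = "maf"
    BETA = "b"
    SE = "se"
    P = "p"

    ALL = [ID, CHROM, POS, REF, ALT, MAF, BETA, SE, P]


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with variant metadata.

    Attributes
    ----------
    dosages:
        ``(n_individuals, n_variants)`` array with entries in {0, 1, 2}.
    variants:
        DataFrame with columns ``id, chrom, pos, ref, alt`` (pos 1-based),
        sorted by (chrom, pos) with positions strictly increasing within
        chromosome.
    individuals:
        Array of unique individual identifiers, row-aligned with ``dosages``.
    chrom_sizes:
        Optional mapping chromosome -> length in bp.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    individuals: np.ndarray
    chrom_sizes: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.individuals = np.asarray(self.individuals)
        n, m = self.dosages.shape
        if len(self.individuals) != n:
            raise ValueError("individuals length does not match dosage rows")
        if len(self.variants) != m:
            raise ValueError("variant table length does not match dosage columns")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per variant."""
        return self.dosages.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per variant."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to variants where ``mask`` is True."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            individuals=self.individuals,
            chrom_sizes=self.chrom_sizes,
        )

    def dosage_of(self, variant_id: str) -> np.ndarray:
        """Dosage vector for one variant id."""
        hits = np.flatnonzero(self.variants[AssociationColumns.ID].to_numpy() == variant_id)
        if len(hits) == 0:
            raise KeyError(f"unknown variant id: {variant_id}")
        return self.dosages[:, hits[0]].astype(float)


@dataclass
class PhenotypeTable:
    """De-regressed proofs with per-individual reliabilities.

    ``y`` holds the de-regressed predicted transmitting ability (PTA) of
    each individual and ``reliability`` its squared accuracy r^2 in (0, 1],
    which determines the residual weight 1/r^2 - 1 in the mixed model.
    """

    individual_id: np.ndarray
    y: np.ndarray
    reliability: np.ndarray

    def __post_init__(self) -> None:
        self.individual_id = np.asarray(self.individual_id)
        self.y = np.asarray(self.y, dtype=float)
        self.reliability = np.asarray(self.reliability, dtype=float)
        if not (len(self.individual_id) == len(self.y) == len(self.reliability)):
            raise ValueError("phenotype columns must have equal length")
        if len(np.unique(self.individual_id)) != len(self.individual_id):
            raise ValueError("individual ids must be unique")
        if np.any(self.reliability <= 0) or np.any(self.reliability > 1):
            raise ValueError("reliability must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.y)

    def to_frame(self, trait: str = "trait") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.individual_id,
                "trait": trait,
                "dePTA": self.y,
                "reliability": self.reliability,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PhenotypeTable":
        return cls(
            individual_id=frame["id"].to_numpy(),
            y=frame["dePTA"].to_numpy(float),
            reliability=frame["reliability"].to_numpy(float),
        )


@dataclass
class GRM:
    """Genomic relationship matrix (VanRaden method 1) with row ids."""

    matrix: np.ndarray
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("GRM must be square")
        if self.ids is None:
            self.ids = np.arange(self.matrix.shape[0])
        self.ids = np.asarray(self.ids)
        if len(self.ids) != self.matrix.shape[0]:
            raise ValueError("id length does not match GRM dimension")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def align(self, ids: np.ndarray) -> np.ndarray:
        """Return the sub-matrix ordered to ``ids`` (must all be present)."""
        lookup = {v: i for i, v in enumerate(self.ids)}
        try:
            idx = np.array([lookup[v] for v in ids])
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"id missing from GRM: {exc}") from exc
        return self.matrix[np.ix_(idx, idx)]


def chromosome_sort_key(label: str):
    """Sort chromosomes ascending by numeric label, then lexicographically.

    Defines the fixed concatenation order used when genome-ordering
    statistic vectors for the cyclical permutation test.
    """
    s = str(label)
    try:
        return (0, float(s), "")
    except ValueError:
        return (1, 0.0, s)


def sort_by_genome(frame: pd.DataFrame, chrom: str = "chrom", pos: str = "pos") -> pd.DataFrame:
    """Sort a table by (chromosome, position) under :func:`chromosome_sort_key`."""
    order = sorted(frame[chrom].unique(), key=chromosome_sort_key)
    rank = {c: i for i, c in enumerate(order)}
    key = frame[chrom].map(rank)
    return (
        frame.assign(_ckey=key)
        .sort_values(["_ckey", pos], kind="mergesort")
        .drop(columns="_ckey")
        .reset_index(drop=True)
    )
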