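"""Synthetic-data generation with known ground truth.

Every downstream stage of the pipeline is exercised on data produced here:
LD-structured biallelic genotypes, polygenic traits observed as noisy
de-regressed proofs whose residual variance scales with 1/r^2 - 1, pairs of
traits with a specified effect-level correlation, gene annotations with
gene-set collections, and per-sample CpG count tables over a toy genome with
spike-in group-differential regions.

All operations are pure functions of (inputs, seed): a single master seed
deterministically derives per-operation sub-seeds, so one configuration line
reproduces a full run bit-identically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gestarch.data import GenotypeMatrix, PhenotypeTable


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


def derive_rng(seed: int, tag: str) -> np.random.Generator:
    """Deterministically derive a per-operation generator from a master seed.

    The tag is hashed with CRC32 so unrelated operations never share a
    stream even when called with the same master seed.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(tag.encode())]))


@dataclass(frozen=True)
class SimConfig:
    """Dimensions and knobs of one simulated study.

    Parameters
    ----------
    n_individuals, n_variants, n_chromosomes, n_genes:
        Counts, all >= 1; variants and genes are split as evenly as possible
        across chromosomes.
    ld_copy_prob:
        Probability in [0, 1) that a haplotype allele copies its left
        neighbour instead of being drawn fresh at the variant's frequency;
        a first-order copying process that produces LD blocks.
    maf_range:
        Interval within (0, 0.5] from which target minor-allele frequencies
        are drawn uniformly.
    genome_length_per_chrom:
        Chromosome length in bp of the toy genome.
    seed:
        Master seed; identical configs give bit-identical outputs.
    """

    n_individuals: int = 500
    n_variants: int = 5000
    n_chromosomes: int = 1
    ld_copy_prob: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_genes: int = 100
    genome_length_per_chrom: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_variants", "n_chromosomes", "n_genes"):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be >= 1")
        if not (0.0 <= self.ld_copy_prob < 1.0):
            raise InvalidConfigError("ld_copy_prob must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidConfigError("maf_range must lie within (0, 0.5]")
        if self.genome_length_per_chrom < self.n_variants // self.n_chromosomes + 1:
            raise InvalidConfigError("genome too short for requested variants")

    @property
    def chromosomes(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.genome_length_per_chrom for c in self.chromosomes}


@dataclass
class TraitTruth:
    """Ground truth for one simulated trait."""

    causal_variant_ids: np.ndarray
    true_effects: np.ndarray  # per causal variant, on the scaled (output) scale
    h2: float
    genetic_values: np.ndarray = field(default=None)  # type: ignore[assignment]
    enriched_feature_id: str | None = None


@dataclass
class MethylTruth:
    """Ground truth for the spike-in differential-methylation simulation.

    ``dmr_intervals`` is a BED-style table (chrom, start, end, effect,
    clamped) of the regions where the high group's methylation proportion
    was shifted; ``baseline`` maps tiles to their baseline proportion.
    """

    dmr_intervals: pd.DataFrame
    effect_size: float
    baseline: pd.DataFrame


def _split_counts(total: int, k: int) -> list[int]:
    base, rem = divmod(total, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Simulate LD-structured biallelic dosages in {0, 1, 2}.

    Haplotypes are built by a first-order copying process: along each
    chromosome, a haplotype's allele at a variant copies the allele at the
    previous variant with probability ``ld_copy_prob`` and is otherwise
    drawn Bernoulli at the variant's target frequency. Copying restarts at
    chromosome boundaries, so LD never crosses chromosomes.
    """
    rng = derive_rng(config.seed, "genotypes")
    n = config.n_individuals
    n_hap = 2 * n
    per_chrom = _split_counts(config.n_variants, config.n_chromosomes)

    dosage_blocks = []
    var_rows = []
    for chrom, m_c in zip(config.chromosomes, per_chrom):
        if m_c == 0:
            continue
        positions = np.sort(
            rng.choice(np.arange(1, config.genome_length_per_chrom + 1), size=m_c, replace=False)
        )
        freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m_c)
        H = np.empty((n_hap, m_c), dtype=np.int8)
        H[:, 0] = rng.random(n_hap) < freqs[0]
        for j in range(1, m_c):
            fresh = rng.random(n_hap) < freqs[j]
            copy = rng.random(n_hap) < config.ld_copy_prob
            H[:, j] = np.where(copy, H[:, j - 1], fresh)
        dosage_blocks.append(H[0::2] + H[1::2])
        for p in positions:
            var_rows.append((f"chr{chrom}:{p}", chrom, int(p), "A", "G"))

    variants = pd.DataFrame(var_rows, columns=["id", "chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(
        dosages=np.concatenate(dosage_blocks, axis=1),
        variants=variants,
        individuals=np.array([f"ind{i:05d}" for i in range(n)]),
        chrom_sizes=config.chrom_sizes,
    )


def _variants_in_genes(genotypes: GenotypeMatrix, genes: pd.DataFrame, gene_ids) -> np.ndarray:
    """Boolean mask over variants falling inside any of the named genes.

    Gene intervals are BED-style; a 1-based variant position p lies inside
    [start, end) iff start < p <= end.
    """
    member = genes[genes["gene_id"].isin(list(gene_ids))]
    mask = np.zeros(genotypes.n_variants, dtype=bool)
    pos = genotypes.variants["pos"].to_numpy()
    chrom = genotypes.variants["chrom"].to_numpy()
    for c, sub in member.groupby("chrom"):
        on_c = chrom == c
        for start, end in sub[["start", "end"]].to_numpy():
            mask |= on_c & (pos > start) & (pos <= end)
    return mask


def simulate_trait(
    genotypes: GenotypeMatrix,
    h2: float,
    n_causal: int,
    seed: int,
    enriched_feature: tuple[str, list[str]] | None = None,
    genes: pd.DataFrame | None = None,
    enrich_frac: float = 0.0,
    reliability_range: tuple[float, float] = (0.8, 0.99),
) -> tuple[PhenotypeTable, TraitTruth]:
    """Simulate a polygenic trait observed as a noisy de-regressed proof.

    The true genetic value is the dosage-weighted sum of causal effects,
    scaled so that its variance equals ``h2``. The observed proof is the
    genetic value plus Gaussian noise with per-individual variance
    ``(1 - h2) * (1/r_i^2 - 1)``, where r_i^2 is the reliability drawn
    uniformly on ``reliability_range`` — mirroring the diagonal residual
    structure of the mixed model, which makes the GWAS weighting exactly
    correct on these data. The ratio sigma_g^2 / (sigma_g^2 + sigma_e^2)
    recovered by REML therefore targets ``h2``.

    When ``enriched_feature`` = (feature_id, member gene ids) is given with
    ``genes``, a fraction ``enrich_frac`` of causal variants is placed
    inside that feature's genes.
    """
    if not (0.0 <= h2 <= 1.0):
        raise InvalidConfigError("h2 must lie in [0, 1]")
    if n_causal > genotypes.n_variants:
        raise InvalidConfigError("n_causal exceeds number of variants")
    rng = derive_rng(seed, "trait")
    n, m = genotypes.dosages.shape
    var_ids = genotypes.variants["id"].to_numpy()

    feature_id = None
    if enriched_feature is not None and enrich_frac > 0:
        if genes is None:
            raise InvalidConfigError("genes table required with enriched_feature")
        feature_id, member_genes = enriched_feature
        inside = np.flatnonzero(_variants_in_genes(genotypes, genes, member_genes))
        outside = np.setdiff1d(np.arange(m), inside)
        k_in = min(int(round(enrich_frac * n_causal)), len(inside))
        k_out = n_causal - k_in
        causal_idx = np.concatenate(
            [
                rng.choice(inside, size=k_in, replace=False),
                rng.choice(outside, size=k_out, replace=False),
            ]
        )
    else:
        causal_idx = rng.choice(m, size=n_causal, replace=False)
    causal_idx = np.sort(causal_idx)

    effects = rng.standard_normal(n_causal)
    if h2 == 0.0:
        effects = np.zeros(n_causal)
        g = np.zeros(n)
    else:
        g = genotypes.dosages[:, causal_idx].astype(float) @ effects
        g -= g.mean()
        sd = g.std()
        if sd == 0:
            raise InvalidConfigError("degenerate genotypes: genetic value has zero variance")
        scale = np.sqrt(h2) / sd
        effects *= scale
        g *= scale

    r2 = rng.uniform(reliability_range[0], reliability_range[1], size=n)
    noise_sd = np.sqrt((1.0 - h2) * (1.0 / r2 - 1.0))
    y = g + rng.standard_normal(n) * noise_sd

    pheno = PhenotypeTable(individual_id=genotypes.individuals, y=y, reliability=r2)
    truth = TraitTruth(
        causal_variant_ids=var_ids[causal_idx],
        true_effects=effects,
        h2=h2,
        genetic_values=g,
        enriched_feature_id=feature_id,
    )
    return pheno, truth


def simulate_correlated_effects(
    genotypes: GenotypeMatrix,
    rg: float,
    h2_a: float,
    h2_b: float,
    seed: int,
    n_causal: int | None = None,
    reliability_range: tuple[float, float] = (0.8, 0.99),
) -> tuple[TraitTruth, TraitTruth, PhenotypeTable, PhenotypeTable]:
    """Simulate two traits whose causal effects correlate at ``rg``.

    The traits share one causal-variant set; their raw effects are drawn
    from a bivariate standard normal with correlation ``rg`` and then scaled
    per trait to hit the requested heritabilities, so the effect-level
    correlation is preserved under scaling.
    """
    if abs(rg) > 1.0:
        raise InvalidConfigError("|rg| must be <= 1")
    rng = derive_rng(seed, "correlated-effects")
    n, m = genotypes.dosages.shape
    if n_causal is None:
        n_causal = m
    causal_idx = np.sort(rng.choice(m, size=n_causal, replace=False))
    var_ids = genotypes.variants["id"].to_numpy()

    z1 = rng.standard_normal(n_causal)
    z2 = rng.standard_normal(n_causal)
    eff_a = z1
    eff_b = rg * z1 + np.sqrt(max(0.0, 1.0 - rg * rg)) * z2

    out = []
    X = genotypes.dosages[:, causal_idx].astype(float)
    for tag, h2, eff in (("a", h2_a, eff_a), ("b", h2_b, eff_b)):
        if not (0.0 <= h2 <= 1.0):
            raise InvalidConfigError("h2 must lie in [0, 1]")
        sub = derive_rng(seed, f"correlated-trait-{tag}")
        if h2 == 0:
            eff = np.zeros(n_causal)
            g = np.zeros(n)
        else:
            g = X @ eff
            g -= g.mean()
            scale = np.sqrt(h2) / g.std()
            eff = eff * scale
            g = g * scale
        r2 = sub.uniform(reliability_range[0], reliability_range[1], size=n)
        y = g + sub.standard_normal(n) * np.sqrt((1.0 - h2) * (1.0 / r2 - 1.0))
        out.append(
            (
                TraitTruth(var_ids[causal_idx], eff, h2, genetic_values=g),
                PhenotypeTable(genotypes.individuals, y, r2),
            )
        )
    (truth_a, ph_a), (truth_b, ph_b) = out
    return truth_a, truth_b, ph_a, ph_b


def simulate_gene_annotation(
    config: SimConfig,
    n_sets: int = 5,
    set_size: int = 15,
    gene_length: int = 5000,
) -> tuple[pd.DataFrame, dict[str, list[str]], str]:
    """Simulate non-overlapping gene intervals and gene-set collections.

    Returns a BED-style gene table (gene_id, chrom, start, end, strand),
    a GMT-style mapping set id -> member gene ids (every set has at least
    10 members, matching the feature-size filter applied to annotation
    sources), and the id of a designated "enrichable" set whose genes are
    used to place causal variants in power tests.
    """
    if config.n_genes < 10:
        raise InvalidConfigError("n_genes must be >= 10 to form gene sets")
    if set_size < 10:
        raise InvalidConfigError("gene sets must contain at least 10 genes")
    rng = derive_rng(config.seed, "annotation")
    per_chrom = _split_counts(config.n_genes, config.n_chromosomes)
    rows = []
    gid = 0
    for chrom, k in zip(config.chromosomes, per_chrom):
        if k == 0:
            continue
        slot = config.genome_length_per_chrom // k
        if slot <= gene_length:
            raise InvalidConfigError("genome too short for requested genes")
        for i in range(k):
            start = i * slot + int(rng.integers(0, slot - gene_length))
            rows.append(
                (f"gene{gid:04d}", chrom, start, start + gene_length, "+" if rng.random() < 0.5 else "-")
            )
            gid += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])

    all_ids = genes["gene_id"].tolist()
    if set_size > len(all_ids):
        raise InvalidConfigError("set_size exceeds number of genes")
    gene_sets: dict[str, list[str]] = {}
    enrichable = "SET_ENRICHABLE"
    gene_sets[enrichable] = sorted(rng.choice(all_ids, size=set_size, replace=False).tolist())
    for s in range(n_sets - 1):
        gene_sets[f"SET_{s:03d}"] = sorted(
            rng.choice(all_ids, size=set_size, replace=False).tolist()
        )
    return genes, gene_sets, enrichable


def simulate_methylomes(
    config: SimConfig,
    n_per_group: int,
    coverage_mean: float,
    n_dmr: int,
    effect_size: float,
    seed: int,
    cpg_spacing: int = 150,
    tile_width: int = 2000,
    baseline_range: tuple[float, float] = (0.1, 0.9),
    negative_binomial: bool = False,
    nb_dispersion: float = 5.0,
) -> tuple[dict[str, pd.DataFrame], MethylTruth]:
    """Simulate per-sample CpG count tables with spike-in DMRs.

    CpG sites are laid down with geometric spacing (mean ``cpg_spacing``)
    along the toy genome; per-site coverage is Poisson around
    ``coverage_mean`` (negative binomial with size ``nb_dispersion`` when
    requested); methylated counts are binomial around a per-tile baseline
    proportion. Inside each of ``n_dmr`` truth tiles the high group's
    proportion is shifted by ``effect_size``, clamped into [0, 1] with the
    clamping recorded in the truth table.

    Samples are named ``high_0 .. high_{k-1}`` and ``low_0 .. low_{k-1}``;
    output tables use the methylKit-style columns
    (chrom, pos, strand, coverage, numCs, numTs) with 1-based positions.
    """
    if n_per_group < 2:
        raise InvalidConfigError("n_per_group must be >= 2")
    if abs(effect_size) > 1:
        raise InvalidConfigError("|effect_size| must be <= 1")
    rng = derive_rng(seed, "methylomes")

    # CpG positions (0-based) per chromosome.
    cpg_chrom, cpg_pos0 = [], []
    for chrom in config.chromosomes:
        gaps = rng.geometric(1.0 / cpg_spacing, size=config.genome_length_per_chrom // cpg_spacing + 64)
        pos = np.cumsum(gaps)
        pos = pos[pos < config.genome_length_per_chrom]
        cpg_chrom.append(np.repeat(chrom, len(pos)))
        cpg_pos0.append(pos)
    chrom_arr = np.concatenate(cpg_chrom)
    pos0 = np.concatenate(cpg_pos0)

    # Per-tile baselines; truth DMRs are tile-aligned intervals.
    tiles_per_chrom = -(-config.genome_length_per_chrom // tile_width)
    n_tiles = tiles_per_chrom * config.n_chromosomes
    baseline = rng.uniform(baseline_range[0], baseline_range[1], size=n_tiles)
    if n_dmr > n_tiles:
        raise InvalidConfigError("n_dmr exceeds number of tiles")
    dmr_tile_idx = np.sort(rng.choice(n_tiles, size=n_dmr, replace=False))

    chrom_rank = {c: i for i, c in enumerate(config.chromosomes)}
    tile_of_cpg = np.array([chrom_rank[c] for c in chrom_arr]) * tiles_per_chrom + pos0 // tile_width

    p_low = baseline[tile_of_cpg]
    shift = np.zeros(n_tiles)
    shift[dmr_tile_idx] = effect_size
    p_high_tile = np.clip(baseline + shift, 0.0, 1.0)
    clamped_tiles = np.abs((baseline + shift) - p_high_tile) > 0
    p_high = p_high_tile[tile_of_cpg]

    truth_rows = []
    for t in dmr_tile_idx:
        c = config.chromosomes[t // tiles_per_chrom]
        start = (t % tiles_per_chrom) * tile_width
        end = min(start + tile_width, config.genome_length_per_chrom)
        truth_rows.append((c, start, end, p_high_tile[t] - baseline[t], bool(clamped_tiles[t])))
    truth = MethylTruth(
        dmr_intervals=pd.DataFrame(
            truth_rows, columns=["chrom", "start", "end", "effect", "clamped"]
        ),
        effect_size=effect_size,
        baseline=pd.DataFrame({"tile_index": np.arange(n_tiles), "baseline": baseline}),
    )

    samples: dict[str, pd.DataFrame] = {}
    n_cpg = len(pos0)
    for group, p_site in (("high", p_high), ("low", p_low)):
        for k in range(n_per_group):
            if negative_binomial:
                lam = rng.gamma(nb_dispersion, coverage_mean / nb_dispersion, size=n_cpg)
                cov = rng.poisson(lam)
            else:
                cov = rng.poisson(coverage_mean, size=n_cpg)
            meth = rng.binomial(cov, p_site)
            samples[f"{group}_{k}"] = pd.DataFrame(
                {
                    "chrom": chrom_arr,
                    "pos": pos0 + 1,
                    "strand": "+",
                    "coverage": cov,
                    "numCs": meth,
                    "numTs": cov - meth,
                }
            )
    return samples, truth
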