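"""End-to-end orchestration of the simulated study.

A single :class:`RunConfig` (one YAML file) fully specifies a run:
simulation dimensions, every stage parameter (defaults are the study's
printed values: 2000-bp tiles, >= 10 reads, |diff| > 5, q grid
{0.05, 0.01, 1e-5, 1e-8, 1e-10}, q0 = 0.01, pathway gene flank 10 kb,
fine-map gene flank 2 kb, PPC cutoff 0.05, 10,000 permutations, MAF 0.01,
HWE 1e-06, alpha 0.05) and a master seed. Stages execute in dependency
order — simulate, gwas (two traits), finemap, enrich, dmr, dmr-enrich,
integrate — and a manifest records the config hash, per-stage output
checksums and wall-clock times; re-running an identical config skips
stages whose outputs already carry matching checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gestarch import __version__, io
from gestarch.data import AssociationColumns as C
from gestarch.dmr import Q_CUTOFF_GRID, adjust_q, call_dmrs, diff_meth_all, filter_cpg_coverage, tile_counts
from gestarch.dmr_enrichment import count_set_test_all, element_density_enrichment
from gestarch.enrichment import enrich_all
from gestarch.finemap import define_candidate_regions, forward_select_signals, gene_ppc
from gestarch.gwas import association_scan, bonferroni_threshold, compute_grm, fit_null_model, variant_qc
from gestarch.integrate import effect_correlation, gwas_in_dmr_enrichment
from gestarch.simulate import SimConfig, simulate_correlated_effects, simulate_gene_annotation, simulate_genotypes, simulate_methylomes

STAGES = ("simulate", "gwas", "finemap", "enrich", "dmr", "dmr_enrich", "integrate")

_STAGE_DEPS = {
    "gwas": ("simulate",),
    "finemap": ("gwas",),
    "enrich": ("gwas",),
    "dmr": ("simulate",),
    "dmr_enrich": ("dmr",),
    "integrate": ("gwas", "dmr"),
}


@dataclass
class RunConfig:
    """Schema-validated run configuration; unknown keys are rejected."""

    # simulation
    n_individuals: int = 500
    n_variants: int = 5000
    n_chromosomes: int = 1
    ld_copy_prob: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_genes: int = 100
    genome_length_per_chrom: int = 1_000_000
    h2: float = 0.5
    rg: float = 0.6
    n_causal: int = 200
    n_methyl_per_group: int = 4
    coverage_mean: float = 30.0
    n_dmr_truth: int = 25
    dmr_effect_size: float = 0.3
    # stage parameters (study defaults)
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    alpha: float = 0.05
    region_flank: int = 1_000_000
    finemap_gene_flank: int = 2000
    ppc_cutoff: float = 0.05
    prior_var: float = 0.04
    p_stop: float = 1e-6
    n_perm: int = 10_000
    window: int = 2000
    step: int = 2000
    min_coverage: int = 10
    min_cpgs: int = 3
    min_abs_diff: float = 5.0
    q_grid: tuple[float, ...] = Q_CUTOFF_GRID
    q0: float = 0.01
    pathway_gene_flank: int = 10_000
    enrich_gene_flank: int = 0
    # control
    seed: int = 0
    stages: tuple[str, ...] = STAGES

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("maf_range", "q_grid", "stages"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_individuals=self.n_individuals,
            n_variants=self.n_variants,
            n_chromosomes=self.n_chromosomes,
            ld_copy_prob=self.ld_copy_prob,
            maf_range=self.maf_range,
            n_genes=self.n_genes,
            genome_length_per_chrom=self.genome_length_per_chrom,
            seed=self.seed,
        )


@dataclass
class RunManifest:
    config_hash: str
    version: str = __version__
    stages: dict = field(default_factory=dict)  # stage -> {files: {path: sha256}, seconds}
    warnings: list = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed or its dependency did not run."""


def run_pipeline(config: RunConfig, outdir) -> RunManifest:
    """Execute the enabled stages in dependency order under ``outdir``.

    Writes every exchange file (VCF + TSV genotypes, phenotype TSVs, genes
    BED6, GMT, per-sample CpG TSVs, association TSVs, enrichment and DMR
    tables) plus ``manifest.json``. When the directory already holds a
    manifest with the same config hash, stages whose recorded output
    checksums still match are skipped.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = tuple(s for s in STAGES if s in config.stages)
    for stage in enabled:
        for dep in _STAGE_DEPS.get(stage, ()):
            if dep not in enabled:
                raise StageError(f"stage {stage!r} requires disabled stage {dep!r}")

    manifest = RunManifest(config_hash=config.config_hash())
    previous = None
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        try:
            previous = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            previous = None
        if previous and previous.get("config_hash") != manifest.config_hash:
            previous = None

    state: dict = {}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for stage in enabled:
            t0 = time.perf_counter()
            runner = _RUNNERS[stage]
            fresh = _stage_is_fresh(previous, stage, outdir)
            try:
                runner(config, outdir, state, recompute_only=fresh)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage {stage!r} failed: {exc}") from exc
            files = {
                str(p.relative_to(outdir)): _checksum(p)
                for p in sorted(outdir.glob(f"{stage}.*")) + sorted(outdir.glob(f"{stage}/*"))
            }
            manifest.stages[stage] = {
                "files": files,
                "seconds": round(time.perf_counter() - t0, 3),
                "skipped_write": fresh,
            }
        manifest.warnings = [str(w.message) for w in caught]
    manifest.to_json(manifest_path)
    return manifest


def _stage_is_fresh(previous, stage: str, outdir: Path) -> bool:
    if not previous or stage not in previous.get("stages", {}):
        return False
    files = previous["stages"][stage].get("files", {})
    if not files:
        return False
    for rel, digest in files.items():
        p = outdir / rel
        if not p.exists() or _checksum(p) != digest:
            return False
    return True


def _run_simulate(cfg: RunConfig, outdir: Path, state: dict, recompute_only: bool = False) -> None:
    sim = cfg.sim_config()
    genotypes = simulate_genotypes(sim)
    genes, gene_sets, enrichable = simulate_gene_annotation(sim)
    truth_a, truth_b, pheno_a, pheno_b = simulate_correlated_effects(
        genotypes, rg=cfg.rg, h2_a=cfg.h2, h2_b=cfg.h2, seed=cfg.seed, n_causal=cfg.n_causal
    )
    methylomes, methyl_truth = simulate_methylomes(
        sim,
        n_per_group=cfg.n_methyl_per_group,
        coverage_mean=cfg.coverage_mean,
        n_dmr=cfg.n_dmr_truth,
        effect_size=cfg.dmr_effect_size,
        seed=cfg.seed,
    )
    state.update(
        genotypes=genotypes,
        genes=genes,
        gene_sets=gene_sets,
        enrichable=enrichable,
        phenotypes={"trait_a": pheno_a, "trait_b": pheno_b},
        truths={"trait_a": truth_a, "trait_b": truth_b},
        methylomes=methylomes,
        methyl_truth=methyl_truth,
    )
    if recompute_only:
        return
    sub = outdir / "simulate"
    sub.mkdir(exist_ok=True)
    io.write_vcf(genotypes, sub / "genotypes.vcf")
    io.write_genotype_tsv(genotypes, sub / "genotypes.tsv")
    io.write_phenotypes(pheno_a, sub / "pheno_trait_a.tsv", trait="trait_a")
    io.write_phenotypes(pheno_b, sub / "pheno_trait_b.tsv", trait="trait_b")
    io.write_bed(genes, sub / "genes.bed", name_col="gene_id")
    io.write_gmt(gene_sets, sub / "gene_sets.gmt")
    for name, table in methylomes.items():
        io.write_cpg_table(table, sub / f"cpg_{name}.tsv")
    methyl_truth.dmr_intervals.to_csv(sub / "truth_dmrs.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "trait": "trait_a",
            "variant": truth_a.causal_variant_ids,
            "effect": truth_a.true_effects,
        }
    ).to_csv(sub / "truth_effects_a.tsv", sep="\t", index=False)


def _run_gwas(cfg: RunConfig, outdir: Path, state: dict, recompute_only: bool = False) -> None:
    genotypes, qc_log = variant_qc(state["genotypes"], cfg.maf_min, cfg.hwe_p_min)
    grm = compute_grm(genotypes, cfg.maf_min)
    state["qc_genotypes"] = genotypes
    state["associations"] = {}
    state["null_models"] = {}
    sub = outdir / "gwas"
    if not recompute_only:
        sub.mkdir(exist_ok=True)
        qc_log.to_csv(sub / "qc_log.tsv", sep="\t", index=False)
    for trait, pheno in state["phenotypes"].items():
        null = fit_null_model(pheno, grm)
        assoc = association_scan(genotypes, pheno, null)
        state["null_models"][trait] = null
        state["associations"][trait] = assoc
        if not recompute_only:
            io.write_associations(assoc, sub / f"assoc_{trait}.tsv")
    state["threshold"] = bonferroni_threshold(len(qc_log[qc_log["kept"]]), cfg.alpha)


def _run_finemap(cfg: RunConfig, outdir: Path, state: dict, recompute_only: bool = False) -> None:
    assoc = state["associations"]["trait_a"]
    regions = define_candidate_regions(
        assoc, state["threshold"], state["genotypes"].chrom_sizes, cfg.region_flank
    )
    all_signals = []
    for region in regions:
        all_signals.extend(
            forward_select_signals(
                region,
                state["qc_genotypes"],
                state["phenotypes"]["trait_a"],
                state["null_models"]["trait_a"],
                p_stop=cfg.p_stop,
                prior_var=cfg.prior_var,
            )
        )
    for i, sig in enumerate(all_signals):
        sig.signal_index = i
    genes_tbl = gene_ppc(all_signals, state["genes"], cfg.finemap_gene_flank, cfg.ppc_cutoff)
    state["signals"] = all_signals
    state["gene_ppc"] = genes_tbl
    if recompute_only:
        return
    sub = outdir / "finemap"
    sub.mkdir(exist_ok=True)
    rows = [
        (s.signal_index, v, c, p, x, s.lead_id)
        for s in all_signals
        for v, c, p, x in zip(s.variant_id, s.chrom, s.pos, s.ppc)
    ]
    pd.DataFrame(rows, columns=["signal", "id", "chrom", "pos", "ppc", "lead"]).to_csv(
        sub / "variant_ppc.tsv", sep="\t", index=False
    )
    genes_tbl.to_csv(sub / "gene_ppc.tsv", sep="\t", index=False)


def _run_enrich(cfg: RunConfig, outdir: Path, state: dict, recompute_only: bool = False) -> None:
    table = enrich_all(
        state["associations"]["trait_a"],
        genes=state["genes"],
        gene_sets=state["gene_sets"],
        n_perm=cfg.n_perm,
        seed=cfg.seed,
        gene_flank=cfg.enrich_gene_flank,
    )
    state["enrichment"] = table
    if not recompute_only:
        sub = outdir / "enrich"
        sub.mkdir(exist_ok=True)
        table.to_csv(sub / "signal_enrichment.tsv", sep="\t", index=False)


def _run_dmr(cfg: RunConfig, outdir: Path, state: dict, recompute_only: bool = False) -> None:
    filtered = {
        name: filter_cpg_coverage(tbl, cfg.min_coverage)
        for name, tbl in state["methylomes"].items()
    }
    tiles = tile_counts(
        filtered,
        window=cfg.window,
        step=cfg.step,
        min_cpgs=cfg.min_cpgs,
        chrom_sizes=state["genotypes"].chrom_sizes,
    )
    labels = {s: ("high" if s.startswith("high") else "low") for s in tiles.samples}
    results = diff_meth_all(tiles, labels)
    results["q"] = adjust_q(results["p"].to_numpy())
    dmr_sets = {q: call_dmrs(results, q, cfg.min_abs_diff) for q in cfg.q_grid}
    state["tiles"] = tiles
    state["tile_results"] = results
    state["dmr_sets"] = dmr_sets
    if recompute_only:
        return
    sub = outdir / "dmr"
    sub.mkdir(exist_ok=True)
    results.to_csv(sub / "tile_results.tsv", sep="\t", index=False)
    io.write_bed(tiles.intervals, sub / "tiles.bed")
    for q, dmrs in dmr_sets.items():
        if len(dmrs.members):
            io.write_bed(dmrs.members, sub / f"dmrs_q{q:g}.bed")


def _run_dmr_enrich(cfg: RunConfig, outdir: Path, state: dict, recompute_only: bool = False) -> None:
    results = state["tile_results"]
    dmrs = state["dmr_sets"][cfg.q0]
    elements = {
        "genes": state["genes"][["chrom", "start", "end"]],
        "truth_dmrs": state["methyl_truth"].dmr_intervals[["chrom", "start", "end"]],
    }
    genome = sum((state["genotypes"].chrom_sizes or {}).values())
    density = element_density_enrichment(dmrs, elements, genome)
    pathways = count_set_test_all(
        results, state["genes"], state["gene_sets"], cfg.pathway_gene_flank, cfg.q0
    )
    state["dmr_density"] = density
    state["dmr_pathways"] = pathways
    if not recompute_only:
        sub = outdir / "dmr_enrich"
        sub.mkdir(exist_ok=True)
        density.to_csv(sub / "element_density.tsv", sep="\t", index=False)
        pathways.to_csv(sub / "pathway_counts.tsv", sep="\t", index=False)


def _run_integrate(cfg: RunConfig, outdir: Path, state: dict, recompute_only: bool = False) -> None:
    assoc_a = state["associations"]["trait_a"]
    assoc_b = state["associations"]["trait_b"]
    corr_all = effect_correlation(assoc_a, assoc_b, seed=cfg.seed)
    grid = gwas_in_dmr_enrichment(assoc_a, state["dmr_sets"], n_perm=cfg.n_perm, seed=cfg.seed)
    state["effect_correlation"] = corr_all
    state["dmr_grid"] = grid
    if recompute_only:
        return
    sub = outdir / "integrate"
    sub.mkdir(exist_ok=True)
    pd.DataFrame(
        [
            (
                corr_all.subset_label,
                corr_all.n_variants,
                corr_all.correlation,
                corr_all.ci_low,
                corr_all.ci_high,
            )
        ],
        columns=["subset", "n_variants", "correlation", "ci_low", "ci_high"],
    ).to_csv(sub / "effect_correlation.tsv", sep="\t", index=False)
    grid.to_csv(sub / "dmr_enrichment_grid.tsv", sep="\t", index=False)


_RUNNERS = {
    "simulate": _run_simulate,
    "gwas": _run_gwas,
    "finemap": _run_finemap,
    "enrich": _run_enrich,
    "dmr": _run_dmr,
    "dmr_enrich": _run_dmr_enrich,
    "integrate": _run_integrate,
}
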