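"""Readers and writers for the pipeline's exchange formats.

Coordinate policy, centralised here to prevent off-by-one drift: VCF and
variant/association tables are 1-based; BED interval files (genes, tiles,
DMRs) are 0-based half-open. Formats: VCF (GT-derived dosages), genotype
matrix TSV, phenotype TSV (id, trait, dePTA, reliability), genes BED6, GMT
gene sets, methylKit-style per-sample CpG TSV (chrom, pos, strand,
coverage, numCs, numTs), association TSV (chrom, pos, id, ref, alt, maf,
b, se, p).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from gestarch.data import AssociationColumns as C, GenotypeMatrix, PhenotypeTable

_GT_BY_DOSE = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write dosages as an uncompressed VCF 4.2 with GT fields."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gestarch\n")
        if genotypes.chrom_sizes:
            for chrom, size in genotypes.chrom_sizes.items():
                fh.write(f"##contig=<ID={chrom},length={size}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, genotypes.individuals))
            + "\n"
        )
        V = genotypes.variants
        D = genotypes.dosages
        for j in range(genotypes.n_variants):
            gts = "\t".join(_GT_BY_DOSE[int(d)] for d in D[:, j])
            fh.write(
                f"{V[C.CHROM].iat[j]}\t{V[C.POS].iat[j]}\t{V[C.ID].iat[j]}\t"
                f"{V[C.REF].iat[j]}\t{V[C.ALT].iat[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read GT-coded dosages from a VCF (plain or bgzipped).

    Uses cyvcf2 when available, else a plain-text fallback for
    uncompressed VCFs.
    """
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover - fallback path
        return _read_vcf_text(path)
    vcf = VCF(str(path))
    individuals = np.array(vcf.samples)
    contigs = {}
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig"):
            fields = dict(
                kv.split("=") for kv in line[len("##contig=<") : -1].split(",") if "=" in kv
            )
            if "ID" in fields and "length" in fields:
                contigs[fields["ID"]] = int(fields["length"])
    rows, doses = [], []
    for rec in vcf:
        alt = rec.ALT[0] if rec.ALT else "."
        rows.append((rec.ID or f"{rec.CHROM}:{rec.POS}", rec.CHROM, rec.POS, rec.REF, alt))
        gt = np.asarray(rec.genotypes)[:, :2]
        doses.append(gt.sum(axis=1))
    variants = pd.DataFrame(rows, columns=[C.ID, C.CHROM, C.POS, C.REF, C.ALT])
    return GenotypeMatrix(
        dosages=np.array(doses, dtype=np.int8).T,
        variants=variants,
        individuals=individuals,
        chrom_sizes=contigs or None,
    )


def _read_vcf_text(path) -> GenotypeMatrix:
    individuals = None
    contigs: dict[str, int] = {}
    rows, doses = [], []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##contig"):
                fields = dict(
                    kv.split("=") for kv in line[len("##contig=<") : -1].split(",") if "=" in kv
                )
                if "ID" in fields and "length" in fields:
                    contigs[fields["ID"]] = int(fields["length"])
            elif line.startswith("#CHROM"):
                individuals = line.split("\t")[9:]
            elif line and not line.startswith("#"):
                f = line.split("\t")
                rows.append((f[2], f[0], int(f[1]), f[3], f[4]))
                doses.append([gt.count("1") for gt in (g.split(":")[0] for g in f[9:])])
    if individuals is None:
        raise ValueError(f"{path}: missing #CHROM header line")
    variants = pd.DataFrame(rows, columns=[C.ID, C.CHROM, C.POS, C.REF, C.ALT])
    return GenotypeMatrix(
        dosages=np.array(doses, dtype=np.int8).T,
        variants=variants,
        individuals=np.array(individuals),
        chrom_sizes=contigs or None,
    )


def write_genotype_tsv(genotypes: GenotypeMatrix, path) -> None:
    """Matrix TSV: variant metadata columns then one dosage column per individual."""
    frame = genotypes.variants.copy()
    for i, ind in enumerate(genotypes.individuals):
        frame[str(ind)] = genotypes.dosages[i]
    frame.to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path, chrom_sizes: dict[str, int] | None = None) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t", dtype={C.CHROM: str})
    meta = [C.ID, C.CHROM, C.POS, C.REF, C.ALT]
    individuals = [c for c in frame.columns if c not in meta]
    return GenotypeMatrix(
        dosages=frame[individuals].to_numpy(np.int8).T,
        variants=frame[meta],
        individuals=np.array(individuals),
        chrom_sizes=chrom_sizes,
    )


def write_phenotypes(pheno: PhenotypeTable, path, trait: str = "trait") -> None:
    pheno.to_frame(trait).to_csv(path, sep="\t", index=False)


def read_phenotypes(path, trait: str | None = None) -> PhenotypeTable:
    frame = pd.read_csv(path, sep="\t")
    if trait is not None:
        frame = frame[frame["trait"] == trait]
    return PhenotypeTable.from_frame(frame)


def write_bed(intervals: pd.DataFrame, path, name_col: str | None = None) -> None:
    """BED: chrom, start, end (+ name/score/strand when available)."""
    cols = ["chrom", "start", "end"]
    out = intervals[cols].copy()
    if name_col and name_col in intervals:
        out["name"] = intervals[name_col]
        out["score"] = 0
        out["strand"] = intervals["strand"] if "strand" in intervals else "+"
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    names = ["chrom", "start", "end", "name", "score", "strand"][: frame.shape[1]]
    frame.columns = names + list(frame.columns[len(names):])
    return frame


def read_genes_bed(path) -> pd.DataFrame:
    bed = read_bed(path)
    bed = bed.rename(columns={"name": "gene_id"})
    if "gene_id" not in bed:
        bed["gene_id"] = [f"gene{i:04d}" for i in range(len(bed))]
    return bed[["gene_id", "chrom", "start", "end"] + (["strand"] if "strand" in bed else [])]


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with Path(path).open("w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets = {}
    with Path(path).open() as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 3:
                sets[fields[0]] = fields[2:]
    return sets


def write_cpg_table(records: pd.DataFrame, path) -> None:
    records[["chrom", "pos", "strand", "coverage", "numCs", "numTs"]].to_csv(
        path, sep="\t", index=False
    )


def read_cpg_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_associations(assoc: pd.DataFrame, path) -> None:
    assoc[[C.CHROM, C.POS, C.ID, C.REF, C.ALT, C.MAF, C.BETA, C.SE, C.P]].to_csv(
        path, sep="\t", index=False
    )


def read_associations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={C.CHROM: str})


def validate_io(path, fmt: str) -> dict:
    """Format-specific validation returning a machine-readable report.

    ``fmt`` is one of {"VCF", "TSV-matrix", "phenotype-TSV", "BED", "GMT",
    "CpG-TSV"}. The report maps "errors"/"warnings" to lists of
    "line <n>: message" strings; an empty error list means the file passed.
    """
    path = Path(path)
    errors: list[str] = []
    warnings_: list[str] = []
    if not path.exists():
        return {"errors": [f"file not found: {path}"], "warnings": []}
    lines = path.read_text().splitlines()

    if fmt == "BED":
        for i, line in enumerate(lines, 1):
            f = line.split("\t")
            if len(f) < 3:
                errors.append(f"line {i}: fewer than 3 columns")
                continue
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                errors.append(f"line {i}: non-integer coordinates")
                continue
            if start < 0:
                errors.append(f"line {i}: negative start")
            if start >= end:
                errors.append(f"line {i}: start >= end")
    elif fmt == "GMT":
        for i, line in enumerate(lines, 1):
            f = line.split("\t")
            if len(f) < 3:
                errors.append(f"line {i}: GMT needs name, description and >= 1 gene")
            elif len(f) - 2 < 10:
                warnings_.append(f"line {i}: set {f[0]!r} has fewer than 10 genes")
    elif fmt == "CpG-TSV":
        header = lines[0].split("\t") if lines else []
        expected = ["chrom", "pos", "strand", "coverage", "numCs", "numTs"]
        if header != expected:
            errors.append(f"line 1: header must be {expected}")
        else:
            for i, line in enumerate(lines[1:], 2):
                f = line.split("\t")
                try:
                    cov, m, u = int(f[3]), int(f[4]), int(f[5])
                except (ValueError, IndexError):
                    errors.append(f"line {i}: malformed counts")
                    continue
                if m + u != cov:
                    errors.append(f"line {i}: numCs + numTs != coverage")
    elif fmt == "phenotype-TSV":
        header = lines[0].split("\t") if lines else []
        if header[:4] != ["id", "trait", "dePTA", "reliability"]:
            errors.append("line 1: header must be id, trait, dePTA, reliability")
        else:
            for i, line in enumerate(lines[1:], 2):
                f = line.split("\t")
                try:
                    r2 = float(f[3])
                except (ValueError, IndexError):
                    errors.append(f"line {i}: malformed reliability")
                    continue
                if not (0 < r2 <= 1):
                    errors.append(f"line {i}: reliability outside (0, 1]")
    elif fmt == "VCF":
        if not lines or not lines[0].startswith("##fileformat=VCF"):
            errors.append("line 1: missing ##fileformat header")
        n_samples = None
        for i, line in enumerate(lines, 1):
            if line.startswith("#CHROM"):
                n_samples = len(line.split("\t")) - 9
            elif not line.startswith("#") and line:
                f = line.split("\t")
                if len(f) < 10:
                    errors.append(f"line {i}: fewer than 10 columns")
                    continue
                try:
                    if int(f[1]) < 1:
                        errors.append(f"line {i}: POS must be >= 1")
                except ValueError:
                    errors.append(f"line {i}: non-integer POS")
                if n_samples is not None and len(f) - 9 != n_samples:
                    errors.append(f"line {i}: sample-column count mismatch")
        if n_samples is None:
            errors.append("missing #CHROM header line")
    elif fmt == "TSV-matrix":
        if not lines:
            errors.append("empty file")
        else:
            ncol = len(lines[0].split("\t"))
            for i, line in enumerate(lines[1:], 2):
                if len(line.split("\t")) != ncol:
                    errors.append(f"line {i}: column-count mismatch")
    else:
        errors.append(f"unknown format: {fmt}")
    return {"errors": errors, "warnings": warnings_}
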