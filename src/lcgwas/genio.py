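"""Text-format input/output: indicator/covariate TSVs, PLINK ped/map, VCF.

All genotype readers return a :class:`~lcgwas.association.GenotypeMatrix`
restricted to autosomes (chromosome labels 1-22); records on other
chromosomes are skipped with a warning.  Positions are 1-based throughout.

PLINK text convention used by the writer: allele ``A`` is the counted
(minor) allele and ``B`` the other; missing calls are ``0 0``.  The reader
counts the alphabetically first allele observed at each SNP, so a
write-read round trip reproduces dosages exactly; files using ACGT coding
are read consistently and re-oriented downstream.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .association import GenotypeMatrix
from .lca import IndicatorMatrix

__all__ = [
    "read_indicators_tsv",
    "write_indicators_tsv",
    "read_covariates_tsv",
    "write_covariates_tsv",
    "write_truth_tsv",
    "read_genotypes",
    "write_ped_map",
    "read_ped_map",
    "write_vcf",
    "read_vcf",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
]

_AUTOSOMES = {str(i) for i in range(1, 23)}


# ---------------------------------------------------------------------------
# indicator / covariate tables


def write_indicators_tsv(indicators: IndicatorMatrix, path) -> None:
    df = indicators.to_dataframe()
    if indicators.case_ids is None:
        df.index = [f"case{i:05d}" for i in range(indicators.n_cases)]
    df.index.name = "case_id"
    out = df.map(lambda v: "" if np.isnan(v) else str(int(v)))
    out.to_csv(path, sep="\t")


def read_indicators_tsv(path) -> IndicatorMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    values = df.replace("", np.nan).astype(float).to_numpy()
    return IndicatorMatrix(
        values=values,
        item_names=[str(c) for c in df.columns],
        case_ids=[str(i) for i in df.index],
    )


def write_covariates_tsv(aux: pd.DataFrame, path) -> None:
    out = aux.copy()
    out["age"] = out["age"].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
    out.to_csv(path, sep="\t", index=False)


def read_covariates_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    return df


def write_truth_tsv(cohort, path) -> None:
    """Persist the generative truth: per-case class, subpopulation, planted SNPs."""
    n_total = cohort.case_flags.shape[0]
    true_class = np.full(n_total, -1, dtype=int)
    true_class[: cohort.truth.true_class.shape[0]] = cohort.truth.true_class
    subpop = (
        cohort.truth.subpopulation
        if cohort.truth.subpopulation is not None
        else np.full(n_total, -1, dtype=int)
    )
    df = pd.DataFrame(
        {
            "sample_id": cohort.genotypes.sample_ids,
            "is_case": cohort.case_flags,
            "true_class": true_class,
            "subpopulation": subpop,
        }
    )
    planted = ";".join(
        f"{sid}:{cls}:{model}" for sid, cls, model in cohort.truth.planted_snps
    )
    with open(path, "w") as fh:
        fh.write(f"# planted_snps={planted or 'none'}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotype formats


def read_genotypes(path, fmt: str) -> GenotypeMatrix:
    """Dispatching reader; ``fmt`` in {'pedmap', 'vcf', 'tsv'}.

    For 'pedmap' and 'tsv', ``path`` is the shared file prefix.
    """
    if fmt == "pedmap":
        return read_ped_map(path)
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "tsv":
        return read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format '{fmt}'")


_PED_ALLELES = {2.0: ("A", "A"), 1.0: ("A", "B"), 0.0: ("B", "B")}


def write_ped_map(genotypes: GenotypeMatrix, prefix, phenotypes=None) -> None:
    prefix = Path(prefix)
    info = genotypes.snp_info
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, row in info.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp_id']}\t0\t{int(row['pos'])}\n")
    pheno = phenotypes if phenotypes is not None else [0] * genotypes.n_samples
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, sid in enumerate(genotypes.sample_ids):
            fields = [sid, sid, "0", "0", "0", str(int(pheno[i]))]
            for g in genotypes.counts[i]:
                fields.extend(_PED_ALLELES.get(g, ("0", "0")))
            fh.write(" ".join(fields) + "\n")


def read_ped_map(prefix) -> GenotypeMatrix:
    prefix = Path(prefix)
    map_rows = []
    keep_cols = []
    with open(prefix.with_suffix(".map")) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{prefix}.map line {lineno}: expected 4 fields")
            chrom = parts[0].removeprefix("chr")
            if chrom not in _AUTOSOMES:
                warnings.warn(
                    f"{prefix}.map line {lineno}: skipping non-autosomal record "
                    f"on chromosome {parts[0]}"
                )
                keep_cols.append(False)
                continue
            keep_cols.append(True)
            map_rows.append({"snp_id": parts[1], "chrom": chrom, "pos": int(parts[3])})
    n_total_snps = len(keep_cols)
    info = pd.DataFrame(map_rows, columns=["snp_id", "chrom", "pos"])

    sample_ids = []
    allele_rows = []
    with open(prefix.with_suffix(".ped")) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 6 + 2 * n_total_snps:
                raise ValueError(
                    f"{prefix}.ped line {lineno}: expected {6 + 2 * n_total_snps} "
                    f"fields, found {len(parts)}"
                )
            sample_ids.append(parts[1])
            alleles = parts[6:]
            row = []
            for j in range(n_total_snps):
                if keep_cols[j]:
                    row.append((alleles[2 * j], alleles[2 * j + 1]))
            allele_rows.append(row)

    m = len(info)
    counts = np.full((len(sample_ids), m), np.nan)
    for j in range(m):
        observed = {
            a
            for row in allele_rows
            for a in row[j]
            if a not in ("0", "-9", ".")
        }
        if not observed:
            continue
        # A/B coding (our writer): A is the counted allele even when absent
        # from a monomorphic column; otherwise count the alphabetically first
        counted = "A" if observed <= {"A", "B"} else sorted(observed)[0]
        for i, row in enumerate(allele_rows):
            a1, a2 = row[j]
            if a1 in ("0", "-9", ".") or a2 in ("0", "-9", "."):
                continue
            counts[i, j] = float((a1 == counted) + (a2 == counted))
    return GenotypeMatrix(counts=counts, snp_info=info, sample_ids=sample_ids)


_VCF_GT = {2.0: "1/1", 1.0: "0/1", 0.0: "0/0"}


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Minimal VCF v4.2 export; ALT is the counted (minor) allele."""
    info = genotypes.snp_info
    order = np.lexsort((info["pos"].to_numpy(), info["chrom"].astype(int).to_numpy()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted({int(c) for c in info["chrom"]}):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        for j in order:
            row = info.iloc[j]
            gts = "\t".join(
                _VCF_GT.get(g, "./.") for g in genotypes.counts[:, j]
            )
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['snp_id']}\tA\tG\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read genotypes from a VCF via cyvcf2; non-autosomes skipped with warning."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    cols = []
    rows = []
    n_skipped = 0
    for var in vcf:
        chrom = var.CHROM.removeprefix("chr")
        if chrom not in _AUTOSOMES:
            n_skipped += 1
            continue
        g = var.gt_types.astype(float)
        g[g == 3.0] = np.nan  # 3 = unknown under gts012
        cols.append(g)
        rows.append(
            {"snp_id": var.ID or f"{chrom}:{var.POS}", "chrom": chrom, "pos": var.POS}
        )
    vcf.close()
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} non-autosomal record(s)")
    counts = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    info = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])
    return GenotypeMatrix(counts=counts, snp_info=info, sample_ids=sample_ids)


def write_genotypes_tsv(genotypes: GenotypeMatrix, prefix) -> None:
    prefix = Path(prefix)
    geno = pd.DataFrame(
        genotypes.counts,
        index=pd.Index(genotypes.sample_ids, name="sample_id"),
        columns=genotypes.snp_info["snp_id"],
    )
    out = geno.map(lambda v: "" if np.isnan(v) else str(int(v)))
    out.to_csv(f"{prefix}.geno.tsv", sep="\t")
    genotypes.snp_info.to_csv(f"{prefix}.snps.tsv", sep="\t", index=False)


def read_genotypes_tsv(prefix) -> GenotypeMatrix:
    geno = pd.read_csv(
        f"{prefix}.geno.tsv", sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    info = pd.read_csv(f"{prefix}.snps.tsv", sep="\t", dtype={"chrom": str})
    counts = geno.replace("", np.nan).astype(float).to_numpy()
    keep = info["chrom"].astype(str).isin(_AUTOSOMES).to_numpy()
    if not keep.all():
        warnings.warn(f"{prefix}: skipped {(~keep).sum()} non-autosomal record(s)")
        counts = counts[:, keep]
        info = info.loc[keep].reset_index(drop=True)
    return GenotypeMatrix(
        counts=counts,
        snp_info=info[["snp_id", "chrom", "pos"]],
        sample_ids=[str(i) for i in geno.index],
    )
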