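"""Readers and writers for the plain-text dialects used across the pipeline.

Formats: dispensing CSV, VCF 4.2 (written directly, read through cyvcf2),
additive dosage TSV, covariate TSV, GMT gene sets, SNP-to-gene map TSV, and a
GCTA-style gzip lower-triangle GRM.  All writers are deterministic: fixed
column orders, fixed float formats, ``\\n`` line endings.
"""

from __future__ import annotations

import gzip
import io as _stdio
from pathlib import Path

import numpy as np
import pandas as pd

from adheregx.genotypes import GenotypeDataset

DISPENSING_COLUMNS = ["patient_id", "fill_day", "days_supply", "med_class"]
COVARIATE_COLUMNS = ["patient_id", "age", "sex"]
SNP_GENE_COLUMNS = ["snp_id", "gene", "chrom", "pos"]


# ---------------------------------------------------------------- dispensing

def write_dispensing_csv(records: pd.DataFrame, path: str | Path) -> None:
    """Write fill events as ``patient_id,fill_day,days_supply,med_class`` CSV."""
    df = records[DISPENSING_COLUMNS].copy()
    df.to_csv(path, index=False, lineterminator="\n")


def read_dispensing_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "med_class": str})
    missing = [c for c in DISPENSING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dispensing CSV {path} missing columns {missing}")
    df["fill_day"] = df["fill_day"].astype(int)
    df["days_supply"] = df["days_supply"].astype(int)
    if len(df) and (df["days_supply"] < 1).any():
        raise ValueError(f"dispensing CSV {path}: days_supply must be >= 1")
    return df[DISPENSING_COLUMNS]


# ---------------------------------------------------------------- covariates

def write_covariates_tsv(covariates: pd.DataFrame, path: str | Path) -> None:
    """Write ``patient_id, age, sex`` TSV with sex coded M/F."""
    df = covariates[COVARIATE_COLUMNS].copy()
    if not df["sex"].isin(["M", "F"]).all():
        raise ValueError("sex must be coded M/F")
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_covariates_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "sex": str})
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"covariate TSV {path} missing columns {missing}")
    bad = set(df["sex"]) - {"M", "F"}
    if bad:
        raise ValueError(f"covariate TSV {path}: sex values {sorted(bad)} not in M/F")
    return df[COVARIATE_COLUMNS]


# ---------------------------------------------------------------- genotypes

def write_dosage_tsv(genotypes: GenotypeDataset, path: str | Path) -> None:
    """Write samples x SNPs dosages (0/1/2, missing as NA), SNP ids as header."""
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(genotypes.snp_ids) + "\n")
        for sid, row in zip(genotypes.sample_ids, genotypes.dosages):
            cells = ["NA" if np.isnan(x) else str(int(x)) for x in row]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def read_dosage_tsv(path: str | Path, snp_meta: pd.DataFrame | None = None) -> GenotypeDataset:
    """Read a dosage TSV; synthesizes minimal SNP metadata when none is given."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    snp_ids = [str(c) for c in df.columns]
    if snp_meta is None:
        snp_meta = pd.DataFrame(
            {
                "snp_id": snp_ids,
                "chrom": "1",
                "pos": np.arange(1, len(snp_ids) + 1),
                "ref": "A",
                "alt": "B",
            }
        )
    else:
        snp_meta = snp_meta.set_index("snp_id").loc[snp_ids].reset_index()
    return GenotypeDataset(
        sample_ids=[str(i) for i in df.index],
        snp_meta=snp_meta,
        dosages=df.to_numpy(dtype=float),
    )


def write_vcf(genotypes: GenotypeDataset, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT genotypes, one record per SNP.

    The counted (dosage) allele is written as ALT so that the GT-derived
    alternate-allele count equals the stored dosage.
    """
    meta = genotypes.snp_meta
    order = np.lexsort((meta["pos"].to_numpy(), meta["chrom"].astype(str).to_numpy()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(meta["chrom"].astype(str).iloc[order]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j in order:
            row = meta.iloc[j]
            calls = [
                "./." if np.isnan(x) else gt_codes[x] for x in genotypes.dosages[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['snp_id']}\t"
                f"{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeDataset:
    """Read a VCF through cyvcf2 into an additive dosage dataset (ALT counts)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)  # gt_types: 0/1/2 = ALT count, 3 = missing
    sample_ids = list(vcf.samples)
    rows, meta_rows = [], []
    for var in vcf:
        dos = var.gt_types.astype(float)
        dos[dos == 3] = np.nan
        rows.append(dos)
        meta_rows.append(
            {
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
            }
        )
    vcf.close()
    dosages = (
        np.vstack(rows).T if rows else np.empty((len(sample_ids), 0), dtype=float)
    )
    return GenotypeDataset(
        sample_ids=sample_ids, snp_meta=pd.DataFrame(meta_rows), dosages=dosages
    )


# ---------------------------------------------------------------- gene sets

def write_gmt(genesets: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    """Write gene sets in GMT (name, description, tab-separated symbols)."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, genes in genesets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    genesets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"GMT line lacks name/description: {line!r}")
            genesets[parts[0]] = [g for g in parts[2:] if g]
    return genesets


def write_snp_gene_map(snp_gene: pd.DataFrame, path: str | Path) -> None:
    snp_gene[SNP_GENE_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_snp_gene_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "gene": str, "chrom": str})
    missing = [c for c in SNP_GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SNP-gene map {path} missing columns {missing}")
    return df[SNP_GENE_COLUMNS]


# ---------------------------------------------------------------- GRM

def write_grm(grm_matrix: np.ndarray, sample_ids: list[str], m_snps: np.ndarray,
              prefix: str | Path) -> None:
    """Write a GRM as GCTA-style ``<prefix>.grm.gz`` + ``<prefix>.grm.id``.

    The gz table has 1-based lower-triangle rows ``i  j  m_snps_ij  a_ij``.
    """
    prefix = str(prefix)
    n = grm_matrix.shape[0]
    # mtime=0 keeps the gzip header deterministic across runs
    with open(prefix + ".grm.gz", "wb") as raw, \
            gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz, \
            _text_wrapper(gz) as fh:
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{int(m_snps[i, j])}\t"
                         f"{grm_matrix[i, j]:.10g}\n")
    with open(prefix + ".grm.id", "w") as fh:
        for sid in sample_ids:
            fh.write(f"{sid}\t{sid}\n")


def _text_wrapper(binary_fh) -> _stdio.TextIOWrapper:
    return _stdio.TextIOWrapper(binary_fh, encoding="utf-8", newline="\n")


def read_grm(prefix: str | Path) -> tuple[np.ndarray, list[str], np.ndarray]:
    prefix = str(prefix)
    ids = [line.split("\t")[1].strip() for line in open(prefix + ".grm.id")]
    n = len(ids)
    a = np.zeros((n, n))
    m = np.zeros((n, n))
    with gzip.open(prefix + ".grm.gz", "rt") as fh:
        for line in fh:
            i_s, j_s, m_s, a_s = line.split()
            i, j = int(i_s) - 1, int(j_s) - 1
            a[i, j] = a[j, i] = float(a_s)
            m[i, j] = m[j, i] = float(m_s)
    return a, ids, m
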