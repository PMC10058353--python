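"""Protection:risk classification of pathways from association odds ratios.

Each SNP passing a significance screen (p < 0.05 by default) is mapped to a
gene; a gene's direction comes from its most significant mapped SNP — OR < 1
protective, OR > 1 risk, OR exactly 1 excluded.  For each gene set the P:R
ratio is the count of protective member genes divided by the count of risk
member genes (an explicit infinity when no risk gene is present); a pathway
is labeled protective when P:R > 1.5 and risk when P:R < 0.5, both strict.
Cross-measure agreement is the fraction of shared names among each measure's
top-k pathways.

The hypergeometric over-representation p-value is a clearly flagged generic
stand-in for proprietary knowledge-base enrichment engines: it tests overlap
with user-supplied gene sets and is not comparable to any such engine's
output.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PROTECTIVE_THRESHOLD = 1.5
RISK_THRESHOLD = 0.5


@dataclass
class PathwayPR:
    """Per-pathway protective/risk gene counts and the P:R ratio."""

    pathway: str
    n_protective: int
    n_risk: int
    pr_ratio: float  # math.inf when n_risk == 0 and n_protective > 0; nan if both 0
    label: str  # "protective" | "risk" | "unlabeled" | "undefined"
    enrich_p: float | None = None


def map_snps_to_genes(
    assoc_results: pd.DataFrame,
    snp_gene_map: pd.DataFrame,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Per-gene direction calls from screened association results.

    SNPs with ``p_wald < p_max`` are joined to the map (unmapped SNPs dropped
    with a logged count); each gene takes the direction of its most
    significant mapped SNP (ties broken by smaller |log OR|, then SNP id).
    Genes whose deciding SNP has OR exactly 1 are excluded with a warning.

    Returns a frame ``gene, direction, source_snp, source_or, source_p``.
    """
    if len(assoc_results) == 0:
        return pd.DataFrame(
            columns=["gene", "direction", "source_snp", "source_or", "source_p"]
        )
    hits = assoc_results.loc[
        np.isfinite(assoc_results["p_wald"]) & (assoc_results["p_wald"] < p_max),
        ["snp_id", "or_", "p_wald"],
    ]
    merged = hits.merge(snp_gene_map[["snp_id", "gene"]], on="snp_id", how="left")
    n_unmapped = int(merged["gene"].isna().sum())
    if n_unmapped:
        logger.info("map_snps_to_genes: dropped %d unmapped SNP(s)", n_unmapped)
    merged = merged.dropna(subset=["gene"])
    if len(merged) == 0:
        return pd.DataFrame(
            columns=["gene", "direction", "source_snp", "source_or", "source_p"]
        )
    with np.errstate(divide="ignore"):
        merged["abs_log_or"] = np.abs(np.log(merged["or_"].to_numpy(float)))
    merged = merged.sort_values(
        ["gene", "p_wald", "abs_log_or", "snp_id"], kind="stable"
    )
    best = merged.groupby("gene", sort=True).head(1)

    neutral = best["or_"] == 1.0
    if neutral.any():
        warnings.warn(
            f"excluding {int(neutral.sum())} gene(s) whose deciding SNP has "
            "OR exactly 1 (no direction)",
            stacklevel=2,
        )
        best = best.loc[~neutral]
    out = pd.DataFrame(
        {
            "gene": best["gene"].to_numpy(),
            "direction": np.where(best["or_"] < 1.0, "protective", "risk"),
            "source_snp": best["snp_id"].to_numpy(),
            "source_or": best["or_"].to_numpy(float),
            "source_p": best["p_wald"].to_numpy(float),
        }
    ).reset_index(drop=True)
    return out


def pr_ratio(
    pathway: str,
    geneset: list[str],
    directions: pd.DataFrame,
    enrich_p: float | None = None,
) -> PathwayPR:
    """P:R ratio of one gene set against a gene-direction table.

    Member genes absent from the direction table are ignored.  With no
    directed member genes at all the ratio is undefined (flagged, not an
    error).
    """
    if len(geneset) == 0:
        raise ValueError(f"gene set {pathway!r} is empty")
    members = set(geneset)
    sub = directions.loc[directions["gene"].isin(members)]
    n_prot = int((sub["direction"] == "protective").sum())
    n_risk = int((sub["direction"] == "risk").sum())
    if n_prot == 0 and n_risk == 0:
        return PathwayPR(pathway, 0, 0, math.nan, "undefined", enrich_p)
    ratio = n_prot / n_risk if n_risk > 0 else math.inf
    if ratio > PROTECTIVE_THRESHOLD:
        label = "protective"
    elif ratio < RISK_THRESHOLD:
        label = "risk"
    else:
        label = "unlabeled"
    return PathwayPR(pathway, n_prot, n_risk, ratio, label, enrich_p)


def ora_standin(
    geneset: list[str], hit_genes: list[str] | set[str], background_size: int
) -> float:
    """Hypergeometric upper-tail over-representation p-value (generic stand-in).

    Probability of observing at least the seen number of hit genes in the
    pathway when ``len(hit_genes)`` hits are drawn from a background of
    ``background_size`` genes.
    """
    hits = set(hit_genes)
    pathway_size = len(set(geneset))
    overlap = len(set(geneset) & hits)
    if background_size < len(hits):
        raise ValueError("background must be at least as large as the hit list")
    if overlap > pathway_size:
        raise ValueError("overlap exceeds pathway size")
    # P(X >= overlap), X ~ Hypergeom(N=background, K=pathway_size, n=#hits)
    return float(
        stats.hypergeom.sf(overlap - 1, background_size, pathway_size, len(hits))
    )


def pathway_pr_table(
    genesets: dict[str, list[str]],
    directions: pd.DataFrame,
    background_size: int | None = None,
) -> pd.DataFrame:
    """P:R ratios (plus the stand-in enrichment p) for every gene set.

    Sorted by enrichment p when available, infinite ratios above all finite
    ones otherwise.
    """
    hit_genes = set(directions["gene"])
    rows = []
    for name, genes in genesets.items():
        enrich = (
            ora_standin(genes, hit_genes, background_size)
            if background_size is not None
            else None
        )
        pr = pr_ratio(name, genes, directions, enrich_p=enrich)
        rows.append(
            {
                "pathway": pr.pathway,
                "n_protective": pr.n_protective,
                "n_risk": pr.n_risk,
                "pr_ratio": pr.pr_ratio,
                "label": pr.label,
                "enrich_p": pr.enrich_p,
            }
        )
    table = pd.DataFrame(rows)
    if background_size is not None and len(table):
        table = table.sort_values("enrich_p", kind="stable").reset_index(drop=True)
    elif len(table):
        table = table.sort_values(
            "pr_ratio", ascending=False, kind="stable", na_position="last"
        ).reset_index(drop=True)
    return table


def pathway_overlap(list_a: list[str], list_b: list[str], top_k: int = 10) -> float:
    """Fraction of shared names among the two top-k pathway lists."""
    for name, lst in (("first", list_a), ("second", list_b)):
        if len(set(lst)) != len(lst):
            raise ValueError(f"duplicate pathway names in {name} list")
        if len(lst) < top_k:
            raise ValueError(f"{name} list has fewer than top_k={top_k} entries")
    return len(set(list_a[:top_k]) & set(list_b[:top_k])) / top_k
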