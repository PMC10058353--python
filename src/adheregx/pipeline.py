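"""End-to-end orchestration: simulate -> phenotype -> QC/PCA -> association ->
GREML -> power -> pathways -> report.

A single :class:`PipelineConfig` drives every stage for one or both
non-adherence measures (PDC80, MPR80), writing per-measure outputs under
``<outdir>/pdc80`` and ``<outdir>/mpr80``, a human-readable report, and a
deterministic JSON manifest (parameters, seeds, SHA-256 checksums of every
artifact) — two runs of the same config produce byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from adheregx import __version__, adherence, assoc, cohort, greml, pathways, power
from adheregx import io as agio
from adheregx import qc as agqc

logger = logging.getLogger(__name__)

STAGES = ("simulate", "adherence", "qc_pca", "assoc", "greml", "power",
          "pathways", "report")
MEASURES = ("pdc80", "mpr80")


@dataclass
class PipelineConfig:
    """All stage parameters, paths and toggles for one pipeline run."""

    outdir: str = "adheregx_run"
    stages: tuple[str, ...] = STAGES
    measures: tuple[str, ...] = MEASURES
    seed: int = 0
    # synthetic cohort (used by the simulate stage)
    cohort: dict = field(default_factory=dict)
    # explicit input paths (required for stages run without simulate)
    records_path: str | None = None
    dosages_path: str | None = None
    covariates_path: str | None = None
    genesets_path: str | None = None
    snp_gene_map_path: str | None = None
    # adherence
    window_days: int = 365
    overlap_policy: str = "shift"
    pooling: str = "any"
    # QC / PCA
    maf_min: float = 0.01
    snp_missing_max: float = 0.05
    sample_missing_max: float = 0.05
    hwe_p_min: float = 1e-6
    k_pcs: int = 4
    # association
    nominal_threshold: float = 1e-6
    n_permutations: int = 1000
    # GREML; None = noise-adapted cutoff (greml.suggest_prune_cutoff) so
    # panel-scale GRM sampling noise is not mistaken for relatedness
    grm_cutoff: float | None = None
    greml_covariates: bool = True
    # power
    power_maf: float = 0.2
    power_grr: float = 1.25
    power_alpha: float = 1e-6
    # pathways
    p_max: float = 0.05
    top_k: int = 10

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        unknown = set(self.measures) - set(MEASURES)
        if unknown:
            raise ValueError(f"unknown measures: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("stages", "measures"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["measures"] = list(self.measures)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(condition: bool, stage: str, message: str) -> None:
    if not condition:
        raise RuntimeError(f"stage {stage!r}: missing upstream output — {message}")


def run_pipeline(config: PipelineConfig) -> tuple[str, dict]:
    """Execute the enabled stages in dependency order.

    Returns the rendered report text and the manifest dict; both are also
    written under ``config.outdir`` (``report.txt``, ``manifest.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    enabled = set(config.stages)
    report_sections: list[str] = []

    records = covariates = genotypes = snp_gene = genesets = None

    if "simulate" in enabled:
        spec_kwargs = dict(config.cohort)
        spec_kwargs.setdefault("seed", config.seed)
        spec_kwargs.setdefault("window_days", config.window_days)
        if "refill_gap_model" in spec_kwargs and isinstance(
            spec_kwargs["refill_gap_model"], dict
        ):
            spec_kwargs["refill_gap_model"] = cohort.RefillGapModel(
                **spec_kwargs["refill_gap_model"]
            )
        spec = cohort.CohortSpec(**spec_kwargs)
        sim = cohort.simulate_cohort(spec)
        paths = cohort.write_fixtures(sim, outdir / "inputs")
        artifacts.update({f"inputs/{p.name}": p for p in paths.values()})
        records, covariates, genotypes = sim.records, sim.covariates, sim.genotypes
        snp_gene, genesets = sim.snp_gene, sim.genesets
        logger.info("simulate: %d patients, %d fills, %d SNPs",
                    spec.n_patients, len(records), genotypes.n_snps)
    else:
        if config.records_path:
            records = agio.read_dispensing_csv(config.records_path)
        if config.covariates_path:
            covariates = agio.read_covariates_tsv(config.covariates_path)
        if config.dosages_path:
            genotypes = agio.read_dosage_tsv(config.dosages_path)
        if config.snp_gene_map_path:
            snp_gene = agio.read_snp_gene_map(config.snp_gene_map_path)
        if config.genesets_path:
            genesets = agio.read_gmt(config.genesets_path)

    # ---------------------------------------------------------- adherence
    phenotypes = labels = None
    if "adherence" in enabled:
        _require(records is not None, "adherence", "dispensing records")
        window = adherence.ObservationWindow(0, config.window_days)
        phenotypes = adherence.compute_phenotypes(
            records, window, overlap_policy=config.overlap_policy,
            pooling=config.pooling,
        )
        adherence.write_phenotypes_tsv(phenotypes, outdir / "phenotypes.tsv")
        artifacts["phenotypes.tsv"] = outdir / "phenotypes.tsv"
        labels = adherence.classify_cohort(phenotypes)
        if covariates is not None:
            prev = adherence.prevalence_table(phenotypes, covariates)
            prev.to_csv(outdir / "prevalence.tsv", sep="\t", index=False,
                        lineterminator="\n")
            artifacts["prevalence.tsv"] = outdir / "prevalence.tsv"
            report_sections.append(_render_prevalence(prev, labels))
        logger.info("adherence: %d phenotyped, %d PDC80 cases, %d MPR80 cases",
                    len(phenotypes), int(labels["pdc80"].sum()),
                    int(labels["mpr80"].sum()))

    # ---------------------------------------------------------- QC + PCA
    qc_genotypes = pcs = None
    if "qc_pca" in enabled:
        _require(genotypes is not None, "qc_pca", "genotype dosages")
        qc_genotypes, qc_report = agqc.qc_filter(
            genotypes, maf_min=config.maf_min,
            snp_missing_max=config.snp_missing_max,
            sample_missing_max=config.sample_missing_max,
            hwe_p_min=config.hwe_p_min,
        )
        qc_report.to_frame().to_csv(outdir / "qc_report.tsv", sep="\t",
                                    index=False, lineterminator="\n")
        artifacts["qc_report.tsv"] = outdir / "qc_report.tsv"
        pcs, _eigvals = agqc.compute_pcs(qc_genotypes, k=config.k_pcs)
        pcs_out = pcs.copy()
        for c in pcs_out.columns[1:]:
            pcs_out[c] = pcs_out[c].map(lambda v: f"{v:.6g}")
        pcs_out.to_csv(outdir / "pcs.tsv", sep="\t", index=False,
                       lineterminator="\n")
        artifacts["pcs.tsv"] = outdir / "pcs.tsv"
        logger.info("qc_pca: %d -> %d SNPs, %d PCs",
                    qc_report.n_snps_in, qc_report.n_snps_out, config.k_pcs)

    covar_table = None
    if covariates is not None and pcs is not None:
        covar_table = covariates.merge(pcs, on="patient_id", how="inner")
    elif covariates is not None:
        covar_table = covariates.copy()

    covar_names = tuple(
        c for c in ("age", "sex", *(f"PC{i+1}" for i in range(config.k_pcs)))
        if covar_table is not None and c in covar_table.columns
    )

    # ---------------------------------------------------------- per-measure
    assoc_tables: dict[str, pd.DataFrame] = {}
    varcomp_tables: dict[str, greml.VarianceComponents] = {}
    power_rows: list[dict] = []
    pr_tables: dict[str, pd.DataFrame] = {}

    for measure in config.measures:
        mdir = outdir / measure
        mdir.mkdir(exist_ok=True)
        y = labels[measure] if labels is not None else None

        if "assoc" in enabled:
            _require(qc_genotypes is not None, "assoc", "QC-passing genotypes")
            _require(y is not None, "assoc", "adherence labels")
            scan_cfg = assoc.ScanConfig(
                covariates=covar_names,
                nominal_threshold=config.nominal_threshold,
                n_permutations=config.n_permutations,
                seed=config.seed,
            )
            results = assoc.scan(qc_genotypes, y, covar_table, scan_cfg)
            if config.n_permutations > 0:
                perm = assoc.permute_scan(qc_genotypes, y, covar_table, scan_cfg)
                results = results.drop(columns=["p_perm", "p_fwer"]).merge(
                    perm[["snp_id", "p_perm", "p_fwer"]], on="snp_id"
                )
            out = mdir / "assoc.tsv"
            _write_assoc_tsv(results, out)
            artifacts[f"{measure}/assoc.tsv"] = out
            assoc_tables[measure] = results
            report_sections.append(_render_assoc(measure, results))

        if "greml" in enabled:
            _require(qc_genotypes is not None, "greml", "QC-passing genotypes")
            _require(y is not None, "greml", "adherence labels")
            grm = greml.compute_grm(qc_genotypes)
            agio.write_grm(grm.matrix, grm.sample_ids, grm.m_snps,
                           mdir / "grm")
            artifacts[f"{measure}/grm.grm.gz"] = mdir / "grm.grm.gz"
            artifacts[f"{measure}/grm.grm.id"] = mdir / "grm.grm.id"
            cutoff = (
                config.grm_cutoff
                if config.grm_cutoff is not None
                else greml.suggest_prune_cutoff(grm)
            )
            retained = greml.prune_related(grm, cutoff=cutoff)
            idx = [grm.sample_ids.index(s) for s in retained]
            pruned = greml.GRM(
                matrix=grm.matrix[np.ix_(idx, idx)],
                sample_ids=retained,
                m_snps=grm.m_snps[np.ix_(idx, idx)],
            )
            vc_covar = None
            if config.greml_covariates and covar_table is not None:
                vc_covar = covar_table[["patient_id", *covar_names]]
            vc = greml.reml_fit(pruned, y, vc_covar)
            vc.to_frame().to_csv(mdir / "varcomp.tsv", sep="\t", index=False,
                                 lineterminator="\n", float_format="%.6g")
            artifacts[f"{measure}/varcomp.tsv"] = mdir / "varcomp.tsv"
            varcomp_tables[measure] = vc
            report_sections.append(_render_varcomp(measure, vc))

        if "power" in enabled:
            _require(y is not None, "power", "adherence labels")
            n_cases = int(y.sum())
            n_controls = int(len(y) - n_cases)
            pspec = power.PowerSpec(
                n_cases=n_cases, n_controls=n_controls,
                prevalence=n_cases / len(y), maf=config.power_maf,
                grr=config.power_grr, alpha=config.power_alpha,
            )
            pw = power.gwas_power(pspec)
            power_rows.append(
                {
                    "measure": measure, "n_cases": n_cases,
                    "n_controls": n_controls,
                    "prevalence": round(n_cases / len(y), 4),
                    "maf": config.power_maf, "grr": config.power_grr,
                    "alpha": config.power_alpha, "power": round(pw, 4),
                }
            )

        if "pathways" in enabled:
            _require(measure in assoc_tables, "pathways", "association results")
            _require(snp_gene is not None, "pathways", "SNP-to-gene map")
            _require(genesets is not None, "pathways", "gene sets (GMT)")
            directions = pathways.map_snps_to_genes(
                assoc_tables[measure], snp_gene, p_max=config.p_max
            )
            background = snp_gene["gene"].nunique()
            table = pathways.pathway_pr_table(genesets, directions,
                                              background_size=background)
            out = mdir / "pathways.tsv"
            table.to_csv(out, sep="\t", index=False, lineterminator="\n",
                         float_format="%.6g")
            artifacts[f"{measure}/pathways.tsv"] = out
            pr_tables[measure] = table
            report_sections.append(_render_pathways(measure, table))

    if power_rows:
        ptable = pd.DataFrame(power_rows)
        ptable.to_csv(outdir / "power.tsv", sep="\t", index=False,
                      lineterminator="\n")
        artifacts["power.tsv"] = outdir / "power.tsv"
        report_sections.append(_render_power(ptable))

    if len(pr_tables) == 2 and "pathways" in enabled:
        ranked = {
            m: t.sort_values("enrich_p", kind="stable")["pathway"].tolist()
            for m, t in pr_tables.items()
        }
        k = min(config.top_k, *(len(v) for v in ranked.values()))
        overlap = pathways.pathway_overlap(
            ranked["pdc80"], ranked["mpr80"], top_k=k
        )
        report_sections.append(
            f"## Cross-measure pathway overlap\n"
            f"top-{k} overlap between PDC80 and MPR80: {overlap:.0%}\n"
        )

    # ---------------------------------------------------------- report
    report_text = ""
    if "report" in enabled:
        header = (
            f"# adheregx pipeline report\n"
            f"measures: {', '.join(config.measures)}; seed: {config.seed}\n"
        )
        report_text = "\n".join([header, *report_sections])
        (outdir / "report.txt").write_text(report_text)
        artifacts["report.txt"] = outdir / "report.txt"

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "checksums": {
            name: _sha256(path) for name, path in sorted(artifacts.items())
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return report_text, manifest


# ---------------------------------------------------------------- rendering

def _write_assoc_tsv(results: pd.DataFrame, path: Path) -> None:
    out = results[
        ["snp_id", "chrom", "pos", "maf", "beta", "se", "or_", "ci_l", "ci_u",
         "p_wald", "p_perm", "p_bonferroni", "n_used"]
    ].rename(columns={"or_": "or", "p_bonferroni": "p_bonf"})
    out.to_csv(path, sep="\t", index=False, lineterminator="\n",
               float_format="%.6g")


def _render_prevalence(prev: pd.DataFrame, labels: dict) -> str:
    lines = ["## Non-adherence prevalence"]
    for _, row in prev.iterrows():
        lines.append(
            f"{row['measure']:>6} {row['stratum']:<12} "
            f"{row['n_nonadherent']:>4}/{row['n']:<4} ({row['pct_display']}%)"
        )
    lines.append(
        f"non-adherent on both measures: {labels['n_nonadherent_both']}"
    )
    return "\n".join(lines) + "\n"


def _render_assoc(measure: str, results: pd.DataFrame, top: int = 10) -> str:
    lines = [f"## Top association results ({measure})",
             "snp_id\tmaf\tOR\t95% CI\tp_wald\tp_bonf"]
    for _, row in results.head(top).iterrows():
        lines.append(
            f"{row['snp_id']}\t{row['maf']:.2f}\t{row['or_']:.2f}\t"
            f"({row['ci_l']:.2f}, {row['ci_u']:.2f})\t{row['p_wald']:.3g}\t"
            f"{row['p_bonferroni']:.3g}"
        )
    return "\n".join(lines) + "\n"


def _render_varcomp(measure: str, vc: greml.VarianceComponents) -> str:
    lines = [
        f"## Variance components ({measure})",
        f"V(G)    {vc.vg:.6f} (SE {vc.se_vg:.6f})",
        f"V(e)    {vc.ve:.6f} (SE {vc.se_ve:.6f})",
        f"Vp      {vc.vp:.6f}",
        f"V(G)/Vp {vc.h2:.6f} (SE {vc.se_h2:.6f})",
        f"LRT p   {vc.lrt_p:.4f}  (converged: {vc.converged}, "
        f"n={vc.n_samples})",
    ]
    return "\n".join(lines) + "\n"


def _render_power(ptable: pd.DataFrame) -> str:
    lines = ["## Power (two-sided allele test)"]
    for _, row in ptable.iterrows():
        lines.append(
            f"{row['measure']}: n={row['n_cases']}+{row['n_controls']}, "
            f"prevalence={row['prevalence']:.2f}, MAF={row['maf']}, "
            f"GRR={row['grr']}, alpha={row['alpha']:g} -> "
            f"power={row['power']:.1%}"
        )
    return "\n".join(lines) + "\n"


def _render_pathways(measure: str, table: pd.DataFrame, top: int = 10) -> str:
    lines = [f"## Pathway protection:risk ({measure})",
             "pathway\tP\tR\tP:R\tlabel\tenrich_p"]
    for _, row in table.head(top).iterrows():
        ratio = "inf" if np.isinf(row["pr_ratio"]) else f"{row['pr_ratio']:.2f}"
        enrich = "" if pd.isna(row["enrich_p"]) else f"{row['enrich_p']:.3g}"
        lines.append(
            f"{row['pathway']}\t{row['n_protective']}\t{row['n_risk']}\t"
            f"{ratio}\t{row['label']}\t{enrich}"
        )
    return "\n".join(lines) + "\n"
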