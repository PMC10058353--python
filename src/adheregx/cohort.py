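"""Seeded synthetic cohort generator.

Emulates the statistical structure of a pharmacy-dispensing adherence study
with genotyped patients: refill histories for adherent and non-adherent
archetypes, a mostly-common-variant SNP panel with block LD and optional
two-subpopulation structure, a liability-threshold binary phenotype with a
planted heritability, age/sex covariates, gene sets, and a SNP-to-gene map.

The defaults mirror the study conditions the downstream stages were built
for: 230 patients, a 365-day observation window, roughly two-thirds
non-adherent, common variants (MAF 5-50%), unrelated individuals.

A single global seed expands into independent child streams (dispensing,
genotypes, phenotype, covariates, gene sets) so any stage can be re-run
reproducibly on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from adheregx import io as agio
from adheregx.genotypes import GenotypeDataset

MED_CLASSES = (
    "prostaglandin",
    "beta_blocker",
    "alpha_agonist",
    "carbonic_anhydrase_inhibitor",
    "rho_kinase_inhibitor",
    "miotic",
)

_STREAMS = ("dispensing", "genotypes", "phenotype", "covariates", "genesets")


@dataclass
class RefillGapModel:
    """Inter-fill delay model per adherence archetype.

    Gaps are drawn as Normal(factor * days_supply, sd_frac * days_supply),
    rounded and floored at 1 day.  Non-adherent patients additionally stop
    refilling altogether with ``nonadherent_stop_prob`` after each fill.
    """

    adherent_gap_factor: float = 1.0
    adherent_gap_sd_frac: float = 0.07
    nonadherent_gap_factor: float = 1.7
    nonadherent_gap_sd_frac: float = 0.35
    nonadherent_stop_prob: float = 0.04


@dataclass
class CohortSpec:
    """Parameters of the synthetic study.

    Probabilities and fractions must lie in [0, 1]; ``maf_range`` in (0, 0.5];
    ``n_causal <= n_snps``; ``window_days >= 1``.
    """

    n_patients: int = 230
    window_days: int = 365
    adherent_fraction: float = 0.335
    refill_gap_model: RefillGapModel = field(default_factory=RefillGapModel)
    supply_days_choices: tuple[int, ...] = (30, 90)
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 5
    ld_copy_prob: float = 0.9
    n_causal: int = 50
    target_h2: float = 0.5
    n_subpops: int = 1
    fst: float = 0.0
    age_range: tuple[float, float] = (43.0, 99.0)
    male_fraction: float = 0.38
    n_genesets: int = 20
    geneset_size: int = 25
    snps_per_gene: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def _prob(name: str, value: float) -> None:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")

        for name in ("adherent_fraction", "target_h2", "fst", "male_fraction",
                     "ld_copy_prob"):
            _prob(name, getattr(self, name))
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.n_causal > self.n_snps:
            raise ValueError(
                f"n_causal ({self.n_causal}) must not exceed n_snps ({self.n_snps})"
            )
        if self.window_days < 1:
            raise ValueError(f"window_days must be >= 1, got {self.window_days}")
        for name in ("n_patients", "n_snps", "n_causal", "ld_block_size",
                     "n_subpops", "n_genesets", "geneset_size", "snps_per_gene"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if any(s < 1 for s in self.supply_days_choices):
            raise ValueError("supply_days_choices entries must be >= 1")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError(f"age_range must be ordered, got {self.age_range}")

    def rng(self, stream: str) -> np.random.Generator:
        """Child generator for a named stage stream, derived from the global seed."""
        if stream not in _STREAMS:
            raise ValueError(f"unknown stream {stream!r}; expected one of {_STREAMS}")
        root = np.random.SeedSequence(self.seed)
        children = root.spawn(len(_STREAMS))
        return np.random.default_rng(children[_STREAMS.index(stream)])

    @property
    def patient_ids(self) -> list[str]:
        return [f"P{i + 1:04d}" for i in range(self.n_patients)]


# ------------------------------------------------------------- dispensing

def simulate_dispensing(
    spec: CohortSpec, archetypes: pd.Series | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate refill events for every patient.

    Adherent-archetype patients refill with gaps centred on their days supply;
    non-adherent patients refill late and may stop early.  Every patient fills
    once at day 0, so phenotypes are defined for the whole cohort.

    Parameters
    ----------
    spec : CohortSpec
    archetypes : pandas.Series, optional
        Boolean non-adherent indicator per patient id.  When omitted,
        archetypes are drawn Bernoulli(1 - adherent_fraction); passing the
        liability-model labels couples refill behaviour to genotype.

    Returns
    -------
    records : DataFrame with columns patient_id, fill_day, days_supply, med_class
    truth : DataFrame with columns patient_id, archetype_nonadherent
    """
    rng = spec.rng("dispensing")
    ids = spec.patient_ids
    if archetypes is None:
        nonadh = rng.random(spec.n_patients) >= spec.adherent_fraction
    else:
        nonadh = archetypes.reindex(ids).to_numpy().astype(bool)
    gm = spec.refill_gap_model
    rows = []
    for pid, is_non in zip(ids, nonadh):
        supply = int(rng.choice(spec.supply_days_choices))
        med = str(rng.choice(MED_CLASSES))
        factor = gm.nonadherent_gap_factor if is_non else gm.adherent_gap_factor
        sd = (gm.nonadherent_gap_sd_frac if is_non else gm.adherent_gap_sd_frac) * supply
        day = 0
        while day < spec.window_days:
            rows.append((pid, day, supply, med))
            if is_non and rng.random() < gm.nonadherent_stop_prob:
                break
            gap = factor * supply + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            day += max(1, int(round(gap)))
    records = pd.DataFrame(
        rows, columns=["patient_id", "fill_day", "days_supply", "med_class"]
    )
    truth = pd.DataFrame({"patient_id": ids, "archetype_nonadherent": nonadh})
    return records, truth


# ------------------------------------------------------------- genotypes

def simulate_genotypes(spec: CohortSpec) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Simulate an additive genotype panel with block LD.

    Per-SNP ancestral MAFs are uniform over ``maf_range``.  Within an LD block
    adjacent SNPs share a latent uniform with probability ``ld_copy_prob``
    (quantile-copying preserves each SNP's marginal frequency while inducing
    positive r^2 that decays along the block).  With ``n_subpops == 2`` and
    ``fst > 0``, subpopulation frequencies are drawn from the Balding-Nichols
    beta model.  Haplotypes are sampled independently within subpopulation, so
    genotypes are in Hardy-Weinberg proportions there.

    Returns the dataset and a truth table of planted causal SNPs with their
    standardized liability effects.
    """
    rng = spec.rng("genotypes")
    n, m = spec.n_patients, spec.n_snps
    # one ancestral MAF per LD block: tightly linked variants share allele
    # frequency, and equal within-block frequencies let quantile-copying reach
    # high r^2 (corr ~ ld_copy_prob between adjacent block members)
    n_blocks = -(-m // spec.ld_block_size)
    p_block = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=n_blocks)
    p_anc = np.repeat(p_block, spec.ld_block_size)[:m]

    if spec.n_subpops < 1:
        raise ValueError("n_subpops must be >= 1")
    subpop = np.repeat(np.arange(spec.n_subpops), int(np.ceil(n / max(spec.n_subpops, 1))))[:n] \
        if spec.n_subpops > 1 else np.zeros(n, dtype=int)
    if spec.n_subpops > 1 and spec.fst > 0:
        a = p_anc * (1 - spec.fst) / spec.fst
        b = (1 - p_anc) * (1 - spec.fst) / spec.fst
        p_sub = rng.beta(a, b, size=(spec.n_subpops, m))
    else:
        p_sub = np.tile(p_anc, (max(spec.n_subpops, 1), 1))

    n_hap = 2 * n
    block_start = np.arange(m) % spec.ld_block_size == 0
    fresh = rng.random((n_hap, m))
    copy = rng.random((n_hap, m)) < spec.ld_copy_prob
    copy[:, block_start] = False
    u = np.empty((n_hap, m))
    if m:
        u[:, 0] = fresh[:, 0]
        for j in range(1, m):
            u[:, j] = np.where(copy[:, j], u[:, j - 1], fresh[:, j])
    hap_subpop = np.repeat(subpop, 2)
    alleles = (u < p_sub[hap_subpop, :]).astype(float)
    dosages = alleles[0::2] + alleles[1::2]

    meta = pd.DataFrame(
        {
            "snp_id": [f"snp{j + 1:05d}" for j in range(m)],
            "chrom": "1",
            "pos": 1 + 5000 * np.arange(m),
            "ref": "A",
            "alt": "C",
        }
    )
    dataset = GenotypeDataset(
        sample_ids=spec.patient_ids, snp_meta=meta, dosages=dosages
    )
    causal_idx = np.sort(rng.choice(m, size=spec.n_causal, replace=False)) \
        if spec.n_causal else np.array([], dtype=int)
    truth = pd.DataFrame(
        {
            "snp_id": meta["snp_id"].iloc[causal_idx].to_numpy(),
            "effect": rng.normal(0.0, 1.0, size=len(causal_idx)),
            "snp_index": causal_idx,
        }
    )
    return dataset, truth


def genetic_liability(genotypes: GenotypeDataset, truth: pd.DataFrame) -> np.ndarray:
    """Raw (unscaled) genetic value: sum of standardized causal dosages x effects."""
    if len(truth) == 0:
        return np.zeros(genotypes.n_samples)
    idx = truth["snp_index"].to_numpy()
    x = genotypes.dosages[:, idx].copy()
    p = np.nanmean(x, axis=0) / 2.0
    col_mean = 2.0 * p
    nan_mask = np.isnan(x)
    x[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    denom = np.sqrt(2.0 * p * (1.0 - p))
    denom[denom == 0] = 1.0
    z = (x - col_mean) / denom
    return z @ truth["effect"].to_numpy()


def simulate_phenotype(
    genotypes: GenotypeDataset, truth: pd.DataFrame, spec: CohortSpec
) -> pd.Series:
    """Binary non-adherence labels from a liability-threshold model.

    Liability = genetic value scaled to variance ``target_h2`` plus
    Normal(0, 1 - target_h2) noise; labels are liability above the empirical
    quantile matching the configured prevalence (1 - adherent_fraction).
    """
    prevalence = 1.0 - spec.adherent_fraction
    if not 0.0 < prevalence < 1.0:
        raise ValueError(
            f"degenerate phenotype: prevalence {prevalence} must be in (0, 1)"
        )
    rng = spec.rng("phenotype")
    n = genotypes.n_samples
    g = genetic_liability(genotypes, truth)
    sd = g.std()
    g_scaled = g / sd * np.sqrt(spec.target_h2) if sd > 0 and spec.target_h2 > 0 \
        else np.zeros(n)
    noise_sd = np.sqrt(max(0.0, 1.0 - spec.target_h2))
    liability = g_scaled + (rng.normal(0.0, noise_sd, size=n) if noise_sd > 0
                            else np.zeros(n))
    threshold = np.quantile(liability, 1.0 - prevalence)
    labels = (liability > threshold).astype(int)
    return pd.Series(labels, index=pd.Index(genotypes.sample_ids, name="patient_id"),
                     name="nonadherent")


# ------------------------------------------------------------- covariates etc.

def simulate_covariates(spec: CohortSpec) -> pd.DataFrame:
    """Age uniform over ``age_range`` and sex Bernoulli(male_fraction), coded M/F."""
    rng = spec.rng("covariates")
    age = np.round(rng.uniform(spec.age_range[0], spec.age_range[1],
                               size=spec.n_patients), 1)
    sex = np.where(rng.random(spec.n_patients) < spec.male_fraction, "M", "F")
    return pd.DataFrame({"patient_id": spec.patient_ids, "age": age, "sex": sex})


def snp_gene_map(genotypes: GenotypeDataset, spec: CohortSpec) -> pd.DataFrame:
    """Map consecutive SNPs onto synthetic genes (``snps_per_gene`` per gene)."""
    k = max(spec.snps_per_gene, 1)
    genes = [f"GENE{j // k + 1:04d}" for j in range(genotypes.n_snps)]
    return pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids,
            "gene": genes,
            "chrom": genotypes.snp_meta["chrom"].astype(str),
            "pos": genotypes.snp_meta["pos"].astype(int),
        }
    )


def simulate_genesets(spec: CohortSpec, gene_universe: list[str]) -> dict[str, list[str]]:
    """Random gene sets (sorted members) over the mapped gene universe."""
    rng = spec.rng("genesets")
    universe = sorted(set(gene_universe))
    sets: dict[str, list[str]] = {}
    for i in range(spec.n_genesets):
        size = min(spec.geneset_size, len(universe))
        members = sorted(rng.choice(universe, size=size, replace=False).tolist())
        sets[f"PATHWAY_{i + 1:03d}"] = members
    return sets


# ------------------------------------------------------------- bundle + fixtures

@dataclass
class Cohort:
    """Everything one simulated study produces, plus the planted truth."""

    spec: CohortSpec
    records: pd.DataFrame
    archetypes: pd.DataFrame
    genotypes: GenotypeDataset
    causal_truth: pd.DataFrame
    labels: pd.Series
    covariates: pd.DataFrame
    snp_gene: pd.DataFrame
    genesets: dict[str, list[str]]


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Run the full generator with refill behaviour coupled to genetic liability.

    Genotypes determine the liability-model labels; those labels select each
    patient's dispensing archetype, so the adherence phenotypes recovered from
    the refill records carry the planted genetic signal.
    """
    genotypes, truth = simulate_genotypes(spec)
    labels = simulate_phenotype(genotypes, truth, spec)
    records, archetypes = simulate_dispensing(spec, archetypes=labels.astype(bool))
    covariates = simulate_covariates(spec)
    sg_map = snp_gene_map(genotypes, spec)
    genesets = simulate_genesets(spec, sg_map["gene"].tolist())
    return Cohort(
        spec=spec,
        records=records,
        archetypes=archetypes,
        genotypes=genotypes,
        causal_truth=truth,
        labels=labels,
        covariates=covariates,
        snp_gene=sg_map,
        genesets=genesets,
    )


def write_fixtures(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write every fixture file; returns the path of each artifact.

    Files: dispensing.csv, genotypes.vcf, dosages.tsv, covariates.tsv,
    genesets.gmt, snp_gene_map.tsv.  All writers are deterministic, so the
    same spec + seed yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dispensing": outdir / "dispensing.csv",
        "vcf": outdir / "genotypes.vcf",
        "dosages": outdir / "dosages.tsv",
        "covariates": outdir / "covariates.tsv",
        "genesets": outdir / "genesets.gmt",
        "snp_gene_map": outdir / "snp_gene_map.tsv",
    }
    try:
        agio.write_dispensing_csv(cohort.records, paths["dispensing"])
        agio.write_vcf(cohort.genotypes, paths["vcf"])
        agio.write_dosage_tsv(cohort.genotypes, paths["dosages"])
        agio.write_covariates_tsv(cohort.covariates, paths["covariates"])
        agio.write_gmt(cohort.genesets, paths["genesets"])
        agio.write_snp_gene_map(cohort.snp_gene, paths["snp_gene_map"])
    except OSError as exc:
        raise OSError(f"failed writing fixtures under {outdir}: {exc}") from exc
    return paths


def spec_to_dict(spec: CohortSpec) -> dict:
    """JSON-serializable view of a spec (for manifests)."""
    d = asdict(spec)
    d["supply_days_choices"] = list(spec.supply_days_choices)
    d["maf_range"] = list(spec.maf_range)
    d["age_range"] = list(spec.age_range)
    return d
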