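"""Per-SNP additive logistic association scan with permutation p-values.

Each QC-passing SNP's minor-allele dosage is tested against binary
non-adherence by maximum-likelihood logistic regression (IRLS) with age, sex
and principal-component covariates.  Wald odds ratios with symmetric-log 95%
confidence intervals are reported, so exp(beta -+ 1.96 se) bracket the OR and
the geometric mean of the bounds equals it.  Empirical p-values come from
permuting phenotype labels as a unit against the fixed genotype/covariate
rows — linkage disequilibrium between SNPs is untouched — using the
efficient-score statistic; a max-T family-wise p-value is returned alongside.
Bonferroni correction is min(1, m p).  LD-proxy intervals span all SNPs
within a flank whose composite-genotype r^2 with the index reaches a cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from adheregx.genotypes import GenotypeDataset

logger = logging.getLogger(__name__)

#: |log-odds| beyond which a fit is flagged as (quasi-)separated
SEPARATION_BETA = 15.0

RESULT_COLUMNS = [
    "snp_id", "chrom", "pos", "maf", "beta", "se", "or_", "ci_l", "ci_u",
    "p_wald", "p_perm", "p_fwer", "p_bonferroni", "n_used", "separation",
]


@dataclass
class ScanConfig:
    """Scan-wide settings.

    ``nominal_threshold`` flags SNPs at the study's nominal genome-wide level
    (10^-6 by default; 10^-5 is the other conventional choice).  ``coding_m``
    optionally fixes the Bonferroni multiplier to the size of an explicitly
    analyzed coding subset; otherwise m is the number of scanned SNPs.
    """

    covariates: tuple[str, ...] = ("age", "sex", "PC1", "PC2", "PC3", "PC4")
    nominal_threshold: float = 1e-6
    n_permutations: int = 10_000
    seed: int = 0
    coding_m: int | None = None

    def __post_init__(self) -> None:
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be >= 0")
        if not 0.0 < self.nominal_threshold < 1.0:
            raise ValueError("nominal_threshold must be in (0, 1)")


@dataclass
class AssocResult:
    """Single-SNP logistic fit summary (Wald inference)."""

    snp_id: str
    beta: float
    se: float
    or_: float
    ci95: tuple[float, float]
    p_wald: float
    n_used: int
    maf: float
    separation: bool = False
    p_perm: float | None = None
    p_bonferroni: float | None = None
    converged: bool = True


def _design_matrix(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    """Intercept plus numeric covariate columns (sex M/F coded 1/0)."""
    if covariates is None or covariates.shape[1] == 0:
        return np.ones((n, 1))
    x = covariates.copy()
    if "sex" in x.columns and x["sex"].dtype == object:
        x["sex"] = (x["sex"] == "M").astype(float)
    mat = x.to_numpy(dtype=float)
    return np.column_stack([np.ones(n), mat])


def _check_collinearity(design: np.ndarray, names: list[str]) -> None:
    cond = np.linalg.cond(design)
    if cond > 1e12:
        raise ValueError(
            f"covariate design is collinear (condition number {cond:.3g}); "
            f"columns: {names}"
        )


def fit_snp(
    dosage: np.ndarray,
    labels: np.ndarray,
    covariates: pd.DataFrame | None = None,
    snp_id: str = "snp",
) -> AssocResult:
    """Logistic regression of labels on one SNP's dosage plus covariates.

    Samples with missing dosage are dropped for this SNP (complete-case).
    Quasi-complete separation is flagged (``separation=True`` with infinite
    CI markers) rather than silently returned.
    """
    dosage = np.asarray(dosage, dtype=float)
    labels = np.asarray(labels, dtype=float)
    keep = ~np.isnan(dosage)
    dosage, labels = dosage[keep], labels[keep]
    if covariates is not None:
        covariates = covariates.loc[np.asarray(keep)]
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("labels must contain both classes after missing-drop")
    n = len(labels)
    covar_mat = _design_matrix(covariates, n)
    design = np.column_stack([covar_mat, dosage])
    p_hat = np.nanmean(dosage) / 2.0
    maf = float(min(p_hat, 1.0 - p_hat))

    with np.errstate(all="ignore"):
        model = sm.GLM(labels, design, family=sm.families.Binomial())
        try:
            fit = model.fit(maxiter=100)
            converged = bool(fit.converged)
        except Exception:  # noqa: BLE001 - any IRLS failure is a flagged result
            fit, converged = None, False

    if fit is None or not np.isfinite(fit.params[-1]):
        return AssocResult(snp_id, np.nan, np.nan, np.nan, (np.nan, np.nan),
                           np.nan, n, maf, separation=True, converged=False)
    beta = float(fit.params[-1])
    se = float(fit.bse[-1])
    separated = abs(beta) > SEPARATION_BETA or not np.isfinite(se)
    if separated:
        or_ = np.inf if beta > 0 else 0.0
        return AssocResult(snp_id, beta, np.inf, or_, (0.0, np.inf), 1.0, n,
                           maf, separation=True, converged=converged)
    z = beta / se
    p_wald = float(2.0 * stats.norm.sf(abs(z)))
    ci = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
    return AssocResult(snp_id, beta, se, float(np.exp(beta)), ci, p_wald, n,
                       maf, separation=False, converged=converged)


def scan(
    genotypes: GenotypeDataset,
    labels: pd.Series,
    covariates: pd.DataFrame | None,
    config: ScanConfig | None = None,
) -> pd.DataFrame:
    """Run the single-SNP scan over every SNP; rows sorted by Wald p.

    ``labels`` and ``covariates`` are aligned to ``genotypes.sample_ids``.
    The returned frame carries OR/CI, Wald and Bonferroni p-values and a
    ``below_nominal`` flag; permutation columns are filled by
    :func:`permute_scan`.
    """
    config = config or ScanConfig()
    y = labels.reindex(genotypes.sample_ids).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("labels missing for some samples")
    covar = None
    if covariates is not None:
        covar = (
            covariates.set_index("patient_id")
            .reindex(genotypes.sample_ids)[list(config.covariates)]
            .reset_index(drop=True)
        )
        if covar.isna().any().any():
            raise ValueError("covariates missing for some samples")
        _check_collinearity(
            _design_matrix(covar, len(y)), ["intercept", *config.covariates]
        )
    m = genotypes.n_snps
    rows = []
    for j in range(m):
        res = fit_snp(
            genotypes.dosages[:, j], y, covar, snp_id=genotypes.snp_ids[j]
        )
        meta = genotypes.snp_meta.iloc[j]
        rows.append(
            {
                "snp_id": res.snp_id,
                "chrom": meta["chrom"],
                "pos": int(meta["pos"]),
                "maf": res.maf,
                "beta": res.beta,
                "se": res.se,
                "or_": res.or_,
                "ci_l": res.ci95[0],
                "ci_u": res.ci95[1],
                "p_wald": res.p_wald,
                "p_perm": np.nan,
                "p_fwer": np.nan,
                "n_used": res.n_used,
                "separation": res.separation,
            }
        )
    results = pd.DataFrame(rows, columns=[c for c in RESULT_COLUMNS
                                          if c != "p_bonferroni"])
    m_eff = config.coding_m if config.coding_m is not None else max(m, 1)
    results["p_bonferroni"] = results["p_wald"].map(
        lambda p: bonferroni(p, m_eff) if np.isfinite(p) else np.nan
    )
    results["below_nominal"] = results["p_wald"] < config.nominal_threshold
    return results.sort_values("p_wald", kind="stable").reset_index(drop=True)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value: min(1, m p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    return min(1.0, m * p)


# ------------------------------------------------------------- permutation

def _irls_null(y: np.ndarray, x: np.ndarray, tol: float = 1e-10,
               max_iter: int = 50) -> np.ndarray:
    """Fitted probabilities of the covariate-only logistic model (plain IRLS)."""
    beta = np.zeros(x.shape[1])
    for _ in range(max_iter):
        eta = x @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1.0 - p), 1e-10, None)
        # weighted least squares step on the working response
        wx = x * w[:, None]
        try:
            delta = np.linalg.solve(x.T @ wx, x.T @ (y - p))
        except np.linalg.LinAlgError:
            break
        beta += delta
        if np.abs(delta).max() < tol:
            break
    return 1.0 / (1.0 + np.exp(-(x @ beta)))


def _score_stats(g: np.ndarray, y: np.ndarray, x: np.ndarray,
                 p0: np.ndarray) -> np.ndarray:
    """Efficient-score chi-square statistic per SNP column of ``g``.

    U_j = g_j'(y - p0); V_j = g_j'Wg_j - g_j'WX (X'WX)^-1 X'Wg_j with
    W = diag(p0 (1 - p0)).  T = U^2 / V is asymptotically chi-square(1).
    """
    w = p0 * (1.0 - p0)
    u = g.T @ (y - p0)
    gw = g * w[:, None]
    xtwx = x.T @ (x * w[:, None])
    xtwg = x.T @ gw
    v = np.einsum("ij,ij->j", g, gw) - np.einsum(
        "ij,ij->j", xtwg, np.linalg.solve(xtwx, xtwg)
    )
    v = np.clip(v, 1e-12, None)
    return u**2 / v


def permute_scan(
    genotypes: GenotypeDataset,
    labels: pd.Series,
    covariates: pd.DataFrame | None,
    config: ScanConfig | None = None,
) -> pd.DataFrame:
    """Label-permutation empirical p-values for every SNP.

    Phenotype labels are permuted as a unit against the fixed genotype and
    covariate rows (LD is preserved by construction); the covariate-only null
    model is refit per permutation and the efficient-score statistic is
    compared with its observed value.  Empirical p uses the add-one
    estimator (1 + #{perm >= obs}) / (1 + B); ``p_fwer`` is the max-T
    family-wise version.  Missing dosages are mean-imputed for this stage.

    Returns a frame ``snp_id, score_stat, p_perm, p_fwer`` in dataset order.
    """
    config = config or ScanConfig()
    if config.n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    y = labels.reindex(genotypes.sample_ids).to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are constant; permutation p undefined")
    n = len(y)
    covar = None
    if covariates is not None:
        covar = (
            covariates.set_index("patient_id")
            .reindex(genotypes.sample_ids)[list(config.covariates)]
            .reset_index(drop=True)
        )
    x = _design_matrix(covar, n)
    g = genotypes.dosages.copy()
    col_mean = np.nanmean(g, axis=0)
    nan_mask = np.isnan(g)
    g[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])

    p0 = _irls_null(y, x)
    t_obs = _score_stats(g, y, x, p0)

    rng = np.random.default_rng(config.seed)
    b = config.n_permutations
    count_ge = np.zeros(genotypes.n_snps)
    count_max_ge = np.zeros(genotypes.n_snps)
    for _ in range(b):
        perm = rng.permutation(n)
        y_p = y[perm]
        p0_p = p0 if x.shape[1] == 1 else _irls_null(y_p, x)
        t_perm = _score_stats(g, y_p, x, p0_p)
        count_ge += t_perm >= t_obs
        count_max_ge += t_perm.max() >= t_obs
    return pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids,
            "score_stat": t_obs,
            "p_perm": (1.0 + count_ge) / (1.0 + b),
            "p_fwer": (1.0 + count_max_ge) / (1.0 + b),
        }
    )


# ------------------------------------------------------------- LD proxies

def ld_proxy_interval(
    index_snp: str,
    genotypes: GenotypeDataset,
    r2_min: float = 0.5,
    flank_bp: int = 100_000,
) -> tuple[str, int, int]:
    """Genomic interval spanned by LD proxies of an index SNP.

    Composite-genotype r^2 (squared Pearson correlation of dosage vectors) is
    computed against every same-chromosome SNP within ``flank_bp``; the
    interval spans the min/max positions of SNPs with r^2 >= ``r2_min``, the
    index always included.  Returns ``(chrom, start_pos, end_pos)`` in
    basepairs (degenerate when no proxy passes).
    """
    meta = genotypes.snp_meta
    hits = meta.index[meta["snp_id"] == index_snp]
    if len(hits) == 0:
        raise KeyError(f"index SNP {index_snp!r} not in dataset")
    j = int(hits[0])
    chrom, pos = str(meta.at[j, "chrom"]), int(meta.at[j, "pos"])
    g_index = genotypes.dosages[:, j]
    if np.nanstd(g_index) == 0:
        raise ValueError(f"index SNP {index_snp!r} is monomorphic")
    near = meta.index[
        (meta["chrom"].astype(str) == chrom)
        & (meta["pos"].astype(int) >= pos - flank_bp)
        & (meta["pos"].astype(int) <= pos + flank_bp)
    ]
    positions = [pos]
    for k in near:
        g = genotypes.dosages[:, int(k)]
        both = ~(np.isnan(g) | np.isnan(g_index))
        if both.sum() < 3 or np.std(g[both]) == 0:
            continue
        r = np.corrcoef(g_index[both], g[both])[0, 1]
        if r * r >= r2_min:
            positions.append(int(meta.at[k, "pos"]))
    return chrom, min(positions), max(positions)


def proxy_interval_bed(intervals: list[tuple[str, int, int]], path) -> None:
    """Write proxy intervals as 0-based half-open BED lines."""
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")
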