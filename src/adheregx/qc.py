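"""Genotype quality control and principal components of population structure.

QC removes SNPs by minor allele frequency, call-rate and Hardy-Weinberg
disequilibrium (exact test, computed in controls when labels are supplied)
and samples by call-rate, with a report whose totals reconcile.  PCA
standardizes dosages by sqrt(2p(1-p)) after per-SNP mean imputation of
missing calls and returns the leading left singular vectors scaled by their
singular values — the conventional GWAS covariate PCs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from adheregx.genotypes import GenotypeDataset

logger = logging.getLogger(__name__)


def hwe_exact_test(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg p-value from genotype counts (Wigginton-style).

    Sums the probabilities of all heterozygote counts, conditional on the
    observed allele counts, that are no more probable than the observed one.
    """
    if min(n_het, n_hom_minor, n_hom_major) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n_hom_major + n_het
    if n_minor > n_major:
        n_minor, n_major = n_major, n_minor
    # log P(het = h | allele counts) up to a shared constant, h same parity as n_minor
    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    logp = (
        hs * np.log(2.0)
        - gammaln(hs + 1)
        - gammaln((n_minor - hs) / 2 + 1)
        - gammaln((n_major - hs) / 2 + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = probs[np.searchsorted(hs, n_het)]
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


@dataclass
class QCReport:
    """Per-filter attrition of a QC pass; ``in - removed == out`` on each axis."""

    n_snps_in: int
    n_samples_in: int
    snp_removals: dict[str, int] = field(default_factory=dict)
    sample_removals: dict[str, int] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def n_snps_out(self) -> int:
        return self.n_snps_in - sum(self.snp_removals.values())

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - sum(self.sample_removals.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("snps", "input", self.n_snps_in)]
        rows += [("snps", f"removed_{k}", v) for k, v in self.snp_removals.items()]
        rows += [("snps", "output", self.n_snps_out), ("samples", "input", self.n_samples_in)]
        rows += [("samples", f"removed_{k}", v) for k, v in self.sample_removals.items()]
        rows += [("samples", "output", self.n_samples_out)]
        return pd.DataFrame(rows, columns=["axis", "step", "count"])


def qc_filter(
    genotypes: GenotypeDataset,
    maf_min: float = 0.01,
    snp_missing_max: float = 0.05,
    sample_missing_max: float = 0.05,
    hwe_p_min: float = 1e-6,
    control_labels: pd.Series | None = None,
) -> tuple[GenotypeDataset, QCReport]:
    """Apply the conventional marker/sample filters in a fixed order.

    Order: SNP call-rate, sample call-rate, MAF, HWE exact test.  The HWE
    test runs in controls (label 0) when ``control_labels`` is given, else in
    all samples.  SNP and sample order is preserved.
    """
    for name, thr in (("maf_min", maf_min), ("snp_missing_max", snp_missing_max),
                      ("sample_missing_max", sample_missing_max), ("hwe_p_min", hwe_p_min)):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {thr}")
    report = QCReport(
        n_snps_in=genotypes.n_snps,
        n_samples_in=genotypes.n_samples,
        thresholds={
            "maf_min": maf_min,
            "snp_missing_max": snp_missing_max,
            "sample_missing_max": sample_missing_max,
            "hwe_p_min": hwe_p_min,
        },
    )
    current = genotypes

    keep = current.snp_missingness() <= snp_missing_max
    report.snp_removals["missingness"] = int((~keep).sum())
    current = current.take_snps(keep)

    keep_s = current.sample_missingness() <= sample_missing_max
    report.sample_removals["missingness"] = int((~keep_s).sum())
    current = current.take_samples(keep_s)

    keep = current.sample_maf() >= maf_min
    report.snp_removals["maf"] = int((~keep).sum())
    current = current.take_snps(keep)

    if current.n_snps:
        dos = current.dosages
        if control_labels is not None:
            ctrl = control_labels.reindex(current.sample_ids).to_numpy() == 0
            dos = dos[ctrl]
        hwe_p = np.ones(current.n_snps)
        for j in range(current.n_snps):
            col = dos[:, j]
            col = col[~np.isnan(col)]
            n_het = int((col == 1).sum())
            n_hom_alt = int((col == 2).sum())
            n_hom_ref = int((col == 0).sum())
            hwe_p[j] = hwe_exact_test(n_het, n_hom_alt, n_hom_ref)
        keep = hwe_p >= hwe_p_min
        report.snp_removals["hwe"] = int((~keep).sum())
        current = current.take_snps(keep)
    else:
        report.snp_removals["hwe"] = 0

    if current.n_snps == 0:
        raise ValueError(
            "all SNPs removed by QC; relax maf_min/snp_missing_max/hwe_p_min"
        )
    return current, report


def compute_pcs(
    genotypes: GenotypeDataset, k: int = 4
) -> tuple[pd.DataFrame, np.ndarray]:
    """Leading principal components of standardized dosages.

    Columns are centred at 2p and scaled by sqrt(2p(1-p)) (sample allele
    frequency p) after mean imputation of missing calls; zero-variance SNPs
    are excluded with a warning.  Scores are U_k * S_k with a fixed sign
    convention (the largest-magnitude loading of each component is positive);
    eigenvalues are S^2 / (n - 1), non-increasing.
    """
    n, m = genotypes.n_samples, genotypes.n_snps
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return (
            pd.DataFrame({"patient_id": genotypes.sample_ids}),
            np.empty(0),
        )
    if k >= min(n, m):
        raise ValueError(f"k ({k}) must be < min(n_samples, n_snps) = {min(n, m)}")
    x = genotypes.dosages.copy()
    p = np.nanmean(x, axis=0) / 2.0
    mean = 2.0 * p
    nan_mask = np.isnan(x)
    x[nan_mask] = np.take(mean, np.where(nan_mask)[1])
    scale = np.sqrt(2.0 * p * (1.0 - p))
    nonzero = scale > 0
    if not nonzero.all():
        warnings.warn(
            f"excluding {int((~nonzero).sum())} zero-variance SNP(s) from PCA",
            stacklevel=2,
        )
    z = (x[:, nonzero] - mean[nonzero]) / scale[nonzero]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    # sign convention: largest-|loading| entry of each right singular vector positive
    for comp in range(k):
        j = np.argmax(np.abs(vt[comp]))
        if vt[comp, j] < 0:
            vt[comp] *= -1
            u[:, comp] *= -1
    scores = u[:, :k] * s[:k]
    eigenvalues = (s[:k] ** 2) / (n - 1)
    table = pd.DataFrame(
        scores, columns=[f"PC{i + 1}" for i in range(k)]
    )
    table.insert(0, "patient_id", genotypes.sample_ids)
    return table, eigenvalues
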