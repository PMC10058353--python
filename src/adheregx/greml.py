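"""GREML heritability of a binary trait: GRM, relatedness pruning, AI-REML.

The genomic relatedness matrix uses the standard standardized-cross-product
estimator with sample allele frequencies,

    A_jk = (1/m) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),

with the usual within-individual diagonal estimator and per-pair SNP counts
when genotypes are missing.  Pairs above a relatedness cutoff (0.025 for
nominally unrelated cohorts) are pruned greedily.  Variance components of
``y = X b + g + e`` with ``g ~ (0, A vg)``, ``e ~ (0, I ve)`` are estimated
by average-information REML with EM warm-up steps, components constrained
non-negative; the trait is analyzed as 0/1, so vg/vp is the observed-scale
heritability (a liability-scale transformation is provided separately).
Standard errors come from the inverse AI matrix (delta method for h^2) and
the test of vg = 0 from a 50:50 chi-square(0)/chi-square(1) mixture LRT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from adheregx.genotypes import GenotypeDataset

logger = logging.getLogger(__name__)


# ------------------------------------------------------------------- GRM

@dataclass
class GRM:
    """Genomic relatedness matrix with per-pair usable-SNP counts."""

    matrix: np.ndarray
    sample_ids: list[str]
    m_snps: np.ndarray

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def compute_grm(genotypes: GenotypeDataset) -> GRM:
    """GRM from additive dosages (sample-frequency standardization).

    Monomorphic SNPs are excluded (count logged).  Missing genotypes are
    skipped, each pair averaging over the SNPs both members carry.
    """
    if genotypes.n_samples < 2:
        raise ValueError("GRM needs at least 2 samples")
    x = genotypes.dosages
    p = np.nanmean(x, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("compute_grm: excluding %d monomorphic SNP(s)", n_mono)
    if not poly.any():
        raise ValueError("no polymorphic SNPs available for the GRM")
    x = x[:, poly]
    p = p[poly]
    denom = 2.0 * p * (1.0 - p)

    present = ~np.isnan(x)
    z = np.where(present, (np.nan_to_num(x) - 2.0 * p) / np.sqrt(denom), 0.0)
    pair_m = present.astype(float) @ present.astype(float).T
    a = (z @ z.T) / np.maximum(pair_m, 1.0)

    # diagonal: within-individual estimator 1 + [x^2 - (1+2p)x + 2p^2] / (2p(1-p))
    diag_terms = np.where(
        present,
        (x**2 - (1.0 + 2.0 * p) * x + 2.0 * p**2) / denom,
        0.0,
    )
    m_ind = present.sum(axis=1).astype(float)
    np.fill_diagonal(a, 1.0 + diag_terms.sum(axis=1) / np.maximum(m_ind, 1.0))
    return GRM(matrix=a, sample_ids=list(genotypes.sample_ids),
               m_snps=pair_m.astype(int))


def suggest_prune_cutoff(grm: GRM, n_sd: float = 4.0,
                         floor: float = 0.025) -> float:
    """Relatedness cutoff adapted to the panel's estimation noise.

    The conventional 0.025 cutoff presumes genome-wide marker counts, where
    the sampling noise of an unrelated pair's relatedness (sd roughly
    1/sqrt(m_effective), inflated by LD) is far below it.  On small panels
    that noise dominates, and a flat 0.025 would prune most of an unrelated
    cohort.  This returns ``max(floor, n_sd * sd(off-diagonals))`` — the floor
    when the panel is dense enough, a noise-respecting threshold otherwise.
    """
    off = grm.matrix[np.triu_indices(grm.n, k=1)]
    return float(max(floor, n_sd * off.std()))


def prune_related(grm: GRM, cutoff: float = 0.025) -> list[str]:
    """Greedy pruning of related pairs; returns retained sample ids.

    While any off-diagonal exceeds ``cutoff``, the sample involved in the most
    offending pairs is removed (ties broken by sample order), so the retained
    set has no pair above the cutoff and is deterministic.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    a = grm.matrix.copy()
    np.fill_diagonal(a, 0.0)
    active = np.ones(grm.n, dtype=bool)
    while True:
        over = (np.abs(a) > cutoff) & active[:, None] & active[None, :]
        degree = over.sum(axis=1)
        if degree.max(initial=0) == 0:
            break
        active[int(np.argmax(degree))] = False
    return [sid for sid, keep in zip(grm.sample_ids, active) if keep]


# ------------------------------------------------------------------- REML

@dataclass
class VarianceComponents:
    """REML variance components of the observed-scale binary trait."""

    vg: float
    ve: float
    se_vg: float
    se_ve: float
    se_h2: float
    lrt: float
    lrt_p: float
    loglik: float
    loglik_null: float
    n_iterations: int
    converged: bool
    n_samples: int

    @property
    def vp(self) -> float:
        return self.vg + self.ve

    @property
    def h2(self) -> float:
        return self.vg / self.vp if self.vp > 0 else np.nan

    def to_frame(self) -> pd.DataFrame:
        """Variance-component table (one row per quantity, value + SE)."""
        rows = [
            ("V(G)", self.vg, self.se_vg),
            ("V(e)", self.ve, self.se_ve),
            ("Vp", self.vp, np.nan),
            ("V(G)/Vp", self.h2, self.se_h2),
            ("LRT_p", self.lrt_p, np.nan),
        ]
        return pd.DataFrame(rows, columns=["component", "value", "se"])


def _reml_loglik(theta: np.ndarray, d: np.ndarray, yt: np.ndarray,
                 xt: np.ndarray) -> tuple[float, np.ndarray]:
    """Restricted log-likelihood in the GRM eigenbasis (constants dropped).

    ``d`` are GRM eigenvalues; V is diagonal there with entries
    ``vg d + ve``.  Returns the log-likelihood and the vector P y needed by
    the derivative computations.
    """
    vg, ve = theta
    dv = vg * d + ve
    if np.any(dv <= 0):
        return -np.inf, np.zeros_like(yt)
    inv = 1.0 / dv
    xtvx = xt.T @ (xt * inv[:, None])
    sign, logdet_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return -np.inf, np.zeros_like(yt)
    beta = np.linalg.solve(xtvx, xt.T @ (yt * inv))
    resid = yt - xt @ beta
    py = resid * inv
    ll = -0.5 * (np.log(dv).sum() + logdet_x + float(yt @ py))
    return ll, py


def _trace_p(a_diag: np.ndarray, d: np.ndarray, theta: np.ndarray,
             xt: np.ndarray) -> float:
    """tr(P A_i) where A_i is diagonal ``a_diag`` in the eigenbasis."""
    vg, ve = theta
    inv = 1.0 / (vg * d + ve)
    xtvx = xt.T @ (xt * inv[:, None])
    xtvx_inv = np.linalg.inv(xtvx)
    # tr(V^-1 A) - tr[(X'V^-1X)^-1 X'V^-1 A V^-1 X]
    w = xt * inv[:, None]
    return float((inv * a_diag).sum()
                 - np.trace(xtvx_inv @ (w.T @ (w * a_diag[:, None]))))


def reml_fit(
    grm: GRM,
    phenotype: pd.Series,
    covariates: pd.DataFrame | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    n_em: int = 4,
) -> VarianceComponents:
    """AI-REML fit of the single-GRM variance-component model.

    The phenotype (0/1) is analyzed on the observed scale.  Four EM warm-up
    iterations precede average-information steps; an AI step is accepted only
    when the restricted likelihood improves (step-halving otherwise, EM as a
    fallback).  Components are clamped at 1e-8 of the phenotypic variance.
    Convergence: |change in log-likelihood| < ``tol``.
    """
    y = phenotype.reindex(grm.sample_ids).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("phenotype missing for some GRM samples")
    n = len(y)
    if covariates is not None:
        cov = (
            covariates.set_index("patient_id")
            .reindex(grm.sample_ids)
            .reset_index(drop=True)
        )
        if "sex" in cov.columns and cov["sex"].dtype == object:
            cov["sex"] = (cov["sex"] == "M").astype(float)
        x = np.column_stack([np.ones(n), cov.to_numpy(dtype=float)])
    else:
        x = np.ones((n, 1))
    n_fixed = x.shape[1]

    d, u = np.linalg.eigh(grm.matrix)
    if d.max() - d.min() < 1e-10:
        raise ValueError(
            "GRM is (a multiple of) the identity; vg and ve are not "
            "separately identifiable"
        )
    yt, xt = u.T @ y, u.T @ x
    vp0 = float(np.var(y, ddof=1))
    floor = 1e-8 * vp0
    theta = np.array([vp0 / 2.0, vp0 / 2.0])
    a_diags = (d, np.ones_like(d))  # eigenbasis diagonals of A and I

    ll, py = _reml_loglik(theta, d, yt, xt)
    n_iter = 0
    converged = False
    for it in range(max_iter):
        n_iter = it + 1
        apy = (d * py, py)  # A_i P y in eigenbasis
        grad = np.array([
            -0.5 * (_trace_p(a_diags[i], d, theta, xt) - float(py @ apy[i]))
            for i in range(2)
        ])
        if it < n_em:
            # EM-REML step: theta_i += theta_i^2 / n * (y'PA_iPy - tr(PA_i))
            new_theta = theta.copy()
            for i in range(2):
                t_i = float(py @ (a_diags[i] * py))
                tr_i = _trace_p(a_diags[i], d, theta, xt)
                new_theta[i] = theta[i] + (theta[i] ** 2 / n) * (t_i - tr_i)
        else:
            # average-information matrix: AI_ij = 0.5 y'P A_i P A_j P y
            pap = [None, None]
            for i in range(2):
                # P (A_i P y) computed via the projection identity
                vg, ve = theta
                inv = 1.0 / (vg * d + ve)
                xtvx = xt.T @ (xt * inv[:, None])
                z = apy[i]
                beta_z = np.linalg.solve(xtvx, xt.T @ (z * inv))
                pap[i] = (z - xt @ beta_z) * inv
            ai = 0.5 * np.array(
                [[float(apy[i] @ pap[j]) for j in range(2)] for i in range(2)]
            )
            try:
                step = np.linalg.solve(ai, grad)
            except np.linalg.LinAlgError:
                step = grad * (vp0 / n)
            new_theta = theta + step

        new_theta = np.clip(new_theta, floor, None)
        new_ll, new_py = _reml_loglik(new_theta, d, yt, xt)
        # step-halving until the likelihood does not decrease
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 20:
            new_theta = np.clip(theta + 0.5 * (new_theta - theta), floor, None)
            new_ll, new_py = _reml_loglik(new_theta, d, yt, xt)
            halvings += 1
        if new_ll < ll - 1e-12:
            new_theta, new_ll, new_py = theta, ll, py
        delta_ll = abs(new_ll - ll)
        theta, ll, py = new_theta, new_ll, new_py
        if it >= n_em and delta_ll < tol:
            converged = True
            break
    if not converged:
        logger.warning("reml_fit: not converged in %d iterations", max_iter)

    # SEs from the inverse AI matrix at the optimum
    apy = (d * py, py)
    vg, ve = theta
    inv = 1.0 / (vg * d + ve)
    xtvx = xt.T @ (xt * inv[:, None])
    pap = []
    for i in range(2):
        z = apy[i]
        beta_z = np.linalg.solve(xtvx, xt.T @ (z * inv))
        pap.append((z - xt @ beta_z) * inv)
    ai = 0.5 * np.array(
        [[float(apy[i] @ pap[j]) for j in range(2)] for i in range(2)]
    )
    try:
        cov_theta = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        cov_theta = np.full((2, 2), np.nan)
    se_vg, se_ve = np.sqrt(np.abs(np.diag(cov_theta)))
    vp = theta.sum()
    grad_h2 = np.array([theta[1], -theta[0]]) / vp**2
    se_h2 = float(np.sqrt(abs(grad_h2 @ cov_theta @ grad_h2)))

    # null model (vg = 0): ve has the closed-form REML estimate RSS/(n - k)
    q, _ = np.linalg.qr(x)
    resid0 = y - q @ (q.T @ y)
    ve0 = float(resid0 @ resid0) / (n - n_fixed)
    ll0 = _null_loglik(ve0, yt, xt, d)
    lrt = max(0.0, 2.0 * (ll - ll0))
    lrt_p = 0.5 * float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 0.5

    return VarianceComponents(
        vg=float(theta[0]), ve=float(theta[1]),
        se_vg=float(se_vg), se_ve=float(se_ve), se_h2=se_h2,
        lrt=lrt, lrt_p=lrt_p, loglik=ll, loglik_null=ll0,
        n_iterations=n_iter, converged=converged, n_samples=n,
    )


def _null_loglik(ve: float, yt: np.ndarray, xt: np.ndarray,
                 d: np.ndarray) -> float:
    """Restricted log-likelihood at vg=0 (V = ve I), same constant convention."""
    ll, _ = _reml_loglik(np.array([0.0, ve]), d, yt, xt)
    return ll


# ---------------------------------------------------------- scale transforms

def observed_to_liability_h2(h2_obs: float, prevalence: float) -> float:
    """Dempster-Lerner/Robertson transformation of observed-scale h^2.

    h2_liab = h2_obs * K(1-K) / phi(t)^2 with threshold t = Phi^-1(1-K).
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    t = stats.norm.isf(prevalence)
    z = stats.norm.pdf(t)
    return h2_obs * prevalence * (1.0 - prevalence) / z**2


def liability_to_observed_h2(h2_liab: float, prevalence: float) -> float:
    """Inverse of :func:`observed_to_liability_h2`."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    t = stats.norm.isf(prevalence)
    z = stats.norm.pdf(t)
    return h2_liab * z**2 / (prevalence * (1.0 - prevalence))
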