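"""Analytic power of a case-control single-SNP association test.

Expected case and control allele frequencies are derived from a
multiplicative (per-allele) genotype relative risk model under
Hardy-Weinberg genotype frequencies, conditioned on the disease prevalence;
power is then that of the two-sided two-proportion test on allele counts:

    power = Phi(|p1 - p2| / SE - z_{1-a/2}) + Phi(-|p1 - p2| / SE - z_{1-a/2})

so a null effect (GRR = 1) yields power exactly alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

_VARIABLE_FIELDS = ("n_cases", "n_controls", "prevalence", "maf", "grr", "alpha")


@dataclass(frozen=True)
class PowerSpec:
    """Design of a case-control association test (additive risk model)."""

    n_cases: int
    n_controls: int
    prevalence: float
    maf: float
    grr: float
    alpha: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if not 0.0 < self.maf < 1.0:
            raise ValueError("maf must be in (0, 1)")
        if self.grr <= 0:
            raise ValueError("grr must be positive")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")


def case_control_allele_freqs(spec: PowerSpec) -> tuple[float, float]:
    """Risk-allele frequency in cases and controls under the model.

    Genotype penetrances are proportional to (1, r, r^2) and scaled so the
    population prevalence matches; an error is raised if the implied
    homozygote penetrance exceeds 1.
    """
    p, r, k = spec.maf, spec.grr, spec.prevalence
    f = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    rel = np.array([1.0, r, r**2])
    baseline = k / float(f @ rel)
    pen = baseline * rel
    if pen.max() > 1.0 + 1e-12:
        raise ValueError(
            f"grr {r} with prevalence {k} implies penetrance {pen.max():.4g} > 1"
        )
    allele_dose = np.array([0.0, 0.5, 1.0])
    p_case = float((allele_dose * f * pen).sum() / k)
    p_ctrl = float((allele_dose * f * (1.0 - pen)).sum() / (1.0 - k))
    return p_case, p_ctrl


def gwas_power(spec: PowerSpec) -> float:
    """Two-sided power of the allele-count test at the spec's alpha."""
    if spec.alpha == 1.0:
        return 1.0
    p1, p2 = case_control_allele_freqs(spec)
    n1, n2 = 2 * spec.n_cases, 2 * spec.n_controls  # allele counts
    se = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    z_crit = stats.norm.isf(spec.alpha / 2.0)
    delta = abs(p1 - p2) / se if se > 0 else 0.0
    return float(stats.norm.cdf(delta - z_crit) + stats.norm.cdf(-delta - z_crit))


def power_curve(spec: PowerSpec, vary: str, grid) -> pd.DataFrame:
    """Evaluate power along a grid of one design parameter."""
    if vary not in _VARIABLE_FIELDS:
        raise ValueError(f"unknown parameter {vary!r}; expected one of {_VARIABLE_FIELDS}")
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    rows = []
    for value in grid:
        if vary in ("n_cases", "n_controls"):
            value = int(value)
        rows.append({vary: value, "power": gwas_power(replace(spec, **{vary: value}))})
    return pd.DataFrame(rows)


def effect_for_power(target_power: float, spec: PowerSpec,
                     direction: str = "risk",
                     grr_limit: float = 20.0) -> float:
    """GRR achieving a target power for the rest of the design.

    Solves ``gwas_power(grr) = target_power`` by bisection, moving away from
    the null (GRR = 1) toward larger GRR (``direction="risk"``) or smaller
    GRR (``direction="protective"``); use it to back out what effect size a
    reported power figure implies.  The multiplicative model caps the
    reachable GRR where a genotype penetrance would exceed 1 — at high
    prevalence the risk direction saturates quickly, while protective
    effects have more room.
    """
    if not 0.0 < target_power < 1.0:
        raise ValueError("target_power must be in (0, 1)")
    if direction not in ("risk", "protective"):
        raise ValueError(f"unknown direction {direction!r}")

    def gap(r: float) -> float:
        return gwas_power(replace(spec, grr=r)) - target_power

    near_null = 1.0 + 1e-9 if direction == "risk" else 1.0 - 1e-9
    if gap(near_null) > 0:
        raise ValueError("target power below the null level alpha")
    # walk the far bound inside the feasible region (penetrance <= 1)
    far = grr_limit if direction == "risk" else 1.0 / grr_limit
    shrink = 0.95 if direction == "risk" else 1.0 / 0.95
    while abs(far - 1.0) > 1e-9:
        try:
            gap_far = gap(far)
            break
        except ValueError:
            far *= shrink
    else:
        raise ValueError("no feasible grr under the penetrance constraint")
    if gap_far < 0:
        raise ValueError(
            f"target power unreachable in the {direction} direction "
            f"(maximum attainable {gap_far + target_power:.3f})"
        )
    lo, hi = (near_null, far) if direction == "risk" else (far, near_null)
    return float(brentq(gap, lo, hi, xtol=1e-10))
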