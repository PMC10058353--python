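"""Logistic association scan: Wald inference, permutation, LD proxies."""

import numpy as np
import pandas as pd
import pytest

from adheregx.assoc import (
    ScanConfig,
    bonferroni,
    fit_snp,
    ld_proxy_interval,
    permute_scan,
    scan,
)
from adheregx.cohort import CohortSpec, simulate_genotypes, simulate_phenotype
from tests.conftest import make_genotypes


def newton_logistic_oracle(x, y, tol=1e-12):
    """From-scratch Newton-Raphson MLE for logit(y) ~ 1 + x."""
    beta = np.zeros(2)
    design = np.column_stack([np.ones_like(x), x])
    for _ in range(200):
        p = 1.0 / (1.0 + np.exp(-design @ beta))
        grad = design.T @ (y - p)
        hess = design.T @ (design * (p * (1 - p))[:, None])
        step = np.linalg.solve(hess, grad)
        beta += step
        if np.abs(step).max() < tol:
            break
    return beta[1]


def table_to_vectors(case_counts, control_counts):
    """Expand a genotype-by-status 2x3 table into dosage/label vectors."""
    dosage, labels = [], []
    for g, (nc, nk) in enumerate(zip(case_counts, control_counts)):
        dosage += [g] * (nc + nk)
        labels += [1] * nc + [0] * nk
    return np.array(dosage, float), np.array(labels, float)


class TestFitSnp:
    def test_matches_newton_oracle_on_2x3_table(self):
        dosage, labels = table_to_vectors((10, 20, 30), (30, 20, 10))
        res = fit_snp(dosage, labels)
        want = newton_logistic_oracle(dosage, labels)
        assert res.beta == pytest.approx(want, abs=1e-6)

    def test_or_ci_internal_consistency(self):
        rng = np.random.default_rng(1)
        dosage = rng.binomial(2, 0.3, size=500).astype(float)
        labels = rng.binomial(1, 0.4, size=500).astype(float)
        res = fit_snp(dosage, labels)
        assert res.or_ == pytest.approx(np.exp(res.beta))
        assert res.ci95 == (
            pytest.approx(np.exp(res.beta - 1.96 * res.se)),
            pytest.approx(np.exp(res.beta + 1.96 * res.se)),
        )
        # the geometric mean of the CI bounds is the OR
        assert np.sqrt(res.ci95[0] * res.ci95[1]) == pytest.approx(res.or_)

    def test_orientation_flip_inverts_or(self):
        dosage, labels = table_to_vectors((10, 20, 30), (30, 20, 10))
        a = fit_snp(dosage, labels)
        b = fit_snp(2.0 - dosage, labels)
        assert b.beta == pytest.approx(-a.beta, abs=1e-8)
        assert b.or_ == pytest.approx(1.0 / a.or_, rel=1e-8)

    def test_null_snp_beta_small(self):
        rng = np.random.default_rng(2)
        n = 5000
        dosage = rng.binomial(2, 0.3, size=n).astype(float)
        labels = rng.binomial(1, 0.5, size=n).astype(float)
        res = fit_snp(dosage, labels)
        assert abs(res.beta) < 4 * res.se

    def test_separation_flagged(self):
        dosage = np.r_[np.zeros(20), np.full(20, 2.0)]
        labels = np.r_[np.zeros(20), np.ones(20)]
        res = fit_snp(dosage, labels)
        assert res.separation

    def test_single_class_error(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_snp(np.array([0.0, 1.0, 2.0]), np.ones(3))

    def test_missing_dropped(self):
        dosage, labels = table_to_vectors((10, 20, 30), (30, 20, 10))
        res_full = fit_snp(dosage, labels)
        dosage2 = np.r_[dosage, np.nan]
        labels2 = np.r_[labels, 1.0]
        res = fit_snp(dosage2, labels2)
        assert res.n_used == len(dosage)
        assert res.beta == pytest.approx(res_full.beta)


class TestScan:
    def test_empty_panel(self):
        g = make_genotypes(np.empty((6, 0)))
        y = pd.Series([0, 1, 0, 1, 0, 1],
                      index=pd.Index(g.sample_ids, name="patient_id"))
        out = scan(g, y, None, ScanConfig(covariates=()))
        assert len(out) == 0

    def test_sorted_with_nominal_flag(self, small_panel):
        rng = np.random.default_rng(3)
        y = pd.Series(rng.binomial(1, 0.5, small_panel.n_samples),
                      index=pd.Index(small_panel.sample_ids, name="patient_id"))
        out = scan(small_panel, y, None,
                   ScanConfig(covariates=(), nominal_threshold=1e-6))
        assert (np.diff(out["p_wald"].to_numpy()) >= -1e-15).all()
        assert out["below_nominal"].equals(out["p_wald"] < 1e-6)
        assert (out["p_bonferroni"] ==
                np.minimum(1.0, out["p_wald"] * small_panel.n_snps)).all()

    def test_planted_signal_detected(self):
        spec = CohortSpec(n_patients=2000, n_snps=60, n_causal=1, target_h2=0.35,
                          adherent_fraction=0.5, ld_block_size=1, seed=17,
                          maf_range=(0.2, 0.4))
        genotypes, truth = simulate_genotypes(spec)
        labels = simulate_phenotype(genotypes, truth, spec)
        out = scan(genotypes, labels, None, ScanConfig(covariates=()))
        assert out["p_wald"].iloc[0] < 1e-6
        assert out["snp_id"].iloc[0] == truth["snp_id"].iloc[0]

    def test_collinear_covariates_error(self, small_panel):
        rng = np.random.default_rng(4)
        n = small_panel.n_samples
        age = rng.uniform(40, 90, n)
        covar = pd.DataFrame(
            {"patient_id": small_panel.sample_ids, "age": age,
             "age2": age * 2.0}
        )
        y = pd.Series(rng.binomial(1, 0.5, n),
                      index=pd.Index(small_panel.sample_ids, name="patient_id"))
        with pytest.raises(ValueError, match="collinear"):
            scan(small_panel, y, covar,
                 ScanConfig(covariates=("age", "age2")))

    def test_orthogonalized_extra_covariate_is_inert(self):
        # a column made W-orthogonal to the design and orthogonal to the
        # residual leaves the MLE untouched
        rng = np.random.default_rng(5)
        n = 400
        dosage = rng.binomial(2, 0.3, n).astype(float)
        age = rng.uniform(40, 90, n)
        labels = rng.binomial(
            1, 1 / (1 + np.exp(-(-0.5 + 0.3 * dosage + 0.01 * age)))
        ).astype(float)
        covar = pd.DataFrame({"age": age})
        base = fit_snp(dosage, labels, covar)
        design = np.column_stack([np.ones(n), age, dosage])
        p = 1.0 / (1.0 + np.exp(-design @ np.linalg.lstsq(
            design, np.log((labels.mean()) / (1 - labels.mean())) * np.ones(n),
            rcond=None)[0]))
        # refit properly to get the MLE probabilities
        import statsmodels.api as sm
        fit = sm.GLM(labels, design, family=sm.families.Binomial()).fit()
        p = fit.fittedvalues
        w = p * (1 - p)
        z0 = rng.normal(size=n)
        basis = np.column_stack([design * w[:, None], labels - p])
        z = z0 - basis @ np.linalg.lstsq(basis, z0, rcond=None)[0]
        covar2 = pd.DataFrame({"age": age, "extra": z})
        augmented = fit_snp(dosage, labels, covar2)
        assert augmented.beta == pytest.approx(base.beta, abs=1e-6)


@pytest.fixture(scope="module")
def null_data():
    spec = CohortSpec(n_patients=300, n_snps=30, n_causal=0,
                      ld_block_size=1, adherent_fraction=0.5, seed=23)
    genotypes, truth = simulate_genotypes(spec)
    labels = simulate_phenotype(genotypes, truth, spec)
    return genotypes, labels


class TestPermutation:
    def test_deterministic_given_seed(self, null_data):
        genotypes, labels = null_data
        cfg = ScanConfig(covariates=(), n_permutations=100, seed=9)
        a = permute_scan(genotypes, labels, None, cfg)
        b = permute_scan(genotypes, labels, None, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_extreme_statistic_floor(self):
        # dosage tracking the labels perfectly: observed beats every permutation
        rng = np.random.default_rng(11)
        labels_arr = np.r_[np.zeros(40), np.ones(40)]
        dosage = 2.0 * labels_arr
        noise = rng.binomial(2, 0.5, 80).astype(float)
        g = make_genotypes(np.column_stack([dosage, noise]))
        y = pd.Series(labels_arr.astype(int),
                      index=pd.Index(g.sample_ids, name="patient_id"))
        cfg = ScanConfig(covariates=(), n_permutations=99, seed=1)
        out = permute_scan(g, y, None, cfg)
        assert out.loc[out["snp_id"] == "s1", "p_perm"].iloc[0] == 1 / 100

    def test_constant_labels_error(self, null_data):
        genotypes, _ = null_data
        y = pd.Series(np.ones(genotypes.n_samples, int),
                      index=pd.Index(genotypes.sample_ids, name="patient_id"))
        with pytest.raises(ValueError, match="constant"):
            permute_scan(genotypes, y, None,
                         ScanConfig(covariates=(), n_permutations=10))

    def test_null_agrees_with_wald(self):
        spec = CohortSpec(n_patients=2000, n_snps=5, n_causal=0,
                          ld_block_size=1, adherent_fraction=0.5, seed=29)
        genotypes, truth = simulate_genotypes(spec)
        labels = simulate_phenotype(genotypes, truth, spec)
        asym = scan(genotypes, labels, None, ScanConfig(covariates=()))
        perm = permute_scan(genotypes, labels, None,
                            ScanConfig(covariates=(), n_permutations=1000, seed=2))
        merged = asym.drop(columns=["p_perm", "p_fwer"]).merge(perm, on="snp_id")
        assert (merged["p_perm"] - merged["p_wald"]).abs().max() < 0.05

    def test_fwer_at_least_pointwise(self, null_data):
        genotypes, labels = null_data
        out = permute_scan(genotypes, labels, None,
                           ScanConfig(covariates=(), n_permutations=200, seed=3))
        assert (out["p_fwer"] >= out["p_perm"] - 1e-12).all()


class TestBonferroni:
    @pytest.mark.parametrize(
        "p, m, want",
        [
            (3.46e-5, 9, 3.11e-4),  # nine coding variants, PDC80 screen
            (4.72e-4, 4, 1.89e-3),  # four coding variants, MPR80 screen
        ],
    )
    def test_coding_subset_corrections(self, p, m, want):
        assert bonferroni(p, m) == pytest.approx(want, rel=5e-3)

    def test_cap_at_one(self):
        assert bonferroni(0.5, 9) == 1.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bonferroni(1.5, 10)
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)


class TestLDProxy:
    def test_no_proxy_degenerate_interval(self):
        rng = np.random.default_rng(7)
        d = rng.binomial(2, 0.3, size=(200, 3)).astype(float)
        g = make_genotypes(d, positions=[10_000, 50_000, 90_000])
        chrom, lo, hi = ld_proxy_interval("s2", g, r2_min=0.99)
        assert (lo, hi) == (50_000, 50_000)

    def test_perfect_ld_duplicate_spans_both(self):
        rng = np.random.default_rng(8)
        x = rng.binomial(2, 0.3, 200).astype(float)
        other = rng.binomial(2, 0.3, 200).astype(float)
        g = make_genotypes(np.column_stack([x, other, x]),
                           positions=[100_000, 120_000, 150_000])
        chrom, lo, hi = ld_proxy_interval("s1", g, r2_min=0.5)
        assert (lo, hi) == (100_000, 150_000)

    def test_flank_respected(self):
        x = np.tile([0.0, 1.0, 2.0], 67)[:200]
        g = make_genotypes(np.column_stack([x, x]),
                           positions=[100_000, 250_000])
        chrom, lo, hi = ld_proxy_interval("s1", g, r2_min=0.5, flank_bp=100_000)
        assert (lo, hi) == (100_000, 100_000)  # the copy sits outside the flank

    def test_monomorphic_index_error(self):
        g = make_genotypes(np.zeros((50, 2)), positions=[1000, 2000])
        with pytest.raises(ValueError, match="monomorphic"):
            ld_proxy_interval("s1", g)

    def test_width_nonincreasing_in_r2(self):
        spec = CohortSpec(n_patients=300, n_snps=40, ld_block_size=40,
                          ld_copy_prob=0.97, n_causal=0, seed=31)
        genotypes, _ = simulate_genotypes(spec)
        index = genotypes.snp_ids[0]
        widths = []
        for r2 in (0.2, 0.5, 0.8):
            _, lo, hi = ld_proxy_interval(index, genotypes, r2_min=r2,
                                          flank_bp=10**9)
            widths.append(hi - lo)
        assert widths[0] >= widths[1] >= widths[2]
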