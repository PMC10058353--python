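"""Synthetic cohort generator: validation, planted structure, determinism, I/O."""

import filecmp

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adheregx import adherence as adh
from adheregx import io as agio
from adheregx.cohort import (
    CohortSpec,
    RefillGapModel,
    genetic_liability,
    simulate_cohort,
    simulate_dispensing,
    simulate_genotypes,
    simulate_phenotype,
    write_fixtures,
)


@pytest.mark.parametrize(
    "kwargs, field",
    [
        ({"maf_range": (0.0, 0.5)}, "maf_range"),
        ({"maf_range": (0.05, 0.6)}, "maf_range"),
        ({"n_causal": 50, "n_snps": 10}, "n_causal"),
        ({"window_days": 0}, "window_days"),
        ({"adherent_fraction": 1.2}, "adherent_fraction"),
        ({"target_h2": -0.1}, "target_h2"),
    ],
)
def test_spec_validation_names_field(kwargs, field):
    with pytest.raises(ValueError, match=field):
        CohortSpec(**kwargs)


class TestDispensing:
    def test_perfect_tiling_when_noiseless(self):
        gm = RefillGapModel(adherent_gap_sd_frac=0.0)
        spec = CohortSpec(n_patients=20, adherent_fraction=1.0,
                          refill_gap_model=gm, seed=1, n_snps=10, n_causal=0)
        records, truth = simulate_dispensing(spec)
        assert not truth["archetype_nonadherent"].any()
        phen = adh.compute_phenotypes(records, adh.ObservationWindow(0, 365))
        assert (phen["pdc"] == 1.0).all()

    def test_empty_cohort(self):
        spec = CohortSpec(n_patients=0, n_snps=10, n_causal=0, seed=1)
        records, truth = simulate_dispensing(spec)
        assert len(records) == 0 and len(truth) == 0

    def test_every_patient_fills_at_least_once(self):
        spec = CohortSpec(n_patients=50, seed=3, n_snps=10, n_causal=0)
        records, _ = simulate_dispensing(spec)
        assert records.groupby("patient_id").size().min() >= 1
        assert set(records["patient_id"]) == set(spec.patient_ids)

    def test_archetype_prevalence_within_binomial_ci(self):
        # configured 33% adherent -> PDC80 non-adherence should land inside the
        # binomial 95% interval around 0.67 at n=230
        spec = CohortSpec(n_patients=230, adherent_fraction=0.33, seed=11,
                          n_snps=10, n_causal=0)
        records, _ = simulate_dispensing(spec)
        phen = adh.compute_phenotypes(records, adh.ObservationWindow(0, 365))
        prev = phen["nonadherent_pdc80"].mean()
        half = 1.96 * np.sqrt(0.67 * 0.33 / 230)
        assert abs(prev - 0.67) < half


class TestGenotypes:
    def test_sample_maf_tracks_drawn_maf(self):
        spec = CohortSpec(n_patients=300, n_snps=1000, ld_block_size=1,
                          n_causal=0, seed=5)
        genotypes, _ = simulate_genotypes(spec)
        drawn = spec.rng("genotypes").uniform(*spec.maf_range, size=spec.n_snps)
        observed = genotypes.allele_freq()
        dev = np.abs(observed - drawn)
        # binomial sampling at 2n draws: E|p_hat - p| = sqrt(2 p(1-p) / (pi 2n))
        expected = np.sqrt(2 * drawn * (1 - drawn) / (np.pi * 2 * spec.n_patients))
        assert 0.5 < dev.mean() / expected.mean() < 2.0

    def test_no_ld_limit(self):
        spec = CohortSpec(n_patients=400, n_snps=200, ld_block_size=1,
                          n_causal=0, seed=6)
        genotypes, _ = simulate_genotypes(spec)
        d = genotypes.dosages
        r = np.corrcoef(d.T)
        off = r[np.triu_indices_from(r, k=1)] ** 2
        # independent SNPs: E[r^2] ~ 1/n
        assert off.mean() < 3.0 / spec.n_patients

    def test_ld_blocks_correlated(self):
        spec = CohortSpec(n_patients=400, n_snps=200, ld_block_size=5,
                          ld_copy_prob=0.9, n_causal=0, seed=6)
        genotypes, _ = simulate_genotypes(spec)
        d = genotypes.dosages
        within = [
            np.corrcoef(d[:, j], d[:, j + 1])[0, 1] ** 2
            for j in range(0, 195)
            if (j % 5) != 4  # adjacent pair inside one block
        ]
        assert np.mean(within) > 0.5

    def test_hardy_weinberg_goodness_of_fit(self):
        spec = CohortSpec(n_patients=500, n_snps=1000, ld_block_size=1,
                          n_causal=0, seed=8)
        genotypes, _ = simulate_genotypes(spec)
        d = genotypes.dosages
        n = spec.n_patients
        rejected = 0
        for j in range(spec.n_snps):
            col = d[:, j]
            p = col.mean() / 2.0
            if p in (0.0, 1.0):
                continue
            obs = np.array([(col == k).sum() for k in (0, 1, 2)])
            exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
            chi2 = ((obs - exp) ** 2 / np.maximum(exp, 1e-12)).sum()
            # 1 df: genotype freqs constrained by the estimated allele freq
            if stats.chi2.sf(chi2, df=1) < 0.001:
                rejected += 1
        assert rejected <= 0.01 * spec.n_snps

    def test_two_subpops_separate_on_pc1(self):
        from adheregx.qc import compute_pcs

        for seed in (1, 2, 3):
            spec = CohortSpec(n_patients=200, n_snps=2000, n_subpops=2, fst=0.1,
                              ld_block_size=1, n_causal=0, seed=seed)
            genotypes, _ = simulate_genotypes(spec)
            pcs, _ = compute_pcs(genotypes, k=2)
            half = spec.n_patients // 2
            membership = np.r_[np.zeros(half), np.ones(spec.n_patients - half)]
            r = np.corrcoef(pcs["PC1"], membership)[0, 1]
            assert abs(r) > 0.9


class TestPhenotype:
    def test_noiseless_limit_deterministic_in_genotype(self):
        spec = CohortSpec(n_patients=200, n_snps=100, n_causal=20,
                          target_h2=1.0, adherent_fraction=0.4, seed=9)
        genotypes, truth = simulate_genotypes(spec)
        labels = simulate_phenotype(genotypes, truth, spec)
        g = genetic_liability(genotypes, truth)
        cut = np.quantile(g / g.std(), spec.adherent_fraction)
        assert np.array_equal(labels.to_numpy(), (g / g.std() > cut).astype(int))

    def test_zero_h2_labels_independent_of_genotype(self):
        spec = CohortSpec(n_patients=500, n_snps=50, n_causal=50,
                          target_h2=0.0, adherent_fraction=0.4, seed=10)
        genotypes, truth = simulate_genotypes(spec)
        labels = simulate_phenotype(genotypes, truth, spec)
        g = genetic_liability(genotypes, truth)
        r = np.corrcoef(g, labels.to_numpy())[0, 1]
        assert abs(r) < 2.5 / np.sqrt(spec.n_patients)

    def test_degenerate_prevalence_raises(self):
        spec = CohortSpec(n_patients=50, n_snps=20, n_causal=5,
                          adherent_fraction=1.0, seed=2)
        genotypes, truth = simulate_genotypes(spec)
        with pytest.raises(ValueError, match="prevalence"):
            simulate_phenotype(genotypes, truth, spec)

    def test_prevalence_matches_configuration(self):
        spec = CohortSpec(n_patients=400, n_snps=100, n_causal=20,
                          adherent_fraction=0.4, seed=12)
        genotypes, truth = simulate_genotypes(spec)
        labels = simulate_phenotype(genotypes, truth, spec)
        assert labels.mean() == pytest.approx(0.6, abs=0.01)


def test_planted_causal_snps_rank_high():
    # the largest-effect causal SNP should sit in the top decile of scan p-values
    from adheregx.assoc import ScanConfig, scan

    hits = 0
    for seed in range(5):
        spec = CohortSpec(n_patients=500, n_snps=300, n_causal=3,
                          target_h2=0.6, adherent_fraction=0.4,
                          ld_block_size=1, seed=seed)
        genotypes, truth = simulate_genotypes(spec)
        labels = simulate_phenotype(genotypes, truth, spec)
        results = scan(genotypes, labels, None, ScanConfig(covariates=()))
        top = truth.loc[truth["effect"].abs().idxmax(), "snp_id"]
        rank = results.index[results["snp_id"] == top][0]
        if rank < spec.n_snps // 10:
            hits += 1
    assert hits >= 4


class TestFixtures:
    @pytest.fixture(scope="class")
    def cohort(self):
        spec = CohortSpec(n_patients=40, n_snps=60, n_causal=10, seed=21)
        return simulate_cohort(spec)

    def test_byte_identical_across_runs(self, cohort, tmp_path):
        spec = cohort.spec
        a = tmp_path / "a"
        b = tmp_path / "b"
        write_fixtures(simulate_cohort(spec), a)
        write_fixtures(simulate_cohort(spec), b)
        for name in ("dispensing.csv", "genotypes.vcf", "dosages.tsv",
                     "covariates.tsv", "genesets.gmt", "snp_gene_map.tsv"):
            assert filecmp.cmp(a / name, b / name, shallow=False), name

    def test_round_trip(self, cohort, tmp_path):
        paths = write_fixtures(cohort, tmp_path)
        records = agio.read_dispensing_csv(paths["dispensing"])
        pd.testing.assert_frame_equal(records, cohort.records)
        dosages = agio.read_dosage_tsv(paths["dosages"])
        np.testing.assert_array_equal(dosages.dosages, cohort.genotypes.dosages)
        assert dosages.sample_ids == cohort.genotypes.sample_ids
        cov = agio.read_covariates_tsv(paths["covariates"])
        pd.testing.assert_frame_equal(cov, cohort.covariates)
        assert agio.read_gmt(paths["genesets"]) == cohort.genesets
        sg = agio.read_snp_gene_map(paths["snp_gene_map"])
        pd.testing.assert_frame_equal(
            sg, cohort.snp_gene, check_dtype=False
        )

    def test_vcf_round_trips_through_external_parser(self, cohort, tmp_path):
        # cyvcf2 is the independent reader: dosages and metadata must survive
        paths = write_fixtures(cohort, tmp_path)
        back = agio.read_vcf(paths["vcf"])
        assert back.sample_ids == cohort.genotypes.sample_ids
        order = np.argsort(back.snp_meta["snp_id"].to_numpy())
        orig_order = np.argsort(cohort.genotypes.snp_meta["snp_id"].to_numpy())
        np.testing.assert_array_equal(
            back.dosages[:, order], cohort.genotypes.dosages[:, orig_order]
        )

    def test_empty_geneset_gmt(self, tmp_path):
        path = tmp_path / "empty.gmt"
        agio.write_gmt({}, path)
        assert agio.read_gmt(path) == {}

    def test_streams_independent(self):
        spec = CohortSpec(n_patients=30, n_snps=40, n_causal=5, seed=33)
        g1, _ = simulate_genotypes(spec)
        _ = simulate_dispensing(spec)  # consuming another stream
        g2, _ = simulate_genotypes(spec)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)
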