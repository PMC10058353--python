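"""Additive-coded genotype container shared by the QC, association and GREML stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: columns every SNP metadata table must carry
SNP_META_COLUMNS = ("snp_id", "chrom", "pos", "ref", "alt")


@dataclass
class GenotypeDataset:
    """Samples x SNPs additive dosage matrix with SNP metadata.

    Parameters
    ----------
    sample_ids : list of str
        One identifier per row of ``dosages``.
    snp_meta : pandas.DataFrame
        One row per SNP with columns ``snp_id, chrom, pos, ref, alt`` (``pos``
        in basepairs).  A ``maf`` column is added/refreshed on construction.
    dosages : numpy.ndarray, shape (n_samples, n_snps)
        Minor-allele counts 0/1/2; missing genotypes are ``nan`` (dtype float).
    """

    sample_ids: list[str]
    snp_meta: pd.DataFrame = field(repr=False)
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x SNPs matrix")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"sample_ids length {len(self.sample_ids)} != dosage rows {n}"
            )
        if len(self.snp_meta) != m:
            raise ValueError(
                f"snp_meta length {len(self.snp_meta)} != dosage columns {m}"
            )
        missing_cols = [c for c in SNP_META_COLUMNS if c not in self.snp_meta.columns]
        if missing_cols:
            raise ValueError(f"snp_meta missing columns: {missing_cols}")
        valid = ~np.isnan(self.dosages)
        if not np.all((self.dosages[valid] >= 0) & (self.dosages[valid] <= 2)):
            raise ValueError("dosages must lie in {0, 1, 2} or be missing")
        self.snp_meta = self.snp_meta.reset_index(drop=True).copy()
        self.snp_meta["maf"] = self.sample_maf()

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return self.snp_meta["snp_id"].tolist()

    def allele_freq(self) -> np.ndarray:
        """Per-SNP sample frequency of the counted (minor-oriented) allele.

        All-missing SNPs get frequency nan.
        """
        present = ~np.isnan(self.dosages)
        n_called = present.sum(axis=0)
        totals = np.where(present, self.dosages, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, totals / (2.0 * n_called), np.nan)

    def sample_maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency, folding frequencies above 0.5."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def snp_missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def sample_missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def take_snps(self, mask_or_idx) -> "GenotypeDataset":
        """New dataset restricted to the given SNP boolean mask or index array."""
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeDataset(
            sample_ids=list(self.sample_ids),
            snp_meta=self.snp_meta.iloc[idx],
            dosages=self.dosages[:, idx],
        )

    def take_samples(self, mask_or_idx) -> "GenotypeDataset":
        """New dataset restricted to the given sample boolean mask or index array."""
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeDataset(
            sample_ids=[self.sample_ids[i] for i in idx],
            snp_meta=self.snp_meta,
            dosages=self.dosages[idx, :],
        )

    def dosage_for(self, snp_id: str) -> np.ndarray:
        """Dosage vector for one SNP id."""
        hits = np.flatnonzero((self.snp_meta["snp_id"] == snp_id).to_numpy())
        if hits.size == 0:
            raise KeyError(f"SNP {snp_id!r} not in dataset")
        return self.dosages[:, hits[0]]
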