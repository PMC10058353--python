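import numpy as np
import pandas as pd
import pytest

from adheregx.cohort import CohortSpec, simulate_genotypes
from adheregx.genotypes import GenotypeDataset


def make_genotypes(dosages, positions=None, chrom="1", sample_ids=None):
    """GenotypeDataset from a plain dosage array (helper for hand examples)."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    meta = pd.DataFrame(
        {
            "snp_id": [f"s{j + 1}" for j in range(m)],
            "chrom": chrom,
            "pos": positions if positions is not None else 1 + 1000 * np.arange(m),
            "ref": "A",
            "alt": "C",
        }
    )
    ids = sample_ids or [f"P{i + 1:04d}" for i in range(n)]
    return GenotypeDataset(sample_ids=ids, snp_meta=meta, dosages=dosages)


def records_frame(fills, patient_id="P0001"):
    """Dispensing frame from (fill_day, days_supply) pairs for one patient."""
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "fill_day": [d for d, _ in fills],
            "days_supply": [s for _, s in fills],
            "med_class": "prostaglandin",
        }
    )


@pytest.fixture(scope="session")
def small_panel():
    """A modest single-population panel shared by QC/assoc/GREML unit tests."""
    spec = CohortSpec(n_patients=300, n_snps=200, n_causal=0, ld_block_size=1,
                      seed=2024)
    genotypes, _truth = simulate_genotypes(spec)
    return genotypes
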