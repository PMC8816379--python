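import numpy as np
import pandas as pd
import pytest

from amniomics import BetaMatrix, CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One seeded synthetic cohort with planted effects (shared, read-only)."""
    config = CohortConfig(seed=7, n_probes=600, n_genes=150)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def null_cohort():
    """Zero-effect cohort: nothing planted anywhere."""
    config = CohortConfig(
        seed=11, n_probes=400, n_genes=100,
        frac_differential_probes=0.0, frac_differential_genes=0.0,
    )
    return generate_cohort(config)


def make_beta(diffs_by_probe, n_pairs, zone="ZAM", base=0.5):
    """Hand-built paired BetaMatrix from per-probe per-patient differences.

    ``diffs_by_probe`` maps probe id -> list of n_pairs differences
    (amnion - choriodecidua); amnion = base + d/2, choriodecidua = base - d/2.
    """
    records, cols = [], {}
    patients = [f"p{i}" for i in range(n_pairs)]
    for patient in patients:
        for tissue in ("amnion", "choriodecidua"):
            records.append((f"{patient}_{tissue}", patient, tissue, zone))
    samples = pd.DataFrame(
        records, columns=["sample_id", "patient", "tissue", "zone"]
    ).set_index("sample_id")
    probes = list(diffs_by_probe)
    for j, patient in enumerate(patients):
        cols[f"{patient}_amnion"] = [
            base + diffs_by_probe[p][j] / 2 for p in probes
        ]
        cols[f"{patient}_choriodecidua"] = [
            base - diffs_by_probe[p][j] / 2 for p in probes
        ]
    values = pd.DataFrame(cols, index=pd.Index(probes, name="probe_id"))
    return BetaMatrix(values=values[samples.index], samples=samples)


def make_manifest(probes, chrom_of=None, gene_of=None):
    n = len(probes)
    return pd.DataFrame(
        {
            "chrom": [chrom_of[p] if chrom_of else "chr1" for p in probes],
            "pos": np.arange(n) * 100,
            "strand": ["+"] * n,
            "gene": [gene_of.get(p, "") if gene_of else "" for p in probes],
            "region": ["body"] * n,
        },
        index=pd.Index(probes, name="probe_id"),
    )
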