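"""Validated in-memory containers for the paired two-layer, two-zone design.

Both omics layers share the same sample structure: each patient contributes
one sample per (tissue, zone) combination — amnion and choriodecidua taken
from the zone of intact morphology (ZIM) and the zone of altered morphology
(ZAM) of the fetal membrane.  The containers below wrap a pandas matrix
(features x samples) together with that sample sheet and enforce the
invariants every downstream stage relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ("patient", "tissue", "zone")


class ValidationError(ValueError):
    """Raised when an input matrix or sample sheet violates its contract."""


def _check_sample_sheet(samples: pd.DataFrame, columns: pd.Index) -> None:
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValidationError(f"sample sheet missing columns: {missing}")
    if not samples.index.is_unique:
        dup = samples.index[samples.index.duplicated()].tolist()
        raise ValidationError(f"duplicate sample ids: {dup}")
    key = samples[list(SAMPLE_COLUMNS)].apply(tuple, axis=1)
    if key.duplicated().any():
        dup = key[key.duplicated()].tolist()
        raise ValidationError(
            f"duplicate (patient, tissue, zone) combinations: {dup}"
        )
    extra = columns.difference(samples.index)
    absent = samples.index.difference(columns)
    if len(extra) or len(absent):
        raise ValidationError(
            "matrix columns and sample sheet disagree: "
            f"unknown columns {list(extra)}, missing columns {list(absent)}"
        )


@dataclass
class BetaMatrix:
    """Methylation beta values (probes x samples) with paired metadata.

    Parameters
    ----------
    values
        DataFrame indexed by probe id, one column per sample id; entries are
        methylation fractions in [0, 1].
    samples
        DataFrame indexed by sample id with columns ``patient``, ``tissue``
        and ``zone``; every (patient, tissue, zone) combination is unique.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        _check_sample_sheet(self.samples, self.values.columns)
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate probe ids: {dup[:5]}")
        arr = self.values.to_numpy(dtype=float)
        bad = ~((arr >= 0.0) & (arr <= 1.0))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                "beta values outside [0, 1], first offender: "
                f"probe {self.values.index[r]!r}, sample "
                f"{self.values.columns[c]!r} = {arr[r, c]!r}"
            )
        # keep sample sheet aligned to matrix column order
        self.samples = self.samples.loc[self.values.columns]

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    def subset_zone(self, zone: str) -> "BetaMatrix":
        keep = self.samples.index[self.samples["zone"] == zone]
        if len(keep) == 0:
            raise ValidationError(f"no samples in zone {zone!r}")
        return BetaMatrix(self.values[keep], self.samples.loc[keep])


@dataclass
class ExpressionMatrix:
    """Expression intensities (genes x samples) with paired metadata.

    ``log2_scale`` records whether values are already log2; linear input is
    log2-transformed by the expression model after a positivity check.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    log2_scale: bool = True

    def __post_init__(self) -> None:
        _check_sample_sheet(self.samples, self.values.columns)
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene ids: {dup[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                "non-finite expression value: gene "
                f"{self.values.index[r]!r}, sample {self.values.columns[c]!r}"
            )
        self.samples = self.samples.loc[self.values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index


MANIFEST_COLUMNS = ("chrom", "pos", "strand", "gene", "region")
GENE_REGIONS = ("promoter", "body", "UTR5", "UTR3", "intergenic")


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Validate a probe manifest (index probe_id; 0-based positions)."""
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValidationError(f"manifest missing columns: {missing}")
    if not manifest.index.is_unique:
        raise ValidationError("manifest probe ids are not unique")
    if (manifest["pos"].to_numpy() < 0).any():
        raise ValidationError("manifest positions must be >= 0")
    bad_region = set(manifest["region"]) - set(GENE_REGIONS)
    if bad_region:
        raise ValidationError(f"unknown gene regions: {sorted(bad_region)}")
    return manifest


@dataclass
class PairedDesign:
    """Per-patient pairing of two tissues within one zone.

    ``diffs`` holds the per-feature difference ``tissue_a - tissue_b`` with
    one column per patient, the quantity every paired statistic here is
    built on.
    """

    diffs: pd.DataFrame
    zone: str
    tissue_a: str
    tissue_b: str

    @property
    def n_pairs(self) -> int:
        return self.diffs.shape[1]


def paired_differences(
    values: pd.DataFrame,
    samples: pd.DataFrame,
    zone: str,
    tissue_a: str,
    tissue_b: str,
) -> PairedDesign:
    """Compute per-patient ``tissue_a - tissue_b`` differences within a zone.

    Raises a :class:`ValidationError` naming the first patient missing one
    of the two tissues, and if fewer than two complete pairs remain.
    """
    zmask = samples["zone"] == zone
    if not zmask.any():
        raise ValidationError(f"no samples in zone {zone!r}")
    zs = samples[zmask]
    patients = sorted(zs["patient"].unique())
    cols_a, cols_b = [], []
    for patient in patients:
        row_a = zs[(zs["patient"] == patient) & (zs["tissue"] == tissue_a)]
        row_b = zs[(zs["patient"] == patient) & (zs["tissue"] == tissue_b)]
        if len(row_a) != 1 or len(row_b) != 1:
            raise ValidationError(
                f"patient {patient!r} is not paired in zone {zone!r}: "
                f"{len(row_a)} {tissue_a!r} sample(s), "
                f"{len(row_b)} {tissue_b!r} sample(s)"
            )
        cols_a.append(row_a.index[0])
        cols_b.append(row_b.index[0])
    if len(patients) < 2:
        raise ValidationError(
            f"need >= 2 complete pairs in zone {zone!r}, got {len(patients)}"
        )
    diffs = pd.DataFrame(
        values[cols_a].to_numpy(dtype=float)
        - values[cols_b].to_numpy(dtype=float),
        index=values.index,
        columns=patients,
    )
    return PairedDesign(diffs=diffs, zone=zone, tissue_a=tissue_a, tissue_b=tissue_b)
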