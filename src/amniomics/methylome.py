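"""Paired differential methylation with permutation-derived delta-beta limits.

The analysis contrasts the two fetal-membrane layers (amnion vs
choriodecidua) within one zone across patients that contribute both
tissues.  Per probe it computes the mean paired difference in methylation
fraction (delta-beta) and a two-sided paired t-test p-value; a Monte-Carlo
sign-flip null then yields per-chromosome lower/upper delta-beta limits
(m, M), and a probe is selected when p < alpha AND its delta-beta falls
outside [m, M].  Selected probes are lifted to direction-labelled gene
calls (a gene counts as more methylated in the amnion when at least one of
its selected probes has positive delta-beta, and conversely).

The null keeps the paired structure: within each patient the two tissue
labels are flipped with probability 1/2, i.e. that patient's difference
changes sign for every probe simultaneously.  Limits are either the
extremes over iterations of the per-chromosome null minima/maxima
(``aggregation="extreme"``) or stated quantiles of those minima/maxima
(``aggregation="quantile"``) — extremes grow without bound in the
iteration count, which the quantile mode avoids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrices import (
    BetaMatrix,
    PairedDesign,
    ValidationError,
    paired_differences,
    validate_manifest,
)


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def _paired_t(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-sided paired t-test on per-patient differences.

    Rows with zero variance get p = 1 (conservative policy keeping the
    pipeline total on constant probes).
    """
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
    zero_var = sd == 0
    t[zero_var] = 0.0
    p[zero_var] = 1.0
    return t, p


def paired_delta_beta(
    beta: BetaMatrix,
    zone: str,
    tissue_a: str,
    tissue_b: str,
) -> pd.DataFrame:
    """Per-probe mean paired delta-beta and paired t-test p-value.

    Returns a DataFrame indexed by probe with columns ``delta_beta``
    (mean over patients of tissue_a - tissue_b), ``t``, ``p_value`` and
    ``n_pairs``.
    """
    design = paired_differences(beta.values, beta.samples, zone, tissue_a, tissue_b)
    diffs = design.diffs.to_numpy()
    t, p = _paired_t(diffs)
    return pd.DataFrame(
        {
            "delta_beta": diffs.mean(axis=1),
            "t": t,
            "p_value": p,
            "n_pairs": design.n_pairs,
        },
        index=design.diffs.index,
    )


def monte_carlo_limits(
    beta: BetaMatrix,
    zone: str,
    tissue_a: str,
    tissue_b: str,
    manifest: pd.DataFrame,
    n_iterations: int = 1000,
    seed: int | np.random.Generator | None = None,
    aggregation: str = "extreme",
    quantile_level: float = 0.01,
) -> pd.DataFrame:
    """Per-chromosome null delta-beta limits (m, M) by sign-flip Monte Carlo.

    Each iteration flips every patient's tissue labels independently with
    probability 1/2 and records the per-chromosome minimum and maximum of
    the resulting null delta-beta.  ``aggregation="extreme"`` takes the
    min of minima and max of maxima over iterations;
    ``aggregation="quantile"`` takes the ``quantile_level`` quantile of
    the minima and the ``1 - quantile_level`` quantile of the maxima.

    Returns a DataFrame indexed by chromosome with columns ``m``, ``M``,
    ``n_iterations``, ``aggregation``, ``quantile_level``.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if aggregation not in ("extreme", "quantile"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    validate_manifest(manifest)
    design = paired_differences(beta.values, beta.samples, zone, tissue_a, tissue_b)
    missing = design.diffs.index.difference(manifest.index)
    if len(missing):
        raise ValidationError(
            f"{len(missing)} probes missing from the manifest, "
            f"e.g. {missing[:3].tolist()}"
        )
    chroms = manifest.loc[design.diffs.index, "chrom"].to_numpy()
    diffs = design.diffs.to_numpy()
    n_pairs = diffs.shape[1]
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_pairs, n_iterations))
    null_db = diffs @ signs / n_pairs  # probes x iterations

    chrom_order = pd.unique(chroms)
    rows = []
    for chrom in chrom_order:
        block = null_db[chroms == chrom]  # probes-on-chrom x iterations
        iter_min = block.min(axis=0)
        iter_max = block.max(axis=0)
        if aggregation == "extreme":
            m, M = float(iter_min.min()), float(iter_max.max())
        else:
            m = float(np.quantile(iter_min, quantile_level))
            M = float(np.quantile(iter_max, 1.0 - quantile_level))
        rows.append((chrom, m, M))
    out = pd.DataFrame(rows, columns=["chrom", "m", "M"]).set_index("chrom")
    out["n_iterations"] = n_iterations
    out["aggregation"] = aggregation
    out["quantile_level"] = quantile_level
    return out


def select_probes(
    dbt: pd.DataFrame,
    limits: pd.DataFrame,
    manifest: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Probes with p < alpha whose delta-beta exceeds the chromosome limits.

    A probe is retained iff ``p_value < alpha`` and (delta_beta < m_chrom
    or delta_beta > M_chrom), both strictly.  The output carries the
    manifest annotation and is sorted by |delta_beta| descending, ties by
    probe id.
    """
    validate_manifest(manifest)
    missing_probe = dbt.index.difference(manifest.index)
    if len(missing_probe):
        raise ValidationError(
            f"probes absent from manifest: {missing_probe[:3].tolist()}"
        )
    chroms = manifest.loc[dbt.index, "chrom"]
    missing_chrom = set(chroms) - set(limits.index)
    if missing_chrom:
        raise ValidationError(
            f"no limits for chromosome(s): {sorted(missing_chrom)}"
        )
    m = limits["m"].loc[chroms].to_numpy()
    M = limits["M"].loc[chroms].to_numpy()
    db = dbt["delta_beta"].to_numpy()
    keep = (dbt["p_value"].to_numpy() < alpha) & ((db < m) | (db > M))
    out = dbt[keep].join(manifest.loc[dbt.index[keep]])
    order = np.lexsort((out.index.to_numpy(), -np.abs(out["delta_beta"].to_numpy())))
    return out.iloc[order]


@dataclass
class GeneCallSets:
    """Direction-labelled gene calls from selected probes.

    ``mA_gt_mC`` holds genes with at least one selected probe more
    methylated in tissue A; ``mA_lt_mC`` the converse.  A gene whose
    selected probes disagree appears in both sets.
    """

    mA_gt_mC: frozenset
    mA_lt_mC: frozenset
    supporting_probes: dict[str, list[tuple[str, float, float]]] = field(
        default_factory=dict
    )

    def swap(self) -> "GeneCallSets":
        return GeneCallSets(
            mA_gt_mC=self.mA_lt_mC,
            mA_lt_mC=self.mA_gt_mC,
            supporting_probes={
                g: [(p, -db, pv) for p, db, pv in recs]
                for g, recs in self.supporting_probes.items()
            },
        )


def call_genes(selected: pd.DataFrame, manifest: pd.DataFrame | None = None) -> GeneCallSets:
    """Lift selected probes to per-gene direction calls.

    Probes without a gene annotation (intergenic) are dropped; probes
    annotated to several genes (semicolon-separated symbols) contribute
    to every mapped gene.
    """
    if manifest is not None and "gene" not in selected.columns:
        selected = selected.join(manifest.loc[selected.index, ["gene"]])
    up, down = set(), set()
    supporting: dict[str, list[tuple[str, float, float]]] = {}
    for probe_id, row in selected.iterrows():
        gene_field = str(row.get("gene", "") or "")
        genes = [g.strip() for g in gene_field.split(";") if g.strip()]
        for gene in genes:
            supporting.setdefault(gene, []).append(
                (probe_id, float(row["delta_beta"]), float(row["p_value"]))
            )
            if row["delta_beta"] > 0:
                up.add(gene)
            elif row["delta_beta"] < 0:
                down.add(gene)
    return GeneCallSets(
        mA_gt_mC=frozenset(up),
        mA_lt_mC=frozenset(down),
        supporting_probes=supporting,
    )


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class PairedMethylationModel:
    """Paired two-layer differential methylation within one zone.

    Parameters
    ----------
    beta
        Validated :class:`~amniomics.matrices.BetaMatrix`.
    manifest
        Probe manifest DataFrame indexed by probe id with ``chrom``,
        ``pos``, ``strand``, ``gene``, ``region``.
    zone, tissue_a, tissue_b
        The comparison: per-patient ``tissue_a - tissue_b`` differences
        within ``zone``.

    Examples
    --------
    >>> model = PairedMethylationModel(beta, manifest, zone="ZAM")
    >>> res = model.fit(alpha=0.05, n_iterations=1000, seed=0)
    >>> res.selected.head(); res.gene_calls.mA_gt_mC
    """

    def __init__(
        self,
        beta: BetaMatrix,
        manifest: pd.DataFrame,
        zone: str,
        tissue_a: str = "amnion",
        tissue_b: str = "choriodecidua",
    ) -> None:
        self.beta = beta
        self.manifest = validate_manifest(manifest)
        self.zone = zone
        self.tissue_a = tissue_a
        self.tissue_b = tissue_b

    def fit(
        self,
        alpha: float = 0.05,
        n_iterations: int = 1000,
        aggregation: str = "extreme",
        quantile_level: float = 0.01,
        seed: int | np.random.Generator | None = None,
    ) -> "PairedMethylationResults":
        dbt = paired_delta_beta(self.beta, self.zone, self.tissue_a, self.tissue_b)
        limits = monte_carlo_limits(
            self.beta,
            self.zone,
            self.tissue_a,
            self.tissue_b,
            self.manifest,
            n_iterations=n_iterations,
            seed=seed,
            aggregation=aggregation,
            quantile_level=quantile_level,
        )
        return PairedMethylationResults(self, dbt, limits, alpha)


@dataclass
class PairedMethylationResults:
    """Fit output: per-probe table, per-chromosome limits, selections.

    ``delta_beta`` is the per-probe table, ``limits`` the per-chromosome
    (m, M) limits, ``selected`` the retained probes and ``gene_calls``
    the direction-labelled gene sets.
    """

    model: PairedMethylationModel
    delta_beta: pd.DataFrame
    limits: pd.DataFrame
    alpha: float

    def __post_init__(self) -> None:
        self.selected = select_probes(
            self.delta_beta, self.limits, self.model.manifest, self.alpha
        )
        self.gene_calls = call_genes(self.selected, self.model.manifest)

    def summary(self) -> str:
        lines = [
            "Paired differential methylation "
            f"({self.model.tissue_a} - {self.model.tissue_b}, "
            f"zone {self.model.zone})",
            f"  probes tested:        {len(self.delta_beta)}",
            f"  pairs:                {int(self.delta_beta['n_pairs'].iloc[0])}",
            f"  alpha:                {self.alpha}",
            "  limits:               "
            f"{self.limits['aggregation'].iloc[0]} over "
            f"{int(self.limits['n_iterations'].iloc[0])} iterations",
            f"  probes selected:      {len(self.selected)}",
            f"  genes mA>mC:          {len(self.gene_calls.mA_gt_mC)}",
            f"  genes mA<mC:          {len(self.gene_calls.mA_lt_mC)}",
        ]
        return "\n".join(lines)

    def selected_bed(self) -> pd.DataFrame:
        """Selected probes as 0-based half-open BED records."""
        sel = self.selected
        return pd.DataFrame(
            {
                "chrom": sel["chrom"].to_numpy(),
                "start": sel["pos"].to_numpy(),
                "end": sel["pos"].to_numpy() + 1,
                "name": sel.index.to_numpy(),
                "score": np.round(np.abs(sel["delta_beta"].to_numpy()) * 1000).astype(int),
                "strand": sel["strand"].to_numpy(),
            }
        )
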