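"""Paired differential expression with fold-change and FDR filters.

Per gene: mean over patients of the paired log2 difference (tissue_a -
tissue_b), a two-sided paired t-test, Benjamini-Hochberg adjustment over
all tested genes, and classification as up / down / unclassified with
|log2 FC| >= threshold (inclusive) and adjusted p < alpha.  Defaults
follow the screening convention used for the fetal-membrane arrays:
|log2 FC| = 2.8 and alpha = 0.01 on BH-adjusted p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrices import ExpressionMatrix, ValidationError, paired_differences
from .methylome import _paired_t
from .stats import adjust_pvalues

LOG10_P_CAP = 320.0


def diff_expression(
    expr: ExpressionMatrix,
    zone: str,
    tissue_a: str = "amnion",
    tissue_b: str = "choriodecidua",
    fc_threshold: float = 2.8,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-gene paired differential expression table.

    Linear-scale input is log2-transformed after a positivity check.
    Returns a DataFrame indexed by gene with columns ``log2_fc``, ``t``,
    ``p_value``, ``adj_p`` (BH) and ``class``.
    """
    values = expr.values
    if not expr.log2_scale:
        arr = values.to_numpy(dtype=float)
        if (arr <= 0).any():
            r, c = np.argwhere(arr <= 0)[0]
            raise ValidationError(
                "linear intensities must be positive to log-transform; "
                f"gene {values.index[r]!r}, sample {values.columns[c]!r}"
            )
        values = np.log2(values)
    design = paired_differences(values, expr.samples, zone, tissue_a, tissue_b)
    diffs = design.diffs.to_numpy()
    t, p = _paired_t(diffs)
    log2_fc = diffs.mean(axis=1)
    adj_p = adjust_pvalues(p, "bh")
    cls = np.where(
        (np.abs(log2_fc) >= fc_threshold) & (adj_p < alpha),
        np.where(log2_fc > 0, "up", "down"),
        "unclassified",
    )
    return pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "t": t,
            "p_value": p,
            "adj_p": adj_p,
            "class": cls,
        },
        index=design.diffs.index,
    )


def volcano_table(det: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot table: gene, log2 FC, -log10 adjusted p, class.

    Adjusted p of zero is capped at -log10 p = 320.
    """
    with np.errstate(divide="ignore"):
        neg_log10 = -np.log10(det["adj_p"].to_numpy())
    neg_log10 = np.minimum(neg_log10, LOG10_P_CAP)
    return pd.DataFrame(
        {
            "gene": det.index.to_numpy(),
            "log2_fc": det["log2_fc"].to_numpy(),
            "neg_log10_adj_p": neg_log10,
            "class": det["class"].to_numpy(),
        }
    )


class PairedExpressionModel:
    """Paired two-layer differential expression within one zone.

    Mirrors :class:`~amniomics.methylome.PairedMethylationModel`:
    construct from an :class:`~amniomics.matrices.ExpressionMatrix`, call
    :meth:`fit` to obtain results with the classified table, volcano
    export and a text summary.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        zone: str,
        tissue_a: str = "amnion",
        tissue_b: str = "choriodecidua",
    ) -> None:
        self.expr = expr
        self.zone = zone
        self.tissue_a = tissue_a
        self.tissue_b = tissue_b

    def fit(
        self, fc_threshold: float = 2.8, alpha: float = 0.01
    ) -> "PairedExpressionResults":
        table = diff_expression(
            self.expr,
            self.zone,
            self.tissue_a,
            self.tissue_b,
            fc_threshold=fc_threshold,
            alpha=alpha,
        )
        return PairedExpressionResults(self, table, fc_threshold, alpha)


@dataclass
class PairedExpressionResults:
    model: PairedExpressionModel
    table: pd.DataFrame
    fc_threshold: float
    alpha: float

    @property
    def up(self) -> frozenset:
        return frozenset(self.table.index[self.table["class"] == "up"])

    @property
    def down(self) -> frozenset:
        return frozenset(self.table.index[self.table["class"] == "down"])

    def volcano_table(self) -> pd.DataFrame:
        return volcano_table(self.table)

    def summary(self) -> str:
        return "\n".join(
            [
                "Paired differential expression "
                f"({self.model.tissue_a} - {self.model.tissue_b}, "
                f"zone {self.model.zone})",
                f"  genes tested:   {len(self.table)}",
                f"  |log2 FC| >=    {self.fc_threshold}",
                f"  adj. p <        {self.alpha} (Benjamini-Hochberg)",
                f"  up-regulated:   {len(self.up)}",
                f"  down-regulated: {len(self.down)}",
            ]
        )
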