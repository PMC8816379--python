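"""Canonical miRNA seed-site scanning and methylation-expression
concordance screening.

A miRNA represses a transcript when its seed (mature nucleotides 2-7/2-8)
pairs with a complementary segment of the 3'UTR.  The four canonical site
classes are recognised, in decreasing specificity:

* 8mer     — perfect match to seed positions 2-8 plus an A opposite
             position 1,
* 7mer-m8  — match to positions 2-8,
* 7mer-A1  — match to positions 2-7 plus the A1 anchor,
* 6mer     — match to positions 2-7 only.

The concordance screen nominates (miRNA, target) pairs in which the miRNA
gene is hypermethylated (hence presumably silenced) in the tissue where
the target is over-expressed — the regulatory logic by which let-7a-2 and
miR-125b-1, hypermethylated in the choriodecidua, are freed to repress
TLR4 in the amnion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bisulfite import reverse_complement
from .matrices import BetaMatrix, paired_differences
from .stats import PairedSample, wilcoxon_signed_rank

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
_RNA_TO_DNA = str.maketrans("U", "T")
_DNA_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA; the seed is nucleotides 2-8 of the mature sequence."""

    name: str
    mature_seq: str

    def __post_init__(self) -> None:
        seq = self.mature_seq.upper()
        if len(seq) < 8:
            raise ValueError(f"mature sequence of {self.name!r} shorter than 8 nt")
        if set(seq) - set("ACGUT"):
            raise ValueError(f"invalid alphabet in mature sequence of {self.name!r}")
        object.__setattr__(self, "mature_seq", seq)

    @property
    def mature_dna(self) -> str:
        return self.mature_seq.translate(_RNA_TO_DNA)

    @property
    def seed(self) -> str:
        """Nucleotides 2-8 of the mature sequence (RNA alphabet kept)."""
        return self.mature_seq[1:8]


def site_motif(mirna: MiRNA, site_type: str) -> str:
    """The exact UTR motif (DNA, 5'->3') implied by a site type.

    The 6mer core is the reverse complement of mature positions 2-7; the
    m8 match prepends the complement of position 8; the A1 anchor appends
    an A (regardless of the identity of mature position 1).
    """
    mature = mirna.mature_dna
    core = reverse_complement(mature[1:7])
    m8 = _DNA_COMP[mature[7]]
    if site_type == "6mer":
        return core
    if site_type == "7mer-m8":
        return m8 + core
    if site_type == "7mer-A1":
        return core + "A"
    if site_type == "8mer":
        return m8 + core + "A"
    raise ValueError(f"unknown site type {site_type!r}")


@dataclass(frozen=True)
class TargetSite:
    """One seed-match site; coordinates 0-based half-open on the UTR."""

    utr_id: str
    mirna_name: str
    site_type: str
    start: int
    end: int


def scan_utr(
    utr: str, mirna: MiRNA, utr_id: str = "utr"
) -> list[TargetSite]:
    """Scan a 3'UTR (DNA) for canonical seed sites of one miRNA.

    Overlapping matches are reported once at the highest-specificity type
    (8mer > 7mer-m8 > 7mer-A1 > 6mer); coordinates cover the full motif.
    """
    utr = utr.upper()
    if set(utr) - set("ACGT"):
        raise ValueError("UTR must be plain DNA (ACGT)")
    core = site_motif(mirna, "6mer")
    m8 = site_motif(mirna, "7mer-m8")[0]
    sites: list[TargetSite] = []
    start = 0
    while True:
        i = utr.find(core, start)
        if i < 0:
            break
        start = i + 1
        has_m8 = i > 0 and utr[i - 1] == m8
        has_a1 = i + 6 < len(utr) and utr[i + 6] == "A"
        if has_m8 and has_a1:
            sites.append(TargetSite(utr_id, mirna.name, "8mer", i - 1, i + 7))
        elif has_m8:
            sites.append(TargetSite(utr_id, mirna.name, "7mer-m8", i - 1, i + 6))
        elif has_a1:
            sites.append(TargetSite(utr_id, mirna.name, "7mer-A1", i, i + 7))
        else:
            sites.append(TargetSite(utr_id, mirna.name, "6mer", i, i + 6))
    return sites


def scan_utrs(
    utrs: Mapping[str, str], mirnas: Iterable[MiRNA]
) -> list[TargetSite]:
    """Scan several UTRs with several miRNAs."""
    out: list[TargetSite] = []
    for utr_id, seq in utrs.items():
        for mirna in mirnas:
            out.extend(scan_utr(seq, mirna, utr_id=utr_id))
    return out


def mirna_gene_methylation(
    beta: BetaMatrix,
    mirna_probe_map: Mapping[str, str],
    zone: str,
    tissue_a: str = "amnion",
    tissue_b: str = "choriodecidua",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-probe paired methylation differences at miRNA genes.

    ``mirna_probe_map`` maps probe id -> miRNA gene.  Returns a per-probe
    table (probe, mirna_gene, delta_beta, p from the exact Wilcoxon
    signed-rank test) and a per-miRNA summary with the direction of the
    median delta-beta: ``mA>mC`` (hypermethylated in ``tissue_a``),
    ``mA<mC``, or ``undetermined`` when the median is exactly zero.
    miRNA genes without any probe in the matrix are dropped with a
    warning.
    """
    probes = [p for p in mirna_probe_map if p in beta.values.index]
    missing_genes = set(mirna_probe_map.values()) - {
        mirna_probe_map[p] for p in probes
    }
    for gene in sorted(missing_genes):
        warnings.warn(f"miRNA gene {gene!r} has no probes in the matrix; dropped",
                      stacklevel=2)
    design = paired_differences(
        beta.values.loc[probes], beta.samples, zone, tissue_a, tissue_b
    )
    rows = []
    for probe in probes:
        d = design.diffs.loc[probe].to_numpy()
        _, p = wilcoxon_signed_rank(
            PairedSample(values_a=d, values_b=np.zeros_like(d))
        )
        rows.append((probe, mirna_probe_map[probe], float(d.mean()), p))
    per_probe = pd.DataFrame(
        rows, columns=["probe_id", "mirna_gene", "delta_beta", "p"]
    )
    summaries = []
    for gene, sub in per_probe.groupby("mirna_gene"):
        med = float(sub["delta_beta"].median())
        if med > 0:
            direction = "mA>mC"
        elif med < 0:
            direction = "mA<mC"
        else:
            direction = "undetermined"
        summaries.append(
            (gene, len(sub), med, int((sub["p"] < alpha).sum()), direction)
        )
    summary = pd.DataFrame(
        summaries,
        columns=["mirna_gene", "n_probes", "median_delta_beta",
                 "n_significant", "direction"],
    )
    return per_probe, summary


@dataclass(frozen=True)
class RegulatoryCandidate:
    mirna_name: str
    target_gene: str
    mirna_meth_direction: str
    target_expr_direction: str
    n_sites: int
    concordant: bool


def nominate_candidates(
    sites: Sequence[TargetSite],
    mirna_meth_summary: pd.DataFrame,
    expr_table: pd.DataFrame,
    utr_gene_map: Mapping[str, str],
    mirna_gene_map: Mapping[str, str] | None = None,
    include_6mer: bool = False,
) -> list[RegulatoryCandidate]:
    """Combine seed sites, miRNA-gene methylation and target expression.

    A candidate is concordant when the miRNA gene is hypermethylated
    (silenced) in the tissue where the target is over-expressed: with
    delta-beta and log2 FC both oriented amnion - choriodecidua, that is
    (mA<mC methylation, down-in-amnion target) or the mirror pair.

    ``mirna_gene_map`` maps mature miRNA names to the miRNA gene row of
    the methylation summary (identity by default).  6mer sites are
    excluded from nomination unless ``include_6mer``.
    """
    mirna_gene_map = dict(mirna_gene_map or {})
    meth_dir = dict(
        zip(mirna_meth_summary["mirna_gene"], mirna_meth_summary["direction"])
    )
    expr_class = dict(zip(expr_table.index, expr_table["class"]))
    counted: dict[tuple[str, str], int] = {}
    for site in sites:
        if site.site_type == "6mer" and not include_6mer:
            continue
        if site.utr_id not in utr_gene_map:
            raise ValueError(f"UTR {site.utr_id!r} has no gene mapping")
        key = (site.mirna_name, utr_gene_map[site.utr_id])
        counted[key] = counted.get(key, 0) + 1
    out = []
    for (mirna_name, gene), n_sites in sorted(counted.items()):
        gene_key = mirna_gene_map.get(mirna_name, mirna_name)
        m_dir = meth_dir.get(gene_key, "unknown")
        e_dir = expr_class.get(gene, "untested")
        concordant = (m_dir == "mA<mC" and e_dir == "down") or (
            m_dir == "mA>mC" and e_dir == "up"
        )
        out.append(
            RegulatoryCandidate(
                mirna_name=mirna_name,
                target_gene=gene,
                mirna_meth_direction=m_dir,
                target_expr_direction=e_dir,
                n_sites=n_sites,
                concordant=concordant,
            )
        )
    return out
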