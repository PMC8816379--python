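"""End-to-end orchestration: methylome -> transcriptome -> integration ->
enrichment -> miRNA stages on one cohort, with a machine-readable run
report."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrichment import enrich
from .integration import cross_omics, venn4, zone_specific
from .io import (
    read_annotations,
    read_beta_matrix,
    read_expression_matrix,
    read_fasta,
    read_manifest,
    read_mirnas,
    write_gene_set,
    _write_table,
)
from .methylome import PairedMethylationModel
from .mirna import mirna_gene_methylation, nominate_candidates, scan_utrs
from .transcriptome import PairedExpressionModel

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run; see the CLI `run` command."""

    beta_matrix: str
    beta_sample_sheet: str
    expression_matrix: str
    expression_sample_sheet: str
    manifest: str
    out_dir: str
    annotations: str | None = None
    utr_fasta: str | None = None
    mirnas: str | None = None
    utr_gene_map: dict[str, str] = field(default_factory=dict)
    mirna_probe_map: dict[str, str] = field(default_factory=dict)
    mirna_gene_map: dict[str, str] = field(default_factory=dict)
    zones: tuple[str, str] = ("ZIM", "ZAM")
    cross_omics_zone: str = "ZAM"
    tissue_a: str = "amnion"
    tissue_b: str = "choriodecidua"
    meth_alpha: float = 0.05
    n_iterations: int = 1000
    aggregation: str = "extreme"
    quantile_level: float = 0.01
    fc_threshold: float = 2.8
    expr_alpha: float = 0.01
    enrich_alpha: float = 0.01
    enrich_correction: str = "bonferroni"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "zones" in raw:
            raw["zones"] = tuple(raw["zones"])
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write intermediates under ``config.out_dir``.

    Returns the run report (also written as ``report.json``): versions,
    parameters, and the set sizes at each stage — the pipeline's
    narrative numbers.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    beta = read_beta_matrix(config.beta_matrix, config.beta_sample_sheet)
    expr = read_expression_matrix(
        config.expression_matrix, config.expression_sample_sheet
    )
    manifest = read_manifest(config.manifest)

    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "meth_alpha": config.meth_alpha,
            "n_iterations": config.n_iterations,
            "aggregation": config.aggregation,
            "quantile_level": config.quantile_level,
            "fc_threshold": config.fc_threshold,
            "expr_alpha": config.expr_alpha,
            "enrich_alpha": config.enrich_alpha,
            "enrich_correction": config.enrich_correction,
        },
        "stages": {},
    }

    # --- differential methylation, both zones -------------------------
    gene_sets: dict[str, frozenset] = {}
    calls_by_zone = {}
    for i, zone in enumerate(config.zones):
        model = PairedMethylationModel(
            beta, manifest, zone, config.tissue_a, config.tissue_b
        )
        res = model.fit(
            alpha=config.meth_alpha,
            n_iterations=config.n_iterations,
            aggregation=config.aggregation,
            quantile_level=config.quantile_level,
            seed=config.seed + i,
        )
        _write_table(
            res.delta_beta, out / f"delta_beta_{zone}.tsv",
            f"per-probe delta beta and paired t-test, zone {zone}, "
            f"{config.tissue_a} - {config.tissue_b}",
        )
        _write_table(
            res.limits, out / f"limits_{zone}.tsv",
            f"per-chromosome Monte-Carlo delta-beta limits, zone {zone}",
        )
        _write_table(
            res.selected, out / f"selected_probes_{zone}.tsv",
            f"selected probes, zone {zone} (p < alpha and outside [m, M])",
        )
        calls_by_zone[zone] = res.gene_calls
        gene_sets[f"{zone}_mA>mC"] = res.gene_calls.mA_gt_mC
        gene_sets[f"{zone}_mA<mC"] = res.gene_calls.mA_lt_mC
        report["stages"][f"diffmeth_{zone}"] = {
            "probes_tested": len(res.delta_beta),
            "probes_selected": len(res.selected),
            "genes_mA_gt_mC": len(res.gene_calls.mA_gt_mC),
            "genes_mA_lt_mC": len(res.gene_calls.mA_lt_mC),
        }
        logger.info("diffmeth %s: %d probes selected", zone, len(res.selected))

    # --- differential expression (cross-omics zone) --------------------
    expr_model = PairedExpressionModel(
        expr, config.cross_omics_zone, config.tissue_a, config.tissue_b
    )
    expr_res = expr_model.fit(
        fc_threshold=config.fc_threshold, alpha=config.expr_alpha
    )
    _write_table(
        expr_res.table, out / "diff_expression.tsv",
        "per-gene paired log2 FC, BH-adjusted p and class, zone "
        f"{config.cross_omics_zone}",
    )
    _write_table(
        expr_res.volcano_table(), out / "volcano.tsv",
        "volcano table: gene, log2_fc, -log10 adj_p (capped 320), class",
        index=False,
    )
    report["stages"]["diffexpr"] = {
        "genes_tested": len(expr_res.table),
        "up": len(expr_res.up),
        "down": len(expr_res.down),
    }

    # --- integration ----------------------------------------------------
    partition = venn4(gene_sets)
    venn_rows = [
        ("+".join(sorted(pattern)), len(members))
        for pattern, members in sorted(
            partition.region_members.items(), key=lambda kv: sorted(kv[0])
        )
    ]
    _write_table(
        pd.DataFrame(venn_rows, columns=["pattern", "size"]),
        out / "venn_regions.tsv",
        "four-way Venn regions over per-zone methylation direction sets",
        index=False,
    )
    zone_spec = {
        zone: zone_specific(partition, zone) for zone in config.zones
    }
    for zone, genes in zone_spec.items():
        write_gene_set(genes, out / f"zone_specific_{zone}.txt")
    cross = cross_omics(calls_by_zone[config.cross_omics_zone], expr_res.table)
    write_gene_set(cross.hyperA_upC, out / "hyperA_upC.txt")
    write_gene_set(cross.hyperC_upA, out / "hyperC_upA.txt")
    report["stages"]["integration"] = {
        "venn_union": sum(n for _, n in venn_rows),
        **{f"zone_specific_{z}": len(g) for z, g in zone_spec.items()},
        "hyperA_upC": len(cross.hyperA_upC),
        "hyperC_upA": len(cross.hyperC_upA),
        "untested_in_expression": len(cross.untested),
    }

    # --- enrichment ------------------------------------------------------
    if config.annotations:
        ann = read_annotations(config.annotations)
        population = set(expr.gene_ids)
        study = set(g for g in zone_spec[config.cross_omics_zone]
                    if g in population)
        result = enrich(
            study, population, ann,
            correction=config.enrich_correction, alpha=config.enrich_alpha,
        )
        _write_table(
            result, out / "enrichment.tsv",
            "term over-representation: hypergeometric upper tail, "
            f"{config.enrich_correction} correction",
            index=False,
        )
        report["stages"]["enrichment"] = {
            "terms_tested": len(result),
            "significant": int(result["significant"].sum()) if len(result) else 0,
        }

    # --- miRNA regulation -------------------------------------------------
    if config.utr_fasta and config.mirnas:
        utrs = read_fasta(config.utr_fasta)
        mirnas = read_mirnas(config.mirnas)
        sites = scan_utrs(utrs, mirnas)
        _write_table(
            pd.DataFrame(
                [(s.utr_id, s.start, s.end, s.mirna_name, s.site_type)
                 for s in sites],
                columns=["utr_id", "start", "end", "mirna", "type"],
            ),
            out / "mirna_sites.tsv",
            "canonical seed sites, 0-based half-open UTR coordinates",
            index=False,
        )
        report["stages"]["mirna_scan"] = {"sites": len(sites)}
        if config.mirna_probe_map:
            per_probe, summary = mirna_gene_methylation(
                beta, config.mirna_probe_map, config.cross_omics_zone,
                config.tissue_a, config.tissue_b,
            )
            _write_table(
                summary, out / "mirna_methylation.tsv",
                "per-miRNA-gene paired methylation summary", index=False,
            )
            candidates = nominate_candidates(
                sites, summary, expr_res.table,
                utr_gene_map=config.utr_gene_map,
                mirna_gene_map=config.mirna_gene_map,
            )
            _write_table(
                pd.DataFrame([c.__dict__ for c in candidates]),
                out / "mirna_candidates.tsv",
                "miRNA->target candidates with concordance flag", index=False,
            )
            report["stages"]["mirna_nominate"] = {
                "candidates": len(candidates),
                "concordant": sum(c.concordant for c in candidates),
            }

    payload = json.dumps(report, indent=2, sort_keys=True)
    report["report_sha256"] = hashlib.sha256(payload.encode()).hexdigest()
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
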