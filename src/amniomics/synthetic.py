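"""Synthetic paired cohorts and sequence fixtures with known ground truth.

Emulates the study design the pipeline targets: nine patients, each
contributing amnion and choriodecidua samples from the zone of intact
(ZIM) and altered (ZAM) morphology, assayed for probe-level methylation
(beta values) and gene-level expression.  Tissue effects are planted in
the ZAM comparison only, with known per-probe/per-gene directions, so
every downstream stage can be scored against truth.

Beta values are generated on the logit scale: probe means are set in beta
units, noise and patient random intercepts are Gaussian on the logit
scale (noise SD rescaled by the delta method so its beta-scale SD matches
``beta_noise_sd``), and the inverse logit maps back into (0, 1) without
censoring.  Patient intercepts are shared across a patient's samples,
which is what gives the paired tests their power.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .matrices import BetaMatrix, ExpressionMatrix
from .mirna import MiRNA, scan_utr, site_motif


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its contract."""


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _invlogit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class CohortConfig:
    """Study-design parameters for the synthetic paired cohort.

    Defaults mirror the design the pipeline emulates: nine patients, the
    amnion/choriodecidua layer pair and the ZIM/ZAM zone pair, with a
    planted methylation shift of 0.3 beta units against a 0.05 beta-unit
    noise floor and a planted expression effect of 4 log2 units against
    0.5 log2 units of noise.
    """

    n_patients: int = 9
    tissues: tuple[str, str] = ("amnion", "choriodecidua")
    zones: tuple[str, str] = ("ZIM", "ZAM")
    n_probes: int = 2000
    n_genes: int = 400
    probes_per_gene: int = 4
    frac_differential_probes: float = 0.05
    delta_beta_effect: float = 0.3
    beta_noise_sd: float = 0.05
    frac_differential_genes: float = 0.05
    log2fc_effect: float = 4.0
    expr_noise_sd: float = 0.5
    patient_sd: float = 0.2
    n_chromosomes: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_probes", "n_genes", "probes_per_gene",
                     "n_chromosomes"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("frac_differential_probes", "frac_differential_genes"):
            frac = getattr(self, name)
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for name in ("beta_noise_sd", "expr_noise_sd", "patient_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_genes * self.probes_per_gene > self.n_probes:
            raise ConfigurationError(
                "n_probes must be >= n_genes * probes_per_gene"
            )
        if len(set(self.tissues)) != 2 or len(set(self.zones)) != 2:
            raise ConfigurationError("tissues and zones must be distinct pairs")


@dataclass
class GroundTruth:
    """Planted effects, all directions oriented tissue A - tissue B.

    ``A>C`` means higher in the first tissue (amnion); planted effects
    apply to the second zone (ZAM) comparison.
    """

    differential_probes: frozenset  # of (probe_id, direction)
    differential_genes_meth: frozenset  # of (gene, direction)
    differential_genes_expr: frozenset  # of (gene, direction)
    planted_sites: list = field(default_factory=list)

    def expected_cross_omics(self) -> tuple[frozenset, frozenset]:
        """Planted inverse-correlation overlaps.

        Returns (hyperA_upC, hyperC_upA): genes hypermethylated in A with
        expression higher in C, and the converse.
        """
        meth = dict(self.differential_genes_meth)
        expr = dict(self.differential_genes_expr)
        hyper_a = frozenset(
            g for g, d in meth.items() if d == "A>C" and expr.get(g) == "A<C"
        )
        hyper_c = frozenset(
            g for g, d in meth.items() if d == "A<C" and expr.get(g) == "A>C"
        )
        return hyper_a, hyper_c


def _beta_noise_scale(mu: np.ndarray, sd_beta: float) -> np.ndarray:
    # delta method: an SD of sd_beta on the beta scale corresponds to
    # sd_beta / (mu (1 - mu)) on the logit scale
    return sd_beta / (mu * (1.0 - mu))


def generate_cohort(
    config: CohortConfig,
) -> tuple[BetaMatrix, ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Generate (BetaMatrix, ExpressionMatrix, manifest, GroundTruth).

    Probes map to genes in consecutive blocks of ``probes_per_gene``
    (surplus probes are intergenic); differential probes are planted by
    gene block so gene-level calls have known truth.  Half of the planted
    expression genes are drawn from the planted methylation genes with
    the opposite orientation, giving a known inverse-correlation overlap
    for the cross-omics stage.
    """
    rng = np.random.default_rng(config.seed)
    tissue_a, tissue_b = config.tissues
    zone_null, zone_eff = config.zones

    # --- manifest -----------------------------------------------------
    probe_ids = [f"cg{i:08d}" for i in range(config.n_probes)]
    genes = [f"GENE{i:04d}" for i in range(config.n_genes)]
    gene_of_probe = np.array(
        [
            genes[i // config.probes_per_gene]
            if i < config.n_genes * config.probes_per_gene
            else ""
            for i in range(config.n_probes)
        ],
        dtype=object,
    )
    chroms = np.array(
        [f"chr{1 + (i % config.n_chromosomes)}" for i in range(config.n_probes)],
        dtype=object,
    )
    regions = rng.choice(
        ["promoter", "body", "UTR5", "UTR3"], size=config.n_probes
    )
    regions[gene_of_probe == ""] = "intergenic"
    manifest = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.arange(config.n_probes, dtype=int) * 500,
            "strand": rng.choice(["+", "-"], size=config.n_probes),
            "gene": gene_of_probe,
            "region": regions,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )

    # --- planted methylation effects (gene blocks) --------------------
    n_diff_meth_genes = int(
        round(config.frac_differential_probes * config.n_probes
              / config.probes_per_gene)
    )
    n_diff_meth_genes = min(n_diff_meth_genes, config.n_genes)
    meth_genes = list(rng.choice(genes, size=n_diff_meth_genes, replace=False))
    meth_dir = {g: ("A>C" if rng.random() < 0.5 else "A<C") for g in meth_genes}
    diff_probes = set()
    probe_effect_dir = pd.Series(0, index=manifest.index, dtype=int)
    for probe_id, gene in zip(probe_ids, gene_of_probe):
        if gene in meth_dir:
            sign = 1 if meth_dir[gene] == "A>C" else -1
            probe_effect_dir[probe_id] = sign
            diff_probes.add((probe_id, meth_dir[gene]))

    # --- planted expression effects -----------------------------------
    n_diff_expr = min(
        int(round(config.frac_differential_genes * config.n_genes)),
        config.n_genes,
    )
    n_from_meth = min(n_diff_expr // 2, len(meth_genes))
    overlap_genes = list(
        rng.choice(meth_genes, size=n_from_meth, replace=False)
    ) if n_from_meth else []
    others = [g for g in genes if g not in meth_dir]
    extra = list(
        rng.choice(others, size=n_diff_expr - n_from_meth, replace=False)
    ) if n_diff_expr - n_from_meth else []
    expr_dir: dict[str, str] = {}
    for g in overlap_genes:  # inverse orientation: hypermethylated => low
        expr_dir[g] = "A<C" if meth_dir[g] == "A>C" else "A>C"
    for g in extra:
        expr_dir[g] = "A>C" if rng.random() < 0.5 else "A<C"

    # --- sample sheet --------------------------------------------------
    patients = [f"patient{p + 1}" for p in range(config.n_patients)]
    records = []
    for patient in patients:
        for zone in config.zones:
            for tissue in config.tissues:
                sid = f"{patient}_{zone}_{tissue}"
                records.append((sid, patient, tissue, zone))
    samples = pd.DataFrame(
        records, columns=["sample_id", "patient", "tissue", "zone"]
    ).set_index("sample_id")

    # --- beta values ----------------------------------------------------
    is_diff = probe_effect_dir.to_numpy() != 0
    base = np.empty(config.n_probes)
    base[~is_diff] = rng.uniform(0.05, 0.95, size=(~is_diff).sum())
    base[is_diff] = rng.uniform(0.2, 0.6, size=is_diff.sum())

    patient_u = rng.normal(
        0.0, config.patient_sd, size=(config.n_probes, config.n_patients)
    )
    beta_cols = {}
    for j, patient in enumerate(patients):
        for zone in config.zones:
            for tissue in config.tissues:
                mu = base.copy()
                if zone == zone_eff:
                    sign = probe_effect_dir.to_numpy()
                    if tissue == tissue_a:
                        mu = mu + np.where(
                            sign > 0, config.delta_beta_effect, 0.0
                        )
                    else:
                        mu = mu + np.where(
                            sign < 0, config.delta_beta_effect, 0.0
                        )
                eps = rng.normal(
                    0.0, _beta_noise_scale(mu, config.beta_noise_sd)
                )
                vals = _invlogit(_logit(mu) + patient_u[:, j] + eps)
                beta_cols[f"{patient}_{zone}_{tissue}"] = vals
    beta_values = pd.DataFrame(
        beta_cols, index=pd.Index(probe_ids, name="probe_id")
    )[samples.index]
    beta = BetaMatrix(values=beta_values, samples=samples.copy())

    # --- expression values ----------------------------------------------
    gene_base = rng.normal(8.0, 2.0, size=config.n_genes)
    gene_patient_u = rng.normal(
        0.0, 0.3, size=(config.n_genes, config.n_patients)
    )
    expr_sign = np.array(
        [1 if expr_dir.get(g) == "A>C" else -1 if expr_dir.get(g) == "A<C" else 0
         for g in genes]
    )
    expr_cols = {}
    for j, patient in enumerate(patients):
        for zone in config.zones:
            for tissue in config.tissues:
                mu = gene_base.copy()
                if zone == zone_eff:
                    if tissue == tissue_a:
                        mu = mu + np.where(
                            expr_sign > 0, config.log2fc_effect, 0.0
                        )
                    else:
                        mu = mu + np.where(
                            expr_sign < 0, config.log2fc_effect, 0.0
                        )
                vals = mu + gene_patient_u[:, j] + rng.normal(
                    0.0, config.expr_noise_sd, size=config.n_genes
                )
                expr_cols[f"{patient}_{zone}_{tissue}"] = vals
    expr_values = pd.DataFrame(
        expr_cols, index=pd.Index(genes, name="gene")
    )[samples.index]
    expr = ExpressionMatrix(
        values=expr_values, samples=samples.copy(), log2_scale=True
    )

    truth = GroundTruth(
        differential_probes=frozenset(diff_probes),
        differential_genes_meth=frozenset(meth_dir.items()),
        differential_genes_expr=frozenset(expr_dir.items()),
    )
    return beta, expr, manifest, truth


def generate_go_annotations(
    genes: Sequence[str],
    n_terms: int,
    enriched_term_spec: tuple[str, Sequence[str]] | None = None,
    base_rate: float = 0.03,
    seed: int = 0,
) -> pd.DataFrame:
    """Random gene->term annotation table with one optionally enriched term.

    Every term annotates each gene independently at ``base_rate``; the
    enriched term additionally annotates its whole target subset.  The
    subset must be contained in the gene universe.
    """
    if n_terms <= 0:
        raise ConfigurationError("n_terms must be positive")
    if not 0.0 <= base_rate <= 1.0:
        raise ConfigurationError("base_rate must be in [0, 1]")
    genes = list(genes)
    rng = np.random.default_rng(seed)
    rows = []
    enriched_id, subset = (None, frozenset())
    if enriched_term_spec is not None:
        enriched_id, target = enriched_term_spec
        subset = frozenset(target)
        outside = subset - set(genes)
        if outside:
            raise ConfigurationError(
                f"enriched subset not in gene universe: {sorted(outside)[:5]}"
            )
    for t in range(n_terms):
        term_id = f"TERM:{t:04d}"
        annotated = {g for g in genes if rng.random() < base_rate}
        if term_id == enriched_id:
            annotated |= subset
        for gene in sorted(annotated):
            rows.append((gene, term_id, f"synthetic process {t}", "biological_process"))
    if enriched_id is not None and not any(r[1] == enriched_id for r in rows):
        # enriched term id outside TERM:0000..  -> emit its subset anyway
        for gene in sorted(subset):
            rows.append((gene, enriched_id, "planted process", "biological_process"))
    return pd.DataFrame(
        rows, columns=["gene", "term_id", "term_name", "namespace"]
    )


def generate_utr(
    length: int,
    planted: Sequence[tuple[MiRNA, str, int]],
    seed: int = 0,
    max_attempts: int = 100,
) -> str:
    """Random 3'UTR containing exactly the planted canonical seed sites.

    ``planted`` lists (miRNA, site type, motif start) triples; motifs must
    be in bounds and non-overlapping.  Elsewhere, seed-complement cores of
    every planted miRNA are excluded by rejection/repair sampling, and the
    bases flanking each planted motif are fixed so the site scans at
    exactly its stated type.  The emitted sequence is re-scanned and must
    reproduce the planted site list exactly.
    """
    if length <= 0:
        raise ConfigurationError("length must be positive")
    spans = []
    for mirna, site_type, pos in planted:
        motif = site_motif(mirna, site_type)
        if pos < 0 or pos + len(motif) > length:
            raise ConfigurationError(
                f"site {site_type} for {mirna.name} at {pos} out of bounds"
            )
        spans.append((pos, pos + len(motif), mirna, site_type, motif))
    spans.sort()
    for (s1, e1, *_), (s2, e2, *_) in zip(spans, spans[1:]):
        if s2 < e1 + 2:  # +2: flank bases adjacent to motifs are fixed too
            raise ConfigurationError("planted sites overlap or touch")

    mirnas = {m.name: m for m, _, _ in planted}
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    for _ in range(max_attempts):
        seq = list(rng.choice(bases, size=length))
        protected: set[int] = set()
        for start, end, mirna, site_type, motif in spans:
            seq[start:end] = list(motif)
            protected.update(range(start, end))
            core = site_motif(mirna, "6mer")
            m8 = site_motif(mirna, "7mer-m8")[0]
            core_start = start + (1 if site_type in ("8mer", "7mer-m8") else 0)
            # fix flanks so the scanner cannot upgrade the site type
            if site_type in ("6mer", "7mer-A1") and core_start > 0:
                left = core_start - 1
                if left not in protected:
                    choices = [b for b in "ACGT" if b != m8]
                    seq[left] = choices[int(rng.integers(len(choices)))]
                    protected.add(left)
            if site_type in ("6mer", "7mer-m8") and core_start + 6 < length:
                right = core_start + 6
                if right not in protected:
                    choices = [b for b in "ACG" if b != "A"] + ["T"]
                    seq[right] = choices[int(rng.integers(len(choices)))]
                    protected.add(right)
        # repair accidental seed cores outside planted spans
        ok = _strip_accidental_cores(seq, mirnas.values(), protected, rng)
        if not ok:
            continue
        utr = "".join(seq)
        observed = []
        for mirna in mirnas.values():
            for site in scan_utr(utr, mirna, utr_id="utr"):
                observed.append((mirna.name, site.site_type, site.start))
        expected = [(m.name, st, pos) for m, st, pos in planted]
        if sorted(observed) == sorted(expected):
            return utr
    raise RuntimeError(
        "could not place planted sites cleanly; seeds may share cores"
    )


def _strip_accidental_cores(seq, mirnas, protected, rng, max_rounds=20) -> bool:
    for _ in range(max_rounds):
        dirty = False
        utr = "".join(seq)
        for mirna in mirnas:
            core = site_motif(mirna, "6mer")
            start = 0
            while True:
                i = utr.find(core, start)
                if i < 0:
                    break
                start = i + 1
                span = set(range(i, i + 6))
                if span <= protected:
                    continue
                mutable = sorted(span - protected)
                pos = mutable[len(mutable) // 2]
                current = seq[pos]
                seq[pos] = rng.choice([b for b in "ACGT" if b != current])
                dirty = True
        if not dirty:
            return True
    return False


@dataclass
class CobraTemplate:
    """Synthetic bisulfite-ready COBRA template.

    The amplicon interior uses only A/T/G except a single Taq I site
    (TCGA, CpG-containing), and primers avoid conversion-sensitive bases
    (no C on the forward strand, no G on the reverse primer), so the
    template is invariant under fully methylated bisulfite conversion —
    the primers are conversion-specific by construction, as bisulfite
    PCR primers are.
    """

    template: str
    fwd: str
    rev: str
    amplicon_length: int
    cut_pos: int


def generate_cobra_template(
    amplicon_len: int,
    cut_pos: int,
    primers: tuple[str, str] | None = None,
    seed: int = 0,
    flank: int = 30,
    primer_len: int = 22,
) -> CobraTemplate:
    """Template whose Taq I digestion yields fragments of ``cut_pos`` and
    ``amplicon_len - cut_pos`` under full methylation.

    The single TCGA site starts at ``cut_pos - 1`` (Taq I cuts T^CGA) and
    must not overlap the primer binding sites.
    """
    if not 0 < cut_pos < amplicon_len:
        raise ConfigurationError("need 0 < cut_pos < amplicon_len")
    rng = np.random.default_rng(seed)
    if primers is None:
        fwd = "".join(rng.choice(list("ATG"), size=primer_len))
        rev = "".join(rng.choice(list("ATC"), size=primer_len))
    else:
        fwd, rev = (p.upper() for p in primers)
        if "C" in fwd or "G" in rev:
            raise ConfigurationError(
                "primers must be bisulfite-compatible: no C in the forward "
                "primer, no G in the reverse primer"
            )
    if len(fwd) + len(rev) >= amplicon_len:
        raise ConfigurationError("primers longer than the amplicon")
    site_start = cut_pos - 1
    if site_start < len(fwd) or site_start + 4 > amplicon_len - len(rev):
        raise ConfigurationError(
            "Taq I site would overlap a primer binding site"
        )
    from .bisulfite import reverse_complement

    rev_rc = reverse_complement(rev)
    for _ in range(100):
        body = list(rng.choice(list("ATG"), size=amplicon_len))
        body[: len(fwd)] = list(fwd)
        body[amplicon_len - len(rev):] = list(rev_rc)
        body[site_start: site_start + 4] = list("TCGA")
        amplicon = "".join(body)
        left = "".join(rng.choice(list("ATG"), size=flank))
        right = "".join(rng.choice(list("ATG"), size=flank))
        template = left + amplicon + right
        if amplicon.count("TCGA") != 1:
            continue
        if template.count(fwd) != 1 or template.count(rev_rc) != 1:
            continue
        return CobraTemplate(
            template=template,
            fwd=fwd,
            rev=rev,
            amplicon_length=amplicon_len,
            cut_pos=cut_pos,
        )
    raise RuntimeError("could not build a clean COBRA template")
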