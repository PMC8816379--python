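"""Readers and writers for the pipeline's interchange formats.

All tabular outputs are TSV/CSV with a single commented header line (a
``#`` line stating column semantics and the 0-based half-open coordinate
convention); readers skip comment lines.  Sequences go through FASTA via
Biopython.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matrices import BetaMatrix, ExpressionMatrix, ValidationError, validate_manifest
from .mirna import MiRNA
from .synthetic import GroundTruth


def _write_table(df: pd.DataFrame, path, comment: str, sep: str = "\t",
                 index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, sep=sep, index=index)


def _read_table(path, sep: str = "\t", index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", index_col=index_col)


# --- beta / expression matrices -------------------------------------------

def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    _write_table(samples, path, "sample sheet: sample_id, patient, tissue, zone")


def read_sample_sheet(path) -> pd.DataFrame:
    return _read_table(path)


def write_beta_matrix(beta: BetaMatrix, matrix_path, sample_sheet_path) -> None:
    _write_table(
        beta.values, matrix_path,
        "beta-value matrix: rows probes, columns samples, values in [0,1]",
        sep=",",
    )
    write_sample_sheet(beta.samples, sample_sheet_path)


def read_beta_matrix(matrix_path, sample_sheet_path) -> BetaMatrix:
    """Read and validate a beta matrix plus its sample sheet.

    Out-of-range beta values and sample-sheet mismatches raise a
    :class:`~amniomics.matrices.ValidationError` naming the offenders.
    """
    values = _read_table(matrix_path, sep=",")
    samples = read_sample_sheet(sample_sheet_path)
    return BetaMatrix(values=values, samples=samples)


def write_expression_matrix(expr: ExpressionMatrix, matrix_path,
                            sample_sheet_path) -> None:
    scale = "log2" if expr.log2_scale else "linear"
    _write_table(
        expr.values, matrix_path,
        f"expression matrix ({scale} scale): rows genes, columns samples",
        sep=",",
    )
    write_sample_sheet(expr.samples, sample_sheet_path)


def read_expression_matrix(matrix_path, sample_sheet_path,
                           log2_scale: bool = True) -> ExpressionMatrix:
    values = _read_table(matrix_path, sep=",")
    samples = read_sample_sheet(sample_sheet_path)
    return ExpressionMatrix(values=values, samples=samples, log2_scale=log2_scale)


# --- manifest / annotations / gene sets -----------------------------------

def write_manifest(manifest: pd.DataFrame, path) -> None:
    _write_table(
        validate_manifest(manifest), path,
        "probe manifest: probe_id, chrom, pos (0-based), strand, gene, region",
    )


def read_manifest(path) -> pd.DataFrame:
    manifest = _read_table(path)
    manifest["gene"] = manifest["gene"].fillna("")
    return validate_manifest(manifest)


def write_annotations(ann: pd.DataFrame, path) -> None:
    _write_table(ann, path, "annotations: gene, term_id, term_name, namespace",
                 index=False)


def read_annotations(path) -> pd.DataFrame:
    return _read_table(path, index_col=None)


def write_gene_set(genes: Iterable[str], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_gene_set(path) -> frozenset:
    lines = Path(path).read_text().splitlines()
    return frozenset(l.strip() for l in lines if l.strip() and not l.startswith("#"))


# --- ground truth -----------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path) -> None:
    rows = (
        [("probe", p, d) for p, d in sorted(truth.differential_probes)]
        + [("gene_meth", g, d) for g, d in sorted(truth.differential_genes_meth)]
        + [("gene_expr", g, d) for g, d in sorted(truth.differential_genes_expr)]
        + [
            ("site", f"{utr}:{mirna}:{stype}", str(pos))
            for utr, mirna, stype, pos in truth.planted_sites
        ]
    )
    _write_table(
        pd.DataFrame(rows, columns=["kind", "id", "direction"]),
        path,
        "planted ground truth: kind in {probe, gene_meth, gene_expr, site}; "
        "directions oriented tissueA - tissueB",
        index=False,
    )


def read_ground_truth(path) -> GroundTruth:
    df = _read_table(path, index_col=None)
    probes, gm, ge, sites = set(), set(), set(), []
    for _, row in df.iterrows():
        kind, ident, direction = row["kind"], row["id"], row["direction"]
        if kind == "probe":
            probes.add((ident, direction))
        elif kind == "gene_meth":
            gm.add((ident, direction))
        elif kind == "gene_expr":
            ge.add((ident, direction))
        elif kind == "site":
            utr, mirna, stype = ident.split(":")
            sites.append((utr, mirna, stype, int(direction)))
        else:
            raise ValidationError(f"unknown ground-truth kind {kind!r}")
    return GroundTruth(
        differential_probes=frozenset(probes),
        differential_genes_meth=frozenset(gm),
        differential_genes_expr=frozenset(ge),
        planted_sites=sites,
    )


# --- sequences --------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_mirnas(path) -> list[MiRNA]:
    """miRNA definitions TSV: columns name, mature_seq."""
    df = _read_table(path, index_col=None)
    return [MiRNA(row["name"], row["mature_seq"]) for _, row in df.iterrows()]


def write_mirnas(mirnas: Iterable[MiRNA], path) -> None:
    df = pd.DataFrame(
        [(m.name, m.mature_seq) for m in mirnas], columns=["name", "mature_seq"]
    )
    _write_table(df, path, "miRNA definitions: name, mature sequence 5'->3'",
                 index=False)


# --- bundled fixtures --------------------------------------------------------

_DATA_DIR = Path(__file__).parent / "data"


def bundled_tlr4_utr() -> tuple[str, str]:
    """The bundled synthetic TLR4 3'UTR stand-in (id, sequence).

    A 2,223-nt synthetic surrogate for the TLR4 3'UTR with one canonical
    seed site planted for each of let-7a and miR-125b; see the FASTA
    header.
    """
    seqs = read_fasta(_DATA_DIR / "tlr4_3utr_synthetic.fasta")
    (name, seq), = seqs.items()
    return name, seq


def bundled_mirnas() -> list[MiRNA]:
    """Mature let-7a-5p and miR-125b-5p definitions."""
    return read_mirnas(_DATA_DIR / "mirnas.tsv")
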