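"""Hypergeometric over-representation analysis of gene sets.

Given a study set drawn from a population universe and a gene->term
annotation table, each term is tested with the upper-tail hypergeometric
probability P(X >= k) for k study hits out of K population hits, study
size n and population size N, with Bonferroni (default), Benjamini-
Hochberg or no correction.  The engine is term-agnostic: GO biological
processes, MeSH-style disease terms or any other annotation table all go
through the same test.
"""

from __future__ import annotations

import logging
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import adjust_pvalues

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ("gene", "term_id", "term_name", "namespace")


def validate_annotations(ann: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    return ann


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts annotated genes in a size-n draw without replacement from a
    population of N genes of which K are annotated.  Computed via the
    log-space survival function; k = 0 gives exactly 1.
    """
    if not (0 <= k <= min(n, K) and K <= N and n <= N):
        raise ValueError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N} "
            "(need 0 <= k <= min(n, K), K <= N, n <= N)"
        )
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy evaluates the tail stably
    return float(min(1.0, sps.hypergeom.sf(k - 1, N, K, n)))


def enrich(
    study: Iterable[str],
    population: Iterable[str],
    ann: pd.DataFrame,
    correction: Literal["bonferroni", "none", "bh"] = "bonferroni",
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Over-representation test of every annotated term in the study set.

    The population is the gene universe (by default the platform's tested
    genes, not the genome); the study set must be contained in it.  Terms
    with zero population hits are skipped and excluded from the
    correction multiplier.  Returns one row per tested term, sorted by
    adjusted then raw p.
    """
    study = set(study)
    population = set(population)
    offenders = sorted(study - population)
    if offenders:
        raise ValueError(
            f"{len(offenders)} study genes absent from the population, "
            f"e.g. {offenders[:5]}"
        )
    validate_annotations(ann)
    ann = ann[ann["gene"].isin(population)]
    n, N = len(study), len(population)
    rows = []
    for (term_id, term_name, namespace), sub in ann.groupby(
        ["term_id", "term_name", "namespace"], sort=True
    ):
        genes = set(sub["gene"])
        K = len(genes)
        if K == 0:  # pragma: no cover - filtered above
            continue
        k = len(genes & study)
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "namespace": namespace,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeom_upper(k, K, n, N),
                "study_genes": ",".join(sorted(genes & study)),
            }
        )
    if not rows:
        logger.info("no term has a population hit; empty result")
    result = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "namespace", "k", "K", "n", "N",
                 "p", "study_genes"],
    )
    if len(result):
        result["adj_p"] = adjust_pvalues(result["p"].to_numpy(), correction)
        compare = result["adj_p"] if correction != "none" else result["p"]
        result["significant"] = compare < alpha
        result = result.sort_values(
            ["adj_p", "p", "term_id"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        result["adj_p"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result
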