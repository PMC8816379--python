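"""Four-way Venn partitioning and methylome x transcriptome intersection.

The methylome analysis yields, per zone, two direction-labelled gene sets
(more methylated in amnion than choriodecidua, and the converse); the
four sets across the two zones are partitioned into their 15 non-empty
membership patterns, from which zone-specific gene sets are read off.
Crossing the methylome calls with the differential-expression classes
yields the inverse-correlation gene lists (hypermethylated in one layer,
over-expressed in the other).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Mapping

import pandas as pd

from .methylome import GeneCallSets


@dataclass
class VennPartition:
    """Exact partition of the union of four named sets by membership
    pattern (patterns are frozensets of set names)."""

    input_sets: dict[str, frozenset]
    region_members: dict[frozenset, frozenset]

    @property
    def region_sizes(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.region_members.items()}

    def region(self, *names: str) -> frozenset:
        """Members belonging to exactly the named sets and no others."""
        return self.region_members.get(frozenset(names), frozenset())


def venn4(sets: Mapping[str, Iterable[str]]) -> VennPartition:
    """Partition four named gene sets by exact membership pattern."""
    names = list(sets)
    if len(names) != 4:
        raise ValueError(f"need exactly 4 named sets, got {len(names)}")
    if len(set(names)) != 4:
        raise ValueError("set names must be distinct")
    frozen = {name: frozenset(sets[name]) for name in names}
    regions: dict[frozenset, set] = {}
    for gene in frozenset().union(*frozen.values()):
        pattern = frozenset(n for n in names if gene in frozen[n])
        regions.setdefault(pattern, set()).add(gene)
    return VennPartition(
        input_sets=frozen,
        region_members={k: frozenset(v) for k, v in regions.items()},
    )


def zone_specific(
    partition: VennPartition,
    zone: str,
    zone_of: Mapping[str, str] | None = None,
) -> frozenset:
    """Union of Venn regions whose pattern involves only one zone's sets.

    ``zone_of`` maps each input-set name to its zone; by default the zone
    is the prefix of the set name before the first underscore (e.g.
    ``"ZAM_mA>mC"`` -> ``"ZAM"``).
    """
    if zone_of is None:
        zone_of = {name: name.split("_", 1)[0] for name in partition.input_sets}
    zones = set(zone_of.values())
    if zone not in zones:
        raise ValueError(f"unknown zone {zone!r}; known zones: {sorted(zones)}")
    members: set = set()
    for pattern, genes in partition.region_members.items():
        if pattern and all(zone_of[name] == zone for name in pattern):
            members |= genes
    return frozenset(members)


def _canon(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass
class CrossOmicsResult:
    """Genes with inverse methylation/expression between the two layers.

    ``hyperA_upC``: hypermethylated in tissue A (amnion) and more
    expressed in tissue B (choriodecidua); ``hyperC_upA`` is the
    converse.  ``provenance`` keeps, per gene, the supporting probe
    records and the expression row.  ``untested`` counts methylome genes
    absent from the expression table (reconciliation report).
    """

    hyperA_upC: frozenset
    hyperC_upA: frozenset
    provenance: dict[str, dict] = field(default_factory=dict)
    untested: frozenset = frozenset()


def cross_omics(
    meth: GeneCallSets,
    expr_table: pd.DataFrame,
    orientation: str = "amnion_first",
    synonym_map: Mapping[str, str] | None = None,
) -> CrossOmicsResult:
    """Intersect methylome direction calls with expression classes.

    ``expr_table`` is a differential-expression table indexed by gene
    with a ``class`` column (up/down/unclassified), oriented tissue A -
    tissue B like the methylome calls.  Gene symbols are matched
    case-insensitively, optionally through a synonym map applied to both
    sides.  ``orientation="choriodecidua_first"`` flips the two output
    sets (for inputs computed with the opposite tissue ordering).
    """
    if orientation not in ("amnion_first", "choriodecidua_first"):
        raise ValueError(f"unknown orientation {orientation!r}")
    synonym_map = {_canon(k): _canon(v) for k, v in (synonym_map or {}).items()}

    def canon(symbol: str) -> str:
        c = _canon(symbol)
        return synonym_map.get(c, c)

    expr_class: dict[str, str] = {}
    expr_row: dict[str, pd.Series] = {}
    for gene, row in expr_table.iterrows():
        key = canon(str(gene))
        expr_class[key] = row["class"]
        expr_row[key] = row

    def intersect(meth_set: frozenset, wanted_class: str) -> tuple[set, set]:
        hits, untested = set(), set()
        for gene in meth_set:
            key = canon(gene)
            if key not in expr_class:
                untested.add(gene)
            elif expr_class[key] == wanted_class:
                hits.add(key)
        return hits, untested

    # hypermethylated in A & higher expressed in B  <=>  class "down" (A - B)
    hyper_a, untested_a = intersect(meth.mA_gt_mC, "down")
    hyper_c, untested_c = intersect(meth.mA_lt_mC, "up")
    if orientation == "choriodecidua_first":
        hyper_a, hyper_c = hyper_c, hyper_a

    provenance: dict[str, dict] = {}
    for gene in sorted(hyper_a | hyper_c):
        probes = [
            rec
            for orig, recs in meth.supporting_probes.items()
            if canon(orig) == gene
            for rec in recs
        ]
        provenance[gene] = {
            "probes": probes,
            "expression": expr_row[gene].to_dict(),
        }
    return CrossOmicsResult(
        hyperA_upC=frozenset(hyper_a),
        hyperC_upA=frozenset(hyper_c),
        provenance=provenance,
        untested=frozenset(untested_a | untested_c),
    )
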