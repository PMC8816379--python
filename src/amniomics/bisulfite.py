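"""In-silico bisulfite conversion, virtual PCR and restriction digestion.

Models the COBRA assay (combined bisulfite restriction analysis): bisulfite
treatment deaminates unmethylated cytosines to uracil (read as thymine
after PCR) while 5-methylcytosine — in practice CpG cytosines — is
protected.  Because the Taq I recognition site TCGA contains a CpG, the
site survives conversion only when that CpG is methylated, so digestion of
the bisulfite PCR product reports the methylation state of the template.

Only the top strand is modelled; primers are matched exactly against the
converted strand (bisulfite PCR primers are conversion-specific by design).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple

DNA_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_VALID_DNA = set("ACGTRYSWKMBDHVN")


class Enzyme(NamedTuple):
    """Restriction enzyme: recognition sequence and cut offset from the
    5' end of the site on the top strand."""

    name: str
    site: str
    cut_offset: int


#: Taq I cuts T^CGA — offset 1, and the site contains a CpG.
TAQ1 = Enzyme("TaqI", "TCGA", 1)


def reverse_complement(seq: str) -> str:
    return seq.translate(DNA_COMPLEMENT)[::-1]


def _check_dna(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID_DNA
    if bad:
        raise ValueError(f"invalid characters in {what}: {sorted(bad)}")
    return seq


@dataclass
class MethylationState:
    """Which CpG cytosines are methylated on the top strand.

    ``mode`` is ``all_methylated``, ``all_unmethylated`` or ``explicit``;
    in explicit mode ``methylated_positions`` lists 0-based coordinates of
    cytosines that must sit in CpG context.
    """

    mode: Literal["all_methylated", "all_unmethylated", "explicit"]
    methylated_positions: frozenset[int] = field(default_factory=frozenset)

    def is_methylated(self, pos: int) -> bool:
        if self.mode == "all_methylated":
            return True
        if self.mode == "all_unmethylated":
            return False
        return pos in self.methylated_positions


def bisulfite_convert(seq: str, state: MethylationState) -> str:
    """Convert the top strand: every C becomes T except methylated CpG
    cytosines.  IUPAC ambiguity codes pass through unchanged."""
    seq = _check_dna(seq)
    if state.mode == "explicit":
        for pos in state.methylated_positions:
            if pos < 0 or pos >= len(seq) or seq[pos] != "C" or (
                pos + 1 >= len(seq) or seq[pos + 1] != "G"
            ):
                raise ValueError(
                    f"explicit methylated position {pos} is not a CpG "
                    "cytosine on the top strand"
                )
    out = list(seq)
    for i, base in enumerate(out):
        if base != "C":
            continue
        in_cpg = i + 1 < len(seq) and seq[i + 1] == "G"
        if not (in_cpg and state.is_methylated(i)):
            out[i] = "T"
    return "".join(out)


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return hits
        hits.append(idx)
        start = idx + 1


def virtual_pcr(template: str, fwd: str, rev: str) -> str:
    """Exact-match virtual PCR on the top strand.

    The forward primer must occur exactly once; the reverse complement of
    the reverse primer must occur exactly once downstream of it.  Returns
    the amplicon spanning both primer binding sites inclusive.
    """
    template = _check_dna(template, "template")
    fwd = _check_dna(fwd, "forward primer")
    rev = _check_dna(rev, "reverse primer")
    fwd_hits = _find_all(template, fwd)
    if len(fwd_hits) != 1:
        raise ValueError(
            f"forward primer binds {len(fwd_hits)} times (need exactly 1)"
        )
    rev_rc = reverse_complement(rev)
    rev_hits = [h for h in _find_all(template, rev_rc) if h >= fwd_hits[0]]
    if len(rev_hits) != 1:
        raise ValueError(
            f"reverse primer binds {len(rev_hits)} times downstream of the "
            "forward primer (need exactly 1)"
        )
    return template[fwd_hits[0]: rev_hits[0] + len(rev_rc)]


@dataclass
class FragmentSet:
    """Restriction fragments of one amplicon.

    Invariants: fragment lengths sum to the amplicon length and there is
    exactly one more fragment than cut.
    """

    amplicon_length: int
    cut_positions: list[int]
    fragment_lengths: list[int]

    def __post_init__(self) -> None:
        assert sum(self.fragment_lengths) == self.amplicon_length
        assert len(self.fragment_lengths) == len(self.cut_positions) + 1


def digest(amplicon: str, enzyme: Enzyme = TAQ1) -> FragmentSet:
    """Cut at every non-overlapping occurrence of the recognition site
    (located left to right).  No site means a single full-length
    fragment."""
    amplicon = _check_dna(amplicon, "amplicon")
    if not enzyme.site:
        raise ValueError("enzyme recognition sequence is empty")
    cuts, start = [], 0
    while True:
        idx = amplicon.find(enzyme.site, start)
        if idx < 0:
            break
        cuts.append(idx + enzyme.cut_offset)
        start = idx + len(enzyme.site)
    bounds = [0] + cuts + [len(amplicon)]
    lengths = sorted(
        (bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)),
        reverse=True,
    )
    return FragmentSet(
        amplicon_length=len(amplicon),
        cut_positions=cuts,
        fragment_lengths=lengths,
    )


def cobra_predict(
    template: str,
    fwd: str,
    rev: str,
    state: MethylationState,
    enzyme: Enzyme = TAQ1,
) -> FragmentSet:
    """Full COBRA prediction: bisulfite conversion under ``state``,
    virtual PCR with conversion-specific primers, then digestion.

    Because TCGA contains a CpG, an entirely unmethylated template loses
    every Taq I site during conversion and yields a single uncut
    fragment.
    """
    converted = bisulfite_convert(template, state)
    amplicon = virtual_pcr(converted, fwd, rev)
    return digest(amplicon, enzyme)
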