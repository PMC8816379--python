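"""Seed-site scanning, site-type hierarchy and the concordance screen."""

import numpy as np
import pandas as pd
import pytest

from amniomics import MiRNA, generate_utr, mirna_gene_methylation, scan_utr, site_motif
from amniomics.bisulfite import reverse_complement
from amniomics.io import bundled_mirnas, bundled_tlr4_utr
from amniomics.mirna import nominate_candidates

LET7A = MiRNA("hsa-let-7a-5p", "UGAGGUAGUAGGUUGUAUAGUU")
MIR125B = MiRNA("hsa-miR-125b-5p", "UCCCUGAGACCCUAACUUGUGA")


class TestMotifs:
    def test_known_let7a_motifs(self):
        # seed 2-7 GAGGUA -> UTR core TACCTC; m8 complement C; A1 anchor A
        assert site_motif(LET7A, "6mer") == "TACCTC"
        assert site_motif(LET7A, "7mer-m8") == "CTACCTC"
        assert site_motif(LET7A, "7mer-A1") == "TACCTCA"
        assert site_motif(LET7A, "8mer") == "CTACCTCA"

    @pytest.mark.parametrize("mirna", [LET7A, MIR125B])
    def test_hierarchy_by_truncation(self, mirna):
        """8mer truncations reproduce the 7mer motifs; both 7mers contain
        the 6mer core."""
        m8 = site_motif(mirna, "8mer")
        assert m8[:-1] == site_motif(mirna, "7mer-m8")
        assert m8[1:] == site_motif(mirna, "7mer-A1")
        assert site_motif(mirna, "6mer") in site_motif(mirna, "7mer-m8")
        assert site_motif(mirna, "6mer") in site_motif(mirna, "7mer-A1")

    def test_u_t_representation_invariance(self):
        as_dna = MiRNA("let7a-dna", LET7A.mature_seq.replace("U", "T"))
        utr = generate_utr(300, [(LET7A, "7mer-A1", 120)], seed=3)
        sites_rna = scan_utr(utr, LET7A)
        sites_dna = scan_utr(utr, as_dna)
        assert [(s.site_type, s.start, s.end) for s in sites_rna] == [
            (s.site_type, s.start, s.end) for s in sites_dna
        ]

    def test_short_mature_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            MiRNA("bad", "UGAGGUA")


class TestScanner:
    def test_no_seed_complement_empty(self):
        utr = generate_utr(500, [], seed=0)
        # background generation excludes nothing when no site is planted,
        # so scrub any accidental cores by checking against a clean string
        clean = utr.replace(site_motif(LET7A, "6mer"), "AAAAAA")
        assert scan_utr(clean, LET7A) == []

    @pytest.mark.parametrize("site_type", ["8mer", "7mer-m8", "7mer-A1", "6mer"])
    def test_planted_site_recovered_exactly(self, site_type):
        utr = generate_utr(400, [(LET7A, site_type, 100)], seed=1)
        sites = scan_utr(utr, LET7A)
        assert len(sites) == 1
        assert sites[0].site_type == site_type
        assert sites[0].start == 100
        assert utr[sites[0].start: sites[0].end] == site_motif(LET7A, site_type)

    def test_two_mirnas_attributed_correctly(self):
        utr = generate_utr(
            600, [(LET7A, "8mer", 100), (MIR125B, "7mer-m8", 400)], seed=2
        )
        s1 = scan_utr(utr, LET7A)
        s2 = scan_utr(utr, MIR125B)
        assert [(s.site_type, s.start) for s in s1] == [("8mer", 100)]
        assert [(s.site_type, s.start) for s in s2] == [("7mer-m8", 400)]

    def test_reverse_complement_not_double_reported(self):
        utr = generate_utr(400, [(LET7A, "8mer", 150)], seed=4)
        fwd_sites = {(s.site_type, s.start) for s in scan_utr(utr, LET7A)}
        rc_sites = {(s.site_type, s.start)
                    for s in scan_utr(reverse_complement(utr), LET7A)}
        assert ("8mer", 150) in fwd_sites
        assert ("8mer", 150) not in rc_sites

    def test_invalid_utr_alphabet_rejected(self):
        with pytest.raises(ValueError, match="DNA"):
            scan_utr("ACGU", LET7A)

    def test_tlr4_fixture_has_sites_for_both_mirnas(self):
        """The bundled synthetic TLR4 3'UTR yields >= 1 canonical site for
        each of let-7a and miR-125b."""
        _, utr = bundled_tlr4_utr()
        assert len(utr) == 2223
        for mirna in bundled_mirnas():
            sites = scan_utr(utr, mirna)
            assert len(sites) >= 1
            assert all(s.site_type in ("8mer", "7mer-m8", "7mer-A1", "6mer")
                       for s in sites)


class TestMethylationScreen:
    def test_shifted_probes_give_direction(self, small_cohort):
        beta, _, manifest, _ = small_cohort
        # pick three probes and shift choriodecidua by +0.2 in ZAM
        probes = list(beta.values.index[:3])
        values = beta.values.copy()
        zam_c = beta.samples.index[
            (beta.samples["zone"] == "ZAM")
            & (beta.samples["tissue"] == "choriodecidua")
        ]
        values.loc[probes, zam_c] = (values.loc[probes, zam_c] + 0.2).clip(0, 1)
        from amniomics import BetaMatrix

        shifted = BetaMatrix(values=values, samples=beta.samples.copy())
        per_probe, summary = mirna_gene_methylation(
            shifted, {p: "MIR-like" for p in probes}, zone="ZAM"
        )
        assert len(per_probe) == 3
        assert summary.loc[0, "direction"] == "mA<mC"

    def test_identical_tissues_flagged(self, small_cohort):
        beta, _, _, _ = small_cohort
        probes = list(beta.values.index[:2])
        values = beta.values.copy()
        for patient in beta.samples["patient"].unique():
            a = f"{patient}_ZAM_amnion"
            c = f"{patient}_ZAM_choriodecidua"
            values.loc[probes, c] = values.loc[probes, a].to_numpy()
        from amniomics import BetaMatrix

        flat = BetaMatrix(values=values, samples=beta.samples.copy())
        with pytest.warns(UserWarning):
            per_probe, summary = mirna_gene_methylation(
                flat, {p: "MIRX" for p in probes}, zone="ZAM"
            )
        assert (per_probe["p"] == 1.0).all()
        assert summary.loc[0, "direction"] == "undetermined"


class TestNomination:
    def _summary(self, direction):
        return pd.DataFrame(
            {"mirna_gene": ["MIR125B1"], "n_probes": [6],
             "median_delta_beta": [-0.2 if direction == "mA<mC" else 0.2],
             "n_significant": [5], "direction": [direction]}
        )

    def _expr(self, cls):
        return pd.DataFrame({"log2_fc": [-4.0 if cls == "down" else 4.0],
                             "class": [cls]}, index=["TLR4"])

    def _sites(self, site_type="8mer"):
        utr = generate_utr(300, [(MIR125B, site_type, 50)], seed=9)
        return scan_utr(utr, MIR125B, utr_id="TLR4_utr")

    def test_no_sites_empty(self):
        assert nominate_candidates(
            [], self._summary("mA<mC"), self._expr("down"), {}
        ) == []

    def test_concordant_triple(self):
        """miRNA gene hypermethylated in choriodecidua, target higher in
        choriodecidua, one 8mer site -> concordant candidate."""
        cands = nominate_candidates(
            self._sites(), self._summary("mA<mC"), self._expr("down"),
            utr_gene_map={"TLR4_utr": "TLR4"},
            mirna_gene_map={"hsa-miR-125b-5p": "MIR125B1"},
        )
        assert len(cands) == 1
        assert cands[0].target_gene == "TLR4"
        assert cands[0].n_sites == 1
        assert cands[0].concordant

    def test_discordant_triple(self):
        cands = nominate_candidates(
            self._sites(), self._summary("mA>mC"), self._expr("down"),
            utr_gene_map={"TLR4_utr": "TLR4"},
            mirna_gene_map={"hsa-miR-125b-5p": "MIR125B1"},
        )
        assert not cands[0].concordant

    def test_6mer_excluded_by_default(self):
        cands = nominate_candidates(
            self._sites("6mer"), self._summary("mA<mC"), self._expr("down"),
            utr_gene_map={"TLR4_utr": "TLR4"},
        )
        assert cands == []

    def test_unmapped_utr_rejected(self):
        with pytest.raises(ValueError, match="gene mapping"):
            nominate_candidates(
                self._sites(), self._summary("mA<mC"), self._expr("down"), {}
            )
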