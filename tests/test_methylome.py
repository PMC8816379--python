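"""Paired delta-beta, Monte-Carlo limits, probe selection and gene calls."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from amniomics import (
    BetaMatrix,
    PairedMethylationModel,
    call_genes,
    monte_carlo_limits,
    paired_delta_beta,
    select_probes,
)
from amniomics.matrices import ValidationError

from conftest import make_beta, make_manifest


class TestPairedDeltaBeta:
    def test_identical_tissues_zero_delta(self):
        beta = make_beta({"p1": [0, 0, 0], "p2": [0, 0, 0]}, n_pairs=3)
        dbt = paired_delta_beta(beta, "ZAM", "amnion", "choriodecidua")
        assert (dbt["delta_beta"] == 0).all()
        assert (dbt["p_value"] == 1.0).all()  # zero-variance policy

    def test_tissue_swap_antisymmetry(self):
        beta = make_beta({"p1": [0.1, 0.15, 0.3], "p2": [-0.2, 0.1, 0.05]},
                         n_pairs=3)
        fwd = paired_delta_beta(beta, "ZAM", "amnion", "choriodecidua")
        rev = paired_delta_beta(beta, "ZAM", "choriodecidua", "amnion")
        np.testing.assert_allclose(fwd["delta_beta"], -rev["delta_beta"])
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"])

    def test_three_pair_closed_form(self):
        """Differences (0.1, 0.2, 0.3): delta-beta 0.2 and p from the
        closed-form paired t with 2 df."""
        beta = make_beta({"p1": [0.1, 0.2, 0.3]}, n_pairs=3)
        dbt = paired_delta_beta(beta, "ZAM", "amnion", "choriodecidua")
        assert dbt["delta_beta"].iloc[0] == pytest.approx(0.2)
        t_hand = 0.2 / (0.1 / np.sqrt(3))
        p_hand = 2 * sps.t.sf(t_hand, df=2)
        assert dbt["p_value"].iloc[0] == pytest.approx(p_hand)
        assert dbt["n_pairs"].iloc[0] == 3

    def test_unpaired_patient_named_in_error(self, small_cohort):
        beta, _, _, _ = small_cohort
        broken = BetaMatrix(
            values=beta.values.drop(columns=["patient3_ZAM_amnion"]),
            samples=beta.samples.drop(index=["patient3_ZAM_amnion"]),
        )
        with pytest.raises(ValidationError, match="patient3"):
            paired_delta_beta(broken, "ZAM", "amnion", "choriodecidua")

    def test_single_pair_rejected(self):
        beta = make_beta({"p1": [0.1]}, n_pairs=1)
        with pytest.raises(ValidationError, match=">= 2"):
            paired_delta_beta(beta, "ZAM", "amnion", "choriodecidua")


def enumerate_limits(diffs_by_probe, chrom_of):
    """Exact per-chromosome extremes over all 2^n sign patterns."""
    probes = list(diffs_by_probe)
    n = len(next(iter(diffs_by_probe.values())))
    limits = {}
    for signs in product((-1, 1), repeat=n):
        null_db = {
            p: float(np.mean([s * d for s, d in zip(signs, diffs_by_probe[p])]))
            for p in probes
        }
        for chrom in set(chrom_of.values()):
            vals = [null_db[p] for p in probes if chrom_of[p] == chrom]
            lo, hi = limits.get(chrom, (np.inf, -np.inf))
            limits[chrom] = (min(lo, min(vals)), max(hi, max(vals)))
    return limits


class TestMonteCarloLimits:
    def test_constant_matrix_gives_zero_limits(self):
        beta = make_beta({"p1": [0, 0, 0], "p2": [0, 0, 0]}, n_pairs=3)
        manifest = make_manifest(["p1", "p2"])
        lim = monte_carlo_limits(beta, "ZAM", "amnion", "choriodecidua",
                                 manifest, n_iterations=50, seed=0)
        assert (lim["m"] == 0).all() and (lim["M"] == 0).all()

    @pytest.mark.parametrize("n_pairs", [2, 3, 4])
    def test_extreme_limits_match_sign_flip_enumeration(self, n_pairs):
        """With few pairs, many extreme-aggregation iterations converge to
        the exhaustive enumeration over all 2^n sign patterns."""
        rng = np.random.default_rng(n_pairs)
        diffs = {
            f"p{i}": list(np.round(rng.normal(0, 0.1, size=n_pairs), 3))
            for i in range(6)
        }
        chrom_of = {f"p{i}": ("chr1" if i < 3 else "chr2") for i in range(6)}
        beta = make_beta(diffs, n_pairs=n_pairs)
        manifest = make_manifest(list(diffs), chrom_of=chrom_of)
        lim = monte_carlo_limits(beta, "ZAM", "amnion", "choriodecidua",
                                 manifest, n_iterations=2000, seed=1)
        exact = enumerate_limits(diffs, chrom_of)
        for chrom, (m_ex, M_ex) in exact.items():
            assert lim.loc[chrom, "m"] == pytest.approx(m_ex, abs=1e-9)
            assert lim.loc[chrom, "M"] == pytest.approx(M_ex, abs=1e-9)

    def test_monte_carlo_limits_bounded_by_enumeration(self):
        """At few iterations the sampled limits lie inside the exact ones."""
        rng = np.random.default_rng(9)
        diffs = {f"p{i}": list(rng.normal(0, 0.1, size=4)) for i in range(4)}
        chrom_of = {p: "chr1" for p in diffs}
        beta = make_beta(diffs, n_pairs=4)
        manifest = make_manifest(list(diffs), chrom_of=chrom_of)
        lim = monte_carlo_limits(beta, "ZAM", "amnion", "choriodecidua",
                                 manifest, n_iterations=5, seed=2)
        exact = enumerate_limits(diffs, chrom_of)
        assert lim.loc["chr1", "m"] >= exact["chr1"][0] - 1e-12
        assert lim.loc["chr1", "M"] <= exact["chr1"][1] + 1e-12

    def test_negation_maps_limits_to_mirror(self):
        diffs = {"p1": [0.1, -0.2, 0.3], "p2": [0.05, 0.07, -0.01]}
        neg = {k: [-x for x in v] for k, v in diffs.items()}
        manifest = make_manifest(list(diffs))
        lim = monte_carlo_limits(make_beta(diffs, 3), "ZAM", "amnion",
                                 "choriodecidua", manifest,
                                 n_iterations=300, seed=3)
        lim_neg = monte_carlo_limits(make_beta(neg, 3), "ZAM", "amnion",
                                     "choriodecidua", manifest,
                                     n_iterations=300, seed=3)
        assert lim_neg.loc["chr1", "m"] == pytest.approx(-lim.loc["chr1", "M"])
        assert lim_neg.loc["chr1", "M"] == pytest.approx(-lim.loc["chr1", "m"])

    def test_quantile_mode_inside_extremes(self):
        rng = np.random.default_rng(4)
        diffs = {f"p{i}": list(rng.normal(0, 0.1, size=6)) for i in range(10)}
        manifest = make_manifest(list(diffs))
        beta = make_beta(diffs, 6)
        ext = monte_carlo_limits(beta, "ZAM", "amnion", "choriodecidua",
                                 manifest, n_iterations=500, seed=5,
                                 aggregation="extreme")
        qua = monte_carlo_limits(beta, "ZAM", "amnion", "choriodecidua",
                                 manifest, n_iterations=500, seed=5,
                                 aggregation="quantile", quantile_level=0.05)
        assert qua.loc["chr1", "m"] >= ext.loc["chr1", "m"]
        assert qua.loc["chr1", "M"] <= ext.loc["chr1", "M"]


class TestSelectProbes:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["delta_beta", "p_value"],
            index=pd.Index([f"cg{i}" for i in range(len(rows))],
                           name="probe_id"),
        ).assign(n_pairs=9)

    def _limits(self, m, M):
        return pd.DataFrame({"m": [m], "M": [M]}, index=pd.Index(["chr1"],
                                                                 name="chrom"))

    def test_inside_limits_excluded_despite_tiny_p(self):
        dbt = self._frame([(0.05, 1e-10)])
        sel = select_probes(dbt, self._limits(-0.1, 0.1),
                            make_manifest(["cg0"]))
        assert len(sel) == 0

    def test_boundary_p_excluded(self):
        dbt = self._frame([(0.5, 0.05)])
        sel = select_probes(dbt, self._limits(-0.1, 0.1),
                            make_manifest(["cg0"]), alpha=0.05)
        assert len(sel) == 0

    def test_hand_truth_table(self):
        """Ten hand-set probes: the retained set is exactly the conjunction
        p < alpha AND delta-beta outside [m, M]."""
        rows = [
            (0.30, 0.001), (0.30, 0.20), (0.05, 0.001), (-0.30, 0.001),
            (-0.05, 0.001), (0.101, 0.049), (0.10, 0.001), (-0.101, 0.0499),
            (0.0, 0.5), (0.25, 0.05),
        ]
        dbt = self._frame(rows)
        manifest = make_manifest(list(dbt.index))
        sel = select_probes(dbt, self._limits(-0.1, 0.1), manifest, alpha=0.05)
        expected = {
            f"cg{i}" for i, (db, p) in enumerate(rows)
            if p < 0.05 and (db < -0.1 or db > 0.1)
        }
        assert set(sel.index) == expected == {"cg0", "cg3", "cg5", "cg7"}
        # sorted by |delta beta| desc, ties by probe id
        assert list(sel.index) == ["cg0", "cg3", "cg5", "cg7"]

    def test_missing_chromosome_limits_rejected(self):
        dbt = self._frame([(0.3, 0.001)])
        manifest = make_manifest(["cg0"], chrom_of={"cg0": "chr9"})
        with pytest.raises(ValidationError, match="chr9"):
            select_probes(dbt, self._limits(-0.1, 0.1), manifest)


class TestCallGenes:
    def _selected(self, records):
        return pd.DataFrame(
            [(db, p, g) for _, db, p, g in records],
            columns=["delta_beta", "p_value", "gene"],
            index=pd.Index([r[0] for r in records], name="probe_id"),
        )

    def test_gene_without_selected_probes_absent(self):
        calls = call_genes(self._selected([]))
        assert calls.mA_gt_mC == frozenset() and calls.mA_lt_mC == frozenset()

    def test_opposite_probes_place_gene_in_both_sets(self):
        calls = call_genes(self._selected([
            ("cg1", 0.3, 0.001, "GX"), ("cg2", -0.2, 0.002, "GX"),
        ]))
        assert "GX" in calls.mA_gt_mC and "GX" in calls.mA_lt_mC
        assert len(calls.supporting_probes["GX"]) == 2

    def test_five_hypermethylated_probes_give_single_direction(self):
        """Five selected probes, all more methylated in the amnion, call
        the gene in mA>mC only — the TLR4 pattern."""
        recs = [(f"cg{i}", 0.1 + 0.05 * i, 0.001, "TLR4") for i in range(5)]
        calls = call_genes(self._selected(recs))
        assert calls.mA_gt_mC == frozenset({"TLR4"})
        assert "TLR4" not in calls.mA_lt_mC

    def test_intergenic_probes_dropped(self):
        calls = call_genes(self._selected([("cg1", 0.3, 0.001, "")]))
        assert not calls.mA_gt_mC and not calls.mA_lt_mC

    def test_multi_gene_probe_contributes_to_all(self):
        calls = call_genes(self._selected([("cg1", 0.3, 0.001, "GA;GB")]))
        assert calls.mA_gt_mC == frozenset({"GA", "GB"})


class TestModelResults:
    def test_fit_antisymmetry_swaps_gene_calls(self, small_cohort):
        beta, _, manifest, _ = small_cohort
        kw = dict(alpha=0.05, n_iterations=300, aggregation="quantile",
                  seed=12)
        fwd = PairedMethylationModel(
            beta, manifest, "ZAM", "amnion", "choriodecidua").fit(**kw)
        rev = PairedMethylationModel(
            beta, manifest, "ZAM", "choriodecidua", "amnion").fit(**kw)
        assert fwd.gene_calls.mA_gt_mC == rev.gene_calls.mA_lt_mC
        assert fwd.gene_calls.mA_lt_mC == rev.gene_calls.mA_gt_mC

    def test_summary_and_bed_export(self, small_cohort):
        beta, _, manifest, _ = small_cohort
        res = PairedMethylationModel(beta, manifest, "ZAM").fit(
            n_iterations=200, aggregation="quantile", seed=1)
        text = res.summary()
        assert "probes selected" in text and "ZAM" in text
        bed = res.selected_bed()
        assert (bed["end"] - bed["start"] == 1).all()
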