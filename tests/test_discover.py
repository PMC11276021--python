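"""Discovery: eligibility, masking, FDR, routes, clumping, classification."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_summary_frame
from gxescan.discover import (
    MHC_HG38,
    Locus,
    SignificanceConfig,
    bh_fdr,
    classify_loci,
    clump,
    discover,
    effective_tests,
    eligibility,
    exclude_mhc,
    ld_r2,
    loci_frame,
    select_1df,
    select_2df,
    sex_heterogeneity,
    two_step,
)


class TestEligibility:
    def test_sample_size_gate_is_strict(self):
        frame = make_summary_frame(n=5)
        frame["K_COHORTS"] = 1
        frame["N"] = 20000
        assert not eligibility(frame)
        frame["N"] = 20001
        assert eligibility(frame)

    def test_cohort_count_gate(self):
        frame = make_summary_frame(n=5)
        frame["N"] = 500
        frame["K_COHORTS"] = 2
        assert not eligibility(frame)
        frame["K_COHORTS"] = 3
        assert eligibility(frame)

    def test_empty_frame_ineligible(self):
        assert not eligibility(make_summary_frame(n=5).iloc[:0])


class TestMhcMask:
    def test_buffer_boundaries(self):
        lo, hi = MHC_HG38
        frame = make_summary_frame(n=4)
        frame["CHR"] = 6
        frame["POS"] = [lo - 1_000_001, lo - 1_000_000, hi + 1_000_000, hi + 1_000_001]
        out = exclude_mhc(frame)
        assert out["POS"].tolist() == [lo - 1_000_001, hi + 1_000_001]

    def test_other_chromosomes_untouched(self):
        frame = make_summary_frame(n=3)
        frame["CHR"] = 5
        frame["POS"] = [MHC_HG38[0], MHC_HG38[1], 1]
        assert len(exclude_mhc(frame)) == 3


class TestFdrAndSelection:
    def test_bh_hand_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_bh_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=100)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all() and (q <= 1).all()

    def test_select_1df_requires_both_gates(self):
        frame = make_summary_frame(n=100, seed=1)
        frame.loc[0, "P_INT"] = 1e-10
        sel = select_1df(frame)
        assert sel["SNPID"].tolist() == ["s0000"]
        # genome-wide threshold is strict at 5e-9
        frame.loc[0, "P_INT"] = 5e-9
        assert select_1df(frame).empty

    def test_select_2df_uses_joint_p(self):
        frame = make_summary_frame(n=100, seed=2)
        frame.loc[3, "P_JOINT"] = 1e-12
        sel = select_2df(frame)
        assert sel["SNPID"].tolist() == ["s0003"]


class TestEffectiveTests:
    def test_independent_variants_counted_fully(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.3, size=(5000, 8)).astype(float)
        assert effective_tests(g) == 8

    def test_duplicated_column_collapses(self):
        rng = np.random.default_rng(4)
        base = rng.binomial(2, 0.3, size=(500, 1)).astype(float)
        g = np.column_stack([base, base, base])
        assert effective_tests(g) == 1

    def test_two_perfect_blocks(self):
        rng = np.random.default_rng(5)
        a = rng.binomial(2, 0.3, size=500).astype(float)
        b = rng.binomial(2, 0.4, size=500).astype(float)
        g = np.column_stack([a, a, b, b])
        assert effective_tests(g) == 2

    def test_empty_rejected_single_is_one(self):
        with pytest.raises(ValueError):
            effective_tests(np.empty((10, 0)))
        assert effective_tests(np.ones((10, 1))) == 1


class TestTwoStep:
    def test_screen_then_bonferroni(self):
        frame = make_summary_frame(n=50, seed=6)
        frame["P_MARG"] = 1.0
        frame.loc[[0, 1, 2, 3], "P_MARG"] = 1e-6  # 4 screened variants
        frame["P_INT"] = 0.5
        frame.loc[0, "P_INT"] = 0.001          # < 0.05/4
        frame.loc[1, "P_INT"] = 0.02           # fails 0.05/4 = 0.0125
        rng = np.random.default_rng(7)
        dosages = {
            s: rng.binomial(2, 0.3, size=800).astype(float)
            for s in frame["SNPID"][:4]
        }
        sel, n_g = two_step(frame, dosages)
        assert n_g == 4
        assert sel["SNPID"].tolist() == ["s0000"]

    def test_missing_dosages_still_count_as_tests(self):
        frame = make_summary_frame(n=20, seed=8)
        frame["P_MARG"] = 1.0
        frame.loc[[0, 1, 2], "P_MARG"] = 1e-6
        sel, n_g = two_step(frame, {})  # no LD source at all
        assert n_g == 3

    def test_no_screened_variants(self):
        frame = make_summary_frame(n=20, seed=9)
        frame["P_MARG"] = 1.0
        sel, n_g = two_step(frame, {})
        assert sel.empty and n_g == 0


class TestLd:
    def test_identity_and_flip_invariance(self):
        rng = np.random.default_rng(10)
        g = rng.binomial(2, 0.3, size=400).astype(float)
        assert ld_r2(g, g) == pytest.approx(1.0)
        assert ld_r2(g, 2.0 - g) == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(11)
        g1 = rng.binomial(2, 0.3, size=5000).astype(float)
        g2 = rng.binomial(2, 0.3, size=5000).astype(float)
        assert ld_r2(g1, g2) < 0.01

    def test_constant_vector_warns(self):
        with pytest.warns(UserWarning):
            assert ld_r2(np.ones(10), np.arange(10.0)) == 0.0


class TestClump:
    def _sig(self, positions, pvals, chrom=1):
        n = len(positions)
        frame = make_summary_frame(n=n, seed=12)
        frame["CHR"] = chrom
        frame["POS"] = positions
        frame["P_SELECT"] = pvals
        frame["ROUTE"] = "1df"
        return frame

    def test_nearby_variants_form_one_locus(self):
        sig = self._sig([1_000_000, 1_400_000], [1e-10, 1e-9])
        loci = clump(sig, None)
        assert len(loci) == 1
        assert loci[0].lead == "s0000"
        assert set(loci[0].members) == {"s0000", "s0001"}

    def test_distant_variants_form_two_loci(self):
        sig = self._sig([1_000_000, 1_600_000], [1e-10, 1e-9])
        loci = clump(sig, None)
        assert len(loci) == 2

    def test_lead_is_most_significant(self):
        sig = self._sig([1_000_000, 1_100_000, 1_200_000], [1e-8, 1e-12, 1e-9])
        loci = clump(sig, None)
        assert loci[0].lead == "s0001"

    def test_input_order_invariance(self):
        sig = self._sig([1_000_000, 1_100_000, 2_500_000], [1e-8, 1e-12, 1e-9])
        a = clump(sig, None)
        b = clump(sig.iloc[::-1].reset_index(drop=True), None)
        assert [(l.lead, sorted(l.members)) for l in a] == [
            (l.lead, sorted(l.members)) for l in b
        ]

    def test_ld_merging_of_distant_leads(self):
        # two leads 600 kb apart but in perfect LD merge into one locus
        sig = self._sig([1_000_000, 1_600_000], [1e-10, 1e-9])
        rng = np.random.default_rng(13)
        g = rng.binomial(2, 0.3, size=400).astype(float)
        dosages = {"s0000": g, "s0001": g.copy()}
        loci = clump(sig, dosages)
        assert len(loci) == 1
        assert set(loci[0].members) == {"s0000", "s0001"}

    def test_empty_input(self):
        assert clump(make_summary_frame(n=3).iloc[:0], None) == []


class TestClassify:
    def _locus(self, route, snp="s0000", chrom=1, pos=1_000_000):
        return Locus(lead=snp, chrom=chrom, pos=pos, members=[snp], route=route, p_lead=1e-10)

    def test_interaction_route_class_x_when_novel(self):
        frame = make_summary_frame(n=5, seed=14)
        known_gxe = pd.DataFrame({"chrom": [2], "pos": [1_000_000]})
        loci = classify_loci([self._locus("1df")], frame, known_gxe_loci=known_gxe)
        assert loci[0].locus_class == "X" and loci[0].novel is True

    def test_interaction_route_near_known_not_x(self):
        frame = make_summary_frame(n=5, seed=15)
        known_gxe = pd.DataFrame({"chrom": [1], "pos": [1_500_000]})  # 0.5 Mb away
        loci = classify_loci([self._locus("1df")], frame, known_gxe_loci=known_gxe)
        assert loci[0].novel is False and loci[0].locus_class == ""

    def test_2df_route_y_vs_z(self):
        frame = make_summary_frame(n=5, seed=16)
        frame["P_MARG"] = 0.5  # marginal effect insignificant everywhere
        frame.loc[0, ["P_INT", "P_MAIN"]] = [1e-9, 1e-3]  # interaction-driven
        frame.loc[1, ["P_INT", "P_MAIN"]] = [1e-3, 1e-9]
        known_bp = pd.DataFrame({"chrom": [9], "pos": [1]})
        loci = classify_loci(
            [self._locus("2df", "s0000"), self._locus("2df", "s0001", pos=1_100_000)],
            frame,
            known_bp_loci=known_bp,
        )
        assert loci[0].locus_class == "Y" and loci[0].driven_by_interaction
        assert loci[1].locus_class == "Z" and not loci[1].driven_by_interaction

    def test_2df_with_significant_marginal_not_prioritized(self):
        frame = make_summary_frame(n=5, seed=17)
        frame.loc[0, "P_MARG"] = 1e-12
        known_bp = pd.DataFrame({"chrom": [9], "pos": [1]})
        loci = classify_loci([self._locus("2df")], frame, known_bp_loci=known_bp)
        assert loci[0].locus_class == ""

    def test_missing_known_tables_leave_novelty_undetermined(self):
        frame = make_summary_frame(n=5, seed=18)
        loci = classify_loci([self._locus("1df")], frame)
        assert loci[0].novel is None and loci[0].locus_class == ""


class TestSexHeterogeneity:
    def test_hand_example(self):
        z, p, sig = sex_heterogeneity(1.0, 0.5, -1.0, 0.5, q=1)
        assert z == pytest.approx(2.0 / np.sqrt(0.5), rel=1e-12)  # 2.8284
        assert p == pytest.approx(0.004678, rel=1e-3)
        assert sig  # 0.00468 < 0.05/1

    def test_bonferroni_divisor(self):
        _, p, sig1 = sex_heterogeneity(1.0, 0.5, -1.0, 0.5, q=1)
        _, _, sig22 = sex_heterogeneity(1.0, 0.5, -1.0, 0.5, q=22)
        assert sig1 and not sig22  # 0.00468 > 0.05/22 = 0.00227

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sex_heterogeneity(1.0, 0.0, 0.0, 1.0, q=1)
        with pytest.raises(ValueError):
            sex_heterogeneity(1.0, 1.0, 0.0, 1.0, q=0)


class TestDiscoverOrchestration:
    def _eligible(self, n=100, seed=20):
        frame = make_summary_frame(n=n, seed=seed)
        frame["N"] = 30000
        frame["K_COHORTS"] = 4
        return frame

    def test_ineligible_table_yields_nothing(self):
        frame = make_summary_frame(n=50, seed=21)
        frame["N"] = 1000
        frame["K_COHORTS"] = 1
        frame.loc[0, "P_INT"] = 1e-20
        assert discover(frame) == []

    def test_route_priority_1df_over_2df(self):
        frame = self._eligible()
        frame.loc[0, "P_INT"] = 1e-15
        frame.loc[0, "P_JOINT"] = 1e-20
        loci = discover(frame)
        assert len(loci) == 1 and loci[0].route == "1df"

    def test_sex_heterogeneity_attached(self):
        frame = self._eligible()
        frame.loc[0, "P_INT"] = 1e-15
        fem = make_summary_frame(n=100, seed=22)
        mal = make_summary_frame(n=100, seed=23)
        fem.loc[0, ["BETA_INT", "SE_INT"]] = [1.0, 0.5]
        mal.loc[0, ["BETA_INT", "SE_INT"]] = [-1.0, 0.5]
        loci = discover(frame, sex_frames={"female": fem, "male": mal})
        assert loci[0].sex_het is not None
        z, p, sig = loci[0].sex_het
        assert z == pytest.approx(2.0 / np.sqrt(0.5), rel=1e-12)
        assert sig

    def test_mhc_hit_masked(self):
        frame = self._eligible()
        frame.loc[0, ["CHR", "POS"]] = [6, (MHC_HG38[0] + MHC_HG38[1]) // 2]
        frame.loc[0, "P_INT"] = 1e-20
        assert discover(frame) == []

    def test_loci_frame_report(self):
        frame = self._eligible()
        frame.loc[0, "P_INT"] = 1e-15
        loci = discover(frame, labels={"trait": "SBP", "exposure": "STST"})
        table = loci_frame(loci)
        assert table.loc[0, "LOCUS_ID"] == "L001"
        assert table.loc[0, "TRAIT"] == "SBP"
        assert table.loc[0, "ROUTE"] == "1df"
        assert table.loc[0, "N_MEMBERS"] == len(loci[0].members)
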