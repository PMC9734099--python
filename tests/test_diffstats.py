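"""Group contrasts, fold changes, aggregated BH and the paired test."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from serodiff import diffstats, io_tables, presence, quantify
from serodiff.diffstats import (
    ContrastSpec,
    aggregate_bh,
    contrast_from_groups,
    log2_fold_change,
    paired_contrast,
    run_contrast,
    run_differential,
    significant_sets,
    two_sample_t,
)
from serodiff.simulate import SimConfig, simulate_study


class TestTwoSampleT:
    def test_identical_samples_give_t0_p1(self):
        t, p = two_sample_t([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_pooled_t_closed_form(self):
        # pooled SD = 1, so t = -3 / sqrt(2/3) = -3.674, p(4 df) ~ 0.0214
        t, p = two_sample_t([1, 2, 3], [4, 5, 6], "student")
        assert t == pytest.approx(-3.6742, abs=1e-3)
        assert p == pytest.approx(0.02131, abs=2e-4)

    def test_side_swap_flips_sign_only(self):
        t1, p1 = two_sample_t([1, 2, 3], [4, 5, 7])
        t2, p2 = two_sample_t([4, 5, 7], [1, 2, 3])
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_welch_differs_under_unequal_variance(self):
        x = [1.0, 1.1, 0.9, 1.05]
        y = [5.0, 9.0, 1.0, 7.0]
        _, p_student = two_sample_t(x, y, "student")
        _, p_welch = two_sample_t(x, y, "welch")
        assert p_student != p_welch

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [2.0, 3.0])


class TestLog2FoldChange:
    def test_printed_worked_examples(self):
        # group means of the kininogen / protease-inhibitor markers
        assert log2_fold_change(101e7, 435e7) == pytest.approx(-2.11, abs=0.01)
        assert log2_fold_change(136e6, 120e7) == pytest.approx(-3.14, abs=0.01)

    def test_equal_means_give_zero(self):
        assert log2_fold_change(7.7, 7.7) == 0.0

    def test_antisymmetry(self):
        assert log2_fold_change(3.0, 5.0) == pytest.approx(-log2_fold_change(5.0, 3.0))

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            log2_fold_change(0.0, 1.0)


class TestAggregateBh:
    def test_single_p_one_term_formula(self):
        assert aggregate_bh([0.01], 3) == pytest.approx([0.03])

    def test_hand_step_up(self):
        np.testing.assert_allclose(
            aggregate_bh([0.01, 0.02, 0.03], 3), [0.03, 0.03, 0.03]
        )

    def test_all_ones_stay_one(self):
        assert aggregate_bh([1.0, 1.0, 1.0], 10).tolist() == [1.0, 1.0, 1.0]

    def test_m_total_below_count_rejected(self):
        with pytest.raises(ValueError):
            aggregate_bh([0.1, 0.2, 0.3], 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_reduces_to_textbook_bh_when_m_equals_n(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=50)
        q = aggregate_bh(p, 50)
        q_oracle = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, q_oracle, rtol=1e-12)

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=40)
        q = aggregate_bh(p, 120)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestRunContrast:
    def _quant(self, X, Y):
        data = np.hstack([X, Y])
        cols = [f"t{i}" for i in range(X.shape[1])] + [
            f"r{i}" for i in range(Y.shape[1])
        ]
        q = pd.DataFrame(data, columns=cols)
        q.index = pd.Index(range(1, len(q) + 1), name="protein_group_id")
        spec = ContrastSpec("toy", cols[: X.shape[1]], cols[X.shape[1]:])
        return q, spec

    def test_null_p_values_near_uniform(self):
        rng = np.random.default_rng(12)
        q, spec = self._quant(rng.normal(size=(1000, 10)), rng.normal(size=(1000, 10)))
        res = run_contrast(q, spec)
        frac = (res["p"] <= 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_protein_with_single_observation_excluded(self):
        X = np.array([[1.0, np.nan, np.nan], [1.0, 2.0, 3.0]])
        Y = np.array([[4.0, 5.0, 6.0], [4.0, 5.0, 6.0]])
        q, spec = self._quant(X, Y)
        res = run_contrast(q, spec)
        assert not res.loc[1, "tested"] and np.isnan(res.loc[1, "p"])
        assert res.loc[2, "tested"]

    def test_means_over_observed_values_only(self):
        X = np.array([[2.0, np.nan, 4.0]])
        Y = np.array([[1.0, 1.0, np.nan]])
        q, spec = self._quant(X, Y)
        res = run_contrast(q, spec)
        assert res.loc[1, "mean_test"] == pytest.approx(3.0)
        assert res.loc[1, "n_test"] == 2 and res.loc[1, "n_ref"] == 2
        assert res.loc[1, "log2fc"] == pytest.approx(np.log2(3.0))

    def test_matches_scalar_t_on_each_row(self):
        rng = np.random.default_rng(4)
        q, spec = self._quant(rng.normal(size=(20, 5)), rng.normal(2, 1, size=(20, 6)))
        res = run_contrast(q, spec)
        for pid in q.index[:5]:
            t, p = two_sample_t(
                q.loc[pid, spec.test_samples], q.loc[pid, spec.ref_samples]
            )
            assert res.loc[pid, "t"] == pytest.approx(t)
            assert res.loc[pid, "p"] == pytest.approx(p)


class TestContrastSpecs:
    def test_sc_is_sample_level_concatenation(self, toy_sheet):
        spec = contrast_from_groups(toy_sheet, "M", "SC")
        assert spec.ref_samples == io_tables.group_samples(
            toy_sheet, "S"
        ) + io_tables.group_samples(toy_sheet, "C")

    def test_overlapping_sides_rejected(self):
        with pytest.raises(ValueError):
            ContrastSpec("bad", ["a", "b"], ["b", "c"])


class TestSignificantSets:
    def _results(self, qtabs):
        out = {}
        for name, qs in qtabs.items():
            out[name] = pd.DataFrame(
                {"q": qs, "tested": True}, index=range(1, len(qs) + 1)
            )
        return out

    def test_disjoint_sets_empty_intersections(self):
        res = self._results(
            {
                "M_vs_S": [0.01, 1, 1],
                "M_vs_C": [1, 0.01, 1],
                "M_vs_SC": [1, 1, 0.01],
                "S_vs_C": [1, 1, 1],
            }
        )
        sets = significant_sets(res)
        assert sets["M_intersection"] == set() and sets["threeway"] == set()

    def test_identical_sets_intersect_to_themselves(self):
        res = self._results(
            {n: [0.01, 0.04, 1.0] for n in ("M_vs_S", "M_vs_C", "M_vs_SC", "S_vs_C")}
        )
        sets = significant_sets(res)
        assert sets["M_intersection"] == {1, 2} == sets["threeway"]

    @pytest.mark.parametrize("seed", range(3))
    def test_random_tables_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        res = self._results(
            {
                n: rng.uniform(size=30)
                for n in ("M_vs_S", "M_vs_C", "M_vs_SC", "S_vs_C")
            }
        )
        sets = significant_sets(res, alpha=0.3)
        expected = set()
        for pid in range(1, 31):
            if all(
                res[n].loc[pid, "q"] <= 0.3 for n in ("M_vs_S", "M_vs_C", "M_vs_SC")
            ):
                expected.add(pid)
        assert sets["M_intersection"] == expected


class TestPairedContrast:
    def _study_matrix(self, n_prot=30, seed=0, shift=0.0):
        cfg = SimConfig(n_proteins=n_prot, seed=seed, de_fraction_m=0.0,
                        de_fraction_s=0.0)
        study = simulate_study(cfg)
        pg = io_tables.apply_qc_filters(study.protein_groups)
        q = quantify.build_quant_matrix(study.peptides, pg, study.sample_sheet)
        return q, study.sample_sheet

    def test_one_sample_t_closed_form(self):
        sheet = pd.DataFrame(
            {
                "sample_id": ["m1", "m2", "m3", "s1", "s2", "s3"],
                "group": ["M", "M", "M", "S", "S", "S"],
                "pair_id": ["p1", "p2", "p3", "p1", "p2", "p3"],
            }
        )
        # differences S - M = {1, 2, 3} -> t = 3.464, p ~ 0.0742
        q = pd.DataFrame(
            {"m1": [10.0], "m2": [10.0], "m3": [10.0],
             "s1": [11.0], "s2": [12.0], "s3": [13.0]},
            index=pd.Index([1], name="protein_group_id"),
        )
        res = paired_contrast(q, sheet)
        assert res.loc[1, "t"] == pytest.approx(3.4641, abs=1e-3)
        assert res.loc[1, "p"] == pytest.approx(0.0742, abs=2e-3)
        assert res.loc[1, "direction_m"] == "down"

    def test_constant_nonzero_differences_flagged_degenerate(self):
        sheet = pd.DataFrame(
            {
                "sample_id": ["m1", "m2", "m3", "s1", "s2", "s3"],
                "group": ["M"] * 3 + ["S"] * 3,
                "pair_id": ["p1", "p2", "p3"] * 2,
            }
        )
        q = pd.DataFrame(
            {"m1": [1.0], "m2": [2.0], "m3": [3.0],
             "s1": [2.0], "s2": [3.0], "s3": [4.0]},
            index=pd.Index([1], name="protein_group_id"),
        )
        res = paired_contrast(q, sheet)
        assert not res.loc[1, "tested"]

    def test_planted_paired_shift_recovered(self):
        """Subject effects cancel in pairing; a within-subject shift is found."""
        cfg = SimConfig(n_proteins=120, seed=21, de_fraction_m=0.2,
                        de_fraction_s=0.0, subject_sd=0.8)
        study = simulate_study(cfg)
        pg = io_tables.apply_qc_filters(study.protein_groups)
        q = quantify.build_quant_matrix(study.peptides, pg, study.sample_sheet)
        res = paired_contrast(q, study.sample_sheet)
        planted = study.truth.de_proteins("M_vs_S")
        found = res.index[(res["q"] <= 0.05).fillna(False)]
        power = np.mean([pid in set(found) for pid in planted])
        assert power >= 0.8

    def test_no_pairs_rejected(self, small_quant):
        sheet = pd.DataFrame(
            {"sample_id": list(small_quant.columns), "group": "M", "pair_id": None}
        )
        with pytest.raises(ValueError):
            paired_contrast(small_quant, sheet)


class TestRunDifferential:
    def test_planted_effects_recovered_with_aggregated_bh(self):
        cfg = SimConfig(n_proteins=200, seed=5)
        study = simulate_study(cfg)
        pg = io_tables.apply_qc_filters(study.protein_groups)
        q = quantify.build_quant_matrix(study.peptides, pg, study.sample_sheet)
        summ = presence.presence_fractions(q, study.sample_sheet)
        qa = q.loc[presence.select_analysis_set(summ)]
        res = run_differential(qa, study.sample_sheet)
        found = set(res["M_vs_S"].index[res["M_vs_S"]["significant"].fillna(False)])
        planted = [p for p in study.truth.de_proteins("M_vs_S") if p in qa.index]
        recovery = np.mean([p in found for p in planted])
        assert recovery >= 0.9

    def test_m_total_defaults_to_three_per_protein(self, small_quant, small_study):
        res = run_differential(small_quant, small_study.sample_sheet)
        # q of the best protein equals p * m_total at rank 1 unless capped later
        df = res["M_vs_S"]
        tested = df[df["tested"]]
        pooled_n = sum(res[n]["tested"].sum() for n in diffstats.M_CENTRIC)
        m_total = diffstats.BH_CONTRAST_MULTIPLIER * len(small_quant)
        assert m_total >= pooled_n
        assert ((tested["q"] >= tested["p"] - 1e-15) | tested["q"].isna()).all()
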