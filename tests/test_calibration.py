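"""Validation machinery: test lists, ranking, ROC/bootstrap, sweeps, null fit."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cten import (
    EmptyDatabaseError,
    ParameterError,
    ValidationError,
    average_replicates,
    bootstrap_ci,
    fit_gamma_mle,
    make_test_lists,
    mixture_score_at,
    null_calibration,
    rank_evaluation,
    roc,
    threshold_sweep,
)


class TestMakeTestLists:
    def test_probe_count_is_ceiling_of_percent(self, study_atlas):
        atlas, _ = study_atlas
        cm = average_replicates(atlas)
        lists = make_test_lists(cm, atlas.probe_annotation, [5], cell_types=["ct01"])
        (tl,) = lists
        assert tl.gene_list.n_input == math.ceil(0.05 * len(cm))  # 250 probes
        assert len(tl.gene_list.ids) <= tl.gene_list.n_input  # gene mapping dedups

    def test_ten_cell_types_times_nine_percents_gives_90_lists(self, study_atlas):
        atlas, _ = study_atlas
        cm = average_replicates(atlas)
        lists = make_test_lists(cm, atlas.probe_annotation, range(2, 11))
        assert len(lists) == 90

    def test_two_top_probes_of_one_gene_shrink_the_list(self):
        cm = pd.DataFrame({"A": [9.0, 8.0, 1.0, 0.5]}, index=["P1", "P2", "P3", "P4"])
        ann = {"P1": ("7", "G7"), "P2": ("7", "G7"), "P3": ("8", "G8"), "P4": ("9", "G9")}
        (tl,) = make_test_lists(cm, ann, [50])  # top 2 probes, one gene
        assert tl.gene_list.ids == ("7",)

    def test_sizes_nonincreasing_in_rank_cutoff_and_deterministic(self, study_atlas):
        atlas, _ = study_atlas
        cm = average_replicates(atlas)
        lists = make_test_lists(cm, atlas.probe_annotation, [2, 5, 8], ["ct03"])
        sizes = [len(tl.gene_list.ids) for tl in sorted(lists, key=lambda t: t.percent)]
        assert sizes == sorted(sizes)
        again = make_test_lists(cm, atlas.probe_annotation, [2, 5, 8], ["ct03"])
        assert [t.gene_list.ids for t in again] == [t.gene_list.ids for t in lists]

    @pytest.mark.parametrize("k", [0, 100, -3])
    def test_percent_domain(self, k, study_atlas):
        atlas, _ = study_atlas
        with pytest.raises(ParameterError):
            make_test_lists(average_replicates(atlas), atlas.probe_annotation, [k])


class TestRankEvaluation:
    def test_planted_signature_ranks_first(self, study_atlas, study_db):
        atlas, _ = study_atlas
        cm = average_replicates(atlas)
        lists = make_test_lists(cm, atlas.probe_annotation, [5])
        ev = rank_evaluation(lists, study_db)
        assert ev.hit_rate == 1.0
        assert set(ev.hits["rank1"]) == set(study_db.cell_types)

    def test_random_lists_rarely_hit(self, study_db):
        from cten import generate_random_lists
        from cten.calibration import LabelledTestList

        # truth ct05: not the lexicographic tie-break winner among zero scores
        lists = [
            LabelledTestList(gl, truth="ct05", percent=0.0)
            for gl in generate_random_lists(study_db.universe, 20, (100, 200), seed=3)
        ]
        ev = rank_evaluation(lists, study_db)
        assert ev.hit_rate <= 0.25  # near the 1/10 chance level

    def test_r_larger_than_cell_types_returns_all(self, study_atlas, study_db):
        atlas, _ = study_atlas
        cm = average_replicates(atlas)
        lists = make_test_lists(cm, atlas.probe_annotation, [5], ["ct01"])
        ev = rank_evaluation(lists, study_db, r=50)
        row = ev.hits.iloc[0]
        ranked = [row[f"rank{i}"] for i in range(1, 51) if row[f"rank{i}"]]
        assert sorted(ranked) == study_db.cell_types

    def test_truth_group_counts_sister_state_as_hit(self):
        scores = pd.DataFrame(
            {"T_rest": [1.0], "T_lps": [9.0]}, index=["L1"]
        )
        r = roc(scores, {"L1": "T_rest"},
                truth_group={"T_rest": "T", "T_lps": "T"})
        # both columns positive under the group: no negatives at all
        assert r.fpr.max() == 0.0


class TestROC:
    def test_separable_scores_give_auc_one(self):
        scores = pd.DataFrame(
            {"A": [30.0, 1.0], "B": [1.0, 30.0]}, index=["L1", "L2"]
        )
        r = roc(scores, {"L1": "A", "L2": "B"}, thresholds=[10.0])
        assert r.auc == 1.0
        assert r.tpr[0] == 1.0 and r.fpr[0] == 0.0

    def test_cutoff_above_global_max_classifies_nothing(self):
        scores = pd.DataFrame({"A": [3.0], "B": [1.0]}, index=["L1"])
        r = roc(scores, {"L1": "A"}, thresholds=[99.0])
        assert r.tpr[0] == 0.0 and r.fpr[0] == 0.0

    def test_rates_monotone_as_cutoff_drops(self, study_atlas, study_db):
        atlas, _ = study_atlas
        cm = average_replicates(atlas)
        lists = make_test_lists(cm, atlas.probe_annotation, [5, 10])
        ev = rank_evaluation(lists, study_db)
        r = roc(ev.scores, ev.truth)
        assert (np.diff(r.tpr) >= 0).all()
        assert (np.diff(r.fpr) >= 0).all()
        assert 0.0 <= r.auc <= 1.0

    def test_missing_truth_column_is_a_validation_error(self):
        scores = pd.DataFrame({"A": [3.0]}, index=["L1"])
        with pytest.raises(ValidationError):
            roc(scores, {"L1": "Z"})

    def test_agrees_with_instance_by_instance_oracle(self):
        rng = np.random.default_rng(11)
        scores = pd.DataFrame(
            rng.gamma(2, 2, size=(8, 6)),
            index=[f"L{i}" for i in range(8)],
            columns=[f"c{j}" for j in range(6)],
        )
        truth = {f"L{i}": f"c{i % 6}" for i in range(8)}
        cuts = [0.5, 1.0, 2.0, 4.0, 8.0]
        r = roc(scores, truth, thresholds=cuts)
        for ci, cut in enumerate(sorted(cuts, reverse=True)):
            tp = fp = pos = neg = 0
            for name in scores.index:
                for col in scores.columns:
                    is_pos = truth[name] == col
                    pos += is_pos
                    neg += not is_pos
                    if scores.at[name, col] >= cut:
                        tp += is_pos
                        fp += not is_pos
            assert r.tpr[ci] == pytest.approx(tp / pos)
            assert r.fpr[ci] == pytest.approx(fp / neg)


class TestBootstrapCI:
    @staticmethod
    def _scores():
        rng = np.random.default_rng(5)
        return pd.DataFrame(
            rng.gamma(2, 2, size=(12, 4)),
            index=[f"L{i}" for i in range(12)],
            columns=[f"c{j}" for j in range(4)],
        ), {f"L{i}": f"c{i % 4}" for i in range(12)}

    def test_same_seed_gives_identical_intervals(self):
        scores, truth = self._scores()
        a = bootstrap_ci(scores, truth, [1.0, 3.0], B=200, seed=42)
        b = bootstrap_ci(scores, truth, [1.0, 3.0], B=200, seed=42)
        for xa, xb in zip(a, b):
            np.testing.assert_array_equal(xa[0], xb[0])
            np.testing.assert_array_equal(xa[1], xb[1])

    def test_identical_rows_give_zero_width_intervals(self):
        scores = pd.DataFrame(
            [[5.0, 1.0]] * 6, index=[f"L{i}" for i in range(6)], columns=["A", "B"]
        )
        truth = {f"L{i}": "A" for i in range(6)}
        (tpr_lo, tpr_hi), (fpr_lo, fpr_hi) = bootstrap_ci(
            scores, truth, [2.0], B=150, seed=0
        )
        np.testing.assert_array_equal(tpr_lo, tpr_hi)
        np.testing.assert_array_equal(fpr_lo, fpr_hi)

    def test_intervals_contain_point_estimate(self):
        scores, truth = self._scores()
        cuts = [0.5, 2.0, 5.0]
        r = roc(scores, truth, thresholds=cuts)
        (tpr_lo, tpr_hi), (fpr_lo, fpr_hi) = bootstrap_ci(
            scores, truth, cuts, B=500, seed=1
        )
        assert ((tpr_lo <= r.tpr + 1e-12) & (r.tpr <= tpr_hi + 1e-12)).all()
        assert ((fpr_lo <= r.fpr + 1e-12) & (r.fpr <= fpr_hi + 1e-12)).all()

    def test_preconditions(self):
        scores, truth = self._scores()
        with pytest.raises(ParameterError):
            bootstrap_ci(scores.iloc[:1], {"L0": "c0"}, [1.0], B=200)
        with pytest.raises(ParameterError):
            bootstrap_ci(scores, truth, [1.0], B=10)


class TestThresholdSweep:
    def test_single_threshold_matches_direct_pipeline(self, study_atlas):
        atlas, _ = study_atlas
        a = threshold_sweep(atlas, [15], seed=9)[15.0]
        b = threshold_sweep(atlas, [15], seed=9)[15.0]
        assert a.auc == b.auc
        np.testing.assert_array_equal(a.tpr, b.tpr)

    def test_threshold_above_planted_fold_empties_the_database(self, study_atlas):
        atlas, _ = study_atlas
        with pytest.raises(EmptyDatabaseError):
            threshold_sweep(atlas, [200.0], seed=0)

    def test_threshold_at_most_one_rejected(self, study_atlas):
        atlas, _ = study_atlas
        with pytest.raises(ParameterError):
            threshold_sweep(atlas, [1.0])


class TestNullCalibration:
    def test_gamma_mle_recovers_known_parameters(self):
        rng = np.random.default_rng(7)
        draws = rng.gamma(2.0, 0.5, size=10_000)
        shape, scale = fit_gamma_mle(draws)
        assert shape == pytest.approx(2.0, rel=0.1)
        assert scale == pytest.approx(0.5, rel=0.1)

    def test_exponential_closed_form_quantile(self):
        q = mixture_score_at(0.0, 1.0, 1.0, 0.95)
        assert q == pytest.approx(-np.log(0.05), abs=1e-6)

    def test_zero_atom_saturating_alpha_gives_zero(self):
        assert mixture_score_at(0.97, 2.0, 0.5, 0.95) == 0.0

    def test_mixture_quantile_monotone_in_alpha(self):
        qs = [mixture_score_at(0.4, 2.0, 0.5, a) for a in (0.5, 0.8, 0.95, 0.99)]
        assert qs == sorted(qs)

    def test_seeded_runs_are_bit_reproducible(self, study_db):
        a = null_calibration(study_db, n_lists=15, size_range=(50, 100), seed=13)
        b = null_calibration(study_db, n_lists=15, size_range=(50, 100), seed=13)
        assert (a.shape, a.scale, a.zero_fraction, a.score_at_alpha) == (
            b.shape, b.scale, b.zero_fraction, b.score_at_alpha
        )

    def test_mixture_quantile_consistent_with_fit(self, study_db):
        nc = null_calibration(study_db, n_lists=15, size_range=(50, 100), seed=13)
        if nc.zero_fraction < nc.alpha:
            mass = nc.zero_fraction + (1 - nc.zero_fraction) * stats.gamma.cdf(
                nc.score_at_alpha, nc.shape, scale=nc.scale
            )
            assert mass == pytest.approx(nc.alpha, abs=1e-9)
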