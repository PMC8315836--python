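"""The synthetic experiment: balance, truncation, social-information rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import crowdwise as cw
from crowdwise.design import sample_truncated_laplace


class TestQuestions:
    def test_count_determinism_and_bounds(self):
        qs = cw.generate_questions(42, seed=1)
        assert len(qs) == 42
        again = cw.generate_questions(42, seed=1)
        assert qs == again
        assert all(q.true_value >= 1e2 and q.true_value <= 1e9 for q in qs)
        assert all(q.width > 0 for q in qs)

    def test_custom_truth_range(self):
        cfg = cw.QuestionConfig(log_truth_low=3, log_truth_high=4)
        qs = cw.generate_questions(100, cfg, seed=2)
        assert all(1e3 <= q.true_value <= 1e4 for q in qs)

    def test_underestimation_bias_in_defaults(self):
        # the centre distribution has negative mean: crowds underestimate
        qs = cw.generate_questions(500, seed=3)
        assert np.mean([q.center for q in qs]) < 0

    @pytest.mark.parametrize(
        "kwargs", [{"n_questions": 0}, {"n_questions": -3}]
    )
    def test_bad_counts_rejected(self, kwargs):
        with pytest.raises(ValueError):
            cw.generate_questions(**kwargs)

    def test_bad_width_rejected(self):
        with pytest.raises(ValueError):
            cw.QuestionConfig(width_low=-0.1)
        with pytest.raises(ValueError):
            cw.Question("Q1", 100.0, 0.0, -0.5)


class TestDesignBalance:
    def test_total_subjects(self, design):
        assert design.n_subjects == 216
        assert design.cells["subject_id"].nunique() == 216

    def test_estimate_slots_per_condition(self, design):
        counts = design.cells.groupby(["treatment", "tau"]).size()
        assert (counts == 504).all()
        assert len(counts) == 18

    def test_each_question_once_per_treatment_tau(self, design):
        gq = design.cells.drop_duplicates(["group_id", "question_id"])
        counts = gq.groupby(["treatment", "question_id", "tau"]).size()
        assert (counts == 1).all()
        # every (question, treatment) covers all six tau levels
        cover = gq.groupby(["treatment", "question_id"])["tau"].nunique()
        assert (cover == 6).all()

    def test_blocks_contain_each_tau_once(self, design):
        gq = design.cells.drop_duplicates(["group_id", "question_id"])
        per_block = gq.groupby(["group_id", "block"])["tau"].apply(
            lambda s: tuple(sorted(s))
        )
        assert set(per_block) == {(1, 3, 5, 7, 9, 11)}

    def test_one_treatment_per_group(self, design):
        assert (design.cells.groupby("group_id")["treatment"].nunique() == 1).all()

    def test_peer_sets_valid(self, design):
        cells = design.cells
        assert (cells["peer_ids"].map(len) == cells["tau"]).all()
        own = [
            r.subject_id in r.peer_ids for r in cells.itertuples(index=False)
        ]
        assert not any(own)
        same_group = [
            all(p.startswith(r.group_id) for p in r.peer_ids)
            for r in cells.itertuples(index=False)
        ]
        assert all(same_group)

    def test_infeasible_designs_fail_loudly(self):
        with pytest.raises(ValueError):
            cw.build_design(n_questions=40)  # not divisible by 6 tau levels
        with pytest.raises(ValueError):
            cw.build_design(group_size=11)  # tau=11 needs 11 peers


class TestPersonalEstimates:
    def test_truncation_bound_respected(self, design, questions):
        records = cw.draw_personal_estimates(questions, design, seed=5)
        log_t = np.log10(records["true_value"].to_numpy())
        assert (records["x_personal"].to_numpy() + log_t).min() > 0

    def test_conservation(self, design, questions):
        records = cw.draw_personal_estimates(questions, design, seed=5)
        assert len(records) == 42 * 216

    def test_missing_question_named(self, design, questions):
        with pytest.raises(KeyError, match="Q042"):
            cw.draw_personal_estimates(questions[:-1], design, seed=5)

    def test_degenerate_width_collapses_to_center(self):
        rng = np.random.default_rng(0)
        x = sample_truncated_laplace(0.4, 1e-12, -5.0, 1000, rng)
        assert np.allclose(x, 0.4, atol=1e-9)

    def test_laplace_moments_monte_carlo(self):
        # closed form: median c, mean |X - median| = w; truncation at
        # -log10(1e9) = -9 is negligible for (c=0, w=0.5)
        rng = np.random.default_rng(42)
        x = sample_truncated_laplace(0.0, 0.5, -9.0, 100_000, rng)
        assert abs(np.median(x)) < 0.01
        assert abs(np.mean(np.abs(x - np.median(x))) - 0.5) < 0.01

    def test_pooled_standardized_estimates_are_laplace(self):
        # (X_p - c) / w pooled over questions ~ unit Laplace when the
        # truncation bound is far away (high true values)
        cfg = cw.QuestionConfig(log_truth_low=6, log_truth_high=9)
        questions = cw.generate_questions(12, cfg, seed=11)
        design = cw.build_design(
            n_groups_per_treatment=6, group_size=12,
            tau_levels=(1, 3, 5, 7, 9, 11), n_questions=12, seed=11,
        )
        records = cw.draw_personal_estimates(questions, design, seed=11)
        pairs = records.drop_duplicates(["subject_id", "question_id"])
        qmap = {q.question_id: q for q in questions}
        z = np.array(
            [
                (r.x_personal - qmap[r.question_id].center) / qmap[r.question_id].width
                for r in pairs.itertuples(index=False)
            ]
        )
        p = stats.kstest(z, stats.laplace.cdf).pvalue
        assert p > 0.01


@pytest.fixture(scope="module")
def records(tiny_setup):
    questions, design = tiny_setup
    partial = cw.draw_personal_estimates(questions, design, seed=8)
    return cw.assign_social_info(partial, design, seed=8)


class TestSocialInfo:
    def test_social_mean_is_peer_mean(self, records, tiny_setup):
        _, design = tiny_setup
        x_of = {
            (r.subject_id, r.question_id): r.x_personal
            for r in records.drop_duplicates(["subject_id", "question_id"]).itertuples(
                index=False
            )
        }
        for r in records.itertuples(index=False):
            peers = np.array([x_of[(p, r.question_id)] for p in r.peer_ids])
            assert r.social_mean == pytest.approx(peers.mean(), abs=1e-14)

    def test_m_equals_log_geometric_mean_of_raw_estimates(self, records):
        # raw estimate E = T 10^X; M must equal log10(gmean(E)/T) to 1e-12
        x_of = {
            (r.subject_id, r.question_id): r.x_personal
            for r in records.drop_duplicates(["subject_id", "question_id"]).itertuples(
                index=False
            )
        }
        for r in records.head(200).itertuples(index=False):
            raw = np.array(
                [r.true_value * 10.0 ** x_of[(p, r.question_id)] for p in r.peer_ids]
            )
            gmean = np.exp(np.mean(np.log(raw)))
            assert abs(r.social_mean - np.log10(gmean / r.true_value)) < 1e-12

    def test_sorted_payload_ascending(self, records):
        import json

        sub = records[records["treatment"] == "sorted"]
        for payload in sub["display_payload"]:
            vals = json.loads(payload)["estimates"]
            assert vals == sorted(vals)

    def test_aggregated_payload_is_mean_and_tau(self, records):
        import json

        sub = records[records["treatment"] == "aggregated"]
        for r in sub.itertuples(index=False):
            payload = json.loads(r.display_payload)
            assert payload["tau"] == r.tau
            assert payload["mean"] == pytest.approx(r.social_mean)

    def test_distance_identity(self, records):
        d = records["social_mean"] - records["x_personal"]
        assert np.allclose(records["distance"], d, atol=0)


def test_records_csv_round_trip(tmp_path, tiny_setup):
    questions, design = tiny_setup
    records = cw.assign_social_info(
        cw.draw_personal_estimates(questions, design, seed=9), design, seed=9
    )
    records["x_second"] = records["x_personal"]
    records["sensitivity"] = 0.0
    path = tmp_path / "records.csv"
    cw.write_records(records, path)
    back = cw.read_records(path)
    assert len(back) == len(records)
    np.testing.assert_allclose(
        back["x_personal"], records["x_personal"], rtol=1e-11
    )
    np.testing.assert_allclose(
        back["social_mean"], records["social_mean"], rtol=1e-11
    )
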