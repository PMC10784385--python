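import numpy as np
import pandas as pd
import pytest

import calyswe as c
from calyswe.quality import apply_exclusion, cis_report, inconsistency_records


def records_df(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "dominating_state",
            "dominated_state",
            "w_dominating",
            "w_dominated",
            "kind",
        ],
    )


class TestDominatedPairs:
    def test_learning_state_dominates_pit(self):
        pairs = c.find_dominated_pairs(["111111", "222333", "313122"])
        assert ("222333", "111111") in pairs

    def test_antichain_has_no_pairs(self):
        assert c.find_dominated_pairs(["123111", "213111", "132111"]) == []

    def test_chain_of_three_gives_three_pairs(self):
        pairs = c.find_dominated_pairs(["111111", "222333", "333333"])
        assert sorted(pairs) == [
            ("222333", "111111"),
            ("333333", "111111"),
            ("333333", "222333"),
        ]

    def test_single_state_rejected(self):
        with pytest.raises(ValueError, match="two"):
            c.find_dominated_pairs(["111111"])


class TestClassification:
    @pytest.mark.parametrize(
        "w1, w2, expected",
        [(0.5, 0.5, "weak"), (0.4, 0.5, "strict"), (0.6, 0.5, "none")],
    )
    def test_weak_and_strict(self, w1, w2, expected):
        assert c.classify(w1, w2) == expected

    def test_out_of_range_weights_rejected(self):
        with pytest.raises(ValueError):
            c.classify(1.2, 0.5)


class TestCISScore:
    def test_consistent_participant_scores_zero(self):
        assert c.cis_score(records_df([])) == 0.0
        rec = records_df([("222333", "111111", 0.6, 0.3, "none")])
        assert c.cis_score(rec) == 0.0

    def test_strict_violation_counts_its_severity(self):
        rec = records_df([("222333", "111111", 0.3, 0.6, "strict")])
        assert c.cis_score(rec) == pytest.approx(0.3)

    def test_exact_tie_costs_the_tie_penalty(self):
        rec = records_df([("222333", "111111", 0.5, 0.5, "weak")])
        assert c.cis_score(rec) == pytest.approx(0.05)
        assert c.cis_score(rec, tie_penalty=0.2) == pytest.approx(0.2)

    def test_monotone_in_records_and_severity(self):
        base = records_df([("222333", "111111", 0.3, 0.6, "strict")])
        more = records_df(
            [
                ("222333", "111111", 0.3, 0.6, "strict"),
                ("333333", "111111", 0.5, 0.5, "weak"),
            ]
        )
        worse = records_df([("222333", "111111", 0.3, 0.8, "strict")])
        assert c.cis_score(more) > c.cis_score(base)
        assert c.cis_score(worse) > c.cis_score(base)

    def test_custom_kernel_is_used(self):
        rec = records_df([("222333", "111111", 0.3, 0.6, "strict")])
        assert c.cis_score(rec, kernel=lambda w1, w2: 1.0) == 1.0

    def test_records_from_answers(self):
        answers = pd.DataFrame(
            {"state": ["111111", "222333", "321123"], "w": [0.8, 0.4, 0.6]}
        )
        rec = inconsistency_records(answers)
        kinds = dict(zip(rec["dominating_state"], rec["kind"]))
        assert kinds["222333"] == "strict"  # 0.4 < 0.8 for the pit


class TestExclusion:
    def make_report(self, cis):
        return pd.DataFrame(
            {
                "participant_id": np.arange(1, len(cis) + 1),
                "cis": cis,
                "n_weak": 0,
                "n_strict": 0,
            }
        )

    def test_zero_fraction_is_identity(self):
        rep = c.exclude_by_cis(self.make_report([0.1, 0.2, 0.3]), fraction=0.0)
        assert not rep["excluded"].any()

    def test_twenty_percent_of_100_keeps_80(self):
        rng = np.random.default_rng(0)
        rep = c.exclude_by_cis(self.make_report(rng.random(100)), fraction=0.2)
        assert (~rep["excluded"]).sum() == 80
        worst = rep.sort_values("cis", ascending=False).head(20)
        assert worst["excluded"].all()

    def test_all_zero_ties_break_by_highest_id(self):
        rep = c.exclude_by_cis(self.make_report([0.0] * 10), fraction=0.2)
        assert set(rep.loc[rep["excluded"], "participant_id"]) == {9, 10}

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            c.exclude_by_cis(self.make_report([0.0]), fraction=1.5)

    def test_apply_exclusion_drops_only_flagged_tto_rows(self, mixed_survey):
        rep = c.exclude_by_cis(cis_report(mixed_survey["tto"]), 0.2)
        kept = apply_exclusion(mixed_survey["tto"], rep)
        dropped = set(rep.loc[rep["excluded"], "participant_id"])
        assert not set(kept["participant_id"]) & dropped
        assert len(kept) == len(mixed_survey["tto"]) - 5 * len(dropped)


class TestDCEConsistency:
    def frame(self, chose_A, pid=1):
        return pd.DataFrame(
            {
                "participant_id": [pid],
                "stateA": ["222332"],
                "stateB": ["232332"],
                "chose_A": [chose_A],
                "is_consistency": [True],
            }
        )

    def test_choosing_dominating_state_passes(self):
        flags, prop = c.dce_consistency_failures(self.frame(False))
        assert not flags["failed"].iloc[0]
        assert prop == 0.0

    def test_choosing_dominated_state_fails(self):
        flags, prop = c.dce_consistency_failures(self.frame(True))
        assert flags["failed"].iloc[0]
        assert prop == 1.0

    def test_missing_pair_flagged_not_failed(self):
        df = self.frame(True)
        extra = pd.DataFrame(
            {
                "participant_id": [2],
                "stateA": ["111111"],
                "stateB": ["333333"],
                "chose_A": [False],
                "is_consistency": [False],
            }
        )
        flags, prop = c.dce_consistency_failures(pd.concat([df, extra]))
        missing = flags.set_index("participant_id").loc[2, "failed"]
        assert pd.isna(missing)
        assert prop == 1.0  # only participant 1 counts


class TestValiditySummaries:
    def test_constant_answers_give_constant_means(self):
        tto = pd.DataFrame(
            {
                "participant_id": [1, 1, 2],
                "state": ["111111", "222333", "111111"],
                "w": [0.5, 0.5, 0.5],
                "is_learning": [False, False, False],
            }
        )
        dce = pd.DataFrame(
            {
                "participant_id": [1],
                "stateA": ["111111"],
                "stateB": ["333333"],
                "chose_A": [False],
                "is_consistency": [False],
            }
        )
        out = c.validity_summaries(tto, dce)
        assert (out["tto_by_state"]["mean_w"] == 0.5).all()
        assert out["dce_by_pair"]["lss_diff"].iloc[0] == -12

    def test_careless_participants_score_higher_cis(self, mixed_survey):
        rep = cis_report(mixed_survey["tto"]).merge(
            mixed_survey["participants"], on="participant_id"
        )
        careless = rep.loc[rep["careless"], "cis"].mean()
        engaged = rep.loc[~rep["careless"], "cis"].mean()
        assert careless > engaged
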