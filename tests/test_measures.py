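"""Measure construction: transforms, smoothing, aggregation rules, domains."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import modeval as me
from modeval.measures import MeasureError, category_group
from modeval.domains import registered_domain

from conftest import make_tweets


def _counts_stream(day_counts: dict[str, dict[str, int]]):
    """day_counts: {date_str: {community: n_tweets}}"""
    rows = []
    for day, by_comm in day_counts.items():
        for comm, n in by_comm.items():
            for i in range(n):
                rows.append(
                    {"tweet_id": f"{day}-{comm}-{i}", "timestamp": f"{day}T10:00:00",
                     "community_id": comm}
                )
    return make_tweets(rows)


class TestContentProportion:
    def test_even_split_gives_zero_logit(self):
        stream = _counts_stream({"2020-03-01": {"A": 50, "B": 50}})
        out = me.content_proportion(stream)
        assert out["value"].tolist() == pytest.approx([0.0, 0.0])

    def test_three_to_one_split_unsmoothed(self):
        stream = _counts_stream({"2020-03-01": {"A": 75, "B": 25}})
        out = me.content_proportion(stream, smoothing=0.0)
        val_a = out[out["community"] == "A"]["value"].iloc[0]
        assert val_a == pytest.approx(np.log(3.0))

    def test_smoothed_proportions_sum_to_one(self):
        stream = _counts_stream(
            {"2020-03-01": {"A": 10, "B": 3, "C": 1}, "2020-03-02": {"A": 2, "B": 2, "C": 2}}
        )
        out = me.content_proportion(stream)
        p = 1.0 / (1.0 + np.exp(-out["value"]))
        sums = pd.DataFrame({"date": out["date"], "p": p}).groupby("date")["p"].sum()
        np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-12)

    def test_retweets_count_toward_content(self):
        rows = [
            {"tweet_id": "t1", "community_id": "A", "timestamp": "2020-03-01T09:00:00"},
            {"tweet_id": "r1", "community_id": "A", "timestamp": "2020-03-01T10:00:00",
             "is_retweet": True, "retweeted_id": "t1"},
            {"tweet_id": "t2", "community_id": "B", "timestamp": "2020-03-01T11:00:00"},
        ]
        out = me.content_proportion(make_tweets(rows), smoothing=0.0)
        val_a = out[out["community"] == "A"]["value"].iloc[0]
        assert val_a == pytest.approx(np.log(2.0))

    def test_single_community_raises(self):
        with pytest.raises(MeasureError):
            me.content_proportion(_counts_stream({"2020-03-01": {"A": 5}}))


class TestVirality:
    def test_smoothing_floor_and_formula(self):
        tweets = make_tweets(
            [
                {"community_id": "A", "follower_count_at_post": 0, "retweet_count_final": 0},
                {"community_id": "B", "follower_count_at_post": 999, "retweet_count_final": 499},
            ]
        )
        out = me.virality(tweets)
        assert out[out["community"] == "A"]["value"].iloc[0] == pytest.approx(0.0)
        assert out[out["community"] == "B"]["value"].iloc[0] == pytest.approx(np.log(0.5))

    def test_daily_value_is_mean_over_tweets_and_ignores_retweets(self):
        tweets = make_tweets(
            [
                {"community_id": "A", "follower_count_at_post": 9, "retweet_count_final": 4},
                {"community_id": "A", "follower_count_at_post": 4, "retweet_count_final": 9},
                {"community_id": "A", "is_retweet": True, "retweeted_id": "t0",
                 "follower_count_at_post": 1_000_000, "retweet_count_final": 0},
            ]
        )
        out = me.virality(tweets)
        a = np.log(5 / 10)
        b = np.log(10 / 5)
        row = out[out["community"] == "A"].iloc[0]
        assert row["value"] == pytest.approx((a + b) / 2)
        assert row["n"] == 2

    def test_community_day_without_user_tweets_is_nan(self):
        tweets = make_tweets(
            [
                {"community_id": "A", "timestamp": "2020-03-01T10:00:00"},
                {"community_id": "A", "timestamp": "2020-03-02T10:00:00"},
                {"community_id": "B", "timestamp": "2020-03-01T10:00:00"},
                {"community_id": "B", "timestamp": "2020-03-02T10:00:00",
                 "is_retweet": True, "retweeted_id": "x"},
            ]
        )
        out = me.virality(tweets)
        missing = out[(out["community"] == "B") & (out["date"].astype(str) == "2020-03-02")]
        assert np.isnan(missing["value"].iloc[0])
        assert missing["n"].iloc[0] == 0


class TestDomainQuality:
    TABLE = me.DomainQualityTable({"good.com": 0.9, "bad.com": 0.2, "mid.org": 0.5})

    def test_min_rule_over_multiple_urls(self):
        tweets = make_tweets(
            [{"community_id": "A", "urls": "https://good.com/x https://bad.com/y"}]
        )
        out = me.domain_quality(tweets, self.TABLE)
        assert out["value"].iloc[0] == pytest.approx(0.2)

    def test_shared_domain_gives_its_rating(self):
        tweets = make_tweets(
            [{"community_id": "A", "urls": "https://mid.org/1"} for _ in range(5)]
        )
        out = me.domain_quality(tweets, self.TABLE)
        assert out["value"].iloc[0] == pytest.approx(0.5)
        assert out["n"].iloc[0] == 5

    def test_unrated_and_malformed_urls_are_excluded(self):
        tweets = make_tweets(
            [
                {"community_id": "A", "urls": "https://unknown.net/a"},
                {"community_id": "A", "urls": "not a url at all"},
                {"community_id": "A", "urls": "https://good.com/b"},
            ]
        )
        out = me.domain_quality(tweets, self.TABLE)
        assert out["value"].iloc[0] == pytest.approx(0.9)
        assert out["n"].iloc[0] == 1

    def test_lowering_a_domain_rating_never_raises_the_daily_mean(self):
        tweets = make_tweets(
            [
                {"community_id": "A", "urls": "https://good.com/x"},
                {"community_id": "A", "urls": "https://mid.org/y https://good.com/z"},
            ]
        )
        base = me.domain_quality(tweets, self.TABLE)["value"].iloc[0]
        lowered = me.DomainQualityTable({"good.com": 0.3, "bad.com": 0.2, "mid.org": 0.5})
        after = me.domain_quality(tweets, lowered)["value"].iloc[0]
        assert after <= base


class TestTopicAggregation:
    def test_unanimous_skepticism(self):
        assert me.aggregate_topic_labels(["Conspiracy"] * 5) == "skepticism"

    def test_commentary_with_mixed_commentary_labels(self):
        labels = ["Politics", "Morality", "Politics", "Civil liberties", "Politics"]
        assert me.aggregate_topic_labels(labels) == "commentary"

    def test_disagreement_across_sets_is_other(self):
        assert me.aggregate_topic_labels(["Conspiracy"] * 4 + ["Promotion"]) == "other"

    def test_wrong_rater_count_raises(self):
        with pytest.raises(MeasureError):
            me.aggregate_topic_labels(["Conspiracy"] * 4)

    def test_single_category_shortcut_matches_unanimous_rule(self):
        for cat in ("Conspiracy", "Promotion", "Politics", "Other"):
            assert category_group(cat) == me.aggregate_topic_labels([cat] * 5)

    def test_disjoint_rule_sets_required(self):
        with pytest.raises(ValueError):
            me.TopicCategoryRules(skepticism=frozenset({"X"}), promotion=frozenset({"X"}))


class TestTopicShare:
    def test_add_one_smoothing_over_four_groups(self):
        rows = [{"community_id": "A", "topic_label": "Conspiracy"} for _ in range(3)]
        rows += [{"community_id": "A", "topic_label": "Promotion"} for _ in range(7)]
        out = me.topic_share(make_tweets(rows))
        skep = out[out["measure"] == "topic_logit(skepticism)"]["value"].iloc[0]
        expected_p = (3 + 1) / (10 + 4)
        assert skep == pytest.approx(np.log(expected_p / (1 - expected_p)))

    def test_group_shares_sum_to_one_pre_transform(self):
        rows = [{"community_id": "A", "topic_label": lb}
                for lb in ["Conspiracy", "Promotion", "Politics", "Other", "Morality"]]
        out = me.topic_share(make_tweets(rows))
        p = 1.0 / (1.0 + np.exp(-out["value"]))
        assert p.sum() == pytest.approx(1.0)

    def test_unlabeled_tweets_count_in_denominator_only(self):
        rows = [{"community_id": "A", "topic_label": "Conspiracy"},
                {"community_id": "A", "topic_label": ""}]
        out = me.topic_share(make_tweets(rows))
        skep = out[out["measure"] == "topic_logit(skepticism)"]
        assert skep["n"].iloc[0] == 1
        p = 1.0 / (1.0 + np.exp(-skep["value"].iloc[0]))
        assert p == pytest.approx((1 + 1) / (2 + 4))


class TestMonthlyAggregate:
    def test_constant_daily_value_is_preserved(self):
        daily = pd.DataFrame(
            {
                "community": "A",
                "date": pd.date_range("2020-03-01", periods=31, freq="D").date,
                "measure": "virality_log",
                "value": -2.5,
                "n": 10,
            }
        )
        out = me.monthly_aggregate(daily)
        assert out["value"].iloc[0] == pytest.approx(-2.5)
        assert out["n"].iloc[0] == 310

    def test_monthly_proportion_recomputed_from_counts(self):
        days = pd.date_range("2020-03-01", periods=31, freq="D").date
        daily = pd.concat(
            [
                pd.DataFrame({"community": "A", "date": days, "measure": "content_logit",
                              "value": 0.0, "n": 300 // 31 + 1}),
                pd.DataFrame({"community": "B", "date": days, "measure": "content_logit",
                              "value": 0.0, "n": 100 // 31 + 1}),
            ],
            ignore_index=True,
        )
        # set counts so that monthly totals are exactly 300 and 100
        daily.loc[daily["community"] == "A", "n"] = [10] * 30 + [0]
        daily.loc[daily["community"] == "B", "n"] = [3] * 30 + [10]
        out = me.monthly_aggregate(daily, smoothing=0.0)
        val_a = out[out["community"] == "A"]["value"].iloc[0]
        p_a = 1.0 / (1.0 + np.exp(-val_a))
        assert p_a == pytest.approx(300 / 400)

    def test_monthly_counts_conserve_daily_counts(self, small_ecosystem):
        daily = me.content_proportion(small_ecosystem.tweets)
        out = me.monthly_aggregate(daily)
        assert out["n"].sum() == daily["n"].sum()

    def test_partial_months_are_flagged(self):
        days = pd.date_range("2020-03-15", periods=20, freq="D").date
        daily = pd.DataFrame(
            {"community": "A", "date": days, "measure": "quality_mean", "value": 0.5, "n": 1}
        )
        out = me.monthly_aggregate(daily)
        assert out["partial_month"].all()


class TestRegisteredDomain:
    @pytest.mark.parametrize(
        "url,expected",
        [
            ("www.example.com/this-is-an-example.html", "example.com"),
            ("https://sub.news.example.com/a/b?c=1", "example.com"),
            ("http://www.bbc.co.uk/news", "bbc.co.uk"),
            ("https://shop.something.com.au", "something.com.au"),
            ("HTTPS://UPPER.EXAMPLE.COM/x", "example.com"),
            ("example.com", "example.com"),
            ("not a url", None),
            ("", None),
            ("http:///nohost", None),
        ],
    )
    def test_extraction_cases(self, url, expected):
        assert registered_domain(url) == expected

    def test_table_rejects_out_of_range_ratings(self):
        with pytest.raises(ValueError):
            me.DomainQualityTable({"x.com": 1.2})
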