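"""Community-level daily outcome measures.

Builds the dependent variables of the moderation-evaluation designs from a
tweet stream:

* **content_logit** — each community's share of all tweets that day (retweets
  and quotes included), Laplace-smoothed and logit-transformed to control for
  floor and ceiling effects;
* **virality_log** — per user-authored tweet, ``log((retweets+1)/(followers+1))``
  (Laplace smoothing with alpha=1 covers never-retweeted tweets and
  zero-follower accounts), averaged per community-day;
* **quality_mean** — per tweet, the minimum quality rating over its URL
  registered domains; averaged over rated tweets per community-day, untransformed;
* **topic_logit(<group>)** — smoothed share of each topic group (skepticism /
  promotion / commentary / other) among a community's tweets, logit-transformed.

All outputs are tidy frames ``community, date, measure, value, n``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domains import DomainQualityTable
from .synthdata import (
    ALL_CATEGORIES,
    COMMENTARY_CATEGORIES,
    PROMOTION_CATEGORIES,
    SKEPTICISM_CATEGORIES,
)

__all__ = [
    "TopicCategoryRules",
    "aggregate_topic_labels",
    "category_group",
    "content_proportion",
    "virality",
    "domain_quality",
    "topic_share",
    "monthly_aggregate",
    "MeasureError",
]

TOPIC_GROUPS = ("skepticism", "promotion", "commentary", "other")


class MeasureError(ValueError):
    """Raised when a measure's preconditions are violated."""


@dataclass(frozen=True)
class TopicCategoryRules:
    """Category sets and rater count behind the topic-group aggregation rule."""

    skepticism: frozenset = frozenset(SKEPTICISM_CATEGORIES)
    promotion: frozenset = frozenset(PROMOTION_CATEGORIES)
    commentary: frozenset = frozenset(COMMENTARY_CATEGORIES)
    n_raters: int = 5

    def __post_init__(self) -> None:
        if self.skepticism & self.promotion or self.skepticism & self.commentary or (
            self.promotion & self.commentary
        ):
            raise ValueError("category sets must be disjoint")


DEFAULT_RULES = TopicCategoryRules()


def aggregate_topic_labels(labels, rules: TopicCategoryRules = DEFAULT_RULES) -> str:
    """Collapse one topic's rater labels into a group.

    skepticism iff all raters chose skepticism categories; promotion iff all
    raters chose promotion categories; commentary iff at least one rater chose
    a commentary category and none chose skepticism or promotion; other
    otherwise (including any disagreement across sets).
    """
    labels = list(labels)
    if len(labels) != rules.n_raters:
        raise MeasureError(f"expected {rules.n_raters} rater labels, got {len(labels)}")
    if all(lb in rules.skepticism for lb in labels):
        return "skepticism"
    if all(lb in rules.promotion for lb in labels):
        return "promotion"
    if any(lb in rules.commentary for lb in labels) and not any(
        lb in rules.skepticism or lb in rules.promotion for lb in labels
    ):
        return "commentary"
    return "other"


def category_group(category: str, rules: TopicCategoryRules = DEFAULT_RULES) -> str:
    """Group of a single category label (unanimous-rater shortcut)."""
    return aggregate_topic_labels([category] * rules.n_raters, rules)


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _day_index(tweets: pd.DataFrame) -> pd.Series:
    return pd.to_datetime(tweets["timestamp"]).dt.date


def content_proportion(tweets: pd.DataFrame, smoothing: float = 1.0) -> pd.DataFrame:
    """Daily logit content share per community.

    Counts every record (user-authored, retweet, quote alike).  Shares are
    Laplace-smoothed: ``p = (count + a) / (total + a * C)`` with ``a`` the
    smoothing constant and ``C`` the number of communities, so exact zeros and
    ones never reach the logit.
    """
    if len(tweets) == 0:
        raise MeasureError("empty tweet stream")
    communities = sorted(tweets["community_id"].unique())
    if len(communities) < 2:
        raise MeasureError("content proportions need >= 2 communities")
    counts = (
        tweets.groupby([_day_index(tweets), "community_id"], observed=True)
        .size()
        .unstack("community_id", fill_value=0)
        .reindex(columns=communities, fill_value=0)
    )
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise MeasureError("day with zero tweets in stream; drop it in preprocessing first")
    c = len(communities)
    p = (counts + smoothing).div(totals + smoothing * c, axis=0)
    out = p.apply(_logit).stack().rename("value").reset_index()
    out.columns = ["date", "community", "value"]
    out["measure"] = "content_logit"
    out["n"] = counts.stack().reset_index(drop=True).astype(int)
    return out[["community", "date", "measure", "value", "n"]]


def virality(tweets: pd.DataFrame, include_missing_days: bool = True) -> pd.DataFrame:
    """Daily mean log Laplace-smoothed retweets per follower, per community.

    Only user-authored tweets enter; community-days with no user-authored
    tweets come back as NaN rows (to be linearly imputed downstream).
    """
    ua = tweets[~tweets["is_retweet"].astype(bool)]
    if len(ua) == 0:
        raise MeasureError("no user-authored tweets in stream")
    v = np.log(
        (ua["retweet_count_final"].to_numpy(dtype=float) + 1.0)
        / (ua["follower_count_at_post"].to_numpy(dtype=float) + 1.0)
    )
    df = pd.DataFrame({"community": ua["community_id"].to_numpy(), "date": _day_index(ua), "v": v})
    grouped = df.groupby(["community", "date"], observed=True)["v"].agg(["mean", "size"])
    out = grouped.reset_index().rename(columns={"mean": "value", "size": "n"})
    out["measure"] = "virality_log"
    out = out[["community", "date", "measure", "value", "n"]]
    if include_missing_days:
        out = _fill_missing_community_days(out, tweets)
    return out


def domain_quality(
    tweets: pd.DataFrame, table: DomainQualityTable, include_missing_days: bool = True
) -> pd.DataFrame:
    """Daily mean min-rule domain-quality score per community.

    Every record with at least one rated URL contributes its minimum rating;
    tweets with no URLs, or only malformed/unrated ones, are excluded from the
    denominator.
    """
    has_url = tweets["urls"].fillna("") != ""
    with_urls = tweets[has_url]
    scores = np.array(
        [table.tweet_score(u.split()) for u in with_urls["urls"]], dtype=object
    )
    rated = np.array([s is not None for s in scores])
    if len(with_urls) == 0 or not rated.any():
        raise MeasureError("no rated URLs in stream")
    df = pd.DataFrame(
        {
            "community": with_urls["community_id"].to_numpy()[rated],
            "date": _day_index(with_urls).to_numpy()[rated],
            "q": scores[rated].astype(float),
        }
    )
    grouped = df.groupby(["community", "date"], observed=True)["q"].agg(["mean", "size"])
    out = grouped.reset_index().rename(columns={"mean": "value", "size": "n"})
    out["measure"] = "quality_mean"
    out = out[["community", "date", "measure", "value", "n"]]
    if include_missing_days:
        out = _fill_missing_community_days(out, tweets)
    return out


def topic_share(
    tweets: pd.DataFrame,
    rules: TopicCategoryRules = DEFAULT_RULES,
    smoothing: float = 1.0,
) -> pd.DataFrame:
    """Daily smoothed logit share of each topic group, per community.

    Tweets carry a category label (retweets inherit the original's); unlabeled
    tweets count in the denominator only.  Smoothing is add-``a`` over the four
    groups: ``p = (count + a) / (total + a * G)``.
    """
    if len(tweets) == 0:
        raise MeasureError("empty tweet stream")
    labels = tweets["topic_label"].fillna("")
    group = labels.map(lambda lb: category_group(lb, rules) if lb else "unlabeled")
    df = pd.DataFrame(
        {"community": tweets["community_id"].to_numpy(), "date": _day_index(tweets), "group": group}
    )
    totals = df.groupby(["community", "date"], observed=True).size()
    frames = []
    g = len(TOPIC_GROUPS)
    for grp_name in TOPIC_GROUPS:
        counts = (
            df[df["group"] == grp_name].groupby(["community", "date"], observed=True).size()
        ).reindex(totals.index, fill_value=0)
        p = (counts + smoothing) / (totals + smoothing * g)
        out = p.rename("value").reset_index()
        out["value"] = _logit(out["value"].to_numpy())
        out["measure"] = f"topic_logit({grp_name})"
        out["n"] = counts.to_numpy().astype(int)
        frames.append(out[["community", "date", "measure", "value", "n"]])
    return pd.concat(frames, ignore_index=True)


def _fill_missing_community_days(out: pd.DataFrame, tweets: pd.DataFrame) -> pd.DataFrame:
    """Add NaN rows for community-days present in the stream span but absent
    from the measure (no contributing tweets), so imputation can see them."""
    days = sorted(_day_index(tweets).unique())
    communities = sorted(tweets["community_id"].unique())
    full = pd.MultiIndex.from_product([communities, days], names=["community", "date"])
    measure = out["measure"].iloc[0]
    indexed = out.set_index(["community", "date"]).reindex(full)
    indexed["measure"] = measure
    indexed["n"] = indexed["n"].fillna(0).astype(int)
    return indexed.reset_index()[["community", "date", "measure", "value", "n"]]


def monthly_aggregate(daily: pd.DataFrame, smoothing: float = 1.0) -> pd.DataFrame:
    """Calendar-month aggregation of a tidy daily panel.

    Content and topic shares are *recomputed* from monthly counts and then
    logit-transformed; virality and quality are tweet-count-weighted means of
    the daily values (equal to the mean over the month's tweet-level values).
    Partial first/last months are included and flagged.
    """
    if len(daily) == 0:
        raise MeasureError("empty daily panel")
    df = daily.copy()
    df["month"] = pd.to_datetime(df["date"]).dt.to_period("M").astype(str)
    frames = []
    for measure, grp in df.groupby("measure", observed=True, sort=False):
        if measure == "content_logit" or measure.startswith("topic_logit"):
            counts = grp.groupby(["community", "month"], observed=True)["n"].sum()
            if measure == "content_logit":
                totals = counts.groupby("month").sum()
                c = counts.index.get_level_values("community").nunique()
                p = (counts + smoothing) / (counts.index.get_level_values("month").map(totals) + smoothing * c)
            else:
                # group share within the community's monthly tweet total:
                # denominators must come from the stream totals, which equal
                # sum over the four groups' n plus unlabeled; recover from the
                # sibling rows if present, else fall back to this group's n
                denom = (
                    df[df["measure"].str.startswith("topic_logit")]
                    .groupby(["community", "month"], observed=True)["n"]
                    .sum()
                )
                g = len(TOPIC_GROUPS)
                p = (counts + smoothing) / (denom.reindex(counts.index) + smoothing * g)
            out = p.rename("value").reset_index()
            out["value"] = _logit(out["value"].to_numpy(dtype=float))
            out["n"] = counts.to_numpy().astype(int)
        else:
            weighted = grp.assign(w=grp["value"] * grp["n"])
            agg = weighted.groupby(["community", "month"], observed=True).agg(
                wsum=("w", "sum"), n=("n", "sum")
            )
            agg["value"] = agg["wsum"] / agg["n"].where(agg["n"] > 0)
            out = agg.reset_index()[["community", "month", "value", "n"]]
        out["measure"] = measure
        frames.append(out[["community", "month", "measure", "value", "n"]])
    result = pd.concat(frames, ignore_index=True)
    result["partial_month"] = result["month"].isin(_partial_months(pd.to_datetime(df["date"])))
    return result


def _partial_months(dates: pd.Series) -> set[str]:
    partial = set()
    by_month = dates.dt.to_period("M")
    for month, grp in dates.groupby(by_month):
        span_days = grp.dt.normalize().nunique()
        if span_days < month.days_in_month:
            partial.add(str(month))
    return partial
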