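"""Synthetic tweet-ecosystem generator with known ground-truth intervention effects.

The generator emulates the moving parts of a large COVID-vaccine Twitter corpus
that the downstream pipeline needs to exercise: ~tens of communities with
heterogeneous baseline activity, weekly-seasonal autocorrelated daily volumes,
heavy-tailed follower counts, Poisson (optionally negative-binomial) retweet
counts, URL sharing from quality-rated domains, topic-category mixtures,
server-outage gaps, and injectable step interventions of known multiplicative
or additive size.  Every injected effect is recorded in a ground-truth ledger
so recovery studies never re-derive truth from the stream itself.

Daily user-authored volume for community *c* follows

    N_ct ~ Poisson( baseline_c * exp(A * sin(2*pi*t/7) + u_ct) * V_ct )

where ``u_ct`` is a stationary AR(1) process and ``V_ct`` is the product of
multiplicative volume factors of interventions active on day *t*.  All
randomness flows from one root seed through per-community substreams
(``numpy.random.SeedSequence.spawn``), so regenerating a single community is
stable under changes elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConfigurationError",
    "InterventionSpec",
    "EcosystemConfig",
    "EcosystemData",
    "default_config",
    "generate_ecosystem",
    "generate_retweet_graph",
    "generate_lsdv_panel",
    "ar1_series",
    "write_tweets_jsonl",
    "read_tweets_jsonl",
    "write_tweets_csv",
    "write_edges_tsv",
    "write_domain_csv",
    "write_transparency_csv",
    "write_ledger_yaml",
]

# Jamison-style vaccine-discourse categories used for topic labels.
SKEPTICISM_CATEGORIES = ("Alternative medicine", "Conspiracy", "Safety concerns")
PROMOTION_CATEGORIES = (
    "Pro-science",
    "Provaccine policy",
    "Criticizing antivaccine beliefs",
    "Promotion",
    "Safety and efficacy",
)
COMMENTARY_CATEGORIES = ("Civil liberties", "Morality", "Politics")
ALL_CATEGORIES = SKEPTICISM_CATEGORIES + PROMOTION_CATEGORIES + COMMENTARY_CATEGORIES + ("Other",)

#: Synthetic domain-quality pool (invented domains, ratings on the [0, 1]
#: expert-consensus scale used by external news-quality lists).
DEFAULT_DOMAIN_POOL: tuple[tuple[str, float], ...] = (
    ("globalhealthorg.int", 0.95),
    ("healthagency.gov", 0.93),
    ("wire-news.com", 0.90),
    ("metro-times.com", 0.85),
    ("sciencedaily-report.com", 0.80),
    ("video-share.com", 0.65),
    ("open-essays.net", 0.55),
    ("partisan-daily.com", 0.45),
    ("contrarian-finance.com", 0.25),
    ("freedom-health-truth.org", 0.15),
    ("miracle-cures.info", 0.10),
)


class ConfigurationError(ValueError):
    """Raised when an :class:`EcosystemConfig` is internally inconsistent."""


@dataclass(frozen=True)
class InterventionSpec:
    """A step intervention applied to a set of communities from a start date.

    ``effect_on_volume`` and ``effect_on_virality`` are multiplicative factors
    (odds-scale / rate-scale ground truths); ``effect_on_quality`` is an
    additive shift of the mean domain-quality rating; ``effect_on_topic_shares``
    maps category name to a log-odds shift of its mixture weight.
    """

    name: str
    communities: tuple[str, ...]
    start: date
    effect_on_volume: float = 1.0
    effect_on_virality: float = 1.0
    effect_on_quality: float = 0.0
    effect_on_topic_shares: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.effect_on_volume <= 0:
            raise ConfigurationError("effect_on_volume must be > 0")
        if self.effect_on_virality <= 0:
            raise ConfigurationError("effect_on_virality must be > 0")


@dataclass
class EcosystemConfig:
    """Full parameterization of the synthetic ecosystem.

    ``baseline_volume``, ``topic_mixture`` and ``quality_center`` are mappings
    keyed by community id; every community must appear in each.
    """

    n_communities: int
    days: int
    start_date: date
    baseline_volume: dict[str, float]
    ar_coefficient: float = 0.5
    volume_noise_sd: float = 0.15
    weekly_seasonality_amplitude: float = 0.10
    follower_mu_log: float = 7.0
    follower_sigma_log: float = 0.8
    retweet_rate: float = 0.05
    retweet_dispersion: float | None = None  # None -> Poisson; else NB size parameter
    engagement_noise_sd: float = 0.20
    engagement_ar: float = 0.3
    retweet_record_fraction: float = 0.3
    url_probability: float = 0.5
    accounts_per_community: int = 300
    within_community_retweet_prob: float = 0.9
    domain_pool: tuple[tuple[str, float], ...] = DEFAULT_DOMAIN_POOL
    quality_center: dict[str, float] = field(default_factory=dict)
    topic_mixture: dict[str, dict[str, float]] = field(default_factory=dict)
    interventions: tuple[InterventionSpec, ...] = ()
    outage_days: tuple[date, ...] = ()
    seed: int = 0

    @property
    def communities(self) -> list[str]:
        return sorted(self.baseline_volume)

    @property
    def end_date(self) -> date:
        return self.start_date + timedelta(days=self.days - 1)

    def validate(self) -> None:
        if self.n_communities != len(self.baseline_volume):
            raise ConfigurationError(
                "baseline_volume must have one entry per community (n_communities)"
            )
        if self.days < 1:
            raise ConfigurationError("days must be >= 1")
        if not (-1.0 < self.ar_coefficient < 1.0):
            raise ConfigurationError("ar_coefficient must lie in (-1, 1)")
        if self.weekly_seasonality_amplitude < 0:
            raise ConfigurationError("weekly_seasonality_amplitude must be >= 0")
        for c, v in self.baseline_volume.items():
            if v <= 0:
                raise ConfigurationError(f"baseline_volume for {c!r} must be > 0")
        for d, q in self.domain_pool:
            if not (0.0 <= q <= 1.0):
                raise ConfigurationError(f"domain quality for {d!r} outside [0, 1]")
        for c, mix in self.topic_mixture.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"topic_mixture for {c!r} sums to {total}, not 1")
            if any(p < 0 for p in mix.values()):
                raise ConfigurationError(f"topic_mixture for {c!r} has negative weights")
        span = {self.start_date + timedelta(days=i) for i in range(self.days)}
        for iv in self.interventions:
            unknown = set(iv.communities) - set(self.baseline_volume)
            if unknown:
                raise ConfigurationError(
                    f"intervention {iv.name!r} targets unknown communities {sorted(unknown)}"
                )
            if iv.start not in span:
                raise ConfigurationError(
                    f"intervention {iv.name!r} start {iv.start} outside simulated span"
                )
        for d in self.outage_days:
            if d not in span:
                raise ConfigurationError(f"outage day {d} outside simulated span")


@dataclass
class EcosystemData:
    """Bundle returned by :func:`generate_ecosystem`."""

    tweets: pd.DataFrame
    edges: pd.DataFrame
    domain_table: pd.DataFrame
    transparency: pd.DataFrame
    ledger: dict
    config: EcosystemConfig


def default_config(
    n_communities: int = 4,
    days: int = 462,
    start_date: date = date(2020, 2, 7),
    baseline_volume: float = 120.0,
    interventions: tuple[InterventionSpec, ...] = (),
    outage_days: tuple[date, ...] = (),
    seed: int = 0,
    **overrides,
) -> EcosystemConfig:
    """Build a ready-to-run config with alternating community profiles.

    Even-indexed communities (``skeptic_0``, ``skeptic_1``, ...) get a
    skepticism-leaning topic mixture and a low domain-quality center;
    odd-indexed communities (``promoter_0``, ...) lean toward promotion with a
    high quality center.  This mirrors the treated/comparator pairing the CITS
    design needs.
    """
    baselines: dict[str, float] = {}
    centers: dict[str, float] = {}
    mixtures: dict[str, dict[str, float]] = {}
    for i in range(n_communities):
        if i % 2 == 0:
            name = f"skeptic_{i // 2}"
            centers[name] = 0.45
            raw = {c: 2.0 for c in SKEPTICISM_CATEGORIES}
            raw.update({c: 0.5 for c in PROMOTION_CATEGORIES})
            raw.update({c: 1.0 for c in COMMENTARY_CATEGORIES})
            raw["Other"] = 1.5
        else:
            name = f"promoter_{i // 2}"
            centers[name] = 0.75
            raw = {c: 0.5 for c in SKEPTICISM_CATEGORIES}
            raw.update({c: 2.0 for c in PROMOTION_CATEGORIES})
            raw.update({c: 0.7 for c in COMMENTARY_CATEGORIES})
            raw["Other"] = 1.5
        total = sum(raw.values())
        mixtures[name] = {c: raw[c] / total for c in ALL_CATEGORIES}
        baselines[name] = baseline_volume
    cfg = EcosystemConfig(
        n_communities=n_communities,
        days=days,
        start_date=start_date,
        baseline_volume=baselines,
        quality_center=centers,
        topic_mixture=mixtures,
        interventions=tuple(interventions),
        outage_days=tuple(outage_days),
        seed=seed,
    )
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise ConfigurationError(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


def ar1_series(
    n: int, phi: float, sigma: float = 1.0, mu: float = 0.0, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Stationary Gaussian AR(1) path of length ``n`` around mean ``mu``.

    The initial state is drawn from the stationary distribution so there is no
    burn-in transient.
    """
    rng = rng or np.random.default_rng()
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma / np.sqrt(1.0 - phi**2))
    eps = rng.normal(0.0, sigma, size=n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return mu + x


def _domain_weights(pool: np.ndarray, center: float, width: float = 0.2) -> np.ndarray:
    w = np.exp(-((pool - center) ** 2) / (2.0 * width**2))
    return w / w.sum()


def _shift_quality_mix(weights: np.ndarray, qualities: np.ndarray, delta: float) -> np.ndarray:
    """Reweight a domain mixture so its mean quality moves by exactly ``delta``.

    Mixes the base weights with a point mass on the extreme-quality domain;
    the mixing weight solves the mean equation in closed form, so the induced
    additive shift is exact in expectation.
    """
    if delta == 0.0:
        return weights
    mu = float(weights @ qualities)
    idx = int(np.argmin(qualities)) if delta < 0 else int(np.argmax(qualities))
    q_star = qualities[idx]
    if abs(q_star - mu) < 1e-12:
        raise ConfigurationError("degenerate domain pool: no room to shift mean quality")
    w = delta / (q_star - mu)
    if not (0.0 <= w <= 1.0):
        raise ConfigurationError(
            f"effect_on_quality={delta} pushes the mean outside the domain pool's range"
        )
    out = (1.0 - w) * weights
    out[idx] += w
    return out


def _shift_topic_mix(probs: np.ndarray, shifts: dict[str, float]) -> np.ndarray:
    if not shifts:
        return probs
    mult = np.array([np.exp(shifts.get(c, 0.0)) for c in ALL_CATEGORIES])
    out = probs * mult
    return out / out.sum()


def _nb_or_poisson(rng: np.random.Generator, lam: np.ndarray, dispersion: float | None) -> np.ndarray:
    if dispersion is None:
        return rng.poisson(lam)
    # Gamma-Poisson mixture: mean lam, variance lam + lam^2 / dispersion.
    shape = dispersion
    gamma = rng.gamma(shape, lam / shape)
    return rng.poisson(gamma)


def generate_ecosystem(config: EcosystemConfig) -> EcosystemData:
    """Generate the full synthetic ecosystem from one root seed.

    Returns tweet stream, aggregated retweet edge list, domain-quality table,
    monthly transparency table and the ground-truth ledger.  Fully reproducible:
    the same config (including seed) yields byte-identical outputs.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    communities = config.communities
    # substream 0..n-1: communities; n: transparency; n+1: graph helpers
    children = root.spawn(len(communities) + 2)

    qualities = np.array([q for _, q in config.domain_pool])
    domains = np.array([d for d, _ in config.domain_pool])
    dates = pd.date_range(config.start_date, periods=config.days, freq="D")
    outage_mask = np.isin(dates.date, np.array(config.outage_days, dtype=object))

    frames = []
    account_pools = {
        c: np.array([f"{c}:acct{j:04d}" for j in range(config.accounts_per_community)])
        for c in communities
    }
    # Zipf-like account activity weights shared across communities.
    act_w = 1.0 / np.arange(1, config.accounts_per_community + 1) ** 1.1
    act_w /= act_w.sum()
    cum_act = np.cumsum(act_w)

    def _weighted_idx(rng: np.random.Generator, cumw: np.ndarray, size: int) -> np.ndarray:
        return np.searchsorted(cumw, rng.random(size) * cumw[-1], side="right").clip(
            0, len(cumw) - 1
        )

    for ci, c in enumerate(communities):
        rng = np.random.default_rng(children[ci])
        t = np.arange(config.days)
        seasonal = config.weekly_seasonality_amplitude * np.sin(2 * np.pi * t / 7.0)
        u = ar1_series(config.days, config.ar_coefficient, config.volume_noise_sd, rng=rng)
        day_mult = np.exp(
            ar1_series(config.days, config.engagement_ar, config.engagement_noise_sd, rng=rng)
        )

        vol_factor = np.ones(config.days)
        vir_factor = np.ones(config.days)
        qual_shift = np.zeros(config.days)
        topic_state = np.zeros(config.days, dtype=np.int64)  # bitmask of active interventions
        topic_ivs = []
        for iv in config.interventions:
            if c not in iv.communities:
                continue
            start_idx = (iv.start - config.start_date).days
            vol_factor[start_idx:] *= iv.effect_on_volume
            vir_factor[start_idx:] *= iv.effect_on_virality
            qual_shift[start_idx:] += iv.effect_on_quality
            if iv.effect_on_topic_shares:
                topic_state[start_idx:] |= 1 << len(topic_ivs)
                topic_ivs.append(iv)

        lam = config.baseline_volume[c] * np.exp(seasonal + u) * vol_factor
        n_ua = rng.poisson(lam)
        n_rt = rng.poisson(config.retweet_record_fraction * lam)
        n_ua[outage_mask] = 0
        n_rt[outage_mask] = 0
        n_rt[n_ua == 0] = 0  # retweet records need a same-day original
        m_total = int(n_ua.sum())
        k_total = int(n_rt.sum())

        base_dw = _domain_weights(qualities, config.quality_center.get(c, 0.6))
        base_tp = np.array(
            [
                config.topic_mixture.get(c, {cat: 1 / len(ALL_CATEGORIES) for cat in ALL_CATEGORIES})[
                    cat
                ]
                for cat in ALL_CATEGORIES
            ]
        )

        day_of_ua = np.repeat(t, n_ua)
        followers = np.floor(
            rng.lognormal(config.follower_mu_log, config.follower_sigma_log, size=m_total)
        ).astype(np.int64)
        rt_lam = config.retweet_rate * followers * day_mult[day_of_ua] * vir_factor[day_of_ua]
        rts = _nb_or_poisson(rng, rt_lam, config.retweet_dispersion)
        has_url = rng.random(m_total) < config.url_probability

        # domain and topic draws: segment tweets by intervention state so the
        # categorical draws stay vectorized per state
        dom_idx = np.empty(m_total, dtype=np.int64)
        topic_idx = np.empty(m_total, dtype=np.int64)
        state_ua = qual_shift[day_of_ua]
        for shift in np.unique(qual_shift):
            mask = state_ua == shift
            dw = _shift_quality_mix(base_dw.copy(), qualities, float(shift))
            dom_idx[mask] = _weighted_idx(rng, np.cumsum(dw), int(mask.sum()))
        tstate_ua = topic_state[day_of_ua]
        for st in np.unique(topic_state):
            mask = tstate_ua == st
            shifts: dict[str, float] = {}
            for bit, iv in enumerate(topic_ivs):
                if st >> bit & 1:
                    for k, v in iv.effect_on_topic_shares.items():
                        shifts[k] = shifts.get(k, 0.0) + v
            tp = _shift_topic_mix(base_tp, shifts)
            topic_idx[mask] = _weighted_idx(rng, np.cumsum(tp), int(mask.sum()))

        urls = np.where(
            has_url,
            np.char.add("https://www.", np.char.add(domains[dom_idx], "/post")),
            "",
        )
        authors = account_pools[c][_weighted_idx(rng, cum_act, m_total)]
        secs_ua = rng.integers(0, 86400, size=m_total)
        ids = np.array([f"{c}:u{j}" for j in range(m_total)])
        topic_labels = np.array(ALL_CATEGORIES, dtype=object)[topic_idx]

        part = pd.DataFrame(
            {
                "tweet_id": ids,
                "author_id": authors,
                "community_id": c,
                "day": day_of_ua,
                "secs": secs_ua,
                "is_retweet": False,
                "retweeted_id": "",
                "follower_count_at_post": followers,
                "retweet_count_final": rts,
                "urls": urls,
                "topic_label": topic_labels,
            }
        )
        parts = [part]

        if k_total:
            # retweet records reference same-day originals, weighted by the
            # original author's follower count (hubs attract shares)
            day_of_rt = np.repeat(t, n_rt)
            src = np.empty(k_total, dtype=np.int64)
            ua_start = np.concatenate([[0], np.cumsum(n_ua)])
            rt_start = np.concatenate([[0], np.cumsum(n_rt)])
            w = followers + 1.0
            unif = rng.random(k_total)
            for d in np.nonzero(n_rt)[0]:
                lo, hi = ua_start[d], ua_start[d + 1]
                cw = np.cumsum(w[lo:hi])
                blk = slice(rt_start[d], rt_start[d + 1])
                src[blk] = lo + np.searchsorted(
                    cw, unif[blk] * cw[-1], side="right"
                ).clip(0, hi - lo - 1)
            cross = rng.random(k_total) >= config.within_community_retweet_prob
            rt_authors = account_pools[c][_weighted_idx(rng, cum_act, k_total)].astype(object)
            if cross.any() and len(communities) > 1:
                others = [o for o in communities if o != c]
                pick = rng.integers(len(others), size=int(cross.sum()))
                aidx = _weighted_idx(rng, cum_act, int(cross.sum()))
                rt_authors[cross] = np.array(
                    [account_pools[others[p]][a] for p, a in zip(pick, aidx)], dtype=object
                )
            parts.append(
                pd.DataFrame(
                    {
                        "tweet_id": np.array([f"{c}:r{j}" for j in range(k_total)]),
                        "author_id": rt_authors,
                        "community_id": c,
                        "day": day_of_rt,
                        "secs": rng.integers(0, 86400, size=k_total),
                        "is_retweet": True,
                        "retweeted_id": ids[src],
                        "follower_count_at_post": np.floor(
                            rng.lognormal(
                                config.follower_mu_log, config.follower_sigma_log, size=k_total
                            )
                        ).astype(np.int64),
                        "retweet_count_final": np.zeros(k_total, dtype=np.int64),
                        "urls": urls[src],
                        "topic_label": topic_labels[src],
                    }
                )
            )
        frames.append(pd.concat(parts, ignore_index=True))

    if frames:
        tweets = pd.concat(frames, ignore_index=True)
        tweets["timestamp"] = (
            pd.to_datetime(dates[tweets["day"].to_numpy()].date)
            + pd.to_timedelta(tweets["secs"].to_numpy(), unit="s")
        )
        tweets = tweets.drop(columns=["day", "secs"])
        tweets = tweets.sort_values(["timestamp", "tweet_id"], kind="mergesort").reset_index(
            drop=True
        )
    else:
        tweets = pd.DataFrame(
            columns=[
                "tweet_id",
                "author_id",
                "community_id",
                "is_retweet",
                "retweeted_id",
                "follower_count_at_post",
                "retweet_count_final",
                "urls",
                "topic_label",
                "timestamp",
            ]
        )

    # aggregate the stream's retweet records into the weighted edge list
    rt = tweets[tweets["is_retweet"]]
    if len(rt):
        originals = tweets.loc[~tweets["is_retweet"], ["tweet_id", "author_id"]].rename(
            columns={"author_id": "original_author"}
        )
        merged = rt.merge(originals, left_on="retweeted_id", right_on="tweet_id", how="inner")
        edges = (
            merged.groupby(["author_id", "original_author"], observed=True)
            .size()
            .reset_index(name="weight")
            .rename(columns={"author_id": "source", "original_author": "target"})
        )
        edges = edges[edges["source"] != edges["target"]].reset_index(drop=True)
    else:
        edges = pd.DataFrame(columns=["source", "target", "weight"])

    domain_table = pd.DataFrame(config.domain_pool, columns=["domain", "quality"])
    transparency = _transparency_table(config, np.random.default_rng(children[len(communities)]))
    ledger = {
        "seed": config.seed,
        "interventions": [
            {
                "name": iv.name,
                "communities": list(iv.communities),
                "start": iv.start.isoformat(),
                "effect_on_volume": float(iv.effect_on_volume),
                "effect_on_virality": float(iv.effect_on_virality),
                "effect_on_quality": float(iv.effect_on_quality),
                "effect_on_topic_shares": {k: float(v) for k, v in iv.effect_on_topic_shares.items()},
                "log_odds_ratio_volume": float(np.log(iv.effect_on_volume)),
                "log_relative_risk_virality": float(np.log(iv.effect_on_virality)),
                "delta_quality": float(iv.effect_on_quality),
            }
            for iv in config.interventions
        ],
    }
    return EcosystemData(tweets, edges, domain_table, transparency, ledger, config)


def _transparency_table(config: EcosystemConfig, rng: np.random.Generator) -> pd.DataFrame:
    months = pd.period_range(config.start_date, config.end_date, freq="M")
    n = len(months)
    ramp = 1.0 + 0.15 * np.arange(n)
    content = np.maximum(1, rng.poisson(2000 * ramp)).astype(int)
    accounts = np.maximum(1, rng.poisson(80 * ramp)).astype(int)
    return pd.DataFrame(
        {"month": months.astype(str), "content_removed": content, "accounts_suspended": accounts}
    )


def generate_retweet_graph(config: EcosystemConfig) -> pd.DataFrame:
    """Standalone preferential-attachment retweet graph with planted communities.

    Independent of the tweet stream: nodes attach within their own community
    with probability ``within_community_retweet_prob`` and pick targets with
    probability proportional to current in-strength plus one (rich-get-richer),
    which yields hub-dominated, approximately scale-free in-degree profiles.
    Edge weights are integer retweet counts >= 1.
    """
    config.validate()
    if config.n_communities < 2:
        raise ConfigurationError("generate_retweet_graph requires >= 2 communities")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x9E37]))
    communities = config.communities
    nodes = {c: [f"{c}:acct{j:04d}" for j in range(config.accounts_per_community)] for c in communities}
    in_strength = {c: np.ones(config.accounts_per_community) for c in communities}
    rows: dict[tuple[str, str], int] = {}
    m_out = 4
    for c in communities:
        for j in range(config.accounts_per_community):
            src = nodes[c][j]
            for _ in range(m_out):
                if rng.random() < config.within_community_retweet_prob or len(communities) == 1:
                    tc = c
                else:
                    others = [o for o in communities if o != c]
                    tc = others[rng.integers(len(others))]
                w = in_strength[tc].copy()
                if tc == c:
                    w[j] = 0.0  # no self-loops
                p = w / w.sum()
                tj = rng.choice(config.accounts_per_community, p=p)
                weight = 1 + rng.poisson(1.0)
                key = (src, nodes[tc][tj])
                rows[key] = rows.get(key, 0) + int(weight)
                in_strength[tc][tj] += weight
    edges = pd.DataFrame(
        [(s, t, w) for (s, t), w in sorted(rows.items())], columns=["source", "target", "weight"]
    )
    return edges


def generate_lsdv_panel(
    n_communities: int = 6,
    n_months: int = 27,
    beta_content: float = -0.5,
    beta_suspended: float = 0.3,
    rho: float = 0.3,
    interaction_content: dict[str, float] | None = None,
    noise_sd: float = 0.3,
    start_month: str = "2020-07",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Synthetic monthly panel generated from known LSDV coefficients.

    Returns ``(monthly_outcomes, transparency, truth)``.  Predictors are the
    platform-wide transparency counts (standardized inside the truth model so
    coefficients are on interpretable scales); the outcome follows

        y_{c,t} = alpha_c + rho * y_{c,t-1}
                  + (beta_content + gamma_c) * x1_{t-1} + beta_suspended * x2_{t-1}
                  + eps_{c,t}

    with ``x1``/``x2`` standardized AR(1) enforcement-intensity series and
    iid Gaussian noise.  ``truth`` records every coefficient.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x15DB]))
    months = pd.period_range(start_month, periods=n_months, freq="M")
    communities = [f"comm_{i}" for i in range(n_communities)]
    x1 = ar1_series(n_months, 0.5, 1.0, rng=rng)
    x2 = ar1_series(n_months, 0.5, 1.0, rng=rng)
    x1 = (x1 - x1.mean()) / x1.std()
    x2 = (x2 - x2.mean()) / x2.std()
    alphas = {c: rng.normal(0.0, 1.0) for c in communities}
    gammas = {c: 0.0 for c in communities}
    if interaction_content:
        gammas.update(interaction_content)
    rows = []
    for c in communities:
        y_prev = alphas[c] / (1 - rho)
        for t in range(n_months):
            xl1 = x1[t - 1] if t >= 1 else 0.0
            xl2 = x2[t - 1] if t >= 1 else 0.0
            y = (
                alphas[c]
                + rho * y_prev
                + (beta_content + gammas[c]) * xl1
                + beta_suspended * xl2
                + rng.normal(0.0, noise_sd)
            )
            rows.append({"community": c, "month": str(months[t]), "value": y})
            y_prev = y
    outcomes = pd.DataFrame(rows)
    transparency = pd.DataFrame(
        {"month": months.astype(str), "content_removed": x1, "accounts_suspended": x2}
    )
    truth = {
        "beta_content": beta_content,
        "beta_suspended": beta_suspended,
        "rho": rho,
        "alphas": alphas,
        "interaction_content": gammas,
        "noise_sd": noise_sd,
    }
    return outcomes, transparency, truth


# ---------------------------------------------------------------------------
# plain-text writers


def _tweets_records(tweets: pd.DataFrame):
    for row in tweets.itertuples(index=False):
        yield {
            "tweet_id": row.tweet_id,
            "author_id": row.author_id,
            "community_id": row.community_id,
            "timestamp": pd.Timestamp(row.timestamp).strftime("%Y-%m-%dT%H:%M:%SZ"),
            "is_retweet": bool(row.is_retweet),
            "retweeted_id": row.retweeted_id or None,
            "follower_count_at_post": int(row.follower_count_at_post),
            "retweet_count_final": int(row.retweet_count_final),
            "urls": row.urls.split() if row.urls else [],
            "topic_label": row.topic_label if row.topic_label else None,
        }


def write_tweets_jsonl(tweets: pd.DataFrame, path) -> None:
    import json

    with open(path, "w") as fh:
        for rec in _tweets_records(tweets):
            fh.write(json.dumps(rec) + "\n")


def read_tweets_jsonl(path) -> pd.DataFrame:
    import json

    rows = []
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            rec["urls"] = " ".join(rec.get("urls") or [])
            rec["retweeted_id"] = rec.get("retweeted_id") or ""
            rec["topic_label"] = rec.get("topic_label") or ""
            rows.append(rec)
    df = pd.DataFrame(rows)
    if len(df):
        df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.tz_localize(None)
    return df


def write_tweets_csv(tweets: pd.DataFrame, path) -> None:
    out = tweets.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def read_tweets_csv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"urls": str, "retweeted_id": str, "topic_label": str},
        keep_default_na=False,
    )
    if len(df):
        df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.tz_localize(None)
        df["is_retweet"] = df["is_retweet"].astype(bool)
    return df


def write_edges_tsv(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False, header=False)


def write_domain_csv(domain_table: pd.DataFrame, path) -> None:
    domain_table.to_csv(path, index=False)


def write_transparency_csv(transparency: pd.DataFrame, path) -> None:
    transparency.to_csv(path, index=False)


def write_ledger_yaml(ledger: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(ledger, fh, sort_keys=False)
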