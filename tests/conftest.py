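"""Shared fixtures: small ecosystems and the two heavyweight simulation
studies (null calibration, parameter recovery), run once per session."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest

import modeval as me
from modeval.synthdata import ar1_series


def make_tweets(rows: list[dict]) -> pd.DataFrame:
    """Minimal tweet frame from per-row dicts with convenient defaults."""
    defaults = {
        "tweet_id": None,
        "author_id": "a1",
        "community_id": "c1",
        "timestamp": "2020-03-01T12:00:00",
        "is_retweet": False,
        "retweeted_id": "",
        "follower_count_at_post": 10,
        "retweet_count_final": 0,
        "urls": "",
        "topic_label": "",
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults, **row)
        if rec["tweet_id"] is None:
            rec["tweet_id"] = f"t{i}"
        out.append(rec)
    df = pd.DataFrame(out, columns=list(defaults))
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


@pytest.fixture(scope="session")
def small_ecosystem() -> me.EcosystemData:
    cfg = me.default_config(
        n_communities=2, days=90, start_date=date(2020, 2, 7), baseline_volume=40.0, seed=11
    )
    return me.generate_ecosystem(cfg)


def fit_and_test_pair(
    rng: np.random.Generator,
    n: int = 540,
    k: int = 30,
    B: int = 200,
    phi: float = 0.5,
    shift: float = 0.0,
    alpha: float = 0.05,
):
    """One null/alternative replicate: simulate a treated/comparator AR(1)
    pair, fit the pre-periods, simulate counterfactuals, and return the
    completed single-series summaries plus the comparative effect.

    ``shift`` is added to the treated series post-period (the alternative)."""
    results = {}
    for role in ("treated", "comparator"):
        y = ar1_series(n + k, phi, 1.0, mu=0.0, rng=rng)
        if role == "treated" and shift:
            y[n:] += shift
        fit = me.fit_pre_period(y[:n], order=(1, 0, 0))
        cf = me.simulate_counterfactual(
            fit, k=k, B=B, seed=int(rng.integers(2**31)), alpha=alpha
        )
        results[role] = me.single_series_z(cf, y[n:])
    comp = me.comparative_z(results["treated"], results["comparator"], pooling="sum")
    return results["treated"], results["comparator"], comp


@pytest.fixture(scope="session")
def null_study():
    """300 null replicates of a treated/comparator pair (no injected effect):
    single-series and comparative Z plus the realized-mean coverage record."""
    rng = np.random.default_rng(20240307)
    single_reject = []
    comparative_reject = []
    covered = []
    for _ in range(300):
        treated, _, comp = fit_and_test_pair(rng)
        single_reject.append(abs(treated.z) > treated.z_crit)
        comparative_reject.append(abs(comp.z) > treated.z_crit)
        lo, hi = treated.ci
        covered.append(lo <= 0.0 <= hi)
    return {
        "n": 300,
        "single_rejection_rate": float(np.mean(single_reject)),
        "comparative_rejection_rate": float(np.mean(comparative_reject)),
        "coverage": float(np.mean(covered)),
    }


def recovery_replicate(seed: int, B: int = 200):
    """One parameter-recovery replicate: synthetic ecosystem with a known
    intervention (volume odds factor 2.0, virality rate factor 1.4, quality
    shift -0.07) at day 420 of 462; returns single-series treated effects."""
    from datetime import timedelta

    phase_start = date(2020, 2, 7) + timedelta(days=420)
    iv = me.InterventionSpec(
        name="policy",
        communities=("skeptic_0",),
        start=phase_start,
        effect_on_volume=2.0,
        effect_on_virality=1.4,
        effect_on_quality=-0.07,
    )
    cfg = me.default_config(
        n_communities=2,
        days=462,
        start_date=date(2020, 2, 7),
        baseline_volume=120.0,
        interventions=(iv,),
        seed=seed,
    )
    eco = me.generate_ecosystem(cfg)
    table = me.DomainQualityTable.from_frame(eco.domain_table)
    panel = pd.concat(
        [
            me.content_proportion(eco.tweets),
            me.virality(eco.tweets),
            me.domain_quality(eco.tweets, table),
        ],
        ignore_index=True,
    )
    start = iv.start
    out = {}
    for mi, measure in enumerate(("content_logit", "virality_log", "quality_mean")):
        s = (
            panel[(panel["measure"] == measure) & (panel["community"] == "skeptic_0")]
            .assign(date=lambda d: pd.to_datetime(d["date"]))
            .set_index("date")["value"]
            .sort_index()
        )
        pre = s[s.index < pd.Timestamp(start)]
        post = s[s.index >= pd.Timestamp(start)]
        fit = me.fit_pre_period(pre.to_numpy(), order=(1, 0, 0))
        cf = me.simulate_counterfactual(
            fit, k=len(post), B=B, seed=np.random.SeedSequence([seed, mi])
        )
        cf = me.single_series_z(cf, post.to_numpy())
        _, est = me.effect_scale(cf.deviation, measure)
        _, lo = me.effect_scale(cf.ci[0], measure)
        _, hi = me.effect_scale(cf.ci[1], measure)
        out[measure] = {"estimate": est, "lo": lo, "hi": hi}
    return out


TRUTH = {"content_logit": 2.0, "virality_log": 1.4, "quality_mean": -0.07}


@pytest.fixture(scope="session")
def recovery_study():
    """100-seed recovery of the injected intervention effects."""
    estimates = {m: [] for m in TRUTH}
    covered = {m: [] for m in TRUTH}
    for seed in range(100):
        rep = recovery_replicate(seed)
        for m, truth in TRUTH.items():
            estimates[m].append(rep[m]["estimate"])
            covered[m].append(rep[m]["lo"] <= truth <= rep[m]["hi"])
    return {
        "medians": {m: float(np.median(v)) for m, v in estimates.items()},
        "coverage_counts": {m: int(np.sum(v)) for m, v in covered.items()},
        "n": 100,
    }


@pytest.fixture(scope="session")
def lsdv_recovery_study():
    """100-seed LSDV coefficient recovery against 2-HAC-SE bands,
    tracked per structural coefficient."""
    names = (
        "content_removed_lag1",
        "accounts_suspended_lag1",
        "D[comm_2]:content_removed_lag1",
    )
    hits = {n: [] for n in names}
    for seed in range(100):
        outcomes, transparency, truth = me.generate_lsdv_panel(
            seed=seed, interaction_content={"comm_2": 0.4}
        )
        fit = me.fit_lsdv(me.build_panel(outcomes, transparency))
        truths = {
            "content_removed_lag1": truth["beta_content"],
            "accounts_suspended_lag1": truth["beta_suspended"],
            "D[comm_2]:content_removed_lag1": truth["interaction_content"]["comm_2"],
        }
        for n in names:
            hits[n].append(abs(fit.params[n] - truths[n]) <= 2.0 * fit.hac_se[n])
    return {"within_2se_counts": {n: int(np.sum(v)) for n, v in hits.items()}, "n": 100}
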