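"""Estimate a policy effect with the comparative interrupted time series.

Injects a known intervention (volume odds factor 2.0, virality rate factor
1.4, quality shift -0.07) on the treated community, fits pre-period SARIMAX
models, simulates counterfactual forecasts, and reports single-series and
comparative effects on their natural scales.
"""

from datetime import date

import pandas as pd

import modeval as me

policy_start = date(2020, 8, 1)
intervention = me.InterventionSpec(
    name="policy",
    communities=("skeptic_0",),
    start=policy_start,
    effect_on_volume=2.0,
    effect_on_virality=1.4,
    effect_on_quality=-0.07,
)
config = me.default_config(
    n_communities=2,
    days=240,
    start_date=date(2020, 2, 7),
    baseline_volume=80.0,
    interventions=(intervention,),
    seed=3,
)
eco = me.generate_ecosystem(config)
table = me.DomainQualityTable.from_frame(eco.domain_table)
panel = pd.concat(
    [
        me.content_proportion(eco.tweets),
        me.virality(eco.tweets),
        me.domain_quality(eco.tweets, table),
    ],
    ignore_index=True,
)
panel = me.impute_measures(panel, me.detect_outages(eco.tweets).dropped_days)

phases = me.PhaseDesign(
    [
        me.Phase("baseline", date(2020, 2, 7), date(2020, 7, 31)),
        me.Phase("policy", policy_start, date(2020, 10, 2)),
    ]
)
effects = me.run_cits(
    panel,
    phases,
    pairs={"skeptic_0": "promoter_0"},
    evaluate=["policy"],
    measures=["content_logit", "virality_log", "quality_mean"],
    B=500,
    seed=1,
    order=(1, 0, 0),
)

cols = ["measure", "role", "scale", "estimate", "lo", "hi", "z", "p"]
print(effects[cols].round(3).to_string(index=False))

# Reading the treated rows: the content odds ratio near 2.0 (CI covering 2.0)
# recovers the injected volume doubling; the relative risk near 1.4 recovers
# the virality factor; the quality delta near -0.07 recovers the additive
# shift.  Comparator rows should show no effect on virality/quality, and the
# comparative rows standardize treated-minus-comparator deviations by the
# pooled forecast spread (Z >> 1.96 flags a clear policy-associated change).
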