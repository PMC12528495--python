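"""Relate outcomes to moderation *intensity* with the fixed-effects model.

Generates a monthly panel from known coefficients (content removals depress
the outcome, suspensions raise it, one community reacts differently), fits
the least-squares dummy-variable regression with one-month-lagged predictors,
a lagged dependent variable and HAC errors, and checks residual stationarity.
"""

import pandas as pd

import modeval as me

outcomes, transparency, truth = me.generate_lsdv_panel(
    n_communities=6,
    n_months=27,
    beta_content=-0.5,
    beta_suspended=0.3,
    rho=0.3,
    interaction_content={"comm_2": 0.4},
    seed=42,
)

design = me.build_panel(outcomes, transparency)
fit = me.fit_lsdv(design)

rows = [
    ("content_removed_lag1", truth["beta_content"]),
    ("accounts_suspended_lag1", truth["beta_suspended"]),
    ("value_lag1", truth["rho"]),
    ("D[comm_2]:content_removed_lag1", truth["interaction_content"]["comm_2"]),
]
print(f"panel: {len(design.data)} rows "
      f"({design.data['community'].nunique()} communities x "
      f"{design.data['month'].nunique()} months), "
      f"reference community {fit.reference_community!r}, HAC lags {fit.hac_lags}")
print(f"\n{'coefficient':34s} {'estimate':>9s} {'HAC SE':>8s} {'truth':>7s}")
for name, tv in rows:
    print(f"{name:34s} {fit.params[name]:9.3f} {fit.hac_se[name]:8.3f} {tv:7.3f}")

adf = me.residual_stationarity(fit)
pooled = adf[adf["community"] == "__pooled__"]["verdict"].iloc[0]
print(f"\nresidual stationarity (ADF, pooled verdict): {pooled}")

# Each estimate should sit within about two HAC standard errors of its truth;
# the lagged-DV coefficient carries a small downward (Nickell) bias at T=27
# months that disappears on longer panels.  A 'stationary' pooled verdict
# licenses the levels regression.
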