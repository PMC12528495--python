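"""Monthly fixed-effects (LSDV) regression of outcomes on moderation intensity.

The design regresses each monthly community outcome on platform-wide
moderation counts — pieces of content removed and accounts suspended — lagged
one month to blunt endogeneity, a first-order lagged dependent variable for
autoregression, a dummy per community (least-squares dummy variables, one
reference community dropped), and optional dummy-by-predictor interactions.
Standard errors are heteroskedasticity- and autocorrelation-consistent
(Newey-West); residual stationarity is checked per community with augmented
Dickey-Fuller tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tsa.stattools import adfuller

__all__ = [
    "PanelDesign",
    "LsdvFit",
    "PanelError",
    "build_panel",
    "fit_lsdv",
    "residual_stationarity",
    "newey_west_lags",
]

PREDICTORS = ("content_removed", "accounts_suspended")


class PanelError(ValueError):
    """Raised on malformed panel inputs (gaps, rank deficiency, ...)."""


@dataclass
class PanelDesign:
    """Aligned monthly design: outcome, lagged predictors, lagged DV, dummies."""

    data: pd.DataFrame  # rows (community, month) with outcome and regressors
    outcome: str
    predictor_columns: tuple[str, ...]
    dummy_columns: tuple[str, ...]
    interaction_columns: tuple[str, ...]
    reference_community: str
    lagged_dv_column: str | None

    @property
    def regressor_columns(self) -> tuple[str, ...]:
        cols = list(self.predictor_columns) + list(self.dummy_columns) + list(
            self.interaction_columns
        )
        if self.lagged_dv_column:
            cols.append(self.lagged_dv_column)
        return tuple(cols)


@dataclass
class LsdvFit:
    """Coefficients with HAC errors plus per-community residual series."""

    params: pd.Series
    hac_se: pd.Series
    p_values: pd.Series
    residuals: pd.DataFrame  # columns community, month, resid
    hac_lags: int
    reference_community: str
    design: PanelDesign
    results: object = field(repr=False, default=None)  # statsmodels OLSResults


def newey_west_lags(t: int) -> int:
    """Newey-West automatic truncation rule ``floor(4 * (T/100)^(2/9))``."""
    return int(np.floor(4.0 * (t / 100.0) ** (2.0 / 9.0)))


def build_panel(
    monthly: pd.DataFrame,
    transparency: pd.DataFrame,
    measure: str | None = None,
    include_lagged_dv: bool = True,
    include_interactions: bool = True,
    scale_per_thousand: bool = False,
    reference_community: str | None = None,
) -> PanelDesign:
    """Align monthly outcomes with one-month-lagged transparency predictors.

    ``monthly`` is tidy (community, month, value [, measure]); ``transparency``
    has month, content_removed, accounts_suspended with contiguous months.
    Predictors at month t-1 are attached to outcomes at month t, so the first
    outcome month is the month after the first transparency month; rows lacking
    a lagged DV are dropped when ``include_lagged_dv``.
    """
    df = monthly.copy()
    if measure is not None:
        if "measure" not in df.columns:
            raise PanelError("monthly frame has no 'measure' column to filter on")
        df = df[df["measure"] == measure]
    if len(df) == 0:
        raise PanelError("no monthly outcome rows")
    df["month"] = pd.PeriodIndex(df["month"], freq="M")

    tr = transparency.copy()
    tr["month"] = pd.PeriodIndex(tr["month"], freq="M")
    tr = tr.sort_values("month").reset_index(drop=True)
    expected = pd.period_range(tr["month"].iloc[0], tr["month"].iloc[-1], freq="M")
    missing = sorted(set(expected) - set(tr["month"]))
    if missing:
        raise PanelError(f"gap in transparency months: {[str(m) for m in missing]}")
    scale = 1e-3 if scale_per_thousand else 1.0
    tr = tr.set_index("month")[list(PREDICTORS)] * scale
    lagged = tr.copy()
    lagged.index = lagged.index + 1  # predictor at t-1 explains outcome at t

    df = df.sort_values(["community", "month"]).reset_index(drop=True)
    for col in PREDICTORS:
        df[f"{col}_lag1"] = df["month"].map(lagged[col])
    if include_lagged_dv:
        df["value_lag1"] = df.groupby("community", observed=True)["value"].shift(1)
    keep = df.dropna(
        subset=[f"{c}_lag1" for c in PREDICTORS] + (["value_lag1"] if include_lagged_dv else [])
    ).reset_index(drop=True)
    if len(keep) == 0:
        raise PanelError("no usable rows after lag alignment")

    communities = sorted(keep["community"].unique())
    ref = reference_community or communities[0]
    if ref not in communities:
        raise PanelError(f"reference community {ref!r} not in panel")
    dummy_cols = []
    inter_cols = []
    for c in communities:
        if c == ref:
            continue
        dcol = f"D[{c}]"
        keep[dcol] = (keep["community"] == c).astype(float)
        dummy_cols.append(dcol)
        if include_interactions:
            for pred in PREDICTORS:
                icol = f"D[{c}]:{pred}_lag1"
                keep[icol] = keep[dcol] * keep[f"{pred}_lag1"]
                inter_cols.append(icol)

    keep["month"] = keep["month"].astype(str)
    return PanelDesign(
        data=keep,
        outcome="value",
        predictor_columns=tuple(f"{c}_lag1" for c in PREDICTORS),
        dummy_columns=tuple(dummy_cols),
        interaction_columns=tuple(inter_cols),
        reference_community=ref,
        lagged_dv_column="value_lag1" if include_lagged_dv else None,
    )


def fit_lsdv(panel: PanelDesign, hac_lags: int | str = "auto") -> LsdvFit:
    """OLS on the LSDV design with Newey-West (HAC) standard errors.

    ``hac_lags="auto"`` applies the ``floor(4 (T/100)^{2/9})`` rule to the
    panel's time length.  Rank deficiency raises an error naming the
    collinear columns.
    """
    data = panel.data
    y = data[panel.outcome].to_numpy(dtype=float)
    cols = list(panel.regressor_columns)
    x = data[cols].to_numpy(dtype=float)
    x_const = sm.add_constant(x, has_constant="add")
    names = ["const"] + cols
    rank = np.linalg.matrix_rank(x_const)
    if rank < x_const.shape[1]:
        bad = _collinear_columns(x_const, names)
        raise PanelError(f"design matrix rank-deficient; suspect columns: {bad}")
    t_len = data["month"].nunique()
    lags = newey_west_lags(t_len) if hac_lags == "auto" else int(hac_lags)
    model = sm.OLS(y, x_const)
    # small-sample degrees-of-freedom correction n/(n-k) on the HAC covariance
    res = model.fit(cov_type="HAC", cov_kwds={"maxlags": lags, "use_correction": True})
    params = pd.Series(res.params, index=names)
    se = pd.Series(res.bse, index=names)
    pvals = pd.Series(res.pvalues, index=names)
    resid = data[["community", "month"]].copy()
    resid["resid"] = res.resid
    return LsdvFit(
        params=params,
        hac_se=se,
        p_values=pvals,
        residuals=resid,
        hac_lags=lags,
        reference_community=panel.reference_community,
        design=panel,
        results=res,
    )


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    """Name columns whose removal restores full rank (greedy scan)."""
    bad = []
    full_rank = np.linalg.matrix_rank(x)
    for j in range(x.shape[1]):
        reduced = np.delete(x, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            bad.append(names[j])
    return bad or names


def residual_stationarity(fit: LsdvFit, alpha: float = 0.05, min_length: int = 12) -> pd.DataFrame:
    """Augmented Dickey-Fuller test per community residual series.

    Returns one row per community (statistic, p, verdict) plus a pooled
    verdict row: "stationary" when a majority of the conclusive series reject
    the unit root at ``alpha``.  The lag order is AIC-selected under a cap of
    one tenth of the series length (short monthly panels leave too few
    observations for the default long-lag search).  Series shorter than
    ``min_length`` or degenerate (constant) are reported as inconclusive
    rather than failed.
    """
    rows = []
    verdicts = []
    for comm, grp in fit.residuals.groupby("community", observed=True):
        r = grp.sort_values("month")["resid"].to_numpy(dtype=float)
        if len(r) < min_length or np.ptp(r) < 1e-12:
            rows.append(
                {"community": comm, "adf_stat": np.nan, "p": np.nan, "verdict": "inconclusive"}
            )
            continue
        maxlag = max(1, min(4, len(r) // 10))
        try:
            stat, p = adfuller(r, maxlag=maxlag, autolag="AIC")[:2]
        except (ValueError, np.linalg.LinAlgError):
            rows.append(
                {"community": comm, "adf_stat": np.nan, "p": np.nan, "verdict": "inconclusive"}
            )
            continue
        verdict = "stationary" if p <= alpha else "non-stationary"
        verdicts.append(verdict)
        rows.append({"community": comm, "adf_stat": float(stat), "p": float(p), "verdict": verdict})
    n_stat = sum(v == "stationary" for v in verdicts)
    if not verdicts:
        pooled = "inconclusive"
    elif n_stat > len(verdicts) / 2:
        pooled = "stationary"
    else:
        pooled = "non-stationary"
    rows.append({"community": "__pooled__", "adf_stat": np.nan, "p": np.nan, "verdict": pooled})
    return pd.DataFrame(rows)
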