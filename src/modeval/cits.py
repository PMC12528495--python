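"""Comparative interrupted time series with SARIMAX simulated counterfactuals.

The workflow mirrors the quasi-experimental design it implements:

1. :func:`fit_pre_period` fits a SARIMAX model (orders fixed or chosen by a
   stepwise AIC search) to the daily series up to, but not including, the
   first day of the evaluated policy, with earlier enforcement phases as 0/1
   exogenous dummies.
2. :func:`simulate_counterfactual` draws ``B`` forecast paths of length ``k``
   from the fitted model (parameters held at their estimates, policy dummy
   held at zero) and summarises the path means ``M_k`` by their Monte-Carlo
   mean ``m_hat`` and standard deviation ``s_hat``.
3. :func:`single_series_z` standardises the observed post-period mean:
   ``Z = (mean(y_post) - m_hat) / s_hat`` with CI
   ``(mean(y_post) - m_hat) +/- z_crit * s_hat``.
4. :func:`comparative_z` contrasts a treated community's deviation with its
   comparator's.  The default pooling adds the two forecast variances
   (``sqrt(s_a^2 + s_p^2)`` — the variance of a difference of independent
   estimates); ``pooling="as_printed"`` subtracts them instead and raises when
   the result is non-positive.
5. :func:`effect_scale` back-transforms average daily differences: odds ratios
   for logit measures, relative risks for log virality, untransformed deltas
   for domain quality.

:func:`run_cits` orchestrates all of the above over (pair, phase, measure)
cells and returns a tidy effect table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.tsa.statespace.sarimax import SARIMAX

from .phases import PhaseDesign

__all__ = [
    "SarimaxSpec",
    "SarimaxFit",
    "CounterfactualSummary",
    "ComparativeEffect",
    "CitsError",
    "fit_pre_period",
    "simulate_counterfactual",
    "single_series_z",
    "comparative_z",
    "effect_scale",
    "run_cits",
]

logger = logging.getLogger(__name__)


class CitsError(ValueError):
    """Raised on invalid CITS inputs or degenerate statistics."""


@dataclass
class SarimaxSpec:
    """Fitted model orders, coefficients and diagnostics."""

    order: tuple[int, int, int]
    seasonal_order: tuple[int, int, int, int]
    params: dict[str, float]
    aic: float
    sigma2: float
    converged: bool
    fallbacks: list[str] = field(default_factory=list)
    ljung_box_p: float | None = None


@dataclass
class SarimaxFit:
    """A fitted pre-period model plus everything needed to forecast from it."""

    spec: SarimaxSpec
    results: object  # statsmodels SARIMAXResults
    n: int
    exog_columns: tuple[str, ...] = ()


@dataclass
class CounterfactualSummary:
    """Simulated-forecast summary and (once observed data arrive) the Z/CI."""

    n: int
    k: int
    B: int
    m_hat: float
    s_hat: float
    M_draws: np.ndarray
    alpha: float = 0.05
    observed_mean: float | None = None
    z: float | None = None
    ci: tuple[float, float] | None = None
    p_two_sided: float | None = None

    @property
    def z_crit(self) -> float:
        return float(stats.norm.ppf(1.0 - self.alpha / 2.0))

    @property
    def deviation(self) -> float:
        if self.observed_mean is None:
            raise CitsError("observed post-period data not attached yet")
        return self.observed_mean - self.m_hat


@dataclass
class ComparativeEffect:
    """Treated-vs-comparator contrast on a chosen report scale."""

    treated: CounterfactualSummary
    comparator: CounterfactualSummary
    pooling: str
    z: float
    p_two_sided: float
    scale: str
    estimate: float
    ci: tuple[float, float]


_MAX_P = 5
_MAX_Q = 5
_MAX_SP = 2
_MAX_SQ = 2


def _fit_one(
    y: np.ndarray,
    order,
    seasonal_order,
    exog,
    trend: str = "c",
):
    model = SARIMAX(
        y,
        exog=exog,
        order=order,
        seasonal_order=seasonal_order,
        trend=trend,
        enforce_stationarity=True,
        enforce_invertibility=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=False, maxiter=200)
        if not _converged(res):
            # derivative-free polish from the L-BFGS point
            res = model.fit(
                disp=False, method="nm", maxiter=2000, start_params=res.params
            )
    return res


def _converged(res) -> bool:
    retvals = getattr(res, "mle_retvals", None) or {}
    return bool(retvals.get("converged", True)) and np.all(np.isfinite(res.params))


def _stepwise_order_search(y, exog, seasonal_period: int):
    """Small stepwise AIC search emulating auto_arima's default behavior.

    The differencing order is set by a KPSS test (difference until the
    stationarity null is no longer rejected, max twice); (p, q) then move by
    +/-1 steps from a set of standard starting models until AIC stops
    improving.  Seasonal (P, Q) are searched over {0, 1} when a seasonal
    period is given.
    """
    from statsmodels.tsa.stattools import kpss

    d = 0
    yy = np.asarray(y, dtype=float)
    for _ in range(2):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_val = kpss(yy, regression="c", nlags="auto")[1]
        if p_val >= 0.05:
            break
        yy = np.diff(yy)
        d += 1

    seasonal_candidates = [(0, 0)]
    if seasonal_period > 1:
        seasonal_candidates += [(1, 0), (0, 1)]

    tried: dict[tuple, float] = {}

    def aic_of(p, q, sp, sq):
        key = (p, d, q, sp, sq)
        if key in tried:
            return tried[key]
        try:
            res = _fit_one(
                y, (p, d, q), (sp, 0, sq, seasonal_period) if seasonal_period > 1 else (0, 0, 0, 0),
                exog,
            )
            aic = res.aic if _converged(res) else np.inf
        except (np.linalg.LinAlgError, ValueError):
            aic = np.inf
        tried[key] = aic
        return aic

    best = None
    best_aic = np.inf
    for sp, sq in seasonal_candidates:
        for p, q in [(2, 2), (0, 0), (1, 0), (0, 1)]:
            aic = aic_of(p, q, sp, sq)
            if aic < best_aic:
                best_aic, best = aic, (p, q, sp, sq)
    improved = True
    while improved and best is not None:
        improved = False
        p, q, sp, sq = best
        for dp, dq in [(1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (-1, -1)]:
            np_, nq = p + dp, q + dq
            if not (0 <= np_ <= _MAX_P and 0 <= nq <= _MAX_Q):
                continue
            aic = aic_of(np_, nq, sp, sq)
            if aic < best_aic - 1e-6:
                best_aic, best = aic, (np_, nq, sp, sq)
                improved = True
    if best is None:
        return (1, 0, 0), (0, 0, 0, 0)
    p, q, sp, sq = best
    seasonal = (sp, 0, sq, seasonal_period) if seasonal_period > 1 else (0, 0, 0, 0)
    return (p, d, q), seasonal


def fit_pre_period(
    series: pd.Series | np.ndarray,
    exog: pd.DataFrame | np.ndarray | None = None,
    order: str | tuple[int, int, int] = "auto",
    seasonal_order: tuple[int, int, int, int] | None = None,
    seasonal_period: int = 7,
) -> SarimaxFit:
    """Fit the pre-policy SARIMAX model.

    ``order="auto"`` runs the stepwise AIC search; a tuple fixes the orders.
    ``seasonal_period`` only matters for the search (daily data default to a
    weekly rhythm; pass 1 for non-seasonal).  Non-convergence triggers a retry
    ladder — increment ``d``, then fall back to (1,0,0) — before a hard error.
    """
    y = np.asarray(series, dtype=float)
    if np.isnan(y).any():
        raise CitsError("series contains NaN; impute before fitting")
    exog_cols: tuple[str, ...] = ()
    x = None
    if exog is not None:
        if isinstance(exog, pd.DataFrame):
            exog_cols = tuple(exog.columns)
            x = exog.to_numpy(dtype=float)
        else:
            x = np.asarray(exog, dtype=float)
            exog_cols = tuple(f"x{i}" for i in range(x.shape[1]))
        if len(x) != len(y):
            raise CitsError("exog length must match series length")
        keep = [i for i in range(x.shape[1]) if np.ptp(x[:, i]) > 0]
        x = x[:, keep] if keep else None
        exog_cols = tuple(exog_cols[i] for i in keep)

    fallbacks: list[str] = []
    if order == "auto":
        order_, seasonal_ = _stepwise_order_search(y, x, seasonal_period)
    else:
        order_ = tuple(order)  # type: ignore[arg-type]
        seasonal_ = tuple(seasonal_order) if seasonal_order else (0, 0, 0, 0)

    attempts = [(order_, seasonal_)]
    p, d, q = order_
    attempts.append(((p, d + 1, q), seasonal_))
    attempts.append(((1, 0, 0), (0, 0, 0, 0)))
    res = None
    used = attempts[0]
    for i, (o, so) in enumerate(attempts):
        try:
            candidate = _fit_one(y, o, so, x)
        except (np.linalg.LinAlgError, ValueError) as err:
            fallbacks.append(f"fit {o}{so} failed: {err}")
            continue
        if _converged(candidate):
            res = candidate
            used = (o, so)
            if i > 0:
                fallbacks.append(f"fell back to order {o}, seasonal {so}")
            break
        fallbacks.append(f"order {o} seasonal {so} did not converge")
    if res is None:
        raise CitsError(f"SARIMAX failed to converge; attempts: {fallbacks}")

    try:
        from statsmodels.stats.diagnostic import acorr_ljungbox

        lb = acorr_ljungbox(res.resid, lags=[min(10, max(1, len(y) // 5))])
        lb_p = float(lb["lb_pvalue"].iloc[0])
    except Exception:  # diagnostics are best-effort
        lb_p = None
    params = dict(zip(res.model.param_names, np.asarray(res.params, dtype=float)))
    spec = SarimaxSpec(
        order=used[0],
        seasonal_order=used[1],
        params=params,
        aic=float(res.aic),
        sigma2=float(params.get("sigma2", np.nan)),
        converged=True,
        fallbacks=fallbacks,
        ljung_box_p=lb_p,
    )
    return SarimaxFit(spec=spec, results=res, n=len(y), exog_columns=exog_cols)


def simulate_counterfactual(
    fit: SarimaxFit,
    k: int,
    B: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    exog_future: pd.DataFrame | np.ndarray | None = None,
    alpha: float = 0.05,
) -> CounterfactualSummary:
    """Draw ``B`` length-``k`` forecast paths and summarise their means.

    The counterfactual holds the evaluated policy's dummy at zero over the
    horizon (supply ``exog_future`` accordingly when the fit used exogenous
    regressors).  Innovations come from the fitted Gaussian model with
    parameters held at their estimates; reproducible from ``seed``.
    """
    if k <= 0:
        raise CitsError("forecast horizon k must be positive")
    if B < 2:
        raise CitsError("need at least B=2 simulated paths")
    x = None
    if fit.exog_columns:
        if exog_future is None:
            x = np.zeros((k, len(fit.exog_columns)))
        else:
            x = np.asarray(exog_future, dtype=float)
            if x.shape != (k, len(fit.exog_columns)):
                raise CitsError("exog_future shape must be (k, n_exog)")
    if isinstance(seed, np.random.SeedSequence):
        seed_int = int(seed.generate_state(1)[0] % (2**31))
    else:
        seed_int = None if seed is None else int(seed) % (2**31)
    paths = fit.results.simulate(
        nsimulations=k,
        repetitions=B,
        anchor="end",
        exog=x,
        random_state=np.random.RandomState(seed_int),
    )
    paths = np.asarray(paths, dtype=float).reshape(k, B)
    M = paths.mean(axis=0)
    return CounterfactualSummary(
        n=fit.n,
        k=k,
        B=B,
        m_hat=float(M.mean()),
        s_hat=float(M.std(ddof=1)),
        M_draws=M,
        alpha=alpha,
    )


def single_series_z(
    cf: CounterfactualSummary, observed: pd.Series | np.ndarray
) -> CounterfactualSummary:
    """Attach the observed post-period series and compute Z, CI and p.

    CI excludes zero exactly when |Z| exceeds the normal critical value — the
    two are algebraically the same statement.
    """
    y = np.asarray(observed, dtype=float)
    if len(y) != cf.k:
        raise CitsError(f"observed series has length {len(y)}, expected horizon k={cf.k}")
    if np.isnan(y).any():
        raise CitsError("observed post-period series contains NaN")
    if cf.s_hat <= 0:
        raise CitsError("degenerate counterfactual: s_hat is zero")
    obs_mean = float(y.mean())
    diff = obs_mean - cf.m_hat
    z = diff / cf.s_hat
    half = cf.z_crit * cf.s_hat
    cf.observed_mean = obs_mean
    cf.z = float(z)
    cf.ci = (diff - half, diff + half)
    cf.p_two_sided = float(2.0 * stats.norm.sf(abs(z)))
    return cf


def comparative_z(
    treated: CounterfactualSummary,
    comparator: CounterfactualSummary,
    pooling: str = "sum",
    measure_kind: str = "content_logit",
) -> ComparativeEffect:
    """Treated-minus-comparator deviation standardised by pooled forecast SD.

    ``pooling="sum"`` (default) uses ``sqrt(s_a^2 + s_p^2)``;
    ``pooling="as_printed"`` uses ``sqrt(s_a^2 - s_p^2)`` and raises a
    degenerate-denominator error when that is non-positive.
    """
    if treated.k != comparator.k:
        raise CitsError("treated and comparator horizons differ")
    if treated.observed_mean is None or comparator.observed_mean is None:
        raise CitsError("attach observed data to both summaries first")
    num = treated.deviation - comparator.deviation
    if pooling == "sum":
        pooled_var = treated.s_hat**2 + comparator.s_hat**2
    elif pooling == "as_printed":
        pooled_var = treated.s_hat**2 - comparator.s_hat**2
        if pooled_var <= 0:
            raise CitsError(
                "as_printed pooling yields non-positive variance "
                f"({pooled_var:.3g}); use pooling='sum'"
            )
    else:
        raise CitsError(f"unknown pooling rule {pooling!r}")
    denom = float(np.sqrt(pooled_var))
    z = num / denom
    half = treated.z_crit * denom
    scale, transform = _scale_for(measure_kind)
    return ComparativeEffect(
        treated=treated,
        comparator=comparator,
        pooling=pooling,
        z=float(z),
        p_two_sided=float(2.0 * stats.norm.sf(abs(z))),
        scale=scale,
        estimate=transform(num),
        ci=(transform(num - half), transform(num + half)),
    )


def _scale_for(measure_kind: str):
    if measure_kind == "content_logit" or measure_kind.startswith("topic_logit"):
        return "odds_ratio", np.exp
    if measure_kind == "virality_log":
        return "relative_risk", np.exp
    if measure_kind == "quality_mean":
        return "delta", lambda v: v
    raise CitsError(f"unknown measure_kind {measure_kind!r}")


def effect_scale(diff: float, measure_kind: str) -> tuple[str, float]:
    """Back-transform an average daily difference onto its report scale.

    Logit measures exponentiate to odds ratios, log virality to relative
    risks, and quality deltas pass through unchanged.
    """
    scale, transform = _scale_for(measure_kind)
    return scale, float(transform(diff))


def run_cits(
    panel: pd.DataFrame,
    phases: PhaseDesign,
    pairs: dict[str, str],
    evaluate: list[str] | None = None,
    measures: list[str] | None = None,
    alpha: float = 0.05,
    B: int = 1000,
    seed: int = 0,
    pooling: str = "sum",
    order: str | tuple[int, int, int] = "auto",
    seasonal_period: int = 7,
    correction: str | None = None,
) -> pd.DataFrame:
    """Full CITS sweep over (pair, evaluated phase, measure) cells.

    ``panel`` is the tidy imputed daily panel; ``pairs`` maps treated
    community → comparator community.  For each cell both series are fit on
    data strictly before the phase start, counterfactuals are simulated with
    the evaluated policy's dummy held at zero, and single-series plus
    comparative statistics are reported.  ``correction="bonferroni"`` widens
    the critical value across pairs within each measure.
    """
    if not pairs:
        raise CitsError("no treated/comparator pairs supplied")
    panel = panel.copy()
    panel["date"] = pd.to_datetime(panel["date"])
    if measures is None:
        measures = sorted(panel["measure"].unique())
    if evaluate is None:
        evaluate = [p.name for p in phases if p.start > panel["date"].min().date()]
    eff_alpha = alpha / len(pairs) if correction == "bonferroni" else alpha

    rows = []
    cell = 0
    for measure in measures:
        sub = panel[panel["measure"] == measure]
        for treated_name, comparator_name in pairs.items():
            if comparator_name not in set(sub["community"]):
                logger.warning("missing comparator %r; pair skipped", comparator_name)
                continue
            for phase_name in evaluate:
                phase = phases[phase_name]
                summaries = {}
                ok = True
                for role, comm in (("treated", treated_name), ("comparator", comparator_name)):
                    s = (
                        sub[sub["community"] == comm]
                        .set_index("date")["value"]
                        .sort_index()
                    )
                    pre = s[s.index < pd.Timestamp(phase.start)]
                    post = s[
                        (s.index >= pd.Timestamp(phase.start))
                        & (s.index <= pd.Timestamp(phase.end))
                    ]
                    if len(pre) < 30 or len(post) < 2:
                        logger.warning(
                            "insufficient data for %s/%s/%s; cell skipped",
                            comm,
                            phase_name,
                            measure,
                        )
                        ok = False
                        break
                    # first phase is the reference level: the phase table
                    # partitions the calendar, so a full dummy set would be
                    # collinear with the intercept
                    exog = phases.dummies(
                        pre.index, exclude=(phase_name, phases.names[0])
                    )
                    fit = fit_pre_period(
                        pre, exog=exog, order=order, seasonal_period=seasonal_period
                    )
                    # per-(pair, phase, measure, role) substream off the root seed
                    cf = simulate_counterfactual(
                        fit,
                        k=len(post),
                        B=B,
                        seed=np.random.SeedSequence([seed, cell]),
                        alpha=eff_alpha,
                    )
                    cell += 1
                    summaries[role] = single_series_z(cf, post)
                if not ok:
                    continue
                comp = comparative_z(
                    summaries["treated"], summaries["comparator"], pooling, measure
                )
                scale, _ = _scale_for(measure)
                for role, comm in (("treated", treated_name), ("comparator", comparator_name)):
                    cfres = summaries[role]
                    _, est = effect_scale(cfres.deviation, measure)
                    lo, hi = cfres.ci
                    _, lo_t = effect_scale(lo, measure)
                    _, hi_t = effect_scale(hi, measure)
                    rows.append(
                        {
                            "pair": f"{treated_name} vs {comparator_name}",
                            "community": comm,
                            "role": role,
                            "phase": phase_name,
                            "measure": measure,
                            "kind": "single_series",
                            "scale": scale,
                            "estimate": est,
                            "lo": lo_t,
                            "hi": hi_t,
                            "z": cfres.z,
                            "p": cfres.p_two_sided,
                            "n": cfres.n,
                            "k": cfres.k,
                        }
                    )
                rows.append(
                    {
                        "pair": f"{treated_name} vs {comparator_name}",
                        "community": treated_name,
                        "role": "comparative",
                        "phase": phase_name,
                        "measure": measure,
                        "kind": "comparative",
                        "scale": comp.scale,
                        "estimate": comp.estimate,
                        "lo": comp.ci[0],
                        "hi": comp.ci[1],
                        "z": comp.z,
                        "p": comp.p_two_sided,
                        "n": summaries["treated"].n,
                        "k": summaries["treated"].k,
                    }
                )
    out = pd.DataFrame(rows)
    out.attrs["alpha"] = alpha
    out.attrs["correction"] = correction or "none"
    out.attrs["pooling"] = pooling
    out.attrs["B"] = B
    out.attrs["seed"] = seed
    return out
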