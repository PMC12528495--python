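"""Server-outage detection and linear-interpolation imputation.

A day is an outage iff it contains zero user-authored (non-retweet) tweets
across all communities.  Because an outage may have started late the previous
day or ended early the next (leaving partial counts), the day immediately
before and after each outage run is dropped as well.  Dropped values of each
daily measure are then replaced by linear interpolation between the nearest
retained neighbours; gaps touching the edge of the span carry the nearest
retained value (flagged in the report, since one-sided gaps have no second
anchor to interpolate against).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
import yaml

__all__ = ["OutageReport", "detect_outages", "impute_measures", "InputError"]


class InputError(ValueError):
    """Raised on structurally unusable input (empty stream, all days dropped)."""


@dataclass
class OutageReport:
    """Outage days, the dropped superset (outages plus flanking days), and
    any edge gaps that had to be handled by nearest-value carry."""

    detected_outage_days: set[date] = field(default_factory=set)
    dropped_days: set[date] = field(default_factory=set)
    edge_gap_days: set[date] = field(default_factory=set)
    span: tuple[date, date] | None = None

    def to_yaml(self, path) -> None:
        payload = {
            "detected_outage_days": sorted(d.isoformat() for d in self.detected_outage_days),
            "dropped_days": sorted(d.isoformat() for d in self.dropped_days),
            "edge_gap_days": sorted(d.isoformat() for d in self.edge_gap_days),
            "span": [d.isoformat() for d in self.span] if self.span else None,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_known_outages(cls, outage_days, span: tuple[date, date]) -> "OutageReport":
        """Build a report from a user-supplied outage-date list (override path)."""
        report = cls(detected_outage_days=set(outage_days), span=span)
        report.dropped_days = _with_flanks(report.detected_outage_days, span)
        return report


def _with_flanks(outages: set[date], span: tuple[date, date]) -> set[date]:
    lo, hi = span
    dropped = set(outages)
    one = timedelta(days=1)
    for d in outages:
        if lo <= d - one <= hi:
            dropped.add(d - one)
        if lo <= d + one <= hi:
            dropped.add(d + one)
    return dropped


def detect_outages(tweets: pd.DataFrame) -> OutageReport:
    """Identify outage days (no user-authored tweets anywhere) and drop flanks.

    The observed span is the closed interval from the first to the last
    calendar day with any record in the stream.
    """
    if len(tweets) == 0:
        raise InputError("empty tweet stream")
    days = pd.to_datetime(tweets["timestamp"]).dt.normalize()
    lo, hi = days.min().date(), days.max().date()
    if (hi - lo).days < 2:
        raise InputError("stream must span at least 3 days to detect outages")
    all_days = pd.date_range(lo, hi, freq="D").date
    ua_days = set(days[~tweets["is_retweet"].astype(bool)].dt.date)
    outages = {d for d in all_days if d not in ua_days}
    report = OutageReport(detected_outage_days=outages, span=(lo, hi))
    report.dropped_days = _with_flanks(outages, (lo, hi))
    return report


def impute_measures(panel: pd.DataFrame, dropped: set[date]) -> pd.DataFrame:
    """Replace measure values on dropped days by linear interpolation.

    ``panel`` is tidy: columns ``community, date, measure, value`` (``n`` kept
    if present).  Interpolation runs independently per (community, measure)
    series over its own calendar index; retained values are untouched and the
    operation is idempotent.
    """
    if len(panel) == 0:
        raise InputError("empty measure panel")
    out = []
    for (comm, meas), grp in panel.groupby(["community", "measure"], observed=True, sort=False):
        grp = grp.sort_values("date").copy()
        mask = grp["date"].isin(dropped).to_numpy()
        vals = grp["value"].to_numpy(dtype=float).copy()
        missing = ~np.isfinite(vals)
        vals[mask] = np.nan
        if (mask | missing).all():
            raise InputError(f"all days dropped for ({comm}, {meas})")
        s = pd.Series(vals, index=pd.to_datetime(grp["date"]))
        s = s.interpolate(method="time", limit_direction="both")
        grp["value"] = s.to_numpy()
        grp["imputed"] = mask | missing
        out.append(grp)
    return pd.concat(out, ignore_index=True)
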