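"""Policy-phase configuration: named date intervals realised as 0/1 dummies.

The default phase table reproduces the sequence of platform enforcement
announcements used in the study design, from the initial period in February
2020 through the suspension of the medical-misinformation policy in late 2022.
Start and end dates are both inclusive.  Two late-2022 rows (the account
reinstatement and the policy suspension) deliberately overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import pandas as pd
import yaml

__all__ = ["Phase", "PhaseDesign", "default_phases", "PRE_PERIOD_END"]


@dataclass(frozen=True)
class Phase:
    name: str
    start: date
    end: date

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"phase {self.name!r}: end before start")


#: Last day of the pre-policy fit span for the content-removal evaluation.
PRE_PERIOD_END = date(2020, 12, 19)

_DEFAULT_ROWS = [
    ("Initial period", date(2020, 2, 7), date(2020, 3, 3)),
    ("Global COVID-19 search prompt & event page", date(2020, 3, 4), date(2020, 3, 15)),
    ("Updated policies & automated tech", date(2020, 3, 16), date(2020, 3, 26)),
    ("Broadened definition of harm", date(2020, 3, 27), date(2020, 4, 1)),
    ("Updated ad policy", date(2020, 4, 2), date(2020, 4, 21)),
    ("Unverified claims violate policies", date(2020, 4, 22), date(2020, 5, 10)),
    ("New labels and warning messages", date(2020, 5, 11), date(2020, 5, 17)),
    ("COVID-19 tab in explore", date(2020, 5, 18), date(2020, 7, 13)),
    ("Clarifying assessment of misleading information", date(2020, 7, 14), date(2020, 12, 19)),
    ("Vaccine misinformation removal policy", date(2020, 12, 20), date(2021, 1, 7)),
    ("Mass deplatforming", date(2021, 1, 8), date(2021, 2, 28)),
    ('"Five strikes" policy', date(2021, 3, 1), date(2022, 11, 22)),
    ("Former president's account reinstated", date(2022, 11, 18), date(2022, 12, 17)),
    ("Medical misinformation policy suspended", date(2022, 11, 23), date(2022, 12, 17)),
]


class PhaseDesign:
    """Ordered phase list plus helpers to build dummy regressor matrices."""

    def __init__(self, phases: list[Phase]):
        if not phases:
            raise ValueError("need at least one phase")
        self.phases = list(phases)
        names = [p.name for p in self.phases]
        if len(set(names)) != len(names):
            raise ValueError("phase names must be unique")

    def __iter__(self):
        return iter(self.phases)

    def __getitem__(self, name: str) -> Phase:
        for p in self.phases:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.phases]

    def dummies(self, index: pd.DatetimeIndex, exclude: tuple[str, ...] = ()) -> pd.DataFrame:
        """0/1 dummy matrix over a daily index; ``exclude`` names are omitted
        (used to hold the evaluated policy at zero in counterfactuals)."""
        out = pd.DataFrame(index=index)
        for p in self.phases:
            if p.name in exclude:
                continue
            col = ((index >= pd.Timestamp(p.start)) & (index <= pd.Timestamp(p.end))).astype(float)
            out[p.name] = col
        return out

    @classmethod
    def from_yaml(cls, path) -> "PhaseDesign":
        with open(path) as fh:
            rows = yaml.safe_load(fh)
        return cls(
            [
                Phase(r["name"], date.fromisoformat(str(r["start"])), date.fromisoformat(str(r["end"])))
                for r in rows
            ]
        )

    def to_yaml(self, path) -> None:
        rows = [
            {"name": p.name, "start": p.start.isoformat(), "end": p.end.isoformat()}
            for p in self.phases
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(rows, fh, sort_keys=False)


def default_phases() -> PhaseDesign:
    return PhaseDesign([Phase(*row) for row in _DEFAULT_ROWS])
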