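"""Drip-irrigation plans: fixed quota-by-cycle schedules, the 30-scheme
scenario grid, and growth-stage allocations of a seasonal water amount.

Vocabulary: the *quota* is the depth (mm) applied per event, the *cycle* the
interval (days) between events, the *amount* the seasonal total (mm);
1 mm over one hectare is 10 m3/ha.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import pandas as pd

from .synthetic import load_fixture

#: Observed irrigation window of the field trials
DEFAULT_START = (5, 18)   # May 18
DEFAULT_END = (8, 26)     # Aug 26

SCENARIO_I_AMOUNTS = (90, 120, 150, 180, 210)       # mm/season
SCENARIO_II_QUOTAS = (10, 13, 18, 20, 24)           # mm/event
CYCLE_EVENTS = ((5, 12), (7, 9), (10, 6))           # (cycle days, events)


@dataclass(frozen=True)
class IrrigationEvent:
    date: date
    depth: float  # mm

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("event depth must be positive")


@dataclass(frozen=True)
class IrrigationPlan:
    events: tuple[IrrigationEvent, ...]
    label: str = ""

    def __post_init__(self) -> None:
        dates = [e.date for e in self.events]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("event dates must be strictly increasing")

    @property
    def total_mm(self) -> float:
        return sum(e.depth for e in self.events)

    def depth_on(self, d: date) -> float:
        return sum(e.depth for e in self.events if e.date == d)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": [pd.Timestamp(e.date) for e in self.events],
                "depth_mm": [e.depth for e in self.events],
                "label": self.label,
            }
        )

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df["date"] = df["date"].dt.strftime("%Y-%m-%d")
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "IrrigationPlan":
        df = pd.read_csv(path, parse_dates=["date"])
        label = str(df["label"].iloc[0]) if "label" in df.columns and len(df) else ""
        events = tuple(
            IrrigationEvent(date=row["date"].date(), depth=row["depth_mm"])
            for _, row in df.iterrows()
        )
        return cls(events=events, label=label)


@dataclass(frozen=True)
class ScenarioSpec:
    scheme_id: str
    quota_mm: float
    cycle_days: int
    n_events: int
    scenario: str = ""  # "I" (fixed seasonal amount) or "II" (fixed quota)

    @property
    def amount_mm(self) -> float:
        return self.quota_mm * self.n_events

    @property
    def total_m3_ha(self) -> float:
        return mm_to_m3_ha(self.amount_mm)


@dataclass(frozen=True)
class StageAllocation:
    """Percent of the seasonal amount and event count per growth stage."""

    stages: tuple[str, ...]
    pct: tuple[float, ...]
    n_events: tuple[int, ...]

    def __post_init__(self) -> None:
        if abs(sum(self.pct) - 100.0) > 1e-9:
            raise ValueError(f"stage percentages sum to {sum(self.pct)}, not 100")
        for s, p, n in zip(self.stages, self.pct, self.n_events):
            if n > 0 and p == 0:
                raise ValueError(f"stage {s} has {n} events but 0% of the water")


def mm_to_m3_ha(depth_mm: float) -> float:
    """Convert an irrigation depth (mm) to a volume per hectare (m3/ha)."""
    if depth_mm < 0:
        raise ValueError("depth must be non-negative")
    return 10.0 * depth_mm


def build_fixed_plan(
    start_date: date,
    quota_mm: float,
    cycle_days: int,
    n_events: int,
    label: str = "",
    season_end: date | None = None,
) -> IrrigationPlan:
    """Events of ``quota_mm`` at ``start_date + k*cycle_days`` for
    k = 0..n_events-1."""
    if n_events < 1 or cycle_days < 1:
        raise ValueError("need n_events >= 1 and cycle_days >= 1")
    dates = [start_date + timedelta(days=k * cycle_days) for k in range(n_events)]
    if season_end is not None and dates[-1] > season_end:
        raise ValueError(
            f"plan extends to {dates[-1]}, past the season end {season_end}"
        )
    return IrrigationPlan(
        events=tuple(IrrigationEvent(date=d, depth=quota_mm) for d in dates),
        label=label,
    )


def build_scenario_grid() -> tuple[ScenarioSpec, ...]:
    """The 30-scheme grid: scenario I fixes the seasonal amount per
    cycle/event triple (quota = amount / events); scenario II fixes the
    per-event quota (amount = quota * events)."""
    specs: list[ScenarioSpec] = []
    i = 1
    for amount in SCENARIO_I_AMOUNTS:
        for cycle, events in CYCLE_EVENTS:
            specs.append(
                ScenarioSpec(
                    scheme_id=f"A{i}", quota_mm=amount / events,
                    cycle_days=cycle, n_events=events, scenario="I",
                )
            )
            i += 1
    for quota in SCENARIO_II_QUOTAS:
        for cycle, events in CYCLE_EVENTS:
            specs.append(
                ScenarioSpec(
                    scheme_id=f"A{i}", quota_mm=float(quota),
                    cycle_days=cycle, n_events=events, scenario="II",
                )
            )
            i += 1
    return tuple(specs)


def plan_for_spec(
    spec: ScenarioSpec, year: int, start: tuple[int, int] = DEFAULT_START
) -> IrrigationPlan:
    """Materialize a scenario spec as dated events in the given year."""
    return build_fixed_plan(
        start_date=date(year, *start),
        quota_mm=spec.quota_mm,
        cycle_days=spec.cycle_days,
        n_events=spec.n_events,
        label=spec.scheme_id,
    )


def stage_allocation_for_year(year: int) -> tuple[StageAllocation, dict[str, tuple[date, date]]]:
    """The experiment's stage allocation and stage windows for 2019 or 2020."""
    table = load_fixture("table2_stage_allocation")
    rows = table[table["year"] == year]
    if rows.empty:
        raise ValueError(f"no stage allocation recorded for {year}")
    alloc = StageAllocation(
        stages=tuple(rows["stage"]),
        pct=tuple(float(p) for p in rows["pct"]),
        n_events=tuple(int(n) for n in rows["n_events"]),
    )
    windows = {
        row["stage"]: (
            _md_date(year, row["window_start"]), _md_date(year, row["window_end"])
        )
        for _, row in rows.iterrows()
    }
    return alloc, windows


def _md_date(year: int, md: str) -> date:
    month, day = (int(x) for x in md.split("-"))
    return date(year, month, day)


def allocate_by_stage(
    total_mm: float,
    allocation: StageAllocation,
    stage_windows: dict[str, tuple[date, date]],
    label: str = "",
) -> IrrigationPlan:
    """Split a seasonal amount across growth stages: each stage receives
    pct*total spread over its event count, events evenly spaced within the
    stage window."""
    events: list[IrrigationEvent] = []
    for stage, pct, n in zip(allocation.stages, allocation.pct, allocation.n_events):
        if n == 0:
            continue
        stage_depth = pct / 100.0 * total_mm
        per_event = stage_depth / n
        start, end = stage_windows[stage]
        span = (end - start).days
        # even spacing: event k at start + (k+1) * span/(n+1), interior points
        for k in range(n):
            d = start + timedelta(days=round((k + 1) * span / (n + 1)))
            events.append(IrrigationEvent(date=d, depth=per_event))
    events.sort(key=lambda e: e.date)
    return IrrigationPlan(events=tuple(events), label=label)


def grid_to_frame(specs: tuple[ScenarioSpec, ...]) -> pd.DataFrame:
    """Scenario grid as a table matching the scenario-fixture schema."""
    return pd.DataFrame(
        {
            "scheme": [s.scheme_id for s in specs],
            "scenario": [s.scenario for s in specs],
            "quota_mm": [s.quota_mm for s in specs],
            "cycle_days": [s.cycle_days for s in specs],
            "n_events": [s.n_events for s in specs],
            "total_m3_ha": [s.total_m3_ha for s in specs],
        }
    )
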