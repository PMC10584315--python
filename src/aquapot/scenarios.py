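"""Scenario study: run the irrigation-scheme grid over multi-year weather,
average season outputs, fit the quadratic irrigation-yield response, and
select optimal schemes by yield or water use efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .engine import CropParameters, run_simulation
from .irrigation import ScenarioSpec, plan_for_spec
from .soil import SoilProfile

RESULT_COLUMNS = [
    "scheme", "quota_mm", "cycle_days", "n_events", "total_m3_ha",
    "yield_t_ha", "biomass_t_ha", "wue_kg_m3", "et_mm",
]


@dataclass(frozen=True)
class ScenarioResult:
    scheme_id: str
    spec: ScenarioSpec
    yield_t_ha: float      # multi-year mean fresh tuber yield
    biomass_t_ha: float
    wue_kg_m3: float
    et_mm: float
    per_year: pd.DataFrame  # one row per weather year


@dataclass(frozen=True)
class QuadraticFit:
    """Least-squares fit of y = a + b x + c x^2 to (irrigation, yield) pairs."""

    a: float
    b: float
    c: float
    r2: float
    n_points: int

    @property
    def vertex_x(self) -> float | None:
        if self.c == 0:
            return None
        return -self.b / (2.0 * self.c)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a + self.b * x + self.c * x * x


def run_scenario_set(
    specs,
    weather_years: dict[int, pd.DataFrame],
    soil: SoilProfile,
    crop: CropParameters,
    planting_month_day: tuple[int, int] = (4, 30),
) -> list[ScenarioResult]:
    """Simulate every scheme over every weather year and average the season
    outputs (unweighted mean over years)."""
    results = []
    for spec in specs:
        rows = []
        for year, wx in weather_years.items():
            try:
                plan = plan_for_spec(spec, year)
                sim = run_simulation(
                    wx, soil, crop, plan,
                    planting_date=date(year, *planting_month_day),
                )
            except Exception as exc:  # annotate with scheme/year context
                raise RuntimeError(
                    f"scheme {spec.scheme_id}, year {year}: {exc}"
                ) from exc
            rows.append(
                {
                    "year": year, "yield_t_ha": sim.yield_fresh,
                    "biomass_t_ha": sim.biomass_final, "wue_kg_m3": sim.wue,
                    "et_mm": sim.et_total,
                }
            )
        per_year = pd.DataFrame(rows)
        results.append(
            ScenarioResult(
                scheme_id=spec.scheme_id, spec=spec,
                yield_t_ha=float(per_year["yield_t_ha"].mean()),
                biomass_t_ha=float(per_year["biomass_t_ha"].mean()),
                wue_kg_m3=float(per_year["wue_kg_m3"].mean()),
                et_mm=float(per_year["et_mm"].mean()),
                per_year=per_year,
            )
        )
    return results


def results_to_frame(results: list[ScenarioResult]) -> pd.DataFrame:
    """Season-summary table in the standard column layout."""
    return pd.DataFrame(
        [
            {
                "scheme": r.scheme_id,
                "quota_mm": r.spec.quota_mm,
                "cycle_days": r.spec.cycle_days,
                "n_events": r.spec.n_events,
                "total_m3_ha": r.spec.total_m3_ha,
                "yield_t_ha": r.yield_t_ha,
                "biomass_t_ha": r.biomass_t_ha,
                "wue_kg_m3": r.wue_kg_m3,
                "et_mm": r.et_mm,
            }
            for r in results
        ],
        columns=RESULT_COLUMNS,
    )


def report_tables(results: list[ScenarioResult]) -> pd.DataFrame:
    """Alias with display rounding left to the caller; full precision here."""
    return results_to_frame(results)


def fit_yield_response(points) -> QuadraticFit:
    """Quadratic least squares through (total irrigation m3/ha, yield t/ha)
    pairs; needs at least three distinct irrigation amounts."""
    pts = [(float(x), float(y)) for x, y in points]
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    if len(set(xs.tolist())) < 3:
        raise ValueError("need at least 3 distinct irrigation amounts to fit")
    c2, c1, c0 = np.polyfit(xs, ys, 2)
    yhat = c0 + c1 * xs + c2 * xs * xs
    ss_res = float(np.sum((ys - yhat) ** 2))
    ss_tot = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return QuadraticFit(a=float(c0), b=float(c1), c=float(c2), r2=r2, n_points=len(pts))


def normalize_results(table: pd.DataFrame) -> pd.DataFrame:
    """Accept either a simulator results frame or one of the packaged
    scenario-outcome fixtures and return a frame with scheme, total_m3_ha,
    cycle_days, yield_t_ha, wue_kg_m3 columns."""
    df = table.copy()
    if "total_m3_ha" not in df.columns:
        if "amount_mm" in df.columns:
            df["total_m3_ha"] = 10.0 * df["amount_mm"]
        elif {"quota_mm", "n_events"} <= set(df.columns):
            df["total_m3_ha"] = 10.0 * df["quota_mm"] * df["n_events"]
        else:
            raise ValueError("cannot determine total irrigation volume")
    return df


def select_optimal(
    table: pd.DataFrame,
    criterion: str = "yield",
    subset: pd.Series | None = None,
    minimize: bool = False,
) -> tuple[str, float]:
    """Scheme id and value optimizing the criterion ('yield' or 'wue').

    Ties are broken by lower total irrigation, then by scheme order (a
    scheme achieving the same outcome with less water is preferred).
    """
    col = {"yield": "yield_t_ha", "wue": "wue_kg_m3"}.get(criterion)
    if col is None:
        raise ValueError(f"unknown criterion {criterion!r}")
    df = normalize_results(table)
    if subset is not None:
        df = df[subset.reindex(df.index, fill_value=False)]
    if df.empty:
        raise ValueError("no schemes left after filtering")
    df = df.reset_index(drop=True)
    key = df[col] if not minimize else -df[col]
    best = key.max()
    ties = df[np.isclose(key, best)]
    ties = ties.sort_values(["total_m3_ha"], kind="stable")
    row = ties.iloc[0]
    return str(row["scheme"]), float(row[col])


def scenario_ii_5day_points(table7: pd.DataFrame) -> list[tuple[float, float]]:
    """(total m3/ha, yield) pairs for the 5-day-cycle schemes of the
    fixed-quota scenario — the point set behind the yield-response fit."""
    df = normalize_results(table7)
    sub = df[df["cycle_days"] == 5]
    return list(zip(sub["total_m3_ha"], sub["yield_t_ha"]))


def pooled_5day_points(table6: pd.DataFrame, table7: pd.DataFrame) -> list[tuple[float, float]]:
    """Unique (total, yield) pairs pooled from both scenario tables, 5-day cycle."""
    pts = set()
    for tbl in (table6, table7):
        df = normalize_results(tbl)
        sub = df[df["cycle_days"] == 5]
        pts.update(zip(sub["total_m3_ha"].astype(float), sub["yield_t_ha"].astype(float)))
    return sorted(pts)
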