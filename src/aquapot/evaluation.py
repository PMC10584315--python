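"""Goodness-of-fit statistics between simulated and measured series.

Four statistics standard in crop-model evaluation: root mean square error
(RMSE), RMSE normalized by the measured mean (NRMSE, %), Willmott's index
of agreement (d), and the squared Pearson correlation (R2). The qualitative
interpretation bands used in reports follow common crop-modelling practice:
NRMSE < 10% very good, < 30% moderate; d and R2 > 0.9 excellent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PairedSeries:
    """Aligned simulated (s) and measured (m) values."""

    s: np.ndarray
    m: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "s", np.asarray(self.s, dtype=float))
        object.__setattr__(self, "m", np.asarray(self.m, dtype=float))
        if self.s.shape != self.m.shape or self.s.ndim != 1:
            raise ValueError("simulated and measured series must be equal-length 1-d")
        if len(self.s) == 0:
            raise ValueError("empty series")
        if np.isnan(self.s).any() or np.isnan(self.m).any():
            raise ValueError("series contain missing values after alignment")

    @property
    def n(self) -> int:
        return len(self.s)

    @property
    def m_bar(self) -> float:
        return float(self.m.mean())

    @property
    def s_bar(self) -> float:
        return float(self.s.mean())


@dataclass(frozen=True)
class GoodnessOfFit:
    rmse: float
    nrmse: float  # %
    d: float
    r2: float
    n: int

    def to_row(self, variable: str = "") -> dict:
        return {
            "variable": variable, "n": self.n, "rmse": self.rmse,
            "nrmse_pct": self.nrmse, "d": self.d, "r2": self.r2,
        }


def rmse(p: PairedSeries) -> float:
    """Root mean square error, in the data's units."""
    return float(np.sqrt(np.mean((p.s - p.m) ** 2)))


def nrmse(p: PairedSeries) -> float:
    """RMSE as a percentage of the measured mean."""
    if p.m_bar == 0:
        raise ValueError("measured mean is zero; NRMSE undefined")
    return rmse(p) / p.m_bar * 100.0


def index_of_agreement(p: PairedSeries) -> float:
    """Willmott's index of agreement,
    d = 1 - sum (Si-Mi)^2 / sum (|Si - Mbar| + |Mi - Mbar|)^2, in [0, 1]."""
    mbar = p.m_bar
    den = float(np.sum((np.abs(p.s - mbar) + np.abs(p.m - mbar)) ** 2))
    if den == 0:
        raise ValueError("degenerate series: all values equal the measured mean")
    return 1.0 - float(np.sum((p.s - p.m) ** 2)) / den


def r_squared(p: PairedSeries) -> float:
    """Squared Pearson correlation between simulated and measured values."""
    sd, md = p.s - p.s_bar, p.m - p.m_bar
    ss, mm = float(np.sum(sd**2)), float(np.sum(md**2))
    if ss == 0 or mm == 0:
        raise ValueError("zero variance in a series; R2 undefined")
    return float(np.sum(sd * md) ** 2 / (ss * mm))


def goodness_of_fit(p: PairedSeries) -> GoodnessOfFit:
    return GoodnessOfFit(
        rmse=rmse(p), nrmse=nrmse(p), d=index_of_agreement(p),
        r2=r_squared(p), n=p.n,
    )


def align_by_date(
    sim_daily: pd.DataFrame,
    obs: pd.DataFrame,
    sim_column: str,
    tolerance_days: int = 1,
) -> PairedSeries:
    """Pair observations with simulated days: exact date match first, else
    the nearest simulated day within the tolerance, else an error."""
    sim = sim_daily.set_index(pd.to_datetime(sim_daily["date"]))[sim_column]
    s_vals, m_vals = [], []
    for _, row in obs.iterrows():
        ts = pd.Timestamp(row["date"])
        if ts in sim.index:
            s_vals.append(float(sim.loc[ts]))
        else:
            deltas = np.abs((sim.index - ts).total_seconds()) / 86400.0
            i = int(np.argmin(deltas))
            if deltas[i] > tolerance_days:
                raise ValueError(
                    f"no simulated day within {tolerance_days} d of {ts.date()}"
                )
            s_vals.append(float(sim.iloc[i]))
        m_vals.append(float(row["value"]))
    if not s_vals:
        raise ValueError("no overlapping dates between simulation and observations")
    return PairedSeries(s=np.array(s_vals), m=np.array(m_vals))


#: observation variable -> column of the daily simulation log (canopy cover
#: observations are in %, the simulation stores a fraction)
_VARIABLE_COLUMNS = {"canopy_cover": "cc", "biomass": "b_cum"}


def evaluate(sim_daily: pd.DataFrame, obs: pd.DataFrame, variable: str) -> GoodnessOfFit:
    """Evaluate a simulated trajectory against an observation series."""
    if variable not in _VARIABLE_COLUMNS:
        raise ValueError(
            f"unknown variable {variable!r}; expected one of {sorted(_VARIABLE_COLUMNS)}"
        )
    sub = obs[obs["variable"] == variable] if "variable" in obs.columns else obs
    if sub.empty:
        raise ValueError(f"no observations of {variable!r}")
    sim = sim_daily.copy()
    col = _VARIABLE_COLUMNS[variable]
    if variable == "canopy_cover":
        sim[col] = sim[col] * 100.0  # fraction -> %
    pair = align_by_date(sim, sub, col)
    return goodness_of_fit(pair)


def report_frame(results: dict[str, GoodnessOfFit]) -> pd.DataFrame:
    """Tabular evaluation report (one row per variable)."""
    return pd.DataFrame([g.to_row(v) for v, g in results.items()])


def report_text(results: dict[str, GoodnessOfFit]) -> str:
    lines = [f"{'variable':<14}{'n':>4}{'RMSE':>10}{'NRMSE%':>10}{'d':>8}{'R2':>8}"]
    for v, g in results.items():
        lines.append(
            f"{v:<14}{g.n:>4}{g.rmse:>10.3f}{g.nrmse:>10.2f}{g.d:>8.3f}{g.r2:>8.3f}"
        )
    return "\n".join(lines)
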