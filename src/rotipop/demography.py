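"""Cohort life-table demography and population growth metrics.

A cohort census records, every ``interval`` hours, the number of surviving
mothers and the offspring born in each interval.  From these the classical
life-table columns are derived:

* ``l_x`` — age-specific survivorship, the fraction of the founding cohort
  alive at census age *x*;
* ``m_x`` — age-specific fecundity, female offspring per surviving
  individual in the interval starting at *x*;
* ``L_x`` — individual-time lived in the interval (trapezoidal convention,
  ``interval * (n_x + n_{x+1}) / 2``);
* ``T_x`` — remaining individual-time summed from age *x* onward;
* ``e_x`` — life expectancy at age *x*, ``T_x / n_x``.

Scalar summaries follow: life expectancy at hatching ``e0``, net
reproductive rate ``R0 = sum(l_x m_x)``, generation time
``T = sum(x l_x m_x) / R0``, the rough growth rate ``ln(R0)/T`` and the
intrinsic rate of increase ``r_m``, the real root of the Euler-Lotka
equation ``sum(exp(-r x) l_x m_x) = 1``.  Ages are in hours throughout, so
``r_m`` is per hour; the population growth rate ``r`` estimated from
density trajectories is per day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import (
    DataIntegrityError,
    SolverFailureError,
    UndefinedQuantityError,
)

__all__ = [
    "CohortTable",
    "LifeTable",
    "LifeHistorySummary",
    "DensityTable",
    "GrowthSummary",
    "build_life_table",
    "net_reproductive_rate",
    "generation_time",
    "intrinsic_rate",
    "mixis_ratio",
    "life_history_summary",
    "population_growth_rate",
    "max_density",
]

COHORT_COLUMNS = ["replicate", "time_h", "survivors", "births_total", "births_mictic"]
DENSITY_COLUMNS = ["replicate", "day", "density"]


@dataclass(frozen=True)
class CohortTable:
    """Census records for one or more replicate cohorts.

    ``data`` is a tidy frame with columns ``replicate, time_h, survivors,
    births_total, births_mictic``.  The row at time *t* holds the survivor
    count at census *t* and the offspring born during the interval starting
    at *t*.  Census times must be uniformly spaced and shared across
    replicates; survivor counts must be non-increasing within a replicate.
    """

    data: pd.DataFrame
    interval: float = 8.0

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise DataIntegrityError(f"cohort table missing columns: {missing}")
        df = df.sort_values(["replicate", "time_h"]).reset_index(drop=True)
        object.__setattr__(self, "data", df)
        times = np.sort(df["time_h"].unique())
        if len(times) < 2:
            raise DataIntegrityError("need at least two census times")
        steps = np.diff(times)
        if not np.allclose(steps, steps[0]):
            raise DataIntegrityError("census times must be uniformly spaced")
        if not np.isclose(steps[0], self.interval):
            raise DataIntegrityError(
                f"census spacing {steps[0]} does not match interval={self.interval}"
            )
        bad_rows = []
        for rep, grp in df.groupby("replicate"):
            surv = grp["survivors"].to_numpy()
            drops = np.where(np.diff(surv) > 0)[0]
            for i in drops:
                bad_rows.append((rep, grp["time_h"].iloc[i + 1]))
        if bad_rows:
            raise DataIntegrityError(
                f"survivor counts increase at (replicate, time_h): {bad_rows}"
            )
        if (df["births_mictic"] > df["births_total"]).any():
            raise DataIntegrityError("births_mictic exceeds births_total")
        if (df[["survivors", "births_total", "births_mictic"]] < 0).to_numpy().any():
            raise DataIntegrityError("negative counts in cohort table")

    @property
    def census_times(self) -> np.ndarray:
        return np.sort(self.data["time_h"].unique())

    @property
    def replicates(self) -> list:
        return sorted(self.data["replicate"].unique().tolist())

    def pooled(self) -> pd.DataFrame:
        """Sum counts over replicates, one row per census time."""
        agg = (
            self.data.groupby("time_h")[["survivors", "births_total", "births_mictic"]]
            .sum()
            .reset_index()
        )
        return agg

    def for_replicate(self, rep) -> "CohortTable":
        sub = self.data[self.data["replicate"] == rep].reset_index(drop=True)
        if sub.empty:
            raise KeyError(f"no such replicate: {rep!r}")
        return CohortTable(sub, interval=self.interval)


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed life-table columns (ages in hours)."""

    x: np.ndarray
    n_x: np.ndarray
    l_x: np.ndarray
    m_x: np.ndarray
    L_x: np.ndarray
    T_x: np.ndarray
    e_x: np.ndarray
    interval: float = 8.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.x,
                "n_x": self.n_x,
                "l_x": self.l_x,
                "m_x": self.m_x,
                "L_x": self.L_x,
                "T_x": self.T_x,
                "e_x": self.e_x,
            }
        )


@dataclass(frozen=True)
class LifeHistorySummary:
    """Scalar life-history parameters of a cohort."""

    e0: float  # hours
    R0: float  # offspring per female
    T: float  # generation time, hours
    r_rough: float  # ln(R0)/T, per hour
    r_m: float  # Euler-Lotka root, per hour
    MR: float  # mixis ratio, fraction
    no_offspring: bool = False

    def to_dict(self) -> dict:
        return {
            "e0": self.e0,
            "R0": self.R0,
            "T": self.T,
            "r_rough": self.r_rough,
            "r_m": self.r_m,
            "MR": self.MR,
        }


@dataclass(frozen=True)
class DensityTable:
    """Population density (ind/mL) per day per replicate."""

    data: pd.DataFrame
    n0: float = 2.0  # inoculation density, ind/mL

    def __post_init__(self) -> None:
        missing = [c for c in DENSITY_COLUMNS if c not in self.data.columns]
        if missing:
            raise DataIntegrityError(f"density table missing columns: {missing}")
        if (self.data["density"] < 0).any():
            raise DataIntegrityError("negative densities")
        df = self.data.sort_values(["replicate", "day"]).reset_index(drop=True)
        object.__setattr__(self, "data", df)

    @property
    def replicates(self) -> list:
        return sorted(self.data["replicate"].unique().tolist())


@dataclass(frozen=True)
class GrowthSummary:
    """Replicate-level population growth metrics with mean +/- SE."""

    per_replicate: pd.DataFrame = field(repr=False)
    mean: float = 0.0
    se: float = 0.0
    label: str = ""


def build_life_table(
    cohort: CohortTable, replicate=None, pool: bool = True
) -> LifeTable:
    """Construct the life table, pooling replicates by summing counts.

    With ``pool=False`` and ``replicate`` given, builds the table for that
    single replicate instead (used for per-replicate mean +/- SE summaries).
    """
    if replicate is not None:
        cohort = cohort.for_replicate(replicate)
    elif not pool and len(cohort.replicates) > 1:
        raise ValueError("pool=False requires a single replicate")
    agg = cohort.pooled()
    x = agg["time_h"].to_numpy(dtype=float)
    n_x = agg["survivors"].to_numpy(dtype=float)
    births = agg["births_total"].to_numpy(dtype=float)
    n0 = n_x[0]
    if n0 <= 0:
        raise DataIntegrityError("cohort starts with zero individuals")
    l_x = n_x / n0
    with np.errstate(divide="ignore", invalid="ignore"):
        m_x = np.where(n_x > 0, births / np.where(n_x > 0, n_x, 1.0), 0.0)
    # trapezoid: individual-time lived in [x, x+dt); zero survivors after
    # the final census by construction
    n_next = np.append(n_x[1:], 0.0)
    L_x = cohort.interval * (n_x + n_next) / 2.0
    T_x = np.cumsum(L_x[::-1])[::-1]
    e_x = np.where(n_x > 0, T_x / np.where(n_x > 0, n_x, 1.0), np.nan)
    return LifeTable(
        x=x, n_x=n_x, l_x=l_x, m_x=m_x, L_x=L_x, T_x=T_x, e_x=e_x,
        interval=cohort.interval,
    )


def net_reproductive_rate(lt: LifeTable) -> float:
    """R0 = sum over ages of l_x * m_x (expected offspring per newborn)."""
    if len(lt.l_x) != len(lt.m_x):
        raise ValueError("l_x and m_x length mismatch")
    return float(np.sum(lt.l_x * lt.m_x))


def generation_time(lt: LifeTable) -> float:
    """T = sum(x * l_x * m_x) / R0, in hours."""
    r0 = net_reproductive_rate(lt)
    if r0 <= 0:
        raise UndefinedQuantityError("generation time undefined when R0 = 0")
    return float(np.sum(lt.x * lt.l_x * lt.m_x) / r0)


def _euler_lotka_residual(r: float, x: np.ndarray, lm: np.ndarray) -> float:
    return float(np.sum(np.exp(-r * x) * lm) - 1.0)


def intrinsic_rate(lt: LifeTable, tol: float = 1e-10) -> float:
    """Solve the Euler-Lotka equation for the intrinsic rate of increase.

    Root-finding is initialised at ``r_rough = ln(R0)/T`` with a bracket of
    +/- 0.5 per hour around it, expanded geometrically if the residual does
    not change sign.  Brent's method then refines the root to ``tol``.
    """
    r0 = net_reproductive_rate(lt)
    if r0 <= 0:
        raise UndefinedQuantityError("Euler-Lotka undefined when R0 = 0")
    lm = lt.l_x * lt.m_x
    x = lt.x
    if np.all(x[lm > 0] == 0):
        raise SolverFailureError("all reproduction at age 0: no finite root")
    t_gen = generation_time(lt)
    r_rough = np.log(r0) / t_gen
    lo, hi = r_rough - 0.5, r_rough + 0.5
    f = lambda r: _euler_lotka_residual(r, x, lm)
    # f is strictly decreasing in r; expand until a sign change is bracketed
    for _ in range(60):
        if f(lo) > 0 >= f(hi) or f(lo) >= 0 > f(hi):
            break
        width = hi - lo
        lo -= width
        hi += width
    else:
        raise SolverFailureError(
            f"no sign change for Euler-Lotka root in [{lo}, {hi}]; "
            f"R0={r0}, T={t_gen}"
        )
    root = optimize.brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)
    if abs(f(root)) > max(tol, 1e-9):
        raise SolverFailureError(f"residual {f(root)} exceeds tolerance {tol}")
    return float(root)


def mixis_ratio(cohort: CohortTable) -> tuple[float, bool]:
    """Fraction of offspring that are mictic (sexual).

    Returns ``(MR, no_offspring)``; MR is 0.0 with the flag set when the
    cohort produced no offspring at all.
    """
    total = float(cohort.data["births_total"].sum())
    mictic = float(cohort.data["births_mictic"].sum())
    if total == 0:
        return 0.0, True
    return mictic / total, False


def life_history_summary(cohort: CohortTable, tol: float = 1e-10) -> LifeHistorySummary:
    """All scalar life-history parameters from a (pooled) cohort."""
    lt = build_life_table(cohort)
    r0 = net_reproductive_rate(lt)
    e0 = float(lt.e_x[0])
    mr, flag = mixis_ratio(cohort)
    if r0 > 0:
        t_gen = generation_time(lt)
        r_rough = float(np.log(r0) / t_gen)
        rm = intrinsic_rate(lt, tol=tol)
    else:
        t_gen, r_rough, rm = np.nan, np.nan, np.nan
    return LifeHistorySummary(
        e0=e0, R0=r0, T=t_gen, r_rough=r_rough, r_m=rm, MR=mr, no_offspring=flag
    )


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
    return mean, se


def population_growth_rate(
    density: DensityTable, window: tuple[float, float] = (2.0, 6.0)
) -> GrowthSummary:
    """Per-replicate exponential growth rate over a day window.

    r = (ln N_t1 - ln N_t0) / (t1 - t0) per day, computed per replicate
    between the window endpoints, then summarised as mean +/- SE.
    """
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window must satisfy t1 > t0")
    rows = []
    for rep in density.replicates:
        sub = density.data[density.data["replicate"] == rep]
        for t in (t0, t1):
            if t not in sub["day"].values:
                raise ValueError(f"replicate {rep!r} has no density at day {t}")
        n_a = float(sub.loc[sub["day"] == t0, "density"].iloc[0])
        n_b = float(sub.loc[sub["day"] == t1, "density"].iloc[0])
        if n_a <= 0 or n_b <= 0:
            raise ValueError(f"non-positive density at window endpoint, replicate {rep!r}")
        rows.append({"replicate": rep, "r": (np.log(n_b) - np.log(n_a)) / (t1 - t0)})
    per = pd.DataFrame(rows)
    mean, se = _mean_se(per["r"].to_numpy())
    return GrowthSummary(per_replicate=per, mean=mean, se=se, label="r_per_day")


def max_density(density: DensityTable) -> GrowthSummary:
    """Per-replicate peak density and its day, summarised as mean +/- SE."""
    rows = []
    for rep in density.replicates:
        sub = density.data[density.data["replicate"] == rep]
        if sub.empty:
            continue
        i = int(sub["density"].to_numpy().argmax())
        rows.append(
            {
                "replicate": rep,
                "dmax": float(sub["density"].iloc[i]),
                "peak_day": float(sub["day"].iloc[i]),
            }
        )
    if not rows:
        raise ValueError("empty density table")
    per = pd.DataFrame(rows)
    mean, se = _mean_se(per["dmax"].to_numpy())
    return GrowthSummary(per_replicate=per, mean=mean, se=se, label="Dmax_ind_per_mL")
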