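"""Ten-year two-arm cost-utility simulation and willingness-to-pay tables.

The simulated intervention treats the lower utility tertile of the OI
group.  Each treated person closes a fixed fraction (*attainment*, base
case 75%) of their *potential improvement* — the gap between their
baseline utility and a target utility of 0.745, the mean of the middle
tertile.  The effect builds linearly over the first year (so year one
contributes half the full effect on average) and is sustained
thereafter.  Both arms lose 0.005 utility per year of ageing, and
annual utilities are discounted at 3.5% per year with the first year
undiscounted, following the NICE reference case.  QALYs are the
discounted sum of annual utilities over the 10-year horizon; the QALY
gain is treatment minus control, per person and in aggregate.

Willingness-to-pay: at a cost-effectiveness threshold λ (£/QALY) and a
per-person QALY gain G, the maximum constant annual treatment cost is
``λ·G / A(r, H)`` where A is the discounted annuity factor — the price
at which the discounted 10-year payment stream divided by the gain
exactly equals the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort

__all__ = [
    "SimConfig",
    "SimResult",
    "WTPTable",
    "annuity_factor",
    "potential_improvement",
    "person_qalys",
    "simulate",
    "sensitivity",
    "wtp_annual",
    "build_wtp_table",
    "DEFAULT_THRESHOLDS",
]

#: Default willingness-to-pay thresholds (currency per QALY).
DEFAULT_THRESHOLDS: tuple[int, ...] = tuple(range(20_000, 100_001, 10_000))


@dataclass(frozen=True)
class SimConfig:
    """All simulation constants.

    Attributes
    ----------
    horizon_years
        Simulation horizon in annual cycles (default 10).
    discount_rate
        Annual discount rate for QALYs and costs (default 0.035).
    attainment
        Fraction of each person's potential improvement reached by the
        end of year 1 (base case 0.75).
    sensitivity_grid
        Attainment fractions explored in sensitivity analysis.
    target_utility
        Treatment target; default 0.745, the middle-tertile mean
        utility of the OI group.
    aging_decrement
        Utility lost per year of ageing in both arms (positive number,
        subtracted; default 0.005 from the utility-on-age regression
        slope).
    utility_bounds
        Clamp range for trajectory utilities (value-set floor to 1).
    """

    horizon_years: int = 10
    discount_rate: float = 0.035
    attainment: float = 0.75
    sensitivity_grid: tuple[float, ...] = (0.55, 0.65, 0.75, 0.85, 0.95)
    target_utility: float = 0.745
    aging_decrement: float = 0.005
    utility_bounds: tuple[float, float] = (-0.285, 1.0)

    def __post_init__(self) -> None:
        if self.horizon_years < 1:
            raise ValueError("horizon must be at least 1 year")
        if not 0 <= self.discount_rate < 1:
            raise ValueError("discount rate must lie in [0, 1)")
        if not 0 < self.attainment <= 1:
            raise ValueError("attainment must lie in (0, 1]")
        lo, hi = self.utility_bounds
        if not lo <= self.target_utility <= hi:
            raise ValueError("target utility must lie within the utility bounds")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw[k] for k in (
            "horizon_years", "discount_rate", "attainment", "sensitivity_grid",
            "target_utility", "aging_decrement", "utility_bounds",
        ) if k in raw}
        for k in ("sensitivity_grid", "utility_bounds"):
            if k in known:
                known[k] = tuple(known[k])
        return cls(**known)


def annuity_factor(rate: float, years: int) -> float:
    """Discounted annuity factor Σ_{t=0}^{years−1} (1+rate)^{−t}.

    The first period is undiscounted; at 3.5% over 10 years the factor
    is 8.60769.
    """
    if years < 1:
        raise ValueError("years must be at least 1")
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    t = np.arange(years)
    return float(((1.0 + rate) ** -t).sum())


def potential_improvement(u0: float, target: float) -> float:
    """Gap between baseline utility and the treatment target,
    clamped at zero for baselines already above the target."""
    return float(max(0.0, target - u0))


def _trajectories(u0: np.ndarray, cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Annual utilities (clamped) for the control and treatment arms.

    Returns arrays of shape (n, horizon).
    """
    lo, hi = cfg.utility_bounds
    t = np.arange(cfg.horizon_years)
    base = u0[:, None] - cfg.aging_decrement * t[None, :]
    delta = cfg.attainment * np.maximum(0.0, cfg.target_utility - u0)
    # linear ramp over year 1 contributes half the full effect on average
    effect = np.where(t[None, :] == 0, 0.5, 1.0) * delta[:, None]
    control = np.clip(base, lo, hi)
    treated = np.clip(base + effect, lo, hi)
    return control, treated


def person_qalys(u0: float, arm: str, cfg: SimConfig | None = None) -> float:
    """Discounted 10-year QALYs for one person in one arm.

    Control: ``Σ_t clamp(u0 − d·t)·(1+r)^{−t}``.  Treatment adds the
    attained improvement, half-weighted in year one (linear ramp).
    """
    cfg = cfg or SimConfig()
    lo, hi = cfg.utility_bounds
    if not lo <= u0 <= hi:
        raise ValueError(f"baseline utility {u0} outside bounds [{lo}, {hi}]")
    if arm not in ("treatment", "control"):
        raise ValueError(f"arm must be 'treatment' or 'control', got {arm!r}")
    control, treated = _trajectories(np.array([u0], dtype=float), cfg)
    disc = (1.0 + cfg.discount_rate) ** -np.arange(cfg.horizon_years)
    traj = treated if arm == "treatment" else control
    return float((traj[0] * disc).sum())


@dataclass(frozen=True)
class SimResult:
    """Per-person and aggregate outcomes of one simulation run.

    ``per_person`` columns: id, baseline, potential_improvement,
    untreated_qalys, treated_qalys, gain.  ``gain_interval`` is the
    mean ± 1.96·SD spread of per-person gains (the convention used in
    the reported results); ``gain_mean_ci`` is the standard-error-based
    95% CI of the mean gain.
    """

    per_person: pd.DataFrame
    attainment: float
    total_treated: float
    total_untreated: float
    total_gain: float
    mean_treated: float
    mean_untreated: float
    mean_gain: float
    gain_sd: float
    gain_interval: tuple[float, float]
    gain_mean_ci: tuple[float, float]


def simulate(
    lower_tertile: Cohort | pd.DataFrame | Sequence[float],
    cfg: SimConfig | None = None,
    ids: Sequence[str] | None = None,
) -> SimResult:
    """Run the two-arm simulation over the treated subgroup.

    Accepts a :class:`Cohort`, a DataFrame with ``id``/``utility``
    columns, or a plain sequence of baseline utilities.
    """
    cfg = cfg or SimConfig()
    if isinstance(lower_tertile, Cohort):
        df = lower_tertile.df
        u0, pids = df["utility"].to_numpy(dtype=float), df["id"].tolist()
    elif isinstance(lower_tertile, pd.DataFrame):
        u0 = lower_tertile["utility"].to_numpy(dtype=float)
        pids = lower_tertile["id"].tolist() if "id" in lower_tertile else None
    else:
        u0 = np.asarray(lower_tertile, dtype=float)
        pids = list(ids) if ids is not None else None
    if u0.size == 0:
        raise ValueError("treated subgroup is empty")
    if pids is None:
        pids = [f"p{i + 1:03d}" for i in range(u0.size)]

    control, treated = _trajectories(u0, cfg)
    disc = (1.0 + cfg.discount_rate) ** -np.arange(cfg.horizon_years)
    q_control = control @ disc
    q_treated = treated @ disc
    gains = q_treated - q_control

    per_person = pd.DataFrame({
        "id": pids,
        "baseline": u0,
        "potential_improvement": np.maximum(0.0, cfg.target_utility - u0),
        "untreated_qalys": q_control,
        "treated_qalys": q_treated,
        "gain": gains,
    })
    mean_gain = float(gains.mean())
    sd = float(gains.std(ddof=1)) if gains.size > 1 else 0.0
    se = sd / np.sqrt(gains.size) if gains.size > 1 else 0.0
    return SimResult(
        per_person=per_person,
        attainment=cfg.attainment,
        total_treated=float(q_treated.sum()),
        total_untreated=float(q_control.sum()),
        total_gain=float(gains.sum()),
        mean_treated=float(q_treated.mean()),
        mean_untreated=float(q_control.mean()),
        mean_gain=mean_gain,
        gain_sd=sd,
        gain_interval=(mean_gain - 1.96 * sd, mean_gain + 1.96 * sd),
        gain_mean_ci=(mean_gain - 1.96 * se, mean_gain + 1.96 * se),
    )


def sensitivity(
    lower_tertile,
    cfg: SimConfig | None = None,
    grid: Iterable[float] | None = None,
) -> dict[float, float]:
    """Mean per-person QALY gain at each attainment fraction.

    Absent clamping the gain is exactly proportional to attainment.
    """
    cfg = cfg or SimConfig()
    grid = tuple(grid) if grid is not None else cfg.sensitivity_grid
    if not grid:
        raise ValueError("sensitivity grid is empty")
    out = {}
    for a in grid:
        out[a] = simulate(lower_tertile, SimConfig(
            horizon_years=cfg.horizon_years,
            discount_rate=cfg.discount_rate,
            attainment=a,
            sensitivity_grid=cfg.sensitivity_grid,
            target_utility=cfg.target_utility,
            aging_decrement=cfg.aging_decrement,
            utility_bounds=cfg.utility_bounds,
        )).mean_gain
    return out


def wtp_annual(threshold: float, gain: float, cfg: SimConfig | None = None) -> float:
    """Maximum constant annual treatment cost at a cost-effectiveness
    threshold.

    ``threshold × gain / annuity_factor``: the discounted total of this
    payment stream over the horizon, divided by the QALY gain, equals
    the threshold exactly.  Unrounded; round to currency units only at
    presentation.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if gain < 0:
        raise ValueError("gain must be non-negative")
    cfg = cfg or SimConfig()
    return threshold * gain / annuity_factor(cfg.discount_rate, cfg.horizon_years)


@dataclass(frozen=True)
class WTPTable:
    """Grid of maximum annual costs: thresholds (rows) × attainment
    fractions (columns), with the per-attainment QALY gains attached."""

    table: pd.DataFrame       # unrounded annual costs
    gains: dict[float, float]

    def rounded(self) -> pd.DataFrame:
        """Presentation copy rounded to whole currency units."""
        return self.table.round(0).astype(int)

    def to_csv(self, path: str | Path) -> None:
        out = self.rounded()
        out.index.name = "threshold"
        out.to_csv(path)


def build_wtp_table(
    gains_by_attainment: dict[float, float],
    thresholds: Iterable[float] | None = None,
    cfg: SimConfig | None = None,
) -> WTPTable:
    """Willingness-to-pay grid from per-attainment QALY gains.

    Every row is linear in its threshold and every column proportional
    to its gain.
    """
    cfg = cfg or SimConfig()
    thresholds = tuple(thresholds) if thresholds is not None else DEFAULT_THRESHOLDS
    if not gains_by_attainment:
        raise ValueError("no gains supplied")
    if any(g <= 0 for g in gains_by_attainment.values()):
        raise ValueError("gains must be positive")
    cols = {}
    for a, gain in sorted(gains_by_attainment.items()):
        cols[a] = [wtp_annual(th, gain, cfg) for th in thresholds]
    df = pd.DataFrame(cols, index=list(thresholds))
    df.index.name = "threshold"
    return WTPTable(table=df, gains=dict(sorted(gains_by_attainment.items())))
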