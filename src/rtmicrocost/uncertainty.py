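"""Uncertainty quantification: percentile bootstrap and tornado analysis.

The non-parametric bootstrap resamples patients with replacement within an
arm (1,000 iterations by default) and forms the 95% CI of the weighted mean
total cost by rank-based trimming — dropping ceil(2.5%) of the iterates at
either end of the sorted vector, not by interpolation.  Stabilized weights
travel with their patients and are not re-estimated per resample.

The one-way sensitivity analysis perturbs one parameter at a time by
+/-20% (prices, maintenance, wages, labor times, annual operating time and
accelerator immobilization time) and records the group mean total cost at
each end; rows sorted by descending range give the tornado diagram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd

from .config import ROLES
from .costing import UnitCostTable, cost_breakdowns


class UncertaintyError(ValueError):
    """Raised for unusable bootstrap or sensitivity configurations."""


@dataclass
class BootstrapConfig:
    iterations: int = 1000
    ci_level: float = 0.95
    seed: int | None = None

    def validate(self) -> None:
        if not 0.0 < self.ci_level < 1.0:
            raise UncertaintyError("ci_level must lie in (0, 1)")
        if self.iterations < 2.0 / (1.0 - self.ci_level):
            raise UncertaintyError(
                f"{self.iterations} iterations cannot resolve a "
                f"{self.ci_level:.0%} percentile CI (need at least "
                f"{math.ceil(2.0 / (1.0 - self.ci_level))})"
            )


@dataclass
class BootstrapResult:
    mean: float
    ci_low: float
    ci_high: float
    iterations: int
    ci_level: float


def percentile_interval(iterates, ci_level: float):
    """Rank-based percentile CI: drop ceil(alpha/2 * B) order statistics per tail."""
    s = np.sort(np.asarray(iterates, dtype=float))
    b = len(s)
    # small epsilon so e.g. 2.5% of 1000 trims exactly 25 despite binary
    # floating-point representation of the tail probability
    k = math.ceil((1.0 - ci_level) / 2.0 * b - 1e-9)
    if 2 * k >= b:
        raise UncertaintyError("too few iterates for the requested CI level")
    return float(s[k]), float(s[b - 1 - k])


def bootstrap_mean_cost(
    total_costs,
    weights=None,
    config: BootstrapConfig | None = None,
    rng: np.random.Generator | None = None,
) -> BootstrapResult:
    """Percentile-bootstrap CI of the weighted mean total cost of one arm.

    The point estimate is the weighted mean of the full data and does not
    depend on the number of iterations.
    """
    config = config if config is not None else BootstrapConfig()
    config.validate()
    y = np.asarray(total_costs, dtype=float)
    if len(y) < 2:
        raise UncertaintyError("need at least 2 patients to bootstrap")
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    idx = rng.integers(0, len(y), size=(config.iterations, len(y)))
    means = (y[idx] * w[idx]).sum(axis=1) / w[idx].sum(axis=1)
    lo, hi = percentile_interval(means, config.ci_level)
    point = float(np.sum(y * w) / w.sum())
    return BootstrapResult(point, lo, hi, config.iterations, config.ci_level)


def bootstrap_by_arm(
    breakdowns: pd.DataFrame,
    weights=None,
    config: BootstrapConfig | None = None,
) -> pd.DataFrame:
    """Arm-stratified bootstrap of the mean total cost; one row per arm."""
    config = config if config is not None else BootstrapConfig()
    rng = np.random.default_rng(config.seed)
    w = np.ones(len(breakdowns)) if weights is None else np.asarray(weights, float)
    rows = []
    for arm, sub in breakdowns.groupby("arm", sort=False):
        res = bootstrap_mean_cost(
            sub["total_cost"].to_numpy(),
            w[breakdowns["arm"].to_numpy() == arm],
            config,
            rng,
        )
        rows.append(
            {
                "arm": arm,
                "mean": res.mean,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "iterations": res.iterations,
                "ci_level": res.ci_level,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-way (tornado) sensitivity analysis


@dataclass
class TornadoRow:
    parameter: str
    base: float
    low: float  # group mean total cost at parameter x (1 - delta)
    high: float  # ... at parameter x (1 + delta)
    range: float = field(init=False)
    pct_change_low: float = field(init=False)
    pct_change_high: float = field(init=False)

    def __post_init__(self):
        self.range = abs(self.high - self.low)
        self.pct_change_low = 100.0 * (self.low - self.base) / self.base
        self.pct_change_high = 100.0 * (self.high - self.base) / self.base


DEFAULT_TORNADO_PARAMETERS = (
    "annual_operating_hours",
    "accelerator_immobilization_time",
    "accelerator_price",
    "external_maintenance",
    "tps_price",
    "labor_time_radiation_therapist",
    "labor_time_dosimetrist",
    "labor_time_medical_physicist",
    "labor_time_radiation_oncologist",
    "wage_radiation_therapist",
)


def _perturbed_inputs(
    unit_costs: UnitCostTable, events: pd.DataFrame, parameter: str, factor: float
):
    """Return (unit_costs, events) with exactly one parameter scaled."""
    uc = UnitCostTable.from_dict(unit_costs.to_dict())  # deep copy
    ev = events
    if parameter == "annual_operating_hours":
        for key, spec in uc.equipment.items():
            uc.equipment[key] = replace(
                spec, annual_operating_hours=spec.annual_operating_hours * factor
            )
    elif parameter == "accelerator_immobilization_time":
        ev = events.copy()
        on_acc = ev["equipment"] == "accelerator"
        ev.loc[on_acc, "equipment_minutes"] *= factor
    elif parameter == "accelerator_price":
        for key in ("accelerator_VMAT", "accelerator_HT"):
            spec = uc.equipment[key]
            uc.equipment[key] = replace(
                spec, purchase_price=spec.purchase_price * factor
            )
    elif parameter == "tps_price":
        spec = uc.equipment["TPS_VMAT"]
        uc.equipment["TPS_VMAT"] = replace(
            spec, purchase_price=spec.purchase_price * factor
        )
    elif parameter == "external_maintenance":
        for key, spec in uc.equipment.items():
            uc.equipment[key] = replace(
                spec, annual_maintenance=spec.annual_maintenance * factor
            )
    elif parameter.startswith("wage_"):
        role = parameter[len("wage_"):]
        if role not in uc.role_wages:
            raise UncertaintyError(f"unknown role in parameter {parameter!r}")
        w = uc.role_wages[role]
        uc.role_wages[role] = replace(
            w, annual_full_gross_wage=w.annual_full_gross_wage * factor
        )
    elif parameter.startswith("labor_time_"):
        role = parameter[len("labor_time_"):]
        if role not in ROLES:
            raise UncertaintyError(f"unknown role in parameter {parameter!r}")
        ev = events.copy()
        on_role = ev["role"] == role
        ev.loc[on_role, "personnel_minutes"] *= factor
    else:
        raise UncertaintyError(f"unknown sensitivity parameter {parameter!r}")
    return uc, ev


def _group_mean_total(events, arms, unit_costs, weights=None) -> float:
    bd = cost_breakdowns(events, arms, unit_costs)
    y = bd["total_cost"].to_numpy()
    w = np.ones(len(y)) if weights is None else np.asarray(weights, float)
    return float(np.sum(y * w) / w.sum())


def one_way_sensitivity(
    unit_costs: UnitCostTable,
    events: pd.DataFrame,
    arms: pd.Series,
    parameters=DEFAULT_TORNADO_PARAMETERS,
    delta: float = 0.20,
    weights=None,
) -> list[TornadoRow]:
    """Group mean total cost with each parameter at x(1-delta) and x(1+delta).

    Exactly one parameter is perturbed per row, all else at baseline; the
    rows come back sorted by descending range.  ``arms`` should normally
    cover a single arm so the tornado describes that technique's total.
    """
    base = _group_mean_total(events, arms, unit_costs, weights)
    rows = []
    for parameter in parameters:
        vals = {}
        for label, factor in (("low", 1.0 - delta), ("high", 1.0 + delta)):
            uc, ev = _perturbed_inputs(unit_costs, events, parameter, factor)
            vals[label] = _group_mean_total(ev, arms, uc, weights)
        rows.append(TornadoRow(parameter, base, vals["low"], vals["high"]))
    rows.sort(key=lambda r: r.range, reverse=True)
    return rows


def tornado_export(rows: list[TornadoRow]) -> pd.DataFrame:
    """Plot-ready tornado table: bar endpoints relative to the base line."""
    if not rows:
        raise UncertaintyError("no tornado rows to export")
    ordered = sorted(rows, key=lambda r: r.range, reverse=True)
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "base": r.base,
                "low": r.low,
                "high": r.high,
                "range": r.range,
                "bar_start": min(r.low, r.high) - r.base,
                "bar_end": max(r.low, r.high) - r.base,
                "pct_change_low": r.pct_change_low,
                "pct_change_high": r.pct_change_high,
            }
            for r in ordered
        ]
    )
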