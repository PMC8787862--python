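"""Micro-costing engine.

Converts per-patient resource-use logs and a unit-cost parameter set into
per-patient cost breakdowns with the component structure of a bottom-up
hospital costing of IMRT preparation and delivery:

* labor is valued at the annual full gross wage (payroll taxes included)
  divided by workable yearly hours;
* equipment is valued by straight-line, undiscounted replacement plus
  maintenance cost spread over annual operating hours (12-year lifespan
  for accelerators, 5 years for the planning system);
* annual machine QC and internal-maintenance labor (medical physicist +
  biomedical technician dedicated hours) is folded into the accelerator's
  annual cost before the hourly rate is formed, so it reaches patients
  through machine occupancy time like any other upkeep cost.

The HT accelerator price includes its integrated planning system, so HT
patients carry no separate TPS components.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .config import ARMS, ROLES

#: the two labor roles performing machine QC / internal maintenance
QC_IM_ROLES = ("medical_physicist", "biomedical_technician")

#: cost components of one patient's breakdown, in table order
COMPONENTS = (
    "image_registration_labor",
    "image_registration_tps",
    "inverse_planning_labor",
    "inverse_planning_tps",
    "patient_qc_labor",
    "setup_d0_labor",
    "setup_d0_accelerator",
    "session_labor",
    "session_accelerator",
)
PLANNING_COMPONENTS = COMPONENTS[:7]
SESSION_COMPONENTS = COMPONENTS[7:]

#: (phase, cost kind) -> component column
_PHASE_COMPONENT = {
    ("image_registration_contouring", "labor"): "image_registration_labor",
    ("image_registration_contouring", "tps"): "image_registration_tps",
    ("inverse_planning", "labor"): "inverse_planning_labor",
    ("inverse_planning", "tps"): "inverse_planning_tps",
    ("patient_qc", "labor"): "patient_qc_labor",
    ("setup_verification_d0", "labor"): "setup_d0_labor",
    ("setup_verification_d0", "accelerator"): "setup_d0_accelerator",
    ("session", "labor"): "session_labor",
    ("session", "accelerator"): "session_accelerator",
}


class CostingError(ValueError):
    """Raised for invalid unit costs or unknown roles/machines in a log."""


@dataclass
class RoleWage:
    annual_full_gross_wage: float  # EUR / year, payroll taxes included
    workable_hours: float  # hours / year


@dataclass
class EquipmentSpec:
    purchase_price: float  # EUR, taxes included
    lifespan_years: float  # straight-line amortization horizon
    annual_maintenance: float  # external maintenance contract, EUR / year
    annual_operating_hours: float  # hours / year


@dataclass
class UnitCostTable:
    """All monetary parameters of the costing model (EUR, one currency year)."""

    role_wages: Mapping[str, RoleWage]
    equipment: Mapping[str, EquipmentSpec]
    #: arm -> {role -> annual dedicated QC/IM hours}
    qc_im_hours: Mapping[str, Mapping[str, float]]
    currency_year: str = "EUR2019"

    def validate(self) -> None:
        for role, w in self.role_wages.items():
            if w.annual_full_gross_wage < 0:
                raise CostingError(f"negative wage for {role}")
            if w.workable_hours <= 0:
                raise CostingError(f"workable hours must be positive for {role}")
        for name, spec in self.equipment.items():
            if spec.lifespan_years <= 0 or spec.annual_operating_hours <= 0:
                raise CostingError(
                    f"lifespan and operating hours must be positive for {name}"
                )
            if spec.purchase_price < 0 or spec.annual_maintenance < 0:
                raise CostingError(f"negative monetary value for {name}")
        for arm, hours in self.qc_im_hours.items():
            if set(hours) != set(QC_IM_ROLES):
                raise CostingError(
                    f"qc_im_hours[{arm}] must cover exactly {QC_IM_ROLES}"
                )

    # -- lookups --------------------------------------------------------

    def wage(self, role: str) -> RoleWage:
        try:
            return self.role_wages[role]
        except KeyError:
            raise CostingError(f"no wage configured for role {role!r}") from None

    def accelerator_key(self, arm: str) -> str:
        return {"VMAT": "accelerator_VMAT", "HT": "accelerator_HT"}[arm]

    def machine_rate(self, machine: str, arm: str) -> float:
        """Hourly cost of a machine; accelerators absorb annual QC/IM labor."""
        key = self.accelerator_key(arm) if machine == "accelerator" else machine
        if machine == "tps":
            if arm == "HT":
                return 0.0  # HT accelerator price includes the TPS
            key = "TPS_VMAT"
        spec = self.equipment.get(key)
        if spec is None:
            raise CostingError(f"no equipment spec for {key!r}")
        qc_im = qc_im_annual_cost(self, arm) if machine == "accelerator" else 0.0
        return equipment_hourly_cost(spec, qc_im)

    # -- round-trip to a structured configuration file ------------------

    def to_dict(self) -> dict:
        return {
            "role_wages": {r: asdict(w) for r, w in self.role_wages.items()},
            "equipment": {k: asdict(s) for k, s in self.equipment.items()},
            "qc_im_hours": {a: dict(h) for a, h in self.qc_im_hours.items()},
            "currency_year": self.currency_year,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "UnitCostTable":
        return cls(
            role_wages={r: RoleWage(**w) for r, w in d["role_wages"].items()},
            equipment={k: EquipmentSpec(**s) for k, s in d["equipment"].items()},
            qc_im_hours={a: dict(h) for a, h in d["qc_im_hours"].items()},
            currency_year=d.get("currency_year", "EUR2019"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "UnitCostTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# elementary valuations


def hourly_wage(annual_full_gross_wage: float, workable_hours: float) -> float:
    """Hourly labor cost: annual full gross wage over workable yearly hours."""
    if workable_hours <= 0:
        raise CostingError("workable_hours must be strictly positive")
    return annual_full_gross_wage / workable_hours


def equipment_hourly_cost(spec: EquipmentSpec, qc_im_annual: float = 0.0) -> float:
    """Hourly equipment cost: straight-line amortization plus annual upkeep.

    (price / lifespan + external maintenance + annual QC/IM labor) spread
    over annual operating hours; undiscounted.
    """
    if spec is None:
        raise CostingError("missing equipment spec")
    if spec.lifespan_years <= 0 or spec.annual_operating_hours <= 0:
        raise CostingError("lifespan and operating hours must be positive")
    annual = (
        spec.purchase_price / spec.lifespan_years
        + spec.annual_maintenance
        + qc_im_annual
    )
    return annual / spec.annual_operating_hours


def qc_im_annual_cost(unit_costs: UnitCostTable, arm: str) -> float:
    """Annual machine QC / internal-maintenance labor cost for one arm.

    Sum over the physicist and technician of hourly full wage times their
    annual dedicated hours.
    """
    hours = unit_costs.qc_im_hours.get(arm)
    if hours is None:
        raise CostingError(f"no QC/IM hours configured for arm {arm!r}")
    total = 0.0
    for role in QC_IM_ROLES:
        if role not in hours:
            raise CostingError(f"qc_im_hours[{arm}] missing role {role!r}")
        w = unit_costs.wage(role)
        total += hourly_wage(w.annual_full_gross_wage, w.workable_hours) * hours[role]
    return total


# ---------------------------------------------------------------------------
# per-patient breakdowns


@dataclass
class CostBreakdown:
    """Per-patient euro amounts for each cost component."""

    patient_id: str
    components: Mapping[str, float] = field(default_factory=dict)

    @property
    def planning_cost(self) -> float:
        return sum(self.components.get(c, 0.0) for c in PLANNING_COMPONENTS)

    @property
    def session_cost(self) -> float:
        return sum(self.components.get(c, 0.0) for c in SESSION_COMPONENTS)

    @property
    def total_cost(self) -> float:
        return self.planning_cost + self.session_cost


def _component_frame(events: pd.DataFrame, unit_costs: UnitCostTable, arms: pd.Series) -> pd.DataFrame:
    """Vectorized component costs for a multi-patient event log."""
    if events.empty:
        return pd.DataFrame(
            0.0, index=pd.Index(arms.index, name="patient_id"), columns=list(COMPONENTS)
        )
    unknown_roles = set(events["role"]) - set(unit_costs.role_wages)
    if unknown_roles:
        raise CostingError(f"events reference roles without wages: {sorted(unknown_roles)}")
    unknown_phases = {
        p for p in events["phase"].unique() if (p, "labor") not in _PHASE_COMPONENT
    }
    if unknown_phases:
        raise CostingError(f"events reference unknown phases: {sorted(unknown_phases)}")

    wage_rate = {
        r: hourly_wage(w.annual_full_gross_wage, w.workable_hours)
        for r, w in unit_costs.role_wages.items()
    }
    machine_rate = {
        (m, arm): unit_costs.machine_rate(m, arm)
        for m in ("accelerator", "tps")
        for arm in ARMS
    }

    ev = events.copy()
    ev["arm"] = ev["patient_id"].map(arms)
    if ev["arm"].isna().any():
        missing = ev.loc[ev["arm"].isna(), "patient_id"].unique()
        raise CostingError(f"events for patients with unknown arm: {list(missing)[:5]}")
    ev["labor_cost"] = (
        ev["personnel_minutes"] / 60.0 * ev["role"].map(wage_rate)
    )
    has_eq = ev["equipment"].isin(["accelerator", "tps"])
    acc_rate = ev["arm"].map({a: machine_rate[("accelerator", a)] for a in ARMS})
    tps_rate = ev["arm"].map({a: machine_rate[("tps", a)] for a in ARMS})
    eq_rate = np.where(
        ev["equipment"] == "accelerator",
        acc_rate,
        np.where(ev["equipment"] == "tps", tps_rate, 0.0),
    )
    ev["equipment_cost"] = ev["equipment_minutes"] / 60.0 * eq_rate

    labor = ev.pivot_table(
        index="patient_id", columns="phase", values="labor_cost",
        aggfunc="sum", fill_value=0.0, sort=False,
    )
    ev_eq = ev[has_eq]
    equip = (
        ev_eq.pivot_table(
            index="patient_id",
            columns=["phase", "equipment"],
            values="equipment_cost",
            aggfunc="sum",
            fill_value=0.0,
            sort=False,
        )
        if not ev_eq.empty
        else pd.DataFrame()
    )

    out = pd.DataFrame(
        0.0, index=pd.Index(arms.index, name="patient_id"), columns=list(COMPONENTS)
    )
    for phase in labor.columns:
        out.loc[labor.index, _PHASE_COMPONENT[(phase, "labor")]] = labor[phase]
    for (phase, machine) in equip.columns:
        comp = _PHASE_COMPONENT.get((phase, machine))
        if comp is None:
            raise CostingError(f"no component for phase {phase!r} with {machine!r}")
        out.loc[equip.index, comp] += equip[(phase, machine)]
    return out


def cost_breakdowns(
    events: pd.DataFrame, arms: pd.Series, unit_costs: UnitCostTable
) -> pd.DataFrame:
    """Per-patient component costs plus derived sums.

    Parameters
    ----------
    events : resource-use log (cohort.EVENT_COLUMNS schema)
    arms : Series mapping patient_id -> arm; its index defines the output
        rows, so patients with an empty log get all-zero components.
    """
    unit_costs.validate()
    out = _component_frame(events, unit_costs, arms)
    out["planning_cost"] = out[list(PLANNING_COMPONENTS)].sum(axis=1)
    out["session_cost"] = out[list(SESSION_COMPONENTS)].sum(axis=1)
    out["total_cost"] = out["planning_cost"] + out["session_cost"]
    out.insert(0, "arm", arms)
    return out.reset_index()


def patient_cost_breakdown(
    events: pd.DataFrame, unit_costs: UnitCostTable, arm: str
) -> CostBreakdown:
    """Cost breakdown of a single patient's event log."""
    if events.empty:
        return CostBreakdown(patient_id="", components={c: 0.0 for c in COMPONENTS})
    pids = events["patient_id"].unique()
    if len(pids) != 1:
        raise CostingError("patient_cost_breakdown expects a single patient's events")
    arms = pd.Series({pids[0]: arm})
    frame = cost_breakdowns(events, arms, unit_costs)
    comp = {c: float(frame.iloc[0][c]) for c in COMPONENTS}
    return CostBreakdown(patient_id=str(pids[0]), components=comp)


def summarize_costs(
    breakdowns: pd.DataFrame, weights: pd.Series | np.ndarray | None = None
) -> pd.DataFrame:
    """Per-arm weighted mean (SD) of each component and the derived rows.

    Weighted moments use normalized weights (frequency-weighted variance
    with a sum-of-weights-minus-one denominator, so unit weights reduce
    exactly to the ordinary mean/SD); derived rows are sums of component
    means, preserving the accounting identities of the per-patient table.
    """
    cols = list(COMPONENTS) + ["planning_cost", "session_cost", "total_cost"]
    if weights is None:
        w = np.ones(len(breakdowns))
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(breakdowns):
            raise CostingError("weights length does not match breakdowns")
        if np.any(w <= 0):
            raise CostingError("weights must be strictly positive")
    rows = []
    for arm, sub in breakdowns.groupby("arm", sort=False):
        wa = w[breakdowns["arm"].to_numpy() == arm]
        sw = wa.sum()
        for col in cols:
            x = sub[col].to_numpy(dtype=float)
            mean = float(np.sum(wa * x) / sw)
            var = float(np.sum(wa * (x - mean) ** 2) / (sw - 1)) if sw > 1 else 0.0
            rows.append(
                {"arm": arm, "component": col, "mean": mean, "sd": np.sqrt(max(var, 0.0)),
                 "n": len(sub), "sum_weights": sw}
            )
    return pd.DataFrame(rows)
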