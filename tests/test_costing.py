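"""Costing engine: valuations, breakdowns, accounting identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rtmicrocost as rtm
from rtmicrocost.costing import (
    COMPONENTS,
    CostingError,
    EquipmentSpec,
    RoleWage,
    UnitCostTable,
    equipment_hourly_cost,
    hourly_wage,
    qc_im_annual_cost,
)


def toy_unit_costs(physicist=80_000.0, technician=48_000.0, qc_hours=None):
    """A hand-checkable unit-cost table (wages at 1,600 workable hours)."""
    qc_hours = qc_hours or {"medical_physicist": 100.0, "biomedical_technician": 50.0}
    wages = {
        "radiation_therapist": RoleWage(48_000.0, 1600.0),
        "dosimetrist": RoleWage(64_000.0, 1600.0),
        "medical_physicist": RoleWage(physicist, 1600.0),
        "radiation_oncologist": RoleWage(160_000.0, 1600.0),
        "resident": RoleWage(40_000.0, 1600.0),
        "biomedical_technician": RoleWage(technician, 1600.0),
    }
    equipment = {
        "accelerator_VMAT": EquipmentSpec(3_600_000.0, 12.0, 0.0, 2500.0),
        "accelerator_HT": EquipmentSpec(4_800_000.0, 12.0, 0.0, 2500.0),
        "TPS_VMAT": EquipmentSpec(250_000.0, 5.0, 0.0, 2500.0),
    }
    return UnitCostTable(
        role_wages=wages,
        equipment=equipment,
        qc_im_hours={"VMAT": dict(qc_hours), "HT": dict(qc_hours)},
    )


class TestElementaryValuations:
    @pytest.mark.parametrize(
        "wage,hours,expected",
        [(80_000, 1_600, 50.0), (0, 1_600, 0.0), (160_000, 1_600, 100.0)],
    )
    def test_hourly_wage(self, wage, hours, expected):
        assert hourly_wage(wage, hours) == pytest.approx(expected)

    def test_hourly_wage_homogeneous(self):
        assert hourly_wage(2 * 77_123, 1_607) == pytest.approx(
            2 * hourly_wage(77_123, 1_607)
        )

    def test_hourly_wage_rejects_zero_hours(self):
        with pytest.raises(CostingError):
            hourly_wage(50_000, 0)

    def test_equipment_hourly_cost_arithmetic(self):
        spec = EquipmentSpec(3_600_000.0, 12.0, 0.0, 2500.0)
        assert equipment_hourly_cost(spec) == pytest.approx(120.0)

    def test_equipment_cost_inverse_in_operating_hours(self):
        spec = EquipmentSpec(3_600_000.0, 12.0, 50_000.0, 2500.0)
        stretched = EquipmentSpec(3_600_000.0, 12.0, 50_000.0, 2500.0 * 1.2)
        assert equipment_hourly_cost(stretched) == pytest.approx(
            equipment_hourly_cost(spec) / 1.2
        )

    def test_equipment_cost_monotone_in_qc_im(self):
        spec = EquipmentSpec(3_600_000.0, 12.0, 10_000.0, 2500.0)
        assert equipment_hourly_cost(spec, 5_000.0) > equipment_hourly_cost(spec, 0.0)

    def test_equipment_cost_missing_spec(self):
        with pytest.raises(CostingError):
            equipment_hourly_cost(None)

    def test_qc_im_two_term_sum(self):
        # physicist 50 EUR/h x 100 h + technician 30 EUR/h x 50 h
        uc = toy_unit_costs()
        assert qc_im_annual_cost(uc, "VMAT") == pytest.approx(6_500.0)

    def test_qc_im_zero_hours(self):
        uc = toy_unit_costs(
            qc_hours={"medical_physicist": 0.0, "biomedical_technician": 0.0}
        )
        assert qc_im_annual_cost(uc, "HT") == 0.0

    def test_qc_im_hours_ratio_at_equal_wages(self):
        """194.5 vs 144 dedicated hours give a 194.5/144 annual-cost ratio."""
        uc = toy_unit_costs()
        uc.qc_im_hours = {
            "VMAT": {"medical_physicist": 120.0, "biomedical_technician": 74.5},
            "HT": {"medical_physicist": 90.0, "biomedical_technician": 54.0},
        }
        # equal split weighting only holds at equal wages
        uc.role_wages["biomedical_technician"] = uc.role_wages["medical_physicist"]
        ratio = qc_im_annual_cost(uc, "VMAT") / qc_im_annual_cost(uc, "HT")
        assert ratio == pytest.approx(194.5 / 144.0)

    def test_qc_im_missing_role(self):
        uc = toy_unit_costs()
        uc.qc_im_hours["VMAT"].pop("biomedical_technician")
        with pytest.raises(CostingError, match="biomedical_technician"):
            qc_im_annual_cost(uc, "VMAT")


def _event(pid, phase, role, personnel, equipment="none", eq_minutes=0.0, idx=0):
    return {
        "patient_id": pid,
        "phase": phase,
        "session_index": idx,
        "role": role,
        "personnel_minutes": personnel,
        "equipment": equipment,
        "equipment_minutes": eq_minutes,
    }


class TestPatientBreakdown:
    def test_zero_minute_log_costs_nothing(self):
        uc = toy_unit_costs()
        events = pd.DataFrame(
            [_event("P1", "session", "radiation_therapist", 0.0, "accelerator", 0.0, 1)]
        )
        bd = rtm.patient_cost_breakdown(events, uc, "VMAT")
        assert all(v == 0.0 for v in bd.components.values())
        assert bd.total_cost == 0.0

    def test_three_event_toy_log_hand_computed(self):
        """Component costs equal per-event multiplication done by hand."""
        uc = toy_unit_costs()
        events = pd.DataFrame(
            [
                _event("P1", "inverse_planning", "dosimetrist", 30.0),
                _event("P1", "session", "radiation_therapist", 60.0, idx=1),
                _event(
                    "P1", "session", "radiation_therapist", 0.0, "accelerator", 30.0, 2
                ),
            ]
        )
        bd = rtm.patient_cost_breakdown(events, uc, "VMAT")
        # dosimetrist 40 EUR/h x 0.5 h; therapist 30 EUR/h x 1 h;
        # accelerator (3.6e6/12 + qc_im 6,500)/2,500 = 122.6 EUR/h x 0.5 h
        assert bd.components["inverse_planning_labor"] == pytest.approx(20.0)
        assert bd.components["session_labor"] == pytest.approx(30.0)
        assert bd.components["session_accelerator"] == pytest.approx(61.3)
        assert bd.total_cost == pytest.approx(111.3)

    def test_ht_tps_minutes_cost_zero(self):
        uc = toy_unit_costs()
        events = pd.DataFrame(
            [
                _event(
                    "P1",
                    "inverse_planning",
                    "dosimetrist",
                    0.0,
                    "tps",
                    120.0,
                )
            ]
        )
        bd = rtm.patient_cost_breakdown(events, uc, "HT")
        assert bd.components["inverse_planning_tps"] == 0.0

    def test_unknown_role_named_in_error(self):
        uc = toy_unit_costs()
        uc.role_wages.pop("dosimetrist")
        events = pd.DataFrame([_event("P1", "inverse_planning", "dosimetrist", 30.0)])
        with pytest.raises(CostingError, match="dosimetrist"):
            rtm.patient_cost_breakdown(events, uc, "VMAT")

    def test_brute_force_oracle_small_cohorts(self, rng):
        """Vectorized breakdowns equal event-by-event summation on <=5 patients."""
        uc = toy_unit_costs()
        wage_rate = {
            r: w.annual_full_gross_wage / w.workable_hours
            for r, w in uc.role_wages.items()
        }
        roles = list(uc.role_wages)
        phases = [
            "image_registration_contouring",
            "inverse_planning",
            "patient_qc",
            "setup_verification_d0",
            "session",
        ]
        for trial in range(10):
            n = int(rng.integers(1, 6))
            arms = pd.Series(
                {f"P{i}": ("HT" if rng.random() < 0.5 else "VMAT") for i in range(n)}
            )
            recs = []
            for pid in arms.index:
                for _ in range(int(rng.integers(1, 8))):
                    phase = phases[rng.integers(len(phases))]
                    allowed = _ALLOWED_EQUIPMENT[phase]
                    eq = allowed[rng.integers(len(allowed))]
                    recs.append(
                        _event(
                            pid,
                            phase,
                            roles[rng.integers(len(roles))],
                            float(rng.uniform(0, 120)),
                            eq,
                            float(rng.uniform(0, 60)) if eq != "none" else 0.0,
                            idx=1 if phase == "session" else 0,
                        )
                    )
            events = pd.DataFrame(recs)
            got = rtm.cost_breakdowns(events, arms, uc).set_index("patient_id")
            # independent oracle: loop every event, accumulate per phase
            expected_total = {pid: 0.0 for pid in arms.index}
            for rec in recs:
                arm = arms[rec["patient_id"]]
                cost = rec["personnel_minutes"] / 60 * wage_rate[rec["role"]]
                if rec["equipment"] == "accelerator":
                    spec = uc.equipment[f"accelerator_{arm}"]
                    rate = (
                        spec.purchase_price / spec.lifespan_years
                        + spec.annual_maintenance
                        + qc_im_annual_cost(uc, arm)
                    ) / spec.annual_operating_hours
                    cost += rec["equipment_minutes"] / 60 * rate
                elif rec["equipment"] == "tps" and arm == "VMAT":
                    spec = uc.equipment["TPS_VMAT"]
                    rate = (
                        spec.purchase_price / spec.lifespan_years
                        + spec.annual_maintenance
                    ) / spec.annual_operating_hours
                    cost += rec["equipment_minutes"] / 60 * rate
                expected_total[rec["patient_id"]] += cost
            for pid in arms.index:
                assert got.loc[pid, "total_cost"] == pytest.approx(
                    expected_total[pid], abs=1e-9
                )


minutes = st.floats(min_value=0.0, max_value=500.0, allow_nan=False)

#: machine occupancy allowed per phase (the component table has no other cells)
_ALLOWED_EQUIPMENT = {
    "image_registration_contouring": ("none", "tps"),
    "inverse_planning": ("none", "tps"),
    "patient_qc": ("none",),
    "setup_verification_d0": ("none", "accelerator"),
    "session": ("none", "accelerator"),
}


def _valid_event_tuples():
    def build(phase):
        return st.tuples(
            st.just(phase),
            st.sampled_from(["radiation_therapist", "dosimetrist"]),
            minutes,
            st.sampled_from(_ALLOWED_EQUIPMENT[phase]),
            minutes,
        )

    return st.sampled_from(list(_ALLOWED_EQUIPMENT)).flatmap(build)


class TestCostingProperties:
    @given(
        data=st.lists(_valid_event_tuples(), min_size=1, max_size=12),
        arm=st.sampled_from(["VMAT", "HT"]),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_accounting_identity_and_homogeneity(self, data, arm):
        """total = planning + session; scaling all unit costs by k scales costs by k."""
        uc = toy_unit_costs()
        events = pd.DataFrame(
            [
                _event("P1", ph, role, per, eq, eqm, idx=1 if ph == "session" else 0)
                for ph, role, per, eq, eqm in data
            ]
        )
        bd = rtm.patient_cost_breakdown(events, uc, arm)
        assert bd.total_cost == pytest.approx(
            bd.planning_cost + bd.session_cost, abs=1e-9
        )
        assert bd.planning_cost == pytest.approx(
            sum(bd.components[c] for c in COMPONENTS[:7]), abs=1e-9
        )
        k = 3.0
        scaled = toy_unit_costs()
        for role, w in scaled.role_wages.items():
            scaled.role_wages[role] = RoleWage(
                w.annual_full_gross_wage * k, w.workable_hours
            )
        for key, s in scaled.equipment.items():
            scaled.equipment[key] = EquipmentSpec(
                s.purchase_price * k,
                s.lifespan_years,
                s.annual_maintenance * k,
                s.annual_operating_hours,
            )
        bd_k = rtm.patient_cost_breakdown(events, scaled, arm)
        assert bd_k.total_cost == pytest.approx(k * bd.total_cost, rel=1e-9)

    def test_adding_events_never_decreases_components(self, rng):
        uc = toy_unit_costs()
        base = [
            _event("P1", "session", "radiation_therapist", 30.0, "accelerator", 20.0, 1)
        ]
        bd0 = rtm.patient_cost_breakdown(pd.DataFrame(base), uc, "VMAT")
        extra = base + [
            _event("P1", "inverse_planning", "dosimetrist", 15.0, "tps", 10.0)
        ]
        bd1 = rtm.patient_cost_breakdown(pd.DataFrame(extra), uc, "VMAT")
        for c in COMPONENTS:
            assert bd1.components[c] >= bd0.components[c] - 1e-12


class TestSummaries:
    def test_unit_weights_reduce_to_plain_moments(self, study_breakdowns):
        summary = rtm.summarize_costs(study_breakdowns)
        vmat_total = summary[
            (summary["arm"] == "VMAT") & (summary["component"] == "total_cost")
        ].iloc[0]
        sub = study_breakdowns[study_breakdowns["arm"] == "VMAT"]["total_cost"]
        assert vmat_total["mean"] == pytest.approx(sub.mean())
        assert vmat_total["sd"] == pytest.approx(sub.std(ddof=1))

    def test_derived_rows_are_sums_of_component_means(self, study_breakdowns, study_weights):
        w = study_weights.reindex(study_breakdowns["patient_id"]).to_numpy()
        summary = rtm.summarize_costs(study_breakdowns, w).set_index(
            ["arm", "component"]
        )["mean"]
        for arm in ("VMAT", "HT"):
            assert summary[(arm, "total_cost")] == pytest.approx(
                summary[(arm, "planning_cost")] + summary[(arm, "session_cost")]
            )
            assert summary[(arm, "planning_cost")] == pytest.approx(
                sum(summary[(arm, c)] for c in COMPONENTS[:7])
            )

    def test_duplicating_patients_leaves_summary_unchanged(self, study_breakdowns):
        doubled = pd.concat([study_breakdowns, study_breakdowns], ignore_index=True)
        a = rtm.summarize_costs(study_breakdowns)
        b = rtm.summarize_costs(doubled)
        assert np.allclose(a["mean"], b["mean"])

    def test_weight_length_mismatch_rejected(self, study_breakdowns):
        with pytest.raises(CostingError):
            rtm.summarize_costs(study_breakdowns, np.ones(3))
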