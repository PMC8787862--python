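"""Configuration objects for the synthetic cohort generator.

The generator emulates a two-arm observational radiotherapy cohort
(VMAT vs helical tomotherapy, HT) with confounded treatment assignment,
per-patient resource-use logs covering every planning phase and every
treatment session, and ordinal CTCAE-style toxicity outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import yaml

ARMS = ("VMAT", "HT")
PLANS = ("SIB", "sequential")
#: fractions delivered per plan type: simultaneous integrated boost vs
#: sequential (pelvic volume then prostate boost)
FRACTIONS = {"SIB": 34, "sequential": 40}

CT_LEVELS = ("cT1", "cT2", "cT3", "cT4")
ENDPOINTS = ("GI", "GU", "sexual")
WINDOWS = ("acute", "late")

#: planning phases preceding treatment delivery, in workflow order
PLANNING_PHASES = (
    "image_registration_contouring",
    "inverse_planning",
    "patient_qc",
    "setup_verification_d0",
)
SESSION_PHASE = "session"

ROLES = (
    "radiation_therapist",
    "dosimetrist",
    "medical_physicist",
    "radiation_oncologist",
    "resident",
    "biomedical_technician",
)

#: which role performs each planning phase in the generated logs
PHASE_ROLE = {
    "image_registration_contouring": "radiation_oncologist",
    "inverse_planning": "dosimetrist",
    "patient_qc": "medical_physicist",
    "setup_verification_d0": "radiation_therapist",
    SESSION_PHASE: "radiation_therapist",
}


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ConfigError(f"{name} must lie in [0, 1], got {p}")


@dataclass
class CovariateModel:
    """Arm-agnostic baseline covariate distributions.

    Age is normal, PSA is log-normal capped at ``psa_cap`` (ng/ml),
    performance status collapses ECOG 1-2 into one level, cT has four
    levels and cN is binary.
    """

    age_mean: float = 68.6
    age_sd: float = 7.6
    p_performance_1_2: float = 0.155
    ct_probs: Sequence[float] = (0.148, 0.290, 0.530, 0.032)
    p_cn1: float = 0.135
    psa_log_mean: float = float(np.log(12.5))
    psa_log_sd: float = 0.72
    psa_cap: float = 100.0

    def validate(self) -> None:
        _check_prob("p_performance_1_2", self.p_performance_1_2)
        _check_prob("p_cn1", self.p_cn1)
        if len(self.ct_probs) != len(CT_LEVELS):
            raise ConfigError("ct_probs must have one entry per cT level")
        for p in self.ct_probs:
            _check_prob("ct_probs entry", p)
        if abs(sum(self.ct_probs) - 1.0) > 1e-9:
            raise ConfigError("ct_probs must sum to 1")
        if self.age_sd < 0 or self.psa_log_sd < 0:
            raise ConfigError("scale parameters must be non-negative")
        if self.psa_cap <= 0:
            raise ConfigError("psa_cap must be positive")


@dataclass
class AssignmentModel:
    """Log-odds of receiving HT given baseline covariates.

    Age and PSA enter centred at ``age_center``/``psa_center``; cT enters
    as indicator contrasts against cT1.
    """

    intercept: float = -0.85
    age: float = 0.035
    performance: float = 0.6
    ct2: float = -0.55
    ct3: float = 0.05
    ct4: float = 0.9
    cn1: float = 1.0
    psa: float = 0.018
    age_center: float = 69.0
    psa_center: float = 16.0

    def linear_predictor(
        self,
        age: np.ndarray,
        performance: np.ndarray,
        ct_level: np.ndarray,
        cn1: np.ndarray,
        psa: np.ndarray,
    ) -> np.ndarray:
        ct_coefs = np.array([0.0, self.ct2, self.ct3, self.ct4])
        return (
            self.intercept
            + self.age * (age - self.age_center)
            + self.performance * performance
            + ct_coefs[ct_level]
            + self.cn1 * cn1
            + self.psa * (psa - self.psa_center)
        )


@dataclass
class ToxicityEndpointModel:
    """Proportional-odds model for one endpoint x window.

    ``cutpoints`` are the three ordered cumulative-logit thresholds of the
    reference (HT) arm; ``log_or_vmat`` shifts the latent scale so that a
    positive value gives VMAT higher odds of a worse grade:
    P(grade <= k | arm) = expit(c_k - log_or_vmat * 1[arm == VMAT]).
    """

    cutpoints: Sequence[float]
    log_or_vmat: float = 0.0

    def validate(self) -> None:
        c = np.asarray(self.cutpoints, dtype=float)
        if c.shape != (3,):
            raise ConfigError("each endpoint needs exactly 3 cutpoints")
        if not np.all(np.diff(c) > 0):
            raise ConfigError(f"cutpoints must be strictly increasing, got {list(c)}")


@dataclass
class ToxicityModel:
    """All endpoint x window grade models plus follow-up availability."""

    endpoints: Mapping[tuple, ToxicityEndpointModel] = field(default_factory=dict)
    p_followup_vmat: float = 98.0 / 106.0
    p_followup_ht: float = 1.0

    def validate(self) -> None:
        _check_prob("p_followup_vmat", self.p_followup_vmat)
        _check_prob("p_followup_ht", self.p_followup_ht)
        for key, m in self.endpoints.items():
            ep, window = key
            if ep not in ENDPOINTS or window not in WINDOWS:
                raise ConfigError(f"unknown toxicity endpoint/window {key}")
            m.validate()


@dataclass
class PhaseTiming:
    """Truncated-normal personnel minutes for one planning phase."""

    mean_minutes: float
    sd_minutes: float
    #: pre-truncation location solved so the truncated mean equals
    #: ``mean_minutes`` (see rtmicrocost.defaults._solve_truncnorm_loc)
    loc_minutes: float | None = None

    def validate(self) -> None:
        if self.mean_minutes <= 0 or self.sd_minutes < 0:
            raise ConfigError("phase timings must be positive")


@dataclass
class TimingModel:
    """Session and planning-time model.

    Session machine minutes are log-normal around stratum medians
    (strata {1}, {2-3}, {>=4} capture the learning curve), multiplied by a
    per-patient log-normal factor; personnel minutes per session are a
    fixed arm-specific multiple of machine minutes.
    """

    session_median_minutes: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {"VMAT": (20.0, 15.0, 13.0), "HT": (18.0, 18.0, 17.0)}
    )
    session_sigma: float = 0.15
    session_patient_sigma: float = 0.18
    session_labor_factor: Mapping[str, float] = field(
        default_factory=lambda: {"VMAT": 2.0, "HT": 1.8}
    )
    #: per-arm truncated-normal accelerator minutes at setup verification D0
    setup_d0_machine: Mapping[str, PhaseTiming] = field(default_factory=dict)
    #: (phase, arm) -> PhaseTiming for personnel minutes
    planning_labor: Mapping[tuple, PhaseTiming] = field(default_factory=dict)
    #: phase -> PhaseTiming for VMAT TPS occupancy minutes
    tps_minutes: Mapping[str, PhaseTiming] = field(default_factory=dict)

    def validate(self) -> None:
        for arm in ARMS:
            med = self.session_median_minutes.get(arm)
            if med is None or len(med) != 3:
                raise ConfigError(f"need 3 session-median strata for {arm}")
            if any(m <= 0 for m in med):
                raise ConfigError("session medians must be strictly positive")
            if self.session_labor_factor.get(arm, 0) <= 0:
                raise ConfigError("session labor factor must be positive")
        if self.session_sigma < 0 or self.session_patient_sigma < 0:
            raise ConfigError("session noise scales must be non-negative")
        for t in self.planning_labor.values():
            t.validate()
        for t in self.tps_minutes.values():
            t.validate()
        for t in self.setup_d0_machine.values():
            t.validate()

    def stratum(self, session_index: int) -> int:
        if session_index < 1:
            raise ConfigError("session_index must be >= 1")
        return 0 if session_index == 1 else (1 if session_index <= 3 else 2)


@dataclass
class CohortConfig:
    """Everything needed to generate one synthetic cohort."""

    n_vmat: int = 106
    n_ht: int = 49
    plan_mix: float = 0.25  # probability of a sequential (40-fraction) plan
    covariates: CovariateModel = field(default_factory=CovariateModel)
    assignment: AssignmentModel = field(default_factory=AssignmentModel)
    toxicity: ToxicityModel = field(default_factory=ToxicityModel)
    timing: TimingModel = field(default_factory=TimingModel)
    seed: int | None = None

    def validate(self) -> None:
        if self.n_vmat <= 0 or self.n_ht <= 0:
            raise ConfigError("arm sizes must be positive")
        _check_prob("plan_mix", self.plan_mix)
        self.covariates.validate()
        self.toxicity.validate()
        self.timing.validate()

    # -- round-trip to a structured configuration file ------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["toxicity"]["endpoints"] = {
            f"{ep}:{w}": asdict(m) for (ep, w), m in self.toxicity.endpoints.items()
        }
        d["timing"]["planning_labor"] = {
            f"{phase}:{arm}": asdict(t)
            for (phase, arm), t in self.timing.planning_labor.items()
        }
        d["timing"]["tps_minutes"] = {
            phase: asdict(t) for phase, t in self.timing.tps_minutes.items()
        }
        d["timing"]["setup_d0_machine"] = {
            arm: asdict(t) for arm, t in self.timing.setup_d0_machine.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        cov = CovariateModel(**d.pop("covariates", {}))
        assign = AssignmentModel(**d.pop("assignment", {}))
        tox_d = dict(d.pop("toxicity", {}))
        endpoints = {
            tuple(key.split(":")): ToxicityEndpointModel(**m)
            for key, m in tox_d.pop("endpoints", {}).items()
        }
        tox = ToxicityModel(endpoints=endpoints, **tox_d)
        tim_d = dict(d.pop("timing", {}))
        planning = {
            tuple(key.split(":")): PhaseTiming(**t)
            for key, t in tim_d.pop("planning_labor", {}).items()
        }
        tps = {k: PhaseTiming(**t) for k, t in tim_d.pop("tps_minutes", {}).items()}
        setup = {
            k: PhaseTiming(**t) for k, t in tim_d.pop("setup_d0_machine", {}).items()
        }
        tim = TimingModel(
            planning_labor=planning, tps_minutes=tps, setup_d0_machine=setup, **tim_d
        )
        known = {"n_vmat", "n_ht", "plan_mix", "seed"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown CohortConfig keys: {sorted(unknown)}")
        return cls(covariates=cov, assignment=assign, toxicity=tox, timing=tim, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
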