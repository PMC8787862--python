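"""Treatment-effect models for cost and ordinal toxicity.

Both outcome models adjust for plan type (sequential vs SIB) and are run
unweighted and under stabilized IPTW:

* total cost: weighted least squares; the arm coefficient is the adjusted
  HT - VMAT cost difference in euros;
* collapsed toxicity grade (0 < 1 < 2 < 3-4): weighted proportional-odds
  (cumulative logit) maximum likelihood, parameterized so a positive arm
  coefficient means higher odds of a worse grade for VMAT.

Because the weights are estimated, both models report robust (sandwich)
standard errors; p-values are two-sided Wald tests.

The weighted proportional-odds likelihood is maximized directly (analytic
score, BFGS) since frequency weights are required; the unit-weight case
coincides with an ordinary cumulative-logit fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm
from statsmodels.tools.numdiff import approx_hess1

from .config import WINDOWS

#: collapsed grade labels in model order
GRADE_LABELS = ("0", "1", "2", "3-4")


class OutcomeError(RuntimeError):
    """Raised for degenerate outcome-model inputs or failed fits."""


@dataclass
class EffectEstimate:
    """Arm effect from one outcome model."""

    outcome: str
    model: str  # "linear" or "ordinal"
    coef: float  # EUR difference (linear) or log-odds (ordinal), HT ref for
    # cost, VMAT-worse-positive for toxicity
    se: float
    p_value: float
    weighting: str  # "unweighted" or "IPTW"
    n: int


# ---------------------------------------------------------------------------
# grade collapsing


def collapse_grades(events, endpoint: str, window: str) -> int:
    """Worst collapsed grade of one patient's events within a follow-up window.

    Acute: events at <= 3 months; late: events at 6 to 24 months.  A patient
    with no in-window events has grade 0 (no toxicity).  Order-independent
    and idempotent over the event list.
    """
    if window not in WINDOWS:
        raise OutcomeError(f"unknown window {window!r}")
    lo, hi = (0.0, 3.0) if window == "acute" else (6.0, 24.0)
    worst = 0
    for ev in events:
        ep, grade, months = ev["endpoint"], int(ev["grade"]), float(ev["months"])
        if ep == endpoint and lo <= months <= hi:
            worst = max(worst, grade)
    return worst


def grade_table(
    toxicity: pd.DataFrame, patients: pd.DataFrame, endpoint: str, window: str
) -> pd.Series:
    """Collapsed grade per followed patient (index: patient_id).

    Patients without toxicity follow-up are excluded; followed patients
    with no in-window events get grade 0.
    """
    if window not in WINDOWS:
        raise OutcomeError(f"unknown window {window!r}")
    lo, hi = (0.0, 3.0) if window == "acute" else (6.0, 24.0)
    followed = patients.loc[patients["toxicity_observed"], "patient_id"]
    sub = toxicity[
        (toxicity["endpoint"] == endpoint)
        & (toxicity["months"] >= lo)
        & (toxicity["months"] <= hi)
    ]
    worst = sub.groupby("patient_id")["grade"].max()
    out = worst.reindex(followed, fill_value=0).astype(int)
    out.index.name = "patient_id"
    return out


# ---------------------------------------------------------------------------
# weighted proportional-odds model


def _cutpoints(theta, n_beta, n_cat):
    """Monotone cutpoints from the unconstrained parameterization."""
    c1 = theta[n_beta]
    steps = np.exp(theta[n_beta + 1 : n_beta + n_cat - 1])
    return np.concatenate([[c1], c1 + np.cumsum(steps)])


def _po_probs_and_score(theta, y, x, n_cat):
    """Per-observation log-likelihood and score of the cumulative-logit model."""
    n, p = x.shape
    cuts = _cutpoints(theta, p, n_cat)
    eta = x @ theta[:p]
    upper = np.concatenate([cuts, [np.inf]])[y] - eta
    lower = np.concatenate([[-np.inf], cuts])[y] - eta
    fu, fl = expit(upper), expit(lower)
    prob = np.clip(fu - fl, 1e-300, None)
    du = np.where(np.isfinite(upper), fu * (1 - fu), 0.0)  # logistic density
    dl = np.where(np.isfinite(lower), fl * (1 - fl), 0.0)
    loglik = np.log(prob)

    # score wrt beta: d loglik / d eta * x
    g_eta = -(du - dl) / prob
    score = np.empty((n, len(theta)))
    score[:, :p] = g_eta[:, None] * x
    # score wrt raw cutpoints: +density/prob at the upper cut, -density/prob
    # at the lower cut
    g_cut = np.zeros((n, n_cat - 1))
    has_upper = y < n_cat - 1
    g_cut[np.arange(n)[has_upper], y[has_upper]] += (du / prob)[has_upper]
    has_lower = y > 0
    g_cut[np.arange(n)[has_lower], y[has_lower] - 1] -= (dl / prob)[has_lower]
    # chain rule to (c1, log-steps)
    score[:, p] = g_cut.sum(axis=1)
    steps = np.exp(theta[p + 1 :])
    for j in range(1, n_cat - 1):
        score[:, p + j] = g_cut[:, j:].sum(axis=1) * steps[j - 1]
    return loglik, score


class OrdinalToxicityModel:
    """Weighted cumulative-logit model of collapsed grade on arm + plan.

    ``grades`` are ints in 0..3; ``arms``/``plans`` are label arrays; the
    design is [VMAT indicator, sequential indicator] so the arm coefficient
    is the log cumulative odds ratio of a worse grade for VMAT vs HT.
    """

    def __init__(self, grades, arms, plans=None, weights=None):
        grades = np.asarray(grades, dtype=int)
        cats = np.unique(grades)
        if len(cats) < 2:
            raise OutcomeError("all grades identical; ordinal model undefined")
        if grades.min() < 0 or grades.max() > 3:
            raise OutcomeError("grades must be in 0..3")
        # re-index observed categories consecutively (absent top categories
        # contribute no cutpoints)
        self._cat_map = {c: i for i, c in enumerate(cats)}
        self.y = np.array([self._cat_map[g] for g in grades])
        self.n_cat = len(cats)
        cols = [np.asarray(arms) == "VMAT"]
        names = ["arm_vmat"]
        if plans is not None and len(np.unique(plans)) > 1:
            cols.append(np.asarray(plans) == "sequential")
            names.append("plan_sequential")
        self.x = np.column_stack(cols).astype(float)
        self.names = names
        self.w = (
            np.ones(len(grades)) if weights is None else np.asarray(weights, float)
        )
        if np.any(self.w <= 0):
            raise OutcomeError("weights must be strictly positive")

    def _aggregate(self):
        """Collapse to unique (y, x) patterns; exact for the weighted MLE."""
        key = np.column_stack([self.y, self.x])
        uniq, inv = np.unique(key, axis=0, return_inverse=True)
        w = np.bincount(inv, weights=self.w)
        w2 = np.bincount(inv, weights=self.w**2)
        y = uniq[:, 0].astype(int)
        x = uniq[:, 1:]
        return y, x, w, w2

    def fit(self) -> "OrdinalResults":
        y, x, w, w2 = self._aggregate()
        p = x.shape[1]
        marg = np.bincount(y, weights=w, minlength=self.n_cat)
        cum = np.clip(np.cumsum(marg)[:-1] / marg.sum(), 0.01, 0.99)
        c0 = np.log(cum / (1 - cum))
        theta0 = np.concatenate(
            [np.zeros(p), [c0[0]], np.log(np.clip(np.diff(c0), 1e-3, None))]
        )

        def nll(theta):
            ll, _ = _po_probs_and_score(theta, y, x, self.n_cat)
            return -np.sum(w * ll)

        def grad(theta):
            _, s = _po_probs_and_score(theta, y, x, self.n_cat)
            return -(w[:, None] * s).sum(axis=0)

        res = minimize(nll, theta0, jac=grad, method="BFGS",
                       options={"maxiter": 500, "gtol": 1e-7})
        if not res.success and np.linalg.norm(grad(res.x)) > 1e-4 * max(1, w.sum()):
            raise OutcomeError(f"ordinal fit did not converge: {res.message}")
        theta = res.x
        # sandwich covariance: bread = Hessian of the weighted NLL, meat
        # accumulates squared per-pattern scores with squared weights
        a = approx_hess1(theta, nll)
        _, s = _po_probs_and_score(theta, y, x, self.n_cat)
        b = (s * w2[:, None]).T @ s
        try:
            a_inv = np.linalg.inv(a)
        except np.linalg.LinAlgError as err:
            raise OutcomeError("singular Hessian in ordinal fit") from err
        cov = a_inv @ b @ a_inv
        return OrdinalResults(self, theta, cov)


class OrdinalResults:
    def __init__(self, model: OrdinalToxicityModel, theta, cov):
        self.model = model
        p = model.x.shape[1]
        self.params = pd.Series(theta[:p], index=model.names)
        self.bse = pd.Series(np.sqrt(np.diag(cov)[:p]), index=model.names)
        self.cutpoints = _cutpoints(theta, p, model.n_cat)
        z = self.params / self.bse
        self.pvalues = pd.Series(
            2 * norm.sf(np.abs(z.to_numpy())), index=model.names
        )

    def effect_estimate(self, outcome: str, weighting: str) -> EffectEstimate:
        return EffectEstimate(
            outcome=outcome,
            model="ordinal",
            coef=float(self.params["arm_vmat"]),
            se=float(self.bse["arm_vmat"]),
            p_value=max(float(self.pvalues["arm_vmat"]), np.finfo(float).tiny),
            weighting=weighting,
            n=len(self.model.y),
        )

    def summary(self) -> str:
        tab = pd.DataFrame(
            {"coef": self.params, "se": self.bse, "p": self.pvalues}
        )
        return (
            "Proportional-odds model (positive coef = worse grades for VMAT)\n"
            + tab.round(4).to_string()
            + f"\ncutpoints: {np.round(self.cutpoints, 4)}"
        )


def weighted_ordinal_model(
    grades, arms, plans=None, weights=None, outcome: str = "toxicity"
) -> EffectEstimate:
    """Fit the weighted proportional-odds model and return the arm effect."""
    weighting = "unweighted" if weights is None else "IPTW"
    res = OrdinalToxicityModel(grades, arms, plans, weights).fit()
    return res.effect_estimate(outcome, weighting)


# ---------------------------------------------------------------------------
# weighted linear cost model


class CostEffectModel:
    """Weighted least squares of total cost on arm + plan.

    Design: intercept, HT indicator, sequential indicator; the HT
    coefficient is the adjusted HT - VMAT cost difference in euros.
    Robust (HC1) standard errors.
    """

    def __init__(self, total_costs, arms, plans=None, weights=None):
        y = np.asarray(total_costs, dtype=float)
        if not np.all(np.isfinite(y)):
            raise OutcomeError("total costs must be finite")
        cols = {"const": np.ones(len(y)), "arm_ht": (np.asarray(arms) == "HT").astype(float)}
        if plans is not None and len(np.unique(plans)) > 1:
            cols["plan_sequential"] = (np.asarray(plans) == "sequential").astype(float)
        x = pd.DataFrame(cols)
        if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
            raise OutcomeError("collinear design in the cost model")
        self.y, self.x = y, x
        self.w = np.ones(len(y)) if weights is None else np.asarray(weights, float)

    def fit(self):
        return sm.WLS(self.y, self.x, weights=self.w).fit(cov_type="HC1")


def weighted_linear_model(
    total_costs, arms, plans=None, weights=None, outcome: str = "total_cost"
) -> EffectEstimate:
    """Fit the weighted linear cost model and return the arm effect."""
    weighting = "unweighted" if weights is None else "IPTW"
    res = CostEffectModel(total_costs, arms, plans, weights).fit()
    return EffectEstimate(
        outcome=outcome,
        model="linear",
        coef=float(res.params["arm_ht"]),
        se=float(res.bse["arm_ht"]),
        p_value=max(float(res.pvalues["arm_ht"]), np.finfo(float).tiny),
        weighting=weighting,
        n=len(total_costs),
    )


def plan_cost_contrast(total_costs, plans, weights=None) -> dict:
    """Weighted mean total cost for sequential vs SIB plans in one arm."""
    y = np.asarray(total_costs, dtype=float)
    plans = np.asarray(plans)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, float)
    out = {}
    for plan in ("sequential", "SIB"):
        mask = plans == plan
        if not mask.any():
            raise OutcomeError(f"no {plan} patients in this arm")
        out[f"mean_{plan}"] = float(np.sum(w[mask] * y[mask]) / w[mask].sum())
    out["difference"] = out["mean_sequential"] - out["mean_SIB"]
    return out


def grade_distribution(
    grades, arms, weights=None
) -> pd.DataFrame:
    """Percentage of each collapsed grade per arm (weighted if given)."""
    grades = np.asarray(grades, dtype=int)
    arms = np.asarray(arms)
    w = np.ones(len(grades)) if weights is None else np.asarray(weights, float)
    rows = []
    for arm in ("VMAT", "HT"):
        mask = arms == arm
        sw = w[mask].sum()
        for g in range(4):
            pct = 100.0 * np.sum(w[mask] * (grades[mask] == g)) / sw if sw else np.nan
            rows.append({"arm": arm, "grade": GRADE_LABELS[g], "percent": pct})
    return pd.DataFrame(rows)
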