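"""Propensity scores, stabilized IPTW weights and balance diagnostics.

The propensity score PS = P(HT | covariates) is estimated by maximum
likelihood logistic regression of the HT indicator on the five baseline
covariates (age, performance status, cT-stage contrasts against cT1, cN,
capped PSA).  Each patient is weighted by the inverse probability of the
treatment actually received (1/PS in HT, 1/(1-PS) in VMAT), stabilized by
the marginal arm probability so the pseudo-population keeps the original
sample size.

Balance is assessed with standardized differences d (sign convention:
HT minus VMAT).  Continuous and binary covariates use the usual pooled
formulas; categorical covariates with more than two levels use the
generalized Mahalanobis form over the L-1 level-proportion contrasts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .config import ARMS, CT_LEVELS


class WeightingError(RuntimeError):
    """Raised for unusable propensity scores or degenerate balance inputs."""


DEFAULT_COVARIATES = ("age", "performance_status", "c_t_stage", "c_n_stage", "psa")

COVARIATE_KINDS = {
    "age": "continuous",
    "performance_status": "binary",
    "c_t_stage": "multilevel",
    "c_n_stage": "binary",
    "psa": "continuous",
}


def _design_matrix(cohort: pd.DataFrame, covariates) -> pd.DataFrame:
    """Fixed design: intercept, age, PS 1-2, cT2..cT4 (vs cT1), cN1, PSA."""
    cols = {"const": np.ones(len(cohort))}
    for cov in covariates:
        if cov == "age":
            cols["age"] = cohort["age"].to_numpy(dtype=float)
        elif cov == "performance_status":
            cols["performance_1_2"] = (
                cohort["performance_status"].astype(str) == "1-2"
            ).astype(float)
        elif cov == "c_t_stage":
            for level in CT_LEVELS[1:]:
                cols[level] = (cohort["c_t_stage"] == level).astype(float)
        elif cov == "c_n_stage":
            cols["cn1"] = (cohort["c_n_stage"] == "cN1").astype(float)
        elif cov == "psa":
            cols["psa"] = cohort["psa"].to_numpy(dtype=float)
        else:
            raise WeightingError(f"unknown covariate {cov!r}")
    return pd.DataFrame(cols, index=cohort.index)


class PropensityModel:
    """Logistic treatment-assignment model for a two-arm cohort.

    Parameters
    ----------
    cohort : patients DataFrame (cohort.PATIENT_COLUMNS schema)
    covariates : baseline covariates entering the linear predictor;
        defaults to the study's five-covariate adjustment set.
    """

    def __init__(self, cohort: pd.DataFrame, covariates=DEFAULT_COVARIATES):
        arms = cohort["arm"]
        if not set(arms.unique()) <= set(ARMS):
            raise WeightingError(f"arms must be among {ARMS}")
        counts = arms.value_counts()
        if any(counts.get(a, 0) < 2 for a in ARMS):
            raise WeightingError("need at least 2 patients per arm")
        if cohort[list(covariates)].isna().any().any():
            raise WeightingError("covariates must be complete for all patients")
        self.cohort = cohort
        self.covariates = tuple(covariates)
        self.exog = _design_matrix(cohort, covariates)
        self.endog = (arms == "HT").astype(float).to_numpy()

    def fit(self, maxiter: int = 100) -> "PropensityResults":
        model = sm.Logit(self.endog, self.exog)
        separation_seen = False
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                res = model.fit(disp=0, maxiter=maxiter)
            separation_seen = any(
                issubclass(w.category, PerfectSeparationWarning) for w in caught
            )
        except (PerfectSeparationError, np.linalg.LinAlgError) as err:
            raise WeightingError(
                "perfect separation in the propensity model; review the "
                "covariate set (a covariate fully predicts the arm)"
            ) from err
        converged = res.mle_retvals.get("converged", False)
        score_norm = float(np.max(np.abs(model.score(res.params))))
        if not converged and score_norm > 1e-6 * max(1.0, len(self.endog)):
            if separation_seen:
                raise WeightingError(
                    "perfect separation in the propensity model; review the "
                    "covariate set (a covariate fully predicts the arm)"
                )
            raise WeightingError(
                f"propensity model did not converge: {res.mle_retvals}"
            )
        ps = np.asarray(res.predict(self.exog))
        eps = 1e-8 if separation_seen else 1e-12
        if np.any((ps <= eps) | (ps >= 1 - eps)):
            raise WeightingError(
                "fitted propensity scores sit on the 0/1 boundary (perfect "
                "separation); review the covariate set"
            )
        return PropensityResults(self, res, ps)


class PropensityResults:
    """Fitted propensity scores, IPTW weights and balance diagnostics."""

    def __init__(self, model: PropensityModel, sm_results, propensity_scores):
        self.model = model
        self._sm_results = sm_results
        self.propensity_scores = propensity_scores
        arms = model.cohort["arm"].to_numpy()
        self.raw_weights, self.stabilized_weights = stabilized_weights(
            propensity_scores, arms, return_raw=True
        )

    @property
    def params(self) -> pd.Series:
        return self._sm_results.params

    @property
    def bse(self) -> pd.Series:
        return self._sm_results.bse

    def weights_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.model.cohort["patient_id"].to_numpy(),
                "propensity_score": self.propensity_scores,
                "raw_weight": self.raw_weights,
                "stabilized_weight": self.stabilized_weights,
            }
        )

    def balance_table(self) -> pd.DataFrame:
        return balance_table(self.model.cohort, self.stabilized_weights)

    def summary(self) -> str:
        bal = self.balance_table()
        lines = [
            "Propensity model (logit of HT assignment)",
            str(self._sm_results.summary2().tables[1].round(4)),
            "",
            f"Sum of stabilized weights: {self.stabilized_weights.sum():.2f} "
            f"(n = {len(self.stabilized_weights)})",
            "",
            "Covariate balance (standardized differences, HT - VMAT):",
            bal.to_string(index=False, float_format=lambda v: f"{v: .3f}"),
        ]
        return "\n".join(lines)


def stabilized_weights(ps, arms, return_raw: bool = False):
    """Stabilized IPTW weights from propensity scores and arm labels.

    HT: (n_HT/n) / PS; VMAT: (n_VMAT/n) / (1 - PS).  Raises if any PS sits
    on the boundary (no silent truncation).
    """
    ps = np.asarray(ps, dtype=float)
    arms = np.asarray(arms)
    if np.any((ps <= 0) | (ps >= 1)):
        raise WeightingError("propensity scores must lie strictly inside (0, 1)")
    is_ht = arms == "HT"
    p_ht = is_ht.mean()
    raw = np.where(is_ht, 1.0 / ps, 1.0 / (1.0 - ps))
    stab = np.where(is_ht, p_ht, 1.0 - p_ht) * raw
    return (raw, stab) if return_raw else stab


# ---------------------------------------------------------------------------
# standardized differences


def _weighted_mean_var(x, w):
    sw = w.sum()
    mean = np.sum(w * x) / sw
    # frequency-weighted variance: unit weights reduce to the ddof=1 sample
    # variance exactly
    var = np.sum(w * (x - mean) ** 2) / (sw - 1.0)
    return mean, var


def standardized_difference(values, arms, weights=None, kind="continuous") -> float:
    """Standardized difference d between HT and VMAT (HT minus VMAT).

    kind='continuous': difference in means over the pooled SD
    sqrt((SD_HT^2 + SD_VMAT^2)/2); 'binary': analogous with p(1-p)
    variances; 'multilevel': generalized Mahalanobis distance over the
    L-1 level-proportion contrasts with the averaged covariance matrix.
    Weighted variants replace all moments by their weighted counterparts.
    """
    values = np.asarray(values)
    arms = np.asarray(arms)
    w = np.ones(len(values)) if weights is None else np.asarray(weights, dtype=float)
    masks = {a: arms == a for a in ARMS}
    if kind == "continuous":
        stats = {
            a: _weighted_mean_var(values[masks[a]].astype(float), w[masks[a]])
            for a in ARMS
        }
        pooled = (stats["HT"][1] + stats["VMAT"][1]) / 2.0
        if pooled <= 0:
            raise WeightingError("zero pooled variance; d undefined")
        return float((stats["HT"][0] - stats["VMAT"][0]) / np.sqrt(pooled))
    if kind == "binary":
        x = values.astype(float) if values.dtype != object else None
        if x is None or set(np.unique(values)) - {0, 1, 0.0, 1.0, True, False}:
            levels = np.unique(values)
            if len(levels) != 2:
                raise WeightingError("binary covariate must have exactly 2 levels")
            x = (values == levels[1]).astype(float)
        p = {a: np.sum(w[masks[a]] * x[masks[a]]) / w[masks[a]].sum() for a in ARMS}
        pooled = (p["HT"] * (1 - p["HT"]) + p["VMAT"] * (1 - p["VMAT"])) / 2.0
        if pooled <= 0:
            raise WeightingError("zero pooled variance; d undefined")
        return float((p["HT"] - p["VMAT"]) / np.sqrt(pooled))
    if kind == "multilevel":
        levels = np.unique(values)
        if len(levels) < 3:
            raise WeightingError("multilevel d needs at least 3 levels")
        props = {}
        for a in ARMS:
            wa = w[masks[a]]
            props[a] = np.array(
                [np.sum(wa * (values[masks[a]] == lv)) / wa.sum() for lv in levels]
            )

        def cov(p):
            q = p[1:]  # drop the first level as reference
            return np.diag(q) - np.outer(q, q)

        t = (props["HT"] - props["VMAT"])[1:]
        s = (cov(props["HT"]) + cov(props["VMAT"])) / 2.0
        try:
            sol = np.linalg.solve(s, t)
        except np.linalg.LinAlgError as err:
            raise WeightingError("singular level-covariance matrix") from err
        return float(np.sqrt(t @ sol))
    raise WeightingError(f"unknown covariate kind {kind!r}")


def balance_table(
    cohort: pd.DataFrame, weights=None, covariates=DEFAULT_COVARIATES
) -> pd.DataFrame:
    """One row per covariate with unweighted and weighted d."""
    rows = []
    arms = cohort["arm"].to_numpy()
    for cov in covariates:
        kind = COVARIATE_KINDS[cov]
        values = cohort[cov].to_numpy()
        row = {
            "covariate": cov,
            "kind": kind,
            "unweighted_d": standardized_difference(values, arms, None, kind),
        }
        if weights is not None:
            row["weighted_d"] = standardized_difference(values, arms, weights, kind)
        rows.append(row)
    return pd.DataFrame(rows)
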