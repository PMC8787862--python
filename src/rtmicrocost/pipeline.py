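"""End-to-end pipeline: simulate -> cost -> weight -> analyze -> bootstrap -> tornado.

All stage outputs are plain CSV; a JSON manifest records the configuration
snapshot, seeds, stage row counts and a SHA-256 digest of every output
file, so a run can be audited and re-run byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .cohort import generate_cohort, write_cohort
from .config import ARMS, ENDPOINTS, WINDOWS, CohortConfig, ConfigError
from .costing import UnitCostTable, cost_breakdowns, summarize_costs
from .defaults import default_cohort_config, default_unit_costs
from .outcomes import (
    grade_distribution,
    grade_table,
    weighted_linear_model,
    weighted_ordinal_model,
)
from .uncertainty import (
    DEFAULT_TORNADO_PARAMETERS,
    BootstrapConfig,
    bootstrap_by_arm,
    one_way_sensitivity,
    tornado_export,
)
from .weighting import PropensityModel

logger = logging.getLogger("rtmicrocost")


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and cause."""


@dataclass
class PipelineConfig:
    """One structured configuration for the whole pipeline.

    ``cohort`` may be a CohortConfig (synthetic generation) or a mapping of
    CSV paths {"patients": ..., "resource_use": ..., "toxicity": ...} for
    user-supplied data.  Unknown keys in the file are errors.
    """

    cohort: CohortConfig | dict = field(default_factory=default_cohort_config)
    unit_costs: UnitCostTable = field(default_factory=default_unit_costs)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    sensitivity_delta: float = 0.20
    sensitivity_parameters: tuple = DEFAULT_TORNADO_PARAMETERS
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {
            "cohort",
            "unit_costs",
            "bootstrap",
            "sensitivity_delta",
            "sensitivity_parameters",
            "seed",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        kwargs = {}
        if "cohort" in raw:
            c = raw["cohort"]
            kwargs["cohort"] = (
                dict(c) if set(c) <= {"patients", "resource_use", "toxicity"}
                else CohortConfig.from_dict(c)
            )
        if "unit_costs" in raw:
            kwargs["unit_costs"] = UnitCostTable.from_dict(raw["unit_costs"])
        if "bootstrap" in raw:
            kwargs["bootstrap"] = BootstrapConfig(**raw["bootstrap"])
        for key in ("sensitivity_delta", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "sensitivity_parameters" in raw:
            kwargs["sensitivity_parameters"] = tuple(raw["sensitivity_parameters"])
        return cls(**kwargs)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as err:
                raise PipelineError(f"stage {name!r} failed: {err}") from err
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(
    config: PipelineConfig | str,
    out_dir: str,
    seed: int | None = None,
) -> dict:
    """Execute every stage and write all tables plus a manifest.

    Returns the manifest dict.  ``seed`` overrides the configured seed.
    """
    if isinstance(config, (str, os.PathLike)):
        config = PipelineConfig.from_yaml(config)
    os.makedirs(out_dir, exist_ok=True)
    seed = seed if seed is not None else config.seed
    outputs: dict[str, str] = {}
    counts: dict[str, int] = {}

    # -- simulate / load -------------------------------------------------
    @_stage("simulate")
    def load_cohort():
        if isinstance(config.cohort, CohortConfig):
            cc = config.cohort
            if seed is not None:
                cc = CohortConfig.from_dict({**cc.to_dict(), "seed": seed})
            patients, events, toxicity = generate_cohort(cc)
            paths = write_cohort(out_dir, patients, events, toxicity, cc)
            outputs.update(paths)
            return patients, events, toxicity
        paths = config.cohort
        patients = pd.read_csv(paths["patients"])
        events = pd.read_csv(paths["resource_use"])
        toxicity = pd.read_csv(paths["toxicity"])
        return patients, events, toxicity

    patients, events, toxicity = load_cohort()
    counts["patients"] = len(patients)
    counts["resource_use_events"] = len(events)

    # -- cost -------------------------------------------------------------
    @_stage("cost")
    def cost():
        arms = patients.set_index("patient_id")["arm"]
        bd = cost_breakdowns(events, arms, config.unit_costs)
        bd.to_csv(os.path.join(out_dir, "cost_breakdowns.csv"), index=False)
        outputs["cost_breakdowns"] = os.path.join(out_dir, "cost_breakdowns.csv")
        return bd

    breakdowns = cost()

    # -- weight -----------------------------------------------------------
    @_stage("weight")
    def weight():
        res = PropensityModel(patients).fit()
        wf = res.weights_frame()
        wf.to_csv(os.path.join(out_dir, "weights.csv"), index=False)
        bal = res.balance_table()
        bal.to_csv(os.path.join(out_dir, "balance.csv"), index=False)
        outputs["weights"] = os.path.join(out_dir, "weights.csv")
        outputs["balance"] = os.path.join(out_dir, "balance.csv")
        return res

    ps_results = weight()
    w = pd.Series(
        ps_results.stabilized_weights, index=patients["patient_id"].to_numpy()
    )

    # -- analyze ----------------------------------------------------------
    @_stage("analyze")
    def analyze():
        sw = w.reindex(breakdowns["patient_id"]).to_numpy()
        summary = summarize_costs(breakdowns, sw)
        summary.to_csv(os.path.join(out_dir, "cost_summary.csv"), index=False)
        outputs["cost_summary"] = os.path.join(out_dir, "cost_summary.csv")

        p_ix = patients.set_index("patient_id")
        effects = []
        for weighting, weights_arr in (("unweighted", None), ("IPTW", sw)):
            est = weighted_linear_model(
                breakdowns["total_cost"],
                p_ix.loc[breakdowns["patient_id"], "arm"],
                p_ix.loc[breakdowns["patient_id"], "plan"],
                weights_arr,
            )
            effects.append(est.__dict__)
        dist_rows = []
        for endpoint in ENDPOINTS:
            for window in WINDOWS:
                grades = grade_table(toxicity, patients, endpoint, window)
                sub = p_ix.loc[grades.index]
                tox_w = w.reindex(grades.index).to_numpy()
                for weighting, weights_arr in (("unweighted", None), ("IPTW", tox_w)):
                    est = weighted_ordinal_model(
                        grades.to_numpy(),
                        sub["arm"].to_numpy(),
                        sub["plan"].to_numpy(),
                        weights_arr,
                        outcome=f"{endpoint}_{window}",
                    )
                    effects.append(est.__dict__)
                    dist = grade_distribution(
                        grades.to_numpy(), sub["arm"].to_numpy(), weights_arr
                    )
                    dist["endpoint"] = endpoint
                    dist["window"] = window
                    dist["weighting"] = weighting
                    dist_rows.append(dist)
        pd.DataFrame(effects).to_csv(
            os.path.join(out_dir, "effects.csv"), index=False
        )
        outputs["effects"] = os.path.join(out_dir, "effects.csv")
        pd.concat(dist_rows, ignore_index=True).to_csv(
            os.path.join(out_dir, "toxicity_distributions.csv"), index=False
        )
        outputs["toxicity_distributions"] = os.path.join(
            out_dir, "toxicity_distributions.csv"
        )

    analyze()

    # -- bootstrap ---------------------------------------------------------
    @_stage("bootstrap")
    def bootstrap():
        cfg = config.bootstrap
        if seed is not None and cfg.seed is None:
            cfg = BootstrapConfig(cfg.iterations, cfg.ci_level, seed)
        sw = w.reindex(breakdowns["patient_id"]).to_numpy()
        boot = bootstrap_by_arm(breakdowns, sw, cfg)
        boot.to_csv(os.path.join(out_dir, "bootstrap.csv"), index=False)
        outputs["bootstrap"] = os.path.join(out_dir, "bootstrap.csv")

    bootstrap()

    # -- tornado -----------------------------------------------------------
    @_stage("tornado")
    def tornado():
        arms_map = patients.set_index("patient_id")["arm"]
        for arm in ARMS:
            pids = arms_map[arms_map == arm].index
            ev = events[events["patient_id"].isin(pids)]
            params = tuple(
                p for p in config.sensitivity_parameters
                if not (arm == "HT" and p == "tps_price")
            )
            rows = one_way_sensitivity(
                config.unit_costs,
                ev,
                arms_map[arms_map == arm],
                params,
                config.sensitivity_delta,
                w.reindex(pids).to_numpy(),
            )
            path = os.path.join(out_dir, f"tornado_{arm}.csv")
            tornado_export(rows).to_csv(path, index=False)
            outputs[f"tornado_{arm}"] = path

    tornado()

    # -- manifest ----------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": {
            "cohort": (
                config.cohort.to_dict()
                if isinstance(config.cohort, CohortConfig)
                else dict(config.cohort)
            ),
            "unit_costs": config.unit_costs.to_dict(),
            "bootstrap": config.bootstrap.__dict__,
            "sensitivity_delta": config.sensitivity_delta,
            "sensitivity_parameters": list(config.sensitivity_parameters),
        },
        "counts": counts,
        "outputs": {k: {"path": p, "sha256": _sha256(p)} for k, p in outputs.items()},
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def render_tables(out_dir: str) -> str:
    """Human-readable report assembled from the stage CSVs (no recomputation)."""
    def need(name):
        path = os.path.join(out_dir, name)
        if not os.path.exists(path):
            raise PipelineError(f"missing stage output {name!r}; run the pipeline first")
        return pd.read_csv(path)

    lines = ["rtmicrocost pipeline report", "=" * 60]

    bal = need("balance.csv")
    lines += ["", "Covariate balance (standardized differences, HT - VMAT)", "-" * 60]
    lines.append(bal.to_string(index=False, float_format=lambda v: f"{v: .3f}"))

    summary = need("cost_summary.csv")
    lines += ["", "Cost per patient (EUR, weighted mean (SD))", "-" * 60]
    wide = summary.pivot(index="component", columns="arm", values=["mean", "sd"])
    comp_order = [c for c in summary["component"].unique()]
    for comp in comp_order:
        cells = []
        for arm in ARMS:
            try:
                m = wide[("mean", arm)][comp]
                s = wide[("sd", arm)][comp]
                cells.append(f"{arm}: {m:10.2f} ({s:.2f})")
            except KeyError:
                cells.append(f"{arm}: absent")
        lines.append(f"{comp:28s} " + "  ".join(cells))

    boot = need("bootstrap.csv")
    lines += ["", "Bootstrap CIs of mean total cost", "-" * 60]
    for _, r in boot.iterrows():
        lines.append(
            f"{r['arm']:5s} mean {r['mean']:8.2f}  "
            f"{int(r['ci_level']*100)}% CI [{r['ci_low']:.2f}, {r['ci_high']:.2f}]"
        )

    tox = need("toxicity_distributions.csv")
    lines += ["", "Toxicity grade distributions (%)", "-" * 60]
    for (endpoint, window), sub in tox.groupby(["endpoint", "window"], sort=True):
        lines.append(f"{endpoint} {window}:")
        for weighting, wsub in sub.groupby("weighting", sort=True):
            piv = wsub.pivot(index="grade", columns="arm", values="percent")
            piv.index = piv.index.astype(str)
            piv = piv.reindex(["0", "1", "2", "3-4"])
            cells = "  ".join(
                f"{arm} " + "/".join(f"{piv[arm][g]:.1f}" for g in piv.index)
                for arm in ARMS
                if arm in piv
            )
            lines.append(f"  {weighting:10s} grades 0/1/2/3-4: {cells}")

    eff = need("effects.csv")
    lines += ["", "Treatment-effect estimates", "-" * 60]
    lines.append(
        eff.to_string(index=False, float_format=lambda v: f"{v: .4f}")
    )

    for arm in ARMS:
        path = os.path.join(out_dir, f"tornado_{arm}.csv")
        if os.path.exists(path):
            t = pd.read_csv(path)
            lines += ["", f"Tornado ({arm}), ranges in EUR", "-" * 60]
            for _, r in t.iterrows():
                lines.append(
                    f"{r['parameter']:34s} range {r['range']:9.2f} "
                    f"({r['pct_change_low']:+.1f}% / {r['pct_change_high']:+.1f}%)"
                )
        else:
            lines += ["", f"Tornado ({arm}): absent"]
    return "\n".join(lines)
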