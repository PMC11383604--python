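"""Cohort-level analysis: per-donor aggregation and ratio-paired testing.

Each donor contributes 1-3 transwell-insert measurements per condition.
Inserts are averaged first (arithmetic mean of Je0 and eta0 within
donor x condition), then conditions are compared with a ratio paired
Student's t test: a paired two-sided t test on the log-transformed
per-donor ratios, equivalently a test of whether the geometric-mean
ratio differs from 1.  No multiple-testing correction is applied;
comparisons are reported one at a time.

``run_experiment`` orchestrates the full synthetic study: simulate a
cohort, fit every trace, build the cohort table, run the planned
comparisons and write a report bundle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .burgers import ForceProtocol
from .fitting import analyze_trace
from .geometry import WireGeometry
from .io import write_trace_csv
from .simulate import Cohort, CohortSpec, simulate_cohort

__all__ = [
    "ComparisonResult",
    "aggregate_donor",
    "ratio_paired_ttest",
    "compare_conditions",
    "run_experiment",
]

#: Direction vocabulary for reporting: metric -> (ratio < 1, ratio > 1).
_DIRECTIONS = {
    "Je0": ("less compliant", "more compliant"),
    "eta0": ("less viscous", "more viscous"),
}


@dataclass
class ComparisonResult:
    """Ratio-paired t test of condition ``b`` against condition ``a``."""

    pair: Tuple[str, str]
    metric: str
    ratios: np.ndarray
    geometric_mean_ratio: float
    t: float
    df: int
    p: float
    direction: str
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "metric": self.metric,
            "ratios": [float(r) for r in self.ratios],
            "geometric_mean_ratio": self.geometric_mean_ratio,
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "direction": self.direction,
            "flags": list(self.flags),
        }


class MissingDataError(ValueError):
    """A donor lacks measurements for a required condition."""


def aggregate_donor(table: pd.DataFrame) -> pd.DataFrame:
    """Mean of the insert measurements within each (donor, condition).

    Expects columns donor, condition, insert, Je0, eta0 (and optionally
    classification / flags, whose worst case is propagated).  The order of
    operations matters: inserts are averaged before any ratio is formed.
    """
    required = {"donor", "condition", "Je0", "eta0"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns {sorted(missing)}")
    if table.empty:
        raise MissingDataError("cohort table is empty")

    def _agg(group: pd.DataFrame) -> pd.Series:
        out = {
            "Je0": group["Je0"].mean(),
            "eta0": group["eta0"].mean(),
            "n_inserts": len(group),
        }
        if "classification" in group:
            counts = group["classification"].value_counts()
            out["classification"] = counts.idxmax()
        if "flags" in group:
            flags = [f for fl in group["flags"] for f in (fl if isinstance(fl, list) else [])]
            out["flags"] = flags
        return pd.Series(out)

    agg = (
        table.groupby(["donor", "condition"], sort=True)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    return agg


def ratio_paired_ttest(a: Sequence[float], b: Sequence[float]) -> ComparisonResult:
    """Paired two-sided t test on log(b/a) across donors.

    t = mean(log(b/a)) / (sd(log(b/a)) / sqrt(n)) with n-1 degrees of
    freedom; the geometric-mean ratio is exp(mean log ratio).  Invariant
    to common rescaling of both vectors.  Degenerate zero-variance cases
    are flagged: p = 1 for identical vectors, p = 0 for an exact common
    ratio != 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D vectors")
    if a.size < 2:
        raise ValueError("need n >= 2 pairs")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("ratio-paired test requires strictly positive values")
    logr = np.log(b / a)
    n = logr.size
    m = float(np.mean(logr))
    s = float(np.std(logr, ddof=1))
    flags = []
    if s == 0.0:
        if m == 0.0:
            t, p = 0.0, 1.0
            flags.append("degenerate: identical paired values")
        else:
            t = math.inf if m > 0 else -math.inf
            p = 0.0
            flags.append("exact-ratio: zero variance with nonzero mean log-ratio")
    else:
        t = m / (s / math.sqrt(n))
        p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return ComparisonResult(
        pair=("a", "b"),
        metric="",
        ratios=np.exp(logr),
        geometric_mean_ratio=float(np.exp(m)),
        t=t,
        df=n - 1,
        p=p,
        direction="",
        flags=flags,
    )


def compare_conditions(
    table: pd.DataFrame,
    plan: Sequence[Tuple[str, str]],
    metrics: Sequence[str] = ("Je0", "eta0"),
) -> list[ComparisonResult]:
    """Run the planned ratio-paired comparisons on a cohort table.

    For each (reference, test) pair in ``plan`` and each metric, inserts
    are averaged per donor first and the log-ratio test is applied to the
    per-donor means.  Donors missing either condition are dropped with a
    flag on the result.
    """
    if not plan:
        raise ValueError("comparison plan is empty")
    agg = aggregate_donor(table)
    results = []
    for ref, test in plan:
        sub = agg[agg["condition"].isin([ref, test])]
        wide = sub.pivot(index="donor", columns="condition", values=list(metrics))
        for metric in metrics:
            cols = wide[metric] if isinstance(wide.columns, pd.MultiIndex) else wide
            if ref not in cols or test not in cols:
                raise MissingDataError(
                    f"conditions {ref!r}/{test!r} absent from the cohort table"
                )
            paired = cols[[ref, test]].dropna()
            dropped = sorted(set(cols.index) - set(paired.index))
            res = ratio_paired_ttest(paired[ref].to_numpy(), paired[test].to_numpy())
            res.pair = (ref, test)
            res.metric = metric
            lo, hi = _DIRECTIONS.get(metric, ("decreased", "increased"))
            res.direction = lo if res.geometric_mean_ratio < 1 else hi
            if dropped:
                res.flags.append(f"dropped donors without both conditions: {dropped}")
            results.append(res)
    return results


# ---------------------------------------------------------------------------
# Orchestration


DEFAULT_PLAN = [("control", "il13"), ("il13", "il13_dtt"), ("control", "il13_dtt")]


def fit_cohort(
    cohort: Cohort,
    geom: WireGeometry,
    n_starts: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit every trace of a simulated cohort; returns the cohort table.

    Rows carry the fitted Je0 / eta0 / recovery ratio / classification per
    (donor, condition, insert) plus the simulation ground truth.
    """
    drag = geom.drag
    rows = []
    for (donor, condition, insert), trace in sorted(cohort.traces.items()):
        # per-cycle QC refits are for single-trace inspection; cohort runs
        # keep only the pooled estimates for throughput
        fit = analyze_trace(trace, drag, n_starts=n_starts, seed=seed, per_cycle_qc=False)
        rows.append(
            {
                "donor": donor,
                "condition": condition,
                "insert": insert,
                "Je0": fit.Je0,
                "eta0": fit.eta0,
                "recovery_ratio": fit.recovery_ratio,
                "classification": fit.classification,
                "residual_norm": fit.residual_norm,
                "F0_N": fit.force_applied,
                "flags": fit.flags,
            }
        )
    return pd.DataFrame(rows)


def run_experiment(config: dict, seed: Optional[int] = None, out_dir=None) -> dict:
    """Full synthetic study: simulate -> fit -> compare -> report.

    ``config`` mirrors the YAML layout: optional sections ``simulation``
    (CohortSpec fields), ``geometry`` (radius_m/length_m/height_m),
    ``protocol`` (t_on/t_off/n_cycles/dt), ``fit`` (n_starts), and
    ``comparisons`` (list of [reference, test] pairs).  Validation happens
    before any computation.  Returns the report bundle as a dict; when
    ``out_dir`` is given, also writes cohort.csv, fits, comparisons.json,
    report.md and run_log.json.
    """
    unknown = set(config) - {"simulation", "geometry", "protocol", "fit", "comparisons", "output"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    geo_cfg = config.get("geometry", {})
    geom = WireGeometry(
        radius=float(geo_cfg.get("radius_m", 12.3e-6)),
        length=float(geo_cfg.get("length_m", 5.3e-3)),
        height=float(geo_cfg.get("height_m", 57e-6)),
    )
    sim_cfg = dict(config.get("simulation", {}))
    if seed is not None:
        sim_cfg["seed"] = int(seed)
    if "conditions" in sim_cfg:
        sim_cfg["conditions"] = tuple(sim_cfg["conditions"])
    for tup in ("il13_effect", "dtt_effect"):
        if tup in sim_cfg:
            sim_cfg[tup] = tuple(sim_cfg[tup])
    spec = CohortSpec(**sim_cfg)
    proto_cfg = config.get("protocol", {})
    protocol_template = ForceProtocol(
        F0=1.0,
        t_on=float(proto_cfg.get("t_on", 10.0)),
        t_off=float(proto_cfg.get("t_off", 20.0)),
        n_cycles=int(proto_cfg.get("n_cycles", 2)),
        dt=float(proto_cfg.get("dt", 0.5)),
    )
    plan = [tuple(p) for p in config.get("comparisons", DEFAULT_PLAN)]
    n_starts = int(config.get("fit", {}).get("n_starts", 8))

    cohort = simulate_cohort(spec, geom, protocol_template)
    table = fit_cohort(cohort, geom, n_starts=n_starts, seed=spec.seed)
    comparisons = compare_conditions(table, plan)
    agg = aggregate_donor(table)

    report = {
        "seed": spec.seed,
        "geometry": geom.to_dict(),
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in vars(spec).items()},
        "comparisons": [c.to_dict() for c in comparisons],
        "classification_by_condition": {
            cond: dict(agg[agg["condition"] == cond]["classification"].value_counts())
            for cond in spec.conditions
        },
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table_out = table.copy()
        table_out["flags"] = table_out["flags"].map(lambda f: ";".join(f))
        table_out.to_csv(out / "cohort.csv", index=False, float_format="%.9g")
        (out / "traces").mkdir(exist_ok=True)
        for (donor, condition, insert), trace in sorted(cohort.traces.items()):
            write_trace_csv(trace, out / "traces" / f"{donor}_{condition}_{insert}.csv")
        (out / "comparisons.json").write_text(
            json.dumps([c.to_dict() for c in comparisons], indent=2) + "\n"
        )
        (out / "run_log.json").write_text(json.dumps(report["spec"], indent=2) + "\n")
        (out / "report.md").write_text(_render_report(report, agg))
    report["cohort_table"] = table
    report["donor_means"] = agg
    return report


def _render_report(report: dict, agg: pd.DataFrame) -> str:
    lines = [
        "# Microwire rheometry synthetic study",
        "",
        f"Seed: {report['seed']}",
        "",
        "## Per-donor condition means",
        "",
        agg.to_string(index=False),
        "",
        "## Ratio-paired comparisons (no multiplicity correction applied)",
        "",
    ]
    for c in report["comparisons"]:
        lines.append(
            f"- {c['pair'][1]} vs {c['pair'][0]}, {c['metric']}: "
            f"geometric-mean ratio {c['geometric_mean_ratio']:.3g} "
            f"({c['direction']}), t = {c['t']:.3g}, df = {c['df']}, p = {c['p']:.3g}"
        )
    lines += ["", "## Classification by condition", ""]
    for cond, counts in report["classification_by_condition"].items():
        lines.append(f"- {cond}: " + ", ".join(f"{k}: {v}" for k, v in counts.items()))
    lines.append("")
    return "\n".join(lines)
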