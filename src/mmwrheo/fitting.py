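"""Creep-compliance inference: displacement -> compliance -> Burgers fit.

The chain mirrors the measurement logic of the microwire rheometer:

1. convert displacement to compliance, ``J(t) = C * x(t) / F0``;
2. segment the recorded force waveform into on/off windows;
3. fit the Burgers creep form to each force-on window, with times taken
   relative to that window's force onset;
4. summarize recovery during the off windows and classify the material as
   a viscoelastic liquid (partial recoil) or solid (near-complete recoil);
5. optionally check stress-sweep invariance of the fitted quantities
   across applied forces (linear viscoelastic regime).

Only the on phase is fitted; the off phase informs the recovery ratio and
the classification.  When several on/off cycles are present each cycle is
fitted separately and the per-cycle estimates are averaged; their spread
doubles as a quality-control metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .burgers import BurgersParams, ComplianceCurve, creep_compliance
from .io import DisplacementTrace

__all__ = [
    "Window",
    "FitResult",
    "FitError",
    "ProtocolError",
    "compliance_from_displacement",
    "curve_from_trace",
    "segment_protocol",
    "fit_burgers",
    "recovery_ratio",
    "classify_gel",
    "stress_sweep_linearity",
    "StressSweepResult",
    "analyze_trace",
]

LIQUID = "viscoelastic_liquid"
SOLID = "viscoelastic_solid"

#: Default recovery-ratio threshold separating solid (near-complete recoil)
#: from liquid behaviour.  Configurable in :func:`classify_gel`.
RECOVERY_THRESHOLD = 0.9


class FitError(RuntimeError):
    """Burgers fit failed to converge; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: Optional[list] = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class ProtocolError(ValueError):
    """Force waveform cannot be segmented into on/off windows."""


@dataclass(frozen=True)
class Window:
    """Half-open index window [start, stop) with an on/off phase label."""

    phase: str  # "on" | "off"
    start: int
    stop: int

    @property
    def n(self) -> int:
        return self.stop - self.start


@dataclass
class FitResult:
    """Outcome of the creep-compliance analysis of one trace.

    Je0 (Pa^-1) and eta0 (Pa*s) are means over the fitted on cycles;
    per-cycle values are kept for quality control.  ``recovery_ratio`` is
    in [0, 1] (1 = complete recoil) and drives the liquid/solid call.
    """

    params: BurgersParams
    Je0: float
    eta0: float
    residual_norm: float
    recovery_ratio: float = float("nan")
    classification: Optional[str] = None
    force_applied: float = float("nan")
    per_cycle: list = field(default_factory=list)
    solid_limit: bool = False
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "Je0_per_Pa": self.Je0,
            "eta0_Pa_s": self.eta0 if math.isfinite(self.eta0) else "inf",
            "residual_norm": self.residual_norm,
            "recovery_ratio": self.recovery_ratio,
            "classification": self.classification,
            "force_applied_N": self.force_applied,
            "per_cycle": [
                {
                    "Je0": c["Je0"],
                    "eta0": c["eta0"] if math.isfinite(c["eta0"]) else "inf",
                    "residual_norm": c["residual_norm"],
                }
                for c in self.per_cycle
            ],
            "solid_limit": self.solid_limit,
            "flags": list(self.flags),
        }


def compliance_from_displacement(x, F0: float, drag: float) -> np.ndarray:
    """J = C * x / F0, element-wise (Pa^-1).

    Linear and homogeneous in x; halving F0 at fixed x doubles J.
    """
    if not F0 > 0:
        raise ValueError("F0 must be > 0")
    if not drag > 0:
        raise ValueError("drag coefficient must be > 0")
    return np.asarray(x, dtype=float) * (drag / F0)


def curve_from_trace(
    trace: DisplacementTrace,
    drag: float,
    F0: Optional[float] = None,
    min_duration: float = 1.0,
) -> ComplianceCurve:
    """Convert a displacement trace to a compliance curve.

    F0 defaults to the trace's recorded force magnitude; the on mask comes
    from segmenting the recorded force waveform.
    """
    if F0 is None:
        F0 = trace.F0
    windows = segment_protocol(trace.force, dt=float(np.median(np.diff(trace.t))),
                               min_duration=min_duration)
    on = np.zeros(len(trace), dtype=bool)
    for w in windows:
        if w.phase == "on":
            on[w.start:w.stop] = True
    J = compliance_from_displacement(trace.x, F0, drag)
    return ComplianceCurve(t=trace.t, J=J, on=on, F0=F0)


def segment_protocol(
    force: np.ndarray,
    dt: float = 1.0,
    threshold: float = 0.5,
    min_duration: float = 1.0,
) -> list[Window]:
    """Segment a sampled force series into ordered on/off windows.

    A sample is "on" when its force exceeds ``threshold`` times the series
    maximum.  Runs shorter than ``min_duration`` seconds are treated as
    glitches and merged into the preceding window (debounce).

    Raises
    ------
    ProtocolError
        If the series never turns on.
    """
    f = np.asarray(force, dtype=float)
    if f.ndim != 1 or f.size < 2:
        raise ProtocolError("force series must be 1-D with >= 2 samples")
    fmax = f.max()
    if fmax <= 0:
        raise ProtocolError("force series has no on phase (no rising edge)")
    on = f > threshold * fmax

    # run-length encode
    runs: list[list] = []  # [phase, start, stop]
    start = 0
    for i in range(1, on.size + 1):
        if i == on.size or on[i] != on[start]:
            runs.append(["on" if on[start] else "off", start, i])
            start = i

    # debounce: merge sub-minimum runs into their predecessor
    min_samples = max(int(round(min_duration / dt)), 1)
    merged: list[list] = []
    for run in runs:
        if merged and (run[2] - run[1]) < min_samples:
            merged[-1][2] = run[2]
        elif merged and merged[-1][0] == run[0]:
            merged[-1][2] = run[2]
        else:
            merged.append(run)
    # a leading glitch shorter than min_samples is absorbed forward
    if len(merged) > 1 and (merged[0][2] - merged[0][1]) < min_samples:
        merged[1][1] = merged[0][1]
        merged = merged[1:]
    # consolidate any same-phase neighbours produced by merging
    out: list[list] = []
    for run in merged:
        if out and out[-1][0] == run[0]:
            out[-1][2] = run[2]
        else:
            out.append(run)
    if not any(r[0] == "on" for r in out):
        raise ProtocolError("force series has no on window after debouncing")
    return [Window(phase, s, e) for phase, s, e in out]


# ---------------------------------------------------------------------------
# Burgers fitting


def _model_and_jac(theta: np.ndarray, t: np.ndarray, steps):
    """Creep model and Jacobian in log-parameter space, with force history.

    theta = (log J1, log J2, log tau, log eta0).  ``steps`` is a list of
    (sign, delay) force steps contributing ``sign * J(t + delay)`` by
    Boltzmann superposition; the window's own onset is (+1, 0).  Prior
    cycles enter with their on (+1) and off (-1) steps, so incomplete
    relaxation between cycles is modelled rather than absorbed into J1.
    """
    with np.errstate(over="ignore", under="ignore", divide="ignore", invalid="ignore"):
        J1, J2, tau, eta0 = np.exp(np.clip(theta, -60.0, 60.0))
        model = np.zeros_like(t)
        jac = np.zeros((t.size, 4))
        for sign, delay in steps:
            ts = t + delay
            e = np.exp(-np.minimum(ts / tau, 700.0))
            model += sign * (J1 + J2 * (1.0 - e) + ts / eta0)
            jac[:, 0] += sign * J1
            jac[:, 1] += sign * J2 * (1.0 - e)
            jac[:, 2] += sign * (-J2 * e * ts / tau)
            jac[:, 3] += sign * (-ts / eta0)
    return model, jac


def _initial_guess(t: np.ndarray, J: np.ndarray) -> np.ndarray:
    """Heuristic start: J1 from the first sample, eta0 from the reciprocal
    slope of the last third, J2 from the asymptote intercept, tau from the
    half-rise time of the retarded amplitude."""
    scale = max(float(np.max(np.abs(J))), 1e-30)
    J1 = max(float(J[0]), 1e-3 * scale)
    k = max(t.size // 3, 2)
    tt, JJ = t[-k:], J[-k:]
    slope = float(np.polyfit(tt, JJ, 1)[0])
    slope = max(slope, 1e-12 * scale / max(t[-1], 1.0))
    eta0 = 1.0 / slope
    intercept = float(np.mean(JJ) - slope * np.mean(tt))
    J2 = max(intercept - J1, 0.05 * scale)
    # half-rise of the retarded component
    retarded = J - J1 - slope * t
    target = 0.5 * max(float(retarded.max()), 1e-3 * scale)
    above = np.nonzero(retarded >= target)[0]
    tau = float(t[above[0]]) if above.size and t[above[0]] > 0 else max(t[-1] / 5.0, 1e-3)
    return np.log([J1, J2, tau, eta0])


def _fit_segments(
    segments: list,
    n_starts: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Multi-start least squares over one or more on-windows.

    ``segments`` is a list of (t_rel, J, steps, baseline) tuples sharing a
    single parameter vector; pooling several cycles breaks the degeneracy
    between J1 and the flow accumulated across cycles, which a single
    window cannot resolve.  Returns (theta, rms residual).
    """
    n_total = sum(t.size for t, _, _, _ in segments)
    scale = max(max(float(np.max(np.abs(J))) for _, J, _, _ in segments), 1e-30)
    t0, J0, _, base0 = segments[0]
    theta0 = _initial_guess(t0, np.maximum(J0 - base0, 0.0))

    def residuals(th):
        return np.concatenate(
            [_model_and_jac(th, t, steps)[0] - J for t, J, steps, _ in segments]
        )

    def jacobian(th):
        return np.vstack([_model_and_jac(th, t, steps)[1] for t, _, steps, _ in segments])

    best_theta, best_cost = None, np.inf
    confirmations = 0
    diagnostics = []
    for s in range(n_starts):
        start = theta0 if s == 0 else theta0 + rng.normal(0.0, math.log(3.0), size=4)
        try:
            res = least_squares(
                residuals,
                start,
                jac=jacobian,
                method="lm",
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
                max_nfev=400,
            )
        except Exception as exc:  # pragma: no cover - defensive
            diagnostics.append({"start": s, "error": str(exc)})
            continue
        if not np.all(np.isfinite(res.x)):
            diagnostics.append({"start": s, "error": "non-finite solution"})
            continue
        if res.cost < best_cost * (1.0 - 1e-9):
            best_cost, best_theta = res.cost, res.x
            confirmations = 0
        elif res.cost <= best_cost * (1.0 + 1e-6):
            confirmations += 1
        # an essentially exact fit (noiseless data), or a second start
        # reconverging to the same optimum, ends the search early
        if math.sqrt(2.0 * best_cost / n_total) < 1e-10 * scale or confirmations >= 1:
            break
    if best_theta is None:
        raise FitError("Burgers fit failed on all starts", diagnostics)
    rms = math.sqrt(2.0 * best_cost / n_total)
    return best_theta, rms


def fit_burgers(
    curve: ComplianceCurve,
    n_starts: int = 8,
    seed: int = 0,
    solid_cap_factor: float = 1e6,
    recovery_threshold: float = RECOVERY_THRESHOLD,
    per_cycle_qc: bool = True,
) -> FitResult:
    """Fit the Burgers creep form to the force-on windows of a curve.

    All on windows (>= 8 samples each) are fitted jointly in
    log-parameter space with multi-start Levenberg-Marquardt; times are
    taken relative to each window's force onset, so the fit is invariant
    to the absolute acquisition time axis, and earlier force steps enter
    the model by Boltzmann superposition.  Pooling the cycles is what
    makes eta0 well determined: within a single later window the flow
    accumulated from previous cycles is indistinguishable from a shift in
    J1.  Individual per-cycle fits are retained as a quality-control
    metric (their Je0 spread is flagged when above 20%).

    A fitted eta0 exceeding ``solid_cap_factor * t_on / Je0`` contributes
    a negligible flow term over the observation window; it is reported as
    the solid sentinel (eta0 = inf) with the ``solid_limit`` flag rather
    than as a meaninglessly large viscosity.

    If the curve contains off windows, the recovery ratio and the
    liquid/solid classification are filled in as well.
    """
    rng = np.random.default_rng(seed)
    windows = _windows_from_mask(curve.on)
    on_windows = [w for w in windows if w.phase == "on" and w.n >= 8]
    if not on_windows:
        raise FitError("no on-window with >= 8 samples to fit")

    # absolute step times of every on/off transition, for history modelling
    step_times = []
    for w in windows:
        if w.phase == "on" and w.n >= 1:
            step_times.append((1.0, float(curve.t[w.start])))
        elif w.phase == "off" and w.start > 0:
            step_times.append((-1.0, float(curve.t[w.start])))

    segments = []
    for w in on_windows:
        onset = float(curve.t[w.start])
        t_rel = curve.t[w.start:w.stop] - onset
        J = curve.J[w.start:w.stop]
        # the window's own step plus all earlier transitions
        steps = tuple((s, onset - ts) for s, ts in step_times if ts <= onset)
        baseline = float(curve.J[w.start - 1]) if w.start > 0 else 0.0
        segments.append((t_rel, J, steps, baseline))

    t_span = max(float(t[-1]) for t, _, _, _ in segments) or 1.0

    def _summarize(theta, rms):
        J1, J2, tau, eta0 = np.exp(np.clip(theta, -60.0, 60.0))
        Je0 = J1 + J2
        solid = eta0 > solid_cap_factor * t_span / Je0
        return {
            "J1": float(J1),
            "J2": float(J2),
            "tau": float(tau),
            "eta0": math.inf if solid else float(eta0),
            "Je0": float(Je0),
            "residual_norm": rms,
            "solid_limit": bool(solid),
        }

    # headline estimates: all on-windows fitted jointly with one parameter set
    pooled = _summarize(*_fit_segments(segments, n_starts, rng))
    # per-cycle fits are kept as a quality-control metric
    per_cycle = (
        [_summarize(*_fit_segments([seg], n_starts, rng)) for seg in segments]
        if per_cycle_qc and len(segments) > 1
        else [pooled]
    )

    eta0 = math.inf if pooled["solid_limit"] else pooled["eta0"]
    params = BurgersParams(J1=pooled["J1"], J2=pooled["J2"], tau=pooled["tau"], eta0=eta0)
    result = FitResult(
        params=params,
        Je0=pooled["Je0"],
        eta0=eta0,
        residual_norm=pooled["residual_norm"],
        force_applied=curve.F0,
        per_cycle=per_cycle,
        solid_limit=pooled["solid_limit"],
    )
    if len(per_cycle) > 1:
        spread = np.std([c["Je0"] for c in per_cycle]) / pooled["Je0"]
        if spread > 0.2:
            result.flags.append(f"per-cycle Je0 spread {spread:.2f} exceeds 0.2")
    if any(w.phase == "off" for w in windows):
        try:
            result.recovery_ratio = recovery_ratio(curve)
            result.classification = classify_gel(result.recovery_ratio, recovery_threshold)
        except ValueError as exc:
            result.flags.append(f"recovery undefined: {exc}")
    return result


def _windows_from_mask(on: np.ndarray) -> list[Window]:
    windows = []
    start = 0
    for i in range(1, on.size + 1):
        if i == on.size or on[i] != on[start]:
            windows.append(Window("on" if on[start] else "off", start, i))
            start = i
    return windows


def recovery_ratio(curve: ComplianceCurve) -> float:
    """Fraction of each cycle's deformation recovered after force release.

    For each on window followed by an off window,

        R = (x_end_on - x_end_off) / (x_end_on - x_baseline)

    where the baseline is the last sample before the on window (zero for
    the first cycle).  Values are clipped to [0, 1] and averaged over
    cycles.  R = 1 means complete recoil (viscoelastic solid); a liquid
    retains the unrecoverable flow ``t_on / eta0`` and recoils only
    partially.

    Raises
    ------
    ValueError
        If no cycle has a positive on-phase deformation.
    """
    windows = _windows_from_mask(curve.on)
    ratios = []
    for i, w in enumerate(windows):
        if w.phase != "on" or i + 1 >= len(windows):
            continue
        off = windows[i + 1]
        baseline = curve.J[w.start - 1] if w.start > 0 else 0.0
        end_on = curve.J[w.stop - 1]
        end_off = curve.J[off.stop - 1]
        rise = end_on - baseline
        if rise <= 0:
            continue
        ratios.append(float(np.clip((end_on - end_off) / rise, 0.0, 1.0)))
    if not ratios:
        raise ValueError("no complete on/off cycle with positive deformation")
    return float(np.mean(ratios))


def classify_gel(result_or_ratio, threshold: float = RECOVERY_THRESHOLD) -> str:
    """Classify as viscoelastic solid iff the recovery ratio >= threshold."""
    R = result_or_ratio.recovery_ratio if isinstance(result_or_ratio, FitResult) else float(result_or_ratio)
    if math.isnan(R):
        raise ValueError("recovery ratio is undefined; cannot classify")
    return SOLID if R >= threshold else LIQUID


@dataclass(frozen=True)
class StressSweepResult:
    verdict: str  # "linear" | "nonlinear"
    cv_Je0: float
    cv_eta0: float
    slope_logJe0_logF: float


def stress_sweep_linearity(
    results: Sequence[FitResult],
    cv_bound: float = 0.2,
    slope_bound: float = 0.1,
) -> StressSweepResult:
    """Check force-independence of the fitted quantities (linear regime).

    Requires >= 3 fits at distinct forces.  Computes the coefficient of
    variation of Je0 and of eta0 across forces and the slope of log(Je0)
    against log(F0); the sweep is declared linear iff both CVs are within
    ``cv_bound`` and the slope magnitude within ``slope_bound``.
    """
    forces = np.array([r.force_applied for r in results], dtype=float)
    if np.unique(forces).size < 3:
        raise ValueError("stress sweep requires fits at >= 3 distinct forces")
    Je0 = np.array([r.Je0 for r in results], dtype=float)
    eta0 = np.array([r.eta0 for r in results], dtype=float)
    cv_J = float(np.std(Je0) / np.mean(Je0))
    cv_e = 0.0 if np.any(np.isinf(eta0)) and np.all(np.isinf(eta0)) else float(
        np.std(eta0) / np.mean(eta0)
    )
    slope = float(np.polyfit(np.log(forces), np.log(Je0), 1)[0])
    linear = cv_J <= cv_bound and cv_e <= cv_bound and abs(slope) <= slope_bound
    return StressSweepResult(
        verdict="linear" if linear else "nonlinear",
        cv_Je0=cv_J,
        cv_eta0=cv_e,
        slope_logJe0_logF=slope,
    )


def analyze_trace(
    trace: DisplacementTrace,
    drag: float,
    F0: Optional[float] = None,
    **fit_kwargs,
) -> FitResult:
    """Full single-trace chain: segment, convert to compliance, fit."""
    curve = curve_from_trace(trace, drag, F0=F0)
    return fit_burgers(curve, **fit_kwargs)
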