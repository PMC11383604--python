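"""Synthetic data with known ground truth for every pipeline input.

Generators cover the four acquisition products the analysis consumes:

* displacement traces of a Burgers material probed by the on/off
  step-force protocol, with additive Gaussian measurement noise;
* donor cohorts for the paired condition designs (control, IL-13,
  IL-13 + DTT, and the thiomer-overlay analogues), with multiplicative
  condition effects on steady-state compliance and zero-shear viscosity;
* multi-channel z-intensity profiles (Gaussian peaks at the cell surface,
  wire center and mucus top);
* rendered time-lapse image stacks of a wire ridge moving along its axis.

All generators are pure functions of their arguments and a seed:
identical calls return identical data.  Condition effects act
multiplicatively on (Je0, eta0) with the retardation time and the J1:J2
split held at control values, the minimal structure supporting
ratio-paired comparisons.  Donor heterogeneity is log-normal; replicate
inserts within a donor share material parameters and differ only in
measurement noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import erf

from .burgers import BurgersParams, ForceProtocol, displacement_response
from .geometry import WireGeometry, ZProfileSet
from .io import DisplacementTrace

__all__ = [
    "simulate_trace",
    "CohortSpec",
    "Cohort",
    "simulate_cohort",
    "LayerLayout",
    "simulate_zprofiles",
    "WireRender",
    "simulate_image_stack",
    "RenderError",
]

#: Condition-specific coil forces (N): 110 nN for control-like gels,
#: 460 nN for the stiffer IL-13 gels (currents 0.6 A and 2.5 A).
CONDITION_FORCES = {
    "control": 110e-9,
    "il13": 460e-9,
    "il13_dtt": 110e-9,
    "thiomer_control": 110e-9,
    "thiomer_il13": 460e-9,
    "thiomer_il13_methimazole": 110e-9,
}


def simulate_trace(
    params: BurgersParams,
    geom: WireGeometry,
    protocol: ForceProtocol,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> DisplacementTrace:
    """Noisy displacement trace of a Burgers material under the protocol.

    ``noise_sigma`` is the additive Gaussian displacement noise expressed
    as a fraction of the recoverable plateau displacement
    ``(F0/C) * Je0`` (so 0.02 means noise worth 2% of the steady-state
    compliance).  Deterministic for a given seed.
    """
    drag = geom.drag
    t, x = displacement_response(params, drag, protocol)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        scale = noise_sigma * (protocol.F0 / drag) * params.Je0
        x = x + rng.normal(0.0, scale, size=x.shape)
    _, force = protocol.force_series(t)
    return DisplacementTrace(t=t, x=x, force=force)


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic donor cohort.

    Donor-level material parameters are log-normal around the control
    medians.  ``il13_effect`` multiplies (Je0, eta0) of the IL-13
    condition relative to control — compliance down, viscosity up.
    ``dtt_effect`` multiplies the IL-13 values for the DTT condition,
    restoring toward control (the default undoes the IL-13 effect
    exactly).  ``noise_sigma`` is the per-trace displacement noise as a
    fraction of the plateau.
    """

    n_donors: int = 5
    inserts_per_donor: int = 3
    Je0_median: float = 0.15          # Pa^-1
    eta0_median: float = 200.0        # Pa*s
    sigma_log: float = 0.3            # donor-to-donor log-SD of Je0 and eta0
    tau: float = 2.0                  # s, shared retardation time
    J1_fraction: float = 2.0 / 3.0    # J1 / Je0 split
    il13_effect: Tuple[float, float] = (0.3, 20.0)
    dtt_effect: Tuple[float, float] = (1.0 / 0.3, 1.0 / 20.0)
    noise_sigma: float = 0.02
    conditions: Tuple[str, ...] = ("control", "il13", "il13_dtt")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 2:
            raise ValueError("need >= 2 donors for a paired design")
        if self.inserts_per_donor not in (1, 2, 3):
            raise ValueError("inserts_per_donor must be 1, 2 or 3")
        if not 0 < self.J1_fraction < 1:
            raise ValueError("J1_fraction must be in (0, 1)")

    def condition_effects(self) -> Dict[str, Tuple[float, float]]:
        """Cumulative (Je0, eta0) multipliers per condition vs control."""
        eJ, ee = self.il13_effect
        dJ, de = self.dtt_effect
        table = {
            "control": (1.0, 1.0),
            "il13": (eJ, ee),
            "il13_dtt": (eJ * dJ, ee * de),
            "thiomer_control": (1.0, 1.0),
            "thiomer_il13": (eJ, ee),
            "thiomer_il13_methimazole": (eJ * dJ, ee * de),
        }
        return {c: table[c] for c in self.conditions}


@dataclass
class Cohort:
    """Simulated cohort: per-trace metadata, raw traces and ground truth."""

    table: pd.DataFrame
    traces: Dict[Tuple[str, str, int], DisplacementTrace]
    truth: dict


def _donor_params(spec: CohortSpec, rng: np.random.Generator) -> list[BurgersParams]:
    donors = []
    for _ in range(spec.n_donors):
        Je0 = spec.Je0_median * math.exp(rng.normal(0.0, spec.sigma_log))
        eta0 = spec.eta0_median * math.exp(rng.normal(0.0, spec.sigma_log))
        donors.append(_params_from_summary(Je0, eta0, spec))
    return donors


def _params_from_summary(Je0: float, eta0: float, spec: CohortSpec) -> BurgersParams:
    return BurgersParams(
        J1=spec.J1_fraction * Je0,
        J2=(1.0 - spec.J1_fraction) * Je0,
        tau=spec.tau,
        eta0=eta0,
    )


def simulate_cohort(
    spec: CohortSpec,
    geom: Optional[WireGeometry] = None,
    protocol_template: Optional[ForceProtocol] = None,
) -> Cohort:
    """Generate paired traces for every (donor, condition, insert).

    Each donor draws one latent control parameter set; condition effects
    multiply (Je0, eta0) while tau and the J1:J2 split stay fixed.  The
    applied force follows the per-condition convention in
    :data:`CONDITION_FORCES` unless a protocol template pins it.
    """
    geom = geom or WireGeometry()
    ss = np.random.SeedSequence(spec.seed)
    donor_rng = np.random.default_rng(ss.spawn(1)[0])
    donors = _donor_params(spec, donor_rng)
    effects = spec.condition_effects()

    rows = []
    traces: Dict[Tuple[str, str, int], DisplacementTrace] = {}
    truth: dict = {"donors": {}, "effects": {k: list(v) for k, v in effects.items()}}
    noise_seeds = iter(np.random.default_rng(ss.spawn(2)[1]).integers(0, 2**31 - 1,
                        size=spec.n_donors * len(effects) * spec.inserts_per_donor))
    for d, base in enumerate(donors):
        donor_id = f"D{d + 1:02d}"
        truth["donors"][donor_id] = {"Je0": base.Je0, "eta0": base.eta0, "tau": base.tau}
        for condition, (eJ, ee) in effects.items():
            params = _params_from_summary(base.Je0 * eJ, base.eta0 * ee, spec)
            F0 = CONDITION_FORCES.get(condition, 110e-9)
            if protocol_template is not None:
                protocol = ForceProtocol(
                    F0=F0,
                    t_on=protocol_template.t_on,
                    t_off=protocol_template.t_off,
                    n_cycles=protocol_template.n_cycles,
                    dt=protocol_template.dt,
                )
            else:
                protocol = ForceProtocol(F0=F0)
            for insert in range(1, spec.inserts_per_donor + 1):
                trace = simulate_trace(
                    params, geom, protocol,
                    noise_sigma=spec.noise_sigma,
                    seed=int(next(noise_seeds)),
                )
                traces[(donor_id, condition, insert)] = trace
                rows.append(
                    {
                        "donor": donor_id,
                        "condition": condition,
                        "insert": insert,
                        "F0_N": F0,
                        "Je0_true": params.Je0,
                        "eta0_true": params.eta0,
                    }
                )
    return Cohort(table=pd.DataFrame(rows), traces=traces, truth=truth)


@dataclass(frozen=True)
class LayerLayout:
    """Axial layout of the imaged layers (um) and shared peak width."""

    cell_surface: float = 10.0
    wire_center: float = 67.0
    mucus_top: float = 80.0
    membrane: Optional[float] = None
    peak_sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.membrane is not None and self.membrane > self.cell_surface:
            raise ValueError("membrane must lie at or below the cell surface")
        if not (self.cell_surface < self.wire_center <= self.mucus_top):
            raise ValueError(
                "layers must be ordered cell_surface < wire_center <= mucus_top"
            )
        if self.peak_sigma <= 0:
            raise ValueError("peak_sigma must be > 0")


def simulate_zprofiles(
    layout: LayerLayout,
    z: Optional[np.ndarray] = None,
    noise: float = 0.0,
    seed: int = 0,
) -> ZProfileSet:
    """Gaussian-peak intensity z-profiles for the three channels.

    ``noise`` is the additive Gaussian noise SD as a fraction of the unit
    peak amplitude; intensities are clipped at zero.
    """
    if z is None:
        z = np.arange(0.0, 100.0 + 1e-9, 0.5)
    z = np.asarray(z, dtype=float)
    rng = np.random.default_rng(seed)
    positions = {
        "membrane": layout.cell_surface,
        "brightfield": layout.wire_center,
        "particles": layout.mucus_top,
    }
    channels = {}
    for name, mu in positions.items():
        y = np.exp(-0.5 * ((z - mu) / layout.peak_sigma) ** 2)
        if noise > 0:
            y = y + rng.normal(0.0, noise, size=y.shape)
        channels[name] = np.clip(y, 0.0, None)
    return ZProfileSet(z=z, channels=channels)


class RenderError(ValueError):
    """Wire would leave the frame during rendering."""


@dataclass(frozen=True)
class WireRender:
    """Rendering parameters for the synthetic wire ridge.

    The wire appears as a bright ridge along +x with a Gaussian transverse
    profile (``width_sigma_px``) and an erf-smoothed visible end
    (``end_sigma_px``, the optical edge width); only the end moves through
    the field of view, the far side extends beyond the frame.
    """

    amplitude: float = 100.0
    width_sigma_px: float = 9.5
    end_sigma_px: float = 1.2
    end_x0: float = 60.0
    y_center: Optional[float] = None
    margin_px: float = 8.0


def simulate_image_stack(
    trace_px: np.ndarray,
    frame_shape: Tuple[int, int] = (64, 192),
    render: WireRender = WireRender(),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render a stack of frames of a wire displaced axially per trace.

    ``trace_px`` gives the per-frame axial displacement in pixels relative
    to frame 0.  ``noise_sigma`` is the additive Gaussian pixel noise in
    intensity units (SNR = render.amplitude / noise_sigma).  Pixel centers
    are at integer coordinates; the rendered end position is analytic, so
    sub-pixel displacements are exact.
    """
    trace_px = np.asarray(trace_px, dtype=float)
    ny, nx = frame_shape
    ends = render.end_x0 + trace_px
    if np.any(ends < render.margin_px) or np.any(ends > nx - render.margin_px):
        raise RenderError(
            f"wire end leaves the frame (range {ends.min():.1f}..{ends.max():.1f} px, "
            f"frame width {nx} px, margin {render.margin_px} px)"
        )
    y0 = render.y_center if render.y_center is not None else (ny - 1) / 2.0
    yy = np.arange(ny)[:, None]
    xx = np.arange(nx)[None, :]
    transverse = np.exp(-0.5 * ((yy - y0) / render.width_sigma_px) ** 2)
    rng = np.random.default_rng(seed)
    frames = np.empty((trace_px.size, ny, nx), dtype=float)
    for k, end in enumerate(ends):
        axial = 0.5 * (1.0 + erf((xx - end) / (math.sqrt(2.0) * render.end_sigma_px)))
        frame = render.amplitude * transverse * axial
        if noise_sigma > 0:
            frame = frame + rng.normal(0.0, noise_sigma, size=frame.shape)
        frames[k] = frame
    return frames
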