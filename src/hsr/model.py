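"""Kinetic model of the HSF1/HSP70 heat-shock-response network.

The model tracks four dynamical variables in a single cell: the
cell-environment temperature theta (degC), the misfolded-protein
concentration [MFP] (uM), the heat-shock-protein concentration [HSP] (uM)
and its mRNA [mHSP] (uM).  Temperature enters only through the
denaturation rate kappa(theta); misfolded proteins titrate chaperones away
from HSF1, and free HSF1 drives HSP transcription with a cubic
(trimerisation) nonlinearity.  The experimental readout is the fraction F
of HSF1:eGFP fluorescence localised in nuclear stress bodies, modelled as
the cube of the free-HSF1 fraction.

All times are in hours and all concentrations in uM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ModelParameters",
    "TemperatureProtocol",
    "CellState",
    "CellParameters",
    "CellTrajectory",
    "denaturation_rate",
    "hsp_free_fraction",
    "hsf1_free_fraction",
    "foci_fraction",
    "derivatives",
    "steady_state",
    "quasi_steady_initial",
    "simulate_trajectory",
]

#: Default relative / absolute tolerances for trajectory integration.
RTOL = 1e-8
ATOL = 1e-10


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants, thresholds and lifetimes of the HSR network.

    Defaults are the calibrated reference values for HeLa cells.

    Parameters
    ----------
    k_d : float
        Denaturation rate scale (uM).
    k_r : float
        Renaturation rate (dimensionless).
    mu : float
        HSP basal transcription rate (uM).
    lam : float
        HSP active (HSF1-driven) transcription rate (uM).
    s0 : float
        Transcription regulation threshold on the free-HSF1 fraction
        (dimensionless).
    beta : float
        HSP translation rate (dimensionless).
    h0 : float
        Translation regulation threshold on the free-HSP fraction
        (dimensionless).
    hsf1_tot_ref : float
        Reference total HSF1 concentration (uM).
    tau_temp : float
        Incubator temperature rise time (h).
    tau_mfp : float
        Misfolded-protein lifetime (h).
    tau_mhsp : float
        HSP mRNA lifetime (h).
    tau_hsp : float
        HSP protein lifetime (h).
    """

    k_d: float = 1.76
    k_r: float = 17.7
    mu: float = 1.47e-3
    lam: float = 0.78
    s0: float = 0.18
    beta: float = 10.0
    h0: float = 0.32
    hsf1_tot_ref: float = 4.0e-2
    tau_temp: float = 1.0 / 15.0
    tau_mfp: float = 0.5
    tau_mhsp: float = 1.0
    tau_hsp: float = 10.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"ModelParameters.{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class CellParameters:
    """Per-cell expression levels: total HSF1 and initial HSP (both uM)."""

    hsf1_tot: float
    hsp0: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.hsf1_tot) and self.hsf1_tot > 0):
            raise ValueError(f"hsf1_tot must be strictly positive, got {self.hsf1_tot!r}")
        if not (math.isfinite(self.hsp0) and self.hsp0 > 0):
            raise ValueError(f"hsp0 must be strictly positive, got {self.hsp0!r}")


@dataclass(frozen=True)
class CellState:
    """Instantaneous dynamical state of one cell."""

    theta: float
    mfp: float
    hsp: float
    mhsp: float

    def __post_init__(self) -> None:
        if self.mfp < 0 or self.hsp < 0 or self.mhsp < 0:
            raise ValueError("concentrations must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.theta, self.mfp, self.hsp, self.mhsp])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CellState":
        return cls(theta=float(y[0]), mfp=float(y[1]), hsp=float(y[2]), mhsp=float(y[3]))


@dataclass(frozen=True)
class TemperatureProtocol:
    """Piecewise-constant incubator setpoint schedule.

    ``segments`` is an ordered list of ``(start_h, end_h, setpoint_degC)``
    covering the simulation window contiguously; ``theta0`` is the
    cell-environment temperature at the start of the window.
    """

    segments: tuple[tuple[float, float, float], ...]
    theta0: float = 37.0

    def __post_init__(self) -> None:
        segs = tuple((float(a), float(b), float(c)) for a, b, c in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("protocol needs at least one segment")
        for start, end, setpoint in segs:
            if not end > start:
                raise ValueError(f"empty or inverted segment ({start}, {end})")
            if not 30.0 <= setpoint <= 50.0:
                raise ValueError(f"setpoint {setpoint} degC outside sanity bounds [30, 50]")
        for (_, e0, _), (s1, _, _) in zip(segs, segs[1:]):
            if not math.isclose(e0, s1, abs_tol=1e-12):
                raise ValueError("segments must be contiguous and ordered")

    @property
    def start(self) -> float:
        return self.segments[0][0]

    @property
    def end(self) -> float:
        return self.segments[-1][1]

    def setpoint(self, t: float) -> float:
        """Setpoint at time ``t`` (right-continuous; last segment closed)."""
        for start, end, setpoint in self.segments:
            if start <= t < end:
                return setpoint
        if math.isclose(t, self.end, abs_tol=1e-12) or t >= self.end:
            return self.segments[-1][2]
        raise ValueError(f"time {t} h outside protocol window [{self.start}, {self.end}]")

    @classmethod
    def step(
        cls,
        stress_temperature: float,
        stress_duration: float = 3.0,
        baseline: float = 37.0,
        pre: float = 1.0,
        post: float = 1.0,
    ) -> "TemperatureProtocol":
        """Baseline -> stress -> baseline schedule with stress onset at t=0."""
        return cls(
            segments=(
                (-pre, 0.0, baseline),
                (0.0, stress_duration, stress_temperature),
                (stress_duration, stress_duration + post, baseline),
            ),
            theta0=baseline,
        )


@dataclass(frozen=True)
class CellTrajectory:
    """Sampled readout time series for one cell.

    ``times`` are hours relative to stress onset; ``f_values`` is the foci
    fraction F in [0, 1]; ``total_fluorescence`` the total HSF1:eGFP signal
    (arbitrary units, constant over the movie for a simulated cell).
    """

    cell_id: str
    times: np.ndarray
    f_values: np.ndarray
    total_fluorescence: np.ndarray
    temperature_c: float = 37.0
    coating: str = "col-"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        f = np.asarray(self.f_values, dtype=float)
        fluor = np.asarray(self.total_fluorescence, dtype=float)
        if times.size == 0:
            raise ValueError("trajectory must have at least one time point")
        if not (np.diff(times) > 0).all():
            raise ValueError("times must be strictly increasing")
        if f.shape != times.shape or fluor.shape != times.shape:
            raise ValueError("times, f_values and total_fluorescence must align")
        if (f < 0).any() or (f > 1).any():
            raise ValueError("F must lie in [0, 1]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "f_values", f)
        object.__setattr__(self, "total_fluorescence", fluor)

    def f_at(self, t: float, tol: float = 1.0 / 12.0) -> float:
        """F at the sample nearest to ``t``, required within ``tol`` hours."""
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > tol + 1e-12:
            raise ValueError(f"no sample within {tol} h of t={t} h")
        return float(self.f_values[i])


# ---------------------------------------------------------------------------
# elementary pieces of the vector field


def denaturation_rate(theta: float, params: ModelParameters) -> float:
    """Temperature-dependent protein denaturation rate kappa(theta), uM.

    kappa(theta) = k_d (1 - 0.4 e^(37-theta)) 1.4^(theta-37), clamped at 0:
    the raw expression turns negative below ~34.7 degC, which would be an
    unphysical negative denaturation flux.
    """
    if not math.isfinite(theta):
        raise ValueError("theta must be finite")
    kappa = params.k_d * (1.0 - 0.4 * math.exp(37.0 - theta)) * 1.4 ** (theta - 37.0)
    return max(kappa, 0.0)


def hsp_free_fraction(state: CellState) -> float:
    """Fraction of chaperone not engaged with misfolded protein.

    [HSP]free = [HSP] / ([HSP] + [MFP]); the empty-cell limit
    hsp = mfp = 0 is taken as 0 (continuous extension along hsp -> 0).
    """
    total = state.hsp + state.mfp
    if total <= 0.0:
        return 0.0
    return state.hsp / total


def hsf1_free_fraction(state: CellState, cell: CellParameters) -> float:
    """Fraction of HSF1 not sequestered by free chaperone.

    [HSF1]free = [HSF1]tot / ([HSF1]tot + [HSP] * [HSP]free); lies in (0, 1].
    """
    if cell.hsf1_tot <= 0:
        raise ValueError("hsf1_tot must be strictly positive")
    return cell.hsf1_tot / (cell.hsf1_tot + state.hsp * hsp_free_fraction(state))


def foci_fraction(state: CellState, cell: CellParameters) -> float:
    """Foci readout F = ([HSF1]free)^3.

    The cube reflects HSF1 trimerisation: foci only become visible once a
    substantial fraction of HSF1 is released from chaperone sequestration.
    """
    return hsf1_free_fraction(state, cell) ** 3


def _rhs(t: float, y: np.ndarray, setpoint: float, hsf1_tot: float, p: ModelParameters) -> list[float]:
    """Vector field on the raw state array [theta, mfp, hsp, mhsp]."""
    theta, mfp, hsp, mhsp = y
    # negative excursions from roundoff are treated as 0 in the fractions
    mfp = max(mfp, 0.0)
    hsp = max(hsp, 0.0)
    mhsp = max(mhsp, 0.0)
    total = hsp + mfp
    if total > 0.0:
        hsp_free = hsp / total
        titration = mfp * mfp / total
        renaturation = p.k_r * mfp * hsp / total
    else:
        hsp_free = 0.0
        titration = 0.0
        renaturation = 0.0
    hsf1_free = hsf1_tot / (hsf1_tot + hsp * hsp_free)
    kappa = p.k_d * (1.0 - 0.4 * math.exp(37.0 - theta)) * 1.4 ** (theta - 37.0)
    if kappa < 0.0:
        kappa = 0.0
    f3 = hsf1_free * hsf1_free * hsf1_free
    return [
        (setpoint - theta) / p.tau_temp,
        (kappa - titration - renaturation) / p.tau_mfp,
        (p.beta * hsp_free / (p.h0 + hsp_free) * mhsp - hsp) / p.tau_hsp,
        (p.mu + p.lam * f3 / (p.s0 ** 3 + f3) - mhsp) / p.tau_mhsp,
    ]


def derivatives(
    state: CellState, cell: CellParameters, setpoint: float, params: ModelParameters
) -> CellState:
    """Time derivative of the state under a fixed incubator setpoint.

    Returned as a CellState-shaped container of d/dt values (the
    non-negativity check is bypassed since derivatives may be negative).
    """
    y = state.as_array()
    if not np.isfinite(y).all():
        raise ValueError("state must be finite")
    d = _rhs(0.0, y, setpoint, cell.hsf1_tot, params)
    out = object.__new__(CellState)
    object.__setattr__(out, "theta", d[0])
    object.__setattr__(out, "mfp", d[1])
    object.__setattr__(out, "hsp", d[2])
    object.__setattr__(out, "mhsp", d[3])
    return out


# ---------------------------------------------------------------------------
# steady state and initial conditions


def steady_state(
    cell: CellParameters,
    params: ModelParameters,
    theta: float = 37.0,
    residual_tol: float = 1e-8,
    max_horizon: float = 3200.0,
) -> CellState:
    """Normothermic fixed point of the network, found by long relaxation.

    Integrates from a neutral interior state over at least 20 HSP
    lifetimes, doubling the horizon until every component of the vector
    field is below ``residual_tol``.  ``cell.hsp0`` is ignored: the fixed
    point defines the steady chaperone level.
    """
    horizon = 20.0 * params.tau_hsp
    y = np.array([theta, 0.01, 0.1, 0.1])
    while True:
        sol = solve_ivp(
            _rhs,
            (0.0, horizon),
            y,
            args=(theta, cell.hsf1_tot, params),
            method="LSODA",
            rtol=1e-12,
            atol=1e-14,
        )
        if not sol.success:
            raise RuntimeError(f"steady-state relaxation failed: {sol.message}")
        y = sol.y[:, -1]
        residual = float(np.max(np.abs(_rhs(0.0, y, theta, cell.hsf1_tot, params))))
        if residual < residual_tol:
            return CellState.from_array(np.clip(y, [-np.inf, 0, 0, 0], None))
        if horizon > max_horizon:
            raise RuntimeError(
                f"steady state not converged within {horizon} h (residual {residual:.3e})"
            )
        horizon *= 2.0


def quasi_steady_initial(
    cell: CellParameters, params: ModelParameters, theta: float = 37.0
) -> CellState:
    """Initial state with hsp fixed at ``cell.hsp0`` and fast variables slaved.

    The stress is much shorter than the HSP lifetime, so a cell's
    chaperone level is an initial condition rather than a dynamical
    outcome.  MFP is set on its nullcline given hsp0 (positive root of
    MFP^2 + (k_r hsp - kappa) MFP - kappa hsp = 0) and mHSP on the mRNA
    nullcline given the resulting free-HSF1 fraction.
    """
    kappa = denaturation_rate(theta, params)
    hsp = cell.hsp0
    b = params.k_r * hsp - kappa
    mfp = 0.5 * (-b + math.sqrt(b * b + 4.0 * kappa * hsp))
    state = CellState(theta=theta, mfp=mfp, hsp=hsp, mhsp=0.0)
    f_free = hsf1_free_fraction(state, cell)
    f3 = f_free ** 3
    mhsp = params.mu + params.lam * f3 / (params.s0 ** 3 + f3)
    return CellState(theta=theta, mfp=mfp, hsp=hsp, mhsp=mhsp)


def simulate_trajectory(
    cell: CellParameters,
    protocol: TemperatureProtocol,
    params: ModelParameters,
    times: Sequence[float],
    cell_id: str = "cell",
    rtol: float = RTOL,
    atol: float = ATOL,
    with_states: bool = False,
):
    """Integrate the network along a temperature protocol, sampling F.

    The initial state at ``times[0]`` has hsp = hsp0 and the fast
    variables on their nullclines at ``protocol.theta0`` (see
    :func:`quasi_steady_initial`).  Integration is piecewise over the
    protocol segments with LSODA (stiff-capable; the incubator time
    constant is two orders of magnitude below the HSP lifetime).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("empty sampling grid")
    if not (np.diff(times) > 0).all():
        raise ValueError("times must be strictly increasing")
    if times[0] < protocol.start - 1e-12 or times[-1] > protocol.end + 1e-12:
        raise ValueError(
            f"sampling grid [{times[0]}, {times[-1]}] outside protocol window "
            f"[{protocol.start}, {protocol.end}]"
        )

    y = quasi_steady_initial(cell, params, theta=protocol.theta0).as_array()
    samples: dict[int, np.ndarray] = {}
    t_now = float(times[0])
    samples[0] = y.copy()
    for start, end, setpoint in protocol.segments:
        if end <= t_now + 1e-12:
            continue
        seg_start = max(start, t_now)
        seg_end = min(end, float(times[-1]))
        if seg_end <= seg_start + 1e-15:
            if end >= times[-1]:
                break
            continue
        mask = (times > seg_start + 1e-12) & (times <= seg_end + 1e-12)
        t_eval = times[mask]
        sol = solve_ivp(
            _rhs,
            (seg_start, seg_end),
            y,
            args=(setpoint, cell.hsf1_tot, params),
            method="LSODA",
            rtol=rtol,
            atol=atol,
            t_eval=t_eval if t_eval.size else None,
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed for {cell_id!r} in segment ({start}, {end}) "
                f"at t={sol.t[-1] if sol.t.size else seg_start:.4f} h: {sol.message}"
            )
        if t_eval.size:
            for j, idx in enumerate(np.nonzero(mask)[0]):
                samples[int(idx)] = sol.y[:, j]
        y = sol.y[:, -1]
        t_now = seg_end
        if t_now >= times[-1] - 1e-12:
            break

    f = np.empty_like(times)
    for idx in range(times.size):
        ys = samples[idx]
        mfp = max(float(ys[1]), 0.0)
        hsp = max(float(ys[2]), 0.0)
        total = hsp + mfp
        hsp_free = hsp / total if total > 0 else 0.0
        free = cell.hsf1_tot / (cell.hsf1_tot + hsp * hsp_free)
        f[idx] = min(max(free ** 3, 0.0), 1.0)

    fluor = np.full_like(times, cell.hsf1_tot)
    traj = CellTrajectory(
        cell_id=cell_id,
        times=times,
        f_values=f,
        total_fluorescence=fluor,
    )
    if with_states:
        states = np.column_stack([samples[i] for i in range(times.size)])
        return traj, states  # states rows: theta, mfp, hsp, mhsp
    return traj


def with_hsp0(cell: CellParameters, hsp0: float) -> CellParameters:
    """Copy of ``cell`` with a different initial chaperone level."""
    return replace(cell, hsp0=hsp0)
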