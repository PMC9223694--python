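"""Population-level descriptors of heat-shock-response heterogeneity.

All statistics operate on per-cell foci-fraction trajectories.  A cell is
a *responder* ("positive") if its F exceeds the 1 % foci detection limit
at some time during the hyperthermia window; responder status is assigned
once per cell and then held fixed when averaging dynamics, so that the
mean amplitude is not biased upward at low-F time points.

The shape of an individual response is summarised by the relaxation index
eta = F(3 h) / F(1 h): 0 means perfect adaptation (the signal returns to
baseline), 1 a plateau, and values above 1 a continuing increase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from hsr.model import CellTrajectory

__all__ = [
    "DETECTION_LIMIT",
    "ResponderCall",
    "AmplitudeSummary",
    "RelaxationHistogram",
    "HillFit",
    "call_responders",
    "responder_fraction",
    "fit_hill_curve",
    "mean_foci_dynamics",
    "amplitude_distribution",
    "relaxation_index",
    "relaxation_indices",
    "relaxation_histogram",
    "activation_function_by_ratio",
]

logger = logging.getLogger(__name__)

#: Foci detection limit: 1 % of HSF1:eGFP fluorescence localised in foci.
DETECTION_LIMIT = 0.01

#: Relaxation-index bin edges (eta regimes: adaptation, imperfect
#: adaptation, plateau, continuing increase).
RELAXATION_BIN_EDGES = (0.0, 0.25, 0.75, 1.25, np.inf)

#: Nearest-sample matching tolerance: half the 10-min sampling interval.
TIME_MATCH_TOL = 1.0 / 12.0


@dataclass(frozen=True)
class ResponderCall:
    """Responder status of one cell over the hyperthermia window."""

    cell_id: str
    is_positive: bool
    max_f: float


@dataclass(frozen=True)
class AmplitudeSummary:
    """Percentile summary (9/25/50/75/91) of F over responders at one time."""

    time_point: float
    p9: float
    p25: float
    p50: float
    p75: float
    p91: float
    n_cells: int

    def __post_init__(self) -> None:
        q = (self.p9, self.p25, self.p50, self.p75, self.p91)
        if any(a > b + 1e-12 for a, b in zip(q, q[1:])):
            raise ValueError("percentiles must be non-decreasing")


@dataclass(frozen=True)
class RelaxationHistogram:
    """Counts of responders per relaxation-index regime."""

    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    n_cells: int

    def __post_init__(self) -> None:
        if sum(self.counts) != self.n_cells:
            raise ValueError("counts must sum to the number of binned cells")


@dataclass(frozen=True)
class HillFit:
    """Hill summary of the responder fraction vs. stress temperature.

    fraction(T) = plateau * (T-37)^h / ((t50-37)^h + (T-37)^h)
    """

    t50: float
    hill_exponent: float
    plateau: float
    residual: float
    degenerate: bool = False

    def predict(self, temperature: np.ndarray) -> np.ndarray:
        dt = np.clip(np.asarray(temperature, dtype=float) - 37.0, 0.0, None)
        h = self.hill_exponent
        return self.plateau * dt ** h / ((self.t50 - 37.0) ** h + dt ** h)


def call_responders(
    trajectories: Iterable[CellTrajectory],
    threshold: float = DETECTION_LIMIT,
    window: tuple[float, float] = (0.0, 3.0),
) -> list[ResponderCall]:
    """Classify each cell by whether F strictly exceeds the detection limit.

    The maximum of F is taken over samples inside ``window`` (inclusive,
    default the 3 h hyperthermia phase); the comparison is strict
    (F > threshold), so a cell sitting exactly at the limit is negative.
    """
    t_lo, t_hi = window
    calls = []
    for traj in trajectories:
        mask = (traj.times >= t_lo - 1e-12) & (traj.times <= t_hi + 1e-12)
        if not mask.any():
            raise ValueError(f"cell {traj.cell_id!r} has no samples in window {window}")
        max_f = float(traj.f_values[mask].max())
        calls.append(ResponderCall(cell_id=traj.cell_id, is_positive=max_f > threshold, max_f=max_f))
    if not calls:
        raise ValueError("no trajectories supplied")
    return calls


def responder_fraction(calls: Sequence[ResponderCall]) -> float:
    """Fraction of cells called positive."""
    if not calls:
        raise ValueError("no responder calls supplied")
    return sum(c.is_positive for c in calls) / len(calls)


def fit_hill_curve(
    temperatures: Sequence[float], fractions: Sequence[float]
) -> HillFit:
    """Least-squares Hill fit of responder fraction vs. stress temperature.

    Serves as an eye-guide summary of the dose-response transition; the
    plateau is left free.  A degenerate input (no variation, all-zero
    fractions) is flagged rather than fitted.
    """
    temps = np.asarray(temperatures, dtype=float)
    fracs = np.asarray(fractions, dtype=float)
    if temps.size < 3:
        raise ValueError("need at least three temperature points")
    if temps.size != fracs.size:
        raise ValueError("temperatures and fractions must align")
    if np.all(fracs <= 0) or np.ptp(fracs) == 0:
        return HillFit(t50=np.nan, hill_exponent=np.nan, plateau=float(fracs.max()),
                       residual=0.0, degenerate=True)

    def hill(t, t50, h, plateau):
        dt = np.clip(t - 37.0, 1e-12, None)
        return plateau * dt ** h / ((t50 - 37.0) ** h + dt ** h)

    # initial guess: half-activation where the fraction crosses half its max
    t50_guess = float(temps[np.argmin(np.abs(fracs - fracs.max() / 2))])
    t50_guess = min(max(t50_guess, 37.5), 49.0)
    try:
        popt, _ = curve_fit(
            hill,
            temps,
            fracs,
            p0=(t50_guess, 8.0, float(fracs.max())),
            bounds=((37.01, 0.1, 0.0), (50.0, 100.0, 1.5)),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"Hill fit did not converge: {exc}") from exc
    residual = float(np.sqrt(np.mean((hill(temps, *popt) - fracs) ** 2)))
    return HillFit(t50=float(popt[0]), hill_exponent=float(popt[1]),
                   plateau=float(popt[2]), residual=residual)


def mean_foci_dynamics(
    trajectories: Sequence[CellTrajectory], calls: Sequence[ResponderCall]
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean of F over responders, on the common sampling grid.

    Restriction to responders keeps the amplitude readout independent of
    the non-responding fraction.  Returns ``(times, mean_f)``; empty with
    a warning when there is no positive cell.
    """
    positive_ids = {c.cell_id for c in calls if c.is_positive}
    chosen = [t for t in trajectories if t.cell_id in positive_ids]
    if not chosen:
        logger.warning("no positive cells: mean dynamics undefined")
        return np.array([]), np.array([])
    times = chosen[0].times
    for t in chosen[1:]:
        if t.times.shape != times.shape or not np.allclose(t.times, times):
            raise ValueError("trajectories must share one sampling grid")
    stack = np.vstack([t.f_values for t in chosen])
    return times.copy(), stack.mean(axis=0)


def amplitude_distribution(
    trajectories: Sequence[CellTrajectory],
    calls: Sequence[ResponderCall],
    time_points: Sequence[float] = (1.0, 3.0),
) -> list[AmplitudeSummary]:
    """Percentile summaries of F over responders at selected time points.

    Quartiles with 9th/91st-percentile whiskers, the box-plot convention
    used throughout; time points are matched to the nearest sample within
    5 minutes.
    """
    positive_ids = {c.cell_id for c in calls if c.is_positive}
    chosen = [t for t in trajectories if t.cell_id in positive_ids]
    if len(chosen) < 2:
        raise ValueError("amplitude distribution needs at least two positive cells")
    out = []
    for tp in time_points:
        values = np.array([t.f_at(tp, tol=TIME_MATCH_TOL) for t in chosen])
        p9, p25, p50, p75, p91 = np.percentile(values, [9, 25, 50, 75, 91])
        out.append(
            AmplitudeSummary(
                time_point=float(tp), p9=float(p9), p25=float(p25), p50=float(p50),
                p75=float(p75), p91=float(p91), n_cells=len(values),
            )
        )
    return out


def relaxation_index(trajectory: CellTrajectory) -> float:
    """Shape index eta = F(3 h) / F(1 h) for one responding cell.

    Undefined (raises) when F(1 h) is zero; callers batching over a
    population should use :func:`relaxation_indices`, which excludes and
    logs such cells.
    """
    f1 = trajectory.f_at(1.0, tol=TIME_MATCH_TOL)
    f3 = trajectory.f_at(3.0, tol=TIME_MATCH_TOL)
    if f1 <= 0.0:
        raise ValueError(f"cell {trajectory.cell_id!r}: F(1 h) = 0, relaxation index undefined")
    return f3 / f1


def relaxation_indices(
    trajectories: Sequence[CellTrajectory], calls: Sequence[ResponderCall]
) -> dict[str, float]:
    """Relaxation index per responder; cells with F(1 h) = 0 are dropped."""
    positive_ids = {c.cell_id for c in calls if c.is_positive}
    etas: dict[str, float] = {}
    for traj in trajectories:
        if traj.cell_id not in positive_ids:
            continue
        try:
            etas[traj.cell_id] = relaxation_index(traj)
        except ValueError:
            logger.info("cell %s excluded from relaxation index (F(1 h) = 0)", traj.cell_id)
    return etas


def relaxation_histogram(etas: Iterable[float]) -> RelaxationHistogram:
    """Histogram of eta over the four response-shape regimes.

    Contiguous half-open bins [0, 0.25), [0.25, 0.75), [0.75, 1.25),
    [1.25, inf): adaptation, imperfect adaptation, plateau, increase.
    """
    values = np.asarray(list(etas), dtype=float)
    if (values < 0).any():
        raise ValueError("relaxation index cannot be negative")
    edges = np.asarray(RELAXATION_BIN_EDGES)
    counts, _ = np.histogram(values, bins=edges)
    return RelaxationHistogram(
        bin_edges=tuple(edges), counts=tuple(int(c) for c in counts), n_cells=int(values.size)
    )


def activation_function_by_ratio(
    f_values: Sequence[float],
    chaperone_levels: Sequence[float],
    hsf1_levels: Sequence[float],
    min_class_size: int = 30,
    classes_per_decade: int = 8,
) -> list[dict]:
    """Quartiles of F binned by the chaperone-to-HSF1 expression ratio.

    Cells are segmented into logarithmically spaced ratio classes
    (expression is log-normal, so log spacing gives comparable occupancy);
    each class is summarised by the median and interquartile range of F.
    Classes with ``min_class_size`` cells or fewer are suppressed, and
    cells with non-positive expression levels are excluded and logged.

    Returns a list of dicts with keys ``ratio_low``, ``ratio_high``,
    ``ratio_mid`` (geometric midpoint), ``q25``, ``median``, ``q75``,
    ``n_cells``.
    """
    f = np.asarray(f_values, dtype=float)
    chap = np.asarray(chaperone_levels, dtype=float)
    hsf1 = np.asarray(hsf1_levels, dtype=float)
    if not (f.shape == chap.shape == hsf1.shape):
        raise ValueError("inputs must align")
    valid = (chap > 0) & (hsf1 > 0) & np.isfinite(f)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("excluded %d cells with non-positive expression levels", n_dropped)
    f, ratio = f[valid], chap[valid] / hsf1[valid]
    if ratio.size == 0:
        raise ValueError("no cells with positive expression levels")

    log_lo, log_hi = np.log10(ratio.min()), np.log10(ratio.max())
    n_classes = max(1, int(np.ceil((log_hi - log_lo) * classes_per_decade)))
    edges = np.logspace(log_lo, log_hi, n_classes + 1)
    edges[-1] *= 1.0 + 1e-12  # include the max ratio in the last class
    out = []
    for lo, hi in zip(edges, edges[1:]):
        mask = (ratio >= lo) & (ratio < hi)
        n = int(mask.sum())
        if n <= min_class_size:
            continue
        q25, med, q75 = np.percentile(f[mask], [25, 50, 75])
        out.append(
            {
                "ratio_low": float(lo),
                "ratio_high": float(hi),
                "ratio_mid": float(np.sqrt(lo * hi)),
                "q25": float(q25),
                "median": float(med),
                "q75": float(q75),
                "n_cells": n,
            }
        )
    return out
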