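"""Synthetic single-cell populations with log-normal expression noise.

Emulates the time-lapse experimental design: ~500 tracked cells per
condition, a 3 h hyperthermia step at 41-44 degC inside a normothermic
window, 10-minute sampling, log-normal cell-to-cell variability of the
chaperone and HSF1 levels, and a 2 % additive measurement error on the
foci fraction F.  Ground truth (the drawn expression levels) is emitted
alongside so every downstream statistic and the inference can be checked
against what generated the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from hsr.model import (
    CellParameters,
    ModelParameters,
    TemperatureProtocol,
    simulate_trajectory,
)
from hsr.inference import reference_steady_hsp

__all__ = [
    "PopulationSpec",
    "GroundTruth",
    "sample_lognormal",
    "generate_population",
    "condition_shift",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Design of one synthetic condition.

    ``hsp0_median=None`` resolves at generation time to the normothermic
    steady-state HSP concentration of the reference cell, so that the
    population is centred on a physiologically consistent level.  CVs are
    coefficients of variation of the log-normal expression distributions;
    the experimentally motivated defaults are 500 cells, 10-minute
    sampling, 3 h of stress and a 2 % measurement error on F.
    """

    n_cells: int = 500
    hsp0_median: float | None = None
    hsp0_cv: float = 0.4
    hsf1_median: float = 4.0e-2
    hsf1_cv: float = 0.4
    stress_temperature: float = 43.0
    stress_duration: float = 3.0
    pre_observation: float = 1.0 / 6.0
    post_observation: float = 1.0
    sampling_interval: float = 1.0 / 6.0
    noise_sigma: float = 0.02
    apply_detection_limit: bool = True
    detection_limit: float = 0.01
    fluorescence_scale: float = 1000.0
    fluorescence_noise_cv: float = 0.0
    hsp_hsf1_log_correlation: float = 0.0
    coating: str = "col-"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be at least 1")
        if self.hsp0_cv < 0 or self.hsf1_cv < 0:
            raise ValueError("coefficients of variation must be non-negative")
        if self.sampling_interval <= 0:
            raise ValueError("sampling interval must be positive")
        if not -1.0 <= self.hsp_hsf1_log_correlation <= 1.0:
            raise ValueError("log correlation must lie in [-1, 1]")

    def protocol(self) -> TemperatureProtocol:
        return TemperatureProtocol.step(
            self.stress_temperature,
            self.stress_duration,
            pre=max(self.pre_observation, self.sampling_interval),
            post=max(self.post_observation, self.sampling_interval),
        )

    def sampling_times(self) -> np.ndarray:
        """10-minute grid from one pre-stress baseline sample to the end."""
        n_pre = int(round(self.pre_observation / self.sampling_interval))
        n_post = int(round((self.stress_duration + self.post_observation) / self.sampling_interval))
        return np.arange(-n_pre, n_post + 1) * self.sampling_interval


@dataclass(frozen=True)
class GroundTruth:
    """Drawn per-cell expression levels for one generated population."""

    table: pd.DataFrame  # cell_id, true_hsp0_uM, true_hsf1_uM
    seed: int


def sample_lognormal(
    n: int, median: float, cv: float, rng: np.random.Generator | int
) -> np.ndarray:
    """Log-normal draws parameterised by median and coefficient of variation.

    X = median * exp(sigma Z) with sigma = sqrt(ln(1 + cv^2)), so the
    distribution median equals ``median`` and its CV equals ``cv``
    exactly; cv = 0 degenerates to a point mass at the median.
    """
    if not median > 0:
        raise ValueError("median must be positive")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if cv == 0:
        return np.full(n, float(median))
    sigma = np.sqrt(np.log1p(cv * cv))
    return median * np.exp(sigma * rng.standard_normal(n))


def _draw_expression(spec: PopulationSpec, hsp0_median: float, rng: np.random.Generator):
    """Correlated log-normal draws of (hsp0, hsf1_tot) for every cell."""
    rho = spec.hsp_hsf1_log_correlation
    z1 = rng.standard_normal(spec.n_cells)
    z2 = rng.standard_normal(spec.n_cells)
    z2 = rho * z1 + np.sqrt(1.0 - rho * rho) * z2
    s_hsp = np.sqrt(np.log1p(spec.hsp0_cv ** 2))
    s_hsf = np.sqrt(np.log1p(spec.hsf1_cv ** 2))
    hsp0 = hsp0_median * np.exp(s_hsp * z1)
    hsf1 = spec.hsf1_median * np.exp(s_hsf * z2)
    return hsp0, hsf1


def generate_population(
    spec: PopulationSpec,
    params: ModelParameters | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a full synthetic condition.

    For each cell: draw (hsp0, hsf1_tot), simulate the step protocol
    37 degC -> stress -> 37 degC via the kinetic model, pass F through
    the measurement model (foci below the 1 % detection limit record as
    0; detected samples get additive Gaussian noise, clipped to [0, 1])
    and report a constant total fluorescence proportional to hsf1_tot
    (optionally with multiplicative log-normal noise).  Setting
    ``apply_detection_limit=False`` yields the raw model F (plus noise
    on every sample, if any).

    Returns the trajectory table (long form, one row per cell and time
    point, columns ``cell_id, time_h, F, total_fluorescence,
    temperature_C, coating``) and the ground-truth sidecar.  Fully
    reproducible: identical (spec, seed) gives identical tables.
    """
    if params is None:
        params = ModelParameters()
    used_seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(used_seed)

    hsp0_median = spec.hsp0_median
    if hsp0_median is None:
        hsp0_median = reference_steady_hsp(params)

    hsp0s, hsf1s = _draw_expression(spec, hsp0_median, rng)
    protocol = spec.protocol()
    times = spec.sampling_times()

    n_digits = len(str(spec.n_cells - 1))
    rows = []
    truth_rows = []
    for i in range(spec.n_cells):
        cell_id = f"cell{i:0{n_digits}d}"
        cell = CellParameters(hsf1_tot=float(hsf1s[i]), hsp0=float(hsp0s[i]))
        try:
            traj = simulate_trajectory(cell, protocol, params, times, cell_id=cell_id)
        except RuntimeError as exc:
            raise RuntimeError(f"simulation failed for {cell_id}: {exc}") from exc
        f_true = traj.f_values
        if spec.apply_detection_limit:
            # foci holding less than the detection limit of the total
            # fluorescence are invisible to blob detection: recorded as 0;
            # measurement noise applies only to detected samples
            detected = f_true > spec.detection_limit
            f = np.zeros_like(f_true)
            f[detected] = f_true[detected]
            if spec.noise_sigma > 0 and detected.any():
                noise = spec.noise_sigma * rng.standard_normal(int(detected.sum()))
                f[detected] = np.clip(f[detected] + noise, 0.0, 1.0)
        else:
            f = f_true
            if spec.noise_sigma > 0:
                f = np.clip(f + spec.noise_sigma * rng.standard_normal(f.size), 0.0, 1.0)
        fluor = hsf1s[i] * spec.fluorescence_scale
        if spec.fluorescence_noise_cv > 0:
            s = np.sqrt(np.log1p(spec.fluorescence_noise_cv ** 2))
            fluor *= np.exp(s * rng.standard_normal())
        for t, f_t in zip(times, f):
            rows.append((cell_id, float(t), float(f_t), float(fluor),
                         spec.stress_temperature, spec.coating))
        truth_rows.append((cell_id, float(hsp0s[i]), float(hsf1s[i])))

    table = pd.DataFrame(
        rows, columns=["cell_id", "time_h", "F", "total_fluorescence", "temperature_C", "coating"]
    )
    truth = GroundTruth(
        table=pd.DataFrame(truth_rows, columns=["cell_id", "true_hsp0_uM", "true_hsf1_uM"]),
        seed=used_seed,
    )
    return table, truth


def condition_shift(spec: PopulationSpec, chaperone_median_factor: float) -> PopulationSpec:
    """Spec for a condition with shifted median chaperone expression.

    Models the collagen-coating (col+) effect as a multiplicative shift
    of the hsp0 median, everything else unchanged.  Requires the spec's
    hsp0_median to be resolved (a number, not None) when the factor is
    applied at generation time with a different reference; with the
    default None it is resolved first against the reference parameters.
    """
    if not chaperone_median_factor > 0:
        raise ValueError("factor must be positive")
    median = spec.hsp0_median
    if median is None:
        median = reference_steady_hsp(ModelParameters())
    return replace(spec, hsp0_median=median * chaperone_median_factor)
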