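"""Synthetic factorial data from a documented ground-truth response surface.

The experimental 192-run dataset behind the process is not publicly
deposited, so every downstream stage (surrogate training, optimization)
is exercised against a seeded generator instead.  The surface is a smooth
stand-in built to show the qualitative behaviour reported for the real
process:

* drying time (DT) falls with temperature, air velocity and target
  moisture content — the last stage of drying is slow, so stopping at a
  higher moisture content saves disproportionate time;
* specific energy consumption (SEC) tracks drying time scaled by
  equipment power, and falls with velocity and moisture content;
* kernel integrity (HR, WR) degrades as moisture content rises, and is
  best under sutural loading, then longitudinal, then vertical;
* shell-breaking rate (SR) falls with moisture content, gains above
  50 °C (shell hardening), and is highest under vertical loading.

Functional forms::

    DT  = A0 * (M0 - MC)^p / [(1 + aT*(T-40)) * (1 + aV*(V-1))]
    SEC = (P0 + cT*(T-40) + cV*(V-1)) * DT / (60 * mass)
    HR  = h0 - hM*(MC-10) + dir_HR
    WR  = HR * (w0 - wM*(MC-10)/100 + dir_WR)
    SR  = clip(s0 - sM*(MC-10) + sT*max(0, T-50) + dir_SR, 0, 100)

The default constants are calibration choices placing the grid extremes
near the magnitudes of the published optimization results (DT roughly
87–1200 min, SEC roughly 1.3–17 MJ/kg, HR 48–89 %, WR 21–52 %, SR
62–99.5 %); they are not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import (
    CONDITION_BOUNDS,
    FACTORIAL_LEVELS,
    FactorialDataset,
    ProcessCondition,
    ResponseVector,
    ValidationError,
    COLUMNS,
)

import pandas as pd


@dataclass(frozen=True)
class SurfaceParams:
    """Coefficients of the synthetic ground-truth response surface.

    Direction-offset triples are ordered (sutural, longitudinal, vertical).
    """

    initial_moisture: float = 30.12  # % d.b. of the fresh commodity
    dt_scale: float = 9.81           # A0, min
    dt_moisture_exponent: float = 1.6
    dt_temp_coeff: float = 0.015     # per °C above 40
    dt_velocity_coeff: float = 0.09  # per m/s above 1
    power_base: float = 1.7          # equipment power scale
    power_temp_coeff: float = 0.01
    power_velocity_coeff: float = 0.02
    batch_mass: float = 2.0          # kg of walnuts per run
    hr_base: float = 87.0
    hr_mc_slope: float = 2.4         # % per %MC
    hr_direction_offsets: tuple[float, float, float] = (2.0, 0.0, -3.0)
    wr_base: float = 0.57            # WR/HR fraction at MC = 10
    wr_mc_slope: float = 0.75        # per %MC, divided by 100 in the form
    wr_direction_offsets: tuple[float, float, float] = (0.01, 0.0, -0.015)
    sr_base: float = 86.5
    sr_mc_slope: float = 1.5
    sr_temp_gain: float = 1.8        # % per °C above the hardening threshold
    sr_temp_threshold: float = 50.0
    sr_direction_offsets: tuple[float, float, float] = (-2.0, 0.0, 4.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise per response (DT, SEC, HR, WR, SR order).

    Defaults are small relative to the signal spans so that surrogate
    recovery is a meaningful check rather than a noise-fitting exercise.
    """

    sigma: tuple[float, float, float, float, float] = (10.0, 0.2, 1.5, 1.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sigma):
            raise ValidationError(f"noise sigmas must be >= 0: {self.sigma}")


def _check_box(X: np.ndarray) -> None:
    for j, name in enumerate(("T", "V", "MC")):
        lo, hi = CONDITION_BOUNDS[name]
        if np.any(X[:, j] < lo) or np.any(X[:, j] > hi):
            raise ValidationError(f"{name} outside [{lo}, {hi}]")
    if not np.all(np.isin(X[:, 3].astype(int), (1, 2, 3))):
        raise ValidationError("D must be 1, 2 or 3")


def true_response_array(X: np.ndarray, params: SurfaceParams) -> np.ndarray:
    """Vectorized noise-free surface: (n, 4) conditions -> (n, 5) responses."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    _check_box(X)
    T, V, MC = X[:, 0], X[:, 1], X[:, 2]
    D = X[:, 3].astype(int)
    p = params

    dt = (
        p.dt_scale
        * (p.initial_moisture - MC) ** p.dt_moisture_exponent
        / ((1.0 + p.dt_temp_coeff * (T - 40.0)) * (1.0 + p.dt_velocity_coeff * (V - 1.0)))
    )
    power = p.power_base + p.power_temp_coeff * (T - 40.0) + p.power_velocity_coeff * (V - 1.0)
    sec = power * dt / (60.0 * p.batch_mass)

    hr_dir = np.asarray(p.hr_direction_offsets)[D - 1]
    hr = p.hr_base - p.hr_mc_slope * (MC - 10.0) + hr_dir

    wr_dir = np.asarray(p.wr_direction_offsets)[D - 1]
    wr = hr * (p.wr_base - p.wr_mc_slope * (MC - 10.0) / 100.0 + wr_dir)

    sr_dir = np.asarray(p.sr_direction_offsets)[D - 1]
    sr = np.clip(
        p.sr_base
        - p.sr_mc_slope * (MC - 10.0)
        + p.sr_temp_gain * np.maximum(0.0, T - p.sr_temp_threshold)
        + sr_dir,
        0.0,
        100.0,
    )
    return np.column_stack([dt, sec, hr, wr, sr])


def true_response(
    condition: ProcessCondition, params: SurfaceParams = SurfaceParams()
) -> ResponseVector:
    """Deterministic surface response at one condition."""
    y = true_response_array(condition.as_array()[None, :], params)[0]
    return ResponseVector(*y)


def _clip_responses(Y: np.ndarray) -> np.ndarray:
    """Clip noisy draws back into the valid response ranges (never resample,
    so seed determinism is preserved)."""
    Y = Y.copy()
    Y[:, 0] = np.maximum(Y[:, 0], 1.0)          # DT > 0
    Y[:, 1] = np.maximum(Y[:, 1], 0.01)         # SEC > 0
    Y[:, 2] = np.clip(Y[:, 2], 0.0, 100.0)      # HR
    Y[:, 3] = np.clip(Y[:, 3], 0.0, Y[:, 2])    # 0 <= WR <= HR
    Y[:, 4] = np.clip(Y[:, 4], 0.0, 100.0)      # SR
    return Y


def generate_dataset(
    params: SurfaceParams = SurfaceParams(),
    noise: NoiseSpec = NoiseSpec(),
    design: dict[str, tuple] | None = None,
) -> FactorialDataset:
    """Seeded factorial dataset: one record per design cell (default 192),
    response = true surface + clipped Gaussian noise."""
    levels = dict(FACTORIAL_LEVELS)
    if design is not None:
        levels.update(design)
    if any(len(v) == 0 for v in levels.values()):
        raise ValidationError("design has an empty level list")
    cells = [
        (t, v, mc, d)
        for t in levels["T"]
        for v in levels["V"]
        for mc in levels["MC"]
        for d in levels["D"]
    ]
    X = np.array(cells, dtype=float)
    Y = true_response_array(X, params)
    rng = np.random.default_rng(noise.seed)
    Y = _clip_responses(Y + rng.normal(0.0, noise.sigma, size=Y.shape))
    frame = pd.DataFrame(np.column_stack([X, Y]), columns=COLUMNS)
    frame["D"] = frame["D"].astype(int)
    return FactorialDataset(frame, provenance="synthetic")


def generate_validation_point(
    params: SurfaceParams,
    noise: NoiseSpec,
    condition: ProcessCondition,
) -> tuple[ProcessCondition, ResponseVector]:
    """One noisy observation at an arbitrary (possibly off-grid) condition,
    emulating a hold-out validation run."""
    rng = np.random.default_rng(noise.seed)
    y = true_response_array(condition.as_array()[None, :], params)
    y = _clip_responses(y + rng.normal(0.0, noise.sigma, size=y.shape))[0]
    return condition, ResponseVector(*y)
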