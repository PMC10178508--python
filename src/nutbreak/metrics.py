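"""Process metrics, model scores and report-table arithmetic.

Process side: kernel-integrity rates from class masses, shell-breaking rate
from crack counts, dry-basis moisture content, specific energy consumption,
shell–kernel clearance and shell hardness.  Model side: RMSE and R² per
response, plus the derived percentages used in comparison reports
(relative prediction error, percent change versus a reference solution, and
RMSE reduction of one model versus a baseline).

All functions compute at full precision; rounding to the report precision
(one or two decimals) is left to the report writers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dataset import RESPONSE_COLUMNS, ValidationError


@dataclass(frozen=True)
class KernelMassBreakdown:
    """Masses (g) of kernel integrity classes: A whole, B half, C quarter,
    D crushed."""

    M_A: float
    M_B: float
    M_C: float
    M_D: float

    def __post_init__(self) -> None:
        masses = (self.M_A, self.M_B, self.M_C, self.M_D)
        if any(m < 0 for m in masses):
            raise ValidationError(f"kernel class masses must be >= 0: {masses}")
        if not sum(masses) > 0:
            raise ValidationError("total kernel mass must be > 0")

    @property
    def total(self) -> float:
        return self.M_A + self.M_B + self.M_C + self.M_D


@dataclass(frozen=True)
class BreakCount:
    """L walnuts cracked over more than 3/4 of their extent, of N total."""

    L: int
    N: int

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValidationError(f"N={self.N} must be > 0")
        if not 0 <= self.L <= self.N:
            raise ValidationError(f"need 0 <= L <= N, got L={self.L}, N={self.N}")


@dataclass(frozen=True)
class ShellGeometry:
    """Maximum inner-wall dimensions A/B/C, kernel dimensions a/b/c
    (longitudinal, vertical, sutural; mm) and shell thickness d (mm)."""

    A: float
    B: float
    C: float
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        dims = (self.A, self.B, self.C, self.a, self.b, self.c, self.d)
        if any(x <= 0 for x in dims):
            raise ValidationError(f"all dimensions must be > 0: {dims}")
        if self.A < self.a or self.B < self.b or self.C < self.c:
            raise ValidationError("shell inner wall must enclose the kernel")


@dataclass(frozen=True)
class EvaluationScores:
    """Per-response R² (dimensionless) and RMSE (units of the response)."""

    r2: Mapping[str, float]
    rmse: Mapping[str, float]

    def __post_init__(self) -> None:
        for name in RESPONSE_COLUMNS:
            if name not in self.r2 or name not in self.rmse:
                raise ValidationError(f"missing scores for response {name}")
            if self.rmse[name] < 0:
                raise ValidationError(f"RMSE[{name}] must be >= 0")


def high_kernel_rate(masses: KernelMassBreakdown) -> float:
    """Mass percentage of kernels not completely crushed (classes A+B+C)."""
    # clamp: the quotient may exceed 1 by one ulp when M_D is tiny
    return min(100.0, 100.0 * (masses.M_A + masses.M_B + masses.M_C) / masses.total)


def whole_kernel_rate(masses: KernelMassBreakdown) -> float:
    """Mass percentage of fully intact kernels (class A only)."""
    return min(100.0, 100.0 * masses.M_A / masses.total)


def shell_breaking_rate(counts: BreakCount) -> float:
    """Percentage of walnuts cracked over more than 3/4 of their extent."""
    return 100.0 * counts.L / counts.N


def moisture_content(W_T: float, W_d: float) -> float:
    """Dry-basis moisture content (%) from wet mass W_T and dry mass W_d."""
    if W_d <= 0:
        raise ZeroDivisionError(f"dry mass must be > 0, got {W_d}")
    if W_T < W_d:
        raise ValidationError(f"wet mass {W_T} below dry mass {W_d}")
    return 100.0 * (W_T - W_d) / W_d


def specific_energy_consumption(E: float, m: float) -> float:
    """Electrical energy E (MJ) per kilogram of walnuts dried."""
    if m <= 0:
        raise ZeroDivisionError(f"walnut mass must be > 0, got {m}")
    return E / m


def shell_kernel_clearance(geom: ShellGeometry) -> float:
    """Mean shell-to-kernel gap (mm) over the three axes:
    (A + B + C - a - b - c - 6d) / 6."""
    return (geom.A + geom.B + geom.C - geom.a - geom.b - geom.c - 6.0 * geom.d) / 6.0


def shell_hardness(F_r: float, D_r: float) -> float:
    """Shell hardness (N/mm): maximum breaking force over deformation at
    that force."""
    if D_r <= 0:
        raise ZeroDivisionError(f"deformation must be > 0, got {D_r}")
    return F_r / D_r


def rmse(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Root mean square error, in the units of the response."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.size == 0:
        raise ValidationError(
            f"need equal nonzero lengths, got {a.shape} and {p.shape}"
        )
    return float(np.sqrt(np.mean((a - p) ** 2)))


def r_squared(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination 1 - SSR/SST."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.size < 2:
        raise ValidationError(
            f"need equal lengths >= 2, got {a.shape} and {p.shape}"
        )
    sst = float(np.sum((a - a.mean()) ** 2))
    if sst == 0.0:
        raise ZeroDivisionError("actual values are constant; R² undefined")
    ssr = float(np.sum((a - p) ** 2))
    return 1.0 - ssr / sst


def relative_error_percent(predicted: float, experimental: float) -> float:
    """Absolute prediction error as a percentage of the experimental value."""
    if experimental == 0:
        raise ZeroDivisionError("experimental value must be nonzero")
    return 100.0 * abs(predicted - experimental) / experimental


def percent_change(value: float, reference: float) -> float:
    """Signed percent change of ``value`` relative to ``reference``."""
    if reference == 0:
        raise ZeroDivisionError("reference value must be nonzero")
    return 100.0 * (value - reference) / reference


def rmse_reduction_percent(rmse_baseline: float, rmse_new: float) -> float:
    """Percentage by which a model's RMSE improves on a baseline's."""
    if rmse_baseline <= 0:
        raise ZeroDivisionError(
            f"baseline RMSE must be > 0, got {rmse_baseline}"
        )
    return 100.0 * (rmse_baseline - rmse_new) / rmse_baseline
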