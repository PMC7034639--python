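"""Logan graphical analysis with a reference tissue.

For reversible tracer kinetics the transformed coordinates

    y(T) = ∫₀ᵀ C_t dt / C_t(T)
    x(T) = [∫₀ᵀ C_ref dt + C_ref(T)/k2'] / C_t(T)

become linear after an equilibration time t*, with slope equal to the
distribution-volume ratio (DVR) between target and reference region.  With a
fast-clearing reference the C_ref(T)/k2' term is small and is omitted by
default (its effect is absorbed into the intercept); an explicit k2' can be
supplied.  Because the reference region stands in for arterial blood, the
slope is a DVR, not an absolute DV — studies that report reference-tissue
"DV" per region are reporting this quantity.

Integrals use the trapezoidal rule with an implicit (0, 0) sample at
injection; the late-phase line is fitted by ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import ParameterError
from .io import TimeActivityCurve


@dataclass(frozen=True)
class LoganPoints:
    """Transformed (x, y) coordinates at each usable frame time."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class LoganResult:
    region_name: str
    reference_name: str
    dvr_slope: float          # the reference-tissue "DV" readout
    intercept: float          # min
    t_star: float             # min
    r_squared: float          # from the fitted late-phase points only
    n_points_used: int
    k2prime_used: Union[float, str] = "omitted"

    def to_dict(self) -> dict:
        return {
            "region": self.region_name,
            "reference": self.reference_name,
            "dvr": self.dvr_slope,
            "dv_paper": self.dvr_slope,   # alias: reference-tissue DV readout
            "intercept_min": self.intercept,
            "t_star_min": self.t_star,
            "r_squared": self.r_squared,
            "n_points_used": self.n_points_used,
            "k2prime": self.k2prime_used,
        }


def cumulative_integral(tac: TimeActivityCurve) -> np.ndarray:
    """Running ∫₀ᵗ of a TAC at each frame midpoint (µCi·min/g).

    The curve is taken as 0 at injection (t = 0) and integrated by the
    trapezoidal rule; non-decreasing for non-negative TACs.
    """
    t = np.concatenate([[0.0], tac.times])
    v = np.concatenate([[0.0], tac.values])
    if np.any(np.diff(t) <= 0):
        raise ParameterError("TAC times must be strictly increasing and positive")
    return cumulative_trapezoid(v, t)


def logan_transform(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    k2prime: Optional[float] = None,
) -> LoganPoints:
    """Transform a target/reference TAC pair into Logan coordinates.

    Frames where the target concentration is not strictly positive cannot be
    transformed and are skipped with a warning.
    """
    if len(target.times) != len(reference.times) or not np.allclose(
        target.times, reference.times
    ):
        raise ParameterError("target and reference TACs must share one time grid")
    if k2prime is not None and k2prime <= 0:
        raise ParameterError("k2prime must be positive when given")

    int_t = cumulative_integral(target)
    int_r = cumulative_integral(reference)
    ct = target.values
    usable = ct > 0
    if not usable.all():
        warnings.warn(
            f"skipping {int((~usable).sum())} Logan points with non-positive "
            f"target concentration",
            stacklevel=2,
        )
    num_x = int_r + (reference.values / k2prime if k2prime is not None else 0.0)
    x = num_x[usable] / ct[usable]
    y = int_t[usable] / ct[usable]
    return LoganPoints(times=target.times[usable], x=x, y=y)


def fit_logan(
    points: LoganPoints,
    t_star: float,
    region_name: str = "",
    reference_name: str = "",
    k2prime_used: Union[float, str] = "omitted",
) -> LoganResult:
    """OLS line through the Logan points with time ≥ t*; slope is the DVR."""
    m = points.times >= t_star
    n = int(m.sum())
    if n < 3:
        raise ParameterError(f"need at least 3 points at or after t* = {t_star} min, got {n}")
    x, y = points.x[m], points.y[m]
    if np.ptp(x) <= 0 or np.var(x) == 0:
        raise ParameterError("degenerate Logan fit: x values have no variance")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return LoganResult(
        region_name=region_name,
        reference_name=reference_name,
        dvr_slope=float(slope),
        intercept=float(intercept),
        t_star=float(t_star),
        r_squared=r2,
        n_points_used=n,
        k2prime_used=k2prime_used,
    )


def select_t_star(points: LoganPoints, max_rel_error: float = 0.10) -> float:
    """Earliest start time after which the Logan plot is acceptably linear.

    Candidates are the point times (keeping ≥ 3 fitted points); the first
    whose OLS fit over all subsequent points has maximum relative residual
    ≤ *max_rel_error* wins.  If none qualifies, falls back to the latest
    third of the scan with a warning.
    """
    if len(points) < 4:
        raise ParameterError("need at least 4 points to select t*")
    for i in range(len(points) - 2):
        t_cand = float(points.times[i])
        x, y = points.x[i:], points.y[i:]
        if np.var(x) == 0:
            continue
        slope, intercept = np.polyfit(x, y, 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(y - (slope * x + intercept)) / np.abs(y)
        if np.nanmax(rel) <= max_rel_error:
            return t_cand
    fallback = float(points.times[0] + 2.0 / 3.0 * (points.times[-1] - points.times[0]))
    warnings.warn(
        f"no t* candidate met max relative residual {max_rel_error}; "
        f"falling back to the latest third of the scan (t* = {fallback:.1f} min)",
        stacklevel=2,
    )
    return fallback


def logan_dvr(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    t_star: Optional[float] = None,
    k2prime: Optional[float] = None,
    max_rel_error: float = 0.10,
) -> LoganResult:
    """Convenience wrapper: transform, pick t* if not given, fit."""
    points = logan_transform(target, reference, k2prime=k2prime)
    if t_star is None:
        t_star = select_t_star(points, max_rel_error=max_rel_error)
    return fit_logan(
        points,
        t_star,
        region_name=target.region_name,
        reference_name=reference.region_name,
        k2prime_used="omitted" if k2prime is None else float(k2prime),
    )
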