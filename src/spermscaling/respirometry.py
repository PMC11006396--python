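"""Closed-chamber respirometry: % air saturation traces to V̇O₂.

A sensor-dish chamber of known volume holds an air-saturated sperm
suspension; dissolved oxygen, expressed as percent air saturation (% AS),
is logged about once a minute. Processing mirrors standard practice:

1. restrict the trace to a saturation window (default 100–75% AS) so that
   rates are compared over similar oxygen regimes and oxy-conformity at
   low saturation does not bias the slope;
2. take the steepest well-determined local linear slope (% AS h⁻¹) by
   exhaustive search over contiguous windows, minimizing SE(slope)/|slope|;
3. subtract the mean slope of sperm-free control chambers (background
   drift and microbial respiration);
4. convert the net decline to an oxygen consumption rate via the oxygen
   capacitance of the air-saturated medium and the chamber volume:

       V̇O₂ [µl O₂ h⁻¹] = |slope|/100 × capacitance [µl O₂ ml⁻¹] × volume [ml]

Defaults correspond to seawater at 21°C (capacitance 5.11 ml O₂ l⁻¹,
numerically equal to µl O₂ ml⁻¹) in 750 µl chambers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

DEFAULT_UPPER = 100.0  # % AS
DEFAULT_LOWER = 75.0  # % AS
DEFAULT_CAPACITANCE = 5.11  # ml O2 per litre of air-saturated seawater at 21°C
DEFAULT_VOLUME_UL = 750.0  # chamber volume, µl
MIN_POINTS = 5


@dataclass
class OxygenTrace:
    """A timestamped % air-saturation series for one chamber."""

    times: np.ndarray  # minutes
    saturation: np.ndarray  # % air saturation
    chamber_id: str = ""
    is_control: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.saturation = np.asarray(self.saturation, dtype=float)
        if self.times.shape != self.saturation.shape:
            raise ValueError("times and saturation must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError(f"chamber {self.chamber_id!r}: times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class SlopeEstimate:
    """An OLS slope over one contiguous window of a trace."""

    slope: float  # % AS h^-1
    standard_error: float  # % AS h^-1
    window: tuple[int, int]  # [start, stop) indices into the filtered trace
    n_points: int
    chamber_id: str = ""


def saturation_filter(
    trace: OxygenTrace,
    upper: float = DEFAULT_UPPER,
    lower: float = DEFAULT_LOWER,
) -> OxygenTrace:
    """Restrict a trace to the saturation analysis window.

    Leading points above ``upper`` are skipped; the returned subseries then
    runs while saturation stays within ``[lower, upper]`` and stops at the
    first excursion. A chamber that never enters the window (e.g. one that
    started well below ``lower`` because oxygen was already depleted)
    yields an empty trace, which callers treat as "exclude this chamber".
    """
    if not upper > lower:
        raise ValueError(f"upper ({upper}) must exceed lower ({lower})")
    sat = trace.saturation
    n = len(trace)
    start = 0
    while start < n and sat[start] > upper:
        start += 1
    if start >= n or sat[start] < lower:
        return OxygenTrace(
            np.empty(0), np.empty(0), chamber_id=trace.chamber_id, is_control=trace.is_control
        )
    stop = start
    while stop < n and lower <= sat[stop] <= upper:
        stop += 1
    return OxygenTrace(
        trace.times[start:stop],
        sat[start:stop],
        chamber_id=trace.chamber_id,
        is_control=trace.is_control,
    )


def _ols_slope_min(times: np.ndarray, sat: np.ndarray) -> tuple[float, float]:
    """OLS slope and its SE in % AS per minute."""
    m = times.size
    tbar = times.mean()
    sbar = sat.mean()
    dt = times - tbar
    sxx = float(dt @ dt)
    slope = float(dt @ (sat - sbar)) / sxx
    resid = sat - sbar - slope * dt
    dof = m - 2
    sigma2 = float(resid @ resid) / dof
    se = math.sqrt(max(sigma2, 0.0) / sxx)
    return slope, se


def best_local_slope(
    trace: OxygenTrace, min_window_fraction: float = 1.0 / 3.0
) -> SlopeEstimate:
    """Steadiest local decline: exhaustive contiguous-window OLS search.

    Every contiguous window of at least ``max(5, ⌈fraction·n⌉)`` points is
    fit by ordinary least squares; the window minimizing the relative
    slope error SE(slope)/|slope| wins. Ties go to the longer window, then
    the earlier start, making the choice deterministic. Slope and SE are
    returned in % AS per hour.
    """
    n = len(trace)
    min_size = max(MIN_POINTS, math.ceil(min_window_fraction * n))
    if n < min_size:
        raise ValueError(
            f"chamber {trace.chamber_id!r}: {n} points < minimum window {min_size}"
        )
    best: tuple[float, int, int] | None = None  # (criterion, -length, start)
    best_est: SlopeEstimate | None = None
    for start in range(0, n - min_size + 1):
        for stop in range(start + min_size, n + 1):
            t = trace.times[start:stop]
            s = trace.saturation[start:stop]
            slope, se = _ols_slope_min(t, s)
            crit = se / abs(slope) if slope != 0.0 else math.inf
            # relative errors at rounding level are exact ties, so a
            # noise-free trace resolves to the longest window
            if crit < 1e-12:
                crit = 0.0
            key = (crit, -(stop - start), start)
            if best is None or key < best:
                best = key
                best_est = SlopeEstimate(
                    slope=slope * 60.0,
                    standard_error=se * 60.0,
                    window=(start, stop),
                    n_points=stop - start,
                    chamber_id=trace.chamber_id,
                )
    assert best_est is not None
    return best_est


def control_corrected_slope(
    sample: SlopeEstimate, controls: list[SlopeEstimate]
) -> float:
    """Net decline: sample slope minus the arithmetic mean of control
    slopes (% AS h⁻¹)."""
    if not controls:
        raise ValueError("at least one control slope is required")
    control_mean = sum(c.slope for c in controls) / len(controls)
    return sample.slope - control_mean


def slope_to_vo2(
    net_slope: float,
    capacitance: float = DEFAULT_CAPACITANCE,
    volume: float = DEFAULT_VOLUME_UL,
) -> float:
    """Convert a net saturation decline to oxygen consumption.

    Parameters
    ----------
    net_slope : control-corrected decline, % AS h⁻¹ (negative = consuming).
    capacitance : oxygen content of the air-saturated medium, ml O₂ l⁻¹
        (numerically µl O₂ per ml of medium).
    volume : chamber volume in µl.

    Returns V̇O₂ in µl O₂ h⁻¹. A non-negative net slope (chamber gaining
    oxygen after correction) maps to 0 with a warning rather than a
    negative respiration rate.
    """
    if not (capacitance > 0):
        raise ValueError(f"capacitance must be > 0, got {capacitance!r}")
    if not (volume > 0):
        raise ValueError(f"volume must be > 0, got {volume!r}")
    if net_slope > 0:
        warnings.warn(
            "positive net slope (oxygen increasing after control correction); "
            "clamping V̇O2 to 0",
            stacklevel=2,
        )
    decline = abs(min(net_slope, 0.0))
    return decline / 100.0 * capacitance * (volume / 1000.0)


def process_trace(
    sample: OxygenTrace,
    controls: list[OxygenTrace],
    upper: float = DEFAULT_UPPER,
    lower: float = DEFAULT_LOWER,
    capacitance: float = DEFAULT_CAPACITANCE,
    volume: float = DEFAULT_VOLUME_UL,
    min_window_fraction: float = 1.0 / 3.0,
) -> tuple[SlopeEstimate, float]:
    """Full single-chamber pipeline: filter → local slope → control
    correction → V̇O₂. Returns the sample slope estimate and V̇O₂.

    Raises ``ValueError`` when the sample trace never enters the
    saturation window (the chamber must be excluded).
    """
    filtered = saturation_filter(sample, upper=upper, lower=lower)
    if len(filtered) == 0:
        raise ValueError(
            f"chamber {sample.chamber_id!r}: no points within "
            f"[{lower}, {upper}]% AS; exclude this chamber"
        )
    est = best_local_slope(filtered, min_window_fraction=min_window_fraction)
    control_ests = []
    for ctrl in controls:
        cf = saturation_filter(ctrl, upper=upper, lower=lower)
        if len(cf) >= MIN_POINTS:
            control_ests.append(best_local_slope(cf, min_window_fraction=min_window_fraction))
    if not control_ests:
        raise ValueError("no usable control trace within the saturation window")
    net = control_corrected_slope(est, control_ests)
    return est, slope_to_vo2(net, capacitance=capacitance, volume=volume)
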