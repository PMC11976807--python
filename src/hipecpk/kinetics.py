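"""Closed-form two-compartment kinetics: zero-order tissue input, first-order loss.

During perfusion the abdominal cavity acts as a drug reservoir (central
compartment) feeding the tissue (peripheral compartment) at a constant
zero-order rate until the supply is exhausted at time ``t_in``; the tissue
eliminates the drug first-order with rate constant ``k_e``.  With the tissue
starting drug-free this gives the piecewise closed form

    C(t) = (k_in/k_e) · (1 − e^{−k_e t})            for 0 ≤ t ≤ t_in
    C(t) = C(t_in) · e^{−k_e (t − t_in)}            for t > t_in

which rises to a single peak at exactly t_in and decays mono-exponentially
after.  Only the tissue concentration is observed, so the central
compartment's initial amount, transfer rate and bolus schedule are not
separately identifiable: they collapse into (k_in, t_in, k_e), the
parameterization estimated here.  ``map_central_parameterization`` documents
the correspondence with the reservoir description.

Units: concentration µg/mL, time min, k_in µg·mL⁻¹·min⁻¹, k_e min⁻¹.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PKParams",
    "DerivedPK",
    "CentralMapping",
    "concentration_at",
    "cumulative_auc",
    "interval_average",
    "derived_parameters",
    "map_central_parameterization",
]


@dataclass(frozen=True)
class PKParams:
    """Structural kinetic parameters for one concentration–time curve.

    k_in : zero-order rise rate of tissue concentration (µg·mL⁻¹·min⁻¹)
    t_in : duration of the input window (min); the peak occurs here
    k_e  : first-order elimination rate constant (min⁻¹)
    """

    k_in: float
    t_in: float
    k_e: float

    def __post_init__(self) -> None:
        if self.k_in < 0:
            raise ValueError(f"k_in must be >= 0, got {self.k_in}")
        if not self.t_in > 0:
            raise ValueError(f"t_in must be > 0, got {self.t_in}")
        if not self.k_e > 0:
            raise ValueError(f"k_e must be > 0, got {self.k_e}")


@dataclass(frozen=True)
class DerivedPK:
    """Derived exposure metrics for one fitted curve (all non-negative)."""

    auc_0_last: float  # µg·min/mL, model AUC from 0 to the last sample time
    c_max: float  # µg/mL
    t_max: float  # min
    t_half: float  # min


def _conc(k_in: float, t_in: float, k_e: float, t: np.ndarray) -> np.ndarray:
    c_peak = (k_in / k_e) * -np.expm1(-k_e * t_in)
    rising = (k_in / k_e) * -np.expm1(-k_e * t)
    falling = c_peak * np.exp(-k_e * np.maximum(t - t_in, 0.0))
    return np.where(t <= t_in, rising, falling)


def _cumint(k_in: float, t_in: float, k_e: float, t: np.ndarray) -> np.ndarray:
    """∫₀ᵗ C(s) ds from the analytic antiderivative of the piecewise form."""
    c_peak = (k_in / k_e) * -np.expm1(-k_e * t_in)
    rise = (k_in / k_e) * (t + np.expm1(-k_e * t) / k_e)
    rise_full = (k_in / k_e) * (t_in + np.expm1(-k_e * t_in) / k_e)
    tail = rise_full + (c_peak / k_e) * -np.expm1(-k_e * np.maximum(t - t_in, 0.0))
    return np.where(t <= t_in, rise, tail)


def concentration_at(params: PKParams, t):
    """Tissue concentration C(t); accepts scalar or array times, t ≥ 0."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    out = _conc(params.k_in, params.t_in, params.k_e, t_arr)
    return float(out) if np.ndim(t) == 0 else out


def cumulative_auc(params: PKParams, t):
    """Analytic ∫₀ᵗ C(s) ds; scalar or array t ≥ 0."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    out = _cumint(params.k_in, params.t_in, params.k_e, t_arr)
    return float(out) if np.ndim(t) == 0 else out


def interval_average(params: PKParams, start, end):
    """Mean concentration over a collection interval.

    Microdialysis samples integrate the concentration over the collection
    window, so the model prediction for one sample is
    ``(1/(end−start)) ∫ C(t) dt`` — computed analytically, including
    intervals straddling t_in.  Vectorized over paired start/end arrays.
    """
    s = np.asarray(start, dtype=float)
    e = np.asarray(end, dtype=float)
    if np.any(s < 0) or np.any(e <= s):
        raise ValueError("intervals require 0 <= start < end")
    out = (_cumint(params.k_in, params.t_in, params.k_e, e) - _cumint(params.k_in, params.t_in, params.k_e, s)) / (
        e - s
    )
    return float(out) if np.ndim(start) == 0 and np.ndim(end) == 0 else out


def derived_parameters(params: PKParams, t_last: float) -> DerivedPK:
    """Derived PK metrics of the fitted curve up to the last sampling time.

    The curve peaks exactly at the end of the input window, so
    t_max = t_in, c_max = C(t_in), t_half = ln2/k_e, and AUC_0–last is the
    analytic integral to ``t_last``.  If the sampling window ends before the
    input does, t_max is clamped to t_last with a warning (peak not observed).
    """
    if not t_last > 0:
        raise ValueError("t_last must be > 0")
    t_max = params.t_in
    if t_last <= params.t_in:
        warnings.warn(
            f"t_last={t_last} <= t_in={params.t_in}: peak not reached in window; clamping t_max"
        )
        t_max = t_last
    return DerivedPK(
        auc_0_last=cumulative_auc(params, t_last),
        c_max=concentration_at(params, t_max),
        t_max=t_max,
        t_half=math.log(2.0) / params.k_e,
    )


@dataclass(frozen=True)
class CentralMapping:
    """Result of mapping the reservoir (central-compartment) description.

    ``windows`` lists the time intervals during which the central compartment
    holds drug and the zero-order input is active.  When the bolus schedule
    keeps the reservoir non-empty until a single depletion time (the default
    assumption, consistent with unimodal observed curves), ``contiguous`` is
    True and ``params`` is the equivalent identifiable parameterization.
    """

    params: PKParams
    windows: tuple[tuple[float, float], ...]
    contiguous: bool


def map_central_parameterization(
    c0_central: float,
    transfer_rate: float,
    doses: list[tuple[float, float]] | None = None,
    volume_scale: float = 1.0,
) -> CentralMapping:
    """Convert the reservoir description into identifiable (k_in, t_in, k_e) form.

    The central compartment starts with ``c0_central`` (concentration
    equivalents), is topped up by ``doses`` (time, amount) scaled by
    ``volume_scale``, and is depleted at the constant ``transfer_rate``
    feeding the tissue.  Total input divided by the transfer rate gives the
    input duration; if the reservoir empties between boluses the input is a
    union of windows rather than one interval (``contiguous=False``), and
    ``t_in`` in the returned params is the *total active duration* — callers
    wanting gap-aware predictions should use ``windows`` directly.

    Elimination is a tissue property and is not determined by this mapping:
    the returned PKParams carries a placeholder k_e = 1.0 which callers
    replace (``dataclasses.replace``) before simulating.
    """
    if c0_central < 0 or transfer_rate < 0 or volume_scale < 0:
        raise ValueError("inputs must be non-negative")
    doses = sorted(doses or [], key=lambda d: d[0])
    if any(a < 0 or t < 0 for t, a in doses):
        raise ValueError("dose times and amounts must be non-negative")
    total = c0_central + volume_scale * sum(a for _, a in doses)
    if transfer_rate == 0:
        if total > 0:
            raise ValueError("transfer_rate = 0 with positive central content: infinite input duration")
        return CentralMapping(PKParams(0.0, 1.0, 1.0), (), True)
    if total == 0:
        return CentralMapping(PKParams(0.0, 1.0, 1.0), (), True)

    # event walk: deplete linearly at transfer_rate, top up at bolus times
    windows: list[tuple[float, float]] = []
    content = c0_central
    t_cur = 0.0
    open_start = 0.0 if content > 0 else None
    for t_dose, amount in doses:
        if open_start is not None:
            run_out = t_cur + content / transfer_rate
            if run_out < t_dose - 1e-12:
                windows.append((open_start, run_out))
                open_start = None
                content = 0.0
            else:
                content -= transfer_rate * (t_dose - t_cur)
        t_cur = t_dose
        add = volume_scale * amount
        if add > 0:
            content += add
            if open_start is None:
                open_start = t_cur
    if open_start is not None:
        windows.append((open_start, t_cur + content / transfer_rate))

    active = sum(e - s for s, e in windows)
    contiguous = len(windows) == 1
    return CentralMapping(PKParams(k_in=transfer_rate, t_in=active, k_e=1.0), tuple(windows), contiguous)
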