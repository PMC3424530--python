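"""Closed-form expected weight change for nearest-neighbor triplet STDP under
a regular one-spike-per-cycle oscillatory protocol.

Protocol assumptions: both neurons fire exactly once per oscillation period
1/f (so f equals the firing rate); the postsynaptic neuron is perfectly
phase-locked (spikes at i/f); presynaptic spike times are uniform within a
window of width T centered on the postsynaptic spikes; the effective
transmission delay d satisfies |d| < 1/f - T/2; and the triplet depression
amplitude A3- is zero (as in the minimal parameter fits).

Because the postsynaptic interspike interval is constant at 1/f, the triplet
gating factor of every potentiation event is the constant
``a2_plus + a3_plus * exp(-1/(f tau_y))``, which is hoisted out of the lag
integrals.  The remaining integrals of ``exp(-dt1/tau)`` over the uniform
lag distributions have three delay regimes mirroring the doublet analysis;
the expected change per cycle is the sum of the potentiation per
postsynaptic spike and the depression per presynaptic spike.  With
``a3_plus = 0`` the same formulas describe the nearest-neighbor doublet rule.

All times in ms; ``freq_f`` in Hz (period 1000/f ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kernels import TripletParams
from .surfaces import WeightChangeSurface

__all__ = [
    "OscillatoryAnalysisSpec",
    "triplet_ltp_per_post",
    "triplet_ltd_per_pre",
    "triplet_dw_per_cycle",
    "triplet_grid",
]


@dataclass(frozen=True)
class OscillatoryAnalysisSpec:
    """Oscillation frequency f (Hz), synchronization window T (ms), delay d (ms).

    Valid when T <= 1000/f (the window fits inside one period) and
    |d| < 1000/f - T/2 (windows of adjacent cycles do not interleave at the
    synapse).
    """

    freq_f: float
    window_T: float
    delay_d: float

    def __post_init__(self) -> None:
        if not (self.freq_f > 0):
            raise ValueError(f"freq_f must be > 0, got {self.freq_f!r}")
        if not (self.window_T > 0):
            raise ValueError(f"window_T must be > 0, got {self.window_T!r}")
        period = 1000.0 / self.freq_f
        if self.window_T > period:
            raise ValueError(
                f"window_T={self.window_T} ms exceeds the oscillation period {period} ms"
            )
        if not (abs(self.delay_d) < period - self.window_T / 2.0):
            raise ValueError(
                f"|delay_d|={abs(self.delay_d)} ms must be < period - T/2 "
                f"= {period - self.window_T / 2.0} ms"
            )

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.freq_f


def _require_pair_only_ltd(params: TripletParams) -> None:
    if params.a3_minus != 0:
        raise ValueError("the closed-form oscillatory analysis requires a3_minus == 0")


def _ltp_lag_integral(spec: OscillatoryAnalysisSpec, tau: float) -> float:
    """Mean of exp(-dt1/tau) over the last-presynaptic-spike lag distribution."""
    T, d, P = spec.window_T, spec.delay_d, spec.period_ms
    if d < -T / 2.0:
        # the whole presynaptic window precedes the postsynaptic spike
        return tau * (math.exp(-(-d - T / 2.0) / tau) - math.exp(-(-d + T / 2.0) / tau)) / T
    if d > T / 2.0:
        # only the previous cycle's presynaptic spike precedes it
        return tau * (
            math.exp(-(P - d - T / 2.0) / tau) - math.exp(-(P - d + T / 2.0) / tau)
        ) / T
    # mixture: same-cycle partner with probability (T/2-d)/T (dt1 uniform on
    # [0, T/2-d]), previous-cycle partner otherwise (dt1 uniform over a full
    # window of width T around P - d)
    same = tau * (1.0 - math.exp(-(T / 2.0 - d) / tau)) / T
    prev = (T / 2.0 + d) * tau * (
        math.exp(-(P - T / 2.0 - d) / tau) - math.exp(-(P + T / 2.0 - d) / tau)
    ) / (T * T)
    return same + prev


def _ltd_lag_integral(spec: OscillatoryAnalysisSpec, tau: float) -> float:
    """Mean of exp(-dt1/tau) over the last-postsynaptic-spike lag distribution."""
    T, d, P = spec.window_T, spec.delay_d, spec.period_ms
    if d < -T / 2.0:
        return tau * (
            math.exp(-(P + d - T / 2.0) / tau) - math.exp(-(P + d + T / 2.0) / tau)
        ) / T
    if d > T / 2.0:
        return tau * (math.exp(-(d - T / 2.0) / tau) - math.exp(-(d + T / 2.0) / tau)) / T
    # same-cycle postsynaptic partner with probability (T/2+d)/T, otherwise
    # the previous cycle's (dt1 uniform on [P - T/2 + d, P])
    return tau * (
        1.0 - math.exp(-(T / 2.0 + d) / tau)
        + math.exp(-(P - T / 2.0 + d) / tau) - math.exp(-P / tau)
    ) / T


def triplet_ltp_per_post(spec: OscillatoryAnalysisSpec, params: TripletParams) -> float:
    """Expected potentiation per postsynaptic spike (>= 0).

    The constant postsynaptic interspike interval makes the triplet gate a
    common prefactor ``scale * (a2_plus + a3_plus * exp(-period/tau_y))``.
    """
    _require_pair_only_ltd(params)
    prefactor = params.scale * (
        params.a2_plus + params.a3_plus * math.exp(-spec.period_ms / params.tau_y)
    )
    return prefactor * _ltp_lag_integral(spec, params.tau_plus)


def triplet_ltd_per_pre(spec: OscillatoryAnalysisSpec, params: TripletParams) -> float:
    """Expected depression per presynaptic spike (<= 0); independent of tau_x
    because a3_minus is required to be zero."""
    _require_pair_only_ltd(params)
    return -params.scale * params.a2_minus * _ltd_lag_integral(spec, params.tau_minus)


def triplet_dw_per_cycle(spec: OscillatoryAnalysisSpec, params: TripletParams) -> float:
    """Expected net weight change per oscillation period (one pre + one post spike)."""
    return triplet_ltp_per_post(spec, params) + triplet_ltd_per_pre(spec, params)


def triplet_grid(freq_f: float, T_values, d_values, params: TripletParams,
                 preset_name: str = "") -> WeightChangeSurface:
    """Surface of expected change per cycle over (T, d) at fixed frequency.

    Cells violating the protocol's validity constraints (T > period or
    |d| >= period - T/2) are masked, not errored.
    """
    T_arr = np.asarray(T_values, dtype=float)
    d_arr = np.asarray(d_values, dtype=float)
    if T_arr.size == 0 or d_arr.size == 0:
        raise ValueError("axes must be non-empty")
    period = 1000.0 / freq_f
    values = np.full((T_arr.size, d_arr.size), np.nan)
    mask = np.zeros_like(values, dtype=bool)
    for i, T in enumerate(T_arr):
        for j, d in enumerate(d_arr):
            if T <= 0 or T > period or abs(d) >= period - T / 2.0:
                mask[i, j] = True
                continue
            values[i, j] = triplet_dw_per_cycle(
                OscillatoryAnalysisSpec(freq_f, T, d), params
            )
    return WeightChangeSurface(
        axis1_name="T_ms", axis1=T_arr, axis2_name="d_ms", axis2=d_arr,
        values=values, mask=mask if mask.any() else None,
        meta={"quantity": "expected_dw_per_cycle", "f_Hz": freq_f,
              "preset": preset_name or "TripletParams",
              "units": "ms (axes); dimensionless weight (values)"},
    )
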