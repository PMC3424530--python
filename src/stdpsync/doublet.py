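"""Closed-form expected weight change for doublet STDP under rectangular lag
distributions, and equilibrium weights of the weight-dependent doublet rules.

The central quantity is the expected weight change per relevant spike pair,

    dw = integral F(t) G(t) dt,

where F is the doublet kernel and G the probability density of pair time
lags at the synapse.  For a synchronization window of width T (ms) and an
effective transmission delay d (ms, axonal minus back-propagation delay),
G is uniform on [-T/2 - d, T/2 - d] with height 1/T, and the integral has a
piecewise-exponential closed form with three delay regimes:

* d < -T/2 : the whole window sits at positive lags (pure LTP),
* d >  T/2 : the whole window sits at negative lags (pure LTD),
* |d| <= T/2 : the window straddles zero and both branches contribute.

For the weight-dependent rules the zero of the expected change yields a
closed-form equilibrium weight; its rate-coding limit (T -> infinity) is
implemented as an explicit analytic mode to avoid precision loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .kernels import (
    DoubletKernelParams,
    InterpolationParams,
    PowerLawParams,
)
from .surfaces import WeightChangeSurface

__all__ = [
    "RectLagWindow",
    "SyncSpec",
    "Equilibrium",
    "rect_window_from_sync",
    "expected_dw_window",
    "expected_dw_sync",
    "kernel_integral",
    "equilibrium_powerlaw",
    "equilibrium_interp",
    "dw_grid",
]


@dataclass(frozen=True)
class RectLagWindow:
    """One rectangular piece of a pair-lag density G: height ``c`` on [t1, t2] (ms).

    A list of windows represents a mixture; the total mass is the sum of
    ``c * (t2 - t1)`` over the pieces.
    """

    c: float
    t1: float
    t2: float

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError(f"density height c must be >= 0, got {self.c!r}")
        if self.t1 > self.t2:
            raise ValueError(f"window bounds must satisfy t1 <= t2, got ({self.t1}, {self.t2})")

    @property
    def mass(self) -> float:
        return self.c * (self.t2 - self.t1)


@dataclass(frozen=True)
class SyncSpec:
    """Synchronization window width T (ms) and effective transmission delay d (ms).

    ``delay_d`` is the *effective* delay d = d_ax - d_bap (axonal minus
    back-propagation delay); the two components are not stored separately.
    ``window_T = math.inf`` selects the rate-coding limit where the
    equilibrium functions support it.
    """

    window_T: float
    delay_d: float

    def __post_init__(self) -> None:
        if not (self.window_T > 0):
            raise ValueError(f"window_T must be > 0, got {self.window_T!r}")


@dataclass(frozen=True)
class Equilibrium:
    """Equilibrium weight together with its qualitative regime.

    ``regime`` is one of ``"equilibrium"`` (finite fixed point),
    ``"pure_ltd"`` (delay beyond the window: the weight decays to 0) and
    ``"unbounded_ltp"`` (delay before the window: supra-linear unlimited
    growth; ``value`` is NaN as a tagged sentinel, never infinity, so that
    parameter sweeps can render the region distinctly).
    """

    value: float
    regime: str


def rect_window_from_sync(sync: SyncSpec) -> RectLagWindow:
    """Uniform lag window of a synchronization event: height 1/T on [-T/2-d, T/2-d]."""
    T, d = sync.window_T, sync.delay_d
    if not math.isfinite(T):
        raise ValueError("rect_window_from_sync requires a finite window_T")
    return RectLagWindow(c=1.0 / T, t1=-T / 2.0 - d, t2=T / 2.0 - d)


def _dw_one_window(win: RectLagWindow, k: DoubletKernelParams) -> float:
    """Exact integral of F * rect(c, t1, t2), split by the window's position."""
    c, t1, t2 = win.c, win.t1, win.t2
    if t1 >= 0:  # entirely positive lags: pure LTP branch
        return c * k.a_plus * k.tau_plus * (
            math.exp(-t1 / k.tau_plus) - math.exp(-t2 / k.tau_plus)
        )
    if t2 <= 0:  # entirely negative lags: pure LTD branch
        return -c * k.a_minus * k.tau_minus * (
            math.exp(t2 / k.tau_minus) - math.exp(t1 / k.tau_minus)
        )
    # straddles zero
    return (
        c * k.a_plus * k.tau_plus * (1.0 - math.exp(-t2 / k.tau_plus))
        - c * k.a_minus * k.tau_minus * (1.0 - math.exp(t1 / k.tau_minus))
    )


def expected_dw_window(
    windows: Union[RectLagWindow, Sequence[RectLagWindow]],
    kernel: DoubletKernelParams,
) -> float:
    """Expected weight change per pairing for a rectangular-mixture lag density.

    The integral of F * G is evaluated exactly, piece by piece (the expected
    change is linear in G, so a mixture is just the sum over its rectangles).
    """
    if isinstance(windows, RectLagWindow):
        windows = [windows]
    return sum(_dw_one_window(w, kernel) for w in windows)


def expected_dw_sync(sync: SyncSpec, kernel: DoubletKernelParams) -> float:
    """Expected weight change per pairing for a synchronization window (c = 1/T).

    Direct closed form in the three delay regimes; agrees with
    :func:`expected_dw_window` applied to :func:`rect_window_from_sync`
    to well below 1e-12.
    """
    T, d = sync.window_T, sync.delay_d
    if not math.isfinite(T):
        raise ValueError("expected_dw_sync requires a finite window_T")
    c = 1.0 / T
    tp, tm = kernel.tau_plus, kernel.tau_minus
    if d < -T / 2.0:
        return c * kernel.a_plus * tp * (
            math.exp((T / 2.0 + d) / tp) - math.exp((-T / 2.0 + d) / tp)
        )
    if d > T / 2.0:
        return -c * kernel.a_minus * tm * (
            math.exp((T / 2.0 - d) / tm) - math.exp((-T / 2.0 - d) / tm)
        )
    return (
        c * kernel.a_plus * tp * (1.0 - math.exp(-(T / 2.0 - d) / tp))
        - c * kernel.a_minus * tm * (1.0 - math.exp(-(T / 2.0 + d) / tm))
    )


def kernel_integral(kernel: DoubletKernelParams) -> float:
    """Total integral of the doublet kernel: a_plus*tau_plus - a_minus*tau_minus.

    Negative for realistic parameters, so uncorrelated (flat-lag) firing
    yields net depression.
    """
    return kernel.a_plus * kernel.tau_plus - kernel.a_minus * kernel.tau_minus


def _branch_ratio(T: float, d: float, alpha: float, tau_plus: float, tau_minus: float) -> float:
    """tau+ (1 - e^{-(T/2-d)/tau+}) / (alpha tau- (1 - e^{-(T/2+d)/tau-}))."""
    if math.isinf(T):
        return tau_plus / (alpha * tau_minus)
    num = tau_plus * (1.0 - math.exp(-(T / 2.0 - d) / tau_plus))
    den = alpha * tau_minus * (1.0 - math.exp(-(T / 2.0 + d) / tau_minus))
    return num / den


def equilibrium_powerlaw(sync: SyncSpec, params: PowerLawParams) -> Equilibrium:
    """Equilibrium weight of the power-law rule, in units of ``w_ref``.

    For |d| <= T/2 the fixed point is
    ``(tau+ (1-e^{-(T/2-d)/tau+}) / (alpha tau- (1-e^{-(T/2+d)/tau-})))^{1/(1-mu)}``.
    ``d > T/2`` gives pure LTD (weight 0); ``d < -T/2`` gives unbounded
    supra-linear LTP (tagged sentinel, see :class:`Equilibrium`).
    ``window_T = inf`` selects the rate-coding limit
    ``(tau+/(alpha tau-))^{1/(1-mu)}`` analytically.
    """
    if params.mu >= 1:
        raise ValueError("equilibrium exponent 1/(1-mu) undefined for mu >= 1")
    T, d = sync.window_T, sync.delay_d
    if math.isfinite(T):
        if d >= T / 2.0:
            # at d = T/2 the potentiation integral vanishes and w_inf -> 0
            return Equilibrium(0.0, "pure_ltd")
        if d <= -T / 2.0:
            # at d = -T/2 the depression integral vanishes and w_inf diverges
            return Equilibrium(math.nan, "unbounded_ltp")
    ratio = _branch_ratio(T, d, params.alpha, params.tau_plus, params.tau_minus)
    return Equilibrium(ratio ** (1.0 / (1.0 - params.mu)), "equilibrium")


def equilibrium_interp(sync: SyncSpec, params: InterpolationParams) -> float:
    """Equilibrium weight of the interpolating rule, a sigmoid in the delay.

    Returns 1 for ``d < -T/2`` (saturated LTP), 0 for ``d > T/2`` (pure LTD)
    and ``1 / (1 + (alpha tau- (1-e^{-(T/2+d)/tau-}) /
    (tau+ (1-e^{-(T/2-d)/tau+})))^{1/mu})`` for ``|d| <= T/2``.  Always in [0, 1].
    """
    if params.mu <= 0:
        raise ValueError("mu must be > 0 for the interpolating equilibrium")
    T, d = sync.window_T, sync.delay_d
    if math.isfinite(T):
        # inclusive boundaries: the sigmoid saturates exactly there
        if d >= T / 2.0:
            return 0.0
        if d <= -T / 2.0:
            return 1.0
    ratio = _branch_ratio(T, d, params.alpha, params.tau_plus, params.tau_minus)
    # evaluate the logistic in log space: 1/mu can be huge (almost-additive
    # limit mu -> 0) and ratio**(-1/mu) overflows long before w leaves [0, 1]
    log_odds = -math.log(ratio) / params.mu
    if log_odds > 700:
        return 0.0
    if log_odds < -700:
        return 1.0
    return 1.0 / (1.0 + math.exp(log_odds))


def _check_axis(name: str, values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} axis must be non-empty")
    if arr.size > 1 and not np.all(np.diff(arr) > 0):
        raise ValueError(f"{name} axis must be strictly increasing")
    return arr


def dw_grid(T_values, d_values, model, preset_name: str = "") -> WeightChangeSurface:
    """Surface of expected weight change (or equilibrium weight) over (T, d).

    ``model`` selects the quantity: a :class:`DoubletKernelParams` yields the
    expected change per pairing, a :class:`PowerLawParams` or
    :class:`InterpolationParams` the equilibrium weight.  Rows are T
    ascending, columns d ascending; unbounded power-law cells are masked.
    """
    T_arr = _check_axis("T", T_values)
    d_arr = _check_axis("d", d_values)
    values = np.empty((T_arr.size, d_arr.size))
    mask = np.zeros_like(values, dtype=bool)
    if isinstance(model, DoubletKernelParams):
        quantity = "expected_dw_per_pairing"
        for i, T in enumerate(T_arr):
            for j, d in enumerate(d_arr):
                values[i, j] = expected_dw_sync(SyncSpec(T, d), model)
    elif isinstance(model, PowerLawParams):
        quantity = "equilibrium_weight_powerlaw"
        for i, T in enumerate(T_arr):
            for j, d in enumerate(d_arr):
                eq = equilibrium_powerlaw(SyncSpec(T, d), model)
                values[i, j] = eq.value
                mask[i, j] = eq.regime == "unbounded_ltp"
    elif isinstance(model, InterpolationParams):
        quantity = "equilibrium_weight_interp"
        for i, T in enumerate(T_arr):
            for j, d in enumerate(d_arr):
                values[i, j] = equilibrium_interp(SyncSpec(T, d), model)
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    return WeightChangeSurface(
        axis1_name="T_ms", axis1=T_arr, axis2_name="d_ms", axis2=d_arr,
        values=values, mask=mask if mask.any() else None,
        meta={"quantity": quantity, "preset": preset_name or type(model).__name__,
              "units": "ms (axes); dimensionless weight (values)"},
    )
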