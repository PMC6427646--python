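"""Leaky integrate-and-fire (LIF) membrane dynamics.

Each input spike at time ``ti`` contributes a postsynaptic potential
shaped by the double-exponential kernel

    K(dt) = V0 * (exp(-dt/tau) - exp(-dt/tau_s)),   dt = t - ti >= 0,

and zero for dt < 0 (causality).  ``tau`` is the membrane integration
time constant, ``tau_s`` the synaptic-current decay (tau > tau_s), and
``V0`` normalizes the kernel peak to exactly 1.  The membrane voltage of
an output neuron is the weighted sum over channels of the kernel
responses of all spikes before t, plus the resting potential.  A spike
is emitted when the voltage crosses the firing threshold; the readout
neurons here fire at most one spike per trial, so no reset dynamics are
modeled and the *unshunted* voltage maximum is the quantity of interest
for learning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .data import Trial

__all__ = [
    "LIFParams",
    "VoltageSummary",
    "DEFAULT_TAU_GRID",
    "default_lif_grid",
    "kernel_peak_time",
    "normalizer_v0",
    "psp_kernel",
    "membrane_voltage_at",
    "psp_matrix",
    "evaluation_grid",
    "max_voltage",
]

#: default membrane time constants searched by cross-validation, seconds;
#: the synaptic constant follows the tau_s = tau/4 convention
DEFAULT_TAU_GRID = (0.05, 0.1, 0.2, 0.5, 1.0)


def default_lif_grid() -> list[dict]:
    """Hyperparameter grid over (tau, tau_s) pairs for CV selection."""
    return [{"tau": t, "tau_s": t / 4.0} for t in DEFAULT_TAU_GRID]


def kernel_peak_time(tau: float, tau_s: float) -> float:
    """Lag at which the unnormalized kernel attains its maximum."""
    if not tau > tau_s > 0:
        raise ValueError(f"need tau > tau_s > 0, got tau={tau}, tau_s={tau_s}")
    return tau * tau_s / (tau - tau_s) * math.log(tau / tau_s)


def normalizer_v0(tau: float, tau_s: float) -> float:
    """Normalization constant making the kernel peak equal 1.

    With t* the peak lag, V0 = 1 / (exp(-t*/tau) - exp(-t*/tau_s)).
    Rejects tau <= tau_s, where the kernel has no positive peak.
    """
    t_peak = kernel_peak_time(tau, tau_s)
    peak = math.exp(-t_peak / tau) - math.exp(-t_peak / tau_s)
    return 1.0 / peak


@dataclass(frozen=True)
class LIFParams:
    """LIF neuron parameters.

    tau, tau_s : seconds, membrane / synaptic decay constants (tau > tau_s)
    theta      : firing threshold (dimensionless voltage), default 1
    v_rest     : resting potential, default 0
    grid_dt    : uniform step of the voltage-evaluation grid, seconds
    v0         : derived; kernel-peak normalizer (do not set by hand)
    """

    tau: float = 0.2
    tau_s: float = 0.05
    theta: float = 1.0
    v_rest: float = 0.0
    grid_dt: float = 1e-3
    v0: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not self.tau > self.tau_s > 0:
            raise ValueError(
                f"need tau > tau_s > 0, got tau={self.tau}, tau_s={self.tau_s}"
            )
        if self.grid_dt <= 0:
            raise ValueError("grid_dt must be positive")
        object.__setattr__(self, "v0", normalizer_v0(self.tau, self.tau_s))

    @property
    def t_peak(self) -> float:
        return kernel_peak_time(self.tau, self.tau_s)


@dataclass(frozen=True)
class VoltageSummary:
    """Maximal membrane voltage of one output neuron over one trial."""

    v_max: float
    t_max: float
    fired: bool
    fire_time: Optional[float] = None


def psp_kernel(dt, params: LIFParams):
    """Normalized PSP kernel K(dt); 0 for negative lags.

    Accepts scalars or arrays; vectorized over ``dt``.
    """
    dt = np.asarray(dt, dtype=float)
    with np.errstate(over="ignore"):
        val = params.v0 * (np.exp(-dt / params.tau) - np.exp(-dt / params.tau_s))
    out = np.where(dt >= 0, val, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def membrane_voltage_at(
    trial: Trial, weights: Sequence[float], t: float, params: LIFParams
) -> float:
    """Membrane voltage V(t): weighted kernel sum over spikes before t."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (trial.n_channels,):
        raise ValueError(
            f"weights shape {w.shape} does not match {trial.n_channels} channels"
        )
    v = params.v_rest
    for wi, times in zip(w, trial.spike_times()):
        past = times[times < t]
        if past.size:
            v += wi * float(np.sum(psp_kernel(t - past, params)))
    return v


def psp_matrix(trial: Trial, times: np.ndarray, params: LIFParams) -> np.ndarray:
    """Per-channel kernel sums at each evaluation time.

    Returns P with ``P[g, c] = sum over spikes ti of channel c, ti < times[g],
    of K(times[g] - ti)``, so a neuron's voltage trace is ``P @ w + v_rest``.
    The matrix depends only on the trial, not on any weight vector, which
    lets one trial serve every output neuron (and every epoch) at once.
    """
    times = np.asarray(times, dtype=float)
    n_ch = trial.n_channels
    P = np.zeros((times.size, n_ch))
    for c, ti in enumerate(trial.spike_times()):
        if ti.size == 0:
            continue
        dt = times[:, None] - ti[None, :]
        K = psp_kernel(dt, params)
        K[dt <= 0] = 0.0  # strictly-before-t convention
        P[:, c] = K.sum(axis=1)
    return P


def evaluation_grid(trial: Trial, params: LIFParams) -> np.ndarray:
    """Sorted union of all spike times and a uniform grid over the trial."""
    uniform = np.arange(0.0, trial.duration + 0.5 * params.grid_dt, params.grid_dt)
    uniform = uniform[uniform <= trial.duration]
    pieces = [uniform] + [t for t in trial.spike_times() if t.size]
    return np.unique(np.concatenate(pieces))


def max_voltage(
    trial: Trial,
    weights: Sequence[float],
    params: LIFParams,
    grid_dt: Optional[float] = None,
    refine: bool = True,
) -> VoltageSummary:
    """Maximal membrane voltage, its time, and threshold-crossing state.

    The voltage is evaluated on the union of all spike arrival times and
    a uniform grid of step ``grid_dt`` over [0, duration]; the true
    maximum of the smooth inter-event voltage lies between samples, so a
    bounded scalar minimization (tolerance 1e-6 s) refines the best grid
    point when ``refine`` is on.  Ties in the argmax break toward the
    earliest time; ``fired`` reports whether any evaluation exceeded the
    threshold and ``fire_time`` the first grid time that did.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (trial.n_channels,):
        raise ValueError(
            f"weights shape {w.shape} does not match {trial.n_channels} channels"
        )
    if grid_dt is not None:
        if grid_dt <= 0:
            raise ValueError("grid_dt must be positive")
        params_eval = LIFParams(
            tau=params.tau, tau_s=params.tau_s, theta=params.theta,
            v_rest=params.v_rest, grid_dt=grid_dt,
        )
    else:
        params_eval = params
    grid = evaluation_grid(trial, params_eval)
    V = psp_matrix(trial, grid, params) @ w + params.v_rest
    best = int(np.argmax(V))  # np.argmax returns the first (earliest) maximum
    v_max, t_max = float(V[best]), float(grid[best])

    if refine and trial.n_spikes:
        lo = grid[best - 1] if best > 0 else grid[0]
        hi = grid[best + 1] if best + 1 < grid.size else grid[-1]
        if hi > lo:
            res = minimize_scalar(
                lambda t: -membrane_voltage_at(trial, w, t, params),
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-6},
            )
            if -res.fun > v_max:
                v_max, t_max = float(-res.fun), float(res.x)

    crossed = V > params.theta
    fired = bool(crossed.any()) or v_max > params.theta
    fire_time = float(grid[int(np.argmax(crossed))]) if crossed.any() else (
        t_max if fired else None
    )
    return VoltageSummary(v_max=v_max, t_max=t_max, fired=fired, fire_time=fire_time)
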