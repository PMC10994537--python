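"""Fine-grid numerics shared by the forward simulator and the kinetic fitter.

All kinetic computations run on a uniform fine time grid (default 1-s step,
expressed in minutes) with trapezoidal quadrature; frame values are averages
of the fine curve over each frame interval.
"""

from __future__ import annotations

import numpy as np
from scipy import signal
from scipy.interpolate import PchipInterpolator

from .core import FrameSchedule

FINE_DT_MIN = 1.0 / 60.0  # 1-s step, in minutes


def fine_grid(schedule: FrameSchedule, dt: float = FINE_DT_MIN) -> np.ndarray:
    """Uniform time grid in minutes covering the whole acquisition."""
    end_min = schedule.ends[-1] / 60.0
    n = int(round(end_min / dt))
    return np.linspace(0.0, end_min, n + 1)


def expconv(f: np.ndarray, dt: float, k: float) -> np.ndarray:
    """Trapezoidal convolution of ``f`` with ``exp(-k t)`` on a uniform grid.

    Uses the exact recursion y[n] = a*y[n-1] + dt/2*(f[n] + a*f[n-1]) with
    a = exp(-k*dt), evaluated as a linear IIR filter (O(N)).
    """
    if k < 0:
        raise ValueError("rate constant must be non-negative")
    a = np.exp(-k * dt)
    y = signal.lfilter([dt / 2.0, a * dt / 2.0], [1.0, -a], f)
    # recursion seeds y[0] = dt/2*f[0]; the true integral at t=0 is 0
    y -= (dt / 2.0) * f[0] * a ** np.arange(len(f))
    return y


def frame_average(curve: np.ndarray, t: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Average a fine-grid curve over each frame (trapezoidal integral /
    frame duration). Frame boundaries need not lie on the grid; the cumulative
    integral is interpolated linearly at the exact boundary times.
    """
    dt = t[1] - t[0]
    cum = np.concatenate([[0.0], np.cumsum((curve[1:] + curve[:-1]) / 2.0 * dt)])
    starts_min = schedule.starts / 60.0
    ends_min = schedule.ends / 60.0
    ints = np.interp(ends_min, t, cum) - np.interp(starts_min, t, cum)
    return ints / (schedule.durations / 60.0)


def tac_to_fine(values: np.ndarray, schedule: FrameSchedule, t: np.ndarray) -> np.ndarray:
    """Reconstruct a fine-grid curve from frame-averaged TAC values.

    Monotone cubic (PCHIP) interpolation through the frame mid-times anchored
    at (0, 0), followed by a per-frame additive constant so that the fine
    curve's frame averages reproduce the measured TAC exactly. The correction
    keeps the basis-function fit self-consistent with frame-averaged data
    while staying bounded on noisy input.
    """
    mids_min = schedule.mids / 60.0
    knots_t = np.concatenate([[0.0], mids_min])
    knots_v = np.concatenate([[0.0], values])
    fine = PchipInterpolator(knots_t, knots_v, extrapolate=True)(t)
    starts_min = schedule.starts / 60.0
    frame_of_t = np.searchsorted(starts_min, t, side="right") - 1
    frame_of_t = np.clip(frame_of_t, 0, schedule.n_frames - 1)
    # per-frame constant correction to restore exact frame averages; iterated
    # because trapezoids straddling frame boundaries mix adjacent corrections
    for _ in range(3):
        corr = values - frame_average(fine, t, schedule)
        fine = fine + corr[frame_of_t]
    return fine
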