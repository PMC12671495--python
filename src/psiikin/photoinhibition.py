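"""Photoinhibition kinetics: exponential decline of Fv/Fm under excess
light and the half-time of that decline.

The decay is modelled as y(t) = y_plateau + (y_init - y_plateau)·exp(-kt);
t_half = ln2/k refers to the init→plateau span, which makes it invariant
to the plateau level.  The same fit applies unchanged to chlorophyll
photobleaching courses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize

from .io import TimeSeriesTrace, TraceKind

__all__ = ["PhotoinhibitionFit", "simulate_fvfm_decay", "fit_decay_half_time"]

_H = 3600.0  # trace time base is seconds; rates and half-times reported in hours


@dataclass
class PhotoinhibitionFit:
    y_init: float
    y_plateau: float
    k_per_h: float
    t_half_h: float
    rss: float
    t_half_crossing_h: float = float("nan")  # nonparametric cross-check
    conf: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.y_init > self.y_plateau >= 0:
            raise ValueError("need y_init > y_plateau >= 0")
        if self.t_half_h <= 0:
            raise ValueError("t_half must be > 0")


def simulate_fvfm_decay(
    y_init: float, y_plateau: float, k_per_h: float, t_grid
) -> TimeSeriesTrace:
    """Exponential Fv/Fm decline on a time grid in seconds."""
    t = np.asarray(t_grid, dtype=float)
    y = y_plateau + (y_init - y_plateau) * np.exp(-k_per_h * t / _H)
    return TimeSeriesTrace(
        time=t, value=y, kind=TraceKind.FVFM_COURSE,
        meta={"y_init": y_init, "y_plateau": y_plateau, "k_per_h": k_per_h},
    )


def fit_decay_half_time(trace: TimeSeriesTrace) -> PhotoinhibitionFit:
    """Fit the exponential decay and report t_half = ln2/k (hours).

    Also reports the nonparametric time at which the raw course crosses
    halfway between its initial and final values, as a model-free
    cross-check.  Raises on traces with no declining trend.
    """
    t_h = trace.time / _H
    y = trace.value
    if len(trace) < 4:
        raise ValueError("need at least 4 time points")
    if y[-1] >= y[0] - 1e-12:
        raise ValueError("no photoinhibition signal: trace is not declining")

    pars = Parameters()
    span = float(y[0] - y[-1])
    pars.add("y_init", value=float(y[0]), min=0.0)
    # start strictly inside the bound: leastsq stalls on a bound-pinned start
    pars.add("y_plateau", value=max(float(y[-1]) - 0.1 * span, 1e-4), min=0.0)
    pars.add("k", value=max(1.0 / max(t_h[-1], 1e-6), 1e-6), min=1e-9)

    def residual(p):
        return (
            p["y_plateau"].value
            + (p["y_init"].value - p["y_plateau"].value) * np.exp(-p["k"].value * t_h)
            - y
        )

    out = minimize(residual, pars, method="leastsq")
    if not out.success:
        raise RuntimeError(f"decay fit failed: {out.message}")
    k = out.params["k"].value
    conf = {
        name: (1.96 * par.stderr if par.stderr else float("nan"))
        for name, par in out.params.items()
    }

    # model-free halfway crossing between observed endpoints
    half_level = 0.5 * (y[0] + y[-1])
    below = y <= half_level
    t_cross = float("nan")
    if below.any():
        i = int(np.argmax(below))
        if i > 0:
            frac = (half_level - y[i - 1]) / (y[i] - y[i - 1])
            t_cross = float(t_h[i - 1] + frac * (t_h[i] - t_h[i - 1]))
        else:
            t_cross = float(t_h[0])

    return PhotoinhibitionFit(
        y_init=out.params["y_init"].value,
        y_plateau=out.params["y_plateau"].value,
        k_per_h=k, t_half_h=float(np.log(2.0) / k),
        rss=float(np.sum(out.residual**2)),
        t_half_crossing_h=t_cross, conf=conf,
    )
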