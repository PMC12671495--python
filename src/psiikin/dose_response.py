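"""Light-saturation fitting for ECS-derived pmf amplitudes (or any
amplitude-vs-irradiance curve).

Default model is the rectangular hyperbola amp(I) = amp_max·I/(I + I_half),
with I_half the half-saturation irradiance in µmol photons m⁻² s⁻¹; an
exponential-saturation alternative amp_max·(1 - exp(-I/I_c)) is available
(its I_half = I_c·ln2 is reported on the same scale).  The fit is
scale-equivariant: rescaling amplitudes rescales amp_max and leaves I_half
unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize

from .io import TimeSeriesTrace

__all__ = ["SaturationFit", "fit_saturation"]


@dataclass
class SaturationFit:
    amp_max: float
    i_half: float
    rss: float
    model: str = "hyperbola"
    conf: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.amp_max <= 0 or self.i_half <= 0:
            raise ValueError("amp_max and I_half must be > 0")

    def predict(self, intensity) -> np.ndarray:
        x = np.asarray(intensity, dtype=float)
        if self.model == "hyperbola":
            return self.amp_max * x / (x + self.i_half)
        tau = self.i_half / np.log(2.0)
        return self.amp_max * (1.0 - np.exp(-x / tau))


def fit_saturation(points, model: str = "hyperbola") -> SaturationFit:
    """Fit a saturation curve to (irradiance, amplitude) points.

    ``points`` may be an (n, 2) array-like or a TimeSeriesTrace whose
    "time" axis is irradiance.  Needs >= 4 intensities; warns when the data
    do not reach ~3× the estimated half-saturation (poorly constrained
    asymptote).
    """
    if isinstance(points, TimeSeriesTrace):
        pts = np.column_stack([points.time, points.value])
    else:
        pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 4:
        raise ValueError("need at least 4 (intensity, amplitude) points")
    if model not in ("hyperbola", "exponential"):
        raise ValueError("model must be 'hyperbola' or 'exponential'")
    x, y = pts[:, 0], pts[:, 1]

    pars = Parameters()
    pars.add("amp_max", value=float(y.max()) * 1.2, min=1e-12)
    pars.add("i_half", value=float(np.median(x)), min=1e-9)

    def residual(p):
        a, ih = p["amp_max"].value, p["i_half"].value
        if model == "hyperbola":
            return a * x / (x + ih) - y
        return a * (1.0 - np.exp(-x * np.log(2.0) / ih)) - y

    out = minimize(residual, pars, method="leastsq")
    if not out.success:
        raise RuntimeError(f"saturation fit failed: {out.message}")
    notes = []
    if float(x.max()) < 3.0 * out.params["i_half"].value:
        notes.append("non-saturating data: asymptote poorly constrained")
        warnings.warn(notes[-1])
    conf = {
        name: (1.96 * par.stderr if par.stderr else float("nan"))
        for name, par in out.params.items()
    }
    return SaturationFit(
        amp_max=out.params["amp_max"].value, i_half=out.params["i_half"].value,
        rss=float(np.sum(out.residual**2)), model=model, conf=conf, warnings=notes,
    )
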