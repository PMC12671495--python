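"""Saturating-pulse (PAM) fluorescence analysis.

Extracts per-pulse levels (Fs, Fm′, optional F0′) from a continuous PAM
trace plus its pulse protocol, and derives the standard quench/yield
quantities:

    NPQ     = (Fm - Fm′)/Fm′                    (Stern–Volmer)
    Φ_II    = (Fm′ - Fs)/Fm′
    Φ_NPQ   = Fs/Fm′ - Fs/Fm
    Φ_NO    = Fs/Fm
    qL      = (Fm′ - Fs)/(Fm′ - F0′) · F0′/Fs

with F0′ estimated as F0 / (Fv/Fm + F0/Fm′) when not measured.  The three
yields partition absorbed light into photochemistry, regulated dissipation
and unregulated losses and sum to 1 identically.  NPQ is split into the
rapidly relaxing qE and the sustained qI at the end of the recorded dark
window; an exponential-unmixing alternative is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize

from .io import PulseProtocol, TimeSeriesTrace

__all__ = [
    "PulseRecord",
    "QuenchSeries",
    "QuenchDecomposition",
    "SigmoidFit",
    "extract_pulse_levels",
    "npq_timecourse",
    "partition_yields",
    "decompose_qe_qi",
    "npq_integral",
    "fit_sigmoid_lhc_npq",
]

# level-extraction windows relative to the pulse time (s): Fm' is the max
# inside the pulse window, Fs the median of ~1 s preceding it — robust to
# ±50 ms pulse-timing jitter
_PULSE_WIN = (-0.5, 1.0)
_FS_WIN = (-1.5, -0.5)


@dataclass
class PulseRecord:
    t: float
    Fs: float
    Fm_prime: float
    F0_prime: float | None = None

    def __post_init__(self) -> None:
        if not self.Fs > 0:
            raise ValueError("Fs must be > 0")
        if self.Fm_prime < self.Fs:
            raise ValueError("Fm' must be >= Fs")


@dataclass
class QuenchSeries:
    """Dark-adapted F0/Fm plus the ordered per-pulse records of a session."""

    F0: float
    Fm: float
    pulses: list[PulseRecord] = field(default_factory=list)
    protocol: PulseProtocol | None = None

    def __post_init__(self) -> None:
        if not (self.Fm > self.F0 > 0):
            raise ValueError("need Fm > F0 > 0")
        for rec in self.pulses:
            # small Fm' > Fm excursions (<=2%) are attributed to noise
            if rec.Fm_prime > 1.02 * self.Fm:
                warnings.warn(
                    f"Fm' at t={rec.t} exceeds dark-adapted Fm by more than 2%"
                )

    @property
    def fv_fm(self) -> float:
        return (self.Fm - self.F0) / self.Fm

    @property
    def times(self) -> np.ndarray:
        return np.array([r.t for r in self.pulses])


@dataclass
class QuenchDecomposition:
    qE: float
    qI: float
    npq_max: float


@dataclass
class SigmoidFit:
    y0: float
    a: float
    x0: float
    b: float
    r_squared: float
    predicted: np.ndarray


def _window(trace: TimeSeriesTrace, lo: float, hi: float) -> np.ndarray:
    mask = (trace.time >= lo) & (trace.time <= hi)
    return trace.value[mask]


def extract_pulse_levels(
    trace: TimeSeriesTrace, protocol: PulseProtocol
) -> QuenchSeries:
    """Read (Fs, Fm′) at every protocol pulse from a continuous PAM trace.

    F0 is the median of the pre-actinic dark baseline, Fm the maximum
    within the first pulse window (which must precede actinic light);
    per pulse, Fm′ is the maximum inside the pulse window and Fs the
    median of the second preceding it.
    """
    light = protocol.light_periods()
    if not light:
        raise ValueError("protocol has no actinic light period")
    t_on = light[0][0]
    if not protocol.pulses or protocol.pulses[0] >= t_on:
        raise ValueError("need a dark-adapted pulse before the first actinic segment")

    base_mask = trace.time < t_on
    for tp in protocol.pulses:
        if tp < t_on:
            base_mask &= ~(
                (trace.time >= tp + _PULSE_WIN[0]) & (trace.time <= tp + _PULSE_WIN[1])
            )
    if not base_mask.any():
        raise ValueError("no dark-baseline samples before actinic onset")
    F0 = float(np.median(trace.value[base_mask]))

    first = protocol.pulses[0]
    fm_samples = _window(trace, first + _PULSE_WIN[0], first + _PULSE_WIN[1])
    if fm_samples.size == 0:
        raise ValueError(f"pulse window at t={first} contains no samples")
    Fm = float(np.max(fm_samples))

    records = []
    for tp in protocol.pulses:
        pw = _window(trace, tp + _PULSE_WIN[0], tp + _PULSE_WIN[1])
        if pw.size == 0:
            raise ValueError(f"pulse window at t={tp} contains no samples")
        fs = _window(trace, tp + _FS_WIN[0], tp + _FS_WIN[1])
        Fs = float(np.median(fs)) if fs.size else F0
        records.append(PulseRecord(t=tp, Fs=max(Fs, 1e-12), Fm_prime=float(np.max(pw))))
    return QuenchSeries(F0=F0, Fm=Fm, pulses=records, protocol=protocol)


def npq_timecourse(series: QuenchSeries) -> np.ndarray:
    """Stern–Volmer NPQ(t) = (Fm - Fm′)/Fm′ per pulse; shape (n, 2)."""
    out = []
    for rec in series.pulses:
        if rec.Fm_prime <= 0:
            raise ValueError(f"non-positive Fm' at t={rec.t}")
        out.append((rec.t, (series.Fm - rec.Fm_prime) / rec.Fm_prime))
    return np.array(out)


def partition_yields(series: QuenchSeries, lake_model: bool = False) -> np.ndarray:
    """Per-pulse (t, Φ_II, Φ_NPQ, Φ_NO, qL); the yields sum to 1 exactly.

    Default is the simple complementary partition (Φ_NO = Fs/Fm).  With
    ``lake_model=True`` the lake-model variant is used:
    Φ_NO = 1/(NPQ + 1 + qL(Fm/F0 - 1)) and Φ_NPQ = 1 - Φ_II - Φ_NO.
    """
    rows = []
    for rec in series.pulses:
        Fs, Fmp = rec.Fs, rec.Fm_prime
        F0p = rec.F0_prime
        if F0p is None:
            F0p = series.F0 / (series.fv_fm + series.F0 / Fmp)
        if Fmp - F0p <= 0:
            raise ValueError(f"degenerate Fm' = F0' at t={rec.t}")
        qL = (Fmp - Fs) / (Fmp - F0p) * (F0p / Fs)
        phi_ii = (Fmp - Fs) / Fmp
        if lake_model:
            npq = (series.Fm - Fmp) / Fmp
            phi_no = 1.0 / (npq + 1.0 + qL * (series.Fm / series.F0 - 1.0))
            phi_npq = 1.0 - phi_ii - phi_no
        else:
            phi_no = Fs / series.Fm
            phi_npq = Fs / Fmp - Fs / series.Fm
        rows.append((rec.t, phi_ii, phi_npq, phi_no, qL))
    return np.array(rows)


def decompose_qe_qi(
    npq: np.ndarray, protocol: PulseProtocol, method: str = "endpoint"
) -> QuenchDecomposition:
    """Split NPQ into fast (qE) and sustained (qI) components.

    ``endpoint`` (default): npq_max is NPQ at the last pulse of the first
    light period; qI is NPQ at the final pulse strictly inside the dark
    window that follows; qE = npq_max - qI.  ``unmix``: qI from a
    single-exponential fit of the dark relaxation, extrapolated to
    infinite dark time.
    """
    npq = np.asarray(npq, dtype=float)
    light = protocol.light_periods()
    if not light:
        raise ValueError("protocol has no light period")
    l_start, l_end, _ = light[0]
    dark_after = [w for w in protocol.dark_windows if w[0] >= l_end - 1e-9]
    if not dark_after:
        raise ValueError("no dark window after the first light period")
    d_start, d_end = dark_after[0]

    t = npq[:, 0]
    in_light = (t >= l_start) & (t <= l_end)
    in_dark = (t > d_start) & (t < d_end)
    if not in_light.any():
        raise ValueError("no pulses during the first light period")
    if not in_dark.any():
        raise ValueError("no pulses during the dark-relaxation window")
    npq_max = float(npq[in_light][-1, 1])

    if method == "endpoint":
        qi = float(npq[in_dark][-1, 1])
    elif method == "unmix":
        td = npq[in_dark][:, 0] - d_start
        yd = npq[in_dark][:, 1]
        pars = Parameters()
        pars.add("qi", value=float(yd[-1]), min=0.0)
        pars.add("amp", value=max(float(yd[0] - yd[-1]), 1e-6), min=0.0)
        pars.add("tau", value=max(float(td[-1]) / 4.0, 1.0), min=1e-3)
        out = minimize(
            lambda p: p["qi"].value + p["amp"].value * np.exp(-td / p["tau"].value) - yd,
            pars,
        )
        qi = float(out.params["qi"].value)
    else:
        raise ValueError(f"unknown method '{method}'")
    qi = min(max(qi, 0.0), npq_max)
    return QuenchDecomposition(qE=npq_max - qi, qI=qi, npq_max=npq_max)


def npq_integral(
    npq: np.ndarray, window: tuple[float, float], baseline_subtract: bool = False
) -> float:
    """Trapezoidal definite integral of NPQ(t) over ``window`` (s).

    With ``baseline_subtract`` the NPQ value at the window start is removed
    before integrating (whether published integrals were baseline-corrected
    is ambiguous; the raw trapezoid is the default).
    """
    npq = np.asarray(npq, dtype=float)
    t, y = npq[:, 0], npq[:, 1]
    lo, hi = window
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise ValueError(f"window ({lo}, {hi}) exceeds NPQ time course span")
    grid = np.unique(np.concatenate([[lo, hi], t[(t > lo) & (t < hi)]]))
    vals = np.interp(grid, t, y)
    if baseline_subtract:
        vals = vals - vals[0]
    return float(np.trapezoid(vals, grid))


def fit_sigmoid_lhc_npq(points, enforce_increasing: bool = True) -> SigmoidFit:
    """4-parameter logistic fit of NPQ integral vs LHC content.

    y = y0 + a / (1 + exp(-(x - x0)/b)); with ``enforce_increasing`` the
    amplitude a is bounded below by 0 so the fitted curve is monotone
    increasing in LHC content.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 5:
        raise ValueError("need at least 5 (lhc_content, integral) points")
    x, y = pts[:, 0], pts[:, 1]
    pars = Parameters()
    span = float(y.max() - y.min())
    pars.add("y0", value=float(y.min()))
    pars.add("a", value=max(span, 1e-9), min=0.0 if enforce_increasing else -np.inf)
    pars.add("x0", value=float(np.median(x)))
    pars.add("b", value=max(float(x.max() - x.min()) / 8.0, 1e-12), min=1e-15)

    def residual(p):
        return p["y0"].value + p["a"].value / (
            1.0 + np.exp(-(x - p["x0"].value) / p["b"].value)
        ) - y

    out = minimize(residual, pars, method="leastsq")
    if not out.success:
        raise RuntimeError(f"logistic fit did not converge: {out.message}")
    pred = residual(out.params) + y
    ss_res = float(np.sum((pred - y) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SigmoidFit(
        y0=out.params["y0"].value, a=out.params["a"].value,
        x0=out.params["x0"].value, b=out.params["b"].value,
        r_squared=r2, predicted=pred,
    )
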