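"""Synthetic-data generator: every input the analysis pipeline consumes,
produced from genotype presets.

The generator is deliberately independent of the analysis code paths: all
kinetics here are integrated numerically with ``scipy.integrate.solve_ivp``
(or written as explicit formulas), whereas the analysis modules use the
implicit closed forms, matrix exponentials and least-squares fits.  With
``noise=0`` the output is the exact model curve; noise is multiplicative
Gaussian (fluorescence noise scales with signal), clipped at zero, and
fully determined by the seed.

Emulated experiment kinds
-------------------------
dcmu_induction : sigmoidal fluorescence rise in DCMU-treated leaves
                 (0–2 s, 1 ms grid by default)
pq_rise        : no-DCMU rise shaped by a finite PQ pool
pam_session    : stepped light-response PAM run (dark baseline, then
                 increasing actinic steps, saturating pulse at each step)
npq_protocol   : two consecutive 8-min illumination periods at
                 1000 µmol photons m⁻² s⁻¹ with 8-min dark recoveries,
                 pulses every 30 s
vaz_course     : xanthophyll V/A/Z fractions over 8 min light + 8 min dark
fvfm_course    : Fv/Fm decline over 6 h of photoinhibitory treatment
ecs_curve      : ECS_t amplitude at 8 irradiances from 25 to 1000 µmol
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .io import PigmentProfile, PulseProtocol, TimeSeriesTrace, TraceKind
from .presets import GenotypePreset

__all__ = ["Dataset", "generate_dataset", "add_noise", "KINDS"]

KINDS = (
    "dcmu_induction", "pq_rise", "pam_session", "npq_protocol",
    "vaz_course", "fvfm_course", "ecs_curve",
)

# PAM sampling and pulse shape
_DT = 0.5            # s
_PULSE_LEN = 0.6     # s the detector sits at Fm' during a saturating pulse


@dataclass
class Dataset:
    """One generated experiment: trace(s), optional protocol, provenance."""

    kind: str
    trace: TimeSeriesTrace | None = None
    profile: PigmentProfile | None = None
    protocol: PulseProtocol | None = None
    provenance: dict = field(default_factory=dict)


def add_noise(trace: TimeSeriesTrace, relative_sd: float, seed: int) -> TimeSeriesTrace:
    """Multiplicative Gaussian noise, clipped at zero; sd=0 is the identity."""
    if relative_sd < 0:
        raise ValueError("relative_sd must be >= 0")
    if relative_sd == 0:
        return trace
    rng = np.random.default_rng(seed)
    noisy = trace.value * (1.0 + relative_sd * rng.standard_normal(trace.value.size))
    return TimeSeriesTrace(
        time=trace.time.copy(), value=np.clip(noisy, 0.0, None),
        kind=trace.kind, meta=dict(trace.meta),
    )


def _vf(C: np.ndarray, p: float) -> np.ndarray:
    # connected-units hyperbola, written out locally: the generator shares
    # no code with the analysis-side model
    return (1.0 - p) * C / (1.0 - p * C)


def _dcmu_trace(preset: GenotypePreset, t_max: float, dt: float) -> TimeSeriesTrace:
    p = preset.J / (1.0 + preset.J)
    t = np.arange(0.0, t_max + 0.5 * dt, dt)

    def rhs(_t, y):
        C = min(y[0], 1.0 - 1e-12)
        return [preset.k_ph * (1.0 - C) / (1.0 - p * C)]

    sol = solve_ivp(rhs, (0.0, t[-1]), [0.0], t_eval=t, method="DOP853",
                    rtol=1e-11, atol=1e-13)
    C = np.clip(sol.y[0], 0.0, 1.0)
    F = preset.F0 + preset.Fv * _vf(C, p)
    meta = {"genotype": preset.name, "dcmu": True, "actinic_umol": 7}
    return TimeSeriesTrace(time=t, value=F, kind=TraceKind.INDUCTION, meta=meta)


def _pq_rise_trace(preset: GenotypePreset, t_max: float, dt: float) -> TimeSeriesTrace:
    p = preset.J / (1.0 + preset.J)
    t = np.arange(0.0, t_max + 0.5 * dt, dt)

    def rhs(_t, y):
        C = min(max(y[0], 0.0), 1.0 - 1e-12)
        q = max(y[1], 0.0)
        flux = preset.k_ox * C * q
        return [preset.k_ph * (1.0 - C) / (1.0 - p * C) - flux, -flux / preset.n_pq]

    sol = solve_ivp(rhs, (0.0, t[-1]), [0.0, 1.0], t_eval=t, method="LSODA",
                    rtol=1e-10, atol=1e-12)
    C = np.clip(sol.y[0], 0.0, 1.0)
    F = preset.F0 + preset.Fv * _vf(C, p)
    meta = {"genotype": preset.name, "dcmu": False, "actinic_umol": 7}
    return TimeSeriesTrace(time=t, value=F, kind=TraceKind.INDUCTION, meta=meta)


def _npq_light(preset: GenotypePreset, t_rel: float, zea_loaded: bool) -> float:
    """NPQ during an illumination period, biphasic rise.

    After a first light period the slow (Zea-linked) phase is already
    engaged, giving the faster second rise seen experimentally.
    """
    fast = preset.qE * (1.0 - np.exp(-t_rel / preset.tau_fast))
    if zea_loaded:
        slow = preset.qI
    else:
        slow = preset.qI * (1.0 - np.exp(-t_rel / preset.tau_slow))
    return fast + slow


def _npq_dark(preset: GenotypePreset, npq_at_off: float, qi_level: float,
              t_rel: float) -> float:
    fast_part = max(npq_at_off - qi_level, 0.0)
    return qi_level + fast_part * np.exp(-t_rel / preset.tau_relax)


def _npq_protocol(preset: GenotypePreset) -> tuple[TimeSeriesTrace, PulseProtocol]:
    """Two 8-min light periods at 1000 µmol with 8-min dark recoveries."""
    base, light, dark = 60.0, 480.0, 480.0
    edges = [0.0, base, base + light, base + light + dark,
             base + 2 * light + dark, base + 2 * light + 2 * dark]
    segments = [(edges[1], edges[2], 1000.0), (edges[3], edges[4], 1000.0)]
    dark_windows = [(edges[0], edges[1]), (edges[2], edges[3]), (edges[4], edges[5])]
    pulses = list(np.arange(30.0, edges[5], 30.0))
    protocol = PulseProtocol(segments=segments, pulses=pulses,
                             dark_windows=dark_windows)

    Fm, F0 = 1.0, preset.F0
    t = np.arange(0.0, edges[5] + _DT / 2, _DT)

    def npq_at(tt: float) -> float:
        if tt <= edges[1]:
            return 0.0
        if tt <= edges[2]:
            return _npq_light(preset, tt - edges[1], zea_loaded=False)
        npq_off1 = _npq_light(preset, light, zea_loaded=False)
        qi1 = npq_off1 - preset.qE * (1.0 - np.exp(-light / preset.tau_fast))
        if tt <= edges[3]:
            return _npq_dark(preset, npq_off1, qi1, tt - edges[2])
        if tt <= edges[4]:
            rise2 = preset.qE * (1.0 - np.exp(-(tt - edges[3]) / preset.tau_fast))
            carry = _npq_dark(preset, npq_off1, qi1, dark)
            return carry + rise2
        npq_off2 = _npq_dark(preset, npq_off1, qi1, dark) + preset.qE * (
            1.0 - np.exp(-light / preset.tau_fast))
        return _npq_dark(preset, npq_off2, qi1, tt - edges[4])

    # continuous Fs-level signal; Phi_II ~ 0.3 under 1000 umol in the light
    signal = np.empty_like(t)
    for i, tt in enumerate(t):
        fmp = Fm / (1.0 + npq_at(tt))
        in_light = any(a <= tt <= b for a, b, _ in segments)
        signal[i] = fmp * 0.7 if in_light else min(F0, fmp)
    # saturating pulses ride on top
    for tp in pulses:
        mask = (t >= tp) & (t <= tp + _PULSE_LEN)
        signal[mask] = Fm / (1.0 + npq_at(tp))
    meta = {"genotype": preset.name, "actinic_umol": 1000, "dcmu": False}
    return TimeSeriesTrace(time=t, value=signal, kind=TraceKind.PAM, meta=meta), protocol


_PAM_STEPS = (25.0, 50.0, 100.0, 200.0, 300.0, 400.0, 600.0, 800.0, 1000.0)


def _pam_session(preset: GenotypePreset) -> tuple[TimeSeriesTrace, PulseProtocol]:
    """Stepped light-response run encoding the preset's yield plateaus.

    Per step of intensity I the generator sets the steady-state partition
    Φ_NO(I) (rising from F0/Fm to the preset plateau), Φ_NPQ(I)
    (saturating to its plateau, capped so Φ_II stays positive) and
    back-computes Fs = Φ_NO·Fm and Fm′ = Fs/(Φ_NO + Φ_NPQ).
    """
    base, step = 120.0, 120.0
    Fm, F0 = 1.0, preset.F0
    phi_no_dark = F0 / Fm

    segments = []
    pulses = [60.0]
    t_end = base + step * len(_PAM_STEPS)
    for k, inten in enumerate(_PAM_STEPS):
        a = base + k * step
        segments.append((a, a + step, inten))
        pulses.append(a + step - 2.0)
    protocol = PulseProtocol(segments=segments, pulses=pulses,
                             dark_windows=[(0.0, base)])

    def phi_no(I: float) -> float:
        return phi_no_dark + (preset.phi_no_plateau - phi_no_dark) * (
            1.0 - np.exp(-I / 60.0))

    def phi_npq(I: float) -> float:
        raw = preset.phi_npq_plateau * (1.0 - np.exp(-I / 150.0))
        return min(raw, 1.0 - phi_no(I) - 0.02)

    t = np.arange(0.0, t_end + _DT / 2, _DT)
    signal = np.full_like(t, F0)
    for a, b, inten in segments:
        fs = phi_no(inten) * Fm
        signal[(t >= a) & (t <= b)] = fs
    for tp in pulses:
        inten = protocol.intensity_at(tp)
        if inten == 0:
            fmp = Fm
        else:
            fs = phi_no(inten) * Fm
            fmp = fs / (phi_no(inten) + phi_npq(inten))
        signal[(t >= tp) & (t <= tp + _PULSE_LEN)] = fmp
    meta = {"genotype": preset.name, "protocol": "light_response", "dcmu": False}
    return TimeSeriesTrace(time=t, value=signal, kind=TraceKind.PAM, meta=meta), protocol


def _vaz_course(preset: GenotypePreset) -> tuple[PigmentProfile, PulseProtocol]:
    light, dark = 480.0, 480.0
    protocol = PulseProtocol(segments=[(0.0, light, 1000.0)],
                             dark_windows=[(light, light + dark)])
    t = np.arange(0.0, light + dark + 1.0, 30.0)

    def rhs(tt, y):
        V, A, Z = y
        on = tt <= light
        kvd = preset.k_vd if on else 0.0
        kaz = preset.k_az if on else 0.0
        kep = preset.k_ep
        return [-kvd * V + kep * A,
                kvd * V - (kaz + kep) * A + kep * Z,
                kaz * A - kep * Z]

    # integrate the two constant-light segments separately so the solver
    # never steps across the light-off discontinuity
    tl = t[t <= light]
    sol1 = solve_ivp(rhs, (0.0, light), [1.0, 0.0, 0.0], t_eval=tl,
                     rtol=1e-11, atol=1e-13)
    td = t[t > light]
    sol2 = solve_ivp(rhs, (light, t[-1]), list(sol1.y[:, -1]), t_eval=td,
                     rtol=1e-11, atol=1e-13)
    y = np.hstack([sol1.y, sol2.y])
    meta = {"genotype": preset.name, "actinic_umol": 1000,
            "vaz_per_100_chl": preset.vaz_per_100chl}
    profile = PigmentProfile(time=t, V=np.clip(y[0], 0, 1), A=np.clip(y[1], 0, 1),
                             Z=np.clip(y[2], 0, 1), meta=meta)
    return profile, protocol


def _fvfm_course(preset: GenotypePreset, hours: float = 6.0) -> TimeSeriesTrace:
    t = np.arange(0.0, hours * 3600.0 + 1.0, 900.0)
    k = preset.pi_k_per_h / 3600.0
    y = preset.pi_y_plateau + (preset.pi_y_init - preset.pi_y_plateau) * np.exp(-k * t)
    meta = {"genotype": preset.name, "actinic_umol": 550, "temperature": "4C"}
    return TimeSeriesTrace(time=t, value=y, kind=TraceKind.FVFM_COURSE, meta=meta)


_ECS_IRRADIANCES = (25.0, 50.0, 100.0, 150.0, 250.0, 400.0, 650.0, 1000.0)


def _ecs_curve(preset: GenotypePreset) -> TimeSeriesTrace:
    I = np.array(_ECS_IRRADIANCES)
    amp = preset.ecs_amp_rel * I / (I + preset.ecs_i_half)
    meta = {"genotype": preset.name, "x_axis": "irradiance_umol"}
    return TimeSeriesTrace(time=I, value=amp, kind=TraceKind.ECS_POINT_SET, meta=meta)


def generate_dataset(
    preset: GenotypePreset, what: str, seed: int = 0, noise: float = 0.0,
    t_max: float | None = None, dt: float | None = None,
) -> Dataset:
    """Generate one synthetic experiment for a genotype preset.

    Deterministic given (preset, what, seed, noise); ``noise=0`` returns
    the exact model curve.  ``t_max``/``dt`` override the default time
    grid where a grid applies.
    """
    if what not in KINDS:
        raise ValueError(f"unknown dataset kind '{what}'; choose from {KINDS}")
    prov = {"genotype": preset.name, "seed": seed, "noise": noise,
            "provenance": dict(preset.provenance)}

    if what == "dcmu_induction":
        trace = _dcmu_trace(preset, t_max or 2.0, dt or 1e-3)
        return Dataset(what, trace=add_noise(trace, noise, seed), provenance=prov)
    if what == "pq_rise":
        default_t = 4.0 * preset.n_pq / preset.k_ph
        trace = _pq_rise_trace(preset, t_max or default_t, dt or 2e-3)
        return Dataset(what, trace=add_noise(trace, noise, seed), provenance=prov)
    if what == "pam_session":
        trace, protocol = _pam_session(preset)
        return Dataset(what, trace=add_noise(trace, noise, seed),
                       protocol=protocol, provenance=prov)
    if what == "npq_protocol":
        trace, protocol = _npq_protocol(preset)
        return Dataset(what, trace=add_noise(trace, noise, seed),
                       protocol=protocol, provenance=prov)
    if what == "vaz_course":
        profile, protocol = _vaz_course(preset)
        if noise > 0:
            rng = np.random.default_rng(seed)
            for name in ("V", "A", "Z"):
                arr = getattr(profile, name)
                noisy = np.clip(arr * (1 + noise * rng.standard_normal(arr.size)), 0, 1)
                setattr(profile, name, noisy)
        return Dataset(what, profile=profile, protocol=protocol, provenance=prov)
    if what == "fvfm_course":
        trace = _fvfm_course(preset)
        return Dataset(what, trace=add_noise(trace, noise, seed), provenance=prov)
    # ecs_curve
    trace = _ecs_curve(preset)
    return Dataset(what, trace=add_noise(trace, noise, seed), provenance=prov)
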