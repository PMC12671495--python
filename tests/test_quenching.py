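import numpy as np
import pytest

from psiikin import (
    PulseProtocol,
    PulseRecord,
    QuenchSeries,
    TimeSeriesTrace,
    TraceKind,
    decompose_qe_qi,
    extract_pulse_levels,
    fit_sigmoid_lhc_npq,
    generate_dataset,
    make_preset,
    npq_integral,
    npq_timecourse,
    partition_yields,
)


def _rect_pulse_trace(pulse_levels, fs_level=0.3, f0=0.2, dt=0.5):
    """Flat trace at fs_level with rectangular pulses of known heights.

    The first level is fired in darkness (it plays the role of Fm)."""
    pulses = [15.0] + [45.0 + 30.0 * i for i in range(len(pulse_levels) - 1)]
    t_end = pulses[-1] + 30.0
    t = np.arange(0.0, t_end, dt)
    v = np.full_like(t, fs_level)
    v[t < 28.0] = f0  # dark baseline
    for tp, lvl in zip(pulses, pulse_levels):
        v[(t >= tp) & (t <= tp + 0.6)] = lvl
    proto = PulseProtocol(
        segments=[(28.0, t_end, 500.0)], pulses=pulses, dark_windows=[(0.0, 28.0)]
    )
    return TimeSeriesTrace(time=t, value=v, kind=TraceKind.PAM), proto


def test_rectangular_pulse_levels_recovered_exactly():
    levels = [1.0, 0.8, 0.6, 0.5]
    trace, proto = _rect_pulse_trace(levels)
    series = extract_pulse_levels(trace, proto)
    assert series.F0 == pytest.approx(0.2)
    assert series.Fm == pytest.approx(1.0)
    got = [rec.Fm_prime for rec in series.pulses]
    assert got == pytest.approx(levels)
    assert all(rec.Fs == pytest.approx(0.3) for rec in series.pulses[1:])


def test_jittered_pulse_timing_still_within_one_percent():
    levels = [1.0, 0.8, 0.6, 0.5]
    trace, proto = _rect_pulse_trace(levels)
    rng = np.random.default_rng(7)
    jittered = PulseProtocol(
        segments=proto.segments,
        pulses=[tp + rng.uniform(-0.05, 0.05) for tp in proto.pulses],
        dark_windows=proto.dark_windows,
    )
    series = extract_pulse_levels(trace, jittered)
    got = np.array([rec.Fm_prime for rec in series.pulses])
    assert np.max(np.abs(got - levels) / np.array(levels)) < 0.01


def test_npq_formula():
    series = QuenchSeries(
        F0=0.2, Fm=2.0,
        pulses=[PulseRecord(t=0, Fs=0.5, Fm_prime=1.0),
                PulseRecord(t=30, Fs=0.5, Fm_prime=2.0)],
    )
    npq = npq_timecourse(series)
    assert npq[0, 1] == pytest.approx(1.0)   # (2-1)/1
    assert npq[1, 1] == pytest.approx(0.0)   # unquenched


def test_yield_partition_hand_arithmetic():
    series = QuenchSeries(
        F0=0.1, Fm=1.0, pulses=[PulseRecord(t=0, Fs=0.3, Fm_prime=0.5)]
    )
    _, phi_ii, phi_npq, phi_no, _ = partition_yields(series)[0]
    assert phi_ii == pytest.approx(0.4)
    assert phi_npq == pytest.approx(0.3)
    assert phi_no == pytest.approx(0.3)
    assert phi_ii + phi_npq + phi_no == pytest.approx(1.0, abs=1e-15)


def test_dark_adapted_pulse_limit():
    # Fs=F0 and Fm'=Fm: Phi_II = Fv/Fm, Phi_NPQ = 0, qL = 1
    series = QuenchSeries(
        F0=0.18, Fm=1.0, pulses=[PulseRecord(t=0, Fs=0.18, Fm_prime=1.0)]
    )
    _, phi_ii, phi_npq, _, qL = partition_yields(series)[0]
    assert phi_ii == pytest.approx(series.fv_fm)
    assert phi_npq == pytest.approx(0.0, abs=1e-15)
    assert qL == pytest.approx(1.0)


@pytest.mark.parametrize("genotype", ["WT", "npq4", "koLHCII", "koLhcb"])
def test_yield_conservation_across_presets(genotype):
    ds = generate_dataset(make_preset(genotype), "pam_session")
    series = extract_pulse_levels(ds.trace, ds.protocol)
    rows = partition_yields(series)
    sums = rows[:, 1] + rows[:, 2] + rows[:, 3]
    assert np.max(np.abs(sums - 1.0)) < 1e-14


def test_decompose_flat_zero_npq():
    proto = PulseProtocol(
        segments=[(60, 540, 1000)], pulses=list(np.arange(30.0, 1020.0, 30.0)),
        dark_windows=[(0, 60), (540, 1020)],
    )
    npq = np.column_stack([np.arange(30.0, 1020.0, 30.0),
                           np.zeros(33)])
    dec = decompose_qe_qi(npq, proto)
    assert dec.qE == 0.0 and dec.qI == 0.0 and dec.npq_max == 0.0


def test_psbs_null_preset_has_no_fast_component():
    ds = generate_dataset(make_preset("npq4"), "npq_protocol")
    series = extract_pulse_levels(ds.trace, ds.protocol)
    dec = decompose_qe_qi(npq_timecourse(series), ds.protocol)
    assert dec.qE == pytest.approx(0.0, abs=0.02)
    assert dec.qI > 0.2


def test_exponential_unmixing_agrees_with_endpoint_split():
    ds = generate_dataset(make_preset("WT"), "npq_protocol")
    series = extract_pulse_levels(ds.trace, ds.protocol)
    npq = npq_timecourse(series)
    a = decompose_qe_qi(npq, ds.protocol, method="endpoint")
    b = decompose_qe_qi(npq, ds.protocol, method="unmix")
    assert b.qE == pytest.approx(a.qE, rel=0.05)


def test_npq_integral_constant_and_additive():
    t = np.arange(0.0, 601.0, 30.0)
    npq = np.column_stack([t, np.ones_like(t)])
    assert npq_integral(npq, (0.0, 480.0)) == pytest.approx(480.0)
    whole = npq_integral(npq, (0.0, 600.0))
    parts = npq_integral(npq, (0.0, 250.0)) + npq_integral(npq, (250.0, 600.0))
    assert whole == pytest.approx(parts)
    with pytest.raises(ValueError, match="exceeds"):
        npq_integral(npq, (0.0, 1000.0))


def test_sigmoid_fit_recovers_noiseless_logistic():
    x = np.linspace(0.004, 0.028, 16)
    y = 50.0 + 400.0 / (1.0 + np.exp(-(x - 0.015) / 0.003))
    fit = fit_sigmoid_lhc_npq(np.column_stack([x, y]))
    assert fit.y0 == pytest.approx(50.0, rel=1e-3)
    assert fit.a == pytest.approx(400.0, rel=1e-3)
    assert fit.x0 == pytest.approx(0.015, rel=1e-3)
    assert fit.r_squared > 0.999999
    # a >= 0 enforced: fitted curve monotone increasing
    assert np.all(np.diff(fit.predicted[np.argsort(x)]) >= 0)
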