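import ast
from pathlib import Path

import numpy as np
import pytest

from psiikin import (
    TimeSeriesTrace,
    TraceKind,
    add_noise,
    available_genotypes,
    generate_dataset,
    make_preset,
    write_trace,
)
from psiikin.presets import GenotypePreset, numeric_fields

ANALYSIS_MODULES = (
    "connectivity", "quenching", "xanthophyll", "photoinhibition", "dose_response",
)


def test_unknown_genotype_lists_available():
    with pytest.raises(KeyError, match="WT"):
        make_preset("no-such-line")


def test_preset_is_a_private_copy():
    a = make_preset("WT")
    a.J = 99.0
    assert make_preset("WT").J == 2.05


def test_shipped_presets():
    assert set(available_genotypes()) == {
        "WT", "npq4", "NoM", "koLHCII", "koLhcb", "lowLHCII"
    }
    wt = make_preset("WT")
    assert wt.J == 2.05 and wt.fvfm == 0.82
    ko = make_preset("koLHCII")
    assert ko.sigma_rel == 0.55 and ko.qE == 0.8
    assert make_preset("npq4").qE == 0.0


def test_every_numeric_preset_field_has_provenance():
    """Each preset annotates the origin of every numeric parameter."""
    fields = numeric_fields()
    assert "J" in fields and "qE" in fields
    for name in available_genotypes():
        preset = make_preset(name)
        for f in fields:
            assert f in preset.provenance and preset.provenance[f].strip(), (
                f"{name}.{f} lacks a provenance note"
            )


def test_analysis_modules_do_not_import_generator():
    """Recovery tests are honest only if analyzers share no code with the
    generator: no analysis module may import synthetic or presets."""
    src_dir = Path(__file__).resolve().parents[1] / "src" / "psiikin"
    for mod in ANALYSIS_MODULES:
        tree = ast.parse((src_dir / f"{mod}.py").read_text())
        for node in ast.walk(tree):
            names = []
            if isinstance(node, ast.Import):
                names = [a.name for a in node.names]
            elif isinstance(node, ast.ImportFrom):
                names = [node.module or ""]
            for n in names:
                assert "synthetic" not in n and "presets" not in n, (
                    f"{mod} imports generator code ({n})"
                )


def test_same_seed_identical_bytes(tmp_path):
    a = generate_dataset(make_preset("WT"), "dcmu_induction", seed=3, noise=0.02)
    b = generate_dataset(make_preset("WT"), "dcmu_induction", seed=3, noise=0.02)
    c = generate_dataset(make_preset("WT"), "dcmu_induction", seed=4, noise=0.02)
    pa, pb, pc = (tmp_path / n for n in ("a.csv", "b.csv", "c.csv"))
    write_trace(a.trace, pa)
    write_trace(b.trace, pb)
    write_trace(c.trace, pc)
    assert pa.read_bytes() == pb.read_bytes()
    assert pa.read_bytes() != pc.read_bytes()


def test_zero_noise_is_exact_model_curve():
    ds0 = generate_dataset(make_preset("WT"), "dcmu_induction", seed=1, noise=0.0)
    ds1 = generate_dataset(make_preset("WT"), "dcmu_induction", seed=2, noise=0.0)
    assert np.array_equal(ds0.trace.value, ds1.trace.value)


def test_add_noise_contract():
    trace = TimeSeriesTrace(time=np.arange(4.0), value=np.full(4, 2.0),
                            kind=TraceKind.PAM)
    assert add_noise(trace, 0.0, 1) is trace
    with pytest.raises(ValueError):
        add_noise(trace, -0.1, 1)
    noisy = add_noise(trace, 5.0, 1)  # huge sd exercises the clip
    assert np.all(noisy.value >= 0.0)


def test_noisy_replicate_mean_approaches_truth():
    # CLT check: mean of 1000 noisy replicates of a constant trace
    trace = TimeSeriesTrace(time=np.arange(10.0), value=np.full(10, 1.0),
                            kind=TraceKind.PAM)
    sd = 0.03
    means = [add_noise(trace, sd, seed).value.mean() for seed in range(1000)]
    se = sd / np.sqrt(10 * 1000)
    assert abs(np.mean(means) - 1.0) < 3 * se


def test_unknown_kind_rejected():
    with pytest.raises(ValueError, match="unknown dataset kind"):
        generate_dataset(make_preset("WT"), "spectral_scan")


def test_generated_protocol_matches_trace_span():
    from psiikin import validate_protocol

    for what in ("npq_protocol", "pam_session"):
        ds = generate_dataset(make_preset("WT"), what)
        assert validate_protocol(ds.protocol, ds.trace) == []


def test_preset_closure_rate_scales_with_cross_section():
    wt = make_preset("WT")
    for g in ("koLHCII", "NoM", "koLhcb"):
        pre = make_preset(g)
        assert pre.k_ph == pytest.approx(pre.sigma_rel * wt.k_ph)


def test_photosensitivity_ordering_of_presets():
    halves = {g: make_preset(g).pi_t_half_h
              for g in ("lowLHCII", "NoM", "koLHCII", "WT")}
    assert halves["lowLHCII"] < halves["NoM"] < halves["koLHCII"] < halves["WT"]
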