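"""End-to-end pipeline: generate (or load) traces, run the selected
analyses, write a machine-readable results JSON plus a human-readable
summary.  Deterministic under a fixed seed."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .connectivity import (
    cross_section_rescale,
    fit_dcmu_induction,
    slowdown_and_pq_ratio,
    two_thirds_antenna_size,
)
from .dose_response import fit_saturation
from .io import read_protocol, read_trace
from .photoinhibition import fit_decay_half_time
from .presets import make_preset
from .quenching import decompose_qe_qi, extract_pulse_levels, npq_integral, npq_timecourse, partition_yields
from .synthetic import generate_dataset
from .xanthophyll import XanthophyllState, deepoxidation_index, fit_vaz

ALL_ANALYSES = ("induction", "rescale", "pq_ratio", "quench", "yields",
                "vaz", "photoinhibition", "ecs")

__all__ = ["RunConfig", "run_pipeline", "ALL_ANALYSES"]


@dataclass
class RunConfig:
    """Either a generator spec (genotype + seed + noise) or explicit input
    paths — exactly one of the two."""

    out_dir: str
    genotype: str | None = None
    inputs: dict = field(default_factory=dict)  # analysis -> {trace, protocol}
    analyses: tuple = ALL_ANALYSES
    reference_genotype: str = "WT"
    seed: int = 0
    noise: float = 0.0

    def __post_init__(self) -> None:
        if bool(self.genotype) == bool(self.inputs):
            raise ValueError("exactly one of genotype / inputs must be given")
        bad = set(self.analyses) - set(ALL_ANALYSES)
        if bad:
            raise ValueError(f"unknown analyses: {sorted(bad)}")


def _round(x: float, nd: int = 6) -> float:
    return float(round(float(x), nd))


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured analyses and write results to ``out_dir``.

    Returns the results dictionary; any stage failure is re-raised with
    the stage name attached.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {"genotype": config.genotype, "seed": config.seed}
    stage = "setup"
    try:
        if config.genotype:
            preset = make_preset(config.genotype)
            ref = make_preset(config.reference_genotype)
        for analysis in config.analyses:
            stage = analysis
            results[analysis] = _run_one(analysis, config, preset if config.genotype else None, ref if config.genotype else None)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    payload = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "results": results,
    }
    text = json.dumps(payload, indent=1, sort_keys=True)
    (out_dir / "results.json").write_text(text + "\n")
    (out_dir / "summary.txt").write_text(_summary(results))
    return payload


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(
        {
            "genotype": config.genotype, "inputs": config.inputs,
            "analyses": list(config.analyses), "seed": config.seed,
            "noise": config.noise, "reference": config.reference_genotype,
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_or_generate(analysis: str, kind: str, config: RunConfig, preset):
    if preset is not None:
        return generate_dataset(preset, kind, seed=config.seed, noise=config.noise)
    spec = config.inputs.get(analysis)
    if spec is None:
        raise ValueError(f"no input configured for analysis '{analysis}'")

    class _Loaded:
        trace = read_trace(spec["trace"]) if "trace" in spec else None
        protocol = read_protocol(spec["protocol"]) if "protocol" in spec else None
        profile = None

    return _Loaded()


def _run_one(analysis: str, config: RunConfig, preset, ref) -> dict:
    if analysis == "induction":
        ds = _load_or_generate(analysis, "dcmu_induction", config, preset)
        fit = fit_dcmu_induction(ds.trace)
        t23, inv = two_thirds_antenna_size(ds.trace)
        return {
            "J": _round(fit.params.J), "k_ph": _round(fit.params.k_ph),
            "F0": _round(fit.params.F0), "Fv": _round(fit.params.Fv),
            "t23_s": _round(t23), "inv_t23_per_s": _round(inv),
        }
    if analysis == "rescale":
        if preset is None:
            raise ValueError("rescale requires generator mode or two traces")
        ds = generate_dataset(preset, "dcmu_induction", seed=config.seed,
                              noise=config.noise, t_max=6.0)
        ds_ref = generate_dataset(ref, "dcmu_induction", seed=config.seed + 1,
                                  noise=config.noise, t_max=6.0)
        res = cross_section_rescale(ds.trace, ds_ref.trace)
        return {"sigma_rel": _round(res.factor),
                "v06_time_ratio": _round(res.v06_time_ratio),
                "shape_score": _round(res.shape_score)}
    if analysis == "pq_ratio":
        if preset is None:
            raise ValueError("pq_ratio requires generator mode")
        ds = generate_dataset(preset, "pq_rise", seed=config.seed, noise=config.noise)
        ds_ref = generate_dataset(ref, "pq_rise", seed=config.seed + 1,
                                  noise=config.noise)
        res = slowdown_and_pq_ratio(ds.trace, ds_ref.trace,
                                    sigma_ratio=preset.sigma_rel / ref.sigma_rel)
        return {"slowdown": _round(res.slowdown),
                "pq_per_rc_ratio": _round(res.pq_per_rc_ratio),
                "pq_per_rc_rounded": res.pq_per_rc_rounded}
    if analysis == "quench":
        ds = _load_or_generate(analysis, "npq_protocol", config, preset)
        series = extract_pulse_levels(ds.trace, ds.protocol)
        npq = npq_timecourse(series)
        dec = decompose_qe_qi(npq, ds.protocol)
        t_on = ds.protocol.light_periods()[0][0]
        integral = npq_integral(npq, (t_on, t_on + 480.0))
        return {"fv_fm": _round(series.fv_fm), "qE": _round(dec.qE),
                "qI": _round(dec.qI), "npq_max": _round(dec.npq_max),
                "npq_integral_0_8min": _round(integral)}
    if analysis == "yields":
        ds = _load_or_generate(analysis, "pam_session", config, preset)
        series = extract_pulse_levels(ds.trace, ds.protocol)
        rows = partition_yields(series)
        plateau = [r for r in rows if ds.protocol.intensity_at(r[0]) >= 200]
        phi_no = sum(r[3] for r in plateau) / len(plateau)
        return {"fv_fm": _round(series.fv_fm), "phi_no_plateau": _round(phi_no)}
    if analysis == "vaz":
        ds = _load_or_generate(analysis, "vaz_course", config, preset)
        profile = ds.profile
        t_off = ds.protocol.light_periods()[0][1]
        idx = int(np.argmin(np.abs(profile.time - t_off)))
        state = XanthophyllState(V=profile.V[idx], A=profile.A[idx], Z=profile.Z[idx])
        kin = fit_vaz(profile, ds.protocol)
        return {"di_end_of_light": _round(deepoxidation_index(state)),
                "k_vd": _round(kin.k_vd, 8), "k_az": _round(kin.k_az, 8),
                "k_ep": _round(kin.k_ep, 8)}
    if analysis == "photoinhibition":
        ds = _load_or_generate(analysis, "fvfm_course", config, preset)
        fit = fit_decay_half_time(ds.trace)
        return {"t_half_h": _round(fit.t_half_h), "y_init": _round(fit.y_init),
                "y_plateau": _round(fit.y_plateau)}
    if analysis == "ecs":
        ds = _load_or_generate(analysis, "ecs_curve", config, preset)
        fit = fit_saturation(ds.trace)
        return {"i_half": _round(fit.i_half), "amp_max": _round(fit.amp_max)}
    raise ValueError(f"unknown analysis '{analysis}'")


def _summary(results: dict) -> str:
    lines = [f"psiikin pipeline results — genotype {results.get('genotype')}"]
    for key, val in results.items():
        if isinstance(val, dict):
            body = ", ".join(f"{k}={v}" for k, v in val.items())
            lines.append(f"  {key}: {body}")
    return "\n".join(lines) + "\n"
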