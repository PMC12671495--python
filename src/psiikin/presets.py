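"""Genotype parameter presets for the synthetic-trace generator.

Each preset bundles, for one Arabidopsis PSII-antenna genotype, every
parameter the generator needs: connectivity J and relative optical
cross-section, dark-adapted fluorescence levels, PQ-pool size, NPQ
amplitudes and time constants, xanthophyll-cycle rates, photoinhibition
decay, and pmf (ECS) saturation.  Published measurements are encoded
directly; parameters the source experiments do not constrain are filled
with field-realistic values and tagged ``assumed`` (or ``calibrated`` when
a rate was solved once so that a published steady state emerges from the
kinetic scheme).  The ``provenance`` mapping records the origin of every
numeric field.

The photochemical closure rate is derived, not stored: the wild-type rate
reproduces the published WT functional antenna size (1/t_2/3 = 5.76 s⁻¹
under the weak measuring light), and mutant rates scale by the published
relative cross-sections (0.55 / 1.9 / 0.25 for koLHCII / NoM / koLhcb).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, fields

__all__ = ["GenotypePreset", "make_preset", "available_genotypes", "WT_INV_T23"]

WT_INV_T23 = 5.76        # s^-1; published WT functional antenna size
WT_N_PQ = 12.0           # oxidized-PQ electron equivalents per RC, WT
K_OX = 150.0             # s^-1; Q_A- -> PQ reoxidation rate (both assumed,
                         # literature-scale; see docs/methods.md)


def _tau23(J: float) -> float:
    """Dimensionless two-thirds time of the connected-units rise at k=1."""
    p = J / (1.0 + J)
    V = 2.0 / 3.0
    C = V / (1.0 - p + p * V)
    return p * C - (1.0 - p) * math.log(1.0 - C)


_K_PH_WT = _tau23(2.05) * WT_INV_T23  # = 7.0279 s^-1


@dataclass
class GenotypePreset:
    name: str
    J: float                  # connectivity
    sigma_rel: float          # optical cross-section relative to WT
    f0_rel: float             # F0 per Chl, normalized to WT (metadata)
    fvfm: float               # dark-adapted Fv/Fm
    n_pq_ratio: float         # PQ-pool electron equivalents per RC, vs WT
    qE: float                 # fast NPQ amplitude
    qI: float                 # sustained NPQ amplitude
    tau_fast: float           # s, qE rise
    tau_slow: float           # s, qI (Zea-linked) rise
    tau_relax: float          # s, qE dark relaxation
    phi_npq_plateau: float    # Phi_NPQ at saturating light
    phi_no_plateau: float     # Phi_NO at >=200 umol
    di_target: float          # end-of-light de-epoxidation index
    k_vd: float               # s^-1, V->A under light
    k_az: float               # s^-1, A->Z under light
    k_ep: float               # s^-1, dark epoxidation
    pi_y_init: float          # Fv/Fm at start of photoinhibitory treatment
    pi_y_plateau: float       # asymptote of the Fv/Fm decay
    pi_t_half_h: float        # h, photoinhibition half-time (k = ln2/t_half)
    ecs_amp_rel: float        # pmf amplitude relative to WT
    ecs_i_half: float         # umol photons m^-2 s^-1
    vaz_per_100chl: float     # xanthophyll-cycle pool size
    psbs_rel: float           # PsbS/PSII core, relative to WT (metadata)
    provenance: dict = field(default_factory=dict)

    @property
    def k_ph(self) -> float:
        """Photochemical closure rate (s⁻¹) under the weak measuring light."""
        return self.sigma_rel * _K_PH_WT

    @property
    def n_pq(self) -> float:
        return self.n_pq_ratio * WT_N_PQ

    @property
    def k_ox(self) -> float:
        return K_OX

    @property
    def F0(self) -> float:
        """Dark F0 in relative units with Fm normalized to 1."""
        return 1.0 - self.fvfm

    @property
    def Fv(self) -> float:
        return self.fvfm

    @property
    def pi_k_per_h(self) -> float:
        return math.log(2.0) / self.pi_t_half_h


_T2 = "Table 2"
_F2C = "Fig 2C normalization factors (0.55, 1.9, 0.25)"
_ASSUMED = "assumed"
_COMMON = {
    "tau_fast": _ASSUMED + " (30 s, sub-minute qE rise)",
    "tau_slow": _ASSUMED + " (180 s, Zea-linked slow phase)",
    "tau_relax": _ASSUMED + " (60 s, fast dark relaxation)",
    "k_az": _ASSUMED + " (A->Z faster than V->A)",
    "k_ep": _ASSUMED + " (slow dark epoxidation, ~30 min half-time)",
    "ecs_i_half": "Results: half-saturation of pmf at ~100 umol for all genotypes",
}


def _preset(**kw) -> GenotypePreset:
    prov = {**_COMMON, **kw.pop("provenance")}
    return GenotypePreset(provenance=prov, **kw)


_PRESETS: dict[str, GenotypePreset] = {
    "WT": _preset(
        name="WT", J=2.05, sigma_rel=1.0, f0_rel=1.0, fvfm=0.82,
        n_pq_ratio=1.0, qE=2.2, qI=0.5,
        tau_fast=30.0, tau_slow=180.0, tau_relax=60.0,
        phi_npq_plateau=0.60, phi_no_plateau=0.28,
        di_target=0.30, k_vd=1.1614665e-3, k_az=3.0e-3, k_ep=4.0e-4,
        pi_y_init=0.82, pi_y_plateau=0.0,
        pi_t_half_h=math.log(2.0) / (math.log(1.25) / 6.0),
        ecs_amp_rel=1.0, ecs_i_half=100.0, vaz_per_100chl=5.2, psbs_rel=1.0,
        provenance={
            "J": _T2, "sigma_rel": "reference genotype", "f0_rel": _T2,
            "fvfm": _T2, "n_pq_ratio": "reference genotype",
            "qE": "Results: maximal qE amplitude 2.2 in wild type",
            "qI": _ASSUMED,
            "phi_npq_plateau": "Results: Phi_NPQ reaching 0.6 in wild type",
            "phi_no_plateau": "Results: Phi_NO steady at 0.28 above 200 umol",
            "di_target": "Results/Fig 3B: DI ~0.3 upon illumination",
            "k_vd": "calibrated so DI(8 min light) = 0.30",
            "pi_y_init": _T2, "pi_y_plateau": _ASSUMED,
            "pi_t_half_h": "derived: Fv/Fm reaches 80% of 0.82 after 6 h",
            "ecs_amp_rel": "reference genotype",
            "vaz_per_100chl": "Results: 5.2 xanthophylls per 100 Chls",
            "psbs_rel": "reference genotype",
        },
    ),
    "npq4": _preset(
        name="npq4", J=2.05, sigma_rel=1.0, f0_rel=1.0, fvfm=0.82,
        n_pq_ratio=1.0, qE=0.0, qI=0.4,
        tau_fast=30.0, tau_slow=240.0, tau_relax=60.0,
        phi_npq_plateau=0.05, phi_no_plateau=0.40,
        di_target=0.30, k_vd=1.1614665e-3, k_az=3.0e-3, k_ep=4.0e-4,
        pi_y_init=0.82, pi_y_plateau=0.0, pi_t_half_h=8.0,
        ecs_amp_rel=1.0, ecs_i_half=100.0, vaz_per_100chl=5.2, psbs_rel=0.0,
        provenance={
            "J": _ASSUMED + " (wild-type antenna)", "sigma_rel": _ASSUMED,
            "f0_rel": _ASSUMED, "fvfm": _ASSUMED + " (wild-type-like pigments, Table 1)",
            "n_pq_ratio": _ASSUMED,
            "qE": "Results: PsbS deletion gives complete loss of qE; npq4 lowest qE",
            "qI": _ASSUMED + " (slowest dark recovery)",
            "phi_npq_plateau": _ASSUMED, "phi_no_plateau": _ASSUMED,
            "di_target": _ASSUMED + " (xanthophyll cycle intact)",
            "k_vd": _ASSUMED + " (wild-type rate)",
            "pi_y_init": _ASSUMED, "pi_y_plateau": _ASSUMED, "pi_t_half_h": _ASSUMED,
            "ecs_amp_rel": _ASSUMED, "vaz_per_100chl": _ASSUMED,
            "psbs_rel": "PsbS-null by construction",
        },
    ),
    "NoM": _preset(
        name="NoM", J=0.79, sigma_rel=1.9, f0_rel=3.23, fvfm=0.61,
        n_pq_ratio=6.0, qE=1.8, qI=0.5,
        tau_fast=90.0, tau_slow=180.0, tau_relax=60.0,
        phi_npq_plateau=0.60, phi_no_plateau=0.35,
        di_target=0.30, k_vd=1.1614665e-3, k_az=3.0e-3, k_ep=4.0e-4,
        pi_y_init=0.61, pi_y_plateau=0.0, pi_t_half_h=1.4,
        ecs_amp_rel=0.95, ecs_i_half=100.0, vaz_per_100chl=5.5, psbs_rel=1.0,
        provenance={
            "J": _T2, "sigma_rel": _F2C, "f0_rel": _T2, "fvfm": _T2,
            "n_pq_ratio": "Discussion: PQ per active RC roughly 6x wild type",
            "qE": _ASSUMED + " (robust quenching, below wild type)",
            "qI": _ASSUMED,
            "tau_fast": _ASSUMED + " (residual qE slowly activated)",
            "phi_npq_plateau": "Results: Phi_NPQ reaching 0.6 in NoM",
            "phi_no_plateau": _ASSUMED,
            "di_target": _ASSUMED, "k_vd": _ASSUMED + " (wild-type rate)",
            "pi_y_init": _T2, "pi_y_plateau": _ASSUMED,
            "pi_t_half_h": "Results: t_1/2 = 1.4 h for NoM",
            "ecs_amp_rel": _ASSUMED, "vaz_per_100chl": _ASSUMED,
            "psbs_rel": _ASSUMED,
        },
    ),
    "koLHCII": _preset(
        name="koLHCII", J=1.76, sigma_rel=0.55, f0_rel=2.13, fvfm=0.76,
        n_pq_ratio=1.0, qE=0.8, qI=0.4,
        tau_fast=30.0, tau_slow=180.0, tau_relax=60.0,
        phi_npq_plateau=0.40, phi_no_plateau=0.60,
        di_target=0.30, k_vd=1.1614665e-3, k_az=3.0e-3, k_ep=4.0e-4,
        pi_y_init=0.76, pi_y_plateau=0.0, pi_t_half_h=1.9,
        ecs_amp_rel=0.80, ecs_i_half=100.0, vaz_per_100chl=7.6, psbs_rel=0.5,
        provenance={
            "J": _T2 + " (#17)", "sigma_rel": _F2C, "f0_rel": _T2, "fvfm": _T2,
            "n_pq_ratio": "Results: PQ pool per RC equal to wild type",
            "qE": "Results: maximal qE amplitude of 0.8",
            "qI": _ASSUMED + " (no substantial increase in qI)",
            "phi_npq_plateau": "Results: Phi_NPQ 0.4-0.45 in koLHCII",
            "phi_no_plateau": "Results: Phi_NO increased to 0.6",
            "di_target": "Results: DI kinetics similar to wild type (~0.3)",
            "k_vd": _ASSUMED + " (wild-type rate)",
            "pi_y_init": _T2,
            "pi_y_plateau": _ASSUMED,
            "pi_t_half_h": "Results: t_1/2 = 1.9 h for koLHCII",
            "ecs_amp_rel": "Results: pmf reduced by 20% in koLHCII",
            "vaz_per_100chl": "Results: 7.6 xanthophylls per 100 Chls",
            "psbs_rel": "Fig 3A: PsbS/PSII core reduced by 50%",
        },
    ),
    "koLhcb": _preset(
        name="koLhcb", J=0.60, sigma_rel=0.25, f0_rel=5.46, fvfm=0.54,
        n_pq_ratio=6.0, qE=0.45, qI=0.15,
        tau_fast=100.0, tau_slow=240.0, tau_relax=60.0,
        phi_npq_plateau=0.20, phi_no_plateau=0.80,
        di_target=0.50, k_vd=1.9456039e-3, k_az=6.0e-3, k_ep=4.0e-4,
        pi_y_init=0.54, pi_y_plateau=0.0, pi_t_half_h=1.6,
        ecs_amp_rel=0.65, ecs_i_half=100.0, vaz_per_100chl=9.4, psbs_rel=0.83,
        provenance={
            "J": _T2 + " (#16)", "sigma_rel": _F2C, "f0_rel": _T2, "fvfm": _T2,
            "n_pq_ratio": "Discussion: slowing comparable to NoM",
            "qE": "calibrated: maximal NPQ at 22% of wild type (with qI)",
            "qI": "calibrated: maximal NPQ at 22% of wild type (with qE)",
            "tau_fast": _ASSUMED + " (much slower NPQ rise than koLHCII)",
            "tau_slow": _ASSUMED,
            "phi_npq_plateau": "Results: Phi_NPQ remained very low (0.2)",
            "phi_no_plateau": "Results: Phi_NO increased to 0.8",
            "di_target": "Results: significantly faster, DI ~0.5",
            "k_vd": "calibrated so DI(8 min light) = 0.50",
            "k_az": _ASSUMED + " (fast conversion of lipid-phase Vio)",
            "pi_y_init": _T2, "pi_y_plateau": _ASSUMED, "pi_t_half_h": _ASSUMED,
            "ecs_amp_rel": "Results: pmf reduced by 35% in koLhcb",
            "vaz_per_100chl": "Results: 9.4 xanthophylls per 100 Chls",
            "psbs_rel": "Fig 3A: PsbS reduced by 14-20%",
        },
    ),
    "lowLHCII": _preset(
        name="lowLHCII", J=1.70, sigma_rel=0.55, f0_rel=2.1, fvfm=0.70,
        n_pq_ratio=1.0, qE=1.0, qI=0.4,
        tau_fast=30.0, tau_slow=180.0, tau_relax=60.0,
        phi_npq_plateau=0.45, phi_no_plateau=0.50,
        di_target=0.30, k_vd=1.1614665e-3, k_az=3.0e-3, k_ep=4.0e-4,
        pi_y_init=0.70, pi_y_plateau=0.0, pi_t_half_h=1.1,
        ecs_amp_rel=0.80, ecs_i_half=100.0, vaz_per_100chl=6.0, psbs_rel=0.7,
        provenance={
            "J": _ASSUMED + " (LHCII-retaining, koLHCII-like stoichiometry)",
            "sigma_rel": _ASSUMED + " (same PSII/LHC ratio as koLHCII)",
            "f0_rel": _ASSUMED, "fvfm": _ASSUMED, "n_pq_ratio": _ASSUMED,
            "qE": _ASSUMED + " (NPQ higher than koLHCII)",
            "qI": _ASSUMED,
            "phi_npq_plateau": _ASSUMED, "phi_no_plateau": _ASSUMED,
            "di_target": _ASSUMED, "k_vd": _ASSUMED + " (wild-type rate)",
            "pi_y_init": _ASSUMED, "pi_y_plateau": _ASSUMED,
            "pi_t_half_h": "Results: t_1/2 = 1.1 h for lowLHCII",
            "ecs_amp_rel": _ASSUMED, "vaz_per_100chl": _ASSUMED,
            "psbs_rel": _ASSUMED,
        },
    ),
}


def available_genotypes() -> list[str]:
    return sorted(_PRESETS)


def make_preset(genotype: str) -> GenotypePreset:
    """Return the shipped preset for a genotype (a private copy)."""
    try:
        return copy.deepcopy(_PRESETS[genotype])
    except KeyError:
        raise KeyError(
            f"unknown genotype '{genotype}'; available: {', '.join(available_genotypes())}"
        ) from None


def numeric_fields() -> list[str]:
    """Names of the numeric preset fields (used to audit provenance)."""
    return [
        f.name for f in fields(GenotypePreset)
        if f.type == "float"
    ]
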