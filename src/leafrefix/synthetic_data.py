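"""Study-shaped synthetic gas-exchange data.

Generates A/Ci curves and trait tables with the statistical structure the
downstream analysis is designed to detect: six woody species spanning
deciduous/evergreen and primary/climax groups, three seasons, the ten-step
CO2 sequence, and species-level contrasts in mesophyll resistance that
translate into contrasts in refixation percentage.

All randomness flows from one master seed through per-sample
``numpy.random.SeedSequence`` spawning, so studies are bit-reproducible and
individual samples can be regenerated in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .aci_fit import ACiCurve, GasExchangeRecord, SPECIES_INFO
from .fvcb_refix import (
    FvCBParams,
    KineticConstants,
    InfeasibleOperatingPointError,
    net_assimilation_min,
    stomatal_resistance,
)

__all__ = [
    "SpeciesProfile",
    "StudyDesign",
    "DEFAULT_PROFILES",
    "default_profiles",
    "draw_parameters",
    "simulate_curve",
    "simulate_study",
]

#: variables a profile must provide (mean, sd) for
PROFILE_VARS = (
    "Vcmax", "Jmax", "TPU", "Rd", "rm", "gsw",
    "LMA", "water_content", "Tcw", "Fias",
)

#: multiplicative season effects applied to profile means.  Photosynthetic
#: capacity and LMA are lowest early in the season, water content highest;
#: rm and the anatomical traits carry no season effect.
SEASON_EFFECTS: dict[str, dict[str, float]] = {
    "early": {"Vcmax": 0.85, "Jmax": 0.85, "TPU": 0.85, "Rd": 0.9,
              "gsw": 1.1, "LMA": 0.85, "water_content": 1.12},
    "mid": {},
    "late": {"Vcmax": 0.95, "Jmax": 0.95, "TPU": 0.95, "Rd": 0.95,
             "gsw": 0.9, "LMA": 1.05, "water_content": 0.95},
}

SEASONS = ("early", "mid", "late")


@dataclass(frozen=True)
class SpeciesProfile:
    """Generative distributions (mean, sd) of one species' traits."""

    species: str
    functional_type: str
    succession: str
    means: dict[str, float]
    sds: dict[str, float]
    rm_trait_corr: float = 0.5  # correlation of rm with LMA and Tcw

    def __post_init__(self) -> None:
        for var in PROFILE_VARS:
            if var not in self.means or var not in self.sds:
                raise ValueError(f"profile {self.species!r} missing variable {var!r}")
            if not self.means[var] > 0:
                raise ValueError(f"profile {self.species!r}: mean {var} must be positive")
            if self.sds[var] < 0:
                raise ValueError(f"profile {self.species!r}: sd {var} must be non-negative")

    def season_mean(self, var: str, season: str) -> float:
        return self.means[var] * SEASON_EFFECTS.get(season, {}).get(var, 1.0)


def _profile(species: str, means: dict[str, float], sds: dict[str, float]) -> SpeciesProfile:
    ft, succ = SPECIES_INFO[species]
    return SpeciesProfile(species=species, functional_type=ft, succession=succ,
                          means=means, sds=sds)


# Trait means are calibrated so the full simulate -> fit -> refix pipeline
# yields species-mean refixation percentages near the published group
# contrasts (deciduous ~ 36-42%, evergreen climax ~ 55-60%); they are
# calibration targets, not ground-truth claims.
DEFAULT_PROFILES: tuple[SpeciesProfile, ...] = (
    _profile(
        "Betula pendula",
        means=dict(Vcmax=70.0, Jmax=108.5, TPU=7.93, Rd=1.2, rm=0.55, gsw=0.209,
                   LMA=62.0, water_content=58.0, Tcw=0.20, Fias=38.2),
        sds=dict(Vcmax=8.0, Jmax=11.0, TPU=0.8, Rd=0.25, rm=0.14, gsw=0.045,
                 LMA=7.0, water_content=4.0, Tcw=0.03, Fias=9.7),
    ),
    _profile(
        "Quercus robur",
        means=dict(Vcmax=88.0, Jmax=136.4, TPU=10.05, Rd=1.5, rm=0.40, gsw=0.357,
                   LMA=78.0, water_content=55.0, Tcw=0.22, Fias=28.8),
        sds=dict(Vcmax=10.0, Jmax=14.0, TPU=1.0, Rd=0.3, rm=0.10, gsw=0.07,
                 LMA=9.0, water_content=4.0, Tcw=0.03, Fias=6.9),
    ),
    _profile(
        "Larix decidua",
        means=dict(Vcmax=62.0, Jmax=96.1, TPU=7.02, Rd=1.1, rm=0.65, gsw=0.184,
                   LMA=95.0, water_content=56.0, Tcw=0.39, Fias=35.5),
        sds=dict(Vcmax=7.0, Jmax=10.0, TPU=0.7, Rd=0.22, rm=0.16, gsw=0.04,
                 LMA=11.0, water_content=4.0, Tcw=0.08, Fias=6.0),
    ),
    _profile(
        "Pinus sylvestris",
        means=dict(Vcmax=52.0, Jmax=80.6, TPU=5.88, Rd=1.0, rm=0.90, gsw=0.170,
                   LMA=155.0, water_content=52.0, Tcw=0.90, Fias=15.8),
        sds=dict(Vcmax=6.0, Jmax=8.5, TPU=0.6, Rd=0.2, rm=0.22, gsw=0.038,
                 LMA=16.0, water_content=4.0, Tcw=0.12, Fias=5.5),
    ),
    _profile(
        "Picea abies",
        means=dict(Vcmax=44.0, Jmax=68.2, TPU=4.74, Rd=0.9, rm=1.60, gsw=0.068,
                   LMA=190.0, water_content=51.0, Tcw=1.20, Fias=21.7),
        sds=dict(Vcmax=5.0, Jmax=7.0, TPU=0.5, Rd=0.18, rm=0.38, gsw=0.015,
                 LMA=19.0, water_content=4.0, Tcw=0.08, Fias=5.1),
    ),
    _profile(
        "Vaccinium vitis-idaea",
        means=dict(Vcmax=40.0, Jmax=62.0, TPU=4.22, Rd=0.85, rm=1.80, gsw=0.050,
                   LMA=165.0, water_content=53.0, Tcw=0.55, Fias=39.7),
        sds=dict(Vcmax=5.0, Jmax=6.5, TPU=0.45, Rd=0.17, rm=0.42, gsw=0.011,
                 LMA=17.0, water_content=4.0, Tcw=0.09, Fias=6.4),
    ),
)


def default_profiles() -> list[SpeciesProfile]:
    return list(DEFAULT_PROFILES)


@dataclass(frozen=True)
class StudyDesign:
    """Shape of a simulated study; defaults mirror the measurement protocol."""

    seasons: tuple[str, ...] = SEASONS
    replicates: int = 9
    co2_sequence: tuple[float, ...] = (400, 300, 200, 100, 50, 400, 600, 800, 1000, 1200)
    irradiance: float = 1000.0  # umol quanta m-2 s-1
    pressure: float = 101325.0  # Pa
    tleaf: float = 25.0  # degC
    rh: float = 50.0  # %
    noise_sd: float = 0.2  # additive Gaussian noise on A, umol m-2 s-1
    leaf_area: float = 6.0  # chamber-projected leaf area, cm2
    kinetics: KineticConstants = field(default_factory=KineticConstants)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kinetics"] = dataclasses.asdict(self.kinetics)
        return d


def draw_parameters(
    profile: SpeciesProfile, season: str, rng: np.random.Generator
) -> tuple[FvCBParams, dict[str, float]]:
    """Draw one replicate's parameters and traits.

    rm, LMA and Tcw are drawn from a shared latent factor (correlation
    ``profile.rm_trait_corr``) so that high-resistance leaves also carry the
    morphology the comparative statistics are meant to pick up.  Draws are
    truncated at a small positive floor.
    """
    rho = profile.rm_trait_corr
    z: dict[str, float] = {}
    z_rm = rng.standard_normal()
    for var in PROFILE_VARS:
        eps = rng.standard_normal()
        if var == "rm":
            z[var] = z_rm
        elif var in ("LMA", "Tcw") and rho > 0:
            z[var] = rho * z_rm + math.sqrt(1.0 - rho * rho) * eps
        else:
            z[var] = eps

    values: dict[str, float] = {}
    for var in PROFILE_VARS:
        mean = profile.season_mean(var, season)
        val = mean + profile.sds[var] * z[var]
        values[var] = max(val, 1e-6)

    kinetics = KineticConstants()
    params = FvCBParams(
        Vcmax=values["Vcmax"], Jmax=values["Jmax"], TPU=values["TPU"],
        Rd=values["Rd"], rm=values["rm"], kinetics=kinetics,
    )
    traits = {k: values[k] for k in ("gsw", "LMA", "water_content", "Tcw", "Fias")}
    return params, traits


def _equilibrium_point(ca_pa: float, r_sc: float, params: FvCBParams):
    """Solve Ci such that the diffusive supply matches the biochemical demand.

    The residual Ci + r_sc * A(Ci) - Ca is strictly increasing in Ci, so the
    root is unique and bracketed by (0, Ca + r_sc * (Rd + 5)).
    """

    def f(ci: float) -> float:
        return ci + r_sc * net_assimilation_min(ci, params).A - ca_pa

    lo, hi = 1e-6, ca_pa + r_sc * (params.Rd + 5.0)
    ci = brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)
    return net_assimilation_min(ci, params)


def simulate_curve(
    params: FvCBParams,
    design: StudyDesign,
    gsw: float,
    rng: np.random.Generator,
    sample_id: str = "sim",
    species: str = "Betula pendula",
    season: str = "mid",
    leaf_area: float | None = None,
) -> ACiCurve:
    """Forward-simulate one curve along the design's CO2 sequence.

    At each step the intercellular CO2 is solved self-consistently from the
    stomatal supply (Ci = Ca - A * r_sc in pressure units), measurement noise
    is added to A, and the recorded Ci is back-computed from the noisy A as a
    gas-exchange system would.  Infeasible steps are emitted flagged, with A
    and Ci carried at the chamber boundary condition.
    """
    P = design.pressure
    r_sc = stomatal_resistance(gsw, P)
    records: list[GasExchangeRecord] = []
    for ppm in design.co2_sequence:
        ca_pa = ppm * 1e-6 * P
        flagged = False
        try:
            point = _equilibrium_point(ca_pa, r_sc, params)
            a_true = point.A
        except (InfeasibleOperatingPointError, ValueError):
            a_true, flagged = -params.Rd, True
        noise = rng.normal(0.0, design.noise_sd) if design.noise_sd > 0 else 0.0
        a_rec = a_true + noise
        ci_pa = max(ca_pa - r_sc * a_rec, 1e-3)
        records.append(
            GasExchangeRecord(
                co2_ref=float(ppm),
                A=float(a_rec),
                Ci=float(ci_pa / (1e-6 * P)),
                gsw=float(gsw),
                Tleaf=design.tleaf,
                Q=design.irradiance,
                P=P,
                rh=design.rh,
                flagged=flagged,
            )
        )
    return ACiCurve(
        sample_id=sample_id,
        species=species,
        season=season,
        records=records,
        leaf_area=leaf_area if leaf_area is not None else design.leaf_area,
    )


def simulate_study(
    design: StudyDesign | None = None,
    profiles: list[SpeciesProfile] | None = None,
    seed: int = 0,
) -> tuple[list[ACiCurve], pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a full study.

    Returns ``(curves, trait_table, truth_table, manifest)``.  The truth table
    records the generating parameters of every sample; the manifest carries
    the seed, the design and a profile hash for exact reproduction.
    """
    design = design or StudyDesign()
    profiles = profiles if profiles is not None else default_profiles()

    n_samples = len(profiles) * len(design.seasons) * design.replicates
    root = np.random.SeedSequence(seed)
    children = root.spawn(max(n_samples, 1))

    curves: list[ACiCurve] = []
    trait_rows: list[dict] = []
    truth_rows: list[dict] = []
    idx = 0
    for profile in profiles:
        for season in design.seasons:
            for rep in range(design.replicates):
                rng = np.random.default_rng(children[idx])
                idx += 1
                sample_id = f"{_abbrev(profile.species)}-{season}-{rep + 1:02d}"
                params, traits = draw_parameters(profile, season, rng)
                curve = simulate_curve(
                    params, design, traits["gsw"], rng,
                    sample_id=sample_id, species=profile.species, season=season,
                )
                curves.append(curve)
                meta = dict(
                    sample_id=sample_id,
                    species=profile.species,
                    season=season,
                    functional_type=profile.functional_type,
                    succession=profile.succession,
                )
                trait_rows.append(
                    meta
                    | dict(
                        LMA=traits["LMA"],
                        water_content=traits["water_content"],
                        Tcw=traits["Tcw"],
                        Fias=traits["Fias"],
                    )
                )
                truth_rows.append(
                    meta
                    | dict(
                        Vcmax=params.Vcmax, Jmax=params.Jmax, TPU=params.TPU,
                        Rd=params.Rd, rm=params.rm, gsw=traits["gsw"],
                    )
                )

    trait_table = pd.DataFrame(trait_rows)
    truth_table = pd.DataFrame(truth_rows)
    manifest = {
        "seed": seed,
        "n_curves": len(curves),
        "design": design.to_dict(),
        "profiles_sha256": profiles_hash(profiles),
        "species": [p.species for p in profiles],
    }
    return curves, trait_table, truth_table, manifest


def profiles_hash(profiles: list[SpeciesProfile]) -> str:
    payload = json.dumps(
        [dataclasses.asdict(p) for p in profiles], sort_keys=True
    ).encode()
    return hashlib.sha256(payload).hexdigest()


def _abbrev(species: str) -> str:
    genus, _, rest = species.partition(" ")
    return (genus[0] + rest.replace(" ", "")[:3]).capitalize() if rest else genus[:4]
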