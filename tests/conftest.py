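import logging

import numpy as np
import pytest

from leafrefix.aci_fit import ACiCurve
from leafrefix.fvcb_refix import FvCBParams
from leafrefix.synthetic_data import (
    DEFAULT_PROFILES,
    StudyDesign,
    simulate_curve,
    simulate_study,
)

logging.getLogger("leafrefix").setLevel(logging.ERROR)


def profile_params(profile, season="mid"):
    return FvCBParams(
        **{k: profile.season_mean(k, season) for k in ("Vcmax", "Jmax", "TPU", "Rd", "rm")}
    )


@pytest.fixture(scope="session")
def profiles():
    return list(DEFAULT_PROFILES)


@pytest.fixture(scope="session")
def noise_free_design():
    return StudyDesign(noise_sd=0.0)


@pytest.fixture(scope="session")
def noise_free_curves(profiles, noise_free_design) -> dict[str, tuple[ACiCurve, FvCBParams]]:
    """One exact forward-model curve per default species profile (mid season)."""
    out = {}
    rng = np.random.default_rng(0)
    for p in profiles:
        params = profile_params(p)
        curve = simulate_curve(
            params, noise_free_design, p.means["gsw"], rng, species=p.species,
            sample_id=f"nf-{p.species}",
        )
        out[p.species] = (curve, params)
    return out


@pytest.fixture(scope="session")
def tiny_study():
    """Small noisy study reused across IO / stats tests (12 curves)."""
    design = StudyDesign(replicates=2, seasons=("early", "mid"))
    profiles = [DEFAULT_PROFILES[1], DEFAULT_PROFILES[3], DEFAULT_PROFILES[4]]
    return simulate_study(design, profiles, seed=11)
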