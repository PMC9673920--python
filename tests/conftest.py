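import numpy as np
import pytest
from hypothesis import settings

import glycopk as g
import glycopk.io as gio

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def registry():
    return g.default_registry()


@pytest.fixture
def cho_profile(registry):
    """Formulation-like profile: G0F 60%, G1F 25%, G2F/Man5/G0F-N 5% each."""
    return g.SampleProfile(
        animal_id="A1",
        group="CHO-mAb1-IV",
        route="IV",
        time_h=0.0,
        fractions={"G0F": 0.60, "G1F": 0.25, "G2F": 0.05, "Man5": 0.05, "G0F-N": 0.05},
    )


def study_inputs(study):
    """Turn a SyntheticStudy bundle into reader-level objects."""
    reg = g.default_registry()
    profiles = gio.profiles_from_frame(study.profiles, reg)
    conc = gio.concentrations_from_frame(study.concentrations)
    standards = gio.profiles_from_frame(study.standards, reg)
    return profiles, conc, standards


@pytest.fixture
def make_study(registry):
    """Factory for a default CHO-like synthetic study."""

    def _make(route="IV", seed=0, noise=None, params=None, n_animals=5):
        design = g.default_study_design(route, n_animals=n_animals)
        params = params or g.PKParameters.with_default_multipliers(registry)
        noise = noise or g.NoiseModel(seed=seed)
        study = g.generate_study(design, params, noise, registry)
        return design, params, study

    return _make
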