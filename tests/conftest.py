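import dataclasses

import numpy as np
import pytest

from lichenphys import synthetic as syn
from lichenphys.datamodel import LightCurve, ThallusSample


@pytest.fixture(scope="session")
def default_cfg():
    return syn.DEFAULT_CONFIG


@pytest.fixture(scope="session")
def noise_free_run30(default_cfg):
    """Dense noise-free drying run with its generating config and truth."""
    cfg = dataclasses.replace(default_cfg, n_curves=30, noise_sd_frac=0.0)
    sample = syn.sample_for_config(cfg, "nf30", "XX")
    run = syn.generate_drying_run(sample, cfg)
    truth = syn.true_core_parameters(cfg)
    return run, cfg, truth


@pytest.fixture(scope="session")
def panel0():
    """One calibrated 7-species fixture panel (seed 0)."""
    return syn.fixture_panel(0)


@pytest.fixture(scope="session")
def panels():
    """Forty seeded fixture panels (seeds 0..39); expensive, built once."""
    return [syn.fixture_panel(seed) for seed in range(40)]


def make_sample(
    sample_id="s1",
    species_code="XX",
    site="here",
    dry_mass_mg=100.0,
    area_cm2=2.0,
    full_wet_mass_mg=400.0,
):
    return ThallusSample(
        sample_id=sample_id,
        species_code=species_code,
        site=site,
        dry_mass_mg=dry_mass_mg,
        area_cm2=area_cm2,
        full_wet_mass_mg=full_wet_mass_mg,
    )


PROTOCOL = (0.0, 12.0, 25.0, 50.0, 100.0, 300.0, 500.0, 1000.0, 1500.0)


def make_curve(assim, ppfd=PROTOCOL, curve_index=0, mass_before=300.0, mass_after=280.0):
    return LightCurve(
        curve_index=curve_index,
        ppfd_steps=ppfd,
        assim=assim,
        mass_before_mg=mass_before,
        mass_after_mg=mass_after,
    )
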