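import dataclasses

import pytest

from vesseldyn.morphodynamics import RegionMap
from vesseldyn.synthetic_data import EmbryoSimConfig, generate_embryo


def region_map_for(cfg: EmbryoSimConfig) -> RegionMap:
    return RegionMap.from_scaffold(cfg.n_isv, cfg.isv_spacing, cfg.isv_length)


@pytest.fixture(scope="session")
def zero_noise_embryo():
    """One embryo with no observation noise: every injected event is exact."""
    cfg = dataclasses.replace(EmbryoSimConfig(), noise_sd=0.0, seed=11)
    tracks, diameters, ledger = generate_embryo(cfg)
    return cfg, tracks, diameters, ledger


@pytest.fixture(scope="session")
def default_embryo():
    """One embryo under the default study conditions (0.5 um noise)."""
    cfg = dataclasses.replace(EmbryoSimConfig(), seed=7)
    tracks, diameters, ledger = generate_embryo(cfg)
    return cfg, tracks, diameters, ledger


@pytest.fixture(scope="session")
def quiet_embryo():
    """No divisions, no exchange, no noise: a fixed 60-cell, 109-frame lattice."""
    cfg = dataclasses.replace(
        EmbryoSimConfig(), noise_sd=0.0, seed=3,
        division_hazard={"aISV": 0.0, "vISV": 0.0},
        p_immigration_dlav=0.0, p_emigration_dlav=0.0, p_immigration_pcv=0.0,
        n_da_cells=20, n_dlav_cells=0,
    )
    tracks, diameters, ledger = generate_embryo(cfg)
    return cfg, tracks, diameters, ledger
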