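"""Shared fixtures: all synthetic data is generated at test time."""

from dataclasses import replace

import numpy as np
import pytest

import chromarch as ca
from chromarch.contact import ice_balance, oe_transform


@pytest.fixture(scope="session")
def default_sim():
    """Default toy genome + truth (2 x 20 Mb, 200 genes/chrom)."""
    cfg = ca.SimulationConfig()
    genome, truth = ca.simulate_genome(cfg, seed=1)
    return genome, truth, cfg


@pytest.fixture(scope="session")
def strong_boundary_sim():
    """Genome with strong planted boundaries (gamma=3, f=0.3) plus a
    balanced + O/E 40-kb matrix, for TAD-recovery style tests."""
    cfg = replace(ca.SimulationConfig(), insulation=0.3)
    genome, truth = ca.simulate_genome(cfg, seed=1)
    m = ca.simulate_contact_map(genome, truth, cfg, 40_000, seed=2)
    ice_balance(m)
    oe_transform(m)
    return genome, truth, cfg, m


@pytest.fixture(scope="session")
def balanced_500k(default_sim):
    genome, truth, cfg = default_sim
    m = ca.simulate_contact_map(genome, truth, cfg, 500_000, seed=2)
    ice_balance(m)
    oe_transform(m)
    return m


@pytest.fixture(scope="session")
def medip_track(default_sim):
    genome, truth, cfg = default_sim
    return ca.simulate_medip_tracks(genome, truth, cfg, cfg.medip_window, seed=3)


@pytest.fixture(scope="session")
def default_peaks(default_sim):
    genome, truth, cfg = default_sim
    return ca.simulate_peaks(genome, truth, cfg, seed=4)
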