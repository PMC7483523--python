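"""Shared fixtures: small simulated data sets reused across the suite.

All synthetic inputs are generated at test time by the package's own
simulator with fixed seeds; session scope keeps the slow photon-trace
simulations to one run each.
"""

import numpy as np
import pytest

from pscfcs import hydro, simulate as sim, trace as tr

#: focus geometry shared by the simulation fixtures
FOCUS = hydro.FocusGeometry(waist=0.25e-6, axial=2.5e-6)
#: quiet background typical of a clean confocal setup (~0.2 kHz/channel)
BACKGROUND = tr.BackgroundModel(2e-4, 2e-4)
TAU_TRUE = 150e-6


@pytest.fixture(scope="session")
def single_species_sim():
    """20 s of a donor-only species with tau = 150 us (Cy3B-like);
    long enough that a single conventional-FCS fit sits within a few
    percent of the ground-truth transit time."""
    mols = [sim.MoleculeSpec.from_tau(0.0, TAU_TRUE, FOCUS, brightness=0.05, count=24)]
    cfg = sim.SimulationConfig(
        duration=20.0, seed=2024, focus=FOCUS, background=BACKGROUND
    )
    trace, log = sim.simulate_confocal_smd(mols, cfg)
    return trace, log, cfg


@pytest.fixture(scope="session")
def fig1_style_sim():
    """Six-molecule two-species scenario: four molecules at E = 0.11 and
    two at E = 0.33, equal brightness and diffusion, 60 s.

    Brightness 0.15 photons per fine bin (~156 kHz peak) keeps typical
    bursts above ~50 photons so the shot-noise width of the efficiency
    peaks stays well below their 0.22 separation."""
    mols = [
        sim.MoleculeSpec.from_tau(0.11, TAU_TRUE, FOCUS, brightness=0.15, count=4),
        sim.MoleculeSpec.from_tau(0.33, TAU_TRUE, FOCUS, brightness=0.15, count=2),
    ]
    cfg = sim.SimulationConfig(
        duration=60.0,
        seed=515,
        focus=FOCUS,
        background=BACKGROUND,
        box_edges=(3e-6, 3e-6, 10e-6),
    )
    trace, log = sim.simulate_confocal_smd(mols, cfg)
    return trace, log, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
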