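"""Shared fixtures: a desk-scale acquisition (4x4 antennas, 10 rotations,
101 frequency points) that exercises the full chain in seconds."""

import numpy as np
import pytest

import mwibeam as mw


@pytest.fixture(scope="session")
def scaled_geom():
    return mw.build_cylindrical_array(4, 4, 0.1, 10, 36.0)


@pytest.fixture(scope="session")
def freqs101():
    return mw.default_frequency_grid(101)


@pytest.fixture(scope="session")
def grid2mm():
    return mw.build_imaging_grid(0.08, 0.002, array_radius=0.1)


@pytest.fixture(scope="session")
def delays2mm(grid2mm, scaled_geom):
    return mw.compute_delay_table(
        mw.compute_distance_tables(grid2mm, scaled_geom), eps_b=1.0)


@pytest.fixture(scope="session")
def tiny_dataset(scaled_geom):
    """Small deterministic dataset for I/O and preprocessing tests."""
    phantom = mw.make_phantom("B", seed=3)
    freqs = mw.default_frequency_grid(11)
    return mw.simulate_scatter_dataset(phantom, scaled_geom, freqs)
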