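"""Shared fixtures: the reference imaging configuration and a small fast one."""

import numpy as np
import pytest

import mwtomo as mt
from mwtomo.forward import DDASolver, complex_k2


@pytest.fixture(scope="session")
def default_geometry():
    """Reference configuration: 25 cm / 64-cell grid, 69.8 mm zone, 16 antennas."""
    grid = mt.build_grid(0.25, 64)
    zone = mt.select_imaging_zone(grid, 0.0698)
    array = mt.build_antenna_array(16, 0.152, 1.0, grid=grid, zone=zone)
    return grid, zone, array


@pytest.fixture(scope="session")
def small_geometry():
    """Fast configuration for algebraic identities: 32-cell grid, 8 antennas.

    The frequency is lowered to 0.7 GHz to keep the cell sub-wavelength in
    the lossy bath at this coarser resolution.
    """
    grid = mt.build_grid(0.25, 32)
    zone = mt.select_imaging_zone(grid, 0.0698)
    array = mt.build_antenna_array(8, 0.152, 1.0, grid=grid, zone=zone)
    freq = mt.FrequencySpec(0.7e9)
    bath = mt.DielectricProperties(20.9, 1.35)
    return grid, zone, array, freq, bath


@pytest.fixture(scope="session")
def small_phantom_sweep(small_geometry):
    """Fields and measurements for a small off-center inclusion phantom."""
    grid, zone, array, freq, bath = small_geometry
    obj = mt.DielectricProperties(16.9, 1.15)
    spec = mt.PhantomSpec(bath, (((-0.012, 0.018), 0.02, obj),), freq.f, 0.0, 1, 0)
    pmap = mt.make_property_map(spec, grid, zone, freq)
    solver = DDASolver(zone, array, freq, pmap.k2_background)
    fields, mset = solver.sweep(pmap)
    return pmap, solver, fields, mset


@pytest.fixture(scope="session")
def fig7_sweep(default_geometry):
    """Homogeneous-start sweep at 1300 MHz, bath eps_r = 22, sigma = 1 S/m."""
    grid, zone, array = default_geometry
    freq = mt.FrequencySpec(1.3e9)
    bath = mt.DielectricProperties(22.0, 1.0)
    pmap = mt.PropertyMap.homogeneous(zone, bath, freq)
    solver = DDASolver(zone, array, freq, pmap.k2_background)
    fields, mset = solver.sweep(pmap)
    return freq, bath, pmap, solver, fields, mset
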