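"""Shared fixtures: geometries and meshes are generated once per session."""
import numpy as np
import pytest

from retmech.geometry import (GeometryParams, build_vessel_geometry,
                              generate_mesh, make_annulus_mesh, place_pois, UM)


@pytest.fixture(scope="session")
def default_geometry():
    geom = build_vessel_geometry()
    place_pois(geom)
    return geom


@pytest.fixture(scope="session")
def coarse_mesh(default_geometry):
    """Default bifurcation at 6 µm: cheap enough for pipeline tests."""
    return generate_mesh(default_geometry, 6.0)


@pytest.fixture(scope="session")
def default_pois_m(default_geometry):
    return default_geometry.poi_coords * UM


@pytest.fixture(scope="session")
def channel_mesh():
    """Straight 80 µm channel, the plane-Poiseuille oracle domain."""
    geom = build_vessel_geometry(
        GeometryParams(inlet_width=80.0, outlet_widths=(80.0,), box=(200.0, 120.0)))
    return generate_mesh(geom, 2.0)


@pytest.fixture(scope="session")
def annulus_mesh():
    """Thick-walled cylinder section (Lame benchmark): a=100, b=200 µm."""
    return make_annulus_mesh(100.0, 200.0, 10, 96)
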