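"""Shared fixtures.

Expensive whole-cycle simulations are session-scoped and run at a reduced
resolution (1.25 mm mesh, 96 gait samples) that keeps every qualitative
contact/wear feature of the default setup while the full suite stays fast.
"""

from __future__ import annotations

import numpy as np
import pytest

import kneewear as kw
from kneewear.kinematics import get_condition

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass

STUDY_CONDITIONS = [
    "distal/high",
    "distal/intermediate",
    "iso/iso",
    "iso/modified-intermediate",
    "iso/modified-high",
    "distal/modified-intermediate",
]

TEST_RESOLUTION_MM = 1.25
TEST_N_SAMPLES = 96


@pytest.fixture(scope="session")
def default_geometry():
    return kw.build_default_geometry("midsize")


@pytest.fixture(scope="session")
def default_mesh(default_geometry):
    _, tib = default_geometry
    return kw.tessellate(tib, TEST_RESOLUTION_MM)


@pytest.fixture(scope="session")
def coarse_mesh(default_geometry):
    _, tib = default_geometry
    return kw.tessellate(tib, 2.0)


@pytest.fixture(scope="session")
def gvf_material(default_geometry):
    _, tib = default_geometry
    return kw.material_preset("GVF", layer_thickness_mm=tib.thickness_mm)


@pytest.fixture(scope="session")
def xlk_material(default_geometry):
    _, tib = default_geometry
    return kw.material_preset("XLK", layer_thickness_mm=tib.thickness_mm)


@pytest.fixture(scope="session")
def gvf_map():
    return kw.default_wear_map("GVF")


@pytest.fixture(scope="session")
def xlk_map():
    return kw.default_wear_map("XLK")


@pytest.fixture(scope="session")
def gvf_results(default_geometry, default_mesh, gvf_material, gvf_map):
    """Wear results for the six-condition conventional-polyethylene study."""
    out = {}
    for name in STUDY_CONDITIONS:
        out[name] = kw.run_condition(
            get_condition(name),
            default_geometry,
            gvf_material,
            gvf_map,
            n_samples=TEST_N_SAMPLES,
            mesh=default_mesh,
        )
    return out


@pytest.fixture(scope="session")
def xlk_results(default_geometry, default_mesh, xlk_material, xlk_map):
    """The four-condition cross-linked arm (no full-standard test)."""
    out = {}
    for name in [
        "distal/high",
        "distal/intermediate",
        "iso/modified-intermediate",
        "iso/modified-high",
    ]:
        out[name] = kw.run_condition(
            get_condition(name),
            default_geometry,
            xlk_material,
            xlk_map,
            n_samples=TEST_N_SAMPLES,
            mesh=default_mesh,
        )
    return out


def flat_mesh(half_extent_mm: float, resolution_mm: float) -> kw.SurfaceMesh:
    """A flat square foundation surface (oracle geometry)."""
    from kneewear.geometry import SurfaceMesh, _tributary_areas, structured_surface_mesh

    verts, faces = structured_surface_mesh(
        lambda x, z: np.zeros_like(np.asarray(x) * np.asarray(z)),
        (-half_extent_mm, half_extent_mm),
        (-half_extent_mm, half_extent_mm),
        resolution_mm,
    )
    areas = _tributary_areas(verts, faces)
    normals = np.tile([0.0, 1.0, 0.0], (len(verts), 1))
    mask = np.ones(len(verts), dtype=bool)
    return SurfaceMesh(verts, faces, normals, areas, mask, np.inf)
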