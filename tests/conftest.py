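"""Shared fixtures: analytic meshes and desk-scale templates."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from surfmorph.geometry import SurfaceMesh, vertex_adjacency


def icosphere_mesh(subdivisions: int = 3, radius: float = 1.0) -> SurfaceMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions)
    return SurfaceMesh(np.asarray(ico.vertices) * radius, np.asarray(ico.faces))


def asymmetric_blob(subdivisions: int = 3) -> SurfaceMesh:
    """A smooth star-shaped surface with no rotational symmetry.

    Registration tests need a shape whose alignment is unique; spheres and
    axis-aligned ellipsoids admit symmetry-related optima.
    """
    ico = trimesh.creation.icosphere(subdivisions=subdivisions)
    u = np.asarray(ico.vertices)
    bump = (
        1
        + 0.12 * np.sin(3.9 * u[:, 0] + 0.2)
        + 0.10 * np.cos(2.7 * u[:, 1] + 1.1)
        + 0.08 * np.sin(2.1 * u[:, 2] + 2.3)
    )
    v = u * np.array([50.0, 38.0, 30.0]) * bump[:, None]
    return SurfaceMesh(v, np.asarray(ico.faces))


@pytest.fixture(scope="session")
def unit_icosphere() -> SurfaceMesh:
    return icosphere_mesh(3)


@pytest.fixture(scope="session")
def template_mesh() -> SurfaceMesh:
    """Desk-scale template: 2562-vertex icosphere at 60 mm radius."""
    return icosphere_mesh(4, radius=60.0)


@pytest.fixture(scope="session")
def template_adjacency(template_mesh):
    return vertex_adjacency(template_mesh)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
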