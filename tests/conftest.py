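"""Shared fixtures: phantom volumes, clouds, fields, and full pipeline runs.

The expensive full-pipeline reconstructions are session-scoped so each
phantom is reconstructed exactly once for the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from vesselmesh import (
    Bifurcation,
    Dumbbell,
    PipelineConfig,
    Sphere,
    Torus,
    build_oriented_cloud,
    compute_indicator_field,
    rasterize,
    run_pipeline,
)
from vesselmesh.points import extract_point_arrays

SPHERE_RADIUS = 20.0


@pytest.fixture(scope="session")
def sphere_shape():
    return Sphere((0.0, 0.0, 0.0), SPHERE_RADIUS)


@pytest.fixture(scope="session")
def sphere_vol(sphere_shape):
    return rasterize(sphere_shape, (1.0, 1.0, 1.0), margin=2)


@pytest.fixture(scope="session")
def sphere_points(sphere_vol):
    return extract_point_arrays(sphere_vol)


@pytest.fixture(scope="session")
def sphere_cloud(sphere_vol, sphere_points):
    return build_oriented_cloud(sphere_points, sphere_vol, k=10)


@pytest.fixture(scope="session")
def sphere_field(sphere_cloud):
    return compute_indicator_field(sphere_cloud, depth=6)


@pytest.fixture(scope="session")
def sphere_result(sphere_shape):
    """Full pipeline on the R=20 sphere at depth 6."""
    return run_pipeline(sphere_shape, PipelineConfig(depth=6))


@pytest.fixture(scope="session")
def bifurcation_shape():
    return Bifurcation(radius=6.0, length=24.0, angle_deg=60.0)


@pytest.fixture(scope="session")
def bifurcation_result(bifurcation_shape):
    """Full pipeline on the Y-bifurcation (two radius-6 tubes at 60 deg)."""
    return run_pipeline(bifurcation_shape, PipelineConfig(depth=6))


@pytest.fixture(scope="session")
def torus_shape():
    return Torus((0.0, 0.0, 0.0), major_radius=12.0, minor_radius=4.0)


@pytest.fixture(scope="session")
def torus_result(torus_shape):
    """Full pipeline on the torus; depth 5 keeps the genus test brisk."""
    return run_pipeline(torus_shape, PipelineConfig(depth=5))


@pytest.fixture(scope="session")
def dumbbell_shape():
    return Dumbbell()


@pytest.fixture(scope="session")
def dumbbell_result(dumbbell_shape):
    return run_pipeline(dumbbell_shape, PipelineConfig(depth=6))


@pytest.fixture(scope="session")
def plane_field():
    """Smooth half-space indicator from an analytic plane cloud (z = 0
    surface, object below), for exact flat-surface expansion tests."""
    from vesselmesh.normals import OrientedPointCloud

    xs = np.linspace(-20.0, 20.0, 41)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    pos = np.stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)], axis=1)
    normals = np.tile([0.0, 0.0, -1.0], (len(pos), 1))  # inward = downward
    cloud = OrientedPointCloud(pos, normals)
    return compute_indicator_field(cloud, depth=5)
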