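"""Shared fixtures built on the package's analytic validation joints."""

from __future__ import annotations

import pytest
import trimesh

from osteorom.mesh import TriMesh
from osteorom.validation import (  # noqa: F401  (re-exported for tests)
    cylinder_landmarks,
    cylinder_mesh,
    make_cylinder_joint,
    make_locator_joint,
)

@pytest.fixture(scope="session")
def unit_cube() -> TriMesh:
    return TriMesh(parts=[trimesh.creation.box(extents=[1, 1, 1])], label="cube")


@pytest.fixture(scope="session")
def default_joint():
    """First joint of a small default synthetic column."""
    from osteorom.synthetic import SyntheticColumnSpec, generate_column

    col = generate_column(SyntheticColumnSpec(n_vertebrae=2))
    return col.joints[0]


@pytest.fixture(scope="session")
def default_column():
    from osteorom.synthetic import SyntheticColumnSpec, generate_column

    return generate_column(SyntheticColumnSpec(n_vertebrae=3))
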