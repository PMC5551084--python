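import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def brute_force_sr(mesh, plane_normal):
    """Independent rugosity oracle: explicit per-triangle loop.

    Shares no code with the package's vectorised path: areas via the cross
    product, projections via |cos| with the plane normal, summed in a loop.
    """
    n = np.asarray(plane_normal, dtype=float)
    n = n / np.linalg.norm(n)
    total = 0.0
    proj = 0.0
    for face in mesh.faces:
        a, b, c = (mesh.vertices[i] for i in face)
        cross = np.cross(b - a, c - a)
        area = 0.5 * float(np.linalg.norm(cross))
        total += area
        proj += 0.5 * abs(float(np.dot(cross, n)))
    return total, proj
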