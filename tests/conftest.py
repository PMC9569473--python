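import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from xlassembly.structure import AtomRecord, Structure
from xlassembly import synthetic as syn

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def icosa_cage() -> Structure:
    """Twelve Cα pseudo-atoms on an icosahedron of radius 25 Å, residues 1-12.

    Used as a surrounding anchor set: restraints from a body inside the cage
    pull in opposing directions, which pins the body's pose.
    """
    phi = (1 + 5**0.5) / 2
    verts = []
    for a in (1.0, -1.0):
        for b in (phi, -phi):
            verts += [(0, a, b), (a, b, 0), (b, 0, a)]
    verts = np.array(verts)
    verts = verts / np.linalg.norm(verts, axis=1, keepdims=True) * 25.0
    return Structure(
        [
            AtomRecord("A", i + 1, "LYS", "CA", *map(float, v))
            for i, v in enumerate(verts)
        ]
    )


def cage_restraints(truth: Structure, cage: Structure, k_nearest: int = 3):
    """Tight restraints (d_max = true distance) from every mobile residue to
    its nearest cage vertices; directions surround the body."""
    verts = cage.coords
    cage_res = cage.residues()
    restraints = []
    for res in truth.residues():
        pt = truth.coord(res)
        dists = np.linalg.norm(verts - pt, axis=1)
        for i in np.argsort(dists)[:k_nearest]:
            restraints.append((res, cage_res[i], float(dists[i])))
    return restraints


@pytest.fixture(scope="session")
def toy():
    """The packaged toy five-segment fixture (default seed)."""
    return syn.toy_apob_fixture(seed=0)
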