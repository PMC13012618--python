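"""Shared fixtures: small synthetic systems and independent oracles."""

import numpy as np
import pytest

from allonet import synthetic
from allonet.model import Topology, FrameEnsemble


@pytest.fixture(scope="session")
def chain200():
    """200-residue backbone chain (N, CA, CB, C, O per residue) along x."""
    names, resids, resnames, coords = [], [], [], []
    for r in range(1, 201):
        x0 = 0.38 * r
        for name, off in [("N", (-0.12, 0.05, 0.0)), ("CA", (0.0, 0.0, 0.03)),
                          ("CB", (0.0, -0.11, 0.11)), ("C", (0.12, 0.05, 0.0)),
                          ("O", (0.14, 0.17, -0.02))]:
            names.append(name)
            resids.append(r)
            resnames.append("ALA")
            coords.append(np.array(off) + [x0, 0.0, 0.0])
    top = Topology.from_atom_records(names, resids, resnames)
    ens = FrameEnsemble(top, np.array(coords)[None])
    return top, ens


@pytest.fixture(scope="session")
def contact_fixture():
    """All six scripted contact geometries in one 4-frame ensemble."""
    script = [
        synthetic.ContactScriptEntry("hbond_pass", [0, 1, 2]),
        synthetic.ContactScriptEntry("hbond_fail_angle", [0, 1, 2, 3]),
        synthetic.ContactScriptEntry("ionic", [0, 1, 2, 3]),
        synthetic.ContactScriptEntry("pi_stack", [0, 1, 2, 3]),
        synthetic.ContactScriptEntry("pi_cation", [0, 1, 2, 3]),
        synthetic.ContactScriptEntry("hydrophobic", [0, 1, 2, 3]),
    ]
    return synthetic.make_contact_script_ensemble(script, n_frames=4)


@pytest.fixture(scope="session")
def planted_small():
    """Planted-path ensemble small enough for unit tests."""
    spec = synthetic.EnsembleSpec(n_frames=1000, seed=11)
    return synthetic.make_planted_network_ensemble(spec)


def dihedral_oracle(p1, p2, p3, p4):
    """Independent signed dihedral (degrees): arccos of unit normals with a
    triple-product sign, coded separately from the library's atan2 form."""
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b3 = np.asarray(p4) - np.asarray(p3)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1u = n1 / np.linalg.norm(n1)
    n2u = n2 / np.linalg.norm(n2)
    cosphi = np.clip(n1u @ n2u, -1.0, 1.0)
    phi = np.degrees(np.arccos(cosphi))
    if np.dot(np.cross(n1u, n2u), b2) < 0:
        phi = -phi
    if phi <= -180.0:
        phi += 360.0
    return phi
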