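"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check: RMSD via
direct numerical minimization over a rotation-vector parameterization, and
contact detection via an O(N²) all-pairs scan.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from barrelgate.structure_io import Atom, Structure, Trajectory


def brute_force_min_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD over proper rotations+translations by direct optimization.

    Parameterizes the rotation as a rotation vector and minimizes the RMSD
    of the centered point sets numerically, from several starts to dodge
    local minima.  Independent of the SVD solution it is used to check.
    """
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)

    def cost(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1)))

    best = np.inf
    rng = np.random.default_rng(1234)
    starts = [np.zeros(3)] + [rng.uniform(-np.pi, np.pi, 3) for _ in range(7)]
    for x0 in starts:
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
        best = min(best, res.fun)
    return float(best)


def brute_force_contacts(coords, lipid_atoms, atoms_by_resid, cutoff):
    """O(N²) all-pairs contact scan without spatial acceleration."""
    hits = set()
    for resid, idx in atoms_by_resid.items():
        found = False
        for i in idx:
            for j in lipid_atoms:
                d = np.linalg.norm(coords[i] - coords[j])
                if d <= cutoff:
                    hits.add(resid)
                    found = True
                    break
            if found:
                break
    return hits


def make_structure(spec_atoms) -> Structure:
    """Build a Structure from (name, resname, resid, chain, element, xyz) tuples."""
    atoms = [
        Atom(serial=i + 1, name=n, resname=rn, resid=r, chain=c, element=e,
             coords=np.asarray(xyz, dtype=float))
        for i, (n, rn, r, c, e, xyz) in enumerate(spec_atoms)
    ]
    return Structure(atoms)


def ca_structure(positions, resid_start: int = 1) -> Structure:
    """A Cα-only chain at the given positions."""
    return make_structure([
        ("CA", "ALA", resid_start + i, "A", "C", p) for i, p in enumerate(positions)
    ])


def static_trajectory(structure: Structure, n_frames: int) -> Trajectory:
    frames = np.repeat(structure.coords[None], n_frames, axis=0)
    return Trajectory(structure, frames)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def square_structure():
    """Four non-collinear Cα atoms (a planar square)."""
    return ca_structure([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)])
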