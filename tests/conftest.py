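import numpy as np
import pytest

from phenodyn.synthetic_traj import make_did_dad_topology
from phenodyn.traj_io import AtomRecord, Structure, Trajectory


@pytest.fixture(scope="session")
def topology():
    """Full synthetic DID-DAD backbone (chain A 57-245, chain B 960-975)."""
    return make_did_dad_topology()


@pytest.fixture(scope="session")
def small_topology():
    """Compact topology for statistics that only need the interface pair."""
    return make_did_dad_topology(did_residues=(57, 80), dad_residues=(960, 975))


@pytest.fixture()
def tiny_structure():
    """A 3-residue peptide with standard backbone atoms."""
    atoms = []
    serial = 1
    for i, resid in enumerate((1, 2, 3)):
        for name, off in (("N", 0.0), ("CA", 0.5), ("C", 1.0), ("O", 1.5)):
            # bent backbone: superposition needs a non-collinear point set
            atoms.append(
                AtomRecord(serial, name, "ALA", "A", resid,
                           np.array([3.8 * i + off, 0.4 * i * i, 0.6 * (i % 2)]))
            )
            serial += 1
    return Structure(atoms=atoms, title="tiny")


@pytest.fixture()
def tiny_trajectory(tiny_structure):
    coords = tiny_structure.coordinates()
    frames = np.stack([coords, coords + 1.0])
    return Trajectory(topology=tiny_structure, frames=frames, frame_interval=1.0)


def enumeration_fisher_2x2(table):
    """Independent oracle: full hypergeometric enumeration with the
    point-probability two-sided rule."""
    from scipy.special import comb

    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def point(x):
        return (comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True)
                / comb(n, c1, exact=True))

    p_obs = point(a)
    return sum(point(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if point(x) <= p_obs * (1 + 1e-12))


def brute_force_min_rmsd(mobile, reference, n_grid=4000, seed=0):
    """Independent minimum-RMSD oracle: dense random SO(3) sampling
    followed by Nelder-Mead refinement on the rotation vector.  Translation
    is optimal at centroids for any rotation, so only rotation is searched.
    Returns RMSD in Å."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    mobile = mobile - mobile.mean(axis=0)
    reference = reference - reference.mean(axis=0)

    def rmsd_of(rotmats):
        fitted = np.einsum("rij,nj->rni", rotmats, mobile)
        return np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=2), axis=1))

    rots = Rotation.random(n_grid, random_state=seed)
    vals = rmsd_of(rots.as_matrix())
    best = rots[int(np.argmin(vals))].as_rotvec()

    def objective(rv):
        return rmsd_of(Rotation.from_rotvec(rv).as_matrix()[None])[0]

    res = minimize(objective, best, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    return float(res.fun)
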