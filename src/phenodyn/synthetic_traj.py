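"""Synthetic trajectory generator with analytically known ground truth.

Stands in for long all-atom MD production runs: residues fluctuate about a
reference structure with a commanded per-residue Gaussian amplitude, and a
designated interface residue pair (here Gly62 in the DID against Glu968 in
the DAD) switches between bound and unbound distances through a two-state
Markov chain.  Because displacements are i.i.d. Gaussian per axis, the
expected per-residue RMSF has the closed form sigma * sqrt(3), and the
stationary unbound occupancy of the contact chain is
p_unbind / (p_unbind + p_rebind) — both exactly testable.

Frame 0 is always the noise-free reference, mirroring the use of the
minimized starting structure as the t = 0 reference for RMSF and for the
dissociation statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .traj_io import AtomRecord, AtomSelection, Structure, Trajectory, select_atoms
from .units import nm_to_ang

__all__ = [
    "FluctuationSpec",
    "ContactSwitchSpec",
    "generate_harmonic_trajectory",
    "generate_contact_trajectory",
    "expected_rmsf",
    "make_did_dad_topology",
]

_BACKBONE_OFFSETS = {
    # Local backbone geometry (Å), coarse but chemically sensible spacings.
    "N": np.array([-1.2, 0.5, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.3, 0.6, 0.0]),
    "O": np.array([1.4, 1.8, 0.2]),
}


def make_did_dad_topology(
    did_residues: tuple[int, int] = (57, 245),
    dad_residues: tuple[int, int] = (960, 975),
    rise_per_residue: float = 1.8,
    helix_radius: float = 8.0,
    interface_pair: tuple[tuple[str, int], tuple[str, int]] = (("A", 62), ("B", 968)),
    interface_distance_nm: float = 0.67,
) -> Structure:
    """Build a deterministic two-chain backbone topology.

    Chain A covers the DID residue range (default 57-245, containing Gly62
    and the fluctuation clusters at 80-96 and 152-164); chain B covers a
    DAD segment numbered in full-length coordinates so that residue 968
    exists explicitly.  Backbone N, CA, C, O atoms are laid out on a coarse
    helix — geometry only needs to be non-degenerate, not physical.
    """
    atoms: list[AtomRecord] = []
    serial = 1

    def add_chain(chain_id: str, lo: int, hi: int, origin: np.ndarray) -> None:
        nonlocal serial
        for k, resid in enumerate(range(lo, hi + 1)):
            theta = 2.0 * np.pi * k / 3.6  # ~3.6 residues per helical turn
            ca = origin + np.array(
                [
                    helix_radius * np.cos(theta),
                    helix_radius * np.sin(theta),
                    rise_per_residue * k,
                ]
            )
            resname = "GLY" if resid in (62, 73) else ("GLU" if resid == 968 else "ALA")
            for name, off in _BACKBONE_OFFSETS.items():
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        atom_name=name,
                        residue_name=resname,
                        chain_id=chain_id,
                        residue_number=resid,
                        position=ca + off,
                    )
                )
                serial += 1

    add_chain("A", did_residues[0], did_residues[1], np.zeros(3))
    # Place the DAD chain alongside the DID so the 62-968 pair starts bound.
    add_chain("B", dad_residues[0], dad_residues[1], np.array([14.0, 0.0, 10.0]))

    # Slide chain B rigidly so the interface Cα pair sits at the commanded
    # bound distance (the docked autoinhibited geometry).
    def ca_pos(chain: str, resid: int) -> np.ndarray:
        for a in atoms:
            if a.chain_id == chain and a.residue_number == resid and a.atom_name == "CA":
                return a.position
        raise ValueError(f"no CA for {chain}{resid}")

    (ch_a, res_a), (ch_b, res_b) = interface_pair
    pa, pb = ca_pos(ch_a, res_a), ca_pos(ch_b, res_b)
    gap = pb - pa
    norm = np.linalg.norm(gap)
    shift = (nm_to_ang(interface_distance_nm) / norm - 1.0) * gap
    moved = [
        a if a.chain_id != ch_b
        else AtomRecord(a.serial, a.atom_name, a.residue_name, a.chain_id,
                        a.residue_number, a.position + shift)
        for a in atoms
    ]
    return Structure(atoms=moved, title="synthetic DID-DAD backbone")


@dataclass
class FluctuationSpec:
    """Per-residue harmonic fluctuation parameters.

    sigma_per_residue maps (chain_id, residue_number) -> per-axis
    displacement stdev in nm; a plain float applies to all residues.
    """

    reference: Structure
    sigma_per_residue: dict[tuple[str, int], float] | float
    n_frames: int = 100
    rigid_motion: bool = False
    seed: int = 0
    ar1_rho: float = 0.0  # optional frame-to-frame correlation, default off
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must be in [0, 1)")
        sigmas = self.sigma_map().values()
        if any(s < 0 for s in sigmas):
            raise ValueError("all sigma values must be >= 0")

    def sigma_map(self) -> dict[tuple[str, int], float]:
        residues = self.reference.residues()
        if isinstance(self.sigma_per_residue, (int, float)):
            return {r: float(self.sigma_per_residue) for r in residues}
        missing = set(self.sigma_per_residue) - set(residues)
        if missing:
            raise ValueError(f"sigma map names residues absent from reference: {sorted(missing)}")
        return {r: float(self.sigma_per_residue.get(r, 0.0)) for r in residues}


@dataclass
class ContactSwitchSpec:
    """Two-state (bound/unbound) Markov switching of an interface contact.

    When unbound, every atom of ``group_b`` is rigidly translated by
    ``unbound_offset`` (nm) along ``displacement_axis``, so the commanded
    pair-distance offset is exact by construction.
    """

    group_a: str
    group_b: str
    bound_distance: float = 0.67  # nm, informational; set by the reference
    unbound_offset: float = 0.8  # nm
    p_unbind: float = 0.05
    p_rebind: float = 0.20
    displacement_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_unbind, self.p_rebind):
            if not 0.0 <= p <= 1.0:
                raise ValueError("transition probabilities must lie in [0, 1]")
        if not self.unbound_offset > 0:
            raise ValueError("unbound_offset must be positive")
        axis = np.asarray(self.displacement_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("displacement_axis must be non-zero")
        self.displacement_axis = axis / norm

    @property
    def stationary_unbound(self) -> float:
        """Stationary unbound occupancy p_u = p_unbind / (p_unbind + p_rebind)."""
        tot = self.p_unbind + self.p_rebind
        return self.p_unbind / tot if tot > 0 else 0.0


def _per_atom_sigma_ang(spec: FluctuationSpec) -> np.ndarray:
    sigma = spec.sigma_map()
    return np.array(
        [nm_to_ang(sigma[(a.chain_id, a.residue_number)]) for a in spec.reference.atoms]
    )


def _harmonic_frames(spec: FluctuationSpec, rng: np.random.Generator) -> np.ndarray:
    ref = spec.reference.coordinates()
    n_atoms = ref.shape[0]
    sig = _per_atom_sigma_ang(spec)[:, None]
    frames = np.empty((spec.n_frames, n_atoms, 3))
    frames[0] = ref
    if spec.ar1_rho > 0.0:
        # AR(1) displacement process with the commanded stationary stdev.
        rho = spec.ar1_rho
        innov_scale = np.sqrt(1.0 - rho**2)
        disp = rng.standard_normal((n_atoms, 3)) * sig
        for f in range(1, spec.n_frames):
            disp = rho * disp + innov_scale * rng.standard_normal((n_atoms, 3)) * sig
            frames[f] = ref + disp
    else:
        noise = rng.standard_normal((spec.n_frames - 1, n_atoms, 3)) * sig[None]
        frames[1:] = ref[None] + noise
    return frames


def _apply_rigid_motion(frames: np.ndarray, rng: np.random.Generator) -> None:
    """Random proper rotation (uniform on SO(3)) + translation (10 Å box),
    applied in place to every frame except frame 0."""
    for f in range(1, frames.shape[0]):
        rot = Rotation.random(random_state=rng).as_matrix()
        trans = rng.uniform(-5.0, 5.0, size=3)
        center = frames[f].mean(axis=0)
        frames[f] = (frames[f] - center) @ rot.T + center + trans


def generate_harmonic_trajectory(spec: FluctuationSpec) -> Trajectory:
    """Reference + isotropic Gaussian displacements, i.i.d. across frames.

    Frame 0 equals the reference exactly.  With ``rigid_motion`` on, every
    later frame additionally receives a random rigid-body motion, which
    optimal superposition must remove without residue.
    """
    rng = np.random.default_rng(spec.seed)
    frames = _harmonic_frames(spec, rng)
    if spec.rigid_motion:
        _apply_rigid_motion(frames, rng)
    return Trajectory(
        topology=spec.reference, frames=frames, frame_interval=spec.frame_interval
    )


def generate_contact_trajectory(
    base: FluctuationSpec, contact: ContactSwitchSpec
) -> tuple[Trajectory, np.ndarray]:
    """Harmonic trajectory with Markov bound/unbound switching of group_b.

    Returns the trajectory and the true per-frame state series (0 = bound,
    1 = unbound).  The chain starts bound at frame 0 (the reference).
    """
    sel_a = select_atoms(base.reference, contact.group_a)
    sel_b = select_atoms(base.reference, contact.group_b)
    if set(sel_a.indices) & set(sel_b.indices):
        raise ValueError("contact groups must not share atoms")

    rng = np.random.default_rng(base.seed)
    frames = _harmonic_frames(base, rng)

    state_rng = np.random.default_rng(contact.seed)
    states = np.zeros(base.n_frames, dtype=int)
    u = state_rng.random(base.n_frames)
    for f in range(1, base.n_frames):
        if states[f - 1] == 0:
            states[f] = 1 if u[f] < contact.p_unbind else 0
        else:
            states[f] = 0 if u[f] < contact.p_rebind else 1

    offset_ang = nm_to_ang(contact.unbound_offset) * contact.displacement_axis
    b_idx = sel_b.as_array()
    unbound = np.nonzero(states == 1)[0]
    frames[np.ix_(unbound, b_idx)] += offset_ang

    if base.rigid_motion:
        _apply_rigid_motion(frames, rng)

    traj = Trajectory(
        topology=base.reference, frames=frames, frame_interval=base.frame_interval
    )
    return traj, states


def expected_rmsf(spec: FluctuationSpec) -> dict[tuple[str, int], float]:
    """Ground-truth RMSF per residue, nm: sqrt(E||dx||^2) = sigma * sqrt(3)."""
    return {r: s * np.sqrt(3.0) for r, s in spec.sigma_map().items()}
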