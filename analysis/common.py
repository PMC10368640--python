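"""Shared study conditions for the analysis scripts.

Two arms, each comparing a wild-type-like condition against a
destabilised-variant-like condition:

* trajectory arm — the variant condition has an elevated fluctuation
  amplitude in the first flexible loop (residues 80-96), loses the second
  peak (152-164), and its interface contact unbinds far more often
  (stationary unbound occupancy 0.77 vs 0.13 for wild type, the
  dissociation contrast the pipeline is built to measure);
* imaging arm — the variant condition shifts actin cells toward fine/no
  cables, fragments and peripheralises mitochondria, and moves
  microtubule arrays from radial toward mixed/parallel.
"""

from __future__ import annotations

from pathlib import Path

from phenodyn.synthetic_traj import ContactSwitchSpec, FluctuationSpec, make_did_dad_topology

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

N_FRAMES = 500  # one frame per ns, a 500-frame production run
CONTACT_A = "chain A and resid 62 and name CA"
CONTACT_B_ATOM = "chain B and resid 968 and name CA"
CONTACT_B_GROUP = "chain B"

# per-axis displacement sigma (nm); RMSF ground truth is sigma * sqrt(3)
TRAJ_CONDITIONS = {
    "wildtype": {
        "baseline_sigma": 0.05,
        "elevated": {(80, 96): 0.20, (152, 164): 0.20,
                     (180, 194): 0.085, (208, 220): 0.085},
        # ~13% stationary unbound occupancy
        "p_unbind": 0.03, "p_rebind": 0.20,
    },
    "variant": {
        "baseline_sigma": 0.05,
        "elevated": {(80, 96): 0.28, (180, 194): 0.085, (208, 220): 0.085},
        # ~77% stationary unbound occupancy
        "p_unbind": 0.20, "p_rebind": 0.06,
    },
}

CELL_CONDITIONS = {
    "wildtype": {
        "actin_mixture": (0.55, 0.30, 0.10, 0.05),
        "mito_mixture": (0.8, 0.15, 0.05),
        "mt_mixture": (0.7, 0.2, 0.1),
    },
    "variant": {
        "actin_mixture": (0.05, 0.15, 0.45, 0.35),
        "mito_mixture": (0.05, 0.25, 0.7),
        "mt_mixture": (0.1, 0.3, 0.6),
    },
}

N_CELLS_PER_GROUP = 30


def build_specs(condition: str, seed: int) -> tuple[FluctuationSpec, ContactSwitchSpec]:
    cfg = TRAJ_CONDITIONS[condition]
    topo = make_did_dad_topology()
    sigma = {res: cfg["baseline_sigma"] for res in topo.residues()}
    for (lo, hi), s in cfg["elevated"].items():
        for chain, resnum in topo.residues():
            if chain == "A" and lo <= resnum <= hi:
                sigma[(chain, resnum)] = s
    base = FluctuationSpec(reference=topo, sigma_per_residue=sigma,
                           n_frames=N_FRAMES, seed=seed)
    contact = ContactSwitchSpec(
        group_a=CONTACT_A, group_b=CONTACT_B_GROUP,
        p_unbind=cfg["p_unbind"], p_rebind=cfg["p_rebind"],
        unbound_offset=0.8, seed=seed + 1,
    )
    return base, contact
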