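#!/usr/bin/env python
"""Simulate the two trajectory conditions and write them as multi-model PDB.

Generates a wild-type-like and a destabilised-variant-like 500-frame
trajectory of the synthetic DID-DAD backbone (per-residue harmonic
fluctuations plus two-state Markov switching of the Gly62-Glu968 interface
contact), writes the PDB files and per-frame truth tables under scratch/
(they are bulky), and a small summary of the commanded conditions under
results/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH, TRAJ_CONDITIONS, build_specs

from phenodyn.synthetic_traj import expected_rmsf, generate_contact_trajectory
from phenodyn.traj_io import write_multimodel_pdb

SEED = 20260901


def main() -> None:
    outdir = SCRATCH / "trajectories"
    outdir.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    rows = []
    for i, condition in enumerate(TRAJ_CONDITIONS):
        base, contact = build_specs(condition, seed=SEED + 100 * i)
        traj, states = generate_contact_trajectory(base, contact)
        pdb_path = outdir / f"{condition}.pdb"
        write_multimodel_pdb(traj, pdb_path)
        truth = pd.DataFrame({"frame": range(traj.n_frames), "unbound": states})
        truth.to_csv(outdir / f"{condition}_truth.csv", index=False)

        exp = expected_rmsf(base)
        peak = max(v for (c, r), v in exp.items() if c == "A")
        rows.append({
            "condition": condition,
            "n_frames": traj.n_frames,
            "n_atoms": traj.n_atoms,
            "commanded_unbound_occupancy": contact.stationary_unbound,
            "observed_unbound_fraction": states.mean(),
            "expected_peak_rmsf_nm": peak,
            "pdb": str(pdb_path),
        })
        print(f"{condition}: {traj.n_frames} frames, commanded unbound occupancy "
              f"{contact.stationary_unbound:.3f}, realised {states.mean():.3f}")

    pd.DataFrame(rows).to_csv(RESULTS / "trajectory_conditions.csv", index=False)
    print(f"wrote {RESULTS / 'trajectory_conditions.csv'}")


if __name__ == "__main__":
    main()
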