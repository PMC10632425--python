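#!/usr/bin/env python
"""Generate the ground-truth synthetic datasets for all three strands.

Writes the three-condition DEER dataset (traces + truth record), the truth
record of the bilayer binding trajectory (the trajectory itself is
regenerated from its seed by later steps; at 5000 frames it is not worth
serializing), and a toy structure pair with its known transform.
"""

import argparse
import json
from pathlib import Path

from asymcycle.structure_io import write_structure
from asymcycle.synthetic_data import (
    StructureTruthSpec,
    consensus_nbs_preset,
    default_lipid_spec,
    gen_deer_dataset,
    gen_lipid_trajectory,
    gen_structure_pair,
    write_deer_dataset,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=str, default="results/synthetic")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    traces, truth = gen_deer_dataset(consensus_nbs_preset(noise_sd=0.005, seed=args.seed))
    write_deer_dataset(traces, truth, out / "deer")
    print(f"DEER: {len(traces)} conditions x {traces[0].signal.size} points -> {out/'deer'}")

    lipid_spec = default_lipid_spec(seed=args.seed)
    _, lipid_truth = gen_lipid_trajectory(lipid_spec)
    (out / "lipid_truth.json").write_text(json.dumps(lipid_truth, indent=1))
    realized = [s["realized_bound_fraction"] for s in lipid_truth["binding_sites"]]
    print(
        f"lipid: {lipid_spec.n_frames} frames, {len(realized)} binding sites, "
        f"mean realized bound fraction {sum(realized)/len(realized):.3f} "
        f"(design 0.6) -> {out/'lipid_truth.json'}"
    )

    spec = StructureTruthSpec(
        rotation_axis=(0.3, -0.5, 0.8), rotation_angle_deg=47.0,
        translation=(5.0, -3.0, 2.0), seed=args.seed,
    )
    base, moved, struct_truth = gen_structure_pair(spec)
    write_structure(base, out / "pair_base.pdb")
    write_structure(moved, out / "pair_moved.pdb")
    (out / "pair_truth.json").write_text(json.dumps(struct_truth, indent=1))
    print(f"structures: rigid pair (47 deg) -> {out/'pair_*.pdb'}")


if __name__ == "__main__":
    main()
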