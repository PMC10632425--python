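import numpy as np
import pytest

from asymcycle.structure_io import TrajectoryView
from asymcycle.synthetic_data import (
    BindingSite,
    LipidTruthSpec,
    consensus_nbs_preset,
    gen_deer_dataset,
    gen_lipid_trajectory,
)


@pytest.fixture(scope="session")
def deer_preset():
    """Three-condition preset traces at the study noise level, with truth."""
    traces, truth = gen_deer_dataset(consensus_nbs_preset(noise_sd=0.005, seed=7))
    return traces, truth


@pytest.fixture(scope="session")
def lipid_traj_small():
    """Short bilayer trajectory with 4 two-state binding sites (f=0.6)."""
    spec = LipidTruthSpec(
        n_lipids_per_leaflet=10,
        n_frames=800,
        binding_sites=tuple(
            BindingSite(resid=r, bound_fraction=0.6, mean_dwell=20.0)
            for r in (101, 102, 103, 104)
        ),
        seed=3,
    )
    traj, truth = gen_lipid_trajectory(spec)
    return traj, truth


def make_micro_trajectory(frames):
    """Hand-built TrajectoryView: a LYS tripeptide stub plus one lipid.

    ``frames`` is a list of dicts mapping atom key -> xyz; keys are
    ('A', resid, name) for protein atoms and ('L', 900, name) for the lipid
    (P and C2).  Used for constructed-geometry angle and distance tests.
    """
    roster = [
        ("A", 1, "ALA", "N", "N"),
        ("A", 1, "ALA", "CA", "C"),
        ("A", 1, "ALA", "C", "C"),
        ("A", 1, "ALA", "O", "O"),
        ("A", 2, "LYS", "CA", "C"),
        ("A", 2, "LYS", "CB", "C"),
        ("A", 2, "LYS", "NZ", "N"),
        ("A", 3, "ALA", "N", "N"),
        ("A", 3, "ALA", "CA", "C"),
        ("A", 3, "ALA", "C", "C"),
        ("A", 3, "ALA", "O", "O"),
        ("L", 900, "POPC", "P", "P"),
        ("L", 900, "POPC", "C2", "C"),
    ]
    coords = np.zeros((len(frames), len(roster), 3))
    for f, frame in enumerate(frames):
        for i, (ch, rid, _rn, name, _el) in enumerate(roster):
            coords[f, i] = frame[(ch, rid, name)]
    chain = np.array([r[0] for r in roster], dtype=object)
    resid = np.array([r[1] for r in roster], dtype=int)
    resname = np.array([r[2] for r in roster], dtype=object)
    name = np.array([r[3] for r in roster], dtype=object)
    element = np.array([r[4] for r in roster], dtype=object)
    is_protein = chain == "A"
    is_lipid = ~is_protein
    lipid_id = np.where(is_lipid, 0, -1)
    is_phos = np.array([n == "P" for n in name]) & is_lipid
    return TrajectoryView(
        coords=coords, dt_ns=1.0, chain=chain, resid=resid, resname=resname,
        name=name, element=element, is_protein=is_protein, is_lipid=is_lipid,
        lipid_id=lipid_id, is_phosphorus=is_phos,
    )


def micro_frame(
    ca=(1.0, 0.0, 0.0), nz=(2.0, 0.0, 0.0), lipid_p=(50.0, 0.0, 0.0)
):
    """One frame for make_micro_trajectory with controllable key atoms.

    Neighbour backbone atoms (residues 1 and 3) cluster at the origin, so the
    first angle vector is CA - origin; NZ sets the second vector.
    """
    frame = {}
    eps = 1e-3
    offsets = {"N": (eps, 0, 0), "CA": (0, eps, 0), "C": (-eps, 0, 0), "O": (0, -eps, 0)}
    for rid, zoff in ((1, eps), (3, -eps)):
        for nm, off in offsets.items():
            frame[("A", rid, nm)] = np.array(off) + np.array([0, 0, zoff])
    frame[("A", 2, "CA")] = np.asarray(ca, dtype=float)
    frame[("A", 2, "CB")] = 0.5 * (np.asarray(ca) + np.asarray(nz))
    frame[("A", 2, "NZ")] = np.asarray(nz, dtype=float)
    frame[("L", 900, "P")] = np.asarray(lipid_p, dtype=float)
    frame[("L", 900, "C2")] = np.asarray(lipid_p, dtype=float) + np.array([0, 0, 2.0])
    return frame
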