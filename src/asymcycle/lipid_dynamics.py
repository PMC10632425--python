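"""Protein-lipid interaction analytics on trajectories.

Given a :class:`~asymcycle.structure_io.TrajectoryView` of a membrane protein
in a bilayer, this module quantifies how lipids engage the protein surface:

* leaflet assignment of each lipid from its phosphorus z-position relative to
  the per-frame bilayer midplane;
* per-lipid minimum heavy-atom distance to the protein surface over time;
* residence fractions (fraction of frames in contact) of lipids at basic
  surface residues, the normalized 0-1 scale on which stably bound lipids
  approach 1 and gliding lipids stay low;
* per-leaflet 2-D kernel-density maps of lipid phosphorus positions within a
  shell of the protein, in which sharp peaks mark stable binding sites and
  smeared density marks lipids gliding along the surface;
* the side-chain orientation angle of basic residues (Lys/Arg), defined by
  the vector from the centre of mass of the neighbouring residues' backbone
  to the residue's alpha carbon and the vector from the alpha carbon to the
  centre of mass of the terminal charged nitrogens.

All metrics are invariant under global rigid transforms of each frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde

from .structure_io import BACKBONE_ATOMS, TrajectoryView

__all__ = [
    "LeafletAssignment",
    "ContactSeries",
    "ResidenceSummary",
    "DensityMap",
    "AngleSeries",
    "assign_leaflets",
    "min_distance_series",
    "contact_series",
    "residence_fractions",
    "kde_density_map",
    "sidechain_angle_series",
    "basic_surface_residues",
    "dwell_times",
]

#: terminal charged nitrogen atoms used for the side-chain vector
_TERMINAL_N = {"LYS": ("NZ",), "ARG": ("NH1", "NH2")}

#: theoretical maximum accessible surface areas (A^2, Tien et al. scale) used
#: for relative side-chain accessibility of the basic residues
_MAX_SASA = {"LYS": 236.0, "ARG": 274.0}


@dataclass
class LeafletAssignment:
    """Constant per-lipid leaflet labels plus the per-frame midplane."""

    leaflet: dict[int, str]  # lipid molecule id -> 'upper' | 'lower'
    midplane_z: np.ndarray  # (n_frames,)

    def ids(self, which: str) -> list[int]:
        return sorted(lid for lid, leaf in self.leaflet.items() if leaf == which)


@dataclass
class ContactSeries:
    """Boolean per-frame contact record for one (residue, lipid-set) query."""

    residue: tuple[str, int]
    bound: np.ndarray  # bool, length n_frames
    cutoff: float

    @property
    def fraction(self) -> float:
        return float(self.bound.mean())


@dataclass
class ResidenceSummary:
    """Residence fractions at basic surface residues with box-plot statistics."""

    fractions: dict[tuple[str, int], float]
    cutoff: float
    series: dict[tuple[str, int], ContactSeries] = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return np.array(list(self.fractions.values()))

    def stats(self) -> dict[str, float]:
        v = self.values
        return {
            "n": int(v.size),
            "min": float(v.min()),
            "q1": float(np.percentile(v, 25)),
            "median": float(np.percentile(v, 50)),
            "q3": float(np.percentile(v, 75)),
            "mean": float(v.mean()),
            "max": float(v.max()),
        }


@dataclass
class DensityMap:
    """Normalized 2-D occupancy density of lipid phosphorus in one leaflet."""

    leaflet: str
    x: np.ndarray  # grid x centers
    y: np.ndarray  # grid y centers
    density: np.ndarray  # (len(y), len(x)), integrates to 1 over the grid
    bandwidth: float  # isotropic Gaussian bandwidth (A)
    shell: float  # collection shell around the protein (A)
    n_points: int = 0
    grid_spacing: float = 1.0

    @property
    def mass(self) -> float:
        return float(self.density.sum() * self.grid_spacing**2)

    @property
    def peak(self) -> tuple[float, float, float]:
        """(x, y, value) of the density maximum."""
        iy, ix = np.unravel_index(np.argmax(self.density), self.density.shape)
        return float(self.x[ix]), float(self.y[iy]), float(self.density[iy, ix])


@dataclass
class AngleSeries:
    """Per-frame side-chain orientation angle (degrees) for one basic residue."""

    residue: tuple[str, int]
    angles: np.ndarray  # degrees in [0, 180]; NaN for skipped frames
    skipped_frames: list[int] = field(default_factory=list)


def assign_leaflets(traj: TrajectoryView) -> LeafletAssignment:
    """Assign every lipid with a phosphorus atom to a leaflet.

    The bilayer midplane in each frame is the mean z of all lipid phosphorus
    atoms; a lipid is 'upper' in a frame when its phosphorus sits above the
    midplane, and its final label is the majority vote over frames.
    """
    p_idx = np.flatnonzero(traj.is_phosphorus & (traj.lipid_id >= 0))
    if p_idx.size == 0:
        raise ValueError("trajectory contains no lipid phosphorus atoms")
    pz = traj.coords[:, p_idx, 2]  # (n_frames, n_P)
    mid = pz.mean(axis=1)
    above = pz > mid[:, None]
    leaflet: dict[int, str] = {}
    lids = traj.lipid_id[p_idx]
    for lid in np.unique(lids):
        cols = np.flatnonzero(lids == lid)
        frac_up = above[:, cols].mean()
        leaflet[int(lid)] = "upper" if frac_up >= 0.5 else "lower"
    return LeafletAssignment(leaflet=leaflet, midplane_z=mid)


def min_distance_series(traj: TrajectoryView, lipid_id: int) -> np.ndarray:
    """Per-frame minimum heavy-atom distance of one lipid to the protein surface."""
    lip = np.flatnonzero((traj.lipid_id == lipid_id) & traj.heavy)
    if lip.size == 0:
        raise ValueError(f"unknown lipid molecule id {lipid_id}")
    prot = np.flatnonzero(traj.is_protein & traj.heavy)
    if prot.size == 0:
        raise ValueError("trajectory contains no protein heavy atoms")
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        tree = cKDTree(traj.coords[f, prot])
        d, _ = tree.query(traj.coords[f, lip], k=1)
        out[f] = d.min()
    return out


def _sidechain_heavy(traj: TrajectoryView, chain: str, resid: int) -> np.ndarray:
    idx = traj.residue_atoms(chain, resid)
    if idx.size == 0:
        raise ValueError(f"residue {chain}:{resid} not in trajectory")
    mask = ~np.isin(traj.name[idx], list(BACKBONE_ATOMS)) & (traj.element[idx] != "H")
    return idx[mask]


def contact_series(
    traj: TrajectoryView, residue: tuple[str, int], cutoff: float = 4.0,
    lipid_ids=None,
) -> ContactSeries:
    """Frame-by-frame: is any lipid heavy atom within ``cutoff`` of the
    residue's side-chain heavy atoms?  ``lipid_ids`` restricts the query to a
    lipid subset (per-lipid residence); default is any lipid."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sc = _sidechain_heavy(traj, *residue)
    if sc.size == 0:
        raise ValueError(f"residue {residue[0]}:{residue[1]} has no side-chain heavy atoms")
    if lipid_ids is None:
        lip = np.flatnonzero((traj.lipid_id >= 0) & traj.heavy)
    else:
        lip = np.flatnonzero(np.isin(traj.lipid_id, list(lipid_ids)) & traj.heavy)
    if lip.size == 0:
        raise ValueError("no lipid heavy atoms selected")
    bound = np.empty(traj.n_frames, dtype=bool)
    for f in range(traj.n_frames):
        tree = cKDTree(traj.coords[f, lip])
        d, _ = tree.query(traj.coords[f, sc], k=1, distance_upper_bound=cutoff)
        bound[f] = np.any(np.isfinite(d) & (d <= cutoff))
    return ContactSeries(residue=residue, bound=bound, cutoff=cutoff)


def residence_fractions(
    traj: TrajectoryView, basic_residues, cutoff: float = 4.0,
    keep_series: bool = False,
) -> ResidenceSummary:
    """Residence fraction (fraction of frames in contact with any lipid) for
    each listed basic residue, on the normalized 0-1 scale."""
    residues = list(basic_residues)
    if not residues:
        raise ValueError("basic residue list is empty")
    fractions: dict[tuple[str, int], float] = {}
    series: dict[tuple[str, int], ContactSeries] = {}
    for res in residues:
        cs = contact_series(traj, tuple(res), cutoff)
        fractions[tuple(res)] = cs.fraction
        if keep_series:
            series[tuple(res)] = cs
    return ResidenceSummary(fractions=fractions, cutoff=cutoff, series=series)


def dwell_times(series: ContactSeries) -> np.ndarray:
    """Lengths (in frames) of contiguous bound runs in a contact series."""
    b = series.bound.astype(int)
    edges = np.diff(np.concatenate([[0], b, [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return ends - starts


def kde_density_map(
    traj: TrajectoryView,
    assignment: LeafletAssignment,
    leaflet: str,
    shell: float = 20.0,
    bandwidth: float | None = None,
    grid_spacing: float = 1.0,
    frame_stride: int = 1,
) -> DensityMap:
    """Gaussian-kernel density of lipid phosphorus (X, Y) positions near the
    protein for one leaflet.

    Phosphorus positions within ``shell`` (default 20 A) of any protein atom
    are pooled over frames (every ``frame_stride``-th frame) and smoothed with
    an isotropic Gaussian kernel (Scott's-rule bandwidth unless given) on a
    regular grid padded by three bandwidths; the map is normalized to unit
    mass on the grid.
    """
    if leaflet not in ("upper", "lower"):
        raise ValueError("leaflet must be 'upper' or 'lower'")
    if frame_stride < 1:
        raise ValueError("frame_stride must be >= 1")
    lids = assignment.ids(leaflet)
    p_idx = np.flatnonzero(traj.is_phosphorus & np.isin(traj.lipid_id, lids))
    prot = np.flatnonzero(traj.is_protein)
    pts = []
    for f in range(0, traj.n_frames, frame_stride):
        tree = cKDTree(traj.coords[f, prot])
        d, _ = tree.query(traj.coords[f, p_idx], k=1)
        near = d <= shell
        if np.any(near):
            pts.append(traj.coords[f, p_idx[near], :2])
    if not pts:
        raise ValueError(
            f"no lipid phosphorus within {shell} A of the protein in leaflet {leaflet!r}"
        )
    xy = np.vstack(pts)
    if bandwidth is None:
        kde = gaussian_kde(xy.T)
    else:
        sd = np.sqrt(np.mean(np.var(xy, axis=0, ddof=1)))
        kde = gaussian_kde(xy.T, bw_method=bandwidth / sd if sd > 0 else 1.0)
    bw = float(np.sqrt(np.mean(np.diag(kde.covariance))))
    pad = 3.0 * bw
    # the grid must resolve the kernel: clamp the spacing to the bandwidth
    grid_spacing = min(grid_spacing, bw) if bw > 0 else grid_spacing
    x = np.arange(xy[:, 0].min() - pad, xy[:, 0].max() + pad + grid_spacing, grid_spacing)
    y = np.arange(xy[:, 1].min() - pad, xy[:, 1].max() + pad + grid_spacing, grid_spacing)
    gx, gy = np.meshgrid(x, y)
    dens = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(gy.shape)
    dens = np.clip(dens, 0.0, None)
    mass = dens.sum() * grid_spacing**2
    dens /= mass
    return DensityMap(
        leaflet=leaflet, x=x, y=y, density=dens, bandwidth=bw, shell=shell,
        n_points=xy.shape[0], grid_spacing=grid_spacing,
    )


def _com(coords: np.ndarray) -> np.ndarray:
    return coords.mean(axis=0)


def sidechain_angle_series(traj: TrajectoryView, residue: tuple[str, int]) -> AngleSeries:
    """Side-chain orientation angle of a Lys or Arg residue over frames.

    v1 points from the centre of mass of the backbone atoms (N, CA, C, O) of
    residues i-1 and i+1 to the alpha carbon of residue i; v2 points from the
    alpha carbon to the centre of mass of the terminal charged nitrogens (NZ
    for Lys, NH1/NH2 for Arg).  The angle between v1 and v2 is returned in
    degrees within [0, 180].
    """
    chain, resid = residue
    idx = traj.residue_atoms(chain, resid)
    if idx.size == 0:
        raise ValueError(f"residue {chain}:{resid} not in trajectory")
    resname = str(traj.resname[idx[0]])
    if resname not in _TERMINAL_N:
        raise ValueError(f"{chain}:{resid} is {resname}, need LYS or ARG")
    ca = idx[traj.name[idx] == "CA"]
    term = idx[np.isin(traj.name[idx], list(_TERMINAL_N[resname]))]
    if ca.size != 1 or term.size == 0:
        raise ValueError(f"{chain}:{resid}: missing CA or terminal nitrogen atoms")
    neighbor_bb = []
    for nb in (resid - 1, resid + 1):
        nb_idx = traj.residue_atoms(chain, nb)
        nb_bb = nb_idx[np.isin(traj.name[nb_idx], ["N", "CA", "C", "O"])]
        if nb_bb.size == 0:
            raise ValueError(
                f"{chain}:{resid}: neighbour residue {nb} missing (chain terminus?)"
            )
        neighbor_bb.append(nb_bb)
    nb_all = np.concatenate(neighbor_bb)

    angles = np.full(traj.n_frames, np.nan)
    skipped: list[int] = []
    for f in range(traj.n_frames):
        xyz = traj.coords[f]
        v1 = xyz[ca[0]] - _com(xyz[nb_all])
        v2 = _com(xyz[term]) - xyz[ca[0]]
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 < 1e-9 or n2 < 1e-9 or not (np.all(np.isfinite(v1)) and np.all(np.isfinite(v2))):
            skipped.append(f)
            continue
        cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
        angles[f] = np.degrees(np.arccos(cosang))
    if skipped:
        warnings.warn(
            f"{chain}:{resid}: skipped {len(skipped)} frames with degenerate geometry"
        )
    return AngleSeries(residue=residue, angles=angles, skipped_frames=skipped)


def basic_surface_residues(
    traj: TrajectoryView, threshold: float = 0.2, frame: int = 0
) -> list[tuple[str, int]]:
    """Lys/Arg residues whose side chain is solvent-exposed on one frame.

    Exposure is the Shrake-Rupley accessible surface area of the side-chain
    heavy atoms divided by the residue's theoretical maximum; residues above
    ``threshold`` relative accessibility are returned.  Intended as the
    default residue set; an explicit user list always takes precedence.
    """
    import biotite.structure as struc

    prot = np.flatnonzero(traj.is_protein)
    arr = struc.AtomArray(prot.size)
    arr.coord = np.asarray(traj.coords[frame, prot], dtype=np.float32)
    arr.chain_id = traj.chain[prot].astype("U4")
    arr.res_id = traj.resid[prot]
    arr.res_name = traj.resname[prot].astype("U5")
    arr.atom_name = traj.name[prot].astype("U6")
    arr.element = traj.element[prot].astype("U2")
    arr.hetero = np.zeros(prot.size, dtype=bool)
    sasa = struc.sasa(arr, vdw_radii="Single")
    sasa = np.nan_to_num(sasa)

    out = []
    for chain in np.unique(arr.chain_id):
        cmask = arr.chain_id == chain
        for resid in np.unique(arr.res_id[cmask]):
            rmask = cmask & (arr.res_id == resid)
            resname = arr.res_name[rmask][0]
            if resname not in _TERMINAL_N:
                continue
            sc = rmask & ~np.isin(arr.atom_name, list(BACKBONE_ATOMS))
            rel = sasa[sc].sum() / _MAX_SASA[resname]
            if rel >= threshold:
                out.append((str(chain), int(resid)))
    return sorted(out)
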