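"""Coordinate-model and trajectory I/O for the analysis pipeline.

Structures (PDB / mmCIF, read through gemmi) are flattened into a simple
array-backed :class:`StructureModel`; trajectories (DCD/XTC or a plain
multi-frame PDB, read through MDAnalysis) become a :class:`TrajectoryView`
with a fixed atom roster whose flags distinguish protein atoms, lipid
molecules and lipid phosphorus atoms.  Residue numbering is kept exactly as
authored in the file, insertion codes included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "StructureModel",
    "TrajectoryView",
    "SelectionError",
    "DEFAULT_LIPID_RESNAMES",
    "BACKBONE_ATOMS",
    "read_structure",
    "write_structure",
    "select_atoms",
    "read_trajectory",
    "write_trajectory",
    "read_residue_map",
    "write_residue_map",
]

#: Residue names treated as lipids by default; the deposited het codes for
#: modeled lipids vary between entries, so the set is user-overridable and is
#: supplemented by a structural rule (has a P atom, lacks a peptide backbone).
DEFAULT_LIPID_RESNAMES = frozenset(
    {"POPC", "POPA", "POPE", "POPG", "PC", "PA", "LPP", "PC1", "PLC", "PEF", "LHG"}
)

BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")

_AMINO3 = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL MSE".split()
)


class SelectionError(ValueError):
    """Raised for malformed atom-selection expressions."""


@dataclass
class StructureModel:
    """A single coordinate model flattened into parallel arrays."""

    chain: np.ndarray  # str
    resid: np.ndarray  # int, author numbering
    icode: np.ndarray  # str, insertion code ('' if none)
    resname: np.ndarray  # str
    name: np.ndarray  # atom name, str
    element: np.ndarray  # str
    coords: np.ndarray  # (n, 3) float, Angstrom
    het: np.ndarray  # bool
    model_id: str = "1"

    def __post_init__(self) -> None:
        n = len(self.name)
        if n == 0:
            raise ValueError("structure contains no atoms")
        if self.coords.shape != (n, 3) or not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be a finite (n, 3) array")
        keys = list(zip(self.chain, self.resid, self.icode, self.name))
        if len(set(keys)) != n:
            raise ValueError("duplicate (chain, residue, atom name) in model")

    def __len__(self) -> int:
        return len(self.name)

    @property
    def is_amino(self) -> np.ndarray:
        return np.isin(self.resname, list(_AMINO3))

    def residue_atoms(self, chain: str, resid: int, icode: str = "") -> np.ndarray:
        """Indices of all atoms of one residue."""
        return np.flatnonzero(
            (self.chain == chain) & (self.resid == resid) & (self.icode == icode)
        )

    def subset(self, indices) -> "StructureModel":
        idx = np.asarray(indices, dtype=int)
        return StructureModel(
            chain=self.chain[idx],
            resid=self.resid[idx],
            icode=self.icode[idx],
            resname=self.resname[idx],
            name=self.name[idx],
            element=self.element[idx],
            coords=self.coords[idx],
            het=self.het[idx],
            model_id=self.model_id,
        )


@dataclass
class TrajectoryView:
    """Frames of coordinates over a fixed atom roster with role flags."""

    coords: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    dt_ns: float
    chain: np.ndarray
    resid: np.ndarray
    resname: np.ndarray
    name: np.ndarray
    element: np.ndarray
    is_protein: np.ndarray  # bool
    is_lipid: np.ndarray  # bool
    lipid_id: np.ndarray  # int, -1 for non-lipid atoms
    is_phosphorus: np.ndarray  # bool

    def __post_init__(self) -> None:
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.dt_ns <= 0:
            raise ValueError("frame interval must be positive")
        lids = np.unique(self.lipid_id[self.lipid_id >= 0])
        for lid in lids:
            if not np.any(self.lipid_id == lid):
                raise ValueError(f"lipid molecule {lid} maps to no atoms")
        if np.any(self.is_lipid & (self.lipid_id < 0)):
            raise ValueError("lipid atom without a lipid molecule id")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def lipid_ids(self) -> np.ndarray:
        return np.unique(self.lipid_id[self.lipid_id >= 0])

    @property
    def heavy(self) -> np.ndarray:
        return self.element != "H"

    def residue_atoms(self, chain: str, resid: int) -> np.ndarray:
        return np.flatnonzero((self.chain == chain) & (self.resid == resid))


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        fmt = fmt.lower()
        if fmt not in ("pdb", "cif", "mmcif"):
            raise ValueError(f"unsupported structure format {fmt!r}")
        return "cif" if fmt == "mmcif" else fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix == "gz":
        suffix = path.suffixes[-2].lower().lstrip(".")
    if suffix in ("pdb", "ent"):
        return "pdb"
    if suffix in ("cif", "mmcif"):
        return "cif"
    raise ValueError(f"cannot infer structure format from {path.name!r}")


def read_structure(path, format: str | None = None) -> StructureModel:
    """Read the first model of a PDB or mmCIF file into a StructureModel.

    All ATOM and HETATM records are kept; author residue numbering and
    insertion codes are preserved verbatim.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"unreadable {fmt} file {path.name}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path.name}: no models in file")
    st.setup_entities()
    model = st[0]
    rows = []
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            for atom in res:
                rows.append(
                    (
                        chain.name,
                        res.seqid.num,
                        (res.seqid.icode or " ").strip(),
                        res.name,
                        atom.name,
                        atom.element.name,
                        atom.pos.x,
                        atom.pos.y,
                        atom.pos.z,
                        het,
                    )
                )
    if not rows:
        raise ValueError(f"{path.name}: model contains no atoms")
    cols = list(zip(*rows))
    return StructureModel(
        chain=np.array(cols[0], dtype=object),
        resid=np.array(cols[1], dtype=int),
        icode=np.array(cols[2], dtype=object),
        resname=np.array(cols[3], dtype=object),
        name=np.array(cols[4], dtype=object),
        element=np.array(cols[5], dtype=object),
        coords=np.column_stack([cols[6], cols[7], cols[8]]).astype(float),
        het=np.array(cols[9], dtype=bool),
        model_id=str(getattr(model, "name", "1") or "1"),
    )


def _to_gemmi(structure: StructureModel):
    import gemmi

    st = gemmi.Structure()
    model = gemmi.Model("1")
    # gemmi's add_* methods copy their argument, so each level must be fully
    # populated before being added to its parent
    for ch_name in dict.fromkeys(structure.chain):  # preserve order
        chain = gemmi.Chain(str(ch_name))
        idx = np.flatnonzero(structure.chain == ch_name)
        groups: list[tuple[tuple, list[int]]] = []
        for i in idx:
            key = (structure.resid[i], structure.icode[i], structure.resname[i])
            if not groups or groups[-1][0] != key:
                groups.append((key, []))
            groups[-1][1].append(i)
        for (resid, icode, resname), atom_idx in groups:
            res = gemmi.Residue()
            res.name = str(resname)
            res.seqid = gemmi.SeqId(int(resid), icode or " ")
            res.het_flag = "H" if structure.het[atom_idx[0]] else "A"
            for i in atom_idx:
                atom = gemmi.Atom()
                atom.name = str(structure.name[i])
                atom.element = gemmi.Element(str(structure.element[i]))
                atom.pos = gemmi.Position(*structure.coords[i])
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: StructureModel, path) -> None:
    """Write a StructureModel as PDB or mmCIF (by extension)."""
    path = Path(path)
    st = _to_gemmi(structure)
    fmt = _infer_format(path, None)
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

def _residue_has(structure: StructureModel, names) -> np.ndarray:
    """Per-atom bool: atom's residue contains any atom named in ``names``."""
    keys = np.array(
        [f"{c}|{r}|{i}" for c, r, i in zip(structure.chain, structure.resid, structure.icode)],
        dtype=object,
    )
    has = set(keys[np.isin(structure.name, list(names))])
    return np.array([k in has for k in keys], dtype=bool)


def lipid_mask(structure: StructureModel, lipid_resnames=DEFAULT_LIPID_RESNAMES) -> np.ndarray:
    """Atoms belonging to lipid molecules.

    A residue counts as a lipid if its name is in ``lipid_resnames`` or if it
    contains a phosphorus atom while lacking the peptide backbone (N, CA, C).
    """
    named = np.isin(structure.resname, list(lipid_resnames))
    has_p = _residue_has(structure, {"P"}) | (structure.element == "P")
    has_bb = (
        _residue_has(structure, {"N"})
        & _residue_has(structure, {"CA"})
        & _residue_has(structure, {"C"})
    )
    # propagate the per-residue P flag to all atoms of the residue
    keys = np.array(
        [f"{c}|{r}|{i}" for c, r, i in zip(structure.chain, structure.resid, structure.icode)],
        dtype=object,
    )
    p_res = set(keys[has_p])
    has_p_res = np.array([k in p_res for k in keys], dtype=bool)
    return named | (has_p_res & ~has_bb & ~structure.is_amino)


def select_atoms(structure: StructureModel, selection: str, lipid_resnames=DEFAULT_LIPID_RESNAMES):
    """Select atom indices with a small 'clause and clause' expression language.

    Supported clauses: ``chain X``, ``resid N`` / ``resid N-M``, ``name A,B``,
    ``resname A,B``, ``protein``, ``lipid``, ``phosphorus``, ``backbone``,
    ``sidechain``, ``heavy``, ``het``.  Returns indices sorted by
    (chain, resid, insertion code, atom name); an empty result warns but is
    not an error.
    """
    mask = np.ones(len(structure), dtype=bool)
    text = selection.strip()
    if not text:
        raise SelectionError("empty selection")
    for clause in [c.strip() for c in text.split(" and ")]:
        parts = clause.split(None, 1)
        kw = parts[0].lower()
        if kw == "chain":
            if len(parts) != 2:
                raise SelectionError(f"'chain' needs an argument: {clause!r}")
            mask &= np.isin(structure.chain, parts[1].split(","))
        elif kw == "resid":
            if len(parts) != 2:
                raise SelectionError(f"'resid' needs an argument: {clause!r}")
            sub = np.zeros(len(structure), dtype=bool)
            for token in parts[1].split(","):
                try:
                    if "-" in token[1:]:
                        a, b = token[0] + token[1:].split("-", 1)[0], token[1:].split("-", 1)[1]
                        lo_r, hi_r = int(a), int(b)
                    else:
                        lo_r = hi_r = int(token)
                except ValueError as exc:
                    raise SelectionError(f"bad residue range {token!r}") from exc
                sub |= (structure.resid >= lo_r) & (structure.resid <= hi_r)
            mask &= sub
        elif kw == "name":
            if len(parts) != 2:
                raise SelectionError(f"'name' needs an argument: {clause!r}")
            mask &= np.isin(structure.name, parts[1].split(","))
        elif kw == "resname":
            if len(parts) != 2:
                raise SelectionError(f"'resname' needs an argument: {clause!r}")
            mask &= np.isin(structure.resname, parts[1].split(","))
        elif kw == "protein" and len(parts) == 1:
            mask &= structure.is_amino & ~structure.het
        elif kw == "lipid" and len(parts) == 1:
            mask &= lipid_mask(structure, lipid_resnames)
        elif kw == "phosphorus" and len(parts) == 1:
            mask &= structure.element == "P"
        elif kw == "backbone" and len(parts) == 1:
            mask &= np.isin(structure.name, list(BACKBONE_ATOMS)) & structure.is_amino
        elif kw == "sidechain" and len(parts) == 1:
            mask &= (
                structure.is_amino
                & ~np.isin(structure.name, list(BACKBONE_ATOMS))
                & (structure.element != "H")
            )
        elif kw == "heavy" and len(parts) == 1:
            mask &= structure.element != "H"
        elif kw == "het" and len(parts) == 1:
            mask &= structure.het
        else:
            raise SelectionError(f"unknown selection clause {clause!r}")
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        warnings.warn(f"selection {selection!r} matched no atoms")
        return idx
    order = np.lexsort(
        (
            structure.name[idx].astype(str),
            structure.icode[idx].astype(str),
            structure.resid[idx],
            structure.chain[idx].astype(str),
        )
    )
    return idx[order]


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def _roster_flags(resnames, names, elements, lipid_resnames):
    resnames = np.asarray(resnames, dtype=object)
    names = np.asarray(names, dtype=object)
    elements = np.asarray(elements, dtype=object)
    is_amino = np.isin(resnames, list(_AMINO3))
    is_lipid_res = np.isin(resnames, list(lipid_resnames))
    is_phosphorus = (elements == "P") | ((elements == "") & (names == "P"))
    return is_amino, is_lipid_res, is_phosphorus


def read_trajectory(
    topology_path,
    coords_path=None,
    dt_ns: float | None = None,
    lipid_resnames=DEFAULT_LIPID_RESNAMES,
) -> TrajectoryView:
    """Read a trajectory (DCD/XTC with a topology, or a multi-frame PDB).

    Roster flags come from naming rules: residues named in ``lipid_resnames``
    are lipids (each residue one lipid molecule), standard amino-acid residues
    are protein, and P atoms are flagged as phosphorus.
    """
    import MDAnalysis as mda

    topology_path = Path(topology_path)
    if not topology_path.exists():
        raise FileNotFoundError(topology_path)
    try:
        if coords_path is None:
            u = mda.Universe(str(topology_path))
        else:
            u = mda.Universe(str(topology_path), str(coords_path))
    except Exception as exc:
        msg = str(exc)
        raise ValueError(f"failed to load trajectory: {msg}") from exc

    atoms = u.atoms
    n_atoms = len(atoms)
    resnames = np.array([r for r in atoms.resnames], dtype=object)
    names = np.array([n for n in atoms.names], dtype=object)
    try:
        elements = np.array([e.capitalize() for e in atoms.elements], dtype=object)
    except Exception:
        elements = np.array([mda.topology.guessers.guess_atom_element(n) for n in names], dtype=object)
    try:
        chains = np.array([c for c in atoms.chainIDs], dtype=object)
    except Exception:
        chains = np.array([s for s in atoms.segids], dtype=object)
    resids = np.asarray(atoms.resids, dtype=int)

    is_amino, is_lipid_res, is_phos = _roster_flags(resnames, names, elements, lipid_resnames)
    lipid_id = np.full(n_atoms, -1, dtype=int)
    res_index = np.asarray(atoms.resindices)
    next_id = 0
    for ri in np.unique(res_index[is_lipid_res]):
        lipid_id[res_index == ri] = next_id
        next_id += 1

    frames = np.empty((len(u.trajectory), n_atoms, 3), dtype=float)
    for i, _ts in enumerate(u.trajectory):
        frames[i] = atoms.positions
    if dt_ns is None:
        dt = getattr(u.trajectory, "dt", None)
        dt_ns = (dt / 1000.0) if dt else 1.0  # MDAnalysis dt is in ps

    return TrajectoryView(
        coords=frames,
        dt_ns=float(dt_ns),
        chain=chains,
        resid=resids,
        resname=resnames,
        name=names,
        element=elements,
        is_protein=is_amino & ~is_lipid_res,
        is_lipid=is_lipid_res,
        lipid_id=lipid_id,
        is_phosphorus=is_phos & is_lipid_res,
    )


def write_trajectory(traj: TrajectoryView, path) -> None:
    """Write a TrajectoryView as a multi-frame PDB (plain-text fallback format)."""
    import MDAnalysis as mda

    path = Path(path)
    n = traj.n_atoms
    # build residue index per atom preserving roster order
    res_keys = [f"{c}|{r}|{rn}" for c, r, rn in zip(traj.chain, traj.resid, traj.resname)]
    seen: dict[str, int] = {}
    atom_resindex = np.empty(n, dtype=int)
    for i, k in enumerate(res_keys):
        if k not in seen:
            seen[k] = len(seen)
        atom_resindex[i] = seen[k]
    n_res = len(seen)
    first_atom = [res_keys.index(k) for k in seen]
    u = mda.Universe.empty(
        n, n_residues=n_res, atom_resindex=atom_resindex, trajectory=True
    )
    u.add_TopologyAttr("names", traj.name.astype(str))
    u.add_TopologyAttr("elements", traj.element.astype(str))
    u.add_TopologyAttr("resnames", traj.resname.astype(str)[first_atom])
    u.add_TopologyAttr("resids", traj.resid[first_atom])
    u.add_TopologyAttr("chainIDs", traj.chain.astype(str))
    u.add_TopologyAttr("occupancies", np.ones(n))
    u.add_TopologyAttr("tempfactors", np.zeros(n))
    with mda.Writer(str(path), n, multiframe=True) as w:
        for f in range(traj.n_frames):
            u.atoms.positions = traj.coords[f]
            w.write(u.atoms)


# ---------------------------------------------------------------------------
# residue correspondence maps
# ---------------------------------------------------------------------------

def fetch_structure(accession: str, cache_dir="scratch/pdb", timeout: float = 15.0) -> StructureModel:
    """Download an mmCIF model from the RCSB and read it (cached on disk).

    Requires network access; raises RuntimeError with the underlying cause
    when the archive is unreachable.
    """
    import urllib.error
    import urllib.request

    accession = accession.strip().upper()
    if not (len(accession) == 4 and accession[0].isdigit()):
        raise ValueError(f"{accession!r} is not a PDB accession")
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    dest = cache / f"{accession}.cif"
    if not dest.exists():
        url = f"https://files.rcsb.org/download/{accession}.cif"
        try:
            with urllib.request.urlopen(url, timeout=timeout) as resp:
                data = resp.read()
        except (urllib.error.URLError, OSError, TimeoutError) as exc:
            raise RuntimeError(
                f"could not download {accession} from {url} "
                f"(network unavailable?): {exc}"
            ) from exc
        dest.write_bytes(data)
    return read_structure(dest)


def read_residue_map(path) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    """Read a two-column residue correspondence file.

    Each line pairs two residues as ``CHAIN:RESID  CHAIN:RESID`` (whitespace
    separated; ``#`` comments allowed).  No residue may repeat on either side.
    """
    path = Path(path)
    pairs = []
    seen_a, seen_b = set(), set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            text = line.split("#")[0].strip()
            if not text:
                continue
            fields = text.split()
            if len(fields) != 2:
                raise ValueError(f"{path.name}:{lineno}: expected two columns, got {len(fields)}")
            out = []
            for f in fields:
                if ":" not in f:
                    raise ValueError(f"{path.name}:{lineno}: expected CHAIN:RESID, got {f!r}")
                ch, rid = f.split(":", 1)
                try:
                    out.append((ch, int(rid)))
                except ValueError as exc:
                    raise ValueError(f"{path.name}:{lineno}: bad residue number {rid!r}") from exc
            a, b = out
            if a in seen_a or b in seen_b:
                raise ValueError(f"{path.name}:{lineno}: residue repeated in map")
            seen_a.add(a)
            seen_b.add(b)
            pairs.append((a, b))
    if not pairs:
        raise ValueError(f"{path.name}: empty residue map")
    return pairs


def write_residue_map(pairs, path) -> None:
    with open(path, "w") as fh:
        fh.write("# chainA:resid  chainB:resid\n")
        for (ca, ra), (cb, rb) in pairs:
            fh.write(f"{ca}:{ra}\t{cb}:{rb}\n")
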