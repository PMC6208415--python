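"""Conformational-ensemble container and per-ensemble descriptive statistics.

An :class:`Ensemble` is the single input everything else derives from: a
``frames x atoms x 3`` coordinate array (in Angstrom) together with a
lightweight :class:`Topology` describing residues, atoms and which chains are
the ligand.  Reading of multi-model PDB files and binary trajectory formats
(DCD/XTC/NetCDF + topology PDB) is delegated to mdtraj; secondary structure
is assigned with mdtraj's DSSP implementation and reduced to the
helix/sheet/turn/other alphabet used by the communication threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Topology",
    "Ensemble",
    "SSMatrix",
    "FormatError",
    "EmptyInputError",
    "load_ensemble",
    "select_analysis_window",
    "superpose",
    "mean_structure",
    "rmsd_rmsf",
    "assign_secondary_structure",
]

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


class FormatError(ValueError):
    """Raised when input files are inconsistent with each other."""


class EmptyInputError(ValueError):
    """Raised when no frames (or too few) are available for analysis."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    residue_index: int  # index into Topology.residues
    is_backbone: bool


@dataclass(frozen=True)
class Residue:
    chain_id: str
    resid: int  # author residue number
    resname: str


@dataclass
class Topology:
    """Residue/atom bookkeeping for an ensemble.

    ``ligand_chains`` flags chain ids whose residues are treated as the
    ligand in downstream analyses (direct protein-ligand communication,
    exclusion of short ligands from the MCP distribution).
    """

    residues: list[Residue]
    atoms: list[Atom]
    ligand_chains: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.ligand_chains = frozenset(self.ligand_chains)
        last: dict[str, int] = {}
        for r in self.residues:
            if r.chain_id in last and r.resid <= last[r.chain_id]:
                raise ValueError(
                    f"residue indices must increase within chain {r.chain_id!r}"
                )
            last[r.chain_id] = r.resid
        for a in self.atoms:
            if not 0 <= a.residue_index < len(self.residues):
                raise ValueError(f"atom {a.name} maps to no residue")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom_residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms], dtype=int)

    def residue_atom_indices(self) -> list[np.ndarray]:
        """Atom indices grouped per residue, in residue order."""
        groups: list[list[int]] = [[] for _ in self.residues]
        for i, a in enumerate(self.atoms):
            groups[a.residue_index].append(i)
        return [np.array(g, dtype=int) for g in groups]

    def ca_indices(self) -> np.ndarray:
        """One CA atom index per residue; -1 where a residue lacks a CA."""
        out = np.full(len(self.residues), -1, dtype=int)
        for i, a in enumerate(self.atoms):
            if a.name == "CA" and out[a.residue_index] < 0:
                out[a.residue_index] = i
        return out

    def is_ligand_residue(self) -> np.ndarray:
        return np.array(
            [r.chain_id in self.ligand_chains for r in self.residues], dtype=bool
        )

    def chain_codes(self) -> np.ndarray:
        """Integer chain code per residue (stable order of appearance)."""
        codes: dict[str, int] = {}
        out = np.empty(len(self.residues), dtype=int)
        for i, r in enumerate(self.residues):
            out[i] = codes.setdefault(r.chain_id, len(codes))
        return out

    def resids(self) -> np.ndarray:
        """Author residue number per residue."""
        return np.array([r.resid for r in self.residues], dtype=int)

    def sequence_separation(self, i: int, j: int) -> int | None:
        """|resid difference| within one chain; None across chains."""
        ri, rj = self.residues[i], self.residues[j]
        if ri.chain_id != rj.chain_id:
            return None
        return abs(ri.resid - rj.resid)

    def sequence_positions(self) -> np.ndarray:
        """0-based consecutive position of each residue within its chain."""
        counters: dict[str, int] = {}
        out = np.empty(len(self.residues), dtype=int)
        for i, r in enumerate(self.residues):
            out[i] = counters.get(r.chain_id, 0)
            counters[r.chain_id] = out[i] + 1
        return out

    def label(self, res_index: int) -> str:
        r = self.residues[res_index]
        return f"{r.chain_id}:{r.resid}"


@dataclass
class Ensemble:
    """A set of conformations of one molecular system.

    Coordinates are stored in Angstrom.  ``replicate_bounds`` records the
    frame count contributed by each input replicate so that the analysis
    window (equilibration discard) can be applied per replicate before
    frames are pooled.
    """

    topology: Topology
    coords: np.ndarray  # (frames, atoms, 3), Angstrom
    replicate_bounds: tuple[int, ...] = ()
    frame_times_ns: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[0] < 2:
            raise EmptyInputError("an ensemble needs at least 2 frames")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise FormatError(
                f"coordinate atom count {self.coords.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if not self.replicate_bounds:
            self.replicate_bounds = (self.n_frames,)
        if sum(self.replicate_bounds) != self.n_frames:
            raise ValueError("replicate_bounds must sum to the frame count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_residues(self) -> int:
        return self.topology.n_residues

    def ca_coords(self) -> np.ndarray:
        """(frames, residues, 3) CA coordinates; errors on a missing CA."""
        ca = self.topology.ca_indices()
        missing = np.nonzero(ca < 0)[0]
        if missing.size:
            lbl = self.topology.label(int(missing[0]))
            raise ValueError(f"residue {lbl} has no CA atom")
        return self.coords[:, ca, :]

    def to_mdtraj(self):
        """Build an mdtraj.Trajectory view of this ensemble (nm units)."""
        import mdtraj as md

        top = md.Topology()
        chains: dict[str, object] = {}
        md_res = []
        for r in self.topology.residues:
            ch = chains.get(r.chain_id)
            if ch is None:
                ch = top.add_chain()
                chains[r.chain_id] = ch
            md_res.append(top.add_residue(r.resname, ch, resSeq=r.resid))
        from mdtraj.core import element as elem

        for a in self.topology.atoms:
            try:
                e = elem.get_by_symbol(a.element)
            except KeyError:
                e = elem.virtual
            top.add_atom(a.name, e, md_res[a.residue_index])
        return md.Trajectory(self.coords / 10.0, top)


@dataclass
class SSMatrix:
    """Per-frame secondary-structure labels over {H, E, T, C}."""

    labels: np.ndarray  # (frames, residues) of single characters
    persistence: np.ndarray  # per-residue fraction of frames in {H, E, T}

    def __post_init__(self) -> None:
        if np.any(self.persistence < 0) or np.any(self.persistence > 1):
            raise ValueError("persistence must lie in [0, 1]")


def _element_from_name(name: str) -> str:
    name = name.strip()
    if name[:2].capitalize() in {"Cl", "Br", "Na", "Mg", "Zn", "Fe", "Se"}:
        return name[:2].capitalize()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _topology_from_mdtraj(md_top, ligand_chains: set[str]) -> Topology:
    chain_letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    residues: list[Residue] = []
    atoms: list[Atom] = []
    for chain in md_top.chains:
        cid = getattr(chain, "chain_id", None) or chain_letters[
            chain.index % len(chain_letters)
        ]
        for res in chain.residues:
            residues.append(Residue(cid, res.resSeq, res.name))
            ridx = len(residues) - 1
            for at in res.atoms:
                sym = at.element.symbol if at.element is not None else "C"
                atoms.append(
                    Atom(at.name, sym, ridx, at.name in BACKBONE_NAMES)
                )
    return Topology(residues, atoms, frozenset(ligand_chains))


def load_ensemble(
    paths,
    topology_path: str | None = None,
    ligand_chains=(),
    stride: int = 1,
) -> Ensemble:
    """Read one ensemble from multi-model PDB or trajectory files.

    Each path contributes one replicate; frames are concatenated in file
    order and the per-file frame counts are recorded so the analysis window
    can later be applied per replicate.
    """
    import mdtraj as md

    if isinstance(paths, (str, bytes)):
        paths = [paths]
    paths = list(paths)
    if not paths:
        raise EmptyInputError("no input files given")

    parts = []
    for p in paths:
        if topology_path is not None:
            t = md.load(str(p), top=str(topology_path), stride=stride)
        else:
            t = md.load(str(p), stride=stride)
        if t.n_frames == 0:
            raise EmptyInputError(f"{p} contains no frames")
        parts.append(t)
    n_atoms = parts[0].n_atoms
    for p, t in zip(paths, parts):
        if t.n_atoms != n_atoms:
            raise FormatError(
                f"{p} has {t.n_atoms} atoms, expected {n_atoms}"
            )
    topo = _topology_from_mdtraj(parts[0].topology, set(ligand_chains))
    coords = np.concatenate([t.xyz for t in parts], axis=0) * 10.0  # nm -> A
    bounds = tuple(t.n_frames for t in parts)
    return Ensemble(topo, coords, replicate_bounds=bounds)


def select_analysis_window(e: Ensemble, discard_leading: float) -> Ensemble:
    """Drop the leading (equilibration) fraction of each replicate.

    ``discard_leading=0.25`` on 20-frame replicates keeps the last 15 frames
    of each; pooled statistics are then computed on what remains.
    """
    if not 0 <= discard_leading < 1:
        raise ValueError("discard_leading must lie in [0, 1)")
    if discard_leading == 0:
        return e
    keep_idx: list[np.ndarray] = []
    new_bounds: list[int] = []
    start = 0
    for n in e.replicate_bounds:
        drop = math.ceil(discard_leading * n)
        keep = np.arange(start + drop, start + n)
        if keep.size:
            keep_idx.append(keep)
            new_bounds.append(keep.size)
        start += n
    total = sum(new_bounds)
    if total < 2:
        raise EmptyInputError(
            f"analysis window keeps {total} frame(s); need at least 2"
        )
    idx = np.concatenate(keep_idx)
    return Ensemble(
        e.topology,
        e.coords[idx],
        replicate_bounds=tuple(new_bounds),
        frame_times_ns=None
        if e.frame_times_ns is None
        else e.frame_times_ns[idx],
    )


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t with R @ P + t ~= Q (least squares)."""
    from scipy.spatial.transform import Rotation

    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    rot, _ = Rotation.align_vectors(Q - qc, P - pc)
    R = rot.as_matrix()
    return R, qc - R @ pc


def _fit_frames(coords: np.ndarray, sel: np.ndarray, ref_frame: int) -> np.ndarray:
    ref = coords[ref_frame, sel, :]
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        R, t = _kabsch(coords[f, sel, :], ref)
        out[f] = coords[f] @ R.T + t
    return out


def superpose(e: Ensemble, reference_frame: int = 0, core: bool = True) -> Ensemble:
    """Least-squares superpose every frame on a reference frame using CAs.

    With ``core=True`` (default) the fit is refined in a second pass on the
    least-mobile half of the residues (CA fluctuation at or below the
    median), so that a few highly flexible residues do not drag the frame
    of reference and leak apparent motion into the rigid part.
    """
    ca = e.topology.ca_indices()
    sel = ca[ca >= 0]
    if sel.size < 3:
        sel = np.arange(e.n_atoms)
    out = _fit_frames(e.coords, sel, reference_frame)
    if core and sel.size >= 4:
        fluct = np.sqrt(
            ((out[:, sel, :] - out[:, sel, :].mean(axis=0)) ** 2)
            .sum(axis=2)
            .mean(axis=0)
        )
        stable = sel[fluct <= np.median(fluct)]
        if stable.size >= 3:
            out = _fit_frames(e.coords, stable, reference_frame)
    return Ensemble(
        e.topology,
        out,
        replicate_bounds=e.replicate_bounds,
        frame_times_ns=e.frame_times_ns,
    )


def mean_structure(e: Ensemble, superposed: bool = False) -> np.ndarray:
    """Per-atom mean coordinates after superposition onto frame 0."""
    if not superposed:
        e = superpose(e)
    return e.coords.mean(axis=0)


def rmsd_rmsf(
    e: Ensemble, ca_only: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame RMSD vs frame 0 and per-residue RMSF vs the mean structure.

    Frames are first superposed on frame 0 (CA fit).  RMSF of a residue is
    the root of the mean squared deviation of its atoms from the mean
    structure, averaged over frames and over the residue's atoms (all heavy
    atoms by default, CA only with ``ca_only=True``).
    """
    es = superpose(e)
    if ca_only:
        atom_sel = es.topology.ca_indices()
        groups = [np.array([i]) if i >= 0 else np.array([], dtype=int)
                  for i in atom_sel]
        coords = es.coords
    else:
        groups = es.topology.residue_atom_indices()
        coords = es.coords

    diff0 = coords - coords[0]
    rmsd = np.sqrt((diff0 ** 2).sum(axis=2).mean(axis=1))

    mean = coords.mean(axis=0)
    msd_atom = ((coords - mean) ** 2).sum(axis=2).mean(axis=0)  # per atom
    rmsf = np.array(
        [np.sqrt(msd_atom[g].mean()) if g.size else np.nan for g in groups]
    )
    return rmsd, rmsf


_DSSP_REDUCE = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "T",
}


def assign_secondary_structure(e: Ensemble) -> SSMatrix:
    """DSSP labels per frame, reduced to {H, E, T, C}.

    3-10 and pi helices map to H, isolated beta bridges to E, hydrogen
    bonded turns to T, everything else (bends, coil, missing backbone) to C.
    Persistence is the per-residue fraction of frames with a non-C label.
    """
    import mdtraj as md

    traj = e.to_mdtraj()
    names_per_res = [
        {a.name for a in e.topology.atoms if a.residue_index == i}
        for i in range(e.n_residues)
    ]
    incomplete = [
        i for i, names in enumerate(names_per_res)
        if not {"N", "CA", "C", "O"} <= names
    ]
    if incomplete:
        warnings.warn(
            f"{len(incomplete)} residue(s) lack full backbone; labelled C",
            stacklevel=2,
        )
    raw = md.compute_dssp(traj, simplified=False)
    labels = np.empty(raw.shape, dtype="<U1")
    for code, out in _DSSP_REDUCE.items():
        labels[raw == code] = out
    labels[~np.isin(raw, list(_DSSP_REDUCE))] = "C"
    for i in incomplete:
        labels[:, i] = "C"
    persistence = (labels != "C").mean(axis=0)
    return SSMatrix(labels, persistence)
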