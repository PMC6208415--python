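"""Synthetic conformational ensembles with planted dynamical architecture.

The generator builds an idealized mean structure (NeRF-constructed ideal
alpha helices for rigid blocks, compact coil blobs for flexible loops,
optionally a short peptide ligand chain) and draws frames as Gaussian
displacements around it:

* residues of a rigid block share one small rigid-body translation per
  frame, plus independent per-residue jitter, so intra-block CA distances
  fluctuate only through the jitter (CP ~ 2 sigma_jitter^2);
* residues of a flexible loop share a block-correlated displacement
  (intra-block correlation rho) of amplitude sigma_loop, giving high RMSF
  and high pairwise displacement correlation;
* a planted bridge pair (i, j) overrides residue j's displacement to copy
  residue i's plus 1-D noise along the separation vector, realising a
  prescribed CA-CA distance variance while both flanks fluctuate with
  their independent blocks (an isolated low-variance communication);
* a planted unit-overlap residue rides the loop's shared noise projected
  perpendicular to the separation vector toward a designated helix
  partner, so it joins a clique (flexible, correlated, proximal to the
  loop) while keeping one low-variance pathway contact;
* a ligand chain copies the rigid noise of the block it binds, placing one
  hydrogen-bond contact with a designated protein residue.

Atom templates are idealized (fixed internal geometry) - sufficient for the
distance/contact/burial mathematics, with no physical energetics.  All
randomness flows from a single integer seed; identical seeds give
bit-identical ensembles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .ensemble import Atom, Ensemble, Residue, Topology

__all__ = [
    "HelixBlock",
    "LoopBlock",
    "BridgePair",
    "UnitOverlap",
    "LigandSpec",
    "PlantedContact",
    "SyntheticSpec",
    "GroundTruth",
    "GenerationError",
    "generate_ensemble",
    "generate_mutant_family",
    "unit_recovery_spec",
    "bridge_spec",
    "mutant_family_spec",
]

CLASH_TOLERANCE = 1.8  # A; mean-structure atoms closer than this -> error
MIN_RESIDUE_SPACING = 3.0  # A; CA-CA self-avoidance on the mean structure


class GenerationError(ValueError):
    """Raised when a spec produces infeasible mean-structure geometry."""


# ---------------------------------------------------------------------------
# spec dataclasses


@dataclass(frozen=True)
class HelixBlock:
    """A rigid ideal alpha-helix segment.

    ``origin`` is the start of the helix axis, ``axis`` its direction,
    ``phase_deg`` the roll about the axis (used to aim residue side chains).
    """

    n_res: int
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    phase_deg: float = 0.0
    sigma_rigid: float = 0.35  # per-axis rigid-body translation noise, A
    sigma_jitter: float = 0.10  # per-axis per-residue jitter, A


@dataclass(frozen=True)
class LoopBlock:
    """A compact flexible blob of residues with block-correlated motion."""

    n_res: int
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sigma: float = 1.0  # per-axis correlated-displacement amplitude, A
    rho: float = 0.9  # intra-block displacement correlation
    sigma_jitter: float = 0.10


@dataclass(frozen=True)
class BridgePair:
    """An isolated low-variance communication bridge.

    Residue j's displacement copies residue i's plus 1-D noise of the
    prescribed variance along the separation vector; both residues
    additionally receive shared noise perpendicular to that vector
    (``flank_noise``), which decouples them from their own helices so the
    pair communicates efficiently only with itself.
    """

    i: int  # global residue index
    j: int
    variance: float = 0.05  # target CA-CA distance variance, A^2
    contact_dist: float = 4.0  # planted CB-CB distance, A
    flank_noise: float = 0.9  # per-axis perpendicular shared noise, A


@dataclass(frozen=True)
class UnitOverlap:
    residue: int  # helix residue that also rides the loop noise
    partner: int  # its low-variance pathway partner (same chain, |sep| in 2..3)
    loop_block: int  # index (in blocks) of the loop whose noise it shares
    amplitude: float = 1.0  # loop-noise amplitude multiplier


@dataclass(frozen=True)
class LigandSpec:
    n_res: int = 3
    follows_block: int = 0  # helix block whose rigid noise the ligand copies
    contact_residue: int = 3  # protein residue receiving the planted H-bond
    sigma_jitter: float = 0.05
    chain_id: str = "B"


@dataclass(frozen=True)
class PlantedContact:
    """A CB-CB contact present in a target fraction of frames."""

    i: int
    j: int
    occupancy: float = 1.0
    contact_dist: float = 4.0


@dataclass(frozen=True)
class Perturbation:
    """A synthetic 'mutation' applied on top of a wild-type spec."""

    kind: str  # "jitter_inflation" | "loop_sigma_scale"
    magnitude: float


@dataclass
class SyntheticSpec:
    blocks: tuple = ()
    bridges: tuple[BridgePair, ...] = ()
    overlap: UnitOverlap | None = None
    ligand: LigandSpec | None = None
    contacts: tuple[PlantedContact, ...] = ()
    n_frames: int = 500
    # residues whose independent jitter is inflated by a perturbation
    jitter_inflation_residues: tuple[int, ...] = ()
    jitter_inflation_sigma: float = 0.0
    loop_sigma_scale: float = 1.0

    def block_ranges(self) -> list[tuple[int, int]]:
        """[start, stop) global residue range of each block, chain A."""
        out, start = [], 0
        for b in self.blocks:
            out.append((start, start + b.n_res))
            start += b.n_res
        return out

    @property
    def n_protein_residues(self) -> int:
        return sum(b.n_res for b in self.blocks)


@dataclass
class GroundTruth:
    """What was planted, for verification against detected features."""

    block_ranges: list[tuple[int, int]]
    block_kinds: list[str]  # "helix" | "loop"
    bridges: list[BridgePair]
    overlap: UnitOverlap | None
    ligand_contact: int | None
    sigma_jitter: dict[int, float] = field(default_factory=dict)

    def expected_cp(self, i: int, j: int) -> float | None:
        """Closed-form CP for pairs the noise model pins down exactly."""
        for b in self.bridges:
            if {i, j} == {b.i, b.j}:
                return b.variance
        for (s, e), kind in zip(self.block_ranges, self.block_kinds):
            if kind == "helix" and s <= i < e and s <= j < e:
                return self.sigma_jitter.get(i, 0.1) ** 2 + \
                    self.sigma_jitter.get(j, 0.1) ** 2
        return None

    def helix_residues(self) -> list[set[int]]:
        return [
            set(range(s, e))
            for (s, e), k in zip(self.block_ranges, self.block_kinds)
            if k == "helix"
        ]

    def loop_residues(self) -> list[set[int]]:
        return [
            set(range(s, e))
            for (s, e), k in zip(self.block_ranges, self.block_kinds)
            if k == "loop"
        ]


# ---------------------------------------------------------------------------
# mean-structure construction

# Backbone internal coordinates of an ideal alpha helix (phi=-57, psi=-47).
_BOND_N_CA, _BOND_CA_C, _BOND_C_N, _BOND_C_O = 1.458, 1.525, 1.329, 1.231
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA = 111.2, 116.2, 121.7
_ANG_CA_C_O = 120.8
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0


def _nerf(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom d given three predecessors and internal coordinates."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _ideal_helix_backbone(n_res: int) -> list[dict[str, np.ndarray]]:
    """N/CA/C/O/CB coordinates of an ideal alpha helix, arbitrary frame."""
    # seed atoms for the NeRF chain
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = math.radians(_ANG_N_CA_C)
    C = CA + np.array(
        [-_BOND_CA_C * math.cos(ang), _BOND_CA_C * math.sin(ang), 0.0]
    )
    residues = [{"N": N, "CA": CA, "C": C}]
    for _ in range(1, n_res):
        prev = residues[-1]
        N = _nerf(prev["N"], prev["CA"], prev["C"], _BOND_C_N, _ANG_CA_C_N, _PSI)
        CA = _nerf(prev["CA"], prev["C"], N, _BOND_N_CA, _ANG_C_N_CA, _OMEGA)
        C = _nerf(prev["C"], N, CA, _BOND_CA_C, _ANG_N_CA_C, _PHI)
        residues.append({"N": N, "CA": CA, "C": C})
    # carbonyl O: in the peptide plane, trans to the next N (or to psi=-47
    # continuation for the last residue)
    for res in residues:
        res["O"] = _nerf(res["N"], res["CA"], res["C"], _BOND_C_O,
                         _ANG_CA_C_O, _PSI + 180.0)
        # CB: tetrahedral branch off CA
        res["CB"] = _nerf(res["N"], res["C"], res["CA"], 1.53, 110.5, -122.0)
    return residues


def _align_helix(residues, origin, axis, phase_deg):
    """Rigidly place a helix: CA principal axis -> ``axis`` from ``origin``."""
    ca = np.array([r["CA"] for r in residues])
    centroid = ca.mean(axis=0)
    # principal axis via SVD, oriented from first to last residue
    _, _, vt = np.linalg.svd(ca - centroid)
    a0 = vt[0]
    if np.dot(ca[-1] - ca[0], a0) < 0:
        a0 = -a0
    target = np.asarray(axis, dtype=float)
    target /= np.linalg.norm(target)
    R1 = _rotation_between(a0, target)
    phase = math.radians(phase_deg)
    R2 = _axis_rotation(target, phase)
    R = R2 @ R1
    start = centroid + a0 * np.dot(ca[0] - centroid, a0)
    out = []
    for r in residues:
        out.append({k: R @ (v - start) + np.asarray(origin, float)
                    for k, v in r.items()})
    return out


def _rotation_between(u, v):
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # pick any perpendicular axis
        p = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        ax = np.cross(u, p)
        return _axis_rotation(ax / np.linalg.norm(ax), math.pi)
    ax = np.cross(u, v)
    s = np.linalg.norm(ax)
    ax = ax / s
    return _axis_rotation(ax, math.atan2(s, c))


def _axis_rotation(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * K @ K


_LOOP_OFFSETS = {  # compact GLY-like template, parallel for all loop residues
    "N": np.array([-0.6, 0.0, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([0.6, 0.0, 0.0]),
    "O": np.array([0.6, 0.6, 0.0]),
}


def _loop_blob(n_res: int, center) -> list[dict[str, np.ndarray]]:
    """CA positions on a regular simplex/bipyramid: all residues proximal."""
    if n_res == 4:  # regular tetrahedron, edge 3.45 A
        e = 3.45
        r = e * math.sqrt(3.0 / 8.0)
        verts = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        verts *= r / np.linalg.norm(verts[0])
    else:  # points on a sphere, golden-angle spiral, radius for >=3.2 spacing
        r = 3.3 / (2 * math.sin(math.pi / max(n_res, 3)))
        golden = math.pi * (3 - math.sqrt(5))
        verts = []
        for k in range(n_res):
            z = 1 - 2 * (k + 0.5) / n_res
            rad = math.sqrt(max(0.0, 1 - z * z))
            verts.append([r * rad * math.cos(golden * k),
                          r * rad * math.sin(golden * k), r * z])
        verts = np.array(verts)
    out = []
    for v in verts:
        ca = np.asarray(center, float) + v
        out.append({k: ca + off for k, off in _LOOP_OFFSETS.items()})
    return out


def _build_mean_structure(spec: SyntheticSpec):
    """Mean coordinates + topology; returns (topology, coords, res_atoms)."""
    res_coords: list[dict[str, np.ndarray]] = []
    resnames: list[str] = []
    kinds: list[str] = []
    for b in spec.blocks:
        if isinstance(b, HelixBlock):
            placed = _align_helix(
                _ideal_helix_backbone(b.n_res), b.origin, b.axis, b.phase_deg
            )
            res_coords.extend(placed)
            resnames.extend(["ALA"] * b.n_res)
            kinds.extend(["helix"] * b.n_res)
        elif isinstance(b, LoopBlock):
            res_coords.extend(_loop_blob(b.n_res, b.center))
            resnames.extend(["GLY"] * b.n_res)
            kinds.extend(["loop"] * b.n_res)
        else:
            raise TypeError(f"unknown block type {type(b).__name__}")

    # planted CB-CB contacts: re-aim the CB atoms of the pair at each other
    for c in list(spec.bridges) + list(spec.contacts):
        for a, bb in ((c.i, c.j), (c.j, c.i)):
            ca_a = res_coords[a]["CA"]
            ca_b = res_coords[bb]["CA"]
            u = ca_b - ca_a
            d = np.linalg.norm(u)
            u /= d
            ext = (d - c.contact_dist) / 2.0
            res_coords[a]["CB"] = ca_a + ext * u
            if resnames[a] == "GLY":
                resnames[a] = "ALA"

    # overlap residue: plant a CB-CB contact with its designated partner
    if spec.overlap is not None:
        o = spec.overlap
        ca_a, ca_b = res_coords[o.residue]["CA"], res_coords[o.partner]["CA"]
        u = ca_b - ca_a
        d = np.linalg.norm(u)
        u /= d
        ext = max((d - 4.0) / 2.0, 0.8)
        res_coords[o.residue]["CB"] = ca_a + ext * u
        res_coords[o.partner]["CB"] = ca_b - ext * u

    residues = [Residue("A", i + 1, resnames[i]) for i in range(len(res_coords))]

    # ligand chain: placed so its first N H-bonds the contact residue's O,
    # extending radially away from the protein centroid
    lig_range = None
    if spec.ligand is not None:
        L = spec.ligand
        p = L.contact_residue
        o_p = res_coords[p]["O"]
        centroid = np.mean([rc["CA"] for rc in res_coords], axis=0)
        # outward = radial direction from the contact residue's helix axis
        # (falls back to the direction away from the protein centroid)
        outward = None
        start = 0
        for b in spec.blocks:
            if isinstance(b, HelixBlock) and start <= p < start + b.n_res:
                axis = np.asarray(b.axis, float)
                axis /= np.linalg.norm(axis)
                rel = res_coords[p]["CA"] - np.asarray(b.origin, float)
                outward = rel - np.dot(rel, axis) * axis
                break
            start += b.n_res
        if outward is None or np.linalg.norm(outward) < 1e-6:
            outward = res_coords[p]["CA"] - centroid
        outward = outward / np.linalg.norm(outward)
        # orient the residue template along the outward direction so no
        # ligand atom points back into the protein
        Rlig = _rotation_between(np.array([1.0, 0.0, 0.0]), outward)
        offsets = {kk: Rlig @ off for kk, off in _LOOP_OFFSETS.items()}
        n0 = o_p + 3.3 * outward
        base = n0 - offsets["N"]
        lig_start = len(res_coords)
        for k in range(L.n_res):
            ca = base + outward * (3.8 * k)
            res_coords.append({kk: ca + off for kk, off in offsets.items()})
            residues.append(Residue(L.chain_id, k + 1, "GLY"))
            kinds.append("ligand")
        lig_range = (lig_start, len(res_coords))

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    res_atom_slices: list[slice] = []
    for ridx, rc in enumerate(res_coords):
        start = len(atoms)
        order = ["N", "CA", "C", "O"] + (["CB"] if "CB" in rc else [])
        for name in order:
            el = name[0]
            atoms.append(Atom(name, el, ridx, name in {"N", "CA", "C", "O"}))
            coords.append(rc[name])
        res_atom_slices.append(slice(start, len(atoms)))

    lig_chain = (
        frozenset({spec.ligand.chain_id}) if spec.ligand is not None
        else frozenset()
    )
    topo = Topology(residues, atoms, lig_chain)
    coords = np.array(coords)
    _check_geometry(coords, topo)
    return topo, coords, kinds, lig_range


def _check_geometry(coords: np.ndarray, topo: Topology) -> None:
    from scipy.spatial import cKDTree

    res_of = topo.atom_residue_indices()
    tree = cKDTree(coords)
    for a, b in tree.query_pairs(CLASH_TOLERANCE):
        # covalently linked sequence neighbours are allowed to touch
        if abs(res_of[a] - res_of[b]) > 1:
            raise GenerationError(
                f"atoms of residues {res_of[a]} and {res_of[b]} clash "
                f"(< {CLASH_TOLERANCE} A) in the mean structure"
            )
    ca = topo.ca_indices()
    cac = coords[ca]
    t2 = cKDTree(cac)
    for a, b in t2.query_pairs(MIN_RESIDUE_SPACING):
        if abs(a - b) > 1:
            raise GenerationError(
                f"residues {a} and {b} closer than {MIN_RESIDUE_SPACING} A"
            )


# ---------------------------------------------------------------------------
# frame generation


def generate_ensemble(
    spec: SyntheticSpec, seed: int
) -> tuple[Ensemble, GroundTruth]:
    """Draw an ensemble of frames around the spec's mean structure."""
    topo, mean, kinds, lig_range = _build_mean_structure(spec)
    rng = np.random.default_rng(seed)
    F = spec.n_frames
    n_res = topo.n_residues
    ranges = spec.block_ranges()

    # per-frame, per-residue displacement (A)
    disp = np.zeros((F, n_res, 3))
    jitter_sigma: dict[int, float] = {}
    loop_shared: dict[int, np.ndarray] = {}  # block index -> (F, 3)
    block_translation: dict[int, np.ndarray] = {}

    for bi, (b, (s, e)) in enumerate(zip(spec.blocks, ranges)):
        if isinstance(b, HelixBlock):
            t = rng.normal(0.0, b.sigma_rigid, size=(F, 3))
            block_translation[bi] = t
            disp[:, s:e, :] += t[:, None, :]
            for r in range(s, e):
                jitter_sigma[r] = b.sigma_jitter
        else:  # LoopBlock
            sigma = b.sigma * spec.loop_sigma_scale
            shared = rng.normal(0.0, 1.0, size=(F, 3))
            loop_shared[bi] = shared * sigma
            indep = rng.normal(0.0, 1.0, size=(F, e - s, 3))
            disp[:, s:e, :] += sigma * (
                math.sqrt(b.rho) * shared[:, None, :]
                + math.sqrt(1.0 - b.rho) * indep
            )
            for r in range(s, e):
                jitter_sigma[r] = b.sigma_jitter

    # the ligand rides the rigid noise of the block it binds
    if spec.ligand is not None and lig_range is not None:
        t = block_translation.get(spec.ligand.follows_block)
        if t is not None:
            disp[:, lig_range[0]:lig_range[1], :] += t[:, None, :]
        for r in range(*lig_range):
            jitter_sigma[r] = spec.ligand.sigma_jitter

    # per-residue jitter (shared by all atoms of the residue)
    for r in range(n_res):
        sj = jitter_sigma.get(r, 0.1)
        if r in spec.jitter_inflation_residues:
            sj = math.hypot(sj, spec.jitter_inflation_sigma)
            jitter_sigma[r] = sj
        disp[:, r, :] += rng.normal(0.0, sj, size=(F, 3))

    # unit-overlap residue: add loop shared noise perpendicular to the
    # separation vector toward its pathway partner
    if spec.overlap is not None:
        o = spec.overlap
        shared = loop_shared[o.loop_block]  # (F, 3)
        ca = topo.ca_indices()
        sep = mean[ca[o.partner]] - mean[ca[o.residue]]
        sep /= np.linalg.norm(sep)
        proj = shared - np.outer(shared @ sep, sep)  # remove sep component
        disp[:, o.residue, :] += o.amplitude * proj

    # planted bridges: shared perpendicular noise decouples both residues
    # from their flanks; residue j then copies residue i's displacement
    # plus 1-D noise along the separation vector (prescribed variance)
    ca = topo.ca_indices()
    for br in spec.bridges:
        u = mean[ca[br.j]] - mean[ca[br.i]]
        u /= np.linalg.norm(u)
        perp = rng.normal(0.0, br.flank_noise, size=(F, 3))
        perp -= np.outer(perp @ u, u)
        disp[:, br.i, :] += perp
        eps = rng.normal(0.0, math.sqrt(br.variance), size=F)
        disp[:, br.j, :] = disp[:, br.i, :] + eps[:, None] * u
        jitter_sigma[br.j] = 0.0

    # planted fractional-occupancy contacts: break the contact in a random
    # (1 - occupancy) subset of frames by displacing residue j outward
    for c in spec.contacts:
        n_off = int(round((1.0 - c.occupancy) * F))
        if n_off > 0:
            off_frames = rng.choice(F, size=n_off, replace=False)
            u = mean[ca[c.j]] - mean[ca[c.i]]
            u /= np.linalg.norm(u)
            disp[off_frames, c.j, :] += 4.0 * u

    # assemble atom coordinates: every atom of a residue shares its shift
    res_of = topo.atom_residue_indices()
    coords = mean[None, :, :] + disp[:, res_of, :]

    truth = GroundTruth(
        block_ranges=ranges,
        block_kinds=[
            "helix" if isinstance(b, HelixBlock) else "loop"
            for b in spec.blocks
        ],
        bridges=list(spec.bridges),
        overlap=spec.overlap,
        ligand_contact=(
            spec.ligand.contact_residue if spec.ligand is not None else None
        ),
        sigma_jitter=jitter_sigma,
    )
    return Ensemble(topo, coords), truth


# ---------------------------------------------------------------------------
# reference architectures (the package's default study conditions)


def unit_recovery_spec(n_frames: int = 500) -> SyntheticSpec:
    """One rigid helix plus one flexible correlated loop.

    The helix should be recovered as a pathway-based unit, the loop as a
    clique-based unit.  Backbone i->i+4 hydrogen bonds alone link four
    interleaved residue strands; three planted side-chain contacts stitch
    the strands into one connected block, as side-chain packing does in
    real helices.
    """
    return SyntheticSpec(
        blocks=(
            HelixBlock(18, origin=(0, 0, 0), axis=(0, 0, 1)),
            LoopBlock(4, center=(8.0, 0.0, 30.0)),
        ),
        contacts=(
            PlantedContact(2, 5),
            PlantedContact(8, 11),
            PlantedContact(13, 16),
        ),
        n_frames=n_frames,
    )


def bridge_spec(n_frames: int = 500) -> SyntheticSpec:
    """Two packed helices joined by one planted communication bridge.

    The helices are far enough apart that the only cross-helix contact is
    the bridge pair; a flexible loop connects them at the top, one helix
    residue doubles as a unit-overlap bridge, and a short peptide ligand
    rides the first helix with a single planted H-bond contact.
    """
    # chain A: H1 = 0..15, loop = 16..19, H2 = 20..35
    return SyntheticSpec(
        blocks=(
            HelixBlock(16, origin=(0, 0, 0), axis=(0, 0, 1),
                       sigma_rigid=0.55),
            LoopBlock(4, center=(15.0, 3.6, 21.8), rho=0.9),
            HelixBlock(16, origin=(13.0, 0.0, 22.5), axis=(0, 0, -1),
                       sigma_rigid=0.55),
        ),
        bridges=(BridgePair(7, 29, variance=0.05),),
        overlap=UnitOverlap(residue=22, partner=25, loop_block=1),
        ligand=LigandSpec(n_res=3, follows_block=0, contact_residue=3),
        contacts=(
            # intra-helix strand connectors (side-chain packing); the
            # overlap pair (22, 25) doubles as the remaining H2 connector
            PlantedContact(2, 5),
            PlantedContact(8, 11),
            PlantedContact(9, 12),
            PlantedContact(24, 27),
            PlantedContact(31, 34),
        ),
        n_frames=n_frames,
    )


def mutant_family_spec(n_frames: int = 500) -> SyntheticSpec:
    """Two closely packed helices with a junction loop (mutable system).

    The helix interface carries hydrophobic contacts whose communication is
    just below threshold in the wild type; perturbations that degrade local
    backbone communication push the threshold over them and pathway counts
    explode.
    """
    return SyntheticSpec(
        blocks=(
            HelixBlock(16, origin=(0, 0, 0), axis=(0, 0, 1),
                       sigma_rigid=0.55),
            LoopBlock(4, center=(6.0, 0.0, 28.5)),
            HelixBlock(16, origin=(12.5, 0.0, 22.5), axis=(0, 0, -1),
                       sigma_rigid=0.55),
        ),
        contacts=(
            # intra-helix strand connectors
            PlantedContact(2, 5),
            PlantedContact(8, 11),
            PlantedContact(9, 12),
            PlantedContact(22, 25),
            PlantedContact(24, 27),
            PlantedContact(31, 34),
            # helix-interface packing contacts: efficient only once local
            # backbone communication degrades (deleterious mutants);
            # residues distinct from the connector pairs (one CB each)
            PlantedContact(0, 35),
            PlantedContact(4, 31),
            PlantedContact(7, 28),
            PlantedContact(13, 23),
        ),
        n_frames=n_frames,
    )


_JUNCTION_HELIX_RESIDUES = (14, 15, 20, 21)  # helix ends flanking the loop


def generate_mutant_family(
    wt_spec: SyntheticSpec,
    n_deleterious: int = 10,
    n_neutral: int = 10,
    seed: int = 0,
    n_frames: int | None = None,
):
    """Wild type plus labelled synthetic mutants.

    Deleterious mutants inflate the independent jitter of the loop and the
    helix residues flanking it (degrading local backbone communication and
    raising MCP, hence CP_cut, hence pathway counts); neutral mutants only
    rescale the correlated loop amplitude.  Returns
    ``(wt_ensemble, [(mutation_id, label, ensemble), ...])``.
    """
    from .mutscan import HIGHLY_DELETERIOUS, NEUTRAL

    rng = np.random.default_rng(seed)
    if n_frames is not None:
        wt_spec = replace(wt_spec, n_frames=n_frames)
    loop_res: tuple[int, ...] = ()
    for (s, e), b in zip(wt_spec.block_ranges(), wt_spec.blocks):
        if isinstance(b, LoopBlock):
            loop_res = tuple(range(s, e))
            break
    targets = tuple(sorted(set(loop_res) | set(_JUNCTION_HELIX_RESIDUES)))

    wt_ens, _ = generate_ensemble(wt_spec, seed=int(rng.integers(2**31)))
    out = []
    for k in range(n_deleterious):
        sigma = 0.6 + 0.4 * (k / max(n_deleterious - 1, 1))
        spec = replace(
            wt_spec,
            jitter_inflation_residues=targets,
            jitter_inflation_sigma=sigma,
        )
        ens, _ = generate_ensemble(spec, seed=int(rng.integers(2**31)))
        out.append((f"DEL{k:02d}", HIGHLY_DELETERIOUS, ens))
    for k in range(n_neutral):
        scale = 0.85 + 0.3 * (k / max(n_neutral - 1, 1))
        spec = replace(wt_spec, loop_sigma_scale=scale)
        ens, _ = generate_ensemble(spec, seed=int(rng.integers(2**31)))
        out.append((f"NEU{k:02d}", NEUTRAL, ens))
    return wt_ens, out
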