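"""Per-frame non-covalent interactions reduced to stable interactions.

Two interaction classes are detected: hydrogen bonds (donor/acceptor N,O
heavy atoms within 3.5 A, with a D-H...A angle of at least 120 degrees when
the donor hydrogen is present, distance-only otherwise) and hydrophobic
contacts (apolar carbon pairs within 4.5 A).  A pair of residues interacts
in a frame when any qualifying atom pair does; its occupancy is the
fraction of analysis frames with an interaction, and pairs below the
stability threshold ``s_min`` are dropped.  Covalent sequence neighbours
(|i - j| <= 1 on one chain) are always excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import Ensemble

__all__ = [
    "InteractionRecord",
    "InteractionSet",
    "detect_frame_interactions",
    "stable_interactions",
    "APOLAR_CARBONS",
]

# Carbons bonded to no N/O/S, per standard amino-acid connectivity.
APOLAR_CARBONS: dict[str, frozenset[str]] = {
    "ALA": frozenset({"CB"}),
    "ARG": frozenset({"CB", "CG"}),
    "ASN": frozenset({"CB"}),
    "ASP": frozenset({"CB"}),
    "CYS": frozenset(),
    "GLN": frozenset({"CB", "CG"}),
    "GLU": frozenset({"CB", "CG"}),
    "GLY": frozenset(),
    "HIS": frozenset({"CB"}),
    "ILE": frozenset({"CB", "CG1", "CG2", "CD1"}),
    "LEU": frozenset({"CB", "CG", "CD1", "CD2"}),
    "LYS": frozenset({"CB", "CG", "CD"}),
    "MET": frozenset({"CB"}),
    "PHE": frozenset({"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "PRO": frozenset({"CB", "CG"}),
    "SER": frozenset(),
    "THR": frozenset({"CG2"}),
    "TRP": frozenset({"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"}),
    "TYR": frozenset({"CB", "CG", "CD1", "CD2", "CE1", "CE2"}),
    "VAL": frozenset({"CB", "CG1", "CG2"}),
}


@dataclass(frozen=True)
class InteractionRecord:
    pair: tuple[int, int]  # residue indices, a < b
    kind: str  # "hbond" | "hydrophobic" | "hbond+hydrophobic"
    occupancy: float

    def __post_init__(self) -> None:
        a, b = self.pair
        if a == b:
            raise ValueError("an interaction needs two distinct residues")
        if not 0 < self.occupancy <= 1:
            raise ValueError("occupancy must lie in (0, 1]")


@dataclass
class InteractionSet:
    records: list[InteractionRecord]
    s_min: float
    n_frames: int = 0
    _pairs: frozenset[tuple[int, int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for r in self.records:
            if r.occupancy < self.s_min - 1e-12:
                raise ValueError("record below the stability threshold")
        self._pairs = frozenset(r.pair for r in self.records)

    @property
    def pairs(self) -> frozenset[tuple[int, int]]:
        return self._pairs

    def __contains__(self, pair: tuple[int, int]) -> bool:
        a, b = pair
        return (min(a, b), max(a, b)) in self._pairs

    def __len__(self) -> int:
        return len(self.records)


def _atom_classes(e: Ensemble):
    """Per-atom flags: polar N/O heavy atoms, apolar carbons, hydrogens."""
    topo = e.topology
    n = topo.n_atoms
    polar = np.zeros(n, dtype=bool)
    is_oxygen = np.zeros(n, dtype=bool)
    apolar = np.zeros(n, dtype=bool)
    hydro = np.zeros(n, dtype=bool)
    for i, a in enumerate(topo.atoms):
        el = a.element.upper()
        if el == "H":
            hydro[i] = True
        elif el in ("N", "O"):
            polar[i] = True
            is_oxygen[i] = el == "O"
        elif el == "C":
            allowed = APOLAR_CARBONS.get(topo.residues[a.residue_index].resname)
            if allowed is None:
                # unknown residue type: treat side-chain carbons as apolar
                apolar[i] = a.name not in ("C", "CA")
            else:
                apolar[i] = a.name in allowed
    return polar, is_oxygen, apolar, hydro


def _candidate_atom_pairs(e: Ensemble, mask_a, mask_b, cutoff, same_ok=False):
    """Atom-index pairs that could come within ``cutoff`` in any frame.

    Candidates are taken from the mean structure with a slack equal to the
    two largest per-atom displacements from the mean, which makes the
    prefilter exact: no qualifying frame pair is missed.
    """
    from scipy.spatial import cKDTree

    mean = e.coords.mean(axis=0)
    disp = np.sqrt(((e.coords - mean) ** 2).sum(axis=2)).max(axis=0)
    top2 = np.sort(disp)[-2:].sum() if disp.size >= 2 else 2 * disp.max()
    ia = np.nonzero(mask_a)[0]
    ib = np.nonzero(mask_b)[0]
    if ia.size == 0 or ib.size == 0:
        return np.empty((0, 2), dtype=int)
    ta = cKDTree(mean[ia])
    tb = cKDTree(mean[ib])
    hits = ta.query_ball_tree(tb, cutoff + top2)
    out = []
    for k, lst in enumerate(hits):
        a = ia[k]
        for m in lst:
            b = ib[m]
            if a < b or (same_ok and a != b):
                out.append((a, b))
    if not out:
        return np.empty((0, 2), dtype=int)
    arr = np.array(sorted(set((min(a, b), max(a, b)) for a, b in out)), dtype=int)
    return arr


def _residue_pair_key(topo, a_atom: int, b_atom: int):
    ra = topo.atoms[a_atom].residue_index
    rb = topo.atoms[b_atom].residue_index
    if ra == rb:
        return None
    i, j = (ra, rb) if ra < rb else (rb, ra)
    # covalent sequence neighbours (resid difference <= 1, one chain) excluded
    sep = topo.sequence_separation(i, j)
    if sep is not None and sep <= 1:
        return None
    return i, j


def _donor_hydrogens(e: Ensemble, polar: np.ndarray, hydro: np.ndarray):
    """Map donor heavy atom -> attached hydrogen indices (frame-0 geometry)."""
    out: dict[int, list[int]] = {}
    h_idx = np.nonzero(hydro)[0]
    if h_idx.size == 0:
        return out
    heavy = np.nonzero(polar)[0]
    c0 = e.coords[0]
    for h in h_idx:
        d = np.sqrt(((c0[heavy] - c0[h]) ** 2).sum(axis=1))
        k = int(np.argmin(d))
        if d[k] < 1.25:
            out.setdefault(int(heavy[k]), []).append(int(h))
    return out


def _virtual_amide_geometry(e: Ensemble, donors_h) -> dict[int, tuple[int, int]]:
    """Backbone amide N -> (previous C index, own CA index).

    Used to place a virtual amide hydrogen (opposite the bisector of the
    C(prev)-N and CA-N bonds) when the structure carries no hydrogens, so
    the donor-angle criterion can still be applied.  First-in-chain and
    proline nitrogens are skipped.
    """
    topo = e.topology
    out: dict[int, tuple[int, int]] = {}
    n_of_res: dict[int, int] = {}
    ca_of_res: dict[int, int] = {}
    c_of_res: dict[int, int] = {}
    for i, a in enumerate(topo.atoms):
        if a.name == "N":
            n_of_res.setdefault(a.residue_index, i)
        elif a.name == "CA":
            ca_of_res.setdefault(a.residue_index, i)
        elif a.name == "C":
            c_of_res.setdefault(a.residue_index, i)
    for r, n_idx in n_of_res.items():
        if n_idx in donors_h:
            continue  # real hydrogens present
        if topo.residues[r].resname == "PRO":
            continue
        prev = r - 1
        if (
            prev < 0
            or topo.residues[prev].chain_id != topo.residues[r].chain_id
            or topo.residues[r].resid - topo.residues[prev].resid != 1
            or prev not in c_of_res
            or r not in ca_of_res
        ):
            continue
        out[n_idx] = (c_of_res[prev], ca_of_res[r])
    return out


def _virtual_h_coords(e: Ensemble, n_idx: int, c_prev: int, ca: int) -> np.ndarray:
    """Per-frame virtual amide hydrogen position for one backbone N."""
    n = e.coords[:, n_idx, :]
    u = n - e.coords[:, c_prev, :]
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = n - e.coords[:, ca, :]
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    w = u + v
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    return n + 0.98 * w


def _frame_masks(
    e: Ensemble,
    hbond_dist: float,
    hbond_angle_deg: float,
    hydrophobic_dist: float,
):
    """Per-frame boolean presence for every candidate residue pair.

    Returns (pair_list, presence (F, n_pairs), kinds per pair).
    """
    topo = e.topology
    polar, is_ox, apolar, hydro = _atom_classes(e)

    hb_atoms = _candidate_atom_pairs(e, polar, polar, hbond_dist)
    ph_atoms = _candidate_atom_pairs(e, apolar, apolar, hydrophobic_dist)
    donors_h = _donor_hydrogens(e, polar, hydro)
    virtual_n = _virtual_amide_geometry(e, donors_h)
    vh_cache: dict[int, np.ndarray] = {}

    F = e.n_frames
    pair_index: dict[tuple[int, int], int] = {}
    presence_h: list[np.ndarray] = []
    presence_p: list[np.ndarray] = []

    def slot(key):
        if key not in pair_index:
            pair_index[key] = len(pair_index)
            presence_h.append(np.zeros(F, dtype=bool))
            presence_p.append(np.zeros(F, dtype=bool))
        return pair_index[key]

    cos_cut = np.cos(np.deg2rad(hbond_angle_deg))

    for a, b in hb_atoms:
        if not (is_ox[a] or is_ox[b]):
            continue  # require at least one oxygen in a distance-only pair
        key = _residue_pair_key(topo, a, b)
        if key is None:
            continue
        va = e.coords[:, a, :]
        vb = e.coords[:, b, :]
        d = np.sqrt(((va - vb) ** 2).sum(axis=1))
        ok = d <= hbond_dist
        # angular criterion for donors with real or virtual hydrogens;
        # a pair qualifies when EITHER direction passes as donor->acceptor
        any_donor = False
        dir_ok = np.zeros(F, dtype=bool)
        for donor, acc in ((a, b), (b, a)):
            h_coords: list[np.ndarray] = []
            for h in donors_h.get(donor, ()):  # real hydrogens
                h_coords.append(e.coords[:, h, :])
            if donor in virtual_n:
                if donor not in vh_cache:
                    vh_cache[donor] = _virtual_h_coords(
                        e, donor, *virtual_n[donor]
                    )
                h_coords.append(vh_cache[donor])
            if not h_coords:
                continue
            any_donor = True
            vd = e.coords[:, donor, :]
            vc = e.coords[:, acc, :]
            for vh in h_coords:
                u = vd - vh
                w = vc - vh
                cosang = (u * w).sum(axis=1) / (
                    np.linalg.norm(u, axis=1) * np.linalg.norm(w, axis=1)
                )
                # angle >= 120 deg  <=>  cos(angle) <= cos(120 deg)
                dir_ok |= cosang <= cos_cut
        if any_donor:
            ok = ok & dir_ok
        if ok.any():
            presence_h[slot(key)] |= ok

    for a, b in ph_atoms:
        key = _residue_pair_key(topo, a, b)
        if key is None:
            continue
        d = np.sqrt(((e.coords[:, a, :] - e.coords[:, b, :]) ** 2).sum(axis=1))
        ok = d <= hydrophobic_dist
        if ok.any():
            presence_p[slot(key)] |= ok

    pairs = [None] * len(pair_index)
    for key, k in pair_index.items():
        pairs[k] = key
    return pairs, presence_h, presence_p


def detect_frame_interactions(
    e: Ensemble,
    frame: int,
    hbond_dist: float = 3.5,
    hbond_angle_deg: float = 120.0,
    hydrophobic_dist: float = 4.5,
) -> set[tuple[tuple[int, int], str]]:
    """Residue-pair interactions present in one frame."""
    if not 0 <= frame < e.n_frames:
        raise IndexError("frame out of range")
    pairs, ph, pp = _frame_masks(e, hbond_dist, hbond_angle_deg, hydrophobic_dist)
    out = set()
    for key, mh, mp in zip(pairs, ph, pp):
        if mh[frame]:
            out.add((key, "hbond"))
        if mp[frame]:
            out.add((key, "hydrophobic"))
    return out


def stable_interactions(
    e: Ensemble,
    s_min: float = 0.5,
    hbond_dist: float = 3.5,
    hbond_angle_deg: float = 120.0,
    hydrophobic_dist: float = 4.5,
) -> InteractionSet:
    """Interactions present in at least a fraction ``s_min`` of frames.

    Occupancy pools both interaction kinds per residue pair: a pair counts
    as interacting in a frame when any hydrogen bond or hydrophobic contact
    between its atoms is present.
    """
    if not 0 < s_min <= 1:
        raise ValueError("s_min must lie in (0, 1]")
    pairs, ph, pp = _frame_masks(e, hbond_dist, hbond_angle_deg, hydrophobic_dist)
    records = []
    for key, mh, mp in zip(pairs, ph, pp):
        occ = float((mh | mp).mean())
        if occ < s_min:
            continue
        kinds = []
        if mh.any():
            kinds.append("hbond")
        if mp.any():
            kinds.append("hydrophobic")
        records.append(InteractionRecord(key, "+".join(kinds), occ))
    records.sort(key=lambda r: r.pair)
    return InteractionSet(records, s_min, n_frames=e.n_frames)
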