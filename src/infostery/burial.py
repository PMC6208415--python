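"""Circular-variance (CV) burial of residues.

The CV of an atom is one minus the norm of the mean unit vector toward all
neighbouring atoms within a cutoff radius r_c: an atom surrounded
isotropically by protein has CV near 1 (buried), an atom with all its
neighbours on one side has CV near 0 (protruding).  Residue CV averages
the atomic values; per protein, values are min-max rescaled to [0, 1] and
residues at or above ``cv_cut`` (default 0.6) are called buried.  CV is
evaluated on the ensemble-mean structure: it is used as a static filter.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .ensemble import Topology

__all__ = ["CVProfile", "atom_cv", "residue_cv", "buried_residues"]


@dataclass
class CVProfile:
    raw_cv: np.ndarray  # per residue, in [0, 1]
    scaled_cv: np.ndarray  # min-max rescaled per protein
    r_c: float
    cv_cut: float

    def __post_init__(self) -> None:
        for v in (self.raw_cv, self.scaled_cv):
            if np.any(v < -1e-9) or np.any(v > 1 + 1e-9):
                raise ValueError("CV values must lie in [0, 1]")


def atom_cv(coords: np.ndarray, i: int, r_c: float = 20.0) -> float:
    """Circular variance of atom i among all atoms within r_c.

    Undefined (ValueError) when the atom has no neighbour inside r_c.
    """
    coords = np.asarray(coords, dtype=float)
    diff = coords - coords[i]
    dist = np.linalg.norm(diff, axis=1)
    mask = (dist > 0) & (dist <= r_c)
    mask[i] = False
    n_i = int(mask.sum())
    if n_i == 0:
        raise ValueError(f"atom {i} has no neighbour within {r_c} A")
    unit = diff[mask] / dist[mask, None]
    return float(1.0 - np.linalg.norm(unit.sum(axis=0)) / n_i)


def _all_atom_cv(coords: np.ndarray, r_c: float) -> np.ndarray:
    """Vectorised atomic CV for every atom (KD-tree neighbour search)."""
    from scipy.spatial import cKDTree

    coords = np.asarray(coords, dtype=float)
    tree = cKDTree(coords)
    neigh = tree.query_ball_tree(tree, r_c)
    out = np.zeros(len(coords))
    for i, lst in enumerate(neigh):
        js = [j for j in lst if j != i]
        if not js:
            out[i] = np.nan
            continue
        diff = coords[js] - coords[i]
        dist = np.linalg.norm(diff, axis=1)
        keep = dist > 0
        if not keep.any():
            out[i] = np.nan
            continue
        unit = diff[keep] / dist[keep, None]
        out[i] = 1.0 - np.linalg.norm(unit.sum(axis=0)) / keep.sum()
    return out


def residue_cv(
    mean_coords: np.ndarray,
    topology: Topology,
    r_c: float = 20.0,
    cv_cut: float = 0.6,
) -> CVProfile:
    """Per-residue CV on a (mean) structure, min-max rescaled.

    All heavy atoms, ligand included, act as neighbours (the ligand occludes
    the protein residues it faces).  An atom with no neighbour within r_c is
    treated as maximally protruding (CV 0) with a warning.
    """
    heavy = np.array(
        [a.element.upper() != "H" for a in topology.atoms], dtype=bool
    )
    coords = np.asarray(mean_coords, dtype=float)[heavy]
    acv = _all_atom_cv(coords, r_c)
    if np.isnan(acv).any():
        warnings.warn(
            "atom(s) with no neighbour within r_c treated as protruding",
            stacklevel=2,
        )
        acv = np.nan_to_num(acv, nan=0.0)
    res_of = topology.atom_residue_indices()[heavy]
    n = topology.n_residues
    raw = np.zeros(n)
    for r in range(n):
        sel = res_of == r
        raw[r] = acv[sel].mean() if sel.any() else 0.0
    lo, hi = raw.min(), raw.max()
    if n < 2 or hi - lo <= 0:
        raise ValueError("CV scaling needs >= 2 residues with distinct values")
    scaled = (raw - lo) / (hi - lo)
    return CVProfile(raw_cv=raw, scaled_cv=scaled, r_c=r_c, cv_cut=cv_cut)


def buried_residues(profile: CVProfile, use_raw: bool = False) -> set[int]:
    """Residues with CV at or above the burial threshold (inclusive)."""
    vals = profile.raw_cv if use_raw else profile.scaled_cv
    return set(np.nonzero(vals >= profile.cv_cut)[0].tolist())
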