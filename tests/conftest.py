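"""Shared fixtures: tiny hand-built ensembles and topology helpers."""

from __future__ import annotations

import numpy as np
import pytest

from infostery.ensemble import Atom, Ensemble, Residue, Topology


def make_topology(n_res: int, chain: str = "A", resname: str = "ALA",
                  atom_names=("CA",), ligand_chains=()) -> Topology:
    residues = [Residue(chain, i + 1, resname) for i in range(n_res)]
    atoms = []
    for r in range(n_res):
        for name in atom_names:
            atoms.append(
                Atom(name, name[0], r, name in {"N", "CA", "C", "O"})
            )
    return Topology(residues, atoms, frozenset(ligand_chains))


def ca_ensemble(ca_coords: np.ndarray, **kw) -> Ensemble:
    """Ensemble with one CA atom per residue from (frames, residues, 3)."""
    ca_coords = np.asarray(ca_coords, dtype=float)
    topo = make_topology(ca_coords.shape[1], **kw)
    return Ensemble(topo, ca_coords)


@pytest.fixture
def line_ensemble() -> Ensemble:
    """Three CA-only residues on a line, two identical frames."""
    frame = np.array([[0.0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]])
    return ca_ensemble(np.stack([frame, frame]))


@pytest.fixture(scope="session")
def helix_ensemble():
    """Small rigid-helix + flexible-loop synthetic ensemble (one seed)."""
    from infostery.synthetic import generate_ensemble, unit_recovery_spec

    return generate_ensemble(unit_recovery_spec(n_frames=300), seed=11)


@pytest.fixture(scope="session")
def bridge_analysis():
    """Full analysis of the bridge-showcase architecture (one seed)."""
    from infostery.pipeline import EnsembleAnalysis
    from infostery.synthetic import bridge_spec, generate_ensemble

    ens, truth = generate_ensemble(bridge_spec(n_frames=400), seed=5)
    return EnsembleAnalysis(ens), truth
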