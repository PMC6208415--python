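"""Tabular and molecular-viewer output writers for analysis results."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pathways import BLACK, GREY

__all__ = ["write_analysis_outputs", "write_pymol_script"]


def _res_frame(topo) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chain": [r.chain_id for r in topo.residues],
            "resid": [r.resid for r in topo.residues],
        }
    )


def write_analysis_outputs(analysis, outdir) -> Path:
    """Write the standard per-stage TSV tables and a JSON summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    topo = analysis.ensemble.topology
    base = _res_frame(topo)

    rmsd, rmsf = analysis.rmsd, analysis.rmsf
    pd.DataFrame({"frame": np.arange(len(rmsd)), "rmsd_A": rmsd}).to_csv(
        out / "rmsd.tsv", sep="\t", index=False
    )
    base.assign(rmsf_A=rmsf).to_csv(out / "rmsf.tsv", sep="\t", index=False)
    base.assign(persistence=analysis.ss.persistence).to_csv(
        out / "ss_persistence.tsv", sep="\t", index=False
    )

    ia = analysis.interactions
    pd.DataFrame(
        {
            "chain_a": [topo.residues[r.pair[0]].chain_id for r in ia.records],
            "resid_a": [topo.residues[r.pair[0]].resid for r in ia.records],
            "chain_b": [topo.residues[r.pair[1]].chain_id for r in ia.records],
            "resid_b": [topo.residues[r.pair[1]].resid for r in ia.records],
            "kind": [r.kind for r in ia.records],
            "occupancy": [r.occupancy for r in ia.records],
        }
    ).to_csv(out / "interactions.tsv", sep="\t", index=False)

    cp = analysis.cp
    iu, ju = np.triu_indices(cp.cp.shape[0], k=1)
    pd.DataFrame({"i": iu, "j": ju, "cp_A2": cp.cp[iu, ju]}).to_csv(
        out / "cp_matrix.tsv", sep="\t", index=False
    )
    base.assign(mcp_A2=cp.mcp).to_csv(out / "mcp.tsv", sep="\t", index=False)
    (out / "communication.json").write_text(
        json.dumps(
            {"p_ss": cp.p_ss, "cp_cut": cp.cp_cut, "quantile_q": cp.quantile_q},
            indent=2,
        )
    )

    ps = analysis.pathways_at()
    with open(out / "pathways.tsv", "w") as fh:
        for p in ps.pathways:
            fh.write("-".join(topo.label(r) for r in p.residues) + "\n")
    base.assign(traversal=ps.traversal).to_csv(
        out / "traversal.tsv", sep="\t", index=False
    )

    dp = analysis.dotplot_at()
    rows = []
    for (i, j), c in sorted(dp.dots.items()):
        cls = "grey" if c == GREY else ("black" if c == BLACK else "colored")
        rows.append((i, j, cls, c if c >= 0 else ""))
    pd.DataFrame(rows, columns=["i", "j", "class", "unit_id"]).to_csv(
        out / "dotplot.tsv", sep="\t", index=False
    )

    units = analysis.units_at()
    urows = []
    for u in units.pathway_units + units.clique_units:
        for r in sorted(u.members):
            urows.append(
                (topo.residues[r].chain_id, topo.residues[r].resid, u.kind, u.id)
            )
    pd.DataFrame(urows, columns=["chain", "resid", "kind", "unit_id"]).to_csv(
        out / "units.tsv", sep="\t", index=False
    )

    pt = analysis.persistency()
    base.assign(
        pathway_score=pt.pathway_score, clique_score=pt.clique_score
    ).to_csv(out / "persistency.tsv", sep="\t", index=False)

    cv = analysis.cv_profile
    buried = analysis.buried
    base.assign(
        raw_cv=cv.raw_cv,
        scaled_cv=cv.scaled_cv,
        buried=[i in buried for i in range(topo.n_residues)],
    ).to_csv(out / "burial.tsv", sep="\t", index=False)

    write_pymol_script(analysis, out / "pathways_view.pml")
    return out


def write_prediction_outputs(analysis, prediction, outdir) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    topo = analysis.ensemble.topology
    cv = analysis.cv_profile
    buried = analysis.buried
    rows = []
    for r in sorted(prediction.residues):
        rows.append(
            (
                topo.residues[r].chain_id,
                topo.residues[r].resid,
                "+".join(sorted(prediction.strategies[r])),
                r in buried,
                round(float(cv.scaled_cv[r]), 4),
            )
        )
    pd.DataFrame(
        rows, columns=["chain", "resid", "strategies", "buried", "scaled_cv"]
    ).to_csv(out / "sensitive_positions.tsv", sep="\t", index=False)
    with open(out / "isolated_pairs.tsv", "w") as fh:
        for i, j in sorted(prediction.isolated_pairs):
            fh.write(f"{topo.label(i)}\t{topo.label(j)}\n")
    return out


def write_pymol_script(analysis, path) -> None:
    """Molecular-viewer script: pathway segments with thickness proportional
    to the per-pair pathway count, spheres sized by traversal count."""
    ps = analysis.pathways_at()
    topo = analysis.ensemble.topology
    pair_count: dict[tuple[int, int], int] = {}
    for p in ps.pathways:
        for a, b in zip(p.residues, p.residues[1:]):
            key = (min(a, b), max(a, b))
            pair_count[key] = pair_count.get(key, 0) + 1
    max_pair = max(pair_count.values(), default=1)
    max_trav = max(int(ps.traversal.max()), 1)
    lines = ["hide everything", "show cartoon", "color grey80"]
    for (i, j), c in sorted(pair_count.items()):
        ri, rj = topo.residues[i], topo.residues[j]
        name = f"path_{i}_{j}"
        lines.append(
            f"distance {name}, chain {ri.chain_id} and resi {ri.resid} and "
            f"name CA, chain {rj.chain_id} and resi {rj.resid} and name CA"
        )
        lines.append(f"set dash_width, {1 + 5 * c / max_pair:.2f}, {name}")
        lines.append(f"hide labels, {name}")
    for r in np.nonzero(ps.traversal)[0]:
        res = topo.residues[int(r)]
        scale = 0.2 + 0.8 * ps.traversal[r] / max_trav
        lines.append(
            f"show spheres, chain {res.chain_id} and resi {res.resid} "
            f"and name CA"
        )
        lines.append(
            f"set sphere_scale, {scale:.2f}, chain {res.chain_id} and "
            f"resi {res.resid} and name CA"
        )
    Path(path).write_text("\n".join(lines) + "\n")
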