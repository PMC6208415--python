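# infostery

Communication-network ("infostery") analysis of protein conformational
ensembles: extract **communication pathways**, **dynamical units**,
**communication bridges** and **burial scores** from molecular-dynamics
trajectories or multi-model PDB files, then

1. **predict positions highly sensitive to mutations** from a single
   wild-type ensemble, and
2. **classify mutant ensembles** as highly deleterious vs neutral from
   their pathway concentration.

It is aimed at structural bioinformaticians who have short MD simulations
(tens of nanoseconds) of a protein or protein–ligand complex and want an
automated, interpretable readout of which residues carry the structure's
internal communication.

## The model

Communication between residues *i* and *j* is quantified by the
**communication propensity**, the variance of their Cα–Cα distance over the
ensemble:

```
CP(i,j) = ⟨(d_ij − d̄_ij)²⟩        [Å²]
```

Residues that move together (low CP) communicate efficiently. The
threshold CP_cut is calibrated against local backbone communication: for
each residue the **MCP** averages CP over sequence neighbours within ±4
(divided by a literal 8), and CP_cut is the *p*<sub>ss</sub>-quantile of
the MCP distribution, where *p*<sub>ss</sub> is the fraction of residues
holding stable secondary structure (DSSP H/E/T in more than half of the
frames).

A **communication pathway** is a chain of residues in which consecutive
members are sequence-non-adjacent and linked by stable non-covalent
interactions (hydrogen bonds ≤ 3.5 Å with a ≥ 120° donor angle, or apolar
carbon contacts ≤ 4.5 Å, present in ≥ 50% of frames), and *every* pair of
members satisfies CP ≤ CP_cut. Pathway-adjacent pairs are in *direct*
communication, co-members in *indirect* communication. Two kinds of
**dynamical units** emerge: pathway-based units (connected components of
pathway adjacency — rigid, co-moving regions) and clique-based units
(cliques of proximal residues, min inter-atomic distance < 3.7 Å, with
concerted high fluctuations — flexible regions).

**Communication bridges** — the predicted mutation-sensitive positions —
are (1) residues persistently found in both unit kinds, (2) residues in
direct communication with the ligand, and (3) residue pairs forming
*isolated direct communications*: isolated black dots on the
direct/indirect dot plot across a CP_cut sweep, i.e. pairs that
communicate far better than their local context. Burial is measured by
circular variance (CV, r_c = 20 Å; residues with scaled CV ≥ 0.6 are
buried) and filters strategies 1 and 3.

For mutant classification, a mutant is called **highly deleterious** when
its number of highly connected residues (crossed by > k pathways) exceeds
1.2× the wild-type value; group differences are assessed by inverse-CDF
curves and a label-permutation test on the largest curve difference.

## Worked example

Generate a synthetic two-helix complex with a planted communication bridge,
a ligand contact and a flexible loop, then predict its sensitive positions:

```bash
infostery synth --arch bridge --frames 300 --seed 7 --out wt.pdb
infostery predict-sensitive --traj wt.pdb --ligand-chain B \
    --discard-leading 0 --out run/
```

Output:

```
A:4     ligand_direct
A:8     isolated_direct
A:23    unit_overlap
A:30    isolated_direct
```

and `run/sensitive_positions.tsv`:

```
chain  resid  strategies       buried  scaled_cv
A      4      ligand_direct    False   0.5268
A      8      isolated_direct  True    0.9031
A      23     unit_overlap     True    0.6801
A      30     isolated_direct  True    0.8722
```

These are exactly the planted bridges: residue A:4 hydrogen-bonds the
ligand and rides its motion (direct communication with the ligand); A:8 and
A:30 are the isolated low-variance pair joining the two helices (scaled CV
≈ 0.9: deeply buried); A:23 belongs to both a pathway-based and a
clique-based unit. `run/` also contains the CP matrix, MCP values, pathway
list, dot plot, unit decomposition, persistency scores, burial table and a
PyMOL script (`pathways_view.pml`) drawing pathways with thickness
proportional to pathway count.

Library use mirrors the CLI:

```python
from infostery import EnsembleAnalysis, load_ensemble

ens = load_ensemble(["rep1.xtc", "rep2.xtc"], topology_path="top.pdb",
                    ligand_chains={"B"})
analysis = EnsembleAnalysis(ens)          # pass AnalysisConfig() to tune
prediction = analysis.predict_sensitive() # the three bridge strategies
stats = analysis.mutant_stats("WT")       # pathway-concentration summary
```

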