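# allonet

Trajectory-analysis toolkit for dissecting allosteric mechanisms in
molecular-dynamics ensembles — built around the workflow used to study how a
J-domain cochaperone primes the Hsp70 chaperone's nucleotide-binding domain
(NBD) for ATP hydrolysis, and reusable for any system where the questions
are of the same shape:

* **Order parameters & PCA** — inter-subdomain pseudo-torsions (dihedral of
  four group centres of mass), atom dihedrals, COM/minimum distances,
  antiparallel β-sheet content via template-RMSD switching, and PCA of
  coordinate covariance with cross-system projection.
* **Typed contact fingerprints** — hydrogen-bond / ionic / π-stacking /
  π-cation / hydrophobic contacts with exact per-frame frequencies, a
  differential table flagging contacts whose frequency shifts by more than
  40 percentage points between two systems, residue-role classification
  (ligand-binding, interlobe-interface, at 50% persistence), and chord-diagram
  export.
* **Dynamic correlation networks** — residue/ligand nodes, persistent-contact
  edges (0.45 nm, 75% of frames), generalized-correlation weights
  GC = √(1 − e^(−2I/3)) from k-NN mutual information, optimal
  (Floyd–Warshall) and twenty suboptimal allosteric pathways on
  d = −log GC, Louvain communities with a 1% size floor, betweenness
  centrality, and cutoff sensitivity scans with Jaccard similarity.
* **Free-energy reconstruction** — WHAM on umbrella-sampling windows
  (canonical ladder: ten windows spanning 0.3–1.2 nm, k = 1500 kJ·mol⁻¹·nm⁻²,
  310 K), moving-block bootstrap errors sized by the integrated
  autocorrelation time, convergence-vs-length diagnostics and state
  free-energy differences (e.g. a T199-close state < 0.4 nm vs a T199-far
  state > 0.65 nm along the T199–γ-phosphate distance).
* **Synthetic generators with ground truth** — planted correlated chains
  (known allosteric path), planted correlation blocks (known communities),
  Boltzmann samples from known 1-D potentials under the harmonic window
  ladder (known PMF), scripted contact geometries (known frequencies and
  types) and exact geometry fixtures, so every stage is testable without any
  external download.

Structure/trajectory I/O (PDB, GRO, XTC, DCD) goes through MDAnalysis;
coordinates are nm internally and residue numbering is always the source
file's numbering. See `docs/methods.md` for the models, defaults, and what
the synthetic validation does and does not show.

## Worked example: recovering a planted allosteric pathway

```python
from allonet import synthetic, network
from allonet.model import select

# 30-residue bead ensemble, 5000 frames; residues 5→25 coupled through
# four intermediates with per-dimension correlation 0.8
spec = synthetic.EnsembleSpec(seed=3)
top, ens, truth = synthetic.make_planted_network_ensemble(spec)

nodes = network.assign_nodes(top, select(top, "all"))
net = network.build_network(ens, nodes)          # 0.45 nm, 75%, GC weights
src, snk = truth.planted_path[0] - 1, truth.planted_path[-1] - 1
paths = network.suboptimal_paths(net, src, snk, 20)

print("planted:", truth.planted_path)
print("optimal:", [int(top.resids[i]) for i in paths.optimal])
occ = paths.node_occurrence()
print("occurrence of planted nodes:",
      [round(occ[r - 1], 2) for r in truth.planted_path])
```

Output:

```
planted: [5, 9, 13, 17, 21, 25]
optimal: [5, 9, 13, 17, 21, 25]
occurrence of planted nodes: [1.0, 0.95, 0.95, 1.0, 0.9, 1.0]
```

The optimal network path is exactly the planted chain — the correlated
residues form short d = −log GC links — and the planted nodes dominate the
21-path occurrence profile (endpoints appear in every path by construction;
the strongest background node reaches ~0.43).

A free-energy example in three lines:

```python
from allonet import synthetic, free_energy as fe
ds, truth = synthetic.make_umbrella_dataset(synthetic.UmbrellaSpec(seed=1))
profile = fe.wham(ds, n_bins=100)    # min-anchored G(ξ) in kcal/mol and kT
```

On the canonical ten-window ladder over a known harmonic potential the
reconstructed profile matches the analytic parabola with RMSE ≈ 0.06 kT
across the sampled range.

## Command line

```bash
allonet run --config src/allonet/configs/demo.yaml --out demo_out
allonet validate --config src/allonet/configs/paper_defaults.yaml
allonet wham --seed 3 --out wham_out
```

Verbs: `synth`, `contacts`, `network`, `paths`, `communities`,
`orderparams`, `pca`, `wham`, `sensitivity`, `run`, `validate`. Every verb
is a thin wrapper over `allonet.pipeline`; all randomness flows from config
seeds and re-running an identical config reproduces a byte-identical
manifest (output hashes included).

### Selection mini-grammar

`resid 40-115`, `resname ALA`, `name CA`, `chain A`, `backbone`, `heavy`,
`calpha`, `all`, combined with `and`, `or`, `not` and parentheses, e.g.
`"(resid 1-39 or resid 116-188) and backbone"`. Unknown names are errors,
not empty selections.

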