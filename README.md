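# mabshape

Conformational analysis of hinge-linked IgG1 antibody trajectories.

An IgG1 is three domains — two antigen-binding Fabs and one Fc — tethered by
a flexible hinge. Because the hinge leaves each Fab free to swing, global
descriptors like RMSD converge poorly, and the informative coordinates are
the latitude/longitude (θ, ϕ) of each Fab in a body frame anchored to the
Fc. `mabshape` implements that analysis layer for molecular-dynamics
ensembles of antibodies (and for pseudo-atomic toy systems it can generate
itself):

- **Fc-anchored Fab angles** — per frame, a right-handed frame with origin
  at the hinge centroid, z along the Fc principal axis toward the hinge,
  x along the CH2(A)→CH2(B) direction orthogonalized against z; each Fab's
  direction gives θ = arccos(v·ẑ/|v|) and ϕ = atan2(v·ŷ, v·x̂).
- **Y/T shape classification** — a frame is T-shaped when both Fabs have
  θ ≥ 85°, Y-shaped when both have θ < 85°, asymmetric otherwise; Δϕ =
  ϕᵢ − ϕ₀ (wrapped to (−180°, 180°]) tracks Fab rotation.
- **Accelerated-MD reweighting** — frames carrying a boost energy ΔV ≥ 0
  are reweighted with the Maclaurin series of exp(βΔV) truncated at order
  k (10 by default), w = Σₖ (βΔV)ᵏ/k!, onto a binned (θ₁, θ₂) surface;
  PMF = −k_BT ln p, zeroed at its minimum. Frames in bins with
  PMF < 0.5 kcal/mol form the minimum-energy set used downstream. The
  boost-parameter recipe EthreshD = DIHED + 4·n_res, αD = (4·n_res)/5,
  EthreshP = EPTOT + 0.16·n_atoms, αP = 0.16·n_atoms is included.
- **GROMOS clustering** — iterative neighbor counting on the pairwise
  minimal-RMSD matrix at a fixed cutoff (0.75/0.65 nm for antibodies in
  plain/boosted runs, 0.1 nm for glycans), medoid = the neighbor-richest
  frame of each round.
- **Essential dynamics** — PCA of the superposed Cα coordinate covariance;
  reconstruction along single eigenvectors isolates one collective motion,
  whose Δϕ distribution can be compared with the full signal.
- **Descriptors** — CH2 opening (Cα–Cα distance of the two glycosylated
  Asn), glycan chain minimum distance and Fc-aligned center-of-mass
  displacement, heavy-atom contacts at 4 Å between the light-chain
  C-terminus and the hinge, geometric hydrogen bonds (D···A ≤ 0.35 nm,
  D–H···A ≥ 120°), glycosidic φ/ψ torsions with reference-range occupancy,
  RMSD/RMSF/Rg.
- **Synthetic data** — a toy-antibody generator with exact per-frame ground
  truth, and a rejection sampler that draws (θ₁, θ₂) ensembles from a known
  density under an analytic boost, so every stage is testable without MD.

Topologies are PDB; trajectories DCD/XTC (anything MDTraj reads); atom
groups come from a YAML mapping of group names to 0-based index lists or
MDTraj selection strings.

## Worked example

`examples/02_amd_reweighting.py` plants a two-well (θ₁, θ₂) density (wells
at 70° and 100° with a 1 kcal/mol depth gap), samples 50,000 points under a
Gaussian boost, and reweights:

```
rejection efficiency:      0.20
PMF minimum at theta = (71.2, 68.8) deg   planted (70, 70)
well depth gap:            0.96 kcal/mol      planted 1.00
max |PMF - analytic|:      0.127 kcal/mol on 122 populated bins
minimum-energy frames (PMF < 0.5): 22955 of 50000
```

The 10th-order series puts the free-energy minimum in the planted well
(within one 2.5° bin), recovers the inter-well depth difference to
0.04 kcal/mol, and tracks the analytic surface to ~0.13 kcal/mol wherever
the sample is dense. The other examples cover shape classification,
clustering/ED, the descriptor set, and the end-to-end pipeline; each prints
the planted value next to the recovered one.

The same stages are available from a shell:

```
mabshape synth --seed 42 --frames 2000 --out toy/
mabshape angles --top toy/topology.pdb --traj toy/traj.dcd \
    --groups toy/groups.yml --out angles.csv
mabshape fes --angles angles.csv --boost amd.log --order 10 \
    --cutoff 0.5 --out fes.csv,minframes.txt
```

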