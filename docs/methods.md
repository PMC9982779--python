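# Methods

This note records the models, conventions and numerical choices behind
`mabshape`, and what the synthetic benchmarks do and do not demonstrate.

## The Fc-anchored frame and Fab angles

The hinge leaves an IgG1's two Fab arms roughly four slow degrees of
freedom: a latitude θ and a longitude ϕ per Fab, measured in a frame that
moves with the Fc. The frame is rebuilt for every trajectory frame:

- **origin** — centroid of the hinge atoms. The hinge is the natural pivot
  and the most frame-stable anchor available.
- **z** — the dominant principal axis of the Fc atom cloud (leading right
  singular vector of the centered Fc coordinates). The axis sign is fixed
  so +z runs from the Fc centroid toward the hinge centroid, i.e. toward
  the side of the molecule where the Fabs attach. Signing on the Fab
  midpoint instead would be unstable: whenever both Fabs swing past the
  equator (θ > 90°, the T-shape region) their midpoint crosses to the Fc
  side and such a rule would flip the frame, mapping θ → 180° − θ
  mid-trajectory. The Fab-midpoint rule is kept only as a fallback for the
  degenerate case where hinge and Fc centroids coincide.
- **x** — the CH2(A)-centroid → CH2(B)-centroid vector, orthogonalized
  against z and normalized. If that vector is parallel to z within 1e-6
  the construction raises rather than guessing.
- **y = z × x** completes a right-handed orthonormal triad.

Each Fab's direction vector v runs from the origin to the Fab's atom
centroid (a fitted Fab long axis would measure Fab *orientation*; the
latitude/longitude picture describes Fab *position*, which the centroid
captures directly). Then θ = arccos(v·ẑ/|v|) ∈ [0°, 180°] and
ϕ = atan2(v·ŷ, v·x̂) ∈ (−180°, 180°]. Because the frame is rebuilt per
frame from internal geometry, all angles are invariant under rigid motion
of the whole molecule — verified to 1e-6° under random rotations and
translations.

Shape calls use a θ threshold of 85° on both Fabs (T when both ≥ 85°, Y
when both < 85°, asymmetric otherwise); the threshold is a parameter. Δϕ is
reported wrapped into (−180°, 180°] by default; a cumulative (unwrapped)
variant is available for motions that accumulate beyond half a turn. The
reference frame's Δϕ is exactly zero.

## Boosted-ensemble reweighting

A dual-boost accelerated run samples the modified potential V + ΔV, so the
observed density is p₀·exp(−βΔV) and each frame must be reweighted by
exp(+βΔV) to recover unbiased statistics. The exponential is approximated
by its Maclaurin series truncated at order k_max = 10, accumulated term by
term (t_k = t_{k−1}·x/k) for numerical stability. At βΔV = 3 the 10th-order
series is accurate to ~3e-4 relative; a diagnostic records the relative
deviation at the largest βΔV seen and warns above 1%, since beyond
βΔV ≈ 5 the truncation bias becomes material.

Weights are binned on a (θ₁, θ₂) grid with 2.5° bins by default — fine
enough to resolve the 85° threshold while keeping of order a hundred frames
per occupied bin at the ensemble sizes used here. Bin probabilities are
normalized over the whole grid; PMF = −k_BT ln p, shifted so the occupied
minimum is exactly 0; empty bins carry +inf and are excluded from
normalization and minimum searches. k_BT defaults to 300 K
(0.5962 kcal/mol), the simulation temperature, and is configurable.
Minimum-energy frame selection returns every frame whose bin has
PMF < 0.5 kcal/mol (cutoff configurable, must be positive); the
global-minimum bin always qualifies, so the set is never empty.

Boost energies arrive either as two-column text (frame, ΔV) or as
AMBER-style logs whose last two numeric columns are the potential and
dihedral boosts; the dual-boost total is their sum. Only the total ΔV is
consumed.

The boost-parameter recipe maps 50-ns average energies to thresholds:
EthreshD = DIHED + 4 kcal/mol per solute residue, αD a fifth of that
increment, EthreshP = EPTOT + 0.16 kcal/mol per atom, αP equal to that
increment.

## Clustering and essential dynamics

The pairwise matrix holds minimal RMSD after optimal superposition (Cα for
protein, glycosidic oxygens for glycans). Superposed RMSD is symmetric
analytically; the matrix is symmetrized to remove float noise and carries a
zero diagonal. GROMOS clustering then repeats: count each pool frame's
neighbors within the cutoff (self included, ties broken toward the lower
frame index), promote the richest frame to medoid, remove it and its
neighbors, stop at the cluster cap. Clusters are emitted in decreasing
size; leftover frames keep label −1, and populations plus the unassigned
fraction sum to 1 exactly. Default cutoffs/caps follow the protein
(0.75 nm/15 for plain runs, 0.65 nm/10 for boosted runs) and glycan
(0.1 nm/10) settings used throughout.

Essential dynamics superposes all frames on frame 0, then once more on the
resulting mean (iterated-mean superposition — the mean is a better, less
arbitrary reference than any single frame), computes the 3N×3N covariance
of the Cα coordinates in double precision, and eigendecomposes it.
Coordinates are not mass-weighted (plain Cα PCA). Eigenvalues are reported
descending with normalized cumulative variance; their sum equals the total
superposed variance to 1e-8. A filtered trajectory along components C is
mean + Σ_{c∈C} proj_c·v_c; restricted to the minimum-energy frames it
yields the per-component Δϕ distributions. The geometry groups must lie
inside the ED selection for this reconstruction (enforced with a clear
error).

## Descriptors

- **CH2 opening**: Cα–Cα distance between the two glycosylated Asn
  residues. Side-chain atoms are perturbed by the glycosidic linkage, so
  the backbone atom is the stable choice.
- **Glycan minimum distance**: per-frame minimum over all heavy-atom pairs
  between the chains, fucose included.
- **Glycan center-of-mass displacement**: frames are superposed on the Fc
  atoms onto a reference frame (frame 0 of the analyzed subset), then the
  chain's mass-weighted centroid displacement from its reference position
  is measured; alignment removes rigid-body motion so only motion relative
  to the Fc remains. The reference-frame choice is recorded in the output
  metadata.
- **Contacts**: for each residue of the light-chain C-terminal group,
  per-frame counts of heavy-atom pairs within 0.4 nm of the hinge group
  (per-frame pair counts, not binary occupancies). Counts are monotone in
  the cutoff.
- **Hydrogen bonds**: donors are N/O/S atoms with a covalent H, acceptors
  N/O/S; a bond is counted when the donor–acceptor heavy-atom distance is
  ≤ 0.35 nm and the D–H···A angle is ≥ 120°. Both criteria are parameters;
  these defaults are the common geometric convention for
  trajectory H-bond analysis. Output is frequency per unique residue pair
  over the analyzed frames, optionally tagged by donor chain class.
  Topologies without explicit hydrogens raise with guidance.
- **Glycosidic torsions**: φ = O5–C1–Ox–Cx and ψ = C1–Ox–Cx–C(x+1) per
  linkage, specified as atom quadruples by residue and atom name; angles in
  (−180°, 180°] and per-linkage occupancy of a supplied reference window
  (windows may wrap through ±180°).
- **RMSD/RMSF/Rg** on Cα after least-squares superposition (reference:
  frame 0 for RMSD, the mean structure for RMSF).

Units are nm and degrees everywhere in outputs; angles are radians only
internally.

## Replica handling

Replicas are loaded independently, optionally strided (production save
intervals rarely match the analysis grid, so the stride is an explicit
option rather than an implied constant), trimmed of an equilibration head
(or reduced to a kept tail), and concatenated with per-frame provenance.
Three replicas retaining 7000 frames each yield exactly 21,000 analysis
frames. Atom-count mismatches fail naming the offending file.

## Synthetic data: what it emulates, and what it does not

The toy antibody is pseudo-atomic: an elongated Fc slab (54 atoms), a
5-atom hinge whose centroid sits exactly at the construction origin, two
rigid 8-atom Fab clouds placed at sampled (θ, ϕ) on a 4-nm sphere, CH2
clusters whose Asn pseudo-residues realize a sampled CH2 distance exactly,
and two 6-atom glycan chains (with named glycosidic oxygens and a fucose
pseudo-atom) placed inside or outside the Fc cavity with Gaussian jitter.
Each frame optionally receives a random global rotation and translation, so
recovering planted values exercises the full rotation-equivariant path.
Default sampling laws: shape mixture (T, Y, asym) = (0.3, 0.5, 0.2) with
T latitudes ~ N(100°, 5°) and Y latitudes ~ N(70°, 5°), truncated at the
85° threshold so labels are exact; ϕ ~ N(±90°, 20°); CH2 ~ N(4.8, 0.3) nm —
values chosen to mirror the shape fractions, θ wells and CH2 medians
reported for real IgG1 ensembles. Hydrogen-bond fixtures are the one
all-atom exception, carrying explicit donor hydrogens with an exact planted
occupancy.

The boosted-sample generator draws (θ₁, θ₂) from a truncated Gaussian
mixture (default: wells at 70° and 100°, σ = 6°, populations set by a
1 kcal/mol depth gap) under a Gaussian boost bump (height 1.5 kcal/mol,
βΔV ≤ 2.5, within the validated series radius), by exact rejection
sampling. The unbiased bin probabilities have a closed form (products of
normal CDF differences), giving an analytic reference PMF.

What passing these benchmarks shows: the geometric constructions, the
reweighting estimator, the clustering/ED algorithms and the descriptor
arithmetic are correct, rotation-equivariant and deterministic. What it
does not show: anything about force fields, sampling convergence, or real
antibody energetics — the toys have no physics, rigid domains, and no
correlation structure between descriptors beyond what is planted.

## Problem sizes and determinism

The bundled analyses run at desk scale: 2,000–20,000-frame toy ensembles
for angle and shape statistics, 50,000-sample boosted ensembles for
reweighting (where the well-depth check is specified), hundreds of frames
for the O(n²) clustering paths, and minimal-atom replicas for frame
accounting. Everything downstream of a seed is deterministic: reruns with
the same seed and configuration produce byte-identical CSVs. Trajectory
coordinates are stored in single precision (the trajectory-format
convention); the generator additionally keeps its double-precision
coordinates, which is what the strict (1e-6°) round-trip checks consume,
while file round trips are validated at the ~1e-3° level that float32
storage supports. RMSD values near zero are similarly limited to ~1e-3 nm
agreement with the double-precision Kabsch reference.

## Known limitations

- The z-axis principal direction becomes ill-conditioned for a nearly
  spherical Fc selection; real Fc domains (and the toy slab) are clearly
  elongated.
- Maclaurin reweighting is the only estimator offered (no cumulant or
  Gaussian-approximation variants), matching its intended use.
- GROMOS clustering materializes the full O(n²) RMSD matrix; for very long
  ensembles subsample first.
- H-bond detection requires explicit hydrogens and bonds in the topology;
  no heuristic hydrogen placement is attempted.
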