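# Methods

## Model overview

`mbmscreen` implements ligand-anchored consensus-pharmacophore screening.
The object of study is a multi-target ligand — modelled here on a rigid
tetracyclic isoquinolinium cation (C20H18NO4⁺, 25 heavy atoms) — whose
proven complexes all present the same physicochemical motif: a buried
anion neutralising the N⁺, aromatic/aliphatic pockets stacking the ring
system, and H-bond acceptors on the ether oxygens. The pipeline abstracts
each complex into a pharmacophore, merges the pharmacophores into one
consensus motif (MBM), and scores candidate targets by how much of the
motif they reproduce and how precisely.

## Binding-site definition

The site around the ligand contains every receptor residue with at least
one heavy atom within a cutoff of **any** ligand heavy atom
(nearest-atom convention; default radius 7 Å, the distance shell within
which the cationic ligand engages neighbouring residues). A centroid
sphere was rejected because it misses contacts at the ends of elongated
ligands. Hydrogens are ignored throughout; residue numbering is taken
verbatim from the file. Structures carrying two ligand copies (the
RamR-type dual site) yield one complex model per copy, labelled
"site I", "site II" in file order.

Ligand bond orders and formal charges cannot be read from PDB records, so
they come from the packaged SDF template when the HETATM element sequence
matches it in order; otherwise bonds are perceived from interatomic
distances (covalent-radius sums + 0.45 Å) and the cation is taken as the
nitrogen with the most (≥ 3) heavy neighbours.

## Interaction typing and cutoffs

Receptor groups are typed from residue/atom names: Glu/Asp carboxylates
and nucleic-acid phosphates → anion; Lys/Arg → cation (His only when
explicitly flagged protonated — no pKa model is applied); Phe/Tyr/Trp/His
and nucleobase rings → aromatic; Ala/Val/Leu/Ile/Met/Pro side chains →
aliphatic hydrophobe; amide N/O and polar side chains → H-bond
donor/acceptor. Unknown residues are skipped with a warning, never
fatally.

Detected interactions and their distance cutoffs (Å, configurable):

| kind              | partners                     | distance            | default |
|-------------------|------------------------------|---------------------|---------|
| attractive_charge | ligand cation ↔ anion        | centroid–centroid   | 7.0     |
| pi_pi             | ring ↔ ring                  | centroid–centroid   | 6.0     |
| pi_alkyl          | ring ↔ hydrophobe (both ways)| centroid–centroid   | 5.5     |
| hydrogen_bond     | donor ↔ acceptor             | nearest heavy atom  | 3.5     |

The 7 Å charge cutoff is the model's anchor radius; the others mirror
common pharmacophore-software defaults. v1 applies **no angular terms**
(π-stack geometry, H-bond angles); this is a deliberate simplification
recorded in report metadata. The N⁺–anion distance utility defaults to
the minimum over anion-group atoms (the crystallographic measurement
convention); a centroid mode is provided because either convention is
defensible.

## Pharmacophore convention

Features are placed at **ligand-side** group centroids. This is the one
genuinely open design choice in the extraction step: placing features on
the ligand means pharmacophores from different targets all live on the
common scaffold, so superimposing them reduces to aligning the shared
ligand pose — an exact, convex problem — rather than matching feature
clouds. The frame is recorded in the JSON (`mbm-pharmacophore/1` schema).
Default tolerance is 1.6 Å per feature; same-kind duplicates within
0.5 Å merge to their centroid (one ring engaged in both π–π and π-alkyl
contributes one feature). Feature lists are sorted by (kind, position),
making generation byte-deterministic.

## Consensus construction

All feature sets are rigidly transported into the reference frame (first
input's ligand pose by default) via Kabsch superposition of the canonical
heavy-atom correspondence. Same-kind features are then single-linkage
clustered at 1.5 Å; every cluster supported by ≥ 2 distinct sources
becomes a consensus feature at the member centroid with tolerance =
max(member tolerances). Single linkage was chosen because jittered
copies of one true feature form a tight chain, while decoys sit far
away; the 1.5 Å cutoff is just under the feature tolerance. Both knobs
are exposed. The build is permutation-invariant for a fixed reference.

## Matching and scoring

A candidate is aligned into the MBM frame through its ligand pose, then
features are assigned one-to-one to MBM features of the same kind within
a 2.0 Å pair cutoff. The assignment maximises the number of pairs *n*
and, among maximum assignments, minimises the total distance (solved per
kind by the Hungarian algorithm with a prohibitive pseudo-cost on
out-of-cutoff pairs; ties broken lexicographically so results are
platform-stable). RMSD over matched pairs defaults to root-mean-square;
an arithmetic-mean mode exists because the quantity is sometimes
described as an "average distance" even when named RMSD — the default
follows the name.

Scoring constants (all in `ScoringParams`): α = 2.599, β = −5.234,
κ = −5.905, BP₀ = 49.243, threshold 0.5 (inclusive ≥). Numerical
conventions:

- *n* = 0 ⇒ BP = 0 ⇒ fit = 0 (avoids log 0 and encodes "no match");
- RMSD is clamped at a 0.1 Å floor before exponentiation — β < 0 makes
  BP singular at 0, and the floor keeps perfect matches finite and
  top-ranked;
- fit defaults to the natural-log sigmoid, which simplifies exactly to
  BP/(BP + BP₀); base-10 is provided for fidelity testing. Both give
  fit(BP₀) = 0.5 exactly, and fit is strictly increasing in BP, so
  ranking by fit equals ranking by BP under either convention.

## Calibration and the BP–K_D link

The link is read as log₁₀(BP) = 1/K_D − κ, making the response 1/K_D
linear in (log₁₀ n, log₁₀ RMSD, 1); α, β, κ are then ordinary least
squares. The design is unidentifiable when n and RMSD are both constant;
this is detected and raised. Note that under this reading, positive K_D
requires log₁₀ BP > −κ; with the default constants that means BP > ~8×10⁵
(small RMSD). The literal transform of K_D in the source model is
ambiguous, so the link object is pluggable, and calibration is validated
by self-consistent recovery (exact on noiseless data; ±0.1 per parameter
at σ = 0.05 link-scale noise with 50 observations) rather than against
external affinities.

## Assay utilities

- Inhibition % = [1 − (S−S₀)/(C−C₀)] × 100; degenerate controls
  (C = C₀) are rejected. The quantity is invariant under common
  rescaling of all four readings.
- IC50 by ordinary linear regression of inhibition on concentration, as
  in the validation experiments this mirrors — a four-parameter logistic
  is deliberately **not** implemented. The 50 % crossing must lie within
  twice the concentration span, else "not bracketed".
- SPR steady-state: least-squares fit of R(C) = R_max·C/(K_D + C) with
  deterministic initialiser (R_max⁰ = max response, K_D⁰ = median
  concentration) and positivity bounds. All-zero responses are
  unidentifiable and rejected. Concentrations are μM throughout.

## Synthetic fixtures: what they emulate, and what not

The generator stands in for crystal structures and binding assays:

- **Toy complexes**: the rigid template ligand at the origin plus
  side-chain fragments (Glu/Asp carboxylate, Phe/Tyr ring, Ala/Leu
  hydrophobes, Lys, Ser, cytosine + phosphate) placed at exact distances
  from a chosen anchor (N⁺, ring centroid, nearest surface atom) along
  well-separated directions, fragment tails pointing away so the key
  atom stays nearest. Distances are exact by construction and verifiable
  on re-read at PDB coordinate precision.
- **Planted-motif pharmacophore sets**: `n_targets` = 6 sources (the
  size of the proven-complex panel: five structures, one with a dual
  site), each a rigidly moved copy of a 4-feature constellation on the
  ligand scaffold (N⁺ cation, two aromatic-system centroids, one ether
  acceptor) with iid Gaussian jitter (default σ = 0.3 Å, a tight
  crystal-to-crystal variation) plus per-target decoys sampled in a
  4–10 Å shell. Decoys are excluded within 2 × cluster_radius of planted
  features **and of every other decoy**, so no decoy can join or form a
  consensus cluster and the ground truth (per-target n_true, rmsd_true)
  is unambiguous by construction. Target 0 keeps the identity frame so
  the MBM reference frame coincides with the planted frame.
- **Affinity observations**: (n, RMSD) drawn with n ∈ {3..8} and RMSD
  uniform on [0.05, 0.12] Å — the region where the default link yields
  positive K_D under the default constants — mapped through the link
  with optional Gaussian noise on the link (1/K_D) scale; draws with
  non-positive K_D are skipped and counted.

What the fixtures do **not** emulate: conformational flexibility of the
ligand or receptor, water-mediated contacts, protonation equilibria,
crystallographic disorder, or realistic decoy correlation structure.
Passing the recovery tests therefore demonstrates the correctness of the
geometry, clustering, assignment and regression machinery under the
stated noise model — not screening performance on real structures.

## Problem sizes and determinism

Default test workloads: 200 matching instances (≤ 6 features/side)
against an exhaustive assignment oracle; 50 seeded consensus-recovery
runs (6 targets, jitter σ = 0.5 Å = cluster_radius/3, 3 decoys each);
50-observation calibrations; 8-point SPR curves — sizes at which the
brute-force oracles are exact and the whole suite runs in seconds. All
stochastic tests use fixed seeds; every generator is deterministic given
its seed.

## Known limitations

- Distance-only interaction criteria (no angles) over-detect stacking in
  contrived geometries.
- Receptor typing is name-table-driven; modified residues and uncommon
  protonation states are skipped rather than modelled.
- The fallback cation assignment (nitrogen of highest degree) is a
  heuristic for templates that cannot be matched; it is correct for
  isoquinolinium-like ligands only.
- Consensus features are unweighted by support in scoring (v1); no
  excluded-volume spheres are emitted.
- Published per-target fit values depend on a proprietary pharmacophore
  generator and unpublished per-target (n, RMSD); they are used as
  threshold inputs, not reproduction targets.
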