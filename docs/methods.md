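# Methods

## Protocol overview

`pharmvote` screens a molecule library against an *ensemble* of receptor
conformations rather than a single structure.  Each conformation
independently produces a set of 3-point pharmacophores from its affinity
grid maps; a molecule collects one vote per conformation whose set it
matches; the vote total is the score.  Ensemble voting smooths over the
arbitrariness of any single snapshot and turns a binary pharmacophore
filter into a graded ranking.

## Affinity maps

One map per probe class (H-bond donor, H-bond acceptor as the per-point
minimum of the O/N/S flavors, hydrophobic, aromatic, charged), on a cubic
grid of default side 12.5 Å and spacing 0.25 Å centered on the active
space (51 points per axis; the file format counts intervals, so
`NELEMENTS 50 50 50` carries 51³ = 132 651 values, x index fastest).
Maps normally come from an external grid calculator; a simplified internal
calculator (12-6 well per heavy atom, a Gaussian H-bond term at 1.9 Å to
complementary atoms for donor/acceptor probes — complementary atoms are
exempt from the 12-6 wall so the H-bond contact is not masked — and a
signed 1/r term for the charged probe, clamped at +100 kcal/mol) exists so
the pipeline runs and is testable without external tools.  It is a
qualitative surrogate, not a force field.

The acceptor-combination rule is a genuine open choice; we use the
per-point *minimum* (most favorable flavor): a site is an acceptor hotspot
if any of O, N or S binds well there.  Sum or average would dilute a
strong O well with indifferent N/S energies.

## Receptor-specificity filter

For each map we histogram |E| over strictly negative grid energies
(bin width 0.01 kcal/mol) and compute the Pearson (non-excess) kurtosis
m₄/m₂² from bin centers weighted by counts.  Heavy-tailed histograms —
many favorable cells scattered over the box — indicate a flat,
non-specific landscape for that probe and the map is discarded.
Thresholds: 3.0 for acceptor/aromatic/hydrophobic, 4.5 for donor (donor
maps are systematically heavier-tailed), 23 for ion–dipole and 50 for
ion–ion; each charged map is judged twice, once per ionic class.
Discarding is strict (> threshold), with a 1e-9 relative guard so a
kurtosis equal to the threshold up to floating-point noise passes.

Conventions worth noting:

* Kurtosis is computed from the *binned* histogram, not raw values; at the
  default resolution the two agree within 1% for ≥10⁴ samples spanning
  ≥50 bins (tested), so the choice is nearly immaterial.
* The normal distribution scores exactly 3, the uniform 9/5 — these anchor
  the thresholds and are used as calibration checks.
* Maps with no negative cells, or a single populated bin, carry no usable
  signal; they are discarded rather than treated as errors.
* Kurtosis of raw values is scale-invariant; the binned version acquires a
  weak bin-width dependence, so rescaling energies requires rescaling
  `bin_width` identically for identical decisions.

## Hotspots and features

From each retained map the k = ⌊x/100 · N_neg⌋ lowest-energy negative
cells are selected (x defaults to 0.7%, with 0.3–0.5% equally workable;
ties at the cutoff break lexicographically on the grid index, making
selection deterministic and nested in x).  Selected cells are clustered
by 26-connectivity (faces+edges+corners, so thin diagonal shells do not
fragment; 6-connectivity is available).  Each cluster becomes one feature:
center = energy-weighted mean with weights |Eᵢ|, radius of gyration =
weighted RMS distance from the center (exactly 0 for single-cell
clusters).  Donor/acceptor features get a unit direction from the feature
center toward the nearest chemically complementary receptor atom (donor →
receptor O, or N with no bound hydrogen; acceptor → donor hydrogens, or
N/Ser-Thr-Tyr hydroxyl oxygens in hydrogen-free structures).  The
direction points feature → receptor.

Ion–ion interactions are handled structurally rather than from grid
clusters: one feature of fixed radius 4.0 Å on the charged-group atom of
each Arg (CZ), Lys (NZ), Glu (CD) and Asp (CG) inside the active space,
emitted only when the charged map passed the ion–ion kurtosis test —
keeping the two ionic treatments parallel (grid features, too, require a
retained map).

Only features whose centers lie inside the active-space sphere (radius
5 Å around the grid center; boundary inclusive) are kept.

## Pharmacophores

Every combination of three features of one (frame, active space) forms a
pharmacophore, except triples containing a pair of *different-type*
features closer than 1 Å (strict; same-type pairs are exempt).  Features
never mix across active spaces: each space has its own grid center, so
cross-space triples would span regions never jointly calibrated.  Each
pharmacophore carries the frame's full volume-exclusion list: a 0.5 Å
sphere per backbone heavy atom (N, CA, C, O, and terminal OXT) and a
1.5 Å sphere per residue side-chain center of mass (unweighted heavy-atom
mean; glycine contributes none).  The radii are deliberately small so
slightly larger ligand groups still fit.

Pharmer-compatible JSON export (`Aromatic`, `HydrogenDonor`,
`HydrogenAcceptor`, `Hydrophobic`, `PositiveIon`/`NegativeIon`,
`ExclusionSphere`) allows the external Pharmer program as an alternative
screening backend.  Ionic features require an explicit charge sign at
export time because the grid probe's sign is not modeled.  Exported point
radii are floored at 0.5 Å so zero-r_g features stay matchable.

## Matching

A conformer matches a pharmacophore when *some* rigid placement (proper
rotation + translation — a physical molecule cannot be mirrored) brings
three of its typed feature points within the features' effective radii
r_eff = max(r_g, 0.5 Å) without pushing any heavy atom strictly inside an
exclusion sphere.  The 0.5 Å floor exists because single-cell hotspots
have r_g = 0 and would otherwise be unmatchable; its value mirrors the
backbone exclusion radius.

The implementation searches type-compatible assignments with a pairwise
distance pre-filter (|d_conf − d_pharm| ≤ r_eff,i + r_eff,j), then tries
an unweighted and a 1/r_eff²-weighted Kabsch superposition, and — because
per-point feasibility is not the same thing as the least-squares optimum —
falls back to a deterministic minimax refinement over SO(3) (L-BFGS on
the rotation vector, smooth-max objective, fixed starts) before declaring
failure.  The contract is placement *existence*, verified in the tests
against a randomized rotation-search oracle with zero false negatives.
Collinear triples leave a free rotation about the line axis and are
handled by a deterministic sweep over that one-parameter family (both
axis orientations).  Note that any bare 3-point set superposes onto its
mirror image by a proper rotation (reflect across its own plane), so
chirality discriminates only through the remaining atoms (exclusion
clashes) or direction vectors — both covered by tests.

Direction constraints (molecule donor-H direction vs feature direction
within 45°) are available but off by default; enrichment results are
reported without them.

Tautomers and protonation states are grouped under one molecule id by
stripping a trailing `_<integer>` suffix; any conformer of any member
matching any pharmacophore of a frame earns that frame's vote.

## Voting, ranking and metrics

Votes are row sums of the boolean molecule × frame match matrix; frames
with empty pharmacophore sets still count in the denominator (they simply
cast no votes), preserving comparability.  Ranking is by descending votes
with *explicit tie blocks* — ties are pervasive at small frame counts, and
jittering them would make results irreproducible.  Enrichment statistics
are tie-aware: when the top-N^x% cutoff falls inside a block, the hit
count is the expectation under uniform random within-block order
(fractional hits).  This is deterministic and unbiased; a fully tied
ranking gives EF_x = 1 exactly at every x.  N^x% uses round-half-up with
a floor of 1 so tiny libraries still define EF.

Bootstrap errors resample *frames* (columns), not molecules, with
replacement, 100 replicates by default, recomputing votes → ranking → EP
per replicate and reporting the pointwise mean and standard deviation.
The estimate captures only frame-sampling uncertainty, not grid-model or
threshold choices.

## Synthetic benchmark

The generator emulates the protocol's three external inputs under full
seed determinism (every artifact byte-identical across runs):

* **Receptor ensemble** — 12 pseudo-residues (Ala/Gly/Arg/Lys/Glu/Asp
  with valid backbone and side-chain atom names) on an 8 Å shell around
  the pocket center, side chains pointing outward; frame i = frame 0 +
  per-atom Gaussian jitter (default 0.1 Å).
* **Grid ensemble** — planted wells are flat-bottomed super-Gaussian
  profiles (exponent 4, depth 3 kcal/mol, width 1.5 Å) with a mild
  central deepening (depth/6, width 0.6 Å).  The flat bottom is what makes
  the histogram compact (kurtosis ≈ 2.4 → retained): a plain Gaussian
  well produces a heavy-tailed histogram (κ ≈ 5–8) that the filter would
  — correctly, by its own logic — discard.  The central deepening makes
  the top-x% cells cluster compactly at the planted center so feature
  recovery is sharp (center error < 0.1 Å, r_g ≈ 0.35 Å).  Non-planted
  maps carry either a +0.1 kcal/mol baseline (no negative cells →
  discarded as empty) or zero-mean noise whose half-normal negative-energy
  histogram scores κ ≈ 3.9 (> 3 → discarded by kurtosis), giving the
  filter true negatives of both kinds.  Well centers jitter with the
  receptor.
* **Library** — actives reproduce the planted donor/acceptor/hydrophobic
  triangle (side lengths 3.0–4.3 Å) under a random rigid rotation with
  0.5 Å Gaussian jitter per point, plus Poisson(1) random extra typed
  points; three conformers per molecule; heavy atoms sit at the feature
  points (clear of the receptor shell).  Decoys are uniform random typed
  point clouds with the same size distribution.  The 0.5 Å jitter is
  chosen so the per-frame active match fraction sits strictly inside
  (0, 1) (measured 0.75–0.90) while decoys match at ≈ 0.07 — actives are
  enriched but not trivially separable, which is what makes the bootstrap
  and frame-count behavior informative.

What passing the synthetic benchmark does *not* show: decoys here are
geometry-mismatched, not property-matched as in curated screening decoy
sets; receptor pseudo-residues have no real chemistry; the internal
affinity surrogate is not a force field.  The benchmark validates the
*machinery* (filtering, feature recovery, matching, voting, metrics), not
virtual-screening realism on real targets.

## Problem sizes and numerical choices

Default benchmark sizes — 20 frames (100 for the bootstrap frame-count
comparison), 20 actives / 480 decoys, 51³-point grids — were chosen so
the full end-to-end run completes in minutes on one core while leaving
the vote distribution non-degenerate.  Other conventions: energies must
be finite everywhere (maps with NaN are rejected at write time); grid
cell-count rounding uses floor with a 1e-9 guard against float droop
(0.7% of 1000 is exactly 7); component ordering, hotspot-cell tie-breaks
and enumeration order are all fixed so every stage is bit-reproducible;
pipeline stages persist TSV/JSON artifacts with content hashes, and any
frame subset can be recomputed independently.

## Known limitations

* The simplified affinity calculator ignores desolvation, electrostatic
  screening and atom-type-specific van der Waals parameters.
* The matcher tests 3-point placements only; 4-point pharmacophores and
  partial-match scoring are out of scope.
* Exclusion testing uses heavy atoms against a transform chosen by the
  feature-point fit; in pathological cases a different feasible placement
  could avoid an exclusion the chosen one hits.
* Conformer generation is not provided: libraries must ship 3D conformers
  (SDF) or pre-typed feature clouds (JSON).
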