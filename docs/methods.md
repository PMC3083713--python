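# Methods

This note documents the models, numerical choices and limitations behind
`idpanchor`.  Empirical numbers quoted here are the ones the test suite and
`scripts/acceptance.py` themselves compute.

## Structures and ensembles

Coordinates are handled as a small object tree (`Structure` → `Residue` →
`Atom`) keyed by author residue numbering (p53 numbering 17–29 for the
`ETFSDLWKLLPEN` segment); nothing is re-indexed, so residue labels such as
Phe19 mean the same thing everywhere.  PDB parsing/serialisation is
delegated to gemmi; multi-model files map to an `Ensemble` of frames with
identical topology and an optional time step (ns per frame, default 5 ps in
the generator, a typical MD save interval).  Only blank/'A' altlocs are
kept; insertion codes and non-standard residues pass through but are
excluded from χ analysis with a logged warning.  Hydrogens are parsed but
excluded from SASA and RMSD by default (NACCESS convention).

## SASA and anchor classification

The Shrake–Rupley engine places `n` test points (default 960) on each
atom's accessible sphere of radius r + 1.4 Å using a Fibonacci lattice —
deterministic by construction, no RNG — and counts points outside every
neighbour's accessible sphere:
SASA_i = (exposed fraction) · 4π(r_i + r_probe)².
Radii are NACCESS-style united-atom values resolved by element
(C 1.87, N 1.65, O 1.40, S 1.85, P 1.80, H 1.00 Å), with a hard error for
unresolvable atoms.  Accuracy, measured by the tests: < 0.1% against the
closed-form isolated sphere at 960 points, < 2% against the analytic
two-sphere cap formula, within 3σ of a Monte-Carlo surface-sampling oracle,
and < 2% total-SASA deviation from an independent implementation (biotite)
given the same radii.  Adding atoms never increases any existing atom's
SASA (checked property).

A residue is an **anchor** for a given complex when
bound SASA ≤ 15 Å² (burial cutoff) AND unbound SASA ≥ 30 Å² (exposure
cutoff).  The burial cutoff is the published operational definition; the
exposure cutoff is this package's quantification of "exposed in the
unbound state" — the literature states no number — and is a mandatory,
echoed parameter.  Classification defaults to total residue SASA, with a
side-chain-only mode.  The unbound reference is either the complex
conformation with the partner deleted (default) or an unbound-ensemble
mean; both are supported because the underlying study used both and found
them equivalent.

## Torsions, superposition, helix assignment

Dihedrals use the atan2 formulation, IUPAC sign, range (−180°, 180°];
χ₁ = N–Cα–Cβ–γ (OG for Ser, OG1 for Thr), χ₂ = Cα–Cβ–Cγ–δ with Cδ1 for
Phe/Trp/Leu.  Missing atoms yield explicit missing values that are removed
from every statistical denominator.  Superposition is unweighted
Kabsch least squares via SVD with reflection correction; the tests verify
equality with a quaternion-eigenvalue oracle and with scipy's
`Rotation.align_vectors` to 1e-8 Å.

Helix assignment is a deliberately simplified two-criterion rule (a full
hydrogen-bond-energy secondary-structure assignment is out of scope): a
residue is helical if (a) its (φ, ψ) lies in the α-basin box
φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°] within a run of ≥ 4 consecutive
in-basin residues, or (b) it takes part in an O(i)→N(i+4) contact < 3.5 Å.
On the ideal helix fixture (φ = −57°, ψ = −47°) both criteria fire for the
whole window; on extended chains neither does.

## Unfolding detection

τ_u is the time of the first frame of the first run of ≥ `dwell` frames
(default 10) in which backbone RMSD over the helix window Phe19–Leu26
exceeds 2.5 Å AND the helix fraction is below 0.25.  The window follows the
RMSD-analysis convention; the alternative Thr18–Leu26 window is supported.
These numeric thresholds are this package's declared operationalisation of
a published criterion that combined secondary structure, RMSD and visual
inspection without printed numbers; they are mandatory-echoed config, and
τ_u is provably monotone in the RMSD threshold (tested).  Helix-state
statistics exclude a 1 ns equilibration prefix by default.  The packaged
reference table of published unfolding times yields 24.5 ± 11.8 ns for the
ten MDM2-helix trajectories and 5.2 ± 3.1 ns for the five Taz2-helix
trajectories (sample sd), recomputed exactly by `summarize_unfolding`.

## Rotamer regions, populations, transitions

Regions are circular half-open intervals [lo, hi) in χ₁ (Phe19: A/B/C) or
χ₁×χ₂ rectangles (Trp23: 1–6); region sets must be pairwise disjoint
(validated at load) and frames on a boundary go to the earlier-listed
region, so classification is deterministic.  The shipped bounds sit at
standard rotamer-well boundaries (g−/t/g+ thirds; sign halves of Trp χ₂)
and are estimates recorded as config, not measured values.  Phe/Tyr χ₂ is
folded into [−90°, 90°) before any region or reference test; Trp is not
folded (the indole is asymmetric).  Caveat of the folding: bound-like
matching uses 360°-circular distance on the folded value, which
overestimates distances across the ±90° seam; the shipped references
(χ₂ = 71°, −30°, 60°) sit far from the seam.

Populations are binomial: p = matching frames / defined frames,
se = √(p(1−p)/n).  Frames with undefined χ stay out of the denominator;
unassigned-but-defined frames stay in it, so the disjoint-region partition
plus "unassigned" sums to exactly 1.  Bound-like matching requires both χ
angles within a circular tolerance (default ±40°) of the reference; the
tolerance is a mandatory, echoed parameter standing in for an unstated
matching rule in the literature.  Among the shipped bound references only
the Phe19/MDM2 pair (177°, 71°) is a published value; the others are
representative rotamer centres, marked as estimates in the config.

Transition counting collapses runs shorter than `min_dwell_frames` and
counts label changes between the surviving runs; with dwell 1 it is the raw
change count.  It is invariant under state relabelling and time reversal
(property-tested).

## Synthetic ensembles (what they emulate, what they do not)

The generator builds every frame from internal coordinates (NeRF chaining
with fixed ideal bond lengths/angles; L-chirality checked against a CCD
reference residue), so requested φ/ψ/χ torsions are reproduced exactly
(< 1e-6°) at zero noise, and to a few degrees under 0.1 Å Gaussian
coordinate noise.  Backbone states follow a two-state helix/coil schedule
with geometric dwell times (helix: −57°/−47° ± 8° uniform jitter; coil:
φ ~ U(−160°, −60°), ψ ~ U(100°, 180°)).  Per-residue rotamer states are
drawn from target stationary distributions — iid per frame or as a sticky
Markov chain with chosen mean dwell — with ±10° uniform jitter around the
state centres; a joint option couples two residues by drawing pair labels
from a forced joint table (`joint_from_marginals` pins chosen cells and
rescales the rest, so marginals drift upward from the inputs — a synthetic
coupling device, not an exact fit).  Default state populations are the
published helix-state and disordered-state bound-like populations of the
four anchors (e.g. Phe19 anchor-type 59.5% in helix, 19.2% disordered),
with the remaining mass spread over decoy rotamers as a fixed choice.

The generator emulates the *statistical* structure the analyses consume:
two backbone states, state-dependent rotamer populations, dwell times,
coordinate noise.  It models no physics — no sterics, solvent, energies or
realistic kinetics — so passing tests demonstrate correctness of the
measurement pipeline on ensembles with known truth, not reproduction of
molecular-dynamics behaviour on real trajectories.

The cage-complex fixture surrounds chosen residues with carbon atoms placed
on their accessible spheres, pruned where they could shadow non-pocket
residues (full occlusion-protection radius for spatially distant residues,
clash-only pruning within 6 Å of the pocket, where partial occlusion is
harmless because those residues stay far above the burial cutoff).  Over
randomized pockets the classifier recovers the constructed anchor set
exactly (20/20 in the acceptance run).

## Problem sizes and determinism

Study-scale runs use 2000 frames per state ensemble (binomial se ≈ 1.1% at
p ≈ 0.6), 500 seeded replicates per recovery target, a 49,000-frame
(245 ns at 5 ps) series for transition counting at the published flip rate
(~1 per 1.9 ns), and 240–960 SASA points depending on whether a
classification or a surface-accuracy question is asked.  All randomness
flows from `numpy.random.default_rng` seeds recorded in the outputs; the
same seed reproduces ensembles bit-identically.

## Known limitations

* Region bounds and most bound-reference angles are estimates, not
  measured complex values; they are configuration and should be replaced
  when experimental structures are at hand.
* The helix criterion is a proxy; it agrees with full secondary-structure
  assignment on clean helices and coils but will differ near 3₁₀/turn
  boundaries.
* Proline is built with an unclosed five-ring (geometry-only placement).
* `joint_from_marginals` trades marginal fidelity for an exact forced cell.
* SASA radii are united-atom style; including explicit hydrogens with these
  radii would double-count volume.
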