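# idpanchor

Anchor-residue and side-chain rotamer analysis for conformational ensembles
of intrinsically disordered peptides, built around the p53 transactivation
segment Glu17–Asn29 (sequence `ETFSDLWKLLPEN`, "p53N").

## The scientific problem

Short disordered binding regions (molecular recognition features, MoRFs)
often bury a handful of residues deeply in a partner's binding groove.
These **anchor residues** are solvent-exposed in the unbound chain and
become essentially fully buried on binding — operationally, a residue is an
anchor when its solvent-accessible surface area (SASA) in the complex drops
to ≤ 15 Å² while it stays exposed in the unbound state.  The p53 segment
uses *different* anchors for different partners: Phe19, Trp23 and Leu26 in
the MDM2-bound mode, Leu22 in the Taz2-bound mode.

The central question this package addresses quantitatively: **how often does
the unbound ensemble already sample the bound-like side-chain rotamer
states of its anchor residues?**  Concretely it computes, over an ensemble
of unbound conformers:

* per-residue SASA by the Shrake–Rupley method (probe 1.4 Å, deterministic
  Fibonacci point lattice, NACCESS-style radii) and the two-sided anchor
  classification above;
* side-chain torsions χ₁ = N–Cα–Cβ–Cγ and χ₂ = Cα–Cβ–Cγ–Cδ₁, classified
  into named circular regions (three χ₁ regions A/B/C for Phe19, six χ₁×χ₂
  rectangles 1–6 for Trp23), with Phe/Tyr χ₂ folded into [−90°, 90°) for
  ring symmetry;
* populations p ± √(p(1−p)/n) of each region and of *bound-like*
  conformations (both χ angles within a circular tolerance, default ±40°,
  of a complex-derived reference), separately for helix-state and
  disordered-state frames;
* the joint 18-cell Phe19×Trp23 occupancy matrix and rotamer transition
  counts (with run-length debouncing);
* helix unfolding times τ_u from a sustained backbone-RMSD excursion plus
  loss of helix content, and group summaries (mean ± sd).

Because explicit-solvent MD is out of scope, the package ships a
geometry-exact synthetic-ensemble generator (internal-coordinate peptide
builder, two-state helix/coil switching, per-residue rotamer Markov
sampling with target populations) whose ground truth makes every analysis
stage testable.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
inputs and write tables under `results/`:

```
python analysis/01_simulate_ensembles.py --seed 1
python analysis/02_anchor_analysis.py
python analysis/03_helix_unfolding.py
python analysis/04_rotamer_populations.py --seed 1 --n-frames 300
```

Output of steps 02–04 (seed 1):

```
mdm2_like: anchors [19, 23, 26] (constructed pocket [19, 23, 26]) -> results/02_anchors_mdm2_like.tsv
taz2_like: anchors [22] (constructed pocket [22]) -> results/02_anchors_taz2_like.tsv
step trajectory: unfolds at frame 50 (25.0 ns); 48 helix-state / 20 disordered-state frames
reference table: MS mean 24.5 ns (sd 11.8), TS mean 5.2 ns (sd 3.1) -> results/03_unfolding_summary.tsv
helix      Phe19 p53N-MDM2 (anchor-type): 59.0% +/- 2.8%
helix      Phe19 p53N-Taz2 (non-anchor): 12.0% +/- 1.9%
...
library-preference reversal in the helix state for: ['Phe19']
joint Phe19/Trp23: P(A,1) = 55.3% (marginals A 69.7%, 1 73.0%)
rotamer transitions of Phe19 over 300 frames: 130
```

Reading this: the cage-complex fixtures recover exactly the constructed
anchor sets of the two binding modes; the step trajectory unfolds at its
scripted 25 ns; the packaged unfolding-time table averages to 24.5 ± 11.8 ns
(MDM2-helix starts) and 5.2 ± 3.1 ns (Taz2-helix starts); in the helix-state
ensemble Phe19 occupies its MDM2-bound-like (anchor-type) rotamer ~59% of
the time but its Taz2-bound-like conformation only ~12% — the reverse of the
empirical rotamer-library preference (31.71% vs 47.08%), which is the
signature of helix-conditioned anchor preformation.

The same stages are available as a CLI (`idpanchor anchors | populations |
joint | transitions | unfold | simulate | report`); every output file starts
with a header echoing the version, a config hash and all thresholds.

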