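# Default rotamer-region definitions and bound-state reference conformations
# for the p53 N-terminal segment (Glu17-Asn29).
#
# All intervals are circular half-open [lo, hi) in degrees.  The region
# bounds below are ESTIMATES placed at standard rotamer-well boundaries
# (gauche-/trans/gauche+ thirds for chi1, sign halves for Trp chi2); they are
# configuration, not measured values.  Among the bound references, only the
# Phe19 MDM2-bound pair (chi1 177, chi2 71) is a published bound-pose value;
# the remaining references are representative rotamer centres for the bound
# conformations and should be replaced with complex-derived angles when the
# experimental structures are available.
#
# Phe19 chi2 is symmetry-folded into [-90, 90) upstream, so its regions and
# references live on the folded circle.

chain_id: A
match_tolerance: 40.0   # deg per chi angle, circular distance, both must match

region_sets:
  - seq_id: 19
    residue: PHE
    regions:             # chi1 only; chi2 not distinguished (ring symmetry)
      - {label: A, chi1: [120.0, -120.0]}    # trans well, holds the MDM2-bound 177
      - {label: B, chi1: [-120.0, 0.0]}      # gauche- well (Taz2-bound-like)
      - {label: C, chi1: [0.0, 120.0]}       # gauche+ well
  - seq_id: 22
    residue: LEU
    regions:
      - {label: mt, chi1: [-120.0, 0.0], chi2: [120.0, -120.0]}
      - {label: tp, chi1: [120.0, -120.0], chi2: [0.0, 120.0]}
  - seq_id: 23
    residue: TRP
    regions:             # chi1 thirds x chi2 sign halves -> six rectangles
      - {label: "1", chi1: [120.0, -120.0], chi2: [0.0, 180.0]}   # MDM2-bound-like
      - {label: "2", chi1: [120.0, -120.0], chi2: [-180.0, 0.0]}
      - {label: "3", chi1: [-120.0, 0.0], chi2: [0.0, 180.0]}     # Taz2-bound-like
      - {label: "4", chi1: [-120.0, 0.0], chi2: [-180.0, 0.0]}
      - {label: "5", chi1: [0.0, 120.0], chi2: [0.0, 180.0]}
      - {label: "6", chi1: [0.0, 120.0], chi2: [-180.0, 0.0]}
  - seq_id: 26
    residue: LEU
    regions:
      - {label: mt, chi1: [-120.0, 0.0], chi2: [120.0, -120.0]}
      - {label: tp, chi1: [120.0, -120.0], chi2: [0.0, 120.0]}

bound_references:
  - {seq_id: 19, complex: p53N-MDM2, chi1: 177.0, chi2: 71.0, role: anchor-type}
  - {seq_id: 19, complex: p53N-Taz2, chi1: -65.0, chi2: -30.0, role: non-anchor}
  - {seq_id: 22, complex: p53N-MDM2, chi1: 177.0, chi2: 65.0, role: non-anchor}
  - {seq_id: 22, complex: p53N-Taz2, chi1: -65.0, chi2: 175.0, role: anchor-type}
  - {seq_id: 23, complex: p53N-MDM2, chi1: 180.0, chi2: 90.0, role: anchor-type}
  - {seq_id: 23, complex: p53N-Taz2, chi1: -60.0, chi2: 90.0, role: non-anchor}
  - {seq_id: 26, complex: p53N-MDM2, chi1: -65.0, chi2: 175.0, role: anchor-type}
  - {seq_id: 26, complex: p53N-Taz2, chi1: 177.0, chi2: 65.0, role: non-anchor}
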