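#!/usr/bin/env python
"""Bound-like rotamer populations, joint occupancy and transition counts.

Regenerates the helix-state, disordered-state and joint-coupled ensembles
(same seeds as analysis/01_simulate_ensembles.py), measures for each anchor
residue the population of its anchor-type and non-anchor bound-like
conformations, compares them against the packaged rotamer-library
reference, builds the 18-cell Phe19 x Trp23 joint matrix, and counts
rotamer transitions.
"""

import argparse
from pathlib import Path

import pandas as pd

from idpanchor.conformational_states import (
    classify_frames,
    compare_with_library,
    count_transitions,
    extract_chi_series,
    joint_population,
    load_region_config,
    population,
    population_table,
)
from idpanchor.synthetic_ensembles import (
    DISORDERED_STATE_TARGETS,
    HELIX_STATE_TARGETS,
    GeneratorSpec,
    joint_from_marginals,
    sample_ensemble,
)

NAMES = {19: "Phe19", 22: "Leu22", 23: "Trp23", 26: "Leu26"}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-frames", type=int, default=400)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    region_sets, bound_refs = load_region_config()

    ensembles = {
        "helix": sample_ensemble(GeneratorSpec(
            n_frames=args.n_frames, backbone="helix",
            rotamer_targets=HELIX_STATE_TARGETS, seed=args.seed))[0],
        "disordered": sample_ensemble(GeneratorSpec(
            n_frames=args.n_frames, backbone="coil",
            rotamer_targets=DISORDERED_STATE_TARGETS, seed=args.seed + 1))[0],
    }

    tables = []
    lib_input = {}
    for state, ens in ensembles.items():
        for seq_id, name in NAMES.items():
            chi1, chi2 = extract_chi_series(ens, "A", seq_id)
            labels = classify_frames(chi1, chi2, region_sets[seq_id])
            refs = [r for r in bound_refs if r.residue_key == ("A", seq_id)]
            tables.append(population_table(("A", seq_id), state, labels,
                                           region_sets[seq_id], refs, chi1, chi2))
            for ref in refs:
                est = population(ref, chi1=chi1, chi2=chi2)
                if state == "helix":
                    lib_input[(name, ref.complex_label)] = est.fraction
                print(f"{state:10s} {name} {ref.complex_label} ({ref.role}): "
                      f"{100 * est.fraction:.1f}% +/- {100 * est.se:.1f}%")
    pops = pd.concat(tables, ignore_index=True)
    pops.to_csv(args.outdir / "04_populations.tsv", sep="\t", index=False,
                float_format="%.4f")

    lib_cmp = compare_with_library(lib_input)
    lib_cmp.to_csv(args.outdir / "04_library_comparison.tsv", sep="\t",
                   index=False, float_format="%.2f")
    rev = lib_cmp.loc[lib_cmp["reversed"], "residue"].unique()
    print(f"library-preference reversal in the helix state for: {list(rev)}")

    joint_ens = sample_ensemble(GeneratorSpec(
        n_frames=args.n_frames, backbone="helix",
        joint_targets={(19, 23): joint_from_marginals(
            {"A": 0.595, "B": 0.405}, {"1": 0.624, "4": 0.376},
            forced={("A", "1"): 0.51})},
        seed=args.seed + 2))[0]
    lab = {}
    for seq_id in (19, 23):
        chi1, chi2 = extract_chi_series(joint_ens, "A", seq_id)
        lab[seq_id] = classify_frames(chi1, chi2, region_sets[seq_id])
    mat = joint_population(lab[19], lab[23])
    mat.to_csv(args.outdir / "04_joint_phe19_trp23.tsv", sep="\t",
               float_format="%.4f")
    print(f"joint Phe19/Trp23: P(A,1) = {100 * mat.loc['A', '1']:.1f}% "
          f"(marginals A {100 * mat.sum(axis=1)['A']:.1f}%, "
          f"1 {100 * mat.sum(axis=0)['1']:.1f}%)")

    for seq_id in (19, 23):
        n = count_transitions(lab[seq_id], min_dwell_frames=1)
        print(f"rotamer transitions of {NAMES[seq_id]} over "
              f"{args.n_frames} frames: {n}")


if __name__ == "__main__":
    main()
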