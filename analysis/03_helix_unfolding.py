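#!/usr/bin/env python
"""Helix unfolding times: scripted trajectories plus the published table.

Runs unfolding detection on a scripted helix-to-coil step trajectory (the
controllable stand-in for an MD run) and on a switching trajectory from the
generator, then summarises the packaged reference unfolding-time table per
trajectory group (MS = MDM2-helix starts, TS = Taz2-helix starts, DS =
disordered starts).
"""

import argparse
from pathlib import Path

from idpanchor.helix_dynamics import (
    detect_unfolding,
    load_reference_unfolding_times,
    partition_states,
    summarize_unfolding,
)
from idpanchor.structure_io import Ensemble
from idpanchor.synthetic_ensembles import GeneratorSpec, build_peptide, sample_ensemble


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    helix = build_peptide()
    coil = build_peptide(backbone="extended")
    step = Ensemble(frames=[helix] * 50 + [coil] * 20, dt=0.5, label="step")
    res = detect_unfolding(step, helix, dwell=5)
    h_idx, d_idx = partition_states(step, res, equilibration_ns=1.0)
    print(f"step trajectory: unfolds at frame {res.unfolding_frame} "
          f"({res.unfolding_time_ns} ns); "
          f"{len(h_idx)} helix-state / {len(d_idx)} disordered-state frames")

    spec = GeneratorSpec(n_frames=300, backbone="helix", backbone_mean_dwell=120,
                         seed=args.seed, label="switching")
    ens, gt = sample_ensemble(spec)
    res2 = detect_unfolding(ens, helix, dwell=5)
    first_switch = gt.switch_frames[0] if gt.switch_frames else None
    print(f"switching trajectory: first constructed switch at frame "
          f"{first_switch}, detected unfolding frame {res2.unfolding_frame}")

    summary = summarize_unfolding(load_reference_unfolding_times())
    out = args.outdir / "03_unfolding_summary.tsv"
    out.write_text("# group summary of the packaged unfolding-time table\n"
                   + summary.to_csv(sep="\t", float_format="%.2f"))
    print(f"reference table: MS mean {summary.loc['MS', 'mean_ns']:.1f} ns "
          f"(sd {summary.loc['MS', 'sd_ns']:.1f}), "
          f"TS mean {summary.loc['TS', 'mean_ns']:.1f} ns "
          f"(sd {summary.loc['TS', 'sd_ns']:.1f}) -> {out}")


if __name__ == "__main__":
    main()
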