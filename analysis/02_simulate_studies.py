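#!/usr/bin/env python
"""Simulate the study designs the downstream analyses consume.

Three cross-sectional cohorts emulate a precursor-stage comparison (healthy
donors, MGUS-like, SMM-like — all at the same baseline 20% latent activity,
since pathway activity is not expected to change across these stages), one
cohort emulates an NFκB-high molecular cluster (80% latent activity), and a
paired longitudinal study emulates an 8-patient relapse design with the
pathway activity shift and BCL2A1 upregulation switched on
(couple_bcl2_to_pathway=True, so differential BCL2A1 tracks the pathway).

Writes: <name>_matrix.tsv / _annotations.tsv per study.
"""

import argparse
from pathlib import Path

from pathscore.expression_io import write_annotations, write_matrix
from pathscore.sta_engine import load_model
from pathscore.synthetic_data import (
    CohortSpec,
    LongitudinalSpec,
    simulate_cohort,
    simulate_longitudinal_study,
)

COHORTS = (
    ("healthy", 18, 0.2),
    ("MGUS", 40, 0.2),
    ("SMM", 12, 0.2),
    ("NFKB_cluster", 22, 0.8),
)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=11)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)
    model = load_model(args.out_dir / "model.json")

    for i, (label, n, rate) in enumerate(COHORTS):
        matrix, truth = simulate_cohort(
            model,
            CohortSpec(n_samples=n, activity_rate=rate, cohort_label=label,
                       seed=args.seed + i),
        )
        write_matrix(matrix, args.out_dir / f"{label}_matrix.tsv")
        write_annotations(matrix.annotations, args.out_dir / f"{label}_annotations.tsv")
        print(f"cohort {label}: n={n}, latent activity rate {rate:.0%}, "
              f"truly active {int(truth.latent_state.sum())}")

    spec = LongitudinalSpec(seed=args.seed + 10, couple_bcl2_to_pathway=True)
    matrix, truth = simulate_longitudinal_study(model, spec)
    write_matrix(matrix, args.out_dir / "longitudinal_matrix.tsv")
    write_annotations(matrix.annotations, args.out_dir / "longitudinal_annotations.tsv")
    up = truth.bcl2a1_upregulated
    print(f"longitudinal: {spec.n_patients} patients x {len(spec.timepoints)} "
          f"timepoints; BCL2A1 upregulated in {int(up.sum())}/{len(up)} patients "
          f"at {spec.fold_change_magnitude:g}-fold")


if __name__ == "__main__":
    main()
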