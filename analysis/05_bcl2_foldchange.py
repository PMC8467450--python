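#!/usr/bin/env python
"""Paired >2-fold classification of the six BCL-2 family transcripts.

For each patient of the longitudinal study, computes the linear fold change
of each BCL-2 family gene between diagnosis and second-line induction
(relapse) and reports the percentage of patients exceeding 2-fold per gene,
split into NFκB-regulated (BCL2A1, BCL2L1, BCL2) and NFκB-independent
(BCL2L10, MCL1, BCL2L2) members.  The study was generated with 5/8 patients
carrying a 4-fold BCL2A1 multiplier, so BCL2A1 should report 62.5%.

Writes: foldchange.tsv
"""

import argparse
from pathlib import Path

from pathscore.bcl2_analysis import (
    BCL2_FAMILY_GENES,
    PairedDesign,
    classify_fold_changes,
    paired_fold_change,
)
from pathscore.expression_io import ProbesetAnnotation, map_probesets, read_matrix


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    matrix = read_matrix(
        args.out_dir / "longitudinal_matrix.tsv",
        annotations_path=args.out_dir / "longitudinal_annotations.tsv",
    )
    annotation = ProbesetAnnotation.from_synthetic_ids(matrix.probeset_ids)
    gm = map_probesets(matrix, annotation, genes=list(BCL2_FAMILY_GENES))
    design = PairedDesign.from_annotations(matrix.annotations, "diagnosis",
                                           "induction_2")
    ratios = paired_fold_change(gm, design, list(BCL2_FAMILY_GENES))
    result = classify_fold_changes(ratios)

    lines = ["gene\tgroup\tpct_over_2fold\tn_flagged\tn_patients"]
    for group, pct in result.partitioned_percentages().items():
        print(f"{group}:")
        for gene, value in pct.items():
            n_flagged = int(result.flags[gene].sum())
            print(f"  {gene}: {value:.1f}% ({n_flagged}/{len(design.pairs)} patients "
                  f">{result.threshold:g}-fold)")
            lines.append(f"{gene}\t{group}\t{value!r}\t{n_flagged}\t{len(design.pairs)}")
    (args.out_dir / "foldchange.tsv").write_text("\n".join(lines) + "\n")


if __name__ == "__main__":
    main()
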