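"""Reusable in-silico experiments over the synthetic studies.

These functions bundle the simulate → calibrate → score → test chains the
analysis drivers, test suite, and reproduction script all run: building the
default calibrated model, measuring relapse-detection power and null
calibration over replicate longitudinal studies, and recovering fold-change
fractions from a single relapse study.

Replicate studies simulate only the two compared timepoints and omit
background genes: neither enters the activity score nor the paired test,
so this is a pure cost saving, not a change of conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bcl2_analysis import (
    BCL2_FAMILY_GENES,
    PairedDesign,
    classify_fold_changes,
    paired_fold_change,
)
from .cohort_analysis import paired_increase_test
from .expression_io import ExpressionMatrix, ProbesetAnnotation, map_probesets
from .sta_engine import PathwayModel, build_model, calibrate, score_matrix
from .synthetic_data import (
    LongitudinalSpec,
    simulate_calibration_set,
    simulate_longitudinal_study,
    simulation_panel,
)

#: default calibration-set size per label
CALIBRATION_N = 25


def default_calibrated_model(seed: int = 0, noise_sd: float = 0.5) -> PathwayModel:
    """Reference model calibrated on a simulated labelled training set."""
    panel = simulation_panel()
    reference = build_model(panel)
    training = simulate_calibration_set(
        reference, CALIBRATION_N, CALIBRATION_N, noise_sd=noise_sd, seed=seed
    )
    return calibrate(panel, training)


def score_series(model: PathwayModel, matrix: ExpressionMatrix) -> pd.Series:
    """0–100 activity scores indexed by sample id."""
    return pd.Series(
        {s.sample_id: s.score for s in score_matrix(model, matrix)}, name="score"
    )


def paired_relapse_pvalue(
    model: PathwayModel, spec: LongitudinalSpec, *, test_seed: int
) -> float:
    """One replicate: simulate, score, and run the paired one-sided test."""
    matrix, _ = simulate_longitudinal_study(model, spec)
    scores = score_series(model, matrix)
    baseline_tp, followup_tp = spec.timepoints[0], spec.timepoints[-1]
    design = PairedDesign.from_annotations(matrix.annotations, baseline_tp, followup_tp)
    baseline = [scores[b] for b, _ in design.pairs.values()]
    followup = [scores[f] for _, f in design.pairs.values()]
    _, p = paired_increase_test(baseline, followup, seed=test_seed)
    return p


def relapse_detection_rate(
    model: PathwayModel,
    *,
    n_replicates: int,
    activity_shift: float,
    n_patients: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of replicate longitudinal studies detecting the relapse shift.

    With ``activity_shift=0`` this measures the test's type-I error rate.
    """
    rejections = 0
    for rep in range(n_replicates):
        spec = LongitudinalSpec(
            n_patients=n_patients,
            timepoints=("diagnosis", "induction_2"),
            relapse_timepoints=("induction_2",),
            activity_shift_at_relapse=activity_shift,
            n_background_genes=0,
            seed=seed + rep,
        )
        if paired_relapse_pvalue(model, spec, test_seed=seed + rep) < alpha:
            rejections += 1
    return rejections / n_replicates


def foldchange_recovery(
    model: PathwayModel,
    *,
    n_patients: int = 8,
    upregulated_fraction: float = 0.625,
    fold_change_magnitude: float = 4.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.Series:
    """Per-gene >2-fold percentages from one low-noise relapse study."""
    spec = LongitudinalSpec(
        n_patients=n_patients,
        bcl2a1_upregulated_fraction=upregulated_fraction,
        fold_change_magnitude=fold_change_magnitude,
        noise_sd=noise_sd,
        seed=seed,
    )
    matrix, truth = simulate_longitudinal_study(model, spec)
    annotation = ProbesetAnnotation(dict(truth.probeset_to_gene))
    gm = map_probesets(matrix, annotation, genes=list(BCL2_FAMILY_GENES))
    design = PairedDesign.from_annotations(
        matrix.annotations, "diagnosis", "induction_2"
    )
    ratios = paired_fold_change(gm, design, list(BCL2_FAMILY_GENES))
    return classify_fold_changes(ratios).percentages
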