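"""Synthetic expression studies with known ground truth.

Emulates the study designs the pipeline consumes: cross-sectional cohorts
with a binary latent pathway state per sample, labelled calibration sets,
and longitudinal paired designs in which pathway activity rises at relapse
and a configurable fraction of patients upregulate *BCL2A1*.

Generative model (all on the log2 scale, additive Gaussian noise):

* each sample carries a latent pathway state drawn Bernoulli(activity rate);
* each panel gene draws a binary transcription state from the model's CPT
  given that latent state; its probesets read
  ``mu_low + effect_size·[transcribed] + N(0, noise_sd)``;
* background genes are pure noise around a common baseline;
* the six BCL-2 family genes (BCL2A1, BCL2L1, BCL2, BCL2L10, MCL1, BCL2L2)
  are always generated by a dedicated rule: background level plus explicit
  per-patient multipliers, independent of the latent pathway node by
  default.  Setting ``couple_bcl2_to_pathway`` ties BCL2A1, BCL2L1 and BCL2
  to the latent state (they are direct NFκB targets), which is the scenario
  in which differential BCL2A1 expression correlates with differential
  target-gene expression.  Because the family rule overrides the panel rule,
  synthetic studies are normally scored with :func:`simulation_panel`, the
  default panel minus the family genes, so that family-gene regulation can
  be toggled without feeding back into the activity score.
* longitudinal designs add a per-patient baseline offset (random effect) to
  every intensity, making paired analyses genuinely better than unpaired.

Identical spec + seed ⇒ bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression_io import ExpressionMatrix
from .sta_engine import (
    ACTIVE,
    INACTIVE,
    CalibrationSet,
    PanelGene,
    PathwayModel,
    default_panel,
)

#: NFκB-regulated pro-survival BCL-2 family members
BCL2_NFKB_REGULATED = ("BCL2A1", "BCL2L1", "BCL2")
#: NFκB-independent pro-survival BCL-2 family members
BCL2_NFKB_INDEPENDENT = ("BCL2L10", "MCL1", "BCL2L2")
BCL2_FAMILY = BCL2_NFKB_REGULATED + BCL2_NFKB_INDEPENDENT

DEFAULT_TIMEPOINTS = ("diagnosis", "induction_1", "induction_2", "maintenance")
DEFAULT_RELAPSE_TIMEPOINTS = ("induction_2", "maintenance")


def simulation_panel() -> tuple[PanelGene, ...]:
    """Default panel restricted to non-BCL-2-family genes.

    The generator produces BCL-2 family probesets by its own rule, so
    scoring synthetic studies with this panel keeps the activity score
    independent of the family genes' configured regulation.
    """
    return tuple(pg for pg in default_panel() if pg.symbol not in BCL2_FAMILY)


@dataclass(frozen=True)
class CohortSpec:
    """Conditions for one cross-sectional cohort.

    ``activity_rate`` may be a probability or an explicit per-sample tuple
    of 0/1 latent states.
    """

    n_samples: int
    activity_rate: float | tuple[int, ...] = 0.2
    effect_size: float = 2.0
    noise_sd: float = 0.5
    n_background_genes: int = 200
    background_baseline: float = 6.0
    couple_bcl2_to_pathway: bool = False
    cohort_label: str = "cohort"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValidationError("n_samples must be ≥ 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be ≥ 0")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be ≥ 0")
        if self.n_background_genes < 0:
            raise ValidationError("n_background_genes must be ≥ 0")
        if isinstance(self.activity_rate, (tuple, list)):
            states = tuple(int(s) for s in self.activity_rate)
            if len(states) != self.n_samples:
                raise ValidationError(
                    "explicit activity states must match n_samples"
                )
            if any(s not in (0, 1) for s in states):
                raise ValidationError("explicit activity states must be 0/1")
            object.__setattr__(self, "activity_rate", states)
        elif not (0.0 <= float(self.activity_rate) <= 1.0):
            raise ValidationError("activity_rate must lie in [0,1]")


@dataclass(frozen=True)
class LongitudinalSpec:
    """Conditions for a paired longitudinal study.

    Defaults mirror a two-line total-therapy design: samples at diagnosis,
    after first-line induction, after second-line induction (relapse), and
    before maintenance; the latent activation probability rises by
    ``activity_shift_at_relapse`` at the relapse timepoints, and a
    ``bcl2a1_upregulated_fraction`` of patients (rounded to whole patients)
    multiply their *BCL2A1* expression by ``fold_change_magnitude`` there.
    """

    n_patients: int = 8
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    relapse_timepoints: tuple[str, ...] = DEFAULT_RELAPSE_TIMEPOINTS
    baseline_activity_rate: float = 0.2
    activity_shift_at_relapse: float = 0.6
    bcl2a1_upregulated_fraction: float = 0.625
    fold_change_magnitude: float = 4.0
    effect_size: float = 2.0
    noise_sd: float = 0.5
    patient_effect_sd: float = 0.3
    n_background_genes: int = 200
    background_baseline: float = 6.0
    couple_bcl2_to_pathway: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be ≥ 1")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ValidationError("duplicate timepoint labels")
        unknown = [t for t in self.relapse_timepoints if t not in self.timepoints]
        if unknown:
            raise ValidationError(f"relapse timepoints not in timepoints: {unknown}")
        if not (0.0 <= self.bcl2a1_upregulated_fraction <= 1.0):
            raise ValidationError("bcl2a1_upregulated_fraction must lie in [0,1]")
        if self.fold_change_magnitude <= 0:
            raise ValidationError("fold_change_magnitude must be > 0")
        if self.noise_sd < 0 or self.patient_effect_sd < 0:
            raise ValidationError("noise standard deviations must be ≥ 0")
        if not (0.0 <= self.baseline_activity_rate <= 1.0):
            raise ValidationError("baseline_activity_rate must lie in [0,1]")


@dataclass
class GroundTruth:
    """Latent truth emitted alongside every simulated matrix."""

    latent_state: pd.Series
    transcription: pd.DataFrame
    probeset_to_gene: dict[str, str]
    bcl2a1_upregulated: pd.Series | None = None


# ---------------------------------------------------------------------------
# core generator
# ---------------------------------------------------------------------------


def _family_baselines(baseline: float) -> dict[str, float]:
    return {g: baseline for g in BCL2_FAMILY}


def _generate_samples(
    model: PathwayModel,
    latent: np.ndarray,
    sample_ids: list[str],
    *,
    effect_size: float,
    noise_sd: float,
    n_background_genes: int,
    background_baseline: float,
    couple_bcl2: bool,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Shared generative core; returns (matrix, transcription truth, ps→gene)."""
    n = len(sample_ids)
    rows: dict[str, np.ndarray] = {}
    probeset_to_gene: dict[str, str] = {}
    tx_records: dict[str, np.ndarray] = {}

    # panel genes (family genes are handled by the dedicated family rule)
    for gene in model.genes:
        if gene.symbol in BCL2_FAMILY:
            continue
        p = np.where(latent == 1, gene.p_tx_given_active, gene.p_tx_given_inactive)
        tx = (rng.random(n) < p).astype(int)
        tx_records[gene.symbol] = tx
        for ps in gene.probesets:
            noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
            rows[ps.probeset_id] = ps.mu_low + effect_size * tx + noise
            probeset_to_gene[ps.probeset_id] = gene.symbol

    # BCL-2 family genes: background level, optionally coupled to the pathway
    family_ids: dict[str, list[str]] = {}
    panel_family = {
        g.symbol: [ps.probeset_id for ps in g.probesets]
        for g in model.genes
        if g.symbol in BCL2_FAMILY
    }
    baselines = _family_baselines(background_baseline)
    for sym in BCL2_FAMILY:
        ids = panel_family.get(sym, [f"{sym}_ps1"])
        family_ids[sym] = ids
        coupled = couple_bcl2 and sym in BCL2_NFKB_REGULATED
        if coupled:
            p = np.where(latent == 1, 0.9, 0.1)
            tx = (rng.random(n) < p).astype(int)
            tx_records[sym] = tx
        else:
            tx = np.zeros(n, dtype=int)
        for pid in ids:
            noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
            rows[pid] = baselines[sym] + effect_size * tx + noise
            probeset_to_gene[pid] = sym

    # background genes: pure noise
    for i in range(n_background_genes):
        pid = f"BG{i + 1:04d}_ps1"
        noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
        rows[pid] = background_baseline + noise
        probeset_to_gene[pid] = f"BG{i + 1:04d}"

    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    transcription = pd.DataFrame.from_dict(
        tx_records, orient="index", columns=sample_ids
    )
    return matrix, transcription, probeset_to_gene


def simulate_cohort(
    model: PathwayModel, spec: CohortSpec
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Cross-sectional cohort with latent per-sample pathway states."""
    rng = np.random.default_rng(spec.seed)
    sample_ids = [f"{spec.cohort_label}_S{i + 1:03d}" for i in range(spec.n_samples)]
    if isinstance(spec.activity_rate, tuple):
        latent = np.array(spec.activity_rate, dtype=int)
    else:
        latent = (rng.random(spec.n_samples) < float(spec.activity_rate)).astype(int)
    data, transcription, ps2gene = _generate_samples(
        model,
        latent,
        sample_ids,
        effect_size=spec.effect_size,
        noise_sd=spec.noise_sd,
        n_background_genes=spec.n_background_genes,
        background_baseline=spec.background_baseline,
        couple_bcl2=spec.couple_bcl2_to_pathway,
        rng=rng,
    )
    annotations = pd.DataFrame(
        {
            "cohort": spec.cohort_label,
            "patient_id": sample_ids,
            "timepoint": "",
            "label": "",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = GroundTruth(
        latent_state=pd.Series(latent, index=sample_ids, name="latent_state"),
        transcription=transcription,
        probeset_to_gene=ps2gene,
    )
    return ExpressionMatrix(data, annotations), truth


def simulate_calibration_set(
    model: PathwayModel,
    n_active: int,
    n_inactive: int,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> CalibrationSet:
    """Labelled training profiles drawn from the model's own emissions.

    The transcription state is set deterministically to the modal state
    given the label (transcribed for up-responsive genes in active samples,
    and so on), so that at ``noise_sd=0`` calibration reproduces the model's
    emission means exactly — a closed generative loop.
    """
    if n_active < 1 or n_inactive < 1:
        raise ValidationError("need at least one sample per label")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be ≥ 0")
    rng = np.random.default_rng(seed)
    profiles: list[dict[str, float]] = []
    labels: list[str] = []
    for label, count in ((ACTIVE, n_active), (INACTIVE, n_inactive)):
        for _ in range(count):
            profile: dict[str, float] = {}
            for gene in model.genes:
                if label == ACTIVE:
                    transcribed = gene.direction == "up"
                else:
                    transcribed = gene.direction == "down"
                for ps in gene.probesets:
                    mu = ps.mu_high if transcribed else ps.mu_low
                    eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                    profile[ps.probeset_id] = mu + eps
            profiles.append(profile)
            labels.append(label)
    return CalibrationSet(profiles=profiles, labels=labels)


def simulate_longitudinal_study(
    model: PathwayModel, spec: LongitudinalSpec
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Paired multi-timepoint study with a relapse activity shift.

    The number of *BCL2A1*-upregulated patients is
    ``round(fraction · n_patients)``, drawn without replacement, so the
    realised fraction is exact rather than Bernoulli — fold-change
    percentages computed downstream recover the configured fraction
    deterministically at low noise.
    """
    rng = np.random.default_rng(spec.seed)
    patients = [f"P{i + 1:02d}" for i in range(spec.n_patients)]
    n_up = int(round(spec.bcl2a1_upregulated_fraction * spec.n_patients))
    up_idx = set(rng.choice(spec.n_patients, size=n_up, replace=False).tolist())
    offsets = (
        rng.normal(0.0, spec.patient_effect_sd, spec.n_patients)
        if spec.patient_effect_sd > 0
        else np.zeros(spec.n_patients)
    )

    sample_ids: list[str] = []
    latent_list: list[int] = []
    ann_rows: list[tuple[str, str, str]] = []
    for ti, tp in enumerate(spec.timepoints):
        is_relapse = tp in spec.relapse_timepoints
        p_active = float(
            np.clip(
                spec.baseline_activity_rate
                + (spec.activity_shift_at_relapse if is_relapse else 0.0),
                0.0,
                1.0,
            )
        )
        for pi, pid in enumerate(patients):
            sid = f"{pid}_{tp}"
            sample_ids.append(sid)
            latent_list.append(int(rng.random() < p_active))
            ann_rows.append((sid, pid, tp))
    latent = np.array(latent_list, dtype=int)

    data, transcription, ps2gene = _generate_samples(
        model,
        latent,
        sample_ids,
        effect_size=spec.effect_size,
        noise_sd=spec.noise_sd,
        n_background_genes=spec.n_background_genes,
        background_baseline=spec.background_baseline,
        couple_bcl2=spec.couple_bcl2_to_pathway,
        rng=rng,
    )

    # per-patient baseline offsets, identical across that patient's samples
    offset_by_sample = np.array(
        [offsets[patients.index(pid)] for _, pid, _ in ann_rows]
    )
    data = data + offset_by_sample[np.newaxis, :]

    # BCL2A1 multiplier at relapse timepoints for the selected patients
    log2_fc = float(np.log2(spec.fold_change_magnitude))
    bcl2a1_rows = [p for p, g in ps2gene.items() if g == "BCL2A1"]
    for j, (sid, pid, tp) in enumerate(ann_rows):
        if patients.index(pid) in up_idx and tp in spec.relapse_timepoints:
            data.loc[bcl2a1_rows, sid] = data.loc[bcl2a1_rows, sid] + log2_fc

    annotations = pd.DataFrame(
        {
            "cohort": "longitudinal",
            "patient_id": [pid for _, pid, _ in ann_rows],
            "timepoint": [tp for _, _, tp in ann_rows],
            "label": "",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = GroundTruth(
        latent_state=pd.Series(latent, index=sample_ids, name="latent_state"),
        transcription=transcription,
        probeset_to_gene=ps2gene,
        bcl2a1_upregulated=pd.Series(
            [i in up_idx for i in range(spec.n_patients)],
            index=patients,
            name="bcl2a1_upregulated",
        ),
    )
    return ExpressionMatrix(data, annotations), truth
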