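"""Paired relapse analyses of the pro-survival BCL-2 gene family.

Three questions, mirroring the relapse work-up of a paired
diagnosis/relapse design:

* per patient and gene, the linear fold change ``2^(followup − baseline)``
  of log2 expression between the two timepoints;
* the per-gene percentage of patients exceeding a fold-change threshold
  (strict ``>``, default 2-fold), reported separately for the
  NFκB-regulated trio (BCL2A1, BCL2L1, BCL2) and the NFκB-independent trio
  (BCL2L10, MCL1, BCL2L2);
* the correlation between differential anchor-gene expression (ΔBCL2A1)
  and differential expression of each pathway target gene, as Pearson R
  from a per-target simple linear regression of Δtarget on Δanchor.  No
  multiple-testing correction is applied across the target panel; read the
  table accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_analysis import GroupComparisonResult, compare_groups
from .errors import ValidationError
from .expression_io import ExpressionMatrix

NFKB_REGULATED = ("BCL2A1", "BCL2L1", "BCL2")
NFKB_INDEPENDENT = ("BCL2L10", "MCL1", "BCL2L2")
BCL2_FAMILY_GENES = NFKB_REGULATED + NFKB_INDEPENDENT

FOLD_CHANGE_THRESHOLD = 2.0


@dataclass(frozen=True)
class PairedDesign:
    """patient → (baseline sample, follow-up sample) pairing."""

    pairs: Mapping[str, tuple[str, str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for pid, (b, f) in self.pairs.items():
            for sid in (b, f):
                if sid in seen:
                    raise ValidationError(
                        f"sample {sid!r} appears in more than one pair"
                    )
                seen.add(sid)
        object.__setattr__(self, "pairs", dict(self.pairs))

    @property
    def patients(self) -> list[str]:
        return list(self.pairs)

    @classmethod
    def from_annotations(
        cls,
        annotations: pd.DataFrame,
        baseline_timepoint: str,
        followup_timepoint: str,
    ) -> "PairedDesign":
        """Pair samples of each patient across two annotated timepoints.

        Patients lacking either timepoint are silently excluded (ragged
        panels are expected in longitudinal cohorts).
        """
        pairs = {}
        for pid, sub in annotations.groupby("patient_id", sort=True):
            by_tp = dict(zip(sub["timepoint"], sub.index))
            if baseline_timepoint in by_tp and followup_timepoint in by_tp:
                pairs[str(pid)] = (
                    str(by_tp[baseline_timepoint]),
                    str(by_tp[followup_timepoint]),
                )
        if not pairs:
            raise ValidationError(
                f"no patient has both timepoints "
                f"{baseline_timepoint!r} and {followup_timepoint!r}"
            )
        return cls(pairs)


@dataclass
class FoldChangeResult:
    """Per-patient ratios, threshold flags, and per-gene percentages."""

    ratios: pd.DataFrame  # patients × genes, linear scale
    flags: pd.DataFrame  # patients × genes, bool (ratio > threshold)
    percentages: pd.Series  # per gene, 0–100
    threshold: float

    def partitioned_percentages(self) -> dict[str, pd.Series]:
        """Percentages split into NFκB-regulated / -independent reporting groups."""
        out = {}
        reg = [g for g in self.percentages.index if g in NFKB_REGULATED]
        ind = [g for g in self.percentages.index if g in NFKB_INDEPENDENT]
        other = [
            g for g in self.percentages.index if g not in NFKB_REGULATED + NFKB_INDEPENDENT
        ]
        if reg:
            out["nfkb_regulated"] = self.percentages[reg]
        if ind:
            out["nfkb_independent"] = self.percentages[ind]
        if other:
            out["other"] = self.percentages[other]
        return out


def _check_design_samples(matrix: ExpressionMatrix, design: PairedDesign) -> None:
    cols = set(matrix.sample_ids)
    missing = [
        sid
        for pair in design.pairs.values()
        for sid in pair
        if sid not in cols
    ]
    if missing:
        raise ValidationError(f"design samples absent from the matrix: {missing}")


def paired_fold_change(
    gene_matrix: ExpressionMatrix,
    design: PairedDesign,
    genes: Sequence[str],
) -> pd.DataFrame:
    """Linear fold change per (patient, gene) between paired samples.

    Expects a gene-level matrix (see
    :func:`pathscore.expression_io.map_probesets`); the ratio is
    ``2^(followup_log2 − baseline_log2)``.
    """
    missing_genes = [g for g in genes if g not in set(gene_matrix.probeset_ids)]
    if missing_genes:
        raise ValidationError(f"genes absent from the matrix: {missing_genes}")
    _check_design_samples(gene_matrix, design)
    data = gene_matrix.data
    out = {}
    for pid, (b, f) in design.pairs.items():
        delta = data.loc[list(genes), f].to_numpy() - data.loc[list(genes), b].to_numpy()
        out[pid] = 2.0 ** delta
    return pd.DataFrame.from_dict(out, orient="index", columns=list(genes))


def classify_fold_changes(
    ratios: pd.DataFrame, threshold: float = FOLD_CHANGE_THRESHOLD
) -> FoldChangeResult:
    """Flag ratios strictly above ``threshold``; report per-gene percentages.

    A ratio of exactly ``threshold`` is *not* flagged (strict inequality
    at the boundary).
    """
    if ratios.shape[0] == 0:
        raise ValidationError("empty design: no patients to classify")
    values = ratios.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)) or np.any(values <= 0):
        raise ValidationError("ratios must be finite and positive")
    flags = ratios > threshold
    percentages = 100.0 * flags.sum(axis=0) / flags.shape[0]
    return FoldChangeResult(
        ratios=ratios,
        flags=flags,
        percentages=percentages.rename("pct_over_threshold"),
        threshold=float(threshold),
    )


def differential_correlation(
    gene_matrix: ExpressionMatrix,
    design: PairedDesign,
    anchor_gene: str,
    target_genes: Sequence[str],
) -> pd.DataFrame:
    """Correlate differential anchor expression with each target's differential.

    Per patient, Δ = followup − baseline log2 expression.  For each target
    the simple linear regression of Δtarget on Δanchor yields Pearson R,
    the two-sided regression p value, and the slope.  Rows are sorted by
    decreasing R (heat-map order).  A target with zero Δ variance is
    reported with R = 0, slope = 0, p = 1 by convention.
    """
    if len(design.pairs) < 3:
        raise ValidationError("need ≥3 patients for differential correlation")
    genes = [anchor_gene, *target_genes]
    missing = [g for g in genes if g not in set(gene_matrix.probeset_ids)]
    if missing:
        raise ValidationError(f"genes absent from the matrix: {missing}")
    _check_design_samples(gene_matrix, design)
    data = gene_matrix.data
    baselines = [b for b, _ in design.pairs.values()]
    followups = [f for _, f in design.pairs.values()]
    delta = (
        data.loc[genes, followups].to_numpy() - data.loc[genes, baselines].to_numpy()
    )
    delta = pd.DataFrame(delta, index=genes, columns=design.patients)
    d_anchor = delta.loc[anchor_gene].to_numpy()
    if np.allclose(d_anchor, d_anchor[0]):
        raise ValidationError(
            f"zero variance in differential {anchor_gene} expression; R undefined"
        )
    records = []
    for g in target_genes:
        d_t = delta.loc[g].to_numpy()
        if np.allclose(d_t, d_t[0]):
            records.append((g, 0.0, 1.0, 0.0))
            continue
        fit = stats.linregress(d_anchor, d_t)
        records.append((g, float(fit.rvalue), float(fit.pvalue), float(fit.slope)))
    result = pd.DataFrame(records, columns=["gene", "r", "p", "slope"]).set_index(
        "gene"
    )
    return result.sort_values("r", ascending=False)


def cluster_expression_compare(
    gene_matrix: ExpressionMatrix,
    cluster_labels: Mapping[str, str] | pd.Series,
    gene: str,
) -> GroupComparisonResult:
    """Compare one gene's expression across molecular clusters.

    Delegates to :func:`pathscore.cohort_analysis.compare_groups` on the
    gene's values grouped by cluster label.
    """
    if gene not in set(gene_matrix.probeset_ids):
        raise ValidationError(f"gene {gene!r} absent from the matrix")
    labels = pd.Series(dict(cluster_labels) if not isinstance(cluster_labels, pd.Series)
                       else cluster_labels)
    values = gene_matrix.data.loc[gene]
    groups: dict[str, list[float]] = {}
    for sid, lab in labels.items():
        if sid in values.index:
            groups.setdefault(str(lab), []).append(float(values[sid]))
    return compare_groups(groups)
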