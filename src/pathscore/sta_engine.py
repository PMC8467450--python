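"""Three-layer Bayesian network for transcription-factor pathway activity.

The model infers, per sample, the probability that a pathway's driving
transcription complex is actively transcribing its target genes.  It is a
tree-structured Bayesian network with three layers:

* a single binary root node — pathway *active* / *inactive*;
* one binary node per target gene — the gene is / is not being transcribed,
  with a conditional probability table (CPT) linking it to the root;
* continuous evidence nodes — the log2 intensity of each microarray probeset
  interrogating a gene, modelled as a two-component Gaussian whose mean
  depends on the gene's transcription state (``mu_high`` when transcribed,
  ``mu_low`` when silent, shared ``sigma``).

Because genes are conditionally independent given the root and probesets are
conditionally independent given their gene, the root posterior is exact: each
gene's transcription state is summed out locally and the per-gene evidence
ratios multiply.  The posterior is reported as a probability, as capped
log2-odds, and as a 0–100 score obtained by an affine, clipped map of the
log2-odds between calibration anchors.

An optional hard-evidence mode binarises each probeset at the midpoint of its
two means instead of using Gaussian densities; it is provided for
sensitivity analysis, the soft Gaussian mode is the default.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logsumexp

from .errors import (
    CalibrationError,
    ConfigurationError,
    MissingEvidenceError,
    ParseError,
    ValidationError,
)

LN2 = math.log(2.0)

#: cap on reported log2-odds; keeps scores finite on saturated evidence
LOG2_ODDS_CAP = 20.0

#: lower bound on calibrated emission standard deviations (log2 units)
SIGMA_FLOOR = 0.05

#: evidence error rate used by the hard-binarisation mode
HARD_EVIDENCE_ERROR = 0.05

MODEL_FORMAT_VERSION = 1

ACTIVE, INACTIVE = "active", "inactive"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbesetEmission:
    """Two-state Gaussian emission for one probeset.

    ``mu_high`` is the expected log2 intensity when the parent gene is being
    transcribed, ``mu_low`` when it is not; ``sigma`` is shared between the
    two states.
    """

    probeset_id: str
    mu_low: float
    mu_high: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValidationError(
                f"probeset {self.probeset_id}: sigma must be > 0, got {self.sigma}"
            )
        for name in ("mu_low", "mu_high"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"probeset {self.probeset_id}: {name} not finite")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.mu_low + self.mu_high)


@dataclass(frozen=True)
class TargetGene:
    """One target gene of the pathway's transcription complex.

    ``direction`` is ``"up"`` when transcription becomes *more* likely with
    pathway activity and ``"down"`` when it becomes less likely;
    ``p_tx_given_active`` / ``p_tx_given_inactive`` are the CPT entries
    P(transcribed | pathway state).
    """

    symbol: str
    direction: str
    p_tx_given_active: float
    p_tx_given_inactive: float
    probesets: tuple[ProbesetEmission, ...]

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValidationError(
                f"gene {self.symbol}: direction must be 'up' or 'down'"
            )
        for name in ("p_tx_given_active", "p_tx_given_inactive"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"gene {self.symbol}: {name}={p} outside [0,1]")
        if self.direction == "up" and not (
            self.p_tx_given_active > self.p_tx_given_inactive
        ):
            raise ValidationError(
                f"gene {self.symbol}: up-responsive gene requires "
                "p_tx_given_active > p_tx_given_inactive"
            )
        if self.direction == "down" and not (
            self.p_tx_given_active < self.p_tx_given_inactive
        ):
            raise ValidationError(
                f"gene {self.symbol}: down-responsive gene requires "
                "p_tx_given_active < p_tx_given_inactive"
            )
        if len(self.probesets) < 1:
            raise ValidationError(f"gene {self.symbol}: needs at least one probeset")
        object.__setattr__(self, "probesets", tuple(self.probesets))


@dataclass(frozen=True)
class ScoreNormalization:
    """Anchors mapping log2-odds onto the 0–100 activity scale."""

    lo_log2odds: float
    hi_log2odds: float

    def __post_init__(self) -> None:
        if not (self.hi_log2odds > self.lo_log2odds):
            raise ConfigurationError(
                f"normalization requires hi > lo, got "
                f"lo={self.lo_log2odds}, hi={self.hi_log2odds}"
            )


@dataclass(frozen=True)
class PathwayModel:
    """Calibrated Bayesian network for one signalling pathway."""

    pathway_name: str
    prior_active: float
    genes: tuple[TargetGene, ...]
    normalization: ScoreNormalization

    def __post_init__(self) -> None:
        if not (0.0 < self.prior_active < 1.0):
            raise ValidationError(
                f"prior_active must lie in (0,1), got {self.prior_active}"
            )
        object.__setattr__(self, "genes", tuple(self.genes))
        symbols = [g.symbol for g in self.genes]
        if len(set(symbols)) != len(symbols):
            raise ValidationError("gene symbols in a model must be unique")
        ids = self.probeset_ids
        if len(set(ids)) != len(ids):
            raise ValidationError("a probeset may belong to exactly one gene")

    @property
    def probeset_ids(self) -> tuple[str, ...]:
        return tuple(ps.probeset_id for g in self.genes for ps in g.probesets)

    def probeset_to_gene(self) -> dict[str, str]:
        return {ps.probeset_id: g.symbol for g in self.genes for ps in g.probesets}


@dataclass(frozen=True)
class ActivityScore:
    """Per-sample inference result."""

    sample_id: str
    posterior: float
    log2_odds: float
    score: float


@dataclass
class CalibrationSet:
    """Ground-truth labelled training profiles for calibration.

    ``profiles`` holds one probeset→log2-intensity mapping per sample and
    ``labels`` the matching ``"active"`` / ``"inactive"`` annotations.
    """

    profiles: list[Mapping[str, float]]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.profiles) != len(self.labels):
            raise ValidationError("profiles and labels differ in length")
        bad = sorted({l for l in self.labels} - {ACTIVE, INACTIVE})
        if bad:
            raise ValidationError(f"unknown calibration labels: {bad}")

    def n_label(self, label: str) -> int:
        return sum(1 for l in self.labels if l == label)


@dataclass(frozen=True)
class PanelGene:
    """Uncalibrated panel entry: a gene, its direction, and its probesets.

    CPT overrides are optional; ``None`` means "use the calibration-time
    defaults".
    """

    symbol: str
    direction: str
    probeset_ids: tuple[str, ...]
    p_tx_given_active: float | None = None
    p_tx_given_inactive: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValidationError(
                f"panel gene {self.symbol}: direction must be 'up' or 'down'"
            )
        if len(self.probeset_ids) < 1:
            raise ValidationError(f"panel gene {self.symbol}: needs ≥1 probeset id")
        object.__setattr__(self, "probeset_ids", tuple(self.probeset_ids))


# ---------------------------------------------------------------------------
# default panel
# ---------------------------------------------------------------------------

_DEFAULT_PANEL_SPEC: tuple[tuple[str, int], ...] = (
    # canonical NFκB target genes; counts are synthetic probesets per gene
    ("NFKBIA", 2),
    ("TNFAIP3", 2),
    ("BIRC3", 2),
    ("CCL2", 2),
    ("CXCL8", 2),
    ("ICAM1", 2),
    ("IL6", 2),
    ("TNF", 2),
    ("TRAF1", 1),
    ("BCL2A1", 1),
    ("BCL2L1", 1),
    ("PLAU", 1),
    ("PTGS2", 1),
    ("VCAM1", 1),
    ("SOD2", 1),
    ("CD40", 1),
)


def default_panel() -> tuple[PanelGene, ...]:
    """Literature-derived default NFκB target-gene panel.

    Sixteen canonical NFκB targets, each mapped to one or two synthetic
    probeset identifiers (``SYMBOL_ps1`` …).  This panel reproduces the
    *method* — it is deliberately not any proprietary calibrated panel.
    """
    return tuple(
        PanelGene(
            symbol=sym,
            direction="up",
            probeset_ids=tuple(f"{sym}_ps{i + 1}" for i in range(n)),
        )
        for sym, n in _DEFAULT_PANEL_SPEC
    )


def build_model(
    panel: Sequence[PanelGene] | None = None,
    *,
    baseline: float = 6.0,
    effect_size: float = 2.0,
    sigma: float = 0.5,
    prior_active: float = 0.5,
    p_tx_given_active: float = 0.9,
    p_tx_given_inactive: float = 0.1,
    anchors: tuple[float, float] = (-LOG2_ODDS_CAP, LOG2_ODDS_CAP),
    pathway_name: str = "NFkB",
) -> PathwayModel:
    """Construct an uncalibrated reference model directly from a panel.

    Every probeset receives ``mu_low = baseline`` and
    ``mu_high = baseline + effect_size``; ``mu_high`` always describes the
    transcribed state, whatever the gene's response direction.  Used to
    seed simulations before data-driven calibration is possible.
    """
    panel = tuple(panel) if panel is not None else default_panel()
    genes = []
    for pg in panel:
        p_a = pg.p_tx_given_active
        p_i = pg.p_tx_given_inactive
        if p_a is None or p_i is None:
            if pg.direction == "up":
                p_a, p_i = p_tx_given_active, p_tx_given_inactive
            else:
                p_a, p_i = p_tx_given_inactive, p_tx_given_active
        genes.append(
            TargetGene(
                symbol=pg.symbol,
                direction=pg.direction,
                p_tx_given_active=p_a,
                p_tx_given_inactive=p_i,
                probesets=tuple(
                    ProbesetEmission(pid, baseline, baseline + effect_size, sigma)
                    for pid in pg.probeset_ids
                ),
            )
        )
    return PathwayModel(
        pathway_name=pathway_name,
        prior_active=prior_active,
        genes=tuple(genes),
        normalization=ScoreNormalization(*anchors),
    )


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def _norm_logpdf(x: float, mu: float, sigma: float) -> float:
    z = (x - mu) / sigma
    return -0.5 * z * z - math.log(sigma) - 0.5 * math.log(2.0 * math.pi)


def _gene_log_evidence(gene: TargetGene, values: Sequence[float], p_tx: float,
                       mode: str) -> float:
    """log P(probeset intensities | pathway state) for one gene.

    Sums the binary transcription state out of the gene's local subtree.
    """
    ll_tx = 0.0   # transcribed branch
    ll_sil = 0.0  # silent branch
    for ps, x in zip(gene.probesets, values):
        if mode == "soft":
            ll_tx += _norm_logpdf(x, ps.mu_high, ps.sigma)
            ll_sil += _norm_logpdf(x, ps.mu_low, ps.sigma)
        else:  # hard binarisation at the emission midpoint
            high = x >= ps.midpoint
            ll_tx += math.log(1.0 - HARD_EVIDENCE_ERROR if high else HARD_EVIDENCE_ERROR)
            ll_sil += math.log(HARD_EVIDENCE_ERROR if high else 1.0 - HARD_EVIDENCE_ERROR)
    with np.errstate(divide="ignore"):
        terms = np.array(
            [np.log(p_tx) + ll_tx, np.log1p(-p_tx) + ll_sil], dtype=float
        )
    return float(logsumexp(terms))


def _ln_odds(model: PathwayModel, profile: Mapping[str, float], mode: str) -> float:
    ln_odds = math.log(model.prior_active) - math.log1p(-model.prior_active)
    for gene in model.genes:
        values = [float(profile[ps.probeset_id]) for ps in gene.probesets]
        ll_active = _gene_log_evidence(gene, values, gene.p_tx_given_active, mode)
        ll_inactive = _gene_log_evidence(gene, values, gene.p_tx_given_inactive, mode)
        ln_odds += ll_active - ll_inactive
    return ln_odds


def infer_activity(
    model: PathwayModel,
    profile: Mapping[str, float],
    *,
    sample_id: str = "sample",
    mode: str = "soft",
) -> ActivityScore:
    """Exact posterior probability of pathway activity for one profile.

    Parameters
    ----------
    model
        Calibrated pathway model.
    profile
        Mapping probeset id → log2 intensity; must contain every model
        probeset (missing evidence raises, it is never imputed).
    mode
        ``"soft"`` (Gaussian class-conditional densities, default) or
        ``"hard"`` (binarise each probeset at the midpoint of its means).

    Returns
    -------
    ActivityScore
        Posterior P(active | evidence), log2-odds capped at ±20, and the
        normalized 0–100 score.
    """
    if mode not in ("soft", "hard"):
        raise ConfigurationError(f"unknown inference mode {mode!r}")
    missing = [p for p in model.probeset_ids if p not in profile]
    if missing:
        raise MissingEvidenceError(missing)
    for pid in model.probeset_ids:
        if not math.isfinite(float(profile[pid])):
            raise ValidationError(f"non-finite intensity for probeset {pid}")
    ln_odds = _ln_odds(model, profile, mode)
    posterior = float(expit(ln_odds))
    log2_odds = float(np.clip(ln_odds / LN2, -LOG2_ODDS_CAP, LOG2_ODDS_CAP))
    score = normalize_score(log2_odds, model.normalization)
    return ActivityScore(
        sample_id=sample_id, posterior=posterior, log2_odds=log2_odds, score=score
    )


def normalize_score(log2_odds: float, norm: ScoreNormalization) -> float:
    """Affine map of log2-odds from [lo, hi] onto [0, 100], clipped."""
    span = norm.hi_log2odds - norm.lo_log2odds
    raw = 100.0 * (log2_odds - norm.lo_log2odds) / span
    return float(np.clip(raw, 0.0, 100.0))


def score_matrix(model: PathwayModel, matrix, *, mode: str = "soft") -> list[ActivityScore]:
    """Apply :func:`infer_activity` to every sample column of a matrix.

    ``matrix`` may be an :class:`~pathscore.expression_io.ExpressionMatrix`
    or a bare probesets × samples DataFrame.  Output order follows column
    order.
    """
    data = getattr(matrix, "data", matrix)
    missing = [p for p in model.probeset_ids if p not in data.index]
    if missing:
        raise MissingEvidenceError(missing)
    sub = data.loc[list(model.probeset_ids)]
    return [
        infer_activity(
            model, dict(zip(sub.index, sub[col].to_numpy())), sample_id=str(col),
            mode=mode,
        )
        for col in sub.columns
    ]


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def calibrate(
    panel: Sequence[PanelGene],
    training: CalibrationSet,
    pseudocount: float = 0.0,
    prior_active: float = 0.5,
    *,
    p_tx_given_active: float = 0.9,
    p_tx_given_inactive: float = 0.1,
    sigma_floor: float = SIGMA_FLOOR,
    pathway_name: str = "NFkB",
) -> PathwayModel:
    """Fit emission parameters and score anchors from labelled profiles.

    Per probeset the two emission means are the label-conditional sample
    means (shrunk toward the pooled mean with weight ``pseudocount``); the
    shared sigma pools the within-label sums of squares and is floored at
    ``sigma_floor``.  Up-responsive genes take ``mu_high`` from the
    active-labelled samples, down-responsive genes from the inactive ones.
    Gene CPTs use the supplied defaults unless the panel entry overrides
    them.  The 0–100 normalization anchors are the minimum and maximum
    (capped) log2-odds observed on the training samples themselves.
    """
    panel = tuple(panel)
    n_active = training.n_label(ACTIVE)
    n_inactive = training.n_label(INACTIVE)
    if n_active < 2 or n_inactive < 2:
        raise CalibrationError(
            f"need ≥2 samples per label, got active={n_active}, "
            f"inactive={n_inactive}"
        )
    if pseudocount < 0:
        raise ValidationError("pseudocount must be ≥ 0")

    all_ids = [pid for pg in panel for pid in pg.probeset_ids]
    for i, prof in enumerate(training.profiles):
        missing = [pid for pid in all_ids if pid not in prof]
        if missing:
            raise CalibrationError(
                f"training profile {i} is missing probesets: {missing}"
            )

    active_idx = [i for i, l in enumerate(training.labels) if l == ACTIVE]
    inactive_idx = [i for i, l in enumerate(training.labels) if l == INACTIVE]

    mean_a: dict[str, float] = {}
    mean_i: dict[str, float] = {}
    sigma: dict[str, float] = {}
    for pid in all_ids:
        xa = np.array([float(training.profiles[i][pid]) for i in active_idx])
        xi = np.array([float(training.profiles[i][pid]) for i in inactive_idx])
        pooled = float(np.concatenate([xa, xi]).mean())
        ma, mi = float(xa.mean()), float(xi.mean())
        if pseudocount > 0:
            ma = (len(xa) * ma + pseudocount * pooled) / (len(xa) + pseudocount)
            mi = (len(xi) * mi + pseudocount * pooled) / (len(xi) + pseudocount)
        ss = float(((xa - xa.mean()) ** 2).sum() + ((xi - xi.mean()) ** 2).sum())
        s = math.sqrt(ss / (len(xa) + len(xi) - 2))
        if s < sigma_floor:
            if s == 0.0:
                warnings.warn(
                    f"probeset {pid}: zero intensity variance; sigma floored at "
                    f"{sigma_floor}",
                    stacklevel=2,
                )
            s = sigma_floor
        mean_a[pid], mean_i[pid], sigma[pid] = ma, mi, s

    genes = []
    for pg in panel:
        p_a = pg.p_tx_given_active
        p_i = pg.p_tx_given_inactive
        if p_a is None or p_i is None:
            if pg.direction == "up":
                p_a, p_i = p_tx_given_active, p_tx_given_inactive
            else:
                p_a, p_i = p_tx_given_inactive, p_tx_given_active
        probesets = []
        for pid in pg.probeset_ids:
            if pg.direction == "up":
                mu_high, mu_low = mean_a[pid], mean_i[pid]
            else:
                mu_high, mu_low = mean_i[pid], mean_a[pid]
            if mu_high < mu_low:
                warnings.warn(
                    f"probeset {pid} ({pg.symbol}): calibrated mu_high < mu_low — "
                    "label means run against the declared response direction",
                    stacklevel=2,
                )
            probesets.append(
                ProbesetEmission(pid, mu_low=mu_low, mu_high=mu_high, sigma=sigma[pid])
            )
        genes.append(
            TargetGene(
                symbol=pg.symbol,
                direction=pg.direction,
                p_tx_given_active=p_a,
                p_tx_given_inactive=p_i,
                probesets=tuple(probesets),
            )
        )

    # normalization anchors: range of capped log2-odds over the training set
    interim = PathwayModel(
        pathway_name=pathway_name,
        prior_active=prior_active,
        genes=tuple(genes),
        normalization=ScoreNormalization(-LOG2_ODDS_CAP, LOG2_ODDS_CAP),
    )
    l2o = [
        float(
            np.clip(_ln_odds(interim, prof, "soft") / LN2, -LOG2_ODDS_CAP, LOG2_ODDS_CAP)
        )
        for prof in training.profiles
    ]
    lo, hi = min(l2o), max(l2o)
    if not hi > lo:
        raise CalibrationError(
            "training samples yield a degenerate log2-odds range; "
            "cannot set normalization anchors"
        )
    return PathwayModel(
        pathway_name=pathway_name,
        prior_active=prior_active,
        genes=tuple(genes),
        normalization=ScoreNormalization(lo, hi),
    )


# ---------------------------------------------------------------------------
# panel & model serialization
# ---------------------------------------------------------------------------

_PANEL_COLUMNS = (
    "symbol",
    "direction",
    "probesets",
    "p_tx_given_active",
    "p_tx_given_inactive",
)


def write_panel(panel: Sequence[PanelGene], path: str | Path) -> None:
    """Write a panel as tab-delimited text (bit-exact round trip)."""
    lines = ["\t".join(_PANEL_COLUMNS)]
    for pg in panel:
        lines.append(
            "\t".join(
                [
                    pg.symbol,
                    pg.direction,
                    ",".join(pg.probeset_ids),
                    "" if pg.p_tx_given_active is None else repr(pg.p_tx_given_active),
                    ""
                    if pg.p_tx_given_inactive is None
                    else repr(pg.p_tx_given_inactive),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_panel(path: str | Path) -> tuple[PanelGene, ...]:
    """Read a tab-delimited panel file written by :func:`write_panel`."""
    lines = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    header = tuple(lines[0].split("\t"))
    if header != _PANEL_COLUMNS:
        raise ParseError(f"unexpected panel header: {header}")
    panel = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != len(_PANEL_COLUMNS):
            raise ParseError(
                f"line {lineno}: expected {len(_PANEL_COLUMNS)} fields, "
                f"got {len(fields)}"
            )
        sym, direction, probesets, p_a, p_i = fields
        panel.append(
            PanelGene(
                symbol=sym,
                direction=direction,
                probeset_ids=tuple(probesets.split(",")),
                p_tx_given_active=float(p_a) if p_a else None,
                p_tx_given_inactive=float(p_i) if p_i else None,
            )
        )
    return tuple(panel)


def save_model(model: PathwayModel, path: str | Path) -> None:
    """Serialize a calibrated model to versioned JSON."""
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "pathway_name": model.pathway_name,
        "prior_active": model.prior_active,
        "normalization": {
            "lo_log2odds": model.normalization.lo_log2odds,
            "hi_log2odds": model.normalization.hi_log2odds,
        },
        "genes": [
            {
                "symbol": g.symbol,
                "direction": g.direction,
                "p_tx_given_active": g.p_tx_given_active,
                "p_tx_given_inactive": g.p_tx_given_inactive,
                "probesets": [
                    {
                        "probeset_id": ps.probeset_id,
                        "mu_low": ps.mu_low,
                        "mu_high": ps.mu_high,
                        "sigma": ps.sigma,
                    }
                    for ps in g.probesets
                ],
            }
            for g in model.genes
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_model(path: str | Path) -> PathwayModel:
    doc = json.loads(Path(path).read_text())
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ConfigurationError(
            f"unsupported model format version {version!r} "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    genes = tuple(
        TargetGene(
            symbol=g["symbol"],
            direction=g["direction"],
            p_tx_given_active=g["p_tx_given_active"],
            p_tx_given_inactive=g["p_tx_given_inactive"],
            probesets=tuple(
                ProbesetEmission(
                    ps["probeset_id"], ps["mu_low"], ps["mu_high"], ps["sigma"]
                )
                for ps in g["probesets"]
            ),
        )
        for g in doc["genes"]
    )
    return PathwayModel(
        pathway_name=doc["pathway_name"],
        prior_active=doc["prior_active"],
        genes=genes,
        normalization=ScoreNormalization(
            doc["normalization"]["lo_log2odds"], doc["normalization"]["hi_log2odds"]
        ),
    )
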