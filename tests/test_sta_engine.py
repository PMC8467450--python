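"""Inference, calibration, and scoring of the pathway-activity network."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathscore.errors import (
    CalibrationError,
    ConfigurationError,
    MissingEvidenceError,
    ValidationError,
)
from pathscore.sta_engine import (
    ACTIVE,
    INACTIVE,
    CalibrationSet,
    PanelGene,
    PathwayModel,
    ProbesetEmission,
    ScoreNormalization,
    TargetGene,
    build_model,
    calibrate,
    default_panel,
    infer_activity,
    load_model,
    normalize_score,
    read_panel,
    save_model,
    score_matrix,
    write_panel,
)
from pathscore.synthetic_data import simulate_cohort, CohortSpec

from .oracles import enumeration_posterior, random_profile, random_small_model


def _flat_model(prior=0.5):
    """All emissions identical in both states: evidence carries no information."""
    genes = tuple(
        TargetGene(
            symbol=f"G{i}",
            direction="up",
            p_tx_given_active=0.9,
            p_tx_given_inactive=0.1,
            probesets=(ProbesetEmission(f"G{i}_ps1", 6.0, 6.0, 0.5),),
        )
        for i in range(3)
    )
    return PathwayModel("flat", prior, genes, ScoreNormalization(-4.0, 4.0))


class TestInferActivity:
    def test_uninformative_evidence_returns_prior(self):
        model = _flat_model(prior=0.37)
        profile = {pid: 5.0 for pid in model.probeset_ids}
        assert infer_activity(model, profile).posterior == pytest.approx(0.37, abs=1e-12)

    def test_matches_enumeration_on_fixed_two_gene_network(self, two_gene_model):
        profile = {"A_ps1": 7.2, "B_ps1": 5.1}
        expected = enumeration_posterior(two_gene_model, profile)
        got = infer_activity(two_gene_model, profile).posterior
        assert got == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_on_random_small_networks(self, rng):
        for _ in range(100):
            model = random_small_model(rng)
            profile = random_profile(model, rng)
            expected = enumeration_posterior(model, profile)
            got = infer_activity(model, profile).posterior
            assert got == pytest.approx(expected, abs=1e-10)

    def test_saturated_up_evidence_overwhelms_any_prior(self):
        for prior in (0.01, 0.2, 0.5):
            model = build_model(
                default_panel()[:4],
                prior_active=prior,
                p_tx_given_active=1.0,
                p_tx_given_inactive=0.0,
            )
            profile = {
                ps.probeset_id: ps.mu_high for g in model.genes for ps in g.probesets
            }
            assert infer_activity(model, profile).posterior >= 0.99

    def test_missing_probeset_raises_listing_ids(self, two_gene_model):
        with pytest.raises(MissingEvidenceError, match="B_ps1"):
            infer_activity(two_gene_model, {"A_ps1": 6.0})

    def test_non_finite_intensity_rejected(self, two_gene_model):
        with pytest.raises(ValidationError, match="non-finite"):
            infer_activity(two_gene_model, {"A_ps1": float("nan"), "B_ps1": 5.0})

    def test_gene_and_probeset_order_do_not_change_posterior(self, rng):
        model = random_small_model(rng, max_genes=3, max_probesets=2)
        profile = random_profile(model, rng)
        reordered = PathwayModel(
            pathway_name=model.pathway_name,
            prior_active=model.prior_active,
            genes=tuple(
                TargetGene(
                    symbol=g.symbol,
                    direction=g.direction,
                    p_tx_given_active=g.p_tx_given_active,
                    p_tx_given_inactive=g.p_tx_given_inactive,
                    probesets=tuple(reversed(g.probesets)),
                )
                for g in reversed(model.genes)
            ),
            normalization=model.normalization,
        )
        a = infer_activity(model, profile).posterior
        b = infer_activity(reordered, profile).posterior
        assert a == pytest.approx(b, abs=1e-14)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        base=st.floats(min_value=3.0, max_value=9.0),
        bump=st.floats(min_value=0.0, max_value=6.0),
    )
    def test_raising_an_up_probeset_never_decreases_posterior(
        self, two_gene_model, base, bump
    ):
        lo = infer_activity(two_gene_model, {"A_ps1": base, "B_ps1": 5.0})
        hi = infer_activity(two_gene_model, {"A_ps1": base + bump, "B_ps1": 5.0})
        assert hi.posterior >= lo.posterior - 1e-12

    def test_outputs_respect_bounds_even_on_extreme_evidence(self, two_gene_model):
        for x in (-50.0, 0.0, 50.0):
            s = infer_activity(two_gene_model, {"A_ps1": x, "B_ps1": x})
            assert 0.0 <= s.posterior <= 1.0
            assert abs(s.log2_odds) <= 20.0
            assert 0.0 <= s.score <= 100.0

    def test_hard_mode_binarises_at_midpoint(self, two_gene_model):
        above = infer_activity(
            two_gene_model, {"A_ps1": 6.6, "B_ps1": 5.4}, mode="hard"
        )
        below = infer_activity(
            two_gene_model, {"A_ps1": 6.4, "B_ps1": 5.1}, mode="hard"
        )
        assert above.posterior > below.posterior


class TestNormalizeScore:
    @pytest.mark.parametrize(
        "l2o,expected",
        [(-4.0, 0.0), (4.0, 100.0), (0.0, 50.0), (2.0, 75.0), (-9.0, 0.0), (9.0, 100.0)],
    )
    def test_affine_endpoints_and_clipping(self, l2o, expected):
        norm = ScoreNormalization(-4.0, 4.0)
        assert normalize_score(l2o, norm) == pytest.approx(expected)

    def test_inverted_anchors_rejected(self):
        with pytest.raises(ConfigurationError):
            ScoreNormalization(4.0, -4.0)


class TestCalibrate:
    @staticmethod
    def _panel():
        return (
            PanelGene("A", "up", ("A_ps1",)),
            PanelGene("B", "up", ("B_ps1", "B_ps2")),
        )

    @staticmethod
    def _training(active_level=10.0, inactive_level=4.0, jitter=None):
        ids = ("A_ps1", "B_ps1", "B_ps2")
        profiles, labels = [], []
        for i in range(3):
            eps = 0.0 if jitter is None else jitter[i]
            profiles.append({p: active_level + eps for p in ids})
            labels.append(ACTIVE)
        for i in range(3):
            eps = 0.0 if jitter is None else -jitter[i]
            profiles.append({p: inactive_level + eps for p in ids})
            labels.append(INACTIVE)
        return CalibrationSet(profiles, labels)

    def test_noiseless_two_level_training_recovers_levels_and_endpoints(self):
        with pytest.warns(UserWarning, match="zero intensity variance"):
            model = calibrate(self._panel(), self._training())
        for g in model.genes:
            for ps in g.probesets:
                assert ps.mu_high == 10.0
                assert ps.mu_low == 4.0
        active = {p: 10.0 for p in model.probeset_ids}
        inactive = {p: 4.0 for p in model.probeset_ids}
        assert infer_activity(model, active).score == pytest.approx(100.0)
        assert infer_activity(model, inactive).score == pytest.approx(0.0)

    def test_label_conditional_means_match_hand_computed_columns(self, rng):
        panel = self._panel()
        ids = [pid for pg in panel for pid in pg.probeset_ids]
        values = rng.normal(7.0, 1.0, size=(12, len(ids)))
        values[:6] += 2.0  # keep label means on the declared up direction
        labels = [ACTIVE] * 6 + [INACTIVE] * 6
        profiles = [dict(zip(ids, row)) for row in values]
        model = calibrate(panel, CalibrationSet(profiles, labels))
        by_id = {ps.probeset_id: ps for g in model.genes for ps in g.probesets}
        for j, pid in enumerate(ids):
            assert by_id[pid].mu_high == pytest.approx(
                values[:6, j].mean(), abs=1e-12
            )
            assert by_id[pid].mu_low == pytest.approx(
                values[6:, j].mean(), abs=1e-12
            )

    def test_coincident_label_means_leave_posterior_at_prior(self):
        panel = (PanelGene("A", "up", ("A_ps1",)),)
        profiles = [
            {"A_ps1": 5.0},
            {"A_ps1": 7.0},
            {"A_ps1": 5.0},
            {"A_ps1": 7.0},
        ]
        labels = [ACTIVE, ACTIVE, INACTIVE, INACTIVE]
        with pytest.raises(CalibrationError):
            # identical emissions ⇒ flat log-odds ⇒ no usable anchors
            calibrate(panel, CalibrationSet(profiles, labels), pseudocount=0.0)
        # the emission itself contributes likelihood ratio 1: check directly
        em = ProbesetEmission("A_ps1", 6.0, 6.0, 1.0)
        gene = TargetGene("A", "up", 0.9, 0.1, (em,))
        model = PathwayModel("t", 0.3, (gene,), ScoreNormalization(-4, 4))
        assert infer_activity(model, {"A_ps1": 5.2}).posterior == pytest.approx(
            0.3, abs=1e-12
        )

    def test_too_few_samples_per_label_rejected(self):
        cs = CalibrationSet(
            [{"A_ps1": 1.0, "B_ps1": 1.0, "B_ps2": 1.0}] * 3,
            [ACTIVE, ACTIVE, INACTIVE],
        )
        with pytest.raises(CalibrationError, match="≥2 samples"):
            calibrate(self._panel(), cs)

    def test_calibration_separates_labels_with_perfect_auc(self, calibrated_model):
        """Active-labelled training-style samples all outrank inactive ones."""
        from pathscore.synthetic_data import simulate_calibration_set

        cal = simulate_calibration_set(calibrated_model, 15, 15, noise_sd=0.0, seed=5)
        scores = [
            infer_activity(calibrated_model, p).score for p in cal.profiles
        ]
        active = [s for s, l in zip(scores, cal.labels) if l == ACTIVE]
        inactive = [s for s, l in zip(scores, cal.labels) if l == INACTIVE]
        assert min(active) > max(inactive)  # empirical AUC = 1.0


class TestScoreMatrix:
    def test_batch_equals_per_sample_inference(self, calibrated_model):
        matrix, _ = simulate_cohort(
            calibrated_model,
            CohortSpec(n_samples=20, activity_rate=0.5, seed=7, n_background_genes=5),
        )
        batch = score_matrix(calibrated_model, matrix)
        assert len(batch) == 20
        for s in batch:
            solo = infer_activity(
                calibrated_model, matrix.profile(s.sample_id), sample_id=s.sample_id
            )
            assert s.posterior == pytest.approx(solo.posterior, abs=1e-12)
            assert s.score == pytest.approx(solo.score, abs=1e-12)

    def test_column_permutation_permutes_scores(self, calibrated_model):
        matrix, _ = simulate_cohort(
            calibrated_model,
            CohortSpec(n_samples=6, activity_rate=0.5, seed=3, n_background_genes=0),
        )
        base = {s.sample_id: s.score for s in score_matrix(calibrated_model, matrix)}
        shuffled = matrix.data[list(reversed(matrix.data.columns))]
        perm = {s.sample_id: s.score for s in score_matrix(calibrated_model, shuffled)}
        assert base == perm

    def test_scores_equal_enumeration_oracle_per_sample(self, rng):
        model = random_small_model(rng, max_genes=3)
        import pandas as pd

        cols = {
            f"S{i}": {pid: float(rng.uniform(3, 10)) for pid in model.probeset_ids}
            for i in range(20)
        }
        frame = pd.DataFrame(cols)
        for s in score_matrix(model, frame):
            expected = enumeration_posterior(model, dict(frame[s.sample_id]))
            assert s.posterior == pytest.approx(expected, abs=1e-12)

    def test_missing_row_raises(self, two_gene_model):
        import pandas as pd

        frame = pd.DataFrame({"S1": {"A_ps1": 6.0}})
        with pytest.raises(MissingEvidenceError, match="B_ps1"):
            score_matrix(two_gene_model, frame)


class TestSerialization:
    def test_panel_round_trip_is_bit_exact(self, tmp_path):
        panel = default_panel() + (
            PanelGene("XDOWN", "down", ("XDOWN_ps1",), 0.1234567891234, 0.9),
        )
        path = tmp_path / "panel.tsv"
        write_panel(panel, path)
        assert read_panel(path) == panel

    def test_model_round_trip_preserves_all_parameters(
        self, tmp_path, calibrated_model
    ):
        path = tmp_path / "model.json"
        save_model(calibrated_model, path)
        assert load_model(path) == calibrated_model

    def test_wrong_format_version_rejected(self, tmp_path, calibrated_model):
        path = tmp_path / "model.json"
        save_model(calibrated_model, path)
        doc = path.read_text().replace('"format_version": 1', '"format_version": 99')
        path.write_text(doc)
        with pytest.raises(ConfigurationError, match="format version"):
            load_model(path)
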