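"""Fold construction, accuracy, cross-validation harness and SAM analysis."""

import numpy as np
import pandas as pd
import pytest

from depfuse.cohort import CohortSpec, generate_cohort, generate_sam_frame
from depfuse.errors import ConfigurationError, InvalidInputError
from depfuse.evaluate import (
    ConfusionMatrix,
    accuracy,
    make_folds,
    run_cv,
    sam_analysis,
    sessions_to_sam_frame,
)


class TestMakeFolds:
    def test_52_subjects_reproduce_42_5_5_pattern(self):
        ids = [f"S{i:03d}" for i in range(52)]
        labels = [i % 2 for i in range(52)]
        plan = make_folds(ids, labels, k=10, seed=0)
        for round_ in plan.rounds:
            assert 41 <= len(round_["train"]) <= 43
            assert 4 <= len(round_["val"]) <= 6
            assert 4 <= len(round_["test"]) <= 6
        assert any(
            (len(r["train"]), len(r["val"]), len(r["test"])) == (42, 5, 5)
            for r in plan.rounds
        )

    def test_roles_partition_all_subjects(self):
        ids = [f"S{i}" for i in range(23)]
        plan = make_folds(ids, k=5, seed=3)
        for round_ in plan.rounds:
            all_ids = round_["train"] + round_["val"] + round_["test"]
            assert sorted(all_ids) == sorted(ids)
            assert not set(round_["train"]) & set(round_["test"])
            assert not set(round_["val"]) & set(round_["test"])

    def test_degenerate_k_rejected(self):
        with pytest.raises(ConfigurationError, match="validation fold collides"):
            make_folds(["a", "b", "c", "d"], k=2)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            make_folds(["a", "b"], k=3)

    def test_stratification_balances_folds(self):
        ids = [f"S{i}" for i in range(40)]
        labels = [i < 20 for i in range(40)]
        genders = ["m" if i % 2 else "f" for i in range(40)]
        plan = make_folds(ids, labels, genders, k=10, seed=1)
        lab = dict(zip(ids, labels))
        for fold in plan.folds:
            counts = sum(lab[s] for s in fold)
            assert counts == 2  # 4 subjects per fold, half per class


class TestAccuracy:
    def test_arithmetic(self):
        assert accuracy(ConfusionMatrix(tp=4, tn=5, fp=1, fn=0)) == pytest.approx(0.9)

    def test_perfect_and_zero(self):
        assert accuracy(ConfusionMatrix(tp=3, tn=2)) == 1.0
        assert accuracy(ConfusionMatrix(fp=2, fn=1)) == 0.0

    def test_error_identity(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(0, 10, 4)
            if tp + tn + fp + fn == 0:
                continue
            cm = ConfusionMatrix(int(tp), int(tn), int(fp), int(fn))
            assert accuracy(cm) == pytest.approx(1 - (fp + fn) / cm.total)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            accuracy(ConfusionMatrix())

    def test_from_predictions(self):
        cm = ConfusionMatrix.from_predictions([1, 1, 0, 0], [1, 0, 0, 1])
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 1, 1)


def amplitude_classifier(train, val, seed):
    """Cheap stand-in model: logistic rule on session deformation spread."""
    from depfuse.cohort import landmark_template

    template = landmark_template()

    def spread(s):
        return float(np.mean([np.abs(f.points - template).mean() for f in s.frames_3d]))

    xs = np.array([spread(s) for s in train])
    ys = np.array([s.label for s in train])
    thr = (xs[ys == 0].mean() + xs[ys == 1].mean()) / 2
    sign = 1.0 if xs[ys == 1].mean() < thr else -1.0

    def predictor(test):
        p = 1 / (1 + np.exp(sign * 50 * (np.array([spread(s) for s in test]) - thr)))
        return {"amp": p}

    return predictor


class TestRunCv:
    def test_fold_records_and_determinism(self, tiny_cohort):
        _, sessions, _ = tiny_cohort
        subs = sorted({s.subject_id for s in sessions})
        labels = {s.subject_id: s.label for s in sessions}
        plan = make_folds(subs, [labels[s] for s in subs], k=4, seed=0)
        r1 = run_cv(sessions, amplitude_classifier, plan, base_seed=0)
        r2 = run_cv(sessions, amplitude_classifier, plan, base_seed=0)
        assert len(r1.fold_accuracy) == 4
        pd.testing.assert_frame_equal(r1.per_session, r2.per_session)

    def test_true_labels_beat_permuted(self, tiny_cohort):
        _, sessions, _ = tiny_cohort
        subs = sorted({s.subject_id for s in sessions})
        labels = {s.subject_id: s.label for s in sessions}
        plan = make_folds(subs, [labels[s] for s in subs], k=4, seed=0)
        true_res = run_cv(sessions, amplitude_classifier, plan, base_seed=0)
        # permute subject labels coherently
        rng = np.random.default_rng(0)
        perm = dict(zip(subs, rng.permutation([labels[s] for s in subs])))
        import copy

        permuted = []
        for s in sessions:
            c = copy.copy(s)
            c.label = int(perm[s.subject_id])
            permuted.append(c)
        perm_res = run_cv(permuted, amplitude_classifier, plan, base_seed=0)
        assert true_res.mean_accuracy("amp") > perm_res.mean_accuracy("amp")

    def test_breakdown_and_ci(self, tiny_cohort):
        _, sessions, _ = tiny_cohort
        subs = sorted({s.subject_id for s in sessions})
        labels = {s.subject_id: s.label for s in sessions}
        plan = make_folds(subs, [labels[s] for s in subs], k=4, seed=0)
        res = run_cv(sessions, amplitude_classifier, plan, base_seed=0)
        table = res.breakdown(("task", "valence"))
        assert len(table) == 15
        lo, hi = res.confidence_interval("amp")
        assert lo <= res.mean_accuracy("amp") <= hi


class TestSamAnalysis:
    def test_layout(self):
        frame = generate_sam_frame(CohortSpec.tiny(n_subjects_per_cell=4, seed=2))
        out = sam_analysis(frame)
        assert len(out) == 2 * 5 * 3
        assert set(out["dimension"]) == {"valence", "arousal"}

    def test_single_subject_group_is_na(self):
        frame = generate_sam_frame(CohortSpec.tiny(n_subjects_per_cell=1, seed=2))
        # drop one group's subjects except one row per cell is impossible;
        # instead keep a single depressed subject
        sub = frame[(frame.label == 0) | (frame.subject_id == "S0002")]
        out = sam_analysis(sub)
        assert out["p_value"].isna().all()

    def test_strong_effect_flags_emotional_film_cells_more_than_neutral(self):
        reps = 40
        counts = {"emotional": 0, "neutral": 0}
        for seed in range(reps):
            frame = generate_sam_frame(
                CohortSpec.tiny(n_subjects_per_cell=8, effect_size=2.0, seed=seed)
            )
            out = sam_analysis(frame)
            val = out[(out.dimension == "valence") & (out.task == "film")]
            counts["emotional"] += int(val[val.valence == "positive"].significant.iloc[0])
            counts["emotional"] += int(val[val.valence == "negative"].significant.iloc[0])
            counts["neutral"] += int(val[val.valence == "neutral"].significant.iloc[0])
        assert counts["emotional"] / 2 > counts["neutral"] + reps * 0.05

    def test_sessions_to_frame(self, tiny_cohort):
        _, sessions, _ = tiny_cohort
        frame = sessions_to_sam_frame(sessions)
        assert len(frame) == len(sessions)
        out = sam_analysis(sessions)
        assert np.isfinite(out["p_value"]).all()

    def test_bh_correction_adds_column(self):
        frame = generate_sam_frame(CohortSpec.tiny(n_subjects_per_cell=4, seed=9))
        out = sam_analysis(frame, bh_correct=True)
        assert "p_adjusted" in out.columns
        assert (out["p_adjusted"].dropna() >= out["p_value"].dropna() - 1e-12).all()
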