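"""Subject-wise rotating 10-fold cross-validation and SAM analysis.

Folds are assigned at the subject level (no individual contributes to more
than one of train/validation/test within a round) with stratification by
label and gender. Roles rotate: round r tests fold r, validates fold r+1
and trains on the remaining k-2 folds, giving the 80/10/10 split that
yields 42/5/5 subjects per round for a 52-subject stratum.

``sam_analysis`` reproduces the pre/post affective-rating comparison:
per task x valence cell, group means of the post-pre delta and the Welch
two-sample p-value, flagged at p < 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InvalidInputError
from .preprocess import Session, TASKS, VALENCES

__all__ = [
    "ConfusionMatrix",
    "FoldPlan",
    "make_folds",
    "accuracy",
    "run_cv",
    "CvResult",
    "sam_analysis",
    "sessions_to_sam_frame",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InvalidInputError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        yt = np.asarray(y_true).astype(int)
        yp = np.asarray(y_pred).astype(int)
        if yt.shape != yp.shape:
            raise InvalidInputError("label vectors differ in length")
        return cls(
            tp=int(np.sum((yt == 1) & (yp == 1))),
            tn=int(np.sum((yt == 0) & (yp == 0))),
            fp=int(np.sum((yt == 0) & (yp == 1))),
            fn=int(np.sum((yt == 1) & (yp == 0))),
        )


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if cm.total == 0:
        raise InvalidInputError("accuracy undefined for an empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


@dataclass(frozen=True)
class FoldPlan:
    """k folds of subject ids plus the rotating train/val/test rounds."""

    k: int
    folds: tuple[tuple[str, ...], ...]
    rounds: tuple[dict, ...]  # each: {"train": ids, "val": ids, "test": ids}

    def __post_init__(self) -> None:
        all_ids = [s for f in self.folds for s in f]
        if len(all_ids) != len(set(all_ids)):
            raise ConfigurationError("a subject appears in two folds")


def _spaced_fold_sizes(n: int, k: int) -> list[int]:
    """Near-equal fold sizes with the remainder spread evenly, not clustered."""
    base, rem = divmod(n, k)
    sizes = [base] * k
    for i in range(rem):
        sizes[int(round(i * k / rem)) % k] += 1
    return sizes


def make_folds(
    subject_ids,
    labels=None,
    genders=None,
    k: int = 10,
    seed: int = 0,
) -> FoldPlan:
    """Stratified subject-level folds with rotating roles.

    Requires k >= 3 (test, validation and at least one training fold) and
    at least k subjects. Stratification interleaves label x gender strata
    so every fold is near-balanced.
    """
    ids = list(subject_ids)
    if k < 3:
        raise ConfigurationError(
            "k must be >= 3: with k < 3 the validation fold collides with the test fold"
        )
    if len(ids) < k:
        raise ConfigurationError(f"{len(ids)} subjects cannot fill {k} folds")
    labels = list(labels) if labels is not None else [0] * len(ids)
    genders = list(genders) if genders is not None else ["-"] * len(ids)
    rng = np.random.default_rng(seed)
    strata: dict[tuple, list[str]] = {}
    for sid, lab, gen in zip(ids, labels, genders):
        strata.setdefault((lab, gen), []).append(sid)
    for members in strata.values():
        rng.shuffle(members)
    # interleave strata round-robin so folds get proportional mixes
    order: list[str] = []
    pools = [list(m) for _, m in sorted(strata.items(), key=lambda kv: str(kv[0]))]
    while any(pools):
        for pool in pools:
            if pool:
                order.append(pool.pop())
    sizes = _spaced_fold_sizes(len(ids), k)
    folds, start = [], 0
    for size in sizes:
        folds.append(tuple(order[start : start + size]))
        start += size
    rounds = []
    for r in range(k):
        test = folds[r]
        val = folds[(r + 1) % k]
        train = tuple(
            s for i, f in enumerate(folds) if i not in (r, (r + 1) % k) for s in f
        )
        rounds.append({"train": train, "val": val, "test": test})
    return FoldPlan(k=k, folds=tuple(folds), rounds=tuple(rounds))


@dataclass
class CvResult:
    """Cross-validation output tables."""

    per_session: pd.DataFrame  # one row per evaluated session
    fold_accuracy: pd.DataFrame  # per fold x model accuracy

    def mean_accuracy(self, model: str = "joint") -> float:
        sub = self.fold_accuracy[self.fold_accuracy["model"] == model]
        return float(sub["accuracy"].mean())

    def confidence_interval(self, model: str = "joint") -> tuple[float, float]:
        """Normal-approximation 95% CI of the mean over folds."""
        sub = self.fold_accuracy[self.fold_accuracy["model"] == model]["accuracy"]
        half = 1.96 * float(sub.std(ddof=1)) / np.sqrt(len(sub))
        m = float(sub.mean())
        return m - half, m + half

    def breakdown(self, by=("task", "valence")) -> pd.DataFrame:
        """Pooled accuracy per grouping (e.g. task x valence or gender)."""
        rows = []
        models = [c[2:] for c in self.per_session.columns if c.startswith("p_")]
        for keys, grp in self.per_session.groupby(list(by)):
            keys = keys if isinstance(keys, tuple) else (keys,)
            row = dict(zip(by, keys))
            for m in models:
                row[m] = float(np.mean((grp[f"p_{m}"] >= 0.5).astype(int) == grp["label"]))
            rows.append(row)
        return pd.DataFrame(rows)


def run_cv(
    sessions: list[Session],
    fit_predict,
    plan: FoldPlan,
    base_seed: int = 0,
) -> CvResult:
    """Train from scratch per round and score the held-out test subjects.

    ``fit_predict(train_sessions, val_sessions, seed)`` must return a
    callable mapping a session list to a dict of probability arrays keyed
    by model name (e.g. {"2d": ..., "3d": ..., "joint": ...}). Subject-level
    leakage is asserted programmatically for every round.
    """
    by_subject: dict[str, list[Session]] = {}
    for s in sessions:
        by_subject.setdefault(s.subject_id, []).append(s)
    records = []
    fold_rows = []
    for r, round_ in enumerate(plan.rounds):
        train_ids, val_ids, test_ids = (
            set(round_["train"]),
            set(round_["val"]),
            set(round_["test"]),
        )
        assert not (train_ids & test_ids) and not (val_ids & test_ids) and not (
            train_ids & val_ids
        ), "subject-level leakage between fold roles"
        train = [s for sid in sorted(train_ids) for s in by_subject[sid]]
        val = [s for sid in sorted(val_ids) for s in by_subject[sid]]
        test = [s for sid in sorted(test_ids) for s in by_subject[sid]]
        if len({s.label for s in train}) < 2:
            warnings.warn(f"round {r}: single-class training set, skipped", stacklevel=2)
            continue
        predictor = fit_predict(train, val, base_seed + r)
        probs = predictor(test)
        for i, sess in enumerate(test):
            rec = {
                "fold": r,
                "subject_id": sess.subject_id,
                "task": sess.task,
                "valence": sess.valence,
                "gender": sess.gender,
                "label": sess.label,
            }
            for name, arr in probs.items():
                rec[f"p_{name}"] = float(arr[i])
            records.append(rec)
        y = np.array([s.label for s in test])
        for name, arr in probs.items():
            cm = ConfusionMatrix.from_predictions(y, np.asarray(arr) >= 0.5)
            fold_rows.append(
                {"fold": r, "model": name, "n_test": cm.total, "accuracy": accuracy(cm)}
            )
    return CvResult(
        per_session=pd.DataFrame(records), fold_accuracy=pd.DataFrame(fold_rows)
    )


def sessions_to_sam_frame(sessions: list[Session]) -> pd.DataFrame:
    rows = []
    n_missing = 0
    for s in sessions:
        if s.sam_pre is None or s.sam_post is None:
            n_missing += 1
            continue
        rows.append(
            {
                "subject_id": s.subject_id,
                "label": s.label,
                "task": s.task,
                "valence": s.valence,
                "d_valence": s.sam_post[0] - s.sam_pre[0],
                "d_arousal": s.sam_post[1] - s.sam_pre[1],
            }
        )
    if n_missing:
        warnings.warn(f"{n_missing} sessions without SAM ratings excluded", stacklevel=2)
    return pd.DataFrame(rows)


def sam_analysis(
    data,
    threshold: float = 0.1,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Group comparison of SAM post-pre deltas per task x valence cell.

    ``data`` is a list of Sessions or a DataFrame with columns label,
    task, valence, d_valence, d_arousal. Returns one row per emotional
    dimension x task x valence with group means, the Welch two-sample
    p-value and a significance flag at ``threshold`` (optionally
    Benjamini-Hochberg adjusted). Cells with fewer than two ratings in
    either group get p = NaN.
    """
    frame = data if isinstance(data, pd.DataFrame) else sessions_to_sam_frame(data)
    rows = []
    for dim, col in (("valence", "d_valence"), ("arousal", "d_arousal")):
        for task in TASKS:
            for val in VALENCES:
                cell = frame[(frame["task"] == task) & (frame["valence"] == val)]
                healthy = cell[cell["label"] == 0][col].to_numpy()
                depressed = cell[cell["label"] == 1][col].to_numpy()
                if len(healthy) < 2 or len(depressed) < 2:
                    p = np.nan
                else:
                    p = float(
                        stats.ttest_ind(healthy, depressed, equal_var=False).pvalue
                    )
                rows.append(
                    {
                        "dimension": dim,
                        "task": task,
                        "valence": val,
                        "mean_healthy": float(healthy.mean()) if len(healthy) else np.nan,
                        "mean_depressed": float(depressed.mean()) if len(depressed) else np.nan,
                        "p_value": p,
                    }
                )
    out = pd.DataFrame(rows)
    pvals = out["p_value"].to_numpy()
    if bh_correct:
        finite = np.isfinite(pvals)
        adj = np.full_like(pvals, np.nan)
        adj[finite] = stats.false_discovery_control(pvals[finite])
        out["p_adjusted"] = adj
        out["significant"] = adj < threshold
    else:
        out["significant"] = pvals < threshold
    return out
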