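"""End-to-end recognition and the evaluation harness.

Recognition of an unknown recording follows four steps: segment into
stages and extract component features; score every element against the
trained component classifiers; build the dual-bit test code from the
maximal- and submaximal-probability subclasses; match the code against
the reference table by AND-popcount.

The evaluation harness reproduces the study protocol on a labelled
dataset: for each Θ it builds the suggested training set, trains on
four fifths of its repetitions, and reports accuracy on TA (the held
out fifth of the trained gestures' samples), TB (all samples of
untrained gestures) and TC = TA ∪ TB, plus per-element component
accuracies and paired t-tests between adjacent Θ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_rel

from .core import (
    GestureRecording,
    StagePolicy,
    SubclassInventory,
    ValidationError,
    ELEMENT_NAMES,
)
from .classifiers import ComponentClassifierBank, score_all_components
from .codec import CodeTable, GestureCode, encode_test, match_scores
from .features import GestureFeatures, extract_features
from .preprocess import WindowingSpec
from .trainset import expand_training_set, select_minimal_training_set, train_user_bank


@dataclass
class RecognitionResult:
    """Predicted gesture plus full diagnostics of the match."""

    gesture_id: str
    score: int
    test_code: GestureCode
    rankings: dict[str, list[tuple[int, float]]]
    match_scores: dict[str, int]

    def top1_representation(self) -> dict[str, int]:
        return {name: ranks[0][0] for name, ranks in self.rankings.items()}


def recognize_features(features: GestureFeatures, bank: ComponentClassifierBank,
                       table: CodeTable, inventory: SubclassInventory,
                       hand: str = "right") -> RecognitionResult:
    """Classify already-extracted features (steps 2-4)."""
    rankings = score_all_components(features, bank, hand=hand)
    x = encode_test(rankings, inventory)
    scores = match_scores(x, table)
    best = int(np.argmax(scores))
    gids = table.gesture_ids
    return RecognitionResult(
        gesture_id=gids[best],
        score=int(scores[best]),
        test_code=x,
        rankings=rankings,
        match_scores={g: int(s) for g, s in zip(gids, scores)},
    )


def recognize(rec: GestureRecording, bank: ComponentClassifierBank,
              table: CodeTable, inventory: SubclassInventory,
              policy: StagePolicy | None = None,
              windowing: WindowingSpec | None = None,
              hand: str = "right") -> RecognitionResult:
    """Four-step recognition of one recording."""
    feats = extract_features(rec, hand=hand, policy=policy, windowing=windowing)
    return recognize_features(feats, bank, table, inventory, hand=hand)


@dataclass
class EvaluationResult:
    """Θ-sweep results of the study protocol."""

    summary: pd.DataFrame            # theta, split, accuracy, n_samples
    component_accuracy: pd.DataFrame  # theta x 13 element columns (+ overall)
    per_gesture: pd.DataFrame        # theta, gesture_id, split, accuracy, n
    ttests: pd.DataFrame             # theta_low, theta_high, p_value
    train_sizes: dict[int, int]      # theta -> size(T)

    def accuracy(self, theta: int, split: str) -> float:
        df = self.summary
        row = df[(df.theta == theta) & (df.split == split)]
        if row.empty:
            raise ValidationError(f"no accuracy recorded for theta={theta}, {split}")
        return float(row.accuracy.iloc[0])


def _split_repetitions(reps: list[GestureRecording], rng: np.random.Generator
                       ) -> tuple[list, list]:
    """Hold out one fifth (at least one) of a gesture's repetitions."""
    order = rng.permutation(len(reps))
    n_train = int(round(0.8 * len(reps)))
    n_train = min(max(n_train, 1), len(reps) - 1)
    train = [reps[i] for i in order[:n_train]]
    test = [reps[i] for i in order[n_train:]]
    return train, test


def evaluate(recordings: list[GestureRecording], inventory: SubclassInventory,
             table: CodeTable, theta_grid=(1, 2, 3), seed: int = 0,
             policy: StagePolicy | None = None,
             windowing: WindowingSpec | None = None,
             n_iter: int = 25, hand: str = "right") -> EvaluationResult:
    """Run the Θ-sweep protocol on a labelled dataset.

    Every gesture needs at least two repetitions.  Reference
    representations are decoded from the code table (one-hot codes are
    bijective with representations).
    """
    by_gesture: dict[str, list[GestureRecording]] = {}
    for rec in recordings:
        by_gesture.setdefault(rec.gesture_id, []).append(rec)
    for gid, recs in by_gesture.items():
        if len(recs) < 2:
            raise ValidationError(f"gesture {gid!r} has fewer than 2 repetitions")
        if gid not in table.entries:
            raise ValidationError(f"gesture {gid!r} missing from the code table")
    reference_reps = table.representations()

    # features are Θ-independent: extract once
    cache: dict = {}
    for rec in recordings:
        cache[(id(rec), hand)] = extract_features(rec, hand=hand, policy=policy,
                                                  windowing=windowing)

    minimal = select_minimal_training_set(inventory, reference_reps)
    summary_rows, comp_rows, pg_rows = [], [], []
    train_sizes: dict[int, int] = {}
    for theta in theta_grid:
        spec = (minimal if theta == 1 else
                expand_training_set(minimal, theta, inventory, reference_reps))
        t_set = spec.gestures
        train_sizes[theta] = len(t_set)
        rng = np.random.default_rng((int(seed) * 131 + int(theta)) % (2 ** 31 - 1))
        train_recs, ta = [], []
        for gid in sorted(t_set):
            tr, te = _split_repetitions(by_gesture[gid], rng)
            train_recs += tr
            ta += te
        tb = [r for gid in sorted(set(by_gesture) - t_set)
              for r in by_gesture[gid]]
        bank = train_user_bank(train_recs, inventory, reference_reps,
                               policy=policy, windowing=windowing,
                               seed=int(seed), n_iter=n_iter,
                               features_cache=cache)
        splits = {"TA": ta, "TB": tb, "TC": ta + tb}
        correct_flags: dict[int, bool] = {}
        element_hits = {name: [] for name in ELEMENT_NAMES}
        for rec in splits["TC"]:
            feats = cache[(id(rec), hand)]
            res = recognize_features(feats, bank, table, inventory, hand=hand)
            correct_flags[id(rec)] = res.gesture_id == rec.gesture_id
            truth = reference_reps[rec.gesture_id]
            top1 = res.top1_representation()
            for name in ELEMENT_NAMES:
                element_hits[name].append(top1[name] == truth.element(name))
        for split, recs in splits.items():
            flags = [correct_flags[id(r)] for r in recs]
            summary_rows.append({
                "theta": theta, "split": split,
                "accuracy": float(np.mean(flags)) if flags else np.nan,
                "n_samples": len(flags),
            })
        comp_row = {"theta": theta}
        for name in ELEMENT_NAMES:
            comp_row[name] = float(np.mean(element_hits[name]))
        comp_row["overall"] = float(np.mean(
            [comp_row[name] for name in ELEMENT_NAMES]))
        comp_rows.append(comp_row)
        for gid in sorted(by_gesture):
            split = "TA" if gid in t_set else "TB"
            recs = splits[split]
            flags = [correct_flags[id(r)] for r in recs if r.gesture_id == gid]
            pg_rows.append({
                "theta": theta, "gesture_id": gid, "split": split,
                "accuracy": float(np.mean(flags)), "n": len(flags),
            })

    pg = pd.DataFrame(pg_rows)
    tt_rows = []
    thetas = list(theta_grid)
    for lo, hi in zip(thetas, thetas[1:]):
        a = pg[pg.theta == lo].set_index("gesture_id").accuracy
        b = pg[pg.theta == hi].set_index("gesture_id").accuracy
        common = a.index.intersection(b.index)
        if len(common) > 1 and not np.allclose(a[common], b[common]):
            p = float(ttest_rel(a[common], b[common]).pvalue)
        else:
            p = np.nan
        tt_rows.append({"theta_low": lo, "theta_high": hi, "p_value": p})
    return EvaluationResult(
        summary=pd.DataFrame(summary_rows),
        component_accuracy=pd.DataFrame(comp_rows),
        per_gesture=pg,
        ttests=pd.DataFrame(tt_rows),
        train_sizes=train_sizes,
    )
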