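"""Training-set construction and per-user classifier training.

The reference subject's representations tell which subclasses each
target gesture contains.  For each component a greedy set cover picks
gestures until every subclass is represented; the union of the five
component training sets is the suggested gesture training set T, whose
size is at most the sum of the component set sizes.  Raising the
per-subclass occurrence count Θ grows T monotonically toward the full
target set.  A new user records only T; their stage features are
labelled with the reference representations and used to train the
component classifier bank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    ComponentRepresentation,
    GestureRecording,
    StagePolicy,
    SubclassInventory,
    ValidationError,
    COMPONENTS,
    ELEMENTS,
)
from .classifiers import (
    ComponentClassifierBank,
    GaussianComponentClassifier,
    SequenceComponentClassifier,
)
from .features import extract_features
from .preprocess import WindowingSpec
from .subclassing import component_vector, trajectory_observation


@dataclass
class TrainingSetSpec:
    """Suggested training gestures: per-component sets and their union."""

    component_sets: dict[str, set[str]]
    theta: int = 1

    def __post_init__(self):
        missing = set(COMPONENTS) - set(self.component_sets)
        if missing:
            raise ValidationError(f"component sets missing: {sorted(missing)}")

    @property
    def gestures(self) -> set[str]:
        """The union T of the five component training sets."""
        out: set[str] = set()
        for s in self.component_sets.values():
            out |= s
        return out

    @property
    def size(self) -> int:
        return len(self.gestures)

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "component_sets": {c: sorted(s) for c, s in self.component_sets.items()},
        }

    @classmethod
    def from_dict(cls, d) -> "TrainingSetSpec":
        return cls(component_sets={c: set(v) for c, v in d["component_sets"].items()},
                   theta=int(d["theta"]))


def gesture_subclasses(rep: ComponentRepresentation, component: str) -> set[int]:
    """Subclasses of one component contained in a gesture (any stage)."""
    return {rep.element(name) for name, comp, _stage in ELEMENTS if comp == component}


def _component_cover(reps: dict[str, ComponentRepresentation], component: str,
                     n_subclasses: int) -> set[str]:
    """Greedy cover: repeatedly add the gesture containing the most
    uncovered subclasses (ties to the lexicographically first id)."""
    contains = {gid: gesture_subclasses(rep, component) for gid, rep in reps.items()}
    uncovered = set(range(1, n_subclasses + 1))
    available = set.union(*contains.values()) if contains else set()
    if not uncovered <= available:
        raise ValidationError(
            f"{component}: subclasses {sorted(uncovered - available)} are not "
            "represented by any target gesture")
    chosen: set[str] = set()
    while uncovered:
        gid = max(sorted(contains), key=lambda g: len(contains[g] & uncovered))
        if not contains[gid] & uncovered:
            raise ValidationError(f"{component}: cover stalled")  # unreachable
        chosen.add(gid)
        uncovered -= contains[gid]
    return chosen


def select_minimal_training_set(inventory: SubclassInventory,
                                reps: dict[str, ComponentRepresentation]
                                ) -> TrainingSetSpec:
    """The Θ=1 training set: per component, a greedy cover in which every
    subclass is represented by at least one gesture."""
    sets = {
        comp: _component_cover(reps, comp, inventory.component(comp).n)
        for comp in COMPONENTS
    }
    return TrainingSetSpec(component_sets=sets, theta=1)


def expand_training_set(spec: TrainingSetSpec, theta: int,
                        inventory: SubclassInventory,
                        reps: dict[str, ComponentRepresentation]
                        ) -> TrainingSetSpec:
    """Grow the training set so each subclass occurs in min(Θ, available)
    distinct gestures.  Nested: spec(Θ) ⊆ spec(Θ+1)."""
    if theta < 1:
        raise ValidationError("theta must be >= 1")
    sets = {c: set(s) for c, s in spec.component_sets.items()}
    for comp in COMPONENTS:
        n = inventory.component(comp).n
        by_subclass = {
            i: sorted(g for g, r in reps.items()
                      if i in gesture_subclasses(r, comp))
            for i in range(1, n + 1)
        }
        for level in range(2, theta + 1):
            for i in range(1, n + 1):
                count = sum(1 for g in sets[comp]
                            if i in gesture_subclasses(reps[g], comp))
                for g in by_subclass[i]:
                    if count >= min(level, len(by_subclass[i])):
                        break
                    if g not in sets[comp]:
                        sets[comp].add(g)
                        count += 1
    return TrainingSetSpec(component_sets=sets, theta=theta)


@dataclass
class _SequencePool:
    sequences: list = field(default_factory=list)
    labels: list = field(default_factory=list)


def collect_training_data(
    recordings: list[GestureRecording],
    reference_reps: dict[str, ComponentRepresentation],
    policy: StagePolicy | None = None,
    windowing: WindowingSpec | None = None,
    hand: str = "right",
    features_cache: dict | None = None,
):
    """Label every recording's stage features with the reference
    representation of its gesture and pool them per component."""
    seq_pools = {c: _SequencePool() for c in ("handshape", "trajectory")}
    vec_pools = {c: ([], []) for c in ("orientation", "axis", "rotation")}
    for rec in recordings:
        if rec.gesture_id not in reference_reps:
            raise ValidationError(
                f"no reference representation for gesture {rec.gesture_id!r}")
        rep = reference_reps[rec.gesture_id]
        key = (id(rec), hand)
        if features_cache is not None and key in features_cache:
            feats = features_cache[key]
        else:
            feats = extract_features(rec, hand=hand, policy=policy,
                                     windowing=windowing)
            if features_cache is not None:
                features_cache[key] = feats
        for name, comp, stage in ELEMENTS:
            sub = rep.element(name)
            if comp == "handshape":
                seq_pools[comp].sequences.append(feats.handshape[stage])
                seq_pools[comp].labels.append(sub)
            elif comp == "trajectory":
                seq_pools[comp].sequences.append(
                    trajectory_observation(feats.trajectory))
                seq_pools[comp].labels.append(sub)
            else:
                X, y = vec_pools[comp]
                X.append(component_vector(feats, comp, stage))
                y.append(sub)
    return seq_pools, vec_pools


def train_user_bank(
    train_recordings: list[GestureRecording],
    inventory: SubclassInventory,
    reference_reps: dict[str, ComponentRepresentation],
    policy: StagePolicy | None = None,
    windowing: WindowingSpec | None = None,
    seed: int = 0,
    n_iter: int = 25,
    features_cache: dict | None = None,
) -> ComponentClassifierBank:
    """Train the per-hand component classifier bank from a user's
    recordings of the suggested training set.

    Two-handed recordings contribute to an independent left-hand bank;
    one-handed gestures train only the right hand.  Raises naming the
    (component, subclass) if a subclass of the inventory has no training
    data.
    """
    hands_needed = ["right"]
    if any(rec.hands == "both" for rec in train_recordings):
        hands_needed.append("left")
    bank: dict[str, dict] = {}
    for hand in hands_needed:
        recs = (train_recordings if hand == "right"
                else [r for r in train_recordings if r.hands == "both"])
        seq_pools, vec_pools = collect_training_data(
            recs, reference_reps, policy=policy, windowing=windowing,
            hand=hand, features_cache=features_cache)
        comps: dict[str, object] = {}
        for comp in ("handshape", "trajectory"):
            pool = seq_pools[comp]
            _check_coverage(comp, pool.labels, inventory)
            clf = SequenceComponentClassifier(n_iter=n_iter, random_state=seed)
            comps[comp] = clf.fit(pool.sequences, pool.labels)
        for comp in ("orientation", "axis", "rotation"):
            X, y = vec_pools[comp]
            _check_coverage(comp, y, inventory)
            comps[comp] = GaussianComponentClassifier().fit(np.asarray(X), y)
        bank[hand] = comps
    return ComponentClassifierBank(hands=bank)


def _check_coverage(component: str, labels, inventory: SubclassInventory) -> None:
    have = set(int(v) for v in labels)
    need = set(range(1, inventory.component(component).n + 1))
    missing = sorted(need - have)
    if missing:
        raise ValidationError(
            f"component {component!r}: no training sequences for subclass(es) "
            f"{missing}")
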