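"""Domain types shared by every stage of the recognition framework.

A sign gesture is treated as a combination of five components -- hand
shape, orientation, axis, rotation and trajectory -- observed through a
forearm wristband carrying four surface-EMG channels (1000 Hz) and a
3-axis accelerometer plus 3-axis gyroscope (100 Hz).  The first four
components are evaluated in three temporal stages (beginning, middle,
end) while the trajectory spans the whole gesture, giving the 13-element
component representation (Sb, Sm, Se, Ob, Om, Oe, Ab, Am, Ae, Rb, Rm,
Re, Tr) that the rest of the package encodes and classifies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

SEMG_RATE = 1000.0
"""Surface-EMG sampling rate in Hz."""

INERTIAL_RATE = 100.0
"""Accelerometer / gyroscope sampling rate in Hz."""

COMPONENTS = ("handshape", "orientation", "axis", "rotation", "trajectory")

STAGES = ("begin", "middle", "end")

#: The 13 representation elements in canonical order: (name, component, stage).
#: The trajectory component has a single whole-gesture element.
ELEMENTS = (
    ("sb", "handshape", "begin"),
    ("sm", "handshape", "middle"),
    ("se", "handshape", "end"),
    ("ob", "orientation", "begin"),
    ("om", "orientation", "middle"),
    ("oe", "orientation", "end"),
    ("ab", "axis", "begin"),
    ("am", "axis", "middle"),
    ("ae", "axis", "end"),
    ("rb", "rotation", "begin"),
    ("rm", "rotation", "middle"),
    ("re", "rotation", "end"),
    ("tr", "trajectory", None),
)

ELEMENT_NAMES = tuple(e[0] for e in ELEMENTS)


class SignCompError(Exception):
    """Base class for all package errors."""


class ValidationError(SignCompError):
    """A domain invariant was violated (non-finite samples, bad shapes...)."""


class FormatError(SignCompError):
    """A persisted artifact could not be parsed."""


@dataclass(frozen=True)
class StagePolicy:
    """Fractional boundaries of the three temporal stages.

    The defaults follow the convention of taking the first 25 % of a
    gesture as the beginning stage, the 20--80 % span as the middle
    stage and the last 25 % as the end stage; begin/end intentionally
    overlap the middle.
    """

    begin: tuple[float, float] = (0.0, 0.25)
    middle: tuple[float, float] = (0.20, 0.80)
    end: tuple[float, float] = (0.75, 1.0)

    def __post_init__(self) -> None:
        for name in ("begin", "middle", "end"):
            a, b = getattr(self, name)
            if not (0.0 <= a < b <= 1.0):
                raise ValidationError(f"stage {name!r} interval {a, b} not within [0, 1]")
        if self.begin[0] != 0.0:
            raise ValidationError("begin stage must start at fraction 0")
        if self.end[1] != 1.0:
            raise ValidationError("end stage must finish at fraction 1")

    def fractions(self, stage: str) -> tuple[float, float]:
        return getattr(self, stage)


@dataclass
class HandSignals:
    """Raw signals of one hand: sEMG (4 x Ns), ACC and GYRO (3 x Na)."""

    semg: np.ndarray  # shape (4, Ns), millivolts, 1000 Hz
    acc: np.ndarray   # shape (3, Na), g units, 100 Hz
    gyro: np.ndarray  # shape (3, Na), deg/s, 100 Hz

    def __post_init__(self) -> None:
        self.semg = np.asarray(self.semg, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)


@dataclass
class GestureRecording:
    """One pre-segmented repetition of a sign gesture.

    ``hands`` is ``"right"`` for one-handed signs and ``"both"`` for
    two-handed signs, in which case ``left`` mirrors ``right`` with its
    own independent signals.
    """

    subject_id: str
    gesture_id: str
    repetition: int
    hands: str  # "right" | "both"
    right: HandSignals
    left: HandSignals | None = None

    def __post_init__(self) -> None:
        validate_recording(self)

    @property
    def n_semg(self) -> int:
        return self.right.semg.shape[1]

    @property
    def n_inertial(self) -> int:
        return self.right.acc.shape[1]

    def hand(self, which: str) -> HandSignals:
        if which == "right":
            return self.right
        if which == "left":
            if self.left is None:
                raise ValidationError("recording has no left-hand signals")
            return self.left
        raise ValidationError(f"unknown hand {which!r}")


def _validate_hand(sig: HandSignals, label: str) -> None:
    if sig.semg.ndim != 2 or sig.semg.shape[0] != 4:
        raise ValidationError(f"{label}: sEMG must be 4 x Ns, got {sig.semg.shape}")
    for name, arr in (("acc", sig.acc), ("gyro", sig.gyro)):
        if arr.ndim != 2 or arr.shape[0] != 3:
            raise ValidationError(f"{label}: {name} must be 3 x Na, got {arr.shape}")
    if sig.acc.shape[1] != sig.gyro.shape[1]:
        raise ValidationError(f"{label}: ACC and GYRO lengths differ")
    for name, arr in (("semg", sig.semg), ("acc", sig.acc), ("gyro", sig.gyro)):
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"{label}: non-finite samples in {name}")
    ns, na = sig.semg.shape[1], sig.acc.shape[1]
    if ns < 200 or na < 20:
        raise ValidationError(
            f"{label}: gesture too short (Ns={ns}, Na={na}; need >= 0.2 s)")
    if abs(ns - 10 * na) > 10:
        raise ValidationError(
            f"{label}: sampling-rate ratio violated (Ns={ns}, Na={na})")


def validate_recording(rec: GestureRecording) -> None:
    """Check every recording invariant; raise :class:`ValidationError` on failure."""
    if rec.hands not in ("right", "both"):
        raise ValidationError(f"hands must be 'right' or 'both', got {rec.hands!r}")
    if int(rec.repetition) < 1:
        raise ValidationError("repetition must be >= 1")
    _validate_hand(rec.right, "right hand")
    if rec.hands == "both":
        if rec.left is None:
            raise ValidationError("hands='both' requires left-hand signals")
        _validate_hand(rec.left, "left hand")
    elif rec.left is not None:
        raise ValidationError("hands='right' must not carry left-hand signals")


@dataclass(frozen=True)
class ComponentRepresentation:
    """The 13 subclass indices of a gesture, all 1-based."""

    sb: int
    sm: int
    se: int
    ob: int
    om: int
    oe: int
    ab: int
    am: int
    ae: int
    rb: int
    rm: int
    re: int
    tr: int

    def as_tuple(self) -> tuple[int, ...]:
        return tuple(getattr(self, name) for name in ELEMENT_NAMES)

    @classmethod
    def from_tuple(cls, values) -> "ComponentRepresentation":
        values = tuple(int(v) for v in values)
        if len(values) != 13:
            raise ValidationError(f"representation needs 13 elements, got {len(values)}")
        return cls(*values)

    def element(self, name: str) -> int:
        return int(getattr(self, name))

    def __post_init__(self) -> None:
        for name in ELEMENT_NAMES:
            v = getattr(self, name)
            if int(v) < 1:
                raise ValidationError(f"element {name} must be a 1-based index, got {v}")
            object.__setattr__(self, name, int(v))

    def validate_against(self, inventory: "SubclassInventory") -> None:
        for name, component, _stage in ELEMENTS:
            n = inventory.component(component).n
            v = getattr(self, name)
            if not 1 <= v <= n:
                raise ValidationError(
                    f"element {name}={v} outside 1..{n} for component {component}")


@dataclass
class ComponentInventory:
    """Subclasses of one component: count, cluster centers, representatives.

    ``centers`` has one row per subclass in the clustering space of that
    component; ``representatives`` maps each 1-based subclass index to
    the gesture ids of the reference set containing it (in any stage).
    """

    n: int
    centers: np.ndarray
    representatives: dict[int, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.n < 1:
            raise ValidationError("subclass count must be >= 1")
        if self.centers.shape[0] != self.n:
            raise ValidationError(
                f"{self.centers.shape[0]} centers for {self.n} subclasses")
        for idx, gids in self.representatives.items():
            if not 1 <= int(idx) <= self.n:
                raise ValidationError(f"representative index {idx} out of range")
            if not gids:
                raise ValidationError(f"subclass {idx} has no representative gesture")


@dataclass
class SubclassInventory:
    """Per-component subclass inventories discovered from reference data."""

    components: dict[str, ComponentInventory]

    def __post_init__(self) -> None:
        missing = set(COMPONENTS) - set(self.components)
        if missing:
            raise ValidationError(f"inventory missing components: {sorted(missing)}")

    def component(self, name: str) -> ComponentInventory:
        try:
            return self.components[name]
        except KeyError:
            raise ValidationError(f"unknown component {name!r}") from None

    @property
    def counts(self) -> tuple[int, ...]:
        """Subclass counts in canonical component order."""
        return tuple(self.components[c].n for c in COMPONENTS)

    def segment_lengths(self) -> tuple[int, ...]:
        """Bit-segment lengths of a gesture code in 13-element order."""
        return tuple(self.components[comp].n for _name, comp, _stage in ELEMENTS)


def representation_dict(rep: ComponentRepresentation) -> dict[str, int]:
    return {name: getattr(rep, name) for name in ELEMENT_NAMES}


def representation_from_dict(d) -> ComponentRepresentation:
    return ComponentRepresentation.from_tuple(d[name] for name in ELEMENT_NAMES)


def dataclass_fields(obj) -> list[str]:
    return [f.name for f in dataclasses.fields(obj)]
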