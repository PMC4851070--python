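"""Gesture encoding and code matching.

Each of the 13 representation elements is encoded as a one-hot binary
segment of length equal to that component's subclass count, and the
segments are concatenated in canonical element order (bit 1 leftmost
within a segment).  Reference codes carry exactly one bit per segment;
test codes set both the maximal- and submaximal-probability subclass
bits to absorb execution differences between users.  Matching is by
popcount of the bitwise AND against every table entry.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    ComponentRepresentation,
    SubclassInventory,
    ValidationError,
    ELEMENT_NAMES,
)

log = logging.getLogger(__name__)


def encode_subclass(i: int, n: int) -> np.ndarray:
    """Length-``n`` binary segment with (1-based) bit ``i`` set."""
    if not 1 <= i <= n:
        raise ValidationError(f"subclass index {i} outside 1..{n}")
    seg = np.zeros(n, dtype=np.uint8)
    seg[i - 1] = 1
    return seg


@dataclass(frozen=True)
class GestureCode:
    """A concatenated binary gesture code with its segment lengths."""

    bits: np.ndarray              # uint8 0/1, length sum(segment_lengths)
    segment_lengths: tuple[int, ...]

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=np.uint8)
        object.__setattr__(self, "bits", bits)
        object.__setattr__(self, "segment_lengths", tuple(int(n) for n in self.segment_lengths))
        if len(self.segment_lengths) != 13:
            raise ValidationError("a gesture code has 13 segments")
        if bits.shape != (sum(self.segment_lengths),):
            raise ValidationError(
                f"code length {bits.shape} != sum of segments {sum(self.segment_lengths)}")
        if not np.all((bits == 0) | (bits == 1)):
            raise ValidationError("code bits must be 0/1")

    def __len__(self) -> int:
        return self.bits.shape[0]

    def popcount(self) -> int:
        return int(self.bits.sum())

    def segments(self) -> list[np.ndarray]:
        out, pos = [], 0
        for n in self.segment_lengths:
            out.append(self.bits[pos:pos + n])
            pos += n
        return out

    def as_string(self, sep: str = "") -> str:
        """The printable code, optionally with a separator between segments."""
        return sep.join("".join(map(str, seg)) for seg in self.segments())

    @classmethod
    def from_string(cls, s: str, segment_lengths) -> "GestureCode":
        s = s.replace(" ", "")
        if set(s) - {"0", "1"}:
            raise ValidationError("code string must contain only 0/1")
        return cls(bits=np.frombuffer(s.encode(), dtype=np.uint8) - ord("0"),
                   segment_lengths=tuple(segment_lengths))


def encode_gesture(rep: ComponentRepresentation,
                   inventory: SubclassInventory) -> GestureCode:
    """One-hot reference code of a gesture (popcount 13)."""
    rep.validate_against(inventory)
    lengths = inventory.segment_lengths()
    segs = [encode_subclass(rep.element(name), n)
            for name, n in zip(ELEMENT_NAMES, lengths)]
    return GestureCode(bits=np.concatenate(segs), segment_lengths=lengths)


def decode_code(code: GestureCode) -> ComponentRepresentation:
    """Invert a one-hot reference code back to its representation."""
    values = []
    for seg in code.segments():
        if int(seg.sum()) != 1:
            raise ValidationError("only one-hot reference codes can be decoded")
        values.append(int(np.argmax(seg)) + 1)
    return ComponentRepresentation.from_tuple(values)


def encode_test(rankings: dict[str, list[tuple[int, float]]],
                inventory: SubclassInventory) -> GestureCode:
    """Dual-bit test code: per element, the top-1 and top-2 subclass bits.

    ``rankings`` maps each element name to its subclass scores sorted
    descending, as produced by
    :func:`signcomp.classifiers.score_all_components`.  Components with
    a single subclass contribute one bit.
    """
    lengths = inventory.segment_lengths()
    segs = []
    for name, n in zip(ELEMENT_NAMES, lengths):
        if name not in rankings or not rankings[name]:
            raise ValidationError(f"missing ranking for element {name!r}")
        seg = np.zeros(n, dtype=np.uint8)
        for idx, _score in rankings[name][:2]:
            if not 1 <= idx <= n:
                raise ValidationError(f"ranked subclass {idx} outside 1..{n}")
            seg[idx - 1] = 1
        segs.append(seg)
    return GestureCode(bits=np.concatenate(segs), segment_lengths=lengths)


@dataclass
class CodeTable:
    """Ordered map from gesture id to reference :class:`GestureCode`."""

    entries: dict[str, GestureCode]

    def __post_init__(self):
        lengths = {code.segment_lengths for code in self.entries.values()}
        if len(lengths) > 1:
            raise ValidationError("all codes in a table must share segment lengths")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def gesture_ids(self) -> list[str]:
        return list(self.entries)

    @property
    def segment_lengths(self) -> tuple[int, ...]:
        first = next(iter(self.entries.values()))
        return first.segment_lengths

    def matrix(self) -> np.ndarray:
        return np.stack([c.bits for c in self.entries.values()])

    def representations(self) -> dict[str, ComponentRepresentation]:
        return {gid: decode_code(code) for gid, code in self.entries.items()}

    def to_dict(self) -> dict:
        return {
            "segment_lengths": list(self.segment_lengths),
            "entries": [
                {"gesture_id": gid, "code": code.as_string()}
                for gid, code in self.entries.items()
            ],
        }

    @classmethod
    def from_dict(cls, d) -> "CodeTable":
        lengths = tuple(int(n) for n in d["segment_lengths"])
        entries = {
            e["gesture_id"]: GestureCode.from_string(e["code"], lengths)
            for e in d["entries"]
        }
        return cls(entries=entries)


def build_code_table(reps: dict[str, ComponentRepresentation],
                     inventory: SubclassInventory) -> CodeTable:
    """Encode every target gesture; duplicate codes are legal (distinct
    words may share all 13 components) but are logged."""
    entries: dict[str, GestureCode] = {}
    seen: dict[bytes, str] = {}
    for gid, rep in reps.items():
        code = encode_gesture(rep, inventory)
        key = code.bits.tobytes()
        if key in seen:
            log.warning("gesture %r shares its code with %r", gid, seen[key])
        else:
            seen[key] = gid
        entries[gid] = code
    return CodeTable(entries=entries)


def match_scores(x: GestureCode, table: CodeTable) -> np.ndarray:
    """Popcount of ``x AND C_i`` for every table entry, in table order."""
    if len(table) == 0:
        raise ValidationError("empty code table")
    if table.segment_lengths != x.segment_lengths:
        raise ValidationError("code length mismatch between test code and table")
    return table.matrix() @ x.bits.astype(np.int64)


def match_code(x: GestureCode, table: CodeTable) -> str:
    """Gesture id with the highest matching score (ties to the earliest
    table entry, with a warning)."""
    scores = match_scores(x, table)
    best = int(np.argmax(scores))
    if np.count_nonzero(scores == scores[best]) > 1:
        warnings.warn("code-match tie broken to earliest table entry",
                      stacklevel=2)
    return table.gesture_ids[best]
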