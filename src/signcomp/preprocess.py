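"""Stage segmentation, overlapped windowing and trajectory resampling.

All sample indices are 0-based and all intervals half-open.  Stage
boundaries are computed as ``[floor(a*L), floor(b*L))`` from the
fractional :class:`~signcomp.core.StagePolicy`, independently on the
1000 Hz sEMG grid and the 100 Hz inertial grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import StagePolicy, ValidationError, STAGES


@dataclass(frozen=True)
class WindowingSpec:
    """Overlapped analysis windows for sEMG feature extraction.

    Defaults are a 128 ms window with a 64 ms increment at 1000 Hz, a
    common choice for sEMG pattern recognition.
    """

    window_len: int = 128
    increment: int = 64

    def __post_init__(self) -> None:
        if not 0 < self.increment <= self.window_len:
            raise ValidationError(
                f"need 0 < increment <= window_len, got {self.increment}, {self.window_len}")

    @classmethod
    def from_ms(cls, window_ms: float = 128.0, increment_ms: float = 64.0,
                rate: float = 1000.0) -> "WindowingSpec":
        return cls(window_len=int(round(window_ms * rate / 1000.0)),
                   increment=int(round(increment_ms * rate / 1000.0)))


def segment_stages(length: int, policy: StagePolicy | None = None
                   ) -> dict[str, tuple[int, int]]:
    """Half-open sample intervals of the begin/middle/end stages.

    Parameters
    ----------
    length : total number of samples L (must be >= 20).
    policy : stage fractions; defaults to 0-25 / 20-80 / 75-100 %.

    Returns
    -------
    dict mapping stage name to ``(start, stop)`` with
    ``start = floor(a*L)`` and ``stop = floor(b*L)``.
    """
    if length < 20:
        raise ValidationError(f"signal too short to segment: L={length} < 20")
    policy = policy or StagePolicy()
    out = {}
    for stage in STAGES:
        a, b = policy.fractions(stage)
        out[stage] = (int(np.floor(a * length)), int(np.floor(b * length)))
    return out


def stage_slice(x: np.ndarray, stage: str, policy: StagePolicy | None = None
                ) -> np.ndarray:
    """Slice the last axis of ``x`` to one stage's samples."""
    start, stop = segment_stages(x.shape[-1], policy)[stage]
    return x[..., start:stop]


def window_signal(x: np.ndarray, spec: WindowingSpec) -> np.ndarray:
    """Split a 1-D series into overlapped frames.

    Frame ``k`` covers ``[k*inc, k*inc + window_len)``; the count is
    ``floor((len - window_len)/inc) + 1`` and a trailing partial window
    is dropped.  Returns an array of shape ``(n_frames, window_len)``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError("window_signal expects a 1-D series")
    n = x.shape[0]
    if n < spec.window_len:
        raise ValidationError(
            f"signal of length {n} shorter than window {spec.window_len}")
    n_frames = (n - spec.window_len) // spec.increment + 1
    starts = np.arange(n_frames) * spec.increment
    return np.stack([x[s:s + spec.window_len] for s in starts])


def resample_linear(x: np.ndarray, m: int = 64) -> np.ndarray:
    """Resample a 1-D series to ``m`` points by linear interpolation.

    The ``m`` query positions are equally spaced over the full series,
    so the first and last samples are preserved exactly and a series
    already of length ``m`` passes through unchanged.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.shape[0] < 2:
        raise ValidationError("resample_linear needs a 1-D series of length >= 2")
    positions = np.linspace(0.0, x.shape[0] - 1, m)
    return np.interp(positions, np.arange(x.shape[0]), x)
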