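"""The five component feature extractors.

Hand shape is characterised per sEMG frame by a 32-dimensional vector
(4 channels x [MAV, a1..a4, ZC, SSC, WL]); axis and rotation by the
per-stage channel standard deviations plus shared-normalisation signed
correlation values of the mean-removed ACC (resp. GYRO) channels;
orientation by the per-stage ACC channel means (the gravity direction);
trajectory by the whole-gesture ACC+GYRO curves resampled to 64 points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.regression.linear_model import burg

from .core import GestureRecording, StagePolicy, ValidationError, STAGES
from .preprocess import WindowingSpec, resample_linear, stage_slice, window_signal

AR_ORDER = 4
HANDSHAPE_DIM = 4 * (4 + AR_ORDER)  # 32
TRAJECTORY_POINTS = 64


def mav(x: np.ndarray) -> float:
    """Mean absolute value, (1/N) * sum |x_n|."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValidationError("mav of empty series")
    return float(np.mean(np.abs(x)))


def ar_coefficients(x: np.ndarray, p: int = AR_ORDER) -> np.ndarray:
    """Order-``p`` autoregressive coefficients of ``x``.

    Uses Burg's method and returns coefficients ``a_1..a_p`` in the
    convention ``x(n) = w(n) - sum_k a_k x(n-k)``.  A constant or
    degenerate series yields a zero vector with a warning instead of
    aborting the surrounding gesture.
    """
    x = np.asarray(x, dtype=float)
    if x.size <= p:
        raise ValidationError(f"need more than p={p} samples for an AR({p}) fit")
    if np.ptp(x) == 0.0:
        warnings.warn("constant series: AR coefficients set to zero", stacklevel=2)
        return np.zeros(p)
    try:
        rho, _sigma2 = burg(x, order=p, demean=True)
    except (ValueError, np.linalg.LinAlgError):
        warnings.warn("degenerate series: AR coefficients set to zero", stacklevel=2)
        return np.zeros(p)
    if not np.all(np.isfinite(rho)):
        warnings.warn("non-finite AR fit: coefficients set to zero", stacklevel=2)
        return np.zeros(p)
    return -np.asarray(rho, dtype=float)


def default_threshold(x: np.ndarray) -> float:
    """The amplitude threshold 0.05 * std(x) used by ZC and SSC."""
    return 0.05 * float(np.std(np.asarray(x, dtype=float)))


def zero_crossings(x: np.ndarray, threshold: float | None = None) -> int:
    """Count sign changes between consecutive samples whose amplitude
    gap reaches ``threshold`` (default 0.05 * std of the frame)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValidationError("zero_crossings needs at least 2 samples")
    thr = default_threshold(x) if threshold is None else float(threshold)
    sign_change = x[:-1] * x[1:] < 0
    big_enough = np.abs(x[:-1] - x[1:]) >= thr
    return int(np.count_nonzero(sign_change & big_enough))


def slope_sign_changes(x: np.ndarray, threshold: float | None = None) -> int:
    """Count samples where the slope changes sign with product of the
    neighbouring differences at least ``threshold``."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValidationError("slope_sign_changes needs at least 3 samples")
    thr = default_threshold(x) if threshold is None else float(threshold)
    prod = (x[1:-1] - x[:-2]) * (x[1:-1] - x[2:])
    # a flat neighbourhood (zero product) is not a slope change even when
    # the degenerate threshold of a constant frame is zero
    return int(np.count_nonzero((prod >= thr) & (prod > 0)))


def waveform_length(x: np.ndarray) -> float:
    """Cumulative amplitude path length, sum |x_{n+1} - x_n|."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValidationError("waveform_length needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


def frame_features(frame: np.ndarray) -> np.ndarray:
    """The 8 time-domain features of one channel frame:
    [MAV, a1, a2, a3, a4, ZC, SSC, WL]."""
    return np.concatenate((
        [mav(frame)],
        ar_coefficients(frame),
        [zero_crossings(frame), slope_sign_changes(frame), waveform_length(frame)],
    ))


def handshape_features(stage_semg: np.ndarray, spec: WindowingSpec | None = None
                       ) -> np.ndarray:
    """Per-frame 32-dimensional handshape features of a 4-channel sEMG stage.

    Returns an array of shape ``(n_frames, 32)`` in channel-major order
    ``[ch1: MAV,a1..a4,ZC,SSC,WL, ch2: ..., ch3: ..., ch4: ...]``.
    """
    stage_semg = np.asarray(stage_semg, dtype=float)
    if stage_semg.ndim != 2 or stage_semg.shape[0] != 4:
        raise ValidationError(f"expected 4 x Ns sEMG stage, got {stage_semg.shape}")
    spec = spec or WindowingSpec()
    frames_per_ch = [window_signal(ch, spec) for ch in stage_semg]
    n_frames = frames_per_ch[0].shape[0]
    out = np.empty((n_frames, HANDSHAPE_DIM))
    for k in range(n_frames):
        out[k] = np.concatenate([frame_features(fr[k]) for fr in frames_per_ch])
    return out


def axis_features(stage_acc: np.ndarray) -> np.ndarray:
    """Axis features of a 3-channel stage: (std1, std2, std3, r12, r13, r23).

    Channels are mean-removed; ``Snorm`` is the sum of the Euclidean
    norms of the mean-removed channels and
    ``r_ij = |S_i . S_j| / Snorm * sign(S_i . S_j)``.  Note the shared
    normalisation: this is a signed co-energy ratio, not a Pearson
    correlation.  An identically-zero stage returns all zeros.
    """
    s = np.asarray(stage_acc, dtype=float)
    if s.ndim != 2 or s.shape[0] != 3:
        raise ValidationError(f"expected 3 x Na stage, got {s.shape}")
    if s.shape[1] < 2:
        raise ValidationError("axis features need at least 2 samples")
    s = s - s.mean(axis=1, keepdims=True)
    stds = s.std(axis=1)
    snorm = float(np.sum(np.linalg.norm(s, axis=1)))
    if snorm == 0.0:
        return np.zeros(6)
    r = []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        dot = float(s[i] @ s[j])
        r.append(abs(dot) / snorm * np.sign(dot))
    return np.concatenate((stds, r))


def orientation_features(stage_acc: np.ndarray) -> np.ndarray:
    """Per-channel mean of the 3-axis ACC stage -- the gravity direction."""
    s = np.asarray(stage_acc, dtype=float)
    if s.ndim != 2 or s.shape[0] != 3 or s.shape[1] < 1:
        raise ValidationError(f"expected non-empty 3 x Na stage, got {s.shape}")
    return s.mean(axis=1)


def rotation_features(stage_gyro: np.ndarray) -> np.ndarray:
    """Rotation features: identical contract to :func:`axis_features` on GYRO."""
    return axis_features(stage_gyro)


def trajectory_features(acc: np.ndarray, gyro: np.ndarray,
                        m: int = TRAJECTORY_POINTS) -> np.ndarray:
    """Whole-gesture ACC+GYRO curves resampled to ``m`` points.

    Returns shape ``(m, 6)`` with columns (acc_x, acc_y, acc_z,
    gyro_x, gyro_y, gyro_z).
    """
    acc = np.asarray(acc, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    if acc.shape[0] != 3 or gyro.shape[0] != 3 or acc.shape[1] != gyro.shape[1]:
        raise ValidationError("trajectory needs matching 3 x Na ACC and GYRO")
    if acc.shape[1] < 2:
        raise ValidationError("trajectory needs at least 2 samples")
    chans = [resample_linear(ch, m) for ch in acc] + [resample_linear(ch, m) for ch in gyro]
    return np.stack(chans, axis=1)


@dataclass
class GestureFeatures:
    """All component features of one hand of one recording.

    ``handshape[stage]`` is ``(n_frames, 32)``; ``orientation[stage]``
    is ``(3,)``; ``axis[stage]`` and ``rotation[stage]`` are ``(6,)``;
    ``trajectory`` is ``(64, 6)``.
    """

    handshape: dict[str, np.ndarray]
    orientation: dict[str, np.ndarray]
    axis: dict[str, np.ndarray]
    rotation: dict[str, np.ndarray]
    trajectory: np.ndarray

    def stage_vector(self, component: str, stage: str | None) -> np.ndarray:
        if component == "trajectory":
            return self.trajectory
        return getattr(self, component)[stage]


def extract_features(rec: GestureRecording, hand: str = "right",
                     policy: StagePolicy | None = None,
                     windowing: WindowingSpec | None = None) -> GestureFeatures:
    """Segment one hand of a recording into stages and extract all
    five component features."""
    policy = policy or StagePolicy()
    windowing = windowing or WindowingSpec()
    sig = rec.hand(hand)
    handshape, orientation, axis_f, rotation = {}, {}, {}, {}
    for stage in STAGES:
        semg_stage = stage_slice(sig.semg, stage, policy)
        acc_stage = stage_slice(sig.acc, stage, policy)
        gyro_stage = stage_slice(sig.gyro, stage, policy)
        handshape[stage] = handshape_features(semg_stage, windowing)
        orientation[stage] = orientation_features(acc_stage)
        axis_f[stage] = axis_features(acc_stage)
        rotation[stage] = rotation_features(gyro_stage)
    return GestureFeatures(
        handshape=handshape,
        orientation=orientation,
        axis=axis_f,
        rotation=rotation,
        trajectory=trajectory_features(sig.acc, sig.gyro),
    )
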