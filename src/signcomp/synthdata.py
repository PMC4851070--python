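"""Synthetic gesture generator with planted, known component subclasses.

The generator emulates wristband recordings of pre-segmented sign
gestures so that every stage of the framework -- feature extraction,
subclass clustering, classifier training and code matching, including
recognition of gestures absent from the training set -- can be tested
against ground truth:

* **hand shape** drives the sEMG: band-limited (20-450 Hz) Gaussian
  interference-pattern noise whose per-channel amplitude vector (mV) is
  the subclass signature, piecewise constant over the three stages;
* **orientation** drives the per-stage gravity direction of the ACC
  (unit magnitude, z axis through the palm);
* **axis** adds a zero-mean, Hann-enveloped two-cycle translation
  burst (g) along the subclass axis within each stage (the envelope
  vanishes at the stage edges, so bursts do not bleed into the
  overlapping analysis windows of neighbouring stages);
* **rotation** adds the analogous angular-velocity burst (deg/s) on the
  GYRO;
* **trajectory** adds localized Gabor wavelets (a six-cycle-per-stage
  carrier under a Gaussian envelope) whose channel-to-time-slot
  permutation, per stage, is the subclass signature.  Every channel
  receives exactly one wavelet per stage, so the per-stage signal power
  seen by the axis and rotation features is the same for every
  trajectory subclass and only the temporal arrangement differs; the
  carrier band sits above the two-cycle burst band so the trajectory
  clustering metric can separate the two.

All waveforms are parameterised in cycles per stage rather than Hz, so
the resampled 64-point trajectory curves are duration-invariant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .core import (
    ComponentInventory,
    ComponentRepresentation,
    GestureRecording,
    HandSignals,
    StagePolicy,
    SubclassInventory,
    ValidationError,
    COMPONENTS,
    ELEMENTS,
    INERTIAL_RATE,
    SEMG_RATE,
    STAGES,
)
from .preprocess import WindowingSpec

#: Convenience noise levels ("low" is near the clean limit, "moderate"
#: emulates an ordinary wearable session).
NOISE_LOW = 0.1
NOISE_MODERATE = 0.35

# signal amplitudes (units: mV, g, deg/s)
_AXIS_BURST_G = 3.0
_ROTATION_BURST_DPS = 100.0
_TRAJ_WAVELET_ACC_G = 0.6
_TRAJ_WAVELET_GYRO_DPS = 20.0
_WAVELET_CYCLES = 6          # Gabor carrier, cycles per stage
_ACC_NOISE_G = 0.25          # at noise = 1
_GYRO_NOISE_DPS = 25.0       # at noise = 1
_SEMG_BASELINE_MV = 0.03     # at noise = 1
_BURST_CYCLES = 2

def _gravity_directions(n: int, tilt_deg: float = 40.0) -> np.ndarray:
    """Unit gravity directions: the palm-down pole plus ``n - 1`` evenly
    spaced directions on a cone tilted ``tilt_deg`` from it.  Orientations
    within a gesture change by moderate wrist rotations, not full flips,
    so the set is deliberately compact."""
    t = np.deg2rad(tilt_deg)
    dirs = [(0.0, 0.0, 1.0)]
    for k in range(n - 1):
        phi = 2 * np.pi * k / (n - 1)
        dirs.append((np.sin(t) * np.cos(phi), np.sin(t) * np.sin(phi), np.cos(t)))
    return np.asarray(dirs)

_MOTION_AXES = np.array([
    (1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (1, 0, 1), (0, 1, 1),
], dtype=float)
_MOTION_AXES /= np.linalg.norm(_MOTION_AXES, axis=1, keepdims=True)

_PERMS3 = list(itertools.permutations(range(3)))  # 6 channel-slot layouts

#: Wavelet slot centers as fractions of each generation stage.  Begin-stage
#: slots lean early and end-stage slots lean late so no wavelet enters the
#: overlapping 20-80 % middle analysis window of a neighbouring stage.
_SLOT_FRACTIONS = ((0.15, 0.40, 0.65), (0.25, 0.50, 0.75), (0.35, 0.60, 0.85))

_MAX_COUNTS = {"handshape": 16, "orientation": 8, "axis": 6, "rotation": 6,
               "trajectory": 12}


def _counts_dict(counts) -> dict[str, int]:
    if not isinstance(counts, dict):
        counts = dict(zip(COMPONENTS, counts))
    if set(counts) != set(COMPONENTS):
        raise ValidationError(f"counts must cover components {COMPONENTS}")
    for comp, n in counts.items():
        n = int(n)
        if n < 2:
            raise ValidationError(
                f"{comp}: need >= 2 subclasses so submaximal bits are meaningful")
        if n > _MAX_COUNTS[comp]:
            raise ValidationError(
                f"{comp}: at most {_MAX_COUNTS[comp]} synthetic subclasses")
    return {c: int(counts[c]) for c in COMPONENTS}


def _sample_semg_amplitudes(n: int, rng: np.random.Generator,
                            min_dist: float = 0.3) -> np.ndarray:
    """Distinct 4-channel sEMG amplitude vectors (mV) with a minimum
    mutual Euclidean separation."""
    out: list[np.ndarray] = []
    for _ in range(20000):
        cand = rng.uniform(0.1, 1.0, size=4)
        if all(np.linalg.norm(cand - p) >= min_dist for p in out):
            out.append(cand)
            if len(out) == n:
                return np.asarray(out)
    raise ValidationError(f"could not place {n} separated sEMG amplitude vectors")


@dataclass
class SyntheticWorldSpec:
    """Deterministic description of a synthetic gesture vocabulary's
    component subclasses and noise level."""

    counts: dict[str, int]
    noise: float
    seed: int
    semg_amplitudes: np.ndarray = field(init=False)    # (n_S, 4) mV
    gravity: np.ndarray = field(init=False)            # (n_O, 3) unit g
    axes: np.ndarray = field(init=False)               # (n_A, 3) unit
    rotation_axes: np.ndarray = field(init=False)      # (n_R, 3) unit

    def __post_init__(self):
        self.counts = _counts_dict(self.counts)
        if self.noise < 0:
            raise ValidationError("noise must be >= 0")
        rng = np.random.default_rng(self.seed)
        self.semg_amplitudes = _sample_semg_amplitudes(self.counts["handshape"], rng)
        self.gravity = _gravity_directions(self.counts["orientation"])
        self.axes = _MOTION_AXES[: self.counts["axis"]].copy()
        self.rotation_axes = _MOTION_AXES[: self.counts["rotation"]].copy()

    @property
    def n_representations(self) -> int:
        n = self.counts
        return (n["handshape"] ** 3 * n["orientation"] ** 3 * n["axis"] ** 3
                * n["rotation"] ** 3 * n["trajectory"])

    def traj_permutation(self, subclass: int, stage_idx: int, group: str) -> tuple:
        """Channel-to-slot permutation of trajectory ``subclass`` (1-based)
        in one stage, for the ``"acc"`` or ``"gyro"`` channel triple."""
        t = subclass - 1
        if group == "acc":
            return _PERMS3[(t + stage_idx) % 6]
        return _PERMS3[(t + 2 * stage_idx + 3) % 6]

    def traj_sign(self, subclass: int) -> float:
        return 1.0 if subclass <= 6 else -1.0


def make_world(counts=(6, 4, 3, 3, 6), noise: float = NOISE_MODERATE,
               seed: int = 0) -> SyntheticWorldSpec:
    """Build a synthetic world; identical seeds give identical worlds."""
    return SyntheticWorldSpec(counts=counts, noise=float(noise), seed=int(seed))


def _gabor(idx: np.ndarray, center: float, sigma: float,
           stage_len: float) -> np.ndarray:
    """Gabor wavelet: a six-cycle-per-stage sine carrier, phase-locked to
    the wavelet center, under a Gaussian envelope.  Approximately
    zero-mean and spectrally above the motion-burst band."""
    z = (idx - center) / sigma
    carrier = np.sin(2 * np.pi * _WAVELET_CYCLES * (idx - center) / stage_len)
    return np.exp(-0.5 * z ** 2) * carrier


def _stage_bounds(n: int) -> list[tuple[int, int]]:
    """Non-overlapping generation stages at 25/50/25 % of the samples."""
    b1, b2 = int(np.floor(0.25 * n)), int(np.floor(0.75 * n))
    return [(0, b1), (b1, b2), (b2, n)]


def _gravity_bounds(n: int) -> list[tuple[int, int]]:
    """Gravity switches orientation at the centers of the 20-25 % and
    75-80 % analysis-window overlap zones, so each feature window sees at
    most half an overlap zone of a neighbouring stage's gravity."""
    b1, b2 = int(np.floor(0.225 * n)), int(np.floor(0.775 * n))
    return [(0, b1), (b1, b2), (b2, n)]


_SEMG_SOS = butter(4, [20.0, 450.0], btype="bandpass", fs=SEMG_RATE, output="sos")


def generate_gesture(rep: ComponentRepresentation, world: SyntheticWorldSpec,
                     duration_s: float | None = None, rng=None,
                     subject_id: str = "synth", gesture_id: str = "G000",
                     repetition: int = 1,
                     noise: float | None = None) -> GestureRecording:
    """Synthesise one right-handed recording of ``rep``.

    ``rng`` may be a seed or a :class:`numpy.random.Generator`; with
    ``noise=0`` and a fixed duration the signals are deterministic.
    """
    rep.validate_against(_counts_inventory(world))
    rng = np.random.default_rng(rng)
    noise = world.noise if noise is None else float(noise)
    if duration_s is None:
        duration_s = rng.uniform(2.0, 2.6)
    na = int(round(duration_s * INERTIAL_RATE))
    ns = 10 * na
    acc = np.zeros((3, na))
    gyro = np.zeros((3, na))
    bounds = _stage_bounds(na)
    amp_jit = lambda: np.clip(1.0 + 0.15 * noise * rng.standard_normal(), 0.5, 1.5)

    stage_elements = {
        "orientation": (rep.ob, rep.om, rep.oe),
        "axis": (rep.ab, rep.am, rep.ae),
        "rotation": (rep.rb, rep.rm, rep.re),
    }
    for s_idx, (g0, g1) in enumerate(_gravity_bounds(na)):
        g_dir = world.gravity[stage_elements["orientation"][s_idx] - 1]
        acc[:, g0:g1] += g_dir[:, None]
    for s_idx, (s0, s1) in enumerate(bounds):
        length = s1 - s0
        frac = (np.arange(s0, s1) - s0) / length
        hann = np.sin(np.pi * frac) ** 2
        # Hann-enveloped translation burst along the axis subclass
        a_dir = world.axes[stage_elements["axis"][s_idx] - 1]
        phase = 0.2 * noise * rng.standard_normal()
        burst = hann * np.sin(2 * np.pi * _BURST_CYCLES * frac + phase)
        acc[:, s0:s1] += _AXIS_BURST_G * amp_jit() * a_dir[:, None] * burst[None, :]
        # angular-velocity burst along the rotation subclass
        r_dir = world.rotation_axes[stage_elements["rotation"][s_idx] - 1]
        phase = 0.2 * noise * rng.standard_normal()
        burst = hann * np.sin(2 * np.pi * _BURST_CYCLES * frac + phase)
        gyro[:, s0:s1] += (_ROTATION_BURST_DPS * amp_jit()
                           * r_dir[:, None] * burst[None, :])
        # trajectory wavelets: one per channel per stage, slot permuted
        idx = np.arange(s0, s1, dtype=float)
        sigma = 0.125 * length
        sign = world.traj_sign(rep.tr)
        for group, target, amp in (("acc", acc, _TRAJ_WAVELET_ACC_G),
                                   ("gyro", gyro, _TRAJ_WAVELET_GYRO_DPS)):
            perm = world.traj_permutation(rep.tr, s_idx, group)
            for j, ch in enumerate(perm):
                center = (s0 + _SLOT_FRACTIONS[s_idx][j] * length
                          + 0.02 * noise * length * rng.standard_normal())
                target[ch, s0:s1] += (sign * amp * amp_jit()
                                      * _gabor(idx, center, sigma, length))
    acc += _ACC_NOISE_G * noise * rng.standard_normal((3, na))
    gyro += _GYRO_NOISE_DPS * noise * rng.standard_normal((3, na))

    # sEMG: shaped interference noise with per-stage amplitude signatures
    raw = rng.standard_normal((4, ns))
    shaped = sosfiltfilt(_SEMG_SOS, raw, axis=1)
    shaped /= shaped.std(axis=1, keepdims=True)
    envelope = np.zeros((4, ns))
    amps = world.semg_amplitudes
    for s_idx, sub in enumerate((rep.sb, rep.sm, rep.se)):
        s0, s1 = _stage_bounds(ns)[s_idx]
        jit = np.clip(1.0 + 0.2 * noise * rng.standard_normal(4), 0.4, 1.6)
        envelope[:, s0:s1] = (amps[sub - 1] * jit)[:, None]
    semg = shaped * envelope + _SEMG_BASELINE_MV * noise * rng.standard_normal((4, ns))

    return GestureRecording(
        subject_id=subject_id, gesture_id=gesture_id,
        repetition=int(repetition), hands="right",
        right=HandSignals(semg=semg, acc=acc, gyro=gyro),
    )


def _counts_inventory(world: SyntheticWorldSpec) -> SubclassInventory:
    """A bounds-only inventory (empty centers) for representation checks."""
    comps = {}
    for comp, n in world.counts.items():
        comps[comp] = ComponentInventory(n=n, centers=np.zeros((n, 1)))
    return SubclassInventory(components=comps)


def _covering_representations(world: SyntheticWorldSpec, n_blocks: int = 3,
                              shift: int = 0) -> list[ComponentRepresentation]:
    """Deterministic representations that jointly cover every subclass of
    every component, cycling indices with per-component/stage offsets so
    component combinations are decorrelated."""
    k = n_blocks * max(world.counts.values())
    reps = []
    for j in range(k):
        values = []
        for e_idx, (_name, comp, stage) in enumerate(ELEMENTS):
            n = world.counts[comp]
            s_off = 0 if stage is None else STAGES.index(stage)
            values.append((j + shift + 2 * e_idx + s_off) % n + 1)
        reps.append(ComponentRepresentation.from_tuple(values))
    return reps


def world_inventory(world: SyntheticWorldSpec,
                    policy: StagePolicy | None = None,
                    windowing: WindowingSpec | None = None) -> SubclassInventory:
    """Ground-truth inventory: subclass centers measured from a noiseless
    calibration batch of covering gestures (deterministic for a world)."""
    from .features import extract_features
    from .subclassing import component_vector

    reps = _covering_representations(world)
    vecs: dict[str, list] = {c: [] for c in COMPONENTS}  # (stage, sub, vec)
    representatives: dict[str, dict[int, set[str]]] = {c: {} for c in COMPONENTS}
    for j, rep in enumerate(reps):
        gid = f"CAL{j:03d}"
        rec = generate_gesture(rep, world, duration_s=2.2, rng=j, noise=0.0,
                               gesture_id=gid)
        feats = extract_features(rec, policy=policy, windowing=windowing)
        for name, comp, stage in ELEMENTS:
            sub = rep.element(name)
            vecs[comp].append((stage, sub, component_vector(feats, comp, stage)))
            representatives[comp].setdefault(sub, set()).add(gid)
    comps = {}
    for comp, n in world.counts.items():
        entries = vecs[comp]
        centers = np.stack([
            np.mean([v for _s, sub, v in entries if sub == j], axis=0)
            for j in range(1, n + 1)
        ])
        comps[comp] = ComponentInventory(n=n, centers=centers,
                                         representatives=representatives[comp])
    return SubclassInventory(components=comps)


@dataclass
class SyntheticDataset:
    """Recordings plus the ground truth they were generated from."""

    world: SyntheticWorldSpec
    recordings: list[GestureRecording]
    representations: dict[str, ComponentRepresentation]
    inventory: SubclassInventory
    code_table: "object"  # CodeTable; typed loosely to avoid an import cycle

    def by_gesture(self) -> dict[str, list[GestureRecording]]:
        out: dict[str, list[GestureRecording]] = {}
        for rec in self.recordings:
            out.setdefault(rec.gesture_id, []).append(rec)
        return out


def generate_dataset(n_gestures: int, reps_per_gesture: int,
                     world: SyntheticWorldSpec, seed: int = 0,
                     subject_id: str = "synth",
                     noise: float | None = None,
                     representations: dict[str, ComponentRepresentation] | None = None,
                     ) -> SyntheticDataset:
    """Sample a target gesture set and synthesise all its repetitions.

    Representations are distinct; the first few are covering gestures so
    that every subclass of every component occurs in the set.  The
    emitted inventory and code table are derived from the planted ground
    truth and are mutually consistent with the representations.  Passing
    ``representations`` (e.g. from a reference subject's dataset) makes a
    new subject perform the same vocabulary instead of sampling one.
    """
    from .codec import build_code_table

    if representations is not None:
        if len(representations) != n_gestures:
            raise ValidationError("representations do not match n_gestures")
        for rep in representations.values():
            rep.validate_against(_counts_inventory(world))
        rng = np.random.default_rng(seed)
        recordings = []
        for gid in representations:
            for r in range(1, reps_per_gesture + 1):
                recordings.append(generate_gesture(
                    representations[gid], world, rng=rng,
                    subject_id=subject_id, gesture_id=gid, repetition=r,
                    noise=noise))
        inventory = world_inventory(world)
        code_table = build_code_table(representations, inventory)
        return SyntheticDataset(world=world, recordings=recordings,
                                representations=dict(representations),
                                inventory=inventory, code_table=code_table)

    if n_gestures > world.n_representations:
        raise ValidationError(
            f"{n_gestures} gestures exceed the {world.n_representations} "
            "distinct representations of this world")
    rng = np.random.default_rng(seed)
    chosen: list[tuple[int, ...]] = []
    seen: set[tuple[int, ...]] = set()
    # two covering blocks so every subclass occurs in at least two
    # distinct gestures (a singleton subclass cannot survive the
    # small-cluster pruning of subclass discovery)
    for rep in _covering_representations(world, n_blocks=2,
                                         shift=int(rng.integers(0, 1000))):
        t = rep.as_tuple()
        if len(chosen) < n_gestures and t not in seen:
            chosen.append(t)
            seen.add(t)
    while len(chosen) < n_gestures:
        values = tuple(
            int(rng.integers(1, world.counts[comp] + 1))
            for _name, comp, _stage in ELEMENTS
        )
        if values not in seen:
            chosen.append(values)
            seen.add(values)
    representations = {
        f"G{i + 1:03d}": ComponentRepresentation.from_tuple(t)
        for i, t in enumerate(chosen)
    }
    recordings = []
    for gid in representations:
        for r in range(1, reps_per_gesture + 1):
            recordings.append(generate_gesture(
                representations[gid], world, rng=rng, subject_id=subject_id,
                gesture_id=gid, repetition=r, noise=noise))
    inventory = world_inventory(world)
    code_table = build_code_table(representations, inventory)
    return SyntheticDataset(world=world, recordings=recordings,
                            representations=representations,
                            inventory=inventory, code_table=code_table)
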