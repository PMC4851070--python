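"""Subclass discovery on reference data: fuzzy c-means clustering with
small-cluster pruning and near-center merging, plus nearest-center
subclass assignment for building component representations.

Sequence-valued components are clustered on fixed-length summaries:
handshape stages on the stage-averaged 32-dimensional frame features,
trajectories on the flattened 64x6 resampled curves after per-stage mean
removal and gyro unit balancing (c-means needs fixed-length vectors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import kmeans_plusplus
from sklearn.utils import check_array, check_random_state

from .core import (
    ComponentInventory,
    ComponentRepresentation,
    SubclassInventory,
    ValidationError,
    COMPONENTS,
    ELEMENTS,
    STAGES,
)
from .features import GestureFeatures

log = logging.getLogger(__name__)

#: Gyroscope magnitudes (deg/s) comparable to 1 g of acceleration in the
#: trajectory clustering metric; balances the mixed-unit 64x6 curves.
GYRO_UNIT_SCALE = 250.0

#: 64-point index ranges of the three non-overlapping gesture stages
#: detrended independently in the trajectory metric.
_TRAJ_SEGMENTS = ((0, 16), (16, 48), (48, 64))

#: Number of within-stage Fourier harmonics removed (with the mean) from
#: each segment of the trajectory metric.
_TRAJ_DETREND_HARMONICS = 3


#: Global 64-point indices of the centers of the two stage-overlap zones
#: (20-25 % and 75-80 %), where the hand orientation hands over from one
#: stage's attitude to the next.
_HANDOVER_POINTS = (14.4, 49.6)


def _segment_residual_projectors() -> list[np.ndarray]:
    out = []
    for a, b in _TRAJ_SEGMENTS:
        p = b - a
        t = np.arange(p)
        cols = [np.ones(p)]
        for k in range(1, _TRAJ_DETREND_HARMONICS + 1):
            cols.append(np.sin(2 * np.pi * k * t / p))
            cols.append(np.cos(2 * np.pi * k * t / p))
        # level-shift regressors where an orientation handover can fall
        # inside this segment (absorbs the interpolated gravity step)
        for h in _HANDOVER_POINTS:
            if a < h < b:
                rel = h - a
                for pos in (int(np.floor(rel)), int(np.ceil(rel)) + 1):
                    if 0 < pos < p:
                        cols.append((t >= pos).astype(float))
        basis = np.column_stack(cols)
        out.append(np.eye(p) - basis @ np.linalg.pinv(basis))
    return out


_RESIDUAL_PROJECTORS = _segment_residual_projectors()


def trajectory_observation(traj: np.ndarray) -> np.ndarray:
    """Normalised 64x6 trajectory observation sequence.

    Gyro columns are divided by :data:`GYRO_UNIT_SCALE` (unit balancing)
    and each stage segment of each channel is detrended by removing its
    mean and first three within-stage Fourier harmonics.  The removed
    smooth baseline is exactly the content the orientation (per-stage
    gravity offset) and axis/rotation (per-stage oscillatory burst)
    features describe; what remains is the transient fine structure that
    characterises the path itself.  Used both as the clustering space
    (flattened) and as the observation sequence of the trajectory HMM.
    """
    v = np.asarray(traj, dtype=float).copy()
    if v.shape != (64, 6):
        raise ValidationError(f"expected 64 x 6 trajectory, got {v.shape}")
    v[:, 3:] /= GYRO_UNIT_SCALE
    for (a, b), proj in zip(_TRAJ_SEGMENTS, _RESIDUAL_PROJECTORS):
        v[a:b] = proj @ v[a:b]
    return v


def trajectory_metric_vector(traj: np.ndarray) -> np.ndarray:
    """Flattened form of :func:`trajectory_observation` (clustering space)."""
    return trajectory_observation(traj).ravel()


def component_vector(features: GestureFeatures, component: str,
                     stage: str | None) -> np.ndarray:
    """The fixed-length clustering-space vector of one element."""
    if component == "trajectory":
        return trajectory_metric_vector(features.trajectory)
    if component == "handshape":
        return np.asarray(features.handshape[stage]).mean(axis=0)
    return np.asarray(features.stage_vector(component, stage), dtype=float)


@dataclass
class FuzzyClusteringResult:
    """Centers, soft memberships and the final objective of a c-means run."""

    centers: np.ndarray      # (k, d)
    membership: np.ndarray   # (n, k), rows sum to 1
    objective: float

    @property
    def labels(self) -> np.ndarray:
        """Hard assignment: argmax membership (0-based cluster index)."""
        return np.argmax(self.membership, axis=1)


def _memberships(X: np.ndarray, centers: np.ndarray, m: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Fuzzy memberships and squared distances for fixed centers."""
    d2 = cdist(X, centers, "sqeuclidean")
    u = np.zeros_like(d2)
    zero_rows = np.min(d2, axis=1) == 0.0
    if np.any(zero_rows):
        hit = np.argmin(d2[zero_rows], axis=1)
        u[np.where(zero_rows)[0], hit] = 1.0
    nz = ~zero_rows
    if np.any(nz):
        # u_ik = 1 / sum_j (d_ik / d_jk)^(1/(m-1)) on squared distances
        ratio = d2[nz, :, None] / d2[nz, None, :]
        u[nz] = 1.0 / np.sum(ratio ** (1.0 / (m - 1.0)), axis=2)
    return u, d2


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy c-means clustering with deterministic k-means++ seeding.

    Parameters
    ----------
    n_clusters : number of clusters k.
    m : fuzzifier (> 1); 2 is the conventional default.
    tol : convergence threshold on the maximum center shift.
    max_iter : iteration cap.
    n_init : number of k-means++ restarts; the run with the lowest
        objective is kept.
    random_state : seed for the k-means++ initialisation.

    Attributes
    ----------
    cluster_centers_ : (k, d) fixed-point centers.
    membership_ : (n, k) membership degrees, rows summing to 1.
    labels_ : hard assignments (argmax membership).
    objective_ : final value of sum_ik u_ik^m d_ik^2.
    objective_history_ : objective after every update (non-increasing).
    """

    def __init__(self, n_clusters: int = 2, m: float = 2.0, tol: float = 1e-5,
                 max_iter: int = 300, n_init: int = 1, random_state=None):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X)
        n = X.shape[0]
        if not 1 <= self.n_clusters <= n:
            raise ValidationError(
                f"need 1 <= k <= n points, got k={self.n_clusters}, n={n}")
        if self.m <= 1.0:
            raise ValidationError("fuzzifier m must be > 1")
        rng = check_random_state(self.random_state)
        best = None
        for _ in range(max(1, self.n_init)):
            state = self._fit_once(X, rng)
            if best is None or state[3][-1] < best[3][-1]:
                best = state
        self.cluster_centers_, self.membership_, _d2, history = best
        self.labels_ = np.argmax(self.membership_, axis=1)
        self.objective_ = history[-1]
        self.objective_history_ = history
        self.n_iter_ = len(history)
        return self

    def _fit_once(self, X, rng):
        if self.n_clusters == 1:
            centers = X.mean(axis=0, keepdims=True)
        else:
            centers, _ = kmeans_plusplus(X, self.n_clusters, random_state=rng)
        history = []
        u, d2 = _memberships(X, centers, self.m)
        for it in range(self.max_iter):
            um = u ** self.m
            denom = um.sum(axis=0)
            # a center losing all support keeps its position but is nudged
            # off any exact duplicate so memberships stay well defined
            new_centers = np.where(denom[:, None] > 0,
                                   (um.T @ X) / np.maximum(denom, 1e-300)[:, None],
                                   centers)
            new_centers = self._split_duplicates(new_centers, X, rng)
            shift = float(np.max(np.linalg.norm(new_centers - centers, axis=1)))
            centers = new_centers
            u, d2 = _memberships(X, centers, self.m)
            history.append(float(np.sum((u ** self.m) * d2)))
            if shift < self.tol:
                break
        return centers, u, d2, history

    @staticmethod
    def _split_duplicates(centers: np.ndarray, X: np.ndarray,
                          rng: np.random.RandomState) -> np.ndarray:
        """Perturb centers that collapsed onto each other."""
        scale = max(float(np.ptp(X)), 1.0) * 1e-9
        for i in range(1, centers.shape[0]):
            while np.any(np.all(centers[:i] == centers[i], axis=1)):
                centers[i] = centers[i] + rng.standard_normal(centers.shape[1]) * scale
        return centers

    def soft_membership(self, X) -> np.ndarray:
        X = check_array(X)
        u, _ = _memberships(X, self.cluster_centers_, self.m)
        return u

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.soft_membership(X), axis=1)

    @property
    def result_(self) -> FuzzyClusteringResult:
        return FuzzyClusteringResult(
            centers=self.cluster_centers_,
            membership=self.membership_,
            objective=self.objective_,
        )


def fuzzy_cmeans(X: np.ndarray, k: int, m: float = 2.0, tol: float = 1e-5,
                 max_iter: int = 300, seed=None, n_init: int = 1
                 ) -> FuzzyClusteringResult:
    """Functional wrapper around :class:`FuzzyCMeans`."""
    return FuzzyCMeans(n_clusters=k, m=m, tol=tol, max_iter=max_iter,
                       n_init=n_init,
                       random_state=seed).fit(np.asarray(X, dtype=float)).result_


def auto_merge_distance(centers: np.ndarray, fraction: float = 0.25) -> float:
    """Default merge threshold: ``fraction`` of the median inter-center distance."""
    if centers.shape[0] < 2:
        return 0.0
    return fraction * float(np.median(pdist(centers)))


def prune_and_merge(X: np.ndarray, result: FuzzyClusteringResult,
                    min_members: int = 2, merge_dist: float | None = None,
                    m: float = 2.0) -> FuzzyClusteringResult:
    """Discard under-populated clusters and merge near-identical centers.

    Clusters with fewer than ``min_members`` hard members are removed
    (their points fall to the nearest surviving center); center pairs
    closer than ``merge_dist`` are replaced by their member-count
    weighted mean.  Both steps repeat until stable.  When ``merge_dist``
    is None it is recomputed from the surviving centers on every pass
    (0.25 x their median inter-center distance), so duplicate centers of
    an over-provisioned initial clustering do not depress the threshold.
    """
    X = np.asarray(X, dtype=float)
    centers = np.asarray(result.centers, dtype=float).copy()
    auto = merge_dist is None
    while True:
        if auto:
            merge_dist = auto_merge_distance(centers)
        u, _ = _memberships(X, centers, m)
        counts = np.bincount(np.argmax(u, axis=1), minlength=centers.shape[0])
        small = counts < min_members
        if np.any(small):
            if np.all(small):
                raise ValidationError(
                    f"all {centers.shape[0]} clusters have fewer than "
                    f"{min_members} members")
            drop = int(np.argmin(np.where(small, counts, np.iinfo(np.int64).max)))
            log.info("pruning cluster %d (%d members)", drop, counts[drop])
            centers = np.delete(centers, drop, axis=0)
            continue
        if centers.shape[0] >= 2:
            dists = squareform(pdist(centers))
            np.fill_diagonal(dists, np.inf)
            i, j = np.unravel_index(np.argmin(dists), dists.shape)
            if dists[i, j] < merge_dist:
                i, j = min(i, j), max(i, j)
                w_i, w_j = counts[i], counts[j]
                log.info("merging clusters %d and %d (distance %.4g)", i, j,
                         dists[i, j])
                centers[i] = (w_i * centers[i] + w_j * centers[j]) / (w_i + w_j)
                centers = np.delete(centers, j, axis=0)
                continue
        break
    u, d2 = _memberships(X, centers, m)
    return FuzzyClusteringResult(
        centers=centers, membership=u,
        objective=float(np.sum((u ** m) * d2)),
    )


def extract_component_subclasses(
    reference_features: dict[str, list[GestureFeatures]],
    component: str,
    k0: int,
    seed=None,
    min_members: int = 2,
    merge_dist: float | None = None,
    n_init: int = 5,
) -> tuple[ComponentInventory, dict[tuple[str, str | None], int]]:
    """Discover one component's subclasses from a reference subject.

    ``reference_features`` maps gesture id to the features of its
    repetitions; repetitions are averaged (in the clustering space)
    before clustering so each gesture contributes one point per stage.

    Returns the inventory entry and the hard subclass label (1-based)
    of every ``(gesture_id, stage)`` point.
    """
    if component not in COMPONENTS:
        raise ValidationError(f"unknown component {component!r}")
    stages = [None] if component == "trajectory" else list(STAGES)
    points, meta = [], []
    for gid in sorted(reference_features):
        reps = reference_features[gid]
        if not reps:
            raise ValidationError(f"gesture {gid!r} has no feature sets")
        for stage in stages:
            vecs = [component_vector(f, component, stage) for f in reps]
            points.append(np.mean(vecs, axis=0))
            meta.append((gid, stage))
    X = np.asarray(points)
    k0 = min(k0, X.shape[0])
    result = fuzzy_cmeans(X, k0, seed=seed, n_init=n_init)
    result = prune_and_merge(X, result, min_members=min_members,
                             merge_dist=merge_dist)
    hard = result.labels
    representatives: dict[int, set[str]] = {}
    labels: dict[tuple[str, str | None], int] = {}
    for (gid, stage), lab in zip(meta, hard):
        idx = int(lab) + 1
        labels[(gid, stage)] = idx
        representatives.setdefault(idx, set()).add(gid)
    # prune_and_merge leaves no empty clusters, so every subclass has
    # at least one representative gesture
    inventory = ComponentInventory(
        n=result.centers.shape[0],
        centers=result.centers,
        representatives=representatives,
    )
    return inventory, labels


def build_reference(
    reference_features: dict[str, list[GestureFeatures]],
    k0: dict[str, int] | int,
    seed=None,
    min_members: int = 2,
    merge_dist: float | None = None,
) -> tuple[SubclassInventory, dict[str, ComponentRepresentation]]:
    """Run subclass extraction for all five components and assemble the
    reference representations of every gesture."""
    if isinstance(k0, int):
        k0 = {c: k0 for c in COMPONENTS}
    components: dict[str, ComponentInventory] = {}
    labels: dict[str, dict[tuple[str, str | None], int]] = {}
    for ci, comp in enumerate(COMPONENTS):
        comp_seed = None if seed is None else int(seed) + ci
        components[comp], labels[comp] = extract_component_subclasses(
            reference_features, comp, k0[comp], seed=comp_seed,
            min_members=min_members, merge_dist=merge_dist)
    inventory = SubclassInventory(components=components)
    reps = {}
    for gid in reference_features:
        values = [labels[comp][(gid, stage)] for _n, comp, stage in ELEMENTS]
        reps[gid] = ComponentRepresentation.from_tuple(values)
    return inventory, reps


def assign_representation(features: GestureFeatures,
                          inventory: SubclassInventory) -> ComponentRepresentation:
    """Nearest-center subclass of each of the 13 elements."""
    values = []
    for _name, comp, stage in ELEMENTS:
        entry = inventory.component(comp)
        if entry.centers.size == 0:
            raise ValidationError(f"empty inventory for component {comp}")
        vec = component_vector(features, comp, stage)
        d = np.linalg.norm(entry.centers - vec[None, :], axis=1)
        values.append(int(np.argmin(d)) + 1)
    return ComponentRepresentation.from_tuple(values)
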