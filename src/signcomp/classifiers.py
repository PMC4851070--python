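"""Component classifiers.

Handshape and trajectory are sequence components and are modelled per
subclass by continuous HMMs with five left-to-right states and three
diagonal-covariance Gaussian mixture components per state; orientation,
axis and rotation are static per-stage vectors modelled per subclass by
a single multivariate Gaussian.  Classification is maximum likelihood
over the subclass models, with scores exposed in full so the codec can
set both the maximal- and submaximal-probability bits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GMMHMM
from hmmlearn.base import ConvergenceMonitor
from scipy.stats import multivariate_normal
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans
from sklearn.utils import check_array, check_random_state

from .core import ValidationError, ELEMENTS
from .features import GestureFeatures
from .subclassing import component_vector, trajectory_observation

log = logging.getLogger(__name__)

N_STATES = 5
N_MIX = 3
VAR_FLOOR = 1e-6


class _TraceMonitor(ConvergenceMonitor):
    """Convergence monitor that records the full log-likelihood trace."""

    def __init__(self, tol, n_iter):
        super().__init__(tol=tol, n_iter=n_iter, verbose=False)
        self.trace: list[float] = []

    def report(self, log_prob):
        self.trace.append(float(log_prob))
        super().report(log_prob)


# ---------------------------------------------------------------------------
# Gaussian models (orientation / axis / rotation)


@dataclass
class GaussianModel:
    """A single multivariate normal subclass model."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)

    def loglik(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if x.shape != self.mean.shape:
            raise ValidationError(
                f"dimension mismatch: x {x.shape} vs model {self.mean.shape}")
        return float(multivariate_normal.logpdf(x, mean=self.mean, cov=self.cov))

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "cov": self.cov.tolist()}

    @classmethod
    def from_dict(cls, d) -> "GaussianModel":
        return cls(mean=np.asarray(d["mean"]), cov=np.asarray(d["cov"]))


def train_gaussian(samples: np.ndarray, reg: float = 1e-6) -> GaussianModel:
    """Fit a subclass Gaussian: sample mean and ridge-regularised covariance.

    The covariance is the (n-1)-denominator sample covariance plus
    ``reg * I``, which keeps it positive definite even for degenerate
    samples.
    """
    X = np.asarray(samples, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("train_gaussian needs an n x d matrix with n >= 2")
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1) + reg * np.eye(X.shape[1])
    return GaussianModel(mean=mean, cov=cov)


def gaussian_loglik(model: GaussianModel, x: np.ndarray) -> float:
    """Full d-dimensional multivariate normal log-density of ``x``."""
    return model.loglik(x)


def classify_vector(models: list[GaussianModel], x: np.ndarray) -> int:
    """1-based index of the highest-likelihood model (ties to lowest index)."""
    scores = score_models(models, x)
    return _argmax_with_tie_warning(scores)


def score_models(models, obs) -> np.ndarray:
    if not models:
        raise ValidationError("empty model list")
    return np.array([m.loglik(obs) for m in models])


def _argmax_with_tie_warning(scores: np.ndarray) -> int:
    best = int(np.argmax(scores))
    if np.count_nonzero(scores == scores[best]) > 1:
        warnings.warn("likelihood tie broken to lowest subclass index",
                      stacklevel=3)
    return best + 1


class GaussianComponentClassifier(ClassifierMixin, BaseEstimator):
    """Per-subclass multivariate-Gaussian classifier for the static
    components (orientation, axis, rotation).

    Parameters
    ----------
    reg : ridge added to each covariance diagonal.  ``"auto"`` scales
        the ridge to 1e-3 times the mean pooled per-dimension variance,
        which keeps near-singular subclass covariances from dominating
        the likelihood comparison when training samples are few.

    Attributes
    ----------
    classes_ : sorted 1-based subclass indices seen in ``y``.
    models_ : one :class:`GaussianModel` per class.
    """

    def __init__(self, reg: float | str = "auto"):
        self.reg = reg

    def fit(self, X, y):
        X = check_array(X)
        y = np.asarray(y, dtype=int)
        if X.shape[0] != y.shape[0]:
            raise ValidationError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if self.reg == "auto":
            pooled = float(np.mean(np.var(X, axis=0)))
            reg = max(1e-3 * pooled, 1e-9)
        else:
            reg = float(self.reg)
        self.reg_ = reg
        self.models_ = [train_gaussian(X[y == c], reg=reg) for c in self.classes_]
        return self

    def log_likelihood(self, X) -> np.ndarray:
        """(n_samples, n_classes) matrix of per-class log-densities."""
        X = check_array(X)
        return np.stack([score_models(self.models_, x) for x in X])

    def predict(self, X) -> np.ndarray:
        ll = self.log_likelihood(X)
        return self.classes_[np.argmax(ll, axis=1)]

    def to_dict(self) -> dict:
        return {"classes": self.classes_.tolist(), "reg": self.reg_,
                "models": [m.to_dict() for m in self.models_]}

    @classmethod
    def from_dict(cls, d) -> "GaussianComponentClassifier":
        obj = cls(reg=d["reg"])
        obj.reg_ = d["reg"]
        obj.classes_ = np.asarray(d["classes"], dtype=int)
        obj.models_ = [GaussianModel.from_dict(m) for m in d["models"]]
        return obj


# ---------------------------------------------------------------------------
# HMM models (handshape / trajectory)


@dataclass
class HmmModel:
    """A trained subclass GMM-HMM plus its training log-likelihood trace."""

    hmm: GMMHMM
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.hmm.means_.shape[-1]

    def loglik(self, seq: np.ndarray) -> float:
        seq = np.asarray(seq, dtype=float)
        if seq.ndim != 2 or seq.shape[1] != self.n_features:
            raise ValidationError(
                f"sequence shape {seq.shape} does not match model dimension "
                f"{self.n_features}")
        return float(self.hmm.score(seq))

    def to_dict(self) -> dict:
        h = self.hmm
        return {
            "n_states": int(h.n_components),
            "n_mix": int(h.n_mix),
            "startprob": h.startprob_.tolist(),
            "transmat": h.transmat_.tolist(),
            "weights": h.weights_.tolist(),
            "means": h.means_.tolist(),
            "covars": h.covars_.tolist(),
            "loglik_trace": list(self.loglik_trace),
        }

    @classmethod
    def from_dict(cls, d) -> "HmmModel":
        return build_hmm(
            startprob=np.asarray(d["startprob"], dtype=float),
            transmat=np.asarray(d["transmat"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            means=np.asarray(d["means"], dtype=float),
            covars=np.asarray(d["covars"], dtype=float),
            loglik_trace=list(d.get("loglik_trace", [])),
        )


def build_hmm(startprob, transmat, weights, means, covars,
              loglik_trace=()) -> HmmModel:
    """Assemble an :class:`HmmModel` from explicit diagonal-covariance
    GMM-HMM parameters (used by deserialisation and by tests that need
    models with known parameters)."""
    means = np.asarray(means, dtype=float)
    n_states, n_mix, _ = means.shape
    hmm = GMMHMM(n_components=n_states, n_mix=n_mix, covariance_type="diag",
                 init_params="", params="")
    hmm.startprob_ = np.asarray(startprob, dtype=float)
    hmm.transmat_ = np.asarray(transmat, dtype=float)
    hmm.weights_ = np.asarray(weights, dtype=float)
    hmm.means_ = means
    hmm.covars_ = np.asarray(covars, dtype=float)
    hmm.n_features = means.shape[-1]
    return HmmModel(hmm=hmm, loglik_trace=list(loglik_trace))


def _left_right_transmat(n_states: int) -> np.ndarray:
    t = np.zeros((n_states, n_states))
    for i in range(n_states - 1):
        t[i, i], t[i, i + 1] = 0.6, 0.4
    t[-1, -1] = 1.0
    return t


def _init_emissions(sequences, n_states, n_mix, var_floor, rng):
    """Mixture initialisation by uniform temporal segmentation of every
    sequence into ``n_states`` blocks and per-state k-means over the
    pooled block frames.  The variance floor is scale-aware: a fraction
    of the pooled per-dimension variance, so near-duplicate mixture
    members cannot collapse a component onto a numerical spike."""
    d = sequences[0].shape[1]
    pools = [[] for _ in range(n_states)]
    for seq in sequences:
        for s, block in enumerate(np.array_split(seq, n_states)):
            if block.size:
                pools[s].append(block)
    global_var = np.maximum(np.var(np.vstack(sequences), axis=0), var_floor)
    floor = np.maximum(var_floor, 1e-3 * global_var)
    means = np.empty((n_states, n_mix, d))
    covars = np.empty((n_states, n_mix, d))
    weights = np.empty((n_states, n_mix))
    for s in range(n_states):
        pool = np.vstack(pools[s]) if pools[s] else np.vstack(sequences)
        if pool.shape[0] < n_mix:
            extra = pool[rng.randint(pool.shape[0], size=n_mix - pool.shape[0])]
            extra = extra + rng.standard_normal(extra.shape) * np.sqrt(global_var) * 1e-3
            pool = np.vstack([pool, extra])
        km = KMeans(n_clusters=n_mix, n_init=1, random_state=rng).fit(pool)
        means[s] = km.cluster_centers_
        for j in range(n_mix):
            members = pool[km.labels_ == j]
            var = np.var(members, axis=0) if members.shape[0] > 1 else global_var
            covars[s, j] = np.maximum(var, floor)
            weights[s, j] = max(members.shape[0], 1)
    weights /= weights.sum(axis=1, keepdims=True)
    return means, covars, weights


def train_hmm(sequences, n_states: int = N_STATES, n_mix: int = N_MIX,
              n_iter: int = 25, tol: float = 1e-3,
              var_floor: float = VAR_FLOOR, seed=0) -> HmmModel:
    """Baum-Welch fit of a left-to-right GMM-HMM on observation sequences.

    The start state is fixed to the first state; transition zeros of the
    left-to-right topology are preserved by EM.  Deterministic for a
    fixed seed.  Raises if any sequence is shorter than ``n_states``.
    """
    sequences = [np.asarray(s, dtype=float) for s in sequences]
    if not sequences:
        raise ValidationError("train_hmm needs at least one sequence")
    for s in sequences:
        if s.ndim != 2:
            raise ValidationError("sequences must be T x d arrays")
        if s.shape[0] < n_states:
            raise ValidationError(
                f"sequence of length {s.shape[0]} shorter than {n_states} states")
    rng = check_random_state(seed)
    means, covars, weights = _init_emissions(sequences, n_states, n_mix,
                                             var_floor, rng)
    model = GMMHMM(n_components=n_states, n_mix=n_mix, covariance_type="diag",
                   init_params="", params="tmcw", n_iter=n_iter, tol=tol,
                   min_covar=var_floor, random_state=rng)
    model.startprob_ = np.zeros(n_states)
    model.startprob_[0] = 1.0
    model.transmat_ = _left_right_transmat(n_states)
    model.means_ = means
    model.covars_ = covars
    model.weights_ = weights
    model.monitor_ = _TraceMonitor(tol=tol, n_iter=n_iter)
    X = np.vstack(sequences)
    lengths = [s.shape[0] for s in sequences]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # hmmlearn warns on floored covariances
        model.fit(X, lengths=lengths)
    finite = all(np.all(np.isfinite(getattr(model, a))) for a in
                 ("startprob_", "transmat_", "weights_", "means_", "covars_"))
    if not finite:
        # EM diverged on a degenerate pool: keep the moment-based
        # initialisation, which is always a proper model
        warnings.warn("EM produced non-finite parameters; "
                      "keeping the initial model", stacklevel=2)
        return build_hmm(startprob=np.eye(n_states)[0],
                         transmat=_left_right_transmat(n_states),
                         weights=weights, means=means, covars=covars)
    model.covars_ = np.maximum(model.covars_, var_floor)
    trace = model.monitor_.trace
    drops = [b - a for a, b in zip(trace, trace[1:]) if b < a - 1e-8 * max(1, abs(a))]
    if drops:
        log.warning("EM log-likelihood decreased by up to %.3g", -min(drops))
    return HmmModel(hmm=model, loglik_trace=trace)


def hmm_loglik(model: HmmModel, seq: np.ndarray) -> float:
    """log P(seq | model) via the scaled forward recursion."""
    return model.loglik(seq)


def classify_sequence(models: list[HmmModel], seq: np.ndarray) -> int:
    """1-based index of the highest-likelihood HMM (ties to lowest index)."""
    scores = score_models(models, seq)
    return _argmax_with_tie_warning(scores)


class SequenceComponentClassifier(ClassifierMixin, BaseEstimator):
    """Per-subclass GMM-HMM classifier for the sequence components
    (handshape frame sequences, 64-point trajectories).

    ``fit`` takes a list of T_k x d observation sequences and their
    1-based subclass labels and trains one left-to-right GMM-HMM per
    subclass.
    """

    def __init__(self, n_states: int = N_STATES, n_mix: int = N_MIX,
                 n_iter: int = 25, tol: float = 1e-3,
                 var_floor: float = VAR_FLOOR, random_state=0):
        self.n_states = n_states
        self.n_mix = n_mix
        self.n_iter = n_iter
        self.tol = tol
        self.var_floor = var_floor
        self.random_state = random_state

    def fit(self, sequences, y):
        y = np.asarray(y, dtype=int)
        if len(sequences) != y.shape[0]:
            raise ValidationError("sequences and labels length mismatch")
        self.classes_ = np.unique(y)
        seed0 = check_random_state(self.random_state).randint(2 ** 31 - 1)
        self.models_ = []
        for rank, c in enumerate(self.classes_):
            seqs = [s for s, lab in zip(sequences, y) if lab == c]
            self.models_.append(
                train_hmm(seqs, n_states=self.n_states, n_mix=self.n_mix,
                          n_iter=self.n_iter, tol=self.tol,
                          var_floor=self.var_floor, seed=seed0 + rank))
        return self

    def log_likelihood(self, seq) -> np.ndarray:
        return score_models(self.models_, np.asarray(seq, dtype=float))

    def predict(self, sequences) -> np.ndarray:
        return np.array([
            self.classes_[classify_sequence(self.models_, s) - 1]
            for s in sequences
        ])

    def to_dict(self) -> dict:
        return {"classes": self.classes_.tolist(),
                "models": [m.to_dict() for m in self.models_]}

    @classmethod
    def from_dict(cls, d) -> "SequenceComponentClassifier":
        obj = cls()
        obj.classes_ = np.asarray(d["classes"], dtype=int)
        obj.models_ = [HmmModel.from_dict(m) for m in d["models"]]
        return obj


# ---------------------------------------------------------------------------
# The per-hand classifier bank


_SEQUENCE_COMPONENTS = ("handshape", "trajectory")


@dataclass
class ComponentClassifierBank:
    """Trained subclass classifiers for every component, per hand."""

    hands: dict[str, dict[str, BaseEstimator]]

    def classifier(self, component: str, hand: str = "right"):
        try:
            return self.hands[hand][component]
        except KeyError:
            raise ValidationError(
                f"no trained classifier for component {component!r}, hand {hand!r}"
            ) from None

    def model_counts(self, hand: str = "right") -> dict[str, int]:
        return {c: len(clf.models_) for c, clf in self.hands[hand].items()}

    def to_dict(self) -> dict:
        out = {"hands": {}}
        for hand, comps in self.hands.items():
            out["hands"][hand] = {c: clf.to_dict() for c, clf in comps.items()}
        return out

    @classmethod
    def from_dict(cls, d) -> "ComponentClassifierBank":
        hands = {}
        for hand, comps in d["hands"].items():
            hands[hand] = {}
            for comp, block in comps.items():
                if comp in _SEQUENCE_COMPONENTS:
                    hands[hand][comp] = SequenceComponentClassifier.from_dict(block)
                else:
                    hands[hand][comp] = GaussianComponentClassifier.from_dict(block)
        return cls(hands=hands)


def score_all_components(features: GestureFeatures,
                         bank: ComponentClassifierBank,
                         hand: str = "right") -> dict[str, list[tuple[int, float]]]:
    """Subclass scores of all 13 representation elements.

    For each element, returns ``(subclass index, log-likelihood)`` pairs
    sorted by descending score -- the ranking the dual-bit test encoding
    consumes.
    """
    rankings: dict[str, list[tuple[int, float]]] = {}
    for name, comp, stage in ELEMENTS:
        clf = bank.classifier(comp, hand)
        if comp in _SEQUENCE_COMPONENTS:
            obs = (trajectory_observation(features.trajectory)
                   if comp == "trajectory" else features.handshape[stage])
            scores = clf.log_likelihood(obs)
        else:
            vec = component_vector(features, comp, stage)
            scores = clf.log_likelihood(vec[None, :])[0]
        order = np.argsort(-scores, kind="stable")
        rankings[name] = [(int(clf.classes_[i]), float(scores[i])) for i in order]
    return rankings
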