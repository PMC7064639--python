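"""Linear discriminant classifiers and the bagged majority-vote ensemble.

The core model is shrinkage-regularized LDA (RLDA): the pooled
within-class covariance Σ is replaced by

    Σ_γ = (1 - γ) Σ + γ I,        γ in [0, 1],

which keeps the discriminant well-conditioned when the feature dimension
approaches the trial count — the usual regime for window-mean fNIRS
features.  γ may be fixed (0.1 is the conventional weak-learner value)
or estimated analytically with the Ledoit–Wolf formula.

The ensemble draws bootstrap resamples of the training set (same size,
with replacement), fits one RLDA weak learner per resample, and
aggregates by majority vote; in the binary ±1 encoding the aggregate is
H(x) = sign(Σ_n sign(h_n(x))).  Ties are broken deterministically toward
the lowest class index and flagged, so even ensemble sizes remain usable
(odd sizes are still recommended).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.svm import SVC

from .errors import (
    DataError,
    DomainError,
    ModelError,
    SampleSizeError,
    ShapeError,
)
from .features import FeatureMatrix

MAX_BOOTSTRAP_RETRIES = 100


def _as_xy(
    features: FeatureMatrix | np.ndarray, labels: Sequence[str] | None
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(features, FeatureMatrix):
        X, y = features.values, np.asarray(features.labels, dtype=object)
    else:
        if labels is None:
            raise DataError("labels are required when passing a bare array")
        X = np.asarray(features, dtype=float)
        y = np.asarray(list(labels), dtype=object)
    if X.ndim != 2:
        raise ShapeError(f"feature array must be 2-D, got {X.shape}")
    if X.shape[0] != y.shape[0]:
        raise ShapeError(f"{X.shape[0]} rows but {y.shape[0]} labels")
    if not np.all(np.isfinite(X)):
        raise DataError("non-finite feature values")
    return X, y


# ---------------------------------------------------------------------------
# LDA / RLDA


@dataclass
class LDAModel:
    """Fitted (regularized) linear discriminant model.

    Scores are the Gaussian-equal-covariance discriminants

        δ_k(x) = log π_k − ½ μ_kᵀ Σ_γ⁻¹ μ_k + xᵀ Σ_γ⁻¹ μ_k,

    and prediction is argmax over k with ties broken toward the lowest
    class index.
    """

    classes: list[str]
    priors: np.ndarray
    means: np.ndarray  # (K, d)
    pooled_cov: np.ndarray  # (d, d)
    gamma: float
    _coef: np.ndarray = field(repr=False, default=None)  # (K, d)
    _intercept: np.ndarray = field(repr=False, default=None)  # (K,)

    def __post_init__(self) -> None:
        if self._coef is None:
            sigma_g = self.regularized_covariance
            self._coef = np.linalg.solve(sigma_g, self.means.T).T
            self._intercept = np.log(self.priors) - 0.5 * np.einsum(
                "kd,kd->k", self.means, self._coef
            )

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    @property
    def regularized_covariance(self) -> np.ndarray:
        d = self.pooled_cov.shape[0]
        return (1.0 - self.gamma) * self.pooled_cov + self.gamma * np.eye(d)

    def scores(self, x: np.ndarray) -> np.ndarray:
        """Per-class discriminant values; accepts a vector or a matrix."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        X = np.atleast_2d(x)
        if X.shape[1] != self.n_features:
            raise ShapeError(
                f"input has {X.shape[1]} features, model expects "
                f"{self.n_features}"
            )
        s = X @ self._coef.T + self._intercept
        return s[0] if single else s

    def predict(self, x: np.ndarray) -> np.ndarray | str:
        s = self.scores(x)
        if s.ndim == 1:
            return self.classes[int(np.argmax(s))]
        idx = np.argmax(s, axis=1)  # argmax takes the first (lowest) index
        return np.asarray([self.classes[i] for i in idx], dtype=object)

    def to_dict(self) -> dict:
        return {
            "kind": "lda",
            "classes": self.classes,
            "priors": self.priors.tolist(),
            "means": self.means.tolist(),
            "pooled_cov": self.pooled_cov.tolist(),
            "gamma": self.gamma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LDAModel":
        return cls(
            classes=list(d["classes"]),
            priors=np.asarray(d["priors"]),
            means=np.asarray(d["means"]),
            pooled_cov=np.asarray(d["pooled_cov"]),
            gamma=float(d["gamma"]),
        )


def fit_lda(
    features: FeatureMatrix | np.ndarray,
    labels: Sequence[str] | None = None,
    gamma: float | str = 0.0,
    classes: Sequence[str] | None = None,
) -> LDAModel:
    """Fit (regularized) LDA.

    Class priors are empirical frequencies, class means are sample means,
    and Σ is the pooled within-class covariance with divisor N − K
    (unbiased).  ``gamma`` is the shrinkage weight in [0, 1] or the
    string ``"ledoit_wolf"`` to estimate it from the class-centered data.
    ``classes`` fixes the class ordering (default: sorted labels).
    """
    X, y = _as_xy(features, labels)
    cls = [str(c) for c in (classes if classes is not None else sorted(set(y)))]
    if len(cls) < 2:
        raise SampleSizeError(f"need >= 2 classes, got {len(cls)}")
    n, d = X.shape
    k = len(cls)
    priors = np.empty(k)
    means = np.empty((k, d))
    scatter = np.zeros((d, d))
    centered = np.empty_like(X)
    pos = 0
    for j, c in enumerate(cls):
        Xc = X[y == c]
        if Xc.shape[0] < 2:
            raise SampleSizeError(
                f"class {c!r} has {Xc.shape[0]} sample(s); need >= 2"
            )
        priors[j] = Xc.shape[0] / n
        means[j] = Xc.mean(axis=0)
        dev = Xc - means[j]
        scatter += dev.T @ dev
        centered[pos : pos + Xc.shape[0]] = dev
        pos += Xc.shape[0]
    pooled = scatter / (n - k)
    if gamma == "ledoit_wolf":
        gamma = ledoit_wolf_gamma(centered, centered=True)
    gamma = float(gamma)
    if not 0.0 <= gamma <= 1.0:
        raise DomainError(f"gamma must lie in [0, 1], got {gamma}")
    return LDAModel(
        classes=cls, priors=priors, means=means, pooled_cov=pooled,
        gamma=gamma,
    )


def lda_scores(model: LDAModel, x: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`LDAModel.scores`."""
    return model.scores(x)


def ledoit_wolf_gamma(
    features: FeatureMatrix | np.ndarray,
    labels: Sequence[str] | None = None,
    centered: bool = False,
) -> float:
    """Analytic optimal shrinkage intensity toward the scaled identity.

    Implements the Ledoit–Wolf estimator: with S the sample covariance
    (divisor n), m = tr(S)/d, the intensity is

        γ* = min(b̄², δ²) / δ²,
        δ² = ‖S − mI‖_F²/d,
        b̄² = (1/n²) Σ_i ‖x_i x_iᵀ − S‖_F²/d,

    clipped to [0, 1].  When labels are given the data are centered per
    class first (the relevant covariance for LDA is within-class); when
    the empirical covariance is exactly zero γ* = 1 (full shrinkage).
    """
    if isinstance(features, FeatureMatrix):
        X = features.values
        labels = features.labels
    else:
        X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ShapeError(f"feature array must be 2-D, got {X.shape}")
    n, d = X.shape
    if n < 2:
        raise SampleSizeError("Ledoit-Wolf needs >= 2 samples")
    if centered:
        Xc = X
    elif labels is not None:
        y = np.asarray(list(labels), dtype=object)
        Xc = np.empty_like(X, dtype=float)
        for c in np.unique(y):
            m = y == c
            Xc[m] = X[m] - X[m].mean(axis=0)
    else:
        Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / n
    mu = np.trace(S) / d
    delta2 = np.sum((S - mu * np.eye(d)) ** 2) / d
    if delta2 <= np.finfo(float).eps * max(1.0, mu**2):
        return 1.0
    sq_norms = np.einsum("ij,ij->i", Xc, Xc)
    beta2 = (np.sum(sq_norms**2) / n - np.sum(S * S)) / (n * d)
    beta2 = min(beta2, delta2)
    return float(np.clip(beta2 / delta2, 0.0, 1.0))


# ---------------------------------------------------------------------------
# bagging ensemble


@dataclass
class BaggingEnsembleModel:
    """Majority-vote ensemble of RLDA weak learners fitted on bootstrap
    resamples of the training set."""

    classes: list[str]
    weak_learners: list[LDAModel]
    resample_indices: np.ndarray  # (n_learn, n_train)
    gamma: float
    seed: int | None

    @property
    def n_learn(self) -> int:
        return len(self.weak_learners)

    def predict(self, x: np.ndarray) -> np.ndarray | str:
        return predict_majority(self, x)

    def to_dict(self) -> dict:
        return {
            "kind": "bagging",
            "classes": self.classes,
            "gamma": self.gamma,
            "seed": self.seed,
            "resample_indices": self.resample_indices.tolist(),
            "weak_learners": [m.to_dict() for m in self.weak_learners],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BaggingEnsembleModel":
        return cls(
            classes=list(d["classes"]),
            weak_learners=[
                LDAModel.from_dict(m) for m in d["weak_learners"]
            ],
            resample_indices=np.asarray(d["resample_indices"], dtype=int),
            gamma=float(d["gamma"]),
            seed=d.get("seed"),
        )


def fit_bagging(
    features: FeatureMatrix | np.ndarray,
    labels: Sequence[str] | None = None,
    n_learn: int = 25,
    gamma: float = 0.1,
    seed: int | np.random.Generator | None = 0,
    resample: bool = True,
) -> BaggingEnsembleModel:
    """Fit the bagged RLDA ensemble.

    Draws ``n_learn`` bootstrap resamples of the full training-set size
    with replacement (resample fraction 100%) and fits one RLDA weak
    learner with shrinkage ``gamma`` per resample.  A resample that drops
    a class below 2 members is redrawn, up to 100 times.  With
    ``resample=False`` every learner trains on the full data — a
    degenerate ensemble used to validate the voting rule.
    """
    X, y = _as_xy(features, labels)
    if n_learn < 1:
        raise DomainError(f"n_learn must be >= 1, got {n_learn}")
    cls = sorted(set(y))
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = X.shape[0]
    learners: list[LDAModel] = []
    indices = np.empty((n_learn, n), dtype=np.int64)
    for m in range(n_learn):
        if not resample:
            idx = np.arange(n)
        else:
            for attempt in range(MAX_BOOTSTRAP_RETRIES + 1):
                idx = rng.integers(0, n, size=n)
                counts = {c: int(np.sum(y[idx] == c)) for c in cls}
                if all(v >= 2 for v in counts.values()):
                    break
            else:  # pragma: no cover - needs pathological class sizes
                raise SampleSizeError(
                    f"could not draw a usable bootstrap resample in "
                    f"{MAX_BOOTSTRAP_RETRIES} retries (classes too small)"
                )
        indices[m] = idx
        learners.append(fit_lda(X[idx], y[idx], gamma=gamma, classes=cls))
    return BaggingEnsembleModel(
        classes=cls,
        weak_learners=learners,
        resample_indices=indices,
        gamma=gamma,
        seed=seed if isinstance(seed, int) else None,
    )


def predict_majority(
    ensemble: BaggingEnsembleModel,
    x: np.ndarray,
    return_record: bool = False,
):
    """Majority (plurality) vote over the weak learners.

    In the binary case with classes encoded ±1 this is exactly
    H(x) = sign(Σ_n sign(h_n(x))), with sign(0) resolved toward the
    lowest class index.  With ``return_record=True`` also returns the
    per-sample tie flags and the (n_learn, n_samples) vote matrix.
    """
    if ensemble.n_learn == 0:
        raise ModelError("ensemble has no weak learners")
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    class_index = {c: i for i, c in enumerate(ensemble.classes)}
    votes = np.empty((ensemble.n_learn, X.shape[0]), dtype=np.int64)
    for m, learner in enumerate(ensemble.weak_learners):
        pred = np.atleast_1d(learner.predict(X))
        votes[m] = [class_index[p] for p in pred]
    k = len(ensemble.classes)
    counts = np.apply_along_axis(
        lambda v: np.bincount(v, minlength=k), 0, votes
    )  # (k, n_samples)
    winner = np.argmax(counts, axis=0)  # first max -> lowest class index
    tie = (counts == counts.max(axis=0)).sum(axis=0) > 1
    labels = np.asarray([ensemble.classes[i] for i in winner], dtype=object)
    if single:
        labels, tie = labels[0], bool(tie[0])
    if return_record:
        return labels, tie, votes
    return labels


# ---------------------------------------------------------------------------
# one-vs-one multiclass wrapper


@dataclass
class OvOModel:
    """One-vs-one multiclass wrapper: one binary model per unordered
    class pair, aggregated by plurality over pairwise winners."""

    classes: list[str]
    pairs: list[tuple[str, str]]
    models: list

    def predict(self, x: np.ndarray) -> np.ndarray | str:
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        X = np.atleast_2d(x)
        class_index = {c: i for i, c in enumerate(self.classes)}
        counts = np.zeros((len(self.classes), X.shape[0]), dtype=int)
        for model in self.models:
            pred = np.atleast_1d(model.predict(X))
            for j, p in enumerate(pred):
                counts[class_index[p], j] += 1
        winner = np.argmax(counts, axis=0)
        labels = np.asarray([self.classes[i] for i in winner], dtype=object)
        return labels[0] if single else labels


def fit_one_vs_one(
    features: FeatureMatrix | np.ndarray,
    labels: Sequence[str] | None = None,
    base_fitter: Callable[[np.ndarray, np.ndarray], object] = None,
) -> OvOModel:
    """Fit C(K, 2) pairwise binary models with ``base_fitter(X, y)``.

    For two classes this is a single binary model and predictions reduce
    to the base model's.
    """
    if base_fitter is None:
        base_fitter = lambda X, y: fit_lda(X, y, gamma=0.0)  # noqa: E731
    X, y = _as_xy(features, labels)
    cls = sorted(set(y))
    if len(cls) < 2:
        raise SampleSizeError("one-vs-one needs >= 2 classes")
    pairs, models = [], []
    for i in range(len(cls)):
        for j in range(i + 1, len(cls)):
            a, b = cls[i], cls[j]
            mask = (y == a) | (y == b)
            pairs.append((a, b))
            models.append(base_fitter(X[mask], y[mask]))
    return OvOModel(classes=cls, pairs=pairs, models=models)


# ---------------------------------------------------------------------------
# linear SVM baseline


@dataclass
class LinearSVMModel:
    """Soft-margin linear SVM with train-set standardization baked in."""

    classes: list[str]
    mean: np.ndarray
    scale: np.ndarray
    svc: SVC

    def predict(self, x: np.ndarray) -> np.ndarray | str:
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        X = (np.atleast_2d(x) - self.mean) / self.scale
        pred = self.svc.predict(X).astype(object)
        return pred[0] if single else pred


def fit_linear_svm(
    features: FeatureMatrix | np.ndarray,
    labels: Sequence[str] | None = None,
    cost: float = 1.0,
) -> LinearSVMModel:
    """Standardize features by training mean/SD, then fit a soft-margin
    linear SVM (libsvm via scikit-learn).

    A zero-variance feature gets SD 1 so standardization stays finite;
    test vectors are transformed with the stored training statistics.
    """
    X, y = _as_xy(features, labels)
    if cost <= 0:
        raise DomainError(f"cost must be > 0, got {cost}")
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale[scale == 0.0] = 1.0
    svc = SVC(kernel="linear", C=cost)
    svc.fit((X - mean) / scale, y.astype(str))
    return LinearSVMModel(
        classes=sorted(set(y)), mean=mean, scale=scale, svc=svc
    )


# ---------------------------------------------------------------------------
# classifier specs (uniform fit interface for cross-validation)


class ClassifierSpec:
    """A named, parameterized recipe producing a fitted model on demand.

    ``fit(X, y, rng)`` must be deterministic given the data and the
    generator state; stochastic specs declare ``stochastic = True`` and
    receive a seeded generator from the evaluation layer.
    """

    name: str = "base"
    stochastic: bool = False

    def fit(self, X, y, rng: np.random.Generator | None = None):
        raise NotImplementedError

    def describe(self) -> dict:
        return {"name": self.name}


class LDASpec(ClassifierSpec):
    """Plain or shrinkage LDA.  ``gamma`` may be a number or
    ``"ledoit_wolf"``; plain LDA (γ=0) wraps ternary problems one-vs-one,
    while regularized LDA is applied natively multiclass."""

    def __init__(self, gamma: float | str = 0.0, ovo_multiclass=None):
        self.gamma = gamma
        if ovo_multiclass is None:
            ovo_multiclass = gamma == 0.0
        self.ovo_multiclass = ovo_multiclass
        self.name = "lda" if gamma == 0.0 else f"rlda(gamma={gamma})"

    def fit(self, X, y, rng=None):
        if self.ovo_multiclass and len(set(y)) > 2:
            return fit_one_vs_one(
                X, y, base_fitter=lambda a, b: fit_lda(a, b, gamma=self.gamma)
            )
        return fit_lda(X, y, gamma=self.gamma)

    def describe(self):
        return {"name": self.name, "gamma": self.gamma,
                "ovo_multiclass": self.ovo_multiclass}


class BaggingSpec(ClassifierSpec):
    """Bagged RLDA ensemble (the method under study)."""

    stochastic = True

    def __init__(self, n_learn: int = 25, gamma: float = 0.1):
        self.n_learn = n_learn
        self.gamma = gamma
        self.name = f"rlda_bagging(n_learn={n_learn},gamma={gamma})"

    def fit(self, X, y, rng=None):
        seed = rng if rng is not None else 0
        return fit_bagging(
            X, y, n_learn=self.n_learn, gamma=self.gamma, seed=seed
        )

    def describe(self):
        return {"name": self.name, "n_learn": self.n_learn,
                "gamma": self.gamma}


class SVMSpec(ClassifierSpec):
    """Standardized linear SVM baseline (one-vs-one for >= 3 classes,
    matching libsvm's internal strategy)."""

    def __init__(self, cost: float = 1.0):
        self.cost = cost
        self.name = f"linear_svm(cost={cost})"

    def fit(self, X, y, rng=None):
        return fit_linear_svm(X, y, cost=self.cost)

    def describe(self):
        return {"name": self.name, "cost": self.cost}


def make_classifier(kind: str, **params) -> ClassifierSpec:
    """Build a spec from a config-style name: ``lda``, ``rlda``,
    ``rlda_bagging`` or ``linear_svm``."""
    kind = kind.lower()
    if kind == "lda":
        return LDASpec(gamma=0.0, **params)
    if kind == "rlda":
        return LDASpec(gamma=params.pop("gamma", "ledoit_wolf"), **params)
    if kind == "rlda_bagging":
        return BaggingSpec(**params)
    if kind == "linear_svm":
        return SVMSpec(**params)
    raise DomainError(f"unknown classifier kind {kind!r}")
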