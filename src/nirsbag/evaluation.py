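"""Cross-validated evaluation, information transfer rate, and the
statistical comparison machinery.

Accuracy is estimated by stratified repeated k-fold cross-validation
(default 10 repetitions x 10 folds).  Accuracies convert to bitrates via
the Wolpaw information-transfer-rate formula, significance against
guessing uses the exact binomial tail, normality is screened with the
Anderson–Darling test, paired methods are compared with two-tailed
paired t-tests, and families of p-values are corrected with the
Benjamini–Hochberg false-discovery-rate step-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

from .classifiers import ClassifierSpec, _as_xy
from .errors import (
    ComputationError,
    DataError,
    DegenerateDataError,
    DomainError,
    SampleSizeError,
    StratificationError,
)
from .features import FeatureMatrix

# Accuracy conventionally regarded as sufficient for effective BCI
# control (used only for flagging in reports).
EFFECTIVE_CONTROL_THRESHOLD = 0.70


# ---------------------------------------------------------------------------
# folds and cross-validation


def stratified_folds(
    labels: Sequence[str],
    k: int = 10,
    repetitions: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Seeded stratified fold assignments, shape (repetitions, n_trials).

    Within each repetition every class's trials are permuted and dealt
    round-robin across the ``k`` folds, so per-class fold counts differ
    by at most one.
    """
    y = np.asarray(list(labels), dtype=object)
    n = y.shape[0]
    if k < 2:
        raise DomainError(f"k must be >= 2, got {k}")
    for c in np.unique(y):
        if np.sum(y == c) < k:
            raise StratificationError(
                f"class {c!r} has {int(np.sum(y == c))} trials, fewer than "
                f"k={k} folds"
            )
    rng = np.random.default_rng(seed)
    folds = np.empty((repetitions, n), dtype=np.int64)
    for r in range(repetitions):
        for c in np.unique(y):
            idx = np.flatnonzero(y == c)
            perm = rng.permutation(idx)
            folds[r, perm] = np.arange(perm.size) % k
    return folds


@dataclass
class CVResult:
    """Outcome of one repeated-CV run of one classifier."""

    classifier: dict  # spec echo
    per_fold_accuracy: np.ndarray  # (repetitions, k)
    per_trial_predictions: np.ndarray  # (repetitions, n_trials), labels
    folds: np.ndarray  # (repetitions, n_trials)
    labels: list[str]
    k: int
    repetitions: int
    seed: int

    @property
    def mean_accuracy(self) -> float:
        """Mean per-trial correctness over every repetition."""
        y = np.asarray(self.labels, dtype=object)
        return float(np.mean(self.per_trial_predictions == y[None, :]))

    @property
    def per_repetition_accuracy(self) -> np.ndarray:
        """Mean per-trial correctness within each repetition (length =
        repetitions); the paired unit for method comparisons."""
        y = np.asarray(self.labels, dtype=object)
        return np.mean(self.per_trial_predictions == y[None, :], axis=1)

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "mean_accuracy": self.mean_accuracy,
            "per_repetition_accuracy": self.per_repetition_accuracy.tolist(),
            "per_fold_accuracy": self.per_fold_accuracy.tolist(),
            "k": self.k,
            "repetitions": self.repetitions,
            "seed": self.seed,
        }


def cross_validate(
    features: FeatureMatrix | np.ndarray,
    classifier: ClassifierSpec,
    folds: np.ndarray,
    labels: Sequence[str] | None = None,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified k-fold cross-validation.

    For every repetition x fold the classifier is fitted on the
    out-of-fold trials only — any standardization or shrinkage selection
    happens inside ``classifier.fit`` on that training split, so nothing
    leaks from the held-out fold.  Stochastic classifiers receive a
    generator seeded by (seed, repetition, fold), making the whole run
    bit-reproducible.
    """
    X, y = _as_xy(features, labels)
    folds = np.asarray(folds)
    if folds.ndim != 2 or folds.shape[1] != X.shape[0]:
        raise DataError(
            f"folds shape {folds.shape} incompatible with "
            f"{X.shape[0]} trials"
        )
    reps = folds.shape[0]
    k = int(folds.max()) + 1
    per_fold = np.empty((reps, k))
    preds = np.empty((reps, X.shape[0]), dtype=object)
    for r in range(reps):
        for f in range(k):
            test = folds[r] == f
            train = ~test
            rng = (
                np.random.default_rng([seed, r, f])
                if classifier.stochastic
                else None
            )
            try:
                model = classifier.fit(X[train], y[train], rng=rng)
            except Exception as exc:
                raise ComputationError(
                    f"classifier {classifier.name!r} failed on repetition "
                    f"{r}, fold {f}: {exc}"
                ) from exc
            p = np.atleast_1d(model.predict(X[test]))
            preds[r, test] = p
            per_fold[r, f] = np.mean(p == y[test])
    return CVResult(
        classifier=classifier.describe(),
        per_fold_accuracy=per_fold,
        per_trial_predictions=preds,
        folds=folds,
        labels=[str(v) for v in y],
        k=k,
        repetitions=reps,
        seed=seed,
    )


@dataclass
class SweepResult:
    """Accuracy curve over a 1-D hyperparameter grid."""

    param: str
    values: list
    cv_results: list[CVResult]
    selected: object

    @property
    def mean_accuracies(self) -> np.ndarray:
        return np.asarray([r.mean_accuracy for r in self.cv_results])


def sweep_hyperparameters(
    features: FeatureMatrix | np.ndarray,
    grid: dict,
    folds: np.ndarray,
    labels: Sequence[str] | None = None,
    classifier_kind: str = "rlda_bagging",
    fixed: dict | None = None,
    seed: int = 0,
) -> SweepResult:
    """Cross-validate the classifier at every grid point of one
    hyperparameter (``{"n_learn": [...]}`` or ``{"gamma": [...]}``) and
    select the argmax of mean accuracy, ties toward the smaller value.
    """
    from .classifiers import make_classifier

    if len(grid) != 1:
        raise DomainError("grid must contain exactly one parameter")
    (param, values), = grid.items()
    values = list(values)
    if not values:
        raise DomainError("grid is empty")
    fixed = dict(fixed or {})
    results = []
    for v in values:
        spec = make_classifier(classifier_kind, **{**fixed, param: v})
        results.append(
            cross_validate(features, spec, folds, labels=labels, seed=seed)
        )
    accs = [r.mean_accuracy for r in results]
    order = sorted(range(len(values)), key=lambda i: (-accs[i], values[i]))
    return SweepResult(
        param=param, values=values, cv_results=results,
        selected=values[order[0]],
    )


class NestedSelectionSpec(ClassifierSpec):
    """Hyperparameter selection nested inside each training fold.

    On every ``fit`` the candidate values are scored by an inner
    stratified k-fold CV run on the training data only, the argmax is
    selected (ties toward the smaller value) and the final model is
    refitted on the full training split — so the outer evaluation folds
    never inform the choice.  The alternative of selecting on the outer
    folds themselves is available through the sweep API (outer-fold
    selection mode).
    """

    stochastic = True

    def __init__(
        self,
        classifier_kind: str,
        param: str,
        values: Sequence,
        fixed: dict | None = None,
        inner_k: int = 5,
        inner_repetitions: int = 1,
    ):
        if not values:
            raise DomainError("candidate value list is empty")
        self.classifier_kind = classifier_kind
        self.param = param
        self.values = list(values)
        self.fixed = dict(fixed or {})
        self.inner_k = inner_k
        self.inner_repetitions = inner_repetitions
        self.name = (
            f"{classifier_kind}({param} in {self.values}, nested)"
        )

    def fit(self, X, y, rng: np.random.Generator | None = None):
        from .classifiers import make_classifier

        rng = rng if rng is not None else np.random.default_rng(0)
        inner_seed = int(rng.integers(2**31))
        folds = stratified_folds(
            y, k=self.inner_k, repetitions=self.inner_repetitions,
            seed=inner_seed,
        )
        accs = []
        for v in self.values:
            spec = make_classifier(
                self.classifier_kind, **{**self.fixed, self.param: v}
            )
            accs.append(
                cross_validate(
                    X, spec, folds, labels=y, seed=inner_seed
                ).mean_accuracy
            )
        order = sorted(
            range(len(self.values)),
            key=lambda i: (-accs[i], self.values[i]),
        )
        best = self.values[order[0]]
        final = make_classifier(
            self.classifier_kind, **{**self.fixed, self.param: best}
        )
        model = final.fit(X, y, rng=rng)
        model.selected_value = best
        return model

    def describe(self):
        return {
            "name": self.name,
            "kind": self.classifier_kind,
            "param": self.param,
            "values": self.values,
            "fixed": self.fixed,
            "selection": "nested",
        }


# ---------------------------------------------------------------------------
# information transfer rate and chance level


def bitrate(acc: float, n_classes: int, trial_seconds: float) -> float:
    """Wolpaw information transfer rate in bits per minute:

        (60/T) [log2 n + acc log2 acc + (1-acc) log2((1-acc)/(n-1))]

    with the convention 0·log2(0) = 0 at acc ∈ {0, 1}.  T defaults in
    the pipeline to the 10-s task period.
    """
    if not 0.0 <= acc <= 1.0:
        raise DomainError(f"accuracy must lie in [0, 1], got {acc}")
    if n_classes < 2:
        raise DomainError(f"need >= 2 classes, got {n_classes}")
    if trial_seconds <= 0:
        raise DomainError(f"trial_seconds must be > 0, got {trial_seconds}")
    bits = np.log2(n_classes)
    if acc > 0.0:
        bits += acc * np.log2(acc)
    if acc < 1.0:
        bits += (1.0 - acc) * np.log2((1.0 - acc) / (n_classes - 1))
    return float(60.0 / trial_seconds * bits)


def chance_level(
    n_trials: int, n_classes: int = 2, alpha: float = 0.05
) -> float:
    """Binomial chance threshold: k*/n for the smallest k* with
    P[Binomial(n, 1/n_classes) >= k*] < alpha (exact tail, no normal
    approximation)."""
    if n_trials < 1:
        raise DomainError(f"n_trials must be >= 1, got {n_trials}")
    if n_classes < 2:
        raise DomainError(f"need >= 2 classes, got {n_classes}")
    if not 0.0 < alpha < 1.0:
        raise DomainError(f"alpha must lie in (0, 1), got {alpha}")
    p = 1.0 / n_classes
    for k in range(n_trials + 2):
        # P[X >= k] = sf(k - 1)
        if sst.binom.sf(k - 1, n_trials, p) < alpha:
            return k / n_trials
    raise ComputationError("binomial tail never dropped below alpha")


# ---------------------------------------------------------------------------
# statistics


class AndersonDarlingResult(NamedTuple):
    statistic: float  # A^2, uncorrected
    corrected_statistic: float  # A^2 * (1 + 0.75/n + 2.25/n^2)
    p_value: float


def anderson_darling_normality(x: Sequence[float]) -> AndersonDarlingResult:
    """Anderson–Darling test of composite normality (mean and variance
    estimated from the sample).

    The statistic is corrected for sample size as
    A²* = A² (1 + 0.75/n + 2.25/n²) and the p-value follows the
    standard piecewise-exponential approximation for that case, matching
    the usual R/MATLAB implementations.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 8:
        raise SampleSizeError(f"need n >= 8 samples, got {n}")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise DegenerateDataError("sample has zero variance")
    z = np.sort((x - x.mean()) / sd)
    cdf = sst.norm.cdf(z)
    eps = np.finfo(float).tiny
    cdf = np.clip(cdf, eps, 1.0 - 1e-16)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(cdf) + np.log1p(-cdf[::-1])))
    a2c = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if a2c >= 0.6:
        p = np.exp(1.2937 - 5.709 * a2c + 0.0186 * a2c**2)
    elif a2c > 0.34:
        p = np.exp(0.9177 - 4.279 * a2c - 1.38 * a2c**2)
    elif a2c > 0.2:
        p = 1.0 - np.exp(-8.318 + 42.796 * a2c - 59.938 * a2c**2)
    else:
        p = 1.0 - np.exp(-13.436 + 101.14 * a2c - 223.73 * a2c**2)
    return AndersonDarlingResult(float(a2), float(a2c), float(np.clip(p, 0, 1)))


class PairedTTestResult(NamedTuple):
    t: float
    df: int
    p_value: float


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> PairedTTestResult:
    """Two-tailed paired t-test on d = a − b (df = n − 1).

    Identical difference vectors (zero variance) are a degenerate input
    and raise, rather than silently reporting p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError(f"paired vectors must match, got {a.shape}, {b.shape}")
    if a.size < 2:
        raise SampleSizeError("paired t-test needs n >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0.0:
        raise DegenerateDataError(
            "differences have zero variance; the paired t statistic is "
            "undefined"
        )
    res = sst.ttest_rel(a, b)
    return PairedTTestResult(float(res.statistic), int(a.size - 1),
                             float(res.pvalue))


def wilcoxon_signed_rank(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Wilcoxon signed-rank fallback for non-normal paired differences
    (two-sided).  Off by default in reports; available when the
    normality screen rejects."""
    res = sst.wilcoxon(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)


def fdr_correct(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone,
    rank-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise DataError("p_values must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
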