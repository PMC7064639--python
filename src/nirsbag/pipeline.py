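"""End-to-end experiment orchestration and method comparison.

``run_experiment`` drives one session through the full chain —
simulate (or load) → MBLL → band-pass → epoch → baseline → window-mean
features → cross-validated classification — with every configured
classifier evaluated on the *same* fold assignments, so the comparison
is paired by design.  ``compare_report`` then runs the paired
statistics: per-repetition accuracy vectors, Anderson–Darling normality
screen, two-tailed paired t-tests, Benjamini–Hochberg correction, plus
bitrates, the binomial chance level, and the conventional 70%
effective-control flag.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classifiers import make_classifier
from .errors import (
    ConfigError,
    DegenerateDataError,
    PairingError,
    SampleSizeError,
)
from .evaluation import (
    EFFECTIVE_CONTROL_THRESHOLD,
    CVResult,
    NestedSelectionSpec,
    anderson_darling_normality,
    bitrate,
    chance_level,
    cross_validate,
    fdr_correct,
    paired_ttest,
    stratified_folds,
    sweep_hyperparameters,
)
from .features import extract_features
from .io import read_events, read_recording, write_events, write_recording
from .preprocess import (
    FilterSpec,
    MbllParameters,
    bandpass_filter,
    baseline_correct,
    mbll_convert,
    segment_epochs,
)
from .synth import SynthSessionConfig, generate_session

logger = logging.getLogger("nirsbag")


@dataclass
class PipelineConfig:
    """Declarative description of one experiment run.

    Either ``synth`` (a :class:`SynthSessionConfig` or its dict form) or
    ``recording_path``+``events_path`` must be given.  ``classifiers``
    is a list of ``{"kind": ..., **params}`` dicts; a list-valued
    ``n_learn`` for ``rlda_bagging`` triggers ensemble-size selection —
    nested inside each training fold by default, or on the evaluation
    folds themselves with ``outer_selection=True``.
    """

    synth: SynthSessionConfig | dict | None = None
    recording_path: str | None = None
    events_path: str | None = None
    mbll: MbllParameters | dict | None = None
    filter: FilterSpec | dict = field(default_factory=FilterSpec)
    epoch_window: tuple[float, float] = (-1.0, 15.0)
    baseline_interval: tuple[float, float] = (-1.0, 0.0)
    feature_windows: tuple = ((5.0, 10.0), (10.0, 15.0))
    classifiers: tuple = (
        {"kind": "rlda"},
        {"kind": "rlda_bagging", "n_learn": 25, "gamma": 0.1},
    )
    cv_k: int = 10
    cv_repetitions: int = 10
    seed: int = 0
    trial_seconds: float = 10.0
    count_break_in_trial: bool = False
    alpha: float = 0.05
    outer_selection: bool = False
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if isinstance(self.synth, dict):
            nested = dict(self.synth)
            from .synth import HrfConfig, NoiseConfig

            if isinstance(nested.get("hrf"), dict):
                nested["hrf"] = HrfConfig(**nested["hrf"])
            if isinstance(nested.get("noise"), dict):
                nested["noise"] = NoiseConfig(**nested["noise"])
            if "classes" in nested:
                nested["classes"] = tuple(nested["classes"])
            if "iti_range_s" in nested:
                nested["iti_range_s"] = tuple(nested["iti_range_s"])
            self.synth = SynthSessionConfig(**nested)
        if isinstance(self.mbll, dict):
            self.mbll = MbllParameters(**self.mbll)
        if isinstance(self.filter, dict):
            self.filter = FilterSpec(**self.filter)
        if self.synth is None and not (
            self.recording_path and self.events_path
        ):
            raise ConfigError(
                "config needs either a synth block or recording_path + "
                "events_path"
            )
        if not self.classifiers:
            raise ConfigError("at least one classifier must be configured")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("epoch_window", "baseline_interval"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "feature_windows" in raw:
            raw["feature_windows"] = tuple(
                tuple(w) for w in raw["feature_windows"]
            )
        if "classifiers" in raw:
            raw["classifiers"] = tuple(raw["classifiers"])
        return cls(**raw)


@dataclass
class ComparisonReport:
    """Paired statistical comparison of cross-validated methods."""

    methods: list[str]
    mean_accuracy: dict
    per_repetition_accuracy: dict
    bitrates: dict
    chance_level: float
    effective_threshold: float
    flags: dict  # method -> {"effective": bool, "above_chance": bool}
    pairs: list[dict]  # a, b, t, df, p_raw, p_corrected, normality_p, ...
    alpha: float
    n_trials: int
    n_classes: int
    trial_seconds: float

    def to_dict(self) -> dict:
        return asdict(self)


def compare_report(
    cv_results: list[CVResult],
    alpha: float = 0.05,
    trial_seconds: float = 10.0,
    chance_alpha: float = 0.05,
) -> ComparisonReport:
    """Pairwise paired comparison of >= 2 CV results on identical folds.

    The paired unit is the per-repetition mean accuracy (one value per
    CV repetition).  Differences are screened for normality
    (Anderson–Darling); the t-test runs regardless, with the screen
    recorded, and p-values are BH-corrected across all pairs.  A pair
    with zero-variance differences is a degenerate input and raises.
    """
    if len(cv_results) < 2:
        raise ConfigError("need >= 2 CV results to compare")
    ref = cv_results[0]
    for r in cv_results[1:]:
        if not np.array_equal(r.folds, ref.folds):
            raise PairingError(
                "CV results were not computed on identical fold "
                "assignments; the paired comparison is invalid"
            )
        if r.labels != ref.labels:
            raise PairingError("CV results cover different trial labels")
    names = [r.classifier["name"] for r in cv_results]
    if len(set(names)) != len(names):
        names = [f"{n}#{i}" for i, n in enumerate(names)]
    n_trials = len(ref.labels)
    n_classes = len(set(ref.labels))
    chance = chance_level(n_trials, n_classes, chance_alpha)
    per_rep = {
        nm: r.per_repetition_accuracy for nm, r in zip(names, cv_results)
    }
    mean_acc = {nm: r.mean_accuracy for nm, r in zip(names, cv_results)}
    rates = {
        nm: bitrate(mean_acc[nm], n_classes, trial_seconds) for nm in names
    }
    flags = {
        nm: {
            "effective": mean_acc[nm] >= EFFECTIVE_CONTROL_THRESHOLD,
            "above_chance": mean_acc[nm] > chance,
        }
        for nm in names
    }
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = per_rep[names[i]], per_rep[names[j]]
            d = a - b
            if np.std(d, ddof=1) == 0.0:
                raise DegenerateDataError(
                    f"accuracy differences between {names[i]!r} and "
                    f"{names[j]!r} have zero variance; the paired t-test "
                    "is undefined"
                )
            try:
                normality_p = anderson_darling_normality(d).p_value
            except (DegenerateDataError, SampleSizeError):
                # screen unavailable (too few repetitions / no spread);
                # the t-test still runs, with the screen marked missing
                normality_p = float("nan")
            tt = paired_ttest(a, b)
            pairs.append(
                {
                    "a": names[i],
                    "b": names[j],
                    "mean_difference": float(np.mean(d)),
                    "t": tt.t,
                    "df": tt.df,
                    "p_raw": tt.p_value,
                    "normality_p": normality_p,
                    "normality_rejected": bool(normality_p < alpha),
                }
            )
    corrected = fdr_correct([p["p_raw"] for p in pairs])
    for p, c in zip(pairs, corrected):
        p["p_corrected"] = float(c)
        p["significant"] = bool(c < alpha)
    return ComparisonReport(
        methods=names,
        mean_accuracy=mean_acc,
        per_repetition_accuracy={
            nm: v.tolist() for nm, v in per_rep.items()
        },
        bitrates=rates,
        chance_level=chance,
        effective_threshold=EFFECTIVE_CONTROL_THRESHOLD,
        flags=flags,
        pairs=pairs,
        alpha=alpha,
        n_trials=n_trials,
        n_classes=n_classes,
        trial_seconds=trial_seconds,
    )


@dataclass
class ExperimentReport:
    """In-memory result of :func:`run_experiment`."""

    cv_results: list[CVResult]
    comparison: ComparisonReport
    folds: np.ndarray
    sweeps: dict


def _build_spec(entry: dict, cfg: PipelineConfig):
    """Turn one classifier config entry into (spec, sweep_request)."""
    entry = dict(entry)
    kind = entry.pop("kind", None)
    if kind is None:
        raise ConfigError(f"classifier entry lacks 'kind': {entry}")
    grid_params = {
        k: v for k, v in entry.items() if isinstance(v, (list, tuple))
    }
    if not grid_params:
        return make_classifier(kind, **entry), None
    if len(grid_params) > 1:
        raise ConfigError(
            f"at most one classifier parameter may be a grid, got "
            f"{sorted(grid_params)}"
        )
    (param, values), = grid_params.items()
    fixed = {k: v for k, v in entry.items() if k not in grid_params}
    if cfg.outer_selection:
        return None, {"kind": kind, "param": param,
                      "values": list(values), "fixed": fixed}
    return (
        NestedSelectionSpec(kind, param, list(values), fixed=fixed),
        None,
    )


def run_experiment(config: PipelineConfig) -> ExperimentReport:
    """Run the configured experiment; write reports when ``out_dir``
    is set.

    Stages: obtain the session (synthetic or from disk), convert optical
    densities if present, band-pass filter, epoch, baseline-correct,
    extract window-mean features, build one shared set of stratified
    folds, cross-validate every classifier on those folds, and compile
    the paired comparison report.
    """
    t0 = time.time()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    if config.synth is not None:
        logger.info("generating synthetic session (seed=%s)",
                    config.synth.seed)
        recording, events = generate_session(config.synth)
    else:
        logger.info("loading recording %s", config.recording_path)
        recording = read_recording(config.recording_path)
        events = read_events(config.events_path)

    if any(c.signal_kind.startswith("od_") for c in recording.channels):
        logger.info("converting optical densities (MBLL)")
        recording = mbll_convert(recording, config.mbll)

    logger.info("band-pass filtering %s-%s Hz",
                config.filter.low_cut_hz, config.filter.high_cut_hz)
    filtered = bandpass_filter(recording, config.filter)
    epochs = segment_epochs(filtered, events, window=config.epoch_window)
    epochs = baseline_correct(epochs, interval=config.baseline_interval)
    feats = extract_features(epochs, windows=config.feature_windows)
    logger.info("features: %d trials x %d features",
                feats.n_trials, feats.n_features)

    folds = stratified_folds(
        feats.labels, k=config.cv_k, repetitions=config.cv_repetitions,
        seed=config.seed,
    )
    cv_results: list[CVResult] = []
    sweeps: dict = {}
    for entry in config.classifiers:
        spec, sweep_req = _build_spec(entry, config)
        if sweep_req is not None:
            logger.info("sweeping %s over %s (outer-fold selection)",
                        sweep_req["param"], sweep_req["values"])
            sw = sweep_hyperparameters(
                feats,
                {sweep_req["param"]: sweep_req["values"]},
                folds,
                classifier_kind=sweep_req["kind"],
                fixed=sweep_req["fixed"],
                seed=config.seed,
            )
            sweeps[sweep_req["kind"]] = sw
            idx = sw.values.index(sw.selected)
            cv_results.append(sw.cv_results[idx])
            continue
        logger.info("cross-validating %s", spec.name)
        cv_results.append(
            cross_validate(feats, spec, folds, seed=config.seed)
        )

    trial_seconds = config.trial_seconds
    if config.count_break_in_trial and config.synth is not None:
        trial_seconds = config.synth.task_duration_s + float(
            np.mean(config.synth.iti_range_s)
        )
    comparison = compare_report(
        cv_results, alpha=config.alpha, trial_seconds=trial_seconds
    )

    if out_dir:
        _write_outputs(out_dir, config, recording, events, cv_results,
                       comparison, sweeps)
    logger.info("experiment finished in %.1f s", time.time() - t0)
    return ExperimentReport(
        cv_results=cv_results, comparison=comparison, folds=folds,
        sweeps=sweeps,
    )


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return json.loads(json.dumps(d, default=str))


def _write_outputs(out_dir, config, recording, events, cv_results,
                   comparison, sweeps) -> None:
    import importlib.metadata as im

    write_recording(recording, out_dir / "session")
    write_events(events, out_dir / "session.events.tsv")
    for i, r in enumerate(cv_results):
        safe = f"cv_{i}_{r.classifier['name'].split('(')[0]}"
        with open(out_dir / f"{safe}.json", "w", encoding="utf-8") as fh:
            json.dump(r.to_dict(), fh, indent=1)
        np.savetxt(
            out_dir / f"{safe}.folds.tsv",
            r.per_fold_accuracy,
            delimiter="\t",
            fmt="%.6f",
            header="\t".join(f"fold{j}" for j in range(r.k)),
            comments="",
        )
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(comparison.to_dict(), fh, indent=1)
    for kind, sw in sweeps.items():
        with open(out_dir / f"sweep_{kind}.json", "w",
                  encoding="utf-8") as fh:
            json.dump(
                {
                    "param": sw.param,
                    "values": sw.values,
                    "mean_accuracies": sw.mean_accuracies.tolist(),
                    "selected": sw.selected,
                },
                fh, indent=1,
            )
    versions = {}
    for pkg in ("numpy", "scipy", "pandas", "scikit-learn",
                "statsmodels"):
        try:
            versions[pkg] = im.version(pkg)
        except im.PackageNotFoundError:  # pragma: no cover
            versions[pkg] = None
    manifest = {
        "nirsbag_version": __version__,
        "config": _config_dict(config),
        "library_versions": versions,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
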