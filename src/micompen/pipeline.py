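"""End-to-end orchestration: recording -> features -> embedding -> CV scores.

Stage order follows the analysis framework: epoching, conventional
filtering, SOBI-ICA artifact zeroing, CompEn feature extraction, ANOVA
screening (descriptive), Laplacian Eigenmap reduction, and 10-fold
stratified cross-validated classification with KNN (k=5, Euclidean),
RBF-kernel SVM (C=10, sigma=0.5) and a 100-tree random forest.

All data-dependent statistics — feature standardisation and the
eigenmap — are fit on training folds only; test folds are mapped by the
Nystrom extension.  A master seed fans out to per-stage seeds through
``numpy.random.SeedSequence`` so stages are individually reproducible.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_score, recall_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import eeg_io, preprocess, synthgen
from .eeg_io import CLASS_ORDER, EpochSet, RawRecording
from .embedding import LaplacianEigenmap
from .features import FeatureTable, extract_features
from .screening import screen_features

logger = logging.getLogger(__name__)

#: the RBF "smoothing value" sigma enters as k(x,y) = exp(-||x-y||^2 / (2 sigma^2))
SVM_SIGMA = 0.5
SVM_C = 10.0
KNN_K = 5
RF_TREES = 100


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class ClassifierResult:
    accuracy: float              # percent
    macro_precision: float       # percent
    macro_recall: float          # percent
    confusion: np.ndarray        # 4x4, rows = true class in CLASS_ORDER
    predictions: np.ndarray


@dataclass
class ClassificationReport:
    per_classifier: dict[str, ClassifierResult]
    fold_assignments: np.ndarray
    seed: int
    truth: np.ndarray = field(default=None)

    def summary_frame(self):
        import pandas as pd
        return pd.DataFrame({
            name: {"accuracy_%": r.accuracy,
                   "macro_precision_%": r.macro_precision,
                   "macro_recall_%": r.macro_recall}
            for name, r in self.per_classifier.items()}).T

    def to_json(self, path) -> None:
        out = {name: {
            "accuracy_percent": r.accuracy,
            "macro_precision_percent": r.macro_precision,
            "macro_recall_percent": r.macro_recall,
            "confusion_matrix": r.confusion.tolist(),
            "class_order": list(CLASS_ORDER)}
            for name, r in self.per_classifier.items()}
        out["seed"] = self.seed
        Path(path).write_text(json.dumps(out, indent=2))


def evaluate(predictions: np.ndarray, truth: np.ndarray) -> ClassifierResult:
    """Accuracy, macro precision/recall (percent) and confusion matrix.

    The confusion matrix uses the fixed class order (left hand, right
    hand, foot, tongue); rows are true classes.  Zero-division in a
    macro average contributes 0 for that class, with a warning.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth must have equal length")
    unknown = set(predictions) | set(truth)
    if not unknown <= set(CLASS_ORDER):
        raise ValueError(f"unknown labels: {sorted(unknown - set(CLASS_ORDER))}")
    acc = 100.0 * float((predictions == truth).mean())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec = 100.0 * precision_score(truth, predictions, labels=list(CLASS_ORDER),
                                       average="macro", zero_division=0)
        rec = 100.0 * recall_score(truth, predictions, labels=list(CLASS_ORDER),
                                   average="macro", zero_division=0)
    cm = confusion_matrix(truth, predictions, labels=list(CLASS_ORDER))
    return ClassifierResult(accuracy=acc, macro_precision=float(prec),
                            macro_recall=float(rec), confusion=cm,
                            predictions=predictions)


def _stage_seeds(master: int) -> dict[str, int]:
    names = ("synth", "cv", "rf", "screening")
    children = np.random.SeedSequence(master).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % 2 ** 31)
            for n, c in zip(names, children)}


def make_classifiers(rf_seed: int, tune_c: bool = False) -> dict:
    svm = SVC(kernel="rbf", C=SVM_C, gamma=1.0 / (2.0 * SVM_SIGMA ** 2))
    if tune_c:
        svm = GridSearchCV(svm, {"C": [10.0 ** e for e in range(-4, 5)]},
                           cv=10, n_jobs=1)
    return {
        "KNN": KNeighborsClassifier(n_neighbors=KNN_K, metric="euclidean"),
        "SVM": svm,
        "RF": RandomForestClassifier(n_estimators=RF_TREES,
                                     random_state=rf_seed),
    }


def classify_features(X: np.ndarray, labels: np.ndarray, seed: int = 0,
                      embedding_enabled: bool = True, n_folds: int = 10,
                      n_neighbors: int = 5, r: int = 10,
                      weight_scheme: str = "binary",
                      tune_c: bool = False) -> ClassificationReport:
    """Stratified k-fold CV of KNN/SVM/RF on a feature matrix.

    Per fold: standardise on the training fold, optionally embed with a
    Laplacian Eigenmap fit on the training fold (test points via the
    Nystrom extension), then fit each classifier and predict the test
    fold.  Returns pooled out-of-fold predictions per classifier.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    seeds = _stage_seeds(seed)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=seeds["cv"])
    names = list(make_classifiers(0))
    preds = {n: np.empty(len(labels), dtype=labels.dtype) for n in names}
    folds = np.empty(len(labels), dtype=int)
    for f, (tr, te) in enumerate(skf.split(X, labels)):
        folds[te] = f
        scaler = StandardScaler().fit(X[tr])
        Xtr, Xte = scaler.transform(X[tr]), scaler.transform(X[te])
        if embedding_enabled:
            le = LaplacianEigenmap(n_neighbors=n_neighbors, r=r,
                                   weight_scheme=weight_scheme).fit(Xtr)
            Xtr, Xte = le.transform(Xtr), le.transform(Xte)
        for name, clf in make_classifiers(seeds["rf"], tune_c).items():
            clf.fit(Xtr, labels[tr])
            preds[name][te] = clf.predict(Xte)
    per = {n: evaluate(preds[n], labels) for n in names}
    return ClassificationReport(per_classifier=per, fold_assignments=folds,
                                seed=seed, truth=labels)


DEFAULT_CONFIG: dict = {
    "input": {"kind": "synthetic", "n_trials": 40, "fs": 250.0,
              "hurst_gap": None, "path": None, "format": None},
    "preprocess": {"enabled": True, "notch": 50.0, "band": [8.0, 30.0],
                   "n_lags": 100, "xcorr_threshold": 0.5},
    "epoch": {"window": [0.0, 6.0]},
    "features": {"kmax": 20, "dispersion_m": 2, "dispersion_c": 2},
    "screening": {"enabled": True, "alpha": 0.05},
    "embedding": {"enabled": True, "n_neighbors": 5, "r": 10,
                  "weight_scheme": "binary"},
    "classify": {"n_folds": 10, "tune_c": False},
    "seed": 0,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(
            base.get(k), dict) else v
    return out


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        cfg = _merge(cfg, yaml.safe_load(Path(path).read_text()) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


@dataclass
class PipelineArtifacts:
    report: ClassificationReport
    features: FeatureTable
    epochs: EpochSet
    recording: RawRecording
    screening: object | None = None
    decomposition: object | None = None
    ground_truth: object | None = None


def run_pipeline(config: dict | str | Path | None = None,
                 outdir: str | Path | None = None) -> PipelineArtifacts:
    """Run every stage in order and return (and optionally persist) artifacts.

    ``config`` may be a YAML path or a dict following
    :data:`DEFAULT_CONFIG`; omitted keys take their defaults.  On stage
    failure a :class:`PipelineError` names the stage; artifacts produced
    up to that point are persisted to ``outdir`` if one was given.
    """
    cfg = load_config(config) if not isinstance(config, dict) \
        else _merge(DEFAULT_CONFIG, config)
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(int(cfg["seed"]))
    arts: dict = {}

    def persist() -> None:
        if outdir is None:
            return
        if "features" in arts:
            arts["features"].to_tsv(outdir / "features.tsv")
        if "screening" in arts and arts["screening"] is not None:
            arts["screening"].to_tsv(outdir / "screening.tsv")
        if "report" in arts:
            arts["report"].to_json(outdir / "report.json")
            arts["report"].summary_frame().to_csv(
                outdir / "report.tsv", sep="\t")

    stage = "input"
    try:
        inp = cfg["input"]
        if inp["kind"] == "synthetic":
            sigs = None
            if inp.get("hurst_gap") is not None:
                sigs = synthgen.default_signatures(hurst_gap=inp["hurst_gap"])
            rec, truth = synthgen.generate_recording(
                n_trials=int(inp["n_trials"]), fs=float(inp["fs"]),
                signatures=sigs, seed=seeds["synth"])
            arts["ground_truth"] = truth
        else:
            rec = eeg_io.read_recording(inp["path"], inp.get("format"))
        arts["recording"] = rec

        stage = "preprocess"
        pp = cfg["preprocess"]
        dec = None
        if pp["enabled"]:
            rec, dec = preprocess.denoise(
                rec, notch=pp["notch"], band=tuple(pp["band"]),
                n_lags=int(pp["n_lags"]), threshold=pp["xcorr_threshold"])
        arts["decomposition"] = dec

        stage = "epoch"
        epochs = eeg_io.epoch(rec, window=tuple(cfg["epoch"]["window"]))

        stage = "features"
        ft = extract_features(epochs, **cfg["features"])
        arts["features"] = ft

        stage = "screening"
        screening = None
        if cfg["screening"]["enabled"]:
            screening = screen_features(ft, alpha=cfg["screening"]["alpha"],
                                        seed=seeds["screening"])
        arts["screening"] = screening

        stage = "classify"
        emb = cfg["embedding"]
        report = classify_features(
            ft.values, ft.labels, seed=int(cfg["seed"]),
            embedding_enabled=emb["enabled"], n_folds=cfg["classify"]["n_folds"],
            n_neighbors=emb["n_neighbors"], r=emb["r"],
            weight_scheme=emb["weight_scheme"],
            tune_c=cfg["classify"]["tune_c"])
        arts["report"] = report
    except Exception as exc:
        persist()
        logger.error("pipeline aborted in stage %r", stage)
        raise PipelineError(stage, exc) from exc

    persist()
    return PipelineArtifacts(
        report=arts["report"], features=arts["features"], epochs=epochs,
        recording=arts["recording"], screening=arts.get("screening"),
        decomposition=arts.get("decomposition"),
        ground_truth=arts.get("ground_truth"))
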