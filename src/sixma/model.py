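"""End-to-end 6mA site-prediction pipeline and cross-validation harness.

The pipeline is encoder → (optional) attention fusion → ensemble classifier.
It is organised as a model/results pair:

* :class:`SitePredictor` is built from a :class:`~sixma.datasets.LabeledDataset`
  plus an encoder choice, an attention configuration (or None to disable the
  fusion step) and a classifier back-end; ``fit()`` returns
* :class:`SitePredictorResults`, which carries every fitted component
  (PSTNPds frequency matrices, attention transformer, trained classifier),
  predicts and evaluates held-out windows, renders a ``summary()`` table and
  serialises to a JSON bundle.

:func:`cross_validate` runs stratified k-fold evaluation. Because the
PSTNPds frequencies (and the attention weights) are label statistics, they
are fitted per fold on the training split only (``leak_mode='fold_safe'``,
the default). ``leak_mode='whole_dataset'`` instead fits the PSTNPds
matrices once on all records, test folds included — the protocol ambiguity
found in much of the site-prediction literature — and exists purely to
demonstrate how much that leakage inflates cross-validated scores.
"""

from __future__ import annotations

import base64
import json
import pickle
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.ensemble import AdaBoostClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .attention import AttentionConfig, AttentionTransformer, fit_attention, transform_attention
from .datasets import LabeledDataset
from .encoders import ENCODER_NAMES, FeatureMatrix, PSTNPdsModel, encode, fit_pstnpds
from .errors import FitError, NotFittedError, ParameterError
from .metrics import METRIC_NAMES, MetricsReport, evaluate_scores

__all__ = [
    "ClassifierSpec",
    "EncoderSpec",
    "CVConfig",
    "CVReport",
    "SitePredictor",
    "SitePredictorResults",
    "train_pipeline",
    "predict",
    "cross_validate",
]

CLASSIFIER_KINDS = ("gbdt_lightgbm", "gbdt_xgboost", "adaboost", "decision_tree")


@dataclass(frozen=True)
class ClassifierSpec:
    """Ensemble back-end and its hyperparameters.

    Defaults: 100 trees, depth 6 for the boosting back-ends (a single
    decision tree grows unrestricted), learning rate 0.1, fixed seed.
    """

    kind: str = "gbdt_xgboost"
    n_estimators: int = 100
    max_depth: int | None = 6
    learning_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ParameterError(
                f"unknown classifier kind {self.kind!r}; choose from {CLASSIFIER_KINDS}"
            )

    def build(self):
        if self.kind == "gbdt_lightgbm":
            from lightgbm import LGBMClassifier

            return LGBMClassifier(
                n_estimators=self.n_estimators, max_depth=self.max_depth or -1,
                learning_rate=self.learning_rate, random_state=self.seed,
                n_jobs=1, verbose=-1,
            )
        if self.kind == "gbdt_xgboost":
            from xgboost import XGBClassifier

            return XGBClassifier(
                n_estimators=self.n_estimators, max_depth=self.max_depth,
                learning_rate=self.learning_rate, random_state=self.seed,
                n_jobs=1, verbosity=0, eval_metric="logloss",
            )
        if self.kind == "adaboost":
            return AdaBoostClassifier(
                n_estimators=self.n_estimators, learning_rate=self.learning_rate,
                random_state=self.seed,
            )
        return DecisionTreeClassifier(max_depth=None, random_state=self.seed)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "n_estimators": self.n_estimators,
                "max_depth": self.max_depth, "learning_rate": self.learning_rate,
                "seed": self.seed}


@dataclass(frozen=True)
class EncoderSpec:
    """Encoder choice plus its parameters (k for kmer, window for enac)."""

    name: str = "pstnpds"
    k: int = 3
    window: int = 5

    def __post_init__(self) -> None:
        if self.name not in ENCODER_NAMES:
            raise ParameterError(
                f"unknown encoder {self.name!r}; choose from {ENCODER_NAMES}"
            )

    def to_dict(self) -> dict:
        return {"name": self.name, "k": self.k, "window": self.window}


@dataclass(frozen=True)
class CVConfig:
    """Stratified k-fold setup (default 5 folds, shuffled from ``seed``)."""

    folds: int = 5
    stratified: bool = True
    seed: int = 0
    leak_mode: str = "fold_safe"

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ParameterError(f"folds must be >= 2, got {self.folds}")
        if self.leak_mode not in ("fold_safe", "whole_dataset"):
            raise ParameterError(
                f"leak_mode must be 'fold_safe' or 'whole_dataset', got {self.leak_mode!r}"
            )

    def to_dict(self) -> dict:
        return {"folds": self.folds, "stratified": self.stratified,
                "seed": self.seed, "leak_mode": self.leak_mode}


def _coerce_encoder(enc) -> EncoderSpec:
    return EncoderSpec(name=enc) if isinstance(enc, str) else enc


def _coerce_classifier(clf) -> ClassifierSpec:
    return ClassifierSpec(kind=clf) if isinstance(clf, str) else clf


class SitePredictor:
    """Model object: a labeled training set plus pipeline configuration.

    Parameters
    ----------
    dataset
        Training windows (both classes required to fit).
    encoder
        Encoder name or :class:`EncoderSpec` (default PSTNPds).
    attention
        :class:`AttentionConfig` for the fusion step, or None to feed the
        encoder output straight to the classifier.
    classifier
        Classifier kind or :class:`ClassifierSpec`
        (default XGBoost gradient boosting).
    """

    def __init__(self, dataset: LabeledDataset, encoder="pstnpds",
                 attention: AttentionConfig | None = AttentionConfig(),
                 classifier="gbdt_xgboost"):
        self.dataset = dataset
        self.encoder = _coerce_encoder(encoder)
        self.attention = attention
        self.classifier = _coerce_classifier(classifier)

    @classmethod
    def from_fasta(cls, pos_path, neg_path, **kwargs) -> "SitePredictor":
        from .datasets import read_labeled_fasta

        return cls(read_labeled_fasta(pos_path, neg_path), **kwargs)

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "SitePredictor":
        from .datasets import read_dataset_tsv

        return cls(read_dataset_tsv(path), **kwargs)

    def fit(self, pstnp_model: PSTNPdsModel | None = None) -> "SitePredictorResults":
        """Fit every pipeline component on the model's dataset.

        A pre-fitted ``pstnp_model`` may be supplied (the CV harness uses
        this to implement the whole-dataset leak mode); by default the
        PSTNPds frequencies are estimated from this model's own dataset.
        """
        ds = self.dataset
        ds.require_both_classes()
        if self.encoder.name == "pstnpds" and pstnp_model is None:
            pstnp_model = fit_pstnpds(ds)
        X = encode(ds, self.encoder.name, k=self.encoder.k,
                   window=self.encoder.window, pstnp_model=pstnp_model)
        att = None
        if self.attention is not None:
            att = fit_attention(X, ds.labels, self.attention)
            X = transform_attention(att, X)
        clf = self.classifier.build()
        clf.fit(X.values, ds.labels)
        return SitePredictorResults(
            model=self,
            pstnp_model=pstnp_model if self.encoder.name == "pstnpds" else None,
            attention_=att,
            classifier_=clf,
            feature_names=list(X.feature_names),
            provenance={
                "encoder": self.encoder.to_dict(),
                "attention": None if self.attention is None else self.attention.to_dict(),
                "classifier": self.classifier.to_dict(),
                "train_fingerprint": ds.fingerprint(),
                "n_pos": ds.n_pos, "n_neg": ds.n_neg, "L": ds.length,
            },
        )


@dataclass
class SitePredictorResults:
    """Fitted pipeline: estimates, diagnostics, prediction and persistence."""

    model: SitePredictor | None
    pstnp_model: PSTNPdsModel | None
    attention_: AttentionTransformer | None
    classifier_: object
    feature_names: list[str]
    provenance: dict = field(default_factory=dict)

    # -- feature path -------------------------------------------------------
    def _features(self, ds: LabeledDataset, *, reweighted: bool = True) -> FeatureMatrix:
        enc = EncoderSpec(**self.provenance["encoder"])
        X = encode(ds, enc.name, k=enc.k, window=enc.window, pstnp_model=self.pstnp_model)
        if reweighted and self.attention_ is not None:
            X = transform_attention(self.attention_, X)
        return X

    # -- prediction ---------------------------------------------------------
    def predict(self, ds: LabeledDataset, threshold: float = 0.5):
        """Positive-class scores in [0,1] and thresholded labels
        (label 1 iff score >= threshold)."""
        if self.classifier_ is None:
            raise NotFittedError("predict requested from an unfitted pipeline")
        X = self._features(ds)
        scores = np.asarray(self.classifier_.predict_proba(X.values))[:, 1]
        return scores, (scores >= threshold).astype(int)

    def evaluate(self, ds: LabeledDataset, threshold: float = 0.5) -> MetricsReport:
        scores, _ = self.predict(ds, threshold)
        return evaluate_scores(ds.labels, scores, threshold)

    def attention_map(self, ds: LabeledDataset):
        from .attention import export_attention_map

        if self.attention_ is None:
            raise NotFittedError("this pipeline was fitted without attention")
        return export_attention_map(self.attention_, self._features(ds, reweighted=False))

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        p = self.provenance
        lines = [
            "6mA site-prediction pipeline (fitted)",
            "=" * 45,
            f"encoder:     {p['encoder']['name']} {p['encoder']}",
            f"attention:   {'off' if p['attention'] is None else p['attention']}",
            f"classifier:  {p['classifier']['kind']} {p['classifier']}",
            f"training:    n_pos={p['n_pos']}, n_neg={p['n_neg']}, L={p['L']}",
            f"fingerprint: {p['train_fingerprint']}",
            f"features:    {len(self.feature_names)}",
        ]
        if self.attention_ is not None and self.attention_.loss_trajectory:
            traj = self.attention_.loss_trajectory
            lines.append(
                f"attention cross-entropy: {traj[0]:.4f} -> {traj[-1]:.4f} "
                f"over {len(traj)} epochs"
            )
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        """Write a JSON model bundle.

        XGBoost/LightGBM classifiers serialise to their native text formats;
        the sklearn back-ends (AdaBoost, decision tree) have no text form
        and are embedded as base64 pickle.
        """
        clf_spec = ClassifierSpec(**self.provenance["classifier"])
        if clf_spec.kind == "gbdt_xgboost":
            payload = {"format": "xgboost_json",
                       "data": self.classifier_.get_booster().save_raw("json").decode()}
        elif clf_spec.kind == "gbdt_lightgbm":
            payload = {"format": "lightgbm_text",
                       "data": self.classifier_.booster_.model_to_string()}
        else:
            payload = {"format": "pickle_base64",
                       "data": base64.b64encode(pickle.dumps(self.classifier_)).decode()}
        bundle = {
            "provenance": self.provenance,
            "feature_names": self.feature_names,
            "pstnp_model": None if self.pstnp_model is None else self.pstnp_model.to_dict(),
            "attention": None if self.attention_ is None else self.attention_.to_dict(),
            "classifier": payload,
        }
        with open(path, "w") as fh:
            json.dump(bundle, fh)

    @classmethod
    def load(cls, path) -> "SitePredictorResults":
        with open(path) as fh:
            bundle = json.load(fh)
        prov = bundle["provenance"]
        spec = ClassifierSpec(**prov["classifier"])
        payload = bundle["classifier"]
        if payload["format"] == "xgboost_json":
            clf = spec.build()
            clf.load_model(bytearray(payload["data"].encode()))
        elif payload["format"] == "lightgbm_text":
            import lightgbm

            booster = lightgbm.Booster(model_str=payload["data"])
            clf = _LGBMBoosterAdapter(booster)
        else:
            clf = pickle.loads(base64.b64decode(payload["data"]))
        return cls(
            model=None,
            pstnp_model=(None if bundle["pstnp_model"] is None
                         else PSTNPdsModel.from_dict(bundle["pstnp_model"])),
            attention_=(None if bundle["attention"] is None
                        else AttentionTransformer.from_dict(bundle["attention"])),
            classifier_=clf,
            feature_names=list(bundle["feature_names"]),
            provenance=prov,
        )


class _LGBMBoosterAdapter:
    """predict_proba facade over a bare LightGBM booster loaded from text."""

    def __init__(self, booster):
        self.booster = booster

    def predict_proba(self, X):
        p = np.asarray(self.booster.predict(X)).ravel()
        return np.column_stack([1.0 - p, p])


# ---------------------------------------------------------------------------
# Functional facade
# ---------------------------------------------------------------------------

def train_pipeline(train: LabeledDataset, encoder="pstnpds",
                   attention: AttentionConfig | None = AttentionConfig(),
                   classifier="gbdt_xgboost") -> SitePredictorResults:
    """Fit the full pipeline on *train*; see :class:`SitePredictor`."""
    return SitePredictor(train, encoder=encoder, attention=attention,
                         classifier=classifier).fit()


def predict(results: SitePredictorResults, ds: LabeledDataset, threshold: float = 0.5):
    return results.predict(ds, threshold)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Per-fold metric reports plus mean/std aggregation and a config echo."""

    fold_reports: list[MetricsReport]
    mean: dict
    std: dict
    config: dict

    def summary(self) -> str:
        hdr = f"{'metric':<8}" + "".join(f"{m:>10}" for m in METRIC_NAMES)
        rows = [
            f"{'mean':<8}" + "".join(f"{self.mean[m]:>10.4f}" for m in METRIC_NAMES),
            f"{'std':<8}" + "".join(f"{self.std[m]:>10.4f}" for m in METRIC_NAMES),
        ]
        lines = [
            f"Stratified {self.config['cv']['folds']}-fold cross-validation "
            f"({self.config['cv']['leak_mode']})",
            "=" * len(hdr), hdr, "-" * len(hdr), *rows,
        ]
        for i, rep in enumerate(self.fold_reports):
            d = rep.to_dict()
            lines.append(
                f"fold {i:<3}" + "".join(f"{d[m]:>10.4f}" for m in METRIC_NAMES)
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "mean": self.mean,
            "std": self.std,
            "folds": [r.to_dict() for r in self.fold_reports],
        }


def make_folds(labels: np.ndarray, cv: CVConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled stratified (train, test) index pairs covering every record once."""
    counts = np.bincount(labels, minlength=2)
    if cv.folds > counts.min():
        raise ParameterError(
            f"folds={cv.folds} exceeds the smaller class size {counts.min()}"
        )
    splitter = StratifiedKFold(n_splits=cv.folds, shuffle=True, random_state=cv.seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros(labels.size), labels)]


def cross_validate(ds: LabeledDataset, encoder="pstnpds",
                   attention: AttentionConfig | None = AttentionConfig(),
                   classifier="gbdt_xgboost",
                   cv: CVConfig = CVConfig()) -> CVReport:
    """Stratified k-fold evaluation of the full pipeline.

    In ``fold_safe`` mode every label-dependent component (PSTNPds
    frequencies, attention, classifier) is fitted per fold on that fold's
    training split only. In ``whole_dataset`` mode the PSTNPds frequencies
    are fitted once on all records — including each fold's test windows —
    which leaks label information into the test features and inflates every
    metric; it exists only to quantify that inflation.
    """
    ds.require_both_classes()
    enc, clf = _coerce_encoder(encoder), _coerce_classifier(classifier)
    labels = ds.labels
    folds = make_folds(labels, cv)

    leaked_pstnp = None
    if cv.leak_mode == "whole_dataset" and enc.name == "pstnpds":
        leaked_pstnp = fit_pstnpds(ds)

    reports: list[MetricsReport] = []
    for fold_id, (tr, te) in enumerate(folds):
        train_ds, test_ds = ds.subset(tr), ds.subset(te)
        predictor = SitePredictor(train_ds, encoder=enc, attention=attention,
                                  classifier=clf)
        results = predictor.fit(pstnp_model=leaked_pstnp)
        if cv.leak_mode == "fold_safe" and results.pstnp_model is not None:
            # invariant: the fold's frequency matrices were estimated on the
            # fold's training records and nothing else
            assert results.pstnp_model.train_fingerprint == train_ds.fingerprint()
        results.provenance["fold_id"] = fold_id
        reports.append(results.evaluate(test_ds))

    mean = {m: float(np.mean([getattr(r, m) for r in reports])) for m in METRIC_NAMES}
    std = {m: float(np.std([getattr(r, m) for r in reports])) for m in METRIC_NAMES}
    return CVReport(
        fold_reports=reports, mean=mean, std=std,
        config={
            "encoder": enc.to_dict(),
            "attention": None if attention is None else attention.to_dict(),
            "classifier": clf.to_dict(),
            "cv": cv.to_dict(),
            "n_pos": ds.n_pos, "n_neg": ds.n_neg, "L": ds.length,
        },
    )
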