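"""Confusion-matrix metrics, leave-one-specimen-out cross-validation,
cross-area transfer validation, and table-style reporting.

The positive class is fascicular nerve throughout. The Matthews
correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

summarises a binary confusion matrix in [-1, 1]; accuracy, sensitivity,
specificity, PPV and NPV are the usual ratios. Reported rounding: MCC,
ACC, PPV, NPV to three decimals; SENS and SPEC as percentages to one
decimal.

Leave-one-specimen-out (LOSO): for each specimen the whole pipeline —
feature statistics and classifier — is fitted on the remaining
specimens only, the held-out specimen is predicted, and the per-fold
confusion matrices are summed before metrics are computed. Transfer
validation trains once on the cervical-area data and evaluates once on
the forearm-area data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import predict, train_cart, train_plsda, train_svm_rbf
from .features import (
    FeatureMatrix,
    combine_features,
    pca_features,
    scale_features,
    segment_features,
)
from .spectra import SpectraDataset

logger = logging.getLogger(__name__)

#: Missing marker for metrics with a zero denominator.
UNDEFINED = float("nan")


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FN/FP/TN counts; fascicular nerve is the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fn + other.fn,
                               self.fp + other.fp, self.tn + other.tn)

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionMatrix":
        t = np.asarray(y_true).astype(int)
        p = np.asarray(y_pred).astype(int)
        if t.shape != p.shape:
            raise ValueError("label arrays differ in length")
        return cls(
            tp=int(np.sum((t == 1) & (p == 1))),
            fn=int(np.sum((t == 1) & (p == 0))),
            fp=int(np.sum((t == 0) & (p == 1))),
            tn=int(np.sum((t == 0) & (p == 0))),
        )


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient.

    An all-zero matrix is undefined (NaN). When one of the four
    denominator factors is zero the value is reported as 0 per the
    widespread convention (logged).
    """
    if cm.total == 0:
        return UNDEFINED
    denom = ((cm.tp + cm.fp) * (cm.tp + cm.fn)
             * (cm.tn + cm.fp) * (cm.tn + cm.fn))
    if denom == 0:
        logger.info("MCC denominator factor is zero; reporting 0 by convention")
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else UNDEFINED


@dataclass
class MetricsRow:
    """One report row: counts plus the derived metrics."""

    method: str
    feature_selection: str
    cm: ConfusionMatrix

    @property
    def mcc(self) -> float:
        return mcc(self.cm)

    @property
    def acc(self) -> float:
        return _ratio(self.cm.tp + self.cm.tn, self.cm.total)

    @property
    def sens_pct(self) -> float:
        return 100.0 * _ratio(self.cm.tp, self.cm.tp + self.cm.fn)

    @property
    def spec_pct(self) -> float:
        return 100.0 * _ratio(self.cm.tn, self.cm.fp + self.cm.tn)

    @property
    def ppv(self) -> float:
        return _ratio(self.cm.tp, self.cm.tp + self.cm.fp)

    @property
    def npv(self) -> float:
        return _ratio(self.cm.tn, self.cm.tn + self.cm.fn)

    def rounded(self) -> dict:
        """Report rounding: 3 decimals, SENS/SPEC 1-decimal percent."""
        r3 = lambda v: round(v, 3) if not math.isnan(v) else UNDEFINED
        r1 = lambda v: round(v, 1) if not math.isnan(v) else UNDEFINED
        return {
            "method": self.method, "feature_selection": self.feature_selection,
            "MCC": r3(self.mcc), "ACC": r3(self.acc),
            "SENS": r1(self.sens_pct), "SPEC": r1(self.spec_pct),
            "PPV": r3(self.ppv), "NPV": r3(self.npv),
            "TP": self.cm.tp, "FN": self.cm.fn,
            "FP": self.cm.fp, "TN": self.cm.tn,
        }


def summary_metrics(cm: ConfusionMatrix, method: str = "",
                    feature_selection: str = "") -> MetricsRow:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return MetricsRow(method, feature_selection, cm)


# ---------------------------------------------------------------------
# pipeline plumbing shared by LOSO and transfer validation


@dataclass
class EvalPipeline:
    """What to train in each fold: a feature route and a classifier.

    ``feature_method`` is one of fit | pca | segments | combined |
    spectra (the last is PLS-DA's direct-on-spectra route).
    """

    classifier: str = "svm_rbf"
    feature_method: str = "combined"
    n_components: int = 30
    segment_length_nm: float = 20.0
    n_latent: int = 10
    svm_C: float = 1.0
    cart_min_leaf: int = 5
    random_state: int = 0
    #: standardise features before the classifier (always on for SVM)
    scale: bool | None = None

    def wants_fit_table(self) -> bool:
        return self.feature_method in ("fit", "combined")


def _build_features(pipeline: EvalPipeline, train_ds: SpectraDataset,
                    test_ds: SpectraDataset, fit_table: pd.DataFrame | None,
                    ) -> tuple[FeatureMatrix, FeatureMatrix]:
    X_train = train_ds.intensity_matrix()
    X_test = test_ds.intensity_matrix()
    ids_train = train_ds.location_ids()
    ids_test = test_ds.location_ids()
    method = pipeline.feature_method

    def fit_mats():
        if fit_table is None:
            raise ValueError("this pipeline needs a precomputed fit table")
        # keep rows aligned with the spectra so fit features can be
        # combined with PCA/segment features; non-converged fits are
        # carried through with a warning rather than dropped here
        from .features import FIT_FEATURE_NAMES

        def fm(ids):
            sub = fit_table.loc[ids]
            if "converged" in sub.columns:
                n_bad = int((~sub["converged"].astype(bool)).sum())
                if n_bad:
                    logger.warning("%d non-converged fit(s) in partition", n_bad)
            return FeatureMatrix(sub[FIT_FEATURE_NAMES].to_numpy(dtype=float),
                                 [f"fit_{n}" for n in FIT_FEATURE_NAMES],
                                 list(ids), "fit")

        return fm(ids_train), fm(ids_test)

    if method == "fit":
        return fit_mats()
    if method == "pca":
        return pca_features(X_train, X_test, ids_train, ids_test,
                            pipeline.n_components)
    if method == "segments":
        return segment_features(X_train, X_test, ids_train, ids_test,
                                pipeline.segment_length_nm, train_ds.grid)
    if method == "combined":
        f_tr, f_te = fit_mats()
        p_tr, p_te = pca_features(X_train, X_test, ids_train, ids_test,
                                  pipeline.n_components)
        s_tr, s_te = segment_features(X_train, X_test, ids_train, ids_test,
                                      pipeline.segment_length_nm, train_ds.grid)
        return combine_features(f_tr, p_tr, s_tr), combine_features(f_te, p_te, s_te)
    if method == "spectra":
        names = [f"w{int(w)}" for w in train_ds.grid.wavelengths]
        return (FeatureMatrix(X_train, names, ids_train, "combined"),
                FeatureMatrix(X_test, names, ids_test, "combined"))
    raise ValueError(f"unknown feature method {method!r}")


def _train_and_predict(pipeline: EvalPipeline, train_fm: FeatureMatrix,
                       test_fm: FeatureMatrix, y_train: np.ndarray,
                       ) -> tuple[np.ndarray, dict]:
    scale = pipeline.scale
    if scale is None:
        scale = pipeline.classifier == "svm_rbf"
    if scale:
        train_fm, test_fm = scale_features(train_fm, test_fm)
    if pipeline.classifier == "svm_rbf":
        clf = train_svm_rbf(train_fm.values, y_train, train_fm.feature_names,
                            C=pipeline.svm_C)
    elif pipeline.classifier == "plsda":
        clf = train_plsda(train_fm.values, y_train, train_fm.feature_names,
                          n_latent=pipeline.n_latent)
    elif pipeline.classifier == "cart":
        clf = train_cart(train_fm.values, y_train, train_fm.feature_names,
                         min_samples_leaf=pipeline.cart_min_leaf,
                         random_state=pipeline.random_state)
    else:
        raise ValueError(f"unknown classifier {pipeline.classifier!r}")
    y_pred = predict(clf, test_fm.values, test_fm.feature_names)
    return y_pred, train_fm.train_stats


@dataclass
class FoldRecord:
    """Per-fold log entry from LOSO."""

    held_out: str
    cm: ConfusionMatrix
    n_train: int
    n_test: int
    train_stats: dict = field(default_factory=dict, repr=False)


def loso_cv(dataset: SpectraDataset, pipeline: EvalPipeline,
            fit_table: pd.DataFrame | None = None,
            ) -> tuple[ConfusionMatrix, MetricsRow, list[FoldRecord]]:
    """Leave-one-specimen-out CV of the full pipeline.

    Every fold refits the feature transforms and the classifier on the
    retained specimens only; per-fold confusion matrices are summed and
    metrics computed on the summed matrix.
    """
    specimens = dataset.specimen_ids
    if len(specimens) < 2:
        raise ValueError("LOSO needs at least two specimens")
    total = ConfusionMatrix(0, 0, 0, 0)
    folds: list[FoldRecord] = []
    for sp in specimens:
        train_ds = dataset.subset(lambda s: s.specimen_id != sp)
        test_ds = dataset.subset(lambda s: s.specimen_id == sp)
        y_train = train_ds.labels()
        if len(np.unique(y_train)) < 2:
            raise ValueError(
                f"training partition single-class when holding out {sp!r}")
        train_fm, test_fm = _build_features(pipeline, train_ds, test_ds, fit_table)
        y_pred, stats = _train_and_predict(pipeline, train_fm, test_fm, y_train)
        cm = ConfusionMatrix.from_labels(test_ds.labels(), y_pred)
        total = total + cm
        folds.append(FoldRecord(sp, cm, len(train_ds), len(test_ds), stats))
        logger.info("fold %s: %s", sp, cm)
    row = summary_metrics(total, pipeline.classifier, pipeline.feature_method)
    return total, row, folds


def transfer_validate(train_dataset: SpectraDataset, test_dataset: SpectraDataset,
                      pipeline: EvalPipeline,
                      fit_table: pd.DataFrame | None = None) -> MetricsRow:
    """Single train on one area, single evaluation on the other."""
    overlap = set(train_dataset.location_ids()) & set(test_dataset.location_ids())
    if overlap:
        raise ValueError(f"train/test share location_ids: {sorted(overlap)[:5]}")
    y_train = train_dataset.labels()
    if len(np.unique(y_train)) < 2:
        raise ValueError("training area contains a single class")
    train_fm, test_fm = _build_features(pipeline, train_dataset, test_dataset,
                                        fit_table)
    y_pred, _ = _train_and_predict(pipeline, train_fm, test_fm, y_train)
    cm = ConfusionMatrix.from_labels(test_dataset.labels(), y_pred)
    return summary_metrics(cm, pipeline.classifier, pipeline.feature_method)


def report_tables(rows: list[MetricsRow]) -> pd.DataFrame:
    """Report with the canonical column set and rounding; one row per
    (classification method, feature selection)."""
    cols = ["method", "feature_selection", "MCC", "ACC", "SENS", "SPEC",
            "PPV", "NPV", "TP", "FN", "FP", "TN"]
    return pd.DataFrame([r.rounded() for r in rows], columns=cols)


def format_report(rows: list[MetricsRow]) -> str:
    return report_tables(rows).to_string(index=False)
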