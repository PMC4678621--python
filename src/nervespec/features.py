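"""Feature extraction: fit parameters, PCA scores, wavelength-segment
features, their combination, and training-statistics-based scaling.

Every transform computes its statistics (means, standard deviations,
principal axes, segment boundaries) on the TRAINING partition only and
applies the frozen transform to held-out spectra — the grouped
cross-validation in :mod:`nervespec.evaluation` relies on this to be
leakage-free.

Segment features: each spectrum is first normalised to unit mean
intensity (removing calibration-amplitude fluctuations), then each
wavelength is z-scored against the training set, and the z-scores are
summed within contiguous wavelength segments (default 20 nm). A segment
score is strongly positive where a spectrum runs above the average
spectrum over that band, strongly negative below it, and near zero
where it behaves averagely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .grid import DEFAULT_GRID, WavelengthGrid
from .optics import TissueOpticalParams

logger = logging.getLogger(__name__)

FEATURE_METHODS = ("fit", "pca", "segments", "combined")


@dataclass
class FeatureMatrix:
    """Per-spectrum feature vectors plus the training statistics that
    produced them (so new spectra can be transformed identically)."""

    values: np.ndarray
    feature_names: list[str]
    location_ids: list[str]
    method: str
    train_stats: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.size and self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length does not match matrix width")
        if self.values.shape[0] != len(self.location_ids):
            raise ValueError("location_ids length does not match row count")
        if self.method not in FEATURE_METHODS:
            raise ValueError(f"unknown feature method {self.method!r}")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names,
                          index=self.location_ids)
        df.index.name = "location_id"
        return df


#: canonical order of the 12 fit-parameter features
FIT_FEATURE_NAMES = list(TissueOpticalParams.names())


def fit_features(fit_table: pd.DataFrame) -> FeatureMatrix:
    """Use the 12 fitted parameters directly as features.

    Rows whose fit did not converge are excluded (and logged); the
    caller decides how to handle the missing locations.
    """
    keep = fit_table
    if "converged" in fit_table.columns:
        bad = ~fit_table["converged"].astype(bool)
        if bad.any():
            logger.warning("excluding %d non-converged fits from features",
                           int(bad.sum()))
            keep = fit_table[~bad]
    return FeatureMatrix(
        values=keep[FIT_FEATURE_NAMES].to_numpy(dtype=float),
        feature_names=[f"fit_{n}" for n in FIT_FEATURE_NAMES],
        location_ids=[str(i) for i in keep.index],
        method="fit",
    )


def pca_features(train_spectra: np.ndarray, apply_spectra: np.ndarray,
                 train_ids: list[str], apply_ids: list[str],
                 n_components: int = 30) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Project spectra onto principal axes of the mean-centred TRAINING set.

    Standard PCA on raw calibrated spectra; axes ordered by explained
    variance. Returns (train, apply) feature matrices sharing one set of
    training statistics.
    """
    train_spectra = np.atleast_2d(train_spectra)
    apply_spectra = np.atleast_2d(apply_spectra)
    if n_components > min(train_spectra.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_train, n_wavelengths)")
    pca = PCA(n_components=n_components, svd_solver="full")
    train_scores = pca.fit_transform(train_spectra)
    apply_scores = pca.transform(apply_spectra)
    names = [f"pca_{i + 1}" for i in range(n_components)]
    stats = {"mean": pca.mean_, "components": pca.components_,
             "explained_variance": pca.explained_variance_}
    return (
        FeatureMatrix(train_scores, names, list(train_ids), "pca", stats),
        FeatureMatrix(apply_scores, names, list(apply_ids), "pca", stats),
    )


def _segment_slices(n_points: int, seg_points: int) -> list[slice]:
    """Contiguous segments; the tail remainder joins the last segment."""
    n_seg = n_points // seg_points
    if n_seg < 2:
        raise ValueError("segment length leaves fewer than two segments")
    bounds = [i * seg_points for i in range(n_seg)] + [n_points]
    return [slice(bounds[i], bounds[i + 1]) for i in range(n_seg)]


def segment_features(train_spectra: np.ndarray, apply_spectra: np.ndarray,
                     train_ids: list[str], apply_ids: list[str],
                     segment_length_nm: float = 20.0,
                     grid: WavelengthGrid = DEFAULT_GRID,
                     ) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Wavelength-segment features (see module docstring).

    With 20 nm segments on the 1311-point 1 nm grid this yields 65
    segments, the last one absorbing the 11 leftover points.
    """
    seg_points = int(round(segment_length_nm / grid.step))
    slices = _segment_slices(grid.n_points, seg_points)

    def normalise(X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        means = X.mean(axis=1, keepdims=True)
        if np.any(means <= 0):
            raise ValueError("cannot normalise a spectrum with non-positive mean")
        return X / means

    train_n = normalise(train_spectra)
    apply_n = normalise(apply_spectra)
    mu = train_n.mean(axis=0)
    sd = train_n.std(axis=0, ddof=0)
    zero_sd = sd == 0
    if np.any(zero_sd):
        logger.warning("zero training sd at %d wavelengths; z-scores set to 0",
                       int(zero_sd.sum()))
    safe_sd = np.where(zero_sd, 1.0, sd)

    def transform(Xn):
        z = (Xn - mu) / safe_sd
        z[:, zero_sd] = 0.0
        return np.column_stack([z[:, s].sum(axis=1) for s in slices])

    wl = grid.wavelengths
    names = [f"seg_{wl[s.start]:.0f}_{wl[s.stop - 1]:.0f}" for s in slices]
    stats = {"mean": mu, "sd": sd, "segment_slices": slices,
             "segment_length_nm": segment_length_nm}
    return (
        FeatureMatrix(transform(train_n), names, list(train_ids), "segments", stats),
        FeatureMatrix(transform(apply_n), names, list(apply_ids), "segments", stats),
    )


def combine_features(*matrices: FeatureMatrix) -> FeatureMatrix:
    """Horizontal concatenation; rows must be the same locations in the
    same order. Method-prefixed names are preserved."""
    mats = [m for m in matrices if m.n_features > 0]
    if not mats:
        raise ValueError("nothing to combine")
    ids = mats[0].location_ids
    for m in mats[1:]:
        if m.location_ids != ids:
            raise ValueError("feature matrices cover different spectra or order")
    return FeatureMatrix(
        values=np.hstack([m.values for m in mats]),
        feature_names=[n for m in mats for n in m.feature_names],
        location_ids=list(ids),
        method="combined",
        train_stats={m.method: m.train_stats for m in mats},
    )


def scale_features(train_fm: FeatureMatrix, apply_fm: FeatureMatrix,
                   ) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Standardise each feature to zero mean / unit sd using TRAINING
    statistics; zero-variance features map to 0 (logged)."""
    if train_fm.feature_names != apply_fm.feature_names:
        raise ValueError("train/apply feature names differ")
    mu = train_fm.values.mean(axis=0)
    sd = train_fm.values.std(axis=0, ddof=0)
    zero = sd == 0
    if np.any(zero):
        logger.warning("constant training feature(s): %s",
                       [train_fm.feature_names[i] for i in np.flatnonzero(zero)])
    safe = np.where(zero, 1.0, sd)

    def tr(fm: FeatureMatrix) -> FeatureMatrix:
        z = (fm.values - mu) / safe
        z[:, zero] = 0.0
        stats = dict(fm.train_stats)
        stats["scale_mean"] = mu
        stats["scale_sd"] = sd
        return FeatureMatrix(z, list(fm.feature_names), list(fm.location_ids),
                             fm.method, stats)

    return tr(train_fm), tr(apply_fm)
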