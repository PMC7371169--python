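"""Window-level feature extraction.

The default registry maps each 9-channel window to 54 named features:

* per channel (9): mean, standard deviation, minimum, maximum, RMS — 45;
* pairwise Pearson correlations within the accelerometer triplet and
  within the gyroscope triplet — 6;
* signal magnitude area of the acceleration — 1;
* dominant periodogram frequency of the acceleration magnitude and its
  power — 2.

The registry is pluggable: a :class:`FeatureConfig` carries an ordered
tuple of extractor callables, each returning an ordered name→value dict, so
an alternative feature space can be dropped in without touching any other
stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from .errors import EmptyDatasetError, ValidationError
from .ethogram import sorted_classes
from .segmentation import Window

logger = logging.getLogger(__name__)

Extractor = Callable[[np.ndarray, tuple[str, ...], float], dict[str, float]]

_ACC = slice(0, 3)
_GYR = slice(3, 6)


def channel_stats(samples, channels, rate) -> dict[str, float]:
    out: dict[str, float] = {}
    for j, name in enumerate(channels):
        x = samples[:, j]
        out[f"{name}_mean"] = float(np.mean(x))
        out[f"{name}_sd"] = float(np.std(x))
        out[f"{name}_min"] = float(np.min(x))
        out[f"{name}_max"] = float(np.max(x))
        out[f"{name}_rms"] = float(np.sqrt(np.mean(x * x)))
    return out


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    # zero-variance channels get correlation 0 by convention, not NaN
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        logger.debug("zero-variance channel in correlation; reporting 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def axis_correlations(samples, channels, rate) -> dict[str, float]:
    out: dict[str, float] = {}
    for block in (_ACC, _GYR):
        names = channels[block]
        x = samples[:, block]
        for i in range(3):
            for j in range(i + 1, 3):
                out[f"corr_{names[i]}_{names[j]}"] = _safe_corr(x[:, i], x[:, j])
    return out


def signal_magnitude_area(samples, channels, rate) -> dict[str, float]:
    return {"sma": float(np.mean(np.sum(np.abs(samples[:, _ACC]), axis=1)))}


def dominant_frequency(samples, channels, rate) -> dict[str, float]:
    """Dominant non-DC periodogram peak of the acceleration magnitude."""
    mag = np.linalg.norm(samples[:, _ACC], axis=1)
    freqs, power = periodogram(mag - np.mean(mag), fs=rate)
    freqs, power = freqs[1:], power[1:]  # drop DC
    k = int(np.argmax(power))
    return {"accmag_domfreq": float(freqs[k]),
            "accmag_dompower": float(power[k])}


DEFAULT_EXTRACTORS: tuple[Extractor, ...] = (
    channel_stats,
    axis_correlations,
    signal_magnitude_area,
    dominant_frequency,
)


@dataclass(frozen=True)
class FeatureConfig:
    extractors: tuple[Extractor, ...] = DEFAULT_EXTRACTORS


def extract_features(window: Window,
                     config: FeatureConfig = FeatureConfig(),
                     expected_samples: int | None = None
                     ) -> tuple[list[str], np.ndarray]:
    """Feature names and values for one window. Deterministic."""
    if expected_samples is not None \
            and window.samples.shape[0] != expected_samples:
        raise ValidationError(
            f"window has {window.samples.shape[0]} samples, "
            f"expected {expected_samples}"
        )
    if window.samples.shape[0] < 2:
        raise ValidationError("window too short for feature extraction")
    names: list[str] = []
    values: list[float] = []
    for extractor in config.extractors:
        d = extractor(window.samples, window.channels, _window_rate(window))
        for k, v in d.items():
            if k in names:
                raise ValidationError(f"duplicate feature name {k!r}")
            names.append(k)
            values.append(v)
    vec = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(vec)):
        raise ValidationError("non-finite feature value produced")
    return names, vec


def _window_rate(window: Window) -> float:
    return getattr(window, "sampling_rate", 50.0)


@dataclass
class FeatureDataset:
    """Feature matrix with per-row label, individual and group annotations."""

    X: np.ndarray                    # (n, p)
    feature_names: tuple[str, ...]
    y: np.ndarray                    # (n,) behaviour labels
    individual_id: np.ndarray        # (n,)
    group_id: np.ndarray             # (n,)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        self.individual_id = np.asarray(self.individual_id, dtype=object)
        self.group_id = np.asarray(self.group_id, dtype=object)
        n = self.X.shape[0]
        if not (len(self.y) == len(self.individual_id)
                == len(self.group_id) == n):
            raise ValidationError("row counts of X/y/individual/group differ")
        if self.X.shape[1] != len(self.feature_names):
            raise ValidationError("feature_names length != number of columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValidationError("feature names must be unique")
        if n and not np.all(np.isfinite(self.X)):
            raise ValidationError("feature matrix contains non-finite values")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def classes(self) -> tuple[str, ...]:
        return sorted_classes(self.y)

    @property
    def individuals(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.individual_id)))

    def subset(self, indices) -> "FeatureDataset":
        idx = np.asarray(indices)
        return FeatureDataset(self.X[idx], self.feature_names, self.y[idx],
                              self.individual_id[idx], self.group_id[idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df["behaviour"] = self.y
        df["individual_id"] = self.individual_id
        df["group_id"] = self.group_id
        return df


def concat_datasets(datasets) -> FeatureDataset:
    datasets = list(datasets)
    if not datasets:
        raise EmptyDatasetError("no datasets to concatenate")
    names = datasets[0].feature_names
    for d in datasets[1:]:
        if d.feature_names != names:
            raise ValidationError("feature names differ between datasets")
    return FeatureDataset(
        np.vstack([d.X for d in datasets]),
        names,
        np.concatenate([d.y for d in datasets]),
        np.concatenate([d.individual_id for d in datasets]),
        np.concatenate([d.group_id for d in datasets]),
    )


def build_feature_dataset(windows,
                          config: FeatureConfig = FeatureConfig()
                          ) -> FeatureDataset:
    """Extract features for every window, in canonical row order.

    Rows are sorted by (individual_id, start time) so the matrix is
    invariant to the input ordering of windows.
    """
    windows = sorted(windows, key=lambda w: (w.individual_id, w.start_s))
    if not windows:
        raise EmptyDatasetError("no windows to featurize")
    shapes = {w.samples.shape for w in windows}
    if len(shapes) > 1:
        raise ValidationError(f"inconsistent window shapes: {shapes}")
    names0, first = extract_features(windows[0], config)
    X = np.empty((len(windows), len(first)))
    X[0] = first
    for i, w in enumerate(windows[1:], start=1):
        _, X[i] = extract_features(w, config)
    return FeatureDataset(
        X,
        tuple(names0),
        np.array([w.behaviour for w in windows], dtype=object),
        np.array([w.individual_id for w in windows], dtype=object),
        np.array([w.group_id for w in windows], dtype=object),
    )


@dataclass(frozen=True)
class Scaler:
    """Per-feature standardization parameters (fit on training rows only)."""

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def fit_scaler(X: np.ndarray) -> Scaler:
    mean = np.mean(X, axis=0)
    sd = np.std(X, axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)  # constant features pass through
    return Scaler(mean, sd)
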