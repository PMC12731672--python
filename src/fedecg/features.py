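"""Canonical fiducial-feature data model.

Every record in this package is one heartbeat described by nine scalar
fiducial features of the P-QRS-T cycle plus a three-way diagnostic label
(arrhythmic / healthy / ischemic).  The feature registry below fixes the
column order used everywhere: in CSV files, in the ``(n, 9)`` matrices the
classifiers consume, and in the length-9 sequences fed to the LSTM.

Units: HR in beats/min; R-H, P-H and ST in mV (ST is the segment *level*
relative to the isoelectric line, so it may be negative); PRQ, QT, QTC,
RR-I and QRS in ms.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical feature order. Immutable; identical across the whole package.
FEATURE_NAMES: tuple[str, ...] = (
    "HR", "R-H", "P-H", "PRQ", "QT", "QTC", "RR-I", "QRS", "ST",
)
N_FEATURES = len(FEATURE_NAMES)

#: Class code registry: arrhythmic -> 0, healthy -> 1, ischemic -> 2.
CLASS_NAMES: tuple[str, ...] = ("arrhythmic", "healthy", "ischemic")
CLASS_TO_CODE: dict[str, int] = {name: i for i, name in enumerate(CLASS_NAMES)}
N_CLASSES = len(CLASS_NAMES)

#: Features that must be strictly positive for a record to be valid.
_POSITIVE_FEATURES = ("HR", "PRQ", "QT", "QTC", "RR-I", "QRS")

CSV_HEADER = ("subject_id", "label") + FEATURE_NAMES


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class LabelError(ValueError):
    """A label string is not one of the three recognised classes."""


@dataclass
class FeatureMatrix:
    """Labelled fiducial-feature table: an ``(n, 9)`` float matrix in
    canonical column order plus integer class codes and optional subject ids.
    """

    values: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray | None = None
    feature_names: tuple[str, ...] = field(default=FEATURE_NAMES)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1, N_FEATURES)
        self.labels = np.asarray(self.labels, dtype=int).reshape(-1)
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"values has {self.values.shape[0]} rows but labels has "
                f"{self.labels.shape[0]} entries"
            )
        if tuple(self.feature_names) != FEATURE_NAMES:
            raise SchemaError(f"feature order must be {FEATURE_NAMES}")
        if self.subject_ids is not None:
            self.subject_ids = np.asarray(self.subject_ids)
            if self.subject_ids.shape[0] != self.n:
                raise ValueError("subject_ids length mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def __len__(self) -> int:
        return self.n

    def class_counts(self) -> np.ndarray:
        """Records per class code, length 3."""
        return np.bincount(self.labels, minlength=N_CLASSES)

    def class_proportions(self) -> np.ndarray:
        c = self.class_counts()
        return c / c.sum() if c.sum() else c.astype(float)

    def take(self, idx: np.ndarray) -> "FeatureMatrix":
        """Row subset (copy), preserving subject ids."""
        idx = np.asarray(idx)
        return FeatureMatrix(
            self.values[idx].copy(),
            self.labels[idx].copy(),
            None if self.subject_ids is None else self.subject_ids[idx].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(FEATURE_NAMES))
        df.insert(0, "label", [CLASS_NAMES[c] for c in self.labels])
        sid = self.subject_ids
        df.insert(0, "subject_id", sid if sid is not None else [""] * self.n)
        return df

    @staticmethod
    def concat(parts: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        parts = list(parts)
        if not parts:
            return FeatureMatrix(np.empty((0, N_FEATURES)), np.empty(0, dtype=int))
        have_sid = all(p.subject_ids is not None for p in parts)
        return FeatureMatrix(
            np.concatenate([p.values for p in parts]),
            np.concatenate([p.labels for p in parts]),
            np.concatenate([p.subject_ids for p in parts]) if have_sid else None,
        )


def _normalize_label(raw: object, row: int) -> int:
    s = str(raw).strip().casefold()
    if s not in CLASS_TO_CODE:
        raise LabelError(
            f"row {row}: unknown label {raw!r}; expected one of {CLASS_NAMES} "
            "(case-insensitive)"
        )
    return CLASS_TO_CODE[s]


def read_fiducial_csv(path) -> FeatureMatrix:
    """Read a fiducial-feature CSV into a :class:`FeatureMatrix`.

    The reader accepts any column order, matches feature names
    case-insensitively, ignores unknown columns with a warning, and
    case-folds label strings.  A missing feature or label column raises
    :class:`SchemaError`; an unrecognised label raises :class:`LabelError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap: dict[str, str] = {}
    canon = {name.casefold(): name for name in FEATURE_NAMES}
    label_col = None
    subject_col = None
    for col in df.columns:
        key = col.strip().casefold()
        if key in canon:
            colmap[canon[key]] = col
        elif key == "label":
            label_col = col
        elif key == "subject_id":
            subject_col = col
        else:
            logger.warning("read_fiducial_csv: ignoring unknown column %r", col)
    missing = [f for f in FEATURE_NAMES if f not in colmap]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if label_col is None:
        raise SchemaError("missing required column(s): label")

    values = np.empty((len(df), N_FEATURES), dtype=float)
    for j, name in enumerate(FEATURE_NAMES):
        raw = df[colmap[name]].to_numpy()
        for i, cell in enumerate(raw):
            try:
                values[i, j] = float(cell) if cell != "" else np.nan
            except ValueError:
                raise ValueError(
                    f"row {i}: cannot parse {cell!r} in column {name!r} as a number"
                ) from None
    labels = np.array(
        [_normalize_label(v, i) for i, v in enumerate(df[label_col].to_numpy())],
        dtype=int,
    )
    subject_ids = df[subject_col].to_numpy() if subject_col is not None else None
    return FeatureMatrix(values, labels, subject_ids)


def write_fiducial_csv(data: FeatureMatrix, path) -> None:
    """Write the canonical CSV (header ``subject_id,label,HR,...,ST``), with
    full float precision so a read-back is value-exact."""
    df = data.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")


#: Rejection reasons, checked in order; a bad row is counted under the first
#: rule it violates.
REJECTION_RULES = ("non-finite value", "non-positive hr", "non-positive interval")


def validate_records(data: FeatureMatrix) -> tuple[FeatureMatrix, dict[str, int]]:
    """Filter out rows violating the record invariants.

    Mirrors beat-level cleaning of premature/missing/ectopic beats, applied at
    the feature-row level: rows with non-finite values or non-positive
    rate/interval features are excluded.  Never raises on bad rows; returns
    the clean subset and a count of rejections by first violated rule.
    """
    v = data.values
    finite = np.isfinite(v).all(axis=1)
    hr_ok = v[:, FEATURE_NAMES.index("HR")] > 0
    interval_ok = np.ones(data.n, dtype=bool)
    for name in _POSITIVE_FEATURES[1:]:
        interval_ok &= v[:, FEATURE_NAMES.index(name)] > 0
    # first-violated-rule attribution
    reject_finite = ~finite
    reject_hr = finite & ~hr_ok
    reject_interval = finite & hr_ok & ~interval_ok
    keep = finite & hr_ok & interval_ok
    report = {
        REJECTION_RULES[0]: int(reject_finite.sum()),
        REJECTION_RULES[1]: int(reject_hr.sum()),
        REJECTION_RULES[2]: int(reject_interval.sum()),
    }
    return data.take(np.flatnonzero(keep)), report


class FeatureScaler:
    """Per-feature z-score scaler (location/scale), sklearn-transformer style.

    Constant columns get scale 1 (with a warning) so they map to zero rather
    than dividing by zero.  The fitted state is two length-9 vectors, making
    the scaler cheap to serialise and to average across federated clients.
    """

    def fit(self, data: FeatureMatrix | np.ndarray) -> "FeatureScaler":
        X = data.values if isinstance(data, FeatureMatrix) else np.asarray(data, float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to fit a scaler")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        if np.any(sd == 0):
            warnings.warn("constant feature column(s); using scale 1", stacklevel=2)
        self.scale_ = np.where(sd == 0, 1.0, sd)
        self.n_samples_seen_ = X.shape[0]
        return self

    def transform(self, data: FeatureMatrix | np.ndarray) -> np.ndarray:
        X = data.values if isinstance(data, FeatureMatrix) else np.asarray(data, float)
        return (X - self.mean_) / self.scale_

    def fit_transform(self, data) -> np.ndarray:
        return self.fit(data).transform(data)

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) * self.scale_ + self.mean_

    def to_dict(self) -> dict:
        return {"mean": self.mean_.tolist(), "scale": self.scale_.tolist(),
                "n_samples": int(self.n_samples_seen_)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureScaler":
        s = cls()
        s.mean_ = np.asarray(d["mean"], float)
        s.scale_ = np.asarray(d["scale"], float)
        s.n_samples_seen_ = int(d.get("n_samples", 0))
        return s


def average_scalers(scalers: Sequence[FeatureScaler],
                    sizes: Sequence[int] | None = None) -> FeatureScaler:
    """Size-weighted average of client scalers, used by the server to build
    an evaluation scaler without seeing raw client data."""
    scalers = list(scalers)
    if not scalers:
        raise ValueError("no scalers to average")
    w = np.ones(len(scalers)) if sizes is None else np.asarray(sizes, float)
    w = w / w.sum()
    out = FeatureScaler()
    out.mean_ = sum(wi * s.mean_ for wi, s in zip(w, scalers))
    out.scale_ = sum(wi * s.scale_ for wi, s in zip(w, scalers))
    out.n_samples_seen_ = int(sum(getattr(s, "n_samples_seen_", 0) for s in scalers))
    return out


def standardize_features(
    train: FeatureMatrix, apply_to: FeatureMatrix
) -> tuple[FeatureMatrix, FeatureScaler]:
    """Fit a z-score scaler on ``train`` and apply it to ``apply_to``.

    Returns the scaled copy of ``apply_to`` and the fitted scaler.
    """
    scaler = FeatureScaler().fit(train)
    scaled = FeatureMatrix(
        scaler.transform(apply_to), apply_to.labels.copy(),
        None if apply_to.subject_ids is None else apply_to.subject_ids.copy(),
    )
    return scaled, scaler
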