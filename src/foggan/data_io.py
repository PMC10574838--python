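"""Reading, preprocessing, splitting and scaling of Daphnet-style recordings.

The on-disk format is the plain-text layout of the Daphnet freezing-of-gait
corpus: one sample per line, eleven whitespace-separated numeric fields —
a millisecond time stamp, nine acceleration channels in milli-g (ankle,
thigh and trunk; horizontal-forward / vertical / horizontal-lateral each),
and an annotation in {0, 1, 2} (0 = outside the experiment, 1 = walk /
stand / turn, 2 = freeze).

Preprocessing follows the binary-classification convention for this
corpus: annotation-0 rows are dropped, freeze (2) becomes label 0 and
no-freeze (1) stays label 1.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CHANNEL_NAMES",
    "N_CHANNELS",
    "Recording",
    "RecordingCollection",
    "LabeledMatrix",
    "Scaler",
    "DaphnetParseError",
    "read_daphnet_file",
    "write_daphnet_file",
    "combine_recordings",
    "preprocess",
    "split_train_eval",
    "fit_scaler",
    "apply_scaler",
    "invert_scaler",
]

CHANNEL_NAMES = (
    "acc_ankle_hor",
    "acc_ankle_ver",
    "acc_ankle_lat",
    "acc_thigh_hor",
    "acc_thigh_ver",
    "acc_thigh_lat",
    "acc_trunk_hor",
    "acc_trunk_ver",
    "acc_trunk_lat",
)
N_CHANNELS = len(CHANNEL_NAMES)
VALID_ANNOTATIONS = (0, 1, 2)


class DaphnetParseError(ValueError):
    """A sensor file line that does not follow the 11-field numeric layout."""


@dataclass
class Recording:
    """One parsed sensor file: time stamps, 9 channels, annotations, a tag."""

    time: np.ndarray          # (n,) int milliseconds, strictly increasing
    channels: np.ndarray      # (n, 9) float milli-g
    annotation: np.ndarray    # (n,) int in {0, 1, 2}
    source_name: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=np.int64)
        self.channels = np.asarray(self.channels, dtype=float)
        self.annotation = np.asarray(self.annotation, dtype=np.int64)
        n = len(self.time)
        if self.channels.shape != (n, N_CHANNELS):
            raise ValueError(
                f"channels must have shape ({n}, {N_CHANNELS}), got {self.channels.shape}"
            )
        if self.annotation.shape != (n,):
            raise ValueError("annotation length must match time length")
        if not np.isin(self.annotation, VALID_ANNOTATIONS).all():
            bad = sorted(set(self.annotation) - set(VALID_ANNOTATIONS))
            raise ValueError(f"annotation values outside {{0,1,2}}: {bad}")
        if n > 1 and not (np.diff(self.time) > 0).all():
            raise ValueError(f"time stamps not strictly increasing in {self.source_name!r}")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class RecordingCollection:
    """Several recordings stacked row-wise, keeping a per-row source tag."""

    time: np.ndarray
    channels: np.ndarray
    annotation: np.ndarray
    source: np.ndarray        # (n,) str tag per row

    def __len__(self) -> int:
        return len(self.annotation)


def read_daphnet_file(path: str | os.PathLike) -> Recording:
    """Parse one Daphnet-format text file into a :class:`Recording`.

    Raises :class:`DaphnetParseError` naming the (1-based) line number on a
    malformed line, and ``ValueError`` on annotations outside {0,1,2}.
    An empty file yields an empty recording.
    """
    with open(path, "r") as fh:
        raw_lines = fh.read().splitlines()
    rows = []
    for lineno, line in enumerate(raw_lines, start=1):
        tokens = line.split()
        if not tokens:
            continue
        if len(tokens) != 11:
            raise DaphnetParseError(
                f"{path}: line {lineno}: expected 11 fields, got {len(tokens)}"
            )
        try:
            rows.append([float(t) for t in tokens])
        except ValueError as exc:
            raise DaphnetParseError(f"{path}: line {lineno}: non-numeric field ({exc})")
    name = os.path.basename(os.fspath(path))
    if not rows:
        return Recording(
            time=np.empty(0, dtype=np.int64),
            channels=np.empty((0, N_CHANNELS)),
            annotation=np.empty(0, dtype=np.int64),
            source_name=name,
        )
    arr = np.asarray(rows, dtype=float)
    ann = arr[:, 10]
    if not np.isin(ann, VALID_ANNOTATIONS).all():
        bad_line = int(np.flatnonzero(~np.isin(ann, VALID_ANNOTATIONS))[0])
        raise ValueError(
            f"{path}: annotation outside {{0,1,2}} (first offending data row {bad_line + 1})"
        )
    return Recording(
        time=arr[:, 0].astype(np.int64),
        channels=arr[:, 1:10],
        annotation=ann.astype(np.int64),
        source_name=name,
    )


def write_daphnet_file(recording: Recording, path: str | os.PathLike) -> None:
    """Write a recording in the same 11-field text layout the reader accepts."""
    with open(path, "w") as fh:
        for t, ch, a in zip(recording.time, recording.channels, recording.annotation):
            fields = " ".join(f"{v:.6g}" for v in ch)
            fh.write(f"{int(t)} {fields} {int(a)}\n")


def combine_recordings(recordings: Sequence[Recording]) -> RecordingCollection:
    """Stack recordings into one collection with per-row source tags."""
    if not recordings:
        raise ValueError("cannot combine an empty list of recordings")
    time = np.concatenate([r.time for r in recordings])
    channels = np.vstack([r.channels for r in recordings])
    annotation = np.concatenate([r.annotation for r in recordings])
    source = np.concatenate(
        [np.full(len(r), r.source_name, dtype=object) for r in recordings]
    )
    return RecordingCollection(time, channels, annotation, source)


# ---------------------------------------------------------------------------
# Labeled matrices, preprocessing
# ---------------------------------------------------------------------------

LABEL_FREEZE = 0
LABEL_NO_FREEZE = 1


@dataclass
class Scaler:
    """Per-feature standardizer (location/scale); constant features keep scale 1."""

    mean_: np.ndarray | None = None
    scale_: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.mean_ is not None

    def fit(self, X: np.ndarray) -> "Scaler":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        std = X.std(axis=0)
        self.scale_ = np.where(std == 0.0, 1.0, std)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise ValueError("scaler has not been fitted")
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise ValueError("scaler has not been fitted")
        return np.asarray(X, dtype=float) * self.scale_ + self.mean_


@dataclass
class LabeledMatrix:
    """N x k feature matrix with binary labels (0 = freeze, 1 = no-freeze)."""

    X: np.ndarray
    y: np.ndarray
    scaled: bool = False
    scaler_state: Scaler | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.y) != len(self.X):
            raise ValueError("X and y must have equal length")
        if len(self.y) and not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary {0, 1}")
        if self.scaled and self.scaler_state is None:
            raise ValueError("a scaled matrix must carry its scaler state")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_csv(self, path: str | os.PathLike) -> None:
        cols = [f"f{i + 1}" for i in range(self.n_features)]
        df = pd.DataFrame(self.X, columns=cols)
        df["label"] = self.y
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "LabeledMatrix":
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ValueError(f"{path}: missing 'label' column")
        y = df.pop("label").to_numpy()
        return cls(X=df.to_numpy(dtype=float), y=y)


def preprocess(data: Recording | RecordingCollection) -> LabeledMatrix:
    """Drop annotation-0 rows and binarize: freeze (2) -> 0, no-freeze (1) -> 1.

    Time and source columns are discarded; raises if no rows survive, since
    nothing downstream can train on an empty matrix.
    """
    keep = data.annotation != 0
    if not keep.any():
        raise ValueError("preprocessing removed every row (all annotations were 0)")
    ann = data.annotation[keep]
    y = np.where(ann == 2, LABEL_FREEZE, LABEL_NO_FREEZE)
    return LabeledMatrix(X=data.channels[keep], y=y, scaled=False)


def split_train_eval(
    m: LabeledMatrix, train_fraction: float, seed: int
) -> tuple[LabeledMatrix, LabeledMatrix]:
    """Seeded uniform row split; train gets ``floor(train_fraction * N)`` rows."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = len(m)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    n_train = int(np.floor(train_fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    tr, ev = perm[:n_train], perm[n_train:]
    return (
        LabeledMatrix(m.X[tr], m.y[tr], m.scaled, m.scaler_state),
        LabeledMatrix(m.X[ev], m.y[ev], m.scaled, m.scaler_state),
    )


def fit_scaler(train: LabeledMatrix) -> Scaler:
    """Fit a per-feature standardizer on the training split only."""
    return Scaler().fit(train.X)


def apply_scaler(m: LabeledMatrix, s: Scaler) -> LabeledMatrix:
    return LabeledMatrix(s.transform(m.X), m.y, scaled=True, scaler_state=s)


def invert_scaler(m: LabeledMatrix, s: Scaler) -> LabeledMatrix:
    return LabeledMatrix(s.inverse_transform(m.X), m.y, scaled=False, scaler_state=None)
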