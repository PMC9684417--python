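"""Signal and annotation containers plus plain-text interchange formats.

The canonical on-disk formats are deliberately simple and text-based:

* **Signal CSV** — UTF-8, ``#``-prefixed metadata lines (``# fs=<Hz>``),
  a header row of channel labels, then one row per sample with one
  column per channel, stored at full ``repr`` precision.
* **Annotation text** — ``#``-prefixed metadata (``# fs=<Hz>``,
  ``# label=<label>``), then one 0-based integer sample index per line.

Sample indexing is 0-based everywhere and windows are half-open
``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SignalRecord",
    "AnnotationSet",
    "ANNOTATION_LABELS",
    "read_signal_csv",
    "write_signal_csv",
    "read_annotations",
    "write_annotations",
    "read_wfdb",
]

ANNOTATION_LABELS = ("maternal_ref", "fetal_ref", "maternal_det", "fetal_det")


class FormatError(ValueError):
    """Raised when an on-disk file cannot be parsed."""


@dataclass(frozen=True)
class SignalRecord:
    """A multichannel uniformly-sampled signal.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)``; amplitudes in
        arbitrary (but shared) units.
    fs
        Sampling rate in Hz.
    channel_labels
        One label per channel.
    record_id
        Free-form identifier.
    """

    samples: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = ()
    record_id: str = ""

    def __post_init__(self) -> None:
        samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 2 or samples.shape[0] < 1 or samples.shape[1] < 1:
            raise ValueError("samples must be a non-empty (channels, time) matrix")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        labels = tuple(self.channel_labels)
        if not labels:
            labels = tuple(f"ch{i + 1}" for i in range(samples.shape[0]))
        if len(labels) != samples.shape[0]:
            raise ValueError(
                f"{len(labels)} labels for {samples.shape[0]} channels"
            )
        object.__setattr__(self, "channel_labels", labels)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, index: int) -> "SignalRecord":
        """Single-channel view of channel ``index``."""
        return SignalRecord(
            self.samples[index : index + 1],
            self.fs,
            (self.channel_labels[index],),
            self.record_id,
        )

    def with_samples(self, samples: np.ndarray) -> "SignalRecord":
        return replace(self, samples=samples)


@dataclass(frozen=True)
class AnnotationSet:
    """Sorted R-peak sample positions (0-based) with a source label."""

    indices: np.ndarray
    fs: float
    label: str = "fetal_ref"

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64).ravel()
        idx = np.unique(idx)  # sorts and deduplicates
        if idx.size and idx[0] < 0:
            raise ValueError("annotation indices must be non-negative")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.label not in ANNOTATION_LABELS:
            raise ValueError(
                f"label must be one of {ANNOTATION_LABELS}, got {self.label!r}"
            )
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.size)

    def times_s(self) -> np.ndarray:
        """Annotation positions in seconds."""
        return self.indices / self.fs

    def validate_against(self, record: SignalRecord) -> None:
        if len(self) and (self.indices[-1] >= record.n_samples):
            raise ValueError(
                f"annotation index {self.indices[-1]} outside record of "
                f"{record.n_samples} samples"
            )


def _parse_meta(path: Path) -> tuple[dict[str, str], int]:
    """Read leading ``# key=value`` comment lines; return (meta, n_skip)."""
    meta: dict[str, str] = {}
    n_skip = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_skip += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta, n_skip


def read_signal_csv(path: str | Path, fs: float | None = None) -> SignalRecord:
    """Read a signal CSV.

    ``fs`` is taken from a ``# fs=<Hz>`` comment line; if the file has no
    such line the ``fs`` argument is required.
    """
    path = Path(path)
    meta, n_skip = _parse_meta(path)
    if "fs" in meta:
        fs_value = float(meta["fs"])
    elif fs is not None:
        fs_value = float(fs)
    else:
        raise FormatError(
            f"{path}: no '# fs=' metadata line and no fs override given"
        )
    try:
        frame = pd.read_csv(path, skiprows=n_skip, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows
        raise FormatError(f"{path}: malformed CSV body: {exc}") from exc
    if frame.shape[1] < 1 or frame.shape[0] < 1:
        raise FormatError(f"{path}: empty signal body")
    for col in frame.columns:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: non-numeric value in column {col!r}, data row {row}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise FormatError(f"{path}: missing value in column {col!r}, data row {row}")
        frame[col] = numeric
    return SignalRecord(
        frame.to_numpy(dtype=float).T,
        fs_value,
        tuple(str(c) for c in frame.columns),
        record_id=path.stem,
    )


def write_signal_csv(record: SignalRecord, path: str | Path) -> Path:
    """Write ``record`` as a signal CSV (full float precision); returns the path."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fs={record.fs!r}\n")
        fh.write(",".join(record.channel_labels) + "\n")
        for row in record.samples.T:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")
    return path


def read_annotations(path: str | Path, fs: float | None = None,
                     label: str | None = None) -> AnnotationSet:
    """Read an annotation text file (one 0-based integer index per line)."""
    path = Path(path)
    meta, _ = _parse_meta(path)
    fs_value = float(meta["fs"]) if "fs" in meta else fs
    if fs_value is None:
        raise FormatError(f"{path}: no '# fs=' metadata line and no fs override")
    label_value = label or meta.get("label", "fetal_ref")
    indices: list[int] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.strip()
            if not body or body.startswith("#"):
                continue
            try:
                value = int(body)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer annotation {body!r}"
                ) from exc
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative index {value}")
            indices.append(value)
    return AnnotationSet(np.array(indices, dtype=np.int64), fs_value, label_value)


def write_annotations(ann: AnnotationSet, path: str | Path) -> Path:
    """Write ``ann`` as an annotation text file; returns the path."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fs={ann.fs!r}\n")
        fh.write(f"# label={ann.label}\n")
        for idx in ann.indices:
            fh.write(f"{int(idx)}\n")
    return path


def read_wfdb(record_path: str | Path, annotation_ext: str | None = None,
              annotation_label: str = "fetal_ref") -> tuple[
                  SignalRecord, AnnotationSet | None]:
    """Optional loader for WFDB-style records (PhysioNet layout).

    Requires the third-party ``wfdb`` package; it is an optional extra and
    never needed for building or testing this package — CSV is the
    canonical interchange format.
    """
    try:
        import wfdb  # type: ignore[import-not-found]
    except ImportError as exc:  # pragma: no cover - exercised only with extra
        raise ImportError(
            "WFDB loading requires the optional 'wfdb' package "
            "(pip install fecg-sagwo[wfdb])"
        ) from exc
    record_path = Path(record_path)
    rec = wfdb.rdrecord(str(record_path))  # pragma: no cover
    signal = SignalRecord(  # pragma: no cover
        rec.p_signal.T, float(rec.fs),
        tuple(rec.sig_name), record_id=record_path.stem,
    )
    ann = None
    if annotation_ext is not None:  # pragma: no cover
        wf_ann = wfdb.rdann(str(record_path), annotation_ext)
        ann = AnnotationSet(np.asarray(wf_ann.sample, dtype=np.int64),
                            float(rec.fs), annotation_label)
    return signal, ann  # pragma: no cover
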