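"""Labeled spectra container and CSV round-trip I/O.

A :class:`SpectraSet` holds one absorbance matrix on a shared wavenumber
grid together with per-sample labels and unique sample identifiers.  It is
the exchange object used by every downstream stage.

The only on-disk format is CSV with the header
``sample_id,label,<wn1>,<wn2>,...`` where the wavenumber column headers are
numeric and strictly increasing.  Values are written with Python's shortest
round-trip ``repr`` so that ``read(write(s)) == s`` bit-exactly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SpectraSet", "SpectraParseError", "read_spectra_csv", "write_spectra_csv"]


class SpectraParseError(ValueError):
    """Raised when a spectra CSV (or constructed set) violates the format."""


@dataclass
class SpectraSet:
    """Absorbance spectra on a common wavenumber grid.

    Parameters
    ----------
    wavenumbers
        Strictly increasing grid in cm^-1, shape ``(p,)``.
    absorbance
        Unitless absorbance matrix, shape ``(n, p)``; all entries finite.
    labels
        Per-sample categorical class (e.g. storage time ``"6h"``), length n.
    sample_ids
        Unique per-sample identifiers, length n.  Row order is meaningful
        and preserved by all I/O.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    labels: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.labels = np.asarray(self.labels, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self._validate()

    def _validate(self) -> None:
        if self.wavenumbers.ndim != 1:
            raise SpectraParseError("wavenumbers must be one-dimensional")
        n, p = self.absorbance.shape
        if p != self.wavenumbers.size:
            raise SpectraParseError(
                f"absorbance has {p} columns but there are "
                f"{self.wavenumbers.size} wavenumbers"
            )
        if self.labels.size != n or self.sample_ids.size != n:
            raise SpectraParseError(
                f"labels ({self.labels.size}) and sample_ids "
                f"({self.sample_ids.size}) must match {n} spectra"
            )
        if self.wavenumbers.size and np.any(np.diff(self.wavenumbers) <= 0):
            bad = int(np.argmax(np.diff(self.wavenumbers) <= 0))
            raise SpectraParseError(
                f"non-increasing wavenumbers at column {bad + 1}: "
                f"{self.wavenumbers[bad]} -> {self.wavenumbers[bad + 1]}"
            )
        if not np.all(np.isfinite(self.absorbance)):
            i, j = np.argwhere(~np.isfinite(self.absorbance))[0]
            raise SpectraParseError(
                f"non-finite absorbance for sample {self.sample_ids[i]!r} "
                f"at wavenumber {self.wavenumbers[j]}"
            )
        ids, counts = np.unique(self.sample_ids.astype(str), return_counts=True)
        if np.any(counts > 1):
            raise SpectraParseError(f"duplicate sample_id {ids[counts > 1][0]!r}")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.absorbance.shape[1]

    @property
    def classes(self) -> np.ndarray:
        """Sorted unique labels."""
        return np.unique(self.labels.astype(str))

    def select(self, index: np.ndarray) -> "SpectraSet":
        """Row subset (or reordering) by integer/boolean index."""
        return SpectraSet(
            wavenumbers=self.wavenumbers,
            absorbance=self.absorbance[index],
            labels=self.labels[index],
            sample_ids=self.sample_ids[index],
        )

    def with_absorbance(self, absorbance: np.ndarray) -> "SpectraSet":
        """Same metadata with a replaced absorbance matrix."""
        return SpectraSet(
            wavenumbers=self.wavenumbers,
            absorbance=absorbance,
            labels=self.labels,
            sample_ids=self.sample_ids,
        )

    def equals(self, other: "SpectraSet") -> bool:
        """Field-by-field exact equality."""
        return (
            np.array_equal(self.wavenumbers, other.wavenumbers)
            and np.array_equal(self.absorbance, other.absorbance)
            and np.array_equal(self.labels.astype(str), other.labels.astype(str))
            and np.array_equal(self.sample_ids.astype(str), other.sample_ids.astype(str))
        )


def read_spectra_csv(path) -> SpectraSet:
    """Read a ``sample_id,label,<wn>...`` CSV into a validated SpectraSet.

    Raises
    ------
    SpectraParseError
        On a malformed header, non-numeric cells, duplicate sample ids, or
        a non-increasing wavenumber grid; the message names the offending
        row or column.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(frame.columns)
    if len(cols) < 2 or cols[0] != "sample_id" or cols[1] != "label":
        raise SpectraParseError(
            f"header must start with 'sample_id,label', got {cols[:2]}"
        )
    try:
        wavenumbers = np.array([float(c) for c in cols[2:]], dtype=float)
    except ValueError as exc:
        raise SpectraParseError(f"non-numeric wavenumber header: {exc}") from None
    if frame.shape[0]:
        values = np.empty((frame.shape[0], wavenumbers.size), dtype=float)
        for j, col in enumerate(cols[2:]):
            try:
                values[:, j] = frame[col].to_numpy(dtype=float)
            except ValueError:
                for i, cell in enumerate(frame[col]):
                    try:
                        float(cell)
                    except ValueError:
                        raise SpectraParseError(
                            f"non-numeric cell {cell!r} at row {i + 2}, "
                            f"column {col!r}"
                        ) from None
                raise
    else:
        values = np.empty((0, wavenumbers.size), dtype=float)
    return SpectraSet(
        wavenumbers=wavenumbers,
        absorbance=values,
        labels=frame["label"].to_numpy(dtype=object),
        sample_ids=frame["sample_id"].to_numpy(dtype=object),
    )


def write_spectra_csv(data: SpectraSet, path) -> str:
    """Write a SpectraSet to CSV; deterministic bytes for identical input.

    All numeric values (wavenumber headers included) are printed with the
    shortest decimal representation that round-trips to the same float, so
    ``read_spectra_csv(write_spectra_csv(s)) == s`` exactly.
    """
    buf = io.StringIO()
    header = ["sample_id", "label"] + [repr(float(w)) for w in data.wavenumbers]
    buf.write(",".join(header) + "\n")
    for i in range(data.n_samples):
        row = [str(data.sample_ids[i]), str(data.labels[i])]
        row.extend(repr(float(v)) for v in data.absorbance[i])
        buf.write(",".join(row) + "\n")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())
    return str(path)
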