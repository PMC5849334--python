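"""Reading, validation and writing of 1D NMR spectra matrices.

A spectra matrix is a delimited text file whose header row holds the
chemical-shift (ppm) axis and whose subsequent rows hold one intensity
vector per sample, optionally preceded by a sample-id column.  Internally
the axis is always stored index-ascending / ppm-descending (the plotting
convention for 1H NMR); ascending input is flipped on read and the flip is
recorded.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np


class SpectraFormatError(ValueError):
    """Malformed spectra file (ragged rows, unparseable header, ...)."""


class SpectraValidationError(ValueError):
    """Structurally parseable input that violates a SpectraSet invariant."""


@dataclass
class SpectraSet:
    """A set of 1D NMR spectra sharing one chemical-shift axis.

    Attributes
    ----------
    ppm
        Chemical-shift axis, length P, strictly decreasing.
    intensities
        N x P real matrix, one spectrum per row.
    sample_ids
        N unique sample labels.
    response
        Optional length-N numeric response (class codes or a covariate).
    flipped
        True when the input axis was ascending and was reversed on read.
    """

    ppm: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]
    response: np.ndarray | None = None
    flipped: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.response is not None:
            self.response = np.asarray(self.response, dtype=float)

        d = np.diff(self.ppm)
        if self.ppm.size < 2 or not (np.all(d > 0) or np.all(d < 0)):
            raise SpectraValidationError("ppm axis must be strictly monotonic")
        if np.all(d > 0):  # ascending input: store ppm-descending
            self.ppm = self.ppm[::-1].copy()
            self.intensities = self.intensities[:, ::-1].copy()
            self.flipped = True
        n, p = self.intensities.shape
        if p != self.ppm.size:
            raise SpectraValidationError(
                f"intensity rows have {p} values but the axis has {self.ppm.size}"
            )
        if not np.all(np.isfinite(self.intensities)):
            bad = np.where(~np.isfinite(self.intensities).all(axis=1))[0][0]
            raise SpectraValidationError(
                f"non-finite intensity in sample {self.sample_ids[bad]!r}"
            )
        if len(self.sample_ids) != n:
            raise SpectraValidationError("sample_ids length does not match rows")
        if len(set(self.sample_ids)) != n:
            raise SpectraValidationError("duplicate sample ids")
        if self.response is not None and self.response.size != n:
            raise SpectraValidationError("response length does not match samples")

    # -- coordinate conventions -------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.ppm.size

    def ppm_of(self, index: int | np.ndarray) -> float | np.ndarray:
        """Chemical shift at a (0-based) measurement index."""
        return self.ppm[index]

    def index_of(self, ppm_value: float | np.ndarray) -> int | np.ndarray:
        """Nearest measurement index for a chemical shift (bijective on axis values)."""
        idx = np.abs(self.ppm[None, :] - np.atleast_1d(ppm_value)[:, None]).argmin(axis=1)
        return int(idx[0]) if np.isscalar(ppm_value) or np.ndim(ppm_value) == 0 else idx

    def with_response(self, response) -> "SpectraSet":
        return replace(self, response=np.asarray(response, dtype=float))


def _delimiter(path: Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "tsv" if Path(path).suffix.lower() in {".tsv", ".txt"} else "csv"
    if dialect not in {"csv", "tsv"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def read_spectra(path, dialect: str | None = None) -> SpectraSet:
    """Read a spectra matrix (header = ppm axis, one row per sample).

    A leading header cell that does not parse as a number marks a sample-id
    column; otherwise rows are labelled ``s0, s1, ...``.
    """
    path = Path(path)
    sep = _delimiter(path, dialect)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter=sep) if r]
    if not rows:
        raise SpectraFormatError(f"{path}: empty file")
    header = rows[0]
    has_ids = False
    try:
        float(header[0])
    except ValueError:
        has_ids = True
    try:
        ppm = np.array([float(v) for v in (header[1:] if has_ids else header)])
    except ValueError as exc:
        raise SpectraFormatError(f"{path}: header row is not a numeric ppm axis") from exc

    width = len(header)
    ids, data = [], []
    for k, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise SpectraFormatError(
                f"{path}: row {k} has {len(row)} fields, expected {width}"
            )
        if has_ids:
            ids.append(row[0])
            vals = row[1:]
        else:
            ids.append(f"s{k - 2}")
            vals = row
        try:
            data.append([float(v) for v in vals])
        except ValueError as exc:
            raise SpectraFormatError(f"{path}: non-numeric intensity in row {k}") from exc
    return SpectraSet(ppm=ppm, intensities=np.array(data), sample_ids=ids)


def write_spectra(spectra: SpectraSet, path, dialect: str | None = None) -> None:
    """Write a SpectraSet so that ``read_spectra`` reproduces it exactly.

    Values are printed with 17 significant digits (round-trip safe for
    float64).
    """
    path = Path(path)
    sep = _delimiter(path, dialect)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow(["sample_id"] + [f"{v:.17g}" for v in spectra.ppm])
        for sid, row in zip(spectra.sample_ids, spectra.intensities):
            w.writerow([sid] + [f"{v:.17g}" for v in row])


def read_response(path, column: str | None = None) -> np.ndarray:
    """Read a response vector.

    Either a single-column file of numbers, or a sample-metadata CSV with a
    header from which ``column`` (default: ``response``) is taken, in file
    order.  A two-level categorical column is coded 0/1 by sorted level.
    """
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] == 1 and column is None:
        col = df.iloc[:, 0]
    else:
        name = column or "response"
        if name not in df.columns:
            raise SpectraValidationError(f"{path}: no column named {name!r}")
        col = df[name]
    if col.dtype == object:
        levels = sorted(col.unique())
        if len(levels) != 2:
            raise SpectraValidationError(
                "categorical responses must have exactly two levels; "
                "code multi-level responses numerically"
            )
        col = col.map({levels[0]: 0.0, levels[1]: 1.0})
    return col.to_numpy(dtype=float)
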