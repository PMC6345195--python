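"""Reading, validation, resampling and centering of digitized pen trajectories.

Drawings arrive either as 2-column CSV (``x,y``, optional header) or as
whitespace-separated SVC handwriting files whose 7 columns are
``x y timestamp pen-status azimuth altitude pressure``; only the spatial
coordinates are consumed.  Every drawing is resampled onto a fixed number of
points (4096 by default) so that DCT spectra of different drawings are
comparable coefficient by coefficient.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_POINTS = 8


class DegenerateInputError(ValueError):
    """A drawing too short (or otherwise too degenerate) to analyse."""


class ParameterError(ValueError):
    """An out-of-range parameter value."""


class Label(str, enum.Enum):
    ET = "ET"
    CONTROL = "CONTROL"
    UNKNOWN = "UNKNOWN"


class Hand(str, enum.Enum):
    DOMINANT = "DOMINANT"
    NONDOMINANT = "NONDOMINANT"
    UNKNOWN = "UNKNOWN"


@dataclass
class DrawingSample:
    """One spiral drawing: raw coordinate stream plus metadata.

    ``x_raw``/``y_raw`` are in tablet length units; ``t_raw`` (optional) in
    seconds, strictly increasing; ``fs_nominal`` is the tablet sampling rate.
    """

    subject_id: str
    x_raw: np.ndarray
    y_raw: np.ndarray
    label: Label = Label.UNKNOWN
    hand: Hand = Hand.UNKNOWN
    t_raw: np.ndarray | None = None
    fs_nominal: float = 100.0

    def __post_init__(self) -> None:
        self.x_raw = np.asarray(self.x_raw, dtype=float)
        self.y_raw = np.asarray(self.y_raw, dtype=float)
        if self.x_raw.shape != self.y_raw.shape or self.x_raw.ndim != 1:
            raise ValueError("x_raw and y_raw must be 1-D and of equal length")
        if len(self.x_raw) < MIN_POINTS:
            raise DegenerateInputError(
                f"drawing {self.subject_id!r} has {len(self.x_raw)} points; "
                f"at least {MIN_POINTS} are required"
            )
        if not (np.all(np.isfinite(self.x_raw)) and np.all(np.isfinite(self.y_raw))):
            raise ValueError("coordinates must be finite")
        if self.t_raw is not None:
            self.t_raw = np.asarray(self.t_raw, dtype=float)
            if self.t_raw.shape != self.x_raw.shape:
                raise ValueError("t_raw must match coordinate length")
            if np.any(np.diff(self.t_raw) <= 0):
                raise ValueError("t_raw must be strictly increasing")

    @property
    def n_points(self) -> int:
        return len(self.x_raw)


@dataclass
class CoordinateSequence:
    """A drawing resampled to exactly ``n`` points at effective rate ``fs``."""

    x: np.ndarray
    y: np.ndarray
    fs: float
    centered: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D and of equal length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("coordinates must be finite")

    @property
    def n(self) -> int:
        return len(self.x)


def _read_csv_coords(path: Path) -> tuple[np.ndarray, np.ndarray]:
    with open(path) as fh:
        first = fh.readline()
    has_header = any(c.isalpha() for c in first)
    if has_header:
        df = pd.read_csv(path)
        cols = {c.strip().lower(): c for c in df.columns}
        if "x" in cols and "y" in cols:
            return df[cols["x"]].to_numpy(float), df[cols["y"]].to_numpy(float)
        raise ValueError(f"{path}: header present but no 'x'/'y' columns")
    df = pd.read_csv(path, header=None)
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def _read_svc_coords(path: Path) -> tuple[np.ndarray, np.ndarray]:
    # Some SVC dialects carry a first line holding only the point count.
    with open(path) as fh:
        first = fh.readline()
    skip = 1 if len(first.split()) == 1 else 0
    df = pd.read_csv(path, sep=r"\s+", header=None, skiprows=skip)
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def read_drawing(
    path: str | Path,
    format: str = "auto",
    subject_id: str | None = None,
    label: Label = Label.UNKNOWN,
    fs_nominal: float = 100.0,
) -> DrawingSample:
    """Read a drawing from CSV or SVC; non-coordinate columns are discarded.

    Rows with non-finite coordinates are dropped (with a logged count); fewer
    than 8 surviving rows raises :class:`DegenerateInputError`.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format == "auto":
        format = "svc" if path.suffix.lower() == ".svc" else "csv"
    if format == "csv":
        x, y = _read_csv_coords(path)
    elif format == "svc":
        x, y = _read_svc_coords(path)
    else:
        raise ParameterError(f"unknown format {format!r}")

    ok = np.isfinite(x) & np.isfinite(y)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: dropped %d rows with non-finite coordinates", path, n_bad)
        x, y = x[ok], y[ok]
    if len(x) < MIN_POINTS:
        raise DegenerateInputError(
            f"{path}: only {len(x)} valid coordinate rows (minimum {MIN_POINTS})"
        )
    return DrawingSample(
        subject_id=subject_id or path.stem,
        x_raw=x,
        y_raw=y,
        label=label,
        fs_nominal=fs_nominal,
    )


def resample_to_n(sample: DrawingSample, n_points: int = 4096) -> CoordinateSequence:
    """Linearly resample both axes onto ``n_points`` uniform sample-index positions.

    The first and last original points are preserved exactly and the effective
    sampling rate is rescaled by ``n_points / original_length``, so the drawing
    still spans the same wall-clock duration.
    """
    if n_points < 2:
        raise ParameterError("n_points must be at least 2")
    n_src = sample.n_points
    grid = np.linspace(0.0, n_src - 1, n_points)
    src = np.arange(n_src, dtype=float)
    x = np.interp(grid, src, sample.x_raw)
    y = np.interp(grid, src, sample.y_raw)
    fs = sample.fs_nominal * n_points / n_src
    return CoordinateSequence(
        x=x,
        y=y,
        fs=fs,
        centered=False,
        meta={"subject_id": sample.subject_id, "label": sample.label.value},
    )


def center_coordinates(seq: CoordinateSequence) -> CoordinateSequence:
    """Subtract the per-axis mean (idempotent up to floating-point tolerance)."""
    return replace(
        seq, x=seq.x - seq.x.mean(), y=seq.y - seq.y.mean(), centered=True
    )


def write_coordinates(seq: CoordinateSequence, path: str | Path) -> None:
    """Serialize as 2-column CSV with 10 significant digits."""
    np.savetxt(
        path,
        np.column_stack([seq.x, seq.y]),
        fmt="%.10g",
        delimiter=",",
        header="x,y",
        comments="",
    )
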