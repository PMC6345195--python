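"""Orthonormal DCT-II analysis, partial reconstructions, residues and the two
scalar-sequence constructions that characterize a spiral drawing.

The transform pair is the orthonormal DCT-II / DCT-III convention

    X_k = c_k sum_n x_n cos(pi/N (n + 1/2) k),   c_0 = sqrt(1/N), c_k = sqrt(2/N)

so that forward followed by inverse recovers the signal exactly and Parseval
holds coefficient-for-coefficient.  A spiral drawn without tremor is smooth
and its per-axis DCT energy is compacted into the first few coefficients;
reconstructing from only the first ``L`` coefficients and subtracting
(the *residue*) therefore isolates the high-order tremor content.

Two one-dimensional characterizations of an (x, y) drawing are provided:

* the radius sequence  r_n = sqrt(x_n^2 + y_n^2)  (polar radius about the
  centroid when coordinates are centered), and
* the residue-distance sequence  rd_n = sqrt(xhat_n^2 + yhat_n^2)  where
  xhat, yhat are the per-axis order-L DCT residues.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, idct

from .ingest import CoordinateSequence, ParameterError


class SequenceKind(str, enum.Enum):
    RADIUS = "RADIUS"
    RESIDUE_DISTANCE = "RESIDUE_DISTANCE"
    RAW_AXIS = "RAW_AXIS"


@dataclass
class DCTSpectrum:
    """The N orthonormal DCT-II coefficients of a length-N sequence."""

    coeffs: np.ndarray

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 1:
            raise ValueError("coeffs must be 1-D")

    @property
    def n(self) -> int:
        return len(self.coeffs)


@dataclass
class ScalarSequence:
    """A real-valued characterization of one drawing, with its sampling rate."""

    values: np.ndarray
    fs: float
    kind: SequenceKind = SequenceKind.RAW_AXIS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sequence values must be finite")
        if self.kind in (SequenceKind.RADIUS, SequenceKind.RESIDUE_DISTANCE):
            if np.any(self.values < 0):
                raise ValueError(f"{self.kind.value} values must be non-negative")

    @property
    def n(self) -> int:
        return len(self.values)


def dct2_forward(x: np.ndarray) -> DCTSpectrum:
    """Forward orthonormal DCT-II of a real sequence."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input must be finite")
    return DCTSpectrum(dct(x, type=2, norm="ortho"))


def dct2_inverse(spec: DCTSpectrum) -> np.ndarray:
    """Inverse (DCT-III) of the orthonormal DCT-II; exact recovery."""
    return idct(spec.coeffs, type=2, norm="ortho")


def partial_reconstruction(spec: DCTSpectrum, L: int) -> np.ndarray:
    """Reconstruct from only the first ``L`` coefficients (k = 0..L-1).

    ``L = N`` reproduces the full inverse; ``L = 0`` gives the zero sequence.
    """
    if not 0 <= L <= spec.n:
        raise ParameterError(f"L must be in [0, {spec.n}], got {L}")
    kept = spec.coeffs.copy()
    kept[L:] = 0.0
    return idct(kept, type=2, norm="ortho")


def residue(x: np.ndarray, L: int) -> np.ndarray:
    """Original minus its order-L partial reconstruction; x = approx + residue."""
    x = np.asarray(x, dtype=float)
    return x - partial_reconstruction(dct2_forward(x), L)


def radius_sequence(seq: CoordinateSequence) -> ScalarSequence:
    """Pointwise Euclidean norm of the coordinates (polar radius)."""
    return ScalarSequence(
        values=np.hypot(seq.x, seq.y), fs=seq.fs, kind=SequenceKind.RADIUS
    )


def residue_distance_sequence(seq: CoordinateSequence, L: int) -> ScalarSequence:
    """Pointwise norm of the per-axis order-L DCT residues.

    The DCT is applied to x and y separately; residues are combined, never
    computed on the radius itself.
    """
    rd = np.hypot(residue(seq.x, L), residue(seq.y, L))
    return ScalarSequence(values=rd, fs=seq.fs, kind=SequenceKind.RESIDUE_DISTANCE)


def write_scalar_sequence(seq: ScalarSequence, path, L: int | None = None) -> None:
    """Single-column CSV; the header records kind, L and fs."""
    header = f"value (kind={seq.kind.value}, L={'' if L is None else L}, fs={seq.fs:g})"
    np.savetxt(path, seq.values, fmt="%.10g", header=header, comments="# ")
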