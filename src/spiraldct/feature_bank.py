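"""Temporal and spectral feature banks computed on a scalar drawing sequence.

The 35 scalars (20 temporal + 15 spectral, in a fixed canonical order) are
classic surface-EMG-style descriptors applied to the radius or
residue-distance sequence of a spiral drawing:

temporal
    SENT (sample entropy, m=3, r=0.2*STD), MAV, VAR, RMS, LOG (log detector),
    WL (waveform length), STD, AAC (difference absolute standard deviation),
    FD (Higuchi fractal dimension, k_max=5), MFL (= log WL), MYO (myopulse
    percentage rate), IEMG, SSI, ZC (mean crossings), SSC (slope sign
    changes), WAMP (Wilson amplitude, threshold = signal mean), AR1..AR4
    (order-4 Yule-Walker autoregressive coefficients).
spectral (from the Welch periodogram)
    Pmax, Fmax, MP, TP, MNF (mean frequency), MDF (median frequency), STDp,
    SM1..SM3 (spectral moments), KUR, SKW, Auto1..Auto3 (lag-1..3 normalized
    autocorrelation of the time sequence).

Conventions the formulas leave open (log base, ZC tie handling, Welch
segmentation, ...) are fixed here and documented in ``FeatureParams`` and the
methods note.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import signal, stats
from statsmodels.regression.linear_model import yule_walker

from .dct_core import ScalarSequence
from .ingest import DegenerateInputError, ParameterError

logger = logging.getLogger(__name__)

TEMPORAL_FEATURE_NAMES: tuple[str, ...] = (
    "SENT", "MAV", "VAR", "RMS", "LOG", "WL", "STD", "AAC", "FD", "MFL",
    "MYO", "IEMG", "SSI", "ZC", "SSC", "WAMP", "AR1", "AR2", "AR3", "AR4",
)
SPECTRAL_FEATURE_NAMES: tuple[str, ...] = (
    "Pmax", "Fmax", "MP", "TP", "MNF", "MDF", "STDp", "SM1", "SM2", "SM3",
    "KUR", "SKW", "Auto1", "Auto2", "Auto3",
)
FEATURE_NAMES: tuple[str, ...] = TEMPORAL_FEATURE_NAMES + SPECTRAL_FEATURE_NAMES

LOG_FLOOR = 1e-12  # |x| floor inside the log detector


@dataclass
class FeatureParams:
    """Tunable parameters of the feature bank.

    ``sampen_r`` is a tolerance *factor*: the matching tolerance is
    ``sampen_r`` times the sample standard deviation of the sequence.
    ``higuchi_kmax`` is the largest curve-length scale of Higuchi's
    estimator.  The Welch settings control the periodogram every spectral
    feature is read from.
    """

    sampen_m: int = 3
    sampen_r: float = 0.2
    higuchi_kmax: int = 5
    ar_order: int = 4
    welch_segment: int = 256
    welch_overlap: float = 0.5
    welch_window: str = "hamming"
    autocorr_lags: int = 3

    def __post_init__(self) -> None:
        if self.sampen_m < 1:
            raise ParameterError("sampen_m must be >= 1")
        if self.higuchi_kmax < 2:
            raise ParameterError("higuchi_kmax must be >= 2")
        if self.ar_order < 1:
            raise ParameterError("ar_order must be >= 1")
        if not 0 <= self.welch_overlap < 1:
            raise ParameterError("welch_overlap must be in [0, 1)")


@njit(cache=True)
def _sampen_pair_counts(x: np.ndarray, m: int, r: float):  # pragma: no cover
    """Counts of template pairs within Chebyshev tolerance r at lengths m, m+1."""
    nt = x.shape[0] - m  # templates that can be extended by one sample
    a = 0
    b = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            d = 0.0
            for k in range(m):
                t = abs(x[i + k] - x[j + k])
                if t > d:
                    d = t
                    if d > r:
                        break
            if d <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


def sample_entropy(x: np.ndarray, m: int = 3, r: float = 0.2) -> float:
    """Sample entropy with Chebyshev distance, self-matches excluded.

    ``r`` is a factor of the sample (N-1) standard deviation.  Degenerate
    inputs (constant sequence, or no matches at either template length)
    return 0 with a warning rather than +/-inf.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if len(x) < 2 * (m + 1):
        raise DegenerateInputError(f"need at least {2 * (m + 1)} samples for m={m}")
    sd = np.std(x, ddof=1)
    if sd == 0:
        warnings.warn("constant sequence: sample entropy set to 0")
        return 0.0
    a, b = _sampen_pair_counts(x, m, r * sd)
    if a == 0 or b == 0:
        warnings.warn("no template matches: sample entropy set to 0")
        return 0.0
    return float(-np.log(a / b))


def higuchi_fd(x: np.ndarray, kmax: int = 5) -> float:
    """Higuchi's fractal dimension from mean curve lengths at scales 1..kmax.

    The log mean curve length is regressed on log(1/k) by least squares; the
    slope is the dimension estimate (1 for smooth curves, up to 2 for noise).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    ks = np.arange(1, kmax + 1)
    lengths = np.empty(kmax)
    for k in ks:
        lm = []
        for m in range(k):
            n_seg = (n - 1 - m) // k
            if n_seg < 1:
                continue
            idx = m + np.arange(n_seg + 1) * k
            ll = np.abs(np.diff(x[idx])).sum() * (n - 1) / (n_seg * k) / k
            lm.append(ll)
        lengths[k - 1] = np.mean(lm) if lm else 0.0
    if np.any(lengths <= 0):
        warnings.warn("degenerate curve lengths: Higuchi FD set to 0")
        return 0.0
    slope, _ = np.polyfit(np.log(1.0 / ks), np.log(lengths), 1)
    return float(slope)


def _zero_crossings(x: np.ndarray) -> int:
    # Sign changes of (x - mean); exact zeros take the sign of the following
    # sample so an alternating +/- sequence counts every consecutive pair.
    s = np.sign(x - x.mean())
    for i in range(len(s) - 2, -1, -1):
        if s[i] == 0:
            s[i] = s[i + 1]
    return int(np.sum(s[:-1] * s[1:] < 0))


def _slope_sign_changes(x: np.ndarray) -> int:
    d = np.diff(x)
    d = d[d != 0]  # zero slopes are skipped
    return int(np.sum(d[:-1] * d[1:] < 0))


def _ar_coefficients(x: np.ndarray, order: int) -> np.ndarray:
    if np.std(x) == 0:
        warnings.warn("constant sequence: AR coefficients set to 0")
        return np.zeros(order)
    rho, _sigma = yule_walker(x, order=order, method="mle")
    return np.asarray(rho, dtype=float)


def temporal_features(seq: ScalarSequence, params: FeatureParams | None = None) -> dict:
    """Evaluate the 20 temporal descriptors on ``seq.values``."""
    params = params or FeatureParams()
    x = seq.values
    n = len(x)
    if n < 2 * (params.sampen_m + 1):
        raise DegenerateInputError(
            f"sequence of {n} samples too short for temporal features"
        )
    absx = np.abs(x)
    diffs = np.diff(x)
    mav = absx.mean()
    var = x.var(ddof=1)
    std = np.sqrt(var)
    rms = np.sqrt(np.mean(x**2))
    wl = np.abs(diffs).sum()
    mean = x.mean()

    feats = {
        "SENT": sample_entropy(x, params.sampen_m, params.sampen_r),
        "MAV": mav,
        "VAR": var,
        "RMS": rms,
        "LOG": float(np.exp(np.mean(np.log(np.maximum(absx, LOG_FLOOR))))),
        "WL": wl,
        "STD": std,
        "AAC": float(np.sqrt(np.sum(diffs**2) / (n - 1))),
        "FD": higuchi_fd(x, params.higuchi_kmax),
        "MFL": float(np.log(wl)) if wl > 0 else float(np.log(LOG_FLOOR)),
        "MYO": 100.0 * np.mean(x > 2 * mean),
        "IEMG": absx.sum(),
        "SSI": float(np.sum(x**2)),
        "ZC": float(_zero_crossings(x)),
        "SSC": float(_slope_sign_changes(x)),
        "WAMP": float(np.sum(np.abs(diffs) > mean)),
    }
    ar = _ar_coefficients(x, params.ar_order)
    for i in range(4):
        feats[f"AR{i + 1}"] = float(ar[i]) if i < len(ar) else 0.0
    return {k: float(v) for k, v in feats.items()}


def welch_psd(seq: ScalarSequence, params: FeatureParams | None = None):
    """Welch periodogram (density scaling) of a scalar sequence."""
    params = params or FeatureParams()
    if seq.fs is None or seq.fs <= 0:
        raise ParameterError("sequence sampling rate must be set and positive")
    nper = min(params.welch_segment, seq.n)
    f, p = signal.welch(
        seq.values,
        fs=seq.fs,
        window=params.welch_window,
        nperseg=nper,
        noverlap=int(nper * params.welch_overlap),
    )
    return f, p


def _autocorrelation(x: np.ndarray, lags: int) -> np.ndarray:
    xc = x - x.mean()
    denom = np.dot(xc, xc)
    if denom == 0:
        warnings.warn("constant sequence: autocorrelation set to 0")
        return np.zeros(lags)
    return np.array([np.dot(xc[:-k], xc[k:]) / denom for k in range(1, lags + 1)])


def spectral_features(seq: ScalarSequence, params: FeatureParams | None = None) -> dict:
    """Evaluate the 15 spectral descriptors on the Welch periodogram of ``seq``."""
    params = params or FeatureParams()
    f, p = welch_psd(seq, params)
    tp = p.sum()
    cum = np.cumsum(p)
    mdf = f[np.searchsorted(cum, tp / 2.0)] if tp > 0 else 0.0
    feats = {
        "Pmax": p.max(),
        "Fmax": f[int(np.argmax(p))],
        "MP": p.mean(),
        "TP": tp,
        "MNF": float(np.sum(f * p) / tp) if tp > 0 else 0.0,
        "MDF": mdf,
        "STDp": np.std(p, ddof=1),
        "SM1": float(np.sum(p * f)),
        "SM2": float(np.sum(p * f**2)),
        "SM3": float(np.sum(p * f**3)),
        "KUR": float(stats.kurtosis(p, fisher=False)),
        "SKW": float(stats.skew(p)),
    }
    auto = _autocorrelation(seq.values, params.autocorr_lags)
    for i in range(3):
        feats[f"Auto{i + 1}"] = float(auto[i]) if i < len(auto) else 0.0
    return {k: float(v) for k, v in feats.items()}


def extract_all(seq: ScalarSequence, params: FeatureParams | None = None) -> dict:
    """All 35 named features in canonical order (temporal, then spectral)."""
    params = params or FeatureParams()
    feats = temporal_features(seq, params)
    feats.update(spectral_features(seq, params))
    out = {name: feats[name] for name in FEATURE_NAMES}
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite features: {bad}")
    return out
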