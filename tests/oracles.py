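"""Independent, literal loop-based oracles used to cross-check the package.

Everything here is written from the defining formulas, without reusing the
implementation under test (the Welch periodogram itself is shared input for
the spectral-feature oracles; the features computed from it are re-derived
by explicit loops).
"""

import math

import numpy as np
from scipy.signal import welch


# ---------------------------------------------------------------- DCT oracle
def dct2_direct(x):
    """O(N^2) direct evaluation of the orthonormal DCT-II sum."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    out = np.empty(n)
    for k in range(n):
        ck = math.sqrt(1.0 / n) if k == 0 else math.sqrt(2.0 / n)
        out[k] = ck * sum(
            x[i] * math.cos(math.pi / n * (i + 0.5) * k) for i in range(n)
        )
    return out


def idct2_direct(coeffs):
    """O(N^2) direct evaluation of the inverse (DCT-III) sum."""
    c = np.asarray(coeffs, dtype=float)
    n = len(c)
    out = np.empty(n)
    for i in range(n):
        acc = 0.0
        for k in range(n):
            ck = math.sqrt(1.0 / n) if k == 0 else math.sqrt(2.0 / n)
            acc += ck * c[k] * math.cos(math.pi / n * (i + 0.5) * k)
        out[i] = acc
    return out


# ------------------------------------------------------- temporal-feature oracles
def sampen_direct(x, m, r_factor):
    """Literal sample entropy: Chebyshev distance, self-matches excluded."""
    x = np.asarray(x, dtype=float)
    r = r_factor * np.std(x, ddof=1)
    nt = len(x) - m
    a = b = 0
    for i in range(nt):
        for j in range(nt):
            if i == j:
                continue
            dm = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if dm <= r:
                b += 1
                if max(dm, abs(x[i + m] - x[j + m])) <= r:
                    a += 1
    if a == 0 or b == 0:
        return 0.0
    return -math.log(a / b)


def higuchi_direct(x, kmax):
    """Literal Higuchi curve-length estimator."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    logs = []
    for k in range(1, kmax + 1):
        lk = []
        for m in range(k):
            n_seg = (n - 1 - m) // k
            if n_seg < 1:
                continue
            total = sum(
                abs(x[m + i * k] - x[m + (i - 1) * k]) for i in range(1, n_seg + 1)
            )
            lk.append(total * (n - 1) / (n_seg * k) / k)
        logs.append((math.log(1.0 / k), math.log(np.mean(lk))))
    xs = np.array([a for a, _ in logs])
    ys = np.array([b for _, b in logs])
    slope = np.polyfit(xs, ys, 1)[0]
    return float(slope)


def temporal_direct(x):
    """Loop-based evaluation of the closed-form temporal descriptors."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    mu = sum(x) / n
    mav = sum(abs(v) for v in x) / n
    var = sum((v - mu) ** 2 for v in x) / (n - 1)
    wl = sum(abs(x[i + 1] - x[i]) for i in range(n - 1))
    # zero crossings: sign of (x - mean), zeros take the following sample's sign
    signs = []
    for v in x:
        d = v - mu
        signs.append(0 if d == 0 else (1 if d > 0 else -1))
    for i in range(n - 2, -1, -1):
        if signs[i] == 0:
            signs[i] = signs[i + 1]
    zc = sum(1 for i in range(n - 1) if signs[i] * signs[i + 1] < 0)
    diffs = [x[i + 1] - x[i] for i in range(n - 1)]
    nz = [d for d in diffs if d != 0]
    ssc = sum(1 for i in range(len(nz) - 1) if nz[i] * nz[i + 1] < 0)
    return {
        "MAV": mav,
        "VAR": var,
        "STD": math.sqrt(var),
        "RMS": math.sqrt(sum(v**2 for v in x) / n),
        "LOG": math.exp(sum(math.log(max(abs(v), 1e-12)) for v in x) / n),
        "WL": wl,
        "AAC": math.sqrt(sum(d**2 for d in diffs) / (n - 1)),
        "MFL": math.log(wl),
        "MYO": 100.0 * sum(1 for v in x if v > 2 * mu) / n,
        "IEMG": sum(abs(v) for v in x),
        "SSI": sum(v**2 for v in x),
        "ZC": float(zc),
        "SSC": float(ssc),
        "WAMP": float(sum(1 for d in diffs if abs(d) > mu)),
    }


def ar_yule_walker_direct(x, order):
    """Yule-Walker with biased autocovariance, solved as a linear system."""
    x = np.asarray(x, dtype=float) - np.mean(x)
    n = len(x)
    r = np.array(
        [sum(x[: n - k] * x[k:]) / n for k in range(order + 1)]
    )
    R = np.empty((order, order))
    for i in range(order):
        for j in range(order):
            R[i, j] = r[abs(i - j)]
    return np.linalg.solve(R, r[1 : order + 1])


# ------------------------------------------------------- spectral-feature oracle
def spectral_direct(values, fs, nperseg=256, overlap=0.5, window="hamming"):
    """Loop-based spectral descriptors from the shared Welch periodogram."""
    nper = min(nperseg, len(values))
    f, p = welch(values, fs=fs, window=window, nperseg=nper,
                 noverlap=int(nper * overlap))
    n = len(p)
    tp = sum(p)
    mp = tp / n
    cum = 0.0
    mdf = 0.0
    for fi, pi in zip(f, p):
        cum += pi
        if cum >= tp / 2:
            mdf = fi
            break
    mean_p = tp / n
    m2 = sum((pi - mean_p) ** 2 for pi in p) / n
    m3 = sum((pi - mean_p) ** 3 for pi in p) / n
    m4 = sum((pi - mean_p) ** 4 for pi in p) / n
    imax = int(np.argmax(p))
    return {
        "Pmax": max(p),
        "Fmax": f[imax],
        "MP": mp,
        "TP": tp,
        "MNF": sum(fi * pi for fi, pi in zip(f, p)) / tp,
        "MDF": mdf,
        "STDp": math.sqrt(sum((pi - mean_p) ** 2 for pi in p) / (n - 1)),
        "SM1": sum(pi * fi for fi, pi in zip(f, p)),
        "SM2": sum(pi * fi**2 for fi, pi in zip(f, p)),
        "SM3": sum(pi * fi**3 for fi, pi in zip(f, p)),
        "KUR": m4 / m2**2,
        "SKW": m3 / m2**1.5,
    }


def autocorr_direct(x, lags):
    x = np.asarray(x, dtype=float)
    mu = x.mean()
    xc = x - mu
    denom = sum(v * v for v in xc)
    return [
        sum(xc[i] * xc[i + k] for i in range(len(x) - k)) / denom
        for k in range(1, lags + 1)
    ]


# ---------------------------------------------------------------- CV oracle
def loo_accuracy_direct(fit_predict, X, y):
    """Brute-force leave-one-out: retrain for every held-out sample.

    ``fit_predict(X_train, y_train, x_test) -> label`` is supplied by the
    caller so the oracle exercises the splitting/tallying logic only.
    """
    correct = 0
    n = len(y)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        pred = fit_predict(X[mask], y[mask], X[i : i + 1])
        if pred == y[i]:
            correct += 1
    return 100.0 * correct / n


def knn_predict_direct(X_train, y_train, x_test, k):
    """Brute-force k-NN with the nearest-neighbor tie rule."""
    d = [float(np.linalg.norm(row - x_test[0])) for row in X_train]
    order = sorted(range(len(d)), key=lambda i: (d[i], i))[:k]
    votes = [y_train[i] for i in order]
    labs = sorted(set(votes))
    counts = {l: votes.count(l) for l in labs}
    top = max(counts.values())
    winners = [l for l in labs if counts[l] == top]
    return winners[0] if len(winners) == 1 else votes[0]
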