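"""Quantitative evaluation of surrogate signals against ground truth.

The reported agreement metric is the absolute Pearson correlation |r|
between the projection vector and the manually labelled diaphragm track:
the sign of a principal component is arbitrary, so only the magnitude of
the linear association is meaningful.  Method comparison uses a
one-tailed Wilcoxon rank-sum (Mann-Whitney) test, since correlation
coefficients cluster near 1 and are not normally distributed.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .io import DiaphragmTrack, SurrogateSignal

#: Combined sample size up to which the rank-sum test enumerates the exact
#: permutation distribution.
EXACT_RANKSUM_LIMIT = 12

DEFAULT_HIST_EDGES = (0.0, 0.8, 0.9, 1.0)


def _values(x) -> np.ndarray:
    if isinstance(x, SurrogateSignal):
        return x.values
    if isinstance(x, DiaphragmTrack):
        return x.positions
    return np.asarray(x, dtype=float)


def correlation(p, truth) -> float:
    """Absolute Pearson correlation between a surrogate and ground truth.

    Both inputs must have equal length >= 3 and nonzero variance; a
    constant signal has no defined correlation and raises.
    """
    a = _values(p)
    b = _values(truth)
    if a.shape != b.shape:
        raise ValueError(
            f"length mismatch: signal has {a.size}, truth has {b.size}"
        )
    if a.size < 3:
        raise ValueError("need at least 3 samples to correlate")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(abs(np.corrcoef(a, b)[0, 1]))


def rescale_overlay(
    p, target_min: float, target_max: float, truth=None
) -> np.ndarray:
    """Affinely map a signal onto a target range for visual overlay.

    ``min(p) -> target_min`` and ``max(p) -> target_max``; when a truth
    track is supplied the orientation is flipped if that increases the
    (signed) correlation, compensating the arbitrary PCA sign.
    """
    v = _values(p).astype(float)
    if np.ptp(v) == 0:
        raise ValueError("cannot rescale a constant signal")
    if truth is not None:
        t = _values(truth)
        if np.corrcoef(v, t)[0, 1] < 0:
            v = -v
    out = (v - v.min()) / np.ptp(v)
    return out * (target_max - target_min) + target_min


def corr_histogram(rs, edges=DEFAULT_HIST_EDGES) -> np.ndarray:
    """Bin correlation coefficients (default bins emphasize the robustness
    bands below 0.8 and above 0.9; the top bin is right-closed)."""
    rs = np.asarray(list(rs), dtype=float)
    if rs.size == 0:
        return np.zeros(len(edges) - 1, dtype=int)
    counts, _ = np.histogram(rs, bins=np.asarray(edges, dtype=float))
    return counts


def compare_methods(rs_a, rs_b) -> float:
    """One-tailed Wilcoxon rank-sum p-value for H1: A's values exceed B's.

    For combined sample size <= 12 the exact permutation distribution of
    the rank sum is enumerated (ties handled with midranks and a mid-p
    correction, so identical samples give exactly p = 0.5 and swapping
    the arguments maps p to 1 - p).  Larger samples use the normal
    approximation with tie correction.
    """
    a = np.asarray(list(rs_a), dtype=float)
    b = np.asarray(list(rs_b), dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs at least 3 values")
    if a.size + b.size <= EXACT_RANKSUM_LIMIT:
        return _exact_ranksum(a, b)
    res = stats.mannwhitneyu(
        a, b, alternative="greater", method="asymptotic", use_continuity=False
    )
    return float(res.pvalue)


def _exact_ranksum(a: np.ndarray, b: np.ndarray) -> float:
    """Exact mid-p of the one-tailed rank-sum test by full enumeration."""
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)  # midranks under ties
    n = combined.size
    na = a.size
    observed = ranks[:na].sum()
    greater = equal = total = 0
    for idx in itertools.combinations(range(n), na):
        s = ranks[list(idx)].sum()
        if s > observed + 1e-12:
            greater += 1
        elif abs(s - observed) <= 1e-12:
            equal += 1
        total += 1
    return (greater + 0.5 * equal) / total


def band_power_fraction(
    values, fs: float, freq: float, halfwidth_hz: float | None = None
) -> float:
    """Fraction of a signal's (DC-free) spectral power within a band.

    The signal is standardized, its periodogram computed, and the power in
    ``freq +/- halfwidth_hz`` (default: one frequency bin) is divided by
    the total non-DC power.  Used to quantify residual cardiac content in
    a surrogate.
    """
    v = _values(values).astype(float)
    if np.ptp(v) == 0:
        raise ValueError("band power undefined for a constant signal")
    v = (v - v.mean()) / v.std()
    spectrum = np.abs(np.fft.rfft(v)) ** 2
    freqs = np.fft.rfftfreq(v.size, d=1.0 / fs)
    if halfwidth_hz is None:
        halfwidth_hz = fs / v.size
    band = np.abs(freqs - freq) <= halfwidth_hz
    total = spectrum[1:].sum()
    return float(spectrum[band].sum() / total)


def summarize(records) -> pd.DataFrame:
    """Mean +/- std table of correlations grouped by method and scope.

    ``records`` is a DataFrame (or convertible) with columns ``method``,
    ``scope`` and ``r``.  Sample std uses ddof=1; single-value groups
    report std 0 and are flagged by their n column.  Column order:
    method, scope, n, mean, std.
    """
    df = pd.DataFrame(records)
    if df.empty:
        raise ValueError("no records to summarize")
    rows = []
    for (method, scope), grp in df.groupby(["method", "scope"], sort=True):
        r = grp["r"].to_numpy(dtype=float)
        rows.append(
            {
                "method": method,
                "scope": scope,
                "n": int(r.size),
                "mean": float(r.mean()),
                "std": float(r.std(ddof=1)) if r.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["method", "scope", "n", "mean", "std"])


def comparison_matrix(
    rs_by_method: dict, methods: list[str] | None = None
) -> pd.DataFrame:
    """Pairwise one-tailed rank-sum p-values, rows tested > columns."""
    if methods is None:
        methods = list(rs_by_method)
    mat = pd.DataFrame(index=methods, columns=methods, dtype=float)
    for m1 in methods:
        for m2 in methods:
            if m1 != m2:
                mat.loc[m1, m2] = compare_methods(
                    rs_by_method[m1], rs_by_method[m2]
                )
    return mat
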