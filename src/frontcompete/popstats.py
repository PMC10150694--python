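"""Population-level analyses downstream of the per-event quantification.

Covers the temporal cross-correlation between cell stretching (relative
skeleton length) and the absolute difference in front Cdc42 activity between
the winning and losing fronts; stratification of reversing cells into slow
and fast responders; and the binomial proportion summaries and two-group
tests used for population comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "XcorrConfig",
    "ResponderCall",
    "loess_smooth",
    "stretch_signal_xcorr",
    "stratify_responder",
    "proportion_summary",
    "compare",
]


@dataclass
class XcorrConfig:
    span: float = 0.10            # loess span, fraction of the trace
    degree: int = 2
    min_trace_frames: int = 10    # 30 s at 3 s frames

    def __post_init__(self) -> None:
        if not 0.0 < self.span <= 1.0:
            raise ValueError("span must be in (0, 1]")
        if self.min_trace_frames < 3:
            raise ValueError("min_trace_frames must be >= 3")


@dataclass
class ResponderCall:
    x: float          # retracting-front distance from apex at stimulation
    y: float          # minimum apex distance before reprotrusion
    ratio: float
    klass: str        # "slow" or "fast"
    flagged: bool = False   # y > x is geometrically unexpected


# --------------------------------------------------------------------------
# Loess smoothing (local weighted polynomial regression)
# --------------------------------------------------------------------------

def loess_smooth(y: np.ndarray, span: float = 0.10,
                 degree: int = 2) -> np.ndarray:
    """Local polynomial regression with tricube weights.

    The window around each point holds the ``ceil(span * n)`` nearest
    neighbours (truncated, hence asymmetric, near the trace ends).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    x = np.arange(n, dtype=float)
    k = max(int(np.ceil(span * n)), degree + 1)
    out = np.empty(n)
    for i in range(n):
        lo = max(0, min(i - k // 2, n - k))
        idx = np.arange(lo, lo + k)
        d = np.abs(idx - i)
        dmax = d.max()
        w = (1 - (d / dmax) ** 3) ** 3 if dmax > 0 else np.ones_like(d,
                                                                     float)
        w = np.maximum(w, 1e-9)
        V = np.vander(idx - i, degree + 1, increasing=True)
        W = np.sqrt(w)[:, None]
        beta, *_ = np.linalg.lstsq(W * V, np.sqrt(w) * y[idx], rcond=None)
        out[i] = beta[0]
    return out


# --------------------------------------------------------------------------
# Stretch vs signaling cross-correlation
# --------------------------------------------------------------------------

def stretch_signal_xcorr(rel_length: np.ndarray,
                         activity_winning: np.ndarray,
                         activity_losing: np.ndarray,
                         config: XcorrConfig | None = None) -> dict:
    """Pearson correlation of stretching vs |winning - losing| activity at
    each integer-frame lag.

    Positive lag means stretching leads the activity difference by that many
    frames.  Traces shorter than ``min_trace_frames`` are rejected; constant
    series have no defined correlation.  Returns lags, correlations and the
    lag of maximum correlation.
    """
    config = config or XcorrConfig()
    stretch = np.asarray(rel_length, dtype=float)
    signal = np.abs(np.asarray(activity_winning, dtype=float)
                    - np.asarray(activity_losing, dtype=float))
    n = stretch.size
    if n != signal.size:
        raise ValueError("trace length mismatch")
    if n < config.min_trace_frames:
        raise ValueError(
            f"trace of {n} frames shorter than the "
            f"{config.min_trace_frames}-frame minimum")
    stretch = loess_smooth(stretch, config.span, config.degree)
    signal = loess_smooth(signal, config.span, config.degree)
    max_lag = int(min(10, n // 3))
    lags = np.arange(-max_lag, max_lag + 1)
    corrs = np.empty(lags.size)
    for i, lag in enumerate(lags):
        if lag >= 0:
            a, b = stretch[:n - lag], signal[lag:]
        else:
            a, b = stretch[-lag:], signal[:n + lag]
        if (np.std(a) <= 1e-12 * (1 + abs(np.mean(a)))
                or np.std(b) <= 1e-12 * (1 + abs(np.mean(b)))):
            raise ValueError("constant series: correlation undefined")
        corrs[i] = sps.pearsonr(a, b)[0]
    return {"lags": lags, "correlations": corrs,
            "peak_lag": int(lags[int(np.argmax(corrs))])}


# --------------------------------------------------------------------------
# Responder stratification
# --------------------------------------------------------------------------

def stratify_responder(x: float, y: float) -> ResponderCall:
    """Slow/fast responder call for a reversing cell.

    ``x`` is the retracting front's distance from the obstacle apex when
    stimulation started, ``y`` its minimum apex distance before reprotrusion.
    Cells with y/x < 0.5 are slow responders (they retract most of the way
    back before reversing); the rest, including the y/x = 0.5 boundary, are
    fast.
    """
    if x <= 0:
        raise ValueError("x must be positive")
    if y < 0:
        raise ValueError("y must be non-negative")
    ratio = y / x
    return ResponderCall(x=x, y=y, ratio=ratio,
                         klass="slow" if ratio < 0.5 else "fast",
                         flagged=y > x)


# --------------------------------------------------------------------------
# Proportions and two-group tests
# --------------------------------------------------------------------------

def proportion_summary(k: int, n: int) -> tuple[float, float]:
    """Fraction of successes with its binomial standard deviation,
    sqrt(p(1-p)/n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    p = k / n
    return p, float(np.sqrt(p * (1.0 - p) / n))


def compare(group_a, group_b, test: str = "wilcoxon") -> tuple[float, float]:
    """Two-sided two-group comparison.

    ``test="wilcoxon"`` runs the Wilcoxon rank-sum (Mann-Whitney) test on two
    samples; ``test="fisher"`` runs Fisher's exact test, where each group is
    a (successes, failures) count pair.  Returns (statistic, p-value).
    """
    if test == "wilcoxon":
        a = np.asarray(group_a, dtype=float)
        b = np.asarray(group_b, dtype=float)
        if a.size == 0 or b.size == 0:
            raise ValueError("empty group")
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if test == "fisher":
        table = np.array([group_a, group_b], dtype=int)
        if table.shape != (2, 2):
            raise ValueError("fisher test needs 2x2 counts")
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        return float(odds), float(p)
    raise ValueError(f"unknown test {test!r}")
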