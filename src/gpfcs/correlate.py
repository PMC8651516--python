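"""Autocorrelation of photon traces (multiple-tau scheme plus a brute-force
reference estimator).

Both estimators compute the same normalized fluctuation autocorrelation

    G(tau) = <F(t) F(t+tau)> / (<F>_lead <F>_lag) - 1,

with *symmetric* normalization: the leading and lagged segments are each
normalized by their own mean, which suppresses the finite-trace bias of
the naive single-mean estimator.  The zero-lag (shot-noise) point is never
reported; the first lag is one bin.
"""

from __future__ import annotations

import numpy as np

from .containers import CorrelationCurve, PhotonTrace

__all__ = ["autocorrelate", "brute_force_acf"]


def _check_channel(trace: PhotonTrace, channel: str) -> np.ndarray:
    f = trace.channel(channel).astype(np.float64)
    if f.sum() == 0:
        raise ValueError(f"empty channel: {channel!r} has no counts")
    return f


def _g_at_lag(f: np.ndarray, k: int) -> float:
    """Symmetric-normalized correlation of signal ``f`` at integer lag k."""
    lead = f[:-k]
    lag = f[k:]
    num = float(np.dot(lead, lag)) / lead.size
    denom = lead.mean() * lag.mean()
    if denom == 0:
        return 0.0
    return num / denom - 1.0


def autocorrelate(
    trace: PhotonTrace,
    channel: str = "sum",
    m: int = 16,
    max_lag: float | None = None,
) -> CorrelationCurve:
    """Multiple-tau autocorrelation of one trace channel.

    The first 2m lags are evaluated at the native bin width; thereafter
    the trace is rebinned by a factor of two per octave and lags
    m+1 ... 2m of each octave are evaluated on the rebinned signal, so lag
    spacing and averaging time double together.  ``max_lag`` (seconds)
    optionally truncates the curve.
    """
    if m < 2:
        raise ValueError("m must be at least 2")
    f = _check_channel(trace, channel)
    if f.size < 2 * m:
        raise ValueError(f"trace too short: need at least {2 * m} bins")
    lags: list[float] = []
    g: list[float] = []
    bin_level = trace.bin_width
    level = 0
    while True:
        ks = range(1, 2 * m + 1) if level == 0 else range(m + 1, 2 * m + 1)
        added = False
        for k in ks:
            if k > f.size // 2:
                break
            tau = k * bin_level
            if max_lag is not None and tau > max_lag:
                break
            lags.append(tau)
            g.append(_g_at_lag(f, k))
            added = True
        if not added and level > 0:
            break
        if max_lag is not None and lags and lags[-1] >= max_lag:
            break
        # rebin by 2 for the next octave
        n2 = f.size // 2
        if n2 < 2 * m + 2:
            break
        f = f[: 2 * n2].reshape(n2, 2).sum(axis=1)
        bin_level *= 2.0
        level += 1
    return CorrelationCurve(
        np.asarray(lags),
        np.asarray(g),
        mean_count_rate_blue=trace.mean_rate_khz("blue"),
        mean_count_rate_red=trace.mean_rate_khz("red"),
        acquisition_time=trace.duration,
        channel=channel,
        meta={"m": m, "scheme": "multiple-tau", **trace.meta},
    )


def brute_force_acf(
    trace: PhotonTrace, channel: str = "sum", lags: list[int] | None = None
) -> CorrelationCurve:
    """Direct O(N*L) evaluation of the normalized estimator (test oracle).

    ``lags`` are integer bin multiples; defaults to 1..32.
    """
    f = _check_channel(trace, channel)
    if lags is None:
        lags = list(range(1, 33))
    lags = sorted(int(k) for k in lags)
    if lags[0] < 1:
        raise ValueError("lags must be positive bin multiples")
    if lags[-1] >= f.size:
        raise ValueError("lag exceeds trace length")
    g = []
    for k in lags:
        lead = f[:-k]
        lag = f[k:]
        prod = (lead * lag).sum() / lead.size
        denom = lead.mean() * lag.mean()
        g.append(prod / denom - 1.0 if denom != 0 else 0.0)
    return CorrelationCurve(
        np.asarray(lags, dtype=float) * trace.bin_width,
        np.asarray(g),
        mean_count_rate_blue=trace.mean_rate_khz("blue"),
        mean_count_rate_red=trace.mean_rate_khz("red"),
        acquisition_time=trace.duration,
        channel=channel,
        meta={"scheme": "brute-force", **trace.meta},
    )
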