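"""Goodness-of-fit metrics: RMSE, normalised RMSE (percent), adjusted R2."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["rmse", "nrmse", "r2_adjusted", "MetricsReport", "metrics_report"]


def _as_pair(measured, predicted) -> tuple[np.ndarray, np.ndarray]:
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape:
        raise ValueError(f"length mismatch: measured {m.shape} vs predicted {p.shape}")
    if m.size == 0:
        raise ValueError("empty input")
    return m, p


def rmse(measured, predicted) -> float:
    """Root mean square error, in the units of the inputs."""
    m, p = _as_pair(measured, predicted)
    return float(np.sqrt(np.mean((m - p) ** 2)))


def nrmse(measured, predicted) -> float:
    """RMSE normalised by the mean of the measured values, in percent."""
    m, p = _as_pair(measured, predicted)
    mean = float(np.mean(m))
    if mean <= 0:
        raise ValueError(f"mean of measured values must be positive (got {mean})")
    return 100.0 * rmse(m, p) / mean


def r2_adjusted(measured, predicted, p: int) -> float:
    """Adjusted coefficient of determination.

    ``1 - [SSE / (n - p - 1)] / [SST / (n - 1)]`` where ``p`` is the number
    of predictors. Requires ``n > p + 1`` and non-constant measured values.
    """
    m, pred = _as_pair(measured, predicted)
    n = m.size
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    sst = float(np.sum((m - m.mean()) ** 2))
    if sst == 0:
        raise ValueError("zero variance in measured values")
    sse = float(np.sum((m - pred) ** 2))
    return 1.0 - (sse / (n - p - 1)) / (sst / (n - 1))


@dataclass(frozen=True)
class MetricsReport:
    r2_adjusted: float
    rmse: float
    nrmse: float
    n: int
    p: int

    def to_dict(self) -> dict:
        return asdict(self)


def metrics_report(measured, predicted, p: int) -> MetricsReport:
    m, pred = _as_pair(measured, predicted)
    return MetricsReport(
        r2_adjusted=r2_adjusted(m, pred, p),
        rmse=rmse(m, pred),
        nrmse=nrmse(m, pred),
        n=m.size,
        p=p,
    )
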