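"""Aboveground-biomass estimation from multispectral reflectance.

Two ingredients: the two-band enhanced vegetation index (EVI2) and a
two-level linear model whose intercept and slope both vary linearly with
cumulative growing degree days (GDD).  The two-level form

    level 1:  AGB = b0 + b1 * EVI2
    level 2:  bj  = g_j0 + g_j1 * GDD

expands to the single interaction regression

    AGB = g00 + g01*GDD + g10*EVI2 + g11*GDD*EVI2

which is how it is fitted here (the forms are algebraically identical).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .evaluation import nrmse, r2_adjusted

__all__ = [
    "SpectralSample",
    "HLMCoefficients",
    "PUBLISHED_COEFFICIENTS",
    "evi2",
    "hlm_predict",
    "hlm_fit",
    "HLMFit",
    "plot_agb_from_sampling",
]


@dataclass(frozen=True)
class SpectralSample:
    """One plot-level reflectance observation, optionally with measured AGB."""

    plot_id: str
    date: dt.date
    nir: float
    red: float
    gdd: float
    agb_measured: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.nir <= 1.0 and 0.0 <= self.red <= 1.0):
            raise ValueError(
                f"{self.plot_id} {self.date}: reflectance outside [0, 1] "
                f"(nir={self.nir}, red={self.red})"
            )
        if self.gdd < 0:
            raise ValueError(f"{self.plot_id} {self.date}: negative gdd")

    @property
    def evi2(self) -> float:
        return evi2(self.nir, self.red)


@dataclass(frozen=True)
class HLMCoefficients:
    """Level-2 coefficients: intercept/GDD-slope of b0 and of b1."""

    g00: float
    g01: float
    g10: float
    g11: float

    def __post_init__(self) -> None:
        for f in (self.g00, self.g01, self.g10, self.g11):
            if not np.isfinite(f):
                raise ValueError("coefficients must be finite")

    def level1(self, gdd: float) -> tuple[float, float]:
        """(b0, b1) at a given GDD."""
        return self.g00 + self.g01 * gdd, self.g10 + self.g11 * gdd


#: Reference coefficient set from the published calibration.
PUBLISHED_COEFFICIENTS = HLMCoefficients(g00=1.22, g01=0.02, g10=-13.35, g11=0.38)


def evi2(nir: float, red: float) -> float:
    """Two-band enhanced vegetation index ``2.5 * (NIR - R) / (NIR + 2.4 R + 1)``."""
    if not (0.0 <= nir <= 1.0 and 0.0 <= red <= 1.0):
        raise ValueError(f"reflectance outside [0, 1]: nir={nir}, red={red}")
    return 2.5 * (nir - red) / (nir + 2.4 * red + 1.0)


def evi2_to_nir(evi2_value: float, red: float) -> float:
    """Invert :func:`evi2` for NIR at fixed red reflectance.

    Used by the synthetic generator to manufacture reflectance pairs whose
    index round-trips to a target value.  Requires ``evi2_value < 2.5``.
    """
    if evi2_value >= 2.5:
        raise ValueError("index value not attainable")
    nir = (2.5 * red + evi2_value * (2.4 * red + 1.0)) / (2.5 - evi2_value)
    return nir


def hlm_predict(evi2_value: float, gdd: float, coeffs: HLMCoefficients) -> float:
    """Raw model value ``(g00 + g01*GDD) + (g10 + g11*GDD) * EVI2`` in t/ha.

    No clamping: low GDD/index combinations can legitimately go negative;
    map production applies a clamp-to-zero flag separately.
    """
    b0, b1 = coeffs.level1(gdd)
    return b0 + b1 * evi2_value


@dataclass(frozen=True)
class HLMFit:
    coefficients: HLMCoefficients
    r2: float
    nrmse_pct: float
    n: int


def hlm_fit(samples: Sequence[SpectralSample]) -> HLMFit:
    """Least-squares fit of the expanded interaction regression.

    Requires at least four samples spanning at least two distinct GDD values
    (otherwise the GDD columns are collinear with the constant term).
    """
    samples = [s for s in samples if s.agb_measured is not None]
    if len(samples) < 4:
        raise ValueError(f"need >= 4 samples with measured AGB, got {len(samples)}")
    gdd = np.array([s.gdd for s in samples])
    e = np.array([s.evi2 for s in samples])
    y = np.array([s.agb_measured for s in samples])

    X = np.column_stack([np.ones_like(gdd), gdd, e, gdd * e])
    rank = np.linalg.matrix_rank(X)
    if rank < 4:
        bad = []
        if np.ptp(gdd) == 0:
            bad.append("gdd (single value: g01, g11 unidentifiable)")
        if np.ptp(e) == 0:
            bad.append("evi2 (single value: g10, g11 unidentifiable)")
        raise np.linalg.LinAlgError(
            "singular fit: design matrix rank %d < 4; collinear columns: %s"
            % (rank, ", ".join(bad) or "gdd x evi2 interaction")
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    coeffs = HLMCoefficients(*beta)
    pred = X @ beta
    return HLMFit(
        coefficients=coeffs,
        r2=r2_adjusted(y, pred, p=3),
        nrmse_pct=nrmse(y, pred),
        n=len(samples),
    )


def plot_agb_from_sampling(
    total_dry_mass_20stems: float,
    stems_per_hectare: float,
    scale: float = 1e-6,
) -> float:
    """Convert a 20-stem destructive sample to plot AGB via ``(D*n*15)/20``.

    ``scale`` is an explicit unit-normalisation constant: the raw formula on
    grams and stems per hectare yields grams per hectare x 15, and the
    default ``1e-6`` converts g to t so the result is in t/ha.  It is kept
    explicit because the published constants (15, 20) do not dimensionally
    produce t/ha on their own.
    """
    if total_dry_mass_20stems < 0 or stems_per_hectare < 0 or scale < 0:
        raise ValueError("inputs must be non-negative")
    return total_dry_mass_20stems * stems_per_hectare * 15.0 / 20.0 * scale
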