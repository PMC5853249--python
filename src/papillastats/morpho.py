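"""Morphometric helpers: wall thickness, remodelled-cell classification,
papilla spacing geometry, bundle orientation proportions, and the lagged
correlation between remodelling and papilla time courses."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spatial import BundleSet

__all__ = [
    "WallMeasurement",
    "TimeSeriesPair",
    "mean_wall_thickness",
    "classify_remodelled",
    "papilla_gap",
    "orientation_proportions",
    "lagged_r2",
]


@dataclass(frozen=True)
class WallMeasurement:
    """Cross-sectional wall area (nm^2) over a cell width (nm).

    The uniform wall layer is uneven across the outer periclinal wall, so
    its average thickness is estimated as area / width (nm^2 / nm = nm).
    """

    cross_sectional_area: float
    cell_width: float

    def __post_init__(self) -> None:
        if not (self.cross_sectional_area > 0 and self.cell_width > 0):
            raise ValueError("area and width must be positive")


@dataclass(frozen=True)
class TimeSeriesPair:
    """Two %-of-cells time courses on a common hourly grid."""

    time_h: np.ndarray
    series_a: np.ndarray  # % cells with remodelled actin
    series_b: np.ndarray  # % cells with WI papillae

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        a = np.asarray(self.series_a, dtype=float)
        b = np.asarray(self.series_b, dtype=float)
        if not (t.shape == a.shape == b.shape):
            raise ValueError("grids and series must share one shape")
        for s in (a, b):
            if np.any((s < 0) | (s > 100)):
                raise ValueError("percentages must lie in [0, 100]")
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "series_a", a)
        object.__setattr__(self, "series_b", b)


def mean_wall_thickness(m: WallMeasurement) -> float:
    """Average wall thickness in nm: cross-sectional area / cell width."""
    return m.cross_sectional_area / m.cell_width


def classify_remodelled(fraction_short_bundle_interface: float) -> bool:
    """A cell counts as remodelled iff short bundles occupy strictly more
    than half of its outer periclinal wall/cytoplasmic interface."""
    f = fraction_short_bundle_interface
    if not 0.0 <= f <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    return f > 0.5


def papilla_gap(spacing: float, diameter: float) -> float:
    """Clear distance (nm) between neighbouring papilla flanks.

    1.5 µm centre-to-centre spacing minus the 380 nm papilla diameter
    leaves ~1.1 µm — the length of the short bundles that fit between
    adjoining papillae.
    """
    if not spacing > diameter:
        raise ValueError("spacing must exceed diameter")
    return spacing - diameter


def orientation_proportions(bundles: BundleSet) -> tuple[float, float]:
    """(% horizontal, % vertical) of the linear bundles.

    Verticality is an upstream flag on each segment (through-plane
    bundles appear as dots of bundle-scale diameter); percentages sum
    to 100.
    """
    linear = bundles.linear_segments()
    if not linear:
        raise ValueError("orientation proportions need >= 1 linear bundle")
    n = len(linear)
    n_vert = sum(1 for s in linear if s.orientation == "vertical")
    return 100.0 * (n - n_vert) / n, 100.0 * n_vert / n


def lagged_r2(
    pair: TimeSeriesPair, lag_grid: Sequence[float]
) -> tuple[float, float]:
    """Best lag (h) and squared Pearson correlation between the series.

    For each candidate lag, series_b is shifted earlier by that lag
    (b(t + lag) compared against a(t)) via linear interpolation on the
    overlapping part of the grid; returns the lag maximising R^2 (first
    maximum on ties) and that R^2.  Requires >= 3 overlapping points at
    every candidate lag.
    """
    lags = np.asarray(list(lag_grid), dtype=float)
    if lags.size == 0:
        raise ValueError("lag_grid must be non-empty")
    t = pair.time_h
    best_lag, best_r2 = None, -np.inf
    for lag in lags:
        shifted_t = t + lag
        ok = (shifted_t >= t[0]) & (shifted_t <= t[-1])
        if ok.sum() < 3:
            raise ValueError(f"fewer than 3 overlapping points at lag {lag}")
        a = pair.series_a[ok]
        b = np.interp(shifted_t[ok], t, pair.series_b)
        if np.std(a) == 0 or np.std(b) == 0:
            r2 = 1.0 if np.allclose(a, a[0]) and np.allclose(b, b[0]) else 0.0
        else:
            r2 = float(np.corrcoef(a, b)[0, 1] ** 2)
        if r2 > best_r2:
            best_lag, best_r2 = float(lag), r2
    return best_lag, best_r2
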