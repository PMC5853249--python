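"""Monte-Carlo test of spatial association between actin bundle ends and
wall-ingrowth (WI) papillae.

Trans-differentiating transfer cells build finger-like wall ingrowth
papillae (~380 nm diameter) on their outer periclinal wall while the
cortical actin network fragments into short, thin bundles (~1.1 µm x
150 nm).  This module quantifies whether bundle *ends* cluster around
papilla centres beyond what random bundle placement would produce.

The statistic is the percentage of papillae that have at least one
linear-bundle endpoint strictly within a distance threshold (default
400 nm) of their centre.  The null model keeps the papillae fixed at
their measured coordinates and re-places the same number of bundles,
with their measured lengths, uniformly at random inside the cell's
observation window; the single-tail p-value is the proportion of random
placements that reach an association percentage at least as high as the
observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

# Field-scale defaults (nm unless stated otherwise)
DEFAULT_THRESHOLD_NM = 400.0
DEFAULT_N_SIMS = 1000
DEFAULT_PAPILLA_DIAMETER_NM = 380.0
MAX_REJECTION_DRAWS = 10**6

__all__ = [
    "CellRegion",
    "PapillaPattern",
    "BundleSegment",
    "BundleSet",
    "AssociationResult",
    "CohortSummary",
    "count_associated_papillae",
    "place_random_bundles",
    "monte_carlo_test",
    "aggregate_cells",
]


@dataclass(frozen=True)
class CellRegion:
    """Axis-aligned rectangular observation window, origin at (0, 0).

    Represents the paradermal focal plane of one adaxial epidermal cell:
    ``width`` runs along the cell's long axis, ``height`` along the short
    axis, both in nm.
    """

    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError("region width and height must be positive")

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean mask of which (..., 2) points lie inside the window."""
        xy = np.asarray(xy, dtype=float)
        return (
            (xy[..., 0] >= 0.0)
            & (xy[..., 0] <= self.width)
            & (xy[..., 1] >= 0.0)
            & (xy[..., 1] <= self.height)
        )


@dataclass(frozen=True)
class PapillaPattern:
    """Fixed point set of papilla centres (nm) with a common diameter.

    The centres are measured observations and are never resampled by the
    null model.
    """

    centres: np.ndarray
    papilla_diameter: float = DEFAULT_PAPILLA_DIAMETER_NM

    def __post_init__(self) -> None:
        centres = np.atleast_2d(np.asarray(self.centres, dtype=float))
        if centres.size == 0:
            centres = centres.reshape(0, 2)
        if centres.shape[1] != 2:
            raise ValueError("centres must be an (n, 2) array of nm coordinates")
        object.__setattr__(self, "centres", centres)
        if not self.papilla_diameter > 0:
            raise ValueError("papilla_diameter must be positive")

    @property
    def n(self) -> int:
        return self.centres.shape[0]


@dataclass(frozen=True)
class BundleSegment:
    """One actin bundle in the focal plane.

    Linear bundles carry two endpoints ``p1``/``p2`` (nm); circular
    bundles (actin rings around initiating papillae) carry their centre in
    ``p1`` and the ring diameter in ``ring_diameter``.  Only linear
    bundles have ends and therefore only they enter the association
    statistic.  ``orientation`` is an upstream flag: ``"horizontal"``
    for in-plane bundles, ``"vertical"`` for through-plane bundles that
    appear as dots.
    """

    shape: str  # "linear" | "circular"
    p1: tuple[float, float]
    p2: tuple[float, float] | None = None
    diameter: float = 150.0
    ring_diameter: float | None = None
    orientation: str = "horizontal"

    def __post_init__(self) -> None:
        if self.shape not in ("linear", "circular"):
            raise ValueError(f"unknown bundle shape {self.shape!r}")
        if not self.diameter > 0:
            raise ValueError("bundle diameter must be positive")
        if self.orientation not in ("horizontal", "vertical"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.shape == "linear":
            if self.p2 is None:
                raise ValueError("linear bundle requires two endpoints")
            if self.length <= 0:
                raise ValueError("linear bundle must have positive length")
        else:
            if self.ring_diameter is None or not self.ring_diameter > 0:
                raise ValueError("circular bundle requires positive ring_diameter")

    @property
    def length(self) -> float:
        """Euclidean end-to-end length (nm); circumference for rings."""
        if self.shape == "circular":
            return math.pi * float(self.ring_diameter)
        return math.hypot(
            self.p2[0] - self.p1[0], self.p2[1] - self.p1[1]
        )


@dataclass(frozen=True)
class BundleSet:
    """Actin bundles of one cell, referenced to its observation window."""

    segments: tuple[BundleSegment, ...]
    region: CellRegion

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        for seg in self.segments:
            pts = [seg.p1] if seg.shape == "circular" else [seg.p1, seg.p2]
            if not np.all(self.region.contains(np.asarray(pts))):
                raise ValueError("bundle segment lies outside the cell region")

    def linear_segments(self) -> tuple[BundleSegment, ...]:
        return tuple(s for s in self.segments if s.shape == "linear")

    def linear_endpoints(self) -> np.ndarray:
        """(2k, 2) array of all endpoints of the k linear segments."""
        linear = self.linear_segments()
        if not linear:
            return np.empty((0, 2))
        return np.array(
            [p for seg in linear for p in (seg.p1, seg.p2)], dtype=float
        )

    def linear_dims(self) -> list[tuple[float, float]]:
        """(length, diameter) of each linear segment, the null's inputs."""
        return [(s.length, s.diameter) for s in self.linear_segments()]


@dataclass(frozen=True)
class AssociationResult:
    """Observed association, its Monte-Carlo null, and the p-value."""

    n_papillae: int
    n_associated: int
    percent_observed: float
    null_percents: np.ndarray
    p_value: float
    n_sims: int
    threshold: float
    seed: int
    cell_id: str = ""

    @property
    def p_display(self) -> str:
        """Report string: a raw 0 renders as '< 1/n_sims'."""
        if self.p_value == 0.0:
            return f"< {1.0 / self.n_sims:g}"
        return f"{self.p_value:g}"


@dataclass(frozen=True)
class CohortSummary:
    """Mean +/- SE of the per-cell association percentages."""

    per_cell_results: tuple[AssociationResult, ...]
    mean_percent: float
    se_percent: float
    n_cells: int


# ---------------------------------------------------------------------------
# Observed statistic


def _associated_flags(
    centres: np.ndarray, endpoints: np.ndarray, threshold: float
) -> np.ndarray:
    if endpoints.shape[0] == 0:
        return np.zeros(centres.shape[0], dtype=bool)
    d = cdist(centres, endpoints)
    return (d < threshold).any(axis=1)


def count_associated_papillae(
    papillae: PapillaPattern,
    bundles: BundleSet,
    threshold: float = DEFAULT_THRESHOLD_NM,
) -> tuple[int, np.ndarray]:
    """Count papillae with a linear-bundle end strictly within ``threshold``.

    A papilla is associated iff at least one endpoint of at least one
    linear bundle lies at Euclidean distance < threshold (nm) from its
    centre.  Circular bundles have no ends and are ignored.  Returns the
    count and the per-papilla boolean flags.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    if papillae.n == 0:
        raise ValueError("association statistic undefined for zero papillae")
    flags = _associated_flags(
        papillae.centres, bundles.linear_endpoints(), threshold
    )
    return int(flags.sum()), flags


# ---------------------------------------------------------------------------
# Null model: random placement of the measured bundles


def _sample_segment_endpoints(
    region: CellRegion,
    lengths: np.ndarray,
    rng: np.random.Generator,
    edge_mode: str = "contain",
    max_draws: int = MAX_REJECTION_DRAWS,
) -> np.ndarray:
    """Sample (n, 2, 2) endpoint pairs: midpoint uniform in the window,
    orientation uniform on [0, pi), conditioned (for ``contain``) on the
    whole segment lying inside the window by rejection sampling.

    ``torus`` mode skips the rejection and wraps endpoints periodically.
    """
    n = lengths.shape[0]
    out = np.empty((n, 2, 2), dtype=float)
    if n == 0:
        return out
    if edge_mode == "torus":
        mid = rng.uniform((0, 0), (region.width, region.height), size=(n, 2))
        theta = rng.uniform(0.0, math.pi, size=n)
        half = np.stack(
            [np.cos(theta), np.sin(theta)], axis=1
        ) * (lengths[:, None] / 2.0)
        out[:, 0] = np.mod(mid - half, (region.width, region.height))
        out[:, 1] = np.mod(mid + half, (region.width, region.height))
        return out
    if edge_mode != "contain":
        raise ValueError(f"unknown edge_mode {edge_mode!r}")
    if np.any(lengths >= min(region.width, region.height)):
        raise ValueError(
            "segment length must be smaller than both window sides"
        )
    pending = np.arange(n)
    draws = 0
    while pending.size:
        m = pending.size
        draws += m
        if draws > max_draws:
            raise RuntimeError(
                f"rejection sampling exceeded {max_draws} draws"
            )
        mid = rng.uniform((0, 0), (region.width, region.height), size=(m, 2))
        theta = rng.uniform(0.0, math.pi, size=m)
        half = np.stack(
            [np.cos(theta), np.sin(theta)], axis=1
        ) * (lengths[pending, None] / 2.0)
        p1 = mid - half
        p2 = mid + half
        ok = region.contains(p1) & region.contains(p2)
        idx = pending[ok]
        out[idx, 0] = p1[ok]
        out[idx, 1] = p2[ok]
        pending = pending[~ok]
    return out


def place_random_bundles(
    region: CellRegion,
    dims: Sequence[tuple[float, float]],
    rng: np.random.Generator,
    edge_mode: str = "contain",
) -> BundleSet:
    """Lay down linear bundles of prescribed (length, diameter) at random.

    Midpoints are uniform over the window and orientations uniform on
    [0, pi), conditioned on full containment (the default) — the null
    model of the association test.
    """
    dims_arr = np.asarray([(l, d) for l, d in dims], dtype=float).reshape(-1, 2)
    if np.any(dims_arr <= 0):
        raise ValueError("lengths and diameters must be positive")
    ends = _sample_segment_endpoints(
        region, dims_arr[:, 0], rng, edge_mode=edge_mode
    )
    segments = [
        BundleSegment(
            shape="linear",
            p1=tuple(ends[i, 0]),
            p2=tuple(ends[i, 1]),
            diameter=float(dims_arr[i, 1]),
        )
        for i in range(dims_arr.shape[0])
    ]
    return BundleSet(segments=tuple(segments), region=region)


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    # substream keyed on (seed, replicate index) for reproducibility
    return np.random.default_rng(np.random.SeedSequence([seed, replicate]))


def monte_carlo_test(
    papillae: PapillaPattern,
    observed_bundles: BundleSet,
    n_sims: int = DEFAULT_N_SIMS,
    threshold: float = DEFAULT_THRESHOLD_NM,
    seed: int = 0,
    edge_mode: str = "contain",
    pseudo_count: bool = False,
    cell_id: str = "",
) -> AssociationResult:
    """Single-tail Monte-Carlo randomization test for one cell.

    The papillae stay at their measured coordinates; each replicate
    re-places the observed linear bundles (same lengths, same count)
    uniformly at random and recomputes the association percentage.  The
    p-value is the proportion of replicates with an association
    percentage >= the observed one; ``pseudo_count=True`` uses the
    (k+1)/(n+1) estimator instead of the raw proportion.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    n_obs, _ = count_associated_papillae(papillae, observed_bundles, threshold)
    n_pap = papillae.n
    percent_observed = 100.0 * n_obs / n_pap

    dims = observed_bundles.linear_dims()
    lengths = np.asarray([l for l, _ in dims], dtype=float)
    region = observed_bundles.region
    centres = papillae.centres

    null_counts = np.empty(n_sims, dtype=np.int64)
    for rep in range(n_sims):
        rng = _replicate_rng(seed, rep)
        ends = _sample_segment_endpoints(
            region, lengths, rng, edge_mode=edge_mode
        ).reshape(-1, 2)
        null_counts[rep] = _associated_flags(centres, ends, threshold).sum()

    k = int((null_counts >= n_obs).sum())  # tie-safe: compare counts
    if pseudo_count:
        p_value = (k + 1) / (n_sims + 1)
    else:
        p_value = k / n_sims
    return AssociationResult(
        n_papillae=n_pap,
        n_associated=n_obs,
        percent_observed=percent_observed,
        null_percents=100.0 * null_counts / n_pap,
        p_value=p_value,
        n_sims=n_sims,
        threshold=threshold,
        seed=seed,
        cell_id=cell_id,
    )


def aggregate_cells(results: Iterable[AssociationResult]) -> CohortSummary:
    """Mean and SE (sample sd / sqrt(n)) of per-cell association percentages."""
    results = tuple(results)
    if not results:
        raise ValueError("aggregate_cells requires at least one cell result")
    percents = np.array([r.percent_observed for r in results])
    n = percents.size
    mean = float(percents.mean())
    se = 0.0 if n == 1 else float(percents.std(ddof=1) / math.sqrt(n))
    return CohortSummary(
        per_cell_results=results,
        mean_percent=mean,
        se_percent=se,
        n_cells=n,
    )
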