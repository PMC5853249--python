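"""Synthetic data with the statistical structure the analyses assume.

No coordinate data from the original micrographs are deposited, so the
pipeline is exercised on generated cells: papilla centres on a jittered
square lattice at ~1.5 µm pitch, linear actin bundles (~1.1 µm x 150 nm)
of which a controllable fraction has an end planted within the
association radius of a papilla, per-cell fluorescence tables with a
BFA-like plasma-membrane baseline, and lagged logistic time courses of
actin remodelling vs papilla appearance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .spatial import (
    BundleSegment,
    BundleSet,
    CellRegion,
    PapillaPattern,
    _sample_segment_endpoints,
)

REGIONS = ("outer_periclinal", "anticlinal", "inner_periclinal")

__all__ = [
    "PapillaGenConfig",
    "BundleGenConfig",
    "FluorGenConfig",
    "REGIONS",
    "generate_papilla_lattice",
    "generate_bundles",
    "generate_fluorescence_dataset",
    "generate_timecourse",
]


@dataclass(frozen=True)
class PapillaGenConfig:
    """Geometry of the papilla point pattern.

    Defaults follow the measured papilla geometry: 380 nm diameter at
    1.5 µm centre-to-centre spacing (a density of ~4.4e5 papillae per
    mm^2 of outer periclinal wall).
    """

    region: CellRegion
    spacing: float = 1500.0  # nm, centre-to-centre
    jitter_sd: float = 0.0  # nm, isotropic Gaussian jitter per site
    papilla_diameter: float = 380.0  # nm

    def __post_init__(self) -> None:
        if not self.spacing > self.papilla_diameter:
            raise ValueError("spacing must exceed the papilla diameter")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


@dataclass(frozen=True)
class BundleGenConfig:
    """Short, thin linear bundle population of one cell.

    Length/diameter means follow the measured 15-h bundle dimensions
    (1.1 µm x 150 nm); the printed uncertainties are standard errors, so
    the population sds here (100 and 40 nm) are generator choices.
    ``assoc_fraction`` is the fraction of bundles constructed with one
    end inside the attachment disc (radius ``attach_radius``) around a
    randomly chosen papilla; the rest are placed uniformly at random.
    """

    n_bundles: int
    assoc_fraction: float = 0.6
    length_mean: float = 1100.0
    length_sd: float = 100.0
    diameter_mean: float = 150.0
    diameter_sd: float = 40.0
    attach_radius: float = 400.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.assoc_fraction <= 1.0:
            raise ValueError("assoc_fraction must be in [0, 1]")
        if self.length_mean <= 0 or self.diameter_mean <= 0:
            raise ValueError("means must be positive")
        if self.length_sd < 0 or self.diameter_sd < 0:
            raise ValueError("sds must be >= 0")
        if self.n_bundles < 0:
            raise ValueError("n_bundles must be >= 0")
        if self.attach_radius <= 0:
            raise ValueError("attach_radius must be positive")


@dataclass(frozen=True)
class FluorGenConfig:
    """Per-region fluorescence means for a treatment and its BFA baseline.

    Mirrors the sampling design of the trafficking tables: 25 cells per
    cotyledon across 4 replicate cotyledons, with independent Gaussian
    cell-to-cell noise.
    """

    treatment_means: dict[str, float]
    bfa_means: dict[str, float]
    cell_sd: float = 50.0
    n_cells: int = 25
    n_cotyledons: int = 4
    treatment_label: str = "treatment"
    bfa_label: str = "BFA"

    def __post_init__(self) -> None:
        for means in (self.treatment_means, self.bfa_means):
            missing = set(REGIONS) - set(means)
            if missing:
                raise ValueError(f"missing regions: {sorted(missing)}")
        if self.cell_sd < 0:
            raise ValueError("cell_sd must be >= 0")
        if self.n_cells < 1 or self.n_cotyledons < 1:
            raise ValueError("counts must be >= 1")


def generate_papilla_lattice(
    cfg: PapillaGenConfig, seed: int = 0
) -> PapillaPattern:
    """Papilla centres on a jittered square lattice.

    The window is tiled with whole lattice cells of side ``spacing``
    (n = floor(side / spacing) per axis), each contributing one site at
    its centre; sites are jittered by isotropic Gaussian(0, jitter_sd)
    and any point displaced outside the window is dropped.
    """
    nx = int(cfg.region.width // cfg.spacing)
    ny = int(cfg.region.height // cfg.spacing)
    if nx < 1 or ny < 1:
        raise ValueError("window holds no lattice site at this spacing")
    xs = (np.arange(nx) + 0.5) * cfg.spacing
    ys = (np.arange(ny) + 0.5) * cfg.spacing
    grid = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1).reshape(-1, 2)
    rng = np.random.default_rng(seed)
    if cfg.jitter_sd > 0:
        grid = grid + rng.normal(0.0, cfg.jitter_sd, size=grid.shape)
        grid = grid[cfg.region.contains(grid)]
    if grid.shape[0] == 0:
        raise ValueError("all lattice sites jittered out of the window")
    return PapillaPattern(
        centres=grid, papilla_diameter=cfg.papilla_diameter
    )


def _truncated_normal(
    mean: float, sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Normal(mean, sd) truncated to (0, inf); degenerate at sd == 0."""
    if sd == 0:
        return np.full(size, mean)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(
        a, np.inf, loc=mean, scale=sd, size=size, random_state=rng
    )


def generate_bundles(
    papillae: PapillaPattern,
    region: CellRegion,
    cfg: BundleGenConfig,
    seed: int = 0,
) -> BundleSet:
    """Linear bundles, a fraction of them planted next to papillae.

    Each bundle independently: with probability ``assoc_fraction`` one
    endpoint is placed uniformly in the disc of radius ``attach_radius``
    around a uniformly chosen papilla centre and the other endpoint at
    the sampled length in a uniform direction (direction redrawn until
    the segment is contained in the window); otherwise the bundle is
    placed exactly as the Monte-Carlo null places it.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_bundles
    if cfg.assoc_fraction > 0 and papillae.n == 0:
        raise ValueError("assoc_fraction > 0 requires papillae")
    lengths = _truncated_normal(cfg.length_mean, cfg.length_sd, n, rng)
    diameters = _truncated_normal(cfg.diameter_mean, cfg.diameter_sd, n, rng)
    if np.any(lengths >= min(region.width, region.height)):
        raise ValueError("sampled bundle length exceeds the window")
    attached = rng.random(n) < cfg.assoc_fraction
    segments: list[BundleSegment] = []
    for i in range(n):
        if attached[i]:
            p1, p2 = _place_attached(
                papillae, region, float(lengths[i]), cfg.attach_radius, rng
            )
        else:
            ends = _sample_segment_endpoints(
                region, lengths[i : i + 1], rng
            )[0]
            p1, p2 = tuple(ends[0]), tuple(ends[1])
        segments.append(
            BundleSegment(
                shape="linear", p1=p1, p2=p2, diameter=float(diameters[i])
            )
        )
    return BundleSet(segments=tuple(segments), region=region)


def _place_attached(
    papillae: PapillaPattern,
    region: CellRegion,
    length: float,
    attach_radius: float,
    rng: np.random.Generator,
    max_draws: int = 10**5,
) -> tuple[tuple[float, float], tuple[float, float]]:
    centres = papillae.centres
    for _ in range(max_draws):
        c = centres[rng.integers(centres.shape[0])]
        r = attach_radius * math.sqrt(rng.random())
        phi = rng.uniform(0.0, 2.0 * math.pi)
        p1 = c + r * np.array([math.cos(phi), math.sin(phi)])
        if not region.contains(p1):
            continue
        # redraw orientation until the far endpoint is contained
        for _ in range(64):
            theta = rng.uniform(0.0, 2.0 * math.pi)
            p2 = p1 + length * np.array([math.cos(theta), math.sin(theta)])
            if region.contains(p2):
                return tuple(p1), tuple(p2)
    raise RuntimeError("could not place attached bundle inside the window")


def generate_fluorescence_dataset(
    cfg: FluorGenConfig, seed: int = 0
) -> pd.DataFrame:
    """Long-format per-cell intensity table for a treatment and its BFA
    baseline: columns treatment, cotyledon, cell, region, intensity."""
    rng = np.random.default_rng(seed)
    rows = []
    for label, means in (
        (cfg.treatment_label, cfg.treatment_means),
        (cfg.bfa_label, cfg.bfa_means),
    ):
        for cot in range(cfg.n_cotyledons):
            for cell in range(cfg.n_cells):
                for region in REGIONS:
                    rows.append(
                        {
                            "treatment": label,
                            "cotyledon": cot,
                            "cell": cell,
                            "region": region,
                            "intensity": means[region]
                            + rng.normal(0.0, cfg.cell_sd),
                        }
                    )
    return pd.DataFrame(rows)


def generate_timecourse(
    lag_h: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    t_max: float = 15.0,
    dt: float = 1.0,
    midpoint_h: float = 7.0,
    rate_h: float = 1.5,
) -> pd.DataFrame:
    """Two lagged logistic %-of-cells time courses on a 0..t_max grid.

    ``pct_remodelled`` follows 100 / (1 + exp(-(t - midpoint)/rate));
    ``pct_papillae`` is the same logistic displaced ``lag_h`` hours later,
    with independent additive Gaussian noise on both series.
    """
    if lag_h < 0:
        raise ValueError("lag_h must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_max + dt / 2, dt)

    def logistic(x: np.ndarray) -> np.ndarray:
        return 100.0 / (1.0 + np.exp(-(x - midpoint_h) / rate_h))

    a = logistic(t)
    b = logistic(t - lag_h)
    if noise_sd > 0:
        # percentages of cells cannot leave [0, 100]
        a = np.clip(a + rng.normal(0.0, noise_sd, size=t.shape), 0.0, 100.0)
        b = np.clip(b + rng.normal(0.0, noise_sd, size=t.shape), 0.0, 100.0)
    return pd.DataFrame(
        {"time_h": t, "pct_remodelled": a, "pct_papillae": b}
    )
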