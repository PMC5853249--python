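"""Membrane surface-area budget of wall-ingrowth papilla construction.

A growing papilla is modelled as a cylinder of diameter ``d`` protruding
height ``h`` into the cytoplasm, capped either flat or hemispherically.
Exocytotic vesicles (diameter ``d_v``) deliver the wall volume that is
not synthesized in situ at the plasma membrane (callose fraction
``f_c``); every unit of delivered volume brings vesicle membrane at the
sphere's surface-to-volume ratio 6/d_v.  The membrane that remains on
the finished papilla surface is far less than the membrane fused, and
the balance must be retrieved by endocytosis:

    retrieval fraction R = 1 - A_retained / A_fused,
    A_fused = 6 * (1 - f_c) * V_papilla / d_v.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "PapillaGeometry",
    "BudgetParams",
    "MembraneBudget",
    "compute_budget",
    "calibrate_budget",
]


@dataclass(frozen=True)
class PapillaGeometry:
    """Papilla solid: diameter and protrusion height in nm, cap shape."""

    diameter: float = 380.0
    height: float = 500.0
    cap: str = "flat"  # "flat" | "hemispherical"

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError("diameter must be positive")
        if self.cap not in ("flat", "hemispherical"):
            raise ValueError(f"unknown cap shape {self.cap!r}")
        if self.cap == "hemispherical" and self.height < self.diameter / 2:
            raise ValueError("height must be >= radius for hemispherical cap")
        if self.height <= 0:
            raise ValueError("height must be positive")

    def surface_area(self) -> float:
        """Plasma-membrane area retained on the papilla (nm^2)."""
        d, h = self.diameter, self.height
        if self.cap == "flat":
            return math.pi * d * h + math.pi * d**2 / 4.0
        return math.pi * d * (h - d / 2.0) + math.pi * d**2 / 2.0

    def volume(self) -> float:
        """Papilla wall volume (nm^3) of the same solid."""
        d, h = self.diameter, self.height
        r = d / 2.0
        if self.cap == "flat":
            return math.pi * r**2 * h
        return math.pi * r**2 * (h - r) + (2.0 / 3.0) * math.pi * r**3


@dataclass(frozen=True)
class BudgetParams:
    """Vesicle diameter (nm) and in-situ callose volume fraction."""

    vesicle_diameter: float = 100.0
    callose_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.vesicle_diameter > 0:
            raise ValueError("vesicle_diameter must be positive")
        if not 0.0 <= self.callose_fraction <= 1.0:
            raise ValueError("callose_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class MembraneBudget:
    retained_area: float  # nm^2 left on the papilla surface
    delivered_volume: float  # nm^3 of vesicle-delivered wall material
    fused_area: float  # nm^2 of vesicle membrane fused
    retrieval_fraction: float  # share of fused membrane endocytosed
    clamped: bool = False  # True when A_fused < A_retained forced R = 0


def compute_budget(
    geom: PapillaGeometry, params: BudgetParams
) -> MembraneBudget:
    """Evaluate the exo-/endocytosis membrane budget for one papilla."""
    a_ret = geom.surface_area()
    v_d = (1.0 - params.callose_fraction) * geom.volume()
    a_fus = 6.0 * v_d / params.vesicle_diameter
    if a_fus == 0.0:
        raise ValueError(
            "no membrane fused (callose_fraction = 1); budget undefined"
        )
    r = 1.0 - a_ret / a_fus
    clamped = False
    if r < 0.0:
        warnings.warn(
            "fused membrane smaller than retained membrane; "
            "retrieval fraction clamped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        r, clamped = 0.0, True
    return MembraneBudget(
        retained_area=a_ret,
        delivered_volume=v_d,
        fused_area=a_fus,
        retrieval_fraction=r,
        clamped=clamped,
    )


def calibrate_budget(
    geom: PapillaGeometry,
    target_r: float,
    free_param: str,
    vesicle_diameter: float | None = None,
    callose_fraction: float | None = None,
    rtol: float = 1e-9,
) -> float:
    """Solve the budget equation for one unknown parameter.

    Finds the ``free_param`` value ("vesicle_diameter" or
    "callose_fraction", the other held fixed) at which the retrieval
    fraction equals ``target_r``, by bisection (Brent) to relative
    tolerance ``rtol``.  R is strictly decreasing in both parameters, so
    the solution is unique when it exists.
    """
    if not 0.0 < target_r < 1.0:
        raise ValueError("target_r must lie in (0, 1)")

    a_ret = geom.surface_area()
    v_p = geom.volume()

    def r_of(dv: float, fc: float) -> float:
        return 1.0 - a_ret * dv / (6.0 * (1.0 - fc) * v_p)

    if free_param == "vesicle_diameter":
        if callose_fraction is None:
            raise ValueError("callose_fraction must be fixed")
        fc = callose_fraction
        if not 0.0 <= fc < 1.0:
            raise ValueError("fixed callose_fraction must lie in [0, 1)")
        hi = 6.0 * (1.0 - fc) * v_p / a_ret  # d_v at which R hits 0
        f = lambda dv: r_of(dv, fc) - target_r
    elif free_param == "callose_fraction":
        if vesicle_diameter is None:
            raise ValueError("vesicle_diameter must be fixed")
        dv = vesicle_diameter
        if not dv > 0:
            raise ValueError("fixed vesicle_diameter must be positive")
        if r_of(dv, 0.0) < target_r:
            raise ValueError(
                "target retrieval fraction infeasible at this vesicle size"
            )
        f = lambda fc: r_of(dv, fc) - target_r
        hi = 1.0 - 1e-15
    else:
        raise ValueError(f"unknown free_param {free_param!r}")

    lo = 1e-15
    if f(lo) * f(hi) > 0:
        raise ValueError("target retrieval fraction infeasible")
    return float(brentq(f, lo, hi, rtol=rtol))
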