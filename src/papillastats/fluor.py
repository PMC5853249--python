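"""BFA-baseline correction of FM4-64FX fluorescence and derived summaries.

FM4-64FX labels endocytosed membrane, but in the narrow cytoplasm of
trans-differentiating epidermal cells its plasma-membrane signal cannot
be separated optically from vesicle signal.  Cotyledons cultured on
Brefeldin A (BFA), which blocks exo-/endocytosis, provide a
plasma-membrane-only baseline: cytoplasmic vesicle fluorescence is
estimated as treatment minus BFA, with the SE of an unpaired difference
of means, sqrt(se1^2 + se2^2).  Regional totals and the derived
fold-increase / percent-decline / percent-inhibition statistics follow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

REGIONS = ("outer_periclinal", "anticlinal", "inner_periclinal")

__all__ = [
    "RegionalIntensity",
    "CorrectedIntensity",
    "bfa_correct",
    "correct_table",
    "table_totals",
    "relative_change",
    "summarize_cells",
]


@dataclass(frozen=True)
class RegionalIntensity:
    """Mean +/- SE fluorescence (arbitrary units) of one cell region."""

    treatment: str
    region: str
    mean: float
    se: float
    n: int = 1

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class CorrectedIntensity:
    """Baseline-corrected regional mean: clipped at 0 for reporting, with
    the unclipped difference retained for diagnostics."""

    treatment: str
    region: str
    mean: float
    se: float
    raw_mean: float


def bfa_correct(
    treatment: RegionalIntensity, bfa: RegionalIntensity
) -> CorrectedIntensity:
    """Subtract the BFA plasma-membrane baseline from a regional mean.

    corrected mean = max(0, treatment - bfa); SE = sqrt(se_t^2 + se_b^2)
    (unpaired difference of independent means).  Negative differences are
    clipped to 0 — the trafficking tables print exact 0 entries — while
    the raw difference is kept on the result.
    """
    if treatment.region != bfa.region:
        raise ValueError(
            f"region mismatch: {treatment.region!r} vs {bfa.region!r}"
        )
    raw = treatment.mean - bfa.mean
    se = math.sqrt(treatment.se**2 + bfa.se**2)
    return CorrectedIntensity(
        treatment=treatment.treatment,
        region=treatment.region,
        mean=max(0.0, raw),
        se=se,
        raw_mean=raw,
    )


def correct_table(
    table: pd.DataFrame, bfa_label: str = "BFA"
) -> pd.DataFrame:
    """BFA-correct a `treatment,region,mean,se,n` table.

    Every non-BFA treatment is corrected region-by-region against the
    ``bfa_label`` rows; returns columns treatment, region, mean, se,
    raw_mean.
    """
    required = {"treatment", "region", "mean", "se"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    bfa_rows = table[table["treatment"] == bfa_label]
    if bfa_rows.empty:
        raise ValueError(f"no rows with treatment == {bfa_label!r}")
    bfa_by_region = {
        row["region"]: RegionalIntensity(
            treatment=bfa_label,
            region=row["region"],
            mean=float(row["mean"]),
            se=float(row["se"]),
            n=int(row.get("n", 1)),
        )
        for _, row in bfa_rows.iterrows()
    }
    out = []
    for _, row in table[table["treatment"] != bfa_label].iterrows():
        region = row["region"]
        if region not in bfa_by_region:
            raise ValueError(f"no BFA baseline for region {region!r}")
        treat = RegionalIntensity(
            treatment=row["treatment"],
            region=region,
            mean=float(row["mean"]),
            se=float(row["se"]),
            n=int(row.get("n", 1)),
        )
        c = bfa_correct(treat, bfa_by_region[region])
        out.append(
            {
                "treatment": c.treatment,
                "region": c.region,
                "mean": c.mean,
                "se": c.se,
                "raw_mean": c.raw_mean,
            }
        )
    return pd.DataFrame(out)


def table_totals(corrected: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment totals over the three cell regions.

    total mean = sum of regional means; total SE = sqrt(sum of SE^2).
    Errors if any treatment is missing a region.
    """
    out = []
    for treatment, grp in corrected.groupby("treatment", sort=False):
        present = set(grp["region"])
        missing = set(REGIONS) - present
        if missing:
            raise ValueError(
                f"treatment {treatment!r} missing regions {sorted(missing)}"
            )
        out.append(
            {
                "treatment": treatment,
                "mean": float(grp["mean"].sum()),
                "se": float(np.sqrt((grp["se"] ** 2).sum())),
            }
        )
    return pd.DataFrame(out)


def relative_change(
    reference_total: float, new_total: float, mode: str, raw: bool = False
) -> float:
    """Derived change statistic between two totals.

    fold_increase: (new - ref)/ref, reported to 1 decimal.
    percent_decline: 100*(ref - new)/ref, reported to 1 decimal.
    percent_inhibition: 100*(ref - new)/ref, reported to the nearest
    integer.  ``raw=True`` returns the unrounded value.
    """
    if not reference_total > 0:
        raise ValueError("reference_total must be positive")
    if mode == "fold_increase":
        value = (new_total - reference_total) / reference_total
        return value if raw else round(value, 1)
    if mode == "percent_decline":
        value = 100.0 * (reference_total - new_total) / reference_total
        return value if raw else round(value, 1)
    if mode == "percent_inhibition":
        value = 100.0 * (reference_total - new_total) / reference_total
        return value if raw else float(round(value))
    raise ValueError(f"unknown mode {mode!r}")


def summarize_cells(raw: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-cell intensity table to per-treatment regional
    mean +/- SE.

    Cells are first averaged within each cotyledon; the reported mean and
    SE are the mean and standard error (sample sd / sqrt(n)) across the
    replicate cotyledons, matching the tables' n = number of cotyledons.
    """
    required = {"treatment", "cotyledon", "region", "intensity"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    per_cot = (
        raw.groupby(["treatment", "region", "cotyledon"], sort=False)[
            "intensity"
        ]
        .mean()
        .reset_index()
    )
    out = []
    for (treatment, region), grp in per_cot.groupby(
        ["treatment", "region"], sort=False
    ):
        vals = grp["intensity"].to_numpy()
        n = vals.size
        se = 0.0 if n == 1 else float(vals.std(ddof=1) / math.sqrt(n))
        out.append(
            {
                "treatment": treatment,
                "region": region,
                "mean": float(vals.mean()),
                "se": se,
                "n": n,
            }
        )
    return pd.DataFrame(out)
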