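"""Readers/writers for the CSV/TSV/JSON interfaces and run configuration.

Coordinates are stored as floats in nm (never µm) with '.' decimals and a
UTF-8 header row; cell_id is an opaque string.  Every run report echoes
the fully resolved configuration and the seed so runs are replayable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .spatial import (
    AssociationResult,
    BundleSegment,
    BundleSet,
    CellRegion,
    CohortSummary,
    PapillaPattern,
    aggregate_cells,
)

logger = logging.getLogger("papillastats")

PAPILLA_COLUMNS = ["cell_id", "x_nm", "y_nm"]
BUNDLE_COLUMNS = [
    "cell_id",
    "shape",
    "x1_nm",
    "y1_nm",
    "x2_nm",
    "y2_nm",
    "diameter_nm",
]

__all__ = [
    "RunConfig",
    "read_pattern_tables",
    "write_pattern_tables",
    "write_report",
    "read_transcript_table",
]


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters of one association run."""

    threshold_nm: float = 400.0
    n_sims: int = 1000
    seed: int = 0
    edge_mode: str = "contain"
    pseudo_count: bool = False
    papilla_diameter_nm: float = 380.0

    def __post_init__(self) -> None:
        if not self.threshold_nm > 0:
            raise ValueError("threshold_nm must be positive")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if self.edge_mode not in ("contain", "torus"):
            raise ValueError(f"unknown edge_mode {self.edge_mode!r}")


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def _coerce_float(df: pd.DataFrame, cols: list[str], path) -> None:
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
            raise ValueError(
                f"{path}: non-numeric value in column {c!r} near line {line}"
            )
        df[c] = coerced


def read_pattern_tables(
    papillae_path,
    bundles_path,
    papilla_diameter: float = 380.0,
    region: CellRegion | None = None,
) -> dict[str, tuple[PapillaPattern, BundleSet]]:
    """Load per-cell papilla/bundle coordinate tables.

    Papillae CSV: ``cell_id,x_nm,y_nm``.  Bundles CSV:
    ``cell_id,shape,x1_nm,y1_nm,x2_nm,y2_nm,diameter_nm`` where circular
    bundles store their centre in (x1, y1) and ring diameter in x2.  If
    ``region`` is None, each cell's window is the tight axis-aligned
    bounding box of its own coordinates (origin kept at 0,0).  Returns an
    ordered dict keyed by cell_id.
    """
    pap = pd.read_csv(papillae_path)
    _require_columns(pap, PAPILLA_COLUMNS, papillae_path)
    _coerce_float(pap, ["x_nm", "y_nm"], papillae_path)
    bnd = pd.read_csv(bundles_path)
    _require_columns(bnd, BUNDLE_COLUMNS, bundles_path)
    _coerce_float(
        bnd, ["x1_nm", "y1_nm", "x2_nm", "y2_nm", "diameter_nm"], bundles_path
    )
    bad_shape = ~bnd["shape"].isin(["linear", "circular"])
    if bad_shape.any():
        line = int(bad_shape.idxmax()) + 2
        raise ValueError(
            f"{bundles_path}: unknown shape token near line {line}"
        )

    out: dict[str, tuple[PapillaPattern, BundleSet]] = {}
    for cell_id, grp in pap.groupby("cell_id", sort=False):
        centres = grp[["x_nm", "y_nm"]].to_numpy(dtype=float)
        cell_bnd = bnd[bnd["cell_id"] == cell_id]
        if region is None:
            xs = np.concatenate(
                [centres[:, 0], cell_bnd[["x1_nm", "x2_nm"]].to_numpy().ravel()]
            )
            ys = np.concatenate(
                [centres[:, 1], cell_bnd[["y1_nm", "y2_nm"]].to_numpy().ravel()]
            )
            cell_region = CellRegion(
                width=float(max(xs.max(), 1.0)),
                height=float(max(ys.max(), 1.0)),
            )
        else:
            cell_region = region
        segments = []
        for _, row in cell_bnd.iterrows():
            if row["shape"] == "linear":
                segments.append(
                    BundleSegment(
                        shape="linear",
                        p1=(row["x1_nm"], row["y1_nm"]),
                        p2=(row["x2_nm"], row["y2_nm"]),
                        diameter=row["diameter_nm"],
                    )
                )
            else:
                segments.append(
                    BundleSegment(
                        shape="circular",
                        p1=(row["x1_nm"], row["y1_nm"]),
                        ring_diameter=row["x2_nm"],
                        diameter=row["diameter_nm"],
                    )
                )
        out[str(cell_id)] = (
            PapillaPattern(centres=centres, papilla_diameter=papilla_diameter),
            BundleSet(segments=tuple(segments), region=cell_region),
        )
    return out


def write_pattern_tables(
    cells: dict[str, tuple[PapillaPattern, BundleSet]],
    papillae_path,
    bundles_path,
) -> None:
    """Write per-cell patterns back to the papillae/bundles CSV schema."""
    pap_rows, bnd_rows = [], []
    for cell_id, (papillae, bundles) in cells.items():
        for x, y in papillae.centres:
            pap_rows.append({"cell_id": cell_id, "x_nm": x, "y_nm": y})
        for seg in bundles.segments:
            if seg.shape == "linear":
                bnd_rows.append(
                    {
                        "cell_id": cell_id,
                        "shape": "linear",
                        "x1_nm": seg.p1[0],
                        "y1_nm": seg.p1[1],
                        "x2_nm": seg.p2[0],
                        "y2_nm": seg.p2[1],
                        "diameter_nm": seg.diameter,
                    }
                )
            else:
                bnd_rows.append(
                    {
                        "cell_id": cell_id,
                        "shape": "circular",
                        "x1_nm": seg.p1[0],
                        "y1_nm": seg.p1[1],
                        "x2_nm": seg.ring_diameter,
                        "y2_nm": 0.0,
                        "diameter_nm": seg.diameter,
                    }
                )
    pd.DataFrame(pap_rows, columns=PAPILLA_COLUMNS).to_csv(
        papillae_path, index=False
    )
    pd.DataFrame(bnd_rows, columns=BUNDLE_COLUMNS).to_csv(
        bundles_path, index=False
    )


def _result_record(r: AssociationResult) -> dict:
    return {
        "cell_id": r.cell_id,
        "n_papillae": r.n_papillae,
        "n_associated": r.n_associated,
        "percent_observed": r.percent_observed,
        "p_value": r.p_value,
        "p_display": r.p_display,
        "n_sims": r.n_sims,
        "threshold_nm": r.threshold,
        "null_mean_percent": float(np.mean(r.null_percents)),
        "null_sd_percent": float(np.std(r.null_percents, ddof=1))
        if r.n_sims > 1
        else 0.0,
    }


def write_report(
    results: list[AssociationResult],
    out_dir,
    config: RunConfig,
) -> CohortSummary:
    """Write the JSON run report and the per-cell TSV; returns the cohort
    summary (errors on an empty cohort)."""
    summary = aggregate_cells(results)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = {
        "tool": "papillastats",
        "version": __version__,
        "config": asdict(config),
        "seed": config.seed,
        "cohort": {
            "n_cells": summary.n_cells,
            "mean_percent": summary.mean_percent,
            "se_percent": summary.se_percent,
        },
        "cells": [_result_record(r) for r in results],
    }
    (out_dir / "association_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "percent_observed": r.percent_observed,
                "p_value": r.p_value,
                "p_display": r.p_display,
            }
            for r in results
        ]
    ).to_csv(out_dir / "association_per_cell.tsv", sep="\t", index=False)
    for r in results:
        logger.info(
            "cell %s: %d papillae, %d associated (%.1f%%), p %s",
            r.cell_id,
            r.n_papillae,
            r.n_associated,
            r.percent_observed,
            r.p_display,
        )
        logger.debug("cell %s null percents: %s", r.cell_id, r.null_percents)
    return summary


def read_transcript_table(path) -> list:
    """Load a transcript TSV into TranscriptRecord rows."""
    from .deg import TranscriptRecord

    df = pd.read_csv(path, sep="\t")
    required = [
        "gene_id",
        "rpkm_0h",
        "rpkm_3h",
        "rpkm_12h",
        "log2fc_0_3",
        "log2fc_3_12",
        "fdr_0_3",
        "fdr_3_12",
    ]
    _require_columns(df, required, path)
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                TranscriptRecord(
                    gene_id=str(row["gene_id"]),
                    rpkm_0h=float(row["rpkm_0h"]),
                    rpkm_3h=float(row["rpkm_3h"]),
                    rpkm_12h=float(row["rpkm_12h"]),
                    log2fc_0_3=float(row["log2fc_0_3"]),
                    log2fc_3_12=float(row["log2fc_3_12"]),
                    fdr_0_3=float(row["fdr_0_3"]),
                    fdr_3_12=float(row["fdr_3_12"]),
                    ca_sensitive=bool(row.get("ca_sensitive", False)),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: bad record at line {i + 2}: {exc}")
    return records
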