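"""Per-cell median intensities and the ALK Signaling Index (ASI).

The ASI of a cell is the fraction of pSMAD1/5/9 signal that is nuclear,

    ASI = pSMAD_nuc / (pSMAD_nuc + pSMAD_cyt),

where pSMAD_nuc and pSMAD_cyt are the *median* pixel intensities over the
nuclear ROI and the perinuclear annulus.  At dynamic equilibrium (SMADs
distributed homogeneously between nucleus and cytosol) the ASI is 0.5;
complete nuclear translocation drives it toward 1.0.  Being a ratio of
medians of the same channel, the ASI is invariant to any positive rescaling
of the pSMAD intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import (
    AnnulusSpec,
    LabeledField,
    SegmentationParams,
    make_annulus,
    max_project,
    segment_nuclei,
)

__all__ = [
    "CellMeasurement",
    "FieldResult",
    "measure_cell",
    "compute_asi",
    "quantify_field",
    "pool_runs",
    "summarize_conditions",
    "CELL_TABLE_COLUMNS",
]

# Versioned per-cell CSV schema; the contract consumed by dose-response fitting.
CELL_TABLE_COLUMNS = [
    "field_id",
    "cell_id",
    "centroid_x",
    "centroid_y",
    "nucleus_area_px",
    "psmad_nuc_median",
    "psmad_cyt_median",
    "asi",
    "exclusion_reason",
]


@dataclass
class CellMeasurement:
    """One cell's ROI medians and ASI (NaN when excluded)."""

    cell_id: int
    centroid: tuple[float, float]       # (y, x) pixels
    nucleus_area: float                 # px²
    psmad_nuc: float
    psmad_cyt: float
    asi: float
    exclusion_reason: str = ""

    @property
    def excluded(self) -> bool:
        return bool(self.exclusion_reason)


@dataclass
class FieldResult:
    """All cell measurements of one imaged field, retained and excluded."""

    cells: list[CellMeasurement]
    metadata: Mapping[str, object] = field(default_factory=dict)
    field_obj: LabeledField | None = None
    warning: str | None = None

    @property
    def retained(self) -> list[CellMeasurement]:
        return [c for c in self.cells if not c.excluded]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def asis(self) -> np.ndarray:
        return np.array([c.asi for c in self.retained], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row = {
                "field_id": self.metadata.get("field_id", ""),
                "cell_id": c.cell_id,
                "centroid_x": c.centroid[1],
                "centroid_y": c.centroid[0],
                "nucleus_area_px": c.nucleus_area,
                "psmad_nuc_median": c.psmad_nuc,
                "psmad_cyt_median": c.psmad_cyt,
                "asi": c.asi,
                "exclusion_reason": c.exclusion_reason,
            }
            for k, v in self.metadata.items():
                if k != "field_id":
                    row[k] = v
            rows.append(row)
        cols = CELL_TABLE_COLUMNS + [
            k for k in self.metadata if k != "field_id"
        ]
        return pd.DataFrame(rows, columns=cols)


def measure_cell(
    psmad_proj: np.ndarray,
    nucleus_mask: np.ndarray,
    annulus_mask: np.ndarray,
) -> tuple[float, float]:
    """Median pSMAD intensity over the nuclear and annulus ROIs.

    Both masks must be non-empty and disjoint.  The median of an even-sized
    pixel set is the midpoint average of the two central values.
    """
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    annulus_mask = np.asarray(annulus_mask, dtype=bool)
    if not nucleus_mask.any():
        raise ValueError("empty nuclear ROI")
    if not annulus_mask.any():
        raise ValueError("empty annulus ROI")
    if np.any(nucleus_mask & annulus_mask):
        raise ValueError("nuclear and annulus ROIs overlap")
    img = np.asarray(psmad_proj, dtype=float)
    return float(np.median(img[nucleus_mask])), float(np.median(img[annulus_mask]))


def compute_asi(psmad_nuc: float, psmad_cyt: float) -> float:
    """ASI = nuc / (nuc + cyt); NaN when both medians are zero.

    An all-dark cell (both medians zero) carries no localization
    information, so it is marked undefined rather than forced to 0.5.
    """
    if psmad_nuc < 0 or psmad_cyt < 0:
        raise ValueError("median intensities must be non-negative")
    total = psmad_nuc + psmad_cyt
    if total == 0:
        return float("nan")
    return psmad_nuc / total


def quantify_field(
    dapi_stack: np.ndarray,
    psmad_stack: np.ndarray,
    seg_params: SegmentationParams = SegmentationParams(),
    annulus_spec: AnnulusSpec = AnnulusSpec(),
    metadata: Mapping[str, object] | None = None,
    pixel_size: float | None = None,
    background: float = 0.0,
) -> FieldResult:
    """Full quantification chain for one two-channel field.

    max-project both channels, segment nuclei from DAPI, build each cell's
    perinuclear annulus, take ROI medians and form the ASI.  Deterministic
    for fixed inputs.  ``background``, when nonzero, is subtracted from the
    pSMAD projection (clipped at 0) before measurement — off by default as
    raw camera units are assumed.
    """
    dapi_stack = np.asarray(dapi_stack)
    psmad_stack = np.asarray(psmad_stack)
    if dapi_stack.shape[-2:] != psmad_stack.shape[-2:]:
        raise ValueError(
            f"channel x-y shapes differ: {dapi_stack.shape[-2:]} vs "
            f"{psmad_stack.shape[-2:]}"
        )
    dapi_proj = max_project(dapi_stack)
    psmad_proj = np.asarray(max_project(psmad_stack), dtype=float)
    if background:
        psmad_proj = np.clip(psmad_proj - background, 0.0, None)

    fieldobj = segment_nuclei(dapi_proj, seg_params)
    fieldobj.psmad_proj = psmad_proj
    metadata = dict(metadata or {})

    cells: list[CellMeasurement] = []
    warning = None
    if fieldobj.n_cells == 0:
        warning = "zero nuclei segmented in this field"
        warnings.warn(warning, stacklevel=2)
    centroids = ndimage.center_of_mass(
        np.ones_like(fieldobj.labels), fieldobj.labels, fieldobj.cell_ids
    ) if fieldobj.n_cells else []
    for cid, centroid in zip(fieldobj.cell_ids, centroids):
        nucleus = fieldobj.labels == cid
        area = float(nucleus.sum())
        annulus = make_annulus(fieldobj, int(cid), annulus_spec, pixel_size)
        if not annulus.any():
            cells.append(CellMeasurement(
                cell_id=int(cid), centroid=tuple(map(float, centroid)),
                nucleus_area=area, psmad_nuc=float("nan"),
                psmad_cyt=float("nan"), asi=float("nan"),
                exclusion_reason="empty_annulus",
            ))
            continue
        nuc_med, cyt_med = measure_cell(psmad_proj, nucleus, annulus)
        asi = compute_asi(nuc_med, cyt_med)
        reason = "zero_signal" if np.isnan(asi) else ""
        cells.append(CellMeasurement(
            cell_id=int(cid), centroid=tuple(map(float, centroid)),
            nucleus_area=area, psmad_nuc=nuc_med, psmad_cyt=cyt_med,
            asi=asi, exclusion_reason=reason,
        ))
    return FieldResult(cells=cells, metadata=metadata, field_obj=fieldobj,
                       warning=warning)


def pool_runs(fields: Sequence[FieldResult]) -> pd.DataFrame:
    """Concatenate per-cell rows across fields/runs into one tidy table.

    All fields must share the same metadata key set (conflicting schemas
    raise); rows keep their condition/replicate tags so groups can be
    compared downstream.
    """
    fields = list(fields)
    if not fields:
        return pd.DataFrame(columns=CELL_TABLE_COLUMNS)
    key_sets = {tuple(sorted(f.metadata.keys())) for f in fields}
    if len(key_sets) > 1:
        raise ValueError(f"conflicting metadata key sets across fields: {key_sets}")
    return pd.concat([f.to_dataframe() for f in fields], ignore_index=True)


def summarize_conditions(
    cell_table: pd.DataFrame, by: str | Iterable[str] = "condition"
) -> pd.DataFrame:
    """Per-condition mean/median/SD of retained per-cell ASIs."""
    by = [by] if isinstance(by, str) else list(by)
    kept = cell_table[cell_table["exclusion_reason"].fillna("") == ""]
    g = kept.groupby(by)["asi"]
    out = g.agg(mean_asi="mean", median_asi="median", sd_asi="std", n_cells="count")
    return out.reset_index()
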