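"""DAPI nuclear segmentation and perinuclear annulus construction.

The cytoplasmic ROI used by the quantification is not a full cell body:
pSMAD1/5/9 is sampled in a thin band just outside each nucleus (default
3 px wide, flush with the nuclear boundary), which confines the measurement
to the thickest part of the cytoplasm and avoids regions where endothelial
cells overlap.  The band is built from the exact Euclidean distance
transform of the nucleus, so a pixel belongs to the annulus of cell k iff
its distance to the nearest pixel of nucleus k lies in (offset,
offset + width] — identical to the set difference of two Euclidean
dilations — and all nuclear pixels of every cell are then excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, morphology, segmentation as sk_seg

__all__ = [
    "SegmentationParams",
    "AnnulusSpec",
    "LabeledField",
    "max_project",
    "segment_nuclei",
    "make_annulus",
    "annulus_offset_sweep",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the nucleus segmentation.

    ``threshold_method``: "otsu" (default) or "isodata" (the ImageJ
    "Default" variant, for macro compatibility).  Touching nuclei are split
    by watershed on the Euclidean distance transform with h-maxima marker
    smoothing (``h_maxima``).  Border-touching nuclei are excluded by
    default because their annuli would be truncated, biasing the
    cytoplasmic median.
    """

    threshold_method: str = "otsu"
    min_nucleus_area: float = 50.0     # px²
    max_nucleus_area: float = 10000.0  # px²
    split_touching: bool = True
    exclude_border: bool = True
    fill_holes: bool = True
    h_maxima: float = 2.0

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "isodata"):
            raise ValueError("threshold_method must be 'otsu' or 'isodata'")
        if not (0 < self.min_nucleus_area < self.max_nucleus_area):
            raise ValueError("need 0 < min_nucleus_area < max_nucleus_area")


@dataclass(frozen=True)
class AnnulusSpec:
    """Perinuclear band geometry: inner offset from the nuclear boundary and
    band width.  Units are pixels by default; ``unit='um'`` interprets both
    numbers in µm and requires a pixel size at use time (the source protocol
    states the band width both as 3 px and as 3 µm; both are supported)."""

    offset: float = 0.0
    width: float = 3.0
    unit: str = "px"

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        if self.width < 1e-9 or (self.unit == "px" and self.width < 1):
            raise ValueError("width must be >= 1 px (or positive in µm)")
        if self.unit not in ("px", "um"):
            raise ValueError("unit must be 'px' or 'um'")

    def in_pixels(self, pixel_size: float | None = None) -> tuple[float, float]:
        if self.unit == "px":
            return self.offset, self.width
        if pixel_size is None or pixel_size <= 0:
            raise ValueError("µm-unit annulus needs a positive pixel_size")
        return self.offset / pixel_size, self.width / pixel_size


@dataclass
class LabeledField:
    """Segmentation product every measurement consumes: the nucleus label
    map (0 = background, k = nucleus k, labels contiguous from 1) plus the
    channel projections it was derived from."""

    labels: np.ndarray
    dapi_proj: np.ndarray
    psmad_proj: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_cells(self) -> int:
        return int(self.cell_ids.size)


def max_project(stack: np.ndarray) -> np.ndarray:
    """Pixelwise maximum-intensity projection over z.

    Accepts a (Z, Y, X) stack (a single-plane stack projects to itself) or a
    2-D image, which is returned as-is.
    """
    arr = np.asarray(stack)
    if arr.ndim == 2:
        return arr
    if arr.ndim != 3:
        raise ValueError(f"expected a (Z, Y, X) stack, got ndim={arr.ndim}")
    if arr.shape[0] == 0:
        raise ValueError("empty stack: no z-planes to project")
    return arr.max(axis=0)


def _h_maxima_markers(edt: np.ndarray, h: float) -> np.ndarray:
    """Watershed markers from h-maxima of a distance transform.

    Maxima whose saddle with a higher maximum is shallower than ``h`` must
    collapse into one marker.  Taking the maximal plateaus of the grayscale
    h-reconstruction guarantees that: near-equal discrete ridge maxima end
    up on one exactly-equal connected plateau (the reconstructed level
    propagates as the same float), whereas marking maximal pixels of the
    raw transform would leave them as separate, disconnected markers.
    """
    rec = morphology.reconstruction(edt - h, edt, method="dilation",
                                    footprint=np.ones((3, 3)))
    peaks = morphology.local_maxima(rec, connectivity=2)
    markers, _ = ndimage.label(peaks, structure=np.ones((3, 3)))
    return markers


def segment_nuclei(
    dapi_proj: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
) -> LabeledField:
    """Segment individual nuclei from a DAPI projection.

    threshold -> fill holes -> optional distance-transform watershed split
    -> area filter -> optional border exclusion -> relabel 1..K.  An
    all-background image yields a valid empty labeling.
    """
    img = np.asarray(dapi_proj, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("dapi_proj must be a non-empty 2-D image")

    provenance = {"threshold_method": params.threshold_method}
    if img.max() == img.min():
        labels = np.zeros(img.shape, dtype=np.int32)
        provenance["threshold"] = None
        return LabeledField(labels=labels, dapi_proj=img, provenance=provenance)

    thr_fn = filters.threshold_otsu if params.threshold_method == "otsu" \
        else filters.threshold_isodata
    thr = float(thr_fn(img))
    provenance["threshold"] = thr
    binary = img > thr
    if params.fill_holes:
        binary = ndimage.binary_fill_holes(binary)

    if params.split_touching:
        edt = ndimage.distance_transform_edt(binary)
        markers = _h_maxima_markers(edt, params.h_maxima)
        labels = sk_seg.watershed(-edt, markers=markers, mask=binary)
    else:
        labels, _ = ndimage.label(binary)
    labels = np.asarray(labels, dtype=np.int32)

    areas = np.bincount(labels.ravel())
    bad = np.nonzero(
        (areas < params.min_nucleus_area) | (areas > params.max_nucleus_area)
    )[0]
    bad = bad[bad > 0]
    if bad.size:
        labels[np.isin(labels, bad)] = 0
    if params.exclude_border:
        labels = sk_seg.clear_border(labels)
    labels, _, _ = sk_seg.relabel_sequential(labels)
    return LabeledField(labels=np.asarray(labels, dtype=np.int32),
                        dapi_proj=img, provenance=provenance)


def make_annulus(
    field: LabeledField,
    cell_id: int,
    spec: AnnulusSpec = AnnulusSpec(),
    pixel_size: float | None = None,
) -> np.ndarray:
    """Boolean annulus mask for one cell.

    Equals dilate(nucleus, offset + width) minus dilate(nucleus, offset)
    (Euclidean dilations), minus the nuclear pixels of *every* label and
    anything outside the field.  Annuli of adjacent cells may overlap each
    other — ROI medians are robust and only nuclear contamination is
    excluded.  An empty result (fully crowded nucleus) is returned as an
    all-False mask for the caller to flag and exclude.
    """
    labels = field.labels
    if cell_id <= 0 or not np.any(labels == cell_id):
        raise KeyError(f"cell_id {cell_id} not present in the label map")
    offset, width = spec.in_pixels(pixel_size)
    nucleus = labels == cell_id
    dist = ndimage.distance_transform_edt(~nucleus)
    ring = (dist > offset) & (dist <= offset + width)
    return ring & (labels == 0)


def annulus_offset_sweep(
    field: LabeledField,
    psmad_proj: np.ndarray | None = None,
    offsets: list[float] = (0.0, 1.0, 2.0, 5.0),
    width: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-quantify the field at several annulus inner offsets.

    This is the robustness check that moving the band away from the nuclear
    boundary does not change the ASI (no bright perinuclear compartment is
    being singled out).  Returns ``(summary, per_cell)`` DataFrames; the
    summary has one row per offset with the mean ASI, and a warning flag
    when more than half the cells lost their annulus at that offset.
    """
    from .quantify import compute_asi, measure_cell

    offsets = list(offsets)
    if not offsets:
        raise ValueError("need at least one offset")
    if psmad_proj is None:
        psmad_proj = field.psmad_proj
    if psmad_proj is None:
        raise ValueError("no pSMAD projection available")

    rows, summary_rows = [], []
    for off in offsets:
        spec = AnnulusSpec(offset=off, width=width)
        asis, n_empty = [], 0
        for cid in field.cell_ids:
            ann = make_annulus(field, int(cid), spec)
            if not ann.any():
                n_empty += 1
                continue
            nuc_med, cyt_med = measure_cell(psmad_proj, field.labels == cid, ann)
            a = compute_asi(nuc_med, cyt_med)
            if not np.isnan(a):
                asis.append(a)
                rows.append({"offset": off, "cell_id": int(cid), "asi": a})
        n_total = field.n_cells
        warned = n_total > 0 and n_empty > 0.5 * n_total
        if warned:
            warnings.warn(
                f"offset {off}: empty annuli for {n_empty}/{n_total} cells",
                stacklevel=2,
            )
        summary_rows.append({
            "offset": off,
            "mean_asi": float(np.mean(asis)) if asis else np.nan,
            "n_cells": len(asis),
            "n_empty": n_empty,
            "warning": warned,
        })
    return pd.DataFrame(summary_rows), pd.DataFrame(rows)
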