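"""Validation morphometrics: junction tortuosity, puncta counts, actin planes.

Three independent quantifications used to validate perturbations of the
endothelial monolayer:

* **Junction tortuosity** — for a bicellular junction traced as a polyline
  between two vertices, ``tortuosity = (L - P) / P`` with L the path length
  and P the straight-line vertex distance; 0 for a straight junction, and
  invariant under rigid motions and uniform scaling.
* **CtxB puncta counting** — max z-projection, global IsoData ("Default")
  autothreshold, binary watershed on the distance transform to split
  touching puncta, connected components, exclusion of anything below
  1 µm², optional per-nucleus normalization.
* **Apical/basal F-actin intensity** — average-intensity projection of the
  two z-planes nearest the requested surface, summarized by the median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, segmentation as sk_seg

from .segmentation import _h_maxima_markers, max_project

__all__ = [
    "JunctionMeasurement",
    "PunctaResult",
    "ActinIntensityResult",
    "tortuosity_index",
    "count_puncta",
    "actin_intensity",
]


@dataclass
class JunctionMeasurement:
    vertex_a: tuple[float, float]
    vertex_b: tuple[float, float]
    path: np.ndarray
    P: float            # straight-line vertex distance
    L: float            # polyline path length
    tortuosity: float   # (L - P) / P


def tortuosity_index(
    vertex_a: tuple[float, float],
    vertex_b: tuple[float, float],
    path: np.ndarray,
    endpoint_tol: float = 1e-6,
) -> JunctionMeasurement:
    """Tortuosity (L - P) / P of a traced junction.

    The polyline must start and end at the two vertices (in either order).
    Coincident vertices leave P = 0 and the index undefined, so they raise.
    """
    a = np.asarray(vertex_a, dtype=float)
    b = np.asarray(vertex_b, dtype=float)
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or path.shape[1] != 2 or path.shape[0] < 2:
        raise ValueError("path must be an (N >= 2, 2) polyline")
    p = float(np.linalg.norm(b - a))
    if p == 0.0:
        raise ValueError("coincident vertices: P = 0, tortuosity undefined")
    forward = (np.linalg.norm(path[0] - a) <= endpoint_tol
               and np.linalg.norm(path[-1] - b) <= endpoint_tol)
    backward = (np.linalg.norm(path[0] - b) <= endpoint_tol
                and np.linalg.norm(path[-1] - a) <= endpoint_tol)
    if not (forward or backward):
        raise ValueError("path endpoints do not coincide with the vertices")
    seg = np.diff(path, axis=0)
    length = float(np.sum(np.linalg.norm(seg, axis=1)))
    return JunctionMeasurement(
        vertex_a=tuple(a), vertex_b=tuple(b), path=path,
        P=p, L=length, tortuosity=(length - p) / p,
    )


@dataclass
class PunctaResult:
    n_puncta: int                 # puncta with area >= min_area
    n_excluded: int               # components below min_area
    n_nuclei: int | None
    puncta_per_nucleus: float     # NaN when n_nuclei is 0/None
    min_area: float               # µm²
    pixel_size: float             # µm/px
    threshold: float | None       # autothreshold used, None for blank fields
    areas_um2: np.ndarray         # retained puncta areas


def count_puncta(
    stack: np.ndarray,
    pixel_size: float,
    min_area: float = 1.0,
    n_nuclei: int | None = None,
    split_touching: bool = True,
    h_maxima: float = 0.5,
) -> PunctaResult:
    """Count bright puncta in a field, excluding anything below ``min_area``.

    Pipeline: max z-projection -> IsoData global autothreshold -> binary
    watershed on the Euclidean distance transform (splits touching puncta)
    -> connected components -> area filter in µm².  The count is invariant
    to positive rescaling of the intensities (the histogram-derived
    threshold scales along).  When ``n_nuclei`` is given and positive, the
    count is normalized per nucleus; with 0 nuclei the normalization is
    marked undefined (NaN) rather than raised.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if n_nuclei is not None and n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    proj = np.asarray(max_project(stack), dtype=float)
    if proj.max() == proj.min():
        return PunctaResult(
            n_puncta=0, n_excluded=0, n_nuclei=n_nuclei,
            puncta_per_nucleus=(0.0 if n_nuclei else float("nan")),
            min_area=min_area, pixel_size=pixel_size, threshold=None,
            areas_um2=np.array([]),
        )
    thr = float(filters.threshold_isodata(proj))
    binary = proj > thr
    if split_touching:
        edt = ndimage.distance_transform_edt(binary)
        markers = _h_maxima_markers(edt, h_maxima)
        labels = sk_seg.watershed(-edt, markers=markers, mask=binary)
    else:
        labels, _ = ndimage.label(binary)
    areas_px = np.bincount(np.asarray(labels).ravel())[1:]
    areas_px = areas_px[areas_px > 0]
    areas_um2 = areas_px * pixel_size**2
    kept = areas_um2[areas_um2 >= min_area]
    n = int(kept.size)
    per_nucleus = n / n_nuclei if n_nuclei else float("nan")
    return PunctaResult(
        n_puncta=n, n_excluded=int(areas_um2.size - n), n_nuclei=n_nuclei,
        puncta_per_nucleus=per_nucleus, min_area=min_area,
        pixel_size=pixel_size, threshold=thr, areas_um2=np.sort(kept),
    )


@dataclass
class ActinIntensityResult:
    side: str
    median_intensity: float
    planes_used: tuple[int, int]
    projection: str = "average"
    degenerate: bool = False    # True when apical and basal share the pair


def actin_intensity(
    stack: np.ndarray,
    side: str,
    plane_map: str | dict | None,
) -> ActinIntensityResult:
    """Median F-actin intensity near one surface of the monolayer.

    The two z-planes closest to the requested side (``"apical"`` or
    ``"basal"``) are average-projected and the projection's median pixel
    intensity is reported.  Stack orientation is never guessed:
    ``plane_map`` must be ``"apical_first"``/``"basal_first"`` or a dict
    with explicit plane indices per side, e.g. ``{"apical": [6, 7],
    "basal": [0, 1]}``.  A 2-plane stack necessarily serves both sides and
    is flagged as degenerate.
    """
    arr = np.asarray(stack, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected a (Z, Y, X) stack")
    n_z = arr.shape[0]
    if n_z < 2:
        raise ValueError("need at least 2 z-planes for a surface projection")
    if side not in ("apical", "basal"):
        raise ValueError("side must be 'apical' or 'basal'")
    if plane_map is None:
        raise ValueError(
            "stack orientation unknown: pass plane_map='apical_first', "
            "'basal_first', or explicit plane indices per side"
        )
    if isinstance(plane_map, dict):
        idx = tuple(int(i) for i in plane_map[side])
        if len(idx) != 2:
            raise ValueError("plane_map must give exactly two planes per side")
    else:
        if plane_map not in ("apical_first", "basal_first"):
            raise ValueError(f"unknown plane_map {plane_map!r}")
        first_is_side = plane_map == f"{side}_first"
        idx = (0, 1) if first_is_side else (n_z - 2, n_z - 1)
    proj = arr[list(idx)].mean(axis=0)
    return ActinIntensityResult(
        side=side,
        median_intensity=float(np.median(proj)),
        planes_used=idx,
        degenerate=(n_z == 2),
    )
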