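"""Seeded synthetic-microscopy generator with ground-truth annotations.

Produces every input the analysis consumes — two-channel confocal-like image
stacks (DAPI + pSMAD1/5/9), per-cell dose-response tables, junction polylines
of known tortuosity, and puncta fields with known size inventories — so the
whole pipeline is testable without access to raw imaging data.

Model of a field
----------------
Nuclei are ellipses with uniform interior intensity placed by rejection
sampling with a minimum center spacing (default density emulates ~100 cells
per multi-field run).  Cytoplasm is modelled as a shell of configurable width
around each nucleus: the quantification only ever samples a thin perinuclear
annulus, so full cell bodies are unnecessary.  The pSMAD channel encodes a
ground-truth per-cell ALK Signaling Index (ASI): nuclear pixels receive
I_n = asi * total and each cell's shell receives I_c = (1 - asi) * total,
so that I_n / (I_n + I_c) equals the requested ASI exactly.

Noise is additive Gaussian applied once to the rendered 2-D content and then
scaled through the z-intensity profile (every z-plane is the same image at a
plane-dependent brightness with its maximum at the central plane); the max
projection therefore recovers the noisy 2-D image exactly.  Real confocal
noise is mixed Poisson-Gaussian and independent per plane; the analysis uses
ROI medians, which are robust to this simplification.

Determinism: all randomness flows from the scene seed through named
``numpy.random.SeedSequence`` substreams (one per cell, keyed by cell index,
plus dedicated streams for placement and noise), so identical configs produce
bit-identical arrays regardless of call order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import integrate, ndimage

from .doseresponse import DoseResponseDataset, four_pl

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "DoseResponseTruth",
    "PunctaTruth",
    "JunctionTrace",
    "generate_nuclei_field",
    "render_psmad_channel",
    "simulate_scene",
    "generate_dose_response",
    "generate_junction_trace",
    "generate_puncta_field",
    "write_scene",
]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic two-channel field.

    ``pixel_size`` (µm/px) has no default: the source imaging protocol does
    not state a magnification, so physical-unit conversions must be explicit.
    Intensities are arbitrary camera units; ``true_asi`` is the ground-truth
    nuclear fraction of pSMAD signal, strictly inside (0, 1) for renderable
    scenes (0.5 = equal nuclear and cytoplasmic median intensity).
    """

    pixel_size: float
    field_shape: tuple[int, int] = (512, 512)
    n_z: int = 3
    n_cells: int = 100
    nucleus_radius_range: tuple[float, float] = (8.0, 14.0)
    nucleus_eccentricity_range: tuple[float, float] = (0.0, 0.6)
    min_center_spacing: float = 36.0
    dapi_intensity: float = 200.0
    psmad_total_intensity: float = 200.0
    true_asi: float = 0.5
    noise_sd: float = 0.0
    dapi_blur_sigma: float = 1.0
    shell_width: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (µm per pixel)")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.n_z < 1:
            raise ValueError("need at least one z-plane")
        lo, hi = self.nucleus_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("nucleus radii must be positive and ordered")
        elo, ehi = self.nucleus_eccentricity_range
        if not (0 <= elo <= ehi < 1):
            raise ValueError("eccentricity range must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 < self.true_asi < 1.0):
            raise ValueError("true_asi must be strictly inside (0, 1)")
        h, w = self.field_shape
        if 2 * hi >= min(h, w):
            raise ValueError("nucleus radius exceeds the field")


@dataclass
class SyntheticScene:
    """A rendered field plus its ground truth."""

    config: SceneConfig
    dapi_stack: np.ndarray            # (n_z, H, W) float32
    truth_labels: np.ndarray          # (H, W) int32; 0 = background
    truth_asi: np.ndarray             # per-cell, aligned with labels 1..K
    psmad_stack: np.ndarray | None = None
    placement_warning: str | None = None

    @property
    def n_cells(self) -> int:
        return int(self.truth_labels.max())


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def _z_weights(n_z: int) -> np.ndarray:
    """Brightness profile over z; exactly 1.0 at the central plane."""
    mid = (n_z - 1) // 2
    off = np.abs(np.arange(n_z) - mid)
    return 1.0 / (1.0 + 0.5 * off)


def _stack_from_plane(plane: np.ndarray, n_z: int) -> np.ndarray:
    w = _z_weights(n_z)
    return (w[:, None, None] * plane[None, :, :]).astype(np.float32)


def generate_nuclei_field(config: SceneConfig) -> SyntheticScene:
    """Place elliptical nuclei and render the DAPI stack.

    Placement is rejection sampling with ``min_center_spacing``; if a cell
    cannot be placed within a bounded number of tries the scene is returned
    with fewer cells and an explicit warning.  Same config (incl. seed) gives
    bit-identical output.
    """
    h, w = config.field_shape
    r_lo, r_hi = config.nucleus_radius_range
    margin = r_hi + config.shell_width + 1
    if 2 * margin >= min(h, w):
        raise ValueError("field too small for the requested nucleus/shell size")

    place_rng = _rng(config.seed, 0)
    centers: list[tuple[float, float]] = []
    max_tries = 2000
    n_placed = config.n_cells
    for i in range(config.n_cells):
        for _ in range(max_tries):
            cy = place_rng.uniform(margin, h - margin)
            cx = place_rng.uniform(margin, w - margin)
            if all((cy - y) ** 2 + (cx - x) ** 2 >= config.min_center_spacing**2
                   for y, x in centers):
                centers.append((cy, cx))
                break
        else:
            n_placed = i
            break
    placement_warning = None
    if n_placed < config.n_cells:
        placement_warning = (
            f"placed {n_placed}/{config.n_cells} nuclei before exhausting retries; "
            "reduce min_center_spacing or n_cells"
        )
        warnings.warn(placement_warning, stacklevel=2)

    labels = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    for k, (cy, cx) in enumerate(centers, start=1):
        cell_rng = _rng(config.seed, 1, k)
        a = cell_rng.uniform(r_lo, r_hi)
        ecc = cell_rng.uniform(*config.nucleus_eccentricity_range)
        b = a * np.sqrt(1.0 - ecc**2)
        theta = cell_rng.uniform(0.0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        xr = (xx - cx) * ct + (yy - cy) * st
        yr = -(xx - cx) * st + (yy - cy) * ct
        inside = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        labels[inside & (labels == 0)] = k

    dapi2d = np.where(labels > 0, config.dapi_intensity, 0.0)
    if config.dapi_blur_sigma > 0:
        dapi2d = ndimage.gaussian_filter(dapi2d, config.dapi_blur_sigma)
    if config.noise_sd > 0:
        dapi2d = dapi2d + _rng(config.seed, 2).normal(0.0, config.noise_sd, dapi2d.shape)
        dapi2d = np.clip(dapi2d, 0.0, None)

    asi = np.full(len(centers), config.true_asi, dtype=float)
    return SyntheticScene(
        config=config,
        dapi_stack=_stack_from_plane(dapi2d, config.n_z),
        truth_labels=labels,
        truth_asi=asi,
        placement_warning=placement_warning,
    )


def render_psmad_channel(
    scene: SyntheticScene,
    true_asi: float | np.ndarray | None = None,
    noise_sd: float | None = None,
    shell_width: float | None = ...,
    allow_all_nuclear: bool = False,
    blur_sigma: float = 0.0,
) -> SyntheticScene:
    """Render the pSMAD channel so each cell realizes its ground-truth ASI.

    Nuclear pixels of cell k receive ``asi_k * total`` and its cytoplasmic
    shell ``(1 - asi_k) * total``; shell pixels shared between neighbours are
    assigned to the nearest nucleus.  ``shell_width=None`` extends every
    cell's cytoplasm over the whole background (useful for homogeneous-field
    controls).  ``true_asi`` must lie strictly in (0, 1); the degenerate
    all-nuclear limit (ASI exactly 1.0, zero cytoplasmic intensity) is only
    renderable with ``allow_all_nuclear=True`` and zero noise.

    Returns the scene (mutated in place) with ``psmad_stack`` and
    ``truth_asi`` filled in.
    """
    cfg = scene.config
    if scene.truth_labels.max() == 0 and cfg.n_cells > 0:
        raise ValueError("scene has no placed nuclei to render")
    n = scene.n_cells
    if true_asi is None:
        true_asi = cfg.true_asi
    asi = np.broadcast_to(np.asarray(true_asi, dtype=float), (n,)).copy()
    if noise_sd is None:
        noise_sd = cfg.noise_sd
    if shell_width is ...:
        shell_width = cfg.shell_width

    if np.any(asi >= 1.0) or np.any(asi <= 0.0):
        pure = np.all(asi == 1.0)
        if not (pure and allow_all_nuclear and noise_sd == 0):
            raise ValueError(
                "true_asi must be strictly inside (0, 1); ASI = 1.0 (zero "
                "cytoplasmic signal) requires allow_all_nuclear=True and noise_sd=0"
            )

    labels = scene.truth_labels
    total = cfg.psmad_total_intensity
    i_nuc = asi * total
    i_cyt = (1.0 - asi) * total

    plane = np.zeros(labels.shape, dtype=float)
    nuc = labels > 0
    plane[nuc] = i_nuc[labels[nuc] - 1]
    if n > 0:
        dist, (iy, ix) = ndimage.distance_transform_edt(~nuc, return_indices=True)
        nearest = labels[iy, ix]
        shell = ~nuc if shell_width is None else (~nuc) & (dist <= shell_width)
        plane[shell] = i_cyt[nearest[shell] - 1]
    if blur_sigma > 0:
        plane = ndimage.gaussian_filter(plane, blur_sigma)
    if noise_sd > 0:
        plane = plane + _rng(cfg.seed, 3).normal(0.0, noise_sd, plane.shape)
        plane = np.clip(plane, 0.0, None)

    scene.psmad_stack = _stack_from_plane(plane, cfg.n_z)
    scene.truth_asi = asi
    return scene


def simulate_scene(config: SceneConfig, **render_kwargs) -> SyntheticScene:
    """Convenience: place nuclei then render the pSMAD channel."""
    return render_psmad_channel(generate_nuclei_field(config), **render_kwargs)


# ---------------------------------------------------------------------------
# Dose-response forward model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseResponseTruth:
    """Ground-truth 4PL parameters for simulated per-cell ASI titrations.

    ``ec50`` is in pg/mL for ligand axes or dyn/cm^2 for shear-stress axes;
    bottom/top/noise_sd are in ASI units.
    """

    bottom: float = 0.5
    top: float = 0.75
    ec50: float = 17.0
    hill: float = 1.0
    doses: tuple[float, ...] = (0.0, 0.46, 1.4, 4.1, 12.0, 37.0, 110.0, 1000.0)
    n_cells_per_dose: int = 100
    noise_sd: float = 0.03
    seed: int = 0
    condition: str = ""
    axis: str = "dose"

    def __post_init__(self) -> None:
        if self.top <= self.bottom:
            raise ValueError("top must exceed bottom")
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be non-negative")
        if len(set(self.doses)) < 2:
            raise ValueError("need at least 2 distinct doses")
        if self.noise_sd < 0 or self.n_cells_per_dose < 1:
            raise ValueError("invalid noise_sd or n_cells_per_dose")


def generate_dose_response(truth: DoseResponseTruth) -> DoseResponseDataset:
    """Per-cell responses ``4PL(dose) + N(0, noise_sd)``, seeded."""
    rng = _rng(truth.seed, 10)
    doses = np.repeat(np.asarray(truth.doses, dtype=float), truth.n_cells_per_dose)
    mean = four_pl(doses, truth.bottom, truth.top, truth.ec50, truth.hill)
    resp = mean + (rng.normal(0.0, truth.noise_sd, doses.shape)
                   if truth.noise_sd > 0 else 0.0)
    return DoseResponseDataset(
        dose=doses, response=np.asarray(resp, dtype=float),
        condition=truth.condition, axis=truth.axis,
    )


# ---------------------------------------------------------------------------
# Junction traces
# ---------------------------------------------------------------------------

@dataclass
class JunctionTrace:
    """Polyline between two junction vertices with analytic ground truth.

    ``arc_length_true`` is the continuous curve's length (closed form or
    numeric quadrature); the polyline's own length converges to it under
    refinement.
    """

    vertex_a: tuple[float, float]
    vertex_b: tuple[float, float]
    path: np.ndarray                    # (N, 2) of (y, x)
    arc_length_true: float
    chord_length: float
    kind: str


def generate_junction_trace(
    kind: str,
    vertex_a: tuple[float, float] = (0.0, 0.0),
    vertex_b: tuple[float, float] = (0.0, 100.0),
    n_points: int = 200,
    amplitude: float = 10.0,
    periods: float = 2.0,
) -> JunctionTrace:
    """Generate a junction polyline of known tortuosity.

    kinds: ``straight`` (L = P), ``semicircle`` (L = πP/2), ``sine``
    (amplitude/periods transverse sine wave; L from numeric quadrature).
    """
    a = np.asarray(vertex_a, dtype=float)
    b = np.asarray(vertex_b, dtype=float)
    chord = float(np.linalg.norm(b - a))
    if chord == 0.0:
        raise ValueError("coincident vertices: tortuosity undefined (P = 0)")
    if n_points < 2:
        raise ValueError("need at least 2 path points")
    t = np.linspace(0.0, 1.0, n_points)
    u = (b - a) / chord                       # unit chord direction
    v = np.array([-u[1], u[0]])               # unit normal

    if kind == "straight":
        path = a[None, :] + t[:, None] * (b - a)[None, :]
        arc = chord
    elif kind == "semicircle":
        ang = np.pi * t
        along = 0.5 * chord * (1.0 - np.cos(ang))
        across = 0.5 * chord * np.sin(ang)
        path = a[None, :] + along[:, None] * u[None, :] + across[:, None] * v[None, :]
        arc = np.pi * chord / 2.0
    elif kind == "sine":
        phase = 2.0 * np.pi * periods
        along = chord * t
        across = amplitude * np.sin(phase * t)
        path = a[None, :] + along[:, None] * u[None, :] + across[:, None] * v[None, :]
        arc = float(integrate.quad(
            lambda s: np.hypot(chord, amplitude * phase * np.cos(phase * s)),
            0.0, 1.0, limit=200,
        )[0])
    else:
        raise ValueError(f"unknown junction kind {kind!r}")
    return JunctionTrace(
        vertex_a=tuple(a), vertex_b=tuple(b), path=path,
        arc_length_true=float(arc), chord_length=chord, kind=kind,
    )


# ---------------------------------------------------------------------------
# Puncta fields
# ---------------------------------------------------------------------------

@dataclass
class PunctaTruth:
    """Inventory of rendered puncta, split at the area-exclusion threshold."""

    n_large: int
    n_small: int
    areas: list[float]                  # µm², per punctum, rasterized
    positions: list[tuple[float, float]]
    touching_pair: tuple[int, int] | None
    threshold_area: float
    seed: int


def generate_puncta_field(
    n_large: int = 20,
    n_small: int = 15,
    area_large: float = 2.0,
    area_small: float = 0.5,
    pixel_size: float = 0.2,
    field_shape: tuple[int, int] = (256, 256),
    n_z: int = 1,
    intensity: float = 150.0,
    threshold_area: float = 1.0,
    touching_pair: bool = False,
    seed: int = 0,
) -> tuple[np.ndarray, PunctaTruth]:
    """Render bright disks on a dark background with a known size inventory.

    Disk areas (µm²) strictly straddle ``threshold_area``; puncta do not
    overlap unless ``touching_pair=True``, in which case one extra pair of
    above-threshold disks is rendered slightly overlapping and flagged so
    watershed splitting can be tested against it.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if not (area_small < threshold_area <= area_large):
        raise ValueError("areas must strictly straddle the threshold")
    r_large = np.sqrt(area_large / np.pi) / pixel_size
    r_small = np.sqrt(area_small / np.pi) / pixel_size
    if r_small < 1.0:
        raise ValueError(
            f"small-punctum radius {r_small:.2f} px is below one pixel at "
            f"pixel_size={pixel_size}"
        )
    h, w = field_shape
    rng = _rng(seed, 20)
    margin = 2 * r_large + 4
    spacing = 2.5 * r_large + 2

    centers: list[tuple[float, float]] = []
    radii: list[float] = []

    def _place(r: float, near: tuple[float, float] | None = None) -> tuple[float, float]:
        for _ in range(5000):
            if near is None:
                cy = rng.uniform(margin, h - margin)
                cx = rng.uniform(margin, w - margin)
            else:
                # slight overlap with the partner disk for the touching pair
                ang = rng.uniform(0, 2 * np.pi)
                cy = near[0] + 1.6 * r * np.sin(ang)
                cx = near[1] + 1.6 * r * np.cos(ang)
                if not (margin <= cy <= h - margin and margin <= cx <= w - margin):
                    continue
            ok = all(
                np.hypot(cy - y, cx - x) >= spacing
                for (y, x), r0 in zip(centers, radii)
                if near is None or (y, x) != near
            )
            if ok:
                return cy, cx
        raise RuntimeError("could not place all puncta; enlarge the field")

    order: list[tuple[float, bool]] = [(r_large, True)] * n_large + \
        [(r_small, False)] * n_small
    pair_idx: tuple[int, int] | None = None
    for r, _big in order:
        centers.append(_place(r))
        radii.append(r)
    if touching_pair:
        i = len(centers)
        c1 = _place(r_large)
        centers.append(c1)
        radii.append(r_large)
        centers.append(_place(r_large, near=c1))
        radii.append(r_large)
        pair_idx = (i, i + 1)
        n_large += 2

    yy, xx = np.mgrid[0:h, 0:w]
    plane = np.zeros((h, w), dtype=float)
    areas_px: list[float] = []
    for (cy, cx), r in zip(centers, radii):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        plane[disk] = intensity
        areas_px.append(float(disk.sum()))
    areas_um2 = [a * pixel_size**2 for a in areas_px]
    # rasterization must not move any punctum across the threshold
    for a, r in zip(areas_um2, radii):
        nominal_large = r == r_large
        if nominal_large != (a >= threshold_area):
            raise RuntimeError(
                f"rasterized area {a:.3f} µm² crossed the {threshold_area} µm² "
                "threshold; adjust areas or pixel_size"
            )
    stack = _stack_from_plane(plane, n_z)
    truth = PunctaTruth(
        n_large=n_large, n_small=n_small, areas=areas_um2,
        positions=[(float(y), float(x)) for y, x in centers],
        touching_pair=pair_idx, threshold_area=threshold_area, seed=seed,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# On-disk representation
# ---------------------------------------------------------------------------

def write_scene(scene: SyntheticScene, out_dir: str | Path) -> dict[str, Path]:
    """Write a scene as multi-channel TIFF + label TIFF + JSON ground truth.

    The image stack is written with axes ZCYX (channel order DAPI, pSMAD);
    the sidecar carries the config and per-cell true ASI.
    """
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if scene.psmad_stack is None:
        raise ValueError("render the pSMAD channel before writing the scene")
    stack = np.stack([scene.dapi_stack, scene.psmad_stack], axis=1)  # (Z, C, Y, X)
    paths = {
        "stack": out / "scene.tif",
        "labels": out / "truth_labels.tif",
        "truth": out / "truth.json",
    }
    tifffile.imwrite(paths["stack"], stack.astype(np.float32), imagej=True,
                     metadata={"axes": "ZCYX"})
    tifffile.imwrite(paths["labels"], scene.truth_labels.astype(np.uint16))
    sidecar = {
        "config": asdict(scene.config),
        "true_asi": [float(a) for a in scene.truth_asi],
        "n_cells": scene.n_cells,
        "placement_warning": scene.placement_warning,
    }
    paths["truth"].write_text(json.dumps(sidecar, indent=2))
    return paths
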