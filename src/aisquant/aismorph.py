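"""Per-cell proximal-axon morphometry: soma, GAP and AIS.

Measurement model
-----------------
On a maximum-intensity projection, the soma is delimited on the MAP2
channel from a seed point, with concave cuts at each annotated neurite
entry zone.  The AIS is detected as the supra-threshold ankyrin-G
component outside the soma (threshold calibrated on control cells); only
cells with a single soma-derived AIS enter the quantitative analysis.
The GAP is the stretch of thresholded axon between the soma boundary and
the proximal end of the AIS.  Lengths are medial-axis geodesic lengths
(8-connected, √2 diagonal steps, smoothed to remove pixelation bias);
areas are pixel counts × pixel_size²; mean axonal calibers are area/length.
Channel distributions are integrated densities of background-subtracted
pNF-M/H and panNav images over the GAP and AIS, summed into per-cell
totals; the AIS/GAP panNav ratio is undefined (and the cell excluded from
ratio comparisons) when the cell has no GAP.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, graph, morphology

from . import imgcore
from .imgcore import MeasurementError, MultichannelStack, Roi, ThresholdModel

logger = logging.getLogger(__name__)


class SegmentationError(ValueError):
    """Soma delimitation failed (e.g. seed on background)."""


class DelineationError(ValueError):
    """GAP delineation failed (e.g. AIS not connected to the soma)."""


# ---------------------------------------------------------------------------
# annotations


@dataclass
class NeuriteEntry:
    """Annotated neurite entry zone on the soma boundary.

    ``point`` is (row, col) in pixels, ``direction`` the outward unit
    vector of the leaving process, ``width_um`` its approximate caliber.
    """

    point: tuple[float, float]
    direction: tuple[float, float]
    width_um: float


@dataclass
class CellAnnotation:
    """Semi-manual per-cell input: soma seed plus neurite entry zones.

    ``soma_polygon_um`` optionally supplies the exact soma contour
    ((x, y) vertices in µm), in which case delimitation rasterises it
    directly (pass-through mode).
    """

    cell_id: str
    soma_seed: tuple[int, int]
    neurite_entries: list[NeuriteEntry] = field(default_factory=list)
    soma_polygon_um: np.ndarray | None = None


@dataclass
class MorphConfig:
    """Tunable morphometry parameters (µm unless noted)."""

    min_ais_length_um: float = 5.0       # despeckling guard on AIS candidates
    min_acc_area_um2: float = 1.0        # minimum accumulation footprint
    min_region_overlap_um2: float = 0.5  # overlap needed to claim a region
    gap_slack_um: float = 0.5            # geodesic corridor slack for the GAP
    min_gap_length_um: float = 0.5       # below this the cell has no GAP
    soma_cut_curvature_factor: float = 2.0   # arc radius / process width
    soma_cut_min_radius_um: float = 2.0
    soma_cut_halfwidth_factor: float = 1.5   # lateral reach / process width
    soma_cut_min_halfwidth_um: float = 1.5
    path_smooth_window: int = 7          # px, for geodesic length smoothing
    halfmax_refine: bool = True          # refine tube areas at half maximum
    region_erosion_px: int = 2           # overlap tests use region interiors


# ---------------------------------------------------------------------------
# measurement record


@dataclass
class ProximalAxonMeasurement:
    """Per-cell soma/GAP/AIS geometry and channel densities."""

    cell_id: str
    soma_area: float = math.nan
    n_ais: int = 0
    included: bool = False
    ais_connected: bool = False
    gap_length: float = math.nan
    ais_length: float = math.nan
    gap_area: float = math.nan
    ais_area: float = math.nan
    gap_caliber: float = math.nan
    ais_caliber: float = math.nan
    gap_caliber_reason: str = ""
    id_pnf_gap: float = math.nan
    id_pnf_ais: float = math.nan
    id_pnf_total: float = math.nan
    id_nav_gap: float = math.nan
    id_nav_ais: float = math.nan
    id_nav_total: float = math.nan
    nav_ais_to_gap_ratio: float = math.nan
    nav_ratio_reason: str = ""
    has_gap: bool = False
    has_accumulation: bool = False
    accumulation_extent: str = "none"

    def to_row(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# geometry helpers


class _CroppedMcp:
    """MCP on the bounding box of the traversable mask (cheaper than the
    full field); tracebacks are reported in full-image coordinates."""

    def __init__(self, mcp, offset):
        self._mcp = mcp
        self._offset = offset

    def traceback(self, end):
        r0, c0 = self._offset
        path = self._mcp.traceback((end[0] - r0, end[1] - c0))
        return [(r + r0, c + c0) for r, c in path]


def _geodesic_costs(traversable: np.ndarray, sources: np.ndarray):
    """8-connected geodesic distance (px units, √2 diagonals) from source
    pixels through a traversable mask.  Returns (costs, mcp)."""
    starts = np.argwhere(sources & traversable)
    if len(starts) == 0:
        return np.full(traversable.shape, np.inf), None
    rows, cols = np.nonzero(traversable)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    cost = np.where(traversable[r0:r1, c0:c1], 1.0, np.inf)
    mcp = graph.MCP_Geometric(cost)
    local, _ = mcp.find_costs(starts - (r0, c0))
    costs = np.full(traversable.shape, np.inf)
    costs[r0:r1, c0:c1] = local
    return costs, _CroppedMcp(mcp, (r0, c0))

def _smoothed_path_length_px(path: np.ndarray, window: int) -> float:
    """Length of a pixel chain after moving-average smoothing.

    Raw 8-connected chains overestimate Euclidean length by up to ~8%
    (staircase effect); smoothing the coordinates before summing segment
    norms removes almost all of that bias while keeping the endpoints
    fixed.
    """
    if len(path) < 2:
        return 0.0
    pts = np.asarray(path, dtype=float)
    if len(pts) > window > 2:
        kernel = np.ones(window) / window
        sm = np.column_stack(
            [np.convolve(pts[:, i], kernel, mode="valid") for i in (0, 1)]
        )
        sm = np.vstack([pts[0], sm, pts[-1]])
    else:
        sm = pts
    return float(np.linalg.norm(np.diff(sm, axis=0), axis=1).sum())


def mask_geodesic_length_um(
    mask: np.ndarray, pixel_size: float, entry: tuple[int, int] | None = None,
    smooth_window: int = 7,
) -> float:
    """Geodesic diameter (or eccentricity from ``entry``) of a mask, µm.

    Uses two geodesic passes: from the entry (or an arbitrary pixel) to the
    farthest pixel, then a smoothed traceback of that farthest path.
    """
    if not mask.any():
        return 0.0
    if entry is None:
        seed = tuple(np.argwhere(mask)[0])
        costs, _ = _geodesic_costs(mask, _point_mask(mask.shape, seed))
        costs_m = np.where(mask, costs, -np.inf)
        entry = tuple(np.unravel_index(np.argmax(costs_m), mask.shape))
    costs, mcp = _geodesic_costs(mask, _point_mask(mask.shape, entry))
    costs_m = np.where(mask & np.isfinite(costs), costs, -np.inf)
    far = tuple(np.unravel_index(np.argmax(costs_m), mask.shape))
    if mcp is None or not np.isfinite(costs[far]):
        return 0.0
    path = mcp.traceback(far)
    return _smoothed_path_length_px(np.asarray(path), smooth_window) * pixel_size


def _point_mask(shape, pt) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[int(pt[0]), int(pt[1])] = True
    return m


def _halfmax_refine(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Restrict a detected tube mask to pixels above half its plateau
    intensity.  For a step-edge profile blurred by a symmetric PSF the
    half-maximum contour sits on the true boundary, so refined areas track
    true tube widths much better than threshold-level masks."""
    if not mask.any():
        return mask
    plateau = float(np.median(image[mask]))
    refined = mask & (image > 0.5 * plateau)
    return refined if refined.any() else mask


# ---------------------------------------------------------------------------
# operations


def delimit_soma(
    map2_mip: np.ndarray,
    tuj1_mip: np.ndarray,
    annotation: CellAnnotation,
    pixel_size: float,
    config: MorphConfig | None = None,
    map2_threshold: float | None = None,
) -> Roi:
    """Delimit the soma from the MAP2 channel.

    The supra-threshold MAP2 component containing the seed is cut at each
    annotated neurite entry zone by a circular cut (radius scaled to the
    annotated process width) centred just outside the boundary, producing
    the concave contour of a hand-drawn soma outline.  If the annotation
    carries an explicit soma polygon it is rasterised directly.
    """
    config = config or MorphConfig()
    shape = map2_mip.shape
    if annotation.soma_polygon_um is not None:
        from .synthgen import _rasterize_polygon

        mask = _rasterize_polygon(annotation.soma_polygon_um, pixel_size, shape)
        return Roi(label="soma", mask=mask, source_channel="map2")

    thr = (
        map2_threshold
        if map2_threshold is not None
        else float(filters.threshold_otsu(map2_mip))
    )
    above = map2_mip > thr
    seed = tuple(int(v) for v in annotation.soma_seed)
    if not above[seed]:
        raise SegmentationError(
            f"cell {annotation.cell_id}: soma seed {seed} lies below the "
            f"MAP2 threshold ({thr:.3g})"
        )
    for entry in annotation.neurite_entries:
        # thin circular-arc cut through the entry point, concave around the
        # leaving process: severs it from the soma without removing area
        r_um = max(
            config.soma_cut_curvature_factor * entry.width_um,
            config.soma_cut_min_radius_um,
        )
        r_px = r_um / pixel_size
        half_um = max(
            config.soma_cut_halfwidth_factor * entry.width_um,
            config.soma_cut_min_halfwidth_um,
        )
        half_px = half_um / pixel_size
        centre = (
            entry.point[0] + r_px * entry.direction[0],
            entry.point[1] + r_px * entry.direction[1],
        )
        reach = int(np.ceil(half_px + 4))
        lo_r = max(int(entry.point[0]) - reach, 0)
        hi_r = min(int(entry.point[0]) + reach + 1, shape[0])
        lo_c = max(int(entry.point[1]) - reach, 0)
        hi_c = min(int(entry.point[1]) + reach + 1, shape[1])
        rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]
        dist = np.hypot(rr - centre[0], cc - centre[1])
        near = (
            np.hypot(rr - entry.point[0], cc - entry.point[1])
            <= half_px + 2.0
        )
        above[lo_r:hi_r, lo_c:hi_c] &= ~(
            (np.abs(dist - r_px) <= 1.2) & near
        )
    if not above[seed]:
        raise SegmentationError(
            f"cell {annotation.cell_id}: seed removed by neurite cuts"
        )
    labels, _ = ndimage.label(above, structure=np.ones((3, 3)))
    mask = labels == labels[seed]
    return Roi(label="soma", mask=mask, source_channel="map2")


def detect_ais(
    ankg_mip: np.ndarray,
    thr: ThresholdModel,
    soma: Roi,
    pixel_size: float,
    config: MorphConfig | None = None,
) -> tuple[list[Roi], int]:
    """Detect AIS candidates on the ankyrin-G channel.

    Candidates are connected supra-threshold components outside the soma,
    merged by a single morphological closing (radius 1 px) so that touching
    fragments count once, then filtered by a minimum geodesic length.
    Each retained candidate is tightened to its half-maximum contour (the
    threshold-level component is dilated by the point-spread flank).
    Zero candidates is a valid outcome.
    """
    config = config or MorphConfig()
    above = ankg_mip > thr.value
    above = ndimage.binary_closing(above, structure=morphology.disk(1))
    above &= ~soma.mask
    labels, n = ndimage.label(above, structure=np.ones((3, 3)))
    rois: list[Roi] = []
    for i in range(1, n + 1):
        comp = labels == i
        if comp.sum() * pixel_size**2 < 0.5 * config.min_ais_length_um:
            continue  # cheap area prefilter before the geodesic pass
        length = mask_geodesic_length_um(
            comp, pixel_size, smooth_window=config.path_smooth_window
        )
        if length >= config.min_ais_length_um:
            refined = (
                _halfmax_refine(ankg_mip, comp)
                if config.halfmax_refine
                else comp
            )
            rois.append(Roi(label="ais", mask=refined, source_channel="ankg"))
    return rois, len(rois)


def delineate_gap(
    soma: Roi,
    ais: Roi,
    axon_mask: np.ndarray,
    pixel_size: float,
    config: MorphConfig | None = None,
) -> tuple[Roi, float]:
    """Delineate the GAP between the soma boundary and the proximal AIS end.

    The GAP is the set of thresholded-axon pixels lying on near-shortest
    geodesic paths between the soma and the AIS: pixels whose geodesic
    distance from the soma plus geodesic distance to the AIS does not
    exceed the soma→AIS entry distance by more than a slack of one axon
    caliber.  Its length is the smoothed geodesic trace from the soma
    boundary to the proximal AIS pixel; an AIS abutting the soma yields an
    empty GAP of length 0.
    """
    config = config or MorphConfig()
    corridor = (axon_mask | ais.mask) & ~soma.mask
    sources = ndimage.binary_dilation(soma.mask, np.ones((3, 3))) & corridor
    d_soma, mcp = _geodesic_costs(corridor, sources)
    in_ais = ais.mask & np.isfinite(d_soma)
    if mcp is None or not in_ais.any():
        raise DelineationError(
            "AIS is not connected to the soma through the axon mask"
        )
    d_entry = float(d_soma[in_ais].min())
    entry = tuple(
        np.argwhere(in_ais & (d_soma == d_soma[in_ais].min()))[0]
    )
    path = np.asarray(mcp.traceback(entry))
    gap_length = (
        _smoothed_path_length_px(path, config.path_smooth_window) * pixel_size
    )

    d_ais, _ = _geodesic_costs(corridor, ais.mask)
    slack_px = config.gap_slack_um / pixel_size
    gap_mask = (
        corridor
        & ~ais.mask
        & np.isfinite(d_soma)
        & np.isfinite(d_ais)
        & (d_soma + d_ais <= d_entry + slack_px)
    )
    return Roi(label="gap", mask=gap_mask, source_channel="tuj1"), gap_length


def measure_geometry(
    gap: Roi,
    ais: Roi,
    gap_length: float,
    ais_length: float,
    pixel_size: float,
) -> dict:
    """Areas (µm²) and mean axonal calibers (area / length, µm).

    A zero-length region yields an undefined caliber with a reason code
    rather than a division failure.
    """
    out = {
        "gap_area": gap.area(pixel_size),
        "ais_area": ais.area(pixel_size),
        "gap_length": gap_length,
        "ais_length": ais_length,
        "gap_caliber": math.nan,
        "ais_caliber": math.nan,
        "gap_caliber_reason": "",
        "ais_caliber_reason": "",
    }
    if gap_length > 0:
        out["gap_caliber"] = out["gap_area"] / gap_length
    else:
        out["gap_caliber_reason"] = "zero_length"
    if ais_length > 0:
        out["ais_caliber"] = out["ais_area"] / ais_length
    else:
        out["ais_caliber_reason"] = "zero_length"
    return out


def channel_distributions(
    pnf_mip: np.ndarray,
    nav_mip: np.ndarray,
    gap: Roi,
    ais: Roi,
    pixel_size: float,
) -> dict:
    """Integrated densities of pNF-M/H and panNav in GAP and AIS.

    Per-channel totals are the exact sums of the two regions.  The panNav
    AIS/GAP ratio is undefined (reason-coded) for cells without a GAP or
    with zero GAP signal; such cells are excluded from ratio comparisons.
    """
    if ais.n_pixels == 0:
        raise MeasurementError("empty AIS ROI")
    out = {}
    for name, img in (("pnf", pnf_mip), ("nav", nav_mip)):
        id_gap = (
            imgcore.integrated_density(img, gap, pixel_size)
            if gap.n_pixels
            else 0.0
        )
        id_ais = imgcore.integrated_density(img, ais, pixel_size)
        out[f"id_{name}_gap"] = id_gap
        out[f"id_{name}_ais"] = id_ais
        out[f"id_{name}_total"] = id_gap + id_ais
    if gap.n_pixels == 0:
        out["nav_ais_to_gap_ratio"] = math.nan
        out["nav_ratio_reason"] = "no_gap"
    elif out["id_nav_gap"] == 0:
        out["nav_ais_to_gap_ratio"] = math.nan
        out["nav_ratio_reason"] = "zero_gap_signal"
    else:
        out["nav_ais_to_gap_ratio"] = out["id_nav_ais"] / out["id_nav_gap"]
        out["nav_ratio_reason"] = ""
    return out


def detect_accumulation(
    pnf_mip: np.ndarray,
    thr: ThresholdModel,
    gap: Roi,
    ais: Roi,
    pixel_size: float,
    config: MorphConfig | None = None,
) -> tuple[bool, str]:
    """Detect a proximal pNF-M/H accumulation and its extent.

    An accumulation is a supra-threshold pNF-M/H component of at least
    ``min_acc_area_um2`` overlapping the GAP or AIS by at least
    ``min_region_overlap_um2``.  The extent is ``gap_only`` when only the
    GAP is hit and ``gap_and_ais`` when the AIS is involved.  Overlap is
    tested against region *interiors* (eroded by ``region_erosion_px``) so
    that point-spread bleed across the GAP/AIS boundary cannot claim the
    neighbouring region; a region too thin to erode is used as is.
    """
    config = config or MorphConfig()
    above = pnf_mip > thr.value
    labels, n = ndimage.label(above, structure=np.ones((3, 3)))
    px2 = pixel_size**2
    min_px = config.min_acc_area_um2 / px2
    overlap_px = config.min_region_overlap_um2 / px2

    def interior(mask):
        if config.region_erosion_px <= 0 or not mask.any():
            return mask
        eroded = ndimage.binary_erosion(
            mask, iterations=config.region_erosion_px
        )
        return eroded if eroded.any() else mask

    gap_int, ais_int = interior(gap.mask), interior(ais.mask)
    hit_gap = hit_ais = False
    for i in range(1, n + 1):
        comp = labels == i
        if comp.sum() < min_px:
            continue
        if (comp & gap_int).sum() >= overlap_px:
            hit_gap = True
        if (comp & ais_int).sum() >= overlap_px:
            hit_ais = True
    if hit_ais:
        return True, "gap_and_ais"
    if hit_gap:
        return True, "gap_only"
    return False, "none"


def apply_inclusion_filter(
    measurements: Sequence[ProximalAxonMeasurement],
) -> list[ProximalAxonMeasurement]:
    """Flag the cells entering quantitative analysis: exactly one AIS,
    reachable from the soma along the thresholded axon mask."""
    return [
        replace(m, included=(m.n_ais == 1 and m.ais_connected))
        for m in measurements
    ]


#: default calibration percentiles per channel, set against the pooled
#: pixel abundance of the structure each threshold must separate: the AIS
#: occupies ~1% of a control field so the AnkG percentile sits below that
#: rank; β3-tubulin-positive structures cover ~10% of a field; pNF-M/H
#: needs a near-ceiling percentile because normal axons carry moderate
#: phospho-neurofilament staining and only accumulations should exceed
#: what control cells show.
DEFAULT_CALIBRATION_PERCENTILES = {
    "ankg": 98.0,
    "pnf": 99.99,
    "tuj1": 92.0,
    "nfl": 99.0,
}


def calibrate_thresholds(
    control_mips: Mapping[str, Sequence[np.ndarray]],
    percentiles: Mapping[str, float] | None = None,
) -> dict[str, ThresholdModel]:
    """Calibrate per-channel thresholds on pooled control projections."""
    percentiles = {**DEFAULT_CALIBRATION_PERCENTILES, **(percentiles or {})}
    return {
        ch: imgcore.calibrate_threshold(
            images, param=percentiles.get(ch, 99.0), channel=ch
        )
        for ch, images in control_mips.items()
    }


# ---------------------------------------------------------------------------
# per-cell pipeline


def measure_cell(
    stack: MultichannelStack,
    annotation: CellAnnotation,
    thresholds: Mapping[str, ThresholdModel],
    config: MorphConfig | None = None,
) -> ProximalAxonMeasurement:
    """Run the full proximal-axon measurement on one cell.

    ``thresholds`` must provide calibrated models for ``ankg`` and ``pnf``.
    Cells without exactly one soma-connected AIS are returned with
    ``included=False`` and undefined geometry.
    """
    config = config or MorphConfig()
    ps = stack.pixel_size
    mips = {
        ch: imgcore.max_intensity_projection(stack, ch)
        for ch in ("map2", "tuj1", "ankg", "pnf", "pannav")
    }
    soma = delimit_soma(mips["map2"], mips["tuj1"], annotation, ps, config)
    m = ProximalAxonMeasurement(
        cell_id=annotation.cell_id, soma_area=soma.area(ps)
    )
    ais_rois, m.n_ais = detect_ais(
        mips["ankg"], thresholds["ankg"], soma, ps, config
    )
    if m.n_ais != 1:
        return m
    ais = ais_rois[0]

    axon_mask = mips["tuj1"] > float(filters.threshold_otsu(mips["tuj1"]))
    try:
        gap, gap_length = delineate_gap(soma, ais, axon_mask, ps, config)
        m.ais_connected = True
    except DelineationError:
        m.ais_connected = False
        return m
    m.included = True
    if gap_length < config.min_gap_length_um:
        # an AIS abutting the soma: no GAP region (halo pixels discarded)
        gap = Roi("gap", np.zeros_like(gap.mask), "tuj1")
        gap_length = 0.0
    m.has_gap = gap.n_pixels > 0

    if config.halfmax_refine:
        ais_meas = Roi(
            "ais", _halfmax_refine(mips["ankg"], ais.mask), "ankg"
        )
        gap_meas = (
            Roi("gap", _halfmax_refine(mips["tuj1"], gap.mask), "tuj1")
            if gap.n_pixels
            else gap
        )
    else:
        ais_meas, gap_meas = ais, gap

    entry = None
    if ais_meas.n_pixels:
        # proximal end: the AIS pixel geodesically closest to the soma
        corridor = (axon_mask | ais_meas.mask) & ~soma.mask
        sources = ndimage.binary_dilation(soma.mask, np.ones((3, 3))) & corridor
        d_soma, _ = _geodesic_costs(corridor, sources)
        in_ais = ais_meas.mask & np.isfinite(d_soma)
        if in_ais.any():
            entry = tuple(
                np.argwhere(in_ais & (d_soma == d_soma[in_ais].min()))[0]
            )
    ais_length = mask_geodesic_length_um(
        ais_meas.mask, ps, entry=entry, smooth_window=config.path_smooth_window
    )

    geom = measure_geometry(gap_meas, ais_meas, gap_length, ais_length, ps)
    for k in (
        "gap_area", "ais_area", "gap_length", "ais_length",
        "gap_caliber", "ais_caliber", "gap_caliber_reason",
    ):
        setattr(m, k, geom[k])

    rois = [soma, gap, ais]
    pnf_bg = imgcore.subtract_background(mips["pnf"], rois=rois)
    nav_bg = imgcore.subtract_background(mips["pannav"], rois=rois)
    dist = channel_distributions(pnf_bg, nav_bg, gap_meas, ais_meas, ps)
    for k, v in dist.items():
        setattr(m, k, v)

    m.has_accumulation, m.accumulation_extent = detect_accumulation(
        mips["pnf"], thresholds["pnf"], gap, ais, ps, config
    )
    return m


def measure_cohort(
    cells,
    thresholds: Mapping[str, ThresholdModel],
    config: MorphConfig | None = None,
) -> pd.DataFrame:
    """Measure an iterable of ``(stack, annotation)`` pairs into a tidy
    DataFrame (one row per cell, inclusion flags applied)."""
    measurements = [
        measure_cell(stack, ann, thresholds, config) for stack, ann in cells
    ]
    measurements = apply_inclusion_filter(measurements)
    return pd.DataFrame([m.to_row() for m in measurements])
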