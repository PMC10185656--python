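"""Synthetic multichannel neuron images and patch-clamp sweeps with ground truth.

The generator emulates the raw data of an iPSC-derived motor neuron
immunofluorescence / electrophysiology study so that every downstream
measurement can be validated against known truth:

* geometry — a convex soma, a tubular proximal axon split into a GAP
  segment (between soma and AIS) followed by an ankyrin-G-positive AIS
  segment, dendrites, and a background neurite network with a controllable
  area fraction;
* chemistry — per-channel emission amplitudes per region (nuclei, β3-tubulin,
  MAP2, AnkG, pNF-M/H, panNav, NF-L), optional phospho-neurofilament
  accumulation in the GAP or GAP+AIS, optional sodium-channel mislocalisation
  into the GAP, and NF-L soma puncta;
* electrophysiology — current-clamp step families (1-s steps) whose action
  potentials realise four firing regimes (none, one spike, adaptive,
  repetitive) from a closed-form spike template, plus voltage-clamp step
  families with known Na/K current amplitudes.

Everything is deterministic given (parameters, seed); rendering is 2-D
geometry replicated into a thin Z-stack because all downstream measurements
operate on maximum-intensity projections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .imgcore import MultichannelStack

CHANNELS = ("nuclei", "tuj1", "map2", "ankg", "pnf", "pannav", "nfl")

#: emission regions, in painting order (later entries override earlier ones)
REGIONS = ("neurites", "dendrites", "distal", "gap", "ais", "soma", "nucleus")


class GenerationError(ValueError):
    """A sampled or requested geometry violates a generator constraint."""


class RenderError(ValueError):
    """Ground truth cannot be rendered into the requested field."""


# ---------------------------------------------------------------------------
# imaging ground truth


def _default_amplitudes() -> dict:
    # per-channel emission level per region; background is the fill value
    return {
        "nuclei": {"background": 0.02, "nucleus": 0.9},
        "tuj1": {
            "background": 0.02, "soma": 0.85, "gap": 0.8, "ais": 0.8,
            "distal": 0.8, "dendrites": 0.7, "neurites": 0.55,
        },
        "map2": {
            "background": 0.02, "soma": 0.95, "dendrites": 0.8, "gap": 0.4,
        },
        "ankg": {"background": 0.03, "ais": 0.95},
        "pnf": {
            "background": 0.02, "soma": 0.12, "gap": 0.15, "ais": 0.15,
            "distal": 0.15, "dendrites": 0.05,
        },
        "pannav": {"background": 0.02, "soma": 0.05, "gap": 0.08, "ais": 0.8},
        "nfl": {"background": 0.02, "soma": 0.2, "puncta": 0.85},
    }


@dataclass
class NeuronParams:
    """Sampling ranges for one synthetic neuron.  Lengths/calibers in µm.

    Every ``(lo, hi)`` pair is sampled uniformly; degenerate ranges pin the
    value.  Amplitude jitter multiplies every non-background emission level
    by ``U(1-a, 1+a)`` per cell.
    """

    soma_radius: tuple[float, float] = (5.0, 8.5)
    gap_length: tuple[float, float] = (1.0, 6.0)
    ais_length: tuple[float, float] = (15.0, 45.0)
    gap_caliber: tuple[float, float] = (0.9, 1.5)
    ais_caliber: tuple[float, float] = (0.8, 1.4)
    distal_length: tuple[float, float] = (3.0, 8.0)
    axon_total_length: tuple[float, float] | None = None
    axon_angle_deg: tuple[float, float] = (-20.0, 20.0)
    axon_wiggle_deg: float = 6.0
    n_dendrites: tuple[int, int] = (2, 4)
    dendrite_length: tuple[float, float] = (6.0, 14.0)
    dendrite_caliber: tuple[float, float] = (0.6, 1.0)
    p_zero_ais: float = 0.0
    p_double_ais: float = 0.0
    p_accumulation: float = 0.0
    p_acc_gap_and_ais: float = 0.5
    accumulation_amplitude: float = 0.65
    nav_gap_amplitude: tuple[float, float] | None = None
    nfl_soma_fraction: tuple[float, float] = (0.05, 0.2)
    neurite_area_fraction: tuple[float, float] = (0.02, 0.06)
    amplitudes: dict = field(default_factory=_default_amplitudes)
    amp_jitter: float = 0.08


def control_params() -> NeuronParams:
    """Conditions of a healthy-control culture."""
    return NeuronParams(p_accumulation=0.05)


def calibration_params() -> NeuronParams:
    """Control cells for threshold calibration: pathology-free.

    Detection thresholds are defined on control cells that show no
    accumulations — a single accumulation-bearing cell in a small
    calibration set would drag a near-ceiling pooled percentile up to
    accumulation intensity and blind the detector.
    """
    return NeuronParams(p_accumulation=0.0)


def mutant_params() -> NeuronParams:
    """Conditions of a mutant (ALS-like) culture: longer GAP, thicker
    proximal axon, sodium-channel leakage into the GAP, frequent
    neurofilament accumulations."""
    return NeuronParams(
        gap_length=(5.0, 14.0),
        gap_caliber=(1.5, 2.3),
        ais_caliber=(1.1, 1.8),
        nav_gap_amplitude=(0.3, 0.5),
        p_accumulation=0.5,
        nfl_soma_fraction=(0.15, 0.4),
    )


@dataclass
class NeuronGroundTruth:
    """Complete per-cell imaging ground truth (coordinates in µm)."""

    cell_id: str
    soma_polygon: np.ndarray          # (n, 2) closed (x, y) polygon, µm
    soma_area: float                  # µm², shoelace area of the polygon
    axon_path: np.ndarray             # (m, 2) polyline from soma boundary
    gap_length: float
    ais_length: float
    gap_caliber: float
    ais_caliber: float
    n_ais: int
    has_accumulation: bool
    accumulation_extent: str          # none | gap_only | gap_and_ais
    channel_amplitudes: dict          # channel -> region -> emission level
    nfl_soma_fraction: float
    neurite_area_fraction: float
    seed: int
    dendrites: list = field(default_factory=list)   # [(path, caliber), ...]
    secondary_axon: np.ndarray | None = None        # second AIS branch
    secondary_ais_length: float = 0.0

    def __post_init__(self) -> None:
        if self.accumulation_extent not in ("none", "gap_only", "gap_and_ais"):
            raise GenerationError(
                f"bad accumulation_extent {self.accumulation_extent!r}"
            )
        if self.has_accumulation != (self.accumulation_extent != "none"):
            raise GenerationError(
                "has_accumulation inconsistent with accumulation_extent"
            )
        axon_len = float(
            np.linalg.norm(np.diff(self.axon_path, axis=0), axis=1).sum()
        )
        if self.gap_length + self.ais_length > axon_len + 1e-9:
            raise GenerationError(
                "gap_length + ais_length exceeds axon path length "
                f"({self.gap_length} + {self.ais_length} > {axon_len:.3f})"
            )


def _u(rng: np.random.Generator, rng_pair) -> float:
    lo, hi = rng_pair
    if hi < lo:
        raise GenerationError(f"empty range ({lo}, {hi})")
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def _polygon_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _convex_soma(rng: np.random.Generator, centre, radius: float) -> np.ndarray:
    """Convex polygon: hull of radially jittered boundary points."""
    from scipy.spatial import ConvexHull

    ang = np.sort(rng.uniform(0, 2 * np.pi, 14))
    r = radius * rng.uniform(0.75, 1.0, ang.size)
    pts = np.column_stack(
        [centre[0] + r * np.cos(ang), centre[1] + r * np.sin(ang)]
    )
    hull = ConvexHull(pts)
    return pts[hull.vertices]


def _ray_polygon_exit(poly: np.ndarray, centre, direction) -> np.ndarray:
    """Point where a ray from the centre leaves a convex polygon."""
    best_t = 0.0
    n = len(poly)
    d = np.asarray(direction, float)
    c = np.asarray(centre, float)
    for i in range(n):
        a, b = poly[i], poly[(i + 1) % n]
        e = b - a
        denom = d[0] * (-e[1]) - d[1] * (-e[0])
        if abs(denom) < 1e-12:
            continue
        rhs = a - c
        t = (rhs[0] * (-e[1]) - rhs[1] * (-e[0])) / denom
        s = (d[0] * rhs[1] - d[1] * rhs[0]) / denom
        if t > best_t and -1e-9 <= s <= 1 + 1e-9:
            best_t = t
    return c + best_t * d


def _wiggly_path(
    rng: np.random.Generator, start, angle: float, total: float,
    wiggle_deg: float, step: float = 4.0,
) -> np.ndarray:
    pts = [np.asarray(start, float)]
    remaining = total
    a = angle
    while remaining > 1e-9:
        seg = min(step, remaining)
        a += np.deg2rad(rng.uniform(-wiggle_deg, wiggle_deg))
        pts.append(pts[-1] + seg * np.array([np.cos(a), np.sin(a)]))
        remaining -= seg
    return np.asarray(pts)


def generate_neuron(
    params: NeuronParams, seed: int, cell_id: str | None = None,
    field_um: tuple[float, float] = (56.0, 88.0),
) -> NeuronGroundTruth:
    """Sample one neuron ground truth.  Identical (params, seed) pairs give
    identical records.

    ``field_um`` is the (height, width) of the target field; the soma is
    placed near the left edge and the axon heads right so that default
    parameter ranges always fit.
    """
    rng = np.random.default_rng(seed)
    h, w = field_um

    soma_radius = _u(rng, params.soma_radius)
    centre = np.array([
        soma_radius + 4.0 + rng.uniform(0, 2.0),
        h / 2 + rng.uniform(-3.0, 3.0),
    ])
    poly = _convex_soma(rng, centre, soma_radius)

    gap_length = _u(rng, params.gap_length)
    ais_length = _u(rng, params.ais_length)
    if params.axon_total_length is not None:
        total = _u(rng, params.axon_total_length)
        if total < gap_length + ais_length:
            raise GenerationError(
                "axon_total_length < gap_length + ais_length: "
                f"{total} < {gap_length} + {ais_length}"
            )
    else:
        total = gap_length + ais_length + _u(rng, params.distal_length)

    angle = np.deg2rad(_u(rng, params.axon_angle_deg))
    start = _ray_polygon_exit(poly, centre, [np.cos(angle), np.sin(angle)])
    axon_path = _wiggly_path(rng, start, angle, total, params.axon_wiggle_deg)
    if (axon_path.min(axis=0) < 1.0).any() or (
        axon_path[:, 0].max() > w - 1.0 or axon_path[:, 1].max() > h - 1.0
    ):
        # re-draw straighter before giving up
        axon_path = _wiggly_path(rng, start, angle, total, 0.0)

    # dendrites leave the soma away from the axon direction
    dendrites = []
    n_dend = int(rng.integers(params.n_dendrites[0], params.n_dendrites[1] + 1))
    for _ in range(n_dend):
        da = angle + np.deg2rad(rng.uniform(60.0, 300.0))
        dstart = _ray_polygon_exit(poly, centre, [np.cos(da), np.sin(da)])
        dlen = _u(rng, params.dendrite_length)
        dpath = _wiggly_path(rng, dstart, da, dlen, 10.0, step=3.0)
        dpath[:, 0] = np.clip(dpath[:, 0], 0.5, w - 0.5)
        dpath[:, 1] = np.clip(dpath[:, 1], 0.5, h - 0.5)
        dendrites.append((dpath, _u(rng, params.dendrite_caliber)))

    # 0 / 1 / 2 AIS branches
    u = rng.uniform()
    if u < params.p_zero_ais:
        n_ais = 0
    elif u < params.p_zero_ais + params.p_double_ais:
        n_ais = 2
    else:
        n_ais = 1
    secondary_axon = None
    secondary_ais_length = 0.0
    if n_ais == 2:
        sa = angle + np.deg2rad(rng.choice([-1.0, 1.0]) * rng.uniform(35.0, 55.0))
        sstart = _ray_polygon_exit(poly, centre, [np.cos(sa), np.sin(sa)])
        secondary_ais_length = float(rng.uniform(12.0, 20.0))
        secondary_axon = _wiggly_path(
            rng, sstart, sa, 2.0 + secondary_ais_length + 2.0, 4.0
        )
        secondary_axon[:, 0] = np.clip(secondary_axon[:, 0], 0.5, w - 0.5)
        secondary_axon[:, 1] = np.clip(secondary_axon[:, 1], 0.5, h - 0.5)

    # accumulation status; zero-GAP cells cannot host a GAP accumulation
    has_acc = bool(rng.uniform() < params.p_accumulation)
    if gap_length <= 0:
        has_acc = False
    if has_acc:
        extent = (
            "gap_and_ais"
            if rng.uniform() < params.p_acc_gap_and_ais
            else "gap_only"
        )
    else:
        extent = "none"

    amps = {c: dict(v) for c, v in params.amplitudes.items()}
    jitter = params.amp_jitter
    if jitter > 0:
        for ch in amps:
            f = float(rng.uniform(1 - jitter, 1 + jitter))
            for region, a in amps[ch].items():
                if region != "background":
                    amps[ch][region] = a * f
    if params.nav_gap_amplitude is not None:
        amps["pannav"]["gap"] = _u(rng, params.nav_gap_amplitude)
    if has_acc:
        amps["pnf"]["gap"] = params.accumulation_amplitude
        if extent == "gap_and_ais":
            amps["pnf"]["ais"] = params.accumulation_amplitude

    return NeuronGroundTruth(
        cell_id=cell_id or f"cell{seed:06d}",
        soma_polygon=poly,
        soma_area=_polygon_area(poly),
        axon_path=axon_path,
        gap_length=gap_length,
        ais_length=ais_length,
        gap_caliber=_u(rng, params.gap_caliber),
        ais_caliber=_u(rng, params.ais_caliber),
        n_ais=n_ais,
        has_accumulation=has_acc,
        accumulation_extent=extent,
        channel_amplitudes=amps,
        nfl_soma_fraction=_u(rng, params.nfl_soma_fraction),
        neurite_area_fraction=_u(rng, params.neurite_area_fraction),
        seed=seed,
        dendrites=dendrites,
        secondary_axon=secondary_axon,
        secondary_ais_length=secondary_ais_length,
    )


# ---------------------------------------------------------------------------
# rendering


@dataclass
class RenderConfig:
    """Rasterisation settings.  ``field_size`` is (rows, cols) in px."""

    pixel_size: float = 0.2            # µm/px (63x objective regime)
    z_slices: int = 5
    psf_sigma: float = 0.2             # µm; 0 disables blurring
    noise_gaussian_sd: float = 0.02    # fraction of dynamic range
    noise_poisson_scale: float = 0.0   # photons per unit intensity; 0 = off
    bit_depth: int = 16
    field_size: tuple[int, int] = (280, 440)
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def field_um(self) -> tuple[float, float]:
        return (
            self.field_size[0] * self.pixel_size,
            self.field_size[1] * self.pixel_size,
        )


def _pixel_grid(shape):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return rr, cc


def _rasterize_polygon(poly_um, pixel_size, shape) -> np.ndarray:
    from skimage.draw import polygon as draw_polygon

    rows = poly_um[:, 1] / pixel_size - 0.5
    cols = poly_um[:, 0] / pixel_size - 0.5
    rr, cc = draw_polygon(rows, cols, shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _sample_path(path_um: np.ndarray, step_um: float):
    """Resample a polyline at ~step_um spacing; returns points + arclength."""
    seg = np.linalg.norm(np.diff(path_um, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(np.ceil(total / step_um)) + 1, 2)
    si = np.linspace(0.0, total, n)
    x = np.interp(si, s, path_um[:, 0])
    y = np.interp(si, s, path_um[:, 1])
    return np.column_stack([x, y]), si


def _tube_masks(
    path_um: np.ndarray, radius_of_s, pixel_size: float, shape,
    max_radius_um: float,
):
    """Pixels within a varying-radius tube around a path, with the arclength
    of the nearest path sample for segment assignment."""
    samples, arclen = _sample_path(path_um, step_um=pixel_size / 3.0)
    tree = cKDTree(samples / pixel_size - 0.5)  # px coords (x, y)
    pad = int(np.ceil(max_radius_um / pixel_size)) + 2
    r0 = max(int(np.floor(path_um[:, 1].min() / pixel_size)) - pad, 0)
    r1 = min(int(np.ceil(path_um[:, 1].max() / pixel_size)) + pad, shape[0])
    c0 = max(int(np.floor(path_um[:, 0].min() / pixel_size)) - pad, 0)
    c1 = min(int(np.ceil(path_um[:, 0].max() / pixel_size)) + pad, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    pts = np.column_stack([cc.ravel(), rr.ravel()]).astype(float)
    dist, idx = tree.query(pts)
    dist_um = dist * pixel_size
    s_um = arclen[idx]
    inside = dist_um <= radius_of_s(s_um)
    out = np.zeros(shape, dtype=bool)
    out[rr.ravel()[inside], cc.ravel()[inside]] = True
    s_map = np.full(shape, np.nan)
    s_map[rr.ravel()[inside], cc.ravel()[inside]] = s_um[inside]
    return out, s_map


def render_stack(
    gt: NeuronGroundTruth, cfg: RenderConfig
) -> tuple[MultichannelStack, dict[str, np.ndarray]]:
    """Render ground truth into a multichannel Z-stack plus label masks.

    Returns the stack and a dict of boolean masks exactly marking the
    ground-truth pixels of each region (``soma``, ``gap``, ``ais``,
    ``distal``, ``dendrites``, ``neurites``, ``nucleus``, and ``ais2`` for
    a secondary AIS branch).
    """
    shape = cfg.field_size
    ps = cfg.pixel_size
    h_um, w_um = cfg.field_um
    for pts in [gt.soma_polygon, gt.axon_path]:
        if (pts[:, 0].min() < 0 or pts[:, 1].min() < 0
                or pts[:, 0].max() >= w_um or pts[:, 1].max() >= h_um):
            raise RenderError(
                f"cell {gt.cell_id}: geometry outside the "
                f"{h_um:.0f}x{w_um:.0f} µm field"
            )
    rng = np.random.default_rng([int(gt.seed) % (2**31), 7])

    soma = _rasterize_polygon(gt.soma_polygon, ps, shape)

    # proximal axon tube: caliber switches from GAP to AIS to distal
    g, a = gt.gap_length, gt.ais_length
    rg, ra = gt.gap_caliber / 2.0, gt.ais_caliber / 2.0
    rd = ra * 0.8

    def radius_of_s(s):
        return np.where(s < g, rg, np.where(s < g + a, ra, rd))

    axon, s_map = _tube_masks(
        gt.axon_path, radius_of_s, ps, shape, max(rg, ra)
    )
    axon &= ~soma
    gap = axon & (s_map < g)
    ais = axon & (s_map >= g) & (s_map < g + a)
    distal = axon & (s_map >= g + a)
    if gt.n_ais == 0:
        # geometric AIS exists but carries no AnkG signal
        pass

    ais2 = np.zeros(shape, dtype=bool)
    if gt.secondary_axon is not None:
        sg, sa = 2.0, gt.secondary_ais_length
        tube2, s2 = _tube_masks(
            gt.secondary_axon, lambda s: np.full_like(s, ra), ps, shape, ra
        )
        tube2 &= ~soma
        ais2 = tube2 & (s2 >= sg) & (s2 < sg + sa)
        distal |= tube2 & ~ais2

    dendr = np.zeros(shape, dtype=bool)
    for dpath, dcal in gt.dendrites:
        t, _ = _tube_masks(
            dpath, lambda s, r=dcal / 2.0: np.full_like(s, r), ps, shape,
            dcal / 2.0,
        )
        dendr |= t
    dendr &= ~(soma | axon | ais2)

    # nucleus: disc at the soma centroid
    centre = gt.soma_polygon.mean(axis=0)
    rr, cc = _pixel_grid(shape)
    d2 = ((cc + 0.5) * ps - centre[0]) ** 2 + ((rr + 0.5) * ps - centre[1]) ** 2
    nucleus = (d2 <= (0.5 * np.sqrt(gt.soma_area / np.pi)) ** 2) & soma

    neurites = _neurite_network(
        rng, shape, ps, gt.neurite_area_fraction,
        occupied=soma, already_positive=axon | ais2 | dendr,
    )

    masks = {
        "soma": soma, "gap": gap, "ais": ais, "ais2": ais2,
        "distal": distal, "dendrites": dendr, "neurites": neurites,
        "nucleus": nucleus,
    }

    region_px = {
        "neurites": neurites, "dendrites": dendr, "distal": distal,
        "gap": gap, "ais": ais if gt.n_ais != 0 else np.zeros(shape, bool),
        "soma": soma, "nucleus": nucleus,
    }
    # secondary AIS emits like the primary one
    planes = {}
    for ch in cfg.channels:
        amps = gt.channel_amplitudes.get(ch, {"background": 0.0})
        base = np.full(shape, amps.get("background", 0.0))
        for region in REGIONS:
            if region in amps:
                base[region_px[region]] = amps[region]
        if ch == "ankg" and gt.n_ais != 0 and "ais" in amps:
            base[ais2] = amps["ais"]
        if ch == "pnf" and gt.has_accumulation:
            base[gap] = amps["gap"]  # amplitudes already hold the elevation
        if ch == "nfl" and "puncta" in amps:
            base = _paint_nfl_puncta(
                base, soma, gt.nfl_soma_fraction, amps["puncta"], rng
            )
        if cfg.psf_sigma > 0:
            base = ndimage.gaussian_filter(base, cfg.psf_sigma / ps)
        planes[ch] = base

    # thin Z-stack: per-slice axial weight peaking at exactly 1 mid-stack
    z = cfg.z_slices
    centre_z = (z - 1) / 2.0
    sigma_z = max(z / 3.0, 0.5)
    weights = np.exp(-0.5 * ((np.arange(z) - centre_z) / sigma_z) ** 2)
    weights[int(round(centre_z))] = 1.0

    data = np.empty((len(cfg.channels), z, shape[0], shape[1]))
    for ci, ch in enumerate(cfg.channels):
        stack_ch = planes[ch][None, :, :] * weights[:, None, None]
        if cfg.noise_poisson_scale > 0:
            stack_ch = (
                rng.poisson(np.maximum(stack_ch, 0) * cfg.noise_poisson_scale)
                / cfg.noise_poisson_scale
            )
        if cfg.noise_gaussian_sd > 0:
            stack_ch = stack_ch + cfg.noise_gaussian_sd * rng.standard_normal(
                (z, shape[0], shape[1]), dtype=np.float32
            )
        data[ci] = stack_ch

    stack = MultichannelStack(
        data=data, channel_names=list(cfg.channels), pixel_size=ps
    )
    return stack, masks


def _paint_nfl_puncta(base, soma, fraction, amplitude, rng):
    idx = np.flatnonzero(soma.ravel())
    k = int(round(fraction * idx.size))
    chosen = rng.choice(idx, size=k, replace=False)
    out = base.copy().ravel()
    out[chosen] = amplitude
    return out.reshape(base.shape)


def _neurite_network(rng, shape, ps, target_fraction, occupied, already_positive):
    """Random straight thin neurites until the non-soma positive area
    fraction (including axon/dendrites) reaches the target."""
    h, w = shape
    denom = int((~occupied).sum())
    target_px = int(round(target_fraction * denom))
    union = already_positive & ~occupied
    neurites = np.zeros(shape, dtype=bool)
    covered = int(union.sum())
    guard = 0
    from skimage.draw import line as draw_line

    while covered < target_px and guard < 3000:
        guard += 1
        length = rng.uniform(8.0, 20.0) / ps
        ang = rng.uniform(0, 2 * np.pi)
        r0 = rng.uniform(0, h - 1)
        c0 = rng.uniform(0, w - 1)
        r1 = np.clip(r0 + length * np.sin(ang), 0, h - 1)
        c1 = np.clip(c0 + length * np.cos(ang), 0, w - 1)
        rr, cc = draw_line(int(r0), int(c0), int(r1), int(c1))
        # dilate to ~0.4 µm caliber inside a local window only
        lo_r, hi_r = max(rr.min() - 2, 0), min(rr.max() + 3, h)
        lo_c, hi_c = max(cc.min() - 2, 0), min(cc.max() + 3, w)
        win = np.zeros((hi_r - lo_r, hi_c - lo_c), dtype=bool)
        win[rr - lo_r, cc - lo_c] = True
        win = ndimage.binary_dilation(win)
        win &= ~occupied[lo_r:hi_r, lo_c:hi_c]
        added = win & ~union[lo_r:hi_r, lo_c:hi_c]
        covered += int(added.sum())
        union[lo_r:hi_r, lo_c:hi_c] |= win
        neurites[lo_r:hi_r, lo_c:hi_c] |= win
    return neurites & ~already_positive


# ---------------------------------------------------------------------------
# annotations (the stand-in for the semi-manual inputs)


def annotation_for(gt: NeuronGroundTruth, cfg: RenderConfig):
    """Build the per-cell annotation (soma seed + neurite entry zones) that
    the morphometry stage consumes, from ground truth."""
    from .aismorph import CellAnnotation, NeuriteEntry

    ps = cfg.pixel_size
    centre = gt.soma_polygon.mean(axis=0)
    seed_px = (int(round(centre[1] / ps - 0.5)), int(round(centre[0] / ps - 0.5)))
    entries = []

    def entry_from(path, caliber):
        p0, p1 = path[0], path[1]
        d = p1 - p0
        d = d / max(np.linalg.norm(d), 1e-9)
        return NeuriteEntry(
            point=(float(p0[1] / ps - 0.5), float(p0[0] / ps - 0.5)),
            direction=(float(d[1]), float(d[0])),
            width_um=float(caliber),
        )

    for dpath, dcal in gt.dendrites:
        entries.append(entry_from(dpath, dcal))
    entries.append(entry_from(gt.axon_path, gt.gap_caliber))
    if gt.secondary_axon is not None:
        entries.append(entry_from(gt.secondary_axon, gt.ais_caliber))
    return CellAnnotation(
        cell_id=gt.cell_id, soma_seed=seed_px, neurite_entries=entries
    )


# ---------------------------------------------------------------------------
# electrophysiology ground truth and sweep synthesis


@dataclass
class ApTemplate:
    """Closed-form action-potential waveform added on top of the membrane
    response: ``amp * (1 - exp(-t/tau_rise))**2 * exp(-t/tau_fall)``,
    peak-normalised.  The sigmoidal onset gives a well-defined voltage at
    which dV/dt first exceeds a detection criterion."""

    amplitude: float = 95.0   # mV from onset to peak
    tau_rise: float = 0.3e-3  # s
    tau_fall: float = 1.5e-3  # s
    duration: float = 10e-3   # s of support

    def _shape_raw(self, t):
        t = np.asarray(t, dtype=float)
        out = np.where(
            t >= 0,
            (1 - np.exp(-np.maximum(t, 0) / self.tau_rise)) ** 2
            * np.exp(-np.maximum(t, 0) / self.tau_fall),
            0.0,
        )
        return out

    @property
    def t_peak(self) -> float:
        # g'(t)=0: 2/tau_r * e^{-t/tau_r}/(1-e^{-t/tau_r}) = 1/tau_f
        return brentq(
            lambda t: (2 / self.tau_rise) * np.exp(-t / self.tau_rise)
            / (1 - np.exp(-t / self.tau_rise))
            - 1 / self.tau_fall,
            1e-7, self.duration,
        )

    @property
    def peak_norm(self) -> float:
        return float(self._shape_raw(self.t_peak))

    def waveform(self, t):
        """Voltage offset (mV) at time t (s) after template onset."""
        return self.amplitude * self._shape_raw(t) / self.peak_norm

    def dvdt(self, t):
        """Analytic derivative of the waveform, mV/s."""
        t = np.asarray(t, dtype=float)
        tr, tf = self.tau_rise, self.tau_fall
        e_r = np.exp(-np.maximum(t, 0) / tr)
        e_f = np.exp(-np.maximum(t, 0) / tf)
        g = (1 - e_r) ** 2 * e_f
        dg = (2 * (1 - e_r) * e_r / tr) * e_f - g / tf
        return np.where(t >= 0, self.amplitude / self.peak_norm * dg, 0.0)

    def onset_crossing(self, criterion_mv_per_ms: float = 10.0) -> float:
        """Time (s) at which dV/dt first reaches the criterion."""
        crit = criterion_mv_per_ms * 1e3  # mV/s
        # bracket between onset and the point of maximal rise
        grid = np.linspace(1e-9, self.t_peak, 2000)
        t_steepest = grid[int(np.argmax(self.dvdt(grid)))]
        return brentq(lambda t: self.dvdt(t) - crit, 1e-9, t_steepest)

    def threshold_offset(self, criterion_mv_per_ms: float = 10.0) -> float:
        """Voltage offset above template onset where dV/dt crosses the
        criterion — the template's intrinsic spike threshold."""
        return float(self.waveform(self.onset_crossing(criterion_mv_per_ms)))

    def half_width(self, criterion_mv_per_ms: float = 10.0) -> float:
        """Analytic width (s) at half height between the criterion-defined
        threshold and the peak."""
        thr = self.threshold_offset(criterion_mv_per_ms)
        level = thr + (self.amplitude - thr) / 2.0
        tp = self.t_peak
        t_up = brentq(lambda t: self.waveform(t) - level, 1e-9, tp)
        t_dn = brentq(lambda t: self.waveform(t) - level, tp, self.duration)
        return t_dn - t_up


REGIMES = ("none", "one_spike", "adaptive", "repetitive")

DEFAULT_PROTOCOL = tuple(float(a) for a in range(5, 105, 5))  # pA, 1-s steps


@dataclass
class EphysGroundTruth:
    """Per-cell electrophysiology ground truth."""

    cell_id: str
    regime: str
    spike_times_per_sweep: list          # s from step onset, one list/sweep
    true_rmp: float                      # mV, raw pipette potential baseline
    true_rheobase: float | None          # pA, None when regime is none
    na_peak: float                       # pA (negative, inward)
    k_low: float                         # pA (positive, late outward)
    cm: float                            # pF
    rs_start: float = 6.0                # MΩ
    rs_end: float = 6.3                  # MΩ
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise GenerationError(f"unknown regime {self.regime!r}")
        counts = [len(s) for s in self.spike_times_per_sweep]
        if self.regime == "none" and any(counts):
            raise GenerationError("regime 'none' must have no spikes")
        if self.regime == "one_spike" and counts and max(counts) > 1:
            raise GenerationError("regime 'one_spike' allows one spike/sweep")


@dataclass
class EphysParams:
    """Sampling ranges for synthetic recordings."""

    rmp: tuple[float, float] = (-75.0, -58.0)
    cm: tuple[float, float] = (20.0, 60.0)
    rs: tuple[float, float] = (5.0, 8.0)
    rs_drift_frac: tuple[float, float] = (0.0, 0.12)
    na_peak: tuple[float, float] = (-1500.0, -500.0)
    k_low: tuple[float, float] = (200.0, 700.0)
    rheobase_index: tuple[int, int] = (2, 7)   # index into the protocol
    input_resistance_gohm: float = 0.3
    tau_membrane: float = 0.02                  # s
    template: ApTemplate = field(default_factory=ApTemplate)


def generate_ephys_cell(
    params: EphysParams, regime: str, seed: int,
    protocol: Sequence[float] = DEFAULT_PROTOCOL,
    step_duration: float = 1.0, cell_id: str | None = None,
) -> EphysGroundTruth:
    """Sample ground truth realising one of the four firing regimes."""
    if regime not in REGIMES:
        raise GenerationError(f"unknown regime {regime!r}")
    rng = np.random.default_rng(seed)
    n_sweeps = len(protocol)
    spikes: list[list[float]] = [[] for _ in range(n_sweeps)]
    rheo = None
    if regime != "none":
        i0 = int(rng.integers(params.rheobase_index[0],
                              params.rheobase_index[1] + 1))
        i0 = min(i0, n_sweeps - 1)
        rheo = float(protocol[i0])
        for i in range(i0, n_sweeps):
            extra = i - i0
            if regime == "one_spike":
                t0 = 0.16 - 0.004 * min(extra, 10)
                spikes[i] = [t0]
            elif regime == "adaptive":
                k = min(3 + extra // 2, 7)
                isi0, r = 0.030, 1.25
                t = 0.13 - 0.003 * min(extra, 8)
                times = [t]
                for j in range(k - 1):
                    t += isi0 * r**j
                    times.append(t)
                spikes[i] = times
            else:  # repetitive
                k = min(8 + extra, 20)
                times = np.linspace(0.05, 0.97, k)
                spikes[i] = list(map(float, times))
        for ts in spikes:
            if ts and (min(ts) < 0 or max(ts) >= step_duration):
                raise GenerationError("spike time outside the step window")
    rs0 = _u(rng, params.rs)
    return EphysGroundTruth(
        cell_id=cell_id or f"ephys{seed:06d}",
        regime=regime,
        spike_times_per_sweep=spikes,
        true_rmp=_u(rng, params.rmp),
        true_rheobase=rheo,
        na_peak=_u(rng, params.na_peak),
        k_low=_u(rng, params.k_low),
        cm=_u(rng, params.cm),
        rs_start=rs0,
        rs_end=rs0 * (1 + _u(rng, params.rs_drift_frac)),
        seed=seed,
    )


def generate_sweeps(
    gt: EphysGroundTruth,
    protocol: Sequence[float] = DEFAULT_PROTOCOL,
    fs: float = 50_000.0,
    params: EphysParams | None = None,
    noise_sd_mv: float = 0.3,
    pre_s: float = 0.1,
    step_duration: float = 1.0,
    post_s: float = 0.1,
    junction_potential: float = 15.0,
):
    """Synthesise a current-clamp sweep family.

    Baseline equals ``gt.true_rmp`` (plus noise); each step drives an
    exponential subthreshold depolarisation, and the spike template is
    added with its peak at each ground-truth spike time.  Noise is
    low-pass-smoothed white noise rescaled to ``noise_sd_mv``.
    """
    from .ephysfeat import SweepSet

    if fs <= 0:
        raise GenerationError("fs must be > 0")
    amps = np.asarray(protocol, dtype=float)
    if np.any(np.diff(amps) <= 0) or np.any(amps <= 0):
        raise GenerationError("protocol must be strictly increasing, positive")
    params = params or EphysParams()
    tpl = params.template
    n = int(round((pre_s + step_duration + post_s) * fs))
    t = np.arange(n) / fs
    in_step = (t >= pre_s) & (t < pre_s + step_duration)
    rng = np.random.default_rng([int(gt.seed) % (2**31), 11])

    peak_shift = tpl.t_peak
    sweeps = np.empty((len(amps), n))
    for i, amp in enumerate(amps):
        dv = params.input_resistance_gohm * amp  # GΩ·pA = mV
        v = np.full(n, gt.true_rmp)
        ts = t[in_step] - pre_s
        v[in_step] += dv * (1 - np.exp(-ts / params.tau_membrane))
        after = t >= pre_s + step_duration
        v_end = dv * (1 - np.exp(-step_duration / params.tau_membrane))
        v[after] += v_end * np.exp(
            -(t[after] - pre_s - step_duration) / params.tau_membrane
        )
        for st in gt.spike_times_per_sweep[i]:
            if not 0 <= st < step_duration:
                raise GenerationError(
                    f"spike time {st} outside the step window"
                )
            onset = pre_s + st - peak_shift
            idx0 = int(np.floor(onset * fs))
            idx1 = min(int(np.ceil((onset + tpl.duration) * fs)), n)
            tt = t[idx0:idx1] - onset
            v[idx0:idx1] += tpl.waveform(tt)
        if noise_sd_mv > 0:
            white = rng.normal(0, 1.0, n)
            smooth = ndimage.gaussian_filter1d(white, sigma=4.0)
            smooth *= noise_sd_mv / max(smooth.std(), 1e-12)
            v = v + smooth
        sweeps[i] = v
    return SweepSet(
        mode="current_clamp",
        fs=fs,
        sweeps=sweeps,
        command_amplitudes=amps,
        rs_start=gt.rs_start,
        rs_end=gt.rs_end,
        cm=gt.cm,
        junction_potential=junction_potential,
        step_duration=step_duration,
        step_onset=pre_s,
        cell_id=gt.cell_id,
    )


def generate_baseline(
    gt: EphysGroundTruth, duration: float = 31.0, fs: float = 5_000.0,
    noise_sd_mv: float = 0.3,
):
    """Quiescent pre-protocol recording used for RMP averaging."""
    n = int(round(duration * fs))
    rng = np.random.default_rng([int(gt.seed) % (2**31), 13])
    v = np.full(n, gt.true_rmp)
    if noise_sd_mv > 0:
        white = rng.normal(0, 1.0, n)
        smooth = ndimage.gaussian_filter1d(white, sigma=4.0)
        smooth *= noise_sd_mv / max(smooth.std(), 1e-12)
        v = v + smooth
    return v


def generate_vc_sweeps(
    gt: EphysGroundTruth,
    step_voltages: Sequence[float] = tuple(range(-20, 45, 10)),
    fs: float = 50_000.0,
    noise_sd_pa: float = 5.0,
    pre_s: float = 0.02,
    step_duration: float = 0.2,
):
    """Voltage-clamp step family: a fast inactivating inward (Na-like)
    transient followed by a sustained outward (K-like) current.  The last
    sweep carries the full ground-truth amplitudes."""
    from .ephysfeat import SweepSet

    volts = np.asarray(step_voltages, dtype=float)
    n = int(round((pre_s + step_duration + 0.02) * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng([int(gt.seed) % (2**31), 17])
    tau_r, tau_f = 0.3e-3, 1.2e-3
    tp = np.log(tau_f / tau_r) * tau_r * tau_f / (tau_f - tau_r)
    na_shape = lambda ts: (np.exp(-ts / tau_f) - np.exp(-ts / tau_r)) / (
        np.exp(-tp / tau_f) - np.exp(-tp / tau_r)
    )
    sweeps = np.empty((len(volts), n))
    for i in range(len(volts)):
        scale = (i + 1) / len(volts)
        cur = np.zeros(n)
        ts = t - pre_s
        act = ts >= 0
        cur[act] += scale * gt.na_peak * na_shape(ts[act])
        cur[act] += scale * gt.k_low * (1 - np.exp(-ts[act] / 0.03))
        if noise_sd_pa > 0:
            white = rng.normal(0, 1.0, n)
            smooth = ndimage.gaussian_filter1d(white, sigma=4.0)
            smooth *= noise_sd_pa / max(smooth.std(), 1e-12)
            cur = cur + smooth
        sweeps[i] = cur
    return SweepSet(
        mode="voltage_clamp",
        fs=fs,
        sweeps=sweeps,
        command_amplitudes=volts,
        rs_start=gt.rs_start,
        rs_end=gt.rs_end,
        cm=gt.cm,
        step_duration=step_duration,
        step_onset=pre_s,
        cell_id=gt.cell_id,
    )


# ---------------------------------------------------------------------------
# cohort helpers and on-disk formats


def generate_cohort(
    n_cells: int,
    params: NeuronParams,
    cfg: RenderConfig,
    seed: int,
    group: str = "control",
):
    """Yield ``(gt, stack, masks, annotation)`` for a seeded cohort."""
    ss = np.random.SeedSequence([seed, 101])
    child_seeds = ss.generate_state(n_cells) % (2**31)
    for i in range(n_cells):
        gt = generate_neuron(
            params, int(child_seeds[i]),
            cell_id=f"{group}_{i:04d}", field_um=cfg.field_um,
        )
        stack, masks = render_stack(gt, cfg)
        yield gt, stack, masks, annotation_for(gt, cfg)


def ground_truth_frame(gts: Sequence[NeuronGroundTruth]) -> pd.DataFrame:
    """Tabular (CSV-ready) view of imaging ground truth, one row per cell."""
    rows = []
    for gt in gts:
        rows.append(
            {
                "cell_id": gt.cell_id,
                "soma_area": gt.soma_area,
                "gap_length": gt.gap_length,
                "ais_length": gt.ais_length,
                "gap_caliber": gt.gap_caliber,
                "ais_caliber": gt.ais_caliber,
                "n_ais": gt.n_ais,
                "has_accumulation": gt.has_accumulation,
                "accumulation_extent": gt.accumulation_extent,
                "nfl_soma_fraction": gt.nfl_soma_fraction,
                "neurite_area_fraction": gt.neurite_area_fraction,
                "seed": gt.seed,
            }
        )
    return pd.DataFrame(rows)


def write_sweepset_csv(sweepset, path_csv: str | Path) -> None:
    """Wide CSV (time + one column per sweep) plus a JSON metadata sidecar."""
    n = sweepset.sweeps.shape[1]
    t = np.arange(n) / sweepset.fs
    cols = {"time_s": t}
    for i, amp in enumerate(sweepset.command_amplitudes):
        cols[f"sweep_{i:02d}"] = sweepset.sweeps[i]
    pd.DataFrame(cols).to_csv(path_csv, index=False, float_format="%.6g")
    sidecar = {
        "mode": sweepset.mode,
        "fs": sweepset.fs,
        "command_amplitudes": list(map(float, sweepset.command_amplitudes)),
        "rs_start": sweepset.rs_start,
        "rs_end": sweepset.rs_end,
        "cm": sweepset.cm,
        "junction_potential": sweepset.junction_potential,
        "step_duration": sweepset.step_duration,
        "step_onset": sweepset.step_onset,
        "cell_id": sweepset.cell_id,
    }
    Path(str(path_csv) + ".json").write_text(json.dumps(sidecar, indent=1))
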