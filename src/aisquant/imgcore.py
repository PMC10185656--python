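"""Image primitives shared by the imaging pipeline.

All quantitative imaging operations work on maximum-intensity projections
(MIP) of multichannel Z-stacks.  Intensities are handled as floating point
regardless of the stored bit depth; pixel coordinates are 0-based,
row-major, pixel-centred; areas are pixel counts scaled by ``pixel_size**2``
(µm² per pixel).

The key measurement here is the *integrated density* of a region of
interest: the product of the ROI area (µm²) and its mean gray value, which
is algebraically identical to the pixel-value sum times ``pixel_size**2``.
Intensity thresholds are calibrated on control images — by default the
percentile of the pooled control pixel distribution — and carry their
calibration provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

ROI_LABELS = ("soma", "gap", "ais", "accumulation", "neurites", "other")


class ChannelLookupError(KeyError):
    """Requested channel name is not present in a stack."""


class CalibrationError(ValueError):
    """Threshold calibration received unusable input."""


class MeasurementError(ValueError):
    """A measurement kernel received an unusable ROI or image."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class MultichannelStack:
    """A named-channel fluorescence Z-stack with physical pixel size.

    Parameters
    ----------
    data:
        Array of shape ``(n_channels, n_slices, height, width)``.
    channel_names:
        One name per channel; lookups are case-insensitive.
    pixel_size:
        Lateral pixel size in µm/px (> 0).
    """

    data: np.ndarray
    channel_names: list[str]
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(
                f"expected (C, Z, Y, X) data, got shape {self.data.shape}"
            )
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    def channel_index(self, name: str) -> int:
        lowered = [c.lower() for c in self.channel_names]
        try:
            return lowered.index(name.lower())
        except ValueError:
            raise ChannelLookupError(
                f"unknown channel {name!r}; available: {self.channel_names}"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(Z, Y, X)`` sub-stack for one channel."""
        return self.data[self.channel_index(name)]

    def write_ome_tiff(self, path: str | Path, bit_depth: int = 16) -> None:
        """Write the stack as an OME-TIFF with named channels.

        Intensities are clipped to [0, 1] and quantised to the requested
        bit depth (8 or 16).
        """
        if bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        dtype = np.uint8 if bit_depth == 8 else np.uint16
        scale = float(2**bit_depth - 1)
        raw = np.clip(self.data, 0.0, 1.0)
        quantised = np.round(raw * scale).astype(dtype)
        tifffile.imwrite(
            str(path),
            quantised,
            ome=True,
            metadata={
                "axes": "CZYX",
                "Channel": {"Name": list(self.channel_names)},
                "PhysicalSizeX": self.pixel_size,
                "PhysicalSizeY": self.pixel_size,
            },
        )

    @classmethod
    def read_ome_tiff(
        cls,
        path: str | Path,
        channel_names: Sequence[str] | None = None,
        pixel_size: float | None = None,
    ) -> "MultichannelStack":
        """Read an OME-TIFF (or plain multipage TIFF with explicit metadata).

        Channel names and pixel size are taken from the OME metadata when
        present; pass them explicitly for plain TIFFs or to override.
        Integer data are rescaled to [0, 1] by the dtype range.
        """
        with tifffile.TiffFile(str(path)) as tif:
            arr = tif.asarray()
            meta_names, meta_ps = _parse_ome_metadata(tif)
        if arr.ndim == 3:  # single channel
            arr = arr[None]
        if arr.ndim != 4:
            raise ValueError(f"cannot interpret TIFF of shape {arr.shape}")
        if np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(np.float64) / float(np.iinfo(arr.dtype).max)
        names = list(channel_names) if channel_names else meta_names
        if names is None or len(names) != arr.shape[0]:
            names = [f"ch{i}" for i in range(arr.shape[0])]
        ps = pixel_size if pixel_size is not None else meta_ps
        if ps is None:
            raise ValueError("pixel_size not in metadata; pass it explicitly")
        return cls(data=arr, channel_names=names, pixel_size=float(ps))


def _parse_ome_metadata(tif: tifffile.TiffFile):
    names = None
    ps = None
    try:
        import xml.etree.ElementTree as ET

        if tif.ome_metadata:
            root = ET.fromstring(tif.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            chans = root.findall(".//ome:Channel", ns)
            got = [c.get("Name") for c in chans]
            if got and all(got):
                names = got
            px = root.find(".//ome:Pixels", ns)
            if px is not None and px.get("PhysicalSizeX"):
                ps = float(px.get("PhysicalSizeX"))
    except Exception:  # noqa: BLE001 - metadata is best-effort
        logger.debug("OME metadata parse failed", exc_info=True)
    return names, ps


@dataclass
class Roi:
    """A labelled pixel set on a 2-D image.

    Stored as a boolean mask with the shape of the parent image; helper
    constructors accept explicit coordinate lists.
    """

    label: str
    mask: np.ndarray
    source_channel: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if self.label not in ROI_LABELS:
            raise ValueError(f"label must be one of {ROI_LABELS}")

    @classmethod
    def from_coords(
        cls,
        label: str,
        coords: np.ndarray,
        shape: tuple[int, int],
        source_channel: str = "",
    ) -> "Roi":
        mask = np.zeros(shape, dtype=bool)
        coords = np.asarray(coords, dtype=int)
        if coords.size:
            if coords[:, 0].min() < 0 or coords[:, 0].max() >= shape[0]:
                raise ValueError("ROI rows out of image bounds")
            if coords[:, 1].min() < 0 or coords[:, 1].max() >= shape[1]:
                raise ValueError("ROI cols out of image bounds")
            mask[coords[:, 0], coords[:, 1]] = True
        return cls(label=label, mask=mask, source_channel=source_channel)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def area(self, pixel_size: float) -> float:
        """ROI area in µm²."""
        return self.n_pixels * pixel_size**2

    # -- JSON serialisation (run-length encoded over the flattened mask) ----

    def to_json_dict(self) -> dict:
        flat = self.mask.ravel()
        # runs of True: store (start, length) pairs
        padded = np.concatenate(([False], flat, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, ends = edges[::2], edges[1::2]
        return {
            "label": self.label,
            "source_channel": self.source_channel,
            "shape": list(self.mask.shape),
            "rle": [[int(s), int(e - s)] for s, e in zip(starts, ends)],
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "Roi":
        shape = tuple(d["shape"])
        flat = np.zeros(int(np.prod(shape)), dtype=bool)
        for start, length in d["rle"]:
            flat[start : start + length] = True
        return cls(
            label=d["label"],
            mask=flat.reshape(shape),
            source_channel=d.get("source_channel", ""),
        )


def write_rois_json(rois: Sequence[Roi], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([r.to_json_dict() for r in rois], indent=1)
    )


def read_rois_json(path: str | Path) -> list[Roi]:
    return [Roi.from_json_dict(d) for d in json.loads(Path(path).read_text())]


@dataclass
class ThresholdModel:
    """An intensity threshold with its calibration provenance."""

    channel: str
    value: float
    calibration: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "channel": self.channel,
                    "value": self.value,
                    "calibration": self.calibration,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdModel":
        d = json.loads(Path(path).read_text())
        return cls(d["channel"], float(d["value"]), d.get("calibration", {}))


# ---------------------------------------------------------------------------
# operations


def max_intensity_projection(
    stack: MultichannelStack, channel: str
) -> np.ndarray:
    """Maximum-intensity projection of one channel over Z."""
    return stack.channel(channel).max(axis=0)


def calibrate_threshold(
    control_images: Sequence[np.ndarray],
    method: str = "percentile",
    param: float = 99.0,
    channel: str = "",
    control_ids: Sequence[str] | None = None,
) -> ThresholdModel:
    """Calibrate an intensity threshold on control images.

    The default (and currently only) method pools all pixels of the control
    images and takes the ``param``-th percentile as an order statistic of
    the pooled vector.  The returned model records the method, parameter
    and the ids of the control images it was calibrated on.
    """
    if len(control_images) == 0:
        raise CalibrationError("at least one control image is required")
    if method != "percentile":
        raise CalibrationError(f"unknown calibration method {method!r}")
    pooled = np.concatenate([np.asarray(im, float).ravel() for im in control_images])
    value = float(np.quantile(pooled, param / 100.0, method="inverted_cdf"))
    return ThresholdModel(
        channel=channel,
        value=value,
        calibration={
            "method": "percentile",
            "param": float(param),
            "control_image_ids": list(control_ids or []),
            "n_control_images": len(control_images),
            "n_pooled_pixels": int(pooled.size),
        },
    )


def subtract_background(
    image: np.ndarray,
    background: float | np.ndarray | None = None,
    rois: Sequence[Roi] | None = None,
) -> np.ndarray:
    """Subtract a background estimate, clipping at zero.

    When ``background`` is None it defaults to the median of pixels outside
    all registered ROIs (the whole image when no ROIs are given).
    """
    image = np.asarray(image, dtype=np.float64)
    if background is None:
        outside = np.ones(image.shape, dtype=bool)
        for roi in rois or []:
            outside &= ~roi.mask
        if not outside.any():
            raise MeasurementError("ROIs cover the image; no background pixels")
        background = float(np.median(image[outside]))
    background = np.asarray(background, dtype=np.float64)
    if not np.all(np.isfinite(background)) or np.any(background < 0):
        raise MeasurementError("background estimate must be finite and >= 0")
    if np.all(background >= image.max()):
        logger.warning(
            "background estimate %s exceeds image maximum; returning zeros",
            background,
        )
    return np.maximum(image - background, 0.0)


def integrated_density(
    image: np.ndarray, roi: Roi, pixel_size: float
) -> float:
    """Integrated density of a ROI: area (µm²) × mean gray value.

    Identically equal to the pixel-value sum times ``pixel_size**2``.
    """
    if roi.n_pixels == 0:
        raise MeasurementError(f"empty ROI ({roi.label})")
    image = np.asarray(image, dtype=np.float64)
    return float(image[roi.mask].sum() * pixel_size**2)


def positive_area_fraction(
    image: np.ndarray, roi: Roi, thr: ThresholdModel
) -> float:
    """Fraction of ROI pixels strictly above the threshold value.

    The comparison is strict: a pixel exactly at the threshold counts as
    negative.
    """
    if roi.n_pixels == 0:
        raise MeasurementError(f"empty ROI ({roi.label})")
    values = np.asarray(image, dtype=np.float64)[roi.mask]
    return float(np.count_nonzero(values > thr.value) / values.size)
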