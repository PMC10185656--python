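"""Whole-culture neurofilament quantification.

Three read-outs characterise neurofilament pathology at the culture level:

* per-cell NF-L soma signal — the positive-area fraction of each soma
  above a threshold calibrated on randomly drawn control images, plus the
  median soma intensity;
* the prevalence of proximal pNF-M/H accumulations, aggregated per
  experiment (one percentage per differentiation batch) before any group
  statistic;
* neurite-network density — the percentage of field area positive for
  β3-tubulin after deleting all soma pixels from both numerator and
  denominator.

Threshold comparisons are strict (a pixel exactly at the threshold is
negative), matching the convention used throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imgcore import MeasurementError, Roi, ThresholdModel, positive_area_fraction

logger = logging.getLogger(__name__)


@dataclass
class NfCellRecord:
    """Per-cell NF-L soma quantification."""

    cell_id: str
    soma_nfl_fraction: float
    soma_nfl_median_intensity: float
    has_proximal_accumulation: bool = False


@dataclass
class FieldRecord:
    """Per-field neurite network density."""

    field_id: str
    tuj1_positive_fraction: float  # percent of non-soma field area
    n_cells: int


def random_control_images(
    images: Sequence[np.ndarray], n: int | None, seed: int
) -> list[np.ndarray]:
    """Seeded random subsample of control images for threshold calibration
    (``n=None`` keeps them all)."""
    if n is None or n >= len(images):
        return list(images)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(images), size=n, replace=False)
    return [images[i] for i in sorted(idx)]


def soma_nfl_quant(
    nfl_mip: np.ndarray,
    soma_rois: Mapping[str, Roi],
    thr: ThresholdModel,
) -> list[NfCellRecord]:
    """NF-L positive-area fraction and median intensity per soma.

    Cells whose ROI is empty are skipped with a logged reason.
    """
    records = []
    for cell_id, roi in soma_rois.items():
        if roi.n_pixels == 0:
            logger.warning("cell %s skipped: empty soma ROI", cell_id)
            continue
        records.append(
            NfCellRecord(
                cell_id=cell_id,
                soma_nfl_fraction=positive_area_fraction(nfl_mip, roi, thr),
                soma_nfl_median_intensity=float(
                    np.median(np.asarray(nfl_mip, float)[roi.mask])
                ),
            )
        )
    return records


def accumulation_prevalence(
    cells: pd.DataFrame,
    group_col: str = "group",
    experiment_col: str = "experiment",
    flag_col: str = "has_proximal_accumulation",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percentage of cells with proximal accumulations, per experiment.

    Returns ``(per_experiment, per_group)``: one percentage per
    (group, experiment), then the group mean ± SEM over experiments —
    mirroring a dot-per-experiment plot.  Empty experiments are excluded
    with a warning.
    """
    rows = []
    for (group, exp), sub in cells.groupby([group_col, experiment_col]):
        if len(sub) == 0:  # pragma: no cover - groupby drops empty groups
            logger.warning("experiment %s/%s empty; excluded", group, exp)
            continue
        rows.append(
            {
                group_col: group,
                experiment_col: exp,
                "n_cells": len(sub),
                "percent_with_accumulation": 100.0 * sub[flag_col].mean(),
            }
        )
    per_exp = pd.DataFrame(rows)
    if per_exp.empty:
        return per_exp, pd.DataFrame()
    per_group = (
        per_exp.groupby(group_col)["percent_with_accumulation"]
        .agg(
            mean="mean",
            sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0,
            n_experiments="count",
        )
        .reset_index()
    )
    return per_exp, per_group


def neurite_density(
    tuj1_mip: np.ndarray,
    soma_rois: Sequence[Roi],
    thr: ThresholdModel,
    field_id: str = "",
) -> FieldRecord:
    """β3-tubulin positive percentage of the field with somas deleted.

    Soma pixels are removed from both the numerator and the denominator so
    the measure reflects the neurite network only.
    """
    soma_union = np.zeros(np.asarray(tuj1_mip).shape, dtype=bool)
    for roi in soma_rois:
        soma_union |= roi.mask
    keep = ~soma_union
    if not keep.any():
        raise MeasurementError("soma ROIs cover the entire field")
    values = np.asarray(tuj1_mip, float)[keep]
    fraction = 100.0 * np.count_nonzero(values > thr.value) / values.size
    return FieldRecord(
        field_id=field_id,
        tuj1_positive_fraction=float(fraction),
        n_cells=len(soma_rois),
    )
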