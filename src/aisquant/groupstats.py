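"""Group comparisons: Kruskal–Wallis + Dunn, Fisher's exact, fold gate.

The decision layer mirrors the study design: measurements are compared
across groups with the Kruskal–Wallis H test (mid-ranks, tie-corrected)
followed by Dunn's pairwise z-tests with multiplicity adjustment (Holm by
default).  Frequency tables (e.g. firing-pattern distributions) are
compared pairwise with Fisher's exact test and Bonferroni adjustment.

Integrated-density measures carry an additional *fold-difference gate*:
a pairwise difference is only declared significant when the ratio of
group medians reaches the gate (default 3).  The gate is a conjunction —
it can only shrink the set of significant calls — and its direction
(require fold ≥ gate, the default, or fold ≤ gate) is configurable and
recorded in the report.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class StatsInputError(ValueError):
    """Unusable input to a statistical comparison."""


@dataclass
class ComparisonResult:
    """Outcome of one measure's group comparison."""

    measure: str
    groups: list[str]
    kw_statistic: float
    kw_p: float
    dunn_p: dict = field(default_factory=dict)   # (g1, g2) -> adjusted p
    dunn_p_raw: dict = field(default_factory=dict)
    fold_difference: dict = field(default_factory=dict)
    passes_fold_gate: dict = field(default_factory=dict)
    declared_significant: dict = field(default_factory=dict)


def kruskal_dunn(
    samples: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    adjust: str = "holm",
) -> ComparisonResult:
    """Kruskal–Wallis H (tie-corrected mid-ranks) with Dunn's post hoc.

    Dunn's pairwise z statistics use pooled mid-ranks with the standard
    tie correction; two-sided normal p values are adjusted over all pairs
    (Holm by default).
    """
    groups = list(samples)
    if len(groups) < 2:
        raise StatsInputError("at least two groups are required")
    arrays = {}
    for g in groups:
        arr = np.asarray(list(samples[g]), dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size < 2:
            raise StatsInputError(f"group {g!r} has fewer than 2 values")
        arrays[g] = arr

    h, p = stats.kruskal(*arrays.values())

    pooled = np.concatenate(list(arrays.values()))
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    offsets = np.cumsum([0] + [arrays[g].size for g in groups])
    mean_ranks = {
        g: ranks[offsets[i] : offsets[i + 1]].mean()
        for i, g in enumerate(groups)
    }
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(groups, 2))
    raw = {}
    for g1, g2 in pairs:
        se = math.sqrt(
            var_base * (1.0 / arrays[g1].size + 1.0 / arrays[g2].size)
        )
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        raw[(g1, g2)] = 2.0 * stats.norm.sf(abs(z))
    if raw:
        _, adj, _, _ = multipletests(list(raw.values()), method=adjust)
        adjusted = dict(zip(raw.keys(), map(float, adj)))
    else:
        adjusted = {}
    return ComparisonResult(
        measure="",
        groups=groups,
        kw_statistic=float(h),
        kw_p=float(p),
        dunn_p=adjusted,
        dunn_p_raw={k: float(v) for k, v in raw.items()},
        declared_significant={k: v < alpha for k, v in adjusted.items()},
    )


def fisher_exact_pairwise(
    counts: Mapping[str, Mapping[str, int]],
    alpha: float = 0.05,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Pairwise Fisher's exact tests on per-group category counts.

    For every group pair and category a 2×2 table (in category vs not)
    is tested two-sided; p values are adjusted over the whole family.
    Zero-margin tables yield p = 1 with a note.
    """
    groups = list(counts)
    categories = sorted({c for g in groups for c in counts[g]})
    totals = {g: sum(counts[g].values()) for g in groups}
    rows = []
    for g1, g2 in itertools.combinations(groups, 2):
        for cat in categories:
            a = counts[g1].get(cat, 0)
            b = totals[g1] - a
            c = counts[g2].get(cat, 0)
            d = totals[g2] - c
            note = ""
            if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
                p = 1.0
                note = "zero_margin"
            else:
                _, p = stats.fisher_exact([[a, b], [c, d]])
            rows.append(
                {
                    "group_a": g1,
                    "group_b": g2,
                    "category": cat,
                    "p": float(p),
                    "note": note,
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        _, adj, _, _ = multipletests(df["p"].to_numpy(), method=adjust)
        df["p_adj"] = adj
        df["significant"] = df["p_adj"] < alpha
    return df


def fold_gate(
    control: Sequence[float],
    mutant: Sequence[float],
    gate: float = 3.0,
    direction: str = "ge",
) -> tuple[float, bool]:
    """Fold difference of group medians (mutant / control) and gate verdict.

    With ``direction='ge'`` (default) the gate passes when the fold
    reaches the threshold; ``'le'`` inverts the reading.  A non-positive
    control median leaves the fold undefined and the gate fails closed.
    """
    control = np.asarray(list(control), dtype=float)
    mutant = np.asarray(list(mutant), dtype=float)
    control = control[~np.isnan(control)]
    mutant = mutant[~np.isnan(mutant)]
    if control.size == 0 or mutant.size == 0:
        raise StatsInputError("both samples must be non-empty")
    cm = float(np.median(control))
    if cm <= 0:
        return math.nan, False
    fold = float(np.median(mutant)) / cm
    passes = fold >= gate if direction == "ge" else fold <= gate
    return fold, passes


DEFAULT_ID_PREFIXES = ("id_",)


def build_report(
    measurements: pd.DataFrame,
    control_group: str,
    group_col: str = "group",
    measures: Sequence[str] | None = None,
    alpha: float = 0.05,
    gate: float = 3.0,
    gate_direction: str = "ge",
    id_prefixes: Sequence[str] = DEFAULT_ID_PREFIXES,
    adjust: str = "holm",
) -> pd.DataFrame:
    """Per-measure comparison table over a tidy measurement frame.

    One row per measure × group pair: Kruskal–Wallis H and p, Dunn
    adjusted p, the mutant/control fold difference, and the final call.
    Integrated-density measures (names starting with one of
    ``id_prefixes``) must additionally pass the fold gate to be declared
    significant.  Deterministic given its inputs.
    """
    if measurements.empty:
        return pd.DataFrame()
    if group_col not in measurements.columns:
        raise StatsInputError(f"missing required column {group_col!r}")
    if measures is None:
        measures = [
            c
            for c in measurements.columns
            if c != group_col
            and pd.api.types.is_numeric_dtype(measurements[c])
        ]
    missing = [m for m in measures if m not in measurements.columns]
    if missing:
        raise StatsInputError(f"missing measure columns: {missing}")

    rows = []
    for measure in measures:
        samples = {
            g: sub[measure].dropna().to_numpy()
            for g, sub in measurements.groupby(group_col)
        }
        samples = {g: v for g, v in samples.items() if v.size >= 2}
        if len(samples) < 2:
            continue
        res = kruskal_dunn(samples, alpha=alpha, adjust=adjust)
        is_id = any(measure.startswith(p) for p in id_prefixes)
        for (g1, g2), p_adj in res.dunn_p.items():
            fold = math.nan
            gate_pass = True
            if control_group in (g1, g2):
                ctrl = samples[control_group]
                other = samples[g2 if g1 == control_group else g1]
                try:
                    fold, gp = fold_gate(ctrl, other, gate, gate_direction)
                except StatsInputError:
                    fold, gp = math.nan, False
                if is_id:
                    gate_pass = gp
            declared = bool(p_adj < alpha) and gate_pass
            rows.append(
                {
                    "measure": measure,
                    "group_a": g1,
                    "group_b": g2,
                    "n_a": int(samples[g1].size),
                    "n_b": int(samples[g2].size),
                    "kw_statistic": res.kw_statistic,
                    "kw_p": res.kw_p,
                    "dunn_p_adj": p_adj,
                    "fold_difference": fold,
                    "fold_gated": is_id,
                    "passes_fold_gate": gate_pass,
                    "declared_significant": declared,
                }
            )
    return pd.DataFrame(rows)


def write_report_csv(report: pd.DataFrame, path: str | Path) -> None:
    """Write the comparison report with a fixed float format so identical
    inputs always produce byte-identical files."""
    report.to_csv(path, index=False, float_format="%.10g")


def plot_report(
    measurements: pd.DataFrame,
    measures: Sequence[str],
    out_dir: str | Path,
    group_col: str = "group",
) -> list[Path]:
    """Violin + strip plot per measure, written as SVG; returns the paths."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    rng = np.random.default_rng(0)
    for measure in measures:
        fig, ax = plt.subplots(figsize=(4, 3))
        groups = sorted(measurements[group_col].unique())
        data = [
            measurements.loc[measurements[group_col] == g, measure].dropna()
            for g in groups
        ]
        nonempty = [d for d in data if len(d) > 1]
        if nonempty:
            ax.violinplot(
                [d.to_numpy() for d in nonempty],
                positions=[i for i, d in enumerate(data) if len(d) > 1],
                showmedians=True,
            )
        for i, d in enumerate(data):
            x = i + rng.uniform(-0.08, 0.08, len(d))
            ax.plot(x, d, "k.", ms=3, alpha=0.6)
        ax.set_xticks(range(len(groups)))
        ax.set_xticklabels(groups, rotation=30, ha="right")
        ax.set_ylabel(measure)
        fig.tight_layout()
        path = out_dir / f"{measure}.svg"
        fig.savefig(path)
        plt.close(fig)
        paths.append(path)
    return paths
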