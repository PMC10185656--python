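"""Patch-clamp analysis: QC gating, AP features, firing-pattern classes.

Conventions
-----------
* Recordings are current-clamp step families (default 1-s steps, 5–100 pA)
  or voltage-clamp step families, digitised at a common sampling rate.
* QC: cells are excluded when the series resistance exceeds 10 MΩ, drifts
  by more than 20% over the recording, or the junction-corrected resting
  membrane potential is not more hyperpolarised than −35 mV.
* The liquid junction potential (15 mV for a K-gluconate internal) is
  subtracted from measured potentials: corrected V = measured V − JP.
* Spikes are peaks crossing 0 mV whose rising phase reaches the dV/dt
  criterion (default 10 mV/ms), with a 2-ms refractory period.
* AP features come from the first AP of the first spiking sweep: the
  rheobase is that sweep's command amplitude; the threshold is the voltage
  where dV/dt first exceeds the criterion; the amplitude is peak −
  threshold; the half-width is measured at threshold + amplitude/2; the
  delay runs from step onset to the threshold crossing.  The maximum
  firing frequency is the largest per-sweep spike count divided by the
  step duration.
* Firing patterns: *none* (no spikes anywhere), *one spike* (at most one
  per sweep), otherwise on the max-count sweep *repetitive* when firing
  spans at least 80% of the step with a last/first inter-spike-interval
  ratio below 2, else *adaptive*.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class SweepFormatError(ValueError):
    """A sweep file or sweep set is structurally invalid."""


@dataclass
class SweepSet:
    """A current- or voltage-clamp sweep family with recording metadata.

    ``sweeps`` has shape (n_sweeps, n_samples); current-clamp signals are
    in mV, voltage-clamp signals in pA.  ``command_amplitudes`` are pA
    (current clamp) or mV (voltage clamp) and must be strictly increasing.
    """

    mode: str
    fs: float
    sweeps: np.ndarray
    command_amplitudes: np.ndarray
    rs_start: float | None = None
    rs_end: float | None = None
    cm: float | None = None
    junction_potential: float = 15.0
    step_duration: float = 1.0
    step_onset: float = 0.1
    cell_id: str = ""
    baseline_signal: np.ndarray | None = None
    baseline_fs: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("current_clamp", "voltage_clamp"):
            raise SweepFormatError(f"unknown mode {self.mode!r}")
        if not self.fs > 0:
            raise SweepFormatError("fs must be > 0")
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        self.command_amplitudes = np.asarray(
            self.command_amplitudes, dtype=float
        )
        if len(self.command_amplitudes) != self.sweeps.shape[0]:
            raise SweepFormatError(
                "one command amplitude per sweep is required"
            )
        if np.any(np.diff(self.command_amplitudes) <= 0):
            raise SweepFormatError(
                "command amplitudes must be strictly increasing"
            )

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.sweeps.shape[1]) / self.fs


def read_sweepset_csv(path_csv: str | Path) -> SweepSet:
    """Read the wide sweep CSV (time + one column per sweep) and its JSON
    metadata sidecar (``<file>.csv.json``)."""
    df = pd.read_csv(path_csv)
    sidecar_path = Path(str(path_csv) + ".json")
    if not sidecar_path.exists():
        raise SweepFormatError(f"missing metadata sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    sweep_cols = [c for c in df.columns if c != "time_s"]
    return SweepSet(
        mode=meta["mode"],
        fs=float(meta["fs"]),
        sweeps=df[sweep_cols].to_numpy().T,
        command_amplitudes=np.asarray(meta["command_amplitudes"], float),
        rs_start=meta.get("rs_start"),
        rs_end=meta.get("rs_end"),
        cm=meta.get("cm"),
        junction_potential=meta.get("junction_potential", 15.0),
        step_duration=meta.get("step_duration", 1.0),
        step_onset=meta.get("step_onset", 0.1),
        cell_id=meta.get("cell_id", ""),
    )


# ---------------------------------------------------------------------------
# records


@dataclass
class ApFeatureRecord:
    """Per-cell current-clamp feature set."""

    cell_id: str = ""
    rmp: float = math.nan            # mV, junction-corrected
    delay: float = math.nan          # ms, step onset -> threshold crossing
    threshold: float = math.nan      # mV
    amplitude: float = math.nan      # mV, peak - threshold
    peak_amplitude: float = math.nan  # mV, absolute peak
    half_width: float = math.nan     # ms
    rheobase: float = math.nan       # pA
    max_frequency: float = math.nan  # Hz
    pattern: str = "none"
    qc_pass: bool = True
    qc_reasons: list = field(default_factory=list)

    def to_row(self) -> dict:
        d = dict(self.__dict__)
        d["qc_reasons"] = ";".join(self.qc_reasons)
        return d


@dataclass
class VcFeatureRecord:
    """Per-cell voltage-clamp current densities."""

    cell_id: str = ""
    na_peak_density: float = math.nan  # pA/pF (negative, inward)
    k_low_density: float = math.nan    # pA/pF (late outward)
    na_k_ratio: float = math.nan       # |Na| / K
    ratio_reason: str = ""


# ---------------------------------------------------------------------------
# operations


def qc_gate(
    sweepset: SweepSet,
    rmp: float | None = None,
    rs_max: float = 10.0,
    rs_drift_max: float = 0.20,
    rmp_max: float = -35.0,
) -> tuple[bool, list[str]]:
    """Inclusion gate on recording metadata.

    Fails when Rs exceeds ``rs_max`` MΩ, Rs drifts by more than
    ``rs_drift_max`` (fractional), or the junction-corrected RMP is not
    more hyperpolarised than ``rmp_max``.  Missing metadata fails with
    reason ``metadata_missing``.  ``rmp`` may be supplied directly or is
    computed from the baseline recording when present.
    """
    reasons: list[str] = []
    if sweepset.rs_start is None or sweepset.rs_end is None:
        reasons.append("metadata_missing:rs")
    else:
        if sweepset.rs_start > rs_max:
            reasons.append("rs")
        if abs(sweepset.rs_end - sweepset.rs_start) / sweepset.rs_start > rs_drift_max:
            reasons.append("delta_rs")
    if rmp is None and sweepset.baseline_signal is not None:
        rmp = compute_rmp(
            sweepset.baseline_signal,
            sweepset.baseline_fs or sweepset.fs,
            sweepset.junction_potential,
        )
    if rmp is None:
        reasons.append("metadata_missing:rmp")
    elif rmp >= rmp_max:
        reasons.append("rmp")
    return (len(reasons) == 0, reasons)


def compute_rmp(
    signal: np.ndarray,
    fs: float,
    junction_potential: float = 15.0,
    min_duration: float = 30.0,
) -> float:
    """Resting membrane potential: the mean of a quiescent recording minus
    the liquid junction potential."""
    signal = np.asarray(signal, dtype=float)
    if signal.size / fs < min_duration:
        raise ValueError(
            f"RMP window {signal.size / fs:.1f}s shorter than the required "
            f"{min_duration:.0f}s"
        )
    return float(signal.mean() - junction_potential)


def detect_spikes(
    sweep: np.ndarray,
    fs: float,
    step_onset: float = 0.0,
    dvdt_criterion: float = 10.0,
    refractory: float = 2e-3,
    peak_level: float = 0.0,
) -> np.ndarray:
    """Spike times (s from step onset) in one current-clamp sweep.

    A spike is a peak above ``peak_level`` mV whose preceding 2 ms contain
    a dV/dt of at least ``dvdt_criterion`` mV/ms; peaks closer than the
    refractory period are merged into the larger one.
    """
    from scipy.signal import find_peaks

    v = np.asarray(sweep, dtype=float)
    idx, _ = find_peaks(
        v, height=peak_level, distance=max(int(refractory * fs), 1)
    )
    if idx.size == 0:
        return np.array([])
    dvdt = np.gradient(v) * fs / 1000.0  # mV/ms
    look = max(int(2e-3 * fs), 2)
    keep = [
        i for i in idx if dvdt[max(i - look, 0) : i + 1].max() >= dvdt_criterion
    ]
    return np.asarray(keep) / fs - step_onset


def classify_pattern(
    spike_times_per_sweep: Sequence[Sequence[float]],
    step_duration: float = 1.0,
    coverage_min: float = 0.8,
    isi_ratio_max: float = 2.0,
) -> str:
    """Four-class firing pattern from per-sweep spike times.

    *none*: no spikes on any sweep.  *one_spike*: at most one per sweep.
    Otherwise the max-count sweep decides: *repetitive* when the last
    spike falls at ≥ ``coverage_min`` of the step and the last/first ISI
    ratio is below ``isi_ratio_max``; *adaptive* otherwise.
    """
    counts = [len(s) for s in spike_times_per_sweep]
    if not counts or max(counts) == 0:
        return "none"
    if max(counts) == 1:
        return "one_spike"
    best = max(range(len(counts)), key=lambda i: counts[i])
    times = np.sort(np.asarray(spike_times_per_sweep[best], dtype=float))
    isis = np.diff(times)
    coverage_ok = times[-1] >= coverage_min * step_duration
    ratio_ok = isis[-1] / isis[0] < isi_ratio_max if isis[0] > 0 else False
    return "repetitive" if (coverage_ok and ratio_ok) else "adaptive"


def ap_features(
    sweepset: SweepSet,
    spikes_per_sweep: Sequence[np.ndarray] | None = None,
    dvdt_criterion: float = 10.0,
    rmp: float = math.nan,
) -> ApFeatureRecord:
    """Extract AP features from a current-clamp sweep family.

    With no spiking sweep the record comes back with pattern ``none`` and
    undefined AP fields; no exception is raised.
    """
    if sweepset.mode != "current_clamp":
        raise SweepFormatError("ap_features requires current-clamp sweeps")
    fs = sweepset.fs
    if spikes_per_sweep is None:
        spikes_per_sweep = [
            detect_spikes(sw, fs, sweepset.step_onset, dvdt_criterion)
            for sw in sweepset.sweeps
        ]
    rec = ApFeatureRecord(cell_id=sweepset.cell_id, rmp=rmp)
    rec.pattern = classify_pattern(
        spikes_per_sweep, sweepset.step_duration
    )
    counts = [len(s) for s in spikes_per_sweep]
    if max(counts, default=0) == 0:
        return rec
    rec.max_frequency = max(counts) / sweepset.step_duration

    first = next(i for i, c in enumerate(counts) if c > 0)
    rec.rheobase = float(sweepset.command_amplitudes[first])
    v = sweepset.sweeps[first]
    peak_idx = int(round((spikes_per_sweep[first][0] + sweepset.step_onset) * fs))
    lo = max(peak_idx - 5, 0)
    hi = min(peak_idx + 6, v.size)
    peak_idx = lo + int(np.argmax(v[lo:hi]))
    rec.peak_amplitude = float(v[peak_idx])

    dvdt = np.gradient(v) * fs / 1000.0  # mV/ms
    onset_idx = int(round(sweepset.step_onset * fs))
    # walk back from the steepest point of the upstroke (the slope at the
    # peak itself is ~0) to the last sub-criterion sample
    w0 = max(onset_idx, peak_idx - int(2e-3 * fs))
    i = w0 + int(np.argmax(dvdt[w0 : peak_idx + 1]))
    while i > w0 and dvdt[i - 1] >= dvdt_criterion:
        i -= 1
    thr_idx = i
    rec.threshold = float(v[thr_idx])
    rec.delay = (thr_idx - onset_idx) / fs * 1000.0
    rec.amplitude = rec.peak_amplitude - rec.threshold

    level = rec.threshold + rec.amplitude / 2.0
    i = peak_idx
    while i > thr_idx and v[i - 1] > level:
        i -= 1
    t_up = _cross_time(v, i - 1, level, fs) if i > 0 else thr_idx / fs
    j = peak_idx
    while j < v.size - 1 and v[j + 1] > level:
        j += 1
    t_dn = _cross_time(v, j, level, fs) if j < v.size - 1 else j / fs
    rec.half_width = (t_dn - t_up) * 1000.0
    return rec


def _cross_time(v: np.ndarray, i: int, level: float, fs: float) -> float:
    """Sub-sample crossing time of ``level`` between samples i and i+1."""
    v0, v1 = v[i], v[i + 1]
    frac = 0.5 if v1 == v0 else (level - v0) / (v1 - v0)
    return (i + float(np.clip(frac, 0.0, 1.0))) / fs


def vc_features(
    sweepset: SweepSet,
    na_window: float = 0.010,
    k_tail_fraction: float = 0.10,
) -> VcFeatureRecord:
    """Sodium / potassium current densities from a voltage-clamp family.

    Per sweep the Na current is the most negative value within the first
    ``na_window`` seconds after step onset and the K current the mean over
    the final ``k_tail_fraction`` of the step; values are reported at the
    sweep maximising |Na| and scaled by the membrane capacitance.
    """
    if sweepset.mode != "voltage_clamp":
        raise SweepFormatError("vc_features requires voltage-clamp sweeps")
    if sweepset.cm is None or sweepset.cm <= 0:
        raise ValueError("membrane capacitance must be positive")
    fs = sweepset.fs
    i0 = int(round(sweepset.step_onset * fs))
    i_na = int(round((sweepset.step_onset + na_window) * fs))
    step_end = sweepset.step_onset + sweepset.step_duration
    i_tail = int(round((step_end - k_tail_fraction * sweepset.step_duration) * fs))
    i_end = min(int(round(step_end * fs)), sweepset.sweeps.shape[1])

    na_per_sweep = sweepset.sweeps[:, i0:i_na].min(axis=1)
    best = int(np.argmax(np.abs(na_per_sweep)))
    na_peak = float(na_per_sweep[best])
    k_low = float(sweepset.sweeps[best, i_tail:i_end].mean())

    rec = VcFeatureRecord(
        cell_id=sweepset.cell_id,
        na_peak_density=na_peak / sweepset.cm,
        k_low_density=k_low / sweepset.cm,
    )
    if rec.k_low_density == 0:
        rec.ratio_reason = "zero_k_current"
    else:
        rec.na_k_ratio = abs(rec.na_peak_density) / rec.k_low_density
    return rec


def analyze_cell(
    cc_sweeps: SweepSet,
    baseline: np.ndarray | None = None,
    baseline_fs: float | None = None,
    dvdt_criterion: float = 10.0,
) -> ApFeatureRecord:
    """QC + RMP + spike detection + features for one current-clamp cell."""
    rmp = math.nan
    if baseline is not None:
        rmp = compute_rmp(
            baseline, baseline_fs or cc_sweeps.fs, cc_sweeps.junction_potential
        )
    elif cc_sweeps.baseline_signal is not None:
        rmp = compute_rmp(
            cc_sweeps.baseline_signal,
            cc_sweeps.baseline_fs or cc_sweeps.fs,
            cc_sweeps.junction_potential,
        )
    rec = ap_features(cc_sweeps, dvdt_criterion=dvdt_criterion, rmp=rmp)
    rec.qc_pass, rec.qc_reasons = qc_gate(
        cc_sweeps, rmp=None if math.isnan(rmp) else rmp
    )
    return rec
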