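"""Scalar descriptors of the pERK response and ensemble summaries.

Three descriptors characterize a pERK time course on the two-hour window:

* ``max_pERK`` — the window maximum (molecules/cell);
* ``T1`` — the first time at which that maximum is attained (minutes),
  i.e. how quickly ERK is phosphorylated;
* ``T2`` — the total time the signal spends above half its maximum
  (minutes), i.e. how sustained the response is. T2 is computed as the
  measure of the super-half-max set with linear interpolation at the
  crossings, which is well defined even for multi-modal responses.

The combination ratio R compares co-stimulation with the sum of the
mono-stimulations:  R = max pERK(FGF and VEGF) /
(max pERK(FGF) + max pERK(VEGF)).  R > 1 indicates a supra-additive
(synergistic) combination, R = 1 an additive one, R < 1 antagonism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import (
    ReadoutSeries, StimulusProtocol, simulate, Trajectory, SimulationError,
)


class UndefinedRatioError(ZeroDivisionError):
    """Both mono-stimulation maxima are zero, so R is undefined."""


@dataclass
class MetricsRecord:
    max_pERK: float
    T1: float
    T2: float
    protocol: StimulusProtocol | None = None
    parameter_set_id: str = "baseline"
    max_at_boundary: bool = False

    def __post_init__(self):
        if self.max_pERK < 0:
            raise ValueError("max_pERK must be non-negative")


@dataclass
class RatioRecord:
    R: float
    max_combo: float
    max_fgf: float
    max_vegf: float
    parameter_set_id: str = "baseline"


def compute_metrics(series: ReadoutSeries,
                    horizon_min: float | None = None) -> MetricsRecord:
    """Window maximum, time-to-max (T1) and super-half-max duration (T2).

    An identically-zero series yields (0, 0, 0) by convention. When the
    maximum sits on the final grid point the record is flagged
    (``max_at_boundary``), mirroring the practice of omitting T1/T2 for
    responses that have not peaked within the window.
    """
    t = np.asarray(series.times, dtype=float)
    v = np.asarray(series.values, dtype=float)
    if t.size == 0:
        raise ValueError("empty series")
    if horizon_min is not None:
        keep = t <= horizon_min + 1e-9
        t, v = t[keep], v[keep]
    vmax = float(v.max())
    if vmax <= 0:
        return MetricsRecord(0.0, 0.0, 0.0, parameter_set_id=series.parameter_set_id)
    imax = int(np.argmax(v))
    t1 = float(t[imax])
    half = vmax / 2.0
    above = v > half
    # measure of {t : v(t) > half} with linear interpolation at crossings
    t2 = 0.0
    for i in range(len(t) - 1):
        a, b = v[i], v[i + 1]
        dt = t[i + 1] - t[i]
        if above[i] and above[i + 1]:
            t2 += dt
        elif above[i] != above[i + 1]:
            frac = (a - half) / (a - b)  # crossing position from left node
            t2 += dt * (frac if above[i] else 1.0 - frac)
    return MetricsRecord(
        vmax, t1, t2,
        parameter_set_id=series.parameter_set_id,
        max_at_boundary=(imax == len(t) - 1),
    )


def metrics_from_trajectory(traj: Trajectory, readout: str = "pERK_total") -> MetricsRecord:
    rec = compute_metrics(traj.readout(readout))
    rec.protocol = traj.protocol
    return rec


def combination_ratio(
    model, params, fgf_nM: float, vegf_nM: float,
    readout: str = "pERK_total", **sim_kwargs,
) -> RatioRecord:
    """Simulate combo, FGF-alone and VEGF-alone under identical settings and
    form R = max(combo) / (max(FGF) + max(VEGF))."""
    if fgf_nM <= 0 and vegf_nM <= 0:
        raise ValueError("at least one dose must be positive")
    maxima = {}
    for key, (f, v) in {
        "combo": (fgf_nM, vegf_nM),
        "fgf": (fgf_nM, 0.0),
        "vegf": (0.0, vegf_nM),
    }.items():
        traj = simulate(model, params, StimulusProtocol(fgf_nM=f, vegf_nM=v),
                        **sim_kwargs)
        maxima[key] = traj.readout(readout).max()
    denom = maxima["fgf"] + maxima["vegf"]
    if denom <= 0:
        raise UndefinedRatioError(
            "both mono-stimulation maxima are zero; R undefined")
    pid = getattr(params, "id", None) or "baseline"
    return RatioRecord(maxima["combo"] / denom, maxima["combo"],
                       maxima["fgf"], maxima["vegf"], parameter_set_id=pid)


@dataclass
class EnsembleSummary:
    median: float
    ci_low: float
    ci_high: float
    values: np.ndarray
    p_vs_1: float | None = None

    def to_dict(self) -> dict:
        d = {"median": self.median, "ci_low": self.ci_low,
             "ci_high": self.ci_high, "n": int(len(self.values))}
        if self.p_vs_1 is not None:
            d["p_vs_1"] = self.p_vs_1
        return d


def ensemble_summary(
    records: list, attr: str | None = None, *,
    n_boot: int = 10_000, seed: int = 0, test_vs_1: bool = False,
) -> EnsembleSummary:
    """Median and percentile-bootstrap 95% CI for the median across an
    ensemble of records.

    ``records`` may be MetricsRecord/RatioRecord objects (give ``attr``,
    e.g. "max_pERK" or "R") or plain numbers. ``test_vs_1`` adds a
    two-sided Wilcoxon signed-rank p-value against 1 (used for R).
    """
    if len(records) == 0:
        raise ValueError("need at least one record")
    if attr is not None:
        values = np.array([getattr(r, attr) for r in records], dtype=float)
    else:
        values = np.asarray(records, dtype=float)
    med = float(np.median(values))
    if len(values) == 1 or np.ptp(values) == 0:
        lo = hi = med
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(values), size=(n_boot, len(values)))
        boot = np.median(values[idx], axis=1)
        lo, hi = (float(x) for x in np.percentile(boot, [2.5, 97.5]))
    p = None
    if test_vs_1:
        diffs = values - 1.0
        if np.allclose(diffs, 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(diffs).pvalue)
    return EnsembleSummary(med, lo, hi, values, p)


def metrics_table(records: list[MetricsRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"parameter_set_id": r.parameter_set_id, "max_pERK": r.max_pERK,
               "T1_min": r.T1, "T2_min": r.T2,
               "max_at_boundary": r.max_at_boundary}
        if r.protocol is not None:
            row.update(fgf_nM=r.protocol.fgf_nM, vegf_nM=r.protocol.vegf_nM,
                       heparin_ug_per_ml=r.protocol.heparin_ug_per_ml)
        rows.append(row)
    return pd.DataFrame(rows)
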