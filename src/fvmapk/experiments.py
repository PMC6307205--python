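"""In-silico perturbation experiments over the best-fit ensemble.

Four experiment drivers, each a pure function of (model, parameter sets,
spec): the FGF x VEGF combination dose grid, the VEGFR2 density scan, the
VEGFR2 -> FGFR1 trafficking-parameter swaps, and the heparin pERK
difference. All return tidy DataFrames (one row per parameter set and
condition) ready for CSV export; none mutates the model or the ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import SignalingModel, build_heparin_extension, ligand_unit_convert
from .simulate import StimulusProtocol, simulate, SimulationError
from .metrics import (compute_metrics, combination_ratio, ensemble_summary,
                      UndefinedRatioError)

#: VEGFR2 trafficking parameter -> its FGFR1 counterpart
TRAFFICKING_SWAP_MAP = {
    "k_intf": "k_intf_R1", "k_intb": "k_intb_R1",
    "k_recf": "k_recf_R1", "k_recb": "k_recb_R1",
    "k_degf": "k_degf_R1", "k_degb": "k_degb_R1",
}

DEFAULT_DOSE_GRID_NM = (0.01, 0.05, 0.1, 0.5, 1.0, 2.0)
DEFAULT_DENSITY_FACTORS = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0)
DEFAULT_HEPARIN_TIMES_MIN = (10.0, 15.0, 30.0, 60.0)


@dataclass
class ExperimentSpec:
    kind: str
    fgf_doses_nM: tuple = DEFAULT_DOSE_GRID_NM
    vegf_doses_nM: tuple = DEFAULT_DOSE_GRID_NM
    density_factors: tuple = DEFAULT_DENSITY_FACTORS
    swap_selection: tuple = ("all", "k_intf", "k_intb", "k_int",
                             "k_recf", "k_recb", "k_rec",
                             "k_degf", "k_degb", "k_deg")
    heparin_ug_per_ml: float = 500.0
    heparin_times_min: tuple = DEFAULT_HEPARIN_TIMES_MIN
    heparin_fgf_ng_per_ml: tuple = (0.16, 0.8, 4.0, 20.0, 100.0, 500.0)
    reference_dose_nM: float = 0.5

    def __post_init__(self):
        if any(f <= 0 for f in self.density_factors):
            raise ValueError("density factors must be positive")
        for doses in (self.fgf_doses_nM, self.vegf_doses_nM):
            if any(d < 0 for d in doses):
                raise ValueError("doses must be non-negative")


def _ensemble(param_sets) -> list:
    if not param_sets:
        raise ValueError("ensemble must be non-empty")
    return list(param_sets)


def _metric_row(model, ps, fgf, vegf, **sim_kwargs):
    pid = getattr(ps, "id", None) or "set"
    try:
        traj = simulate(model, ps, StimulusProtocol(fgf_nM=fgf, vegf_nM=vegf),
                        **sim_kwargs)
    except SimulationError as err:
        return {"parameter_set_id": pid, "fgf_nM": fgf, "vegf_nM": vegf,
                "error": str(err)}
    rec = compute_metrics(traj.readout("pERK_total"))
    return {"parameter_set_id": pid, "fgf_nM": fgf, "vegf_nM": vegf,
            "max_pERK": rec.max_pERK, "T1_min": rec.T1, "T2_min": rec.T2,
            "max_at_boundary": rec.max_at_boundary, "error": ""}


def run_combination_grid(model: SignalingModel, param_sets, spec: ExperimentSpec
                         | None = None, **sim_kwargs):
    """Metrics for every (FGF, VEGF) pair including mono-stimulations, and
    the combination ratio R for strictly positive dose pairs."""
    spec = spec or ExperimentSpec(kind="combination_grid")
    sets = _ensemble(param_sets)
    fgf_doses = (0.0,) + tuple(spec.fgf_doses_nM)
    vegf_doses = (0.0,) + tuple(spec.vegf_doses_nM)
    metric_rows, ratio_rows = [], []
    for ps in sets:
        pid = getattr(ps, "id", None) or "set"
        maxima = {}
        for f in fgf_doses:
            for v in vegf_doses:
                if f == 0 and v == 0:
                    continue
                row = _metric_row(model, ps, f, v, **sim_kwargs)
                metric_rows.append(row)
                if "max_pERK" in row:
                    maxima[(f, v)] = row["max_pERK"]
        for f in spec.fgf_doses_nM:
            for v in spec.vegf_doses_nM:
                try:
                    combo = maxima[(f, v)]
                    solo_f, solo_v = maxima[(f, 0.0)], maxima[(0.0, v)]
                except KeyError:
                    continue
                denom = solo_f + solo_v
                if denom <= 0:
                    continue
                ratio_rows.append({
                    "parameter_set_id": pid, "fgf_nM": f, "vegf_nM": v,
                    "R": combo / denom, "max_combo": combo,
                    "max_fgf": solo_f, "max_vegf": solo_v,
                })
    return pd.DataFrame(metric_rows), pd.DataFrame(ratio_rows)


def run_vegfr2_density_scan(model: SignalingModel, param_sets,
                            spec: ExperimentSpec | None = None, **sim_kwargs):
    """Scale the VEGFR2 initial amount and record mono/combination metrics
    and R at the reference equimolar dose (default 0.5 nM each)."""
    spec = spec or ExperimentSpec(kind="vegfr2_density")
    sets = _ensemble(param_sets)
    d = spec.reference_dose_nM
    rows = []
    for factor in spec.density_factors:
        for ps in sets:
            pid = getattr(ps, "id", None) or "set"
            vals = dict(getattr(ps, "values_dict", None) or ps or {})
            base_r2 = vals.get("init:VEGFR2") or next(
                s.initial_amount for s in model.network.species
                if s.name == "VEGFR2")
            vals["init:VEGFR2"] = base_r2 * factor
            maxima = {}
            for label, (f, v) in {"fgf": (d, 0.0), "vegf": (0.0, d),
                                  "combo": (d, d)}.items():
                try:
                    traj = simulate(model, vals,
                                    StimulusProtocol(fgf_nM=f, vegf_nM=v),
                                    **sim_kwargs)
                except SimulationError as err:
                    maxima[label] = np.nan
                    continue
                rec = compute_metrics(traj.readout("pERK_total"))
                maxima[label] = rec.max_pERK
                rows.append({
                    "parameter_set_id": pid, "density_factor": factor,
                    "stimulus": label, "max_pERK": rec.max_pERK,
                    "T1_min": rec.T1, "T2_min": rec.T2,
                })
            denom = maxima["fgf"] + maxima["vegf"]
            if np.isfinite(denom) and denom > 0:
                rows.append({
                    "parameter_set_id": pid, "density_factor": factor,
                    "stimulus": "ratio_R", "max_pERK": np.nan,
                    "T1_min": np.nan, "T2_min": np.nan,
                    "R": maxima["combo"] / denom,
                })
    return pd.DataFrame(rows)


def run_trafficking_swap(model: SignalingModel, param_sets,
                         spec: ExperimentSpec | None = None, **sim_kwargs):
    """Replace selected VEGFR2 trafficking rates with the FGFR1 values and
    record the 0.5 nM VEGF response, with the fitted-VEGF and 0.5 nM FGF
    references."""
    spec = spec or ExperimentSpec(kind="trafficking_swap")
    sets = _ensemble(param_sets)
    d = spec.reference_dose_nM
    groups = {"k_int": ("k_intf", "k_intb"), "k_rec": ("k_recf", "k_recb"),
              "k_deg": ("k_degf", "k_degb"),
              "all": tuple(TRAFFICKING_SWAP_MAP)}
    rows = []
    for ps in sets:
        pid = getattr(ps, "id", None) or "set"
        base_vals = dict(getattr(ps, "values_dict", None) or ps or {})
        fgfr_rates = model.fgfr1_trafficking()
        for cond in ("fitted_fgf", "fitted") + tuple(spec.swap_selection):
            vals = dict(base_vals)
            if cond == "fitted_fgf":
                f, v = d, 0.0
            else:
                f, v = 0.0, d
                if cond != "fitted":
                    names = groups.get(cond, (cond,))
                    for nm in names:
                        if nm not in TRAFFICKING_SWAP_MAP:
                            raise KeyError(f"unknown trafficking parameter {nm!r}")
                        vals[nm] = model.network.parameters[
                            TRAFFICKING_SWAP_MAP[nm]]
            try:
                traj = simulate(model, vals,
                                StimulusProtocol(fgf_nM=f, vegf_nM=v),
                                **sim_kwargs)
            except SimulationError as err:
                rows.append({"parameter_set_id": pid, "condition": cond,
                             "error": str(err)})
                continue
            rec = compute_metrics(traj.readout("pERK_total"))
            rows.append({"parameter_set_id": pid, "condition": cond,
                         "max_pERK": rec.max_pERK, "T1_min": rec.T1,
                         "T2_min": rec.T2,
                         "max_at_boundary": rec.max_at_boundary, "error": ""})
    return pd.DataFrame(rows)


def run_heparin_difference(model: SignalingModel, param_sets,
                           spec: ExperimentSpec | None = None, **sim_kwargs):
    """pERK(with heparin) - pERK(without) per FGF dose, time point and
    parameter set."""
    spec = spec or ExperimentSpec(kind="heparin_difference")
    sets = _ensemble(param_sets)
    hep_model = build_heparin_extension(model, spec.heparin_ug_per_ml)
    times = np.asarray(spec.heparin_times_min, dtype=float)
    grid = np.unique(np.concatenate([[0.0], times,
                                     np.arange(0.0, 120.5, 1.0)]))
    rows = []
    for ps in sets:
        pid = getattr(ps, "id", None) or "set"
        for ng in spec.heparin_fgf_ng_per_ml:
            fgf = ligand_unit_convert(ng, "ng_per_ml", "FGF")
            try:
                base = simulate(model, ps,
                                StimulusProtocol(fgf_nM=fgf,
                                                 output_grid_min=grid),
                                **sim_kwargs).readout("pERK_total")
                hep = simulate(hep_model, ps,
                               StimulusProtocol(
                                   fgf_nM=fgf,
                                   heparin_ug_per_ml=spec.heparin_ug_per_ml,
                                   output_grid_min=grid),
                               **sim_kwargs).readout("pERK_total")
            except SimulationError as err:
                rows.append({"parameter_set_id": pid, "fgf_ng_per_ml": ng,
                             "error": str(err)})
                continue
            for t in times:
                i = int(np.argmin(np.abs(grid - t)))
                rows.append({
                    "parameter_set_id": pid, "fgf_ng_per_ml": ng,
                    "time_min": t,
                    "delta_pERK": float(hep.values[i] - base.values[i]),
                    "error": "",
                })
    return pd.DataFrame(rows)


def summarize(df: pd.DataFrame, value_col: str, group_cols: list[str],
              seed: int = 0) -> pd.DataFrame:
    """Median and bootstrap 95% CI of a value column per condition group."""
    out = []
    for keys, sub in df.dropna(subset=[value_col]).groupby(group_cols):
        if not isinstance(keys, tuple):
            keys = (keys,)
        s = ensemble_summary(sub[value_col].to_numpy(), seed=seed)
        row = dict(zip(group_cols, keys))
        row.update(median=s.median, ci_low=s.ci_low, ci_high=s.ci_high,
                   n=len(sub))
        out.append(row)
    return pd.DataFrame(out)
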