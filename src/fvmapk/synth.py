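"""Synthetic training/validation data with the structure of the study data.

The original model was trained on time courses digitized from published
immunoblot figures, which are not redistributable. This module generates
datasets with the same structure from a known ground-truth parameter set:

* pERK time courses at the six-dose FGF panel (0.16-500 ng/ml), normalized
  by the panel-wide maximum;
* a pVEGFR2 time course at 5 ng/ml VEGF, self-normalized;
* a pERK time course at 50 ng/ml VEGF, self-normalized;

plus validation-shaped tables (10 ng/ml FGF pERK; 80 ng/ml VEGF pVEGFR2;
the sign of the pERK difference with/without 500 ug/ml heparin at four time
points across the FGF panel).

Measurement noise is multiplicative lognormal (densitometry noise is
scale-proportional), applied before normalization; the default CV is 10%.
Because lognormal noise is strictly positive, normalized observations stay
positive and the WSSR's division contract holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (SignalingModel, build_main_network,
                    build_heparin_extension, ligand_unit_convert)
from .simulate import StimulusProtocol, simulate
from .calibrate import (TrainingDataset, FGF_PANEL_NG_PER_ML, fit_model,
                        baseline_parameter_set, training_objective,
                        ParameterSet, select_best, validation_score,
                        DETECTION_FLOOR)

#: sparse sampling grid emulating figure time courses (~8 points / 2 h)
DEFAULT_TIME_GRID_MIN = (5.0, 10.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0)
#: time points for the heparin-difference validation table
HEPARIN_TIMES_MIN = (10.0, 15.0, 30.0, 60.0)
DEFAULT_NOISE_CV = 0.10


@dataclass
class SyntheticStudy:
    true_parameters: ParameterSet | dict | None
    training: list[TrainingDataset]
    validation: list[TrainingDataset]
    heparin_table: pd.DataFrame
    noise_cv: float
    seed: int


def _noisy(values: np.ndarray, cv: float, rng) -> np.ndarray:
    if cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if cv == 0:
        return values.copy()
    sigma = np.sqrt(np.log1p(cv ** 2))
    # mean-one lognormal multiplier
    return values * rng.lognormal(-sigma ** 2 / 2, sigma, size=values.shape)


def _sample_readout(model, params, proto: StimulusProtocol, readout: str,
                    times) -> np.ndarray:
    grid = np.unique(np.concatenate([
        np.arange(0.0, proto.horizon_min + 0.25, 1.0), np.asarray(times)]))
    p = StimulusProtocol(proto.fgf_nM, proto.vegf_nM, proto.heparin_ug_per_ml,
                         proto.horizon_min, output_grid_min=grid)
    series = simulate(model, params, p).readout(readout)
    return np.interp(times, series.times, series.values)


def _build_dataset(name, readout, scheme, cond_curves, noise_cv, rng,
                   times) -> TrainingDataset:
    noisy = {c: _noisy(v, noise_cv, rng) for c, v in cond_curves.items()}
    if scheme == "panel_max":
        norm = max(v.max() for v in noisy.values())
        normed = {c: v / norm for c, v in noisy.items()}
    else:
        normed = {c: v / v.max() for c, v in noisy.items()}
    table_rows = []
    for cond, vals in normed.items():
        for t, v in zip(times, vals):
            table_rows.append({"condition": cond, "time_min": t,
                               "value": float(max(v, DETECTION_FLOOR))})
    return TrainingDataset(
        name=name, readout=readout, scheme=scheme,
        conditions=cond_curves.protocols,
        table=pd.DataFrame(table_rows),
    )


class _CurveSet(dict):
    protocols: dict


def generate_training_like(
    true_params=None, noise_cv: float = DEFAULT_NOISE_CV, seed: int = 0,
    model: SignalingModel | None = None,
    times=DEFAULT_TIME_GRID_MIN,
) -> SyntheticStudy:
    """Simulate the three training conditions from a ground truth, apply
    multiplicative lognormal noise, normalize per scheme, and emit the
    validation-shaped tables from the same truth."""
    rng = np.random.default_rng(seed)
    model = model or build_main_network()
    times = np.asarray(times, dtype=float)

    def curveset(protos: dict[str, StimulusProtocol], readout) -> _CurveSet:
        cs = _CurveSet()
        cs.protocols = protos
        for cond, proto in protos.items():
            cs[cond] = _sample_readout(model, true_params, proto, readout, times)
        return cs

    # training set 1: FGF dose panel, panel-normalized pERK
    fgf_protos = {
        f"FGF_{ng:g}ng_ml": StimulusProtocol(
            fgf_nM=ligand_unit_convert(ng, "ng_per_ml", "FGF"))
        for ng in FGF_PANEL_NG_PER_ML
    }
    ds1 = _build_dataset("pERK_FGF_panel", "pERK_total", "panel_max",
                         curveset(fgf_protos, "pERK_total"), noise_cv, rng,
                         times)
    # training set 2: pVEGFR2 at 5 ng/ml VEGF
    v5 = {"VEGF_5ng_ml": StimulusProtocol(
        vegf_nM=ligand_unit_convert(5.0, "ng_per_ml", "VEGF"))}
    ds2 = _build_dataset("pR2_VEGF_5ng", "pR2_total", "per_condition",
                         curveset(v5, "pR2_total"), noise_cv, rng, times)
    # training set 3: pERK at 50 ng/ml VEGF
    v50 = {"VEGF_50ng_ml": StimulusProtocol(
        vegf_nM=ligand_unit_convert(50.0, "ng_per_ml", "VEGF"))}
    ds3 = _build_dataset("pERK_VEGF_50ng", "pERK_total", "per_condition",
                         curveset(v50, "pERK_total"), noise_cv, rng, times)

    # validation sets from the same truth
    f10 = {"FGF_10ng_ml": StimulusProtocol(
        fgf_nM=ligand_unit_convert(10.0, "ng_per_ml", "FGF"))}
    va = _build_dataset("pERK_FGF_10ng", "pERK_total", "per_condition",
                        curveset(f10, "pERK_total"), noise_cv, rng, times)
    v80 = {"VEGF_80ng_ml": StimulusProtocol(
        vegf_nM=ligand_unit_convert(80.0, "ng_per_ml", "VEGF"))}
    vb = _build_dataset("pR2_VEGF_80ng", "pR2_total", "per_condition",
                        curveset(v80, "pR2_total"), noise_cv, rng, times)

    # heparin difference signs at four time points across the FGF panel
    hep_model = build_heparin_extension(model)
    hep_rows = []
    for ng in FGF_PANEL_NG_PER_ML:
        fgf = ligand_unit_convert(ng, "ng_per_ml", "FGF")
        base = _sample_readout(model, true_params,
                               StimulusProtocol(fgf_nM=fgf), "pERK_total",
                               HEPARIN_TIMES_MIN)
        hep = _sample_readout(hep_model, true_params,
                              StimulusProtocol(fgf_nM=fgf,
                                               heparin_ug_per_ml=500.0),
                              "pERK_total", HEPARIN_TIMES_MIN)
        for t, d in zip(HEPARIN_TIMES_MIN, hep - base):
            hep_rows.append({"fgf_ng_per_ml": ng, "time_min": t,
                             "value": float(d)})
    heparin_table = pd.DataFrame(hep_rows)

    return SyntheticStudy(
        true_parameters=true_params, training=[ds1, ds2, ds3],
        validation=[va, vb], heparin_table=heparin_table,
        noise_cv=noise_cv, seed=seed,
    )


def save_study_csv(study: SyntheticStudy, directory) -> None:
    """Write the study tables in the CSV dialect the calibration readers use
    (columns: dataset, condition, time_min, value)."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for group, sets in (("training", study.training),
                        ("validation", study.validation)):
        frames = []
        for ds in sets:
            t = ds.table.copy()
            t.insert(0, "dataset", ds.name)
            frames.append(t)
        pd.concat(frames, ignore_index=True).to_csv(
            directory / f"{group}.csv", index=False)
    study.heparin_table.to_csv(directory / "validation_heparin.csv",
                               index=False)


@dataclass
class RecoveryReport:
    truth: dict[str, float]
    recovered: dict[str, float]
    log10_error: dict[str, float]
    objective_truth: float
    objective_recovered: float
    within_2x: list[str]
    seed: int

    def recovery_rate(self, names: list[str]) -> float:
        names = [n for n in names if n in self.log10_error]
        if not names:
            return float("nan")
        hits = sum(abs(self.log10_error[n]) <= np.log10(2.0) for n in names)
        return hits / len(names)


def recovery_experiment(
    seed: int = 0, noise_cv: float = 0.0, *,
    n_starts: int = 2, n_particles: int = 12, n_iterations: int = 25,
    free_names: list[str] | None = None,
    perturb_decades: float = 0.3,
    model: SignalingModel | None = None,
) -> RecoveryReport:
    """Draw a truth near baseline, generate a synthetic study, refit with
    multi-start PSO, and report per-quantity log10 errors.

    ``free_names`` restricts the fit to a subset of the 39 free quantities
    (all others stay at the true values), which keeps scaled-down budgets
    meaningful; the default fits all 39.
    """
    rng = np.random.default_rng(seed)
    model = model or build_main_network()
    base = baseline_parameter_set(model)
    names = free_names or list(base.values)
    truth = dict(base.values)
    for n in names:
        lo, hi = base.bounds[n]
        shift = rng.uniform(-perturb_decades, perturb_decades)
        truth[n] = float(np.clip(base.values[n] * 10 ** shift, lo, hi))
    truth_sub = {n: truth[n] for n in names}

    study = generate_training_like(truth_sub, noise_cv=noise_cv,
                                   seed=seed, model=model)
    fits = []
    for i in range(n_starts):
        fits.append(fit_model(model, study.training,
                              n_particles=n_particles,
                              n_iterations=n_iterations,
                              seed=seed * 1000 + i, free_names=names))
    best = min(fits, key=lambda f: f.wssr)
    recovered = best.parameter_set.values
    log_err = {n: float(np.log10(recovered[n] / truth_sub[n])) for n in names}
    obj_truth = training_objective(model, truth_sub, study.training)
    within = [n for n in names if abs(log_err[n]) <= np.log10(2.0)]
    return RecoveryReport(
        truth=truth_sub, recovered=dict(recovered), log10_error=log_err,
        objective_truth=obj_truth, objective_recovered=best.wssr,
        within_2x=within, seed=seed,
    )
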