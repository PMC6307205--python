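"""Model calibration: weighted SSR objective, PSO search, best-set selection.

The 39 free quantities (34 rate constants plus 5 initial amounts, addressed
as ``init:<species>``) are estimated against three normalized training
datasets:

1. pERK time courses at six FGF doses (0.16-500 ng/ml), all divided by the
   single maximum across the six doses within two hours ("panel_max"
   scheme);
2. a pVEGFR2 time course at 5 ng/ml VEGF, divided by its own maximum
   ("per_condition");
3. a pERK time course at 50 ng/ml VEGF, divided by its own maximum.

The objective is the weighted sum of squared residuals

    WSSR(theta) = sum_i ((V_pred,i(theta) - V_exp,i) / V_exp,i)^2

minimized by particle swarm optimization over bounds one order of magnitude
above and below baseline, searched in log10 space. Candidate fits are
scored on three held-out validation sets (10 ng/ml FGF pERK, 80 ng/ml VEGF
pVEGFR2, and the sign pattern of the heparin pERK difference), and the 16
sets with the smallest combined training + validation error form the
working ensemble.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .model import SignalingModel, build_main_network, ligand_unit_convert
from .simulate import StimulusProtocol, simulate, SimulationError

#: multiplicative half-width of the search box around baseline
BOUND_FACTOR = 10.0
#: objective value charged for a failed simulation
FAILURE_PENALTY = 1e6

#: normalized values below this fraction of the normalizer are clipped to
#: it, in data and predictions alike -- immunoblot quantification cannot
#: resolve signal below a background floor, and the relative-residual
#: objective would otherwise give near-zero points unbounded weight
DETECTION_FLOOR = 0.01

#: default integration tolerances during fitting (coarser than production;
#: the objective only needs the readouts at the data's time points)
FIT_RTOL = 1e-6
FIT_ATOL = 1e-3


@dataclass
class ParameterSet:
    """A candidate parameter assignment for the free quantities."""

    values: dict[str, float]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    id: str = "set"
    wssr_train: float | None = None
    wssr_validation: float | None = None

    @property
    def values_dict(self) -> dict[str, float]:
        return dict(self.values)

    def check_bounds(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            v = self.values[name]
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    def to_dict(self) -> dict:
        return {
            "id": self.id, "values": self.values,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "wssr_train": self.wssr_train,
            "wssr_validation": self.wssr_validation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(values=dict(d["values"]),
                   bounds={k: tuple(v) for k, v in d.get("bounds", {}).items()},
                   id=d.get("id", "set"),
                   wssr_train=d.get("wssr_train"),
                   wssr_validation=d.get("wssr_validation"))


def baseline_parameter_set(model: SignalingModel,
                           bound_factor: float = BOUND_FACTOR) -> ParameterSet:
    """Baseline values and two-decade bounds for the model's free quantities."""
    values, bounds = {}, {}
    init = {s.name: s.initial_amount for s in model.network.species}
    for name in model.free_quantities:
        base = (init[name[5:]] if name.startswith("init:")
                else model.network.parameters[name])
        if base <= 0:
            raise ValueError(f"free quantity {name!r} has non-positive baseline")
        values[name] = base
        bounds[name] = (base / bound_factor, base * bound_factor)
    return ParameterSet(values=values, bounds=bounds, id="baseline")


# -- objective -------------------------------------------------------------

FGF_PANEL_NG_PER_ML = (0.16, 0.8, 4.0, 20.0, 100.0, 500.0)


@dataclass
class TrainingDataset:
    """Normalized observations for one dataset.

    ``table`` columns: condition (str), time_min, value. ``conditions`` maps
    the condition label to a StimulusProtocol. ``scheme`` is "panel_max"
    (all conditions share the normalizer: the global max across conditions)
    or "per_condition" (each condition normalized by its own max).
    """

    name: str
    readout: str  # pERK_total or pR2_total
    scheme: str
    conditions: dict[str, StimulusProtocol]
    table: pd.DataFrame
    floor: float = DETECTION_FLOOR

    def __post_init__(self):
        if self.scheme not in ("panel_max", "per_condition"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if (self.table["value"] <= 0).any():
            raise ValueError(
                f"{self.name}: observed values must be positive (the WSSR "
                "divides by them)")


def wssr(predicted, observed) -> float:
    """Sum of squared relative residuals sum(((pred-obs)/obs)^2)."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("prediction/observation length mismatch")
    if (observed == 0).any():
        idx = int(np.flatnonzero(observed == 0)[0])
        raise ZeroDivisionError(f"observed value is zero at index {idx}")
    return float((((predicted - observed) / observed) ** 2).sum())


def normalize_prediction(curves: dict[str, np.ndarray], scheme: str) -> dict[str, np.ndarray]:
    """Apply a dataset's normalization scheme to simulated curves.

    "panel_max": every curve is divided by the single global maximum across
    all curves. "per_condition": each curve is divided by its own maximum.
    A zero normalizer marks a degenerate simulation.
    """
    if scheme == "panel_max":
        global_max = max((float(np.max(v)) for v in curves.values()), default=0.0)
        if global_max <= 0:
            raise ZeroDivisionError("degenerate simulation: zero panel maximum")
        return {k: v / global_max for k, v in curves.items()}
    if scheme == "per_condition":
        out = {}
        for k, v in curves.items():
            m = float(np.max(v))
            if m <= 0:
                raise ZeroDivisionError(
                    f"degenerate simulation: zero maximum for condition {k!r}")
            out[k] = v / m
        return out
    raise ValueError(f"unknown scheme {scheme!r}")


def _simulate_dataset(model, params, ds: TrainingDataset,
                      rtol=FIT_RTOL, atol=FIT_ATOL) -> dict[str, np.ndarray]:
    """Predicted readout values at each condition's data time points.

    Predictions and observations are normalized over the same support (the
    dataset's sampled time points), matching how normalization is applied
    to the sparse measured curves themselves."""
    curves = {}
    for cond, proto in ds.conditions.items():
        tpts = np.sort(ds.table.loc[ds.table["condition"] == cond,
                                    "time_min"].unique())
        grid = np.unique(np.concatenate([[0.0], tpts]))
        p = StimulusProtocol(proto.fgf_nM, proto.vegf_nM,
                             proto.heparin_ug_per_ml, proto.horizon_min,
                             output_grid_min=grid)
        traj = simulate(model, params, p, rtol=rtol, atol=atol)
        series = traj.readout(ds.readout)
        curves[cond] = (tpts, np.interp(tpts, series.times, series.values))
    return curves


def dataset_wssr(model, params, ds: TrainingDataset,
                 rtol=FIT_RTOL, atol=FIT_ATOL) -> float:
    curves = _simulate_dataset(model, params, ds, rtol, atol)
    norm = normalize_prediction({c: v for c, (_, v) in curves.items()},
                                ds.scheme)
    preds, obs = [], []
    for cond, (tpts, _) in curves.items():
        sub = ds.table[ds.table["condition"] == cond].sort_values("time_min")
        preds.extend(np.interp(sub["time_min"].to_numpy(), tpts, norm[cond]))
        obs.extend(sub["value"].to_numpy())
    preds = np.maximum(preds, ds.floor)
    obs = np.maximum(obs, ds.floor)
    return wssr(preds, obs)


def training_objective(model, theta: ParameterSet | dict,
                       datasets: list[TrainingDataset],
                       rtol=FIT_RTOL, atol=FIT_ATOL) -> float:
    """Summed WSSR over the training datasets; a simulation failure incurs
    the large finite penalty immediately (any failed dataset already makes
    the candidate unusable, so the remaining datasets are skipped rather
    than risking further expensive pathological integrations)."""
    total = 0.0
    for ds in datasets:
        try:
            total += dataset_wssr(model, theta, ds, rtol, atol)
        except (SimulationError, ZeroDivisionError):
            return FAILURE_PENALTY
    return total


# -- PSO -------------------------------------------------------------------

@dataclass
class FitResult:
    parameter_set: ParameterSet
    wssr: float
    trace: np.ndarray  # global-best objective per iteration
    seed: int
    n_evaluations: int = 0


def pso_minimize(
    objective, bounds: list[tuple[float, float]], *,
    n_particles: int = 40, n_iterations: int = 300, seed: int = 0,
    inertia: float = 0.729, cognitive: float = 1.49445, social: float = 1.49445,
    callback=None,
) -> FitResult:
    """Global-best particle swarm optimization with reflecting bounds.

    Uses the standard constriction coefficients (w=0.729, c1=c2=1.49445).
    Positions leaving the box are reflected back inside and the velocity
    component is reversed, preserving swarm diversity near the bounds.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if not np.all(np.isfinite(lo) & np.isfinite(hi) & (lo < hi)):
        raise ValueError("bounds must be finite with lower < upper")
    d = len(bounds)
    span = hi - lo
    x = lo + rng.uniform(size=(n_particles, d)) * span
    v = rng.uniform(-1, 1, size=(n_particles, d)) * span * 0.1
    fx = np.array([objective(xi) for xi in x])
    pbest, fbest = x.copy(), fx.copy()
    g = int(np.argmin(fbest))
    gbest, fgbest = pbest[g].copy(), float(fbest[g])
    trace = [fgbest]
    n_eval = n_particles
    for it in range(n_iterations):
        r1 = rng.uniform(size=(n_particles, d))
        r2 = rng.uniform(size=(n_particles, d))
        v = (inertia * v + cognitive * r1 * (pbest - x)
             + social * r2 * (gbest[None, :] - x))
        x = x + v
        # reflect at bounds
        for _ in range(3):
            under = x < lo
            over = x > hi
            if not (under.any() or over.any()):
                break
            x = np.where(under, 2 * lo - x, x)
            x = np.where(over, 2 * hi - x, x)
            v = np.where(under | over, -v, v)
        np.clip(x, lo, hi, out=x)
        fx = np.array([objective(xi) for xi in x])
        n_eval += n_particles
        improved = fx < fbest
        pbest[improved] = x[improved]
        fbest[improved] = fx[improved]
        g = int(np.argmin(fbest))
        if fbest[g] < fgbest:
            fgbest = float(fbest[g])
            gbest = pbest[g].copy()
        trace.append(fgbest)
        if callback is not None:
            callback(it, fgbest)
    ps = ParameterSet(values={f"x{i}": float(gbest[i]) for i in range(d)},
                      id=f"pso_seed{seed}", wssr_train=fgbest)
    return FitResult(ps, fgbest, np.array(trace), seed, n_eval)


def fit_model(
    model: SignalingModel, datasets: list[TrainingDataset], *,
    n_particles: int = 20, n_iterations: int = 60, seed: int = 0,
    free_names: list[str] | None = None, callback=None,
) -> FitResult:
    """One PSO run over the model's free quantities in log10 space."""
    base = baseline_parameter_set(model)
    names = free_names or list(base.values)
    log_bounds = [(np.log10(base.bounds[n][0]), np.log10(base.bounds[n][1]))
                  for n in names]

    def objective(z):
        vals = {n: 10.0 ** z[i] for i, n in enumerate(names)}
        return training_objective(model, vals, datasets)

    res = pso_minimize(objective, log_bounds, n_particles=n_particles,
                       n_iterations=n_iterations, seed=seed, callback=callback)
    values = {n: 10.0 ** res.parameter_set.values[f"x{i}"]
              for i, n in enumerate(names)}
    ps = ParameterSet(values=values,
                      bounds={n: base.bounds[n] for n in names},
                      id=f"fit_seed{seed}", wssr_train=res.wssr)
    return FitResult(ps, res.wssr, res.trace, seed, res.n_evaluations)


# -- validation and selection ----------------------------------------------

def validation_score(model, params, validation_sets: list[TrainingDataset],
                     heparin_table: pd.DataFrame | None = None,
                     heparin_model=None) -> float:
    """Summed WSSR on the validation datasets plus, when a heparin
    difference table is given, a sign-agreement penalty (one unit per
    time/dose point whose predicted pERK difference has the wrong sign)."""
    total = 0.0
    for ds in validation_sets:
        try:
            total += dataset_wssr(model, params, ds)
        except (SimulationError, ZeroDivisionError):
            total += FAILURE_PENALTY
    if heparin_table is not None and heparin_model is not None:
        try:
            total += _heparin_sign_penalty(heparin_model, model, params,
                                           heparin_table)
        except SimulationError:
            total += FAILURE_PENALTY
    return total


def _heparin_sign_penalty(hep_model, model, params,
                          table: pd.DataFrame) -> float:
    penalty = 0.0
    for dose_ng, sub in table.groupby("fgf_ng_per_ml"):
        fgf = ligand_unit_convert(float(dose_ng), "ng_per_ml", "FGF")
        tpts = np.sort(sub["time_min"].unique())
        grid = np.unique(np.concatenate([[0.0], tpts]))
        if grid[-1] < 120.0:
            grid = np.append(grid, 120.0)
        base = simulate(model, params,
                        StimulusProtocol(fgf_nM=fgf, output_grid_min=grid),
                        rtol=FIT_RTOL, atol=FIT_ATOL).readout("pERK_total")
        hep = simulate(hep_model, params,
                       StimulusProtocol(fgf_nM=fgf, heparin_ug_per_ml=500.0,
                                        output_grid_min=grid),
                       rtol=FIT_RTOL, atol=FIT_ATOL).readout("pERK_total")
        for _, row in sub.iterrows():
            i = int(np.argmin(np.abs(grid - row["time_min"])))
            delta = hep.values[i] - base.values[i]
            if np.sign(delta) != np.sign(row["value"]) and row["value"] != 0:
                penalty += 1.0
    return penalty


def select_best(fits: list[FitResult],
                validation_scores: dict[str, float] | None = None,
                k: int = 16) -> list[ParameterSet]:
    """Rank fits by training WSSR plus validation score and keep the best k.

    Ties break by training WSSR, then by id. With fewer than k fits all are
    returned (with a warning via warnings)."""
    import warnings

    if not fits:
        raise ValueError("no fits to select from")
    validation_scores = validation_scores or {}

    def key(fr: FitResult):
        v = validation_scores.get(fr.parameter_set.id, 0.0)
        return (fr.wssr + v, fr.wssr, fr.parameter_set.id)

    ranked = sorted(fits, key=key)
    if len(ranked) < k:
        warnings.warn(f"only {len(ranked)} fits available (< {k})")
    out = []
    for fr in ranked[:k]:
        ps = fr.parameter_set
        ps.wssr_train = fr.wssr
        ps.wssr_validation = validation_scores.get(ps.id)
        out.append(ps)
    return out


# -- ensemble persistence ---------------------------------------------------

def save_parameter_sets(sets: list[ParameterSet], path) -> None:
    with open(path, "w") as fh:
        json.dump([ps.to_dict() for ps in sets], fh, indent=1)


def load_parameter_sets(path) -> list[ParameterSet]:
    with open(path) as fh:
        return [ParameterSet.from_dict(d) for d in json.load(fh)]


def load_best_fit_ensemble() -> list[ParameterSet]:
    """The packaged 16-set working ensemble.

    These sets were produced by running this module's PSO calibration
    against the packaged synthetic training data (see
    :mod:`fvmapk.synth`); they are synthetic stand-ins for the original
    study's fitted ensemble, which is not redistributed here.
    """
    from importlib import resources

    ref = resources.files("fvmapk").joinpath("data/best_fits_synthetic.json")
    with resources.as_file(ref) as path:
        return load_parameter_sets(path)
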