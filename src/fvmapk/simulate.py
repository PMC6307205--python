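"""Stimulation protocols, stiff ODE integration, and trajectory containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import assemble_rhs, NetworkConfigError
from .model import SignalingModel, heparin_partition, ligand_unit_convert

DEFAULT_HORIZON_MIN = 120.0
DEFAULT_GRID_STEP_MIN = 0.5
#: integration tolerances; phospho-species span many orders of magnitude
RTOL = 1e-8
ATOL = 1e-6  # molecules/cell

#: ceiling on RHS evaluations per simulation; healthy runs use <= ~3.3k
#: even at production tolerances, so hitting this marks a pathological
#: parameter draw whose integration would otherwise grind for minutes
MAX_NFEV = 20_000


class _BudgetExceeded(Exception):
    pass


class _BudgetedRHS:
    """Wrap an assembled RHS with an evaluation budget."""

    def __init__(self, rhs, max_nfev):
        self._rhs = rhs
        self.jacobian = rhs.jacobian
        self._left = max_nfev

    def __call__(self, t, y):
        self._left -= 1
        if self._left <= 0:
            raise _BudgetExceeded
        return self._rhs(t, y)


class SimulationError(RuntimeError):
    def __init__(self, message, parameter_set_id=None, protocol=None):
        super().__init__(message)
        self.parameter_set_id = parameter_set_id
        self.protocol = protocol


def default_grid(horizon_min: float = DEFAULT_HORIZON_MIN,
                 step: float = DEFAULT_GRID_STEP_MIN) -> np.ndarray:
    return np.arange(0.0, horizon_min + step / 2, step)


@dataclass
class StimulusProtocol:
    fgf_nM: float = 0.0
    vegf_nM: float = 0.0
    heparin_ug_per_ml: float = 0.0
    horizon_min: float = DEFAULT_HORIZON_MIN
    output_grid_min: np.ndarray | None = None
    allow_long_horizon: bool = False

    def __post_init__(self):
        if min(self.fgf_nM, self.vegf_nM, self.heparin_ug_per_ml) < 0:
            raise ValueError("doses must be non-negative")
        if self.horizon_min > DEFAULT_HORIZON_MIN and not self.allow_long_horizon:
            raise ValueError(
                "horizon beyond 120 min is outside the model's stated validity "
                "window; pass allow_long_horizon=True to override"
            )
        if self.output_grid_min is None:
            self.output_grid_min = default_grid(self.horizon_min)
        self.output_grid_min = np.asarray(self.output_grid_min, dtype=float)
        grid = self.output_grid_min
        if grid[0] != 0 or np.any(np.diff(grid) <= 0):
            raise ValueError("output grid must start at 0 and increase strictly")

    def label(self) -> str:
        parts = [f"FGF={self.fgf_nM:g}nM", f"VEGF={self.vegf_nM:g}nM"]
        if self.heparin_ug_per_ml:
            parts.append(f"hep={self.heparin_ug_per_ml:g}ug/ml")
        return ",".join(parts)


@dataclass
class ReadoutSeries:
    times: np.ndarray
    values: np.ndarray
    name: str
    parameter_set_id: str = "baseline"

    def max(self) -> float:
        return float(np.max(self.values))


@dataclass
class Trajectory:
    times: np.ndarray
    amounts: np.ndarray  # (time, species)
    species_names: list[str]
    protocol: StimulusProtocol
    parameter_set_id: str = "baseline"
    readout_defs: dict[str, list[str]] = field(default_factory=dict)

    def series(self, species: str) -> np.ndarray:
        try:
            j = self.species_names.index(species)
        except ValueError:
            raise KeyError(f"unknown species {species!r}")
        return self.amounts[:, j]

    def readout(self, name: str) -> ReadoutSeries:
        """Sum the species subset defining a named readout."""
        if name not in self.readout_defs:
            raise KeyError(f"unknown readout {name!r}")
        members = self.readout_defs[name]
        total = np.zeros_like(self.times)
        for sp in members:
            total = total + self.series(sp)
        return ReadoutSeries(self.times, total, name, self.parameter_set_id)

    def to_frame(self, readouts_only: bool = False) -> pd.DataFrame:
        rows = []
        names = (list(self.readout_defs) if readouts_only else self.species_names)
        for n in names:
            vals = (self.readout(n).values if readouts_only else self.series(n))
            rows.append(pd.DataFrame({
                "time_min": self.times,
                "species_or_readout": n,
                "amount": vals,
            }))
        df = pd.concat(rows, ignore_index=True)
        df["parameter_set_id"] = self.parameter_set_id
        df["fgf_nM"] = self.protocol.fgf_nM
        df["vegf_nM"] = self.protocol.vegf_nM
        df["heparin_ug_per_ml"] = self.protocol.heparin_ug_per_ml
        return df


def _split_overrides(params) -> tuple[dict, dict]:
    """Split a parameter mapping into rate-constant and initial-amount parts.

    Fitted initial amounts are addressed as ``init:<species>``.
    """
    if params is None:
        return {}, {}
    values = getattr(params, "values_dict", None)
    if values is None:
        values = dict(params)
    rate, init = {}, {}
    for key, val in values.items():
        if key.startswith("init:"):
            init[key[5:]] = float(val)
        else:
            rate[key] = float(val)
    return rate, init


def simulate(
    model: SignalingModel,
    params=None,
    protocol: StimulusProtocol | None = None,
    rtol: float = RTOL,
    atol: float = ATOL,
    parameter_set_id: str | None = None,
) -> Trajectory:
    """Integrate the model under a stimulation protocol.

    ``params`` may be None (baseline), a mapping of rate-constant names (and
    ``init:<species>`` entries) to values, or a calibration ParameterSet.
    Ligand species are clamped at the protocol doses; with heparin present
    the extracellular FGF pools are clamped at the solution-partition
    equilibrium (see :func:`fvmapk.model.heparin_partition`).
    """
    protocol = protocol or StimulusProtocol()
    rate_over, init_over = _split_overrides(params)
    pid = parameter_set_id or getattr(params, "id", None) or "baseline"

    net = model.network
    names = [s.name for s in net.species]
    init_over = dict(init_over)
    init_over["FGF"] = protocol.fgf_nM
    init_over["VEGF"] = protocol.vegf_nM
    if "Hep" in names:
        merged = {**net.parameters, **rate_over}
        hep_nM = ligand_unit_convert(
            protocol.heparin_ug_per_ml * 1000.0, "ng_per_ml", "heparin")
        K = merged["kf_fgf_hep"] / merged["kr_fgf_hep"]
        free, c1, c2 = heparin_partition(protocol.fgf_nM, hep_nM, K)
        init_over.update({"FGF": free, "Hep": hep_nM,
                          "FGF_Hep": c1, "FGF2_Hep": c2})
    elif protocol.heparin_ug_per_ml > 0:
        raise SimulationError(
            "protocol specifies heparin but the model has no heparin "
            "extension; build it with build_heparin_extension()",
            pid, protocol)

    rhs = _BudgetedRHS(assemble_rhs(net, rate_over), MAX_NFEV)
    y0 = net.initial_state(init_over)

    # min_step and the evaluation budget bound the work a pathological
    # parameter draw can demand: the fastest legitimate timescale is
    # ~1e-5 min, so hopeless integrations become prompt, catchable failures
    try:
        sol = solve_ivp(
            rhs, (0.0, protocol.horizon_min), y0,
            method="LSODA", jac=rhs.jacobian, min_step=1e-8,
            t_eval=protocol.output_grid_min, rtol=rtol, atol=atol,
        )
    except _BudgetExceeded:
        raise SimulationError(
            f"integration exceeded {MAX_NFEV} RHS evaluations", pid, protocol)
    if not sol.success:
        raise SimulationError(
            f"integrator failure: {sol.message}", pid, protocol)
    y = sol.y.T
    if not np.all(np.isfinite(y)):
        raise SimulationError("non-finite state in trajectory", pid, protocol)
    if y.min() < -1000 * atol:
        raise SimulationError(
            f"negative excursion {y.min():.3g} beyond tolerance", pid, protocol)
    return Trajectory(
        times=sol.t, amounts=y, species_names=names, protocol=protocol,
        parameter_set_id=pid, readout_defs=model.readout_defs,
    )


def ensemble_simulate(
    model: SignalingModel,
    param_sets: list,
    protocol: StimulusProtocol | None = None,
    **kwargs,
) -> list:
    """Simulate each parameter set; failed sets yield SimulationError entries
    in the returned list rather than aborting the remaining sets."""
    if not param_sets:
        raise ValueError("need at least one parameter set")
    out = []
    for i, ps in enumerate(param_sets):
        pid = getattr(ps, "id", None) or f"set{i}"
        try:
            out.append(simulate(model, ps, protocol,
                                parameter_set_id=pid, **kwargs))
        except SimulationError as err:
            out.append(err)
    return out


def ensemble_readout(trajectories: list, name: str) -> pd.DataFrame:
    """Tidy per-set readout values with ensemble mean/sd columns."""
    ok = [t for t in trajectories if isinstance(t, Trajectory)]
    if not ok:
        raise SimulationError("all ensemble members failed")
    mat = np.column_stack([t.readout(name).values for t in ok])
    df = pd.DataFrame(mat, columns=[t.parameter_set_id for t in ok])
    df.insert(0, "time_min", ok[0].times)
    df["mean"] = mat.mean(axis=1)
    df["sd"] = mat.std(axis=1, ddof=1) if mat.shape[1] > 1 else 0.0
    return df
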