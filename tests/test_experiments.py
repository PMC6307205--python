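"""Perturbation-experiment drivers over the best-fit ensemble."""

import numpy as np
import pandas as pd
import pytest

import fvmapk as fv
from fvmapk.experiments import (
    ExperimentSpec, run_combination_grid, run_vegfr2_density_scan,
    run_trafficking_swap, run_heparin_difference, summarize,
    TRAFFICKING_SWAP_MAP,
)
from fvmapk.simulate import StimulusProtocol
from fvmapk.metrics import compute_metrics
from conftest import FAST


@pytest.fixture(scope="module")
def small_ensemble(ensemble):
    return ensemble[:6]


class TestCombinationGrid:
    @pytest.fixture(scope="class")
    def grid(self, main_model, ensemble):
        spec = ExperimentSpec(kind="combination_grid",
                              fgf_doses_nM=(0.1, 0.5),
                              vegf_doses_nM=(0.5,))
        return run_combination_grid(main_model, ensemble[:6], spec, **FAST)

    def test_shape_contract(self, grid):
        metrics, ratios = grid
        # (2+1) x (1+1) dose pairs minus the (0,0) cell, per parameter set
        assert len(metrics) == 6 * (3 * 2 - 1)
        assert len(ratios) == 6 * 2

    def test_mono_cells_match_independent_runs(self, grid, main_model,
                                               ensemble):
        metrics, _ = grid
        ps = ensemble[0]
        cell = metrics[(metrics.parameter_set_id == ps.id)
                       & (metrics.fgf_nM == 0.5) & (metrics.vegf_nM == 0.0)]
        traj = fv.simulate(main_model, ps, StimulusProtocol(fgf_nM=0.5),
                           **FAST)
        rec = compute_metrics(traj.readout("pERK_total"))
        assert cell["max_pERK"].iloc[0] == pytest.approx(rec.max_pERK)

    def test_ratio_consistent_with_metrics(self, grid):
        metrics, ratios = grid
        row = ratios.iloc[0]
        assert row["R"] == pytest.approx(
            row["max_combo"] / (row["max_fgf"] + row["max_vegf"]))

    def test_fgf_dominates_vegf_at_equimolar_doses(self, main_model,
                                                   small_ensemble):
        """0.5 nM FGF induces orders of magnitude more pERK than 0.5 nM
        VEGF (high FGFR1 density + slow trafficking vs sparse, fast-cycling
        VEGFR2)."""
        spec = ExperimentSpec(kind="combination_grid", fgf_doses_nM=(0.5,),
                              vegf_doses_nM=(0.5,))
        metrics, _ = run_combination_grid(main_model, small_ensemble, spec,
                                          **FAST)
        fgf = metrics[(metrics.fgf_nM == 0.5) & (metrics.vegf_nM == 0.0)]
        vegf = metrics[(metrics.fgf_nM == 0.0) & (metrics.vegf_nM == 0.5)]
        assert np.median(fgf["max_pERK"]) > 50 * np.median(vegf["max_pERK"])
        assert np.median(fgf["max_pERK"]) > 1e5


class TestDensityScan:
    @pytest.fixture(scope="class")
    def scan(self, main_model, ensemble):
        spec = ExperimentSpec(kind="vegfr2_density",
                              density_factors=(0.1, 1.0, 5.0))
        return run_vegfr2_density_scan(main_model, ensemble, spec, **FAST)

    def _combo_median(self, scan, factor):
        sub = scan[(scan.density_factor == factor)
                   & (scan.stimulus == "combo")]
        return float(np.median(sub["max_pERK"]))

    def test_factor_one_matches_baseline_combination(self, scan, main_model,
                                                     ensemble):
        ps = ensemble[0]
        sub = scan[(scan.density_factor == 1.0) & (scan.stimulus == "combo")
                   & (scan.parameter_set_id == ps.id)]
        traj = fv.simulate(main_model, ps,
                           StimulusProtocol(fgf_nM=0.5, vegf_nM=0.5), **FAST)
        rec = compute_metrics(traj.readout("pERK_total"))
        assert sub["max_pERK"].iloc[0] == pytest.approx(rec.max_pERK,
                                                        rel=1e-6)

    def test_fivefold_density_never_hurts_and_can_double(self, scan):
        """x5 VEGFR2 never lowers any fit's combination response and more
        than doubles it for fits near the cascade threshold (saturated
        fits gain less; the >90% reference-model gain is asserted in the
        acceptance suite)."""
        combo = scan[scan.stimulus == "combo"].pivot(
            index="parameter_set_id", columns="density_factor",
            values="max_pERK")
        gains = combo[5.0] / combo[1.0]
        assert (gains >= 0.999).all()
        assert gains.max() > 1.9

    def test_tenfold_reduction_gives_modest_decrease(self, scan):
        """x0.1 VEGFR2 lowers the combination response by a modest fraction
        (the FGF arm dominates the baseline combination)."""
        drop = 1.0 - self._combo_median(scan, 0.1) / self._combo_median(scan,
                                                                        1.0)
        assert 0.0 < drop < 0.35

    def test_ratio_tends_to_one_as_density_shrinks(self, scan):
        r_low = scan[(scan.density_factor == 0.1)
                     & (scan.stimulus == "ratio_R")]["R"]
        r_base = scan[(scan.density_factor == 1.0)
                      & (scan.stimulus == "ratio_R")]["R"]
        assert abs(np.median(r_low) - 1.0) < abs(np.median(r_base) - 1.0)
        assert np.median(r_low) == pytest.approx(1.0, abs=0.05)


class TestTraffickingSwap:
    @pytest.fixture(scope="class")
    def swap(self, main_model, ensemble):
        spec = ExperimentSpec(kind="trafficking_swap",
                              swap_selection=("all", "k_intb", "k_recb",
                                              "k_degf"))
        return run_trafficking_swap(main_model, ensemble[:8], spec, **FAST)

    def _median(self, swap, cond):
        return float(np.median(swap[swap.condition == cond]["max_pERK"]))

    def test_noop_swap_leaves_metrics_unchanged(self, main_model, ensemble):
        """Swapping a rate to a value it already has changes nothing."""
        ps = ensemble[0]
        vals = dict(ps.values_dict)
        vals["k_degf"] = main_model.network.parameters["k_degf_R1"]
        a = fv.simulate(main_model, vals, StimulusProtocol(vegf_nM=0.5),
                        **FAST)
        b = fv.simulate(main_model, vals, StimulusProtocol(vegf_nM=0.5),
                        **FAST)
        assert np.array_equal(a.amounts, b.amounts)

    def test_unknown_parameter_rejected(self, main_model, small_ensemble):
        spec = ExperimentSpec(kind="trafficking_swap",
                              swap_selection=("k_bogus",))
        with pytest.raises(KeyError):
            run_trafficking_swap(main_model, small_ensemble, spec, **FAST)

    def test_slowing_internalization_increases_perk(self, swap):
        assert self._median(swap, "k_intb") > self._median(swap, "fitted")

    def test_slowing_recycling_decreases_perk(self, swap):
        assert self._median(swap, "k_recb") < self._median(swap, "fitted")

    def test_full_swap_reaches_fgf_magnitude(self, swap):
        """With all six VEGFR2 trafficking rates set to the FGFR1 values,
        0.5 nM VEGF reaches the same order of magnitude as 0.5 nM FGF."""
        all_swap = self._median(swap, "all")
        fgf_ref = self._median(swap, "fitted_fgf")
        assert all_swap > 0.1 * fgf_ref

    def test_swap_map_covers_all_six_rates(self):
        assert set(TRAFFICKING_SWAP_MAP) == {"k_intf", "k_intb", "k_recf",
                                             "k_recb", "k_degf", "k_degb"}


class TestHeparinDifference:
    def test_zero_heparin_delta_zero(self, main_model, ensemble):
        spec = ExperimentSpec(kind="heparin_difference",
                              heparin_ug_per_ml=0.0,
                              heparin_fgf_ng_per_ml=(4.0,),
                              heparin_times_min=(15.0, 60.0))
        df = run_heparin_difference(main_model, ensemble[:2], spec, **FAST)
        assert np.max(np.abs(df["delta_pERK"])) <= 1.0  # ~0 vs 1e5 scale

    def test_batched_output_matches_two_single_runs(self, main_model,
                                                    hep_model, ensemble):
        spec = ExperimentSpec(kind="heparin_difference",
                              heparin_fgf_ng_per_ml=(20.0,),
                              heparin_times_min=(15.0,))
        df = run_heparin_difference(main_model, ensemble[:1], spec, **FAST)
        from fvmapk.model import ligand_unit_convert
        fgf = ligand_unit_convert(20.0, "ng_per_ml", "FGF")
        grid = np.unique(np.concatenate([[0.0, 15.0],
                                         np.arange(0.0, 120.5, 1.0)]))
        base = fv.simulate(main_model, ensemble[0],
                           StimulusProtocol(fgf_nM=fgf, output_grid_min=grid),
                           **FAST).readout("pERK_total")
        hep = fv.simulate(hep_model, ensemble[0],
                          StimulusProtocol(fgf_nM=fgf, heparin_ug_per_ml=500.0,
                                           output_grid_min=grid),
                          **FAST).readout("pERK_total")
        i = int(np.argmin(np.abs(grid - 15.0)))
        assert df["delta_pERK"].iloc[0] == pytest.approx(
            float(hep.values[i] - base.values[i]), rel=1e-6, abs=1e-3)


class TestSummaries:
    def test_summarize_groups_and_bounds(self, main_model, small_ensemble):
        spec = ExperimentSpec(kind="combination_grid", fgf_doses_nM=(0.5,),
                              vegf_doses_nM=(0.5,))
        _, ratios = run_combination_grid(main_model, small_ensemble, spec,
                                         **FAST)
        summ = summarize(ratios, "R", ["fgf_nM", "vegf_nM"])
        assert len(summ) == 1
        row = summ.iloc[0]
        assert row["ci_low"] <= row["median"] <= row["ci_high"]
        assert row["n"] == len(small_ensemble)
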