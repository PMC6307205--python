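# fvmapk — FGF/VEGF crosstalk in MAPK → ERK signaling

A mass-action kinetic model of how two pro-angiogenic growth factors, FGF
and VEGF, individually and in combination activate ERK through the MAPK
cascade in an endothelial-like cell — together with the machinery to
calibrate it, interrogate it, and rerun its in-silico experiments. It is
aimed at systems-biology researchers studying receptor-level control of
MAPK signaling and at anyone who needs a worked, tested example of the
full ODE-model workflow: network assembly, stiff simulation, eFAST global
sensitivity analysis, PSO parameter estimation against normalized
time-course data, and ensemble-based perturbation experiments.

## The model in brief

The state **y** collects molecular amounts (molecules/cell; ligands are
clamped nM concentrations) and evolves by mass action,

    dy/dt = S · v(y),      v_j = kf_j · Π [reactants] − kr_j · Π [products].

The main network (70 reactions, 72 species, 75 rate constants) contains:
the FGF arm, where FGF + HSGAG → FGF:HSGAG recruits FGFR1 into a ternary
complex that dimerizes, autophosphorylates, and phosphorylates FRS2, under
ppERK-driven FRS2-ubiquitination feedback; the VEGF arm, where
VEGF + VEGFR2 ↔ pR2 (one-step autophosphorylation) recruits Grb2:Sos,
loads Ras-GTP and activates Raf; and a shared two-site MEK/ERK cascade
with saturable phosphatases, which makes the cascade an ultrasensitive
switch and the two arms compete and synergize. Receptors internalize,
recycle and degrade (six VEGFR2 trafficking rates; one shared bound-FGFR1
set). A heparin extension (+26 reactions, +25 species, +3 constants)
models soluble-heparin competition for FGF. Response descriptors follow
the study conventions: the 2-h maximum of total pERK, the time to that
maximum (T1), the duration above half-maximum (T2), and the combination
ratio

    R = max pERK(FGF and VEGF) / (max pERK(FGF) + max pERK(VEGF)),

with R > 1 meaning the combination beats the sum of the parts.

Because the original study's fitted parameter values live in supplementary
tables that are not redistributed here, the packaged network is a
documented reconstruction engineered to the published structural counts,
and the packaged 16-set "best-fit" ensemble
(`src/fvmapk/data/best_fits_synthetic.json`) was produced by running this
package's own PSO calibration against its synthetic training data. See
`docs/methods.md` for what that does and does not claim.

## Worked example

```python
import numpy as np
import fvmapk as fv

model = fv.build_main_network()   # 70 reactions / 72 species / 75 constants

# reference parameterization: is 0.5 nM FGF + 0.5 nM VEGF supra-additive?
r = fv.combination_ratio(model, None, fgf_nM=0.5, vegf_nM=0.5)
print(f"R = {r.R:.3f}  (combo {r.max_combo:.3g} vs "
      f"{r.max_fgf:.3g} + {r.max_vegf:.3g})")

# best-fit ensemble: magnitude and speed of the FGF response
ensemble = fv.load_best_fit_ensemble()   # 16 calibrated parameter sets
recs = [fv.compute_metrics(
    fv.simulate(model, ps,
                fv.StimulusProtocol(fgf_nM=0.5)).readout("pERK_total"))
    for ps in ensemble]
print(f"0.5 nM FGF: median max pERK "
      f"{np.median([r.max_pERK for r in recs]):.3g} molecules/cell, "
      f"median T1 {np.median([r.T1 for r in recs]):.1f} min")
```

prints:

```
R = 1.078  (combo 8.83e+05 vs 8.16e+05 + 3.94e+03)
0.5 nM FGF: median max pERK 3.37e+05 molecules/cell, median T1 8.0 min
```

— an FGF response that peaks within minutes on the 1e5-1e6
phosphorylated-ERK-per-cell scale, a VEGF-alone response orders of
magnitude weaker at the same dose, and a combination about 8% above the
sum of the parts at the reference parameterization. Across the fitted
ensemble the VEGF-arm amplitude (and hence R) spreads over orders of
magnitude, mirroring the identifiability limits of normalized training
data; `docs/methods.md` discusses this.

The numbered scripts under `analysis/` run the full workflow and write
tidy CSVs under `results/`: `01_build_model.py` (assembly + YAML/SBML
export), `02_sensitivity.py` (eFAST), `03_generate_data.py` (synthetic
training data), `04_fit.py` (PSO calibration and best-16 selection),
`05_response_metrics.py` (dose grids, R, T1/T2), `06_experiments.py`
(VEGFR2 density scan, trafficking swaps, heparin difference), and
`07_recovery.py` (parameter recovery). A thin `mapk` console script
exposes the same operations (`mapk simulate --fgf-nm 0.5 --ensemble`,
`mapk sensitivity --stimulus vegf`, `mapk experiment density`, ...).

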