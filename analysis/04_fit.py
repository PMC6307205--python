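"""Calibrate the model against the synthetic training data and select the
best-16 ensemble.

Mirrors the study workflow at a scaled-down search budget: multiple
independent PSO runs over the 39 free quantities (log10 space, two-decade
bounds), each run scored on the training WSSR; candidates are then scored
on the three validation datasets (10 ng/ml FGF pERK, 80 ng/ml VEGF pR2,
heparin-difference sign agreement) and the 16 sets with the smallest
combined error are kept as the working ensemble.

Writes results/fit/* and refreshes the packaged ensemble fixture
src/fvmapk/data/best_fits_synthetic.json (synthetic stand-in for the
original study's fitted ensemble).
"""

import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from fvmapk import build_main_network, build_heparin_extension
from fvmapk.calibrate import (fit_model, select_best, validation_score,
                              save_parameter_sets)
from fvmapk.synth import generate_training_like

N_RUNS = 24
N_PARTICLES = 15
N_ITERATIONS = 40
STUDY_SEED = 2026
NOISE_CV = 0.10

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out = ROOT / "results" / "fit"
    out.mkdir(parents=True, exist_ok=True)
    model = build_main_network()
    hep_model = build_heparin_extension(model)
    study = generate_training_like(noise_cv=NOISE_CV, seed=STUDY_SEED)

    # per-run checkpoints make the campaign resumable; each run is fully
    # determined by its seed (checkpoints are scratch artifacts)
    runs_dir = ROOT / "scratch" / "fit_runs_checkpoints"
    runs_dir.mkdir(parents=True, exist_ok=True)
    from fvmapk.calibrate import FitResult, ParameterSet

    fits = []
    for i in range(N_RUNS):
        ckpt = runs_dir / f"run_{i:02d}.json"
        if ckpt.exists():
            d = json.loads(ckpt.read_text())
            ps = ParameterSet.from_dict(d["parameter_set"])
            fr = FitResult(ps, d["wssr"], np.asarray(d["trace"]),
                           d["seed"], d["n_evaluations"])
            print(f"run {i:2d}: train WSSR {fr.wssr:8.3f}  (checkpoint)",
                  flush=True)
        else:
            t0 = time.time()
            fr = fit_model(model, study.training, n_particles=N_PARTICLES,
                           n_iterations=N_ITERATIONS, seed=1000 + i)
            ckpt.write_text(json.dumps({
                "parameter_set": fr.parameter_set.to_dict(),
                "wssr": fr.wssr, "trace": list(map(float, fr.trace)),
                "seed": fr.seed, "n_evaluations": fr.n_evaluations}))
            print(f"run {i:2d}: train WSSR {fr.wssr:8.3f}  "
                  f"({fr.n_evaluations} evals, {time.time()-t0:.0f}s)",
                  flush=True)
        fits.append(fr)

    vals = {}
    for fr in fits:
        ps = fr.parameter_set
        vals[ps.id] = validation_score(model, ps, study.validation,
                                       heparin_table=study.heparin_table,
                                       heparin_model=hep_model)
        ps.wssr_validation = vals[ps.id]
    best16 = select_best(fits, vals, k=16)

    rows = [{"id": fr.parameter_set.id, "wssr_train": fr.wssr,
             "wssr_validation": vals[fr.parameter_set.id],
             "selected": fr.parameter_set.id in {p.id for p in best16}}
            for fr in fits]
    table = pd.DataFrame(rows).sort_values("wssr_train")
    table.to_csv(out / "fit_summary.csv", index=False)
    print(table.to_string(index=False))

    save_parameter_sets(best16, out / "best16.json")
    fixture = ROOT / "src" / "fvmapk" / "data" / "best_fits_synthetic.json"
    save_parameter_sets(best16, fixture)
    sel = [fr.wssr + vals[fr.parameter_set.id] for fr in fits
           if fr.parameter_set.id in {p.id for p in best16}]
    print(f"\nselected 16 of {len(fits)}; combined error range "
          f"{min(sel):.2f} .. {max(sel):.2f}")
    print(f"ensemble fixture -> {fixture}")


if __name__ == "__main__":
    main()
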