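"""Generate the synthetic training/validation study used for calibration.

Simulates the three training conditions (six-dose FGF pERK panel, 5 ng/ml
VEGF pVEGFR2, 50 ng/ml VEGF pERK) and the validation conditions from the
baseline ground truth, applies 10% multiplicative lognormal noise, and
writes the normalized tables to results/data/. The calibration step
(04_fit.py) regenerates the same study from its seed, so these CSVs are a
human-readable record rather than a pipeline dependency.
"""

from pathlib import Path

from fvmapk.synth import generate_training_like, save_study_csv

ROOT = Path(__file__).resolve().parents[1]
STUDY_SEED = 2026
NOISE_CV = 0.10


def main() -> None:
    out = ROOT / "results" / "data"
    study = generate_training_like(noise_cv=NOISE_CV, seed=STUDY_SEED)
    save_study_csv(study, out)
    for ds in study.training:
        print(f"training  {ds.name:16s} {len(ds.table):3d} points "
              f"({ds.scheme})")
    for ds in study.validation:
        print(f"validation {ds.name:16s} {len(ds.table):3d} points")
    hep = study.heparin_table
    print(f"validation heparin-difference table: {len(hep)} points, "
          f"{int((hep.value > 0).sum())} positive / "
          f"{int((hep.value < 0).sum())} negative")
    print(f"tables -> {out}")


if __name__ == "__main__":
    main()
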