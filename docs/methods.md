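# Methods

## Model

`fvmapk` implements a mass-action kinetic model of ERK activation by two
pro-angiogenic growth factors, FGF and VEGF, in an endothelial-like cell.
All chemistry is elementary mass action — binding, unbinding and catalytic
release steps — assembled into an ODE system d**y**/dt = **S·v(y)**, where
**S** is the stoichiometry matrix and **v** the flux vector. The main
network has 70 reactions, 72 species and 75 named rate constants; shared
kinetics (one trafficking rate set for all bound FGFR1 forms, symmetric
two-site kinase/phosphatase steps) are expressed by several reactions
referencing one named constant.

**FGF arm.** FGF binds cell-surface heparan sulfate proteoglycans (HSGAG,
1e5 sites/cell) and, competitively and non-productively, free FGFR1
(20,000/cell). Only the FGF:HSGAG complex recruits FGFR1 into the
signaling-competent ternary complex; ternary complexes dimerize,
trans-autophosphorylate and phosphorylate FRS2. pFRS2 is the FGF-arm MEK
kinase. Doubly phosphorylated ERK drives ubiquitination of FRS2 and pFRS2
(FRS2u), a negative feedback that terminates the FGF response within
minutes and makes it transient. The binary FGF:FGFR1 complex is the source
of the biphasic dose response: at high doses it sequesters receptor away
from the ternary route.

**VEGF arm.** VEGF binding to VEGFR2 (1,000/cell) is lumped with receptor
autophosphorylation into one reversible step (pR2), since the receptor
monomers phosphorylate each other upon ligation and the phosphorylation
mechanism is not the modeling target. pR2 recruits Grb2:Sos directly or via
phosphorylated Shc; Sos catalyzes Ras GTP-loading, Ras-GTP activates Raf,
and aRaf is the VEGF-arm MEK kinase. GAP plus slow intrinsic hydrolysis
deactivate Ras-GTP.

**Shared MAPK core.** Both arms converge on two-site, distributive MEK and
ERK phosphorylation with explicit kinase-substrate complexes. Ptase2
dephosphorylates pMEK/ppMEK (association `k_dpMEK_p`, catalytic `ked1`/
`ked2`), Ptase3 dephosphorylates pERK/ppERK, and Ptase1 serves pFRS2, pShc
and aRaf with site-specific rates. Because both arms compete for the same
saturable phosphatases, the cascade behaves as a zero-order-ultrasensitive
switch: the strong FGF flux crosses the Ptase2 capacity easily, the weak
VEGF flux crosses it only at high dose, and a sub-threshold VEGF flux
*added to* an FGF stimulus is disproportionately effective — the mechanism
behind the supra-additive combination ratio.

**Trafficking.** Free and bound receptors internalize, recycle, and are
degraded into explicit degraded-pool species, so receptor moieties remain
conserved and the "all phosphorylated receptor except the degraded pool"
readout is well defined. All bound FGFR1 forms share one (slow) rate set;
VEGFR2 has six rates (`k_intf/k_intb`, `k_recf/k_recb`, `k_degf/k_degb`),
all fast relative to FGFR1, which is why the sparse VEGFR2 pool is quickly
consumed.

**Heparin extension** (+26 reactions, +25 species, +3 rate constants).
Soluble heparin chains carry two equivalent FGF sites. The extracellular
pools (free FGF, singly and doubly loaded chains) are clamped at their
solution equilibrium, computed per protocol from the total dose
(`heparin_partition`); the two-hour window and media reservoir justify
clamping. Heparin-held FGF can still recruit FGFR1 into
signaling-competent complexes, but with a lower association rate
(`kf_fhepR`) than the surface-assembled route, and doubly-loaded chains can
cross-link receptors into a phosphorylated but signaling-incompetent
assembly. At low FGF, sequestration dominates (pERK falls); at high FGF,
heparin relieves the binary FGF:FGFR1 sequestration and adds a productive
route (pERK rises) — reproducing the sign flip of the measured heparin
difference.

## Units and scope

Cell-associated species are amounts in molecules/cell; extracellular
ligands are clamped concentrations in nM (no depletion within the 2-h
window). Ligand doses convert as nM = (ng/ml)·1000/MW with MW(FGF) =
25 kDa (fixed by the 100 ng/ml = 4 nM pairing used for the training dose
axis), MW(VEGF) = 45.455 kDa (50 ng/ml = 1.1 nM) and MW(heparin) = 15 kDa.
Time is in minutes. No ligand or protein synthesis/turnover is modeled
beyond ubiquitination and the degraded pools; trajectories past 120 min
are outside the model's stated validity and require an explicit override.

## Baseline parameters

Rate constants start at literature-typical magnitudes — ligand-receptor
association ~1e7 /M/s (0.6 /nM/min), protein-protein association 1e-6 to
1e-4 /(molecules/cell)/min for a ~1 pL cell, catalytic rates 1-100 /min,
trafficking rates 0.005-0.3 /min — and were then calibrated once, as a
whole, so that the documented behaviors of the published model hold at
baseline: the biphasic FGF panel with an interior peak; max pERK near
8e5 molecules/cell at 0.5 nM FGF versus ~1e3-1e4 at 0.5 nM VEGF with a
steep VEGF dose response reaching ~1e5 at 2 nM; a fast transient FGF
response (T1 of minutes, T2 under ten minutes) versus a slower, more
sustained VEGF response; and the directional effects of VEGFR2 density and
trafficking perturbations. This calibration fixes the package's ground
truth; the synthetic-data generator and all experiments run from it. The
reconstruction does not reproduce every printed number of the original
study (its fitted values live in a supplement that is not redistributed
here); residual quantitative gaps at baseline are the FGF T1 (6.5-7 min
versus "within six minutes") and a roughly two-fold-short T2 contrast.

## Calibration

The 39 free quantities are 34 rate constants (the shared MAPK core, the
VEGFR2 activation/Ras/Raf interface, and the six VEGFR2 trafficking rates)
plus 5 initial amounts (FRS2, Ptase2, Ras, MEK, ERK) — the quantities the
sensitivity analysis flags and the ones spanning both arms. Bounds are one
order of magnitude either side of baseline; the swarm searches log10 space
(multiplicative bounds make the decade the natural metric). The objective
is the weighted SSR over three normalized training sets (six-dose FGF pERK
panel normalized by the panel-wide maximum; 5 ng/ml VEGF pR2 and 50 ng/ml
VEGF pERK each self-normalized). Both data and predictions are clipped at
a 1% detection floor before the relative residual: blot densitometry
cannot resolve signal below background, and without the floor near-zero
points dominate the objective. Predictions are normalized over the same
support as the data (the sampled time points), so noise-free synthetic
data generated from a parameter vector scores an objective of zero at that
vector.

PSO uses the standard constriction coefficients (inertia 0.729, cognitive
= social = 1.49445) with reflecting bounds. The packaged ensemble was
produced by 24 independent runs of 15 particles x 40 iterations against
the packaged synthetic study (seed 2026, noise CV 10%) — a deliberately
scaled-down analogue of the original 72-run campaign — scored on the three
validation sets (10 ng/ml FGF pERK, 80 ng/ml VEGF pR2, heparin-difference
sign agreement), with the best 16 by combined training + validation error
kept. The ensemble file is labelled synthetic
(`data/best_fits_synthetic.json`); it stands in for the original study's
fitted sets, which are not redistributable.

Because every training signal is normalized, the absolute amplitude of
the VEGF-arm response is only weakly identified: independent swarm runs
scatter across the threshold of the ultrasensitive MAPK switch, and
per-fit VEGF metrics span orders of magnitude (much as the per-fit dot
plots of such ensembles do). Ensemble results are therefore summarized by
medians with bootstrap CIs, which are stable against this spread, and the
perturbation analyses report the reference-parameterization value
alongside the ensemble distribution.

## Sensitivity analysis

eFAST follows the resampling recipe standard in systems biology: the input
of interest is driven at the maximum interference-free frequency
(`(NS-1)/(2M)` for M = 4 harmonics), the whole complementary set at unit
frequency with independent random phases, over NR random-phase curves of
NS points; S_ti = 1 − (variance below `omega_max/2`)/(total variance),
averaged over curves. Driving every complementary input at unit frequency
(rather than spreading them over several low frequencies) keeps the
complementary variance inside the cutoff; on the Ishigami benchmark the
spread assignment biases S_ti by up to +0.19 while the unit-frequency
assignment is accurate to < 0.01 at NS = 129. Inputs are sampled
log-uniformly across their two-decade bounds. An inert dummy input
estimates the bias floor; inputs rank as influential when their per-curve
S_ti exceeds the dummy's (one-sided t-test, alpha 0.05). Failed or
non-finite simulations are imputed with the per-curve median output;
dropping them would corrupt the spectrum.

## Response metrics

`max_pERK` is the window maximum of the pERK readout (all free and bound
singly/doubly phosphorylated ERK). T1 is the first time attaining that
maximum; T2 is the measure of the super-half-max set with linear
interpolation at crossings — well defined for multi-modal responses, where
"time above half-max" would otherwise be ambiguous. Metrics are evaluated
on the 120-min window on a 0.5-min grid; records whose maximum falls on
the final grid point carry a boundary flag (those responses have not
peaked within the window). The combination ratio R divides the
co-stimulation maximum by the sum of the mono-stimulation maxima; R for a
dose pair with one zero dose equals 1 identically because the combination
equals the non-trivial mono-stimulation. Ensemble summaries report the
median with a seeded percentile-bootstrap 95% CI (10,000 resamples) and,
for R, a two-sided Wilcoxon signed-rank test against 1 — a documented
stand-in, since the original significance procedure is not specified
beyond its alpha.

## Numerical choices

LSODA with analytic Jacobian (assembled from leave-one-out products over
the flux terms), rtol 1e-8 / atol 1e-6 molecules/cell for production runs;
phospho-species span ~8 orders of magnitude, so pure relative control is
insufficient. Fitting and ensemble screening use rtol 1e-6 / atol 1e-3,
validated by a convergence check (halving tolerances moves pERK by
< 0.1%). Negative excursions beyond 1000x atol abort with an error rather
than being clipped — silent clipping hides stiffness failures; the wide
margin accommodates the benign overshoot that adaptive steppers produce
around steep transients in components of order 1e5-1e6. Conserved-moiety
vectors come from the exact (sympy) left null space of the stoichiometry
matrix restricted to non-clamped species.

## Synthetic data: what it does and does not emulate

The generator reproduces the *structure* of the study's training data —
conditions, sparse ~8-point/2-h sampling, normalization schemes — with
multiplicative lognormal noise (default CV 10%, mean-one), applied before
normalization, because densitometry noise is scale-proportional. It does
not emulate blot saturation, background subtraction artifacts, inter-lab
batch effects, or cell-line differences (the original training data mix
three cell types under a shared-kinetics assumption). Passing tests
therefore demonstrate that the pipeline — simulation, objective,
optimizer, selection — is self-consistent and can recover influential
parameters from data of this information content; they do not certify the
rate constants against real endothelial measurements.

## Problem sizes

Default test and acceptance runs use scaled-down budgets chosen to keep
the full pipeline reproducible on a single CPU: PSO at 10-15 particles x
20-40 iterations with 2-3 starts for recovery checks (the packaged
ensemble used 24 runs), eFAST at 33-65 samples/curve x 2-4 curves on the
ODE model and 129 x 5 on analytic benchmarks, and ensembles of 6-16 sets
per experiment. The analysis scripts under `analysis/` run the same code
at the full packaged-ensemble sizes.

## Known limitations

* The reaction table is a reconstruction engineered to the published
  structural counts from the published network description; individual
  reactions and baseline constants are plausible but not authoritative.
* The VEGF arm sits near a sharp ultrasensitive threshold between 0.5 and
  2 nM; outputs there are sensitive to parameter detail, and ensemble
  spread for VEGF metrics is correspondingly large.
* Signaling by internalized receptors, VEGFR1/NRP1, FGF-activated Ras-Raf,
  ligand depletion, and dynamics beyond two hours are out of scope by
  design.
* The WSSR magnitudes are not comparable to the original study's printed
  error band, which depends on its digitized data; here the objective is
  defined on synthetic tables with a detection floor.
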