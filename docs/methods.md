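# Methods

## Scope and model chain

`qtddi` predicts the population-level and per-subject QTc consequences of
co-administering two ion-channel-blocking drugs. The chain is:
exposure → per-channel Hill block → two-drug combination → conductance
scaling in a human ventricular myocyte strand → pseudoECG → QT/QTcB →
trial aggregation and comparison against observed clinical values. Every
stage is deterministic given its inputs; all randomness enters through
the population sampler and is governed by a single master seed.

## Interaction models

Per channel, two drugs' fractional inhibitions are combined by

* capped sum: `min(eA + eB, 1)` — no mechanistic assumption, effects
  simply accumulate up to full block;
* Bliss independence: `eA + eB − eA·eB` — independent action at distinct
  sites;
* Loewe additivity: `(eA + eB − 2·eA·eB)/(1 − eA·eB)` — dose addition,
  same site and mechanism.

All three assume neither synergy nor antagonism, are symmetric, reduce to
`eA` at `eB = 0`, are monotone in each argument and map [0,1]² into
[0,1]. On the open square they are ordered Loewe ≤ Bliss ≤ sum (the Bliss
− Loewe gap is `eA·eB(1−eA)(1−eB)/(1−eA·eB) ≥ 0`). The Loewe expression
is a two-drug formula; the API deliberately rejects more than two drugs
rather than invent an n-drug generalisation. At `eA = eB = 1` the Loewe
quotient is 0/0; the limit along any interior path is 1, so the
implementation returns 1 by continuity (tested). For Hill exponent 1 and
a shared IC50, Loewe combination is exactly dose addition:
`loewe(hill(a), hill(b)) = hill(a + b)`; the suite verifies this identity
to 1e−12 on a concentration grid, which pins the algebra of both the
Hill and the Loewe implementations.

## Myocyte and strand model

The cellular substrate is the ten Tusscher–Panfilov (2006) human
ventricular model with its published endo/M/epi parameter sets. The
variant choice (over the 2004 model) is ours: it is the variant commonly
used for transmural-strand studies and provides the three subtypes.
Integration is hybrid Rush–Larsen (gates) / forward Euler (everything
else) at dt = 0.02 ms, with the analytic steady-state quadratic update
for Ca²⁺ buffering; halving dt moves APD90 by well under 1 ms (tested).
Drug block is tonic conductance scaling `g′ = g(1 − E)` of gKr, gKs, gNa
and gCaL only — no state- or use-dependence.

The strand is 25 endo / 35 M / 40 epi cells at Δx = 0.15 mm coupled with
diffusion coefficient D = 0.154 mm²/ms (explicit scheme; the config
validates the dt ≤ Δx²/2D stability bound), paced at the endocardial end
(3 cells, −52 pA/pF, 1 ms) at cycle length 1000 ms. These geometry
values are our own defaults chosen to give physiological conduction
(≈ 0.7–0.8 mm/ms here) and a positive T wave; they are all
configurable. Pre-pacing to quasi-steady state is done on uncoupled
single cells per subtype (50 beats by default) and the coupled strand
then runs 3 beats; this hybrid warm-up trades a small residual drift
(baseline QTcB reproducible to ≪ 0.5 ms) for a large runtime saving.

The scaled-down mode used by the test suite and demo configs is a
12/18/20-cell strand with 20 pre-pacing beats and 2 coupled beats; the
full mode is the default of `StrandConfig()`. The suite's problem sizes
(2–3 subjects, 1–2 replicates) are likewise scaled-down choices; the
bundled study designs default to the clinical studies' subject counts
and 10 replicates.

## PseudoECG and QT detection

The unipolar pseudoECG is the standard line-source expression
`Φe(t) ∝ Σx (−∂V/∂x)·∂(1/r)/∂x·Δx` with the electrode 20 mm beyond the
epicardial end on the fiber axis. Electrode geometry scales amplitude but
leaves the measured QT essentially unchanged (tested within 2 ms).

QT = (T-wave end) − (QRS onset). QRS onset is the first sample where
|dΦ/dt| exceeds 5 % of its global maximum. T-wave end uses the tangent
method: within the post-QRS window the dominant deflection from the
isoelectric baseline (median of the final tenth of the beat) is taken as
the T wave; the steepest sign-adjusted downslope after its peak defines a
tangent whose intersection with the baseline is T-end. Both landmarks are
invariant to time translation and amplitude scaling. RR is identified
with the pacing cycle length (there is no heart-rate model), so at
1000 ms pacing QTcB = QT.

No attempt is made to reproduce published *absolute* predicted QT values:
the original study's simulator geometry, pre-pacing protocol and QT
detection rule are proprietary/undisclosed, and its PK inputs came from a
closed-source PBPK platform. The reproduction surface is (a) the distance
arithmetic on the published mean triplets and (b) the qualitative
pharmacology (IKr-block monotonicity, model ordering), both covered by
the suite.

## Synthetic exposure generator

The generator emulates what a full PBPK simulation provided in the
original workflow — per-subject heart-tissue concentration–time profiles
whose Cmax and AUC match published targets — without any mechanism. It
is a one-compartment model with first-order absorption,
`C(t) = F·D·ka/(V(ka−ke))·(e^{−ke t} − e^{−ka t})` (analytic limit
`F·D·ka·t·e^{−ka t}/V` at ka = ke), heart tissue = plasma × constant
partition ratio (default 1). Calibration fixes dose, F and ka (default
1/h), pins `ke·V` from AUC = F·D/(ke·V) and solves Cmax for ke by Brent's
method on (0, ka); the attainable Cmax/AUC ratio on that branch is
bounded by ka/e and infeasible pairs raise. Round-trip accuracy is well
within 1 % for every bundled target pair.

Inter-individual variability is independent log-normal on ka, ke and V
with CV 30 % by default (σ² = ln(1+cv²), median preserved). The DDI
enters only through an exposure-modifier pair (Cmax ratio, AUC ratio ≥ 1)
applied as `C′(t) = mC·C(t·mC/mA)` — amplitude scaling plus time
stretching, which hits both ratios exactly for closed-form profiles.

What this generator does **not** emulate: multi-compartment distribution,
nonlinear or time-dependent CYP inhibition kinetics, dosing-schedule
accumulation, correlated covariates (age/sex/organ function), and
within-subject concentration–QT temporal coupling. Tests passing against
it therefore demonstrate correctness of the pipeline's arithmetic and
qualitative pharmacology, not predictive accuracy for real populations.

The bundled exposure table preserves the published censoring: cells
reported as "<5 ng/ml", subsets of subjects, or values read off a graph
carry flags and are never imputed. Predicted AUCs are unavailable for six
of the eight studies; the study-design table fills those with Cmax × a
nominal 10 h mean residence time, flagged illustrative. The
clarithromycin row's printed predicted Cmax values imply a T+I/T ratio
below 1, which contradicts metabolic inhibition; the design table clamps
that study's exposure multipliers at 1 (no PK interaction) rather than
extrapolate. Channel IC50/n values are likewise illustrative
literature-scale stand-ins, labelled as such in the fixture file.

## Trial engine

One replicate samples a fresh population (replicate seeds = master seed +
1009·replicate, all well below 2³¹), generates per-arm profiles, and
drives the block with the heart-tissue concentration at the victim's Tmax
— a static worst-case coupling chosen because the temporal
concentration–ECG alignment of the original workflow is unknown; a
`profile_max` option exists. The same subject (same PK draw) is carried
across all arms and interaction models, so ΔQTcB contrasts are paired —
required for the per-subject flip analysis. Strand results are memoised
on the block vector (rounded at 1e−9), so arms with identical block — a
drug-free baseline, or T+I with an inert perpetrator — cost one
simulation.

Summaries average over subjects within replicate, then over replicates;
the 95 % CI uses the t-distribution across replicate means and
degenerates to zero width for a single replicate.

## Evaluation

The distance D (README formula) uses within-source baseline subtraction:
predicted deltas are taken against the predicted baseline and observed
deltas against the observed baseline. This convention reproduces five of
the eight published sum-model distances exactly to two decimals
(paroxetine 4.69, ketoconazole 48.61, clarithromycin 21.43, one
erythromycin study 14.27, itraconazole 24.05) and the ketoconazole
Bliss/Loewe and second-erythromycin Bliss values within 0.2 %. The
remaining printed values (fluconazole in particular) are not recoverable
from the rounded table entries under any baseline convention we tried —
recomputation gives ≈ 18.3 vs a printed 31.28 — and are treated as
reflecting the authors' unrounded internal values; the recomputed numbers
are reported as-is. One erythromycin study published only QT *changes*;
its observed ΔT and ΔT+I are used directly, with no baseline available.

Welch's unequal-variance t-test (two-sided, Welch–Satterthwaite df, via
scipy) compares observed and predicted ΔQTcB sets; no multiple-testing
correction is applied. The flip count marks a subject as a case when the
models' ΔQTcB predictions straddle the threshold — strictly below on one
side, at-or-above on the other — with the threshold at the 5 ms level of
regulatory concern; model ranking by D breaks exact ties in the fixed
order sum, Bliss, Loewe (ties do not occur in the bundled data).

## Known limitations

* Uniform block along the strand; no transmural drug-sensitivity gradient.
* Tonic block only — kinetics-dependent (e.g. use-dependent hERG) block
  is out of scope, as are other myocyte models.
* Absolute QTc level (~350 ms baseline at the scaled strand) sits below
  typical clinical means; all analyses are baseline-subtracted.
* The two-drug restriction is structural (Loewe formula); n ≥ 3
  combinations are rejected by design.
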