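# Methods

This note documents the models, conventions, parameter choices and
numerical decisions behind `pb212pk`, and what the synthetic validation
does and does not establish.

## Decay-chain model

The ²¹²Pb series is modelled as an acyclic branching chain solved in
closed form. Constants are pinned in one versioned table
(`src/pb212pk/data/nuclear_data.yaml`): ²¹²Pb 10.64 h, ²¹²Bi 60.55 min,
²¹²Po 0.299 μs, ²⁰⁸Tl 3.053 min; ²¹²Bi branches 64.06% β (→ ²¹²Po) /
35.94% α (→ ²⁰⁸Tl); 238 keV γ yield 43.6%. These are standard evaluated
nuclear data; pinning them makes every downstream number reproducible
from the repository alone.

`bateman_evolve` enumerates decay paths from each populated nuclide and
sums the classic Bateman product terms, with branching fractions
multiplied along each path; the stable ²⁰⁸Pb sink is handled as λ = 0
inside the same formula, so total atoms are conserved identically.
Two numerical points:

* The fastest member (²¹²Po, λ ≈ 8×10⁹ h⁻¹) underflows its own
  exponential at any macroscopic time; the coefficients in which its λ
  appears in both numerator and denominator remain well conditioned in
  double precision (verified against a stiff ODE oracle to <1e-10
  relative; the test suite requires <1e-6).
* Near-degenerate decay constants (|λᵢ−λⱼ| < 1e-10·λ_max) make the
  Bateman denominators blow up; such paths fall back to a matrix
  exponential of the path's bidiagonal rate matrix, which is the exact
  confluent limit. The default chain has no degeneracies; the fallback
  exists for user-defined chains.

`chain_activity_ratio` (total unstable activity over parent activity,
≈3.21 at equilibrium) quantifies why a gross-current dose calibrator
needs a chain-aware dial setting while a 238 keV-windowed γ-counter
reads the parent alone. The dial-value→response physics is *not*
modelled: dial settings are opaque labels and readings at different
dials are compared empirically, which is all the cross-calibration
use-case requires.

## Calibration conventions

The dial overestimation ratio uses the percent-OF convention,
100 × suspect/trusted: 888/277.87 = 319.6%, reported to the nearest 10%
(320%). The percent-increase reading (219.6%) is arithmetically
inconsistent with both the ≈3.2× overestimation factor and the
downstream ≈30 μCi corrected dose, so percent-of is the only coherent
interpretation and is documented here once. Same-source readings must
agree in time to 5 min. Counts→activity conversion divides by live
time, counting efficiency and the 238 keV γ yield.

## %ID/g and the two decay-correction conventions

For a sample counted at t_c, collected at t_k, injected at t_0, with a
per-animal standard (fraction f of the injected dose, counted at t_s):

    S₀ = C_std · e^{+λ(t_s − t_0)} / f
    %ID/g(to_injection)  = 100 · C · e^{+λ(t_c − t_0)} / (S₀ · m)
    %ID/g(to_collection) = 100 · C · e^{+λ(t_c − t_k)} / (S₀ · m)

Counting delay cancels between sample and standard, so %ID/g is
invariant to when the γ-counter ran; the two conventions differ exactly
by e^{+λ(t_k − t_0)}. This identity is enforced as a property test at
1e-10 relative. Background subtraction clamps at zero and flags the
sample instead of dropping it, keeping cohort n intact. The standard's
dilution scheme is carried explicitly as `standard_fraction` so any
bench protocol is representable; the generator uses per-animal
standards. Organ labels are normalised to lower-case singular with an
alias map (kidneys→kidney).

Daughter ingrowth is deliberately absent from the %ID/g decay terms:
the 185–250 keV window isolates the parent's 238 keV line, so parent
decay alone is the correct correction for γ-counter data.

## TAC, AUC and the T/K ratio

AUCs are linear trapezoids on the group-mean curve. Defaults integrate
the observed range only (1→24 h), with no origin anchoring and no tail:
the least-assumption choice, since neither an uptake-phase shape nor a
terminal slope is observed in a 3-point design. Both alternatives are
exposed (`zero_origin` prepends (0,0); `tail='exponential'` extends
with the terminal log-linear slope). On convex decaying curves the
trapezoid overestimates the exact integral, on concave underestimates;
for the *ratio* of two organs with similar effective curvature the bias
largely cancels (≈1–3% on the shipped presets, measured against closed
forms).

Because destructive sampling forbids per-animal AUCs, uncertainty comes
from a stratified bootstrap: animals are resampled with replacement
within each timepoint stratum and the whole TAC→AUC→ratio computation is
repeated; the 95% CI is the 2.5–97.5 percentile band. Two small-sample
refinements, both measured by simulation against the generator's exact
truth (2000 studies, B = 1000):

* **m = n−1 resampling.** The plain n-out-of-n bootstrap estimates each
  stratum mean's variance with the population formula, biased low by
  (n−1)/n — material at n = 4–5. Drawing m = n−1 per stratum makes the
  resampled-mean variance an unbiased estimate of the true sampling
  variance. This raised measured CI coverage from ~84–88% to ~91%.
* **Organ pairing.** The generator's biological scatter is independent
  per (animal, organ), so tumor and kidney are resampled independently
  by default; forcing both organs to come from the same resampled
  animals propagates the spurious in-sample cross-organ correlation of
  a 5-animal stratum into the CI and measurably degrades coverage. For
  real data with correlated organ effects, `pair_organs=True` restores
  whole-animal resampling.

Group comparisons use the two-sided pooled-variance Student t test
(not Welch), with the conventional star mapping (*, **, ***, **** at
0.05, 0.01, 0.001, 0.0001). The default comparison target is per-animal
organ %ID/g between compounds at a chosen timepoint; for AUC ratios the
bootstrap CI is the provided uncertainty statement.

## Synthetic cohort generator

Per organ, the decay-free biology is a two-rate uptake–washout curve

    A(t) = A_peak · (e^{−k_wash t} − e^{−k_up t}) / max_t(·),

normalised so A_peak is the profile maximum (closed-form peak time
t* = ln(k_up/k_wash)/(k_up−k_wash); k_up = k_wash handled by the k·t·e^{−kt}
limit; k_wash = 0 gives monotone saturation). Simulated measurements
apply, in order: physical decay to collection, a unit-mean lognormal
per-(animal, organ) multiplier with CV 20% (the biological scatter),
decay over the 30-min counting delay, and Poisson noise on both signal
counts and a Poisson background that the counter subtracts. Counting
configuration defaults: 0.37 MBq injected, 35% efficiency, 60 s live
time, 0.5 cps background, 1% per-animal standard counted 15 min after
injection. At these settings Poisson noise is ≲1% and the inter-animal
CV dominates — deliberately, since published cohort SDs reflect biology,
not counting statistics. Organ masses are fixed per organ (tumor 0.25 g,
kidney 0.30 g, ...), so mass variation is not a modelled noise source.

Exact integrals of the generating curves (sums of exponentials, with
the extra λ term under the collection convention) give ground-truth
organ AUCs and T/K ratios for any window, which is what the pipeline is
validated against.

### Presets

Four synthetic look-alike parameter sets are shipped. They are
calibrated to exactly two quantitative anchors — decay-free tumor
%ID/g at 4 h of 50 (dotamtate-like) and 10 (dotatate-like) — plus
qualitative orderings: collection-corrected T/K ≈ 3.2 for the
dotamtate-like preset, slightly above 1 (jr11-like), ≈ 0.92
(psc-peg2-toc-like), ≈ 1.45 (dotatate-like); fast pancreas washout for
the two DOTAM-chelated presets. Within each preset the kidney washout
rate is chosen close to the tumor's so the 3-point trapezoid introduces
only ≈1–3% ratio bias against the exact integral, keeping the
validation margins interpretable. The presets claim no fidelity to any
real animal beyond those anchors; in particular absolute kidney levels,
uptake rates and all minor-organ values are invented plausibilia.

### What the generator does not emulate

No excretion/whole-body mass balance across organs, no daughter recoil
or redistribution biology, no tumor-growth or receptor-saturation
effects, no correlated organ effects within an animal, no timepoint
jitter or missing samples. Passing validation therefore shows the
*computational pipeline* is correct and its uncertainty statements are
calibrated under a realistic noise magnitude — not that any preset
predicts real biodistribution.

## Validation experiments (problem sizes)

* **Recovery:** n = 200/timepoint, all four presets × both conventions;
  the pipeline T/K ratio must land within 5% of the exact ratio
  (observed gap: 0.1–3%, dominated by the trapezoid's sampling bias).
* **Coverage:** 100 simulated studies at n = 5/timepoint, B = 1000
  bootstrap replicates; the 95% CI must cover the truth in ≥90 studies
  (measured long-run coverage ≈91%; a 100-study draw carries ±3
  binomial noise). Seeds derive from one `SeedSequence` spawn per
  study, split between generator and bootstrap streams.
* **Mode sensitivity:** a fixture pair sharing one kidney profile —
  tumor advantage accruing early (k_wash 0.4 h⁻¹) vs late (0.005 h⁻¹) —
  whose T/K ranking flips between conventions: the retainer wins under
  injection correction, the early compound under collection correction,
  because the collection convention discounts activity that would have
  decayed away before late timepoints. This is the structural reason
  convention choice can reverse compound comparisons.

## Known limitations

* No absorbed dose in Gy, S-values or MIRD-style organ dosimetry; AUC
  of %ID/g is a surrogate that ignores emission energy per organ and
  cross-dose.
* The t* = 1–24 h window truncates both the uptake phase and the tail;
  window sensitivity must be explored with the exposed flags rather
  than assumed away.
* The iTLC RCY and bench kinetics table are laboratory fixture data for
  the QC logic, not computable quantities.
* The molar mass of the flagship peptide is ambiguous in its source
  records (printed μg↔nmol pairing implies ≈1818 g/mol; the formula
  gives ≈1433 g/mol, salt form unstated); both conversions are carried
  and the caller must choose explicitly.
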