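# Methods

## Unit system and sign convention

All computation is done in the unit system native to AFM force
spectroscopy: pN for forces, nm for distances, s for times (pulling
velocities in µm/s and contact times in ms, following instrument
convention). Energies are in pN·nm with k_B = 1.380649 × 10⁻² pN·nm/K, so
k_B·T = 4.1164 pN·nm at the default temperature of 298.15 K (room
temperature; configurable through `Environment`).

Adhesion forces are stored as positive magnitudes. On a raw deflection
signal, adhesion pulls the cantilever toward the sample and appears
negative; after the sign is fixed, a slip bond obeying Bell kinetics must
have a *decaying* lifetime under load, t(F) = t₀·exp(−x_β F/k_B T), with
t₀ the longest (equilibrium) lifetime. All fits, samplers and detections
use this convention consistently.

## Bond model and samplers

A bond is parameterized by its zero-force off-rate k₀ (1/s) and
transition-state distance x_β (nm). Under constant force the lifetime is
exponential with mean t₀·exp(−x_β F/k_B T). Under a constant loading rate
LR, the off-rate grows as k(F) = k₀·exp(x_β F/k_B T) and the
rupture-force survival law is

    S(F) = exp[ (k₀ k_B T)/(x_β LR) · (1 − exp(x_β F/k_B T)) ],

which the sampler inverts exactly: F = (k_B T/x_β)·ln(1 − (x_β LR)/(k₀
k_B T)·ln U) with U uniform on (0,1). The distribution's mode is the
Bell–Evans most probable force; when LR·x_β ≤ k₀·k_B T the density is
maximal at zero force and the closed-form mode is reported as 0 with a
`below_threshold` flag. The degenerate case x_β = 0 (force-independent
bond) falls back to the exponential limit.

Sampler correctness is established against the analytic survival law
(Kolmogorov–Smirnov at n = 10⁴) and against the closed-form mode, and the
log-linearity of the empirical mode in LR (slope k_B T/x_β) is checked by
regression over 4.5 decades.

## Synthetic curve generation

The generator emulates the two experimental protocols, not the instrument:

* **Retract force–distance curves**: 512 samples over a 40 nm ramp.
  Each rupture event is rendered as a worm-like-chain (WLC,
  interpolation form F = (k_B T/L_p)·[1/(4(1−x/L_c)²) − 1/4 + x/L_c])
  force rise whose contour is solved so the rise reaches the rupture
  force exactly at the rupture separation, detaching abruptly there.
  The tether defaults: persistence length 0.38 nm, contour 9 nm of PEG
  linker + 6 nm of unfolded polypeptide = 15 nm total, placing specific
  ruptures at ≈8–13 nm separation, inside the 5–25 nm specific window.
  The WLC (rather than a freely jointed chain) is a cosmetic choice: only
  the rupture coordinates enter the analysis. Baseline noise is Gaussian
  with sd 3 pN, so the five-sigma specific threshold is ≈15 pN. With
  probability 0.1 a non-specific short-range adhesion (20–80 pN amplitude,
  1.2 nm exponential decay) is added near the contact point.

* **Height-clamp force–time traces**: square force pulses on a noisy zero
  baseline, 0.5 ms sampling over 1.5 s.

* **Loading rates**: per event, LR = k_eff·v with median-preserving
  log-normal scatter of 20% cv. The scatter reflects that real
  per-velocity loading-rate distributions are empirical, not a single
  nominal value; the cv is a modeling choice (configurable). k_eff is the
  series stiffness of the cantilever (70 pN/nm nominal) and the WLC
  tether evaluated at 72% extension (≈17 pN/nm), giving k_eff ≈ 13.8
  pN/nm. The Bell–Evans slope — hence x_β recovery — is invariant to the
  overall LR scale, so this choice affects realism, not correctness.

* **Study conditions**: five pulling velocities (1, 3.1, 6.3, 12.5,
  25 µm/s), ~92 events per velocity (≈460 per dataset), contact times
  2–502 ms as metadata, clamp forces uniform on 20–120 pN with 134 events
  per clamp dataset.

What the generator does *not* emulate: cantilever hydrodynamics and
drift, multiple-barrier (catch-bond) kinetics, contact-region mechanics,
tip-chemistry variability, and any contact-time dependence within one
dataset (each contact time/state is a separate parameter set). Passing
recovery tests therefore demonstrates the correctness of the analysis
chain under the stated noise model, not robustness to every artifact of
real recordings.

## Event detection

* Baseline: least-absolute-deviations line (median quantile regression)
  over the far 30% of the retract; beyond 25 nm no specific event can
  occur, so that region is adhesion-free by construction of the filters.
  Noise sd = 1.4826 × median absolute residual.
* Candidates: local maxima of the baseline-corrected force after a
  5-sample running average, at least 3 sd high and prominent. The peak
  force is read from a lighter 3-sample average at the apex (the full
  smoothing window biases steep peaks low; raw samples are noisy).
* Rupture criterion: within 2 nm after the peak the force must either
  return to within 2 sd of baseline or drop by at least half the peak
  height. The pure return-to-baseline rule fails on multi-event curves,
  where the not-yet-ruptured tether's WLC tail keeps the force above
  baseline tolerance after an earlier rupture.
* Specificity: closed windows [5, 25] nm (binding) / [10, 25] nm
  (extraction of the reconstituted polypeptide, matching its ≈15 nm
  unfolded contour), force ≥ 5 × noise sd. Curves are kept only when
  exactly one specific event is present; discard reasons are logged.
* Loading rate per event: least-squares slope of force vs time
  (time = separation / pulling velocity) over the contiguous rise between
  30% and 95% of peak force — this window avoids the nonlinear WLC toe
  and the rupture discontinuity. Fewer than 6 rise samples leave the
  event without a loading rate; such events count for force
  distributions but not for DFS reduction.
* Clamp events: 5-sample running average; baseline and noise from the
  trace median/MAD (events are sparse); an event is an excursion beyond
  2 sd that starts and ends inside the trace and clears the five-sigma
  threshold at its peak; intra-event peak-to-trough fluctuation above
  5 pN discards the event, evaluated on the excursion interior (one
  smoothing window trimmed at each edge, where the running average
  ramps).

On 2,000 synthetic curves at the default noise level, detection achieves
recall and precision ≥ 0.95 for true specific events ≥ 25 pN (the test
suite and `analysis/02_detect_events.py` recompute this).

## Kinetic fitting

* **Bell fit** (`fit_bell`): events are pooled into equal-width force
  bins (default 8; the bin count is not dictated by the protocol and is
  configurable) and ln(mean lifetime) is regressed on mean force with
  weights ∝ bin counts. The model is linear in (ln t₀, x_β), so the
  weighted normal equations solve it exactly — no iteration can fail to
  converge outside the documented degenerate cases (zero force spread,
  < 3 bins). Two bias corrections are applied, both vanishing on exact
  inputs: (i) the bin-averaged lifetime exceeds the lifetime at the
  bin-mean force by sinh(a)/a, a = x_β·w/(2 k_B T) for bin width w
  (forces ≈ uniform within a bin); this factor is divided out, iterating
  on the fitted x_β; (ii) the small-sample bias of the log of a bin mean,
  E[ln t̄] ≈ ln E[t̄] − Var(t̄)/(2 E[t̄]²), is removed using each bin's
  empirical lifetime sd and count. Without these corrections t₀ is
  overestimated by ≈10% under the default binning.
* **KDE reduction** (`dfs_reduce`): per velocity, the most probable force
  is the Gaussian-KDE mode (Silverman bandwidth, 512-point grid spanning
  the data ± 3 bandwidths) on the raw scale; the most probable loading
  rate is the KDE mode on the log scale (loading rates are positive and
  right-skewed), transformed back. Groups need ≥ 5 events with defined
  loading rates; smaller groups are skipped with a warning.
* **Bell–Evans fit** (`fit_bell_evans`): weights ∝ per-velocity counts;
  multi-start Levenberg–Marquardt over a log grid k₀ ∈ [10⁻⁴, 10³] 1/s ×
  x_β ∈ [0.05, 10] nm (log-parameterized for robustness across decades),
  then a final refinement with (k₀, x_β) on their natural scale so the
  covariance — and the symmetric 95% CI reported for k₀ — refers to the
  parameters directly. "Iterative fitting" here means multi-start until
  convergence; no data re-weighting between iterations. Preconditions:
  ≥ 2 points spanning ≥ a factor 3 in loading rate; a non-positive
  weighted slope of F vs ln LR is a model-invalid error. With exactly two
  points the system is determined and CIs are undefined (NaN).
* **Confidence intervals**: 95%, Student-t on the fit covariance with the
  residual degrees of freedom. For t₀ (fitted as ln t₀) the CI half-width
  is mapped by the delta method, keeping the ± reporting convention.
* **Arrhenius conversion**: ΔG = −ln(τ_D·k₀) in k_B T units with
  τ_D = 10⁻⁵ s (configurable); ΔG_err = k₀_err/k₀. In k_B T units the
  conversion is temperature-free; the `Environment` argument exists for
  interface symmetry.

Parameter recovery: over 20 seeded replicates of the five-velocity DFS
experiment (92 events/velocity), the generating x_β lies inside the
fitted 95% CI in ≥ 90% of replicates; the same holds for t₀ and x_β in
the 134-event height-clamp experiment. Both checks run in the test suite
and are summarized by `scripts/acceptance.py` (50 replicates for the
reported point values; the median is used as the point summary because
the per-replicate estimates are right-skewed).

## Statistics

* Mann–Whitney U: exact distribution for tie-free samples with
  n_a + n_b ≤ 12, tie-corrected normal approximation with continuity
  correction otherwise (via scipy); validated against brute-force
  enumeration of all group assignments for every layout with
  n_a + n_b ≤ 10.
* Mean-force regression: per-variant OLS of per-contact-time mean forces
  on contact time *in seconds*, independent lines per variant
  (block-diagonal design). The regression is validated by synthetic
  recovery only; no literature coefficients are asserted because the
  published slope units are not consistent with the force trend over the
  stated time range.
* Density profiles: Gaussian KDE, Silverman bandwidth, mass-conservation
  checked to 10⁻³; point-mass inputs produce a single narrow peak.

## Numerical choices and degenerate inputs

* WLC inversion (extension at force, event contour) uses Brent's method
  on the dimensionless extension in (0, 1−10⁻⁹); tolerance 10⁻¹².
* KDE of a zero-variance sample returns the sample value directly.
* On noiseless curves the k×sd thresholds degenerate to 0; a 0.5 pN
  floor stands in so constructed noise-free fixtures behave sensibly.
* All generators draw from an explicit `numpy.random.Generator`; the
  pipeline and CLI route every random draw through one seeded generator
  per run, making outputs byte-reproducible.

## Problem sizes

The shipped analyses use the study-condition sizes (460/372/322/311
rupture events for the four DFS conditions, 134 clamp events, 2,000
curves for the detection benchmark, 20–50 replicates for recovery
summaries). These sizes match the emulated experiments; larger runs only
sharpen the Monte-Carlo summaries.

## Known limitations

* The Bell/Bell–Evans machinery assumes a single sharp barrier and slip
  bonds; multi-barrier or catch-bond landscapes are out of scope.
* Mode regression on KDE-reduced points is the implemented estimator
  (matching the emulated analysis); maximum-likelihood rupture-force
  fitting would use each event individually and is not provided.
* The KDE mode carries a small smoothing bias on skewed rupture-force
  distributions (≲ 1 pN at n ≈ 10² per group with Silverman bandwidth);
  it shifts all velocities similarly and therefore perturbs k₀ more than
  x_β.
* Baseline estimation assumes the far 30% of the retract is event-free,
  which the 25 nm specific window guarantees here but tether designs with
  longer linkers would violate.
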