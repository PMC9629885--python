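# Methods

## Binding model

A bivalent antibody (two identical binding sites, per-site dissociation
constant K_D) equilibrated with drug at concentration `Dose` has per-site
occupancy `theta = Dose/(K_D + Dose)` when the drug is in excess of the
binding sites (free drug ~ total drug).  A bridging assay detects an
antibody only if at least one paratope is free, which happens with
probability `1 - theta^2`.  The expected signal is therefore

    Response = Ab * (1 - theta^2) = Ab * (1 + 2 Dose K_A) / (1 + Dose K_A)^2

with `Ab` the zero-dose plateau and `K_A = 1/K_D`.  The association- and
dissociation-constant forms are algebraically identical; the package
evaluates the `K_A` form because it is finite at zero dose (the other form
divides by `Dose`).  A polyclonal response is approximated as biclonal:
the biphasic model is the sum of two independent phases, ordered so that
phase 1 is the high-affinity (smaller K_D) phase.  Site independence, no
avidity or cooperativity, and complete equilibration are assumed
throughout; no more than two phases are modelled.

All concentrations are carried in molar internally.  Mass-unit doses
(ng/mL) are converted with a configurable drug molar mass defaulting to
150,000 g/mol, the nominal mass of a human IgG — the reporting layer
converts K_D back to pM/nM.

## Estimation

Both models are fitted by nonlinear least squares over the logs of the
parameters (positivity plus conditioning: K_D spans ~10 decades).
Initialisation is a deterministic multi-start: one K_D start per decade
from 100x below the lowest observed dose to 100x above the highest; at
each start the amplitudes, which enter the model linearly, are set by a
small linear solve.  The best residual sum of squares wins, ties breaking
toward the smaller high-affinity K_D.  Convergence uses a 1e-10 relative
cost tolerance with at most 500 evaluations per start.  Optimisation runs
inside a wide log-space box (16 nats beyond the data scales) that never
binds for identifiable fits but keeps degenerate ones finite.

The default loss is *relative* least squares — residuals divided by the
observed signal — because immunoassay noise is close to constant-CV, and
under that noise the relative loss is the correctly weighted estimator.
On the reference recovery problem (Ab = 1000, K_D = 2 pM, 8-point series,
CV 0.10) it roughly halves the sampling error of log K_D relative to
unweighted fitting, whose asymptotic median |relative error| (~15%) is
dominated by the plateau points that carry no affinity information.
`weights="unweighted"` restores plain least squares on the raw signal.

A K_D estimate more than 1000x outside the observed dose window is
declared unidentifiable (`converged = False`): the data contain no
curvature there, and such fits must fail downstream QC rather than emit a
number.  Biphasic fits with K_D2/K_D1 < 3 are flagged as having
indistinguishable phases.

Parameter covariance is `s^2 (J'J)^-1` with `s^2 = rss/(n-k)` and J the
(weighted) Jacobian in log space at the optimum.  Confidence bounds on the
mean response use first-order propagation of that covariance through the
model gradient with a Student-t quantile at `n - k` degrees of freedom.
These are mean-response bounds, not prediction intervals for new wells:
the flatness test compares fitted-curve ends, for which the mean response
is the relevant quantity.  A numerically singular covariance (condition
number above 1e12) yields infinite bounds, which guarantees a flatness
failure instead of a spuriously confident verdict.

## Model selection

The small-sample Akaike criterion with the residual variance profiled out,

    AICc = n ln(rss/n) + 2k + 2k(k+1)/(n - k - 1),   k = 2 or 4,

is computed for both fits (constants shared by the two models cancel in
the comparison, and both use identical weights).  Akaike weights
`exp(-delta/2)` normalised over the two models give the model
probabilities; the biphasic model is selected only when its probability
strictly exceeds 50%, an exact tie going to the monophasic model by
parsimony.  An exact fit (rss = 0) maps to AICc = -inf and is handled by
the same parsimony rule.  With 8-point curves the AICc penalty difference
between k=4 and k=2 is large (~14.9), so a biphasic call requires a
substantial rss improvement — the intended small-sample conservatism.
The biphasic summaries — `K_D(geo) = sqrt(K_D1 K_D2)` (which always lies
between K_D1 and K_D2) and the amplitude proportions `Ab_i / (Ab1 + Ab2)`
— are reported for every sample regardless of the selection.

## Quality gating

The flatness test evaluates the confidence bounds (level 0.99 by default)
at the minimum and maximum observed dose: the curve passes when the lower
bound at the lowest dose strictly exceeds the upper bound at the highest
dose, i.e. when the two ends of the inhibition curve are statistically
separated.  "Overlap" is read literally: a shared point fails.  Bounds are
evaluated at the extreme observed doses — since the fitted response is
monotone, separation of the extremes is separation of the whole range.
A sample's K_D is `accepted` only when both the monophasic and biphasic
fits pass; failing samples are retained in every output with a flag, never
dropped.

The signal window — the observed (replicate-averaged) signal at the lowest
dose divided by the signal at the highest — is attached as a descriptive
statistic.  Window >= 4.0 and ADA log titer >= 3.0 are annotation
thresholds marking the empirically reliable regime; they are not hard
gates.

## Apparent concentration

A four-parameter logistic is fitted to the positive-control calibrators
(at least five levels, strictly monotone replicate means; the 4PL's
(a, d, b) <-> (d, a, -b) symmetry is canonicalised to positive slope).
Sample signals are inverted through the closed-form inverse 4PL,
multiplied by the assay dilution, and divided by the control's enrichment
recovery (default 0.30) to back-calculate a pre-enrichment serum
concentration.  The monoclonal control cannot represent a polyclonal ADA
mixture (parallelism is not established), so results are semi-quantitative
by construction; signals outside the calibrated range are flagged
below/above quantitation and never extrapolated.  The dilution and
recovery factors are carried on the result so any of the three scales
(diluted, eluate, serum) can be recovered.

## Simulator

The simulator is the package's independent physics oracle.  For each dose
it solves the exact mass balance for the free drug L shared by all
antibody clones,

    l_tot = L + sum_c sites_c * L / (kd_c + L),

by bracketed root finding on [0, l_tot] (the left side is strictly
increasing, so the root is unique; solved to ~1e-15 relative), then forms
the signal `background + scale * sum_c (sites_c/2) (1 - theta_c^2)` with
`theta_c = L/(kd_c + L)` — `sites_c/2` because an IgG clone contributes
two sites per detectable antibody.  In the dilute regime (sites well below
K_D and every dose) this converges to the closed-form models; with
concentrated antibody it reproduces the ligand-depletion right-shift of
apparent K_D that the closed-form models cannot represent.  Noise is
multiplicative log-normal at a stated CV (mean-preserving), plus an
additive background applied before the noise; a seed is mandatory and all
per-sample streams are spawned from it.

What the simulator does not emulate: the enrichment chemistry and its
acid-cycle losses, instrument-level event counting, plate-layout
artifacts, and true polyclonality beyond two clones.  Passing tests
therefore validate the analysis pipeline against the stated physics, not
the wet-lab behaviour of real plates.

## Default study scenario

The default scenario encodes a seven-patient affinity-maturation time
course on the assay's 8-point, 5-fold, 1000 -> 0.0128 ng/mL dose design:

* Each patient carries two clones at `K_D(geo)/sqrt(30)` and
  `K_D(geo)*sqrt(30)` (30-fold phase separation).  True K_D(geo) falls
  geometrically from start to end of each patient's time course, with
  per-patient fold-changes of 20x to 2000x — within the 20–10,000x range
  a maturing clinical response can span.  Start values are capped at
  ~3 nM: the fixed dose window (top dose 6.7 nM at 150 kDa) cannot
  resolve affinities far above the top dose, which is also why very early
  clinical time points fail quality criteria.
* Patients 1–4 have 4–6 time points with the high-affinity site fraction
  rising 0.25-0.35 -> 0.65-0.80; patient 5 has three time points with a
  flat 50/50 mixture; patients 6–7 contribute two time points each.
* Total binding-site concentration rises from 2e-14 to 8e-14 M (rising
  titer, staying in the dilute regime so fitted values track truth), and
  log10 titer rises linearly from 2.0 to 4.5, with NAb positivity
  annotated above titer 3.5.
* Defaults: detection scale 1e18 signal units per molar antibody,
  background 20 units, noise CV 0.08 — a mid-range immunoassay CV; the
  assay's own noise magnitude is not established, so the CV is a free
  simulation parameter, not a measured property.

## Problem sizes and numerical choices

Monte-Carlo checks use 200 replicate curves per condition (recovery at
CV 0.10; selection rates at CV 0.05 for monophasic truth and for
1000x-separated biphasic truth), which bounds the standard error of a
selection rate near 3% while keeping a full validation run to a few
minutes on one CPU.  The flatness ladder uses 25 fixed-seed replicates at
each of three amplitudes (100, 1000, 20000 units over a background of
100).  Root finding, tie-breaking, and degenerate-input handling
(zero-dose wells, constant signals, singular covariances, out-of-range
calibrator signals) are described above at the point where each arises.

## Known limitations

* The biclonal decomposition is a summary of a polyclonal reality; the
  reported proportions are model constructs, most meaningful when the
  phases are well separated (>= 3x is the minimum flagged, ~30x typical
  in simulation).
* The excess-ligand closed forms understate K_D when antibody
  concentrations approach the dose scale (depletion); the simulator
  quantifies but the fitter does not correct this.
* Display rounding of precision statistics follows one-decimal half-up
  convention for mean and SD (integer for %CV), which matches conventional
  bioanalytical reporting of low-pM values but is not significant-figure
  aware for very different magnitudes; the unrounded values are always
  carried alongside.
* Confidence bounds are first-order (delta-method); they agree with a
  parametric bootstrap to within a fifth of the interval width on
  well-behaved fits but can be optimistic for near-degenerate ones, which
  the flatness gate is designed to catch.
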