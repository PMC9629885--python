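# ada-affinity

Apparent binding affinity (K_D) of anti-drug antibodies (ADA) from
solution-equilibrium free-ADA inhibition curves.

## The problem

Clinical ADA responses are polyclonal: a patient's serum contains antibody
populations spanning femtomolar to micromolar affinities for a
biotherapeutic, and those affinities mature over months of treatment.  A
solution-equilibrium assay measures this by incubating a fixed amount of
enriched ADA against a serial dilution of drug and detecting, in a bridging
ligand-binding assay, only the ADA that still carries a free paratope.  The
resulting dose–signal inhibition curve encodes the apparent K_D.

This package provides the analysis side of that workflow for bioanalytical
scientists: model fitting and selection, curve-quality gating, apparent
concentration estimation, longitudinal affinity-maturation summaries, and a
physically exact assay simulator for validation.

## The models

With `Dose` the drug concentration, `K_A = 1/K_D`, and `Ab` the maximal
(zero-dose) signal of a phase, the expected free-ADA signal is

```
monophasic:  Response = Ab (1 + 2 Dose K_A) / (1 + Dose K_A)^2
                      = Ab (1 - 1 / (K_D/Dose + 1)^2)
biphasic:    the sum of two such terms (phase 1 = high affinity,
             phase 2 = low affinity, K_D1 <= K_D2)
```

The monophasic form is the probability `1 - theta^2` that a bivalent
antibody keeps at least one free paratope at per-site occupancy
`theta = Dose/(K_D + Dose)`, scaled by `Ab`.  Both models are fitted by
multi-start nonlinear least squares in log-parameter space; the winner is
chosen by small-sample-corrected AIC (AICc) converted to Akaike
probabilities, with probability > 50% required to call a curve biphasic.
Biphasic fits additionally report the geometric-mean `K_D(geo) =
sqrt(K_D1 K_D2)` and the amplitude-normalised proportion of the high- vs
low-affinity population.  A "flatness test" gates quality: the 99%
confidence bound of the fitted response at the lowest dose must clear the
bound at the highest dose for both fits, otherwise the K_D is flagged.

## Worked example

```python
>>> import ada_affinity as aa
>>> ds = aa.make_dose_series()          # 8 points, 5-fold, from 1000 ng/mL
>>> ds.doses_source[-1]
0.0128
>>> truth = aa.BindingParamsBi(500, 1e-12, 500, 1e-9)
>>> curve = aa.AffinityCurve("demo", ds.doses_molar,
...                          aa.response_bi(ds.doses_molar, truth))
>>> res = aa.fit_biphasic(curve)
>>> print(res.summary())
Free-ADA binding fit: biphasic
  n = 8, k = 4, rss = 2.69376e-30, converged = True
  Ab1 = 500  (high-affinity phase)
  K_D1 = 1e-12 M  (95% CI 1e-12 .. 1e-12)
  Ab2 = 500  (low-affinity phase)
  K_D2 = 1e-09 M  (95% CI 1e-09 .. 1e-09)
  K_D(geo) = 3.162e-11 M, proportion high = 0.500
>>> choice = aa.choose_model(aa.fit_monophasic(curve), res)
>>> choice.selected, round(choice.prob_bi, 3)
('biphasic', 1.0)
```

The fit recovers both dissociation constants of the noiseless two-phase
curve exactly (1 pM and 1 nM), the AICc probability identifies the curve
as biphasic, and `K_D(geo)` = 31.6 pM summarises the mixture with the
high-affinity phase holding 50% of the signal amplitude.

Replicate precision of a positive-control K_D (values in pM):

```python
>>> s = aa.precision_summary([1.4, 1.2, 2.9, 2.3])
>>> s.mean_rounded, s.sd_rounded, s.cv_rounded
(2.0, 0.8, 41)
```

The command-line pipeline simulates a seven-patient affinity-maturation
study, fits every curve, and reports trajectories:

```
ada-affinity end-to-end --seed 1 --outdir run1 --plots
```

which logs `report: 22/27 samples accepted, r(log titer, log KD) = -0.948`
and writes per-sample fits, per-patient trajectories (fold-changes of
25–1955x over the time course), QC flags, and plots under `run1/`.

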