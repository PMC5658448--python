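# Methods

This note documents the models behind `kinsig`, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the
numerical choices a user fitting or extending the package should know about.

## Binding model

A single receptor pool of density `r_tot` (default 1.0, so all occupancies
are fractional) binds up to three competing ligands by mass action:

    dRL_i/dt = kon_i · L_i(t) · R(t) − koff_i · RL_i(t),
    R(t) = r_tot − Σ_i RL_i(t).

Assumptions:

* **No depletion.** Free ligand concentrations `L_i(t)` are piecewise
  constant, set by addition events. Plate assays run at large volume excess
  over receptor, so ligand consumption is negligible; this also makes the
  ODE linear within each segment.
* **Pre-incubation is an event.** A 30-min antagonist pre-incubation is an
  antagonist addition 30 min before the agonist event, with no washout —
  matching how both functional protocols are actually run. Exported
  functional time courses are shifted so t = 0 is agonist addition.
* **No rebinding/diffusion microkinetics.** Local rebinding effects are not
  modelled; competition is purely through the shared free-receptor pool.
* **Nonspecific binding is zero.** "Specific binding" in the dual-point
  assay is the bound-radioligand state itself.
* **Temperature is implicit.** Different assay temperatures are represented
  by supplying different kon/koff sets; there is no Arrhenius model.

Integration uses LSODA with rtol 1e-8 / atol 1e-10; every addition event is
a hard breakpoint (the integrator restarts), so the discontinuous inputs
never sit inside a step. Free receptor is computed as `r_tot − Σ bound`,
making mass conservation exact by construction.

Closed forms kept alongside the ODE: the Motulsky–Mahan biexponential for
two ligands co-added to an empty pool (with the repeated-root case handled
by its analytic limit), the Gaddum equilibrium occupancy, the Schild dose
ratio, and the Cheng–Prusoff IC50. The ODE is validated against the
Motulsky–Mahan solution to better than 1e-4 relative across four decades of
rate and concentration combinations, and against Gaddum at long horizon to
1e-3.

`competition_ic50_at_time` deserves a note: the dual-point assay doses each
competitor at a concentration producing ~50% (30–70%) radioligand inhibition
*as observed at the read*. For slowly associating competitors that
concentration is far above the equilibrium IC50 (an equilibrium-IC50 dose of
a koff = 1e-4 min⁻¹ competitor binds almost nothing within 120 min, which
would push its KRI back toward 1 and destroy the KRI–koff ordering). The
helper inverts the closed-form solution at t2 to reproduce the
experimental titration rule.

## Transduction model

Functional readouts (cAMP luminescence, impedance) rise and fall over tens
of minutes even under sustained agonist. The transient is generated by
first-order desensitization of agonist-occupied receptor feeding a
hyperbolic (operational-model-style) amplifier:

    A(t) = max(b(t) − D(t), 0)        active occupancy (b = fractional bound agonist)
    dD/dt = k_des · A(t),  D(0) = 0   desensitized pool
    E(t)  = gain · efficacy · A(t)    stimulus
    dr/dt = k_syn · E/(1+E) − k_deg · (r − basal),  r(0) = basal.

Desensitization (rather than response auto-decay alone) was chosen because
it makes the peak time concentration-dependent — lower agonist
concentrations peak later, as real traces do. The hyperbolic coupling
produces receptor reserve (functional EC50 below the binding KD, growing
with `gain`) and lets slow antagonists depress the fitted maximum rather
than merely right-shift the curve.

Defaults (per-minute rates):

| calibration | gain | k_syn | k_deg | k_des | basal | saturating peak |
|-------------|------|-------|-------|-------|-------|-----------------|
| `camp`      | 5    | 100   | 0.08  | 0.06  | 10    | 23 min          |
| `impedance` | 50   | 2     | 0.10  | 0.12  | 0.2   | 24 min          |

Both calibrations were fixed once so that a saturating agonist peaks inside
the 20–30 min window on a 1-min grid. The `camp` gain is deliberately
modest: in this receptor system the cAMP readout shows near-complete Emax
ablation by slowly dissociating antagonists, i.e. little spare-receptor
buffering, and a high gain would mask blockade entirely. `impedance` runs at
10× the gain, encoding the systematically left-shifted potencies (and weaker
Emax depression) of label-free morphology readouts. Readout units are
arbitrary (RLU-like and NCI-like).

Noise is multiplicative-plus-additive Gaussian per well and time point
(`v·(1+ε_m) + ε_a`), reflecting scatter that scales with signal; replicate
CVs of 5–15% are typical, and the generator defaults to cv 0.05–0.10
depending on calibration when noise is requested (protocols are noiseless
unless a `NoiseModel` is passed).

## Synthetic assay designs

The generator emulates: time- and concentration-dependent transients peaking
20–30 min post-stimulation; 30-min antagonist pre-incubation at panel
concentrations (canonically 0.07 / 0.21 / 0.7 nM) before agonist titration;
antagonist titration against an EC80 challenge with an antagonist-free
control; and the dual-point competition association protocol (radioligand
2.5 nM, reads at 30 and 120 min, competitor inside the 30–70% inhibition
window). Functional traces use a 1-min grid over 45 min. The EC80 used by
the IC50 protocol is expected to come from a *prior fit* of the agonist-only
simulation, mirroring lab practice, not from generating parameters.

Deliberately not emulated: plate-geometry and edge effects, liquid-handler
artifacts, luciferase substrate kinetics, cytoskeletal mechanics, pathway
branching (readouts are generic transduced signals), and drift or
autocorrelated noise. Passing tests therefore demonstrate correctness of
the analysis chain under the stated noise model, not robustness to every
real-plate pathology.

Determinism: a single seed fans out to per-condition substreams keyed by a
CRC of the condition id, so adding or reordering conditions leaves other
conditions' noise untouched; every dataset carries a metadata block (full
protocol echo, seed, generator version) sufficient to regenerate it
bit-exactly.

## Analysis procedures

* **KRI** = B_t1/B_t2 with replicates averaged at each read.
* **Peak analysis**: max(value − baseline) per well; baseline is the mean of
  pre-stimulation samples when the trace has them, else the first sample. No
  smoothing — replicate structure, not filtering, handles noise.
* **Variable-slope logistic fits**: unweighted least squares, five
  deterministic starts with the EC50 initialization spanning the observed
  concentration range, bounds hill ∈ [0.05, 10] and |logEC50| within 3
  decades of the data; asymptotic standard errors from the Jacobian.
  Non-convergence and degenerate (flat) data yield a flagged result, never
  an exception; EC50 estimates more than one decade outside the fitted range
  are flagged extrapolated. Descending (inhibition) fits mirror the
  concentration axis so the Hill slope stays positive.
* **Normalization** scales all peaks so the control's *fitted* top is 100% —
  less noise-sensitive than dividing by the single largest observation.
* **Onset**: OLS slope of value vs time over samples strictly after agonist
  addition up to and including the 8-min endpoint, per replicate, then
  averaged.
* **Dunnett's post-test**: two-sided many-to-one comparisons using a seeded
  Monte Carlo sample (default 1e5 draws) of the max-|T| multivariate-t null
  with the exact unbalanced correlation structure
  ρ_ij = √(n_i n_j/((n_i+n0)(n_j+n0))); the null sample is cached per
  (group sizes, df, draws, seed), so repeated calls are cheap and
  deterministic. Family-wise error is verified by simulation to sit in
  [0.03, 0.07] at α = 0.05 under the null.
* **Surmountability labels**: surmountable if the Emax reduction is not
  significant; partially insurmountable if significant with normalized
  Emax ≥ 50%; insurmountable below 50%. The 50% cut is a package convention
  — the field uses these labels qualitatively — and the Dunnett comparison
  is run on top-concentration (Emax-level) replicate peaks.

## Design notes and known limitations

* **Truncated pre-incubation is load-bearing.** With a 30-min
  pre-incubation, an antagonist's occupancy at agonist addition is governed
  by kobs = koff·(1 + I/KD); at I = 2·KD a koff = 0.005 min⁻¹ antagonist
  reaches only ~24% blockade, which no transduction calibration can turn
  into a >20% Emax loss. Insurmountability in this package (normalized
  Emax < 80%) emerges at panel-top concentrations several-fold above KD
  (e.g. 0.7 nM of a KD 0.1 nM, koff 0.005 min⁻¹ antagonist → Emax ≈ 72%),
  exactly as the strongest experimental conditions use. Comparisons meant to
  isolate residence time per se should pre-equilibrate the antagonist.
* **Probe dependency is a matched-response phenomenon.** At equal L/KD, the
  slowly dissociating agonist (SP) is also the slower associator
  (kobs = koff·(1+L/KD)), and every mechanism in the model then penalizes SP
  more. The experimentally observed stronger onset suppression for NKA
  appears when each agonist is challenged at the EC80 implied by its
  functional potency (SP 2.2 nM → 8.8 nM ≈ 78×KD; NKA 483 nM → 1932 nM ≈
  10×KD): SP's challenge sits far up its occupancy curve and shrugs off the
  dose-ratio shift, NKA's does not. The probe-dependency tests use that
  matched-EC80 design.
* The radioligand's own rate constants are not separately published for this
  system; the package assumes SP's (it is an SP analogue). The two
  antagonist fixtures (`aprepitant_like`, `dfa_like`) are synthetic
  stand-ins: koff from reported kinetic behaviour, kon back-calculated from
  published affinities. Quantitative potencies and Emax values from the
  replica suite are therefore illustrative, not reproductions of measured
  antagonist data.
* Fits are per-condition; there is no global (shared-parameter) fitting,
  no weighting, and no Bayesian option. kon/koff are inputs, never fitted.
* Problem sizes throughout (8-point titrations, 3 replicates, 100-seed
  recovery studies, 2000-experiment error-rate simulations, 1e5-draw Dunnett
  nulls) are the package's test defaults, chosen to estimate each quantity
  to well inside its acceptance band.
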