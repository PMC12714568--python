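# Methods

This note records the models, numerical choices, and limitations behind
`protonex`, at the level a maintainer or careful user needs.

## Bloch–McConnell forward models

Magnetization is propagated in a 3N-vector basis (x, y, z per exchanging
site). Site resonance offsets are referenced to the population-average
chemical shift, matching the convention of placing the off-resonance carrier
relative to the observed exchange-averaged peak; shift differences are stored
in ppm (positive downfield, minor minus dominant) and converted per probe as
ω = 2π · ppm · Larmor(MHz). A single (R1, R2) pair is shared across all sites
of a model — the standard assumption when the minor state's relaxation cannot
be determined independently. The homogeneous equation is propagated
(relaxation toward zero, not thermal equilibrium): over the ≤120 ms delays
relevant here the equilibrium-recovery term is negligible, and this is the
convention under which far-off-resonance CEST intensity decays as
exp(−R1·t), which the implementation reproduces.

**Propagation.** The evolution matrix is diagonalized once per grid point
(batched `numpy.linalg.eig` over the full acquisition grid), with a
scaling-and-squaring (`scipy.linalg.expm`) fallback whenever the eigenvector
basis has condition number above 1e12. Rate constants above 1e9 s⁻¹ are
rejected as outside the propagator's validated range. An independent
high-accuracy ODE integration path (`propagate_ode`, DOP853 at rtol 1e-12)
exists solely for validation and is kept free of the eigendecomposition code.

**R1ρ extraction.** The equilibrium populations are tilted along an effective
field, propagated for five evenly spaced delays (default 0–60 ms), projected
onto the initial axis, and reduced to a rate by a log-linear fit — the same
pipeline the experiment applies to peak intensities, so simulated and
"measured" data go through identical reductions.

**Initial alignment rule.** For k_ex/|Δω| ≥ 5 (fast exchange) the
population-average magnetization is tilted along the average effective field;
below 5 the ground-state magnetization is tilted along the ground-state
effective field. The threshold is a documented default: in both regimes the
alternative choice changes R1ρ by under 1% of the exchange contribution
(property-tested), so the rule's exact cutoff is not critical. The
trigonometric no-exchange limit R1·cos²θ + R2·sin²θ is exact only to leading
order in (R2−R1)/ω_eff; the simulator reproduces it to ~1e-5 relative at
typical effective fields, which is the tolerance the tests use.

**CEST and B1 inhomogeneity.** Saturation is applied for a 100 ms delay
(default) over offsets spanning ±6 ppm and fields of 10–1000 Hz. The B1
distribution is modeled as Gaussian with relative SD 0.10 and averaged in two
complementary ways: a 5-node Gauss–Hermite quadrature captures the smooth
dependence of saturation efficiency on B1, and each oscillatory eigenmode is
additionally damped by exp(−Δφ²/2) with Δφ = σ·t·ω₁²/ω_eff, the first-order
phase spread of that mode across the continuous distribution. A small-node
quadrature alone cannot represent the dephasing of coherent on-resonance
nutation (the discrete cosine comb never converges); the analytic damping
fixes this and was verified against brute-force 401-point continuous
averaging (maximum deviation 7.6e-4 in normalized intensity over a full
two-field grid).

## Fitting

All fits are weighted least squares with 1/SD² weights (unit weight, with a
warning, where SDs are missing), using `scipy.optimize.least_squares` (TRF)
with rates and populations transformed (log, and logit scaled to (0, 0.5) for
the minor population) so bounds are enforced smoothly.

**Two-state global fits** share (k_ex, p) across probes with per-probe
(Δω, R1, R2). Start points are screened before optimization: for each
(k_ex, p) candidate on a log-spaced ladder (k_ex ∈ [50, 5e4] s⁻¹,
p ∈ [1e-4, 0.3]), each probe's starting Δω is chosen independently — the χ²
decomposes across probes at fixed shared parameters — from a candidate set
containing the Rex-centroid estimate and generic magnitudes of both signs,
by direct evaluation. Only the best-ranked combined starts receive full
optimizer runs; ties break by start index. This screening is what makes the
fits reliable in the weak-exchange regime, where the Δω sign and the
slow-exchange (small k_ex, inflated p) basin are the dominant failure modes.
High-pH datasets with negligible exchange contribution still return poorly
determined parameters — as they must — but their large Monte Carlo SDs
downweight them correctly in downstream weighted fits.

**Monte Carlo uncertainties** are parametric: data are resampled from
Normal(best-fit prediction, reported SD) and refitted warm-started from the
best fit; the SD of each parameter across iterations is reported. Iterations
that fail to converge are dropped, and a result with >20% drops is flagged. A
residual-bootstrap variant is not provided; parametric resampling is the
documented default.

**The constrained three-state fit** (GS ⇌ GS⁺ ⇌ ES2⁺, linear topology) pins
the protonation step: k_ex,prot = k_prot([H⁺] + 10^(−pKa_GS)) with
k_prot = 6e11 M⁻¹s⁻¹ (diffusion-limited; 7e11 appears elsewhere in the
source literature and can be passed explicitly) and pKa_GS = 4.0. State
populations at each pH follow the Henderson–Hasselbalch fraction at pKa_GS
for GS⁺ and the apparent pKa (default 4.0) for ES2⁺. Free parameters: one
k_ex,conf shared over probes and pH, plus per-probe GS⁺ and ES2⁺ shift
offsets and (R1, R2) shared across pH within the dataset (whether the
original analysis shared relaxation rates across pH is unstated; sharing is
this implementation's choice and is exposed per dataset). ES2⁺ shift offsets
start from per-probe two-state fits of the lowest-pH (largest-Rex) profiles,
GS⁺ offsets from zero. A pinned protonation rate slower than the fitted
conformational rate is flagged as a mechanism inversion, not an error.

**CEST fits** free (p, k_ex, Δω, R1, R2) or pin the exchange parameters to
zero (null model); parameter SEMs come from the diagonal of (JᵀJ)⁻¹ of the
weighted fit. Model selection uses AIC = χ² + 2k and BIC = χ² + k·ln n on
the weighted-χ² scale, converted to Akaike/Bayes weights. Note the
calibration of the 50%-weight decision: under a no-exchange truth the
with-exchange fit gains a ~χ²₃-distributed amount of χ² (three effectively
extra parameters, with the population bounded at zero), so "exchange wins
the Akaike weight" has a false-positive rate near 5–10%; demanding
wAIC(null) > 0.7 instead fails a genuine null ~20% of the time. The
package therefore treats the larger weight as the model call.

**pH-series fits** of the five-state model hold the ES1 pair fixed
(K_conf = 0.01, pKa = 7.5 by default) and float (K_conf^ES2, pKa^ES2) from a
multi-start grid (pKa 4–9 step 0.5 × log₁₀K_conf −5–1). The degeneracy scan
profiles χ² along a pKa grid, refitting only K_conf^ES2, and reports the
Δχ² ≤ 1 band. That band is a 1σ (≈68%) interval for one profiled parameter —
its measured coverage at 10% noise is 67/100 — and the lower edge is the
"pKa ≥ x" bound; the upper side is reported as open when the band reaches
the grid edge, which is the typical outcome because pKa and K_conf
compensate along the apparent-pKa direction.

## Thermodynamic conventions

[H⁺] = 10^(−pH) exactly (bulk-solution activity scale); Hill coefficient
fixed at 1; T = 298.15 K; R = 1.987204e-3 kcal mol⁻¹ K⁻¹ so penalties come
out in kcal/mol. With the published rounded parameters the five-state penalty
is monotone in pH: it falls from the −RT ln K_conf ≈ 4.15 kcal/mol neutral
plateau toward a floor of ≈2.0 kcal/mol under acid, where the competing
protonated ES1 absorbs the ensemble — a floor, not an interior dip. The
chemical-shift-perturbation population estimate uses the unweighted mean of
per-probe |Δδ_obs|/|Δδ_ref| ratios clipped to [0, 1]; other weighting
conventions exist and give different numbers, so the convention is part of
the reported value.

## Kinetic simulation

The 3×3 rate matrix over (ES1⁺, GS, ES2⁺) has columns summing to zero;
eigendecomposition propagates it, with the conserved mode detected relative
to the matrix norm (an absolute zero-test fails for stiff matrices whose
"zero" eigenvalue carries ‖K‖·ε rounding) and snapped to exactly zero. The
simulation window extends automatically until |dP/dt| < 1e-6 s⁻¹ — at
k_ex ≈ 500 s⁻¹ equilibrium needs ~10 ms, so short fixed windows are
extended rather than trusted. Apparent (p_minor, k_ex) come from a
mono-exponential fit of the ES2⁺ channel; a Wald–Wolfowitz runs test on the
residual signs flags visibly multi-exponential traces.

Mechanism predictions follow the standard limiting forms (for example
CS^prot: k_forward = [K_conf/(K_conf+1)]·k_prot·[H⁺], k_reverse = k_deprot).
Classification is by decision rules — pH-flat forward rate → CS^conf;
diffusion-limited slope (1e10–1e11 M⁻¹s⁻¹) → IF^prot; sub-diffusion slope
with pH-flat reverse → CS^prot or IF^conf, separated by the forward-rate
solvent isotope effect. CS^prot with K_conf approaching 1 is genuinely
indistinguishable from IF^prot by slope alone; the classifier does not
pretend otherwise.

## Synthetic data

Generators are pure functions of (truth, scheme, noise, seed): identical
inputs give bit-identical tables, zero noise returns the forward model
exactly, and SD columns record the applied noise so refit χ² is calibrated
near 1. Defaults emulate the study's conditions: minor populations 0.1–2%
over pH 5.4–7.4 from the five-state model, k_ex of ~500–900 s⁻¹ from
k_on[H⁺] + k_off, Δω up to a few ppm at 600–900 MHz fields, 2% relative
noise on R1ρ and 0.01 absolute noise on normalized CEST intensity. Spin-lock
grids use powers of ~100–1200 Hz with offsets spanning ±3× the power;
identifiability of (k_ex, p) in the weak-exchange regime requires the denser
low-power offset sampling (7–9 offsets per power) the defaults provide —
coarser grids leave the slow-exchange basin competitive and were the main
failure mode found during development. What the generators do not emulate:
spectral overlap, peak picking, phase/baseline artifacts, field-dependent R2,
temperature drift, or Hartmann–Hahn transfer losses — so passing recovery
suites demonstrate statistical correctness of the analysis chain, not
robustness to spectral pathology.

## Problem sizes in the test suite

The statistical acceptance checks run at sizes chosen to keep the full suite
in single-digit minutes while retaining power: simulator-versus-ODE
equivalence on 100 random models; Monte Carlo coverage with 20 seeded
repeats × 120 MC iterations, three probes × 28 grid points; the five-pH
kinetics recovery with two probes × 36 points per pH and 60 MC iterations;
three-state recovery with two probes × 12 points × five pH; CEST model
selection with 30 simulations per truth on a 2-field × 25-offset grid.
All randomness is seeded, so results are reproducible run to run.

## Known limitations

- Two excited states at most; no Hill n ≠ 1 cooperativity, ionic-strength or
  temperature dependence.
- The B1-inhomogeneity damping is first-order in the eigenvalue's B1
  dependence; for extreme inhomogeneity (σ ≫ 10%) use more quadrature nodes.
- Model-weight calibration is asymptotic; for very small CEST grids the
  χ²-penalty accounting in AIC/BIC becomes approximate.
- The apparent-pKa direction is intrinsically degenerate in (pKa, K_conf);
  only the combination, the lower pKa bound, and externally fixed parameters
  are reliably recoverable from population-versus-pH data alone.
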