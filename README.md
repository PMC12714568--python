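# protonex

Proton-coupled conformational exchange in RNA: Bloch–McConnell simulation and
fitting of R1ρ relaxation-dispersion and CEST profiles, multi-state
thermodynamic models of excited-state populations versus pH, explicit
rate-matrix kinetic simulation, and discrimination of induced-fit versus
conformational-selection protonation mechanisms.

## Who this is for

NMR spectroscopists and RNA biophysicists characterizing lowly populated,
short-lived "excited" conformational states (ESs) whose formation is coupled
to nucleobase protonation — for example an ES stabilized by a protonated
C⁺–C mismatch. Such states can sit at 0.1–2% population with exchange rates of
10²–10⁴ s⁻¹ and apparent pKa values depressed far below the experimental pH
window, which makes every stage of the analysis (forward simulation, global
fitting, thermodynamic decomposition, kinetic mechanism assignment)
statistically delicate. The package implements that full chain with seeded
synthetic-data generators, so each stage is testable end to end without any
measured spectra.

## The models

**Exchange observables.** The magnetization of an N-site exchanging spin
system evolves under the Bloch–McConnell equations, d**M**/dt = L **M**, with
L the 3N×3N matrix combining rotating-frame precession (site offsets Ω_i),
the irradiation field ω₁, relaxation (R1, R2 shared across sites), and
first-order exchange. R1ρ is extracted the way the experiment measures it:
tilt the equilibrium magnetization along the effective field, propagate for
five evenly spaced delays, project back onto the initial axis, and fit a
mono-exponential. CEST profiles evolve z-magnetization under saturation for a
fixed delay over a grid of offsets and B1 fields, averaging over B1
inhomogeneity.

**Thermodynamics.** A five-state scheme
ES1⁺ ⇌ ES1 ⇌ GS ⇌ ES2 ⇌ ES2⁺ links two excited states to the ground state
through conformational equilibrium constants K_conf = [ES]/[GS] and to their
protonated forms through intrinsic pKa values (Hill n = 1,
[H⁺] = 10^(−pH)). The measured apparent pKa of a proton-coupled transition is

    pKa_apparent = pKa_intrinsic + log10(K_conf)

and the apparent ES2 population (neutral + protonated, which is what the NMR
probes report) is

    p_ES2(pH) = K₂(1 + 10^(pKa₂−pH)) / [1 + K₁(1 + 10^(pKa₁−pH)) + K₂(1 + 10^(pKa₂−pH))]

The free-energy penalty any process selecting ES2 must pay is
ΔG_penalty = −RT ln p_ES2.

**Kinetics.** The three-species scheme ES1⁺ ⇌ GS ⇌ ES2⁺ is solved by
diagonalizing its 3×3 rate matrix; the slow species' approach to equilibrium
is reduced to apparent two-state observables (p_minor, k_ex) by a
mono-exponential fit. The pH dependence of k_forward = k_on[H⁺] and
k_reverse = k_off, solvent kinetic isotope effects, and fold-change
predictions for equilibrium-shifting mutations together discriminate the four
limiting mechanisms (CS/IF × protonation/conformational rate-limiting).

## A worked example

```
$ python examples/ph_thermodynamics.py
pH    apparent p_ES2   penalty (kcal/mol)
5.4      1.987%        2.32
6.0      0.914%        2.78
6.4      0.474%        3.17
7.0      0.195%        3.70

apparent pKa = intrinsic 7.1 + log10(K_conf) = 4.05
protonated ES2 fraction at pH 6.4: 83%
minimum penalty over pH 2-5.4: 1.99 kcal/mol (floored by the competing protonated ES1)

noiseless refit: pKa = 7.10, K_conf = 9.00e-04 (truth 7.10, 9.00e-04)
```

At the best-fit parameters the apparent ES2 population rises ~10-fold from
pH 7.0 to pH 5.4 while the competing protonated ES1 keeps the low-pH
formation penalty near 2 kcal/mol instead of letting it fall to zero; the
intrinsic pKa of 7.1 is depressed to an apparent 4.05 by the ~4 kcal/mol
conformational penalty. The other scripts in `examples/` cover R1ρ profile
simulation, global two-state fitting with Monte Carlo errors, CEST model
selection, kinetic mechanism discrimination, and the end-to-end pipeline.

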