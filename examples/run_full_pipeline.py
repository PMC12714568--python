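"""End-to-end analysis of a synthetic multi-pH R1rho dataset.

Generates a four-pH, two-probe dataset from the published thermodynamic and
kinetic truths, writes it as a tab-separated table, and runs the pipeline:
per-pH global two-state fits, pH-series assembly, the five-state thermodynamic
fit with a pKa degeneracy scan, and the pH-linear kinetic fit with a mechanism
call.  All outputs land in ``pipeline_out/``.
"""

from pathlib import Path

import pandas as pd

import protonex as px

out = Path("pipeline_out")
out.mkdir(exist_ok=True)

thermo_truth = px.ThermoParams()
kon, koff = 8.2e6, 490.0
probes = {px.Probe("U38-N3", 91.2): -2.0, px.Probe("U23-C6", 226.3): 2.5}
relax = px.RelaxParams(2.0, 20.0)
grid = px.default_spinlock_grid((100.0, 200.0, 400.0, 900.0), 7, 3.0)

frames = []
for i, ph in enumerate((5.4, 6.0, 6.4, 7.0)):
    p = float(px.population_es2(ph, thermo_truth))
    kex = kon * 10.0**-ph + koff
    for j, (probe, dw) in enumerate(probes.items()):
        model = px.two_state(p, kex, dw)
        frames.append(px.gen_r1rho_dataset(model, relax, [probe], grid,
                                           px.NoiseModel(0.02, 300 + 10 * i + j),
                                           ph=ph))
px.write_profile_table(pd.concat(frames, ignore_index=True),
                       out / "r1rho.tsv", "r1rho")

config = px.AnalysisConfig(
    r1rho_path=str(out / "r1rho.tsv"), outdir=str(out / "run"),
    ph_values=[5.4, 6.0, 6.4, 7.0], mc_iter=40, n_starts=3, seed=7,
)
report = px.run_pipeline(config)

print("thermodynamics:")
print(f"  apparent pKa = {report['thermo']['apparent_pka']:.2f} "
      "(truth 4.05; the pKa/K_conf pair is individually degenerate,")
print("   the apparent pKa they imply is what the data pin down)")
print(f"  intrinsic pKa lower bound = {report['thermo']['pka_lower_bound']:.1f}")
print("kinetics:")
print(f"  k_on = {report['kinetics']['kon']:.2e} /M/s, "
      f"k_off = {report['kinetics']['koff']:.0f} /s, "
      f"mechanism call: {report['kinetics']['mechanism']}")
print("  (k_on sits below the generator's 8.2e6 because the competing ES1")
print("   branch suppresses the apparent forward rate at low pH, the same")
print("   deviation from linearity the real measurements show)")
print(f"\nall intermediates are in {out / 'run'}")
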