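"""End-to-end analysis: per-pH two-state fits -> pH-dependent populations ->
thermodynamic model fit and pKa degeneracy scan -> pH-linear kinetics and
mechanism report.

Each stage writes its intermediate table or report into the output directory
before the next stage runs, so a failing stage leaves everything before it on
disk; the resolved configuration and the seeds in use are always recorded.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import fit_two_state_global
from .kinetics import classify_mechanism, fit_proton_linear
from .tables import (
    AnalysisConfig,
    PHSERIES_COLUMNS,
    phseries_to_points,
    read_profile_table,
    write_profile_table,
)
from .thermo import ThermoParams, apparent_pka, fit_ph_series, pka_degeneracy_scan

log = logging.getLogger("protonex.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; outputs of earlier stages were kept."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full analysis described by ``config`` and return the report dict.

    Stages: (1) global two-state fit of the R1rho table at each pH, sharing
    k_ex and p across probes, with Monte Carlo SDs; (2) assembly of the
    pH-dependent apparent population series; (3) weighted fit of the
    five-state thermodynamic model plus a pKa degeneracy scan; (4) weighted
    pH-linear fits of k_forward/k_reverse and a mechanism classification.
    All numeric outputs are deterministic for a fixed config.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_file(outdir / "resolved_config.txt")
    log.info("run seeded with %d; outputs in %s", config.seed, outdir)

    stage = "two_state_fits"
    try:
        data = read_profile_table(config.r1rho_path, "r1rho")
        fit_rows = []
        ph_rows = []
        for i, ph in enumerate(config.ph_values):
            sub = data[np.isclose(data["ph"], ph)]
            if sub.empty:
                raise ValueError(f"no rows at pH {ph}")
            fr = fit_two_state_global(
                sub,
                n_starts=config.n_starts,
                mc_iter=config.mc_iter,
                seed=config.seed + i,
            )
            log.info(
                "pH %.2f: chi2=%.3f (start %d) kex=%.1f p=%.4f",
                ph, fr.chi2, fr.start_index, fr.params["kex"], fr.params["p"],
            )
            row = {"ph": ph, "rchi2": fr.reduced_chi2, "converged": fr.converged}
            for k, v in fr.params.items():
                row[k] = v
                row[k + "_sd"] = fr.sds.get(k, 0.0)
            fit_rows.append(row)
            ph_rows.append(
                {"ph": ph, "p_es2": fr.params["p"], "sd": fr.sds.get("p") or None}
            )
        pd.DataFrame(fit_rows).to_csv(outdir / "two_state_fits.tsv", sep="\t",
                                      index=False, na_rep="NA")
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError(stage, e) from e

    stage = "ph_series"
    try:
        series = pd.DataFrame(ph_rows, columns=PHSERIES_COLUMNS)
        keep = ~series["ph"].isin(config.exclude_ph)
        series = series[keep].reset_index(drop=True)
        write_profile_table(series, outdir / "ph_series.tsv", "phseries")
        points = phseries_to_points(series)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "thermo_fit"
    try:
        fixed = ThermoParams(kconf_es1=config.kconf_es1, pka_es1=config.pka_es1)
        tf = fit_ph_series(points, fixed=fixed)
        pka_grid = np.arange(
            config.pka_scan_start, config.pka_scan_stop + 1e-9, config.pka_scan_step
        )
        scan = pka_degeneracy_scan(points, pka_grid, fixed=fixed)
        app_pka = apparent_pka(tf.params["pka_es2"], tf.params["kconf_es2"])
        _write_kv(
            outdir / "thermo_fit.txt",
            {
                "pka_es2": tf.params["pka_es2"],
                "pka_es2_sd": tf.sds["pka_es2"],
                "kconf_es2": tf.params["kconf_es2"],
                "kconf_es2_sd": tf.sds["kconf_es2"],
                "apparent_pka": app_pka,
                "reduced_chi2": tf.reduced_chi2 if tf.n_points > tf.n_params else "NA",
                "pka_lower_bound": scan["pka_lower_bound"],
            },
        )
        pd.DataFrame({"pka": scan["pka_grid"], "chi2": scan["chi2"]}).to_csv(
            outdir / "pka_degeneracy.tsv", sep="\t", index=False
        )
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "kinetics"
    try:
        kin_points = []
        for row in fit_rows:
            if row["ph"] in config.exclude_ph:
                continue
            kf = row["p"] * row["kex"]
            kr = (1.0 - row["p"]) * row["kex"]
            # first-order error propagation from the MC SDs
            kf_sd = float(np.hypot(row["kex"] * row["p_sd"], row["p"] * row["kex_sd"]))
            kr_sd = float(np.hypot(row["kex"] * row["p_sd"],
                                   (1 - row["p"]) * row["kex_sd"]))
            kin_points.append((row["ph"], kf, kf_sd or 1.0, kr, kr_sd or 1.0))
        kin = fit_proton_linear(kin_points)
        mechanism = classify_mechanism(kin_points)
        _write_kv(
            outdir / "kinetics_fit.txt",
            {
                "kon": kin["kon"],
                "kon_sd": kin["kon_sd"],
                "koff": kin["koff"],
                "koff_sd": kin["koff_sd"],
                "mechanism": mechanism,
            },
        )
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    report = {
        "two_state": fit_rows,
        "ph_series": series.to_dict("records"),
        "thermo": {
            "pka_es2": tf.params["pka_es2"],
            "kconf_es2": tf.params["kconf_es2"],
            "apparent_pka": app_pka,
            "pka_lower_bound": scan["pka_lower_bound"],
        },
        "kinetics": {**{k: kin[k] for k in ("kon", "kon_sd", "koff", "koff_sd")},
                     "mechanism": mechanism},
        "seed": config.seed,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report


def _write_kv(path: Path, mapping: dict) -> None:
    path.write_text("".join(f"{k} = {v}\n" for k, v in mapping.items()))
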