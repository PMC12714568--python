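"""Seeded synthetic-data generators.

These generators stand in for the NMR measurements the analyses consume: R1rho
profile tables over spin-lock power/offset grids, CEST intensity grids, and
pH-dependent excited-state population series.  Each is a pure function of
(truth, scheme, noise, seed): the same inputs reproduce the same table bit for
bit, and zero noise returns the forward model exactly.

Default acquisition grids mirror typical aromatic-carbon / imino-nitrogen
relaxation-dispersion practice: spin-lock powers of a few hundred to a few
thousand Hz with offsets out to a few multiples of the power, and CEST
saturation fields of 10-1000 Hz scanned over +/-6 ppm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exchange import (
    CESTScheme,
    ExchangeModel,
    Probe,
    RelaxParams,
    simulate_cest,
    simulate_r1rho_grid,
)
from .thermo import PHPopulationPoint, ThermoParams, population_es2


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian measurement noise.

    ``sigma`` is a relative SD for R1rho values and an absolute SD for
    normalized CEST intensities.  ``sigma = 0`` reproduces the forward model
    exactly; a fixed seed reproduces the noise draw exactly.
    """

    sigma: float = 0.0
    seed: int | None = None
    kind: str = "gaussian"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.kind != "gaussian":
            raise ValueError("only gaussian noise is supported")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def default_spinlock_grid(
    powers_hz: Sequence[float] = (150.0, 300.0, 600.0, 1200.0),
    offsets_per_power: int = 5,
    max_offset_factor: float = 3.0,
) -> list[tuple[float, float]]:
    """(power, offset) pairs with offsets spanning +/- a multiple of each power."""
    grid = []
    for p in powers_hz:
        for off in np.linspace(-max_offset_factor * p, max_offset_factor * p,
                               offsets_per_power):
            # strictly on-resonance points carry no tilt information; nudge
            grid.append((float(p), float(off) if off != 0 else 1e-6))
    return grid


def gen_r1rho_dataset(
    truth: ExchangeModel,
    relax: RelaxParams,
    probes: Sequence[Probe],
    scheme_grid: Sequence[tuple[float, float]],
    noise: NoiseModel,
    ph: float = 6.4,
) -> pd.DataFrame:
    """Simulate an R1rho profile table over the given (power, offset) grid.

    Returns the standard columns ``[probe, field_mhz, ph, power_hz, offset_hz,
    r1rho, r1rho_sd]``; the SD column records the applied relative noise so
    that downstream weighted refits have calibrated chi^2.
    """
    if len(scheme_grid) == 0:
        raise ValueError("scheme grid is empty")
    rng = noise.rng()
    rows = []
    powers = np.array([g[0] for g in scheme_grid], dtype=float)
    offsets = np.array([g[1] for g in scheme_grid], dtype=float)
    for probe in probes:
        vals = simulate_r1rho_grid(truth, relax, probe, powers, offsets)
        sds = noise.sigma * vals
        obs = vals + rng.normal(0.0, 1.0, size=vals.shape) * sds if noise.sigma > 0 else vals
        for pw, off, v, s in zip(powers, offsets, obs, sds):
            rows.append(
                {
                    "probe": probe.name,
                    "field_mhz": probe.larmor_mhz,
                    "ph": ph,
                    "power_hz": pw,
                    "offset_hz": off,
                    "r1rho": float(v),
                    "r1rho_sd": float(s),
                }
            )
    return pd.DataFrame(rows)


def gen_cest_profile(
    truth: ExchangeModel,
    relax: RelaxParams,
    probe: Probe,
    scheme: CESTScheme,
    noise: NoiseModel,
    ph: float = 6.4,
) -> pd.DataFrame:
    """Simulate a CEST grid table with absolute Gaussian intensity noise."""
    grid = simulate_cest(truth, relax, probe, scheme)
    rng = noise.rng()
    obs = grid + rng.normal(0.0, noise.sigma, size=grid.shape) if noise.sigma > 0 else grid
    rows = []
    for i, b1 in enumerate(scheme.b1_hz):
        for j, off in enumerate(scheme.offsets_ppm):
            rows.append(
                {
                    "probe": probe.name,
                    "field_mhz": probe.larmor_mhz,
                    "ph": ph,
                    "b1_hz": float(b1),
                    "offset_ppm": float(off),
                    "intensity": float(obs[i, j]),
                    "intensity_sd": float(noise.sigma),
                }
            )
    return pd.DataFrame(rows)


def gen_ph_population_series(
    truth: ThermoParams,
    ph_values: Sequence[float],
    relative_noise: float = 0.0,
    seed: int | None = None,
    include_es1: bool = True,
) -> list[PHPopulationPoint]:
    """Apparent ES2 populations at the given pH values, perturbed multiplicatively.

    SDs are set to ``relative_noise * value`` so the generated series carries the
    weights its own refits expect.
    """
    if len(ph_values) == 0:
        raise ValueError("ph_values is empty")
    rng = np.random.default_rng(seed)
    pts = []
    for ph in ph_values:
        p = float(population_es2(float(ph), truth, include_es1=include_es1))
        sd = relative_noise * p
        obs = p * (1.0 + rng.normal(0.0, relative_noise)) if relative_noise > 0 else p
        pts.append(PHPopulationPoint(ph=float(ph), p_es2=float(max(obs, 1e-12)),
                                     sd=sd if sd > 0 else None))
    return pts
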