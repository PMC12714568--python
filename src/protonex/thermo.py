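"""Proton-coupled thermodynamics of competing RNA excited states.

A five-state scheme ES1+ <-> ES1 <-> GS <-> ES2 <-> ES2+ links two alternative
secondary structures (ES1, ES2) to the neutral ground state through conformational
equilibrium constants K_conf and to their protonated forms through intrinsic pKa
values, assuming a Hill coefficient of 1 and [H+] = 10^-pH (activity scale).  The
apparent pKa of the overall GS -> ES+ transition is the intrinsic pKa lowered by
the conformational penalty, pKa_app = pKa + log10(K_conf).

The module provides the population and free-energy-penalty curves versus pH,
weighted least-squares fitting of measured pH series, a profile-likelihood
degeneracy scan for the intrinsic pKa, and a chemical-shift-perturbation
population estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .fitting import FitResult

#: gas constant in kcal mol^-1 K^-1
R_KCAL = 1.987204e-3


def _pow10(x):
    """10**x with the exponent clipped to +/-150 (ratios saturate safely)."""
    return 10.0 ** np.clip(x, -150.0, 150.0)


@dataclass(frozen=True)
class ThermoParams:
    """Parameters of the five-state proton-coupled thermodynamic model.

    ``kconf_es1``/``kconf_es2`` are the conformational equilibrium constants
    [ES]/[GS] of the neutral excited states; ``pka_es1``/``pka_es2`` their
    intrinsic pKa values.  ``hill_n`` is fixed at 1 (single-proton binding).
    """

    kconf_es1: float = 0.01
    pka_es1: float = 7.5
    kconf_es2: float = 0.9e-3
    pka_es2: float = 7.1
    hill_n: float = 1.0
    temperature_k: float = 298.15

    def __post_init__(self) -> None:
        if self.kconf_es2 <= 0 or (self.kconf_es1 < 0):
            raise ValueError("conformational equilibrium constants must be positive")
        if self.temperature_k <= 0:
            raise ValueError("temperature must be positive")


def apparent_pka(pka_intrinsic: float, kconf: float) -> float:
    """Apparent pKa of a proton-coupled conformational transition.

    The midpoint of the overall GS -> ES+ transition: the intrinsic pKa of the
    excited state shifted by the conformational penalty, pKa + log10(K_conf).
    """
    if kconf <= 0:
        raise ValueError("K_conf must be positive")
    return pka_intrinsic + np.log10(kconf)


def protonated_fraction(pka: float, ph: float) -> float:
    """Henderson-Hasselbalch protonated fraction 10^(pKa-pH)/(1+10^(pKa-pH))."""
    r = 10.0 ** (np.asarray(pka) - np.asarray(ph))
    return r / (1.0 + r)


def state_fractions(ph: float | np.ndarray, params: ThermoParams) -> dict[str, np.ndarray]:
    """Equilibrium fractions of all five states (GS, ES1, ES1+, ES2, ES2+)."""
    ph = np.asarray(ph, dtype=float)
    r1 = _pow10(params.hill_n * (params.pka_es1 - ph))
    r2 = _pow10(params.hill_n * (params.pka_es2 - ph))
    terms = {
        "GS": np.ones_like(ph),
        "ES1": params.kconf_es1 * np.ones_like(ph),
        "ES1+": params.kconf_es1 * r1,
        "ES2": params.kconf_es2 * np.ones_like(ph),
        "ES2+": params.kconf_es2 * r2,
    }
    z = sum(terms.values())
    return {k: v / z for k, v in terms.items()}


def population_es2(
    ph: float | np.ndarray,
    params: ThermoParams,
    include_es1: bool = True,
) -> float | np.ndarray:
    """Apparent ES2 population (neutral + protonated) at the given pH.

    With ``include_es1`` the denominator carries all five states; without it the
    competing ES1/ES1+ pair is dropped (the three-state form appropriate for the
    mutant that eliminates ES1).
    """
    ph = np.asarray(ph, dtype=float)
    r2 = _pow10(params.hill_n * (params.pka_es2 - ph))
    num = params.kconf_es2 * (1.0 + r2)
    den = 1.0 + num
    if include_es1:
        r1 = _pow10(params.hill_n * (params.pka_es1 - ph))
        den = den + params.kconf_es1 * (1.0 + r1)
    out = num / den
    return float(out) if out.ndim == 0 else out


def penalty(
    ph: float | np.ndarray,
    params: ThermoParams,
    include_es1: bool = True,
) -> float | np.ndarray:
    """Free-energy penalty -RT ln(apparent p_ES2) in kcal/mol.

    The cost any process selecting ES2 must pay at the given pH; infinite (with
    a warning) when the apparent population vanishes.
    """
    p = np.asarray(population_es2(ph, params, include_es1=include_es1))
    rt = R_KCAL * params.temperature_k
    with np.errstate(divide="ignore"):
        g = -rt * np.log(p)
    if np.any(p <= 0):
        warnings.warn("zero ES2 population: penalty is infinite", stacklevel=2)
    return float(g) if g.ndim == 0 else g


# ---------------------------------------------------------------------------
# pH-series fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PHPopulationPoint:
    """One measured apparent ES2 population at a given pH."""

    ph: float
    p_es2: float
    sd: float | None = None


def _series_arrays(points: Sequence[PHPopulationPoint]):
    ph = np.array([p.ph for p in points], dtype=float)
    y = np.array([p.p_es2 for p in points], dtype=float)
    sd = np.array(
        [p.sd if (p.sd is not None and p.sd > 0) else np.nan for p in points],
        dtype=float,
    )
    if np.isnan(sd).any():
        warnings.warn("pH points without SDs received unit weight", stacklevel=3)
    w = np.where(np.isnan(sd), 1.0, 1.0 / sd**2)
    return ph, y, np.sqrt(w)


_FREE_DEFAULT = ("kconf_es2", "pka_es2")


def fit_ph_series(
    points: Sequence[PHPopulationPoint],
    fixed: ThermoParams | None = None,
    free: Sequence[str] = _FREE_DEFAULT,
    include_es1: bool = True,
    pka_grid: np.ndarray | None = None,
    log10_kconf_grid: np.ndarray | None = None,
) -> FitResult:
    """Weighted least-squares fit of the pH-dependent apparent ES2 population.

    ``fixed`` supplies every parameter not being fitted (by default the ES1 pair
    is held and (K_conf^ES2, pKa^ES2) float).  A multi-start grid over pKa in
    [4, 9] (step 0.5) crossed with log10 K_conf in [-5, 1] guards against local
    minima; the lowest-chi^2 start wins.  A series with no usable pH contrast is
    flagged ``"degenerate-series"`` and its SDs inflated.
    """
    if len(points) < 3:
        raise ValueError("need at least three pH points")
    base = fixed if fixed is not None else ThermoParams()
    for name in free:
        if name not in ("kconf_es1", "pka_es1", "kconf_es2", "pka_es2"):
            raise ValueError(f"cannot free unknown parameter {name!r}")
    ph, y, sqw = _series_arrays(points)

    log_scaled = {name: name.startswith("kconf") for name in free}

    def apply(x: np.ndarray) -> ThermoParams:
        kw = {}
        for name, xi in zip(free, x):
            kw[name] = float(_pow10(xi)) if log_scaled[name] else float(np.clip(xi, -20.0, 30.0))
        return replace(base, **kw)

    def residuals(x: np.ndarray) -> np.ndarray:
        p = population_es2(ph, apply(x), include_es1=include_es1)
        return (p - y) * sqw

    pka_grid = np.arange(4.0, 9.01, 0.5) if pka_grid is None else np.asarray(pka_grid)
    lk_grid = (
        np.arange(-5.0, 1.01, 1.0)
        if log10_kconf_grid is None
        else np.asarray(log10_kconf_grid)
    )

    def starts():
        has_pka = any(n.startswith("pka") for n in free)
        has_k = any(n.startswith("kconf") for n in free)
        pk_vals = pka_grid if has_pka else [None]
        lk_vals = lk_grid if has_k else [None]
        for pk in pk_vals:
            for lk in lk_vals:
                x0 = []
                for name in free:
                    if name.startswith("pka"):
                        x0.append(pk if pk is not None else getattr(base, name))
                    else:
                        x0.append(
                            lk if lk is not None else np.log10(getattr(base, name))
                        )
                yield np.array(x0, dtype=float)

    best = None
    for i, x0 in enumerate(starts()):
        sol = least_squares(residuals, x0, method="lm", max_nfev=200)
        chi2 = float(sol.cost * 2)
        if best is None or chi2 < best[0] - 1e-12:
            best = (chi2, i, sol)
    chi2, start_idx, sol = best

    fitted = apply(sol.x)
    params = {name: getattr(fitted, name) for name in free}
    # covariance-based SDs (delta method through the log transform)
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac)
        raw_sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        raw_sd = np.full(len(free), np.nan)
    sds = {}
    for name, xi, si in zip(free, sol.x, raw_sd):
        sds[name] = float(si * 10.0**xi * np.log(10.0)) if log_scaled[name] else float(si)

    flags = []
    if np.ptp(y) < 1e-12 or not np.all(np.isfinite(raw_sd)):
        flags.append("degenerate-series")
        sds = {k: (v if np.isfinite(v) else 0.0) * 10.0 + 10.0 for k, v in sds.items()}

    return FitResult(
        params=params,
        sds=sds,
        chi2=chi2,
        n_points=len(points),
        n_params=len(free),
        converged=bool(sol.success),
        start_index=start_idx,
        flags=flags,
    )


def pka_degeneracy_scan(
    points: Sequence[PHPopulationPoint],
    pka_grid: Sequence[float],
    fixed: ThermoParams | None = None,
    include_es1: bool = True,
) -> dict[str, object]:
    """Profile the fit chi^2 along a grid of intrinsic ES2 pKa values.

    For each grid pKa only K_conf^ES2 is refitted.  Returns the chi^2 profile,
    the lowest grid pKa whose chi^2 stays within min(chi^2) + 1 (the 1-sigma
    lower bound for one profiled parameter), and whether the band is still open
    at the upper grid edge.
    """
    base = fixed if fixed is not None else ThermoParams()
    grid = np.asarray(pka_grid, dtype=float)
    chi2 = np.empty(grid.size)
    for i, pk in enumerate(grid):
        fr = fit_ph_series(
            points,
            fixed=replace(base, pka_es2=float(pk)),
            free=("kconf_es2",),
            include_es1=include_es1,
        )
        chi2[i] = fr.chi2
    cmin = float(chi2.min())
    inside = chi2 <= cmin + 1.0
    lower = float(grid[inside][0])
    upper = float(grid[inside][-1])
    upper_open = bool(inside[-1])
    return {
        "pka_grid": grid,
        "chi2": chi2,
        "pka_best": float(grid[int(np.argmin(chi2))]),
        "pka_lower_bound": lower,
        "pka_upper_bound": upper,
        "upper_open": upper_open,
    }


def csp_population(
    observed_shifts: Mapping[str, float],
    reference_shifts: Mapping[str, float],
) -> float:
    """Population of a protonated species from chemical-shift perturbations.

    Each probe contributes |observed shift change| / |full protonation shift
    change| clipped to [0, 1]; the unweighted mean across probes is returned.
    """
    missing = set(observed_shifts) - set(reference_shifts)
    if missing:
        raise KeyError(f"no reference shift for probes: {sorted(missing)}")
    fracs = []
    for name, obs in observed_shifts.items():
        ref = reference_shifts[name]
        if ref == 0:
            raise ValueError(f"reference shift for {name!r} is zero")
        fracs.append(min(abs(obs) / abs(ref), 1.0))
    return float(np.mean(fracs))
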