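"""Inverse problems: global two-state fits of R1rho profiles, the constrained
three-state (GS <-> GS+ <-> ES2+) fit, CEST fits with model selection, and Monte
Carlo parameter uncertainties.

Profile tables are plain pandas DataFrames.  R1rho tables carry the columns
``[probe, field_mhz, ph, power_hz, offset_hz, r1rho, r1rho_sd]`` and CEST tables
``[probe, field_mhz, ph, b1_hz, offset_ppm, intensity, intensity_sd]``, where
``field_mhz`` is the Larmor frequency of the *observed* nucleus.  Weighted least
squares uses 1/SD^2 weights; rows lacking an SD get unit weight.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit, logit

from .exchange import (
    CESTScheme,
    ExchangeModel,
    Probe,
    RelaxParams,
    linear_three_state,
    simulate_cest,
    simulate_r1rho_grid,
    two_state,
)

R1RHO_COLUMNS = ["probe", "field_mhz", "ph", "power_hz", "offset_hz", "r1rho", "r1rho_sd"]
CEST_COLUMNS = ["probe", "field_mhz", "ph", "b1_hz", "offset_ppm", "intensity", "intensity_sd"]

DEFAULT_DELAYS = (0.0, 0.015, 0.030, 0.045, 0.060)


class UnderDeterminedError(ValueError):
    """Raised when a fit has fewer data points than free parameters."""


@dataclass
class FitResult:
    """Best-fit parameters with uncertainties and goodness-of-fit summaries."""

    params: dict[str, float]
    sds: dict[str, float]
    chi2: float
    n_points: int
    n_params: int
    converged: bool = True
    start_index: int = 0
    weights: dict[str, float] | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def reduced_chi2(self) -> float:
        dof = self.n_points - self.n_params
        if dof <= 0:
            raise ValueError("no degrees of freedom: n_points <= n_params")
        return self.chi2 / dof


def _relax(r1: float, r2: float) -> RelaxParams:
    """RelaxParams without the R2 < R1 warning (optimizers probe such values)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return RelaxParams(r1, r2)


def _weights(sd: pd.Series) -> np.ndarray:
    sd = pd.to_numeric(sd, errors="coerce")
    w = np.ones(len(sd))
    ok = sd.notna() & (sd > 0)
    w[ok.to_numpy()] = 1.0 / sd[ok].to_numpy() ** 2
    if not ok.all():
        warnings.warn("rows without SDs received unit weight", stacklevel=3)
    return w


def _probes_from_table(data: pd.DataFrame) -> dict[str, Probe]:
    out = {}
    for name, grp in data.groupby("probe", sort=False):
        fields = grp["field_mhz"].unique()
        out[str(name)] = Probe(str(name), float(fields[0]))
    return out


# ---------------------------------------------------------------------------
# Two-state global fit
# ---------------------------------------------------------------------------

def _default_starts(n_starts: int) -> list[tuple[float, float]]:
    """(k_ex, p) start points, log-spaced over the plausible exchange regime."""
    kex = np.geomspace(50.0, 5e4, max(2, int(np.ceil(np.sqrt(n_starts)))))
    p = np.geomspace(1e-4, 0.3, max(2, int(np.ceil(n_starts / len(kex)))))
    pairs = [(float(k), float(q)) for k in kex for q in p]
    return pairs[:n_starts]


def _dw_init_from_profile(grp: pd.DataFrame, larmor_mhz: float) -> float:
    """Start Delta-omega at the Rex-weighted centroid of the offset axis.

    The exchange contribution peaks near the minor-state resonance, so the
    centroid of the excess R1rho over its baseline gives a signed estimate of
    the shift difference.
    """
    off = grp["offset_hz"].to_numpy(dtype=float)
    pw = grp["power_hz"].to_numpy(dtype=float)
    r = grp["r1rho"].to_numpy(dtype=float)
    # strip the no-exchange tilt baseline R1 cos^2(theta) + R2 sin^2(theta)
    sin2 = pw**2 / (pw**2 + off**2)
    r1_0, r2_0 = max(r.min(), 0.0), np.quantile(r, 0.25)
    ex = np.clip(r - (r1_0 * (1 - sin2) + r2_0 * sin2), 0.0, None)
    if ex.sum() <= 0:
        return 1.0
    dw = float((ex * off).sum() / ex.sum()) / larmor_mhz
    return dw if abs(dw) > 0.2 else 1.0


def fit_two_state_global(
    data: pd.DataFrame,
    starts: Sequence[tuple[float, float]] | None = None,
    n_starts: int = 8,
    mc_iter: int = 0,
    seed: int | None = None,
    delays_s: Sequence[float] = DEFAULT_DELAYS,
    dw_init: Mapping[str, float] | None = None,
) -> FitResult:
    """Global two-state Bloch-McConnell fit sharing k_ex and p across probes.

    Each probe contributes its own Delta-omega, R1, and R2; ``k_ex`` and the
    minor-state population ``p`` are shared.  Rates and populations are fitted
    through log/logit transforms to keep them in range; the lowest-chi^2
    multi-start wins (ties broken by start index).  With ``mc_iter`` > 0 the
    parameter SDs come from parametric Monte Carlo resampling.
    """
    data = data.reset_index(drop=True)
    probes = _probes_from_table(data)
    names = list(probes)
    n_params = 2 + 3 * len(names)
    if len(data) < n_params:
        raise UnderDeterminedError(
            f"{len(data)} points cannot constrain {n_params} parameters"
        )
    if any((data.groupby("probe").size() < 6)):
        warnings.warn("fewer than 6 points for some probe", stacklevel=2)

    y = data["r1rho"].to_numpy(dtype=float)
    w = _weights(data["r1rho_sd"])
    sqw = np.sqrt(w)
    groups = {n: data.index[data["probe"] == n].to_numpy() for n in names}
    grids = {
        n: (
            data.loc[groups[n], "power_hz"].to_numpy(dtype=float),
            data.loc[groups[n], "offset_hz"].to_numpy(dtype=float),
        )
        for n in names
    }

    def unpack(x: np.ndarray):
        kex = float(np.exp(x[0]))
        p = float(expit(x[1]) * 0.5)
        per = {}
        for i, n in enumerate(names):
            dw, lr1, lr2 = x[2 + 3 * i : 5 + 3 * i]
            per[n] = (float(dw), float(np.exp(lr1)), float(np.exp(lr2)))
        return kex, p, per

    def predict(x: np.ndarray) -> np.ndarray:
        kex, p, per = unpack(x)
        pred = np.empty(len(data))
        for n in names:
            dw, r1, r2 = per[n]
            model = two_state(p, kex, dw)
            powers, offsets = grids[n]
            pred[groups[n]] = simulate_r1rho_grid(
                model, _relax(r1, r2), probes[n], powers, offsets,
                delays_s=delays_s,
            )
        return pred

    def residuals(x: np.ndarray) -> np.ndarray:
        return (predict(x) - y) * sqw

    def pack(kex: float, p: float, per: Mapping[str, tuple[float, float, float]]):
        x = np.empty(n_params)
        x[0] = np.log(kex)
        x[1] = logit(np.clip(p / 0.5, 1e-12, 1 - 1e-12))
        for i, n in enumerate(names):
            dw, r1, r2 = per[n]
            x[2 + 3 * i : 5 + 3 * i] = dw, np.log(r1), np.log(r2)
        return x

    # initial per-probe nuisance values
    per0 = {}
    for n in names:
        grp = data.loc[groups[n]]
        dw0 = dw_init[n] if dw_init and n in dw_init else _dw_init_from_profile(
            grp, probes[n].larmor_mhz
        )
        r2_0 = max(float(grp["r1rho"].min()), 0.5)
        per0[n] = (dw0, max(0.3 * r2_0, 0.2), r2_0)

    # bounds in transformed space keep the propagator in its stable range
    lb = np.full(n_params, -np.inf)
    ub = np.full(n_params, np.inf)
    lb[0], ub[0] = np.log(1.0), np.log(3e6)
    lb[1], ub[1] = -30.0, 30.0
    for i in range(len(names)):
        lb[2 + 3 * i], ub[2 + 3 * i] = -50.0, 50.0
        lb[3 + 3 * i : 5 + 3 * i] = np.log(1e-3)
        ub[3 + 3 * i : 5 + 3 * i] = np.log(1e4)

    # screen starts: for each (k_ex, p) candidate the chi^2 decomposes across
    # probes at fixed shared parameters, so each probe's starting Delta-omega is
    # picked independently from a candidate ladder (the Rex-centroid estimate
    # plus generic magnitudes of both signs) by direct evaluation; only the
    # best-ranked combined starts get full optimizer runs.
    if starts is not None:
        kp_candidates = list(starts)
        n_fit = len(kp_candidates)
    else:
        kp_candidates = _default_starts(max(n_starts, 8))
        n_fit = n_starts

    def probe_chi2(n: str, kex: float, p: float, dw: float, r1: float, r2: float):
        powers, offsets = grids[n]
        pred = simulate_r1rho_grid(
            two_state(p, kex, dw), _relax(r1, r2), probes[n], powers, offsets,
            delays_s=delays_s,
        )
        idx = groups[n]
        return float(np.sum(((pred - y[idx]) * sqw[idx]) ** 2))

    dw_cands = {
        n: sorted({round(s * m, 3) for s in (1.0, -1.0)
                   for m in (abs(per0[n][0]), 1.0, 2.0, 3.0)})
        for n in names
    }
    screened = []
    for i, (kex0, p0) in enumerate(kp_candidates):
        total = 0.0
        per_s = {}
        for n in names:
            _, r1_0, r2_0 = per0[n]
            c2, dw_best = min(
                (probe_chi2(n, kex0, p0, dw, r1_0, r2_0), dw) for dw in dw_cands[n]
            )
            per_s[n] = (dw_best, r1_0, r2_0)
            total += c2
        x0 = np.clip(pack(kex0, p0, per_s), lb + 1e-9, ub - 1e-9)
        screened.append((total, i, x0))
    screened.sort(key=lambda t: (t[0], t[1]))

    best = None
    for chi2_0, i, x0 in screened[:n_fit]:
        sol = least_squares(residuals, x0, method="trf", bounds=(lb, ub),
                            max_nfev=400)
        chi2 = float(sol.cost * 2)
        if best is None or chi2 < best[0] - 1e-12:
            best = (chi2, i, sol)
    chi2, start_idx, sol = best
    kex, p, per = unpack(sol.x)
    params = {"kex": kex, "p": p}
    for n in names:
        dw, r1, r2 = per[n]
        params[f"dw:{n}"] = dw
        params[f"r1:{n}"] = r1
        params[f"r2:{n}"] = r2
    result = FitResult(
        params=params,
        sds={k: 0.0 for k in params},
        chi2=chi2,
        n_points=len(data),
        n_params=n_params,
        converged=bool(sol.success),
        start_index=start_idx,
    )
    if not sol.success:
        result.flags.append("non-convergent")

    if mc_iter > 0:
        pred = predict(sol.x)
        sd = pd.to_numeric(data["r1rho_sd"], errors="coerce").fillna(0.0).to_numpy()

        def refit(y_new: np.ndarray) -> dict[str, float] | None:
            def res(x):
                return (predict(x) - y_new) * sqw
            s = least_squares(res, np.clip(sol.x, lb + 1e-9, ub - 1e-9),
                              method="trf", bounds=(lb, ub), max_nfev=80,
                              ftol=1e-6, xtol=1e-6)
            if not s.success and s.status <= 0:
                return None
            kex_i, p_i, per_i = unpack(s.x)
            out = {"kex": kex_i, "p": p_i}
            for n in names:
                dw, r1, r2 = per_i[n]
                out.update({f"dw:{n}": dw, f"r1:{n}": r1, f"r2:{n}": r2})
            return out

        sds, mc_flags = monte_carlo_uncertainty(refit, pred, sd, n_iter=mc_iter, seed=seed)
        result.sds.update(sds)
        result.flags.extend(mc_flags)
    return result


def monte_carlo_uncertainty(
    refit: Callable[[np.ndarray], dict[str, float] | None],
    predictions: np.ndarray,
    sds: np.ndarray,
    n_iter: int = 500,
    seed: int | None = None,
) -> tuple[dict[str, float], list[str]]:
    """Parametric Monte Carlo SDs: resample data from Normal(prediction, SD),
    refit, and return the spread of each refitted parameter.

    ``refit`` maps a resampled data vector to a parameter dict (or None on
    failure).  Failing iterations are dropped; if more than 20% fail, the result
    carries an ``"mc-unstable"`` flag.
    """
    rng = np.random.default_rng(seed)
    draws = []
    n_fail = 0
    for _ in range(n_iter):
        y_new = predictions + rng.normal(0.0, 1.0, size=predictions.shape) * sds
        out = refit(y_new)
        if out is None:
            n_fail += 1
        else:
            draws.append(out)
    flags = []
    if n_fail > 0.2 * n_iter:
        flags.append("mc-unstable")
    if not draws:
        return {}, flags + ["mc-empty"]
    keys = draws[0].keys()
    sds_out = {
        k: float(np.std([d[k] for d in draws], ddof=1)) if len(draws) > 1 else 0.0
        for k in keys
    }
    return sds_out, flags


# ---------------------------------------------------------------------------
# Constrained three-state fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThreeStateConstraints:
    """Fixed quantities of the linear GS <-> GS+ <-> ES2+ fit.

    The protonation step is pinned: its exchange rate at a given pH is
    ``k_ex,prot = k_prot * ([H+] + 10^-pKa_GS)`` with diffusion-limited
    ``k_prot``; the protonated-GS fraction of the GS pool follows the
    Henderson-Hasselbalch relation at ``pka_gs``; the ES2+ population follows
    the apparent pKa of the overall transition.
    """

    k_prot: float = 6.0e11
    pka_gs: float = 4.0
    pka_app_es2: float = 4.0
    dw_gsplus_init: Mapping[str, float] | None = None
    dw_es2plus_init: Mapping[str, float] | None = None

    def kex_prot(self, ph: float) -> float:
        return self.k_prot * (10.0 ** (-ph) + 10.0 ** (-self.pka_gs))

    def f_gsplus(self, ph: float) -> float:
        r = 10.0 ** (self.pka_gs - ph)
        return r / (1.0 + r)

    def populations(self, ph: float) -> np.ndarray:
        """Fractions (GS, GS+, ES2+) at the given pH."""
        f = self.f_gsplus(ph)
        r = 10.0 ** (self.pka_app_es2 - ph)  # [ES2+] / ([GS] + [GS+])
        p = np.array([(1.0 - f), f, r])
        return p / p.sum()


def three_state_model(
    constraints: ThreeStateConstraints,
    ph: float,
    kex_conf: float,
    dw_gsplus_ppm: float,
    dw_es2plus_ppm: float,
) -> ExchangeModel:
    """Linear GS <-> GS+ <-> ES2+ exchange model at one pH under the constraints."""
    pops = constraints.populations(ph)
    return linear_three_state(
        pops,
        constraints.kex_prot(ph),
        kex_conf,
        [0.0, dw_gsplus_ppm, dw_es2plus_ppm],
        labels=("GS", "GS+", "ES2+"),
    )


def fit_three_state_constrained(
    data: pd.DataFrame,
    constraints: ThreeStateConstraints,
    kex_conf_init: float = 500.0,
    share_relax_across_ph: bool = True,
    delays_s: Sequence[float] = DEFAULT_DELAYS,
) -> FitResult:
    """Constrained three-state global fit of a multi-pH R1rho dataset.

    Free parameters: the conformational exchange rate ``k_ex,conf`` (shared over
    probes and pH) and, per probe, the GS+ and ES2+ shift offsets plus R1/R2.
    The protonation step is pinned by ``constraints``.  A dataset whose pinned
    protonation rate falls below the fitted conformational rate is physically
    inverted and is flagged with a warning, not an error.
    """
    ph_values = sorted(data["ph"].unique())
    if len(ph_values) < 3:
        raise ValueError("need at least three pH values for the three-state fit")
    data = data.reset_index(drop=True)
    probes = _probes_from_table(data)
    names = list(probes)
    n_params = 1 + 4 * len(names)

    y = data["r1rho"].to_numpy(dtype=float)
    sqw = np.sqrt(_weights(data["r1rho_sd"]))
    blocks = []
    for n in names:
        for ph in ph_values:
            idx = data.index[(data["probe"] == n) & (data["ph"] == ph)].to_numpy()
            if idx.size:
                blocks.append(
                    (
                        n,
                        float(ph),
                        idx,
                        data.loc[idx, "power_hz"].to_numpy(dtype=float),
                        data.loc[idx, "offset_hz"].to_numpy(dtype=float),
                    )
                )

    def unpack(x):
        kex_conf = float(np.exp(x[0]))
        per = {}
        for i, n in enumerate(names):
            dwg, dwe, lr1, lr2 = x[1 + 4 * i : 5 + 4 * i]
            per[n] = (float(dwg), float(dwe), float(np.exp(lr1)), float(np.exp(lr2)))
        return kex_conf, per

    def residuals(x):
        kex_conf, per = unpack(x)
        pred = np.empty(len(data))
        for n, ph, idx, powers, offsets in blocks:
            dwg, dwe, r1, r2 = per[n]
            model = three_state_model(constraints, ph, kex_conf, dwg, dwe)
            pred[idx] = simulate_r1rho_grid(
                model, _relax(r1, r2), probes[n], powers, offsets,
                delays_s=delays_s,
            )
        return (pred - y) * sqw

    # starting shift offsets follow the standard prescription: the ES2+ offset
    # of each probe begins at the Delta-omega of a two-state fit of its
    # largest-Rex (lowest-pH) profile, and the GS+ offset begins at zero
    ph_low = min(ph_values)
    dw_rd: dict[str, float] = {}
    for n in names:
        if constraints.dw_es2plus_init and n in constraints.dw_es2plus_init:
            continue
        grp_low = data[(data["probe"] == n) & np.isclose(data["ph"], ph_low)]
        if len(grp_low) >= 8:
            try:
                two = fit_two_state_global(grp_low, n_starts=3, delays_s=delays_s)
                dw_rd[n] = two.params[f"dw:{n}"]
            except (UnderDeterminedError, ValueError):
                pass

    x0 = np.empty(n_params)
    x0[0] = np.log(kex_conf_init)
    for i, n in enumerate(names):
        grp = data[data["probe"] == n]
        grp_low = grp[np.isclose(grp["ph"], ph_low)]
        if constraints.dw_es2plus_init and n in constraints.dw_es2plus_init:
            dwe0 = constraints.dw_es2plus_init[n]
        elif n in dw_rd:
            dwe0 = dw_rd[n]
        else:
            dwe0 = _dw_init_from_profile(grp_low if len(grp_low) else grp,
                                         probes[n].larmor_mhz)
        dwg0 = (
            constraints.dw_gsplus_init[n]
            if constraints.dw_gsplus_init and n in constraints.dw_gsplus_init
            else 0.0
        )
        r2_0 = max(float(grp["r1rho"].min()), 0.5)
        x0[1 + 4 * i : 5 + 4 * i] = dwg0, dwe0, np.log(max(0.3 * r2_0, 0.2)), np.log(r2_0)

    lb = np.full(n_params, -np.inf)
    ub = np.full(n_params, np.inf)
    lb[0], ub[0] = np.log(1.0), np.log(3e6)
    for i in range(len(names)):
        lb[1 + 4 * i : 3 + 4 * i], ub[1 + 4 * i : 3 + 4 * i] = -50.0, 50.0
        lb[3 + 4 * i : 5 + 4 * i] = np.log(1e-3)
        ub[3 + 4 * i : 5 + 4 * i] = np.log(1e4)

    # screen ES2+ shift-sign combinations and a log-spaced k_ex,conf ladder
    sign_combos = (
        list(itertools.product((1.0, -1.0), repeat=len(names)))
        if len(names) <= 3
        else [(1.0,) * len(names), (-1.0,) * len(names)]
    )
    screened = []
    for kex0 in np.geomspace(100.0, 3000.0, 4):
        for signs in sign_combos:
            xs = x0.copy()
            xs[0] = np.log(kex0)
            for i, s in enumerate(signs):
                xs[2 + 4 * i] *= s
            xs = np.clip(xs, lb + 1e-9, ub - 1e-9)
            screened.append((float(np.sum(residuals(xs) ** 2)), xs))
    screened.sort(key=lambda t: t[0])

    sol = None
    for chi2_0, xs in screened[:2]:
        s = least_squares(residuals, xs, method="trf", bounds=(lb, ub), max_nfev=600)
        if sol is None or float(s.cost) < float(sol.cost) - 1e-12:
            sol = s
    kex_conf, per = unpack(sol.x)
    chi2 = float(sol.cost * 2)

    params = {"kex_conf": kex_conf}
    for n in names:
        dwg, dwe, r1, r2 = per[n]
        params.update({f"dw_gsplus:{n}": dwg, f"dw_es2plus:{n}": dwe,
                       f"r1:{n}": r1, f"r2:{n}": r2})
    result = FitResult(
        params=params,
        sds={k: 0.0 for k in params},
        chi2=chi2,
        n_points=len(data),
        n_params=n_params,
        converged=bool(sol.success),
    )
    min_kex_prot = min(constraints.kex_prot(float(ph)) for ph in ph_values)
    if min_kex_prot < kex_conf:
        warnings.warn(
            "pinned protonation exchange is slower than the fitted conformational "
            "exchange (mechanism inversion)",
            stacklevel=2,
        )
        result.flags.append("mechanism-inversion")
    # per-probe reduced chi2 diagnostics
    res = residuals(sol.x)
    for n in names:
        idx = data.index[data["probe"] == n].to_numpy()
        dof = max(idx.size - n_params / len(names), 1)
        result.params[f"rchi2:{n}"] = float((res[idx] ** 2).sum() / dof)
        result.sds[f"rchi2:{n}"] = 0.0
    return result


# ---------------------------------------------------------------------------
# CEST fit and model selection
# ---------------------------------------------------------------------------

def _cest_scheme_from_table(data: pd.DataFrame, **scheme_kw) -> tuple[CESTScheme, np.ndarray, np.ndarray]:
    b1 = np.array(sorted(data["b1_hz"].unique()), dtype=float)
    offs = np.array(sorted(data["offset_ppm"].unique()), dtype=float)
    scheme = CESTScheme(tuple(b1), tuple(offs), **scheme_kw)
    ib1 = np.searchsorted(b1, data["b1_hz"].to_numpy(dtype=float))
    ioff = np.searchsorted(offs, data["offset_ppm"].to_numpy(dtype=float))
    return scheme, ib1, ioff


def fit_cest(
    data: pd.DataFrame,
    mode: str = "with-exchange",
    dw_init: float = -2.8,
    t_relax_s: float = 0.100,
    b1_inhomogeneity: float = 0.10,
    n_quad: int = 5,
) -> FitResult:
    """Two-state Bloch-McConnell fit of a CEST profile.

    ``mode='with-exchange'`` frees (p, k_ex, dw, R1, R2); ``mode='no-exchange'``
    pins p = k_ex = dw = 0 and fits only (R1, R2).  Parameter SEMs come from the
    diagonal of the covariance matrix (J^T J)^-1 of the weighted fit.
    """
    if mode not in ("with-exchange", "no-exchange"):
        raise ValueError(f"unknown CEST fit mode {mode!r}")
    data = data.reset_index(drop=True)
    probes = _probes_from_table(data)
    if len(probes) != 1:
        raise ValueError("fit_cest expects a single-probe profile")
    probe = next(iter(probes.values()))
    scheme, ib1, ioff = _cest_scheme_from_table(
        data, t_relax_s=t_relax_s,
        b1_inhomogeneity=b1_inhomogeneity, n_quad=n_quad,
    )
    y = data["intensity"].to_numpy(dtype=float)
    sqw = np.sqrt(_weights(data["intensity_sd"]))

    if y.max() - y.min() < 1e-3:
        flags = ["degenerate-profile"]
    elif y.max() < 0.05:
        flags = ["all-saturated"]
    else:
        flags = []

    with_exchange = mode == "with-exchange"

    def predict(theta: np.ndarray) -> np.ndarray:
        if with_exchange:
            p, kex, dw, r1, r2 = theta
        else:
            p, kex, dw = 0.0, 0.0, 0.0
            r1, r2 = theta
        model = two_state(p, kex, dw)
        grid = simulate_cest(model, _relax(r1, r2), probe, scheme)
        return grid[ib1, ioff]

    def residuals(theta):
        return (predict(theta) - y) * sqw

    # crude initial relaxation guesses from the far-off-resonance plateau
    plateau = float(np.quantile(y, 0.9))
    r1_0 = max(-np.log(max(plateau, 1e-3)) / scheme.t_relax_s, 0.1)
    if with_exchange:
        theta0 = np.array([0.01, 500.0, dw_init, r1_0, 10.0 * r1_0])
        lb = [0.0, 0.0, -np.inf, 1e-3, 1e-3]
        ub = [0.5, 1e6, np.inf, np.inf, np.inf]
        pnames = ["p", "kex", "dw", "r1", "r2"]
    else:
        theta0 = np.array([r1_0, 10.0 * r1_0])
        lb = [1e-3, 1e-3]
        ub = [np.inf, np.inf]
        pnames = ["r1", "r2"]

    sol = least_squares(residuals, theta0, bounds=(lb, ub), max_nfev=300)
    chi2 = float(sol.cost * 2)

    # covariance from the weighted jacobian
    J = sol.jac
    try:
        cov = np.linalg.inv(J.T @ J)
        sems = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        sems = np.full(len(pnames), np.nan)
        flags.append("singular-covariance")

    params = dict(zip(pnames, map(float, sol.x)))
    sds = dict(zip(pnames, map(float, sems)))
    if not with_exchange:
        params.update({"p": 0.0, "kex": 0.0, "dw": 0.0})
        sds.update({"p": 0.0, "kex": 0.0, "dw": 0.0})
    return FitResult(
        params=params,
        sds=sds,
        chi2=chi2,
        n_points=len(data),
        n_params=len(pnames),
        converged=bool(sol.success),
        flags=flags,
    )


def model_weights(fit_exch: FitResult, fit_null: FitResult) -> dict[str, float]:
    """Akaike and Bayesian information-criterion weights for exchange vs null.

    Uses AIC = chi^2 + 2k and BIC = chi^2 + k ln n on the weighted chi^2 scale.
    Returns ``{"waic_exchange", "waic_null", "wbic_exchange", "wbic_null"}``;
    each pair sums to one.
    """
    if fit_exch.n_points != fit_null.n_points:
        raise ValueError("model weights require fits of the identical dataset")
    n = fit_exch.n_points
    out = {}
    for crit, penalty in (("aic", lambda k: 2.0 * k), ("bic", lambda k: k * np.log(n))):
        ic_e = fit_exch.chi2 + penalty(fit_exch.n_params)
        ic_n = fit_null.chi2 + penalty(fit_null.n_params)
        m = min(ic_e, ic_n)
        we = np.exp(-(ic_e - m) / 2.0)
        wn = np.exp(-(ic_n - m) / 2.0)
        out[f"w{crit}_exchange"] = float(we / (we + wn))
        out[f"w{crit}_null"] = float(wn / (we + wn))
    return out
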